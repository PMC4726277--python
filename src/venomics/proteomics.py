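"""PSM filtering and peptide-to-protein mapping.

PSMs pass on charge-dependent Xcorr thresholds plus a deltaCn floor (all
inclusive).  Passing peptides are mapped onto the predicted protein database
by exact substring match, optionally requiring tryptic boundaries.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "PSM",
    "ProteinEvidence",
    "DEFAULT_XCORR_MIN",
    "DCN_MIN",
    "filter_psms",
    "map_peptides",
    "infer_proteins",
    "read_psm_table",
    "write_psm_table",
]

DCN_MIN = 0.1
DEFAULT_XCORR_MIN = {1: 1.9, 2: 2.2, 3: 3.75}
MAX_MISSED_CLEAVAGES = 2

# average residue masses (Da), used only by the optional gel-slice check
_AVG_MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "E": 129.12, "Q": 128.13, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}
_WATER = 18.02


@dataclass(frozen=True)
class PSM:
    peptide: str
    charge: int
    xcorr: float
    delta_cn: float
    slice: Optional[int] = None

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        bad = set(self.peptide) - set(_AVG_MASS)
        if bad:
            raise ValueError(f"peptide has non-standard residues {sorted(bad)}")


@dataclass
class ProteinEvidence:
    transcript_id: str
    peptides: set = field(default_factory=set)
    ambiguous: bool = False

    @property
    def n_unique_peptides(self) -> int:
        return len(self.peptides)


def filter_psms(
    psms: Sequence[PSM],
    dcn_min: float = DCN_MIN,
    xcorr_min: Mapping[int, float] = DEFAULT_XCORR_MIN,
) -> list[PSM]:
    """Keep PSMs with delta_cn >= dcn_min and xcorr >= the charge threshold.

    Charges above the highest threshold key use that key's threshold.
    """
    max_charge = max(xcorr_min)
    out = []
    for psm in psms:
        threshold = xcorr_min[min(psm.charge, max_charge)]
        if psm.delta_cn >= dcn_min and psm.xcorr >= threshold:
            out.append(psm)
    return out


def _tryptic_boundaries(protein: str, start: int, end: int) -> bool:
    """Both peptide boundaries coincide with tryptic cut sites or termini."""
    left_ok = start == 0 or (protein[start - 1] in "KR" and protein[start] != "P")
    right_ok = end == len(protein) or (
        protein[end - 1] in "KR" and protein[end] != "P"
    )
    return left_ok and right_ok


def _missed_cleavages(peptide: str) -> int:
    return sum(
        1
        for i in range(len(peptide) - 1)
        if peptide[i] in "KR" and peptide[i + 1] != "P"
    )


def map_peptides(
    peptides: Sequence[str],
    proteins: Mapping[str, str],
    enzyme_consistent: bool = True,
    max_missed_cleavages: int = MAX_MISSED_CLEAVAGES,
) -> list[ProteinEvidence]:
    """Map peptides onto proteins by exact substring match.

    With ``enzyme_consistent`` (default) a match must sit on tryptic
    boundaries and contain at most ``max_missed_cleavages`` internal cut
    sites.  Peptides hitting more than one protein mark every target
    ambiguous.
    """
    if not proteins:
        raise ValueError("protein database is empty")
    evidence: dict[str, ProteinEvidence] = {}
    for peptide in dict.fromkeys(peptides):  # unique, input order
        if enzyme_consistent and _missed_cleavages(peptide) > max_missed_cleavages:
            continue
        targets = []
        for tid, protein in proteins.items():
            pos = protein.find(peptide)
            while pos != -1:
                if not enzyme_consistent or _tryptic_boundaries(
                    protein, pos, pos + len(peptide)
                ):
                    targets.append(tid)
                    break
                pos = protein.find(peptide, pos + 1)
        for tid in targets:
            rec = evidence.setdefault(tid, ProteinEvidence(tid))
            rec.peptides.add(peptide)
            if len(targets) > 1:
                rec.ambiguous = True
    return list(evidence.values())


def infer_proteins(
    evidence: Sequence[ProteinEvidence], min_peptides: int = 1
) -> set[str]:
    """Transcripts confirmed by at least ``min_peptides`` passing peptides."""
    return {
        e.transcript_id for e in evidence if e.n_unique_peptides >= min_peptides
    }


def protein_mass(protein: str) -> float:
    """Average molecular mass in Da (used by the optional gel-slice check)."""
    return sum(_AVG_MASS[r] for r in protein) + _WATER


# ---------------------------------------------------------------------------
# TSV interfaces

def read_psm_table(path) -> list[PSM]:
    psms = []
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            raw_slice = row.get("slice") or None
            psms.append(
                PSM(
                    peptide=row["peptide"],
                    charge=int(row["charge"]),
                    xcorr=float(row["xcorr"]),
                    delta_cn=float(row["delta_cn"]),
                    slice=int(raw_slice) if raw_slice else None,
                )
            )
    return psms


def write_psm_table(path, psms: Sequence[PSM]) -> None:
    with open(path, "w") as handle:
        handle.write("peptide\tcharge\txcorr\tdelta_cn\tslice\n")
        for p in psms:
            raw_slice = "" if p.slice is None else str(p.slice)
            handle.write(
                f"{p.peptide}\t{p.charge}\t{p.xcorr:.4f}\t{p.delta_cn:.4f}\t{raw_slice}\n"
            )


def write_confirmed(path, evidence: Sequence[ProteinEvidence]) -> None:
    with open(path, "w") as handle:
        handle.write("transcript_id\tn_unique_peptides\tambiguous\n")
        for e in sorted(evidence, key=lambda x: x.transcript_id):
            handle.write(f"{e.transcript_id}\t{e.n_unique_peptides}\t{e.ambiguous}\n")
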
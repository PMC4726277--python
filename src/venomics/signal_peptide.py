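"""Secretion-signal calling.

Three routes produce :class:`SignalCall` objects: annotation transfer through
best hits with complete N-termini, a built-in weight-matrix/hydropathy
heuristic, and a reader for external predictor output.  ``has_sp`` is a
three-state value: True, False, or None (undetermined).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional, Sequence

from .seq_utils import BestHit, TranscriptRecord

__all__ = [
    "SignalCall",
    "has_complete_n_terminus",
    "transfer_signal_call",
    "local_signal_score",
    "concordance",
    "read_reference_table",
    "read_external_calls",
    "resolve_calls",
]

MIN_PROTEIN_LEN = 15
CLEAVAGE_MIN, CLEAVAGE_MAX = 10, 40
N_REGION_LEN = 5
H_WINDOW = 8
H_MIN_HYDROPATHY = 1.6
SMALL_RESIDUES = set("AGSCTV")  # allowed at the -3 and -1 positions

# Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass
class SignalCall:
    transcript_id: str
    has_sp: Optional[bool]
    method: str  # transfer | local | external
    cleavage_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.cleavage_pos is not None:
            if not self.has_sp:
                raise ValueError("cleavage_pos requires has_sp=True")
            if not CLEAVAGE_MIN <= self.cleavage_pos <= CLEAVAGE_MAX:
                raise ValueError(
                    f"cleavage_pos {self.cleavage_pos} outside "
                    f"[{CLEAVAGE_MIN}, {CLEAVAGE_MAX}]"
                )


def has_complete_n_terminus(hit: BestHit) -> bool:
    """A transcript covers its subject's N-terminus iff s_start == 1."""
    return hit.s_start == 1


def transfer_signal_call(
    record: TranscriptRecord, ref: dict[str, tuple[bool, Optional[int]]]
) -> SignalCall:
    """Transfer the reference annotation of the best-hit subject."""
    if record.best_hit is None or record.best_hit.subject_id not in ref:
        return SignalCall(record.id, None, "transfer")
    has_sp, cleavage = ref[record.best_hit.subject_id]
    return SignalCall(record.id, has_sp, "transfer", cleavage if has_sp else None)


def _charge(residues: str) -> int:
    return sum(+1 if r in "KR" else -1 if r in "DE" else 0 for r in residues)


def _best_h_window(protein: str, site: int) -> Optional[float]:
    """Max mean hydropathy over 8-residue windows in residues 2..site-3.

    Residue indices are 1-based; returns None when no window fits or the
    best window falls below the hydropathy floor.
    """
    lo, hi = 2, site - 3  # 1-based inclusive span available to the h-region
    best = None
    for start in range(lo, hi - H_WINDOW + 2):
        window = protein[start - 1 : start - 1 + H_WINDOW]
        mean_h = sum(KYTE_DOOLITTLE.get(r, -4.5) for r in window) / H_WINDOW
        if best is None or mean_h > best:
            best = mean_h
    if best is None or best < H_MIN_HYDROPATHY:
        return None
    return best


def local_signal_score(protein: str, transcript_id: str = "") -> SignalCall:
    """Heuristic signal-peptide call on a predicted protein.

    A candidate cleavage site (last residue of the signal) at position
    10..40 qualifies when (i) the net charge of residues 1..5 is >= 0,
    (ii) an 8-residue window within residues 2..site-3 has mean
    Kyte-Doolittle hydropathy >= 1.6, and (iii) the residues at the -3 and
    -1 positions are small (A/G/S/C/T/V).  The reported cleavage position is
    the qualifying site with the most hydrophobic h-window (earliest on
    ties).  Proteins shorter than 15 aa are undetermined.
    """
    if len(protein) < MIN_PROTEIN_LEN:
        return SignalCall(transcript_id, None, "local")
    if _charge(protein[:N_REGION_LEN]) < 0:
        return SignalCall(transcript_id, False, "local")
    best_site = None
    best_score = None
    for site in range(CLEAVAGE_MIN, min(CLEAVAGE_MAX, len(protein) - 1) + 1):
        minus3 = protein[site - 3]  # 0-based index of 1-based position site-2
        minus1 = protein[site - 1]
        if minus3 not in SMALL_RESIDUES or minus1 not in SMALL_RESIDUES:
            continue
        score = _best_h_window(protein, site)
        if score is None:
            continue
        if best_score is None or score > best_score:
            best_score = score
            best_site = site
    if best_site is None:
        return SignalCall(transcript_id, False, "local")
    return SignalCall(transcript_id, True, "local", best_site)


def concordance(calls_a: Sequence[SignalCall], calls_b: Sequence[SignalCall]) -> float:
    """Fraction of ids with equal has_sp among those determined in both."""
    by_id_a = {c.transcript_id: c.has_sp for c in calls_a}
    by_id_b = {c.transcript_id: c.has_sp for c in calls_b}
    common = set(by_id_a) & set(by_id_b)
    if not common:
        raise ValueError("call sets share no transcript ids")
    determined = [
        i for i in common if by_id_a[i] is not None and by_id_b[i] is not None
    ]
    if not determined:
        raise ValueError("no transcript determined in both call sets")
    agree = sum(by_id_a[i] == by_id_b[i] for i in determined)
    return agree / len(determined)


def resolve_calls(
    transfer: Sequence[SignalCall],
    local: Sequence[SignalCall],
    precedence: str = "transfer",
) -> list[SignalCall]:
    """Merge two call sets; the preceding method wins where it is determined."""
    if precedence not in ("transfer", "local"):
        raise ValueError("precedence must be 'transfer' or 'local'")
    first, second = (transfer, local) if precedence == "transfer" else (local, transfer)
    by_id = {c.transcript_id: c for c in second}
    merged: dict[str, SignalCall] = dict(by_id)
    for call in first:
        existing = merged.get(call.transcript_id)
        if call.has_sp is not None or existing is None:
            merged[call.transcript_id] = call
    return list(merged.values())


# ---------------------------------------------------------------------------
# TSV interfaces

def read_reference_table(path) -> dict[str, tuple[bool, Optional[int]]]:
    """Reference annotations: subject_id, has_sp, cleavage_pos (optional)."""
    table: dict[str, tuple[bool, Optional[int]]] = {}
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            cleavage = row.get("cleavage_pos") or None
            table[row["subject_id"]] = (
                row["has_sp"].strip().lower() in ("1", "true", "yes"),
                int(cleavage) if cleavage else None,
            )
    return table


def read_external_calls(path) -> list[SignalCall]:
    """External predictor output: transcript_id, has_sp, cleavage_pos."""
    calls = []
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            raw = row["has_sp"].strip().lower()
            has_sp = None if raw in ("", "na", "none") else raw in ("1", "true", "yes")
            cleavage = row.get("cleavage_pos") or None
            calls.append(
                SignalCall(
                    row["transcript_id"],
                    has_sp,
                    "external",
                    int(cleavage) if (cleavage and has_sp) else None,
                )
            )
    return calls


def write_calls(path, calls: Sequence[SignalCall]) -> None:
    with open(path, "w") as handle:
        handle.write("transcript_id\thas_sp\tmethod\tcleavage_pos\n")
        for c in calls:
            sp = "" if c.has_sp is None else str(c.has_sp)
            pos = "" if c.cleavage_pos is None else str(c.cleavage_pos)
            handle.write(f"{c.transcript_id}\t{sp}\t{c.method}\t{pos}\n")
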
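"""Synthetic input generation with planted ground truth.

Every file the pipeline consumes can be produced here: a transcriptome whose
venom genes carry constructed secretion signals, a two-tissue count table
drawn from a negative-binomial model, a PSM table whose passing peptides are
exact tryptic fragments of the predicted venom proteins, and similarity
tables engineered to reproduce a chosen three-set Venn design.

All randomness flows from ``SimulationConfig.seed`` through per-stage child
seeds, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from . import seq_utils
from .seq_utils import TranscriptRecord, tryptic_digest
from .proteomics import PSM, write_psm_table
from .venom_compare import OUTFMT6_COLUMNS

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigError",
    "generate_transcriptome",
    "generate_counts",
    "generate_psm_table",
    "generate_homology_tables",
    "simulate_all",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# mature/background regions model soluble (non-secreted) proteins: strongly
# hydrophobic residues are down-weighted so sustained h-region-like windows
# arise rarely outside planted signals
_BACKGROUND_WEIGHTS = np.array(
    [0.5 if aa in "ILVF" else 1.0 for aa in AA_ALPHABET]
)
_BACKGROUND_WEIGHTS = _BACKGROUND_WEIGHTS / _BACKGROUND_WEIGHTS.sum()

# codon choices per residue (standard table, no ambiguity)
_CODONS: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()
_STOPS = sorted(standard_dna_table.stop_codons)

# score sampling bands for the engineered similarity tables: shared pairs get
# bit scores on [55, 300], unshared on [20, 45]; e-value = 10^(-bit/10)
_BIT_SHARED = (55.0, 300.0)
_BIT_UNSHARED = (20.0, 45.0)


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimulationConfig:
    n_transcripts: int = 200
    n_venom: int = 20
    fold_change_venom: float = 8.0
    library_size_vg: int = 5_000_000
    library_size_carcass: int = 5_000_000
    dispersion: float = 0.05
    sp_fraction_background: float = 0.05
    psm_depth: float = 3.0
    venn_design: tuple[int, int, int, int] = (5, 5, 5, 5)
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 1:
            raise ConfigError("n_transcripts must be >= 1")
        if not 0 <= self.n_venom <= self.n_transcripts:
            raise ConfigError("n_venom must be in [0, n_transcripts]")
        if self.fold_change_venom <= 0:
            raise ConfigError("fold_change_venom must be positive")
        if self.library_size_vg <= 0:
            raise ConfigError("library_size_vg must be positive")
        if self.library_size_carcass <= 0:
            raise ConfigError("library_size_carcass must be positive")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        if not 0 <= self.sp_fraction_background <= 1:
            raise ConfigError("sp_fraction_background must be in [0, 1]")
        if self.psm_depth < 0:
            raise ConfigError("psm_depth must be non-negative")
        if len(self.venn_design) != 4 or any(v < 0 for v in self.venn_design):
            raise ConfigError("venn_design must be four non-negative counts")
        if sum(self.venn_design) != self.n_venom:
            raise ConfigError("venn_design must sum to n_venom")


@dataclass
class GroundTruth:
    venom_ids: set = field(default_factory=set)
    sp_ids: set = field(default_factory=set)
    psm_supported_ids: set = field(default_factory=set)
    venn_labels: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "venom_ids": sorted(self.venom_ids),
                "sp_ids": sorted(self.sp_ids),
                "psm_supported_ids": sorted(self.psm_supported_ids),
                "venn_labels": dict(sorted(self.venn_labels.items())),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(
            venom_ids=set(raw["venom_ids"]),
            sp_ids=set(raw["sp_ids"]),
            psm_supported_ids=set(raw["psm_supported_ids"]),
            venn_labels=dict(raw["venn_labels"]),
        )


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, config.seed])


def _sample_protein(
    rng: np.random.Generator, length: int, weights: Optional[np.ndarray] = None
) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length, p=weights))


def _sample_signal_peptide(rng: np.random.Generator) -> str:
    """A textbook-compliant signal: charged n-region, hydrophobic h-region,
    small residues at the -3 and -1 positions of the c-region."""
    n_region = "M" + "".join(rng.choice(list("KR"), size=rng.integers(1, 4)))
    h_region = "".join(rng.choice(list("LIVF"), size=rng.integers(8, 13)))
    mid = "".join(rng.choice(list("AGST"), size=rng.integers(0, 3)))
    c_region = mid + rng.choice(list("AGS")) + rng.choice(list("QNHL")) + rng.choice(list("AGS"))
    return n_region + h_region + c_region


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [rng.choice(_CODONS[aa]) for aa in protein]
    codons.append(rng.choice(_STOPS))
    return "".join(codons)


def _random_utr(rng: np.random.Generator, min_codons: int = 3, max_codons: int = 10) -> str:
    n = int(rng.integers(min_codons, max_codons + 1))
    return "".join(rng.choice(list("ACGT"), size=3 * n))


def _build_transcript(rng: np.random.Generator, protein: str) -> str:
    """Embed a protein-coding ORF between UTRs.

    The 5' UTR is a codon multiple ending in an in-frame stop, so the ORF's
    stop-free segment starts exactly at the initiator Met.
    """
    utr5 = _random_utr(rng) + "TAA"
    utr3 = _random_utr(rng)
    return utr5 + _reverse_translate(rng, protein) + utr3


def generate_transcriptome(
    config: SimulationConfig,
) -> tuple[list[TranscriptRecord], GroundTruth]:
    """Simulate transcripts and the planted truth about them."""
    config.validate()
    rng = _stage_rng(config, 0)
    ids = [f"syn{i:05d}_c0" for i in range(config.n_transcripts)]
    venom_ids = sorted(
        str(x)
        for x in np.array(ids)[rng.permutation(config.n_transcripts)[: config.n_venom]]
    )
    venom_set = set(venom_ids)

    truth = GroundTruth(venom_ids=venom_set)
    records = []
    for tid in ids:
        is_venom = tid in venom_set
        has_sp = is_venom or rng.random() < config.sp_fraction_background
        mature_len = int(rng.integers(80, 221))
        if has_sp:
            protein = _sample_signal_peptide(rng) + _sample_protein(
                rng, mature_len, _BACKGROUND_WEIGHTS
            )
            truth.sp_ids.add(tid)
        else:
            protein = "M" + _sample_protein(rng, mature_len, _BACKGROUND_WEIGHTS)
        records.append(TranscriptRecord(tid, _build_transcript(rng, protein)))

    truth.psm_supported_ids = set(venom_set)
    shuffled = [str(x) for x in np.array(venom_ids)[rng.permutation(len(venom_ids))]]
    labels = []
    for label, count in zip(("unique", "nv_only", "oep_only", "both"), config.venn_design):
        labels.extend([label] * count)
    truth.venn_labels = dict(zip(shuffled, labels))
    return records, truth


def generate_counts(
    config: SimulationConfig,
    truth: GroundTruth,
    records: Sequence[TranscriptRecord],
) -> pd.DataFrame:
    """Two-tissue count table from a negative-binomial model.

    Venom genes have expected FPKM ratio ``fold_change_venom`` with expected
    venom-gland FPKM well above 10; background genes share one mean across
    tissues.  ``dispersion`` = 0 gives counts equal to their rounded
    expectations.
    """
    config.validate()
    rng = _stage_rng(config, 1)
    rows = []
    for rec in records:
        eff_len = float(len(rec.sequence))
        if rec.id in truth.venom_ids:
            # narrow carcass base keeps the venom excess small relative to
            # the library, so realised FPKM ratios stay near the design fold
            fpkm_car = rng.uniform(7.0, 20.0)
            fpkm_vg = fpkm_car * config.fold_change_venom
        else:
            fpkm_vg = fpkm_car = float(rng.lognormal(mean=np.log(20.0), sigma=1.0))
        mu_vg = fpkm_vg * eff_len * config.library_size_vg / 1e9
        mu_car = fpkm_car * eff_len * config.library_size_carcass / 1e9
        if config.dispersion == 0:
            count_vg, count_car = int(round(mu_vg)), int(round(mu_car))
        else:
            # gamma-Poisson mixture = NB with var mu + dispersion*mu^2;
            # dispersion -> 0 approaches Poisson sampling smoothly
            shape = 1.0 / config.dispersion
            count_vg = int(rng.poisson(rng.gamma(shape, config.dispersion * mu_vg)))
            count_car = int(rng.poisson(rng.gamma(shape, config.dispersion * mu_car)))
        rows.append(
            {
                "transcript_id": rec.id,
                "count_vg": count_vg,
                "count_carcass": count_car,
                "effective_length": eff_len,
            }
        )
    return pd.DataFrame(rows)


def generate_psm_table(
    config: SimulationConfig,
    truth: GroundTruth,
    proteins: Mapping[str, Optional[str]],
    n_decoys: Optional[int] = None,
) -> list[PSM]:
    """PSMs for psm-supported proteins plus sub-threshold decoys.

    Each supported protein gets >= 1 PSM whose peptide is an exact tryptic
    fragment and whose scores pass the charge-dependent thresholds.  Decoys
    are random peptides with deltaCn below the 0.1 floor.  Proteins without
    a tryptic peptide of length >= 6 are skipped with a warning.
    """
    config.validate()
    rng = _stage_rng(config, 2)
    psms = []
    for tid in sorted(truth.psm_supported_ids):
        protein = proteins.get(tid)
        if not protein:
            warnings.warn(f"{tid}: no predicted protein, skipped")
            continue
        peptides = [p for p in tryptic_digest(protein, 0, 6) if set(p) <= set(AA_ALPHABET)]
        if not peptides:
            warnings.warn(f"{tid}: no tryptic peptide of length >= 6, skipped")
            continue
        k = max(1, int(rng.poisson(config.psm_depth)))
        chosen = rng.choice(peptides, size=min(k, len(peptides)), replace=False)
        for pep in chosen:
            charge = int(rng.choice([2, 3]))
            threshold = {1: 1.9, 2: 2.2, 3: 3.75}[charge]
            psms.append(
                PSM(
                    peptide=str(pep),
                    charge=charge,
                    xcorr=float(threshold + rng.uniform(0.05, 2.0)),
                    delta_cn=float(rng.uniform(0.1, 0.4)),
                    slice=int(rng.integers(1, 22)),
                )
            )
    if n_decoys is None:
        n_decoys = max(10, len(psms) // 2)
    for _ in range(n_decoys):
        pep = _sample_protein(rng, int(rng.integers(8, 16)))
        psms.append(
            PSM(
                peptide=pep,
                charge=int(rng.choice([1, 2, 3])),
                xcorr=float(rng.uniform(0.5, 5.0)),
                delta_cn=float(rng.uniform(0.0, 0.095)),
                slice=int(rng.integers(1, 22)),
            )
        )
    order = rng.permutation(len(psms))
    return [psms[i] for i in order]


def _hit_row(
    rng: np.random.Generator, qid: str, sid: str, passing: bool
) -> dict:
    lo, hi = _BIT_SHARED if passing else _BIT_UNSHARED
    bit = round(float(rng.uniform(lo, hi)), 1)
    length = int(rng.integers(80, 301))
    pident = round(float(rng.uniform(30.0, 95.0)), 2)
    return {
        "qseqid": qid,
        "sseqid": sid,
        "pident": pident,
        "length": length,
        "mismatch": int(round(length * (1 - pident / 100))),
        "gapopen": int(rng.integers(0, 3)),
        "qstart": 1,
        "qend": length,
        "sstart": 1,
        "send": length,
        "evalue": 10.0 ** (-bit / 10.0),
        "bitscore": bit,
    }


def generate_homology_tables(
    config: SimulationConfig,
    truth: GroundTruth,
    n_nv: int = 79,
    n_nv_oep_shared: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Similarity tables engineered to realise ``truth.venn_labels``.

    Shared pairs get scores above the dual cutoff, unshared pairs scores
    below it, and queries labelled ``unique`` get no rows at all, so the
    compare module recovers the planted Venn design exactly.  Also emits a
    reference-vs-reference table (``n_nv`` queries, ``n_nv_oep_shared``
    passing) used by the enrichment comparison.
    """
    config.validate()
    rng = _stage_rng(config, 3)
    nv_rows, oep_rows = [], []
    for i, tid in enumerate(sorted(truth.venn_labels)):
        label = truth.venn_labels[tid]
        if label == "unique":
            continue
        nv_rows.append(_hit_row(rng, tid, f"NVP{i:04d}", label in ("nv_only", "both")))
        oep_rows.append(_hit_row(rng, tid, f"OEP{i:04d}", label in ("oep_only", "both")))
    nv_oep_rows = [
        _hit_row(rng, f"NVQ{i:04d}", f"OEP{i + 5000:04d}", i < n_nv_oep_shared)
        for i in range(n_nv)
    ]
    empty = pd.DataFrame(columns=OUTFMT6_COLUMNS)

    def frame(rows):
        return pd.DataFrame(rows, columns=OUTFMT6_COLUMNS) if rows else empty.copy()

    return frame(nv_rows), frame(oep_rows), frame(nv_oep_rows)


def write_outfmt6(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def simulate_all(config: SimulationConfig, outdir) -> GroundTruth:
    """Generate and write every pipeline input under ``outdir``.

    Files: transcripts.fasta, counts.tsv, psms.tsv, pp_vs_nv.tsv,
    pp_vs_oep.tsv, nv_vs_oep.tsv, ground_truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = generate_transcriptome(config)
    seq_utils.write_fasta(
        outdir / "transcripts.fasta", [(r.id, r.sequence) for r in records]
    )
    counts = generate_counts(config, truth, records)
    counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
    proteins = {
        tid: seq_utils.predict_orf(rec)
        for tid, rec in ((r.id, r) for r in records)
        if tid in truth.psm_supported_ids
    }
    psms = generate_psm_table(config, truth, proteins)
    write_psm_table(outdir / "psms.tsv", psms)
    nv, oep, nv_oep = generate_homology_tables(config, truth)
    write_outfmt6(outdir / "pp_vs_nv.tsv", nv)
    write_outfmt6(outdir / "pp_vs_oep.tsv", oep)
    write_outfmt6(outdir / "nv_vs_oep.tsv", nv_oep)
    (outdir / "ground_truth.json").write_text(truth.to_json() + "\n")
    return truth
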
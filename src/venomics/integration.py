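"""Three-evidence integration, functional categorisation, and the pipeline.

A transcript is a venom candidate iff it is differentially expressed in the
venom gland, carries a secretion signal (undetermined calls are exclusions),
and is confirmed by at least one passing peptide.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import expression, proteomics, seq_utils, signal_peptide, venom_compare
from .expression import ExpressionRecord
from .signal_peptide import SignalCall

__all__ = [
    "VenomCandidate",
    "CATEGORIES",
    "DEFAULT_CATEGORY_RULES",
    "identify_venom_candidates",
    "categorize",
    "annotation_rate",
    "run_pipeline",
]

CATEGORIES = (
    "enzymes",
    "protease_inhibitors",
    "recognition_binding",
    "others",
    "unknown",
)

# ordered keyword rules; first matching category wins.  Inhibitor domain
# terms precede enzyme terms so "protease inhibitor" never matches "protease".
DEFAULT_CATEGORY_RULES: list[tuple[str, list[str]]] = [
    (
        "protease_inhibitors",
        ["kazal", "serpin", "pacifastin", "cystatin", "protease inhibitor"],
    ),
    (
        "enzymes",
        [
            "protease", "peptidase", "lipase", "esterase", "phosphatase",
            "nuclease", "hydrolase", "deaminase", "transaminase", "amylase",
            "dehydrogenase", "transpeptidase", "reductase", "sulfatase",
            "isomerase",
        ],
    ),
    (
        "recognition_binding",
        ["binding protein", "receptor", "gobp", "lectin"],
    ),
]

# "venom protein X" with a single-letter designation is an unknown
_VENOM_LETTER = re.compile(r"venom protein [a-z]\b", re.IGNORECASE)
_UNINFORMATIVE = ("hypothetical", "uncharacterized", "unnamed")


@dataclass
class VenomCandidate:
    transcript_id: str
    de_flag: bool
    has_sp: bool
    proteomic_confirmed: bool
    fpkm_vg: float
    category: str = "unknown"
    annotation: str = ""


def categorize(
    annotation: Optional[str],
    rules: Sequence[tuple[str, Sequence[str]]] = tuple(DEFAULT_CATEGORY_RULES),
) -> str:
    """Rule-based functional category of a best-hit annotation string."""
    if not annotation or not annotation.strip():
        return "unknown"
    text = annotation.lower()
    for category, keywords in rules:
        if any(k in text for k in keywords):
            return category
    if any(term in text for term in _UNINFORMATIVE) or _VENOM_LETTER.search(text):
        return "unknown"
    return "others"


def load_category_rules(path) -> list[tuple[str, list[str]]]:
    """Category keyword rules from a YAML list of {category, keywords} maps."""
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    return [(entry["category"], list(entry["keywords"])) for entry in raw]


def annotation_rate(n_annotated: int, n_total: int, digits: int = 2) -> float:
    """Percentage of sequences with an informative annotation."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_annotated / n_total, digits)


def identify_venom_candidates(
    expr: Sequence[ExpressionRecord],
    sp_calls: Sequence[SignalCall],
    confirmed: set[str],
    annotations: Optional[Mapping[str, str]] = None,
) -> list[VenomCandidate]:
    """Intersect the three evidence streams.

    Output is sorted by descending venom-gland FPKM then transcript id.
    """
    sp_by_id = {c.transcript_id: c.has_sp for c in sp_calls}
    candidates = []
    for rec in expr:
        has_sp = sp_by_id.get(rec.transcript_id)
        if not (rec.de_flag and has_sp is True and rec.transcript_id in confirmed):
            continue
        annotation = (annotations or {}).get(rec.transcript_id, "")
        candidates.append(
            VenomCandidate(
                transcript_id=rec.transcript_id,
                de_flag=True,
                has_sp=True,
                proteomic_confirmed=True,
                fpkm_vg=rec.fpkm_vg,
                category=categorize(annotation),
                annotation=annotation,
            )
        )
    candidates.sort(key=lambda c: (-c.fpkm_vg, c.transcript_id))
    return candidates


def run_pipeline(
    indir,
    outdir,
    sp_method: str = "local",
    reference_sp_table=None,
    fpkm_min: float = expression.FPKM_MIN,
    log2_min: float = expression.LOG2_MIN,
    q_max: float = expression.Q_MAX,
    ev_max: float = venom_compare.EVALUE_MAX,
    bs_min: float = venom_compare.BITSCORE_MIN,
) -> dict:
    """Run expression -> signal -> proteomics -> integration -> compare.

    ``indir`` must contain transcripts.fasta, counts.tsv and psms.tsv;
    pp_vs_nv.tsv / pp_vs_oep.tsv enable the comparative stage.  Per-stage
    TSVs, a stats JSON and a summary JSON are written to ``outdir``; the
    summary dict is returned.
    """
    indir, outdir = Path(indir), Path(outdir)
    for name in ("transcripts.fasta", "counts.tsv", "psms.tsv"):
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing input file: {indir / name}")
    outdir.mkdir(parents=True, exist_ok=True)

    # expression stage
    counts = pd.read_csv(indir / "counts.tsv", sep="\t")
    expr = expression.expression_table(
        counts, fpkm_min=fpkm_min, log2_min=log2_min, q_max=q_max
    )
    expression.records_to_frame(expr).to_csv(
        outdir / "expression.tsv", sep="\t", index=False
    )

    # ORF prediction + signal stage
    records = [
        seq_utils.TranscriptRecord(tid, seq)
        for tid, seq in seq_utils.read_fasta(indir / "transcripts.fasta")
    ]
    proteins = {rec.id: seq_utils.predict_orf(rec) for rec in records}
    if sp_method == "local":
        calls = [
            signal_peptide.local_signal_score(prot, tid)
            if prot is not None
            else signal_peptide.SignalCall(tid, None, "local")
            for tid, prot in proteins.items()
        ]
    elif sp_method == "transfer":
        if reference_sp_table is None:
            raise ValueError("transfer method requires a reference table path")
        ref = signal_peptide.read_reference_table(reference_sp_table)
        calls = [signal_peptide.transfer_signal_call(rec, ref) for rec in records]
    elif sp_method == "external":
        calls = signal_peptide.read_external_calls(indir / "signal_external.tsv")
    else:
        raise ValueError(f"unknown sp_method {sp_method!r}")
    signal_peptide.write_calls(outdir / "signal_calls.tsv", calls)

    # proteomic stage
    psms = proteomics.read_psm_table(indir / "psms.tsv")
    passing = proteomics.filter_psms(psms)
    protein_db = {tid: p for tid, p in proteins.items() if p}
    evidence = proteomics.map_peptides([p.peptide for p in passing], protein_db)
    proteomics.write_confirmed(outdir / "confirmed.tsv", evidence)
    confirmed = proteomics.infer_proteins(evidence)

    # integration
    candidates = identify_venom_candidates(expr, calls, confirmed)
    pd.DataFrame(
        {
            "transcript_id": [c.transcript_id for c in candidates],
            "fpkm_vg": [c.fpkm_vg for c in candidates],
            "category": [c.category for c in candidates],
            "annotation": [c.annotation for c in candidates],
        }
    ).to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    summary = {
        "n_transcripts": len(records),
        "n_de": sum(r.de_flag for r in expr),
        "n_sp": sum(c.has_sp is True for c in calls),
        "n_confirmed": len(confirmed),
        "n_candidates": len(candidates),
        "candidate_ids": [c.transcript_id for c in candidates],
        "thresholds": {
            "fpkm_min": fpkm_min,
            "log2_min": log2_min,
            "q_max": q_max,
            "ev_max": ev_max,
            "bs_min": bs_min,
        },
    }

    # comparative stage (optional inputs)
    nv_path, oep_path = indir / "pp_vs_nv.tsv", indir / "pp_vs_oep.tsv"
    if nv_path.exists() and oep_path.exists():
        nv = _read_maybe_empty(nv_path)
        oep = _read_maybe_empty(oep_path)
        query_ids = [c.transcript_id for c in candidates]
        paired = venom_compare.build_paired_scores(query_ids, nv, oep)
        assignments, venn_counts = venom_compare.venn_partition(paired, ev_max, bs_min)
        pd.DataFrame(
            {
                "protein_id": [a.protein_id for a in assignments],
                "label": [a.label for a in assignments],
            }
        ).to_csv(outdir / "venn.tsv", sep="\t", index=False)
        n_ev, n_bs, fractions = venom_compare.paired_better_fraction(paired)
        wmsr_ev = venom_compare.wilcoxon_evalue_pairs(paired)
        wmsr_bs = venom_compare.wilcoxon_bitscore_pairs(paired)
        stats_out = {
            "venn_counts": dict(zip(venom_compare.VENN_LABELS, venn_counts)),
            "n_better_evalue": n_ev,
            "n_better_bitscore": n_bs,
            "better_fractions": list(fractions),
            "wmsr_evalue": {
                "statistic": wmsr_ev.statistic,
                "p_value": wmsr_ev.p_value,
                "n_used": wmsr_ev.n_used,
                "method": wmsr_ev.method,
            },
            "wmsr_bitscore": {
                "statistic": wmsr_bs.statistic,
                "p_value": wmsr_bs.p_value,
                "n_used": wmsr_bs.n_used,
                "method": wmsr_bs.method,
            },
        }
        (outdir / "compare_stats.json").write_text(
            json.dumps(stats_out, indent=2) + "\n"
        )
        summary["venn_counts"] = list(venn_counts)

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def _read_maybe_empty(path) -> pd.DataFrame:
    try:
        return venom_compare.read_outfmt6(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=venom_compare.OUTFMT6_COLUMNS)
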
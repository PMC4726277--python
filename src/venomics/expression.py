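"""FPKM computation, two-library differential expression and qPCR analysis.

The DE test is the conditional exact binomial test: given the two-tissue
total t for a gene, the venom-gland count is Binomial(t, p0) under H0, with
p0 the venom-gland share of the summed library sizes.  Two-sided p-values sum
the probabilities of all outcomes no more likely than the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionRecord",
    "QpcrRecord",
    "compute_fpkm",
    "log2_ratio",
    "de_test",
    "bh_adjust",
    "de_filter",
    "ddct_fold_change",
    "expression_table",
]

# relative slack when comparing floating-point outcome probabilities
_PMF_SLACK = 1e-9

FPKM_MIN = 10.0
LOG2_MIN = 1.0
Q_MAX = 0.001


@dataclass
class ExpressionRecord:
    transcript_id: str
    count_vg: int
    count_carcass: int
    effective_length: float
    fpkm_vg: float = 0.0
    fpkm_carcass: float = 0.0
    log2_ratio: float = math.nan
    p_value: float = 1.0
    q_value: float = 1.0
    de_flag: bool = False


@dataclass
class QpcrRecord:
    gene: str
    ct_target_vg: Sequence[float]
    ct_ref_vg: Sequence[float]
    ct_target_carcass: Sequence[float]
    ct_ref_carcass: Sequence[float]


def compute_fpkm(count: float, library_size: float, effective_length: float) -> float:
    """FPKM = 1e9 * count / (library_size * effective_length)."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if effective_length <= 0:
        raise ValueError("effective_length must be positive")
    return 1e9 * count / (library_size * effective_length)


def log2_ratio(fpkm_vg: float, fpkm_carcass: float) -> float:
    """log2 fold change; +inf when carcass is 0, NaN when both are 0."""
    if fpkm_vg < 0 or fpkm_carcass < 0:
        raise ValueError("FPKM values must be non-negative")
    if fpkm_vg == 0 and fpkm_carcass == 0:
        return math.nan
    if fpkm_carcass == 0:
        return math.inf
    if fpkm_vg == 0:
        return -math.inf
    return math.log2(fpkm_vg / fpkm_carcass)


def de_test(
    count_vg: int,
    count_carcass: int,
    libsize_vg: float,
    libsize_carcass: float,
    method: str = "exact",
) -> float:
    """Two-sided p-value for tissue enrichment of one gene.

    ``method='exact'`` (default) uses minimum-likelihood ordering of the
    conditional binomial; ``method='normal'`` uses the normal approximation
    to the same binomial.
    """
    if libsize_vg <= 0 or libsize_carcass <= 0:
        raise ValueError("library sizes must be positive")
    t = int(count_vg) + int(count_carcass)
    if t == 0:
        return 1.0
    p0 = libsize_vg / (libsize_vg + libsize_carcass)
    if method == "exact":
        pmf = stats.binom.pmf(np.arange(t + 1), t, p0)
        observed = pmf[int(count_vg)]
        return float(min(1.0, pmf[pmf <= observed * (1 + _PMF_SLACK)].sum()))
    if method == "normal":
        mu = t * p0
        sd = math.sqrt(t * p0 * (1 - p0))
        z = (count_vg - mu) / sd
        return float(min(1.0, 2 * stats.norm.sf(abs(z))))
    raise ValueError(f"unknown method {method!r}")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def de_filter(
    records: Sequence[ExpressionRecord],
    fpkm_min: float = FPKM_MIN,
    log2_min: float = LOG2_MIN,
    q_max: float = Q_MAX,
) -> list[ExpressionRecord]:
    """Set ``de_flag`` on each record; all three comparisons strict.

    An infinite ratio passes the ratio criterion; an undefined (NaN) ratio
    never does.
    """
    for rec in records:
        ratio_ok = (not math.isnan(rec.log2_ratio)) and rec.log2_ratio > log2_min
        rec.de_flag = bool(
            rec.fpkm_vg > fpkm_min and ratio_ok and rec.q_value < q_max
        )
    return list(records)


def ddct_fold_change(rec: QpcrRecord) -> tuple[float, Optional[float]]:
    """2^-ddCt relative expression plus an equal-variance t-test p-value.

    dCt = mean(Ct target) - mean(Ct reference) per tissue; the p-value
    compares per-replicate dCt values between tissues (Student's t, pooled
    variance).  With fewer than two replicates in either tissue the fold
    change is still returned and the p-value is ``None``.
    """
    def _dct_reps(target, ref):
        target = list(target)
        ref = list(ref)
        if not target or not ref:
            raise ValueError("replicate lists must be non-empty")
        if len(target) == len(ref):
            return [t - r for t, r in zip(target, ref)]
        ref_mean = sum(ref) / len(ref)
        return [t - ref_mean for t in target]

    dct_vg = _dct_reps(rec.ct_target_vg, rec.ct_ref_vg)
    dct_car = _dct_reps(rec.ct_target_carcass, rec.ct_ref_carcass)
    ddct = (sum(dct_vg) / len(dct_vg)) - (sum(dct_car) / len(dct_car))
    fold = 2.0 ** (-ddct)
    if len(dct_vg) < 2 or len(dct_car) < 2:
        return fold, None
    t_res = stats.ttest_ind(dct_vg, dct_car, equal_var=True)
    return fold, float(t_res.pvalue)


def expression_table(
    counts: pd.DataFrame,
    libsize_vg: Optional[float] = None,
    libsize_carcass: Optional[float] = None,
    fpkm_min: float = FPKM_MIN,
    log2_min: float = LOG2_MIN,
    q_max: float = Q_MAX,
    method: str = "exact",
) -> list[ExpressionRecord]:
    """Run the whole expression stage on a counts table.

    ``counts`` needs columns transcript_id, count_vg, count_carcass,
    effective_length.  Library sizes default to the column sums.
    """
    if libsize_vg is None:
        libsize_vg = float(counts["count_vg"].sum())
    if libsize_carcass is None:
        libsize_carcass = float(counts["count_carcass"].sum())
    records = []
    for row in counts.itertuples(index=False):
        rec = ExpressionRecord(
            transcript_id=str(row.transcript_id),
            count_vg=int(row.count_vg),
            count_carcass=int(row.count_carcass),
            effective_length=float(row.effective_length),
        )
        rec.fpkm_vg = compute_fpkm(rec.count_vg, libsize_vg, rec.effective_length)
        rec.fpkm_carcass = compute_fpkm(
            rec.count_carcass, libsize_carcass, rec.effective_length
        )
        rec.log2_ratio = log2_ratio(rec.fpkm_vg, rec.fpkm_carcass)
        rec.p_value = de_test(
            rec.count_vg, rec.count_carcass, libsize_vg, libsize_carcass, method
        )
        records.append(rec)
    q = bh_adjust([r.p_value for r in records])
    for rec, qv in zip(records, q):
        rec.q_value = float(qv)
    return de_filter(records, fpkm_min, log2_min, q_max)


def records_to_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "fpkm_vg": [r.fpkm_vg for r in records],
            "fpkm_carcass": [r.fpkm_carcass for r in records],
            "log2_ratio": [round(r.log2_ratio, 2) for r in records],
            "p_value": [r.p_value for r in records],
            "q_value": [r.q_value for r in records],
            "de_flag": [r.de_flag for r in records],
        }
    )
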
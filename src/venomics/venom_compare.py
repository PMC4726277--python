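"""Comparative analysis of venom-protein sets.

Given tabular similarity searches of one query venom set against two
reference sets, this module extracts per-query best hits, applies the dual
e-value/bit-score homology cutoff, partitions queries into a three-set Venn
structure, and runs the paired statistics: better-score fractions, the exact
Wilcoxon matched-pairs signed-rank test, and the two-sided Fisher exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedScore",
    "VennAssignment",
    "TestResult",
    "OUTFMT6_COLUMNS",
    "read_outfmt6",
    "best_hits",
    "homology_call",
    "build_paired_scores",
    "venn_partition",
    "paired_better_fraction",
    "wilcoxon_signed_rank",
    "fisher_exact_2x2",
    "cutoff_sensitivity",
]

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

EVALUE_MAX = 1e-5
BITSCORE_MIN = 50.0
EVALUE_FLOOR = 1e-180  # zero e-values floored before log10
EXACT_N_MAX = 25  # signed-rank switches to the normal approximation above
_PMF_SLACK = 1e-7

VENN_LABELS = ("unique", "nv_only", "oep_only", "both")


@dataclass
class PairedScore:
    protein_id: str
    ev_nv: Optional[float] = None
    bs_nv: Optional[float] = None
    ev_oep: Optional[float] = None
    bs_oep: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.ev_nv is None) != (self.bs_nv is None):
            raise ValueError("ev_nv and bs_nv must be absent together")
        if (self.ev_oep is None) != (self.bs_oep is None):
            raise ValueError("ev_oep and bs_oep must be absent together")


@dataclass(frozen=True)
class VennAssignment:
    protein_id: str
    label: str


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_used: int
    method: str


def read_outfmt6(path) -> pd.DataFrame:
    """Read a 12-column tab-separated similarity table (outfmt-6 dialect)."""
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS)
    if (df["evalue"] < 0).any() or (df["bitscore"] < 0).any():
        raise ValueError("e-values and bit scores must be non-negative")
    return df


def best_hits(rows: pd.DataFrame) -> dict[str, tuple[float, float, str]]:
    """Best hit per query: minimum e-value, ties by max bit score then
    lexicographic subject id.  Returns query -> (evalue, bitscore, subject)."""
    out: dict[str, tuple[float, float, str]] = {}
    for row in rows.itertuples(index=False):
        key = (float(row.evalue), -float(row.bitscore), str(row.sseqid))
        current = out.get(row.qseqid)
        if current is None or key < (current[0], -current[1], current[2]):
            out[str(row.qseqid)] = (float(row.evalue), float(row.bitscore), str(row.sseqid))
    return out


def homology_call(
    evalue: float,
    bitscore: float,
    ev_max: float = EVALUE_MAX,
    bs_min: float = BITSCORE_MIN,
) -> bool:
    """Dual inclusive cutoff: evalue <= ev_max and bitscore >= bs_min."""
    return evalue <= ev_max and bitscore >= bs_min


def build_paired_scores(
    query_ids: Sequence[str],
    nv_rows: pd.DataFrame,
    oep_rows: pd.DataFrame,
) -> list[PairedScore]:
    """Assemble per-query best-hit score pairs against the two reference sets."""
    nv = best_hits(nv_rows)
    oep = best_hits(oep_rows)
    paired = []
    for qid in query_ids:
        ps = PairedScore(qid)
        if qid in nv:
            ps.ev_nv, ps.bs_nv = nv[qid][0], nv[qid][1]
        if qid in oep:
            ps.ev_oep, ps.bs_oep = oep[qid][0], oep[qid][1]
        paired.append(ps)
    return paired


def venn_partition(
    paired: Sequence[PairedScore],
    ev_max: float = EVALUE_MAX,
    bs_min: float = BITSCORE_MIN,
) -> tuple[list[VennAssignment], tuple[int, int, int, int]]:
    """Assign each query to {unique, nv_only, oep_only, both}.

    Returns the assignments plus counts in that label order.
    """
    assignments = []
    counts = dict.fromkeys(VENN_LABELS, 0)
    for ps in paired:
        in_nv = ps.ev_nv is not None and homology_call(ps.ev_nv, ps.bs_nv, ev_max, bs_min)
        in_oep = ps.ev_oep is not None and homology_call(ps.ev_oep, ps.bs_oep, ev_max, bs_min)
        label = (
            "both" if in_nv and in_oep
            else "nv_only" if in_nv
            else "oep_only" if in_oep
            else "unique"
        )
        assignments.append(VennAssignment(ps.protein_id, label))
        counts[label] += 1
    return assignments, tuple(counts[k] for k in VENN_LABELS)


def paired_better_fraction(
    paired: Sequence[PairedScore],
) -> tuple[int, int, tuple[float, float]]:
    """Count queries scoring strictly better against the first reference set.

    Better means smaller e-value / larger bit score.  A query with a hit in
    one set and none in the other counts as better for the set with the hit;
    a query with no hits in either counts for neither.  Fractions are over
    all queries.
    """
    n_better_ev = 0
    n_better_bs = 0
    for ps in paired:
        if ps.ev_nv is not None and ps.ev_oep is not None:
            if ps.ev_nv < ps.ev_oep:
                n_better_ev += 1
            if ps.bs_nv > ps.bs_oep:
                n_better_bs += 1
        elif ps.ev_nv is not None:  # hit in nv only
            n_better_ev += 1
            n_better_bs += 1
    n = len(paired)
    fractions = (n_better_ev / n, n_better_bs / n) if n else (0.0, 0.0)
    return n_better_ev, n_better_bs, fractions


def _signed_rank_exact_p(
    scaled_ranks: np.ndarray, w2: float, alternative: str
) -> float:
    """Exact signed-rank p by dynamic programming over the null distribution.

    ``scaled_ranks`` are the tie-averaged ranks times 2 (integers), ``w2``
    the observed positive-rank sum on the same scale.  Under H0 each rank is
    positive independently with probability 1/2; the DP enumerates the
    distribution of the positive-rank sum exactly (counts are integers
    < 2^53 for n <= 25, so float arithmetic is exact).
    """
    total = int(scaled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in scaled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    denom = 2.0 ** len(scaled_ranks)
    support = np.arange(total + 1)
    if alternative == "greater":
        mask = support >= w2 - 1e-9
    elif alternative == "less":
        mask = support <= w2 + 1e-9
    else:  # two-sided, symmetric null around total/2
        mu = total / 2.0
        mask = np.abs(support - mu) >= abs(w2 - mu) - 1e-9
    return float(min(1.0, counts[mask].sum() / denom))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_n_max: int = EXACT_N_MAX,
) -> TestResult:
    """Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped; tied absolute differences get average
    ranks.  The statistic is the positive-rank sum W.  Exact p by sign-vector
    enumeration (via DP) for n <= ``exact_n_max``, else a normal
    approximation with continuity correction and tie-adjusted variance.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("x and y must be equal-length 1-d sequences")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, 0, "wilcoxon-signed-rank")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= exact_n_max:
        scaled = np.rint(ranks * 2).astype(np.int64)
        w2 = round(w * 2, 6)
        p = _signed_rank_exact_p(scaled, w2, alternative)
        method = "wilcoxon-signed-rank-exact"
    else:
        mu = n * (n + 1) / 4.0
        # var = sum(r_i^2)/4 absorbs the tie correction automatically
        sd = math.sqrt(float((ranks**2).sum()) / 4.0)
        if alternative == "two-sided":
            z = (abs(w - mu) - 0.5) / sd
            p = float(min(1.0, 2 * stats.norm.sf(z)))
        elif alternative == "greater":
            p = float(stats.norm.sf((w - mu - 0.5) / sd))
        else:
            p = float(stats.norm.cdf((w - mu + 0.5) / sd))
        method = "wilcoxon-signed-rank-normal"
    return TestResult(w, p, n, method)


def wilcoxon_evalue_pairs(
    paired: Sequence[PairedScore], alternative: str = "two-sided"
) -> TestResult:
    """Signed-rank test on log10 e-value pairs (complete pairs only)."""
    xs, ys = [], []
    for ps in paired:
        if ps.ev_nv is not None and ps.ev_oep is not None:
            xs.append(math.log10(max(ps.ev_nv, EVALUE_FLOOR)))
            ys.append(math.log10(max(ps.ev_oep, EVALUE_FLOOR)))
    if not xs:
        return TestResult(0.0, 1.0, 0, "wilcoxon-signed-rank")
    return wilcoxon_signed_rank(xs, ys, alternative)


def wilcoxon_bitscore_pairs(
    paired: Sequence[PairedScore], alternative: str = "two-sided"
) -> TestResult:
    """Signed-rank test on bit-score pairs (complete pairs only)."""
    xs, ys = [], []
    for ps in paired:
        if ps.bs_nv is not None and ps.bs_oep is not None:
            xs.append(ps.bs_nv)
            ys.append(ps.bs_oep)
    if not xs:
        return TestResult(0.0, 1.0, 0, "wilcoxon-signed-rank")
    return wilcoxon_signed_rank(xs, ys, alternative)


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, alternative: str = "two-sided"
) -> TestResult:
    """Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Conditions on both margins (hypergeometric); the two-sided p sums all
    tables with point probability <= the observed one (minimum-likelihood
    method).  The statistic is the sample odds ratio (a*d)/(b*c).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise ValueError("table is empty")
    row1 = a + b
    col1 = a + c
    k_min = max(0, col1 - (c + d))
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    observed = pmf[a - k_min]
    if alternative == "two-sided":
        p = float(pmf[pmf <= observed * (1 + _PMF_SLACK)].sum())
    elif alternative == "greater":
        p = float(pmf[support >= a].sum())
    elif alternative == "less":
        p = float(pmf[support <= a].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    if a * d == 0 and b * c == 0:
        odds = math.nan
    return TestResult(odds, min(1.0, p), n, "fisher-exact")


def cutoff_sensitivity(
    paired: Sequence[PairedScore],
    bs_grid: Sequence[float],
    ev_max: float = EVALUE_MAX,
) -> pd.DataFrame:
    """Venn counts recomputed at each bit-score cutoff (fixed e-value cutoff)."""
    if len(bs_grid) == 0:
        raise ValueError("bit-score grid must be non-empty")
    rows = []
    for bs in bs_grid:
        _, counts = venn_partition(paired, ev_max=ev_max, bs_min=bs)
        rows.append({"bitscore_min": bs, **dict(zip(VENN_LABELS, counts))})
    return pd.DataFrame(rows)
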
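"""Paired-tissue differential methylation and expression correlation.

Implements the depth/missingness CpG filters, element-level means, an
exact Wilcoxon signed-rank test (enumeration-equivalent dynamic
programme for small n), Spearman correlation with exact small-n
p-values, Fisher enrichment, and global per-tissue summaries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from sinescope.io_formats import Interval, MethylationRecord


@dataclass(frozen=True)
class FilteredCpG:
    chrom: str
    pos: int
    samples: dict[str, tuple[int, int]]  # sample_id -> (n_meth, n_total)

    def level(self, sample_id: str) -> float:
        m, t = self.samples[sample_id]
        return m / t


@dataclass(frozen=True)
class ElementMethylation:
    element_id: str
    sample_means: dict[str, float]
    n_cpg: int


@dataclass(frozen=True)
class TestResult:
    statistic: float  # W, sum of positive ranks
    p_value: float
    effect: float  # difference of tissue means (t1 - t2)
    n_pairs: int
    degenerate: bool = False  # all differences zero


@dataclass(frozen=True)
class CorrelationResult:
    element_id: str
    gene_id: str
    rho: float
    p_value: float
    sign: str  # "+", "-", or "0" when undefined/ns


@dataclass(frozen=True)
class DifferentialResult:
    element_id: str
    n_cpg: int
    test: TestResult
    dm: bool


# ---------------------------------------------------------------------------
# CpG filtering and element means
# ---------------------------------------------------------------------------

def filter_cpgs(
    records: list[MethylationRecord],
    min_depth: int = 10,
    max_depth: int = 300,
    max_missing: float = 0.5,
    n_samples: int | None = None,
) -> list[FilteredCpG]:
    """Apply depth and missing-rate filters per CpG.

    A sample is missing at a CpG when its depth is < ``min_depth`` or
    > ``max_depth`` (bounds inclusive-survive). The CpG is dropped when
    the missing fraction across samples is strictly above
    ``max_missing``; retained CpGs keep only non-missing samples.
    Idempotent: filtering a filtered table changes nothing.
    """
    all_samples = {r.sample_id for r in records}
    total = n_samples if n_samples is not None else len(all_samples)
    if total == 0:
        return []
    grouped: dict[tuple[str, int], dict[str, tuple[int, int]]] = {}
    order: list[tuple[str, int]] = []
    for r in records:
        key = (r.chrom, r.pos)
        if key not in grouped:
            grouped[key] = {}
            order.append(key)
        grouped[key][r.sample_id] = (r.n_meth, r.n_total)
    out: list[FilteredCpG] = []
    for key in sorted(order):
        kept = {
            sid: mt
            for sid, mt in grouped[key].items()
            if min_depth <= mt[1] <= max_depth
        }
        missing = (total - len(kept)) / total
        if missing > max_missing:
            continue
        out.append(FilteredCpG(key[0], key[1], kept))
    return out


def element_methylation(
    filtered: list[FilteredCpG],
    elements: "dict[str, Interval] | list",
    min_cpg: int = 1,
) -> list[ElementMethylation]:
    """Per-sample unweighted mean CpG level over each element span.

    ``elements`` maps element_id to a span interval (a list of objects
    with ``element_id``/``full_span`` attributes also works). Elements
    with fewer than ``min_cpg`` retained CpGs are omitted.
    """
    if not isinstance(elements, dict):
        elements = {
            (el.element_id or f"el{i:04d}"): el.full_span for i, el in enumerate(elements)
        }
    out: list[ElementMethylation] = []
    for eid, span in elements.items():
        cpgs = [
            c for c in filtered if c.chrom == span.chrom and span.start <= c.pos < span.end
        ]
        if len(cpgs) < min_cpg:
            continue
        per_sample: dict[str, list[float]] = {}
        for c in cpgs:
            for sid in c.samples:
                per_sample.setdefault(sid, []).append(c.level(sid))
        means = {sid: sum(v) / len(v) for sid, v in per_sample.items()}
        out.append(ElementMethylation(element_id=eid, sample_means=means, n_cpg=len(cpgs)))
    return out


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------

def _signed_ranks(diffs: np.ndarray) -> np.ndarray:
    return sps.rankdata(np.abs(diffs))


def wilcoxon_signed_rank(
    x,
    y=None,
    exact_max_n: int = 25,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    ``x`` and ``y`` are the paired vectors (or ``x`` the differences).
    Zero differences are dropped before ranking; ties get average
    ranks. For n ≤ ``exact_max_n`` the p-value is exact over all 2^n
    sign assignments (computed by an equivalent dynamic programme);
    otherwise a tie-corrected normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    effect = float(np.mean(d))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, effect=effect, n_pairs=0, degenerate=True)
    ranks = _signed_ranks(d)
    w = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        # distribution of 2W over all sign assignments via subset-sum DP
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: total + 1 - r]
            dist = dist + shifted
        dist /= dist.sum()
        w2 = int(round(2 * w))
        p_le = dist[: w2 + 1].sum()
        p_ge = dist[w2:].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w - mean) / math.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(statistic=w, p_value=float(p), effect=effect, n_pairs=n)


def spearman(
    meth_vector,
    expr_vector,
    element_id: str = "",
    gene_id: str = "",
    exact_max_n: int = 9,
    sign_threshold: float = 0.01,
) -> CorrelationResult:
    """Spearman correlation with exact permutation p for small n.

    Ranks use average ties. For n ≤ ``exact_max_n`` the two-sided p is
    the exact permutation tail of |rho|; otherwise the t-approximation.
    The sign field is set when p < ``sign_threshold``.
    """
    x = np.asarray(meth_vector, dtype=float)
    y = np.asarray(expr_vector, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(element_id, gene_id, float("nan"), 1.0, "0")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)

    def _rho(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    rho = _rho(rx, ry)
    if n <= exact_max_n:
        target = abs(rho) - 1e-12
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rho(rx, np.asarray(perm))) >= target:
                count += 1
        p = count / total
    else:
        t = rho * math.sqrt((n - 2) / max(1e-12, 1.0 - rho * rho))
        p = min(1.0, 2.0 * sps.t.sf(abs(t), df=n - 2))
    sign = "0"
    if p < sign_threshold:
        sign = "+" if rho > 0 else "-"
    return CorrelationResult(element_id, gene_id, rho, float(p), sign)


def fisher_enrichment(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2×2 count table.

    Returns (sample odds ratio, p). The p-value is the conditional
    hypergeometric sum over tables at most as probable as the observed
    one.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin")
    n = r1 + r2
    dist = sps.hypergeom(n, r1, c1)
    p_obs = dist.pmf(a)
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    xs = np.arange(lo, hi + 1)
    pmf = dist.pmf(xs)
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    odds = math.inf if b * c == 0 and a * d > 0 else (a * d) / (b * c) if b * c else float("nan")
    return odds, min(1.0, p)


# ---------------------------------------------------------------------------
# Differential pipeline
# ---------------------------------------------------------------------------

def _pairs_by_individual(
    em: ElementMethylation,
    design: list[tuple[str, str, str]],
    tissues: tuple[str, str],
) -> tuple[np.ndarray, np.ndarray]:
    by_ind: dict[str, dict[str, str]] = {}
    for sid, ind, tis in design:
        by_ind.setdefault(ind, {})[tis] = sid
    xs, ys = [], []
    for ind in sorted(by_ind):
        s1 = by_ind[ind].get(tissues[0])
        s2 = by_ind[ind].get(tissues[1])
        if s1 in em.sample_means and s2 in em.sample_means:
            xs.append(em.sample_means[s1])
            ys.append(em.sample_means[s2])
    return np.asarray(xs), np.asarray(ys)


def differential_elements(
    element_meth: list[ElementMethylation],
    design: list[tuple[str, str, str]],
    tissues: tuple[str, str] = ("muscle", "testis"),
    min_cpg: int = 10,
    p_threshold: float = 0.01,
    min_abs_diff: float = 0.3,
    paired: bool = True,
) -> list[DifferentialResult]:
    """Differentially methylated elements under the paired Wilcoxon test.

    An element is DM iff it has ≥ ``min_cpg`` filtered CpGs, Wilcoxon
    p < ``p_threshold``, and |mean(t1) − mean(t2)| > ``min_abs_diff``.
    Set ``min_abs_diff=0`` for the relaxed criterion without the
    effect-size filter.
    """
    out: list[DifferentialResult] = []
    for em in element_meth:
        if paired:
            xs, ys = _pairs_by_individual(em, design, tissues)
        else:
            xs = np.asarray(
                [em.sample_means[s] for s, _, t in design if t == tissues[0] and s in em.sample_means]
            )
            ys = np.asarray(
                [em.sample_means[s] for s, _, t in design if t == tissues[1] and s in em.sample_means]
            )
            m = min(len(xs), len(ys))
            xs, ys = xs[:m], ys[:m]
        if len(xs) < 2:
            continue
        test = wilcoxon_signed_rank(xs, ys)
        diff = float(xs.mean() - ys.mean())
        test = TestResult(test.statistic, test.p_value, diff, test.n_pairs, test.degenerate)
        dm = (
            em.n_cpg >= min_cpg
            and test.p_value < p_threshold
            and abs(diff) > min_abs_diff
        )
        out.append(DifferentialResult(em.element_id, em.n_cpg, test, dm))
    return out


def restrict_to_regions(
    elements: list,
    regions: list[Interval],
) -> list:
    """Keep elements whose span overlaps at least one region by ≥1 bp."""
    out = []
    for el in elements:
        span = el.full_span if hasattr(el, "full_span") else el
        if any(span.overlaps(r) for r in regions):
            out.append(el)
    return out


@dataclass(frozen=True)
class GlobalSummary:
    sample_means: dict[str, float]
    tissue_mean: dict[str, float]
    tissue_cv_percent: dict[str, float]
    t_statistic: float
    p_value: float


def global_summary(
    element_meth: list[ElementMethylation],
    design: list[tuple[str, str, str]],
    tissues: tuple[str, str] = ("muscle", "testis"),
) -> GlobalSummary:
    """Per-sample global means, per-tissue CV (%), paired t between tissues."""
    sample_means: dict[str, float] = {}
    for sid, _, _ in design:
        vals = [em.sample_means[sid] for em in element_meth if sid in em.sample_means]
        if vals:
            sample_means[sid] = sum(vals) / len(vals)
    by_ind: dict[str, dict[str, float]] = {}
    for sid, ind, tis in design:
        if sid in sample_means:
            by_ind.setdefault(ind, {})[tis] = sample_means[sid]
    pairs = [
        (v[tissues[0]], v[tissues[1]])
        for v in by_ind.values()
        if tissues[0] in v and tissues[1] in v
    ]
    if len(pairs) < 2:
        raise ValueError("need at least 2 paired individuals")
    tissue_mean = {}
    tissue_cv = {}
    for j, tis in enumerate(tissues):
        vals = np.asarray([p[j] for p in pairs])
        tissue_mean[tis] = float(vals.mean())
        tissue_cv[tis] = float(100.0 * vals.std(ddof=1) / vals.mean())
    d = np.asarray([p[0] - p[1] for p in pairs])
    if np.allclose(d.std(ddof=1), 0):
        tstat = 0.0 if np.allclose(d.mean(), 0) else math.inf
        p = 1.0 if tstat == 0.0 else 0.0
    else:
        tstat = float(d.mean() / (d.std(ddof=1) / math.sqrt(len(d))))
        p = float(min(1.0, 2.0 * sps.t.sf(abs(tstat), df=len(d) - 1)))
    return GlobalSummary(sample_means, tissue_mean, tissue_cv, tstat, p)
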
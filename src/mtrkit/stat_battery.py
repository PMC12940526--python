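"""Reusable statistical primitives for the constraint analysis.

Everything downstream of the MTR profile runs through the procedures
collected here: two-sided Fisher's exact tests with Haldane–Anscombe
stabilised log2 odds ratios, Wilson score intervals, pooled two-proportion
z-tests, tie-corrected Kruskal–Wallis with Dunn's post hoc pairwise tests
and a compact letter display, Mann–Whitney U, Benjamini–Hochberg q-values,
bias-corrected descriptive moments, and the clinical-class-by-structural-
state enrichment scan.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Fisher's exact test with Haldane–Anscombe odds ratio
# ----------------------------------------------------------------------
@lru_cache(maxsize=100_000)
def _hypergeom_pmf(N: int, K: int, n: int) -> tuple[int, np.ndarray]:
    """Support start and pmf vector for Hypergeometric(N, K, n)."""
    lo = max(0, n - (N - K))
    hi = min(K, n)
    support = np.arange(lo, hi + 1)
    return lo, stats.hypergeom.pmf(support, N, K, n)


def fisher_ha(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """(log2 odds ratio with Haldane–Anscombe correction, two-sided exact p).

    The two-sided p follows the probability-ordering rule: the total mass
    of tables (margins fixed) whose hypergeometric probability does not
    exceed that of the observed table.  The odds ratio adds 0.5 to every
    cell when any cell is zero, else uses raw cells.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if a + b + c + d == 0:
        return float("nan"), float("nan")
    if 0 in (a, b, c, d):
        or_ = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        or_ = (a * d) / (b * c)
    log2_or = math.log2(or_)

    N = a + b + c + d
    K = a + b  # row-1 margin
    n = a + c  # col-1 margin
    lo, pmf = _hypergeom_pmf(N, K, n)
    p_obs = pmf[a - lo]
    # relative tolerance guards against float noise in pmf ties
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return log2_or, min(p, 1.0)


# ----------------------------------------------------------------------
# proportions
# ----------------------------------------------------------------------
def wilson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return float("nan"), float("nan")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=1 - conf, method="wilson")
    return float(lo), float(hi)


def two_prop_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-sided."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both sample sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        logger.warning("two_prop_z: degenerate pooled proportion %s; z set to 0", pooled)
        return 0.0, 1.0
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return z, 2 * float(stats.norm.sf(abs(z)))


# ----------------------------------------------------------------------
# rank-based group comparisons
# ----------------------------------------------------------------------
@dataclass
class GroupComparison:
    labels: list[str]
    h_statistic: float
    p_global: float
    dunn_z: pd.DataFrame  # pairwise z, labels x labels
    dunn_q: pd.DataFrame  # BH-adjusted pairwise p
    letters: dict[str, str]


def _compact_letters(
    labels: Sequence[str], nonsig: set[frozenset[str]]
) -> dict[str, str]:
    """Compact letter display via maximal cliques of the non-significance graph.

    Two groups share a letter iff their adjusted pairwise p >= alpha; this
    holds exactly because every edge of the graph lies in some maximal
    clique and every letter is a clique.  Cliques are ordered by their
    first member in the supplied label order so that the first group is
    always lettered 'a'.
    """
    labels = list(labels)
    adj = {
        u: {v for v in labels if v != u and frozenset((u, v)) in nonsig}
        for u in labels
    }
    cliques: list[tuple[str, ...]] = []
    # group counts are small (structural states, clinical classes): subset
    # enumeration is simpler than a general clique algorithm and exact
    for r in range(len(labels), 0, -1):
        for subset in itertools.combinations(labels, r):
            members = set(subset)
            if any(not (members - {u}) <= adj[u] for u in subset):
                continue
            if any(members <= set(c) for c in cliques):
                continue  # not maximal
            cliques.append(subset)
    cliques.sort(key=lambda c: min(labels.index(u) for u in c))
    letters: dict[str, list[str]] = {u: [] for u in labels}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for u in clique:
            letters[u].append(letter)
    return {u: "".join(sorted(ls)) for u, ls in letters.items()}


def kruskal_dunn(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> GroupComparison:
    """Kruskal–Wallis plus FDR-corrected Dunn's pairwise post hoc tests.

    Dunn's z uses pooled mid-ranks with the usual tie correction; the
    pairwise p-values are adjusted by Benjamini–Hochberg across all pairs
    and summarised as a compact letter display at level ``alpha``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    labels = list(labels)

    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        k = len(groups)
        square = pd.DataFrame(0.0, index=labels, columns=labels)
        ones = pd.DataFrame(1.0, index=labels, columns=labels)
        return GroupComparison(labels, 0.0, 1.0, square, ones,
                               {u: "a" for u in labels})

    h, p_global = stats.kruskal(*groups)

    ranks = stats.rankdata(pooled)
    N = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (N - 1))
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)

    pairs = list(itertools.combinations(range(len(groups)), 2))
    zmat = pd.DataFrame(0.0, index=labels, columns=labels)
    raw_p = []
    for i, j in pairs:
        var = (N * (N + 1) / 12 - tie_term) * (1 / sizes[i] + 1 / sizes[j])
        z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
        zmat.iloc[i, j] = z
        zmat.iloc[j, i] = -z
        raw_p.append(2 * float(stats.norm.sf(abs(z))))
    q = multipletests(raw_p, method="fdr_bh")[1]
    qmat = pd.DataFrame(1.0, index=labels, columns=labels)
    nonsig: set[frozenset[str]] = set()
    for (i, j), qv in zip(pairs, q):
        qmat.iloc[i, j] = qmat.iloc[j, i] = qv
        if qv >= alpha:
            nonsig.add(frozenset((labels[i], labels[j])))
    letters = _compact_letters(labels, nonsig)
    return GroupComparison(labels, float(h), float(p_global), zmat, qmat, letters)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U with tie correction.

    Exact p for small tie-free samples, normal approximation otherwise
    (scipy's automatic policy).  Completely tied data short-circuits to
    (n1*n2/2, 1.0), where the variance term vanishes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return len(a) * len(b) / 2, 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


# ----------------------------------------------------------------------
# multiple testing and moments
# ----------------------------------------------------------------------
def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DescriptiveStats:
    """Sample moments; skewness is adjusted Fisher–Pearson, kurtosis is
    bias-corrected *excess* kurtosis (0 for a normal distribution)."""

    n: int
    mean: float
    stddev: float
    skewness: float
    kurtosis: float


def descriptive(values: Sequence[float]) -> DescriptiveStats:
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 1:
        raise ValueError("need at least one value")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if n >= 2 else float("nan")
    constant = n >= 2 and sd == 0.0
    skew = (
        float(stats.skew(x, bias=False)) if n >= 3 and not constant else float("nan")
    )
    kurt = (
        float(stats.kurtosis(x, fisher=True, bias=False))
        if n >= 4 and not constant
        else float("nan")
    )
    return DescriptiveStats(n, mean, sd, skew, kurt)


# ----------------------------------------------------------------------
# clinical-class enrichment by structural state
# ----------------------------------------------------------------------
@dataclass
class EnrichmentResult:
    state: str
    clinical_class: str
    a: int  # class in state
    b: int  # other classes in state
    c: int  # class elsewhere
    d: int  # other classes elsewhere
    log2_or: float
    p: float
    q: float = float("nan")


def significance_stars(q: float) -> str:
    if np.isnan(q):
        return ""
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


def clinvar_state_enrichment(
    variants: pd.DataFrame,
    states: Optional[Sequence[str]] = None,
    classes: Sequence[str] = ("pathogenic", "benign", "vus"),
) -> pd.DataFrame:
    """Each structural state versus all other states combined, per class.

    ``variants`` needs columns ``state`` and ``clinical_class``; classes
    outside ``classes`` are dropped before testing.  A positive log2 odds
    ratio means the class is enriched in the state.  One BH family spans
    all (state x class) tests of the run.
    """
    df = variants[variants["clinical_class"].isin(classes)]
    if states is None:
        states = sorted(df["state"].unique())
    rows: list[EnrichmentResult] = []
    total = len(df)
    for state in states:
        in_state = df["state"] == state
        n_state = int(in_state.sum())
        for clin in classes:
            if n_state == 0 or total == 0:
                rows.append(EnrichmentResult(state, clin, 0, 0, 0, 0,
                                             float("nan"), float("nan")))
                continue
            is_class = df["clinical_class"] == clin
            a = int((in_state & is_class).sum())
            b = n_state - a
            c = int(is_class.sum()) - a
            d = total - a - b - c
            log2_or, p = fisher_ha([[a, b], [c, d]])
            rows.append(EnrichmentResult(state, clin, a, b, c, d, log2_or, p))
    defined = [r for r in rows if not np.isnan(r.p)]
    if defined:
        q = bh_fdr([r.p for r in defined])
        for r, qv in zip(defined, q):
            r.q = float(qv)
    out = pd.DataFrame(
        [
            {
                "state": r.state,
                "clinical_class": r.clinical_class,
                "n_class_in_state": r.a,
                "n_other_in_state": r.b,
                "n_class_elsewhere": r.c,
                "n_other_elsewhere": r.d,
                "log2_or": r.log2_or,
                "p": r.p,
                "q": r.q,
            }
            for r in rows
        ]
    )
    out["significance"] = [significance_stars(q) for q in out["q"]]
    return out
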
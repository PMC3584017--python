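"""Nonparametric comparisons of divergence distributions across loci.

Two tests are used when comparing barcode loci:

* **Kruskal-Wallis** across the loci's inter- (or intra-)specific distance
  distributions, with Dunn's rank-mean z-tests as the post-hoc pairwise
  comparison (Bonferroni-adjusted by default), and
* the **Wilcoxon matched-pair signed-rank test** between each species'
  minimum inter-specific and maximum intra-specific distance, to ask
  whether a locus' inter-specific divergence systematically exceeds its
  intra-specific divergence.

The Wilcoxon p-value is exact (full sign-flip distribution, equivalent to
enumerating all 2^n assignments) for up to 25 nonzero differences, using
mid-ranks for tied magnitudes and dropping zero differences; beyond that a
normal approximation with continuity and tie correction is used.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class GroupSample:
    """One locus' distance sample for a group comparison."""

    label: str
    values: list[float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.size and (not np.isfinite(arr).all()
                         or arr.min() < 0 or arr.max() > 1):
            raise ValueError(f"{self.label}: values must be finite in [0, 1]")


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    z: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass
class TestResult:
    statistic: float
    p_value: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    direction: str | None = None  # wilcoxon: which side of the pairs is larger


def _adjust(p_raw: list[float], method: str) -> list[float]:
    m = len(p_raw)
    if method == "none" or m == 0:
        return list(p_raw)
    if method == "bonferroni":
        return [min(1.0, p * m) for p in p_raw]
    if method == "holm":
        order = np.argsort(p_raw)
        adj = [0.0] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_raw[idx])
            adj[idx] = min(1.0, running)
        return adj
    raise ValueError(f"unknown adjustment {method!r}")


def kruskal_wallis(
    groups: Sequence[GroupSample],
    adjust: str = "bonferroni",
    alpha: float = 0.05,
) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with Dunn's pairwise post-hoc.

    The H statistic and its chi-square p-value (k-1 df) come from scipy;
    Dunn's z compares rank means under the pooled tie-corrected variance,
    with per-pair p-values adjusted by ``adjust``.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g in groups:
        if not g.values:
            raise ValueError(f"group {g.label!r} is empty")
    values = np.concatenate([np.asarray(g.values, float) for g in groups])
    if np.all(values == values[0]):
        return TestResult(statistic=0.0, p_value=1.0, pairwise=[])
    H, p = sps.kruskal(*[g.values for g in groups])

    # Dunn's test on joint ranks
    ranks = sps.rankdata(values)
    N = len(values)
    sizes = [len(g.values) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean()
                  for i in range(len(groups))]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term

    pairs, zs, ps_raw = [], [], []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(base_var * (1 / sizes[i] + 1 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        pairs.append((groups[i].label, groups[j].label))
        zs.append(z)
        ps_raw.append(2 * sps.norm.sf(abs(z)))
    ps_adj = _adjust(ps_raw, adjust)
    pairwise = [
        PairwiseComparison(pair=pr, z=float(z), p_raw=float(praw),
                           p_adjusted=float(padj),
                           significant=bool(padj < alpha))
        for pr, z, praw, padj in zip(pairs, zs, ps_raw, ps_adj)
    ]
    return TestResult(statistic=float(H), p_value=float(p), pairwise=pairwise)


def _signed_rank_exact_sf_cdf(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of W+ over all sign assignments.

    ``ranks2`` are the doubled mid-ranks (integers). Returns the count of
    assignments achieving each doubled W+ value, which is exactly the
    2^n enumeration aggregated by outcome.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_matched(
    pairs: Sequence[tuple[float, float]],
    alternative: str = "two-sided",
    exact_limit: int = 25,
) -> TestResult:
    """Wilcoxon matched-pair signed-rank test on (min_inter, max_intra).

    Differences are first - second; zeros are dropped, tied magnitudes get
    mid-ranks. The statistic reported is W+ (rank sum of positive
    differences). ``direction`` names the larger side ("first", "second",
    or "tie"). Exact p for <= ``exact_limit`` nonzero differences.
    """
    if not pairs:
        raise ValueError("no pairs")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    diffs = np.array([a - b for a, b in pairs], dtype=float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, direction="tie")
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    w_minus = float(ranks[diffs < 0].sum())
    direction = ("first" if w_plus > w_minus
                 else "second" if w_minus > w_plus else "tie")

    if n <= exact_limit:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_exact_sf_cdf(ranks2)
        total = counts.sum()  # == 2^n
        w2 = int(round(2 * w_plus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        _, t = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - float(np.sum(t**3 - t)) / 48.0
        sd = np.sqrt(var)

        def z_of(w: float, side: str) -> float:
            cc = 0.5 if side == "ge" else -0.5
            return (w - mean - cc) / sd if side == "ge" else (w - mean + cc) / sd

        p_ge = sps.norm.sf(z_of(w_plus, "ge"))
        p_le = sps.norm.cdf(z_of(w_plus, "le"))
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2 * min(p_le, p_ge))
    return TestResult(statistic=w_plus, p_value=float(p), direction=direction)


def stars(p: float) -> str:
    """Conventional significance stars for report tables."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def write_stats_report(results: dict[str, TestResult], path) -> None:
    """TSV report: one row per test plus one per post-hoc pair."""
    with open(path, "w") as fh:
        fh.write("test\tpair\tstatistic\tp_value\tsignificance\tdirection\n")
        for name, res in results.items():
            fh.write(f"{name}\t-\t{res.statistic:.4f}\t{res.p_value:.4g}\t"
                     f"{stars(res.p_value)}\t{res.direction or '-'}\n")
            for cmp in res.pairwise:
                fh.write(
                    f"{name}\t{cmp.pair[0]} vs {cmp.pair[1]}\t{cmp.z:.4f}\t"
                    f"{cmp.p_adjusted:.4g}\t{stars(cmp.p_adjusted)}\t-\n"
                )
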
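"""Non-parametric statistical battery for epoch comparisons.

Three layers, mirroring how a multi-epoch stress protocol is evaluated:

* :func:`kruskal_wallis` -- rank-based H test (tie-corrected) across any
  number of groups, with a chi-square p-value by default and an exact
  permutation p-value available for small samples;
* :func:`pairwise_epoch_tests` -- named epoch contrasts (e.g. stress vs the
  preceding no-stress epoch), each a two-group Kruskal-Wallis test at a
  Bonferroni-corrected per-test alpha = family_alpha / n_pairs;
* :func:`spearman_matrix` -- Spearman rank correlations between two metric
  families, Bonferroni-corrected over all |a| * |b| pairs (for 4 x 8
  families at FWER 0.05 the per-test alpha is 0.05/32 = 0.0015625,
  conventionally printed as 0.0016).

All tests are rank-based and therefore invariant to strictly increasing
transforms of the data.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "EpochSummary",
    "TestReport",
    "kruskal_wallis",
    "pairwise_epoch_tests",
    "spearman_matrix",
    "bonferroni_alpha",
]


@dataclass
class EpochSummary:
    """Per-subject mean values of one metric inside one protocol epoch."""

    metric_name: str
    epoch_label: str
    per_subject_means: np.ndarray

    def __post_init__(self) -> None:
        self.per_subject_means = np.asarray(self.per_subject_means, dtype=float)


@dataclass
class TestReport:
    comparison: str
    statistic: float
    p_value: float
    alpha: float
    significant: bool
    note: str = ""

    def as_row(self) -> dict:
        return {
            "comparison": self.comparison,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
            "note": self.note,
        }


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test threshold controlling the family-wise error rate."""
    if n_tests < 1:
        raise ValueError("need at least one test")
    return family_alpha / n_tests


def _h_statistic(ranks: np.ndarray, sizes: list[int], tie_factor: float) -> float:
    """Tie-corrected Kruskal-Wallis H from pooled ranks split by sizes."""
    n = ranks.size
    h = 0.0
    start = 0
    for sz in sizes:
        rs = ranks[start : start + sz].sum()
        h += rs * rs / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_factor if tie_factor > 0 else 0.0


def kruskal_wallis(
    groups: list[np.ndarray], method: str = "asymptotic", alpha: float = 0.05
) -> TestReport:
    """Kruskal-Wallis H test across groups.

    ``method="asymptotic"`` uses the chi-square approximation (scipy);
    ``method="exact"`` enumerates every assignment of the pooled values to
    the group sizes (feasible for total n up to ~10) and reports the
    fraction of assignments with H at least as large as observed.  Groups
    whose values are all identical across the pool yield H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestReport(
            comparison="kruskal-wallis",
            statistic=0.0,
            p_value=1.0,
            alpha=alpha,
            significant=False,
            note="all values identical",
        )
    if method == "asymptotic":
        h, p = sps.kruskal(*groups)
        return TestReport("kruskal-wallis", float(h), float(p), alpha, p <= alpha)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    n = pooled.size
    if n > 10:
        raise ValueError("exact permutation enumeration limited to n <= 10")
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_factor = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (n**3 - n)
    sizes = [g.size for g in groups]
    h_obs = _h_statistic(ranks, sizes, tie_factor)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        hp = _h_statistic(ranks[list(perm)], sizes, tie_factor)
        if hp >= h_obs - 1e-12:
            count += 1
        total += 1
    p = count / total
    return TestReport("kruskal-wallis (exact)", float(h_obs), float(p), alpha, p <= alpha)


def pairwise_epoch_tests(
    summaries: list[EpochSummary],
    pairs: list[tuple[str, str]],
    family_alpha: float = 0.05,
    method: str = "asymptotic",
) -> list[TestReport]:
    """Bonferroni-corrected two-group Kruskal-Wallis tests per epoch pair.

    ``summaries`` holds per-subject epoch means of a single metric; each
    named pair (a, b) is tested at alpha = family_alpha / len(pairs).
    Pairs naming an absent epoch are skipped with a warning.
    """
    by_label: dict[str, EpochSummary] = {}
    metric = summaries[0].metric_name if summaries else ""
    for s in summaries:
        by_label[s.epoch_label] = s
    alpha = bonferroni_alpha(family_alpha, len(pairs))
    reports = []
    for a, b in pairs:
        if a not in by_label or b not in by_label:
            warnings.warn(f"epoch pair ({a}, {b}) missing from summaries; skipped")
            continue
        rep = kruskal_wallis(
            [by_label[a].per_subject_means, by_label[b].per_subject_means],
            method=method,
            alpha=alpha,
        )
        rep.comparison = f"{metric}: {a} vs {b}"
        reports.append(rep)
    return reports


def spearman_matrix(
    a: dict[str, np.ndarray],
    b: dict[str, np.ndarray],
    family_alpha: float = 0.05,
) -> list[TestReport]:
    """Spearman rho for every pairing of series in family ``a`` with family
    ``b``, at the Bonferroni per-test alpha family_alpha / (|a| * |b|).

    Series must be aligned (same observations in the same order).  A
    constant series yields an undefined rho, reported as nan and flagged.
    """
    alpha = bonferroni_alpha(family_alpha, len(a) * len(b))
    reports = []
    for name_a, xa in a.items():
        for name_b, xb in b.items():
            xa = np.asarray(xa, dtype=float)
            xb = np.asarray(xb, dtype=float)
            if xa.size != xb.size:
                raise ValueError(f"series {name_a!r} and {name_b!r} not aligned")
            note = ""
            if np.all(xa == xa[0]) or np.all(xb == xb[0]):
                rho, p = float("nan"), float("nan")
                note = "constant series; rho undefined"
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho, p = sps.spearmanr(xa, xb)
            sig = bool(p <= alpha) if not math.isnan(p) else False
            reports.append(
                TestReport(f"{name_a} ~ {name_b}", float(rho), float(p), alpha, sig, note)
            )
    return reports
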
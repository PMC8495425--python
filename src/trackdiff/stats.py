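"""Group-level statistics for diffusion-coefficient comparisons.

ECDFs of per-trajectory D, two-sample Kolmogorov-Smirnov and Mann-Whitney
tests, Kruskal-Wallis with Dunn's post hoc comparisons, percent-of-vehicle
normalization, and summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import ValidationError

__all__ = [
    "GroupSummary",
    "KruskalDunnResult",
    "ecdf",
    "ks_compare",
    "mann_whitney",
    "kruskal_dunn",
    "percent_of_vehicle",
    "group_summary",
]


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float
    median: float
    q25: float
    q75: float


@dataclass
class KruskalDunnResult:
    H: float
    p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, z, p_raw, p_adj, reject


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF: returns (sorted values, fractions).

    F(x_(k)) = k/n, so the final fraction is exactly 1.0.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if len(x) == 0:
        raise ValidationError("ECDF of an empty sample is undefined")
    return x, np.arange(1, len(x) + 1) / len(x)


def ks_compare(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic two-sided p).

    The statistic is sup |ECDF_a − ECDF_b|.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("KS needs at least 2 observations per sample")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U with midrank ties.

    Exact two-sided p for min(n) ≤ 8 with no ties; normal approximation
    otherwise. Returns (U of the first sample, p).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 1 or len(b) < 1:
        raise ValidationError("Mann-Whitney needs non-empty samples")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_dunn(groups: dict, alpha: float = 0.05, adjust: str = "holm") -> KruskalDunnResult:
    """Kruskal-Wallis omnibus test with Dunn's post hoc pairwise z tests.

    ``groups`` maps label → sample. H carries the tie correction; Dunn's z
    uses pooled midranks,

        z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j)),

    with T = Σ(t³ − t) over tie groups. Pairwise p-values are adjusted by
    ``adjust`` ∈ {'holm', 'bonferroni', 'none'}.
    """
    if len(groups) < 3:
        raise ValidationError("Kruskal-Wallis post hoc needs >= 3 groups")
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    for k, s in zip(labels, samples):
        if len(s) < 2:
            raise ValidationError(f"group {k!r} has fewer than 2 observations")

    H, p = sps.kruskal(*samples)

    pooled = np.concatenate(samples)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for k, s in zip(labels, samples):
        mean_ranks[k] = float(np.mean(ranks[start : start + len(s)]))
        sizes[k] = len(s)
        start += len(s)

    _, tie_counts = np.unique(pooled, return_counts=True)
    T = float(np.sum(tie_counts**3 - tie_counts))
    var_term = N * (N + 1) / 12.0 - T / (12.0 * (N - 1))

    rows = []
    for ga, gb in combinations(labels, 2):
        z = (mean_ranks[ga] - mean_ranks[gb]) / np.sqrt(
            var_term * (1.0 / sizes[ga] + 1.0 / sizes[gb])
        )
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": ga, "group_b": gb, "z": float(z), "p_raw": float(p_raw)})
    table = pd.DataFrame(rows)
    if adjust == "none":
        table["p_adj"] = table["p_raw"]
    elif adjust in ("holm", "bonferroni"):
        table["p_adj"] = multipletests(table["p_raw"], method=adjust)[1]
    else:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    table["reject"] = table["p_adj"] < alpha
    return KruskalDunnResult(H=float(H), p=float(p), pairwise=table)


def percent_of_vehicle(treated, vehicle) -> tuple[float, float]:
    """Treated values as percent of the vehicle mean.

    Each treated value is divided by the vehicle mean and scaled to 100;
    returns (mean percent, SEM of the scaled values). The vehicle mean's
    own uncertainty is ignored, matching the usual plotting convention.
    """
    treated = np.asarray(treated, dtype=float)
    vehicle = np.asarray(vehicle, dtype=float)
    vmean = float(np.mean(vehicle))
    if not vmean > 0:
        raise ValidationError("vehicle mean must be positive")
    scaled = treated / vmean * 100.0
    n = len(scaled)
    sem = float(np.std(scaled, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(np.mean(scaled)), sem


def group_summary(values, label: str = "") -> GroupSummary:
    """Mean, SEM, median and interquartile range of one group."""
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValidationError("empty group")
    n = len(x)
    sem = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    q25, med, q75 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return GroupSummary(
        group=label,
        n=n,
        mean=float(np.mean(x)),
        sem=sem,
        median=float(med),
        q25=float(q25),
        q75=float(q75),
    )
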
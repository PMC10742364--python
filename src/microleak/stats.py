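"""Group comparison statistics for microleakage studies.

The analysis pipeline mirrors standard practice for capped dye-penetration
data: an a-priori sample-size computation from a one-way fixed-effects
ANOVA power analysis (Cohen's f), a Shapiro--Wilk normality gate, the
Kruskal--Wallis omnibus test on midranks with tie correction, and Dunn's
pairwise z-tests with Bonferroni adjustment over all k(k-1)/2 pairs.

The normality gate exists because the complete-penetration cap piles
probability mass at a single value, which reliably breaks normality and
pushes the analysis onto the nonparametric path.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupStudy",
    "TestReport",
    "sample_size_oneway",
    "shapiro_gate",
    "kruskal_wallis",
    "dunn_bonferroni",
    "summarize",
]


@dataclass
class GroupStudy:
    """Specimen-level penetration values grouped by manufacturing method."""

    groups: dict[str, list[float]]
    delaminated_counts: dict[str, int] = field(default_factory=dict)
    complete_penetration_counts: dict[str, int] = field(default_factory=dict)

    def labels(self) -> list[str]:
        return list(self.groups)

    def arrays(self) -> list[np.ndarray]:
        return [np.asarray(v, dtype=float) for v in self.groups.values()]


@dataclass
class TestReport:
    shapiro_p: dict[str, float]
    nonparametric: bool
    omnibus_statistic: float
    omnibus_p: float
    pairwise_adjusted_p: dict[tuple[str, str], float]
    group_mean: dict[str, float]
    group_sd: dict[str, float]
    group_n: dict[str, int]


def sample_size_oneway(
    effect_size_f: float,
    alpha: float = 0.05,
    power: float = 0.8,
    k: int = 3,
    n_max: int = 10**6,
) -> int:
    """Smallest balanced total N for a one-way fixed-effects ANOVA power target.

    The power at total sample size N is the noncentral-F survival
    probability above the level-``alpha`` critical value, with
    noncentrality lambda = f**2 * N and degrees of freedom
    (k - 1, N - k).  N is increased in steps of k (balanced allocation)
    until the power reaches the target.

    With f = 0.5, alpha = 0.05, power = 0.8 and k = 3 this returns 42.
    """
    if effect_size_f <= 0:
        raise ValueError("effect_size_f must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if k < 2:
        raise ValueError("need at least 2 groups")

    for n_total in range(2 * k, n_max + 1, k):
        df1, df2 = k - 1, n_total - k
        f_crit = sps.f.isf(alpha, df1, df2)
        achieved = sps.ncf.sf(f_crit, df1, df2, effect_size_f**2 * n_total)
        if achieved >= power:
            return n_total
    raise ValueError(f"target power {power} unreachable within N <= {n_max}")


def shapiro_gate(
    study: GroupStudy, alpha: float = 0.05
) -> tuple[dict[str, float], bool]:
    """Shapiro--Wilk p-value per group and the nonparametric-path flag.

    The flag is true iff any group rejects normality at ``alpha``.  A
    zero-variance group (all specimens at the cap, say) is treated as
    non-normal with p = 0 and a warning rather than an exception.
    """
    p_values: dict[str, float] = {}
    for label, values in study.groups.items():
        arr = np.asarray(values, dtype=float)
        if len(arr) < 3:
            raise ValueError(f"group {label!r} has n={len(arr)} < 3")
        if np.ptp(arr) == 0.0:
            warnings.warn(
                f"group {label!r} has zero variance; treated as non-normal",
                stacklevel=2,
            )
            p_values[label] = 0.0
        else:
            p_values[label] = float(sps.shapiro(arr).pvalue)
    flag = any(p < alpha for p in p_values.values())
    return p_values, flag


def kruskal_wallis(study: GroupStudy) -> tuple[float, float]:
    """Kruskal--Wallis H (midranks, tie-corrected) and chi-square p-value."""
    arrays = study.arrays()
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if sum(len(a) for a in arrays) < 5:
        raise ValueError("need total N >= 5")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def dunn_bonferroni(study: GroupStudy) -> dict[tuple[str, str], float]:
    """Dunn pairwise z-tests on midranks, Bonferroni-adjusted over all pairs.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j))
    with tie correction T = sum(t^3 - t) / (12 (N - 1)); each two-sided
    normal p-value is multiplied by k(k-1)/2 and clipped at 1.
    """
    labels = study.labels()
    arrays = study.arrays()
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")

    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + len(a)].mean())
        sizes.append(len(a))
        start += len(a)

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term

    n_pairs = len(labels) * (len(labels) - 1) // 2
    adjusted: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(len(labels)), 2):
        se = np.sqrt(variance_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0.0 else (mean_ranks[i] - mean_ranks[j]) / se
        raw = 2.0 * sps.norm.sf(abs(z))
        adjusted[(labels[i], labels[j])] = float(min(1.0, raw * n_pairs))
    return adjusted


def summarize(study: GroupStudy) -> dict[str, dict[str, float]]:
    """Per-group mean, sample sd (n-1), n, and failure-mode counts."""
    out: dict[str, dict[str, float]] = {}
    for label, values in study.groups.items():
        arr = np.asarray(values, dtype=float)
        if len(arr) == 0:
            raise ValueError(f"group {label!r} is empty")
        out[label] = {
            "n": int(len(arr)),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
            "delaminated": int(study.delaminated_counts.get(label, 0)),
            "complete_penetration": int(
                study.complete_penetration_counts.get(label, 0)
            ),
        }
    return out


def full_report(study: GroupStudy, alpha: float = 0.05) -> TestReport:
    """Run the whole procedure: normality gate, omnibus test, pairwise tests."""
    shapiro_p, flag = shapiro_gate(study, alpha)
    h, p = kruskal_wallis(study)
    pairwise = dunn_bonferroni(study)
    summary = summarize(study)
    return TestReport(
        shapiro_p=shapiro_p,
        nonparametric=flag,
        omnibus_statistic=h,
        omnibus_p=p,
        pairwise_adjusted_p=pairwise,
        group_mean={g: s["mean"] for g, s in summary.items()},
        group_sd={g: s["sd"] for g, s in summary.items()},
        group_n={g: int(s["n"]) for g, s in summary.items()},
    )
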
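"""Round summaries, timepoint analytics and composition comparisons.

These are the campaign-level analytics: per-round distribution of the
objective readout against the basal-medium reference, Spearman coupling
between sampling timepoints, per-medium changing ratios between two
timepoints, and a per-component rank-sum comparison of two sets of
optimized media (e.g. the top 10 of the regular vs. time-saving modes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .active_loop import CampaignResult
from .dataset import Dataset
from .design import DesignSpace, MediumCombination

__all__ = [
    "RoundSummary",
    "CompositionComparison",
    "round_summary",
    "fraction_above_reference",
    "timepoint_correlation",
    "changing_ratio",
    "compare_compositions",
    "exact_rank_sum_p",
]


@dataclass
class RoundSummary:
    round_label: str
    n_media: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    fraction_above_reference: float
    cv_mae_mean: Optional[float]

    def validate(self) -> None:
        if not (self.minimum <= self.q1 <= self.median <= self.q3 <= self.maximum):
            raise ValueError(f"{self.round_label}: quartile ordering violated")
        if not 0.0 <= self.fraction_above_reference <= 1.0:
            raise ValueError(f"{self.round_label}: fraction outside [0, 1]")


@dataclass
class CompositionComparison:
    components: list[str]
    group_a: dict[str, np.ndarray]  # per-component fold values, first media set
    group_b: dict[str, np.ndarray]
    statistic: np.ndarray  # Mann-Whitney U (group a)
    p_value: np.ndarray  # two-sided
    significant: np.ndarray  # p < alpha
    alpha: float

    def significant_components(self) -> list[str]:
        return [c for c, s in zip(self.components, self.significant) if s]


def _summarize(values: np.ndarray, label: str, reference: float, cv_mae) -> RoundSummary:
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # inclusive linear interpolation
    s = RoundSummary(
        round_label=label,
        n_media=len(values),
        minimum=float(values.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(values.max()),
        fraction_above_reference=float(np.mean(values > reference)),
        cv_mae_mean=cv_mae,
    )
    s.validate()
    return s


def round_summary(result: CampaignResult, reference_a450: float) -> list[RoundSummary]:
    """Distribution of per-medium mean A450 at the objective timepoint, per round."""
    if not result.rounds:
        raise ValueError("campaign has no rounds")
    ds = result.dataset
    obj = result.config.objective_timepoint
    out = [
        _summarize(
            ds.mean_a450(obj, ds.ids_in_round("initial")).to_numpy(),
            "initial",
            reference_a450,
            None,
        )
    ]
    for r in result.rounds:
        label = f"round{r.round_index}"
        cv_mae = r.cv_report.mean_mae if r.cv_report is not None else None
        out.append(
            _summarize(ds.mean_a450(obj, ds.ids_in_round(label)).to_numpy(), label,
                       reference_a450, cv_mae)
        )
    return out


def fraction_above_reference(
    dataset: Dataset, round_label: str, timepoint: float, reference: float
) -> float:
    """Fraction of the round's media whose mean A450 strictly exceeds the reference."""
    ids = dataset.ids_in_round(round_label)
    if not ids:
        raise ValueError(f"no media in round {round_label!r}")
    means = dataset.mean_a450(timepoint, ids).to_numpy()
    return float(np.mean(means > reference))


def timepoint_correlation(
    dataset: Dataset, t_a: float, t_b: float
) -> tuple[float, float]:
    """Spearman rank correlation between per-medium mean A450 at two timepoints."""
    a = dataset.mean_a450(t_a).to_numpy()
    b = dataset.mean_a450(t_b).to_numpy()
    if len(a) < 3:
        raise ValueError("need at least 3 media for a rank correlation")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def changing_ratio(dataset: Dataset, t_a: float, t_b: float) -> pd.DataFrame:
    """Per-medium ratio mean A450(t_b) / mean A450(t_a).

    Media whose denominator mean is not positive get a missing ratio and a
    raised ``flagged`` bit instead of an infinite or negative-signed ratio.
    """
    a = dataset.mean_a450(t_a)
    b = dataset.mean_a450(t_b)
    flagged = a <= 0
    ratio = pd.Series(np.where(flagged, np.nan, b / a.where(~flagged)), index=a.index)
    return pd.DataFrame({"ratio": ratio, "flagged": flagged})


# ---------------------------------------------------------------------------
# Rank-sum composition comparison
# ---------------------------------------------------------------------------

def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by dynamic programming over tie-averaged ranks.

    Enumerates the permutation null of the rank sum over all C(n, n1)
    assignments (ranks doubled so tie-averaged ranks stay integral).
    Returns (U statistic of ``x``, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # tie-averaged
    doubled = np.rint(2 * ranks).astype(int)
    s_obs = int(np.rint(doubled[:n1].sum()))
    u_obs = (s_obs / 2.0) - n1 * (n1 + 1) / 2.0

    max_sum = int(doubled.sum())
    # dp[j][s] = number of j-subsets of the doubled ranks with sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in doubled:
        for j in range(n1, 0, -1):
            dp[j, r:] += dp[j - 1, : max_sum + 1 - r]
    dist = dp[n1]
    total = dist.sum()
    p_le = dist[: s_obs + 1].sum() / total
    p_ge = dist[s_obs:].sum() / total
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return float(u_obs), float(p)


def compare_compositions(
    best_a: Sequence[MediumCombination],
    best_b: Sequence[MediumCombination],
    space: DesignSpace,
    alpha: float = 0.05,
) -> CompositionComparison:
    """Per-component two-sided rank-sum test between two sets of media.

    Uses the exact permutation null when both groups have <= 10 media, and
    the tie-corrected normal approximation otherwise; components flagged at
    ``alpha`` are those whose concentrations differ between the two sets.
    """
    if len(best_a) == 0 or len(best_b) == 0:
        raise ValueError("both media lists must be non-empty")
    names = space.names
    ga, gb, stat, pval = {}, {}, [], []
    A = np.array([c.folds for c in best_a], dtype=float)
    B = np.array([c.folds for c in best_b], dtype=float)
    exact = len(best_a) <= 10 and len(best_b) <= 10
    for j, name in enumerate(names):
        xa, xb = A[:, j], B[:, j]
        ga[name], gb[name] = xa, xb
        if np.all(xa == xa[0]) and np.all(xb == xa[0]):
            stat.append(len(xa) * len(xb) / 2.0)
            pval.append(1.0)
            continue
        if exact:
            u, p = exact_rank_sum_p(xa, xb)
        else:
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
            u, p = float(res.statistic), float(res.pvalue)
        stat.append(u)
        pval.append(p)
    pval_arr = np.array(pval)
    return CompositionComparison(
        components=names,
        group_a=ga,
        group_b=gb,
        statistic=np.array(stat),
        p_value=pval_arr,
        significant=pval_arr < alpha,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Plot bundle (optional; mirrors the campaign figures' layouts)
# ---------------------------------------------------------------------------

def plot_round_boxplots(result: CampaignResult, reference_a450: float, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ds = result.dataset
    obj = result.config.objective_timepoint
    labels = ["initial"] + [f"round{r.round_index}" for r in result.rounds]
    data = [ds.mean_a450(obj, ds.ids_in_round(l)).to_numpy() for l in labels]
    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
    ax.boxplot(data, tick_labels=labels)
    ax.axhline(reference_a450, color="gray", lw=1)
    ax.set_ylabel(f"A450 at {obj:g} h (a.u.)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_timepoint_scatter(dataset: Dataset, t_a: float, t_b: float, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = dataset.mean_a450(t_a)
    b = dataset.mean_a450(t_b)
    rho, p = timepoint_correlation(dataset, t_a, t_b)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(a, b, s=12, alpha=0.6)
    ax.set_xlabel(f"A450 at {t_a:g} h")
    ax.set_ylabel(f"A450 at {t_b:g} h")
    ax.set_title(f"Spearman rho = {rho:.3f} (p = {p:.2g})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_importance(report, path, top_k: int = 10) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = report.top(top_k)
    names = [n for n, _ in pairs][::-1]
    vals = [v for _, v in pairs][::-1]
    sd = dict(zip(report.components, report.sd))
    fig, ax = plt.subplots(figsize=(5, 0.35 * len(names) + 1.5))
    ax.barh(names, vals, xerr=[sd[n] for n in names])
    ax.set_xlabel("impurity-reduction importance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
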
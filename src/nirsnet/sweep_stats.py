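"""Threshold sweep and between-group statistics.

Network indices depend on the binarization threshold, so they are computed
over a grid of thresholds (default 0.275 to 0.625 in steps of 0.025, 15
values) for every subject, and the two behavioral groups are compared with
two-sample t-tests at each threshold.  The grid bounds follow the usual
practice: the lower bound should keep only statistically significant
correlations, the upper bound should keep the mean degree above ln(N) so the
networks stay (approximately) connected; :func:`check_bounds` reports both
diagnostics for a given dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import CorrelationMatrix, pearson_matrix
from .graph_metrics import binarize
from .null_models import small_world_metrics
from .preprocess import bandpass, normalize_and_average, segment
from .synthetic_data import Recording, SimulationConfig, simulate_cohort

__all__ = [
    "METRICS",
    "SweepResult",
    "threshold_grid",
    "check_bounds",
    "subject_metrics",
    "compare_groups",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: metric columns carried through the sweep and the group comparison
METRICS = ("C", "L", "K_mean", "sigma")


def threshold_grid(
    t_min: float = 0.275, t_max: float = 0.625, step: float = 0.025
) -> np.ndarray:
    """Inclusive arithmetic threshold grid (default: 15 values)."""
    if step <= 0:
        raise ValueError("step must be positive")
    if t_min > t_max:
        raise ValueError("t_min must not exceed t_max")
    n = int(np.floor((t_max - t_min) / step + 1e-9)) + 1
    grid = t_min + step * np.arange(n)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    return grid


class BoundsCheck(NamedTuple):
    """Diagnostic grid bounds: significance floor and connectivity ceiling."""

    t_min_ok: float | None
    t_max_ok: float | None
    r_critical: float


def critical_r(n_samples: int, alpha: float = 0.05) -> float:
    """Two-sided critical |r| for testing r = 0 with n_samples observations.

    From the exact relation t = r sqrt((n-2)/(1-r^2)) under the null.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    df = n_samples - 2
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_crit / np.sqrt(df + t_crit**2))


def check_bounds(
    matrices: Sequence[CorrelationMatrix],
    n_samples: int,
    alpha: float = 0.05,
    grid: np.ndarray | None = None,
) -> BoundsCheck:
    """Report which part of the grid satisfies the usual bound heuristics.

    ``t_min_ok`` — smallest grid value at or above the critical |r| for
    significance at ``alpha`` given ``n_samples``; ``t_max_ok`` — largest grid
    value at which every supplied network keeps mean degree >= ln(N).  Both
    are diagnostics: nothing is enforced.
    """
    if grid is None:
        grid = threshold_grid()
    r_crit = critical_r(n_samples, alpha)
    ok_min = [t for t in grid if t >= r_crit]
    t_min_ok = float(ok_min[0]) if ok_min else None
    t_max_ok = None
    if matrices:
        n = matrices[0].n_channels
        for t in grid:
            mean_degrees = [
                binarize(m, float(t)).adjacency.sum() / n for m in matrices
            ]
            if min(mean_degrees) >= np.log(n):
                t_max_ok = float(t)
    return BoundsCheck(t_min_ok=t_min_ok, t_max_ok=t_max_ok, r_critical=r_crit)


def subject_metrics(
    recordings: Sequence[Recording],
    case: str,
    grid: np.ndarray | None = None,
    null_n: int = 100,
    n_swaps: int | None = None,
    seed: int | np.random.SeedSequence | None = None,
    low: float = 0.01,
    high: float = 0.3,
    use_average: bool = False,
    normalize_scale: bool = False,
) -> pd.DataFrame:
    """Per-subject, per-threshold network metrics for one trial case.

    Pipeline per recording: band-pass -> segment(case) -> normalize ->
    Pearson matrix -> for each threshold: binarize, C/L/K_mean, null ensemble,
    sigma.  Subjects without usable trials are dropped with a warning.
    Returns a tidy DataFrame with one row per subject × threshold.
    """
    if grid is None:
        grid = threshold_grid()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rows: list[dict] = []
    for recording in recordings:
        subject_ss = ss.spawn(1)[0]
        filtered = bandpass(recording, low=low, high=high)
        try:
            epoch_set = segment(filtered, case)
        except ValueError as exc:
            logger.warning("dropping %s: %s", recording.subject_id, exc)
            continue
        if epoch_set.n_trials == 0:
            logger.warning(
                "dropping %s: no usable %s trials", recording.subject_id, case
            )
            continue
        epoch_set = normalize_and_average(epoch_set, scale=normalize_scale)
        matrix = pearson_matrix(epoch_set, use_average=use_average)
        for threshold, child in zip(grid, subject_ss.spawn(len(grid))):
            net = binarize(matrix, float(threshold))
            m = small_world_metrics(
                net, n_random=null_n, n_swaps=n_swaps, seed=child, strict=False
            )
            rows.append(
                {
                    "subject_id": recording.subject_id,
                    "group": recording.group,
                    "case": case,
                    "threshold": float(threshold),
                    "C": m.C,
                    "L": m.L,
                    "K_mean": m.K_mean,
                    "C_rand": m.C_rand,
                    "L_rand": m.L_rand,
                    "sigma": m.sigma,
                    "connected": m.connected,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SweepResult:
    """Group-level metric curves and per-threshold two-sample tests.

    ``stats`` is tidy: one row per threshold × metric with group means, SDs,
    sample sizes, the t statistic, two-sided p value, and a significance flag
    at ``alpha``; disconnection counts per group are included per threshold.
    """

    thresholds: np.ndarray
    group_a: str
    group_b: str
    case: str
    stats: pd.DataFrame
    alpha: float = 0.05
    tables: dict = field(default_factory=dict)

    def metric_stats(self, metric: str) -> pd.DataFrame:
        return self.stats[self.stats["metric"] == metric].reset_index(drop=True)

    def significant_fraction(self, metric: str) -> float:
        sub = self.metric_stats(metric)
        return float(sub["significant"].mean())


def compare_groups(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    equal_var: bool = False,
    paired: bool = False,
    alpha: float = 0.05,
    fdr: bool = False,
) -> SweepResult:
    """Two-sample t-tests between groups at every threshold and metric.

    Welch (unequal variance) by default; ``equal_var=True`` gives Student's
    pooled test, ``paired=True`` a paired test on subject-sorted rows.  With
    ``fdr=True`` the significance flags use Benjamini-Hochberg adjusted p
    values across the thresholds of each metric (raw p values are always
    reported).
    """
    if table_a.empty or table_b.empty:
        raise ValueError("both metric tables must be nonempty")
    grid_a = np.sort(table_a["threshold"].unique())
    grid_b = np.sort(table_b["threshold"].unique())
    if len(grid_a) != len(grid_b) or not np.allclose(grid_a, grid_b):
        raise ValueError("threshold grids differ between the two tables")
    group_a = str(table_a["group"].iloc[0])
    group_b = str(table_b["group"].iloc[0])
    case = str(table_a["case"].iloc[0]) if "case" in table_a else ""

    rows = []
    for threshold in grid_a:
        sub_a = table_a[np.isclose(table_a["threshold"], threshold)]
        sub_b = table_b[np.isclose(table_b["threshold"], threshold)]
        if paired:
            sub_a = sub_a.sort_values("subject_id")
            sub_b = sub_b.sort_values("subject_id")
        for metric in METRICS:
            a = sub_a[metric].to_numpy(dtype=float)
            b = sub_b[metric].to_numpy(dtype=float)
            a_ok, b_ok = a[np.isfinite(a)], b[np.isfinite(b)]
            if len(a_ok) < 2 or len(b_ok) < 2:
                raise ValueError(
                    f"fewer than 2 finite values for {metric} at T={threshold} "
                    "in one group"
                )
            if paired:
                if len(a) != len(b):
                    raise ValueError("paired test requires equal group sizes")
                t_stat, p_val = stats.ttest_rel(a, b, nan_policy="omit")
            else:
                t_stat, p_val = stats.ttest_ind(
                    a_ok, b_ok, equal_var=equal_var
                )
            rows.append(
                {
                    "threshold": float(threshold),
                    "metric": metric,
                    "mean_a": float(a_ok.mean()),
                    "sd_a": float(a_ok.std(ddof=1)),
                    "n_a": int(len(a_ok)),
                    "mean_b": float(b_ok.mean()),
                    "sd_b": float(b_ok.std(ddof=1)),
                    "n_b": int(len(b_ok)),
                    "t": float(t_stat),
                    "p": float(p_val),
                    "n_disconnected_a": int((~sub_a["connected"]).sum())
                    if "connected" in sub_a
                    else 0,
                    "n_disconnected_b": int((~sub_b["connected"]).sum())
                    if "connected" in sub_b
                    else 0,
                }
            )
    result = pd.DataFrame(rows)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        result["p_fdr"] = np.nan
        for metric in METRICS:
            mask = result["metric"] == metric
            result.loc[mask, "p_fdr"] = multipletests(
                result.loc[mask, "p"], method="fdr_bh"
            )[1]
        result["significant"] = result["p_fdr"] < alpha
    else:
        result["significant"] = result["p"] < alpha
    return SweepResult(
        thresholds=grid_a,
        group_a=group_a,
        group_b=group_b,
        case=case,
        stats=result,
        alpha=alpha,
    )


def run_pipeline(
    config: SimulationConfig | None = None,
    case: str = "win-win",
    grid: np.ndarray | None = None,
    null_n: int = 100,
    n_swaps: int | None = None,
    seed: int | None = None,
    **compare_kwargs,
) -> SweepResult:
    """End-to-end run on a synthetic cohort: simulate, sweep, compare.

    ``seed`` (when given) seeds the null ensembles; the cohort itself is
    seeded by ``config.seed``.  The per-group metric tables are attached to
    the result as ``result.tables``.
    """
    if config is None:
        config = SimulationConfig()
    cohort = simulate_cohort(config)
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(2)
    tables = {}
    for group, group_seed in zip(("spontaneous", "control"), seeds):
        recs = [r for r in cohort if r.group == group]
        tables[group] = subject_metrics(
            recs, case, grid=grid, null_n=null_n, n_swaps=n_swaps, seed=group_seed
        )
    result = compare_groups(
        tables["spontaneous"], tables["control"], **compare_kwargs
    )
    result.tables = tables
    return result
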
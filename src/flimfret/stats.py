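"""Statistical comparisons for lifetime data.

Two-group comparisons use an unpaired two-tailed t-test (Student's pooled
test by default, Welch behind a flag), matching standard Prism-style
analysis.  Peri-cellular gradients are summarised as the ordinary
least-squares slope of lifetime on ring-bin index per cell; groups of cells
are compared either by a t-test on per-cell slopes (primary) or by a pooled
regression with a group x ring interaction term (alternative).  Time
courses are tested for convergence to a reference (e.g. the donor-only
control) by scanning t-tests over timepoints.

All p-values are reported raw; no multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .contours import RingProfile

__all__ = [
    "GroupSamples",
    "TTestResult",
    "SlopeComparison",
    "ConvergenceResult",
    "ttest_unpaired",
    "per_cell_slope",
    "compare_slopes",
    "timecourse_convergence",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GroupSamples:
    """A labelled group of scalar observations (per-hydrogel or per-cell
    lifetimes, or per-cell slopes)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("each group needs at least 2 observations")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class TTestResult:
    """Unpaired two-tailed t-test result."""

    statistic: float
    df: float
    pvalue: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    equal_variance: bool

    def significant(self, alpha: float = DEFAULT_ALPHA) -> bool:
        return self.pvalue < alpha


def _as_group(x, label: str) -> GroupSamples:
    return x if isinstance(x, GroupSamples) else GroupSamples(label, np.asarray(x, dtype=float))


def ttest_unpaired(a, b, equal_variance: bool = True) -> TTestResult:
    """Unpaired two-tailed t-test between two groups.

    ``equal_variance=True`` gives Student's pooled test (default),
    ``False`` Welch's test.  Raises if both groups are degenerate
    (zero variance in each).
    """
    a = _as_group(a, "a")
    b = _as_group(b, "b")
    if a.sd == 0.0 and b.sd == 0.0:
        raise ValueError("both groups have zero variance; t-test undefined")
    with warnings.catch_warnings():
        # near-identical groups trigger scipy's catastrophic-cancellation
        # warning; the t = 0 case is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a.values, b.values, equal_var=equal_variance)
    df = float(res.df)
    stat = float(res.statistic)
    p = float(res.pvalue)
    if stat == 0.0:
        p = 1.0  # exact null: identical means
    return TTestResult(
        statistic=stat,
        df=df,
        pvalue=p,
        mean_a=a.mean,
        mean_b=b.mean,
        sd_a=a.sd,
        sd_b=b.sd,
        equal_variance=equal_variance,
    )


def per_cell_slope(profile: RingProfile | pd.DataFrame) -> float:
    """OLS slope of lifetime on ring-bin index for one cell (ns per ring bin).

    Invalid ring bins are excluded listwise; at least 3 valid bins are
    required.
    """
    if isinstance(profile, RingProfile):
        frame = profile.to_frame()
    else:
        frame = profile
    valid = frame[frame["valid"].astype(bool)]
    if len(valid) < 3:
        raise ValueError("need at least 3 valid ring bins for a slope")
    x = valid["ring_bin"].to_numpy(dtype=float)
    y = valid["tau_ns"].to_numpy(dtype=float)
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


@dataclass
class SlopeComparison:
    """Between-group comparison of per-cell lifetime-vs-ring slopes.

    ``ttest`` is the primary per-cell-then-t-test result;
    ``interaction_pvalue`` the alternative pooled-regression test of the
    group x ring interaction coefficient.
    """

    slopes_a: np.ndarray
    slopes_b: np.ndarray
    ttest: TTestResult
    interaction_coef: float | None = None
    interaction_pvalue: float | None = None
    labels: tuple[str, str] = ("A", "B")

    @property
    def mean_slopes(self) -> tuple[float, float]:
        return float(np.mean(self.slopes_a)), float(np.mean(self.slopes_b))

    @property
    def pvalue(self) -> float:
        return self.ttest.pvalue


def _group_slopes(group: Sequence) -> np.ndarray:
    out = []
    for item in group:
        if isinstance(item, (RingProfile, pd.DataFrame)):
            out.append(per_cell_slope(item))
        else:
            out.append(float(item))
    return np.asarray(out, dtype=float)


def compare_slopes(
    group_a: Sequence,
    group_b: Sequence,
    equal_variance: bool = True,
    labels: tuple[str, str] = ("A", "B"),
) -> SlopeComparison:
    """Compare lifetime-vs-ring slopes between two groups of cells.

    Each group is a sequence of per-cell ring profiles (or precomputed
    slopes).  Primary test: unpaired two-tailed t-test on per-cell slopes.
    A pooled OLS with a group x ring interaction is fitted as an
    alternative whenever profiles (not bare slopes) are supplied.
    """
    slopes_a = _group_slopes(group_a)
    slopes_b = _group_slopes(group_b)
    if slopes_a.size < 2 or slopes_b.size < 2:
        raise ValueError("need at least 2 cells per group")
    res = ttest_unpaired(
        GroupSamples(labels[0], slopes_a), GroupSamples(labels[1], slopes_b), equal_variance
    )
    coef = pval = None
    frames = []
    for grp, items in zip((0.0, 1.0), (group_a, group_b)):
        for item in items:
            if isinstance(item, (RingProfile, pd.DataFrame)):
                f = item.to_frame() if isinstance(item, RingProfile) else item
                f = f[f["valid"].astype(bool)][["ring_bin", "tau_ns"]].copy()
                f["group"] = grp
                frames.append(f)
    if frames and len(frames) == slopes_a.size + slopes_b.size:
        data = pd.concat(frames, ignore_index=True)
        X = pd.DataFrame(
            {
                "ring": data["ring_bin"],
                "group": data["group"],
                "ring_x_group": data["ring_bin"] * data["group"],
            }
        )
        fit = sm.OLS(data["tau_ns"], sm.add_constant(X)).fit()
        coef = float(fit.params["ring_x_group"])
        pval = float(fit.pvalues["ring_x_group"])
    return SlopeComparison(
        slopes_a=slopes_a,
        slopes_b=slopes_b,
        ttest=res,
        interaction_coef=coef,
        interaction_pvalue=pval,
        labels=labels,
    )


@dataclass
class ConvergenceResult:
    """First timepoint at which a time course is statistically
    indistinguishable from the reference, with the full p(t) trace.
    ``time`` is None when the series never converges."""

    time: float | None
    index: int | None
    pvalues: np.ndarray
    times: np.ndarray
    alpha: float

    @property
    def converged(self) -> bool:
        return self.time is not None


def timecourse_convergence(
    times: Sequence[float],
    replicates: Sequence[Sequence[float]],
    reference,
    alpha: float = DEFAULT_ALPHA,
    equal_variance: bool = True,
) -> ConvergenceResult:
    """Earliest timepoint whose t-test against the reference gives p > alpha.

    Parameters
    ----------
    times : sequence of float
        Timepoints (minutes), one per replicate set.
    replicates : sequence of sequences
        >= 2 replicate lifetimes per timepoint.
    reference : GroupSamples or array-like
        Reference observations (e.g. donor-only control), >= 2 values.
    """
    times = np.asarray(times, dtype=float)
    if times.size != len(replicates):
        raise ValueError("times and replicates must align")
    ref = _as_group(reference, "reference")
    pvalues = np.empty(times.size)
    for i, reps in enumerate(replicates):
        grp = GroupSamples(f"t={times[i]}", np.asarray(reps, dtype=float))
        try:
            pvalues[i] = ttest_unpaired(grp, ref, equal_variance).pvalue
        except ValueError:  # both degenerate -> identical -> indistinguishable
            pvalues[i] = 1.0
    above = np.nonzero(pvalues > alpha)[0]
    if above.size:
        idx = int(above[0])
        return ConvergenceResult(float(times[idx]), idx, pvalues, times, alpha)
    return ConvergenceResult(None, None, pvalues, times, alpha)
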
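"""Quantitative analyses of gain-modulated tuning curves.

Covers: linearity of eye-position modulation measured by the coefficient of
determination R^2 of an ordinary least-squares line fit; population
histograms of R^2; a multiplicativity test comparing each fixation's curve
to a scaled copy of the straight-ahead reference; and a coarse profile
classification (monotonic / peaked / unresponsive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hardwired import (
    FixationFamily,
    PopulationGrid,
    ResponseCurve,
    eye_sweep,
)

__all__ = [
    "LinearityResult",
    "MultiplicativityResult",
    "R2Histogram",
    "linearity_r2",
    "r2_histogram",
    "multiplicativity_test",
    "classify_profile",
    "population_linearity",
    "curves_from_csv",
    "analyze_curves",
]

# Significant-activity gate: a curve counts as "active" when its maximum rate
# and its dynamic range both clear these floors.  The thresholds are a
# package convention (chosen to exclude near-silent trained outputs) and are
# configurable at every call site.
ACTIVITY_MIN = 0.1
RANGE_MIN = 0.05

#: SST below this is treated as a flat (degenerate) curve with R^2 := 0.
DEGENERATE_SST = 1e-12


@dataclass(frozen=True)
class LinearityResult:
    """OLS line fit of rate against the swept variable."""

    r_squared: float
    slope: float
    intercept: float
    active: bool
    degenerate: bool = False


@dataclass(frozen=True)
class MultiplicativityResult:
    """Best scalar fits of each curve to the reference, and the worst misfit."""

    scale_constants: dict  # fixation (deg) -> optimal scale constant
    max_relative_residual: float
    passes: bool
    tolerance: float


@dataclass(frozen=True)
class R2Histogram:
    bin_edges: tuple
    proportions: tuple  # percent per bin, summing to 100
    n: int


def linearity_r2(
    curve: ResponseCurve,
    *,
    activity_min: float = ACTIVITY_MIN,
    range_min: float = RANGE_MIN,
) -> LinearityResult:
    """Coefficient of determination of a linear fit to a tuning curve.

    Fits rate against the abscissa by ordinary least squares with intercept;
    ``R^2 = 1 - SSE/SST`` lies in [0, 1].  A flat curve (SST ~ 0) — and,
    by the same symmetry argument, any curve whose best-fit slope is zero —
    yields R^2 = 0.  The ``active`` flag reports whether the curve clears
    the significant-activity gate (max rate >= ``activity_min`` and dynamic
    range >= ``range_min``); R^2 is computed regardless.
    """
    if len(curve) < 3:
        raise ValueError("linearity_r2 requires at least 3 points")
    y = curve.rates
    active = bool(y.max() >= activity_min and (y.max() - y.min()) >= range_min)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst < DEGENERATE_SST:
        return LinearityResult(0.0, 0.0, float(y.mean()), active, degenerate=True)
    fit = stats.linregress(curve.abscissa, y)
    r2 = float(fit.rvalue**2)
    if r2 < 1e-15:  # zero-slope fit at double precision (symmetric curves)
        r2 = 0.0
    return LinearityResult(r2, float(fit.slope), float(fit.intercept), active)


def r2_histogram(values, bin_width: float = 0.2) -> R2Histogram:
    """Bin R^2 values into half-open bins [0, w), ..., [1-w, 1] (top closed).

    Returns per-bin percentages of the population.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("r2_histogram requires a non-empty list")
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError("R^2 values must lie in [0, 1]")
    nbins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    counts, _ = np.histogram(vals, bins=edges)  # last bin closed above
    props = counts / vals.size * 100.0
    return R2Histogram(
        bin_edges=tuple(edges), proportions=tuple(props), n=int(vals.size)
    )


def multiplicativity_test(
    family: FixationFamily, tolerance: float = 0.05
) -> MultiplicativityResult:
    """Test whether fixation curves are scalar multiples of the reference.

    For each non-reference fixation e the scale constant minimizing
    ``sum((c * r0 - r_e)^2)`` is ``c_e = <r0, r_e> / <r0, r0>``; the
    reported statistic is ``max_e ||c_e r0 - r_e|| / ||r_e||``.  Exact
    scalar multiples give residual 0.
    """
    r0 = family.reference_curve.rates
    denom = float(np.dot(r0, r0))
    if denom < 1e-300 or np.linalg.norm(r0) == 0:
        raise ValueError("reference curve has zero norm")
    constants: dict = {}
    worst = 0.0
    for f, c in zip(family.fixations, family.curves):
        if np.isclose(f, family.reference_fixation):
            continue
        re_ = c.rates
        ce = float(np.dot(r0, re_) / denom)
        constants[f] = ce
        norm_e = float(np.linalg.norm(re_))
        resid = float(np.linalg.norm(ce * r0 - re_)) / norm_e if norm_e > 0 else 0.0
        worst = max(worst, resid)
    return MultiplicativityResult(
        scale_constants=constants,
        max_relative_residual=worst,
        passes=worst <= tolerance,
        tolerance=tolerance,
    )


def classify_profile(
    curve: ResponseCurve,
    *,
    activity_min: float = ACTIVITY_MIN,
    range_min: float = RANGE_MIN,
    edge_steps: int = 2,
    interior_margin_deg: float = 5.0,
    drop_fraction: float = 0.2,
    tv_slack: float = 1.1,
) -> str:
    """Coarse tuning-profile label: 'monotonic', 'peaked' or 'unresponsive'.

    Unresponsive if the activity gate fails.  Monotonic if the maximum lies
    within ``edge_steps`` grid points of a boundary and the curve's total
    variation does not exceed ``tv_slack`` times its range (i.e., it is
    essentially single-sloped).  Peaked if the maximum sits at least
    ``interior_margin_deg`` degrees inside both boundaries and the rate falls
    by at least ``drop_fraction`` of the range on both sides.  Anything else
    is labeled monotonic (the larger-R^2 reading of an ambiguous curve).
    """
    if len(curve) < 3:
        raise ValueError("classify_profile requires at least 3 points")
    y = curve.rates
    x = curve.abscissa
    rng = float(y.max() - y.min())
    if not (y.max() >= activity_min and rng >= range_min):
        return "unresponsive"
    am = int(np.argmax(y))
    tv = float(np.sum(np.abs(np.diff(y))))
    near_edge = am <= edge_steps or am >= len(y) - 1 - edge_steps
    if near_edge and tv <= tv_slack * rng:
        return "monotonic"
    interior = (x[am] - x[0]) >= interior_margin_deg and (
        x[-1] - x[am]
    ) >= interior_margin_deg
    if (
        interior
        and (y[am] - y[: am + 1].min()) >= drop_fraction * rng
        and (y[am] - y[am:].min()) >= drop_fraction * rng
    ):
        return "peaked"
    return "monotonic"


def population_linearity(
    grid: PopulationGrid, eye_grid=None, rho: float | None = None
) -> pd.DataFrame:
    """Eye-sweep linearity for every neuron of a hardwired population.

    Each neuron is swept across eye positions with the stimulus clamped to
    its preferred retinal location.  ``rho`` optionally overrides the grid's
    eye-position tuning width for the sweep (the lattice is unchanged).
    Returns a frame with columns alpha, beta, r_squared, slope, intercept,
    active.
    """
    from dataclasses import replace as _replace

    if rho is not None:
        grid = _replace(
            grid, eye_template=_replace(grid.eye_template, width=float(rho))
        )
    rows = []
    for n in grid.neurons:
        res = linearity_r2(eye_sweep(n, grid, eye_grid))
        rows.append(
            (n.alpha, n.beta, res.r_squared, res.slope, res.intercept, res.active)
        )
    return pd.DataFrame(
        rows, columns=["alpha", "beta", "r_squared", "slope", "intercept", "active"]
    )


def curves_from_csv(path) -> dict:
    """Load user tuning curves from CSV columns unit_id, abscissa_deg, rate."""
    df = pd.read_csv(path, comment="#")
    required = {"unit_id", "abscissa_deg", "rate"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must contain columns {sorted(required)}")
    out = {}
    for uid, grp in df.groupby("unit_id"):
        grp = grp.sort_values("abscissa_deg")
        out[uid] = ResponseCurve(
            abscissa=grp["abscissa_deg"].to_numpy(),
            rates=grp["rate"].to_numpy(),
            context={"unit_id": uid},
        )
    return out


def analyze_curves(curves: dict, **gate_kwargs) -> pd.DataFrame:
    """Per-curve linearity and profile class for a dict of ResponseCurves."""
    rows = []
    for uid, c in curves.items():
        res = linearity_r2(c, **{k: v for k, v in gate_kwargs.items()
                                 if k in ("activity_min", "range_min")})
        rows.append(
            (uid, res.r_squared, res.slope, res.intercept, res.active,
             classify_profile(c, **gate_kwargs))
        )
    return pd.DataFrame(
        rows,
        columns=["unit_id", "r_squared", "slope", "intercept", "active", "profile"],
    )
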
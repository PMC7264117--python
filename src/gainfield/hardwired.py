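"""Hardwired gain-field population.

A single layer of visual output neurons tiles the joint space of preferred
retinal location alpha and preferred eye position beta in integer steps.
Each neuron's activation is the sum of a retinal Gaussian and an eye-position
Gaussian, passed through a shared sigmoid.  With the default ranges
([-10, 10] deg retinal x [-35, 35] deg eye) the population has
21 x 71 = 1491 neurons.

Neurons are identified by their (alpha, beta) pair.  The internal storage
order is eye-major (beta slowest, alpha fastest); it is a recorded
convention only and carries no scientific meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .tuning import SigmoidSpec, TuningSpec, combined_activation, sigmoid_rate

__all__ = [
    "HardwiredNeuron",
    "PopulationGrid",
    "ResponseCurve",
    "FixationFamily",
    "DEFAULT_RETINAL_RANGE",
    "DEFAULT_EYE_RANGE",
    "DEFAULT_SIGMA",
    "DEFAULT_RHO",
    "DEFAULT_PEAK",
    "DEFAULT_SIGMOID",
    "build_population",
    "neuron_rate",
    "eye_sweep",
    "retinal_sweep_family",
    "population_to_frame",
]

DEFAULT_RETINAL_RANGE = (-10.0, 10.0)
DEFAULT_EYE_RANGE = (-35.0, 35.0)
DEFAULT_SIGMA = 6.0  # retinal tuning width (deg)
DEFAULT_RHO = 20.0  # eye-position tuning width (deg)
DEFAULT_PEAK = 0.485  # h_max for both components
DEFAULT_SIGMOID = SigmoidSpec(slope=1.9, threshold=0.99)


@dataclass(frozen=True)
class HardwiredNeuron:
    """A visual output neuron identified by its preferred (alpha, beta)."""

    alpha: float  # preferred retinal location (deg)
    beta: float  # preferred eye position (deg)


@dataclass
class ResponseCurve:
    """Firing rate as a function of one swept variable.

    ``abscissa`` is strictly increasing (degrees); ``rates`` lie in [0, 1];
    ``context`` records which variable was swept and what was held fixed.
    """

    abscissa: np.ndarray
    rates: np.ndarray
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.abscissa.ndim != 1 or self.abscissa.shape != self.rates.shape:
            raise ValueError("abscissa and rates must be 1-D and equal length")
        if len(self.abscissa) and np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("abscissa must be strictly increasing")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")
        if np.any(self.rates < -1e-12) or np.any(self.rates > 1 + 1e-12):
            raise ValueError("rates must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.abscissa)


@dataclass
class FixationFamily:
    """One retinal-sweep curve per fixation, sharing the retinal abscissa."""

    fixations: list
    curves: list
    reference_fixation: float = 0.0

    def __post_init__(self) -> None:
        if len(self.fixations) != len(self.curves):
            raise ValueError("one curve per fixation required")
        ref = [c for f, c in zip(self.fixations, self.curves)
               if np.isclose(f, self.reference_fixation)]
        if not ref:
            raise ValueError(
                f"reference fixation {self.reference_fixation} deg missing"
            )
        first = self.curves[0].abscissa
        for c in self.curves[1:]:
            if not np.array_equal(c.abscissa, first):
                raise ValueError("all curves must share the same abscissa")

    @property
    def reference_curve(self) -> ResponseCurve:
        for f, c in zip(self.fixations, self.curves):
            if np.isclose(f, self.reference_fixation):
                return c
        raise ValueError("reference fixation missing")  # pragma: no cover


@dataclass
class PopulationGrid:
    """The full (alpha, beta) lattice with its shared tuning templates."""

    neurons: list
    retinal_range: tuple
    eye_range: tuple
    step: float
    retinal_template: TuningSpec  # preferred field is per-neuron
    eye_template: TuningSpec
    sigmoid: SigmoidSpec

    def __len__(self) -> int:
        return len(self.neurons)

    @property
    def retinal_points(self) -> np.ndarray:
        return _grid_points(self.retinal_range, self.step)

    @property
    def eye_points(self) -> np.ndarray:
        return _grid_points(self.eye_range, self.step)

    def retinal_spec(self, neuron: HardwiredNeuron) -> TuningSpec:
        return replace(self.retinal_template, preferred=neuron.alpha)

    def eye_spec(self, neuron: HardwiredNeuron) -> TuningSpec:
        return replace(self.eye_template, preferred=neuron.beta)


def _grid_points(rng: Sequence[float], step: float) -> np.ndarray:
    lo, hi = float(rng[0]), float(rng[1])
    n = (hi - lo) / step
    n_int = int(round(n))
    if abs(n - n_int) > 1e-9:
        raise ValueError(f"step {step} does not divide range {rng}")
    return lo + step * np.arange(n_int + 1)


def build_population(
    retinal_range=DEFAULT_RETINAL_RANGE,
    eye_range=DEFAULT_EYE_RANGE,
    step: float = 1.0,
    *,
    sigma: float = DEFAULT_SIGMA,
    rho: float = DEFAULT_RHO,
    h_max_r: float = DEFAULT_PEAK,
    h_max_e: float = DEFAULT_PEAK,
    sigmoid: SigmoidSpec = DEFAULT_SIGMOID,
) -> PopulationGrid:
    """Build the complete lattice of hardwired visual neurons.

    Every integer-step (alpha, beta) combination inside the two ranges occurs
    exactly once; the neuron count is the product of the two grid sizes.

    Parameters
    ----------
    retinal_range, eye_range : (lo, hi) in degrees
    step : grid step in degrees; must divide both range widths.
    sigma, rho : retinal / eye-position Gaussian tuning widths (deg).
    h_max_r, h_max_e : peak activation of each component.
    sigmoid : shared rate transfer.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    alphas = _grid_points(retinal_range, step)
    betas = _grid_points(eye_range, step)
    neurons = [
        HardwiredNeuron(alpha=float(a), beta=float(b)) for b in betas for a in alphas
    ]
    return PopulationGrid(
        neurons=neurons,
        retinal_range=(float(retinal_range[0]), float(retinal_range[1])),
        eye_range=(float(eye_range[0]), float(eye_range[1])),
        step=float(step),
        retinal_template=TuningSpec(preferred=0.0, width=sigma, peak=h_max_r),
        eye_template=TuningSpec(preferred=0.0, width=rho, peak=h_max_e),
        sigmoid=sigmoid,
    )


def neuron_rate(neuron: HardwiredNeuron, x, y, grid: PopulationGrid):
    """Instantaneous firing rate for stimulus at retinal ``x`` and eye at ``y``.

    Composition of the additive Gaussian activation and the sigmoid transfer;
    accepts scalars or broadcastable arrays.
    """
    h = combined_activation(x, y, grid.retinal_spec(neuron), grid.eye_spec(neuron))
    return sigmoid_rate(h, grid.sigmoid)


def eye_sweep(
    neuron: HardwiredNeuron,
    grid: PopulationGrid,
    eye_grid=None,
    stimulus_at: float | None = None,
) -> ResponseCurve:
    """Rate across eye positions with the retinal stimulus held fixed.

    By default the stimulus sits at the neuron's preferred retinal location
    and the sweep covers the grid's eye-position points.
    """
    eye_grid = grid.eye_points if eye_grid is None else np.asarray(eye_grid, float)
    if eye_grid.size == 0:
        raise ValueError("eye_grid must be non-empty")
    x = neuron.alpha if stimulus_at is None else float(stimulus_at)
    rates = neuron_rate(neuron, x, eye_grid, grid)
    return ResponseCurve(
        abscissa=eye_grid,
        rates=np.atleast_1d(rates),
        context={"swept": "eye", "stimulus_at": x,
                 "alpha": neuron.alpha, "beta": neuron.beta},
    )


def retinal_sweep_family(
    neuron: HardwiredNeuron,
    grid: PopulationGrid,
    fixations,
    retinal_grid=None,
    reference_fixation: float = 0.0,
) -> FixationFamily:
    """One retinal-sweep curve per fixation.

    ``fixations`` must include the straight-ahead reference (0 deg by
    default), against which multiplicativity is later assessed.
    """
    fixations = [float(f) for f in fixations]
    if not fixations:
        raise ValueError("fixations must be non-empty")
    if not any(np.isclose(f, reference_fixation) for f in fixations):
        raise ValueError(
            f"reference fixation {reference_fixation} deg must be included"
        )
    retinal_grid = (
        grid.retinal_points if retinal_grid is None else np.asarray(retinal_grid, float)
    )
    curves = [
        ResponseCurve(
            abscissa=retinal_grid,
            rates=np.atleast_1d(neuron_rate(neuron, retinal_grid, f, grid)),
            context={"swept": "retinal", "fixation": f,
                     "alpha": neuron.alpha, "beta": neuron.beta},
        )
        for f in fixations
    ]
    return FixationFamily(
        fixations=fixations, curves=curves, reference_fixation=reference_fixation
    )


def population_to_frame(grid: PopulationGrid, retinal_xs=None, eye_ys=None) -> pd.DataFrame:
    """Tidy table of rates: columns alpha, beta, retinal_x, eye_y, rate."""
    xs = grid.retinal_points if retinal_xs is None else np.asarray(retinal_xs, float)
    ys = grid.eye_points if eye_ys is None else np.asarray(eye_ys, float)
    rows = []
    xg, yg = np.meshgrid(xs, ys, indexing="ij")
    for n in grid.neurons:
        r = neuron_rate(n, xg, yg, grid)
        rows.append(
            pd.DataFrame(
                {
                    "alpha": n.alpha,
                    "beta": n.beta,
                    "retinal_x": xg.ravel(),
                    "eye_y": yg.ravel(),
                    "rate": np.asarray(r).ravel(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
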
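"""Self-organizing two-layer gain-field network.

An input layer of 92 Gaussian-tuned units (71 eye-position units at 1-degree
preferred spacing on [-35, 35], 21 retinal units on [-10, 10]) feeds a layer
of 100 leaky-integrator output neurons through a sparse, non-negative weight
matrix.  Output rates are produced by a sigmoid whose argument is shifted by
the population activation percentile p_pi, implementing soft winner-take-all
competition (lateral inhibition).  Weights grow by a Hebbian rule on the
product of pre- and postsynaptic rates and each output's weight vector is
renormalized to unit Euclidean norm after every update, which bounds growth
and preserves Dale's law (all weights stay non-negative).

Time constants and step sizes are in seconds; the Forward-Euler step
defaults to one-tenth of the membrane time constant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tuning import SigmoidSpec, TuningSpec, sigmoid_rate

__all__ = [
    "InputLayer",
    "Network",
    "SELFORG_SIGMOID",
    "default_input_layer",
    "input_rates",
    "init_network",
    "nearest_rank_percentile",
    "step_dynamics",
    "competitive_rates",
    "hebbian_update",
    "response_surfaces",
    "save_network",
    "load_network",
]

SELFORG_SIGMOID = SigmoidSpec(slope=4.5, threshold=0.0)

DEFAULT_EYE_RANGE = (-35.0, 35.0)
DEFAULT_RETINAL_RANGE = (-10.0, 10.0)
DEFAULT_H_MAX = 2.0
DEFAULT_RHO = 15.0
DEFAULT_SIGMA = 6.0
DEFAULT_TAU = 0.1  # membrane time constant (s); 100 ms
DEFAULT_LEARNING_RATE = 0.05  # Hebbian rate (per second)
DEFAULT_SPARSENESS_PERCENTILE = 90.0
DEFAULT_CONNECTIVITY = 10.0  # percent of inputs each output receives
DEFAULT_N_OUTPUTS = 100


@dataclass
class InputLayer:
    """Gaussian-tuned input units of the two modalities.

    Eye-position units come first in the rate vector, retinal units second.
    Preferred values are stored as arrays for speed; ``eye_units`` /
    ``retinal_units`` expose them as TuningSpecs.
    """

    eye_preferred: np.ndarray
    retinal_preferred: np.ndarray
    eye_width: float = DEFAULT_RHO
    retinal_width: float = DEFAULT_SIGMA
    eye_peak: float = DEFAULT_H_MAX
    retinal_peak: float = DEFAULT_H_MAX
    sigmoid: SigmoidSpec = SELFORG_SIGMOID

    def __post_init__(self) -> None:
        self.eye_preferred = np.asarray(self.eye_preferred, dtype=float)
        self.retinal_preferred = np.asarray(self.retinal_preferred, dtype=float)
        if self.eye_width <= 0 or self.retinal_width <= 0:
            raise ValueError("tuning widths must be positive")

    @property
    def n_units(self) -> int:
        return len(self.eye_preferred) + len(self.retinal_preferred)

    @property
    def eye_units(self) -> list:
        return [TuningSpec(p, self.eye_width, self.eye_peak)
                for p in self.eye_preferred]

    @property
    def retinal_units(self) -> list:
        return [TuningSpec(p, self.retinal_width, self.retinal_peak)
                for p in self.retinal_preferred]


def default_input_layer(rho: float = DEFAULT_RHO, sigma: float = DEFAULT_SIGMA,
                        h_max: float = DEFAULT_H_MAX,
                        sigmoid: SigmoidSpec = SELFORG_SIGMOID) -> InputLayer:
    """The standard 71 + 21 = 92 unit input layer at 1-degree spacing."""
    return InputLayer(
        eye_preferred=np.arange(DEFAULT_EYE_RANGE[0], DEFAULT_EYE_RANGE[1] + 1),
        retinal_preferred=np.arange(
            DEFAULT_RETINAL_RANGE[0], DEFAULT_RETINAL_RANGE[1] + 1
        ),
        eye_width=rho,
        retinal_width=sigma,
        eye_peak=h_max,
        retinal_peak=h_max,
        sigmoid=sigmoid,
    )


def input_rates(layer: InputLayer, x: float, y: float) -> np.ndarray:
    """Instantaneous input rates for stimulus at retinal ``x``, eye at ``y``.

    Each unit's Gaussian activation (eye units evaluated at ``y``, retinal
    units at ``x``) is passed through the shared sigmoid.  Rates are
    instantaneous functions of the current condition: the input layer has
    no internal dynamics.
    """
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("x and y must be finite")
    he = layer.eye_peak * np.exp(
        -((y - layer.eye_preferred) ** 2) / (2.0 * layer.eye_width**2)
    )
    hr = layer.retinal_peak * np.exp(
        -((x - layer.retinal_preferred) ** 2) / (2.0 * layer.retinal_width**2)
    )
    return np.asarray(
        sigmoid_rate(np.concatenate([he, hr]), layer.sigmoid), dtype=float
    )


@dataclass
class Network:
    """Output layer state and its learning parameters.

    ``weights`` is (n_outputs, n_inputs), non-negative, zero off the
    connectivity ``mask``, with unit-norm rows; ``h_state`` holds the
    leaky-integrator activations.
    """

    weights: np.ndarray
    mask: np.ndarray
    h_state: np.ndarray
    tau: float = DEFAULT_TAU
    dt: float | None = None  # defaults to tau / 10
    learning_rate: float = DEFAULT_LEARNING_RATE
    sparseness_percentile: float = DEFAULT_SPARSENESS_PERCENTILE
    connectivity_fraction: float = DEFAULT_CONNECTIVITY
    output_sigmoid: SigmoidSpec = SELFORG_SIGMOID
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt is None:
            self.dt = self.tau / 10.0
        self.weights = np.asarray(self.weights, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.h_state = np.asarray(self.h_state, dtype=float)

    @property
    def n_outputs(self) -> int:
        return self.weights.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.weights.shape[1]


def init_network(
    seed,
    layer: InputLayer,
    n_outputs: int = DEFAULT_N_OUTPUTS,
    *,
    connectivity_fraction: float = DEFAULT_CONNECTIVITY,
    tau: float = DEFAULT_TAU,
    dt: float | None = None,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    sparseness_percentile: float = DEFAULT_SPARSENESS_PERCENTILE,
    output_sigmoid: SigmoidSpec = SELFORG_SIGMOID,
) -> Network:
    """Create a network with random sparse connectivity and random weights.

    Each output receives a unique random subset of
    ``floor(connectivity_fraction/100 * n_inputs)`` afferents drawn without
    replacement.  Masked weights start uniform on [0, 1] and each row is
    renormalized to unit norm immediately, so the unit-norm invariant holds
    from t = 0.  Fully reproducible: ``seed`` (an int or a
    ``numpy.random.SeedSequence``) expands into separate connectivity and
    weight streams.
    """
    if not (0 < connectivity_fraction <= 100):
        raise ValueError("connectivity_fraction must be in (0, 100]")
    n_in = layer.n_units
    k = int(np.floor(connectivity_fraction / 100.0 * n_in))
    if k < 1:
        raise ValueError(
            f"connectivity {connectivity_fraction}% of {n_in} inputs "
            "yields zero afferents per output"
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    conn_rng, weight_rng, _ = (np.random.default_rng(c) for c in ss.spawn(3))
    mask = np.zeros((n_outputs, n_in), dtype=bool)
    for i in range(n_outputs):
        mask[i, conn_rng.choice(n_in, size=k, replace=False)] = True
    weights = weight_rng.uniform(0.0, 1.0, size=(n_outputs, n_in)) * mask
    weights /= np.linalg.norm(weights, axis=1, keepdims=True)
    return Network(
        weights=weights,
        mask=mask,
        h_state=np.zeros(n_outputs),
        tau=tau,
        dt=dt,
        learning_rate=learning_rate,
        sparseness_percentile=sparseness_percentile,
        connectivity_fraction=connectivity_fraction,
        output_sigmoid=output_sigmoid,
        seed=None if isinstance(seed, np.random.SeedSequence) else int(seed),
    )


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * N)-th smallest value.

    With p = 90 and N = 100 this is the 90th smallest activation, so ten
    values sit strictly above it when all values are distinct.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n == 0:
        raise ValueError("percentile of empty array")
    rank = max(1, int(np.ceil(percentile / 100.0 * n)))
    rank = min(rank, n)
    return float(np.partition(v, rank - 1)[rank - 1])


def step_dynamics(net: Network, v_in: np.ndarray) -> np.ndarray:
    """One Forward-Euler step of the leaky-integrator activations.

    ``h <- h + (dt/tau) * (-h + W v_in)`` applied to all outputs
    simultaneously.  Returns (and stores) the updated state.
    """
    drive = net.weights @ np.asarray(v_in, dtype=float)
    net.h_state = net.h_state + (net.dt / net.tau) * (-net.h_state + drive)
    if not np.all(np.isfinite(net.h_state)):
        raise FloatingPointError("non-finite activation state in step_dynamics")
    return net.h_state


def competitive_rates(net: Network) -> np.ndarray:
    """Output rates under percentile competition.

    ``v_i = sigmoid(h_i - p_pi - theta)`` where p_pi is the nearest-rank
    ``sparseness_percentile`` of the current activations, recomputed at
    every step.  Neurons whose activation equals p_pi fire at exactly 0.5
    when theta = 0.
    """
    p = nearest_rank_percentile(net.h_state, net.sparseness_percentile)
    return np.asarray(
        sigmoid_rate(net.h_state - p, net.output_sigmoid), dtype=float
    )


def hebbian_update(net: Network, v_in: np.ndarray, v_out: np.ndarray) -> np.ndarray:
    """Hebbian weight growth followed by per-row renormalization.

    ``dw_ij = dt * learning_rate * v_i * v_j`` on masked synapses only, then
    each output row is rescaled to unit Euclidean norm.  Non-negative rates
    keep all weights non-negative (Dale-consistent).
    """
    v_in = np.asarray(v_in, dtype=float)
    v_out = np.asarray(v_out, dtype=float)
    scale = net.dt * net.learning_rate
    if scale == 0.0:
        # nothing to add; skip the renormalization so the stored unit-norm
        # rows are returned bit-for-bit unchanged
        return net.weights
    dw = scale * np.outer(v_out, v_in)
    net.weights = net.weights + dw * net.mask
    norms = np.linalg.norm(net.weights, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise FloatingPointError("zero-norm weight row after Hebbian update")
    net.weights = net.weights / norms
    return net.weights


def response_surfaces(net: Network, layer: InputLayer, xs, ys) -> np.ndarray:
    """Steady-state competitive responses over a stimulus-condition grid.

    For each condition (x, y) the integrator fixed point is
    ``h* = W v_in(x, y)``; competition (p_pi across the population at that
    condition) then yields the rates.  Returns an array of shape
    (n_outputs, len(xs), len(ys)).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    V = np.stack(
        [input_rates(layer, x, y) for x in xs for y in ys], axis=1
    )  # (n_in, n_cond)
    H = net.weights @ V  # (n_out, n_cond)
    n = net.n_outputs
    rank = min(n, max(1, int(np.ceil(net.sparseness_percentile / 100.0 * n))))
    p = np.partition(H, rank - 1, axis=0)[rank - 1]
    R = np.asarray(sigmoid_rate(H - p, net.output_sigmoid), dtype=float)
    return R.reshape(n, len(xs), len(ys))


# --- checkpoint serialization: JSON header + CSV weight table -------------

def save_network(net: Network, prefix) -> tuple:
    """Write ``<prefix>.json`` (config/provenance) + ``<prefix>.weights.csv``.

    The CSV holds one row per existing synapse (output, input, weight); the
    connectivity mask is implied by the rows present.
    """
    prefix = Path(prefix)
    header = {
        "n_outputs": net.n_outputs,
        "n_inputs": net.n_inputs,
        "tau": net.tau,
        "dt": net.dt,
        "learning_rate": net.learning_rate,
        "sparseness_percentile": net.sparseness_percentile,
        "connectivity_fraction": net.connectivity_fraction,
        "output_sigmoid": {
            "slope": net.output_sigmoid.slope,
            "threshold": net.output_sigmoid.threshold,
        },
        "seed": net.seed,
        "h_state": net.h_state.tolist(),
        "config": net.config,
    }
    json_path = prefix.with_suffix(".json")
    csv_path = prefix.parent / (prefix.name + ".weights.csv")
    json_path.parent.mkdir(parents=True, exist_ok=True)
    json_path.write_text(json.dumps(header, indent=1))
    ii, jj = np.nonzero(net.mask)
    pd.DataFrame(
        {"output": ii, "input": jj, "weight": net.weights[ii, jj]}
    ).to_csv(csv_path, index=False)
    return json_path, csv_path


def load_network(prefix) -> Network:
    """Restore a network saved by :func:`save_network`."""
    prefix = Path(prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    table = pd.read_csv(prefix.parent / (prefix.name + ".weights.csv"))
    n_out, n_in = header["n_outputs"], header["n_inputs"]
    weights = np.zeros((n_out, n_in))
    mask = np.zeros((n_out, n_in), dtype=bool)
    weights[table["output"], table["input"]] = table["weight"]
    mask[table["output"], table["input"]] = True
    sig = header["output_sigmoid"]
    return Network(
        weights=weights,
        mask=mask,
        h_state=np.asarray(header["h_state"], dtype=float),
        tau=header["tau"],
        dt=header["dt"],
        learning_rate=header["learning_rate"],
        sparseness_percentile=header["sparseness_percentile"],
        connectivity_fraction=header["connectivity_fraction"],
        output_sigmoid=SigmoidSpec(sig["slope"], sig["threshold"]),
        seed=header["seed"],
        config=header.get("config", {}),
    )
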
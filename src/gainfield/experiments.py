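"""Experiment orchestration: the runnable analyses behind each figure-style
result, as library functions plus a disk-writing dispatcher.

Each experiment function takes a resolved :class:`ExperimentConfig` and
returns in-memory results (DataFrames / dicts); :func:`run_experiment`
executes one by name and writes CSV/JSON bundles (plus optional PNG plots)
with the config hash and seed embedded for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, hardwired, selforg, training
from .config import ExperimentConfig, config_hash
from .tuning import SigmoidSpec

__all__ = [
    "FIG2_NEURONS",
    "FIG4_NEURONS",
    "FIG4_FIXATIONS",
    "FIG9_FIXATIONS",
    "train_network",
    "trained_output_summary",
    "fig2_curves",
    "fig3_rho_sweep",
    "fig4_multiplicativity",
    "selforg_train",
    "fig7_rho_sweep",
    "fig9_multiplicativity",
    "run_experiment",
]

#: (alpha, beta) identities of the hardwired eye-sweep examples.
FIG2_NEURONS = ((-10.0, -34.0), (-5.0, -18.0), (0.0, 0.0), (5.0, 18.0), (10.0, 34.0))
#: Hardwired multiplicativity examples (rho = 15 deg).
FIG4_NEURONS = ((-10.0, -34.0), (-10.0, -25.0), (10.0, 34.0))
FIG4_FIXATIONS = (-35.0, -12.0, 0.0, 12.0, 35.0)
#: Fixation set for trained-network multiplicativity (rho = 17 deg).
FIG9_FIXATIONS = (-20.0, -12.0, 0.0, 12.0, 20.0)


def _grid(config: ExperimentConfig, rho: float | None = None) -> hardwired.PopulationGrid:
    return hardwired.build_population(
        sigma=config.sigma,
        rho=config.rho if rho is None else rho,
        h_max_r=config.h_max,
        h_max_e=config.h_max,
        sigmoid=SigmoidSpec(config.phi_slope, config.theta),
    )


# --------------------------------------------------------------- hardwired

def fig2_curves(config: ExperimentConfig) -> dict:
    """Eye sweeps and linearity for the five example hardwired neurons."""
    grid = _grid(config)
    curve_rows, r2_rows = [], []
    for alpha, beta in FIG2_NEURONS:
        n = hardwired.HardwiredNeuron(alpha, beta)
        curve = hardwired.eye_sweep(n, grid)
        res = analysis.linearity_r2(curve)
        curve_rows.append(pd.DataFrame({
            "alpha": alpha, "beta": beta,
            "eye_y": curve.abscissa, "rate": curve.rates,
        }))
        r2_rows.append((alpha, beta, res.r_squared, res.slope, res.intercept))
    return {
        "curves": pd.concat(curve_rows, ignore_index=True),
        "r2": pd.DataFrame(r2_rows,
                           columns=["alpha", "beta", "r_squared",
                                    "slope", "intercept"]),
    }


def fig3_rho_sweep(config: ExperimentConfig) -> dict:
    """Population R^2 histograms across eye-tuning widths."""
    grid = _grid(config)
    hist_rows, summary = [], []
    per_neuron = []
    for rho in config.rho_values:
        df = analysis.population_linearity(grid, rho=rho)
        hist = analysis.r2_histogram(df["r_squared"])
        for lo, hi, p in zip(hist.bin_edges[:-1], hist.bin_edges[1:],
                             hist.proportions):
            hist_rows.append((rho, lo, hi, p))
        summary.append((
            rho,
            float((df["r_squared"] <= 0.2).mean() * 100),
            float((df["r_squared"] < 0.5).mean() * 100),
            float((df["r_squared"] > 0.8).mean() * 100),
            float(df["r_squared"].median()),
        ))
        df = df.assign(rho=rho)
        per_neuron.append(df)
    return {
        "histograms": pd.DataFrame(
            hist_rows, columns=["rho", "bin_lo", "bin_hi", "percent"]
        ),
        "summary": pd.DataFrame(
            summary,
            columns=["rho", "pct_le_0.2", "pct_lt_0.5", "pct_gt_0.8",
                     "median_r2"],
        ),
        "per_neuron": pd.concat(per_neuron, ignore_index=True),
    }


def fig4_multiplicativity(config: ExperimentConfig) -> dict:
    """Scalar-multiple test of fixation families for the example neurons."""
    rho = config.rho if config.rho is not None else 15.0  # resolved() sets it
    grid = _grid(config, rho=rho)
    curve_rows, results = [], []
    for alpha, beta in FIG4_NEURONS:
        n = hardwired.HardwiredNeuron(alpha, beta)
        fam = hardwired.retinal_sweep_family(n, grid, FIG4_FIXATIONS)
        res = analysis.multiplicativity_test(
            fam, tolerance=config.multiplicativity_tolerance
        )
        for f, c in zip(fam.fixations, fam.curves):
            curve_rows.append(pd.DataFrame({
                "alpha": alpha, "beta": beta, "fixation": f,
                "retinal_x": c.abscissa, "rate": c.rates,
            }))
        results.append({
            "alpha": alpha, "beta": beta, "rho": rho,
            "scale_constants": res.scale_constants,
            "max_relative_residual": res.max_relative_residual,
            "passes": res.passes, "tolerance": res.tolerance,
        })
    return {
        "curves": pd.concat(curve_rows, ignore_index=True),
        "multiplicativity": results,
    }


# ------------------------------------------------------------ self-organizing

def train_network(
    seed: int,
    rho: float = selforg.DEFAULT_RHO,
    *,
    config: ExperimentConfig | None = None,
) -> tuple:
    """Initialize and train one network; returns (net, layer, log).

    ``seed`` is the global seed: it expands into independent connectivity,
    weight and fixation-target streams.
    """
    cfg = (config or ExperimentConfig(experiment="selforg_train")).resolved()
    layer = selforg.default_input_layer(
        rho=rho, sigma=cfg.sigma, h_max=cfg.h_max,
        sigmoid=SigmoidSpec(cfg.phi_slope, cfg.theta),
    )
    net = selforg.init_network(
        seed, layer, cfg.n_outputs,
        connectivity_fraction=cfg.connectivity,
        tau=cfg.tau, dt=cfg.dt,
        learning_rate=cfg.learning_rate,
        sparseness_percentile=cfg.sparseness_percentile,
        output_sigmoid=SigmoidSpec(cfg.phi_slope, cfg.theta),
    )
    net.config = {"rho": rho, "config_hash": config_hash(cfg)}
    schedule = training.make_schedule(seed, training.TrainingConfig(
        epochs=cfg.epochs,
        fixations_per_period=cfg.fixations_per_period,
        fixation_duration=cfg.fixation_duration,
        saccade_speed=cfg.saccade_speed,
        schedule_mode=cfg.schedule_mode,
    ))
    _, log = training.run_training(
        net, layer, schedule, learn_during_saccades=cfg.learn_during_saccades
    )
    return net, layer, log


def trained_output_summary(
    net: selforg.Network,
    layer: selforg.InputLayer,
    *,
    activity_min: float = analysis.ACTIVITY_MIN,
    range_min: float = analysis.RANGE_MIN,
) -> pd.DataFrame:
    """Eye-sweep linearity and profile class for every trained output.

    Responses are the steady-state competitive rates over the full
    (retinal x eye) condition grid; each output is characterized at its
    best retinal location (the retinal index of its surface maximum).
    """
    xs = layer.retinal_preferred
    ys = layer.eye_preferred
    R = selforg.response_surfaces(net, layer, xs, ys)
    rows = []
    for i in range(net.n_outputs):
        ix = int(np.unravel_index(np.argmax(R[i]), R[i].shape)[0])
        curve = hardwired.ResponseCurve(
            abscissa=ys, rates=np.clip(R[i, ix, :], 0.0, 1.0),
            context={"output": i, "retinal_x": float(xs[ix])},
        )
        res = analysis.linearity_r2(
            curve, activity_min=activity_min, range_min=range_min
        )
        label = analysis.classify_profile(
            curve, activity_min=activity_min, range_min=range_min
        )
        rows.append((i, float(xs[ix]), res.r_squared, res.active, label))
    return pd.DataFrame(
        rows, columns=["output", "best_retinal_x", "r_squared", "active",
                       "profile"]
    )


def selforg_train(config: ExperimentConfig) -> dict:
    """Train one network at the default width and summarize its outputs."""
    net, layer, log = train_network(config.seed, rho=config.rho, config=config)
    return {
        "net": net,
        "layer": layer,
        "log": log.frame,
        "summary": trained_output_summary(
            net, layer, activity_min=config.activity_min,
            range_min=config.range_min,
        ),
    }


def fig7_rho_sweep(config: ExperimentConfig) -> dict:
    """Train at each eye-tuning width and tabulate output profile classes."""
    rows = []
    for rho in config.rho_values:
        for seed in config.seeds:
            net, layer, _ = train_network(seed, rho=rho, config=config)
            summ = trained_output_summary(
                net, layer, activity_min=config.activity_min,
                range_min=config.range_min,
            ).assign(rho=rho, seed=seed)
            rows.append(summ)
    per_output = pd.concat(rows, ignore_index=True)
    class_table = (
        per_output.groupby(["rho", "seed", "profile"])
        .size()
        .rename("count")
        .reset_index()
    )
    return {"per_output": per_output, "classes": class_table}


def fig9_multiplicativity(config: ExperimentConfig) -> dict:
    """Multiplicativity of trained monotonic outputs (rho = 17 deg setup)."""
    rho = config.rho if config.rho is not None else 17.0
    rows = []
    for seed in config.seeds:
        net, layer, _ = train_network(seed, rho=rho, config=config)
        xs, ys = layer.retinal_preferred, layer.eye_preferred
        R = selforg.response_surfaces(net, layer, xs, ys)
        summ = trained_output_summary(
            net, layer, activity_min=config.activity_min,
            range_min=config.range_min,
        )
        iy = {f: int(np.where(ys == f)[0][0]) for f in FIG9_FIXATIONS}
        for _, row in summ[summ["profile"] == "monotonic"].iterrows():
            i = int(row["output"])
            curves = [
                hardwired.ResponseCurve(
                    abscissa=xs, rates=np.clip(R[i, :, iy[f]], 0.0, 1.0),
                    context={"fixation": f},
                )
                for f in FIG9_FIXATIONS
            ]
            fam = hardwired.FixationFamily(
                fixations=list(FIG9_FIXATIONS), curves=curves
            )
            if np.linalg.norm(fam.reference_curve.rates) < 1e-9:
                continue
            res = analysis.multiplicativity_test(
                fam, tolerance=config.multiplicativity_tolerance
            )
            rows.append((seed, i, row["r_squared"],
                         res.max_relative_residual, res.passes))
    return {
        "results": pd.DataFrame(
            rows, columns=["seed", "output", "r_squared",
                           "max_relative_residual", "passes"]
        ),
        "rho": rho,
    }


# ---------------------------------------------------------------- dispatch

def _write_csv(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(provenance + "\n")
        df.to_csv(fh, index=False)


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute the named experiment and write its result bundle.

    Writes the frozen resolved config, CSV tables, a JSON summary and
    (optionally) PNG plots under ``config.outdir``.  Identical config and
    seed reproduce byte-identical CSVs.
    """
    cfg = config.resolved()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    prov = f"# experiment={cfg.experiment} config={chash} seed={cfg.seed}"
    cfg.to_yaml(outdir / "config.resolved.yaml")

    fn = {
        "fig2_curves": fig2_curves,
        "fig3_rho_sweep": fig3_rho_sweep,
        "fig4_multiplicativity": fig4_multiplicativity,
        "selforg_train": selforg_train,
        "fig7_rho_sweep": fig7_rho_sweep,
        "fig9_multiplicativity": fig9_multiplicativity,
    }[cfg.experiment]
    results = fn(cfg)

    summary: dict = {"experiment": cfg.experiment, "config_hash": chash,
                     "seed": cfg.seed}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            _write_csv(obj, outdir / f"{name}.csv", prov)
        elif isinstance(obj, selforg.Network):
            selforg.save_network(obj, outdir / "checkpoint")
        elif isinstance(obj, selforg.InputLayer):
            continue
        else:
            summary[name] = obj
    (outdir / "summary.json").write_text(
        json.dumps(_to_jsonable(summary), indent=1)
    )
    if cfg.plot:
        _plot(cfg, results, outdir)
    return outdir


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _plot(cfg: ExperimentConfig, results: dict, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "curves" in results:
        df = results["curves"]
        xcol = "eye_y" if "eye_y" in df.columns else "retinal_x"
        group_cols = [c for c in ("alpha", "beta") if c in df.columns]
        fig, ax = plt.subplots(figsize=(6, 4))
        hue = "fixation" if "fixation" in df.columns else None
        for key, grp in df.groupby(group_cols + ([hue] if hue else [])):
            ax.plot(grp[xcol], grp["rate"], label=str(key))
        ax.set_xlabel(f"{xcol} (deg)")
        ax.set_ylabel("firing rate")
        ax.legend(fontsize=6)
        fig.savefig(outdir / "curves.png", dpi=120)
        plt.close(fig)
    if "histograms" in results:
        df = results["histograms"]
        rhos = sorted(df["rho"].unique())
        fig, axes = plt.subplots(1, len(rhos), figsize=(3 * len(rhos), 3),
                                 squeeze=False)
        for ax, rho in zip(axes[0], rhos):
            sub = df[df["rho"] == rho]
            ax.bar(sub["bin_lo"], sub["percent"], width=0.18, align="edge")
            ax.set_title(f"rho={rho}")
            ax.set_xlabel("R^2")
        axes[0][0].set_ylabel("% of neurons")
        fig.tight_layout()
        fig.savefig(outdir / "histograms.png", dpi=120)
        plt.close(fig)
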
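"""Experiment grids and the simulate-fit pipeline.

Three experiments probe how the remote tilt aftereffect depends on the
adapting texture's orientation structure:

* **exp1** — noisy concentric adaptors: signal/noise layout
  (intermixed, proximal-noise annulus, distal-noise annulus) crossed
  with structure coherence.
* **exp2** — linear orientation gradients anchored at the test site
  (implied orientation 15 deg CCW): gradient rate x gradient axis x
  reflectional symmetry, all with a 90%-coherence proximal noise
  annulus of outer radius 9.53 deg.
* **exp3** — a rate-5 horizontal gradient quantized into
  constant-orientation bands of varying width.

Each grid carries exactly one no-adaptation baseline.  For every
condition the pipeline computes the observer's adaptation state,
simulates constant-stimuli blocks, fits the psychometric function,
bootstraps the PSE standard error, and reports the TAE relative to the
baseline fit.  Everything is deterministic given the grid's master seed
and the observer parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    LayoutGeometry,
    OrientationField,
    apply_symmetry,
    coherence_for_radius,
    quantize_field,
    solve_noise_radius,
    test_location,
)
from .observer import (
    DEFAULT_LEVELS,
    ObserverParams,
    predicted_tae,
    simulate_block,
)
from .psychofit import (
    FittingError,
    bootstrap_se,
    compute_tae,
    fit_psychometric,
)
from .synth import TextureSpec, render_texture, sample_elements

__all__ = [
    "Condition",
    "ConditionGrid",
    "build_grid",
    "run_pipeline",
    "summarize",
]

EXPERIMENT_IDS = ("exp1", "exp2", "exp3", "baseline")

DEFAULT_COHERENCES = (0.25, 0.5, 0.75, 1.0)
DEFAULT_RATES = (0.0, 1.25, 2.5, 5.0, 7.5, 10.0)
DEFAULT_BAND_WIDTHS = (0.2, 2.0, 4.0, 8.0, 12.0, 24.0, 36.0)
EXP2_ANNULUS_RADIUS = 9.53


@dataclass(frozen=True)
class Condition:
    """One adaptation condition: a field, a layout and observer overrides."""

    condition_id: str
    field: OrientationField | None        # None for the baseline
    layout: LayoutGeometry
    observer_overrides: dict = dc_field(default_factory=dict)

    @property
    def is_baseline(self) -> bool:
        return self.field is None


@dataclass(frozen=True)
class ConditionGrid:
    """A full experiment: conditions, blocks per condition, master seed."""

    experiment_id: str
    conditions: tuple[Condition, ...]
    blocks: int = 4
    master_seed: int = 0
    levels: tuple[float, ...] = DEFAULT_LEVELS
    reps: int = 10

    def __post_init__(self):
        ids = [c.condition_id for c in self.conditions]
        if len(set(ids)) != len(ids):
            raise ValueError("condition ids must be unique")
        n_base = sum(c.is_baseline for c in self.conditions)
        if n_base != 1:
            raise ValueError("grid must contain exactly one baseline condition")


def _baseline_condition() -> Condition:
    return Condition("baseline", None, LayoutGeometry(coherence=0.0))


def _proximal_layout(coherence: float) -> LayoutGeometry:
    lay = LayoutGeometry(noise_layout="proximal", coherence=coherence)
    radius = solve_noise_radius(lay, coherence)
    return replace(lay, annulus_outer_radius=radius)


def _distal_layout(coherence: float) -> LayoutGeometry:
    lay = LayoutGeometry(noise_layout="distal", coherence=coherence)
    radius = solve_noise_radius(lay, coherence)
    return replace(lay, annulus_outer_radius=radius)


def _exp2_layout() -> LayoutGeometry:
    lay = LayoutGeometry(
        noise_layout="proximal", annulus_outer_radius=EXP2_ANNULUS_RADIUS
    )
    coh = coherence_for_radius(lay, EXP2_ANNULUS_RADIUS)
    return replace(lay, coherence=coh)


def build_grid(experiment_id: str, config: dict | None = None) -> ConditionGrid:
    """Build the default condition grid for one experiment.

    `config` may override ``coherences``, ``rates``, ``axes``,
    ``symmetries``, ``band_widths``, ``blocks``, ``seed``, ``levels`` and
    ``reps``.  Every grid includes exactly one no-adaptation baseline.
    """
    cfg = dict(config or {})
    blocks = int(cfg.get("blocks", 4))
    seed = int(cfg.get("seed", 0))
    levels = tuple(cfg.get("levels", DEFAULT_LEVELS))
    reps = int(cfg.get("reps", 10))
    conditions: list[Condition] = [_baseline_condition()]

    if experiment_id == "baseline":
        pass
    elif experiment_id == "exp1":
        concentric = OrientationField("concentric")
        for layout_name in cfg.get("layouts", ("intermixed", "proximal", "distal")):
            for coh in cfg.get("coherences", DEFAULT_COHERENCES):
                if layout_name == "intermixed":
                    lay = LayoutGeometry(noise_layout="intermixed", coherence=coh)
                elif layout_name == "proximal":
                    lay = _proximal_layout(coh)
                else:
                    lay = _distal_layout(coh)
                conditions.append(
                    Condition(
                        f"exp1-{layout_name}-c{int(round(coh * 100)):03d}",
                        concentric,
                        lay,
                    )
                )
    elif experiment_id == "exp2":
        lay = _exp2_layout()
        for rate in cfg.get("rates", DEFAULT_RATES):
            for axis in cfg.get("axes", ("horizontal", "vertical")):
                for sym in cfg.get("symmetries", (False, True)):
                    field = OrientationField(
                        "linear_gradient",
                        gradient_rate=rate,
                        axis=axis,
                        anchor_point=test_location(),
                        anchor_orientation=15.0,
                    )
                    if sym:
                        field = apply_symmetry(field, axis)
                    cid = f"exp2-{axis[0]}-r{rate:g}-{'sym' if sym else 'asym'}"
                    conditions.append(Condition(cid, field, lay))
    elif experiment_id == "exp3":
        lay = _exp2_layout()
        base = OrientationField(
            "linear_gradient",
            gradient_rate=float(cfg.get("rate", 5.0)),
            axis="horizontal",
            anchor_point=test_location(),
            anchor_orientation=15.0,
        )
        for width in cfg.get("band_widths", DEFAULT_BAND_WIDTHS):
            conditions.append(
                Condition(f"exp3-w{width:g}", quantize_field(base, width), lay)
            )
    else:
        raise ValueError(f"unknown experiment id {experiment_id!r}")

    return ConditionGrid(
        experiment_id=experiment_id,
        conditions=tuple(conditions),
        blocks=blocks,
        master_seed=seed,
        levels=levels,
        reps=reps,
    )


def _condition_row(cond: Condition) -> dict:
    f = cond.field
    return {
        "condition_id": cond.condition_id,
        "layout": cond.layout.noise_layout,
        "coherence": cond.layout.coherence,
        "annulus_outer_radius": cond.layout.annulus_outer_radius,
        "field_kind": None if f is None else f.kind,
        "gradient_rate": None if f is None else f.gradient_rate,
        "band_width": None if f is None else f.band_width,
        "axis": None if f is None else f.axis,
        "symmetry": None if f is None else f.symmetry,
    }


def _simulate_condition(cond, params, true_pse, grid, rng):
    blocks = [
        simulate_block(
            params,
            true_pse,
            rng,
            levels=grid.levels,
            reps=grid.reps,
            condition_id=cond.condition_id,
            block=b,
        )
        for b in range(grid.blocks)
    ]
    return pd.concat(blocks, ignore_index=True)


def run_pipeline(
    grid: ConditionGrid,
    observer: ObserverParams | None = None,
    out_dir=None,
    n_boot: int = 1000,
    render: bool = False,
) -> pd.DataFrame:
    """Run the simulate-fit pipeline over a grid.

    Per condition: predict the adaptation state, simulate `grid.blocks`
    constant-stimuli blocks, fit the psychometric function, bootstrap the
    PSE standard error (skipped when ``n_boot == 0``), and compute the
    TAE against the grid's baseline fit.  Fitting failures are recorded
    as flagged rows, never dropped silently.

    With `out_dir` set, per-condition trial CSVs and the summary table
    are written there; `render` additionally saves one example adaptor
    frame per adaptation condition as PNG for visual QC (the response
    simulation itself consumes field descriptors analytically and never
    renders).
    """
    params = observer or ObserverParams()
    out_path = None if out_dir is None else Path(out_dir)
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    seed_root = np.random.SeedSequence(grid.master_seed)
    cond_seeds = seed_root.spawn(len(grid.conditions))

    # baseline first: its fit anchors every TAE
    base_idx = next(i for i, c in enumerate(grid.conditions) if c.is_baseline)
    order = [base_idx] + [i for i in range(len(grid.conditions)) if i != base_idx]

    rows = []
    base_fit = None
    for i in order:
        cond = grid.conditions[i]
        rng = np.random.default_rng(cond_seeds[i])
        row = _condition_row(cond)
        if cond.is_baseline:
            state = None
            true_pse, implied = 0.0, 0.0
        else:
            state = predicted_tae(cond.field, cond.layout, params)
            implied = state.implied_orientation_at_test
            true_pse = math.copysign(1.0, implied) * state.predicted_tae if implied else state.predicted_tae
        trials = _simulate_condition(cond, params, true_pse, grid, rng)
        if out_path is not None:
            trials.to_csv(out_path / f"trials_{cond.condition_id}.csv", index=False)
        row.update(
            predicted_tae=0.0 if state is None else state.predicted_tae,
            implied_orientation=implied,
            n_trials=len(trials),
        )
        try:
            fit = fit_psychometric(trials)
            se = bootstrap_se(trials, n_boot=n_boot, rng=rng) if n_boot else float("nan")
            row.update(
                pse=fit.pse,
                slope=fit.slope,
                pse_se=se,
                converged=fit.converged,
                flag="",
            )
            if cond.is_baseline:
                base_fit = fit
                row.update(tae=0.0, tae_se=0.0)
            else:
                tae = compute_tae(fit, base_fit, implied) if implied else fit.pse - base_fit.pse
                base_se = next(r["pse_se"] for r in rows if r["condition_id"] == "baseline")
                tae_se = math.hypot(se, base_se) if n_boot else float("nan")
                row.update(tae=tae, tae_se=tae_se)
        except FittingError as err:
            row.update(
                pse=float("nan"),
                slope=float("nan"),
                pse_se=float("nan"),
                converged=False,
                tae=float("nan"),
                tae_se=float("nan"),
                flag=str(err),
            )
        rows.append(row)
        if render and out_path is not None and not cond.is_baseline:
            spec = TextureSpec(
                field=cond.field, layout=cond.layout, seed=int(cond_seeds[i].entropy % 2**31)
            )
            img = render_texture(sample_elements(spec), spec)
            img.save_png(out_path / f"adaptor_{cond.condition_id}.png")

    results = pd.DataFrame(rows)
    # restore grid order
    results = (
        results.set_index("condition_id")
        .loc[[c.condition_id for c in grid.conditions]]
        .reset_index()
    )
    if out_path is not None:
        results.to_csv(out_path / "results.csv", index=False)
    return results


def summarize(results: pd.DataFrame, out_path=None, plot: bool = False) -> dict:
    """Summarise a result table.

    Reports, where the relevant conditions are present: the gradient rate
    maximising the mean TAE (exp2), the sign of the TAE-vs-coherence
    slope (exp1), and the largest quantization band width whose TAE
    exceeds twice its standard error (exp3).  ``TAE > 2 SE`` is the
    summariser's shorthand for a consistent effect.
    """
    if results.empty:
        raise ValueError("empty result table")
    adapt = results[(results["condition_id"] != "baseline") & (results["flag"] == "")]
    report: dict = {"n_conditions": int(len(results)) - 1}

    rates = adapt.dropna(subset=["gradient_rate"])
    rates = rates[rates["field_kind"].isin(["linear_gradient"])]
    if len(rates):
        mean_tae = rates.groupby("gradient_rate")["tae"].mean()
        report["peak_gradient_rate"] = float(mean_tae.idxmax())
        report["peak_gradient_tae"] = float(mean_tae.max())

    coh = adapt[adapt["field_kind"] == "concentric"]
    if len(coh) and coh["coherence"].nunique() > 1:
        slope = np.polyfit(coh["coherence"], coh["tae"], 1)[0]
        report["coherence_slope_sign"] = int(np.sign(slope))
        report["coherence_slope"] = float(slope)

    bands = adapt.dropna(subset=["band_width"])
    if len(bands):
        sig = bands[bands["tae"] > 2.0 * bands["tae_se"]]
        report["largest_significant_band_width"] = (
            float(sig["band_width"].max()) if len(sig) else None
        )

    if not len(rates) and not len(coh) and not len(bands):
        report["note"] = "no estimable adaptation conditions"

    if out_path is not None:
        out_path = Path(out_path)
        out_path.mkdir(parents=True, exist_ok=True)
        (out_path / "report.json").write_text(json.dumps(report, indent=2))
        lines = [f"{k}: {v}" for k, v in report.items()]
        (out_path / "report.txt").write_text("\n".join(lines) + "\n")
        if plot:
            _plot_summary(results, out_path)
    return report


def _plot_summary(results: pd.DataFrame, out_path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    adapt = results[results["condition_id"] != "baseline"]
    for xcol, fname in (
        ("coherence", "tae_vs_coherence.png"),
        ("gradient_rate", "tae_vs_gradient.png"),
        ("band_width", "tae_vs_band_width.png"),
    ):
        sub = adapt.dropna(subset=[xcol, "tae"])
        if xcol == "coherence":
            sub = sub[sub["field_kind"] == "concentric"]
        if xcol == "gradient_rate":
            sub = sub[sub["field_kind"] == "linear_gradient"]
        if len(sub) < 2:
            continue
        fig, ax = plt.subplots(figsize=(4, 3))
        for layout, grp in sub.groupby("layout"):
            g = grp.groupby(xcol)["tae"].mean()
            ax.errorbar(
                g.index,
                g.values,
                yerr=grp.groupby(xcol)["tae_se"].mean().values,
                marker="o",
                label=layout,
            )
        ax.set_xlabel(xcol.replace("_", " "))
        ax.set_ylabel("TAE (deg)")
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out_path / fname, dpi=120)
        plt.close(fig)
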
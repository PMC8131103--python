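"""Named in-silico experiments with persisted, reproducible outputs.

Each experiment is a pure function of its parameter block and seeds; the
``run_experiment`` entry point executes one by name, writes snapshot and
metrics tables (CSV), a JSON metadata record and figure-style plots, and
returns the metrics as a dictionary.  The ``fast`` flag divides step and
snapshot counts by ten for quick runs; SD-based acceptance bands are then
widened by sqrt(10) in ``compare_to_reference``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import cytoneme_metrics as cm
from . import pattern_metrics as pm
from .cytoneme_sim import CytonemeParams, CytonemeSnapshot, simulate as cyto_simulate
from .vertex_sim import (
    CellType,
    VertexParams,
    VertexRun,
    init_aggregate,
    invasion_protocol,
    simulate as vertex_simulate,
)

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "compare_to_reference",
    "EXPERIMENTS",
    "cytoneme_params",
    "vertex_params",
    "run_cytoneme",
    "run_homogeneous",
    "run_mixed",
    "run_gamma_sweep",
    "run_invasion",
    "DEFAULT_GAMMA_GRID",
]

DEFAULT_GAMMA_GRID = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0)


# ---------------------------------------------------------------------------
# canonical study-condition parameter blocks


def cytoneme_params(e_ii: float, seed: int, fast: bool = False) -> CytonemeParams:
    """Paper-scale cytoneme schedule, or a tenth-scale fast variant."""
    if fast:
        return CytonemeParams(
            e_ii=e_ii,
            seed=seed,
            total_steps=600_000,
            burn_in_steps=150_000,
            snapshot_interval=4_000,
            snapshot_count=101,
        )
    return CytonemeParams(e_ii=e_ii, seed=seed)


def vertex_params(seed: int, fast: bool = False, **overrides) -> VertexParams:
    """Full vertex-model schedule, or a reduced fast variant."""
    if fast:
        base = VertexParams(
            seed=seed,
            total_steps=260_000,
            burn_in=120_000,
            snapshot_count=100,
            snapshot_interval=1_400,
        )
    else:
        base = VertexParams(seed=seed)
    return base.replace(**overrides) if overrides else base


# ---------------------------------------------------------------------------
# experiment bodies (also the computational surface used by the acceptance
# harness)


def run_cytoneme(e_ii: float, seed: int, fast: bool = False) -> list[CytonemeSnapshot]:
    params = cytoneme_params(e_ii, seed, fast)
    return cyto_simulate(params)


def run_homogeneous(seed: int, fast: bool = False) -> tuple[VertexRun, pm.NeighborStats]:
    """Two-colour Ihog control: an aggregate of 50 red + 50 green cells.

    The aggregate is pre-formed (see :func:`adhesim.vertex_sim.init_aggregate`);
    the run equilibrates its geometry and (colour-symmetric) arrangement.
    """
    params = vertex_params(seed, fast)
    rng = np.random.default_rng(seed)
    init = init_aggregate(params, {CellType.IHOG_RED: 50, CellType.IHOG_GREEN: 50}, rng)
    run = vertex_simulate(params, init)
    return run, pm.neighbor_stats(run.snapshots)


def run_mixed(
    ratio: float, seed: int, fast: bool = False
) -> tuple[VertexRun, pm.NeighborStats, str]:
    """Mixed 50 Ihog / 50 Hh steady state at the given adhesion ratio.

    Runs both seeded branches and selects the lower-energy phase (see
    :func:`adhesim.pattern_metrics.mixed_steady_state`).
    """
    params = vertex_params(seed, fast).with_ratio(ratio)
    rng = np.random.default_rng(seed)
    return pm.mixed_steady_state(params, rng)


def run_gamma_sweep(
    seed: int, grid: Sequence[float] = DEFAULT_GAMMA_GRID, fast: bool = False
) -> pm.SweepResult:
    """Adhesion-ratio sweep with per-ratio dual-branch mixed simulations.

    Near the phase boundary the losing branch decays slowly, so the full
    schedule runs 2M steps per branch to let both energy traces plateau
    before the comparison; the fast variant keeps the standard schedule.
    """
    if fast:
        params = vertex_params(seed, False)
    else:
        steps = 2_000_000
        params = vertex_params(seed, False).replace(
            total_steps=steps,
            burn_in=steps // 2,
            snapshot_count=300,
            snapshot_interval=(steps - steps // 2) // 300,
        )
    rng = np.random.default_rng(seed)
    return pm.gamma_sweep(grid, params, rng)


def run_invasion(seed: int, ratio: float = 30.0, fast: bool = False):
    """Ihog aggregate first, then 50 invading Hh cells at the given ratio.

    Phase 2 runs longer (2M steps, annealed from kBT 0.3) because the
    inserted cells must intercalate through the aggregate.
    """
    steps = 650_000 if fast else 2_000_000
    params = (
        vertex_params(seed, False)
        .replace(
            total_steps=steps,
            burn_in=steps // 2,
            snapshot_count=300,
            snapshot_interval=(steps - steps // 2) // 300,
            k_bt_start=0.3,
            anneal_steps=steps // 2,
        )
        .with_ratio(ratio)
    )
    rng = np.random.default_rng(seed)
    run1, run2 = invasion_protocol(params, rng)
    stats = pm.neighbor_stats(run2.snapshots[-100:])
    return run1, run2, stats, pm.classify_pattern(stats)


# ---------------------------------------------------------------------------
# named experiments with persistence


@dataclass
class ExperimentConfig:
    """A named, fully seeded experiment with an output directory."""

    name: str
    seed: int = 0
    fast: bool = False
    outdir: Path | str = "results"
    overrides: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(
            {"name": self.name, "seed": self.seed, "fast": self.fast, **self.overrides},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _snapshot_table(snapshots: Sequence[CytonemeSnapshot], e_ii: float) -> pd.DataFrame:
    rows = []
    for s in snapshots:
        for i in range(len(s.lengths)):
            rows.append(
                {
                    "e_ii": e_ii,
                    "step": s.step,
                    "cytoneme_id": i,
                    "position": int(s.positions[i]),
                    "length": int(s.lengths[i]),
                    "contact_count": int(s.contact_counts[i]),
                }
            )
    return pd.DataFrame(rows)


def _exp_cytoneme_baseline(cfg: ExperimentConfig) -> dict:
    report: dict = {"experiment": cfg.name}
    snaps = {}
    for k, e_ii in enumerate((0.0, 15.0)):
        snaps[e_ii] = run_cytoneme(e_ii, cfg.seed + k, cfg.fast)
        render_cytonemes(
            snaps[e_ii][-1], 100, Path(cfg.outdir) / f"cytonemes_eii_{e_ii:g}.png"
        )
    for e_ii, ss in snaps.items():
        mean, sd = cm.mean_length(ss)
        report[f"mean_length_eii_{e_ii:g}"] = mean
        report[f"sd_length_eii_{e_ii:g}"] = sd
        counts = [cm.interaction_count(s) for s in ss]
        report[f"mean_interactions_eii_{e_ii:g}"] = float(np.mean(counts))
        report[f"sd_interactions_eii_{e_ii:g}"] = float(np.std(counts, ddof=1))
    report["pearson_r_eii_15"] = cm.length_interaction_correlation(snaps[15.0])
    t, p = sstats.ttest_ind(
        [s.mean_length for s in snaps[15.0]], [s.mean_length for s in snaps[0.0]]
    )
    report["length_ttest_p"] = float(p)
    cfg_dir = Path(cfg.outdir)
    for e_ii, ss in snaps.items():
        _snapshot_table(ss, e_ii).to_csv(
            cfg_dir / f"cytoneme_snapshots_eii_{e_ii:g}.csv", index=False
        )
    return report


def _exp_eii_sweep(cfg: ExperimentConfig) -> dict:
    grid = cfg.overrides.get("grid", (0.0, 5.0, 15.0, 30.0, 50.0))
    snaps = {e: run_cytoneme(e, cfg.seed, cfg.fast) for e in grid}
    rows = []
    by_control = {}
    for e_ii, ss in snaps.items():
        mean, sd = cm.mean_length(ss)
        reps = [cm.find_bundles(s) for s in ss]
        singular = float(np.mean([r.singular_count / r.n_total for r in reps]))
        rows.append(
            {
                "e_ii": e_ii,
                "mean_length": mean,
                "sd_length": sd,
                "singular_fraction": singular,
                "bundled_fraction": 1.0 - singular,
            }
        )
        by_control[e_ii] = ss
    sweep = cm.bundling_summary(by_control)
    for row, rec in zip(rows, sweep.records):
        row["mean_bundling_index"] = rec["mean"]
        row["sd_bundling_index"] = rec["sd"]
    df = pd.DataFrame(rows)
    df.to_csv(Path(cfg.outdir) / "eii_sweep.csv", index=False)
    return {"experiment": cfg.name, "table": df.to_dict("records")}


def render_tissue(state, path: Path) -> None:
    """Figure-style rendering of a tessellation snapshot (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {0: "#d62728", 1: "#2ca02c", 2: "#1f77b4", 3: "0.88"}
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(
        state.points[:, 0],
        state.points[:, 1],
        c=[colors[int(l)] for l in state.labels],
        s=18,
    )
    ax.set_xlim(0, state.box_size)
    ax.set_ylim(0, state.box_size)
    ax.set_aspect(1)
    ax.set_title("generator points (grey = environment)")
    fig.savefig(path, dpi=110)
    plt.close(fig)


def render_cytonemes(snapshot: CytonemeSnapshot, surface_length: int, path: Path) -> None:
    """Draw cytonemes as vertical filaments on the periodic surface line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.hlines(0, 0, surface_length, color="k", lw=2)
    for x, h in zip(snapshot.positions, snapshot.lengths):
        ax.vlines(x, 0, h, color="tab:blue", lw=2)
    ax.set_xlim(-1, surface_length + 1)
    ax.set_xlabel("surface site")
    ax.set_ylabel("segments")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _tissue_table(run: VertexRun) -> pd.DataFrame:
    rows = []
    box = run.params.box_size
    for snap in run.snapshots[:: max(1, len(run.snapshots) // 10)]:
        tess = snap.tessellation
        for i in range(snap.m):
            rows.append(
                {
                    "step": snap.step,
                    "cell_id": i,
                    "label": CellType(int(snap.labels[i])).name,
                    "x": float(snap.points[i, 0]),
                    "y": float(snap.points[i, 1]),
                    "area": float(tess.areas[i]),
                    "perimeter": float(tess.perimeters[i]),
                    "n_neighbors": int(tess.n_neighbors[i]),
                    "box_size": box,
                }
            )
    return pd.DataFrame(rows)


def _energy_trace_table(run: VertexRun) -> pd.DataFrame:
    steps = [s.step for s in run.snapshots]
    return pd.DataFrame({"step": steps, "total_energy": run.energy_trace})


def _stats_report(stats: pm.NeighborStats) -> dict:
    return {
        "n_center": stats.n_center,
        "mean_neighbors": stats.mean_neighbors,
        "sd_neighbors": stats.sd_neighbors,
        "mean_like": stats.mean_like,
        "sd_like": stats.sd_like,
        "classification": pm.classify_pattern(stats),
    }


def _exp_vertex_homogeneous(cfg: ExperimentConfig) -> dict:
    run, stats = run_homogeneous(cfg.seed, cfg.fast)
    _tissue_table(run).to_csv(Path(cfg.outdir) / "vertex_homogeneous.csv", index=False)
    _energy_trace_table(run).to_csv(
        Path(cfg.outdir) / "vertex_homogeneous_energy.csv", index=False
    )
    render_tissue(run.snapshots[-1], Path(cfg.outdir) / "vertex_homogeneous.png")
    return {
        "experiment": cfg.name,
        "acceptance_rate": run.acceptance_rate,
        **_stats_report(stats),
    }


def _exp_vertex_mixed(cfg: ExperimentConfig) -> dict:
    ratio = cfg.overrides.get("ratio", 30.0)
    run, stats, branch = run_mixed(ratio, cfg.seed, cfg.fast)
    _tissue_table(run).to_csv(Path(cfg.outdir) / "vertex_mixed.csv", index=False)
    _energy_trace_table(run).to_csv(
        Path(cfg.outdir) / "vertex_mixed_energy.csv", index=False
    )
    render_tissue(run.snapshots[-1], Path(cfg.outdir) / "vertex_mixed.png")
    return {
        "experiment": cfg.name,
        "ratio": ratio,
        "branch": branch,
        "acceptance_rate": run.acceptance_rate,
        **_stats_report(stats),
    }


def _exp_gamma_sweep(cfg: ExperimentConfig) -> dict:
    grid = cfg.overrides.get("grid", DEFAULT_GAMMA_GRID)
    sweep = run_gamma_sweep(cfg.seed, grid, fast=cfg.fast)
    pd.DataFrame(sweep.records).to_csv(Path(cfg.outdir) / "gamma_sweep.csv", index=False)
    return {
        "experiment": cfg.name,
        "transition": sweep.transition,
        "ambiguous": sweep.ambiguous,
        "records": sweep.records,
    }


def _exp_invasion(cfg: ExperimentConfig) -> dict:
    ratio = cfg.overrides.get("ratio", 30.0)
    run1, run2, stats, cls = run_invasion(cfg.seed, ratio, cfg.fast)
    _tissue_table(run2).to_csv(Path(cfg.outdir) / "invasion_phase2.csv", index=False)
    return {
        "experiment": cfg.name,
        "ratio": ratio,
        "final_classification": cls,
        **_stats_report(stats),
    }


EXPERIMENTS = {
    "cytoneme-baseline": _exp_cytoneme_baseline,
    "eii-sweep": _exp_eii_sweep,
    "vertex-homogeneous": _exp_vertex_homogeneous,
    "vertex-mixed": _exp_vertex_mixed,
    "gamma-sweep": _exp_gamma_sweep,
    "invasion": _exp_invasion,
}


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute a named experiment, persist outputs, and return its report."""
    if config.name not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {config.name!r}; known: {sorted(EXPERIMENTS)}"
        )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report = EXPERIMENTS[config.name](config)
    report["wall_time_s"] = round(time.time() - t0, 2)
    report["seed"] = config.seed
    report["fast"] = config.fast
    report["config_hash"] = config.config_hash()
    with open(outdir / f"{config.name}-report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def compare_to_reference(report: dict, targets: list[dict], fast: bool = False) -> pd.DataFrame:
    """Evaluate a report against reference targets.

    Each target is a dict with keys ``id``, ``metric``, ``value`` and either
    ``tol`` (absolute band) or ``sd`` (band of 1 reference SD, widened by
    sqrt(10) in fast mode).  Missing metrics yield a 'not evaluated' row.
    """
    rows = []
    widen = np.sqrt(10.0) if fast else 1.0
    for t in targets:
        metric = t["metric"]
        if metric not in report or report[metric] is None:
            rows.append({"id": t["id"], "metric": metric, "status": "not evaluated"})
            continue
        got = float(report[metric])
        band = float(t["tol"]) if "tol" in t else float(t["sd"]) * widen
        ok = abs(got - float(t["value"])) <= band
        rows.append(
            {
                "id": t["id"],
                "metric": metric,
                "value": got,
                "reference": float(t["value"]),
                "band": band,
                "status": "pass" if ok else "fail",
            }
        )
    return pd.DataFrame(rows)
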
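"""Figure-level experiment protocols, aggregation, and file output.

Each protocol regenerates its own goals and networks from a master seed
(child seeds per replicate), runs the relevant engine, and reduces the
replicate runs to per-condition summary statistics: the mode (ties
toward the smaller value), mean and population standard deviation of
the end-state waist, plus convergence counts.  Default replicate counts
and generation caps are desk-scale reductions of the study's 100-run
protocols; ``full=True`` restores the full scale.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .evolution import (
    EnsembleResult,
    EvolutionConfig,
    NetworkInit,
    evolve_ensemble,
    expand_network,
)
from .goals import GoalMatrix, expand_goal, generate_goal, normalize_variance_norm
from .network import compose_batch
from .nonlinear import default_nonlinear_config, evolve_nonlinear_ensemble, make_digit_dataset
from .ode import integrate_ensemble

__all__ = [
    "ExperimentSpec",
    "RunSummary",
    "EXPERIMENTS",
    "run_experiment",
    "summarize",
    "make_goals",
    "make_initial_populations",
]

EXPERIMENTS = (
    "waist_vs_rank",
    "waist_vs_A0",
    "trajectories",
    "min_waist_dist",
    "fluctuation",
    "expansion",
    "nonlinear",
    "ode_phase",
)


@dataclass
class ExperimentSpec:
    """Declarative description of one figure-level protocol.

    ``options`` carries protocol-specific settings (fluctuation variant,
    expansion sizes, ODE step, ...) documented in the protocol functions.
    """

    experiment: str
    replicates: int = 20
    ranks: Sequence[int] = (1, 2, 3, 4, 5, 6)
    A0_values: Sequence[float] = (0.01,)
    M: int = 6
    L: int = 4
    norm: float = 60.0
    variance_normalize: bool = False
    config: EvolutionConfig = field(default_factory=EvolutionConfig)
    seed: int = 0
    out_dir: str | None = None
    options: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if len(self.ranks) == 0 or len(self.A0_values) == 0:
            raise ValueError("parameter grids must be nonempty")

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentSpec":
        """Load a spec from TOML or YAML; a ``config`` table maps onto
        :class:`EvolutionConfig` fields."""
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            raw = tomllib.loads(path.read_text())
        else:
            import yaml

            raw = yaml.safe_load(path.read_text())
        cfg = EvolutionConfig(**raw.pop("config", {}))
        return cls(config=cfg, **raw)


@dataclass
class RunSummary:
    """Per-run records and their per-condition aggregates."""

    runs: pd.DataFrame
    summary: pd.DataFrame
    artifacts: dict[str, Any] = field(default_factory=dict)


def _mode_smallest(values: Sequence[int]) -> int:
    vals, counts = np.unique(np.asarray(values), return_counts=True)
    return int(vals[np.argmax(counts)])  # np.unique sorts: first max = smallest


def summarize(rows: pd.DataFrame, by: Sequence[str] = ("rank", "A0")) -> pd.DataFrame:
    """Aggregate per-run rows into mode/mean/sd of the end waist per cell.

    The mode breaks ties toward the smaller waist; the standard deviation
    is the population sd over all runs in the cell.  Cells are also
    summarized over converged runs only, so both conventions for the
    study's error bars are reported.
    """
    if rows.empty:
        raise ValueError("no runs to summarize")
    by = [b for b in by if b in rows.columns]
    out = []
    for keys, grp in rows.groupby(list(by)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        conv = grp[grp["converged_at"] >= 0]
        rec = dict(zip(by, keys))
        rec.update(
            n=len(grp),
            n_converged=len(conv),
            waist_mode=_mode_smallest(grp["end_waist"]),
            waist_mean=float(grp["end_waist"].mean()),
            waist_sd=float(grp["end_waist"].std(ddof=0)),
            min_waist_mean=float(grp["min_waist"].mean()),
        )
        if len(conv):
            rec.update(
                waist_mode_converged=_mode_smallest(conv["end_waist"]),
                waist_mean_converged=float(conv["end_waist"].mean()),
                waist_sd_converged=float(conv["end_waist"].std(ddof=0)),
            )
        else:
            rec.update(
                waist_mode_converged=np.nan,
                waist_mean_converged=np.nan,
                waist_sd_converged=np.nan,
            )
        out.append(rec)
    return pd.DataFrame(out)


def make_goals(
    M: int,
    rank: int,
    norm: float,
    replicates: int,
    seed: int,
    variance_normalize: bool = False,
) -> tuple[np.ndarray, list[GoalMatrix]]:
    """One independent random goal per replicate (child seed per run)."""
    goals = []
    for r in range(replicates):
        g = generate_goal(M, rank, norm, np.random.default_rng([seed, rank, r]))
        if variance_normalize:
            g = normalize_variance_norm(g, norm**2)
        goals.append(g)
    return np.stack([g.entries for g in goals]), goals


def make_initial_populations(
    M: int, L: int, N: int, A0: float, replicates: int, seed: int
) -> np.ndarray:
    """One random founder per replicate, cloned N times, scaled to ``A0``."""
    rng = np.random.default_rng([seed, 101])
    raw = rng.random((replicates, L, M, M))
    norms = np.linalg.norm(compose_batch(raw), axis=(1, 2))
    founders = raw * (A0 / norms[:, None, None, None]) ** (1.0 / L)
    return np.broadcast_to(
        founders[:, None], (replicates, N) + founders.shape[1:]
    ).copy()


def _rows_from_ensemble(
    res: EnsembleResult, rank: int, A0: float, seed: int
) -> pd.DataFrame:
    bi_fit = res.best_fitness[:, -1]
    return pd.DataFrame(
        {
            "rank": rank,
            "A0": A0,
            "seed": seed,
            "replicate": np.arange(res.R),
            "converged_at": res.converged_at,
            "end_waist": res.end_waist,
            "min_waist": res.min_waist,
            "final_fitness": bi_fit,
        }
    )


def _grid_runs(spec: ExperimentSpec, n_generations: int | None = None) -> tuple[
    pd.DataFrame, dict[tuple[int, float], EnsembleResult]
]:
    rows, results = [], {}
    for rank in spec.ranks:
        for A0 in spec.A0_values:
            goals, _ = make_goals(
                spec.M, rank, spec.norm, spec.replicates, spec.seed,
                spec.variance_normalize,
            )
            res = evolve_ensemble(
                dataclasses.replace(spec.config, seed=spec.seed),
                goals[None],
                [0],
                NetworkInit(spec.M, spec.L, A0),
                n_generations=n_generations,
                rng=np.random.default_rng([spec.seed, rank, int(A0 * 1000) % 2**31]),
            )
            rows.append(_rows_from_ensemble(res, rank, A0, spec.seed))
            results[(rank, A0)] = res
    return pd.concat(rows, ignore_index=True), results


# ---------------------------------------------------------------------------
# protocols


def _exp_waist_vs_rank(spec: ExperimentSpec) -> RunSummary:
    """End-state waist (mode over runs) as a function of goal rank."""
    rows, results = _grid_runs(spec)
    summary = summarize(rows)
    counts = {
        f"rank{rank}": res.end_active_counts.tolist()
        for (rank, _), res in results.items()
    }
    return RunSummary(rows, summary, {"end_active_counts": counts})


def _exp_waist_vs_A0(spec: ExperimentSpec) -> RunSummary:
    """Mean end-state waist against the initial link intensity A0.

    Also reports, per A0, the fraction of runs ending at waist 1 and at
    waist < M (the two transition curves of the study).
    """
    rows, _ = _grid_runs(spec)
    summary = summarize(rows)
    frac = (
        rows.assign(
            waist1=rows.end_waist == 1, bowtie=rows.end_waist < spec.M
        )
        .groupby(["rank", "A0"])[["waist1", "bowtie"]]
        .mean()
        .reset_index()
    )
    return RunSummary(rows, summary, {"fractions": frac})


def _exp_trajectories(spec: ExperimentSpec) -> RunSummary:
    """Per-layer active-node trajectories averaged over converged runs."""
    n_gen = spec.options.get("n_generations", spec.config.max_generations)
    rows, results = _grid_runs(spec, n_generations=n_gen)
    mean_trajs = {}
    for (rank, A0), res in results.items():
        conv = res.converged_at >= 0
        use = conv if conv.any() else np.ones(res.R, bool)
        mean_trajs[(rank, A0)] = pd.DataFrame(
            {
                "generation": res.generations,
                "mean_fitness": res.mean_fitness[use].mean(axis=0),
                **{
                    f"active_l{k + 2}": res.active_counts[use, :, k].mean(axis=0)
                    for k in range(res.active_counts.shape[2])
                },
                "waist": res.waist[use].mean(axis=0),
            }
        )
    return RunSummary(rows, summarize(rows), {"mean_trajectories": mean_trajs})


def _exp_min_waist_dist(spec: ExperimentSpec) -> RunSummary:
    """Distribution of the instantaneous minimum waist per (rank, A0)."""
    n_gen = spec.options.get("n_generations", spec.config.max_generations)
    rows, _ = _grid_runs(spec, n_generations=n_gen)
    dist = (
        rows.groupby(["rank", "A0", "min_waist"]).size().rename("count").reset_index()
    )
    return RunSummary(rows, summarize(rows), {"min_waist_distribution": dist})


def _exp_fluctuation(spec: ExperimentSpec) -> RunSummary:
    """Goal-fluctuation protocols: goal redrawn every ``period`` generations.

    options: ``variant`` in {"after_adaptation", "rank_switch", "from_start"},
    ``period`` (default 1000), ``epochs`` (default 10), ``switch_rank``
    (rank after the first change, variant "rank_switch", default 6).
    Ranks are taken per run from ``spec.ranks`` (first entry = initial rank).
    """
    variant = spec.options.get("variant", "after_adaptation")
    period = int(spec.options.get("period", 1000))
    epochs = int(spec.options.get("epochs", 10))
    switch_rank = int(spec.options.get("switch_rank", 6))
    rank0 = int(spec.ranks[0])
    A0 = float(spec.A0_values[0])
    R = spec.replicates
    cfg = dataclasses.replace(spec.config, seed=spec.seed)
    rng = np.random.default_rng([spec.seed, 77])

    def epoch_goals(rank: int, epoch: int) -> np.ndarray:
        out, _ = make_goals(
            spec.M, rank, spec.norm, R, spec.seed + 1000 * (epoch + 1),
            spec.variance_normalize,
        )
        return out

    epoch_ranks = [rank0] + [
        switch_rank if variant == "rank_switch" else rank0
    ] * (epochs - 1)
    goals_by_epoch = np.stack(
        [epoch_goals(rk, e) for e, rk in enumerate(epoch_ranks)]
    )
    rows = []
    if variant == "from_start":
        res = evolve_ensemble(
            cfg,
            goals_by_epoch,
            [e * period for e in range(epochs)],
            NetworkInit(spec.M, spec.L, A0),
            n_generations=epochs * period,
            stop_on_convergence=False,
            rng=rng,
        )
        rows.append(
            _rows_from_ensemble(res, rank0, A0, spec.seed).assign(phase="fluctuating")
        )
        art = {"trajectory": res}
        pre_waist = post_waist = None
    else:
        adapt = evolve_ensemble(
            cfg,
            goals_by_epoch[:1],
            [0],
            NetworkInit(spec.M, spec.L, A0),
            rng=rng,
        )
        rows.append(
            _rows_from_ensemble(adapt, rank0, A0, spec.seed).assign(phase="adapt")
        )
        fluct = evolve_ensemble(
            cfg,
            goals_by_epoch[1:],
            [e * period for e in range(epochs - 1)],
            adapt.final_populations,
            n_generations=(epochs - 1) * period,
            stop_on_convergence=False,
            rng=rng,
        )
        rows.append(
            _rows_from_ensemble(
                fluct, epoch_ranks[-1], A0, spec.seed
            ).assign(phase="fluctuating")
        )
        pre_waist, post_waist = adapt.end_waist, fluct.waist[:, -1]
        art = {
            "adapt": adapt,
            "fluctuating": fluct,
            "pre_waist": pre_waist,
            "post_waist": post_waist,
        }
    runs = pd.concat(rows, ignore_index=True)
    summary = summarize(runs, by=("phase", "rank", "A0"))
    return RunSummary(runs, summary, art)


def _exp_expansion(spec: ExperimentSpec) -> RunSummary:
    """Goal/network expansion versus a no-expansion control.

    Rank-1 goals of dimension ``M`` are expanded to ``expand_to`` at
    generation ``expand_at`` (network padded with near-zero links); the
    control keeps the original goal.  options: ``expand_to`` (default
    2M), ``expand_at`` (default 1000), ``pad_scale`` (default 1e-3).
    """
    expand_to = int(spec.options.get("expand_to", 2 * spec.M))
    expand_at = int(spec.options.get("expand_at", 1000))
    pad_scale = float(spec.options.get("pad_scale", 1e-3))
    A0 = float(spec.A0_values[0])
    R = spec.replicates
    cfg = dataclasses.replace(spec.config, seed=spec.seed)
    rng = np.random.default_rng([spec.seed, 78])

    goal_entries, goal_objs = make_goals(spec.M, 1, spec.norm, R, spec.seed)
    phase1 = evolve_ensemble(
        cfg,
        goal_entries[None],
        [0],
        NetworkInit(spec.M, spec.L, A0),
        n_generations=expand_at,
        stop_on_convergence=False,
        rng=rng,
    )
    # expanded arm
    big_goals = np.stack(
        [
            expand_goal(g, expand_to, np.random.default_rng([spec.seed, 9, r])).entries
            for r, g in enumerate(goal_objs)
        ]
    )
    N = cfg.N
    big_pop = np.stack(
        [
            np.stack(
                [
                    expand_network(
                        phase1.final_populations[r, n], expand_to, pad_scale, rng
                    ).matrices
                    for n in range(N)
                ]
            )
            for r in range(R)
        ]
    )
    expanded = evolve_ensemble(cfg, big_goals[None], [0], big_pop, rng=rng)
    control = evolve_ensemble(
        cfg, goal_entries[None], [0], phase1.final_populations, rng=rng
    )
    rows = pd.concat(
        [
            _rows_from_ensemble(expanded, 1, A0, spec.seed).assign(arm="expanded"),
            _rows_from_ensemble(control, 1, A0, spec.seed).assign(arm="control"),
        ],
        ignore_index=True,
    )
    summary = summarize(rows, by=("arm", "rank", "A0"))
    return RunSummary(
        rows, summary, {"expanded": expanded, "control": control}
    )


def _exp_nonlinear(spec: ExperimentSpec) -> RunSummary:
    """A0 dependence of the waist in the tanh digit-classification task.

    options: ``n_images`` (default 300), ``n_generations`` (default
    2500), ``noise`` (default 0.1).
    """
    n_images = int(spec.options.get("n_images", 300))
    n_gen = int(spec.options.get("n_generations", 2500))
    noise = float(spec.options.get("noise", 0.1))
    data = make_digit_dataset(
        n_images, np.random.default_rng([spec.seed, 55]), noise=noise
    )
    cfg = default_nonlinear_config(
        seed=spec.seed,
        N=spec.config.N,
        selection=spec.config.selection,
        max_generations=n_gen,
    )
    rows = []
    trajs = {}
    for A0 in spec.A0_values:
        tr = evolve_nonlinear_ensemble(cfg, A0, data, replicates=spec.replicates)
        trajs[A0] = tr
        rows.append(
            pd.DataFrame(
                {
                    "rank": -1,
                    "A0": A0,
                    "seed": spec.seed,
                    "replicate": np.arange(spec.replicates),
                    "converged_at": -1,
                    "end_waist": tr.end_waist,
                    "min_waist": tr.min_waist,
                    "final_fitness": tr.best_fitness[:, -1],
                }
            )
        )
    runs = pd.concat(rows, ignore_index=True)
    return RunSummary(runs, summarize(runs, by=("A0",)), {"trajectories": trajs})


def _exp_ode_phase(spec: ExperimentSpec) -> RunSummary:
    """ODE-surrogate sweep of end-state waist over the A0 grid.

    options: ``dt`` (default 0.5), ``t_end`` (default 5e4), ``eta``
    (default 1e-4).
    """
    dt = float(spec.options.get("dt", 0.5))
    t_end = float(spec.options.get("t_end", 5e4))
    eta = float(spec.options.get("eta", 1e-4))
    R = spec.replicates
    rows = []
    for rank in spec.ranks:
        for A0 in spec.A0_values:
            goals, _ = make_goals(
                spec.M, rank, spec.norm, R, spec.seed, spec.variance_normalize
            )
            init = make_initial_populations(
                spec.M, spec.L, 1, A0, R, spec.seed + int(A0 * 997) % 10007
            )[:, 0]
            res = integrate_ensemble(
                init, goals, eta=eta, dt=dt, t_end=t_end, record_stride=200
            )
            rows.append(
                pd.DataFrame(
                    {
                        "rank": rank,
                        "A0": A0,
                        "seed": spec.seed,
                        "replicate": np.arange(R),
                        "converged_at": np.where(
                            np.array(res.status) == "converged", 0, -1
                        ),
                        "end_waist": res.end_waist,
                        "min_waist": res.min_waist,
                        "final_fitness": res.fitness[:, -1],
                    }
                )
            )
    runs = pd.concat(rows, ignore_index=True)
    return RunSummary(runs, summarize(runs))


_DISPATCH = {
    "waist_vs_rank": _exp_waist_vs_rank,
    "waist_vs_A0": _exp_waist_vs_A0,
    "trajectories": _exp_trajectories,
    "min_waist_dist": _exp_min_waist_dist,
    "fluctuation": _exp_fluctuation,
    "expansion": _exp_expansion,
    "nonlinear": _exp_nonlinear,
    "ode_phase": _exp_ode_phase,
}


def run_experiment(spec: ExperimentSpec) -> RunSummary:
    """Execute a protocol and (if ``out_dir`` is set) write its artifacts.

    Writes ``runs.csv`` (per-run rows), ``summary.csv`` (aggregates),
    ``manifest.json`` (spec, seed, version, timing) and, for trajectory
    protocols, one mean-trajectory CSV per condition.
    """
    t0 = time.time()
    result = _DISPATCH[spec.experiment](spec)
    if spec.out_dir is not None:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.runs.to_csv(out / "runs.csv", index=False)
        result.summary.to_csv(out / "summary.csv", index=False)
        for key, val in result.artifacts.items():
            if isinstance(val, pd.DataFrame):
                val.to_csv(out / f"{key}.csv", index=False)
            elif isinstance(val, dict) and all(
                isinstance(v, pd.DataFrame) for v in val.values()
            ):
                for cond, df in val.items():
                    tag = "_".join(str(c) for c in np.atleast_1d(cond))
                    df.to_csv(out / f"{key}_{tag}.csv", index=False)
        manifest = {
            "experiment": spec.experiment,
            "seed": spec.seed,
            "replicates": spec.replicates,
            "ranks": list(spec.ranks),
            "A0_values": [float(a) for a in spec.A0_values],
            "M": spec.M,
            "L": spec.L,
            "norm": spec.norm,
            "variance_normalize": spec.variance_normalize,
            "config": dataclasses.asdict(spec.config),
            "options": {k: str(v) for k, v in spec.options.items()},
            "version": __version__,
            "wall_seconds": round(time.time() - t0, 2),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result
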
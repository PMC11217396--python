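"""Genetic algorithm for layered linear networks.

One generation is: duplicate the population of ``N`` individuals to
``2N``, give 20% of the pool a single product-rule mutation (one link
multiplied by a Gaussian factor xi ~ N(1, 0.1)), evaluate fitness
``F = -||A - G||_F^2`` (optionally with an L1/L2 link cost), and select
``N`` survivors by tournament (group size 4) or elite selection.

The hot path is the ensemble kernel :func:`evolve_ensemble`, which
evolves many independent replicate populations simultaneously as one
``(R, 2N, L, M, M)`` array; all per-generation work is batched numpy.
Only mutated individuals are re-evaluated (parents and copies keep their
cached fitness), which makes long runs cheap.  The single-run surface
(:func:`run_evolution`, :func:`generation_step`, ...) wraps this kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .goals import GoalMatrix
from .network import DEFAULT_THRESHOLDS, LayeredNetwork, compose_batch

__all__ = [
    "EvolutionConfig",
    "NetworkInit",
    "Trajectory",
    "EnsembleResult",
    "mutate",
    "generation_step",
    "tournament_select",
    "regularized_fitness",
    "run_evolution",
    "evolve_ensemble",
    "expand_network",
    "instantaneous_min_waist",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """All GA hyperparameters.

    Defaults are the study conditions: population ``N = 100``, mutation
    rate 0.2 per (duplicated) population, multiplier xi ~ N(1, 0.1)
    resampled on the rare nonpositive draw, tournament selection with
    group size 4, convergence at mean fitness >= -0.01.
    """

    N: int = 100
    mutate_fraction: float = 0.2
    xi_mean: float = 1.0
    xi_var: float = 0.1
    xi_resample_nonpositive: bool = True
    selection: str = "tournament"  # "tournament" | "elite"
    tournament_size: int = 4
    convergence_fitness: float = -0.01
    max_generations: int = 150_000
    reg_kind: str = "none"  # "none" | "L1" | "L2"
    reg_lambda: float = 0.0
    seed: int = 0
    record_stride: int = 25
    active_node_definition: str = "fitness_drop"
    active_threshold: float | None = None
    mutate_pool: str = "all"  # "all" (whole 2N pool) | "copies" (second half)

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if not 0 <= self.mutate_fraction <= 1:
            raise ValueError("mutate_fraction must lie in [0, 1]")
        if self.xi_var <= 0:
            raise ValueError("xi_var must be positive")
        if self.tournament_size < 2:
            raise ValueError("tournament_size must be >= 2")
        if self.selection not in ("tournament", "elite"):
            raise ValueError(f"unknown selection scheme: {self.selection!r}")
        if self.reg_kind not in ("none", "L1", "L2"):
            raise ValueError(f"unknown regularization: {self.reg_kind!r}")
        if self.reg_lambda < 0:
            raise ValueError("reg_lambda must be nonnegative")
        if self.mutate_pool not in ("all", "copies"):
            raise ValueError(f"unknown mutate_pool: {self.mutate_pool!r}")

    @property
    def threshold(self) -> float:
        if self.active_threshold is not None:
            return self.active_threshold
        return DEFAULT_THRESHOLDS[self.active_node_definition]


@dataclass(frozen=True)
class NetworkInit:
    """Initial-network prescription: random positive links scaled to A0."""

    M: int = 6
    L: int = 4
    A0: float = 0.01


@dataclass
class Trajectory:
    """Per-generation records of one evolutionary run (at the record stride)."""

    generations: np.ndarray
    mean_fitness: np.ndarray
    best_fitness: np.ndarray
    active_counts: np.ndarray  # (n_records, L - 1), middle layers 2..L
    waist: np.ndarray
    epoch: np.ndarray
    converged_at: int | None
    final_network: LayeredNetwork
    final_population: np.ndarray  # (N, L, M, M)

    def to_frame(self):
        import pandas as pd

        d = {
            "generation": self.generations,
            "mean_fitness": self.mean_fitness,
            "best_fitness": self.best_fitness,
        }
        for k in range(self.active_counts.shape[1]):
            d[f"active_l{k + 2}"] = self.active_counts[:, k]
        d["waist"] = self.waist
        d["epoch"] = self.epoch
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# batched primitives


def _batch_scores(
    stacks: np.ndarray, goals: np.ndarray, reg_kind: str, reg_lambda: float
) -> np.ndarray:
    """(Regularized) fitness of a ``(B, L, M, M)`` batch against ``(B, M, M)`` goals."""
    A = compose_batch(stacks)
    diff = A - goals
    f = -np.einsum("bij,bij->b", diff, diff)
    if reg_kind == "L1" and reg_lambda > 0:
        f = f - reg_lambda * np.abs(stacks).sum(axis=(1, 2, 3))
    elif reg_kind == "L2" and reg_lambda > 0:
        f = f - reg_lambda * np.einsum("blij,blij->b", stacks, stacks)
    return f


def _draw_xi(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    mean: float,
    var: float,
    resample_nonpositive: bool,
) -> np.ndarray:
    xi = rng.normal(mean, np.sqrt(var), shape)
    if resample_nonpositive:
        bad = xi <= 0
        while np.any(bad):
            xi[bad] = rng.normal(mean, np.sqrt(var), int(bad.sum()))
            bad = xi <= 0
    return xi


def _distinct_indices(
    rng: np.random.Generator, R: int, pool: int, k: int, offset: int = 0
) -> np.ndarray:
    """k distinct indices per replicate, drawn uniformly from [offset, offset+pool)."""
    keys = rng.random((R, pool))
    return np.argpartition(keys, k - 1, axis=1)[:, :k] + offset


def _tournament_indices(
    fit: np.ndarray, n_select: int, group_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Winner indices of ``n_select`` tournaments per replicate.

    Each tournament samples ``group_size`` members without replacement
    from the pool; groups themselves are drawn with replacement.
    """
    R, P = fit.shape
    if group_size > P:
        raise ValueError("group size cannot exceed pool size")
    cand = rng.integers(0, P, (R, n_select, group_size))
    # reject groups with internal duplicates (probability ~3% for 4-of-200)
    while True:
        s = np.sort(cand, axis=2)
        dup = (s[:, :, 1:] == s[:, :, :-1]).any(axis=2)
        if not dup.any():
            break
        cand[dup] = rng.integers(0, P, (int(dup.sum()), group_size))
    scores = np.take_along_axis(fit[:, None, :], cand, axis=2)
    win = np.argmax(scores, axis=2)
    return np.take_along_axis(cand, win[:, :, None], axis=2)[:, :, 0]


def _batch_waists(
    stacks: np.ndarray,
    goals: np.ndarray,
    definition: str,
    threshold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Active-node counts and waist size for a batch of networks.

    Returns ``(counts (R, L - 1), waist (R,))`` for middle node layers
    ``2..L``, using the same importance definitions as
    :func:`bowtie_evo.network.node_importance`.
    """
    R, L, M, _ = stacks.shape
    if definition == "max_link":
        raw = np.empty((R, L - 1, M))
        for k in range(L - 1):
            raw[:, k] = np.maximum(
                stacks[:, k].max(axis=2), stacks[:, k + 1].max(axis=1)
            )
    else:
        A_full = compose_batch(stacks)
        dele = np.broadcast_to(stacks[:, None, None], (R, L - 1, M, L, M, M)).copy()
        for li in range(L - 1):
            for i in range(M):
                dele[:, li, i, li, i, :] = 0.0
                dele[:, li, i, li + 1, :, i] = 0.0
        A_del = compose_batch(dele.reshape(R * (L - 1) * M, L, M, M)).reshape(
            R, L - 1, M, M, M
        )
        if definition == "fitness_drop":
            F_full = -np.sum((A_full - goals) ** 2, axis=(1, 2))
            F_del = -np.sum((A_del - goals[:, None, None]) ** 2, axis=(3, 4))
            raw = np.abs(F_del - F_full[:, None, None])
        else:
            raw = np.sum((A_full[:, None, None] - A_del) ** 2, axis=(3, 4))
    totals = raw.sum(axis=2, keepdims=True)
    P = np.divide(raw, totals, out=np.zeros_like(raw), where=totals > 0)
    counts = (P > threshold).sum(axis=2)
    return counts, counts.min(axis=1)


# ---------------------------------------------------------------------------
# public single-network operations


def mutate(
    individual: LayeredNetwork,
    rng: np.random.Generator,
    xi_mean: float = 1.0,
    xi_var: float = 0.1,
    resample_nonpositive: bool = True,
    _forced_xi: float | None = None,
) -> LayeredNetwork:
    """Product-rule mutation: one uniformly chosen link is multiplied by xi.

    ``xi ~ N(xi_mean, xi_var)``, redrawn while nonpositive (the variance
    is small enough that this is a ~1e-3 tail event).  ``_forced_xi`` is
    a test hook that bypasses the draw.
    """
    out = individual.copy()
    flat = out.matrices.reshape(-1)
    idx = int(rng.integers(0, flat.size))
    if _forced_xi is not None:
        xi = float(_forced_xi)
    else:
        xi = float(_draw_xi(rng, (1,), xi_mean, xi_var, resample_nonpositive)[0])
    flat[idx] *= xi
    return out


def regularized_fitness(
    net: "LayeredNetwork | np.ndarray",
    goal: "GoalMatrix | np.ndarray",
    reg_kind: str = "none",
    reg_lambda: float = 0.0,
) -> float:
    """Fitness minus an optional link cost: L1 ``lam*Sum|A|`` or L2 ``lam*Sum A^2``."""
    if reg_lambda < 0:
        raise ValueError("reg_lambda must be nonnegative")
    if reg_kind not in ("none", "L1", "L2"):
        raise ValueError(f"unknown regularization: {reg_kind!r}")
    stack = net.matrices if isinstance(net, LayeredNetwork) else np.asarray(net, float)
    goal_e = goal.entries if isinstance(goal, GoalMatrix) else np.asarray(goal, float)
    return float(
        _batch_scores(stack[None], goal_e[None], reg_kind, reg_lambda)[0]
    )


def tournament_select(
    pool: Sequence[LayeredNetwork],
    fitnesses: Sequence[float],
    group_size: int,
    rng: np.random.Generator,
    n_select: int | None = None,
) -> list[LayeredNetwork]:
    """Select ``n_select`` (default ``len(pool)//2``) winners by tournament."""
    if n_select is None:
        n_select = len(pool) // 2
    fit = np.asarray(fitnesses, dtype=float)[None, :]
    idx = _tournament_indices(fit, n_select, group_size, rng)[0]
    return [pool[i].copy() for i in idx]


def generation_step(
    population: list[LayeredNetwork],
    goal: "GoalMatrix | np.ndarray",
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> tuple[list[LayeredNetwork], dict]:
    """One full GA generation on an explicit list population.

    Duplicates to ``2N``, mutates ``floor(mutate_fraction * 2N)`` distinct
    individuals (one link each), evaluates all, selects ``N``.  Returns
    the new population and per-generation stats.
    """
    N = len(population)
    if N != config.N:
        raise ValueError(f"population size {N} does not match config.N={config.N}")
    goal_e = goal.entries if isinstance(goal, GoalMatrix) else np.asarray(goal, float)
    pop = np.stack([ind.matrices for ind in population] * 2)  # (2N, L, M, M)
    P = 2 * N
    k = int(config.mutate_fraction * P)
    if k > 0:
        pool = P if config.mutate_pool == "all" else N
        off = 0 if config.mutate_pool == "all" else N
        idx = _distinct_indices(rng, 1, pool, k, off)[0]
        links = rng.integers(0, pop[0].size, k)
        xi = _draw_xi(
            rng, (k,), config.xi_mean, config.xi_var, config.xi_resample_nonpositive
        )
        flat = pop.reshape(P, -1)
        flat[idx, links] *= xi
    goals = np.broadcast_to(goal_e, (P,) + goal_e.shape)
    fit = _batch_scores(pop, goals, config.reg_kind, config.reg_lambda)
    if config.selection == "elite":
        # (mu + lambda)-style: rank parents and actually-mutated copies only,
        # so unmutated duplicates never displace distinct survivors
        cand = np.zeros(P, dtype=bool)
        cand[:N] = True
        if k > 0:
            cand[idx] = True
        sel = np.argsort(-np.where(cand, fit, -np.inf), kind="stable")[:N]
    else:
        sel = _tournament_indices(fit[None], N, config.tournament_size, rng)[0]
    new_pop = [LayeredNetwork(pop[i].copy()) for i in sel]
    stats = {
        "mean_fitness": float(fit[sel].mean()),
        "best_fitness": float(fit[sel].max()),
        "evaluations": P,
    }
    return new_pop, stats


# ---------------------------------------------------------------------------
# ensemble kernel


@dataclass
class EnsembleResult:
    """Records of ``R`` independent replicate runs evolved in lockstep.

    End-state quantities (``end_waist``, ``final_networks``) are taken at
    the generation a replicate first converged (mean fitness >= the
    configured threshold); for replicates that never converged, at the
    last generation.  ``min_waist`` is the instantaneous minimum over the
    recorded generations up to that point.
    """

    generations: np.ndarray  # (n_rec,)
    mean_fitness: np.ndarray  # (R, n_rec)
    best_fitness: np.ndarray  # (R, n_rec)
    active_counts: np.ndarray  # (R, n_rec, L - 1)
    waist: np.ndarray  # (R, n_rec)
    epoch: np.ndarray  # (n_rec,)
    converged_at: np.ndarray  # (R,), -1 if never
    end_waist: np.ndarray  # (R,)
    end_active_counts: np.ndarray  # (R, L - 1)
    min_waist: np.ndarray  # (R,)
    final_networks: np.ndarray  # (R, L, M, M), best individual snapshots
    final_populations: np.ndarray  # (R, N, L, M, M)

    @property
    def R(self) -> int:
        return self.mean_fitness.shape[0]


def evolve_ensemble(
    config: EvolutionConfig,
    goals_by_epoch: np.ndarray,
    switch_generations: Sequence[int],
    init: "NetworkInit | np.ndarray",
    n_generations: int | None = None,
    stop_on_convergence: bool = True,
    rng: np.random.Generator | None = None,
) -> EnsembleResult:
    """Evolve ``R`` replicate populations simultaneously.

    Parameters
    ----------
    goals_by_epoch:
        Array ``(E, R, M, M)``: goal entries per epoch and replicate.
    switch_generations:
        Epoch start generations, first must be 0, strictly increasing.
    init:
        Either a :class:`NetworkInit` (fresh random populations) or an
        explicit ``(R, N, L, M, M)`` array of starting populations.
    n_generations:
        Hard cap; defaults to ``config.max_generations``.
    stop_on_convergence:
        Stop once every replicate has converged *and* the last epoch has
        begun.  Convergence per replicate is still tracked when False.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    goals_by_epoch = np.asarray(goals_by_epoch, dtype=float)
    E, R, M, _ = goals_by_epoch.shape
    switch_generations = list(switch_generations)
    if switch_generations[0] != 0 or len(switch_generations) != E:
        raise ValueError("switch_generations must start at 0, one per epoch")
    if n_generations is None:
        n_generations = config.max_generations

    N = config.N
    P = 2 * N
    if isinstance(init, NetworkInit):
        # one random founder configuration per replicate, cloned into the
        # whole population ("a random configuration with link intensity A0")
        L = init.L
        pops = np.empty((R, N, L, M, M))
        for r in range(R):
            raw = rng.random((L, M, M))
            norm = np.linalg.norm(compose_batch(raw[None])[0])
            pops[r] = (raw * (init.A0 / norm) ** (1.0 / L))[None]
    else:
        pops = np.asarray(init, dtype=float).copy()
        L = pops.shape[2]
    if pops.shape != (R, N, L, M, M):
        raise ValueError(f"initial populations have shape {pops.shape}")

    pop = np.empty((R, P, L, M, M))
    pop[:, :N] = pops
    fit = np.full((R, P), -np.inf)
    rr = np.arange(R)[:, None]

    k = int(config.mutate_fraction * P)
    pool, off = (P, 0) if config.mutate_pool == "all" else (N, N)
    threshold = config.threshold
    definition = config.active_node_definition
    plain = config.reg_kind == "none" or config.reg_lambda == 0.0

    epoch_idx = 0
    goals = goals_by_epoch[0]
    fit[:, :N] = _batch_scores(
        pop[:, :N].reshape(R * N, L, M, M),
        np.repeat(goals, N, axis=0),
        config.reg_kind,
        config.reg_lambda,
    ).reshape(R, N)

    records: list[tuple] = []
    converged_at = np.full(R, -1, dtype=int)
    end_waist = np.full(R, -1, dtype=int)
    end_counts = np.full((R, L - 1), -1, dtype=int)
    min_waist = np.full(R, np.iinfo(np.int64).max, dtype=int)
    final_nets = np.empty((R, L, M, M))

    def plain_mean_fitness() -> np.ndarray:
        if plain:
            return fit[:, :N].mean(axis=1)
        return _batch_scores(
            pop[:, :N].reshape(R * N, L, M, M),
            np.repeat(goals, N, axis=0),
            "none",
            0.0,
        ).reshape(R, N).mean(axis=1)

    def record(gen: int) -> None:
        bi = np.argmax(fit[:, :N], axis=1)
        best = pop[np.arange(R), bi]
        counts, waist = _batch_waists(best, goals, definition, threshold)
        mf = plain_mean_fitness()
        bf = fit[np.arange(R), bi] if plain else _batch_scores(
            best, goals, "none", 0.0
        )
        records.append((gen, mf, bf, counts, waist, epoch_idx))
        fresh = converged_at < 0
        np.minimum(min_waist, np.where(fresh, waist, min_waist), out=min_waist)
        newly = fresh & (mf >= config.convergence_fitness)
        if newly.any():
            converged_at[newly] = gen
            end_waist[newly] = waist[newly]
            end_counts[newly] = counts[newly]
            final_nets[newly] = best[newly]

    record(0)
    gen = 0
    while gen < n_generations:
        gen += 1
        # epoch switch
        if epoch_idx + 1 < E and gen >= switch_generations[epoch_idx + 1]:
            epoch_idx += 1
            goals = goals_by_epoch[epoch_idx]
            fit[:, :N] = _batch_scores(
                pop[:, :N].reshape(R * N, L, M, M),
                np.repeat(goals, N, axis=0),
                config.reg_kind,
                config.reg_lambda,
            ).reshape(R, N)
        # duplicate
        pop[:, N:] = pop[:, :N]
        fit[:, N:] = fit[:, :N]
        # mutate
        if k > 0:
            idx = _distinct_indices(rng, R, pool, k, off)
            links = rng.integers(0, L * M * M, (R, k))
            xi = _draw_xi(
                rng,
                (R, k),
                config.xi_mean,
                config.xi_var,
                config.xi_resample_nonpositive,
            )
            flat = pop.reshape(R, P, -1)
            flat[rr, idx, links] *= xi
            sub = pop[rr, idx].reshape(R * k, L, M, M)
            g_sub = np.repeat(goals, k, axis=0)
            fit[rr, idx] = _batch_scores(
                sub, g_sub, config.reg_kind, config.reg_lambda
            ).reshape(R, k)
        # select
        if config.selection == "elite":
            cand = np.zeros((R, P), dtype=bool)
            cand[:, :N] = True
            if k > 0:
                cand[rr, idx] = True
            sel = np.argsort(
                -np.where(cand, fit, -np.inf), axis=1, kind="stable"
            )[:, :N]
        else:
            sel = _tournament_indices(fit, N, config.tournament_size, rng)
        pop[:, :N] = pop[rr, sel]
        fit[:, :N] = np.take_along_axis(fit, sel, axis=1)

        if gen % config.record_stride == 0 or gen == n_generations:
            record(gen)
            if (
                stop_on_convergence
                and epoch_idx == E - 1
                and np.all(converged_at >= 0)
            ):
                break
        elif plain and stop_on_convergence and epoch_idx == E - 1:
            # cheap convergence probe between records
            if np.all(
                (converged_at >= 0)
                | (fit[:, :N].mean(axis=1) >= config.convergence_fitness)
            ):
                record(gen)
                break

    if records[-1][0] != gen:
        record(gen)
    # non-converged replicates: end state is the last generation
    open_r = converged_at < 0
    if open_r.any():
        last = records[-1]
        end_waist[open_r] = last[4][open_r]
        end_counts[open_r] = last[3][open_r]
        bi = np.argmax(fit[:, :N], axis=1)
        final_nets[open_r] = pop[np.arange(R), bi][open_r]

    gens = np.array([r[0] for r in records])
    return EnsembleResult(
        generations=gens,
        mean_fitness=np.stack([r[1] for r in records], axis=1),
        best_fitness=np.stack([r[2] for r in records], axis=1),
        active_counts=np.stack([r[3] for r in records], axis=1),
        waist=np.stack([r[4] for r in records], axis=1),
        epoch=np.array([r[5] for r in records]),
        converged_at=converged_at,
        end_waist=end_waist,
        end_active_counts=end_counts,
        min_waist=min_waist,
        final_networks=final_nets,
        final_populations=pop[:, :N].copy(),
    )


def run_evolution(
    config: EvolutionConfig,
    schedule: "GoalMatrix | Sequence[tuple[int, GoalMatrix]]",
    network_init: "NetworkInit | LayeredNetwork | np.ndarray",
    n_generations: int | None = None,
    stop_on_convergence: bool | None = None,
) -> Trajectory:
    """Run one evolutionary trajectory under a goal or goal schedule.

    ``schedule`` is a single :class:`GoalMatrix` or a list of
    ``(generation, GoalMatrix)`` switches starting at generation 0.
    ``network_init`` is a :class:`NetworkInit` prescription, a single
    network (cloned into the founding population), or an explicit
    ``(N, L, M, M)`` population array.  Non-convergence by the generation
    cap is reported via ``converged_at = None``, never an exception.
    """
    if isinstance(schedule, GoalMatrix):
        schedule = [(0, schedule)]
    switch_gens = [g for g, _ in schedule]
    if switch_gens[0] != 0:
        raise ValueError("schedule must define a goal from generation 0")
    goals_by_epoch = np.stack([g.entries for _, g in schedule])[:, None]

    if isinstance(network_init, LayeredNetwork):
        init = np.broadcast_to(
            network_init.matrices,
            (1, config.N) + network_init.matrices.shape,
        ).copy()
    elif isinstance(network_init, np.ndarray):
        init = network_init[None] if network_init.ndim == 4 else network_init
    else:
        init = network_init

    if stop_on_convergence is None:
        stop_on_convergence = len(schedule) == 1

    res = evolve_ensemble(
        config,
        goals_by_epoch,
        switch_gens,
        init,
        n_generations=n_generations,
        stop_on_convergence=stop_on_convergence,
    )
    conv = int(res.converged_at[0])
    return Trajectory(
        generations=res.generations,
        mean_fitness=res.mean_fitness[0],
        best_fitness=res.best_fitness[0],
        active_counts=res.active_counts[0],
        waist=res.waist[0],
        epoch=res.epoch,
        converged_at=None if conv < 0 else conv,
        final_network=LayeredNetwork(res.final_networks[0]),
        final_population=res.final_populations[0],
    )


def expand_network(
    net: "LayeredNetwork | np.ndarray",
    new_M: int,
    pad_scale: float,
    rng: np.random.Generator,
) -> LayeredNetwork:
    """Embed each layer in the top-left block of a larger near-zero matrix.

    Models the network-side response to goal expansion: new rows/columns
    are filled with i.i.d. uniform(0, pad_scale) links, so new nodes start
    with near-zero intensity and existing links are preserved exactly.
    """
    if pad_scale <= 0:
        raise ValueError("pad_scale must be positive")
    stack = net.matrices if isinstance(net, LayeredNetwork) else np.asarray(net, float)
    L, M, _ = stack.shape
    if new_M <= M:
        raise ValueError(f"new_M must exceed M={M}, got {new_M}")
    out = rng.uniform(0.0, pad_scale, (L, new_M, new_M))
    out[:, :M, :M] = stack
    return LayeredNetwork(out)


def instantaneous_min_waist(traj: "Trajectory | np.ndarray") -> int:
    """Narrowest waist the lineage passed through during the run."""
    waists = traj.waist if isinstance(traj, Trajectory) else np.asarray(traj)
    if waists.size == 0:
        raise ValueError("empty trajectory")
    return int(np.min(waists))
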
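"""Synthesis of goal (target in-out relation) matrices.

A goal matrix ``G`` is the ideal input-output map an evolving layered
network is selected to approximate.  Its three controlled statistics —
dimension ``M``, rank ``r`` and Frobenius norm — are the knobs the whole
study turns: rank deficiency models redundant biological demands, the
norm sets the gap ``||G||_F >> A0`` that drives bow-tie formation.

Goals are built as sums of ``r`` outer products of strictly positive
random vectors, so every entry is nonnegative and a nonnegative network
(a product of nonnegative link matrices) can reach fitness zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "GoalMatrix",
    "ScheduleSpec",
    "generate_goal",
    "normalize_variance_norm",
    "expand_goal",
    "goal_schedule",
    "save_goal",
    "load_goal",
]

#: relative singular-value cutoff for the numerical rank
RANK_TOL = 1e-9

#: offset added to uniform(0,1) generator components so they are bounded
#: away from zero (keeps outer products strictly positive)
_GEN_EPS = 1e-2


def numerical_rank(matrix: np.ndarray, tol: float = RANK_TOL) -> int:
    """Count singular values above ``tol`` times the largest one."""
    sv = np.linalg.svd(np.asarray(matrix, dtype=float), compute_uv=False)
    if sv.size == 0 or sv[0] == 0.0:
        return 0
    return int(np.sum(sv > tol * sv[0]))


@dataclass(frozen=True)
class GoalMatrix:
    """A target in-out matrix with its measured structural metadata.

    Parameters
    ----------
    entries:
        The ``M x M`` matrix itself.
    rank:
        Numerical rank (singular values above ``RANK_TOL`` relative).
    frob_norm:
        Frobenius norm of ``entries``.
    generators:
        Optional ``(U, V)`` pair with ``entries = U @ V.T``; kept for
        rank-1 goals so they can later be expanded by extending the
        generating vectors.
    """

    entries: np.ndarray
    rank: int
    frob_norm: float
    generators: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError(f"goal entries must be a square matrix, got {e.shape}")
        object.__setattr__(self, "entries", e)

    @property
    def M(self) -> int:
        return self.entries.shape[0]

    def with_measured_metadata(self) -> "GoalMatrix":
        """Return a copy whose rank and norm are re-measured from entries."""
        return GoalMatrix(
            entries=self.entries,
            rank=numerical_rank(self.entries),
            frob_norm=float(np.linalg.norm(self.entries)),
            generators=self.generators,
        )


def generate_goal(
    M: int,
    rank: int,
    norm: float,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> GoalMatrix:
    """Draw a random nonnegative ``M x M`` goal of exact rank and norm.

    The matrix is a sum of ``rank`` outer products ``u_k v_k^T`` of
    vectors with components uniform(0,1) + eps, rescaled to the requested
    Frobenius norm.  Rank collapse (a measure-zero event) triggers a
    redraw; the declared rank is always verified by SVD.
    """
    if not 1 <= rank <= M:
        raise ValueError(f"rank must satisfy 1 <= rank <= M={M}, got {rank}")
    if norm <= 0:
        raise ValueError(f"norm must be positive, got {norm}")

    for _ in range(max_tries):
        U = rng.random((M, rank)) + _GEN_EPS
        V = rng.random((M, rank)) + _GEN_EPS
        G = U @ V.T
        if numerical_rank(G) == rank:
            break
    else:  # pragma: no cover - probability ~0
        raise RuntimeError("failed to draw a goal of the requested rank")

    scale = norm / float(np.linalg.norm(G))
    U = U * scale
    return GoalMatrix(
        entries=U @ V.T,
        rank=rank,
        frob_norm=norm,
        generators=(U, V),
    )


def normalize_variance_norm(G: GoalMatrix, D: float) -> GoalMatrix:
    """Standardize goal elements and shift to a prescribed squared norm.

    Each element is centred and scaled to unit population variance, then
    shifted by ``sqrt(D/N^2 - 1)`` so that the squared Frobenius norm of
    the result is exactly ``D``.  This removes the rank-dependent bias in
    element variance (a rank-1 goal has fewer independent elements and
    hence a systematically smaller spread than a full-rank one).

    The shift adds a rank-one component, so the output rank is re-measured
    rather than inherited.
    """
    N = G.M
    if D < N * N:
        raise ValueError(f"D must be >= N^2 = {N * N} for a real shift, got {D}")
    mean = float(G.entries.mean())
    var = float(G.entries.var())  # population variance over all N^2 elements
    if var <= 1e-30:
        raise ValueError("goal matrix is constant; variance normalization undefined")
    Z = (G.entries - mean) / np.sqrt(var) + np.sqrt(D / N**2 - 1.0)
    return GoalMatrix(
        entries=Z,
        rank=numerical_rank(Z),
        frob_norm=float(np.linalg.norm(Z)),
        generators=None,
    )


def _rank1_generators(G: GoalMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Recover rank-1 generating vectors, from metadata or by SVD."""
    if G.generators is not None:
        U, V = G.generators
        return U[:, 0].copy(), V[:, 0].copy()
    u, s, vt = np.linalg.svd(G.entries)
    # a nonnegative rank-1 matrix admits nonnegative singular vectors
    return np.abs(u[:, 0]) * np.sqrt(s[0]), np.abs(vt[0]) * np.sqrt(s[0])


def expand_goal(
    G: GoalMatrix,
    new_M: int,
    rng: np.random.Generator,
    u_ext: np.ndarray | None = None,
    v_ext: np.ndarray | None = None,
) -> GoalMatrix:
    """Grow a rank-1 goal to ``new_M`` inputs/outputs, preserving its block.

    Models gene duplication / de-novo addition of receptors and targets:
    the generating outer-product vectors are extended with positive random
    components (scaled to the mean magnitude of the existing ones), so the
    upper-left ``M x M`` block is unchanged and the rank stays 1 while the
    norm grows.  ``u_ext``/``v_ext`` override the random extensions.
    """
    if new_M <= G.M:
        raise ValueError(f"new_M must exceed M={G.M}, got {new_M}")
    if G.rank != 1:
        raise ValueError("expansion is defined for rank-1 goals")
    u, v = _rank1_generators(G)
    n_extra = new_M - G.M
    if u_ext is None:
        u_ext = (rng.random(n_extra) + _GEN_EPS) * float(np.mean(u))
    if v_ext is None:
        v_ext = (rng.random(n_extra) + _GEN_EPS) * float(np.mean(v))
    u_new = np.concatenate([u, np.asarray(u_ext, dtype=float)])
    v_new = np.concatenate([v, np.asarray(v_ext, dtype=float)])
    entries = np.outer(u_new, v_new)
    entries[: G.M, : G.M] = G.entries  # exact block preservation
    return GoalMatrix(
        entries=entries,
        rank=numerical_rank(entries),
        frob_norm=float(np.linalg.norm(entries)),
        generators=(u_new[:, None], v_new[:, None]),
    )


@dataclass(frozen=True)
class ScheduleSpec:
    """Description of a sequence of goal switches during evolution.

    ``ranks`` is either a single int (all epochs) or one rank per epoch.
    Dimension and requested norm are held fixed across epochs; with
    ``variance_normalize`` each goal additionally passes through
    :func:`normalize_variance_norm` with ``D = norm**2``.
    """

    period: int
    n_epochs: int
    M: int
    ranks: int | Sequence[int]
    norm: float = 60.0
    variance_normalize: bool = False
    start_generation: int = 0

    def rank_of_epoch(self, epoch: int) -> int:
        if isinstance(self.ranks, int):
            return self.ranks
        return int(self.ranks[epoch])


def goal_schedule(spec: ScheduleSpec, seed: int) -> list[tuple[int, GoalMatrix]]:
    """Materialize a schedule as ``[(generation, GoalMatrix), ...]``.

    Epoch ``k`` starts at ``start_generation + k * period`` and its goal
    is drawn from an independent child stream seeded by ``(seed, k)``, so
    any epoch is reproducible on its own.
    """
    if spec.period <= 0:
        raise ValueError("schedule period must be positive")
    if spec.n_epochs < 1:
        raise ValueError("schedule needs at least one epoch")
    if not isinstance(spec.ranks, int) and len(spec.ranks) != spec.n_epochs:
        raise ValueError("ranks sequence length must equal n_epochs")

    out: list[tuple[int, GoalMatrix]] = []
    for k in range(spec.n_epochs):
        gen = spec.start_generation + k * spec.period
        child = np.random.default_rng([int(seed), k])
        goal = generate_goal(spec.M, spec.rank_of_epoch(k), spec.norm, child)
        if spec.variance_normalize:
            goal = normalize_variance_norm(goal, spec.norm**2)
        out.append((gen, goal))
    if any(out[i][0] >= out[i + 1][0] for i in range(len(out) - 1)):
        raise ValueError("schedule generation indices must be strictly increasing")
    return out


def save_goal(goal: GoalMatrix, path: str | Path, seed: int | None = None) -> None:
    """Write entries as TSV plus a JSON sidecar with the metadata."""
    path = Path(path)
    np.savetxt(path, goal.entries, delimiter="\t")
    sidecar = {"M": goal.M, "rank": goal.rank, "frob_norm": goal.frob_norm, "seed": seed}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_goal(path: str | Path) -> GoalMatrix:
    entries = np.loadtxt(Path(path), delimiter="\t")
    return GoalMatrix(
        entries=entries,
        rank=numerical_rank(entries),
        frob_norm=float(np.linalg.norm(entries)),
    )
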
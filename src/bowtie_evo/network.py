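"""Layered linear networks, their fitness and bow-tie statistics.

A network with ``L + 1`` node layers of ``M`` nodes each is encoded by a
stack of nonnegative ``M x M`` link matrices ``A^(1)..A^(L)``; the
composed in-out matrix is ``A = A^(L) ... A^(1)`` and fitness against a
goal ``G`` is ``F = -||A - G||_F^2``.  Bow-tie structure is read off the
per-node importance of the middle node layers (layers ``2..L``): a node
is *active* when its importance exceeds a threshold, the *waist* is the
middle layer with the fewest active nodes, and the network is a bow-tie
when the waist is narrower than ``M``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .goals import GoalMatrix

__all__ = [
    "LayeredNetwork",
    "NodeImportanceProfile",
    "WaistReport",
    "DEFAULT_THRESHOLDS",
    "compose",
    "compose_batch",
    "fitness",
    "init_network",
    "delete_node",
    "node_importance",
    "waist_stats",
]

#: default activity cutoffs per importance definition
DEFAULT_THRESHOLDS = {
    "fitness_drop": 1e-3,
    "inout_drop": 1e-3,
    "max_link": 0.05,
}


@dataclass
class LayeredNetwork:
    """Stack of ``L`` nonnegative ``M x M`` link matrices (the genotype).

    ``matrices[l-1]`` holds ``A^(l)``, the links from node layer ``l`` to
    node layer ``l + 1``; entry ``(i, j)`` is the intensity from node
    ``j`` to node ``i``.
    """

    matrices: np.ndarray  # shape (L, M, M)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1] != m.shape[2]:
            raise ValueError(f"expected a (L, M, M) stack, got shape {m.shape}")
        if np.any(m < 0):
            raise ValueError("link intensities must be nonnegative")
        self.matrices = m

    @property
    def L(self) -> int:
        return self.matrices.shape[0]

    @property
    def M(self) -> int:
        return self.matrices.shape[1]

    def copy(self) -> "LayeredNetwork":
        return LayeredNetwork(self.matrices.copy())

    def to_json(self) -> str:
        return json.dumps(
            {"M": self.M, "L": self.L, "matrices": self.matrices.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "LayeredNetwork":
        d = json.loads(text)
        return cls(np.asarray(d["matrices"], dtype=float))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "LayeredNetwork":
        return cls.from_json(Path(path).read_text())


def _as_stack(net: "LayeredNetwork | np.ndarray") -> np.ndarray:
    if isinstance(net, LayeredNetwork):
        return net.matrices
    return np.asarray(net, dtype=float)


def _as_goal_entries(goal: "GoalMatrix | np.ndarray") -> np.ndarray:
    if isinstance(goal, GoalMatrix):
        return goal.entries
    return np.asarray(goal, dtype=float)


def compose(net: "LayeredNetwork | np.ndarray") -> np.ndarray:
    """In-out matrix ``A = A^(L) A^(L-1) ... A^(1)``."""
    stack = _as_stack(net)
    if stack.shape[0] == 0:
        raise ValueError("cannot compose an empty stack")
    out = stack[0]
    for l in range(1, stack.shape[0]):
        out = stack[l] @ out
    return out


def compose_batch(stacks: np.ndarray) -> np.ndarray:
    """Compose a batch of stacks: ``(B, L, M, M) -> (B, M, M)``."""
    out = stacks[:, 0]
    for l in range(1, stacks.shape[1]):
        out = stacks[:, l] @ out
    return out


def fitness(net: "LayeredNetwork | np.ndarray", goal: "GoalMatrix | np.ndarray") -> float:
    """Negative squared Frobenius distance ``-||A - G||_F^2`` (max 0)."""
    A = compose(net)
    G = _as_goal_entries(goal)
    if A.shape != G.shape:
        raise ValueError(f"network output {A.shape} does not match goal {G.shape}")
    diff = A - G
    return float(-np.sum(diff * diff))


def init_network(M: int, L: int, A0: float, rng: np.random.Generator) -> LayeredNetwork:
    """Random positive network rescaled so ``||compose(net)||_F = A0``.

    Entries are i.i.d. uniform(0,1); every layer is multiplied by the
    common factor ``(A0 / ||A_raw||_F)**(1/L)`` so the composed norm — the
    initial link intensity ``A0`` of the study — is met exactly.
    """
    if A0 <= 0:
        raise ValueError(f"A0 must be positive, got {A0}")
    raw = rng.random((L, M, M))
    norm = float(np.linalg.norm(compose(raw)))
    return LayeredNetwork(raw * (A0 / norm) ** (1.0 / L))


def delete_node(
    net: LayeredNetwork, layer: int, node: int
) -> LayeredNetwork:
    """Copy of ``net`` with middle node ``node`` of node layer ``layer`` removed.

    Removal zeroes row ``node`` of ``A^(layer-1)`` (all its inputs) and
    column ``node`` of ``A^(layer)`` (all its outputs).  ``layer`` is the
    1-based node-layer index and must be a middle layer, ``2 <= layer <= L``;
    ``node`` is 0-based.
    """
    if not 2 <= layer <= net.L:
        raise ValueError(
            f"only middle node layers 2..{net.L} can be deleted, got {layer}"
        )
    if not 0 <= node < net.M:
        raise ValueError(f"node index out of range: {node}")
    out = net.copy()
    out.matrices[layer - 2, node, :] = 0.0
    out.matrices[layer - 1, :, node] = 0.0
    return out


def _deleted_composes(stack: np.ndarray) -> np.ndarray:
    """Composed matrices for every single middle-node deletion.

    Returns shape ``(L - 1, M, M, M)``: axis 0 indexes the middle node
    layer (layers ``2..L``), axis 1 the deleted node.
    """
    L, M, _ = stack.shape
    stacks = np.broadcast_to(stack, (L - 1, M, L, M, M)).copy()
    for li in range(L - 1):
        for i in range(M):
            stacks[li, i, li, i, :] = 0.0
            stacks[li, i, li + 1, :, i] = 0.0
    return compose_batch(stacks.reshape((L - 1) * M, L, M, M)).reshape(L - 1, M, M, M)


@dataclass
class NodeImportanceProfile:
    """Per-(middle layer, node) importance fractions ``P_i^l``.

    ``values[k, i]`` is the importance of node ``i`` in node layer
    ``layers[k]``; within each layer the values sum to 1 unless the
    layer is perfectly neutral (all raw scores zero), in which case the
    whole row is 0 and every node is reported inactive.
    """

    values: np.ndarray  # (L - 1, M)
    definition: str
    threshold: float
    layers: list[int] = field(default_factory=list)

    def to_table(self):
        """Tidy (layer, node, P, active) table as a pandas DataFrame."""
        import pandas as pd

        rows = []
        for k, layer in enumerate(self.layers):
            for i in range(self.values.shape[1]):
                p = float(self.values[k, i])
                rows.append((layer, i, p, p > self.threshold))
        return pd.DataFrame(rows, columns=["layer", "node", "P", "active"])


def _normalize_rows(raw: np.ndarray) -> np.ndarray:
    totals = raw.sum(axis=1, keepdims=True)
    out = np.zeros_like(raw)
    nz = totals[:, 0] > 0
    out[nz] = raw[nz] / totals[nz]
    return out


def node_importance(
    net: "LayeredNetwork | np.ndarray",
    goal: "GoalMatrix | np.ndarray",
    definition: str = "fitness_drop",
    threshold: float | None = None,
) -> NodeImportanceProfile:
    """Importance ``P_i^l`` of every middle-layer node, by one of three rules.

    ``fitness_drop``
        Relative absolute fitness decrease on deleting the node.
    ``inout_drop``
        Relative squared Frobenius norm of the change in the composed
        in-out matrix on deleting the node.
    ``max_link``
        Relative strength of the node's single largest input or output
        link.
    """
    stack = _as_stack(net)
    L, M, _ = stack.shape
    if L < 2:
        raise ValueError("bow-tie analysis needs at least one middle node layer")
    if definition not in DEFAULT_THRESHOLDS:
        raise ValueError(f"unknown importance definition: {definition!r}")
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS[definition]
    G = _as_goal_entries(goal)

    if definition == "max_link":
        raw = np.empty((L - 1, M))
        for k in range(L - 1):
            # inputs: rows of A^(layer-1); outputs: columns of A^(layer)
            raw[k] = np.maximum(stack[k].max(axis=1), stack[k + 1].max(axis=0))
    else:
        A_full = compose(stack)
        A_del = _deleted_composes(stack)  # (L-1, M, M, M)
        if definition == "fitness_drop":
            F_full = -np.sum((A_full - G) ** 2)
            F_del = -np.sum((A_del - G) ** 2, axis=(2, 3))
            raw = np.abs(F_del - F_full)
        else:  # inout_drop
            raw = np.sum((A_full - A_del) ** 2, axis=(2, 3))

    return NodeImportanceProfile(
        values=_normalize_rows(raw),
        definition=definition,
        threshold=float(threshold),
        layers=list(range(2, L + 1)),
    )


@dataclass
class WaistReport:
    """Active-node counts of the middle layers and the resulting waist."""

    active_counts: np.ndarray  # per middle layer, aligned with `layers`
    layers: list[int]
    waist_layer: int
    waist_size: int
    is_bowtie: bool
    M: int

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"layer": self.layers, "active": self.active_counts}
        )


def waist_stats(
    profile: NodeImportanceProfile, threshold: float | None = None
) -> WaistReport:
    """Count active nodes per middle layer and locate the waist.

    A node is active when ``P_i^l > threshold``.  The waist is the middle
    layer with the fewest active nodes (ties broken toward the lowest
    layer index); the network is a bow-tie when the waist is below ``M``.
    """
    if threshold is None:
        threshold = profile.threshold
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    M = profile.values.shape[1]
    counts = (profile.values > threshold).sum(axis=1)
    k = int(np.argmin(counts))  # argmin takes the first minimum: lowest layer
    return WaistReport(
        active_counts=counts,
        layers=list(profile.layers),
        waist_layer=profile.layers[k],
        waist_size=int(counts[k]),
        is_bowtie=bool(counts[k] < M),
        M=M,
    )
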
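"""Tanh-activated layered networks evolving on a digit-classification task.

The nonlinear variant replaces the linear in-out map by a 5-layer
network ``u = f(A4 f(A3 f(A2 f(A1 v))))`` with activation
``f(x) = (1 + tanh(x)) / 2``, a 64-pixel (8x8) image input and a 6-bit
group target.  Weights are signed; the GA mutation multiplier is drawn
from N(1, 0.5) *without* resampling negative draws, so links can flip
sign.  Initial weights are uniform(-1, 1), rescaled so the Frobenius
norm of the composed product ``A4 A3 A2 A1`` equals ``A0``.

The bundled synthetic generator draws noisy, jittered 8x8 glyphs for
the digits 2/4/6/8 so no dataset download is needed; the scikit-learn
packaged digits can be substituted where available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .evolution import EvolutionConfig, _distinct_indices, _draw_xi, _tournament_indices

__all__ = [
    "NonlinearNetwork",
    "DigitDataset",
    "NonlinearTrajectory",
    "DEFAULT_GROUP_MAP",
    "activation",
    "forward",
    "make_digit_dataset",
    "classification_fitness",
    "init_nonlinear",
    "evolve_nonlinear",
    "evolve_nonlinear_ensemble",
    "default_nonlinear_config",
]

N_PIXELS = 64
N_OUT = 6

#: redundant class -> 6-group encoding: four digit classes mapped onto six
#: groups, with two of the classes each activating two groups
DEFAULT_GROUP_MAP: Mapping[int, tuple[int, ...]] = {
    2: (1, 0, 0, 0, 0, 0),
    4: (0, 1, 0, 0, 0, 0),
    6: (0, 0, 1, 1, 0, 0),
    8: (0, 0, 0, 0, 1, 1),
}

# 8x8 glyph templates for the four digit classes (row strings, 1 = ink)
_GLYPHS = {
    2: (
        "00111100",
        "01000010",
        "00000010",
        "00000100",
        "00011000",
        "00100000",
        "01000000",
        "01111110",
    ),
    4: (
        "00001100",
        "00010100",
        "00100100",
        "01000100",
        "01111110",
        "00000100",
        "00000100",
        "00000100",
    ),
    6: (
        "00011100",
        "00100000",
        "01000000",
        "01011100",
        "01100010",
        "01000010",
        "01000010",
        "00111100",
    ),
    8: (
        "00111100",
        "01000010",
        "01000010",
        "00111100",
        "01000010",
        "01000010",
        "01000010",
        "00111100",
    ),
}


def activation(x: np.ndarray) -> np.ndarray:
    """Elementwise ``f(x) = (1 + tanh(x)) / 2``, mapping into (0, 1)."""
    return 0.5 * (1.0 + np.tanh(x))


@dataclass
class NonlinearNetwork:
    """Signed weight stack: A1 of shape (6, 64), A2..A4 of shape (6, 6)."""

    matrices: list[np.ndarray]

    def __post_init__(self) -> None:
        mats = [np.asarray(m, dtype=float) for m in self.matrices]
        if len(mats) != 4 or mats[0].shape != (N_OUT, N_PIXELS) or any(
            m.shape != (N_OUT, N_OUT) for m in mats[1:]
        ):
            raise ValueError(
                "expected matrices of shapes (6,64), (6,6), (6,6), (6,6)"
            )
        self.matrices = mats

    def copy(self) -> "NonlinearNetwork":
        return NonlinearNetwork([m.copy() for m in self.matrices])


def forward(net: NonlinearNetwork, v: np.ndarray) -> np.ndarray:
    """Network output for one 64-vector or a (64, n) image batch."""
    v = np.asarray(v, dtype=float)
    squeeze = v.ndim == 1
    h = v[:, None] if squeeze else v
    if h.shape[0] != N_PIXELS:
        raise ValueError(f"input must have {N_PIXELS} rows, got {h.shape}")
    for m in net.matrices:
        h = activation(m @ h)
    return h[:, 0] if squeeze else h


@dataclass
class DigitDataset:
    """Flattened 8x8 digit images with class labels and 6-bit group targets."""

    images: np.ndarray  # (n, 64), values in [0, 1]
    class_labels: np.ndarray  # (n,), values in {2, 4, 6, 8}
    group_targets: np.ndarray  # (n, 6), binary

    def __len__(self) -> int:
        return self.images.shape[0]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.images, delimiter="\t")
        sidecar = {
            "class_labels": self.class_labels.tolist(),
            "group_targets": self.group_targets.tolist(),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "DigitDataset":
        path = Path(path)
        images = np.loadtxt(path, delimiter="\t")
        d = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            images=images,
            class_labels=np.asarray(d["class_labels"]),
            group_targets=np.asarray(d["group_targets"], dtype=float),
        )


def _glyph_array(digit: int) -> np.ndarray:
    return np.array([[int(c) for c in row] for row in _GLYPHS[digit]], dtype=float)


def make_digit_dataset(
    n: int,
    rng: np.random.Generator,
    source: str = "synthetic",
    noise: float = 0.1,
    max_shift: int = 1,
    group_map: Mapping[int, Sequence[int]] = DEFAULT_GROUP_MAP,
) -> DigitDataset:
    """Build the 4-class (2/4/6/8) image set with redundant 6-group targets.

    ``synthetic`` draws the bundled glyph templates with a random integer
    shift of up to ``max_shift`` pixels and additive Gaussian pixel noise
    (clipped to [0, 1]).  ``packaged`` slices the scikit-learn bundled
    digits instead (no noise model applied).
    """
    if n < 1:
        raise ValueError("need at least one image")
    classes = sorted(group_map)
    if source == "synthetic":
        labels = np.array([classes[i % len(classes)] for i in range(n)])
        images = np.empty((n, N_PIXELS))
        for i, lab in enumerate(labels):
            img = _glyph_array(int(lab))
            if max_shift > 0:
                dy, dx = rng.integers(-max_shift, max_shift + 1, 2)
                img = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
                if dy > 0:
                    img[:dy] = 0
                elif dy < 0:
                    img[dy:] = 0
                if dx > 0:
                    img[:, :dx] = 0
                elif dx < 0:
                    img[:, dx:] = 0
            if noise > 0:
                img = img + rng.normal(0.0, noise, img.shape)
            images[i] = np.clip(img, 0.0, 1.0).ravel()
    elif source == "packaged":
        from sklearn.datasets import load_digits

        data = load_digits()
        mask = np.isin(data.target, classes)
        x, y = data.data[mask] / 16.0, data.target[mask]
        idx = rng.choice(x.shape[0], size=n, replace=n > x.shape[0])
        images, labels = x[idx], y[idx]
    else:
        raise ValueError(f"unknown dataset source: {source!r}")
    targets = np.array([group_map[int(lab)] for lab in labels], dtype=float)
    return DigitDataset(images=images, class_labels=labels, group_targets=targets)


def classification_fitness(net: NonlinearNetwork, data: DigitDataset) -> float:
    """Squared-error score ``F = -sum_images ||u - target||^2`` (max 0)."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    u = forward(net, data.images.T)  # (6, n)
    return float(-np.sum((u - data.group_targets.T) ** 2))


def init_nonlinear(A0: float, rng: np.random.Generator) -> NonlinearNetwork:
    """Uniform(-1, 1) weights rescaled so ``||A4 A3 A2 A1||_F = A0``.

    A common positive factor ``(A0 / ||A_raw||_F)**(1/4)`` multiplies all
    four layers.
    """
    if A0 <= 0:
        raise ValueError("A0 must be positive")
    mats = [rng.uniform(-1, 1, (N_OUT, N_PIXELS))] + [
        rng.uniform(-1, 1, (N_OUT, N_OUT)) for _ in range(3)
    ]
    prod = mats[3] @ mats[2] @ mats[1] @ mats[0]
    s = (A0 / np.linalg.norm(prod)) ** 0.25
    return NonlinearNetwork([m * s for m in mats])


def default_nonlinear_config(**overrides) -> EvolutionConfig:
    """GA settings for the nonlinear task: xi ~ N(1, 0.5), sign flips allowed."""
    base = dict(
        xi_var=0.5,
        xi_resample_nonpositive=False,
        record_stride=25,
        max_generations=2000,
    )
    base.update(overrides)
    return EvolutionConfig(**base)


@dataclass
class NonlinearTrajectory:
    """Recorded statistics of one (or a batch of) nonlinear GA runs."""

    generations: np.ndarray
    mean_fitness: np.ndarray  # (R, n_rec)
    best_fitness: np.ndarray
    active_counts: np.ndarray  # (R, n_rec, 3): hidden node layers 2..4
    waist: np.ndarray  # (R, n_rec)
    end_waist: np.ndarray  # (R,)
    min_waist: np.ndarray  # (R,)
    final_networks: list[NonlinearNetwork]


_SHAPES = [(N_OUT, N_PIXELS), (N_OUT, N_OUT), (N_OUT, N_OUT), (N_OUT, N_OUT)]
_SIZES = [s[0] * s[1] for s in _SHAPES]
_OFFSETS = np.cumsum([0] + _SIZES)  # flat-index boundaries per layer
_TOTAL = int(_OFFSETS[-1])


def _batch_forward(mats: list[np.ndarray], X: np.ndarray) -> np.ndarray:
    """Outputs for a batch of networks: mats[l] is (B, *shape), X is (64, n)."""
    h = activation(np.einsum("bij,jn->bin", mats[0], X))
    for l in range(1, 4):
        h = activation(mats[l] @ h)
    return h  # (B, 6, n)


def _batch_class_fitness(
    mats: list[np.ndarray], X: np.ndarray, T: np.ndarray
) -> np.ndarray:
    u = _batch_forward(mats, X)
    d = u - T
    return -np.einsum("bin,bin->b", d, d)


def _batch_hidden_waists(
    mats: list[np.ndarray], X: np.ndarray, T: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Deletion-based active counts for hidden node layers 2..4.

    Deleting hidden node ``i`` of node layer ``l`` zeroes row ``i`` of
    ``A^(l-1)`` and column ``i`` of ``A^(l)``; importance is the relative
    absolute drop in classification fitness.
    """
    B = mats[0].shape[0]
    F_full = _batch_class_fitness(mats, X, T)
    raw = np.empty((B, 3, N_OUT))
    for k in range(3):  # node layer 2 + k
        for i in range(N_OUT):
            dele = [m.copy() if l in (k, k + 1) else m for l, m in enumerate(mats)]
            dele[k][:, i, :] = 0.0
            dele[k + 1][:, :, i] = 0.0
            raw[:, k, i] = np.abs(_batch_class_fitness(dele, X, T) - F_full)
    totals = raw.sum(axis=2, keepdims=True)
    P = np.divide(raw, totals, out=np.zeros_like(raw), where=totals > 0)
    counts = (P > threshold).sum(axis=2)
    return counts, counts.min(axis=1)


def evolve_nonlinear_ensemble(
    config: EvolutionConfig,
    A0: float,
    data: DigitDataset,
    replicates: int = 1,
    n_generations: int | None = None,
    rng: np.random.Generator | None = None,
) -> NonlinearTrajectory:
    """Evolve ``replicates`` independent populations on the digit task.

    Same generation structure as the linear engine (duplicate to 2N,
    single-link multiplicative mutation of 20% of the pool, tournament or
    elite selection), with signed weights and heterogeneous layer shapes.
    Only mutated individuals are re-evaluated each generation.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if n_generations is None:
        n_generations = config.max_generations
    R = replicates
    N = config.N
    P = 2 * N
    B = R * P
    X = data.images.T  # (64, n)
    T = data.group_targets.T[None]  # (1, 6, n), broadcast over batch

    # population tensors, replicate-major: index r * P + p
    mats = [np.empty((B,) + s) for s in _SHAPES]
    for r in range(R):
        for n_i in range(N):
            net = init_nonlinear(A0, rng)
            for l in range(4):
                mats[l][r * P + n_i] = net.matrices[l]
    live = (np.arange(B).reshape(R, P)[:, :N]).ravel()  # current individuals
    fit = np.full(B, -np.inf)
    fit[live] = _batch_class_fitness([m[live] for m in mats], X, T)
    fit = fit.reshape(R, P)
    for l in range(4):
        mats[l] = mats[l].reshape((R, P) + _SHAPES[l])

    k = int(config.mutate_fraction * P)
    pool, off = (P, 0) if config.mutate_pool == "all" else (N, N)
    rr = np.arange(R)[:, None]
    threshold = config.threshold

    records: list[tuple] = []
    min_waist = np.full(R, N_OUT, dtype=int)

    def record(gen: int) -> None:
        bi = np.argmax(fit[:, :N], axis=1)
        best = [m[np.arange(R), bi] for m in mats]
        counts, waist = _batch_hidden_waists(best, X, T[0], threshold)
        records.append(
            (gen, fit[:, :N].mean(axis=1), fit[np.arange(R), bi], counts, waist)
        )
        np.minimum(min_waist, waist, out=min_waist)

    record(0)
    for gen in range(1, n_generations + 1):
        for l in range(4):
            mats[l][:, N:] = mats[l][:, :N]
        fit[:, N:] = fit[:, :N]
        if k > 0:
            idx = _distinct_indices(rng, R, pool, k, off)
            links = rng.integers(0, _TOTAL, (R, k))
            xi = _draw_xi(
                rng,
                (R, k),
                config.xi_mean,
                config.xi_var,
                config.xi_resample_nonpositive,
            )
            for l in range(4):
                in_layer = (links >= _OFFSETS[l]) & (links < _OFFSETS[l + 1])
                if not in_layer.any():
                    continue
                r_i, k_i = np.nonzero(in_layer)
                flat = mats[l].reshape(R, P, -1)
                flat[r_i, idx[r_i, k_i], links[r_i, k_i] - _OFFSETS[l]] *= xi[
                    r_i, k_i
                ]
            sub = [m[rr, idx].reshape((R * k,) + s) for m, s in zip(mats, _SHAPES)]
            fit[rr, idx] = _batch_class_fitness(sub, X, T).reshape(R, k)
        if config.selection == "elite":
            sel = np.argpartition(fit, P - N - 1, axis=1)[:, P - N :]
        else:
            sel = _tournament_indices(fit, N, config.tournament_size, rng)
        for l in range(4):
            mats[l][:, :N] = mats[l][rr, sel]
        fit[:, :N] = np.take_along_axis(fit, sel, axis=1)
        if gen % config.record_stride == 0 or gen == n_generations:
            record(gen)

    bi = np.argmax(fit[:, :N], axis=1)
    finals = [
        NonlinearNetwork([mats[l][r, bi[r]].copy() for l in range(4)])
        for r in range(R)
    ]
    return NonlinearTrajectory(
        generations=np.array([r[0] for r in records]),
        mean_fitness=np.stack([r[1] for r in records], axis=1),
        best_fitness=np.stack([r[2] for r in records], axis=1),
        active_counts=np.stack([r[3] for r in records], axis=1),
        waist=np.stack([r[4] for r in records], axis=1),
        end_waist=records[-1][4],
        min_waist=min_waist,
        final_networks=finals,
    )


def evolve_nonlinear(
    config: EvolutionConfig,
    A0: float,
    data: DigitDataset,
    n_generations: int | None = None,
) -> NonlinearTrajectory:
    """Single-run convenience wrapper around the ensemble kernel."""
    return evolve_nonlinear_ensemble(
        config, A0, data, replicates=1, n_generations=n_generations
    )
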
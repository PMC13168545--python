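"""Full-batch gradient-descent training of shallow and deep linear networks.

The trainer exists to check the analytic mode dynamics against an
actual network: weights start as small i.i.d. Gaussians, every epoch is
one exact gradient step on the summed quadratic loss
``L = sum_i 0.5 ||Y_i - W_D ... W_1 X_i||^2``, and the composed map is
projected onto the dataset's singular basis after each recorded epoch.

The per-step continuous-time increment implied by a learning rate
``eta`` on the summed loss is ``eta * P`` (P items), so a trace indexed
by epoch overlays the analytic trajectories with ``tau = 1/(eta * P)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import sqrt

import numpy as np

from .dataset import Dataset, ModeDecomposition, correlation_matrices, dataset_modes

__all__ = [
    "LinearNetwork",
    "TrainConfig",
    "TrainTrace",
    "init_network",
    "balanced_init",
    "calibrate_sigma0",
    "default_learning_rate",
    "train",
    "effective_spectrum",
    "group_spectrum",
    "initial_mode_strengths",
    "block_norms",
    "xgamma_yomega_norm_theory",
    "DivergenceError",
]

BLOCK_NAMES = ("XO->YO", "XO->YG", "XG->YO", "XG->YG")


class DivergenceError(RuntimeError):
    """Raised when the loss increases beyond tolerance during training."""


@dataclass
class LinearNetwork:
    """An ordered stack of weight matrices (layer 1 first)."""

    weights: list[np.ndarray]

    @property
    def depth(self) -> int:
        return len(self.weights)

    @property
    def in_dim(self) -> int:
        return self.weights[0].shape[1]

    @property
    def out_dim(self) -> int:
        return self.weights[-1].shape[0]

    def composed(self) -> np.ndarray:
        """The end-to-end linear map W_D ... W_1."""
        M = self.weights[0]
        for W in self.weights[1:]:
            M = W @ M
        return M

    def copy(self) -> "LinearNetwork":
        return LinearNetwork([W.copy() for W in self.weights])


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float
    epochs: int
    sigma0: float
    seed: int = 0
    record_every: int | None = None  # default: 1 if epochs <= 5000 else 10

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be nonnegative")
        if self.record_every is not None and self.record_every < 1:
            raise ValueError("record_every must be >= 1")

    @property
    def cadence(self) -> int:
        if self.record_every is not None:
            return self.record_every
        return 1 if self.epochs <= 5000 else 10


@dataclass
class TrainTrace:
    """Per-recorded-epoch history of one training run."""

    epochs: np.ndarray                 # (T,)
    loss: np.ndarray                   # (T,)
    spectrum: np.ndarray               # (T, rank) group-wise effective singular values
    norms: np.ndarray                  # (T, 4) Frobenius norms, order BLOCK_NAMES
    final: LinearNetwork
    modes: ModeDecomposition
    pi0: np.ndarray                    # implied initial strengths per mode
    tau: float                         # epoch-to-analytic-time constant
    block_names: tuple[str, ...] = BLOCK_NAMES


def default_learning_rate(d: Dataset) -> float:
    """Step size keeping the stiffest mode well inside the stable band.

    The discrete shallow update contracts mode alpha by
    ``(1 - eta P delta_alpha)`` per step, so we take
    ``eta = 0.02 / (P * delta1)``; equivalently a rate of ``0.02/delta1``
    on the item-averaged correlations.
    """
    from .dataset import theoretical_spectrum

    spec = theoretical_spectrum(d.params)
    return 0.02 / (d.n_items * spec.delta1)


def calibrate_sigma0(pi0: float, nh: int, depth: int) -> float:
    """Weight scale so a random init has expected mode strength ``pi0``.

    Depth 1 has no hidden layer: the projection of an i.i.d. Gaussian
    map onto a mode has standard deviation ``sigma0``, so we return
    ``pi0`` directly as the scale.  For depth 2 the early-time growth of
    a mode is seeded by the symmetric component ``s0 = (W1 v + W2^T u)/2``
    whose squared norm has mean ``nh * sigma0**2 / 2``; solving for the
    target gives ``sigma0 = sqrt(2 pi0 / nh)``.  Deeper stacks reuse the
    per-layer scale of the depth-2 rule (the worked comparisons train
    depths 1 and 2).
    """
    if pi0 <= 0:
        raise ValueError("pi0 must be positive")
    if depth == 1:
        return pi0
    if nh < 1:
        raise ValueError("nh must be >= 1 for depth >= 2")
    return sqrt(2.0 * pi0 / nh)


def init_network(
    in_dim: int,
    out_dim: int,
    nh: int,
    depth: int,
    sigma0: float,
    seed: int,
) -> LinearNetwork:
    """Small i.i.d. Gaussian initialisation, reproducible from ``seed``."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if in_dim < 1 or out_dim < 1:
        raise ValueError("dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    dims = [in_dim] + [nh] * (depth - 1) + [out_dim]
    weights = [
        rng.normal(0.0, sigma0, size=(dims[i + 1], dims[i]))
        for i in range(depth)
    ]
    return LinearNetwork(weights)


def balanced_init(
    modes: ModeDecomposition,
    nh: int,
    pi0: float,
    seed: int,
    *,
    in_dim: int | None = None,
    out_dim: int | None = None,
) -> LinearNetwork:
    """Depth-2 balanced initialisation with exact mode strength ``pi0``.

    Builds ``W1 = sqrt(pi0) B Vt`` and ``W2 = sqrt(pi0) U B^T`` with a
    seeded random ``nh x rank`` orthonormal ``B``, so the composed map
    is exactly ``pi0`` along every dataset mode and the two layers are
    balanced.  This is the decoupled initialisation whose dynamics the
    sigmoidal closed form describes exactly (up to discretisation); the
    unstructured Gaussian init of :func:`init_network` only approaches
    it statistically.
    """
    if nh < modes.rank:
        raise ValueError(f"nh ({nh}) must be >= the dataset rank ({modes.rank})")
    if pi0 <= 0:
        raise ValueError("pi0 must be positive")
    rng = np.random.default_rng(seed)
    B, _ = np.linalg.qr(rng.normal(size=(nh, modes.rank)))
    W1 = sqrt(pi0) * B @ modes.Vt
    W2 = sqrt(pi0) * modes.U @ B.T
    if in_dim is not None and W1.shape[1] != in_dim:
        raise ValueError("mode basis does not match the requested input dim")
    if out_dim is not None and W2.shape[0] != out_dim:
        raise ValueError("mode basis does not match the requested output dim")
    return LinearNetwork([W1, W2])


def initial_mode_strengths(net: LinearNetwork, modes: ModeDecomposition) -> np.ndarray:
    """Implied initial effective singular value per dataset mode.

    Depth 1: the signed projection ``u^T W v``.  Depth 2: the squared
    norm of the symmetric seed ``(W1 v + W2^T u)/2``, which is the
    coefficient of the ``exp(2 lambda t / tau)`` growth of the mode and
    therefore the ``pi0`` the logistic trajectory starts from.  Within a
    degenerate group the seeds mix, so the eigenvalues of the group's
    seed Gram matrix are reported (descending within the group).  For
    deeper stacks the depth-2 seed of the two outer layers is used as an
    estimate.
    """
    if net.depth == 1:
        M = net.composed()
        return np.einsum("ia,ij,aj->a", modes.U, M, modes.Vt)
    W1, W2 = net.weights[0], net.weights[-1]
    mid = np.eye(W2.shape[1], W1.shape[0])
    if net.depth > 2:
        for W in net.weights[1:-1]:
            mid = mid @ W
    a = W1 @ modes.Vt.T             # nh x rank
    b = (W2 @ mid).T @ modes.U      # nh x rank
    s0 = 0.5 * (a + b)
    out = np.empty(modes.rank)
    for g in modes.groups:
        gram = s0[:, g].T @ s0[:, g]
        out[g] = np.sort(np.linalg.eigvalsh(gram))[::-1]
    return out


def effective_spectrum(net: LinearNetwork | np.ndarray, modes: ModeDecomposition) -> np.ndarray:
    """Per-mode effective singular values of the composed map.

    The map is projected onto the dataset's singular basis,
    ``M_ab = u_a^T W v_b``; for a nondegenerate mode the diagonal entry
    is returned, while for a group of equal singular values the singular
    values of the group's projected block are reported (rotation within
    a degenerate subspace is physically meaningless).
    """
    W = net.composed() if isinstance(net, LinearNetwork) else np.asarray(net)
    M = modes.U.T @ W @ modes.Vt.T
    return group_spectrum(M, modes)


def group_spectrum(M: np.ndarray, modes: ModeDecomposition) -> np.ndarray:
    """Group-wise singular values of a projected map (see effective_spectrum)."""
    out = np.empty(modes.rank)
    for g in modes.groups:
        if len(g) == 1:
            out[g[0]] = M[g[0], g[0]]
        else:
            block = M[np.ix_(g, g)]
            out[g] = np.sort(np.linalg.svd(block, compute_uv=False))[::-1]
    return out


def block_norms(net: LinearNetwork | np.ndarray, d: Dataset) -> dict[str, float]:
    """Frobenius norms of the composed map restricted to the four blocks.

    Keys follow BLOCK_NAMES: input block (compositional XO or
    noncompositional XG) -> output block (YO or YG).
    """
    W = net.composed() if isinstance(net, LinearNetwork) else np.asarray(net)
    rows = {"YO": d.y_comp, "YG": d.y_noncomp}
    cols = {"XO": d.x_comp, "XG": d.x_noncomp}
    return {
        f"{cn}->{rn}": float(np.linalg.norm(W[rows[rn], cols[cn]]))
        for cn, rn in (("XO", "YO"), ("XO", "YG"), ("XG", "YO"), ("XG", "YG"))
    }


def xgamma_yomega_norm_theory(params, pi1: float) -> float:
    """Closed-form Frobenius norm of the XG -> YO block at strength pi1.

    ``sqrt(2**nx * ny * kx * r**2 * pi1**2 / ((kx r**2 + 2**nx)(ky r**2 + 2**nx)))``
    -- the weight the network places on item-specific input features
    when producing the compositional part of the signal.  It decays to
    zero as nx grows: with enough items the network has to rely on the
    compositional input structure.
    """
    from .dataset import DatasetParams

    if not isinstance(params, DatasetParams):
        params = DatasetParams(*params)
    if pi1 < 0:
        raise ValueError("pi1 must be nonnegative")
    P = params.n_items
    num = P * params.ny * params.kx * params.r ** 2 * pi1 ** 2
    den = (params.kx * params.r ** 2 + P) * (params.ky * params.r ** 2 + P)
    return sqrt(num / den)


def train(net: LinearNetwork, d: Dataset, cfg: TrainConfig) -> TrainTrace:
    """Train by full-batch gradient descent on the summed quadratic loss.

    Records loss, group-wise effective spectrum and the four block
    norms every ``cfg.cadence`` epochs (plus epoch 0 and the final
    epoch).  Aborts with :class:`DivergenceError` if the loss rises by
    more than a tiny tolerance between consecutive epochs.
    """
    if net.in_dim != d.X.shape[0] or net.out_dim != d.Y.shape[0]:
        raise ValueError(
            f"network maps {net.in_dim} -> {net.out_dim} but dataset needs "
            f"{d.X.shape[0]} -> {d.Y.shape[0]}"
        )
    modes = dataset_modes(d)
    sigma_x, sigma_yx = correlation_matrices(d)
    P = d.n_items
    eta = cfg.learning_rate
    tau = 1.0 / (eta * P)
    pi0 = initial_mode_strengths(net, modes)

    weights = [W.copy() for W in net.weights]
    sq_target = float(np.sum(d.Y * d.Y))

    def loss_of(Wc: np.ndarray) -> float:
        R = d.Y - Wc @ d.X
        return 0.5 * float(np.sum(R * R))

    rec_epochs, rec_loss, rec_spec, rec_norms = [], [], [], []

    def record(epoch: int, Wc: np.ndarray) -> None:
        rec_epochs.append(epoch)
        rec_loss.append(loss_of(Wc))
        rec_spec.append(group_spectrum(modes.U.T @ Wc @ modes.Vt.T, modes))
        nb = block_norms(Wc, d)
        rec_norms.append([nb[k] for k in BLOCK_NAMES])

    def composed_of(ws) -> np.ndarray:
        M = ws[0]
        for W in ws[1:]:
            M = W @ M
        return M

    Wc = composed_of(weights)
    record(0, Wc)
    prev_loss = rec_loss[0]
    tol = 1e-9 * max(sq_target, 1.0)

    for epoch in range(1, cfg.epochs + 1):
        # gradient of the summed loss: dL/dW_l = -P * (suffix)^T E (prefix)^T
        E = sigma_yx - Wc @ sigma_x  # item-averaged residual correlation
        Dn = len(weights)
        prefixes = [None] * Dn   # product W_{l-1} ... W_1
        suffixes = [None] * Dn   # product W_D ... W_{l+1}
        acc = np.eye(weights[0].shape[1])
        for l in range(Dn):
            prefixes[l] = acc
            acc = weights[l] @ acc
        acc = np.eye(weights[-1].shape[0])
        for l in range(Dn - 1, -1, -1):
            suffixes[l] = acc
            acc = acc @ weights[l]
        new_weights = [
            W + eta * P * (suffixes[l].T @ E @ prefixes[l].T)
            for l, W in enumerate(weights)
        ]
        weights = new_weights
        Wc = composed_of(weights)
        cur = loss_of(Wc)
        if cur > prev_loss + tol:
            raise DivergenceError(
                f"loss increased at epoch {epoch}: {prev_loss:.6g} -> {cur:.6g}; "
                "reduce the learning rate"
            )
        prev_loss = cur
        if epoch % cfg.cadence == 0 or epoch == cfg.epochs:
            record(epoch, Wc)

    return TrainTrace(
        epochs=np.asarray(rec_epochs),
        loss=np.asarray(rec_loss),
        spectrum=np.asarray(rec_spec),
        norms=np.asarray(rec_norms),
        final=LinearNetwork(weights),
        modes=modes,
        pi0=pi0,
        tau=tau,
    )


def trace_to_frame(trace: TrainTrace):
    """TrainTrace as a tidy DataFrame (one row per recorded epoch)."""
    import pandas as pd

    data = {"epoch": trace.epochs, "loss": trace.loss}
    for a in range(trace.spectrum.shape[1]):
        data[f"pi_{a + 1}"] = trace.spectrum[:, a]
    for i, name in enumerate(trace.block_names):
        data[f"norm[{name}]"] = trace.norms[:, i]
    return pd.DataFrame(data)


def save_network(net: LinearNetwork, path, meta: dict | None = None) -> None:
    """Write the layer stack as delimited text with a JSON header."""
    header = {
        "depth": net.depth,
        "shapes": [list(W.shape) for W in net.weights],
        "meta": meta or {},
    }
    flat = np.concatenate([W.ravel() for W in net.weights])
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        for v in flat:
            fh.write(repr(float(v)) + "\n")


def load_network(path) -> LinearNetwork:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("missing JSON header line")
        header = json.loads(first[1:])
        flat = np.loadtxt(fh, ndmin=1)
    weights = []
    pos = 0
    for nr, nc in header["shapes"]:
        weights.append(flat[pos : pos + nr * nc].reshape(nr, nc).copy())
        pos += nr * nc
    return LinearNetwork(weights)
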
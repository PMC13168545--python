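"""Parametric space of compositional/noncompositional datasets.

A dataset in the space is defined by five positive integers
``(nx, ny, kx, ky, r)``:

* ``nx`` -- number of compositional input features.  The compositional
  input block ``XO`` enumerates every +-1 pattern of length ``nx``, so
  the dataset has ``P = 2**nx`` items (meanings).
* ``ny`` -- number of compositional output features (``ny <= nx``);
  the compositional output block ``YO`` is the first ``ny`` rows of
  ``XO``.
* ``kx``, ``ky`` -- number of noncompositional identity blocks on the
  input/output side.  Each block is ``r * I_P``: a unique, item-specific
  feature per meaning/signal.
* ``r`` -- scale of the noncompositional blocks.

Matrices are stored features x items (columns are items).  The whole
spectrum of the item-averaged correlation matrices ``Sigma_x = X X^T/P``
and ``Sigma_yx = Y X^T/P`` is known in closed form: two distinct input
singular values (``delta1``, ``delta2``) and three distinct input-output
singular values (``lambda1 > lambda2 > lambda3``) with asymptotic
network strengths ``pi_i = lambda_i / delta``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import sqrt

import numpy as np

__all__ = [
    "DatasetParams",
    "Dataset",
    "TheoreticalSpectrum",
    "ModeDecomposition",
    "build_dataset",
    "correlation_matrices",
    "theoretical_spectrum",
    "dataset_modes",
    "rcr",
    "count_distinct_columns",
    "numerical_rank",
    "write_dataset_csv",
    "read_dataset_csv",
]

#: singular values below RANK_RTOL * s_max count as zero
RANK_RTOL = 1e-8

#: refuse to materialise datasets with more than this many items
MAX_ITEMS = 2 ** 16


@dataclass(frozen=True)
class DatasetParams:
    """The five integers defining one dataset in the space."""

    nx: int
    ny: int
    kx: int
    ky: int
    r: int

    def __post_init__(self) -> None:
        for name in ("nx", "ny", "kx", "ky", "r"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.ny > self.nx:
            raise ValueError(
                f"ny ({self.ny}) must not exceed nx ({self.nx}): the compositional "
                "output features are a subset of the compositional input features"
            )

    @property
    def n_items(self) -> int:
        return 2 ** self.nx

    def to_dict(self) -> dict:
        return {k: int(getattr(self, k)) for k in ("nx", "ny", "kx", "ky", "r")}


@dataclass(frozen=True)
class Dataset:
    """A realized dataset: input/output matrices plus block bookkeeping.

    ``X`` is ``(nx + kx * P) x P`` and ``Y`` is ``(ny + ky * P) x P``
    with ``P = 2**nx`` items as columns.  ``x_comp``/``y_comp`` are the
    row slices of the compositional blocks; the remaining rows hold the
    stacked ``r * I`` identity blocks.
    """

    params: DatasetParams
    X: np.ndarray
    Y: np.ndarray

    @property
    def n_items(self) -> int:
        return self.X.shape[1]

    @property
    def x_comp(self) -> slice:
        return slice(0, self.params.nx)

    @property
    def x_noncomp(self) -> slice:
        return slice(self.params.nx, self.X.shape[0])

    @property
    def y_comp(self) -> slice:
        return slice(0, self.params.ny)

    @property
    def y_noncomp(self) -> slice:
        return slice(self.params.ny, self.Y.shape[0])

    # convenience views -------------------------------------------------
    @property
    def XO(self) -> np.ndarray:
        return self.X[self.x_comp]

    @property
    def XG(self) -> np.ndarray:
        return self.X[self.x_noncomp]

    @property
    def YO(self) -> np.ndarray:
        return self.Y[self.y_comp]

    @property
    def YG(self) -> np.ndarray:
        return self.Y[self.y_noncomp]


@dataclass(frozen=True)
class TheoreticalSpectrum:
    """Closed-form singular values of one dataset's correlation matrices.

    ``delta1``/``delta2`` are the distinct singular values of the input
    correlation; ``lambda1 > lambda2 > lambda3`` those of the
    input-output correlation; ``pi1``, ``pi2``, ``pi3`` the asymptotic
    effective singular values ``lambda / delta`` (``lambda1`` and
    ``lambda2`` pair with ``delta1``, ``lambda3`` with ``delta2``).
    """

    delta1: float
    delta2: float
    lambda1: float
    lambda2: float
    lambda3: float
    pi1: float
    pi2: float
    pi3: float

    @property
    def lambdas(self) -> tuple[float, float, float]:
        return (self.lambda1, self.lambda2, self.lambda3)

    @property
    def deltas(self) -> tuple[float, float, float]:
        """Input singular value paired with each lambda."""
        return (self.delta1, self.delta1, self.delta2)

    @property
    def pis(self) -> tuple[float, float, float]:
        return (self.pi1, self.pi2, self.pi3)

    def to_dict(self) -> dict:
        return {
            k: float(getattr(self, k))
            for k in (
                "delta1", "delta2",
                "lambda1", "lambda2", "lambda3",
                "pi1", "pi2", "pi3",
            )
        }


def _all_sign_patterns(nx: int) -> np.ndarray:
    """All +-1 patterns of length nx, as an nx x 2**nx matrix.

    Columns are in binary-counting order of the bits, with 0 -> -1 and
    1 -> +1; the most significant bit is row 0.
    """
    P = 2 ** nx
    codes = np.arange(P)
    bits = (codes[None, :] >> np.arange(nx - 1, -1, -1)[:, None]) & 1
    return (2 * bits - 1).astype(float)


def build_dataset(params: DatasetParams | tuple, *, max_items: int = MAX_ITEMS) -> Dataset:
    """Construct the dataset for ``params``.

    Item (column) order is the binary-counting order of the ``nx`` bits
    mapped ``{0 -> -1, 1 -> +1}``.  Raises ``ValueError`` for invalid
    parameters or when ``2**nx`` exceeds ``max_items``.
    """
    if not isinstance(params, DatasetParams):
        params = DatasetParams(*params)
    P = params.n_items
    if P > max_items:
        raise ValueError(
            f"dataset would have 2**{params.nx} = {P} items, above the size "
            f"guard of {max_items}; raise max_items to build it anyway"
        )
    XO = _all_sign_patterns(params.nx)
    eye = np.eye(P)
    X = np.vstack([XO] + [params.r * eye] * params.kx)
    Y = np.vstack([XO[: params.ny]] + [params.r * eye] * params.ky)
    return Dataset(params=params, X=X, Y=Y)


def correlation_matrices(d: Dataset) -> tuple[np.ndarray, np.ndarray]:
    """Item-averaged correlations ``(Sigma_x, Sigma_yx)`` of a dataset."""
    P = d.n_items
    sigma_x = d.X @ d.X.T / P
    sigma_yx = d.Y @ d.X.T / P
    return sigma_x, sigma_yx


def theoretical_spectrum(params: DatasetParams | tuple) -> TheoreticalSpectrum:
    """Closed-form spectrum of the dataset defined by ``params``."""
    if not isinstance(params, DatasetParams):
        params = DatasetParams(*params)
    P = params.n_items
    cx = params.kx * params.r ** 2  # total noncompositional input power
    cy = params.ky * params.r ** 2
    delta1 = (cx + P) / P
    delta2 = cx / P
    lambda1 = sqrt((cx + P) * (cy + P)) / P
    lambda2 = sqrt((cx + P) * cy) / P
    lambda3 = sqrt(cx * cy) / P
    return TheoreticalSpectrum(
        delta1=delta1,
        delta2=delta2,
        lambda1=lambda1,
        lambda2=lambda2,
        lambda3=lambda3,
        pi1=lambda1 / delta1,
        pi2=lambda2 / delta1,
        pi3=lambda3 / delta2,
    )


@dataclass(frozen=True)
class ModeDecomposition:
    """SVD of ``Sigma_yx`` with modes grouped by (near-)equal singular value.

    ``U``/``Vt`` hold the singular vectors of the nonzero modes, signs
    fixed so each right singular vector's largest-magnitude entry is
    positive.  ``groups`` lists index arrays of modes sharing a singular
    value (within tolerance), in descending order; ``deltas`` gives the
    input singular value paired with each mode (the ``Sigma_x`` singular
    value of its right singular vector).
    """

    U: np.ndarray
    s: np.ndarray
    Vt: np.ndarray
    deltas: np.ndarray
    groups: tuple[np.ndarray, ...] = field(default=())

    @property
    def rank(self) -> int:
        return len(self.s)

    def group_values(self) -> list[tuple[float, int]]:
        """(singular value, multiplicity) per group, descending."""
        return [(float(self.s[g[0]]), len(g)) for g in self.groups]


def dataset_modes(d: Dataset, *, rtol: float = RANK_RTOL) -> ModeDecomposition:
    """Numerical SVD of ``Sigma_yx`` with deterministic signs and grouping."""
    sigma_x, sigma_yx = correlation_matrices(d)
    U, s, Vt = np.linalg.svd(sigma_yx, full_matrices=False)
    keep = s > rtol * s[0]
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    # deterministic signs: largest-magnitude entry of each v_alpha positive
    for a in range(len(s)):
        j = np.argmax(np.abs(Vt[a]))
        if Vt[a, j] < 0:
            Vt[a] = -Vt[a]
            U[:, a] = -U[:, a]
    # pair each mode with its input singular value via the quadratic form
    deltas = np.einsum("ai,ij,aj->a", Vt, sigma_x, Vt)
    # group near-equal singular values (multiplicities are inferred, not assumed)
    groups: list[list[int]] = []
    for a, val in enumerate(s):
        if groups and abs(s[groups[-1][0]] - val) <= 1e-6 * s[0]:
            groups[-1].append(a)
        else:
            groups.append([a])
    return ModeDecomposition(
        U=U, s=s, Vt=Vt, deltas=deltas,
        groups=tuple(np.asarray(g) for g in groups),
    )


def numerical_rank(M: np.ndarray, *, rtol: float = RANK_RTOL) -> int:
    """Rank of ``M`` counting singular values above ``rtol * s_max``."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.size == 0:
        raise ValueError("empty matrix has no rank")
    s = np.linalg.svd(M, compute_uv=False)
    if s[0] == 0.0:
        return 0
    return int(np.sum(s > rtol * s[0]))


def count_distinct_columns(M: np.ndarray, *, tol: float | None = None) -> int:
    """Number of equivalence classes of columns under distance <= tol.

    ``tol`` defaults to ``RANK_RTOL`` times the largest column norm.
    Exhaustive pairwise comparison with union-find; intended for
    desk-scale item counts.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    n = M.shape[1]
    if n == 0:
        raise ValueError("matrix has no items (columns)")
    if tol is None:
        scale = float(np.max(np.linalg.norm(M, axis=0), initial=0.0))
        tol = RANK_RTOL * max(scale, 1.0)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(M[:, i] - M[:, j]) <= tol:
                parent[find(j)] = find(i)
    return len({find(i) for i in range(n)})


def rcr(
    X: np.ndarray,
    Y: np.ndarray,
    *,
    tol: float = RANK_RTOL,
    cardinality: int | None = None,
) -> float:
    """Rank-cardinality ratio of a meaning-signal mapping.

    ``rank(Y X^T) / min(|X|, |Y|)`` where ``|X|``/``|Y|`` count distinct
    columns (items) of the supplied matrices and rank is the numerical
    rank at relative tolerance ``tol``.  A ratio near 0 means the
    mapping can be learned from far fewer examples than it expresses
    (regular yet expressive); 1 means every item must be seen.

    ``cardinality`` overrides the denominator, e.g. to keep the original
    item count when scoring a collapsed (post-iterated-learning) output.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"X and Y must have equal item counts, got {X.shape[1]} and {Y.shape[1]}"
        )
    if X.shape[1] == 0:
        raise ValueError("zero items")
    if tol <= 0:
        raise ValueError("tol must be positive")
    rank = numerical_rank(Y @ X.T, rtol=tol)
    if cardinality is None:
        cardinality = min(count_distinct_columns(X), count_distinct_columns(Y))
    if cardinality < 1:
        raise ValueError("cardinality must be >= 1")
    return rank / cardinality


# ---------------------------------------------------------------------------
# plain-text I/O: CSV body with a one-line JSON header comment

def write_dataset_csv(d: Dataset, path) -> None:
    """Write a dataset as CSV with a JSON header line recording params."""
    header = {
        "params": d.params.to_dict(),
        "x_rows": int(d.X.shape[0]),
        "y_rows": int(d.Y.shape[0]),
        "items": int(d.n_items),
    }
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        stacked = np.vstack([d.X, d.Y])
        for row in stacked:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_dataset_csv(path) -> Dataset:
    """Read a dataset written by :func:`write_dataset_csv`."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("missing JSON header line")
        header = json.loads(first[1:])
        body = np.loadtxt(fh, delimiter=",", ndmin=2)
    params = DatasetParams(**header["params"])
    x_rows = header["x_rows"]
    X = body[:x_rows]
    Y = body[x_rows:]
    d = Dataset(params=params, X=X, Y=Y)
    ref = build_dataset(params)
    if X.shape != ref.X.shape or Y.shape != ref.Y.shape:
        raise ValueError("file dimensions do not match the declared parameters")
    return d
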
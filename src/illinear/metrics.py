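"""Systematicity taxonomy, expressivity and the interlacing check.

Systematic generalization is cast as the identification of low-rank
substructure: a mapping is systematic when it relies on a substructure
whose rank-cardinality ratio (RCR) is lower than that of the full
dataset -- fewer examples buy the same expressive reach.  Output,
input and full systematicity test the output side, the input side and
both at once; the weak-full variant asks whether the reliance on
item-specific input features vanishes as the number of compositional
input features grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import RANK_RTOL, count_distinct_columns, numerical_rank, rcr

__all__ = [
    "SystematicityReport",
    "expressivity",
    "output_systematic",
    "input_systematic",
    "full_systematic",
    "weak_full_trend",
    "interlacing_check",
]


@dataclass(frozen=True)
class SystematicityReport:
    """Verdict and the ratios behind it."""

    verdict: bool
    kind: str                  # 'output' | 'input' | 'full'
    rcr_full: float
    rcr_substructure: float
    rank_condition: bool | None = None   # side condition, where applicable
    tol: float = RANK_RTOL

    def to_dict(self) -> dict:
        return {
            "verdict": bool(self.verdict),
            "kind": self.kind,
            "rcr_full": float(self.rcr_full),
            "rcr_substructure": float(self.rcr_substructure),
            "rank_condition": None if self.rank_condition is None else bool(self.rank_condition),
            "tol": float(self.tol),
        }


def expressivity(Y: np.ndarray, tol: float | None = None) -> int:
    """Number of distinct signals (unique output columns) under ``tol``."""
    return count_distinct_columns(Y, tol=tol)


def output_systematic(
    X: np.ndarray, Y_sub: np.ndarray, Y: np.ndarray, tol: float = RANK_RTOL
) -> SystematicityReport:
    """Does relying on output substructure ``Y_sub`` lower the RCR?

    True iff ``RCR(X, Y_sub) < RCR(X, Y)`` (strict).
    """
    full = rcr(X, Y, tol=tol)
    sub = rcr(X, Y_sub, tol=tol)
    return SystematicityReport(
        verdict=sub < full, kind="output", rcr_full=full, rcr_substructure=sub, tol=tol
    )


def input_systematic(
    X_sub: np.ndarray, X: np.ndarray, Y: np.ndarray, tol: float = RANK_RTOL
) -> SystematicityReport:
    """Does relying on input substructure ``X_sub`` lower the RCR?

    True iff ``RCR(X_sub, X_sub) < RCR(X, X)`` and the substructure
    carries enough rank to produce the outputs:
    ``rank(X_sub X_sub^T) >= rank(Y X_sub^T)``.
    """
    full = rcr(X, X, tol=tol)
    sub = rcr(X_sub, X_sub, tol=tol)
    rank_ok = numerical_rank(X_sub @ X_sub.T, rtol=tol) >= numerical_rank(
        np.asarray(Y) @ np.asarray(X_sub).T, rtol=tol
    )
    return SystematicityReport(
        verdict=(sub < full) and rank_ok,
        kind="input",
        rcr_full=full,
        rcr_substructure=sub,
        rank_condition=rank_ok,
        tol=tol,
    )


def full_systematic(
    X_sub: np.ndarray,
    Y_sub: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    tol: float = RANK_RTOL,
) -> SystematicityReport:
    """Input and output systematicity on the same substructures.

    True iff ``RCR(X_sub, X_sub) < RCR(X, X)``,
    ``RCR(X_sub, Y_sub) < RCR(X, Y)`` and
    ``rank(X_sub X_sub^T) >= rank(Y_sub X_sub^T)``.
    """
    in_full = rcr(X, X, tol=tol)
    in_sub = rcr(X_sub, X_sub, tol=tol)
    io_full = rcr(X, Y, tol=tol)
    io_sub = rcr(X_sub, Y_sub, tol=tol)
    rank_ok = numerical_rank(np.asarray(X_sub) @ np.asarray(X_sub).T, rtol=tol) >= numerical_rank(
        np.asarray(Y_sub) @ np.asarray(X_sub).T, rtol=tol
    )
    return SystematicityReport(
        verdict=(in_sub < in_full) and (io_sub < io_full) and rank_ok,
        kind="full",
        rcr_full=io_full,
        rcr_substructure=io_sub,
        rank_condition=rank_ok,
        tol=tol,
    )


def weak_full_trend(nx_values, ny: int, kx: int, ky: int, r: int) -> dict:
    """Decay of the item-specific-input -> compositional-output coupling.

    Evaluates the closed-form XG -> YO block norm at the converged
    strength ``pi1`` for each ``nx`` in ``nx_values`` (>= 3 increasing
    values) and reports whether the sequence is strictly decreasing and
    its final/initial ratio -- the operational check that the mapping
    becomes systematic as the meaning space grows.
    """
    from .dataset import DatasetParams, theoretical_spectrum
    from .simulator import xgamma_yomega_norm_theory

    nx_values = [int(v) for v in nx_values]
    if len(nx_values) < 3 or any(b <= a for a, b in zip(nx_values, nx_values[1:])):
        raise ValueError("need at least 3 strictly increasing nx values")
    norms = []
    for nx in nx_values:
        p = DatasetParams(nx=nx, ny=ny, kx=kx, ky=ky, r=r)
        pi1 = theoretical_spectrum(p).pi1
        norms.append(xgamma_yomega_norm_theory(p, pi1))
    norms = np.asarray(norms)
    return {
        "nx": nx_values,
        "norm": norms,
        "strictly_decreasing": bool(np.all(np.diff(norms) < 0)),
        "final_over_initial": float(norms[-1] / norms[0]),
    }


def interlacing_check(M: np.ndarray, tol: float = 1e-10) -> bool:
    """No single row or column deletion increases the top singular value.

    Brute force over all deletions; returns True when every submatrix's
    leading singular value is within ``tol`` of or below the original's.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.size == 0:
        raise ValueError("empty matrix")
    top = np.linalg.svd(M, compute_uv=False)[0]
    for i in range(M.shape[0]):
        sub = np.delete(M, i, axis=0)
        if sub.size and np.linalg.svd(sub, compute_uv=False)[0] > top + tol:
            return False
    for j in range(M.shape[1]):
        sub = np.delete(M, j, axis=1)
        if sub.size and np.linalg.svd(sub, compute_uv=False)[0] > top + tol:
            return False
    return True
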
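"""Effective-singular-value dynamics of linear networks under gradient flow.

One learning *mode* is a singular value ``lambda`` of the input-output
correlation, its paired input singular value ``delta``, the small
initial effective strength ``pi0`` and the time constant ``tau`` (one
full-batch step per unit of ``t / tau``).  The mode's effective
singular value ``pi(t)`` obeys the reduced gradient flow

    tau * dpi/dt = D * pi**(2 - 2/D) * (lambda - delta * pi)

for a network of depth ``D`` (number of weight matrices).  ``D = 1``
gives an exponential approach to the asymptote ``lambda/delta``;
``D = 2`` a logistic (sigmoidal) trajectory; ``D > 2`` has no
elementary closed form and is integrated numerically.

Two landmark times characterise a trajectory: the *escaping time*, when
``pi`` first exceeds a small threshold ``rho`` (learning begins), and
the *hitting time*, when ``pi`` is first within ``rho`` of the
asymptote (learning completes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad, solve_ivp

__all__ = [
    "ModeState",
    "Trajectory",
    "ThresholdTimes",
    "shallow_trajectory",
    "deep_trajectory",
    "depth_rate",
    "trajectory",
    "escaping_time",
    "hitting_time",
    "threshold_times",
    "optimal_depth",
    "depth_separation_grid",
    "DEFAULT_RHO",
]

#: escape/hit threshold used throughout the worked settings
DEFAULT_RHO = 0.005


@dataclass(frozen=True)
class ModeState:
    """One learning mode of a linear network."""

    lam: float          # input-output singular value (lambda_alpha)
    delta: float        # paired input singular value (delta_alpha)
    pi0: float = 1e-3   # initial effective singular value
    tau: float = 1.0    # time constant (training steps)
    depth: int = 2      # number of weight matrices

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.delta <= 0 or self.tau <= 0:
            raise ValueError("lam, delta and tau must be positive")
        if self.pi0 < 0:
            raise ValueError("pi0 must be nonnegative")
        if int(self.depth) != self.depth or self.depth < 1:
            raise ValueError("depth must be an integer >= 1")
        if self.pi0 >= self.asymptote:
            raise ValueError(
                f"pi0 ({self.pi0}) must lie below the asymptote "
                f"lambda/delta ({self.asymptote}): training starts from small weights"
            )

    @property
    def asymptote(self) -> float:
        return self.lam / self.delta


@dataclass(frozen=True)
class Trajectory:
    """An effective-singular-value time course, one row per mode."""

    times: np.ndarray           # (T,)
    values: np.ndarray          # (n_modes, T)
    modes: tuple[ModeState, ...]


@dataclass(frozen=True)
class ThresholdTimes:
    escape: float
    hit: float
    rho: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.escape <= self.hit):
            raise ValueError("expected 0 <= escape <= hit")


def shallow_trajectory(mode: ModeState, t) -> np.ndarray | float:
    """Depth-1 trajectory: exponential relaxation to ``lambda/delta``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    a = mode.asymptote
    decay = np.exp(-mode.delta * t / mode.tau)
    out = a * (1.0 - decay) + mode.pi0 * decay
    return float(out) if out.ndim == 0 else out


def deep_trajectory(mode: ModeState, t) -> np.ndarray | float:
    """Depth-2 trajectory: logistic growth at rate ``2 lambda / tau``.

    ``pi0 = 0`` is a fixed point of the deep dynamics; the trajectory
    then stays at zero (a warning is emitted).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    if mode.pi0 == 0.0:
        warnings.warn(
            "pi0 = 0 is a fixed point of the deep dynamics; the mode never leaves zero",
            stacklevel=2,
        )
        out = np.zeros_like(t)
        return float(out) if out.ndim == 0 else out
    a = mode.asymptote
    out = a / (1.0 - (1.0 - a / mode.pi0) * np.exp(-2.0 * mode.lam * t / mode.tau))
    return float(out) if out.ndim == 0 else out


def depth_rate(pi: float, mode: ModeState) -> float:
    """Reduced gradient-flow rate ``dpi/dt`` at strength ``pi``.

    ``tau * dpi/dt = D * pi**(2 - 2/D) * (lambda - delta * pi)``; the
    exponent vanishes for ``D = 1`` (rate independent of ``pi``) and the
    ``D = 2`` case is the logistic rate ``2 pi (lambda - delta pi)``.
    """
    if pi < 0:
        raise ValueError("pi must be nonnegative")
    D = mode.depth
    expo = 2.0 - 2.0 / D
    return D * pi ** expo * (mode.lam - mode.delta * pi) / mode.tau


def trajectory(mode: ModeState, times) -> np.ndarray:
    """Evaluate the mode's trajectory at the requested times.

    Closed forms for depth 1 and 2; adaptive numerical integration of
    the reduced flow for deeper networks (relative tolerance 1e-10).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    if mode.depth == 1:
        return shallow_trajectory(mode, times)
    if mode.pi0 == 0.0:
        warnings.warn("pi0 = 0 is a fixed point; returning the zero trajectory", stacklevel=2)
        return np.zeros_like(times)
    if mode.depth == 2:
        return deep_trajectory(mode, times)
    order = np.argsort(times)
    t_sorted = times[order]
    sol = solve_ivp(
        lambda _t, y: [depth_rate(max(y[0], 0.0), mode)],
        (0.0, max(float(t_sorted[-1]), 1e-12)),
        [mode.pi0],
        t_eval=np.maximum(t_sorted, 0.0),
        rtol=1e-10,
        atol=1e-13,
        method="LSODA",
    )
    if not sol.success:
        raise RuntimeError(f"trajectory integration failed: {sol.message}")
    vals = np.empty_like(times)
    vals[order] = sol.y[0]
    return vals


def _time_to_reach(mode: ModeState, target: float) -> float:
    """Time for the mode to grow from pi0 to ``target`` (any depth).

    Computed by quadrature of ``dt = tau dp / (D p**(2-2/D) (lam - delta p))``,
    which is exact for the monotone regime pi0 < target < asymptote.
    """
    D = mode.depth
    expo = 2.0 - 2.0 / D

    def integrand(p: float) -> float:
        return mode.tau / (D * p ** expo * (mode.lam - mode.delta * p))

    val, _err = quad(integrand, mode.pi0, target, limit=500)
    return val


def escaping_time(mode: ModeState, rho: float = DEFAULT_RHO) -> float:
    """First time the trajectory reaches ``rho`` (learning begins)."""
    a = mode.asymptote
    if not (mode.pi0 <= rho < a):
        raise ValueError(f"need pi0 <= rho < lambda/delta, got rho={rho}")
    if rho == mode.pi0:
        return 0.0
    if mode.depth == 1:
        return mode.tau / mode.delta * math.log((a - mode.pi0) / (a - rho))
    if mode.pi0 == 0.0:
        raise ValueError("pi0 = 0 never escapes (fixed point of the deep dynamics)")
    if mode.depth == 2:
        return (
            mode.tau / (2.0 * mode.lam)
            * math.log(rho * (a - mode.pi0) / (mode.pi0 * (a - rho)))
        )
    return _time_to_reach(mode, rho)


def hitting_time(mode: ModeState, rho: float = DEFAULT_RHO) -> float:
    """First time the trajectory is within ``rho`` of its asymptote."""
    a = mode.asymptote
    if not (0.0 < rho <= a - mode.pi0):
        raise ValueError(f"need 0 < rho <= lambda/delta - pi0, got rho={rho}")
    if rho == a - mode.pi0:
        return 0.0
    if mode.depth == 1:
        return mode.tau / mode.delta * math.log((a - mode.pi0) / rho)
    if mode.pi0 == 0.0:
        raise ValueError("pi0 = 0 never converges (fixed point of the deep dynamics)")
    if mode.depth == 2:
        return (
            mode.tau / (2.0 * mode.lam)
            * math.log((a - rho) * (a - mode.pi0) / (rho * mode.pi0))
        )
    return _time_to_reach(mode, a - rho)


def threshold_times(mode: ModeState, rho: float = DEFAULT_RHO) -> ThresholdTimes:
    return ThresholdTimes(
        escape=escaping_time(mode, rho), hit=hitting_time(mode, rho), rho=rho
    )


def optimal_depth(pi0: float) -> tuple[float, int]:
    """Depth minimising the initial learning speed: ``1 - 2 ln(pi0)``.

    Returns the real-valued optimum and its nearest integer.  Slower
    initial learning keeps slow modes pinned near zero while fast modes
    converge, which is what makes the generational bottleneck selective.
    """
    if not (0.0 < pi0 < 1.0):
        raise ValueError("pi0 must lie strictly between 0 and 1")
    d = 1.0 - 2.0 * math.log(pi0)
    return d, round(d)


def depth_separation_grid(
    fast: ModeState,
    slow: ModeState,
    depths,
    rho: float = DEFAULT_RHO,
    *,
    objective: str = "escape_hit",
) -> "np.ndarray":
    """Mode-separation score over a grid of integer depths.

    ``objective='escape_hit'`` scores each depth by the escaping time of
    the slow (removable) mode minus the hitting time of the fast
    (maintained) mode -- how long the removable mode is still pinned at
    its initial value after the maintained mode has converged, which is
    the window a single generation's bottleneck can exploit.
    ``objective='escape_escape'`` uses the difference of escaping times
    instead.  Returns an array of shape (len(depths), 2) with columns
    (depth, separation).
    """
    if objective not in ("escape_hit", "escape_escape"):
        raise ValueError(f"unknown objective {objective!r}")
    rows = []
    for D in depths:
        f = replace(fast, depth=int(D))
        s = replace(slow, depth=int(D))
        if objective == "escape_hit":
            sep = escaping_time(s, rho) - hitting_time(f, rho)
        else:
            sep = escaping_time(s, rho) - escaping_time(f, rho)
        rows.append((int(D), sep))
    return np.asarray(rows, dtype=float)
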
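"""The generational loop: bottlenecked training, relabelling, convergence.

Each generation a fresh learner trains on the language produced by its
predecessor, but training halts at a bottleneck time ``t*`` before full
convergence.  The learner's outputs (logits) on every item become the
targets for the next generation; the inputs never change.  Because the
dataset's singular vectors are preserved across generations, the whole
process reduces to a recursion on the effective singular values: the
asymptote of generation ``G`` is whatever strength generation ``G - 1``
reached, ``lambda_alpha^G = delta_alpha * pi_alpha^(G-1)``.

For a shallow learner every mode decays toward the initialisation
strength ``pi0`` -- the language degenerates.  A deep learner's
sigmoidal dynamics let a well-placed ``t*`` preserve fast (maintained)
modes at full strength for dozens of generations while slow (removable)
modes are progressively driven to zero, yielding a converged language
of lower rank but undiminished expressivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import (
    Dataset,
    DatasetParams,
    TheoreticalSpectrum,
    build_dataset,
    dataset_modes,
    rcr,
    count_distinct_columns,
    numerical_rank,
    theoretical_spectrum,
)
from .dynamics import DEFAULT_RHO, ModeState, escaping_time, hitting_time
from .simulator import (
    LinearNetwork,
    TrainConfig,
    balanced_init,
    block_norms,
    calibrate_sigma0,
    default_learning_rate,
    init_network,
    train,
)

__all__ = [
    "GenerationConfig",
    "ILTrace",
    "ConvergedLanguage",
    "BottleneckPlan",
    "relabel",
    "run_il_analytic",
    "run_il_simulated",
    "choose_bottleneck",
    "conserving_bottleneck",
    "converged_language",
]

#: analytic engine clamps mode strengths below this to exactly zero
ZERO_FLOOR = 1e-12


@dataclass(frozen=True)
class GenerationConfig:
    """Settings for one iterated-learning run."""

    generations: int
    t_star: float               # bottleneck time per generation, in tau units
    depth: int = 2
    pi0: float = 1e-3
    tau: float = 1.0
    rho: float = DEFAULT_RHO
    seed: int = 0               # master seed; per-generation seeds derive from it

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.t_star <= 0:
            raise ValueError("t_star must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0 < self.pi0 < 1):
            raise ValueError("pi0 must lie in (0, 1)")


@dataclass
class ILTrace:
    """Per-generation record of an iterated-learning run."""

    generations: np.ndarray        # (G,) 1-based generation index
    pi: np.ndarray                 # (G, n_modes) end-of-generation strengths
    lambdas: np.ndarray            # (G, n_modes) singular values trained on
    engine: str                    # 'analytic' or 'simulated'

    # populated by dataset-aware engines
    rank: np.ndarray | None = None
    expressivity: np.ndarray | None = None
    rcr_values: np.ndarray | None = None
    norms: np.ndarray | None = None          # (G, 4) block norms
    relabelled: list[np.ndarray] = field(default_factory=list)

    def to_frame(self):
        """Long-format DataFrame: generation, mode, value."""
        import pandas as pd

        G, n = self.pi.shape
        return pd.DataFrame(
            {
                "generation": np.repeat(self.generations, n),
                "mode": np.tile(np.arange(1, n + 1), G),
                "pi": self.pi.ravel(),
                "lambda": self.lambdas.ravel(),
            }
        )


def relabel(d: Dataset, mapping: np.ndarray | LinearNetwork) -> np.ndarray:
    """Next generation's output matrix: the mapping applied to every item."""
    W = mapping.composed() if isinstance(mapping, LinearNetwork) else np.asarray(mapping)
    if W.shape[1] != d.X.shape[0]:
        raise ValueError(
            f"mapping expects {W.shape[1]} input features, dataset has {d.X.shape[0]}"
        )
    return W @ d.X


def _one_generation(lam, delta, asymptote, cfg: GenerationConfig) -> np.ndarray:
    """End-of-generation strength for modes trained toward ``asymptote``.

    Evaluates the generational closed forms directly: they stay valid
    when the asymptote has decayed below ``pi0`` (the mode then relaxes
    downward from ``pi0``), which happens late in a collapse.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    a = np.atleast_1d(np.asarray(asymptote, dtype=float))
    out = np.zeros_like(lam)
    live = (lam > ZERO_FLOOR) & (a > ZERO_FLOOR)
    t, p0, tau = cfg.t_star, cfg.pi0, cfg.tau
    if cfg.depth == 1:
        decay = np.exp(-delta[live] * t / tau)
        out[live] = a[live] * (1.0 - decay) + p0 * decay
    else:
        # depth >= 2 shares the sigmoidal generational form
        decay = np.exp(-2.0 * lam[live] * t / tau)
        out[live] = a[live] / (1.0 - (1.0 - a[live] / p0) * decay)
    return out


def run_il_analytic(
    spectrum: TheoreticalSpectrum | tuple,
    cfg: GenerationConfig,
) -> ILTrace:
    """Exact generational recursion on the three distinct modes.

    ``spectrum`` may be a :class:`TheoreticalSpectrum` or an explicit
    ``(lambdas, deltas)`` pair of sequences.  Per generation the
    asymptote is reset to the previous end-of-generation strength and
    the learner restarts from ``pi0``.  Strengths that fall below the
    zero floor are clamped to exactly zero (the mode is removed).
    """
    if isinstance(spectrum, TheoreticalSpectrum):
        lambdas = np.asarray(spectrum.lambdas, dtype=float)
        deltas = np.asarray(spectrum.deltas, dtype=float)
    else:
        lambdas, deltas = (np.asarray(v, dtype=float) for v in spectrum)
    pis, lams = [], []
    lam = lambdas.copy()
    for _g in range(cfg.generations):
        asym = lam / deltas
        pi = _one_generation(lam, deltas, asym, cfg)
        pi[pi < ZERO_FLOOR] = 0.0
        pis.append(pi)
        lams.append(lam.copy())
        lam = deltas * pi
    return ILTrace(
        generations=np.arange(1, cfg.generations + 1),
        pi=np.asarray(pis),
        lambdas=np.asarray(lams),
        engine="analytic",
    )


def run_il_simulated(
    d: Dataset,
    cfg: GenerationConfig,
    *,
    nh: int | None = None,
    learning_rate: float | None = None,
    init: str = "gaussian",
) -> ILTrace:
    """Generational loop with actual gradient-descent learners.

    Each generation draws a fresh small-init network (seed derived from
    the master seed), trains for ``round(t_star * tau_epochs)`` epochs
    on the current labels, then relabels every item with the learner's
    outputs.  Records the same per-generation quantities as the
    analytic engine plus rank, expressivity, rank-cardinality ratio
    and block norms of each produced language.

    ``init='gaussian'`` draws unstructured small Gaussian weights (the
    realistic learner); ``init='balanced'`` (depth 2 only) starts every
    mode at exactly ``pi0`` with balanced layers, the initialisation
    the analytic recursion models exactly -- use it for quantitative
    engine cross-checks.
    """
    if init not in ("gaussian", "balanced"):
        raise ValueError(f"unknown init {init!r}")
    if init == "balanced" and cfg.depth != 2:
        raise ValueError("balanced init is defined for depth 2")
    modes0 = dataset_modes(d)
    if nh is None:
        nh = modes0.rank + 2
    eta = learning_rate if learning_rate is not None else default_learning_rate(d)
    P = d.n_items
    tau_epochs = 1.0 / (eta * P)
    epochs = max(1, round(cfg.t_star / cfg.tau * tau_epochs))
    sigma0 = calibrate_sigma0(cfg.pi0, nh, cfg.depth)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.generations)

    Y = d.Y.copy()
    pis, lams, ranks, expr, rcrs, norms, relab = [], [], [], [], [], [], []
    orig_card = count_distinct_columns(d.X)
    for g in range(cfg.generations):
        dg = Dataset(params=d.params, X=d.X, Y=Y)
        lam_g = dataset_modes(dg).s if g else modes0.s
        if init == "balanced":
            net = balanced_init(modes0, nh, cfg.pi0, int(seeds[g]))
        else:
            net = init_network(d.X.shape[0], d.Y.shape[0], nh, cfg.depth, sigma0, int(seeds[g]))
        trace = train(
            net, dg,
            TrainConfig(learning_rate=eta, epochs=epochs, sigma0=sigma0,
                        seed=int(seeds[g]), record_every=max(1, epochs)),
        )
        W = trace.final.composed()
        # measure against the ORIGINAL dataset's singular basis
        from .simulator import effective_spectrum

        pis.append(effective_spectrum(W, modes0))
        lam_pad = np.zeros(modes0.rank)
        lam_pad[: len(lam_g)] = lam_g[: modes0.rank]
        lams.append(lam_pad)
        Y = relabel(d, W)
        relab.append(Y)
        ranks.append(numerical_rank(Y @ d.X.T))
        expr.append(count_distinct_columns(Y, tol=1e-3))
        rcrs.append(rcr(d.X, Y, cardinality=orig_card))
        nb = block_norms(W, d)
        norms.append([nb[k] for k in ("XO->YO", "XO->YG", "XG->YO", "XG->YG")])
    return ILTrace(
        generations=np.arange(1, cfg.generations + 1),
        pi=np.asarray(pis),
        lambdas=np.asarray(lams),
        engine="simulated",
        rank=np.asarray(ranks),
        expressivity=np.asarray(expr),
        rcr_values=np.asarray(rcrs),
        norms=np.asarray(norms),
        relabelled=relab,
    )


@dataclass(frozen=True)
class BottleneckPlan:
    """Outcome of bottleneck selection."""

    t_star: float
    single_generation: bool     # True if one generation cleanly separates
    min_generations: int        # generations needed for removal at t_star
    maintained: tuple[int, ...] # group indices kept (0 = lambda1 group)
    removable: tuple[int, ...]


def _group_modes(spectrum: TheoreticalSpectrum, cfg_depth: int, pi0: float, tau: float):
    lams = np.asarray(spectrum.lambdas)
    dels = np.asarray(spectrum.deltas)
    return [
        ModeState(lam=l, delta=dl, pi0=pi0, tau=tau, depth=cfg_depth)
        for l, dl in zip(lams, dels)
    ]


def choose_bottleneck(
    spectrum: TheoreticalSpectrum,
    depth: int = 2,
    pi0: float = 1e-3,
    rho: float = DEFAULT_RHO,
    *,
    maintained: tuple[int, ...] = (0,),
    tau: float = 1.0,
    margin: float = 0.05,
    max_generations: int = 200,
) -> BottleneckPlan:
    """Pick a bottleneck and the number of generations it needs.

    A single generation suffices only when the fastest removable mode
    has not yet escaped (``pi <= rho``) by the time the slowest
    maintained mode converges; ``t*`` is then that hitting time times
    ``1 + margin``.  Otherwise no generation-0 bottleneck removes
    cleanly, and the plan searches for the minimal horizon ``G`` for
    which some ``t*`` both conserves every maintained mode within
    ``rho`` of its original asymptote over all ``G`` generations and
    drives every removable mode below ``rho`` by generation ``G``.
    Raises ``ValueError`` when nothing is removable (all three distinct
    singular values designated maintained) or no horizon up to
    ``max_generations`` succeeds.
    """
    if depth < 2:
        raise ValueError("selective removal requires depth >= 2 (sigmoidal dynamics)")
    maintained = tuple(sorted(set(maintained)))
    removable = tuple(i for i in range(3) if i not in maintained)
    if not removable:
        raise ValueError("no removable modes: all distinct singular values are maintained")
    modes = _group_modes(spectrum, depth, pi0, tau)
    t_hit_maint = max(hitting_time(modes[i], rho) for i in maintained)
    t_esc_rem = min(escaping_time(modes[i], rho) for i in removable)
    lam0 = np.asarray(spectrum.lambdas, dtype=float)
    dels = np.asarray(spectrum.deltas, dtype=float)

    if t_esc_rem >= t_hit_maint:
        return BottleneckPlan(
            t_star=t_hit_maint * (1.0 + margin),
            single_generation=True,
            min_generations=1,
            maintained=maintained,
            removable=removable,
        )

    def removed_by(ts: float, horizon: int) -> bool:
        cfg = GenerationConfig(
            generations=1, t_star=ts, depth=depth, pi0=pi0, tau=tau, rho=rho
        )
        lam = lam0.copy()
        for _ in range(horizon):
            pi = _one_generation(lam, dels, lam / dels, cfg)
            lam = dels * pi
        return all(pi[i] <= rho for i in removable)

    for g in range(1, max_generations + 1):
        try:
            ts = conserving_bottleneck(
                spectrum, generations=g, depth=depth, pi0=pi0, rho=rho,
                tau=tau, maintained=maintained,
            )
        except ValueError:
            continue
        if removed_by(ts, g):
            return BottleneckPlan(
                t_star=ts,
                single_generation=False,
                min_generations=g,
                maintained=maintained,
                removable=removable,
            )
    raise ValueError(
        f"no bottleneck removes the removable modes within {max_generations} "
        "generations while conserving the maintained modes"
    )


def conserving_bottleneck(
    spectrum: TheoreticalSpectrum,
    *,
    generations: int,
    depth: int = 2,
    pi0: float = 1e-3,
    rho: float = DEFAULT_RHO,
    tau: float = 1.0,
    maintained: tuple[int, ...] = (0, 1),
    drift_fraction: float = 0.8,
) -> float:
    """Smallest ``t*`` whose maintained-mode drift over a horizon stays small.

    Bottleneck times close to the maintained modes' hitting time leak a
    little strength every generation, and the leak compounds.  This
    bisects ``t*`` between the slowest maintained hitting time and the
    fastest removable hitting time so that the worst maintained-mode
    deviation from its original asymptote over ``generations``
    generations equals ``drift_fraction * rho``.  Smaller ``t*`` removes
    the unwanted modes faster, so the minimiser is the efficient choice.
    """
    modes = _group_modes(spectrum, depth, pi0, tau)
    removable = tuple(i for i in range(3) if i not in maintained)
    if not removable:
        raise ValueError("no removable modes")
    lo = max(hitting_time(modes[i], rho) for i in maintained)
    hi = min(hitting_time(modes[i], rho) for i in removable)
    if hi <= lo:
        raise ValueError("no bottleneck window: removable modes converge before maintained")
    lam0 = np.asarray(spectrum.lambdas, dtype=float)
    dels = np.asarray(spectrum.deltas, dtype=float)
    asym0 = lam0 / dels
    target = drift_fraction * rho

    def drift(ts: float) -> float:
        cfg = GenerationConfig(
            generations=1, t_star=ts, depth=depth, pi0=pi0, tau=tau, rho=rho
        )
        lam = lam0.copy()
        worst = 0.0
        for _ in range(generations):
            pi = _one_generation(lam, dels, lam / dels, cfg)
            lam = dels * pi
            worst = max(worst, max(abs(pi[i] - asym0[i]) for i in maintained))
        return worst

    from scipy.optimize import brentq

    if drift(hi) > target:
        raise ValueError(
            "even the largest admissible t* cannot conserve the maintained modes "
            f"within {target} over {generations} generations"
        )
    if drift(lo) <= target:
        return lo
    return float(brentq(lambda ts: drift(ts) - target, lo, hi, xtol=1e-10))


@dataclass(frozen=True)
class ConvergedLanguage:
    """The mapping iterated learning converges to: maintained modes only."""

    params: DatasetParams
    W: np.ndarray                  # the converged linear map
    outputs: np.ndarray            # signals for every item, W @ X
    rank: int
    n_modes: int                   # retained mode count
    expressivity: int
    rcr_original_cardinality: float
    rcr_collapsed_cardinality: float


def converged_language(params: DatasetParams | tuple) -> ConvergedLanguage:
    """Construct the infinite-generation deep IL fixed point.

    Only the top (lambda1) group of modes is retained, at its asymptotic
    strength ``pi1``; every other mode is removed.  The resulting map
    has rank equal to the lambda1 multiplicity (= ny), reproduces the
    compositional output block exactly, and replaces the item-specific
    identity block with entangled combinations of compositional
    components.  Both rank-cardinality conventions are reported: the
    original item count ``2**nx`` and the collapsed count of distinct
    produced signals.
    """
    if not isinstance(params, DatasetParams):
        params = DatasetParams(*params)
    d = build_dataset(params)
    modes = dataset_modes(d)
    spec = theoretical_spectrum(params)
    top = modes.groups[0]
    W = (modes.U[:, top] * spec.pi1) @ modes.Vt[top, :]
    outputs = W @ d.X
    expr = count_distinct_columns(outputs, tol=1e-6)
    orig_card = d.n_items
    return ConvergedLanguage(
        params=params,
        W=W,
        outputs=outputs,
        rank=numerical_rank(W),
        n_modes=len(top),
        expressivity=expr,
        rcr_original_cardinality=rcr(d.X, outputs, cardinality=orig_card),
        rcr_collapsed_cardinality=rcr(d.X, outputs, cardinality=min(orig_card, expr)),
    )
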
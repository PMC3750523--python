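"""Reaction-system builders for gene expression with multimerization.

The single-gene model has four reactions: delayed transcription (the start
site S is occupied for a gamma-distributed interval with mean ``1/k_M`` and
CV ``alpha_M**-0.5``, after which S and the transcript M are released
together), first-order mRNA decay, translation at rate ``k_P * M`` with an
optional maturation delay on the protein, and first-order protein decay.
On top of that the builders add homomer assembly chains (orders 2..N),
heterodimerization between two genes, or a mutually repressing toggle
switch.

Species naming: gene ``g`` uses ``Sg`` (start site), ``Mg`` (mRNA), ``Pg``
(free monomer), ``Pgxn`` (order-n homomer), ``P1_2`` (heterodimer) and
``Xg`` (bookkeeping total-subunit counter, maintained by production and
degradation counting so that ``Xg == sum_k k * Pgxk`` is an exact integer
identity at all times).

The module also fits transcription-interval samples with the two competing
interval models (gamma vs a sequential three-exponential) by maximum
likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .stochastic_engine import (
    INSTANT,
    DelayDistribution,
    RateLike,
    ReactionSpec,
    RepressionRate,
)

__all__ = [
    "ExpressionParams",
    "MultimerParams",
    "ToggleParams",
    "IntervalFitResult",
    "build_monomer_gene",
    "build_homomer_system",
    "build_heterodimer_system",
    "build_toggle_switch",
    "monomer_initial",
    "heterodimer_initial",
    "homomer_species",
    "fit_interval_models",
]


def _positive(value: float, name: str) -> float:
    value = float(value)
    if not (value > 0 and math.isfinite(value)):
        raise ValueError(f"{name} must be positive and finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ExpressionParams:
    """Single-gene expression parameters, in units of the protein lifetime.

    k_M     mean transcription (initiation) rate
    alpha_M gamma shape of the transcription interval (1 = exponential,
            >1 sub-Poissonian mRNA, <1 super-Poissonian)
    d_M     mRNA degradation rate
    k_P     translation initiation rate per mRNA
    tau_P   protein maturation delay: a fixed time or a DelayDistribution
            (defaults to 0; a truncated normal reproduces the maturation
            noise robustness check)
    d_P     protein degradation rate (1 by convention)
    """

    k_M: float
    d_M: float
    k_P: float
    alpha_M: float = 1.0
    tau_P: float | DelayDistribution = 0.0
    d_P: float = 1.0

    def __post_init__(self):
        for name in ("k_M", "d_M", "k_P", "alpha_M", "d_P"):
            object.__setattr__(self, name, _positive(getattr(self, name), name))
        if isinstance(self.tau_P, DelayDistribution):
            return
        if not (float(self.tau_P) >= 0):
            raise ValueError("tau_P must be >= 0")
        object.__setattr__(self, "tau_P", float(self.tau_P))

    @property
    def maturation_delay(self) -> DelayDistribution:
        if isinstance(self.tau_P, DelayDistribution):
            return self.tau_P
        return DelayDistribution.fixed(self.tau_P)


@dataclass(frozen=True)
class MultimerParams:
    """Homomerization parameters.

    order
        Highest multimer order N (>= 1; N = 1 means no multimerization).
    association, dissociation
        Either a single rate applied to every (n, k) assembly pair, or a
        mapping {(n, k): rate}.  Association defaults to INSTANT and
        dissociation to 0, the paper-standard conditions for the sweeps.
    """

    order: int
    association: RateLike | Mapping[tuple[int, int], RateLike] = INSTANT
    dissociation: float | Mapping[tuple[int, int], float] = 0.0

    def __post_init__(self):
        if int(self.order) != self.order or self.order < 1:
            raise ValueError("multimer order must be an integer >= 1")
        object.__setattr__(self, "order", int(self.order))

    def _rate(self, table, n: int, k: int, what: str):
        r = table[(n, k)] if isinstance(table, Mapping) else table
        if not (r is INSTANT or (isinstance(r, (int, float)) and r >= 0)):
            raise ValueError(f"{what} rate for ({n},{k}) must be nonnegative or INSTANT")
        return r

    def association_rate(self, n: int, k: int):
        return self._rate(self.association, n, k, "association")

    def dissociation_rate(self, n: int, k: int):
        return self._rate(self.dissociation, n, k, "dissociation")

    def pairs(self) -> list[tuple[int, int]]:
        """All (n, k) assembly pairs with 2 <= n <= N, k <= n/2."""
        return [(n, k) for n in range(2, self.order + 1) for k in range(1, n // 2 + 1)]


def monomer_initial(gene: str = "1") -> dict[str, int]:
    """Initial state for a gene built here: one available start site."""
    return {f"S{gene}": 1}


def heterodimer_initial() -> dict[str, int]:
    return {"S1": 1, "S2": 1}


def homomer_species(gene: str, n: int) -> str:
    """Name of the order-n homomer of gene ``gene`` (n = 1 is the monomer)."""
    if n < 1:
        raise ValueError("order must be >= 1")
    return f"P{gene}" if n == 1 else f"P{gene}x{n}"


def build_monomer_gene(
    p: ExpressionParams, gene: str = "1", track_x: bool = False
) -> list[ReactionSpec]:
    """Reactions 1-4: delayed transcription, decay, translation, decay.

    Transcription is an INSTANT reaction that consumes the start site and
    releases it together with the transcript after one shared gamma
    interval, so the promoter is occupied for the full duration and
    consecutive transcript productions are separated by i.i.d. gamma
    intervals (mean ``1/k_M``, CV ``alpha_M**-0.5``).
    """
    S, M, P, X = f"S{gene}", f"M{gene}", f"P{gene}", f"X{gene}"
    interval = DelayDistribution.transcription_interval(p.alpha_M, p.k_M)
    mat = p.maturation_delay
    translation_products = {M: 1, P: 1}
    delays = {}
    if not (mat.family == "degenerate" and mat.params[0] == 0.0):
        delays[P] = mat
    if track_x:
        translation_products[X] = 1
        if P in delays:
            delays[X] = mat
    rxns = [
        ReactionSpec(
            {S: 1}, {S: 1, M: 1}, INSTANT,
            delays={S: interval, M: interval}, shared_delay=True,
            name=f"transcription_{gene}",
        ),
        ReactionSpec({M: 1}, {}, p.d_M, name=f"mrna_decay_{gene}"),
        ReactionSpec(
            {M: 1}, translation_products, p.k_P,
            delays=delays, shared_delay=bool(delays),
            name=f"translation_{gene}",
        ),
        ReactionSpec(
            {P: 1}, {}, p.d_P,
            tracked_deltas={X: -1} if track_x else {},
            name=f"monomer_decay_{gene}",
        ),
    ]
    return rxns


def _assembly_reactions(
    gene: str, m: MultimerParams, d_P: float, track_x: bool
) -> list[ReactionSpec]:
    X = f"X{gene}"
    rxns: list[ReactionSpec] = []
    for n, k in m.pairs():
        lo, hi = homomer_species(gene, k), homomer_species(gene, n - k)
        prod = homomer_species(gene, n)
        reactants = {lo: 2} if lo == hi else {lo: 1, hi: 1}
        rxns.append(
            ReactionSpec(
                reactants, {prod: 1}, m.association_rate(n, k),
                priority=n, name=f"assoc_{gene}_{n}_{k}",
            )
        )
        rxns.append(
            ReactionSpec(
                {prod: 1}, reactants, float(m.dissociation_rate(n, k)),
                name=f"dissoc_{gene}_{n}_{k}",
            )
        )
    for n in range(2, m.order + 1):
        rxns.append(
            ReactionSpec(
                {homomer_species(gene, n): 1},
                {homomer_species(gene, n - 1): 1},
                n * d_P,
                tracked_deltas={X: -1} if track_x else {},
                name=f"multimer_decay_{gene}_{n}",
            )
        )
    return rxns


def build_homomer_system(
    p: ExpressionParams, m: MultimerParams, gene: str = "1", track_x: bool = True
) -> list[ReactionSpec]:
    """Gene plus the order-N homomer assembly chain (Reactions 9-11).

    Associations combine an order-k and an order-(n-k) homomer into an
    order-n homomer for every 2 <= n <= N, k <= n/2; dissociations reverse
    them; an order-n homomer loses one subunit at rate ``n * d_P``.
    """
    if m.order < 2:
        raise ValueError("build_homomer_system requires multimer order >= 2")
    return build_monomer_gene(p, gene, track_x=track_x) + _assembly_reactions(
        gene, m, p.d_P, track_x
    )


def build_heterodimer_system(
    p1: ExpressionParams,
    p2: ExpressionParams,
    a12: RateLike = INSTANT,
    u12: float = 0.0,
) -> list[ReactionSpec]:
    """Two independently transcribed genes whose monomers heterodimerize.

    Reactions 5-8: association P1 + P2 -> P1_2, dissociation, and the two
    single-subunit degradations P1_2 -> P2 and P1_2 -> P1 (one subunit dies,
    the partner survives).
    """
    if not (a12 is INSTANT or (isinstance(a12, (int, float)) and a12 >= 0)):
        raise ValueError("a12 must be a nonnegative rate or INSTANT")
    if not (isinstance(u12, (int, float)) and u12 >= 0):
        raise ValueError("u12 must be a nonnegative rate")
    D = "P1_2"
    rxns = build_monomer_gene(p1, "1", track_x=True)
    rxns += build_monomer_gene(p2, "2", track_x=True)
    rxns += [
        ReactionSpec({"P1": 1, "P2": 1}, {D: 1}, a12, priority=2, name="assoc_12"),
        ReactionSpec({D: 1}, {"P1": 1, "P2": 1}, float(u12), name="dissoc_12"),
        ReactionSpec({D: 1}, {"P2": 1}, p1.d_P, tracked_deltas={"X1": -1}, name="dimer_decay_1"),
        ReactionSpec({D: 1}, {"P1": 1}, p2.d_P, tracked_deltas={"X2": -1}, name="dimer_decay_2"),
    ]
    return rxns


@dataclass(frozen=True)
class ToggleParams:
    """Toggle switch built from two mutually repressing multimer genes.

    The effective transcription rate of gene j is
    ``k_M_max / (1 + P_{i x N} / K)`` where P_{i x N} is the order-N homomer
    of the other gene and K the repressor-promoter dissociation constant.
    :meth:`standard` derives (k_M_max, K) from the repression scale C under
    the standard conditions d_M = 6 d_P, k_M / (N d_M) = 5, k_P / d_P = 5,
    K = C k_M k_P / (N d_M d_P).
    """

    k_M_max: float
    K: float
    order: int
    expression: ExpressionParams
    C: float | None = None
    multimer: MultimerParams | None = None

    def __post_init__(self):
        _positive(self.k_M_max, "k_M_max")
        _positive(self.K, "K")
        if self.C is not None:
            _positive(self.C, "C")
        if int(self.order) != self.order or self.order < 1:
            raise ValueError("order must be an integer >= 1")
        object.__setattr__(self, "order", int(self.order))
        if self.multimer is None:
            object.__setattr__(self, "multimer", MultimerParams(order=self.order))
        elif self.multimer.order != self.order:
            raise ValueError("multimer.order must match order")

    @classmethod
    def standard(cls, order: int, C: float, d_P: float = 1.0) -> "ToggleParams":
        C = _positive(C, "C")
        d_M = 6.0 * d_P
        k_M = 5.0 * order * d_M          # expected transcript number k_M/(N d_M) = 5
        k_P = 5.0 * d_P                  # expected proteins per transcript = 5
        K = C * (k_M / order) / d_M * k_P / d_P
        expr = ExpressionParams(k_M=k_M, d_M=d_M, k_P=k_P, alpha_M=1.0, d_P=d_P)
        return cls(k_M_max=k_M, K=K, order=order, expression=expr, C=C)

    def repressor(self, gene: str) -> str:
        return homomer_species(gene, self.order)


def build_toggle_switch(t: ToggleParams) -> list[ReactionSpec]:
    """Two genes, each transcribed at a rate repressed by the other's
    order-N homomer.

    Requires ``alpha_M == 1``: with exponential initiation intervals the
    delayed renewal formulation and a Markovian propensity coincide in law,
    so transcription is implemented as a zero-delay reaction whose
    propensity ``k_M_max / (1 + P_repressor / K)`` is re-evaluated after
    every event.  Non-exponential (alpha_M != 1) initiation has no
    event-wise well-defined state-dependent rate and is rejected.
    """
    if t.expression.alpha_M != 1.0:
        raise ValueError(
            "the state-dependent transcription rate is only exact for alpha_M = 1"
        )
    p = t.expression
    rxns: list[ReactionSpec] = []
    for j, i in (("1", "2"), ("2", "1")):
        M, P = f"M{j}", f"P{j}"
        rxns += [
            ReactionSpec(
                {}, {M: 1},
                RepressionRate(t.k_M_max, t.K, t.repressor(i)),
                name=f"transcription_{j}",
            ),
            ReactionSpec({M: 1}, {}, p.d_M, name=f"mrna_decay_{j}"),
            ReactionSpec({M: 1}, {M: 1, P: 1}, p.k_P, name=f"translation_{j}"),
            ReactionSpec({P: 1}, {}, p.d_P, name=f"monomer_decay_{j}"),
        ]
        if t.order >= 2:
            rxns += _assembly_reactions(j, t.multimer, p.d_P, track_x=False)
    return rxns


# ---------------------------------------------------------------------------
# interval-distribution fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntervalFitResult:
    """Maximum-likelihood fits of transcription-interval samples."""

    gamma_shape: float
    gamma_scale: float
    gamma_loglik: float
    hypoexp_rates: tuple[float, float, float]
    hypoexp_loglik: float

    @property
    def preferred(self) -> str:
        """Model with the higher maximized likelihood."""
        return "gamma" if self.gamma_loglik >= self.hypoexp_loglik else "three_exponential"


def _hypoexp_logpdf(t: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """log pdf of the sum of three independent exponentials.

    Evaluated as ``l1 l2 l3`` times the second divided difference of
    ``exp(-l t)`` over the rates, with the first divided differences
    computed through ``expm1`` so that nearly equal rates do not suffer
    catastrophic cancellation.
    """
    l1, l2, l3 = np.sort(rates)

    def d1(a: float, b: float) -> np.ndarray:
        # (exp(-a t) - exp(-b t)) / (a - b) for a <= b; factoring out the
        # slower exponential keeps it finite for large gaps and expm1 keeps
        # it exact for tiny ones
        h = (b - a) * t
        out = np.where(h > 1e-12, np.expm1(-h) / np.where(h != 0, h, 1.0), -1.0 + h / 2)
        return t * np.exp(-a * t) * out

    dd = (d1(l1, l2) - d1(l2, l3)) / (l1 - l3)
    f = l1 * l2 * l3 * dd
    return np.log(np.maximum(f, 1e-300))


def _fit_hypoexp(x: np.ndarray) -> tuple[np.ndarray, float]:
    """MLE of three-exponential rates by multi-start Nelder-Mead.

    Rates are parameterized as ordered with relative gaps bounded below
    (``l_{i+1} = l_i (1 + 1e-3 + e^theta)``) to keep the pdf evaluation
    well-conditioned.
    """
    eps = 1e-3

    def rates_of(theta: np.ndarray) -> np.ndarray:
        l1 = math.exp(theta[0])
        l2 = l1 * (1.0 + eps + math.exp(theta[1]))
        l3 = l2 * (1.0 + eps + math.exp(theta[2]))
        return np.array([l1, l2, l3])

    def nll(theta: np.ndarray) -> float:
        if np.any(np.abs(theta) > 50):
            return 1e308
        return -float(np.sum(_hypoexp_logpdf(x, rates_of(theta))))

    mean = float(np.mean(x))
    base = 3.0 / mean
    starts = [
        np.array([math.log(base), 0.0, 0.0]),
        np.array([math.log(base / 3), math.log(2.0), math.log(2.0)]),
        np.array([math.log(base), -3.0, -3.0]),       # near-Erlang
        np.array([math.log(base / 10), math.log(8.0), math.log(8.0)]),
    ]
    best = None
    for s in starts:
        res = optimize.minimize(nll, s, method="Nelder-Mead",
                                options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    rates = rates_of(best.x)
    return rates, -float(best.fun)


def fit_interval_models(intervals: Sequence[float]) -> IntervalFitResult:
    """Fit gamma and sequential three-exponential models to interval data.

    Both fits are by maximum likelihood; the preferred model is the one
    with higher maximized likelihood (both have an equal number of free
    parameters up to one, so the raw likelihood comparison mirrors the
    original analysis).
    """
    x = np.asarray(intervals, dtype=float)
    if x.ndim != 1 or len(x) < 10:
        raise ValueError("need at least 10 intervals")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("intervals must be positive and finite")
    if np.ptp(x) == 0:
        raise ValueError("gamma MLE is undefined for a degenerate (all-equal) sample")
    shape, _, scale = stats.gamma.fit(x, floc=0)
    g_ll = float(np.sum(stats.gamma.logpdf(x, shape, scale=scale)))
    rates, h_ll = _fit_hypoexp(x)
    return IntervalFitResult(
        gamma_shape=float(shape),
        gamma_scale=float(scale),
        gamma_loglik=g_ll,
        hypoexp_rates=tuple(float(r) for r in np.sort(rates)),
        hypoexp_loglik=h_ll,
    )
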
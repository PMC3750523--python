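"""Exact stochastic simulation with delayed product release.

The simulator implements the delayed variant of Gillespie's stochastic
simulation algorithm: a reaction fires according to its mass-action
propensity, but each product may be released only after a (possibly random)
delay.  Pending products are held on a time-ordered waitlist and release
events interleave exactly with reaction firings, so trajectories are
statistically exact realisations of the delayed chemical master equation.

Two additional rate classes are supported beside ordinary rate constants:

* :data:`INSTANT` — the reaction fires the moment its reactants are
  available.  Instant reactions are resolved as a deterministic fixpoint
  after every state change (see :func:`resolve_instant_reactions`), which is
  how effectively-infinite association rates and delay-gated transcription
  are modelled.
* state-dependent rates — either the structured :class:`RepressionRate`
  law ``k_max / (1 + x[repressor] / K)`` or an arbitrary Python callable of
  the species-count mapping.

Time is measured in units of the protein lifetime (d_P = 1 by convention
throughout the package).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from heapq import heappop, heappush
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "INSTANT",
    "DelayDistribution",
    "RepressionRate",
    "ReactionSpec",
    "SimulationState",
    "TrajectorySample",
    "simulate",
    "draw_delay",
    "resolve_instant_reactions",
]


class _Instant:
    """Sentinel for an effectively-infinite reaction rate."""

    _inst = None

    def __new__(cls):
        if cls._inst is None:
            cls._inst = super().__new__(cls)
        return cls._inst

    def __repr__(self):  # pragma: no cover - trivial
        return "INSTANT"


INSTANT = _Instant()

# delay family codes shared with the numba kernel
_FAM_DEGENERATE = 0
_FAM_GAMMA = 1
_FAM_TRUNCNORM = 2

_FAMILIES = {"degenerate": _FAM_DEGENERATE, "gamma": _FAM_GAMMA, "truncnorm": _FAM_TRUNCNORM}


@dataclass(frozen=True)
class DelayDistribution:
    """Distribution of the release delay of one reaction product.

    Families
    --------
    ``degenerate``
        Always exactly ``value`` (``value = 0`` means immediate release).
    ``gamma``
        Gam(shape, scale).  Parameterised for transcription intervals via
        :meth:`transcription_interval`: shape ``alpha_m`` and scale
        ``1/(alpha_m * k_m)`` give mean ``1/k_m`` and coefficient of
        variation (sd/mean) ``alpha_m**-0.5``.
    ``truncnorm``
        Normal(mean, sd) truncated at zero by rejection; used for the
        protein-maturation robustness check.
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown delay family {self.family!r}")
        p = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", p)
        if self.family == "degenerate":
            if len(p) != 1 or p[0] < 0 or not math.isfinite(p[0]):
                raise ValueError("degenerate delay needs one value >= 0")
        elif self.family == "gamma":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValueError("gamma delay needs shape > 0 and scale > 0")
        elif self.family == "truncnorm":
            if len(p) != 2 or p[1] <= 0:
                raise ValueError("truncated normal delay needs sd > 0")

    # -- constructors -----------------------------------------------------
    @classmethod
    def fixed(cls, value: float) -> "DelayDistribution":
        return cls("degenerate", (value,))

    @classmethod
    def gamma(cls, shape: float, scale: float) -> "DelayDistribution":
        return cls("gamma", (shape, scale))

    @classmethod
    def transcription_interval(cls, alpha_m: float, k_m: float) -> "DelayDistribution":
        """Gamma transcription-interval delay: mean 1/k_m, CV alpha_m**-0.5."""
        if alpha_m <= 0 or k_m <= 0:
            raise ValueError("alpha_m and k_m must be positive")
        return cls.gamma(alpha_m, 1.0 / (alpha_m * k_m))

    @classmethod
    def truncated_normal(cls, mean: float, sd: float) -> "DelayDistribution":
        return cls("truncnorm", (mean, sd))

    # -- moments ----------------------------------------------------------
    @property
    def mean(self) -> float:
        if self.family == "degenerate":
            return self.params[0]
        if self.family == "gamma":
            return self.params[0] * self.params[1]
        raise NotImplementedError("truncated-normal mean is not closed over its parameters here")

    @property
    def cv(self) -> float:
        """sd/mean; for the gamma family equals shape**-0.5."""
        if self.family == "degenerate":
            return 0.0
        if self.family == "gamma":
            return self.params[0] ** -0.5
        raise NotImplementedError


@dataclass(frozen=True)
class RepressionRate:
    """Structured state-dependent rate ``k_max / (1 + x[repressor] / K)``.

    This is the non-cooperative repression law used for toggle-switch
    transcription, with ``K`` the repressor-promoter dissociation constant.
    """

    k_max: float
    K: float
    repressor: str

    def __post_init__(self):
        if not (self.k_max >= 0 and math.isfinite(self.k_max)):
            raise ValueError("k_max must be a nonnegative finite real")
        if not (self.K > 0 and math.isfinite(self.K)):
            raise ValueError("K must be positive and finite")

    def __call__(self, counts: Mapping[str, int]) -> float:
        return self.k_max / (1.0 + counts.get(self.repressor, 0) / self.K)


RateLike = float | _Instant | RepressionRate | Callable[[Mapping[str, int]], float]


def _check_stoich(stoich: Mapping[str, int], what: str) -> dict[str, int]:
    out = {}
    for sp, n in stoich.items():
        if not isinstance(sp, str) or not sp:
            raise ValueError(f"{what} species names must be nonempty strings")
        if int(n) != n or n < 0:
            raise ValueError(f"{what} stoichiometry for {sp!r} must be a nonnegative integer")
        if n > 0:
            out[sp] = int(n)
    return out


@dataclass(frozen=True)
class ReactionSpec:
    """One stochastic reaction.

    Parameters
    ----------
    reactants, products
        Species -> stoichiometric count (nonnegative integers).
    rate
        Rate constant (per time unit, mass-action convention: the propensity
        is ``rate * prod_i C(x_i, m_i)``), or :data:`INSTANT`, or a
        :class:`RepressionRate`, or a callable of the species-count mapping
        returning a nonnegative finite propensity factor.
    delays
        Per-product release-delay distribution; products not listed are
        released immediately.
    shared_delay
        If true, a single delay value is drawn per firing (from the first
        delayed product's distribution) and applied to every delayed
        product — e.g. transcription releases the promoter site and the
        transcript after the same interval.
    tracked_deltas
        Signed immediate count changes applied on firing that never enter
        any propensity.  Used for bookkeeping species such as the total
        subunit count X_i.
    priority
        Resolution priority among simultaneously applicable INSTANT
        reactions (higher fires first; ties broken lexically by product
        then reactant names).  Builders set it to the order of the multimer
        formed so that higher-order assembly wins.
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate: RateLike
    delays: Mapping[str, DelayDistribution] = field(default_factory=dict)
    shared_delay: bool = False
    tracked_deltas: Mapping[str, int] = field(default_factory=dict)
    priority: int = 0
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "reactants", _check_stoich(self.reactants, "reactant"))
        object.__setattr__(self, "products", _check_stoich(self.products, "product"))
        td = {sp: int(n) for sp, n in self.tracked_deltas.items() if int(n) == n and n != 0}
        object.__setattr__(self, "tracked_deltas", td)
        if not self.reactants and not self.products and not td:
            raise ValueError("reaction must touch at least one species")
        r = self.rate
        if isinstance(r, (int, float)):
            if not (r >= 0 and math.isfinite(r)):
                raise ValueError(f"rate must be nonnegative and finite, got {r!r}")
            object.__setattr__(self, "rate", float(r))
        elif not (r is INSTANT or isinstance(r, RepressionRate) or callable(r)):
            raise ValueError(f"unsupported rate {r!r}")
        for sp in self.delays:
            if sp not in self.products:
                raise ValueError(f"delay given for non-product species {sp!r}")

    @property
    def is_instant(self) -> bool:
        return self.rate is INSTANT


@dataclass
class SimulationState:
    """Mutable simulator state: clock, counts, and the release waitlist."""

    clock: float = 0.0
    counts: dict[str, int] = field(default_factory=dict)
    waitlist: list[tuple[float, str, int]] = field(default_factory=list)

    def copy(self) -> "SimulationState":
        return SimulationState(self.clock, dict(self.counts), list(self.waitlist))


@dataclass(frozen=True)
class TrajectorySample:
    """Copy-number snapshots of every species on a fixed sampling grid.

    ``counts`` has shape (n_species, n_grid); snapshots reflect the state
    immediately after any event occurring exactly at a sample time.
    """

    grid: np.ndarray
    species: tuple[str, ...]
    counts: np.ndarray
    seed: int

    def __post_init__(self):
        if self.counts.shape != (len(self.species), len(self.grid)):
            raise ValueError("counts shape must be (n_species, n_grid)")

    def __getitem__(self, species: str) -> np.ndarray:
        try:
            return self.counts[self.species.index(species)]
        except ValueError:
            raise KeyError(species) from None

    def get(self, species: str, default: int = 0) -> np.ndarray:
        """Series for ``species``, or a constant ``default`` series."""
        if species in self.species:
            return self[species]
        return np.full(len(self.grid), default, dtype=np.int64)

    def to_dataframe(self):
        """Tidy (time, species, count) table."""
        import pandas as pd

        n = len(self.grid)
        return pd.DataFrame(
            {
                "time": np.repeat(self.grid, len(self.species)),
                "species": np.tile(np.asarray(self.species, dtype=object), n),
                "count": self.counts.T.reshape(-1),
            }
        )


# ---------------------------------------------------------------------------
# model compilation
# ---------------------------------------------------------------------------

_LAW_CONST = 0
_LAW_REPRESSION = 1
_LAW_CALLABLE = 2


class CompiledModel:
    """Index-based form of a reaction list, shared by both backends."""

    def __init__(self, model: Sequence[ReactionSpec], extra_species: Sequence[str] = ()):
        species: set[str] = set(extra_species)
        for rx in model:
            species.update(rx.reactants, rx.products, rx.tracked_deltas)
            if isinstance(rx.rate, RepressionRate):
                species.add(rx.rate.repressor)
        self.species: tuple[str, ...] = tuple(sorted(species))
        self.index = {sp: i for i, sp in enumerate(self.species)}

        def sort_key(rx: ReactionSpec):
            return (-rx.priority, tuple(sorted(rx.products)), tuple(sorted(rx.reactants)))

        self.instant = sorted((rx for rx in model if rx.is_instant), key=sort_key)
        # zero-rate reactions can never fire; drop them from the propensity set
        self.finite = [
            rx for rx in model if not rx.is_instant and not (isinstance(rx.rate, float) and rx.rate == 0.0)
        ]
        self.has_callable = any(
            callable(rx.rate) and not isinstance(rx.rate, RepressionRate)
            for rx in self.finite
        )

    def _tables(self, reactions: list[ReactionSpec]):
        """Flatten reactions into CSR-style integer tables for the kernel."""
        re_off, re_sp, re_st = [0], [], []
        de_off, de_sp, de_dl = [0], [], []  # net immediate deltas (signed)
        dp_off, dp_sp, dp_ct, dp_fam, dp_p1, dp_p2, dp_new = [0], [], [], [], [], [], []
        law, rate, law_sp, law_K = [], [], [], []
        for rx in reactions:
            for sp, st in sorted(rx.reactants.items()):
                re_sp.append(self.index[sp])
                re_st.append(st)
            re_off.append(len(re_sp))
            delta: dict[str, int] = {}
            for sp, st in rx.reactants.items():
                delta[sp] = delta.get(sp, 0) - st
            delayed = []
            for sp, st in sorted(rx.products.items()):
                d = rx.delays.get(sp)
                if d is None or (d.family == "degenerate" and d.params[0] == 0.0):
                    delta[sp] = delta.get(sp, 0) + st
                else:
                    delayed.append((sp, st, d))
            for sp, dv in rx.tracked_deltas.items():
                delta[sp] = delta.get(sp, 0) + dv
            for sp in sorted(delta):
                if delta[sp] != 0:
                    de_sp.append(self.index[sp])
                    de_dl.append(delta[sp])
            de_off.append(len(de_sp))
            for j, (sp, st, d) in enumerate(delayed):
                dp_sp.append(self.index[sp])
                dp_ct.append(st)
                dp_fam.append(_FAMILIES[d.family])
                dp_p1.append(d.params[0])
                dp_p2.append(d.params[1] if len(d.params) > 1 else 0.0)
                dp_new.append(0 if (rx.shared_delay and j > 0) else 1)
            dp_off.append(len(dp_sp))
            if rx.is_instant:
                law.append(_LAW_CONST)
                rate.append(0.0)
                law_sp.append(0)
                law_K.append(1.0)
            elif isinstance(rx.rate, RepressionRate):
                law.append(_LAW_REPRESSION)
                rate.append(rx.rate.k_max)
                law_sp.append(self.index[rx.rate.repressor])
                law_K.append(rx.rate.K)
            elif isinstance(rx.rate, float):
                law.append(_LAW_CONST)
                rate.append(rx.rate)
                law_sp.append(0)
                law_K.append(1.0)
            else:
                law.append(_LAW_CALLABLE)
                rate.append(0.0)
                law_sp.append(0)
                law_K.append(1.0)
        ai = lambda v: np.asarray(v, dtype=np.int64)
        af = lambda v: np.asarray(v, dtype=np.float64)
        return dict(
            re_off=ai(re_off), re_sp=ai(re_sp), re_st=ai(re_st),
            de_off=ai(de_off), de_sp=ai(de_sp), de_dl=ai(de_dl),
            dp_off=ai(dp_off), dp_sp=ai(dp_sp), dp_ct=ai(dp_ct),
            dp_fam=ai(dp_fam), dp_p1=af(dp_p1), dp_p2=af(dp_p2), dp_new=ai(dp_new),
            law=ai(law), rate=af(rate), law_sp=ai(law_sp), law_K=af(law_K),
        )


def _combinations(x: int, m: int) -> float:
    """Number of distinct reactant combinations C(x, m)."""
    if x < m:
        return 0.0
    if m == 1:
        return float(x)
    if m == 2:
        return x * (x - 1) / 2.0
    return float(math.comb(x, m))


def _propensity(rx: ReactionSpec, counts: Mapping[str, int]) -> float:
    if callable(rx.rate):  # RepressionRate is also callable
        a = float(rx.rate(counts))
    else:
        a = rx.rate
    for sp, st in rx.reactants.items():
        a *= _combinations(counts.get(sp, 0), st)
    if not (a >= 0 and math.isfinite(a)):
        raise ArithmeticError(
            f"non-finite or negative propensity {a!r} for reaction {rx.name or rx!r}"
        )
    return a


def draw_delay(d: DelayDistribution, rng: np.random.Generator) -> float:
    """Draw one release delay; degenerate delays consume no randomness."""
    if d.family == "degenerate":
        return d.params[0]
    if d.family == "gamma":
        return float(rng.gamma(d.params[0], d.params[1]))
    # truncated normal by rejection
    while True:
        v = rng.normal(d.params[0], d.params[1])
        if v >= 0.0:
            return float(v)


_INSTANT_FIRE_LIMIT = 1_000_000


def resolve_instant_reactions(
    state: SimulationState,
    model: Sequence[ReactionSpec],
    rng: np.random.Generator | None = None,
) -> SimulationState:
    """Fire INSTANT reactions to exhaustion and return the settled state.

    Repeatedly fires one instance of the highest-priority applicable
    INSTANT reaction, rescanning from the top after every firing, until no
    INSTANT reaction is applicable.  Delayed products of instant reactions
    are pushed onto the waitlist (``rng`` is required if any such delay is
    random).  Raises ``RuntimeError`` on a non-terminating cascade.
    """
    state = state.copy()
    instant = CompiledModel(model).instant if any(rx.is_instant for rx in model) else []
    if not instant:
        return state
    counts = state.counts
    heap = list(state.waitlist)
    import heapq

    heapq.heapify(heap)
    fired = 0
    while True:
        for rx in instant:
            if all(counts.get(sp, 0) >= st for sp, st in rx.reactants.items()):
                _fire(rx, counts, state.clock, heap, rng)
                fired += 1
                if fired > _INSTANT_FIRE_LIMIT:
                    raise RuntimeError(
                        "instant-reaction cascade did not terminate "
                        f"(> {_INSTANT_FIRE_LIMIT} firings); the model likely contains "
                        "a cycle of INSTANT reactions"
                    )
                break
        else:
            break
    state.waitlist = sorted(heap)
    return state


def _fire(
    rx: ReactionSpec,
    counts: dict[str, int],
    clock: float,
    heap: list,
    rng: np.random.Generator | None,
) -> None:
    for sp, st in rx.reactants.items():
        counts[sp] = counts.get(sp, 0) - st
    shared: float | None = None
    for sp, st in sorted(rx.products.items()):
        d = rx.delays.get(sp)
        if d is None or (d.family == "degenerate" and d.params[0] == 0.0):
            counts[sp] = counts.get(sp, 0) + st
        else:
            if rx.shared_delay and shared is not None:
                tau = shared
            else:
                if d.family != "degenerate" and rng is None:
                    raise ValueError("an rng is required to draw random release delays")
                tau = draw_delay(d, rng) if d.family != "degenerate" else d.params[0]
                if rx.shared_delay:
                    shared = tau
            heappush(heap, (clock + tau, sp, st))
    for sp, dv in rx.tracked_deltas.items():
        counts[sp] = counts.get(sp, 0) + dv
    for sp, c in counts.items():
        if c < 0:
            raise RuntimeError(
                f"species {sp!r} driven negative by reaction {rx.name or rx!r}: "
                "stoichiometry bug"
            )


# ---------------------------------------------------------------------------
# simulation drivers
# ---------------------------------------------------------------------------


def _grid(t_end: float, dt: float) -> np.ndarray:
    n = int(math.floor(t_end / dt + 1e-9)) + 1
    return np.arange(n) * dt


def simulate(
    model: Sequence[ReactionSpec],
    initial: Mapping[str, int],
    t_end: float,
    sample_interval: float,
    seed: int,
    backend: str = "auto",
) -> TrajectorySample:
    """Run one exact delayed-SSA trajectory.

    Parameters
    ----------
    model
        Reactions; an empty list yields a constant trajectory.
    initial
        Initial copy numbers (missing species start at 0).
    t_end, sample_interval
        Simulation horizon and sampling interval; the state is recorded on
        the grid {0, dt, 2*dt, ..., t_end} (the transient is included).
    seed
        Seeds the single pseudo-random stream of the run; identical
        (model, initial, seed, backend) give bit-identical trajectories.
    backend
        "auto" (numba kernel when every rate is a constant, INSTANT or
        RepressionRate; pure-Python loop otherwise), "numba" or "python".
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    if not sample_interval > 0:
        raise ValueError("sample_interval must be positive")
    for sp, c in initial.items():
        if int(c) != c or c < 0:
            raise ValueError(f"initial count for {sp!r} must be a nonnegative integer")
    seed = int(seed)
    cm = CompiledModel(model, extra_species=list(initial))
    if backend == "auto":
        backend = "python" if cm.has_callable else "numba"
    if backend == "numba" and cm.has_callable:
        raise ValueError("models with Python-callable rates require the python backend")
    if backend == "numba":
        from ._kernel import run_compiled

        return run_compiled(cm, initial, t_end, sample_interval, seed)
    if backend != "python":
        raise ValueError(f"unknown backend {backend!r}")
    return _simulate_python(cm, initial, t_end, sample_interval, seed)


def _simulate_python(
    cm: CompiledModel,
    initial: Mapping[str, int],
    t_end: float,
    dt: float,
    seed: int,
) -> TrajectorySample:
    rng = np.random.default_rng(seed)
    grid = _grid(t_end, dt)
    n_grid = len(grid)
    counts: dict[str, int] = {sp: 0 for sp in cm.species}
    counts.update({sp: int(c) for sp, c in initial.items()})
    heap: list[tuple[float, str, int]] = []
    samples = np.zeros((len(cm.species), n_grid), dtype=np.int64)

    def settle(clock: float) -> None:
        fired = 0
        while True:
            for rx in cm.instant:
                if all(counts.get(sp, 0) >= st for sp, st in rx.reactants.items()):
                    _fire(rx, counts, clock, heap, rng)
                    fired += 1
                    if fired > _INSTANT_FIRE_LIMIT:
                        raise RuntimeError("instant-reaction cascade did not terminate")
                    break
            else:
                return

    t = 0.0
    settle(t)
    gi = 0
    while True:
        a = [_propensity(rx, counts) for rx in cm.finite]
        a0 = sum(a)
        t_rxn = t + rng.exponential(1.0 / a0) if a0 > 0 else math.inf
        t_wl = heap[0][0] if heap else math.inf
        t_ev = min(t_rxn, t_wl)
        while gi < n_grid and grid[gi] < t_ev - 1e-9:
            for sp, i in cm.index.items():
                samples[i, gi] = counts[sp]
            gi += 1
        if gi >= n_grid:
            break
        if t_wl <= t_rxn:
            t, sp, ct = heappop(heap)
            counts[sp] = counts.get(sp, 0) + ct
        else:
            t = t_rxn
            u = rng.random() * a0
            acc = 0.0
            ri = len(a) - 1
            for i, ai in enumerate(a):
                acc += ai
                if u < acc:
                    ri = i
                    break
            _fire(cm.finite[ri], counts, t, heap, rng)
        settle(t)
    return TrajectorySample(grid=grid, species=cm.species, counts=samples, seed=seed)
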
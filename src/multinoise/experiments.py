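"""Parameter-sweep drivers for the multimerization analysis.

Each driver reproduces one of the study's computations over a factorial
parameter grid: homodimer gains in mean and noise, heterodimer vs
doubled-rate homodimer, higher-order homomers (optionally with the
transcription rate scaled by the order to compensate the mean), the
monomer-multimer cross-correlation sweep, and the toggle-switch
mean-switching-time sweep.

The default grid is a deliberately coarse 3-point-per-parameter subsample
(d_M, k_M, k_P in {0.1, 1, 10}, alpha_M = 1, 10^4 time units) that keeps a
full sweep in the minutes range while preserving every qualitative
ordering; :meth:`SweepConfig.full_scale` selects the full-size study
conditions (9 log-spaced points per rate decade pair, alpha_M in
{1, 2, 3, 5, 10}, 10^5 time units).

Every row of a sweep table records the parameter values and the seed that
produced it, so any row can be recomputed in isolation.  By default the
tested and null models of a grid point share a seed (paired seeds) which
reduces the Monte-Carlo variance of their gain; set ``paired_seeds=False``
to disable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import gene_models as gm
from . import summary_stats as ss
from .stochastic_engine import simulate

__all__ = [
    "SweepConfig",
    "SweepResult",
    "run_homodimer_sweep",
    "run_heterodimer_sweep",
    "run_higher_order_sweep",
    "run_crosscorr_sweep",
    "run_toggle_sweep",
    "run_stationarity_check",
    "paper_c_grid",
]

_MOD = 2**31 - 1


def _seed(base: int, *indices: int) -> int:
    """Deterministic per-task seed below 2^31 derived from a base seed."""
    h = (int(base) + 1) * 2654435761 % _MOD
    for i in indices:
        h = (h * 40503 + int(i) + 1) % _MOD
    return h


@dataclass(frozen=True)
class SweepConfig:
    """Grids and simulation settings shared by the sweep drivers."""

    k_M_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    d_M_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    k_P_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    alpha_M_values: tuple[float, ...] = (1.0,)
    t_end: float = 1e4
    sample_interval: float = 1.0
    base_seed: int = 0
    paired_seeds: bool = True
    n_batches: int = 20

    def __post_init__(self):
        for name in ("k_M_grid", "d_M_grid", "k_P_grid", "alpha_M_values"):
            g = tuple(float(v) for v in getattr(self, name))
            if not g:
                raise ValueError(f"{name} must be nonempty")
            object.__setattr__(self, name, g)
        if not self.t_end > 0:
            raise ValueError("t_end must be positive")

    @classmethod
    def full_scale(cls, base_seed: int = 0) -> "SweepConfig":
        """The full-size study conditions (hours of compute)."""
        g = tuple(np.round(np.logspace(-1, 1, 9), 6))
        return cls(
            k_M_grid=g, d_M_grid=g, k_P_grid=g,
            alpha_M_values=(1.0, 2.0, 3.0, 5.0, 10.0),
            t_end=1e5, sample_interval=1.0, base_seed=base_seed,
        )

    def points(self) -> list[dict]:
        out = []
        for i, (k_M, d_M, k_P, a) in enumerate(
            itertools.product(self.k_M_grid, self.d_M_grid, self.k_P_grid, self.alpha_M_values)
        ):
            out.append({"index": i, "k_M": k_M, "d_M": d_M, "k_P": k_P, "alpha_M": a})
        return out


@dataclass
class SweepResult:
    """One row per parameter set, plus the config that produced it."""

    kind: str
    table: pd.DataFrame
    config: dict

    def to_csv(self, path) -> None:
        """Write the table as CSV with a JSON manifest sidecar."""
        path = Path(path)
        self.table.to_csv(path, index=False)
        manifest = {"kind": self.kind, "config": self.config, "rows": len(self.table)}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=2))


def _expr(pt: dict, k_M_factor: float = 1.0) -> gm.ExpressionParams:
    return gm.ExpressionParams(
        k_M=pt["k_M"] * k_M_factor, d_M=pt["d_M"], k_P=pt["k_P"], alpha_M=pt["alpha_M"]
    )


def _simulate_homomer(pt, order, cfg, seed, k_M_factor=1.0):
    model = gm.build_homomer_system(_expr(pt, k_M_factor), gm.MultimerParams(order=order))
    return simulate(model, gm.monomer_initial("1"), cfg.t_end, cfg.sample_interval, seed)


def _simulate_monomer(pt, cfg, seed, k_M_factor=1.0):
    model = gm.build_monomer_gene(_expr(pt, k_M_factor), "1")
    return simulate(model, gm.monomer_initial("1"), cfg.t_end, cfg.sample_interval, seed)


def _subunit_conservation(sample, gene: str, order: int) -> bool:
    """Exact identity X = sum_k k * P_{xk} at every sample time."""
    total = np.zeros(len(sample.grid), dtype=np.int64)
    for n in range(1, order + 1):
        total += n * sample.get(gm.homomer_species(gene, n))
    return bool(np.array_equal(total, sample.get(f"X{gene}")))


def _stats(series, n_batches):
    """(mean, mean SE, eta, eta SE); eta is NaN where undefined.

    At extreme low-expression grid points a multimer may never form in the
    whole run (all-zero series) — its noise is then undefined and reported
    as NaN rather than failing the grid point; batches with an undefined
    eta are likewise skipped in the batch-means SE.
    """
    x = np.asarray(series, dtype=float)
    mu = float(x.mean())
    mu_se = ss.batch_stat_se(x, np.mean, n_batches)
    if mu == 0:
        return mu, mu_se, np.nan, np.nan
    e = ss.eta(x)
    vals = [ss.eta(b) for b in np.array_split(x, n_batches) if b.mean() > 0]
    e_se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
    return mu, mu_se, e, e_se


def _safe_gain(tested, null, tested_se=0.0, null_se=0.0):
    """(gain, se), NaN when either statistic is undefined or the null is 0.

    A grid corner where a complex never forms has no defined ratio; the
    row stays usable with NaN gains instead of failing the sweep point.
    """
    if not (null and null > 0) or not np.isfinite(null) or not np.isfinite(tested):
        return np.nan, np.nan
    g = ss.gain(tested, null, "stat",
                tested_se if np.isfinite(tested_se) else 0.0,
                null_se if np.isfinite(null_se) else 0.0)
    return g.gain, g.gain_se


def _run_rows(points, worker) -> pd.DataFrame:
    rows = []
    for pt in points:
        row = dict(pt)
        try:
            row.update(worker(pt))
            row["status"] = "ok"
        except Exception as exc:  # a failed grid point must not kill the sweep
            row["status"] = f"error: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def run_homodimer_sweep(cfg: SweepConfig) -> SweepResult:
    """Homodimer (tested) vs monomer (null) gains in mean and noise.

    Reports gains for the dimer count P1x2, for the functional pool
    Y1 = P1 + P1x2, and the conservation flag X1 == P1 + 2 P1x2.
    """

    def worker(pt):
        seed = _seed(cfg.base_seed, 0, pt["index"])
        null_seed = seed if cfg.paired_seeds else _seed(cfg.base_seed, 1, pt["index"])
        null = _simulate_monomer(pt, cfg, null_seed)
        tested = _simulate_homomer(pt, 2, cfg, seed)
        nb = cfg.n_batches
        out = {"seed": seed, "null_seed": null_seed}
        mu0, mu0_se, e0, e0_se = _stats(null["P1"], nb)
        out.update(mu_x1_null=mu0, mu_x1_null_se=mu0_se, eta_x1_null=e0, eta_x1_null_se=e0_se)
        y1 = tested["P1"] + tested["P1x2"]
        for label, series in (("p11", tested["P1x2"]), ("y1", y1), ("x1", tested["X1"])):
            mu, mu_se, e, e_se = _stats(series, nb)
            out[f"mu_{label}"] = mu
            out[f"eta_{label}"] = e
            mg, mg_se = _safe_gain(mu, mu0, mu_se, mu0_se)
            eg, eg_se = _safe_gain(e, e0, e_se, e0_se)
            out[f"mean_gain_{label}"], out[f"mean_gain_{label}_se"] = mg, mg_se
            out[f"eta_gain_{label}"], out[f"eta_gain_{label}_se"] = eg, eg_se
        out["conserved"] = _subunit_conservation(tested, "1", 2)
        out["y1_identity"] = bool(np.array_equal(y1, tested["X1"] - tested["P1x2"]))
        return out

    return SweepResult("homodimer", _run_rows(cfg.points(), worker), asdict(cfg))


def run_heterodimer_sweep(cfg: SweepConfig) -> SweepResult:
    """Heterodimer (tested) vs doubled-k_M homodimer (null), plus the
    single-gene monomer reference.

    The homodimer null doubles the transcription rate to compensate for the
    heterodimer's two genes each producing subunits at rate k_M.
    """

    def worker(pt):
        seed = _seed(cfg.base_seed, 2, pt["index"])
        null_seed = seed if cfg.paired_seeds else _seed(cfg.base_seed, 3, pt["index"])
        mono_seed = seed if cfg.paired_seeds else _seed(cfg.base_seed, 4, pt["index"])
        p = _expr(pt)
        hetero_model = gm.build_heterodimer_system(p, p)
        hetero = simulate(hetero_model, gm.heterodimer_initial(), cfg.t_end,
                          cfg.sample_interval, seed)
        homo = _simulate_homomer(pt, 2, cfg, null_seed, k_M_factor=2.0)
        mono = _simulate_monomer(pt, cfg, mono_seed)
        nb = cfg.n_batches
        mu_h, mu_h_se, e_h, e_h_se = _stats(hetero["P1_2"], nb)
        mu_d, mu_d_se, e_d, e_d_se = _stats(homo["P1x2"], nb)
        mu_m, mu_m_se, e_m, e_m_se = _stats(mono["P1"], nb)
        mu_x1, _, e_x1, _ = _stats(hetero["X1"], nb)
        cons = bool(
            np.array_equal(hetero["X1"], hetero["P1"] + hetero["P1_2"])
            and np.array_equal(hetero["X2"], hetero["P2"] + hetero["P1_2"])
        )
        mr, mr_se = _safe_gain(mu_h, mu_d, mu_h_se, mu_d_se)
        er, _ = _safe_gain(e_h, e_d, e_h_se, e_d_se)
        ehm, ehm_se = _safe_gain(e_h, e_m, e_h_se, e_m_se)
        edm, edm_se = _safe_gain(e_d, e_m, e_d_se, e_m_se)
        mhm, _ = _safe_gain(mu_h, mu_m, mu_h_se, mu_m_se)
        mdm, _ = _safe_gain(mu_d, mu_m, mu_d_se, mu_m_se)
        return {
            "seed": seed, "null_seed": null_seed,
            "mu_hetero": mu_h, "eta_hetero": e_h,
            "mu_homo2km": mu_d, "eta_homo2km": e_d,
            "mu_monomer": mu_m, "eta_monomer": e_m,
            "mu_x1_hetero": mu_x1, "eta_x1_hetero": e_x1,
            "mean_ratio_hetero_homo": mr, "mean_ratio_hetero_homo_se": mr_se,
            "eta_ratio_hetero_homo": er,
            "eta_gain_hetero_vs_monomer": ehm, "eta_gain_hetero_vs_monomer_se": ehm_se,
            "eta_gain_homo2km_vs_monomer": edm, "eta_gain_homo2km_vs_monomer_se": edm_se,
            "mean_gain_hetero_vs_monomer": mhm,
            "mean_gain_homo2km_vs_monomer": mdm,
            "conserved": cons,
        }

    return SweepResult("heterodimer", _run_rows(cfg.points(), worker), asdict(cfg))


def run_higher_order_sweep(
    cfg: SweepConfig, orders: Sequence[int] = (2, 3, 4, 5), compensate: bool = False
) -> SweepResult:
    """Order-N homomer vs monomer gains for several orders.

    With ``compensate=True`` the homomer gene's k_M is multiplied by N so
    the multimer mean matches the monomer mean at high expression (the
    adjusted-rate comparison); without it the expression kinetics are
    identical and the mean gain is bounded by 1/N.
    """
    points = [dict(pt, order=N) for N in orders for pt in cfg.points()]

    def worker(pt):
        N = pt["order"]
        seed = _seed(cfg.base_seed, 5, pt["index"], N, int(compensate))
        null_seed = seed if cfg.paired_seeds else _seed(cfg.base_seed, 6, pt["index"], N)
        factor = float(N) if compensate else 1.0
        tested = _simulate_homomer(pt, N, cfg, seed, k_M_factor=factor)
        null = _simulate_monomer(pt, cfg, null_seed)
        nb = cfg.n_batches
        mu0, mu0_se, e0, e0_se = _stats(null["P1"], nb)
        top = tested[gm.homomer_species("1", N)]
        y = sum(tested.get(gm.homomer_species("1", n)) for n in range(1, N + 1))
        mu, mu_se, e, e_se = _stats(top, nb)
        mu_y, mu_y_se, e_y, e_y_se = _stats(y, nb)
        mg, mg_se = _safe_gain(mu, mu0, mu_se, mu0_se)
        eg, eg_se = _safe_gain(e, e0, e_se, e0_se)
        yg, yg_se = _safe_gain(e_y, e0, e_y_se, e0_se)
        return {
            "seed": seed, "null_seed": null_seed, "compensated": compensate,
            "mu_monomer": mu0, "eta_monomer": e0,
            "mu_multimer": mu, "eta_multimer": e,
            "mu_y1": mu_y, "eta_y1": e_y,
            "mean_gain_multimer": mg, "mean_gain_multimer_se": mg_se,
            "eta_gain_multimer": eg, "eta_gain_multimer_se": eg_se,
            "eta_gain_y1": yg, "eta_gain_y1_se": yg_se,
            "conserved": _subunit_conservation(tested, "1", N),
        }

    return SweepResult("higher_order", _run_rows(points, worker), asdict(cfg))


def run_crosscorr_sweep(
    cfg: SweepConfig, orders: Sequence[int] = (2, 3, 4, 5), max_lag: float = 30.0
) -> SweepResult:
    """Zero-lag cross-correlation and its half-life, per order and point.

    Correlates the total subunit count X1 (the quantity transcription
    controls directly) with the top multimer count P1xN; with instant
    association and no dissociation the free-monomer count is only the
    assembly remainder X1 mod N, so X1 is the meaningful monomer-side
    series.  The study samples this experiment at 0.1 time-unit intervals.
    """
    points = [dict(pt, order=N) for N in orders for pt in cfg.points()]

    def worker(pt):
        N = pt["order"]
        seed = _seed(cfg.base_seed, 7, pt["index"], N)
        if N == 1:
            sample = _simulate_monomer(pt, cfg, seed)
            x = mult = sample["P1"]
        else:
            sample = _simulate_homomer(pt, N, cfg, seed)
            x = sample["X1"]
            mult = sample[gm.homomer_species("1", N)]
        res = ss.cross_correlation(x, mult, max_lag=max_lag, dt=cfg.sample_interval)
        peak_at_zero = bool(res.zero_lag >= res.cc.max() - 1e-9)
        return {
            "seed": seed,
            "zero_lag_cc": res.zero_lag,
            "half_life": res.half_life,
            "peak_at_zero": peak_at_zero,
            "conserved": True if N == 1 else _subunit_conservation(sample, "1", N),
        }

    return SweepResult("crosscorr", _run_rows(points, worker), asdict(cfg))


def paper_c_grid() -> np.ndarray:
    """The study's repression-scale grid {a 10^b : a in 1..9, b in -4..4}."""
    return np.sort(np.concatenate([np.arange(1, 10) * 10.0**b for b in range(-4, 5)]))


def run_toggle_sweep(
    orders: Sequence[int] = (1, 2, 3),
    C_grid: Iterable[float] = (1e-3, 1.0, 1e3),
    n_samples: int = 100_000,
    sample_interval: float = 1.0 / 30.0,
    replicates: int = 1,
    base_seed: int = 0,
) -> SweepResult:
    """Mean switching time of the multimer toggle switch per (order, C).

    Each (N, C) pair is simulated ``replicates`` times; completed dwell
    times are pooled across replicates before averaging, which keeps the
    estimate usable in the strong-repression regime where a single run of
    ``n_samples`` may contain only a few switches.  Rows with fewer than
    two switches overall report NaN and are flagged.
    """
    t_end = n_samples * sample_interval
    rows = []
    for N in orders:
        for ci, C in enumerate(C_grid):
            t = gm.ToggleParams.standard(N, C)
            model = gm.build_toggle_switch(t)
            rep1, rep2 = t.repressor("1"), t.repressor("2")
            dwells = []
            n_switches = 0
            seeds = []
            for r in range(replicates):
                seed = _seed(base_seed, 8, N, ci, r)
                seeds.append(seed)
                sample = simulate(model, {}, t_end, sample_interval, seed)
                sw = ss.switch_indices(sample[rep1], sample[rep2])
                n_switches += len(sw)
                if len(sw) >= 2:
                    dwells.append(np.diff(sw[:, 0]) * sample_interval)
            pooled = np.concatenate(dwells) if dwells else np.empty(0)
            total_time = t_end * replicates
            rows.append({
                "order": N, "C": C, "K": t.K, "k_M_max": t.k_M_max,
                "seeds": ",".join(map(str, seeds)),
                "n_switches": n_switches,
                "n_dwells": len(pooled),
                "mean_switching_time": float(pooled.mean()) if len(pooled) else np.nan,
                # censoring-robust estimate: observed time per observed switch
                "time_per_switch": total_time / n_switches if n_switches else np.nan,
                "total_time": total_time,
                "status": "ok" if len(pooled) else "error: fewer than 2 switches",
            })
    config = {
        "orders": list(orders), "C_grid": [float(c) for c in C_grid],
        "n_samples": n_samples, "sample_interval": sample_interval,
        "replicates": replicates, "base_seed": base_seed,
    }
    return SweepResult("toggle", pd.DataFrame(rows), config)


def run_stationarity_check(
    pt: dict | None = None,
    order: int = 2,
    n_replicates: int = 200,
    t_end: float = 100.0,
    sample_interval: float = 1.0,
    base_seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Replicate-ensemble stationarity fraction for a homomer model.

    Simulates ``n_replicates`` independent trajectories of the order-N
    homomer at one parameter point (default k_M = d_M = k_P = 1, the
    sweeps' central point) and returns the fraction of sample times whose
    cross-replicate multimer-count distribution is indistinguishable from
    the final-time distribution (two-sample KS at level ``alpha``).
    """
    pt = dict(index=0, k_M=1.0, d_M=1.0, k_P=1.0, alpha_M=1.0) | (pt or {})
    model = gm.build_homomer_system(_expr(pt), gm.MultimerParams(order=order))
    top = gm.homomer_species("1", order)
    reps = []
    for r in range(n_replicates):
        seed = _seed(base_seed, 9, r)
        sample = simulate(model, gm.monomer_initial("1"), t_end, sample_interval, seed)
        reps.append(sample[top])
    return ss.stationarity_fraction(np.vstack(reps), alpha=alpha)
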
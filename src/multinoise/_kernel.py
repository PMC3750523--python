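"""Numba implementation of the delayed-SSA inner loop.

Semantics are identical to the pure-Python loop in ``stochastic_engine``:
direct-method next-reaction selection, a binary-heap waitlist for delayed
product release, and a one-firing-at-a-time priority fixpoint for INSTANT
reactions.  Only models whose rates are constants, INSTANT, or the
structured repression law can be compiled here; arbitrary Python-callable
rates run on the Python backend.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from numba import njit

from .stochastic_engine import CompiledModel, TrajectorySample, _grid

# error codes returned by the kernel
_ERR_OK = 0
_ERR_INSTANT_CYCLE = 1
_ERR_NEGATIVE = 2
_ERR_NONFINITE = 3

_INSTANT_FIRE_LIMIT = 1_000_000


@njit(cache=True)
def _heap_push(wt, wsp, wct, n, t, sp, ct):
    if n >= wt.shape[0]:
        m = wt.shape[0] * 2
        nwt = np.empty(m, np.float64)
        nwsp = np.empty(m, np.int64)
        nwct = np.empty(m, np.int64)
        nwt[:n] = wt[:n]
        nwsp[:n] = wsp[:n]
        nwct[:n] = wct[:n]
        wt, wsp, wct = nwt, nwsp, nwct
    i = n
    wt[i] = t
    wsp[i] = sp
    wct[i] = ct
    while i > 0:
        p = (i - 1) // 2
        if wt[p] <= wt[i]:
            break
        wt[p], wt[i] = wt[i], wt[p]
        wsp[p], wsp[i] = wsp[i], wsp[p]
        wct[p], wct[i] = wct[i], wct[p]
        i = p
    return wt, wsp, wct, n + 1


@njit(cache=True)
def _heap_pop(wt, wsp, wct, n):
    t, sp, ct = wt[0], wsp[0], wct[0]
    n -= 1
    wt[0], wsp[0], wct[0] = wt[n], wsp[n], wct[n]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        s = i
        if l < n and wt[l] < wt[s]:
            s = l
        if r < n and wt[r] < wt[s]:
            s = r
        if s == i:
            break
        wt[s], wt[i] = wt[i], wt[s]
        wsp[s], wsp[i] = wsp[i], wsp[s]
        wct[s], wct[i] = wct[i], wct[s]
        i = s
    return t, sp, ct, n


@njit(cache=True)
def _draw_delay(fam, p1, p2):
    if fam == 0:  # degenerate; no randomness consumed
        return p1
    if fam == 1:  # gamma(shape, scale)
        return np.random.gamma(p1, p2)
    while True:  # normal truncated at zero by rejection
        v = np.random.normal(p1, p2)
        if v >= 0.0:
            return v


@njit(cache=True)
def _fire(
    ri, t, x,
    de_off, de_sp, de_dl,
    dp_off, dp_sp, dp_ct, dp_fam, dp_p1, dp_p2, dp_new,
    wt, wsp, wct, wn,
):
    err = 0
    for j in range(de_off[ri], de_off[ri + 1]):
        sp = de_sp[j]
        x[sp] += de_dl[j]
        if x[sp] < 0:
            err = _ERR_NEGATIVE
    tau = 0.0
    for j in range(dp_off[ri], dp_off[ri + 1]):
        if dp_new[j] == 1:
            tau = _draw_delay(dp_fam[j], dp_p1[j], dp_p2[j])
        wt, wsp, wct, wn = _heap_push(wt, wsp, wct, wn, t + tau, dp_sp[j], dp_ct[j])
    return err, wt, wsp, wct, wn


@njit(cache=True)
def _settle(
    t, x,
    ni, i_re_off, i_re_sp, i_re_st,
    i_de_off, i_de_sp, i_de_dl,
    i_dp_off, i_dp_sp, i_dp_ct, i_dp_fam, i_dp_p1, i_dp_p2, i_dp_new,
    wt, wsp, wct, wn,
):
    fired = 0
    progress = True
    while progress:
        progress = False
        for ri in range(ni):
            ok = True
            for j in range(i_re_off[ri], i_re_off[ri + 1]):
                if x[i_re_sp[j]] < i_re_st[j]:
                    ok = False
                    break
            if ok:
                err, wt, wsp, wct, wn = _fire(
                    ri, t, x,
                    i_de_off, i_de_sp, i_de_dl,
                    i_dp_off, i_dp_sp, i_dp_ct, i_dp_fam, i_dp_p1, i_dp_p2, i_dp_new,
                    wt, wsp, wct, wn,
                )
                if err != 0:
                    return err, wt, wsp, wct, wn
                fired += 1
                if fired > _INSTANT_FIRE_LIMIT:
                    return _ERR_INSTANT_CYCLE, wt, wsp, wct, wn
                progress = True
                break
    return 0, wt, wsp, wct, wn


@njit(cache=True)
def _run(
    x0, n_grid, dt, t_end,
    # finite reactions
    nr, law, rate, law_sp, law_K,
    re_off, re_sp, re_st,
    de_off, de_sp, de_dl,
    dp_off, dp_sp, dp_ct, dp_fam, dp_p1, dp_p2, dp_new,
    # instant reactions (priority-ordered)
    ni, i_re_off, i_re_sp, i_re_st,
    i_de_off, i_de_sp, i_de_dl,
    i_dp_off, i_dp_sp, i_dp_ct, i_dp_fam, i_dp_p1, i_dp_p2, i_dp_new,
    seed,
):
    np.random.seed(seed)
    x = x0.copy()
    n_species = x.shape[0]
    samples = np.zeros((n_grid, n_species), np.int64)
    a = np.zeros(nr, np.float64)
    wt = np.empty(1024, np.float64)
    wsp = np.empty(1024, np.int64)
    wct = np.empty(1024, np.int64)
    wn = 0
    t = 0.0
    err, wt, wsp, wct, wn = _settle(
        t, x, ni, i_re_off, i_re_sp, i_re_st, i_de_off, i_de_sp, i_de_dl,
        i_dp_off, i_dp_sp, i_dp_ct, i_dp_fam, i_dp_p1, i_dp_p2, i_dp_new,
        wt, wsp, wct, wn,
    )
    if err != 0:
        return samples.T, err, -1
    gi = 0
    while True:
        a0 = 0.0
        for ri in range(nr):
            if law[ri] == 1:
                v = rate[ri] / (1.0 + x[law_sp[ri]] / law_K[ri])
            else:
                v = rate[ri]
            for j in range(re_off[ri], re_off[ri + 1]):
                c = x[re_sp[j]]
                m = re_st[j]
                if c < m:
                    v = 0.0
                    break
                if m == 1:
                    v *= c
                elif m == 2:
                    v *= c * (c - 1) * 0.5
                else:
                    f = 1.0
                    for q in range(m):
                        f *= (c - q) / (q + 1)
                    v *= f
            if not (v >= 0.0 and np.isfinite(v)):
                return samples.T, _ERR_NONFINITE, ri
            a[ri] = v
            a0 += v
        if a0 > 0.0:
            t_rxn = t + np.random.exponential(1.0 / a0)
        else:
            t_rxn = np.inf
        t_wl = wt[0] if wn > 0 else np.inf
        t_ev = min(t_rxn, t_wl)
        while gi < n_grid and gi * dt < t_ev - 1e-9:
            for s in range(n_species):
                samples[gi, s] = x[s]
            gi += 1
        if gi >= n_grid:
            break
        if t_wl <= t_rxn:
            t, sp, ct, wn = _heap_pop(wt, wsp, wct, wn)
            x[sp] += ct
        else:
            t = t_rxn
            u = np.random.random() * a0
            acc = 0.0
            ri = nr - 1
            for i in range(nr):
                acc += a[i]
                if u < acc:
                    ri = i
                    break
            err, wt, wsp, wct, wn = _fire(
                ri, t, x, de_off, de_sp, de_dl,
                dp_off, dp_sp, dp_ct, dp_fam, dp_p1, dp_p2, dp_new,
                wt, wsp, wct, wn,
            )
            if err != 0:
                return samples.T, err, ri
        err, wt, wsp, wct, wn = _settle(
            t, x, ni, i_re_off, i_re_sp, i_re_st, i_de_off, i_de_sp, i_de_dl,
            i_dp_off, i_dp_sp, i_dp_ct, i_dp_fam, i_dp_p1, i_dp_p2, i_dp_new,
            wt, wsp, wct, wn,
        )
        if err != 0:
            return samples.T, err, -1
    return samples.T, _ERR_OK, -1


def run_compiled(
    cm: CompiledModel,
    initial: Mapping[str, int],
    t_end: float,
    dt: float,
    seed: int,
) -> TrajectorySample:
    grid = _grid(t_end, dt)
    x0 = np.zeros(len(cm.species), np.int64)
    for sp, c in initial.items():
        x0[cm.index[sp]] = int(c)
    fin = cm._tables(cm.finite)
    ins = cm._tables(cm.instant)
    counts, err, where = _run(
        x0, len(grid), float(dt), float(t_end),
        len(cm.finite), fin["law"], fin["rate"], fin["law_sp"], fin["law_K"],
        fin["re_off"], fin["re_sp"], fin["re_st"],
        fin["de_off"], fin["de_sp"], fin["de_dl"],
        fin["dp_off"], fin["dp_sp"], fin["dp_ct"],
        fin["dp_fam"], fin["dp_p1"], fin["dp_p2"], fin["dp_new"],
        len(cm.instant), ins["re_off"], ins["re_sp"], ins["re_st"],
        ins["de_off"], ins["de_sp"], ins["de_dl"],
        ins["dp_off"], ins["dp_sp"], ins["dp_ct"],
        ins["dp_fam"], ins["dp_p1"], ins["dp_p2"], ins["dp_new"],
        int(seed) % (2**32),
    )
    if err == _ERR_INSTANT_CYCLE:
        raise RuntimeError(
            "instant-reaction cascade did not terminate; the model likely "
            "contains a cycle of INSTANT reactions"
        )
    if err == _ERR_NEGATIVE:
        name = cm.finite[where].name if 0 <= where < len(cm.finite) else "?"
        raise RuntimeError(f"species count driven negative (reaction {name!r}): stoichiometry bug")
    if err == _ERR_NONFINITE:
        name = cm.finite[where].name if 0 <= where < len(cm.finite) else "?"
        raise ArithmeticError(f"non-finite propensity in reaction {name!r}")
    return TrajectorySample(grid=grid, species=cm.species, counts=counts, seed=int(seed))
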
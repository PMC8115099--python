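"""Compiled per-step sweep over the lattice.

One function performs the randomized sequential update of every occupied
box (production, uptake, growth, death, division with mutation) so the hot
loop can be jit-compiled with numba.  The semantics mirror the scalar
reference operations in :mod:`bqsim.engine`; the module falls back to pure
Python (same code path, same numpy RNG calls) when numba is unavailable.

All randomness inside the sweep (visit order, threshold noise, daughter
placement, mutation) draws from one Mersenne-Twister stream seeded through
:func:`seed_kernel`; the simulation driver reseeds it from (run seed, step
index) before every sweep so concurrent simulations stay independent.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every simulation test
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _seed_impl(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


def seed_kernel(seed: int) -> None:
    """Seed the sweep's random stream (numba's when compiled, numpy's not)."""
    _seed_impl(np.int64(seed))


@njit(cache=True)
def _sweep(geno, bio, S, P,
           alpha, b0, b1, b2, mut,
           g_max, d_max, base_death, eps_amp,
           K_S, K_P, yield_S, dt,
           div_thr, death_thr, bio_cap,
           moore, monod, ev_buf):
    L = geno.shape[0]
    beta = np.empty(3)
    beta[0], beta[1], beta[2] = b0, b1, b2

    # collect occupied boxes, then visit them in a fresh random permutation
    n = 0
    rows = np.empty(L * L, np.int64)
    cols = np.empty(L * L, np.int64)
    for i in range(L):
        for j in range(L):
            if geno[i, j] >= 0:
                rows[n] = i
                cols[n] = j
                n += 1
    order = np.arange(n)
    np.random.shuffle(order)

    nbr_r = np.empty(8, np.int64)
    nbr_c = np.empty(8, np.int64)
    n_offsets = 8 if moore else 4
    off_r = np.array([-1, 1, 0, 0, -1, -1, 1, 1], np.int64)
    off_c = np.array([0, 0, -1, 1, -1, 1, -1, 1], np.int64)

    n_ev = 0
    for k in range(n):
        r = rows[order[k]]
        c = cols[order[k]]
        g = geno[r, c]
        if g < 0:
            continue
        if base_death > 0.0 and np.random.random() < base_death * dt:
            geno[r, c] = -1
            bio[r, c] = 0.0
            continue
        X = bio[r, c]

        # production of carried goods
        for j in range(3):
            if (g >> (2 - j)) & 1:
                P[j, r, c] += alpha * X * dt

        # uptake of non-carried goods; track the scarcest fulfillment
        smin = 1.0
        for j in range(3):
            if (g >> (2 - j)) & 1:
                continue
            pj = P[j, r, c]
            R = beta[j] * alpha * X * dt
            if monod:
                s = pj / (K_P + pj)
            else:
                s = 1.0 if R <= 0.0 else min(pj, R) / R
            if R > 0.0:
                u = min(pj, R)
                P[j, r, c] = pj - u
            if s < smin:
                smin = s

        # substrate-limited growth
        s_here = S[r, c]
        g_pot = g_max * s_here / (K_S + s_here)
        uptake = g_pot * X * dt / yield_S
        if uptake > s_here:
            uptake = s_here
            g_real = uptake * yield_S / (X * dt)
        else:
            g_real = g_pot
        S[r, c] = s_here - uptake

        n_func = ((g >> 2) & 1) + ((g >> 1) & 1) + (g & 1)
        C = alpha * n_func
        G = d_max * smin
        X = X + ((g_real - C) - (d_max - G)) * X * dt

        # death against the noisy lower threshold
        eps = 0.0
        if eps_amp > 0.0:
            eps = (2.0 * np.random.random() - 1.0) * eps_amp
        if X <= 0.0 or X < death_thr + eps:
            geno[r, c] = -1
            bio[r, c] = 0.0
            continue

        # division against the noisy upper threshold
        eps = 0.0
        if eps_amp > 0.0:
            eps = (2.0 * np.random.random() - 1.0) * eps_amp
        if X >= div_thr + eps:
            n_empty = 0
            for m in range(n_offsets):
                nr = (r + off_r[m]) % L
                nc = (c + off_c[m]) % L
                if geno[nr, nc] < 0:
                    nbr_r[n_empty] = nr
                    nbr_c[n_empty] = nc
                    n_empty += 1
            if n_empty == 0:
                if X > bio_cap:  # contact inhibition: defer, cap biomass
                    X = bio_cap
            else:
                pick = np.random.randint(0, n_empty)
                nr = nbr_r[pick]
                nc = nbr_c[pick]
                X *= 0.5
                child = g
                if mut > 0.0:
                    for j in range(3):
                        bit = 1 << (2 - j)
                        if (child & bit) and np.random.random() < mut:
                            child = child & ~bit
                geno[nr, nc] = child
                bio[nr, nc] = X
                if child != g:
                    ev_buf[n_ev, 0] = child
                    ev_buf[n_ev, 1] = g
                    ev_buf[n_ev, 2] = nr
                    ev_buf[n_ev, 3] = nc
                    n_ev += 1
        bio[r, c] = X
    return n_ev


@njit(cache=True)
def _diffuse_field(f, lam, out):
    L = f.shape[0]
    for i in range(L):
        im = i - 1 if i > 0 else L - 1
        ip = i + 1 if i < L - 1 else 0
        for j in range(L):
            jm = j - 1 if j > 0 else L - 1
            jp = j + 1 if j < L - 1 else 0
            lap = f[im, j] + f[ip, j] + f[i, jm] + f[i, jp] - 4.0 * f[i, j]
            out[i, j] = f[i, j] + lam * lap


def diffuse_inplace(field, lam, scratch) -> None:
    """Fast periodic 5-point diffusion step; same arithmetic as the
    reference :func:`bqsim.diffusion.diffuse` (term order preserved, so
    results agree bit-for-bit)."""
    _diffuse_field(field, float(lam), scratch)
    field[:] = scratch


def sweep_kernel(geno, bio, S, P, alpha, b0, b1, b2, mut, g_max, d_max,
                 base_death, eps_amp, K_S, K_P, yield_S, dt, div_thr,
                 death_thr, bio_cap, moore, monod, ev_buf) -> int:
    """Run one randomized sequential sweep in place; returns event count."""
    return _sweep(geno, bio, S, P, float(alpha), float(b0), float(b1),
                  float(b2), float(mut), float(g_max), float(d_max),
                  float(base_death), float(eps_amp), float(K_S), float(K_P),
                  float(yield_S), float(dt), float(div_thr), float(death_thr),
                  float(bio_cap), bool(moore), bool(monod), ev_buf)
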
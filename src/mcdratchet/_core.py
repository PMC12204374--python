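"""Numba kernels for the Brownian-ratchet simulation loop.

Everything in the per-step hot path lives here as nopython-compiled
functions operating on plain numpy arrays.  The Python-facing state and
parameter objects are in engine.py / params.py; they pack down to the
arrays and the parameter vector consumed here.

Randomness: one counter-based splitmix64 stream per trajectory, carried as
a single uint64 in ``rng[0]``.  Every stochastic sub-step draws from this
stream in a fixed iteration order (particles by id, McdB sites by
(carboxysome, site) index), so a (params, seed) pair fully determines the
run.  Normals come from Box-Muller on two stream draws.

Parameter vector layout (internal units nm, s, pN): see the ``I_*`` index
constants below.  Per-step transition probabilities 1 - exp(-rate*dt) are
precomputed in the vector.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# -- parameter-vector indices (internal units: nm, s, pN) --
I_LX = 0          # nucleoid length (nm)
I_LY = 1          # nucleoid width (nm)
I_A = 2           # lattice spacing (nm)
I_DIAM = 3        # carboxysome hard-core diameter (nm)
I_P_HOP = 4       # per-step hop attempt probability (4 D_A / a^2) * dt
I_P_REBIND = 5    # per-step rebind probability
I_P_OFF = 6       # per-step intrinsic unbinding probability
I_P_BON = 7       # per-step bond formation probability
I_P_BOFF = 8      # per-step bond break probability
I_KAB = 9         # bond stiffness (pN/nm)
I_KSELF = 10      # self-association stiffness (pN/nm)
I_REST_SELF = 11  # self-association rest length (nm)
I_SELF_RANGE = 12 # self-association engagement cutoff (nm)
I_MAXEXT = 13     # bond hard-guard extension (nm)
I_CAPR = 14       # bond capture radius (nm)
I_DT = 15         # time step (s)
I_SQ2DDT = 16     # sqrt(2 D_carb dt) (nm)
I_MOBDT = 17      # dt / gamma = D_carb * dt / kBT (nm / pN)
I_REST_AB = 18    # bond rest length (nm)
NPAR = 19

_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_M1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_M2 = np.uint64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _next_u64(rng):
    rng[0] = rng[0] + _SM_GAMMA
    z = rng[0]
    z = (z ^ (z >> np.uint64(30))) * _SM_M1
    z = (z ^ (z >> np.uint64(27))) * _SM_M2
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def rand_u(rng):
    """Uniform double in [0, 1) from the top 53 bits of splitmix64."""
    return float(_next_u64(rng) >> np.uint64(11)) * _INV53


@njit(cache=True, inline="always")
def rand_n(rng):
    """Standard normal via Box-Muller (cosine branch)."""
    u1 = rand_u(rng)
    if u1 < 1e-300:
        u1 = 1e-300
    u2 = rand_u(rng)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)


@njit(cache=True)
def hop(P, occ, a_site, a_bond_carb, rng):
    """Lattice hopping of unbonded nucleoid McdA; hops into occupied or
    out-of-bounds sites are rejected (hard-bounded exclusion lattice)."""
    nx, ny = occ.shape
    p = P[I_P_HOP]
    if p <= 0.0:
        return
    for i in range(a_site.shape[0]):
        if a_site[i, 0] < 0 or a_bond_carb[i] >= 0:
            continue
        if rand_u(rng) < p:
            d = int(rand_u(rng) * 4.0)
            ix, iy = a_site[i, 0], a_site[i, 1]
            jx, jy = ix, iy
            if d == 0:
                jx = ix + 1
            elif d == 1:
                jx = ix - 1
            elif d == 2:
                jy = iy + 1
            else:
                jy = iy - 1
            if 0 <= jx < nx and 0 <= jy < ny and occ[jx, jy] < 0:
                occ[ix, iy] = -1
                occ[jx, jy] = i
                a_site[i, 0] = jx
                a_site[i, 1] = jy


@njit(cache=True)
def rebind(P, occ, a_site, rng):
    """Cytoplasm -> nucleoid rebinding onto a uniformly random empty site.

    Sampling is by rejection (the lattice is never near full in practice);
    after 200 misses the empty sites are enumerated and one drawn uniformly,
    so a crowded lattice still gives each empty site equal probability.  A
    full lattice leaves the particle cytoplasmic.
    """
    nx, ny = occ.shape
    p = P[I_P_REBIND]
    if p <= 0.0:
        return
    for i in range(a_site.shape[0]):
        if a_site[i, 0] >= 0:
            continue
        if rand_u(rng) < p:
            placed = False
            for _ in range(200):
                ix = int(rand_u(rng) * nx)
                iy = int(rand_u(rng) * ny)
                if occ[ix, iy] < 0:
                    occ[ix, iy] = i
                    a_site[i, 0] = ix
                    a_site[i, 1] = iy
                    placed = True
                    break
            if not placed:
                nempty = 0
                for ix in range(nx):
                    for iy in range(ny):
                        if occ[ix, iy] < 0:
                            nempty += 1
                if nempty == 0:
                    continue
                k = int(rand_u(rng) * nempty)
                for ix in range(nx):
                    for iy in range(ny):
                        if occ[ix, iy] < 0:
                            if k == 0:
                                occ[ix, iy] = i
                                a_site[i, 0] = ix
                                a_site[i, 1] = iy
                                placed = True
                            k -= 1
                        if placed:
                            break
                    if placed:
                        break


@njit(cache=True)
def unbind_intrinsic(P, occ, a_site, a_bond_carb, rng):
    """Intrinsic nucleoid release of unbonded McdA into the cytoplasm."""
    p = P[I_P_OFF]
    if p <= 0.0:
        return
    for i in range(a_site.shape[0]):
        if a_site[i, 0] < 0 or a_bond_carb[i] >= 0:
            continue
        if rand_u(rng) < p:
            occ[a_site[i, 0], a_site[i, 1]] = -1
            a_site[i, 0] = -1
            a_site[i, 1] = -1


@njit(cache=True)
def form_bonds(P, occ, a_site, a_bond_carb, a_bond_site, centers, offsets,
               site_bond, rng):
    """Bond formation between free McdB sites and nearby nucleoid McdA.

    Each free McdB site considers its nearest free, unbonded nucleoid McdA
    within the capture radius and attempts to bind with the per-step
    probability.  When several sites compete for one McdA the pair with the
    smallest separation wins (then lowest site index); the losing site
    falls through to its next-nearest candidate.  Implemented by sorting
    all in-range (site, McdA) pairs by distance and sweeping greedily with
    a one-attempt-per-site rule.
    """
    ncarb, nsites = site_bond.shape
    nx, ny = occ.shape
    a = P[I_A]
    capr = P[I_CAPR]
    p_on = P[I_P_BON]
    if p_on <= 0.0:
        return
    capr2 = capr * capr

    max_pairs = ncarb * nsites * 16
    dist = np.empty(max_pairs, np.float64)
    psite = np.empty(max_pairs, np.int64)
    pa = np.empty(max_pairs, np.int64)
    m = 0
    for c in range(ncarb):
        for s in range(nsites):
            if site_bond[c, s] >= 0:
                continue
            px = centers[c, 0] + offsets[c, s, 0]
            py = centers[c, 1] + offsets[c, s, 1]
            ix0 = int(np.floor((px - capr) / a - 0.5))
            ix1 = int(np.ceil((px + capr) / a - 0.5))
            iy0 = int(np.floor((py - capr) / a - 0.5))
            iy1 = int(np.ceil((py + capr) / a - 0.5))
            if ix0 < 0:
                ix0 = 0
            if iy0 < 0:
                iy0 = 0
            if ix1 > nx - 1:
                ix1 = nx - 1
            if iy1 > ny - 1:
                iy1 = ny - 1
            for ix in range(ix0, ix1 + 1):
                for iy in range(iy0, iy1 + 1):
                    ai = occ[ix, iy]
                    if ai < 0 or a_bond_carb[ai] >= 0:
                        continue
                    dx = (ix + 0.5) * a - px
                    dy = (iy + 0.5) * a - py
                    d2 = dx * dx + dy * dy
                    if d2 <= capr2 and m < max_pairs:
                        dist[m] = np.sqrt(d2)
                        psite[m] = c * nsites + s
                        pa[m] = ai
                        m += 1
    if m == 0:
        return
    # composite sort key: distance, then site index, then McdA id.
    # The index terms only matter for ties below ~1e-6 nm, i.e. exact
    # geometric ties; they keep the sweep fully deterministic.
    key = dist[:m] + psite[:m] * 1e-7 + pa[:m] * 1e-11
    order = np.argsort(key)
    attempted = np.zeros(ncarb * nsites, np.uint8)
    for oi in range(m):
        o = order[oi]
        gs = psite[o]
        ai = pa[o]
        if attempted[gs]:
            continue
        if a_bond_carb[ai] >= 0:
            continue  # taken by a nearer site; this site tries its next pair
        attempted[gs] = 1
        if rand_u(rng) < p_on:
            c = gs // nsites
            s = gs % nsites
            a_bond_carb[ai] = c
            a_bond_site[ai] = s
            site_bond[c, s] = ai


@njit(cache=True)
def bond_forces(P, centers, offsets, site_bond, a_site, f):
    """Accumulate Hookean bond forces on each carboxysome into f.

    Each bond pulls the McdB site toward the McdA lattice anchor with
    force -k_AB * (extension - rest_length) along the separation (rest
    length 0 by default: a pure tether)."""
    ncarb, nsites = site_bond.shape
    a = P[I_A]
    kab = P[I_KAB]
    rest = P[I_REST_AB]
    for c in range(ncarb):
        for s in range(nsites):
            ai = site_bond[c, s]
            if ai < 0:
                continue
            px = centers[c, 0] + offsets[c, s, 0]
            py = centers[c, 1] + offsets[c, s, 1]
            dx = px - (a_site[ai, 0] + 0.5) * a
            dy = py - (a_site[ai, 1] + 0.5) * a
            if rest > 0.0:
                r = np.sqrt(dx * dx + dy * dy)
                if r > 1e-12:
                    scale = kab * (r - rest) / r
                    f[c, 0] -= scale * dx
                    f[c, 1] -= scale * dy
            else:
                f[c, 0] -= kab * dx
                f[c, 1] -= kab * dy


@njit(cache=True)
def self_forces(P, centers, f):
    """Accumulate pairwise self-association spring forces into f.

    Engaged only while the center distance is within self_range; restoring
    toward the contact rest length, equal and opposite on the pair."""
    ncarb = centers.shape[0]
    kself = P[I_KSELF]
    rest = P[I_REST_SELF]
    rng_cut = P[I_SELF_RANGE]
    for c in range(ncarb):
        for d in range(c + 1, ncarb):
            dx = centers[d, 0] - centers[c, 0]
            dy = centers[d, 1] - centers[c, 1]
            r = np.sqrt(dx * dx + dy * dy)
            if r <= rng_cut and r > 1e-12:
                fmag = kself * (r - rest)  # >0 attracts, <0 restores to contact
                ux = dx / r
                uy = dy / r
                f[c, 0] += fmag * ux
                f[c, 1] += fmag * uy
                f[d, 0] -= fmag * ux
                f[d, 1] -= fmag * uy


@njit(cache=True)
def self_force_pairs(P, centers, table):
    """Per-pair self-association forces for momentum bookkeeping.

    table has shape (n_pairs, 2, 2): force on the lower-index member and on
    the higher-index member of each (c, d) pair, c < d in row-major order."""
    ncarb = centers.shape[0]
    kself = P[I_KSELF]
    rest = P[I_REST_SELF]
    rng_cut = P[I_SELF_RANGE]
    idx = 0
    for c in range(ncarb):
        for d in range(c + 1, ncarb):
            dx = centers[d, 0] - centers[c, 0]
            dy = centers[d, 1] - centers[c, 1]
            r = np.sqrt(dx * dx + dy * dy)
            table[idx, 0, 0] = 0.0
            table[idx, 0, 1] = 0.0
            table[idx, 1, 0] = 0.0
            table[idx, 1, 1] = 0.0
            if r <= rng_cut and r > 1e-12:
                fmag = kself * (r - rest)
                ux = dx / r
                uy = dy / r
                table[idx, 0, 0] = fmag * ux
                table[idx, 0, 1] = fmag * uy
                table[idx, 1, 0] = -fmag * ux
                table[idx, 1, 1] = -fmag * uy
            idx += 1


@njit(cache=True, inline="always")
def _reflect(x, lo, hi):
    # specular reflection into [lo, hi]; loop handles large excursions
    for _ in range(64):
        if x < lo:
            x = 2.0 * lo - x
        elif x > hi:
            x = 2.0 * hi - x
        else:
            break
    if x < lo:
        x = lo
    elif x > hi:
        x = hi
    return x


@njit(cache=True)
def displace(P, centers, f, rng):
    """Overdamped Euler-Maruyama displacement, then hard-core overlap
    resolution and specular boundary reflection.

    Returns True if all coordinates stayed finite.  Overlap resolution and
    reflection are alternated a few times so neither correction reintroduces
    the other's violation at step scale."""
    ncarb = centers.shape[0]
    mobdt = P[I_MOBDT]
    noise = P[I_SQ2DDT]
    for c in range(ncarb):
        centers[c, 0] += f[c, 0] * mobdt + noise * rand_n(rng)
        centers[c, 1] += f[c, 1] * mobdt + noise * rand_n(rng)
    diam = P[I_DIAM]
    lx = P[I_LX]
    ly = P[I_LY]
    for _ in range(4):
        moved = False
        for c in range(ncarb):
            for d in range(c + 1, ncarb):
                dx = centers[d, 0] - centers[c, 0]
                dy = centers[d, 1] - centers[c, 1]
                r = np.sqrt(dx * dx + dy * dy)
                if r < diam:
                    if r < 1e-9:
                        # coincident centers: separate along x deterministically
                        dx, dy, r = 1.0, 0.0, 1.0
                    push = 0.5 * (diam - r)
                    ux = dx / r
                    uy = dy / r
                    centers[c, 0] -= push * ux
                    centers[c, 1] -= push * uy
                    centers[d, 0] += push * ux
                    centers[d, 1] += push * uy
                    moved = True
        for c in range(ncarb):
            xr = _reflect(centers[c, 0], 0.0, lx)
            yr = _reflect(centers[c, 1], 0.0, ly)
            if xr != centers[c, 0] or yr != centers[c, 1]:
                moved = True
                centers[c, 0] = xr
                centers[c, 1] = yr
        if not moved:
            break
    ok = True
    for c in range(ncarb):
        if not (np.isfinite(centers[c, 0]) and np.isfinite(centers[c, 1])):
            ok = False
    return ok


@njit(cache=True)
def break_bonds(P, occ, a_site, a_bond_carb, a_bond_site, centers, offsets,
                site_bond, rng):
    """Stochastic bond breaking, plus the hard over-extension guard.

    A break ejects the McdA straight to the cytoplasm (stimulated release
    idealized as instantaneous) and vacates its lattice site."""
    ncarb, nsites = site_bond.shape
    a = P[I_A]
    p_off = P[I_P_BOFF]
    maxext2 = P[I_MAXEXT] * P[I_MAXEXT]
    for c in range(ncarb):
        for s in range(nsites):
            ai = site_bond[c, s]
            if ai < 0:
                continue
            px = centers[c, 0] + offsets[c, s, 0]
            py = centers[c, 1] + offsets[c, s, 1]
            dx = px - (a_site[ai, 0] + 0.5) * a
            dy = py - (a_site[ai, 1] + 0.5) * a
            ext2 = dx * dx + dy * dy
            if ext2 > maxext2 or (p_off > 0.0 and rand_u(rng) < p_off):
                site_bond[c, s] = -1
                a_bond_carb[ai] = -1
                a_bond_site[ai] = -1
                occ[a_site[ai, 0], a_site[ai, 1]] = -1
                a_site[ai, 0] = -1
                a_site[ai, 1] = -1


@njit(cache=True)
def step_once(P, occ, a_site, a_bond_carb, a_bond_site, centers, offsets,
              site_bond, f, rng):
    """One full time step in the fixed sub-step order:
    hops, rebinding, intrinsic unbinding, bond formation, forces,
    displacement (+ exclusion + reflection), bond breaking."""
    hop(P, occ, a_site, a_bond_carb, rng)
    rebind(P, occ, a_site, rng)
    unbind_intrinsic(P, occ, a_site, a_bond_carb, rng)
    form_bonds(P, occ, a_site, a_bond_carb, a_bond_site, centers, offsets,
               site_bond, rng)
    f[:] = 0.0
    bond_forces(P, centers, offsets, site_bond, a_site, f)
    self_forces(P, centers, f)
    ok = displace(P, centers, f, rng)
    break_bonds(P, occ, a_site, a_bond_carb, a_bond_site, centers, offsets,
                site_bond, rng)
    return ok


@njit(cache=True)
def run_steps(P, nsteps, rec_every, occ, a_site, a_bond_carb, a_bond_site,
              centers, offsets, site_bond, rng, rec_xy, rec_nb):
    """Advance nsteps, recording centers and live-bond counts every
    rec_every steps (slot k//rec_every; slot 0 is pre-filled by the caller
    with the initial state).  Returns 0 on success or the 1-based step
    index at which a non-finite coordinate appeared."""
    ncarb = centers.shape[0]
    nsites = site_bond.shape[1]
    f = np.zeros((ncarb, 2), np.float64)
    for k in range(1, nsteps + 1):
        ok = step_once(P, occ, a_site, a_bond_carb, a_bond_site, centers,
                       offsets, site_bond, f, rng)
        if not ok:
            return k
        if k % rec_every == 0:
            r = k // rec_every
            for c in range(ncarb):
                rec_xy[r, c, 0] = centers[c, 0]
                rec_xy[r, c, 1] = centers[c, 1]
                nb = 0
                for s in range(nsites):
                    if site_bond[c, s] >= 0:
                        nb += 1
                rec_nb[r, c] = nb
    return 0
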
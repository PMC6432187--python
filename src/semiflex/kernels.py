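"""Numba-compiled Monte Carlo engine.

All hot-loop code lives here: pair energies, local (range) energy sums,
move proposals and the sweep loop itself.  The Python-facing modules
(`models`, `moves`, `sampling`) are thin wrappers around these kernels.

Conventions
-----------
* positions: contiguous ``(N*M, 3)`` float64 array; chain ``c`` occupies
  rows ``[c*N, (c+1)*N)``.
* model parameters are passed as scalars; ``kind`` is 0 (bead-stick) or 1
  (bead-spring); ``L <= 0`` means "no box".
* minimal image is applied to *inter-chain* pair distances only; bond
  vectors and intra-chain pairs use plain differences (chains are stored
  unwrapped and their contour length is < L/2 by contract).
* a proposed move transforms a contiguous bead range ``[a, b)`` of one
  chain rigidly (or moves a single bead), so energy terms internal to the
  range cancel in the difference and only range<->rest LJ pairs, window
  bends and window bonds need evaluating.
* the acceptance rule is either canonical (``exp(-beta dEp)``) or a binned
  generalized weight table ``lnW(Ep)``; proposals leaving the table range
  are rejected.
"""

import numpy as np
from numba import njit

KIND_STICK = 0
KIND_SPRING = 1

# move-kind indices (order fixed; cumulative probabilities use it too)
MOVE_LOCAL = 0
MOVE_CRANK = 1
MOVE_PIVOT = 2
MOVE_TRANS = 3

# series column layout produced by run_mc
SERIES_COLUMNS = ("ep", "elj", "ebend", "efene", "rg2", "ree", "cr", "gamma2")


@njit(cache=True)
def _pair_lj(r2, eps, sig2, rc2, vshift):
    if r2 >= rc2:
        return 0.0
    if r2 <= 0.0:
        return np.inf
    s = sig2 / r2
    s6 = s * s * s
    return 4.0 * eps * (s6 * s6 - s6) - vshift


@njit(cache=True)
def _dist2(pos, i, j, N, L):
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    if L > 0.0 and i // N != j // N:
        dx -= L * np.floor(dx / L + 0.5)
        dy -= L * np.floor(dy / L + 0.5)
        dz -= L * np.floor(dz / L + 0.5)
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def _bend_term(pos, v):
    # (1 - cos theta) at interior vertex v, bonds (v-1 -> v) and (v -> v+1)
    ax = pos[v, 0] - pos[v - 1, 0]
    ay = pos[v, 1] - pos[v - 1, 1]
    az = pos[v, 2] - pos[v - 1, 2]
    bx = pos[v + 1, 0] - pos[v, 0]
    by = pos[v + 1, 1] - pos[v, 1]
    bz = pos[v + 1, 2] - pos[v, 2]
    na = np.sqrt(ax * ax + ay * ay + az * az)
    nb = np.sqrt(bx * bx + by * by + bz * bz)
    if na <= 0.0 or nb <= 0.0:
        return 0.0
    c = (ax * bx + ay * by + az * bz) / (na * nb)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return 1.0 - c


@njit(cache=True)
def _fene_term(r, K, R, r0):
    x = (r - r0) / R
    arg = 1.0 - x * x
    if arg <= 0.0:
        return np.inf
    return -0.5 * K * R * R * np.log(arg)


@njit(cache=True)
def total_energy_arrays(pos, N, M, kind, eps, sigma, rc, kappa, K, R, r0, L):
    """Full (elj, ebend_raw, efene) sums over a conformation."""
    sig2 = sigma * sigma
    rc2 = rc * rc
    sr6 = (sig2 / rc2) ** 3
    vshift = 4.0 * eps * (sr6 * sr6 - sr6)
    nb = N * M
    elj = 0.0
    for i in range(nb):
        for j in range(i + 1, nb):
            if j == i + 1 and i % N != N - 1:
                continue  # bonded neighbours excluded from LJ (both models)
            elj += _pair_lj(_dist2(pos, i, j, N, L), eps, sig2, rc2, vshift)
    ebend = 0.0
    for c in range(M):
        for v in range(c * N + 1, c * N + N - 1):
            ebend += _bend_term(pos, v)
    efene = 0.0
    if kind == KIND_SPRING:
        for c in range(M):
            for i in range(c * N, c * N + N - 1):
                r = np.sqrt(_dist2(pos, i, i + 1, N, 0.0))
                efene += _fene_term(r, K, R, r0)
    return elj, ebend, efene


@njit(cache=True)
def _range_energy(pos, N, M, a, b, kind, eps, sig2, rc2, vshift, K, R, r0, L):
    """Energy terms that can change when beads [a, b) of one chain move rigidly.

    LJ pairs between the range and everything outside it, bending terms at
    vertices in a window around the range boundaries (interior terms are
    included too -- they cancel exactly in the before/after difference), and
    bonds in the same window.
    """
    nbtot = N * M
    elj = 0.0
    for i in range(a, b):
        for j in range(nbtot):
            if a <= j < b:
                continue
            if i // N == j // N and (j == i + 1 or j == i - 1):
                continue
            elj += _pair_lj(_dist2(pos, i, j, N, L), eps, sig2, rc2, vshift)
    c0 = a // N
    cs = c0 * N
    ce = cs + N
    ebend = 0.0
    vlo = a - 2 if a - 2 > cs else cs + 1
    vhi = b + 1 if b + 1 < ce - 1 else ce - 2
    for v in range(vlo, vhi + 1):
        ebend += _bend_term(pos, v)
    efene = 0.0
    if kind == KIND_SPRING:
        blo = a - 1 if a - 1 > cs else cs
        bhi = b if b < ce - 1 else ce - 2
        for i in range(blo, bhi + 1):
            r = np.sqrt(_dist2(pos, i, i + 1, N, 0.0))
            efene += _fene_term(r, K, R, r0)
    return elj, ebend, efene


@njit(cache=True)
def _random_unit():
    while True:
        x = np.random.normal(0.0, 1.0)
        y = np.random.normal(0.0, 1.0)
        z = np.random.normal(0.0, 1.0)
        n = np.sqrt(x * x + y * y + z * z)
        if n > 1e-12:
            return x / n, y / n, z / n


@njit(cache=True)
def _rotate_bead(pos, i, px, py, pz, ux, uy, uz, ca, sa):
    # Rodrigues rotation of bead i about axis (u) through point (p)
    x = pos[i, 0] - px
    y = pos[i, 1] - py
    z = pos[i, 2] - pz
    dot = ux * x + uy * y + uz * z
    cx = uy * z - uz * y
    cy = uz * x - ux * z
    cz = ux * y - uy * x
    omc = 1.0 - ca
    pos[i, 0] = px + x * ca + cx * sa + ux * dot * omc
    pos[i, 1] = py + y * ca + cy * sa + uy * dot * omc
    pos[i, 2] = pz + z * ca + cz * sa + uz * dot * omc


@njit(cache=True)
def _measure(pos, N, M, L, out):
    """Per-conformation observables: mean Rgyr^2, mean Ree, CR, Gamma2."""
    rg2 = 0.0
    ree = 0.0
    coms = np.empty((M, 3))
    units = np.empty((M, 3))
    ok = np.empty(M, np.bool_)
    for c in range(M):
        cs = c * N
        cx = 0.0
        cy = 0.0
        cz = 0.0
        for i in range(cs, cs + N):
            cx += pos[i, 0]
            cy += pos[i, 1]
            cz += pos[i, 2]
        cx /= N
        cy /= N
        cz /= N
        coms[c, 0] = cx
        coms[c, 1] = cy
        coms[c, 2] = cz
        s = 0.0
        for i in range(cs, cs + N):
            dx = pos[i, 0] - cx
            dy = pos[i, 1] - cy
            dz = pos[i, 2] - cz
            s += dx * dx + dy * dy + dz * dz
        rg2 += s / N
        ex = pos[cs, 0] - pos[cs + N - 1, 0]
        ey = pos[cs, 1] - pos[cs + N - 1, 1]
        ez = pos[cs, 2] - pos[cs + N - 1, 2]
        rn = np.sqrt(ex * ex + ey * ey + ez * ez)
        ree += rn
        if rn > 1e-12:
            units[c, 0] = ex / rn
            units[c, 1] = ey / rn
            units[c, 2] = ez / rn
            ok[c] = True
        else:
            units[c, 0] = 0.0
            units[c, 1] = 0.0
            units[c, 2] = 0.0
            ok[c] = False
    out[0] = rg2 / M
    out[1] = ree / M
    # end-to-end correlation CR (nematic-like): mean of squared pair dots
    if M >= 2:
        s = 0.0
        npair = 0
        for i in range(M):
            if not ok[i]:
                continue
            for j in range(i + 1, M):
                if not ok[j]:
                    continue
                d = (units[i, 0] * units[j, 0] + units[i, 1] * units[j, 1]
                     + units[i, 2] * units[j, 2])
                s += d * d
                npair += 1
        out[2] = s / npair if npair > 0 else np.nan
        # phase-separation parameter Gamma2 = (1/(2 M^2)) sum_{i,j} |dcom|^2
        g = 0.0
        for i in range(M):
            for j in range(i + 1, M):
                dx = coms[i, 0] - coms[j, 0]
                dy = coms[i, 1] - coms[j, 1]
                dz = coms[i, 2] - coms[j, 2]
                if L > 0.0:
                    dx -= L * np.floor(dx / L + 0.5)
                    dy -= L * np.floor(dy / L + 0.5)
                    dz -= L * np.floor(dz / L + 0.5)
                g += dx * dx + dy * dy + dz * dz
        out[3] = g / (M * M)  # ordered-pair double sum = 2 * sum_{i<j}
    else:
        out[2] = np.nan
        out[3] = np.nan


@njit(cache=True)
def _rewrap_chain(pos, cs, N, L):
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for i in range(cs, cs + N):
        cx += pos[i, 0]
        cy += pos[i, 1]
        cz += pos[i, 2]
    sx = -L * np.floor(cx / (N * L))
    sy = -L * np.floor(cy / (N * L))
    sz = -L * np.floor(cz / (N * L))
    if sx != 0.0 or sy != 0.0 or sz != 0.0:
        for i in range(cs, cs + N):
            pos[i, 0] += sx
            pos[i, 1] += sy
            pos[i, 2] += sz


@njit(cache=True)
def run_mc(pos, N, M, kind, eps, sigma, rc, kappa, K, R, r0, L,
           use_table, beta, e0, de, lnw,
           n_sweeps, discard, seed,
           pcum, amp_local, amp_crank, amp_pivot, amp_trans,
           resync_every):
    """Run ``n_sweeps`` Monte Carlo sweeps (N*M elementary proposals each).

    Modifies ``pos`` in place.  Returns
    ``(series, hist, accepted, attempted, elj, ebend, efene)`` where
    ``series`` has one row per post-discard sweep with columns
    ``SERIES_COLUMNS`` and ``hist`` counts post-discard sweep visits on the
    energy grid ``e0 + k*de`` (one count per sweep).

    ``use_table == 1`` selects generalized-ensemble acceptance with the
    binned ``lnw``; otherwise canonical acceptance at inverse temperature
    ``beta``.  All proposals are symmetric, so the Hastings ratio is 1.
    """
    np.random.seed(seed)
    sig2 = sigma * sigma
    rc2 = rc * rc
    sr6 = (sig2 / rc2) ** 3
    vshift = 4.0 * eps * (sr6 * sr6 - sr6)
    nb = N * M
    nbins = lnw.shape[0]

    elj, ebend, efene = total_energy_arrays(
        pos, N, M, kind, eps, sigma, rc, kappa, K, R, r0, L)
    ep = elj + kappa * ebend + efene

    nm = n_sweeps - discard
    series = np.zeros((nm, 8))
    hist = np.zeros(nbins, np.int64)
    accepted = np.zeros(4, np.int64)
    attempted = np.zeros(4, np.int64)
    old = np.empty((N, 3))
    obs = np.zeros(4)

    for sweep in range(n_sweeps):
        for _step in range(nb):
            u = np.random.random()
            mk = 0
            while mk < 3 and u > pcum[mk]:
                mk += 1
            c = int(np.random.random() * M)
            if c >= M:
                c = M - 1
            cs = c * N
            a = cs
            b = cs
            if mk == MOVE_LOCAL:
                k = cs + int(np.random.random() * N)
                a = k
                b = k + 1
            elif mk == MOVE_CRANK:
                k = cs + int(np.random.random() * N)
                a = k
                b = k + 1
            elif mk == MOVE_PIVOT:
                if N < 3:
                    continue
                p = cs + 1 + int(np.random.random() * (N - 2))
                a = p + 1
                b = cs + N
            else:
                a = cs
                b = cs + N
            attempted[mk] += 1

            eljo, ebendo, efeneo = _range_energy(
                pos, N, M, a, b, kind, eps, sig2, rc2, vshift, K, R, r0, L)

            nmov = b - a
            for i in range(nmov):
                old[i, 0] = pos[a + i, 0]
                old[i, 1] = pos[a + i, 1]
                old[i, 2] = pos[a + i, 2]

            if mk == MOVE_LOCAL:
                pos[a, 0] += amp_local * (2.0 * np.random.random() - 1.0)
                pos[a, 1] += amp_local * (2.0 * np.random.random() - 1.0)
                pos[a, 2] += amp_local * (2.0 * np.random.random() - 1.0)
            elif mk == MOVE_CRANK:
                k = a
                ang = amp_crank * (2.0 * np.random.random() - 1.0)
                ca = np.cos(ang)
                sa = np.sin(ang)
                if k == cs:
                    ux, uy, uz = _random_unit()
                    _rotate_bead(pos, k, pos[k + 1, 0], pos[k + 1, 1],
                                 pos[k + 1, 2], ux, uy, uz, ca, sa)
                elif k == cs + N - 1:
                    ux, uy, uz = _random_unit()
                    _rotate_bead(pos, k, pos[k - 1, 0], pos[k - 1, 1],
                                 pos[k - 1, 2], ux, uy, uz, ca, sa)
                else:
                    ux = pos[k + 1, 0] - pos[k - 1, 0]
                    uy = pos[k + 1, 1] - pos[k - 1, 1]
                    uz = pos[k + 1, 2] - pos[k - 1, 2]
                    nn = np.sqrt(ux * ux + uy * uy + uz * uz)
                    if nn < 1e-12:
                        ux, uy, uz = _random_unit()
                    else:
                        ux /= nn
                        uy /= nn
                        uz /= nn
                    _rotate_bead(pos, k, pos[k - 1, 0], pos[k - 1, 1],
                                 pos[k - 1, 2], ux, uy, uz, ca, sa)
            elif mk == MOVE_PIVOT:
                p = a - 1
                ux, uy, uz = _random_unit()
                ang = amp_pivot * (2.0 * np.random.random() - 1.0)
                ca = np.cos(ang)
                sa = np.sin(ang)
                px = pos[p, 0]
                py = pos[p, 1]
                pz = pos[p, 2]
                for i in range(a, b):
                    _rotate_bead(pos, i, px, py, pz, ux, uy, uz, ca, sa)
            else:
                dx = amp_trans * (2.0 * np.random.random() - 1.0)
                dy = amp_trans * (2.0 * np.random.random() - 1.0)
                dz = amp_trans * (2.0 * np.random.random() - 1.0)
                for i in range(a, b):
                    pos[i, 0] += dx
                    pos[i, 1] += dy
                    pos[i, 2] += dz

            eljn, ebendn, efenen = _range_energy(
                pos, N, M, a, b, kind, eps, sig2, rc2, vshift, K, R, r0, L)

            dlj = eljn - eljo
            dbend = ebendn - ebendo
            dfene = efenen - efeneo
            dep = dlj + kappa * dbend + dfene

            accept = False
            if np.isfinite(dep):
                epn = ep + dep
                if use_table == 1:
                    inew = int(np.floor((epn - e0) / de))
                    if 0 <= inew < nbins:
                        iold = int(np.floor((ep - e0) / de))
                        if iold < 0:
                            iold = 0
                        elif iold >= nbins:
                            iold = nbins - 1
                        dw = lnw[inew] - lnw[iold]
                        if dw >= 0.0 or np.random.random() < np.exp(dw):
                            accept = True
                else:
                    arg = -beta * dep
                    if arg >= 0.0 or np.random.random() < np.exp(arg):
                        accept = True

            if accept:
                elj += dlj
                ebend += dbend
                efene += dfene
                ep += dep
                accepted[mk] += 1
                if mk == MOVE_TRANS and L > 0.0:
                    _rewrap_chain(pos, cs, N, L)
            else:
                for i in range(nmov):
                    pos[a + i, 0] = old[i, 0]
                    pos[a + i, 1] = old[i, 1]
                    pos[a + i, 2] = old[i, 2]

        if resync_every > 0 and (sweep + 1) % resync_every == 0:
            if L > 0.0:
                for c2 in range(M):
                    _rewrap_chain(pos, c2 * N, N, L)
            elj, ebend, efene = total_energy_arrays(
                pos, N, M, kind, eps, sigma, rc, kappa, K, R, r0, L)
            ep = elj + kappa * ebend + efene

        if sweep >= discard:
            row = sweep - discard
            _measure(pos, N, M, L, obs)
            series[row, 0] = ep
            series[row, 1] = elj
            series[row, 2] = ebend
            series[row, 3] = efene
            series[row, 4] = obs[0]
            series[row, 5] = obs[1]
            series[row, 6] = obs[2]
            series[row, 7] = obs[3]
            ib = int(np.floor((ep - e0) / de))
            if 0 <= ib < nbins:
                hist[ib] += 1

    return series, hist, accepted, attempted, elj, ebend, efene
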
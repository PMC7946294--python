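"""Numba kernels for the integrated-information engine.

Everything here works on primitive arrays and bitmask-encoded node subsets so
that the hot path (per-state cause-effect structures and the unidirectional
cut search) runs at compiled speed.  Conventions:

* Node subsets (mechanisms, purviews, cut parts) are integer bitmasks; node
  ``i`` is bit ``i`` and also the ``i``-th (least-significant-first) bit of a
  state index.
* A repertoire over a purview ``P`` with ``p`` set bits is stored compactly as
  a length ``2**p`` vector indexed by the purview bits extracted in order.
* The earth mover's distance uses the Hamming ground metric between bit
  states and is solved exactly by successive-shortest-path min-cost transport
  (no approximation; validated against an LP oracle in the test suite).

The per-(mechanism, purview) minimum over disconnections exploits two exact
shortcuts: effect repertoires are Bernoulli products, for which the Hamming
EMD reduces to the sum of per-node marginal differences; and for cause-side
candidates, the total-variation distance is a lower bound on the EMD (every
unit of probability mass moved costs at least one bit flip), which prunes
partitions that cannot beat the current minimum before any transport solve.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: mass below this is treated as zero in transport bookkeeping
_EPS = 1e-14


def dist_table(n_bits: int) -> np.ndarray:
    """Hamming distances between all pairs of ``n_bits``-bit states."""
    states = np.arange(1 << n_bits)
    xor = states[:, None] ^ states[None, :]
    return np.array(
        [[bin(v).count("1") for v in row] for row in xor], dtype=np.float64
    )


@njit(cache=True)
def _popcount(x):
    c = 0
    while x:
        x &= x - 1
        c += 1
    return c


@njit(cache=True)
def _pext(x, mask):
    """Compact the bits of ``x`` selected by ``mask`` (low bits first)."""
    out = 0
    bit = 0
    m = mask
    while m:
        low = m & (-m)
        if x & low:
            out |= 1 << bit
        bit += 1
        m &= m - 1
    return out


@njit(cache=True)
def _pdep(z, mask):
    """Inverse of :func:`_pext`: scatter low bits of ``z`` into ``mask``."""
    out = 0
    bit = 0
    m = mask
    while m:
        low = m & (-m)
        if z & (1 << bit):
            out |= low
        bit += 1
        m &= m - 1
    return out


@njit(cache=True)
def emd_hamming(p, q, D):
    """Exact EMD between distributions ``p`` and ``q`` under ground metric ``D``.

    Successive-shortest-path min-cost transport on the bipartite
    excess/deficit graph, with Johnson potentials so Dijkstra applies to the
    residual network.  ``D`` may be any (larger) distance table; only the
    leading ``len(p)`` rows/columns are read.
    """
    m = p.shape[0]
    srcs = np.empty(m, np.int64)
    snks = np.empty(m, np.int64)
    ns = 0
    nd = 0
    for i in range(m):
        d = p[i] - q[i]
        if d > _EPS:
            srcs[ns] = i
            ns += 1
        elif d < -_EPS:
            snks[nd] = i
            nd += 1
    if ns == 0 or nd == 0:
        return 0.0
    sup = np.empty(ns)
    dem = np.empty(nd)
    for a in range(ns):
        sup[a] = p[srcs[a]] - q[srcs[a]]
    for b in range(nd):
        dem[b] = q[snks[b]] - p[snks[b]]
    cost = np.empty((ns, nd))
    for a in range(ns):
        for b in range(nd):
            cost[a, b] = D[srcs[a], snks[b]]
    flow = np.zeros((ns, nd))
    pulled = np.zeros(ns)  # flow already drawn source <- super-source
    pushed = np.zeros(nd)  # flow already sent sink -> super-sink
    ss = ns + nd
    tt = ns + nd + 1
    nv = ns + nd + 2
    pot = np.zeros(nv)
    dist = np.empty(nv)
    visited = np.empty(nv, np.uint8)
    parent = np.empty(nv, np.int64)
    INF = 1e30
    remaining = 0.0
    for a in range(ns):
        remaining += sup[a]
    guard = 0
    while remaining > 1e-12 and guard < 100000:
        guard += 1
        for v in range(nv):
            dist[v] = INF
            visited[v] = 0
            parent[v] = -1
        dist[ss] = 0.0
        while True:
            u = -1
            du = INF
            for v in range(nv):
                if visited[v] == 0 and dist[v] < du:
                    du = dist[v]
                    u = v
            if u < 0 or u == tt:
                break
            visited[u] = 1
            if u == ss:
                for a in range(ns):
                    if visited[a] or sup[a] <= _EPS:
                        continue
                    rc = pot[ss] - pot[a]
                    if rc < 0.0:
                        rc = 0.0
                    nd_ = du + rc
                    if nd_ < dist[a] - 1e-15:
                        dist[a] = nd_
                        parent[a] = ss
            elif u < ns:
                a = u
                if not visited[ss] and pulled[a] > _EPS:
                    rc = pot[a] - pot[ss]
                    if rc < 0.0:
                        rc = 0.0
                    nd_ = du + rc
                    if nd_ < dist[ss] - 1e-15:
                        dist[ss] = nd_
                        parent[ss] = a
                for b in range(nd):
                    v = ns + b
                    if visited[v]:
                        continue
                    rc = cost[a, b] + pot[a] - pot[v]
                    if rc < 0.0:
                        rc = 0.0
                    nd_ = du + rc
                    if nd_ < dist[v] - 1e-15:
                        dist[v] = nd_
                        parent[v] = a
            elif u < ss:
                b = u - ns
                if not visited[tt] and dem[b] > _EPS:
                    rc = pot[u] - pot[tt]
                    if rc < 0.0:
                        rc = 0.0
                    nd_ = du + rc
                    if nd_ < dist[tt] - 1e-15:
                        dist[tt] = nd_
                        parent[tt] = u
                for a in range(ns):
                    if visited[a] or flow[a, b] <= _EPS:
                        continue
                    rc = -cost[a, b] + pot[u] - pot[a]
                    if rc < 0.0:
                        rc = 0.0
                    nd_ = du + rc
                    if nd_ < dist[a] - 1e-15:
                        dist[a] = nd_
                        parent[a] = u
            else:  # u == tt, handled by the break above
                pass
        if dist[tt] >= INF:
            break
        dt = dist[tt]
        for v in range(nv):
            dv = dist[v]
            if dv > dt:
                dv = dt
            pot[v] += dv
        # bottleneck along the augmenting path ss -> ... -> tt
        delta = remaining
        v = tt
        while v != ss:
            u = parent[v]
            if u == ss:  # ss -> source v
                if sup[v] < delta:
                    delta = sup[v]
            elif v == ss:
                pass
            elif v == tt:  # sink u -> tt
                if dem[u - ns] < delta:
                    delta = dem[u - ns]
            elif v < ns and u >= ns and u < ss:  # backward sink u -> source v
                if flow[v, u - ns] < delta:
                    delta = flow[v, u - ns]
            elif v == ss and u < ns:
                if pulled[u] < delta:
                    delta = pulled[u]
            v = u
        v = tt
        while v != ss:
            u = parent[v]
            if u == ss:
                sup[v] -= delta
                pulled[v] += delta
            elif v == tt:
                dem[u - ns] -= delta
                pushed[u - ns] += delta
            elif u < ns and v >= ns:  # forward source u -> sink v
                flow[u, v - ns] += delta
            elif v < ns and u >= ns and u < ss:  # backward
                flow[v, u - ns] -= delta
            elif v == ss:  # residual source u -> ss
                pulled[u] -= delta
                sup[u] += delta
            v = u
        remaining -= delta
    total = 0.0
    for a in range(ns):
        for b in range(nd):
            total += flow[a, b] * cost[a, b]
    return total


@njit(cache=True)
def _tables(tpm, state):
    """Per-state building blocks.

    ``em[M, j]``: probability node ``j`` is on at t+tau given the mechanism
    ``M`` fixed at the current state and all other nodes uniform (effect
    marginal; row 0 is the fully unconstrained marginal).

    ``cl[P, i, z]``: likelihood of node ``i``'s current state given the
    purview ``P`` took compact past state ``z`` and non-purview past nodes
    were uniform (the Bayesian-inversion building block of cause repertoires).
    """
    N, n = tpm.shape
    em = np.zeros((N, n))
    for M in range(N):
        cnt = 0
        for s in range(N):
            if (s & M) == (state & M):
                cnt += 1
                for j in range(n):
                    em[M, j] += tpm[s, j]
        for j in range(n):
            em[M, j] /= cnt
    cl = np.zeros((N, n, N))
    cnts = np.zeros(N)
    for P in range(N):
        psz = 1 << _popcount(P)
        for z in range(psz):
            cnts[z] = 0.0
        for s in range(N):
            z = _pext(s, P)
            cnts[z] += 1.0
            for i in range(n):
                if (state >> i) & 1:
                    cl[P, i, z] += tpm[s, i]
                else:
                    cl[P, i, z] += 1.0 - tpm[s, i]
        for i in range(n):
            for z in range(psz):
                cl[P, i, z] /= cnts[z]
    return em, cl


@njit(cache=True)
def _cause_rep(M, P, cl, cache, flag, n):
    """Normalized cause repertoire of mechanism ``M`` over purview ``P``.

    Memoized in ``cache[M, P]``; an all-zero normalizer (an unreachable
    mechanism state) falls back to the uniform distribution.
    """
    if flag[M, P]:
        return
    psz = 1 << _popcount(P)
    if M == 0:
        u = 1.0 / psz
        for z in range(psz):
            cache[M, P, z] = u
    else:
        tot = 0.0
        for z in range(psz):
            v = 1.0
            for i in range(n):
                if (M >> i) & 1:
                    v *= cl[P, i, z]
            cache[M, P, z] = v
            tot += v
        if tot <= 1e-300:
            u = 1.0 / psz
            for z in range(psz):
                cache[M, P, z] = u
        else:
            for z in range(psz):
                cache[M, P, z] /= tot
    flag[M, P] = 1


@njit(cache=True)
def _phi_eff(M, P, em, n):
    """Minimum-EMD disconnection on the effect side (closed form).

    Both the whole and any partitioned effect repertoire are Bernoulli
    products, so the Hamming EMD is the sum of per-node marginal differences
    and each purview node independently joins the cheaper part.  A partition
    with an empty mechanism part must keep at least one purview node (the
    trivial partition is excluded), forcing the cheapest single-node noising.
    """
    best = 1e30
    lb = M & (-M)
    sub = M
    while True:
        if sub & lb:
            M1 = sub
            M2 = M ^ sub
            if M2 == 0:
                c = 1e30
                for j in range(n):
                    if (P >> j) & 1:
                        d = abs(em[M, j] - em[0, j])
                        if d < c:
                            c = d
            else:
                c = 0.0
                for j in range(n):
                    if (P >> j) & 1:
                        d1 = abs(em[M, j] - em[M1, j])
                        d2 = abs(em[M, j] - em[M2, j])
                        c += d1 if d1 < d2 else d2
            if c < best:
                best = c
        if sub == 0:
            break
        sub = (sub - 1) & M
    return best


@njit(cache=True)
def _phi_cause(M, P, cl, cache, flag, D, n, scratch):
    """Minimum-EMD disconnection on the cause side (exact transport).

    Enumerates unordered bipartitions of (mechanism, purview); the
    total-variation lower bound prunes transport solves that cannot improve
    on the incumbent minimum.
    """
    psz = 1 << _popcount(P)
    _cause_rep(M, P, cl, cache, flag, n)
    w = cache[M, P]
    best = 1e30
    lb = M & (-M)
    sub = M
    while True:
        if sub & lb:
            M1 = sub
            M2 = M ^ sub
            P1 = P
            while True:
                P2 = P ^ P1
                if not (M2 == 0 and P2 == 0):
                    if P1:
                        _cause_rep(M1, P1, cl, cache, flag, n)
                    if P2:
                        _cause_rep(M2, P2, cl, cache, flag, n)
                    tv = 0.0
                    for z in range(psz):
                        full = _pdep(z, P)
                        v = 1.0
                        if P1:
                            v *= cache[M1, P1, _pext(full, P1)]
                        if P2:
                            v *= cache[M2, P2, _pext(full, P2)]
                        scratch[z] = v
                        tv += abs(w[z] - v)
                    tv *= 0.5
                    if tv < best - 1e-15:
                        if tv < 1e-14:
                            return 0.0
                        d = emd_hamming(w[:psz], scratch[:psz], D)
                        if d < best:
                            best = d
                if P1 == 0:
                    break
                P1 = (P1 - 1) & P
        if sub == 0:
            break
        sub = (sub - 1) & M
    return best


@njit(cache=True)
def _ces(tpm, state, D):
    """Full cause-effect structure of ``tpm`` in ``state``.

    Returns, indexed by mechanism mask (entry 0 unused):
    ``em`` effect-marginal table, mechanism ``phis`` (= min of the two
    sides), per-side phis, core purview masks, cause repertoires expanded to
    the full state space (off-purview nodes uniform), and expanded effect
    repertoires as per-node marginal vectors (off-purview nodes at 0.5).

    Core purviews maximize phi; ties go to the larger purview, then to the
    first (lowest-mask) purview in enumeration order.
    """
    N, n = tpm.shape
    em, cl = _tables(tpm, state)
    cache = np.zeros((N, N, N))
    flag = np.zeros((N, N), np.uint8)
    scratch = np.zeros(N)
    phis = np.zeros(N)
    phis_c = np.zeros(N)
    phis_e = np.zeros(N)
    core_c = np.zeros(N, np.int64)
    core_e = np.zeros(N, np.int64)
    cause_full = np.zeros((N, N))
    eff_marg = np.zeros((N, n))
    for M in range(1, N):
        bp = -1
        bphi = -1.0
        bsz = -1
        for P in range(1, N):
            f = _phi_eff(M, P, em, n)
            sz = _popcount(P)
            if f > bphi + 1e-10 or (f > bphi - 1e-10 and sz > bsz):
                if f > bphi:
                    bphi = f
                bp = P
                bsz = sz
        phis_e[M] = bphi
        core_e[M] = bp
        bp = -1
        bphi = -1.0
        bsz = -1
        for P in range(1, N):
            f = _phi_cause(M, P, cl, cache, flag, D, n, scratch)
            sz = _popcount(P)
            if f > bphi + 1e-10 or (f > bphi - 1e-10 and sz > bsz):
                if f > bphi:
                    bphi = f
                bp = P
                bsz = sz
        phis_c[M] = bphi
        core_c[M] = bp
        phis[M] = phis_c[M] if phis_c[M] < phis_e[M] else phis_e[M]
        Pe = core_e[M]
        for j in range(n):
            if (Pe >> j) & 1:
                eff_marg[M, j] = em[M, j]
            else:
                eff_marg[M, j] = 0.5
        Pc = core_c[M]
        psz = 1 << _popcount(Pc)
        scale = psz / N
        _cause_rep(M, Pc, cl, cache, flag, n)
        for s in range(N):
            cause_full[M, s] = cache[M, Pc, _pext(s, Pc)] * scale
    return em, phis, phis_c, phis_e, core_c, core_e, cause_full, eff_marg


@njit(cache=True)
def _apply_cut(tpm, from_mask):
    """Noise all influences of ``from_mask`` nodes onto the complement.

    Each target column is re-computed by marginalizing the from-part's
    current-state bits under the uniform distribution; from-part columns and
    influences onto the from-part are untouched.
    """
    N, n = tpm.shape
    out = np.empty_like(tpm)
    not_from = (N - 1) ^ from_mask
    nf = 1 << _popcount(from_mask)
    accs = np.zeros(n)
    for s in range(N):
        base = s & not_from
        for j in range(n):
            accs[j] = 0.0
        f = from_mask
        while True:
            row = base | f
            for j in range(n):
                if ((from_mask >> j) & 1) == 0:
                    accs[j] += tpm[row, j]
            if f == 0:
                break
            f = (f - 1) & from_mask
        for j in range(n):
            if (from_mask >> j) & 1:
                out[s, j] = tpm[s, j]
            else:
                out[s, j] = accs[j] / nf
    return out


@njit(cache=True)
def _ces_distance(
    phis_f, cause_f, marg_f, phis_c, cause_c, marg_c, uncon_eff, D, n
):
    """phi-weighted distance between two cause-effect structures.

    Per mechanism: the matched mass min(phi_full, phi_cut) pays the EMD
    between the two core cause (and effect) repertoires; the residual
    |phi_full - phi_cut| is moved to the maximally uninformative
    distributions (uniform on the cause side, the unconstrained effect
    repertoire on the effect side).  Effect-side EMDs use the product
    closed form.
    """
    N = cause_f.shape[1]
    tot = 0.0
    uni = np.full(N, 1.0 / N)
    for M in range(1, N):
        pf = phis_f[M]
        pc = phis_c[M]
        mn = pf if pf < pc else pc
        if mn > 1e-15:
            dc = emd_hamming(cause_f[M], cause_c[M], D)
            de = 0.0
            for j in range(n):
                de += abs(marg_f[M, j] - marg_c[M, j])
            tot += mn * (dc + de)
        resid = pf - pc
        if resid < 0.0:
            resid = -resid
        if resid > 1e-15:
            if pf >= pc:
                dc = emd_hamming(cause_f[M], uni, D)
                de = 0.0
                for j in range(n):
                    de += abs(marg_f[M, j] - uncon_eff[j])
            else:
                dc = emd_hamming(cause_c[M], uni, D)
                de = 0.0
                for j in range(n):
                    de += abs(marg_c[M, j] - uncon_eff[j])
            tot += resid * (dc + de)
    return tot


@njit(cache=True)
def _big_phi_state(tpm, state, D):
    """System-level integrated information of ``tpm`` in ``state``.

    Minimum, over all unidirectional cuts (enumerated by ascending from-part
    mask; the first minimizer wins ties), of the CES distance between the
    full and cut systems.  Returns (big_phi, minimal from-mask, full-CES
    mechanism phis).
    """
    N, n = tpm.shape
    em, phis, phis_c, phis_e, core_c, core_e, cause_full, eff_marg = _ces(
        tpm, state, D
    )
    uncon_eff = em[0]
    best = 1e30
    best_f = -1
    for F in range(1, N - 1):
        cut_tpm = _apply_cut(tpm, F)
        (_, cphis, _, _, _, _, ccause, cmarg) = _ces(cut_tpm, state, D)
        d = _ces_distance(
            phis, cause_full, eff_marg, cphis, ccause, cmarg, uncon_eff, D, n
        )
        if d < best:
            best = d
            best_f = F
    if best < 0.0:
        best = 0.0
    return best, best_f, phis
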
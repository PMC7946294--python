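"""Independent brute-force reference implementation for the IIT quantities.

Everything here is deliberately naive in structure: explicit enumeration of
states, partitions and cuts straight from the definitions, with earth
mover's distances solved as dense transportation linear programs by scipy.
It shares no code with the package engine (which uses closed forms, pruning
and a min-cost-flow transport solver) and is used only as a test oracle.
Repertoires and LP solutions are memoized for speed; memoization does not
change any value.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

_EMD_CACHE: dict = {}


def hamming(a: int, b: int) -> int:
    return bin(a ^ b).count("1")


def emd_lp(p, q) -> float:
    """Transportation LP: exact EMD with the Hamming ground metric."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    key = (p.tobytes(), q.tobytes())
    if key in _EMD_CACHE:
        return _EMD_CACHE[key]
    m = p.size
    cost = np.array(
        [[hamming(i, j) for j in range(m)] for i in range(m)], dtype=float
    ).ravel()
    A_eq = np.zeros((2 * m, m * m))
    for i in range(m):
        A_eq[i, i * m : (i + 1) * m] = 1.0
    for j in range(m):
        A_eq[m + j, j::m] = 1.0
    b_eq = np.concatenate([p, q])
    res = linprog(
        cost,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=(0, None),
        method="highs",
        options={
            "primal_feasibility_tolerance": 1e-10,
            "dual_feasibility_tolerance": 1e-10,
        },
    )
    assert res.success
    _EMD_CACHE[key] = float(res.fun)
    return float(res.fun)


def _consistent(n, bits_of):
    """Boolean mask over system states matching the given node bits."""
    states = np.arange(2**n)
    sel = np.ones(2**n, dtype=bool)
    for node, b in bits_of:
        sel &= ((states >> node) & 1) == b
    return sel


def effect_rep(probs, n, mechanism, mech_state, purview, cache=None):
    """p(purview at t+tau | mechanism state, other nodes uniform)."""
    key = ("e", mechanism, mech_state, purview)
    if cache is not None and key in cache:
        return cache[key]
    rows = _consistent(n, list(zip(mechanism, mech_state)))
    rep = np.empty(2 ** len(purview))
    for z in range(rep.size):
        v = 1.0
        for k, j in enumerate(purview):
            pj = probs[rows, j].mean()
            v *= pj if (z >> k) & 1 else 1.0 - pj
        rep[z] = v
    if cache is not None:
        cache[key] = rep
    return rep


def cause_rep(probs, n, mechanism, mech_state, purview, cache=None):
    """Bayes inversion with per-mechanism-node factorized likelihoods."""
    key = ("c", mechanism, mech_state, purview)
    if cache is not None and key in cache:
        return cache[key]
    psz = 2 ** len(purview)
    if not mechanism:
        rep = np.full(psz, 1.0 / psz)
    else:
        rep = np.ones(psz)
        for z in range(psz):
            sel = _consistent(
                n, [(j, (z >> k) & 1) for k, j in enumerate(purview)]
            )
            for i, b in zip(mechanism, mech_state):
                col = probs[sel, i]
                rep[z] *= (col if b else 1.0 - col).mean()
        tot = rep.sum()
        rep = np.full(psz, 1.0 / psz) if tot <= 0 else rep / tot
    if cache is not None:
        cache[key] = rep
    return rep


def all_partitions(mechanism, purview):
    """Unordered bipartitions of (mechanism, purview); no (empty, empty) part."""
    seen = set()
    out = []
    for m_bits in range(2 ** len(mechanism)):
        m1 = tuple(i for k, i in enumerate(mechanism) if (m_bits >> k) & 1)
        m2 = tuple(i for i in mechanism if i not in m1)
        for p_bits in range(2 ** len(purview)):
            p1 = tuple(j for k, j in enumerate(purview) if (p_bits >> k) & 1)
            p2 = tuple(j for j in purview if j not in p1)
            if (tuple(), tuple()) in [(m1, p1), (m2, p2)]:
                continue
            parts = frozenset([(m1, p1), (m2, p2)])
            if parts in seen:
                continue
            seen.add(parts)
            out.append(((m1, p1), (m2, p2)))
    return out


def partitioned_rep(probs, n, direction, state_of, partition, purview, cache=None):
    rep_fn = cause_rep if direction == "cause" else effect_rep
    joint = np.ones(2 ** len(purview))
    for mech_part, purv_part in partition:
        if not purv_part:
            continue
        part_state = tuple(state_of[i] for i in mech_part)
        part = rep_fn(probs, n, mech_part, part_state, purv_part, cache)
        for z in range(joint.size):
            zz = 0
            for k, j in enumerate(purv_part):
                zz |= (((z >> purview.index(j)) & 1)) << k
            joint[z] *= part[zz]
    return joint


def phi_mip(probs, n, mechanism, mech_state, purview, direction, cache=None):
    rep_fn = cause_rep if direction == "cause" else effect_rep
    whole = rep_fn(probs, n, mechanism, mech_state, purview, cache)
    state_of = dict(zip(mechanism, mech_state))
    seen = set()
    cands = []
    for partition in all_partitions(mechanism, purview):
        r = partitioned_rep(
            probs, n, direction, state_of, partition, purview, cache
        )
        key = r.tobytes()
        if key in seen:  # identical candidate, identical EMD
            continue
        seen.add(key)
        # total variation lower-bounds the EMD (any moved mass costs >= 1)
        cands.append((0.5 * np.abs(whole - r).sum(), r))
    cands.sort(key=lambda c: c[0])
    best = np.inf
    for tv, r in cands:
        if tv >= best:  # no remaining candidate can undercut the incumbent
            break
        if tv < 1e-14:
            return 0.0
        best = min(best, emd_lp(whole, r))
    return best


def core(probs, n, mechanism, mech_state, direction, cache=None):
    """(phi, purview): max-phi purview, ties to larger then lowest mask."""
    best_phi, best_purv, best_sz = -1.0, None, -1
    for pmask in range(1, 2**n):
        purview = tuple(i for i in range(n) if (pmask >> i) & 1)
        phi = phi_mip(probs, n, mechanism, mech_state, purview, direction, cache)
        if phi > best_phi + 1e-10 or (
            phi > best_phi - 1e-10 and len(purview) > best_sz
        ):
            best_phi = max(best_phi, phi)
            best_purv = purview
            best_sz = len(purview)
    return best_phi, best_purv


def expand_cause(rep, purview, n):
    out = np.empty(2**n)
    for s in range(2**n):
        z = 0
        for k, j in enumerate(purview):
            z |= ((s >> j) & 1) << k
        out[s] = rep[z] * (2 ** len(purview)) / 2**n
    return out


def expand_effect(probs, n, mechanism, mech_state, purview):
    """Full product vector; off-purview nodes at the uniform 0.5."""
    rows = _consistent(n, list(zip(mechanism, mech_state)))
    marg = np.full(n, 0.5)
    for j in purview:
        marg[j] = probs[rows, j].mean()
    out = np.ones(2**n)
    for s in range(2**n):
        v = 1.0
        for j in range(n):
            v *= marg[j] if (s >> j) & 1 else 1.0 - marg[j]
        out[s] = v
    return out


def ces(probs, n, state_bits):
    """All concepts: phi, per-side phis, core purviews, expanded repertoires."""
    cache: dict = {}
    out = {}
    for msize in range(1, n + 1):
        for mechanism in itertools.combinations(range(n), msize):
            mech_state = tuple(int(state_bits[i]) for i in mechanism)
            phi_c, purv_c = core(probs, n, mechanism, mech_state, "cause", cache)
            phi_e, purv_e = core(probs, n, mechanism, mech_state, "effect", cache)
            cr = cause_rep(probs, n, mechanism, mech_state, purv_c, cache)
            out[mechanism] = {
                "phi": min(phi_c, phi_e),
                "phi_cause": phi_c,
                "phi_effect": phi_e,
                "core_cause": purv_c,
                "core_effect": purv_e,
                "cause_expanded": expand_cause(cr, purv_c, n),
                "effect_expanded": expand_effect(
                    probs, n, mechanism, mech_state, purv_e
                ),
            }
    return out


def apply_cut(probs, n, from_part):
    """Noise from_part -> complement by explicit averaging over from states."""
    out = probs.copy()
    to_part = [j for j in range(n) if j not in from_part]
    for s in range(2**n):
        variants = []
        for bits in itertools.product((0, 1), repeat=len(from_part)):
            s2 = s
            for i, b in zip(from_part, bits):
                s2 = (s2 & ~(1 << i)) | (b << i)
            variants.append(s2)
        for j in to_part:
            out[s, j] = np.mean([probs[v, j] for v in variants])
    return out


def _distance_with_ref(full, cut, n, uncon_eff):
    uniform = np.full(2**n, 1.0 / 2**n)
    total = 0.0
    for mechanism, f in full.items():
        c = cut[mechanism]
        mn = min(f["phi"], c["phi"])
        if mn > 0:
            total += mn * (
                emd_lp(f["cause_expanded"], c["cause_expanded"])
                + emd_lp(f["effect_expanded"], c["effect_expanded"])
            )
        resid = abs(f["phi"] - c["phi"])
        if resid > 0:
            big = f if f["phi"] >= c["phi"] else c
            total += resid * (
                emd_lp(big["cause_expanded"], uniform)
                + emd_lp(big["effect_expanded"], uncon_eff)
            )
    return total


def ces_distance_full(full, cut, n, probs_full):
    """Distance given the full system's TPM (for the unconstrained effect)."""
    uncon = expand_effect(probs_full, n, (), (), tuple(range(n)))
    return _distance_with_ref(full, cut, n, uncon)


def big_phi(probs, n, state_bits, full=None):
    """Minimum over all unidirectional cuts of the CES distance."""
    if full is None:
        full = ces(probs, n, state_bits)
    uncon = expand_effect(probs, n, (), (), tuple(range(n)))
    best = np.inf
    for fmask in range(1, 2**n - 1):
        from_part = tuple(i for i in range(n) if (fmask >> i) & 1)
        cut_probs = apply_cut(probs, n, from_part)
        cut_struct = ces(cut_probs, n, state_bits)
        best = min(best, _distance_with_ref(full, cut_struct, n, uncon))
    return max(best, 0.0)
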
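"""Mechanism-level phi, concepts, cause-effect structures and system-level Phi.

This module implements the IIT 3.0 quantities for small binary systems
described by a state-by-node TPM:

* **Repertoires** -- the probability distribution a *mechanism* (a subset of
  nodes in its current state) specifies over the past (cause) or future
  (effect) states of a *purview*, with nodes outside the conditioning set
  marginalized under the maximum-entropy (uniform) distribution.
* **phi** -- a mechanism's irreducibility over a purview: the minimum earth
  mover's distance (Hamming ground metric) between the intact repertoire and
  the best "disconnected" approximation, where disconnections replace
  mechanism-purview influences with uniform noise.
* **Concepts and the cause-effect structure (CES)** -- each mechanism's core
  cause and core effect (the phi-maximizing purviews) with
  phi = min(phi_cause, phi_effect); the CES collects all 2**n - 1 concepts.
* **Phi (system level)** -- the minimum over unidirectional system cuts of
  the phi-weighted distance between the full and cut CES.  A completely
  feedforward system has a cut that changes nothing, hence Phi = 0.

Repertoire comparisons across structures expand both sides to the full
n-node space, filling off-purview nodes with the uniform distribution; this
single convention (declared here, used everywhere) makes distances between
concepts with different purviews well defined.

Tie-breaking is deterministic throughout: purview ties go to the larger
purview then to the first in ascending-mask order; partition and cut ties go
to the first candidate in enumeration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .tpm import StateByNodeTPM

CAUSE = "cause"
EFFECT = "effect"

_DIST_CACHE: dict[int, np.ndarray] = {}


def _dist(n_bits: int) -> np.ndarray:
    if n_bits not in _DIST_CACHE:
        _DIST_CACHE[n_bits] = _engine.dist_table(n_bits)
    return _DIST_CACHE[n_bits]


def _mask(nodes) -> int:
    return sum(1 << i for i in nodes)


def _nodes(mask: int, n: int) -> tuple[int, ...]:
    return tuple(i for i in range(n) if (mask >> i) & 1)


def mechanism_order(n_nodes: int) -> list[tuple[int, ...]]:
    """Canonical mechanism order: by size, then ascending bitmask."""
    masks = sorted(range(1, 2**n_nodes), key=lambda m: (bin(m).count("1"), m))
    return [_nodes(m, n_nodes) for m in masks]


@dataclass
class Repertoire:
    """Probability distribution over the ``2**|purview|`` purview states."""

    probs: np.ndarray
    purview: tuple
    direction: str
    #: set when a zero normalizer forced the uniform fallback
    degenerate: bool = False

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.size != 2 ** len(self.purview):
            raise ValueError("repertoire size does not match purview")
        if abs(self.probs.sum() - 1.0) > 1e-10 or (self.probs < -1e-12).any():
            raise ValueError("repertoire must be a probability distribution")

    def expand(self, n_nodes: int, node_ids: tuple) -> np.ndarray:
        """Expand to the full state space, off-purview nodes uniform."""
        pmask = _mask(node_ids)
        psz = self.probs.size
        out = np.empty(2**n_nodes)
        for s in range(2**n_nodes):
            out[s] = self.probs[_engine._pext(s, pmask)] * psz / 2**n_nodes
        return out


@dataclass
class MechanismPartition:
    """Bipartition of (mechanism, purview); each part = (mech part, purview part)."""

    part1: tuple
    part2: tuple


@dataclass
class CoreRepertoire:
    purview: tuple
    repertoire: Repertoire
    phi: float


@dataclass
class Concept:
    mechanism: tuple
    core_cause: CoreRepertoire
    core_effect: CoreRepertoire
    phi: float


@dataclass
class SystemCut:
    """Unidirectional cut: influences from ``from_part`` onto ``to_part`` noised."""

    from_part: tuple
    to_part: tuple


@dataclass
class CauseEffectStructure:
    """All 2**n - 1 concepts of a system in a state (zero-phi concepts kept)."""

    concepts: list
    system_state: np.ndarray
    label: str = "full"
    # flat arrays used for structure distances (indexed by mechanism mask)
    _phis: np.ndarray = field(default=None, repr=False)
    _cause_expanded: np.ndarray = field(default=None, repr=False)
    _effect_marginals: np.ndarray = field(default=None, repr=False)
    _unconstrained_effect: np.ndarray = field(default=None, repr=False)

    def phis(self) -> np.ndarray:
        """Mechanism phi values in canonical order (the IIS of this state)."""
        return np.array([c.phi for c in self.concepts])


@dataclass
class SystemResult:
    big_phi: float
    minimal_cut: SystemCut
    full_ces: CauseEffectStructure
    cut_ces: CauseEffectStructure


def _check_nodes(tpm: StateByNodeTPM, nodes) -> None:
    for i in nodes:
        if not 0 <= i < tpm.n_nodes:
            raise IndexError(f"node {i} outside system of {tpm.n_nodes} nodes")


def effect_repertoire(
    tpm: StateByNodeTPM, mechanism, mech_state, purview
) -> Repertoire:
    """Distribution over future purview states given the mechanism's state.

    Product over purview nodes of the node's on-probability conditioned on
    the mechanism being in ``mech_state`` with all other nodes uniform.  An
    empty mechanism yields the unconstrained effect repertoire.
    """
    mechanism, purview = tuple(mechanism), tuple(purview)
    _check_nodes(tpm, mechanism)
    _check_nodes(tpm, purview)
    if not purview:
        raise ValueError("purview must be non-empty")
    if len(mech_state) != len(mechanism):
        raise ValueError("mech_state length must match mechanism")
    n = tpm.n_nodes
    states = np.arange(2**n)
    consistent = np.ones(2**n, dtype=bool)
    for i, b in zip(mechanism, mech_state):
        consistent &= ((states >> i) & 1) == b
    marg = tpm.probs[consistent].mean(axis=0)  # (n,) on-probabilities
    probs = np.ones(2 ** len(purview))
    for k, j in enumerate(purview):
        on = (np.arange(2 ** len(purview)) >> k) & 1
        probs *= np.where(on, marg[j], 1.0 - marg[j])
    return Repertoire(probs, purview, EFFECT)


def cause_repertoire(
    tpm: StateByNodeTPM, mechanism, mech_state, purview
) -> Repertoire:
    """Distribution over past purview states given the mechanism's state.

    Bayesian inversion: proportional, over purview states ``z``, to the
    product over mechanism nodes of the likelihood of that node's current
    state given the purview in ``z`` at t-tau and non-purview past nodes
    uniform.  A zero normalizer (unreachable mechanism state) returns the
    uniform distribution flagged as degenerate.
    """
    mechanism, purview = tuple(mechanism), tuple(purview)
    _check_nodes(tpm, mechanism)
    _check_nodes(tpm, purview)
    if not purview:
        raise ValueError("purview must be non-empty")
    if len(mech_state) != len(mechanism):
        raise ValueError("mech_state length must match mechanism")
    n = tpm.n_nodes
    psz = 2 ** len(purview)
    if not mechanism:
        return Repertoire(np.full(psz, 1.0 / psz), purview, CAUSE)
    states = np.arange(2**n)
    z_of_s = np.zeros(2**n, dtype=np.int64)
    for k, j in enumerate(purview):
        z_of_s |= (((states >> j) & 1)) << k
    probs = np.ones(psz)
    for i, b in zip(mechanism, mech_state):
        lik_s = tpm.probs[:, i] if b else 1.0 - tpm.probs[:, i]
        lik_z = np.bincount(z_of_s, weights=lik_s, minlength=psz)
        lik_z /= np.bincount(z_of_s, minlength=psz)
        probs *= lik_z
    tot = probs.sum()
    if tot <= 1e-300:
        return Repertoire(
            np.full(psz, 1.0 / psz), purview, CAUSE, degenerate=True
        )
    return Repertoire(probs / tot, purview, CAUSE)


def emd(p: Repertoire, q: Repertoire) -> float:
    """Exact earth mover's distance, Hamming ground metric on purview states."""
    if tuple(p.purview) != tuple(q.purview):
        raise ValueError("repertoires must share a purview")
    if p.probs.shape != q.probs.shape:
        raise ValueError("repertoires must share a state space")
    return float(
        _engine.emd_hamming(p.probs, q.probs, _dist(len(p.purview)))
    )


def mechanism_partitions(mechanism, purview):
    """All valid bipartitions of (mechanism, purview), deterministic order.

    Unordered bipartitions; neither part may be (empty, empty), which also
    excludes the trivial whole/empty partition.  The first mechanism part
    always contains the mechanism's first node (or the whole mechanism when
    the other part's mechanism is empty).
    """
    mechanism, purview = tuple(mechanism), tuple(purview)
    mech_set, purv_set = set(mechanism), set(purview)
    first = mechanism[0]
    out = []
    m_subsets = [
        tuple(i for i in mechanism if (bit >> mechanism.index(i)) & 1)
        for bit in range(2 ** len(mechanism))
    ]
    for m1 in m_subsets:
        if first not in m1:
            continue
        m2 = tuple(i for i in mechanism if i not in m1)
        for pbits in range(2 ** len(purview)):
            p1 = tuple(j for k, j in enumerate(purview) if (pbits >> k) & 1)
            p2 = tuple(j for j in purview if j not in p1)
            if not m2 and not p2:
                continue  # trivial partition
            out.append(MechanismPartition((m1, p1), (m2, p2)))
    assert mech_set and purv_set
    return out


def _part_repertoire(tpm, direction, mechanism, mech_state, partition):
    """Product of the two parts' repertoires on the purview state space."""
    state_of = dict(zip(mechanism, mech_state))
    purview = tuple(
        sorted(partition.part1[1] + partition.part2[1])
    )
    probs = np.ones(2 ** len(purview))
    rep_fn = cause_repertoire if direction == CAUSE else effect_repertoire
    for mech_part, purv_part in (partition.part1, partition.part2):
        if not purv_part:
            continue
        part_state = tuple(state_of[i] for i in mech_part)
        rep = rep_fn(tpm, mech_part, part_state, purv_part)
        # place the part's distribution on the joint purview space
        expand = np.ones(2 ** len(purview))
        for s in range(2 ** len(purview)):
            z = 0
            for k, j in enumerate(purv_part):
                bit = (s >> purview.index(j)) & 1
                z |= bit << k
            expand[s] = rep.probs[z]
        probs *= expand
    return Repertoire(probs, purview, direction)


def phi_mip(
    tpm: StateByNodeTPM, mechanism, mech_state, purview, direction
) -> tuple[float, MechanismPartition]:
    """Irreducibility of a mechanism over a purview in one direction.

    Minimum over all valid bipartitions of the EMD between the whole
    repertoire and the product of the parts' repertoires (severed influences
    noised by uniform marginalization).  Ties keep the first partition in
    enumeration order.
    """
    mechanism, purview = tuple(mechanism), tuple(purview)
    if not mechanism:
        raise ValueError("mechanism must be non-empty")
    rep_fn = cause_repertoire if direction == CAUSE else effect_repertoire
    whole = rep_fn(tpm, mechanism, mech_state, purview)
    best, best_part = np.inf, None
    for part in mechanism_partitions(mechanism, purview):
        cut_rep = _part_repertoire(tpm, direction, mechanism, mech_state, part)
        d = emd(whole, cut_rep)
        if d < best - 1e-15:
            best = d
            best_part = part
    return float(best), best_part


def core_repertoire(
    tpm: StateByNodeTPM, mechanism, mech_state, direction
) -> CoreRepertoire:
    """The phi-maximizing purview with its repertoire (core cause / effect).

    Scans all non-empty purviews; ties break toward the larger purview, then
    the first in ascending-mask order.
    """
    mechanism = tuple(mechanism)
    if not mechanism:
        raise ValueError("mechanism must be non-empty")
    n = tpm.n_nodes
    best_phi, best_purv, best_sz = -1.0, None, -1
    for pmask in range(1, 2**n):
        purview = _nodes(pmask, n)
        phi, _ = phi_mip(tpm, mechanism, mech_state, purview, direction)
        sz = len(purview)
        if phi > best_phi + 1e-10 or (phi > best_phi - 1e-10 and sz > best_sz):
            best_phi = max(best_phi, phi)
            best_purv = purview
            best_sz = sz
    rep_fn = cause_repertoire if direction == CAUSE else effect_repertoire
    rep = rep_fn(tpm, mechanism, mech_state, best_purv)
    return CoreRepertoire(best_purv, rep, float(best_phi))


def concept(tpm: StateByNodeTPM, mechanism, system_state) -> Concept:
    """A mechanism's core cause, core effect, and phi = min of the two."""
    mechanism = tuple(mechanism)
    system_state = np.asarray(system_state)
    mech_state = tuple(int(system_state[i]) for i in mechanism)
    cc = core_repertoire(tpm, mechanism, mech_state, CAUSE)
    ce = core_repertoire(tpm, mechanism, mech_state, EFFECT)
    return Concept(mechanism, cc, ce, min(cc.phi, ce.phi))


def _state_index(system_state, n) -> int:
    system_state = np.asarray(system_state)
    return int(sum(int(system_state[i]) << i for i in range(n)))


def _assemble_ces(tpm, system_state, label, engine_out):
    em, phis, phis_c, phis_e, core_c, core_e, cause_full, eff_marg = engine_out
    n = tpm.n_nodes
    system_state = np.asarray(system_state)
    concepts = []
    for mech in mechanism_order(n):
        m = _mask(mech)
        mech_state = tuple(int(system_state[i]) for i in mech)
        pc, pe = _nodes(core_c[m], n), _nodes(core_e[m], n)
        cc = CoreRepertoire(
            pc, cause_repertoire(tpm, mech, mech_state, pc), float(phis_c[m])
        )
        ce = CoreRepertoire(
            pe, effect_repertoire(tpm, mech, mech_state, pe), float(phis_e[m])
        )
        concepts.append(Concept(mech, cc, ce, float(phis[m])))
    return CauseEffectStructure(
        concepts,
        system_state,
        label=label,
        _phis=phis,
        _cause_expanded=cause_full,
        _effect_marginals=eff_marg,
        _unconstrained_effect=em[0].copy(),
    )


def compute_ces(tpm: StateByNodeTPM, system_state) -> CauseEffectStructure:
    """Concepts for all 2**n - 1 non-empty mechanisms, canonical order."""
    n = tpm.n_nodes
    out = _engine._ces(tpm.probs, _state_index(system_state, n), _dist(n))
    return _assemble_ces(tpm, system_state, "full", out)


def enumerate_cuts(n_nodes: int) -> list[SystemCut]:
    """All 2**n - 2 ordered bipartitions (from-part -> to-part)."""
    if n_nodes < 2:
        raise ValueError("a system cut needs at least 2 nodes")
    cuts = []
    for fmask in range(1, 2**n_nodes - 1):
        cuts.append(
            SystemCut(
                _nodes(fmask, n_nodes),
                _nodes((2**n_nodes - 1) ^ fmask, n_nodes),
            )
        )
    return cuts


def apply_cut(tpm: StateByNodeTPM, cut: SystemCut) -> StateByNodeTPM:
    """Replace all influences from ``cut.from_part`` onto ``cut.to_part`` by noise."""
    n = tpm.n_nodes
    fmask = _mask(cut.from_part)
    tmask = _mask(cut.to_part)
    if fmask & tmask or (fmask | tmask) != 2**n - 1 or not fmask or not tmask:
        raise ValueError("cut parts must be complementary and non-empty")
    probs = _engine._apply_cut(tpm.probs, fmask)
    return StateByNodeTPM(
        probs,
        n_nodes=n,
        tau_samples=tpm.tau_samples,
        unobserved=tpm.unobserved.copy(),
    )


def ces_distance(
    full: CauseEffectStructure, cut: CauseEffectStructure
) -> float:
    """phi-weighted distance between two cause-effect structures.

    Sum over mechanisms of min(phi_full, phi_cut) times the EMDs between the
    expanded core cause and effect repertoires, plus |phi_full - phi_cut|
    times the EMDs from the larger-phi concept's repertoires to the
    maximally uninformative distributions (uniform for causes, the
    unconstrained effect repertoire for effects).
    """
    if len(full.concepts) != len(cut.concepts) or any(
        a.mechanism != b.mechanism
        for a, b in zip(full.concepts, cut.concepts)
    ):
        raise ValueError("structures must share the mechanism census")
    if not np.array_equal(full.system_state, cut.system_state):
        raise ValueError("structures must share the system state")
    n = int(np.log2(full._cause_expanded.shape[1]))
    return float(
        _engine._ces_distance(
            full._phis,
            full._cause_expanded,
            full._effect_marginals,
            cut._phis,
            cut._cause_expanded,
            cut._effect_marginals,
            full._unconstrained_effect,
            _dist(n),
            n,
        )
    )


def compute_big_phi(tpm: StateByNodeTPM, system_state) -> SystemResult:
    """System-level integrated information with the minimal cut and both CES."""
    n = tpm.n_nodes
    if n < 2:
        raise ValueError("system-level Phi needs at least 2 nodes")
    state = _state_index(system_state, n)
    D = _dist(n)
    big_phi, best_f, _ = _engine._big_phi_state(tpm.probs, state, D)
    cut = SystemCut(_nodes(best_f, n), _nodes((2**n - 1) ^ best_f, n))
    full_ces = compute_ces(tpm, system_state)
    cut_tpm = apply_cut(tpm, cut)
    cut_out = _engine._ces(cut_tpm.probs, state, D)
    cut_ces = _assemble_ces(cut_tpm, system_state, "cut", cut_out)
    return SystemResult(float(big_phi), cut, full_ces, cut_ces)


def big_phi_and_phis(
    tpm: StateByNodeTPM, system_state
) -> tuple[float, np.ndarray]:
    """Fast path: (Phi, mechanism phis in canonical order) for one state.

    Used by the study pipeline, which needs only the numbers, not the
    repertoire objects.
    """
    n = tpm.n_nodes
    state = _state_index(system_state, n)
    big_phi, _, phis = _engine._big_phi_state(tpm.probs, state, _dist(n))
    order = [_mask(m) for m in mechanism_order(n)]
    return float(big_phi), phis[order]
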
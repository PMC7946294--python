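"""Ground-truth binary Markov systems and pseudo-LFP study generation.

Two families of generators back the test surface of the whole pipeline:

* **Binary Markov systems** with a known state-by-node TPM -- feedforward
  copy chains (which must carry zero system-level integrated information) and
  logistically coupled recurrent networks (whose integration grows with the
  coupling strength).  Sampling from these systems closes the
  estimate-and-recover loop for the TPM estimator.

* **Pseudo-LFP recordings** -- coupled second-order autoregressive processes
  producing oscillatory, autocorrelated traces.  A study mimics the real
  experiment's dimensions (13 subjects x 2 conditions x 8 epochs x 15
  channels x 2250 samples at 1000 Hz) with bidirectional cross-channel
  coupling during "wake" and the same couplings scaled down by one factor
  during "anesthesia", the generative analogue of anesthesia preferentially
  disrupting global communication.

All randomness fans out from a single integer seed through per-subject /
per-epoch substreams, so identical seeds reproduce studies bit for bit.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import BinaryTimeSeries, ContinuousRecording
from .tpm import StateByNodeTPM

WAKE = "wake"
ANESTHESIA = "anesthesia"
CONDITIONS = (WAKE, ANESTHESIA)


@dataclass
class GroundTruthSystem:
    """A binary Markov system with a known generative TPM."""

    n_nodes: int
    tpm: StateByNodeTPM
    topology_label: str  # feedforward | recurrent | independent | coupled_pairs


@dataclass
class SyntheticStudyConfig:
    """Dimensions and coupling strengths of a synthetic wake/anesthesia study.

    Defaults mirror the real study's dimensions.  ``coupling_anesthesia`` must
    be below ``coupling_wake``; both are dimensionless scalings of the same
    cross-channel weight matrix.
    """

    n_subjects: int = 13
    n_epochs_per_condition: int = 8
    n_channels: int = 15
    samples_per_epoch: int = 2250
    sampling_rate: float = 1000.0
    coupling_wake: float = 0.35
    coupling_anesthesia: float = 0.07
    seed: int = 0

    def __post_init__(self):
        if self.coupling_anesthesia > self.coupling_wake:
            raise ValueError(
                "coupling_anesthesia must not exceed coupling_wake"
            )

    def coupling(self, condition: str) -> float:
        if condition == WAKE:
            return self.coupling_wake
        if condition == ANESTHESIA:
            return self.coupling_anesthesia
        raise ValueError(f"unknown condition {condition!r}")


@dataclass
class ContinuousStudy:
    """Per-(subject, condition, epoch) continuous channel matrices."""

    config: SyntheticStudyConfig
    epochs: dict = field(default_factory=dict)  # (subj, cond, epoch) -> rec

    def recording(self, subject: int, condition: str, epoch: int) -> ContinuousRecording:
        return self.epochs[(subject, condition, epoch)]

    def keys(self):
        return sorted(self.epochs.keys(), key=lambda k: (k[0], k[1], k[2]))

    def save(self, out_dir: str | Path) -> None:
        """Write one delimited matrix per epoch plus a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = []
        for (subj, cond, ep), rec in sorted(self.epochs.items()):
            name = f"subject{subj:02d}_{cond}_epoch{ep:02d}.csv"
            np.savetxt(out / name, rec.data, delimiter=",", fmt="%.10g")
            manifest.append(
                {
                    "file": name,
                    "subject": subj,
                    "condition": cond,
                    "epoch": ep,
                    "sampling_rate": rec.sampling_rate,
                    "coupling": self.config.coupling(cond),
                    "seed": self.config.seed,
                }
            )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, in_dir: str | Path, config: SyntheticStudyConfig | None = None):
        in_dir = Path(in_dir)
        manifest = json.loads((in_dir / "manifest.json").read_text())
        study = cls(config=config)
        for entry in manifest:
            data = np.loadtxt(in_dir / entry["file"], delimiter=",")
            study.epochs[(entry["subject"], entry["condition"], entry["epoch"])] = (
                ContinuousRecording(data, entry["sampling_rate"])
            )
        return study


def desk_study_config(
    seed: int = 0, coupled: bool = True, n_subjects: int = 2
) -> SyntheticStudyConfig:
    """Reduced 6-channel study used for desk-scale end-to-end runs.

    Same epoch structure and sampling rate as the full configuration, with 6
    channels and 2 subjects so a complete Phi/IIS/decoding pass finishes in
    minutes on one CPU.  ``coupled=False`` gives the null study: both
    conditions share the wake coupling, so no condition signal exists by
    construction.
    """
    default = SyntheticStudyConfig()
    return SyntheticStudyConfig(
        n_subjects=n_subjects,
        n_channels=6,
        coupling_wake=default.coupling_wake,
        coupling_anesthesia=(
            default.coupling_anesthesia if coupled else default.coupling_wake
        ),
        seed=seed,
    )


def make_feedforward_tpm(n_nodes: int, copy_fidelity: float) -> StateByNodeTPM:
    """Copy chain: node i+1 copies node i with probability ``copy_fidelity``.

    Node 1 turns on with fixed probability 0.5 independent of everything, so
    the chain is driven but has no feedback whatsoever; such a system must
    generate zero system-level integrated information.
    """
    if not 2 <= n_nodes <= 5:
        raise ValueError("n_nodes must be between 2 and 5")
    if not 0.5 <= copy_fidelity <= 1.0:
        raise ValueError("copy_fidelity must lie in [0.5, 1]")
    n_states = 2**n_nodes
    probs = np.empty((n_states, n_nodes))
    probs[:, 0] = 0.5
    for j in range(1, n_nodes):
        pred_on = (np.arange(n_states) >> (j - 1)) & 1
        probs[:, j] = np.where(pred_on, copy_fidelity, 1.0 - copy_fidelity)
    return StateByNodeTPM(probs, n_nodes=n_nodes)


def make_recurrent_tpm(n_nodes: int, coupling: float, seed: int) -> StateByNodeTPM:
    """Logistic recurrent network with symmetric random weights.

    Each node's on-probability is a logistic function of a weighted sum of all
    nodes' current spins (+-1), with weights drawn symmetrically from N(0, 1)
    and scaled by ``coupling``.  Zero coupling gives the fully unconstrained
    all-0.5 matrix; the logistic link keeps every entry a valid probability at
    any coupling.
    """
    if coupling < 0:
        raise ValueError("coupling must be >= 0")
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((n_nodes, n_nodes))
    w = (w + w.T) / np.sqrt(2.0)  # symmetric, entries still unit variance
    n_states = 2**n_nodes
    spins = 2.0 * ((np.arange(n_states)[:, None] >> np.arange(n_nodes)) & 1) - 1.0
    drive = coupling * spins @ w  # (states, nodes)
    probs = 1.0 / (1.0 + np.exp(-drive))
    return StateByNodeTPM(probs, n_nodes=n_nodes)


def sample_time_series(
    tpm: StateByNodeTPM, n_samples: int, seed: int
) -> BinaryTimeSeries:
    """Sample a Markov chain: each node drawn independently from its TPM row.

    The per-node independent draws realize the conditional-independence
    assumption of the state-by-node model (no instantaneous interactions).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    n = tpm.n_nodes
    weights = 1 << np.arange(n)
    data = np.empty((n_samples, n), dtype=np.int8)
    state = rng.integers(0, 2, size=n)
    data[0] = state
    u = rng.random((n_samples - 1, n))
    idx = int(state @ weights)
    for t in range(1, n_samples):
        state = (u[t - 1] < tpm.probs[idx]).astype(np.int8)
        data[t] = state
        idx = int(state @ weights)
    return BinaryTimeSeries(data, epoch_id="sampled")


def is_feedforward(tpm: StateByNodeTPM) -> bool:
    """Structural check: does some node ordering make the system feedforward?

    A system is feedforward if its nodes can be ordered so that no node's
    next-state probability depends on any *later* node's current state, i.e.
    each TPM column is invariant to flips of later-node bits.  Exhaustive over
    orderings (n <= 5).
    """
    n = tpm.n_nodes
    states = np.arange(2**n)
    depends = np.zeros((n, n), dtype=bool)  # depends[j, i]: column j reads bit i
    for j in range(n):
        col = tpm.probs[:, j]
        for i in range(n):
            if not np.allclose(col, col[states ^ (1 << i)], atol=1e-12):
                depends[j, i] = True
    for order in itertools.permutations(range(n)):
        pos = {node: k for k, node in enumerate(order)}
        if all(
            not depends[j, i] or pos[i] <= pos[j]
            for j in range(n)
            for i in range(n)
            if i != j
        ):
            return True
    return False


def _subject_dynamics(config: SyntheticStudyConfig, subject: int):
    """Per-subject AR(2) parameters: oscillator poles and coupling weights."""
    rng = np.random.default_rng([config.seed, subject, 0xA12])
    n = config.n_channels
    freqs = rng.uniform(5.0, 40.0, size=n)  # Hz, per-channel oscillation
    radius = 0.9
    theta = 2.0 * np.pi * freqs / config.sampling_rate
    a1 = 2.0 * radius * np.cos(theta)
    a2 = np.full(n, -(radius**2))
    g = rng.standard_normal((n, n))
    g = g + g.T  # bidirectional coupling
    np.fill_diagonal(g, 0.0)
    if n > 1:
        g /= np.linalg.norm(g, 2)  # unit spectral norm before scaling
    return a1, a2, g


def _stable_coupled_ar(a1, a2, coupling, g):
    """Companion-form AR(2) matrices, rescaled if marginally unstable."""
    n = a1.size
    A1 = np.diag(a1) + coupling * g
    A2 = np.diag(a2)
    companion = np.block(
        [[A1, A2], [np.eye(n), np.zeros((n, n))]]
    )
    rho = np.max(np.abs(np.linalg.eigvals(companion)))
    if rho >= 0.995:
        shrink = 0.99 / rho
        A1 = A1 * shrink
        A2 = A2 * shrink**2
    return A1, A2


def generate_pseudo_lfp(config: SyntheticStudyConfig) -> ContinuousStudy:
    """Simulate the full study: coupled AR(2) traces per subject/condition/epoch.

    Channels are damped stochastic oscillators (AR(2), Gaussian innovations)
    with symmetric cross-channel coupling at lag 1.  Wake epochs use
    ``coupling_wake``; anesthesia epochs scale the identical weight matrix by
    ``coupling_anesthesia``.  Subjects differ in oscillator frequencies and
    weights; epochs differ only in their noise stream.
    """
    study = ContinuousStudy(config=config)
    n = config.n_channels
    burn_in = 300
    total = config.samples_per_epoch + burn_in
    for subject in range(1, config.n_subjects + 1):
        a1, a2, g = _subject_dynamics(config, subject)
        for cond_idx, condition in enumerate(CONDITIONS):
            A1, A2 = _stable_coupled_ar(a1, a2, config.coupling(condition), g)
            for epoch in range(1, config.n_epochs_per_condition + 1):
                rng = np.random.default_rng(
                    [config.seed, subject, cond_idx + 1, epoch]
                )
                eps = rng.standard_normal((total, n))
                x = np.zeros((total, n))
                x[0], x[1] = eps[0], eps[1]
                for t in range(2, total):
                    x[t] = A1 @ x[t - 1] + A2 @ x[t - 2] + eps[t]
                study.epochs[(subject, condition, epoch)] = ContinuousRecording(
                    x[burn_in:], config.sampling_rate
                )
    return study
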
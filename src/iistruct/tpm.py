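"""State-by-node transition probability matrices estimated from binary series.

The system model used throughout this package is the *state-by-node* TPM: a
``2**n x n`` matrix whose row ``s`` gives, for each node ``j``, the probability
that ``j`` is 'on' at time ``t + tau`` given that the whole system was in state
``s`` at time ``t``.  Nodes are conditionally independent given the past state
(no instantaneous interactions), so the full ``2**n x 2**n`` state-by-state
matrix is recoverable as a product of per-node Bernoullis.

State indexing is little-endian: the node with the lowest channel label is the
least-significant bit.  The convention is declared once in
:attr:`StateByNodeTPM.state_order` and threaded everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LITTLE_ENDIAN = "little-endian"


def state_index(bits: np.ndarray | list[int]) -> int:
    """Map a binary state vector to its row index (node 0 = LSB)."""
    bits = np.asarray(bits)
    if bits.ndim != 1:
        raise ValueError("state must be a 1-D binary vector")
    return int(np.sum(bits.astype(np.int64) << np.arange(bits.size)))


def state_from_index(index: int, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`state_index`."""
    if not 0 <= index < 2**n_nodes:
        raise ValueError(f"index {index} out of range for {n_nodes} nodes")
    return (index >> np.arange(n_nodes)) & 1


@dataclass
class StateByNodeTPM:
    """``2**n x n`` conditional probability matrix at lag ``tau_samples``."""

    probs: np.ndarray
    n_nodes: int
    tau_samples: int = 1
    state_order: str = LITTLE_ENDIAN
    #: True for rows whose current state never occurred in the data; such rows
    #: are filled with the maximum-entropy value 0.5 and carry zero weight in
    #: every state-weighted average downstream.
    unobserved: np.ndarray = field(default=None)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (2**self.n_nodes, self.n_nodes):
            raise ValueError(
                f"probs must have shape {(2**self.n_nodes, self.n_nodes)}, "
                f"got {self.probs.shape}"
            )
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("TPM entries must lie in [0, 1]")
        if self.unobserved is None:
            self.unobserved = np.zeros(2**self.n_nodes, dtype=bool)

    def state_by_state(self) -> np.ndarray:
        """Expand to the full ``2**n x 2**n`` matrix (product of Bernoullis)."""
        n = self.n_nodes
        out = np.ones((2**n, 2**n))
        for j in range(n):
            on = (np.arange(2**n) >> j) & 1
            pj = self.probs[:, j][:, None]
            out *= np.where(on[None, :], pj, 1.0 - pj)
        return out


@dataclass
class StateCounts:
    """Occurrences of each system state as the time-``t`` end of a transition."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def estimate_tpm(
    series, nodes, tau_samples: int = 1
) -> tuple[StateByNodeTPM, StateCounts]:
    """Estimate the state-by-node TPM of ``nodes`` from one binarized epoch.

    Every valid transition within the epoch is counted (overlapping windows,
    stride 1; transitions never cross epoch boundaries).  For each observed
    current state ``s`` and node ``j``::

        probs[s, j] = #(system == s at t, node j on at t+tau) / #(system == s at t)

    Unobserved current states are filled with 0.5 per node (maximum entropy)
    and flagged in :attr:`StateByNodeTPM.unobserved`; they receive zero weight
    in all state-weighted averages, so the fill never reaches a reported value.

    Parameters
    ----------
    series
        A :class:`~iistruct.preprocess.BinaryTimeSeries` or a 0/1 array of
        shape ``(samples, channels)``.
    nodes
        Column indices of the channels forming the system, in label order.
    tau_samples
        Lag in samples (4 at 1000 Hz corresponds to the 4 ms default).
    """
    data = getattr(series, "data", series)
    data = np.asarray(data)
    nodes = list(nodes)
    if len(set(nodes)) != len(nodes):
        raise ValueError("nodes must be distinct")
    if tau_samples < 1:
        raise ValueError("tau_samples must be >= 1")
    n_samples = data.shape[0]
    if n_samples <= tau_samples:
        raise ValueError(
            f"epoch of {n_samples} samples has no transitions at lag {tau_samples}"
        )
    n = len(nodes)
    sub = data[:, nodes].astype(np.int64)
    idx = sub @ (1 << np.arange(n))  # little-endian state index per sample

    cur = idx[: n_samples - tau_samples]
    counts = np.bincount(cur, minlength=2**n)
    on_counts = np.zeros((2**n, n), dtype=np.int64)
    nxt = sub[tau_samples:]
    np.add.at(on_counts, cur, nxt)

    observed = counts > 0
    probs = np.full((2**n, n), 0.5)
    probs[observed] = on_counts[observed] / counts[observed, None]
    tpm = StateByNodeTPM(
        probs, n_nodes=n, tau_samples=tau_samples, unobserved=~observed
    )
    return tpm, StateCounts(counts)
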
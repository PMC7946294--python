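"""Study-level orchestration: channel sets, state weighting, epoch averaging.

For every (subject, condition, epoch, channel set) the pipeline estimates a
state-by-node TPM from the binarized epoch, computes system-level Phi and the
mechanism-level phi vector (the integrated information structure, IIS) for
every *observed* system state, and collapses states by occurrence-weighted
averaging.  Unobserved states carry zero weight, so skipping them leaves
every reported average unchanged.  Epoch averages are plain means.

Channel sets default to size 4: with 15 channels that is C(15, 4) = 1365
systems of 16 states and 15 mechanisms each (4/6/4/1 of sizes 1-4).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iit import big_phi_and_phis, mechanism_order
from .preprocess import binarize_median
from .synthetic import CONDITIONS, ContinuousStudy
from .tpm import StateCounts, estimate_tpm


@dataclass
class ChannelSetFeatures:
    """Spatial summary of a channel set on the linear probe.

    ``location``: mean channel label relative to channel 1 (the most central
    channel); larger means more peripheral.  ``total_path_distance``: sum of
    pairwise absolute label differences; larger means more spread out.
    """

    location: float
    total_path_distance: float


def channel_sets(n_channels: int, k: int) -> list[tuple[int, ...]]:
    """All C(n, k) k-channel subsets of labels 1..n, lexicographic order."""
    if not 1 <= k <= n_channels:
        raise ValueError(f"need 1 <= k <= n_channels, got k={k}")
    return list(itertools.combinations(range(1, n_channels + 1), k))


def state_weighted_average(per_state_values, counts: StateCounts) -> float:
    """Average a per-state quantity weighted by state occurrence counts."""
    c = counts.counts
    if isinstance(per_state_values, dict):
        v = np.zeros(c.size)
        for s, val in per_state_values.items():
            v[s] = val
    else:
        v = np.asarray(per_state_values, dtype=float)
    if v.shape != c.shape:
        raise ValueError("values and counts must cover the same state space")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero counts: state-weighted average undefined")
    return float((v * c).sum() / total)


def epoch_average(per_epoch) -> float:
    """Arithmetic mean across epochs."""
    per_epoch = list(per_epoch)
    if not per_epoch:
        raise ValueError("cannot average zero epochs")
    return float(np.mean(per_epoch))


def spatial_features(channel_set) -> ChannelSetFeatures:
    """Location (mean label - 1) and total path distance of a channel set."""
    labels = np.asarray(channel_set, dtype=float)
    if len(set(channel_set)) != len(channel_set):
        raise ValueError("channel labels must be distinct")
    location = float(np.mean(labels - 1.0))
    dist = float(
        sum(
            abs(a - b)
            for a, b in itertools.combinations(labels, 2)
        )
    )
    return ChannelSetFeatures(location, dist)


def mechanism_sizes(k: int) -> np.ndarray:
    """Mechanism sizes in canonical order (e.g. k=4: four 1s, six 2s, ...)."""
    return np.array([len(m) for m in mechanism_order(k)])


def binarize_study(study: ContinuousStudy, quantile: float = 0.5) -> dict:
    """Median-split every epoch of a continuous study."""
    return {
        key: binarize_median(rec, quantile=quantile, epoch_id=f"{key}")
        for key, rec in study.epochs.items()
    }


def set_column(channel_set) -> str:
    return "-".join(str(c) for c in channel_set)


def run_study(
    bins: dict,
    k: int = 4,
    tau_samples: int = 4,
    quantile: float = 0.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Compute Phi and the IIS for every epoch and channel set of a study.

    Parameters
    ----------
    bins
        Mapping (subject, condition, epoch) -> BinaryTimeSeries, e.g. from
        :func:`binarize_study`.
    k
        Channel-set size (2-5; default 4).
    tau_samples
        TPM lag in samples (default 4, i.e. 4 ms at 1000 Hz).
    quantile, seed
        Recorded as provenance columns only.

    Returns
    -------
    A tidy table with one row per (subject, condition, epoch, channel set):
    ``big_phi``, the state-weighted mechanism phis ``phi_1 .. phi_{2^k-1}``
    (canonical mechanism order), spatial features, and provenance.
    """
    if not 2 <= k <= 5:
        raise ValueError("channel-set size k must be between 2 and 5")
    keys = sorted(bins.keys())
    n_channels = bins[keys[0]].n_channels
    sets = channel_sets(n_channels, k)
    n_mechs = 2**k - 1
    rows = []
    for key in keys:
        subject, condition, epoch = key
        series = bins[key]
        if series is None:
            warnings.warn(f"missing epoch {key}; skipped", stacklevel=2)
            continue
        for cset in sets:
            nodes = [c - 1 for c in cset]
            tpm, counts = estimate_tpm(series, nodes, tau_samples=tau_samples)
            observed = np.flatnonzero(counts.counts)
            per_state_phi = np.zeros(2**k)
            per_state_mech = np.zeros((2**k, n_mechs))
            for s in observed:
                state = (int(s) >> np.arange(k)) & 1
                big_phi, phis = big_phi_and_phis(tpm, state)
                per_state_phi[s] = big_phi
                per_state_mech[s] = phis
            feats = spatial_features(cset)
            row = {
                "subject": subject,
                "condition": condition,
                "epoch": epoch,
                "channel_set": set_column(cset),
                "set_location": feats.location,
                "set_path_distance": feats.total_path_distance,
                "big_phi": state_weighted_average(per_state_phi, counts),
                "tau_samples": tau_samples,
                "quantile": quantile,
                "seed": seed,
            }
            for m in range(n_mechs):
                row[f"phi_{m + 1}"] = state_weighted_average(
                    per_state_mech[:, m], counts
                )
            rows.append(row)
    return pd.DataFrame(rows)


def condition_means(table: pd.DataFrame) -> pd.Series:
    """Mean Phi per condition, averaging epochs then subjects and sets."""
    per_epoch = table.groupby(["condition", "subject", "channel_set"])[
        "big_phi"
    ].mean()
    return per_epoch.groupby("condition").mean()
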
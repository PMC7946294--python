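"""Continuous multichannel recordings -> binarized, epoch-segmented series.

The preprocessing chain mirrors standard practice for linear-probe LFP data:
bipolar re-referencing of adjacent electrodes (16 electrodes -> 15 channels,
channel 1 the most central), segmentation into fixed-length epochs, and a
per-channel, per-epoch median split into binary 'on'/'off' states.  The median
split guarantees near-maximal entropy per channel, so no channel dominates the
transition statistics by base-rate alone.

A pass-through slot is kept where a line-noise notch filter would sit for real
recordings; synthetic data carries no line noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ContinuousRecording:
    """Real-valued multichannel trace, ``data`` of shape (samples, channels)."""

    data: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("recording must be non-empty")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class BinaryTimeSeries:
    """Binarized epoch: 0/1 ``data`` of shape (samples, channels).

    ``channel_labels`` are 1-based ordered integers (1 = most central channel);
    ``thresholds`` records the per-channel voltage threshold used.
    """

    data: np.ndarray
    epoch_id: str = ""
    channel_labels: tuple = ()
    thresholds: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("binary series entries must be 0 or 1")
        self.data = self.data.astype(np.int8)
        if not self.channel_labels:
            self.channel_labels = tuple(range(1, self.data.shape[1] + 1))

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def bipolar_rereference(rec: ContinuousRecording) -> ContinuousRecording:
    """Subtract neighbouring electrodes: channel i = electrode i - electrode i+1.

    A recording from ``m`` electrodes yields ``m - 1`` re-referenced channels,
    removing signal components common to adjacent sites.
    """
    if rec.n_channels < 2:
        raise ValueError("bipolar re-referencing needs at least 2 electrodes")
    return ContinuousRecording(
        rec.data[:, :-1] - rec.data[:, 1:], rec.sampling_rate
    )


def segment_epochs(
    rec: ContinuousRecording, epoch_seconds: float
) -> list[ContinuousRecording]:
    """Split into consecutive non-overlapping epochs of ``epoch_seconds``.

    The trailing partial segment is discarded.  An 18 s recording at 1000 Hz
    with 2.25 s epochs yields 8 epochs of 2250 samples.
    """
    n_per = epoch_seconds * rec.sampling_rate
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(
            "epoch_seconds x sampling_rate must be a whole number of samples"
        )
    n_per = int(round(n_per))
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"epoch ({n_per} samples)"
        )
    return [
        ContinuousRecording(
            rec.data[i * n_per : (i + 1) * n_per], rec.sampling_rate
        )
        for i in range(n_epochs)
    ]


def binarize_median(
    epoch: ContinuousRecording,
    quantile: float = 0.5,
    epoch_id: str = "",
) -> BinaryTimeSeries:
    """Median-split binarization: 'on' iff strictly above the channel threshold.

    The threshold is the within-epoch per-channel ``quantile`` (default the
    median); exact-threshold samples go to 'off'.  With tie-free continuous
    data and an even number of samples this puts exactly half the samples 'on'
    per channel.  Constant channels degenerate to all-'off' and trigger a
    warning (zero entropy carries no transition information).
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie strictly between 0 and 1")
    thresholds = np.quantile(epoch.data, quantile, axis=0)
    constant = np.ptp(epoch.data, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"channel(s) {np.flatnonzero(constant) + 1} are constant; "
            "binarized to all-'off' (degenerate entropy)",
            stacklevel=2,
        )
    return BinaryTimeSeries(
        (epoch.data > thresholds).astype(np.int8),
        epoch_id=epoch_id,
        thresholds=thresholds,
    )
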
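"""EEG preprocessing: band-pass filtering, epoching, artifact gating, channel selection.

The fixed preprocessing order is filter -> (optional EOG regression) ->
1-s epoching -> amplitude-threshold artifact rejection.  Cortical
characterization additionally drops the fronto-central/temporal channel
groups; classification keeps all 61 channels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .montage import GROUP_PREFIXES, group_of

logger = logging.getLogger(__name__)

#: Channel groups excluded from the cortical-characterization path.
DEFAULT_EXCLUDED_GROUPS: frozenset[str] = frozenset({"Fp", "FC", "C", "CP", "T", "TP"})

#: Artifact amplitude threshold, microvolts.
ARTIFACT_THRESHOLD_UV = 80.0


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in microvolts.

    ``samples`` is channels x time; an optional EOG trace rides along for
    blink regression.
    """

    samples: np.ndarray          # (n_channels, n_times), microvolts
    fs: float                    # Hz
    channel_labels: tuple
    condition: str = ""
    eog: np.ndarray | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("label count must equal channel-row count")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples in recording")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class EpochedEEG:
    """1-s epochs with a per-epoch artifact mask (True = artifact)."""

    epochs: np.ndarray           # (n_epochs, n_channels, n_samples)
    fs: float
    channel_labels: tuple
    condition: str = ""
    artifact_mask: np.ndarray = field(default=None)
    epoch_times: np.ndarray = field(default=None)   # epoch onsets, s

    def __post_init__(self):
        if self.epochs.shape[2] != int(round(self.fs)):
            raise ValueError("epochs must be exactly 1 s long")
        n = self.epochs.shape[0]
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(n, dtype=bool)
        if self.epoch_times is None:
            self.epoch_times = np.arange(n, dtype=float)
        if len(self.artifact_mask) != n:
            raise ValueError("mask length must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def clean(self) -> np.ndarray:
        """Epochs with artifacts removed."""
        return self.epochs[~self.artifact_mask]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification (default 5th order, 2-45 Hz)."""

    order: int = 5
    band: tuple = (2.0, 45.0)
    mode: str = "zero-phase"     # "zero-phase" | "causal"

    def validate(self, fs: float) -> None:
        lo, hi = self.band
        if not (0 < lo < hi < fs / 2):
            raise ValueError(f"band {self.band} invalid for fs={fs}")
        if self.mode not in ("zero-phase", "causal"):
            raise ValueError(f"unknown filter mode {self.mode!r}")


def bandpass_filter(rec: EEGRecording, spec: FilterSpec = FilterSpec()) -> EEGRecording:
    """Band-pass filter each channel independently (zero-phase by default)."""
    spec.validate(rec.fs)
    sos = signal.butter(spec.order, spec.band, btype="bandpass", fs=rec.fs, output="sos")
    if spec.mode == "zero-phase":
        out = signal.sosfiltfilt(sos, rec.samples, axis=1)
        eog = None if rec.eog is None else signal.sosfiltfilt(sos, rec.eog)
    else:
        out = signal.sosfilt(sos, rec.samples, axis=1)
        eog = None if rec.eog is None else signal.sosfilt(sos, rec.eog)
    return replace(rec, samples=out, eog=eog)


def regress_eog(rec: EEGRecording) -> EEGRecording:
    """Subtract the least-squares EOG projection from every EEG channel.

    A linear stand-in for dedicated online blink-correction: for each
    channel, the regression weight of the EOG trace is estimated over the
    whole recording and the fitted component removed, leaving the output
    (empirically) uncorrelated with EOG.
    """
    if rec.eog is None:
        warnings.warn("no EOG channel present; EOG regression skipped")
        return rec
    eog = rec.eog - rec.eog.mean()
    denom = float(eog @ eog)
    if denom == 0:
        warnings.warn("EOG channel is constant; EOG regression skipped")
        return rec
    weights = (rec.samples - rec.samples.mean(axis=1, keepdims=True)) @ eog / denom
    cleaned = rec.samples - weights[:, None] * eog[None, :]
    return replace(rec, samples=cleaned)


def epoch_signal(rec: EEGRecording) -> EpochedEEG:
    """Cut the recording into consecutive non-overlapping 1-s epochs.

    Epochs start at t = 0; a trailing partial second is dropped.
    """
    n_per = int(round(rec.fs))
    n_epochs = rec.samples.shape[1] // n_per
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")
    cut = rec.samples[:, : n_epochs * n_per]
    epochs = cut.reshape(rec.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    return EpochedEEG(
        epochs=epochs.copy(),
        fs=rec.fs,
        channel_labels=tuple(rec.channel_labels),
        condition=rec.condition,
        epoch_times=np.arange(n_epochs, dtype=float),
    )


def reject_artifacts(ep: EpochedEEG, threshold: float = ARTIFACT_THRESHOLD_UV) -> EpochedEEG:
    """Flag epochs in which any sample strictly exceeds ±threshold microvolts."""
    if threshold <= 0:
        raise ValueError("artifact threshold must be positive")
    mask = np.abs(ep.epochs).max(axis=(1, 2)) > threshold
    n = int(mask.sum())
    logger.info(
        "artifact rejection (%s): %d/%d epochs flagged (%.2f%%)",
        ep.condition or "?", n, ep.n_epochs, 100.0 * n / ep.n_epochs,
    )
    return EpochedEEG(
        epochs=ep.epochs,
        fs=ep.fs,
        channel_labels=ep.channel_labels,
        condition=ep.condition,
        artifact_mask=mask,
        epoch_times=ep.epoch_times,
    )


def channel_subset_indices(labels, excluded_groups=DEFAULT_EXCLUDED_GROUPS) -> list[int]:
    """Indices of channels whose 10-10 group prefix is NOT excluded."""
    unknown = set(excluded_groups) - set(GROUP_PREFIXES)
    if unknown:
        raise ValueError(f"unknown channel group(s): {sorted(unknown)}")
    return [i for i, lab in enumerate(labels) if group_of(lab) not in excluded_groups]


def select_channels(obj, excluded_groups=DEFAULT_EXCLUDED_GROUPS):
    """Drop the channels of the excluded 10-10 groups from a recording or epochs.

    With the default exclusion set on the 61-channel montage this removes
    28 channels and keeps 33.  Group membership uses longest-prefix
    matching, so excluding "T" drops T7/T8 but not FT7 or TP7.
    """
    keep = channel_subset_indices(obj.channel_labels, excluded_groups)
    labels = tuple(obj.channel_labels[i] for i in keep)
    if isinstance(obj, EEGRecording):
        return replace(obj, samples=obj.samples[keep], channel_labels=labels)
    if isinstance(obj, EpochedEEG):
        return EpochedEEG(
            epochs=obj.epochs[:, keep, :],
            fs=obj.fs,
            channel_labels=labels,
            condition=obj.condition,
            artifact_mask=obj.artifact_mask,
            epoch_times=obj.epoch_times,
        )
    raise TypeError(f"cannot select channels on {type(obj)!r}")
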
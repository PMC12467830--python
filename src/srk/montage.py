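"""61-channel 10-10 EEG montage: labels, group prefixes, 3-D positions.

The recording montage is the 61-electrode subset of the extended 10-10
system used for high-density cognitive EEG (Fp1 ... O2, linked-earlobe
reference).  Channel *groups* are the standard 10-10 prefix families
(Fp, AF, F, FT, FC, T, C, TP, CP, P, PO, O); group membership is decided
by longest-prefix matching so that e.g. "C" never captures "CP" or "Cz"
never loses to "C".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 61 channel labels, in recording order.
CHANNELS_61: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

#: 10-10 group prefixes, longest first so prefix matching is unambiguous.
GROUP_PREFIXES: tuple[str, ...] = (
    "Fp", "AF", "FT", "FC", "TP", "CP", "PO", "F", "T", "C", "P", "O",
)

#: Posterior groups used for resting alpha / IAF estimation.
POSTERIOR_GROUPS: frozenset[str] = frozenset({"P", "PO", "O"})


def group_of(label: str) -> str:
    """Return the 10-10 group prefix of a channel label (longest match)."""
    for prefix in GROUP_PREFIXES:
        if label.startswith(prefix):
            return prefix
    raise ValueError(f"channel label {label!r} has no known 10-10 group prefix")


@dataclass(frozen=True)
class ChannelSet:
    """Ordered channel labels with their group tags and unit-sphere positions."""

    labels: tuple[str, ...]
    groups: tuple[str, ...]
    positions: np.ndarray = field(repr=False)  # (n, 3), unit sphere

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def indices_of_groups(self, groups) -> list[int]:
        wanted = set(groups)
        return [i for i, g in enumerate(self.groups) if g in wanted]


def _standard_positions(labels) -> np.ndarray:
    """Unit-sphere electrode positions from the bundled standard 10-05 montage."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mon = mne.channels.make_standard_montage("standard_1005")
    ch_pos = mon.get_positions()["ch_pos"]
    pos = np.array([ch_pos[lab] for lab in labels], dtype=float)
    # Head-frame origin is not the sphere centre; recentre then normalise.
    pos = pos - pos.mean(axis=0)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return pos


def make_montage() -> ChannelSet:
    """Build the 61-channel recording montage.

    Returns the labels in recording order, their 10-10 group prefixes and
    approximate unit-sphere positions (used by the spherical forward model).
    """
    groups = tuple(group_of(lab) for lab in CHANNELS_61)
    positions = _standard_positions(CHANNELS_61)
    return ChannelSet(labels=CHANNELS_61, groups=groups, positions=positions)
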
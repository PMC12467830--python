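"""IAF-anchored spectral features: PSD, band power, GFP, REF z-scoring.

Band boundaries are anchored to the Individual Alpha Frequency (IAF),
estimated as the posterior-channel spectral peak of a one-minute
eyes-closed rest recording.  Per 1-s epoch, a Hanning-windowed
periodogram (1 Hz resolution) yields channel x band power features;
features are normalized per feature to z-units against the passive REF
baseline condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .montage import POSTERIOR_GROUPS, group_of

#: All seven IAF-anchored bands, in order.
BAND_NAMES = ("Delta", "Theta", "AlphaHigh", "Beta1", "Beta2", "Beta3", "Gamma")

#: The six bands entering activation matrices and classification (no Delta).
ANALYSIS_BANDS = ("Theta", "AlphaHigh", "Beta1", "Beta2", "Beta3", "Gamma")

#: Band edges as offsets from the IAF: name -> (low_offset, high_offset).
#: Delta's lower edge and Gamma's upper edge are absolute (2 and 45 Hz).
_IAF_OFFSETS = {
    "Delta": (None, -6.0),
    "Theta": (-6.0, -2.0),
    "AlphaHigh": (0.0, 2.0),
    "Beta1": (2.0, 11.0),
    "Beta2": (11.0, 16.0),
    "Beta3": (16.0, 20.0),
    "Gamma": (20.0, None),
}

SPECTRUM_RANGE = (2.0, 45.0)

DEFAULT_IAF = 10.0


@dataclass(frozen=True)
class BandScheme:
    """IAF-anchored band edges; [low, high) except the last band's closed top."""

    iaf: float
    bands: dict                  # name -> (low, high), Hz
    analysis_bands: tuple = ANALYSIS_BANDS

    def edges(self, name: str) -> tuple[float, float]:
        return self.bands[name]

    def band_of(self, freq: float) -> str | None:
        for name, (lo, hi) in self.bands.items():
            if lo <= freq < hi or (name == BAND_NAMES[-1] and freq == hi):
                return name
        return None


@dataclass
class SpectrumSet:
    """Per-epoch, per-channel power spectral densities at 1 Hz resolution."""

    psd: np.ndarray              # (n_epochs, n_channels, n_freqs), power per 1-Hz bin
    freqs: np.ndarray            # bin centres, Hz
    channel_labels: tuple
    condition: str = ""


@dataclass
class FeatureTable:
    """Epoch x (channel, band) power features.

    ``values`` has one row per artifact-free epoch; the feature index is
    channel-major over ``channel_labels`` x ``band_names``.  ``units`` is
    "power" (uV^2) or "z" after REF normalization.
    """

    values: np.ndarray           # (n_epochs, n_features)
    channel_labels: tuple
    band_names: tuple
    condition: str = ""
    units: str = "power"
    degenerate: np.ndarray = field(default=None)   # features with zero REF SD

    def __post_init__(self):
        expected = len(self.channel_labels) * len(self.band_names)
        if self.values.ndim != 2 or self.values.shape[1] != expected:
            raise ValueError(
                f"feature matrix has {self.values.shape[1]} columns, expected {expected}"
            )
        if self.degenerate is None:
            self.degenerate = np.zeros(expected, dtype=bool)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature_index(self) -> list[tuple[str, str]]:
        return [(ch, b) for ch in self.channel_labels for b in self.band_names]

    def column(self, channel: str, band: str) -> int:
        return self.channel_labels.index(channel) * len(self.band_names) + (
            self.band_names.index(band)
        )

    def to_dataframe(self):
        import pandas as pd

        cols = pd.MultiIndex.from_tuples(self.feature_index(), names=["channel", "band"])
        return pd.DataFrame(self.values, columns=cols)


@dataclass
class GFPSeries:
    """Global Field Power: channel-collapsed band power per epoch, uV^2."""

    values: np.ndarray           # (n_epochs, n_bands)
    band_names: tuple
    condition: str = ""


@dataclass
class RefNormalization:
    """Per-feature mean/SD estimated on the REF condition's clean epochs."""

    mean: np.ndarray
    sd: np.ndarray
    degenerate: np.ndarray       # True where REF SD == 0

    def apply(self, values: np.ndarray) -> np.ndarray:
        sd = np.where(self.degenerate, 1.0, self.sd)
        z = (values - self.mean) / sd
        z[:, self.degenerate] = np.nan
        return z

    def invert(self, z: np.ndarray) -> np.ndarray:
        sd = np.where(self.degenerate, 1.0, self.sd)
        return z * sd + self.mean


# ---------------------------------------------------------------------------

def estimate_iaf(rest, search_range=(7.0, 13.0), prominence_ratio=1.2) -> float:
    """Estimate the Individual Alpha Frequency from eyes-closed rest epochs.

    The PSD is averaged over clean epochs of the posterior (P, PO, O)
    channels; the IAF is the 1-Hz bin with maximal power inside
    ``search_range``.  If the peak is not prominent (less than
    ``prominence_ratio`` times the median in-range power) a warning is
    issued and the population default of 10 Hz is returned.
    """
    posterior = [i for i, lab in enumerate(rest.channel_labels)
                 if group_of(lab) in POSTERIOR_GROUPS]
    if not posterior:
        raise ValueError("no posterior (P/PO/O) channels available for IAF")
    spec = compute_psd(rest)
    mean_psd = spec.psd[:, posterior, :].mean(axis=(0, 1))
    in_range = (spec.freqs >= search_range[0]) & (spec.freqs <= search_range[1])
    window = mean_psd[in_range]
    peak = float(window.max())
    floor = float(np.median(window))
    if floor > 0 and peak / floor < prominence_ratio:
        warnings.warn(
            f"no prominent alpha peak in {search_range} Hz; defaulting IAF to "
            f"{DEFAULT_IAF} Hz"
        )
        return DEFAULT_IAF
    return float(spec.freqs[in_range][int(np.argmax(window))])


def define_bands(iaf: float, offsets=None) -> BandScheme:
    """Build the IAF-anchored band scheme.

    Defaults: Delta [2, IAF-6), Theta [IAF-6, IAF-2), AlphaHigh
    [IAF, IAF+2), Beta1 [IAF+2, IAF+11), Beta2 [IAF+11, IAF+16), Beta3
    [IAF+16, IAF+20), Gamma [IAF+20, 45].  The Alpha-Low gap
    [IAF-2, IAF) is deliberately left out.  Edges outside [2, 45] Hz are
    clipped with a warning.
    """
    if not (7.0 <= iaf <= 13.0):
        raise ValueError(f"IAF {iaf} Hz outside the plausible 7-13 Hz range")
    offsets = dict(_IAF_OFFSETS if offsets is None else offsets)
    lo_abs, hi_abs = SPECTRUM_RANGE
    bands = {}
    for name, (off_lo, off_hi) in offsets.items():
        lo = lo_abs if off_lo is None else iaf + off_lo
        hi = hi_abs if off_hi is None else iaf + off_hi
        if lo < lo_abs or hi > hi_abs:
            warnings.warn(f"band {name} [{lo}, {hi}) clipped to {SPECTRUM_RANGE}")
            lo, hi = max(lo, lo_abs), min(hi, hi_abs)
        bands[name] = (lo, hi)
    return BandScheme(iaf=iaf, bands=bands)


def _hann_rfft(epochs: np.ndarray, fs: float):
    """Hann-windowed rFFT of 1-s epochs with Parseval-consistent scaling.

    Returns (freqs, X, scale) where ``sum_over_bins(scale * |X|^2 * c)``
    with c = 2 for interior bins equals the windowed mean-square power.
    """
    n = epochs.shape[-1]
    win = signal.windows.hann(n, sym=False)
    X = np.fft.rfft(epochs * win, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = 1.0 / (win @ win)
    return freqs, X, scale


def compute_psd(ep) -> SpectrumSet:
    """Per-epoch Hanning periodogram with 1 Hz bins (power per bin, uV^2)."""
    n = ep.epochs.shape[-1]
    if n != int(round(ep.fs)):
        raise ValueError("epochs must be 1 s long for 1 Hz resolution")
    freqs, X, scale = _hann_rfft(ep.epochs, ep.fs)
    psd = scale * np.abs(X) ** 2
    psd[..., 1:-1] *= 2.0        # fold negative frequencies
    return SpectrumSet(
        psd=psd, freqs=freqs, channel_labels=tuple(ep.channel_labels),
        condition=ep.condition,
    )


def band_bins(freqs: np.ndarray, scheme: BandScheme, name: str) -> np.ndarray:
    """Boolean mask of PSD bins whose centre falls inside a band."""
    lo, hi = scheme.edges(name)
    mask = (freqs >= lo) & (freqs < hi)
    if name == BAND_NAMES[-1]:   # top band is closed above
        mask |= freqs == hi
    return mask


def band_power(spec: SpectrumSet, scheme: BandScheme, bands=ANALYSIS_BANDS) -> FeatureTable:
    """Sum PSD bins into per-epoch channel x band power features (channel-major)."""
    fmax = spec.freqs[-1]
    for name in bands:
        lo, hi = scheme.edges(name)
        if hi > fmax:
            raise ValueError(f"band {name} extends beyond spectral support ({fmax} Hz)")
    n_ep, n_ch, _ = spec.psd.shape
    masks = [band_bins(spec.freqs, scheme, name) for name in bands]
    out = np.empty((n_ep, n_ch, len(bands)))
    for j, m in enumerate(masks):
        out[:, :, j] = spec.psd[:, :, m].sum(axis=2)
    return FeatureTable(
        values=out.reshape(n_ep, n_ch * len(bands)),
        channel_labels=spec.channel_labels,
        band_names=tuple(bands),
        condition=spec.condition,
        units="power",
    )


def compute_gfp(features: FeatureTable) -> GFPSeries:
    """Global Field Power: mean band power over channels, per epoch and band."""
    if features.units != "power":
        raise ValueError("GFP is defined on power-unit features")
    if len(features.channel_labels) == 0:
        raise ValueError("empty channel set")
    n_ep = features.values.shape[0]
    cube = features.values.reshape(
        n_ep, len(features.channel_labels), len(features.band_names)
    )
    return GFPSeries(
        values=cube.mean(axis=1),
        band_names=features.band_names,
        condition=features.condition,
    )


def fit_ref_normalization(ref: FeatureTable) -> RefNormalization:
    """Estimate per-feature mean/SD on REF epochs (features with SD=0 flagged)."""
    if ref.values.shape[0] < 2:
        raise ValueError("REF needs >= 2 clean epochs")
    mean = ref.values.mean(axis=0)
    sd = ref.values.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} feature(s) have zero REF SD; flagged")
    return RefNormalization(mean=mean, sd=sd, degenerate=degenerate)


def zscore_to_ref(features: FeatureTable, ref: FeatureTable):
    """Z-score features against the REF condition, per feature per epoch."""
    norm = fit_ref_normalization(ref)
    z = norm.apply(features.values)
    table = FeatureTable(
        values=z,
        channel_labels=features.channel_labels,
        band_names=features.band_names,
        condition=features.condition,
        units="z",
        degenerate=norm.degenerate.copy(),
    )
    return table, norm
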
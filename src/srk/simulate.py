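"""Synthetic S-R-K sessions with planted, recoverable ground truth.

A session emulates the experimental protocol: a one-minute eyes-closed
rest segment (clear alpha peak at a configurable individual alpha
frequency), a passive REF baseline, and six task segments (S1, S2, R1,
R2, K1, K2), together with behavioural logs per condition.

EEG background is 1/f (pink) noise generated at the dipole sources and
projected to the electrodes through the lead field, plus a small amount
of sensor noise.  Condition-specific activity is planted as band-limited
oscillations at the sources of designated Brodmann parcels, with
amplitudes *calibrated* so that the z-shift of the downstream
BA x band feature (sLORETA power on the 33 characterization channels,
z-scored to REF) matches the requested effect size.  The calibration
solves a small linear system per band, which also accounts for
inverse-solution leakage between simultaneously planted parcels.

Stereotyped blinks (frontal-weighted transients with a paired EOG
trace) and gross-amplitude artifact events are planted at configurable
rates and recorded in the session truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import KnowledgeLog, RuleLog, TrackLog
from .inverse import InverseConfig, LeadField, build_leadfield
from .mapping import ANALYSIS_BANDS, BAAtlas, aggregate_to_ba, make_atlas, source_band_power
from .montage import CHANNELS_61, group_of, make_montage
from .preprocess import (
    DEFAULT_EXCLUDED_GROUPS,
    EEGRecording,
    channel_subset_indices,
    epoch_signal,
)
from .spectral import band_bins, define_bands

CONDITIONS = ("S1", "S2", "R1", "R2", "K1", "K2")
SEGMENTS = ("rest", "REF") + CONDITIONS

#: Class labels used by the binary classifier.
CLASS_OF_CONDITION = {"S1": "SR", "S2": "SR", "R1": "SR", "R2": "SR",
                      "K1": "K", "K2": "K"}

_STREAM_ID = {name: i for i, name in enumerate(SEGMENTS)}

_BACKGROUND_STD_UV = 10.0       # per-channel RMS of the pink background
_SENSOR_STD_UV = 2.0            # additive sensor noise RMS
_BLINK_AMP_UV = 160.0           # EOG blink peak
_BLINK_PROPAGATION = {"Fp": 0.35, "AF": 0.20, "F": 0.08}
_GROSS_AMP_UV = 150.0           # gross-artifact pulse amplitude
_ALPHA_AMP_UV = 8.0             # resting alpha amplitude on posterior channels


@dataclass
class BehaviourParams:
    """Per-condition controls for the behavioural simulator."""

    tracking_jitter: float = 1.0        # cursor jitter SD, screen units
    rule_success_p: float = 0.9         # per-slot success probability
    k1_t_opt: float = 60.0              # ideal circuit time, s
    k1_t_extra: float = 30.0            # mean extra circuit time, s
    k1_t_event: float = 30.0            # mean event-solving time, s
    k2_n_att: int = 2                   # attempts to find the sequence
    k2_t_used: float = 300.0            # time used of the 1200 s budget, s


@dataclass
class SimulationConfig:
    """Full description of one synthetic session (fixed seed => fixed bytes)."""

    seed: int = 0
    fs: float = 250.0
    n_channels: int = 61
    iaf_true: float = 10.0
    durations: dict = field(default_factory=lambda: {s: 60.0 for s in SEGMENTS})
    effect_map: dict = field(default_factory=dict)  # (cond, BA, band) -> z
    noise_level: float = 1.0
    blink_rate: float = 2.0             # events / minute
    gross_artifact_rate: float = 0.0    # events / minute
    behaviour: BehaviourParams = field(default_factory=BehaviourParams)
    n_sources: int = 660
    #: feature space in which effect_map z-shifts are calibrated:
    #: "ba" — BA x band sLORETA power on the 33 characterization channels
    #: (what the cortical-mapping path tests); "channel" — 61-channel x band
    #: power (what the classifier consumes), targeted at the planted
    #: pattern's peak channel.
    effect_space: str = "ba"
    #: global state shifts: (condition, band) -> z.  Scales the condition's
    #: background band content so that EVERY channel's band-power feature
    #: shifts by z (in REF z-units) — a whole-cortex state difference, the
    #: planted ground truth for classification experiments.
    state_map: dict = field(default_factory=dict)

    def validate(self, atlas: BAAtlas | None = None) -> None:
        if self.effect_space not in ("ba", "channel"):
            raise ValueError(f"unknown effect space {self.effect_space!r}")
        for (cond, band) in self.state_map:
            if cond not in CONDITIONS:
                raise ValueError(f"state map references unknown condition {cond!r}")
            if band not in ANALYSIS_BANDS:
                raise ValueError(f"state map references unknown band {band!r}")
        for name, d in self.durations.items():
            if d <= 0:
                raise ValueError(f"duration of segment {name!r} must be > 0")
        for (cond, ba, band) in self.effect_map:
            if cond not in ("REF",) + CONDITIONS:
                raise ValueError(f"effect map references unknown condition {cond!r}")
            if band not in ANALYSIS_BANDS:
                raise ValueError(f"effect map references unknown band {band!r}")
            if atlas is not None and ba not in atlas.labels:
                raise ValueError(f"effect map references BA {ba!r} absent from atlas")
        if not 7.0 <= self.iaf_true <= 13.0:
            raise ValueError("iaf_true must lie in [7, 13] Hz")

    def rng(self, stream: str) -> np.random.Generator:
        import zlib

        sid = _STREAM_ID.get(stream)
        if sid is None:  # stable across processes (unlike hash())
            sid = 1000 + zlib.crc32(stream.encode()) % (2**20)
        return np.random.default_rng([self.seed, sid])

    def labels(self) -> tuple:
        return CHANNELS_61[: self.n_channels]


@dataclass
class SyntheticSession:
    """Recordings, logs and the planted ground truth of one subject."""

    config: SimulationConfig
    recordings: dict                    # segment -> EEGRecording
    logs: dict                          # condition -> behavioural log
    truth: dict                         # effect_map, iaf, artifact events, labels
    leadfield: LeadField
    atlas: BAAtlas


# ---------------------------------------------------------------------------
# noise and waveform primitives

def pink_noise(rng: np.random.Generator, n_signals: int, n_samples: int,
               fs: float) -> np.ndarray:
    """1/f-power noise, unit variance per row (spectral synthesis)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    spec = amp * (rng.standard_normal((n_signals, freqs.size))
                  + 1j * rng.standard_normal((n_signals, freqs.size)))
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _blink_waveform(fs: float) -> np.ndarray:
    """A 400 ms raised-cosine blink transient, unit peak."""
    n = int(round(0.4 * fs))
    t = np.linspace(0, np.pi, n)
    return np.sin(t) ** 2


def _place_events(rng, rate_per_min, duration, fs, width_s):
    """Poisson event onsets (sample indices) that fit inside the recording."""
    lam = rate_per_min * duration / 60.0
    n_events = rng.poisson(lam)
    max_onset = int(duration * fs) - int(width_s * fs) - 1
    if max_onset <= 0:
        return np.array([], dtype=int)
    return np.sort(rng.integers(0, max_onset, size=n_events))


# ---------------------------------------------------------------------------
# rest segment (channel-level: only used for IAF estimation)

def simulate_rest_eeg(config: SimulationConfig) -> EEGRecording:
    """One-minute eyes-closed rest: pink background plus a posterior alpha rhythm."""
    config.validate()
    duration = config.durations["rest"]
    n = int(round(duration * config.fs))
    labels = config.labels()
    rng = config.rng("rest")
    t = np.arange(n) / config.fs
    alpha = np.sin(2 * np.pi * config.iaf_true * t + rng.uniform(0, 2 * np.pi))
    weights = np.array(
        [1.0 if group_of(lab) in ("P", "PO", "O") else 0.25 for lab in labels]
    )
    x = _ALPHA_AMP_UV * weights[:, None] * alpha[None, :]
    if config.noise_level > 0:
        x = x + (config.noise_level * _BACKGROUND_STD_UV
                 * pink_noise(rng, len(labels), n, config.fs))
    return EEGRecording(samples=x, fs=config.fs, channel_labels=labels,
                        condition="rest")


# ---------------------------------------------------------------------------
# condition segments (source-level with calibrated planted effects)

def _background(config: SimulationConfig, segment: str, leadfield: LeadField,
                rng: np.random.Generator) -> np.ndarray:
    """Pink source noise projected to electrodes plus sensor noise, microvolts."""
    n = int(round(config.durations[segment] * config.fs))
    n_src = leadfield.n_sources
    src = pink_noise(rng, n_src, n, config.fs)
    # unit-norm columns: mean channel power of the projection is n_src / n_elec
    src_std = (_BACKGROUND_STD_UV * config.noise_level
               / np.sqrt(n_src / leadfield.n_electrodes))
    x = leadfield.A @ (src_std * src)
    if config.noise_level > 0:
        x += _SENSOR_STD_UV * config.noise_level * pink_noise(
            rng, leadfield.n_electrodes, n, config.fs)
    return x


def _band_center_freq(band: str, iaf: float) -> float:
    scheme = define_bands(iaf)
    lo, hi = scheme.edges(band)
    return float(np.round((lo + hi) / 2.0))


class _MeasurementPath:
    """The downstream BA x band feature path used for effect calibration.

    Mirrors the characterization pipeline: drop the excluded channel
    groups, apply the standardized inverse on the subset lead field and
    average source power within parcels.
    """

    def __init__(self, config: SimulationConfig, leadfield: LeadField,
                 atlas: BAAtlas):
        from .inverse import InverseOperator

        labels = config.labels()
        keep = channel_subset_indices(labels, DEFAULT_EXCLUDED_GROUPS)
        self.keep = keep
        self.labels = tuple(labels[i] for i in keep)
        self.leadfield = leadfield.subset(self.labels)
        self.op = InverseOperator(self.leadfield, InverseConfig())
        self.atlas = atlas
        self.scheme = define_bands(config.iaf_true)
        self.config = config

    def features(self, electrode_signal: np.ndarray) -> np.ndarray:
        """(n_epochs, n_parcels, n_bands) BA band power from a 61-ch signal."""
        rec = EEGRecording(
            samples=electrode_signal[self.keep], fs=self.config.fs,
            channel_labels=self.labels,
        )
        ep = epoch_signal(rec)
        sp = source_band_power(ep, self.leadfield, self.scheme,
                               InverseConfig(), clean_only=False)
        return aggregate_to_ba(sp, self.atlas)

    #: alias kept for call sites that read better with the explicit name
    ba_features = features

    def source_fft_bins(self, electrode_signal: np.ndarray, bins):
        """Inverse-projected Hann rFFT coefficients at selected 1-Hz bins.

        Returns ``(Y, scale)`` with Y of shape (n_sources, n_epochs,
        len(bins)); ``scale * 2 * |Y|^2 / S_ll`` summed over bins is the
        standardized band-power contribution of those (interior) bins.
        """
        from scipy.signal.windows import hann

        fs = int(round(self.config.fs))
        x = electrode_signal[self.keep]
        n_ep = x.shape[1] // fs
        ep = x[:, : n_ep * fs].reshape(len(self.keep), n_ep, fs)
        win = hann(fs, sym=False)
        X = np.fft.rfft(ep * win, axis=-1)[:, :, bins]   # (n_ch, n_ep, nb)
        Xf = X.reshape(len(self.keep), -1)
        Y = self.op.T @ self.op.center(Xf)
        return Y.reshape(self.op.T.shape[0], n_ep, len(bins)), 1.0 / (win @ win)


class _ChannelPath:
    """61-channel band-power feature path (the classifier's feature space)."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.scheme = define_bands(config.iaf_true)

    def features(self, electrode_signal: np.ndarray) -> np.ndarray:
        """(n_epochs, n_channels, n_bands) band power from a 61-ch signal."""
        from .spectral import band_power, compute_psd

        rec = EEGRecording(samples=electrode_signal, fs=self.config.fs,
                           channel_labels=self.config.labels())
        ep = epoch_signal(rec)
        table = band_power(compute_psd(ep), self.scheme)
        n_ep = table.values.shape[0]
        return table.values.reshape(n_ep, len(table.channel_labels),
                                    len(table.band_names))

    def fft_bins(self, electrode_signal: np.ndarray, bins):
        """Hann rFFT coefficients at selected 1-Hz bins, per channel/epoch."""
        from scipy.signal.windows import hann

        fs = int(round(self.config.fs))
        n_ch = electrode_signal.shape[0]
        n_ep = electrode_signal.shape[1] // fs
        ep = electrode_signal[:, : n_ep * fs].reshape(n_ch, n_ep, fs)
        win = hann(fs, sym=False)
        X = np.fft.rfft(ep * win, axis=-1)[:, :, bins]
        return X, 1.0 / (win @ win)


def _ref_segment(config, leadfield, atlas):
    """The full REF recording (background + blinks), as the pipeline sees it."""
    rec, _truth = simulate_condition_eeg(config, "REF", leadfield, atlas,
                                         ref_stats={})
    return rec.samples


def _ref_feature_stats(config, leadfield, atlas, path=None):
    """Per-(row, band) mean/SD of the REF segment in the calibration space.

    Statistics come from the full REF recording (blinks included) so the
    calibration's normalizers match what downstream z-scoring will use.
    """
    if path is None:
        path = (_MeasurementPath(config, leadfield, atlas)
                if config.effect_space == "ba" else _ChannelPath(config))
    feats = path.features(_ref_segment(config, leadfield, atlas))
    return feats.mean(axis=0), feats.std(axis=0, ddof=1), path


def _parcel_mode(path, leadfield, ba, src_idx):
    """Source weights of a parcel's most detectable oscillation mode.

    Maximizes the parcel-mean standardized power produced per unit of
    total electrode power, i.e. the top generalized eigenvector of
    (B' D B, A_S' A_S) with B the average-referenced measurement-path
    patterns of the parcel's sources and D the parcel's standardization
    weights.  The returned vector is scaled to a unit-norm electrode
    pattern on the full montage.
    """
    from scipy.linalg import eigh

    A_meas = path.leadfield.A[:, src_idx]              # 33 x n
    B = A_meas - A_meas.mean(axis=0, keepdims=True)    # average reference
    T_S = path.op.T[src_idx]                           # n x 33
    D = (T_S / path.op.S_diag[src_idx, None]).T @ T_S / src_idx.size
    M = B.T @ D @ B
    A_full = leadfield.A[:, src_idx]
    N = A_full.T @ A_full
    vals, vecs = eigh(M, N)
    w = vecs[:, -1]
    pattern = A_full @ w
    return w / np.linalg.norm(pattern)


def _planted_oscillations(config, condition, leadfield, atlas, path,
                          ref_mean, ref_sd, n_samples, background):
    """Electrode-level planted oscillation signal calibrated to effect_map."""
    entries = [(ba, band, z) for (cond, ba, band), z in config.effect_map.items()
               if cond == condition]
    if not entries:
        return np.zeros((leadfield.n_electrodes, n_samples)), {}
    t = np.arange(n_samples) / config.fs
    total = np.zeros((leadfield.n_electrodes, n_samples))
    # this condition's actual background realization: the calibration
    # corrects for its realized deviation from the REF mean
    bg_preview = background
    cond_feats = path.features(bg_preview)
    mu_c = cond_feats.mean(axis=0)
    amplitudes = {}
    bands = sorted({band for _, band, _ in entries})
    for band in bands:
        planted = [(ba, z) for ba, b, z in entries if b == band]
        freq = _band_center_freq(band, config.iaf_true)
        b_idx = ANALYSIS_BANDS.index(band)
        # a Hann-windowed integer-frequency sinusoid occupies exactly the
        # bins freq-1, freq, freq+1; keep those inside the band
        epoch_freqs = np.fft.rfftfreq(int(config.fs), 1.0 / config.fs)
        mask = band_bins(epoch_freqs, path.scheme, band)
        bins = [b for b in (int(freq) - 1, int(freq), int(freq) + 1)
                if 0 < b < int(config.fs) // 2 and mask[b]]
        # unit-amplitude oscillation per planted parcel (61-electrode signal).
        # Per-source weights are the parcel's most detectable mode: the real
        # vector maximizing the parcel's own feature response per unit
        # electrode power (generalized eigenvector).  This keeps the sensor
        # amplitude needed for a given z-shift minimal — arbitrary phase
        # patterns can self-cancel through the inverse and would demand
        # amplitudes that trip the artifact gate.  Weights and the global
        # phase are fixed per (parcel, band) — NOT per condition — so both
        # repetitions of a level share the same spatial generator.
        unit_signals, patterns = [], []
        for ba, _ in planted:
            src_idx = atlas.sources_of(ba)
            if config.effect_space == "ba":
                w_mode = _parcel_mode(path, leadfield, ba, src_idx)
            else:
                # coherent patch: in channel space the feature response IS the
                # pattern's power at the peak electrode, which cannot
                # self-cancel, so the natural in-phase patch suffices
                ones = np.ones(src_idx.size)
                w_mode = ones / np.linalg.norm(leadfield.A[:, src_idx] @ ones)
            ph_rng = np.random.default_rng(
                [config.seed, 91, atlas.labels.index(ba), ANALYSIS_BANDS.index(band)])
            phase0 = ph_rng.uniform(0, 2 * np.pi)
            osc = np.sin(2 * np.pi * freq * t + phase0)
            pattern = leadfield.A[:, src_idx] @ w_mode
            patterns.append(pattern)
            unit_signals.append(pattern[:, None] * osc[None, :])
        # realized-mean calibration: with feature increment
        #   f_r(a) = 2 sum_j a_j L_rj + sum_jk a_j a_k Q_rjk
        # (L the background cross term of THIS realization, Q the
        # oscillation Gram), solve f_r(a) = z_r * sd_REF_r - (mu_C - mu_R)_r
        if config.effect_space == "ba":
            # rows: the planted parcels; units: sources, standardized weights
            rows = [atlas.labels.index(ba) for ba, _ in planted]
            sels = [atlas.sources_of(atlas.labels[r]) for r in rows]
            Ybg, scale = path.source_fft_bins(bg_preview, bins)
            Yu = [path.source_fft_bins(u[:, : int(config.fs)], bins)[0][:, 0, :]
                  for u in unit_signals]
            w = 2.0 * scale / path.op.S_diag       # interior-bin power weights
        else:
            # rows: each planted pattern's peak electrode; units: channels
            rows = [int(np.argmax(np.abs(p))) for p in patterns]
            sels = [np.array([r]) for r in rows]
            Ybg, scale = path.fft_bins(bg_preview, bins)
            Yu = [path.fft_bins(u[:, : int(config.fs)], bins)[0][:, 0, :]
                  for u in unit_signals]
            w = np.full(Ybg.shape[0], 2.0 * scale)
        n_p = len(planted)
        L = np.empty((n_p, n_p))
        Q = np.empty((n_p, n_p, n_p))
        mean_bg = Ybg.mean(axis=1)                 # (n_units, nb)
        for r, sel in enumerate(sels):
            wsel = w[sel][:, None]
            for j in range(n_p):
                L[r, j] = float(np.mean(np.sum(
                    wsel * np.real(np.conj(mean_bg[sel]) * Yu[j][sel]), axis=1)))
                for k in range(n_p):
                    Q[r, j, k] = float(np.mean(np.sum(
                        wsel * np.real(np.conj(Yu[j][sel]) * Yu[k][sel]), axis=1)))
        target = np.array(
            [z * ref_sd[r, b_idx] - (mu_c[r, b_idx] - ref_mean[r, b_idx])
             for (ba, z), r in zip(planted, rows)]
        )

        def residual(a):
            return 2.0 * L @ a + np.einsum("rjk,j,k->r", Q, a, a) - target

        from scipy.optimize import least_squares

        a0 = np.sqrt(np.clip(target, 0.0, None)
                     / np.clip(np.einsum("rrr->r", Q), 1e-12, None))
        sol = least_squares(residual, a0, bounds=(0.0, np.inf))
        for (ba, _), a, u in zip(planted, sol.x, unit_signals):
            amplitudes[(ba, band)] = float(a)
            total += a * u
    return total, amplitudes


def _ref_channel_stats(config, leadfield, atlas):
    """Per-(channel, band) mean/SD of the full REF segment's power features."""
    cp = _ChannelPath(config)
    feats = cp.features(_ref_segment(config, leadfield, atlas))
    return feats.mean(axis=0), feats.std(axis=0, ddof=1)


def _apply_state_shift(config, condition, x, ref_chan_stats):
    """Scale the background's band content for a whole-cortex state shift.

    For each (condition, band) entry of ``config.state_map``, every
    channel's band spectrum is multiplied so that its per-epoch band-power
    feature shifts by exactly z REF-SDs:  g_c^2 = (mu_R + z sd_R)/mu_C
    per channel c.  Returns the shifted signal and the per-band median
    gain (for the truth record).
    """
    entries = {band: z for (cond, band), z in config.state_map.items()
               if cond == condition}
    if not entries:
        return x, {}
    mu_r, sd_r = ref_chan_stats
    cp = _ChannelPath(config)
    mu_c = cp.features(x).mean(axis=0)
    n = x.shape[1]
    freqs = np.fft.rfftfreq(n, 1.0 / config.fs)
    X0 = np.fft.rfft(x, axis=1)

    idx = {band: ANALYSIS_BANDS.index(band) for band in entries}
    masks = {band: band_bins(freqs, cp.scheme, band) for band in entries}
    targets = {band: mu_r[:, idx[band]] + z * sd_r[:, idx[band]]
               for band, z in entries.items()}

    def apply(gain_by_band):
        X = X0.copy()
        for band, g in gain_by_band.items():
            X[:, masks[band]] *= g[:, None]
        return np.fft.irfft(X, n=n, axis=1)

    # first pass: naive per-channel gain, ignoring Hann leakage across the
    # band edges (which dilutes the realized feature shift)
    g0 = {band: np.sqrt(np.clip(targets[band] / mu_c[:, idx[band]], 0.0, None))
          for band in entries}
    r0 = cp.features(apply(g0)).mean(axis=0)
    # second pass: the epoch feature is linear in g^2 (in-band content) plus
    # a leakage constant; solve the two-point linear model per channel
    g1 = {}
    for band in entries:
        b = idx[band]
        denom = g0[band] ** 2 - 1.0
        slope = np.where(np.abs(denom) > 1e-9,
                         (r0[:, b] - mu_c[:, b]) / np.where(denom == 0, 1, denom),
                         mu_c[:, b])
        slope = np.clip(slope, 1e-12 * np.maximum(mu_c[:, b], 1e-30), None)
        offset = mu_c[:, b] - slope
        g1[band] = np.sqrt(np.clip((targets[band] - offset) / slope, 0.0, None))
    gains = {band: float(np.median(g1[band])) for band in entries}
    return apply(g1), gains


def simulate_condition_eeg(
    config: SimulationConfig,
    condition: str,
    leadfield: LeadField,
    atlas: BAAtlas,
    ref_stats=None,
):
    """Simulate one REF/task segment; returns ``(EEGRecording, truth_dict)``.

    Planted band-limited source activity at the parcels named in
    ``config.effect_map`` is scaled so the downstream z-shift versus REF
    matches the requested effect size in the configured feature space
    (``effect_space``: BA x band inverse power, or channel x band power
    at the pattern's peak electrode).  Blink and gross-amplitude events
    are added at their configured rates and reported in the truth dict
    (onset sample indices and affected 1-s epochs).
    """
    if condition not in ("REF",) + CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    config.validate(atlas)
    labels = config.labels()
    fs = config.fs
    n = int(round(config.durations[condition] * fs))
    rng = config.rng(condition)

    x = _background(config, condition, leadfield, rng)

    truth = {"condition": condition, "blink_onsets": [], "gross_onsets": [],
             "gross_epochs": [], "planted_amplitudes": {}, "state_gains": {}}

    if isinstance(ref_stats, dict):
        eff_stats = ref_stats.get("effect")
        chan_stats = ref_stats.get("channel")
    else:
        eff_stats, chan_stats = ref_stats, None

    # blinks go in BEFORE effect calibration: they stay in the analysed data
    # (sub-threshold), so the calibration must see the same statistics the
    # pipeline's REF normalization will
    eog = _SENSOR_STD_UV * pink_noise(rng, 1, n, fs)[0]
    blink = _blink_waveform(fs)
    weights = np.array([_BLINK_PROPAGATION.get(group_of(lab), 0.0) for lab in labels])
    for onset in _place_events(rng, config.blink_rate, config.durations[condition],
                               fs, 0.4):
        seg = slice(onset, onset + blink.size)
        eog[seg] += _BLINK_AMP_UV * blink
        x[:, seg] += _BLINK_AMP_UV * weights[:, None] * blink[None, :]
        truth["blink_onsets"].append(int(onset))

    if condition != "REF" and any(c == condition for (c, _, _) in config.effect_map):
        if eff_stats is None:
            eff_stats = _ref_feature_stats(config, leadfield, atlas)
        ref_mean, ref_sd, path = eff_stats
        osc, amplitudes = _planted_oscillations(
            config, condition, leadfield, atlas, path, ref_mean, ref_sd, n, x)
        x = x + osc
        truth["planted_amplitudes"] = amplitudes

    if condition != "REF" and any(c == condition for (c, _) in config.state_map):
        if chan_stats is None:
            chan_stats = _ref_channel_stats(config, leadfield, atlas)
        x, gains = _apply_state_shift(config, condition, x, chan_stats)
        truth["state_gains"] = gains

    # gross-amplitude events: short large pulses on a few channels
    pulse = np.ones(int(round(0.2 * fs)))
    for onset in _place_events(rng, config.gross_artifact_rate,
                               config.durations[condition], fs, 0.2):
        chans = rng.choice(len(labels), size=3, replace=False)
        sign = rng.choice([-1.0, 1.0])
        seg = slice(onset, onset + pulse.size)
        x[chans, seg] += sign * _GROSS_AMP_UV * pulse[None, :]
        truth["gross_onsets"].append(int(onset))
        first = onset // int(fs)
        last = (onset + pulse.size - 1) // int(fs)
        truth["gross_epochs"].extend(range(first, last + 1))
    truth["gross_epochs"] = sorted(set(truth["gross_epochs"]))

    rec = EEGRecording(samples=x, fs=fs, channel_labels=labels,
                       condition=condition, eog=eog)
    return rec, truth


# ---------------------------------------------------------------------------
# behavioural logs

def _zigzag_track() -> np.ndarray:
    """The ideal task track: a fixed zig-zag polyline in screen units."""
    xs = np.linspace(0, 100, 11)
    ys = np.tile([0.0, 20.0], 6)[:11]
    return np.column_stack([xs, ys])


def simulate_behavior(config: SimulationConfig, condition: str):
    """Behavioural log for one condition with controllable accuracy.

    S conditions yield a :class:`TrackLog` (ideal polyline plus jittered
    cursor samples), R conditions a :class:`RuleLog` with 7 turn and
    7 altitude slots, K1/K2 a :class:`KnowledgeLog` with the respective
    timing/attempt fields.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    p = config.behaviour
    rng = config.rng(f"behaviour-{condition}")
    completion = float(config.durations.get(condition, 60.0))
    if condition.startswith("S"):
        track = _zigzag_track()
        # sample along the ideal polyline, then jitter perpendicular-ish
        seg_len = np.linalg.norm(np.diff(track, axis=0), axis=1)
        cum = np.concatenate([[0], np.cumsum(seg_len)])
        # sample the arc length evenly but keep every vertex so the
        # noise-free cursor path retraces the polyline exactly
        s = np.unique(np.concatenate([np.linspace(0, seg_len.sum(), 200), cum]))
        pts = np.empty((s.size, 2))
        for i, si in enumerate(s):
            k = min(np.searchsorted(cum, si, side="right") - 1, len(seg_len) - 1)
            f = (si - cum[k]) / seg_len[k]
            pts[i] = track[k] + f * (track[k + 1] - track[k])
        jitter = (p.tracking_jitter * rng.standard_normal(pts.shape)
                  if p.tracking_jitter > 0 else 0.0)
        t = np.linspace(0, completion, s.size)
        samples = np.column_stack([t, pts + jitter])
        return TrackLog(cursor_samples=samples, ideal_track=track,
                        completion_time=completion)
    if condition.startswith("R"):
        outcomes = (rng.random(14) < p.rule_success_p).astype(int)
        return RuleLog(turn_outcomes=tuple(outcomes[:7]),
                       alt_outcomes=tuple(outcomes[7:]),
                       completion_time=completion)
    if condition == "K1":
        t_ev = float(rng.exponential(p.k1_t_event)) if p.k1_t_event > 0 else 0.0
        t_cir = p.k1_t_opt + (float(rng.exponential(p.k1_t_extra)) if p.k1_t_extra > 0 else 0.0)
        return KnowledgeLog(variant="K1", t_opt=p.k1_t_opt, t_cir=t_cir,
                            t_ev=t_ev, completion_time=completion)
    return KnowledgeLog(variant="K2", n_att=p.k2_n_att,
                        t_used=float(np.clip(p.k2_t_used, 0.0, 1200.0)),
                        completion_time=completion)


def knowledge_effect_map(z: float = 1.5) -> dict:
    """The default planted configuration for Knowledge-specific activity.

    Frontal theta and gamma increases (bilateral BA8 / BA10) in both K
    repetitions — the signature the battery is designed to elicit during
    deliberate problem solving — at effect size ``z`` (in z-units of the
    configured calibration feature space vs REF).  This compact map is
    the study condition for cortical-map recovery.
    """
    cells = (("BA10-L", "Gamma"), ("BA10-R", "Gamma"),
             ("BA8-L", "Theta"), ("BA8-R", "Theta"))
    return {(cond, ba, band): z for cond in ("K1", "K2") for ba, band in cells}


def knowledge_state_map(z: float = 1.5,
                        bands=("Theta", "Beta3", "Gamma")) -> dict:
    """A global Knowledge-state spectral difference for classification runs.

    A cognitive *state* change shifts band power over the whole cortex at
    once, not in one isolated parcel — and a distance-based classifier in
    a 366-feature space can only see such distributed differences, since
    a handful of shifted features is swamped by the remaining noise
    dimensions.  Returns a ``state_map`` planting per-channel band-power
    z-shifts of size ``z`` in both K repetitions for the given bands.
    """
    return {(cond, band): z for cond in ("K1", "K2") for band in bands}


# ---------------------------------------------------------------------------
# whole sessions

def simulate_session(config: SimulationConfig,
                     leadfield: LeadField | None = None,
                     atlas: BAAtlas | None = None) -> SyntheticSession:
    """Generate a full synthetic session (rest + REF + six conditions + logs)."""
    montage = make_montage()
    if leadfield is None:
        pos = montage.positions[: config.n_channels]
        leadfield = build_leadfield(pos, config.labels(),
                                    n_sources=config.n_sources, seed=config.seed)
    if atlas is None:
        atlas = make_atlas(leadfield.source_positions)
    config.validate(atlas)

    recordings = {"rest": simulate_rest_eeg(config)}
    truth = {
        "iaf_true": config.iaf_true,
        "effect_map": {f"{c}|{ba}|{band}": z
                       for (c, ba, band), z in config.effect_map.items()},
        "events": {},
        "epoch_labels": {},
    }
    ref_stats = {}
    if config.effect_map:
        ref_stats["effect"] = _ref_feature_stats(config, leadfield, atlas)
    if config.state_map:
        ref_stats["channel"] = _ref_channel_stats(config, leadfield, atlas)
    for segment in ("REF",) + CONDITIONS:
        rec, seg_truth = simulate_condition_eeg(config, segment, leadfield,
                                                atlas, ref_stats=ref_stats)
        recordings[segment] = rec
        truth["events"][segment] = seg_truth
        n_epochs = int(rec.duration)
        if segment in CLASS_OF_CONDITION:
            truth["epoch_labels"][segment] = [CLASS_OF_CONDITION[segment]] * n_epochs
    logs = {c: simulate_behavior(config, c) for c in CONDITIONS}
    return SyntheticSession(config=config, recordings=recordings, logs=logs,
                            truth=truth, leadfield=leadfield, atlas=atlas)
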
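"""Brodmann-area activation mapping from standardized source band power.

Per epoch and frequency band, sLORETA standardized power is computed by
projecting the epoch's Hann-windowed spectrum through the linear inverse
operator and summing the band's bins (Parseval-equivalent to band-pass
filtering in time before inverting, but one matrix product per epoch).
Source power is averaged within each Brodmann-area parcel, z-scored to
the REF condition per (area, band), and each cell is tested for
activation: Kolmogorov-Smirnov normality gate, then Student's t (normal)
or the rank-based analogue (non-normal).  Maps from the two repetitions
of a level are intersected (significant in both, signs agreeing) to form
the S, R and K maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .inverse import InverseConfig, InverseOperator, LeadField
from .spectral import ANALYSIS_BANDS, BandScheme, _hann_rfft, band_bins

#: Default 33 Brodmann parcel numbers (x2 hemispheres = 66 parcels).
DEFAULT_BA_NUMBERS = (
    1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 17, 18, 19, 20, 21, 22, 23, 24,
    31, 32, 37, 38, 39, 40, 41, 42, 43, 44, 45, 46, 47, 25,
)


@dataclass
class BAAtlas:
    """Mapping from source index to Brodmann-area parcel label."""

    labels: tuple                       # 66 parcel labels, ordered
    source_to_ba: np.ndarray            # (n_sources,) index into labels

    def __post_init__(self):
        self.source_to_ba = np.asarray(self.source_to_ba)
        counts = np.bincount(self.source_to_ba, minlength=len(self.labels))
        if (counts == 0).any():
            empty = [self.labels[i] for i in np.flatnonzero(counts == 0)]
            raise ValueError(f"parcel(s) without sources: {empty}")

    @property
    def n_parcels(self) -> int:
        return len(self.labels)

    def sources_of(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.source_to_ba == self.labels.index(label))


def make_atlas(source_positions=None, n_sources: int = 660,
               ba_numbers=DEFAULT_BA_NUMBERS) -> BAAtlas:
    """Assign sources to 66 spatially compact parcels (33 BAs x 2 hemispheres).

    Parcel centroids are mirror-symmetric across the mid-sagittal (x = 0)
    plane — one left and one right parcel per Brodmann number — and each
    source joins its nearest centroid, so parcels are compact patches of
    roughly equal size.  Labels read "BA10-L", "BA10-R", ...
    """
    from .inverse import _fibonacci_sphere

    if source_positions is None:
        # the default lattice used by build_leadfield (jitter-free)
        pts = _fibonacci_sphere(n_sources)
        pts[:, 2] = 0.25 + 0.75 * pts[:, 2]
        source_positions = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    source_positions = np.asarray(source_positions, dtype=float)
    dirs = source_positions / np.linalg.norm(source_positions, axis=1, keepdims=True)

    base = _fibonacci_sphere(len(ba_numbers))
    base[:, 2] = 0.25 + 0.75 * base[:, 2]
    base[:, 0] = np.abs(base[:, 0]) + 1e-3       # fold onto the right hemisphere
    base /= np.linalg.norm(base, axis=1, keepdims=True)
    mirrored = base * np.array([-1.0, 1.0, 1.0])
    centroids = np.concatenate([mirrored, base])  # L block then R block
    labels = tuple(f"BA{num}-{hemi}" for hemi in ("L", "R") for num in ba_numbers)

    assign = np.argmax(dirs @ centroids.T, axis=1)   # nearest on the sphere
    # guarantee every parcel owns at least one source
    for k in np.flatnonzero(np.bincount(assign, minlength=len(labels)) == 0):
        assign[int(np.argmax(dirs @ centroids[k]))] = k
    return BAAtlas(labels=labels, source_to_ba=assign)


@dataclass
class ActivationMatrix:
    """Parcel x band grid of activation statistics for one condition."""

    labels: tuple                       # parcel labels (rows)
    band_names: tuple                   # columns
    mean_z: np.ndarray                  # (n_parcels, n_bands)
    statistic: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray             # bool
    testable: np.ndarray                # bool; False where too few epochs
    test_used: np.ndarray = field(default=None)   # "t" | "rank" | ""
    alpha: float = 0.05
    condition: str = ""

    def __post_init__(self):
        if self.test_used is None:
            self.test_used = np.full(self.mean_z.shape, "", dtype=object)

    def n_significant(self) -> int:
        return int(self.significant.sum())

    def significant_cells(self) -> set:
        rows, cols = np.nonzero(self.significant)
        return {(self.labels[r], self.band_names[c]) for r, c in zip(rows, cols)}

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for r, lab in enumerate(self.labels):
            for c, band in enumerate(self.band_names):
                rows.append({
                    "parcel": lab, "band": band, "mean_z": self.mean_z[r, c],
                    "statistic": self.statistic[r, c], "p_value": self.p_value[r, c],
                    "significant": bool(self.significant[r, c]),
                    "testable": bool(self.testable[r, c]),
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# standardized source band power

def source_band_power(
    ep,
    leadfield: LeadField,
    scheme: BandScheme,
    cfg: InverseConfig = InverseConfig(),
    bands=ANALYSIS_BANDS,
    clean_only: bool = True,
) -> np.ndarray:
    """sLORETA standardized band power per clean epoch, source and band.

    Returns an array of shape (n_epochs, n_sources, n_bands).  The epoch
    spectrum (Hann rFFT) is projected through the inverse operator; band
    power is the bin sum of standardized power, identical by Parseval to
    inverting the band-filtered time series.
    """
    if tuple(ep.channel_labels) != tuple(leadfield.electrode_labels):
        raise ValueError("epoch channels do not match lead field electrodes")
    op = InverseOperator(leadfield, cfg)
    data = ep.clean() if clean_only else ep.epochs
    freqs, X, scale = _hann_rfft(data, ep.fs)     # (n_ep, n_ch, n_freq) complex
    masks = [band_bins(freqs, scheme, name) for name in bands]
    union = np.logical_or.reduce(masks)            # only project needed bins
    interior = (freqs > 0) & (freqs < freqs[-1])
    X = X[:, :, union]
    n_ep, _, n_f = X.shape
    Xf = X.transpose(1, 0, 2).reshape(len(ep.channel_labels), -1)
    Y = op.T @ op.center(Xf)                       # (n_src, n_ep * n_f)
    P = (np.abs(Y) ** 2).reshape(op.T.shape[0], n_ep, n_f)
    P *= scale
    P[..., interior[union]] *= 2.0
    P /= op.S_diag[:, None, None]
    out = np.empty((n_ep, op.T.shape[0], len(bands)))
    for j, m in enumerate(masks):
        out[:, :, j] = P[:, :, m[union]].sum(axis=2).T
    return out


def aggregate_to_ba(source_power: np.ndarray, atlas: BAAtlas) -> np.ndarray:
    """Mean standardized power over each parcel's sources.

    Input (n_epochs, n_sources, n_bands) -> output
    (n_epochs, n_parcels, n_bands).
    """
    n_ep, n_src, n_bands = source_power.shape
    if n_src != len(atlas.source_to_ba):
        raise ValueError("source count does not match atlas")
    sums = np.zeros((n_ep, atlas.n_parcels, n_bands))
    np.add.at(sums.transpose(1, 0, 2), atlas.source_to_ba,
              source_power.transpose(1, 0, 2))
    counts = np.bincount(atlas.source_to_ba, minlength=atlas.n_parcels)
    return sums / counts[None, :, None]


def zscore_ba_to_ref(ba_power: np.ndarray, ref_ba_power: np.ndarray):
    """Z-score parcel band power against REF, per (parcel, band) cell."""
    mean = ref_ba_power.mean(axis=0)
    sd = ref_ba_power.std(axis=0, ddof=1)
    degenerate = sd == 0
    sd = np.where(degenerate, 1.0, sd)
    z = (ba_power - mean) / sd
    z[:, degenerate] = np.nan
    return z, (mean, sd, degenerate)


# ---------------------------------------------------------------------------
# activation statistics

_KS_ALPHA = 0.05
MIN_EPOCHS_PER_CELL = 8


def _test_one_sample(z: np.ndarray):
    """Normality-gated one-sample test of z against 0."""
    if np.ptp(z) == 0:
        return np.nan, np.nan, ""
    mu, sd = z.mean(), z.std(ddof=1)
    ks_p = stats.kstest(z, "norm", args=(mu, sd)).pvalue
    if ks_p > _KS_ALPHA:
        res = stats.ttest_1samp(z, 0.0)
        return float(res.statistic), float(res.pvalue), "t"
    res = stats.wilcoxon(z)
    return float(res.statistic), float(res.pvalue), "rank"


def _test_two_sample(z: np.ndarray, ref: np.ndarray):
    """Normality-gated two-sample test (condition vs reference group)."""
    if np.ptp(z) == 0 and np.ptp(ref) == 0:
        return np.nan, np.nan, ""
    ks_ok = True
    for v in (z, ref):
        sd = v.std(ddof=1)
        if sd == 0:
            ks_ok = False
            break
        if stats.kstest(v, "norm", args=(v.mean(), sd)).pvalue <= _KS_ALPHA:
            ks_ok = False
            break
    if ks_ok:
        res = stats.ttest_ind(z, ref)
        return float(res.statistic), float(res.pvalue), "t"
    res = stats.mannwhitneyu(z, ref)    # Kruskal-Wallis with k=2
    return float(res.statistic), float(res.pvalue), "rank"


def test_activation(
    ba_z: np.ndarray,
    labels,
    band_names=ANALYSIS_BANDS,
    condition: str = "",
    alpha: float = 0.05,
    ref_ba_z: np.ndarray | None = None,
    fdr: bool = False,
) -> ActivationMatrix:
    """Per-(parcel, band) activation test on z-scored epochs.

    ``ba_z`` is (n_epochs, n_parcels, n_bands).  Without ``ref_ba_z`` the
    contrast is the one-sample vs-REF test of z against 0; with it, a
    two-sample condition-vs-reference test.  Each cell is gated by a
    Kolmogorov-Smirnov normality test (t-test if normal, rank test
    otherwise).  No multiplicity correction by default; ``fdr=True``
    applies Benjamini-Hochberg across the grid.
    """
    n_parcels, n_bands = len(labels), len(band_names)
    mean_z = np.full((n_parcels, n_bands), np.nan)
    statistic = np.full((n_parcels, n_bands), np.nan)
    p_value = np.full((n_parcels, n_bands), np.nan)
    testable = np.zeros((n_parcels, n_bands), dtype=bool)
    test_used = np.full((n_parcels, n_bands), "", dtype=object)
    for r in range(n_parcels):
        for c in range(n_bands):
            z = ba_z[:, r, c]
            z = z[np.isfinite(z)]
            if z.size < MIN_EPOCHS_PER_CELL:
                continue
            mean_z[r, c] = z.mean()
            if ref_ba_z is None:
                s, p, kind = _test_one_sample(z)
            else:
                ref = ref_ba_z[:, r, c]
                ref = ref[np.isfinite(ref)]
                if ref.size < MIN_EPOCHS_PER_CELL:
                    continue
                s, p, kind = _test_two_sample(z, ref)
            if kind == "":
                continue            # degenerate constant cell: untestable
            testable[r, c] = True
            statistic[r, c], p_value[r, c], test_used[r, c] = s, p, kind
    p_adj = p_value.copy()
    if fdr:
        flat = p_value[testable]
        order = np.argsort(flat)
        m = flat.size
        ranked = flat[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty_like(flat)
        adj[order] = np.clip(ranked, 0, 1)
        p_adj[testable] = adj
    significant = testable & (p_adj <= alpha)
    return ActivationMatrix(
        labels=tuple(labels), band_names=tuple(band_names), mean_z=mean_z,
        statistic=statistic, p_value=p_adj, significant=significant,
        testable=testable, test_used=test_used, alpha=alpha, condition=condition,
    )


def common_activation(map1: ActivationMatrix, map2: ActivationMatrix) -> ActivationMatrix:
    """Intersect two repetitions: significant in both with agreeing signs.

    The reported statistic/mean is the mean of the two repetitions' mean
    z values; the p-value is the larger of the two.
    """
    if map1.labels != map2.labels or map1.band_names != map2.band_names:
        raise ValueError("activation matrices have mismatched grids")
    if map1.alpha != map2.alpha:
        raise ValueError("activation matrices tested at different alpha")
    same_sign = np.sign(map1.mean_z) == np.sign(map2.mean_z)
    significant = map1.significant & map2.significant & same_sign
    return ActivationMatrix(
        labels=map1.labels,
        band_names=map1.band_names,
        mean_z=(map1.mean_z + map2.mean_z) / 2.0,
        statistic=(map1.mean_z + map2.mean_z) / 2.0,
        p_value=np.maximum(map1.p_value, map2.p_value),
        significant=significant,
        testable=map1.testable & map2.testable,
        alpha=map1.alpha,
        condition=f"{map1.condition}+{map2.condition}",
    )
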
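"""Distributed linear inverse: spherical lead field and sLORETA standardization.

The forward model is the linear system ``A x = b + n`` where A is the
lead field (each column the scalp potential pattern of one unit dipole),
x the dipole strengths and b the measured electrode potentials.  The
minimum-norm estimate under an average-reference constraint is

    x_hat = A' (A A' + lambda H)^+ b,        H = I - 11'/m

and sLORETA standardizes each source by its resolution-derived variance,

    power_l = x_hat_l^2 / S_ll,   S = A' (A A' + lambda H)^+ A,

which localizes a single noise-free point source exactly (Cauchy-Schwarz
on the PSD matrix S).  The desk-scale lead field is a homogeneous
conducting sphere with radially oriented dipoles (classical Legendre
series solution); a seeded smooth random matrix is available for tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre

_LEGENDRE_TERMS = 80


@dataclass
class LeadField:
    """Electrode x source gain matrix with source/electrode geometry."""

    A: np.ndarray                       # (n_electrodes, n_sources)
    source_positions: np.ndarray        # (n_sources, 3)
    electrode_positions: np.ndarray     # (n_electrodes, 3)
    electrode_labels: tuple

    def __post_init__(self):
        if self.A.ndim != 2 or self.A.shape[0] != len(self.electrode_labels):
            raise ValueError("lead field rows must match electrode labels")
        if np.any(np.linalg.norm(self.A, axis=0) == 0):
            raise ValueError("lead field has an all-zero column")

    @property
    def n_electrodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_sources(self) -> int:
        return self.A.shape[1]

    def subset(self, labels) -> "LeadField":
        """Restrict to a subset of electrodes (rows), preserving order given."""
        idx = [self.electrode_labels.index(lab) for lab in labels]
        return LeadField(
            A=self.A[idx],
            source_positions=self.source_positions,
            electrode_positions=self.electrode_positions[idx],
            electrode_labels=tuple(labels),
        )


@dataclass(frozen=True)
class InverseConfig:
    """Regularization settings for the standardized inverse."""

    lam: float = 1e-8                   # relative to mean eigenvalue of A A'
    lam_method: str = "fixed"           # "fixed" | "cross-validation"
    average_reference: bool = True

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.lam_method not in ("fixed", "cross-validation"):
            raise ValueError(f"unknown lambda method {self.lam_method!r}")


@dataclass
class SourceEstimate:
    """Standardized (dimensionless) source power, per source [per epoch]."""

    power: np.ndarray                   # (n_sources,) or (n_epochs, n_sources)


def _sphere_potentials(electrodes: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Surface potentials of radial unit dipoles in a homogeneous unit sphere.

    Classical series: V(gamma) ∝ sum_n (2n+1) f^(n-1) P_n(cos gamma) for a
    radial dipole at eccentricity f, electrode at angular distance gamma.
    """
    radii = np.linalg.norm(sources, axis=1)
    units = sources / radii[:, None]
    cosg = np.clip(electrodes @ units.T, -1.0, 1.0)     # (n_elec, n_src)
    n = np.arange(1, _LEGENDRE_TERMS + 1)
    # f^(n-1) per source, (n_src, N); P_n(cosg) per term, (N, n_elec, n_src)
    f_pow = radii[:, None] ** (n[None, :] - 1)
    V = np.zeros_like(cosg)
    for k, nk in enumerate(n):
        V += (2 * nk + 1) * f_pow[:, k][None, :] * eval_legendre(nk, cosg)
    return V


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5 ** 0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(1 - z ** 2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def build_leadfield(
    electrode_positions: np.ndarray,
    electrode_labels,
    n_sources: int = 660,
    geometry: str = "spherical",
    seed: int = 0,
    source_positions: np.ndarray | None = None,
    source_radius: float = 0.85,
) -> LeadField:
    """Build a desk-scale lead field.

    ``spherical`` places sources quasi-uniformly on a shell of radius
    ``source_radius`` inside a unit conducting sphere (upper hemisphere
    biased like cortex) and evaluates the analytic radial-dipole gains;
    ``random-smooth`` draws a seeded random matrix smoothed over
    electrodes.  Columns are normalized to unit norm in both cases.
    """
    rng = np.random.default_rng(seed)
    electrode_positions = np.asarray(electrode_positions, dtype=float)
    if n_sources < 66:
        raise ValueError("need at least 66 sources (one per Brodmann parcel)")
    if electrode_positions.shape[0] > 61:
        raise ValueError("at most 61 electrodes supported")

    if source_positions is None:
        pts = _fibonacci_sphere(n_sources)
        # compress the lower hemisphere: cortex lives mostly above the ears
        pts[:, 2] = 0.25 + 0.75 * pts[:, 2]
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        jitter = rng.normal(scale=0.01, size=pts.shape)
        pts = pts + jitter
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * source_radius
        source_positions = pts
    else:
        source_positions = np.asarray(source_positions, dtype=float)

    if geometry == "spherical":
        A = _sphere_potentials(electrode_positions, source_positions)
    elif geometry == "random-smooth":
        raw = rng.standard_normal((electrode_positions.shape[0], source_positions.shape[0]))
        # smooth across electrodes with a spatial kernel so columns are EEG-like
        d = np.linalg.norm(
            electrode_positions[:, None, :] - electrode_positions[None, :, :], axis=-1
        )
        K = np.exp(-(d ** 2) / (2 * 0.5 ** 2))
        A = K @ raw
    else:
        raise ValueError(f"unknown lead field geometry {geometry!r}")

    norms = np.linalg.norm(A, axis=0)
    if np.any(norms == 0):
        raise ValueError("degenerate geometry produced an all-zero column")
    A = A / norms
    return LeadField(
        A=A,
        source_positions=source_positions,
        electrode_positions=electrode_positions,
        electrode_labels=tuple(electrode_labels),
    )


# ---------------------------------------------------------------------------

class InverseOperator:
    """Precomputed sLORETA operator for a fixed lead field and lambda."""

    def __init__(self, leadfield: LeadField, cfg: InverseConfig = InverseConfig()):
        m = leadfield.n_electrodes
        H = np.eye(m) - np.ones((m, m)) / m
        A = H @ leadfield.A if cfg.average_reference else leadfield.A
        G = A @ A.T
        lam_abs = cfg.lam * np.trace(G) / m
        M = G + lam_abs * (H if cfg.average_reference else np.eye(m))
        Minv = np.linalg.pinv(M, hermitian=True)
        self.T = A.T @ Minv                      # (n_sources, n_electrodes)
        self.S_diag = np.einsum("ij,ji->i", self.T, A)   # diag of T A
        if np.any(self.S_diag <= 0):
            raise np.linalg.LinAlgError(
                "resolution matrix has non-positive diagonal; the system is "
                "singular — set lambda > 0"
            )
        self.A = A
        self.average_reference = cfg.average_reference
        self._H = H

    def center(self, b: np.ndarray) -> np.ndarray:
        if not self.average_reference:
            return b
        return b - b.mean(axis=0, keepdims=True)

    def standardized_power(self, b: np.ndarray) -> np.ndarray:
        """sLORETA standardized power per source for data b (electrodes[, t])."""
        x = self.T @ self.center(np.atleast_2d(b.T).T if b.ndim == 1 else b)
        if b.ndim == 1:
            x = x.ravel()
            return x ** 2 / self.S_diag
        return (x ** 2) / self.S_diag[:, None]


def sloreta_inverse(b: np.ndarray, leadfield: LeadField,
                    cfg: InverseConfig = InverseConfig()) -> SourceEstimate:
    """Standardized source power for one measurement vector (or matrix)."""
    if cfg.lam_method == "cross-validation":
        lam = cross_validate_lambda(np.atleast_2d(b.T).T if b.ndim == 1 else b, leadfield)
        cfg = InverseConfig(lam=lam, lam_method="fixed",
                            average_reference=cfg.average_reference)
    op = InverseOperator(leadfield, cfg)
    return SourceEstimate(power=op.standardized_power(b).T)


def cross_validate_lambda(
    B: np.ndarray,
    leadfield: LeadField,
    grid=None,
) -> float:
    """Choose lambda by leave-one-electrode-out prediction error.

    For each candidate lambda and each held-out electrode i, the minimum-
    norm source estimate is computed from the remaining electrodes and
    used (through row i of the lead field) to predict electrode i; the
    lambda minimizing total squared prediction error over all columns of
    ``B`` (electrodes x observations) is returned, on the same relative
    scale as :class:`InverseConfig.lam`.

    The CV deliberately runs on unreferenced data: under an average
    reference the held-out channel is the negative sum of the others, so
    a lambda of zero would reconstruct it exactly and the criterion
    would always pick the smallest candidate.
    """
    if grid is None:
        grid = np.logspace(-6, 1, 8)
    m = leadfield.n_electrodes
    A = leadfield.A
    Bc = B
    G = A @ A.T
    scale = np.trace(G) / m
    errors = []
    for lam in grid:
        err = 0.0
        for i in range(m):
            keep = np.arange(m) != i
            Gi = G[np.ix_(keep, keep)]
            Mi = Gi + lam * scale * np.eye(m - 1)
            x = A[keep].T @ np.linalg.solve(Mi, Bc[keep])
            pred = A[i] @ x
            err += float(np.sum((Bc[i] - pred) ** 2))
        errors.append(err)
    return float(grid[int(np.argmin(errors))])
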
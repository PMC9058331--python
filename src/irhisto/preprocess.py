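"""Fingerprint truncation, modified EMSC correction and quality filtering.

Extended multiplicative signal correction (EMSC) decomposes each observed
spectrum by ordinary least squares into

    observed ≈ scale * reference
               + Σ_i b_i * interference_i          (paraffin basis)
               + Σ_j c_j * Legendre_j(t)           (smooth baseline)

where t is the wavenumber axis mapped affinely to [-1, 1].  Dividing out the
fitted interference and baseline terms and the multiplicative scale performs
de-paraffinization, baseline removal and normalization in one step, so FFPE
sections need no chemical dewaxing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from numpy.polynomial import legendre

from .core import (
    HyperCube,
    InvariantError,
    SpectraTable,
    WavenumberAxis,
)

AMIDE_I_CENTER = 1654.0  # cm^-1, protein amide I band used for quality checks


def truncate_fingerprint(obj, low: float = 1000.0, high: float = 1800.0):
    """Restrict a cube or spectra table to axis points in [low, high]."""
    if low >= high:
        raise InvariantError(f"low ({low}) must be < high ({high})")
    axis = obj.axis
    keep = (axis.values >= low) & (axis.values <= high)
    if not keep.any():
        raise InvariantError(
            f"[{low}, {high}] does not intersect the axis "
            f"[{axis.values[0]}, {axis.values[-1]}]"
        )
    if keep.all():
        return obj
    new_axis = WavenumberAxis(axis.values[keep])
    if isinstance(obj, HyperCube):
        return HyperCube(
            obj.sample_id, obj.pathology, new_axis,
            obj.data[:, :, keep], obj.pixel_size,
        )
    if isinstance(obj, SpectraTable):
        return obj.with_spectra(obj.spectra[:, keep], new_axis)
    raise TypeError(f"cannot truncate object of type {type(obj).__name__}")


def compute_reference(table: SpectraTable) -> np.ndarray:
    """Channel-wise mean spectrum, the EMSC reference."""
    if len(table) == 0:
        raise InvariantError("cannot compute a reference from an empty table")
    return table.spectra.mean(axis=0)


def build_paraffin_basis(
    paraffin: SpectraTable | np.ndarray, n_components: int
) -> list[np.ndarray]:
    """Paraffin interference basis: the mean spectrum plus the first
    ``n_components`` principal directions of the mean-centered paraffin
    measurements (orthonormal)."""
    spectra = paraffin.spectra if isinstance(paraffin, SpectraTable) else np.asarray(paraffin, float)
    n = spectra.shape[0]
    if n_components < 0:
        raise InvariantError("n_components must be >= 0")
    if n_components >= n:
        raise InvariantError(
            f"n_components ({n_components}) must be < spectrum count ({n})"
        )
    mean = spectra.mean(axis=0)
    components = [mean]
    if n_components > 0:
        centered = spectra - mean
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        # degeneracy judged against the raw data scale, not s[0], so that
        # an all-identical input (centered = rounding dust) is still flagged
        tol = max(float(np.linalg.norm(spectra)), 1e-300) * 1e-10
        for i in range(n_components):
            if s[i] <= tol:
                warnings.warn(
                    f"paraffin principal direction {i} is numerically "
                    f"degenerate (zero variance)",
                    RuntimeWarning,
                )
            components.append(vt[i])
    return components


def _legendre_design(axis: WavenumberAxis, degree: int) -> np.ndarray:
    w = axis.values
    t = 2.0 * (w - w[0]) / (w[-1] - w[0]) - 1.0
    return legendre.legvander(t, degree)  # (n_channels, degree+1)


@dataclass
class EMSCBasis:
    """Design of the EMSC least-squares problem."""

    axis: WavenumberAxis
    reference: np.ndarray
    interference_components: list[np.ndarray] = field(default_factory=list)
    baseline_degree: int = 4

    def __post_init__(self):
        self.reference = np.asarray(self.reference, dtype=float)
        if self.reference.shape != (len(self.axis),):
            raise InvariantError("reference length must match the axis")
        self.interference_components = [
            np.asarray(c, dtype=float) for c in self.interference_components
        ]
        for c in self.interference_components:
            if c.shape != (len(self.axis),):
                raise InvariantError(
                    "interference component length must match the axis"
                )
        if self.baseline_degree < 0:
            raise InvariantError("baseline_degree must be >= 0")
        d = self.design
        if np.linalg.matrix_rank(d) < d.shape[1]:
            raise InvariantError(
                "EMSC design matrix is rank deficient: "
                + ", ".join(self._collinear_columns(d))
            )

    @property
    def n_interference(self) -> int:
        return len(self.interference_components)

    @property
    def column_names(self) -> list[str]:
        return (
            ["reference"]
            + [f"interference_{i}" for i in range(self.n_interference)]
            + [f"legendre_{j}" for j in range(self.baseline_degree + 1)]
        )

    @property
    def design(self) -> np.ndarray:
        cols = [self.reference]
        cols.extend(self.interference_components)
        design = np.column_stack(cols + [_legendre_design(self.axis, self.baseline_degree)])
        return design

    def _collinear_columns(self, design: np.ndarray) -> list[str]:
        # columns whose R diagonal (pivotless QR) collapses are the culprits
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = diag <= diag.max() * 1e-10
        return [n for n, b in zip(self.column_names, bad) if b]


@dataclass(frozen=True)
class EMSCFit:
    """Fitted EMSC coefficients and residual for one spectrum."""

    scale: float
    interference_coeffs: np.ndarray
    baseline_coeffs: np.ndarray
    residual_rms: float


@dataclass
class EMSCFitTable:
    """Vectorized EMSC fits for a whole table (one row per spectrum)."""

    scale: np.ndarray
    interference_coeffs: np.ndarray  # (n, k)
    baseline_coeffs: np.ndarray      # (n, degree+1)
    residual_rms: np.ndarray

    def __len__(self) -> int:
        return self.scale.size

    def __getitem__(self, i: int) -> EMSCFit:
        return EMSCFit(
            float(self.scale[i]),
            self.interference_coeffs[i].copy(),
            self.baseline_coeffs[i].copy(),
            float(self.residual_rms[i]),
        )


def fit_emsc_batch(spectra: np.ndarray, basis: EMSCBasis) -> EMSCFitTable:
    """Least-squares EMSC fits of many spectra via one pseudoinverse."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spectra.shape[1] != len(basis.axis):
        raise InvariantError("spectra are not on the basis axis")
    design = basis.design
    coeffs = np.linalg.pinv(design) @ spectra.T  # (n_cols, n)
    residual = spectra.T - design @ coeffs
    rms = np.sqrt(np.mean(residual**2, axis=0))
    k = basis.n_interference
    return EMSCFitTable(
        scale=coeffs[0],
        interference_coeffs=coeffs[1 : 1 + k].T,
        baseline_coeffs=coeffs[1 + k :].T,
        residual_rms=rms,
    )


def fit_emsc(observed: np.ndarray, basis: EMSCBasis) -> EMSCFit:
    """EMSC fit of a single spectrum."""
    return fit_emsc_batch(observed[None, :], basis)[0]


def apply_emsc(
    observed: np.ndarray,
    fit: EMSCFit,
    basis: EMSCBasis,
    scale_guard: float = 1e-3,
) -> np.ndarray | None:
    """Corrected spectrum, or None (quality-reject) if |scale| < guard."""
    if abs(fit.scale) < scale_guard:
        return None
    corrected = np.asarray(observed, dtype=float).copy()
    for b, comp in zip(fit.interference_coeffs, basis.interference_components):
        corrected -= b * comp
    corrected -= _legendre_design(basis.axis, basis.baseline_degree) @ fit.baseline_coeffs
    return corrected / fit.scale


def emsc_correct(
    table: SpectraTable, basis: EMSCBasis, scale_guard: float = 1e-3
) -> tuple[SpectraTable, EMSCFitTable]:
    """Fit and apply EMSC to every record of a table.

    Records whose |scale| falls below ``scale_guard`` get NaN spectra; they
    are flagged rather than raised, and :func:`quality_filter` removes them.
    """
    fits = fit_emsc_batch(table.spectra, basis)
    design = basis.design
    k = basis.n_interference
    removed = fits.interference_coeffs @ design[:, 1 : 1 + k].T
    removed += fits.baseline_coeffs @ design[:, 1 + k :].T
    corrected = table.spectra - removed
    safe = np.abs(fits.scale) >= scale_guard
    corrected[safe] /= fits.scale[safe, None]
    corrected[~safe] = np.nan
    return table.with_spectra(corrected), fits


@dataclass
class QualityCriteria:
    """Bounds that a spectrum's EMSC fit must satisfy to be kept."""

    min_scale: float = 0.2
    max_scale: float = 5.0
    max_residual_rms: float = np.inf
    min_amide1_height: float = 0.05

    def __post_init__(self):
        if not (0 < self.min_scale < self.max_scale):
            raise InvariantError("require 0 < min_scale < max_scale")
        if self.max_residual_rms < 0 or self.min_amide1_height < 0:
            raise InvariantError("bounds must be >= 0")


def default_criteria(fits: EMSCFitTable) -> QualityCriteria:
    """Data-scaled defaults: residual bound at 10x the median residual."""
    return QualityCriteria(
        max_residual_rms=10.0 * float(np.median(fits.residual_rms))
    )


@dataclass
class RejectionLog:
    """Which records were rejected and why (a record may hit several rules)."""

    kept: np.ndarray                  # boolean mask over input records
    counts: dict[str, int]            # rejection count per rule
    reasons: pd.DataFrame             # per-record boolean rule matrix

    @property
    def n_rejected(self) -> int:
        return int((~self.kept).sum())


def quality_filter(
    corrected: SpectraTable,
    fits: EMSCFitTable,
    criteria: QualityCriteria,
) -> tuple[SpectraTable, RejectionLog]:
    """Keep records whose EMSC fit and corrected spectrum pass all criteria.

    ``corrected`` is the EMSC-corrected table (the amide-I height criterion
    reads the corrected absorbance near 1654 cm^-1).
    """
    if len(fits) != len(corrected):
        raise InvariantError("one fit per record required")
    scale = fits.scale
    amide_idx = corrected.axis.nearest_index(AMIDE_I_CENTER)
    amide = corrected.spectra[:, amide_idx]
    fail_scale = (scale < criteria.min_scale) | (scale > criteria.max_scale)
    fail_resid = fits.residual_rms > criteria.max_residual_rms
    with np.errstate(invalid="ignore"):
        fail_amide = ~(amide >= criteria.min_amide1_height)  # NaN fails too
    reasons = pd.DataFrame(
        {"scale": fail_scale, "residual": fail_resid, "amide1": fail_amide}
    )
    kept = ~(fail_scale | fail_resid | fail_amide)
    log = RejectionLog(
        kept=kept.to_numpy() if hasattr(kept, "to_numpy") else kept,
        counts={c: int(reasons[c].sum()) for c in reasons.columns},
        reasons=reasons,
    )
    return corrected.select(log.kept), log
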
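"""Synthetic FTIR tissue cohorts with known ground truth.

Emulates the statistical structure the analysis pipeline assumes: fingerprint
region absorbance spectra (1000-1800 cm^-1, 4 cm^-1 sampling) built from
Gaussian bands at literature peak positions, contaminated by additive
paraffin bands (1380 and 1468 cm^-1), multiplicative scatter scaling, smooth
polynomial baselines and white noise, laid out as gland-like 2-D tissue maps
whose nuclear/cytoplasm contrast collapses in the cancer class.

The generator returns, next to the observed cubes, the ground-truth tissue
maps and per-pixel contamination coefficients, so preprocessing and
segmentation can be scored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy import ndimage

from .core import (
    EPITHELIUM,
    HyperCube,
    InvariantError,
    PATHOLOGY_ORDER,
    Pathology,
    SpectraTable,
    TissueClass,
    WavenumberAxis,
)

logger = logging.getLogger(__name__)

#: Fingerprint region sampled at 4 cm^-1: 201 points from 1000 to 1800.
DEFAULT_AXIS = WavenumberAxis(np.arange(1000.0, 1801.0, 4.0))


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian absorbance band: center (cm^-1), sd width, amplitude."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self):
        if not self.width > 0:
            raise InvariantError("peak width must be > 0")
        if self.amplitude < 0:
            raise InvariantError("peak amplitude must be >= 0")
        if not (900.0 <= self.center <= 1900.0):
            raise InvariantError("peak center must lie in or near 1000-1800")

    def evaluate(self, axis: WavenumberAxis) -> np.ndarray:
        w = axis.values
        return self.amplitude * np.exp(-0.5 * ((w - self.center) / self.width) ** 2)


@dataclass
class ClassProfile:
    """Band set of one tissue class plus per-pathology peak modulation.

    ``pathology_modulation`` maps pathology -> {peak center -> multiplicative
    factor at unit effect size}.  The cohort's ``effect_size`` e rescales a
    stored factor f to ``1 + e*(f - 1)``, so e=0 makes all groups identical
    and e=1 reproduces the stored contrast.
    """

    tissue_class: TissueClass
    peaks: list[PeakSpec]
    pathology_modulation: dict[Pathology, dict[float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self):
        centers = {p.center for p in self.peaks}
        for pathology, mods in self.pathology_modulation.items():
            for center, factor in mods.items():
                if factor <= 0:
                    raise InvariantError("modulation factors must be > 0")
                if center not in centers:
                    raise InvariantError(
                        f"modulated peak {center} not in profile for "
                        f"{self.tissue_class.value}"
                    )


def render_pure_spectrum(
    profile: ClassProfile,
    pathology: Pathology,
    axis: WavenumberAxis = DEFAULT_AXIS,
    effect_size: float = 1.0,
) -> np.ndarray:
    """Noise-free class spectrum: sum of modulated Gaussian bands."""
    if not isinstance(pathology, Pathology):
        pathology = Pathology(str(pathology))  # raises on unknown label
    mods = profile.pathology_modulation.get(pathology, {})
    out = np.zeros(len(axis))
    for peak in profile.peaks:
        factor = 1.0 + effect_size * (mods.get(peak.center, 1.0) - 1.0)
        factor = max(factor, 0.05)
        out += factor * peak.evaluate(axis)
    return out


def default_profiles() -> dict[TissueClass, ClassProfile]:
    """Band assignments: 1040 sugars, 1078/1238 DNA, 1160 proteins,
    1546 amide II, 1654 amide I, 1726 phospholipids.  1380/1468 are reserved
    for paraffin contamination and never appear in tissue profiles.

    Pathology contrast: DNA bands rise normal < adenoma < EM < cancer, with
    EM placed nearest adenoma so those two groups overlap most at moderate
    signal; the cytoplasmic sugar band falls with neoplastic progression but
    is elevated in EM (retained intracytoplasmic mucin), which is the main
    feature separating EM from adenoma in epithelium-only models.
    """
    A, EM, CA = Pathology.ADENOMA, Pathology.EPITHELIAL_MISPLACEMENT, Pathology.CANCER
    dna_mod = {A: {1078.0: 1.30, 1238.0: 1.25},
               EM: {1078.0: 1.42, 1238.0: 1.36},
               CA: {1078.0: 1.65, 1238.0: 1.55}}
    cyto_mod = {A: {1040.0: 0.85, 1078.0: 1.30},
                EM: {1040.0: 1.35, 1078.0: 1.42},
                CA: {1040.0: 0.60, 1078.0: 1.65}}
    return {
        TissueClass.NUCLEAR: ClassProfile(
            TissueClass.NUCLEAR,
            [PeakSpec(1078, 10, 0.45), PeakSpec(1238, 12, 0.40),
             PeakSpec(1160, 10, 0.15), PeakSpec(1546, 14, 0.55),
             PeakSpec(1654, 16, 0.90), PeakSpec(1726, 10, 0.10)],
            dna_mod,
        ),
        TissueClass.CYTOPLASMIC: ClassProfile(
            TissueClass.CYTOPLASMIC,
            [PeakSpec(1040, 12, 0.40), PeakSpec(1160, 10, 0.20),
             PeakSpec(1078, 10, 0.10), PeakSpec(1546, 14, 0.50),
             PeakSpec(1654, 16, 0.85), PeakSpec(1726, 10, 0.15)],
            cyto_mod,
        ),
        TissueClass.MUCIN: ClassProfile(
            TissueClass.MUCIN,
            [PeakSpec(1040, 14, 0.90), PeakSpec(1160, 12, 0.30),
             PeakSpec(1546, 14, 0.25), PeakSpec(1654, 16, 0.45)],
            {EM: {1040.0: 1.25}},
        ),
        TissueClass.LAMINA_PROPRIA: ClassProfile(
            TissueClass.LAMINA_PROPRIA,
            [PeakSpec(1238, 12, 0.20), PeakSpec(1160, 10, 0.25),
             PeakSpec(1546, 14, 0.50), PeakSpec(1654, 16, 0.80),
             PeakSpec(1726, 10, 0.05)],
        ),
        TissueClass.SUBMUCOSA: ClassProfile(
            TissueClass.SUBMUCOSA,
            [PeakSpec(1238, 12, 0.28), PeakSpec(1160, 10, 0.38),
             PeakSpec(1546, 14, 0.58), PeakSpec(1654, 16, 0.95),
             PeakSpec(1040, 12, 0.08)],
        ),
        TissueClass.STROMA: ClassProfile(
            TissueClass.STROMA,
            [PeakSpec(1238, 12, 0.33), PeakSpec(1160, 10, 0.30),
             PeakSpec(1546, 14, 0.62), PeakSpec(1654, 16, 1.00),
             PeakSpec(1078, 10, 0.08)],
        ),
        TissueClass.BACKGROUND: ClassProfile(TissueClass.BACKGROUND, []),
    }


@dataclass
class ContaminationModel:
    """Observation model applied to each pure pixel spectrum.

    observed = scatter_scale * pure
               + sum_i amplitude_i * paraffin_band_i
               + Legendre baseline
               + N(0, noise_sd) per channel
    """

    paraffin_peaks: list[PeakSpec] = field(
        default_factory=lambda: [PeakSpec(1380, 9, 1.0), PeakSpec(1468, 11, 0.8)]
    )
    paraffin_amplitude_range: tuple[float, float] = (0.1, 0.6)
    scatter_scale_range: tuple[float, float] = (0.7, 1.3)
    baseline_degree: int = 2
    baseline_coeff_scale: tuple[float, ...] = (0.05, 0.02, 0.01)
    noise_sd: float = 0.005

    def __post_init__(self):
        lo, hi = self.paraffin_amplitude_range
        if lo > hi:
            raise InvariantError("paraffin amplitude range inverted")
        slo, shi = self.scatter_scale_range
        if not (0 < slo <= shi):
            raise InvariantError("scatter range must be positive and ordered")
        if self.baseline_degree < 0:
            raise InvariantError("baseline_degree must be >= 0")
        if len(self.baseline_coeff_scale) != self.baseline_degree + 1:
            raise InvariantError(
                "baseline_coeff_scale needs one entry per polynomial term"
            )
        if self.noise_sd < 0:
            raise InvariantError("noise_sd must be >= 0")

    def paraffin_components(self, axis: WavenumberAxis) -> np.ndarray:
        """(n_peaks, n_channels) matrix of paraffin band shapes."""
        if not self.paraffin_peaks:
            return np.empty((0, len(axis)))
        return np.vstack([p.evaluate(axis) for p in self.paraffin_peaks])

    def baseline_design(self, axis: WavenumberAxis) -> np.ndarray:
        """(n_terms, n_channels) Legendre terms on axis mapped to [-1, 1]."""
        w = axis.values
        t = 2.0 * (w - w[0]) / (w[-1] - w[0]) - 1.0
        return legendre.legvander(t, self.baseline_degree).T


@dataclass(frozen=True)
class ContaminationTruth:
    """Coefficients actually drawn when contaminating spectra."""

    scatter_scale: np.ndarray     # (n,)
    paraffin_amplitudes: np.ndarray  # (n, n_peaks)
    baseline_coeffs: np.ndarray   # (n, degree+1)


def contaminate_batch(
    spectra: np.ndarray,
    model: ContaminationModel,
    axis: WavenumberAxis,
    rng: np.random.Generator,
) -> tuple[np.ndarray, ContaminationTruth]:
    """Contaminate many pure spectra at once; returns drawn ground truth."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    n = spectra.shape[0]
    scatter = rng.uniform(*model.scatter_scale_range, size=n)
    n_peaks = len(model.paraffin_peaks)
    amplitudes = rng.uniform(*model.paraffin_amplitude_range, size=(n, n_peaks))
    scales = np.asarray(model.baseline_coeff_scale)
    coeffs = rng.uniform(-1.0, 1.0, size=(n, model.baseline_degree + 1)) * scales
    observed = scatter[:, None] * spectra
    observed += amplitudes @ model.paraffin_components(axis)
    observed += coeffs @ model.baseline_design(axis)
    if model.noise_sd > 0:
        observed += rng.normal(0.0, model.noise_sd, size=observed.shape)
    return observed, ContaminationTruth(scatter, amplitudes, coeffs)


def contaminate(
    spectrum: np.ndarray,
    model: ContaminationModel,
    rng: np.random.Generator,
    axis: WavenumberAxis = DEFAULT_AXIS,
) -> tuple[np.ndarray, ContaminationTruth]:
    """Contaminate a single spectrum; see :func:`contaminate_batch`."""
    observed, truth = contaminate_batch(spectrum[None, :], model, axis, rng)
    return observed[0], truth


def simulate_paraffin_spectra(
    model: ContaminationModel,
    n: int,
    rng: np.random.Generator,
    axis: WavenumberAxis = DEFAULT_AXIS,
    noise_sd: float = 1e-4,
) -> np.ndarray:
    """Tissue-free paraffin measurements for building an EMSC paraffin basis.

    Each spectrum draws an independent amplitude per paraffin band, so the
    set spans the full band subspace.
    """
    comps = model.paraffin_components(axis)
    amps = rng.uniform(*model.paraffin_amplitude_range, size=(n, comps.shape[0]))
    out = amps @ comps
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# Spatial layout
# ---------------------------------------------------------------------------

def generate_label_map(
    tile_shape: tuple[int, int],
    pathology: Pathology,
    glands_per_image: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Tissue-class map (array of TissueClass values as strings).

    Non-cancer pathologies get elliptical glands — mucin lumen, cytoplasmic
    interior, nuclear rim — in a connective-tissue field (lamina propria for
    normal/adenoma, submucosa for epithelial misplacement).  Cancer gets
    irregular epithelial blobs whose pixels interleave nuclear and
    cytoplasmic labels at random (the lost gland architecture) in stroma.
    """
    pathology = Pathology(str(pathology))
    nr, nc = int(tile_shape[0]), int(tile_shape[1])
    if nr < 8 or nc < 8:
        raise InvariantError("tile_shape must be at least 8x8")
    if pathology is Pathology.CANCER:
        return _cancer_map((nr, nc), int(glands_per_image), rng)
    background = (
        TissueClass.SUBMUCOSA
        if pathology is Pathology.EPITHELIAL_MISPLACEMENT
        else TissueClass.LAMINA_PROPRIA
    )
    return _gland_map((nr, nc), background, int(glands_per_image), rng)


def _gland_map(
    shape: tuple[int, int],
    background: TissueClass,
    glands_per_image: int,
    rng: np.random.Generator,
) -> np.ndarray:
    nr, nc = shape
    label = np.full((nr, nc), background.value, dtype="<U32")
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    placed = 0
    min_r = 3.0
    for _ in range(int(glands_per_image)):
        max_r = 0.38 * min(nr, nc)
        if max_r < min_r:
            break
        a = rng.uniform(min_r, max_r)
        b = rng.uniform(min_r, max_r)
        r0 = rng.uniform(a, nr - 1 - a) if nr - 1 - a > a else (nr - 1) / 2
        c0 = rng.uniform(b, nc - 1 - b) if nc - 1 - b > b else (nc - 1) / 2
        d = np.sqrt(((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2)
        # nuclear rim and cytoplasmic annulus have equal areas (and match the
        # 50:50 nuclear/cytoplasmic mix of cancer blobs), so that epithelium
        # composition carries no pathology signal: at zero effect size the
        # group mean epithelial spectra must converge
        lumen_r = 0.38
        rim_r = np.sqrt((1.0 + lumen_r**2) / 2.0)  # ~0.756
        label[(d <= 1.0) & (d > rim_r)] = TissueClass.NUCLEAR.value
        label[(d <= rim_r) & (d > lumen_r)] = TissueClass.CYTOPLASMIC.value
        lumen = d <= lumen_r
        if not lumen.any():  # tiny gland: keep at least the center pixel
            lumen = (np.rint(rr) == np.rint(r0)) & (np.rint(cc) == np.rint(c0))
        label[lumen] = TissueClass.MUCIN.value
        placed += 1
    if placed < glands_per_image:
        logger.warning(
            "placed %d of %d glands in a %dx%d tile", placed,
            glands_per_image, nr, nc,
        )
    if glands_per_image > 0 and placed > 0:
        # overlapping glands can erase a ring class; repair the inventory
        for cls, d_target in (
            (TissueClass.MUCIN, 0.0),
            (TissueClass.CYTOPLASMIC, 0.57),
            (TissueClass.NUCLEAR, 0.9),
        ):
            if not (label == cls.value).any():
                d = np.sqrt(((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2)
                idx = np.unravel_index(np.argmin(np.abs(d - d_target)), d.shape)
                label[idx] = cls.value
    return label


def _cancer_map(
    shape: tuple[int, int], glands_per_image: int, rng: np.random.Generator
) -> np.ndarray:
    nr, nc = shape
    # draw a reference gland layout with the same mechanics and use its
    # realized nuclear:(nuclear+cytoplasmic) ratio as the blob mix
    # probability, so epithelium composition is identically distributed
    # across pathologies (pixelation bias and all) and carries no label
    # signal on its own
    reference = _gland_map(
        shape, TissueClass.LAMINA_PROPRIA, max(glands_per_image, 1), rng
    )
    n_nuc = float((reference == TissueClass.NUCLEAR.value).sum())
    n_cyt = float((reference == TissueClass.CYTOPLASMIC.value).sum())
    p_nuclear = n_nuc / (n_nuc + n_cyt) if n_nuc + n_cyt > 0 else 0.5
    field_ = ndimage.gaussian_filter(
        rng.standard_normal((nr, nc)), sigma=max(1.5, min(nr, nc) / 12.0)
    )
    thresh = np.quantile(field_, 0.55)
    epi = field_ > thresh
    if epi.sum() < 4:
        flat = np.argsort(field_, axis=None)[-4:]
        epi = np.zeros_like(epi)
        epi[np.unravel_index(flat, epi.shape)] = True
    label = np.full((nr, nc), TissueClass.STROMA.value, dtype="<U32")
    # nuclear/cytoplasmic pixels interleaved at random: architecture is lost
    epi_idx = np.nonzero(epi)
    mix = rng.random(epi.sum()) < p_nuclear
    sub = label[epi_idx]
    sub[mix] = TissueClass.NUCLEAR.value
    sub[~mix] = TissueClass.CYTOPLASMIC.value
    label[epi_idx] = sub
    for cls in (TissueClass.NUCLEAR, TissueClass.CYTOPLASMIC):
        if not (label == cls.value).any():
            i = (epi_idx[0][0], epi_idx[1][0])
            label[i] = cls.value
    return label


#: Tissue classes a pathology's label map may contain (background excluded).
CLASS_INVENTORY: dict[Pathology, frozenset[TissueClass]] = {
    Pathology.NORMAL: frozenset(
        {TissueClass.NUCLEAR, TissueClass.CYTOPLASMIC, TissueClass.MUCIN,
         TissueClass.LAMINA_PROPRIA}
    ),
    Pathology.ADENOMA: frozenset(
        {TissueClass.NUCLEAR, TissueClass.CYTOPLASMIC, TissueClass.MUCIN,
         TissueClass.LAMINA_PROPRIA}
    ),
    Pathology.EPITHELIAL_MISPLACEMENT: frozenset(
        {TissueClass.NUCLEAR, TissueClass.CYTOPLASMIC, TissueClass.MUCIN,
         TissueClass.SUBMUCOSA}
    ),
    Pathology.CANCER: frozenset(
        {TissueClass.NUCLEAR, TissueClass.CYTOPLASMIC, TissueClass.STROMA}
    ),
}


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-design parameters for a synthetic cohort.

    Defaults follow the emulated study: 10 samples per diagnostic group,
    128x128-pixel tiles at 1.1 µm pitch, fingerprint axis at 4 cm^-1.
    """

    samples_per_group: int = 10
    tile_shape: tuple[int, int] = (128, 128)
    glands_per_image: tuple[int, int] = (2, 4)  # inclusive count range
    effect_size: float = 1.0
    contamination: ContaminationModel = field(default_factory=ContaminationModel)
    seed: int = 0
    axis: WavenumberAxis = DEFAULT_AXIS
    pixel_size: float = 1.1
    profiles: dict[TissueClass, ClassProfile] = field(default_factory=default_profiles)

    def __post_init__(self):
        if self.samples_per_group < 1:
            raise InvariantError("samples_per_group must be >= 1")
        if self.tile_shape[0] < 8 or self.tile_shape[1] < 8:
            raise InvariantError("tile_shape must be at least 8x8")
        lo, hi = self.glands_per_image
        if lo < 0 or hi < lo:
            raise InvariantError("glands_per_image must be a valid count range")


@dataclass
class SyntheticCohort:
    """Generated cubes plus per-sample ground truth."""

    cubes: list[HyperCube]
    label_maps: dict[str, np.ndarray]
    contamination: dict[str, ContaminationTruth]

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [c.sample_id for c in self.cubes],
                "pathology": [c.pathology.value for c in self.cubes],
            }
        )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """4 x samples_per_group cubes with ground truth; seed-deterministic."""
    rng = np.random.default_rng(config.seed)
    cubes: list[HyperCube] = []
    label_maps: dict[str, np.ndarray] = {}
    contamination: dict[str, ContaminationTruth] = {}
    nr, nc = config.tile_shape
    for pathology in PATHOLOGY_ORDER:
        for i in range(config.samples_per_group):
            sample_id = f"{pathology.value}_{i:02d}"
            glands = int(rng.integers(config.glands_per_image[0],
                                      config.glands_per_image[1] + 1))
            label_map = generate_label_map(
                (nr, nc), pathology, glands, rng
            )
            pure = np.zeros((nr, nc, len(config.axis)))
            for cls in TissueClass:
                mask = label_map == cls.value
                if not mask.any():
                    continue
                pure[mask] = render_pure_spectrum(
                    config.profiles[cls], pathology, config.axis,
                    config.effect_size,
                )
            flat = pure.reshape(-1, len(config.axis))
            observed, truth = contaminate_batch(
                flat, config.contamination, config.axis, rng
            )
            cubes.append(
                HyperCube(
                    sample_id=sample_id,
                    pathology=pathology,
                    axis=config.axis,
                    data=observed.reshape(nr, nc, len(config.axis)),
                    pixel_size=config.pixel_size,
                )
            )
            label_maps[sample_id] = label_map
            contamination[sample_id] = truth
    return SyntheticCohort(cubes, label_maps, contamination)
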
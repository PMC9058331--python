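"""End-to-end orchestration: simulate → preprocess → segment → extract →
cross-validate → report.

The pipeline works on synthetic cohorts (or cubes read from disk) and wires
the modules together with one seed.  Cluster labelling uses the ground-truth
majority rule when truth maps are available; on real data the mapping would
come from a pathologist-reviewed YAML file instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classify, preprocess, segment, synthetic
from .core import (
    EPITHELIUM,
    HyperCube,
    Pathology,
    SpectraTable,
    TissueClass,
    concat_tables,
    flatten_cube,
)

#: Cluster counts used for per-image K-means on synthetic tissue: non-cancer
#: images carry four tissue classes (background pixels are quality-rejected
#: upstream), cancer images three.
DEFAULT_K_BY_PATHOLOGY = {
    Pathology.NORMAL: 4,
    Pathology.ADENOMA: 4,
    Pathology.EPITHELIAL_MISPLACEMENT: 4,
    Pathology.CANCER: 3,
}


@dataclass
class PipelineConfig:
    low: float = 1000.0
    high: float = 1800.0
    baseline_degree: int = 4
    n_paraffin_components: int = 2
    n_paraffin_spectra: int = 200
    k_by_pathology: dict = field(
        default_factory=lambda: dict(DEFAULT_K_BY_PATHOLOGY)
    )
    kmeans_restarts: int = 5
    extraction_classes: frozenset = EPITHELIUM
    cv: classify.CVConfig = field(default_factory=classify.CVConfig)


@dataclass
class PipelineResult:
    cv: classify.CVResult
    extracted: SpectraTable
    rejection_counts: dict[str, int]
    n_input_spectra: int


def preprocess_cohort(
    cubes: list[HyperCube],
    contamination: synthetic.ContaminationModel,
    config: PipelineConfig,
    seed: int,
) -> tuple[SpectraTable, dict[str, int]]:
    """Truncate, EMSC-correct and quality-filter every cube's spectra.

    The paraffin basis is built from simulated tissue-free paraffin
    measurements; the EMSC reference is the mean of all truncated tissue
    spectra (label-free, computed once upstream of cross-validation).
    """
    tables = [
        preprocess.truncate_fingerprint(flatten_cube(c), config.low, config.high)
        for c in cubes
    ]
    raw = concat_tables(tables)
    rng = np.random.default_rng(seed)
    paraffin = synthetic.simulate_paraffin_spectra(
        contamination, config.n_paraffin_spectra, rng, raw.axis
    )
    basis = preprocess.EMSCBasis(
        axis=raw.axis,
        reference=preprocess.compute_reference(raw),
        interference_components=preprocess.build_paraffin_basis(
            paraffin, config.n_paraffin_components
        ),
        baseline_degree=config.baseline_degree,
    )
    corrected, fits = preprocess.emsc_correct(raw, basis)
    criteria = preprocess.default_criteria(fits)
    passing, log = preprocess.quality_filter(corrected, fits, criteria)
    return passing, log.counts


def segment_and_extract(
    table: SpectraTable,
    cohort: synthetic.SyntheticCohort,
    config: PipelineConfig,
    seed: int,
) -> SpectraTable:
    """Per-sample K-means, ground-truth cluster labelling, class extraction."""
    pieces = []
    pathology_of = {c.sample_id: c.pathology for c in cohort.cubes}
    for sample_id in table.sample_ids:
        sub = table.for_sample(sample_id)
        k = config.k_by_pathology[pathology_of[sample_id]]
        k = min(k, len(sub))
        cmap = segment.kmeans_segment(
            sub, k, seed=seed, restarts=config.kmeans_restarts
        )
        truth = cohort.label_maps[sample_id]
        cmap = segment.auto_label_by_ground_truth(cmap, truth)
        extracted = segment.extract_class_spectra(
            sub, cmap, config.extraction_classes
        )
        if len(extracted):
            pieces.append(extracted)
    return concat_tables(pieces)


def run_pipeline(
    cohort_config: synthetic.CohortConfig,
    groups=None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Full analysis of a synthetic cohort; seeded by the cohort seed."""
    config = config or PipelineConfig()
    cohort = synthetic.generate_cohort(cohort_config)
    table, rejections = preprocess_cohort(
        cohort.cubes, cohort_config.contamination, config,
        seed=cohort_config.seed + 1,
    )
    extracted = segment_and_extract(
        table, cohort, config, seed=cohort_config.seed + 2
    )
    cv = classify.losocv(extracted, groups=groups, config=config.cv)
    return PipelineResult(
        cv=cv,
        extracted=extracted,
        rejection_counts=rejections,
        n_input_spectra=sum(int(np.prod(c.data.shape[:2])) for c in cohort.cubes),
    )
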
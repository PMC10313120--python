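"""Synthetic cohort generation for pipeline testing and calibration.

Variants are drawn from four effect classes that mirror the loss-of-function
continuum the classifier targets: ``severe_lof`` (transactivation well below
40 %WT, usually with a second severe assay and defective insulin secretion),
``moderate_lof`` (40-60 %WT), ``mild_lof`` (60-65 %WT) and ``neutral``
(WT-like function, normal secretion).  Percent-of-WT readouts are Gaussian
around the class mean with a configurable coefficient of variation,
truncated at zero; GSIS insulin levels are drawn uniformly within class
ranges.  Structural-prediction flags and prior annotation codes are sampled
with class-dependent probabilities.  Clinical records are Gaussian around
the study cohort's published summary statistics with per-column missingness.

All randomness flows through one integer seed; identical configurations
produce identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AnnotationEvidence,
    EvidenceCode,
    FunctionalAssayPanel,
    MDOutcome,
    PatientRecord,
    SequencePrediction,
    StructuralPredictionSet,
    StructurePrediction,
    VariantId,
)

_AA3_CODES = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)


@dataclass(frozen=True)
class EffectClassSpec:
    """Generative description of one variant effect class."""

    name: str
    # mean %WT per assay
    ta_hela_mean: float
    ta_ins1_mean: float
    dna_binding_mean: float
    protein_expression_mean: float
    nuclear_localization_mean: float
    cv: float = 0.10  # shared coefficient of variation of the percent assays
    # uniform ranges for insulin (µg/L)
    gsis_basal_range: tuple[float, float] = (3.0, 9.0)
    gsis_stimulated_range: tuple[float, float] = (1.0, 7.0)
    gsis_gbc_range: tuple[float, float] = (8.0, 37.0)
    # structural-signal probabilities (conditional on analysis being run)
    p_structural_done: float = 0.0
    p_seq_destab: float = 0.0
    p_struct_higher: float = 0.0
    p_md_defect: float = 0.0
    # annotation-code inclusion probabilities
    annotation_probs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise ValueError("cv must be > 0")
        for name in ("gsis_basal_range", "gsis_stimulated_range", "gsis_gbc_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid range {name}: ({lo}, {hi})")
        for p in (self.p_structural_done, self.p_seq_destab,
                  self.p_struct_higher, self.p_md_defect):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


# Class parameters are the empirical per-class statistics of the 14-variant
# study panel: assay means, insulin ranges, and the frequencies of each
# annotation code / structural outcome among the variants the pipeline
# places in that class.
DEFAULT_CLASS_SPECS: dict[str, EffectClassSpec] = {
    "severe_lof": EffectClassSpec(
        name="severe_lof",
        ta_hela_mean=26, ta_ins1_mean=58, dna_binding_mean=29,
        protein_expression_mean=72, nuclear_localization_mean=75,
        gsis_basal_range=(5, 9), gsis_stimulated_range=(1, 5),
        gsis_gbc_range=(19, 31),
        p_structural_done=0.6, p_seq_destab=0.9, p_struct_higher=0.9,
        p_md_defect=0.4,
        annotation_probs={"PM1": 0.9, "PM2": 0.9, "PP5": 0.4, "PVS1": 0.2},
    ),
    "moderate_lof": EffectClassSpec(
        name="moderate_lof",
        ta_hela_mean=47, ta_ins1_mean=85, dna_binding_mean=108,
        protein_expression_mean=75, nuclear_localization_mean=74,
        gsis_basal_range=(5, 15), gsis_stimulated_range=(4, 7),
        gsis_gbc_range=(15, 37),
        p_structural_done=0.5, p_seq_destab=1.0, p_struct_higher=0.5,
        p_md_defect=0.5,
        annotation_probs={"PM1": 0.5, "PM2": 1.0, "PP3": 0.7, "PP6": 0.5},
    ),
    "mild_lof": EffectClassSpec(
        name="mild_lof",
        ta_hela_mean=62, ta_ins1_mean=57, dna_binding_mean=118,
        protein_expression_mean=97, nuclear_localization_mean=71,
        gsis_basal_range=(3, 7), gsis_stimulated_range=(2, 5),
        gsis_gbc_range=(8, 25),
        annotation_probs={"PM1": 1.0, "PM2": 1.0, "PP3": 1.0},
    ),
    "neutral": EffectClassSpec(
        name="neutral",
        ta_hela_mean=90, ta_ins1_mean=98, dna_binding_mean=112,
        protein_expression_mean=73, nuclear_localization_mean=77,
        gsis_basal_range=(3, 8), gsis_stimulated_range=(8, 45),
        gsis_gbc_range=(8, 48),
        annotation_probs={"PM1": 0.5, "PM2": 1.0, "PP3": 0.5, "BP4_Strong": 0.25},
    ),
}

# class mixture matching the study's 14-variant composition
DEFAULT_WEIGHTS = {
    "severe_lof": 5 / 14,
    "moderate_lof": 4 / 14,
    "mild_lof": 1 / 14,
    "neutral": 4 / 14,
}

# published cohort summaries used as generative clinical parameters:
# parameter -> (mean, sd)
DEFAULT_CLINICAL_PARAMS = {
    "age_at_onset": (21.0, 6.5),
    "duration": (9.9, 6.7),
    "bmi": (23.0, 4.0),
    "fpg": (181.0, 64.0),
    "ppg": (277.0, 97.0),
    "hba1c": (9.2, 2.4),
    "c_peptide_fasting": (0.9, 0.4),
    "c_peptide_stimulated": (1.5, 0.6),
    "total_cholesterol": (169.0, 41.0),
    "triglycerides": (137.0, 82.0),
    "hdl": (39.0, 8.5),
    "ldl": (94.0, 36.0),
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_variants: int = 14
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    seed: int = 0
    missingness: float = 0.05       # per clinical column
    clinical_params: dict = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_PARAMS)
    )
    class_specs: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SPECS)
    )

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        tot = sum(self.weights.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"class weights must sum to 1, got {tot}")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")
        unknown = set(self.weights) - set(self.class_specs)
        if unknown:
            raise ValueError(f"weights reference unknown classes: {unknown}")


def _truncated_normal(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Gaussian truncated at zero (percentages cannot be negative)."""
    a = (0.0 - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                     random_state=rng))


def generate_panel(
    spec: EffectClassSpec, seed: int | np.random.Generator
) -> tuple[FunctionalAssayPanel, str]:
    """Draw one functional assay panel from an effect class.

    Returns the panel together with its true class label.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pct = {
        name: _truncated_normal(getattr(spec, f"{name}_mean"),
                                max(spec.cv * getattr(spec, f"{name}_mean"), 1e-9),
                                rng)
        for name in ("ta_hela", "ta_ins1", "dna_binding",
                     "protein_expression", "nuclear_localization")
    }
    gsis = {
        f"gsis_{cond}": float(rng.uniform(*getattr(spec, f"gsis_{cond}_range")))
        for cond in ("basal", "stimulated", "gbc")
    }
    # glibenclamide potentiates secretion; never below the stimulated level
    gsis["gsis_gbc"] = max(gsis["gsis_gbc"], gsis["gsis_stimulated"])
    return FunctionalAssayPanel(**pct, **gsis), spec.name


def _generate_structural(
    spec: EffectClassSpec, rng: np.random.Generator
) -> StructuralPredictionSet:
    if rng.random() >= spec.p_structural_done:
        return StructuralPredictionSet()
    seq = (SequencePrediction.DESTABILIZING
           if rng.random() < spec.p_seq_destab else SequencePrediction.NO_DEFECT)
    struct = (StructurePrediction.HIGHER_DESTABILIZING
              if rng.random() < spec.p_struct_higher
              else StructurePrediction.LEAST_DESTABILIZING)
    md = (MDOutcome.DEFECT if rng.random() < spec.p_md_defect
          else MDOutcome.NO_DEFECT)
    return StructuralPredictionSet(seq, struct, md)


def _generate_annotations(
    spec: EffectClassSpec, rng: np.random.Generator
) -> AnnotationEvidence:
    codes = [
        EvidenceCode.parse(code)
        for code, p in sorted(spec.annotation_probs.items())
        if rng.random() < p
    ]
    return AnnotationEvidence(frozenset(codes))


def _random_variant_id(rng: np.random.Generator, index: int) -> VariantId:
    pos = int(rng.integers(91, 632))
    ref, alt = rng.choice(len(_AA3_CODES), size=2, replace=False)
    protein = f"p.{_AA3_CODES[ref]}{pos}{_AA3_CODES[alt]}"
    return VariantId(protein, f"c.{3 * pos}N>N")


@dataclass(frozen=True)
class SyntheticVariant:
    variant: VariantId
    true_class: str
    panel: FunctionalAssayPanel
    structural: StructuralPredictionSet
    annotations: AnnotationEvidence


@dataclass(frozen=True)
class SyntheticCohort:
    config: SyntheticCohortConfig
    variants: tuple[SyntheticVariant, ...]
    patients: tuple[PatientRecord, ...]

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_change": [v.variant.protein_change for v in self.variants],
                "true_class": [v.true_class for v in self.variants],
            }
        )


def _stratified_labels(weights: dict, n: int, rng: np.random.Generator) -> list[str]:
    """Fix the class composition at weights*n (largest-remainder rounding),
    shuffled: the generator emulates a cohort of fixed composition, so only
    within-class variation is random, not the class counts themselves."""
    names = sorted(weights)
    base = {c: int(np.floor(weights[c] * n)) for c in names}
    short = n - sum(base.values())
    by_frac = sorted(names, key=lambda c: -(weights[c] * n - np.floor(weights[c] * n)))
    for c in by_frac[:short]:
        base[c] += 1
    labels = [c for c in names for _ in range(base[c])]
    rng.shuffle(labels)
    return labels


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort (variants plus one carrier each)."""
    rng = np.random.default_rng(config.seed)
    labels = _stratified_labels(config.weights, config.n_variants, rng)

    variants: list[SyntheticVariant] = []
    patients: list[PatientRecord] = []
    for i, cname in enumerate(labels):
        spec = config.class_specs[cname]
        vid = _random_variant_id(rng, i)
        panel, label = generate_panel(spec, rng)
        structural = _generate_structural(spec, rng)
        annotations = _generate_annotations(spec, rng)
        variants.append(SyntheticVariant(vid, label, panel, structural, annotations))

        clinical = {}
        for param, (mean, sd) in config.clinical_params.items():
            if rng.random() < config.missingness:
                clinical[param] = None
            else:
                # clinical fields are strictly positive when present
                clinical[param] = max(round(_truncated_normal(mean, sd, rng), 2), 0.01)
        patients.append(PatientRecord(
            patient_id=f"S-{i + 1:03d}",
            gender="F" if rng.random() < 0.55 else "M",
            variant=vid,
            **clinical,
        ))
    return SyntheticCohort(config, tuple(variants), tuple(patients))
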
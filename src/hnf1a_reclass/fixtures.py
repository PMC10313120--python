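"""Packaged study dataset: 14 HNF1A variants and 20 MODY patients.

The functional panels (transactivation in HeLa and INS-1 cells, DNA binding,
protein expression, nuclear localization — all %WT — and GSIS insulin levels
in µg/L at basal, stimulated and glibenclamide-potentiated conditions), the
categorical structural-prediction outcomes, the prior annotation evidence and
the published re-interpretations are transcribed from the source study's
variant tables; the clinical table carries the 20 patients with their
scattered missing fields.

Where the study's summary table and its narrative disagree on a variant's
evidence list, both readings are stored; ``annotations`` (the default
pipeline input) follows the narrative reading, which is the one consistent
with the published tier for every variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Optional

from .datatypes import (
    AnnotationEvidence,
    FunctionalAssayPanel,
    MDOutcome,
    PatientRecord,
    SequencePrediction,
    StructuralPredictionSet,
    StructurePrediction,
    Tier,
    VariantId,
)

_ND = "not_done"


@dataclass(frozen=True)
class FixtureVariant:
    variant: VariantId
    panel: FunctionalAssayPanel
    structural: StructuralPredictionSet
    annotations: AnnotationEvidence           # narrative reading (default)
    annotations_2015: AnnotationEvidence      # prior-classification column
    prior_tier: Tier                          # initial 2015-guideline verdict
    expected_tier: Tier                       # published re-interpretation
    expected_evidence_table: tuple[str, ...]  # summary-table evidence list
    expected_evidence_text: tuple[str, ...]   # narrative evidence list


def _sps(seq: str, struct: str, md: str) -> StructuralPredictionSet:
    return StructuralPredictionSet(
        SequencePrediction(seq), StructurePrediction(struct), MDOutcome(md)
    )


def _fv(
    protein: str,
    cdna: str,
    panel_vals: tuple[float, ...],
    structural: StructuralPredictionSet,
    ann: tuple[str, ...],
    ann2015: tuple[str, ...],
    prior: Tier,
    tier: Tier,
    ev_table: tuple[str, ...],
    ev_text: tuple[str, ...],
) -> FixtureVariant:
    ta_hela, ta_ins1, dnab, expr, loc, basal, stim, gbc = panel_vals
    return FixtureVariant(
        variant=VariantId(protein, cdna),
        panel=FunctionalAssayPanel(
            ta_hela=ta_hela, ta_ins1=ta_ins1, dna_binding=dnab,
            protein_expression=expr, nuclear_localization=loc,
            gsis_basal=basal, gsis_stimulated=stim, gsis_gbc=gbc,
        ),
        structural=structural,
        annotations=AnnotationEvidence.from_strings(ann),
        annotations_2015=AnnotationEvidence.from_strings(ann2015),
        prior_tier=prior,
        expected_tier=tier,
        expected_evidence_table=ev_table,
        expected_evidence_text=ev_text,
    )


_V, _LP, _P, _B = Tier.VUS, Tier.LIKELY_PATHOGENIC, Tier.PATHOGENIC, Tier.BENIGN

_VARIANTS: tuple[FixtureVariant, ...] = (
    _fv("p.Lys120Asn", "c.360G>C", (47, 90, 92, 76, 81, 5, 4, 15),
        _sps("destabilizing", "higher_destabilizing", "defect"),
        ("PM2",), ("PM1", "PM2"), _V, _LP,
        ("PS3_Moderate", "PP3_Strong"),
        ("PS3_Moderate", "PM2", "PP3_Strong")),
    _fv("p.Gln125His", "c.375G>C", (53, 52, 103, 67, 77, 9, 4, 32),
        _sps("destabilizing", "least_destabilizing", _ND),
        ("PM2", "PP6"), ("PM1", "PM2"), _V, _LP,
        ("PS3_Moderate", "PP3", "PP6"),
        ("PS3_Moderate", "PM2", "PP3_Supporting", "PP6")),
    _fv("p.Asn127del", "c.377_379delACA", (23, 58, 21, 66, 57, 7, 5, 19),
        StructuralPredictionSet(),
        ("PM1",), ("PM1", "PM2"), _V, _P,
        ("PS3_Strong",),
        ("PS3_Strong", "PM1")),
    _fv("p.Val134Ile", "c.400G>A", (38, 32, 38, 75, 71, 8, 1, 21),
        _sps("no_defect", "least_destabilizing", _ND),
        ("PM2",), ("PM1", "PM2", "PP3"), _V, _LP,
        ("PS3_Strong",),
        ("PS3_Strong", "PM2")),
    _fv("p.Arg200Trp", "c.598C>T", (27, 84, 32, 71, 67, 5, 2, 19),
        _sps("destabilizing", "higher_destabilizing", "no_defect"),
        ("PM1", "PM2", "PP5"), ("PM1", "PM2", "PP5"), _V, _P,
        ("PS3_Strong",),
        ("PS3_Strong", "PM1", "PM2", "PP3_Supporting", "PP5")),
    _fv("p.Arg272His", "c.815G>A", (26, 59, 31, 91, 84, 7, 4, 19),
        _sps("destabilizing", "higher_destabilizing", "defect"),
        ("PM1", "PM2", "PP5"), ("PM1", "PM2", "PP3", "PP5"), _LP, _P,
        ("PS3_Strong",),
        ("PS3_Strong", "PM1", "PM2", "PP5", "PP3_Strong")),
    _fv("p.Gly292fs*25", "c.872-873dupC", (18, 55, 23, 58, 98, 9, 4, 31),
        StructuralPredictionSet(),
        ("PVS1",), ("PVS1",), _LP, _P,
        ("PS3_Strong",),
        ("PVS1", "PS3_Strong")),
    _fv("p.Ala301Thr", "c.901G>A", (105, 123, 105, 54, 75, 8, 45, 48),
        StructuralPredictionSet(),
        ("PM1", "PM2", "BP4_Strong"), ("PM1", "PM2"), _V, _B,
        ("BS3_Strong", "BP4_Strong"),
        ("PM1", "PM2", "BS3_Strong", "BP4_Strong")),
    _fv("p.Thr354Met", "c.1061C>T", (62, 57, 118, 97, 71, 5, 2, 11),
        StructuralPredictionSet(),
        ("PM1", "PM2", "PP3"), ("PM1", "PM2", "PP3"), _V, _LP,
        ("PS3_Supporting",),
        ("PS3_Supporting", "PM1", "PM2", "PP3")),
    _fv("p.Ala367Val", "c.1100C>T", (61, 56, 130, 87, 76, 3, 8, 8),
        StructuralPredictionSet(),
        ("PM1", "PM2", "PP3"), ("PM1", "PM2"), _V, _V,
        ("BS3_Strong", "BP4_Strong"),
        ("PM1", "PM2", "PP3", "BS3_Strong")),
    _fv("p.Pro379Ser", "c.1135C>T", (42, 75, 125, 80, 65, 15, 5, 37),
        StructuralPredictionSet(),
        ("PM1", "PM2", "PP3"), ("PM1", "PM2", "PM5", "PP3"), _LP, _LP,
        ("PS3_Moderate",),
        ("PS3_Moderate", "PM1", "PM2", "PP3")),
    _fv("p.Asp602Asn", "c.1804G>A", (51, 72, 115, 68, 95, 3, 11, 11),
        StructuralPredictionSet(),
        ("PM2",), ("PM1", "PM2"), _V, _V,
        ("BS3_Strong",),
        ("PM2", "BS3_Strong")),
    _fv("p.Leu611Pro", "c.1832T>C", (45, 137, 112, 76, 71, 5, 7, 25),
        StructuralPredictionSet(),
        ("PM2", "PP3", "PP6"), ("PM1", "PM2", "PP3"), _V, _LP,
        ("PS3_Moderate",),
        ("PS3_Moderate", "PM2", "PP3", "PP6_Supporting")),
    _fv("p.Glu619Lys", "c.1855G>A", (97, 90, 97, 81, 60, 6, 16, 11),
        StructuralPredictionSet(),
        ("PM2", "PP3"), ("PM1", "PM2", "PP3"), _V, _V,
        ("BS3_Strong",),
        ("PM2", "PP3", "BS3_Strong")),
)


def _pr(pid, gender, variant, *vals) -> PatientRecord:
    names = PatientRecord.NUMERIC_FIELDS
    kwargs = {n: (None if v is None else float(v)) for n, v in zip(names, vals)}
    return PatientRecord(pid, gender, VariantId(variant), **kwargs)


# Columns after variant: age_at_onset, duration, bmi, fpg, ppg, hba1c,
# c_peptide_fasting, c_peptide_stimulated, total_cholesterol, triglycerides,
# hdl, ldl.  None marks a dash in the clinical table.
_PATIENTS: tuple[PatientRecord, ...] = (
    _pr("M-026", "F", "p.Lys120Asn", 14, 3.7, 19.1, 188, 315, 7.1, 0.7, 1.1, 127, 61, 33, 82),
    _pr("M-027", "M", "p.Gln125His", 26, 6.3, 24, 134, 248, 6.9, 1, 2.2, 150, 167, 32, 85),
    _pr("M-028", "F", "p.Asn127del", 14.9, 18.1, 19.1, 277, 414, 9.5, 0.6, 0.8, 177, 134, 47, 101),
    _pr("M-124", "M", "p.Val134Ile", 26.7, 6.3, 21.9, 194, 390, 9.8, 0.5, 0.8, 136, 174, 27, 94),
    _pr("M-125", "M", "p.Arg200Trp", 22.8, 16.1, 17.9, 161, 280, 8.3, 0.5, 1.2, 152, 84, 47, 88),
    _pr("M-126", "F", "p.Arg200Trp", 11, 1, 23.2, 114, 171, None, 0.9, None, None, None, None, None),
    _pr("M-129", "F", "p.Arg272His", 26, 8, 26.9, 106, 204, 6.4, 1.2, 2, 250, 71, 45, 49),
    _pr("M-130", "F", "p.Arg272His", 23, 5, 23, 125, 220, 6.9, 1, 2.3, 191, 209, 28, 121),
    _pr("M-131", "F", "p.Gly292fs*25", 19.1, 13, 17.3, 204, 197, 10.8, 1.1, 2, 211, 176, 44, 132),
    _pr("M-035", "F", "p.Gly292fs*25", 11, 4, 18.6, 127, 225, 8.7, 0.9, 1.5, 153, 114, 59, 98),
    _pr("M-132", "M", "p.Ala301Thr", 28, 19, None, 114, 155, 7.3, None, None, 193, 136, 47, 125),
    _pr("M-133", "M", "p.Thr354Met", 24.8, 5, 16.2, 159, 243, 6.9, 0.7, 1.3, 125, 77, 39, 71),
    _pr("M-138", "F", "p.Ala367Val", 11.6, 5, 24.1, 219, 291, 11, 1, 1.6, 138, 65, 43, 82),
    _pr("M-134", "M", "p.Pro379Ser", 26, 6.8, 24, 268, 310, 11.4, None, None, 270, 150, 31, 209),
    _pr("M-135", "F", "p.Pro379Ser", 23, 3, 26.3, 250, 310, 11.2, 2.16, None, 145, 95, 41, 85),
    _pr("M-036", "M", "p.Pro379Ser", 24, 10, 27.6, 305, 521, 15.4, 0.2, 0.3, 187, 439, 37, 40),
    _pr("M-136", "F", "p.Pro379Ser", 14, None, 21.2, 289, 431, 12.7, 0.56, 1.31, 145, 95, 41, 85),
    _pr("M-139", "F", "p.Asp602Asn", 14, 5, 20, 159, 280, 9, 2, 2.6, 195, 110, 40, 70),
    _pr("M-137", "M", "p.Leu611Pro", 28.8, 18.2, 31.6, 108, 147, 6, 1.1, 3, 154, 95, 30, 105),
    _pr("M-040", "M", "p.Glu619Lys", 32, 27, 26.3, 134, 191, 9.5, 0.7, 1.4, 117, 160, 25, 60),
)

# Published summaries of the clinical table that the package reports but does
# not assert, because they cannot be recomputed from the printed records
# (see docs/methods.md): key -> (printed value, recomputed value).
NON_REPRODUCIBLE_SUMMARIES = MappingProxyType({
    "duration_mean": (9.9, 9.5),
    "fpg_mean": (181.0, 182.0),
    "c_peptide_stimulated_mean": (1.5, 1.6),
    "bmi_mean": (23.0, 22.5),
    "likely_pathogenic_percent": (42.8, 42.9),
})


@dataclass(frozen=True)
class StudyFixture:
    variants: tuple[FixtureVariant, ...]
    patients: tuple[PatientRecord, ...]

    def variant(self, protein_change: str) -> FixtureVariant:
        for fv in self.variants:
            if fv.variant.protein_change == protein_change:
                return fv
        raise KeyError(protein_change)


def load_study_fixture() -> StudyFixture:
    """Return the packaged 14-variant / 20-patient study dataset."""
    return StudyFixture(_VARIANTS, _PATIENTS)
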
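"""Strength-modulated PS3/BS3/PP3 evidence assignment.

The functional arm grades loss of function from the HeLa transactivation
assay corroborated by DNA binding, protein expression and GSIS:

* PS3 Strong  — at least ``min_severe_assays`` of {transactivation-HeLa,
  DNA binding, protein expression} below 40 %WT, with defective stimulated
  insulin secretion; escalated to VeryStrong when transactivation is
  additionally below 25 %WT.
* PS3 Moderate — otherwise, transactivation below 60 %WT with a secretion
  defect (the published 40-60 %WT band, extended downward so grading stays
  monotone when the severe rule's corroboration is absent).
* PS3 Supporting — otherwise, transactivation below 65 %WT with a secretion
  defect (the 60-65 %WT band).
* BS3 Strong — otherwise (no damaging functional signature).

Transactivation in INS-1 cells is deliberately not counted toward the
severe-assay tally (endogenous HNF1A inflates it), nor is nuclear
localization.  The structural arm grades the three in-silico signals
(sequence-based stability, structure-based stability, molecular dynamics):
all three defective -> PP3 Strong, one or two -> PP3 Supporting, none -> no
computational evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .datatypes import (
    AnnotationEvidence,
    EvidenceCode,
    EvidenceSet,
    FunctionalAssayPanel,
    MDOutcome,
    SequencePrediction,
    Strength,
    StructuralPredictionSet,
    StructurePrediction,
    Thresholds,
)


class EvidenceNotAssignable(ValueError):
    """Required assay fields are missing; no functional code can be emitted."""


@dataclass(frozen=True)
class EvidenceRuleTrace:
    """Audit record of one rule evaluation."""

    rule_id: str
    inputs: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    result: Optional[str] = None

    def __str__(self) -> str:
        ins = ", ".join(f"{k}={v}" for k, v in self.inputs.items())
        return f"{self.rule_id}({ins}) -> {self.result or 'none'}"


def assign_functional_evidence(
    panel: FunctionalAssayPanel, t: Thresholds = Thresholds()
) -> tuple[EvidenceCode, EvidenceRuleTrace]:
    """Grade the functional evidence for one variant.

    Returns exactly one code: a PS3 at very-strong/strong/moderate/supporting
    strength, or BS3 at strong.  Raises :class:`EvidenceNotAssignable` when
    transactivation-HeLa or stimulated insulin is missing (a silent benign
    call on absent data would be unsafe).
    """
    if panel.ta_hela is None or panel.gsis_stimulated is None:
        raise EvidenceNotAssignable(
            "ta_hela and gsis_stimulated are required for functional evidence"
        )
    ta = panel.ta_hela
    stim = panel.gsis_stimulated
    defect = stim < t.gsis_defect_cutoff

    severe_assays = [
        name
        for name in ("ta_hela", "dna_binding", "protein_expression")
        if getattr(panel, name) is not None and getattr(panel, name) < t.ta_severe
    ]
    inputs = {
        "ta_hela": ta,
        "dna_binding": panel.dna_binding,
        "protein_expression": panel.protein_expression,
        "gsis_stimulated": stim,
        "severe_assays": severe_assays,
    }
    tvals = {
        "ta_severe": t.ta_severe,
        "ta_escalation": t.ta_escalation,
        "min_severe_assays": t.min_severe_assays,
        "gsis_defect_cutoff": t.gsis_defect_cutoff,
    }

    # Bands are evaluated as cascading ceilings in priority order: once the
    # two-severe-assay rule fails, any transactivation below the moderate
    # band's upper edge is a moderate defect (not only [40, 60)) — this keeps
    # the grading monotone in every activity measurement while assigning the
    # identical code wherever the severe rule covers TA < 40.
    if len(severe_assays) >= t.min_severe_assays and defect:
        if t.escalation_enabled and ta < t.ta_escalation:
            code = EvidenceCode("PS3", Strength.VERY_STRONG)
            rule = "PS3_very_strong"
        else:
            code = EvidenceCode("PS3", Strength.STRONG)
            rule = "PS3_strong"
    elif ta < t.ta_moderate_band[1] and defect:
        code = EvidenceCode("PS3", Strength.MODERATE)
        rule = "PS3_moderate"
    elif ta < t.ta_supporting_band[1] and defect:
        code = EvidenceCode("PS3", Strength.SUPPORTING)
        rule = "PS3_supporting"
    else:
        code = EvidenceCode("BS3", Strength.STRONG)
        rule = "BS3_strong_default"
    trace = EvidenceRuleTrace(rule, inputs, tvals, code.to_string())
    return code, trace


def structural_defect_signals(s: StructuralPredictionSet) -> int:
    """Count independent in-silico defect signals (0-3).

    A 'least destabilizing' structure-based outcome is not a defect signal,
    nor are no-defect or not-done outcomes.
    """
    n = 0
    if s.sequence_based is SequencePrediction.DESTABILIZING:
        n += 1
    if s.structure_based is StructurePrediction.HIGHER_DESTABILIZING:
        n += 1
    if s.md_simulation is MDOutcome.DEFECT:
        n += 1
    return n


def assign_structural_evidence(
    s: StructuralPredictionSet,
) -> tuple[Optional[EvidenceCode], EvidenceRuleTrace]:
    """Grade computational/structural evidence: PP3 Strong when all three
    analyses show a defect, PP3 Supporting for one or two, none otherwise."""
    n = structural_defect_signals(s)
    inputs = {
        "sequence_based": s.sequence_based.value,
        "structure_based": s.structure_based.value,
        "md_simulation": s.md_simulation.value,
        "defect_signals": n,
    }
    if n == 3:
        code = EvidenceCode("PP3", Strength.STRONG)
    elif n >= 1:
        code = EvidenceCode("PP3", Strength.SUPPORTING)
    else:
        code = None
    trace = EvidenceRuleTrace(
        "PP3_structural", inputs, {}, code.to_string() if code else None
    )
    return code, trace


def build_evidence_set(
    panel: FunctionalAssayPanel,
    structural: StructuralPredictionSet = StructuralPredictionSet(),
    annotations: AnnotationEvidence = AnnotationEvidence(),
    thresholds: Thresholds = Thresholds(),
) -> tuple[EvidenceSet, list[EvidenceRuleTrace]]:
    """Assemble the full evidence set for one variant.

    The functional code comes from :func:`assign_functional_evidence`; when
    any structural analysis was run, its PP3 verdict replaces an
    annotation-level PP3 (including replacement by nothing when the
    structural analyses found no defect); all other annotation codes pass
    through unchanged at their stated strengths.
    """
    func_code, func_trace = assign_functional_evidence(panel, thresholds)
    struct_code, struct_trace = assign_structural_evidence(structural)

    codes: list[EvidenceCode] = [func_code]
    notes: list[str] = [str(func_trace)]
    traces = [func_trace]

    if structural.any_done:
        traces.append(struct_trace)
        if struct_code is not None:
            codes.append(struct_code)
            notes.append(str(struct_trace))

    for ann in sorted(annotations.codes, key=lambda c: c.code):
        if ann.code == "PP3" and structural.any_done:
            continue  # superseded by the structural verdict
        codes.append(ann)
        notes.append(f"annotation_passthrough -> {ann.to_string()}")

    return EvidenceSet(tuple(codes), tuple(notes)), traces
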
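import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hnf1a_reclass.datatypes import (
    AnnotationEvidence,
    EvidenceCode,
    FunctionalAssayPanel,
    MDOutcome,
    SequencePrediction,
    Strength,
    StructuralPredictionSet,
    StructurePrediction,
    Thresholds,
)
from hnf1a_reclass.evidence import (
    EvidenceNotAssignable,
    assign_functional_evidence,
    assign_structural_evidence,
    build_evidence_set,
)

# Published functional-evidence grades per variant (the two tier-P in-frame
# variants carry the very-strong escalation that yields their printed tier).
EXPECTED_FUNCTIONAL = {
    "p.Lys120Asn": ("PS3", Strength.MODERATE),
    "p.Gln125His": ("PS3", Strength.MODERATE),
    "p.Asn127del": ("PS3", Strength.VERY_STRONG),
    "p.Val134Ile": ("PS3", Strength.STRONG),
    "p.Arg200Trp": ("PS3", Strength.STRONG),
    "p.Arg272His": ("PS3", Strength.STRONG),
    "p.Gly292fs*25": ("PS3", Strength.VERY_STRONG),
    "p.Ala301Thr": ("BS3", Strength.STRONG),
    "p.Thr354Met": ("PS3", Strength.SUPPORTING),
    "p.Ala367Val": ("BS3", Strength.STRONG),
    "p.Pro379Ser": ("PS3", Strength.MODERATE),
    "p.Asp602Asn": ("BS3", Strength.STRONG),
    "p.Leu611Pro": ("PS3", Strength.MODERATE),
    "p.Glu619Lys": ("BS3", Strength.STRONG),
}


class TestFunctionalEvidence:
    def test_all_study_variants_graded_as_published(self, study):
        for fv in study.variants:
            code, trace = assign_functional_evidence(fv.panel)
            expected = EXPECTED_FUNCTIONAL[fv.variant.protein_change]
            assert (code.code, code.strength) == expected, fv.variant.protein_change
            assert trace.result == code.to_string()

    def test_escalation_disabled_demotes_to_strong(self, study):
        t = Thresholds(escalation_enabled=False)
        code, _ = assign_functional_evidence(study.variant("p.Asn127del").panel, t)
        assert (code.code, code.strength) == ("PS3", Strength.STRONG)

    def test_normal_gsis_blocks_moderate_band(self, study):
        # TA 51% but stimulated insulin 11 µg/L: no secretion defect -> BS3
        code, _ = assign_functional_evidence(study.variant("p.Asp602Asn").panel)
        assert code.to_string() == "BS3_Strong"

    def test_wt_like_panel_is_benign_strong(self):
        panel = FunctionalAssayPanel(
            ta_hela=100, ta_ins1=100, dna_binding=100,
            protein_expression=100, nuclear_localization=100,
            gsis_basal=5, gsis_stimulated=45, gsis_gbc=48,
        )
        code, _ = assign_functional_evidence(panel)
        assert code.to_string() == "BS3_Strong"

    def test_missing_required_fields_raise(self):
        with pytest.raises(EvidenceNotAssignable):
            assign_functional_evidence(FunctionalAssayPanel(gsis_stimulated=4))
        with pytest.raises(EvidenceNotAssignable):
            assign_functional_evidence(FunctionalAssayPanel(ta_hela=20))

    def test_single_severe_assay_insufficient_for_strong(self):
        # severe TA alone (other assays normal) grades moderate, not strong
        panel = FunctionalAssayPanel(
            ta_hela=30, dna_binding=90, protein_expression=90,
            gsis_basal=5, gsis_stimulated=3, gsis_gbc=10,
        )
        code, _ = assign_functional_evidence(panel)
        assert (code.code, code.strength) == ("PS3", Strength.MODERATE)

    @staticmethod
    def _rank(code: EvidenceCode) -> int:
        return 0 if code.code == "BS3" else int(code.strength)

    @given(
        ta=st.floats(0, 150), dnab=st.floats(0, 150), expr=st.floats(0, 150),
        stim=st.floats(0, 45),
        field=st.sampled_from(
            ["ta_hela", "dna_binding", "protein_expression", "gsis_stimulated"]
        ),
        frac=st.floats(0.0, 1.0),
    )
    @settings(max_examples=300, deadline=None)
    def test_decreasing_activity_never_moves_toward_benign(
        self, ta, dnab, expr, stim, field, frac
    ):
        base = FunctionalAssayPanel(
            ta_hela=ta, dna_binding=dnab, protein_expression=expr,
            gsis_basal=5, gsis_stimulated=stim, gsis_gbc=stim,
        )
        worse = dataclasses.replace(base, **{field: getattr(base, field) * frac})
        c0, _ = assign_functional_evidence(base)
        c1, _ = assign_functional_evidence(worse)
        assert self._rank(c1) >= self._rank(c0)


class TestStructuralEvidence:
    @pytest.mark.parametrize(
        "seq, struct, md, expected",
        [
            ("destabilizing", "higher_destabilizing", "defect",
             ("PP3", Strength.STRONG)),
            ("destabilizing", "higher_destabilizing", "no_defect",
             ("PP3", Strength.SUPPORTING)),
            ("destabilizing", "least_destabilizing", "not_done",
             ("PP3", Strength.SUPPORTING)),
            ("no_defect", "least_destabilizing", "not_done", None),
            ("not_done", "not_done", "not_done", None),
        ],
    )
    def test_signal_counting(self, seq, struct, md, expected):
        s = StructuralPredictionSet(
            SequencePrediction(seq), StructurePrediction(struct), MDOutcome(md)
        )
        code, _ = assign_structural_evidence(s)
        assert ((code.code, code.strength) if code else None) == expected


class TestBuildEvidenceSet:
    def test_frameshift_with_pvs1(self, study):
        fv = study.variant("p.Gly292fs*25")
        evset, _ = build_evidence_set(fv.panel, fv.structural, fv.annotations)
        assert set(evset.to_strings()) == {"PVS1", "PS3_VeryStrong"}

    def test_benign_panel_keeps_annotations(self, study):
        fv = study.variant("p.Ala301Thr")
        evset, _ = build_evidence_set(fv.panel, fv.structural, fv.annotations)
        assert set(evset.to_strings()) == {"BS3_Strong", "BP4_Strong", "PM1", "PM2"}

    def test_empty_annotations_wt_panel(self):
        panel = FunctionalAssayPanel(ta_hela=100, gsis_basal=5,
                                     gsis_stimulated=45, gsis_gbc=48)
        evset, _ = build_evidence_set(panel)
        assert evset.to_strings() == ["BS3_Strong"]

    def test_structural_verdict_replaces_annotation_pp3(self, study):
        # V134I: structural analyses found no defect, so a prior PP3
        # annotation is dropped rather than passed through
        fv = study.variant("p.Val134Ile")
        evset, _ = build_evidence_set(
            fv.panel, fv.structural, fv.annotations_2015
        )
        assert "PP3" not in {c.code for c in evset}

    def test_annotation_pp3_passes_through_without_structural_data(self, study):
        fv = study.variant("p.Thr354Met")
        evset, _ = build_evidence_set(fv.panel, fv.structural, fv.annotations)
        assert "PP3" in {c.code for c in evset}

    def test_every_code_has_provenance(self, study):
        for fv in study.variants:
            evset, _ = build_evidence_set(fv.panel, fv.structural, fv.annotations)
            assert len(evset.provenance) == len(evset.codes)
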
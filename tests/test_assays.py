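import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import t as tdist

from hnf1a_reclass.assays import (
    DefectFlag,
    TriplicateMeasurement,
    assay_defect_flags,
    gsis_metrics,
    normalize_to_wt,
)
from hnf1a_reclass.datatypes import FunctionalAssayPanel, Thresholds


def pooled_t_oracle(a, b):
    """Closed-form two-sample pooled t-test, written independently of the
    implementation path (textbook formula, df = n1 + n2 - 2)."""
    n1, n2 = len(a), len(b)
    m1, m2 = sum(a) / n1, sum(b) / n2
    s1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    s2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    sp = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    t = (m1 - m2) / math.sqrt(sp * (1 / n1 + 1 / n2))
    return 2 * tdist.sf(abs(t), n1 + n2 - 2)


class TestNormalizeToWt:
    def test_identity_gives_100_percent_p_one(self):
        wt = TriplicateMeasurement((2.0, 2.2, 2.1))
        res = normalize_to_wt(wt, wt)
        assert res.percent_wt == pytest.approx(100.0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_halved_signal_gives_50_percent(self):
        wt = TriplicateMeasurement((2.0, 2.2, 2.1))
        var = TriplicateMeasurement(tuple(v * 0.5 for v in wt.values))
        assert normalize_to_wt(var, wt).percent_wt == pytest.approx(50.0)

    def test_against_closed_form_t_oracle(self):
        # frozen from the textbook pooled-t formula: t = -12.2474, df = 4
        var = TriplicateMeasurement((1.0, 1.2, 1.1))
        wt = TriplicateMeasurement((2.0, 2.2, 2.1))
        res = normalize_to_wt(var, wt)
        assert res.percent_wt == pytest.approx(52.380952, abs=1e-5)
        assert res.p_value == pytest.approx(0.000255217, rel=1e-4)
        assert res.p_value == pytest.approx(pooled_t_oracle(var.values, wt.values))
        assert res.significant

    def test_sd_scaled_by_wt_mean_only(self):
        var = TriplicateMeasurement((1.0, 1.2, 1.1))
        wt = TriplicateMeasurement((2.0, 2.2, 2.1))
        res = normalize_to_wt(var, wt)
        assert res.sd_percent == pytest.approx(100 * var.sd / wt.mean)

    def test_constant_equal_groups_p_one(self):
        m = TriplicateMeasurement((1.0, 1.0, 1.0))
        assert normalize_to_wt(m, m).p_value == 1.0

    def test_zero_wt_mean_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_wt(
                TriplicateMeasurement((1.0, 1.0, 1.0)),
                TriplicateMeasurement((0.0, 0.0, 0.0)),
            )

    @given(
        vals=st.tuples(*[st.floats(0.1, 10)] * 6),
        c=st.floats(0.01, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, vals, c):
        var = TriplicateMeasurement(vals[:3])
        wt = TriplicateMeasurement(vals[3:])
        base = normalize_to_wt(var, wt)
        scaled = normalize_to_wt(
            TriplicateMeasurement(tuple(v * c for v in var.values)),
            TriplicateMeasurement(tuple(v * c for v in wt.values)),
        )
        assert scaled.percent_wt == pytest.approx(base.percent_wt, rel=1e-9)
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-6)

    def test_welch_option_differs_under_unequal_variance(self):
        var = TriplicateMeasurement((1.0, 5.0, 9.0))
        wt = TriplicateMeasurement((2.0, 2.01, 2.02))
        assert normalize_to_wt(var, wt, welch=True).p_value != pytest.approx(
            normalize_to_wt(var, wt).p_value
        )


class TestGsisMetrics:
    @pytest.mark.parametrize(
        "basal, stim, gbc, defect, enhancement",
        [
            (5, 4, 15, True, 11),    # severe secretion defect, GBC rescues
            (8, 45, 48, False, 3),   # WT-like secretion
            (0, 0, 0, True, 0),      # degenerate zero panel
        ],
    )
    def test_examples(self, basal, stim, gbc, defect, enhancement):
        panel = FunctionalAssayPanel(gsis_basal=basal, gsis_stimulated=stim,
                                     gsis_gbc=gbc)
        m = gsis_metrics(panel)
        assert m.secretion_defect is defect
        assert m.gbc_enhancement == pytest.approx(enhancement)

    def test_stimulation_index_missing_when_basal_zero(self):
        m = gsis_metrics(FunctionalAssayPanel(gsis_basal=0, gsis_stimulated=3,
                                              gsis_gbc=5))
        assert m.stimulation_index is None

    def test_stimulation_index_value(self):
        m = gsis_metrics(FunctionalAssayPanel(gsis_basal=5, gsis_stimulated=10,
                                              gsis_gbc=12))
        assert m.stimulation_index == pytest.approx(2.0)

    def test_missing_gsis_field_rejected(self):
        with pytest.raises(ValueError):
            gsis_metrics(FunctionalAssayPanel(gsis_basal=5))

    def test_negative_input_rejected_at_construction(self):
        with pytest.raises(ValueError):
            FunctionalAssayPanel(gsis_basal=-1)

    def test_configurable_defect_cutoff(self):
        panel = FunctionalAssayPanel(gsis_basal=5, gsis_stimulated=10, gsis_gbc=12)
        assert not gsis_metrics(panel).secretion_defect
        assert gsis_metrics(panel, Thresholds(gsis_defect_cutoff=12)).secretion_defect


class TestDefectFlags:
    @pytest.mark.parametrize(
        "field, value, flag",
        [
            ("ta_hela", 18, DefectFlag.SEVERE),
            ("ta_hela", 47, DefectFlag.REDUCED),
            ("ta_hela", 97, DefectFlag.NORMAL),
            ("dna_binding", 38, DefectFlag.SEVERE),
            ("dna_binding", 40, DefectFlag.NORMAL),
            ("protein_expression", 21, DefectFlag.SEVERE),
            ("protein_expression", 54, DefectFlag.MARKEDLY_REDUCED),
            ("protein_expression", 66, DefectFlag.REDUCED),
            ("protein_expression", 100, DefectFlag.NORMAL),
            ("nuclear_localization", 57, DefectFlag.REDUCED),
            ("nuclear_localization", 67, DefectFlag.REDUCED),
            ("nuclear_localization", 75, DefectFlag.NORMAL),
        ],
    )
    def test_band_membership(self, field, value, flag):
        panel = FunctionalAssayPanel(**{field: value})
        assert assay_defect_flags(panel)[field] is flag

    @given(value=st.floats(0, 200))
    @settings(max_examples=200, deadline=None)
    def test_bands_partition_every_assay(self, value):
        panel = FunctionalAssayPanel(
            ta_hela=value, ta_ins1=value, dna_binding=value,
            protein_expression=value, nuclear_localization=value,
        )
        flags = assay_defect_flags(panel)
        assert set(flags) == {
            "ta_hela", "ta_ins1", "dna_binding", "protein_expression",
            "nuclear_localization",
        }
        assert all(isinstance(f, DefectFlag) for f in flags.values())

    def test_missing_fields_yield_missing_flags(self):
        flags = assay_defect_flags(FunctionalAssayPanel(ta_hela=50))
        assert list(flags) == ["ta_hela"]

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            assay_defect_flags(FunctionalAssayPanel(gsis_basal=5))
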
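import pytest

from hnf1a_reclass.combiner import CombinerPolicy, classify_variant
from hnf1a_reclass.datatypes import Thresholds
from hnf1a_reclass.fixtures import load_study_fixture


@pytest.fixture(scope="session")
def study():
    """The packaged 14-variant / 20-patient study dataset."""
    return load_study_fixture()


@pytest.fixture(scope="session")
def study_results(study):
    """Default-config classification of every study variant."""
    return {
        fv.variant.protein_change: classify_variant(
            fv.panel, fv.structural, fv.annotations,
            Thresholds(), CombinerPolicy(),
        )
        for fv in study.variants
    }
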
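"""Reporter-assay normalization and GSIS-derived metrics.

Raw luciferase readouts (firefly/renilla ratios) come in independent
triplicates per construct.  Activity is reported as mean percent of the
wild-type construct (WT set to 100%) with the SD scaled the same way, and a
two-tailed unpaired t-test on the raw triplicates decides significance at
alpha = 0.05.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .datatypes import FunctionalAssayPanel, Thresholds


@dataclass(frozen=True)
class TriplicateMeasurement:
    """Raw replicate readouts for one construct (n=3 by design)."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError("at least two replicates required")
        if any(v < 0 for v in self.values):
            raise ValueError("readouts must be non-negative")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class NormalizedActivity:
    percent_wt: float
    sd_percent: float
    p_value: float
    significant: bool


def normalize_to_wt(
    variant: TriplicateMeasurement,
    wt: TriplicateMeasurement,
    alpha: float = 0.05,
    welch: bool = False,
) -> NormalizedActivity:
    """Normalize a variant's triplicate to wild-type = 100%.

    percent_wt = 100 * mean(variant) / mean(wt); the SD is divided by the WT
    mean only (WT uncertainty is not propagated).  The p-value comes from an
    unpaired two-tailed Student t-test on the raw replicates (pooled
    variance, df = 4 at n=3; Welch via ``welch=True``).  Both groups constant
    and equal gives p = 1.0.
    """
    wt_mean = wt.mean
    if wt_mean <= 0:
        raise ValueError("degenerate reference: WT mean must be > 0")
    percent = 100.0 * variant.mean / wt_mean
    sd_percent = 100.0 * variant.sd / wt_mean

    if variant.sd == 0.0 and wt.sd == 0.0:
        p = 1.0 if variant.mean == wt_mean else 0.0
    else:
        res = stats.ttest_ind(variant.values, wt.values, equal_var=not welch)
        p = float(res.pvalue)
        if math.isnan(p):  # zero pooled variance edge cases
            p = 1.0 if variant.mean == wt_mean else 0.0
    return NormalizedActivity(percent, sd_percent, p, bool(p < alpha))


@dataclass(frozen=True)
class GsisMetrics:
    """Derived glucose-stimulated insulin secretion metrics (insulin µg/L)."""

    stimulation_index: Optional[float]  # stimulated / basal; None if basal 0
    gbc_enhancement: float              # glibenclamide-potentiated minus stimulated
    secretion_defect: bool              # stimulated below the defect cut-off


def gsis_metrics(
    panel: FunctionalAssayPanel, thresholds: Thresholds = Thresholds()
) -> GsisMetrics:
    """Compute secretion metrics from a panel's three GSIS conditions."""
    for name in ("gsis_basal", "gsis_stimulated", "gsis_gbc"):
        if getattr(panel, name) is None:
            raise ValueError(f"{name} is required for GSIS metrics")
    basal, stim, gbc = panel.gsis_basal, panel.gsis_stimulated, panel.gsis_gbc
    index = None if basal == 0 else stim / basal
    return GsisMetrics(
        stimulation_index=index,
        gbc_enhancement=gbc - stim,
        secretion_defect=bool(stim < thresholds.gsis_defect_cutoff),
    )


class DefectFlag(enum.Enum):
    SEVERE = "severe"                      # < 40 %WT
    MARKEDLY_REDUCED = "markedly_reduced"  # expression 40-60 %WT
    REDUCED = "reduced"                    # assay-specific intermediate band
    NORMAL = "normal"


def _flag_ta(v: float) -> DefectFlag:
    if v < 40:
        return DefectFlag.SEVERE
    if v < 60:
        return DefectFlag.REDUCED
    return DefectFlag.NORMAL


def _flag_dna_binding(v: float) -> DefectFlag:
    return DefectFlag.SEVERE if v < 40 else DefectFlag.NORMAL


def _flag_expression(v: float) -> DefectFlag:
    if v < 40:
        return DefectFlag.SEVERE
    if v <= 60:
        return DefectFlag.MARKEDLY_REDUCED
    if v <= 75:
        return DefectFlag.REDUCED
    return DefectFlag.NORMAL


def _flag_localization(v: float) -> DefectFlag:
    if v < 40:
        return DefectFlag.SEVERE
    if 57 <= v <= 67:
        return DefectFlag.REDUCED
    return DefectFlag.NORMAL


_FLAGGERS = {
    "ta_hela": _flag_ta,
    "ta_ins1": _flag_ta,
    "dna_binding": _flag_dna_binding,
    "protein_expression": _flag_expression,
    "nuclear_localization": _flag_localization,
}


def assay_defect_flags(panel: FunctionalAssayPanel) -> dict[str, DefectFlag]:
    """Band each present percent-of-WT readout into a defect flag.

    Bands are assay-specific so the published defect groupings are
    reproduced: transactivation severe <40 / reduced 40-60; DNA binding
    severe <40; expression severe <40 / markedly reduced 40-60 / reduced
    60-75 (exclusive/inclusive so that 60 falls in the markedly-reduced
    band); localization reduced on the closed band 57-67.  Each band system
    partitions [0, inf); missing readouts yield no flag.
    """
    flags: dict[str, DefectFlag] = {}
    for name, fn in _FLAGGERS.items():
        v = getattr(panel, name)
        if v is not None:
            flags[name] = fn(v)
    if not flags:
        raise ValueError("no percent-of-WT readouts present")
    return flags
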
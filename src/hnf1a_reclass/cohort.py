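"""Cohort-level summaries: clinical means, tier tallies, defect groups.

Missing clinical values are excluded per column (pairwise deletion); every
summary row therefore reports the n actually used so printed means with
unknown denominators can be audited.  Display rounding is half-up at the
conventional precision: integers for mg/dL analytes, one decimal otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .assays import DefectFlag, assay_defect_flags
from .datatypes import Classification, FunctionalAssayPanel, PatientRecord, Tier


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the clinical-table convention)."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


# parameter -> (units, display decimals)
CLINICAL_PARAMETERS: dict[str, tuple[str, int]] = {
    "age_at_onset": ("years", 1),
    "duration": ("years", 1),
    "bmi": ("kg/m^2", 1),
    "fpg": ("mg/dL", 0),
    "ppg": ("mg/dL", 0),
    "hba1c": ("%", 1),
    "c_peptide_fasting": ("pmol/L", 1),
    "c_peptide_stimulated": ("pmol/L", 1),
    "total_cholesterol": ("mg/dL", 0),
    "triglycerides": ("mg/dL", 0),
    "hdl": ("mg/dL", 0),
    "ldl": ("mg/dL", 0),
}


@dataclass(frozen=True)
class SummaryRow:
    parameter: str
    n_used: int
    mean: Optional[float]       # unrounded
    sd: Optional[float]         # sample SD (n-1); None when n_used < 2
    units: str
    display_mean: Optional[float]  # half-up at the display precision
    display_sd: Optional[float]


def summarize_cohort(records: Sequence[PatientRecord]) -> list[SummaryRow]:
    """One summary row per numeric clinical parameter, missing excluded."""
    if not records:
        raise ValueError("empty cohort")
    rows = []
    for param, (units, dec) in CLINICAL_PARAMETERS.items():
        vals = [getattr(r, param) for r in records]
        present = [v for v in vals if v is not None]
        n = len(present)
        mean = float(np.mean(present)) if n >= 1 else None
        sd = float(np.std(present, ddof=1)) if n >= 2 else None
        rows.append(SummaryRow(
            parameter=param, n_used=n, mean=mean, sd=sd, units=units,
            display_mean=None if mean is None else round_half_up(mean, dec),
            display_sd=None if sd is None else round_half_up(sd, 1),
        ))
    return rows


def summary_frame(rows: Iterable[SummaryRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def _display_percent(pct: float) -> float:
    # two significant figures below 10%, one decimal otherwise
    if pct < 10:
        digits = 2 - int(math.floor(math.log10(pct))) - 1 if pct > 0 else 1
        return round_half_up(pct, digits)
    return round_half_up(pct, 1)


def tier_tally(classifications: Sequence[Classification]) -> dict[str, dict]:
    """Counts and display percentages over the five tiers."""
    if not classifications:
        raise ValueError("no classifications to tally")
    total = len(classifications)
    out: dict[str, dict] = {}
    for tier in Tier:
        count = sum(1 for c in classifications if c.tier is tier)
        out[tier.value] = {
            "count": count,
            "percent": _display_percent(100.0 * count / total) if count else 0.0,
        }
    return out


def _minmax(values: list[float]) -> Optional[tuple[float, float]]:
    return (min(values), max(values)) if values else None


def defect_group_counts(panels: Sequence[FunctionalAssayPanel]) -> dict:
    """Recompute the published assay-defect group sizes and GSIS ranges.

    The DNA-binding severe count is included in the report: the numeric
    <40 %WT rule is applied as stated, even though the narrative count in
    the source differs from its own table (see docs/methods.md).
    """
    if not panels:
        raise ValueError("no panels")
    flags = [assay_defect_flags(p) for p in panels]
    expr = [p.protein_expression for p in panels if p.protein_expression is not None]
    return {
        "ta_severe_count": sum(
            1 for f in flags if f.get("ta_hela") is DefectFlag.SEVERE
        ),
        "dna_binding_severe_count": sum(
            1 for f in flags if f.get("dna_binding") is DefectFlag.SEVERE
        ),
        "expression_below60_count": sum(1 for v in expr if v < 60),
        "expression_reduced_61_75_count": sum(
            1 for f in flags if f.get("protein_expression") is DefectFlag.REDUCED
        ),
        "localization_reduced_count": sum(
            1 for f in flags if f.get("nuclear_localization") is DefectFlag.REDUCED
        ),
        "basal_insulin_range": _minmax(
            [p.gsis_basal for p in panels if p.gsis_basal is not None]
        ),
        "stimulated_insulin_range": _minmax(
            [p.gsis_stimulated for p in panels if p.gsis_stimulated is not None]
        ),
        "gbc_insulin_range": _minmax(
            [p.gsis_gbc for p in panels if p.gsis_gbc is not None]
        ),
    }
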
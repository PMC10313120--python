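"""Readers/writers for the pipeline's TSV/CSV dialect and YAML config.

Variant tables are UTF-8 TSV with a header; missing values are empty fields
(never 0).  Evidence codes serialize as ``CODE`` or ``CODE_Strength``
(e.g. ``PS3_Moderate``), annotation sets as comma-joined code strings.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .combiner import DEFAULT_POINT_VALUES, ClassificationResult, CombinerPolicy
from .datatypes import (
    AnnotationEvidence,
    FunctionalAssayPanel,
    MDOutcome,
    SequencePrediction,
    Strength,
    StructuralPredictionSet,
    StructurePrediction,
    Thresholds,
    Tier,
    VariantId,
)

VARIANT_COLUMNS = [
    "protein_change", "cdna_change",
    "ta_hela", "ta_ins1", "dna_binding", "protein_expression",
    "nuclear_localization", "gsis_basal", "gsis_stimulated", "gsis_gbc",
    "sequence_based", "structure_based", "md_simulation",
    "annotations", "expected_tier", "true_class",
]

PATIENT_COLUMNS = [
    "patient_id", "gender", "protein_change", "age_at_onset", "duration",
    "bmi", "fpg", "ppg", "hba1c", "c_peptide_fasting", "c_peptide_stimulated",
    "total_cholesterol", "triglycerides", "hdl", "ldl",
]


@dataclasses.dataclass(frozen=True)
class VariantRow:
    """One parsed input row of a variant table."""

    variant: VariantId
    panel: FunctionalAssayPanel
    structural: StructuralPredictionSet
    annotations: AnnotationEvidence
    expected_tier: Optional[Tier] = None
    true_class: Optional[str] = None


class TableFormatError(ValueError):
    """A variant/patient table failed validation; message names the row."""


def variant_rows_to_frame(rows: Sequence[VariantRow]) -> pd.DataFrame:
    recs = []
    for r in rows:
        rec = {
            "protein_change": r.variant.protein_change,
            "cdna_change": r.variant.cdna_change,
            **{f: getattr(r.panel, f) for f in
               FunctionalAssayPanel.PERCENT_FIELDS + FunctionalAssayPanel.GSIS_FIELDS},
            "sequence_based": r.structural.sequence_based.value,
            "structure_based": r.structural.structure_based.value,
            "md_simulation": r.structural.md_simulation.value,
            "annotations": ",".join(r.annotations.to_strings()),
            "expected_tier": r.expected_tier.value if r.expected_tier else None,
            "true_class": r.true_class,
        }
        recs.append(rec)
    return pd.DataFrame(recs, columns=VARIANT_COLUMNS)


def write_variant_table(rows: Sequence[VariantRow], path) -> None:
    variant_rows_to_frame(rows).to_csv(path, sep="\t", index=False)


def _opt_float(value, row_no: int, col: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise TableFormatError(f"row {row_no}: non-numeric {col}={value!r}")


def read_variant_table(path) -> list[VariantRow]:
    """Parse a variant TSV; raises :class:`TableFormatError` naming bad rows."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise TableFormatError(f"no variants in {path}")
    missing = {"protein_change"} - set(df.columns)
    if missing:
        raise TableFormatError(f"missing required columns: {sorted(missing)}")
    rows: list[VariantRow] = []
    for i, rec in enumerate(df.to_dict("records"), start=2):  # 1-based + header
        def get(col, default=""):
            v = rec.get(col, default)
            return "" if (v is None or (isinstance(v, float) and pd.isna(v))) else v

        try:
            vid = VariantId(str(get("protein_change")), str(get("cdna_change")))
            panel = FunctionalAssayPanel(**{
                f: _opt_float(get(f), i, f)
                for f in FunctionalAssayPanel.PERCENT_FIELDS
                + FunctionalAssayPanel.GSIS_FIELDS
            })
            structural = StructuralPredictionSet(
                SequencePrediction(get("sequence_based", "not_done") or "not_done"),
                StructurePrediction(get("structure_based", "not_done") or "not_done"),
                MDOutcome(get("md_simulation", "not_done") or "not_done"),
            )
            annotations = AnnotationEvidence.from_strings(
                str(get("annotations")).split(",") if get("annotations") else []
            )
            tier_txt = get("expected_tier")
            expected = Tier(tier_txt) if tier_txt else None
            true_class = str(get("true_class")) or None
        except TableFormatError:
            raise
        except (ValueError, KeyError) as exc:
            raise TableFormatError(f"row {i}: {exc}") from exc
        rows.append(VariantRow(vid, panel, structural, annotations, expected, true_class))
    return rows


def patients_to_frame(patients) -> pd.DataFrame:
    recs = []
    for p in patients:
        rec = {"patient_id": p.patient_id, "gender": p.gender,
               "protein_change": p.variant.protein_change}
        rec.update({f: getattr(p, f) for f in p.NUMERIC_FIELDS})
        recs.append(rec)
    return pd.DataFrame(recs, columns=PATIENT_COLUMNS)


def write_patient_table(patients, path) -> None:
    patients_to_frame(patients).to_csv(path, index=False)


def read_patient_table(path):
    from .datatypes import PatientRecord

    df = pd.read_csv(path, dtype={"patient_id": str, "gender": str})
    if df.empty:
        raise TableFormatError(f"no patients in {path}")
    out = []
    for i, rec in enumerate(df.to_dict("records"), start=2):
        try:
            numeric = {
                f: _opt_float(rec.get(f), i, f) for f in PatientRecord.NUMERIC_FIELDS
            }
            out.append(PatientRecord(
                str(rec["patient_id"]), str(rec["gender"]),
                VariantId(str(rec["protein_change"])), **numeric,
            ))
        except TableFormatError:
            raise
        except (ValueError, KeyError) as exc:
            raise TableFormatError(f"row {i}: {exc}") from exc
    return out


# --------------------------------------------------------------------------
# Configuration round-trip
# --------------------------------------------------------------------------

def config_to_dict(thresholds: Thresholds, policy: CombinerPolicy,
                   seed: int = 0) -> dict:
    return {
        "thresholds": {
            "ta_severe": thresholds.ta_severe,
            "ta_moderate_band": list(thresholds.ta_moderate_band),
            "ta_supporting_band": list(thresholds.ta_supporting_band),
            "ta_escalation": thresholds.ta_escalation,
            "min_severe_assays": thresholds.min_severe_assays,
            "gsis_defect_cutoff": thresholds.gsis_defect_cutoff,
            "alpha": thresholds.alpha,
            "escalation_enabled": thresholds.escalation_enabled,
        },
        "policy": {
            "kind": policy.kind,
            "point_values": {s.name.lower(): v
                             for s, v in policy.point_values.items()},
            "pathogenic_cutoff": policy.pathogenic_cutoff,
            "likely_pathogenic_cutoff": policy.likely_pathogenic_cutoff,
        },
        "seed": seed,
    }


def config_from_dict(d: dict) -> tuple[Thresholds, CombinerPolicy, int]:
    t = d.get("thresholds", {})
    thresholds = Thresholds(
        ta_severe=t.get("ta_severe", 40.0),
        ta_moderate_band=tuple(t.get("ta_moderate_band", (40.0, 60.0))),
        ta_supporting_band=tuple(t.get("ta_supporting_band", (60.0, 65.0))),
        ta_escalation=t.get("ta_escalation", 25.0),
        min_severe_assays=t.get("min_severe_assays", 2),
        gsis_defect_cutoff=t.get("gsis_defect_cutoff", 8.0),
        alpha=t.get("alpha", 0.05),
        escalation_enabled=t.get("escalation_enabled", True),
    )
    p = d.get("policy", {})
    points = {
        Strength[name.upper()]: v
        for name, v in p.get(
            "point_values",
            {s.name.lower(): v for s, v in DEFAULT_POINT_VALUES.items()},
        ).items()
    }
    policy = CombinerPolicy(
        kind=p.get("kind", "points-hybrid"),
        point_values=points,
        pathogenic_cutoff=p.get("pathogenic_cutoff", 10),
        likely_pathogenic_cutoff=p.get("likely_pathogenic_cutoff", 6),
    )
    return thresholds, policy, int(d.get("seed", 0))


def write_config(path, thresholds: Thresholds, policy: CombinerPolicy,
                 seed: int = 0) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(thresholds, policy, seed),
                       sort_keys=False))


def read_config(path) -> tuple[Thresholds, CombinerPolicy, int]:
    return config_from_dict(yaml.safe_load(Path(path).read_text()) or {})


# --------------------------------------------------------------------------
# Classification report
# --------------------------------------------------------------------------

def report_frame(rows: Sequence[VariantRow],
                 results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Per-variant report: tier, points, fired evidence, traces, and the
    expected tier column when the input carried one."""
    recs = []
    for row, res in zip(rows, results):
        cls = res.classification
        recs.append({
            "protein_change": row.variant.protein_change,
            "cdna_change": row.variant.cdna_change,
            "domain": row.variant.domain_location.value,
            "tier": cls.tier.value,
            "pathogenic_points": cls.pathogenic_points,
            "conflict": cls.conflict_flag,
            "evidence": ",".join(res.evidence.to_strings()),
            "expected_tier": row.expected_tier.value if row.expected_tier else "",
            "traces": "; ".join(str(t) for t in res.traces),
        })
    return pd.DataFrame(recs)
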
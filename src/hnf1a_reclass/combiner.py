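"""Evidence combination into the five-tier verdict.

The default policy is a hybrid: pathogenic codes are scored additively with
the Bayesian point values (Supporting 1, Moderate 2, Strong 4, VeryStrong 8;
Pathogenic at >= 10 points, Likely Pathogenic at 6-9), while benign codes are
combined categorically (two strong benign codes -> Benign; one strong plus a
supporting, or two supporting -> Likely Benign).  A benign verdict stands
only when the pathogenic score is below the Likely-Pathogenic cutoff;
benign evidence that neither reaches a benign tier nor is outweighed by a
pathogenic score of >= 10 yields VUS with the conflict flag set.

The classical categorical combining rules are available as an alternative
policy (``kind="categorical-2015"``) for comparison runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .datatypes import (
    AnnotationEvidence,
    Classification,
    EvidenceSet,
    FunctionalAssayPanel,
    Polarity,
    Strength,
    StructuralPredictionSet,
    Thresholds,
    Tier,
)
from .evidence import EvidenceRuleTrace, build_evidence_set

DEFAULT_POINT_VALUES = {
    Strength.SUPPORTING: 1,
    Strength.MODERATE: 2,
    Strength.STRONG: 4,
    Strength.VERY_STRONG: 8,
}


@dataclass(frozen=True)
class CombinerPolicy:
    kind: str = "points-hybrid"   # or "categorical-2015"
    point_values: dict = field(default_factory=lambda: dict(DEFAULT_POINT_VALUES))
    pathogenic_cutoff: int = 10   # points for Pathogenic
    likely_pathogenic_cutoff: int = 6  # points for Likely Pathogenic

    def __post_init__(self) -> None:
        if self.kind not in ("points-hybrid", "categorical-2015"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        vals = [self.point_values[s] for s in Strength]
        if sorted(vals) != vals or len(set(vals)) != len(vals):
            raise ValueError("point values must strictly increase with strength")
        if not 0 < self.likely_pathogenic_cutoff < self.pathogenic_cutoff:
            raise ValueError("cutoffs must satisfy 0 < LP < P")


def _benign_tier(strong: int, supporting: int) -> Tier | None:
    """Categorical benign rules; None when benign evidence is insufficient."""
    if strong >= 2:
        return Tier.BENIGN
    if (strong >= 1 and supporting >= 1) or supporting >= 2:
        return Tier.LIKELY_BENIGN
    return None


def combine(evidence: EvidenceSet, policy: CombinerPolicy = CombinerPolicy()) -> Classification:
    """Combine an evidence set into a five-tier classification."""
    if policy.kind == "categorical-2015":
        return _combine_categorical(evidence)

    points = sum(
        policy.point_values[c.strength]
        for c in evidence
        if c.polarity is Polarity.PATHOGENIC
    )
    benign_codes = [c for c in evidence if c.polarity is Polarity.BENIGN]
    b_strong = sum(1 for c in benign_codes if c.strength >= Strength.STRONG)
    b_supp = sum(1 for c in benign_codes if c.strength < Strength.STRONG)

    tier_b = _benign_tier(b_strong, b_supp)
    conflict = False
    if tier_b is not None and points < policy.likely_pathogenic_cutoff:
        tier = tier_b
    elif benign_codes:
        if points >= policy.pathogenic_cutoff:
            tier = Tier.PATHOGENIC
        else:
            tier = Tier.VUS
        conflict = True
    elif points >= policy.pathogenic_cutoff:
        tier = Tier.PATHOGENIC
    elif points >= policy.likely_pathogenic_cutoff:
        tier = Tier.LIKELY_PATHOGENIC
    else:
        tier = Tier.VUS
    return Classification(tier, points, b_strong, b_supp, conflict)


def _combine_categorical(evidence: EvidenceSet) -> Classification:
    """The classical categorical combining rules, applied to the modulated
    strengths (a PS3 applied at Moderate counts as a moderate code)."""
    path = [c for c in evidence if c.polarity is Polarity.PATHOGENIC]
    vs = sum(1 for c in path if c.strength is Strength.VERY_STRONG)
    s = sum(1 for c in path if c.strength is Strength.STRONG)
    m = sum(1 for c in path if c.strength is Strength.MODERATE)
    p = sum(1 for c in path if c.strength is Strength.SUPPORTING)

    benign = [c for c in evidence if c.polarity is Polarity.BENIGN]
    b_strong = sum(1 for c in benign if c.strength >= Strength.STRONG)
    b_supp = sum(1 for c in benign if c.strength < Strength.STRONG)

    pathogenic = (
        (vs >= 1 and (s >= 1 or m >= 2 or (m == 1 and p == 1) or p >= 2))
        or s >= 2
        or (s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)))
    )
    likely = (
        (vs == 1 and m == 1)
        or (s == 1 and 1 <= m <= 2)
        or (s == 1 and p >= 2)
        or m >= 3
        or (m == 2 and p >= 2)
        or (m == 1 and p >= 4)
    )
    tier_b = _benign_tier(b_strong, b_supp)

    points = sum(DEFAULT_POINT_VALUES[c.strength] for c in path)
    if (pathogenic or likely) and tier_b is not None:
        return Classification(Tier.VUS, points, b_strong, b_supp, True)
    if pathogenic:
        return Classification(Tier.PATHOGENIC, points, b_strong, b_supp)
    if likely:
        return Classification(Tier.LIKELY_PATHOGENIC, points, b_strong, b_supp)
    if tier_b is not None:
        return Classification(tier_b, points, b_strong, b_supp)
    return Classification(Tier.VUS, points, b_strong, b_supp, bool(benign and path))


@dataclass(frozen=True)
class ClassificationResult:
    classification: Classification
    evidence: EvidenceSet
    traces: tuple[EvidenceRuleTrace, ...]


def classify_variant(
    panel: FunctionalAssayPanel,
    structural: StructuralPredictionSet = StructuralPredictionSet(),
    annotations: AnnotationEvidence = AnnotationEvidence(),
    thresholds: Thresholds = Thresholds(),
    policy: CombinerPolicy = CombinerPolicy(),
) -> ClassificationResult:
    """Full per-variant pipeline: evidence assignment then combination."""
    evset, traces = build_evidence_set(panel, structural, annotations, thresholds)
    cls = combine(evset, policy)
    return ClassificationResult(cls, evset, tuple(traces))
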
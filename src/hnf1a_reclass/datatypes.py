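"""Domain types for HNF1A variant re-interpretation.

The HNF1A transcription factor has a dimerization domain (residues 1-33), a
bipartite DNA-binding domain (POU-specific 91-181, an inter-subdomain linker
182-202, POU-homeo 203-281) and a C-terminal transactivation domain (282-631).
Variant effects are quantified as percent of wild-type activity in reporter,
DNA-binding, expression and localization assays, plus glucose-stimulated
insulin secretion (GSIS) in beta-cell lines; the evidence engine turns these
into strength-modulated ACMG/AMP codes.

Missing measurements are represented as ``None`` throughout, never as 0: a
variant with no localization data is different from one that fails to reach
the nucleus at all.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Optional


class ParseError(ValueError):
    """A notation string could not be interpreted."""


# --------------------------------------------------------------------------
# Protein-change notation
# --------------------------------------------------------------------------

_AA3 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}
_AA1 = {v: k for k, v in _AA3.items()}


class ChangeKind(enum.Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    DELETION = "deletion"
    FRAMESHIFT = "frameshift"


@dataclass(frozen=True)
class ProteinChange:
    """Parsed protein-level notation (subset of HGVS used in clinical tables)."""

    ref_residue: str          # one-letter code
    position: int
    alt_residue_or_event: str  # one-letter code, "del", or "fs*N"
    kind: ChangeKind
    three_letter: bool = True  # style of the source string, for round-tripping

    def format(self) -> str:
        """Render back to notation; round-trips parse_protein_change input."""
        if self.three_letter:
            ref = _AA1.get(self.ref_residue, self.ref_residue)
        else:
            ref = self.ref_residue
        if self.kind is ChangeKind.MISSENSE or self.kind is ChangeKind.SYNONYMOUS:
            alt = self.alt_residue_or_event
            if self.three_letter:
                alt = _AA1.get(alt, alt)
            return f"p.{ref}{self.position}{alt}"
        if self.kind is ChangeKind.DELETION:
            return f"p.{ref}{self.position}del"
        return f"p.{ref}{self.position}{self.alt_residue_or_event}"


_PAT = re.compile(
    r"^p\.(?P<ref>[A-Za-z]{3}|[A-Z*])(?P<pos>\d+)"
    r"(?P<rest>[A-Za-z]{3}|[A-Z*]|del|Del|fs\*?\d*)$"
)


def parse_protein_change(notation: str) -> ProteinChange:
    """Parse a protein-change string such as ``p.Lys120Asn`` or ``p.G292fs*25``.

    Accepts three-letter and one-letter residue codes, single-residue
    deletions (``del``) and frameshifts (``fs*N``).  Raises :class:`ParseError`
    naming the offending token otherwise.
    """
    if not isinstance(notation, str) or not notation.startswith("p."):
        raise ParseError(f"protein notation must start with 'p.': {notation!r}")
    m = _PAT.match(notation)
    if not m:
        raise ParseError(f"unparseable protein notation: {notation!r}")
    ref_tok, pos, rest = m.group("ref"), int(m.group("pos")), m.group("rest")
    if pos < 1:
        raise ParseError(f"residue position must be >= 1 in {notation!r}")

    three = len(ref_tok) == 3
    if three:
        if ref_tok not in _AA3:
            raise ParseError(f"unknown residue code {ref_tok!r} in {notation!r}")
        ref = _AA3[ref_tok]
    else:
        ref = ref_tok

    if rest.lower() == "del":
        return ProteinChange(ref, pos, "del", ChangeKind.DELETION, three)
    if rest.lower().startswith("fs"):
        return ProteinChange(ref, pos, rest, ChangeKind.FRAMESHIFT, three)
    if len(rest) == 3:
        if rest not in _AA3:
            raise ParseError(f"unknown residue code {rest!r} in {notation!r}")
        alt = _AA3[rest]
    else:
        alt = rest
    kind = ChangeKind.SYNONYMOUS if alt == ref else ChangeKind.MISSENSE
    return ProteinChange(ref, pos, alt, kind, three)


# --------------------------------------------------------------------------
# Domain map
# --------------------------------------------------------------------------

class Domain(enum.Enum):
    DIMERIZATION = "dimerization"
    LINKER = "linker"
    POU_S = "POU_S"
    DBD_INTERFACE = "DBD_interface"
    POU_H = "POU_H"
    TRANSACTIVATION = "transactivation"


# Inclusive 1-based ranges; totals to a partition of 1..631.
DOMAIN_RANGES: tuple[tuple[int, int, Domain], ...] = (
    (1, 33, Domain.DIMERIZATION),
    (34, 90, Domain.LINKER),
    (91, 181, Domain.POU_S),
    (182, 202, Domain.DBD_INTERFACE),
    (203, 281, Domain.POU_H),
    (282, 631, Domain.TRANSACTIVATION),
)

PROTEIN_LENGTH = 631


def locate_domain(position: int) -> Domain:
    """Map a residue index to its HNF1A domain.

    The DNA-binding region (91-281) splits into POU-specific (91-181), the
    inter-subdomain interface (182-202, e.g. Arg200) and POU-homeo (203-281);
    282-631 is the transactivation domain.  Positions beyond the 631-residue
    protein raise ``ValueError``.
    """
    if position < 1:
        raise ValueError(f"residue position must be >= 1, got {position}")
    if position > PROTEIN_LENGTH:
        raise ValueError(
            f"residue {position} beyond HNF1A length {PROTEIN_LENGTH}"
        )
    for lo, hi, dom in DOMAIN_RANGES:
        if lo <= position <= hi:
            return dom
    raise AssertionError("domain map is total on 1..631")  # pragma: no cover


@dataclass(frozen=True)
class VariantId:
    protein_change: str
    cdna_change: str = ""

    def __post_init__(self) -> None:
        if not self.protein_change:
            raise ValueError("protein_change must be non-empty")

    @property
    def parsed(self) -> ProteinChange:
        return parse_protein_change(self.protein_change)

    @property
    def domain_location(self) -> Domain:
        return locate_domain(self.parsed.position)


# --------------------------------------------------------------------------
# Assay panel and structural predictions
# --------------------------------------------------------------------------

_PERCENT_FIELDS = (
    "ta_hela", "ta_ins1", "dna_binding", "protein_expression",
    "nuclear_localization",
)
_GSIS_FIELDS = ("gsis_basal", "gsis_stimulated", "gsis_gbc")


@dataclass(frozen=True)
class FunctionalAssayPanel:
    """Per-variant functional readouts.

    Percent fields are % of wild-type (WT = 100; values above 100 are
    permitted); GSIS fields are secreted insulin in µg/L at basal 2.8 mM
    glucose, stimulating 16.7 mM glucose, and 16.7 mM plus 100 µM
    glibenclamide.  ``None`` marks a measurement that was not made.
    """

    ta_hela: Optional[float] = None
    ta_ins1: Optional[float] = None
    dna_binding: Optional[float] = None
    protein_expression: Optional[float] = None
    nuclear_localization: Optional[float] = None
    gsis_basal: Optional[float] = None
    gsis_stimulated: Optional[float] = None
    gsis_gbc: Optional[float] = None

    def __post_init__(self) -> None:
        for name in _PERCENT_FIELDS + _GSIS_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    PERCENT_FIELDS = _PERCENT_FIELDS
    GSIS_FIELDS = _GSIS_FIELDS


class SequencePrediction(enum.Enum):
    DESTABILIZING = "destabilizing"
    NO_DEFECT = "no_defect"
    NOT_DONE = "not_done"


class StructurePrediction(enum.Enum):
    HIGHER_DESTABILIZING = "higher_destabilizing"
    LEAST_DESTABILIZING = "least_destabilizing"
    NO_DEFECT = "no_defect"
    NOT_DONE = "not_done"


class MDOutcome(enum.Enum):
    DEFECT = "defect"
    NO_DEFECT = "no_defect"
    NOT_DONE = "not_done"


@dataclass(frozen=True)
class StructuralPredictionSet:
    """Categorical outcomes of the in-silico structural analyses.

    These are consumed as inputs (the conservation, stability and molecular-
    dynamics computations themselves are out of scope); ``NOT_DONE`` is
    distinct from ``NO_DEFECT``.
    """

    sequence_based: SequencePrediction = SequencePrediction.NOT_DONE
    structure_based: StructurePrediction = StructurePrediction.NOT_DONE
    md_simulation: MDOutcome = MDOutcome.NOT_DONE

    @property
    def any_done(self) -> bool:
        return (
            self.sequence_based is not SequencePrediction.NOT_DONE
            or self.structure_based is not StructurePrediction.NOT_DONE
            or self.md_simulation is not MDOutcome.NOT_DONE
        )


# --------------------------------------------------------------------------
# Evidence codes
# --------------------------------------------------------------------------

class Polarity(enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


class Strength(enum.IntEnum):
    SUPPORTING = 1
    MODERATE = 2
    STRONG = 3
    VERY_STRONG = 4

    @property
    def label(self) -> str:
        return {
            Strength.SUPPORTING: "Supporting",
            Strength.MODERATE: "Moderate",
            Strength.STRONG: "Strong",
            Strength.VERY_STRONG: "VeryStrong",
        }[self]


_CANONICAL_STRENGTH = {
    "PVS": Strength.VERY_STRONG,
    "PS": Strength.STRONG,
    "PM": Strength.MODERATE,
    "PP": Strength.SUPPORTING,
    "BA": Strength.VERY_STRONG,
    "BS": Strength.STRONG,
    "BP": Strength.SUPPORTING,
}

_CODE_PAT = re.compile(r"^(PVS|PS|PM|PP|BA|BS|BP)(\d+)$")

_STRENGTH_ALIASES = {
    "verystrong": Strength.VERY_STRONG,
    "very_strong": Strength.VERY_STRONG,
    "strong": Strength.STRONG,
    "moderate": Strength.MODERATE,
    "supporting": Strength.SUPPORTING,
}


def canonical_strength(code: str) -> Strength:
    m = _CODE_PAT.match(code)
    if not m:
        raise ValueError(f"not an ACMG/AMP code identifier: {code!r}")
    return _CANONICAL_STRENGTH[m.group(1)]


@dataclass(frozen=True)
class EvidenceCode:
    """An ACMG/AMP code applied at a (possibly modulated) strength level."""

    code: str
    strength: Strength = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        canon = canonical_strength(self.code)  # validates the identifier
        if self.strength is None:
            object.__setattr__(self, "strength", canon)

    @property
    def polarity(self) -> Polarity:
        return Polarity.PATHOGENIC if self.code[0] == "P" else Polarity.BENIGN

    @property
    def is_modulated(self) -> bool:
        return self.strength is not canonical_strength(self.code)

    def to_string(self) -> str:
        if self.is_modulated or self.code in ("PS3", "BS3"):
            return f"{self.code}_{self.strength.label}"
        return self.code

    @classmethod
    def parse(cls, text: str) -> "EvidenceCode":
        """Parse ``PM2``, ``PS3_Moderate``, ``BP4_Strong`` etc."""
        text = text.strip()
        if "_" in text:
            code, _, qual = text.partition("_")
            key = qual.strip().lower()
            if key not in _STRENGTH_ALIASES:
                raise ValueError(f"unknown strength qualifier {qual!r} in {text!r}")
            return cls(code, _STRENGTH_ALIASES[key])
        return cls(text)


# Codes the pipeline accepts as prior annotation evidence (everything the
# engine itself does not compute).
ANNOTATION_UNIVERSE = frozenset(
    {"PVS1", "PM1", "PM2", "PM5", "PP3", "PP5", "PP6", "BP4"}
)
_FUNCTIONAL_CODES = frozenset({"PS3", "BS3"})


@dataclass(frozen=True)
class AnnotationEvidence:
    """Prior evidence codes from the non-functional ACMG/AMP arms."""

    codes: frozenset[EvidenceCode] = frozenset()

    def __post_init__(self) -> None:
        ids = [c.code for c in self.codes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate code identifiers in annotation set")
        for c in self.codes:
            if c.code in _FUNCTIONAL_CODES:
                raise ValueError(
                    f"{c.code} is assigned by the evidence engine, "
                    "not accepted as prior annotation"
                )
            if not _CODE_PAT.match(c.code):
                raise ValueError(f"unknown evidence code {c.code!r}")

    @classmethod
    def from_strings(cls, texts) -> "AnnotationEvidence":
        return cls(frozenset(EvidenceCode.parse(t) for t in texts if t.strip()))

    def to_strings(self) -> list[str]:
        return sorted(c.to_string() for c in self.codes)


@dataclass(frozen=True)
class EvidenceSet:
    """Evidence codes for one variant plus per-code provenance notes.

    Invariants: code identifiers unique; at most one PS3-family code and at
    most one BS3 code, never both.
    """

    codes: tuple[EvidenceCode, ...]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [c.code for c in self.codes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"conflicting duplicate evidence codes: {dup}")
        if "PS3" in ids and "BS3" in ids:
            raise ValueError("PS3 and BS3 are mutually exclusive")
        if self.provenance and len(self.provenance) != len(self.codes):
            raise ValueError("one provenance note per code required")

    def __iter__(self):
        return iter(self.codes)

    def __len__(self) -> int:
        return len(self.codes)

    def to_strings(self) -> list[str]:
        return [c.to_string() for c in self.codes]


# --------------------------------------------------------------------------
# Classification verdicts
# --------------------------------------------------------------------------

class Tier(enum.Enum):
    PATHOGENIC = "Pathogenic"
    LIKELY_PATHOGENIC = "LikelyPathogenic"
    VUS = "VUS"
    LIKELY_BENIGN = "LikelyBenign"
    BENIGN = "Benign"


@dataclass(frozen=True)
class Classification:
    tier: Tier
    pathogenic_points: int
    benign_strong_count: int = 0
    benign_supporting_count: int = 0
    conflict_flag: bool = False

    def __post_init__(self) -> None:
        if self.pathogenic_points < 0:
            raise ValueError("pathogenic_points must be >= 0")


# --------------------------------------------------------------------------
# Patient records and thresholds
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientRecord:
    """One clinical/biochemical workup row; any numeric field may be None."""

    patient_id: str
    gender: str                       # "M" or "F"
    variant: VariantId
    age_at_onset: Optional[float] = None      # years
    duration: Optional[float] = None          # years of diabetes
    bmi: Optional[float] = None               # kg/m^2
    fpg: Optional[float] = None               # fasting plasma glucose, mg/dL
    ppg: Optional[float] = None               # post-prandial glucose, mg/dL
    hba1c: Optional[float] = None             # %
    c_peptide_fasting: Optional[float] = None     # pmol/L
    c_peptide_stimulated: Optional[float] = None  # pmol/L
    total_cholesterol: Optional[float] = None  # mg/dL
    triglycerides: Optional[float] = None      # mg/dL
    hdl: Optional[float] = None                # mg/dL
    ldl: Optional[float] = None                # mg/dL
    treatment_before: str = ""
    treatment_after: str = ""

    NUMERIC_FIELDS = (
        "age_at_onset", "duration", "bmi", "fpg", "ppg", "hba1c",
        "c_peptide_fasting", "c_peptide_stimulated",
        "total_cholesterol", "triglycerides", "hdl", "ldl",
    )

    def __post_init__(self) -> None:
        if self.gender not in ("M", "F"):
            raise ValueError(f"gender must be 'M' or 'F', got {self.gender!r}")
        for name in self.NUMERIC_FIELDS:
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present, got {v}")


@dataclass(frozen=True)
class Thresholds:
    """Tunable cut-offs of the evidence engine (all in %WT unless noted).

    Defaults encode the published calibration: transactivation below 40%
    marks a severe defect (strong pathogenic evidence when corroborated by a
    second severe assay and defective insulin secretion), 40-60% a moderate
    defect, 60-65% a supporting-level defect; stimulated insulin below
    8 µg/L marks a secretion defect; transactivation below 25% escalates a
    two-assay-severe variant to very-strong functional evidence.
    """

    ta_severe: float = 40.0
    ta_moderate_band: tuple[float, float] = (40.0, 60.0)
    ta_supporting_band: tuple[float, float] = (60.0, 65.0)
    ta_escalation: float = 25.0
    min_severe_assays: int = 2
    gsis_defect_cutoff: float = 8.0   # µg/L stimulated insulin
    alpha: float = 0.05
    escalation_enabled: bool = True

    def __post_init__(self) -> None:
        if not (self.ta_escalation < self.ta_severe
                <= self.ta_moderate_band[0] < self.ta_moderate_band[1]
                <= self.ta_supporting_band[0] < self.ta_supporting_band[1]):
            raise ValueError("threshold bands must be ordered and disjoint")
        if self.min_severe_assays < 1:
            raise ValueError("min_severe_assays must be >= 1")
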
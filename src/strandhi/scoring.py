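"""Health Index (HI) scoring for stranded marine tetrapod necropsy records.

The HI condenses eight necropsy/histopathology parameters into a single
normalized score in [0, 1] (1 = healthy, 0 = every parameter at its worst).
Each parameter contributes ``score x weight``, where the score is an ordinal
0-3 and the weight reflects how critical the finding is for short-term
homeostasis.  Parameters scored by the *number of affected organ systems*
take the highest weight among the systems involved.  The weighted sum is
divided by the taxon-specific maximum achievable sum (``HImax``) and
subtracted from 1:

    HI = 1 - sum_i(score_i * weight_i) / HImax

If any of the eight parameters cannot be assessed, the HI is *not
determinable* — a partial sum would artificially inflate the apparent
health of the animal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Taxon",
    "OrganSystem",
    "Parameter",
    "NecropsyRecord",
    "ScoringScheme",
    "ParameterScore",
    "HIResult",
    "ValidationFinding",
    "SYSTEM_WEIGHT_CLASS",
    "systemic_score_from_count",
    "weight_for_systems",
    "himax",
    "compute_hi",
    "validate_record",
]


class Taxon(str, enum.Enum):
    """The three zoological classes covered by beach-monitoring necropsies."""

    SEABIRD = "seabird"
    MARINE_MAMMAL = "marine_mammal"
    SEA_TURTLE = "sea_turtle"


class OrganSystem(str, enum.Enum):
    """The ten organ systems recorded in standard necropsy protocols."""

    INTEGUMENTARY = "integumentary"
    CARDIOVASCULAR = "cardiovascular"
    NERVOUS = "nervous"
    RESPIRATORY = "respiratory"
    DIGESTIVE = "digestive"
    URINARY = "urinary"
    LYMPHO_HEMATOPOIETIC = "lympho_hematopoietic"
    ENDOCRINE = "endocrine"
    MUSCULOSKELETAL = "musculoskeletal"
    REPRODUCTIVE = "reproductive"


#: Importance of each system for short-term homeostasis.  Class-3 systems
#: (nervous, endocrine, cardiovascular) carry the heaviest weight when a
#: systemic parameter involves them.  Integumentary is class 1: skin disease
#: is already captured by the dedicated cutaneous-injuries parameter.
SYSTEM_WEIGHT_CLASS: Mapping[OrganSystem, int] = {
    OrganSystem.REPRODUCTIVE: 1,
    OrganSystem.MUSCULOSKELETAL: 1,
    OrganSystem.LYMPHO_HEMATOPOIETIC: 1,
    OrganSystem.INTEGUMENTARY: 1,
    OrganSystem.DIGESTIVE: 2,
    OrganSystem.RESPIRATORY: 2,
    OrganSystem.URINARY: 2,
    OrganSystem.NERVOUS: 3,
    OrganSystem.ENDOCRINE: 3,
    OrganSystem.CARDIOVASCULAR: 3,
}


class Parameter(str, enum.Enum):
    """The eight HI parameters, in necropsy-protocol order."""

    BODY = "body"
    SYSTEMIC_MACRO = "systemic_macro"
    CUTANEOUS = "cutaneous"
    ORGANIZED = "organized"
    SYSTEMIC_HISTO = "systemic_histo"
    PARASITOSIS = "parasitosis"
    LYMPHOID_DEPLETION = "lymphoid_depletion"
    THYROID = "thyroid"


#: Parameters whose raw observation is a set of affected organ systems.
SYSTEM_PARAMETERS = (
    Parameter.SYSTEMIC_MACRO,
    Parameter.ORGANIZED,
    Parameter.SYSTEMIC_HISTO,
)

MAX_SCORE = 3
N_SYSTEMS = len(OrganSystem)


@dataclass(frozen=True)
class NecropsyRecord:
    """One animal's raw HI observations.

    Ordinal scores are integers 0-3 or ``None`` (not assessed).  The three
    systemic parameters are recorded as sets of affected :class:`OrganSystem`
    or ``None``.  ``carcass_code`` is the decomposition stage (2 = fresh);
    it is carried for filtering but does not enter the score.
    """

    record_id: str
    taxon: Taxon
    species: str = ""
    carcass_code: int = 2
    body_score: Optional[int] = None
    systems_macro: Optional[frozenset] = None
    cutaneous_score: Optional[int] = None
    systems_organized: Optional[frozenset] = None
    systems_histo: Optional[frozenset] = None
    parasitosis_score: Optional[int] = None
    lymphoid_depletion_score: Optional[int] = None
    thyroid_score: Optional[int] = None

    def __post_init__(self):
        for name in ("systems_macro", "systems_organized", "systems_histo"):
            value = getattr(self, name)
            if value is not None and not isinstance(value, frozenset):
                object.__setattr__(self, name, frozenset(value))


@dataclass(frozen=True)
class ScoringScheme:
    """Weight tables and taxon-specific maxima.

    Two variants are supported.  ``paper_consistent`` (the default) gives the
    organized-lesions parameter the same system-dependent weights (1-3) as
    the two systemic-conditions parameters, which yields maxima of 48 for
    seabirds/marine mammals and 51 for sea turtles.  ``literal_weights``
    fixes the organized-lesions weight at 1, yielding maxima 42/45.
    """

    variant: str = "paper_consistent"
    body_weight_by_taxon: Mapping[Taxon, int] = field(
        default_factory=lambda: {
            Taxon.SEABIRD: 1,
            Taxon.MARINE_MAMMAL: 1,
            Taxon.SEA_TURTLE: 2,
        }
    )
    fixed_weights: Mapping[Parameter, int] = field(
        default_factory=lambda: {
            Parameter.CUTANEOUS: 1,
            Parameter.PARASITOSIS: 1,
            Parameter.LYMPHOID_DEPLETION: 2,
            Parameter.THYROID: 2,
        }
    )
    organized_uses_system_weights: bool = True

    @classmethod
    def paper_consistent(cls) -> "ScoringScheme":
        return cls(variant="paper_consistent", organized_uses_system_weights=True)

    @classmethod
    def literal_weights(cls) -> "ScoringScheme":
        return cls(variant="literal_weights", organized_uses_system_weights=False)

    @classmethod
    def from_name(cls, name: str) -> "ScoringScheme":
        if name in ("paper", "paper_consistent"):
            return cls.paper_consistent()
        if name in ("literal", "literal_weights"):
            return cls.literal_weights()
        raise ValueError(f"unknown scoring scheme {name!r}")

    def max_weight(self, parameter: Parameter, taxon: Taxon) -> int:
        """Largest weight the parameter can take for this taxon."""
        if parameter is Parameter.BODY:
            return self.body_weight_by_taxon[taxon]
        if parameter in (Parameter.SYSTEMIC_MACRO, Parameter.SYSTEMIC_HISTO):
            return max(SYSTEM_WEIGHT_CLASS.values())
        if parameter is Parameter.ORGANIZED:
            return max(SYSTEM_WEIGHT_CLASS.values()) if self.organized_uses_system_weights else 1
        return self.fixed_weights[parameter]


@dataclass(frozen=True)
class ParameterScore:
    """One parameter's contribution: ``value = score x weight``."""

    parameter: Parameter
    score: int
    weight: int

    @property
    def value(self) -> int:
        return self.score * self.weight


@dataclass(frozen=True)
class HIResult:
    """Outcome of scoring one record.

    ``hi`` is present iff ``determinable`` (no missing parameter); otherwise
    ``missing_parameters`` lists the parameters that blocked the index.
    """

    record_id: str
    parameter_values: Sequence[ParameterScore]
    raw_sum: int
    himax: int
    hi: Optional[float]
    determinable: bool
    missing_parameters: Sequence[str]

    def value_of(self, parameter: Parameter) -> int:
        for ps in self.parameter_values:
            if ps.parameter is parameter:
                return ps.value
        raise KeyError(parameter)


@dataclass(frozen=True)
class ValidationFinding:
    """A single problem found in a record: format error or missing datum."""

    kind: str  # "ordinal_out_of_range" | "unknown_system" | "duplicate_system"
    #            | "unknown_taxon" | "missing"
    parameter: Optional[str]
    message: str


def systemic_score_from_count(n_systems: int) -> int:
    """Ordinal 0-3 from the number of affected organ systems.

    0 systems -> 0; 1-3 -> 1; 4-6 -> 2; 7 or more -> 3.
    """
    if not isinstance(n_systems, (int,)) or isinstance(n_systems, bool):
        raise ValueError(f"system count must be an integer, got {n_systems!r}")
    if n_systems < 0 or n_systems > N_SYSTEMS:
        raise ValueError(
            f"system count must be between 0 and {N_SYSTEMS}, got {n_systems}"
        )
    if n_systems == 0:
        return 0
    if n_systems <= 3:
        return 1
    if n_systems <= 6:
        return 2
    return 3


def weight_for_systems(systems: Iterable[OrganSystem]) -> int:
    """Highest weight class among the affected systems (1 for the empty set).

    The empty-set weight is irrelevant in practice: a count of zero forces
    the score, and hence the parameter value, to zero.
    """
    weights = [1]
    for s in systems:
        if not isinstance(s, OrganSystem):
            try:
                s = OrganSystem(s)
            except ValueError:
                raise ValueError(f"unknown organ system {s!r}") from None
        weights.append(SYSTEM_WEIGHT_CLASS[s])
    return max(weights)


def himax(taxon: Taxon, scheme: Optional[ScoringScheme] = None) -> int:
    """Maximum achievable weighted sum for a taxon — the HI denominator.

    48 for seabirds and marine mammals, 51 for sea turtles under the default
    scheme (42/45 under ``literal_weights``).
    """
    scheme = scheme or ScoringScheme.paper_consistent()
    taxon = Taxon(taxon)
    return sum(MAX_SCORE * scheme.max_weight(p, taxon) for p in Parameter)


_ORDINAL_FIELDS = {
    Parameter.BODY: "body_score",
    Parameter.CUTANEOUS: "cutaneous_score",
    Parameter.PARASITOSIS: "parasitosis_score",
    Parameter.LYMPHOID_DEPLETION: "lymphoid_depletion_score",
    Parameter.THYROID: "thyroid_score",
}
_SYSTEM_FIELDS = {
    Parameter.SYSTEMIC_MACRO: "systems_macro",
    Parameter.ORGANIZED: "systems_organized",
    Parameter.SYSTEMIC_HISTO: "systems_histo",
}


def validate_record(record: NecropsyRecord) -> list[ValidationFinding]:
    """Check a record for format errors and missing parameters.

    Returns one finding per violation.  Missing parameters are findings of
    class ``"missing"``: they make the HI indeterminable but are not format
    errors.  A well-formed, complete record returns an empty list.
    """
    findings: list[ValidationFinding] = []
    try:
        Taxon(record.taxon)
    except ValueError:
        findings.append(
            ValidationFinding("unknown_taxon", None, f"unknown taxon {record.taxon!r}")
        )
    for parameter, fieldname in _ORDINAL_FIELDS.items():
        score = getattr(record, fieldname)
        if score is None:
            findings.append(
                ValidationFinding("missing", parameter.value, f"{parameter.value} not assessed")
            )
        elif not isinstance(score, int) or isinstance(score, bool) or not 0 <= score <= 3:
            findings.append(
                ValidationFinding(
                    "ordinal_out_of_range",
                    parameter.value,
                    f"{fieldname}={score!r} outside ordinal range 0-3",
                )
            )
    for parameter, fieldname in _SYSTEM_FIELDS.items():
        systems = getattr(record, fieldname)
        if systems is None:
            findings.append(
                ValidationFinding("missing", parameter.value, f"{parameter.value} not assessed")
            )
            continue
        seen = set()
        for s in systems:
            label = s.value if isinstance(s, OrganSystem) else s
            try:
                OrganSystem(label)
            except ValueError:
                findings.append(
                    ValidationFinding(
                        "unknown_system", parameter.value, f"unknown organ system {label!r}"
                    )
                )
                continue
            if label in seen:
                findings.append(
                    ValidationFinding(
                        "duplicate_system", parameter.value, f"duplicate organ system {label!r}"
                    )
                )
            seen.add(label)
    return findings


def compute_hi(record: NecropsyRecord, scheme: Optional[ScoringScheme] = None) -> HIResult:
    """Score a single necropsy record.

    Raises :class:`ValueError` on format errors (out-of-range ordinals,
    unknown systems or taxon).  Missing parameters do not raise: the result
    comes back with ``determinable=False`` and no ``hi``.
    """
    scheme = scheme or ScoringScheme.paper_consistent()
    findings = validate_record(record)
    errors = [f for f in findings if f.kind != "missing"]
    if errors:
        raise ValueError("; ".join(f.message for f in errors))
    missing = [f.parameter for f in findings if f.kind == "missing"]

    hmax = himax(record.taxon, scheme)
    if missing:
        return HIResult(
            record_id=record.record_id,
            parameter_values=(),
            raw_sum=0,
            himax=hmax,
            hi=None,
            determinable=False,
            missing_parameters=tuple(missing),
        )

    values: list[ParameterScore] = []
    for parameter in Parameter:
        if parameter in _ORDINAL_FIELDS:
            score = getattr(record, _ORDINAL_FIELDS[parameter])
            if parameter is Parameter.BODY:
                weight = scheme.body_weight_by_taxon[Taxon(record.taxon)]
            else:
                weight = scheme.fixed_weights[parameter]
        else:
            systems = getattr(record, _SYSTEM_FIELDS[parameter])
            score = systemic_score_from_count(len(systems))
            if parameter is Parameter.ORGANIZED and not scheme.organized_uses_system_weights:
                weight = 1
            else:
                weight = weight_for_systems(systems)
        values.append(ParameterScore(parameter, score, weight))

    raw_sum = sum(ps.value for ps in values)
    return HIResult(
        record_id=record.record_id,
        parameter_values=tuple(values),
        raw_sum=raw_sum,
        himax=hmax,
        hi=1.0 - raw_sum / hmax,
        determinable=True,
        missing_parameters=(),
    )
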
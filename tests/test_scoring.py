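"""Unit and property tests for the single-record Health Index scoring."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strandhi.scoring import (
    NecropsyRecord,
    OrganSystem,
    Parameter,
    ScoringScheme,
    Taxon,
    compute_hi,
    himax,
    systemic_score_from_count,
    validate_record,
    weight_for_systems,
)

from conftest import SEVEN_SYSTEMS_WITH_W3, make_record, worst_record

# --------------------------------------------------------------------------
# Independent oracle: the HI formula evaluated from scratch with its own
# hard-coded weight tables, never touching the implementation's scheme logic.

ORACLE_SYSTEM_WEIGHT = {
    "reproductive": 1, "musculoskeletal": 1, "lympho_hematopoietic": 1,
    "integumentary": 1,
    "digestive": 2, "respiratory": 2, "urinary": 2,
    "nervous": 3, "endocrine": 3, "cardiovascular": 3,
}


def oracle_count_score(n):
    return [0, 1, 1, 1, 2, 2, 2, 3, 3, 3, 3][n]


def oracle_raw_sum(taxon, body, macro, cutaneous, organized, histo,
                   parasitosis, lymphoid, thyroid, organized_system_weights=True):
    body_w = 2 if taxon == "sea_turtle" else 1
    total = body * body_w

    def set_value(systems, system_weights=True):
        labels = [s.value if isinstance(s, OrganSystem) else s for s in systems]
        weight = max([1] + [ORACLE_SYSTEM_WEIGHT[l] for l in labels]) if system_weights else 1
        return oracle_count_score(len(labels)) * weight

    total += set_value(macro)
    total += cutaneous * 1
    total += set_value(organized, organized_system_weights)
    total += set_value(histo)
    total += parasitosis * 1
    total += lymphoid * 2
    total += thyroid * 2
    return total


def oracle_hi(taxon, scheme_name, **kw):
    organized_sw = scheme_name == "paper_consistent"
    raw = oracle_raw_sum(taxon, organized_system_weights=organized_sw, **kw)
    hmax = {"paper_consistent": {"sea_turtle": 51}.get(taxon, 48),
            "literal_weights": {"sea_turtle": 45}.get(taxon, 42)}[scheme_name]
    return 1.0 - raw / hmax


# --------------------------------------------------------------------------
# Ordinal score from system counts and weight lookup


@pytest.mark.parametrize(
    "count,expected",
    [(0, 0), (1, 1), (2, 1), (3, 1), (4, 2), (5, 2), (6, 2), (7, 3), (8, 3), (10, 3)],
)
def test_systemic_score_bands(count, expected):
    assert systemic_score_from_count(count) == expected


@pytest.mark.parametrize("count", [-1, 11, 100])
def test_systemic_score_rejects_impossible_counts(count):
    with pytest.raises(ValueError):
        systemic_score_from_count(count)


@pytest.mark.parametrize(
    "systems,expected",
    [
        ({OrganSystem.RESPIRATORY, OrganSystem.DIGESTIVE, OrganSystem.NERVOUS}, 3),
        ({OrganSystem.REPRODUCTIVE}, 1),
        (set(), 1),
        ({OrganSystem.DIGESTIVE, OrganSystem.URINARY}, 2),
        ({"cardiovascular"}, 3),
    ],
)
def test_weight_for_systems_takes_highest_class(systems, expected):
    assert weight_for_systems(systems) == expected


def test_weight_for_systems_rejects_unknown_label():
    with pytest.raises(ValueError, match="spleen"):
        weight_for_systems({"spleen"})


# --------------------------------------------------------------------------
# Taxon-specific maxima


@pytest.mark.parametrize(
    "taxon,scheme,expected",
    [
        (Taxon.SEABIRD, "paper_consistent", 48),
        (Taxon.MARINE_MAMMAL, "paper_consistent", 48),
        (Taxon.SEA_TURTLE, "paper_consistent", 51),
        (Taxon.SEABIRD, "literal_weights", 42),
        (Taxon.MARINE_MAMMAL, "literal_weights", 42),
        (Taxon.SEA_TURTLE, "literal_weights", 45),
    ],
)
def test_himax(taxon, scheme, expected):
    assert himax(taxon, ScoringScheme.from_name(scheme)) == expected


@pytest.mark.parametrize("scheme", ["paper_consistent", "literal_weights"])
def test_turtle_maximum_exceeds_seabird_by_body_weight_difference(scheme):
    s = ScoringScheme.from_name(scheme)
    assert himax(Taxon.SEA_TURTLE, s) - himax(Taxon.SEABIRD, s) == 3
    assert himax(Taxon.SEABIRD, s) == himax(Taxon.MARINE_MAMMAL, s)


@pytest.mark.parametrize("taxon", list(Taxon))
@pytest.mark.parametrize("scheme", ["paper_consistent", "literal_weights"])
def test_worst_record_attains_himax_and_hi_zero(taxon, scheme):
    s = ScoringScheme.from_name(scheme)
    result = compute_hi(worst_record(taxon), s)
    assert result.raw_sum == himax(taxon, s)
    assert result.hi == pytest.approx(0.0, abs=1e-9)


# --------------------------------------------------------------------------
# compute_hi: boundary contracts, the worked example, missing data


@pytest.mark.parametrize("taxon", list(Taxon))
def test_all_zero_record_is_perfect_health(taxon):
    result = compute_hi(make_record(taxon=taxon))
    assert result.determinable
    assert result.hi == pytest.approx(1.0, abs=1e-9)
    assert result.raw_sum == 0


def test_worked_example_three_systems_including_nervous():
    """One to three affected systems scores 1; nervous pins the weight at 3;
    the parameter contributes 1 x 3 = 3 and a seabird's HI is 1 - 3/48."""
    record = make_record(
        systems_macro={OrganSystem.RESPIRATORY, OrganSystem.DIGESTIVE, OrganSystem.NERVOUS}
    )
    result = compute_hi(record)
    assert result.value_of(Parameter.SYSTEMIC_MACRO) == 3
    assert result.hi == pytest.approx(1.0 - 3.0 / 48.0, abs=1e-9)


@pytest.mark.parametrize(
    "missing_field,parameter",
    [
        ("thyroid_score", "thyroid"),
        ("body_score", "body"),
        ("systems_histo", "systemic_histo"),
    ],
)
def test_missing_parameter_makes_hi_indeterminable(missing_field, parameter):
    record = make_record(**{missing_field: None})
    result = compute_hi(record)
    assert not result.determinable
    assert result.hi is None
    assert parameter in result.missing_parameters


def test_out_of_range_ordinal_raises():
    with pytest.raises(ValueError, match="0-3"):
        compute_hi(make_record(body_score=5))


def test_body_weight_doubles_for_sea_turtles():
    bird = compute_hi(make_record(taxon=Taxon.SEABIRD, body_score=2))
    turtle = compute_hi(make_record(taxon=Taxon.SEA_TURTLE, body_score=2))
    assert bird.value_of(Parameter.BODY) == 2
    assert turtle.value_of(Parameter.BODY) == 4


def test_organized_weight_depends_on_scheme_variant():
    record = make_record(systems_organized={OrganSystem.NERVOUS})
    default = compute_hi(record, ScoringScheme.paper_consistent())
    literal = compute_hi(record, ScoringScheme.literal_weights())
    assert default.value_of(Parameter.ORGANIZED) == 3  # score 1 x system weight 3
    assert literal.value_of(Parameter.ORGANIZED) == 1  # score 1 x fixed weight 1


# --------------------------------------------------------------------------
# Oracle equivalence over a structured grid of records

SMALL_SETS = [
    frozenset(),
    frozenset({OrganSystem.REPRODUCTIVE}),
    frozenset({OrganSystem.NERVOUS}),
    frozenset({OrganSystem.DIGESTIVE, OrganSystem.URINARY}),
    frozenset({OrganSystem.RESPIRATORY, OrganSystem.DIGESTIVE, OrganSystem.NERVOUS}),
    frozenset({OrganSystem.MUSCULOSKELETAL, OrganSystem.LYMPHO_HEMATOPOIETIC,
               OrganSystem.INTEGUMENTARY}),
]


@pytest.mark.parametrize("scheme", ["paper_consistent", "literal_weights"])
@pytest.mark.parametrize("taxon", [Taxon.SEABIRD, Taxon.SEA_TURTLE])
def test_compute_hi_matches_brute_force_oracle(taxon, scheme):
    s = ScoringScheme.from_name(scheme)
    for body, cut, para, lymph, thy in itertools.product(range(4), repeat=5):
        for macro, organized, histo in itertools.product(SMALL_SETS[:3], SMALL_SETS[3:],
                                                         SMALL_SETS[::2]):
            record = make_record(
                taxon=taxon, body_score=body, cutaneous_score=cut,
                parasitosis_score=para, lymphoid_depletion_score=lymph,
                thyroid_score=thy, systems_macro=macro,
                systems_organized=organized, systems_histo=histo,
            )
            expected = oracle_hi(
                taxon.value, scheme, body=body, macro=macro, cutaneous=cut,
                organized=organized, histo=histo, parasitosis=para,
                lymphoid=lymph, thyroid=thy,
            )
            assert compute_hi(record, s).hi == pytest.approx(expected, abs=1e-9)


def test_himax_is_attained_maximum_over_enumerated_records():
    """Brute-force maximization over a spanning record space recovers HImax."""
    for taxon in Taxon:
        for scheme in (ScoringScheme.paper_consistent(), ScoringScheme.literal_weights()):
            best = 0
            for body in range(4):
                for systems in (frozenset(), SEVEN_SYSTEMS_WITH_W3, frozenset(OrganSystem)):
                    record = make_record(
                        taxon=taxon, body_score=body, cutaneous_score=3,
                        parasitosis_score=3, lymphoid_depletion_score=3,
                        thyroid_score=3, systems_macro=systems,
                        systems_organized=systems, systems_histo=systems,
                    )
                    best = max(best, compute_hi(record, scheme).raw_sum)
            assert best == himax(taxon, scheme)


# --------------------------------------------------------------------------
# Monotonicity and range properties

ordinals = st.integers(min_value=0, max_value=3)
system_sets = st.frozensets(st.sampled_from(list(OrganSystem)), max_size=10)


@st.composite
def records(draw):
    return make_record(
        taxon=draw(st.sampled_from(list(Taxon))),
        body_score=draw(ordinals),
        cutaneous_score=draw(ordinals),
        parasitosis_score=draw(ordinals),
        lymphoid_depletion_score=draw(ordinals),
        thyroid_score=draw(ordinals),
        systems_macro=draw(system_sets),
        systems_organized=draw(system_sets),
        systems_histo=draw(system_sets),
    )


@settings(max_examples=200, derandomize=True)
@given(records())
def test_hi_bounded_and_perfect_only_when_all_zero(record):
    result = compute_hi(record)
    assert 0.0 <= result.hi <= 1.0
    assert result.raw_sum <= result.himax
    all_zero = (
        record.body_score == record.cutaneous_score == record.parasitosis_score
        == record.lymphoid_depletion_score == record.thyroid_score == 0
        and not record.systems_macro and not record.systems_organized
        and not record.systems_histo
    )
    assert (result.hi == 1.0) == all_zero


@settings(max_examples=150, derandomize=True)
@given(records(), st.sampled_from(["body_score", "cutaneous_score", "parasitosis_score",
                                   "lymphoid_depletion_score", "thyroid_score"]))
def test_raising_any_ordinal_never_raises_hi(record, field):
    score = getattr(record, field)
    if score == 3:
        return
    bumped = make_record(
        taxon=record.taxon,
        **{
            f: getattr(record, f)
            for f in ("body_score", "cutaneous_score", "parasitosis_score",
                      "lymphoid_depletion_score", "thyroid_score", "systems_macro",
                      "systems_organized", "systems_histo")
        }
        | {field: score + 1},
    )
    assert compute_hi(bumped).hi <= compute_hi(record).hi


@settings(max_examples=150, derandomize=True)
@given(records(), st.sampled_from(["systems_macro", "systems_organized", "systems_histo"]),
       st.sampled_from(list(OrganSystem)))
def test_adding_a_system_never_raises_hi(record, field, system):
    systems = getattr(record, field)
    if system in systems:
        return
    bumped = make_record(
        taxon=record.taxon,
        **{
            f: getattr(record, f)
            for f in ("body_score", "cutaneous_score", "parasitosis_score",
                      "lymphoid_depletion_score", "thyroid_score", "systems_macro",
                      "systems_organized", "systems_histo")
        }
        | {field: systems | {system}},
    )
    assert compute_hi(bumped).hi <= compute_hi(record).hi


# --------------------------------------------------------------------------
# Record validation


def test_validate_complete_record_is_clean(healthy_record):
    assert validate_record(healthy_record) == []


def test_validate_flags_out_of_range_ordinal():
    findings = validate_record(make_record(body_score=5))
    assert len(findings) == 1
    assert findings[0].kind == "ordinal_out_of_range"
    assert findings[0].parameter == "body"


def test_validate_reports_missing_as_nonerror_finding():
    findings = validate_record(make_record(thyroid_score=None))
    assert [(f.kind, f.parameter) for f in findings] == [("missing", "thyroid")]


def test_validate_flags_unknown_taxon_and_system():
    record = NecropsyRecord(
        record_id="x", taxon="walrus", body_score=0, cutaneous_score=0,
        parasitosis_score=0, lymphoid_depletion_score=0, thyroid_score=0,
        systems_macro=frozenset({"spleen"}), systems_organized=frozenset(),
        systems_histo=frozenset(),
    )
    kinds = {f.kind for f in validate_record(record)}
    assert kinds == {"unknown_taxon", "unknown_system"}
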
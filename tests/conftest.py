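import pytest

from strandhi.scoring import NecropsyRecord, OrganSystem, Taxon

ALL_SYSTEMS = frozenset(OrganSystem)

#: Seven systems including every weight-3 system: count >= 7 gives score 3,
#: and the weight-3 membership pins the parameter weight at its maximum.
SEVEN_SYSTEMS_WITH_W3 = frozenset(
    {
        OrganSystem.NERVOUS,
        OrganSystem.ENDOCRINE,
        OrganSystem.CARDIOVASCULAR,
        OrganSystem.DIGESTIVE,
        OrganSystem.RESPIRATORY,
        OrganSystem.URINARY,
        OrganSystem.REPRODUCTIVE,
    }
)


def make_record(taxon=Taxon.SEABIRD, **overrides):
    """A complete, all-healthy record; override individual fields as needed."""
    fields = dict(
        record_id="r1",
        taxon=taxon,
        species="test",
        carcass_code=2,
        body_score=0,
        systems_macro=frozenset(),
        cutaneous_score=0,
        systems_organized=frozenset(),
        systems_histo=frozenset(),
        parasitosis_score=0,
        lymphoid_depletion_score=0,
        thyroid_score=0,
    )
    fields.update(overrides)
    return NecropsyRecord(**fields)


def worst_record(taxon):
    """Every parameter at its maximum: body 3, seven+ systems incl. weight-3
    in all three systemic parameters, all other ordinals 3."""
    return make_record(
        taxon=taxon,
        body_score=3,
        systems_macro=SEVEN_SYSTEMS_WITH_W3,
        systems_organized=SEVEN_SYSTEMS_WITH_W3,
        systems_histo=SEVEN_SYSTEMS_WITH_W3,
        cutaneous_score=3,
        parasitosis_score=3,
        lymphoid_depletion_score=3,
        thyroid_score=3,
    )


@pytest.fixture
def healthy_record():
    return make_record()
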
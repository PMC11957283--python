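"""Score one necropsy record and walk through the arithmetic.

A seabird whose only finding is macroscopic lesions in the respiratory,
digestive and nervous systems: three systems score 1 (the 1-3 band), the
nervous system pins the weight at 3, so the parameter contributes 3 of the
48 available points and the HI is 1 - 3/48.
"""

from strandhi import (
    NecropsyRecord,
    OrganSystem,
    Parameter,
    Taxon,
    compute_hi,
)

record = NecropsyRecord(
    record_id="example-001",
    taxon=Taxon.SEABIRD,
    species="Larus dominicanus",
    carcass_code=2,
    body_score=0,
    systems_macro={OrganSystem.RESPIRATORY, OrganSystem.DIGESTIVE, OrganSystem.NERVOUS},
    cutaneous_score=0,
    systems_organized=frozenset(),
    systems_histo=frozenset(),
    parasitosis_score=0,
    lymphoid_depletion_score=0,
    thyroid_score=0,
)

result = compute_hi(record)
print(f"record {result.record_id}  (HImax = {result.himax})")
for ps in result.parameter_values:
    print(f"  {ps.parameter.value:<20s} score {ps.score} x weight {ps.weight} = {ps.value}")
print(f"raw sum = {result.raw_sum}")
print(f"HI = 1 - {result.raw_sum}/{result.himax} = {result.hi:.4f}")
print("An HI of 1 is a fully healthy animal; this bird loses 3/48 of the scale")
print("to a single three-system macroscopic finding involving the nervous system.")
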
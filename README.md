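# strandhi

A Python library for computing and analysing the **Health Index (HI)** of
stranded marine tetrapods — seabirds, sea turtles and marine mammals —
from necropsy and histopathology findings. It is aimed at stranding-network
veterinarians and population-health analysts who want an objective,
comparable health score per carcass and cohort-level statistics over
thousands of records.

## The index

Eight parameters are scored 0–3 at necropsy/histopathology: body condition,
systemic conditions on macroscopy, cutaneous injuries, organized (old,
resolved) lesions, systemic conditions on histopathology, parasitosis with
tissue lesions, lymphoid depletion, and thyroid alterations. Each score is
multiplied by a weight and the weighted sum is normalized by the
taxon-specific maximum:

```
HI = 1 − Σᵢ scoreᵢ · wᵢ / HImax,        HImax = 48 (seabirds, marine mammals)
                                                 51 (sea turtles)
```

so HI = 1 is a fully healthy animal and HI = 0 has every parameter at its
worst. Parameters scored by the *number of affected organ systems*
(0 systems → 0; 1–3 → 1; 4–6 → 2; ≥7 → 3) take the highest weight class
among the systems involved: 1 for reproductive/musculoskeletal/
lympho-hematopoietic/integumentary, 2 for digestive/respiratory/urinary,
3 for nervous/endocrine/cardiovascular. Body score is the one parameter
weighted by taxon (1 for the fast-metabolism endotherms, 2 for sea
turtles), which is where the 48 vs 51 maxima come from. If any parameter
cannot be assessed the HI is *not determinable* — a partial sum would
artificially flatter the animal. An alternative `literal_weights` scheme
(organized-lesions weight fixed at 1; maxima 42/45) is available; see
`docs/methods.md` for why two variants exist.

On top of single-record scoring the package provides cohort statistics
(per-group n/mean/sd/min/max, Fisher–Pearson g1 skewness, five-category HI
binning, Kruskal–Wallis with Dunn pairwise comparisons against subjective
good/fair/poor ratings, per-parameter contribution profiles by HI
category), a synthetic cohort generator with known latent morbidity for
end-to-end validation, CSV schemas, and a small CLI.

## Worked example

`python examples/score_single_record.py` scores a seabird whose only
finding is macroscopic lesions in the respiratory, digestive and nervous
systems:

```
record example-001  (HImax = 48)
  body                 score 0 x weight 1 = 0
  systemic_macro       score 1 x weight 3 = 3
  cutaneous            score 0 x weight 1 = 0
  ...
raw sum = 3
HI = 1 - 3/48 = 0.9375
```

Three affected systems fall in the 1–3 band (score 1) and the nervous
system carries weight 3, so the parameter contributes 1 × 3 = 3 points and
the HI drops 3/48 below perfect health.

The other examples exercise the cohort layer on simulated data —
`cohort_summaries.py` (per-taxon summaries, negative g1 skewness, HI
category frequencies), `rating_comparison.py` (Kruskal–Wallis H and Dunn
pairwise z against simulated good/fair/poor ratings), and
`parameter_contributions.py` (mean parameter values rising monotonically
toward the worse HI bins).

The same pipeline is available from the shell:

```sh
strandhi simulate --n 2000 --seed 42 --out-records records.csv --out-truth truth.csv
strandhi score --records records.csv --out results.csv        # fresh carcasses only
strandhi summarize --input results.csv --out summary.csv
strandhi compare --input merged.csv --group-column vet_rating --out report.json
```

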
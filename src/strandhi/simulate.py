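"""Synthetic necropsy cohorts with a known latent morbidity structure.

Each simulated animal carries an unobserved morbidity level m in [0, 1]
drawn from a Beta distribution (right-skewed by default: most stranded
animals are moderately ill, few are at the extreme).  Ordinal parameters
arise from m through a cumulative-threshold model with a small
category-shift noise; affected organ systems are included independently
with probability increasing in m.  Subjective veterinarian ratings
("good" / "fair" / "poor") come from thresholding m with a misclassification
probability emulating inter-rater disagreement.  Because the ground truth m
is retained, the scoring and statistics pipeline can be validated
end-to-end: the computed HI should be strongly negatively correlated with
m, and rating groups should separate under a Kruskal-Wallis test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

from .scoring import (
    SYSTEM_WEIGHT_CLASS,
    NecropsyRecord,
    OrganSystem,
    Parameter,
    Taxon,
)

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "VET_CATEGORIES",
    "ordinal_from_latent",
    "simulate_cohort",
    "simulate_vet_ratings",
]

VET_CATEGORIES = ("good", "fair", "poor")

#: Ordinal parameters filled directly from the latent morbidity.
_ORDINAL_PARAMS = (
    Parameter.BODY,
    Parameter.CUTANEOUS,
    Parameter.PARASITOSIS,
    Parameter.LYMPHOID_DEPLETION,
    Parameter.THYROID,
)

_DEFAULT_THRESHOLDS: Mapping[Parameter, Tuple[float, float, float]] = {
    p: (0.25, 0.5, 0.8) for p in _ORDINAL_PARAMS
}


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic stranding cohort.

    Defaults emulate the composition and severity profile of a large
    beach-monitoring cohort: a taxon mix dominated by seabirds and sea
    turtles, right-skewed Beta(2, 5) morbidity (so the HI distribution is
    bounded, centred near 0.7 and left-skewed), cumulative ordinal
    thresholds at 0.25/0.5/0.8 with a 10% adjacent-category noise, and
    per-system inclusion probability rising linearly in morbidity with
    critical (weight-3) systems half as likely to be involved.
    """

    n_animals: int = 2000
    taxon_mix: Mapping[Taxon, float] = field(
        default_factory=lambda: {
            Taxon.SEABIRD: 0.61,
            Taxon.SEA_TURTLE: 0.34,
            Taxon.MARINE_MAMMAL: 0.05,
        }
    )
    shape_a: float = 2.0
    shape_b: float = 5.0
    ordinal_thresholds: Mapping[Parameter, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_THRESHOLDS)
    )
    ordinal_noise: float = 0.1
    system_inclusion_base: float = 1.2
    weight3_factor: float = 0.5
    missing_rate: float = 0.0
    vet_cutpoints: Tuple[float, float] = (0.35, 0.65)
    vet_noise: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be positive")
        total = sum(self.taxon_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"taxon proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.taxon_mix.values()):
            raise ValueError("taxon proportions must be non-negative")
        for p, thr in self.ordinal_thresholds.items():
            _check_thresholds(thr)
        if not 0.0 <= self.ordinal_noise <= 1.0:
            raise ValueError("ordinal_noise must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        c1, c2 = self.vet_cutpoints
        if not 0.0 < c1 < c2 < 1.0:
            raise ValueError("vet cutpoints must be increasing within (0, 1)")
        if not 0.0 <= self.vet_noise <= 1.0:
            raise ValueError("vet_noise must be in [0, 1]")


@dataclass
class SimulatedCohort:
    """Generated records plus the ground truth that produced them."""

    records: list[NecropsyRecord]
    latent_morbidity: dict[str, float]
    vet_rating: dict[str, str]
    config: Optional[SimConfig] = None


def _check_thresholds(thresholds: Sequence[float]) -> None:
    t = tuple(thresholds)
    if len(t) != 3 or not all(0.0 < x < 1.0 for x in t) or not (t[0] < t[1] < t[2]):
        raise ValueError(f"thresholds must be 3 strictly increasing values in (0,1), got {t}")


def ordinal_from_latent(m: float, thresholds: Sequence[float], noise: float,
                        rng: np.random.Generator) -> int:
    """Ordinal 0-3 category of morbidity ``m`` under a cumulative-threshold map.

    The base category is the number of thresholds at or below ``m``.  With
    probability ``noise`` the category shifts one step up or down (equal
    odds); a shift that would leave the 0-3 range is dropped, so boundary
    categories keep the whole shift mass at their base value.
    """
    _check_thresholds(thresholds)
    if noise < 0:
        raise ValueError("noise must be non-negative")
    base = int(sum(m >= t for t in thresholds))
    if noise > 0 and rng.random() < noise:
        shifted = base + (1 if rng.random() < 0.5 else -1)
        if 0 <= shifted <= 3:
            return shifted
    return base


def _sample_systems(m: float, config: SimConfig, rng: np.random.Generator) -> frozenset:
    base_p = config.system_inclusion_base * m
    included = []
    for system in OrganSystem:
        p = base_p * (config.weight3_factor if SYSTEM_WEIGHT_CLASS[system] == 3 else 1.0)
        if rng.random() < min(1.0, max(0.0, p)):
            included.append(system)
    return frozenset(included)


def simulate_cohort(config: Optional[SimConfig] = None,
                    rng: Optional[np.random.Generator] = None) -> SimulatedCohort:
    """Draw a full cohort: records, latent morbidity, and vet ratings.

    All randomness flows through one generator seeded by ``config.seed``
    (unless an explicit ``rng`` is passed), so an identical config yields an
    identical cohort.
    """
    config = config or SimConfig()
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    taxa = list(config.taxon_mix.keys())
    probs = np.array([config.taxon_mix[t] for t in taxa], dtype=float)
    probs = probs / probs.sum()
    taxon_idx = rng.choice(len(taxa), size=config.n_animals, p=probs)
    morbidity = rng.beta(config.shape_a, config.shape_b, size=config.n_animals)

    width = max(6, len(str(config.n_animals)))
    records: list[NecropsyRecord] = []
    latent: dict[str, float] = {}
    for i in range(config.n_animals):
        m = float(morbidity[i])
        record_id = f"sim-{i:0{width}d}"

        ordinals = {
            p: ordinal_from_latent(m, config.ordinal_thresholds[p], config.ordinal_noise, rng)
            for p in _ORDINAL_PARAMS
        }
        systems = {p: _sample_systems(m, config, rng) for p in
                   (Parameter.SYSTEMIC_MACRO, Parameter.ORGANIZED, Parameter.SYSTEMIC_HISTO)}

        fields: dict = {
            "body_score": ordinals[Parameter.BODY],
            "cutaneous_score": ordinals[Parameter.CUTANEOUS],
            "parasitosis_score": ordinals[Parameter.PARASITOSIS],
            "lymphoid_depletion_score": ordinals[Parameter.LYMPHOID_DEPLETION],
            "thyroid_score": ordinals[Parameter.THYROID],
            "systems_macro": systems[Parameter.SYSTEMIC_MACRO],
            "systems_organized": systems[Parameter.ORGANIZED],
            "systems_histo": systems[Parameter.SYSTEMIC_HISTO],
        }
        if config.missing_rate > 0:
            for key in list(fields):
                if rng.random() < config.missing_rate:
                    fields[key] = None

        records.append(
            NecropsyRecord(
                record_id=record_id,
                taxon=taxa[taxon_idx[i]],
                species="simulated",
                carcass_code=2,
                **fields,
            )
        )
        latent[record_id] = m

    cohort = SimulatedCohort(records=records, latent_morbidity=latent,
                             vet_rating={}, config=config)
    simulate_vet_ratings(cohort, config.vet_cutpoints, config.vet_noise, rng)
    return cohort


def simulate_vet_ratings(cohort: SimulatedCohort,
                         cutpoints: Tuple[float, float] = (0.35, 0.65),
                         vet_noise: float = 0.15,
                         rng: Optional[np.random.Generator] = None) -> SimulatedCohort:
    """Assign good/fair/poor ratings by thresholding latent morbidity.

    With probability ``vet_noise`` a rating moves to an adjacent category
    (ties broken equally for "fair"), emulating inter-rater disagreement.
    Updates ``cohort.vet_rating`` in place and returns the cohort.
    """
    c1, c2 = cutpoints
    if not 0.0 < c1 < c2 < 1.0:
        raise ValueError("vet cutpoints must be increasing within (0, 1)")
    if not 0.0 <= vet_noise <= 1.0:
        raise ValueError("vet_noise must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(0)

    for record in cohort.records:
        m = cohort.latent_morbidity[record.record_id]
        idx = 0 if m < c1 else (1 if m < c2 else 2)
        if vet_noise > 0 and rng.random() < vet_noise:
            if idx == 0:
                idx = 1
            elif idx == 2:
                idx = 1
            else:
                idx = 0 if rng.random() < 0.5 else 2
        cohort.vet_rating[record.record_id] = VET_CATEGORIES[idx]
    return cohort
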
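"""Configuration types for simulation and pipeline runs.

All distances are planar metres, all dates ISO calendar dates at day
resolution, all probabilities in [0, 1].
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Sequence


@dataclass(frozen=True)
class HabitatRect:
    """Axis-aligned rectangular habitat extent in metres.

    Real habitat outlines can be supplied as GeoJSON polygons instead
    (see :mod:`plovernet.io`); rectangles are sufficient for all the
    distance and containment logic the analyses need.
    """

    label: str
    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(f"habitat {self.label!r} has empty extent")

    def contains(self, x: float, y: float) -> bool:
        return self.xmin <= x <= self.xmax and self.ymin <= y <= self.ymax

    def overlaps(self, other: "HabitatRect") -> bool:
        return not (
            self.xmax <= other.xmin
            or other.xmax <= self.xmin
            or self.ymax <= other.ymin
            or other.ymax <= self.ymin
        )


#: Default study layout: three non-overlapping habitat blocks, with
#: non-breeding surveys run in saltmarsh and grassland only.
DEFAULT_HABITATS: tuple[HabitatRect, ...] = (
    HabitatRect("saltmarsh", 0.0, 0.0, 1500.0, 1000.0),
    HabitatRect("grassland", 1700.0, 0.0, 3200.0, 1000.0),
    HabitatRect("semi-desert", 3400.0, 0.0, 4900.0, 1000.0),
)

DEFAULT_SURVEYED_HABITATS: tuple[str, ...] = ("saltmarsh", "grassland")


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of the simulated resident population.

    ``pair_bond_attraction`` (q) is the probability that a pair both
    detected in the same survey shares a sampling period, and, given a
    shared period, the probability the two are placed within the
    chain distance of each other.  q = 0 removes any social signal of
    pairing; larger q strengthens the SRI -> pairing relationship.
    """

    n_individuals: int = 120
    sex_ratio_male: float = 0.5
    n_years: int = 4
    first_year: int = 2015
    habitats: Sequence[HabitatRect] = DEFAULT_HABITATS
    ringed_fraction: float = 0.8
    pair_fraction: float = 0.9
    pair_bond_attraction: float = 0.5
    habitat_fidelity: float = 0.9
    position_sd_m: float = 30.0
    pair_colocate_radius_m: float = 12.0
    hotspots_per_habitat: int = 3
    hotspot_sd_m: float = 40.0
    period_locality: float = 0.8
    breed_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        for name in (
            "sex_ratio_male",
            "ringed_fraction",
            "pair_fraction",
            "pair_bond_attraction",
            "habitat_fidelity",
            "breed_prob",
        ):
            _check_prob(name, getattr(self, name))
        if self.position_sd_m < 0 or self.pair_colocate_radius_m < 0:
            raise ValueError("spatial scales must be non-negative")
        if self.hotspots_per_habitat < 1 or self.hotspot_sd_m < 0:
            raise ValueError("invalid hotspot parameters")
        _check_prob("period_locality", self.period_locality)
        habs = list(self.habitats)
        if not habs:
            raise ValueError("at least one habitat required")
        labels = [h.label for h in habs]
        if len(set(labels)) != len(labels):
            raise ValueError("habitat labels must be unique")
        for i, a in enumerate(habs):
            for b in habs[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError(
                        f"habitats {a.label!r} and {b.label!r} overlap"
                    )

    @property
    def years(self) -> list[int]:
        return list(range(self.first_year, self.first_year + self.n_years))


@dataclass(frozen=True)
class SurveyDesign:
    """Sampling effort of the non-breeding surveys.

    The breeding season starts on ``season_start_monthday`` of each year;
    pre-breeding networks drop surveys within ``exclusion_days`` of it.
    Sampling periods are fixed at 10 minutes.
    """

    surveys_per_year: int = 22
    periods_per_survey: int = 6
    period_length_min: int = 10
    detection_prob: float = 0.35
    season_start_monthday: tuple[int, int] = (8, 1)
    exclusion_days: int = 14
    first_survey_monthday: tuple[int, int] = (1, 15)
    last_survey_monthday: tuple[int, int] = (7, 20)
    surveyed_habitats: Sequence[str] = DEFAULT_SURVEYED_HABITATS

    def __post_init__(self) -> None:
        if self.period_length_min != 10:
            raise ValueError("sampling periods are fixed at 10 minutes")
        if self.exclusion_days < 0:
            raise ValueError("exclusion_days must be >= 0")
        if self.surveys_per_year < 1 or self.periods_per_survey < 1:
            raise ValueError("survey counts must be >= 1")
        _check_prob("detection_prob", self.detection_prob)

    def season_start(self, year: int) -> date:
        m, d = self.season_start_monthday
        return date(year, m, d)


@dataclass
class GroundTruth:
    """Effect sizes baked into a simulated dataset.

    ``true_sri_effect`` records the pair co-location probability q used
    when generating sightings (0 means pairing carries no social
    signal); ``dispersal_stay_prob_by_success`` maps previous-nest fate
    to the probability of nesting in the same habitat the next year.
    ``true_pairs`` is filled in by the generator.
    """

    true_sri_effect: float = 0.5
    nest_success_prob: float = 0.6
    dispersal_stay_prob_by_success: dict[bool, float] = field(
        default_factory=lambda: {True: 0.9, False: 0.6}
    )
    true_pairs: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_prob("true_sri_effect", self.true_sri_effect)
        _check_prob("nest_success_prob", self.nest_success_prob)
        for k, v in self.dispersal_stay_prob_by_success.items():
            _check_prob(f"dispersal_stay_prob_by_success[{k}]", v)

    def to_json_dict(self) -> dict:
        return {
            "true_sri_effect": self.true_sri_effect,
            "nest_success_prob": self.nest_success_prob,
            "dispersal_stay_prob_by_success": {
                str(k): v for k, v in self.dispersal_stay_prob_by_success.items()
            },
            "true_pairs": [list(t) for t in self.true_pairs],
        }
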
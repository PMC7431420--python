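"""Synthetic sighting streams and nest records for a resident shorebird.

The generator emulates the data regime of a colour-ringed, socially
monogamous plover population surveyed outside the breeding season:
sparse multi-year sighting streams (most but not all adults ringed, few
repeat sightings per bird), pairs that co-locate during surveys, an
August–December breeding season in a small number of discrete habitats,
and strong habitat fidelity across years.  Effect sizes (pair
co-location, nest success, success-dependent dispersal) are known inputs
so that the downstream analyses can be checked for parameter recovery.

Randomness is driven by one global integer seed expanded into per-stage,
per-year and per-survey substreams, so identical configurations always
reproduce identical tables.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import GroundTruth, PopulationConfig, SurveyDesign

# Substream tags keeping the population / sighting / nest stages independent.
_STREAM_POPULATION = 1
_STREAM_SIGHTINGS = 2
_STREAM_NESTS = 3

SIGHTING_COLUMNS = [
    "individual_id",
    "sex",
    "date",
    "period_id",
    "x",
    "y",
    "habitat",
    "year",
]

NEST_COLUMNS = [
    "nest_id",
    "male_id",
    "female_id",
    "x",
    "y",
    "habitat",
    "laid_date",
    "incubation_end",
    "success",
    "year",
]


@dataclass
class SimulatedData:
    """Bundle of generated tables plus the ground truth that made them."""

    roster: pd.DataFrame
    sightings: pd.DataFrame
    nests: pd.DataFrame
    ground_truth: GroundTruth
    config: PopulationConfig
    design: SurveyDesign


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, stream]))


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Build the individual roster: id, sex, home habitat/centre, partner.

    Sex counts follow ``sex_ratio_male`` up to rounding.  Pairs are
    male–female, formed preferentially within a shared home habitat;
    a bird belongs to at most one pair.  Column ``ringed`` marks the
    birds that can ever appear in the sighting stream.
    """
    rng = _rng(config.seed, _STREAM_POPULATION)
    n = config.n_individuals
    n_males = int(round(n * config.sex_ratio_male))
    sexes = np.array(["M"] * n_males + ["F"] * (n - n_males))

    habs = list(config.habitats)
    hab_idx = rng.integers(0, len(habs), size=n)
    # home ranges cluster around a few foraging hotspots per habitat,
    # which is what produces occasional chance associations
    hotspots = {
        hi: np.column_stack(
            [
                rng.uniform(h.xmin, h.xmax, size=config.hotspots_per_habitat),
                rng.uniform(h.ymin, h.ymax, size=config.hotspots_per_habitat),
            ]
        )
        for hi, h in enumerate(habs)
    }
    home_x = np.empty(n)
    home_y = np.empty(n)
    hotspot_idx = np.empty(n, dtype=int)
    for i, hi in enumerate(hab_idx):
        h = habs[hi]
        k = rng.integers(config.hotspots_per_habitat)
        hotspot_idx[i] = hi * config.hotspots_per_habitat + k
        spot = hotspots[hi][k]
        home_x[i] = np.clip(
            spot[0] + rng.normal(0.0, config.hotspot_sd_m), h.xmin, h.xmax
        )
        home_y[i] = np.clip(
            spot[1] + rng.normal(0.0, config.hotspot_sd_m), h.ymin, h.ymax
        )

    ids = [f"{s}{i + 1:03d}" for i, s in enumerate(sexes)]
    ringed = rng.random(n) < config.ringed_fraction

    roster = pd.DataFrame(
        {
            "individual_id": ids,
            "sex": sexes,
            "habitat": [habs[i].label for i in hab_idx],
            "home_x": home_x,
            "home_y": home_y,
            "hotspot": hotspot_idx,
            "ringed": ringed,
            "partner_id": [""] * n,
        }
    )

    n_pairs = int(round(config.pair_fraction * min(n_males, n - n_males)))
    males = roster.index[roster.sex == "M"].to_numpy()
    females = roster.index[roster.sex == "F"].to_numpy()
    # pair within habitat first, then across habitats for the remainder
    pairs: list[tuple[int, int]] = []
    free_m, free_f = list(males), list(females)
    for h in habs:
        hm = [i for i in free_m if roster.at[i, "habitat"] == h.label]
        hf = [i for i in free_f if roster.at[i, "habitat"] == h.label]
        rng.shuffle(hm)
        rng.shuffle(hf)
        for m, f in zip(hm, hf):
            if len(pairs) >= n_pairs:
                break
            pairs.append((m, f))
            free_m.remove(m)
            free_f.remove(f)
    rng.shuffle(free_m)
    rng.shuffle(free_f)
    while len(pairs) < n_pairs and free_m and free_f:
        pairs.append((free_m.pop(), free_f.pop()))

    for m, f in pairs:
        roster.at[m, "partner_id"] = roster.at[f, "individual_id"]
        roster.at[f, "partner_id"] = roster.at[m, "individual_id"]
    return roster


def _survey_dates(design: SurveyDesign, year: int) -> list[date]:
    m0, d0 = design.first_survey_monthday
    m1, d1 = design.last_survey_monthday
    start = date(year, m0, d0).toordinal()
    end = date(year, m1, d1).toordinal()
    days = np.linspace(start, end, design.surveys_per_year)
    return [date.fromordinal(int(round(d))) for d in days]


def generate_sightings(
    roster: pd.DataFrame,
    design: SurveyDesign,
    config: PopulationConfig,
) -> pd.DataFrame:
    """Simulate the non-breeding sighting stream.

    Each survey visits the surveyed habitats on one day and records each
    ringed resident bird with probability ``detection_prob``, with
    Gaussian spatial noise around its home-range centre.  The observer
    covers one local area per 10-min period, so a bird's period matches
    its hotspot with probability ``period_locality`` (uniform
    otherwise).  Pair members both detected in a survey share a period
    with probability q = ``pair_bond_attraction``, and, given a shared
    period, sit within the pair co-location radius of each other with
    probability q.  A bird appears at most once per sampling period.
    """
    if roster.empty:
        raise ValueError("roster is empty")
    surveyed = set(design.surveyed_habitats)
    candidates = roster[
        roster.ringed & roster.habitat.isin(surveyed)
    ].reset_index(drop=True)

    id_to_row = {r.individual_id: i for i, r in candidates.iterrows()}
    pair_rows = [
        (i, id_to_row[r.partner_id])
        for i, r in candidates.iterrows()
        if r.sex == "M" and r.partner_id in id_to_row
    ]

    q = config.pair_bond_attraction
    rows: list[dict] = []
    root = np.random.SeedSequence([config.seed, _STREAM_SIGHTINGS])
    year_streams = root.spawn(config.n_years)
    for yi, year in enumerate(config.years):
        survey_streams = year_streams[yi].spawn(design.surveys_per_year)
        for day, ss in zip(_survey_dates(design, year), survey_streams):
            rng = np.random.default_rng(ss)
            nc = len(candidates)
            detected = rng.random(nc) < design.detection_prob
            # the observer covers one local area per 10-min period, so a
            # bird's period tracks its hotspot with prob period_locality
            local_period = (
                candidates.hotspot.to_numpy() % design.periods_per_survey
            )
            periods = np.where(
                rng.random(nc) < config.period_locality,
                local_period,
                rng.integers(0, design.periods_per_survey, size=nc),
            )
            x = candidates.home_x.to_numpy() + rng.normal(
                0.0, config.position_sd_m, size=nc
            )
            y = candidates.home_y.to_numpy() + rng.normal(
                0.0, config.position_sd_m, size=nc
            )
            for m, f in pair_rows:
                if not (detected[m] and detected[f]):
                    continue
                if rng.random() < q:
                    periods[f] = periods[m]
                if periods[f] == periods[m] and rng.random() < q:
                    theta = rng.uniform(0.0, 2.0 * np.pi)
                    r = rng.uniform(0.0, config.pair_colocate_radius_m)
                    x[f] = x[m] + r * np.cos(theta)
                    y[f] = y[m] + r * np.sin(theta)
            for i in np.flatnonzero(detected):
                rec = candidates.iloc[i]
                rows.append(
                    {
                        "individual_id": rec.individual_id,
                        "sex": rec.sex,
                        "date": pd.Timestamp(day),
                        "period_id": f"{day.isoformat()}-P{periods[i] + 1:02d}",
                        "x": x[i],
                        "y": y[i],
                        "habitat": rec.habitat,
                        "year": year,
                    }
                )
    return pd.DataFrame(rows, columns=SIGHTING_COLUMNS)


def generate_nests(
    roster: pd.DataFrame,
    config: PopulationConfig,
    ground_truth: GroundTruth,
) -> pd.DataFrame:
    """Simulate nesting attempts of the roster's pairs across years.

    Each pair breeds in a year with probability ``breed_prob`` and makes
    at most one attempt per year (laying late Aug–Nov, incubation ~30 d,
    nest placed uniformly inside the chosen habitat).  The first attempt
    sits in the pair's home habitat with probability ``habitat_fidelity``;
    after a previous-year attempt, the pair stays in the same habitat
    with probability ``dispersal_stay_prob_by_success[prev_success]``.
    ``ground_truth.true_pairs`` is filled with the realised pair-years.
    """
    pairs = roster[(roster.sex == "M") & (roster.partner_id != "")]
    if pairs.empty:
        raise ValueError("roster contains no pairs")
    rng = _rng(config.seed, _STREAM_NESTS)
    habs = {h.label: h for h in config.habitats}
    other = {
        lab: [o for o in habs if o != lab] for lab in habs
    }
    stay = ground_truth.dispersal_stay_prob_by_success

    rows: list[dict] = []
    ground_truth.true_pairs = []
    counters = {year: 0 for year in config.years}
    for rec in pairs.itertuples():
        # habitat of the pair's first attempt: home habitat with fidelity
        if rng.random() < config.habitat_fidelity:
            current = rec.habitat
        else:
            current = other[rec.habitat][rng.integers(len(other[rec.habitat]))]
        prev_success: bool | None = None
        for year in config.years:
            if rng.random() >= config.breed_prob:
                prev_success = None
                continue
            if prev_success is not None:
                if rng.random() >= stay[prev_success]:
                    current = other[current][rng.integers(len(other[current]))]
            h = habs[current]
            laid_doy = int(np.clip(round(rng.normal(259, 18)), 214, 334))
            laid = date(year, 1, 1) + timedelta(days=laid_doy - 1)
            inc_days = max(5, int(round(rng.normal(30, 3))))
            success = bool(rng.random() < ground_truth.nest_success_prob)
            counters[year] += 1
            rows.append(
                {
                    "nest_id": f"N{year}-{counters[year]:03d}",
                    "male_id": rec.individual_id,
                    "female_id": rec.partner_id,
                    "x": rng.uniform(h.xmin, h.xmax),
                    "y": rng.uniform(h.ymin, h.ymax),
                    "habitat": current,
                    "laid_date": pd.Timestamp(laid),
                    "incubation_end": pd.Timestamp(laid + timedelta(days=inc_days)),
                    "success": success,
                    "year": year,
                }
            )
            ground_truth.true_pairs.append(
                (rec.individual_id, rec.partner_id, year)
            )
            prev_success = success
    return pd.DataFrame(rows, columns=NEST_COLUMNS)


def simulate_dataset(
    config: PopulationConfig | None = None,
    design: SurveyDesign | None = None,
    ground_truth: GroundTruth | None = None,
) -> SimulatedData:
    """Generate a full dataset (roster, sightings, nests) in one call."""
    config = config or PopulationConfig()
    design = design or SurveyDesign()
    if ground_truth is None:
        ground_truth = GroundTruth(true_sri_effect=config.pair_bond_attraction)
    roster = generate_population(config)
    sightings = generate_sightings(roster, design, config)
    nests = generate_nests(roster, config, ground_truth)
    return SimulatedData(roster, sightings, nests, ground_truth, config, design)


def null_effect_config(seed: int = 0, **overrides) -> PopulationConfig:
    """Configuration with no social signal of pairing (q = 0)."""
    overrides.setdefault("pair_bond_attraction", 0.0)
    return PopulationConfig(seed=seed, **overrides)
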
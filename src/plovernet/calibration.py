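"""Monte-Carlo calibration of the pairing permutation test.

Simulates many independent datasets, runs the mate-randomisation test
of the SRI -> pair-formation slope on each, and reports the rejection
rate at a given alpha: the type-I error when the generator carries no
social signal of pairing (q = 0), the power when it does.

Calibration datasets are generated so that the permutation test's null
hypothesis — pairing is random among pairs nesting within the same
habitat and season — actually holds when q = 0.  That requires a
single survey season (pairs persist across years, a dyad-level
repeated measure that only the crossed random effects of the full
model absorb) and full habitat fidelity (with fidelity < 1, home and
nest habitat diverge and pairing still tracks home habitat, so the
stated null is false even without any social effect).  The per-dataset
population is deliberately small (44 individuals) so that hundreds of
datasets with hundreds of permutation replicates each stay cheap; the
sampling design otherwise matches the generator defaults.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import analyses, synthetic
from .config import PopulationConfig, SurveyDesign

#: population used for calibration runs — small but otherwise default-like.
#: 60 individuals with full survey effort keeps the male x female grid
#: dense enough that the permutation distribution of the slope is
#: effectively continuous (tiny grids leave large ties, making the
#: doubled two-tailed p overly conservative).
CALIBRATION_KWARGS = dict(
    n_individuals=60,
    n_years=1,
    pair_fraction=0.9,
    habitat_fidelity=1.0,
)
CALIBRATION_DESIGN = SurveyDesign(
    surveys_per_year=22, periods_per_survey=6, detection_prob=0.45
)

#: pair co-location probability used as the "strong effect" condition
STRONG_EFFECT_Q = 0.6


@dataclass
class CalibrationResult:
    rejection_rate: float
    n_datasets: int
    n_failed: int
    p_values: np.ndarray


def pairing_test_pvalue(
    seed: int,
    q: float,
    n_perm: int = 500,
    stratum: tuple[str, ...] = ("year", "habitat"),
) -> float:
    """p-value of the A2 pairing test on one simulated dataset.

    Returns NaN when the dataset is degenerate (no usable grid or an
    unstable observed fit), which callers count as a failed dataset.
    """
    config = PopulationConfig(
        seed=seed, pair_bond_attraction=q, **CALIBRATION_KWARGS
    )
    sim = synthetic.simulate_dataset(config, CALIBRATION_DESIGN)
    try:
        bundle = analyses.build_bundle(sim.sightings, sim.nests)
        result = analyses.pairing_permutation_test(
            bundle, n_perm=n_perm, seed=seed, stratum=stratum
        )
    except (ValueError, RuntimeError):
        return float("nan")
    return result.p_two_tailed


def rejection_rate(
    n_datasets: int,
    q: float,
    alpha: float = 0.05,
    n_perm: int = 500,
    seed: int = 0,
) -> CalibrationResult:
    """Fraction of simulated datasets on which the pairing test rejects.

    Dataset seeds are drawn from ``seed`` so distinct calibration runs
    use independent data; degenerate datasets are excluded from the
    rate (and counted in ``n_failed``).
    """
    # keep derived seeds well inside the 32-bit range
    base = np.random.SeedSequence(seed).generate_state(n_datasets, np.uint32)
    ps = np.array(
        [pairing_test_pvalue(int(s >> 1), q, n_perm=n_perm) for s in base]
    )
    ok = np.isfinite(ps)
    rate = float(np.mean(ps[ok] < alpha)) if ok.any() else float("nan")
    return CalibrationResult(
        rejection_rate=rate,
        n_datasets=int(ok.sum()),
        n_failed=int((~ok).sum()),
        p_values=ps[ok],
    )


def type_one_error(
    n_datasets: int = 100, alpha: float = 0.05, n_perm: int = 500, seed: int = 0
) -> CalibrationResult:
    """Rejection rate with no simulated social signal of pairing (q = 0)."""
    return rejection_rate(n_datasets, q=0.0, alpha=alpha, n_perm=n_perm, seed=seed)


def power_strong_effect(
    n_datasets: int = 50, alpha: float = 0.05, n_perm: int = 500, seed: int = 0
) -> CalibrationResult:
    """Rejection rate under the strong pair co-location condition."""
    return rejection_rate(
        n_datasets, q=STRONG_EFFECT_Q, alpha=alpha, n_perm=n_perm, seed=seed
    )
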
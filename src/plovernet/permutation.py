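"""Randomisation null models and permutation p-values.

Three null schemes, each preserving the sampling structure it
conditions on:

* data-stream: individual identities shuffled across the group slots of
  each 10-min sampling period (group count and sizes per period, and
  each period's set of observed individuals, are conserved);
* mate: female identities shuffled among breeding pairs within a
  stratum (year, or year x habitat), conditioning pairing patterns on
  habitat fidelity;
* nest: the (x, y, laid, incubation end) tuples shuffled jointly among
  nests within year x habitat, conditioning spatial/temporal nesting
  structure on habitat choice.

Two-tailed permutation p-values use the add-one convention (the
observed value counts as one realisation of the null) and, by default,
double the smaller tail probability, capped at 1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .network import GroupAssignment

logger = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    """Observed statistic, its null distribution and the two-tailed p."""

    statistic_name: str
    observed: float
    null_values: np.ndarray
    n_perm: int
    p_two_tailed: float
    seed: int
    n_failed: int = 0

    def summary(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "n_perm": self.n_perm,
            "n_failed": self.n_failed,
            "null_mean": float(np.mean(self.null_values)),
            "null_sd": float(np.std(self.null_values, ddof=1)),
            "p_two_tailed": self.p_two_tailed,
            "seed": self.seed,
        }


def datastream_randomise(
    assignments: Sequence[GroupAssignment],
    rng: np.random.Generator,
) -> list[GroupAssignment]:
    """Shuffle identities across group slots within each sampling period.

    Group sizes and the set of individuals per period are preserved, so
    each individual's sighting frequency and the period-level group
    structure match the observed data exactly.
    """
    out = []
    for ga in assignments:
        ids = sorted(ga.individuals)
        perm = rng.permutation(len(ids))
        shuffled = [ids[i] for i in perm]
        groups = []
        pos = 0
        for g in ga.groups:
            groups.append(frozenset(shuffled[pos : pos + len(g)]))
            pos += len(g)
        out.append(GroupAssignment(period_id=ga.period_id, groups=tuple(groups)))
    return out


def mate_randomise(
    pairs: pd.DataFrame,
    rng: np.random.Generator,
    stratum: Sequence[str] = ("year",),
) -> pd.DataFrame:
    """Permute female identities among pairs within each stratum.

    Male identities and all stratum columns stay fixed; the multiset of
    (female, stratum) combinations is preserved.  Strata of size one
    are no-ops.
    """
    out = pairs.copy()
    for _, idx in out.groupby(list(stratum), sort=True).groups.items():
        idx = np.asarray(idx)
        out.loc[idx, "female_id"] = (
            out.loc[idx, "female_id"].to_numpy()[rng.permutation(len(idx))]
        )
    return out


NEST_SHUFFLE_COLUMNS = ["x", "y", "laid_date", "incubation_end"]


def nest_randomise(
    nests: pd.DataFrame,
    rng: np.random.Generator,
    stratum: Sequence[str] = ("year", "habitat"),
) -> pd.DataFrame:
    """Jointly permute nest locations and timing within each stratum.

    The (x, y, laid_date, incubation_end) tuple moves as one unit, so
    within-stratum distance and overlap multisets are conserved; pair
    identities and success flags stay on their rows.
    """
    out = nests.copy()
    for _, idx in out.groupby(list(stratum), sort=True).groups.items():
        idx = np.asarray(idx)
        vals = out.loc[idx, NEST_SHUFFLE_COLUMNS].to_numpy()
        out.loc[idx, NEST_SHUFFLE_COLUMNS] = vals[rng.permutation(len(idx))]
    return out


def pvalue_two_tailed(
    observed: float,
    null_values: Iterable[float],
    method: str = "doubled",
) -> float:
    """Two-tailed permutation p with the observed value included.

    ``doubled`` (default): p = min(1, 2 * min(p_up, p_down)) with
    p_up = (1 + #{null >= obs}) / (n + 1) and p_down analogous.
    ``deviation``: extremity measured as absolute deviation from the
    null mean, p = (1 + #{|null - m| >= |obs - m|}) / (n + 1).
    """
    if not np.isfinite(observed):
        raise ValueError("observed statistic is not finite")
    nulls = np.asarray(list(null_values), dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null distribution")
    n = nulls.size
    if method == "doubled":
        p_up = (1 + np.sum(nulls >= observed)) / (n + 1)
        p_down = (1 + np.sum(nulls <= observed)) / (n + 1)
        return float(min(1.0, 2.0 * min(p_up, p_down)))
    if method == "deviation":
        m = nulls.mean()
        return float(
            (1 + np.sum(np.abs(nulls - m) >= abs(observed - m))) / (n + 1)
        )
    raise ValueError(f"unknown method {method!r}")


def run_permutation_test(
    statistic_fn: Callable[[object], float],
    randomiser: Callable[[object, np.random.Generator], object],
    data: object,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic_name: str = "statistic",
    method: str = "doubled",
    max_failure_fraction: float = 0.10,
) -> PermutationResult:
    """Permutation test of ``statistic_fn`` under a randomisation scheme.

    The statistic is recomputed on ``n_perm`` independently randomised
    copies of ``data``; each replicate uses its own RNG substream of
    ``seed`` so results do not depend on execution order.  Replicates
    whose statistic fails (exception or non-finite) are dropped with a
    logged count; more than ``max_failure_fraction`` failures aborts,
    as the null distribution would be unreliable.
    """
    observed = float(statistic_fn(data))
    if not np.isfinite(observed):
        raise ValueError("statistic_fn returned non-finite observed value")
    streams = np.random.SeedSequence(seed).spawn(n_perm)
    nulls = []
    n_failed = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        try:
            val = float(statistic_fn(randomiser(data, rng)))
        except Exception as exc:  # noqa: BLE001 - replicate-level guard
            logger.debug("replicate failed: %s", exc)
            val = np.nan
        if np.isfinite(val):
            nulls.append(val)
        else:
            n_failed += 1
    if n_failed > max_failure_fraction * n_perm:
        raise RuntimeError(
            f"{n_failed}/{n_perm} permutation replicates failed; "
            "null distribution unreliable"
        )
    if n_failed:
        logger.warning("%d/%d permutation replicates failed", n_failed, n_perm)
    nulls = np.asarray(nulls)
    return PermutationResult(
        statistic_name=statistic_name,
        observed=observed,
        null_values=nulls,
        n_perm=n_perm,
        p_two_tailed=pvalue_two_tailed(observed, nulls, method=method),
        seed=seed,
        n_failed=n_failed,
    )
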
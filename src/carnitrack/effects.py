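"""Absolute protected-area effect from matched pairs of survey units.

The absolute PA effect for a matched pair is the treated-minus-control
difference in the track index in a given year; positive values mean higher
carnivore density inside the protected area.  Because pairs contribute
unequal numbers of years, the pooled and regional summaries use iterative
random sampling: each of (by default) 1000 iterations draws one year's
difference per pair and takes the median across pairs; the point estimate is
the median of the iteration medians and the 95 % CI its 2.5th/97.5th
percentiles.  Annual effects are tested against zero with one-sample t-tests
under a Bonferroni correction over the years tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class EffectEstimate:
    """Median absolute PA effect with resampled 95 % CI for one stratum."""

    species: str
    stratum: str  # "national", a region name, or a year label
    median_effect: float
    ci_low: float
    ci_high: float
    n_pairs: int
    n_iterations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "stratum": self.stratum,
            "median_effect": self.median_effect,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_pairs": self.n_pairs,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
        }


def pair_differences(
    pairs: pd.DataFrame, observations: pd.DataFrame, species: str
) -> pd.DataFrame:
    """Treated-minus-control index differences per pair and year.

    One row per (pair, year) in which *both* members of the pair have an
    observation of the species.  Pairs with no common observed year are
    dropped (count kept in ``.attrs['n_pairs_dropped']``).
    """
    known = set(observations["species"].unique())
    if species not in known:
        raise ValueError(f"unknown species {species!r}; observed: {sorted(known)}")
    obs = observations.loc[observations["species"] == species, ["unit_id", "year", "index"]]
    merged = (
        pairs[["treated_id", "control_id"]]
        .merge(obs.rename(columns={"unit_id": "treated_id", "index": "index_t"}), on="treated_id")
        .merge(
            obs.rename(columns={"unit_id": "control_id", "index": "index_c"}),
            on=["control_id", "year"],
        )
    )
    merged["delta"] = merged["index_t"] - merged["index_c"]
    merged["species"] = species
    out = merged[["treated_id", "control_id", "year", "species", "delta"]].sort_values(
        ["treated_id", "control_id", "year"], ignore_index=True
    )
    n_dropped = len(pairs) - out.groupby(["treated_id", "control_id"]).ngroups
    if n_dropped:
        logger.info("%d pair(s) had no common observed years and were dropped", n_dropped)
    out.attrs["n_pairs_dropped"] = int(n_dropped)
    return out


def _iteration_medians(diffs: pd.DataFrame, n_iterations: int, rng) -> np.ndarray:
    """Medians across pairs of one randomly drawn year-delta per pair."""
    grouped = diffs.sort_values(["treated_id", "control_id", "year"])
    deltas = grouped["delta"].to_numpy(float)
    sizes = grouped.groupby(["treated_id", "control_id"], sort=True).size().to_numpy()
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    # one uniform year draw per (iteration, pair)
    u = rng.random((n_iterations, len(sizes)))
    idx = offsets[None, :] + (u * sizes[None, :]).astype(np.int64)
    return np.median(deltas[idx], axis=1)


def pooled_median_ci(
    diffs: pd.DataFrame,
    n_iterations: int = 1000,
    seed: int = 0,
    species: str | None = None,
    stratum: str = "national",
) -> EffectEstimate:
    """Median absolute PA effect with a percentile resampling 95 % CI.

    Each iteration samples one year's difference per matched pair (to
    control for unequal numbers of repeated observations across pairs) and
    takes the median across pairs.  The estimate is the median of the
    iteration medians; the CI the 2.5th and 97.5th percentiles.
    """
    n_pairs = diffs.groupby(["treated_id", "control_id"]).ngroups
    if n_pairs < 2:
        raise ValueError("need at least 2 matched pairs with usable years")
    rng = np.random.default_rng(seed)
    med = _iteration_medians(diffs, n_iterations, rng)
    lo, mid, hi = np.percentile(med, [2.5, 50.0, 97.5])
    return EffectEstimate(
        species=species or str(diffs["species"].iloc[0]),
        stratum=stratum,
        median_effect=float(mid),
        ci_low=float(lo),
        ci_high=float(hi),
        n_pairs=int(n_pairs),
        n_iterations=n_iterations,
        seed=seed,
    )


def annual_effects(diffs: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-year mean absolute PA effect tested against zero.

    Years with at least two pair differences get a two-sided one-sample
    t-test; the Bonferroni multiplier is the number of years tested for the
    species.  Years with n <= 10 are flagged (reported separately, as small
    samples).  A zero-variance year is degenerate: p = 1 when the mean is
    exactly 0, otherwise p -> 0; either way the row is flagged.
    """
    rows = []
    for year, grp in diffs.groupby("year", sort=True):
        d = grp["delta"].to_numpy(float)
        if len(d) < 2:
            continue
        degenerate = bool(np.all(d == d[0]))
        if degenerate:
            p_raw = 1.0 if d[0] == 0.0 else 0.0
            t_stat = 0.0 if d[0] == 0.0 else np.inf * np.sign(d[0])
        else:
            t_stat, p_raw = stats.ttest_1samp(d, 0.0)
        rows.append(
            {
                "species": str(grp["species"].iloc[0]),
                "year": int(year),
                "n": int(len(d)),
                "mean_effect": float(d.mean()),
                "median_effect": float(np.median(d)),
                "t_statistic": float(t_stat),
                "p_raw": float(p_raw),
                "small_sample": bool(len(d) <= 10),
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * len(out))
        out["significant"] = out["p_bonferroni"] < alpha
    return out


def regional_estimates(
    diffs: pd.DataFrame,
    region_map: pd.Series,
    n_iterations: int = 1000,
    seed: int = 0,
) -> list:
    """Pooled median effect within each regional cluster.

    ``region_map`` maps unit id -> region label.  A pair whose members fall
    in different regions is assigned to its treated member's region.
    Regions with fewer than 2 pairs are skipped (logged).
    """
    missing = set(diffs["treated_id"]) - set(region_map.index)
    if missing:
        raise KeyError(f"unmapped unit labels: {sorted(missing)[:10]}")
    region = region_map[diffs["treated_id"]].to_numpy()
    out = []
    for i, reg in enumerate(pd.unique(region)):
        sub = diffs[region == reg]
        if sub.groupby(["treated_id", "control_id"]).ngroups < 2:
            logger.info("region %s has < 2 pairs; skipped", reg)
            continue
        out.append(
            pooled_median_ci(
                sub,
                n_iterations=n_iterations,
                seed=seed + i,
                stratum=str(reg),
            )
        )
    return out
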
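"""Protein correlation profiling over density-gradient fractions.

A protein's sedimentation profile is its PAI across the ordered gradient
fractions, divided by its summed PAI so the profile integrates to one.
Proximity to a reference complex is scored with the χ² profile distance

    χ²(x, p) = Σ_i (x_i − p_i)² / p_i

where ``i`` runs over fractions, ``x`` is the protein's normalized
profile and ``p`` the reference profile (the member-median profile of a
reference complex, renormalized).  The reference sits in the denominator,
so the statistic is deliberately asymmetric: deviations are weighted by
where the *reference* has mass.  Fractions where the reference is
(numerically) zero are floored at ``epsilon`` instead of being dropped —
dropping them would reward proteins with mass where the reference has
none.  Distances are computed per biological replicate and combined as
the arithmetic mean; plotting replicate 1 against replicate 2 is the
standard concordance display for this screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import ComplexDefinition
from .quantify import AbundanceMatrix

DEFAULT_EPSILON = 1e-4


class ProfileError(ValueError):
    pass


@dataclass
class ProfileSet:
    """Sum-normalized fraction profiles (rows sum to 1) plus the proteins
    excluded for having no signal anywhere in the gradient."""

    profiles: pd.DataFrame
    excluded: list[str]


def build_profiles(pai_by_fraction: AbundanceMatrix | pd.DataFrame) -> ProfileSet:
    """Normalize per-protein PAIs across fractions into unit-sum profiles.

    Missing PAIs are treated as zero signal (absence from a fraction is
    informative in a gradient, not missing-at-random).  Proteins with zero
    total are excluded and reported.
    """
    values = pai_by_fraction.values if isinstance(pai_by_fraction, AbundanceMatrix) else pai_by_fraction
    if values.shape[1] < 2:
        raise ProfileError("need at least 2 fractions to build profiles")
    filled = values.fillna(0.0)
    totals = filled.sum(axis=1)
    excluded = list(totals.index[totals <= 0])
    kept = filled.loc[totals > 0]
    profiles = kept.div(totals[totals > 0], axis=0)
    return ProfileSet(profiles, excluded)


def reference_profile(
    definition: ComplexDefinition, profiles: pd.DataFrame
) -> tuple[pd.Series, list[str]]:
    """Aggregate member profiles into a reference profile.

    Uses the members of ``definition`` that are present among the profiles
    (the detected-intersection rule), aggregates per fraction with the
    definition's rule, then renormalizes to unit sum.  Returns the profile
    and the members actually used.
    """
    members = [m for m in definition.members if m in profiles.index]
    if not members:
        raise ProfileError(
            f"no member of reference {definition.name!r} detected in the profiles"
        )
    sub = profiles.loc[members]
    if definition.aggregation == "median":
        agg = sub.median(axis=0)
    elif definition.aggregation == "mean":
        agg = sub.mean(axis=0)
    else:  # single
        agg = sub.iloc[0]
    total = agg.sum()
    if total <= 0:
        raise ProfileError(f"reference {definition.name!r} has zero aggregate profile")
    return agg / total, members


def chi2(
    profile: Sequence[float] | pd.Series,
    reference: Sequence[float] | pd.Series,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """χ² distance between a normalized profile and a reference profile."""
    x = np.asarray(profile, dtype=float)
    p = np.asarray(reference, dtype=float)
    if x.shape != p.shape:
        raise ProfileError(
            f"profile grids differ: {x.shape} vs {p.shape}"
        )
    denom = np.maximum(p, epsilon)
    return float(np.sum((x - p) ** 2 / denom))


def pcp_screen(
    replicate_profiles: Mapping[object, pd.DataFrame],
    reference: ComplexDefinition,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """χ² screen of every protein against one reference, per replicate.

    Proteins must be profiled in every replicate to be scored.  The output
    has one ``chi2_<replicate>`` column per replicate, their arithmetic
    mean, and an ascending rank on the mean (rank 1 = closest to the
    reference); it directly supports the replicate-vs-replicate scatter.
    """
    if len(replicate_profiles) < 2:
        raise ProfileError("pcp_screen needs at least 2 replicates")
    reps = sorted(replicate_profiles, key=str)
    common = None
    for rep in reps:
        idx = set(replicate_profiles[rep].index)
        common = idx if common is None else common & idx
    common = sorted(common)
    if not common:
        raise ProfileError("no protein profiled in all replicates")

    per_rep = {}
    for rep in reps:
        profiles = replicate_profiles[rep]
        ref, _ = reference_profile(reference, profiles)
        per_rep[rep] = {
            prot: chi2(profiles.loc[prot], ref, epsilon=epsilon) for prot in common
        }
    out = pd.DataFrame(
        {f"chi2_{rep}": pd.Series(per_rep[rep]) for rep in reps}
    ).loc[common]
    out.insert(len(out.columns), "mean_chi2", out.mean(axis=1))
    means = out["mean_chi2"].to_numpy()
    order = sorted(range(len(common)), key=lambda i: (means[i], common[i]))
    ranks = np.empty(len(common), dtype=int)
    ranks[order] = np.arange(1, len(common) + 1)
    out["rank"] = ranks
    out.index.name = "protein"
    return out.sort_values("rank")
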
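"""Differential regulator association between conditions.

For a regulator complex (19S, PA28αβ, PA28γ, PA200, PI31) the per-sample
abundance index is the arithmetic mean of the PAIs of its proteins.  This
value is divided by the ncP20S abundance in the same sample — ncP20S, the
eleven subunits common to every 20S core particle, represents the total
20S pool, so the ratio is a per-proteasome occupancy that cancels any
global per-sample intensity scale.  Ratios are kept per replicate (never
averaged before comparison, to preserve biological variability), then the
mean ratio of each condition is expressed relative to a reference
condition (set to 1) and compared with a two-sided two-sample Student
t-test on the per-replicate ratios.  Significance tiers follow the usual
0.05 / 0.01 / 0.001 star convention; no multiple-testing correction is
applied by default (a Benjamini–Hochberg option is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ComplexDefinition
from .correlation import build_reference_abundances
from .quantify import AbundanceMatrix


class DifferentialError(ValueError):
    pass


def regulator_pai(
    pai: AbundanceMatrix, definition: ComplexDefinition
) -> tuple[pd.Series, list[str]]:
    """Mean member PAI per sample for one regulator (missing PAIs → 0).

    Returns the per-sample series and the member proteins used.
    """
    members = [m for m in definition.members if m in pai.values.index]
    if not members:
        raise DifferentialError(f"no member of {definition.name!r} detected")
    series = pai.values.loc[members].fillna(0.0).mean(axis=0)
    series.name = definition.name
    return series, members


def normalized_pai(
    regulator: pd.Series, ncp20s: pd.Series
) -> tuple[pd.Series, list[str]]:
    """Per-sample regulator/ncP20S ratio.

    Samples where the ncP20S denominator is zero (or missing) cannot be
    normalized; they are excluded and reported.
    """
    ncp20s = ncp20s.reindex(regulator.index)
    bad = list(regulator.index[(ncp20s <= 0) | ncp20s.isna()])
    kept = [s for s in regulator.index if s not in bad]
    ratio = regulator[kept] / ncp20s[kept]
    return ratio, bad


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def relative_normalized_pai(
    groups: Mapping[str, Sequence[float]],
    reference_condition: str,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Condition means relative to a reference condition, with t-tests.

    ``groups`` maps condition → per-sample normalized PAIs.  Each
    condition's mean is divided by the reference condition's mean (the
    reference is exactly 1); p-values come from a two-sided two-sample
    Student t-test of the condition's ratios against the reference's
    (``equal_var=False`` switches to the Welch variant).  Conditions with
    fewer than two replicates get a ratio but an undefined p-value.
    """
    if reference_condition not in groups:
        raise DifferentialError(
            f"reference condition {reference_condition!r} not among {sorted(groups)}"
        )
    ref = np.asarray(groups[reference_condition], dtype=float)
    if ref.size < 2:
        raise DifferentialError("reference condition needs >= 2 replicates")
    ref_mean = ref.mean()
    if ref_mean == 0:
        raise DifferentialError("reference condition has zero mean normalized PAI")
    rows = []
    for condition in groups:
        vals = np.asarray(groups[condition], dtype=float)
        if condition == reference_condition:
            rel, p = 1.0, 1.0  # a condition never differs from itself
        else:
            rel = float(vals.mean() / ref_mean)
            if vals.size < 2:
                p = np.nan
            else:
                p = float(stats.ttest_ind(vals, ref, equal_var=equal_var).pvalue)
        rows.append(
            {
                "condition": condition,
                "relative_value": rel,
                "n": int(vals.size),
                "p_value": p,
                "significance": _stars(p),
            }
        )
    return pd.DataFrame(rows).set_index("condition")


def differential_analysis(
    pai: AbundanceMatrix,
    metadata: pd.DataFrame,
    regulators: Sequence[ComplexDefinition],
    ncp20s: ComplexDefinition,
    reference_condition: str,
    equal_var: bool = True,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """End-to-end differential association over a sample series.

    ``metadata`` must map every sample to a condition (columns
    ``sample_id`` and ``condition``).  Returns one row per regulator ×
    condition with the relative normalized PAI and its p-value.  With
    ``bh_correct`` the p-values of the non-reference conditions are
    Benjamini–Hochberg adjusted across regulators per condition.
    """
    condition_of = dict(zip(metadata["sample_id"], metadata["condition"]))
    unknown = [s for s in pai.samples if s not in condition_of]
    if unknown:
        raise DifferentialError(f"samples without condition metadata: {unknown}")
    nc_series, _ = regulator_pai(pai, ncp20s)

    frames = []
    for definition in regulators:
        reg_series, members = regulator_pai(pai, definition)
        ratio, excluded = normalized_pai(reg_series, nc_series)
        groups: dict[str, list[float]] = {}
        for sid, value in ratio.items():
            groups.setdefault(condition_of[sid], []).append(float(value))
        result = relative_normalized_pai(groups, reference_condition, equal_var=equal_var)
        result.insert(0, "regulator", definition.name)
        result["n_members"] = len(members)
        result["excluded_samples"] = ";".join(excluded)
        frames.append(result.reset_index())
    out = pd.concat(frames, ignore_index=True)
    if bh_correct:
        mask = (out["condition"] != reference_condition) & out["p_value"].notna()
        for condition, grp in out[mask].groupby("condition"):
            adjusted = _benjamini_hochberg(grp["p_value"].to_numpy())
            out.loc[grp.index, "p_adjusted"] = adjusted
        out.loc[~mask, "p_adjusted"] = np.nan
    return out.set_index(["regulator", "condition"])


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted
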
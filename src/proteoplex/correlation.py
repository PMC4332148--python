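"""Cross-purification correlation of protein abundances.

The AP-MS analogue of correlation profiling: two proteins that always
co-occur in the same complex should have proportional abundances across a
series of affinity purifications from biologically diverse samples.
Association is scored with the Pearson coefficient on raw (untransformed)
PAIs across the purification series; the squared coefficient R² — the
coefficient of determination, more stringent than R itself — is the
reported statistic.  Reference sub-complex abundances are built per
sample from the member PAIs using each definition's aggregation rule.

Missing PAIs become zeros before correlating: with a fixed bait,
non-detection of a prey reflects low co-purification, and
pairwise-complete deletion would bias the correlation upward.

Confidence filtering of putative interactors requires a signed Pearson
r above threshold against at least one 20S-subtype reference (so strong
anticorrelation does not pass), at least two reference peptides, and a
median S/N above 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import ComplexDefinition
from .quantify import AbundanceMatrix


class CorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationRecord:
    """Pearson correlation between two abundance vectors.

    ``undefined`` marks zero-variance inputs; such records are excluded
    from downstream clustering rather than zero-filled.
    """

    x_id: str
    y_id: str
    r: float
    r2: float
    n: int
    undefined: bool = False


def build_reference_abundances(
    pai: AbundanceMatrix, definitions: Sequence[ComplexDefinition]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-sample reference abundances (references × samples).

    Members are intersected with the detected proteins; a member's missing
    PAI in a sample counts as zero (absence from an IP is informative).
    Returns the matrix and the members used per reference.
    """
    values = pai.values
    refs = {}
    members_used = {}
    for d in definitions:
        members = [m for m in d.members if m in values.index]
        if not members:
            raise CorrelationError(f"reference {d.name!r} has no detected member")
        sub = values.loc[members].fillna(0.0)
        if d.aggregation == "median":
            refs[d.name] = sub.median(axis=0)
        elif d.aggregation == "mean":
            refs[d.name] = sub.mean(axis=0)
        else:
            refs[d.name] = sub.iloc[0]
        members_used[d.name] = members
    return pd.DataFrame(refs).T, members_used


def correlate(
    x: Sequence[float] | pd.Series,
    y: Sequence[float] | pd.Series,
    x_id: str = "x",
    y_id: str = "y",
) -> CorrelationRecord:
    """Pearson r and R² between two abundance vectors over the same samples.

    Missing values are zero-filled in both vectors.  At least three
    samples are required; zero variance in either vector yields an
    ``undefined`` record.
    """
    xa = np.nan_to_num(np.asarray(x, dtype=float))
    ya = np.nan_to_num(np.asarray(y, dtype=float))
    if xa.shape != ya.shape:
        raise CorrelationError("abundance vectors cover different sample sets")
    n = xa.size
    if n < 3:
        raise CorrelationError(f"need >= 3 samples, got {n}")
    xd = xa - xa.mean()
    yd = ya - ya.mean()
    sx = float(np.sqrt(np.sum(xd * xd)))
    sy = float(np.sqrt(np.sum(yd * yd)))
    if sx == 0.0 or sy == 0.0:
        return CorrelationRecord(x_id, y_id, np.nan, np.nan, n, undefined=True)
    r = float(np.dot(xd, yd) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    return CorrelationRecord(x_id, y_id, r, r * r, n)


def correlation_matrix(
    pai: AbundanceMatrix,
    references: pd.DataFrame,
    targets: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """R² (and companion r) of every target protein against every reference.

    Returns ``(r2, r)`` DataFrames of shape targets × references with a
    deterministic (input) ordering; undefined correlations are NaN.
    """
    values = pai.values
    if targets is None:
        targets = list(values.index)
    else:
        missing = [t for t in targets if t not in values.index]
        if missing:
            raise CorrelationError(f"targets absent from the PAI matrix: {missing}")
    if list(references.columns) != list(values.columns):
        references = references.reindex(columns=values.columns)
    r = pd.DataFrame(
        index=pd.Index(targets, name="protein"), columns=references.index, dtype=float
    )
    for t in targets:
        for ref in references.index:
            rec = correlate(values.loc[t], references.loc[ref], t, str(ref))
            r.loc[t, ref] = np.nan if rec.undefined else rec.r
    return r * r, r


def filter_pips(
    pai: AbundanceMatrix,
    r_matrix: pd.DataFrame,
    subtype_references: Sequence[str] = ("ncP20S", "sP20S", "iP20S"),
    r_threshold: float = 0.8,
    min_peptides: int = 2,
    min_median_sn: float = 10.0,
) -> pd.DataFrame:
    """Confidence filter for putative proteasome-interacting proteins.

    Keeps proteins whose signed Pearson r exceeds ``r_threshold`` against
    at least one of the three 20S-subtype references, that were quantified
    with at least ``min_peptides`` reference peptides, and whose median
    S/N exceeds ``min_median_sn``.  Each survivor is labeled with its
    argmax-r subtype reference.  An empty result is legitimate.
    """
    missing = [s for s in subtype_references if s not in r_matrix.columns]
    if missing:
        raise CorrelationError(f"subtype references absent from r matrix: {missing}")
    sub = r_matrix[list(subtype_references)]
    support = pai.peptide_support.reindex(r_matrix.index)

    rows = []
    for protein in r_matrix.index:
        r_vals = sub.loc[protein]
        if r_vals.isna().all():
            continue
        best_ref = r_vals.idxmax()
        best_r = float(r_vals.max())
        n_pep = support.loc[protein, "n_ref_peptides"]
        med_sn = support.loc[protein, "median_sn"]
        if best_r <= r_threshold:
            continue
        if pd.isna(n_pep) or int(n_pep) < min_peptides:
            continue
        if pd.isna(med_sn) or float(med_sn) <= min_median_sn:
            continue
        rows.append(
            {
                "protein": protein,
                "best_reference": best_ref,
                "best_r": best_r,
                "n_ref_peptides": int(n_pep),
                "median_sn": float(med_sn),
            }
        )
    return pd.DataFrame(
        rows, columns=["protein", "best_reference", "best_r", "n_ref_peptides", "median_sn"]
    ).set_index("protein")
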
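"""Internal-standard calibration and TOP3 protein abundance indexes.

Label-free quantification proceeds from a long-form peptide table (one row
per peptide ion × sample, XIC peak area as the intensity) in three steps:

1. **Run calibration** — spiked isotopically labeled standard peptides are
   present at a constant amount in every run, so per-run intensity drift is
   estimated as the median, over standards, of each standard's cross-sample
   mean intensity divided by its intensity in the run; all intensities in
   the run are multiplied by that factor.
2. **Reference-peptide selection** — for each protein, peptide ions are
   ranked by their summed calibrated intensity across all samples
   (unobserved = 0) and the top three are retained; proteins seen with only
   one or two peptides keep what they have.  Ties break lexicographically
   on peptide id so the selection is deterministic.
3. **PAI** — the protein abundance index in a sample is the arithmetic
   mean of the reference peptides' calibrated intensities observed there.
   A reference peptide missing from a sample is by default excluded from
   the mean (dropout at low intensity is stochastic); ``missing_ref="zero"``
   switches to counting it as zero.

The same three reference peptides are used in every sample, which is what
makes the PAI comparable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["sample_id", "protein", "peptide_id", "xic_area", "is_standard"]


class PeptideTableError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


def validate_peptide_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the peptide-table contract: required columns, uniqueness of
    (sample, protein, peptide), non-negative intensities."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise PeptideTableError(f"peptide table missing columns: {missing}")
    if (table["xic_area"] < 0).any():
        raise PeptideTableError("negative xic_area values")
    dup = table.duplicated(subset=["sample_id", "protein", "peptide_id"])
    if dup.any():
        examples = table.loc[dup, ["sample_id", "protein", "peptide_id"]].head(3)
        raise PeptideTableError(
            f"duplicate (sample, protein, peptide) rows, e.g.\n{examples}"
        )
    return table


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if "is_standard" in table.columns:
        table["is_standard"] = table["is_standard"].astype(bool)
    return validate_peptide_table(table)


@dataclass
class CalibrationResult:
    table: pd.DataFrame
    factors: pd.Series  # per-sample multiplicative scale factor


def calibrate_runs(table: pd.DataFrame) -> CalibrationResult:
    """Rescale every run onto a common intensity scale using the spiked
    standard peptides.

    Per sample the factor is ``median over observed standards of
    (cross-sample mean of the standard / its intensity here)``.  A sample
    with no observed standard cannot be calibrated and raises an error
    naming it.
    """
    validate_peptide_table(table)
    std = table[table["is_standard"]]
    samples = pd.unique(table["sample_id"])
    if std.empty:
        raise CalibrationError(
            f"no standard peptides observed in any sample: {list(samples)}"
        )
    mean_by_std = std.groupby("peptide_id")["xic_area"].mean()
    factors = {}
    for sid in samples:
        obs = std[std["sample_id"] == sid]
        if obs.empty:
            raise CalibrationError(f"sample {sid!r} has no observed standard peptides")
        ratios = mean_by_std.loc[obs["peptide_id"]].to_numpy() / obs["xic_area"].to_numpy()
        factors[sid] = float(np.median(ratios))
    factors = pd.Series(factors, name="scale_factor")
    out = table.copy()
    # S/N is a within-run ratio, so it is left untouched by calibration
    out["xic_area"] = out["xic_area"] * out["sample_id"].map(factors)
    return CalibrationResult(out, factors)


def select_reference_peptides(table: pd.DataFrame) -> dict[str, list[str]]:
    """TOP3 reference-peptide choice per protein.

    Ranks each protein's peptide ions by total calibrated intensity summed
    over all samples (missing observations count as zero) and keeps at
    most three; exact ties are broken by the lexicographically smaller
    peptide id.
    """
    validate_peptide_table(table)
    work = table[~table["is_standard"]]
    sums = work.groupby(["protein", "peptide_id"])["xic_area"].sum()
    refs: dict[str, list[str]] = {}
    for protein, grp in sums.groupby(level="protein"):
        ranked = sorted(
            grp.droplevel("protein").items(), key=lambda kv: (-kv[1], kv[0])
        )
        refs[str(protein)] = [pid for pid, _ in ranked[:3]]
    return refs


@dataclass
class AbundanceMatrix:
    """Protein × sample PAI matrix with per-protein quantification support.

    ``values`` holds the PAIs (NaN = protein not quantified in a sample);
    in gradient mode the "samples" are the ordered fractions of one run.
    ``peptide_support`` carries, per protein, the number of reference
    peptides used and the median signal-to-noise ratio over all their
    observations — the quantities the confidence filters act on.
    """

    values: pd.DataFrame
    peptide_support: pd.DataFrame

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path: str | Path, support_path: str | Path | None = None) -> None:
        self.values.rename_axis("protein").to_csv(path, sep="\t")
        if support_path is not None:
            self.peptide_support.rename_axis("protein").to_csv(support_path, sep="\t")

    @classmethod
    def read(cls, path: str | Path, support_path: str | Path | None = None) -> "AbundanceMatrix":
        values = pd.read_csv(path, sep="\t", index_col="protein")
        if support_path is not None:
            support = pd.read_csv(support_path, sep="\t", index_col="protein")
        else:
            support = pd.DataFrame(
                {"n_ref_peptides": np.nan, "median_sn": np.nan}, index=values.index
            )
        return cls(values, support)


def compute_pai(
    table: pd.DataFrame,
    refs: Mapping[str, list[str]] | None = None,
    missing_ref: Literal["mean", "zero"] = "mean",
) -> AbundanceMatrix:
    """Compute the protein abundance index matrix from a calibrated table.

    ``refs`` should come from :func:`select_reference_peptides` on the same
    table; it is computed on the fly when omitted.
    """
    validate_peptide_table(table)
    if refs is None:
        refs = select_reference_peptides(table)
    work = table[~table["is_standard"]]
    samples = list(pd.unique(work["sample_id"]))

    ref_pairs = {(p, pid) for p, pids in refs.items() for pid in pids}
    mask = [
        (p, pid) in ref_pairs
        for p, pid in zip(work["protein"], work["peptide_id"])
    ]
    ref_rows = work[np.asarray(mask, dtype=bool)]

    wide = ref_rows.pivot_table(
        index=["protein", "peptide_id"], columns="sample_id", values="xic_area",
        aggfunc="first",
    ).reindex(columns=samples)
    if missing_ref == "mean":
        pai = wide.groupby(level="protein").mean()
    elif missing_ref == "zero":
        pai = wide.fillna(0.0).groupby(level="protein").mean()
        # a protein entirely unobserved in a sample stays missing, not 0
        seen = wide.notna().groupby(level="protein").any()
        pai = pai.where(seen)
    else:
        raise ValueError(f"unknown missing_ref policy {missing_ref!r}")
    pai = pai.reindex(sorted(refs), columns=samples)

    n_ref = pd.Series({p: len(pids) for p, pids in refs.items()}, name="n_ref_peptides")
    if "sn_ratio" in ref_rows.columns:
        median_sn = ref_rows.groupby("protein")["sn_ratio"].median()
    else:
        median_sn = pd.Series(np.nan, index=pai.index)
    support = pd.DataFrame(
        {"n_ref_peptides": n_ref, "median_sn": median_sn}
    ).reindex(pai.index)
    return AbundanceMatrix(pai, support)


def quantify(
    table: pd.DataFrame,
    calibrate: bool = True,
    missing_ref: Literal["mean", "zero"] = "mean",
) -> tuple[AbundanceMatrix, pd.Series | None]:
    """Full quantification: calibrate (optionally), select TOP3, compute PAIs.

    Returns the abundance matrix and the per-run calibration factors
    (``None`` when calibration is skipped).
    """
    factors = None
    if calibrate:
        result = calibrate_runs(table)
        table, factors = result.table, result.factors
    refs = select_reference_peptides(table)
    return compute_pai(table, refs, missing_ref=missing_ref), factors
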
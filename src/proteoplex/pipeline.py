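"""End-to-end orchestration: simulate → quantify → analyze, with a manifest.

A :class:`RunConfig` captures the run mode (``apms``, ``gradient`` or
``timecourse``), the seed, and every documented analysis toggle with its
default.  ``run_pipeline`` writes each stage's artifact under fixed file
names and finishes with a manifest recording the config hash, seed,
package versions and per-stage row counts, so a run can be reproduced or
any stage re-run from its intermediates.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .catalog import default_catalog
from .clustering import ahc_upgma, max_normalize, pca_pearson, supervised_cluster
from .correlation import build_reference_abundances, correlation_matrix, filter_pips
from .differential import differential_analysis
from .pcp import build_profiles, pcp_screen
from .quantify import quantify
from .simulate import (
    GroundTruthModel,
    simulate_apms,
    simulate_gradient,
    simulate_ifng_timecourse,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class RunConfig(BaseModel):
    """All knobs of one pipeline run, with their defaults."""

    mode: Literal["apms", "gradient", "timecourse"] = "apms"
    seed: int = 0
    outdir: str = "proteoplex_run"
    # quantification
    calibrate: bool = True
    missing_ref: Literal["mean", "zero"] = "mean"
    # gradient screen
    pcp_reference: str = "PA28αβ"
    epsilon: float = 1e-4
    gradient_replicates: int = 2
    # correlation / PIP filter
    r_threshold: float = 0.8
    min_peptides: int = 2
    min_median_sn: float = 10.0
    # differential
    reference_condition: Optional[str] = None
    equal_var: bool = True
    regulators: list[str] = Field(
        default_factory=lambda: ["19S", "PA28αβ", "PA28γ", "PA200", "PI31"]
    )
    # simulation ground truth (None = package defaults)
    model: Optional[GroundTruthModel] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                json.loads(self.model_dump_json()), fh, allow_unicode=True, sort_keys=True
            )

    def digest(self) -> str:
        payload = json.dumps(
            json.loads(self.model_dump_json()), sort_keys=True, ensure_ascii=False
        )
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured run and return the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog, defs = default_catalog()
    defs_by_name = {d.name: d for d in defs}
    for name in [config.pcp_reference] + config.regulators:
        if name not in defs_by_name:
            raise PipelineError("config", f"unknown reference complex {name!r}")

    model = config.model or GroundTruthModel()
    model = model.model_copy(update={"seed": config.seed})
    counts: dict[str, int] = {}

    # --- simulate -----------------------------------------------------
    try:
        if config.mode == "apms":
            dataset = simulate_apms(model)
        elif config.mode == "gradient":
            dataset = simulate_gradient(model, replicates=config.gradient_replicates)
        else:
            dataset = simulate_ifng_timecourse(model)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc
    dataset.write(outdir)
    counts["peptide_rows"] = len(dataset.peptide_table)
    counts["samples"] = dataset.metadata["sample_id"].nunique()

    # --- quantify -----------------------------------------------------
    def quantify_table(table: pd.DataFrame):
        try:
            return quantify(
                table, calibrate=config.calibrate, missing_ref=config.missing_ref
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("quantify", str(exc)) from exc

    if config.mode == "gradient":
        screens_input = {}
        for rep, table in dataset.replicate_tables().items():
            matrix, _ = quantify_table(table)
            profile_set = build_profiles(matrix)
            screens_input[f"rep{rep}"] = profile_set.profiles
            matrix.write(outdir / f"pai_rep{rep}.tsv")
        try:
            screen = pcp_screen(
                screens_input, defs_by_name[config.pcp_reference], epsilon=config.epsilon
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("pcp", str(exc)) from exc
        screen.to_csv(outdir / "chi2.tsv", sep="\t")
        counts["proteins_screened"] = len(screen)
    else:
        matrix, factors = quantify_table(dataset.peptide_table)
        matrix.write(outdir / "pai.tsv", outdir / "peptide_support.tsv")
        if factors is not None:
            factors.rename_axis("sample_id").to_csv(outdir / "calibration.tsv", sep="\t")
        counts["proteins_quantified"] = len(matrix.proteins)

        # --- correlate + cluster -------------------------------------
        try:
            references, _ = build_reference_abundances(matrix, defs)
            r2, r = correlation_matrix(matrix, references)
            pips = filter_pips(
                matrix,
                r,
                r_threshold=config.r_threshold,
                min_peptides=config.min_peptides,
                min_median_sn=config.min_median_sn,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("correlate", str(exc)) from exc
        r2.to_csv(outdir / "r2_matrix.tsv", sep="\t")
        r.to_csv(outdir / "r_matrix.tsv", sep="\t")
        pips.to_csv(outdir / "pips.tsv", sep="\t")
        counts["confident_pips"] = len(pips)

        try:
            clusterable = r2.dropna(axis=0)
            sup = supervised_cluster(clusterable)
            norm, _ = max_normalize(matrix)
            dendro, _ = ahc_upgma(norm)
            pca = pca_pearson(norm)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("cluster", str(exc)) from exc
        (outdir / "supervised_order.tsv").write_text(
            "protein\n" + "\n".join(sup.row_order) + "\n", encoding="utf-8"
        )
        (outdir / "ahc.nwk").write_text(dendro.to_newick() + "\n", encoding="utf-8")
        pca.scores.rename_axis("protein").to_csv(outdir / "pca_scores.tsv", sep="\t")
        pca.loadings.rename_axis("sample_id").to_csv(outdir / "pca_loadings.tsv", sep="\t")
        pca.explained.rename_axis("component").to_csv(outdir / "pca_explained.tsv", sep="\t")

        # --- differential --------------------------------------------
        reference_condition = config.reference_condition
        if reference_condition is None:
            reference_condition = str(dataset.metadata["condition"].iloc[0])
        try:
            diff = differential_analysis(
                matrix,
                dataset.metadata,
                [defs_by_name[r_] for r_ in config.regulators],
                defs_by_name["ncP20S"],
                reference_condition,
                equal_var=config.equal_var,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("differential", str(exc)) from exc
        diff.to_csv(outdir / "differential.tsv", sep="\t")
        counts["differential_rows"] = len(diff)

    # --- manifest -----------------------------------------------------
    config.to_yaml(outdir / "config.yaml")
    manifest = {
        "config_sha256": config.digest(),
        "seed": config.seed,
        "mode": config.mode,
        "proteoplex_version": __version__,
        "pandas_version": pd.__version__,
        "counts": counts,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, ensure_ascii=False)
    return outdir
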
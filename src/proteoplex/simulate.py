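"""Synthetic peptide-level MS data from a ground-truth complex model.

The generator emulates bottom-up label-free proteomics of immunopurified
proteasomes (AP-MS mode) and of glycerol-gradient fractions (PCP mode):

* each cell line carries planted 20S-subtype fractions (sP20S / iP20S /
  intermediate) and a total 20S level;
* regulators (19S, PA28αβ, PA28γ, PA200, PI31) bind each subtype with a
  planted association propensity in [0, 1] — the expected bound regulator
  per 20S particle of that subtype;
* an immunopurification captures a fixed yield (default 0.87) of the 20S
  pool together with its bound regulators;
* each protein is digested into a fixed set of peptide ions whose
  ionization-efficiency factors are drawn once and reused across samples
  (the premise that makes TOP3 with fixed reference peptides comparable
  across runs), observed with multiplicative lognormal noise
  (σ = sqrt(ln(1 + CV²))), stochastic dropout, and a per-run drift factor;
* eight isotopically labeled standard peptides are spiked at a constant
  amount per run and perturbed only by the run drift, providing the handle
  for inter-run calibration.

All planted values are retained in :class:`SimulatedDataset.truth` so that
downstream estimates can be compared against ground truth in recovery
tests.  With a fixed seed the output is reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .catalog import default_catalog

NC_SUBUNITS: tuple[str, ...] = (
    "α1", "α2", "α3", "α4", "α5", "α6", "α7", "β3", "β4", "β6", "β7",
)

#: Subunit composition of each 20S subtype.  The default intermediate is
#: the β1i/β5i form (carries both inducible subunits but not β2i, so β2i
#: remains an exclusive iP20S proxy).
SUBTYPE_COMPOSITION: dict[str, tuple[str, ...]] = {
    "sP20S": NC_SUBUNITS + ("β1", "β2", "β5"),
    "iP20S": NC_SUBUNITS + ("β1i", "β2i", "β5i"),
    "intermediate": NC_SUBUNITS + ("β1i", "β2", "β5i"),
}

REGULATOR_NAMES: tuple[str, ...] = ("19S", "PA28αβ", "PA28γ", "PA200", "PI31")

N_STANDARDS = 8
BASE_INTENSITY = 1e6
#: Signal-to-noise is reported as intensity over a fixed noise floor.
SN_FLOOR = 5e3


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal factors with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _loading_factor(rng: np.random.Generator, cv: float) -> float:
    """Bounded per-sample loading factor, log-uniform with the given CV.

    Loading deviations come from immunoassay imprecision when samples are
    brought to a nominal equal amount; gross mis-loads are caught and
    redone, so the factor is bounded rather than heavy-tailed.  A
    log-uniform on [e^-w, e^w] with w = cv·√3 has log-scale standard
    deviation ≈ cv.
    """
    if cv <= 0:
        return 1.0
    w = cv * np.sqrt(3.0)
    return float(np.exp(rng.uniform(-w, w)))


class CellLine(BaseModel):
    """Planted proteasome composition of one cell line."""

    name: str
    subtype_fractions: dict[str, float]
    total_20S: float = 1.0
    replicates: int = 3
    regulator_pools: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_fractions(self) -> "CellLine":
        total = sum(self.subtype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"subtype fractions of {self.name!r} sum to {total}, not 1"
            )
        for k, v in self.subtype_fractions.items():
            if k not in SUBTYPE_COMPOSITION:
                raise ValueError(f"unknown 20S subtype {k!r} in {self.name!r}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"fraction {k}={v} outside [0, 1]")
        if self.total_20S <= 0:
            raise ValueError("total_20S must be positive")
        return self


class PeptideModel(BaseModel):
    """Peptide-level observation model."""

    peptides_per_protein: int = Field(default=5, ge=1)
    #: lognormal σ of the fixed per-peptide ionization factors; reference
    #: (top-intensity) peptides of one protein typically span a ~2× range
    efficiency_sigma: float = Field(default=0.45, ge=0.0)
    noise_cv: float = Field(default=0.2, ge=0.0)
    #: dropout of the most intense peptides of targeted, abundant
    #: complexes is rare
    missing_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    drift_cv: float = Field(default=0.2, ge=0.0)


class GradientSpecies(BaseModel):
    """One sedimenting complex species: composition and Gaussian peak."""

    name: str
    complexes: list[str]
    amount: float = 1.0
    center: float
    width: float = 1.5


class GradientModel(BaseModel):
    n_fractions: int = Field(default=19, ge=2)
    species: list[GradientSpecies] = Field(default_factory=lambda: _default_species())


class Background(BaseModel):
    n_contaminants: int = Field(default=30, ge=0)
    contaminant_level: float = Field(default=0.05, ge=0.0)


def _default_species() -> list[GradientSpecies]:
    # Fraction indexes run from dense (bottom, low index) to light; the
    # 26S holoenzyme sediments deepest, free 20S and small regulators stay
    # higher in the gradient.  The iP20S is planted predominantly in a
    # PA28αβ-capped species.
    mk = GradientSpecies
    return [
        mk(name="26S", complexes=["sP20S", "19S"], amount=1.0, center=7.0, width=1.5),
        mk(name="iP20S-PA28αβ", complexes=["iP20S", "PA28αβ"], amount=0.8, center=11.0, width=1.5),
        mk(name="free-sP20S", complexes=["sP20S"], amount=0.8, center=14.0, width=1.5),
        mk(name="free-iP20S", complexes=["iP20S"], amount=0.1, center=14.0, width=1.5),
        mk(name="free-int20S", complexes=["intermediate"], amount=0.3, center=14.0, width=1.5),
        mk(name="sP20S-PA28γ", complexes=["sP20S", "PA28γ"], amount=0.25, center=13.0, width=1.5),
        mk(name="free-19S", complexes=["19S"], amount=0.3, center=16.0, width=1.5),
    ]


def default_cell_lines() -> list[CellLine]:
    """Nine human cell lines spanning a wide range of iP20S content.

    Immunoproteasome-rich hematopoietic lines (U937, KG1a, NB4) carry
    30–50% inducible-subtype 20S; epithelial/fibroblast lines are
    sP20S-dominated.  Totals vary so that sP20S and iP20S amounts are
    close to uncorrelated across lines.  Replicate counts (3, 3, 3, 3, 3,
    3, 2, 2, 2) yield 24 purifications in total.
    """
    spec = [
        # name, inducible share f (iP20S = 0.75 f, intermediate = 0.25 f), reps
        # hematopoietic lines carry 50-67% inducible 20S, epithelial and
        # fibroblast lines 2-20%
        ("U937", 0.67, 3),
        ("KG1a", 0.65, 3),
        ("NB4", 0.50, 3),
        ("HeLa", 0.20, 3),
        ("HEK293T", 0.12, 3),
        ("HCT116", 0.15, 3),
        ("RKO", 0.08, 2),
        ("U2OS", 0.20, 2),
        ("MRC5", 0.025, 2),
    ]
    lines = []
    for name, f, reps in spec:
        fractions = {
            "sP20S": 1.0 - f,
            "iP20S": 0.75 * f,
            "intermediate": 0.25 * f,
        }
        # total_20S is 1 for every line: purifications are loaded at an
        # equal nominal 20S amount, and per-sample loading imprecision is
        # modeled separately (loading_cv)
        lines.append(
            CellLine(name=name, subtype_fractions=fractions, total_20S=1.0, replicates=reps)
        )
    return lines


def default_propensities() -> dict[str, dict[str, float]]:
    """Planted regulator–subtype association propensities.

    The 19S binds both major subtypes equally; PA28αβ strongly prefers the
    iP20S; PI31 and PA200 prefer the sP20S; PA28γ has no preference.
    Intermediate subtypes default to the iP20S propensity row.
    """
    return {
        "19S": {"sP20S": 0.5, "iP20S": 0.5},
        "PA28αβ": {"sP20S": 0.05, "iP20S": 0.9},
        "PA28γ": {"sP20S": 0.35, "iP20S": 0.35},
        "PA200": {"sP20S": 0.7, "iP20S": 0.05},
        "PI31": {"sP20S": 0.8, "iP20S": 0.05},
    }


class GroundTruthModel(BaseModel):
    """All planted parameters of a simulated experiment."""

    cell_lines: list[CellLine] = Field(default_factory=default_cell_lines)
    association_propensity: dict[str, dict[str, float]] = Field(
        default_factory=default_propensities
    )
    capture_yield: float = Field(default=0.87, gt=0.0, le=1.0)
    #: CV of the per-sample loading factor shared by every captured
    #: protein: samples are loaded at a nominal equal 20S amount, but the
    #: immunoassay that sets the load is imprecise.  This shared factor is
    #: what gives subunits of the same complex their high cross-sample
    #: correlation.
    loading_cv: float = Field(default=0.5, ge=0.0)
    biological_cv: float = Field(default=0.1, ge=0.0)
    peptide_model: PeptideModel = Field(default_factory=PeptideModel)
    gradient_model: GradientModel = Field(default_factory=GradientModel)
    background: Background = Field(default_factory=Background)
    seed: int = 0

    @field_validator("association_propensity")
    @classmethod
    def _check_propensities(cls, v):
        for reg, row in v.items():
            for subtype, p in row.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"propensity ({reg}, {subtype}) = {p} outside [0, 1]"
                    )
        return v

    def propensity(self, regulator: str, subtype: str) -> float:
        if regulator not in self.association_propensity:
            raise KeyError(f"no association propensities declared for {regulator!r}")
        row = self.association_propensity[regulator]
        if subtype in row:
            return row[subtype]
        if subtype == "intermediate" and "iP20S" in row:
            # intermediate subtypes associate like the immunoproteasome
            return row["iP20S"]
        raise KeyError(f"propensity ({regulator!r}, {subtype!r}) not declared")


@dataclass
class SimulatedDataset:
    """A peptide table with sample metadata and the planted ground truth."""

    peptide_table: pd.DataFrame
    metadata: pd.DataFrame
    truth: dict

    def replicate_tables(self) -> dict[object, pd.DataFrame]:
        """Split the peptide table by replicate (one table per gradient run)."""
        out = {}
        for rep, meta in self.metadata.groupby("replicate", sort=True):
            sids = set(meta["sample_id"])
            out[rep] = self.peptide_table[
                self.peptide_table["sample_id"].isin(sids)
            ].reset_index(drop=True)
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.peptide_table.to_csv(outdir / "peptides.tsv", sep="\t", index=False)
        self.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=1, ensure_ascii=False, default=float)


# ---------------------------------------------------------------------------
# shared machinery


def _protein_universe(background: Background) -> list[str]:
    catalog, defs = default_catalog()
    in_subtypes = {s for comp in SUBTYPE_COMPOSITION.values() for s in comp}
    in_regulators = {m for d in defs if d.name in REGULATOR_NAMES for m in d.members}
    ordered = [n for n in catalog.names if n in in_subtypes | in_regulators]
    contaminants = [f"CONT{i:03d}" for i in range(1, background.n_contaminants + 1)]
    return ordered + contaminants


def _regulator_members() -> dict[str, tuple[str, ...]]:
    _, defs = default_catalog()
    return {d.name: d.members for d in defs if d.name in REGULATOR_NAMES}


def _peptide_efficiencies(
    proteins: Sequence[str], model: GroundTruthModel, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Fixed per-peptide ionization factors, drawn once per protein."""
    k = model.peptide_model.peptides_per_protein
    sigma = model.peptide_model.efficiency_sigma
    return {p: rng.lognormal(mean=0.0, sigma=sigma, size=k) for p in proteins}


def _standard_nominals(rng: np.random.Generator) -> np.ndarray:
    """Constant spiked amounts of the 8 labeled standard peptides."""
    return rng.lognormal(mean=np.log(1e5), sigma=0.3, size=N_STANDARDS)


def _emit_sample_rows(
    sample_id: str,
    abundance: Mapping[str, float],
    efficiencies: Mapping[str, np.ndarray],
    standard_nominals: np.ndarray,
    run_scale: float,
    model: GroundTruthModel,
    rng: np.random.Generator,
    rows: list,
) -> None:
    pm = model.peptide_model
    for protein in abundance:
        eff = efficiencies[protein]
        noise = _lognormal_factors(rng, pm.noise_cv, eff.shape[0])
        observed = rng.random(eff.shape[0]) >= pm.missing_rate
        intensities = abundance[protein] * eff * noise * run_scale * BASE_INTENSITY
        for j in range(eff.shape[0]):
            if not observed[j] or intensities[j] <= 0:
                continue
            rows.append(
                (
                    sample_id,
                    protein,
                    f"{protein}_pep{j + 1}",
                    intensities[j],
                    intensities[j] / SN_FLOOR,
                    False,
                )
            )
    for j in range(N_STANDARDS):
        inten = standard_nominals[j] * run_scale
        rows.append((sample_id, "STANDARD", f"STD{j + 1:02d}", inten, inten / SN_FLOOR, True))


_COLUMNS = ["sample_id", "protein", "peptide_id", "xic_area", "sn_ratio", "is_standard"]


def _apms_abundance(
    realized_subtypes: Mapping[str, float],
    model: GroundTruthModel,
    regulator_members: Mapping[str, tuple[str, ...]],
    proteins: Sequence[str],
    contaminant_abund: Mapping[str, float],
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-protein captured abundance for one purification.

    20S subunits inherit the realized abundance of every subtype they
    belong to; regulator subunits inherit the propensity-weighted bound
    amount; both are scaled by the capture yield.  Returns (abundance,
    regulator_bound) with bound amounts pre-capture.
    """
    y = model.capture_yield
    abundance = dict.fromkeys(proteins, 0.0)
    for subtype, amt in realized_subtypes.items():
        for su in SUBTYPE_COMPOSITION[subtype]:
            abundance[su] += y * amt
    bound = {}
    for reg, members in regulator_members.items():
        b = sum(
            amt * model.propensity(reg, subtype)
            for subtype, amt in realized_subtypes.items()
        )
        bound[reg] = b
        for m in members:
            abundance[m] += y * b
    for c, amt in contaminant_abund.items():
        abundance[c] = amt
    return abundance, bound


def _run_apms_like(
    model: GroundTruthModel,
    sample_specs: list[dict],
    root: np.random.SeedSequence,
) -> SimulatedDataset:
    """Common AP-MS sample emitter for the purification-based designs.

    ``sample_specs`` entries carry sample_id, condition, cell_line,
    replicate and the per-subtype *expected* abundances; biological
    lognormal noise and all measurement-level effects are applied here.
    """
    ss_eff, ss_std, ss_samples = root.spawn(3)
    proteins = _protein_universe(model.background)
    contaminant_names = [p for p in proteins if p.startswith("CONT")]
    regulator_members = _regulator_members()
    efficiencies = _peptide_efficiencies(proteins, model, np.random.default_rng(ss_eff))
    standard_nominals = _standard_nominals(np.random.default_rng(ss_std))

    rows: list = []
    meta_rows = []
    truth_samples = {}
    sample_streams = ss_samples.spawn(len(sample_specs))
    for spec, stream in zip(sample_specs, sample_streams):
        rng = np.random.default_rng(stream)
        loading = _loading_factor(rng, model.loading_cv)
        realized = {}
        for subtype in sorted(spec["expected_subtypes"]):
            expected = spec["expected_subtypes"][subtype]
            if expected <= 0:
                continue
            realized[subtype] = (
                expected * loading * _lognormal_factors(rng, model.biological_cv, ())
            )

        # contaminant amounts are drawn independently per sample so that
        # they correlate with no complex (the null background for
        # correlation-specificity checks)
        contaminant_abund = {
            c: model.background.contaminant_level * float(rng.lognormal(0.0, 1.0))
            for c in contaminant_names
        }
        abundance, bound = _apms_abundance(
            realized, model, regulator_members, proteins, contaminant_abund
        )
        run_scale = float(_lognormal_factors(rng, model.peptide_model.drift_cv, ()))
        _emit_sample_rows(
            spec["sample_id"], abundance, efficiencies, standard_nominals,
            run_scale, model, rng, rows,
        )
        meta_rows.append(
            {
                "sample_id": spec["sample_id"],
                "cell_line": spec["cell_line"],
                "replicate": spec["replicate"],
                "condition": spec["condition"],
                "fraction": "",
            }
        )
        truth_samples[spec["sample_id"]] = {
            "cell_line": spec["cell_line"],
            "condition": spec["condition"],
            "replicate": spec["replicate"],
            "loading": loading,
            "subtype_abundance": {k: float(v) for k, v in realized.items()},
            "regulator_bound": {k: float(v) for k, v in bound.items()},
            "run_scale": run_scale,
            "protein_abundance": {k: float(v) for k, v in abundance.items()},
        }

    table = pd.DataFrame(rows, columns=_COLUMNS)
    metadata = pd.DataFrame(meta_rows)
    truth = {
        "model": model.model_dump(),
        "samples": truth_samples,
        "standard_nominals": [float(x) for x in standard_nominals],
    }
    return SimulatedDataset(table, metadata, truth)


# ---------------------------------------------------------------------------
# public generators


def simulate_apms(
    model: GroundTruthModel,
    replicates_per_line: int | Mapping[str, int] | None = None,
) -> SimulatedDataset:
    """Simulate one AP-MS purification series across the model's cell lines.

    ``replicates_per_line`` overrides the per-line replicate counts: an
    integer applies to every line, a mapping per line, and ``None`` uses
    each line's own ``replicates`` field (the default design gives 24
    samples across 9 lines).
    """
    specs = []
    for line in model.cell_lines:
        if isinstance(replicates_per_line, int):
            reps = replicates_per_line
        elif replicates_per_line is not None:
            reps = replicates_per_line[line.name]
        else:
            reps = line.replicates
        if reps < 1:
            raise ValueError(f"replicate count for {line.name!r} must be >= 1")
        expected = {
            s: line.total_20S * f for s, f in line.subtype_fractions.items()
        }
        for r in range(1, reps + 1):
            specs.append(
                {
                    "sample_id": f"{line.name}_r{r}",
                    "cell_line": line.name,
                    "condition": line.name,
                    "replicate": r,
                    "expected_subtypes": expected,
                }
            )
    root = np.random.SeedSequence(model.seed)
    return _run_apms_like(model, specs, root)


def simulate_ifng_timecourse(
    model: GroundTruthModel,
    timepoints: Sequence[float] = (0, 24, 48, 72),
    fold_schedule: Mapping[str, Mapping[float, float]] | None = None,
    replicates: int = 3,
    cell_line: str | None = None,
) -> SimulatedDataset:
    """Simulate an IFNγ stimulation time course on one cell line.

    ``fold_schedule`` maps subtype → {timepoint: multiplier} applied to the
    base subtype abundances (default: iP20S rises to 8×, sP20S falls to
    0.5× by 72 h; intermediates follow the iP20S schedule).  Every declared
    subtype must cover every requested timepoint.

    The default base is an unstimulated HeLa-like composition with only 5%
    inducible 20S: starting from a low immuno baseline is what keeps the
    total 20S pool (the ncP20S normalizer) approximately constant while
    the subtype amounts swing 8× up and 2× down.
    """
    if fold_schedule is None:
        fold_schedule = {
            "iP20S": {0: 1.0, 24: 2.0, 48: 4.0, 72: 8.0},
            "sP20S": {0: 1.0, 24: 0.85, 48: 0.7, 72: 0.5},
        }
    if cell_line is None:
        line = CellLine(
            name="HeLa",
            subtype_fractions={"sP20S": 0.95, "iP20S": 0.0375, "intermediate": 0.0125},
            total_20S=1.0,
        )
    else:
        line = {l.name: l for l in model.cell_lines}[cell_line]

    def fold(subtype: str, t: float) -> float:
        sched = fold_schedule.get(subtype)
        if sched is None and subtype == "intermediate":
            sched = fold_schedule.get("iP20S")
        if sched is None:
            return 1.0
        if t not in sched:
            raise KeyError(f"timepoint {t!r} missing from fold schedule of {subtype!r}")
        return sched[t]

    specs = []
    for t in timepoints:
        expected = {
            s: line.total_20S * f * fold(s, t)
            for s, f in line.subtype_fractions.items()
        }
        for r in range(1, replicates + 1):
            specs.append(
                {
                    "sample_id": f"t{t:g}h_r{r}",
                    "cell_line": line.name,
                    "condition": f"{t:g}h",
                    "replicate": r,
                    "expected_subtypes": expected,
                }
            )
    root = np.random.SeedSequence(model.seed)
    dataset = _run_apms_like(model, specs, root)
    dataset.truth["fold_schedule"] = {
        s: {f"{t:g}": v for t, v in sched.items()} for s, sched in fold_schedule.items()
    }
    return dataset


def simulate_gradient(model: GroundTruthModel, replicates: int = 2) -> SimulatedDataset:
    """Simulate glycerol-gradient fractionation runs of one lysate.

    Every declared species sediments as a Gaussian over fraction indexes
    1..F; a protein's noise-free abundance in a fraction is the sum over
    the species containing it.  Each fraction of each replicate is one MS
    run with its own drift factor and spiked standards.  Contaminant
    proteins get broad, randomly centered profiles uncorrelated with any
    complex.
    """
    gm = model.gradient_model
    if gm.n_fractions < 2:
        raise ValueError("need at least 2 fractions")
    catalog, defs = default_catalog()
    defs_by_name = {d.name: d for d in defs}

    def complex_members(name: str) -> tuple[str, ...]:
        if name in SUBTYPE_COMPOSITION:
            return SUBTYPE_COMPOSITION[name]
        if name in defs_by_name:
            return defs_by_name[name].members
        raise KeyError(f"species references unknown complex {name!r}")

    proteins = _protein_universe(model.background)
    contaminant_names = [p for p in proteins if p.startswith("CONT")]
    fractions = np.arange(1, gm.n_fractions + 1, dtype=float)

    root = np.random.SeedSequence(model.seed)
    ss_eff, ss_std, ss_truth, ss_runs = root.spawn(4)
    efficiencies = _peptide_efficiencies(proteins, model, np.random.default_rng(ss_eff))
    standard_nominals = _standard_nominals(np.random.default_rng(ss_std))

    profile = {p: np.zeros(gm.n_fractions) for p in proteins}
    for sp in gm.species:
        shape = np.exp(-0.5 * ((fractions - sp.center) / sp.width) ** 2)
        for cx in sp.complexes:
            for member in complex_members(cx):
                profile[member] += sp.amount * shape

    rng_truth = np.random.default_rng(ss_truth)
    contaminant_params = {}
    for c in contaminant_names:
        center = rng_truth.uniform(1.0, float(gm.n_fractions))
        width = rng_truth.uniform(4.0, 7.0)
        amount = model.background.contaminant_level * rng_truth.lognormal(0.0, 0.5)
        contaminant_params[c] = (center, width, amount)
        profile[c] = amount * np.exp(-0.5 * ((fractions - center) / width) ** 2)

    rows: list = []
    meta_rows = []
    run_scales = {}
    run_streams = ss_runs.spawn(replicates * gm.n_fractions)
    idx = 0
    for rep in range(1, replicates + 1):
        for fi, f in enumerate(fractions):
            rng = np.random.default_rng(run_streams[idx])
            idx += 1
            sample_id = f"rep{rep}_F{int(f):02d}"
            abundance = {p: float(profile[p][fi]) for p in proteins}
            run_scale = float(_lognormal_factors(rng, model.peptide_model.drift_cv, ()))
            run_scales[sample_id] = run_scale
            _emit_sample_rows(
                sample_id, abundance, efficiencies, standard_nominals,
                run_scale, model, rng, rows,
            )
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "cell_line": "",
                    "replicate": rep,
                    "condition": "gradient",
                    "fraction": int(f),
                }
            )

    table = pd.DataFrame(rows, columns=_COLUMNS)
    metadata = pd.DataFrame(meta_rows)
    truth = {
        "model": model.model_dump(),
        "protein_profiles": {p: [float(x) for x in v] for p, v in profile.items()},
        "contaminant_params": {
            c: {"center": float(a), "width": float(b), "amount": float(d)}
            for c, (a, b, d) in contaminant_params.items()
        },
        "run_scales": run_scales,
        "standard_nominals": [float(x) for x in standard_nominals],
    }
    return SimulatedDataset(table, metadata, truth)
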
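"""Planted-truth recovery studies on the synthetic study designs.

Each function runs one end-to-end trial of a study design against the
generator's planted ground truth and reports what the analysis recovered.
These are the package's own validation experiments: they answer "does the
pipeline recover the structure it was built to detect, under realistic
noise?" and power both the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

from .catalog import default_catalog
from .clustering import ahc_upgma, max_normalize, supervised_cluster
from .correlation import (
    build_reference_abundances,
    correlate,
    correlation_matrix,
    filter_pips,
)
from .differential import differential_analysis
from .pcp import build_profiles, pcp_screen
from .quantify import quantify
from .simulate import (
    Background,
    CellLine,
    GroundTruthModel,
    simulate_apms,
    simulate_gradient,
)

#: The three planted association groups of the default AP-MS design:
#: immuno-subtype partners, standard-subtype partners, and the common core
#: (20S non-catalytic subunits plus the 19S regulatory particle).
IMMUNO_GROUP = frozenset({"β1i", "β2i", "β5i", "PA28α", "PA28β"})
STANDARD_GROUP = frozenset({"β1", "β2", "β5", "PI31", "PA200"})


def _core_group() -> frozenset[str]:
    _, defs = default_catalog()
    by_name = {d.name: d for d in defs}
    return frozenset(set(by_name["ncP20S"].members) | set(by_name["19S"].members))


def _partition_matches_planted_groups(labels: dict[str, int]) -> bool:
    groups = (IMMUNO_GROUP, STANDARD_GROUP, _core_group())
    label_sets = []
    for group in groups:
        present = {labels[p] for p in group if p in labels}
        if len(present) != 1:
            return False
        label_sets.append(next(iter(present)))
    return len(set(label_sets)) == 3


@dataclass
class AssociationTrial:
    r2_ip20s_pa28ab: float
    r2_sp20s_pa28ab: float
    supervised_recovered: bool
    upgma_recovered: bool
    n_confident_pips: int

    @property
    def success(self) -> bool:
        return (
            self.r2_ip20s_pa28ab >= 0.8
            and self.r2_sp20s_pa28ab <= 0.2
            and self.supervised_recovered
            and self.upgma_recovered
        )


def association_recovery_trial(seed: int) -> AssociationTrial:
    """One 24-sample AP-MS study: reference correlations and 3-group
    recovery by supervised clustering and UPGMA.

    Mirrors the published workflow: proteins pass the confidence filter
    before entering the clustering, and the recovered 3-cut partition is
    compared against the planted association groups.
    """
    _, defs = default_catalog()
    model = GroundTruthModel(seed=seed)
    dataset = simulate_apms(model)
    matrix, _ = quantify(dataset.peptide_table)
    references, _ = build_reference_abundances(matrix, defs)
    r2_ip = correlate(references.loc["iP20S"], references.loc["PA28αβ"]).r2
    r2_sp = correlate(references.loc["sP20S"], references.loc["PA28αβ"]).r2

    r2, r = correlation_matrix(matrix, references)
    pips = filter_pips(matrix, r)
    planted = IMMUNO_GROUP | STANDARD_GROUP | _core_group()
    targets = sorted(set(pips.index) & planted)

    proxies = {"β5", "β2i", "PA28α", "PA28β", "PI31", "PA200"}
    sup_ok = ahc_ok = False
    if proxies <= set(targets):
        sup = supervised_cluster(r2.loc[targets].dropna())
        sup_ok = _partition_matches_planted_groups(sup.dendrogram.cut(3))
        norm, _ = max_normalize(matrix.values.loc[targets])
        dendro, _ = ahc_upgma(norm)
        ahc_ok = _partition_matches_planted_groups(dendro.cut(3))
    return AssociationTrial(r2_ip, r2_sp, sup_ok, ahc_ok, len(pips))


@dataclass
class GradientTrial:
    best_non_reference_protein: str
    beta2i_mean_chi2: float

    @property
    def success(self) -> bool:
        return self.best_non_reference_protein == "β2i"


def gradient_recovery_trial(seed: int, replicates: int = 2) -> GradientTrial:
    """One two-replicate gradient study: does β2i show the closest profile
    to the PA28αβ reference among all non-PA28 proteins?"""
    _, defs = default_catalog()
    by_name = {d.name: d for d in defs}
    model = GroundTruthModel(seed=seed)
    dataset = simulate_gradient(model, replicates=replicates)
    profiles = {
        rep: build_profiles(quantify(table)[0]).profiles
        for rep, table in dataset.replicate_tables().items()
    }
    screen = pcp_screen(profiles, by_name["PA28αβ"])
    non_reference = screen.drop(index=["PA28α", "PA28β"], errors="ignore")
    best = str(non_reference["mean_chi2"].idxmin())
    chi2_b2i = float(screen.loc["β2i", "mean_chi2"]) if "β2i" in screen.index else float("nan")
    return GradientTrial(best, chi2_b2i)


def two_line_model(
    seed: int,
    pa28ab: tuple[float, float] = (0.2, 0.8),
    pi31: tuple[float, float] = (0.8, 0.1),
    replicates: int = 4,
    n_contaminants: int = 0,
) -> GroundTruthModel:
    """The two-cell-line differential design: one line carries only
    standard 20S, the other only immuno 20S; regulator propensities
    (sP20S, iP20S) encode the planted association ratios."""
    lines = [
        CellLine(
            name="sP_line", replicates=replicates,
            subtype_fractions={"sP20S": 1.0, "iP20S": 0.0, "intermediate": 0.0},
        ),
        CellLine(
            name="iP_line", replicates=replicates,
            subtype_fractions={"sP20S": 0.0, "iP20S": 1.0, "intermediate": 0.0},
        ),
    ]
    propensities = {
        "19S": {"sP20S": 0.5, "iP20S": 0.5},
        "PA28αβ": {"sP20S": pa28ab[0], "iP20S": pa28ab[1]},
        "PA28γ": {"sP20S": 0.35, "iP20S": 0.35},
        "PA200": {"sP20S": 0.5, "iP20S": 0.5},
        "PI31": {"sP20S": pi31[0], "iP20S": pi31[1]},
    }
    return GroundTruthModel(
        seed=seed,
        cell_lines=lines,
        association_propensity=propensities,
        background=Background(n_contaminants=n_contaminants),
    )


@dataclass
class DifferentialTrial:
    pa28ab_relative: float
    pa28ab_p: float
    pi31_relative_sp_over_ip: float
    pi31_p: float
    reference_relative: float


def differential_recovery_trial(seed: int) -> DifferentialTrial:
    """One two-line differential study with planted 4× (PA28αβ, toward the
    immuno line) and 8× (PI31, toward the standard line) ratios."""
    _, defs = default_catalog()
    by_name = {d.name: d for d in defs}
    model = two_line_model(seed)
    dataset = simulate_apms(model)
    matrix, _ = quantify(dataset.peptide_table)
    result = differential_analysis(
        matrix,
        dataset.metadata,
        [by_name["PA28αβ"], by_name["PI31"]],
        by_name["ncP20S"],
        "sP_line",
    )
    pa = result.loc[("PA28αβ", "iP_line")]
    pi = result.loc[("PI31", "iP_line")]
    return DifferentialTrial(
        pa28ab_relative=float(pa["relative_value"]),
        pa28ab_p=float(pa["p_value"]),
        pi31_relative_sp_over_ip=float(1.0 / pi["relative_value"]),
        pi31_p=float(pi["p_value"]),
        reference_relative=float(result.loc[("PA28αβ", "sP_line"), "relative_value"]),
    )


def null_ttest_trial(seed: int, alpha: float = 0.05) -> bool:
    """One null differential dataset (equal propensities, n = 4 per
    condition); returns whether the PA28αβ t-test falsely rejects."""
    _, defs = default_catalog()
    by_name = {d.name: d for d in defs}
    model = two_line_model(seed, pa28ab=(0.5, 0.5), pi31=(0.5, 0.5))
    # under the null both lines carry the same subtype so that the only
    # condition difference is noise
    lines = [
        CellLine(
            name=name, replicates=4,
            subtype_fractions={"sP20S": 1.0, "iP20S": 0.0, "intermediate": 0.0},
        )
        for name in ("sP_line", "iP_line")
    ]
    model = model.model_copy(update={"cell_lines": lines})
    dataset = simulate_apms(model)
    matrix, _ = quantify(dataset.peptide_table)
    result = differential_analysis(
        matrix, dataset.metadata, [by_name["PA28αβ"]], by_name["ncP20S"], "sP_line"
    )
    return bool(result.loc[("PA28αβ", "iP_line"), "p_value"] < alpha)
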
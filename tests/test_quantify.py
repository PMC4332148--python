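import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from proteoplex.quantify import (
    CalibrationError,
    PeptideTableError,
    calibrate_runs,
    compute_pai,
    quantify,
    select_reference_peptides,
    validate_peptide_table,
)
from proteoplex.simulate import Background, GroundTruthModel, PeptideModel, simulate_apms


# --- independent oracle -----------------------------------------------------


def brute_force_pai(table, missing_ref="mean"):
    """Direct re-derivation of TOP3 PAIs: rank peptides by cross-sample
    summed intensity, slice the top three, average per sample."""
    work = table[~table["is_standard"]]
    samples = list(dict.fromkeys(work["sample_id"]))
    out = {}
    for protein in sorted(set(work["protein"])):
        rows = work[work["protein"] == protein]
        totals = {}
        for pid in set(rows["peptide_id"]):
            totals[pid] = rows[rows["peptide_id"] == pid]["xic_area"].sum()
        ranked = sorted(totals, key=lambda p: (-totals[p], p))[:3]
        pai = {}
        for s in samples:
            vals = [
                float(rows[(rows["sample_id"] == s) & (rows["peptide_id"] == p)]["xic_area"].iloc[0])
                for p in ranked
                if not rows[(rows["sample_id"] == s) & (rows["peptide_id"] == p)].empty
            ]
            if not vals:
                pai[s] = np.nan
            elif missing_ref == "mean":
                pai[s] = float(np.mean(vals))
            else:
                pai[s] = float(np.sum(vals) / len(ranked))
        out[protein] = pai
    return pd.DataFrame(out).T.reindex(columns=samples)


def random_table(rng, n_samples=4, n_proteins=3, max_peptides=5, missing=0.2):
    rows = []
    samples = [f"s{i}" for i in range(n_samples)]
    for p in range(n_proteins):
        n_pep = int(rng.integers(1, max_peptides + 1))
        for j in range(n_pep):
            for s in samples:
                if rng.random() < missing:
                    continue
                rows.append(
                    {
                        "sample_id": s,
                        "protein": f"P{p}",
                        "peptide_id": f"P{p}_pep{j}",
                        "xic_area": float(rng.lognormal(10, 1)),
                        "sn_ratio": 20.0,
                        "is_standard": False,
                    }
                )
    # make sure every sample retains at least one row
    df = pd.DataFrame(rows)
    return df[df["sample_id"].isin(samples)]


# --- table contract ---------------------------------------------------------


class TestTableContract:
    def test_duplicate_rows_rejected(self, peptide_table_factory):
        table = peptide_table_factory(
            [("s1", "P1", "a", 10), ("s1", "P1", "a", 12)]
        )
        with pytest.raises(PeptideTableError, match="duplicate"):
            validate_peptide_table(table)

    def test_negative_intensity_rejected(self, peptide_table_factory):
        table = peptide_table_factory([("s1", "P1", "a", -5)])
        with pytest.raises(PeptideTableError, match="negative"):
            validate_peptide_table(table)


# --- calibration ------------------------------------------------------------


class TestCalibration:
    def test_identical_standards_leave_table_unchanged(self, peptide_table_factory):
        table = peptide_table_factory(
            [
                ("s1", "P1", "a", 100),
                ("s2", "P1", "a", 300),
                ("s1", "STD", "std1", 50, 10, True),
                ("s2", "STD", "std1", 50, 10, True),
            ]
        )
        result = calibrate_runs(table)
        assert (result.factors == 1.0).all()
        pd.testing.assert_frame_equal(result.table, table)

    def test_half_intensity_standards_give_factor_two(self, peptide_table_factory):
        table = peptide_table_factory(
            [
                ("s1", "P1", "a", 100),
                ("s2", "P1", "a", 100),
                ("s3", "P1", "a", 100),
                ("s1", "STD", "std1", 60, 10, True),
                ("s2", "STD", "std1", 60, 10, True),
                ("s3", "STD", "std1", 30, 10, True),
            ]
        )
        result = calibrate_runs(table)
        # cross-sample mean 50; factor for s3 = 50/30, for s1/s2 = 50/60
        assert result.factors["s3"] == pytest.approx(50 / 30)
        assert result.factors["s1"] == pytest.approx(50 / 60)
        calibrated = result.table
        s3 = calibrated[(calibrated["sample_id"] == "s3") & (calibrated["protein"] == "P1")]
        assert s3["xic_area"].iloc[0] == pytest.approx(100 * 50 / 30)

    def test_sample_without_standards_named_in_error(self, peptide_table_factory):
        table = peptide_table_factory(
            [
                ("s1", "P1", "a", 100),
                ("s1", "STD", "std1", 50, 10, True),
                ("s2", "P1", "a", 100),
            ]
        )
        with pytest.raises(CalibrationError, match="s2"):
            calibrate_runs(table)

    def test_calibration_removes_planted_drift(self):
        """Inter-run drift planted by the simulator is fully absorbed:
        post-calibration standard intensities have (numerically) zero CV."""
        model = GroundTruthModel(
            seed=21,
            peptide_model=PeptideModel(noise_cv=0.0, missing_rate=0.0, drift_cv=0.4),
            background=Background(n_contaminants=0),
        )
        ds = simulate_apms(model)
        result = calibrate_runs(ds.peptide_table)
        std = result.table[result.table["is_standard"]]
        stats = std.groupby("peptide_id")["xic_area"].agg(["std", "mean"])
        assert (stats["std"] / stats["mean"]).max() < 1e-10
        # factors invert the planted run scales up to one global constant
        planted = pd.Series(
            {s: d["run_scale"] for s, d in ds.truth["samples"].items()}
        )
        product = result.factors * planted
        assert product.max() / product.min() == pytest.approx(1.0, abs=1e-10)


# --- reference peptide selection -------------------------------------------


class TestReferenceSelection:
    def test_top3_by_cross_sample_sum(self, peptide_table_factory):
        rows = []
        for pid, sums in [("a", [5, 5]), ("b", [15, 15]), ("c", [10, 10]), ("d", [2, 3])]:
            for i, v in enumerate(sums):
                rows.append((f"s{i}", "P1", pid, v))
        refs = select_reference_peptides(peptide_table_factory(rows))
        assert refs["P1"] == ["b", "c", "a"]

    def test_proteins_with_fewer_peptides_keep_all(self, peptide_table_factory):
        table = peptide_table_factory([("s1", "P1", "a", 10), ("s1", "P1", "b", 20)])
        assert select_reference_peptides(table)["P1"] == ["b", "a"]

    def test_exact_tie_breaks_lexicographically(self, peptide_table_factory):
        table = peptide_table_factory(
            [
                ("s1", "P1", "w", 30),
                ("s1", "P1", "x", 20),
                ("s1", "P1", "z", 10),
                ("s1", "P1", "y", 10),
            ]
        )
        assert select_reference_peptides(table)["P1"] == ["w", "x", "y"]


# --- PAI --------------------------------------------------------------------


class TestPai:
    def test_mean_of_three_references(self, peptide_table_factory):
        table = peptide_table_factory(
            [("s1", "P1", "a", 100), ("s1", "P1", "b", 200), ("s1", "P1", "c", 300)]
        )
        matrix = compute_pai(table)
        assert matrix.values.loc["P1", "s1"] == pytest.approx(200)

    def test_mean_over_observed_references(self, peptide_table_factory):
        table = peptide_table_factory(
            [
                ("s1", "P1", "a", 50),
                ("s1", "P1", "b", 150),
                ("s1", "P1", "c", 300),
                ("s2", "P1", "a", 50),
                ("s2", "P1", "b", 150),
            ]
        )
        matrix = compute_pai(table)
        assert matrix.values.loc["P1", "s2"] == pytest.approx(100)

    def test_zero_imputation_policy(self, peptide_table_factory):
        table = peptide_table_factory(
            [
                ("s1", "P1", "a", 50),
                ("s1", "P1", "b", 150),
                ("s1", "P1", "c", 300),
                ("s2", "P1", "a", 50),
                ("s2", "P1", "b", 150),
            ]
        )
        matrix = compute_pai(table, missing_ref="zero")
        assert matrix.values.loc["P1", "s2"] == pytest.approx(200 / 3)

    def test_peptide_support_reported(self, peptide_table_factory):
        table = peptide_table_factory(
            [("s1", "P1", "a", 10, 5), ("s1", "P1", "b", 20, 15), ("s1", "P2", "a", 9, 30)]
        )
        matrix = compute_pai(table)
        assert matrix.peptide_support.loc["P1", "n_ref_peptides"] == 2
        assert matrix.peptide_support.loc["P1", "median_sn"] == pytest.approx(10)
        assert matrix.peptide_support.loc["P2", "n_ref_peptides"] == 1

    @pytest.mark.parametrize("missing_ref", ["mean", "zero"])
    def test_oracle_equivalence_on_random_tables(self, rng, missing_ref):
        """TOP3 PAIs match a from-scratch rank/slice/average recomputation."""
        for _ in range(50):
            table = random_table(rng)
            got = compute_pai(table, missing_ref=missing_ref).values
            want = brute_force_pai(table, missing_ref=missing_ref)
            got, want = got.align(want)
            pd.testing.assert_frame_equal(got, want, rtol=1e-12, check_names=False)

    def test_scale_equivariance(self, peptide_table_factory):
        """Scaling one run (standards included) is absorbed by calibration.

        Calibration fixes the relative, not absolute, intensity scale: the
        recalibrated PAIs equal the originals up to one global constant
        (the cross-sample reference level shifts with the scaled run).
        """
        rows = [
            ("s1", "P1", "a", 100), ("s1", "P1", "b", 220),
            ("s2", "P1", "a", 90), ("s2", "P1", "b", 260),
            ("s3", "P1", "a", 120), ("s3", "P1", "b", 180),
        ]
        for s in ("s1", "s2", "s3"):
            rows += [(s, "STD", "std1", 40, 10, True), (s, "STD", "std2", 70, 10, True)]
        base = peptide_table_factory(rows)
        scaled = base.copy()
        k = 7.5
        scaled.loc[scaled["sample_id"] == "s2", "xic_area"] *= k
        got_base, _ = quantify(base)
        got_scaled, _ = quantify(scaled)
        ratio = got_scaled.values / got_base.values
        expected_global = (2 + k) / 3  # reference-level shift from the scaled run
        assert np.allclose(ratio.to_numpy(), expected_global, rtol=1e-12)

    @given(bump=st.floats(min_value=0.0, max_value=1e6, allow_nan=False))
    def test_pai_monotone_in_reference_intensity(self, bump):
        table = pd.DataFrame(
            {
                "sample_id": ["s1"] * 3,
                "protein": ["P1"] * 3,
                "peptide_id": ["a", "b", "c"],
                "xic_area": [100.0, 200.0, 300.0],
                "is_standard": [False] * 3,
            }
        )
        before = compute_pai(table).values.loc["P1", "s1"]
        bumped = table.copy()
        bumped.loc[bumped["peptide_id"] == "b", "xic_area"] += bump
        after = compute_pai(bumped).values.loc["P1", "s1"]
        assert after >= before
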
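"""Plate normalization, candidate selection, validation rule, statistics."""

import numpy as np
import pandas as pd
import pytest

from junctionscreen.screen import (
    PlateZScorer,
    aggregate_and_select,
    correlate_parameters,
    plate_zscores,
    validate_oligos,
    validate_oligo_table,
)
from junctionscreen.screen import test_normality as shapiro_normality


def _plate(samples, controls, plate="P01", role="pos_ctrl"):
    rows = []
    for i, v in enumerate(controls):
        rows.append((plate, f"C{i:02d}", "CTRL", "none", role, 1, True, v, v, v))
    for i, v in enumerate(samples):
        rows.append((plate, f"S{i:02d}", f"G{i}", "pool", "sample", 1, True, v, v, v))
    return pd.DataFrame(
        rows,
        columns=[
            "plate", "well", "gene", "oligo", "role", "replicate", "qc_pass",
            "ecad_raw", "juna_raw", "cyta_raw",
        ],
    )


class TestPlateZScores:
    def test_closed_form_moment_zscore(self):
        # controls mean 50 SD 10, sample 66.5 -> z = 1.65 exactly
        controls = [40.0, 50.0, 60.0, 50.0]  # mean 50, ddof=0 SD = sqrt(50)
        controls = [50 - 10, 50 + 10, 50 - 10, 50 + 10]  # mean 50, SD 10
        z = plate_zscores(_plate([66.5], controls), robust=False)
        sample = z[z["role"] == "sample"]
        assert sample["z_ecad"].iloc[0] == pytest.approx(1.65, abs=1e-12)

    def test_sample_at_control_center_scores_zero(self):
        z = plate_zscores(_plate([50.0], [40, 45, 50, 55, 60]), robust=True)
        assert z[z["role"] == "sample"]["z_ecad"].iloc[0] == pytest.approx(0.0)

    def test_location_invariance(self):
        base = _plate([37.0, 62.0, 55.0], [40, 50, 60, 50])
        shifted = base.copy()
        for c in ("ecad_raw", "juna_raw", "cyta_raw"):
            shifted[c] = shifted[c] + 123.4
        for robust in (True, False):
            z0 = plate_zscores(base, robust=robust)
            z1 = plate_zscores(shifted, robust=robust)
            np.testing.assert_allclose(z0["z_ecad"], z1["z_ecad"], atol=1e-9)

    def test_zero_scale_controls_flagged_not_infinite(self):
        scorer = PlateZScorer(robust=False)
        z = scorer.fit_transform(_plate([60.0], [50.0, 50.0, 50.0]))
        assert scorer.plate_stats_["flagged"].all()
        assert z[z["role"] == "sample"]["z_ecad"].isna().all()

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError):
            plate_zscores(_plate([60.0], [50.0]))

    def test_idempotence_on_standardized_controls(self):
        # Z-scoring already-Z-scored controls: center 0, scale 1
        ctrl = np.array([-1.5, -0.5, 0.5, 1.5])
        ctrl = (ctrl - ctrl.mean()) / ctrl.std()
        scorer = PlateZScorer(robust=False).fit(_plate([], ctrl.tolist()))
        stats = scorer.plate_stats_.iloc[0]
        assert stats["center_ecad_raw"] == pytest.approx(0.0, abs=1e-12)
        assert stats["scale_ecad_raw"] == pytest.approx(1.0, abs=1e-12)


class TestAggregateAndSelect:
    def _ztable(self, gene_reps):
        rows = []
        for gene, reps in gene_reps.items():
            for r, (z, qc) in enumerate(reps, start=1):
                rows.append(
                    {
                        "gene": gene, "role": "sample", "replicate": r,
                        "qc_pass": qc, "z_ecad": z, "z_juna": 0.0, "z_cyta": 0.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_median_of_replicates_and_candidate_calls(self):
        agg, _ = aggregate_and_select(
            self._ztable(
                {
                    "A": [(2.0, True), (1.0, True), (1.8, True)],
                    "B": [(-2.0, True), (-2.0, True), (9.0, True)],
                    "C": [(1.65, True), (1.65, True), (1.65, True)],
                }
            )
        )
        a = agg.set_index("gene")
        assert a.loc["A", "median_z_ecad"] == pytest.approx(1.8)
        assert bool(a.loc["A", "candidate"])
        assert a.loc["B", "median_z_ecad"] == pytest.approx(-2.0)  # outlier-robust
        assert bool(a.loc["B", "candidate"])
        assert not bool(a.loc["C", "candidate"])  # boundary is strict

    def test_all_qc_failed_gene_goes_to_rejects(self):
        agg, rejects = aggregate_and_select(
            self._ztable({"A": [(2.0, True)], "B": [(5.0, False), (5.0, False)]})
        )
        assert list(rejects["gene"]) == ["B"]
        assert "B" not in set(agg["gene"])

    def test_qc_failed_replicates_excluded_from_median(self):
        agg, _ = aggregate_and_select(
            self._ztable({"A": [(2.0, True), (2.0, True), (99.0, False)]})
        )
        assert agg["median_z_ecad"].iloc[0] == pytest.approx(2.0)

    def test_phenotype_multiplicity(self):
        df = pd.DataFrame(
            [
                {"gene": "T", "role": "sample", "replicate": 1, "qc_pass": True,
                 "z_ecad": 3.0, "z_juna": -3.0, "z_cyta": 2.0},
                {"gene": "S", "role": "sample", "replicate": 1, "qc_pass": True,
                 "z_ecad": 3.0, "z_juna": 0.0, "z_cyta": 0.0},
            ]
        )
        agg, _ = aggregate_and_select(df)
        a = agg.set_index("gene")
        assert a.loc["T", "phenotype_multiplicity"] == "triple"
        assert a.loc["S", "phenotype_multiplicity"] == "single"


class TestValidateOligos:
    @pytest.mark.parametrize(
        "zs,expected",
        [
            ((2.0, 1.9, -0.3, 0.1), "validated_up"),
            ((2.0, 2.0, -2.0, -2.0), "ambiguous"),
            ((1.0, 1.2, -0.5, 0.0), "not_validated"),
            ((-1.4, -1.2, 0.3, 0.0), "validated_down"),
            ((2.0, -0.2, 0.1, 0.3), "not_validated"),  # one oligo not enough
            ((2.0, 1.1, -1.2, -1.3), "ambiguous"),
        ],
    )
    def test_four_oligo_rule(self, zs, expected):
        assert validate_oligos(zs, cutoff=1.0) == expected

    def test_fewer_than_four_oligos_warns(self):
        with pytest.warns(UserWarning):
            assert validate_oligos((2.0, 2.0, 1.9), cutoff=1.0) == "validated_up"

    def test_table_wrapper(self):
        df = pd.DataFrame(
            {
                "gene": ["A"] * 4 + ["B"] * 4,
                "oligo": list("1234") * 2,
                "median_z_ecad": [2, 2, 0, 0, -2, -2, 2, 2],
            }
        )
        calls = validate_oligo_table(df, cutoff=1.0).set_index("gene")["call"]
        assert calls["A"] == "validated_up" and calls["B"] == "ambiguous"


class TestCorrelations:
    def test_perfect_correlation(self):
        df = pd.DataFrame({"median_z_ecad": [1.0, 2, 3, 4], "median_z_juna": [2.0, 4, 6, 8]})
        out = correlate_parameters(df, [("median_z_ecad", "median_z_juna")])
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        hits = 0
        for s in range(20):
            r = np.random.default_rng(s)
            df = pd.DataFrame(
                {"median_z_ecad": r.normal(size=300), "median_z_juna": r.normal(size=300)}
            )
            out = correlate_parameters(df, [("median_z_ecad", "median_z_juna")])
            hits += abs(out["r"].iloc[0]) < 0.2
        assert hits >= 19

    def test_planted_common_factor_recovered(self):
        # true rho = 0.65 at n = 156: estimate within +/- 0.15
        estimates = []
        for s in range(10):
            r = np.random.default_rng(s)
            z = r.standard_normal((156, 2))
            x = z[:, 0]
            y = 0.65 * z[:, 0] + np.sqrt(1 - 0.65**2) * z[:, 1]
            df = pd.DataFrame({"median_z_ecad": x, "median_z_juna": y})
            out = correlate_parameters(df, [("median_z_ecad", "median_z_juna")])
            estimates.append(out["r"].iloc[0])
        assert np.median(np.abs(np.array(estimates) - 0.65)) < 0.15

    def test_constant_column_reported_missing(self):
        df = pd.DataFrame({"median_z_ecad": [1.0, 1, 1, 1], "median_z_juna": [1.0, 2, 3, 4]})
        out = correlate_parameters(df, [("median_z_ecad", "median_z_juna")])
        assert np.isnan(out["r"].iloc[0])


class TestNormality:
    def test_normal_sample_rarely_rejected(self):
        passes = sum(
            shapiro_normality(np.random.default_rng(s).normal(size=500))["p_raw"] > 0.05
            for s in range(10)
        )
        assert passes >= 8

    def test_lognormal_rejected_raw_but_not_after_transform(self):
        x = np.random.default_rng(3).lognormal(size=800)
        r = shapiro_normality(x)
        assert r["p_raw"] < 1e-6
        assert r["p_log"] > 0.05

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            shapiro_normality(np.ones(20))

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            shapiro_normality([1.0, 2.0, 3.0])
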
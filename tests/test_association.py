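"""Density binning, paired contrasts, structure enrichment, clustering."""

import numpy as np
import pandas as pd
import pytest

from editome.association import (
    BinnedDensitySpec,
    binned_density_correlation,
    cluster_libraries,
    halfgene_paired_test,
    matched_conservation_contrast,
    rank_bins,
    structure_enrichment_test,
    temperature_shift_analysis,
)

from conftest import binom_tail_oracle


class TestRankBins:
    def test_equal_sizes_and_determinism(self):
        v = pd.Series(np.random.default_rng(0).normal(size=200))
        b1, b2 = rank_bins(v, 20), rank_bins(v, 20)
        assert (b1 == b2).all()
        assert b1.value_counts().nunique() == 1  # 10 per bin

    def test_monotone_in_covariate(self):
        v = pd.Series(np.arange(40.0))
        b = rank_bins(v, 4)
        assert (b.diff().dropna() >= 0).all()


class TestBinnedDensity:
    def _bg(self, densities, per_bin=50):
        rows = []
        for b, d in enumerate(densities):
            n_edit = int(round(d * per_bin))
            for i in range(per_bin):
                rows.append({"covariate": float(b * per_bin + i),
                             "edited": i < n_edit, "level": 0.3})
        return pd.DataFrame(rows)

    def test_flat_density_reports_zero_rho_with_tie_flag(self):
        bg = self._bg([0.2] * 20)
        out = binned_density_correlation(bg, BinnedDensitySpec("covariate"))
        assert out["rho"] == 0.0 and out["tied"]

    def test_strictly_increasing_density_gives_rho_one(self):
        bg = self._bg(np.linspace(0.0, 0.95, 20))
        out = binned_density_correlation(bg, BinnedDensitySpec("covariate"))
        assert out["rho"] == pytest.approx(1.0)
        assert out["p"] < 1e-10

    def test_positional_gradient_detected(self):
        """Editing probability increasing along the transcript yields a
        positive density trend over 20 position bins."""
        rng = np.random.default_rng(1)
        n = 4000
        relpos = rng.uniform(0, 1, n)
        edited = rng.random(n) < 0.02 + 0.10 * relpos
        bg = pd.DataFrame({"covariate": relpos, "edited": edited, "level": 0.3})
        out = binned_density_correlation(bg, BinnedDensitySpec("covariate"))
        assert out["rho"] > 0 and out["p"] < 0.05

    def test_level_weighted_variant(self):
        bg = self._bg([0.5] * 20)
        spec = BinnedDensitySpec("covariate", weighting="level_weighted")
        out = binned_density_correlation(bg, spec)
        assert out["table"]["density"].iloc[0] == pytest.approx(0.5 * 0.3)


class TestHalfGene:
    def test_identical_halves_give_null(self):
        df = pd.DataFrame({"front": [0.1] * 20, "rear": [0.1] * 20})
        out = halfgene_paired_test(df)
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_rear_enrichment_detected(self):
        rng = np.random.default_rng(2)
        front = rng.uniform(0.05, 0.15, 20)
        df = pd.DataFrame({"front": front, "rear": front * 2 + rng.normal(0, 0.005, 20)})
        out = halfgene_paired_test(df)
        assert (df["rear"] > df["front"]).sum() >= 18
        assert out["t"] > 0 and out["p"] < 0.05

    def test_too_few_bins_rejected(self):
        df = pd.DataFrame({"front": [0.1, np.nan], "rear": [0.2, 0.3]})
        with pytest.raises(ValueError, match="usable bins"):
            halfgene_paired_test(df)


class TestMatchedConservation:
    def _bg(self, rng, effect=1.0):
        n = 8000
        coverage = rng.poisson(20, n) + 5
        phylop = rng.normal(0, 1, n)
        base = 0.2
        p = np.minimum(base * np.where(phylop > np.median(phylop), effect, 1.0), 1)
        edited = rng.random(n) < p
        return pd.DataFrame({"coverage": coverage, "phylop": phylop,
                             "edited": edited})

    def test_null_ratio_near_one(self):
        out = matched_conservation_contrast(self._bg(np.random.default_rng(3)))
        assert out["table"]["ratio"].mean() == pytest.approx(1.0, abs=0.25)

    def test_conserved_enrichment_detected(self):
        out = matched_conservation_contrast(
            self._bg(np.random.default_rng(4), effect=2.5)
        )
        assert (out["table"]["ratio"] < 1).sum() >= 16
        assert out["t"] < 0 and out["p"] < 0.001

    def test_all_conserved_edited_gives_zero_ratio(self):
        # editing confined to sites far above every per-bin median split
        rng = np.random.default_rng(5)
        bg = self._bg(rng, effect=1.0)
        bg["edited"] &= bg["phylop"] > 1.5
        out = matched_conservation_contrast(bg)
        assert (out["table"]["ratio"].dropna() == 0).all()


class TestStructureEnrichment:
    HAIRPINS = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [100]})

    def test_everything_in_hairpins_gives_p_one(self):
        sites = [("c", i) for i in range(20)]
        bg = [("c", i) for i in range(100)]
        out = structure_enrichment_test(sites, self.HAIRPINS, bg, 200, seed=0)
        assert out["observed"] == 20
        assert out["p"] == pytest.approx(1.0)

    def test_enrichment_p_matches_binomial_tail(self):
        # background 10% in hairpins, 100 sites, 50 observed inside
        bg = [("c", i) for i in range(1000)]  # positions 0..99 inside
        sites = [("c", i) for i in range(50)] + [("d", i) for i in range(50)]
        out = structure_enrichment_test(sites, self.HAIRPINS, bg, 1000, seed=1)
        assert out["observed"] == 50
        assert out["p"] < 0.001
        assert binom_tail_oracle(100, 50, 0.1) < 1e-20

    def test_deterministic_under_seed(self):
        bg = [("c", i) for i in range(500)]
        sites = [("c", i) for i in range(30)]
        a = structure_enrichment_test(sites, self.HAIRPINS, bg, 300, seed=5)
        b = structure_enrichment_test(sites, self.HAIRPINS, bg, 300, seed=5)
        assert a == b


class TestClusterLibraries:
    def test_identical_libraries_merge_first(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1, 50)
        m = pd.DataFrame({"L1": x, "L2": x, "L3": rng.uniform(0, 1, 50)})
        out = cluster_libraries(m)
        assert out["correlation"].loc["L1", "L2"] == pytest.approx(1.0)
        assert out["newick"].count("L1") == 1
        # first merge joins the identical pair at distance ~0
        assert out["linkage"][0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(out["linkage"][0, 0]), int(out["linkage"][0, 1])} == {0, 1}

    def test_temperature_outweighs_sex_in_merging(self):
        """Libraries sharing a temperature condition (strong planted shift)
        merge before libraries sharing a sex (weak shift)."""
        rng = np.random.default_rng(7)
        base = rng.beta(2, 4, 200)
        temp_shift = -0.08
        sex_shift = 0.01
        noise = lambda: rng.normal(0, 0.01, 200)  # noqa: E731
        m = pd.DataFrame({
            "F_25": base + noise(),
            "M_25": base + sex_shift + noise(),
            "F_30": base + temp_shift + noise(),
            "M_30": base + temp_shift + sex_shift + noise(),
        }).clip(0, 1)
        out = cluster_libraries(m)
        first = {int(out["linkage"][0, 0]), int(out["linkage"][0, 1])}
        second = {int(out["linkage"][1, 0]), int(out["linkage"][1, 1])}
        cols = list(m.columns)
        same_temp_pairs = [{cols.index("F_25"), cols.index("M_25")},
                           {cols.index("F_30"), cols.index("M_30")}]
        assert first in same_temp_pairs and second in same_temp_pairs

    def test_distance_matrix_symmetric_zero_diagonal(self, small_dataset):
        *_, counts = small_dataset
        wide = counts.pivot_table(index=["chrom", "pos"], columns="library_id",
                                  values="level").dropna()
        out = cluster_libraries(wide.iloc[:100])
        corr = out["correlation"]
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_single_library_rejected(self):
        with pytest.raises(ValueError, match="two libraries"):
            cluster_libraries(pd.DataFrame({"L1": [0.1, 0.2]}))


class TestTemperatureShift:
    def test_identical_levels_reported_not_applicable(self):
        shifts = pd.DataFrame({"delta": [0.0] * 10,
                               "category": ["N"] * 5 + ["S"] * 5})
        other = pd.Series([0.0] * 10)
        out = temperature_shift_analysis(shifts, other_species_shifts=other)
        assert out["category_summary"].loc["N", "mean"] == 0.0
        assert out["cross_species"] is None

    def test_planted_category_gap_recovered(self):
        rng = np.random.default_rng(8)
        n_n, n_s = 300, 300
        shifts = pd.DataFrame({
            "delta": np.concatenate([
                rng.normal(-0.01, 0.02, n_n), rng.normal(-0.05, 0.02, n_s)
            ]),
            "category": ["N"] * n_n + ["S"] * n_s,
        })
        out = temperature_shift_analysis(shifts)
        summary = out["category_summary"]
        gap = summary.loc["N", "mean"] - summary.loc["silent", "mean"]
        se = np.hypot(summary.loc["N", "sem"], summary.loc["silent", "sem"])
        assert abs(gap - 0.04) < 3 * se

    def test_cross_species_correlation_of_shared_shifts(self):
        rng = np.random.default_rng(9)
        true = rng.normal(-0.03, 0.05, 200)
        shifts = pd.DataFrame({
            "delta": true + rng.normal(0, 0.02, 200),
            "category": ["N"] * 200,
        })
        other = pd.Series(true + rng.normal(0, 0.02, 200))
        out = temperature_shift_analysis(shifts, other_species_shifts=other)
        assert out["cross_species"]["r"] > 0
        assert out["cross_species"]["p"] < 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            temperature_shift_analysis(pd.DataFrame(columns=["delta", "category"]))
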
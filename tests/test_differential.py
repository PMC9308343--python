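"""NB differential test behaviour and allelic group classification."""

import math

import numpy as np
import pandas as pd
import pytest

from hybridase.differential import (
    allele_specific_summary,
    allelic_deg_pipeline,
    bh_adjust,
    call_degs,
    classify_groups,
    group_counts,
    nb_wald_test,
    relaxed_fold_overlap,
    round_half_up_percent,
    size_factors,
)


def nb_draw(rng, mu, alpha, size):
    lam = rng.gamma(1.0 / alpha, np.asarray(mu) * alpha, size=size)
    return rng.poisson(lam)


class TestSizeFactors:
    def test_identical_columns_give_unity(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_column_scales(self):
        counts = pd.DataFrame({"a": [10, 20, 400], "b": [20, 40, 800]})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_matches_brute_force_median_of_ratios(self, rng):
        # odd gene count: the median is a single element, so the linear-space
        # oracle equals the log-space computation exactly
        counts = pd.DataFrame(rng.integers(1, 1000, size=(101, 4)))
        sf = size_factors(counts)
        mat = counts.to_numpy(dtype=float)
        geo = np.exp(np.mean(np.log(mat), axis=1))
        raw = np.array([np.median(mat[:, j] / geo) for j in range(4)])
        raw /= np.exp(np.mean(np.log(raw)))
        assert np.allclose(sf.to_numpy(), raw)

    def test_no_universally_expressed_gene_errors(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError):
            size_factors(counts)


class TestBhAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_step_up(self):
        # ranks 1..4, n=4: min over j>=i of p_j*4/j = 0.04 for all
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, 0.04)

    def test_all_ones(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestNbWald:
    def test_identical_group_means_are_null(self, rng):
        base = rng.integers(50, 500, size=60)
        counts = pd.DataFrame(np.tile(base[:, None], (1, 6)))
        res = nb_wald_test(counts, ["wt"] * 3 + ["KO"] * 3)
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["p_value"] > 0.9).all()

    def test_planted_eightfold_effect_recovered(self, rng):
        n, n_eff = 500, 30
        mu = rng.lognormal(np.log(150), 0.8, n)
        fold = np.ones(n)
        fold[:n_eff] = 8.0
        a = nb_draw(rng, mu[:, None], 0.05, (n, 3))
        b = nb_draw(rng, (mu * fold)[:, None], 0.05, (n, 3))
        counts = pd.DataFrame(np.hstack([a, b]))
        res = call_degs(nb_wald_test(counts, ["wt"] * 3 + ["KO"] * 3))
        assert (res["direction"].iloc[:n_eff] == "up").all()

    def test_null_type_one_error_near_nominal(self, rng):
        rates = []
        for _ in range(3):
            mu = rng.lognormal(np.log(100), 1.0, 2000)
            counts = pd.DataFrame(nb_draw(rng, mu[:, None], 0.1, (2000, 6)))
            res = nb_wald_test(counts, ["wt"] * 3 + ["KO"] * 3)
            rates.append(float((res["p_value"] < 0.05).mean()))
        assert 0.02 < np.mean(rates) < 0.09

    def test_single_level_design_rejected(self):
        counts = pd.DataFrame(np.ones((5, 4), dtype=int))
        with pytest.raises(ValueError):
            nb_wald_test(counts, ["wt"] * 4)


class TestCallDegs:
    def records(self, fdr, log2fc):
        return pd.DataFrame(
            {"log2fc": [log2fc], "fdr": [fdr], "p_value": [fdr]},
            index=pd.Index(["g"], name="gene_id"),
        )

    def test_boundary_fold_change_called(self):
        out = call_degs(self.records(0.04, -0.60))
        assert out.loc["g", "direction"] == "down"

    def test_fdr_above_threshold_is_ns(self):
        out = call_degs(self.records(0.06, -2.0))
        assert out.loc["g", "direction"] == "ns"

    def test_exclusion_list_removes_gene(self):
        out = call_degs(self.records(0.001, -2.0), exclude=["g"])
        assert "g" not in out.index


def direction_frame(**genes):
    """gene -> direction shortcut for classify_groups inputs."""
    return pd.DataFrame(
        {"direction": list(genes.values())},
        index=pd.Index(list(genes.keys()), name="gene_id"),
    )


class TestGroups:
    def test_maternal_down_only_is_group_a(self):
        labels = classify_groups(
            direction_frame(g1="down"), direction_frame(g1="ns")
        )
        assert labels.loc["g1", "down_group"] == "A"
        assert labels.loc["g1", "up_group"] == "none"

    def test_both_down_is_group_c(self):
        labels = classify_groups(
            direction_frame(g1="down"), direction_frame(g1="down")
        )
        assert labels.loc["g1", "down_group"] == "C"

    def test_opposite_directions_carry_two_groups(self):
        labels = classify_groups(
            direction_frame(g1="up"), direction_frame(g1="down")
        )
        assert labels.loc["g1", "up_group"] == "D"
        assert labels.loc["g1", "down_group"] == "B"

    def test_partition_of_down_set(self, rng):
        """{A,B,C} are disjoint and cover all allelic down DEGs exactly."""
        genes = [f"g{i}" for i in range(200)]
        mat = direction_frame(**{
            g: rng.choice(["down", "up", "ns"]) for g in genes
        })
        pat = direction_frame(**{
            g: rng.choice(["down", "up", "ns"]) for g in genes
        })
        labels = classify_groups(mat, pat)
        down_all = set(mat.index[mat.direction == "down"]) | set(
            pat.index[pat.direction == "down"]
        )
        by_group = {
            g: set(labels.index[labels.down_group == g]) for g in "ABC"
        }
        assert by_group["A"] | by_group["B"] | by_group["C"] == down_all
        assert not (by_group["A"] & by_group["B"])
        assert not (by_group["A"] & by_group["C"])
        assert not (by_group["B"] & by_group["C"])

    def test_contrast_flip_maps_down_groups_to_up_groups(self, rng):
        """Swapping wt/KO labels turns each down call into the mirror-image
        up call, mapping {A,B,C} onto {D,E,F} gene-for-gene."""
        mu = rng.lognormal(np.log(200), 0.5, 300)
        fold = np.ones(300)
        fold[:30] = 0.2
        a = nb_draw(rng, mu[:, None], 0.05, (300, 3))
        b = nb_draw(rng, (mu * fold)[:, None], 0.05, (300, 3))
        counts = pd.DataFrame(np.hstack([a, b]))
        cond = ["wt"] * 3 + ["KO"] * 3
        flipped = ["KO"] * 3 + ["wt"] * 3
        fwd = call_degs(nb_wald_test(counts, cond))
        rev = call_degs(nb_wald_test(counts, flipped))
        flip = {"down": "up", "up": "down", "ns": "ns"}
        assert (rev["direction"] == fwd["direction"].map(flip)).all()

    def test_allele_specific_percentage(self):
        counts = {"A": 109, "B": 58, "C": 27, "D": 0, "E": 0, "F": 0}
        summary = allele_specific_summary(counts)
        assert summary["down"]["allele_specific_percent"] == 86

    def test_round_half_up(self):
        assert round_half_up_percent(1, 8) == 13  # 12.5 rounds up
        assert round_half_up_percent(167, 194) == 86


class TestAllelicPipeline:
    def test_low_tpm_genes_filtered_and_masking_respected(self, rng):
        genes = [f"g{i}" for i in range(40)]
        counts = pd.DataFrame(
            nb_draw(rng, 200.0, 0.05, (40, 6)), index=genes
        )
        tpm = pd.DataFrame(np.full((40, 6), 10.0), index=genes)
        tpm.iloc[0] = 0.5  # below the allelic TPM floor everywhere
        mat, pat = allelic_deg_pipeline(
            counts, counts, ["wt"] * 3 + ["KO"] * 3,
            maternal_tpm=tpm, paternal_tpm=tpm,
            masked_paternal=["g1"],
        )
        assert "g0" not in mat.index and "g0" not in pat.index
        assert "g1" in mat.index and "g1" not in pat.index

    def test_single_allele_effect_found_on_one_list_only(self, rng):
        n = 300
        mu = np.full(n, 300.0)
        mat_fold = np.ones(n)
        mat_fold[:20] = 0.25  # maternal-only knockdown
        mat_wt = nb_draw(rng, mu[:, None], 0.05, (n, 3))
        mat_ko = nb_draw(rng, (mu * mat_fold)[:, None], 0.05, (n, 3))
        pat = nb_draw(rng, mu[:, None], 0.05, (n, 6))
        genes = [f"g{i}" for i in range(n)]
        mat_counts = pd.DataFrame(np.hstack([mat_wt, mat_ko]), index=genes)
        pat_counts = pd.DataFrame(pat, index=genes)
        mres, pres = allelic_deg_pipeline(
            mat_counts, pat_counts, ["wt"] * 3 + ["KO"] * 3
        )
        labels = classify_groups(mres, pres)
        planted = {f"g{i}" for i in range(20)}
        found_a = set(labels.index[labels.down_group == "A"])
        assert len(planted & found_a) >= 18
        assert not set(labels.index[labels.down_group == "B"]) & planted


class TestRelaxedOverlap:
    def test_boundary_ratio_called(self):
        means = {
            "BC": (pd.Series({"g": 10.0}), pd.Series({"g": 8.0})),
            "CB": (pd.Series({"g": 10.0}), pd.Series({"g": 8.0})),
        }
        out = relaxed_fold_overlap(means)
        assert out["shared_down"] == {"g"}

    def test_sub_threshold_not_called(self):
        means = {
            "BC": (pd.Series({"g": 10.0}), pd.Series({"g": 9.0})),
            "CB": (pd.Series({"g": 10.0}), pd.Series({"g": 8.0})),
        }
        out = relaxed_fold_overlap(means)
        assert out["shared_down"] == set()

    def test_planted_shared_effects_recovered(self, rng):
        genes = [f"g{i}" for i in range(500)]
        base = pd.Series(rng.uniform(5, 100, 500), index=genes)
        shared = set(genes[:40])
        out_sets = {}
        for cross in ("BC", "CB"):
            noise = rng.lognormal(0, 0.02, 500)
            ko = base * noise
            ko.loc[list(shared)] = base.loc[list(shared)] / 2
            out_sets[cross] = (base, ko)
        result = relaxed_fold_overlap(out_sets)
        assert shared <= result["shared_down"]
        assert len(result["shared_down"] - shared) <= 5
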
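"""Score construction: LD r², clumping, orientation, scaling, quartiles,
partitioned fixed-loci scores, and the genome-wide threshold scan."""

import numpy as np
import pandas as pd
import pytest

from cafescore.config import GpsConfig
from cafescore.scores import (assign_quartiles, best_fit_threshold, build_gps,
                              clump, filter_gps_weights, ld_r2, make_score_set,
                              partition_scores, raw_score, scale_prs,
                              validate_weights)

from conftest import toy_genotypes


def weights_from_variants(variants, beta, p, cns=None):
    """Weight table aligned to genotype metadata (same effect allele)."""
    df = pd.DataFrame({
        "ID": variants["id"].tolist(), "CHR": variants["chrom"].tolist(),
        "POS": variants["pos"].tolist(), "EA": variants["a1"].tolist(),
        "OA": variants["a0"].tolist(), "BETA": beta, "P": p,
    })
    if cns is not None:
        df["CNS"] = cns
    return df


def weight_table(ids, chrom, pos, beta, p, ea="A", oa="G", cns=None):
    m = len(ids)
    df = pd.DataFrame({
        "ID": ids, "CHR": chrom, "POS": pos,
        "EA": [ea] * m if isinstance(ea, str) else ea,
        "OA": [oa] * m if isinstance(oa, str) else oa,
        "BETA": beta, "P": p,
    })
    if cns is not None:
        df["CNS"] = cns
    return df


class TestLdR2:
    def test_worked_example(self):
        # r = 2/sqrt(5.6) so r² = 5/7
        assert ld_r2([0, 1, 2, 0, 1], [0, 1, 2, 1, 1]) == pytest.approx(5 / 7)

    def test_perfect_and_inverted_correlation(self):
        assert ld_r2([0, 1, 2], [0, 1, 2]) == pytest.approx(1.0)
        assert ld_r2([0, 1, 2], [2, 1, 0]) == pytest.approx(1.0)

    def test_symmetry(self):
        a, b = [0, 2, 1, 0, 2], [1, 1, 0, 2, 2]
        assert ld_r2(a, b) == pytest.approx(ld_r2(b, a))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            ld_r2([1, 1, 1], [0, 1, 2])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ld_r2([0, 1], [0, 1, 2])


def naive_clump(weights, genotypes, cfg):
    """Literal re-implementation of the greedy clump rule for small inputs."""
    order = weights.sort_values(["P", "POS", "ID"], kind="mergesort")
    cols = {v: j for j, v in enumerate(genotypes.variants["id"])}
    retired, kept = set(), []
    for _, row in order.iterrows():
        if row["ID"] in retired:
            continue
        kept.append(row["ID"])
        retired.add(row["ID"])
        x = genotypes.dosage[:, cols[row["ID"]]]
        for _, other in order.iterrows():
            if other["ID"] in retired:
                continue
            if other["CHR"] != row["CHR"]:
                continue
            if abs(other["POS"] - row["POS"]) > cfg.clump_window:
                continue
            y = genotypes.dosage[:, cols[other["ID"]]]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            if np.corrcoef(x, y)[0, 1] ** 2 > cfg.clump_r2:
                retired.add(other["ID"])
    meta = weights.set_index("ID")
    return sorted(kept, key=lambda v: (meta.at[v, "CHR"], meta.at[v, "POS"]))


class TestClump:
    def test_two_correlated_variants_keep_smaller_p(self, gps_config):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.4, 300).astype(float)
        dos = np.column_stack([x, x])  # perfect LD
        gm = toy_genotypes(dos, pos=[100, 200])
        w = weight_table(["v0", "v1"], [1, 1], [100, 200],
                         [0.1, 0.1], [0.5, 1e-8])
        assert clump(w, gm, gps_config) == ["v1"]

    def test_correlated_but_distant_variants_both_kept(self, gps_config):
        rng = np.random.default_rng(1)
        x = rng.binomial(2, 0.4, 300).astype(float)
        gm = toy_genotypes(np.column_stack([x, x]), pos=[100, 100 + 300_001])
        w = weight_table(["v0", "v1"], [1, 1], [100, 100 + 300_001],
                         [0.1, 0.1], [0.5, 1e-8])
        assert clump(w, gm, gps_config) == ["v0", "v1"]

    def test_correlated_on_different_chromosomes_both_kept(self, gps_config):
        rng = np.random.default_rng(2)
        x = rng.binomial(2, 0.4, 300).astype(float)
        gm = toy_genotypes(np.column_stack([x, x]), chrom=[1, 2], pos=[100, 100])
        w = weight_table(["v0", "v1"], [1, 2], [100, 100],
                         [0.1, 0.1], [0.5, 1e-8])
        assert sorted(clump(w, gm, gps_config)) == ["v0", "v1"]

    def test_matches_naive_oracle_on_random_instances(self, gps_config):
        rng = np.random.default_rng(3)
        for _ in range(200):
            m = int(rng.integers(2, 13))
            n = 40
            p_allele = rng.uniform(0.15, 0.85, m)
            dos = rng.binomial(2, p_allele, (n, m)).astype(float)
            # induce some LD by copying columns
            for j in range(1, m):
                if rng.random() < 0.4:
                    dos[:, j] = dos[:, j - 1]
            chrom = rng.integers(1, 3, m)
            pos = rng.integers(1, 600_000, m)
            ids = [f"v{j}" for j in range(m)]
            gm = toy_genotypes(dos, chrom=chrom, pos=pos, ids=ids)
            w = weight_table(ids, chrom, pos, rng.normal(0, 0.1, m),
                             rng.uniform(1e-10, 1, m))
            assert clump(w, gm, gps_config) == naive_clump(w, gm, gps_config)

    def test_retained_set_is_mutually_unlinked(self, small_genotypes, gps_config):
        v = small_genotypes.variants
        rng = np.random.default_rng(4)
        w = weight_table(v["id"].tolist(), v["chrom"].tolist(), v["pos"].tolist(),
                         rng.normal(0, 0.1, len(v)), rng.uniform(1e-10, 1, len(v)))
        kept = clump(w, small_genotypes, gps_config)
        meta = v.set_index("id")
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                if meta.at[a, "chrom"] != meta.at[b, "chrom"]:
                    continue
                if abs(meta.at[a, "pos"] - meta.at[b, "pos"]) > gps_config.clump_window:
                    continue
                r2 = ld_r2(small_genotypes.column(a), small_genotypes.column(b))
                assert r2 <= gps_config.clump_r2 + 1e-12

    def test_unknown_variant_rejected(self, small_genotypes, gps_config):
        w = weight_table(["nope"], [1], [100], [0.1], [0.5])
        with pytest.raises(ValueError, match="absent"):
            clump(w, small_genotypes, gps_config)


class TestScoring:
    def test_raw_and_scaled_worked_example(self):
        # betas (0.1, 0.3), dosages (1, 2): raw = 0.7, scaled = 0.7·4/0.8 = 3.5
        gm = toy_genotypes(np.array([[1.0, 2.0]]))
        w = weight_table(["v0", "v1"], [1, 1], [1, 1001], [0.1, 0.3], [0.5, 0.5])
        raw = raw_score(w, gm)
        assert raw[0] == pytest.approx(0.7)
        assert scale_prs(raw, w)[0] == pytest.approx(3.5)

    def test_scaled_score_bounded_by_twice_variant_count(self, small_genotypes):
        v = small_genotypes.variants.head(20)
        rng = np.random.default_rng(5)
        w = weights_from_variants(v, rng.normal(0, 0.1, 20),
                                  rng.uniform(0.001, 1, 20))
        ss = make_score_set("s", w, small_genotypes)
        assert (ss.scaled >= -1e-9).all() and (ss.scaled <= 2 * 20 + 1e-9).all()

    def test_allele_swap_with_negated_beta_is_equivalent(self):
        rng = np.random.default_rng(6)
        dos = rng.binomial(2, 0.4, (50, 2)).astype(float)
        gm = toy_genotypes(dos)  # alleles A (counted) / G
        direct = weight_table(["v0", "v1"], [1, 1], [1, 1001],
                              [0.2, 0.1], [0.5, 0.5], ea="A", oa="G")
        swapped = weight_table(["v0", "v1"], [1, 1], [1, 1001],
                               [-0.2, -0.1], [0.5, 0.5], ea="G", oa="A")
        np.testing.assert_allclose(raw_score(direct, gm), raw_score(swapped, gm))

    def test_strand_complement_resolved(self):
        rng = np.random.default_rng(7)
        dos = rng.binomial(2, 0.4, (50, 1)).astype(float)
        gm = toy_genotypes(dos)  # A/G -> complement T/C
        direct = weight_table(["v0"], [1], [1], [0.2], [0.5], ea="A", oa="G")
        comp = weight_table(["v0"], [1], [1], [0.2], [0.5], ea="T", oa="C")
        np.testing.assert_allclose(raw_score(direct, gm), raw_score(comp, gm))

    def test_allele_mismatch_rejected(self):
        gm = toy_genotypes(np.zeros((4, 1)) + 1.0)
        w = weight_table(["v0"], [1], [1], [0.2], [0.5], ea="C", oa="G")
        with pytest.raises(ValueError, match="mismatch"):
            raw_score(w, gm)

    def test_missing_dosage_imputed_at_twice_allele_frequency(self):
        dos = np.array([[0.0], [1.0], [2.0], [np.nan]])
        gm = toy_genotypes(dos, freq=[0.5])
        w = weight_table(["v0"], [1], [1], [1.0], [0.5])
        raw = raw_score(w, gm)
        assert raw[3] == pytest.approx(2 * 0.5)

    def test_zero_weight_sum_rejected(self):
        w = weight_table(["v0"], [1], [1], [0.0], [0.5])
        with pytest.raises(ValueError, match="positive"):
            scale_prs(np.zeros(3), w)

    def test_standardized_score_has_mean_zero_sd_one(self, small_genotypes):
        v = small_genotypes.variants.head(10)
        w = weights_from_variants(v, np.linspace(0.01, 0.1, 10), [0.5] * 10)
        ss = make_score_set("s", w, small_genotypes)
        assert abs(ss.standardized.mean()) < 1e-9
        assert ss.standardized.std() == pytest.approx(1.0)


class TestValidateWeights:
    def test_missing_column_rejected(self):
        w = weight_table(["v0"], [1], [1], [0.1], [0.5]).drop(columns=["BETA"])
        with pytest.raises(ValueError, match="BETA"):
            validate_weights(w)

    def test_duplicate_id_rejected(self):
        w = weight_table(["v0", "v0"], [1, 1], [1, 2], [0.1, 0.2], [0.5, 0.5])
        with pytest.raises(ValueError, match="unique"):
            validate_weights(w)

    def test_out_of_range_p_rejected(self):
        w = weight_table(["v0"], [1], [1], [0.1], [0.0])
        with pytest.raises(ValueError):
            validate_weights(w)

    def test_missing_cns_column_defaults_to_unannotated(self):
        w = validate_weights(weight_table(["v0"], [1], [1], [0.1], [0.5]))
        assert (w["CNS"] == "unannotated").all()


class TestQuartiles:
    def test_one_to_eight(self):
        np.testing.assert_array_equal(assign_quartiles(np.arange(1, 9)),
                                      [1, 1, 2, 2, 3, 3, 4, 4])

    def test_group_sizes_near_equal_when_n_not_divisible(self):
        rng = np.random.default_rng(8)
        q = assign_quartiles(rng.normal(size=397))
        sizes = sorted(np.bincount(q)[1:])
        assert sizes == [99, 99, 99, 100]

    def test_order_preserved(self):
        x = np.random.default_rng(9).normal(size=100)
        q = assign_quartiles(x)
        assert (q[np.argsort(x)] == np.sort(q)).all()

    def test_too_few_or_constant_rejected(self):
        with pytest.raises(ValueError):
            assign_quartiles([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            assign_quartiles([5.0] * 10)


class TestPartitionScores:
    def _weights(self, small_genotypes, n_cns=6, n_non=4):
        v = small_genotypes.variants.head(n_cns + n_non)
        rng = np.random.default_rng(10)
        return weights_from_variants(
            v, rng.normal(0, 0.1, n_cns + n_non), [0.5] * (n_cns + n_non),
            cns=["CNS"] * n_cns + ["non-CNS"] * n_non)

    def test_subscores_sum_to_full_raw_score(self, small_genotypes):
        full, cns, non = partition_scores(self._weights(small_genotypes),
                                          small_genotypes)
        np.testing.assert_allclose(full.raw, cns.raw + non.raw, atol=1e-9)
        assert cns.n_variants == 6 and non.n_variants == 4

    def test_unannotated_variant_rejected(self, small_genotypes):
        w = self._weights(small_genotypes)
        w.loc[0, "CNS"] = "unannotated"
        with pytest.raises(ValueError, match="unannotated"):
            partition_scores(w, small_genotypes)

    def test_empty_subset_rejected(self, small_genotypes):
        w = self._weights(small_genotypes)
        w["CNS"] = "CNS"
        with pytest.raises(ValueError, match="non-empty"):
            partition_scores(w, small_genotypes)


class TestGps:
    def _full_weights(self, gm, seed=11):
        rng = np.random.default_rng(seed)
        return weights_from_variants(gm.variants, rng.normal(0, 0.1, gm.n_variants),
                                     rng.uniform(1e-10, 1, gm.n_variants))

    def test_filter_drops_rare_and_poorly_imputed(self, gps_config):
        rng = np.random.default_rng(12)
        dos = rng.binomial(2, 0.3, (100, 3)).astype(float)
        gm = toy_genotypes(dos, freq=[0.005, 0.3, 0.3], impq=[1.0, 0.4, 1.0])
        w = self._full_weights(gm)
        kept = filter_gps_weights(w, gm, gps_config)
        assert kept["ID"].tolist() == ["v2"]

    def test_variant_count_monotone_in_threshold(self, small_genotypes, gps_config):
        w = self._full_weights(small_genotypes)
        counts = []
        for t in gps_config.thresholds:
            try:
                counts.append(build_gps(w, small_genotypes, t, gps_config).n_variants)
            except ValueError:
                counts.append(0)  # no variant at a very strict threshold
        assert counts == sorted(counts)
        # threshold 1.0 keeps every clumped variant
        assert counts[-1] == len(clump(w, small_genotypes, gps_config))

    def test_impossible_threshold_rejected(self, small_genotypes, gps_config):
        w = self._full_weights(small_genotypes)
        w["P"] = 0.9
        with pytest.raises(ValueError, match="survive"):
            build_gps(w, small_genotypes, 1e-8, gps_config)

    def test_single_threshold_grid_is_selected(self, small_genotypes, gps_config):
        import dataclasses
        cfg = dataclasses.replace(gps_config, thresholds=(0.3,))
        w = self._full_weights(small_genotypes)
        rng = np.random.default_rng(13)
        bmi = rng.normal(28, 5, small_genotypes.n_samples)
        t, ss, r2 = best_fit_threshold(w, small_genotypes, bmi, cfg)
        assert t == 0.3 and list(r2) == [0.3] and ss.n_variants >= 1

    def test_best_fit_reports_r2_for_each_feasible_threshold(
            self, small_genotypes, gps_config):
        w = self._full_weights(small_genotypes)
        rng = np.random.default_rng(14)
        bmi = rng.normal(28, 5, small_genotypes.n_samples)
        t, ss, r2 = best_fit_threshold(w, small_genotypes, bmi, gps_config)
        assert t in r2
        assert r2[t] == max(r2.values())
        assert all(0 <= v <= 1 for v in r2.values())

    def test_constant_bmi_rejected(self, small_genotypes, gps_config):
        w = self._full_weights(small_genotypes)
        with pytest.raises(ValueError, match="constant"):
            best_fit_threshold(w, small_genotypes,
                               np.full(small_genotypes.n_samples, 27.0),
                               gps_config)
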
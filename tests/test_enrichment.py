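import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdhist.enrichment import (
    build_null,
    correlate_driver,
    ecdf,
    ks_two_sample,
    run_enrichment,
    select_samples,
)
from rdhist.errors import InsufficientSamplesError, ValidationError
from rdhist.preprocess import vst
from rdhist.synthetic import SynthConfig, generate_dataset

from conftest import make_norm


def brute_force_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return cov / np.sqrt(np.mean((x - x.mean()) ** 2) * np.mean((y - y.mean()) ** 2))


def brute_force_ks_d(x, y):
    """Double loop over the pooled support, right-continuous ECDFs."""
    best = 0.0
    for v in np.concatenate([x, y]):
        fx = np.sum(x <= v) / len(x)
        fy = np.sum(y <= v) / len(y)
        best = max(best, abs(fx - fy))
    return best


class TestEcdf:
    def test_ties_collapse(self):
        e = ecdf([2, 2, 5])
        assert e.support.tolist() == [2, 5]
        assert e.probs.tolist() == [2 / 3, 1.0]
        assert e(2) == pytest.approx(2 / 3)
        assert e(1.9) == 0.0

    def test_singleton(self):
        e = ecdf([7.0])
        assert e.support.tolist() == [7.0] and e.probs.tolist() == [1.0]

    def test_final_probability_exactly_one(self):
        rng = np.random.default_rng(0)
        for n in (1, 3, 17, 100):
            assert ecdf(rng.standard_normal(n)).probs[-1] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ecdf([])


class TestKsTwoSample:
    def test_identical_samples(self):
        res = ks_two_sample([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert res.D == 0.0 and res.p == 1.0

    def test_disjoint_supports(self):
        assert ks_two_sample([1, 2, 3], [4, 5, 6]).D == 1.0

    def test_interleaved_example(self):
        assert ks_two_sample([1, 3], [2, 4]).D == 0.5

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValidationError):
            ks_two_sample([1.0], [1.0, 2.0])

    def test_d_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n1, n2 = rng.integers(2, 31, size=2)
            x = np.round(rng.standard_normal(n1), 1)  # ties likely
            y = np.round(rng.standard_normal(n2) + rng.uniform(-1, 1), 1)
            assert ks_two_sample(x, y).D == brute_force_ks_d(x, y)

    def test_exact_p_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        for _ in range(50):
            n1, n2 = rng.integers(3, 35, size=2)
            x = rng.standard_normal(n1)
            y = rng.standard_normal(n2) + rng.uniform(-1, 1)
            mine = ks_two_sample(x, y, method="exact").p
            ref = stats.ks_2samp(x, y, method="exact").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_asymptotic_close_to_scipy_at_large_n(self):
        from scipy import stats

        rng = np.random.default_rng(6)
        x = rng.standard_normal(400)
        y = rng.standard_normal(500) + 0.1
        mine = ks_two_sample(x, y, method="asymp").p
        ref = stats.ks_2samp(x, y, method="asymp").pvalue
        assert mine == pytest.approx(ref, abs=0.02)


class TestCorrelateDriver:
    def norm_from_rows(self, rows, gene_ids):
        return make_norm(np.asarray(rows, dtype=float), gene_ids)

    def test_self_correlation_is_one(self):
        norm = self.norm_from_rows(
            [[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]], ["driver", "copy"]
        )
        rec = correlate_driver(norm, "driver", ["copy"])
        assert rec["r"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_negated_gene_is_minus_one(self):
        driver = np.array([1.0, 2, 3, 4, 5])
        mirrored = 2 * driver.mean() - driver
        norm = self.norm_from_rows([driver, mirrored], ["driver", "neg"])
        rec = correlate_driver(norm, "driver", ["neg"])
        assert rec["r"].iloc[0] == pytest.approx(-1.0, abs=1e-12)

    def test_toy_r_matches_direct_formula(self):
        driver = [1, 2, 3, 4, 5]
        gene = [2, 1, 4, 3, 6]
        norm = self.norm_from_rows([driver, gene], ["driver", "g"])
        rec = correlate_driver(norm, "driver", ["g"])
        assert rec["r"].iloc[0] == pytest.approx(
            brute_force_pearson(driver, gene), abs=1e-12
        )

    def test_zero_variance_gene_recorded_as_null(self, caplog):
        norm = self.norm_from_rows(
            [[1, 2, 3, 4, 5], [7, 7, 7, 7, 7]], ["driver", "flat"]
        )
        with caplog.at_level(logging.WARNING):
            rec = correlate_driver(norm, "driver", ["flat"])
        assert rec["r"].iloc[0] == 0.0 and rec["p"].iloc[0] == 1.0
        assert "zero-variance" in caplog.text

    def test_insufficient_samples_names_subtype(self):
        norm = self.norm_from_rows([[1, 2, 3], [3, 2, 1]], ["driver", "g"])
        with pytest.raises(InsufficientSamplesError, match="lumA"):
            correlate_driver(norm, "driver", ["g"], subtype="lumA")

    def test_excluded_subtypes_dropped(self):
        values = np.arange(12, dtype=float).reshape(2, 6)
        norm = make_norm(values, ["driver", "g"])
        norm.sample_meta.loc[["s4", "s5"], "subtype"] = ["normal-like",
                                                         "unclassified"]
        selected = select_samples(norm.sample_meta, "all")
        assert list(selected) == ["s0", "s1", "s2", "s3"]
        rec = correlate_driver(norm, "driver", ["g"])
        assert rec["n_samples"].iloc[0] == 4

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(0.1, 5, allow_nan=False),
        flip=st.booleans(),
    )
    def test_affine_invariance(self, a, b, flip):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(20)
        y = x + rng.standard_normal(20)
        slope = -b if flip else b
        norm = self.norm_from_rows([x, a + slope * y], ["driver", "g"])
        rec = correlate_driver(norm, "driver", ["g"])
        base = brute_force_pearson(x, y)
        expected = -base if flip else base
        assert rec["r"].iloc[0] == pytest.approx(expected, abs=1e-9)


class TestBuildNull:
    def small_dataset(self, rho=0.0, seed=2, n=200):
        cfg = SynthConfig(
            n_genes=600, module_size=10, rho=rho, log2fc_module=0.0,
            batch_shift=0.0,
            n_samples_per_group={("tumor", "basal"): n, ("normal", "normal"): 2},
            seed=seed,
        )
        matrix, truth = generate_dataset(cfg)
        return vst(matrix), truth

    def test_cardinality_and_order(self):
        norm, truth = self.small_dataset()
        sets = [truth.module_ids[:3], truth.module_ids[3:6]]
        null = build_null(norm, truth.driver_id, sets)
        assert null.shape == (6,)
        singles = [
            correlate_driver(norm, truth.driver_id, s)["r"].to_numpy()
            for s in sets
        ]
        assert np.allclose(null, np.concatenate(singles))

    def test_no_self_pairing(self):
        from rdhist.catalog import sample_random_sets

        norm, truth = self.small_dataset()
        sets = sample_random_sets(norm, exclude=set(truth.module_ids),
                                  set_size=10, n_sets=60, seed=1,
                                  driver=truth.driver_id)
        null = build_null(norm, truth.driver_id, sets)
        assert not np.any(null == 1.0)

    def test_null_pool_centered_under_independence(self):
        from rdhist.catalog import sample_random_sets

        norm, truth = self.small_dataset(rho=0.0)
        sets = sample_random_sets(norm, exclude=set(truth.module_ids),
                                  set_size=10, n_sets=60, seed=5,
                                  driver=truth.driver_id)
        null = build_null(norm, truth.driver_id, sets)
        assert null.size >= 500
        assert abs(null.mean()) < 0.05

    def test_per_set_summary_mode(self):
        norm, truth = self.small_dataset()
        sets = [truth.module_ids[:4], truth.module_ids[4:8]]
        null = build_null(norm, truth.driver_id, sets, per_set_summary=True)
        assert null.shape == (2,)


class TestRunEnrichment:
    def test_default_n_sets_is_one_thousand(self):
        import inspect

        sig = inspect.signature(run_enrichment)
        assert sig.parameters["n_sets"].default == 1000

    def test_detects_module_in_every_subtype(self):
        cfg = SynthConfig(
            n_genes=800, module_size=20, rho=0.5, dispersion=0.1,
            n_samples_per_group={
                ("tumor", "basal"): 200, ("tumor", "lumA"): 200,
                ("tumor", "lumB"): 200, ("tumor", "HER2"): 200,
                ("normal", "normal"): 2,
            },
            seed=31,
        )
        matrix, truth = generate_dataset(cfg)
        norm = vst(matrix)
        results = run_enrichment(
            norm, truth.driver_id, [truth.driver_id, *truth.module_ids],
            subtypes=["basal", "lumA", "lumB", "HER2"], n_sets=200, seed=31,
        )
        assert [r.subtype for r in results] == ["all", "basal", "lumA",
                                                "lumB", "HER2"]
        for r in results:
            assert r.ks.p < 0.05
            assert r.summary["set_median_r"] > r.summary["null_median_r"]
            assert r.null_correlations.size == 200 * len(r.set_correlations)

    def test_seed_determinism(self):
        cfg = SynthConfig(
            n_genes=400, module_size=8, rho=0.3,
            n_samples_per_group={("tumor", "basal"): 50,
                                 ("normal", "normal"): 2},
            seed=9,
        )
        matrix, truth = generate_dataset(cfg)
        norm = vst(matrix)
        args = (norm, truth.driver_id, truth.module_ids)
        r1 = run_enrichment(*args, n_sets=50, seed=4)
        r2 = run_enrichment(*args, n_sets=50, seed=4)
        assert r1[0].ks == r2[0].ks
        assert np.array_equal(r1[0].null_correlations, r2[0].null_correlations)

    def test_unknown_subtype_skipped_with_warning(self, caplog):
        cfg = SynthConfig(
            n_genes=400, module_size=8,
            n_samples_per_group={("tumor", "basal"): 50,
                                 ("normal", "normal"): 2},
            seed=10,
        )
        matrix, truth = generate_dataset(cfg)
        norm = vst(matrix)
        with caplog.at_level(logging.WARNING):
            results = run_enrichment(norm, truth.driver_id, truth.module_ids,
                                     subtypes=["basal", "ghost"], n_sets=20,
                                     seed=0)
        assert [r.subtype for r in results] == ["all", "basal"]
        assert "ghost" in caplog.text

    def test_underpowered_null_warns(self, caplog):
        cfg = SynthConfig(
            n_genes=400, module_size=8,
            n_samples_per_group={("tumor", "basal"): 50,
                                 ("normal", "normal"): 2},
            seed=12,
        )
        matrix, truth = generate_dataset(cfg)
        norm = vst(matrix)
        with caplog.at_level(logging.WARNING):
            run_enrichment(norm, truth.driver_id, truth.module_ids, n_sets=1,
                           seed=0)
        assert "underpowered" in caplog.text
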
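"""Summarization algorithms and the 24-schedule factorial."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensemblemark import (CohortSpec, ProbeLevelCohort, ScheduleSpec,
                          apply_schedule, compute_schedule_matrices,
                          enumerate_schedules, gcrma_summarize, generate_cohort,
                          li_wong_fit, mas5_summarize, mbei_summarize,
                          median_polish, quantile_normalize, reference_schedule,
                          rma_summarize, tukey_biweight)
from ensemblemark.preprocess import (ScheduleError, _biweight_columns,
                                     _rma_background)


def make_probe_cohort(values, probeset_of, gc=None, affinity=None, site="site01"):
    """Assemble a one-site ProbeLevelCohort from a raw probe matrix."""
    values = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"pr{i:03d}" for i in range(len(values))],
        columns=[f"{site}-p{j:03d}" for j in range(np.shape(values)[1])])
    probesets = list(probeset_of)
    n = len(values)
    info = pd.DataFrame({
        "probeset_id": probesets,
        "gc_fraction": gc if gc is not None else np.full(n, 0.5),
        "affinity": affinity if affinity is not None else np.zeros(n),
    }, index=values.index)
    genes = sorted(set(probesets))
    ann = pd.DataFrame({"probeset_id": genes, "gene_id": genes})
    return ProbeLevelCohort(intensities={site: values}, probe_info=info,
                            annotation_default=ann, annotation_alternative=ann)


class TestScheduleFactorial:
    def test_exactly_24_distinct(self):
        scheds = enumerate_schedules()
        assert len(scheds) == 24
        assert len(set(scheds)) == 24

    def test_factor_counts(self):
        scheds = enumerate_schedules()
        assert sum(s.handling == "separate" for s in scheds) == 12
        assert sum(s.annotation == "default" for s in scheds) == 12
        assert len({(s.algorithm, s.log2_output) for s in scheds}) == 6

    def test_canonical_order_golden(self):
        ids = [s.schedule_id for s in enumerate_schedules()]
        assert ids == sorted(ids)
        assert ids[0] == "GCRMA-log2-alternative-combined"
        assert ids[-1] == "RMA-log2-default-separate"
        assert ScheduleSpec.from_id(ids[5]) == enumerate_schedules()[5]

    def test_log2_forced_for_rma_family(self):
        with pytest.raises(ScheduleError):
            ScheduleSpec("RMA", False)
        with pytest.raises(ScheduleError):
            ScheduleSpec("GCRMA", False)


class TestQuantileNormalize:
    def test_hand_computed_example(self):
        out = quantile_normalize(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        assert np.allclose(out, expected)

    def test_single_array_identity(self, rng):
        x = rng.uniform(1, 10, (20, 1))
        assert np.allclose(quantile_normalize(x), x)

    def test_identical_arrays_unchanged(self, rng):
        col = rng.uniform(1, 10, 15)
        x = np.column_stack([col, col, col])
        assert np.allclose(quantile_normalize(x), x)

    def test_ties_receive_mean_of_candidates(self):
        x = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = quantile_normalize(x)
        # tied values in column 0 occupy ranks 1-2; they share the mean of
        # the corresponding across-array order statistics
        m = np.sort(x, axis=0).mean(axis=1)
        assert np.allclose(out[:, 0], [(m[0] + m[1]) / 2, (m[0] + m[1]) / 2, m[2]])

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(2, 30), st.integers(2, 6), st.integers(0, 2 ** 16))
    def test_sorted_columns_equal_and_ranks_preserved(self, n, k, seed):
        x = np.random.default_rng(seed).normal(size=(n, k))
        out = quantile_normalize(x)
        ref = np.sort(out[:, 0])
        for j in range(k):
            assert np.allclose(np.sort(out[:, j]), ref, atol=1e-12)
            assert np.array_equal(np.argsort(x[:, j], kind="stable"),
                                  np.argsort(out[:, j], kind="stable"))

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.array([1.0, 2.0, 3.0]))


class TestMedianPolish:
    # frozen oracle: R stats::medpolish(x, eps=1e-8, maxiter=10) on this table
    X = np.array([[5.1, 6.2, 4.9, 7.0],
                  [5.5, 6.8, 5.2, 7.4],
                  [4.8, 6.0, 4.6, 6.9],
                  [6.1, 7.1, 5.8, 8.0],
                  [5.0, 6.1, 4.8, 7.1]])

    def test_matches_frozen_external_oracle(self):
        res = median_polish(self.X)
        assert res.overall == pytest.approx(5.65, abs=1e-10)
        assert np.allclose(res.row, [0.0, 0.375, -0.225, 0.95, -0.075], atol=1e-10)
        assert np.allclose(res.col, [-0.55, 0.55, -0.80, 1.40], atol=1e-10)
        assert np.allclose(res.fitted_col, [5.10, 6.20, 4.85, 7.05], atol=1e-10)

    def test_residual_medians_near_zero(self, rng):
        res = median_polish(rng.normal(size=(7, 5)), max_iter=10)
        assert np.abs(np.median(res.residuals, axis=1)).max() < 1e-6
        assert np.abs(np.median(res.residuals, axis=0)).max() < 1e-6

    def test_exact_additive_recovery(self, rng):
        row = rng.normal(size=6)
        col = rng.normal(size=4)
        res = median_polish(10.0 + row[:, None] + col[None, :])
        assert np.allclose(res.residuals, 0.0, atol=1e-12)
        assert np.allclose(res.fitted_col - res.fitted_col.mean(),
                           col - col.mean(), atol=1e-10)


class TestTukeyBiweight:
    def test_constant_returns_constant(self):
        assert tukey_biweight([3.0, 3.0, 3.0]) == pytest.approx(3.0)

    def test_symmetric_returns_center(self):
        assert tukey_biweight([1.0, 2.0, 3.0, 4.0, 5.0]) == pytest.approx(3.0, abs=1e-6)

    def test_outlier_downweighted(self):
        x = [1.0, 2.0, 3.0, 4.0, 100.0]
        est = tukey_biweight(x)
        assert 2.5 < est < 3.5
        assert est < np.mean(x)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tukey_biweight([])

    def test_column_vectorization_matches_scalar(self, rng):
        X = rng.normal(5, 2, (11, 6))
        cols = _biweight_columns(X)
        for j in range(6):
            assert cols[j] == pytest.approx(tukey_biweight(X[:, j]), abs=1e-12)


class TestRma:
    def test_single_probe_probeset_passthrough(self, rng):
        raw = rng.uniform(100, 5000, (6, 4))
        cohort = make_probe_cohort(raw, ["A"] * 5 + ["B"])
        em = rma_summarize(cohort)
        # the single-probe ProbeSet equals that probe's processed values
        processed = np.log2(quantile_normalize(_rma_background(raw)))
        assert np.allclose(em.values.loc["B"], processed[5], atol=1e-12)

    def test_multiprobe_value_is_polish_of_processed(self, rng):
        raw = rng.uniform(100, 5000, (8, 5))
        cohort = make_probe_cohort(raw, ["A"] * 8)
        em = rma_summarize(cohort)
        processed = np.log2(quantile_normalize(_rma_background(raw)))
        assert np.allclose(em.values.loc["A"],
                           median_polish(processed).fitted_col, atol=1e-12)

    def test_deterministic(self, small_cohort):
        cohort, _ = small_cohort
        a = rma_summarize(cohort).values
        b = rma_summarize(cohort).values
        pd.testing.assert_frame_equal(a, b)


class TestGcrma:
    def test_flat_gc_background_close_to_rma(self, rng):
        # GC-independent background: regression slope ~ 0, so GCRMA and RMA
        # agree up to the (slightly different) per-array background constant
        signal = rng.uniform(6, 12, (40, 1)) + rng.normal(0, 0.3, (40, 6))
        raw = 2 ** signal + 40.0
        cohort = make_probe_cohort(raw, [f"PS{i // 4}" for i in range(40)],
                                   gc=rng.uniform(0.3, 0.7, 40))
        a = rma_summarize(cohort).values.to_numpy()
        b = gcrma_summarize(cohort).values.to_numpy()
        rmse = np.sqrt(((a - b) ** 2).mean())
        assert rmse < 0.25

    def test_gc_dependent_background_recovered_better(self, rng):
        # strong GC-driven background: GCRMA should track the true signal
        # more closely than RMA (compare centered per-ProbeSet array effects)
        n_probes, n_arrays = 60, 10
        gc = rng.uniform(0.25, 0.75, n_probes)
        probesets = [f"PS{i // 6}" for i in range(n_probes)]
        true_col = rng.normal(0, 1.0, (n_probes // 6, n_arrays))
        base = rng.uniform(5.5, 8.0, n_probes)
        signal = base[:, None] + np.repeat(true_col, 6, axis=0)
        raw = 2 ** signal + 600.0 * gc[:, None] ** 2 \
            * np.exp(rng.normal(0, 0.05, (n_probes, n_arrays)))
        cohort = make_probe_cohort(raw, probesets, gc=gc)

        def mse(emat):
            v = emat.values.to_numpy()
            v = v - v.mean(axis=1, keepdims=True)
            t = true_col - true_col.mean(axis=1, keepdims=True)
            return ((v - t) ** 2).mean()

        assert mse(gcrma_summarize(cohort)) < mse(rma_summarize(cohort))

    def test_missing_gc_rejected(self, rng):
        raw = rng.uniform(100, 500, (4, 3))
        cohort = make_probe_cohort(raw, ["A"] * 4)
        cohort.probe_info["gc_fraction"] = np.nan
        with pytest.raises(ValueError, match="RMA"):
            gcrma_summarize(cohort)


class TestMas5:
    def test_equal_probes_give_that_value_prescaling(self):
        # two ProbeSets with constant probe values v1, v2: biweight of a
        # constant is that constant, so the pre-scaling signals are v1 and v2
        # and their ratio survives the per-array scaling
        raw = np.vstack([np.full((3, 4), 200.0), np.full((3, 4), 800.0)])
        cohort = make_probe_cohort(raw, ["A"] * 3 + ["B"] * 3)
        em = mas5_summarize(cohort)
        assert np.allclose(em.values.loc["B"] / em.values.loc["A"], 4.0)

    def test_per_array_scale_invariance(self, rng):
        raw = rng.uniform(50, 5000, (12, 5))
        cohort1 = make_probe_cohort(raw, [f"PS{i // 3}" for i in range(12)])
        scaled = raw * np.array([1.0, 2.0, 0.5, 7.0, 1.3])[None, :]
        cohort2 = make_probe_cohort(scaled, [f"PS{i // 3}" for i in range(12)])
        a = mas5_summarize(cohort1).values.to_numpy()
        b = mas5_summarize(cohort2).values.to_numpy()
        assert np.allclose(a, b, atol=1e-9)

    def test_hand_computed_toy(self):
        # one array, two ProbeSets of 3 probes; signal = 2^biweight(log2 x),
        # then the 2%-trimmed mean of the two signals is scaled to 500
        raw = np.array([[64.0], [256.0], [1024.0], [32.0], [32.0], [32.0]])
        cohort = make_probe_cohort(raw, ["A"] * 3 + ["B"] * 3)
        sig_a = 2 ** tukey_biweight(np.log2([64.0, 256.0, 1024.0]))
        sig_b = 32.0
        sf = 500.0 / np.mean([sig_a, sig_b])
        em = mas5_summarize(cohort)
        assert em.values.loc["A", em.values.columns[0]] == pytest.approx(sig_a * sf)
        assert em.values.loc["B", em.values.columns[0]] == pytest.approx(sig_b * sf)

    def test_log2_output_flag(self, rng):
        raw = rng.uniform(50, 500, (6, 4))
        cohort = make_probe_cohort(raw, ["A"] * 3 + ["B"] * 3)
        nat = mas5_summarize(cohort, log2_output=False)
        log = mas5_summarize(cohort, log2_output=True)
        assert nat.scale == "natural" and log.scale == "log2"
        assert np.allclose(np.log2(nat.values), log.values)


class TestMbei:
    def test_rank_one_recovery(self, rng):
        phi = rng.uniform(0.5, 2.0, 8)
        theta = rng.uniform(100, 1000, 5)
        theta_hat, phi_hat, obj, converged = li_wong_fit(np.outer(phi, theta))
        assert converged
        assert obj[-1] == pytest.approx(0.0, abs=1e-12)
        # identifiability: sum(phi^2) = n_probes; theta recovered up to that
        assert np.sum(phi_hat ** 2) == pytest.approx(8.0)
        scale = np.sqrt(np.sum(phi ** 2) / 8.0)
        assert np.allclose(theta_hat, theta * scale, rtol=1e-6)

    def test_objective_non_increasing(self, rng):
        X = rng.uniform(10, 1000, (4, 5))
        _, _, obj, _ = li_wong_fit(X)
        assert (np.diff(obj) <= 1e-8 * obj[:-1] + 1e-9).all()

    def test_pseudo_count_effect_shrinks_with_intensity(self, rng):
        probesets = ["A"] * 4
        low = rng.uniform(5, 30, (4, 6))
        high = low * 1000.0
        def theta(raw, pc):
            cohort = make_probe_cohort(raw, probesets)
            return mbei_summarize(cohort, pseudo_count=pc).values.loc["A"].to_numpy()
        rel_low = np.abs(theta(low, 16.0) - theta(low, 0.0)) / theta(low, 0.0)
        rel_high = np.abs(theta(high, 16.0) - theta(high, 0.0)) / theta(high, 0.0)
        assert rel_low.mean() > rel_high.mean()
        assert rel_low.mean() > 0.01

    def test_natural_scale_positive(self, small_cohort):
        cohort, _ = small_cohort
        em = mbei_summarize(cohort)
        assert em.scale == "natural"
        assert (em.values.to_numpy() > 0).all()


class TestApplySchedule:
    def test_single_site_separate_equals_combined(self, rng):
        raw = rng.uniform(50, 5000, (12, 6))
        cohort = make_probe_cohort(raw, [f"PS{i // 3}" for i in range(12)])
        sep = apply_schedule(cohort, None, ScheduleSpec("RMA", True,
                                                        handling="separate"))
        com = apply_schedule(cohort, None, ScheduleSpec("RMA", True,
                                                        handling="combined"))
        assert len(sep) == 1 and len(com) == 1
        assert np.allclose(sep[0].values, com[0].values)

    def test_separate_yields_per_site_matrices(self, small_cohort):
        cohort, clinical = small_cohort
        mats = apply_schedule(cohort, clinical, reference_schedule())
        assert [m.site for m in mats] == cohort.sites
        assert sum(m.values.shape[1] for m in mats) == len(clinical)
        assert all(m.level == "gene" for m in mats)

    def test_missing_required_gene_names_gene_and_schedule(self, rng):
        raw = rng.uniform(50, 5000, (6, 4))
        cohort = make_probe_cohort(raw, ["PS0"] * 3 + ["PS1"] * 3)
        sched = ScheduleSpec("RMA", True, handling="combined")
        with pytest.raises(ScheduleError, match="G9999.*RMA-log2-default-combined"):
            apply_schedule(cohort, None, sched, required_genes=("G9999",))

    def test_alternative_annotation_changes_gene_rows(self, small_cohort):
        cohort, clinical = small_cohort
        d = apply_schedule(cohort, clinical,
                           ScheduleSpec("RMA", True, "default", "combined"))[0]
        a = apply_schedule(cohort, clinical,
                           ScheduleSpec("RMA", True, "alternative", "combined"))[0]
        assert len(a.values) < len(d.values)  # dropped genes
        shared = d.values.index.intersection(a.values.index)
        assert not np.allclose(d.values.loc[shared], a.values.loc[shared])

    def test_compute_schedule_matrices_consistent_with_apply(self, small_cohort):
        cohort, clinical = small_cohort
        scheds = [ScheduleSpec("MAS5", True, "default", "combined"),
                  ScheduleSpec("MAS5", False, "default", "combined")]
        mats = compute_schedule_matrices(cohort, clinical, scheds)
        direct = apply_schedule(cohort, clinical, scheds[0])
        assert np.allclose(mats[scheds[0].schedule_id][0].values,
                           direct[0].values)
        assert np.allclose(mats[scheds[0].schedule_id][0].values,
                           np.log2(mats[scheds[1].schedule_id][0].values))
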
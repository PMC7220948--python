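"""Models, AUC, Mann-Whitney, stratified splits and repeated evaluation."""

import numpy as np
import pytest

from genesig.evaluate import (
    SplitSpec,
    auc,
    evaluate_signatures,
    external_validate,
    fit,
    mannwhitney_u,
    predict_proba,
    stratified_split,
)
from genesig.synthetic import SyntheticConfig, generate, generate_pair

from conftest import auc_pair_counting, make_dataset, mannwhitney_exact_enumeration


def two_group_dataset(seed, n=60, n_genes=5, shift=1.2):
    rng = np.random.default_rng(seed)
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    rng.shuffle(y)
    strata = np.where(rng.random(n) < 0.6, "ER+", "ER-")
    values = rng.normal(8, 1, (n_genes, n)) + shift * y[None, :]
    return make_dataset(values, y, strata=strata)


class TestAuc:
    def test_hand_example(self):
        assert auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_all_tied_scores_give_half(self):
        assert auc([0, 1, 0, 1], [3.0, 3.0, 3.0, 3.0]) == pytest.approx(0.5)

    def test_perfect_ranking(self):
        assert auc([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.normal(size=n), 1)  # rounding creates ties
            assert auc(labels, scores) == pytest.approx(
                auc_pair_counting(labels, scores), abs=1e-12
            )

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestMannWhitney:
    def test_matches_exact_enumeration_small_groups(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            nx, ny = int(rng.integers(3, 8)), int(rng.integers(3, 8))
            x = rng.normal(size=nx)
            y = rng.normal(1.0, 1, size=ny)
            _, p = mannwhitney_u(x, y)
            assert p == pytest.approx(mannwhitney_exact_enumeration(x, y), abs=1e-10)

    def test_identical_lists_give_p_one(self):
        x = [0.6, 0.7, 0.65, 0.72, 0.68, 0.71, 0.69, 0.66, 0.73, 0.64]
        u, p = mannwhitney_u(x, list(x))
        assert p == 1.0
        assert u == pytest.approx(len(x) ** 2 / 2)

    def test_clearly_shifted_groups_significant(self):
        rng = np.random.default_rng(2)
        _, p = mannwhitney_u(rng.normal(0, 1, 50), rng.normal(2, 1, 50))
        assert p < 1e-6


class TestFitPredict:
    def test_label_copy_gene_gives_confident_probabilities(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 15 + [1] * 15)
        values = np.vstack([y * 4.0 + 6 + rng.normal(0, 1e-6, 30)])
        ds = make_dataset(values, y)
        model = fit(ds, ["g0"], model_kind="mlr")
        proba = predict_proba(model, ds)
        assert np.all(proba[y == 1] >= 0.99)

    def test_zero_variance_gene_errors(self):
        ds = make_dataset([[5.0] * 10, list(range(10))], [0] * 5 + [1] * 5)
        with pytest.raises(ValueError, match="zero-variance"):
            fit(ds, ["g0"])

    def test_monotone_in_positive_coefficient_gene(self):
        ds = two_group_dataset(1)
        model = fit(ds, ["g0"], model_kind="mlr")
        coef = model.coefficients[0]
        assert coef > 0
        bumped = make_dataset(ds.values + np.array([[1.0]] + [[0]] * 4),
                              ds.outcome)
        assert np.all(predict_proba(model, bumped) >= predict_proba(model, ds))

    def test_training_auc_optimistic_on_average(self):
        deltas = []
        for seed in range(20):
            ds = two_group_dataset(seed, n=100, n_genes=12, shift=0.4)
            tr, va = stratified_split(ds, SplitSpec(master_seed=seed), 0)
            m = fit(ds.subset(sample_ids=tr), list(ds.gene_ids), seed=seed)
            a_tr = auc(ds.subset(sample_ids=tr).outcome,
                       predict_proba(m, ds.subset(sample_ids=tr)))
            a_va = auc(ds.subset(sample_ids=va).outcome,
                       predict_proba(m, ds.subset(sample_ids=va)))
            deltas.append(a_tr - a_va)
        assert np.mean(deltas) > 0

    @pytest.mark.parametrize("kind", ["mlr", "linear_svm", "rf"])
    def test_all_model_kinds_produce_valid_probabilities(self, kind):
        ds = two_group_dataset(3)
        model = fit(ds, list(ds.gene_ids), model_kind=kind, seed=0)
        proba = predict_proba(model, ds)
        assert proba.shape == (ds.n_samples,)
        assert np.all((proba >= 0) & (proba <= 1))
        assert auc(ds.outcome, proba) > 0.8

    def test_missing_gene_at_predict_time_errors(self):
        ds = two_group_dataset(4)
        model = fit(ds, ["g0", "g1"])
        with pytest.raises(KeyError):
            predict_proba(model, ds.subset(gene_ids=["g0"]))


class TestStratifiedSplit:
    def test_two_to_one_arithmetic(self):
        ds = two_group_dataset(0, n=90)
        spec = SplitSpec(ratio=(2, 1), master_seed=1, use_strata=False)
        tr, va = stratified_split(ds, spec, 0)
        assert len(tr) == 60 and len(va) == 30
        y = ds.annotations.loc[tr, "outcome"]
        # outcome proportions preserved within rounding
        assert abs(y.mean() - ds.outcome.mean()) < 0.05

    def test_same_seed_identical_split(self):
        ds = two_group_dataset(1)
        spec = SplitSpec(master_seed=3)
        assert stratified_split(ds, spec, 5) == stratified_split(ds, spec, 5)

    def test_different_repeats_differ(self):
        ds = two_group_dataset(2)
        spec = SplitSpec(master_seed=3)
        assert stratified_split(ds, spec, 0) != stratified_split(ds, spec, 1)

    @pytest.mark.parametrize("ratio,frac", [((1, 1), 0.5), ((2, 1), 2 / 3), ((3, 1), 0.75)])
    def test_split_ratios(self, ratio, frac):
        ds = two_group_dataset(3, n=120)
        spec = SplitSpec(ratio=ratio, master_seed=0, use_strata=False)
        tr, va = stratified_split(ds, spec, 0)
        assert len(tr) / 120 == pytest.approx(frac, abs=0.03)

    def test_er_strata_respected(self):
        ds = two_group_dataset(4, n=120)
        spec = SplitSpec(master_seed=0, use_strata=True)
        tr, _ = stratified_split(ds, spec, 0)
        ann = ds.annotations
        for outcome in (0, 1):
            for er in ("ER+", "ER-"):
                members = ann[(ann["outcome"] == outcome) & (ann["strata"] == er)]
                in_train = members.index.isin(tr).mean()
                assert abs(in_train - 2 / 3) < 0.2

    def test_singleton_stratum_errors(self):
        ds = make_dataset(
            np.random.default_rng(0).normal(8, 1, (2, 5)),
            [0, 0, 1, 1, 1],
            strata=["A", "A", "A", "A", "B"],
        )
        with pytest.raises(ValueError, match="stratum"):
            stratified_split(ds, SplitSpec(master_seed=0), 0)


class TestEvaluateSignatures:
    def test_identical_signatures_compare_at_p_one(self):
        ds = two_group_dataset(0)
        spec = SplitSpec(n_repeats=10, master_seed=1)
        rep = evaluate_signatures(ds, {"a": ["g0", "g1"], "b": ["g0", "g1"]}, spec)
        (_, _, _, p) = rep.comparisons[0]
        assert p == 1.0
        assert rep.arms["a"].per_split_auc == rep.arms["b"].per_split_auc

    def test_repeat_count_and_summary_order(self):
        ds = two_group_dataset(1)
        spec = SplitSpec(n_repeats=12, master_seed=2)
        rep = evaluate_signatures(ds, {"sig": ["g0", "g1", "g2"]}, spec)
        arm = rep.arms["sig"]
        assert len(arm.per_split_auc) == 12
        assert arm.q1 <= arm.median <= arm.q3
        assert arm.ci95[0] <= arm.ci95[1]

    def test_informative_signature_beats_noise_signature(self):
        cfg = SyntheticConfig(n_samples=120, n_noise=50, n_corr_blocks=0, seed=5)
        ds, truth = generate(cfg)
        informative = list(truth.index[truth["role"] == "informative"])
        noise = [g for g in truth.index[truth["role"] == "noise"]][:5]
        spec = SplitSpec(n_repeats=50, master_seed=4)
        rep = evaluate_signatures(ds, {"inf": informative, "noise": noise}, spec)
        assert rep.arms["inf"].median > rep.arms["noise"].median
        (_, _, _, p) = rep.comparisons[0]
        assert p < 0.001

    def test_end_to_end_bit_reproducible(self):
        ds = two_group_dataset(6)
        spec = SplitSpec(n_repeats=8, master_seed=9)
        a = evaluate_signatures(ds, {"s": ["g0", "g1"]}, spec)
        b = evaluate_signatures(ds, {"s": ["g0", "g1"]}, spec)
        assert a.arms["s"].per_split_auc == b.arms["s"].per_split_auc


class TestExternalValidate:
    def test_exp1_same_distribution_matches_internal(self):
        cfg = SyntheticConfig(n_samples=120, n_noise=30, n_corr_blocks=0, seed=1)
        internal, truth = generate(cfg)
        external, _ = generate(SyntheticConfig(**{**cfg.__dict__, "seed": 2}))
        sig = list(truth.index[truth["role"] == "informative"])
        spec = SplitSpec(n_repeats=30, master_seed=0)
        internal_rep = evaluate_signatures(internal, {"s": sig}, spec)
        exp1 = external_validate(internal, external, sig, mode="exp1", spec=spec)
        assert abs(exp1.arms["signature"].median - internal_rep.arms["s"].median) < 0.1

    def test_exp2_permuted_external_labels_near_chance(self):
        cfg = SyntheticConfig(n_samples=120, n_noise=30, n_corr_blocks=0, seed=3)
        internal, truth = generate(cfg)
        external, _ = generate(SyntheticConfig(**{**cfg.__dict__, "seed": 4}))
        rng = np.random.default_rng(0)
        ann = external.annotations.copy()
        ann["outcome"] = rng.permutation(ann["outcome"].to_numpy())
        permuted = make_dataset(external.values, ann["outcome"].to_numpy(),
                                strata=ann["strata"].to_numpy(),
                                gene_ids=list(external.gene_ids),
                                sample_ids=list(external.sample_ids))
        sig = list(truth.index[truth["role"] == "informative"])
        rep = external_validate(internal, permuted, sig, mode="exp2",
                                spec=SplitSpec(n_repeats=20, master_seed=1))
        assert abs(rep.arms["signature"].median - 0.5) < 0.12

    def test_exp2_zscoring_restores_batch_shifted_auc(self):
        cfg = SyntheticConfig(n_samples=120, n_noise=30, n_corr_blocks=0, seed=7)
        internal, shifted = generate_pair(cfg, batch_shift_sd=2.0)
        _, truth = generate(cfg)
        sig = list(truth.index[truth["role"] == "informative"])
        spec = SplitSpec(n_repeats=20, master_seed=2)
        with_z = external_validate(internal, shifted, sig, mode="exp2", spec=spec)
        without_z = external_validate(internal, shifted, sig, mode="exp2",
                                      spec=spec, zscore=False)
        assert with_z.arms["signature"].median > without_z.arms["signature"].median

    def test_missing_signature_gene_is_named(self):
        ds = two_group_dataset(8)
        external = ds.subset(gene_ids=["g0", "g1"])
        with pytest.raises(KeyError, match="g4"):
            external_validate(ds, external, ["g0", "g4"], mode="exp1",
                              spec=SplitSpec(n_repeats=2, master_seed=0))
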
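"""Splitting, normalization, losses, the training loop and mask pruning."""

import dataclasses

import numpy as np
import pytest

from spinnet import (
    EffectSpec,
    SchemaError,
    SimConfig,
    SpinConfig,
    SplitSpec,
    SpinError,
    TrainParams,
    auc,
    bce_loss,
    cox_loss,
    cox_loss_grad,
    fit_normalizer,
    generate,
    init_model,
    predict,
    sparse_code_masks,
    stratified_split,
    train,
)
from spinnet.annotation import align_dataset
from spinnet.data import ExpressionDataset
from spinnet.training import bce_grad, dataset_loss

from conftest import random_model


def make_dataset(n, q=4, seed=0, task="risk", sexes=None):
    rng = np.random.default_rng(seed)
    if sexes is None:
        sexes = np.array(["male", "female"] * (n // 2) + ["male"] * (n % 2),
                         dtype=object)
    kwargs = {}
    if task == "risk":
        kwargs["label"] = rng.integers(0, 2, n)
    else:
        kwargs["time"] = rng.uniform(1, 10, n)
        kwargs["event"] = rng.integers(0, 2, n)
    return ExpressionDataset(
        rng.standard_normal((n, q)),
        sexes,
        [f"s{i}" for i in range(n)],
        [f"g{i}" for i in range(q)],
        **kwargs,
    )


class TestStratifiedSplit:
    def test_balanced_100_gives_10_10_test(self):
        ds = make_dataset(100, task="survival")
        tr, va, te = stratified_split(ds, SplitSpec(seed=0))
        assert te.n_samples == 20
        assert (te.sex == "male").sum() == 10 and (te.sex == "female").sum() == 10
        assert va.n_samples == 16 and tr.n_samples == 64
        all_ids = sorted(tr.sample_ids + va.sample_ids + te.sample_ids)
        assert all_ids == sorted(ds.sample_ids)  # disjoint and exhaustive

    def test_same_seed_identical(self):
        ds = make_dataset(60, task="survival")
        a = stratified_split(ds, SplitSpec(seed=5))
        b = stratified_split(ds, SplitSpec(seed=5))
        for x, y in zip(a, b):
            assert x.sample_ids == y.sample_ids

    def test_101_samples_within_one_of_exact_fractions(self):
        ds = make_dataset(101, task="survival")
        tr, va, te = stratified_split(ds, SplitSpec(seed=1))
        keys = ds.sex
        for key in ("male", "female"):
            m = (keys == key).sum()
            n_te = (te.sex == key).sum()
            n_va = (va.sex == key).sum()
            n_tr = (tr.sex == key).sum()
            assert abs(n_te - 0.2 * m) <= 1
            assert abs(n_va - 0.16 * m) <= 1
            assert abs(n_tr - 0.64 * m) <= 1

    def test_binary_task_stratifies_on_sex_and_label(self):
        rng = np.random.default_rng(0)
        label = np.array([0, 1] * 50)
        ds = make_dataset(100, task="survival")
        ds = dataclasses.replace(ds, time=None, event=None, label=label)
        tr, va, te = stratified_split(ds, SplitSpec(seed=0))
        for sex in ("male", "female"):
            for lab in (0, 1):
                in_test = ((te.sex == sex) & (te.label == lab)).sum()
                total = ((ds.sex == sex) & (ds.label == lab)).sum()
                assert abs(in_test - 0.2 * total) <= 1
        del rng

    def test_tiny_stratum_raises(self):
        sexes = np.array(["male"] * 58 + ["female"] * 2, dtype=object)
        ds = make_dataset(60, task="survival", sexes=sexes)
        with pytest.raises(SpinError, match="stratum"):
            stratified_split(ds, SplitSpec(seed=0))


class TestNormalizer:
    def test_closed_form_population_standardization(self):
        ds = make_dataset(3, q=1, task="risk")
        ds.expression[:, 0] = [1.0, 2.0, 3.0]
        norm = fit_normalizer(ds)
        out = norm.transform(dataclasses.replace(ds))
        np.testing.assert_allclose(
            out.expression[:, 0], [-1.22474487, 0.0, 1.22474487]
        )

    def test_test_value_at_training_mean_maps_to_zero(self):
        tr = make_dataset(4, q=2, task="risk", seed=1)
        norm = fit_normalizer(tr)
        te = make_dataset(1, q=2, task="risk", seed=2)
        te.expression[0] = tr.expression.mean(axis=0)
        assert np.allclose(norm.transform(te).expression, 0.0)

    def test_constant_gene_dropped_with_warning(self):
        ds = make_dataset(5, q=3, task="risk")
        ds.expression[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            norm = fit_normalizer(ds)
        out = norm.transform(dataclasses.replace(ds))
        assert out.gene_ids == ["g0", "g2"]

    def test_double_application_rejected(self):
        ds = make_dataset(5, task="risk")
        norm = fit_normalizer(ds)
        once = norm.transform(ds)
        with pytest.raises(SpinError, match="already normalized"):
            norm.transform(once)

    def test_unfitted_normalizer_rejected(self):
        from spinnet import Normalizer

        with pytest.raises(SpinError, match="not been fitted"):
            Normalizer().transform(make_dataset(3, task="risk"))


class TestCoxLoss:
    def test_single_event_is_zero(self):
        assert cox_loss([1.7], [2.0], [1]) == pytest.approx(0.0)

    def test_two_sample_closed_form(self):
        assert cox_loss([0.0, 0.0], [1.0, 2.0], [1, 1]) == pytest.approx(
            np.log(2) / 2
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_riskset_enumeration_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        time = rng.integers(1, 4, n).astype(float)  # forces ties
        event = rng.integers(0, 2, n)
        event[rng.integers(n)] = 1
        z = rng.standard_normal(n)
        d = event.sum()
        expected = 0.0
        for i in range(n):
            if event[i]:
                risk = [j for j in range(n) if time[j] >= time[i]]
                expected -= z[i] - np.log(np.sum(np.exp(z[risk])))
        expected /= d
        assert cox_loss(z, time, event) == pytest.approx(expected, rel=1e-12)

    def test_zero_events_raise(self):
        with pytest.raises(SpinError, match="event"):
            cox_loss([0.0, 1.0], [1.0, 2.0], [0, 0])

    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        time = np.round(rng.uniform(1, 5, n), 1)
        event = rng.integers(0, 2, n)
        event[0] = 1
        z = rng.standard_normal(n)
        grad = cox_loss_grad(z, time, event)
        eps = 1e-6
        for k in range(n):
            zp, zm = z.copy(), z.copy()
            zp[k] += eps
            zm[k] -= eps
            fd = (cox_loss(zp, time, event) - cox_loss(zm, time, event)) / (2 * eps)
            assert grad[k] == pytest.approx(fd, abs=1e-5)


class TestBceLoss:
    def test_uninformative_risk_gives_log_two(self):
        assert bce_loss([0.5, 0.5], [0, 1]) == pytest.approx(np.log(2))

    def test_boundary_risks_clamped(self):
        eps = 1e-7
        loss = bce_loss([1.0, 0.0], [1, 0], eps=eps)
        assert loss == pytest.approx(-np.log(1 - eps), rel=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_sample_loop(self, seed):
        rng = np.random.default_rng(seed)
        risk = rng.uniform(0.05, 0.95, 12)
        label = rng.integers(0, 2, 12)
        expected = -np.mean(
            [
                np.log(r) if y else np.log(1 - r)
                for r, y in zip(risk, label)
            ]
        )
        assert bce_loss(risk, label) == pytest.approx(expected, rel=1e-12)
        g = bce_grad(risk, label)
        eps = 1e-7
        for k in range(3):
            rp, rm = risk.copy(), risk.copy()
            rp[k] += eps
            rm[k] -= eps
            fd = (bce_loss(rp, label) - bce_loss(rm, label)) / (2 * eps)
            assert g[k] == pytest.approx(fd, abs=1e-5)


def _separable_fit(seed=0):
    cfg = SimConfig(
        n=200, q=40, r=4, genes_per_pathway=10, overlap=1, task="risk",
        label_noise=0.0, seed=seed,
        effects=[EffectSpec("PW02", "shared", 10.0)],
    )
    dataset, mask, _ = generate(cfg)
    tr, va, te = stratified_split(dataset, SplitSpec(seed=seed))
    norm = fit_normalizer(tr)
    trn, van, ten = (align_dataset(norm.transform(d), mask) for d in (tr, va, te))
    return mask, trn, van, ten


class TestTrain:
    def test_learns_separable_risk_fixture(self):
        mask, trn, van, ten = _separable_fit()
        model = init_model(mask, SpinConfig(task="risk", hidden_sizes=(6,), seed=0))
        fitted, report = train(model, trn, van, TrainParams(seed=0))
        assert auc(predict(fitted, ten), ten.label) > 0.9
        # loss drops over the first training epochs of the standard run
        assert report.train_losses[9] < report.train_losses[0]

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        mask, trn, van, _ = _separable_fit(seed=1)
        model = init_model(mask, SpinConfig(task="risk", hidden_sizes=(4,), seed=1))
        fitted, _ = train(
            model, trn, van,
            TrainParams(learning_rate=0.0, epochs=15, strategies=("standard",),
                        seed=1),
        )
        np.testing.assert_array_equal(fitted.W_G_male, model.W_G_male)
        np.testing.assert_array_equal(fitted.W_H, model.W_H)
        np.testing.assert_array_equal(
            fitted.hidden_weights[0], model.hidden_weights[0]
        )

    def test_same_seed_bitwise_identical_reports(self):
        mask, trn, van, _ = _separable_fit(seed=2)
        params = TrainParams(epochs=30, warmup_epochs=20, seed=2)
        runs = []
        for _ in range(2):
            model = init_model(mask, SpinConfig(task="risk", seed=2))
            _, report = train(model, trn, van, params)
            runs.append(report)
        assert runs[0].train_losses == runs[1].train_losses
        assert runs[0].val_losses == runs[1].val_losses
        assert runs[0].chosen_strategy == runs[1].chosen_strategy

    def test_task_mismatch_raises_schema_error(self):
        mask, trn, van, _ = _separable_fit(seed=3)
        model = init_model(mask, SpinConfig(task="survival", seed=3))
        with pytest.raises(SchemaError, match="task"):
            train(model, trn, van, TrainParams(seed=3))


class TestSparseCoding:
    def test_zero_fraction_changes_nothing(self):
        model = random_model(0, q=10, r=4, task="risk")
        ds = make_dataset(20, q=10, task="risk")
        ds = dataclasses.replace(ds, gene_ids=model.mask.gene_ids)
        out = ds.expression  # alignment not needed: ids renamed in place
        pruned, chosen = sparse_code_masks(model, ds, [0.0])
        assert chosen == {"hidden_0": 0.0}
        np.testing.assert_array_equal(
            pruned.hidden_masks[0], model.hidden_masks[0]
        )
        del out

    def test_tie_broken_toward_larger_fraction(self):
        model = random_model(1, q=8, r=4, hidden=(4,), task="risk")
        w = model.hidden_weights[0]
        flat = np.abs(w).ravel()
        half = len(flat) // 2
        order = np.argsort(flat)
        wf = w.ravel()
        wf[order[:half]] = 0.0  # half the weights exactly zero
        model.hidden_weights[0] = wf.reshape(w.shape)
        ds = make_dataset(15, q=8, task="risk", seed=4)
        ds = dataclasses.replace(ds, gene_ids=model.mask.gene_ids)
        pruned, chosen = sparse_code_masks(model, ds, [0.0, 0.5])
        # pruning exactly the zero weights leaves the model unchanged, so the
        # losses tie and the larger fraction must win
        assert chosen["hidden_0"] == 0.5
        assert dataset_loss(pruned, ds) == pytest.approx(dataset_loss(model, ds))

    @pytest.mark.parametrize("seed", range(3))
    def test_sort_oracle_count_and_magnitudes(self, seed):
        model = random_model(seed, q=12, r=5, hidden=(6,), task="risk")
        ds = make_dataset(15, q=12, task="risk", seed=seed)
        ds = dataclasses.replace(ds, gene_ids=model.mask.gene_ids)
        rho = 0.5
        pruned, _ = sparse_code_masks(model, ds, [rho])
        eff = np.abs(model.hidden_weights[0] * model.hidden_masks[0])
        k = int(np.floor(rho * eff.size))
        kept = pruned.hidden_masks[0].astype(bool)
        assert (~kept).sum() == k
        if k and kept.any():
            assert eff[~kept].max() <= eff[kept].min()

    @pytest.mark.parametrize("seed", range(3))
    def test_pruned_sets_nest_across_fractions(self, seed):
        model = random_model(seed + 10, q=10, r=4, hidden=(5,), task="risk")
        ds = make_dataset(12, q=10, task="risk", seed=seed)
        ds = dataclasses.replace(ds, gene_ids=model.mask.gene_ids)
        masks = {}
        for rho in (0.2, 0.5, 0.8):
            pruned, _ = sparse_code_masks(model, ds, [rho])
            masks[rho] = pruned.hidden_masks[0].astype(bool)
        assert np.all(~masks[0.2] <= ~masks[0.5])
        assert np.all(~masks[0.5] <= ~masks[0.8])

    def test_empty_grid_raises(self):
        model = random_model(2, task="risk")
        ds = make_dataset(10, q=model.n_genes, task="risk")
        ds = dataclasses.replace(ds, gene_ids=model.mask.gene_ids)
        with pytest.raises(SpinError, match="grid"):
            sparse_code_masks(model, ds, [])
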
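import numpy as np
import pandas as pd
import pytest

from fusesurv.datagen import SimulationConfig, simulate_cohort
from fusesurv.encoder import EncoderConfig, init_mock_encoder
from fusesurv.metrics import harrell_cindex
from fusesurv.survnet import (
    PipelineConfig,
    RiskModel,
    SplitAssignment,
    TrainConfig,
    cox_loss_and_risk_gradient,
    cox_partial_likelihood_loss,
    encode_clinical,
    fit_variant,
    fuse_features,
    pan_cancer_pool,
    stratified_split,
    train,
)


class TestStratifiedSplit:
    def test_largest_remainder_counts(self):
        event = np.array([1] * 40 + [0] * 60)
        split = stratified_split(event, seed=0)
        tr = split.rows("train")
        assert event[tr].sum() == 28 and (event[tr] == 0).sum() == 42
        assert len(split.rows("val")) == 15 and len(split.rows("test")) == 15

    def test_seed_determinism(self):
        event = np.random.default_rng(1).integers(0, 2, 97)
        a = stratified_split(event, seed=5)
        b = stratified_split(event, seed=5)
        assert np.array_equal(a.labels, b.labels)

    def test_partition_is_disjoint_and_exhaustive(self):
        event = np.random.default_rng(2).integers(0, 2, 83)
        split = stratified_split(event, seed=3)
        parts = [set(split.rows(p)) for p in ("train", "val", "test")]
        assert sum(len(p) for p in parts) == 83
        assert set().union(*parts) == set(range(83))

    def test_all_censored_still_valid_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            split = stratified_split(np.zeros(30, int), seed=0)
        assert len(split.rows("train")) == 21


class TestFusion:
    def test_embed_clin_width_3075(self, rng):
        emb = rng.normal(size=(10, 3072))
        clin = rng.normal(size=(10, 3))
        assert fuse_features(embeddings=emb, clinical=clin).shape[1] == 3075

    def test_egsp_width_1795(self, rng):
        emb = rng.normal(size=(10, 768))
        expr = rng.normal(size=(10, 1024))
        clin = rng.normal(size=(10, 3))
        fused = fuse_features(emb, expr, clin, training_gene_means=expr[:5].mean(0))
        assert fused.shape[1] == 1795

    def test_mrna_clin_width_1027(self, rng):
        expr = rng.normal(size=(10, 1024))
        clin = rng.normal(size=(10, 3))
        fused = fuse_features(None, expr, clin, training_gene_means=expr.mean(0))
        assert fused.shape[1] == 1027

    def test_training_rows_centered_to_zero(self, rng):
        expr = rng.normal(size=(20, 6)) + 3.0
        train_rows = np.arange(12)
        fused = fuse_features(None, expr, None,
                              training_gene_means=expr[train_rows].mean(0))
        assert np.abs(fused[train_rows].mean(axis=0)).max() < 1e-10

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="sample count"):
            fuse_features(rng.normal(size=(5, 4)), None, rng.normal(size=(6, 2)))


class TestCoxLoss:
    def test_single_subject_event_is_zero(self):
        assert cox_partial_likelihood_loss([1.3], [2.0], [1]) == pytest.approx(0.0)

    def test_no_events_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="no events"):
            assert cox_partial_likelihood_loss([1.0, 2.0], [1.0, 2.0], [0, 0]) == 0.0

    def test_equal_scores_closed_form(self):
        loss = cox_partial_likelihood_loss([0.0, 0.0, 0.0], [1, 2, 3], [1, 1, 0])
        assert loss == pytest.approx(np.log(3) + np.log(2), abs=1e-12)

    def test_matches_double_sum_oracle(self, rng):
        """Direct double-sum evaluation of the printed formula."""
        for trial in range(5):
            n = 8
            r = rng.normal(size=n)
            t = rng.exponential(size=n)
            t[2] = t[6]  # a tie: both must enter each other's risk set
            e = rng.integers(0, 2, n)
            e[:3] = 1
            brute = -sum(
                e[i] * (r[i] - np.log(sum(np.exp(r[j]) for j in range(n) if t[j] >= t[i])))
                for i in range(n)
            )
            assert cox_partial_likelihood_loss(r, t, e) == pytest.approx(brute, abs=1e-10)

    def test_mean_reduction_divides_by_events(self, rng):
        r = rng.normal(size=6)
        t = rng.exponential(size=6)
        e = np.array([1, 1, 0, 1, 0, 0])
        assert cox_partial_likelihood_loss(r, t, e, "mean") == pytest.approx(
            cox_partial_likelihood_loss(r, t, e) / 3
        )

    def test_gradient_matches_finite_differences(self, rng):
        r = rng.normal(size=10)
        t = rng.exponential(size=10)
        e = rng.integers(0, 2, 10)
        e[:2] = 1
        _, g = cox_loss_and_risk_gradient(r, t, e)
        for k in range(10):
            dp, dm = r.copy(), r.copy()
            dp[k] += 1e-6
            dm[k] -= 1e-6
            fd = (cox_partial_likelihood_loss(dp, t, e)
                  - cox_partial_likelihood_loss(dm, t, e)) / 2e-6
            assert g[k] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestModelGradients:
    def test_head_parameter_gradients_match_finite_differences(self, rng):
        """Loss gradient through the risk head vs central differences on a
        10-sample fixture (within 1e-4 relative)."""
        X = rng.normal(size=(10, 4))
        t = rng.exponential(size=10)
        e = np.array([1, 1, 1, 0, 1, 0, 1, 0, 1, 1])
        model = RiskModel(4, head_widths=(6, 3), dropout=0.0, seed=0)
        for p in model.net.parameters():  # move off exact ReLU kinks
            p += rng.normal(0.0, 0.05, size=p.shape)
        out, cache = model.net.forward(X, training=False)
        _, d_risk = cox_loss_and_risk_gradient(out, t, e)
        grads = model.net.backward(d_risk, cache)
        for p, g in zip(model.net.parameters(), grads):
            idx = np.unravel_index(np.argmax(np.abs(g)), g.shape)
            eps, orig = 1e-6, p[idx]
            p[idx] = orig + eps
            up = cox_partial_likelihood_loss(model.predict(X), t, e)
            p[idx] = orig - eps
            dn = cox_partial_likelihood_loss(model.predict(X), t, e)
            p[idx] = orig
            assert g[idx] == pytest.approx((up - dn) / (2 * eps), rel=1e-4, abs=1e-8)


def _toy_training_setup(rng, n=60):
    X = rng.normal(size=(n, 5))
    lp = X @ np.array([1.5, -1.0, 0.5, 0.0, 0.0])
    t = rng.exponential(scale=np.exp(-lp))
    e = np.ones(n, int)
    labels = np.array(["train"] * 40 + ["val"] * 10 + ["test"] * 10)
    return X, t, e, SplitAssignment(labels=labels)


class TestTraining:
    def test_loss_trends_down_on_separable_toy(self, rng):
        X, t, e, split = _toy_training_setup(rng)
        model = RiskModel(5, head_widths=(8,), dropout=0.0, seed=1)
        tr = split.rows("train")
        from fusesurv._nn import AdamW, clip_global_norm

        opt = AdamW(model.net.parameters(), lr=1e-2, weight_decay=0.0)
        losses = []
        for _ in range(5):
            out, cache = model.net.forward(X[tr], training=False)
            loss, d = cox_loss_and_risk_gradient(out, t[tr], e[tr])
            losses.append(loss)
            grads = model.net.backward(d, cache)
            clip_global_norm(grads, 5.0)
            opt.step(grads)
        assert losses[-1] < losses[0]

    def test_early_stopping_halts_within_patience(self, rng):
        """A vanishing learning rate freezes the validation criterion, so
        training must halt once patience is exhausted."""
        X, t, e, split = _toy_training_setup(rng)
        model = RiskModel(5, head_widths=(4,), dropout=0.0, seed=0)
        tc = TrainConfig(lr_grid=(1e-30,), weight_decay_grid=(0.0,),
                         grad_norm_grid=(1.0,), max_epochs=100, patience=3, seed=0)
        _, log = train(model, X, t, e, split, tc)
        assert log["selected"]["best_epoch"] == 0

    def test_seed_determinism_of_selected_weights(self, rng):
        X, t, e, split = _toy_training_setup(rng)
        tc = TrainConfig(lr_grid=(1e-2, 1e-3), weight_decay_grid=(0.01,),
                         grad_norm_grid=(1.0,), max_epochs=10, patience=5, seed=7)
        m1, log1 = train(RiskModel(5, head_widths=(6,), seed=7), X, t, e, split, tc)
        m2, log2 = train(RiskModel(5, head_widths=(6,), seed=7), X, t, e, split, tc)
        assert log1["selected"] == log2["selected"]
        for a, b in zip(m1.net.parameters(), m2.net.parameters()):
            assert np.array_equal(a, b)

    def test_permuting_test_labels_never_touches_training(self, rng):
        """Leakage guard: shuffling test-split outcomes leaves the fitted
        weights bit-identical."""
        X, t, e, split = _toy_training_setup(rng)
        tc = TrainConfig(lr_grid=(1e-2,), weight_decay_grid=(0.01,),
                         grad_norm_grid=(1.0,), max_epochs=8, patience=4, seed=2)
        m1, _ = train(RiskModel(5, head_widths=(6,), seed=2), X, t, e, split, tc)
        te = split.rows("test")
        t2, e2 = t.copy(), e.copy()
        perm = rng.permutation(len(te))
        t2[te] = t[te][perm]
        m2, _ = train(RiskModel(5, head_widths=(6,), seed=2), X, t2, e2, split, tc)
        for a, b in zip(m1.net.parameters(), m2.net.parameters()):
            assert np.array_equal(a, b)

    def test_pure_noise_features_give_chance_test_concordance(self):
        cs = []
        for seed in range(3):
            rng = np.random.default_rng(400 + seed)
            n = 200
            X = rng.normal(size=(n, 10))
            t = rng.exponential(size=n)
            e = rng.random(n) < 0.7
            split = stratified_split(e.astype(int), seed=seed)
            tc = TrainConfig(lr_grid=(1e-2,), weight_decay_grid=(0.01,),
                             grad_norm_grid=(1.0,), max_epochs=15, patience=5,
                             seed=seed)
            model, _ = train(RiskModel(10, head_widths=(8, 4), seed=seed),
                             X, t, e.astype(int), split, tc)
            te = split.rows("test")
            cs.append(harrell_cindex(model.predict(X[te]), t[te],
                                     e[te].astype(int)).estimate)
        assert 0.4 <= np.mean(cs) <= 0.6


@pytest.fixture(scope="module")
def two_cohorts():
    out = []
    for i, label in enumerate(("AA", "BB")):
        cfg = SimulationConfig(n_samples=100, n_genes=30, seed=50 + i,
                               cohort_label=label)
        out.append(simulate_cohort(cfg)[0])
    return out


class TestVariants:
    def _fast_tc(self, seed=0):
        return TrainConfig(lr_grid=(1e-2,), weight_decay_grid=(0.01,),
                           grad_norm_grid=(1.0,), max_epochs=3, patience=2, seed=seed)

    def test_unknown_variant_lists_valid_names(self, two_cohorts):
        with pytest.raises(ValueError, match="EGSP"):
            fit_variant(two_cohorts[0], "Embed+mRNA")

    def test_mrna_clin_input_width(self, two_cohorts):
        pc = PipelineConfig(Ng=12, head_widths=(8,), seed=0)
        res = fit_variant(two_cohorts[0], "mRNA+Clin", pc, self._fast_tc())
        assert res.model.in_dim == 12 + 3  # Ng + Nc

    def test_embed_variant_has_no_clinical_block(self, two_cohorts):
        enc = EncoderConfig(vocab_size=30, hidden_width=8, n_layers=2,
                            pool_type="all", seed=0)
        pc = PipelineConfig(Ng=12, encoder=enc, head_widths=(8,), seed=0)
        res = fit_variant(two_cohorts[0], "Embed", pc, self._fast_tc())
        assert res.model.in_dim == 4 * 8  # Ne only

    def test_egsp_pan_with_frozen_encoder_matches_egsp_embeddings(self, two_cohorts):
        enc = EncoderConfig(vocab_size=30, hidden_width=8, n_layers=2,
                            pool_type="max", seed=0)
        pc = PipelineConfig(Ng=12, Nu=0, encoder=enc, head_widths=(8,), seed=0)
        r_pan = fit_variant(two_cohorts, "EGSP-pan", pc, self._fast_tc())
        fresh = init_mock_encoder(enc)
        for wa, wb in zip(r_pan.encoder.W, fresh.W):
            assert np.array_equal(wa, wb)

    def test_pan_training_with_unfrozen_layers_changes_encoder(self, two_cohorts):
        enc = EncoderConfig(vocab_size=30, hidden_width=8, n_layers=2,
                            pool_type="max", seed=0)
        pc = PipelineConfig(Ng=12, Nu=1, encoder=enc, head_widths=(8,), seed=0)
        res = fit_variant(two_cohorts, "EGSP-pan", pc, self._fast_tc())
        fresh = init_mock_encoder(enc)
        assert not np.array_equal(res.encoder.W[-1], fresh.W[-1])
        assert np.array_equal(res.encoder.W[0], fresh.W[0])  # frozen layer intact

    def test_risks_cover_all_samples_and_splits(self, two_cohorts):
        pc = PipelineConfig(Ng=12, head_widths=(8,), seed=0)
        res = fit_variant(two_cohorts[0], "mRNA+Clin", pc, self._fast_tc())
        assert len(res.risks) == 100
        assert set(res.risks["split"]) == {"train", "val", "test"}


class TestPanPool:
    def test_concatenation_arithmetic(self):
        cohorts = [simulate_cohort(SimulationConfig(n_samples=100, n_genes=5,
                                                    seed=s, cohort_label=l))[0]
                   for s, l in ((1, "AA"), (2, "BB"))]
        splits = [stratified_split(c.event, seed=0) for c in cohorts]
        ids, cohort_of, time, event, pooled = pan_cancer_pool(cohorts, splits)
        assert len(pooled.rows("train")) == 140
        assert np.mean(event) == pytest.approx(
            np.mean([c.event_fraction for c in cohorts])
        )
        assert set(cohort_of) == {"AA", "BB"}
        # original split labels preserved
        assert np.array_equal(pooled.labels[:100], splits[0].labels)

    def test_duplicate_ids_rejected(self):
        c, _ = simulate_cohort(SimulationConfig(n_samples=20, n_genes=5, seed=1))
        split = stratified_split(c.event, seed=0)
        with pytest.raises(ValueError, match="overlapping"):
            pan_cancer_pool([c, c], [split, split])


def test_clinical_encoding_ncolumns_follow_stage_availability():
    c_full, _ = simulate_cohort(SimulationConfig(n_samples=40, n_genes=5, seed=1))
    c_miss, _ = simulate_cohort(SimulationConfig(n_samples=40, n_genes=5, seed=1,
                                                 missing_stage=True))
    tr = np.arange(28)
    assert encode_clinical(c_full.clinical, tr).shape[1] == 3
    assert encode_clinical(c_miss.clinical, tr).shape[1] == 2
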
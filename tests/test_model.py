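"""Conditional VAE contracts: determinism, losses, stopping, prediction."""

import numpy as np
import pytest

from crossbear.model import (CellDataset, CellObservation, CrossSpeciesVAE,
                             FactorDesign, ModelConfig, fit,
                             select_hyperparameters)
from crossbear.synthetic import SyntheticConfig, generate_zinb_dataset


def small_dataset(seed=0, n_cells=150, n_genes=30):
    data = generate_zinb_dataset(SyntheticConfig(
        seed=seed, n_cells=n_cells, n_genes=n_genes, n_cell_types=3,
        depth_range=(100, 300), heldout_type=False))
    return CellDataset(data.counts, data.species, data.batch, data.tissue)


def small_config(**kw):
    defaults = dict(latent_dim=4, hidden_width=16, minibatch_size=64,
                    max_epochs=3, patience_epochs=3, seed=0)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestEncode:
    def test_identical_cells_identical_posteriors(self):
        ds = small_dataset()
        model = CrossSpeciesVAE(30, ds.design, small_config())
        obs = CellObservation(ds.counts[0], ds.species[0])
        p1, p2 = model.encode(obs), model.encode(obs)
        np.testing.assert_array_equal(p1.mean, p2.mean)
        np.testing.assert_array_equal(p1.log_variance, p2.log_variance)

    def test_batch_encoding_is_permutation_equivariant(self):
        ds = small_dataset()
        model = CrossSpeciesVAE(30, ds.design, small_config())
        perm = np.random.default_rng(0).permutation(len(ds))
        post = model.encode_batch(ds.counts, ds.species, ds.batch, ds.tissue)
        post_p = model.encode_batch(ds.counts[perm], ds.species[perm],
                                    ds.batch[perm], ds.tissue[perm])
        np.testing.assert_allclose(post.mean[perm], post_p.mean)

    def test_untrained_seeded_model_is_reproducible(self):
        ds = small_dataset()
        m1 = CrossSpeciesVAE(30, ds.design, small_config(seed=7))
        m2 = CrossSpeciesVAE(30, ds.design, small_config(seed=7))
        obs = CellObservation(ds.counts[3], ds.species[3])
        np.testing.assert_array_equal(m1.encode(obs).mean,
                                      m2.encode(obs).mean)

    def test_unknown_label_and_shape_errors(self):
        ds = small_dataset()
        model = CrossSpeciesVAE(30, ds.design, small_config())
        with pytest.raises(KeyError):
            model.encode(CellObservation(ds.counts[0], "axolotl"))
        with pytest.raises(ValueError):
            model.encode(CellObservation(ds.counts[0][:10], ds.species[0]))


class TestFit:
    def test_same_seed_identical_training_log(self):
        ds = small_dataset()
        m1 = fit(ds, small_config())
        m2 = fit(ds, small_config())
        assert m1.training_log == m2.training_log

    def test_constant_validation_loss_stops_after_patience(self):
        # zero learning rate freezes parameters, so validation loss never
        # improves after the first epoch and the rule forces the stop
        ds = small_dataset()
        model = fit(ds, small_config(learning_rate=0.0, patience_epochs=3,
                                     max_epochs=50))
        assert len(model.training_log) == 4

    def test_training_reduces_validation_loss(self):
        ds = small_dataset(n_cells=300)
        model = fit(ds, small_config(max_epochs=15, patience_epochs=15,
                                     latent_dim=8, hidden_width=32))
        log = model.training_log
        assert log[-1]["val_cvae"] < log[0]["val_cvae"]

    def test_empty_dataset_rejected(self):
        ds = small_dataset()
        empty = CellDataset(ds.counts[:0], ds.species[:0], ds.batch[:0],
                            ds.tissue[:0], design=ds.design)
        with pytest.raises(ValueError):
            fit(empty, small_config())


class TestLosses:
    def test_cvae_equals_reconstruction_plus_kl(self):
        ds = small_dataset()
        model = fit(ds, small_config())
        br = model.loss_breakdown(ds)
        assert abs(br.cvae - (br.reconstruction + br.kl)) < 1e-6

    def test_discriminator_uniform_and_perfect(self):
        ds = small_dataset()
        cfg = small_config(use_discriminator=True)
        model = CrossSpeciesVAE(30, ds.design, cfg)
        k = len(ds.design.species_levels)
        z = np.random.default_rng(0).normal(size=(5, cfg.latent_dim))
        model.disc_W.data[:] = 0.0
        model.disc_b.data[:] = 0.0
        loss = model.discriminator_loss(z, [ds.design.species_levels[0]] * 5)
        np.testing.assert_allclose(loss, np.log(k), rtol=1e-12)
        # saturate towards the true label -> loss ~ 0
        true_idx = 1
        model.disc_b.data[:] = -500.0
        model.disc_b.data[true_idx] = 500.0
        loss = model.discriminator_loss(
            z, [ds.design.species_levels[true_idx]] * 5)
        assert loss < 1e-10

    def test_discriminator_manual_cross_entropy(self):
        design = FactorDesign(["h", "m", "o"])
        cfg = small_config(use_discriminator=True, latent_dim=2)
        model = CrossSpeciesVAE(5, design, cfg)
        model.disc_W.data = np.array([[1.0, 0.0, -1.0], [0.5, -0.5, 0.0]])
        model.disc_b.data = np.array([0.1, 0.2, 0.3])
        z = np.array([[1.0, 2.0]])
        logits = z @ model.disc_W.data + model.disc_b.data
        expected = -(logits[0, 1] - np.log(np.exp(logits).sum()))
        np.testing.assert_allclose(model.discriminator_loss(z, ["m"]),
                                   expected, rtol=1e-12)

    def test_discriminator_disabled_raises(self):
        ds = small_dataset()
        model = CrossSpeciesVAE(30, ds.design, small_config())
        with pytest.raises(RuntimeError):
            model.discriminator_loss(np.zeros((1, 4)), [ds.species[0]])


class TestPredict:
    def test_output_is_depth_normalized_distribution(self):
        ds = small_dataset()
        model = fit(ds, small_config())
        obs = CellObservation(ds.counts[0], ds.species[0])
        mu = model.predict_cross_species(obs, ds.design.species_levels[1])
        assert mu.shape == (30,)
        assert np.all(mu > 0)
        np.testing.assert_allclose(mu.sum(), 1.0, rtol=1e-10)

    def test_identity_swap_matches_own_species_decoding(self):
        ds = small_dataset()
        model = fit(ds, small_config())
        obs = CellObservation(ds.counts[0], ds.species[0])
        mu = model.predict_cross_species(obs, obs.species)
        post = model.encode(obs)
        F = ds.design.encode_factors([obs.species], [obs.batch], [obs.tissue])
        expected = model.decode_np(post.mean[None, :], F).mu_prime[0]
        np.testing.assert_allclose(mu, expected)

    def test_invariant_to_depth_scale_of_identical_counts(self):
        # mu' is a softmax over genes: the cell's stored depth never enters
        ds = small_dataset()
        model = fit(ds, small_config())
        obs = CellObservation(ds.counts[0], ds.species[0])
        target = ds.design.species_levels[1]
        mu1 = model.predict_cross_species(obs, target)
        mu2 = model.predict_cross_species(
            CellObservation(ds.counts[0].copy(), ds.species[0]), target)
        np.testing.assert_array_equal(mu1, mu2)

    def test_linear_toy_decoder_hand_forward(self):
        # force constant hidden activations so the mean head reduces to a
        # softmax of its bias, which we can compute by hand
        design = FactorDesign(["a", "b"])
        cfg = small_config(latent_dim=2, hidden_width=4)
        model = CrossSpeciesVAE(3, design, cfg)
        dec = model.decoder
        dec.W1.data[:] = 0.0
        dec.b1.data[:] = 1.0
        dec.W2.data[:] = 0.0
        dec.b2.data[:] = 1.0
        Wh, bh = dec.heads[0]
        Wh.data[:] = 0.0
        bh.data = np.array([0.3, -0.1, 1.2])
        obs = CellObservation(np.array([4.0, 1.0, 0.0]), "a")
        mu = model.predict_cross_species(obs, "b")
        expected = np.exp(bh.data) / np.exp(bh.data).sum()
        np.testing.assert_allclose(mu, expected, rtol=1e-12)

    def test_unregistered_target_species(self):
        ds = small_dataset()
        model = fit(ds, small_config())
        with pytest.raises(KeyError):
            model.predict_cross_species(
                CellObservation(ds.counts[0], ds.species[0]), "axolotl")


class TestGridSearch:
    def test_singleton_grid_returns_that_model(self):
        ds = small_dataset()
        best, records = select_hyperparameters(
            ds, latent_dims=(4,), use_discriminator=(False,),
            base_config=small_config(max_epochs=2, patience_epochs=2),
            perplexity=4)
        assert len(records) == 1
        assert best.config.latent_dim == 4

    def test_selected_model_attains_max_logged_lisi(self):
        ds = small_dataset(n_cells=200)
        best, records = select_hyperparameters(
            ds, latent_dims=(4, 8), use_discriminator=(False,),
            base_config=small_config(max_epochs=3, patience_epochs=3),
            perplexity=4)
        scores = [r["lisi"] for r in records]
        winner = records[int(np.argmax(scores))]
        assert best.config.latent_dim == winner["latent_dim"]
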
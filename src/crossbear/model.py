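"""Conditional variational autoencoder for cross-species single-cell counts.

The model decomposes each cell's raw UMI count vector into a low-dimensional
species-invariant cell embedding plus one-hot batch/species/tissue factors.
The decoder emits zero-inflated negative binomial parameters per gene: a
depth-corrected mean ``mu'`` (a softmax over genes, so ``d * mu'`` matches the
cell's observed depth ``d``), a per-gene dispersion shared across cells, and
a per-gene dropout logit. Training minimizes reconstruction NLL plus the KL
of the Gaussian posterior against a standard-normal prior; an optional
single-layer adversarial discriminator pushes embeddings to be
species-indistinguishable. Cross-species prediction decodes a cell's
posterior-mean embedding with the indicator of a different species.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from ._autograd import Adam, Tensor, concat
from .likelihood import LatentPosterior, ZINBParams, kl_divergence, zinb_neg_loglik
from .lisi import compute_lisi

__all__ = [
    "CellObservation", "FactorDesign", "ModelConfig", "LossBreakdown",
    "CellDataset", "CrossSpeciesVAE", "fit", "select_hyperparameters",
]


@dataclass
class CellObservation:
    """One cell: raw counts plus its categorical factor labels."""

    counts: np.ndarray
    species: str
    batch: str = "batch0"
    tissue: str = "tissue0"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def depth(self) -> float:
        return float(self.counts.sum())


class FactorDesign:
    """One-hot indicator encoding of the registered factor levels."""

    def __init__(self, species_levels, batch_levels=("batch0",),
                 tissue_levels=("tissue0",)):
        self.species_levels = tuple(species_levels)
        self.batch_levels = tuple(batch_levels)
        self.tissue_levels = tuple(tissue_levels)
        self._sp = {s: i for i, s in enumerate(self.species_levels)}
        self._ba = {b: i for i, b in enumerate(self.batch_levels)}
        self._ti = {t: i for i, t in enumerate(self.tissue_levels)}

    @property
    def n_factor_dims(self) -> int:
        return (len(self.species_levels) + len(self.batch_levels)
                + len(self.tissue_levels))

    def _onehot(self, labels, table, name):
        labels = np.atleast_1d(np.asarray(labels))
        out = np.zeros((labels.shape[0], len(table)))
        for i, lab in enumerate(labels):
            if lab not in table:
                raise KeyError(f"unknown {name} label: {lab!r}")
            out[i, table[lab]] = 1.0
        return out

    def encode_factors(self, species, batch, tissue) -> np.ndarray:
        """(n, n_factor_dims) stacked indicators for species|batch|tissue."""
        return np.hstack([
            self._onehot(species, self._sp, "species"),
            self._onehot(batch, self._ba, "batch"),
            self._onehot(tissue, self._ti, "tissue"),
        ])


@dataclass
class ModelConfig:
    latent_dim: int = 25
    use_discriminator: bool = False
    hidden_layers: int = 2
    hidden_width: int = 128
    learning_rate: float = 1e-3
    minibatch_size: int = 128
    patience_epochs: int = 45
    max_epochs: int = 500
    validation_fraction: float = 0.10
    validation_cap: int = 20000
    adversarial_weight: float = 1.0
    log1p_input: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim <= 0:
            raise ValueError("latent_dim must be positive")
        if self.hidden_layers != 2:
            raise ValueError("encoder/decoder depth is fixed to 2 hidden layers")


@dataclass
class LossBreakdown:
    reconstruction: float
    kl: float
    cvae: float
    discriminator: float | None = None


@dataclass
class CellDataset:
    """Raw count matrix plus per-cell factor labels and the factor design."""

    counts: np.ndarray               # (n_cells, n_genes) raw UMI counts
    species: np.ndarray
    batch: np.ndarray = None
    tissue: np.ndarray = None
    design: FactorDesign = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        n = self.counts.shape[0]
        self.species = np.asarray(self.species)
        if self.batch is None:
            self.batch = np.full(n, "batch0")
        if self.tissue is None:
            self.tissue = np.full(n, "tissue0")
        self.batch = np.asarray(self.batch)
        self.tissue = np.asarray(self.tissue)
        if self.design is None:
            self.design = FactorDesign(
                sorted(set(self.species.tolist())),
                sorted(set(self.batch.tolist())),
                sorted(set(self.tissue.tolist())),
            )

    @classmethod
    def from_anndata(cls, adata) -> "CellDataset":
        import scipy.sparse as sp
        X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
        obs = adata.obs
        return cls(
            counts=X,
            species=obs["species"].to_numpy(),
            batch=obs["batch"].to_numpy() if "batch" in obs else None,
            tissue=obs["tissue"].to_numpy() if "tissue" in obs else None,
        )

    def __len__(self):
        return self.counts.shape[0]

    @property
    def depths(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def factors(self) -> np.ndarray:
        return self.design.encode_factors(self.species, self.batch, self.tissue)


def _glorot(rng, fan_in, fan_out):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=(fan_in, fan_out)),
                  requires_grad=True)


def _zeros(n):
    return Tensor(np.zeros(n), requires_grad=True)


class _MLP:
    """Two hidden ReLU layers followed by one or more affine heads."""

    def __init__(self, rng, n_in, width, head_dims):
        self.W1 = _glorot(rng, n_in, width)
        self.b1 = _zeros(width)
        self.W2 = _glorot(rng, width, width)
        self.b2 = _zeros(width)
        self.heads = [(_glorot(rng, width, h), _zeros(h)) for h in head_dims]

    def params(self):
        ps = [self.W1, self.b1, self.W2, self.b2]
        for W, b in self.heads:
            ps += [W, b]
        return ps

    def __call__(self, x: Tensor):
        h = (x @ self.W1 + self.b1).relu()
        h = (h @ self.W2 + self.b2).relu()
        return [h @ W + b for W, b in self.heads]

    def forward_np(self, x: np.ndarray):
        h = np.maximum(x @ self.W1.data + self.b1.data, 0.0)
        h = np.maximum(h @ self.W2.data + self.b2.data, 0.0)
        return [h @ W.data + b.data for W, b in self.heads]


class CrossSpeciesVAE:
    """Conditional ZINB VAE with optional adversarial species alignment."""

    def __init__(self, n_genes: int, design: FactorDesign,
                 config: ModelConfig | None = None):
        self.n_genes = n_genes
        self.design = design
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        nf = design.n_factor_dims
        self.encoder = _MLP(rng, n_genes + nf, cfg.hidden_width,
                            [cfg.latent_dim, cfg.latent_dim])
        self.decoder = _MLP(rng, cfg.latent_dim + nf, cfg.hidden_width,
                            [n_genes, n_genes])
        # per-gene dispersion, shared across cells: r = softplus(rho)
        self.rho = Tensor(np.zeros(n_genes), requires_grad=True)
        n_species = len(design.species_levels)
        self.disc_W = _glorot(rng, cfg.latent_dim, n_species)
        self.disc_b = _zeros(n_species)
        self.training_log: list[dict] = []
        self._rng = rng

    # -- parameter bookkeeping --------------------------------------------

    def _vae_params(self):
        return self.encoder.params() + self.decoder.params() + [self.rho]

    def _disc_params(self):
        return [self.disc_W, self.disc_b]

    def _snapshot(self):
        return [p.data.copy() for p in self._vae_params() + self._disc_params()]

    def _restore(self, snap):
        for p, d in zip(self._vae_params() + self._disc_params(), snap):
            p.data = d.copy()

    # -- forward passes ----------------------------------------------------

    def _enc_input(self, X: np.ndarray, F: np.ndarray) -> np.ndarray:
        Xin = np.log1p(X) if self.config.log1p_input else X
        return np.hstack([Xin, F])

    def encode_batch(self, X: np.ndarray, species, batch, tissue) -> LatentPosterior:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_genes:
            raise ValueError(
                f"expected {self.n_genes} genes, got {X.shape[1]}")
        F = self.design.encode_factors(species, batch, tissue)
        mean, logvar = self.encoder.forward_np(self._enc_input(X, F))
        return LatentPosterior(mean=mean, log_variance=logvar)

    def encode(self, obs: CellObservation) -> LatentPosterior:
        """Posterior q(z | X, b, s, t) for a single cell."""
        post = self.encode_batch(obs.counts[None, :], [obs.species],
                                 [obs.batch], [obs.tissue])
        return LatentPosterior(post.mean[0], post.log_variance[0])

    def decode_np(self, z: np.ndarray, F: np.ndarray) -> ZINBParams:
        mu_logits, drop = self.decoder.forward_np(np.hstack([z, F]))
        shifted = mu_logits - mu_logits.max(axis=-1, keepdims=True)
        mu = np.exp(shifted)
        mu /= mu.sum(axis=-1, keepdims=True)
        r = np.logaddexp(0.0, self.rho.data) + 1e-4
        return ZINBParams(mu_prime=np.maximum(mu, 1e-300),
                          dispersion=np.broadcast_to(r, mu.shape).copy(),
                          dropout_logit=drop)

    # -- losses (autograd path) ---------------------------------------------

    def _recon_loss_t(self, X: np.ndarray, depth: np.ndarray,
                      z: Tensor, F: np.ndarray) -> Tensor:
        from scipy.special import gammaln as sp_gammaln

        mu_logits, drop = self.decoder(concat([z, Tensor(F)], axis=1))
        log_mu = mu_logits.log_softmax(axis=-1)
        r = self.rho.softplus() + 1e-4                     # (G,)
        log_m = log_mu + np.log(depth)[:, None]            # log(d * mu')
        m = log_m.exp()
        log_r_rm = r.log() - (r + m).log()
        nb0 = r * log_r_rm
        s = drop
        # log P(0) = -softplus(-s) + softplus(nb0 - s); log(1-pi) = -softplus(s)
        log_mix0 = -(-s).softplus() + (nb0 - s).softplus()
        log_pos = (-(s.softplus()) + (Tensor(X) + r).gammaln() - r.gammaln()
                   + nb0 + Tensor(X) * (log_m - (r + m).log()))
        log_pos = log_pos - sp_gammaln(X + 1.0)
        mask0 = (X == 0).astype(np.float64)
        ll = log_mix0 * mask0 + log_pos * (1.0 - mask0)
        return -(ll.sum(axis=1).mean())

    def _kl_t(self, mean: Tensor, logvar: Tensor) -> Tensor:
        per_cell = (mean ** 2.0 + logvar.exp() - logvar - 1.0).sum(axis=1) * 0.5
        return per_cell.mean()

    def _disc_ce_t(self, z: Tensor, species_idx: np.ndarray) -> Tensor:
        logits = z @ self.disc_W + self.disc_b
        logp = logits.log_softmax(axis=-1)
        onehot = np.zeros(logp.shape)
        onehot[np.arange(len(species_idx)), species_idx] = 1.0
        return -((logp * onehot).sum(axis=1).mean())

    def discriminator_loss(self, z, species) -> float:
        """Cross-entropy of the single-layer species discriminator."""
        if not self.config.use_discriminator:
            raise RuntimeError("discriminator is disabled in this config")
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        idx = np.array([self.design._sp[s] for s in np.atleast_1d(species)])
        return float(self._disc_ce_t(Tensor(z), idx).data)

    # -- evaluation ---------------------------------------------------------

    def loss_breakdown(self, dataset: CellDataset) -> LossBreakdown:
        """Deterministic losses at the posterior mean."""
        X = dataset.counts
        F = dataset.factors()
        depth = np.maximum(dataset.depths, 1.0)
        post = self.encode_batch(X, dataset.species, dataset.batch,
                                 dataset.tissue)
        params = self.decode_np(post.mean, F)
        recon = float(np.mean(zinb_neg_loglik(X, depth[:, None], params).sum(axis=1)))
        kl = float(np.mean(kl_divergence(post)))
        out = LossBreakdown(reconstruction=recon, kl=kl, cvae=recon + kl)
        if self.config.use_discriminator:
            idx = np.array([self.design._sp[s] for s in dataset.species])
            out.discriminator = float(
                self._disc_ce_t(Tensor(post.mean), idx).data)
        return out

    # -- training -----------------------------------------------------------

    def fit(self, dataset: CellDataset):
        """Train with early stopping on validation cVAE loss.

        Returns self; per-epoch losses are appended to ``training_log``.
        """
        cfg = self.config
        n = len(dataset)
        if n == 0:
            raise ValueError("empty dataset")
        rng = np.random.default_rng(cfg.seed + 1)
        perm = rng.permutation(n)
        n_val = min(max(1, int(round(cfg.validation_fraction * n))),
                    cfg.validation_cap, n - 1)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        bs = min(cfg.minibatch_size, len(train_idx))

        X = dataset.counts
        F = dataset.factors()
        depth = np.maximum(dataset.depths, 1.0)
        sp_idx = np.array([self.design._sp[s] for s in dataset.species])
        val = CellDataset(X[val_idx], dataset.species[val_idx],
                          dataset.batch[val_idx], dataset.tissue[val_idx],
                          design=dataset.design)

        opt_vae = Adam(self._vae_params(), lr=cfg.learning_rate)
        opt_disc = Adam(self._disc_params(), lr=cfg.learning_rate)

        best_val, best_snap, stall = np.inf, self._snapshot(), 0
        self.training_log = []
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(train_idx))
            batches = [train_idx[order[i:i + bs]]
                       for i in range(0, len(order), bs)]

            dis_losses = []
            if cfg.use_discriminator:
                # step 1: train discriminator on detached embeddings
                for idx in batches:
                    post = self.encode_batch(X[idx], dataset.species[idx],
                                             dataset.batch[idx],
                                             dataset.tissue[idx])
                    eps = rng.standard_normal(post.mean.shape)
                    z = post.mean + np.exp(0.5 * post.log_variance) * eps
                    opt_disc.zero_grad()
                    loss_d = self._disc_ce_t(Tensor(z), sp_idx[idx])
                    loss_d.backward()
                    opt_disc.step()
                    dis_losses.append(float(loss_d.data))

            rec_losses, kl_losses = [], []
            for idx in batches:
                xb, fb, db = X[idx], F[idx], depth[idx]
                enc_in = Tensor(self._enc_input(xb, fb))
                mean_t, logvar_t = self.encoder(enc_in)
                eps = rng.standard_normal(mean_t.shape)
                z = mean_t + (logvar_t * 0.5).exp() * eps
                recon = self._recon_loss_t(xb, db, z, fb)
                kl = self._kl_t(mean_t, logvar_t)
                loss = recon + kl
                if cfg.use_discriminator:
                    loss = loss - cfg.adversarial_weight * self._disc_ce_t(
                        z, sp_idx[idx])
                opt_vae.zero_grad()
                opt_disc.zero_grad()  # grads leak into fixed D; discard
                loss.backward()
                opt_vae.step()
                rec_losses.append(float(recon.data))
                kl_losses.append(float(kl.data))

            val_loss = self.loss_breakdown(val)
            entry = {
                "epoch": epoch,
                "train_reconstruction": float(np.mean(rec_losses)),
                "train_kl": float(np.mean(kl_losses)),
                "val_cvae": val_loss.cvae,
            }
            if cfg.use_discriminator:
                entry["train_discriminator"] = float(np.mean(dis_losses))
            self.training_log.append(entry)

            if val_loss.cvae < best_val:
                best_val, best_snap, stall = val_loss.cvae, self._snapshot(), 0
            else:
                stall += 1
                if stall >= cfg.patience_epochs:
                    break
        self._restore(best_snap)
        self.validation_indices_ = val_idx
        self.best_validation_loss_ = best_val
        return self

    # -- prediction ----------------------------------------------------------

    def predict_cross_species(self, obs, target_species: str) -> np.ndarray:
        """Depth-normalized denoised expression of `obs` in `target_species`.

        Decodes the posterior-mean embedding with the target species
        indicator and the cell's own batch/tissue indicators; returns the
        per-gene mean ``mu'`` (sums to 1 over genes), without sampling or
        dropout.
        """
        if target_species not in self.design._sp:
            raise KeyError(f"unknown species label: {target_species!r}")
        single = isinstance(obs, CellObservation)
        if single:
            obs = CellDataset(obs.counts[None, :], np.array([obs.species]),
                              np.array([obs.batch]), np.array([obs.tissue]),
                              design=self.design)
        post = self.encode_batch(obs.counts, obs.species, obs.batch,
                                 obs.tissue)
        n = len(obs)
        F = self.design.encode_factors(np.full(n, target_species),
                                       obs.batch, obs.tissue)
        mu = self.decode_np(post.mean, F).mu_prime
        return mu[0] if single else mu


def fit(dataset: CellDataset, config: ModelConfig) -> CrossSpeciesVAE:
    """Train a fresh model on `dataset` under `config`."""
    model = CrossSpeciesVAE(dataset.counts.shape[1], dataset.design, config)
    return model.fit(dataset)


def select_hyperparameters(dataset: CellDataset,
                           latent_dims=(25, 50, 100),
                           use_discriminator=(False, True),
                           base_config: ModelConfig | None = None,
                           perplexity: float = 30.0):
    """Grid search; keep the model whose validation embeddings best mix species.

    Trains one model per (use_discriminator, latent_dim) grid point and
    returns ``(best_model, records)`` where the winner maximizes mean LISI
    over species labels on validation-set posterior means. Ties keep the
    earlier grid point (discriminator=False first, ascending latent size).
    """
    base = base_config or ModelConfig()
    records, best, best_score = [], None, -np.inf
    for disc in use_discriminator:
        for ld in latent_dims:
            d = asdict(base)
            d.update(latent_dim=ld, use_discriminator=disc)
            cfg = ModelConfig(**d)
            model = fit(dataset, cfg)
            vi = model.validation_indices_
            post = model.encode_batch(dataset.counts[vi], dataset.species[vi],
                                      dataset.batch[vi], dataset.tissue[vi])
            perp = min(perplexity, (len(vi) - 1) / 3.0)
            score = float(np.mean(compute_lisi(post.mean, dataset.species[vi],
                                               perplexity=perp)))
            records.append({"latent_dim": ld, "use_discriminator": disc,
                            "lisi": score,
                            "val_cvae": model.best_validation_loss_})
            if score > best_score:
                best, best_score = model, score
    if best is None:
        raise RuntimeError("empty hyperparameter grid")
    return best, records
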
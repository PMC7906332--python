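"""Scikit-learn style estimator for the adversarially trained annotator.

``PFPWGANClassifier`` is a multi-label classifier: ``X`` is either an
integer matrix of trigram codes (``mode='sequence'``) or a float feature
matrix (``mode='feature'``); ``y`` is the binary proteins x terms
annotation matrix.  ``adversarial=False`` omits the critic and trains the
generator on plain binary cross-entropy — the PFP-S ablation.

Each outer step runs ``critic_ratio`` critic updates followed by one
generator update; after every epoch the protein-centric Fmax on the held
out validation split is computed and the parameters of the best epoch are
kept.  All randomness (split, initialization, dropout, batch order,
interpolation draws) derives from ``random_state`` through independent
streams, so a run is exactly reproducible and, given the same seed, the
generator-side batches of an adversarial run match those of a PFP-S run.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import autodiff as ad
from .metrics import fmax
from .model import (Discriminator, DiscriminatorConfig, Generator,
                    GeneratorConfig, discriminator_loss, generator_loss)
from .nn import Adam
from .training import TrainLog, TrainingError, split_train_validation

__all__ = ["PFPWGANClassifier"]


class _BatchStream:
    """Endless stream of shuffled mini-batch index arrays."""

    def __init__(self, indices: np.ndarray, batch_size: int, rng: np.random.Generator):
        self.indices = np.asarray(indices)
        self.batch_size = batch_size
        self.rng = rng
        self._queue: list = []

    def __next__(self) -> np.ndarray:
        if not self._queue:
            perm = self.rng.permutation(self.indices)
            self._queue = [perm[i:i + self.batch_size]
                           for i in range(0, len(perm), self.batch_size)]
        return self._queue.pop(0)


class PFPWGANClassifier(BaseEstimator, ClassifierMixin):
    """Conditional-WGAN multi-label protein function classifier.

    Parameters mirror the published setting; widths beyond those stated in
    the source architecture are configurable defaults.
    """

    def __init__(self, mode: str = "sequence", adversarial: bool = True,
                 lambda1: float = 0.03, lambda2: float = 10.0,
                 critic_ratio: int = 10, learning_rate: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999,
                 batch_size: int = 32, max_epochs: int = 10,
                 validation_fraction: float = 0.2,
                 embed_dim: int = 128, n_filters: int = 32, kernel_size: int = 8,
                 pool_size: int = 64, pool_stride: int = 32,
                 dense_sizes: tuple | None = None, dropout_rate: float = 0.2,
                 label_branch_size: int = 256,
                 trunk_sizes: tuple = (512, 256, 128, 64, 32),
                 random_state: int | None = None):
        self.mode = mode
        self.adversarial = adversarial
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.critic_ratio = critic_ratio
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.embed_dim = embed_dim
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.pool_stride = pool_stride
        self.dense_sizes = dense_sizes
        self.dropout_rate = dropout_rate
        self.label_branch_size = label_branch_size
        self.trunk_sizes = trunk_sizes
        self.random_state = random_state

    # -- configuration --------------------------------------------------------
    def _generator_config(self, X: np.ndarray, c: int) -> GeneratorConfig:
        dense = self.dense_sizes
        if dense is None:
            dense = (512, 256) if self.mode == "sequence" else (512, 256, 128)
        kw = dict(n_terms=c, mode=self.mode, embed_dim=self.embed_dim,
                  dropout_rate=self.dropout_rate, n_filters=self.n_filters,
                  kernel_size=self.kernel_size, pool_size=self.pool_size,
                  pool_stride=self.pool_stride, dense_sizes=tuple(dense))
        if self.mode == "sequence":
            kw.update(n_positions=X.shape[1], feature_dim=None)
        else:
            kw.update(n_positions=None, feature_dim=X.shape[1])
        return GeneratorConfig(**kw)

    def _validate(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 2 or y.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y must be 2-D with matching first dimension")
        if X.shape[0] < 5:
            raise ValueError("training needs at least 5 proteins")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must be a binary annotation matrix")
        if self.mode == "sequence":
            if not np.issubdtype(X.dtype, np.integer):
                raise ValueError("sequence mode expects integer trigram codes")
        else:
            X = X.astype(np.float64)
        return X, y.astype(np.float64)

    # -- fitting --------------------------------------------------------------
    def fit(self, X, y):
        X, y = self._validate(X, y)
        n, c = y.shape
        seed = 0 if self.random_state is None else int(self.random_state)
        streams = np.random.SeedSequence(seed).spawn(7)
        (ss_split, ss_init_g, ss_init_d, ss_drop_g, ss_drop_critic,
         ss_eps, ss_batches) = streams
        rng_drop_g = np.random.default_rng(ss_drop_g)
        rng_drop_critic = np.random.default_rng(ss_drop_critic)
        rng_eps = np.random.default_rng(ss_eps)
        ss_gen_batches, ss_critic_batches = ss_batches.spawn(2)

        split_seed = int(np.random.default_rng(ss_split).integers(2 ** 31))
        train_idx, val_idx = split_train_validation(n, self.validation_fraction, split_seed)

        gcfg = self._generator_config(X, c)
        gen = Generator(gcfg, np.random.default_rng(ss_init_g))
        opt_g = Adam(gen.params, self.learning_rate, self.beta1, self.beta2)
        disc = None
        opt_d = None
        if self.adversarial:
            dcfg = DiscriminatorConfig(condition=gcfg,
                                       label_branch_size=self.label_branch_size,
                                       trunk_sizes=tuple(self.trunk_sizes))
            disc = Discriminator(dcfg, np.random.default_rng(ss_init_d))
            opt_d = Adam(disc.params, self.learning_rate, self.beta1, self.beta2)

        gen_batches = _BatchStream(train_idx, self.batch_size,
                                   np.random.default_rng(ss_gen_batches))
        critic_batches = _BatchStream(train_idx, self.batch_size,
                                      np.random.default_rng(ss_critic_batches))
        steps_per_epoch = max(1, len(train_idx) // self.batch_size)
        log = TrainLog()
        best = (-1.0, -1, None)  # fmax, epoch, snapshot

        for epoch in range(self.max_epochs):
            for _ in range(steps_per_epoch):
                if self.adversarial:
                    for _ in range(self.critic_ratio):
                        bi = next(critic_batches)
                        eps = rng_eps.random(len(bi))
                        loss, aux = discriminator_loss(
                            disc, gen, X[bi], y[bi], self.lambda2, eps,
                            gen_rng=rng_drop_critic)
                        if not np.isfinite(loss.item()):
                            raise TrainingError(
                                f"critic loss diverged at update {log.n_critic_updates}")
                        grads = ad.grad(loss, disc.params)
                        opt_d.step(grads)
                        log.critic_loss.append(loss.item())
                        log.gradient_penalty.append(aux["gradient_penalty"])
                        log.grad_norm_mean.append(aux["grad_norm_mean"])
                bi = next(gen_batches)
                lam1 = self.lambda1 if self.adversarial else 0.0
                loss, aux = generator_loss(disc, gen, X[bi], y[bi], lam1, rng=rng_drop_g)
                if not np.isfinite(loss.item()):
                    raise TrainingError(
                        f"generator loss diverged at update {log.n_generator_updates}")
                grads = ad.grad(loss, gen.params)
                opt_g.step(grads)
                log.gen_loss.append(loss.item())
                log.gen_bce.append(aux["bce"])
            scores = self._forward_scores(gen, X[val_idx])
            vf, vt = fmax(y[val_idx].astype(np.int8), scores)
            log.val_fmax.append(vf)
            if vf > best[0]:
                best = (vf, epoch, ([p.data.copy() for p in gen.params], vt))

        if best[2] is not None:
            snapshot, vt = best[2]
            for p, d in zip(gen.params, snapshot):
                p.data = d
            self.threshold_ = float(vt)
        else:  # no epoch improved over -1 is impossible, but stay safe
            self.threshold_ = 0.5
        log.best_epoch = best[1]
        self.generator_ = gen
        self.discriminator_ = disc
        self.train_log_ = log
        self.best_epoch_ = best[1]
        self.validation_fmax_ = best[0]
        self.n_terms_ = c
        self.n_features_in_ = X.shape[1]
        self.train_indices_ = train_idx
        self.validation_indices_ = val_idx
        return self

    # -- inference ------------------------------------------------------------
    def _forward_scores(self, gen: Generator, X: np.ndarray,
                        chunk: int = 256) -> np.ndarray:
        outs = []
        with ad.no_grad():
            for i in range(0, len(X), chunk):
                outs.append(gen.forward(X[i:i + chunk], rng=None).data)
        return np.vstack(outs)

    def predict_proba(self, X) -> np.ndarray:
        """Deterministic assignment scores in [0, 1] (dropout off)."""
        self._check_fitted()
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"X must be (n, {self.n_features_in_})")
        return self._forward_scores(self.generator_, X)

    decision_function = predict_proba

    def predict(self, X) -> np.ndarray:
        """Binary annotations at the validation Fmax-maximizing threshold."""
        return (self.predict_proba(X) >= self.threshold_).astype(np.int8)

    def _check_fitted(self):
        if not hasattr(self, "generator_"):
            raise RuntimeError("estimator is not fitted")

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.multi_output = True
        return tags
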
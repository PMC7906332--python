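"""Conditional generator, Wasserstein critic, and their loss functions.

The generator maps a protein representation ``x`` (trigram codes or a
feature vector) to an assignment vector in ``[0,1]^c``; the critic scores
(protein, assignment) pairs with an unbounded scalar.  The generator
minimizes binary cross-entropy plus a weighted Wasserstein term
``-lambda1 * D(x, G(x))``; the critic minimizes
``D(x, G(x)) - D(x, y)`` plus the gradient penalty
``lambda2 * (||grad_y D(x, y~)||_2 - 1)^2`` evaluated at random
interpolates ``y~`` between real and generated assignment vectors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoding import VOCAB_SIZE
from .nn import Dense, TrigramConvEncoder

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "Generator",
    "Discriminator",
    "binary_cross_entropy",
    "generator_loss",
    "discriminator_loss",
    "gradient_penalty",
    "save_checkpoint",
    "load_checkpoint",
]

BCE_EPS = 1e-7


@dataclass
class GeneratorConfig:
    """Shape of the annotating generator.

    ``dense_sizes`` gives the two hidden layers after the pooled activation
    maps in sequence mode, or the three hidden layers in feature mode.
    """

    n_terms: int
    mode: str = "sequence"
    vocab: int = VOCAB_SIZE
    embed_dim: int = 128
    dropout_rate: float = 0.2
    n_filters: int = 32
    kernel_size: int = 8
    pool_size: int = 64
    pool_stride: int = 32
    dense_sizes: tuple = (512, 256)
    n_positions: int | None = 1000
    feature_dim: int | None = None

    def __post_init__(self):
        if self.mode not in ("sequence", "feature"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_terms < 1:
            raise ValueError("n_terms must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        need = 2 if self.mode == "sequence" else 3
        if len(self.dense_sizes) != need:
            raise ValueError(f"{self.mode} mode needs {need} dense sizes")
        if self.mode == "sequence" and self.n_positions is None:
            raise ValueError("sequence mode needs n_positions")
        if self.mode == "feature" and self.feature_dim is None:
            raise ValueError("feature mode needs feature_dim")


@dataclass
class DiscriminatorConfig:
    """Shape of the conditional Wasserstein critic.

    The condition branch repeats the generator front end (embedding,
    dropout-slot, convolution, average pooling, first dense layer) with its
    own parameters; the assignment vector passes through one dense layer
    (``label_branch_size``); the concatenation feeds five dense layers and a
    single linear output neuron.
    """

    condition: GeneratorConfig
    label_branch_size: int = 256
    trunk_sizes: tuple = (512, 256, 128, 64, 32)

    def __post_init__(self):
        if len(self.trunk_sizes) != 5:
            raise ValueError("critic trunk must have exactly 5 dense layers")
        if self.label_branch_size < 1:
            raise ValueError("label_branch_size must be positive")


def _check_x(config: GeneratorConfig, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if config.mode == "sequence":
        if x.ndim != 2 or x.shape[1] != config.n_positions or not np.issubdtype(x.dtype, np.integer):
            raise ValueError(
                f"sequence-mode input must be integer (batch, {config.n_positions})")
    else:
        if x.ndim != 2 or x.shape[1] != config.feature_dim:
            raise ValueError(f"feature-mode input must be (batch, {config.feature_dim})")
    return x


class _FrontEnd:
    """Condition feature extractor shared by generator and critic."""

    def __init__(self, config: GeneratorConfig, rng, dropout: bool):
        self.config = config
        if config.mode == "sequence":
            self.encoder = TrigramConvEncoder(
                rng, config.vocab, config.embed_dim, config.n_filters,
                config.kernel_size, config.pool_size, config.pool_stride,
                dropout_rate=config.dropout_rate if dropout else 0.0)
            in_dim = self.encoder.out_dim(config.n_positions)
        else:
            self.encoder = None
            in_dim = config.feature_dim
        self.dense = Dense(rng, in_dim, config.dense_sizes[0])
        self.out_dim = config.dense_sizes[0]

    def __call__(self, x: np.ndarray, rng=None) -> Tensor:
        x = _check_x(self.config, x)
        h = self.encoder(x, rng) if self.encoder is not None else Tensor(x)
        return self.dense(h)

    @property
    def params(self):
        enc = self.encoder.params if self.encoder is not None else []
        return enc + self.dense.params


class Generator:
    """Conditional annotating network; output in ``[0,1]^c`` via (tanh+1)/2."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        self.config = config
        self.front = _FrontEnd(config, rng, dropout=True)
        sizes = (self.front.out_dim,) + tuple(config.dense_sizes[1:])
        self.hidden = [Dense(rng, a, b) for a, b in zip(sizes, sizes[1:])]
        last = config.dense_sizes[-1]
        self.out = Dense(rng, last, config.n_terms, activation="tanh")

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None) -> Tensor:
        """Assignment scores for a batch; stochastic iff ``rng`` is given."""
        h = self.front(x, rng)
        for layer in self.hidden:
            h = layer(h)
        t = self.out(h)
        return ad.mul(ad.add(t, 1.0), 0.5)

    @property
    def params(self):
        ps = self.front.params
        for layer in self.hidden:
            ps += layer.params
        return ps + self.out.params


class Discriminator:
    """Conditional Wasserstein critic ``D(x, y) -> R``."""

    def __init__(self, config: DiscriminatorConfig, rng: np.random.Generator):
        self.config = config
        self.front = _FrontEnd(config.condition, rng, dropout=False)
        c = config.condition.n_terms
        self.label_branch = Dense(rng, c, config.label_branch_size)
        sizes = (self.front.out_dim + config.label_branch_size,) + tuple(config.trunk_sizes)
        self.trunk = [Dense(rng, a, b) for a, b in zip(sizes, sizes[1:])]
        self.out = Dense(rng, sizes[-1], 1, activation=None)

    def condition(self, x: np.ndarray) -> Tensor:
        """Condition features of a batch; reusable across several scores."""
        return self.front(x)

    def score(self, cond: Tensor, y) -> Tensor:
        h = ad.concat([self.label_branch(ad.as_tensor(y)), cond], axis=1)
        for layer in self.trunk:
            h = layer(h)
        return self.out(h)

    def forward(self, x: np.ndarray, y) -> Tensor:
        return self.score(self.condition(x), y)

    @property
    def params(self):
        ps = self.front.params + self.label_branch.params
        for layer in self.trunk:
            ps += layer.params
        return ps + self.out.params


# -- losses -------------------------------------------------------------------

def binary_cross_entropy(y_true: np.ndarray, y_pred: Tensor, eps: float = BCE_EPS) -> Tensor:
    """Element-mean BCE with predictions clipped to ``[eps, 1-eps]``."""
    y = np.asarray(y_true, dtype=np.float64)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("ground-truth assignment vectors must be binary")
    p = ad.clip(y_pred, eps, 1.0 - eps)
    pos = ad.mul(Tensor(y), ad.log(p))
    neg = ad.mul(Tensor(1.0 - y), ad.log(ad.add(1.0, ad.mul(p, -1.0))))
    return ad.mul(ad.tmean(ad.add(pos, neg)), -1.0)


def generator_loss(discriminator, generator, x: np.ndarray, y_true: np.ndarray,
                   lambda1: float, rng: np.random.Generator | None = None):
    """Mean BCE minus ``lambda1`` times the critic score of generated pairs.

    Returns ``(loss, aux)`` where ``aux`` maps part names to floats.
    ``discriminator`` may be None when ``lambda1`` is 0 (the PFP-S case).
    """
    if lambda1 < 0:
        raise ValueError("lambda1 must be >= 0")
    y_fake = generator.forward(x, rng)
    bce = binary_cross_entropy(y_true, y_fake)
    if lambda1 == 0.0 or discriminator is None:
        return bce, {"bce": bce.item(), "wasserstein": 0.0}
    critic = ad.tmean(discriminator.score(discriminator.condition(x), y_fake))
    loss = ad.add(bce, ad.mul(critic, -lambda1))
    return loss, {"bce": bce.item(), "wasserstein": critic.item()}


def gradient_penalty(score_fn, y_tilde: Tensor, norm_eps: float = 1e-12):
    """``mean((||grad_y score||_2 - 1)^2)`` with a differentiable graph.

    ``score_fn`` maps the interpolated assignment tensor to per-sample
    scores; the gradient is taken with respect to ``y_tilde`` only.
    Returns ``(penalty, mean_gradient_norm)``.
    """
    s = score_fn(y_tilde)
    (g,) = ad.grad(ad.tsum(s), [y_tilde], create_graph=True)
    norm = ad.sqrt(ad.add(ad.tsum(ad.mul(g, g), axis=1), norm_eps))
    penalty = ad.tmean(ad.power(ad.add(norm, -1.0), 2.0))
    return penalty, norm


def discriminator_loss(discriminator, generator, x: np.ndarray, y_true: np.ndarray,
                       lambda2: float, eps_draws: np.ndarray,
                       gen_rng: np.random.Generator | None = None):
    """Wasserstein critic loss with gradient penalty.

    ``eps_draws`` are per-sample uniform(0,1) interpolation weights.
    Generated assignments are treated as constants (the generator is not
    updated by this loss).  Returns ``(loss, aux)``.
    """
    if lambda2 < 0:
        raise ValueError("lambda2 must be >= 0")
    y = np.asarray(y_true, dtype=np.float64)
    with ad.no_grad():
        y_fake = generator.forward(x, gen_rng).data
    cond = discriminator.condition(x)
    d_fake = ad.tmean(discriminator.score(cond, y_fake))
    d_real = ad.tmean(discriminator.score(cond, y))
    eps = np.asarray(eps_draws, dtype=np.float64).reshape(-1, 1)
    if eps.shape[0] != y.shape[0]:
        raise ValueError("one interpolation draw per sample is required")
    y_tilde = Tensor(eps * y + (1.0 - eps) * y_fake, requires_grad=True)
    penalty, norms = gradient_penalty(lambda yt: discriminator.score(cond, yt), y_tilde)
    loss = ad.add(ad.add(d_fake, ad.mul(d_real, -1.0)), ad.mul(penalty, lambda2))
    aux = {
        "wasserstein": d_fake.item() - d_real.item(),
        "gradient_penalty": penalty.item(),
        "grad_norm_mean": float(norms.data.mean()),
    }
    return loss, aux


# -- checkpoints --------------------------------------------------------------

def save_checkpoint(path, generator: Generator, discriminator: Discriminator | None = None,
                    extra: dict | None = None) -> None:
    """Persist parameters plus embedded configs as an ``.npz`` archive."""
    arrays = {f"gen_{i}": p.data for i, p in enumerate(generator.params)}
    meta = {"generator": asdict(generator.config), "extra": extra or {}}
    if discriminator is not None:
        arrays.update({f"disc_{i}": p.data for i, p in enumerate(discriminator.params)})
        dc = asdict(discriminator.config)
        meta["discriminator"] = dc
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Load a checkpoint; returns ``(generator, discriminator_or_None, extra)``."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        gcfg = GeneratorConfig(**{**meta["generator"],
                                  "dense_sizes": tuple(meta["generator"]["dense_sizes"])})
        gen = Generator(gcfg, np.random.default_rng(0))
        for i, p in enumerate(gen.params):
            p.data = z[f"gen_{i}"]
        disc = None
        if "discriminator" in meta:
            dmeta = meta["discriminator"]
            ccfg = GeneratorConfig(**{**dmeta["condition"],
                                      "dense_sizes": tuple(dmeta["condition"]["dense_sizes"])})
            dcfg = DiscriminatorConfig(
                condition=ccfg,
                label_branch_size=dmeta["label_branch_size"],
                trunk_sizes=tuple(dmeta["trunk_sizes"]))
            disc = Discriminator(dcfg, np.random.default_rng(0))
            for i, p in enumerate(disc.params):
                p.data = z[f"disc_{i}"]
        return gen, disc, meta.get("extra", {})
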
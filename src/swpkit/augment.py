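"""Generative data augmentation for normalized SWP traces.

One generative model is trained per (leaf, condition) group of preprocessed
traces, then sampled to produce virtual traces that extend small training
sets. Three methods share one estimator interface (``fit`` / ``sample``, in
the spirit of :class:`sklearn.mixture.GaussianMixture`):

* :class:`AAEAugmenter` — adversarial autoencoder, the primary method. An
  encoder (411 -> 200 -> 100 -> 100 -> 50) and decoder (mirror image) are
  trained to reconstruct traces under a sum-over-dimensions L1 loss, while a
  discriminator (50 -> 100 -> 100 -> 50 -> 25 -> 1, terminal sigmoid)
  adversarially pushes the aggregated posterior over latent codes toward a
  standard Gaussian prior. Sampling decodes prior draws.
* :class:`VAEAugmenter` — same encoder/decoder widths with a diagonal
  Gaussian latent and a reconstruction + KL objective.
* :class:`GANAugmenter` — fully connected generator (50 -> 411) and
  discriminator (411 -> 1) trained with the standard minimax objective.

All training uses plain stochastic gradient descent with per-sample updates
(a full pass over the group per epoch), dropout 0.2 on hidden layers during
training only, and a single seeded ``numpy`` generator, so runs are
bit-reproducible. Adversarial generator updates use the non-saturating form
(maximize ``log D`` on generated material), which has the same optimum as the
minimax form but does not stall early in training. Generated traces are
clipped to [-1, 1]; the padded-tail zeros are learned, not re-imposed, unless
``rezero_tail`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from swpkit.errors import ConfigError, DataError
from swpkit.nn import MLPNet, bce_fake_grad, bce_real_grad, l1_loss_grad, sigmoid
from swpkit.preprocess import NormalizedTrace

AUGMENT_METHODS: tuple[str, ...] = ("aae", "vae", "gan")


@dataclass(frozen=True)
class AAEConfig:
    """Hyperparameters of the adversarial autoencoder (defaults as published).

    ``*_widths`` list layer sizes including input and output, so
    ``len(widths) - 1`` weight maps. The discriminator's interior widths are a
    documented assumption: only its 50-in / 1-out shape and five-layer depth
    are fixed by the architecture description.
    """

    encoder_widths: tuple[int, ...] = (411, 200, 100, 100, 50)
    decoder_widths: tuple[int, ...] = (50, 100, 100, 200, 411)
    discriminator_widths: tuple[int, ...] = (50, 100, 100, 50, 25, 1)
    dropout: float = 0.2
    recon_lr: float = 1e-4
    gen_lr: float = 5e-4
    epochs: int = 200
    seed: int = 10
    batch_size: int = 1
    decoder_init_scale: float = 0.3
    standardize_codes: bool = True

    def __post_init__(self) -> None:
        if self.encoder_widths[-1] != self.decoder_widths[0]:
            raise ConfigError("encoder output width must equal decoder input width")
        if self.discriminator_widths[0] != self.encoder_widths[-1]:
            raise ConfigError("discriminator input width must equal the latent dim")
        if self.encoder_widths[0] != self.decoder_widths[-1]:
            raise ConfigError("encoder input width must equal decoder output width")
        if self.discriminator_widths[-1] != 1:
            raise ConfigError("discriminator must end in a single output neuron")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")

    @property
    def latent_dim(self) -> int:
        return self.encoder_widths[-1]

    @property
    def trace_length(self) -> int:
        return self.encoder_widths[0]


def _as_matrix(traces, expected_length: int) -> np.ndarray:
    if hasattr(traces, "ndim"):
        X = np.asarray(traces, dtype=float)
        X = np.atleast_2d(X)
    else:
        traces = list(traces)
        if not traces:
            raise DataError("empty trace group")
        X = np.vstack([np.asarray(t.values if hasattr(t, "values") else t, dtype=float)
                       for t in traces])
    if X.shape[0] < 1:
        raise DataError("empty trace group")
    if X.shape[1] != expected_length:
        raise DataError(
            f"trace length {X.shape[1]} does not match the architecture's "
            f"input width {expected_length}"
        )
    return X


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i: i + batch_size]


class _BaseAugmenter:
    """Shared fit/sample surface of the three generative augmenters."""

    method: str = ""

    def get_params(self, deep: bool = True) -> dict:
        return {"cfg": self.cfg}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "history_"):
            raise RuntimeError(f"{type(self).__name__} is not fitted")

    def _decode(self, z: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def sample(self, n: int, seed: int | None = None) -> np.ndarray:
        """Decode ``n`` prior draws into traces, clipped to [-1, 1]."""
        self._check_fitted()
        if n < 1:
            raise ConfigError("n must be >= 1")
        rng = np.random.default_rng(self.cfg.seed if seed is None else seed)
        z = rng.standard_normal((n, self.cfg.latent_dim))
        x = np.clip(self._decode(z), -1.0, 1.0)
        if getattr(self, "rezero_tail", False) and hasattr(self, "max_real_length_"):
            x[:, self.max_real_length_:] = 0.0
        return x


class AAEAugmenter(_BaseAugmenter):
    """Adversarial autoencoder trained on one (leaf, condition) group.

    Each epoch makes a full pass over the group in a seeded random order.
    For every mini-batch three updates run in sequence:

    1. *reconstruction* — encoder and decoder descend the mean-over-batch,
       sum-over-dimensions L1 reconstruction loss at ``recon_lr``;
    2. *regularization* — the discriminator learns to score prior draws
       ``z ~ N(0, I)`` as real and encoder codes as fake, at ``gen_lr``;
    3. *adversarial generator* — the encoder is updated to make its codes
       score real (non-saturating objective), at ``gen_lr``.

    Attributes (after fit)
    ----------------------
    history_ : dict of lists
        Per-epoch mean L1 reconstruction loss, discriminator loss and
        generator loss (``l1_recon``, ``d_loss``, ``g_loss``).
    group_key_ : tuple or None
        (leaf, condition) of the training traces when known.
    """

    method = "aae"

    def __init__(self, cfg: AAEConfig = AAEConfig(), rezero_tail: bool = False):
        self.cfg = cfg
        self.rezero_tail = rezero_tail

    def fit(self, traces, group_key=None):
        cfg = self.cfg
        X = _as_matrix(traces, cfg.trace_length)
        if X.shape[0] < 2:
            raise DataError("need at least 2 traces to train an augmenter")
        rng = np.random.default_rng(cfg.seed)
        enc = MLPNet(cfg.encoder_widths, rng, dropout=cfg.dropout)
        if cfg.standardize_codes:
            # calibrate the code layer so initial codes sit at prior scale
            # (data-dependent init in the LSUV spirit); without it the
            # fixed-rate adversarial updates cannot close the scale gap and
            # prior draws decode far outside the trained region
            z0 = enc.forward(X, train=False)
            scale = max(float(z0.std()), 1e-6)
            enc.W[-1] /= scale
            enc.b[-1] = (enc.b[-1] - z0.mean(axis=0)) / scale
        dec = MLPNet(cfg.decoder_widths, rng, dropout=cfg.dropout)
        for W in dec.W:
            # small-gain start: the decoder grows its response to the latent
            # during training instead of amplifying out-of-cloud prior draws
            W *= cfg.decoder_init_scale
        disc = MLPNet(cfg.discriminator_widths, rng, dropout=cfg.dropout)
        history = {"l1_recon": [], "d_loss": [], "g_loss": []}
        n = X.shape[0]
        for _ in range(cfg.epochs):
            l1s, dls, gls = [], [], []
            for idx in _batches(n, cfg.batch_size, rng):
                x = X[idx]
                # (1) reconstruction
                z = enc.forward(x, train=True, rng=rng)
                xhat = dec.forward(z, train=True, rng=rng)
                l1, g_out = l1_loss_grad(xhat, x)
                g_z = dec.backward(g_out)
                enc.backward(g_z)
                dec.step(cfg.recon_lr)
                enc.step(cfg.recon_lr)
                l1s.append(l1)
                # (2) discriminator: prior draws real, encoder codes fake
                z_fake = enc.forward(x, train=True, rng=rng)
                z_real = rng.standard_normal(z_fake.shape)
                logits = disc.forward(np.vstack([z_real, z_fake]), train=True, rng=rng)
                m = z_real.shape[0]
                loss_r, grad_r = bce_real_grad(logits[:m])
                loss_f, grad_f = bce_fake_grad(logits[m:])
                disc.backward(np.vstack([grad_r, grad_f]) / 2.0)
                disc.step(cfg.gen_lr)
                dls.append((loss_r + loss_f) / 2.0)
                # (3) encoder fools the discriminator (non-saturating)
                z = enc.forward(x, train=True, rng=rng)
                logits = disc.forward(z, train=True, rng=rng)
                g_loss, grad_l = bce_real_grad(logits)
                g_z = disc.backward(grad_l)  # discriminator frozen: no step
                enc.backward(g_z)
                enc.step(cfg.gen_lr)
                gls.append(g_loss)
            history["l1_recon"].append(float(np.mean(l1s)))
            history["d_loss"].append(float(np.mean(dls)))
            history["g_loss"].append(float(np.mean(gls)))
        self.encoder_, self.decoder_, self.discriminator_ = enc, dec, disc
        self.history_ = history
        self.group_key_ = group_key
        return self

    def _decode(self, z: np.ndarray) -> np.ndarray:
        return self.decoder_.forward(z, train=False)

    def encode(self, traces) -> np.ndarray:
        self._check_fitted()
        X = _as_matrix(traces, self.cfg.trace_length)
        return self.encoder_.forward(X, train=False)

    def discriminate(self, z: np.ndarray) -> np.ndarray:
        """Discriminator probability that codes come from the prior; in (0, 1)."""
        self._check_fitted()
        return sigmoid(self.discriminator_.forward(np.atleast_2d(z), train=False))[:, 0]


class VAEAugmenter(_BaseAugmenter):
    """Variational autoencoder baseline with the same encoder/decoder widths.

    The encoder trunk ends one layer short of the latent; two linear heads map
    the last hidden layer to the posterior mean and log-variance. Training
    descends L1 reconstruction plus the analytic diagonal-Gaussian KL term.
    """

    method = "vae"

    def __init__(self, cfg: AAEConfig = AAEConfig(), rezero_tail: bool = False):
        self.cfg = cfg
        self.rezero_tail = rezero_tail

    def fit(self, traces, group_key=None):
        cfg = self.cfg
        X = _as_matrix(traces, cfg.trace_length)
        if X.shape[0] < 2:
            raise DataError("need at least 2 traces to train an augmenter")
        rng = np.random.default_rng(cfg.seed)
        trunk = MLPNet(cfg.encoder_widths[:-1], rng, dropout=cfg.dropout)
        hidden = cfg.encoder_widths[-2]
        latent = cfg.latent_dim
        mu_head = MLPNet((hidden, latent), rng, dropout=0.0)
        lv_head = MLPNet((hidden, latent), rng, dropout=0.0)
        dec = MLPNet(cfg.decoder_widths, rng, dropout=cfg.dropout)
        for W in dec.W:
            W *= cfg.decoder_init_scale
        history = {"l1_recon": [], "kl": []}
        n = X.shape[0]
        for _ in range(cfg.epochs):
            l1s, kls = [], []
            for idx in _batches(n, cfg.batch_size, rng):
                x = X[idx]
                b = x.shape[0]
                h = trunk.forward(x, train=True, rng=rng)
                mu = mu_head.forward(h, train=True, rng=rng)
                lv = np.clip(lv_head.forward(h, train=True, rng=rng), -10.0, 10.0)
                eps = rng.standard_normal(mu.shape)
                std = np.exp(0.5 * lv)
                z = mu + std * eps
                xhat = dec.forward(z, train=True, rng=rng)
                l1, g_out = l1_loss_grad(xhat, x)
                kl = float(-0.5 * np.sum(1.0 + lv - mu**2 - np.exp(lv)) / b)
                g_z = dec.backward(g_out)
                g_mu = g_z + mu / b
                g_lv = g_z * (0.5 * std * eps) + 0.5 * (np.exp(lv) - 1.0) / b
                g_h = mu_head.backward(g_mu) + lv_head.backward(g_lv)
                trunk.backward(g_h)
                for net in (dec, mu_head, lv_head, trunk):
                    net.step(cfg.recon_lr)
                l1s.append(l1)
                kls.append(kl)
            history["l1_recon"].append(float(np.mean(l1s)))
            history["kl"].append(float(np.mean(kls)))
        self.trunk_, self.mu_head_, self.lv_head_, self.decoder_ = trunk, mu_head, lv_head, dec
        self.history_ = history
        self.group_key_ = group_key
        return self

    def _decode(self, z: np.ndarray) -> np.ndarray:
        return self.decoder_.forward(z, train=False)


class GANAugmenter(_BaseAugmenter):
    """GAN baseline: fully connected generator (latent 50 -> 411 outputs) and
    discriminator (411 inputs -> 1), per the published 411-neuron input/output
    setting; interior widths are this package's choice."""

    method = "gan"

    def __init__(
        self,
        cfg: AAEConfig = AAEConfig(),
        generator_widths: tuple[int, ...] = (50, 100, 200, 411),
        discriminator_widths: tuple[int, ...] = (411, 200, 100, 50, 1),
        rezero_tail: bool = False,
    ):
        self.cfg = cfg
        self.generator_widths = generator_widths
        self.discriminator_widths = discriminator_widths
        self.rezero_tail = rezero_tail

    def fit(self, traces, group_key=None):
        cfg = self.cfg
        if self.generator_widths[-1] != self.discriminator_widths[0]:
            raise ConfigError("generator output must match discriminator input")
        X = _as_matrix(traces, self.generator_widths[-1])
        if X.shape[0] < 2:
            raise DataError("need at least 2 traces to train an augmenter")
        rng = np.random.default_rng(cfg.seed)
        gen = MLPNet(self.generator_widths, rng, dropout=cfg.dropout)
        disc = MLPNet(self.discriminator_widths, rng, dropout=cfg.dropout)
        latent = self.generator_widths[0]
        history = {"d_loss": [], "g_loss": []}
        n = X.shape[0]
        for _ in range(cfg.epochs):
            dls, gls = [], []
            for idx in _batches(n, cfg.batch_size, rng):
                x = X[idx]
                b = x.shape[0]
                # discriminator: real traces vs generated
                z = rng.standard_normal((b, latent))
                fake = gen.forward(z, train=True, rng=rng)
                logits = disc.forward(np.vstack([x, fake]), train=True, rng=rng)
                loss_r, grad_r = bce_real_grad(logits[:b])
                loss_f, grad_f = bce_fake_grad(logits[b:])
                disc.backward(np.vstack([grad_r, grad_f]) / 2.0)
                disc.step(cfg.gen_lr)
                dls.append((loss_r + loss_f) / 2.0)
                # generator: non-saturating update
                z = rng.standard_normal((b, latent))
                fake = gen.forward(z, train=True, rng=rng)
                logits = disc.forward(fake, train=True, rng=rng)
                g_loss, grad_l = bce_real_grad(logits)
                g_x = disc.backward(grad_l)
                gen.backward(g_x)
                gen.step(cfg.gen_lr)
                gls.append(g_loss)
            history["d_loss"].append(float(np.mean(dls)))
            history["g_loss"].append(float(np.mean(gls)))
        self.generator_, self.discriminator_ = gen, disc
        self.history_ = history
        self.group_key_ = group_key
        return self

    def _decode(self, z: np.ndarray) -> np.ndarray:
        if z.shape[1] != self.generator_widths[0]:
            z = z[:, : self.generator_widths[0]]
        return self.generator_.forward(z, train=False)

    def sample(self, n: int, seed: int | None = None) -> np.ndarray:
        self._check_fitted()
        if n < 1:
            raise ConfigError("n must be >= 1")
        rng = np.random.default_rng(self.cfg.seed if seed is None else seed)
        z = rng.standard_normal((n, self.generator_widths[0]))
        return np.clip(self._decode(z), -1.0, 1.0)


_AUGMENTERS = {"aae": AAEAugmenter, "vae": VAEAugmenter, "gan": GANAugmenter}


def train_aae(traces, cfg: AAEConfig = AAEConfig(), group_key=None) -> AAEAugmenter:
    """Train an adversarial autoencoder on one (leaf, condition) group."""
    return AAEAugmenter(cfg).fit(traces, group_key=group_key)


def train_vae(traces, cfg: AAEConfig = AAEConfig(), group_key=None) -> VAEAugmenter:
    return VAEAugmenter(cfg).fit(traces, group_key=group_key)


def train_gan(traces, cfg: AAEConfig = AAEConfig(), group_key=None) -> GANAugmenter:
    return GANAugmenter(cfg).fit(traces, group_key=group_key)


def generate_augmented(model: _BaseAugmenter, n: int, seed: int | None = None) -> list[NormalizedTrace]:
    """Sample ``n`` virtual traces from a fitted augmenter as labeled traces.

    Outputs carry ``provenance='augmented'`` and ``aug_``-prefixed sample ids
    so downstream splitting can keep them out of test sets.
    """
    X = model.sample(n, seed=seed)
    leaf, condition = model.group_key_ if model.group_key_ else (8, "Normal")
    return [
        NormalizedTrace(
            values=X[i],
            real_length=X.shape[1],
            sample_id=f"aug_{model.method}_leaf{leaf}_{condition}_{i:03d}",
            leaf=leaf,
            condition=condition,
            provenance="augmented",
        )
        for i in range(X.shape[0])
    ]


def augment_dataset(
    traces,
    method: str = "aae",
    n_per_group: int = 50,
    cfg: AAEConfig = AAEConfig(),
) -> tuple[list[NormalizedTrace], dict]:
    """Train one augmenter per (leaf, condition) group and sample from each.

    Parameters
    ----------
    traces : sequence of NormalizedTrace
        Original (never modified) preprocessed traces, any mix of groups.
    method : {"aae", "vae", "gan"}
    n_per_group : int
        Virtual traces to generate per group (50 at the published scale).

    Returns
    -------
    augmented : list of NormalizedTrace
    models : dict mapping (leaf, condition) to the fitted augmenter
    """
    if method not in _AUGMENTERS:
        raise ConfigError(f"unknown augmentation method {method!r}; choose from {AUGMENT_METHODS}")
    if n_per_group < 1:
        raise ConfigError("n_per_group must be >= 1")
    traces = list(traces)
    groups: dict[tuple[int, str], list[NormalizedTrace]] = {}
    for t in traces:
        groups.setdefault((t.leaf, t.condition), []).append(t)
    if not groups:
        raise DataError("no traces to augment")
    augmented: list[NormalizedTrace] = []
    models: dict[tuple[int, str], _BaseAugmenter] = {}
    for i, (key, members) in enumerate(sorted(groups.items(), key=lambda kv: str(kv[0]))):
        # distinct per-group seeds derived from the configured seed
        group_cfg = replace(cfg, seed=int(np.random.SeedSequence(
            entropy=cfg.seed, spawn_key=(i,)).generate_state(1)[0]))
        model = _AUGMENTERS[method](group_cfg).fit(members, group_key=key)
        model.max_real_length_ = max(t.real_length for t in members)
        models[key] = model
        augmented.extend(generate_augmented(model, n_per_group, seed=group_cfg.seed + 1))
    return augmented, models
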
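"""Privacy-preserving tabular GAN generators and the deep generative ensemble.

Three mechanisms share one adversarial core (MLP generator and discriminator,
non-saturating loss, sigmoid/per-block-softmax output head):

* ``dpgan``   — the discriminator is trained with DP-SGD: per-example gradient
  clipping at C plus Gaussian noise σ·C, with a Rényi-DP accountant advanced
  every step; training halts before the ε budget is exceeded.
* ``pategan`` — training rows are partitioned across teacher discriminators;
  a student discriminator learns from teacher majority votes perturbed with
  Laplace(1/λ) noise on the vote counts, and the generator trains against the
  student.  Each released label is a 2λ-DP query under basic composition.
* ``adsgan``  — a conditional generator (latent noise + a source record) with
  an identifiability penalty λ·mean(max(0, d_within − d(x_syn, x_source)))
  discouraging synthetic points from sitting closer to their source than the
  source's nearest neighbour in the training data.  Not differentially
  private; the ledger says so.

The deep generative ensemble trains several members on different seeds and
pools their samples into one synthetic dataset.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .accounting import PrivacyLedger, calibrate_sigma, compose_pate, epsilon_dpsgd
from .nn import MLP, Adam, TabularHead, sigmoid
from .preprocess import EncodedMatrix, Encoder
from .schema import Cohort

Method = Literal["dpgan", "pategan", "adsgan"]


@dataclass
class GanConfig:
    method: Method = "adsgan"
    latent_dim: int = 32
    hidden_dims: tuple[int, ...] = (64, 64)
    batch_size: int = 128
    epochs: int = 30
    learning_rate: float = 2e-4
    seed: int = 0
    epsilon_budget: float = 1.0      # math.inf disables privacy (sanity runs)
    delta: float | None = None       # default 1/n_train at fit time
    clip_norm: float = 1.0           # dpgan
    noise_multiplier: float | None = None  # dpgan; calibrated from budget if None
    n_teachers: int = 5              # pategan
    laplace_lambda: float = 1e-4     # pategan
    vote_batch: int = 100            # pategan: generated samples labeled per round
    lambda_identifiability: float = 1.0  # adsgan
    recon_weight: float = 2.0        # adsgan: source-reconstruction anchor
    patience: int = 5                # adsgan early stopping (epochs)
    pack: int = 4                    # discriminator packing (mode-collapse guard)

    def validate(self) -> None:
        if self.method not in ("dpgan", "pategan", "adsgan"):
            raise ValueError(f"unknown method {self.method!r}")
        if not self.epsilon_budget > 0:
            raise ValueError("epsilon_budget must be > 0")
        if self.delta is not None and not 0 < self.delta < 1:
            raise ValueError("delta must be in (0, 1)")
        if self.n_teachers < 2:
            raise ValueError("n_teachers must be >= 2")
        if self.lambda_identifiability < 0:
            raise ValueError("lambda_identifiability must be >= 0")
        if self.pack < 1:
            raise ValueError("pack must be >= 1")


@dataclass
class GeneratorModel:
    config: GanConfig
    gen: MLP
    head: TabularHead
    columns: list[str]
    layout: list
    conditional: bool = False
    source_data: np.ndarray | None = None  # adsgan conditioning pool
    ledger: PrivacyLedger | None = None


@dataclass
class SyntheticDataset:
    values: np.ndarray
    columns: list[str]
    cohort: Cohort | None
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.values.shape[0]


# --------------------------------------------------------------------------
def _bce_grads_logit(logit: np.ndarray, label: float | np.ndarray) -> np.ndarray:
    """d BCE / d logit = sigmoid(logit) − label."""
    return sigmoid(logit) - label


def _check_matrix(matrix: EncodedMatrix) -> None:
    if matrix.values.min() < -1e-9 or matrix.values.max() > 1 + 1e-9:
        raise ValueError("encoded matrix entries must lie in [0, 1]")


def train_gan(encoded_train: EncodedMatrix, config: GanConfig
              ) -> tuple[GeneratorModel, PrivacyLedger]:
    """Train one generator; returns the model and its privacy ledger."""
    config.validate()
    _check_matrix(encoded_train)
    X = np.asarray(encoded_train.values, float)
    n, d = X.shape
    delta = config.delta if config.delta is not None else 1.0 / n
    blocks = _blocks_from_layout(encoded_train.layout)
    head = TabularHead(d, blocks)
    rng = np.random.default_rng(config.seed)
    gen = MLP.create([config.latent_dim + (d if config.method == "adsgan" else 0),
                      *config.hidden_dims, d], rng, out_scale=0.05)
    if config.method == "dpgan":
        ledger = _train_dpgan(X, gen, head, config, delta, rng)
        model = GeneratorModel(config, gen, head, encoded_train.columns,
                               encoded_train.layout, ledger=ledger)
    elif config.method == "pategan":
        ledger = _train_pategan(X, gen, head, config, delta, rng)
        model = GeneratorModel(config, gen, head, encoded_train.columns,
                               encoded_train.layout, ledger=ledger)
    else:
        ledger = _train_adsgan(X, gen, head, config, rng)
        model = GeneratorModel(config, gen, head, encoded_train.columns,
                               encoded_train.layout, conditional=True,
                               source_data=X, ledger=ledger)
    return model, ledger


def _blocks_from_layout(layout) -> list[slice]:
    blocks, start, src = [], None, None
    sentinel = type(layout[0])("_end", "_end", "continuous")
    for j, info in enumerate(list(layout) + [sentinel]):
        if info.role == "onehot" and src == info.source:
            continue
        if start is not None:
            blocks.append(slice(start, j))
            start, src = None, None
        if info.role == "onehot":
            start, src = j, info.source
    return blocks


def _gen_forward(gen: MLP, head: TabularHead, z: np.ndarray,
                 rng: np.random.Generator | None = None):
    raw, cache = gen.forward(z)
    out, hcache = head.forward(raw, rng)
    return out, hcache, cache


def _pack_rows(x: np.ndarray, pack: int) -> np.ndarray:
    return x.reshape(x.shape[0] // pack, pack * x.shape[1])


def _gen_step(gen: MLP, head: TabularHead, opt: Adam, z: np.ndarray,
              disc: MLP, rng: np.random.Generator, pack: int = 1,
              extra_grad=None) -> float:
    """Non-saturating generator update against ``disc``; optional additive
    gradient on the generated output (identifiability penalty)."""
    out, hcache, gcache = _gen_forward(gen, head, z, rng)
    logit, dcache = disc.forward(_pack_rows(out, pack))
    # non-saturating: minimize -log D(G(z)) => dL/dlogit = sigmoid(logit) - 1
    dlogit = _bce_grads_logit(logit, 1.0)
    _, _, dpack = disc.backward(dcache, dlogit)
    dout = dpack.reshape(out.shape)
    if extra_grad is not None:
        dout = dout + extra_grad(out)
    draw = head.backward(hcache, out, dout)
    gW, gb, _ = gen.backward(gcache, draw)
    opt.step(gen.params, gW + gb)
    return float(-np.log(sigmoid(logit) + 1e-12).mean())


def _train_dpgan(X, gen, head, config, delta, rng) -> PrivacyLedger:
    n, d = X.shape
    B = min(config.batch_size, n)
    B = max(config.pack, (B // config.pack) * config.pack)
    q = B / n
    steps_total = config.epochs * max(1, n // B)
    private = math.isfinite(config.epsilon_budget)
    if private:
        sigma = config.noise_multiplier
        if sigma is None:
            sigma = calibrate_sigma(q, steps_total, delta, config.epsilon_budget)
        if epsilon_dpsgd(q, sigma, 1, delta) > config.epsilon_budget:
            raise RuntimeError("privacy budget exhausted before the first step")
    else:
        sigma = config.noise_multiplier or 0.0
    ledger = PrivacyLedger("dpgan", delta=delta)
    if not private:
        ledger.note = "non-private run (epsilon budget disabled)"
    pack = config.pack
    disc = MLP.create([d * pack, *config.hidden_dims, 1], rng)
    opt_d = Adam(disc.params, lr=config.learning_rate)
    opt_g = Adam(gen.params, lr=config.learning_rate)
    for _ in range(steps_total):
        if private:
            eps_next = epsilon_dpsgd(q, sigma, ledger.steps + 1, delta)
            if eps_next > config.epsilon_budget:
                break
        idx = rng.choice(n, size=B, replace=False)
        real = _pack_rows(X[idx], pack)
        z = rng.standard_normal((B, config.latent_dim))
        fake, _, _ = _gen_forward(gen, head, z, rng)
        # discriminator: DP gradients on the real half (per-pack clipping
        # bounds any single record's contribution), plain on the fake half
        logit_r, cache_r = disc.forward(real)
        if private:
            gWr, gbr = disc.backward_dp(cache_r, _bce_grads_logit(logit_r, 1.0),
                                        config.clip_norm, sigma, rng)
        else:
            gWr, gbr, _ = disc.backward(cache_r, _bce_grads_logit(logit_r, 1.0))
        logit_f, cache_f = disc.forward(_pack_rows(fake, pack))
        gWf, gbf, _ = disc.backward(cache_f, _bce_grads_logit(logit_f, 0.0))
        grads = [a + b for a, b in zip(gWr + gbr, gWf + gbf)]
        opt_d.step(disc.params, grads)
        if private:
            ledger.log_dpsgd_step(q, sigma)
        z = rng.standard_normal((B, config.latent_dim))
        _gen_step(gen, head, opt_g, z, disc, rng, pack)
    return ledger


def _train_pategan(X, gen, head, config, delta, rng) -> PrivacyLedger:
    n, d = X.shape
    lam = config.laplace_lambda
    m = config.vote_batch
    per_round = compose_pate(lam, m)
    max_rounds = int(math.floor(config.epsilon_budget / per_round + 1e-9)) \
        if math.isfinite(config.epsilon_budget) \
        else config.epochs * max(1, n // config.batch_size)
    if max_rounds < 1:
        raise RuntimeError("privacy budget exhausted before the first vote round")
    ledger = PrivacyLedger("pategan", delta=delta)
    k = config.n_teachers
    parts = np.array_split(rng.permutation(n), k)
    teachers = [MLP.create([d, *config.hidden_dims, 1], rng) for _ in range(k)]
    opts_t = [Adam(t.params, lr=config.learning_rate) for t in teachers]
    student = MLP.create([d, *config.hidden_dims, 1], rng)
    opt_s = Adam(student.params, lr=config.learning_rate)
    opt_g = Adam(gen.params, lr=config.learning_rate)
    B = min(config.batch_size, min(len(p) for p in parts))
    for _ in range(max_rounds):
        if math.isfinite(config.epsilon_budget) and \
                ledger.epsilon_spent + per_round > config.epsilon_budget + 1e-12:
            break
        # teachers: one adversarial step each on their own partition
        for t, opt, part in zip(teachers, opts_t, parts):
            idx = rng.choice(part, size=B, replace=False)
            z = rng.standard_normal((B, config.latent_dim))
            fake, _, _ = _gen_forward(gen, head, z, rng)
            lr_, cr = t.forward(X[idx])
            gWr, gbr, _ = t.backward(cr, _bce_grads_logit(lr_, 1.0))
            lf, cf = t.forward(fake)
            gWf, gbf, _ = t.backward(cf, _bce_grads_logit(lf, 0.0))
            opt.step(t.params, [a + b for a, b in zip(gWr + gbr, gWf + gbf)])
        # noisy vote aggregation on m generated samples (the private queries)
        z = rng.standard_normal((m, config.latent_dim))
        fake, _, _ = _gen_forward(gen, head, z, rng)
        votes = np.zeros(m)
        for t in teachers:
            logit, _ = t.forward(fake)
            votes += (logit[:, 0] > 0).astype(float)
        noisy_real = votes + rng.laplace(0.0, 1.0 / lam, size=m)
        noisy_fake = (k - votes) + rng.laplace(0.0, 1.0 / lam, size=m)
        labels = (noisy_real > noisy_fake).astype(float)
        ledger.log_pate_queries(lam, m)
        # student learns the released labels; generator trains against student
        logit_s, cache_s = student.forward(fake)
        gW, gb, _ = student.backward(cache_s, _bce_grads_logit(logit_s, labels[:, None]))
        opt_s.step(student.params, gW + gb)
        z = rng.standard_normal((config.batch_size, config.latent_dim))
        _gen_step(gen, head, opt_g, z, student, rng)
    return ledger


def identifiability_penalty(x_syn: np.ndarray, x_src: np.ndarray,
                            d_within: np.ndarray, lam: float
                            ) -> tuple[float, np.ndarray]:
    """λ·mean(max(0, d_within − d(x_syn, x_source))) and its gradient in x_syn.

    Positive exactly when a synthetic sample sits closer to its source record
    than that record's nearest neighbour within the training data.
    """
    diff = x_syn - x_src
    dist = np.sqrt((diff**2).sum(axis=1))
    margin = np.maximum(0.0, d_within - dist)
    value = float(lam * margin.mean())
    grad = np.zeros_like(x_syn)
    nz = (margin > 0) & (dist > 1e-12)
    grad[nz] = -lam * diff[nz] / dist[nz, None] / len(x_syn)
    return value, grad


def _train_adsgan(X, gen, head, config, rng) -> PrivacyLedger:
    n, d = X.shape
    ledger = PrivacyLedger("adsgan", note="not differentially private "
                           "(identifiability regularization only)")
    lam = config.lambda_identifiability
    # each training row's nearest-neighbour distance within the training data
    nn_real = NearestNeighbors(n_neighbors=2).fit(X)
    d_within = nn_real.kneighbors(X)[0][:, 1]
    pack = config.pack
    disc = MLP.create([d * pack, *config.hidden_dims, 1], rng)
    opt_d = Adam(disc.params, lr=config.learning_rate)
    opt_g = Adam(gen.params, lr=config.learning_rate)
    B = min(config.batch_size, n)
    B = max(pack, (B // pack) * pack)
    steps_per_epoch = max(1, n // B)
    best, wait = np.inf, 0
    for _ in range(config.epochs):
        epoch_loss = 0.0
        for _ in range(steps_per_epoch):
            idx = rng.choice(n, size=B, replace=False)
            src = X[idx]
            z = np.concatenate([rng.standard_normal((B, config.latent_dim)), src], axis=1)
            fake, _, _ = _gen_forward(gen, head, z, rng)
            lr_, cr = disc.forward(_pack_rows(X[rng.choice(n, size=B, replace=False)], pack))
            gWr, gbr, _ = disc.backward(cr, _bce_grads_logit(lr_, 1.0))
            lf, cf = disc.forward(_pack_rows(fake, pack))
            gWf, gbf, _ = disc.backward(cf, _bce_grads_logit(lf, 0.0))
            opt_d.step(disc.params, [a + b for a, b in zip(gWr + gbr, gWf + gbf)])

            idx = rng.choice(n, size=B, replace=False)
            src = X[idx]
            dw = d_within[idx]
            z = np.concatenate([rng.standard_normal((B, config.latent_dim)), src], axis=1)

            def pen_grad(out, src=src, dw=dw):
                # reconstruction anchor: the conditional generator is pulled
                # toward its source record (this is what the identifiability
                # penalty must then push back against)
                g = config.recon_weight * 2.0 * (out - src)
                if lam > 0.0:
                    _, pg = identifiability_penalty(out, src, dw, lam)
                    g = g + pg * out.shape[0]
                return g  # per-example gradient; batch mean applied downstream

            epoch_loss += _gen_step(gen, head, opt_g, z, disc, rng, pack,
                                    extra_grad=pen_grad)
        epoch_loss /= steps_per_epoch
        if epoch_loss < best - 1e-3:
            best, wait = epoch_loss, 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    return ledger


def sample(model: GeneratorModel, m: int, seed: int,
           encoder: Encoder | None = None) -> SyntheticDataset:
    """Draw ``m`` synthetic encoded rows (exact one-hots) and decode them."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    cfg = model.config
    zs = rng.standard_normal((m, cfg.latent_dim))
    if model.conditional:
        idx = rng.choice(model.source_data.shape[0], size=m, replace=True)
        zs = np.concatenate([zs, model.source_data[idx]], axis=1)
    out, _, _ = _gen_forward(model.gen, model.head, zs, rng)
    hard = model.head.harden(out)
    cohort = None
    if encoder is not None:
        cohort = encoder.inverse_transform(hard)
    prov = {"method": cfg.method, "seed": seed,
            "ledger": model.ledger.to_dict() if model.ledger else None}
    return SyntheticDataset(hard, list(model.columns), cohort, prov)


def build_ensemble(encoded_train: EncodedMatrix, config: GanConfig,
                   n_members: int = 10, total_rows: int | None = None,
                   encoder: Encoder | None = None) -> SyntheticDataset:
    """Deep generative ensemble: train ``n_members`` generators on seeds
    seed+0..n_members−1 and pool ⌈total_rows/n_members⌉ samples from each.

    The reported ε is the maximum member ε (each member is trained on the
    same data; strict sequential composition over members would instead sum
    the budgets — flagged in the provenance rather than silently absorbed).
    """
    total_rows = total_rows if total_rows is not None else encoded_train.n
    if total_rows < n_members:
        raise ValueError("total_rows must be >= n_members")
    per = -(-total_rows // n_members)  # ceil
    chunks, ledgers = [], []
    for i in range(n_members):
        member_cfg = replace(config, seed=config.seed + i)
        model, ledger = train_gan(encoded_train, member_cfg)
        chunks.append(sample(model, per, seed=member_cfg.seed + 10_000).values)
        ledgers.append(ledger)
    values = np.concatenate(chunks, axis=0)[:total_rows]
    cohort = encoder.inverse_transform(values) if encoder is not None else None
    eps = [l.epsilon_spent for l in ledgers]
    prov = {
        "method": config.method,
        "n_members": n_members,
        "epsilon_max_member": float(max(eps)),
        "epsilon_strict_composition": float(sum(eps)),
        "note": "reported budget is per released member; strict composition "
                "across members would sum the member budgets",
        "ledgers": [l.to_dict() for l in ledgers],
    }
    return SyntheticDataset(values, list(encoded_train.columns), cohort, prov)
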
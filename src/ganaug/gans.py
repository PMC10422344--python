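"""Desk-scale implementations of the five GAN augmenter variants.

All five variants share the generic adversarial loop — alternate discriminator
and generator updates on a real/fake objective — and differ in the mechanism
the variant contributes:

* ``dcgan``        strided-convolution discriminator with batch normalisation
                   and a leaky rectifier; transposed-convolution generator.
* ``conditional``  the class label is injected into both networks (one-hot
                   appended to the latent vector; constant label planes
                   appended to the discriminator input).
* ``infogan``      a categorical latent code plus an auxiliary recognition
                   head trained on a variational lower bound of the mutual
                   information between code and output; the code doubles as
                   the class label for augmentation.
* ``cyclegan``     two generator/discriminator pairs translating between two
                   tumor-class image domains with an L1 cycle-consistency
                   penalty and least-squares adversarial loss.  Generators are
                   residual (output = input + correction, last layer
                   zero-initialised), so they start as exact identities.
* ``pggan``        progressive growing: training starts at 4x4 and doubles the
                   working resolution stage by stage, blending each new block
                   in with a fade-in coefficient rising linearly from 0 to 1.

Networks are deliberately small (<= 32 channels); the mechanisms, not the
capacity, are the point.  Fixed seeds give bit-identical training logs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .dataset import (Manifest, Record, load_image, resize_image,
                      save_image)
from .errors import ConfigError, DataError, DivergenceError, UsageError

VARIANTS = ("pggan", "dcgan", "cyclegan", "infogan", "conditional")


@dataclass
class GanConfig:
    variant: str = "dcgan"
    latent_dim: int = 32
    target_resolution: int = 16
    steps: int = 200
    batch_size: int = 16
    learning_rate: float = 2e-3
    seed: int = 0
    # variant extras
    n_classes: int | None = None          # conditional
    code_dim: int | None = None           # infogan categorical code size
    fade_fraction: float = 0.5            # pggan fade-in share of each stage
    cycle_weight: float = 10.0            # cyclegan cycle-consistency weight
    domains: tuple[str, str] | None = None  # cyclegan class pair (a, b)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown GAN variant {self.variant!r}")
        _check_resolution(self.target_resolution)
        if self.latent_dim < 1:
            raise ConfigError("latent_dim must be >= 1")
        if self.steps < 1 or self.batch_size < 1:
            raise ConfigError("steps and batch_size must be >= 1")
        if not (0.0 < self.fade_fraction <= 1.0):
            raise ConfigError("fade_fraction must lie in (0, 1]")


@dataclass
class GanModelState:
    variant: str
    config: GanConfig
    nets: dict = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)
    resolution_reached: int = 0
    label_map: list[str] | None = None     # conditional / infogan classes
    class_tag: str | None = None           # per-class unconditional models
    exemplars: dict | None = None          # cyclegan source images per domain


@dataclass
class AugmentationBatch:
    images: np.ndarray                     # (n, R, R) floats in [0, 1]
    labels: list[str] | None
    variant: str


def _check_resolution(res: int) -> None:
    r = res
    while r > 4 and r % 2 == 0:
        r //= 2
    if r != 4:
        raise ConfigError(f"resolution must be 4*2^k, got {res}")


def pggan_schedule(target_resolution: int) -> list[int]:
    """Stage resolutions [4, 8, ..., target], doubling each stage."""
    _check_resolution(target_resolution)
    out = [4]
    while out[-1] < target_resolution:
        out.append(out[-1] * 2)
    return out


def _channels(res: int) -> int:
    """Channel width at a given resolution: 32 at 4x4, halved per doubling."""
    return max(8, 32 * 4 // res)


def _prep_images(images: np.ndarray, res: int) -> np.ndarray:
    """Stack of (H, W) floats in [0,1] resized to (N, 1, res, res)."""
    if len(images) == 0:
        raise DataError("GAN training set is empty")
    arr = np.stack([resize_image(im, res) for im in np.asarray(images, dtype=float)])
    return np.clip(arr, 0.0, 1.0)[:, None, :, :]


def _log_step(log: list, step: int, d_loss: float, g_loss: float, **extra) -> None:
    if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
        raise DivergenceError(f"non-finite loss at step {step}: "
                              f"d={d_loss}, g={g_loss}")
    log.append({"step": step, "d_loss": float(d_loss), "g_loss": float(g_loss),
                **extra})


# ---------------------------------------------------------------------------
# Network builders
# ---------------------------------------------------------------------------


def _build_g(latent: int, res: int, rng) -> nn.Sequential:
    c = _channels(4)
    layers: list[nn.Layer] = [nn.Dense(latent, c * 16, rng), nn.Reshape((c, 4, 4)),
                              nn.BatchNorm(c), nn.ReLU()]
    cur = 4
    while cur < res:
        c_next = _channels(cur * 2)
        layers += [nn.ConvTranspose2d(c, c_next, 4, rng, stride=2, pad=1),
                   nn.BatchNorm(c_next), nn.ReLU()]
        c, cur = c_next, cur * 2
    layers += [nn.Conv2d(c, 1, 3, rng), nn.Sigmoid()]
    return nn.Sequential(layers)


def _build_d_trunk(res: int, rng, in_ch: int = 1) -> tuple[nn.Sequential, int]:
    """Strided-conv discriminator trunk ending in a flat feature vector."""
    layers: list[nn.Layer] = []
    c_in, cur = in_ch, res
    first = True
    while cur > 4:
        c_out = _channels(cur // 2)
        layers.append(nn.Conv2d(c_in, c_out, 4, rng, stride=2, pad=1))
        if not first:
            layers.append(nn.BatchNorm(c_out))
        layers.append(nn.LeakyReLU(0.2))
        c_in, cur, first = c_out, cur // 2, False
    layers.append(nn.Flatten())
    return nn.Sequential(layers), c_in * 16


# ---------------------------------------------------------------------------
# DCGAN / Conditional GAN
# ---------------------------------------------------------------------------


def _train_dcgan(config: GanConfig, images: np.ndarray,
                 labels: list[str] | None) -> GanModelState:
    conditional = config.variant == "conditional"
    res = config.target_resolution
    rng = np.random.default_rng(config.seed)
    real = _prep_images(images, res)
    n = real.shape[0]

    classes: list[str] = []
    y = None
    if conditional:
        if labels is None:
            raise UsageError("conditional GAN needs labels for its training images")
        classes = sorted(set(labels))
        y = np.array([classes.index(l) for l in labels])
        k = len(classes)
    else:
        k = 0

    g = _build_g(config.latent_dim + k, res, rng)
    d_trunk, feat = _build_d_trunk(res, rng, in_ch=1 + k)
    d_head = nn.Dense(feat, 1, rng)
    gp, gg = nn.collect(g)
    dp, dg = nn.collect(d_trunk, d_head)
    opt_g = nn.Adam(gp, gg, lr=config.learning_rate)
    opt_d = nn.Adam(dp, dg, lr=config.learning_rate)

    def d_forward(x, train):
        return d_head.forward(d_trunk.forward(x, train), train)

    def d_backward(dout):
        return d_trunk.backward(d_head.backward(dout))

    def label_planes(idx, hw):
        planes = np.zeros((len(idx), k, hw, hw))
        planes[np.arange(len(idx)), idx] = 1.0
        return planes

    def make_fake(b, train):
        z = rng.standard_normal((b, config.latent_dim))
        if conditional:
            ci = rng.integers(0, k, size=b)
            onehot = np.zeros((b, k))
            onehot[np.arange(b), ci] = 1.0
            z = np.concatenate([z, onehot], axis=1)
            return g.forward(z, train), ci
        return g.forward(z, train), None

    b = min(config.batch_size, n)
    log: list[dict] = []
    for step in range(config.steps):
        idx = rng.integers(0, n, size=b)
        xr = real[idx]
        if conditional:
            xr = np.concatenate([xr, label_planes(y[idx], res)], axis=1)
        fake, ci = make_fake(b, True)
        if conditional:
            xf = np.concatenate([fake, label_planes(ci, res)], axis=1)
        else:
            xf = fake
        # discriminator update
        opt_d.zero_grad()
        l_r, dl = nn.bce_with_logits(d_forward(xr, True), 1.0)
        d_backward(dl)
        l_f, dl = nn.bce_with_logits(d_forward(xf, True), 0.0)
        d_backward(dl)
        opt_d.step()
        # generator update (non-saturating)
        fake, ci = make_fake(b, True)
        if conditional:
            xf = np.concatenate([fake, label_planes(ci, res)], axis=1)
        else:
            xf = fake
        g_loss, dl = nn.bce_with_logits(d_forward(xf, True), 1.0)
        opt_d.zero_grad()
        dxf = d_backward(dl)
        opt_g.zero_grad()
        g.backward(dxf[:, :1])
        opt_g.step()
        opt_d.zero_grad()
        _log_step(log, step, l_r + l_f, g_loss, resolution=res)

    return GanModelState(variant=config.variant, config=config,
                         nets={"g": g, "d_trunk": d_trunk, "d_head": d_head},
                         log=log, resolution_reached=res,
                         label_map=classes if conditional else None)


# ---------------------------------------------------------------------------
# InfoGAN
# ---------------------------------------------------------------------------


def _train_infogan(config: GanConfig, images: np.ndarray,
                   labels: list[str] | None) -> GanModelState:
    res = config.target_resolution
    rng = np.random.default_rng(config.seed)
    real = _prep_images(images, res)
    n = real.shape[0]
    classes = sorted(set(labels)) if labels else []
    code_dim = config.code_dim or (len(classes) if classes else 3)

    g = _build_g(config.latent_dim + code_dim, res, rng)
    trunk, feat = _build_d_trunk(res, rng)
    head_adv = nn.Dense(feat, 1, rng)
    head_q = nn.Dense(feat, code_dim, rng)
    gp, gg = nn.collect(g)
    dp, dg = nn.collect(trunk, head_adv)
    qp, qg = nn.collect(trunk, head_q)
    opt_g = nn.Adam(gp, gg, lr=config.learning_rate)
    opt_d = nn.Adam(dp, dg, lr=config.learning_rate)
    opt_q = nn.Adam(qp, qg, lr=config.learning_rate)
    lam = 1.0

    def sample_fake(b, train):
        z = rng.standard_normal((b, config.latent_dim))
        code = rng.integers(0, code_dim, size=b)
        onehot = np.zeros((b, code_dim))
        onehot[np.arange(b), code] = 1.0
        return g.forward(np.concatenate([z, onehot], axis=1), train), code

    b = min(config.batch_size, n)
    log: list[dict] = []
    for step in range(config.steps):
        xr = real[rng.integers(0, n, size=b)]
        fake, _ = sample_fake(b, True)
        # discriminator (adversarial heads only)
        opt_d.zero_grad()
        l_r, dl = nn.bce_with_logits(head_adv.forward(trunk.forward(xr, True)), 1.0)
        trunk.backward(head_adv.backward(dl))
        l_f, dl = nn.bce_with_logits(head_adv.forward(trunk.forward(fake, True)), 0.0)
        trunk.backward(head_adv.backward(dl))
        opt_d.step()
        # generator: adversarial + mutual-information lower bound
        fake, code = sample_fake(b, True)
        feat_v = trunk.forward(fake, True)
        adv = head_adv.forward(feat_v)
        qlog = head_q.forward(feat_v)
        g_adv, dadv = nn.bce_with_logits(adv, 1.0)
        g_info, dq = nn.softmax_cross_entropy(qlog, code)
        opt_d.zero_grad()
        opt_q.zero_grad()
        dfeat = head_adv.backward(dadv) + head_q.backward(lam * dq)
        dfake = trunk.backward(dfeat)
        opt_g.zero_grad()
        g.backward(dfake)
        opt_g.step()
        # recognition network update on the same fake batch (constant input)
        opt_q.zero_grad()
        q_loss, dq = nn.softmax_cross_entropy(
            head_q.forward(trunk.forward(fake, True)), code)
        trunk.backward(head_q.backward(dq))
        opt_q.step()
        opt_d.zero_grad()
        opt_q.zero_grad()
        _log_step(log, step, l_r + l_f, g_adv + lam * g_info,
                  resolution=res, info_loss=float(q_loss))

    label_map = classes if len(classes) == code_dim else [str(i) for i in range(code_dim)]
    return GanModelState(variant="infogan", config=config,
                         nets={"g": g, "trunk": trunk, "head_adv": head_adv,
                               "head_q": head_q},
                         log=log, resolution_reached=res, label_map=label_map)


# ---------------------------------------------------------------------------
# CycleGAN
# ---------------------------------------------------------------------------


class ResidualGenerator(nn.Layer):
    """Identity-initialised translator: output = input + f(input).

    The final convolution of ``f`` starts at zero, so the generator is an
    exact identity before training and the cycle-consistency loss starts at 0.
    """

    def __init__(self, rng, c: int = 16):
        super().__init__()
        self.f = nn.Sequential([
            nn.Conv2d(1, c, 3, rng), nn.ReLU(),
            nn.Conv2d(c, c, 3, rng), nn.ReLU(),
            nn.Conv2d(c, 1, 3, rng, zero_init=True)])
        self.params = self.f.all_params
        self.grads = self.f.all_grads

    def forward(self, x, train=False):
        return x + self.f.forward(x, train)

    def backward(self, dout):
        return dout + self.f.backward(dout)

    def zero_grad(self):
        self.f.zero_grad()


def l1_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    return float(np.abs(diff).mean()), np.sign(diff) / pred.size


def cycle_loss(g_ab: ResidualGenerator, g_ba: ResidualGenerator,
               x: np.ndarray) -> float:
    """L1 reconstruction error of a round trip A -> B -> A (evaluation only)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:
        x = x[:, None]
    loss, _ = l1_loss(g_ba.forward(g_ab.forward(x)), x)
    return loss


def _train_cyclegan(config: GanConfig, images: np.ndarray,
                    labels: list[str] | None) -> GanModelState:
    if labels is None or config.domains is None:
        raise UsageError("cyclegan needs labels and a configured class pair")
    dom_a, dom_b = config.domains
    res = config.target_resolution
    rng = np.random.default_rng(config.seed)
    arr = _prep_images(images, res)
    a_set = arr[[i for i, l in enumerate(labels) if l == dom_a]]
    b_set = arr[[i for i, l in enumerate(labels) if l == dom_b]]
    if len(a_set) == 0 or len(b_set) == 0:
        raise DataError(f"both domains {dom_a!r} and {dom_b!r} need images")

    g_ab = ResidualGenerator(rng)
    g_ba = ResidualGenerator(rng)
    da_trunk, feat = _build_d_trunk(res, rng)
    da_head = nn.Dense(feat, 1, rng)
    db_trunk, _ = _build_d_trunk(res, rng)
    db_head = nn.Dense(feat, 1, rng)
    gp, gg = nn.collect(g_ab, g_ba)
    dp, dg = nn.collect(da_trunk, da_head, db_trunk, db_head)
    opt_g = nn.Adam(gp, gg, lr=config.learning_rate)
    opt_d = nn.Adam(dp, dg, lr=config.learning_rate)

    def d_fwd(trunk, head, x, train):
        return head.forward(trunk.forward(x, train), train)

    def d_bwd(trunk, head, dl):
        return trunk.backward(head.backward(dl))

    b = min(config.batch_size, len(a_set), len(b_set))
    log: list[dict] = []
    for step in range(config.steps):
        xa = a_set[rng.integers(0, len(a_set), size=b)]
        xb = b_set[rng.integers(0, len(b_set), size=b)]
        fb = g_ab.forward(xa, True)   # fake B
        fa = g_ba.forward(xb, True)   # fake A
        # discriminators (least-squares)
        opt_d.zero_grad()
        d_loss = 0.0
        for trunk, head, real_x, fake_x in ((db_trunk, db_head, xb, fb),
                                            (da_trunk, da_head, xa, fa)):
            l, dl = nn.mse_loss(d_fwd(trunk, head, real_x, True), 1.0)
            d_bwd(trunk, head, dl)
            d_loss += l
            l, dl = nn.mse_loss(d_fwd(trunk, head, fake_x, True), 0.0)
            d_bwd(trunk, head, dl)
            d_loss += l
        opt_d.step()
        # generators: adversarial + cycle, one direction at a time so every
        # layer's cache is consumed before its next forward
        opt_g.zero_grad()
        g_loss = 0.0
        for g_fwd, g_rev, x_src, trunk, head in (
                (g_ab, g_ba, xa, db_trunk, db_head),
                (g_ba, g_ab, xb, da_trunk, da_head)):
            fake = g_fwd.forward(x_src, True)
            rec = g_rev.forward(fake, True)
            l_cyc, drec = l1_loss(rec, x_src)
            dfake_cyc = g_rev.backward(config.cycle_weight * drec)
            l_adv, dl = nn.mse_loss(d_fwd(trunk, head, fake, True), 1.0)
            opt_d.zero_grad()
            dfake_adv = d_bwd(trunk, head, dl)
            g_fwd.backward(dfake_cyc + dfake_adv)
            g_loss += l_adv + config.cycle_weight * l_cyc
        opt_g.step()
        opt_d.zero_grad()
        _log_step(log, step, d_loss, g_loss, resolution=res)

    exemplars = {dom_a: a_set[:, 0], dom_b: b_set[:, 0]}
    return GanModelState(variant="cyclegan", config=config,
                         nets={"g_ab": g_ab, "g_ba": g_ba},
                         log=log, resolution_reached=res,
                         label_map=[dom_a, dom_b], exemplars=exemplars)


# ---------------------------------------------------------------------------
# PGGAN
# ---------------------------------------------------------------------------


class PgganGenerator:
    """Progressively grown generator with per-stage toRGB heads."""

    def __init__(self, latent: int, schedule: list[int], rng):
        self.schedule = schedule
        c0 = _channels(4)
        self.base = nn.Sequential([nn.Dense(latent, c0 * 16, rng),
                                   nn.Reshape((c0, 4, 4)), nn.ReLU()])
        self.blocks: list[nn.Sequential] = []
        self.to_rgb: list[nn.Sequential] = [
            nn.Sequential([nn.Conv2d(c0, 1, 1, rng, pad=0), nn.Sigmoid()])]
        c = c0
        for res in schedule[1:]:
            c_next = _channels(res)
            self.blocks.append(nn.Sequential([
                nn.Upsample2(), nn.Conv2d(c, c_next, 3, rng), nn.BatchNorm(c_next),
                nn.ReLU()]))
            self.to_rgb.append(nn.Sequential([nn.Conv2d(c_next, 1, 1, rng, pad=0),
                                              nn.Sigmoid()]))
            c = c_next
        self._up = nn.Upsample2()

    def params_to(self, stage: int):
        mods = [self.base] + self.blocks[:stage] + self.to_rgb[: stage + 1]
        return nn.collect(*mods)

    def forward(self, z, stage: int, alpha: float, train=False):
        h = self.base.forward(z, train)
        for blk in self.blocks[: max(stage - 1, 0)]:
            h = blk.forward(h, train)
        if stage == 0:
            self._route = ("plain", 0)
            return self.to_rgb[0].forward(h, train)
        if alpha >= 1.0:
            h = self.blocks[stage - 1].forward(h, train)
            self._route = ("plain", stage)
            return self.to_rgb[stage].forward(h, train)
        old = self._up.forward(self.to_rgb[stage - 1].forward(h, train))
        new = self.to_rgb[stage].forward(
            self.blocks[stage - 1].forward(h, train), train)
        self._route = ("blend", stage, alpha)
        return alpha * new + (1.0 - alpha) * old

    def backward(self, dout):
        route = self._route
        if route[0] == "plain":
            stage = route[1]
            dh = self.to_rgb[stage].backward(dout)
            blocks = self.blocks[:stage]
        else:
            stage, alpha = route[1], route[2]
            dh_new = self.blocks[stage - 1].backward(
                self.to_rgb[stage].backward(alpha * dout))
            dh_old = self.to_rgb[stage - 1].backward(
                self._up.backward((1.0 - alpha) * dout))
            dh = dh_new + dh_old
            blocks = self.blocks[: stage - 1]
        for blk in reversed(blocks):
            dh = blk.backward(dh)
        self.base.backward(dh)


class PgganDiscriminator:
    """Mirror of the generator: per-stage fromRGB inputs, downsampling blocks."""

    def __init__(self, schedule: list[int], rng):
        self.schedule = schedule
        c0 = _channels(4)
        self.from_rgb: list[nn.Sequential] = [
            nn.Sequential([nn.Conv2d(1, c0, 1, rng, pad=0), nn.LeakyReLU(0.2)])]
        self.blocks: list[nn.Sequential] = []
        prev_c = c0
        for res in schedule[1:]:
            c = _channels(res)
            self.from_rgb.append(nn.Sequential([nn.Conv2d(1, c, 1, rng, pad=0),
                                                nn.LeakyReLU(0.2)]))
            self.blocks.append(nn.Sequential([
                nn.Conv2d(c, prev_c, 3, rng), nn.LeakyReLU(0.2), nn.AvgPool2()]))
            prev_c = c
        self.head = nn.Sequential([nn.Flatten(), nn.Dense(c0 * 16, 1, rng)])
        self._down = nn.AvgPool2()

    def params_to(self, stage: int):
        mods = self.from_rgb[: stage + 1] + self.blocks[:stage] + [self.head]
        return nn.collect(*mods)

    def forward(self, x, stage: int, alpha: float, train=False):
        if stage == 0:
            self._route = ("plain", 0)
            h = self.from_rgb[0].forward(x, train)
        elif alpha >= 1.0:
            self._route = ("plain", stage)
            h = self.blocks[stage - 1].forward(
                self.from_rgb[stage].forward(x, train), train)
        else:
            h_new = self.blocks[stage - 1].forward(
                self.from_rgb[stage].forward(x, train), train)
            h_old = self.from_rgb[stage - 1].forward(self._down.forward(x), train)
            self._route = ("blend", stage, alpha)
            h = alpha * h_new + (1.0 - alpha) * h_old
        for blk in reversed(self.blocks[: max(stage - 1, 0)]):
            h = blk.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dout):
        route = self._route
        stage = route[1]
        dh = self.head.backward(dout)
        for blk in self.blocks[: max(stage - 1, 0)]:
            dh = blk.backward(dh)
        if route[0] == "plain":
            if stage == 0:
                return self.from_rgb[0].backward(dh)
            return self.from_rgb[stage].backward(
                self.blocks[stage - 1].backward(dh))
        alpha = route[2]
        dx_new = self.from_rgb[stage].backward(
            self.blocks[stage - 1].backward(alpha * dh))
        dx_old = self._down.backward(
            self.from_rgb[stage - 1].backward((1.0 - alpha) * dh))
        return dx_new + dx_old


def _train_pggan(config: GanConfig, images: np.ndarray) -> GanModelState:
    schedule = pggan_schedule(config.target_resolution)
    rng = np.random.default_rng(config.seed)
    base = np.asarray(images, dtype=float)
    g = PgganGenerator(config.latent_dim, schedule, rng)
    d = PgganDiscriminator(schedule, rng)

    steps_per_stage = max(1, config.steps // len(schedule))
    log: list[dict] = []
    step = 0
    for stage, res in enumerate(schedule):
        real = _prep_images(base, res)
        n = real.shape[0]
        b = min(config.batch_size, n)
        gp, gg = g.params_to(stage)
        dp, dg = d.params_to(stage)
        opt_g = nn.Adam(gp, gg, lr=config.learning_rate)
        opt_d = nn.Adam(dp, dg, lr=config.learning_rate)
        fade_steps = max(1, int(config.fade_fraction * steps_per_stage))
        for s in range(steps_per_stage):
            alpha = 1.0 if stage == 0 else min(1.0, s / fade_steps)
            xr = real[rng.integers(0, n, size=b)]
            z = rng.standard_normal((b, config.latent_dim))
            fake = g.forward(z, stage, alpha, True)
            opt_d.zero_grad()
            l_r, dl = nn.bce_with_logits(d.forward(xr, stage, alpha, True), 1.0)
            d.backward(dl)
            l_f, dl = nn.bce_with_logits(d.forward(fake, stage, alpha, True), 0.0)
            d.backward(dl)
            opt_d.step()
            z = rng.standard_normal((b, config.latent_dim))
            fake = g.forward(z, stage, alpha, True)
            g_loss, dl = nn.bce_with_logits(d.forward(fake, stage, alpha, True), 1.0)
            opt_d.zero_grad()
            dfake = d.backward(dl)
            opt_g.zero_grad()
            g.backward(dfake)
            opt_g.step()
            opt_d.zero_grad()
            _log_step(log, step, l_r + l_f, g_loss,
                      resolution=res, alpha=float(alpha))
            step += 1

    state = GanModelState(variant="pggan", config=config,
                          nets={"g": g, "d": d}, log=log,
                          resolution_reached=schedule[-1])
    return state


# ---------------------------------------------------------------------------
# Public training / generation API
# ---------------------------------------------------------------------------


def train_gan(config: GanConfig, images: np.ndarray,
              labels: list[str] | None = None) -> GanModelState:
    """Train one GAN variant on (N, H, W) images with values in [0, 1]."""
    if len(images) == 0:
        raise DataError("GAN training set is empty")
    if config.variant in ("dcgan", "conditional"):
        return _train_dcgan(config, images, labels)
    if config.variant == "infogan":
        return _train_infogan(config, images, labels)
    if config.variant == "cyclegan":
        return _train_cyclegan(config, images, labels)
    return _train_pggan(config, np.asarray(images, dtype=float))


def generate(state: GanModelState, n: int, label: str | None = None,
             seed: int = 0) -> AugmentationBatch:
    """Sample n synthetic images from a trained state, clipped to [0, 1]."""
    if n < 0:
        raise UsageError("n must be >= 0")
    res = state.resolution_reached
    rng = np.random.default_rng(seed)
    cfg = state.config
    if n == 0:
        return AugmentationBatch(np.zeros((0, res, res)), None, state.variant)

    if state.variant in ("dcgan", "pggan"):
        if label is not None:
            raise UsageError(f"{state.variant} is unconditional; label forbidden")
        z = rng.standard_normal((n, cfg.latent_dim))
        if state.variant == "pggan":
            g: PgganGenerator = state.nets["g"]
            imgs = g.forward(z, len(g.schedule) - 1, 1.0, train=False)
        else:
            imgs = state.nets["g"].forward(z, train=False)
        labels = [state.class_tag] * n if state.class_tag else None
        return AugmentationBatch(np.clip(imgs[:, 0], 0, 1), labels, state.variant)

    if state.variant in ("conditional", "infogan"):
        if label is None:
            raise UsageError(f"{state.variant} requires a class label")
        if label not in (state.label_map or []):
            raise UsageError(f"unknown label {label!r}; known: {state.label_map}")
        k = len(state.label_map)
        onehot = np.zeros((n, k))
        onehot[:, state.label_map.index(label)] = 1.0
        z = np.concatenate([rng.standard_normal((n, cfg.latent_dim)), onehot], axis=1)
        imgs = state.nets["g"].forward(z, train=False)
        return AugmentationBatch(np.clip(imgs[:, 0], 0, 1), [label] * n,
                                 state.variant)

    # cyclegan: translate exemplars of the opposite domain into `label`
    if label is None:
        raise UsageError("cyclegan generation requires the target class label")
    dom_a, dom_b = state.label_map
    if label == dom_b:
        src, gen = state.exemplars[dom_a], state.nets["g_ab"]
    elif label == dom_a:
        src, gen = state.exemplars[dom_b], state.nets["g_ba"]
    else:
        raise UsageError(f"label {label!r} not in configured pair {state.label_map}")
    idx = rng.integers(0, len(src), size=n)
    out = gen.forward(src[idx][:, None], train=False)
    return AugmentationBatch(np.clip(out[:, 0], 0, 1), [label] * n, "cyclegan")


def augment_dataset(manifest: Manifest, states: dict, n_per_class: int,
                    out_dir: str, seed: int = 0) -> dict[str, Manifest]:
    """Build one augmented train manifest per GAN variant.

    ``states[variant]`` is either a single conditional state or a mapping
    ``class -> state`` for per-class unconditional / translation models.
    Synthetic rows carry the generating variant in their origin column;
    validation and test records pass through untouched.
    """
    classes = sorted(manifest.subset("train").class_counts().keys())
    out: dict[str, Manifest] = {}
    os.makedirs(out_dir, exist_ok=True)
    for variant, state in states.items():
        if variant not in VARIANTS:
            raise UsageError(f"unknown variant {variant!r}")
        new_rows: list[Record] = []
        for ci, cls in enumerate(classes):
            if n_per_class == 0:
                continue
            sub_seed = (seed * 1009 + ci) % (2**31 - 1)
            if isinstance(state, dict):
                if cls not in state:
                    raise UsageError(f"no trained {variant} state for class {cls!r}")
                model = state[cls]
                lbl = cls if model.variant == "cyclegan" else None
                batch = generate(model, n_per_class, label=lbl, seed=sub_seed)
            else:
                batch = generate(state, n_per_class, label=cls, seed=sub_seed)
            for i, img in enumerate(batch.images):
                path = os.path.join(out_dir, f"{variant}_{cls}_{i:04d}.png")
                save_image(np.rint(img * 255.0), path)
                new_rows.append(Record(path=path, label=cls, plane="axial",
                                       split="train", origin=variant))
        out[variant] = Manifest(list(manifest.records) + new_rows)
    return out


def load_train_images(manifest: Manifest, resolution: int):
    """Load the train-split images of a manifest as (N, res, res) in [0, 1]."""
    recs = manifest.subset("train").records
    if not recs:
        raise DataError("manifest has no train records")
    imgs = np.stack([resize_image(load_image(r.path) / 255.0, resolution)
                     for r in recs])
    return imgs, [r.label for r in recs]
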
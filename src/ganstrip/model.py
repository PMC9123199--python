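"""The volumetric pix2pix pair: U-Net generator and PatchGAN discriminator.

The generator is an encoder-decoder with skip connections: ``depth``
stride-2 3D convolutions (kernel 4, batch norm, leaky-ReLU 0.2) down,
``depth`` stride-2 transposed convolutions (batch norm, ReLU, dropout on
the leading decoder blocks) up, encoder level i concatenated onto decoder
level depth - i, and a tanh output in [-1, 1].  Following the original
pix2pix design, batch norm is omitted on the first encoder block and at
the bottleneck, and the output block is a bare transposed convolution with
tanh.  The conditioning volume is the generator's only input; no noise
variable is used.

The discriminator concatenates the condition c and a candidate volume at
the input and reduces them through stride-2 convolutions to a patch of
independent real/fake probabilities (sigmoid), one per receptive field.

Objective (the conditional-GAN value plus an L1 term):

    L_cGAN(G, D) = E_{c,x}[log D(c, x)] + E_c[log(1 - D(c, G(c)))]
    L_L1(G)      = E[|x - G(c)|]            (per-voxel mean)
    G* = argmin_G max_D  L_cGAN(G, D) + lambda * L_L1(G),   lambda = 100

Losses are reported as the quantities each network minimizes; the
generator uses the non-saturating adversarial form -log D(c, G(c)).
Probabilities are clamped to [eps, 1 - eps] before logs so every loss is
finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn

__all__ = [
    "EPS",
    "GeneratorConfig",
    "DiscriminatorConfig",
    "LossTerms",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "l1_loss",
    "loss_discriminator",
    "loss_generator",
    "save_checkpoint",
    "load_checkpoint",
]

#: probability clamp applied before logarithms
EPS = 1e-7


@dataclass
class GeneratorConfig:
    """U-Net hyperparameters (defaults follow the full-scale setting)."""

    depth: int = 6
    base_filters: int = 64
    kernel: int = 4
    stride: int = 2
    dropout_layers: int = 3
    dropout_rate: float = 0.5
    init_std: float = 0.02
    max_filter_mult: int = 8

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.dropout_layers > self.depth:
            raise ValueError("dropout_layers must be <= depth")
        if self.kernel < 1 or self.stride < 1:
            raise ValueError("kernel and stride must be positive")

    def filters(self, level):
        return self.base_filters * min(2 ** (level - 1), self.max_filter_mult)


@dataclass
class DiscriminatorConfig:
    """PatchGAN hyperparameters; ``levels`` stride-2 stages fix the patch
    size (a 64-voxel axis with 4 levels yields a 4-patch axis)."""

    levels: int = 4
    base_filters: int = 64
    kernel: int = 4
    stride: int = 2
    init_std: float = 0.02
    max_filter_mult: int = 8

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")

    def filters(self, level):
        return self.base_filters * min(2 ** (level - 1), self.max_filter_mult)

    def patch_shape(self, input_shape):
        div = 2 ** self.levels
        for axis, n in zip("xyz", input_shape):
            if n % div or n < div:
                raise ValueError(
                    f"axis {axis} (size {n}) is not reducible by "
                    f"{self.levels} stride-2 stages"
                )
        return tuple(n // div for n in input_shape)


@dataclass
class LossTerms:
    """The logged loss components of one adversarial step.

    d_real / d_fake are the two discriminator terms, written as the
    quantities D minimizes: -mean log D(c, x) and -mean log(1 - D(c, x_fake)).
    g_adv is the generator's non-saturating adversarial term
    -mean log D(c, x_fake), and g_l1 the mean absolute voxel error.
    """

    d_real: float = 0.0
    d_fake: float = 0.0
    g_adv: float = 0.0
    g_l1: float = 0.0
    lam: float = 100.0

    @property
    def d_total(self):
        return self.d_real + self.d_fake

    @property
    def g_total(self):
        return self.g_adv + self.lam * self.g_l1


def _check_divisible(shape, depth):
    div = 2 ** depth
    for axis, n in zip("xyz", shape):
        if n % div:
            raise ValueError(
                f"input axis {axis} (size {n}) is not divisible by 2^{depth}"
            )


class Generator:
    """Shape-preserving U-Net mapping a conditioning volume to [-1, 1]."""

    def __init__(self, cfg: GeneratorConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        d = cfg.depth
        self.enc = []
        c_prev = 1
        for i in range(1, d + 1):
            f = cfg.filters(i)
            conv = nn.Conv3d(c_prev, f, cfg.kernel, cfg.stride, 1,
                             cfg.init_std, rng)
            bn = nn.BatchNorm3d(f, init_std=cfg.init_std, rng=rng) \
                if 1 < i < d else None
            self.enc.append({"conv": conv, "bn": bn,
                             "act": nn.LeakyReLU(0.2)})
            c_prev = f
        self.dec = []
        self._eff_dropout = min(cfg.dropout_layers, d - 1)
        for j in range(1, d + 1):
            c_in = cfg.filters(d) if j == 1 else 2 * cfg.filters(d - j + 1)
            c_out = 1 if j == d else cfg.filters(d - j)
            convt = nn.ConvTranspose3d(c_in, c_out, cfg.kernel, cfg.stride,
                                       1, cfg.init_std, rng)
            if j == d:
                self.dec.append({"convt": convt, "bn": None, "drop": None,
                                 "act": nn.Tanh()})
            else:
                drop = nn.Dropout(cfg.dropout_rate) \
                    if j <= self._eff_dropout else None
                self.dec.append({"convt": convt,
                                 "bn": nn.BatchNorm3d(c_out,
                                                      init_std=cfg.init_std,
                                                      rng=rng),
                                 "drop": drop,
                                 "act": nn.ReLU()})
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(1)[0])
        for blk in self.dec:
            if blk["drop"] is not None:
                blk["drop"].rng = self.dropout_rng

    # -- plumbing -------------------------------------------------------
    def layers(self):
        out = []
        for blk in self.enc:
            out += [blk["conv"]] + ([blk["bn"]] if blk["bn"] else [])
        for blk in self.dec:
            out += [blk["convt"]] + ([blk["bn"]] if blk["bn"] else [])
        return out

    def zero_grad(self):
        for l in self.layers():
            l.zero_grad()

    # -- compute --------------------------------------------------------
    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3:
            raise ValueError("generator expects a single 3D volume")
        _check_divisible(x.shape, self.cfg.depth)
        h = x[None]
        self._skips = []
        for blk in self.enc:
            h = blk["conv"].forward(h, train)
            if blk["bn"] is not None:
                h = blk["bn"].forward(h, train)
            h = blk["act"].forward(h, train)
            self._skips.append(h)
        d = self.cfg.depth
        self._dec_in_ch = []
        for j, blk in enumerate(self.dec, start=1):
            inp = h if j == 1 else np.concatenate(
                [h, self._skips[d - j]], axis=0)
            self._dec_in_ch.append(h.shape[0])
            h = blk["convt"].forward(inp, train)
            if blk["bn"] is not None:
                h = blk["bn"].forward(h, train)
            if blk["drop"] is not None:
                h = blk["drop"].forward(h, train)
            h = blk["act"].forward(h, train)
        return h[0]

    def backward(self, g_out):
        """Accumulate parameter gradients from d(loss)/d(output); returns
        the gradient with respect to the input volume."""
        d = self.cfg.depth
        # gradient arriving at each encoder activation a_i through a skip
        skip_grads = {}
        g = np.asarray(g_out, dtype=np.float32)[None]
        for j in range(d, 0, -1):
            blk = self.dec[j - 1]
            g = blk["act"].backward(g)
            if blk["drop"] is not None:
                g = blk["drop"].backward(g)
            if blk["bn"] is not None:
                g = blk["bn"].backward(g)
            g_in = blk["convt"].backward(g)
            if j == 1:
                g = g_in  # gradient at the bottleneck activation a_d
            else:
                split = self._dec_in_ch[j - 1]
                g, skip_grads[d - j + 1] = g_in[:split], g_in[split:]
        for i in range(d, 0, -1):
            blk = self.enc[i - 1]
            if i in skip_grads:
                g = g + skip_grads[i]
            g = blk["act"].backward(g)
            if blk["bn"] is not None:
                g = blk["bn"].backward(g)
            g = blk["conv"].backward(g)
        return g[0]


class Discriminator:
    """PatchGAN over the channel-concatenated (condition, candidate) pair."""

    def __init__(self, cfg: DiscriminatorConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.blocks = []
        c_prev = 2
        for i in range(1, cfg.levels + 1):
            f = cfg.filters(i)
            conv = nn.Conv3d(c_prev, f, cfg.kernel, cfg.stride, 1,
                             cfg.init_std, rng)
            bn = nn.BatchNorm3d(f, init_std=cfg.init_std, rng=rng) \
                if i > 1 else None
            self.blocks.append({"conv": conv, "bn": bn,
                                "act": nn.LeakyReLU(0.2)})
            c_prev = f
        self.head = nn.Conv3d(c_prev, 1, kernel=3, stride=1, pad=1,
                              init_std=cfg.init_std, rng=rng)
        self.out_act = nn.Sigmoid()

    def layers(self):
        out = []
        for blk in self.blocks:
            out += [blk["conv"]] + ([blk["bn"]] if blk["bn"] else [])
        out.append(self.head)
        return out

    def zero_grad(self):
        for l in self.layers():
            l.zero_grad()

    def forward(self, condition, candidate, train=False):
        c = np.asarray(condition, dtype=np.float32)
        x = np.asarray(candidate, dtype=np.float32)
        if c.shape != x.shape:
            raise ValueError(
                f"condition {c.shape} and candidate {x.shape} differ in shape"
            )
        self.cfg.patch_shape(c.shape)  # validates the stride plan
        h = np.stack([c, x], axis=0)
        for blk in self.blocks:
            h = blk["conv"].forward(h, train)
            if blk["bn"] is not None:
                h = blk["bn"].forward(h, train)
            h = blk["act"].forward(h, train)
        h = self.head.forward(h, train)
        p = self.out_act.forward(h, train)
        return p[0]

    def backward(self, g_patch):
        """Accumulate parameter gradients; returns (grad_condition,
        grad_candidate) with respect to the two input volumes."""
        g = np.asarray(g_patch, dtype=np.float32)[None]
        g = self.out_act.backward(g)
        g = self.head.backward(g)
        for blk in reversed(self.blocks):
            g = blk["act"].backward(g)
            if blk["bn"] is not None:
                g = blk["bn"].backward(g)
            g = blk["conv"].backward(g)
        return g[0], g[1]


def build_generator(cfg: GeneratorConfig, input_shape=None,
                    seed: int = 0) -> Generator:
    """Construct a generator; when ``input_shape`` is given, validate that
    every axis survives ``depth`` halvings."""
    if input_shape is not None:
        _check_divisible(input_shape, cfg.depth)
    return Generator(cfg, seed=seed)


def build_discriminator(cfg: DiscriminatorConfig, input_shape=None,
                        seed: int = 0) -> Discriminator:
    if input_shape is not None:
        cfg.patch_shape(input_shape)
    return Discriminator(cfg, seed=seed)


def l1_loss(x, x_fake) -> float:
    """Mean absolute voxel difference (the expectation form of the L1 term)."""
    x = np.asarray(x, dtype=np.float64)
    xf = np.asarray(x_fake, dtype=np.float64)
    if x.shape != xf.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xf.shape}")
    return float(np.mean(np.abs(x - xf)))


def _clamp(p):
    return np.clip(p, EPS, 1.0 - EPS)


def loss_discriminator(D, c, x, x_fake, lam: float = 100.0) -> LossTerms:
    """The discriminator's minimization target on one pair (patch-averaged):
    -mean log D(c, x) - mean log(1 - D(c, x_fake))."""
    p_real = _clamp(D.forward(c, x, train=False))
    p_fake = _clamp(D.forward(c, x_fake, train=False))
    return LossTerms(
        d_real=float(-np.mean(np.log(p_real))),
        d_fake=float(-np.mean(np.log(1.0 - p_fake))),
        lam=lam,
    )


def loss_generator(D, c, x, x_fake, lam: float = 100.0) -> LossTerms:
    """The generator's minimization target: -mean log D(c, x_fake) plus
    lambda times the L1 term (both reported separately)."""
    p_fake = _clamp(D.forward(c, x_fake, train=False))
    return LossTerms(
        g_adv=float(-np.mean(np.log(p_fake))),
        g_l1=l1_loss(x, x_fake),
        lam=lam,
    )


# -- serialization ------------------------------------------------------

def _state_dict(model):
    state = {}
    for idx, layer in enumerate(model.layers()):
        for k, v in layer.params.items():
            state[f"layer{idx:03d}.{k}"] = v
        for k, v in layer.buffers.items():
            state[f"layer{idx:03d}.buf.{k}"] = v
    return state


def _load_state(model, state):
    for idx, layer in enumerate(model.layers()):
        for k in layer.params:
            layer.params[k][...] = state[f"layer{idx:03d}.{k}"]
        for k in layer.buffers:
            layer.buffers[k][...] = state[f"layer{idx:03d}.buf.{k}"]


def save_checkpoint(path, generator: Generator, discriminator=None,
                    meta=None) -> None:
    """Serialize model weights (and configs) to a single ``.npz`` file."""
    payload = {f"G.{k}": v for k, v in _state_dict(generator).items()}
    manifest = {"gcfg": asdict(generator.cfg), "meta": meta or {}}
    if discriminator is not None:
        payload.update(
            {f"D.{k}": v for k, v in _state_dict(discriminator).items()})
        manifest["dcfg"] = asdict(discriminator.cfg)
    payload["manifest"] = np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path):
    """Rebuild models from :func:`save_checkpoint` output.

    Returns (generator, discriminator_or_None, meta).
    """
    with np.load(path) as data:
        manifest = json.loads(bytes(data["manifest"]).decode())
        g = Generator(GeneratorConfig(**manifest["gcfg"]))
        _load_state(g, {k[2:]: data[k] for k in data.files
                        if k.startswith("G.")})
        d = None
        if "dcfg" in manifest:
            d = Discriminator(DiscriminatorConfig(**manifest["dcfg"]))
            _load_state(d, {k[2:]: data[k] for k in data.files
                            if k.startswith("D.")})
    return g, d, manifest.get("meta", {})
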
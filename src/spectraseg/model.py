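"""Spectral-preserving segmentation network and its ablation variants.

The backbone is a 3-D encoder-decoder whose third tensor axis is the
energy-bin axis: all down/upsampling uses stride 1x2x2, so every level
keeps the full F-bin spectral resolution, and a final fusion head with
kernel extent (F,1,1) collapses the preserved energy axis into the 13
class logits.  Three spectral modules can be inserted after each
double-convolution block (encoder, bottleneck and decoder):

- ``spec-SE``   — squeeze-excitation channel reweighting per energy bin;
- ``EnergyFiLM`` — per-bin affine modulation predicted from a sinusoidal
  encoding of the bin index (identity at initialization);
- ``FourierGate`` — rFFT-domain magnitude gating of the global spectral
  profile.

Variants: ``plain`` (none), ``sp`` (SE), ``e_sp`` (SE+FiLM), ``fg_sp``
(SE+FourierGate), ``spff`` (all three) and ``blind_control``, which first
averages the input over the energy axis and runs the same architecture
with F=1 — a validation control demonstrating that spectral *shape*, not
band-integrated magnitude, drives material separability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import (Adam, Conv3d, ConvTranspose1x2x2, EnergyFiLM, FourierGate,
                 InstanceNorm3d, LeakyReLU, MaxPool1x2x2, Module, Param,
                 SpectralFusionHead, SpectralSE)

__all__ = [
    "NetworkConfig", "SpectralUNet", "build_network", "predict_labels",
    "count_parameters", "save_checkpoint", "load_checkpoint", "VARIANTS",
]

VARIANTS = ("plain", "sp", "e_sp", "fg_sp", "spff", "blind_control")

#: which spectral modules each variant inserts after the double-conv blocks
_VARIANT_MODULES = {
    "plain": (),
    "sp": ("se",),
    "e_sp": ("se", "film"),
    "fg_sp": ("se", "fg"),
    "spff": ("se", "film", "fg"),
    "blind_control": ("se", "film", "fg"),
}


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters fixing the model graph."""

    variant: str = "spff"
    base_channels: int = 32
    levels: int = 4
    F: int = 5
    C: int = 13
    se_reduction: int = 8
    film_enc_dim: int = 16
    leaky_slope: float = 0.01
    norm: str = "instance"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"choose from {VARIANTS}")
        if self.F < 1 or self.C < 2 or self.base_channels < 4:
            raise ValueError("invalid NetworkConfig dimensions")
        if self.levels < 2:
            raise ValueError("need at least 2 resolution levels")

    @property
    def effective_F(self) -> int:
        return 1 if self.variant == "blind_control" else self.F

    @property
    def widths(self) -> tuple:
        """Channel width at each resolution level (doubling per level)."""
        return tuple(self.base_channels * 2 ** i for i in range(self.levels))


class DoubleConvBlock(Module):
    """Two (conv 3x3x3, instance norm, leaky ReLU) stages plus the variant's
    spectral modules, applied in the order spec-SE, EnergyFiLM, FourierGate."""

    def __init__(self, cin: int, cout: int, cfg: NetworkConfig, seed: int,
                 name: str):
        sl = cfg.leaky_slope
        self.stages: list[Module] = [
            Conv3d(cin, cout, seed, f"{name}.conv1", sl),
            InstanceNorm3d(),
            LeakyReLU(sl),
            Conv3d(cout, cout, seed, f"{name}.conv2", sl),
            InstanceNorm3d(),
            LeakyReLU(sl),
        ]
        mods = _VARIANT_MODULES[cfg.variant]
        F = cfg.effective_F
        if "se" in mods:
            self.stages.append(SpectralSE(cout, seed, f"{name}.se",
                                          cfg.se_reduction, sl))
        if "film" in mods:
            self.stages.append(EnergyFiLM(cout, F, seed, f"{name}.film",
                                          cfg.film_enc_dim, sl))
        if "fg" in mods:
            self.stages.append(FourierGate(F, seed, f"{name}.fg"))

    def forward(self, x: np.ndarray, shape_log: list | None = None) -> np.ndarray:
        for st in self.stages:
            x = st.forward(x)
            if shape_log is not None:
                shape_log.append(x.shape)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for st in reversed(self.stages):
            dy = st.backward(dy)
        return dy


class SpectralUNet(Module):
    """Encoder-decoder over (B, 1, F, H, W) inputs producing (B, C, H, W) logits."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        cfg = config
        w = cfg.widths
        F = cfg.effective_F
        self.enc = [DoubleConvBlock(1 if i == 0 else w[i - 1], w[i], cfg,
                                    seed, f"enc{i}")
                    for i in range(cfg.levels - 1)]
        self.pools = [MaxPool1x2x2() for _ in range(cfg.levels - 1)]
        self.bottleneck = DoubleConvBlock(w[-2], w[-1], cfg, seed, "bottleneck")
        self.ups = [ConvTranspose1x2x2(w[i + 1], w[i], seed, f"up{i}")
                    for i in range(cfg.levels - 1)]
        self.dec = [DoubleConvBlock(2 * w[i], w[i], cfg, seed, f"dec{i}")
                    for i in range(cfg.levels - 1)]
        self.head = SpectralFusionHead(w[0], cfg.C, F, seed, "head")
        self.last_shapes: list[tuple] = []

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        cfg = self.config
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError("input must be (B, 1, F, H, W)")
        if cfg.variant == "blind_control" and x.shape[2] > 1:
            x = x.mean(axis=2, keepdims=True)
        if x.shape[2] != cfg.effective_F:
            raise ValueError(f"energy extent {x.shape[2]} != F={cfg.effective_F}")
        div = 2 ** (cfg.levels - 1)
        if x.shape[3] % div or x.shape[4] % div:
            raise ValueError(f"H and W must be divisible by {div}")
        return x

    def forward(self, x: np.ndarray, record_shapes: bool = False) -> np.ndarray:
        x = self._check_input(x)
        log: list | None = [] if record_shapes else None
        skips = []
        h = x
        for blk, pool in zip(self.enc, self.pools):
            s = blk.forward(h, log)
            skips.append(s)
            h = pool.forward(s)
            if log is not None:
                log.append(h.shape)
        h = self.bottleneck.forward(h, log)
        for i in range(len(self.dec) - 1, -1, -1):
            u = self.ups[i].forward(h)
            if log is not None:
                log.append(u.shape)
            c = np.concatenate([u, skips[i]], axis=1)
            h = self.dec[i].forward(c, log)
        logits = self.head.forward(h)
        if log is not None:
            self.last_shapes = log
        return logits

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        w = self.config.widths
        dh = self.head.backward(dlogits)
        dskips = [None] * len(self.dec)
        for i in range(len(self.dec)):
            dc = self.dec[i].backward(dh)
            du, dskips[i] = dc[:, : w[i]], dc[:, w[i]:]
            dh = self.ups[i].backward(du)
        dh = self.bottleneck.backward(dh)
        for i in range(len(self.enc) - 1, -1, -1):
            ds = self.pools[i].backward(dh) + dskips[i]
            dh = self.enc[i].backward(ds)
        return dh

    def params(self) -> list[Param]:
        out: list[Param] = []
        for blk in self.enc:
            for st in blk.stages:
                out.extend(st.params())
        for st in self.bottleneck.stages:
            out.extend(st.params())
        for up in self.ups:
            out.extend(up.params())
        for blk in self.dec:
            for st in blk.stages:
                out.extend(st.params())
        out.extend(self.head.params())
        return out


def build_network(config: NetworkConfig, seed: int = 0) -> SpectralUNet:
    """Construct the variant's network with seed-deterministic initialization."""
    return SpectralUNet(config, seed)


def predict_labels(logits: np.ndarray) -> np.ndarray:
    """Per-voxel argmax over classes; ties break toward the lowest index."""
    return np.argmax(logits, axis=1)


def count_parameters(network: SpectralUNet) -> int:
    return int(sum(p.data.size for p in network.params()))


def save_checkpoint(path, network: SpectralUNet, seed: int,
                    extra: dict | None = None) -> None:
    """Versioned checkpoint: weights + NetworkConfig + seed + metadata."""
    arrays = {f"param{idx:04d}::{p.name}": p.data
              for idx, p in enumerate(network.params())}
    meta = {"format_version": 1, "config": asdict(network.config),
            "seed": int(seed), "extra": extra or {}}
    np.savez_compressed(path, __meta__=np.str_(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> tuple[SpectralUNet, dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        config = NetworkConfig(**meta["config"])
        net = build_network(config, seed=meta["seed"])
        params = net.params()
        keys = sorted(k for k in z.files if k.startswith("param"))
        if len(keys) != len(params):
            raise ValueError("checkpoint does not match architecture")
        for key, p in zip(keys, params):
            name = key.split("::", 1)[1]
            if name != p.name:
                raise ValueError(f"parameter mismatch: {name} vs {p.name}")
            p.data = z[key].astype(p.data.dtype)
    return net, meta
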
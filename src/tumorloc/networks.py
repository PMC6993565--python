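"""Patch-based 3D segmentation architectures.

Two architectures share one code path for full-size and tiny instances:

* **Dual-path multiscale CNN** ("modified DeepMedic"): a normal-resolution
  path with a 25^3 receptive field (8 valid 3x3x3 convolutions, batch norm,
  residual links over the later layer pairs) in parallel with a
  low-resolution path whose 19^3 input is a factor-3 average-pooled 55^3
  neighbourhood sharing the same center; the low path output is upsampled
  trilinearly by 3, concatenated with the normal path, and a 1x1x1
  convolution head emits class logits over the central 9^3 voxels.

* **Encoder-decoder CNN** ("modified 3D U-Net"): residual encoder blocks
  with group normalization (4 groups) and 0.3 dropout, 2^3 max pooling on
  descent, trilinear upsampling plus skip concatenation on ascent, and a
  final 1x1x1 convolution at input resolution.

Widths are configuration, not architecture: the geometry invariants hold for
any channel counts, which is what lets the test suite exercise tiny
instances of the exact topology.
"""

from __future__ import annotations

import dataclasses
import io
import json
from pathlib import Path

import numpy as np

from . import nncore as nc
from .labels import N_CLASSES


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class DeepMedicConfig:
    in_channels: int = 4
    n_classes: int = N_CLASSES
    conv_widths: tuple[int, ...] = (30, 30, 40, 40, 40, 40, 50, 50)
    head_width: int = 60
    n_conv_per_path: int = 8
    normal_rf: int = 25
    low_rf: int = 19
    low_src_patch: int = 55
    downsample_factor: int = 3
    out_patch: int = 9

    def __post_init__(self) -> None:
        if len(self.conv_widths) != self.n_conv_per_path:
            raise ConfigError("conv_widths must list one width per conv layer")
        if self.normal_rf - 2 * self.n_conv_per_path != self.out_patch:
            raise ConfigError(
                f"receptive-field identity violated: {self.normal_rf} - "
                f"2*{self.n_conv_per_path} != {self.out_patch}")
        low_out = self.low_rf - 2 * self.n_conv_per_path
        if low_out * self.downsample_factor != self.out_patch:
            raise ConfigError(
                f"low-path identity violated: ({self.low_rf} - "
                f"2*{self.n_conv_per_path}) * {self.downsample_factor} != "
                f"{self.out_patch}")
        pooled = (self.low_src_patch + 2 - 3) // self.downsample_factor + 1
        if pooled != self.low_rf:
            raise ConfigError(
                f"pooling {self.low_src_patch} by {self.downsample_factor} "
                f"gives {pooled}, expected {self.low_rf}")


@dataclasses.dataclass
class UNet3DConfig:
    in_channels: int = 4
    n_classes: int = N_CLASSES
    depth: int = 4
    base_width: int = 32
    n_groups: int = 4
    dropout_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ConfigError("depth must be >= 2")

    @property
    def divisor(self) -> int:
        return 2 ** (self.depth - 1)

    def check_patch_side(self, side: int) -> None:
        if side % self.divisor != 0:
            raise ConfigError(
                f"patch side {side} not divisible by 2^(depth-1) = {self.divisor}")


# ---------------------------------------------------------------- blocks


class _ConvBNReLU:
    """Valid 3x3x3 conv + batch norm + ReLU (dual-path CNN building block)."""

    def __init__(self, cin, cout, rng, dtype):
        self.conv = nc.Conv3d(cin, cout, 3, padding=0, rng=rng, dtype=dtype)
        self.bn = nc.BatchNorm3d(cout, dtype=dtype)
        self.relu = nc.ReLU()
        self.layers = [self.conv, self.bn]

    def forward(self, x, train):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, g):
        return self.conv.backward(self.bn.backward(self.relu.backward(g)))


class _ConvGNReLU:
    """Same-padded 3x3x3 conv + group norm (+ optional ReLU)."""

    def __init__(self, cin, cout, n_groups, rng, dtype, relu=True):
        self.conv = nc.Conv3d(cin, cout, 3, padding="same", rng=rng, dtype=dtype)
        self.gn = nc.GroupNorm3d(cout, n_groups, dtype=dtype)
        self.relu = nc.ReLU() if relu else None
        self.layers = [self.conv, self.gn]

    def forward(self, x, train):
        y = self.gn.forward(self.conv.forward(x, train), train)
        return self.relu.forward(y, train) if self.relu else y

    def backward(self, g):
        if self.relu:
            g = self.relu.backward(g)
        return self.conv.backward(self.gn.backward(g))


class _ResEncBlock:
    """Residual encoder block: conv-GN-ReLU, conv-GN, identity add
    (zero-padded channels), ReLU, dropout."""

    def __init__(self, cin, cout, n_groups, dropout, rng, dtype):
        self.b1 = _ConvGNReLU(cin, cout, n_groups, rng, dtype, relu=True)
        self.b2 = _ConvGNReLU(cout, cout, n_groups, rng, dtype, relu=False)
        self.relu = nc.ReLU()
        self.drop = nc.Dropout(dropout, rng)
        self.cin, self.cout = cin, cout
        self.layers = self.b1.layers + self.b2.layers

    def forward(self, x, train):
        y = self.b2.forward(self.b1.forward(x, train), train)
        y = y + nc.match_channels(x, self.cout)
        return self.drop.forward(self.relu.forward(y, train), train)

    def backward(self, g):
        g = self.relu.backward(self.drop.backward(g))
        gx = self.b1.backward(self.b2.backward(g))
        return gx + nc.match_channels_adjoint(g, self.cin)


# ---------------------------------------------------------------- networks


class DeepMedicNet:
    """Dual-path multiscale patch CNN; predicts the central ``out_patch``^3
    voxels of the normal-resolution receptive field."""

    kind = "deepmedic"

    def __init__(self, cfg: DeepMedicConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.seed = seed
        w = cfg.conv_widths
        self.normal = [_ConvBNReLU(cfg.in_channels if i == 0 else w[i - 1], w[i], rng, dtype)
                       for i in range(cfg.n_conv_per_path)]
        self.low = [_ConvBNReLU(cfg.in_channels if i == 0 else w[i - 1], w[i], rng, dtype)
                    for i in range(cfg.n_conv_per_path)]
        self.head1 = nc.Conv3d(2 * w[-1], cfg.head_width, 1, rng=rng, dtype=dtype)
        self.head_bn = nc.BatchNorm3d(cfg.head_width, dtype=dtype)
        self.head_relu = nc.ReLU()
        self.head2 = nc.Conv3d(cfg.head_width, cfg.n_classes, 1, rng=rng, dtype=dtype)
        self._resize: dict[tuple, nc.LinearResize] = {}

    # residual links span layer pairs (3,4), (5,6), (7,8) in 1-based counting
    @staticmethod
    def _pair_start(i: int) -> bool:
        return i >= 2 and i % 2 == 0

    def _path_forward(self, blocks, x, train, residual):
        cache = []
        for i, blk in enumerate(blocks):
            skip = x if (residual and self._pair_start(i)) else None
            x = blk.forward(x, train)
            if residual and i >= 3 and i % 2 == 1:
                s = nc.match_channels(nc.crop_center(cache[-1], 2), x.shape[1])
                x = x + s
            cache.append(skip)
        return x, cache

    def _path_backward(self, blocks, g, cache, residual):
        pend = {}
        for i in reversed(range(len(blocks))):
            if residual and i >= 3 and i % 2 == 1:
                # skip entered at pair start i-1; undo channel match + crop
                cin = cache[i - 1].shape[1]
                gs = nc.match_channels_adjoint(g, cin)
                pend[i - 1] = np.pad(gs, ((0, 0), (0, 0), (2, 2), (2, 2), (2, 2)))
            g = blocks[i].backward(g)
            if i in pend:
                g = g + pend.pop(i)
        return g

    def _get_resize(self, key, mats):
        if key not in self._resize:
            self._resize[key] = nc.LinearResize(mats, dtype=self.dtype)
        return self._resize[key]

    def forward(self, x_normal: np.ndarray, x_low: np.ndarray,
                train: bool = False) -> np.ndarray:
        """``x_normal``: (n, C, 25^3); ``x_low``: (n, C, 19^3) already pooled
        or (n, C, 55^3) to be average-pooled by the downsample factor."""
        cfg = self.cfg
        x_normal = x_normal.astype(self.dtype, copy=False)
        x_low = x_low.astype(self.dtype, copy=False)
        if x_low.shape[2] == cfg.low_src_patch:
            pool = self._get_resize(("pool", x_low.shape[2:]),
                                    [nc.avgpool_matrix(L) for L in x_low.shape[2:]])
            x_low = pool.forward(x_low)
            self._pool = pool
        else:
            self._pool = None
            if x_low.shape[2] != cfg.low_rf:
                raise ConfigError(
                    f"low-path input side {x_low.shape[2]} is neither "
                    f"{cfg.low_rf} nor {cfg.low_src_patch}")
        yn, self._ncache = self._path_forward(self.normal, x_normal, train, residual=True)
        yl, self._lcache = self._path_forward(self.low, x_low, train, residual=False)
        up = self._get_resize(("up", yl.shape[2:]),
                              [nc.upsample_matrix(L, cfg.downsample_factor)
                               for L in yl.shape[2:]])
        self._up = up
        yl_up = up.forward(yl)
        self._split = yn.shape[1]
        y = np.concatenate([yn, yl_up], axis=1)
        y = self.head1.forward(y, train)
        y = self.head_bn.forward(y, train)
        y = self.head_relu.forward(y, train)
        return self.head2.forward(y, train)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head2.backward(dlogits)
        g = self.head_relu.backward(g)
        g = self.head_bn.backward(g)
        g = self.head1.backward(g)
        gn, gl = g[:, : self._split], g[:, self._split:]
        self._path_backward(self.normal, gn, self._ncache, residual=True)
        gl = self._up.backward(gl)
        gl = self._path_backward(self.low, gl, self._lcache, residual=False)
        if self._pool is not None:
            self._pool.backward(gl)

    def param_layers(self) -> list[nc.Layer]:
        out = []
        for blk in self.normal + self.low:
            out.extend(blk.layers)
        out.extend([self.head1, self.head_bn, self.head2])
        return out


class UNet3DNet:
    """Encoder-decoder CNN with residual encoder blocks, group norm and
    trilinear upsampling; shape-preserving."""

    kind = "unet"

    def __init__(self, cfg: UNet3DConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        self.seed = seed
        rng = np.random.default_rng(seed)
        widths = [cfg.base_width * 2**i for i in range(cfg.depth)]
        self.widths = widths
        self.enc = []
        cin = cfg.in_channels
        for i, w in enumerate(widths):
            self.enc.append(_ResEncBlock(cin, w, cfg.n_groups, cfg.dropout_rate,
                                         rng, dtype))
            cin = w
        self.pools = [nc.MaxPool3d2() for _ in range(cfg.depth - 1)]
        self.dec = []
        for i in range(cfg.depth - 2, -1, -1):
            win = widths[i + 1] + widths[i]  # upsampled + skip concat
            self.dec.append([
                _ConvGNReLU(win, widths[i], cfg.n_groups, rng, dtype),
                _ConvGNReLU(widths[i], widths[i], cfg.n_groups, rng, dtype),
            ])
        self.final = nc.Conv3d(widths[0], cfg.n_classes, 1, rng=rng, dtype=dtype)
        self._resize: dict[tuple, nc.LinearResize] = {}

    def _up(self, shape):
        key = ("up2", shape)
        if key not in self._resize:
            self._resize[key] = nc.LinearResize(
                [nc.upsample_matrix(L, 2) for L in shape], dtype=self.dtype)
        return self._resize[key]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cfg = self.cfg
        x = x.astype(self.dtype, copy=False)
        cfg.check_patch_side(x.shape[2])
        for s in x.shape[3:]:
            cfg.check_patch_side(s)
        skips = []
        for i, blk in enumerate(self.enc):
            x = blk.forward(x, train)
            if i < cfg.depth - 1:
                skips.append(x)
                x = self.pools[i].forward(x, train)
        self._ups = []
        self._splits = []
        for lvl, pair in enumerate(self.dec):
            up = self._up(x.shape[2:])
            self._ups.append(up)
            x = up.forward(x)
            skip = skips.pop()
            self._splits.append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
            for blk in pair:
                x = blk.forward(x, train)
        return self.final.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.final.backward(dlogits)
        skip_grads = []
        for lvl in range(len(self.dec) - 1, -1, -1):
            for blk in reversed(self.dec[lvl]):
                g = blk.backward(g)
            split = self._splits[lvl]
            skip_grads.append(g[:, split:])
            g = self._ups[lvl].backward(g[:, :split])
        # ascend back through the encoder (deepest first)
        for i in range(self.cfg.depth - 1, -1, -1):
            g = self.enc[i].backward(g)
            if i > 0:
                g = self.pools[i - 1].backward(g)
                g = g + skip_grads[i - 1]
        return None

    def param_layers(self) -> list[nc.Layer]:
        out = []
        for blk in self.enc:
            out.extend(blk.layers)
        for pair in self.dec:
            for blk in pair:
                out.extend(blk.layers)
        out.append(self.final)
        return out


def build_deepmedic(cfg: DeepMedicConfig, seed: int = 0, dtype=np.float32) -> DeepMedicNet:
    return DeepMedicNet(cfg, seed=seed, dtype=dtype)


def build_unet3d(cfg: UNet3DConfig, seed: int = 0, dtype=np.float32) -> UNet3DNet:
    return UNet3DNet(cfg, seed=seed, dtype=dtype)


def parameter_count(net) -> int:
    return sum(p.size for lay in net.param_layers() for p in lay.params.values())


def extract_patch_pair(volume: np.ndarray, center: tuple[int, int, int],
                       cfg: DeepMedicConfig
                       ) -> tuple[np.ndarray, np.ndarray, tuple[slice, ...]]:
    """Cut the centered (normal, low-resolution-source) patch pair.

    ``volume`` is a (C, X, Y, Z) stack.  Returns the 25^3 normal patch, the
    19^3 average-pooled low patch (pooled from the 55^3 neighbourhood with
    kernel 3, stride 3, pad 1) and the slices of the central 9^3 target
    window in volume coordinates.  Out-of-volume voxels are zero-padded.
    """

    def cut(side: int) -> np.ndarray:
        half = side // 2
        out = np.zeros((volume.shape[0], side, side, side), dtype=volume.dtype)
        src, dst = [], []
        for ax in range(3):
            lo = center[ax] - half
            hi = lo + side
            s_lo, s_hi = max(lo, 0), min(hi, volume.shape[1 + ax])
            src.append(slice(s_lo, s_hi))
            dst.append(slice(s_lo - lo, s_hi - lo))
        out[:, dst[0], dst[1], dst[2]] = volume[:, src[0], src[1], src[2]]
        return out

    normal = cut(cfg.normal_rf)
    low_src = cut(cfg.low_src_patch)
    pool = nc.LinearResize([nc.avgpool_matrix(cfg.low_src_patch)] * 3,
                           dtype=volume.dtype if volume.dtype.kind == "f" else np.float32)
    low = pool.forward(low_src[None].astype(pool.mats[0].dtype))[0]
    half_out = cfg.out_patch // 2
    tgt = tuple(slice(center[ax] - half_out, center[ax] - half_out + cfg.out_patch)
                for ax in range(3))
    return normal, low, tgt


# ------------------------------------------------------------- persistence


def save_model(net, path: str | Path) -> Path:
    """Serialize weights + config so inference is self-describing."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for i, lay in enumerate(net.param_layers()):
        for name, arr in lay.params.items():
            arrays[f"p{i}_{name}"] = arr
        if isinstance(lay, nc.BatchNorm3d):
            arrays[f"s{i}_running_mean"] = lay.running_mean
            arrays[f"s{i}_running_var"] = lay.running_var
    meta = {"kind": net.kind, "seed": net.seed,
            "config": dataclasses.asdict(net.cfg)}
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    with open(path, "wb") as f:
        header = json.dumps(meta).encode()
        f.write(len(header).to_bytes(8, "little"))
        f.write(header)
        f.write(buf.getvalue())
    return path


def load_model(path: str | Path):
    path = Path(path)
    with open(path, "rb") as f:
        n = int.from_bytes(f.read(8), "little")
        meta = json.loads(f.read(n).decode())
        data = np.load(io.BytesIO(f.read()))
    cfg_d = meta["config"]
    if meta["kind"] == "deepmedic":
        cfg_d["conv_widths"] = tuple(cfg_d["conv_widths"])
        net = DeepMedicNet(DeepMedicConfig(**cfg_d), seed=meta["seed"])
    elif meta["kind"] == "unet":
        net = UNet3DNet(UNet3DConfig(**cfg_d), seed=meta["seed"])
    else:
        raise ConfigError(f"unknown model kind {meta['kind']!r}")
    for i, lay in enumerate(net.param_layers()):
        for name in lay.params:
            lay.params[name] = data[f"p{i}_{name}"]
            lay.grads[name] = np.zeros_like(lay.params[name])
        if isinstance(lay, nc.BatchNorm3d):
            lay.running_mean = data[f"s{i}_running_mean"]
            lay.running_var = data[f"s{i}_running_var"]
    return net
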
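"""Fourier-domain residual CNN that corrects ill-posed TKD signals.

The model never sees the field map directly.  The field is first
inverted by TKD; the FFT of the TKD susceptibility supplies two input
channels (real, imaginary) which are concatenated with the dipole
kernel.  A stack of 3D convolutional blocks then outputs a corrected
two-channel k-space map, and the final susceptibility is

    c   = iFFT( network(D, X_TKD) )
    QSM = |c| * sign(Re c)

Training minimizes a weighted sum of (i) the mean squared error against
the label k-space — which drives the repair of the ill-posed cone — and
(ii) an L1 consistency term against the TKD input restricted to the
non-ill-posed region |D| >= thr, which anchors the signals TKD already
gets right.  The network therefore has little to learn: it edits the
conical null region and passes the rest through.

Architecture (all convs 3x3x3, stride 1, padding 1):
ConvBlock -> 8 x ResBlock(ConvBlock -> Dropout -> Conv, + skip)
-> ConvBlock -> ConvBlock -> Conv(-> 2 channels).

Two choices the architecture description leaves open are fixed here and
documented in the methods note: per-volume k-space is normalized by its
root-mean-square magnitude (inputs and labels identically), and the
convolution weights use an identity-preserving initialization — the
residual branches start at zero and the trunk starts as a pass-through
of the TKD channels (carried as +/- channel pairs so LeakyReLU is
lossless), so the untrained network already reproduces TKD and training
only has to learn the corrections.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nnops
from .analytic_recon import NonIllMask, TKDResult, nonill_mask, tkd_reconstruct
from .kspace_physics import (
    B0Vector,
    DipoleKernel,
    FieldMap,
    KSpaceVolume,
    SusceptibilityVolume,
    ValidationError,
    VoxelGrid,
    ifft_volume,
    fft_volume,
    make_dipole_kernel,
)

__all__ = [
    "NetworkConfig",
    "TrainingConfig",
    "NetInputStack",
    "NetworkState",
    "prepare_input",
    "build_network",
    "loss_mse",
    "loss_l1",
    "total_loss",
    "extract_patches",
    "stitch_patches",
    "lr_schedule",
    "train",
    "infer",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    ``feature_width`` 64 matches a full-scale run; 8–16 is the intended
    desk scale.  Kernel size / stride / padding are fixed at 3/1/1 and
    the LeakyReLU slope and dropout rate are part of the architecture.
    """

    feature_width: int = 64
    n_resblocks: int = 8
    dropout_rate: float = 0.2
    leaky_slope: float = 0.1
    thr: float = 0.2
    init_gain: float = 0.05

    def __post_init__(self):
        if self.n_resblocks < 1:
            raise ValidationError("need at least one ResBlock")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout rate must be in [0, 1)")
        if self.feature_width < 4:
            raise ValidationError("feature_width must be >= 4")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization hyper-parameters.

    Adam with initial learning rate ``lr0`` decayed to 90% every 25
    epochs; 64^3 Fourier-domain patches with 50% overlap; both loss
    weights default to 1.
    """

    lr0: float = 1e-4
    lr_decay: float = 0.9
    decay_every: int = 25
    patch_size: int = 64
    overlap: float = 0.5
    w_mse: float = 1.0
    w_l1: float = 1.0
    epochs: int = 50
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.overlap < 1.0):
            raise ValidationError("overlap must be in (0, 1)")
        if self.w_mse < 0 or self.w_l1 < 0:
            raise ValidationError("loss weights must be non-negative")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")


@dataclass
class NetInputStack:
    """Network input: [D, Re(FFT(TKD chi)), Im(FFT(TKD chi))] channels.

    The TKD channels are divided by ``scale`` (per-volume RMS k-space
    magnitude); multiplying by ``scale`` restores the raw TKD k-space.
    """

    channels: np.ndarray  # (3, D, H, W) float32
    scale: float
    grid: VoxelGrid
    kernel: DipoleKernel
    tkd: TKDResult


class KQSMNet:
    """The convolutional trunk; see the module docstring for topology."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        w, s = config.feature_width, config.leaky_slope
        self.head_conv = nnops.Conv3d(3, w)
        self.head = nnops.Sequential([self.head_conv, nnops.LeakyReLU(s)])
        self.resblocks = [
            nnops.ResBlock(w, config.dropout_rate, s, rng=rng)
            for _ in range(config.n_resblocks)
        ]
        self.tail_conv1 = nnops.Conv3d(w, w)
        self.tail_conv2 = nnops.Conv3d(w, w)
        self.out_conv = nnops.Conv3d(w, 2)
        self.tail = nnops.Sequential([
            self.tail_conv1, nnops.LeakyReLU(s),
            self.tail_conv2, nnops.LeakyReLU(s),
            self.out_conv,
        ])
        self.net = nnops.Sequential([self.head, *self.resblocks, self.tail])
        self._init_weights(rng)

    def _init_weights(self, rng: np.random.Generator) -> None:
        """Identity-preserving seeded initialization.

        The TKD real/imag channels are routed through the trunk as
        +/- pairs (LeakyReLU maps a pair (x, -x) to a pair whose
        difference is (1 + slope^m) x after m activations, so the signal
        survives undistorted); every residual branch's closing conv
        starts at zero, so each ResBlock starts as an exact skip.  Small
        seeded noise on all trunk kernels breaks symmetry.
        """
        g = self.config.init_gain
        s = self.config.leaky_slope
        self.head_conv.init_random(rng, gain=g)
        # input channel order: 0 = D, 1 = Re, 2 = Im
        pairs = [(1, 0, +1.0), (1, 1, -1.0), (2, 2, +1.0), (2, 3, -1.0)]
        if self.config.feature_width >= 6:
            pairs += [(0, 4, +1.0), (0, 5, -1.0)]
        for cin, cout, v in pairs:
            self.head_conv.set_center_tap(cin, cout, v)
        for rb in self.resblocks:
            first, last = rb.branch.layers[0], rb.branch.layers[3]
            first.init_random(rng, gain=g)
            last.w[:] = 0.0  # exact skip at init
        n_carry = 6 if self.config.feature_width >= 6 else 4
        for conv in (self.tail_conv1, self.tail_conv2):
            conv.init_random(rng, gain=g)
            for ch in range(n_carry):
                conv.set_center_tap(ch, ch, 1.0)
        self.out_conv.w[:] = 0.0
        readout = 1.0 / (1.0 + s**3)  # three activations along the trunk
        for cin, cout, v in [(0, 0, +readout), (1, 0, -readout),
                             (2, 1, +readout), (3, 1, -readout)]:
            self.out_conv.set_center_tap(cin, cout, v)

    # thin pass-throughs
    def params(self):
        return self.net.params()

    def grads(self):
        return self.net.grads()

    def set_train(self, mode: bool) -> None:
        self.net.set_train(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[0] != 3:
            raise ValidationError(f"expected (3, D, H, W) input, got {x.shape}")
        return self.net.forward(x.astype(np.float32, copy=False))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy.astype(np.float32, copy=False))

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))


@dataclass
class NetworkState:
    """Trained (or freshly built) network plus its provenance."""

    net: KQSMNet
    config: NetworkConfig
    loss_log: List[float] = dc_field(default_factory=list)
    seed: int = 0

    @property
    def n_params(self) -> int:
        return self.net.n_params


def build_network(config: NetworkConfig, seed: int = 0) -> NetworkState:
    """Construct the network with seeded, identity-preserving weights."""
    return NetworkState(net=KQSMNet(config, seed=seed), config=config, seed=seed)


def prepare_input(
    field: FieldMap,
    b0: Optional[B0Vector] = None,
    thr: float = 0.2,
) -> NetInputStack:
    """TKD-invert a field map and assemble the 3-channel k-space input.

    ``b0`` defaults to the orientation carried by the field map.  The
    normalization scale is the RMS magnitude of the TKD k-space (1.0
    for an identically zero field).
    """
    if b0 is None:
        b0 = field.b0
    kernel = make_dipole_kernel(field.grid, b0)
    tkd = tkd_reconstruct(field, kernel, thr)
    re, im = tkd.kspace.real_part, tkd.kspace.imag_part
    scale = float(np.sqrt(np.mean(re * re + im * im)))
    if scale == 0.0:
        scale = 1.0
    channels = np.stack([
        kernel.values, re / scale, im / scale
    ]).astype(np.float32)
    return NetInputStack(channels=channels, scale=scale, grid=field.grid,
                         kernel=kernel, tkd=tkd)


# ---------------------------------------------------------------------------
# losses (public API on KSpaceVolume; array kernels shared with training)


def _as_2ch(k) -> np.ndarray:
    if isinstance(k, KSpaceVolume):
        return np.stack([k.real_part, k.imag_part])
    k = np.asarray(k)
    if k.ndim != 4 or k.shape[0] != 2:
        raise ValidationError("expected a KSpaceVolume or (2, D, H, W) array")
    return k


def _mse_and_grad(pred: np.ndarray, label: np.ndarray):
    if pred.shape != label.shape:
        raise ValidationError("MSE loss: shape mismatch")
    diff = pred - label
    n = pred[0].size  # number of k-points
    return float(np.sum(diff * diff) / n), (2.0 / n) * diff


def _l1_and_grad(pred: np.ndarray, tkd: np.ndarray, mask: np.ndarray):
    if pred.shape != tkd.shape:
        raise ValidationError("L1 loss: shape mismatch")
    nm = int(mask.sum())
    if nm == 0:
        warnings.warn("consistency mask is empty; L1 loss is 0", stacklevel=3)
        return 0.0, np.zeros_like(pred)
    diff = (pred - tkd) * mask  # broadcast over the 2 channels
    mod = np.sqrt(diff[0] ** 2 + diff[1] ** 2)
    loss = float(mod.sum() / nm)
    safe = np.where(mod > 0, mod, 1.0)
    grad = diff / safe / nm
    grad[:, mod == 0] = 0.0
    return loss, grad


def loss_mse(pred, label) -> float:
    """Mean over k-points of the squared complex modulus of the error."""
    return _mse_and_grad(_as_2ch(pred), _as_2ch(label))[0]


def loss_l1(pred, tkd, mask: NonIllMask) -> float:
    """Mean complex-modulus deviation from TKD over the non-ill-posed
    region; k-points outside the mask contribute nothing."""
    m = mask.values if isinstance(mask, NonIllMask) else np.asarray(mask, bool)
    return _l1_and_grad(_as_2ch(pred), _as_2ch(tkd), m)[0]


def total_loss(pred, label, tkd, mask, w_mse: float = 1.0, w_l1: float = 1.0) -> float:
    """Weighted sum  w_mse * MSE(pred, label) + w_l1 * L1(pred, TKD | mask)."""
    if w_mse < 0 or w_l1 < 0:
        raise ValidationError("loss weights must be non-negative")
    return w_mse * loss_mse(pred, label) + w_l1 * loss_l1(pred, tkd, mask)


# ---------------------------------------------------------------------------
# patching


def _axis_starts(dim: int, patch: int, stride: int) -> List[int]:
    starts = list(range(0, dim - patch + 1, stride))
    if starts[-1] + patch < dim:  # clamp a final patch to the boundary
        starts.append(dim - patch)
    return starts


def extract_patches(
    volume, patch_size: int, overlap: float = 0.5
) -> List[Tuple[Tuple[int, int, int], np.ndarray]]:
    """Cube patches with the stated overlap, tiled from the origin and
    clamped to the boundary; every voxel is covered at least once.

    ``volume`` may be a ``KSpaceVolume`` (patched as 2-channel arrays)
    or any array whose last three axes are spatial.  Returns
    ``(offset, patch)`` pairs; offsets index the spatial axes.
    """
    arr = np.stack([volume.real_part, volume.imag_part]) if isinstance(
        volume, KSpaceVolume) else np.asarray(volume)
    spatial = arr.shape[-3:]
    if any(patch_size > d for d in spatial):
        raise ValidationError(
            f"patch size {patch_size} exceeds volume extent {spatial}")
    if not (0.0 < overlap < 1.0):
        raise ValidationError("overlap must be in (0, 1)")
    stride = max(1, int(round(patch_size * (1.0 - overlap))))
    out = []
    for i in _axis_starts(spatial[0], patch_size, stride):
        for j in _axis_starts(spatial[1], patch_size, stride):
            for k in _axis_starts(spatial[2], patch_size, stride):
                patch = arr[..., i:i + patch_size, j:j + patch_size,
                            k:k + patch_size]
                out.append(((i, j, k), patch.copy()))
    return out


def stitch_patches(
    patches: Sequence[Tuple[Tuple[int, int, int], np.ndarray]],
    spatial_shape: Tuple[int, int, int],
) -> np.ndarray:
    """Overlap-average patches back into a full volume (uniform weights)."""
    first = patches[0][1]
    out = np.zeros(first.shape[:-3] + tuple(spatial_shape), dtype=np.float64)
    count = np.zeros(spatial_shape, dtype=np.float64)
    for (i, j, k), p in patches:
        d, h, w = p.shape[-3:]
        out[..., i:i + d, j:j + h, k:k + w] += p
        count[i:i + d, j:j + h, k:k + w] += 1.0
    return out / count


# ---------------------------------------------------------------------------
# training


def lr_schedule(epoch: int, cfg: TrainingConfig) -> float:
    """Step decay: lr0 * lr_decay ** (epoch // decay_every)."""
    return cfg.lr0 * cfg.lr_decay ** (epoch // cfg.decay_every)


def _prepare_example(item, thr: float, patch_size: int, overlap: float):
    """One training volume -> list of aligned (input, label, tkd, mask)
    patch tuples in normalized k-space units."""
    if len(item) == 3:
        field, b0, label = item
    else:
        field, label = item
        b0 = None
    stack = prepare_input(field, b0, thr)
    kspec = fft_volume(label.values, label.grid)
    label2 = np.stack([kspec.real_part, kspec.imag_part]) / stack.scale
    mask = nonill_mask(stack.kernel, thr).values
    tkd2 = stack.channels[1:3].astype(np.float64)
    spatial = stack.grid.shape
    if all(d <= patch_size for d in spatial):
        return [(stack.channels, label2.astype(np.float32),
                 tkd2.astype(np.float32), mask)]
    joined = np.concatenate([
        stack.channels.astype(np.float64), label2, tkd2,
        mask[None].astype(np.float64),
    ])
    out = []
    for _, p in extract_patches(joined, patch_size, overlap):
        out.append((p[0:3].astype(np.float32), p[3:5].astype(np.float32),
                    p[5:7].astype(np.float32), p[7] > 0.5))
    return out


def train(
    dataset: Sequence,
    net_cfg: NetworkConfig,
    train_cfg: TrainingConfig,
    state: Optional[NetworkState] = None,
) -> NetworkState:
    """Optimize the network on (field map, [b0,] label chi) examples.

    Labels are converted to k-space with the same per-volume RMS
    normalization as the inputs.  One Adam step per patch per epoch,
    patches visited in a seeded shuffled order; the learning rate
    follows the step-decay schedule.  Returns the state with a
    per-epoch mean total-loss log.
    """
    if len(dataset) == 0:
        raise ValidationError("training set is empty")
    examples = []
    for item in dataset:
        examples.extend(_prepare_example(
            item, net_cfg.thr, train_cfg.patch_size, train_cfg.overlap))
    if state is None:
        state = build_network(net_cfg, seed=train_cfg.seed)
    net = state.net
    net.set_train(True)
    opt = nnops.Adam(net.params(), lr=train_cfg.lr0)
    rng = np.random.default_rng(train_cfg.seed + 1)
    for epoch in range(train_cfg.epochs):
        opt.lr = lr_schedule(epoch, train_cfg)
        order = rng.permutation(len(examples))
        epoch_loss = 0.0
        for idx in order:
            x, label2, tkd2, mask = examples[idx]
            pred = net.forward(x)
            lm, gm = _mse_and_grad(pred.astype(np.float64), label2)
            ll, gl = _l1_and_grad(pred.astype(np.float64), tkd2, mask)
            loss = train_cfg.w_mse * lm + train_cfg.w_l1 * ll
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (mse={lm}, l1={ll}); "
                    "try a lower learning rate")
            grad = train_cfg.w_mse * gm + train_cfg.w_l1 * gl
            net.backward(grad)
            opt.step(net.grads())
            epoch_loss += loss
        state.loss_log.append(epoch_loss / len(examples))
    net.set_train(False)
    return state


def infer(
    field: FieldMap,
    b0: Optional[B0Vector] = None,
    state: Optional[NetworkState] = None,
    patch_size: Optional[int] = None,
) -> SusceptibilityVolume:
    """Apply the trained network to a field map.

    Default is a fully-convolutional whole-volume pass (the network is
    shape-agnostic); pass ``patch_size`` to stitch overlapping patches
    instead when the volume is too large for one pass.  The corrected
    k-space is un-normalized, inverse-transformed to a complex volume
    ``c``, and the map is ``|c| * sign(Re c)`` (zero where Re c = 0).
    """
    if state is None:
        raise ValidationError("infer requires a trained NetworkState")
    stack = prepare_input(field, b0, state.config.thr)
    net = state.net
    net.set_train(False)
    if patch_size is None or all(d <= patch_size for d in stack.grid.shape):
        out = net.forward(stack.channels)
    else:
        patches = extract_patches(stack.channels, patch_size)
        preds = [(off, net.forward(p)) for off, p in patches]
        out = stitch_patches(preds, stack.grid.shape)
    spec = (out[0].astype(np.float64) + 1j * out[1].astype(np.float64)) * stack.scale
    c = ifft_volume(KSpaceVolume.from_complex(spec, stack.grid))
    qsm = np.abs(c) * np.sign(c.real)
    return SusceptibilityVolume(values=qsm, grid=stack.grid)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(state: NetworkState, path) -> None:
    """Versioned container: config + parameters + loss log (npz)."""
    meta = {
        "format": "kqsm-checkpoint-1",
        "config": state.config.__dict__,
        "seed": state.seed,
    }
    arrays = {f"param_{i}": p for i, p in enumerate(state.net.params())}
    np.savez(path, meta=json.dumps(meta),
             loss_log=np.asarray(state.loss_log), **arrays)


def load_checkpoint(path) -> NetworkState:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta.get("format") != "kqsm-checkpoint-1":
            raise ValidationError("not a kqsm checkpoint")
        config = NetworkConfig(**meta["config"])
        state = build_network(config, seed=meta.get("seed", 0))
        for i, p in enumerate(state.net.params()):
            p[:] = data[f"param_{i}"]
        state.loss_log = [float(x) for x in data["loss_log"]]
    return state
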
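"""Modified 3D U-net for kidney-parenchyma segmentation.

The network follows a residual encoder–decoder design:

* **Contraction path** — per level, a pre-activation residual block of
  two 3×3×3 convolutions (leaky-ReLU before each convolution), followed
  by a 2×2×2 stride-2 convolution for downsampling.  When a block
  changes the channel count its shortcut is a 1×1×1 projection, so the
  downsampling output is element-wise summed with the block's 3×3×3
  convolution output — features are forwarded between stages both
  additively and through the main path.  3D *spatial* dropout (whole
  feature maps) follows each block; with batch size 1 it replaces batch
  normalization.
* **Expansion path** — per level, leaky ReLU, 3×3×3 convolution, 1×1×1
  convolution and a 2×2×2 transposed convolution for upsampling, with
  copy-and-concatenate skip connections from the matching contraction
  level.  The outputs of the last three expansion-path 3×3×3
  convolutions are projected to one channel, upsampled to full
  resolution and element-wise summed immediately before the final
  sigmoid.

Training minimizes the soft-Dice loss with Adam (β1=0.9, β2=0.999,
ε=0) at an initial learning rate of 5e-4, halved when the loss has not
improved for a patience window (default 10 epochs).  The full-scale
schedule is 80 epochs of 272 iterations at batch size 1.

The model/results split mirrors statsmodels: :class:`ParenchymaSegmenter`
holds the data and configuration, ``fit()`` returns a
:class:`TrainedSegmenter` carrying the learned weights, the per-epoch
training log and prediction methods.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from .grids import LabeledMask, Unit, VolumeGrid, crop_to_window, resample

log = logging.getLogger(__name__)

CHECKPOINT_SCHEMA = "renoquant.segnet/1"


@dataclass
class SegNetConfig:
    """Architecture hyperparameters.

    ``levels`` counts resolution stages per path (5 in the full-scale
    configuration); ``base_channels`` is the width at full resolution,
    doubling per level.  The three ``use_*`` flags toggle the residual
    shortcuts, the pre-sigmoid multi-scale sum and the concatenation
    skips (the ablation arms).
    """

    levels: int = 5
    base_channels: int = 32
    leaky_slope: float = 0.01
    spatial_dropout_rate: float = 0.3
    use_residual_blocks: bool = True
    use_elementwise_sum: bool = True
    use_skip_connections: bool = True
    dice_eps: float = 1.0
    # CT soft-tissue windowing: (clip(HU, *norm_clip) - norm_center) / norm_scale
    norm_center: float = 35.0
    norm_scale: float = 30.0
    norm_clip: tuple[float, float] = (-30.0, 100.0)

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("at least two resolution levels are required")
        if not 0.0 <= self.spatial_dropout_rate < 1.0:
            raise ValueError("spatial_dropout_rate must be in [0, 1)")

    @classmethod
    def test_scale(cls, **overrides) -> "SegNetConfig":
        # small net for CPU runs; lighter dropout — 0.3 over-regularizes a
        # ~100k-parameter net trained on a tiny cohort
        kw = dict(levels=3, base_channels=8, spatial_dropout_rate=0.1)
        kw.update(overrides)
        return cls(**kw)

    def channels(self, level: int) -> int:
        return self.base_channels * 2**level

    def validate_input_shape(self, shape) -> None:
        div = 2 ** (self.levels - 1)
        for axis, n in enumerate(shape):
            if n % div:
                raise ValueError(
                    f"input axis {axis} (size {n}) not divisible by 2^(levels-1)={div}"
                )


@dataclass
class TrainConfig:
    """Optimization schedule (defaults are the full-scale recipe)."""

    learning_rate: float = 5e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 0.0
    epochs: int = 80
    iterations_per_epoch: int = 272
    plateau_patience_epochs: int = 10
    lr_halving_factor: float = 0.5
    plateau_rel_improvement: float = 1e-4
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "lr_halving_factor"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.plateau_patience_epochs < 1:
            raise ValueError("patience must be >= 1")

    @classmethod
    def test_scale(cls, **overrides) -> "TrainConfig":
        kw = dict(epochs=16, iterations_per_epoch=70)
        kw.update(overrides)
        return cls(**kw)


class PlateauScheduler:
    """Halve the learning rate when the loss stops improving.

    Improvement means a relative decrease of at least
    ``rel_improvement`` versus the best loss seen so far; otherwise a
    patience counter runs and the rate is multiplied by ``factor`` each
    time the counter reaches ``patience``.
    """

    def __init__(self, lr: float, patience: int, factor: float = 0.5, rel_improvement=1e-4):
        self.lr = lr
        self.patience = patience
        self.factor = factor
        self.rel_improvement = rel_improvement
        self.best = np.inf
        self.stale = 0

    def update(self, loss: float) -> float:
        if loss < self.best * (1.0 - self.rel_improvement) or not np.isfinite(self.best):
            self.best = loss
            self.stale = 0
        else:
            self.stale += 1
            if self.stale >= self.patience:
                self.lr *= self.factor
                self.stale = 0
        return self.lr


# ---------------------------------------------------------------------------
# network


class UNet3D:
    """The network graph: parameter store plus a forward pass."""

    def __init__(self, cfg: SegNetConfig, seed: int = 0):
        self.cfg = cfg
        self.params: dict[str, nn.Parameter] = {}
        self._rng = np.random.default_rng(seed)
        self._build()

    # -- parameter helpers ------------------------------------------------
    def _conv_param(self, name, cout, cin, k):
        fan_in = cin * k**3
        gain = np.sqrt(2.0 / (1.0 + self.cfg.leaky_slope**2))
        std = gain / np.sqrt(fan_in)
        w = nn.Parameter(
            self._rng.normal(0.0, std, size=(cout, cin, k, k, k)).astype(np.float32),
            name=f"{name}.w",
        )
        b = nn.Parameter(np.zeros(cout, dtype=np.float32), name=f"{name}.b")
        self.params[f"{name}.w"] = w
        self.params[f"{name}.b"] = b
        return w, b

    def _deconv_param(self, name, cin, cout):
        std = np.sqrt(2.0) / np.sqrt(cin * 8)
        w = nn.Parameter(
            self._rng.normal(0.0, std, size=(cin, cout, 2, 2, 2)).astype(np.float32),
            name=f"{name}.w",
        )
        b = nn.Parameter(np.zeros(cout, dtype=np.float32), name=f"{name}.b")
        self.params[f"{name}.w"] = w
        self.params[f"{name}.b"] = b
        return w, b

    def _build(self) -> None:
        cfg = self.cfg
        L = cfg.levels
        self._conv_param("stem", cfg.channels(0), 1, 3)
        ch_in = cfg.channels(0)
        for l in range(L):
            c = cfg.channels(l)
            self._conv_param(f"enc{l}.conv1", c, ch_in, 3)
            self._conv_param(f"enc{l}.conv2", c, c, 3)
            if cfg.use_residual_blocks and ch_in != c:
                self._conv_param(f"enc{l}.proj", c, ch_in, 1)
            if l < L - 1:
                self._conv_param(f"down{l}", c, c, 2)
            ch_in = c
        # expansion: from level L-1 back to 0
        ch = cfg.channels(L - 1)
        for l in range(L - 2, -1, -1):
            cl1 = cfg.channels(l + 1)
            self._conv_param(f"dec{l}.conv3", cl1, ch, 3)
            self._conv_param(f"dec{l}.conv1", cl1, cl1, 1)
            self._deconv_param(f"dec{l}.up", cl1, cfg.channels(l))
            ch = cfg.channels(l) * (2 if cfg.use_skip_connections else 1)
        self._conv_param("head.conv3", cfg.channels(0), ch, 3)
        if cfg.use_elementwise_sum:
            for i in range(min(3, L)):
                cin = cfg.channels(0) if i == 0 else cfg.channels(i)
                self._conv_param(f"out.proj{i}", 1, cin, 1)
        else:
            self._conv_param("out.proj0", 1, cfg.channels(0), 1)
        # start the sigmoid near the background prior (foreground is rare)
        for name, p in self.params.items():
            if name.startswith("out.proj") and name.endswith(".b"):
                p.value[:] = -1.0

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params.values()))

    def _c(self, name, x, stride=1, pad="same"):
        return nn.conv3d(x, self.params[f"{name}.w"], self.params[f"{name}.b"], stride, pad)

    def forward(self, x_np: np.ndarray, train: bool = False, rng=None) -> nn.Tensor:
        """Probability map for a normalized input of shape (D, H, W)."""
        cfg = self.cfg
        cfg.validate_input_shape(x_np.shape)
        if rng is None:
            rng = self._rng
        lrelu = lambda t: nn.leaky_relu(t, cfg.leaky_slope)
        L = cfg.levels

        x = self._c("stem", nn.Tensor(x_np[None].astype(np.float32)))
        skips = []
        for l in range(L):
            h = self._c(f"enc{l}.conv1", lrelu(x))
            h = self._c(f"enc{l}.conv2", lrelu(h))
            if cfg.use_residual_blocks:
                short = self._c(f"enc{l}.proj", x, pad=0) if f"enc{l}.proj.w" in self.params else x
                h = nn.add(h, short)
            h = nn.spatial_dropout(h, cfg.spatial_dropout_rate, rng, train)
            skips.append(h)
            if l < L - 1:
                x = self._c(f"down{l}", h, stride=2, pad=0)

        x = skips[-1]
        deep_convs: list[tuple[int, nn.Tensor]] = []  # (level, conv3 output)
        for l in range(L - 2, -1, -1):
            a = self._c(f"dec{l}.conv3", lrelu(x))
            deep_convs.append((l + 1, a))
            h = self._c(f"dec{l}.conv1", a, pad=0)
            u = nn.conv_transpose3d_2x(
                h, self.params[f"dec{l}.up.w"], self.params[f"dec{l}.up.b"]
            )
            x = nn.concat([u, skips[l]]) if cfg.use_skip_connections else u

        a0 = self._c("head.conv3", lrelu(x))
        deep_convs.append((0, a0))

        if cfg.use_elementwise_sum:
            terms = []
            for i, (lvl, a) in enumerate(reversed(deep_convs[-3:])):
                t = self._c(f"out.proj{i}", a, pad=0)
                for _ in range(lvl):
                    t = nn.upsample2(t)
                terms.append(t)
            logits = nn.add(*terms)
        else:
            logits = self._c("out.proj0", a0, pad=0)
        return nn.sigmoid(logits)


def build_network(cfg: SegNetConfig, seed: int = 0) -> UNet3D:
    """Instantiate an untrained segmenter for the given architecture."""
    return UNet3D(cfg, seed=seed)


def soft_dice_loss(pred, target, eps: float = 1.0) -> float:
    """Soft Dice loss on plain arrays (see ``renoquant.nn`` for the
    differentiable version used in training)."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    return 1.0 - (2.0 * (pred * target).sum() + eps) / (pred.sum() + target.sum() + eps)


def normalize_ct(values: np.ndarray, cfg: SegNetConfig) -> np.ndarray:
    lo, hi = cfg.norm_clip
    return (np.clip(np.asarray(values, dtype=np.float32), lo, hi) - cfg.norm_center) / cfg.norm_scale


# ---------------------------------------------------------------------------
# data plumbing


def split_train_validation(ids, train, seed: int = 0):
    """Random, disjoint, exhaustive train/validation split.

    ``train`` is either a fraction in (0, 1) or an absolute count.
    """
    ids = list(ids)
    n = len(ids)
    n_train = int(round(train * n)) if isinstance(train, float) and 0 < train < 1 else int(train)
    if not 0 <= n_train <= n:
        raise ValueError(f"cannot take {n_train} training ids from {n}")
    perm = np.random.default_rng(seed).permutation(n)
    train_ids = [ids[i] for i in sorted(perm[:n_train])]
    val_ids = [ids[i] for i in sorted(perm[n_train:])]
    return train_ids, val_ids


def windows_from_phantom(truth, window_shape, common_spacing_mm=None):
    """CT window + binary target window for one phantom.

    Resamples CT and truth mask to the common grid (defaults to the CT's
    own grid) and crops the central training window.
    """
    ct = truth.ct
    mask = truth.truth_mask.grid
    if common_spacing_mm is not None and not np.allclose(ct.spacing_mm, common_spacing_mm):
        sp = np.asarray(common_spacing_mm, dtype=float)
        shape = tuple(
            int(round(ct.shape[a] * ct.spacing_mm[a] / sp[a])) for a in range(3)
        )
        ct = resample(ct, sp, shape)
        mask = resample(mask, sp, shape, mode="mask")
    ct_w = crop_to_window(ct, window_shape)
    mask_w = crop_to_window(mask, window_shape)
    return ct_w, mask_w


# ---------------------------------------------------------------------------
# model / results


class ParenchymaSegmenter:
    """Segmentation model bound to a training cohort.

    Parameters
    ----------
    pairs : sequence of (VolumeGrid, VolumeGrid)
        CT windows and matching binary target windows (same shape).
    net_config, train_config : configuration dataclasses.
    """

    def __init__(self, pairs, net_config: SegNetConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.pairs = list(pairs)
        if not self.pairs:
            raise ValueError("training cohort is empty")
        self.net_config = net_config or SegNetConfig()
        self.train_config = train_config or TrainConfig()
        shape = self.pairs[0][0].shape
        self.net_config.validate_input_shape(shape)
        for ct_w, m_w in self.pairs:
            if ct_w.shape != shape or m_w.shape != shape:
                raise ValueError("all training windows must share one shape")

    @classmethod
    def from_cohort(cls, truths, window_shape, net_config=None, train_config=None,
                    common_spacing_mm=None):
        pairs = [windows_from_phantom(t, window_shape, common_spacing_mm) for t in truths]
        return cls(pairs, net_config, train_config)

    def fit(self, progress: bool = False) -> "TrainedSegmenter":
        return train(build_network(self.net_config, seed=self.train_config.seed),
                     self.pairs, self.train_config, progress=progress)


def train(net: UNet3D, pairs, tcfg: TrainConfig, progress: bool = False) -> "TrainedSegmenter":
    """Run the training schedule and return the fitted results object.

    One iteration draws one training pair at random (batch size 1),
    computes the soft-Dice loss and takes an Adam step; the plateau
    scheduler watches the mean per-epoch training loss.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("training cohort is empty")
    data = []
    for ct_w, m_w in pairs:
        ct_np = ct_w.values if isinstance(ct_w, VolumeGrid) else np.asarray(ct_w)
        m_np = m_w.values if isinstance(m_w, VolumeGrid) else np.asarray(m_w)
        data.append(
            (normalize_ct(ct_np, net.cfg), np.asarray(m_np, dtype=np.float32)[None])
        )

    rng = np.random.default_rng([tcfg.seed, 1])
    opt = nn.Adam(net.params.values(), lr=tcfg.learning_rate, beta1=tcfg.adam_beta1,
                  beta2=tcfg.adam_beta2, eps=tcfg.adam_epsilon)
    sched = PlateauScheduler(tcfg.learning_rate, tcfg.plateau_patience_epochs,
                             tcfg.lr_halving_factor, tcfg.plateau_rel_improvement)
    records = []
    for epoch in range(tcfg.epochs):
        losses = []
        for _ in range(tcfg.iterations_per_epoch):
            x, t = data[rng.integers(len(data))]
            opt.zero_grad()
            pred = net.forward(x, train=True, rng=rng)
            loss = nn.soft_dice_loss(pred, t, eps=net.cfg.dice_eps)
            lv = float(loss.value)
            if not np.isfinite(lv):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            losses.append(lv)
        mean_loss = float(np.mean(losses))
        opt.lr = sched.update(mean_loss)
        records.append({"epoch": epoch, "loss": mean_loss, "lr": opt.lr})
        if progress:
            log.info("epoch %d  loss %.4f  lr %.2e", epoch, mean_loss, opt.lr)
    return TrainedSegmenter(net.cfg, tcfg, net, pd.DataFrame(records))


class TrainedSegmenter:
    """Fit results: learned weights, training log, prediction methods."""

    def __init__(self, config: SegNetConfig, train_config: TrainConfig,
                 net: UNet3D, training_log: pd.DataFrame):
        self.config = config
        self.train_config = train_config
        self.net = net
        self.training_log = training_log

    # -- prediction -------------------------------------------------------
    def predict_proba(self, ct_window: VolumeGrid) -> VolumeGrid:
        x = normalize_ct(np.asarray(ct_window.values), self.config)
        out = self.net.forward(x, train=False)
        return ct_window.with_values(out.value[0], unit=Unit.PROBABILITY)

    def predict_mask(self, ct_window: VolumeGrid, threshold: float = 0.5) -> LabeledMask:
        prob = self.predict_proba(ct_window)
        return postprocess_probability(prob, threshold)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "schema": CHECKPOINT_SCHEMA,
            "config": asdict(self.config),
            "train_config": asdict(self.train_config),
        }
        buf = io.StringIO()
        self.training_log.to_csv(buf, index=False)
        arrays = {k.replace(".", "__"): p.value for k, p in self.net.params.items()}
        np.savez_compressed(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            __log__=np.frombuffer(buf.getvalue().encode(), dtype=np.uint8),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "TrainedSegmenter":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            if meta.get("schema") != CHECKPOINT_SCHEMA:
                raise ValueError(f"unknown checkpoint schema {meta.get('schema')!r}")
            logdf = pd.read_csv(io.StringIO(bytes(z["__log__"]).decode()))
            cfg_d = meta["config"]
            cfg_d["norm_clip"] = tuple(cfg_d["norm_clip"])
            cfg = SegNetConfig(**cfg_d)
            tcfg = TrainConfig(**meta["train_config"])
            net = build_network(cfg, seed=tcfg.seed)
            for k, p in net.params.items():
                p.value = z[k.replace(".", "__")].astype(np.float32)
        return cls(cfg, tcfg, net, logdf)

    def summary(self) -> str:
        cfg, tl = self.config, self.training_log
        lines = [
            "Kidney parenchyma segmenter (modified 3D U-net)",
            "=" * 48,
            f"levels: {cfg.levels}   base channels: {cfg.base_channels}"
            f"   parameters: {self.net.n_parameters:,}",
            f"residual blocks: {cfg.use_residual_blocks}   multi-scale sum: "
            f"{cfg.use_elementwise_sum}   skips: {cfg.use_skip_connections}",
            f"spatial dropout: {cfg.spatial_dropout_rate}",
            f"epochs trained: {len(tl)}   final loss: "
            f"{tl['loss'].iloc[-1]:.4f}" if len(tl) else "untrained",
            f"final learning rate: {tl['lr'].iloc[-1]:.2e}" if len(tl) else "",
        ]
        return "\n".join(str(x) for x in lines if x)


def postprocess_probability(prob: VolumeGrid, threshold: float = 0.5) -> LabeledMask:
    """Threshold, keep the two largest components, assign laterality.

    An all-background prediction returns an empty mask with a warning
    (a single- or zero-kidney output is a valid, if suspicious, result).
    """
    binary = np.asarray(prob.values) >= threshold
    lab, n = ndimage.label(binary)
    if n == 0:
        warnings.warn("prediction contains no foreground; returning empty mask")
    elif n > 2:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        keep = np.argsort(sizes)[-2:] + 1
        binary = np.isin(lab, keep)
    out_grid = prob.with_values(binary.astype(np.uint8), unit=Unit.BINARY)
    out_grid.meta.update(prob.meta)
    return LabeledMask.from_binary(out_grid)
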
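"""Multilevel encoder/decoder displacement network and training loops.

The network consumes a coarse-to-fine resolution pyramid of the
concatenated source/target pair: each encoder depth receives the
resampled pair at the matching resolution, and each decoder depth emits a
displacement field for that resolution, finest last. Building blocks are
3x3x3 convolutions with group normalization and leaky ReLU activations;
decoder upsampling is fixed trilinear (no transposed convolutions), and
the per-level output heads are zero-initialized so the untrained network
predicts the identity deformation.

Three training modes are supported:

* ``unsupervised`` — per-level NCC + diffusive regularization, summed
  over pyramid levels;
* ``volume_penalty`` — additionally drives the warped tumor-mask volume
  toward zero at every level (masks are needed for training only, never
  at inference);
* ``symmetric`` — forwards both pair orderings and adds the inverse
  consistency of the composed forward/backward fields at every level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .objectives import (ObjectiveConfig, semi_supervised_objective,
                         symmetric_objective, unsupervised_objective,
                         volume_penalty)
from .preprocessing import (NONRIGID_PYRAMID_MM, build_pyramid,
                            normalize_intensity)
from .transforms import apply_affine
from .volumes_io import (AffineTransform, DisplacementField, Image3D,
                         LandmarkSet, SegmentationMask)

__all__ = ["NetworkConfig", "TrainConfig", "TrainingPair", "AugmentConfig",
           "RegistrationNetwork", "build_network", "train", "infer",
           "augment_pair", "save_weights", "load_weights"]


@dataclass
class NetworkConfig:
    levels: int = 3
    base_channels: int = 16
    channels_per_level: tuple | None = None
    norm_groups: int = 8
    negative_slope: float = 0.01
    single_level: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.channels_per_level is None:
            self.channels_per_level = tuple(
                self.base_channels * 2 ** k for k in range(self.levels))
        self.channels_per_level = tuple(self.channels_per_level)
        if len(self.channels_per_level) != self.levels:
            raise ValueError("need one channel count per level")
        for c in self.channels_per_level:
            if c % min(self.norm_groups, c):
                raise ValueError("channels must be divisible by norm_groups")


@dataclass
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 0.002
    lr_decay: float = 0.97
    batch_size: int = 1
    seed: int = 0
    augment: bool = False
    objective_mode: str = "unsupervised"
    val_fraction: float = 0.2
    objective: ObjectiveConfig = dfield(default_factory=ObjectiveConfig)
    pyramid_spacings: tuple = NONRIGID_PYRAMID_MM

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must lie in (0, 1]")
        if self.objective_mode not in ("unsupervised", "volume_penalty",
                                       "symmetric"):
            raise ValueError(f"unknown objective mode {self.objective_mode!r}")


@dataclass(eq=False)
class TrainingPair:
    """A preprocessed, affinely aligned pair (mask used for training only)."""

    source: Image3D
    target: Image3D
    mask: SegmentationMask | None = None
    landmarks_source: LandmarkSet | None = None
    landmarks_target: LandmarkSet | None = None
    pair_id: str = ""


@dataclass
class AugmentConfig:
    max_rotation_deg: float = 5.0
    max_translation_mm: float = 5.0
    max_scale: float = 0.05
    intensity_offset: float = 0.05
    intensity_scale: float = 0.05


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def _he_init(rng, cout, cin, k=3):
    std = np.sqrt(2.0 / (cin * k ** 3))
    return rng.normal(0.0, std, size=(cout, cin, k, k, k)).astype(np.float32)


class RegistrationNetwork:
    """Channel-first 3-D U-Net with per-level pair inputs and field outputs."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, Tensor] = {}
        ch = cfg.channels_per_level
        L = cfg.levels
        # encoder blocks: level k sees (prev features + 2 pair channels)
        for k in range(L):
            extra = 2 if (k == 0 or not cfg.single_level) else 0
            cin = extra if k == 0 else ch[k - 1] + extra
            self._add_block(rng, f"enc{k}", cin, ch[k])
        # decoder blocks for levels L-2 .. 0 (coarse-to-fine refinement)
        for k in range(L - 2, -1, -1):
            self._add_block(rng, f"dec{k}", ch[k + 1] + ch[k], ch[k])
        # output heads (zero-init so the initial prediction is identity)
        head_levels = range(L) if not cfg.single_level else (0,)
        for k in head_levels:
            self.params[f"head{k}.w"] = Tensor(
                np.zeros((3, ch[k], 3, 3, 3), dtype=np.float32),
                requires_grad=True)
            self.params[f"head{k}.b"] = Tensor(np.zeros(3, dtype=np.float32),
                                               requires_grad=True)

    def _add_block(self, rng, name, cin, cout):
        for i, ci in enumerate((cin, cout)):
            self.params[f"{name}.conv{i}.w"] = Tensor(
                _he_init(rng, cout, ci), requires_grad=True)
            self.params[f"{name}.conv{i}.b"] = Tensor(
                np.zeros(cout, dtype=np.float32), requires_grad=True)
            self.params[f"{name}.norm{i}.g"] = Tensor(
                np.ones(cout, dtype=np.float32), requires_grad=True)
            self.params[f"{name}.norm{i}.b"] = Tensor(
                np.zeros(cout, dtype=np.float32), requires_grad=True)

    # -- forward -----------------------------------------------------------
    def _block(self, name, x):
        cfg = self.cfg
        for i in (0, 1):
            x = ad.conv3d(x, self.params[f"{name}.conv{i}.w"],
                          self.params[f"{name}.conv{i}.b"])
            cout = self.params[f"{name}.norm{i}.g"].shape[0]
            groups = min(cfg.norm_groups, cout)
            x = ad.group_norm(x, self.params[f"{name}.norm{i}.g"],
                              self.params[f"{name}.norm{i}.b"], groups)
            x = x.leaky_relu(cfg.negative_slope)
        return x

    @staticmethod
    def _upsample2(x, target_shape):
        from .transforms import identity_coords
        coords = (identity_coords(target_shape, dtype=x.dtype) - 0.5) / 2.0
        return ad.grid_sample(x, Tensor(coords))

    def forward(self, pyr_m, pyr_f):
        """Map two coarse-to-fine pyramids to per-level fields, finest last.

        ``pyr_m``/``pyr_f`` are sequences of Image3D (or arrays), coarse
        to fine, with exactly ``cfg.levels`` entries (a single finest
        volume each for the single-level variant).
        """
        cfg = self.cfg
        L = cfg.levels
        ms = [np.asarray(getattr(p, "data", p), dtype=np.float32)
              for p in pyr_m]
        fs = [np.asarray(getattr(p, "data", p), dtype=np.float32)
              for p in pyr_f]
        if cfg.single_level:
            if len(ms) != 1:
                ms, fs = ms[-1:], fs[-1:]
            fine = ad.stack([Tensor(ms[0]), Tensor(fs[0])], axis=0)
            inputs = [fine] + [None] * (L - 1)
        else:
            if len(ms) != L:
                raise ValueError(f"expected {L} pyramid levels, got {len(ms)}")
            # pyramids arrive coarse->fine; the encoder indexes fine->coarse
            inputs = [ad.stack([Tensor(m), Tensor(f)], axis=0)
                      for m, f in zip(ms[::-1], fs[::-1])]
        enc = []
        x = None
        for k in range(L):
            if x is None:
                x = self._block(f"enc{k}", inputs[0])
            else:
                x = ad.avg_pool3d(x, 2)
                if inputs[k] is not None:
                    x = ad.concatenate([x, inputs[k]], axis=0)
                x = self._block(f"enc{k}", x)
            enc.append(x)
        fields = []
        if not cfg.single_level:
            fields.append(self._head(L - 1, enc[-1]))
        x = enc[-1]
        for k in range(L - 2, -1, -1):
            x = self._upsample2(x, enc[k].shape[1:])
            x = ad.concatenate([x, enc[k]], axis=0)
            x = self._block(f"dec{k}", x)
            if not cfg.single_level or k == 0:
                fields.append(self._head(k, x))
        return fields  # coarse -> fine (finest last)

    def _head(self, k, x):
        return ad.conv3d(x, self.params[f"head{k}.w"],
                         self.params[f"head{k}.b"])

    def parameters(self):
        return list(self.params.values())

    def state_dict(self):
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state):
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=v.data.dtype).reshape(v.shape)


def build_network(cfg: NetworkConfig | None = None) -> RegistrationNetwork:
    return RegistrationNetwork(cfg or NetworkConfig())


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_weights(path, net: RegistrationNetwork) -> None:
    cfg = net.cfg
    meta = json.dumps({
        "levels": cfg.levels, "base_channels": cfg.base_channels,
        "channels_per_level": list(cfg.channels_per_level),
        "norm_groups": cfg.norm_groups,
        "negative_slope": cfg.negative_slope,
        "single_level": cfg.single_level, "seed": cfg.seed})
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **net.state_dict())


def load_weights(path) -> RegistrationNetwork:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__config__"]).decode())
        state = {k: z[k] for k in z.files if k != "__config__"}
    meta["channels_per_level"] = tuple(meta["channels_per_level"])
    net = RegistrationNetwork(NetworkConfig(**meta))
    net.load_state_dict(state)
    return net


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _random_affine(rng, img: Image3D, acfg: AugmentConfig) -> AffineTransform:
    ang = np.deg2rad(rng.uniform(-acfg.max_rotation_deg,
                                 acfg.max_rotation_deg, size=3))
    rots = []
    for i, a in enumerate(ang):
        r = np.eye(3)
        j, k = [x for x in range(3) if x != i]
        r[j, j] = np.cos(a)
        r[j, k] = -np.sin(a)
        r[k, j] = np.sin(a)
        r[k, k] = np.cos(a)
        rots.append(r)
    lin = rots[0] @ rots[1] @ rots[2]
    lin = lin @ np.diag(rng.uniform(1 - acfg.max_scale, 1 + acfg.max_scale,
                                    size=3))
    t = rng.uniform(-acfg.max_translation_mm, acfg.max_translation_mm, size=3)
    extent = (np.array(img.shape) - 1) * img.spacing
    c = img.origin + extent / 2
    return AffineTransform(lin, c - lin @ c + t)


def augment_pair(source: Image3D, target: Image3D,
                 mask: SegmentationMask | None = None,
                 landmarks: tuple | None = None, seed: int = 0,
                 acfg: AugmentConfig | None = None):
    """One random joint affine + per-volume intensity perturbation.

    The same small affine resamples source, target and mask (so their
    alignment is preserved); intensity offset/scale are drawn per volume
    and clamped to [0, 1]. Deterministic given ``seed``. Landmarks, when
    given as a (source_set, target_set) tuple, are mapped through the
    inverse affine so they stay attached to the moved anatomy.
    """
    acfg = acfg or AugmentConfig()
    rng = np.random.default_rng(seed)
    A = _random_affine(rng, source, acfg)
    src = apply_affine(source, A)
    tgt = apply_affine(target, A)
    msk = None
    if mask is not None:
        warped = apply_affine(mask, A)
        msk = SegmentationMask(np.clip(warped.data, 0, 1), warped.spacing,
                               warped.origin)
    out_lms = None
    if landmarks is not None:
        inv = A.inverse()
        out_lms = tuple(
            LandmarkSet(inv.apply_points(l.points), l.labels)
            if l is not None else None for l in landmarks)

    def _jitter(img):
        off = rng.uniform(-acfg.intensity_offset, acfg.intensity_offset)
        sc = rng.uniform(1 - acfg.intensity_scale, 1 + acfg.intensity_scale)
        return img.copy_with(np.clip(img.data * sc + off, 0.0, 1.0))

    return _jitter(src), _jitter(tgt), msk, out_lms


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _pair_pyramids(pair: TrainingPair, spacings, single_level: bool):
    if single_level:
        return [pair.source], [pair.target]
    pm = build_pyramid(pair.source, spacings)
    pf = build_pyramid(pair.target, spacings)
    return list(pm), list(pf)


def _prepare(pair: TrainingPair, spacings, single_level: bool, mode: str):
    """Precompute per-level images and masks for one pair (cacheable)."""
    pm, pf = _pair_pyramids(pair, spacings, single_level)
    masks = None
    if mode == "volume_penalty" and pair.mask is not None:
        from .objectives import _level_masks
        masks = _level_masks(pair.mask, pm)
    return pm, pf, masks


def _pair_loss(net, pair: TrainingPair, mode: str, ocfg: ObjectiveConfig,
               spacings, prepared=None):
    pm, pf, masks = prepared if prepared is not None else _prepare(
        pair, spacings, net.cfg.single_level, mode)
    fields = net.forward(pm, pf)
    if net.cfg.single_level:
        pm, pf = pm[-1:], pf[-1:]
    if mode == "symmetric":
        fields_bwd = net.forward(pf, pm)
        total = None
        for mlv, flv, umf, ufm in zip(pm, pf, fields, fields_bwd):
            j = symmetric_objective(mlv, flv, umf, ufm, ocfg)
            total = j if total is None else total + j
        return total
    total = None
    for i, (mlv, flv, u) in enumerate(zip(pm, pf, fields)):
        if masks is not None and float(masks[i].data.sum()) > 0:
            j = semi_supervised_objective(mlv, flv, u, masks[i], ocfg)
        else:
            j = unsupervised_objective(mlv, flv, u, ocfg)
        total = j if total is None else total + j
    return total


def _val_metrics(net, pair: TrainingPair, mode, ocfg, spacings, prepared):
    """Validation loss and tumor-volume ratio with a single forward pass."""
    pm, pf, _ = prepared
    loss = float(_pair_loss(net, pair, mode, ocfg, spacings, prepared))
    tvr = None
    if pair.mask is not None and float(pair.mask.data.sum()) > 0:
        u = net.forward(pm, pf)[-1]
        tvr = float(volume_penalty(pair.mask, u.detach()))
    return loss, tvr


def train(pairs, net_cfg: NetworkConfig | None = None,
          train_cfg: TrainConfig | None = None, val_pairs=None):
    """Train the displacement network; returns ``(network, history)``.

    ``pairs`` is a list of :class:`TrainingPair`. Unless ``val_pairs`` is
    given explicitly, a seeded ``val_fraction`` split is carved off the
    input list. The network with the best validation loss is returned
    (falling back to the final weights when no validation pair exists),
    together with a per-epoch history of train/validation loss and
    validation tumor-volume ratio.
    """
    net_cfg = net_cfg or NetworkConfig()
    tcfg = train_cfg or TrainConfig()
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty training set")
    if tcfg.objective_mode == "volume_penalty":
        missing = [p.pair_id for p in pairs if p.mask is None]
        if missing:
            raise ValueError(f"volume_penalty mode needs masks; missing for "
                             f"{missing}")
    rng = np.random.default_rng(tcfg.seed)
    if val_pairs is None:
        n_val = int(round(len(pairs) * tcfg.val_fraction))
        order = rng.permutation(len(pairs))
        val_pairs = [pairs[i] for i in order[:n_val]]
        train_pairs = [pairs[i] for i in order[n_val:]]
    else:
        train_pairs = pairs
        val_pairs = list(val_pairs)
    if not train_pairs:
        raise ValueError("no training pairs left after validation split")

    net = RegistrationNetwork(net_cfg)
    opt = ad.Adam(net.parameters(), lr=tcfg.learning_rate)
    ocfg = tcfg.objective
    spacings = tcfg.pyramid_spacings
    mode = tcfg.objective_mode
    # per-pair pyramids/masks are deterministic; cache them unless augmenting
    cache = {}

    def _prep(pair, allow_cache):
        key = id(pair)
        if allow_cache and key in cache:
            return cache[key]
        prep = _prepare(pair, spacings, net_cfg.single_level, mode)
        if allow_cache:
            cache[key] = prep
        return prep

    history = []
    best_val, best_state = np.inf, net.state_dict()
    for epoch in range(tcfg.epochs):
        opt.lr = tcfg.learning_rate * tcfg.lr_decay ** epoch
        order = rng.permutation(len(train_pairs))
        epoch_losses = []
        for idx in order:
            pair = train_pairs[idx]
            if tcfg.augment:
                aug_seed = int(rng.integers(0, 2 ** 31 - 1))
                src, tgt, msk, _ = augment_pair(pair.source, pair.target,
                                                pair.mask, seed=aug_seed)
                pair = replace(pair, source=src, target=tgt,
                               mask=msk if msk is not None else pair.mask)
            loss = _pair_loss(net, pair, mode, ocfg, spacings,
                              prepared=_prep(pair, not tcfg.augment))
            lval = float(loss)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"non-finite training loss on pair {pair.pair_id!r}")
            epoch_losses.append(lval)
            opt.zero_grad()
            loss.backward()
            opt.step()
        val_losses, val_tvrs = [], []
        for pair in val_pairs:
            vl, tv = _val_metrics(net, pair, mode, ocfg, spacings,
                                  _prep(pair, True))
            val_losses.append(vl)
            if tv is not None:
                val_tvrs.append(tv)
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": float(np.mean(val_losses)) if val_losses else np.nan,
            "val_tvr": float(np.mean(val_tvrs)) if val_tvrs else np.nan,
        }
        history.append(row)
        crit = row["val_loss"] if val_losses else row["train_loss"]
        if crit < best_val:
            best_val = crit
            best_state = net.state_dict()
    net.load_state_dict(best_state)
    return net, history


def infer(source: Image3D, target: Image3D, net: RegistrationNetwork,
          spacings=NONRIGID_PYRAMID_MM) -> DisplacementField:
    """Predict the displacement field for a preprocessed, aligned pair.

    By design no segmentation mask enters inference in any mode.
    """
    if source.shape != target.shape:
        raise ValueError("inference expects a same-grid pair")
    if net.cfg.single_level:
        pm, pf = [source], [target]
    else:
        pm = list(build_pyramid(source, spacings))
        pf = list(build_pyramid(target, spacings))
    u = net.forward(pm, pf)[-1]
    return DisplacementField(np.asarray(u.data, dtype=float),
                             source.spacing.copy(), source.origin.copy())
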
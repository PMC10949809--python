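"""Multi-task 3D CNN for imaging + clinical prognosis.

A parameter-efficient network with two image branches (MRI and JD volumes,
each a strided convolution followed by a depthwise-separable convolution and
global average pooling) whose pooled features are fused with the clinical
vector and fed to three output heads:

1. four-year progression to AD dementia — single unit, sigmoid, class-
   weighted binary cross-entropy ``L1``;
2. four-year MMSE slope — single unit, linear, mean-squared error ``L2``;
3. hippocampal volume — single unit, linear, mean-squared error ``L3``.

Training minimizes the weighted sum ``L = w1*L1 + w2*L2 + w3*L3``; the main
task takes weight 1 and the auxiliary tasks small weights (default 0.025),
which regularizes the shared trunk on small cohorts.  Regression targets are
z-scored on the training set so the auxiliary weights act on a comparable
scale; predictions are mapped back to native units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import nn
from .errors import (ConfigurationError, DegenerateLabelsError,
                     DivergenceError, ShapeError)

DEFAULT_AUX_GRID = (0.0, 0.025, 0.050, 0.075, 0.1)


@dataclass(frozen=True)
class LossSpec:
    """Multi-task loss weights; the combined loss is w1*L1 + w2*L2 + w3*L3."""

    w1: float = 1.0
    w2: float = 0.025
    w3: float = 0.025

    def validate(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0:
            raise ConfigurationError("loss weights must be nonnegative")


def combined_loss(spec: LossSpec, l1: float, l2: float, l3: float) -> float:
    """Exact weighted sum of the three per-head losses."""
    spec.validate()
    return spec.w1 * l1 + spec.w2 * l2 + spec.w3 * l3


def class_weights(train_labels: np.ndarray) -> tuple[float, float]:
    """Inverse-frequency pair (w_negative, w_positive): n_total / (2 * n_c)."""
    y = np.asarray(train_labels).astype(int)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 == 0 or n1 == 0:
        raise DegenerateLabelsError("both classes required for class weights")
    n = n0 + n1
    return n / (2.0 * n0), n / (2.0 * n1)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training hyperparameters.

    ``input_shape`` applies to both branches (the MRI is cropped and the JD
    zero-padded to it upstream).  ``param_ceiling`` is the parameter-
    efficiency contract: builds exceeding it fail.
    """

    input_shape: tuple[int, int, int] = (32, 32, 32)
    clinical_dim: int = 6
    branch_channels: tuple[int, int] = (4, 8)
    branch_reduce: int = 4
    branch_embed: int = 12
    fusion_width: int = 16
    epochs: int = 50
    batch_size: int = 4
    learning_rate: float = 1e-3
    lr_milestones: tuple[int, ...] = (20, 40)
    lr_gamma: float = 0.3
    weight_decay: float = 1e-2
    l1_decay: float = 0.1
    dropout: float = 0.7
    param_ceiling: int = 50_000
    seed: int = 0


@dataclass
class ImagingDataset:
    """Preprocessed model inputs for a set of subjects (aligned arrays)."""

    subject_ids: list[str]
    mri: np.ndarray            # (N, 1, D, H, W), rescaled to [-1, 1]
    jd: np.ndarray             # (N, 1, D, H, W), unscaled
    clinical: np.ndarray       # (N, C), min-max scaled on train
    labels: np.ndarray         # (N,) 0/1 progression
    slopes: np.ndarray         # (N,) points/year, native units
    hippo: np.ndarray          # (N,) mm^3, native units

    def __len__(self) -> int:
        return len(self.subject_ids)

    def subset(self, idx: np.ndarray) -> "ImagingDataset":
        return ImagingDataset(
            [self.subject_ids[i] for i in idx], self.mri[idx], self.jd[idx],
            self.clinical[idx], self.labels[idx], self.slopes[idx],
            self.hippo[idx])

    def zeroed(self, *, mri: bool = False, jd: bool = False,
               clinical: bool = False) -> "ImagingDataset":
        """Copy with selected modalities replaced by constant zeros."""
        return ImagingDataset(
            list(self.subject_ids),
            np.zeros_like(self.mri) if mri else self.mri,
            np.zeros_like(self.jd) if jd else self.jd,
            np.zeros_like(self.clinical) if clinical else self.clinical,
            self.labels, self.slopes, self.hippo)


class _Branch:
    """One image branch: strided conv -> separable conv -> 1x1 channel
    reduction -> flattened dense embedding.

    The dense readout keeps per-position weights, so the branch can attend
    to specific spatial locations — which is also what lets block occlusion
    attribute performance to regions.
    """

    def __init__(self, input_shape: tuple[int, int, int],
                 channels: tuple[int, int], reduce_channels: int,
                 embed_dim: int, dropout: float,
                 rng: np.random.Generator) -> None:
        c1, c2 = channels
        self.conv1 = nn.Conv3d(1, c1, kernel=3, stride=2, rng=rng)
        self.bn1 = nn.BatchNorm3d(c1)
        self.relu1 = nn.ReLU()
        self.depthwise = nn.Conv3d(c1, c1, kernel=3, stride=2, groups=c1,
                                   rng=rng)
        self.pointwise = nn.Conv3d(c1, c2, kernel=1, stride=1, rng=rng)
        self.bn2 = nn.BatchNorm3d(c2)
        self.relu2 = nn.ReLU()
        self.reduce = nn.Conv3d(c2, reduce_channels, kernel=1, stride=1,
                                rng=rng)
        self.flatten = nn.Flatten()
        spatial = [((d - 3) // 2 + 1 - 3) // 2 + 1 for d in input_shape]
        if any(s < 1 for s in spatial):
            raise ShapeError(
                f"input shape {input_shape} too small for two strided "
                f"convolutions")
        mid = [self.conv1, self.bn1, self.relu1, self.depthwise,
               self.pointwise, self.bn2, self.relu2, self.reduce]
        if min(spatial) >= 4:      # keep the embed input small
            mid.append(nn.AvgPool3d(2))
            spatial = [s // 2 for s in spatial]
        flat_dim = reduce_channels * int(np.prod(spatial))
        self.dropout = nn.Dropout(dropout)
        self.embed = nn.Dense(flat_dim, embed_dim, rng=rng)
        self.layers = mid + [self.flatten, self.dropout, self.embed]

    def params(self) -> list[nn.Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class MultiTaskCNN:
    """Two-branch volumetric network with clinical fusion and three heads."""

    def __init__(self, config: NetworkConfig) -> None:
        rng = np.random.default_rng([config.seed, 7])
        self.config = config
        self.mri_branch = _Branch(config.input_shape, config.branch_channels,
                                  config.branch_reduce, config.branch_embed,
                                  config.dropout, rng)
        self.jd_branch = _Branch(config.input_shape, config.branch_channels,
                                 config.branch_reduce, config.branch_embed,
                                 config.dropout, rng)
        self.branch_out = config.branch_embed
        fused_in = 2 * self.branch_out + config.clinical_dim
        self.fusion = nn.Dense(fused_in, config.fusion_width, rng=rng)
        self.fusion_relu = nn.ReLU()
        self.head_progression = nn.Dense(config.fusion_width, 1, rng=rng)
        self.head_slope = nn.Dense(config.fusion_width, 1, rng=rng)
        self.head_hippo = nn.Dense(config.fusion_width, 1, rng=rng)
        # target scalers, set by the trainer (mean, sd) in native units
        self.slope_norm: tuple[float, float] = (0.0, 1.0)
        self.hippo_norm: tuple[float, float] = (0.0, 1.0)
        self._check_shapes_and_budget()

    def _check_shapes_and_budget(self) -> None:
        shape = self.config.input_shape
        probe = np.zeros((1, 1) + tuple(shape))
        try:
            self.mri_branch.forward(probe)
        except ShapeError as exc:
            raise ShapeError(
                f"input shape {shape} incompatible with the branch "
                f"architecture: {exc}") from exc
        n = self.parameter_count
        if n > self.config.param_ceiling:
            raise ConfigurationError(
                f"parameter count {n} exceeds ceiling "
                f"{self.config.param_ceiling}")

    def set_training(self, flag: bool,
                     rng: np.random.Generator | None = None) -> None:
        for branch in (self.mri_branch, self.jd_branch):
            branch.dropout.training = flag
            branch.bn1.training = flag
            branch.bn2.training = flag
            if rng is not None:
                branch.dropout.rng = rng

    def params(self) -> list[nn.Param]:
        return (self.mri_branch.params() + self.jd_branch.params()
                + self.fusion.params() + self.fusion_relu.params()
                + self.head_progression.params() + self.head_slope.params()
                + self.head_hippo.params())

    @property
    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward(self, mri: np.ndarray, jd: np.ndarray,
                clinical: np.ndarray) -> tuple[np.ndarray, ...]:
        """Pre-activations (z1, z2, z3), each of shape (N,)."""
        fm = self.mri_branch.forward(mri)
        fj = self.jd_branch.forward(jd)
        fused = np.concatenate([fm, fj, clinical], axis=1)
        self._clin_dim = clinical.shape[1]
        h = self.fusion_relu.forward(self.fusion.forward(fused))
        z1 = self.head_progression.forward(h)[:, 0]
        z2 = self.head_slope.forward(h)[:, 0]
        z3 = self.head_hippo.forward(h)[:, 0]
        return z1, z2, z3

    def backward(self, dz1: np.ndarray, dz2: np.ndarray,
                 dz3: np.ndarray) -> None:
        dh = (self.head_progression.backward(dz1[:, None])
              + self.head_slope.backward(dz2[:, None])
              + self.head_hippo.backward(dz3[:, None]))
        dfused = self.fusion.backward(self.fusion_relu.backward(dh))
        bo = self.branch_out
        self.mri_branch.backward(dfused[:, :bo])
        self.jd_branch.backward(dfused[:, bo:2 * bo])

    def predict(self, data: ImagingDataset,
                batch_size: int = 16) -> pd.DataFrame:
        """Per-subject progression probability and native-unit regressions."""
        was_training = self.mri_branch.dropout.training
        self.set_training(False)
        probs, slopes, hippos = [], [], []
        for start in range(0, len(data), batch_size):
            sl = slice(start, start + batch_size)
            z1, z2, z3 = self.forward(data.mri[sl], data.jd[sl],
                                      data.clinical[sl])
            probs.append(nn.sigmoid(z1))
            slopes.append(z2 * self.slope_norm[1] + self.slope_norm[0])
            hippos.append(z3 * self.hippo_norm[1] + self.hippo_norm[0])
        self.set_training(was_training)
        return pd.DataFrame({
            "subject_id": data.subject_ids,
            "p_progression": np.concatenate(probs),
            "pred_slope": np.concatenate(slopes),
            "pred_hippo": np.concatenate(hippos),
        })


def _weighted_bce(z: np.ndarray, y: np.ndarray,
                  w: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean class-weighted binary cross-entropy on logits, and dL/dz."""
    p = nn.sigmoid(z)
    eps = 1e-12
    loss = float(np.mean(-w * (y * np.log(p + eps)
                               + (1 - y) * np.log(1 - p + eps))))
    grad = w * (p - y) / z.size
    return loss, grad


def _mse(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    diff = z - t
    return float(np.mean(diff ** 2)), 2.0 * diff / z.size


def evaluate_auc(model: MultiTaskCNN, data: ImagingDataset) -> float:
    from .evaluation import auc
    scores = model.predict(data)["p_progression"].to_numpy()
    return auc(scores, data.labels)


def train(model: MultiTaskCNN, train_set: ImagingDataset,
          val_set: ImagingDataset | None, spec: LossSpec,
          config: NetworkConfig | None = None) -> pd.DataFrame:
    """Train in place for the configured number of epochs.

    Returns the per-epoch history (L, L1, L2, L3 on the training set and,
    when a validation set is given, validation AUC and slope R^2).
    Deterministic given the config seed.
    """
    from .evaluation import auc, r_squared

    spec.validate()
    cfg = config or model.config
    w_neg, w_pos = class_weights(train_set.labels)
    y = train_set.labels.astype(float)
    sample_w = np.where(y == 1, w_pos, w_neg)

    s_mu, s_sd = float(train_set.slopes.mean()), float(train_set.slopes.std())
    h_mu, h_sd = float(train_set.hippo.mean()), float(train_set.hippo.std())
    s_sd = s_sd if s_sd > 0 else 1.0
    h_sd = h_sd if h_sd > 0 else 1.0
    model.slope_norm = (s_mu, s_sd)
    model.hippo_norm = (h_mu, h_sd)
    t_slope = (train_set.slopes - s_mu) / s_sd
    t_hippo = (train_set.hippo - h_mu) / h_sd

    opt = nn.Adam(model.params(), lr=cfg.learning_rate,
                  milestones=cfg.lr_milestones, gamma=cfg.lr_gamma,
                  weight_decay=cfg.weight_decay, l1_decay=cfg.l1_decay)
    model.set_training(True, rng=np.random.default_rng([cfg.seed, 13]))
    n = len(train_set)
    history = []
    for epoch in range(cfg.epochs):
        opt.set_epoch(epoch)
        order = np.random.default_rng(
            [cfg.seed, 29, epoch + 1]).permutation(n)
        sums = np.zeros(4)
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            z1, z2, z3 = model.forward(train_set.mri[idx],
                                       train_set.jd[idx],
                                       train_set.clinical[idx])
            l1, dz1 = _weighted_bce(z1, y[idx], sample_w[idx])
            l2, dz2 = _mse(z2, t_slope[idx])
            l3, dz3 = _mse(z3, t_hippo[idx])
            total = combined_loss(spec, l1, l2, l3)
            if not np.isfinite(total):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch + 1}")
            opt.zero_grad()
            model.backward(spec.w1 * dz1, spec.w2 * dz2, spec.w3 * dz3)
            opt.step()
            sums += (total, l1, l2, l3)
            n_batches += 1
        row = {
            "epoch": epoch + 1,
            "L": sums[0] / n_batches, "L1": sums[1] / n_batches,
            "L2": sums[2] / n_batches, "L3": sums[3] / n_batches,
            "lr": opt.lr,
        }
        if val_set is not None and len(val_set) > 0:
            pred = model.predict(val_set)
            labels = val_set.labels
            row["val_auc"] = (auc(pred["p_progression"].to_numpy(), labels)
                              if len(np.unique(labels)) == 2 else np.nan)
            slopes = val_set.slopes
            row["val_r2"] = (r_squared(pred["pred_slope"].to_numpy(), slopes)
                             if np.std(slopes) > 0 else np.nan)
        history.append(row)
    model.set_training(False)
    return pd.DataFrame(history)


def weight_grid_search(grid: Sequence[float],
                       folds: Sequence[tuple[ImagingDataset, ImagingDataset]],
                       config: NetworkConfig,
                       main_task: Literal["progression", "slope"] =
                       "progression") -> tuple[pd.DataFrame, float]:
    """Validation-metric table over auxiliary-weight values.

    For each ``w`` in the grid the auxiliary heads get weight ``w`` (the main
    head keeps weight 1); one model is trained per (w, fold).  The selected
    ``w`` maximizes the mean validation metric of the main task; ties go to
    the smaller w.
    """
    if len(grid) == 0:
        raise ConfigurationError("weight grid is empty")
    rows = []
    for w in grid:
        spec = (LossSpec(1.0, w, w) if main_task == "progression"
                else LossSpec(w, 1.0, w))
        for k, (train_set, val_set) in enumerate(folds):
            model = MultiTaskCNN(config)
            hist = train(model, train_set, val_set, spec, config)
            metric = ("val_auc" if main_task == "progression" else "val_r2")
            rows.append({"w": w, "fold": k + 1,
                         "val_metric": float(hist[metric].iloc[-1])})
    table = pd.DataFrame(rows)
    means = table.groupby("w", sort=True)["val_metric"].mean()
    best_w = float(means.index[np.argmax(means.to_numpy())])  # ties -> smaller
    return table, best_w


def modality_ablation(train_set: ImagingDataset, eval_set: ImagingDataset,
                      config: NetworkConfig,
                      modes: Sequence[str] = ("mri_only", "jd_only", "both"),
                      spec: LossSpec | None = None,
                      include_clinical: bool = False,
                      ) -> tuple[pd.DataFrame, dict[str, MultiTaskCNN]]:
    """Train the network per modality mode and report evaluation AUC.

    A missing modality's branch receives a constant zero volume; with
    ``include_clinical=False`` (default) the clinical vector is zeroed too,
    isolating the imaging contribution.
    """
    spec = spec or LossSpec()
    zero_map = {
        "mri_only": dict(jd=True), "jd_only": dict(mri=True), "both": {}}
    rows, models = [], {}
    for mode in modes:
        if mode not in zero_map:
            raise ConfigurationError(f"unknown ablation mode {mode!r}")
        kw = dict(zero_map[mode])
        if not include_clinical:
            kw["clinical"] = True
        tr = train_set.zeroed(**kw)
        ev = eval_set.zeroed(**kw)
        model = MultiTaskCNN(config)
        train(model, tr, None, spec, config)
        rows.append({"mode": mode, "auc": evaluate_auc(model, ev)})
        models[mode] = model
    return pd.DataFrame(rows), models
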
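"""Dataset assembly, training loop and evaluation for the AC regressor.

A dataset record holds the preprocessed five-angle envelope tensor, the
downsampled B-mode conditioning image and the ground-truth liver attenuation
of one phantom.  Records are split 8:1:1 (train/validation/test) by phantom
id with no leakage; the mean normalized absolute error (MNAE) on the test
split, normalized by the 1.0 dB/cm/MHz ground-truth range, is the headline
metric, together with the no-B-mode ablation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .acoustics import ProbeConfig, acquire, compound_bmode
from .autodiff import Tensor
from .errors import ConfigurationError, InputError, SonoacError
from .network import ACRegressionNet, Adam, NetworkConfig
from .phantom import PhantomSpec, sample_phantom, warp_axial_grid

__all__ = [
    "TrainConfig",
    "EvalReport",
    "PhantomDataset",
    "build_dataset",
    "preprocess_envelopes",
    "preprocess_bmode",
    "train",
    "evaluate",
    "mnae",
    "run_ablation",
]

AC_TRUTH_RANGE = 1.0  # dB/cm/MHz span of the ground-truth liver AC

logger = logging.getLogger(__name__)


class TrainingError(SonoacError):
    """Optimization diverged (non-finite loss)."""


@dataclass
class TrainConfig:
    """Optimization settings.  Counts default to the full-scale 8:1:1 split."""

    n_train: int = 8000
    n_val: int = 1000
    n_test: int = 1000
    loss: str = "l1"
    l2_weight: float = 1e-4
    lr: float = 5e-6  # initial learning rate
    batch_size: int = 16
    max_epochs: int = 200
    patience: int = 20  # early stop: epochs without val improvement
    min_delta: float = 1e-4
    augment_flip: bool = True  # random lateral mirror (a symmetry of the array)
    seed: int = 0


@dataclass
class EvalReport:
    """Held-out evaluation summary (percentages are MNAE values)."""

    mnae: float
    baseline_mnae: float
    per_sample_errors: np.ndarray
    ablation_mnae: float | None = None
    relative_improvement: float | None = None
    per_seed: list[dict] = field(default_factory=list)
    p_value: float | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class PhantomDataset:
    """Preprocessed records plus a leakage-free split assignment."""

    envelopes: np.ndarray  # (n, 5, C, T) float32, log-compressed
    bmodes: np.ndarray  # (n, 1, H, W) float32 in [0, 1]
    targets: np.ndarray  # (n,) dB/cm/MHz
    ids: np.ndarray  # (n,) phantom ids (ints)
    splits: dict[str, np.ndarray]  # name -> index array into records
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        all_idx = np.concatenate([v for v in self.splits.values()])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ConfigurationError("split index sets overlap")

    def subset(self, split: str):
        idx = self.splits[split]
        return self.envelopes[idx], self.bmodes[idx], self.targets[idx]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.envelopes, self.bmodes, self.targets, self.ids):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]


def preprocess_envelopes(env: np.ndarray, out_channels: int, out_time: int,
                         t_start_frac: float = 0.04) -> np.ndarray:
    """(5, ch, T) raw envelopes -> (5, out_channels, out_time) log features.

    Block-averages channels and time, drops the pre-arrival samples, applies
    log compression (the attenuation law is linear in log-amplitude) and
    removes the per-record mean so overall gain does not leak the target.
    """
    n_ang, n_ch, n_t = env.shape
    t0 = int(n_t * t_start_frac)
    cf = max(1, n_ch // out_channels)
    tf = max(1, (n_t - t0) // out_time)
    e = env[:, : cf * out_channels, t0:t0 + tf * out_time]
    e = e.reshape(n_ang, out_channels, cf, out_time, tf).mean(axis=(2, 4))
    floor = float(e.max()) * 1e-5 + 1e-30
    x = np.log10(e + floor)
    x -= x.mean()
    return (x / 2.0).astype(np.float32)


def preprocess_bmode(pixels_db: np.ndarray, size: int, dynamic_range: float) -> np.ndarray:
    """Average-pool a dB image onto (size, size) and rescale to [0, 1]."""
    nz, nx = pixels_db.shape
    fz, fx = nz / size, nx / size
    out = np.empty((size, size), dtype=np.float64)
    for i in range(size):
        z0, z1 = int(i * fz), max(int((i + 1) * fz), int(i * fz) + 1)
        row = pixels_db[z0:z1]
        for j in range(size):
            x0, x1 = int(j * fx), max(int((j + 1) * fx), int(j * fx) + 1)
            out[i, j] = row[:, x0:x1].mean()
    return ((out / dynamic_range) + 1.0).astype(np.float32)


def _split_indices(n: int, rng: np.random.Generator, strata: np.ndarray | None = None,
                   ratio=(8, 1, 1)) -> dict[str, np.ndarray]:
    """8:1:1 split by record id; optionally stratified.

    With ``strata`` (a continuous per-record score, e.g. the target), records
    are sorted by the score and assigned round-robin in shuffled blocks of
    ``sum(ratio)``, so each split sees the same score distribution — a
    standard precaution for small cohorts.
    """
    total = sum(ratio)
    if strata is None:
        order = rng.permutation(n)
    else:
        order = np.argsort(strata, kind="stable")
    template = np.concatenate([np.full(r, i) for i, r in enumerate(ratio)])
    assign = np.empty(n, dtype=int)
    for start in range(0, n, total):
        block = template.copy()
        rng.shuffle(block)
        m = min(total, n - start)
        assign[order[start:start + m]] = block[:m]
    return {
        "train": np.flatnonzero(assign == 0),
        "val": np.flatnonzero(assign == 1),
        "test": np.flatnonzero(assign == 2),
    }


def build_dataset(n: int, spec: PhantomSpec, probe: ProbeConfig, seed: int = 0,
                  net_input: tuple[int, int] = (32, 128), bmode_size: int = 32,
                  bmode_pixel_mm: float = 0.5, progress: bool = False) -> PhantomDataset:
    """Simulate ``n`` phantoms end to end into a training-ready dataset.

    One master seed fans out per-phantom streams for geometry, receiver noise
    and the split shuffle, so the same call is bit-reproducible.
    """
    if n < 10:
        raise InputError("need at least 10 records for an 8:1:1 split")
    logger.info("build_dataset: n=%d seed=%d grid=%s angles=%s",
                n, seed, spec.grid_shape, tuple(probe.angles))
    master = np.random.default_rng(seed)
    phantom_seeds = master.integers(0, 2**31 - 1, size=n)
    noise_seeds = master.integers(0, 2**31 - 1, size=n)
    split_rng = np.random.default_rng(master.integers(0, 2**31 - 1))

    from .phantom import TISSUE_LABELS

    envs, bms, ys, vis = [], [], [], []
    for i in range(n):
        pspec = replace(spec, seed=int(phantom_seeds[i]))
        tmap = sample_phantom(pspec)
        tmap = warp_axial_grid(tmap, pspec.probe_curvature_radius)
        frames = acquire(tmap, probe, seed=int(noise_seeds[i]), phantom_id=str(i))
        bm = compound_bmode(frames, pixel_mm=bmode_pixel_mm)
        envs.append(preprocess_envelopes(frames.envelopes, *net_input))
        bms.append(preprocess_bmode(bm.pixels, bmode_size, bm.dynamic_range)[None])
        ys.append(tmap.liver_ac_truth)
        # liver visibility in the insonified deep window (split stratification)
        iz0 = int(spec.layer_zone_depth / spec.cell_size)
        half_ap = probe.aperture_mm / 2
        ix = np.abs(tmap.lateral_mm()) <= half_ap
        vis.append(float((tmap.label_map[iz0:, ix] == TISSUE_LABELS["liver"]).mean()))
        if progress and (i + 1) % 25 == 0:
            print(f"  built {i + 1}/{n} records")

    ys = np.asarray(ys, dtype=np.float64)
    vis_arr = np.asarray(vis)
    # stratify on coarse visibility bins, then target, so no split is
    # systematically harder than another at small n
    strata = np.round(vis_arr * 3) * 10 + ys
    splits = _split_indices(n, split_rng, strata=strata)
    return PhantomDataset(
        envelopes=np.stack(envs), bmodes=np.stack(bms),
        targets=ys, ids=np.arange(n), splits=splits,
        meta={"seed": seed, "n": n, "probe_angles": tuple(probe.angles),
              "net_input": net_input, "bmode_size": bmode_size,
              "liver_visible_frac": vis_arr},
    )


def mnae(predictions, truths, truth_range: float = AC_TRUTH_RANGE) -> float:
    """Mean normalized absolute error in percent.

    Absolute errors are normalized by the ground-truth range (1.0 dB/cm/MHz)
    rather than per-sample truth, which can be zero.
    """
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(truths, dtype=np.float64)
    if p.size == 0 or p.shape != t.shape:
        raise InputError("predictions and truths must be equal-length, nonempty")
    return float(100.0 * np.mean(np.abs(p - t)) / truth_range)


def _epoch_loss(model: ACRegressionNet, env, bm, y) -> float:
    preds = model.predict(env, bm if model.config.use_bmode else None)
    return float(np.mean(np.abs(preds - y)))


def train(dataset: PhantomDataset, net_config: NetworkConfig,
          train_config: TrainConfig, verbose: bool = False):
    """L1 training with Adam + L2 regularization and validation early stop.

    Returns ``(model, history)``; the model carries the best-validation
    parameters.  Raises :class:`TrainingError` on divergence.
    """
    env_tr, bm_tr, y_tr = dataset.subset("train")
    env_va, bm_va, y_va = dataset.subset("val")
    if len(y_tr) == 0 or len(y_va) == 0:
        raise ConfigurationError("empty train or validation split")
    if set(dataset.splits["train"]) & set(dataset.splits["val"]):
        raise ConfigurationError("train/val splits overlap")

    logger.info("train: seed=%d n_train=%d lr=%g l2=%g use_bmode=%s",
                train_config.seed, len(y_tr), train_config.lr,
                train_config.l2_weight, net_config.use_bmode)
    model = ACRegressionNet(net_config)
    opt = Adam(model.params(), lr=train_config.lr,
               weight_decay=train_config.l2_weight)
    rng = np.random.default_rng(train_config.seed)
    n = len(y_tr)
    bs = min(train_config.batch_size, n)
    history = {"train_l1": [], "val_l1": []}
    best_val, best_state, since_best = np.inf, model.state_dict(), 0

    for epoch in range(train_config.max_epochs):
        model.training = True
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n - bs + 1, bs):
            idx = order[start:start + bs]
            env_np = env_tr[idx].astype(np.float64)
            bm_np = bm_tr[idx].astype(np.float64)
            if train_config.augment_flip:
                flip = rng.random(len(idx)) < 0.5
                env_np[flip] = env_np[flip, :, ::-1, :]  # mirror the channel axis
                bm_np[flip] = bm_np[flip, :, :, ::-1]  # mirror laterally
            env_b = Tensor(env_np)
            bm_b = Tensor(bm_np) if net_config.use_bmode else None
            preds = model.forward(env_b, bm_b)
            loss = (preds - Tensor(y_tr[idx])).abs().mean()
            if not np.isfinite(loss.data):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: {loss.data!r}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data)
        n_batches = max(1, n // bs)
        history["train_l1"].append(ep_loss / n_batches)

        val_l1 = _epoch_loss(model, env_va, bm_va, y_va)
        history["val_l1"].append(val_l1)
        if verbose:
            print(f"epoch {epoch:3d}  train L1 {history['train_l1'][-1]:.4f}  "
                  f"val L1 {val_l1:.4f}")
        if val_l1 < best_val - train_config.min_delta:
            best_val, best_state, since_best = val_l1, model.state_dict(), 0
        else:
            since_best += 1
            if since_best >= train_config.patience:
                break

    model.load_state_dict(best_state)
    model.training = False
    history["best_val_l1"] = best_val
    return model, history


def evaluate(model: ACRegressionNet, dataset: PhantomDataset,
             split: str = "test") -> EvalReport:
    """Held-out MNAE plus the mean-predictor baseline on the same split."""
    env, bm, y = dataset.subset(split)
    preds = model.predict(env, bm if model.config.use_bmode else None)
    errors = np.abs(preds - y)
    y_train = dataset.subset("train")[2]
    baseline = mnae(np.full_like(y, y_train.mean()), y)
    return EvalReport(
        mnae=mnae(preds, y), baseline_mnae=baseline, per_sample_errors=errors,
        meta={"split": split, "n": len(y), "dataset_hash": dataset.content_hash()},
    )


def run_ablation(dataset: PhantomDataset, net_config: NetworkConfig,
                 train_config: TrainConfig, seeds=(0, 1, 2),
                 verbose: bool = False) -> EvalReport:
    """Train B-mode-guided and no-B-mode variants on identical splits/seeds.

    relative_improvement = 100 * (ablation_mnae - mnae) / ablation_mnae,
    averaged over seeds; a paired one-sided t-test gives the p-value that
    B-mode guidance helps.
    """
    per_seed = []
    for s in seeds:
        results = {}
        for tag, use_bmode in (("full", True), ("ablation", False)):
            ncfg = dataclasses.replace(net_config, use_bmode=use_bmode, seed=s)
            tcfg = dataclasses.replace(train_config, seed=s)
            model, _ = train(dataset, ncfg, tcfg, verbose=verbose)
            results[tag] = evaluate(model, dataset).mnae
        per_seed.append({"seed": s, "mnae": results["full"],
                         "ablation_mnae": results["ablation"]})
        if verbose:
            print(f"seed {s}: full {results['full']:.2f}%  "
                  f"ablation {results['ablation']:.2f}%")

    full = np.array([r["mnae"] for r in per_seed])
    abl = np.array([r["ablation_mnae"] for r in per_seed])
    if len(per_seed) >= 2:
        t_res = sps.ttest_rel(abl, full, alternative="greater")
        p_value = float(t_res.pvalue)
    else:
        p_value = None
    mean_full, mean_abl = float(full.mean()), float(abl.mean())
    rel = 100.0 * (mean_abl - mean_full) / mean_abl if mean_abl > 0 else 0.0
    y = dataset.subset("test")[2]
    y_train = dataset.subset("train")[2]
    baseline = mnae(np.full_like(y, y_train.mean()), y)
    return EvalReport(
        mnae=mean_full, baseline_mnae=baseline,
        per_sample_errors=np.array([]), ablation_mnae=mean_abl,
        relative_improvement=rel, per_seed=per_seed, p_value=p_value,
        meta={"seeds": tuple(seeds), "dataset_hash": dataset.content_hash()},
    )
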
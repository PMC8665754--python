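"""Multitask training loop and cross-validation.

The shared feature extractor is trained on both the clinical task and the
conservation task; each task owns its classifier head. Default scheduling
alternates one clinical batch with one conservation batch; a joint
weighted mode sums both losses per step instead. Cross-validation folds
are drawn from clinical examples only — common population variants and
conservation examples may strengthen every training fold but never appear
in a test fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .featurize import FeatureDataset
from .metrics import pr_auc, roc_auc
from .model import Model, ModelConfig, make_model

__all__ = ["TrainConfig", "Adam", "train_multitask", "cross_validate"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 5
    batch_size: int = 128
    learning_rate: float = 1e-3
    task_mixing: str = "alternate_batches"  # or "joint_weighted"
    task_weight: float = 1.0  # conservation loss weight
    oversample_factor: int = 1  # applied to pathogenic training examples
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if self.task_mixing not in {"alternate_batches", "joint_weighted"}:
            raise ValueError(f"unknown task_mixing {self.task_mixing!r}")


class Adam:
    """Adaptive moment optimizer with the usual fixed defaults."""

    def __init__(self, params: dict, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p.data -= (self.lr * (self.m[k] / b1t)
                       / (np.sqrt(self.v[k] / b2t) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _oversampled_indices(ds: FeatureDataset, factor: int) -> np.ndarray:
    idx = np.arange(len(ds))
    if factor <= 1:
        return idx
    pathogenic = idx[ds.labels == 1]
    return np.concatenate([idx] + [pathogenic] * (factor - 1))


def _epoch_batches(n_or_idx, batch_size: int, rng) -> list[np.ndarray]:
    idx = (np.arange(n_or_idx) if np.isscalar(n_or_idx) else np.asarray(n_or_idx))
    perm = rng.permutation(idx)
    return [perm[i:i + batch_size] for i in range(0, len(perm), batch_size)]


def _task_step(model: Model, ds: FeatureDataset, batch: np.ndarray,
               task: str, rng) -> tuple[ad.Tensor, float]:
    logits = model.forward_logits(
        ds.wt[batch], ds.mut[batch], ds.msa[batch],
        ds.snvbox[batch] if model.cfg.use_snvbox else None,
        task=task, train=True, rng=rng,
    )
    loss = ad.softmax_cross_entropy(logits, ds.labels[batch].astype(np.int64))
    return loss, float(loss.data)


def train_multitask(
    clinical: FeatureDataset,
    conservation: FeatureDataset | None,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    model: Model | None = None,
) -> tuple[Model, dict]:
    """Train the shared extractor plus task heads; returns (model, loss log).

    ``conservation=None`` (or a config without a conservation head)
    degenerates to single-task clinical training. Deterministic given the
    config seeds: the loss log is bit-identical across reruns.
    """
    if len(clinical) == 0:
        raise ValueError("empty clinical dataset")
    use_cons = conservation is not None and "conservation" in mcfg.heads
    if use_cons and len(conservation) == 0:
        raise ValueError("empty conservation dataset")
    if use_cons and conservation.window_length != clinical.window_length:
        raise ValueError("datasets featurized at different window lengths")
    if model is None:
        model = make_model(mcfg, clinical.window_length)
    opt = Adam(model.params, lr=tcfg.learning_rate)
    rng = np.random.default_rng(tcfg.seed)
    drop_rng = np.random.default_rng(tcfg.seed + 1)
    clin_idx = _oversampled_indices(clinical, tcfg.oversample_factor)
    log: dict[str, list[float]] = {"clinical": []}
    if use_cons:
        log["conservation"] = []
    for _epoch in range(tcfg.epochs):
        clin_batches = _epoch_batches(clin_idx, tcfg.batch_size, rng)
        cons_batches = (_epoch_batches(len(conservation), tcfg.batch_size, rng)
                        if use_cons else [])
        losses: dict[str, list[float]] = {"clinical": [], "conservation": []}
        steps: list[tuple[str, np.ndarray]] = []
        if tcfg.task_mixing == "alternate_batches" or not use_cons:
            for i in range(max(len(clin_batches), len(cons_batches))):
                if i < len(clin_batches):
                    steps.append(("clinical", clin_batches[i]))
                if i < len(cons_batches):
                    steps.append(("conservation", cons_batches[i]))
            for task, batch in steps:
                ds = clinical if task == "clinical" else conservation
                loss, val = _task_step(model, ds, batch, task, drop_rng)
                if task == "conservation" and tcfg.task_weight != 1.0:
                    loss = loss * ad.Tensor(np.float32(tcfg.task_weight))
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses[task].append(val)
        else:  # joint_weighted
            n_steps = max(len(clin_batches), len(cons_batches))
            for i in range(n_steps):
                opt.zero_grad()
                total = None
                if i < len(clin_batches):
                    loss, val = _task_step(model, clinical, clin_batches[i],
                                           "clinical", drop_rng)
                    losses["clinical"].append(val)
                    total = loss
                if i < len(cons_batches):
                    loss, val = _task_step(model, conservation, cons_batches[i],
                                           "conservation", drop_rng)
                    losses["conservation"].append(val)
                    w = ad.Tensor(np.float32(tcfg.task_weight))
                    loss = loss * w
                    total = loss if total is None else total + loss
                total.backward()
                opt.step()
        log["clinical"].append(float(np.mean(losses["clinical"])))
        if use_cons:
            log["conservation"].append(float(np.mean(losses["conservation"])))
    return model, log


def cross_validate(
    clinical: FeatureDataset,
    k: int,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    conservation: FeatureDataset | None = None,
    seed: int = 0,
) -> list[dict]:
    """Seeded k-fold cross-validation over the clinical examples.

    Only examples with source ``clinical`` are eligible test points;
    common-population examples join every training fold, and conservation
    data (when given) trains the shared extractor in every fold but is
    never tested. Pathogenic oversampling (``tcfg.oversample_factor``)
    applies inside each training fold only, so duplicates cannot leak into
    a test fold. A fold missing one of the two classes reports a metric
    error instead of numbers.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    sources = np.asarray(clinical.sources)
    eligible = np.flatnonzero(sources == "clinical")
    if len(eligible) < k:
        raise ValueError("fewer clinical examples than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(eligible)
    folds = np.array_split(perm, k)
    results: list[dict] = []
    for fold_i, test_idx in enumerate(folds):
        train_mask = np.ones(len(clinical), dtype=bool)
        train_mask[test_idx] = False
        train_ds = clinical.subset(np.flatnonzero(train_mask))
        test_ds = clinical.subset(test_idx)
        fold_tcfg = TrainConfig(
            epochs=tcfg.epochs, batch_size=tcfg.batch_size,
            learning_rate=tcfg.learning_rate, task_mixing=tcfg.task_mixing,
            task_weight=tcfg.task_weight,
            oversample_factor=tcfg.oversample_factor,
            seed=tcfg.seed + fold_i,
        )
        model, _ = train_multitask(train_ds, conservation, mcfg, fold_tcfg)
        scores = model.predict_proba(test_ds)
        labels = test_ds.labels.astype(int)
        entry: dict = {"fold": fold_i, "n_test": int(len(test_ds))}
        try:
            entry["roc_auc"] = roc_auc(scores, labels)
            entry["pr_auc"] = pr_auc(scores, labels)
        except ValueError as exc:
            entry["error"] = str(exc)
        results.append(entry)
    return results
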
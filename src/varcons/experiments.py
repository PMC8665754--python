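"""Desk-scale reference experiments.

Canned experiment recipes over the synthetic fixtures: a held-out
evaluation of the multitask model and the clinical-data-reduction
comparison that demonstrates the transfer of conservation knowledge into
the clinical task. Both are pure functions of their seeds.

Problem sizes are the package's desk-scale defaults: 30 transcripts of
200 residues, 41-residue windows, ~2000 clinical and ~6000 conservation
examples, a 32-unit recurrent encoder trained for 5 epochs with Adam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fixtures import FixtureConfig, TrainingBundle, make_training_bundle
from .metrics import roc_auc
from .model import ModelConfig
from .training import TrainConfig, train_multitask

__all__ = ["DeskScale", "holdout_split", "multitask_holdout_auc",
           "transfer_comparison"]


@dataclass(frozen=True)
class DeskScale:
    """Default model/training sizes for the desk-scale experiments."""

    lstm_hidden: int = 32
    fc_hidden: int = 32
    epochs: int = 5
    batch_size: int = 64
    learning_rate: float = 3e-3
    oversample_factor: int = 4

    def model_config(self, seed: int, heads=("clinical", "conservation")) -> ModelConfig:
        return ModelConfig(lstm_hidden=self.lstm_hidden, fc_hidden=self.fc_hidden,
                           heads=tuple(heads), seed=seed)

    def train_config(self, seed: int) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                           learning_rate=self.learning_rate,
                           oversample_factor=self.oversample_factor, seed=seed)


def holdout_split(n: int, test_fraction: float, seed: int):
    """Seeded train/test index split."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    return perm[n_test:], perm[:n_test]


def multitask_holdout_auc(
    bundle: TrainingBundle | None = None,
    seed: int = 0,
    scale: DeskScale | None = None,
    test_fraction: float = 0.2,
) -> dict:
    """Train the multitask model and report held-out clinical ROC-AUC."""
    scale = scale or DeskScale()
    if bundle is None:
        bundle = make_training_bundle(FixtureConfig(seed=seed))
    train_idx, test_idx = holdout_split(len(bundle.clinical), test_fraction,
                                        seed + 1)
    train_ds = bundle.clinical.subset(train_idx)
    test_ds = bundle.clinical.subset(test_idx)
    model, log = train_multitask(train_ds, bundle.conservation,
                                 scale.model_config(seed),
                                 scale.train_config(seed))
    scores = model.predict_proba(test_ds)
    return {
        "roc_auc": roc_auc(scores, test_ds.labels.astype(int)),
        "n_train": int(len(train_ds)),
        "n_test": int(len(test_ds)),
        "loss_log": log,
    }


def transfer_comparison(
    bundle: TrainingBundle | None = None,
    seed: int = 0,
    n_clinical: int = 200,
    n_seeds: int = 3,
    scale: DeskScale | None = None,
    test_fraction: float = 0.2,
) -> dict:
    """Multitask vs clinical-only with scarce clinical data.

    Reduces the clinical training set to ``n_clinical`` examples and
    compares, over ``n_seeds`` seeds, the held-out clinical ROC-AUC of the
    multitask model (which also trains the shared extractor on
    conservation data) against a clinical-only single-task model. The
    held-out set is the full-size test split in both arms.
    """
    scale = scale or DeskScale()
    if bundle is None:
        bundle = make_training_bundle(FixtureConfig(seed=seed))
    train_idx, test_idx = holdout_split(len(bundle.clinical), test_fraction,
                                        seed + 1)
    test_ds = bundle.clinical.subset(test_idx)
    multi_aucs, single_aucs = [], []
    for i in range(n_seeds):
        s = seed + 10 * (i + 1)
        rng = np.random.default_rng(s)
        small_idx = rng.choice(train_idx, size=min(n_clinical, len(train_idx)),
                               replace=False)
        small_ds = bundle.clinical.subset(small_idx)
        m_multi, _ = train_multitask(small_ds, bundle.conservation,
                                     scale.model_config(s),
                                     scale.train_config(s))
        multi_aucs.append(roc_auc(m_multi.predict_proba(test_ds),
                                  test_ds.labels.astype(int)))
        m_single, _ = train_multitask(small_ds, None,
                                      scale.model_config(s, heads=("clinical",)),
                                      scale.train_config(s))
        single_aucs.append(roc_auc(m_single.predict_proba(test_ds),
                                   test_ds.labels.astype(int)))
    return {
        "multitask_aucs": multi_aucs,
        "single_task_aucs": single_aucs,
        "multitask_median": float(np.median(multi_aucs)),
        "single_task_median": float(np.median(single_aucs)),
        "n_clinical": int(n_clinical),
        "n_seeds": int(n_seeds),
    }
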
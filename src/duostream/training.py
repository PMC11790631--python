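"""Staged transfer-learning training and the repeated-split experiment
protocol.

Stage 1 freezes the 13 shallow conv layers per stream (transferred weights)
and trains the deep fusion part; stage 2 unfreezes everything and fine-tunes
at a lower learning rate.  After every epoch the model is evaluated on the
validation set and the best-accuracy checkpoint is kept.  The experiment
protocol re-randomizes the 6:2:2 split, re-initializes, trains, and
evaluates on the test split for each repeat; per-repeat seeds derive from
the run seed as ``seed + repeat_index``.

Two profiles ship:

* the canonical schedule — 224x224 inputs, 20 epochs at lr 1e-3 then 30 at
  1e-4, batch 24, Adam;
* a desk-scale ``fast`` schedule — 32x32 inputs, reduced channels, 5 + 10
  epochs at lr 3e-3 / 1e-3, batch 8 — small enough for a laptop-class CPU
  while exercising every code path.

Frozen batch-norm layers keep updating their running statistics (only the
learnable tensors are excluded from gradient updates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .datasets import DatasetManifest, SplitSpec, derive_repeat_seed, load_view_pair, split_dataset
from .evaluation import EvalReport, evaluate_predictions
from .model import (
    ModelSpec,
    TwoStreamNet,
    build_two_stream,
    count_parameters,
    get_state,
    set_state,
    shallow_conv_layer_count,
)
from .preprocess import PreprocessConfig, preprocess_pipeline


@dataclass(frozen=True)
class StageSchedule:
    frozen_conv_layers: int
    epochs: int
    learning_rate: float
    batch_size: int = 24
    optimizer: str = "adam"

    def __post_init__(self):
        if self.epochs <= 0 or self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("epochs, learning_rate and batch_size must be positive")
        if self.optimizer not in nn.OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def default_schedules(optimizer: str = "adam"):
    """The canonical staged schedule: freeze 13 / 20 epochs @1e-3, then full
    fine-tuning / 30 epochs @1e-4, batch 24."""
    return (
        StageSchedule(13, 20, 1e-3, 24, optimizer),
        StageSchedule(0, 30, 1e-4, 24, optimizer),
    )


def fast_schedules(optimizer: str = "adam"):
    """Desk-scale schedule for the reduced 32x32 profile."""
    return (
        StageSchedule(13, 5, 3e-3, 8, optimizer),
        StageSchedule(0, 10, 1e-3, 8, optimizer),
    )


@dataclass(frozen=True)
class ExperimentProtocol:
    n_repeats: int = 50
    split: SplitSpec = field(default_factory=SplitSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


# ---------------------------------------------------------------------------
# initialization and freezing
# ---------------------------------------------------------------------------

def shallow_units(model: TwoStreamNet, n_conv_layers: int):
    """(conv, bn) units of the first ``n_conv_layers`` conv layers, all streams."""
    units = []
    for stream in model.streams():
        per_layer = model.conv_units(stream)
        for layer_units in per_layer[:n_conv_layers]:
            units.extend(layer_units)
    return units


def extract_shallow_state(model: TwoStreamNet, n_conv_layers: int | None = None):
    """Shallow conv/bn weights as a flat dict (the transferable state)."""
    if n_conv_layers is None:
        n_conv_layers = shallow_conv_layer_count(model.spec)
    state = {}
    for i, (conv, bn) in enumerate(shallow_units(model, n_conv_layers)):
        state[f"unit{i:03d}/weight"] = conv.weight.data.copy()
        state[f"unit{i:03d}/gamma"] = bn.gamma.data.copy()
        state[f"unit{i:03d}/beta"] = bn.beta.data.copy()
        state[f"unit{i:03d}/running_mean"] = bn.running_mean.copy()
        state[f"unit{i:03d}/running_var"] = bn.running_var.copy()
    return state


def init_from_pretrained(model: TwoStreamNet, source=None, random_fallback: bool = False,
                         rng: np.random.Generator | int | None = None) -> TwoStreamNet:
    """Initialize the shallow layers from a transferred weight dict.

    ``source`` is a dict as produced by :func:`extract_shallow_state` (e.g.
    loaded from a caller-supplied file of ImageNet-pretrained weights).  With
    ``random_fallback`` the shallow layers are re-drawn from ``rng`` instead,
    which keeps the staged protocol runnable fully offline.  Deep layers are
    left at their (seeded) fresh initialization.
    """
    n_shallow = shallow_conv_layer_count(model.spec)
    units = shallow_units(model, n_shallow)
    if source is not None:
        for i, (conv, bn) in enumerate(units):
            w = np.asarray(source[f"unit{i:03d}/weight"])
            if w.shape != conv.weight.data.shape:
                raise ValueError(
                    f"shape mismatch for unit {i}: source {w.shape} vs model {conv.weight.data.shape}"
                )
            conv.weight.data = w.astype(np.float64).copy()
            bn.gamma.data = np.asarray(source[f"unit{i:03d}/gamma"], dtype=np.float64).copy()
            bn.beta.data = np.asarray(source[f"unit{i:03d}/beta"], dtype=np.float64).copy()
            bn.running_mean = np.asarray(source[f"unit{i:03d}/running_mean"], dtype=np.float64).copy()
            bn.running_var = np.asarray(source[f"unit{i:03d}/running_var"], dtype=np.float64).copy()
    elif random_fallback:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        for conv, bn in units:
            f, c, kh, kw = conv.weight.data.shape
            std = np.sqrt(2.0 / (c * kh * kw))
            conv.weight.data = rng.normal(0.0, std, size=(f, c, kh, kw))
            bn.gamma.data = np.ones(f)
            bn.beta.data = np.zeros(f)
            bn.running_mean = np.zeros(f)
            bn.running_var = np.ones(f)
    else:
        raise ValueError("provide a weight source or set random_fallback=True")
    return model


def freeze_shallow(model: TwoStreamNet, n_conv_layers: int) -> TwoStreamNet:
    """Exclude the first ``n_conv_layers`` conv layers (+ their batch-norm
    parameters) per stream from gradient updates; everything else trainable."""
    per_stream = len(model.conv_units(model.streams()[0]))
    if n_conv_layers > per_stream:
        raise ValueError(f"cannot freeze {n_conv_layers} of {per_stream} conv layers")
    for p in model.parameters():
        p.trainable = True
        p.requires_grad = True
    for conv, bn in shallow_units(model, n_conv_layers):
        for p in (conv.weight, bn.gamma, bn.beta):
            p.trainable = False
            p.requires_grad = False
    return model


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def prepare_arrays(manifest: DatasetManifest, config: PreprocessConfig,
                   rng: np.random.Generator | None = None, cache: dict | None = None):
    """Preprocess every pair into batched NCHW arrays + integer labels.

    ``cache`` (pair_id -> ViewPair) is honored only for non-augmenting
    configs, where preprocessing is deterministic.
    """
    fronts, backs, labels = [], [], []
    label_index = {c: i for i, c in enumerate(manifest.classes)}
    for record in manifest.records:
        key = record.pair_id
        if cache is not None and not config.augment and key in cache:
            vp = cache[key]
        else:
            vp = preprocess_pipeline(load_view_pair(record), config, rng, pair_id=key)
            if cache is not None and not config.augment:
                cache[key] = vp
        fronts.append(vp.front.transpose(2, 0, 1))
        backs.append(vp.back.transpose(2, 0, 1))
        labels.append(label_index[record.class_label])
    return np.stack(fronts), np.stack(backs), np.asarray(labels, dtype=np.int64)


def _accuracy(model: TwoStreamNet, data, batch_size: int = 32) -> float:
    fronts, backs, labels = data
    model.eval()
    correct = 0
    for i in range(0, len(labels), batch_size):
        logits = model.forward(fronts[i : i + batch_size], backs[i : i + batch_size]).data
        correct += int((logits.argmax(axis=1) == labels[i : i + batch_size]).sum())
    return correct / len(labels)


def predict(model: TwoStreamNet, data, batch_size: int = 32) -> np.ndarray:
    fronts, backs, labels = data
    model.eval()
    preds = []
    for i in range(0, len(labels), batch_size):
        logits = model.forward(fronts[i : i + batch_size], backs[i : i + batch_size]).data
        preds.append(logits.argmax(axis=1))
    return np.concatenate(preds)


# ---------------------------------------------------------------------------
# staged training
# ---------------------------------------------------------------------------

def train_staged(model: TwoStreamNet, train_data, val_data, schedules,
                 rng: np.random.Generator | int | None = None):
    """Run the staged schedule; returns (model@best-checkpoint, history).

    ``train_data``/``val_data`` are (front NCHW, back NCHW, labels) triples.
    After every epoch the validation accuracy decides the kept checkpoint,
    so the returned model's validation accuracy is >= the final epoch's.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    fronts, backs, labels = train_data
    if len(labels) == 0 or len(val_data[2]) == 0:
        raise ValueError("train and validation sets must be non-empty")
    best_acc, best_state = -1.0, None
    history = []
    for stage_idx, sched in enumerate(schedules, start=1):
        freeze_shallow(model, sched.frozen_conv_layers)
        opt = nn.OPTIMIZERS[sched.optimizer](model.parameters(), lr=sched.learning_rate)
        for epoch in range(1, sched.epochs + 1):
            model.train()
            order = rng.permutation(len(labels))
            losses = []
            for i in range(0, len(order), sched.batch_size):
                idx = order[i : i + sched.batch_size]
                loss = nn.cross_entropy(
                    model.forward(fronts[idx], backs[idx]), labels[idx]
                )
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at stage {stage_idx} epoch {epoch}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            val_acc = _accuracy(model, val_data)
            history.append(
                {
                    "stage": stage_idx,
                    "epoch": epoch,
                    "train_loss": float(np.mean(losses)),
                    "val_accuracy": val_acc,
                }
            )
            if val_acc > best_acc:
                best_acc = val_acc
                best_state = get_state(model)
    set_state(model, best_state)
    freeze_shallow(model, 0)
    return model, history


def evaluate_model(model: TwoStreamNet, data, classes) -> EvalReport:
    """Test-set evaluation: confusion-based metrics + parameter count."""
    preds = predict(model, data)
    y_true = [classes[i] for i in data[2]]
    y_pred = [classes[i] for i in preds]
    report = evaluate_predictions(y_true, y_pred, classes)
    report.param_count = count_parameters(model)
    return report


# ---------------------------------------------------------------------------
# repeated-split experiments and the ablation grid
# ---------------------------------------------------------------------------

@dataclass
class RepeatedResult:
    reports: list
    histories: list

    def metric_frame(self) -> pd.DataFrame:
        rows = [
            {
                "repeat": i,
                "accuracy": r.accuracy,
                "recall_macro": r.recall_macro,
                "f1_macro": r.f1_macro,
                "std_between_classes": r.std_between_classes,
            }
            for i, r in enumerate(self.reports)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        df = self.metric_frame()
        return {
            "mean_accuracy": float(df["accuracy"].mean()),
            "std_accuracy": float(df["accuracy"].std(ddof=0)),
            "mean_recall_macro": float(df["recall_macro"].mean()),
            "mean_f1_macro": float(df["f1_macro"].mean()),
            "mean_std_between_classes": float(df["std_between_classes"].mean()),
            "n_repeats": len(self.reports),
        }


def run_single_experiment(manifest: DatasetManifest, model_spec: ModelSpec,
                          config: PreprocessConfig, schedules, seed: int,
                          cache: dict | None = None, pretrained_source=None):
    """One split -> init -> staged training -> test evaluation."""
    split = SplitSpec(seed=seed)
    train_m, val_m, test_m = split_dataset(manifest, split)
    rng = np.random.default_rng(seed)
    aug_rng = np.random.default_rng(derive_repeat_seed(seed, 104729))
    train_data = prepare_arrays(train_m, config, aug_rng, cache)
    eval_config = replace(config, augment=False)
    val_data = prepare_arrays(val_m, eval_config, cache=cache)
    test_data = prepare_arrays(test_m, eval_config, cache=cache)
    model = build_two_stream(model_spec, rng=np.random.default_rng(derive_repeat_seed(seed, 1)))
    if pretrained_source is not None:
        init_from_pretrained(model, source=pretrained_source)
    else:
        init_from_pretrained(model, random_fallback=True,
                             rng=np.random.default_rng(derive_repeat_seed(seed, 2)))
    model, history = train_staged(model, train_data, val_data, schedules,
                                  rng=np.random.default_rng(derive_repeat_seed(seed, 3)))
    report = evaluate_model(model, test_data, manifest.classes)
    return model, report, history


def run_repeated_experiment(manifest: DatasetManifest, model_spec: ModelSpec,
                            protocol: ExperimentProtocol, config: PreprocessConfig,
                            schedules, pretrained_source=None) -> RepeatedResult:
    """Fresh split + fresh init + staged training + test metrics per repeat."""
    reports, histories = [], []
    cache: dict = {}
    for r in range(protocol.n_repeats):
        seed = derive_repeat_seed(protocol.seed, r)
        _, report, history = run_single_experiment(
            manifest, model_spec, config, schedules, seed,
            cache=cache, pretrained_source=pretrained_source,
        )
        reports.append(report)
        histories.append(history)
    return RepeatedResult(reports=reports, histories=histories)


ABLATION_ROWS = (
    ("front_only", dict(mode="front_only")),
    ("back_only", dict(mode="back_only")),
    ("concat_only", dict(mode="concat_only")),
    ("conv_cross_only", dict(mode="conv_cross_only")),
    ("alpha_1", dict(mode="two_stream_full", fusion_alpha=1.0)),
    ("alpha_1_2", dict(mode="two_stream_full", fusion_alpha=0.5)),
    ("alpha_1_4", dict(mode="two_stream_full", fusion_alpha=0.25)),
    ("alpha_1_3", dict(mode="two_stream_full", fusion_alpha=1.0 / 3.0)),
)


def default_ablation_grid(base_spec: ModelSpec):
    """The 8 ablation variants: front/back only, plain concat, conv-level
    cross residuals only, and the full model at alpha = 1, 1/2, 1/4, 1/3."""
    grid = []
    for name, overrides in ABLATION_ROWS:
        grid.append((name, replace(base_spec, **overrides)))
    return grid


def run_ablation_grid(manifest: DatasetManifest, protocol: ExperimentProtocol,
                      grid, config: PreprocessConfig, schedules) -> pd.DataFrame:
    """One aggregate row per variant, in percent scale (Acc/Recall/F1/STD)."""
    rows = []
    for name, spec in grid:
        result = run_repeated_experiment(manifest, spec, protocol, config, schedules)
        s = result.summary()
        rows.append(
            {
                "method": name,
                "acc_pct": 100 * s["mean_accuracy"],
                "recall_pct": 100 * s["mean_recall_macro"],
                "f1_pct": 100 * s["mean_f1_macro"],
                "std_pct_points": s["mean_std_between_classes"],
            }
        )
    return pd.DataFrame(rows)
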
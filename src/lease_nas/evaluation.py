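"""Metric panel and from-scratch retraining of a derived genotype.

Metrics follow the multi-class panel used for the brain-tumor task:
accuracy, precision, recall, F1, specificity and AUC, each computed
one-vs-rest per class and macro-averaged (unweighted mean over classes),
reported as percentages. Predictions are argmax with ties resolved to the
lowest class index; AUC uses the rank-based (midrank-tie) computation.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from .autograd import Tensor, no_grad
from . import nn
from .explanations import LabeledBatch
from .search_space import Genotype, build_eval_network, count_parameters

__all__ = ["MetricsReport", "compute_metrics", "train_final", "predict_proba"]


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_specificity: float
    macro_auc: float
    per_class: Dict[str, List[float]]
    confusion_matrix: List[List[int]]
    n_parameters: Optional[int] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @staticmethod
    def from_json(text: str) -> "MetricsReport":
        return MetricsReport(**json.loads(text))

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["metric", "value"])
        for name in ("accuracy", "macro_precision", "macro_recall", "macro_f1",
                     "macro_specificity", "macro_auc"):
            writer.writerow([name, f"{getattr(self, name):.4f}"])
        if self.n_parameters is not None:
            writer.writerow(["n_parameters", self.n_parameters])
        return buf.getvalue()


def compute_metrics(y_true, y_prob) -> MetricsReport:
    """Score class-probability predictions against integer labels."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if y_prob.ndim != 2 or len(y_true) != y_prob.shape[0]:
        raise ValueError("y_prob must be [N, K] aligned with y_true")
    if len(y_true) < 1:
        raise ValueError("need at least one example")
    n, k = y_prob.shape
    row_sums = y_prob.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-4):
        raise ValueError("probability rows must sum to 1")

    y_pred = np.argmax(y_prob, axis=1)  # ties resolve to the lowest index
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)

    precision, recall, f1, specificity, auc = [], [], [], [], []
    for c in range(k):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        tn = n - tp - fp - fn
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        precision.append(p)
        recall.append(r)
        f1.append(2 * p * r / (p + r) if p + r else 0.0)
        specificity.append(tn / (tn + fp) if tn + fp else 0.0)
        mask = y_true == c
        if mask.any() and not mask.all():
            auc.append(roc_auc_score(mask.astype(int), y_prob[:, c]))
        else:
            warnings.warn(
                f"class {c} absent from y_true (or the only class); its "
                "one-vs-rest AUC is undefined and excluded from the macro"
            )
            auc.append(np.nan)
    auc_arr = np.asarray(auc)
    defined = auc_arr[~np.isnan(auc_arr)]
    macro_auc = float(defined.mean()) * 100.0 if len(defined) else float("nan")

    return MetricsReport(
        accuracy=100.0 * float(np.trace(cm)) / n,
        macro_precision=100.0 * float(np.mean(precision)),
        macro_recall=100.0 * float(np.mean(recall)),
        macro_f1=100.0 * float(np.mean(f1)),
        macro_specificity=100.0 * float(np.mean(specificity)),
        macro_auc=macro_auc,
        per_class={
            "precision": [100.0 * v for v in precision],
            "recall": [100.0 * v for v in recall],
            "f1": [100.0 * v for v in f1],
            "specificity": [100.0 * v for v in specificity],
            "auc": [100.0 * v if np.isfinite(v) else float("nan") for v in auc],
        },
        confusion_matrix=cm.tolist(),
    )


def predict_proba(net, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Class probabilities of a trained network, in eval mode."""
    from .autograd import softmax

    net.eval()
    probs = []
    with no_grad():
        for start in range(0, len(images), batch_size):
            logits = net(Tensor(images[start : start + batch_size]))
            probs.append(softmax(logits, axis=-1).data)
    net.train()
    return np.concatenate(probs, axis=0)


def train_final(genotype: Genotype, train: LabeledBatch, test: LabeledBatch,
                epochs: int = 3000, batch_size: int = 96,
                init_channels: int = 36, layers: int = 12,
                lr: float = 0.025, momentum: float = 0.9,
                weight_decay: float = 3e-4, seed: int = 0,
                augment=None, log=None):
    """Retrain the discrete network from scratch and score it on the test set.

    Defaults mirror the full-scale evaluation configuration (12 cells, 36
    initial channels, batch 96); desk-scale runs pass smaller values.
    ``augment`` is an optional callable ``(images, rng) -> images`` applied
    to each training minibatch.
    """
    if len(train) == 0 or len(test) == 0:
        raise ValueError("train and test sets must be non-empty")
    num_classes = int(max(train.labels.max(), test.labels.max())) + 1
    in_channels = train.images.shape[1]
    net = build_eval_network(genotype, layers=layers, init_channels=init_channels,
                             num_classes=num_classes, in_channels=in_channels,
                             seed=seed)
    opt = nn.SGD(net.parameters(), lr=lr, momentum=momentum,
                 weight_decay=weight_decay)
    rng = np.random.default_rng(seed)
    for epoch in range(epochs):
        opt.lr = nn.cosine_lr(lr, epoch, epochs)
        order = rng.permutation(len(train))
        losses = []
        for start in range(0, len(train), batch_size):
            idx = order[start : start + batch_size]
            xb = train.images[idx]
            if augment is not None:
                xb = augment(xb, rng)
            loss = nn.cross_entropy(net(Tensor(xb)), train.labels[idx])
            net.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        if log is not None:
            log(epoch, float(np.mean(losses)))
    probs = predict_proba(net, test.images, batch_size)
    report = compute_metrics(test.labels, probs)
    report.n_parameters = count_parameters(net)
    return net, report
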
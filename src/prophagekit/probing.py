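"""Probes over frozen embeddings.

Measures how much phage/bacteria class information a fixed embedding carries:
a linear probe (affine map + sigmoid) tests linear accessibility and a small
two-hidden-layer feed-forward network tests nonlinear structure.  Both are
trained by minibatch gradient descent (Adam) on binary cross-entropy, with
the epoch maximizing dev-set MCC retained.  The headline statistic is the
difference in test MCC between a probe on pretrained embeddings and the same
probe on embeddings from an identically shaped randomly initialized model:
positive values quantify the representational gain attributable to
pretraining.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .core import ConfusionCounts
from .errors import FormatError, ValidationError
from .evaluation import mcc

PROBE_KINDS = ("linear", "mlp")


@dataclass
class EmbeddingSet:
    """A labeled embedding matrix for one split (phage = 1, bacteria = 0)."""

    matrix: np.ndarray
    labels: np.ndarray
    provenance: str = "pretrained"
    split: str = "train"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.labels.shape[0]:
            raise ValidationError("matrix rows and labels must align")
        if self.matrix.shape[0] < 1:
            raise ValidationError("embedding set must contain >= 1 sample")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("embedding matrix contains non-finite entries")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be binary (0/1)")

    @property
    def n_samples(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1])


@dataclass(frozen=True)
class ProbeResult:
    probe_kind: str
    test_mcc: float
    dev_mcc: float
    seed: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.test_mcc <= 1.0 + 1e-9:
            raise ValidationError("MCC out of [-1, 1]")


@dataclass(frozen=True)
class ProbeConfig:
    """Training hyperparameters shared by both probe kinds."""

    hidden_sizes: tuple[int, int] = (256, 64)
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    standardize: bool = False
    class_weight: bool = False


class Probe:
    """A fitted probe: stack of affine layers (ReLU between) + sigmoid."""

    def __init__(
        self,
        kind: str,
        weights: list[np.ndarray],
        biases: list[np.ndarray],
        mean: np.ndarray | None = None,
        scale: np.ndarray | None = None,
    ) -> None:
        self.kind = kind
        self.weights = weights
        self.biases = biases
        self.mean = mean
        self.scale = scale

    @property
    def dim(self) -> int:
        return int(self.weights[0].shape[0])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.dim:
            raise ValidationError(
                f"embedding dim {X.shape[1]} != probe dim {self.dim}"
            )
        if self.mean is not None:
            X = (X - self.mean) / self.scale
        h = X
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < len(self.weights) - 1:
                h = np.maximum(h, 0.0)
        z = np.clip(h[:, 0], -60, 60)
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class predictions at the fixed 0.5 probability threshold."""
        return (self.predict_proba(X) >= 0.5).astype(int)


def _mcc_of(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return mcc(
        ConfusionCounts(
            tp=int(np.sum((y_pred == 1) & (y_true == 1))),
            fp=int(np.sum((y_pred == 1) & (y_true == 0))),
            fn=int(np.sum((y_pred == 0) & (y_true == 1))),
            tn=int(np.sum((y_pred == 0) & (y_true == 0))),
        )
    )


def _init_layers(
    dims: list[int], rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        # He-style scaling, appropriate for the ReLU hidden layers
        weights.append(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    return weights, biases


def train_probe(
    train: EmbeddingSet,
    dev: EmbeddingSet,
    kind: str = "linear",
    config: ProbeConfig | None = None,
    seed: int = 0,
) -> tuple[Probe, ProbeResult]:
    """Fit a probe by Adam on binary cross-entropy, selecting on dev MCC.

    Deterministic given the seed.  Raises when the training set contains a
    single class or the train/dev dimensions disagree.
    """
    if kind not in PROBE_KINDS:
        raise ValidationError(f"probe kind must be one of {PROBE_KINDS}")
    config = config or ProbeConfig()
    if train.dim != dev.dim:
        raise ValidationError(f"train dim {train.dim} != dev dim {dev.dim}")
    if len(np.unique(train.labels)) < 2:
        raise ValidationError("training set must contain both classes")
    rng = np.random.default_rng(seed)
    X, y = train.matrix, train.labels.astype(float)
    mean = scale = None
    if config.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        X = (X - mean) / scale
    sample_w = np.ones_like(y)
    if config.class_weight:
        n_pos = y.sum()
        n_neg = y.size - n_pos
        sample_w = np.where(y == 1, y.size / (2 * n_pos), y.size / (2 * n_neg))
    dims = [train.dim, 1] if kind == "linear" else [
        train.dim, *config.hidden_sizes, 1
    ]
    weights, biases = _init_layers(dims, rng)
    # Adam state
    mW = [np.zeros_like(w) for w in weights]
    vW = [np.zeros_like(w) for w in weights]
    mB = [np.zeros_like(b) for b in biases]
    vB = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    n = X.shape[0]
    best_dev = -np.inf
    best_params: tuple[list[np.ndarray], list[np.ndarray]] | None = None
    epochs_since_best = 0
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb, yb, wb = X[idx], y[idx], sample_w[idx]
            # forward
            acts = [xb]
            h = xb
            for i, (W, b) in enumerate(zip(weights, biases)):
                h = h @ W + b
                if i < len(weights) - 1:
                    h = np.maximum(h, 0.0)
                acts.append(h)
            z = np.clip(acts[-1][:, 0], -60, 60)
            p = 1.0 / (1.0 + np.exp(-z))
            # backward: d(BCE)/dz = p - y, weighted
            delta = ((p - yb) * wb / len(yb))[:, None]
            t += 1
            for i in range(len(weights) - 1, -1, -1):
                gW = acts[i].T @ delta
                gB = delta.sum(axis=0)
                if i > 0:
                    delta = (delta @ weights[i].T) * (acts[i] > 0)
                mW[i] = beta1 * mW[i] + (1 - beta1) * gW
                vW[i] = beta2 * vW[i] + (1 - beta2) * gW**2
                mB[i] = beta1 * mB[i] + (1 - beta1) * gB
                vB[i] = beta2 * vB[i] + (1 - beta2) * gB**2
                lr_t = config.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
                weights[i] -= lr_t * mW[i] / (np.sqrt(vW[i]) + eps)
                biases[i] -= lr_t * mB[i] / (np.sqrt(vB[i]) + eps)
        probe = Probe(kind, weights, biases, mean, scale)
        dev_mcc = _mcc_of(dev.labels, probe.predict(dev.matrix))
        # ties keep the later epoch: more training at equal dev performance
        if dev_mcc >= best_dev:
            best_dev = dev_mcc
            best_params = (
                [w.copy() for w in weights], [b.copy() for b in biases]
            )
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best > config.patience:
                break
    assert best_params is not None
    probe = Probe(kind, best_params[0], best_params[1], mean, scale)
    # test_mcc is filled in by evaluate_probe; this result carries the fit
    return probe, ProbeResult(kind, 0.0, float(best_dev), seed)


def evaluate_probe(
    probe: Probe, test: EmbeddingSet, dev_mcc: float = 0.0, seed: int = 0
) -> ProbeResult:
    """Test-set MCC at the fixed 0.5 probability threshold."""
    if test.n_samples == 0:
        raise ValidationError("empty test set")
    test_mcc = _mcc_of(test.labels, probe.predict(test.matrix))
    return ProbeResult(probe.kind, float(test_mcc), float(dev_mcc), seed)


def delta_mcc(pretrained: ProbeResult, random_init: ProbeResult) -> float:
    """Representational gain from pretraining: MCC difference of twin probes."""
    if pretrained.probe_kind != random_init.probe_kind:
        raise ValidationError(
            f"probe kinds differ: {pretrained.probe_kind} vs {random_init.probe_kind}"
        )
    return pretrained.test_mcc - random_init.test_mcc


def run_probe_experiment(
    train: EmbeddingSet,
    dev: EmbeddingSet,
    test: EmbeddingSet,
    kind: str = "linear",
    config: ProbeConfig | None = None,
    seed: int = 0,
) -> ProbeResult:
    """Train on train/dev, report test MCC: the full probing protocol."""
    probe, fit = train_probe(train, dev, kind=kind, config=config, seed=seed)
    return evaluate_probe(probe, test, dev_mcc=fit.dev_mcc, seed=seed)


def read_embedding_sets(
    matrix_path: str | Path, sidecar_path: str | Path
) -> dict[str, EmbeddingSet]:
    """Load a delimited numeric matrix plus its sidecar label table.

    Sidecar columns: segment_id, label, split, provenance (one row per
    matrix row).  Returns one EmbeddingSet per split.
    """
    X = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
    side = pd.read_csv(sidecar_path, sep="\t")
    required = {"segment_id", "label", "split", "provenance"}
    missing = required - set(side.columns)
    if missing:
        raise FormatError(f"{sidecar_path}: missing columns {sorted(missing)}")
    if len(side) != X.shape[0]:
        raise FormatError(
            f"matrix has {X.shape[0]} rows but sidecar has {len(side)}"
        )
    out: dict[str, EmbeddingSet] = {}
    for split, grp in side.groupby("split"):
        idx = grp.index.to_numpy()
        prov = grp["provenance"].iloc[0]
        out[str(split)] = EmbeddingSet(
            matrix=X[idx], labels=grp["label"].to_numpy(dtype=int),
            provenance=str(prov), split=str(split),
        )
    return out
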
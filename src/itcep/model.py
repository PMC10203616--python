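"""The dual-input convolutional classifier: build, train, persist, predict.

Module 1 convolves the single-residue map of the concatenated pair;
Module 2 convolves the distribution map. Each module ends in a dense
layer; the two module outputs are concatenated and passed through two
L2-regularized dense layers, dropout, and a 2-way softmax. Training
minimizes MSE between the softmax output and one-hot labels with Adagrad.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from itcep.alphabet import AMINO_ACIDS, CDR3_MAX_LEN, CDR3_MIN_LEN, PEPTIDE_MAX_LEN, PEPTIDE_MIN_LEN, is_valid_sequence
from itcep.encoders import (
    AAPPTable,
    PhychemTable,
    FUSION_SCHEMES,
    fuse_pair,
)
from itcep.io_data import PairRecord
from itcep import nn

__all__ = [
    "ModelConfig",
    "ItcepNetwork",
    "TrainedModel",
    "PredictionRecord",
    "build_itcep_model",
    "train_model",
    "encode_features",
    "predict_pairs",
    "rank_tcrs_for_peptide",
    "assign_binding_level",
    "write_prediction_csv",
]

# Binding-level thresholds on the predicted interaction probability.
INTERACTION_THRESHOLD = 0.5
LOW_MEDIUM_THRESHOLD = 0.8
MEDIUM_HIGH_THRESHOLD = 0.95


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters with published defaults."""

    scheme: str = "onehot-aapp"
    module1_conv1_filters: int = 16
    module1_conv1_kernel: tuple[int, int] = (3, 2)
    module1_conv2_filters: int = 32
    module1_conv2_kernel: tuple[int, int] = (6, 4)
    module2_conv_filters: int = 16
    module2_conv_kernel: tuple[int, int] = (1, 2)
    pool_kernel: int = 2
    pool_stride: int = 1
    module_dense: int = 128
    fusion_dense: tuple[int, int] = (256, 128)
    l2_penalty: float = 0.01
    dropout: float = 0.3
    optimizer: str = "adagrad"
    learning_rate: float = 0.01
    loss: str = "mse"
    epochs: int = 60
    batch_size: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.scheme not in FUSION_SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.pool_kernel != 2 or self.pool_stride != 1:
            raise ValueError("only pooling kernel 2 with stride 1 is supported")
        if self.optimizer != "adagrad" or self.loss != "mse":
            raise ValueError("only the Adagrad optimizer with MSE loss is supported")
        for width in (self.module_dense, *self.fusion_dense):
            if width <= 0:
                raise ValueError("dense widths must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["module1_conv1_kernel"] = list(self.module1_conv1_kernel)
        d["module1_conv2_kernel"] = list(self.module1_conv2_kernel)
        d["module2_conv_kernel"] = list(self.module2_conv_kernel)
        d["fusion_dense"] = list(self.fusion_dense)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for k in ("module1_conv1_kernel", "module1_conv2_kernel", "module2_conv_kernel", "fusion_dense"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class PredictionRecord:
    """One scored pair. ``error`` is set (and the numeric fields are None)
    for pairs that fail the curation invariants."""

    peptide: str
    cdr3: str
    probability: float | None
    interaction: int | None
    binding_level: str | None
    error: str | None = None


def _conv_out(shape: tuple[int, int], kernel: tuple[int, int]) -> tuple[int, int]:
    h, w = shape
    kh, kw = kernel
    oh, ow = h - kh + 1, w - kw + 1
    if oh <= 0 or ow <= 0:
        raise ValueError(f"kernel {kernel} does not fit input {shape}")
    return oh, ow


class ItcepNetwork:
    """Two convolutional branches whose dense outputs are concatenated into
    a shared fully connected head ending in a 2-way softmax."""

    def __init__(self, config: ModelConfig, module1_shape: tuple[int, int], module2_shape: tuple[int, int]):
        config.validate()
        self.config = config
        self.module1_shape = module1_shape
        self.module2_shape = module2_shape
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(config.seed + 1)

        # Branch 1: conv -> BN -> ReLU -> conv -> ReLU -> pool -> BN -> ReLU
        s = _conv_out(module1_shape, config.module1_conv1_kernel)
        s2 = _conv_out(s, config.module1_conv2_kernel)
        p2 = _conv_out(s2, (2, 2))
        flat1 = p2[0] * p2[1] * config.module1_conv2_filters
        self.branch1 = nn.Sequential(
            [
                nn.Conv2D(1, config.module1_conv1_filters, config.module1_conv1_kernel, rng),
                nn.BatchNorm(config.module1_conv1_filters),
                nn.ReLU(),
                nn.Conv2D(config.module1_conv1_filters, config.module1_conv2_filters, config.module1_conv2_kernel, rng),
                nn.ReLU(),
                nn.MaxPool2x2(),
                nn.BatchNorm(config.module1_conv2_filters),
                nn.ReLU(),
                nn.Flatten(),
                nn.Dense(flat1, config.module_dense, rng),
                nn.ReLU(),
            ]
        )

        # Branch 2: conv -> ReLU -> pool -> BN -> ReLU
        t = _conv_out(module2_shape, config.module2_conv_kernel)
        tp = _conv_out(t, (2, 2))
        flat2 = tp[0] * tp[1] * config.module2_conv_filters
        self.branch2 = nn.Sequential(
            [
                nn.Conv2D(1, config.module2_conv_filters, config.module2_conv_kernel, rng),
                nn.ReLU(),
                nn.MaxPool2x2(),
                nn.BatchNorm(config.module2_conv_filters),
                nn.ReLU(),
                nn.Flatten(),
                nn.Dense(flat2, config.module_dense, rng),
                nn.ReLU(),
            ]
        )

        d1, d2 = config.fusion_dense
        self.head = nn.Sequential(
            [
                nn.Dense(2 * config.module_dense, d1, rng, l2=config.l2_penalty),
                nn.ReLU(),
                nn.Dense(d1, d2, rng, l2=config.l2_penalty),
                nn.ReLU(),
                nn.Dropout(config.dropout, self._dropout_rng),
                nn.Dense(d2, 2, rng),
            ]
        )

    # -- forward/backward -------------------------------------------------
    def forward(self, x1: np.ndarray, x2: np.ndarray, training: bool = False) -> np.ndarray:
        f1 = self.branch1.forward(x1, training)
        f2 = self.branch2.forward(x2, training)
        return self.head.forward(np.concatenate([f1, f2], axis=1), training)

    def backward(self, dlogits: np.ndarray) -> None:
        dconcat = self.head.backward(dlogits)
        w = self.config.module_dense
        self.branch1.backward(dconcat[:, :w])
        self.branch2.backward(dconcat[:, w:])

    def params(self) -> list[np.ndarray]:
        return self.branch1.params() + self.branch2.params() + self.head.params()

    def grads(self) -> list[np.ndarray]:
        return self.branch1.grads() + self.branch2.grads() + self.head.grads()

    def regularization_loss(self) -> float:
        return self.branch1.regularization_loss() + self.branch2.regularization_loss() + self.head.regularization_loss()

    def predict_proba(self, x1: np.ndarray, x2: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Positive-class probabilities; inference mode (running BN stats,
        no dropout), so results are independent of batching."""
        out = []
        for start in range(0, x1.shape[0], batch_size):
            logits = self.forward(x1[start : start + batch_size], x2[start : start + batch_size], training=False)
            out.append(nn.softmax(logits)[:, 1])
        return np.concatenate(out) if out else np.empty(0)

    # -- persistence ------------------------------------------------------
    def _all_layers(self) -> list[nn.Layer]:
        return self.branch1.layers + self.branch2.layers + self.head.layers

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.params()):
            arrays[f"param_{i}"] = p
        bn = [l for l in self._all_layers() if isinstance(l, nn.BatchNorm)]
        for i, layer in enumerate(bn):
            arrays[f"bn_{i}_mean"] = layer.running_mean
            arrays[f"bn_{i}_var"] = layer.running_var
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p[...] = arrays[f"param_{i}"]
        bn = [l for l in self._all_layers() if isinstance(l, nn.BatchNorm)]
        for i, layer in enumerate(bn):
            layer.running_mean = np.array(arrays[f"bn_{i}_mean"])
            layer.running_var = np.array(arrays[f"bn_{i}_var"])


def build_itcep_model(
    config: ModelConfig,
    module1_shape: tuple[int, int] | None = None,
    module2_shape: tuple[int, int] | None = None,
) -> ItcepNetwork:
    """Construct the untrained network for a fusion scheme.

    Default input shapes follow the scheme: module 1 is 32x20 (one-hot)
    or 32x21 (phychem); module 2 is 20x20 (positional preference) or 2x20
    (stacked composition vectors).
    """
    if module1_shape is None:
        module1_shape = (32, 20) if config.scheme.startswith("onehot") else (32, 21)
    if module2_shape is None:
        module2_shape = (20, 20) if config.scheme.endswith("aapp") else (2, 20)
    return ItcepNetwork(config, module1_shape, module2_shape)


@dataclass
class TrainedModel:
    """A fitted network plus the conventions it was trained with."""

    network: ItcepNetwork
    config: ModelConfig
    history: list[float] = field(default_factory=list)
    residue_order: str = AMINO_ACIDS
    padding: str = "right"

    def predict_proba(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(x1, x2)

    def save(self, directory: str | Path) -> None:
        """Model artifact: serialized weights plus a JSON sidecar with the
        residue order, padding convention, scheme, thresholds and config."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.config.to_dict(),
            "module1_shape": list(self.network.module1_shape),
            "module2_shape": list(self.network.module2_shape),
            "residue_order": self.residue_order,
            "padding": self.padding,
            "scheme": self.config.scheme,
            "thresholds": {
                "interaction": INTERACTION_THRESHOLD,
                "low_medium": LOW_MEDIUM_THRESHOLD,
                "medium_high": MEDIUM_HIGH_THRESHOLD,
            },
            "history": self.history,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))
        np.savez(directory / "weights.npz", **self.network.state_arrays())

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        if meta["residue_order"] != AMINO_ACIDS:
            raise ValueError("model was trained with a different residue order")
        config = ModelConfig.from_dict(meta["config"])
        network = ItcepNetwork(
            config, tuple(meta["module1_shape"]), tuple(meta["module2_shape"])
        )
        with np.load(directory / "weights.npz") as npz:
            network.load_state_arrays({k: npz[k] for k in npz.files})
        return cls(
            network=network,
            config=config,
            history=list(meta.get("history", [])),
        )


def encode_features(
    records: Sequence[PairRecord],
    scheme: str,
    aapp_table: AAPPTable | None = None,
    phychem_table: PhychemTable | None = None,
    training_peptides: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode pairs into the two stacked NHWC input arrays of the model."""
    x1_list, x2_list = [], []
    for rec in records:
        fused = fuse_pair(
            rec.peptide,
            rec.cdr3,
            scheme,
            aapp_table=aapp_table,
            phychem_table=phychem_table,
            training_peptides=training_peptides,
        )
        x1_list.append(fused.module1_map.values)
        x2_list.append(fused.module2_map.values)
    x1 = np.stack(x1_list)[..., None] if x1_list else np.empty((0, 32, 20, 1))
    x2 = np.stack(x2_list)[..., None] if x2_list else np.empty((0, 20, 20, 1))
    return x1, x2


def train_model(
    model: ItcepNetwork,
    x1: np.ndarray,
    x2: np.ndarray,
    labels: Sequence[int],
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Fit with Adagrad on MSE between softmax output and one-hot labels.

    Shuffles per epoch with a seeded generator; the history records one
    mean total loss (data + L2) per epoch. The positive class is output
    index 1.
    """
    config = config or model.config
    labels = np.asarray(labels, dtype=int)
    n = x1.shape[0]
    if n == 0:
        raise ValueError("training set is empty")
    if x2.shape[0] != n or labels.shape[0] != n:
        raise ValueError("features and labels must be aligned")
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be binary")

    y = np.zeros((n, 2))
    y[np.arange(n), labels] = 1.0

    opt = nn.Adagrad(model.params(), model.grads(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 2)
    history: list[float] = []
    for _ in range(config.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(x1[idx], x2[idx], training=True)
            loss, _, dz = nn.mse_softmax_loss_and_grad(logits, y[idx])
            model.backward(dz)
            opt.step()
            epoch_loss += loss + model.regularization_loss()
            n_batches += 1
        history.append(epoch_loss / n_batches)
    return TrainedModel(network=model, config=config, history=history)


def assign_binding_level(probability: float) -> str:
    """Discretize a probability into non-binding/low/medium/high bands.

    <= 0.5 non-binding; (0.5, 0.8) low; [0.8, 0.95] medium; > 0.95 high.
    """
    if not (0.0 <= probability <= 1.0) or not np.isfinite(probability):
        raise ValueError(f"probability {probability} outside [0, 1]")
    if probability <= INTERACTION_THRESHOLD:
        return "non-binding"
    if probability < LOW_MEDIUM_THRESHOLD:
        return "low"
    if probability <= MEDIUM_HIGH_THRESHOLD:
        return "medium"
    return "high"


def _pair_error(rec: PairRecord) -> str | None:
    if not rec.peptide or not rec.cdr3:
        return "missing-field"
    if not is_valid_sequence(rec.peptide) or not is_valid_sequence(rec.cdr3):
        return "alphabet"
    if not (PEPTIDE_MIN_LEN <= len(rec.peptide) <= PEPTIDE_MAX_LEN):
        return "peptide-length"
    if not (CDR3_MIN_LEN <= len(rec.cdr3) <= CDR3_MAX_LEN):
        return "cdr3-length"
    return None


def predict_pairs(
    model: TrainedModel,
    pairs: Sequence[PairRecord],
    aapp_table: AAPPTable | None = None,
    training_peptides: Sequence[str] | None = None,
    phychem_table: PhychemTable | None = None,
) -> list[PredictionRecord]:
    """Score pairs; unseen peptides are routed through the nearest training
    peptide for their positional-preference map. Output order matches
    input order; invalid pairs yield error entries instead of scores."""
    scheme = model.config.scheme
    errors = [_pair_error(rec) for rec in pairs]
    valid = [rec for rec, err in zip(pairs, errors) if err is None]
    probs: dict[int, float] = {}
    if valid:
        x1, x2 = encode_features(valid, scheme, aapp_table, phychem_table, training_peptides)
        p = model.predict_proba(x1, x2)
        valid_indices = [i for i, err in enumerate(errors) if err is None]
        probs = {i: float(pi) for i, pi in zip(valid_indices, p)}

    out: list[PredictionRecord] = []
    for i, (rec, err) in enumerate(zip(pairs, errors)):
        if err is not None:
            out.append(PredictionRecord(rec.peptide, rec.cdr3, None, None, None, error=err))
            continue
        prob = probs[i]
        out.append(
            PredictionRecord(
                peptide=rec.peptide,
                cdr3=rec.cdr3,
                probability=prob,
                interaction=int(prob > INTERACTION_THRESHOLD),
                binding_level=assign_binding_level(prob),
            )
        )
    return out


def rank_tcrs_for_peptide(
    model: TrainedModel,
    peptide: str,
    candidate_cdr3s: Sequence[str],
    aapp_table: AAPPTable | None = None,
    training_peptides: Sequence[str] | None = None,
    phychem_table: PhychemTable | None = None,
) -> list[PredictionRecord]:
    """Score every candidate CDR3 against one peptide, sorted by descending
    probability; ties break by CDR3 lexicographic order."""
    if not candidate_cdr3s:
        raise ValueError("candidate CDR3 list must be non-empty")
    pairs = [PairRecord(peptide=peptide, cdr3=c) for c in candidate_cdr3s]
    records = predict_pairs(model, pairs, aapp_table, training_peptides, phychem_table)
    scored = [r for r in records if r.error is None]
    failed = [r for r in records if r.error is not None]
    scored.sort(key=lambda r: (-r.probability, r.cdr3))
    return scored + failed


def write_prediction_csv(records: Sequence[PredictionRecord], path: str | Path) -> None:
    """Write the five-column prediction CSV: peptide, cdr3, probability,
    interaction, binding_level."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["peptide", "cdr3", "probability", "interaction", "binding_level"])
        for r in records:
            if r.error is not None:
                writer.writerow([r.peptide, r.cdr3, "", "", f"error:{r.error}"])
            else:
                writer.writerow([r.peptide, r.cdr3, f"{r.probability:.6f}", r.interaction, r.binding_level])
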
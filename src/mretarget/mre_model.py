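"""The five-branch CNN-GRU site scorer: build, train, apply, ablate.

Architecture (per branch, on the matching feature tensor): stacked strided
valid 1-D convolutions, each batch-normalized and leaky-ReLU-activated,
with a max-pool (pool size 2) after every convolution except the last; the
conv-stack output feeds a 24-unit GRU (dropout 0.1) whose full sequence
output is flattened.  All branch outputs are concatenated and passed
through dense layers of 90, 55, and 35 nodes (batch norm, leaky ReLU,
dropout 0.1) to a single sigmoid output.

Default branch configurations (filters, kernel, stride per conv layer):

=============  =============================================
mre            (35, 9, 2), (50, 9, 3)          on (150, 4)
chimera        (16, 6, 2), (32, 3, 3), (62, 2, 4) on (53, 4)
duplex         (16, 6, 2), (32, 3, 3), (62, 2, 4) on (60, 4)
fold           (35, 9, 4), (50, 9, 5)          on (150, 3)
conservation   (20, 9, 3), (40, 3, 4), (60, 2, 5) on (150, 1)
=============  =============================================

Filter counts, strides, pool size, GRU width, dense widths, dropout,
epochs, patience, and learning rate follow the published configuration;
kernel widths, the optimizer (Adam), the loss (binary cross-entropy), and
the pooling placement are declared implementation choices.

Training is deterministic for a fixed seed on a fixed backend.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from mretarget import nn
from mretarget.errors import ConfigurationError, DataError, ModelError
from mretarget.feature_builder import BUNDLE_SHAPES

BRANCH_NAMES = ("mre", "chimera", "duplex", "fold", "conservation")

_DEFAULT_CONVS = {
    "mre": ((35, 9, 2), (50, 9, 3)),
    "chimera": ((16, 6, 2), (32, 3, 3), (62, 2, 4)),
    "duplex": ((16, 6, 2), (32, 3, 3), (62, 2, 4)),
    "fold": ((35, 9, 4), (50, 9, 5)),
    "conservation": ((20, 9, 3), (40, 3, 4), (60, 2, 5)),
}


@dataclass(frozen=True)
class BranchSpec:
    """Configuration of one convolutional-recurrent branch."""

    name: str
    conv_layers: tuple[tuple[int, int, int], ...]  # (filters, kernel, stride)
    pool_size: int = 2
    gru_units: int = 24
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.name not in BUNDLE_SHAPES:
            raise ConfigurationError(f"unknown branch name {self.name!r}")
        if not self.conv_layers:
            raise ConfigurationError(f"branch {self.name!r} has no conv layers")


def default_branch_spec(name: str) -> BranchSpec:
    return BranchSpec(name=name, conv_layers=_DEFAULT_CONVS[name])


@dataclass(frozen=True)
class ModelSpec:
    """Full configuration of one region-specific site scorer."""

    region: str = "UTR3"
    branches: tuple[BranchSpec, ...] = field(
        default_factory=lambda: tuple(default_branch_spec(n) for n in BRANCH_NAMES)
    )
    dense_nodes: tuple[int, ...] = (90, 55, 35)
    dense_dropout: float = 0.1
    epochs: int = 200
    early_stop_patience: int = 15
    learning_rate: float = 1e-4
    batch_size: int = 64
    val_fraction: float = 0.1
    seed: int = 0
    name: str = "full"

    def __post_init__(self) -> None:
        if self.region not in ("UTR3", "CDS"):
            raise ConfigurationError(f"unknown region {self.region!r}")
        if not self.branches:
            raise ConfigurationError("a model needs at least one branch")
        names = [b.name for b in self.branches]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate branch names {names}")

    def branch_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.branches)


def _branch_arithmetic(spec: BranchSpec) -> list[dict]:
    """Per-layer output lengths; raises on a non-positive length."""
    length, channels = BUNDLE_SHAPES[spec.name]
    rows = []
    n_convs = len(spec.conv_layers)
    for i, (filters, kernel, stride) in enumerate(spec.conv_layers):
        length = nn.Conv1D.out_length(length, kernel, stride)
        if length <= 0:
            raise ConfigurationError(
                f"branch {spec.name!r} conv layer {i + 1} "
                f"(kernel {kernel}, stride {stride}) yields length {length}"
            )
        rows.append({"branch": spec.name, "layer": f"conv{i + 1}", "type": "conv",
                     "output_len": length, "channels": filters,
                     "kernel": kernel, "stride": stride})
        channels = filters
        if i < n_convs - 1:
            length = nn.MaxPool1D.out_length(length, spec.pool_size)
            if length <= 0:
                raise ConfigurationError(
                    f"branch {spec.name!r} pool after conv layer {i + 1} "
                    f"yields length {length}"
                )
            rows.append({"branch": spec.name, "layer": f"pool{i + 1}", "type": "pool",
                         "output_len": length, "channels": filters,
                         "pool_size": spec.pool_size})
    rows.append({"branch": spec.name, "layer": "gru", "type": "gru",
                 "output_len": length, "channels": spec.gru_units,
                 "units": spec.gru_units, "dropout": spec.dropout})
    rows.append({"branch": spec.name, "layer": "flatten", "type": "flatten",
                 "output_len": length * spec.gru_units, "channels": 1})
    return rows


class MreNetwork(nn.BranchedNetwork):
    """A built (possibly untrained) site scorer with its layer summary."""

    def __init__(self, spec: ModelSpec, branches, head, widths, summary):
        super().__init__(branches, head, widths)
        self.spec = spec
        self.summary_ = summary

    def summary(self) -> list[dict]:
        return list(self.summary_)


def build_model(spec: ModelSpec, rng: Optional[np.random.Generator] = None) -> MreNetwork:
    """Construct the branched network described by ``spec``.

    Layer-length arithmetic is validated up front; a branch whose conv/pool
    chain collapses to a non-positive length raises a configuration error
    naming the offending layer.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    branches: dict[str, nn.Sequential] = {}
    widths: dict[str, int] = {}
    summary: list[dict] = []
    for bspec in spec.branches:
        rows = _branch_arithmetic(bspec)  # validates
        summary.extend(rows)
        length, channels = BUNDLE_SHAPES[bspec.name]
        layers: list[nn.Layer] = []
        n_convs = len(bspec.conv_layers)
        for i, (filters, kernel, stride) in enumerate(bspec.conv_layers):
            layers.append(nn.Conv1D(channels, filters, kernel, stride, rng))
            layers.append(nn.BatchNorm(filters))
            layers.append(nn.LeakyReLU())
            length = nn.Conv1D.out_length(length, kernel, stride)
            channels = filters
            if i < n_convs - 1:
                layers.append(nn.MaxPool1D(bspec.pool_size))
                length = nn.MaxPool1D.out_length(length, bspec.pool_size)
        layers.append(nn.GRU(channels, bspec.gru_units, rng))
        layers.append(nn.Dropout(bspec.dropout, rng))
        layers.append(nn.Flatten())
        branches[bspec.name] = nn.Sequential(layers)
        widths[bspec.name] = length * bspec.gru_units

    concat_width = sum(widths.values())
    head_layers: list[nn.Layer] = []
    in_dim = concat_width
    for nodes in spec.dense_nodes:
        head_layers.append(nn.Dense(in_dim, nodes, rng))
        head_layers.append(nn.BatchNorm(nodes))
        head_layers.append(nn.LeakyReLU())
        head_layers.append(nn.Dropout(spec.dense_dropout, rng))
        summary.append({"branch": "head", "layer": f"dense{nodes}", "type": "dense",
                        "output_len": 1, "channels": nodes, "nodes": nodes,
                        "dropout": spec.dense_dropout})
        in_dim = nodes
    head_layers.append(nn.Dense(in_dim, 1, rng))
    summary.append({"branch": "head", "layer": "output", "type": "dense",
                    "output_len": 1, "channels": 1, "nodes": 1,
                    "activation": "sigmoid"})
    head = nn.Sequential(head_layers)
    return MreNetwork(spec, branches, head, widths, summary)


@dataclass
class TrainedMreModel:
    spec: ModelSpec
    network: MreNetwork
    history: list[dict]

    @property
    def best_val_loss(self) -> float:
        return min(h["val_loss"] for h in self.history)


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    from scipy.stats import rankdata

    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _stratified_split(labels: np.ndarray, val_fraction: float, rng: np.random.Generator):
    train_idx, val_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(len(idx) * val_fraction)))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def _batched_forward(network: MreNetwork, arrays, batch_size=512) -> np.ndarray:
    n = len(next(iter(arrays.values())))
    out = np.empty(n)
    for s in range(0, n, batch_size):
        batch = {k: v[s : s + batch_size] for k, v in arrays.items()}
        out[s : s + batch_size] = network.forward(batch, train=False)
    return out


def check_input_shapes(spec: ModelSpec, arrays: dict[str, np.ndarray]) -> None:
    for name in spec.branch_names():
        if name not in arrays:
            raise DataError(f"missing input array for branch {name!r}")
        expected = BUNDLE_SHAPES[name]
        got = arrays[name].shape[1:]
        if tuple(got) != expected:
            raise DataError(
                f"branch {name!r}: input shape {tuple(got)} does not match {expected}"
            )


def train_mre_model(
    model: MreNetwork,
    dataset: tuple[dict[str, np.ndarray], np.ndarray],
    spec: Optional[ModelSpec] = None,
) -> TrainedMreModel:
    """Train with Adam on binary cross-entropy, early-stopping on a held-out
    stratified validation split (``val_fraction``, seeded).

    Restores the best-epoch weights before returning.  Raises on
    single-class labels and aborts with diagnostics on NaN loss.
    """
    spec = spec or model.spec
    arrays, labels = dataset
    labels = np.asarray(labels, dtype=np.float64)
    if set(np.unique(labels)) != {0.0, 1.0}:
        raise DataError(
            f"training labels must contain both classes, got {sorted(set(labels))}"
        )
    branch_arrays = {name: np.asarray(arrays[name]) for name in spec.branch_names()}
    check_input_shapes(spec, branch_arrays)

    rng = np.random.default_rng(spec.seed)
    train_idx, val_idx = _stratified_split(labels, spec.val_fraction, rng)
    xtr = {k: v[train_idx] for k, v in branch_arrays.items()}
    ytr = labels[train_idx]
    xval = {k: v[val_idx] for k, v in branch_arrays.items()}
    yval = labels[val_idx]

    opt = nn.Adam(lr=spec.learning_rate)
    history: list[dict] = []
    best_loss = np.inf
    best_weights = model.get_weights()
    best_bn = model.batchnorm_state()
    patience_left = spec.early_stop_patience

    n = len(ytr)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for s in range(0, n, spec.batch_size):
            sel = order[s : s + spec.batch_size]
            if len(sel) < 2:
                continue  # batch norm needs >= 2 samples
            batch = {k: v[sel] for k, v in xtr.items()}
            logits = model.forward(batch, train=True)
            loss, dlogit = nn.bce_loss_and_grad(logits, ytr[sel])
            if not np.isfinite(loss):
                raise ModelError(
                    f"NaN/inf training loss at epoch {epoch + 1}, step {n_batches + 1}; "
                    f"lr={spec.learning_rate}, batch_size={spec.batch_size}"
                )
            model.backward(dlogit)
            opt.step(model.params_grads())
            epoch_loss += loss
            n_batches += 1

        val_logits = _batched_forward(model, xval)
        val_loss, _ = nn.bce_loss_and_grad(val_logits, yval)
        val_auc = _rank_auc(nn.sigmoid(val_logits), yval)
        history.append(
            {
                "epoch": epoch + 1,
                "train_loss": epoch_loss / max(n_batches, 1),
                "val_loss": val_loss,
                "val_auc": val_auc,
            }
        )
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_weights = model.get_weights()
            best_bn = model.batchnorm_state()
            patience_left = spec.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    model.set_weights(best_weights)
    model.set_batchnorm_state(best_bn)
    return TrainedMreModel(spec=spec, network=model, history=history)


def score_mres(model: TrainedMreModel, arrays: dict[str, np.ndarray],
               batch_size: int = 512) -> np.ndarray:
    """Sigmoid scores in [0, 1], one per bundle, order preserved.

    Inference uses running batch-norm statistics, so results are invariant
    to batching.
    """
    branch_arrays = {name: np.asarray(arrays[name]) for name in model.spec.branch_names()
                     if name in arrays}
    check_input_shapes(model.spec, branch_arrays)
    logits = _batched_forward(model.network, branch_arrays, batch_size)
    return nn.sigmoid(logits)


def ablation_variants(full_spec: ModelSpec) -> list[ModelSpec]:
    """The five single-branch specs plus the named branch combinations."""
    by_name = {b.name: b for b in full_spec.branches}

    def subset(names: Sequence[str], label: str) -> ModelSpec:
        return ModelSpec(
            region=full_spec.region,
            branches=tuple(by_name[n] for n in names),
            dense_nodes=full_spec.dense_nodes,
            dense_dropout=full_spec.dense_dropout,
            epochs=full_spec.epochs,
            early_stop_patience=full_spec.early_stop_patience,
            learning_rate=full_spec.learning_rate,
            batch_size=full_spec.batch_size,
            val_fraction=full_spec.val_fraction,
            seed=full_spec.seed,
            name=label,
        )

    variants = [subset([n], f"{n}_only") for n in by_name]
    variants.append(subset(["chimera", "conservation"], "chimera_conservation"))
    variants.append(subset(["chimera", "duplex"], "chimera_duplex"))
    variants.append(subset([n for n in by_name if n != "fold"], "no_fold"))
    return variants


# ---------------------------------------------------------------------------
# Serialization: spec JSON + weights npz + history TSV
# ---------------------------------------------------------------------------

def save_model(trained: TrainedMreModel, directory) -> None:
    os.makedirs(directory, exist_ok=True)
    spec_dict = asdict(trained.spec)
    with open(os.path.join(directory, "spec.json"), "w") as fh:
        json.dump(spec_dict, fh, indent=2)
    weights = trained.network.get_weights()
    bn = trained.network.batchnorm_state()
    np.savez(
        os.path.join(directory, "weights.npz"),
        **{f"w{i}": w for i, w in enumerate(weights)},
        **{f"bn{i}": b for i, b in enumerate(bn)},
        n_weights=np.array(len(weights)),
        n_bn=np.array(len(bn)),
    )
    with open(os.path.join(directory, "history.tsv"), "w") as fh:
        fh.write("epoch\ttrain_loss\tval_loss\tval_auc\n")
        for h in trained.history:
            fh.write(f"{h['epoch']}\t{h['train_loss']:.6f}\t{h['val_loss']:.6f}\t{h['val_auc']:.6f}\n")


def load_model(directory) -> TrainedMreModel:
    spec_path = os.path.join(directory, "spec.json")
    if not os.path.exists(spec_path):
        raise ModelError(f"model directory {directory} lacks spec.json")
    with open(spec_path) as fh:
        d = json.load(fh)
    branches = tuple(
        BranchSpec(
            name=b["name"],
            conv_layers=tuple(tuple(c) for c in b["conv_layers"]),
            pool_size=b["pool_size"],
            gru_units=b["gru_units"],
            dropout=b["dropout"],
        )
        for b in d["branches"]
    )
    spec = ModelSpec(
        region=d["region"],
        branches=branches,
        dense_nodes=tuple(d["dense_nodes"]),
        dense_dropout=d["dense_dropout"],
        epochs=d["epochs"],
        early_stop_patience=d["early_stop_patience"],
        learning_rate=d["learning_rate"],
        batch_size=d["batch_size"],
        val_fraction=d["val_fraction"],
        seed=d["seed"],
        name=d.get("name", "full"),
    )
    network = build_model(spec)
    data = np.load(os.path.join(directory, "weights.npz"))
    weights = [data[f"w{i}"] for i in range(int(data["n_weights"]))]
    bn = [data[f"bn{i}"] for i in range(int(data["n_bn"]))]
    network.set_weights(weights)
    network.set_batchnorm_state(bn)
    history = []
    hist_path = os.path.join(directory, "history.tsv")
    if os.path.exists(hist_path):
        import pandas as pd

        history = pd.read_csv(hist_path, sep="\t").to_dict("records")
    return TrainedMreModel(spec=spec, network=network, history=history)
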
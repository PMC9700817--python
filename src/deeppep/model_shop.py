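"""Universal training loop, transfer learning, snapshots and batched
prediction, plus generic sequence->scalar model templates.

Every model is a :class:`SequenceModel`: it knows how to encode a batch of
peptide-table rows, run a forward pass and compute a loss against target
columns.  ``train`` works on any of them with the warmup + cosine schedule;
``predict_batched`` buckets rows by sequence length (so each mini-batch is
padded to its own maximum) and restores the input order afterwards.
"""

from __future__ import annotations

import inspect
import json
from dataclasses import asdict, dataclass

import h5py
import numpy as np
import pandas as pd

from .nn import Adam, Dropout, Module, Tensor, lr_at

SNAPSHOT_FORMAT_VERSION = "deeppep-snapshot-1"


@dataclass
class TrainConfig:
    epochs: int = 100
    warmup_epochs: int = 20
    peak_lr: float = 1e-4
    dropout: float = 0.1
    batch_size: int = 256
    loss: str = "l1"  # "l1" or "bce"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.warmup_epochs <= self.epochs:
            raise ValueError("need 0 <= warmup_epochs <= epochs")
        if not 0 <= self.dropout < 1:
            raise ValueError("need 0 <= dropout < 1")

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        import yaml
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# named presets mirroring the production training recipes
TRAIN_PRESETS: dict[str, TrainConfig] = {
    "ms2_phase1": TrainConfig(epochs=100, warmup_epochs=20, peak_lr=1e-5,
                              dropout=0.1, batch_size=256),
    "ms2_phase2": TrainConfig(epochs=20, warmup_epochs=5, peak_lr=1e-5,
                              dropout=0.1, batch_size=256),
    "ms2_phase3": TrainConfig(epochs=20, warmup_epochs=5, peak_lr=1e-5,
                              dropout=0.1, batch_size=256),
    "ms2_transfer": TrainConfig(epochs=10, warmup_epochs=5, peak_lr=1e-5,
                                dropout=0.1, batch_size=256),
    "rt": TrainConfig(epochs=300, warmup_epochs=30, peak_lr=1e-4,
                      dropout=0.1, batch_size=256),
    "rt_finetune": TrainConfig(epochs=30, warmup_epochs=10, peak_lr=1e-4,
                               dropout=0.1, batch_size=256),
    "ccs": TrainConfig(epochs=300, warmup_epochs=30, peak_lr=1e-4,
                       dropout=0.1, batch_size=256),
    "hla": TrainConfig(epochs=100, warmup_epochs=20, peak_lr=1e-4,
                       dropout=0.1, batch_size=256, loss="bce"),
    "hla_transfer": TrainConfig(epochs=50, warmup_epochs=20, peak_lr=1e-5,
                                dropout=0.1, batch_size=256, loss="bce"),
}


class SequenceModel(Module):
    """Base class for peptide-table models.

    Subclasses set ``build_config`` (constructor kwargs sufficient to
    rebuild the architecture) and implement :meth:`forward_batch`, which
    maps a slice of a peptide table to predictions, and
    :meth:`target_array`.
    """

    target_column: str = ""

    def __init__(self):
        super().__init__()
        self.build_config: dict = {}

    # -- to implement ------------------------------------------------------
    def forward_batch(self, batch: pd.DataFrame) -> Tensor:
        raise NotImplementedError

    def target_array(self, batch: pd.DataFrame) -> np.ndarray:
        return batch[self.target_column].to_numpy(dtype=float)

    # -- shared machinery --------------------------------------------------
    def loss_on(self, batch: pd.DataFrame, loss: str) -> Tensor:
        pred = self.forward_batch(batch)
        target = self.target_array(batch)
        if loss == "l1":
            return (pred - target).abs().mean()
        if loss == "bce":
            eps = 1e-7
            p = pred * (1 - 2 * eps) + eps
            y = target
            return -(p.log() * y + (1.0 - p).log() * (1.0 - y)).mean()
        raise ValueError(f"unknown loss {loss!r}")

    def set_dropout(self, p: float, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for m in self.modules():
            if isinstance(m, Dropout):
                m.p = p
                m._rng = np.random.default_rng(rng.integers(2**31))


def _length_buckets(lengths: np.ndarray, batch_size: int) -> list[np.ndarray]:
    """Row-index batches grouped by sequence length (stable order)."""
    order = np.argsort(lengths, kind="stable")
    return [order[i:i + batch_size] for i in range(0, len(order), batch_size)]


def train(
    model: SequenceModel,
    table: pd.DataFrame,
    cfg: TrainConfig,
    log_path=None,
) -> list[float]:
    """Train in place; returns the per-epoch mean training loss.

    When ``log_path`` is given, the trace is also written as
    line-oriented text (``epoch<TAB>loss``)."""
    if len(table) == 0:
        raise ValueError("empty training table")
    trace: list[float] = []
    if cfg.epochs == 0:
        model.eval()
        return trace
    model.train()
    model.set_dropout(cfg.dropout, cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.peak_lr)
    table = table.reset_index(drop=True)
    lengths = table["sequence"].str.len().to_numpy()
    batches = _length_buckets(lengths, cfg.batch_size)
    for epoch in range(cfg.epochs):
        opt.lr = lr_at(epoch, cfg.epochs, cfg.warmup_epochs, cfg.peak_lr)
        order = rng.permutation(len(batches))
        losses, weights = [], []
        for bi in order:
            idx = batches[bi]
            batch = table.iloc[idx]
            opt.zero_grad()
            loss = model.loss_on(batch, cfg.loss)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            weights.append(len(idx))
        trace.append(float(np.average(losses, weights=weights)))
    model.eval()
    if log_path is not None:
        with open(log_path, "w") as fh:
            for epoch, loss in enumerate(trace):
                fh.write(f"{epoch}\t{loss:.6g}\n")
    return trace


def transfer_learn(
    snapshot_path,
    small_table: pd.DataFrame,
    cfg: TrainConfig,
    model_classes: dict | None = None,
) -> tuple[SequenceModel, list[float]]:
    """Load a snapshot and continue training on a small table."""
    model = load_snapshot(snapshot_path, model_classes)
    trace = train(model, small_table, cfg) if cfg.epochs > 0 else []
    return model, trace


def predict_batched(
    model: SequenceModel,
    table: pd.DataFrame,
    batch_size: int = 256,
):
    """Predictions in input-row order, independent of internal bucketing.

    Returns a float array for scalar models; models whose
    ``forward_batch`` emits per-position matrices get a list of per-row
    arrays instead.
    """
    model.eval()
    table = table.reset_index(drop=True)
    if len(table) == 0:
        return np.zeros(0)
    lengths = table["sequence"].str.len().to_numpy()
    out: dict[int, np.ndarray] = {}
    scalar = True
    for idx in _length_buckets(lengths, batch_size):
        batch = table.iloc[idx]
        try:
            pred = model.forward_batch(batch)
        except Exception as err:
            raise RuntimeError(
                f"prediction failed for rows {idx.tolist()}: {err}"
            ) from err
        data = pred.data
        if data.ndim == 1:
            for k, row in zip(idx, data):
                out[int(k)] = row
        else:
            scalar = False
            lens = lengths[idx]
            for j, k in enumerate(idx):
                out[int(k)] = data[j, : max(lens[j] - 1, 0)]
    if scalar:
        return np.array([float(out[i]) for i in range(len(table))])
    return [out[i] for i in range(len(table))]


# ---------------------------------------------------------------------------
# snapshots
# ---------------------------------------------------------------------------

def save_snapshot(model: SequenceModel, path) -> None:
    """Persist weights, architecture source text and hyperparameters."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = SNAPSHOT_FORMAT_VERSION
        fh.attrs["model_class"] = type(model).__name__
        fh.attrs["arch_source"] = inspect.getsource(type(model))
        fh.attrs["hyperparams"] = json.dumps(model.build_config)
        grp = fh.create_group("weights")
        for name, p in model.named_parameters():
            grp.create_dataset(name, data=p.data)


def read_snapshot_meta(path) -> dict:
    with h5py.File(path, "r") as fh:
        if fh.attrs.get("format_version") != SNAPSHOT_FORMAT_VERSION:
            raise ValueError(
                f"unsupported snapshot format: "
                f"{fh.attrs.get('format_version')!r}"
            )
        return {
            "model_class": fh.attrs["model_class"],
            "arch_source": fh.attrs["arch_source"],
            "hyperparams": json.loads(fh.attrs["hyperparams"]),
        }


def load_snapshot(path, model_classes: dict | None = None) -> SequenceModel:
    """Rebuild the model from a snapshot and restore its weights."""
    meta = read_snapshot_meta(path)
    if model_classes is None:
        from . import models as _models
        from . import hla as _hla
        model_classes = {
            cls.__name__: cls
            for cls in (
                _models.MS2Model, _models.RTModel, _models.CCSModel,
                _hla.HLAClassifier, GenericRegressor, GenericClassifier,
            )
        }
    name = meta["model_class"]
    if name not in model_classes:
        raise ValueError(f"unknown model class in snapshot: {name!r}")
    model = model_classes[name](**meta["hyperparams"])
    with h5py.File(path, "r") as fh:
        state = {k: np.asarray(v) for k, v in fh["weights"].items()}
    model.load_state_arrays(state)
    model.eval()
    return model


# ---------------------------------------------------------------------------
# generic "model shop" templates: sequence -> scalar
# ---------------------------------------------------------------------------

class GenericRegressor(SequenceModel):
    """Small BiLSTM regressor built from config alone (sequence -> scalar)."""

    target_column = "target"

    def __init__(self, embed_dim=16, hidden=32, layers=1, decoder_hidden=32,
                 dropout=0.1, seed=0, target_column=None, sigmoid=False):
        super().__init__()
        from .nn import LSTM, Dropout as _Drop, Embedding, Linear, masked_sum
        from .encoding import AA_VOCAB_SIZE, encode_aa
        self._encode_aa = encode_aa
        self._masked_sum = masked_sum
        self.build_config = dict(
            embed_dim=embed_dim, hidden=hidden, layers=layers,
            decoder_hidden=decoder_hidden, dropout=dropout, seed=seed,
            target_column=target_column, sigmoid=sigmoid,
        )
        if target_column:
            self.target_column = target_column
        self.sigmoid = sigmoid
        rng = np.random.default_rng(seed)
        self.embed = Embedding(AA_VOCAB_SIZE, embed_dim, rng)
        self.lstm = LSTM(embed_dim, hidden, layers, rng, bidirectional=True)
        self.drop = _Drop(dropout, np.random.default_rng(seed + 1))
        self.fc1 = Linear(2 * hidden, decoder_hidden, rng)
        self.fc2 = Linear(decoder_hidden, 1, rng)

    def forward_batch(self, batch: pd.DataFrame) -> Tensor:
        seqs = batch["sequence"].tolist()
        lengths = np.array([len(s) for s in seqs])
        codes = self._encode_aa(seqs)
        x = self.drop(self.embed(codes))
        x = self.lstm(x, lengths)
        pooled = self._masked_sum(x, lengths) * (1.0 / lengths[:, None])
        y = self.fc2(self.fc1(pooled).relu()).reshape(len(seqs))
        return y.sigmoid() if self.sigmoid else y


class GenericClassifier(GenericRegressor):
    """Binary classifier template: the regressor with a sigmoid head."""

    target_column = "label"

    def __init__(self, **kwargs):
        kwargs.setdefault("sigmoid", True)
        kwargs.setdefault("target_column", "label")
        super().__init__(**kwargs)
        self.build_config = dict(kwargs)
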
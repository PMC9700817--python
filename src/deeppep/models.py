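"""MS2, RT and CCS model architectures plus their pre/post-processing.

The production dimensions live in ``config/frozen_dims.yaml`` (with the
parameter-count arithmetic); every architecture also builds at reduced
dimensions for fast training on small data.  MS2 predicts an (n-1) x 8
fragment-intensity matrix per peptide (b/y ions at charge 1-2 plus their
neutral-loss channels, clipped to [0, 1]); RT predicts gradient-normalized
retention time; CCS predicts collisional cross sections, convertible to
timsTOF ion mobilities via the Mason-Schamp relation.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import chem
from .encoding import (
    INSTRUMENTS,
    META_DIM,
    MOD_RAW_DIM,
    encode_aa,
    encode_meta,
    encode_ptm,
)
from .model_shop import SequenceModel, predict_batched
from .nn import (
    LSTM,
    Conv1d,
    Dropout,
    Embedding,
    Linear,
    PReLU,
    Tensor,
    TransformerEncoderLayer,
    masked_sum,
    sinusoidal_positions,
)
from .peptide import (
    DEFAULT_REGISTRY,
    FRAGMENT_COLUMNS,
    _residue_and_mod_masses,
    attach_fragment_indices,
    parse_mod_lists,
)

MASS_N2 = 28.00615          # Da, nitrogen buffer gas
MASON_SCHAMP_CONST = 1059.62245  # CCS in A^2, K0 in cm^2 V^-1 s^-1


def frozen_dims() -> dict:
    with resources.files("deeppep.config").joinpath(
        "frozen_dims.yaml"
    ).open() as fh:
        return yaml.safe_load(fh)


def count_parameters(model) -> int:
    """Number of trainable scalar parameters."""
    return model.num_parameters()


class _ModEmbedding:
    """Shared PTM featurization: 6 raw CHNOSP channels + 2 projected."""

    def _build_mod(self, rng):
        self.mod_proj = Linear(MOD_RAW_DIM - 6, 2, rng, bias=False)

    def _mod_features(self, batch, pad_to) -> Tensor:
        lengths = batch["sequence"].str.len().tolist()
        raw = encode_ptm(
            batch.get("mods", pd.Series([""] * len(batch))),
            batch.get("mod_sites", pd.Series([""] * len(batch))),
            lengths, pad_to, self.registry,
        )
        t = Tensor(raw)
        return Tensor.cat([t[:, :, :6], self.mod_proj(t[:, :, 6:])], axis=-1)


class MS2Model(SequenceModel, _ModEmbedding):
    """Transformer MS2 fragment-intensity model.

    Four encoder layers over the summed sequence/PTM/meta embedding plus
    one extra encoder layer for the neutral-loss branch; two linear output
    heads give 8 channels per cleavage position.  ``mask_modloss=True``
    zeroes the neutral-loss outputs without removing their weights.
    """

    def __init__(self, d_model=256, meta_dim=11, n_heads=8, ffn_dim=1024,
                 n_layers=4, n_modloss_layers=1, decoder_hidden=64,
                 dropout=0.1, mask_modloss=True, seed=0):
        super().__init__()
        self.build_config = dict(
            d_model=d_model, meta_dim=meta_dim, n_heads=n_heads,
            ffn_dim=ffn_dim, n_layers=n_layers,
            n_modloss_layers=n_modloss_layers, decoder_hidden=decoder_hidden,
            dropout=dropout, mask_modloss=mask_modloss, seed=seed,
        )
        self.registry = DEFAULT_REGISTRY
        self.mask_modloss = mask_modloss
        aa_dim = d_model - 8 - meta_dim
        if aa_dim <= 0:
            raise ValueError("d_model too small for the 8+meta embedding")
        rng = np.random.default_rng(seed)
        self.aa_embed = Embedding(27, aa_dim, rng)
        self._build_mod(rng)
        self.meta_nn = Linear(META_DIM, meta_dim, rng)
        drop_rng = np.random.default_rng(seed + 1)
        self.drop = Dropout(dropout, drop_rng)
        self.layers = [
            TransformerEncoderLayer(d_model, n_heads, ffn_dim, dropout, rng)
            for _ in range(n_layers)
        ]
        self.modloss_layers = [
            TransformerEncoderLayer(d_model, n_heads, ffn_dim, dropout, rng)
            for _ in range(n_modloss_layers)
        ]
        self.out_fc1 = Linear(d_model, decoder_hidden, rng)
        self.out_act = PReLU(decoder_hidden)
        self.out_fc2 = Linear(decoder_hidden, 4, rng)
        self.modloss_fc1 = Linear(d_model, decoder_hidden, rng)
        self.modloss_act = PReLU(decoder_hidden)
        self.modloss_fc2 = Linear(decoder_hidden, 4, rng)
        self._frag_targets: np.ndarray | None = None
        self._d_model = d_model

    # -- forward -----------------------------------------------------------
    def forward_batch(self, batch: pd.DataFrame) -> Tensor:
        seqs = batch["sequence"].tolist()
        lengths = np.array([len(s) for s in seqs])
        L = int(lengths.max())
        codes = encode_aa(seqs, L)
        x = Tensor.cat([
            self.aa_embed(codes),
            self._mod_features(batch, L),
            _broadcast_meta(self.meta_nn(Tensor(encode_meta(
                batch["charge"], batch["nce"], batch["instrument"]
            ))), L),
        ], axis=-1)
        x = x + sinusoidal_positions(L, self._d_model)
        x = self.drop(x)
        pad_mask = np.arange(L)[None, :] < lengths[:, None]
        for layer in self.layers:
            x = layer(x, pad_mask)
        main = self.out_fc2(self.out_act(self.out_fc1(x)))
        h = x
        for layer in self.modloss_layers:
            h = layer(h, pad_mask)
        modloss = self.modloss_fc2(self.modloss_act(self.modloss_fc1(h)))
        if self.mask_modloss:
            modloss = modloss * 0.0
        return Tensor.cat([main, modloss], axis=-1)  # (b, L, 8)

    # -- training ----------------------------------------------------------
    def attach_fragment_targets(self, fragment_intensities: pd.DataFrame):
        """Register the fragment-table slice used as training target."""
        self._frag_targets = fragment_intensities[
            list(FRAGMENT_COLUMNS)
        ].to_numpy(dtype=float)

    def loss_on(self, batch: pd.DataFrame, loss: str) -> Tensor:
        if loss != "l1":
            raise ValueError("MS2 model trains with L1 loss")
        if self._frag_targets is None:
            raise ValueError(
                "no fragment targets attached; call attach_fragment_targets"
            )
        pred = self.forward_batch(batch)
        b, L, _ = pred.shape
        lengths = batch["sequence"].str.len().to_numpy()
        target = np.zeros((b, L, 8))
        mask = np.zeros((b, L, 1))
        for i, row in enumerate(batch.itertuples(index=False)):
            n = lengths[i] - 1
            target[i, :n] = self._frag_targets[
                int(row.frag_start_idx):int(row.frag_end_idx)
            ]
            mask[i, :n] = 1.0
        channels = 4 if self.mask_modloss else 8
        diff = (pred - target).abs() * mask
        if self.mask_modloss:
            diff = diff[:, :, :4]
        return diff.sum() / (mask.sum() * channels)

    # -- prediction --------------------------------------------------------
    def predict_fragments(
        self, peptides: pd.DataFrame, batch_size: int = 256
    ) -> pd.DataFrame:
        """Fragment intensity table aligned with the peptides' index
        ranges; values clipped to [0, 1], neutral-loss channels zeroed for
        fragments without a loss-capable modification."""
        if "frag_start_idx" not in peptides.columns:
            peptides = attach_fragment_indices(peptides)
        per_row = predict_batched(self, peptides, batch_size)
        total = int(peptides["frag_end_idx"].max()) if len(peptides) else 0
        out = np.zeros((total, 8))
        for pred, row in zip(per_row, peptides.itertuples(index=False)):
            block = np.clip(pred, 0.0, 1.0)
            names, sites = parse_mod_lists(
                getattr(row, "mods", ""), getattr(row, "mod_sites", "")
            )
            _, loss = _residue_and_mod_masses(
                row.sequence, names, sites, self.registry
            )
            b_capable = (np.maximum.accumulate(loss)[:-1] > 0)
            y_capable = (np.maximum.accumulate(loss[::-1])[::-1][1:] > 0)
            block[:, 4:6] *= b_capable[:, None]
            block[:, 6:8] *= y_capable[:, None]
            out[int(row.frag_start_idx):int(row.frag_end_idx)] = block
        return pd.DataFrame(out, columns=list(FRAGMENT_COLUMNS))


def _broadcast_meta(meta: Tensor, length: int) -> Tensor:
    b, d = meta.shape
    return meta.reshape(b, 1, d) * np.ones((1, length, 1))


class RTModel(SequenceModel, _ModEmbedding):
    """CNN + BiLSTM retention-time regressor (gradient-normalized RT)."""

    target_column = "rt_norm"

    def __init__(self, aa_embed_dim=29, conv_channels=97, conv_kernel=7,
                 lstm_hidden=128, lstm_layers=2, decoder_hidden=64,
                 dropout=0.1, seed=0):
        super().__init__()
        self.build_config = dict(
            aa_embed_dim=aa_embed_dim, conv_channels=conv_channels,
            conv_kernel=conv_kernel, lstm_hidden=lstm_hidden,
            lstm_layers=lstm_layers, decoder_hidden=decoder_hidden,
            dropout=dropout, seed=seed,
        )
        self.registry = DEFAULT_REGISTRY
        rng = np.random.default_rng(seed)
        d_in = aa_embed_dim + 8
        self.aa_embed = Embedding(27, aa_embed_dim, rng)
        self._build_mod(rng)
        self._extra_input_dim = self._charge_input_dim()
        d_in += self._extra_input_dim
        if self._extra_input_dim:
            self.charge_embed = Embedding(11, self._extra_input_dim, rng)
        self.conv = Conv1d(d_in, conv_channels, conv_kernel, rng)
        self.lstm = LSTM(d_in + conv_channels, lstm_hidden, lstm_layers, rng,
                         bidirectional=True)
        self.drop = Dropout(dropout, np.random.default_rng(seed + 1))
        dec_in = 2 * lstm_hidden + self._charge_decoder_dim()
        if self._charge_decoder_dim():
            self.charge_embed_dec = Embedding(
                11, self._charge_decoder_dim(), rng
            )
        self.fc1 = Linear(dec_in, decoder_hidden, rng)
        self.act = PReLU(decoder_hidden)
        self.fc2 = Linear(decoder_hidden, 1, rng)

    # charge hooks, overridden by the CCS model
    def _charge_input_dim(self) -> int:
        return 0

    def _charge_decoder_dim(self) -> int:
        return 0

    def forward_batch(self, batch: pd.DataFrame) -> Tensor:
        seqs = batch["sequence"].tolist()
        lengths = np.array([len(s) for s in seqs])
        L = int(lengths.max())
        codes = encode_aa(seqs, L)
        parts = [self.aa_embed(codes), self._mod_features(batch, L)]
        if self._extra_input_dim:
            z = np.clip(batch["charge"].to_numpy(dtype=int), 0, 10)
            zt = self.charge_embed(z)
            parts.append(zt.reshape(len(seqs), 1, -1) * np.ones((1, L, 1)))
        x = Tensor.cat(parts, axis=-1)
        # zero padded positions so the convolution windows near a peptide's
        # end see the same zeros regardless of the batch pad length
        pad_mask = (np.arange(L)[None, :] < lengths[:, None]).astype(float)
        x = x * pad_mask[:, :, None]
        x = self.drop(x)
        x = Tensor.cat([x, self.conv(x)], axis=-1)
        x = self.lstm(x, lengths)
        pooled = masked_sum(x, lengths)
        if self._charge_decoder_dim():
            z = np.clip(batch["charge"].to_numpy(dtype=int), 0, 10)
            pooled = Tensor.cat([pooled, self.charge_embed_dec(z)], axis=-1)
        y = self.fc2(self.act(self.fc1(pooled)))
        return y.reshape(len(seqs))


class CCSModel(RTModel):
    """RT architecture plus charge-state embeddings at the input and the
    pooled decoder; predicts collisional cross sections (scaled)."""

    target_column = "ccs_norm"

    def __init__(self, charge_input_dim=2, charge_decoder_dim=24, **kwargs):
        self._ci, self._cd = charge_input_dim, charge_decoder_dim
        super().__init__(**kwargs)
        self.build_config.update(
            charge_input_dim=charge_input_dim,
            charge_decoder_dim=charge_decoder_dim,
        )

    def _charge_input_dim(self) -> int:
        return self._ci

    def _charge_decoder_dim(self) -> int:
        return self._cd


def build_production_models(seed: int = 0):
    """The three models at their frozen production dimensions."""
    dims = frozen_dims()
    ms2 = MS2Model(
        d_model=dims["ms2"]["d_model"], meta_dim=dims["ms2"]["meta_dim"],
        n_heads=dims["ms2"]["n_heads"], ffn_dim=dims["ms2"]["ffn_dim"],
        n_layers=dims["ms2"]["n_layers"],
        n_modloss_layers=dims["ms2"]["n_modloss_layers"], seed=seed,
    )
    rt = RTModel(
        aa_embed_dim=dims["rt"]["aa_embed_dim"],
        conv_channels=dims["rt"]["conv_channels"],
        conv_kernel=dims["rt"]["conv_kernel"],
        lstm_hidden=dims["rt"]["lstm_hidden"],
        lstm_layers=dims["rt"]["lstm_layers"], seed=seed,
    )
    ccs = CCSModel(
        charge_input_dim=dims["ccs"]["charge_input_dim"],
        charge_decoder_dim=dims["ccs"]["charge_decoder_dim"],
        aa_embed_dim=dims["rt"]["aa_embed_dim"],
        conv_channels=dims["rt"]["conv_channels"],
        conv_kernel=dims["rt"]["conv_kernel"],
        lstm_hidden=dims["rt"]["lstm_hidden"],
        lstm_layers=dims["rt"]["lstm_layers"], seed=seed,
    )
    return ms2, rt, ccs


# ---------------------------------------------------------------------------
# pre/post-processing
# ---------------------------------------------------------------------------

def normalize_matched_intensities(matched: np.ndarray) -> np.ndarray:
    """Scale a spectrum's matched intensities so the highest equals 1."""
    matched = np.asarray(matched, dtype=float)
    if (matched < 0).any():
        raise ValueError("negative intensity in matched spectrum")
    peak = matched.max(initial=0.0)
    return matched / peak if peak > 0 else matched.copy()


def denormalize_rt(rt_norm, gradient_minutes: float):
    return np.asarray(rt_norm, dtype=float) * gradient_minutes


def calibrate_irt(predicted_rt_norm, reference_irt) -> tuple[float, float]:
    """Least-squares line mapping predicted normalized RT to the iRT scale.

    Mirrors calibration against a small set of reference peptides with
    known iRT values; returns ``(slope, intercept)``.
    """
    x = np.asarray(predicted_rt_norm, dtype=float)
    y = np.asarray(reference_irt, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 reference pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: all reference RTs equal")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def _reduced_mass_sqrt(ion_mass: float) -> float:
    return np.sqrt(ion_mass * MASS_N2 / (ion_mass + MASS_N2))


def ccs_to_mobility(ccs, charge, mz):
    """Mason-Schamp conversion of CCS (A^2) to 1/K0 (V s cm^-2)."""
    ccs = np.asarray(ccs, dtype=float)
    charge = np.asarray(charge, dtype=float)
    mz = np.asarray(mz, dtype=float)
    ion_mass = mz * charge - charge * chem.MASS_PROTON
    if (ion_mass <= 0).any():
        raise ValueError("non-positive ion mass")
    return ccs * _reduced_mass_sqrt(ion_mass) / (MASON_SCHAMP_CONST * charge)


def mobility_to_ccs(mobility, charge, mz):
    """Inverse Mason-Schamp conversion; composes with the forward map to
    the identity."""
    mobility = np.asarray(mobility, dtype=float)
    charge = np.asarray(charge, dtype=float)
    mz = np.asarray(mz, dtype=float)
    ion_mass = mz * charge - charge * chem.MASS_PROTON
    if (ion_mass <= 0).any():
        raise ValueError("non-positive ion mass")
    return mobility * MASON_SCHAMP_CONST * charge / _reduced_mass_sqrt(ion_mass)
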
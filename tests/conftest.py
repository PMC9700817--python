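"""Shared fixtures.

The expensive fixtures (trained tiny models, the rescoring benchmark) are
session-scoped: they are trained once and asserted on by both the module
tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from deeppep import model_shop, rescore, synth
from deeppep.model_shop import TrainConfig
from deeppep.models import MS2Model, RTModel
from deeppep.peptide import attach_fragment_indices, fragment_mz_table


def per_spectrum_pearson(gt: np.ndarray, pred: np.ndarray,
                         table: pd.DataFrame) -> list[float]:
    out = []
    for row in table.itertuples(index=False):
        s, e = int(row.frag_start_idx), int(row.frag_end_idx)
        a, b = gt[s:e].ravel(), pred[s:e].ravel()
        if a.std() > 0 and b.std() > 0:
            out.append(float(np.corrcoef(a, b)[0, 1]))
        else:
            out.append(0.0)
    return out


@pytest.fixture(scope="session")
def rt_experiment(tmp_path_factory):
    """Tiny RT model trained on the hydropathy rule, with a snapshot and a
    few-shot transfer-learning run against a shifted LC condition."""
    cfg = synth.SynthConfig(n_peptides=2000, seed=1)
    table = synth.add_ground_truth(synth.gen_peptides(cfg))
    train_df, test_df = table.iloc[:1500], table.iloc[1500:]
    model = RTModel(aa_embed_dim=16, conv_channels=24, conv_kernel=3,
                    lstm_hidden=24, lstm_layers=1, decoder_hidden=24,
                    dropout=0.0, seed=0)
    tc = TrainConfig(epochs=40, warmup_epochs=5, peak_lr=5e-3, dropout=0.0,
                     batch_size=128, seed=0)
    trace = model_shop.train(model, train_df, tc)
    pred = model_shop.predict_batched(model, test_df)
    r = float(np.corrcoef(pred, test_df["rt_norm"])[0, 1])

    snap = tmp_path_factory.mktemp("snapshots") / "rt_tiny.hdf"
    model_shop.save_snapshot(model, snap)

    # shifted LC condition: compressed + offset gradient
    shifted = table.copy()
    shifted["rt_norm"] = shifted["rt_norm"] * 0.8 + 0.1
    few, held = shifted.iloc[:50], shifted.iloc[1500:]
    pre_mae = float(np.abs(
        model_shop.predict_batched(model, held) - held["rt_norm"]
    ).mean())
    tuned, _ = model_shop.transfer_learn(
        snap, few,
        TrainConfig(epochs=25, warmup_epochs=5, peak_lr=2e-3, dropout=0.0,
                    batch_size=32, seed=0),
    )
    post_mae = float(np.abs(
        model_shop.predict_batched(tuned, held) - held["rt_norm"]
    ).mean())
    return {
        "model": model, "snapshot": snap, "trace": trace,
        "train": train_df, "test": test_df, "heldout_r": r,
        "pre_mae": pre_mae, "post_mae": post_mae,
    }


@pytest.fixture(scope="session")
def ms2_experiment():
    """Tiny MS2 transformer trained on the synthetic fragmentation rule."""
    cfg = synth.SynthConfig(n_peptides=600, seed=2)
    table = synth.add_ground_truth(synth.gen_peptides(cfg))
    frags = synth.ground_truth_fragments(table)
    train_df, test_df = table.iloc[:500], table.iloc[500:]
    model = MS2Model(d_model=64, meta_dim=8, n_heads=4, ffn_dim=128,
                     n_layers=2, n_modloss_layers=1, decoder_hidden=32,
                     dropout=0.0, mask_modloss=False, seed=0)
    model.attach_fragment_targets(frags)
    tc = TrainConfig(epochs=60, warmup_epochs=6, peak_lr=2e-3, dropout=0.0,
                     batch_size=64, seed=0, loss="l1")
    trace = model_shop.train(model, train_df, tc)
    pred = model.predict_fragments(test_df)
    rs = per_spectrum_pearson(frags.to_numpy(), pred.to_numpy(), test_df)
    return {
        "model": model, "trace": trace, "table": table, "frags": frags,
        "test": test_df, "median_r": float(np.median(rs)),
    }


@pytest.fixture(scope="session")
def rescoring_benchmark():
    """The documented synthetic benchmark: 1,500 true + 500 false targets +
    1,500 decoys, 10% intensity jitter, 30% spurious peaks."""
    cfg = synth.SynthConfig(seed=7, intensity_jitter=0.10,
                            spurious_fraction=0.30)
    psms, spectra = synth.gen_psm_table(1500, 500, 1500, cfg, n_raw_files=4)
    psms = attach_fragment_indices(psms)
    predictions = {
        "frag_mz": fragment_mz_table(psms),
        "frag_int": synth.ground_truth_fragments(psms),
        "rt_pred_norm": np.array(
            [synth.synth_rt(s) for s in psms["sequence"]]
        ) / synth.GRADIENT_MINUTES,
    }
    features = rescore.extract_features(psms, predictions, spectra)
    scores = rescore.percolator_rescore(
        features, psms["is_decoy"].to_numpy(), psms["sequence"].to_numpy(),
        seed=0,
    )
    return {
        "psms": psms, "spectra": spectra, "features": features,
        "scores": scores, "predictions": predictions,
    }


@pytest.fixture(scope="session")
def hla_motif_experiment():
    """Separable synthetic motif task: anchors Leu-2 / Val-C-term."""
    from deeppep.hla import HLAClassifier, make_training_table

    pos = synth.gen_motif_peptides(2000, seed=5)
    neg = synth.gen_motif_peptides(2000, seed=6, anchors=())
    table = make_training_table(pos, neg).sample(
        frac=1.0, random_state=0
    ).reset_index(drop=True)
    train_df, test_df = table.iloc[:3200], table.iloc[3200:]
    model = HLAClassifier(embed_dim=16, conv_channels=16, conv_kernel=3,
                          lstm_hidden=24, lstm_layers=1, decoder_hidden=16,
                          dropout=0.0, seed=0)
    tc = TrainConfig(epochs=15, warmup_epochs=3, peak_lr=5e-3, dropout=0.0,
                     batch_size=128, seed=0, loss="bce")
    trace = model_shop.train(model, train_df, tc)
    probs = model_shop.predict_batched(model, test_df)
    labels = test_df["label"].to_numpy() > 0.5
    return {
        "model": model, "trace": trace, "test": test_df, "probs": probs,
        "labels": labels,
        "accuracy": float(np.mean((probs > 0.5) == labels)),
        "true_retained_at_07": float(np.mean(probs[labels] > 0.7)),
        "random_removed_at_07": float(np.mean(probs[~labels] <= 0.7)),
    }
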
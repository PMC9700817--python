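"""MS2/RT/CCS architectures, their output contracts and the surrounding
pre/post-processing (normalization, iRT calibration, Mason-Schamp)."""

import numpy as np
import pandas as pd
import pytest

from deeppep import chem, model_shop, synth
from deeppep.hla import HLAClassifier
from deeppep.models import (
    CCSModel,
    MS2Model,
    RTModel,
    build_production_models,
    calibrate_irt,
    ccs_to_mobility,
    count_parameters,
    denormalize_rt,
    mobility_to_ccs,
    normalize_matched_intensities,
)
from deeppep.peptide import FRAGMENT_COLUMNS, init_peptide_table


@pytest.fixture(scope="module")
def production_models():
    return build_production_models(seed=0)


@pytest.fixture(scope="module")
def tiny_ms2():
    return MS2Model(d_model=32, meta_dim=8, n_heads=4, ffn_dim=48,
                    n_layers=1, n_modloss_layers=1, decoder_hidden=16,
                    dropout=0.0, mask_modloss=False, seed=0)


class TestParameterCounts:
    def test_ms2_total(self, production_models):
        assert count_parameters(production_models[0]) == 3_988_974

    def test_rt_total(self, production_models):
        assert count_parameters(production_models[1]) == 708_224

    def test_ccs_total(self, production_models):
        assert count_parameters(production_models[2]) == 713_452

    def test_hla_total(self):
        assert count_parameters(HLAClassifier()) == 1_669_697


class TestMs2Outputs:
    def test_shape_is_cleavages_by_eight(self, tiny_ms2):
        cfg = synth.SynthConfig(n_peptides=12, seed=30)
        table = synth.gen_peptides(cfg)
        preds = tiny_ms2.predict_fragments(table)
        assert preds.shape[1] == 8
        assert len(preds) == int((table["sequence"].str.len() - 1).sum())

    def test_values_clipped_to_unit_interval(self, tiny_ms2):
        cfg = synth.SynthConfig(n_peptides=20, seed=31)
        preds = tiny_ms2.predict_fragments(synth.gen_peptides(cfg))
        assert preds.to_numpy().min() >= 0.0
        assert preds.to_numpy().max() <= 1.0

    def test_modloss_zero_without_loss_capable_mod(self, tiny_ms2):
        table = init_peptide_table(["PEPTIDEK"], [""], [""])
        preds = tiny_ms2.predict_fragments(table)
        for col in FRAGMENT_COLUMNS[4:]:
            assert (preds[col] == 0).all()

    def test_mask_modloss_zeroes_outputs_not_weights(self):
        masked = MS2Model(d_model=32, meta_dim=8, n_heads=4, ffn_dim=48,
                          n_layers=1, n_modloss_layers=1, decoder_hidden=16,
                          dropout=0.0, mask_modloss=True, seed=0)
        open_ = MS2Model(d_model=32, meta_dim=8, n_heads=4, ffn_dim=48,
                         n_layers=1, n_modloss_layers=1, decoder_hidden=16,
                         dropout=0.0, mask_modloss=False, seed=0)
        assert count_parameters(masked) == count_parameters(open_)
        table = init_peptide_table(["AASDKR"], ["Phospho@S"], ["3"])
        pm = masked.predict_fragments(table)
        po = open_.predict_fragments(table)
        assert (pm[list(FRAGMENT_COLUMNS[4:])].to_numpy() == 0).all()
        # backbone channels agree; the branch only adds the loss outputs
        assert np.allclose(
            pm[list(FRAGMENT_COLUMNS[:4])], po[list(FRAGMENT_COLUMNS[:4])]
        )

    def test_padding_independence(self, tiny_ms2):
        """Predictions for a peptide do not change when it is batched with
        longer peptides (i.e. padded further)."""
        short = init_peptide_table(["PEPTIDEK"])
        both = init_peptide_table(["PEPTIDEK", "A" * 25])
        a = tiny_ms2.predict_fragments(short).to_numpy()
        b = tiny_ms2.predict_fragments(both).to_numpy()[: len(a)]
        assert np.abs(a - b).max() < 1e-9

    def test_unregistered_mod_rejected(self, tiny_ms2):
        table = init_peptide_table(["PEPTIDEK"])
        table.loc[0, "mods"] = "Bogus@P"
        table.loc[0, "mod_sites"] = "1"
        with pytest.raises(Exception, match="Bogus@P"):
            tiny_ms2.predict_fragments(table)


@pytest.fixture(scope="module")
def tiny_pair():
    rt = RTModel(aa_embed_dim=12, conv_channels=8, conv_kernel=3,
                 lstm_hidden=8, lstm_layers=1, decoder_hidden=8,
                 dropout=0.0, seed=0)
    ccs = CCSModel(charge_input_dim=2, charge_decoder_dim=4,
                   aa_embed_dim=12, conv_channels=8, conv_kernel=3,
                   lstm_hidden=8, lstm_layers=1, decoder_hidden=8,
                   dropout=0.0, seed=0)
    return rt, ccs


class TestRtCcsModels:
    def test_scalar_outputs(self, tiny_pair):
        rt, _ = tiny_pair
        table = synth.gen_peptides(synth.SynthConfig(n_peptides=6, seed=33))
        out = model_shop.predict_batched(rt, table)
        assert out.shape == (6,)

    def test_ccs_sensitive_to_charge_rt_not(self, tiny_pair):
        rt, ccs = tiny_pair
        t1 = init_peptide_table(["PEPTIDEKR"], charge=2)
        t2 = init_peptide_table(["PEPTIDEKR"], charge=3)
        assert model_shop.predict_batched(rt, t1) == pytest.approx(
            model_shop.predict_batched(rt, t2)
        )
        assert model_shop.predict_batched(ccs, t1) != pytest.approx(
            model_shop.predict_batched(ccs, t2)
        )

    def test_padding_independence(self, tiny_pair):
        rt, _ = tiny_pair
        a = model_shop.predict_batched(rt, init_peptide_table(["PEPTIDEK"]))
        b = model_shop.predict_batched(
            rt, init_peptide_table(["PEPTIDEK", "A" * 30])
        )
        assert abs(a[0] - b[0]) < 1e-9


class TestNormalization:
    @pytest.mark.parametrize("given,expected", [
        ([10, 5, 0], [1.0, 0.5, 0.0]),
        ([0, 0], [0.0, 0.0]),
        ([7], [1.0]),
    ])
    def test_examples(self, given, expected):
        assert normalize_matched_intensities(np.array(given)).tolist() == \
            expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize_matched_intensities(np.array([1.0, -0.1]))

    def test_rt_denormalization(self):
        assert denormalize_rt(0.5, 60.0) == pytest.approx(30.0)
        assert denormalize_rt(0.0, 60.0) == 0.0


class TestIrtCalibration:
    def test_exact_line_recovered(self):
        x = np.linspace(0.1, 0.9, 11)
        slope, intercept = calibrate_irt(x, 100.0 * x)
        assert slope == pytest.approx(100.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_noisy_line_within_three_se(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, size=60)
        noise = rng.normal(0, 2.0, size=60)
        y = 120.0 * x - 10.0 + noise
        slope, intercept = calibrate_irt(x, y)
        # standard errors of the simple-regression estimates
        resid = y - (slope * x + intercept)
        s2 = (resid ** 2).sum() / (len(x) - 2)
        se_slope = np.sqrt(s2 / ((x - x.mean()) ** 2).sum())
        se_int = np.sqrt(s2 * (1 / len(x) +
                               x.mean() ** 2 / ((x - x.mean()) ** 2).sum()))
        assert abs(slope - 120.0) < 3 * se_slope
        assert abs(intercept + 10.0) < 3 * se_int

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError):
            calibrate_irt([0.5, 0.5, 0.5], [10.0, 20.0, 30.0])
        with pytest.raises(ValueError):
            calibrate_irt([0.5], [10.0])


class TestMasonSchamp:
    def test_zero_ccs_gives_zero_mobility(self):
        assert ccs_to_mobility(0.0, 2, 500.0) == 0.0

    def test_round_trip_identity(self):
        for ccs in (200.0, 400.0, 700.0):
            for z in (1, 2, 3):
                mob = ccs_to_mobility(ccs, z, 500.0)
                assert mobility_to_ccs(mob, z, 500.0) == pytest.approx(
                    ccs, abs=1e-9
                )

    def test_against_independent_formula(self):
        ion_mass = 500.0 * 2 - 2 * chem.MASS_PROTON
        reduced = np.sqrt(ion_mass * 28.00615 / (ion_mass + 28.00615))
        expected = 400.0 * reduced / (1059.62245 * 2)
        assert ccs_to_mobility(400.0, 2, 500.0) == pytest.approx(
            expected, rel=1e-12
        )

    def test_nonpositive_ion_mass_rejected(self):
        with pytest.raises(ValueError):
            ccs_to_mobility(400.0, 1, 0.5)


class TestTrainingContracts:
    def test_l1_loss_used_for_property_models(self):
        """MS2 refuses any loss but L1."""
        m = MS2Model(d_model=32, meta_dim=8, n_heads=4, ffn_dim=48,
                     n_layers=1, n_modloss_layers=1, decoder_hidden=16,
                     seed=0)
        table = init_peptide_table(["PEPTIDEK"])
        with pytest.raises(ValueError, match="L1"):
            m.loss_on(table, "bce")

    def test_ms2_requires_attached_targets(self):
        m = MS2Model(d_model=32, meta_dim=8, n_heads=4, ffn_dim=48,
                     n_layers=1, n_modloss_layers=1, decoder_hidden=16,
                     seed=0)
        with pytest.raises(ValueError, match="attach"):
            m.loss_on(init_peptide_table(["PEPTIDEK"]), "l1")
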
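"""Fragment matching, the 61-feature extractor, target-decoy q-values and
the cross-validated Percolator loop."""

import numpy as np
import pandas as pd
import pytest

from deeppep import rescore, synth
from deeppep.peptide import attach_fragment_indices, fragment_mz_table
from deeppep.rescore import (
    FEATURE_NAMES,
    assign_folds,
    compute_qvalues,
    extract_features,
    match_fragments,
    n_passing,
    percolator_rescore,
    sample_finetune_psms,
)


def brute_force_qvalues(scores, is_decoy):
    """Oracle: evaluate the FDR at every threshold by direct counting."""
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    q = np.empty(len(scores))
    for i, s in enumerate(scores):
        above = scores >= s
        fdrs = []
        # q = min FDR over all thresholds t <= s
        for t in np.unique(scores[scores <= s]):
            sel = scores >= t
            n_d = (sel & is_decoy).sum()
            n_t = (sel & ~is_decoy).sum()
            fdrs.append(n_d / max(n_t, 1))
        q[i] = min(min(fdrs), 1.0)
    return q


class TestMatchFragments:
    def test_exact_peaks_all_matched(self):
        frag_mz = np.array([[200.0, 300.0], [500.0, 0.0]])
        spec_mz = np.array([200.000001, 300.0, 500.0005])
        spec_int = np.array([10.0, 40.0, 20.0])
        got = match_fragments(frag_mz, spec_mz, spec_int, tol_ppm=20)
        assert got[0, 0] == pytest.approx(0.25)
        assert got[0, 1] == pytest.approx(1.0)
        assert got[1, 0] == pytest.approx(0.5)
        assert got[1, 1] == 0.0

    def test_off_by_one_dalton_no_match(self):
        frag_mz = np.array([300.0, 500.0])
        got = match_fragments(frag_mz, np.array([301.0, 499.0]),
                              np.array([5.0, 5.0]), tol_ppm=20)
        assert (got == 0).all()

    def test_most_intense_peak_wins_in_window(self):
        frag_mz = np.array([500.0])
        spec = np.array([499.9999, 500.0004])
        got = match_fragments(frag_mz, spec, np.array([5.0, 50.0]),
                              tol_ppm=20)
        assert got[0] == pytest.approx(1.0)  # the 50-intensity peak

    def test_empty_spectrum_all_zero(self):
        got = match_fragments(np.array([1.0, 2.0]), np.array([]),
                              np.array([]))
        assert (got == 0).all()

    def test_bad_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_fragments(np.array([1.0]), np.array([1.0]),
                            np.array([1.0]), tol_ppm=0)


@pytest.fixture(scope="module")
def small_benchmark():
    cfg = synth.SynthConfig(seed=12)
    psms, spectra = synth.gen_psm_table(40, 10, 40, cfg)
    psms = attach_fragment_indices(psms)
    preds = {
        "frag_mz": fragment_mz_table(psms),
        "frag_int": synth.ground_truth_fragments(psms),
        "rt_pred_norm": np.array(
            [synth.synth_rt(s) for s in psms["sequence"]]
        ) / synth.GRADIENT_MINUTES,
    }
    return psms, spectra, preds


class TestFeatureExtraction:
    def test_exactly_61_columns(self, small_benchmark):
        psms, spectra, preds = small_benchmark
        feats = extract_features(psms, preds, spectra)
        assert feats.shape == (len(psms), 61)
        assert list(feats.columns) == list(FEATURE_NAMES)
        assert np.isfinite(feats.to_numpy()).all()

    def test_perfect_match_maximizes_correlations(self):
        cfg = synth.SynthConfig(seed=13, intensity_jitter=0.0,
                                spurious_fraction=0.0)
        psms, spectra = synth.gen_psm_table(5, 0, 0, cfg)
        psms = attach_fragment_indices(psms)
        preds = {
            "frag_mz": fragment_mz_table(psms),
            "frag_int": synth.ground_truth_fragments(psms),
            "rt_pred_norm": np.zeros(len(psms)),
        }
        feats = extract_features(psms, preds, spectra)
        assert np.allclose(feats["pcc_all"], 1.0, atol=1e-6)
        assert np.allclose(feats["cosine_all"], 1.0, atol=1e-6)
        assert np.allclose(feats["frac_matched"], 1.0)

    def test_decoys_against_random_spectra_decorrelate(self,
                                                       small_benchmark):
        psms, spectra, preds = small_benchmark
        feats = extract_features(psms, preds, spectra)
        decoy_r = feats.loc[psms["is_decoy"].to_numpy(), "pcc_all"]
        assert np.median(np.abs(decoy_r)) < 0.5

    def test_missing_spectrum_names_psm(self, small_benchmark):
        psms, spectra, preds = small_benchmark
        broken = dict(spectra)
        key = (psms["raw_file"].iat[0], psms["spectrum_id"].iat[0])
        del broken[key]
        with pytest.raises(KeyError, match=key[1]):
            extract_features(psms, preds, broken)


class TestQValues:
    def test_simple_example(self):
        scores = np.array([10.0, 9.0, 8.0, 7.0])
        is_decoy = np.array([False, False, False, True])
        q = compute_qvalues(scores, is_decoy)
        assert np.allclose(q[:3], 0.0)

    def test_all_decoys_above_targets(self):
        scores = np.array([10.0, 9.0, 1.0, 0.5])
        is_decoy = np.array([True, True, False, False])
        q = compute_qvalues(scores, is_decoy)
        assert np.allclose(q[2:], 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(size=400).round(2)  # rounding forces ties
        is_decoy = rng.random(400) < 0.5
        got = compute_qvalues(scores, is_decoy)
        want = brute_force_qvalues(scores, is_decoy)
        assert np.allclose(got, want, atol=1e-12)

    def test_alternating_ties_match_oracle(self):
        scores = np.array([5.0, 5.0, 5.0, 5.0, 3.0, 3.0])
        is_decoy = np.array([False, True, False, True, False, True])
        assert np.allclose(
            compute_qvalues(scores, is_decoy),
            brute_force_qvalues(scores, is_decoy),
        )

    def test_monotone_in_score(self):
        rng = np.random.default_rng(15)
        scores = rng.normal(size=300)
        is_decoy = rng.random(300) < 0.4
        q = compute_qvalues(scores, is_decoy)
        order = np.argsort(-scores)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_no_decoys_warns_zero(self):
        with pytest.warns(UserWarning, match="no decoys"):
            q = compute_qvalues(np.array([1.0, 2.0]),
                                np.array([False, False]))
        assert (q == 0).all()

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValueError):
            compute_qvalues(np.array([1.0, np.nan]),
                            np.array([False, True]))


class TestFinetuneSampling:
    def _psms(self, n, n_files, mod_counts, seed=0):
        rng = np.random.default_rng(seed)
        mods = []
        for name, count in mod_counts.items():
            mods.extend([name] * count)
        mods.extend([""] * (n - len(mods)))
        rng.shuffle(mods)
        return pd.DataFrame({
            "sequence": [f"PEPTIDEK{i}" for i in range(n)],
            "mods": mods,
            "mod_sites": ["1" if m else "" for m in mods],
            "raw_file": [f"raw_{i % n_files}" for i in range(n)],
            "spectrum_id": [str(i) for i in range(n)],
            "is_decoy": [False] * n,
        })

    def test_caps_respected_on_large_input(self):
        mod_counts = {f"Mod{i}@K": 400 for i in range(12)}
        psms = self._psms(20000, 20, mod_counts)
        out = sample_finetune_psms(psms, seed=1)
        assert out["raw_file"].nunique() <= 8
        assert len(out) <= 5000 + 10 * 100

    def test_small_input_returned_whole(self):
        psms = self._psms(300, 2, {})
        assert len(sample_finetune_psms(psms, seed=0)) == 300

    def test_top_ten_most_frequent_mods_selected(self):
        counts = {f"Mod{i:02d}@K": 1000 - 50 * i for i in range(12)}
        psms = self._psms(15000, 4, counts)
        out = sample_finetune_psms(psms, seed=2)
        picked = {
            m for mods in out["mods"] if mods for m in mods.split(";")
        }
        expected = {f"Mod{i:02d}@K" for i in range(10)}  # counting oracle
        assert picked == expected
        for name in expected:
            assert (out["mods"] == name).sum() <= 100

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            out = sample_finetune_psms(self._psms(300, 2, {}).head(0))
        assert len(out) == 0


class TestPercolator:
    def test_fold_assignment_partitions_peptides(self):
        peps = np.array(["A", "B", "A", "C", "B", "A"])
        folds = assign_folds(peps, K=2, seed=0)
        for p in "ABC":
            assert len(set(folds[peps == p])) == 1

    def test_fold_assignment_row_order_invariant(self):
        rng = np.random.default_rng(16)
        peps = np.array([f"PEP{i % 37}" for i in range(200)])
        perm = rng.permutation(200)
        a = assign_folds(peps, 2, seed=5)
        b = assign_folds(peps[perm], 2, seed=5)
        assert np.array_equal(a[perm], b)

    def test_identical_features_identical_scores(self):
        n = 60
        feats = pd.DataFrame(
            np.ones((n, len(FEATURE_NAMES))), columns=list(FEATURE_NAMES)
        )
        is_decoy = np.array([i % 2 == 0 for i in range(n)])
        peps = np.array([f"P{i}" for i in range(n)])
        scores = percolator_rescore(feats, is_decoy, peps, seed=0)
        assert np.allclose(scores, scores[0])

    def test_fold_without_decoys_rejected(self):
        n = 20
        feats = pd.DataFrame(
            np.random.default_rng(0).normal(size=(n, len(FEATURE_NAMES))),
            columns=list(FEATURE_NAMES),
        )
        scores_decoy = np.zeros(n, dtype=bool)  # no decoys at all
        peps = np.array([f"P{i}" for i in range(n)])
        with pytest.raises(ValueError, match="lack both classes"):
            percolator_rescore(feats, scores_decoy, peps, seed=0)

    def test_benchmark_gains_over_search_score(self, rescoring_benchmark):
        psms = rescoring_benchmark["psms"]
        raw = n_passing(psms["search_score"].to_numpy(),
                        psms["is_decoy"].to_numpy())
        new = n_passing(rescoring_benchmark["scores"],
                        psms["is_decoy"].to_numpy())
        assert new >= raw

    def test_benchmark_auc_improves(self, rescoring_benchmark):
        from sklearn.metrics import roc_auc_score
        psms = rescoring_benchmark["psms"]
        truth = psms["is_true"].to_numpy()
        auc_raw = roc_auc_score(truth, psms["search_score"])
        auc_new = roc_auc_score(truth, rescoring_benchmark["scores"])
        assert auc_new > auc_raw


class TestPsmTableIO:
    def test_tsv_roundtrip_and_column_mapping(self, tmp_path):
        df = pd.DataFrame({
            "Raw file": ["r1", "r1"],
            "Scan number": [10, 11],
            "Sequence": ["PEPTIDEK", "AAAAKR"],
            "Charge": [2, 3],
            "Score": [50.0, 20.0],
            "Retention time": [12.0, 30.0],
            "Reverse": ["", "+"],
        })
        path = tmp_path / "msms.txt"
        df.to_csv(path, sep="\t", index=False)
        got = rescore.read_psm_tsv(path, rescore.MAXQUANT_COLUMN_MAP)
        assert got["is_decoy"].tolist() == [False, True]
        assert got["raw_file"].tolist() == ["r1", "r1"]
        assert got["mods"].tolist() == ["", ""]
        out = tmp_path / "out.tsv"
        rescore.write_psm_tsv(got, out)
        again = rescore.read_psm_tsv(out)
        assert again["sequence"].tolist() == got["sequence"].tolist()
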
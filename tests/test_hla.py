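"""Proteome concatenation, suffix-array digestion, negative sampling and
the HLA presentation classifier."""

import numpy as np
import pandas as pd
import pytest

from deeppep import model_shop, synth
from deeppep.hla import (
    ConcatProteome,
    DigestIndex,
    HLAClassifier,
    brute_force_digest,
    concat_proteome,
    filter_hla_candidates,
    make_training_table,
    sample_negatives,
    split_train_test,
    train_hla_classifier,
    unspecific_digest,
)
from deeppep.model_shop import TrainConfig


def random_proteome(n_prot, max_len, seed, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    rng = np.random.default_rng(seed)
    prots = [
        "".join(rng.choice(list(alphabet),
                           size=rng.integers(20, max_len)))
        for _ in range(n_prot)
    ]
    return ConcatProteome(prots, [f"P{i}" for i in range(n_prot)])


class TestConcatProteome:
    def test_length_arithmetic(self):
        cat = ConcatProteome(["A" * 10, "C" * 20], ["p1", "p2"])
        assert len(cat.text) == 31

    def test_single_protein_has_no_separator(self):
        cat = ConcatProteome(["PEPTIDE"], ["p"])
        assert "$" not in cat.text

    def test_roundtrip_slicing(self):
        seqs = ["MKTAYIAK", "GELVIS", "QQQQQQQQQQ"]
        cat = ConcatProteome(seqs, ["a", "b", "c"])
        assert [cat.protein(i) for i in range(3)] == seqs

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ConcatProteome([], [])

    def test_fasta_reader_with_uniprot_headers(self, tmp_path):
        fasta = tmp_path / "db.fasta"
        fasta.write_text(
            ">sp|P12345|TEST_HUMAN some protein\nMKTAYIAK\n"
            ">sp|Q99999|OTHER_HUMAN\nGELVISLIVES\n"
        )
        cat = concat_proteome(str(fasta))
        assert cat.ids == ["P12345", "Q99999"]
        assert cat.protein(1) == "GELVISLIVES"

    def test_empty_fasta_rejected(self, tmp_path):
        fasta = tmp_path / "empty.fasta"
        fasta.write_text("")
        with pytest.raises(ValueError):
            concat_proteome(str(fasta))


class TestUnspecificDigest:
    def test_homopolymer_example(self):
        cat = ConcatProteome(["A" * 10], ["p"])
        got = sorted(unspecific_digest(cat).decode(cat.text))
        assert got == ["A" * 8, "A" * 9, "A" * 10]

    def test_short_protein_yields_nothing(self):
        cat = ConcatProteome(["PEPTIDE"], ["p"])  # length 7 < 8
        assert len(unspecific_digest(cat)) == 0

    def test_matches_brute_force_on_random_proteomes(self):
        for seed in (0, 1, 2):
            cat = random_proteome(4, 300, seed)
            idx = unspecific_digest(cat)
            got = idx.decode(cat.text)
            assert len(got) == len(set(got))  # deduplicated
            assert set(got) == brute_force_digest(cat)

    def test_length_bounds_enforced(self):
        cat = random_proteome(2, 200, 3)
        idx = unspecific_digest(cat, 8, 14)
        lengths = idx.ends - idx.starts
        assert lengths.min() >= 8 and lengths.max() <= 14

    def test_nonstandard_residues_excluded(self):
        cat = ConcatProteome(["AAAAXAAAAAAAA"], ["p"])
        got = unspecific_digest(cat).decode(cat.text)
        assert all("X" not in p for p in got)
        # brute force agrees
        assert set(got) == brute_force_digest(cat)

    def test_no_span_crosses_separator(self):
        cat = ConcatProteome(["A" * 9, "C" * 9], ["a", "b"])
        idx = unspecific_digest(cat)
        for pep in idx.decode(cat.text):
            assert "$" not in pep

    def test_bad_length_range_rejected(self):
        cat = ConcatProteome(["A" * 20], ["p"])
        with pytest.raises(ValueError):
            unspecific_digest(cat, 10, 8)

    def test_hdf_roundtrip(self, tmp_path):
        cat = random_proteome(2, 100, 4)
        idx = unspecific_digest(cat)
        path = tmp_path / "digest.hdf"
        idx.to_hdf(path)
        idx2 = DigestIndex.from_hdf(path)
        assert np.array_equal(idx.starts, idx2.starts)
        assert np.array_equal(idx.ends, idx2.ends)
        assert (idx2.min_len, idx2.max_len) == (8, 14)


class TestNegativeSampling:
    def test_matches_length_histogram(self):
        cat = random_proteome(5, 400, 5)
        positives = synth.gen_motif_peptides(100, seed=6)
        negs = sample_negatives(positives, cat, seed=0)
        assert len(negs) == len(positives)
        want = pd.Series([len(p) for p in positives]).value_counts()
        got = pd.Series([len(n) for n in negs]).value_counts()
        assert want.to_dict() == got.to_dict()
        assert not set(negs) & set(positives)
        assert all("$" not in n for n in negs)

    def test_seed_reproducible(self):
        cat = random_proteome(5, 400, 5)
        positives = synth.gen_motif_peptides(50, seed=6)
        assert sample_negatives(positives, cat, seed=3) == \
            sample_negatives(positives, cat, seed=3)

    def test_exhausted_proteome_rejected(self):
        cat = ConcatProteome(["AAAAAAAAA"], ["p"])  # one 9-mer only
        positives = ["AAAAAAAAA"]
        with pytest.raises(ValueError, match="too small"):
            sample_negatives(positives, cat, seed=0)

    def test_empty_positives_rejected(self):
        cat = random_proteome(2, 100, 7)
        with pytest.raises(ValueError):
            sample_negatives([], cat, seed=0)


class TestClassifier:
    def test_single_class_rejected(self):
        table = pd.DataFrame({"sequence": ["PEPTIDEK"], "label": [1.0]})
        with pytest.raises(ValueError, match="both classes"):
            train_hla_classifier(table, TrainConfig(epochs=1,
                                                    warmup_epochs=0))

    def test_split_by_unique_peptide(self):
        table = make_training_table(
            synth.gen_motif_peptides(50, seed=8),
            synth.gen_motif_peptides(50, seed=9, anchors=()),
        )
        tr, te = split_train_test(table, 0.2, seed=0)
        assert len(tr) + len(te) == len(table)
        assert not set(tr["sequence"]) & set(te["sequence"])

    def test_motif_task_accuracy(self, hla_motif_experiment):
        assert hla_motif_experiment["accuracy"] > 0.9

    def test_untrained_model_near_chance(self, hla_motif_experiment):
        model = HLAClassifier(embed_dim=16, conv_channels=16, conv_kernel=3,
                              lstm_hidden=24, lstm_layers=1,
                              decoder_hidden=16, seed=1)
        probs = model_shop.predict_batched(
            model, hla_motif_experiment["test"]
        )
        labels = hla_motif_experiment["labels"]
        acc = np.mean((probs > 0.5) == labels)
        assert 0.3 < acc < 0.7

    def test_probability_output_range(self, hla_motif_experiment):
        probs = hla_motif_experiment["probs"]
        assert (probs > 0).all() and (probs < 1).all()


class TestCandidateFilter:
    def test_thresholds_zero_and_one(self, hla_motif_experiment):
        model = hla_motif_experiment["model"]
        cat = random_proteome(2, 60, 10)
        digest = unspecific_digest(cat)
        all_pass = filter_hla_candidates(model, cat, digest, threshold=0.0)
        none_pass = filter_hla_candidates(model, cat, digest, threshold=1.0)
        assert len(all_pass) == len(digest)
        assert len(none_pass) == 0  # strict inequality

    def test_motif_enrichment_at_07(self, hla_motif_experiment):
        """The 0.7 filter keeps most true-motif peptides and drops most
        background peptides."""
        assert hla_motif_experiment["true_retained_at_07"] > 0.85
        assert hla_motif_experiment["random_removed_at_07"] > 0.80

    def test_candidates_tsv(self, hla_motif_experiment, tmp_path):
        from deeppep.hla import candidates_to_tsv
        model = hla_motif_experiment["model"]
        cat = random_proteome(1, 60, 11)
        digest = unspecific_digest(cat)
        cands = filter_hla_candidates(model, cat, digest, threshold=0.0)
        path = tmp_path / "cands.tsv"
        candidates_to_tsv(cands, path)
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == [
            "sequence", "start", "end", "probability"
        ]
        assert len(back) == len(cands)


class TestTransferToNewMotif:
    def test_few_shot_recovers_held_out_motif(self, tmp_path):
        """A pan-model trained on two motifs, fine-tuned with 100 peptides
        of an unseen third motif, recovers most of that motif's test
        peptides at the 0.7 filter."""
        motif_a = ((2, "L"), (-1, "V"))
        motif_b = ((2, "Y"), (-1, "K"))
        motif_c = ((2, "E"), (-1, "F"))
        pos = (synth.gen_motif_peptides(800, seed=20, anchors=motif_a)
               + synth.gen_motif_peptides(800, seed=21, anchors=motif_b))
        neg = synth.gen_motif_peptides(1600, seed=22, anchors=())
        pan_table = make_training_table(pos, neg).sample(
            frac=1.0, random_state=1
        ).reset_index(drop=True)
        model = HLAClassifier(embed_dim=16, conv_channels=16, conv_kernel=3,
                              lstm_hidden=24, lstm_layers=1,
                              decoder_hidden=16, dropout=0.0, seed=0)
        train_hla_classifier(model=model, samples=pan_table, cfg=TrainConfig(
            epochs=12, warmup_epochs=2, peak_lr=5e-3, dropout=0.0,
            batch_size=128, seed=0, loss="bce",
        ))
        snap = tmp_path / "pan.hdf"
        model_shop.save_snapshot(model, snap)

        few = make_training_table(
            synth.gen_motif_peptides(100, seed=23, anchors=motif_c),
            synth.gen_motif_peptides(100, seed=24, anchors=()),
        )
        tuned, _ = model_shop.transfer_learn(snap, few, TrainConfig(
            epochs=30, warmup_epochs=3, peak_lr=5e-3, dropout=0.0,
            batch_size=64, seed=0, loss="bce",
        ))
        test_c = synth.gen_motif_peptides(400, seed=25, anchors=motif_c)
        probs = model_shop.predict_batched(
            tuned, pd.DataFrame({"sequence": test_c})
        )
        assert np.mean(probs > 0.7) > 0.7
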
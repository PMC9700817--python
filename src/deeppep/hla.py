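"""HLA-I peptide pipeline: unspecific digestion of a proteome and a binary
presentation classifier.

Protein sequences are concatenated into one string with ``"$"`` separators;
the unspecific digest stores only (start, end) index pairs into that
string, never the materialized peptide list.  Deduplication across the
proteome uses a suffix array with its LCP (longest-common-prefix) array:
each distinct substring of length 8-14 is emitted exactly once.  Candidate
peptides are scored by a CNN-LSTM sigmoid classifier; sequences with
probability strictly above 0.7 are retained.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd
from Bio import SeqIO

from .model_shop import SequenceModel, TrainConfig, predict_batched, train
from .nn import (
    LSTM,
    Conv1d,
    Dropout,
    Embedding,
    Linear,
    PReLU,
    Tensor,
    masked_sum,
)

SEPARATOR = "$"
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class ConcatProteome:
    """Proteome flattened to a single ``"$"``-separated string."""

    def __init__(self, sequences: list[str], ids: list[str]):
        if not sequences:
            raise ValueError("empty proteome")
        sequences = [s.upper() for s in sequences]
        for s in sequences:
            if SEPARATOR in s:
                raise ValueError("protein sequence contains the separator")
        self.ids = list(ids)
        self.text = SEPARATOR.join(sequences)
        offsets = [0]
        for s in sequences[:-1]:
            offsets.append(offsets[-1] + len(s) + 1)
        self.offsets = np.array(offsets, dtype=np.int64)
        self.lengths = np.array([len(s) for s in sequences], dtype=np.int64)

    def protein(self, i: int) -> str:
        start = self.offsets[i]
        return self.text[start:start + self.lengths[i]]

    @property
    def n_nonstandard(self) -> int:
        return sum(
            1 for c in self.text if c != SEPARATOR and c not in STANDARD_AA
        )


def _uniprot_accession(header_id: str) -> str:
    parts = header_id.split("|")
    return parts[1] if len(parts) >= 2 else header_id


def concat_proteome(fasta) -> ConcatProteome:
    """Read a FASTA file (UniProt-style headers supported) and flatten it."""
    records = list(SeqIO.parse(fasta, "fasta"))
    if not records:
        raise ValueError(f"no sequences in FASTA {fasta!r}")
    return ConcatProteome(
        [str(r.seq) for r in records],
        [_uniprot_accession(r.id) for r in records],
    )


# ---------------------------------------------------------------------------
# suffix array + LCP digestion
# ---------------------------------------------------------------------------

def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), NumPy-vectorized)."""
    n = len(codes)
    rank = np.asarray(codes, dtype=np.int64)
    sa = np.argsort(rank, kind="stable")
    k = 1
    tmp = np.empty(n, dtype=np.int64)
    while k < n:
        second = np.full(n, -1, dtype=np.int64)
        second[:n - k] = rank[k:]
        order = np.lexsort((second, rank))
        tmp[order[0]] = 0
        prev = order[:-1]
        cur = order[1:]
        new = (rank[cur] != rank[prev]) | (second[cur] != second[prev])
        tmp[cur] = np.cumsum(new)
        rank = tmp.copy()
        sa = order
        if rank[sa[-1]] == n - 1:
            break
        k *= 2
    return sa


def _lcp_array(text: str, sa: np.ndarray) -> np.ndarray:
    """Kasai's algorithm: lcp[r] = LCP(suffix sa[r-1], suffix sa[r])."""
    n = len(text)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and text[i + h] == text[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


class DigestIndex:
    """(start, end) spans into a concatenated proteome, half-open."""

    def __init__(self, starts: np.ndarray, ends: np.ndarray,
                 min_len: int, max_len: int):
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.min_len = min_len
        self.max_len = max_len

    def __len__(self) -> int:
        return len(self.starts)

    def decode(self, text: str, rows=None) -> list[str]:
        if rows is None:
            rows = range(len(self))
        return [text[self.starts[i]:self.ends[i]] for i in rows]

    def to_hdf(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["min_len"] = self.min_len
            fh.attrs["max_len"] = self.max_len
            fh.create_dataset("starts", data=self.starts)
            fh.create_dataset("ends", data=self.ends)

    @classmethod
    def from_hdf(cls, path) -> "DigestIndex":
        with h5py.File(path, "r") as fh:
            return cls(
                np.asarray(fh["starts"]), np.asarray(fh["ends"]),
                int(fh.attrs["min_len"]), int(fh.attrs["max_len"]),
            )


def _valid_run(text: str) -> np.ndarray:
    """run[i] = number of consecutive standard residues starting at i."""
    n = len(text)
    run = np.zeros(n + 1, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        run[i] = run[i + 1] + 1 if text[i] in STANDARD_AA else 0
    return run[:n]


def unspecific_digest(
    cat: ConcatProteome, min_len: int = 8, max_len: int = 14
) -> DigestIndex:
    """All distinct substrings with length in [min_len, max_len].

    Equivalent to brute-force enumeration of every substring of every
    protein followed by proteome-wide deduplication, but stores indices
    only.  Substrings containing the separator or a non-standard residue
    (U, B, X, Z, ...) are excluded.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    text = cat.text
    n = len(text)
    run = _valid_run(text)
    codes = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    sa = _suffix_array(codes)
    lcp = _lcp_array(text, sa)
    starts, ends = [], []
    for r in range(n):
        p = sa[r]
        lo = max(min_len, int(lcp[r]) + 1)
        hi = min(max_len, int(run[p]))
        for ln in range(lo, hi + 1):
            starts.append(p)
            ends.append(p + ln)
    return DigestIndex(np.array(starts, dtype=np.int64),
                       np.array(ends, dtype=np.int64), min_len, max_len)


def brute_force_digest(
    cat: ConcatProteome, min_len: int = 8, max_len: int = 14
) -> set[str]:
    """Independent reference enumeration of the digest peptide set."""
    out: set[str] = set()
    for i in range(len(cat.ids)):
        seq = cat.protein(i)
        for a in range(len(seq)):
            for ln in range(min_len, max_len + 1):
                pep = seq[a:a + ln]
                if len(pep) == ln and set(pep) <= STANDARD_AA:
                    out.add(pep)
    return out


# ---------------------------------------------------------------------------
# negative sampling
# ---------------------------------------------------------------------------

def sample_negatives(
    positives: list[str], cat: ConcatProteome, seed: int = 0,
    max_tries: int = 200,
) -> list[str]:
    """Random proteome substrings with the positives' length distribution.

    Negatives are unique, never cross the ``"$"`` separator, contain only
    standard residues and never coincide with a positive sequence.
    """
    if not positives:
        raise ValueError("positives must be non-empty")
    rng = np.random.default_rng(seed)
    pos_set = set(positives)
    run = _valid_run(cat.text)
    text = cat.text
    need: dict[int, int] = {}
    for p in positives:
        need[len(p)] = need.get(len(p), 0) + 1
    negatives: list[str] = []
    taken: set[str] = set()
    for ln, count in sorted(need.items()):
        starts = np.flatnonzero(run >= ln)
        if len(starts) == 0:
            raise ValueError(f"proteome has no substring of length {ln}")
        got = 0
        for _ in range(max_tries):
            if got >= count:
                break
            draw = rng.choice(starts, size=max(count - got, 16))
            for s in draw:
                pep = text[s:s + ln]
                if pep in pos_set or pep in taken:
                    continue
                negatives.append(pep)
                taken.add(pep)
                got += 1
                if got >= count:
                    break
        if got < count:
            raise ValueError(
                f"proteome too small to sample {count} negatives of "
                f"length {ln}"
            )
    return negatives


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

class HLAClassifier(SequenceModel):
    """ASCII embedding + CNN + two unidirectional LSTM layers + sigmoid."""

    target_column = "label"

    def __init__(self, embed_dim=249, conv_channels=208, conv_kernel=7,
                 lstm_hidden=256, lstm_layers=2, decoder_hidden=64,
                 dropout=0.1, seed=0):
        super().__init__()
        self.build_config = dict(
            embed_dim=embed_dim, conv_channels=conv_channels,
            conv_kernel=conv_kernel, lstm_hidden=lstm_hidden,
            lstm_layers=lstm_layers, decoder_hidden=decoder_hidden,
            dropout=dropout, seed=seed,
        )
        rng = np.random.default_rng(seed)
        self.embed = Embedding(128, embed_dim, rng)
        self.conv = Conv1d(embed_dim, conv_channels, conv_kernel, rng)
        self.lstm = LSTM(embed_dim + conv_channels, lstm_hidden, lstm_layers,
                         rng, bidirectional=False)
        self.drop = Dropout(dropout, np.random.default_rng(seed + 1))
        self.fc1 = Linear(lstm_hidden, decoder_hidden, rng)
        self.act = PReLU(decoder_hidden)
        self.fc2 = Linear(decoder_hidden, 1, rng)

    def forward_batch(self, batch: pd.DataFrame) -> Tensor:
        from .encoding import encode_ascii
        seqs = batch["sequence"].tolist()
        lengths = np.array([len(s) for s in seqs])
        x = self.embed(encode_ascii(seqs))
        L = x.shape[1]
        pad_mask = (np.arange(L)[None, :] < lengths[:, None]).astype(float)
        x = x * pad_mask[:, :, None]
        x = self.drop(x)
        x = Tensor.cat([x, self.conv(x)], axis=-1)
        x = self.lstm(x, lengths)
        pooled = masked_sum(x, lengths)
        return self.fc2(self.act(self.fc1(pooled))).reshape(
            len(seqs)
        ).sigmoid()


def split_train_test(samples: pd.DataFrame, test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """80/20 split by unique peptide sequence."""
    uniq = samples["sequence"].drop_duplicates().to_numpy()
    rng = np.random.default_rng(seed)
    rng.shuffle(uniq)
    n_test = int(round(len(uniq) * test_fraction))
    test_set = set(uniq[:n_test])
    mask = samples["sequence"].isin(test_set)
    return samples[~mask].reset_index(drop=True), \
        samples[mask].reset_index(drop=True)


def make_training_table(positives: list[str],
                        negatives: list[str]) -> pd.DataFrame:
    return pd.DataFrame({
        "sequence": list(positives) + list(negatives),
        "label": [1.0] * len(positives) + [0.0] * len(negatives),
    })


def train_hla_classifier(samples: pd.DataFrame, cfg: TrainConfig,
                         model: HLAClassifier | None = None,
                         ) -> tuple[HLAClassifier, list[float]]:
    labels = set(samples["label"].unique())
    if len(labels) < 2:
        raise ValueError("training table must contain both classes")
    if model is None:
        model = HLAClassifier(seed=cfg.seed)
    trace = train(model, samples, cfg)
    return model, trace


def filter_hla_candidates(
    model: HLAClassifier, cat: ConcatProteome, digest: DigestIndex,
    threshold: float = 0.7, batch_size: int = 512,
    chunk_size: int = 20000,
) -> pd.DataFrame:
    """Digest spans whose predicted probability strictly exceeds the
    threshold; peptides are decoded chunk-wise from the index, never all at
    once."""
    keep_start, keep_end, keep_prob = [], [], []
    text = cat.text
    for lo in range(0, len(digest), chunk_size):
        hi = min(lo + chunk_size, len(digest))
        seqs = [text[digest.starts[i]:digest.ends[i]] for i in range(lo, hi)]
        probs = predict_batched(
            model, pd.DataFrame({"sequence": seqs}), batch_size
        )
        sel = np.flatnonzero(probs > threshold)
        keep_start.extend(digest.starts[lo + sel])
        keep_end.extend(digest.ends[lo + sel])
        keep_prob.extend(probs[sel])
    out = pd.DataFrame({
        "start": np.array(keep_start, dtype=np.int64),
        "end": np.array(keep_end, dtype=np.int64),
        "probability": keep_prob,
    })
    out["sequence"] = [text[s:e] for s, e in zip(out["start"], out["end"])]
    return out


def candidates_to_tsv(candidates: pd.DataFrame, path) -> None:
    candidates[["sequence", "start", "end", "probability"]].to_csv(
        path, sep="\t", index=False
    )
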
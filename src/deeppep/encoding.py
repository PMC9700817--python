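"""Numeric encodings of sequences, PTMs and metadata for the models.

Amino acids map to the integers 1..26 by alphabet position ('A' -> 1, 'Z'
-> 26) with 0 reserved for padding, a 27-symbol vocabulary.  Each PTM is
described per position by the raw element counts of its composition over
the frozen element vocabulary (6 CHNOSP channels first, then the 22 other
elements); the models compress the other-element block to 2 learned
channels, giving the 8-D PTM embedding.  Metadata (precursor charge,
normalized collision energy, instrument type) becomes a fixed-width
vector: charge one-hot up to 10, NCE scaled by 1/100, instrument one-hot
over a small extensible vocabulary.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import chem
from .modification import ModificationRegistry
from .peptide import DEFAULT_REGISTRY, parse_mod_lists

AA_VOCAB_SIZE = 27
#: raw per-position PTM feature width: 6 CHNOSP + 22 other elements
MOD_RAW_DIM = len(chem.ELEMENTS)
#: width of the PTM embedding after the other-element projection: 6 + 2
PTM_FEATURE_DIM = 8
MAX_CHARGE = 10
INSTRUMENTS = ("QE", "Lumos", "timsTOF", "SciexTOF", "unknown")
META_DIM = MAX_CHARGE + 1 + len(INSTRUMENTS)

_ELEMENT_INDEX = {el: i for i, el in enumerate(chem.ELEMENTS)}


def encode_aa(sequences, pad_to: int | None = None) -> np.ndarray:
    """Integer codes (batch, pad_to), right-padded with 0."""
    seqs = list(sequences)
    maxlen = max((len(s) for s in seqs), default=0)
    if pad_to is None:
        pad_to = maxlen
    elif pad_to < maxlen:
        raise ValueError(f"pad_to={pad_to} < longest sequence ({maxlen})")
    out = np.zeros((len(seqs), pad_to), dtype=np.int64)
    for i, s in enumerate(seqs):
        for j, aa in enumerate(s):
            code = ord(aa) - ord("A") + 1
            if not 1 <= code <= 26:
                raise ValueError(f"invalid residue {aa!r} in {s!r}")
            out[i, j] = code
    return out


def encode_ascii(sequences, pad_to: int | None = None) -> np.ndarray:
    """Raw ASCII codes (vocabulary 128), right-padded with 0."""
    seqs = list(sequences)
    maxlen = max((len(s) for s in seqs), default=0)
    if pad_to is None:
        pad_to = maxlen
    out = np.zeros((len(seqs), pad_to), dtype=np.int64)
    for i, s in enumerate(seqs):
        codes = [ord(c) for c in s]
        if any(c >= 128 for c in codes):
            raise ValueError(f"non-ASCII character in {s!r}")
        out[i, : len(codes)] = codes
    return out


def one_hot(codes: np.ndarray, num_classes: int = AA_VOCAB_SIZE) -> np.ndarray:
    codes = np.asarray(codes)
    if codes.min(initial=0) < 0 or codes.max(initial=0) >= num_classes:
        raise ValueError(f"codes out of range [0, {num_classes})")
    return np.eye(num_classes)[codes]


def encode_ptm(
    mods,
    mod_sites,
    seq_lengths,
    pad_to: int,
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> np.ndarray:
    """Raw per-position PTM element counts (batch, pad_to, MOD_RAW_DIM).

    Unmodified positions are all-zero.  The N-terminal site (0) is folded
    onto position 0 and the C-terminal site (-1) onto the last residue.
    """
    mods = list(mods)
    mod_sites = list(mod_sites)
    seq_lengths = list(seq_lengths)
    out = np.zeros((len(mods), pad_to, MOD_RAW_DIM))
    for i, (m, s, n) in enumerate(zip(mods, mod_sites, seq_lengths)):
        names, sites = parse_mod_lists(m, s)
        for name, site in zip(names, sites):
            mod = registry[name]
            pos = 0 if site == 0 else (n - 1 if site == -1 else site - 1)
            for el, cnt in mod.composition.items():
                out[i, pos, _ELEMENT_INDEX[el]] += cnt
    return out


def instrument_index(instrument: str) -> int:
    try:
        return INSTRUMENTS.index(instrument)
    except ValueError:
        return INSTRUMENTS.index("unknown")


def encode_meta(charge, nce, instrument) -> np.ndarray:
    """Meta vectors (batch, META_DIM): charge one-hot | nce/100 | instrument."""
    charge = np.atleast_1d(np.asarray(charge, dtype=np.int64))
    nce = np.atleast_1d(np.asarray(nce, dtype=float))
    instr = np.atleast_1d(np.asarray(instrument, dtype=object))
    if (charge > MAX_CHARGE).any():
        warnings.warn(
            f"charge above {MAX_CHARGE} clamped for encoding", stacklevel=2
        )
    if (charge < 1).any():
        raise ValueError("charge must be >= 1")
    z = np.clip(charge, 1, MAX_CHARGE)
    out = np.zeros((len(charge), META_DIM))
    out[np.arange(len(charge)), z - 1] = 1.0
    out[:, MAX_CHARGE] = nce / 100.0
    for i, name in enumerate(instr):
        out[i, MAX_CHARGE + 1 + instrument_index(str(name))] = 1.0
    return out
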
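"""Peptide tables, monoisotopic masses and b/y fragment m/z computation.

A *peptide table* is a plain :class:`pandas.DataFrame` with one row per
precursor.  Core columns: ``sequence`` (uppercase), ``mods``
(semicolon-joined modification names, may be empty), ``mod_sites``
(semicolon-joined integers; 1-based residue position, 0 = N-terminal,
-1 = C-terminal) and ``charge``.  Fragment data live in a separate
*fragment table* whose rows are the (n-1) cleavage positions of all
peptides concatenated; ``frag_start_idx``/``frag_end_idx`` columns link the
two.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import chem
from .modification import ModificationRegistry

#: The eight fragment channels, in fixed order.
FRAGMENT_COLUMNS = (
    "b+", "b++", "y+", "y++",
    "b_modloss+", "b_modloss++", "y_modloss+", "y_modloss++",
)

DEFAULT_REGISTRY = ModificationRegistry()


def parse_mod_lists(mods: str, mod_sites: str) -> tuple[list[str], list[int]]:
    names = [m for m in str(mods or "").split(";") if m]
    sites = [int(s) for s in str(mod_sites or "").split(";") if s != ""]
    if len(names) != len(sites):
        raise ValueError(
            f"mods/mod_sites length mismatch: {mods!r} vs {mod_sites!r}"
        )
    return names, sites


def peptide_mono_mass(
    sequence: str,
    mods: str = "",
    mod_sites: str = "",
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> float:
    """Monoisotopic mass in Da: residues + water + modification deltas."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    mass = chem.MASS_H2O
    for aa in sequence:
        try:
            mass += chem.AA_MONO_MASS[aa]
        except KeyError:
            raise ValueError(
                f"residue {aa!r} has no defined monoisotopic mass"
            ) from None
    names, _ = parse_mod_lists(mods, mod_sites)
    for name in names:
        mass += registry[name].mono_mass
    return mass


def precursor_mz(mono_mass: float, charge: int) -> float:
    if charge <= 0:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mono_mass + charge * chem.MASS_PROTON) / charge


def allocate_fragment_indices(
    peptide_lengths,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Contiguous half-open row ranges of size n-1 per peptide.

    Returns ``(start_idx, end_idx, total_rows)``.  The fragment table is
    pre-allocated once for all peptides; each peptide owns rows
    ``start:end``.
    """
    lengths = np.asarray(peptide_lengths, dtype=np.int64)
    if (lengths < 2).any():
        bad = lengths[lengths < 2]
        raise ValueError(
            f"peptide length must be >= 2 to have a fragmentable bond, "
            f"got {bad.tolist()}"
        )
    sizes = lengths - 1
    end = np.cumsum(sizes)
    start = end - sizes
    return start, end, int(end[-1]) if len(end) else 0


def attach_fragment_indices(peptides: pd.DataFrame) -> pd.DataFrame:
    start, end, _ = allocate_fragment_indices(
        peptides["sequence"].str.len().to_numpy()
    )
    peptides = peptides.copy()
    peptides["frag_start_idx"] = start
    peptides["frag_end_idx"] = end
    return peptides


def _residue_and_mod_masses(
    sequence: str, names: list[str], sites: list[int],
    registry: ModificationRegistry,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cleavage prefix masses and prefix max-neutral-loss masses.

    Terminal modifications are assigned to the first (site 0) or last
    (site -1) residue, so b ions carry N-terminal mods and y ions carry
    C-terminal ones.
    """
    n = len(sequence)
    res = np.array([chem.AA_MONO_MASS[aa] for aa in sequence])
    loss = np.zeros(n)
    for name, site in zip(names, sites):
        mod = registry[name]
        pos = 0 if site == 0 else (n - 1 if site == -1 else site - 1)
        res[pos] += mod.mono_mass
        loss[pos] = max(loss[pos], mod.modloss_mass)
    return res, loss


def fragment_mz_table(
    peptides: pd.DataFrame,
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> pd.DataFrame:
    """b/y (and neutral-loss) fragment m/z for every cleavage position.

    For cleavage position i (1..n-1), the b_i neutral fragment is the sum of
    the first i residue+modification masses and y_(n-i) is the suffix sum
    plus water.  Charged m/z adds z protons and divides by z.  A neutral-
    loss column is populated only when the corresponding prefix/suffix
    contains a loss-capable modification; a single loss event is applied,
    using the largest loss present in the fragment.
    """
    if "frag_start_idx" not in peptides.columns:
        peptides = attach_fragment_indices(peptides)
    total = int(peptides["frag_end_idx"].max()) if len(peptides) else 0
    out = np.zeros((total, len(FRAGMENT_COLUMNS)))
    for row in peptides.itertuples(index=False):
        names, sites = parse_mod_lists(
            getattr(row, "mods", ""), getattr(row, "mod_sites", "")
        )
        res, loss = _residue_and_mod_masses(row.sequence, names, sites, registry)
        csum = np.cumsum(res)
        b_neutral = csum[:-1]
        y_neutral = csum[-1] - b_neutral + chem.MASS_H2O
        b_loss_mass = np.maximum.accumulate(loss)[:-1]
        y_loss_mass = np.maximum.accumulate(loss[::-1])[::-1][1:]
        block = np.empty((len(b_neutral), 8))
        for j, (neutral, lmass) in enumerate(
            ((b_neutral, None), (y_neutral, None),
             (b_neutral, b_loss_mass), (y_neutral, y_loss_mass))
        ):
            for zi, z in enumerate((1, 2)):
                col = j * 2 + zi if j < 2 else 4 + (j - 2) * 2 + zi
                mz = (neutral + z * chem.MASS_PROTON) / z
                if lmass is not None:
                    mz = np.where(lmass > 0, mz - lmass / z, 0.0)
                block[:, col] = mz
        start, end = int(row.frag_start_idx), int(row.frag_end_idx)
        out[start:end] = block
    return pd.DataFrame(out, columns=list(FRAGMENT_COLUMNS))


def init_peptide_table(
    sequences,
    mods=None,
    mod_sites=None,
    charge=2,
    nce=30.0,
    instrument="QE",
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> pd.DataFrame:
    """Assemble a peptide table with masses, precursor m/z and fragment
    index ranges filled in."""
    n = len(sequences)
    df = pd.DataFrame({
        "sequence": list(sequences),
        "mods": list(mods) if mods is not None else [""] * n,
        "mod_sites": list(mod_sites) if mod_sites is not None else [""] * n,
        "charge": np.broadcast_to(charge, n).copy(),
        "nce": np.broadcast_to(nce, n).astype(float).copy(),
        "instrument": np.broadcast_to(instrument, n).copy(),
    })
    df["mono_mass"] = [
        peptide_mono_mass(s, m, ms, registry)
        for s, m, ms in zip(df["sequence"], df["mods"], df["mod_sites"])
    ]
    df["precursor_mz"] = [
        precursor_mz(m, z) for m, z in zip(df["mono_mass"], df["charge"])
    ]
    return attach_fragment_indices(df)
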
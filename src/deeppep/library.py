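"""Predicted spectral library assembly and HDF/TSV serialization.

A library holds a precursor table (sequence, modifications, charge,
precursor m/z, normalized RT or iRT, ion mobility) and a fragment table
(per precursor: fragment m/z, relative intensity, ion type, fragment
charge, cleavage ordinal).  Defaults follow common DIA-tool conventions:
precursor charges 1-3, precursor m/z window 300-1800, fragment m/z window
200-1800, and at most the 12 most intense b/y fragments (charge 1-2) per
precursor, re-normalized so the strongest retained fragment is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .peptide import (
    DEFAULT_REGISTRY,
    FRAGMENT_COLUMNS,
    attach_fragment_indices,
    fragment_mz_table,
    parse_mod_lists,
    peptide_mono_mass,
    precursor_mz,
)

PRECURSOR_MZ_RANGE = (300.0, 1800.0)
FRAGMENT_MZ_RANGE = (200.0, 1800.0)
TOP_K_FRAGMENTS = 12
LIBRARY_CHARGES = (1, 2, 3)

#: (ion type, fragment charge) of each fragment-table column considered
#: for export; neutral-loss channels are not written to DIA libraries.
_EXPORT_COLUMNS = {"b+": ("b", 1), "b++": ("b", 2),
                   "y+": ("y", 1), "y++": ("y", 2)}

TSV_COLUMNS = (
    "ModifiedPeptide", "StrippedPeptide", "PrecursorCharge", "PrecursorMz",
    "iRT", "IonMobility", "FragmentMz", "RelativeIntensity", "FragmentType",
    "FragmentCharge", "FragmentSeriesNumber",
)


@dataclass
class SpectralLibrary:
    precursors: pd.DataFrame
    fragments: pd.DataFrame  # linked by "precursor_idx"

    def __len__(self) -> int:
        return len(self.precursors)


def render_modified_peptide(sequence: str, mods: str, mod_sites: str) -> str:
    """Bracketed-name dialect, e.g. Phospho at site 3 of AASDK ->
    ``"AAS[Phospho]DK"``; terminal modifications attach before/after the
    sequence as ``"[Acetyl]-"`` / ``"-[...]"``."""
    names, sites = parse_mod_lists(mods, mod_sites)
    by_site: dict[int, str] = {}
    for name, site in zip(names, sites):
        by_site[site] = name.split("@", 1)[0]
    parts = []
    if 0 in by_site:
        parts.append(f"[{by_site[0]}]-")
    for pos, aa in enumerate(sequence, start=1):
        parts.append(aa)
        if pos in by_site:
            parts.append(f"[{by_site[pos]}]")
    if -1 in by_site:
        parts.append(f"-[{by_site[-1]}]")
    return "".join(parts)


def select_top_fragments(
    frag_mz: np.ndarray,
    frag_intensity: np.ndarray,
    k: int = TOP_K_FRAGMENTS,
    mz_window: tuple[float, float] = FRAGMENT_MZ_RANGE,
) -> list[tuple[int, int]]:
    """Indices of the k most intense exportable fragments.

    Input matrices are (n-1, 8) fragment tables; only b/y ions at charge
    1-2 inside the m/z window qualify.  Ties break toward lower m/z.
    Returns (row, column) pairs sorted by descending intensity.
    """
    col_idx = [FRAGMENT_COLUMNS.index(c) for c in _EXPORT_COLUMNS]
    cands = []
    for c in col_idx:
        for r in range(frag_mz.shape[0]):
            mz, inten = frag_mz[r, c], frag_intensity[r, c]
            if inten > 0 and mz_window[0] <= mz <= mz_window[1]:
                cands.append((-inten, mz, r, c))
    cands.sort()
    return [(r, c) for _, _, r, c in cands[:k]]


def build_library(
    peptides: pd.DataFrame,
    ms2_intensities: pd.DataFrame,
    rt_norm: np.ndarray,
    mobility: np.ndarray | None = None,
    charges=LIBRARY_CHARGES,
    precursor_window: tuple[float, float] = PRECURSOR_MZ_RANGE,
    fragment_window: tuple[float, float] = FRAGMENT_MZ_RANGE,
    top_k: int = TOP_K_FRAGMENTS,
    irt_calibration: tuple[float, float] | None = None,
    registry=DEFAULT_REGISTRY,
) -> SpectralLibrary:
    """Expand peptides over charge states and collect top fragments.

    Each input peptide is considered at every charge state in ``charges``;
    precursors outside the precursor m/z window, or with no exportable
    fragment, are dropped.  RT is written as iRT via the calibration line
    when given, else as gradient-normalized RT times 100.
    """
    if "frag_start_idx" not in peptides.columns:
        peptides = attach_fragment_indices(peptides)
    frag_mz_all = fragment_mz_table(peptides, registry).to_numpy()
    frag_int_all = ms2_intensities[list(FRAGMENT_COLUMNS)].to_numpy()
    rt_norm = np.asarray(rt_norm, dtype=float)
    slope, intercept = irt_calibration if irt_calibration else (100.0, 0.0)
    prec_rows, frag_rows = [], []
    for i, row in enumerate(peptides.itertuples(index=False)):
        mono = peptide_mono_mass(
            row.sequence, getattr(row, "mods", ""),
            getattr(row, "mod_sites", ""), registry,
        )
        s, e = int(row.frag_start_idx), int(row.frag_end_idx)
        fmz, fint = frag_mz_all[s:e], frag_int_all[s:e]
        for z in charges:
            pmz = precursor_mz(mono, z)
            if not precursor_window[0] <= pmz <= precursor_window[1]:
                continue
            picks = select_top_fragments(fmz, fint, top_k, fragment_window)
            if not picks:
                continue
            top = max(fint[r, c] for r, c in picks)
            pidx = len(prec_rows)
            prec_rows.append({
                "sequence": row.sequence,
                "mods": getattr(row, "mods", ""),
                "mod_sites": getattr(row, "mod_sites", ""),
                "charge": z,
                "precursor_mz": pmz,
                "rt_norm": rt_norm[i],
                "irt": slope * rt_norm[i] + intercept,
                "mobility": float(mobility[i]) if mobility is not None
                else 0.0,
            })
            n = len(row.sequence)
            for r, c in picks:
                ion, fz = _EXPORT_COLUMNS[FRAGMENT_COLUMNS[c]]
                frag_rows.append({
                    "precursor_idx": pidx,
                    "fragment_mz": fmz[r, c],
                    "relative_intensity": fint[r, c] / top,
                    "ion_type": ion,
                    "fragment_charge": fz,
                    # cleavage ordinal: b_i for row r is i=r+1; y_j is n-1-r
                    "series_number": r + 1 if ion == "b" else n - 1 - r,
                })
    precursors = pd.DataFrame(
        prec_rows, columns=[
            "sequence", "mods", "mod_sites", "charge", "precursor_mz",
            "rt_norm", "irt", "mobility",
        ],
    )
    fragments = pd.DataFrame(
        frag_rows, columns=[
            "precursor_idx", "fragment_mz", "relative_intensity",
            "ion_type", "fragment_charge", "series_number",
        ],
    )
    return SpectralLibrary(precursors, fragments)


def write_tsv(lib: SpectralLibrary, path) -> None:
    """One row per fragment, DIA-tool-compatible columns."""
    rows = []
    prec = lib.precursors
    for frag in lib.fragments.itertuples(index=False):
        p = prec.iloc[int(frag.precursor_idx)]
        rows.append({
            "ModifiedPeptide": render_modified_peptide(
                p["sequence"], p["mods"], p["mod_sites"]
            ),
            "StrippedPeptide": p["sequence"],
            "PrecursorCharge": int(p["charge"]),
            "PrecursorMz": p["precursor_mz"],
            "iRT": p["irt"],
            "IonMobility": p["mobility"],
            "FragmentMz": frag.fragment_mz,
            "RelativeIntensity": frag.relative_intensity,
            "FragmentType": frag.ion_type,
            "FragmentCharge": int(frag.fragment_charge),
            "FragmentSeriesNumber": int(frag.series_number),
        })
    pd.DataFrame(rows, columns=list(TSV_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def write_hdf(lib: SpectralLibrary, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "deeppep-speclib-1"
        for group, df in (("precursors", lib.precursors),
                          ("fragments", lib.fragments)):
            grp = fh.create_group(group)
            for col in df.columns:
                data = df[col].to_numpy()
                if data.dtype == object:
                    grp.create_dataset(
                        col, data=np.array(data, dtype="S")
                    )
                else:
                    grp.create_dataset(col, data=data)
            grp.attrs["columns"] = list(df.columns)


def read_hdf(path) -> SpectralLibrary:
    with h5py.File(path, "r") as fh:
        if fh.attrs.get("format") != "deeppep-speclib-1":
            raise ValueError("not a deeppep spectral-library HDF file")
        tables = {}
        for group in ("precursors", "fragments"):
            grp = fh[group]
            cols = list(grp.attrs["columns"])
            data = {}
            for col in cols:
                arr = np.asarray(grp[col])
                if arr.dtype.kind == "S":
                    arr = arr.astype(str)
                data[col] = arr
            tables[group] = pd.DataFrame(data, columns=cols)
    return SpectralLibrary(tables["precursors"], tables["fragments"])
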
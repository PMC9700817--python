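"""Synthetic peptides, property ground truths, spectra and PSM tables.

Every generator is a pure function of its configuration and seed.  The
ground-truth rules are smooth, physically-motivated surrogates a small
network can learn:

* retention time: affine map of the summed Kyte-Doolittle hydropathy of the
  residues onto a 60-minute gradient (saturating at the gradient edges);
* CCS: linear in m/z and charge, ``a * (mass/z) + b * z + c``;
* MS2: b/y intensity at cleavage i is a Gaussian in the relative position
  i/n whose center shifts with precursor charge and NCE, scaled by a fixed
  proton-affinity weight of the residues flanking the cleavage site, with a
  phospho neutral-loss channel at half the backbone intensity; the matrix
  is normalized to a maximum of 1.

PSM tables combine true targets (spectra generated from their own peptide,
with intensity jitter and spurious peaks), false targets and pseudo-reversed
decoys (spectra of unrelated peptides), with ground-truth labels retained
for benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .peptide import (
    FRAGMENT_COLUMNS,
    attach_fragment_indices,
    fragment_mz_table,
    init_peptide_table,
)

GRADIENT_MINUTES = 60.0
_RT_SLOPE = 0.35        # minutes per hydropathy unit
_RT_INTERCEPT = 30.0    # gradient midpoint
CCS_SLOPE_MZ = 0.5      # A^2 per m/z unit
CCS_SLOPE_Z = 30.0      # A^2 per charge
CCS_INTERCEPT = 100.0   # A^2

#: relative proton-affinity weights controlling fragment intensity
BASICITY = {
    "A": 0.9, "C": 0.8, "D": 0.7, "E": 0.75, "F": 1.0, "G": 0.65,
    "H": 1.25, "I": 1.0, "K": 1.3, "L": 1.05, "M": 0.95, "N": 0.8,
    "P": 0.4, "Q": 0.85, "R": 1.5, "S": 0.75, "T": 0.8, "V": 0.95,
    "W": 1.1, "Y": 1.0,
}

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SynthConfig:
    n_peptides: int = 100
    min_len: int = 7
    max_len: int = 30
    tryptic: bool = True
    #: (modification name, residue, per-site probability)
    mod_menu: tuple = (
        ("Carbamidomethyl@C", "C", 1.0),
        ("Oxidation@M", "M", 0.3),
        ("Phospho@S", "S", 0.15),
        ("Phospho@T", "T", 0.15),
    )
    charge_probs: dict = field(
        default_factory=lambda: {1: 0.05, 2: 0.55, 3: 0.30, 4: 0.10}
    )
    nce_range: tuple = (25.0, 35.0)
    instrument: str = "QE"
    intensity_jitter: float = 0.1   # multiplicative, fraction
    rt_jitter_minutes: float = 0.5
    spurious_fraction: float = 0.3  # spurious peaks per real peak
    seed: int = 0

    def __post_init__(self):
        if self.min_len > self.max_len or self.min_len < 2:
            raise ValueError("need 2 <= min_len <= max_len")
        for p in (self.intensity_jitter, self.spurious_fraction):
            if p < 0:
                raise ValueError("noise levels must be non-negative")


# ---------------------------------------------------------------------------
# ground-truth property rules
# ---------------------------------------------------------------------------

def synth_rt(sequence: str) -> float:
    """Ground-truth retention time in minutes (permutation invariant)."""
    total = sum(KYTE_DOOLITTLE[aa] for aa in sequence)
    rt = _RT_INTERCEPT + _RT_SLOPE * total
    return float(np.clip(rt, 0.0, GRADIENT_MINUTES))


def synth_ccs(mass: float, charge: int) -> float:
    """Ground-truth collisional cross section in A^2."""
    return CCS_SLOPE_MZ * (mass / charge) + CCS_SLOPE_Z * charge + \
        CCS_INTERCEPT


def synth_ms2(sequence: str, charge: int, nce: float,
              mods: str = "", mod_sites: str = "") -> np.ndarray:
    """Ground-truth fragment intensity matrix, shape (n-1, 8), max 1."""
    n = len(sequence)
    i = np.arange(1, n)
    rel = i / n
    center = 0.5 + 0.1 * (charge - 2) + (nce - 30.0) / 200.0
    base = np.exp(-((rel - center) ** 2) / (2 * 0.25 ** 2))
    bw = np.array([BASICITY.get(sequence[j - 1], 0.8) for j in i])
    yw = np.array([BASICITY.get(sequence[j], 0.8) for j in i])
    out = np.zeros((n - 1, 8))
    out[:, 0] = base * bw                 # b+
    out[:, 2] = base * yw * 1.3           # y+
    if charge >= 2:
        out[:, 1] = 0.4 * out[:, 0]       # b++
        out[:, 3] = 0.4 * out[:, 2]       # y++
    # phospho neutral loss at half the backbone channel
    phospho_pos = np.zeros(n, dtype=bool)
    names = [m for m in mods.split(";") if m]
    sites = [int(s) for s in str(mod_sites).split(";") if s != ""]
    for name, site in zip(names, sites):
        if name.startswith("Phospho@") and name[-1] in "ST" and site >= 1:
            phospho_pos[site - 1] = True
    if phospho_pos.any():
        b_has = np.cumsum(phospho_pos)[:-1] > 0
        y_has = np.cumsum(phospho_pos[::-1])[::-1][1:] > 0
        out[:, 4] = 0.5 * out[:, 0] * b_has
        out[:, 5] = 0.5 * out[:, 1] * b_has
        out[:, 6] = 0.5 * out[:, 2] * y_has
        out[:, 7] = 0.5 * out[:, 3] * y_has
    peak = out.max()
    return out / peak if peak > 0 else out


# ---------------------------------------------------------------------------
# peptide tables
# ---------------------------------------------------------------------------

def gen_peptides(cfg: SynthConfig) -> pd.DataFrame:
    """Random peptide table with modifications, charges and metadata."""
    rng = np.random.default_rng(cfg.seed)
    aas = np.array(list(AA20))
    seqs, mods_col, sites_col = [], [], []
    seen = set()
    while len(seqs) < cfg.n_peptides:
        n = int(rng.integers(cfg.min_len, cfg.max_len + 1))
        seq = "".join(rng.choice(aas, size=n))
        if cfg.tryptic:
            seq = seq[:-1] + ("K" if rng.random() < 0.5 else "R")
        if seq in seen:
            continue
        seen.add(seq)
        names, sites = [], []
        for mod_name, residue, prob in cfg.mod_menu:
            if prob <= 0:
                continue
            for pos, aa in enumerate(seq, start=1):
                if aa == residue and rng.random() < prob:
                    names.append(mod_name)
                    sites.append(pos)
        seqs.append(seq)
        mods_col.append(";".join(names))
        sites_col.append(";".join(str(s) for s in sites))
    charges = rng.choice(
        list(cfg.charge_probs), size=cfg.n_peptides,
        p=np.array(list(cfg.charge_probs.values()))
        / sum(cfg.charge_probs.values()),
    )
    nces = rng.uniform(*cfg.nce_range, size=cfg.n_peptides).round(1)
    df = init_peptide_table(
        seqs, mods_col, sites_col, charge=charges, nce=nces,
        instrument=cfg.instrument,
    )
    return df


def add_ground_truth(peptides: pd.DataFrame) -> pd.DataFrame:
    """Attach rt/rt_norm/ccs/ccs_norm ground-truth columns."""
    df = peptides.copy()
    df["rt"] = [synth_rt(s) for s in df["sequence"]]
    df["rt_norm"] = df["rt"] / GRADIENT_MINUTES
    df["ccs"] = [
        synth_ccs(m, z) for m, z in zip(df["mono_mass"], df["charge"])
    ]
    df["ccs_norm"] = df["ccs"] / 1000.0
    return df


def ground_truth_fragments(peptides: pd.DataFrame) -> pd.DataFrame:
    """Fragment intensity table from the deterministic MS2 rule."""
    if "frag_start_idx" not in peptides.columns:
        peptides = attach_fragment_indices(peptides)
    total = int(peptides["frag_end_idx"].max())
    out = np.zeros((total, 8))
    for row in peptides.itertuples(index=False):
        out[int(row.frag_start_idx):int(row.frag_end_idx)] = synth_ms2(
            row.sequence, int(row.charge), float(row.nce),
            getattr(row, "mods", ""), getattr(row, "mod_sites", ""),
        )
    return pd.DataFrame(out, columns=list(FRAGMENT_COLUMNS))


# ---------------------------------------------------------------------------
# spectra and PSM tables
# ---------------------------------------------------------------------------

def gen_motif_peptides(
    n: int, seed: int = 0, min_len: int = 8, max_len: int = 14,
    anchors: tuple = ((2, "L"), (-1, "V")),
) -> list[str]:
    """Random HLA-length peptides carrying fixed anchor residues.

    ``anchors`` are (position, residue) pairs, 1-based with -1 for the
    C-terminus — the synthetic stand-in for an HLA allele's binding motif.
    Pass an empty tuple for motif-free background peptides.
    """
    rng = np.random.default_rng(seed)
    aas = np.array(list(AA20))
    out = []
    for _ in range(n):
        ln = int(rng.integers(min_len, max_len + 1))
        seq = list(rng.choice(aas, size=ln))
        for pos, aa in anchors:
            seq[pos - 1 if pos >= 1 else pos] = aa
        out.append("".join(seq))
    return out


def pseudo_reverse(sequence: str) -> str:
    """Decoy sequence: reverse all residues but keep the C-terminal one."""
    return sequence[:-1][::-1] + sequence[-1]


def _spectrum_for(row, frag_mz: np.ndarray, frag_int: np.ndarray,
                  cfg: SynthConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    keep = frag_int > 0
    mz = frag_mz[keep]
    inten = frag_int[keep]
    if cfg.intensity_jitter > 0:
        inten = inten * np.exp(
            rng.normal(0.0, cfg.intensity_jitter, size=len(inten))
        )
    n_noise = int(round(cfg.spurious_fraction * len(mz)))
    if n_noise:
        mz = np.concatenate([mz, rng.uniform(150.0, 1500.0, size=n_noise)])
        inten = np.concatenate([
            inten, rng.uniform(0.01, 0.3, size=n_noise)
        ])
    order = np.argsort(mz)
    return mz[order], inten[order]


def gen_psm_table(
    n_true: int, n_false_targets: int, n_decoys: int,
    cfg: SynthConfig | None = None, n_raw_files: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """PSM table plus in-memory spectra keyed by (raw_file, spectrum_id).

    True targets carry spectra generated from their own fragment rule
    (with noise per the config); false targets and decoys are paired with
    spectra of unrelated peptides.  ``is_true`` records the ground truth.
    """
    if cfg is None:
        cfg = SynthConfig()
    total = n_true + n_false_targets + n_decoys
    pep_cfg = SynthConfig(
        n_peptides=total, min_len=cfg.min_len, max_len=cfg.max_len,
        tryptic=cfg.tryptic, mod_menu=cfg.mod_menu,
        charge_probs=cfg.charge_probs, nce_range=cfg.nce_range,
        instrument=cfg.instrument, seed=cfg.seed,
    )
    peptides = add_ground_truth(gen_peptides(pep_cfg))
    rng = np.random.default_rng(cfg.seed + 1)
    frag_mz = fragment_mz_table(peptides).to_numpy()
    frag_int = ground_truth_fragments(peptides).to_numpy()

    rows = []
    spectra = {}
    for i, row in enumerate(peptides.itertuples(index=False)):
        if i < n_true:
            kind = "true"
        elif i < n_true + n_false_targets:
            kind = "false"
        else:
            kind = "decoy"
        # spectrum source: own fragments for true PSMs, another random
        # peptide's fragments otherwise
        src = i if kind == "true" else int(rng.integers(n_true))
        s, e = int(peptides["frag_start_idx"].iat[src]), \
            int(peptides["frag_end_idx"].iat[src])
        mz, inten = _spectrum_for(
            row, frag_mz[s:e].ravel(), frag_int[s:e].ravel(), cfg, rng
        )
        raw_file = f"raw_{i % n_raw_files:02d}"
        spectrum_id = f"scan_{i:06d}"
        spectra[(raw_file, spectrum_id)] = (mz, inten)
        seq = row.sequence if kind != "decoy" else pseudo_reverse(
            row.sequence
        )
        true_rt = synth_rt(seq)
        obs_rt = (
            true_rt + rng.normal(0, cfg.rt_jitter_minutes)
            if kind == "true"
            else rng.uniform(0, GRADIENT_MINUTES)
        )
        score = (
            rng.normal(25, 5) if kind == "true" else rng.normal(15, 5)
        )
        rows.append({
            "sequence": seq,
            "mods": "" if kind == "decoy" else row.mods,
            "mod_sites": "" if kind == "decoy" else row.mod_sites,
            "charge": int(row.charge),
            "nce": float(row.nce),
            "instrument": row.instrument,
            "raw_file": raw_file,
            "spectrum_id": spectrum_id,
            "search_score": float(score),
            "is_decoy": kind == "decoy",
            "is_true": kind == "true",
            "observed_rt": float(obs_rt),
        })
    psms = pd.DataFrame(rows)
    return psms, spectra


def write_mgf(spectra: dict, psms: pd.DataFrame, path) -> None:
    """Write spectra as MGF; titles carry the (raw_file, spectrum_id) key."""
    from pyteomics import mgf

    by_key = {
        (r.raw_file, r.spectrum_id): r for r in psms.itertuples(index=False)
    }
    entries = []
    for (raw, sid), (mz, inten) in spectra.items():
        psm = by_key.get((raw, sid))
        params = {"title": f"{raw}.{sid}"}
        if psm is not None:
            params["pepmass"] = (float(np.round(np.sum(inten), 4)), None)
            params["charge"] = [int(psm.charge)]
        entries.append({
            "m/z array": mz, "intensity array": inten, "params": params,
        })
    mgf.write(entries, str(path), file_mode="w")


def read_mgf(path) -> dict:
    """Load an MGF back into the ``{(raw, scan): (mz, intensity)}`` form."""
    from pyteomics import mgf

    out = {}
    with mgf.MGF(str(path)) as reader:
        for spec in reader:
            title = spec["params"]["title"]
            raw, sid = title.split(".", 1)
            out[(raw, sid)] = (
                np.asarray(spec["m/z array"], dtype=float),
                np.asarray(spec["intensity array"], dtype=float),
            )
    return out
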
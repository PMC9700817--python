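"""Semi-supervised PSM rescoring with deep-learning features.

Pipeline: (1) sample a capped PSM subset for model fine-tuning; (2) match
theoretical fragments against spectra and compute 61 discriminative
features per PSM from predicted vs. observed intensities, retention times
and mobilities; (3) rescore with the cross-validated Percolator scheme
(peptide-level folds, logistic regression, iterative positive-set
re-selection at a working FDR) and estimate target-decoy q-values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .peptide import DEFAULT_REGISTRY, parse_mod_lists

#: The 61 feature columns, fixed order.  Documented in docs/methods.md.
FEATURE_NAMES = (
    # predicted-vs-matched intensity similarity
    "pcc_all", "spearman_all", "cosine_all", "spectral_angle_all",
    "pcc_b", "spearman_b", "cosine_b", "spectral_angle_b",
    "pcc_y", "spearman_y", "cosine_y", "spectral_angle_y",
    "pcc_z1", "cosine_z1", "pcc_z2", "cosine_z2",
    "pcc_top3", "cosine_top3", "pcc_top6", "cosine_top6",
    "pcc_top12", "cosine_top12",
    "pcc_sqrt_all", "cosine_sqrt_all",
    # fragment coverage
    "n_pred_frag", "n_matched_frag", "frac_matched",
    "n_pred_b", "n_matched_b", "frac_matched_b",
    "n_pred_y", "n_matched_y", "frac_matched_y",
    "explained_intensity_frac", "n_unmatched_strong_pred",
    "frac_unmatched_strong_pred", "base_peak_is_matched",
    "matched_entropy",
    # retention time
    "rt_pred_norm", "rt_obs_norm", "rt_delta", "abs_rt_delta",
    "rt_delta_minutes",
    # ion mobility
    "mobility_pred", "mobility_obs", "mobility_delta",
    "abs_mobility_delta", "mobility_missing",
    # precursor / peptide
    "search_score", "peptide_length", "charge", "precursor_mz",
    "mass_error_ppm", "abs_mass_error_ppm", "n_mods", "n_modloss_mods",
    "frac_basic_residues", "n_internal_cleavage_sites", "nce",
    # spectrum
    "n_spectrum_peaks", "log_n_spectrum_peaks",
)

_PRED_PRESENT = 0.01   # a predicted fragment counts as expected above this
_PRED_STRONG = 0.5


def sample_finetune_psms(
    psms: pd.DataFrame, seed: int = 0, max_psms: int = 5000,
    max_raw_files: int = 8, top_mods: int = 10, per_mod: int = 100,
) -> pd.DataFrame:
    """Capped fine-tuning subset: at most ``max_psms`` unmodified target
    PSMs from at most ``max_raw_files`` raw files, plus up to ``per_mod``
    PSMs for each of the ``top_mods`` most frequent modifications."""
    if len(psms) == 0:
        warnings.warn("empty PSM table; nothing to sample", stacklevel=2)
        return psms.copy()
    rng = np.random.default_rng(seed)
    targets = psms[~psms["is_decoy"]].copy()
    files = targets["raw_file"].unique()
    if len(files) > max_raw_files:
        files = rng.choice(files, size=max_raw_files, replace=False)
    pool = targets[targets["raw_file"].isin(files)]
    unmod = pool[pool["mods"].fillna("") == ""]
    if len(unmod) > max_psms:
        unmod = unmod.iloc[
            rng.choice(len(unmod), size=max_psms, replace=False)
        ]
    counts: dict[str, int] = {}
    modded = pool[pool["mods"].fillna("") != ""]
    for mods in modded["mods"]:
        for name in str(mods).split(";"):
            if name:
                counts[name] = counts.get(name, 0) + 1
    selected_mods = sorted(counts, key=lambda m: (-counts[m], m))[:top_mods]
    parts = [unmod]
    for name in selected_mods:
        subset = modded[modded["mods"].str.contains(name, regex=False)]
        if len(subset) > per_mod:
            subset = subset.iloc[
                rng.choice(len(subset), size=per_mod, replace=False)
            ]
        parts.append(subset)
    out = pd.concat(parts).drop_duplicates(
        subset=["raw_file", "spectrum_id", "sequence", "mods", "mod_sites"]
    )
    return out.reset_index(drop=True)


def match_fragments(
    frag_mz: np.ndarray, spectrum_mz: np.ndarray,
    spectrum_intensity: np.ndarray, tol_ppm: float = 20.0,
) -> np.ndarray:
    """Most intense spectrum peak within +-tol_ppm of each theoretical m/z.

    ``frag_mz`` may be any shape; zeros (absent fragments) stay zero.  The
    result is normalized so the highest matched intensity equals 1.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    frag = np.asarray(frag_mz, dtype=float)
    out = np.zeros_like(frag)
    if len(spectrum_mz) == 0:
        return out
    flat = frag.ravel()
    res = np.zeros_like(flat)
    mz = np.asarray(spectrum_mz, dtype=float)
    inten = np.asarray(spectrum_intensity, dtype=float)
    for k, m in enumerate(flat):
        if m <= 0:
            continue
        tol = m * tol_ppm * 1e-6
        lo = np.searchsorted(mz, m - tol, side="left")
        hi = np.searchsorted(mz, m + tol, side="right")
        if hi > lo:
            res[k] = inten[lo:hi].max()
    from .models import normalize_matched_intensities
    return normalize_matched_intensities(res).reshape(frag.shape)


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _safe_spearman(a: np.ndarray, b: np.ndarray) -> float:
    return _safe_pearson(rankdata(a), rankdata(b))


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    return 1.0 - 2.0 * np.arccos(np.clip(_cosine(a, b), -1, 1)) / np.pi


def _entropy(x: np.ndarray) -> float:
    s = x.sum()
    if s <= 0:
        return 0.0
    p = x[x > 0] / s
    return float(-(p * np.log(p)).sum())


def psm_features(
    pred: np.ndarray, matched: np.ndarray, psm_row, spectrum,
    rt_pred_norm: float, mobility_pred: float, gradient_minutes: float,
    registry=DEFAULT_REGISTRY,
) -> dict[str, float]:
    """The 61 features for one PSM (pred/matched are (n-1, 8) matrices)."""
    p, m = pred.ravel(), matched.ravel()
    b_cols, y_cols = (0, 1, 4, 5), (2, 3, 6, 7)
    z1_cols, z2_cols = (0, 2, 4, 6), (1, 3, 5, 7)
    f: dict[str, float] = {}
    f["pcc_all"] = _safe_pearson(p, m)
    f["spearman_all"] = _safe_spearman(p, m)
    f["cosine_all"] = _cosine(p, m)
    f["spectral_angle_all"] = _spectral_angle(p, m)
    for tag, cols in (("b", b_cols), ("y", y_cols)):
        pp, mm = pred[:, cols].ravel(), matched[:, cols].ravel()
        f[f"pcc_{tag}"] = _safe_pearson(pp, mm)
        f[f"spearman_{tag}"] = _safe_spearman(pp, mm)
        f[f"cosine_{tag}"] = _cosine(pp, mm)
        f[f"spectral_angle_{tag}"] = _spectral_angle(pp, mm)
    for tag, cols in (("z1", z1_cols), ("z2", z2_cols)):
        pp, mm = pred[:, cols].ravel(), matched[:, cols].ravel()
        f[f"pcc_{tag}"] = _safe_pearson(pp, mm)
        f[f"cosine_{tag}"] = _cosine(pp, mm)
    order = np.argsort(p)[::-1]
    for k in (3, 6, 12):
        sel = order[:k]
        f[f"pcc_top{k}"] = _safe_pearson(p[sel], m[sel])
        f[f"cosine_top{k}"] = _cosine(p[sel], m[sel])
    f["pcc_sqrt_all"] = _safe_pearson(np.sqrt(p), np.sqrt(m))
    f["cosine_sqrt_all"] = _cosine(np.sqrt(p), np.sqrt(m))

    pred_present = p > _PRED_PRESENT
    matched_present = m > 0
    f["n_pred_frag"] = float(pred_present.sum())
    f["n_matched_frag"] = float((pred_present & matched_present).sum())
    f["frac_matched"] = f["n_matched_frag"] / max(f["n_pred_frag"], 1.0)
    for tag, cols in (("b", b_cols), ("y", y_cols)):
        pp = pred[:, cols].ravel() > _PRED_PRESENT
        mm = matched[:, cols].ravel() > 0
        f[f"n_pred_{tag}"] = float(pp.sum())
        f[f"n_matched_{tag}"] = float((pp & mm).sum())
        f[f"frac_matched_{tag}"] = f[f"n_matched_{tag}"] / max(
            f[f"n_pred_{tag}"], 1.0
        )
    spec_mz, spec_int = spectrum
    # mean matched (normalized) intensity per expected fragment
    f["explained_intensity_frac"] = float(
        m.sum() / max(pred_present.sum(), 1.0)
    )
    strong = p > _PRED_STRONG
    f["n_unmatched_strong_pred"] = float((strong & ~matched_present).sum())
    f["frac_unmatched_strong_pred"] = f["n_unmatched_strong_pred"] / max(
        strong.sum(), 1.0
    )
    f["base_peak_is_matched"] = float(np.isclose(m.max(initial=0.0), 1.0))
    f["matched_entropy"] = _entropy(m)

    rt_obs_norm = float(psm_row.observed_rt) / gradient_minutes
    f["rt_pred_norm"] = rt_pred_norm
    f["rt_obs_norm"] = rt_obs_norm
    f["rt_delta"] = rt_pred_norm - rt_obs_norm
    f["abs_rt_delta"] = abs(f["rt_delta"])
    f["rt_delta_minutes"] = f["rt_delta"] * gradient_minutes

    mob_obs = getattr(psm_row, "observed_mobility", None)
    missing = mob_obs is None or (isinstance(mob_obs, float)
                                  and np.isnan(mob_obs))
    f["mobility_pred"] = 0.0 if missing else float(mobility_pred)
    f["mobility_obs"] = 0.0 if missing else float(mob_obs)
    f["mobility_delta"] = f["mobility_pred"] - f["mobility_obs"]
    f["abs_mobility_delta"] = abs(f["mobility_delta"])
    f["mobility_missing"] = float(missing)

    seq = psm_row.sequence
    names, _ = parse_mod_lists(
        getattr(psm_row, "mods", ""), getattr(psm_row, "mod_sites", "")
    )
    from .peptide import peptide_mono_mass, precursor_mz as calc_mz
    mono = peptide_mono_mass(
        seq, getattr(psm_row, "mods", ""), getattr(psm_row, "mod_sites", ""),
        registry,
    )
    z = int(psm_row.charge)
    theo_mz = calc_mz(mono, z)
    obs_mz = float(getattr(psm_row, "observed_mz", theo_mz))
    f["search_score"] = float(psm_row.search_score)
    f["peptide_length"] = float(len(seq))
    f["charge"] = float(z)
    f["precursor_mz"] = theo_mz
    f["mass_error_ppm"] = (obs_mz - theo_mz) / theo_mz * 1e6
    f["abs_mass_error_ppm"] = abs(f["mass_error_ppm"])
    f["n_mods"] = float(len(names))
    f["n_modloss_mods"] = float(
        sum(1 for n in names if registry[n].modloss_mass > 0)
    )
    f["frac_basic_residues"] = sum(seq.count(a) for a in "KRH") / len(seq)
    f["n_internal_cleavage_sites"] = float(
        sum(seq[:-1].count(a) for a in "KR")
    )
    f["nce"] = float(getattr(psm_row, "nce", 0.0))
    f["n_spectrum_peaks"] = float(len(spec_mz))
    f["log_n_spectrum_peaks"] = float(np.log1p(len(spec_mz)))
    return f


def extract_features(
    psms: pd.DataFrame,
    predictions: dict,
    spectra: dict,
    tol_ppm: float = 20.0,
    gradient_minutes: float = 60.0,
    registry=DEFAULT_REGISTRY,
) -> pd.DataFrame:
    """Feature matrix (one row per PSM, exactly 61 columns).

    ``predictions`` holds ``frag_mz`` and ``frag_int`` DataFrames aligned
    with the PSM table's fragment index ranges, per-PSM ``rt_pred_norm``
    and optionally ``mobility_pred`` arrays.
    """
    frag_mz = predictions["frag_mz"].to_numpy()
    frag_int = predictions["frag_int"].to_numpy()
    rt_pred = np.asarray(predictions["rt_pred_norm"], dtype=float)
    mob_pred = np.asarray(
        predictions.get("mobility_pred", np.zeros(len(psms))), dtype=float
    )
    rows = []
    for i, psm in enumerate(psms.itertuples(index=False)):
        key = (psm.raw_file, psm.spectrum_id)
        if key not in spectra:
            raise KeyError(f"no spectrum for PSM {key}")
        s, e = int(psm.frag_start_idx), int(psm.frag_end_idx)
        if e <= s:
            raise ValueError(f"PSM {key} has no fragment rows")
        pred = frag_int[s:e]
        matched = match_fragments(frag_mz[s:e], *spectra[key], tol_ppm)
        rows.append(psm_features(
            pred, matched, psm, spectra[key], float(rt_pred[i]),
            float(mob_pred[i]), gradient_minutes, registry,
        ))
    feats = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    feats = feats.replace([np.inf, -np.inf], np.nan).fillna(0.0)
    return feats


# ---------------------------------------------------------------------------
# target-decoy q-values and Percolator
# ---------------------------------------------------------------------------

def compute_qvalues(scores: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """Target-decoy q-values for every PSM.

    FDR at score threshold t is (#decoys >= t) / (#targets >= t); the
    q-value is the running minimum of the FDR over decreasing score, so it
    is monotone non-increasing in the score.
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if not is_decoy.any():
        warnings.warn("no decoys; q-values are all zero", stacklevel=2)
        return np.zeros(len(scores))
    order = np.argsort(-scores, kind="stable")
    dec = is_decoy[order]
    n_dec = np.cumsum(dec)
    n_tgt = np.cumsum(~dec)
    fdr = n_dec / np.maximum(n_tgt, 1)
    # equal scores share the worst FDR of their group
    s_sorted = scores[order]
    for i in range(len(fdr) - 2, -1, -1):
        if s_sorted[i] == s_sorted[i + 1]:
            fdr[i] = fdr[i + 1]
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    out = np.empty(len(scores))
    out[order] = np.clip(q, 0.0, 1.0)
    return out


def n_passing(scores, is_decoy, fdr: float = 0.01) -> int:
    """Number of target PSMs at or below the given q-value."""
    q = compute_qvalues(scores, is_decoy)
    return int(((q <= fdr) & ~np.asarray(is_decoy, dtype=bool)).sum())


def assign_folds(peptides: np.ndarray, K: int, seed: int) -> np.ndarray:
    """Peptide-level fold assignment: every PSM of a peptide shares a fold,
    independent of row order."""
    peptides = np.asarray(peptides)
    uniq = np.unique(peptides)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(uniq))
    fold_of_pep = {p: perm[i] % K for i, p in enumerate(uniq)}
    return np.array([fold_of_pep[p] for p in peptides])


def percolator_rescore(
    features: pd.DataFrame,
    is_decoy: np.ndarray,
    peptides: np.ndarray,
    K: int = 2,
    iterations: int = 5,
    seed: int = 0,
    working_fdr: float = 0.01,
) -> np.ndarray:
    """Cross-validated semi-supervised rescoring.

    Peptides (not PSMs) are assigned to K folds, so a PSM is never scored
    by a classifier that saw any PSM of the same peptide.  Within the
    training folds, positives are targets passing the working FDR under
    the current score (initialized from ``search_score``) and negatives
    are decoys; a logistic regression on z-scored features is refit for
    the given number of iterations.
    """
    X = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    peptides = np.asarray(peptides)
    folds = assign_folds(peptides, K, seed)
    base_score = features["search_score"].to_numpy(dtype=float)
    final = np.zeros(len(X))
    for f in range(K):
        train_mask = folds != f
        if not is_decoy[train_mask].any() or is_decoy[train_mask].all():
            raise ValueError(f"fold {f}: training folds lack both classes")
        scaler = StandardScaler().fit(X[train_mask])
        Xtr = scaler.transform(X[train_mask])
        score_tr = base_score[train_mask].copy()
        dec_tr = is_decoy[train_mask]
        clf = None
        for _ in range(iterations):
            q = compute_qvalues(score_tr, dec_tr)
            pos = (~dec_tr) & (q <= working_fdr)
            if pos.sum() < 2:
                # too few confident targets; fall back to all targets
                pos = ~dec_tr
            sel = pos | dec_tr
            y = pos[sel].astype(int)
            clf = LogisticRegression(C=1.0, max_iter=1000)
            clf.fit(Xtr[sel], y)
            score_tr = clf.decision_function(Xtr)
        held = clf.decision_function(scaler.transform(X[folds == f]))
        # align fold scores on the held-out decoy distribution so scores
        # are comparable across folds
        dec_held = held[is_decoy[folds == f]]
        if len(dec_held):
            spread = dec_held.std()
            held = (held - dec_held.mean()) / (
                spread if spread > 1e-9 else 1.0
            )
        final[folds == f] = held
    return final


# ---------------------------------------------------------------------------
# PSM table I/O
# ---------------------------------------------------------------------------

MAXQUANT_COLUMN_MAP = {
    "Raw file": "raw_file",
    "Scan number": "spectrum_id",
    "Sequence": "sequence",
    "Charge": "charge",
    "Score": "search_score",
    "Retention time": "observed_rt",
    "Reverse": "is_decoy",
}


def read_psm_tsv(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a tabular PSM file, renaming columns via ``column_map``
    (e.g. :data:`MAXQUANT_COLUMN_MAP` for msms.txt-style tables)."""
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    for col, default in (("mods", ""), ("mod_sites", "")):
        if col not in df.columns:
            df[col] = default
    if "is_decoy" in df.columns and df["is_decoy"].dtype == object:
        df["is_decoy"] = df["is_decoy"].fillna("").astype(str).isin(
            ("+", "True", "true", "1")
        )
    df["spectrum_id"] = df["spectrum_id"].astype(str)
    return df


def write_psm_tsv(psms: pd.DataFrame, path) -> None:
    psms.to_csv(path, sep="\t", index=False)
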
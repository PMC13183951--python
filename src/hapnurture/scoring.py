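"""Polygenic scores from transmitted and non-transmitted haplotypes.

A weight table (marker, effect allele, per-allele weight) is applied to each
haplotype dataset: the offspring's own two haplotypes give the maternal and
paternal transmitted scores, the parental leftover haplotypes give the
non-transmitted scores.  The module also performs the two cohort-level steps
used before modeling: cohort-mean imputation of the non-transmitted score of
an ungenotyped parent (pairs), and within-batch standardization of score
residuals after regressing out optional ancestry covariates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

SCORE_COLUMNS = [
    "pgs_t_maternal",
    "pgs_t_paternal",
    "pgs_nt_maternal",
    "pgs_nt_paternal",
    "pgs_t",
    "pgs_nt",
]


def align_weights(weights: pd.DataFrame, variant_map, unknown: str = "drop"):
    """Map a weight table onto the variant map.

    Returns ``(w, effect_is_alt, marker_idx)`` aligned arrays over the weight
    rows that overlap the map.  ``unknown`` controls rows whose marker is not in
    the map: ``"drop"`` (with a warning) or ``"error"``.  An effect allele that
    matches neither the ref nor the alt allele of its marker is always an error.
    """
    required = {"marker_id", "effect_allele", "weight"}
    if not required <= set(weights.columns):
        raise ValueError(f"weight table must have columns {sorted(required)}")
    pos = pd.Series(np.arange(variant_map.n_markers), index=variant_map.marker_id)
    hit = weights["marker_id"].isin(pos.index).to_numpy()
    if not hit.all():
        n_bad = int((~hit).sum())
        if unknown == "error":
            raise ValueError(f"{n_bad} weight markers absent from the variant map")
        warnings.warn(f"dropping {n_bad} weight rows with markers absent from the variant map")
        weights = weights.loc[hit]
    if len(weights) == 0:
        raise ValueError("no overlap between weight table and variant map")
    idx = pos.loc[weights["marker_id"]].to_numpy()
    ref = variant_map.ref[idx]
    alt = variant_map.alt[idx]
    ea = weights["effect_allele"].to_numpy()
    is_alt = ea == alt
    is_ref = ea == ref
    if not np.all(is_alt | is_ref):
        raise ValueError("effect alleles that match neither ref nor alt of their marker")
    return weights["weight"].to_numpy(dtype=float), is_alt, idx


def haplotype_score(alleles: np.ndarray, w: np.ndarray, effect_is_alt: np.ndarray,
                    marker_idx: np.ndarray):
    """Raw score of each haplotype: sum of weights over carried effect alleles.

    ``alleles`` has shape (n, total markers) with entries {0, 1, -1}; markers
    missing in a haplotype are skipped (no mean imputation).  Returns
    ``(scores, n_used)``.
    """
    a = alleles[:, marker_idx]
    dose = np.where(effect_is_alt[None, :], a, 1 - a).astype(float)
    ok = a >= 0
    dose[~ok] = 0.0
    scores = dose @ w
    return scores, ok.sum(axis=1)


def score_haplotypes(alleles: np.ndarray, weights: pd.DataFrame, variant_map) -> pd.DataFrame:
    """Score a stack of haplotypes (n, markers) against a weight table."""
    w, is_alt, idx = align_weights(weights, variant_map)
    s, n_used = haplotype_score(np.asarray(alleles), w, is_alt, idx)
    return pd.DataFrame({"score": s, "n_markers_used": n_used})


def build_score_table(tmap, weights: pd.DataFrame, variant_map, trait: str = "trait",
                      batch: str = "batch0") -> pd.DataFrame:
    """The four parent-specific scores per offspring plus their sums.

    ``tmap`` is a :class:`~hapnurture.transmission.TransmissionMap`; channel 0 of
    its allele arrays is maternal, channel 1 paternal.  Non-transmitted scores of
    ungenotyped parents come out as NaN (all alleles missing).
    """
    w, is_alt, idx = align_weights(weights, variant_map)

    def chan(arr, c):
        s, n_used = haplotype_score(arr[:, :, c], w, is_alt, idx)
        s = np.where(n_used > 0, s, np.nan)
        return s, n_used

    t_m, used_tm = chan(tmap.t_alleles, 0)
    t_p, used_tp = chan(tmap.t_alleles, 1)
    nt_m, used_ntm = chan(tmap.nt_alleles, 0)
    nt_p, used_ntp = chan(tmap.nt_alleles, 1)

    out = pd.DataFrame(
        {
            "offspring_id": tmap.offspring_ids,
            "trait": trait,
            "pgs_t_maternal": t_m,
            "pgs_t_paternal": t_p,
            "pgs_nt_maternal": nt_m,
            "pgs_nt_paternal": nt_p,
            "n_used_t_maternal": used_tm,
            "n_used_t_paternal": used_tp,
            "n_used_nt_maternal": used_ntm,
            "n_used_nt_paternal": used_ntp,
            "nt_imputed_maternal": False,
            "nt_imputed_paternal": False,
            "batch": batch,
        }
    )
    out["pgs_t"] = out["pgs_t_maternal"] + out["pgs_t_paternal"]
    out["pgs_nt"] = out["pgs_nt_maternal"] + out["pgs_nt_paternal"]
    return out


def impute_missing_nt(scores: pd.DataFrame, per_role: bool = False) -> pd.DataFrame:
    """Replace a missing parental non-transmitted score by the observed-parent mean.

    The default pools the observed maternal and paternal non-transmitted scores
    into a single cohort mean (computed per trait); ``per_role=True`` uses
    mothers-only / fathers-only means instead.  Flags and the combined ``pgs_nt``
    are updated.
    """
    out = scores.copy()
    for trait, grp in out.groupby("trait"):
        obs_m = grp["pgs_nt_maternal"].dropna()
        obs_p = grp["pgs_nt_paternal"].dropna()
        if len(obs_m) + len(obs_p) == 0:
            raise ValueError(f"no observed parental non-transmitted scores for trait {trait!r}")
        pooled = pd.concat([obs_m, obs_p]).mean()
        fill_m = obs_m.mean() if per_role and len(obs_m) else pooled
        fill_p = obs_p.mean() if per_role and len(obs_p) else pooled
        miss_m = grp["pgs_nt_maternal"].isna()
        miss_p = grp["pgs_nt_paternal"].isna()
        out.loc[grp.index[miss_m], "pgs_nt_maternal"] = fill_m
        out.loc[grp.index[miss_p], "pgs_nt_paternal"] = fill_p
        out.loc[grp.index[miss_m], "nt_imputed_maternal"] = True
        out.loc[grp.index[miss_p], "nt_imputed_paternal"] = True
    out["pgs_nt"] = out["pgs_nt_maternal"] + out["pgs_nt_paternal"]
    return out


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def standardize_scores(scores: pd.DataFrame, batch_col: str = "batch",
                       covariate_cols=(), columns=None) -> pd.DataFrame:
    """Within-batch standardization of score residuals.

    Per batch each score column is regressed on the supplied covariate columns
    (ancestry components in real data; typically none in simulation), and the
    residuals are z-scored to mean 0 / SD 1.  Batches with fewer than 3 members
    fall back to the pooled cohort with a warning.  The standardized values are
    written to ``<column>_z``.
    """
    out = scores.copy()
    columns = list(columns) if columns is not None else [c for c in SCORE_COLUMNS if c in out]
    batches = out[batch_col].to_numpy()
    small = pd.Series(batches).value_counts()
    tiny = set(small[small < 3].index)
    if tiny:
        warnings.warn(f"batches with < 3 members pooled: {sorted(map(str, tiny))}")
    eff_batch = np.where(pd.Series(batches).isin(tiny), "__pooled__", batches)

    for col in columns:
        z = np.full(len(out), np.nan)
        for b in np.unique(eff_batch):
            sel = np.nonzero(eff_batch == b)[0]
            fit_rows = np.arange(len(out)) if b == "__pooled__" else sel
            y = out[col].to_numpy(dtype=float)[fit_rows]
            ok = ~np.isnan(y)
            if ok.sum() == 0:
                continue
            r = np.full(fit_rows.size, np.nan)
            if covariate_cols:
                cov = out.iloc[fit_rows].loc[:, list(covariate_cols)].to_numpy(dtype=float)[ok]
                r[ok] = _residualize(y[ok], cov)
            else:
                r[ok] = y[ok]
            sd = np.nanstd(r)
            if sd < 1e-12:
                raise ValueError(
                    f"degenerate standardization for {col!r} in batch {b!r}: residuals have no variance"
                )
            zfit = (r - np.nanmean(r)) / sd
            pos = {row: k for k, row in enumerate(fit_rows)}
            z[sel] = zfit[[pos[row] for row in sel]]
        out[col + "_z"] = z
    return out
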
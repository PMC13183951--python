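"""Convenience wiring of the full analysis chain.

``score_cohort`` runs transmission inference and scoring on a simulated (or
externally loaded) cohort and returns a per-offspring analysis frame with
standardized combined and parent-specific scores merged onto phenotypes —
the input shape the modeling modules expect.  ``frame_from_true_scores``
produces the same shape directly from simulator ground-truth scores, for
replicate calibration studies that do not need the haplotype stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scoring import build_score_table, impute_missing_nt, standardize_scores
from .transmission import infer_transmission

PARENT_SCORE_Z = [
    "pgs_t_maternal_z",
    "pgs_nt_maternal_z",
    "pgs_t_paternal_z",
    "pgs_nt_paternal_z",
]


def score_cohort(cohort, tile_size: int = 150, tau: float = 0.1, impute: bool = True,
                 wave: int = 1):
    """Transmission -> scores -> imputation -> standardization -> analysis frame.

    Returns ``(frame, transmission_map, score_table)``.  The frame holds one row
    per offspring (phenotypes at ``wave``) with standardized combined scores
    (``pgs_t_z``, ``pgs_nt_z``) and the four parent-specific standardized
    scores.  Parent-specific non-transmitted scores keep their missingness (for
    FIML models); the combined ``pgs_nt`` is imputed first when ``impute``.
    """
    tmap = infer_transmission(cohort.haplotypes, cohort.pedigree, cohort.variant_map,
                              tile_size=tile_size, tau=tau)
    table = build_score_table(tmap, cohort.weights, cohort.variant_map)
    # parent-specific columns standardized with missingness intact
    raw = standardize_scores(table, columns=[
        "pgs_t_maternal", "pgs_t_paternal", "pgs_nt_maternal", "pgs_nt_paternal"])
    if impute:
        imp = impute_missing_nt(table)
    else:
        imp = table
    comb = standardize_scores(imp, columns=["pgs_t", "pgs_nt"])

    scores = raw[["offspring_id", *PARENT_SCORE_Z]].merge(
        comb[["offspring_id", "pgs_t_z", "pgs_nt_z", "nt_imputed_maternal", "nt_imputed_paternal"]],
        on="offspring_id",
    )
    pheno = cohort.phenotypes[cohort.phenotypes["wave"] == wave]
    frame = pheno.merge(scores, left_on="individual_id", right_on="offspring_id", how="inner")
    return frame, tmap, table


def frame_from_true_scores(phenotypes: pd.DataFrame, scores: pd.DataFrame,
                           waves=None) -> pd.DataFrame:
    """Analysis frame from simulator ground-truth scores (no haplotype stages).

    ``scores`` is the true-score table (columns z_mt, z_mnt, z_pt, z_pnt);
    combined scores are the standardized sums.  ``waves=None`` keeps all waves
    (long format for the longitudinal model); an integer keeps one wave.
    """
    d = phenotypes if waves is None else phenotypes[phenotypes["wave"] == waves]
    d = d.merge(scores, on=["individual_id", "family_id", "sex"], how="inner").copy()
    d["pgs_t_maternal_z"] = d.pop("z_mt")
    d["pgs_nt_maternal_z"] = d.pop("z_mnt")
    d["pgs_t_paternal_z"] = d.pop("z_pt")
    d["pgs_nt_paternal_z"] = d.pop("z_pnt")
    for comb, a, b in (("pgs_t_z", "pgs_t_maternal_z", "pgs_t_paternal_z"),
                       ("pgs_nt_z", "pgs_nt_maternal_z", "pgs_nt_paternal_z")):
        s = d[a] + d[b]
        d[comb] = (s - s.mean()) / s.std()
    return d
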
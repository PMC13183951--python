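"""Tile-based inference of transmitted and non-transmitted parental alleles.

Each offspring haplotype is compared to the available parental haplotypes in
tiles of adjacent markers (150 by default).  Per tile the best-matching
parental haplotype (minimum Hamming distance over non-missing markers) is
recorded; a genome-wide vote then assigns each offspring haplotype to a parent
(one maternal and one paternal haplotype in trios; in single-genotyped-parent
pairs the haplotype nearer the genotyped parent is claimed and the other is
attributed to the missing parent).  Label switches between adjacent tiles of
the same parent imply a recombination crossover, whose breakpoint is refined
to the marker that minimizes the cumulative mismatch on both sides.  At every
resolved marker the transmitted parental allele and the parent's remaining
(non-transmitted) allele are extracted; non-transmitted alleles of an
ungenotyped parent are missing by construction, while its transmitted alleles
are still observed through the offspring's own haplotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sim import MISSING, HaplotypeSet, TransmissionTruth, VariantMap

# parental haplotype codes used in tile labels
MAT1, MAT2, PAT1, PAT2 = 0, 1, 2, 3
UNRESOLVED = -1


def make_tiles(variant_map: VariantMap, tile_size: int = 150) -> pd.DataFrame:
    """Contiguous tile spans per chromosome (half-open global marker indices).

    A trailing remainder shorter than ``tile_size`` is merged into the final
    tile; a chromosome shorter than ``tile_size`` becomes a single tile with a
    warning.
    """
    if tile_size < 2:
        raise ValueError("tile_size must be at least 2")
    rows = []
    for chrom, sl in variant_map.chrom_slices().items():
        n = sl.stop - sl.start
        if n < tile_size:
            warnings.warn(f"chromosome {chrom} has {n} < {tile_size} markers; using one tile")
            rows.append((chrom, sl.start, sl.stop))
            continue
        n_tiles = n // tile_size
        for t in range(n_tiles):
            start = sl.start + t * tile_size
            stop = start + tile_size if t < n_tiles - 1 else sl.stop
            rows.append((chrom, start, stop))
    return pd.DataFrame(rows, columns=["chrom", "start", "stop"])


@dataclass
class TileAssignment:
    """Per offspring-haplotype, per-tile distances and best-match labels."""

    offspring_ids: np.ndarray
    tiles: pd.DataFrame
    mismatches: np.ndarray  # (n, 2, n_tiles, 4) Hamming counts, -1 unavailable
    valid_counts: np.ndarray  # (n, 2, n_tiles, 4)
    labels: np.ndarray  # (n, 2, n_tiles) in {MAT1..PAT2} or UNRESOLVED
    mother_genotyped: np.ndarray
    father_genotyped: np.ndarray
    tau: float

    def distance_fraction(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = self.mismatches / self.valid_counts
        f[self.mismatches < 0] = np.inf
        f[self.valid_counts == 0] = np.inf
        return f


def _assign_labels(frac: np.ndarray, tau: float) -> np.ndarray:
    """Tile labels with tau threshold and continuity tie-breaking.

    ``frac`` is (n, 2, T, 4) mismatch fractions (inf where a parent is
    unavailable).  Ties between equally good parental haplotypes are broken by
    continuity with the previous tile's label, else the tile is left
    unresolved.
    """
    n, _, T, _ = frac.shape
    labels = np.full((n, 2, T), UNRESOLVED, dtype=np.int8)
    prev = np.full((n, 2), UNRESOLVED, dtype=np.int8)
    eps = 1e-12
    for t in range(T):
        d = frac[:, :, t, :]
        dmin = d.min(axis=2)
        is_min = d <= dmin[:, :, None] + eps
        n_min = is_min.sum(axis=2)
        best = d.argmin(axis=2).astype(np.int8)
        lab = np.where((dmin <= tau) & (n_min == 1), best, UNRESOLVED).astype(np.int8)
        # ties: keep previous label when it is among the minima
        tie = (dmin <= tau) & (n_min > 1)
        if tie.any():
            idx = np.nonzero(tie)
            p = prev[idx]
            ok = p >= 0
            rows, haps = idx[0][ok], idx[1][ok]
            keep = is_min[rows, haps, p[ok]]
            lab[rows[keep], haps[keep]] = p[ok][keep]
        labels[:, :, t] = lab
        prev = np.where(lab >= 0, lab, prev)
    return labels


def match_tiles(haps: HaplotypeSet, pedigree: pd.DataFrame, variant_map: VariantMap,
                tiles: pd.DataFrame = None, tau: float = 0.1,
                offspring_ids=None) -> TileAssignment:
    """Hamming-match every offspring haplotype tile to the available parental haplotypes.

    Missing genotype calls are excluded from both the numerator and denominator
    of the per-tile distance.  Offspring without any genotyped parent raise.
    """
    if tiles is None:
        tiles = make_tiles(variant_map)
    ped = pedigree.set_index("individual_id")
    off = pedigree[pedigree["role"] == "offspring"]
    if offspring_ids is not None:
        off = off[off["individual_id"].isin(set(offspring_ids))]
    off = off.reset_index(drop=True)

    geno = ped["genotyped"]
    mg = geno.reindex(off["mother_id"]).fillna(False).to_numpy(dtype=bool)
    fg = geno.reindex(off["father_id"]).fillna(False).to_numpy(dtype=bool)
    none = ~(mg | fg)
    if none.any():
        bad = off.loc[none, "individual_id"].tolist()[:5]
        raise ValueError(f"offspring without a genotyped parent: {bad}")

    n = len(off)
    m = haps.n_markers
    oa = haps.alleles[haps.index_of(off["individual_id"])]
    ma = haps.alleles[haps.index_of(off["mother_id"])]
    fa = haps.alleles[haps.index_of(off["father_id"])]
    parents = [ma[:, :, 0], ma[:, :, 1], fa[:, :, 0], fa[:, :, 1]]
    avail = np.stack([mg, mg, fg, fg], axis=1)

    starts = tiles["start"].to_numpy()
    T = len(tiles)
    mismatches = np.full((n, 2, T, 4), -1, dtype=np.int64)
    valid = np.zeros((n, 2, T, 4), dtype=np.int64)
    for h in range(2):
        child = oa[:, :, h]
        for k, par in enumerate(parents):
            ok = (child >= 0) & (par >= 0)
            mm = (child != par) & ok
            mismatches[:, h, :, k] = np.add.reduceat(mm, starts, axis=1)
            valid[:, h, :, k] = np.add.reduceat(ok, starts, axis=1)
        mismatches[:, h, :, :][~avail[:, None, :].repeat(T, axis=1)] = -1

    frac = np.where(
        (mismatches >= 0) & (valid > 0), mismatches / np.maximum(valid, 1), np.inf
    )
    labels = _assign_labels(frac, tau)
    return TileAssignment(
        off["individual_id"].to_numpy(dtype=object), tiles, mismatches, valid, labels, mg, fg, tau
    )


@dataclass
class TransmissionMap:
    """Per-marker transmission calls and extracted non-transmitted alleles.

    Channel 0 of the allele arrays is maternal, channel 1 paternal.  ``source``
    holds the index (0/1) of the parental haplotype called transmitted, or -1
    where unresolved or the parent is ungenotyped; ``nt_alleles`` is -1 at the
    same places.  ``t_alleles`` of an ungenotyped parent comes from the
    offspring's own unmatched haplotype, which is still observed.
    """

    offspring_ids: np.ndarray
    hap_parent: np.ndarray  # (n, 2): parent of offspring haplotype, 0 mother / 1 father / -1
    source: np.ndarray  # (n, m, 2) parental-haplotype index per parent channel
    t_alleles: np.ndarray  # (n, m, 2)
    nt_alleles: np.ndarray  # (n, m, 2)
    excluded: np.ndarray  # (n,) conflict flag
    crossovers: pd.DataFrame
    unresolved_fraction: np.ndarray  # (n,) fraction of markers without a maternal-or-paternal call
    diagnostics: list = field(default_factory=list)

    def report(self) -> dict:
        n = len(self.offspring_ids)
        return {
            "n_offspring": int(n),
            "n_excluded": int(self.excluded.sum()),
            "mean_unresolved_fraction": float(np.mean(self.unresolved_fraction)),
            "n_crossovers": int(len(self.crossovers)),
            "mean_crossovers_per_offspring": float(len(self.crossovers) / max(n, 1)),
        }


def _fill_unresolved(lab: np.ndarray) -> np.ndarray:
    """Fill unresolved runs from flanking consensus (or the single available flank)."""
    out = lab.copy()
    T = lab.size
    t = 0
    while t < T:
        if out[t] != UNRESOLVED:
            t += 1
            continue
        a = t
        while t < T and out[t] == UNRESOLVED:
            t += 1
        left = out[a - 1] if a > 0 else UNRESOLVED
        right = out[t] if t < T else UNRESOLVED
        if left == UNRESOLVED and right == UNRESOLVED:
            continue
        if left == UNRESOLVED or right == UNRESOLVED or left == right:
            out[a:t] = left if left != UNRESOLVED else right
    return out


def _best_split(child: np.ndarray, par: np.ndarray, l1: int, l2: int, ws: int, we: int) -> int:
    """Breakpoint inside [ws, we) minimizing cumulative mismatches (l1 left, l2 right)."""
    seg = child[ws:we]
    m1 = ((seg != par[ws:we, l1]) & (seg >= 0) & (par[ws:we, l1] >= 0)).astype(np.int64)
    m2 = ((seg != par[ws:we, l2]) & (seg >= 0) & (par[ws:we, l2] >= 0)).astype(np.int64)
    left = np.concatenate([[0], np.cumsum(m1)])
    right = np.concatenate([np.cumsum(m2[::-1])[::-1], [0]])
    return ws + int(np.argmin(left + right))


def _polish_source(child: np.ndarray, par: np.ndarray, source: np.ndarray,
                   min_gain: int = 2, max_flips: int = 50) -> np.ndarray:
    """Cumulative-mismatch segment correction within resolved runs.

    A pair of crossovers falling inside a single tile leaves the tile's label
    intact while an interior segment actually came from the other parental
    haplotype.  Flipping the maximum-gain segment (the contiguous stretch where
    switching haplotypes removes the most mismatches, a max-subarray scan)
    recovers such hidden segments; the scan repeats until no flip gains at
    least ``min_gain`` informative markers, which guards against chasing
    isolated mismatches caused by phase noise.
    """
    src = source.copy()
    res = src >= 0
    if not res.any():
        return src
    d = np.diff(res.astype(int))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if res[0]:
        starts.insert(0, 0)
    if res[-1]:
        stops.append(res.size)
    for a, b in zip(starts, stops):
        for _ in range(max_flips):
            s = src[a:b]
            cur = par[np.arange(a, b), s]
            oth = par[np.arange(a, b), 1 - s]
            seg = child[a:b]
            ok = (seg >= 0) & (cur >= 0) & (oth >= 0)
            gain = np.where(ok, ((seg != cur).astype(np.int64) - (seg != oth).astype(np.int64)), 0)
            # max-subarray scan for the best segment to flip
            cs = np.concatenate([[0], np.cumsum(gain)])
            runmin = np.minimum.accumulate(cs[:-1])
            gains = cs[1:] - runmin
            hi = int(np.argmax(gains))
            best = int(gains[hi])
            if best < min_gain:
                break
            lo = int(np.argmin(cs[: hi + 1]))
            src[a + lo:a + hi + 1] = 1 - src[a + lo:a + hi + 1]
    return src


def _refine_chromosome(child: np.ndarray, par: np.ndarray, lab: np.ndarray,
                       tiles: pd.DataFrame, sl_start: int, min_gain: int = 2):
    """Per-marker source for one offspring haplotype on one chromosome.

    ``child`` and ``par`` are the chromosome slices of the offspring haplotype
    and the assigned parent's two haplotypes (markers, 2); ``lab`` holds the
    within-parent tile labels (0/1 or -1) for this chromosome's tiles.
    Unresolved runs between agreeing flanks inherit the consensus; between
    disagreeing flanks the crossover breakpoint is refined over the spanning
    window by the cumulative-mismatch scan, as it is between adjacent resolved
    tiles with differing labels.  A final segment-correction pass recovers
    crossover pairs hidden inside single tiles.  Returns the source array
    (crossover breakpoints are derived from its change points).
    """
    mlen = child.size
    source = np.full(mlen, -1, dtype=np.int8)
    lab = _fill_unresolved(lab)
    starts = tiles["start"].to_numpy() - sl_start
    stops = tiles["stop"].to_numpy() - sl_start
    resolved = [t for t in range(lab.size) if lab[t] >= 0]
    if not resolved:
        return source
    for t in resolved:
        source[starts[t]:stops[t]] = lab[t]
    for t1, t2 in zip(resolved[:-1], resolved[1:]):
        l1, l2 = lab[t1], lab[t2]
        ws, we = starts[t1], stops[t2]
        if l1 == l2:
            source[ws:we] = l1  # only reachable across runs _fill could not close
            continue
        b = _best_split(child, par, l1, l2, ws, we)
        source[ws:b] = l1
        source[b:we] = l2
    return _polish_source(child, par, source, min_gain=min_gain)


def resolve_transmission(assign: TileAssignment, haps: HaplotypeSet, pedigree: pd.DataFrame,
                         variant_map: VariantMap) -> TransmissionMap:
    """Genome-wide parent vote, crossover refinement and allele extraction."""
    ped = pedigree.set_index("individual_id")
    off_ids = assign.offspring_ids
    n = off_ids.size
    m = haps.n_markers
    off_rows = pedigree[pedigree["role"] == "offspring"].set_index("individual_id").loc[off_ids]
    oa = haps.alleles[haps.index_of(off_ids)]
    ma = haps.alleles[haps.index_of(off_rows["mother_id"])]
    fa = haps.alleles[haps.index_of(off_rows["father_id"])]

    tiles = assign.tiles
    chrom_slices = variant_map.chrom_slices()
    tile_chrom = tiles["chrom"].to_numpy()

    mm = assign.mismatches.astype(float)
    mm[assign.mismatches < 0] = np.inf
    cost_mother = np.minimum(mm[:, :, :, MAT1], mm[:, :, :, MAT2]).sum(axis=2)  # (n, 2)
    cost_father = np.minimum(mm[:, :, :, PAT1], mm[:, :, :, PAT2]).sum(axis=2)

    hap_parent = np.full((n, 2), -1, dtype=np.int8)
    excluded = np.zeros(n, dtype=bool)
    diagnostics = []
    for i in range(n):
        if assign.mother_genotyped[i] and assign.father_genotyped[i]:
            votes = (cost_father[i] < cost_mother[i]).astype(np.int8)  # 0 mother, 1 father
            if votes[0] == votes[1]:
                excluded[i] = True
                diagnostics.append(
                    {
                        "offspring_id": off_ids[i],
                        "issue": "both haplotypes vote for the same parent",
                        "votes": ("father" if votes[0] else "mother"),
                    }
                )
                continue
            hap_parent[i] = votes
        else:
            g = 0 if assign.mother_genotyped[i] else 1
            cost = cost_mother[i] if g == 0 else cost_father[i]
            claimed = int(np.argmin(cost))
            hap_parent[i, claimed] = g
            hap_parent[i, 1 - claimed] = 1 - g  # the missing parent, by elimination

    source = np.full((n, m, 2), -1, dtype=np.int8)
    t_alleles = np.full((n, m, 2), MISSING, dtype=np.int8)
    nt_alleles = np.full((n, m, 2), MISSING, dtype=np.int8)
    xover_rows = []
    unresolved_fraction = np.zeros(n)
    frac = assign.distance_fraction()

    for i in range(n):
        if excluded[i]:
            unresolved_fraction[i] = 1.0
            continue
        for h in range(2):
            parent = hap_parent[i, h]
            genotyped = (assign.mother_genotyped[i] if parent == 0 else assign.father_genotyped[i])
            if not genotyped:
                # missing parent: transmitted alleles observed via the offspring itself
                own = oa[i, :, h]
                t_alleles[i, own >= 0, parent] = own[own >= 0]
                continue
            base = MAT1 if parent == 0 else PAT1
            par = ma[i] if parent == 0 else fa[i]
            # within-parent tile labels with continuity tie-breaking
            d2 = frac[i, h, :, base:base + 2]
            lab2 = np.full(d2.shape[0], UNRESOLVED, dtype=np.int8)
            prev = UNRESOLVED
            for t in range(d2.shape[0]):
                d0, d1 = d2[t]
                dmin = min(d0, d1)
                if not np.isfinite(dmin) or dmin > assign.tau:
                    continue
                if abs(d0 - d1) <= 1e-12:
                    lab2[t] = prev if prev != UNRESOLVED else UNRESOLVED
                else:
                    lab2[t] = 0 if d0 < d1 else 1
                if lab2[t] != UNRESOLVED:
                    prev = lab2[t]
            for chrom, sl in chrom_slices.items():
                tsel = tile_chrom == chrom
                src = _refine_chromosome(oa[i, sl, h], par[sl], lab2[tsel], tiles[tsel], sl.start)
                source[i, sl, parent] = src
                both = (src[:-1] >= 0) & (src[1:] >= 0)
                for b in (np.nonzero((src[:-1] != src[1:]) & both)[0] + 1):
                    xover_rows.append(
                        {
                            "offspring_id": off_ids[i],
                            "chrom": chrom,
                            "parent": "mother" if parent == 0 else "father",
                            "marker_index": sl.start + int(b),
                        }
                    )
            res = source[i, :, parent] >= 0
            idx = np.nonzero(res)[0]
            src = source[i, idx, parent]
            t_alleles[i, idx, parent] = par[idx, src]
            nt_alleles[i, idx, parent] = par[idx, 1 - src]
        # fraction of markers lacking a transmitted call on the genotyped side(s)
        channels = [p for p, g in ((0, assign.mother_genotyped[i]), (1, assign.father_genotyped[i])) if g]
        if channels:
            unresolved_fraction[i] = float(np.mean(source[i, :, channels] < 0))

    crossovers = pd.DataFrame(xover_rows, columns=["offspring_id", "chrom", "parent", "marker_index"])
    return TransmissionMap(
        off_ids, hap_parent, source, t_alleles, nt_alleles, excluded, crossovers,
        unresolved_fraction, diagnostics,
    )


def infer_transmission(haps: HaplotypeSet, pedigree: pd.DataFrame, variant_map: VariantMap,
                       tile_size: int = 150, tau: float = 0.1) -> TransmissionMap:
    """Convenience pipeline: make_tiles -> match_tiles -> resolve_transmission."""
    tiles = make_tiles(variant_map, tile_size)
    assign = match_tiles(haps, pedigree, variant_map, tiles, tau)
    return resolve_transmission(assign, haps, pedigree, variant_map)


@dataclass
class ConcordanceReport:
    overall: float
    by_role: dict
    by_chrom: dict
    n_compared: int

    def __float__(self) -> float:
        return self.overall


def concordance(tmap: TransmissionMap, truth: TransmissionTruth, parent_haps: HaplotypeSet,
                pedigree: pd.DataFrame, variant_map: VariantMap = None) -> ConcordanceReport:
    """Fraction of inferred non-transmitted alleles equal to the simulated truth.

    ``parent_haps`` must be the error-free simulated haplotypes (phase errors in
    the observed data do not change the true non-transmitted alleles).
    """
    if tmap.t_alleles.shape[1] != parent_haps.n_markers:
        raise ValueError("transmission map and haplotypes disagree on the marker set")
    off_rows = pedigree[pedigree["role"] == "offspring"].set_index("individual_id").loc[
        tmap.offspring_ids
    ]
    tidx = truth.index_of(tmap.offspring_ids)
    ma = parent_haps.alleles[parent_haps.index_of(off_rows["mother_id"])]
    fa = parent_haps.alleles[parent_haps.index_of(off_rows["father_id"])]
    n, m = tmap.source.shape[:2]
    rows = np.arange(n)[:, None]
    cols = np.arange(m)[None, :]
    truth_nt = np.stack(
        [
            ma[rows, cols, 1 - truth.maternal_source[tidx]],
            fa[rows, cols, 1 - truth.paternal_source[tidx]],
        ],
        axis=2,
    )
    inferred = tmap.nt_alleles
    ok = inferred >= 0
    agree = (inferred == truth_nt) & ok
    total = int(ok.sum())
    overall = float(agree.sum() / total) if total else float("nan")
    by_role = {}
    for c, name in ((0, "mother"), (1, "father")):
        t = int(ok[:, :, c].sum())
        by_role[name] = float(agree[:, :, c].sum() / t) if t else float("nan")
    by_chrom = {}
    if variant_map is not None:
        for chrom, sl in variant_map.chrom_slices().items():
            t = int(ok[:, sl].sum())
            by_chrom[int(chrom)] = float(agree[:, sl].sum() / t) if t else float("nan")
    return ConcordanceReport(overall, by_role, by_chrom, total)
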
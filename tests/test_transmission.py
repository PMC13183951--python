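"""Tile matching, transmission resolution and non-transmitted allele extraction."""

import numpy as np
import pandas as pd
import pytest

from hapnurture.sim import (
    GenerativeParams,
    HaplotypeSet,
    TransmissionTruth,
    VariantMap,
    gamete_from_breakpoints,
    simulate_cohort,
)
from hapnurture.transmission import (
    concordance,
    infer_transmission,
    make_tiles,
    match_tiles,
    resolve_transmission,
)


def _vmap(n, chrom=1):
    return VariantMap(
        marker_id=np.array([f"c{chrom}s{i}" for i in range(n)], dtype=object),
        chrom=np.full(n, chrom),
        pos=np.arange(1, n + 1) * 1000,
        cm=np.arange(1, n + 1, dtype=float),
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "G", dtype=object),
    )


def _toy_trio(mother, father, child, n):
    """HaplotypeSet + pedigree for one constructed trio."""
    ids = np.array(["F0_M", "F0_F", "F0_O1"], dtype=object)
    alleles = np.stack([mother, father, child]).astype(np.int8)
    haps = HaplotypeSet(ids, alleles)
    ped = pd.DataFrame(
        {
            "family_id": ["F0"] * 3,
            "individual_id": ids,
            "father_id": [None, None, "F0_F"],
            "mother_id": [None, None, "F0_M"],
            "sex": ["female", "male", "female"],
            "genotyped": [True, True, True],
            "role": ["mother", "father", "offspring"],
        }
    )
    return haps, ped


class TestMakeTiles:
    @pytest.mark.parametrize(
        "n,expected",
        [(450, [150, 150, 150]), (460, [150, 150, 160]), (300, [150, 150])],
    )
    def test_tile_partition(self, n, expected):
        tiles = make_tiles(_vmap(n), tile_size=150)
        sizes = (tiles.stop - tiles.start).tolist()
        assert sizes == expected
        assert tiles.start.iloc[0] == 0 and tiles.stop.iloc[-1] == n

    def test_short_chromosome_single_tile_with_warning(self):
        with pytest.warns(UserWarning):
            tiles = make_tiles(_vmap(149), tile_size=150)
        assert len(tiles) == 1 and (tiles.stop - tiles.start).iloc[0] == 149

    def test_tiny_tile_size_rejected(self):
        with pytest.raises(ValueError):
            make_tiles(_vmap(300), tile_size=1)


class TestMatchTiles:
    def test_error_free_trio_no_recombination(self):
        params = GenerativeParams(n_families=30, n_markers=600, n_chromosomes=2,
                                  crossover_rate=0.0, fraction_trios=1.0,
                                  sibling_rate=0.0, seed=2)
        c = simulate_cohort(params)
        tiles = make_tiles(c.variant_map)
        assign = match_tiles(c.haplotypes, c.pedigree, c.variant_map, tiles)
        frac = assign.distance_fraction()
        best = frac.min(axis=3)
        assert np.allclose(best, 0.0)
        for chrom in (1, 2):
            sel = (assign.tiles.chrom == chrom).to_numpy()
            labs = assign.labels[:, :, sel]
            assert np.all(labs == labs[:, :, [0]])  # constant per chromosome

    def test_crossover_tile_assigned_to_argmin_side(self):
        rng = np.random.default_rng(3)
        n = 450
        mother = rng.integers(0, 2, size=(n, 2)).astype(np.int8)
        father = rng.integers(0, 2, size=(n, 2)).astype(np.int8)
        b = 200  # inside tile 1 (markers 150-300)
        mat_gam, _ = gamete_from_breakpoints(mother, [b], 0)
        pat_gam, _ = gamete_from_breakpoints(father, [], 0)
        child = np.stack([mat_gam, pat_gam], axis=1)
        haps, ped = _toy_trio(mother, father, child, n)
        vmap = _vmap(n)
        assign = match_tiles(haps, ped, vmap, make_tiles(vmap), tau=0.5)
        labs = assign.labels[0, 0]  # maternal haplotype of the child
        assert labs[0] == 0 and labs[2] == 1  # mat1 before, mat2 after
        # tile 1 goes to whichever side has fewer mismatches (enumerated oracle)
        mism = [np.sum(mat_gam[150:300] != mother[150:300, k]) for k in (0, 1)]
        assert labs[1] == int(np.argmin(mism))

    def test_pair_offspring_haplotypes_split_between_parents(self):
        params = GenerativeParams(n_families=40, n_markers=600, n_chromosomes=1,
                                  fraction_trios=0.0, maternal_bias=1.0,
                                  sibling_rate=0.0, seed=4)
        c = simulate_cohort(params)
        tmap = infer_transmission(c.haplotypes, c.pedigree, c.variant_map)
        # mother always genotyped: haplotype 0 (maternal gamete) claimed by her
        assert np.all(tmap.hap_parent[:, 0] == 0)
        assert np.all(tmap.hap_parent[:, 1] == 1)  # missing father by elimination
        assert np.all(tmap.nt_alleles[:, :, 1] < 0)  # paternal NT all missing

    def test_offspring_without_genotyped_parent_rejected(self, small_cohort):
        ped = small_cohort.pedigree.copy()
        ped.loc[ped.role.isin(["mother", "father"]), "genotyped"] = False
        with pytest.raises(ValueError, match="without a genotyped parent"):
            match_tiles(small_cohort.haplotypes, ped, small_cohort.variant_map)


class TestResolve:
    def test_breakpoints_near_truth(self):
        rng = np.random.default_rng(5)
        n = 1500
        mother = rng.integers(0, 2, size=(n, 2)).astype(np.int8)
        father = rng.integers(0, 2, size=(n, 2)).astype(np.int8)
        true_breaks = [400, 1100]
        mat_gam, msrc = gamete_from_breakpoints(mother, true_breaks, 0)
        pat_gam, psrc = gamete_from_breakpoints(father, [], 1)
        child = np.stack([mat_gam, pat_gam], axis=1)
        haps, ped = _toy_trio(mother, father, child, n)
        vmap = _vmap(n)
        tmap = infer_transmission(haps, ped, vmap)
        got = sorted(
            tmap.crossovers.query("parent == 'mother'").marker_index.tolist()
        )
        assert len(got) == 2
        for b, t in zip(got, true_breaks):
            assert abs(b - t) <= 150  # within one tile of the truth
        truth = TransmissionTruth(np.array(["F0_O1"], dtype=object),
                                  msrc[None, :], psrc[None, :])
        rep = concordance(tmap, truth, haps, ped)
        assert rep.overall > 0.99

    def test_homozygous_parent_nt_equals_t(self, trio_cohort):
        c = trio_cohort
        tmap = infer_transmission(c.haplotypes, c.pedigree, c.variant_map)
        off = c.pedigree[c.pedigree.role == "offspring"].set_index("individual_id")
        off = off.loc[tmap.offspring_ids]
        mom = c.haplotypes.alleles[c.haplotypes.index_of(off.mother_id)]
        hom = mom[:, :, 0] == mom[:, :, 1]
        res = tmap.nt_alleles[:, :, 0] >= 0
        sel = hom & res
        assert sel.any()
        assert np.array_equal(tmap.nt_alleles[:, :, 0][sel], tmap.t_alleles[:, :, 0][sel])

    def test_transmitted_plus_nontransmitted_equals_parent_dosage(self, trio_cohort):
        c = trio_cohort
        tmap = infer_transmission(c.haplotypes, c.pedigree, c.variant_map)
        off = c.pedigree[c.pedigree.role == "offspring"].set_index("individual_id")
        off = off.loc[tmap.offspring_ids]
        for channel, col in ((0, "mother_id"), (1, "father_id")):
            parent = c.haplotypes.alleles[c.haplotypes.index_of(off[col])]
            dose = parent.sum(axis=2)
            res = (tmap.t_alleles[:, :, channel] >= 0) & (tmap.nt_alleles[:, :, channel] >= 0)
            s = tmap.t_alleles[:, :, channel] + tmap.nt_alleles[:, :, channel]
            assert np.array_equal(s[res], dose[res])

    def test_unrelated_child_fully_unresolved(self):
        rng = np.random.default_rng(6)
        n = 600
        mother = rng.integers(0, 2, size=(n, 2)).astype(np.int8)
        father = rng.integers(0, 2, size=(n, 2)).astype(np.int8)
        child = rng.integers(0, 2, size=(n, 2)).astype(np.int8)  # unrelated
        haps, ped = _toy_trio(mother, father, child, n)
        vmap = _vmap(n)
        tmap = infer_transmission(haps, ped, vmap, tau=0.1)
        assert np.all(tmap.nt_alleles < 0)
        assert tmap.unresolved_fraction[0] == 1.0 or tmap.excluded[0]

    def test_clone_of_mother_flagged_as_conflict(self):
        rng = np.random.default_rng(7)
        n = 600
        mother = rng.integers(0, 2, size=(n, 2)).astype(np.int8)
        father = 1 - mother  # maximally distinct
        child = mother.copy()  # both haplotypes vote for the mother
        haps, ped = _toy_trio(mother, father, child, n)
        tmap = infer_transmission(haps, ped, _vmap(n))
        assert tmap.excluded[0]
        assert tmap.diagnostics and "same parent" in tmap.diagnostics[0]["issue"]


class TestConcordance:
    def test_perfect_agreement_is_one(self, trio_cohort):
        c = trio_cohort
        # build an inference object whose NT alleles are copied from the truth
        tmap = infer_transmission(c.haplotypes, c.pedigree, c.variant_map)
        off = c.pedigree[c.pedigree.role == "offspring"].set_index("individual_id")
        off = off.loc[tmap.offspring_ids]
        tidx = c.truth.index_of(tmap.offspring_ids)
        rows = np.arange(len(off))[:, None]
        cols = np.arange(c.haplotypes.n_markers)[None, :]
        mom = c.haplotypes_true.alleles[c.haplotypes_true.index_of(off.mother_id)]
        dad = c.haplotypes_true.alleles[c.haplotypes_true.index_of(off.father_id)]
        tmap.nt_alleles = np.stack(
            [
                mom[rows, cols, 1 - c.truth.maternal_source[tidx]],
                dad[rows, cols, 1 - c.truth.paternal_source[tidx]],
            ],
            axis=2,
        )
        rep = concordance(tmap, c.truth, c.haplotypes_true, c.pedigree)
        assert rep.overall == 1.0

    def test_shuffled_calls_match_frequency_based_chance(self, trio_cohort):
        c = trio_cohort
        tmap = infer_transmission(c.haplotypes, c.pedigree, c.variant_map)
        rng = np.random.default_rng(8)
        perm = rng.permutation(len(tmap.offspring_ids))
        shuffled = tmap.nt_alleles[perm]
        # chance level from allele frequencies, computed by brute force
        truth_nt = np.stack(
            [tmap.nt_alleles[:, :, 0], tmap.nt_alleles[:, :, 1]], axis=2
        )  # clean run: inferred ~ truth
        p1_inf = (shuffled == 1).mean(axis=0)
        p1_tru = (truth_nt == 1).mean(axis=0)
        chance = float(np.mean(p1_inf * p1_tru + (1 - p1_inf) * (1 - p1_tru)))
        agree = float((shuffled == truth_nt).mean())
        assert abs(agree - chance) < 0.02
        assert agree < 0.95  # far below the aligned concordance

    def test_monotone_degradation_in_phase_error(self):
        rates = [0.0, 0.002, 0.01]
        vals = []
        for rate in rates:
            params = GenerativeParams(n_families=120, n_markers=1250, n_chromosomes=2,
                                      fraction_trios=1.0, sibling_rate=0.0,
                                      phase_error_rate=rate, seed=77)
            c = simulate_cohort(params)
            tmap = infer_transmission(c.haplotypes, c.pedigree, c.variant_map)
            vals.append(concordance(tmap, c.truth, c.haplotypes_true, c.pedigree).overall)
        assert vals[0] > vals[1] - 0.003 and vals[1] > vals[2] - 0.003
        assert vals[0] > vals[2]

    def test_pair_trio_equivalence(self, trio_cohort):
        """Masking one parent leaves the genotyped parent's resolved calls unchanged."""
        c = trio_cohort
        tm_trio = infer_transmission(c.haplotypes, c.pedigree, c.variant_map)
        ped = c.pedigree.copy()
        ped.loc[ped.role == "father", "genotyped"] = False
        haps = c.haplotypes.copy()
        hidden = ~ped.set_index("individual_id")["genotyped"].loc[haps.ids].to_numpy()
        haps.alleles[hidden] = -1
        tm_pair = infer_transmission(haps, ped, c.variant_map)
        both = (tm_trio.nt_alleles[:, :, 0] >= 0) & (tm_pair.nt_alleles[:, :, 0] >= 0)
        assert both.mean() > 0.95
        assert np.array_equal(
            tm_trio.t_alleles[:, :, 0][both], tm_pair.t_alleles[:, :, 0][both]
        )
        assert np.array_equal(
            tm_trio.nt_alleles[:, :, 0][both], tm_pair.nt_alleles[:, :, 0][both]
        )
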
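"""Synthetic family cohorts with known transmission and phenotype ground truth.

The generator builds founder couples with independent biallelic markers,
produces offspring gametes by meiosis with Poisson-distributed crossovers on a
genetic map, optionally masks one parent per family (turning trios into
single-genotyped-parent pairs), injects haplotype switch errors that emulate
imperfect statistical phasing, and assigns phenotypes under an explicit
generative model:

* direct genetic effects of the offspring's own (transmitted) polygenic score,
* genetic nurture as a direct effect of the parental non-transmitted score
  and/or as mediation through parental phenotypes (a x b paths),
* a family-level random intercept shared by siblings,
* age-varying transmitted / non-transmitted effects across assessment waves,
* optional phenotypic assortative mating between the members of a couple.

Every stochastic choice flows through a single :class:`numpy.random.Generator`
so that identical parameters and seed reproduce the cohort bit for bit.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

MISSING = np.int8(-1)

PEDIGREE_COLUMNS = [
    "family_id",
    "individual_id",
    "father_id",
    "mother_id",
    "sex",
    "genotyped",
    "role",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class VariantMap:
    """Marker scaffold: biallelic variants with physical and genetic positions."""

    marker_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    cm: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        for name in ("marker_id", "chrom", "pos", "cm", "ref", "alt"):
            setattr(self, name, np.asarray(getattr(self, name)))
        n = self.marker_id.size
        if any(getattr(self, f).size != n for f in ("chrom", "pos", "cm", "ref", "alt")):
            raise ValueError("variant map fields must have equal length")
        for c in np.unique(self.chrom):
            sel = self.chrom == c
            if not (np.all(np.diff(self.pos[sel]) > 0) and np.all(np.diff(self.cm[sel]) > 0)):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_markers(self) -> int:
        return int(self.marker_id.size)

    def chromosomes(self) -> np.ndarray:
        # preserves order of first appearance
        _, idx = np.unique(self.chrom, return_index=True)
        return self.chrom[np.sort(idx)]

    def chrom_slices(self) -> dict:
        """Half-open marker-index slice per chromosome (markers are contiguous)."""
        out = {}
        for c in self.chromosomes():
            w = np.nonzero(self.chrom == c)[0]
            if not np.array_equal(w, np.arange(w[0], w[-1] + 1)):
                raise ValueError(f"markers of chromosome {c} are not contiguous")
            out[c] = slice(int(w[0]), int(w[-1]) + 1)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chrom": self.chrom,
                "pos": self.pos,
                "cm": self.cm,
                "ref": self.ref,
                "alt": self.alt,
            }
        )


@dataclass
class HaplotypeSet:
    """Phased alleles per person: ``alleles[i, m, h]`` in {0, 1} or -1 (missing)."""

    ids: np.ndarray
    alleles: np.ndarray
    phase_known: np.ndarray = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (persons, markers, 2)")
        if self.alleles.shape[0] != self.ids.size:
            raise ValueError("ids and alleles disagree on the number of persons")
        if self.phase_known is None:
            self.phase_known = np.ones(self.ids.size, dtype=bool)
        self.phase_known = np.asarray(self.phase_known, dtype=bool)
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def n_persons(self) -> int:
        return int(self.ids.size)

    @property
    def n_markers(self) -> int:
        return int(self.alleles.shape[1])

    def index_of(self, ids) -> np.ndarray:
        return np.array([self._index[i] for i in np.asarray(ids, dtype=object)], dtype=np.intp)

    def dosage(self) -> np.ndarray:
        """Genotype dosage 0/1/2, or -1 where either haplotype is missing."""
        d = self.alleles.sum(axis=2, dtype=np.int16).astype(np.int8)
        d[(self.alleles < 0).any(axis=2)] = MISSING
        return d

    def copy(self) -> "HaplotypeSet":
        return HaplotypeSet(self.ids.copy(), self.alleles.copy(), self.phase_known.copy())


@dataclass
class TransmissionTruth:
    """Simulated ground truth: which parental haplotype each offspring allele came from.

    ``maternal_source[i, m]`` is the index (0/1) of the maternal haplotype carried
    by offspring ``i`` at marker ``m``; offspring haplotype 0 is the maternal
    gamete and haplotype 1 the paternal gamete.  Crossover breakpoints are the
    marker indices where the source changes within a chromosome.
    """

    offspring_ids: np.ndarray
    maternal_source: np.ndarray
    paternal_source: np.ndarray

    def __post_init__(self) -> None:
        self.offspring_ids = np.asarray(self.offspring_ids, dtype=object)
        self.maternal_source = np.asarray(self.maternal_source, dtype=np.int8)
        self.paternal_source = np.asarray(self.paternal_source, dtype=np.int8)
        self._index = {i: k for k, i in enumerate(self.offspring_ids)}

    def index_of(self, ids) -> np.ndarray:
        return np.array([self._index[i] for i in np.asarray(ids, dtype=object)], dtype=np.intp)

    def crossover_counts(self, variant_map: VariantMap) -> pd.DataFrame:
        """Number of source switches per offspring, gamete and chromosome."""
        rows = []
        for chrom, sl in variant_map.chrom_slices().items():
            for name, src in (("maternal", self.maternal_source), ("paternal", self.paternal_source)):
                k = (np.diff(src[:, sl], axis=1) != 0).sum(axis=1)
                rows.append(
                    pd.DataFrame(
                        {
                            "offspring_id": self.offspring_ids,
                            "chrom": chrom,
                            "gamete": name,
                            "n_crossovers": k,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def segments(self, offspring_id, variant_map: VariantMap) -> pd.DataFrame:
        """Segment table (chrom, gamete, start, stop, source_haplotype) for one offspring."""
        i = self._index[offspring_id]
        rows = []
        for chrom, sl in variant_map.chrom_slices().items():
            for name, src in (("maternal", self.maternal_source), ("paternal", self.paternal_source)):
                s = src[i, sl]
                breaks = np.nonzero(np.diff(s) != 0)[0] + 1
                starts = np.concatenate([[0], breaks])
                stops = np.concatenate([breaks, [s.size]])
                for a, b in zip(starts, stops):
                    rows.append(
                        {
                            "chrom": chrom,
                            "gamete": name,
                            "start": int(a) + sl.start,
                            "stop": int(b) + sl.start,
                            "source_haplotype": int(s[a]),
                        }
                    )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generative parameters


@dataclass
class GenerativeParams:
    """Parameters of the synthetic cohort.

    Defaults encode the study conditions the pipeline is calibrated against:
    a 17% trio fraction (3,267 of 19,233 families), direct and nurture
    effects of 0.202 and 0.037 standardized units on the primary continuous
    outcome, a transmitted-score x age slope of -0.004 per year with a null
    non-transmitted x age slope, assessment waves at mean ages 33.0 / 38.9 /
    44.8 years, 61.9% female offspring, and a 41.4% smoking-initiation
    prevalence.  Mediation paths (``a_m``/``a_p`` score-to-parent-phenotype
    and ``b_m``/``b_p`` parent-phenotype-to-offspring loadings) default to
    zero so the direct coefficients are also the marginal ones; mediation
    scenarios switch them on explicitly.
    """

    n_families: int = 2000
    fraction_trios: float = 3267 / 19233
    n_markers: int = 2500  # per chromosome
    n_chromosomes: int = 2
    maf_range: tuple = (0.05, 0.5)
    crossover_rate: float = 1.5  # expected crossovers per chromosome per meiosis
    phase_error_rate: float = 0.0
    sibling_rate: float = 0.2  # fraction of families with a second offspring
    maternal_bias: float = 0.7  # P(mother is the genotyped parent of a pair)

    # effect sizes (standardized scale)
    delta_direct: float = 0.202
    beta_nurture: float = 0.037
    delta_maternal: float = None  # per-parent transmitted effects; default delta_direct/sqrt(2)
    delta_paternal: float = None
    nurture_maternal: float = None
    nurture_paternal: float = None
    a_m: float = 0.0  # maternal score -> maternal phenotype loading
    a_p: float = 0.0
    b_m: float = 0.0  # maternal phenotype -> offspring outcome loading
    b_p: float = 0.0
    am_corr: float = 0.0  # mate-pair correlation of parental phenotypes
    sigma_family: float = 0.2
    sigma_resid: float = None  # default: residual SD completing unit outcome variance
    sigma_person: float = 0.3  # longitudinal person intercept SD
    sigma_age_slope: float = 0.02  # longitudinal person age-slope SD (per year)
    age_slope_T: float = -0.004  # per-year change of the transmitted effect
    age_slope_NT: float = 0.0
    age_main: float = -0.04  # per-year age effect on the standardized outcome
    sex_main: float = 0.085  # male main effect

    # phenotype scaling / binaries
    liability_threshold: float = None  # overrides prevalence_smoking if set
    prevalence_smoking: float = 0.414
    prevalence_cannabis: float = 0.227
    wave_ages: tuple = (33.0, 38.9, 44.8)
    age_sd: float = 8.5
    prop_female: float = 0.619
    mean_cpd: float = 10.24
    sd_cpd: float = 6.0
    mean_alcohol: float = 6.74
    sd_alcohol: float = 8.46
    mean_current_cpd: float = 8.0
    sd_current_cpd: float = 4.0
    former_smoker_rate: float = 0.05

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_families < 1 or self.n_markers < 1 or self.n_chromosomes < 1:
            raise ValueError("n_families, n_markers and n_chromosomes must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.fraction_trios <= 1:
            raise ValueError("fraction_trios must lie in [0, 1]")
        if not 0 <= self.phase_error_rate < 1:
            raise ValueError("phase_error_rate must lie in [0, 1)")
        for name in ("sigma_family", "sigma_person", "sigma_age_slope", "crossover_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sigma_resid is not None and self.sigma_resid < 0:
            raise ValueError("sigma_resid must be non-negative")
        if not -1 < self.am_corr < 1:
            raise ValueError("am_corr must lie in (-1, 1)")

    def parent_effects(self) -> tuple:
        """Per-parent (maternal, paternal) transmitted and non-transmitted effects."""
        s = np.sqrt(2.0)
        dm = self.delta_maternal if self.delta_maternal is not None else self.delta_direct / s
        dp = self.delta_paternal if self.delta_paternal is not None else self.delta_direct / s
        nm = self.nurture_maternal if self.nurture_maternal is not None else self.beta_nurture / s
        np_ = self.nurture_paternal if self.nurture_paternal is not None else self.beta_nurture / s
        return dm, dp, nm, np_

    def replace(self, **kwargs) -> "GenerativeParams":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# founders, meiosis, masking, phase errors


def _rng_for(params: GenerativeParams, rng) -> np.random.Generator:
    return np.random.default_rng(params.seed) if rng is None else rng


def make_variant_map(params: GenerativeParams) -> VariantMap:
    """Uniformly spaced markers; chromosome genetic length = 100 x crossover rate cM."""
    m = params.n_markers
    length_cm = max(params.crossover_rate, 1e-3) * 100.0
    chroms, pos, cm, mids = [], [], [], []
    for c in range(1, params.n_chromosomes + 1):
        chroms.append(np.full(m, c))
        pos.append(np.arange(1, m + 1) * 10_000)
        cm.append((np.arange(m) + 1.0) * length_cm / m)
        mids.append(np.array([f"chr{c}:snp{j}" for j in range(m)], dtype=object))
    n = m * params.n_chromosomes
    return VariantMap(
        marker_id=np.concatenate(mids),
        chrom=np.concatenate(chroms),
        pos=np.concatenate(pos),
        cm=np.concatenate(cm),
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "G", dtype=object),
    )


def simulate_founders(params: GenerativeParams, rng=None):
    """Founder couples with independent markers, MAF ~ Uniform(maf_range).

    Returns ``(HaplotypeSet, PedigreeTable, VariantMap)``; the pedigree holds one
    mother and one father per family, all genotyped.
    """
    rng = _rng_for(params, rng)
    vmap = make_variant_map(params)
    m = vmap.n_markers
    nf = params.n_families
    maf = rng.uniform(params.maf_range[0], params.maf_range[1], size=m)

    fams = np.array([f"FAM{i:05d}" for i in range(nf)], dtype=object)
    mothers = np.array([f + "_M" for f in fams], dtype=object)
    fathers = np.array([f + "_F" for f in fams], dtype=object)
    ids = np.concatenate([mothers, fathers])
    alleles = (rng.random((2 * nf, m, 2)) < maf[None, :, None]).astype(np.int8)
    haps = HaplotypeSet(ids, alleles)

    ped = pd.DataFrame(
        {
            "family_id": np.concatenate([fams, fams]),
            "individual_id": ids,
            "father_id": [None] * (2 * nf),
            "mother_id": [None] * (2 * nf),
            "sex": ["female"] * nf + ["male"] * nf,
            "genotyped": True,
            "role": ["mother"] * nf + ["father"] * nf,
        }
    )
    return haps, ped, vmap


def gamete_from_breakpoints(parent_alleles: np.ndarray, breakpoints, start_haplotype: int):
    """Deterministic gamete for one chromosome: switch source at each breakpoint.

    ``parent_alleles`` has shape (markers, 2); breakpoints are marker indices at
    which the source haplotype toggles.  Returns (alleles, source).
    """
    m = parent_alleles.shape[0]
    switch = np.zeros(m, dtype=np.int64)
    for b in breakpoints:
        if not 0 <= b < m:
            raise ValueError("breakpoint outside chromosome")
        switch[b] += 1
    source = ((start_haplotype + np.cumsum(switch)) % 2).astype(np.int8)
    return parent_alleles[np.arange(m), source], source


def _gametes(parent_alleles: np.ndarray, vmap: VariantMap, rate: float, rng) -> tuple:
    """Vectorized meioses: (k, m, 2) parental alleles -> (k, m) gametes + sources."""
    k, m, _ = parent_alleles.shape
    source = np.empty((k, m), dtype=np.int8)
    for chrom, sl in vmap.chrom_slices().items():
        cm = vmap.cm[sl]
        mlen = cm.size
        length = cm[-1]
        counts = rng.poisson(rate, size=k)
        total = int(counts.sum())
        pos = rng.uniform(0.0, length, size=total)
        owner = np.repeat(np.arange(k), counts)
        idx = np.searchsorted(cm, pos)  # crossover before marker idx
        switch = np.zeros((k, mlen), dtype=np.int32)
        np.add.at(switch, (owner, np.minimum(idx, mlen - 1)), 1)
        # a crossover landing beyond the last marker has no effect
        beyond = idx >= mlen
        if beyond.any():
            np.add.at(switch, (owner[beyond], np.full(beyond.sum(), mlen - 1)), -1)
        start = rng.integers(0, 2, size=k)
        source[:, sl] = ((start[:, None] + np.cumsum(switch, axis=1)) % 2).astype(np.int8)
    rows = np.arange(k)[:, None]
    cols = np.arange(m)[None, :]
    return parent_alleles[rows, cols, source], source


def mate_and_meiose(founders: HaplotypeSet, pedigree: pd.DataFrame, variant_map: VariantMap,
                    params: GenerativeParams, rng=None):
    """Produce offspring by meiosis; returns (HaplotypeSet incl. offspring, pedigree, truth).

    Offspring haplotype 0 is the maternal gamete and haplotype 1 the paternal
    gamete; the returned :class:`TransmissionTruth` records the source parental
    haplotype of every offspring allele.  Each family has one offspring, plus a
    second with probability ``sibling_rate``.
    """
    rng = _rng_for(params, rng)
    couples = pedigree[pedigree["role"] == "mother"][["family_id", "individual_id"]].rename(
        columns={"individual_id": "mother_id"}
    )
    fathers = pedigree[pedigree["role"] == "father"][["family_id", "individual_id"]].rename(
        columns={"individual_id": "father_id"}
    )
    couples = couples.merge(fathers, on="family_id", how="inner")
    missing = set(pedigree["family_id"]) - set(couples["family_id"])
    if missing:
        raise ValueError(f"families without a complete founder couple: {sorted(missing)[:5]}")

    n_off_per_fam = 1 + (rng.random(len(couples)) < params.sibling_rate).astype(int)
    fam_rep = np.repeat(couples["family_id"].to_numpy(), n_off_per_fam)
    mom_rep = np.repeat(couples["mother_id"].to_numpy(), n_off_per_fam)
    dad_rep = np.repeat(couples["father_id"].to_numpy(), n_off_per_fam)
    within = np.concatenate([np.arange(1, k + 1) for k in n_off_per_fam])
    off_ids = np.array([f"{f}_O{j}" for f, j in zip(fam_rep, within)], dtype=object)

    mom_alleles = founders.alleles[founders.index_of(mom_rep)]
    dad_alleles = founders.alleles[founders.index_of(dad_rep)]
    mat_gam, mat_src = _gametes(mom_alleles, variant_map, params.crossover_rate, rng)
    pat_gam, pat_src = _gametes(dad_alleles, variant_map, params.crossover_rate, rng)
    off_alleles = np.stack([mat_gam, pat_gam], axis=2).astype(np.int8)

    haps = HaplotypeSet(
        np.concatenate([founders.ids, off_ids]),
        np.concatenate([founders.alleles, off_alleles], axis=0),
    )
    truth = TransmissionTruth(off_ids, mat_src, pat_src)

    sex = np.where(rng.random(off_ids.size) < params.prop_female, "female", "male")
    off_rows = pd.DataFrame(
        {
            "family_id": fam_rep,
            "individual_id": off_ids,
            "father_id": dad_rep,
            "mother_id": mom_rep,
            "sex": sex,
            "genotyped": True,
            "role": "offspring",
        }
    )
    ped = pd.concat([pedigree, off_rows], ignore_index=True)
    return haps, ped, truth


def mask_parents(pedigree: pd.DataFrame, fraction_trios: float, seed=None,
                 maternal_bias: float = 0.7, rng=None) -> pd.DataFrame:
    """Clear the genotyped flag of one parent in (1 - fraction_trios) of families.

    The mother remains the genotyped parent with probability ``maternal_bias``
    (fathers are genotyped less often in family cohorts).  Offspring flags are
    untouched.
    """
    if not 0 <= fraction_trios <= 1:
        raise ValueError("fraction_trios must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    ped = pedigree.copy()
    fams = ped.loc[ped["role"] == "mother", "family_id"].unique()
    to_pair = fams[rng.random(fams.size) >= fraction_trios]
    mask_father = rng.random(to_pair.size) < maternal_bias
    masked_parent = np.where(mask_father, "father", "mother")
    drop = set(zip(to_pair, masked_parent))
    hit = [
        (f, r) in drop
        for f, r in zip(ped["family_id"], ped["role"])
    ]
    ped.loc[hit, "genotyped"] = False
    return ped


def inject_phase_errors(haps: HaplotypeSet, phase_error_rate: float, seed=None,
                        rng=None, return_counts: bool = False):
    """Per-marker switch errors: from each error site onward the two haplotypes swap.

    Switch state resets at chromosome boundaries only if a ``variant_map`` is not
    given; the simulator applies errors genome-wide, which is equivalent for the
    tile matcher since chromosomes are processed independently.  Genotype dosage
    is invariant by construction.
    """
    if not 0 <= phase_error_rate < 1:
        raise ValueError("phase_error_rate must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = haps.copy()
    if phase_error_rate == 0:
        return (out, np.zeros(out.n_persons, dtype=int)) if return_counts else out
    switches = rng.random(out.alleles.shape[:2]) < phase_error_rate
    state = np.cumsum(switches, axis=1) % 2 == 1
    flipped = out.alleles[:, :, ::-1]
    out.alleles = np.where(state[:, :, None], flipped, out.alleles).astype(np.int8)
    out.phase_known[:] = False
    return (out, switches.sum(axis=1)) if return_counts else out


# ---------------------------------------------------------------------------
# phenotypes


def _phenotypes_from_scores(off: pd.DataFrame, z_parent_full: pd.DataFrame,
                            params: GenerativeParams, rng) -> tuple:
    """Shared phenotype core.

    ``off`` needs columns individual_id, family_id, sex and the four per-parent
    standardized score columns z_mt, z_mnt, z_pt, z_pnt; ``z_parent_full`` is a
    per-family frame with columns family_id, z_mother, z_father (the parents'
    own full-genotype standardized scores).  Returns (long phenotype table,
    info dict).
    """
    dm, dp, nm, np_ = params.parent_effects()
    n = len(off)
    fam_ids, fam_inv = np.unique(off["family_id"].to_numpy(), return_inverse=True)
    nf = fam_ids.size

    zp = z_parent_full.set_index("family_id").loc[fam_ids]
    z_m = zp["z_mother"].to_numpy()
    z_p = zp["z_father"].to_numpy()

    # parental phenotypes with mate-pair correlation am_corr on the noise scale
    rm = np.sqrt(max(1.0 - params.a_m**2, 0.0))
    rp = np.sqrt(max(1.0 - params.a_p**2, 0.0))
    if rm > 0 and rp > 0:
        rho_e = np.clip(params.am_corr / (rm * rp), -0.99, 0.99)
    else:
        rho_e = 0.0
    e_m = rng.standard_normal(nf)
    e_p = rho_e * e_m + np.sqrt(1 - rho_e**2) * rng.standard_normal(nf)
    pheno_m = params.a_m * z_m + rm * e_m
    pheno_p = params.a_p * z_p + rp * e_p

    male = (off["sex"].to_numpy() == "male").astype(float)
    age1 = np.clip(rng.normal(params.wave_ages[0], params.age_sd, n), 18, 67)
    birth_year = np.round(2009 - age1).astype(int)

    eta_core = (
        dm * off["z_mt"].to_numpy()
        + dp * off["z_pt"].to_numpy()
        + nm * off["z_mnt"].to_numpy()
        + np_ * off["z_pnt"].to_numpy()
        + params.b_m * pheno_m[fam_inv]
        + params.b_p * pheno_p[fam_inv]
    )
    cov_part = params.sex_main * male + params.age_main * (age1 - params.wave_ages[0])
    fixed = eta_core + cov_part
    if params.sigma_resid is None:
        sigma_resid = float(np.sqrt(max(1.0 - np.var(fixed) - params.sigma_family**2, 0.05)))
    else:
        sigma_resid = float(params.sigma_resid)

    u_fam = rng.normal(0.0, params.sigma_family, nf)[fam_inv]

    def draw(extra=0.0):
        return fixed + u_fam + rng.normal(0.0, sigma_resid, n) + extra

    thr_smk = (
        params.liability_threshold
        if params.liability_threshold is not None
        else norm.ppf(1 - params.prevalence_smoking)
    )
    thr_can = norm.ppf(1 - params.prevalence_cannabis)

    smoking_initiation = (draw() > thr_smk).astype(int)
    cannabis_initiation = (draw() > thr_can).astype(int)
    y_cpd = draw()
    y_alc = draw()
    cpd = params.mean_cpd + params.sd_cpd * y_cpd
    alcohol = params.mean_alcohol + params.sd_alcohol * y_alc
    years_smoked = rng.uniform(5.0, 25.0, n)
    pack_years = np.clip(cpd, 0.0, None) * years_smoked / 20.0

    former = rng.random(n) < params.former_smoker_rate
    u_person = rng.normal(0.0, params.sigma_person, n)
    u_slope = rng.normal(0.0, params.sigma_age_slope, n)

    zt = (off["z_mt"].to_numpy() + off["z_pt"].to_numpy()) / np.sqrt(2)
    znt = (off["z_mnt"].to_numpy() + off["z_pnt"].to_numpy()) / np.sqrt(2)
    delta_comb = (dm + dp) / np.sqrt(2)
    nurt_comb = (nm + np_) / np.sqrt(2)

    frames = []
    for w, mean_age in enumerate(params.wave_ages, start=1):
        age_w = age1 + (mean_age - params.wave_ages[0])
        ac = age_w - params.wave_ages[0]
        y_w = (
            (delta_comb + params.age_slope_T * ac) * zt
            + (nurt_comb + params.age_slope_NT * ac) * znt
            + params.b_m * pheno_m[fam_inv]
            + params.b_p * pheno_p[fam_inv]
            + params.sex_main * male
            + params.age_main * ac
            + u_fam
            + u_person
            + u_slope * ac
            + rng.normal(0.0, sigma_resid, n)
        )
        current = params.mean_current_cpd + params.sd_current_cpd * y_w
        current[former] = 0.0
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": off["individual_id"].to_numpy(),
                    "family_id": off["family_id"].to_numpy(),
                    "wave": w,
                    "age": age_w,
                    "sex": off["sex"].to_numpy(),
                    "birth_year": birth_year,
                    "smoking_initiation": smoking_initiation,
                    "cpd": cpd,
                    "pack_years": pack_years,
                    "years_smoked": years_smoked,
                    "alcohol_g_day": alcohol,
                    "cannabis_initiation": cannabis_initiation,
                    "current_cpd": current,
                    "former_smoker": former.astype(int),
                    "maternal_cpd": (params.mean_cpd + params.sd_cpd * pheno_m)[fam_inv],
                    "paternal_cpd": (params.mean_cpd + params.sd_cpd * pheno_p)[fam_inv],
                }
            )
        )
    pheno = pd.concat(frames, ignore_index=True)

    info = {
        "delta_maternal": dm,
        "delta_paternal": dp,
        "nurture_maternal": nm,
        "nurture_paternal": np_,
        "delta_direct": delta_comb,
        "beta_nurture": nurt_comb,
        "a_m": params.a_m,
        "a_p": params.a_p,
        "b_m": params.b_m,
        "b_p": params.b_p,
        "sigma_resid": sigma_resid,
        "liability_threshold_smoking": float(thr_smk),
        "liability_threshold_cannabis": float(thr_can),
        "parent_phenotype": pd.DataFrame(
            {"family_id": fam_ids, "pheno_mother": pheno_m, "pheno_father": pheno_p}
        ),
    }
    return pheno, info


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / (s if s > 0 else 1.0)


def assign_phenotypes(haps: HaplotypeSet, truth: TransmissionTruth, pedigree: pd.DataFrame,
                      weights: pd.DataFrame, variant_map: VariantMap,
                      params: GenerativeParams, rng=None) -> tuple:
    """Phenotypes from the true (simulator-known) transmitted/non-transmitted scores.

    Returns ``(PhenotypeTable, info)`` where ``info`` carries the generative
    coefficients and the true per-parent standardized scores used downstream as
    calibration truth.
    """
    from .scoring import align_weights, haplotype_score

    rng = _rng_for(params, rng)
    w, effect_is_alt, widx = align_weights(weights, variant_map)
    if widx.size == 0:
        raise ValueError("weight table shares no markers with the variant map")

    off = pedigree[pedigree["role"] == "offspring"].reset_index(drop=True)
    oidx = haps.index_of(off["individual_id"])
    tidx = truth.index_of(off["individual_id"])
    midx = haps.index_of(off["mother_id"])
    fidx = haps.index_of(off["father_id"])

    off_alleles = haps.alleles[oidx]
    mom = haps.alleles[midx]
    dad = haps.alleles[fidx]
    msrc = truth.maternal_source[tidx]
    psrc = truth.paternal_source[tidx]
    rows = np.arange(len(off))[:, None]
    cols = np.arange(haps.n_markers)[None, :]

    g_mt = haplotype_score(off_alleles[:, :, 0], w, effect_is_alt, widx)[0]
    g_pt = haplotype_score(off_alleles[:, :, 1], w, effect_is_alt, widx)[0]
    g_mnt = haplotype_score(mom[rows, cols, 1 - msrc], w, effect_is_alt, widx)[0]
    g_pnt = haplotype_score(dad[rows, cols, 1 - psrc], w, effect_is_alt, widx)[0]

    fam_first = ~off["family_id"].duplicated()
    mom_full_raw = haplotype_score(mom[:, :, 0], w, effect_is_alt, widx)[0] + haplotype_score(
        mom[:, :, 1], w, effect_is_alt, widx
    )[0]
    dad_full_raw = haplotype_score(dad[:, :, 0], w, effect_is_alt, widx)[0] + haplotype_score(
        dad[:, :, 1], w, effect_is_alt, widx
    )[0]
    zpar = pd.DataFrame(
        {
            "family_id": off.loc[fam_first, "family_id"].to_numpy(),
            "z_mother": _zscore(mom_full_raw[fam_first.to_numpy()]),
            "z_father": _zscore(dad_full_raw[fam_first.to_numpy()]),
        }
    )

    scores = off[["individual_id", "family_id", "sex"]].copy()
    scores["z_mt"] = _zscore(g_mt)
    scores["z_pt"] = _zscore(g_pt)
    scores["z_mnt"] = _zscore(g_mnt)
    scores["z_pnt"] = _zscore(g_pnt)

    pheno, info = _phenotypes_from_scores(scores, zpar, params, rng)
    info["true_scores"] = scores
    info["parent_full_scores"] = zpar
    return pheno, info


# ---------------------------------------------------------------------------
# cohort bundles


@dataclass
class SimulatedCohort:
    """Everything downstream stages need, plus the withheld ground truth."""

    params: GenerativeParams
    variant_map: VariantMap
    haplotypes: HaplotypeSet  # observed: phase errors applied, masked parents blanked
    haplotypes_true: HaplotypeSet
    pedigree: pd.DataFrame
    truth: TransmissionTruth
    phenotypes: pd.DataFrame
    weights: pd.DataFrame
    info: dict = field(default_factory=dict)

    @property
    def true_scores(self) -> pd.DataFrame:
        return self.info["true_scores"]


def default_weights(variant_map: VariantMap, rng=None, density: float = 1.0) -> pd.DataFrame:
    """A synthetic per-trait SNP weight table over the simulated markers."""
    rng = np.random.default_rng(0) if rng is None else rng
    keep = rng.random(variant_map.n_markers) < density
    idx = np.nonzero(keep)[0]
    return pd.DataFrame(
        {
            "marker_id": variant_map.marker_id[idx],
            "effect_allele": variant_map.alt[idx],
            "weight": rng.normal(0.0, 1.0, idx.size),
        }
    )


def simulate_cohort(params: GenerativeParams, weights: pd.DataFrame = None) -> SimulatedCohort:
    """Run the full generator: founders -> meiosis -> phenotypes -> masking -> phase errors.

    The returned cohort's ``haplotypes`` are what an analyst would see: switch
    errors applied and non-genotyped parents blanked to missing; ``haplotypes_true``
    and ``truth`` retain the full simulation state for validation.
    """
    rng = np.random.default_rng(params.seed)
    founders, ped, vmap = simulate_founders(params, rng)
    haps, ped, truth = mate_and_meiose(founders, ped, vmap, params, rng)
    if weights is None:
        weights = default_weights(vmap, rng)
    pheno, info = assign_phenotypes(haps, truth, ped, weights, vmap, params, rng)
    ped = mask_parents(ped, params.fraction_trios, maternal_bias=params.maternal_bias, rng=rng)
    observed = inject_phase_errors(haps, params.phase_error_rate, rng=rng)
    hidden = ~ped.set_index("individual_id")["genotyped"].loc[observed.ids].to_numpy()
    observed.alleles[hidden] = MISSING
    return SimulatedCohort(params, vmap, observed, haps, ped, truth, pheno, weights, info)


def simulate_scores(params: GenerativeParams, rng=None) -> tuple:
    """Score-level shortcut: per-parent standardized scores drawn directly.

    Skips genotypes entirely; each parent's two haplotype scores are iid
    standard normal latents, an offspring's transmitted score is their mean
    plus independent meiotic noise (so siblings correlate 0.5 and transmitted
    plus non-transmitted reconstructs the parent's full score).  Used for
    repeated-replicate calibration studies where the haplotype pipeline would
    dominate runtime.  Returns ``(phenotypes, scores, info)``.
    """
    rng = _rng_for(params, rng)
    nf = params.n_families
    fams = np.array([f"FAM{i:05d}" for i in range(nf)], dtype=object)
    n_off = 1 + (rng.random(nf) < params.sibling_rate).astype(int)
    fam_rep = np.repeat(fams, n_off)
    within = np.concatenate([np.arange(1, k + 1) for k in n_off])
    off_ids = np.array([f"{f}_O{j}" for f, j in zip(fam_rep, within)], dtype=object)
    n = off_ids.size
    fam_inv = np.repeat(np.arange(nf), n_off)

    h = rng.standard_normal((nf, 4))  # haplotype-score latents: m1, m2, p1, p2
    s_m = (h[:, 0] + h[:, 1]) / 2.0
    s_p = (h[:, 2] + h[:, 3]) / 2.0
    xi_m = rng.standard_normal(n) * np.sqrt(0.5)
    xi_p = rng.standard_normal(n) * np.sqrt(0.5)
    z_mt = s_m[fam_inv] + xi_m
    z_mnt = s_m[fam_inv] - xi_m
    z_pt = s_p[fam_inv] + xi_p
    z_pnt = s_p[fam_inv] - xi_p

    sex = np.where(rng.random(n) < params.prop_female, "female", "male")
    scores = pd.DataFrame(
        {
            "individual_id": off_ids,
            "family_id": fam_rep,
            "sex": sex,
            "z_mt": z_mt,
            "z_mnt": z_mnt,
            "z_pt": z_pt,
            "z_pnt": z_pnt,
        }
    )
    zpar = pd.DataFrame(
        {
            "family_id": fams,
            "z_mother": (h[:, 0] + h[:, 1]) / np.sqrt(2),
            "z_father": (h[:, 2] + h[:, 3]) / np.sqrt(2),
        }
    )
    pheno, info = _phenotypes_from_scores(scores, zpar, params, rng)
    info["true_scores"] = scores
    return pheno, scores, info
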
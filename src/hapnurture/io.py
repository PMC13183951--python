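"""Text-format input/output: phased VCF, pedigree, weights, phenotypes.

Phased genotypes travel as VCF with ``0|1``-style GT fields; the pedigree is a
PED-like TSV (FID, IID, PAT, MAT, SEX, GENOTYPED, ROLE); weight tables use the
common polygenic-weight layout (marker_id, effect_allele, weight).  Reading
VCF prefers cyvcf2 when installed and falls back to a plain-text parser (the
simulator only ever writes uncompressed, minimal VCF).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sim import MISSING, HaplotypeSet, VariantMap

_SEX_CODE = {"male": 1, "female": 2}
_SEX_NAME = {1: "male", 2: "female", 0: "unknown"}


def write_vcf(path, haps: HaplotypeSet, variant_map: VariantMap, ids=None) -> None:
    """Write phased genotypes as uncompressed VCF (missing alleles as '.')."""
    ids = list(ids) if ids is not None else list(haps.ids)
    idx = haps.index_of(ids)
    a = haps.alleles[idx]  # (n, m, 2)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in variant_map.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        al = a.astype(object)
        al[a < 0] = "."
        for m in range(variant_map.n_markers):
            gts = "\t".join(f"{al[i, m, 0]}|{al[i, m, 1]}" for i in range(len(ids)))
            fh.write(
                f"{variant_map.chrom[m]}\t{variant_map.pos[m]}\t{variant_map.marker_id[m]}\t"
                f"{variant_map.ref[m]}\t{variant_map.alt[m]}\t.\t.\t.\tGT\t{gts}\n"
            )


def _read_vcf_text(path):
    samples, rows, gts = None, [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            rows.append(parts[:5])
            gts.append([g.split(":")[0] for g in parts[9:]])
    return samples, rows, gts


def read_vcf(path) -> tuple:
    """Read a phased VCF into (HaplotypeSet, VariantMap)."""
    try:
        from cyvcf2 import VCF

        v = VCF(str(path))
        samples = list(v.samples)
        rows, alleles = [], []
        for rec in v:
            rows.append([str(rec.CHROM), rec.POS, rec.ID, rec.REF, rec.ALT[0]])
            g = np.asarray(rec.genotype.array())[:, :2]
            alleles.append(g)
        a = np.stack(alleles, axis=1).astype(np.int8)  # (n, m, 2); -1 already missing
    except ImportError:
        samples, raw, gts = _read_vcf_text(path)
        rows = [[r[0], int(r[1]), r[2], r[3], r[4]] for r in raw]
        m = len(rows)
        n = len(samples)
        a = np.full((n, m, 2), MISSING, dtype=np.int8)
        for j, g in enumerate(gts):
            for i, cell in enumerate(g):
                sep = "|" if "|" in cell else "/"
                h1, h2 = cell.split(sep)
                a[i, j, 0] = MISSING if h1 == "." else int(h1)
                a[i, j, 1] = MISSING if h2 == "." else int(h2)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "marker_id", "ref", "alt"])
    try:
        chrom = pd.to_numeric(df["chrom"])
    except (ValueError, TypeError):
        chrom = df["chrom"]
    vmap = VariantMap(
        marker_id=df["marker_id"].to_numpy(dtype=object),
        chrom=np.asarray(chrom),
        pos=df["pos"].to_numpy(dtype=int),
        cm=df["pos"].to_numpy(dtype=float) / 1e6,  # placeholder map: 1 cM / Mb
        ref=df["ref"].to_numpy(dtype=object),
        alt=df["alt"].to_numpy(dtype=object),
    )
    return HaplotypeSet(np.array(samples, dtype=object), a), vmap


def write_pedigree(path, pedigree: pd.DataFrame) -> None:
    out = pd.DataFrame(
        {
            "FID": pedigree["family_id"],
            "IID": pedigree["individual_id"],
            "PAT": pedigree["father_id"].fillna("0"),
            "MAT": pedigree["mother_id"].fillna("0"),
            "SEX": pedigree["sex"].map(_SEX_CODE).fillna(0).astype(int),
            "GENOTYPED": pedigree["genotyped"].astype(int),
            "ROLE": pedigree["role"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str, "PAT": str, "MAT": str})
    return pd.DataFrame(
        {
            "family_id": raw["FID"],
            "individual_id": raw["IID"],
            "father_id": raw["PAT"].replace("0", None),
            "mother_id": raw["MAT"].replace("0", None),
            "sex": raw["SEX"].map(_SEX_NAME),
            "genotyped": raw["GENOTYPED"].astype(bool),
            "role": raw["ROLE"],
        }
    )


def read_weights(path) -> pd.DataFrame:
    w = pd.read_csv(path, sep="\t")
    need = {"marker_id", "effect_allele", "weight"}
    if not need <= set(w.columns):
        raise ValueError(f"weight table must have columns {sorted(need)}")
    return w


def write_weights(path, weights: pd.DataFrame) -> None:
    weights.to_csv(path, sep="\t", index=False)


def write_phenotypes(path, phenotypes: pd.DataFrame) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_transmission(outdir, tmap, variant_map: VariantMap, truth_report: dict = None) -> None:
    """Write transmitted / non-transmitted allele datasets and a JSON report.

    Both datasets are VCF-like TSVs with one column per offspring holding
    ``maternal|paternal`` alleles; a missing parent's non-transmitted allele is
    '.'.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = [str(i) for i in tmap.offspring_ids]
    for name, arr in (("transmitted", tmap.t_alleles), ("non_transmitted", tmap.nt_alleles)):
        with open(outdir / f"{name}.tsv", "w") as fh:
            fh.write("chrom\tpos\tmarker_id\t" + "\t".join(ids) + "\n")
            a = arr.astype(object)
            a[arr < 0] = "."
            for m in range(variant_map.n_markers):
                cells = "\t".join(f"{a[i, m, 0]}|{a[i, m, 1]}" for i in range(len(ids)))
                fh.write(f"{variant_map.chrom[m]}\t{variant_map.pos[m]}\t{variant_map.marker_id[m]}\t{cells}\n")
    report = tmap.report()
    if truth_report:
        report.update(truth_report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
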
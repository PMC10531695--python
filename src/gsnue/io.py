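"""Readers and writers for the package's text formats.

Genotypes travel as biallelic VCF (GT parsed to alternate-allele dosage) or
as a plain TSV (rows = genotypes, columns = markers, values 0/1/2/NA);
phenotypes as CSV with header genotype_id,n_level,GY,Ns,Nt,NUE; kinship
matrices as TSV with genotype ids on both axes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gsnue.data import GenotypeMatrix, PhenotypeTable
from gsnue.kinship import KinshipMatrix
from gsnue.simulate import TrueArchitecture, compute_nue

_GT_TO_DOSAGE = {
    "0/0": 0.0, "0|0": 0.0,
    "0/1": 1.0, "1/0": 1.0, "0|1": 1.0, "1|0": 1.0,
    "1/1": 2.0, "1|1": 2.0,
    "./.": np.nan, ".|.": np.nan, ".": np.nan,
}


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or TSV (format inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    """Parse a biallelic VCF; multi-allelic sites are rejected and counted."""
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - cyvcf2 is a declared dependency
        VCF = None
    if VCF is not None:
        return _read_vcf_cyvcf2(path)
    return _read_vcf_text(path)


def _read_vcf_cyvcf2(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, marker_ids, chroms, poss = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.genotypes  # [a0, a1, phased]
        dos = np.array(
            [np.nan if g[0] < 0 or g[1] < 0 else float(g[0] + g[1]) for g in gts]
        )
        rows.append(dos)
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if not rows:
        raise ValueError(f"no biallelic markers in {path}")
    meta = pd.DataFrame({"chrom": chroms, "pos": poss})
    meta.attrs["n_multiallelic_rejected"] = n_multi
    return GenotypeMatrix(
        genotype_ids=samples,
        marker_ids=marker_ids,
        dosage=np.column_stack(rows),
        marker_meta=meta,
    )


def _read_vcf_text(path: Path) -> GenotypeMatrix:
    samples, rows, marker_ids, chroms, poss = [], [], [], [], []
    n_multi = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            if len(fields) < 10:
                raise ValueError(f"malformed VCF record at line {lineno}")
            if "," in fields[4]:
                n_multi += 1
                continue
            gt_idx = fields[8].split(":").index("GT")
            dos = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_idx]
                if gt not in _GT_TO_DOSAGE:
                    raise ValueError(f"unparseable GT {gt!r} at line {lineno}")
                dos.append(_GT_TO_DOSAGE[gt])
            rows.append(dos)
            marker_ids.append(fields[2] if fields[2] != "." else f"{fields[0]}:{fields[1]}")
            chroms.append(fields[0])
            poss.append(int(fields[1]))
    if not rows:
        raise ValueError(f"no biallelic markers in {path}")
    meta = pd.DataFrame({"chrom": chroms, "pos": poss})
    meta.attrs["n_multiallelic_rejected"] = n_multi
    return GenotypeMatrix(
        genotype_ids=samples,
        marker_ids=marker_ids,
        dosage=np.array(rows, dtype=float).T,
        marker_meta=meta,
    )


def _read_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.shape[1] == 0:
        raise ValueError(f"no markers in {path}")
    dosage = df.to_numpy(dtype=float)
    obs = dosage[~np.isnan(dosage)]
    fractional = bool(obs.size) and not np.isin(obs, (0.0, 1.0, 2.0)).all()
    return GenotypeMatrix(
        genotype_ids=[str(i) for i in df.index],
        marker_ids=[str(c) for c in df.columns],
        dosage=dosage,
        imputed=fractional,  # mean-imputed panels round-trip with fractions
    )


def write_genotypes_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(G.dosage, index=G.genotype_ids, columns=G.marker_ids)
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def write_genotypes_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a minimal biallelic VCF (alleles A/B placeholders)."""
    frac = G.dosage[~np.isnan(G.dosage)] % 1
    if frac.size and (frac != 0).any():
        raise ValueError("cannot write imputed fractional dosages as VCF")
    meta = G.marker_meta
    back = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.genotype_ids) + "\n")
        for j, mid in enumerate(G.marker_ids):
            chrom = str(meta["chrom"].iloc[j]) if meta is not None and "chrom" in meta else "1"
            pos = int(meta["pos"].iloc[j]) if meta is not None and "pos" in meta else j + 1
            gts = "\t".join(
                "./." if np.isnan(d) else back[d] for d in G.dosage[:, j]
            )
            fh.write(f"{chrom}\t{pos}\t{mid}\tA\tB\t.\tPASS\t.\tGT\t{gts}\n")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read the phenotype CSV; NUE is filled from GY/Ns when absent and
    rows with nonpositive Ns are rejected (with a count in ``attrs``)."""
    df = pd.read_csv(path)
    required = ["genotype_id", "n_level", "GY", "Ns"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"phenotype file missing required column {col!r}")
    n_bad = int((df["Ns"] <= 0).sum())
    df = df[df["Ns"] > 0].copy()
    if "Nt" not in df.columns:
        df["Nt"] = df["Ns"] * 0.7
    if "NUE" not in df.columns or df["NUE"].isna().all():
        df["NUE"] = [compute_nue(gy, ns) for gy, ns in zip(df["GY"], df["Ns"])]
    table = PhenotypeTable(df.reset_index(drop=True))
    table.table.attrs["n_rejected_ns"] = n_bad
    return table


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.table.to_csv(path, index=False, float_format="%.10g")


def write_kinship(K: KinshipMatrix, path: str | Path) -> None:
    pd.DataFrame(K.values, index=K.genotype_ids, columns=K.genotype_ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_kinship(path: str | Path, construction: str = "GRM") -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    vals = (vals + vals.T) / 2.0  # text round-trip can break exact symmetry
    return KinshipMatrix(
        genotype_ids=[str(i) for i in df.index], values=vals, construction=construction
    )


def write_architecture(arch: TrueArchitecture, path: str | Path) -> None:
    payload = {
        "qtl_indices": arch.qtl_indices.tolist(),
        "effects_low_n": arch.effects_low_n.tolist(),
        "effects_high_n": arch.effects_high_n.tolist(),
        "sigma2_a": arch.sigma2_a,
        "sigma2_e": arch.sigma2_e,
        "true_gebv": {
            lv: arch.true_gebv[lv].round(10).tolist() for lv in arch.true_gebv.columns
        },
        "genotype_ids": list(arch.true_gebv.index),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
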
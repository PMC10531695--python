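"""Simulate the wheat-like study population and write its data files.

Emits genotypes (VCF + TSV), phenotypes (CSV) and the true genetic
architecture (JSON), and prints the realized population summaries: marker
MAF spectrum, subpopulation sizes, and realized heritability per N level.
"""

import importlib
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
settings = importlib.import_module("00_settings")

from gsnue import io as gio
from gsnue.simulate import simulate_genotypes, simulate_phenotypes


def main() -> None:
    out = settings.RESULTS
    out.mkdir(parents=True, exist_ok=True)
    cfg = settings.POPULATION

    G = simulate_genotypes(cfg)
    pheno, arch = simulate_phenotypes(G, cfg)

    gio.write_genotypes_vcf(G, out / "genotypes.vcf")
    gio.write_genotypes_tsv(G, out / "genotypes.tsv")
    gio.write_phenotypes(pheno, out / "phenotypes.csv")
    gio.write_architecture(arch, out / "architecture.json")

    maf = G.marker_meta["realized_maf"]
    print(f"population: {G.n_genotypes} genotypes x {G.n_markers} markers")
    print(f"subpopulation sizes: {np.bincount(G.subpop_labels).tolist()}")
    print(f"realized MAF: median {maf.median():.3f}, "
          f"{(maf <= 0.05).sum()} markers at MAF <= 0.05")
    print(f"missing call rate: {np.isnan(G.dosage).mean():.4f}")
    for lv in ("LN", "HN"):
        y = pheno.trait(lv, G.genotype_ids)
        g = arch.true_gebv[lv].to_numpy()
        print(f"{lv}: mean NUE {y.mean():.2f}, target h2 {arch.h2(lv):.2f}, "
              f"realized sample h2 {g.var() / y.var():.3f}")
    print(f"wrote population files to {out}")


if __name__ == "__main__":
    main()
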
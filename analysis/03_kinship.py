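"""Genomic relationship matrix and Gaussian kernel of the QC'd panel.

The GRM (allele-frequency-scaled cross-product) backs the linear mixed
models; the Gaussian kernel on Euclidean genotype distances (median
bandwidth) backs the kernel and ensemble learners.
"""

import importlib
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
settings = importlib.import_module("00_settings")

from gsnue import io as gio
from gsnue.kinship import build_gaussian_kernel, build_grm
from gsnue.qc import recode_centered


def main() -> None:
    out = settings.RESULTS
    Gq = gio.read_genotypes(out / "genotypes_qc.tsv")
    Gq.imputed = True  # QC'd panel carries mean-imputed fractional dosages

    grm = build_grm(Gq.dosage, list(Gq.genotype_ids))
    Xc = recode_centered(Gq)
    kern = build_gaussian_kernel(Xc - Xc.mean(axis=0),
                                 genotype_ids=list(Gq.genotype_ids))

    gio.write_kinship(grm, out / "kinship_grm.tsv")
    gio.write_kinship(kern, out / "kinship_kernel.tsv")

    off = grm.values[~np.eye(grm.n, dtype=bool)]
    print(f"GRM: mean diagonal {grm.values.diagonal().mean():.3f}, "
          f"off-diagonal range [{off.min():.3f}, {off.max():.3f}]")
    print(f"kernel bandwidth (median heuristic): "
          f"{kern.parameters['bandwidth']:.3f}")
    print(f"kernel off-diagonal median: "
          f"{np.median(kern.values[~np.eye(kern.n, dtype=bool)]):.3f}")


if __name__ == "__main__":
    main()
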
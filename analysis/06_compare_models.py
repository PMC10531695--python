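"""Pairwise adaptive standard error of prediction between GS models.

Marker (or back-projected pseudo) effects are screened against a N(0,1)
null with BH-FDR 0.05; the adaptive SE of each model pair is the bootstrap
SE of the paired difference in squared held-out errors, min-max normalized
to the [-0.2, 1] heat-map scale.
"""

import importlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
settings = importlib.import_module("00_settings")

from gsnue import io as gio
from gsnue.comparison import adaptive_se_matrix, pseudo_marker_effects


def main() -> None:
    out = settings.RESULTS
    preds = pd.read_csv(out / "predictions.tsv", sep="\t")
    Gq = gio.read_genotypes(out / "genotypes_qc.tsv")
    Gq.imputed = True
    Xc = Gq.dosage - Gq.dosage.mean(axis=0)

    payload = {}
    for lv in ("LN", "HN"):
        sub = preds[preds["n_level"] == lv]
        errors, effects = {}, {}
        for model in sub["model"].unique():
            msub = sub[sub["model"] == model].sort_values("genotype_id")
            errors[model] = ((msub["observed"] - msub["predicted"]) ** 2).to_numpy()
            gebv = msub["predicted"].to_numpy()
            effects[model] = pseudo_marker_effects(gebv - gebv.mean(), Xc)
        cm = adaptive_se_matrix(errors, effects, n_resamples=2000, fdr=0.05,
                                seed=settings.SEED + 11)
        pd.DataFrame(cm.normalized, index=cm.labels, columns=cm.labels).to_csv(
            out / f"comparison_matrix_{lv}.tsv", sep="\t", float_format="%.4g"
        )
        payload[lv] = {
            "labels": cm.labels,
            "normalized": np.round(cm.normalized, 6).tolist(),
            "declared_different": cm.declared_different.tolist(),
            "n_far_from_normal": cm.n_far_from_normal,
        }
        mean_raw = cm.raw[~np.eye(len(cm.labels), dtype=bool)].mean()
        best = cm.labels[int(np.argmin(cm.raw.sum(axis=1)))]
        print(f"{lv}: mean raw adaptive SE {mean_raw:.4f}; lowest total "
              f"pairwise SE: {best}; "
              f"{int(cm.declared_different.sum() / 2)} pairs declared different")
    with open(out / "comparison_matrix.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


if __name__ == "__main__":
    main()
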
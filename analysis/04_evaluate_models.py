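"""Nested cross-validation of the nine GS models on the NUE trait.

Outer 5-fold testing with inner 10-fold tuning, per N level.  Writes the
per model x N level report (SNP heritability, GEBV means with bootstrap
intervals, variance components, accuracy, train-vs-test Welch p) — the
package's analog of a genetic-parameter summary table — plus the held-out
predictions every later stage consumes.
"""

import importlib
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
settings = importlib.import_module("00_settings")

from gsnue import io as gio
from gsnue.evaluation import CVPlan, run_nested_cv


def main() -> None:
    out = settings.RESULTS
    Gq = gio.read_genotypes(out / "genotypes_qc.tsv")
    Gq.imputed = True
    pheno = gio.read_phenotypes(out / "phenotypes.csv")

    report, preds = run_nested_cv(
        Gq, pheno, plan=CVPlan(outer_folds=5, inner_folds=10, seed=settings.SEED)
    )
    report.table.to_csv(out / "evaluation_report.tsv", sep="\t", index=False,
                        float_format="%.6g")
    preds.to_csv(out / "predictions.tsv", sep="\t", index=False,
                 float_format="%.6g")

    cols = ["model", "n_level", "snp_h2", "accuracy", "Vg", "Ve", "train_test_p"]
    print(report.table[cols].round(3).to_string(index=False))
    best = report.table.groupby("model")["accuracy"].mean().idxmax()
    print(f"\nhighest mean test accuracy: {best} "
          f"({report.table.groupby('model')['accuracy'].mean().max():.3f})")


if __name__ == "__main__":
    main()
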
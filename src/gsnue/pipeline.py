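"""End-to-end orchestration: QC -> kinship -> nested-CV model evaluation ->
bias-variance table -> comparison matrix -> selection-gain report.

Every stage writes its artifact into the output directory; a manifest
records the seed, a config snapshot and a sha256 checksum per file so two
runs with the same config and seed are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gsnue import io as gio
from gsnue import models as M
from gsnue.bias_variance import (
    SyntheticSource,
    decompose_bias_variance,
    knn_predict,
    rows_to_frame,
)
from gsnue.comparison import adaptive_se_matrix, pseudo_marker_effects
from gsnue.data import GenotypeMatrix, PhenotypeTable
from gsnue.evaluation import BASE_MODELS, CVPlan, run_nested_cv
from gsnue.gain import gain_report
from gsnue.kinship import build_gaussian_kernel, build_grm, regularized_inverse
from gsnue.qc import apply_qc, recode_centered
from gsnue.simulate import PopulationConfig, simulate_genotypes, simulate_phenotypes


@dataclass
class RunConfig:
    """Structured configuration of a full pipeline run."""

    out_dir: str = "results/run"
    seed: int = 0
    # exactly one of (genotype_path [+ phenotype_path]) or synthetic config
    genotype_path: str | None = None
    phenotype_path: str | None = None
    synthetic: PopulationConfig | None = None
    models: tuple[str, ...] = BASE_MODELS + ("STACK",)
    maf_threshold: float = 0.05
    hwe_alpha: float | None = 1e-4
    min_call_rate: float = 0.95
    cv: CVPlan = field(default_factory=CVPlan)
    n_levels: tuple[str, ...] = ("LN", "HN")
    model_params: dict = field(default_factory=dict)
    # bias-variance settings
    bv_resamples: int = 100
    bv_k_grid: tuple[int, ...] = (1, 5, 15, 45)
    # comparison settings
    cmp_resamples: int = 2000
    fdr: float = 0.05
    # gain settings
    selected_fraction: float | None = None  # default: 10 / n
    years: int = 1
    holdout_train_frac: float = 0.75

    def __post_init__(self) -> None:
        has_files = self.genotype_path is not None
        if has_files == (self.synthetic is not None):
            raise ValueError("exactly one of input paths or synthetic config required")

    def snapshot(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k not in ("synthetic", "cv")}
        d["models"] = list(self.models)
        d["n_levels"] = list(self.n_levels)
        d["bv_k_grid"] = list(self.bv_k_grid)
        if self.synthetic is not None:
            d["synthetic"] = dict(self.synthetic.__dict__)
        d["cv"] = {
            "outer_folds": self.cv.outer_folds,
            "inner_folds": self.cv.inner_folds,
            "seed": self.cv.seed,
        }
        return d


def holdout_split(
    n: int, train_frac: float = 0.75, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffle split; the training size is floor(train_frac * n)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(train_frac * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the output directory.

    A stage failure aborts with the stage name while earlier artifacts stay
    on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    stage = "setup"

    def _mark(name: str):
        nonlocal stage
        stage = name
        log.append({"stage": name, "t": time.time()})

    try:
        # ------------------------------------------------------------ inputs
        _mark("inputs")
        arch = None
        if config.synthetic is not None:
            pop = config.synthetic
            G = simulate_genotypes(pop)
            pheno, arch = simulate_phenotypes(G, pop)
            gio.write_genotypes_vcf(G, out / "genotypes.vcf")
            gio.write_genotypes_tsv(G, out / "genotypes.tsv")
            gio.write_phenotypes(pheno, out / "phenotypes.csv")
            gio.write_architecture(arch, out / "architecture.json")
        else:
            G = gio.read_genotypes(config.genotype_path)
            pheno = gio.read_phenotypes(config.phenotype_path)

        # ---------------------------------------------------------------- qc
        _mark("qc")
        Gq, qc_report = apply_qc(
            G,
            maf_threshold=config.maf_threshold,
            hwe_alpha=config.hwe_alpha,
            min_call_rate=config.min_call_rate,
        )
        qc_report.per_marker.to_csv(
            out / "qc_per_marker.tsv", sep="\t", index=False, float_format="%.8g"
        )
        qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        with open(out / "qc_report.json", "w") as fh:
            json.dump(
                {
                    k: getattr(qc_report, k)
                    for k in (
                        "n_markers_in",
                        "n_removed_maf",
                        "n_removed_hwe",
                        "n_removed_callrate",
                        "n_markers_out",
                    )
                },
                fh,
                indent=1,
                sort_keys=True,
            )

        # ----------------------------------------------------------- kinship
        _mark("kinship")
        Xc = recode_centered(Gq)
        grm = build_grm(Gq.dosage, list(Gq.genotype_ids))
        kern = build_gaussian_kernel(
            Xc - Xc.mean(axis=0), genotype_ids=list(Gq.genotype_ids)
        )
        gio.write_kinship(grm, out / "kinship_grm.tsv")
        gio.write_kinship(kern, out / "kinship_kernel.tsv")

        # -------------------------------------------------------- evaluation
        _mark("evaluation")
        plan = CVPlan(
            outer_folds=config.cv.outer_folds,
            inner_folds=config.cv.inner_folds,
            seed=config.seed,
        )
        report, preds = run_nested_cv(
            Gq,
            pheno,
            models=config.models,
            plan=plan,
            n_levels=config.n_levels,
            params=config.model_params,
        )
        report.table.to_csv(
            out / "evaluation_report.tsv", sep="\t", index=False, float_format="%.8g"
        )
        report.table.to_json(out / "evaluation_report.json", orient="records", indent=1)
        preds.to_csv(out / "predictions.tsv", sep="\t", index=False, float_format="%.8g")

        # ----------------------------------------------------- bias-variance
        _mark("bias_variance")
        bv_frames = []
        for level in config.n_levels:
            src = _bv_source(Gq, pheno, arch, level, config)
            k_grid = [k for k in config.bv_k_grid if k <= Gq.n_genotypes - 1]
            rows = decompose_bias_variance(
                lambda tx, ty, sx, k: knn_predict(tx, ty, sx, int(k)),
                src,
                k_grid,
                n_resamples=config.bv_resamples,
                seed=config.seed + 7,
            )
            df = rows_to_frame(rows)
            df.insert(0, "n_level", level)
            bv_frames.append(df)
        pd.concat(bv_frames, ignore_index=True).to_csv(
            out / "bias_variance.tsv", sep="\t", index=False, float_format="%.8g"
        )

        # --------------------------------------------------------- comparison
        _mark("comparison")
        cmp_frames = {}
        for level in config.n_levels:
            sub = preds[preds["n_level"] == level]
            errors, effects = {}, {}
            for model in config.models:
                msub = sub[sub["model"] == model].sort_values("genotype_id")
                err = (msub["observed"] - msub["predicted"]) ** 2
                errors[model] = err.to_numpy()
                gebv_hat = msub["predicted"].to_numpy()
                effects[model] = pseudo_marker_effects(
                    gebv_hat - gebv_hat.mean(), Xc - Xc.mean(axis=0)
                )
            cm = adaptive_se_matrix(
                errors,
                effects,
                n_resamples=config.cmp_resamples,
                fdr=config.fdr,
                seed=config.seed + 11,
            )
            cmp_frames[level] = cm
            pd.DataFrame(cm.normalized, index=cm.labels, columns=cm.labels).to_csv(
                out / f"comparison_matrix_{level}.tsv", sep="\t", float_format="%.8g"
            )
        with open(out / "comparison_matrix.json", "w") as fh:
            json.dump(
                {
                    lv: {
                        "labels": cm.labels,
                        "raw": np.round(cm.raw, 10).tolist(),
                        "normalized": np.round(cm.normalized, 10).tolist(),
                        "declared_different": cm.declared_different.tolist(),
                        "n_far_from_normal": cm.n_far_from_normal,
                    }
                    for lv, cm in cmp_frames.items()
                },
                fh,
                indent=1,
                sort_keys=True,
            )

        # --------------------------------------------------------------- gain
        _mark("gain")
        best = (
            "STACK"
            if "STACK" in config.models
            else report.table.groupby("model")["accuracy"].mean().idxmax()
        )
        gebvs, acc, s2e, s2u = {}, {}, {}, {}
        for level in config.n_levels:
            sub = preds[(preds["n_level"] == level) & (preds["model"] == best)]
            ser = sub.set_index("genotype_id")["predicted"]
            gebvs[level] = ser - ser.mean()
            row = report.table[
                (report.table["model"] == best) & (report.table["n_level"] == level)
            ].iloc[0]
            acc[level] = float(row["accuracy"])
            s2e[level] = float(row["Ve"])
            s2u[level] = float(row["Vg"])
        labels = getattr(Gq, "subpop_labels", None)
        if labels is None:
            labels = _structure_labels(Xc)
        Xfix = pd.get_dummies(pd.Series(labels)).to_numpy(dtype=float)
        Ginv, inv_log = regularized_inverse(grm)
        frac = config.selected_fraction or 10.0 / Gq.n_genotypes
        g_rep = gain_report(
            gebvs,
            acc,
            Gq,
            Xfix,
            np.eye(Gq.n_genotypes),
            Ginv,
            s2e,
            s2u,
            selected_fraction=frac,
            years=config.years,
        )
        g_rep.top_genotypes.to_csv(
            out / "top_genotypes.tsv", sep="\t", index=False, float_format="%.8g"
        )
        with open(out / "gain_report.json", "w") as fh:
            json.dump(
                {
                    "model": best,
                    "beta_power": g_rep.beta_power,
                    "selection_intensity": g_rep.selection_intensity,
                    "years": g_rep.years,
                    "accuracy": g_rep.accuracy,
                    "delta_g": g_rep.delta_g,
                    "expected_gain": g_rep.expected_gain,
                    "relative_efficiency": g_rep.relative_efficiency,
                    "top_overlap": g_rep.overlap,
                    "allele_contrast": g_rep.allele_contrast.round(10).to_dict("records"),
                    "grm_inverse_log": inv_log,
                },
                fh,
                indent=1,
                sort_keys=True,
            )

        # 75/25 holdout (the split-mode view of the selected model)
        _mark("holdout")
        tr, te = holdout_split(
            Gq.n_genotypes, config.holdout_train_frac, seed=config.seed + 13
        )
        _holdout_table(Gq, pheno, Xc, grm.values, kern.values, tr, te, best, config).to_csv(
            out / "holdout_predictions.tsv", sep="\t", index=False, float_format="%.8g"
        )

        # ----------------------------------------------------------- manifest
        _mark("manifest")
        files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
        manifest = {
            "seed": config.seed,
            "config": config.snapshot(),
            "checksums": {name: _sha256(out / name) for name in files},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err
    return out


def _bv_source(
    Gq: GenotypeMatrix,
    pheno: PhenotypeTable,
    arch,
    level: str,
    config: RunConfig,
) -> SyntheticSource:
    """Bias-variance data source; synthetic mode when the truth is known."""
    Xc = recode_centered(Gq)
    y = pheno.trait(level, list(Gq.genotype_ids))
    n = Gq.n_genotypes
    n_test = min(40, n // 4)
    rng0 = np.random.default_rng(config.seed + 23)
    test_idx = rng0.choice(n, size=n_test, replace=False)
    train_pool = np.setdiff1d(np.arange(n), test_idx)
    if arch is not None:
        mu = y.mean()
        g = arch.true_gebv[level].to_numpy()
        s2e = arch.sigma2_e[level]
        target = mu + g[test_idx]

        def draw(rng: np.random.Generator):
            noise = rng.normal(0.0, np.sqrt(s2e), size=train_pool.size) if s2e > 0 else 0.0
            return Xc[train_pool], mu + g[train_pool] + noise

        return SyntheticSource(Xc[test_idx], target, s2e, draw)
    from gsnue.bias_variance import FixedSource

    return FixedSource(Xc[train_pool], y[train_pool], Xc[test_idx], y[test_idx])


def _structure_labels(Xc: np.ndarray, k: int = 3) -> np.ndarray:
    """Population-structure clusters from the leading principal components."""
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    pcs = PCA(n_components=min(10, Xc.shape[1])).fit_transform(Xc)
    return KMeans(n_clusters=k, n_init=10, random_state=0).fit_predict(pcs[:, :2])


def _holdout_table(Gq, pheno, Xc, grm, kern, tr, te, model, config) -> pd.DataFrame:
    from gsnue.evaluation import _fit_single, _predict_single

    rows = []
    for level in config.n_levels:
        y = pheno.trait(level, list(Gq.genotype_ids))
        name = model if model != "STACK" else "BAGG"  # single-learner stand-in
        fit = _fit_single(
            name,
            y[tr],
            Xc[tr],
            grm[np.ix_(tr, tr)],
            kern[np.ix_(tr, tr)],
            config.cv.inner_folds,
            {},
            config.seed,
        )
        for split, idx in (("train", tr), ("test", te)):
            pred = (
                fit.intercept + fit.gebv
                if split == "train"
                else _predict_single(fit, idx, tr, Xc, grm, kern)
            )
            for i, p in zip(idx, np.atleast_1d(pred)):
                rows.append(
                    {
                        "genotype_id": Gq.genotype_ids[i],
                        "n_level": level,
                        "split": split,
                        "observed": y[i],
                        "predicted": float(p),
                    }
                )
    return pd.DataFrame(rows)
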
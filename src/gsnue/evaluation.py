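"""Model evaluation: nested cross-validation, accuracy, SNP heritability,
bootstrap GEBV summaries, the learning-rate schedule and the per-model
report table.

The cross-validation design follows the study's two-level scheme read as
nested CV: an outer 5-fold loop provides the test partition, and an inner
10-fold loop on each training split tunes hyper-parameters and produces the
out-of-fold base predictions the stacked ensemble trains on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from gsnue import models as M
from gsnue.data import GenotypeMatrix, PhenotypeTable
from gsnue.kinship import KinshipMatrix, build_gaussian_kernel, build_grm
from gsnue.models import ModelFit, VarianceComponents, snp_heritability
from gsnue.qc import recode_centered

BASE_MODELS = ("rrBLUP", "gBLUP", "LASSO", "BGLR", "RKHS", "SVM", "BOOST", "BAGG")


@dataclass
class CVPlan:
    """Outer/inner fold assignment for every genotype."""

    outer_folds: int = 5
    inner_folds: int = 10
    seed: int = 0
    assignment: np.ndarray = field(default=None)  # outer fold id per genotype

    def materialize(self, n: int) -> "CVPlan":
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        kf = KFold(n_splits=self.outer_folds, shuffle=True, random_state=self.seed)
        assignment = np.empty(n, dtype=int)
        for fold, (_, test_idx) in enumerate(kf.split(np.arange(n))):
            assignment[test_idx] = fold
        return CVPlan(self.outer_folds, self.inner_folds, self.seed, assignment)

    def check_partition(self, n: int) -> None:
        if self.assignment is None or self.assignment.size != n:
            raise ValueError("plan not materialized for this population size")
        counts = np.bincount(self.assignment, minlength=self.outer_folds)
        if counts.sum() != n or (counts < 2).any():
            raise ValueError("every outer fold needs at least 2 genotypes")


@dataclass
class EvaluationReport:
    """Per model x N level summary table (the Table 1 / Table 2 analog)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        acc = self.table["accuracy"].dropna()
        if ((acc < -1 - 1e-9) | (acc > 1 + 1e-9)).any():
            raise ValueError("accuracy outside [-1, 1]")
        h2 = self.table["snp_h2"].dropna()
        if ((h2 < 0) | (h2 > 1)).any():
            raise ValueError("h2 outside [0, 1]")


def accuracy(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Prediction accuracy: Pearson correlation r(y_obs, y_GEBV)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size != predicted.size or observed.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if observed.std() == 0 or predicted.std() == 0:
        raise ValueError("accuracy undefined: zero variance input")
    return float(np.corrcoef(observed, predicted)[0, 1])


def bootstrap_gebv_mean(
    gebvs: np.ndarray, n_boot: int = 1000, conf: float = 0.95, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Percentile bootstrap of the GEBV mean, resampling genotypes."""
    gebvs = np.asarray(gebvs, dtype=float)
    if gebvs.size < 2:
        raise ValueError("need at least 2 GEBVs")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, gebvs.size, size=(n_boot, gebvs.size))
    means = gebvs[idx].mean(axis=1)
    alpha = (1.0 - conf) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(gebvs.mean()), (float(lo), float(hi))


def learning_rate_schedule(
    alpha0: float = 1.0, j_max: int = 9900
) -> tuple[np.ndarray, float]:
    """Hyperbolic decay alpha_j = 100 * alpha0 / (100 + j) for j = 0..j_max."""
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    if j_max < 0:
        raise ValueError("j_max must be >= 0")
    j = np.arange(j_max + 1)
    trace = 100.0 * alpha0 / (100.0 + j)
    return trace, float(trace[-1])


def compare_train_test_means(
    train_gebvs: np.ndarray, test_gebvs: np.ndarray
) -> tuple[float, float, str]:
    """Welch two-sample t-test of H0: equal train/test GEBV means.

    Returns (t, p, stars) with '*' at alpha = 0.05, 'ns' otherwise.
    """
    a = np.asarray(train_gebvs, dtype=float)
    b = np.asarray(test_gebvs, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 GEBVs")
    if np.array_equal(a, b):
        return 0.0, 1.0, "ns"
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), ("*" if p < 0.05 else "ns")


# ---------------------------------------------------------------------------
# Nested cross-validation over the nine models
# ---------------------------------------------------------------------------


def _default_params() -> dict:
    return {
        "BGLR": {"n_iter": 800, "burn_in": 300},
        "SVM": {"C_grid": (1.0, 10.0), "eps_frac_grid": (0.1, 0.5)},
        # constant shrinkage: the epoch-level decay schedule starts at 1.0,
        # which over-steps squared-loss boosting at tree-per-round scale
        "BOOST": {"n_rounds": 60, "max_depth": 2, "use_schedule": False},
        "BAGG": {"n_bags": 40, "max_depth": 3},
        "LASSO": {"cv_folds": None},  # None -> plan.inner_folds
        "STACK": {"epsilon": 0.0},
    }


def _fit_single(
    name: str,
    y: np.ndarray,
    Xc: np.ndarray,
    grm: np.ndarray,
    kern: np.ndarray,
    inner_folds: int,
    params: dict,
    seed: int,
) -> ModelFit:
    """Fit one base model on a training split (hyper-parameters tuned inside)."""
    p = params.get(name, {})
    if name == "rrBLUP":
        return M.fit_rrblup(y, Xc)
    if name == "gBLUP":
        return M.fit_gblup(y, grm)
    if name == "LASSO":
        if "lambda" in p:
            return M.fit_lasso(y, Xc, lambda_=p["lambda"])
        cv = p.get("cv_folds") or inner_folds
        return M.fit_lasso(y, Xc, cv_folds=min(cv, y.size // 3), seed=seed)
    if name == "BGLR":
        return M.fit_bayesian_ridge(
            y, Xc, n_iter=p.get("n_iter", 800), burn_in=p.get("burn_in", 300), seed=seed
        )
    if name == "RKHS":
        return M.fit_rkhs(y, kern)
    if name == "SVM":
        if "fixed" in p:
            return M.fit_svr(y, kern, **p["fixed"])
        return _tune_svr(y, kern, p, inner_folds, seed)
    if name == "BOOST":
        schedule = None
        if p.get("use_schedule", True):
            trace, _ = learning_rate_schedule(1.0, 9900)
            # stage m uses the schedule value at its epoch counter
            schedule = trace[: p.get("n_rounds", 60)]
        return M.fit_boosting(
            y,
            Xc,
            learning_rate=p.get("learning_rate", 0.1),
            n_rounds=p.get("n_rounds", 60),
            max_depth=p.get("max_depth", 2),
            schedule=schedule,
            seed=seed,
        )
    if name == "BAGG":
        return M.fit_bagging(
            y, Xc, n_bags=p.get("n_bags", 40), max_depth=p.get("max_depth", 3), seed=seed
        )
    raise ValueError(f"unknown base model {name!r}")


def _tune_svr(
    y: np.ndarray, kern: np.ndarray, p: dict, inner_folds: int, seed: int
) -> ModelFit:
    """Small inner-CV grid search over (C, epsilon) for kernel SVR."""
    sd = y.std() or 1.0
    grid = [
        {"C": c, "epsilon": f * sd}
        for c in p.get("C_grid", (1.0, 10.0))
        for f in p.get("eps_frac_grid", (0.1, 0.5))
    ]
    if len(grid) == 1:
        best = grid[0]
    else:
        kf = KFold(n_splits=min(inner_folds, y.size // 2), shuffle=True, random_state=seed)
        best, best_mse = None, np.inf
        for g in grid:
            errs = []
            for tr, te in kf.split(y):
                fit = M.fit_svr(y[tr], kern[np.ix_(tr, tr)], **g)
                pred = fit.intercept + M.predict(fit, kern[np.ix_(te, tr)])
                errs.append(np.mean((y[te] - pred) ** 2))
            mse = float(np.mean(errs))
            if mse < best_mse:
                best, best_mse = g, mse
    return M.fit_svr(y, kern, **best)


def _predict_single(
    fit: ModelFit,
    idx_new: np.ndarray,
    idx_tr: np.ndarray,
    Xc: np.ndarray,
    grm: np.ndarray,
    kern: np.ndarray,
) -> np.ndarray:
    """Centered-scale prediction (intercept + GEBV) for held-out genotypes."""
    if fit.model in ("rrBLUP", "LASSO", "BGLR", "BOOST", "BAGG"):
        new = Xc[idx_new]
    elif fit.model in ("gBLUP",):
        new = grm[np.ix_(idx_new, idx_tr)]
    elif fit.model in ("RKHS", "SVM"):
        new = kern[np.ix_(idx_new, idx_tr)]
    else:
        raise ValueError(f"no direct prediction path for {fit.model!r}")
    return fit.intercept + M.predict(fit, new)


def run_nested_cv(
    G: GenotypeMatrix,
    pheno: PhenotypeTable,
    models: tuple[str, ...] = BASE_MODELS + ("STACK",),
    plan: CVPlan | None = None,
    n_levels: tuple[str, ...] = ("LN", "HN"),
    params: dict | None = None,
    n_boot: int = 500,
) -> tuple[EvaluationReport, pd.DataFrame]:
    """Outer 5-fold / inner 10-fold nested CV over the requested models.

    Returns the per model x N level report and the table of held-out
    predictions (one row per genotype x model x N level).
    """
    params = {**_default_params(), **(params or {})}
    plan = (plan or CVPlan()).materialize(G.n_genotypes)
    plan.check_partition(G.n_genotypes)

    Xc = recode_centered(G)
    Xc = Xc - Xc.mean(axis=0)
    grm = build_grm(G.dosage, list(G.genotype_ids)).values
    kern = build_gaussian_kernel(Xc, genotype_ids=list(G.genotype_ids)).values

    base_names = [m for m in models if m != "STACK"]
    want_stack = "STACK" in models
    if want_stack and len(base_names) < 2:
        raise ValueError("STACK needs at least 2 base models")

    rows = []
    pred_rows = []
    for level in n_levels:
        y = pheno.trait(level, list(G.genotype_ids))
        per_model: dict[str, dict] = {
            m: {
                "test_pred": np.full(y.size, np.nan),
                "train_gebvs": [],
                "vcs": [],
                "meta": [],
                "fold_r": [],
            }
            for m in models
        }
        for fold in range(plan.outer_folds):
            te = np.flatnonzero(plan.assignment == fold)
            tr = np.flatnonzero(plan.assignment != fold)
            assert not np.intersect1d(te, tr).size, "train/test folds overlap"
            y_tr = y[tr]
            Xc_tr = Xc[tr]
            grm_tr = grm[np.ix_(tr, tr)]
            kern_tr = kern[np.ix_(tr, tr)]
            seed_fold = plan.seed * 1000 + fold

            fits: dict[str, ModelFit] = {}
            for name in base_names:
                fit = _fit_single(
                    name, y_tr, Xc_tr, grm_tr, kern_tr, plan.inner_folds, params, seed_fold
                )
                fits[name] = fit
                pred = _predict_single(fit, te, tr, Xc, grm, kern)
                per_model[name]["test_pred"][te] = pred
                if np.std(pred) > 0 and np.std(y[te]) > 0:
                    per_model[name]["fold_r"].append(accuracy(y[te], pred))
                per_model[name]["train_gebvs"].append(fit.gebv)
                vc = fit.vc or _fallback_vc(name, y_tr, grm_tr, kern_tr)
                per_model[name]["vcs"].append(vc)
                per_model[name]["meta"].append(fit.training_meta)

            if want_stack:
                stack_fit, stack_pred = _fit_stack_fold(
                    y_tr, tr, te, Xc, grm, kern, base_names, plan, params, seed_fold, fits
                )
                per_model["STACK"]["test_pred"][te] = stack_pred
                if np.std(stack_pred) > 0 and np.std(y[te]) > 0:
                    per_model["STACK"]["fold_r"].append(accuracy(y[te], stack_pred))
                per_model["STACK"]["train_gebvs"].append(stack_fit.gebv)
                per_model["STACK"]["vcs"].append(
                    _fallback_vc("STACK", y_tr, grm_tr, kern_tr)
                )
                per_model["STACK"]["meta"].append(stack_fit.training_meta)

        for name in models:
            d = per_model[name]
            test_pred = d["test_pred"]
            train_gebv_all = np.concatenate(d["train_gebvs"])
            test_gebv = test_pred - np.mean(test_pred)  # GEBV scale, centered
            # accuracy averaged within outer folds: pooling across folds would
            # mix fold intercepts into the correlation and bias the null
            r = float(np.mean(d["fold_r"])) if d["fold_r"] else np.nan
            boot_mean, (blo, bhi) = bootstrap_gebv_mean(
                test_gebv, n_boot=n_boot, seed=plan.seed
            )
            vg = float(np.mean([v.sigma2_a for v in d["vcs"]]))
            ve = float(np.mean([v.sigma2_e for v in d["vcs"]]))
            h2 = float(np.mean([snp_heritability(v) for v in d["vcs"]]))
            t, pval, stars = compare_train_test_means(train_gebv_all, test_gebv)
            lr_min = _lr_summary(name, d["meta"], params)
            rows.append(
                {
                    "model": name,
                    "n_level": level,
                    "snp_h2": h2,
                    "gebv_mean_train": float(train_gebv_all.mean()),
                    "gebv_mean_test": float(test_gebv.mean()),
                    "boot_gebv_mean": boot_mean,
                    "boot_ci_low": blo,
                    "boot_ci_high": bhi,
                    "Vg": vg,
                    "Ve": ve,
                    "accuracy": r,
                    "lr_min": lr_min,
                    "iterations": _iter_summary(name, d["meta"]),
                    "batch_size": int(np.round(y.size * (plan.outer_folds - 1) / plan.outer_folds)),
                    "train_test_t": t,
                    "train_test_p": pval,
                    "signif": stars,
                }
            )
            for i, gid in enumerate(G.genotype_ids):
                pred_rows.append(
                    {
                        "genotype_id": gid,
                        "model": name,
                        "n_level": level,
                        "observed": y[i],
                        "predicted": test_pred[i],
                        "outer_fold": int(plan.assignment[i]),
                    }
                )

    report = EvaluationReport(pd.DataFrame(rows))
    return report, pd.DataFrame(pred_rows)


def _fit_stack_fold(
    y_tr, tr, te, Xc, grm, kern, base_names, plan, params, seed, fits
):
    """Stacked meta-learner for one outer fold.

    Out-of-fold base predictions on the training split come from an inner
    K-fold; the final combination applies the trained base models to the
    held-out genotypes.
    """
    n_tr = y_tr.size
    inner = min(plan.inner_folds, n_tr // 2)
    kf = KFold(n_splits=inner, shuffle=True, random_state=seed)
    oof = np.full((n_tr, len(base_names)), np.nan)
    # reuse the hyper-parameters the outer-fold fits already tuned so the
    # inner loop does no second-level search
    inner_params = dict(params)
    if "LASSO" in fits:
        inner_params["LASSO"] = {"lambda": fits["LASSO"].regularization["lambda"]}
    if "SVM" in fits:
        inner_params["SVM"] = {
            "fixed": {
                "C": fits["SVM"].regularization["C"],
                "epsilon": fits["SVM"].regularization["epsilon"],
            }
        }
    if "BGLR" in fits:
        bp = dict(params.get("BGLR", {}))
        bp["n_iter"] = min(bp.get("n_iter", 800), 400)
        bp["burn_in"] = min(bp.get("burn_in", 300), 150)
        inner_params["BGLR"] = bp
    for itr, ite in kf.split(y_tr):
        for j, name in enumerate(base_names):
            f = _fit_single(
                name,
                y_tr[itr],
                Xc[tr][itr],
                grm[np.ix_(tr[itr], tr[itr])],
                kern[np.ix_(tr[itr], tr[itr])],
                max(2, inner - 1),
                inner_params,
                seed,
            )
            oof[ite, j] = _predict_single(f, tr[ite], tr[itr], Xc, grm, kern)
    base_train = np.column_stack(
        [fits[name].intercept + fits[name].gebv for name in base_names]
    )
    stack = M.fit_stacking(
        oof, y_tr, list(base_names), base_gebvs=base_train,
        epsilon=params.get("STACK", {}).get("epsilon", 0.0),
    )
    base_test = np.column_stack(
        [_predict_single(fits[name], te, tr, Xc, grm, kern) for name in base_names]
    )
    pred = stack.intercept + M.predict(stack, base_test)
    return stack, pred


def _fallback_vc(name, y_tr, grm_tr, kern_tr) -> VarianceComponents:
    """REML components on the model's own input matrix when the fit carries none."""
    K = kern_tr if name in ("SVM", "BOOST", "BAGG", "STACK", "RKHS") else grm_tr
    return M.estimate_variance_components(y_tr, K)


def _lr_summary(name, metas, params) -> float:
    if name == "BOOST":
        traces = [m.get("learning_rate_trace") for m in metas if "learning_rate_trace" in m]
        if traces:
            return float(min(t.min() for t in traces))
    return np.nan


def _iter_summary(name, metas) -> float:
    for key in ("n_iter", "n_rounds", "n_kept_draws"):
        vals = [m[key] for m in metas if key in m]
        if vals:
            return float(np.mean(vals))
    return np.nan
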
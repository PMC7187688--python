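"""Partially-penalized logistic risk models with nested cross-validation.

The risk model minimizes the penalized negative log-likelihood

    (1/n) sum_i { -y_i x_i' beta + log(1 + exp(x_i' beta)) }
        + sum_{l in SNPs} P_lambda(|beta_l|)

where only the SNP coefficients are penalized; the clinical covariates
(and the intercept) are left free. The penalty is the elastic-net family
P_lambda(t) = lambda * (alpha * t + (1 - alpha) * t^2 / 2), with alpha = 1
(lasso), alpha = 0 (ridge) or an intermediate mixing. Optimization is
glmnet-style: an outer quadratic (IRLS) approximation with cyclic
coordinate descent inside, soft-thresholding penalized coordinates, plus a
step-halving safeguard so the exact objective is non-increasing across
outer sweeps.

Model selection follows a nested cross-validation scheme: five stratified
outer folds; within each outer-training set, SNP screening is recomputed
from scratch and a 10-fold inner CV picks (p, penalty, lambda) by mean
validation AUC; the selected model is refit on the whole outer-training set
and scored on the held-out fold. No held-out sample ever enters screening
or tuning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .screening import ScreenCriterion, TopSnpList, screen_cohort, select_top_snps

__all__ = [
    "PenaltySpec",
    "PenalizedModel",
    "CVPlan",
    "CVResult",
    "ExternalValidationResult",
    "fit_penalized_logistic",
    "predict_risk",
    "auc",
    "lambda_grid",
    "fit_lambda_path",
    "make_blup_provider",
    "nested_cv_tune",
    "cross_validate_pipeline",
    "external_validate",
]

_FAMILY_ALPHA = {"lasso": 1.0, "ridge": 0.0, "elastic_net": 0.5}


@dataclass
class PenaltySpec:
    family: str
    lam: float
    alpha: float = 0.5  # elastic-net mixing; ignored for lasso/ridge

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_ALPHA:
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.family == "elastic_net" and not 0.0 < self.alpha < 1.0:
            raise ValueError("elastic-net alpha must be in (0,1)")

    @property
    def mixing(self) -> float:
        if self.family == "elastic_net":
            return self.alpha
        return _FAMILY_ALPHA[self.family]


@dataclass
class PenalizedModel:
    intercept: float
    clinical_coef: np.ndarray
    clinical_names: list[str]
    variant_coef: np.ndarray
    variant_ids: list[str]
    variant_alleles: list[tuple[str, str]]  # (effect, other)
    penalty: PenaltySpec
    converged: bool
    n_sweeps: int
    objective_history: list[float] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def coefficients(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.clinical_coef, self.variant_coef])


@dataclass
class CVPlan:
    n_outer: int = 5
    n_inner: int = 10
    p_grid: tuple[int, ...] = (100, 500, 1000, 5000, 10000, 15000, 20000)
    penalty_grid: tuple[str, ...] = ("lasso", "ridge", "elastic_net")
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    elastic_net_alpha: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outer < 2 or self.n_inner < 2:
            raise ValueError("folds must be >= 2")
        if not self.p_grid or not self.penalty_grid:
            raise ValueError("grids must be non-empty")


@dataclass
class CVResult:
    fold_aucs: list[float]
    mean_auc: float
    sd_auc: float
    selections: list[dict]
    models: list[PenalizedModel]
    screening_lists: list[TopSnpList]
    fold_assignments: np.ndarray


@dataclass
class ExternalValidationResult:
    n_modeled: int
    n_matched: int
    auc: float
    unmatched_log: pd.DataFrame


def model_to_dict(model: PenalizedModel) -> dict:
    """JSON-serializable form carrying everything cross-cohort application needs."""
    return {
        "intercept": model.intercept,
        "clinical_coef": list(map(float, model.clinical_coef)),
        "clinical_names": model.clinical_names,
        "variant_coef": list(map(float, model.variant_coef)),
        "variant_ids": model.variant_ids,
        "variant_alleles": [list(a) for a in model.variant_alleles],
        "penalty": {"family": model.penalty.family, "lambda": model.penalty.lam, "alpha": model.penalty.alpha},
        "converged": model.converged,
        "provenance": model.provenance,
    }


def model_from_dict(d: dict) -> PenalizedModel:
    return PenalizedModel(
        intercept=float(d["intercept"]),
        clinical_coef=np.asarray(d["clinical_coef"], dtype=float),
        clinical_names=list(d["clinical_names"]),
        variant_coef=np.asarray(d["variant_coef"], dtype=float),
        variant_ids=list(d["variant_ids"]),
        variant_alleles=[tuple(a) for a in d["variant_alleles"]],
        penalty=PenaltySpec(d["penalty"]["family"], float(d["penalty"]["lambda"]), float(d["penalty"]["alpha"])),
        converged=bool(d["converged"]),
        n_sweeps=0,
        provenance=d.get("provenance", {}),
    )


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float, alpha: float, mask: np.ndarray) -> float:
    eta = X @ beta
    nll = float(np.mean(-y * eta + np.logaddexp(0.0, eta)))
    b = beta[mask]
    return nll + lam * (alpha * np.abs(b).sum() + 0.5 * (1 - alpha) * (b**2).sum())


def _soft(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


try:  # jit the hot loop; the numpy path below is the reference semantics
    from numba import njit

    @njit(cache=True)
    def _cd_quadratic(Xs, w, r, beta, full_mask, lam, alpha, tol, max_inner):
        n, d1 = Xs.shape
        denom = np.empty(d1)
        for j in range(d1):
            s = 0.0
            for i in range(n):
                s += w[i] * Xs[i, j] * Xs[i, j]
            denom[j] = s / n
        for _it in range(max_inner):
            max_delta = 0.0
            for j in range(d1):
                bj = beta[j]
                rho = 0.0
                for i in range(n):
                    rho += w[i] * Xs[i, j] * r[i]
                rho = rho / n + denom[j] * bj
                if full_mask[j]:
                    t = abs(rho) - lam * alpha
                    num = np.sign(rho) * t if t > 0.0 else 0.0
                    den = denom[j] + lam * (1.0 - alpha)
                else:
                    num = rho
                    den = denom[j]
                new = num / den if den > 0.0 else 0.0
                if new != bj:
                    delta = bj - new
                    for i in range(n):
                        r[i] += Xs[i, j] * delta
                    beta[j] = new
                    if abs(delta) > max_delta:
                        max_delta = abs(delta)
            if max_delta < tol:
                break

except ImportError:  # pragma: no cover - numba is a hard dependency in practice

    def _cd_quadratic(Xs, w, r, beta, full_mask, lam, alpha, tol, max_inner):
        n, d1 = Xs.shape
        denom = (Xs**2 * w[:, None]).mean(axis=0)
        for _it in range(max_inner):
            max_delta = 0.0
            for j in range(d1):
                xj = Xs[:, j]
                bj = beta[j]
                rho = float((w * xj) @ r) / n + denom[j] * bj
                if full_mask[j]:
                    num = _soft(rho, lam * alpha)
                    den = denom[j] + lam * (1 - alpha)
                else:
                    num, den = rho, denom[j]
                new = num / den if den > 0 else 0.0
                if new != bj:
                    r += xj * (bj - new)
                    beta[j] = new
                    max_delta = max(max_delta, abs(new - bj))
            if max_delta < tol:
                break


def _cd_logistic(
    Xs: np.ndarray,
    y: np.ndarray,
    full_mask: np.ndarray,
    lam: float,
    alpha: float,
    beta0: np.ndarray,
    tol: float,
    max_sweeps: int,
) -> tuple[np.ndarray, list[float], bool, int]:
    """IRLS outer loop with cyclic coordinate descent on the quadratic model.

    Step-halving keeps the exact penalized objective non-increasing across
    outer sweeps (the quadratic model can otherwise overshoot).
    """
    d1 = Xs.shape[1]
    beta = beta0.copy()
    obj = _objective(Xs, y, beta, lam, alpha, full_mask)
    history = [obj]
    converged = False
    sweep = 0
    Xs = np.ascontiguousarray(Xs)
    mask_arr = np.ascontiguousarray(full_mask)
    for sweep in range(1, max_sweeps + 1):
        eta = Xs @ beta
        p = _sigmoid(eta)
        w = np.clip(p * (1 - p), 1e-5, None)
        beta_old = beta.copy()
        r = (y - p) / w
        _cd_quadratic(Xs, w, r, beta, mask_arr, lam, alpha, tol, 1000)
        new_obj = _objective(Xs, y, beta, lam, alpha, full_mask)
        step = 1.0
        while new_obj > obj + 1e-12 and step > 1e-6:
            step *= 0.5
            beta = beta_old + step * (beta - beta_old)
            new_obj = _objective(Xs, y, beta, lam, alpha, full_mask)
        history.append(new_obj)
        delta = np.max(np.abs(beta - beta_old))
        obj = new_obj
        if delta < tol:
            converged = True
            break
    return beta, history, converged, sweep


def _standardize_design(X: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n, d = X.shape
    mu = X.mean(axis=0)
    sd = np.ones(d)
    sd[mask] = X[:, mask].std(axis=0)
    sd[sd == 0] = 1.0
    Xs = np.column_stack([np.ones(n), (X - mu) / sd])
    full_mask = np.concatenate([[False], mask])
    return Xs, full_mask, mu, sd


def fit_penalized_logistic(
    X: np.ndarray,
    y: np.ndarray,
    penalty: PenaltySpec,
    penalized_mask: np.ndarray,
    clinical_names: list[str] | None = None,
    variant_ids: list[str] | None = None,
    variant_alleles: list[tuple[str, str]] | None = None,
    max_sweeps: int = 500,
    tol: float = 1e-7,
) -> PenalizedModel:
    """Fit the partially-penalized logistic model by IRLS + coordinate descent.

    ``X`` excludes the intercept (added internally, never penalized);
    ``penalized_mask`` marks the SNP columns of ``X``. Penalized columns are
    standardized internally and coefficients are returned on the original
    scale. Convergence: max absolute coefficient change below ``tol`` on the
    standardized scale; the exact objective is recorded each outer sweep and
    guaranteed non-increasing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate outcome: only one class present")
    n, d = X.shape
    mask = np.asarray(penalized_mask, dtype=bool)
    if mask.shape != (d,):
        raise ValueError("penalized_mask must align with X columns")
    Xs, full_mask, mu, sd = _standardize_design(X, mask)
    beta0 = np.zeros(d + 1)
    beta0[0] = np.log(y.mean() / (1 - y.mean()))
    beta, history, converged, sweep = _cd_logistic(
        Xs, y, full_mask, penalty.lam, penalty.mixing, beta0, tol, max_sweeps
    )
    if not converged:
        warnings.warn(f"penalized logistic fit not converged after {sweep} sweeps")

    # back to the original scale
    coef = beta[1:] / sd
    intercept = beta[0] - float(np.sum(beta[1:] * mu / sd))
    clin_idx = np.flatnonzero(~mask)
    var_idx = np.flatnonzero(mask)
    names = clinical_names or [f"x{j}" for j in clin_idx]
    vids = variant_ids or [f"v{j}" for j in range(var_idx.size)]
    alleles = variant_alleles or [("NA", "NA")] * var_idx.size
    return PenalizedModel(
        intercept=intercept,
        clinical_coef=coef[clin_idx],
        clinical_names=list(names),
        variant_coef=coef[var_idx],
        variant_ids=list(vids),
        variant_alleles=list(alleles),
        penalty=penalty,
        converged=converged,
        n_sweeps=sweep,
        objective_history=history,
    )


def predict_risk(model: PenalizedModel, X: np.ndarray, penalized_mask: np.ndarray | None = None) -> np.ndarray:
    """Inverse-logit risk, columns of ``X`` ordered (clinical..., variants...)."""
    X = np.asarray(X, dtype=float)
    coef = np.concatenate([model.clinical_coef, model.variant_coef])
    if X.shape[1] != coef.size:
        raise ValueError(f"X has {X.shape[1]} columns, model expects {coef.size}")
    return _sigmoid(model.intercept + X @ coef)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random case outscores random control), ties 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: one class absent")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    penalized_mask: np.ndarray,
    family: str,
    n_lambda: int = 50,
    min_ratio: float = 1e-3,
    elastic_net_alpha: float = 0.5,
) -> np.ndarray:
    """Log-spaced lambda grid from the data-driven lambda_max.

    lambda_max is the smallest lambda at which every penalized coefficient
    is zero at the covariate-only solution: max_j |x_j'(y - p0)| / (n alpha)
    over standardized penalized columns, with p0 the covariate-only fitted
    probabilities. Ridge has no finite zeroing lambda; its grid reuses the
    alpha = 1e-3 convention.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    mask = np.asarray(penalized_mask, dtype=bool)
    alpha_eff = max(_FAMILY_ALPHA[family] if family != "elastic_net" else elastic_net_alpha, 1e-3)
    base = fit_penalized_logistic(
        X[:, ~mask], y, PenaltySpec("lasso", 0.0), np.zeros((~mask).sum(), dtype=bool)
    ) if (~mask).any() else None
    if base is not None:
        p0 = predict_risk(base, X[:, ~mask])
    else:
        p0 = np.full(y.size, y.mean())
    Xp = X[:, mask]
    mu, sd = Xp.mean(axis=0), Xp.std(axis=0)
    sd[sd == 0] = 1.0
    Xps = (Xp - mu) / sd
    lam_max = float(np.abs(Xps.T @ (y - p0)).max() / (y.size * alpha_eff))
    lam_max = max(lam_max * (1 + 1e-3), 1e-8)  # nudge past the exact KKT boundary
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def fit_lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    penalized_mask: np.ndarray,
    family: str,
    lams: np.ndarray,
    elastic_net_alpha: float = 0.5,
    tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients along a descending lambda path with warm starts.

    Returns ``(intercepts, coefs)`` on the original scale, one row per
    lambda. Used by the inner tuning loop, where refitting every lambda from
    scratch would dominate the cost.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    mask = np.asarray(penalized_mask, dtype=bool)
    Xs, full_mask, mu, sd = _standardize_design(X, mask)
    alpha = PenaltySpec(family, 0.0, elastic_net_alpha if family == "elastic_net" else 0.5).mixing
    order = np.argsort(lams)[::-1]
    beta = np.zeros(X.shape[1] + 1)
    beta[0] = np.log(y.mean() / (1 - y.mean()))
    intercepts = np.empty(lams.size)
    coefs = np.empty((lams.size, X.shape[1]))
    for k in order:
        beta, _, _, _ = _cd_logistic(Xs, y, full_mask, float(lams[k]), alpha, beta, tol, 200)
        coefs[k] = beta[1:] / sd
        intercepts[k] = beta[0] - float(np.sum(beta[1:] * mu / sd))
    return intercepts, coefs


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(y.size, dtype=int)
    for f, (_, test) in enumerate(skf.split(np.zeros(y.size), y)):
        fold[test] = f
    return fold


def _design(phen: pd.DataFrame, g, ids: list[str], covariates: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(X, penalized_mask) with clinical columns first then SNP dosages."""
    clin = [phen[c].to_numpy(dtype=float) for c in covariates]
    pos = pd.Series(np.arange(g.n_variants), index=g.variants["id"])
    idx = pos[ids].to_numpy()
    G = g.mean_imputed()[:, idx]
    X = np.column_stack(clin + [G]) if clin else G
    mask = np.zeros(X.shape[1], dtype=bool)
    mask[len(clin):] = True
    return X, mask


def nested_cv_tune(
    train_g,
    train_phen: pd.DataFrame,
    plan: CVPlan,
    screen_scores_provider,
    covariates: list[str] = ("age", "sex", "pack_years"),
) -> tuple[dict, pd.DataFrame]:
    """Pick (p, penalty, lambda) by mean inner-CV AUC on the training set.

    ``screen_scores_provider(g, phen)`` must return the training-set variant
    ranking (a TopSnpList covering the largest p in the grid); inner folds
    only tune, per the screening-then-tuning protocol. Ties break toward
    smaller p, then larger lambda (the sparser/simpler model).
    """
    ranking = screen_scores_provider(train_g, train_phen)
    y = train_phen["status"].to_numpy(dtype=float)
    folds = _stratified_folds(y, plan.n_inner, plan.seed)
    rows = []
    best = None
    for p in sorted(plan.p_grid):
        ids = ranking.variant_ids[: min(p, len(ranking.variant_ids))]
        X, mask = _design(train_phen, train_g, ids, list(covariates))
        for family in plan.penalty_grid:
            lams = lambda_grid(
                X, y, mask, family, plan.n_lambda, plan.lambda_min_ratio, plan.elastic_net_alpha
            )
            fold_aucs = np.full((plan.n_inner, lams.size), np.nan)
            for f in range(plan.n_inner):
                tr, va = folds != f, folds == f
                if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
                    warnings.warn(f"inner fold {f} skipped: single-class subset")
                    continue
                icepts, coefs = fit_lambda_path(
                    X[tr], y[tr], mask, family, lams, plan.elastic_net_alpha
                )
                for li in range(lams.size):
                    scores = _sigmoid(icepts[li] + X[va] @ coefs[li])
                    fold_aucs[f, li] = auc(scores, y[va])
            if np.isnan(fold_aucs).all():
                raise RuntimeError("all inner folds skipped (single-class validation sets)")
            mean_aucs = np.nanmean(fold_aucs, axis=0)
            for li, lam in enumerate(lams):
                rows.append(
                    {"p": p, "penalty": family, "lambda": float(lam), "mean_auc": float(mean_aucs[li])}
                )
                cand = (float(mean_aucs[li]), -p, float(lam))
                if best is None or cand > best[0]:
                    best = (cand, {"p": p, "penalty": family, "lambda": float(lam)})
    table = pd.DataFrame(rows)
    sel = dict(best[1])
    sel["mean_inner_auc"] = float(best[0][0])
    return sel, table


def make_blup_provider(criterion_kind: str, max_p: int, screen_covariates=("age", "sex", "height", "pack_years")):
    """Screening provider running GRM/REML/BLUP (or per-SNP OLS) from scratch
    on whatever sample subset it is handed."""

    def provider(g, phen):
        return screen_cohort(
            g, phen, ScreenCriterion(criterion_kind, max_p), list(screen_covariates)
        )

    return provider


def cross_validate_pipeline(
    g,
    phen: pd.DataFrame,
    plan: CVPlan,
    criterion_kind: str = "abs_blup",
    covariates: list[str] = ("age", "sex", "pack_years"),
    screen_covariates: list[str] = ("age", "sex", "height", "pack_years"),
) -> CVResult:
    """Outer 5-fold CV of the full screen-tune-fit-evaluate pipeline.

    Each outer-training set gets its own GRM, REML fit and BLUP ranking
    (falling back to p-value screening if REML lands on the sigma_g2 = 0
    boundary), its own nested tuning, and a refit on the whole training set;
    the held-out fold contributes only its final AUC. Leakage contract: no
    held-out sample influences screening or tuning.
    """
    y = phen["status"].to_numpy(dtype=float)
    outer = _stratified_folds(y, plan.n_outer, plan.seed)
    provider = make_blup_provider(criterion_kind, max(plan.p_grid), screen_covariates)
    fold_aucs, selections, models, lists = [], [], [], []
    for f in range(plan.n_outer):
        tr_idx = np.flatnonzero(outer != f)
        te_idx = np.flatnonzero(outer == f)
        g_tr = g.subset_samples(tr_idx)
        phen_tr = phen.iloc[tr_idx].reset_index(drop=True)
        ranking = provider(g_tr, phen_tr)
        lists.append(ranking)
        inner_plan = CVPlan(
            n_outer=plan.n_outer,
            n_inner=plan.n_inner,
            p_grid=plan.p_grid,
            penalty_grid=plan.penalty_grid,
            n_lambda=plan.n_lambda,
            lambda_min_ratio=plan.lambda_min_ratio,
            elastic_net_alpha=plan.elastic_net_alpha,
            seed=plan.seed + 1000 + f,
        )
        sel, _ = nested_cv_tune(
            g_tr, phen_tr, inner_plan, lambda g_, p_: ranking, covariates=covariates
        )
        ids = ranking.variant_ids[: min(sel["p"], len(ranking.variant_ids))]
        X_tr, mask = _design(phen_tr, g_tr, ids, list(covariates))
        model = fit_penalized_logistic(
            X_tr,
            y[tr_idx],
            PenaltySpec(sel["penalty"], sel["lambda"], plan.elastic_net_alpha),
            mask,
            clinical_names=list(covariates),
            variant_ids=ids,
            variant_alleles=_alleles_for(g_tr, ids),
        )
        model.provenance = {"fold": f, "criterion": ranking.criterion.kind, **sel}
        phen_te = phen.iloc[te_idx].reset_index(drop=True)
        X_te, _ = _design(phen_te, g.subset_samples(te_idx), ids, list(covariates))
        fold_aucs.append(auc(predict_risk(model, X_te), y[te_idx]))
        selections.append(sel)
        models.append(model)
    arr = np.array(fold_aucs)
    return CVResult(
        fold_aucs=fold_aucs,
        mean_auc=float(arr.mean()),
        sd_auc=float(arr.std(ddof=1)),
        selections=selections,
        models=models,
        screening_lists=lists,
        fold_assignments=outer,
    )


def _alleles_for(g, ids: list[str]) -> list[tuple[str, str]]:
    v = g.variants.set_index("id")
    return [(v.loc[i, "allele_effect"], v.loc[i, "allele_other"]) for i in ids]


def external_validate(
    model: PenalizedModel,
    target_g,
    target_phen: pd.DataFrame,
    missing_policy: str = "zero_impute",
    covariates: list[str] | None = None,
) -> ExternalValidationResult:
    """Apply a fitted model to an independent cohort.

    Variants are matched by id and allele pair; a swapped allele pair is
    used with dosages flipped to 2 - dosage. Unmatched model variants
    contribute zero to the linear predictor under either policy
    (``drop_reweight`` drops the terms, ``zero_impute`` scores them as dosage
    zero — numerically identical here, both logged with counts).
    """
    if missing_policy not in ("drop_reweight", "zero_impute"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    covs = list(covariates) if covariates is not None else model.clinical_names
    y = target_phen["status"].to_numpy(dtype=float)
    v = target_g.variants.set_index("id")
    G = target_g.mean_imputed()
    eta = np.full(y.size, model.intercept)
    for name, b in zip(covs, model.clinical_coef):
        eta += b * target_phen[name].to_numpy(dtype=float)
    log_rows = []
    n_matched = 0
    pos = pd.Series(np.arange(target_g.n_variants), index=target_g.variants["id"])
    for vid, (a_eff, a_oth), b in zip(model.variant_ids, model.variant_alleles, model.variant_coef):
        if vid not in v.index:
            log_rows.append({"id": vid, "reason": "absent"})
            continue
        t_eff, t_oth = v.loc[vid, "allele_effect"], v.loc[vid, "allele_other"]
        col = G[:, pos[vid]]
        if (t_eff, t_oth) == (a_eff, a_oth):
            dosage = col
        elif (t_eff, t_oth) == (a_oth, a_eff):
            dosage = 2.0 - col
        else:
            log_rows.append({"id": vid, "reason": "allele_mismatch"})
            continue
        eta += b * dosage
        n_matched += 1
    n_modeled = len(model.variant_ids)
    if n_matched == 0 and n_modeled > 0:
        raise ValueError("no model variants matched the target cohort")
    if n_modeled and n_matched < 0.5 * n_modeled:
        warnings.warn(f"only {n_matched}/{n_modeled} model variants matched the target cohort")
    return ExternalValidationResult(
        n_modeled=n_modeled,
        n_matched=n_matched,
        auc=auc(_sigmoid(eta), y),
        unmatched_log=pd.DataFrame(log_rows, columns=["id", "reason"]),
    )
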
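"""Deviance-based variable-contribution decomposition for the risk model.

The deviance of predicted probabilities ``mu`` against binary outcomes ``y``
is the Bernoulli cross-entropy

    Delta = sum_i -[ y_i log mu_i + (1 - y_i) log(1 - mu_i) ]

(the saturated-model terms vanish for 0/1 outcomes with the 0*log0 = 0
convention; no factor of 2 is applied). The fraction of outcome variability
a model explains is McFadden's pseudo-R^2, (1 - Delta_F/Delta_0) * 100,
against the null (prevalence-only) deviance Delta_0. A variable group's
contribution is the deviance increase when the model is refit without it,
relative to the null: (Delta_i - Delta_F)/Delta_0 * 100. Groups are each
clinical covariate individually plus the SNP block as one unit; removing
the SNP block leaves the covariate-only model.

By default all deviances are out-of-fold: models are fit per CV training
fold (screening recomputed per fold; the tuned (p, penalty, lambda) of the
full model is reused for every reduced refit) and deviances summed over the
held-out predictions of all subjects. An in-sample mode refits on the whole
cohort instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prediction import (
    PenaltySpec,
    _design,
    _sigmoid,
    _stratified_folds,
    fit_penalized_logistic,
    make_blup_provider,
    predict_risk,
)

__all__ = ["DevianceReport", "deviance", "mcfadden_r2", "variable_contributions"]

_CLIP = 1e-12


@dataclass
class DevianceReport:
    delta_null: float
    delta_full: float
    mcfadden_pct: float
    unexplained_pct: float
    contributions: dict[str, float]
    mode: str = "out_of_fold"
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Rows: Unexplained, then one row per variable group."""
        rows = [{"variable": "Unexplained", "pct": self.unexplained_pct}]
        rows += [{"variable": k, "pct": v} for k, v in self.contributions.items()]
        return pd.DataFrame(rows)


def deviance(y: np.ndarray, mu_hat: np.ndarray) -> float:
    """Bernoulli cross-entropy deviance; probabilities clipped to
    [1e-12, 1 - 1e-12] so perfect predictions stay finite."""
    y = np.asarray(y, dtype=float).ravel()
    mu = np.clip(np.asarray(mu_hat, dtype=float).ravel(), _CLIP, 1.0 - _CLIP)
    if y.shape != mu.shape:
        raise ValueError(f"length mismatch: {y.size} labels vs {mu.size} predictions")
    return float(-np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))


def mcfadden_r2(delta_full: float, delta_null: float) -> float:
    """(1 - Delta_F / Delta_0) * 100."""
    if delta_null <= 0:
        raise ValueError("null deviance is zero: single-class outcome")
    return (1.0 - delta_full / delta_null) * 100.0


def variable_contributions(
    g,
    phen: pd.DataFrame,
    best_model_spec: dict,
    n_folds: int = 5,
    seed: int = 0,
    covariates: tuple[str, ...] = ("age", "sex", "pack_years"),
    screen_covariates: tuple[str, ...] = ("age", "sex", "height", "pack_years"),
    mode: str = "out_of_fold",
) -> DevianceReport:
    """Per-variable-group relative deviance contributions.

    ``best_model_spec`` carries the tuned model: keys ``p``, ``penalty``,
    ``lambda``, and optionally ``criterion`` (default abs_blup) and
    ``elastic_net_alpha``. Contributions may come out slightly negative
    (shared deviance between correlated groups; out-of-fold noise) and are
    reported as computed, with a note.
    """
    if mode not in ("out_of_fold", "in_sample"):
        raise ValueError(f"unknown mode {mode!r}")
    y = phen["status"].to_numpy(dtype=float)
    p_keep = int(best_model_spec["p"])
    pen = PenaltySpec(
        best_model_spec["penalty"],
        float(best_model_spec["lambda"]),
        best_model_spec.get("elastic_net_alpha", 0.5),
    )
    criterion = best_model_spec.get("criterion", "abs_blup")
    provider = make_blup_provider(criterion, p_keep, screen_covariates)
    groups = list(covariates) + ["SNPs"]
    notes: list[str] = []

    if mode == "out_of_fold":
        folds = _stratified_folds(y, n_folds, seed)
        fold_iter = [(np.flatnonzero(folds != f), np.flatnonzero(folds == f)) for f in range(n_folds)]
    else:
        idx = np.arange(y.size)
        fold_iter = [(idx, idx)]

    d_null = d_full = 0.0
    d_reduced = {grp: 0.0 for grp in groups}
    for tr_idx, te_idx in fold_iter:
        g_tr, g_te = g.subset_samples(tr_idx), g.subset_samples(te_idx)
        phen_tr = phen.iloc[tr_idx].reset_index(drop=True)
        phen_te = phen.iloc[te_idx].reset_index(drop=True)
        ranking = provider(g_tr, phen_tr)
        ids = ranking.variant_ids[: min(p_keep, len(ranking.variant_ids))]

        prev = np.clip(y[tr_idx].mean(), _CLIP, 1 - _CLIP)
        d_null += deviance(y[te_idx], np.full(te_idx.size, prev))

        def fit_and_predict(covs: list[str], with_snps: bool) -> np.ndarray:
            use_ids = ids if with_snps else []
            if not covs and not use_ids:
                return np.full(te_idx.size, np.clip(y[tr_idx].mean(), _CLIP, 1 - _CLIP))
            X_tr, mask = _design(phen_tr, g_tr, use_ids, covs)
            m = fit_penalized_logistic(X_tr, y[tr_idx], pen, mask)
            X_te, _ = _design(phen_te, g_te, use_ids, covs)
            return predict_risk(m, X_te)

        d_full += deviance(y[te_idx], fit_and_predict(list(covariates), True))
        for grp in groups:
            if grp == "SNPs":
                mu = fit_and_predict(list(covariates), False)
            else:
                mu = fit_and_predict([c for c in covariates if c != grp], True)
            d_reduced[grp] += deviance(y[te_idx], mu)

    mcf = mcfadden_r2(d_full, d_null)
    contributions = {grp: (d_reduced[grp] - d_full) / d_null * 100.0 for grp in groups}
    for grp, v in contributions.items():
        if v < 0:
            notes.append(f"{grp}: negative contribution ({v:.3f}%) reported as computed")
    return DevianceReport(
        delta_null=d_null,
        delta_full=d_full,
        mcfadden_pct=mcf,
        unexplained_pct=100.0 - mcf,
        contributions=contributions,
        mode=mode,
        notes=notes,
    )
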
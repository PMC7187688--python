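"""Genomic mixed model: GRM, REML variance components, SNP BLUP, association.

The screening trait model is

    y ~ MVN(Z beta, sigma_g^2 K + sigma_e^2 I)

with ``K`` the genetic relationship matrix from standardized genotypes and
``Z`` the fixed-effect covariates (intercept, age, sex, height, pack-years).
Single-component REML profiles the restricted likelihood over the
heritability ratio on the eigenbasis of ``K`` (so each evaluation is O(n)
after one eigendecomposition); the multi-component (chromosome-partitioned)
fit uses average-information updates with EM fallback and non-negativity
projection.

Per-SNP BLUP screening scores are ``G' K^-1 (y - Z beta_hat) / sigma_g^2``
with ``G`` the standardized genotype matrix underlying ``K``. The division
by ``sigma_g^2`` is a scale choice only: screening ranks SNPs by absolute
score, and any positive rescaling leaves the ranking unchanged, so these
scores should not be compared in absolute value across tools that scale the
solution differently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GRM",
    "KEig",
    "VarianceComponents",
    "PartitionedVarianceComponents",
    "FixedEffectEstimates",
    "BlupScores",
    "standardize_genotypes",
    "compute_grm",
    "grm_jitter",
    "reml_loglik",
    "reml_fit",
    "reml_fit_partitioned",
    "blup_snp_effects",
    "per_snp_regression",
]


@dataclass
class GRM:
    """Genetic relationship matrix with the ids and variant count behind it."""

    matrix: np.ndarray
    sample_ids: np.ndarray
    n_variants_used: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if not np.isfinite(self.matrix).all():
            raise ValueError("GRM has non-finite entries")


@dataclass
class KEig:
    """Eigendecomposition of a GRM, shared between REML and BLUP."""

    eigvals: np.ndarray
    eigvecs: np.ndarray

    @classmethod
    def from_grm(cls, grm: GRM) -> "KEig":
        w, u = np.linalg.eigh(grm.matrix)
        return cls(np.maximum(w, 0.0), u)


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    se_sigma_g2: float
    se_sigma_e2: float
    loglik: float
    converged: bool
    n_iterations: int


@dataclass
class PartitionedVarianceComponents:
    """Per-component genetic variances from a multi-GRM REML fit."""

    sigma_c2: np.ndarray
    sigma_e2: float
    shares: np.ndarray  # sigma_c2 / sum(sigma_c2)
    h2_total: float
    loglik: float
    converged: bool
    n_iterations: int


@dataclass
class FixedEffectEstimates:
    coefficients: np.ndarray
    names: list[str]


@dataclass
class BlupScores:
    """Per-variant BLUP screening scores.

    ``scale_note`` records that scores are on the G'K^-1 r / sigma_g^2 scale:
    only the absolute-value ranking is meaningful for screening.
    """

    table: pd.DataFrame  # columns: id, chrom, pos, score
    scale_note: str = (
        "scores = G'K^-1(y - Z beta)/sigma_g2 on standardized genotypes; "
        "ranking-valid only, not comparable across scalings"
    )


def standardize_genotypes(
    g, return_index: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Mean-imputed, (g-2p)/sqrt(2p(1-p))-standardized dosage matrix.

    Monomorphic variants cannot be standardized and are excluded with a
    warning; ``return_index`` additionally returns the retained column index.
    """
    vals = g.mean_imputed()
    p = vals.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic variant(s) from standardization")
    vals = vals[:, poly]
    p = p[poly]
    X = (vals - 2 * p) / np.sqrt(2 * p * (1 - p))
    if return_index:
        return X, np.flatnonzero(poly)
    return X


def compute_grm(g) -> GRM:
    """K = (1/m) sum_j x_j x_j' over standardized variants."""
    X, idx = standardize_genotypes(g, return_index=True)
    if idx.size < 1:
        raise ValueError("no polymorphic variants available for a GRM")
    K = X @ X.T / idx.size
    K = (K + K.T) / 2.0
    return GRM(K, g.sample_ids, int(idx.size))


def _rotate(y: np.ndarray, Z: np.ndarray, eig: KEig) -> tuple[np.ndarray, np.ndarray]:
    return eig.eigvecs.T @ y, eig.eigvecs.T @ Z


def reml_loglik(
    y: np.ndarray, Z: np.ndarray, eig: KEig, sigma_g2: float, sigma_e2: float
) -> float:
    """Restricted log-likelihood of (sigma_g2, sigma_e2) given K's eigenbasis."""
    ys, Zs = _rotate(y, Z, eig)
    d = sigma_g2 * eig.eigvals + sigma_e2
    if np.any(d <= 0):
        return -np.inf
    n, q = Z.shape
    ZtViZ = (Zs / d[:, None]).T @ Zs
    sign, logdet_ZtViZ = np.linalg.slogdet(ZtViZ)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(ZtViZ, (Zs / d[:, None]).T @ ys)
    r = ys - Zs @ beta
    quad = float(r @ (r / d))
    _, logdet_ZtZ = np.linalg.slogdet(Z.T @ Z)
    return -0.5 * (
        (n - q) * np.log(2 * np.pi)
        - logdet_ZtZ
        + np.log(d).sum()
        + logdet_ZtViZ
        + quad
    )


def _profile_negloglik(h: float, lam: np.ndarray, ys: np.ndarray, Zs: np.ndarray, logdet_ZtZ: float) -> float:
    """-2x restricted LL profiled over total variance, as a function of h2."""
    n, q = Zs.shape
    d = h * lam + (1.0 - h)
    ZtViZ = (Zs / d[:, None]).T @ Zs
    sign, logdet = np.linalg.slogdet(ZtViZ)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(ZtViZ, (Zs / d[:, None]).T @ ys)
    r = ys - Zs @ beta
    rss = float(r @ (r / d))
    tau = rss / (n - q)
    if tau <= 0:
        return np.inf
    return (n - q) * (np.log(2 * np.pi * tau) + 1.0) - logdet_ZtZ + np.log(d).sum() + logdet


def reml_fit(
    y: np.ndarray,
    Z: np.ndarray,
    K: GRM | np.ndarray,
    eig: KEig | None = None,
    covariate_names: list[str] | None = None,
) -> tuple[VarianceComponents, FixedEffectEstimates]:
    """Single-component REML on the eigenbasis of K.

    Profiles the restricted likelihood over h = sigma_g2/(sigma_g2+sigma_e2)
    in [0, 1), locating the optimum by a coarse grid followed by bounded
    Brent refinement; the boundary h=0 is admissible. Standard errors come
    from the numerical observed information in (sigma_g2, sigma_e2).
    """
    y = np.asarray(y, dtype=float).ravel()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n, q = Z.shape
    if n < q + 2:
        raise ValueError("need n >= q + 2 samples")
    if not np.isfinite(y).all():
        raise ValueError("trait vector must be complete")
    if np.linalg.matrix_rank(Z.T @ Z) < q:
        raise np.linalg.LinAlgError("collinear covariate matrix Z")
    grm = K if isinstance(K, GRM) else GRM(np.asarray(K), np.arange(n).astype(str), 0)
    if eig is None:
        eig = KEig.from_grm(grm)
    ys, Zs = _rotate(y, Z, eig)
    _, logdet_ZtZ = np.linalg.slogdet(Z.T @ Z)
    lam = eig.eigvals

    def nll(h: float) -> float:
        return _profile_negloglik(h, lam, ys, Zs, logdet_ZtZ)

    hs = np.linspace(0.0, 1.0 - 1e-6, 101)
    vals = np.array([nll(h) for h in hs])
    i = int(np.argmin(vals))
    lo = hs[max(i - 1, 0)]
    hi = hs[min(i + 1, len(hs) - 1)]
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12})
    h_hat = float(res.x)
    if nll(0.0) <= res.fun:  # boundary wins
        h_hat = 0.0
    d = h_hat * lam + (1.0 - h_hat)
    ZtViZ = (Zs / d[:, None]).T @ Zs
    beta = np.linalg.solve(ZtViZ, (Zs / d[:, None]).T @ ys)
    r = ys - Zs @ beta
    tau = float(r @ (r / d)) / (n - q)
    sg2, se2 = h_hat * tau, (1.0 - h_hat) * tau
    if 1e-6 < h_hat < 1.0 - 1e-6:
        sg2, se2 = _newton_polish_single(ys, Zs, lam, sg2, se2)
    d = None  # recomputed below from polished components
    dd = sg2 * lam + se2
    ZtViZ = (Zs / dd[:, None]).T @ Zs
    beta = np.linalg.solve(ZtViZ, (Zs / dd[:, None]).T @ ys)
    ll = reml_loglik(y, Z, eig, sg2, se2)
    se_g, se_e = _vc_standard_errors(y, Z, eig, sg2, se2)
    vc = VarianceComponents(
        sigma_g2=sg2,
        sigma_e2=se2,
        h2=sg2 / (sg2 + se2) if sg2 + se2 > 0 else 0.0,
        se_sigma_g2=se_g,
        se_sigma_e2=se_e,
        loglik=ll,
        converged=bool(getattr(res, "success", True)),
        n_iterations=int(getattr(res, "nit", 0)) + len(hs),
    )
    names = covariate_names or [f"z{j}" for j in range(q)]
    return vc, FixedEffectEstimates(beta, names)


def _newton_polish_single(ys, Zs, lam, sg2, se2, max_steps: int = 25):
    """Average-information Newton refinement of (sigma_g2, sigma_e2) in the
    eigenbasis; pins the optimum beyond what a profiled line search resolves."""
    scale = sg2 + se2
    for _ in range(max_steps):
        d = sg2 * lam + se2
        Di = 1.0 / d
        ZD = Zs * Di[:, None]
        M = ZD.T @ Zs
        Minv = np.linalg.inv(M)
        beta = Minv @ (ZD.T @ ys)
        py = (ys - Zs @ beta) * Di  # rotated P y

        def apply_P(v):
            return v * Di - (Zs * Di[:, None]) @ (Minv @ (ZD.T @ v))

        def tr_PK(w):  # w = eigenvalue weights of the kernel (lam or ones)
            t1 = float((w * Di).sum())
            A = (Zs * (w * Di * Di)[:, None]).T @ Zs
            return t1 - float(np.trace(Minv @ A))

        g = np.array(
            [
                -0.5 * (tr_PK(lam) - float(py @ (lam * py))),
                -0.5 * (tr_PK(np.ones_like(lam)) - float(py @ py)),
            ]
        )
        kpy = [lam * py, py]
        pkpy = [apply_P(v) for v in kpy]
        AI = 0.5 * np.array(
            [[float(kpy[i] @ pkpy[j]) for j in range(2)] for i in range(2)]
        )
        try:
            step = np.linalg.solve(AI, g)
        except np.linalg.LinAlgError:
            break
        cand = np.array([sg2, se2]) + step
        if np.any(cand <= 0):
            break
        sg2, se2 = float(cand[0]), float(cand[1])
        if np.max(np.abs(step)) < 1e-13 * scale:
            break
    return sg2, se2


def _vc_standard_errors(y, Z, eig, sg2, se2) -> tuple[float, float]:
    """Numerical observed-information SEs; NaN when the Hessian is singular
    (e.g., at the sigma_g2 = 0 boundary)."""
    scale = max(sg2 + se2, 1e-12)
    h = 1e-5 * scale

    def f(a, b):
        return reml_loglik(y, Z, eig, max(a, 1e-12 * scale), max(b, 1e-12 * scale))

    try:
        H = np.empty((2, 2))
        f0 = f(sg2, se2)
        H[0, 0] = (f(sg2 + h, se2) - 2 * f0 + f(sg2 - h, se2)) / h**2
        H[1, 1] = (f(sg2, se2 + h) - 2 * f0 + f(sg2, se2 - h)) / h**2
        H[0, 1] = H[1, 0] = (
            f(sg2 + h, se2 + h) - f(sg2 + h, se2 - h) - f(sg2 - h, se2 + h) + f(sg2 - h, se2 - h)
        ) / (4 * h**2)
        cov = np.linalg.inv(-H)
        if np.any(np.diag(cov) < 0):
            return float("nan"), float("nan")
        return float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        return float("nan"), float("nan")


def reml_fit_partitioned(
    y: np.ndarray,
    Z: np.ndarray,
    grms: list[GRM],
    max_iter: int = 200,
    tol: float = 1e-10,
) -> PartitionedVarianceComponents:
    """Multi-component REML: V = sum_c sigma_c^2 K_c + sigma_e^2 I.

    Average-information updates with EM fallback when an AI step leaves the
    feasible region or decreases the restricted likelihood; components are
    projected onto the non-negative orthant (tiny floor for numerical
    stability). Converges when successive restricted log-likelihoods differ
    by less than ``tol``.
    """
    y = np.asarray(y, dtype=float).ravel()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n, q = Z.shape
    if len(grms) < 1:
        raise ValueError("need at least one genetic component")
    ids0 = grms[0].sample_ids
    for g_ in grms[1:]:
        if g_.matrix.shape != grms[0].matrix.shape or not np.array_equal(g_.sample_ids, ids0):
            raise ValueError("component GRMs must cover identical samples")
    Ks = [g_.matrix for g_ in grms] + [np.eye(n)]
    c = len(Ks)
    vy = float(np.var(y))
    theta = np.full(c, vy / c)
    floor = 1e-10 * vy

    def loglik_and_P(th):
        V = sum(t * Kc for t, Kc in zip(th, Ks))
        try:
            Vi = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            return -np.inf, None, None
        ZtViZ = Z.T @ Vi @ Z
        sign1, ld_V = np.linalg.slogdet(V)
        sign2, ld_Z = np.linalg.slogdet(ZtViZ)
        if sign1 <= 0 or sign2 <= 0:
            return -np.inf, None, None
        ZtViZ_inv = np.linalg.inv(ZtViZ)
        P = Vi - Vi @ Z @ ZtViZ_inv @ Z.T @ Vi
        _, ld_ZtZ = np.linalg.slogdet(Z.T @ Z)
        ll = -0.5 * ((n - q) * np.log(2 * np.pi) - ld_ZtZ + ld_V + ld_Z + float(y @ P @ y))
        return ll, P, Vi

    ll, P, _ = loglik_and_P(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Py = P @ y
        KPy = [Kc @ Py for Kc in Ks]
        grad = np.array(
            [-0.5 * (np.trace(P @ Kc) - float(Py @ KPy[i])) for i, Kc in enumerate(Ks)]
        )
        theta_prev = theta.copy()
        PKPy = [P @ v for v in KPy]
        AI = 0.5 * np.array([[float(KPy[i] @ PKPy[j]) for j in range(c)] for i in range(c)])
        step = None
        try:
            step = np.linalg.solve(AI, grad)
        except np.linalg.LinAlgError:
            pass
        accepted = False
        if step is not None:
            for damp in (1.0, 0.5, 0.25, 0.1):
                cand = np.maximum(theta + damp * step, floor)
                ll_new, P_new, _ = loglik_and_P(cand)
                if ll_new >= ll - 1e-12:
                    theta, ll_cand, P = cand, ll_new, P_new
                    accepted = True
                    break
        if not accepted:
            # EM step: always increases the restricted likelihood
            cand = np.array(
                [
                    max(
                        theta[i]
                        + theta[i] ** 2 * (float(Py @ KPy[i]) - np.trace(P @ Ks[i])) / n,
                        floor,
                    )
                    for i in range(c)
                ]
            )
            ll_new, P_new, _ = loglik_and_P(cand)
            if ll_new == -np.inf:
                break
            theta, P = cand, P_new
        else:
            ll_new = ll_cand
        step_size = np.max(np.abs(theta - theta_prev))
        if abs(ll_new - ll) < tol and step_size < 1e-10 * max(vy, 1e-12):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    # tail polish: undamped AI (Fisher-scoring) Newton steps on the analytic
    # gradient; near the optimum the quadratic convergence pins the solution
    # more precisely than ll-based line searches, whose comparisons are
    # limited by evaluation noise
    interior = theta > 10 * floor
    if interior.all():
        for _polish in range(30):
            ll_p, P, _ = loglik_and_P(theta)
            if P is None:
                break
            Py = P @ y
            KPy = [Kc @ Py for Kc in Ks]
            grad = np.array(
                [-0.5 * (np.trace(P @ Kc) - float(Py @ KPy[i])) for i, Kc in enumerate(Ks)]
            )
            PKPy = [P @ v for v in KPy]
            AI = 0.5 * np.array(
                [[float(KPy[i] @ PKPy[j]) for j in range(c)] for i in range(c)]
            )
            try:
                step = np.linalg.solve(AI, grad)
            except np.linalg.LinAlgError:
                break
            cand = theta + step
            if np.any(cand < floor):
                break
            theta = cand
            it += 1
            if np.max(np.abs(step)) < 1e-13 * max(vy, 1e-12):
                converged = True
                break
        ll_p, _, _ = loglik_and_P(theta)
        if np.isfinite(ll_p):
            ll = ll_p
    sigma_c2 = np.maximum(theta[:-1], 0.0)
    sigma_c2[sigma_c2 <= 2 * floor] = 0.0
    sigma_e2 = float(theta[-1])
    total_g = float(sigma_c2.sum())
    shares = sigma_c2 / total_g if total_g > 0 else np.zeros_like(sigma_c2)
    return PartitionedVarianceComponents(
        sigma_c2=sigma_c2,
        sigma_e2=sigma_e2,
        shares=shares,
        h2_total=total_g / (total_g + sigma_e2) if total_g + sigma_e2 > 0 else 0.0,
        loglik=float(ll),
        converged=converged,
        n_iterations=it,
    )


def grm_jitter(eigvals: np.ndarray) -> float:
    """Ridge added to K before inversion: 1e-6 * trace(K)/n when the
    smallest eigenvalue is below 1e-10, else 0. Column-centered GRMs are
    always singular (the ones vector is a null eigenvector), so the jitter
    is the rule rather than the exception; 1e-6 keeps the condition number
    low enough that dense solves retain ~10 significant digits while
    perturbing the screening scores negligibly."""
    return 1e-6 * eigvals.sum() / eigvals.size if eigvals.min() < 1e-10 else 0.0


def blup_snp_effects(
    g,
    K: GRM,
    y: np.ndarray,
    Z: np.ndarray,
    fit: tuple[VarianceComponents, FixedEffectEstimates],
    eig: KEig | None = None,
) -> BlupScores:
    """Per-SNP BLUP screening scores G' K^-1 (y - Z beta_hat) / sigma_g2.

    Uses the same standardized genotype matrix that built K; K^-1 acts
    through the eigendecomposition, with a ridge jitter of
    1e-8 * trace(K)/n added when the smallest eigenvalue falls below 1e-10.
    """
    vc, fe = fit
    if vc.sigma_g2 <= 0:
        raise ValueError(
            "sigma_g2 is at the zero boundary; BLUP screening is undefined - use p-value screening"
        )
    y = np.asarray(y, dtype=float).ravel()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if eig is None:
        eig = KEig.from_grm(K)
    X, idx = standardize_genotypes(g, return_index=True)
    r = y - Z @ fe.coefficients
    jitter = grm_jitter(eig.eigvals)
    K_reg = K.matrix + jitter * np.eye(K.matrix.shape[0]) if jitter else K.matrix
    Kinv_r = np.linalg.solve(K_reg, r)
    scores = (X.T @ Kinv_r) / vc.sigma_g2
    table = pd.DataFrame(
        {
            "id": g.variants["id"].to_numpy()[idx],
            "chrom": g.variants["chrom"].to_numpy()[idx],
            "pos": g.variants["pos"].to_numpy()[idx],
            "score": scores,
        }
    )
    return BlupScores(table)


def per_snp_regression(g, y: np.ndarray, Z: np.ndarray) -> pd.DataFrame:
    """Single-SNP OLS of the trait on (Z, genotype), all variants at once.

    Returns a DataFrame (id, chrom, pos, beta, se, p) with the two-sided
    t-test p-value on the genotype coefficient. Computed by projecting the
    covariates out of both the trait and every dosage column (equivalent to
    the joint OLS by Frisch-Waugh-Lovell).
    """
    y = np.asarray(y, dtype=float).ravel()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n, q = Z.shape
    if n < q + 2:
        raise ValueError("insufficient samples for per-SNP regression")
    if np.linalg.matrix_rank(Z.T @ Z) < q:
        raise np.linalg.LinAlgError("collinear covariate matrix Z")
    G = g.mean_imputed()
    Q, _ = np.linalg.qr(Z)
    y_res = y - Q @ (Q.T @ y)
    G_res = G - Q @ (Q.T @ G)
    gg = (G_res**2).sum(axis=0)
    gg_safe = np.where(gg > 0, gg, np.nan)
    beta = (G_res.T @ y_res) / gg_safe
    df = n - q - 1
    rss = float(y_res @ y_res) - beta**2 * gg_safe
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.maximum(rss, 0.0) / df / gg_safe)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isnan(p), 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    return pd.DataFrame(
        {
            "id": g.variants["id"],
            "chrom": g.variants["chrom"],
            "pos": g.variants["pos"],
            "beta": np.where(np.isnan(beta), 0.0, beta),
            "se": se,
            "p": p,
        }
    )
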
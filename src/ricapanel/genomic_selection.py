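"""Genomic prediction: phenotype adjustment, relationship matrices,
ridge/GBLUP, the Bayesian alphabet, a two-kernel G+A model, pedigree BLUP,
and family-stratified cross-validation.

Phenotypes follow the plot model Y_ijk = mu + g_i + t_j + r(t)_jk + e_ijk
(genotype, trial, replicate-within-trial).  Variance components come from
EM-REML on Henderson's mixed-model equations; accession-mean heritability
uses H^2 = s2_g / (s2_g + s2_gy/t + s2_e/(t r)) with t the mean number of
trials per accession and r the mean plots per accession per trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import _gibbs
from .core import GenotypeError, GenotypeMatrix, Pedigree
from .diversity import imputed_dosage


# ---------------------------------------------------------------------------
# phenotype plumbing
# ---------------------------------------------------------------------------

def grain_yield(weight_g: float, area_m2: float = 3.12, mc_pct: float = 14.0) -> float:
    """Grain yield in t/ha from plot grain weight, harvested area and
    moisture content, standardized to 14% moisture:
    ((100 - MC)/86) x (weight_g / area_m2) x 0.01."""
    if mc_pct >= 100 or mc_pct < 0:
        raise ValueError(f"moisture content must lie in [0, 100), got {mc_pct}")
    if area_m2 <= 0:
        raise ValueError("harvested area must be positive")
    return ((100.0 - mc_pct) / 86.0) * (weight_g / area_m2) * 0.01


@dataclass
class VarianceComponents:
    """REML variance components of the plot model plus the trial structure."""

    sigma_g2: float
    sigma_t2: float
    sigma_rt2: float
    sigma_e2: float
    sigma_gy2: float = 0.0
    t: float = 1.0  # mean trials per accession
    r: float = 1.0  # mean plots per accession per trial
    converged: bool = True
    n_iter: int = 0


def _design(values: pd.Series) -> tuple[np.ndarray, list]:
    levels, codes = np.unique(values.to_numpy(), return_inverse=True)
    Z = np.zeros((len(values), len(levels)))
    Z[np.arange(len(values)), codes] = 1.0
    return Z, list(levels)


def _em_reml(
    y: np.ndarray,
    X: np.ndarray,
    Zs: list[np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> tuple[np.ndarray, list[np.ndarray], list[float], float, bool, int]:
    """EM-REML for y = Xb + sum_k Z_k u_k + e with independent factors.

    Returns (b, [u_k], [sigma_k^2], sigma_e^2, converged, n_iter).
    """
    n, p = X.shape
    qs = [Z.shape[1] for Z in Zs]
    var_y = float(np.var(y)) or 1.0
    comps = [0.1 * var_y for _ in Zs]
    sig_e = 0.5 * var_y
    Z = np.hstack(Zs) if Zs else np.zeros((n, 0))
    W = np.hstack([X, Z])
    WtW = W.T @ W
    Wty = W.T @ y
    rank_x = np.linalg.matrix_rank(X)
    floor = 1e-10 * var_y

    b = np.zeros(p)
    us: list[np.ndarray] = [np.zeros(q) for q in qs]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        C = WtW.copy()
        off = p
        for q, s_k in zip(qs, comps):
            lam = sig_e / max(s_k, floor)
            C[off:off + q, off:off + q] += lam * np.eye(q)
            off += q
        Cinv = np.linalg.pinv(C)
        sol = Cinv @ Wty
        b = sol[:p]
        new_comps = []
        off = p
        for q, s_k in zip(qs, comps):
            u_k = sol[off:off + q]
            tr = np.trace(Cinv[off:off + q, off:off + q])
            new_comps.append(max((float(u_k @ u_k) + sig_e * tr) / q, floor))
            off += q
        us = []
        off = p
        for q in qs:
            us.append(sol[off:off + q])
            off += q
        resid = y - W @ sol
        new_sig_e = max(float(y @ resid) / (n - rank_x), floor)
        # EM drags boundary components to zero only at O(1/k); once a
        # component falls below a negligible share of var(y), pin it to the
        # floor and stop counting it toward convergence
        zero_thresh = 1e-3 * var_y
        new_comps = [floor if c < zero_thresh else c for c in new_comps]
        rel = max(
            [
                abs(a - b_) / max(abs(b_), floor)
                for a, b_ in zip(new_comps, comps)
                if not (a == floor and b_ <= zero_thresh)
            ]
            + [abs(new_sig_e - sig_e) / max(sig_e, floor)]
        )
        comps, sig_e = new_comps, new_sig_e
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM-REML did not converge in {max_iter} iterations", stacklevel=2)
    return b, us, comps, sig_e, converged, it


def fit_mixed(
    plots: pd.DataFrame,
    genotype_as: str = "fixed",
) -> tuple[pd.Series, VarianceComponents]:
    """Fit Y = mu + g + t + r(t) + e by EM-REML.

    ``genotype_as="fixed"`` yields BLUEs (adjusted genotype means, cell-means
    coding); ``"random"`` yields BLUPs (mu + shrunken genotype effects).
    Trial and replicate-within-trial are always random.
    """
    if genotype_as not in ("fixed", "random"):
        raise ValueError("genotype_as must be 'fixed' or 'random'")
    req = {"genotype", "trial", "rep", "value"}
    if not req.issubset(plots.columns):
        raise ValueError(f"plots table needs columns {sorted(req)}")
    df = plots.dropna(subset=["value"]).reset_index(drop=True)
    if df["genotype"].nunique() < 2:
        raise ValueError("need at least two genotypes")
    if (df.groupby("trial").size() == 0).any() or df["trial"].nunique() < 1:
        raise ValueError("empty trial")
    y = df["value"].to_numpy(dtype=float)

    Zg, genos = _design(df["genotype"])
    Zt, _ = _design(df["trial"])
    rep_key = df["trial"].astype(str) + "//" + df["rep"].astype(str)
    Zr, _ = _design(rep_key)

    n_trial_per_geno = df.groupby("genotype")["trial"].nunique()
    t_mean = float(n_trial_per_geno.mean())
    r_mean = float(
        df.groupby(["genotype", "trial"]).size().groupby("genotype").mean().mean()
    )

    if genotype_as == "fixed":
        b, us, comps, sig_e, conv, it = _em_reml(y, Zg, [Zt, Zr])
        estimates = pd.Series(b, index=genos, name="BLUE")
        vc = VarianceComponents(
            sigma_g2=float(np.var(estimates.to_numpy(), ddof=1)),
            sigma_t2=comps[0],
            sigma_rt2=comps[1],
            sigma_e2=sig_e,
            t=t_mean,
            r=r_mean,
            converged=conv,
            n_iter=it,
        )
    else:
        X = np.ones((len(df), 1))
        b, us, comps, sig_e, conv, it = _em_reml(y, X, [Zg, Zt, Zr])
        estimates = pd.Series(b[0] + us[0], index=genos, name="BLUP")
        vc = VarianceComponents(
            sigma_g2=comps[0],
            sigma_t2=comps[1],
            sigma_rt2=comps[2],
            sigma_e2=sig_e,
            t=t_mean,
            r=r_mean,
            converged=conv,
            n_iter=it,
        )
    return estimates, vc


def heritability(vc: VarianceComponents, t: float | None = None, r: float | None = None) -> float:
    """Broad-sense heritability of accession means.

    The genotype-by-trial component defaults to 0 when the fitted model
    omitted the interaction term.
    """
    t = vc.t if t is None else t
    r = vc.r if r is None else r
    denom = vc.sigma_g2 + vc.sigma_gy2 / t + vc.sigma_e2 / (t * r)
    if denom <= 0:
        raise ValueError("heritability undefined: zero denominator")
    return vc.sigma_g2 / denom


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------

def grm(gm: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """VanRaden-style genomic relationship matrix.

    G = W W' / (2 sum p_j (1 - p_j)) with W the column-centered dosage
    matrix and p_j the observed alternate-allele frequency.  Missing calls
    must be imputed first (column-mean fallback applied with a warning).
    """
    if isinstance(gm, GenotypeMatrix):
        dose = gm.dosage()
    else:
        dose = np.asarray(gm, dtype=float)
    if np.isnan(dose).any():
        warnings.warn("missing dosages mean-imputed before G construction", stacklevel=2)
        mu = np.nanmean(dose, axis=0)
        idx = np.nonzero(np.isnan(dose))
        dose[idx] = mu[idx[1]]
    p = dose.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise GenotypeError("all markers monomorphic: G undefined")
    W = dose - 2.0 * p[None, :]
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    return (W @ W.T) / denom


def a_matrix(ped: Pedigree) -> pd.DataFrame:
    """Additive (numerator) relationship matrix by the tabular method."""
    ids = ped.ids
    idx = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for i, (ind, sire, dam) in enumerate(ped.entries):
        s = idx.get(sire) if sire is not None else None
        d = idx.get(dam) if dam is not None else None
        A[i, i] = 1.0 + (0.5 * A[s, d] if s is not None and d is not None else 0.0)
        for j in range(i):
            val = 0.0
            if s is not None:
                val += 0.5 * A[j, s]
            if d is not None:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return pd.DataFrame(A, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# ridge / GBLUP
# ---------------------------------------------------------------------------

@dataclass
class RidgeResult:
    """Single-kernel GBLUP fit: GEBVs for every sample in the kernel."""

    gebv: pd.Series
    mu: float
    sigma_u2: float
    sigma_e2: float
    log_reml: float


def _reml_loglik(lam: float, s: np.ndarray, Uty: np.ndarray, Utx: np.ndarray) -> float:
    """Restricted log-likelihood of y = Xb + u + e with u ~ N(0, lam K
    sigma_e^2), profiled over b and sigma_e^2, in the kernel eigenbasis."""
    d = lam * s + 1.0
    n, p = Uty.shape[0], Utx.shape[1]
    XtVX = (Utx.T / d) @ Utx
    XtVy = (Utx.T / d) @ Uty
    b = np.linalg.solve(XtVX, XtVy)
    r = Uty - Utx @ b
    quad = float(r.T / d @ r)
    sig_e = quad / (n - p)
    _, ld_xvx = np.linalg.slogdet(XtVX)
    return -0.5 * (
        (n - p) * np.log(sig_e) + np.sum(np.log(d)) + ld_xvx + (n - p)
    )


def fit_ridge(
    y: pd.Series,
    kernel: pd.DataFrame | np.ndarray,
    sample_order: Sequence[str] | None = None,
    tol: float = 1e-8,
) -> RidgeResult:
    """GBLUP via REML with a spectral decomposition of the training kernel.

    ``y`` holds training phenotypes indexed by sample; ``kernel`` covers all
    samples (training plus candidates).  The variance ratio is found by
    scalar optimization of the restricted likelihood; GEBVs for untested
    samples come from the kernel cross-block.
    """
    if isinstance(kernel, pd.DataFrame):
        all_samples = list(kernel.index)
        K = kernel.to_numpy(dtype=float)
    else:
        K = np.asarray(kernel, dtype=float)
        all_samples = list(sample_order) if sample_order is not None else [str(i) for i in range(len(K))]
    pos = {s: i for i, s in enumerate(all_samples)}
    train = [s for s in y.index if s in pos]
    if y.isna().any():
        raise ValueError("missing phenotypes in training set")
    ti = np.array([pos[s] for s in train])
    Ktt = K[np.ix_(ti, ti)]
    yv = y.loc[train].to_numpy(dtype=float)

    s_eig, U = np.linalg.eigh(Ktt)
    if s_eig.min() < -1e-6:
        raise GenotypeError("kernel is not positive semidefinite")
    s_eig = np.clip(s_eig, 0.0, None)
    Uty = U.T @ yv
    Utx = U.T @ np.ones((len(yv), 1))

    res = minimize_scalar(
        lambda loglam: -_reml_loglik(np.exp(loglam), s_eig, Uty, Utx),
        bounds=(-12.0, 12.0),
        method="bounded",
        options={"xatol": tol},
    )
    lam = float(np.exp(res.x))
    d = lam * s_eig + 1.0
    XtVX = (Utx.T / d) @ Utx
    XtVy = (Utx.T / d) @ Uty
    mu = float(np.linalg.solve(XtVX, XtVy).item())
    r = Uty - Utx[:, 0] * mu
    sig_e = float(r / d @ r) / (len(yv) - 1)
    sig_u = lam * sig_e

    # BLUP for all samples: u = lam * K[:, train] @ Vinv @ (y - mu)
    vinv_r = U @ (r.ravel() / d)
    u_all = lam * (K[:, ti] @ vinv_r)
    gebv = pd.Series(mu + u_all, index=all_samples, name="GEBV")
    return RidgeResult(gebv=gebv, mu=mu, sigma_u2=sig_u, sigma_e2=sig_e, log_reml=-res.fun)


# ---------------------------------------------------------------------------
# Bayesian whole-genome regression
# ---------------------------------------------------------------------------

@dataclass
class GSModelSpec:
    """A genomic-prediction model family with its sampler settings.

    Bayesian hyperpriors follow the conventional whole-genome-regression
    defaults: degrees of freedom 5 and scales chosen so the prior explains
    R2 = 0.5 of the phenotypic variance.
    """

    family: str  # RIDGE | BAYES_A | BAYES_B | BAYES_C | BAYES_L | RKHS_G_A | PEDIGREE_BLUP
    iterations: int = 12000
    burn_in: int = 2000
    thin: int = 5
    df0: float = 5.0
    r2: float = 0.5
    pi_init: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        families = {"RIDGE", "BAYES_A", "BAYES_B", "BAYES_C", "BAYES_L", "RKHS_G_A", "PEDIGREE_BLUP"}
        if self.family not in families:
            raise ValueError(f"unknown family {self.family}; choose from {sorted(families)}")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")


@dataclass
class BayesResult:
    """Posterior summaries of a whole-genome regression fit."""

    effects: np.ndarray
    mu: float
    gebv: pd.Series
    varE_trace: np.ndarray
    pi_mean: float | None = None

    def save_trace(self, path: str) -> None:
        np.savetxt(path, self.varE_trace, fmt="%.8g")


def fit_bayes(
    y: pd.Series,
    dosages: pd.DataFrame | np.ndarray,
    spec: GSModelSpec,
    predict_for: pd.DataFrame | np.ndarray | None = None,
) -> BayesResult:
    """Single-site Gibbs whole-genome regression (BayesA/B/C and the
    Bayesian lasso).

    BayesA places a scaled-inverse-chi-square variance on every marker;
    BayesB combines those per-marker variances with a point mass at zero;
    BayesC uses a shared slab variance with a point mass; the Bayesian
    lasso gives each effect an exponential-mixing normal (double
    exponential marginal).  The residual-variance trace of the thinned
    chain is retained for convergence inspection.
    """
    if spec.family not in {"BAYES_A", "BAYES_B", "BAYES_C", "BAYES_L"}:
        raise ValueError(f"fit_bayes does not handle family {spec.family}")
    if isinstance(dosages, pd.DataFrame):
        train_names = list(y.index)
        X = dosages.loc[train_names].to_numpy(dtype=float)
    else:
        X = np.asarray(dosages, dtype=float)
        train_names = list(y.index)
    if np.isnan(X).any():
        raise ValueError("dosage matrix must be complete (impute first)")
    yv = y.to_numpy(dtype=float)
    n, m = X.shape
    X = np.asfortranarray(X)
    xtx = np.einsum("ij,ij->j", X, X)
    xtx = np.where(xtx > 0, xtx, 1e-12)

    rng = np.random.default_rng(spec.seed)
    vy = float(np.var(yv)) or 1.0
    msx = float(np.sum(X.var(axis=0))) or 1.0
    df0, r2 = spec.df0, spec.r2
    S0 = r2 * vy / msx * (df0 + 2)  # slab/per-marker scale
    dfe0 = 5.0
    Se = vy * (1 - r2) * (dfe0 + 2)

    mu = float(yv.mean())
    beta = np.zeros(m)
    var_beta = np.full(m, S0 / (df0 + 2))
    incl = np.ones(m, dtype=np.int8)
    pi = spec.pi_init
    sigma_e2 = vy * (1 - r2)
    tau2 = np.full(m, 1.0)  # lasso mixing variances
    lam2 = 2.0 * msx / vy  # lasso penalty^2, updated by its Gamma conditional
    e = yv - mu - X @ (beta * (incl if spec.family in ("BAYES_B", "BAYES_C") else 1))

    keep = max((spec.iterations - spec.burn_in) // spec.thin, 1)
    beta_sum = np.zeros(m)
    mu_sum = 0.0
    pi_sum = 0.0
    var_trace = []
    kept = 0

    mixture = spec.family in ("BAYES_B", "BAYES_C")
    for it in range(spec.iterations):
        # intercept
        e += mu
        mu = float(e.mean()) + rng.standard_normal() * np.sqrt(sigma_e2 / n)
        e -= mu

        z = rng.standard_normal(m)
        if mixture:
            u = rng.random(m)
            n_in = _gibbs.sweep_mixture(X, xtx, e, beta, var_beta, sigma_e2, pi, incl, z, u)
            pi = rng.beta(1.0 + n_in, 1.0 + m - n_in)
        else:
            _gibbs.sweep_dense(X, xtx, e, beta, var_beta, sigma_e2, z)

        # effect-variance updates
        if spec.family in ("BAYES_A", "BAYES_B"):
            var_beta = (beta**2 + S0) / rng.chisquare(df0 + 1.0, size=m)
        elif spec.family == "BAYES_C":
            active = incl.astype(bool)
            k = int(active.sum())
            ssb = float(np.sum(beta[active] ** 2))
            shared = (ssb + S0) / rng.chisquare(df0 + k)
            var_beta = np.full(m, shared)
        else:  # BAYES_L
            b2 = np.maximum(beta**2, 1e-12)
            inv_tau2 = rng.wald(np.sqrt(lam2 * sigma_e2 / b2), lam2)
            tau2 = 1.0 / np.maximum(inv_tau2, 1e-12)
            lam2 = rng.gamma(m + 1.0, 1.0 / (0.5 * np.sum(tau2) + 1e-8))
            var_beta = sigma_e2 * tau2

        if not np.all(np.isfinite(beta)):
            raise FloatingPointError(f"divergent chain at iteration {it}")
        sigma_e2 = (float(e @ e) + Se) / rng.chisquare(n + dfe0)

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            beta_eff = beta * incl if mixture else beta
            beta_sum += beta_eff
            mu_sum += mu
            pi_sum += pi
            var_trace.append(sigma_e2)
            kept += 1

    beta_mean = beta_sum / kept
    mu_mean = mu_sum / kept
    if predict_for is None:
        Xp, names = X, train_names
    elif isinstance(predict_for, pd.DataFrame):
        names = list(predict_for.index)
        Xp = predict_for.to_numpy(dtype=float)
    else:
        Xp = np.asarray(predict_for, dtype=float)
        names = [str(i) for i in range(len(Xp))]
    gebv = pd.Series(mu_mean + Xp @ beta_mean, index=names, name="GEBV")
    return BayesResult(
        effects=beta_mean,
        mu=mu_mean,
        gebv=gebv,
        varE_trace=np.array(var_trace),
        pi_mean=pi_sum / kept if mixture else None,
    )


def fit_rkhs_g_a(
    y: pd.Series,
    G: pd.DataFrame,
    A: pd.DataFrame,
    spec: GSModelSpec,
) -> BayesResult:
    """Two-kernel Bayesian model y = 1 mu + g + a + e with g ~ N(0, G s2_g)
    and a ~ N(0, A s2_a), Gibbs-sampled in each kernel's eigenbasis.

    GEBV = posterior mean of mu + g + a over all samples in the kernels;
    training samples are ``y``'s index.
    """
    all_samples = list(G.index)
    if list(A.index) != all_samples:
        A = A.loc[all_samples, all_samples]
    train = list(y.index)
    ti = np.array([all_samples.index(s) for s in train])
    yv = y.to_numpy(dtype=float)
    n = len(ti)
    rng = np.random.default_rng(spec.seed)

    kernels = []
    for K in (G, A):
        Kt = K.to_numpy(dtype=float)[np.ix_(ti, ti)]
        s_eig, U = np.linalg.eigh(Kt)
        keep = s_eig > 1e-8 * s_eig.max()
        kernels.append((U[:, keep], s_eig[keep], K.to_numpy(dtype=float)[:, ti]))

    vy = float(np.var(yv)) or 1.0
    df0 = spec.df0
    Sk = spec.r2 * vy / len(kernels) * (df0 + 2)
    dfe0 = 5.0
    Se = vy * (1 - spec.r2) * (dfe0 + 2)

    mu = float(yv.mean())
    gammas = [np.zeros(U.shape[1]) for U, _, _ in kernels]
    sig_k = [spec.r2 * vy / len(kernels) for _ in kernels]
    sigma_e2 = vy * (1 - spec.r2)
    e = yv - mu
    for (U, _, _), g in zip(kernels, gammas):
        e -= U @ g

    sum_effect = np.zeros(len(all_samples))
    sum_mu = 0.0
    var_trace = []
    kept = 0
    for it in range(spec.iterations):
        e += mu
        mu = float(e.mean()) + rng.standard_normal() * np.sqrt(sigma_e2 / n)
        e -= mu
        for idx, ((U, s_eig, _), g) in enumerate(zip(kernels, gammas)):
            e += U @ g
            uty = U.T @ e
            post_var = 1.0 / (1.0 / sigma_e2 + 1.0 / (s_eig * sig_k[idx]))
            post_mean = post_var * uty / sigma_e2
            g_new = post_mean + rng.standard_normal(len(s_eig)) * np.sqrt(post_var)
            gammas[idx] = g_new
            e -= U @ g_new
            ss = float(np.sum(g_new**2 / s_eig))
            sig_k[idx] = (ss + Sk) / rng.chisquare(len(s_eig) + df0)
        sigma_e2 = (float(e @ e) + Se) / rng.chisquare(n + dfe0)

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            total = np.zeros(len(all_samples))
            for idx, ((U, s_eig, K_cross), g) in enumerate(zip(kernels, gammas)):
                # effect for any sample: K[:, train] @ (pseudo-inverse map)
                # u_train = U g; extend via K cross-block on the training
                # representation: alpha = U diag(1/s) g
                alpha = U @ (g / s_eig)
                total += K_cross @ alpha
            total += mu
            sum_effect += total
            sum_mu += mu
            var_trace.append(sigma_e2)
            kept += 1
    gebv = pd.Series(sum_effect / kept, index=all_samples, name="GEBV")
    return BayesResult(effects=np.array([]), mu=sum_mu / kept, gebv=gebv, varE_trace=np.array(var_trace))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def stratified_cv(
    samples: Sequence[str],
    families: pd.Series,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> list[pd.Series]:
    """Family-stratified k-fold assignments, one Series per repeat.

    Within each family members are shuffled and dealt round-robin to folds;
    the dealing start rotates across families so fold sizes stay balanced.
    """
    samples = list(samples)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(samples):
        raise ValueError("k exceeds the number of samples")
    fam = families.reindex(samples)
    if fam.isna().any():
        raise ValueError("every sample needs a family label")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(repeats):
        folds = pd.Series(np.zeros(len(samples), dtype=int), index=samples)
        pointer = 0
        for f in sorted(set(fam)):
            members = [s for s in samples if fam[s] == f]
            order = rng.permutation(len(members))
            for i, oi in enumerate(order):
                folds[members[oi]] = (pointer + i) % k
            pointer = (pointer + len(members)) % k
        out.append(folds)
    return out


@dataclass
class CVResult:
    """Cross-validated predictive ability."""

    per_repeat_r: list[float]
    mean_r: float
    sd_r: float
    fold_assignments: list[pd.Series]


def predictive_ability(
    y: pd.Series,
    fit_predict: Callable[[pd.Series, list[str]], pd.Series],
    folds: list[pd.Series],
    pool_folds: bool = True,
) -> CVResult:
    """Mean Pearson correlation between observations and cross-validated
    GEBVs over repeats.

    ``fit_predict(y_train, test_samples)`` must return predictions indexed
    by the test samples.  By default folds are pooled within a repeat (one
    correlation per repeat); ``pool_folds=False`` averages per-fold
    correlations instead.
    """
    if float(np.std(y.to_numpy())) == 0:
        raise ValueError("zero-variance observations: correlation undefined")
    rs = []
    for fold in folds:
        preds = {}
        ks = sorted(set(fold))
        per_fold = []
        for kf in ks:
            test = list(fold.index[fold == kf])
            train = list(fold.index[fold != kf])
            if len(test) < 1:
                continue
            p = fit_predict(y.loc[train], test)
            for s in test:
                preds[s] = float(p.loc[s])
            if not pool_folds:
                obs = y.loc[test].to_numpy()
                pr = np.array([preds[s] for s in test])
                per_fold.append(_pearson(obs, pr))
        if pool_folds:
            names = list(preds)
            rs.append(_pearson(y.loc[names].to_numpy(), np.array([preds[s] for s in names])))
        else:
            rs.append(float(np.mean(per_fold)))
    return CVResult(
        per_repeat_r=rs,
        mean_r=float(np.mean(rs)),
        sd_r=float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0,
        fold_assignments=folds,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance vector in correlation")
    return float(np.corrcoef(a, b)[0, 1])


def make_fit_predict(
    model: GSModelSpec,
    gm: GenotypeMatrix | None = None,
    G: pd.DataFrame | None = None,
    A: pd.DataFrame | None = None,
) -> Callable[[pd.Series, list[str]], pd.Series]:
    """Build the ``fit_predict`` closure for one model family.

    Kernels/dosages are computed once up front; each call retrains on the
    fold's training phenotypes and predicts the fold's test samples.
    """
    dosage_df = None
    if gm is not None:
        dosage_df = pd.DataFrame(imputed_dosage(gm), index=gm.samples, columns=gm.marker_ids())
        if G is None:
            Gv = grm(dosage_df.to_numpy())
            G = pd.DataFrame(Gv, index=gm.samples, columns=gm.samples)

    def fp(y_train: pd.Series, test: list[str]) -> pd.Series:
        if model.family == "RIDGE":
            res = fit_ridge(y_train, G)
            return res.gebv.loc[test]
        if model.family == "PEDIGREE_BLUP":
            if A is None:
                raise ValueError("pedigree BLUP needs the A matrix")
            res = fit_ridge(y_train, A)
            return res.gebv.loc[test]
        if model.family == "RKHS_G_A":
            if A is None or G is None:
                raise ValueError("RKHS G+A needs both kernels")
            res = fit_rkhs_g_a(y_train, G, A, model)
            return res.gebv.loc[test]
        if dosage_df is None:
            raise ValueError("Bayesian families need the genotype matrix")
        res = fit_bayes(y_train, dosage_df, model, predict_for=dosage_df.loc[test])
        return res.gebv

    return fp
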
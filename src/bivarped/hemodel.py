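"""Bivariate two-level Haseman-Elston regression with polygenic variance
components, estimated by iterative generalized least squares.

Model, for individual i in pedigree k and traits t = 1..T (T = 1 or 2):

    y_t,ik = x_ik' beta_t + g_t,ik + e_t,ik

where x are fixed effects (SNP dosage plus covariates), g is a polygenic
effect with Cov(g_s,i, g_t,j) = sigma_g[s,t] * 2*Phi_ij, and e is a residual
with Cov(e_s,i, e_t,j) = sigma_e[s,t] * delta_ij. The per-pedigree stacked
covariance is Omega_k = Sigma_g (x) 2*Phi_k + Sigma_e (x) I.

Estimation alternates two levels until the variance parameters stabilize:

* level 1 - generalized least squares of the stacked outcome on the fixed
  effects given the current Omega_k, giving beta and its covariance;
* level 2 - ordinary least squares of the elementwise products of level-1
  residual pairs within pedigrees on the corresponding elements of 2*Phi
  and of the identity, giving updated Sigma_g and Sigma_e (the classic
  Haseman-Elston second level).

SNP hypothesis tests are first-level Wald tests: chi-square with one degree
of freedom per trait tested, two for the joint bivariate test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityWarning, DegenerateError, NumericalError, RangeError
from .io import GenotypeMatrix
from .pedigree import KinshipMatrix, Pedigree
from .qc import ld_r2

__all__ = [
    "TheModelSpec",
    "VarianceComponents",
    "THEFit",
    "AssocResult",
    "fit_bivariate_the",
    "fit_univariate_the",
    "wald_test",
    "interaction_model",
    "variance_explained",
    "genome_scan",
    "genomic_lambda",
]

logger = logging.getLogger(__name__)


@dataclass
class TheModelSpec:
    """Inputs for one fit: trait columns, fixed-effect design, controls.

    ``traits`` is an (n, T) frame/array of standardized trait residuals;
    ``fixed_effects`` an (n, p) design shared by the traits (an intercept is
    added automatically if absent).
    """

    traits: pd.DataFrame
    fixed_effects: pd.DataFrame | None = None
    max_iter: int = 50
    tol: float = 1e-6
    vc_floor: float = 0.0
    robust_se: bool = False

    def __post_init__(self):
        if self.tol <= 0:
            raise RangeError("tol must be > 0")
        if self.vc_floor < 0:
            raise RangeError("vc_floor must be >= 0")


@dataclass
class VarianceComponents:
    """Genetic (polygenic) and residual trait covariance matrices."""

    sigma_g: np.ndarray
    sigma_e: np.ndarray

    def heritability(self) -> np.ndarray:
        """Per-trait sigma_g / (sigma_g + sigma_e) diagonal ratio."""
        tot = np.diag(self.sigma_g) + np.diag(self.sigma_e)
        return np.diag(self.sigma_g) / tot

    def genetic_correlation(self) -> float:
        d = np.sqrt(self.sigma_g[0, 0] * self.sigma_g[1, 1])
        return float(self.sigma_g[0, 1] / d) if d > 0 else np.nan


@dataclass
class THEFit:
    """Result of one two-level Haseman-Elston fit."""

    beta: np.ndarray
    cov_beta: np.ndarray
    beta_names: list[str]
    vc: VarianceComponents
    converged: bool
    iterations: int
    n_used: int
    n_traits: int
    subject_ids: list[str] = field(default_factory=list, repr=False)

    def coef(self, name: str) -> float:
        return float(self.beta[self.beta_names.index(name)])

    def se(self, name: str) -> float:
        i = self.beta_names.index(name)
        return float(np.sqrt(self.cov_beta[i, i]))


@dataclass
class AssocResult:
    """Per-marker association fit summary."""

    marker_id: str
    n_used: int
    beta: tuple[float, ...]
    se: tuple[float, ...]
    vc: VarianceComponents
    wald: float
    df: int
    p: float
    converged: bool
    iterations: int


# ---------------------------------------------------------------------------
# core iterative GLS

def _floor_psd(m: np.ndarray, floor: float) -> np.ndarray:
    """Symmetrize and clip eigenvalues at ``floor`` (eigen-truncation)."""
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    return (v * np.maximum(w, floor)) @ v.T


def _blocks_from_pedigree(subject_ids: list[str], ped: Pedigree,
                          phi: KinshipMatrix) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Row-index blocks per family plus the matching 2*Phi submatrices."""
    fam_of = {r.individual_id: r.family_id for r in ped.members}
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(subject_ids):
        groups.setdefault(fam_of[s], []).append(i)
    blocks, A_list = [], []
    for fam in sorted(groups):
        idx = np.array(groups[fam])
        blocks.append(idx)
        ids = [subject_ids[i] for i in idx]
        A_list.append(2.0 * phi.submatrix(ids))
    return blocks, A_list


def _omega_inverses(A_list, sigma_g, sigma_e):
    """Per-block inverse of Sigma_g (x) A + Sigma_e (x) I.

    Identical relationship blocks (repeated family structures) share one
    inverse, keyed by the byte content of A.
    """
    cache: dict[bytes, np.ndarray] = {}
    out = []
    for A in A_list:
        key = A.tobytes()
        if key not in cache:
            nk = A.shape[0]
            omega = np.kron(sigma_g, A) + np.kron(sigma_e, np.eye(nk))
            try:
                W = np.linalg.inv(omega)
            except np.linalg.LinAlgError:
                try:
                    W = np.linalg.inv(omega + 1e-8 * np.eye(omega.shape[0]))
                except np.linalg.LinAlgError as exc:  # pragma: no cover
                    raise NumericalError("Omega not invertible after flooring") from exc
            cache[key] = W
        out.append(cache[key])
    return out


def _level2_update(resid_blocks, A_list, T, vc_floor):
    """OLS of residual cross-products on (2*Phi, I) elements, per trait pair."""
    # Gram matrix of the two predictors is shared by all trait pairs
    gram = np.zeros((2, 2))
    rhs = np.zeros((T, T, 2))
    for R, A in zip(resid_blocks, A_list):  # R is (T, n_k)
        a = A.ravel()
        d = np.eye(A.shape[0]).ravel()
        gram[0, 0] += a @ a
        gram[0, 1] += a @ d
        gram[1, 1] += d @ d
        for s in range(T):
            for t in range(s, T):
                y = np.outer(R[s], R[t]).ravel()
                rhs[s, t, 0] += a @ y
                rhs[s, t, 1] += d @ y
    gram[1, 0] = gram[0, 1]
    det = np.linalg.det(gram)
    sg = np.zeros((T, T))
    se = np.zeros((T, T))
    for s in range(T):
        for t in range(s, T):
            if det <= 1e-10 * max(gram[0, 0], 1.0) ** 2:
                # predictors collinear (e.g. unrelated singletons where
                # 2*Phi = I): all covariance is residual, polygenic part 0
                g_st, e_st = 0.0, rhs[s, t, 1] / gram[1, 1]
            else:
                g_st, e_st = np.linalg.solve(gram, rhs[s, t])
            sg[s, t] = sg[t, s] = g_st
            se[s, t] = se[t, s] = e_st
    return _floor_psd(sg, vc_floor), _floor_psd(se, vc_floor)


def _fit_the_arrays(Y: np.ndarray, X: np.ndarray, blocks, A_list,
                    max_iter: int, tol: float, vc_floor: float,
                    robust_se: bool = False):
    """Iterative two-level fit on complete arrays. Y is (n, T), X is (n, p)."""
    n, T = Y.shape
    p = X.shape[1]
    d = T * p
    sigma_e = np.cov(Y, rowvar=False).reshape(T, T)
    sigma_g = 0.5 * sigma_e.copy()
    beta = np.zeros(d)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W_list = _omega_inverses(A_list, sigma_g, sigma_e)
        XtWX = np.zeros((d, d))
        XtWy = np.zeros(d)
        for idx, W in zip(blocks, W_list):
            Xk = np.kron(np.eye(T), X[idx])          # (T*nk, T*p)
            yk = Y[idx].T.ravel()                    # trait-major stack
            WX = W @ Xk
            XtWX += Xk.T @ WX
            XtWy += WX.T @ yk
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            # degenerate columns (e.g. an all-zero interaction term) get the
            # minimum-norm solution: coefficient 0 with zero variance
            beta = np.linalg.pinv(XtWX) @ XtWy
        resid_blocks = []
        for idx in blocks:
            fitted = (X[idx] @ beta.reshape(T, p).T).T   # (T, nk)
            resid_blocks.append(Y[idx].T - fitted)
        new_g, new_e = _level2_update(resid_blocks, A_list, T, vc_floor)
        delta = max(np.abs(new_g - sigma_g).max(), np.abs(new_e - sigma_e).max())
        sigma_g, sigma_e = new_g, new_e
        if delta < tol:
            converged = True
            break
    # final level-1 pass at the converged variance components
    W_list = _omega_inverses(A_list, sigma_g, sigma_e)
    XtWX = np.zeros((d, d))
    XtWy = np.zeros(d)
    meat = np.zeros((d, d))
    for idx, W in zip(blocks, W_list):
        Xk = np.kron(np.eye(T), X[idx])
        yk = Y[idx].T.ravel()
        WX = W @ Xk
        XtWX += Xk.T @ WX
        XtWy += WX.T @ yk
    try:
        beta = np.linalg.solve(XtWX, XtWy)
        bread = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        bread = np.linalg.pinv(XtWX)
        beta = bread @ XtWy
    if robust_se:
        for idx, W in zip(blocks, W_list):
            Xk = np.kron(np.eye(T), X[idx])
            yk = Y[idx].T.ravel()
            u = Xk.T @ (W @ (yk - Xk @ beta))
            meat += np.outer(u, u)
        cov_beta = bread @ meat @ bread
    else:
        cov_beta = bread
    return beta, cov_beta, sigma_g, sigma_e, converged, it


def _prepare_design(spec: TheModelSpec):
    """Complete-case alignment; returns Y, X, kept subject ids, names."""
    traits = spec.traits
    if isinstance(traits, pd.DataFrame):
        trait_names = list(traits.columns)
        ids = [str(s) for s in traits.index]
        Y = traits.to_numpy(dtype=float)
    else:
        Y = np.asarray(traits, dtype=float)
        trait_names = [f"t{i + 1}" for i in range(Y.shape[1])]
        ids = [str(i) for i in range(Y.shape[0])]
    if spec.fixed_effects is None:
        X = np.ones((Y.shape[0], 1))
        fe_names = ["intercept"]
    else:
        fe = spec.fixed_effects
        fe_names = list(fe.columns) if isinstance(fe, pd.DataFrame) else (
            [f"x{i}" for i in range(np.asarray(fe).shape[1])])
        X = np.asarray(fe, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if not any(np.all(X[:, j] == X[0, j]) and X[0, j] != 0 for j in range(X.shape[1])):
            X = np.column_stack([np.ones(X.shape[0]), X])
            fe_names = ["intercept"] + fe_names
    keep = ~np.isnan(Y).any(axis=1) & ~np.isnan(X).any(axis=1)
    Y, X = Y[keep], X[keep]
    ids = [s for s, k in zip(ids, keep) if k]
    names = [f"{t}:{f}" for t in trait_names for f in fe_names]
    return Y, X, ids, names


def fit_bivariate_the(spec: TheModelSpec, phi: KinshipMatrix, ped: Pedigree) -> THEFit:
    """Fit the bivariate (or generally T-trait) two-level HE model.

    ``spec.traits`` must be indexed by subject id (matching ``ped``). Rows
    with any missing trait or fixed effect are dropped (complete case).
    """
    Y, X, ids, names = _prepare_design(spec)
    if Y.shape[0] < 50:
        raise RangeError(f"need >= 50 complete-case subjects, got {Y.shape[0]}")
    blocks, A_list = _blocks_from_pedigree(ids, ped, phi)
    beta, cov_beta, sg, se, converged, it = _fit_the_arrays(
        Y, X, blocks, A_list, spec.max_iter, spec.tol, spec.vc_floor, spec.robust_se)
    if not converged:
        logger.warning("tHE fit did not converge in %d iterations", spec.max_iter)
    return THEFit(beta=beta, cov_beta=cov_beta, beta_names=names,
                  vc=VarianceComponents(sg, se), converged=converged,
                  iterations=it, n_used=Y.shape[0], n_traits=Y.shape[1],
                  subject_ids=ids)


def wald_test(fit: THEFit, which: list[str] | list[int]) -> tuple[float, int, float]:
    """First-level Wald test of a coefficient subset: beta' V^-1 beta ~ chi2(df)."""
    idx = [fit.beta_names.index(w) if isinstance(w, str) else int(w) for w in which]
    b = fit.beta[idx]
    V = fit.cov_beta[np.ix_(idx, idx)]
    df = len(idx)
    if np.allclose(V, 0.0, atol=1e-12) and np.allclose(b, 0.0, atol=1e-12):
        return 0.0, df, 1.0  # term absent from the data (e.g. no joint carriers)
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise NumericalError("singular coefficient covariance in Wald test") from exc
    return stat, df, float(stats.chi2.sf(stat, df))


def fit_univariate_the(trait: pd.Series, fixed_effects: pd.DataFrame | None,
                       phi: KinshipMatrix, ped: Pedigree,
                       marker_name: str | None = None, **kwargs) -> AssocResult:
    """Single-trait specialization (scalar variance components, 1-df Wald).

    ``marker_name`` selects the tested fixed-effect column; defaults to the
    last column of ``fixed_effects``.
    """
    traits = trait.to_frame() if isinstance(trait, pd.Series) else trait
    spec = TheModelSpec(traits=traits, fixed_effects=fixed_effects, **kwargs)
    fit = fit_bivariate_the(spec, phi, ped)
    tname = traits.columns[0]
    if marker_name is None:
        marker_name = [n for n in fit.beta_names if n.startswith(f"{tname}:")][-1].split(":", 1)[1]
    coef = f"{tname}:{marker_name}"
    stat, df, p = wald_test(fit, [coef])
    return AssocResult(marker_id=marker_name, n_used=fit.n_used,
                       beta=(fit.coef(coef),), se=(fit.se(coef),),
                       vc=fit.vc, wald=stat, df=df, p=p,
                       converged=fit.converged, iterations=fit.iterations)


def interaction_model(snp1: pd.Series, snp2: pd.Series, traits: pd.DataFrame,
                      phi: KinshipMatrix, ped: Pedigree,
                      covariates: pd.DataFrame | None = None,
                      ld_max: float = 0.5, **kwargs) -> pd.DataFrame:
    """Joint model with both SNPs and their product term.

    Fits each trait univariately and the bivariate outcome with fixed
    effects snp1 + snp2 + snp1*snp2 (plus covariates), reporting per-term
    effect estimates and Wald p-values (1 df per trait, 2 df joint). SNP
    pairs with r^2 >= ``ld_max`` trigger a :class:`CollinearityWarning` but
    the fit is still returned.
    """
    common = traits.index
    r2 = ld_r2(snp1.reindex(common).to_numpy(), snp2.reindex(common).to_numpy())
    if r2 >= ld_max:
        warnings.warn(f"SNP pair LD r2 = {r2:.3f} >= {ld_max}", CollinearityWarning)
    design = pd.DataFrame({
        "snp1": snp1.reindex(common).to_numpy(),
        "snp2": snp2.reindex(common).to_numpy(),
    }, index=common)
    design["snp1_x_snp2"] = design["snp1"] * design["snp2"]
    if covariates is not None:
        design = pd.concat([covariates.reindex(common), design], axis=1)
    rows = []
    t1, t2 = traits.columns[:2]
    bi = fit_bivariate_the(TheModelSpec(traits=traits[[t1, t2]], fixed_effects=design,
                                        **kwargs), phi, ped)
    uni = {t: fit_bivariate_the(TheModelSpec(traits=traits[[t]], fixed_effects=design,
                                             **kwargs), phi, ped) for t in (t1, t2)}
    for term in ("snp1", "snp2", "snp1_x_snp2"):
        row = {"term": term}
        for t, label in ((t1, "t1"), (t2, "t2")):
            f = uni[t]
            stat, df, p = wald_test(f, [f"{t}:{term}"])
            row[f"beta_{label}"] = f.coef(f"{t}:{term}")
            row[f"p_{label}"] = p
        stat, df, p = wald_test(bi, [f"{t1}:{term}", f"{t2}:{term}"])
        row["beta_biv_t1"] = bi.coef(f"{t1}:{term}")
        row["beta_biv_t2"] = bi.coef(f"{t2}:{term}")
        row["p_biv"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def variance_explained(beta1: float, beta2: float, maf: float, sigma_g12: float) -> float:
    """Share of the genetic trait covariance due to one standardized SNP.

    For a SNP with allele frequency ``maf`` and standardized per-allele
    effects beta1, beta2, its contribution to the cross-trait covariance is
    2*maf*(1-maf)*beta1*beta2; dividing by the polygenic covariance
    sigma_g12 gives the proportion explained.
    """
    if sigma_g12 == 0:
        raise DegenerateError("sigma_g12 = 0: co-heritability proportion undefined")
    if not 0 < maf < 1:
        raise RangeError(f"maf {maf} outside (0, 1)")
    return float(2.0 * maf * (1.0 - maf) * beta1 * beta2 / sigma_g12)


# ---------------------------------------------------------------------------
# genome scan

def _fast_scan(Y, X0, G, blocks, W_list):
    """Per-marker GLS with frozen Omega, vectorized over markers.

    X0 is the no-SNP design (n, p0); G the (n, M) genotype matrix. Returns
    arrays of per-trait SNP betas, SEs, Wald 2-df statistics.
    """
    n, T = Y.shape
    p0 = X0.shape[1]
    M = G.shape[1]
    CWC = np.zeros((T, T, p0, p0))
    CWG = np.zeros((T, T, p0, M))
    GWG = np.zeros((T, T, M))
    CWy = np.zeros((T, p0))
    GWy = np.zeros((T, M))
    for idx, W in zip(blocks, W_list):
        nk = len(idx)
        C = X0[idx]
        Gk = G[idx]
        yk = Y[idx]
        for s in range(T):
            for t in range(T):
                Wst = W[s * nk:(s + 1) * nk, t * nk:(t + 1) * nk]
                WC = Wst @ C
                WG = Wst @ Gk
                CWC[s, t] += C.T @ WC
                CWG[s, t] += C.T @ WG
                GWG[s, t] += np.einsum("ij,ij->j", Gk, WG)
                Wy = Wst @ yk[:, t]
                CWy[s] += C.T @ Wy
                GWy[s] += Gk.T @ Wy
    d = T * (p0 + 1)
    betas = np.full((M, T), np.nan)
    ses = np.full((M, T), np.nan)
    walds = np.full(M, np.nan)
    snp_pos = [t * (p0 + 1) + p0 for t in range(T)]
    XtWX = np.zeros((d, d))
    XtWy = np.zeros(d)
    for m in range(M):
        for s in range(T):
            rs = slice(s * (p0 + 1), s * (p0 + 1) + p0)
            XtWy[rs] = CWy[s]
            XtWy[s * (p0 + 1) + p0] = GWy[s, m]
            for t in range(T):
                cs = slice(t * (p0 + 1), t * (p0 + 1) + p0)
                XtWX[rs, cs] = CWC[s, t]
                XtWX[rs, t * (p0 + 1) + p0] = CWG[s, t][:, m]
                XtWX[s * (p0 + 1) + p0, cs] = CWG[t, s][:, m]
                XtWX[s * (p0 + 1) + p0, t * (p0 + 1) + p0] = GWG[s, t][m]
        try:
            cov = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            continue
        beta = cov @ XtWy
        b = beta[snp_pos]
        V = cov[np.ix_(snp_pos, snp_pos)]
        betas[m] = b
        ses[m] = np.sqrt(np.diag(V))
        try:
            walds[m] = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            continue
    return betas, ses, walds


def genome_scan(g: GenotypeMatrix, traits: pd.DataFrame, phi: KinshipMatrix,
                ped: Pedigree, covariates: pd.DataFrame | None = None,
                mode: str = "fast", **kwargs) -> dict:
    """Marker-by-marker bivariate association scan.

    ``fast`` mode estimates the variance components once under the no-SNP
    model and reuses the implied Omega for every marker (missing genotypes
    mean-imputed); ``exact`` mode refits the full model per marker
    (complete case). Returns a dict with ``results`` (one row per marker),
    ``manhattan`` (-log10 p vs position) and ``qq`` (expected vs observed
    quantiles) tables.
    """
    T = traits.shape[1]
    base_spec = TheModelSpec(traits=traits, fixed_effects=covariates, **kwargs)
    base = fit_bivariate_the(base_spec, phi, ped)
    ids = base.subject_ids
    rows = []
    if mode == "fast":
        Y = traits.loc[ids].to_numpy(dtype=float)
        if covariates is None:
            X0 = np.ones((len(ids), 1))
        else:
            X0 = np.column_stack([np.ones(len(ids)),
                                  covariates.loc[ids].to_numpy(dtype=float)])
        Gm = g.subset(subject_ids=ids).values.copy()
        col_mean = np.nanmean(Gm, axis=0)
        nan_mask = np.isnan(Gm)
        Gm[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
        blocks, A_list = _blocks_from_pedigree(ids, ped, phi)
        W_list = _omega_inverses(A_list, base.vc.sigma_g, base.vc.sigma_e)
        betas, ses, walds = _fast_scan(Y, X0, Gm, blocks, W_list)
        pvals = stats.chi2.sf(walds, T)
        for j, m in enumerate(g.markers):
            rows.append({"marker_id": m.marker_id, "chrom": m.chromosome,
                         "pos": m.position,
                         "beta_t1": betas[j, 0],
                         "beta_t2": betas[j, 1] if T > 1 else np.nan,
                         "se_t1": ses[j, 0],
                         "se_t2": ses[j, 1] if T > 1 else np.nan,
                         "wald": walds[j], "df": T, "p": pvals[j],
                         "n": len(ids)})
    elif mode == "exact":
        for j, m in enumerate(g.markers):
            snp = pd.Series(g.values[[g.subject_index(s) for s in g.subject_ids], j],
                            index=g.subject_ids, name="snp").reindex(traits.index)
            design = (pd.concat([covariates, snp], axis=1)
                      if covariates is not None else snp.to_frame())
            try:
                fit = fit_bivariate_the(
                    TheModelSpec(traits=traits, fixed_effects=design, **kwargs), phi, ped)
                which = [f"{t}:snp" for t in traits.columns]
                stat, df, p = wald_test(fit, which)
            except Exception as exc:
                logger.warning("marker %s failed: %s", m.marker_id, exc)
                continue
            b = [fit.coef(w) for w in which]
            s = [fit.se(w) for w in which]
            rows.append({"marker_id": m.marker_id, "chrom": m.chromosome,
                         "pos": m.position,
                         "beta_t1": b[0], "beta_t2": b[1] if T > 1 else np.nan,
                         "se_t1": s[0], "se_t2": s[1] if T > 1 else np.nan,
                         "wald": stat, "df": df, "p": p, "n": fit.n_used})
    else:
        raise RangeError(f"unknown scan mode {mode!r}")
    results = pd.DataFrame(rows)
    ok = results.dropna(subset=["p"])
    manhattan = pd.DataFrame({"chrom": ok["chrom"], "pos": ok["pos"],
                              "neglog10_p": -np.log10(ok["p"].clip(lower=1e-300))})
    pv = np.sort(ok["p"].to_numpy())
    expected = (np.arange(1, len(pv) + 1) - 0.5) / len(pv) if len(pv) else np.array([])
    qq = pd.DataFrame({"expected_neglog10": -np.log10(expected) if len(pv) else [],
                       "observed_neglog10": -np.log10(np.clip(pv, 1e-300, None))})
    return {"results": results, "manhattan": manhattan, "qq": qq,
            "null_vc": base.vc, "mode": mode}


def genomic_lambda(p_values, df: int = 2) -> float:
    """Genomic inflation factor: median implied chi2 over the null median.

    Under the null the implied chi2(df) statistics have median equal to the
    chi2(df) distribution median (0.4549 for 1 df, 1.3863 for 2 df); their
    ratio detects systematic test-statistic inflation.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 100:
        raise RangeError(f"need >= 100 p-values, got {p.size}")
    observed = stats.chi2.isf(p, df)
    return float(np.median(observed) / stats.chi2.ppf(0.5, df))
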
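"""Univariate multi-environment GBLUP with optional genotype x environment term.

The model for the response of line j in environment i is

    y_ij = E_i + g_j + gE_ij + e_ij

with fixed environment effects E_i, genomic line effects
g ~ N(0, sigma1^2 G) where G is the genomic relationship matrix, an
interaction vector gE ~ N(0, sigma2^2 I_I (x) G) — line effects deviate
environment-specifically, borrowing between-line correlation from G within
each environment — and iid residuals e ~ N(0, sigma^2).

Two estimators are provided:

* ``gibbs`` — a Gibbs sampler with flat priors on the fixed effects,
  multivariate-normal full conditionals for g and the per-environment gE
  blocks, and scaled-inverse-chi-square full conditionals for the three
  variances.  Posterior means are reported.
* ``fixed_variances`` — Henderson's mixed-model equations solved exactly at
  user-supplied variances; deterministic, used as the oracle path in tests
  and for shrinkage-limit checks.

Both estimators carry every line's interaction effect in every environment
(observed or not), so predictions for held-out cells come from the same
joint solve / posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve

from .genotypes import GRM, cholesky_factor

__all__ = ["GBLUPSpec", "GBLUPFit", "build_design_matrices", "fit_gblup", "predict_gblup"]

_ZERO_VAR = 1e-12  # an interaction variance at/below this collapses to the WI model


@dataclass
class GBLUPSpec:
    """Estimator settings for one GBLUP fit."""

    include_interaction: bool = True
    estimator: str = "gibbs"  # gibbs | fixed_variances
    n_iterations: int = 6000
    burn_in: int = 1000
    thin: int = 5
    prior_df: float = 5.0
    prior_split: tuple[float, float, float] = (0.25, 0.25, 0.5)
    fixed_variances: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.estimator not in ("gibbs", "reml", "fixed_variances"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if abs(sum(self.prior_split) - 1.0) > 1e-9:
            raise ValueError("prior_split must sum to 1")


@dataclass
class GBLUPFit:
    """Point estimates (posterior means or exact BLUPs) from one fit."""

    env_effects: pd.Series  # indexed by environment id
    genomic_blups: pd.Series  # indexed by line id
    interaction_blups: np.ndarray | None  # (I, J) or None under WI
    variance_estimates: dict
    diagnostics: dict
    include_interaction: bool
    env_ids: list[str]
    line_ids: list[str]
    # posterior standard deviations (zero for the exact solver)
    env_sd: np.ndarray | None = None
    genomic_sd: np.ndarray | None = None
    interaction_sd: np.ndarray | None = None


def _labels(pheno: pd.DataFrame, line_ids, env_ids):
    lines = sorted(pheno["line"].unique()) if line_ids is None else list(line_ids)
    envs = sorted(pheno["environment"].unique()) if env_ids is None else list(env_ids)
    line_index = {l: j for j, l in enumerate(lines)}
    env_index = {e: i for i, e in enumerate(envs)}
    unknown_l = set(pheno["line"]) - set(lines)
    unknown_e = set(pheno["environment"]) - set(envs)
    if unknown_l or unknown_e:
        raise ValueError(f"records with unknown labels: lines {unknown_l}, envs {unknown_e}")
    return lines, envs, line_index, env_index


def build_design_matrices(
    pheno: pd.DataFrame, line_ids: list[str] | None = None, env_ids: list[str] | None = None
):
    """One-hot design matrices (Z_E, Z_G, Z_GE) for a long phenotype table.

    Z_GE columns are environment-major blocks of J lines (column i*J + j for
    environment i, line j), the ordering consistent with the I_I (x) G
    interaction covariance.
    """
    if len(pheno) == 0:
        raise ValueError("empty phenotype table")
    lines, envs, line_index, env_index = _labels(pheno, line_ids, env_ids)
    n, J, I = len(pheno), len(lines), len(envs)
    ei = pheno["environment"].map(env_index).to_numpy()
    li = pheno["line"].map(line_index).to_numpy()
    rows = np.arange(n)
    ones = np.ones(n)
    Z_E = sp.csr_matrix((ones, (rows, ei)), shape=(n, I))
    Z_G = sp.csr_matrix((ones, (rows, li)), shape=(n, J))
    Z_GE = sp.csr_matrix((ones, (rows, ei * J + li)), shape=(n, I * J))
    return Z_E, Z_G, Z_GE


def _single_trait_vector(pheno: pd.DataFrame) -> pd.DataFrame:
    if "trait" in pheno.columns and pheno["trait"].nunique() > 1:
        raise ValueError("GBLUP is univariate: pass a single-trait phenotype table")
    out = pheno.dropna(subset=["value"])
    if len(out) == 0:
        raise ValueError("no non-missing records")
    return out


def fit_gblup(pheno_train: pd.DataFrame, grm: GRM, spec: GBLUPSpec,
              env_ids: list[str] | None = None) -> GBLUPFit:
    """Fit the multi-environment GBLUP on one trait's training records.

    ``pheno_train`` is long format with columns line, environment, value
    (plus an optional single-valued trait column).  Every line must be in
    ``grm``; environment labels default to the sorted labels present.
    """
    pheno = _single_trait_vector(pheno_train)
    lines = grm.line_ids
    _, envs, line_index, env_index = _labels(pheno, lines, env_ids)
    y = pheno["value"].to_numpy(dtype=float)
    ei = pheno["environment"].map(env_index).to_numpy()
    li = pheno["line"].map(line_index).to_numpy()
    J, I, n = len(lines), len(envs), len(y)

    n_per_env = np.bincount(ei, minlength=I)
    if (n_per_env == 0).any():
        empty = [envs[i] for i in np.flatnonzero(n_per_env == 0)]
        raise ValueError(f"environments with no training records: {empty}")

    fac = cholesky_factor(grm)
    Ginv = cho_solve((fac.upper, False), np.eye(J))
    Ginv = (Ginv + Ginv.T) / 2.0

    if spec.estimator == "fixed_variances":
        if spec.fixed_variances is None:
            raise ValueError("fixed_variances estimator requires spec.fixed_variances")
        return _fit_mme(y, ei, li, Ginv, spec, envs, lines, n_per_env)
    if spec.estimator == "reml":
        raise NotImplementedError(
            "REML is not provided; use 'gibbs' or the exact 'fixed_variances' solver"
        )
    return _fit_gibbs(y, ei, li, Ginv, spec, envs, lines, n_per_env)


def _interaction_obs(ei, li, I, J):
    """Per-environment 0/1 observation counts by line, and residual index maps."""
    counts = np.zeros((I, J))
    np.add.at(counts, (ei, li), 1.0)
    return counts


def _fit_mme(y, ei, li, Ginv, spec: GBLUPSpec, envs, lines, n_per_env) -> GBLUPFit:
    """Henderson mixed-model equations at fixed variances (exact, deterministic)."""
    s1, s2, se = spec.fixed_variances
    if s1 <= 0 or se <= 0:
        raise ValueError("genomic and residual variances must be positive")
    I, J, n = len(envs), len(lines), len(y)
    with_u = spec.include_interaction and s2 > _ZERO_VAR

    rows = np.arange(n)
    X = sp.csr_matrix((np.ones(n), (rows, ei)), shape=(n, I))
    Zg = sp.csr_matrix((np.ones(n), (rows, li)), shape=(n, J))
    blocks = [X, Zg]
    if with_u:
        Zu = sp.csr_matrix((np.ones(n), (rows, ei * J + li)), shape=(n, I * J))
        blocks.append(Zu)
    M = sp.hstack(blocks).tocsr()
    A = (M.T @ M).toarray() / se
    rhs = M.T @ y / se
    A[I:I + J, I:I + J] += Ginv / s1
    if with_u:
        for i in range(I):
            sl = slice(I + J + i * J, I + J + (i + 1) * J)
            A[sl, sl] += Ginv / s2
    theta = np.linalg.solve(A, rhs)
    beta = theta[:I]
    g = theta[I:I + J]
    u = theta[I + J:].reshape(I, J) if with_u else None
    e = y - beta[ei] - g[li] - (u[ei, li] if with_u else 0.0)
    fit = GBLUPFit(
        env_effects=pd.Series(beta, index=envs),
        genomic_blups=pd.Series(g, index=lines),
        interaction_blups=u if spec.include_interaction else None,
        variance_estimates={"sigma2_g": s1, "sigma2_ge": s2 if spec.include_interaction else None,
                            "sigma2_e": se, "source": "fixed"},
        diagnostics={"estimator": "fixed_variances", "n_records": n,
                     "rss": float(e @ e)},
        include_interaction=spec.include_interaction,
        env_ids=list(envs), line_ids=list(lines),
        env_sd=np.zeros(I), genomic_sd=np.zeros(J),
        interaction_sd=np.zeros((I, J)) if spec.include_interaction else None,
    )
    if spec.include_interaction and not with_u:
        fit.interaction_blups = np.zeros((I, J))
    return fit


def _sample_mvn(P, rhs, rng):
    """Draw from N(P^{-1} rhs, P^{-1}) via the Cholesky factor of P."""
    c, low = cho_factor(P, lower=True)
    mu = cho_solve((c, low), rhs)
    z = rng.standard_normal(len(rhs))
    # solve L^T x = z gives covariance P^{-1}
    from scipy.linalg import solve_triangular

    return mu + solve_triangular(c, z, lower=True, trans="T")


def _fit_gibbs(y, ei, li, Ginv, spec: GBLUPSpec, envs, lines, n_per_env) -> GBLUPFit:
    rng = np.random.default_rng(spec.seed)
    I, J, n = len(envs), len(lines), len(y)
    with_u = spec.include_interaction
    vary = float(np.var(y)) if np.var(y) > 0 else 1.0
    df0 = spec.prior_df
    S1, S2, Se = (split * vary for split in spec.prior_split)

    # with fixed_variances supplied, the sampler conditions on them (known-
    # variance posterior), which makes its mean comparable to the exact MME
    # solution at the same variances
    fix_vars = spec.fixed_variances is not None

    counts = _interaction_obs(ei, li, I, J)  # (I, J) obs counts
    c_line = counts.sum(axis=0)  # records per line
    env_rows = [np.flatnonzero(ei == i) for i in range(I)]

    beta = np.array([y[r].mean() for r in env_rows])
    g = np.zeros(J)
    u = np.zeros((I, J))
    if fix_vars:
        s1, s2, se = spec.fixed_variances
        s2 = max(s2, _ZERO_VAR) if with_u else s2
    else:
        s1, s2, se = S1, max(S2, 1e-6), Se

    keep = range(spec.burn_in, spec.n_iterations, spec.thin)
    n_keep = len(list(keep))
    sum_beta = np.zeros(I); sumsq_beta = np.zeros(I)
    sum_g = np.zeros(J); sumsq_g = np.zeros(J)
    sum_u = np.zeros((I, J)); sumsq_u = np.zeros((I, J))
    var_samples = np.zeros((n_keep, 3))
    k = 0

    for it in range(spec.n_iterations):
        # fixed environment effects: flat prior, normal full conditional
        r = y - g[li] - (u[ei, li] if with_u else 0.0)
        for i in range(I):
            rows = env_rows[i]
            mean = r[rows].mean()
            beta[i] = mean + rng.normal(0.0, np.sqrt(se / n_per_env[i]))

        # genomic effects g | rest ~ N(P^-1 rhs, P^-1)
        r = y - beta[ei] - (u[ei, li] if with_u else 0.0)
        rhs = np.bincount(li, weights=r, minlength=J) / se
        P = Ginv / s1 + np.diag(c_line / se)
        g = _sample_mvn(P, rhs, rng)

        # interaction blocks, one per environment (all J lines each)
        if with_u:
            r = y - beta[ei] - g[li]
            for i in range(I):
                rows = env_rows[i]
                rhs_i = np.bincount(li[rows], weights=r[rows], minlength=J) / se
                P_i = Ginv / s2 + np.diag(counts[i] / se)
                u[i] = _sample_mvn(P_i, rhs_i, rng)

        # variances: scaled-inverse-chi-square full conditionals
        if not fix_vars:
            q1 = g @ Ginv @ g
            s1 = (q1 + df0 * S1) / rng.chisquare(df0 + J)
            if with_u:
                q2 = float(np.einsum("ij,jk,ik->", u, Ginv, u))
                s2 = (q2 + df0 * S2) / rng.chisquare(df0 + I * J)
            e = y - beta[ei] - g[li] - (u[ei, li] if with_u else 0.0)
            se = (e @ e + df0 * Se) / rng.chisquare(df0 + n)

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            sum_beta += beta; sumsq_beta += beta ** 2
            sum_g += g; sumsq_g += g ** 2
            if with_u:
                sum_u += u; sumsq_u += u ** 2
            var_samples[k] = (s1, s2 if with_u else np.nan, se)
            k += 1

    def _mean_sd(s, ss):
        m = s / k
        v = np.maximum(ss / k - m ** 2, 0.0)
        return m, np.sqrt(v)

    beta_m, beta_sd = _mean_sd(sum_beta, sumsq_beta)
    g_m, g_sd = _mean_sd(sum_g, sumsq_g)
    u_m, u_sd = (_mean_sd(sum_u, sumsq_u) if with_u else (None, None))
    cols = [0, 1, 2] if with_u else [0, 2]
    vmean = np.full(3, np.nan)
    vsd = np.full(3, np.nan)
    vmean[cols] = var_samples[:k, cols].mean(axis=0)
    vsd[cols] = var_samples[:k, cols].std(axis=0)
    return GBLUPFit(
        env_effects=pd.Series(beta_m, index=envs),
        genomic_blups=pd.Series(g_m, index=lines),
        interaction_blups=u_m,
        variance_estimates={
            "sigma2_g": float(vmean[0]), "sigma2_g_sd": float(vsd[0]),
            "sigma2_ge": float(vmean[1]) if with_u else None,
            "sigma2_ge_sd": float(vsd[1]) if with_u else None,
            "sigma2_e": float(vmean[2]), "sigma2_e_sd": float(vsd[2]),
            "source": "gibbs-posterior-mean",
        },
        diagnostics={"estimator": "gibbs", "n_samples": k,
                     "n_iterations": spec.n_iterations, "burn_in": spec.burn_in,
                     "thin": spec.thin, "n_records": n},
        include_interaction=with_u,
        env_ids=list(envs), line_ids=list(lines),
        env_sd=beta_sd, genomic_sd=g_sd, interaction_sd=u_sd,
    )


def predict_gblup(fit: GBLUPFit, cells: list[tuple[str, str]],
                  include_interaction: bool | None = None) -> np.ndarray:
    """Predict y_ij = E_i + g_j (+ gE_ij) for (line, environment) cells."""
    if include_interaction is None:
        include_interaction = fit.include_interaction
    if include_interaction and not fit.include_interaction:
        raise ValueError("fit was made without the interaction term")
    line_index = {l: j for j, l in enumerate(fit.line_ids)}
    env_index = {e: i for i, e in enumerate(fit.env_ids)}
    out = np.empty(len(cells))
    for r, (line, env) in enumerate(cells):
        if line not in line_index or env not in env_index:
            raise ValueError(f"unknown cell ({line}, {env})")
        i, j = env_index[env], line_index[line]
        yhat = fit.env_effects.iloc[i] + fit.genomic_blups.iloc[j]
        if include_interaction:
            yhat += fit.interaction_blups[i, j]
        out[r] = yhat
    return out
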
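"""Bayesian pedigree animal models fitted by Gibbs sampling.

Univariate and bivariate linear mixed models

    y = Xb + Z1 h + Z2 a + e

with fixed effects b (lactation-stage and parity classes), random herd/date
effects h, additive genetic effects a correlated through the pedigree
numerator relationship matrix A, and residuals e.  Priors on b and all
variance components are flat; location effects and variances are sampled
from their full conditionals (scaled inverse chi-square in the univariate
case, inverse Wishart in the bivariate case).

Posterior functionals: intra-herd heritability sigma_a^2/(sigma_a^2 +
sigma_e^2), herd fraction sigma_h^2/(sigma_a^2 + sigma_h^2 + sigma_e^2),
and additive-genetic / herd / residual / phenotypic correlations, each
computed per retained draw and then summarized (posterior mean, shortest
95% highest-density interval, sign probability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from ._gibbs import _scan_biv, _scan_uni
from .pedigree import Pedigree, inbreeding_coefficients

__all__ = [
    "ModelSpec",
    "AInverse",
    "PosteriorDraws",
    "PosteriorSummary",
    "build_a_inverse",
    "gibbs_univariate",
    "gibbs_bivariate",
    "heritability",
    "herd_fraction",
    "component_correlations",
    "posterior_summaries",
]

logger = logging.getLogger(__name__)

N_DIM_CLASSES = 6
N_PARITY_CLASSES = 4


@dataclass
class ModelSpec:
    """Model and chain settings for a Gibbs run."""

    traits: tuple[str, ...] = ("y",)
    use_dim: bool = True
    use_parity: bool = True
    iterations: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("chain iterations must exceed burn-in")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")


@dataclass
class AInverse:
    """Sparse inverse numerator relationship matrix plus inbreeding."""

    matrix: sp.csr_matrix
    inbreeding: np.ndarray
    ids: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws of (co)variance components.

    ``g0``, ``h0``, ``r0`` have shape (n_draws, t, t) with t the number of
    traits (1 for univariate runs).  ``location_mean`` is the posterior mean
    of the stacked location effects [b, h, a] per trait.
    """

    g0: np.ndarray
    h0: np.ndarray
    r0: np.ndarray
    traits: tuple[str, ...] = ("y",)
    location_mean: np.ndarray | None = None
    n_jittered: int = 0

    @classmethod
    def from_variances(cls, var_additive, var_herd, var_residual) -> "PosteriorDraws":
        sa = np.atleast_1d(np.asarray(var_additive, dtype=float))
        sh = np.atleast_1d(np.asarray(var_herd, dtype=float))
        se = np.atleast_1d(np.asarray(var_residual, dtype=float))
        return cls(g0=sa[:, None, None], h0=sh[:, None, None], r0=se[:, None, None])

    @property
    def n_draws(self) -> int:
        return self.g0.shape[0]

    @property
    def n_traits(self) -> int:
        return self.g0.shape[1]

    def var_additive(self, trait: int = 0) -> np.ndarray:
        return self.g0[:, trait, trait]

    def var_herd(self, trait: int = 0) -> np.ndarray:
        return self.h0[:, trait, trait]

    def var_residual(self, trait: int = 0) -> np.ndarray:
        return self.r0[:, trait, trait]


@dataclass
class PosteriorSummary:
    mean: float
    hpd95_low: float
    hpd95_high: float
    sign_probability: float
    relevant: bool
    draws: np.ndarray = field(repr=False, default=None)


def build_a_inverse(ped: Pedigree) -> AInverse:
    """A-inverse by Henderson's rules with inbreeding accounted for.

    Inbreeding coefficients come from the Meuwissen–Luo recursion; each
    animal contributes 1/d_i (the inverse Mendelian-sampling variance) to
    the usual (animal, sire, dam) pattern.
    """
    n = len(ped)
    f = inbreeding_coefficients(ped)
    sires, dams = ped.parent_indices()
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = sires[i], dams[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (f[s] + f[d])
        elif s >= 0:
            di = 0.75 - 0.25 * f[s]
        elif d >= 0:
            di = 0.75 - 0.25 * f[d]
        else:
            di = 1.0
        alpha = 1.0 / di
        rows.append(i); cols.append(i); vals.append(alpha)
        for p in (s, d):
            if p >= 0:
                rows.append(i); cols.append(p); vals.append(-0.5 * alpha)
                rows.append(p); cols.append(i); vals.append(-0.5 * alpha)
                rows.append(p); cols.append(p); vals.append(0.25 * alpha)
        if s >= 0 and d >= 0:
            rows.append(s); cols.append(d); vals.append(0.25 * alpha)
            rows.append(d); cols.append(s); vals.append(0.25 * alpha)
    m = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    m.sum_duplicates()
    return AInverse(matrix=m, inbreeding=f, ids=ped.ids)


def _design_matrices(pheno: pd.DataFrame, ainv: AInverse, spec: ModelSpec):
    """Sparse W = [X Z1 Z2] with first-level fixed effects constrained to 0."""
    n = len(pheno)
    cols = []
    cols.append(sp.csr_matrix(np.ones((n, 1))))
    if spec.use_dim:
        dim = pheno["dim_class"].to_numpy(dtype=int)
        if dim.min() < 1 or dim.max() > N_DIM_CLASSES:
            raise ValueError("dim_class out of range 1..6")
        x = np.zeros((n, N_DIM_CLASSES - 1))
        for lvl in range(2, N_DIM_CLASSES + 1):
            x[dim == lvl, lvl - 2] = 1.0
        cols.append(sp.csr_matrix(x))
    if spec.use_parity:
        par = pheno["parity_class"].to_numpy(dtype=int)
        if par.min() < 1 or par.max() > N_PARITY_CLASSES:
            raise ValueError("parity_class out of range 1..4")
        x = np.zeros((n, N_PARITY_CLASSES - 1))
        for lvl in range(2, N_PARITY_CLASSES + 1):
            x[par == lvl, lvl - 2] = 1.0
        cols.append(sp.csr_matrix(x))
    xmat = sp.hstack(cols, format="csr")
    herd_levels, herd_idx = np.unique(pheno["herd_date_id"].to_numpy(), return_inverse=True)
    z1 = sp.csr_matrix((np.ones(n), (np.arange(n), herd_idx)),
                       shape=(n, len(herd_levels)))
    id_to_pos = {int(a): i for i, a in enumerate(ainv.ids)}
    try:
        animal_idx = np.array([id_to_pos[int(c)] for c in pheno["cow_id"]])
    except KeyError as exc:
        raise ValueError(f"cow id {exc.args[0]} not present in pedigree") from None
    z2 = sp.csr_matrix((np.ones(n), (np.arange(n), animal_idx)),
                       shape=(n, ainv.n))
    w = sp.hstack([xmat, z1, z2], format="csr")
    return w, xmat.shape[1], len(herd_levels)


def _check_response(y: np.ndarray, name: str = "y") -> None:
    if not np.all(np.isfinite(y[~np.isnan(y)])):
        raise ValueError(f"non-finite values in response {name}")
    obs = y[~np.isnan(y)]
    if obs.size < 3 or np.ptp(obs) == 0:
        raise ValueError(f"degenerate (constant or near-empty) response {name}")


def gibbs_univariate(y, pheno: pd.DataFrame, spec: ModelSpec,
                     ainv: AInverse) -> PosteriorDraws:
    """Single-trait Gibbs sampler; returns thinned post-burn-in draws.

    ``y`` is the response per phenotype row (NaN rows are dropped).  Flat
    priors on the variances lead to scaled inverse chi-square full
    conditionals with degrees of freedom (count - 2).
    """
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    pheno = pheno.loc[keep].reset_index(drop=True)
    _check_response(y)
    w, n_fixed, n_herd = _design_matrices(pheno, ainv, spec)
    n = len(y)
    q = ainv.n
    off_h, off_a = n_fixed, n_fixed + n_herd
    m = off_a + q
    wtw = (w.T @ w).tocsr()
    wty = w.T @ y
    ai = ainv.matrix

    rng = np.random.default_rng(spec.seed)
    vy = float(np.var(y))
    sigma_a2, sigma_h2, sigma_e2 = 0.25 * vy, 0.25 * vy, 0.5 * vy
    theta = np.zeros(m)
    n_out = (spec.iterations - spec.burn_in + spec.thin - 1) // spec.thin
    g0 = np.empty((n_out, 1, 1))
    h0 = np.empty((n_out, 1, 1))
    r0 = np.empty((n_out, 1, 1))
    loc_mean = np.zeros(m)
    kept = 0
    for it in range(spec.iterations):
        z = rng.standard_normal(m)
        _scan_uni(wtw.indptr, wtw.indices, wtw.data, wty,
                  ai.indptr, ai.indices, ai.data,
                  off_h, off_a, sigma_e2, sigma_h2, sigma_a2, theta, z)
        a = theta[off_a:]
        h = theta[off_h:off_a]
        e = y - w @ theta
        sigma_a2 = float(a @ (ai @ a)) / rng.chisquare(max(q - 2, 1))
        sigma_h2 = float(h @ h) / rng.chisquare(max(n_herd - 2, 1))
        sigma_e2 = float(e @ e) / rng.chisquare(max(n - 2, 1))
        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            g0[kept, 0, 0] = sigma_a2
            h0[kept, 0, 0] = sigma_h2
            r0[kept, 0, 0] = sigma_e2
            loc_mean += theta
            kept += 1
    loc_mean /= kept
    return PosteriorDraws(g0=g0[:kept], h0=h0[:kept], r0=r0[:kept],
                          traits=spec.traits[:1], location_mean=loc_mean[None, :])


def _draw_invwishart(rng, scale: np.ndarray, df: int, jitter_count: list) -> np.ndarray:
    for attempt in range(5):
        try:
            draw = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
            np.linalg.cholesky(draw)
            return draw
        except np.linalg.LinAlgError:
            jitter_count[0] += 1
            scale = scale + np.eye(scale.shape[0]) * 1e-8 * (10 ** attempt) * np.trace(scale)
    raise np.linalg.LinAlgError("could not draw a positive-definite covariance matrix")


def gibbs_bivariate(y1, y2, pheno: pd.DataFrame, spec: ModelSpec,
                    ainv: AInverse) -> PosteriorDraws:
    """Two-trait Gibbs sampler with inverse-Wishart variance updates.

    Records missing one trait are handled by data augmentation (the missing
    phenotype is drawn from its conditional given the other trait and the
    current effects); records missing both traits are dropped.
    """
    y = np.column_stack([np.asarray(y1, dtype=float), np.asarray(y2, dtype=float)])
    keep = ~np.all(np.isnan(y), axis=1)
    y = y[keep]
    pheno = pheno.loc[keep].reset_index(drop=True)
    _check_response(y[:, 0], "trait 1")
    _check_response(y[:, 1], "trait 2")
    w, n_fixed, n_herd = _design_matrices(pheno, ainv, spec)
    n = len(y)
    q = ainv.n
    off_h, off_a = n_fixed, n_fixed + n_herd
    m = off_a + q
    wtw = (w.T @ w).tocsr()
    ai = ainv.matrix
    miss = np.isnan(y)
    any_missing = bool(miss.any())

    rng = np.random.default_rng(spec.seed)
    yw = y.copy()
    for t in range(2):
        col = yw[:, t]
        col[np.isnan(col)] = np.nanmean(col)
    v0 = np.diag(np.var(yw, axis=0))
    g0c, h0c, r0c = 0.25 * v0, 0.25 * v0, 0.5 * v0
    theta = np.zeros((m, 2))
    n_out = (spec.iterations - spec.burn_in + spec.thin - 1) // spec.thin
    g0 = np.empty((n_out, 2, 2))
    h0 = np.empty((n_out, 2, 2))
    r0 = np.empty((n_out, 2, 2))
    loc_mean = np.zeros((m, 2))
    kept = 0
    jitter = [0]
    for it in range(spec.iterations):
        if any_missing:
            fitted = w @ theta
            for t in range(2):
                o = 1 - t
                rows = miss[:, t] & ~miss[:, o]
                if rows.any():
                    cond_var = r0c[t, t] - r0c[t, o] ** 2 / r0c[o, o]
                    mean = fitted[rows, t] + r0c[t, o] / r0c[o, o] * (
                        yw[rows, o] - fitted[rows, o])
                    yw[rows, t] = mean + rng.standard_normal(rows.sum()) * np.sqrt(
                        max(cond_var, 1e-12))
        wty = w.T @ yw
        rinv = np.linalg.inv(r0c)
        ginv = np.linalg.inv(g0c)
        hinv = np.linalg.inv(h0c)
        z = rng.standard_normal((m, 2))
        _scan_biv(wtw.indptr, wtw.indices, wtw.data, wty,
                  ai.indptr, ai.indices, ai.data,
                  off_h, off_a, rinv, ginv, hinv, theta, z)
        a = theta[off_a:]
        h = theta[off_h:off_a]
        e = yw - w @ theta
        s_a = a.T @ (ai @ a)
        s_h = h.T @ h
        s_e = e.T @ e
        g0c = _draw_invwishart(rng, s_a, max(q - 3, 2), jitter)
        h0c = _draw_invwishart(rng, s_h, max(n_herd - 3, 2), jitter)
        r0c = _draw_invwishart(rng, s_e, max(n - 3, 2), jitter)
        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            g0[kept] = g0c
            h0[kept] = h0c
            r0[kept] = r0c
            loc_mean += theta
            kept += 1
    loc_mean /= kept
    if jitter[0]:
        logger.warning("re-drew %d non-positive-definite covariance draws with jitter",
                       jitter[0])
    return PosteriorDraws(g0=g0[:kept], h0=h0[:kept], r0=r0[:kept],
                          traits=spec.traits[:2], location_mean=loc_mean.T,
                          n_jittered=jitter[0])


def posterior_summaries(samples) -> PosteriorSummary:
    """Posterior mean, shortest 95% HPD interval, and sign probability.

    The sign probability is the fraction of draws sharing the sign of the
    posterior mean; an estimate is flagged relevant when it exceeds 0.95.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 100:
        raise ValueError("need at least 100 posterior draws to summarize")
    mean = float(samples.mean())
    srt = np.sort(samples)
    n = srt.size
    n_in = max(int(np.ceil(0.95 * n)), 1)
    widths = srt[n_in - 1:] - srt[:n - n_in + 1]
    i = int(np.argmin(widths))
    lo, hi = float(srt[i]), float(srt[i + n_in - 1])
    if mean >= 0:
        p = float(np.mean(samples > 0) + 0.5 * np.mean(samples == 0))
    else:
        p = float(np.mean(samples < 0) + 0.5 * np.mean(samples == 0))
    if np.all(samples == samples[0]):
        p = 1.0
    return PosteriorSummary(mean=mean, hpd95_low=lo, hpd95_high=hi,
                            sign_probability=p, relevant=p > 0.95, draws=samples)


def heritability(draws: PosteriorDraws, trait: int = 0) -> PosteriorSummary:
    """Intra-herd heritability: per-draw sigma_a^2/(sigma_a^2 + sigma_e^2)."""
    sa = draws.var_additive(trait)
    se = draws.var_residual(trait)
    return posterior_summaries(sa / (sa + se))


def herd_fraction(draws: PosteriorDraws, trait: int = 0) -> PosteriorSummary:
    """Herd/date share of phenotypic variance, per draw."""
    sa = draws.var_additive(trait)
    sh = draws.var_herd(trait)
    se = draws.var_residual(trait)
    return posterior_summaries(sh / (sa + sh + se))


def component_correlations(draws: PosteriorDraws) -> dict[str, PosteriorSummary]:
    """Per-draw genetic, herd, residual and phenotypic correlations.

    The phenotypic correlation sums component covariances and divides by
    the product of the traits' total (additive + herd + residual) standard
    deviations.
    """
    if draws.n_traits != 2:
        raise ValueError("component correlations require bivariate draws")
    out = {}
    skipped = 0
    comps = {"r_G": draws.g0, "r_H": draws.h0, "r_E": draws.r0}
    valid = np.ones(draws.n_draws, dtype=bool)
    for mats in comps.values():
        valid &= (mats[:, 0, 0] > 0) & (mats[:, 1, 1] > 0)
    skipped = int((~valid).sum())
    if skipped:
        logger.warning("skipped %d draws with a zero variance component", skipped)
    for name, mats in comps.items():
        mats = mats[valid]
        r = mats[:, 0, 1] / np.sqrt(mats[:, 0, 0] * mats[:, 1, 1])
        out[name] = posterior_summaries(r)
    g, h, r_ = draws.g0[valid], draws.h0[valid], draws.r0[valid]
    cov_p = g[:, 0, 1] + h[:, 0, 1] + r_[:, 0, 1]
    var1 = g[:, 0, 0] + h[:, 0, 0] + r_[:, 0, 0]
    var2 = g[:, 1, 1] + h[:, 1, 1] + r_[:, 1, 1]
    out["r_P"] = posterior_summaries(cov_p / np.sqrt(var1 * var2))
    return out
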
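"""Whole-spectrum Bayesian calibration and repeated training–testing.

Any phenotype is regressed on the full standardized absorbance spectrum
with a spike-and-slab ("BayesB") prior: each wavelength coefficient is zero
with probability ``pi_zero`` and otherwise normal with its own variance,
which carries a scaled-inverse-chi-square prior.  Accuracy is assessed by
repeated random 80/20 training–testing; only out-of-fold predictions ever
reach the downstream genetic analyses, with repeated test predictions
averaged per sample and never-tested samples dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._gibbs import _bayesb_chain
from .traits import FAProfile, methane_intensity_milk, methane_yield

__all__ = [
    "BayesBChain",
    "CalibrationModel",
    "CVResult",
    "standardize_spectra",
    "fit_bayesb",
    "repeated_splits",
    "crossvalidate",
    "assemble_validation_db",
    "indirect_predictions",
    "DIRECT_PREDICTIONS",
    "INDIRECT_PREDICTIONS",
    "INFORMATIVE_TRAITS",
]

logger = logging.getLogger(__name__)

DIRECT_PREDICTIONS = ("ch4_dm_ir", "ch4_cm_ir", "ch4_cy_curd_ir",
                      "ch4_cy_solids_ir", "dch4_ir")
INDIRECT_PREDICTIONS = ("ch4_dm_fair", "ch4_cm_fair", "ch4_cy_curd_ir_ir",
                        "ch4_cy_solids_ir_ir", "dch4_cm_ir", "dch4_cm_fair",
                        "dch4_ir_ir", "dch4_ir_fair")
#: component traits whose spectral predictions feed the indirect procedures
INFORMATIVE_TRAITS = ("c4_0", "c16_0iso", "c18_1_t10", "c18_1_t11", "c18_1_c9",
                      "c18_2_c9c12", "cy_curd_pct", "cy_solids_pct", "dcmy")


@dataclass
class BayesBChain:
    """Sampler settings and hyperparameters for one calibration fit."""

    iterations: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    pi_zero: float = 0.95
    df_slab: float = 5.0
    df_residual: float = 5.0
    r2_prior: float = 0.5

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("chain iterations must exceed burn-in")
        if not 0.0 <= self.pi_zero < 1.0:
            raise ValueError("pi_zero must lie in [0, 1)")


def standardize_spectra(values: np.ndarray, ddof: int = 1):
    """Center and scale each wavelength column to mean 0, sd 1.

    Returns ``(standardized, column_means, column_sds)``.  A constant
    column gets sd 1 (so it standardizes to all zeros) with a warning; the
    returned constants invert the transform for non-constant columns.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=ddof)
    constant = sds == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant spectral column(s); sd set to 1")
        sds = np.where(constant, 1.0, sds)
    return (values - means) / sds, means, sds


@dataclass
class CalibrationModel:
    """Fitted spectral regression: intercept, per-wavelength coefficients,
    the training-set standardization constants, and posterior inclusion
    frequencies."""

    intercept: float
    coefficients: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    residual_variance: float
    inclusion_probs: np.ndarray
    chain: BayesBChain
    seed: int

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        """Predict from raw (unstandardized) absorbances."""
        x = (np.atleast_2d(np.asarray(spectra, dtype=float))
             - self.column_means) / self.column_sds
        return self.intercept + x @ self.coefficients


def fit_bayesb(y, spectra, chain: BayesBChain | None = None,
               seed: int = 0) -> CalibrationModel:
    """Fit the spike-and-slab spectral regression by Gibbs sampling.

    ``spectra`` are raw absorbances; standardization constants are computed
    on this training set and stored in the model, so cross-validated use
    never leaks test-set information.
    """
    chain = chain or BayesBChain()
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype values")
    x, means, sds = standardize_spectra(spectra)
    n, p = x.shape
    if len(y) != n:
        raise ValueError("phenotype / spectra length mismatch")
    vy = float(np.var(y))
    if vy == 0:
        # no signal to model: intercept-only
        return CalibrationModel(intercept=float(y[0]), coefficients=np.zeros(p),
                                column_means=means, column_sds=sds,
                                residual_variance=0.0,
                                inclusion_probs=np.zeros(p), chain=chain, seed=seed)
    nu = chain.df_slab
    s0 = chain.r2_prior * vy / max((1.0 - chain.pi_zero) * p, 1.0) * (nu + 2.0) / nu
    nu_e = chain.df_residual
    se0 = (1.0 - chain.r2_prior) * vy * (nu_e + 2.0) / nu_e
    rng = np.random.default_rng(seed)
    iters = chain.iterations
    z_norm = rng.standard_normal((iters, p + 1))
    z_chi_b = rng.chisquare(nu + 1.0, (iters, p))
    z_chi_sig = rng.chisquare(nu, (iters, p))
    z_chi_e = rng.chisquare(n + nu_e, iters)
    u_incl = rng.random((iters, p))
    beta_mean = np.zeros(p)
    mu_var = np.zeros(2)
    incl_mean = np.zeros(p)
    xf = np.asfortranarray(x)
    xtx_diag = np.einsum("ij,ij->j", x, x)
    _bayesb_chain(xtx_diag, xf, y.astype(float), iters, chain.burn_in,
                  chain.thin, chain.pi_zero, nu, s0, nu_e, se0,
                  z_norm, z_chi_b, z_chi_sig, z_chi_e, u_incl,
                  beta_mean, mu_var, incl_mean)
    return CalibrationModel(intercept=float(mu_var[0]), coefficients=beta_mean,
                            column_means=means, column_sds=sds,
                            residual_variance=float(mu_var[1]),
                            inclusion_probs=incl_mean, chain=chain, seed=seed)


@dataclass
class CVResult:
    """Out-of-fold predictions from repeated random train/test splits."""

    observed: np.ndarray
    test_indices: list = field(repr=False, default_factory=list)
    test_predictions: list = field(repr=False, default_factory=list)
    r2_cv: float = np.nan
    rmse_cv: float = np.nan
    seed: int = 0

    @property
    def repetitions(self) -> int:
        return len(self.test_indices)

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        idx = np.concatenate(self.test_indices)
        pred = np.concatenate(self.test_predictions)
        return self.observed[idx], pred

    def times_tested(self) -> np.ndarray:
        counts = np.zeros(len(self.observed), dtype=int)
        for idx in self.test_indices:
            counts[idx] += 1
        return counts

    def mean_test_prediction(self) -> np.ndarray:
        """Per-sample mean of out-of-fold predictions; NaN if never tested."""
        total = np.zeros(len(self.observed))
        counts = self.times_tested()
        for idx, pred in zip(self.test_indices, self.test_predictions):
            total[idx] += pred
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, total / np.maximum(counts, 1), np.nan)


def repeated_splits(n: int, repetitions: int = 10, test_frac: float = 0.2,
                    seed: int = 0):
    """Independent random train/test splits; yields (train_idx, test_idx).

    With R repetitions a sample avoids every test subset with probability
    (1 - test_frac)^R, so about 10.7% of samples are never tested at the
    default 10 repetitions of 80/20.
    """
    n_test = int(round(n * test_frac))
    if n_test < 1 or n_test >= n:
        raise ValueError("test fraction leaves an empty train or test set")
    rng = np.random.default_rng(seed)
    for _ in range(repetitions):
        perm = rng.permutation(n)
        yield np.sort(perm[n_test:]), np.sort(perm[:n_test])


def crossvalidate(y, spectra, repetitions: int = 10, test_frac: float = 0.2,
                  chain: BayesBChain | None = None, seed: int = 0) -> CVResult:
    """Repeated random train/test evaluation of the spectral calibration.

    Each repetition draws an independent random split, fits on the training
    fraction and predicts the held-out samples.  R2 is the squared Pearson
    correlation between pooled out-of-fold predictions and observations;
    RMSE is the root mean squared pooled out-of-fold error.
    """
    y = np.asarray(y, dtype=float)
    spectra = np.asarray(spectra, dtype=float)
    n = len(y)
    if n < 25:
        raise ValueError("need at least 25 samples for train/test evaluation")
    rng = np.random.default_rng(seed)
    result = CVResult(observed=y, seed=seed)
    for train_idx, test_idx in repeated_splits(n, repetitions, test_frac,
                                               seed=int(rng.integers(2 ** 31))):
        model = fit_bayesb(y[train_idx], spectra[train_idx], chain=chain,
                           seed=int(rng.integers(2 ** 31)))
        result.test_indices.append(test_idx)
        result.test_predictions.append(model.predict(spectra[test_idx]))
    obs, pred = result.pooled()
    result.rmse_cv = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if np.std(pred) > 0 and np.std(obs) > 0:
        result.r2_cv = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    else:
        result.r2_cv = 0.0
    return result


def assemble_validation_db(cv_by_trait: dict[str, CVResult],
                           sample_ids=None) -> pd.DataFrame:
    """Inflation-safe phenotype table from out-of-fold predictions only.

    Per trait, a sample's phenotype is the mean of its out-of-fold
    predictions across repetitions; samples never present in any test
    subset carry NaN and rows with no retained trait at all are dropped.
    """
    if not cv_by_trait:
        raise ValueError("no cross-validation results supplied")
    n = len(next(iter(cv_by_trait.values())).observed)
    if sample_ids is None:
        sample_ids = np.arange(n)
    cols = {}
    for trait, cv in cv_by_trait.items():
        if len(cv.observed) != n:
            raise ValueError("cross-validation results cover different sample sets")
        cols[trait] = cv.mean_test_prediction()
    out = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))
    retained = out.notna().sum()
    for trait, count in retained.items():
        logger.info("validation database: trait %s retains %d/%d samples",
                    trait, count, n)
    out = out.dropna(how="all")
    if out.empty:
        raise ValueError("no sample was ever tested; validation database is empty")
    return out


def _fa_from_columns(df: pd.DataFrame) -> FAProfile:
    clipped = {}
    for name in ("c4_0", "c16_0iso", "c18_1_t10", "c18_1_t11", "c18_1_c9",
                 "c18_2_c9c12"):
        vals = df[name].to_numpy(dtype=float)
        neg = vals < 0
        if neg.any():
            logger.info("clipped %d negative predicted values of %s at 0",
                        int(neg.sum()), name)
        clipped[name] = np.clip(vals, 0.0, None)
    return FAProfile(**clipped)


def indirect_predictions(direct: pd.DataFrame, informative: pd.DataFrame,
                         records: pd.DataFrame) -> pd.DataFrame:
    """The eight indirect methane predictions from component predictions.

    ``direct`` holds the five directly predicted traits (columns named as
    in :data:`DIRECT_PREDICTIONS`), ``informative`` the spectra-predicted
    component traits (six fatty acids, the two cheese-yield percentages and
    corrected milk yield ``dcmy``), and ``records`` the measured phenotypes
    (needs ``dmy`` and measured ``dcmy``).  All three frames must share an
    index; NaN components propagate to NaN predictions, and non-positive
    predicted cheese yields invalidate the affected cheese-intensity
    prediction only.
    """
    idx = direct.index
    if not (informative.index.equals(idx) and records.index.equals(idx)):
        raise ValueError("direct, informative and measured frames must share an index")
    out = pd.DataFrame(index=idx)
    fa = _fa_from_columns(informative.fillna(np.nan))
    out["ch4_dm_fair"] = methane_yield(fa)
    out["ch4_cm_fair"] = methane_intensity_milk(fa)
    dcmy_meas = records["dcmy"].to_numpy(dtype=float)
    dcmy_pred = informative["dcmy"].to_numpy(dtype=float)
    ch4_cm_ir = direct["ch4_cm_ir"].to_numpy(dtype=float)
    dch4_from_cm_ir = ch4_cm_ir * dcmy_meas
    dmy = records["dmy"].to_numpy(dtype=float)
    for tail, cy_col in (("curd", "cy_curd_pct"), ("solids", "cy_solids_pct")):
        cy = informative[cy_col].to_numpy(dtype=float)
        bad = ~(cy > 0)
        n_bad = int((bad & np.isfinite(cy)).sum())
        if n_bad:
            logger.warning("%d sample(s) excluded from ch4_cy_%s_ir_ir: "
                           "non-positive predicted cheese yield", n_bad, tail)
        dcy = np.where(bad, np.nan, dmy * cy / 100.0)
        out[f"ch4_cy_{tail}_ir_ir"] = dch4_from_cm_ir / dcy
    out["dch4_cm_ir"] = dcmy_meas * ch4_cm_ir
    out["dch4_cm_fair"] = dcmy_meas * out["ch4_cm_fair"]
    out["dch4_ir_ir"] = dcmy_pred * ch4_cm_ir
    out["dch4_ir_fair"] = dcmy_pred * out["ch4_cm_fair"]
    n_missing = int(out.isna().any(axis=1).sum())
    if n_missing:
        logger.info("%d sample(s) have at least one undefined indirect prediction",
                    n_missing)
    return out
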
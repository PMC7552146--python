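"""Synthetic herd survey: pedigrees, effects, phenotypes and spectra.

Generates a multi-generation pedigree with reused sires, breeding values by
Mendelian-sampling recursion (exact for any pedigree and linear in its
size), herd/date and residual effects with known variance partitions, milk
phenotype records, and spectra carrying a learnable linear signal for the
latent traits.  Everything is driven by one seeded generator so runs are
fully reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import Pedigree, inbreeding_coefficients
from .traits import FAProfile, MilkRecord

__all__ = [
    "SimulationConfig",
    "TrueValues",
    "simulate_pedigree",
    "simulate_effects",
    "simulate_records",
    "simulate_records_frame",
    "simulate_single_trait",
    "simulate_trait_pair",
    "default_spectral_loadings",
]

logger = logging.getLogger(__name__)

FA_NAMES = ("c4_0", "c16_0iso", "c18_1_t10", "c18_1_t11", "c18_1_c9", "c18_2_c9c12")
YIELD_NAMES = ("dmy", "fat_pct", "protein_pct", "cy_curd_pct", "cy_solids_pct")
BASE_TRAITS = FA_NAMES + YIELD_NAMES

_DEFAULT_FA_MEANS = {"c4_0": 3.2, "c16_0iso": 0.25, "c18_1_t10": 0.3,
                     "c18_1_t11": 0.7, "c18_1_c9": 17.0, "c18_2_c9c12": 2.0}
_DEFAULT_FA_SDS = {"c4_0": 0.35, "c16_0iso": 0.05, "c18_1_t10": 0.1,
                   "c18_1_t11": 0.3, "c18_1_c9": 2.2, "c18_2_c9c12": 0.35}
_DEFAULT_YIELD_MEANS = {"dmy": 24.8, "fat_pct": 4.22, "protein_pct": 3.70,
                        "cy_curd_pct": 14.96, "cy_solids_pct": 7.21}
_DEFAULT_YIELD_SDS = {"dmy": 8.0, "fat_pct": 0.70, "protein_pct": 0.43,
                      "cy_curd_pct": 1.89, "cy_solids_pct": 0.93}


class ConfigurationError(ValueError):
    """Impossible or inconsistent simulation settings."""


@dataclass
class SimulationConfig:
    """Settings for the synthetic survey.

    Per-trait variances default to fractions (``var_fractions`` = additive,
    herd/date, residual shares) of each trait's squared scale; explicit
    per-trait overrides go in ``true_var_additive`` etc. as dicts.
    """

    n_herds: int = 85
    cows_per_herd: int = 15
    n_founders: int = 170
    n_generations: int = 4
    n_sires_per_gen: int = 66
    n_dams_per_gen: int = 2400
    var_fractions: tuple[float, float, float] = (0.10, 0.55, 0.35)
    true_var_additive: dict | float | None = None
    true_var_herd: dict | float | None = None
    true_var_residual: dict | float | None = None
    genetic_correlation: float = 0.0
    herd_correlation: float = 0.0
    residual_correlation: float = 0.0
    trait_names: tuple[str, ...] = BASE_TRAITS
    fa_means: dict = field(default_factory=lambda: dict(_DEFAULT_FA_MEANS))
    fa_sds: dict = field(default_factory=lambda: dict(_DEFAULT_FA_SDS))
    yield_means: dict = field(default_factory=lambda: dict(_DEFAULT_YIELD_MEANS))
    yield_sds: dict = field(default_factory=lambda: dict(_DEFAULT_YIELD_SDS))
    dim_class_effects: tuple[float, ...] = (0.0, 0.08, 0.12, 0.10, 0.05, 0.0)
    parity_class_effects: tuple[float, ...] = (0.0, 0.10, 0.15, 0.18)
    n_wavelengths: int = 1060
    spectral_loadings: np.ndarray | None = None
    spectral_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_herds", "cows_per_herd", "n_sires_per_gen", "n_dams_per_gen",
                     "n_wavelengths"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_founders < 2:
            raise ConfigurationError("need at least 2 founders (one sire, one dam)")
        if self.n_generations < 0:
            raise ConfigurationError("n_generations must be >= 0")
        for r in (self.genetic_correlation, self.herd_correlation,
                  self.residual_correlation):
            if abs(r) > 1:
                raise ConfigurationError("correlations must lie in [-1, 1]")
        if any(f < 0 for f in self.var_fractions):
            raise ConfigurationError("variance fractions must be non-negative")
        if self.spectral_noise_sd < 0:
            raise ConfigurationError("spectral noise sd must be >= 0")

    @property
    def n_cows(self) -> int:
        return self.n_herds * self.cows_per_herd

    def trait_scale(self, trait: str) -> float:
        if trait in self.fa_sds:
            return float(self.fa_sds[trait])
        if trait in self.yield_sds:
            return float(self.yield_sds[trait])
        return 1.0

    def trait_mean(self, trait: str) -> float:
        if trait in self.fa_means:
            return float(self.fa_means[trait])
        if trait in self.yield_means:
            return float(self.yield_means[trait])
        return 0.0

    def _lookup(self, override, frac: float, trait: str) -> float:
        if override is None:
            return frac * self.trait_scale(trait) ** 2
        if isinstance(override, dict):
            if trait in override:
                return float(override[trait])
            return frac * self.trait_scale(trait) ** 2
        return float(override)

    def variances(self, trait: str) -> tuple[float, float, float]:
        """(additive, herd, residual) variance of a trait."""
        fa_, fh_, fe_ = self.var_fractions
        out = (self._lookup(self.true_var_additive, fa_, trait),
               self._lookup(self.true_var_herd, fh_, trait),
               self._lookup(self.true_var_residual, fe_, trait))
        if any(v < 0 for v in out):
            raise ConfigurationError("variances must be non-negative")
        return out


@dataclass
class TrueValues:
    """Ground-truth effects underlying the simulated phenotypes."""

    breeding_values: np.ndarray   # (n_animals, n_traits)
    herd_effects: np.ndarray      # (n_herds, n_traits)
    residuals: np.ndarray         # (n_cows, n_traits)
    trait_names: tuple[str, ...]


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Multi-generation pedigree whose final generation is the phenotyped cows.

    Founders (generation 0) have unknown parents; every later animal has
    both parents drawn from the previous generation, so each phenotyped cow
    has ``n_generations`` complete ancestor generations.  Sires are sampled
    with uneven weights so that half-sib families of widely varying size
    arise.  Phenotyped cows are the last ``n_herds * cows_per_herd`` records.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[tuple[int, int, int]] = []
    next_id = 1
    n_f_males = max(cfg.n_founders // 3, 1)
    males = list(range(next_id, next_id + n_f_males))
    females = list(range(next_id + n_f_males, next_id + cfg.n_founders))
    for i in range(cfg.n_founders):
        records.append((next_id, 0, 0))
        next_id += 1
    if cfg.n_generations > 0 and not females:
        raise ConfigurationError("founder generation has no females")
    for gen in range(1, cfg.n_generations + 1):
        final = gen == cfg.n_generations
        if final:
            n_males, n_females = 0, cfg.n_cows
        else:
            n_males, n_females = cfg.n_sires_per_gen, cfg.n_dams_per_gen
        sire_pool = np.asarray(males)
        # heavy-tailed usage weights -> family sizes from a couple to dozens
        w = rng.exponential(size=len(sire_pool)) ** 2
        w /= w.sum()
        new_males, new_females = [], []
        for k in range(n_males + n_females):
            sire = int(rng.choice(sire_pool, p=w))
            dam = int(rng.choice(females))
            records.append((next_id, sire, dam))
            (new_males if k < n_males else new_females).append(next_id)
            next_id += 1
        males, females = new_males, new_females
    return Pedigree(tuple(records))


def _chol(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        # allow PSD boundary cases (zero variance, |r| = 1)
        w, v = np.linalg.eigh(cov)
        if w.min() < -1e-10 * max(w.max(), 1.0):
            raise ValueError("genetic covariance matrix is not positive semi-definite")
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _breeding_values(ped: Pedigree, g0: np.ndarray, rng: np.random.Generator,
                     n_rep: int = 1) -> np.ndarray:
    """(n_rep, n_animals, n_traits) breeding values by Mendelian recursion."""
    n = len(ped)
    t = g0.shape[0]
    chol = _chol(g0)
    f = inbreeding_coefficients(ped)
    sires, dams = ped.parent_indices()
    bv = np.empty((n_rep, n, t))
    z = rng.standard_normal((n_rep, n, t)) @ chol.T
    for i in range(n):
        s, d = sires[i], dams[i]
        if s < 0 and d < 0:
            bv[:, i] = z[:, i]
        elif s < 0 or d < 0:
            p = s if s >= 0 else d
            bv[:, i] = 0.5 * bv[:, p] + np.sqrt(0.75 - 0.25 * f[p]) * z[:, i]
        else:
            scale = np.sqrt(0.5 * (1.0 - 0.5 * (f[s] + f[d])))
            bv[:, i] = 0.5 * (bv[:, s] + bv[:, d]) + scale * z[:, i]
    return bv


def _component_cov(variances: np.ndarray, corr: float) -> np.ndarray:
    t = len(variances)
    cov = np.diag(variances).astype(float)
    if t == 2 and corr != 0.0:
        cov[0, 1] = cov[1, 0] = corr * np.sqrt(variances[0] * variances[1])
    return cov


def simulate_effects(ped: Pedigree, cfg: SimulationConfig,
                     n_rep: int = 1) -> TrueValues:
    """Breeding values, herd/date effects and residuals for all traits.

    When exactly two traits are configured, the configured genetic, herd
    and residual correlations apply between them; otherwise components are
    independent across traits.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    traits = cfg.trait_names
    var_a = np.array([cfg.variances(t)[0] for t in traits])
    var_h = np.array([cfg.variances(t)[1] for t in traits])
    var_e = np.array([cfg.variances(t)[2] for t in traits])
    g0 = _component_cov(var_a, cfg.genetic_correlation)
    h0 = _component_cov(var_h, cfg.herd_correlation)
    r0 = _component_cov(var_e, cfg.residual_correlation)
    bv = _breeding_values(ped, g0, rng, n_rep)
    herd = rng.standard_normal((cfg.n_herds, len(traits))) @ _chol(h0).T
    resid = rng.standard_normal((cfg.n_cows, len(traits))) @ _chol(r0).T
    if n_rep == 1:
        bv = bv[0]
    return TrueValues(breeding_values=bv, herd_effects=herd, residuals=resid,
                      trait_names=traits)


def default_spectral_loadings(cfg: SimulationConfig, n_latent: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Gaussian-bump loadings: each latent trait hits 20 random wavelengths."""
    p = cfg.n_wavelengths
    grid = np.arange(p)
    loadings = np.zeros((n_latent, p))
    for t in range(n_latent):
        centers = rng.choice(p, size=min(20, p), replace=False)
        amps = rng.uniform(0.5, 1.5, size=len(centers)) * rng.choice(
            [-1.0, 1.0], size=len(centers))
        for c, a in zip(centers, amps):
            loadings[t] += a * np.exp(-0.5 * ((grid - c) / 3.0) ** 2)
    return loadings


def simulate_records_frame(ped: Pedigree, tv: TrueValues,
                           cfg: SimulationConfig) -> pd.DataFrame:
    """Phenotype table for the final-generation cows, spectra included.

    Each base trait is mean + class shifts + breeding value + herd effect +
    residual; fatty acids are truncated at zero (the truncation rate is
    logged and should stay below 1% at default settings).  Spectral columns
    are named ``wl_0000 .. wl_1059``.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    n_cows = cfg.n_cows
    cow_ids = ped.ids[-n_cows:]
    herd_ids = np.repeat(np.arange(1, cfg.n_herds + 1), cfg.cows_per_herd)
    parity = rng.integers(1, 5, size=n_cows)
    dim = rng.integers(1, 7, size=n_cows)
    traits = tv.trait_names
    bv_cows = tv.breeding_values[-n_cows:]
    df = pd.DataFrame({"cow_id": cow_ids, "herd_date_id": herd_ids,
                       "parity_class": parity, "dim_class": dim})
    n_trunc = 0
    for j, trait in enumerate(traits):
        sd = cfg.trait_scale(trait)
        shifts = (np.asarray(cfg.dim_class_effects)[dim - 1]
                  + np.asarray(cfg.parity_class_effects)[parity - 1]) * sd
        vals = (cfg.trait_mean(trait) + shifts + bv_cows[:, j]
                + tv.herd_effects[herd_ids - 1, j] + tv.residuals[:, j])
        if trait in FA_NAMES:
            n_trunc += int((vals < 0).sum())
            vals = np.clip(vals, 0.0, None)
        if trait == "dmy":
            vals = np.clip(vals, 0.1, None)
        if trait in ("fat_pct", "protein_pct"):
            vals = np.clip(vals, 0.05, 14.95)
        df[trait] = vals
    if "cy_curd_pct" in df and "cy_solids_pct" in df:
        df["cy_curd_pct"] = np.clip(df["cy_curd_pct"], 0.2, None)
        df["cy_solids_pct"] = np.clip(df["cy_solids_pct"], 0.1,
                                      0.99 * df["cy_curd_pct"])
    rate = n_trunc / max(n_cows * len(FA_NAMES), 1)
    if rate > 0:
        logger.info("truncated %.3f%% of fatty-acid values at 0", 100 * rate)
    if rate > 0.01:
        logger.warning("fatty-acid truncation rate %.1f%% exceeds 1%%", 100 * rate)

    # latent channels for the spectra: base traits plus derived yields
    latent = df[list(traits)].to_numpy(dtype=float).copy()
    if all(c in df for c in ("dmy", "fat_pct", "protein_pct",
                             "cy_curd_pct", "cy_solids_pct")):
        cf = 0.337 + 0.116 * df["fat_pct"] + 0.06 * df["protein_pct"]
        extra = np.column_stack([df["dmy"] * cf,
                                 df["dmy"] * df["cy_curd_pct"] / 100.0,
                                 df["dmy"] * df["cy_solids_pct"] / 100.0])
        latent = np.hstack([latent, extra])
    latent = (latent - latent.mean(axis=0)) / np.where(latent.std(axis=0) > 0,
                                                       latent.std(axis=0), 1.0)
    loadings = cfg.spectral_loadings
    if loadings is None:
        loadings = default_spectral_loadings(cfg, latent.shape[1], rng)
    if loadings.shape != (latent.shape[1], cfg.n_wavelengths):
        raise ConfigurationError(
            f"spectral_loadings must have shape ({latent.shape[1]}, {cfg.n_wavelengths})")
    spectra = latent @ loadings
    if cfg.spectral_noise_sd > 0:
        spectra = spectra + rng.standard_normal(spectra.shape) * cfg.spectral_noise_sd
    spec_cols = pd.DataFrame(spectra,
                             columns=[f"wl_{i:04d}" for i in range(cfg.n_wavelengths)])
    return pd.concat([df.reset_index(drop=True), spec_cols], axis=1)


def simulate_records(ped: Pedigree, tv: TrueValues,
                     cfg: SimulationConfig) -> list[MilkRecord]:
    """List-of-records view of :func:`simulate_records_frame`."""
    df = simulate_records_frame(ped, tv, cfg)
    wl_cols = [c for c in df.columns if c.startswith("wl_")]
    out = []
    for _, row in df.iterrows():
        fa = FAProfile(**{k: float(row[k]) for k in FA_NAMES})
        out.append(MilkRecord(
            cow_id=int(row["cow_id"]), herd_date_id=int(row["herd_date_id"]),
            parity_class=int(row["parity_class"]), dim_class=int(row["dim_class"]),
            dmy=float(row["dmy"]), fat_pct=float(row["fat_pct"]),
            protein_pct=float(row["protein_pct"]),
            cy_curd_pct=float(row["cy_curd_pct"]),
            cy_solids_pct=float(row["cy_solids_pct"]), fa=fa,
            spectrum=row[wl_cols].to_numpy(dtype=float)))
    return out


def _single_trait_cfg(cfg: SimulationConfig, var_a, var_h, var_e,
                      names: tuple[str, ...]) -> SimulationConfig:
    return replace(cfg, trait_names=names,
                   true_var_additive={n: v for n, v in zip(names, np.atleast_1d(var_a))},
                   true_var_herd={n: v for n, v in zip(names, np.atleast_1d(var_h))},
                   true_var_residual={n: v for n, v in zip(names, np.atleast_1d(var_e))})


def simulate_single_trait(ped: Pedigree, cfg: SimulationConfig,
                          var_additive: float, var_herd: float,
                          var_residual: float, mean: float = 0.0):
    """One generic trait with a known variance partition.

    Returns ``(pheno, tv)`` where ``pheno`` has columns cow_id,
    herd_date_id, dim_class, parity_class and ``y``.  Intended for sampler
    parameter-recovery experiments.
    """
    sub = _single_trait_cfg(cfg, var_additive, var_herd, var_residual, ("y",))
    tv = simulate_effects(ped, sub)
    rng = np.random.default_rng(cfg.seed + 3)
    n_cows = cfg.n_cows
    herd_ids = np.repeat(np.arange(1, cfg.n_herds + 1), cfg.cows_per_herd)
    pheno = pd.DataFrame({
        "cow_id": ped.ids[-n_cows:],
        "herd_date_id": herd_ids,
        "parity_class": rng.integers(1, 5, size=n_cows),
        "dim_class": rng.integers(1, 7, size=n_cows),
    })
    pheno["y"] = (mean + tv.breeding_values[-n_cows:, 0]
                  + tv.herd_effects[herd_ids - 1, 0] + tv.residuals[:, 0])
    return pheno, tv


def simulate_trait_pair(ped: Pedigree, cfg: SimulationConfig,
                        var_additive, var_herd, var_residual,
                        genetic_correlation: float,
                        herd_correlation: float = 0.0,
                        residual_correlation: float = 0.0):
    """Two traits with known variance partitions and component correlations."""
    va = np.broadcast_to(np.asarray(var_additive, dtype=float), (2,))
    vh = np.broadcast_to(np.asarray(var_herd, dtype=float), (2,))
    ve = np.broadcast_to(np.asarray(var_residual, dtype=float), (2,))
    sub = _single_trait_cfg(cfg, va, vh, ve, ("y1", "y2"))
    sub = replace(sub, genetic_correlation=genetic_correlation,
                  herd_correlation=herd_correlation,
                  residual_correlation=residual_correlation)
    tv = simulate_effects(ped, sub)
    rng = np.random.default_rng(cfg.seed + 3)
    n_cows = cfg.n_cows
    herd_ids = np.repeat(np.arange(1, cfg.n_herds + 1), cfg.cows_per_herd)
    pheno = pd.DataFrame({
        "cow_id": ped.ids[-n_cows:],
        "herd_date_id": herd_ids,
        "parity_class": rng.integers(1, 5, size=n_cows),
        "dim_class": rng.integers(1, 7, size=n_cows),
    })
    vals = (tv.breeding_values[-n_cows:] + tv.herd_effects[herd_ids - 1]
            + tv.residuals)
    pheno["y1"] = vals[:, 0]
    pheno["y2"] = vals[:, 1]
    return pheno, tv
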
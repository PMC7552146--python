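"""Enteric-methane proxy phenotypes from milk fatty acids, yields and cheese yields.

Five methane traits are derived per cow-sample:

* methane yield per kg dry-matter intake (``ch4_dm``, g/kg),
* methane intensity per kg fat/protein-corrected milk (``ch4_cm``, g/kg),
* daily methane production (``dch4``, g/d),
* methane intensity per kg fresh cheese (``ch4_cy_curd``, g/kg),
* methane intensity per kg cheese solids (``ch4_cy_solids``, g/kg).

The first two are fixed linear forms in six informative fatty acids; the
rest are products/quotients with corrected milk yield and daily cheese
yields.  Functions accept scalars or NumPy arrays and are vectorized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FAProfile",
    "MilkRecord",
    "EMEPhenotypes",
    "UndefinedTraitError",
    "methane_yield",
    "methane_intensity_milk",
    "corrected_milk_yield",
    "daily_methane",
    "methane_intensity_cheese",
    "compute_all_eme",
    "eme_table",
    "EME_TRAIT_NAMES",
]

EME_TRAIT_NAMES = ("ch4_dm", "ch4_cm", "dch4", "ch4_cy_curd", "ch4_cy_solids")

# Methane yield (g/kg DMI) linear form: intercept and coefficients on
# C16:0iso, summed C18:1 trans-10 + trans-11, and C18:2 cis-9,cis-12.
_YIELD_INTERCEPT = 23.39
_YIELD_C16ISO = 9.74
_YIELD_C18_T10T11 = -1.06
_YIELD_C18_2 = -1.75

# Methane intensity per kg corrected milk (g/kg): intercept and
# coefficients on C4:0, C16:0iso, C18:1 cis-9 and summed trans-10 + trans-11.
_INTENSITY_INTERCEPT = 21.13
_INTENSITY_C4 = -1.38
_INTENSITY_C16ISO = 8.53
_INTENSITY_C18_C9 = -0.22
_INTENSITY_C18_T10T11 = -0.59

# Corrected-milk factor CF = a + b*fat% + c*protein%.
_CF_INTERCEPT = 0.337
_CF_FAT = 0.116
_CF_PROTEIN = 0.06


class UndefinedTraitError(ValueError):
    """A trait is undefined for a record (e.g. zero cheese yield)."""


@dataclass(frozen=True)
class FAProfile:
    """Six informative fatty acids, g per 100 g of total fatty acids.

    The two C18:1 trans isomers are stored separately and summed at
    evaluation time because the prediction equations use their sum.
    """

    c4_0: float = 0.0
    c16_0iso: float = 0.0
    c18_1_t10: float = 0.0
    c18_1_t11: float = 0.0
    c18_1_c9: float = 0.0
    c18_2_c9c12: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.c4_0, self.c16_0iso, self.c18_1_t10, self.c18_1_t11,
                self.c18_1_c9, self.c18_2_c9c12)
        for v in vals:
            arr = np.asarray(v, dtype=float)
            finite = arr[np.isfinite(arr)] if arr.ndim else arr
            if np.any(finite < 0) or np.any(finite > 100):
                raise ValueError("fatty acid proportions must lie in [0, 100] g/100 g")
        total = sum(np.asarray(v, dtype=float) for v in vals)
        if np.any(np.asarray(total)[np.isfinite(np.asarray(total))] > 100 + 1e-9):
            raise ValueError("fatty acid proportions sum to more than 100 g/100 g")

    @property
    def c18_1_t10_t11(self):
        return np.asarray(self.c18_1_t10, dtype=float) + np.asarray(self.c18_1_t11, dtype=float)


@dataclass
class MilkRecord:
    """One cow-sample: identifiers, yields, composition, FA profile, spectrum."""

    cow_id: int
    herd_date_id: int
    parity_class: int
    dim_class: int
    dmy: float
    fat_pct: float
    protein_pct: float
    cy_curd_pct: float
    cy_solids_pct: float
    fa: FAProfile
    spectrum: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dmy <= 0:
            raise ValueError("daily milk yield must be positive")
        if not (1 <= self.parity_class <= 4):
            raise ValueError("parity class must be in 1..4")
        if not (1 <= self.dim_class <= 6):
            raise ValueError("DIM class must be in 1..6")
        if not (0 < self.fat_pct < 15 and 0 < self.protein_pct < 15):
            raise ValueError("fat/protein percentages out of physiological range")
        if not (0 < self.cy_solids_pct < self.cy_curd_pct):
            raise ValueError("need 0 < cheese-solids % < fresh-cheese %")


@dataclass
class EMEPhenotypes:
    ch4_dm: float
    ch4_cm: float
    dcmy: float
    dch4: float
    dcy_curd: float
    dcy_solids: float
    ch4_cy_curd: float
    ch4_cy_solids: float
    flags: list = field(default_factory=list)


def methane_yield(fa: FAProfile):
    """Methane yield, g per kg dry-matter intake, from the FA linear form.

    Negative outputs are possible for extreme inputs; they are flagged with
    a warning, not clipped.
    """
    out = (_YIELD_INTERCEPT
           + _YIELD_C16ISO * np.asarray(fa.c16_0iso, dtype=float)
           + _YIELD_C18_T10T11 * fa.c18_1_t10_t11
           + _YIELD_C18_2 * np.asarray(fa.c18_2_c9c12, dtype=float))
    if np.any(out < 0):
        warnings.warn("methane_yield produced negative value(s); retained unclipped")
    return out if out.ndim else float(out)


def methane_intensity_milk(fa: FAProfile):
    """Methane intensity, g per kg fat/protein-corrected milk, from the FA linear form."""
    out = (_INTENSITY_INTERCEPT
           + _INTENSITY_C4 * np.asarray(fa.c4_0, dtype=float)
           + _INTENSITY_C16ISO * np.asarray(fa.c16_0iso, dtype=float)
           + _INTENSITY_C18_C9 * np.asarray(fa.c18_1_c9, dtype=float)
           + _INTENSITY_C18_T10T11 * fa.c18_1_t10_t11)
    if np.any(out < 0):
        warnings.warn("methane_intensity_milk produced negative value(s); retained unclipped")
    return out if out.ndim else float(out)


def corrected_milk_yield(dmy, fat_pct, protein_pct):
    """Fat/protein-corrected daily milk yield, kg/d: dmy * CF(fat%, protein%)."""
    dmy = np.asarray(dmy, dtype=float)
    if np.any(dmy < 0):
        raise ValueError("daily milk yield must be non-negative")
    cf = _CF_INTERCEPT + _CF_FAT * np.asarray(fat_pct, dtype=float) \
        + _CF_PROTEIN * np.asarray(protein_pct, dtype=float)
    out = dmy * cf
    return out if out.ndim else float(out)


def daily_methane(ch4_cm, dcmy):
    """Daily methane production, g/d: intensity-milk times corrected milk yield."""
    dcmy = np.asarray(dcmy, dtype=float)
    if np.any(dcmy < 0):
        raise ValueError("corrected milk yield must be non-negative")
    out = np.asarray(ch4_cm, dtype=float) * dcmy
    return out if out.ndim else float(out)


def methane_intensity_cheese(dch4, dcy):
    """Methane intensity per kg cheese (fresh or solids), g/kg: dch4 / dcy.

    Raises :class:`UndefinedTraitError` for non-positive daily cheese yield;
    such records are excluded from cheese-intensity analyses downstream.
    """
    dcy = np.asarray(dcy, dtype=float)
    if np.any(dcy <= 0):
        raise UndefinedTraitError("cheese intensity undefined for daily cheese yield <= 0")
    out = np.asarray(dch4, dtype=float) / dcy
    return out if out.ndim else float(out)


def compute_all_eme(rec: MilkRecord) -> EMEPhenotypes:
    """All methane phenotypes and auxiliary yields for one record."""
    ch4_dm = methane_yield(rec.fa)
    ch4_cm = methane_intensity_milk(rec.fa)
    dcmy = corrected_milk_yield(rec.dmy, rec.fat_pct, rec.protein_pct)
    dch4 = daily_methane(ch4_cm, dcmy)
    dcy_curd = rec.dmy * rec.cy_curd_pct / 100.0
    dcy_solids = rec.dmy * rec.cy_solids_pct / 100.0
    ch4_cy_curd = methane_intensity_cheese(dch4, dcy_curd)
    ch4_cy_solids = methane_intensity_cheese(dch4, dcy_solids)
    return EMEPhenotypes(ch4_dm=ch4_dm, ch4_cm=ch4_cm, dcmy=dcmy, dch4=dch4,
                         dcy_curd=dcy_curd, dcy_solids=dcy_solids,
                         ch4_cy_curd=ch4_cy_curd, ch4_cy_solids=ch4_cy_solids)


def eme_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized methane phenotypes for a phenotype table.

    Expects columns ``dmy, fat_pct, protein_pct, cy_curd_pct, cy_solids_pct``
    and the six FA columns ``c4_0, c16_0iso, c18_1_t10, c18_1_t11, c18_1_c9,
    c18_2_c9c12``.  Cheese intensities are NaN where the daily cheese yield
    is non-positive (the record count dropped per trait is logged by the
    pipeline); other traits are always defined.
    """
    fa = FAProfile(c4_0=df["c4_0"].to_numpy(), c16_0iso=df["c16_0iso"].to_numpy(),
                   c18_1_t10=df["c18_1_t10"].to_numpy(),
                   c18_1_t11=df["c18_1_t11"].to_numpy(),
                   c18_1_c9=df["c18_1_c9"].to_numpy(),
                   c18_2_c9c12=df["c18_2_c9c12"].to_numpy())
    out = pd.DataFrame(index=df.index)
    out["ch4_dm"] = methane_yield(fa)
    out["ch4_cm"] = methane_intensity_milk(fa)
    out["dcmy"] = corrected_milk_yield(df["dmy"].to_numpy(),
                                       df["fat_pct"].to_numpy(),
                                       df["protein_pct"].to_numpy())
    out["dch4"] = out["ch4_cm"] * out["dcmy"]
    out["dcy_curd"] = df["dmy"] * df["cy_curd_pct"] / 100.0
    out["dcy_solids"] = df["dmy"] * df["cy_solids_pct"] / 100.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ch4_cy_curd"] = np.where(out["dcy_curd"] > 0,
                                      out["dch4"] / out["dcy_curd"], np.nan)
        out["ch4_cy_solids"] = np.where(out["dcy_solids"] > 0,
                                        out["dch4"] / out["dcy_solids"], np.nan)
    return out
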
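"""End-to-end orchestration: simulate -> traits -> calibrate -> genetics.

One YAML config and one master seed drive the whole chain; per-stage seeds
are derived deterministically from the master seed and the stage name so
any stage can be rerun in isolation.  Every output CSV starts with a
comment header carrying the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import genetics as gen
from .pedigree import Pedigree
from .simulate import FA_NAMES, SimulationConfig, simulate_effects, \
    simulate_pedigree, simulate_records_frame
from .traits import EME_TRAIT_NAMES, eme_table

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "stage_seed",
           "write_csv_with_header", "PipelineError"]

logger = logging.getLogger(__name__)

REFERENCE_TRAITS = EME_TRAIT_NAMES  # gas-chromatography-based reference values


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class CalibrationSettings:
    repetitions: int = 10
    test_frac: float = 0.2
    iterations: int = 1_500
    burn_in: int = 500
    thin: int = 5
    pi_zero: float = 0.95


@dataclass
class GeneticsSettings:
    iterations: int = 6_000
    burn_in: int = 1_500
    thin: int = 5
    univariate_traits: tuple[str, ...] = ("ch4_dm", "ch4_dm_ir", "ch4_cm",
                                          "ch4_cm_ir")
    bivariate_pairs: tuple[tuple[str, str], ...] = (("ch4_cm", "ch4_cm_ir"),)


@dataclass
class RunConfig:
    """Everything a full run needs; see the YAML round-trip helpers."""

    outdir: str = "results/pipeline"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=lambda: SimulationConfig(
        n_herds=20, cows_per_herd=15, n_founders=60, n_generations=3,
        n_sires_per_gen=25, n_dams_per_gen=120, n_wavelengths=300))
    calibration: CalibrationSettings = field(default_factory=CalibrationSettings)
    genetics: GeneticsSettings = field(default_factory=GeneticsSettings)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.get("simulation", {}))
        calset = CalibrationSettings(**raw.get("calibration", {}))
        genset = raw.get("genetics", {})
        if "univariate_traits" in genset:
            genset["univariate_traits"] = tuple(genset["univariate_traits"])
        if "bivariate_pairs" in genset:
            genset["bivariate_pairs"] = tuple(tuple(p) for p in genset["bivariate_pairs"])
        return cls(outdir=raw.get("outdir", "results/pipeline"),
                   seed=int(raw.get("seed", 0)), simulation=sim,
                   calibration=calset, genetics=GeneticsSettings(**genset))

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        fields = asdict(self)
        fields.pop("outdir", None)  # hash covers scientific settings only
        payload = json.dumps(fields, sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def write_csv_with_header(df: pd.DataFrame, path, cfg: RunConfig,
                          index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# methaphen seed={cfg.seed} config={cfg.config_hash()}\n")
        df.to_csv(fh, index=index)


def validate_inputs(pheno: pd.DataFrame, pedigree: pd.DataFrame,
                    spectra: np.ndarray | pd.DataFrame):
    """Cross-file consistency diagnostics; returns (fatal, warnings) lists."""
    fatal, warns = [], []
    try:
        ped = Pedigree.from_frame(pedigree)
        known = set(int(i) for i in ped.ids)
    except ValueError as exc:
        fatal.append(f"pedigree invalid: {exc}")
        known = set()
    if known:
        orphans = sorted(set(int(c) for c in pheno["cow_id"]) - known)
        if orphans:
            fatal.append(f"{len(orphans)} cow id(s) absent from pedigree, "
                         f"e.g. {orphans[:5]}")
    n_spec = len(spectra)
    if n_spec != len(pheno):
        fatal.append(f"spectra rows ({n_spec}) != phenotype rows ({len(pheno)})")
    spec_vals = np.asarray(spectra if not isinstance(spectra, pd.DataFrame)
                           else spectra.to_numpy())
    if spec_vals.size and not np.all(np.isfinite(spec_vals)):
        fatal.append("missing or non-finite cells in spectra matrix")
    for col in FA_NAMES:
        if col in pheno:
            bad = int(((pheno[col] < 0) | (pheno[col] > 100)).sum())
            if bad:
                warns.append(f"{bad} out-of-range value(s) in {col}")
    return fatal, warns


def _calibration_models(records: pd.DataFrame, reference: pd.DataFrame,
                        cfg: RunConfig) -> tuple[dict, pd.DataFrame]:
    wl_cols = [c for c in records.columns if c.startswith("wl_")]
    spectra = records[wl_cols].to_numpy(dtype=float)
    cs = cfg.calibration
    chain = cal.BayesBChain(iterations=cs.iterations, burn_in=cs.burn_in,
                            thin=cs.thin, pi_zero=cs.pi_zero)
    targets: dict[str, np.ndarray] = {}
    for ref, name in zip(REFERENCE_TRAITS, cal.DIRECT_PREDICTIONS):
        targets[name] = reference[ref].to_numpy(dtype=float)
    for name in cal.INFORMATIVE_TRAITS:
        src = records if name in records.columns else reference
        targets[name] = src[name].to_numpy(dtype=float)
    cv_results, metric_rows = {}, []
    for name, y in targets.items():
        ok = np.isfinite(y)
        if not ok.all():
            raise PipelineError(f"calibrate: non-finite reference values for {name}")
        cv = cal.crossvalidate(y, spectra, repetitions=cs.repetitions,
                               test_frac=cs.test_frac, chain=chain,
                               seed=stage_seed(cfg.seed, f"calibrate:{name}"))
        cv_results[name] = cv
        metric_rows.append({"trait": name, "r2_cv": cv.r2_cv,
                            "rmse_cv": cv.rmse_cv,
                            "n_never_tested": int((cv.times_tested() == 0).sum())})
        logger.info("calibrate %s: R2cv=%.3f RMSEcv=%.3f", name, cv.r2_cv, cv.rmse_cv)
    return cv_results, pd.DataFrame(metric_rows)


def _genetic_tables(pheno: pd.DataFrame, ainv: gen.AInverse,
                    cfg: RunConfig) -> pd.DataFrame:
    gs = cfg.genetics
    rows = []
    for trait in gs.univariate_traits:
        if trait not in pheno.columns:
            raise PipelineError(f"genetics: unknown trait {trait}")
        spec = gen.ModelSpec(traits=(trait,), iterations=gs.iterations,
                             burn_in=gs.burn_in, thin=gs.thin,
                             seed=stage_seed(cfg.seed, f"genetics:{trait}"))
        draws = gen.gibbs_univariate(pheno[trait].to_numpy(dtype=float),
                                     pheno, spec, ainv)
        h2 = gen.heritability(draws)
        hh = gen.herd_fraction(draws)
        rows.append({"analysis": "univariate", "trait": trait, "parameter": "h2",
                     "mean": h2.mean, "hpd95_low": h2.hpd95_low,
                     "hpd95_high": h2.hpd95_high, "p_sign": h2.sign_probability,
                     "relevant": h2.relevant})
        rows.append({"analysis": "univariate", "trait": trait, "parameter": "h_herd",
                     "mean": hh.mean, "hpd95_low": hh.hpd95_low,
                     "hpd95_high": hh.hpd95_high, "p_sign": hh.sign_probability,
                     "relevant": hh.relevant})
        for name, arr in (("var_additive", draws.var_additive()),
                          ("var_herd", draws.var_herd()),
                          ("var_residual", draws.var_residual())):
            s = gen.posterior_summaries(arr)
            rows.append({"analysis": "univariate", "trait": trait, "parameter": name,
                         "mean": s.mean, "hpd95_low": s.hpd95_low,
                         "hpd95_high": s.hpd95_high, "p_sign": s.sign_probability,
                         "relevant": s.relevant})
    for t1, t2 in gs.bivariate_pairs:
        spec = gen.ModelSpec(traits=(t1, t2), iterations=gs.iterations,
                             burn_in=gs.burn_in, thin=gs.thin,
                             seed=stage_seed(cfg.seed, f"genetics:{t1}|{t2}"))
        draws = gen.gibbs_bivariate(pheno[t1].to_numpy(dtype=float),
                                    pheno[t2].to_numpy(dtype=float),
                                    pheno, spec, ainv)
        for name, summ in gen.component_correlations(draws).items():
            rows.append({"analysis": "bivariate", "trait": f"{t1}|{t2}",
                         "parameter": name, "mean": summ.mean,
                         "hpd95_low": summ.hpd95_low, "hpd95_high": summ.hpd95_high,
                         "p_sign": summ.sign_probability, "relevant": summ.relevant})
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report files under ``cfg.outdir``.

    Returns a dict with the in-memory tables (records, calibration metrics,
    validation database, genetic parameters).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = replace(cfg.simulation, seed=stage_seed(cfg.seed, "simulate"))
    try:
        ped = simulate_pedigree(sim)
        tv = simulate_effects(ped, sim)
        records = simulate_records_frame(ped, tv, sim)
    except Exception as exc:
        raise PipelineError(f"simulate: {exc}") from exc
    ped.write_csv(outdir / "pedigree.csv")
    write_csv_with_header(records, outdir / "records.csv", cfg)

    try:
        reference = eme_table(records)
    except Exception as exc:
        raise PipelineError(f"traits: {exc}") from exc
    write_csv_with_header(reference, outdir / "reference_traits.csv", cfg)

    try:
        cv_results, metrics = _calibration_models(records, reference, cfg)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"calibrate: {exc}") from exc
    write_csv_with_header(metrics, outdir / "calibration_metrics.csv", cfg)

    try:
        valdb = cal.assemble_validation_db(cv_results,
                                           sample_ids=records["cow_id"].to_numpy())
        direct = valdb[list(cal.DIRECT_PREDICTIONS)]
        informative = valdb[list(cal.INFORMATIVE_TRAITS)]
        measured = pd.DataFrame({"dmy": records["dmy"].to_numpy(),
                                 "dcmy": reference["dcmy"].to_numpy()},
                                index=valdb.index)
        indirect = cal.indirect_predictions(direct, informative, measured)
        pheno = pd.concat([records.set_index("cow_id")[
                               ["herd_date_id", "parity_class", "dim_class"]],
                           reference.set_index(records["cow_id"])[
                               list(REFERENCE_TRAITS)],
                           direct, indirect], axis=1, join="inner")
        pheno = pheno.reset_index().rename(columns={"index": "cow_id",
                                                    "sample_id": "cow_id"})
    except (ValueError, KeyError) as exc:
        raise PipelineError(f"assemble: {exc}") from exc
    counts = pheno[list(cal.DIRECT_PREDICTIONS) + list(cal.INDIRECT_PREDICTIONS)]\
        .notna().sum().rename("n_retained").rename_axis("trait").reset_index()
    write_csv_with_header(counts, outdir / "validation_counts.csv", cfg)
    write_csv_with_header(pheno, outdir / "validation_phenotypes.csv", cfg)

    try:
        ainv = gen.build_a_inverse(ped)
        params = _genetic_tables(pheno, ainv, cfg)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"genetics: {exc}") from exc
    write_csv_with_header(params, outdir / "genetic_parameters.csv", cfg)

    summary = outdir / "summary.txt"
    with open(summary, "w") as fh:
        fh.write(f"methaphen pipeline run (seed={cfg.seed}, "
                 f"config={cfg.config_hash()})\n")
        fh.write(f"records: {len(records)} cows, {sim.n_herds} herd/dates, "
                 f"pedigree {len(ped)} animals\n\n")
        fh.write("Calibration (out-of-fold):\n")
        fh.write(metrics.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        fh.write("\n\nValidation database per-trait N:\n")
        fh.write(counts.to_string(index=False))
        fh.write("\n\nGenetic parameters:\n")
        fh.write(params.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        fh.write("\n")
    return {"records": records, "reference": reference, "metrics": metrics,
            "validation": pheno, "genetic_parameters": params}
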
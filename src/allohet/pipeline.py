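"""End-to-end orchestration: data -> allometry fits -> heterosis -> NLDev
-> distances -> structured report.

The report is a plain JSON-serializable dict with one key per stage, a
schema version, and the seed recorded at the top level.  Floating-point
outputs are rounded to 10 significant digits at serialization so reruns
with the same seed produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import allometry, distances, heterosis, phenotype_io, synthetic_data
from .nldev import compare_predictions as _compare_predictions
from .nldev import nldev_table as _nldev_table
from .config import PipelineConfig, SyntheticConfig

log = logging.getLogger("allohet")

REPORT_SCHEMA_VERSION = 1


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {err}")
        self.stage = stage


def _round_floats(obj, ndigits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        return round(v, ndigits) if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _fit_stage(summaries: pd.DataFrame) -> dict:
    out = {}
    models = {}
    for group in ("accession", "hybrid"):
        sub = summaries[summaries["type"] == group]
        entry = {}
        gm = sub.dropna(subset=["mass_mg", "growth_mg_per_d"])
        growth = allometry.fit_growth_allometry(
            gm["mass_mg"], gm["growth_mg_per_d"], "power_mass_corrected",
            fitted_on=group + "s",
        )
        growth_fixed = allometry.fit_growth_allometry(
            gm["mass_mg"], gm["growth_mg_per_d"], "power_fixed", fitted_on=group + "s"
        )
        entry["growth"] = asdict(growth)
        entry["growth_fixed_exponent"] = asdict(growth_fixed)
        entry["growth_delta_aic"] = allometry.compare_models_aic(growth_fixed, growth)
        fm = sub.dropna(subset=["mass_mg", "fruit_n"])
        fruit = allometry.fit_fruit_allometry(
            fm["mass_mg"], fm["fruit_n"], "inverse_quadratic", fitted_on=group + "s"
        )
        entry["fruit"] = asdict(fruit)
        try:
            ricker = allometry.fit_fruit_allometry(
                fm["mass_mg"], fm["fruit_n"], "ricker", fitted_on=group + "s"
            )
            entry["fruit_ricker"] = asdict(ricker)
            entry["fruit_delta_aic"] = allometry.compare_models_aic(ricker, fruit)
        except allometry.FitError as err:
            entry["fruit_ricker"] = None
            entry["fruit_delta_aic"] = None
            log.warning("ricker fit failed for %s: %s", group, err)
        sma = allometry.fit_sma(np.log10(gm["mass_mg"]), np.log10(gm["growth_mg_per_d"]))
        entry["sma_growth"] = {
            "slope": sma.slope,
            "intercept": sma.intercept,
            "r2": sma.r2,
            "n": sma.n,
            "slope_ci95": list(sma.slope_ci95),
            "p_vs_three_quarters": allometry.test_slope(sma, 0.75),
        }
        out[group + "s"] = entry
        models[group] = {"growth": growth, "fruit": fruit, "sma": sma}
    out["sma_slope_difference_p"] = allometry.slope_difference(
        models["accession"]["sma"], models["hybrid"]["sma"]
    )
    out["_models"] = models
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return (and optionally write) the
    report bundle.  Any stage failure raises :class:`StageError`; outputs
    of completed stages are retained in the partially written directory."""
    t_start = time.time()
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "stages": list(config.stages),
    }
    outdir: Optional[Path] = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- io stage -----------------------------------------------------
    try:
        if config.synthetic:
            scfg = config.synthetic_config
            bundle = synthetic_data.generate_dataset(scfg)
            records = bundle["phenotypes"]
            coords = bundle["coords"]
            snps = bundle["snps"]
            report["input"] = {"mode": "synthetic", "config": scfg.to_dict()}
        else:
            records, val_report = phenotype_io.read_phenotypes(config.phenotypes)
            coords = pd.read_csv(config.coords) if config.coords else None
            snps = (
                pd.read_csv(config.snps, sep="\t", index_col=0)
                if config.snps
                else None
            )
            report["input"] = {
                "mode": "external",
                "phenotypes": str(config.phenotypes),
                "validation": {
                    "n_rows": val_report.n_rows,
                    "n_valid": val_report.n_valid,
                    "n_excluded": len(val_report.excluded),
                },
            }
        summaries = phenotype_io.summarize_genotypes(records)
        report["io"] = {
            "n_records": int(len(records)),
            "n_genotypes": int(len(summaries)),
            "n_accessions": int((summaries["type"] == "accession").sum()),
            "n_hybrids": int((summaries["type"] == "hybrid").sum()),
        }
    except Exception as err:  # noqa: BLE001 - stage-named diagnostics
        raise StageError("io", err) from err
    log.info("io stage done (%.1fs)", time.time() - t_start)

    models = None
    if "fit" in config.stages:
        t0 = time.time()
        try:
            fits = _fit_stage(summaries)
            models = fits.pop("_models")
            report["fits"] = fits
        except Exception as err:  # noqa: BLE001
            raise StageError("fit", err) from err
        log.info("fit stage done (%.1fs)", time.time() - t0)
        if outdir:
            (outdir / "fits.json").write_text(
                json.dumps(_round_floats(report["fits"]), indent=2)
            )

    het_table = None
    if "heterosis" in config.stages:
        t0 = time.time()
        try:
            het_table = heterosis.heterosis_table(
                summaries, traits=("mass_mg", "growth_mg_per_d", "fruit_n")
            )
            classes = heterosis.classify_cohort(
                records,
                summaries,
                n_boot=config.n_boot,
                alpha=config.alpha,
                seed=config.seed,
            )
            h2 = {
                trait: heterosis.heritability(records, trait).h2
                for trait in heterosis.TRAITS
            }
            report["heterosis"] = {
                "classification_pct": heterosis.classification_summary(classes),
                "heritability": h2,
                "n_hybrids_measured": int(het_table["hybrid_id"].nunique()),
            }
            if outdir:
                merged = het_table.merge(
                    classes.rename(columns={"trait": "trait"}),
                    on=["hybrid_id", "trait"],
                    how="left",
                )
                merged.to_csv(outdir / "heterosis.csv", index=False)
        except Exception as err:  # noqa: BLE001
            raise StageError("heterosis", err) from err
        log.info("heterosis stage done (%.1fs)", time.time() - t0)

    if "nldev" in config.stages:
        if models is None or het_table is None:
            raise StageError(
                "nldev", RuntimeError("nldev requires the fit and heterosis stages")
            )
        t0 = time.time()
        try:
            nld = {}
            tables = []
            for trait, model in (
                ("growth_mg_per_d", models["accession"]["growth"]),
                ("fruit_n", models["accession"]["fruit"]),
            ):
                table = _nldev_table(summaries, model, trait)
                tables.append(table)
                comp = _compare_predictions(table, het_table, summaries, trait)
                nld[trait] = asdict(comp)
            report["nldev"] = nld
            if outdir:
                pd.concat(tables, ignore_index=True).to_csv(
                    outdir / "nldev.csv", index=False
                )
        except Exception as err:  # noqa: BLE001
            raise StageError("nldev", err) from err
        log.info("nldev stage done (%.1fs)", time.time() - t0)

    if "distances" in config.stages and snps is not None and coords is not None:
        t0 = time.time()
        try:
            filtered, filter_report = distances.filter_snps(snps)
            gdist = distances.genetic_distance_matrix(filtered)
            geo = distances.geographic_distance_matrix(coords)
            dist_report = {"snp_filter": filter_report}
            if het_table is not None:
                regs = {}
                for trait in ("growth_mg_per_d", "fruit_n"):
                    sub = het_table[het_table["trait"] == trait].merge(
                        summaries[["genotype_id", "parent1", "parent2"]],
                        left_on="hybrid_id",
                        right_on="genotype_id",
                    )
                    have = sub["parent1"].isin(gdist.index) & sub["parent2"].isin(
                        gdist.index
                    )
                    sub = sub[have]
                    if len(sub) >= 10:
                        d = np.log10(
                            np.maximum(
                                [
                                    gdist.at[p1, p2]
                                    for p1, p2 in zip(sub["parent1"], sub["parent2"])
                                ],
                                1.0,
                            )
                        )
                        for measure in ("mph", "bph"):
                            res = distances.regress_heterosis_on_distance(
                                d,
                                sub[measure],
                                response=f"{measure}_{trait}",
                                predictor="log10_genetic_distance",
                            )
                            regs[f"{measure}_{trait}"] = asdict(res)
                dist_report["heterosis_regressions"] = regs
            report["distances"] = dist_report
            if outdir:
                ddir = outdir / "distances"
                ddir.mkdir(exist_ok=True)
                distances.distance_long_format(gdist).to_csv(
                    ddir / "genetic.csv", index=False
                )
                distances.distance_long_format(geo).to_csv(
                    ddir / "geographic.csv", index=False
                )
        except Exception as err:  # noqa: BLE001
            raise StageError("distances", err) from err
        log.info("distances stage done (%.1fs)", time.time() - t0)

    report["runtime_s"] = round(time.time() - t_start, 3)
    report = _round_floats(report)
    report.pop("runtime_s")  # not part of the stable schema
    if outdir:
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
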
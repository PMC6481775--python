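"""Reading, validation, harmonization and aggregation of phenotype tables.

The on-disk format is the replicate-level CSV/TSV written by
:mod:`allohet.synthetic_data`: one row per measured plant with columns
``genotype_id, type, parent1, parent2, experiment, replicate, mass_mg,
age_d, growth_mg_per_d, fruit_n``.  Trait-specific missingness is allowed
(NaN), so panels where different traits were scored on different subsets of
genotypes are representable.  Units are fixed: mg, d, mg/d, count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

REQUIRED_COLUMNS = [
    "genotype_id",
    "type",
    "parent1",
    "parent2",
    "experiment",
    "replicate",
    "mass_mg",
    "age_d",
    "growth_mg_per_d",
    "fruit_n",
]

TRAITS = ["mass_mg", "age_d", "growth_mg_per_d", "fruit_n"]


@dataclass
class ValidationReport:
    """Enumerates every row exclusion; nothing is dropped silently."""

    n_rows: int = 0
    n_valid: int = 0
    excluded: list = field(default_factory=list)  # [{"row": i, "reason": ...}]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


class PhenotypeData(NamedTuple):
    records: pd.DataFrame
    report: ValidationReport


def _validate(df: pd.DataFrame) -> PhenotypeData:
    report = ValidationReport(n_rows=len(df))
    keep = np.ones(len(df), dtype=bool)
    for idx, row in df.iterrows():
        reasons = []
        for trait in TRAITS:
            v = row[trait]
            if pd.notna(v) and v <= 0 and not (trait == "fruit_n" and v == 0):
                reasons.append(f"nonpositive {trait}: {v}")
        if row["type"] == "hybrid":
            if pd.isna(row["parent1"]) or pd.isna(row["parent2"]):
                reasons.append("hybrid without two parent ids")
            elif row["parent1"] == row["parent2"]:
                reasons.append("hybrid with identical parent ids")
        if reasons:
            keep[df.index.get_loc(idx)] = False
            report.excluded.append({"row": int(idx), "reason": "; ".join(reasons)})
    records = df[keep].reset_index(drop=True)
    report.n_valid = len(records)
    return PhenotypeData(records, report)


def read_phenotypes(source) -> PhenotypeData:
    """Read and validate a replicate-level phenotype table.

    Delimiter is autodetected from the extension (.tsv/.txt -> tab, else
    comma).  Rows with missing trait values are retained (flagged NaN); rows
    violating hard invariants (nonpositive mass, malformed parentage) are
    excluded and enumerated in the returned report.
    """
    path = Path(source)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table is missing required columns: {missing}")
    for trait in TRAITS:
        df[trait] = pd.to_numeric(df[trait], errors="coerce")
    return _validate(df)


def write_phenotypes(records: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    records.to_csv(path, sep=sep, index=False)


@dataclass
class OffsetEstimate:
    """Cross-experiment correction for one trait.

    ``p_experiment`` is the experiment-effect p-value from the two-way ANOVA
    (genotype x experiment) on the shared genotypes; the linear map
    ``corrected = intercept + slope * observed`` (reference-experiment
    genotype means regressed on target-experiment means) is proposed only
    when that effect is significant.
    """

    trait: str
    p_experiment: float
    intercept: Optional[float] = None
    slope: Optional[float] = None
    slope_se: Optional[float] = None
    significant: bool = False


def estimate_experiment_offset(
    records: pd.DataFrame,
    reference_experiment: str,
    target_experiment: str,
    traits: Sequence[str] = ("age_d",),
    alpha: float = 0.05,
) -> Dict[str, OffsetEstimate]:
    """Calibrate a per-trait linear correction from genotypes shared by two
    experiments.

    Requires >= 3 genotypes present in both experiments.  Per trait, a
    two-way ANOVA with genotype and experiment as interacting factors tests
    for an experiment effect on the replicate-level values; for significant
    traits, ordinary least squares of reference-experiment genotype means on
    target-experiment genotype means yields (intercept, slope).
    """
    ref = records[records["experiment"] == reference_experiment]
    tgt = records[records["experiment"] == target_experiment]
    shared = sorted(set(ref["genotype_id"]) & set(tgt["genotype_id"]))
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 genotypes shared between {reference_experiment} and "
            f"{target_experiment}; found {len(shared)}"
        )
    both = records[
        records["genotype_id"].isin(shared)
        & records["experiment"].isin([reference_experiment, target_experiment])
    ].copy()
    out: Dict[str, OffsetEstimate] = {}
    for trait in traits:
        sub = both.dropna(subset=[trait]).rename(columns={trait: "y"})
        model = smf.ols("y ~ C(genotype_id) * C(experiment)", data=sub).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        p_exp = float(anova.loc["C(experiment)", "PR(>F)"])
        est = OffsetEstimate(trait=trait, p_experiment=p_exp)
        if p_exp < alpha:
            means = (
                sub.groupby(["genotype_id", "experiment"])["y"].mean().unstack()
            )
            x = means[target_experiment].to_numpy()
            y = means[reference_experiment].to_numpy()
            X = sm.add_constant(x)
            fit = sm.OLS(y, X).fit()
            est.intercept, est.slope = float(fit.params[0]), float(fit.params[1])
            est.slope_se = float(fit.bse[1])
            est.significant = True
        out[trait] = est
    return out


def correct_experiment_offset(
    records: pd.DataFrame,
    trait: str,
    coefficients: Tuple[float, float],
    experiment: str,
) -> pd.DataFrame:
    """Apply ``corrected = intercept + slope * observed`` to one trait within
    one experiment; corrected values <= 0 are flagged invalid (set NaN) and
    counted in ``df.attrs['n_invalid_corrected']``."""
    intercept, slope = coefficients
    out = records.copy()
    mask = out["experiment"] == experiment
    corrected = intercept + slope * out.loc[mask, trait]
    bad = corrected <= 0
    out.loc[mask, trait] = corrected.where(~bad)
    out.attrs["n_invalid_corrected"] = int(bad.sum())
    return out


def summarize_genotypes(records: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype per-trait mean/sd/n over replicates.

    Returns one row per genotype with identity columns (type, parents) and,
    for each trait, the replicate mean under the trait's own name plus
    ``<trait>_sd`` (NaN when n < 2) and ``<trait>_n``.  Aggregation is
    permutation-invariant and idempotent when re-applied to its own output.
    """
    ident = (
        records.groupby("genotype_id", sort=True)[["type", "parent1", "parent2"]]
        .first()
    )
    pieces = [ident]
    for trait in TRAITS:
        grp = records.groupby("genotype_id", sort=True)[trait]
        agg = grp.agg(mean="mean", sd="std", n="count")
        agg.loc[agg["n"] < 2, "sd"] = np.nan
        agg.columns = [trait, f"{trait}_sd", f"{trait}_n"]
        pieces.append(agg)
    out = pd.concat(pieces, axis=1).reset_index()
    return out
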
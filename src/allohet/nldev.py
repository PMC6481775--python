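"""Predicting hybrid traits and heterosis from parental allometry curvature.

Given an allometric model g fitted on inbred accessions and the measured
vegetative dry masses of the two parents (M1, M2) and the hybrid (M12), the
predicted hybrid trait value is g(M12) and the parental references are

    MP_pred = (g(M1) + g(M2)) / 2
    BP_pred = max(g(M1), g(M2))

The nonlinear deviation (NLDev) is the heterosis expected purely from the
curvature of the parental allometry:

    NLDev_MP = (g(M12) - MP_pred) / MP_pred
    NLDev_BP = (g(M12) - BP_pred) / BP_pred

For a concave g and near-mid-parent masses, Jensen's inequality makes
NLDev_MP positive — mid-parent heterosis without any genetics.  NLDev is
compared against observed MPH/BPH per hybrid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .allometry import AllometricModel, evaluate

__all__ = [
    "NLDevResult",
    "PredictionComparison",
    "predict_parent_values",
    "nldev",
    "nldev_table",
    "compare_predictions",
    "additive_prediction",
]


@dataclass
class NLDevResult:
    hybrid_id: str
    trait: str
    m1: float  # worst parent by predicted trait value
    m2: float  # best parent by predicted trait value
    m12: float
    predicted: float  # g(m12)
    mp_pred: float
    bp_pred: float
    nldev_mp: float
    nldev_bp: float


def predict_parent_values(
    model: AllometricModel, m1: float, m2: float
) -> Tuple[float, float]:
    """(MP_pred, BP_pred) from the two parental masses (mg, > 0)."""
    if m1 <= 0 or m2 <= 0:
        raise ValueError("parental masses must be positive")
    g1, g2 = evaluate(model, m1), evaluate(model, m2)
    return (g1 + g2) / 2.0, max(g1, g2)


def nldev(
    model: AllometricModel,
    m1: float,
    m2: float,
    m12: float,
    hybrid_id: str = "",
    trait: str = "",
) -> NLDevResult:
    """Nonlinear deviation of the predicted hybrid value from the predicted
    parental references; invariant to swapping the parent labels."""
    if m12 <= 0:
        raise ValueError("hybrid mass must be positive")
    mp_pred, bp_pred = predict_parent_values(model, m1, m2)
    if mp_pred <= 0:
        raise ValueError("predicted mid-parent value must be positive")
    g1, g2 = evaluate(model, m1), evaluate(model, m2)
    worst_m, best_m = (m1, m2) if g1 <= g2 else (m2, m1)
    pred = evaluate(model, m12)
    return NLDevResult(
        hybrid_id=hybrid_id,
        trait=trait,
        m1=float(worst_m),
        m2=float(best_m),
        m12=float(m12),
        predicted=float(pred),
        mp_pred=float(mp_pred),
        bp_pred=float(bp_pred),
        nldev_mp=float((pred - mp_pred) / mp_pred),
        nldev_bp=float((pred - bp_pred) / bp_pred),
    )


def nldev_table(
    summaries: pd.DataFrame,
    model: AllometricModel,
    trait: str,
) -> pd.DataFrame:
    """Per-hybrid NLDev from a genotype-summary frame and an
    accession-fitted model; masses are the genotype-mean vegetative dry
    masses of parents and hybrid."""
    idx = summaries.set_index("genotype_id")
    rows = []
    for _, h in summaries[summaries["type"] == "hybrid"].iterrows():
        p1, p2 = h["parent1"], h["parent2"]
        if p1 not in idx.index or p2 not in idx.index:
            continue
        m1, m2, m12 = idx.at[p1, "mass_mg"], idx.at[p2, "mass_mg"], h["mass_mg"]
        if not (np.isfinite(m1) and np.isfinite(m2) and np.isfinite(m12)):
            continue
        rows.append(nldev(model, m1, m2, m12, hybrid_id=h["genotype_id"], trait=trait).__dict__)
    return pd.DataFrame(rows)


@dataclass
class PredictionComparison:
    trait: str
    n: int
    r2_pred_vs_obs: float
    p_pred_vs_obs: float
    slope_pred_vs_obs: float
    r2_nldev_mp_vs_mph: float
    p_nldev_mp_vs_mph: float
    slope_nldev_mp_vs_mph: float
    r2_nldev_bp_vs_bph: float
    p_nldev_bp_vs_bph: float
    slope_nldev_bp_vs_bph: float


def _r2(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.pvalue), float(res.slope)


def compare_predictions(
    nldev_results: pd.DataFrame,
    heterosis_measures: pd.DataFrame,
    observed: pd.DataFrame,
    trait: str,
) -> PredictionComparison:
    """Pearson r^2 (with OLS slope and significance) of (i) predicted
    g(M12) vs observed hybrid trait, (ii) NLDev_MP vs observed MPH and
    (iii) NLDev_BP vs observed BPH, matched on hybrid id.

    ``observed`` is a genotype-summary frame supplying the observed hybrid
    trait values.
    """
    if len(nldev_results) < 3 or len(heterosis_measures) < 3:
        raise ValueError("need >= 3 matched hybrids")
    het = heterosis_measures[heterosis_measures["trait"] == trait]
    obs = observed.set_index("genotype_id")[trait]
    merged = nldev_results.merge(
        het, left_on="hybrid_id", right_on="hybrid_id", how="inner"
    )
    merged = merged[merged["hybrid_id"].isin(obs.index)]
    merged["observed"] = obs.loc[merged["hybrid_id"]].to_numpy()
    merged = merged.dropna(subset=["observed", "predicted", "nldev_mp", "nldev_bp", "mph", "bph"])
    if len(merged) < 3:
        raise ValueError("need >= 3 matched hybrids")
    r2_po, p_po, s_po = _r2(merged["predicted"].to_numpy(), merged["observed"].to_numpy())
    r2_mp, p_mp, s_mp = _r2(merged["nldev_mp"].to_numpy(), merged["mph"].to_numpy())
    r2_bp, p_bp, s_bp = _r2(merged["nldev_bp"].to_numpy(), merged["bph"].to_numpy())
    return PredictionComparison(
        trait=trait,
        n=len(merged),
        r2_pred_vs_obs=r2_po,
        p_pred_vs_obs=p_po,
        slope_pred_vs_obs=s_po,
        r2_nldev_mp_vs_mph=r2_mp,
        p_nldev_mp_vs_mph=p_mp,
        slope_nldev_mp_vs_mph=s_mp,
        r2_nldev_bp_vs_bph=r2_bp,
        p_nldev_bp_vs_bph=p_bp,
        slope_nldev_bp_vs_bph=s_bp,
    )


def additive_prediction(summaries: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Baseline predictor: hybrid trait = mean of the parents' observed
    trait values (genetic additivity, no allometry)."""
    idx = summaries.set_index("genotype_id")
    rows = []
    for _, h in summaries[summaries["type"] == "hybrid"].iterrows():
        p1, p2 = h["parent1"], h["parent2"]
        if p1 not in idx.index or p2 not in idx.index:
            continue
        y1, y2 = idx.at[p1, trait], idx.at[p2, trait]
        if not (np.isfinite(y1) and np.isfinite(y2)):
            continue
        rows.append(
            {"hybrid_id": h["genotype_id"], "trait": trait, "predicted_additive": (y1 + y2) / 2.0}
        )
    return pd.DataFrame(rows)
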
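"""Pairwise genetic, geographic and phenotypic distances between inbred
genotypes, and regression of heterosis on them.

Genetic distance follows the allele-count convention for fully homozygous
inbred lines: each biallelic site at which two genotypes carry different
(homozygous) alleles contributes 2 allele differences; sites with a missing
call in either genotype are skipped (pairwise-complete).  Markers are
pre-filtered on minor allele frequency and call rate.  Geographic distance
is the great-circle (haversine) distance on a sphere of mean Earth radius;
phenotypic distance is either the Euclidean distance over standardized
trait vectors or the absolute mass difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius

TRAITS = ["mass_mg", "age_d", "growth_mg_per_d", "fruit_n"]


# ---------------------------------------------------------------------------
# SNP filtering and genetic distance


def snp_stats(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-marker call rate and minor allele frequency (missing ignored)."""
    calls = matrix.notna().mean(axis=0)
    freq = matrix.mean(axis=0, skipna=True)
    maf = np.minimum(freq, 1.0 - freq)
    return pd.DataFrame({"call_rate": calls, "maf": maf})


def filter_snps(
    matrix: pd.DataFrame, maf_min: float = 0.05, call_rate_min: float = 0.85
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Drop markers below the MAF or call-rate thresholds.

    Returns the filtered matrix and a report with marker counts before and
    after.  An empty result is allowed (warning-level condition for the
    caller), not an error.
    """
    stats_df = snp_stats(matrix)
    keep = (stats_df["maf"] >= maf_min) & (stats_df["call_rate"] >= call_rate_min)
    filtered = matrix.loc[:, keep[keep].index]
    report = {
        "n_markers_before": int(matrix.shape[1]),
        "n_markers_after": int(filtered.shape[1]),
        "n_removed_maf": int((stats_df["maf"] < maf_min).sum()),
        "n_removed_call_rate": int((stats_df["call_rate"] < call_rate_min).sum()),
    }
    return filtered, report


def genetic_distance(
    matrix: pd.DataFrame,
    pair: Tuple[str, str],
    alleles_per_site: int = 2,
) -> float:
    """Allele-count distance between two genotypes (pairwise-complete sites).

    ``alleles_per_site=2`` is the homozygous-inbred convention (a differing
    site differs at both alleles); 1 counts per-site differences.
    """
    g1 = matrix.loc[pair[0]].to_numpy(dtype=float)
    g2 = matrix.loc[pair[1]].to_numpy(dtype=float)
    ok = np.isfinite(g1) & np.isfinite(g2)
    return float(alleles_per_site * np.sum(g1[ok] != g2[ok]))


def genetic_distance_matrix(
    matrix: pd.DataFrame, alleles_per_site: int = 2, log10: bool = False
) -> pd.DataFrame:
    """All-pairs allele-count distances (vectorized).

    With ``log10=True`` the log10-transformed counts are returned; zero
    counts (identical genotypes) become NaN off-diagonal and are excluded
    from log-scale analyses downstream.
    """
    X = matrix.to_numpy(dtype=float)
    W = np.isfinite(X).astype(float)
    X0 = np.nan_to_num(X)
    ones = W - X0 * W  # (1 - x) where observed
    mismatches = (X0 * W) @ ones.T + ones @ (X0 * W).T
    D = alleles_per_site * mismatches
    np.fill_diagonal(D, 0.0)
    if log10:
        with np.errstate(divide="ignore"):
            D = np.where(D > 0, np.log10(np.maximum(D, 1e-300)), np.nan)
        np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


def top_snp_subset(
    weights: pd.Series, fraction: float = 0.01
) -> list:
    """Markers with the strongest absolute effect sizes.

    Ranks markers by |effect| (positive and negative effects compete
    equally) and returns the top ``fraction`` of them (at least one); ties
    are broken by marker id for determinism.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    w = pd.Series(weights)
    n_sel = max(1, int(round(fraction * len(w))))
    order = sorted(w.index, key=lambda k: (-abs(w[k]), str(k)))
    return list(order[:n_sel])


# ---------------------------------------------------------------------------
# Geographic and phenotypic distances


def geographic_distance(
    coords: pd.DataFrame, pair: Tuple[str, str]
) -> float:
    """Great-circle distance (km) between two genotypes' origins.

    ``coords`` has columns genotype_id, longitude, latitude in decimal
    degrees.
    """
    idx = coords.set_index("genotype_id")
    lon1, lat1 = idx.at[pair[0], "longitude"], idx.at[pair[0], "latitude"]
    lon2, lat2 = idx.at[pair[1], "longitude"], idx.at[pair[1], "latitude"]
    return _haversine(lon1, lat1, lon2, lat2)


def _haversine(lon1, lat1, lon2, lat2) -> float:
    for lon, lat in ((lon1, lat1), (lon2, lat2)):
        if not (-180 <= lon <= 180 and -90 <= lat <= 90):
            raise ValueError(f"coordinates out of range: ({lon}, {lat})")
    lam1, phi1, lam2, phi2 = np.radians([lon1, lat1, lon2, lat2])
    a = (
        np.sin((phi2 - phi1) / 2) ** 2
        + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2) ** 2
    )
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distance_matrix(coords: pd.DataFrame) -> pd.DataFrame:
    ids = coords["genotype_id"].to_numpy()
    lam = np.radians(coords["longitude"].to_numpy(dtype=float))
    phi = np.radians(coords["latitude"].to_numpy(dtype=float))
    if np.any(np.abs(coords["longitude"]) > 180) or np.any(np.abs(coords["latitude"]) > 90):
        raise ValueError("coordinates out of range")
    a = (
        np.sin((phi[:, None] - phi[None, :]) / 2) ** 2
        + np.cos(phi[:, None])
        * np.cos(phi[None, :])
        * np.sin((lam[:, None] - lam[None, :]) / 2) ** 2
    )
    D = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=ids, columns=ids)


def phenotypic_distance(
    summaries: pd.DataFrame,
    pair: Tuple[str, str],
    mode: str = "euclidean",
    traits: Sequence[str] = TRAITS,
    standardize: bool = True,
) -> float:
    """Phenotypic distance between two genotypes.

    ``mode='euclidean'``: Euclidean distance over the trait vector,
    standardized to unit variance across all genotypes in ``summaries`` by
    default (raw mg/d/count axes mix units incoherently).
    ``mode='mass'``: absolute difference in vegetative dry mass (mg).
    """
    idx = summaries.set_index("genotype_id")
    if mode == "mass":
        return float(abs(idx.at[pair[0], "mass_mg"] - idx.at[pair[1], "mass_mg"]))
    if mode != "euclidean":
        raise ValueError("mode must be 'euclidean' or 'mass'")
    table = idx[list(traits)].astype(float)
    if standardize:
        table = (table - table.mean()) / table.std(ddof=1)
    v1, v2 = table.loc[pair[0]], table.loc[pair[1]]
    if v1.isna().any() or v2.isna().any():
        raise ValueError(f"missing trait values for pair {pair}")
    return float(np.sqrt(((v1 - v2) ** 2).sum()))


# ---------------------------------------------------------------------------
# Heterosis ~ distance regression


@dataclass
class QuadraticRegressionResult:
    """OLS fit of heterosis on (d, d^2), with the linear-only fit alongside."""

    response: str
    predictor: str
    n: int
    intercept: float
    linear: float
    quadratic: float
    p_intercept: float
    p_linear: float
    p_quadratic: float
    r2: float
    linear_slope: float
    linear_p: float
    linear_r2: float


def regress_heterosis_on_distance(
    distances: Sequence[float],
    heterosis_values: Sequence[float],
    response: str = "heterosis",
    predictor: str = "distance",
) -> QuadraticRegressionResult:
    """Quadratic OLS of per-hybrid heterosis on parental distance.

    Tests for nonlinearity via the second-order term; the simple linear fit
    is reported alongside.  Requires >= 10 matched pairs and a
    non-degenerate predictor.
    """
    d = np.asarray(distances, dtype=float)
    h = np.asarray(heterosis_values, dtype=float)
    ok = np.isfinite(d) & np.isfinite(h)
    d, h = d[ok], h[ok]
    if len(d) < 10:
        raise ValueError("need >= 10 matched pairs")
    if d.std() == 0:
        raise ValueError("degenerate (constant) predictor")
    X = sm.add_constant(np.column_stack([d, d * d]))
    fit = sm.OLS(h, X).fit()
    Xl = sm.add_constant(d)
    lin = sm.OLS(h, Xl).fit()
    return QuadraticRegressionResult(
        response=response,
        predictor=predictor,
        n=len(d),
        intercept=float(fit.params[0]),
        linear=float(fit.params[1]),
        quadratic=float(fit.params[2]),
        p_intercept=float(fit.pvalues[0]),
        p_linear=float(fit.pvalues[1]),
        p_quadratic=float(fit.pvalues[2]),
        r2=float(fit.rsquared),
        linear_slope=float(lin.params[1]),
        linear_p=float(lin.pvalues[1]),
        linear_r2=float(lin.rsquared),
    )


def distance_long_format(matrix: pd.DataFrame) -> pd.DataFrame:
    """Upper-triangle long format (id1, id2, value) for writing to CSV."""
    ids = matrix.index.to_numpy()
    iu = np.triu_indices(len(ids), k=1)
    return pd.DataFrame(
        {"id1": ids[iu[0]], "id2": ids[iu[1]], "value": matrix.to_numpy()[iu]}
    )
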
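"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator produces replicate-level phenotype tables (inbred accessions
plus F1 hybrids), biallelic SNP matrices with an isolation-by-distance
gradient, genotype coordinates, and logistic growth trajectories.  The key
structural assumption is built in deliberately: hybrids obey the *same*
allometric curves as accessions, and any heterosis of growth rate or fruit
number emerges purely from the curvature of those curves acting on the
hybrids' (near-additive) vegetative dry mass.

All randomness flows from a single integer seed; each stage draws from a
deterministically derived substream, so identical configurations yield
byte-identical tables.
"""

from __future__ import annotations

from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .config import SyntheticConfig

PHENOTYPE_COLUMNS = [
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

_MAX_RESAMPLE = 100

# stage codes for per-stage substreams
_STAGE_ACCESSIONS = 1
_STAGE_HYBRIDS = 2
_STAGE_COORDS = 3
_STAGE_SNPS = 4
_STAGE_SERIES = 5


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def _growth_curve(M: np.ndarray, coeffs: Tuple[float, float, float]) -> np.ndarray:
    a, b, c = coeffs
    return a * M ** (b + c * np.log10(M))


def _fruit_curve(M: np.ndarray, coeffs: Tuple[float, float, float]) -> np.ndarray:
    a, b, c = coeffs
    return M / (a + b * M + c * M * M)


def _draw_traits(
    M: np.ndarray, config: SyntheticConfig, rng: np.random.Generator,
    extra_log10_sd: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """True growth rate and fruit number for genotype-level masses ``M``.

    Traits follow the generative curves with multiplicative lognormal noise;
    fruit number is floored at 1.  Non-finite or nonpositive curve values
    (possible only under pathological coefficient choices) trigger a capped
    resampling of the offending masses.
    """
    growth_sd = float(np.hypot(config.growth_noise_sd, extra_log10_sd))
    fruit_sd = float(np.hypot(config.fruit_noise_sd, extra_log10_sd))
    M = np.asarray(M, dtype=float).copy()
    for _ in range(_MAX_RESAMPLE):
        g = _growth_curve(M, config.growth_coeffs)
        f = _fruit_curve(M, config.fruit_coeffs)
        bad = ~(np.isfinite(g) & np.isfinite(f) & (g > 0) & (f > 0))
        if not bad.any():
            break
        M[bad] = 10.0 ** rng.normal(
            config.mass_log10_mean, config.mass_log10_sd, size=int(bad.sum())
        )
    else:
        raise RuntimeError(
            "could not draw positive finite trait values; check growth_coeffs"
            "/fruit_coeffs (denominator of the fruit curve may cross zero)"
        )
    growth = g * 10.0 ** rng.normal(0.0, growth_sd, size=M.shape)
    fruit = np.maximum(f * 10.0 ** rng.normal(0.0, fruit_sd, size=M.shape), 1.0)
    return M, growth, fruit


def _replicate_records(
    ids: Iterable[str],
    gtype: str,
    parent1: Iterable[Optional[str]],
    parent2: Iterable[Optional[str]],
    experiment: str,
    n_rep: int,
    M: np.ndarray,
    growth: np.ndarray,
    fruit: np.ndarray,
    cv: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Expand genotype-level true values into jittered replicate rows.

    Replicates jitter mass and growth by a lognormal factor with coefficient
    of variation ~cv; age is always defined as mass/growth so the identity
    growth * age = mass holds on every record.
    """
    n = len(M)
    rows = np.repeat(np.arange(n), n_rep)
    jitter = lambda size: np.exp(rng.normal(0.0, cv, size=size)) if cv > 0 else 1.0
    mass_r = M[rows] * jitter(rows.shape)
    growth_r = growth[rows] * jitter(rows.shape)
    fruit_r = np.maximum(np.rint(fruit[rows] * jitter(rows.shape)), 1.0)
    ids = np.asarray(list(ids), dtype=object)
    p1 = np.asarray(list(parent1), dtype=object)
    p2 = np.asarray(list(parent2), dtype=object)
    return pd.DataFrame(
        {
            "genotype_id": ids[rows],
            "type": gtype,
            "parent1": p1[rows],
            "parent2": p2[rows],
            "experiment": experiment,
            "replicate": np.tile(np.arange(1, n_rep + 1), n),
            "mass_mg": mass_r,
            "age_d": mass_r / growth_r,
            "growth_mg_per_d": growth_r,
            "fruit_n": fruit_r,
        }
    )


def generate_accessions(config: SyntheticConfig) -> pd.DataFrame:
    """Replicate-level phenotype records for the inbred accession panel."""
    rng = _stage_rng(config.seed, _STAGE_ACCESSIONS)
    n = config.n_accessions
    M = 10.0 ** rng.normal(config.mass_log10_mean, config.mass_log10_sd, size=n)
    M, growth, fruit = _draw_traits(M, config, rng)
    ids = [f"acc{i:04d}" for i in range(1, n + 1)]
    return _replicate_records(
        ids, "accession", [None] * n, [None] * n, "Exp1",
        config.replicates_accession, M, growth, fruit, config.replicate_cv, rng,
    )


def generate_hybrids(parents: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """F1 records from crosses among the accession panel.

    Each hybrid's true mass is the mid-parent mass times (1 + delta) with
    delta ~ Normal(hybrid_mass_dev_mean, hybrid_mass_dev_sd); growth rate and
    fruit number are then generated from the *same* allometric curves and
    noise as the accessions.  Parent pairs are sampled without replacement
    from distinct parents.
    """
    rng = _stage_rng(config.seed, _STAGE_HYBRIDS)
    parent_mass = parents.groupby("genotype_id", sort=True)["mass_mg"].mean()
    acc_ids = parent_mass.index.to_numpy()
    n_acc = len(acc_ids)
    if n_acc < 2:
        raise ValueError("need at least 2 accessions to form crosses")
    n_pairs_avail = n_acc * (n_acc - 1) // 2
    if config.n_hybrids > n_pairs_avail:
        raise ValueError(
            f"n_hybrids={config.n_hybrids} exceeds the {n_pairs_avail} distinct "
            f"parent pairs available from {n_acc} accessions"
        )
    # sample unordered pairs without replacement via their linear index
    pair_idx = rng.choice(n_pairs_avail, size=config.n_hybrids, replace=False)
    i = (np.floor((1 + np.sqrt(1 + 8 * pair_idx.astype(float))) / 2)).astype(int)
    j = (pair_idx - i * (i - 1) // 2).astype(int)
    p1, p2 = acc_ids[j], acc_ids[i]

    mid = (parent_mass.loc[p1].to_numpy() + parent_mass.loc[p2].to_numpy()) / 2.0
    delta = rng.normal(
        config.hybrid_mass_dev_mean, config.hybrid_mass_dev_sd, size=config.n_hybrids
    )
    # tail guard: a deviation <= -1 would imply nonpositive mass; resample
    # the (rare) draws below -0.95 rather than truncating hard
    for _ in range(_MAX_RESAMPLE):
        bad = delta <= -0.95
        if not bad.any():
            break
        delta[bad] = rng.normal(
            config.hybrid_mass_dev_mean, config.hybrid_mass_dev_sd, size=int(bad.sum())
        )
    else:
        raise RuntimeError(
            "could not draw hybrid mass deviations > -0.95; "
            "check hybrid_mass_dev_mean/hybrid_mass_dev_sd"
        )
    M = mid * (1.0 + delta)
    M, growth, fruit = _draw_traits(
        M, config, rng, extra_log10_sd=config.hybrid_trait_dev_sd
    )
    ids = [f"hyb{i:04d}" for i in range(1, config.n_hybrids + 1)]
    return _replicate_records(
        ids, "hybrid", p1, p2, "Exp2",
        config.replicates_hybrid, M, growth, fruit, config.replicate_cv, rng,
    )


def generate_coordinates(config: SyntheticConfig) -> pd.DataFrame:
    """Uniform longitude/latitude over a Eurasian-scale window per accession."""
    rng = _stage_rng(config.seed, _STAGE_COORDS)
    n = config.n_accessions
    return pd.DataFrame(
        {
            "genotype_id": [f"acc{i:04d}" for i in range(1, n + 1)],
            "longitude": rng.uniform(-10.0, 90.0, size=n),
            "latitude": rng.uniform(35.0, 65.0, size=n),
        }
    )


def generate_snp_matrix(
    config: SyntheticConfig, coords: pd.DataFrame
) -> pd.DataFrame:
    """Homozygous biallelic 0/1 SNP matrix with a spatial frequency gradient.

    Each marker's allele frequency follows a logistic cline along a random
    geographic direction, with per-marker slope ~ Normal(0, spatial_gradient).
    With spatial_gradient > 0 genetic distance therefore correlates
    positively with geographic distance; with 0 the correlation vanishes.
    Missing calls (NaN) are injected at ``missing_rate``.
    """
    rng = _stage_rng(config.seed, _STAGE_SNPS)
    ids = coords["genotype_id"].to_numpy()
    xy = coords[["longitude", "latitude"]].to_numpy(dtype=float)
    direction = rng.normal(size=2)
    direction /= np.linalg.norm(direction)
    score = xy @ direction
    sd = score.std()
    score = (score - score.mean()) / (sd if sd > 0 else 1.0)

    m = config.n_markers
    base = rng.uniform(0.05, 0.95, size=m)
    logit0 = np.log(base / (1.0 - base))
    slope = rng.normal(0.0, config.spatial_gradient, size=m)
    logit = logit0[None, :] + slope[None, :] * score[:, None]
    p = 1.0 / (1.0 + np.exp(-logit))
    calls = (rng.random(size=p.shape) < p).astype(float)
    if config.missing_rate > 0:
        calls[rng.random(size=p.shape) < config.missing_rate] = np.nan
    markers = [f"m{k:05d}" for k in range(1, m + 1)]
    return pd.DataFrame(calls, index=pd.Index(ids, name="genotype_id"), columns=markers)


def generate_growth_series(
    true_K: float,
    true_t0: float,
    true_r: float,
    times: np.ndarray,
    noise_sd: float,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """One logistic growth trajectory K/(1+exp(-r(t-t0))) + Gaussian noise."""
    times = np.asarray(times, dtype=float)
    if true_K <= 0 or true_r <= 0:
        raise ValueError("K and r must be positive")
    if times.size < 5:
        raise ValueError("need at least 5 time points")
    rng = _stage_rng(seed, _STAGE_SERIES)
    mass = true_K / (1.0 + np.exp(-true_r * (times - true_t0)))
    if noise_sd > 0:
        mass = mass + rng.normal(0.0, noise_sd, size=times.shape)
    return times, mass


def generate_dataset(config: SyntheticConfig) -> dict:
    """Full synthetic bundle: phenotypes, coordinates, SNP matrix."""
    accessions = generate_accessions(config)
    hybrids = generate_hybrids(accessions, config)
    phenotypes = pd.concat([accessions, hybrids], ignore_index=True)
    coords = generate_coordinates(config)
    snps = generate_snp_matrix(config, coords)
    return {"phenotypes": phenotypes, "coords": coords, "snps": snps}


def write_dataset(bundle: dict, outdir) -> dict:
    """Write phenotypes.csv, coords.csv and snps.tsv under ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": outdir / "phenotypes.csv",
        "coords": outdir / "coords.csv",
        "snps": outdir / "snps.tsv",
    }
    bundle["phenotypes"].to_csv(paths["phenotypes"], index=False)
    bundle["coords"].to_csv(paths["coords"], index=False)
    bundle["snps"].to_csv(paths["snps"], sep="\t", na_rep="NA")
    return paths
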
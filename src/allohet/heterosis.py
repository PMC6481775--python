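"""Heterosis quantification, bootstrap classification, and heritability.

Mid-parent heterosis (MPH) and best-parent heterosis (BPH) of a trait Y for
an F1 between parents with genotype means Y1 and Y2:

    MPH = (Y12 - mean(Y1, Y2)) / mean(Y1, Y2)
    BPH = (Y12 - max(Y1, Y2)) / max(Y1, Y2)

For positive traits BPH <= MPH always (the denominator is larger and the
numerator smaller).  Hybrids are additionally placed into five discrete
classes by comparing the bootstrap distribution of the hybrid genotype mean
to the mid-, best- and worst-parent values (two-sided vs mid, one-sided vs
best/worst) with Bonferroni control over the whole family of tests.

Broad-sense heritability is the genotypic share of phenotypic variance,
H^2 = var(G) / (var(G) + var(residual)), from a random-intercept
(genotype) variance decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TRAITS = ["mass_mg", "age_d", "growth_mg_per_d", "fruit_n"]

CATEGORIES = ["below_worst", "negative", "additive", "positive", "above_best"]


def mph(y1: float, y2: float, y12: float) -> float:
    """Mid-parent heterosis; parental values must be positive."""
    if y1 <= 0 or y2 <= 0:
        raise ValueError("parental values must be positive")
    mid = (y1 + y2) / 2.0
    return (y12 - mid) / mid


def bph(y1: float, y2: float, y12: float) -> float:
    """Best-parent heterosis; parental values must be positive."""
    if y1 <= 0 or y2 <= 0:
        raise ValueError("parental values must be positive")
    best = max(y1, y2)
    return (y12 - best) / best


def heterosis_table(
    summaries: pd.DataFrame, traits: Sequence[str] = ("growth_mg_per_d", "fruit_n")
) -> pd.DataFrame:
    """Per hybrid x trait MPH/BPH from a genotype-summary frame.

    ``summaries`` is the output of
    :func:`allohet.phenotype_io.summarize_genotypes`; hybrids whose parents
    lack the trait are skipped.
    """
    idx = summaries.set_index("genotype_id")
    hybrids = summaries[summaries["type"] == "hybrid"]
    rows = []
    for _, h in hybrids.iterrows():
        p1, p2 = h["parent1"], h["parent2"]
        if p1 not in idx.index or p2 not in idx.index:
            continue
        for trait in traits:
            y1, y2, y12 = idx.at[p1, trait], idx.at[p2, trait], h[trait]
            if not (np.isfinite(y1) and np.isfinite(y2) and np.isfinite(y12)):
                continue
            if y1 <= 0 or y2 <= 0:
                continue
            rows.append(
                {
                    "hybrid_id": h["genotype_id"],
                    "trait": trait,
                    "y1": y1,
                    "y2": y2,
                    "y12": y12,
                    "mph": mph(y1, y2, y12),
                    "bph": bph(y1, y2, y12),
                }
            )
    return pd.DataFrame(rows, columns=["hybrid_id", "trait", "y1", "y2", "y12", "mph", "bph"])


@dataclass
class HeterosisClassification:
    hybrid_id: str
    trait: str
    category: str
    p_mid: float
    p_best: float
    p_worst: float


def _boot_se(values: np.ndarray, n_boot: int, rng: np.random.Generator) -> float:
    boots = rng.choice(values, size=(n_boot, len(values)), replace=True).mean(axis=1)
    return float(boots.std(ddof=1))


def classify_heterosis(
    hybrid_replicates: Sequence[float],
    parent1_mean: float,
    parent2_mean: float,
    n_boot: int = 1000,
    alpha: float = 0.05,
    family_size: int = 3,
    rng: Optional[np.random.Generator] = None,
    hybrid_id: str = "",
    trait: str = "",
) -> HeterosisClassification:
    """Classify one hybrid's trait against its parents.

    The bootstrap (``n_boot`` resamples with replacement of the hybrid's
    replicate measurements) supplies the standard error of the hybrid
    genotype mean; the mean is then compared to the mid-parent value
    (two-sided), the best parent (one-sided, above) and the worst parent
    (one-sided, below).  P-values are Bonferroni-adjusted by
    ``family_size`` (callers classifying a cohort pass 3 x n_hybrids).

    With < 2 replicates the category is ``unclassifiable``; with zero
    replicate spread the comparison degenerates to exact inequalities.
    """
    y = np.asarray(hybrid_replicates, dtype=float)
    y = y[np.isfinite(y)]
    if len(y) < 2:
        return HeterosisClassification(hybrid_id, trait, "unclassifiable", np.nan, np.nan, np.nan)
    if rng is None:
        rng = np.random.default_rng()
    mean = float(y.mean())
    worst = min(parent1_mean, parent2_mean)
    best = max(parent1_mean, parent2_mean)
    mid = (parent1_mean + parent2_mean) / 2.0
    se = _boot_se(y, n_boot, rng)
    df = n_boot - 1

    def one_sided(value: float, direction: str) -> float:
        if se == 0:
            if direction == "greater":
                return 0.0 if mean > value else 1.0
            return 0.0 if mean < value else 1.0
        t = (mean - value) / se
        return float(stats.t.sf(t, df) if direction == "greater" else stats.t.cdf(t, df))

    if se == 0:
        p_mid = 0.0 if mean != mid else 1.0
    else:
        p_mid = float(2.0 * stats.t.sf(abs((mean - mid) / se), df))
    p_best = one_sided(best, "greater")
    p_worst = one_sided(worst, "less")
    adj = lambda p: min(1.0, p * family_size)
    p_mid, p_best, p_worst = adj(p_mid), adj(p_best), adj(p_worst)

    if p_best < alpha and mean > best:
        category = "above_best"
    elif p_worst < alpha and mean < worst:
        category = "below_worst"
    elif p_mid < alpha:
        category = "positive" if mean > mid else "negative"
    else:
        category = "additive"
    return HeterosisClassification(hybrid_id, trait, category, p_mid, p_best, p_worst)


def classify_cohort(
    records: pd.DataFrame,
    summaries: pd.DataFrame,
    traits: Sequence[str] = TRAITS,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    family_size: Optional[int] = None,
) -> pd.DataFrame:
    """Bootstrap classification of every hybrid for each trait.

    The Bonferroni family defaults to 3 tests x number of hybrids (per
    trait).  Returns a long-format frame with adjusted p-values and the
    assigned category.
    """
    idx = summaries.set_index("genotype_id")
    hyb = records[records["type"] == "hybrid"]
    hybrid_ids = sorted(hyb["genotype_id"].unique())
    fam = family_size if family_size is not None else 3 * len(hybrid_ids)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
    out = []
    groups = {gid: g for gid, g in hyb.groupby("genotype_id")}
    for trait in traits:
        for gid in hybrid_ids:
            g = groups[gid]
            p1, p2 = g["parent1"].iloc[0], g["parent2"].iloc[0]
            if p1 not in idx.index or p2 not in idx.index:
                continue
            y1, y2 = idx.at[p1, trait], idx.at[p2, trait]
            if not (np.isfinite(y1) and np.isfinite(y2)):
                continue
            cls = classify_heterosis(
                g[trait].to_numpy(), y1, y2, n_boot=n_boot, alpha=alpha,
                family_size=fam, rng=rng, hybrid_id=gid, trait=trait,
            )
            out.append(cls.__dict__)
    return pd.DataFrame(out)


def classification_summary(classes: pd.DataFrame) -> Dict[str, Dict[str, float]]:
    """Per-trait percentage of hybrids in each category (sums to 100)."""
    out: Dict[str, Dict[str, float]] = {}
    for trait, grp in classes.groupby("trait"):
        counts = grp["category"].value_counts()
        total = counts.sum()
        pct = {cat: 100.0 * counts.get(cat, 0) / total for cat in CATEGORIES}
        if "unclassifiable" in counts:
            pct["unclassifiable"] = 100.0 * counts["unclassifiable"] / total
        pct["heterotic"] = 100.0 - pct.get("additive", 0.0) - pct.get("unclassifiable", 0.0)
        out[trait] = pct
    return out


@dataclass
class HeritabilityEstimate:
    trait: str
    var_genotype: float
    var_residual: float

    @property
    def h2(self) -> float:
        total = self.var_genotype + self.var_residual
        return self.var_genotype / total if total > 0 else 0.0


def heritability(
    records: pd.DataFrame, trait: str, method: str = "anova"
) -> HeritabilityEstimate:
    """Broad-sense heritability from replicate records.

    ``method='anova'`` (default) is the one-way random-effects
    method-of-moments estimator with the unbalanced-design correction
    n0 = (N - sum(n_i^2)/N) / (k - 1); ``method='reml'`` fits a
    random-intercept mixed model via statsmodels MixedLM.  Computed on all
    supplied records (accessions and hybrids pooled) unless pre-filtered.
    """
    sub = records.dropna(subset=[trait])
    counts = sub.groupby("genotype_id")[trait].count()
    replicated = counts[counts >= 2]
    if len(replicated) < 2:
        raise ValueError("need >= 2 genotypes with >= 2 replicates")
    if method == "reml":
        import statsmodels.formula.api as smf

        data = sub.rename(columns={trait: "y"})[["y", "genotype_id"]]
        fit = smf.mixedlm("y ~ 1", data, groups=data["genotype_id"]).fit(reml=True)
        var_g = float(fit.cov_re.iloc[0, 0])
        var_e = float(fit.scale)
        return HeritabilityEstimate(trait, var_g, var_e)
    if method != "anova":
        raise ValueError("method must be 'anova' or 'reml'")
    grand = sub[trait].mean()
    groups = sub.groupby("genotype_id")[trait]
    ni = groups.count().to_numpy(dtype=float)
    means = groups.mean().to_numpy()
    N, k = ni.sum(), len(ni)
    ss_between = float((ni * (means - grand) ** 2).sum())
    ss_within = float(((sub[trait] - groups.transform("mean")) ** 2).sum())
    msb = ss_between / (k - 1)
    msw = ss_within / (N - k) if N > k else 0.0
    n0 = (N - (ni**2).sum() / N) / (k - 1)
    var_g = max((msb - msw) / n0, 0.0)
    return HeritabilityEstimate(trait, var_g, msw)
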
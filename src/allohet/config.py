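"""Configuration objects for the synthetic cohort generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Tuple

#: Growth-rate allometry g(M) = a * M**(b + c*log10(M)) fitted on 451 natural
#: Arabidopsis thaliana accessions (a, b, c); the generator's default curve.
ACCESSION_GROWTH_COEFFS: Tuple[float, float, float] = (0.022, 1.483, -0.164)

#: Fruit-number allometry f(M) = M / (a + b*M + c*M**2) fitted on the same
#: accession panel (a, b, c).
ACCESSION_FRUIT_COEFFS: Tuple[float, float, float] = (0.155, 0.0022, 1.292e-5)

#: Hybrid-panel counterparts of the two curves above.
HYBRID_GROWTH_COEFFS: Tuple[float, float, float] = (0.020, 1.456, -0.151)
HYBRID_FRUIT_COEFFS: Tuple[float, float, float] = (0.116, 0.0025, 1.444e-5)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic phenotype/genotype cohort.

    Defaults emulate the reference study design: 451 inbred accessions
    phenotyped with n=2 replicates (Exp1), 450 F1 hybrids with n=4 (Exp2),
    vegetative dry mass M roughly lognormal over ~1-2,000 mg, growth rate
    tightly coupled to M through the mass-corrected power law and fruit
    number loosely coupled through the inverse-quadratic curve.

    Parameters
    ----------
    n_accessions, n_hybrids
        Number of inbred genotypes and of F1 crosses between them.
    replicates_accession, replicates_hybrid
        Replicate plants measured per genotype.
    mass_log10_mean, mass_log10_sd
        Genotype-level true mass is drawn as ``10**Normal(mean, sd)`` (mg).
    growth_coeffs, fruit_coeffs
        (a, b, c) of the generative allometries.
    growth_noise_sd, fruit_noise_sd
        SD of the multiplicative log10-scale trait noise around each curve.
    hybrid_mass_dev_mean, hybrid_mass_dev_sd
        Fractional deviation delta of hybrid true mass from the mid-parent
        mass: M_hybrid = mid-parent M * (1 + delta). A negative mean produces
        the negative-skew heterosis regime.
    hybrid_trait_dev_sd
        Optional extra log10-scale deviation applied to hybrid growth/fruit
        on top of the shared curves (0 = hybrids obey the parental
        allometries exactly, the structural assumption under test).
    replicate_cv
        Within-genotype coefficient of variation of replicate measurements.
    n_markers, missing_rate, spatial_gradient
        SNP matrix size, per-call missingness, and strength of the latent
        spatial allele-frequency gradient (isolation by distance).
    seed
        Single global seed; every stage derives its own substream.
    """

    n_accessions: int = 451
    n_hybrids: int = 450
    replicates_accession: int = 2
    replicates_hybrid: int = 4
    mass_log10_mean: float = 1.6
    mass_log10_sd: float = 0.7
    growth_coeffs: Tuple[float, float, float] = ACCESSION_GROWTH_COEFFS
    fruit_coeffs: Tuple[float, float, float] = ACCESSION_FRUIT_COEFFS
    growth_noise_sd: float = 0.05
    fruit_noise_sd: float = 0.3
    hybrid_mass_dev_mean: float = -0.10
    hybrid_mass_dev_sd: float = 0.35
    hybrid_trait_dev_sd: float = 0.0
    replicate_cv: float = 0.1
    n_markers: int = 1000
    missing_rate: float = 0.0
    spatial_gradient: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_accessions": self.n_accessions,
            "n_hybrids": self.n_hybrids,
            "replicates_accession": self.replicates_accession,
            "replicates_hybrid": self.replicates_hybrid,
            "n_markers": self.n_markers,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {value!r}")
        nonneg = {
            "mass_log10_sd": self.mass_log10_sd,
            "growth_noise_sd": self.growth_noise_sd,
            "fruit_noise_sd": self.fruit_noise_sd,
            "hybrid_mass_dev_sd": self.hybrid_mass_dev_sd,
            "hybrid_trait_dev_sd": self.hybrid_trait_dev_sd,
            "replicate_cv": self.replicate_cv,
            "missing_rate": self.missing_rate,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value!r}")
        if self.growth_coeffs[0] <= 0:
            raise ValueError("growth_coeffs.a must be > 0")
        if self.fruit_coeffs[0] <= 0:
            raise ValueError("fruit_coeffs.a must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Either ``synthetic`` is True (a :class:`SyntheticConfig` supplies all
    inputs) or ``phenotypes`` points at a replicate-level phenotype table;
    SNP/coordinate/weight inputs are optional and only enable the distance
    stage.
    """

    synthetic: bool = True
    synthetic_config: SyntheticConfig = field(default_factory=SyntheticConfig)
    phenotypes: Optional[Path] = None
    snps: Optional[Path] = None
    coords: Optional[Path] = None
    snp_weights: Optional[Path] = None
    stages: Sequence[str] = ("fit", "heterosis", "nldev", "distances")
    n_boot: int = 1000
    alpha: float = 0.05
    seed: int = 0
    outdir: Optional[Path] = None

    def __post_init__(self) -> None:
        if not self.synthetic and self.phenotypes is None:
            raise ValueError(
                "either synthetic mode or a phenotype table must be supplied"
            )
        known = {"fit", "heterosis", "nldev", "distances"}
        unknown = set(self.stages) - known
        if unknown:
            raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")
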
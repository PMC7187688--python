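"""Multi-ethnic cohort simulation with known genetic architecture.

Populations diverge from a shared ancestral SNP panel under the
Balding-Nichols model: for ancestral frequency ``p`` and divergence ``Fst``,
each population's frequency is a Beta draw with mean ``p`` and variance
``Fst * p * (1 - p)``. Genotypes are Hardy-Weinberg binomial draws within
population. A continuous lung-function-like endophenotype is built from
standardized causal dosages plus clinical covariate effects (age, sex,
height, pack-years) and Gaussian noise, with causal effects rescaled so the
genetic fraction of the non-covariate variance equals the target SNP
heritability. Disease status is a liability threshold: a sample is a case
when its trait falls below the population's case-fraction quantile,
emulating a spirometric cutoff while letting very different case ratios be
specified per population.

Each population can carry its own causal SNP set; the overlap between the
sets is the knob that plants (or removes) cross-population transferability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, write_genotypes, write_phenotypes

__all__ = [
    "PopulationSpec",
    "SimulationConfig",
    "SimulatedCohort",
    "draw_allele_frequencies",
    "generate_genotypes",
    "generate_phenotypes",
    "make_populations",
    "simulate_cohort",
    "simulate_study",
    "write_cohort",
]

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass
class PopulationSpec:
    """One population's sample size, case fraction, and causal architecture."""

    label: str
    n_samples: int
    case_fraction_target: float
    causal_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    causal_effects: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.causal_indices = np.asarray(self.causal_indices, dtype=int)
        self.causal_effects = np.asarray(self.causal_effects, dtype=float)
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0.0 < self.case_fraction_target < 1.0:
            raise ValueError("case_fraction_target must be in (0,1)")
        if self.causal_indices.size != self.causal_effects.size:
            raise ValueError("causal_indices and causal_effects must match in length")


@dataclass
class SimulationConfig:
    """Panel-wide simulation parameters.

    ``covariate_effects`` are coefficients on the standardized covariates
    (age, sex, height, pack_years) in trait units; the trait's non-covariate
    part has unit variance, so a coefficient of 0.3 contributes 0.09 of
    extra variance. ``fst`` is the Balding-Nichols divergence;
    ``cross_population_causal_overlap`` is the fraction of causal SNPs
    shared between populations when causal sets are auto-assigned.
    """

    n_variants: int = 5000
    fst: float = 0.15
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    target_h2: float = 0.4
    n_causal: int = 100
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": -0.3, "sex": 0.15, "height": 0.3, "pack_years": -0.25}
    )
    cross_population_causal_overlap: float = 1.0
    ld_block_size: int = 1
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst={self.fst} must be in [0,1)")
        if not 0.0 <= self.target_h2 < 1.0:
            raise ValueError(f"target_h2={self.target_h2} must be in [0,1)")
        lo, hi = self.ancestral_maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("ancestral_maf_range must sit within (0, 0.5]")
        if not 0.0 <= self.cross_population_causal_overlap <= 1.0:
            raise ValueError("cross_population_causal_overlap must be in [0,1]")
        if self.n_variants < self.n_causal:
            raise ValueError("n_variants must cover the causal count")


@dataclass
class SimulatedCohort:
    """One population's genotypes and phenotypes plus the ground truth."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: dict

    def __post_init__(self) -> None:
        if len(self.phenotypes) != self.genotypes.n_samples:
            raise ValueError("phenotype rows must match genotype samples")


def draw_allele_frequencies(
    config: SimulationConfig, populations: list[PopulationSpec]
) -> pd.DataFrame:
    """Ancestral and per-population effect-allele frequencies.

    Balding-Nichols: population frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F),
    which has mean p and variance F*p*(1-p). F=0 copies the ancestral
    frequencies. Draws are clipped away from {0,1} so downstream binomial
    sampling and standardization stay well defined.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=config.n_variants)
    out = {"ancestral": p_anc}
    for pop in populations:
        if config.fst == 0.0:
            out[pop.label] = p_anc.copy()
        else:
            ratio = (1.0 - config.fst) / config.fst
            freqs = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio)
            out[pop.label] = np.clip(freqs, 1e-6, 1.0 - 1e-6)
    return pd.DataFrame(out)


def _variant_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    m = config.n_variants
    chrom = (np.arange(m) * 22 // m + 1).astype(str)
    pos = np.empty(m, dtype=int)
    for c in np.unique(chrom):
        mask = chrom == c
        pos[mask] = np.arange(1, mask.sum() + 1) * 1000
    pairs = [_ALLELE_PAIRS[k] for k in rng.integers(0, len(_ALLELE_PAIRS), size=m)]
    return pd.DataFrame(
        {
            "id": [f"snp{j:06d}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "allele_effect": [a for a, _ in pairs],
            "allele_other": [b for _, b in pairs],
        }
    )


def generate_genotypes(
    freqs: np.ndarray,
    population: PopulationSpec,
    variants: pd.DataFrame,
    rng: np.random.Generator,
    ld_block_size: int = 1,
    ld_rho: float = 0.0,
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes (binomial(2, freq)) for one population.

    With ``ld_block_size > 1`` and ``ld_rho > 0``, adjacent variants within a
    block are correlated through a shared AR(1) Gaussian liability per
    haplotype (a coarse linkage-disequilibrium stand-in; off by default).
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0.0) | (freqs >= 1.0)):
        raise ValueError("frequencies must lie strictly inside (0,1)")
    n, m = population.n_samples, freqs.size
    if ld_block_size <= 1 or ld_rho == 0.0:
        values = rng.binomial(2, freqs, size=(n, m)).astype(float)
    else:
        from scipy.stats import norm

        thresh = norm.ppf(freqs)  # allele present when latent < threshold
        values = np.zeros((n, m))
        for _hap in range(2):
            z = rng.standard_normal((n, m))
            for start in range(0, m, ld_block_size):
                blk = slice(start, min(start + ld_block_size, m))
                zb = z[:, blk]
                for j in range(1, zb.shape[1]):
                    zb[:, j] = ld_rho * zb[:, j - 1] + np.sqrt(1 - ld_rho**2) * zb[:, j]
                z[:, blk] = zb
            values += (z < thresh).astype(float)
    samples = pd.DataFrame(
        {
            "id": [f"{population.label}_{i:05d}" for i in range(n)],
            "reported_sex": "unknown",
        }
    )
    return GenotypeMatrix(values, variants.copy(), samples)


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Clinical covariates with realistic marginals.

    Age ~ N(57, 9) years; sex ~ Bernoulli(0.5) (1 = male); height ~ N by sex
    (175/162 cm); pack-years zero-inflated Gamma (40% never-smokers,
    Gamma(1.5, 20) otherwise); family history ~ Bernoulli(0.15).
    """
    age = rng.normal(57.0, 9.0, size=n)
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    height = np.where(sex == 1, rng.normal(175.0, 7.0, n), rng.normal(162.0, 6.0, n))
    smoker = rng.random(n) >= 0.4
    pack_years = np.where(smoker, rng.gamma(1.5, 20.0, size=n), 0.0)
    family_history = rng.binomial(1, 0.15, size=n).astype(float)
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "height": height,
            "pack_years": pack_years,
            "family_history": family_history,
        }
    )


def generate_phenotypes(
    genotypes: GenotypeMatrix,
    population: PopulationSpec,
    config: SimulationConfig,
    pop_freqs: np.ndarray,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Continuous trait, thresholded case status, covariates, and truth.

    The genetic value is a weighted sum of standardized causal dosages,
    rescaled so its variance is ``target_h2`` against noise variance
    ``1 - target_h2``; covariate effects add on top, so REML on the trait
    with covariates as fixed effects targets h2 = sigma_g^2/(sigma_g^2 +
    sigma_e^2). Cases are samples below the case-fraction quantile of the
    trait (low lung function = disease).
    """
    n = genotypes.n_samples
    idx = population.causal_indices
    if idx.size and idx.max() >= genotypes.n_variants:
        raise ValueError("causal index outside variant panel")
    h2 = config.target_h2
    g_value = np.zeros(n)
    if idx.size and h2 > 0:
        p = np.asarray(pop_freqs, dtype=float)[idx]
        G = (genotypes.values[:, idx] - 2 * p) / np.sqrt(2 * p * (1 - p))
        raw = G @ population.causal_effects
        sd = raw.std()
        if sd > 0:
            g_value = raw / sd * np.sqrt(h2)
    noise = rng.normal(0.0, np.sqrt(1.0 - h2), size=n)
    cov = _draw_covariates(n, rng)
    cov_contrib = np.zeros(n)
    for name, beta in config.covariate_effects.items():
        x = cov[name].to_numpy()
        sd = x.std()
        if beta != 0.0 and sd > 0:
            cov_contrib += beta * (x - x.mean()) / sd
    trait = g_value + cov_contrib + noise
    cutoff = np.quantile(trait, population.case_fraction_target)
    status = (trait < cutoff).astype(int)
    var_g = float(np.var(g_value))
    var_e = float(np.var(noise))
    truth = {
        "label": population.label,
        "causal_indices": idx.tolist(),
        "causal_effects": population.causal_effects.tolist(),
        "realized_h2": var_g / (var_g + var_e) if var_g + var_e > 0 else 0.0,
        "genetic_values": g_value.tolist(),
        "case_fraction": float(status.mean()),
        "allele_frequencies": np.asarray(pop_freqs, dtype=float).tolist(),
    }
    phen = pd.DataFrame(
        {
            "sample_id": genotypes.samples["id"],
            "status": status,
            "trait": trait,
            "age": cov["age"],
            "sex": cov["sex"],
            "height": cov["height"],
            "pack_years": cov["pack_years"],
            "family_history": cov["family_history"],
            "ethnicity": population.label,
        }
    )
    return phen, truth


def make_populations(
    config: SimulationConfig,
    labels: list[str],
    n_samples: list[int],
    case_fractions: list[float],
    effect_distribution: str = "normal",
) -> list[PopulationSpec]:
    """Assign causal sets realizing the configured cross-population overlap.

    The first ``round(overlap * n_causal)`` causal indices are shared by all
    populations; the remainder are population-private, drawn disjointly.
    ``effect_distribution``: "normal" draws standard-normal effect sizes (a
    polygenic spectrum with many near-zero effects); "equal" gives every
    causal SNP the same magnitude with a random sign (a planted-signal
    architecture where each causal SNP carries h2/n_causal of the genetic
    variance, useful when screening detectability itself is under test).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    if effect_distribution not in ("normal", "equal"):
        raise ValueError(f"unknown effect distribution {effect_distribution!r}")

    def draw_effects(k_: int) -> np.ndarray:
        if effect_distribution == "normal":
            return rng.standard_normal(k_)
        return rng.choice([-1.0, 1.0], size=k_)

    k = config.n_causal
    n_shared = int(round(config.cross_population_causal_overlap * k))
    n_private = k - n_shared
    need = n_shared + n_private * len(labels)
    if need > config.n_variants:
        raise ValueError("variant panel too small for requested causal architecture")
    pool = rng.choice(config.n_variants, size=need, replace=False)
    shared = pool[:n_shared]
    shared_eff = draw_effects(n_shared)
    pops = []
    for i, (lab, n, cf) in enumerate(zip(labels, n_samples, case_fractions)):
        private = pool[n_shared + i * n_private : n_shared + (i + 1) * n_private]
        eff_private = draw_effects(n_private)
        idx = np.concatenate([shared, private])
        eff = np.concatenate([shared_eff, eff_private])
        order = np.argsort(idx)
        pops.append(
            PopulationSpec(
                label=lab,
                n_samples=n,
                case_fraction_target=cf,
                causal_indices=idx[order],
                causal_effects=eff[order],
            )
        )
    return pops


def simulate_cohort(
    config: SimulationConfig, populations: list[PopulationSpec]
) -> list[SimulatedCohort]:
    """Simulate one cohort per population on a shared variant panel."""
    freqs = draw_allele_frequencies(config, populations)
    meta_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    variants = _variant_table(config, meta_rng)
    cohorts = []
    for i, pop in enumerate(populations):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, i]))
        g = generate_genotypes(
            freqs[pop.label].to_numpy(),
            pop,
            variants,
            rng,
            ld_block_size=config.ld_block_size,
            ld_rho=config.ld_rho,
        )
        phen, truth = generate_phenotypes(g, pop, config, freqs[pop.label].to_numpy(), rng)
        truth["fst"] = config.fst
        truth["target_h2"] = config.target_h2
        cohorts.append(SimulatedCohort(g, phen, truth))
    return cohorts


def simulate_study(
    config: SimulationConfig,
    labels: list[str] | None = None,
    n_samples: list[int] | None = None,
    case_fractions: list[float] | None = None,
) -> list[SimulatedCohort]:
    """Convenience wrapper: two populations at study-like shapes by default.

    Defaults follow the shape of real multi-ethnic COPD panels — a
    case-enriched case/control population (case fraction ~0.5) and a
    population-cohort-style group with a low case fraction (~0.09).
    """
    labels = labels or ["POP1", "POP2"]
    n_samples = n_samples or [2000] * len(labels)
    case_fractions = case_fractions or ([0.3] * len(labels))
    pops = make_populations(config, labels, n_samples, case_fractions)
    return simulate_cohort(config, pops)


def write_cohort(cohort: SimulatedCohort, prefix: str | Path) -> None:
    """PLINK BED/BIM/FAM + phenotype TSV + truth JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_genotypes(cohort.genotypes, prefix, dialect="plink_bed")
    write_phenotypes(cohort.phenotypes, prefix.with_suffix(".pheno.tsv"))
    prefix.with_suffix(".truth.json").write_text(json.dumps(cohort.truth))
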
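"""Synthetic-locus generator with known ground truth.

Emulates a deep resequencing study of a single ~528 kb locus: a
rare-heavy site-frequency spectrum, Hardy-Weinberg genotypes for
case-control cohorts ascertained under a logistic disease model,
age/sex-structured quantitative traits, a two-study variant-capture
process for mark-recapture work, and nuclear pedigrees for segregation
checks.  Every generator is a pure function of (config, seed): per-stage
random streams are derived from the master seed with fixed
``SeedSequence`` spawn keys, so stages are independently reproducible.

Spectra
-------
``neutral``   allele count i on 2N chromosomes drawn with P(i) ~ 1/i
              (the standard neutral expectation), f = i/(2N).
``beta``      f ~ Beta(a, b), a flexible skewed alternative.
``disc1_like`` two-component log-uniform mixture calibrated to the
              observed rare:common split of the motivating study design
              (2010 rare : 708 common, i.e. 74% of sites below 1% MAF) —
              a small-2N neutral spectrum cannot be that rare-heavy.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CASE_GROUPS, CohortSheet, GenotypeMatrix, VariantRecord
from .pedigree import Pedigree, PedigreeMember
from .pool import CaptureCount

import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "CaptureTruth",
    "AscertainmentError",
    "DEFAULT_GROUP_SIZES",
    "DISC1_RARE_FRACTION",
    "simulate_frequencies",
    "disc1_like_frequencies",
    "simulate_cohort",
    "simulate_capture",
    "simulate_pedigree",
]

#: Cohort sizes of the motivating study design: 240 SZ, 221 BD, 192 rMDD
#: cases and 889 population controls.
DEFAULT_GROUP_SIZES = {"SZ": 240, "BD": 221, "rMDD": 192, "control": 889}

#: Observed rare fraction of the motivating design: 2010 of 2718 sites
#: below 1% MAF.
DISC1_RARE_FRACTION = 2010 / 2718

# fixed spawn keys so each stage has its own reproducible stream
_STREAMS = {"ascertain": 0, "covariates": 1, "traits": 2}


class AscertainmentError(RuntimeError):
    """Case/control quotas could not be filled within the draw budget."""


@dataclass
class SimulationConfig:
    """Stated world for the cohort generator.

    Parameters
    ----------
    n_sites
        Number of segregating sites S at the locus.
    ref_diploid_size
        Diploid reference size N for the site-frequency spectrum
        (allele counts live on 1..2N-1).
    group_sizes
        Samples per diagnosis group; defaults to the motivating study.
    causal_or
        ``[(site_index, odds_ratio)]`` multiplicative per-minor-allele
        disease effects.
    causal_beta
        ``[(site_index, beta)]`` additive per-minor-allele trait effects.
    alpha
        Baseline log-odds of being a case; default logit(0.1) ~ -2.2
        (≈10% lifetime prevalence of the pooled diagnoses).
    gamma_age, gamma_sex, sigma
        Trait covariate effects (per year; F vs M) and residual SD.
    age_range
        Uniform age support; default 69-71 years, a single-year birth
        cohort at the age the control panel was phenotyped.
    max_draw_factor
        Rejection-sampling budget: at most ``factor * n_samples`` draws.
    """

    n_sites: int = 2718
    ref_diploid_size: int = 200
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    causal_or: list = field(default_factory=list)
    causal_beta: list = field(default_factory=list)
    alpha: float = -2.2
    gamma_age: float = 0.0
    gamma_sex: float = 0.0
    sigma: float = 1.0
    age_range: tuple = (69.0, 71.0)
    trait_name: str = "trait"
    max_draw_factor: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.ref_diploid_size < 2:
            raise ValueError("ref_diploid_size must be >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if any(orv <= 0 for _, orv in self.causal_or):
            raise ValueError("odds ratios must be positive")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        unknown = set(self.group_sizes) - {*CASE_GROUPS, "control"}
        if unknown:
            raise ValueError(f"unknown groups {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Ground truth the generator knows and the pipeline must recover."""

    frequencies: np.ndarray
    causal_or: list
    causal_beta: list
    n_draws_used: int | None = None


@dataclass
class CaptureTruth:
    frequencies: np.ndarray
    detected_a: np.ndarray
    detected_b: np.ndarray
    stratum: np.ndarray  # per-site stratum label (by study-A sample MAF)


def simulate_frequencies(
    S: int,
    N: int,
    seed: int,
    spectrum: str = "neutral",
    beta_params: tuple = (0.2, 2.0),
) -> np.ndarray:
    """Population allele frequencies for S sites.

    ``neutral``: count i in {1..2N-1} with probability proportional to
    1/i, f = i/(2N).  ``beta``: f ~ Beta(a, b) (continuous alternative).
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if N < 2:
        raise ValueError("reference diploid size N must be >= 2")
    rng = np.random.default_rng(seed)
    if spectrum == "neutral":
        counts = np.arange(1, 2 * N)
        w = 1.0 / counts
        f = rng.choice(counts, size=S, p=w / w.sum()) / (2.0 * N)
    elif spectrum == "beta":
        a, b = beta_params
        f = rng.beta(a, b, size=S)
        f = np.clip(f, 1.0 / (2 * N), 1 - 1.0 / (2 * N))
    else:
        raise ValueError("spectrum must be 'neutral' or 'beta'")
    return f


def disc1_like_frequencies(
    S: int = 2718,
    seed: int = 0,
    rare_fraction: float = DISC1_RARE_FRACTION,
    f_min: float = 5e-4,
    f_split: float = 0.01,
    f_max: float = 0.5,
) -> np.ndarray:
    """Rare-heavy mixture spectrum: with probability ``rare_fraction`` a
    site's minor-allele frequency is log-uniform on [f_min, f_split),
    otherwise log-uniform on [f_split, f_max]."""
    rng = np.random.default_rng(seed)
    rare = rng.random(S) < rare_fraction
    lo = np.where(rare, np.log(f_min), np.log(f_split))
    hi = np.where(rare, np.log(f_split), np.log(f_max))
    return np.exp(rng.uniform(lo, hi))


def _liability_probs(genotypes: np.ndarray, config: SimulationConfig) -> np.ndarray:
    logit = np.full(genotypes.shape[0], config.alpha)
    for site, orv in config.causal_or:
        logit = logit + np.log(orv) * genotypes[:, site]
    return 1.0 / (1.0 + np.exp(-logit))


def simulate_cohort(
    config: SimulationConfig, frequencies: np.ndarray
) -> tuple[GenotypeMatrix, CohortSheet, SyntheticTruth]:
    """Ascertained case-control cohort with genotypes, covariates and a
    quantitative trait.

    Genotypes are Hardy-Weinberg Binomial(2, f_v) draws; affection
    follows the logistic model logit P(case) = alpha + sum_v
    log(OR_v) g_iv, and individuals are drawn until every group quota is
    filled (rejection sampling = case-control ascertainment), a case
    being assigned uniformly at random among unfilled case groups.  The
    trait is y_i = sum_v beta_v g_iv + gamma_age age_i + gamma_sex
    sex_i + eps_i with eps ~ N(0, sigma^2), ages uniform on the
    configured range and sex Bernoulli(1/2) (coded M=0, F=1).
    """
    frequencies = np.asarray(frequencies, dtype=float)
    if frequencies.size != config.n_sites:
        raise ValueError("frequencies length must equal config.n_sites")
    for site, _ in [*config.causal_or, *config.causal_beta]:
        if not 0 <= site < config.n_sites:
            raise ValueError(f"causal site index {site} out of range")
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    rng_asc, rng_cov, rng_trait = (np.random.default_rng(c) for c in children)

    quotas = {g: config.group_sizes.get(g, 0) for g in (*CASE_GROUPS, "control")}
    n_total = sum(quotas.values())
    if n_total < 1:
        raise ValueError("total cohort size must be >= 1")
    need_cases = {g: quotas[g] for g in CASE_GROUPS}
    need_controls = quotas["control"]

    genos: list[np.ndarray] = []
    groups: list[str] = []
    max_draws = config.max_draw_factor * n_total
    drawn = 0
    batch = max(256, n_total)
    while (any(v > 0 for v in need_cases.values()) or need_controls > 0):
        if drawn >= max_draws:
            raise AscertainmentError(
                f"quotas unfilled after {drawn} draws "
                f"(remaining cases {need_cases}, controls {need_controls})"
            )
        nb = min(batch, max_draws - drawn)
        g = rng_asc.binomial(2, frequencies[None, :], size=(nb, config.n_sites)).astype(np.int8)
        p_case = _liability_probs(g, config)
        is_case = rng_asc.random(nb) < p_case
        # uniform assignment among unfilled case groups, fixed per draw
        for i in range(nb):
            if is_case[i]:
                open_groups = [grp for grp in CASE_GROUPS if need_cases[grp] > 0]
                if not open_groups:
                    continue
                grp = open_groups[rng_asc.integers(len(open_groups))]
                need_cases[grp] -= 1
            else:
                if need_controls <= 0:
                    continue
                grp = "control"
                need_controls -= 1
            genos.append(g[i])
            groups.append(grp)
        drawn += nb

    order = np.argsort(
        [(*CASE_GROUPS, "control").index(grp) for grp in groups], kind="stable"
    )
    calls = np.stack(genos, axis=0)[order]
    groups = [groups[i] for i in order]

    n = len(groups)
    ages = rng_cov.uniform(*config.age_range, size=n)
    sex01 = rng_cov.integers(0, 2, size=n)
    eps = rng_trait.normal(0.0, config.sigma, size=n)
    y = eps + config.gamma_age * ages + config.gamma_sex * sex01
    for site, beta in config.causal_beta:
        y = y + beta * calls[:, site]

    width = len(str(n))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    span, start = 528_000, 231_656_716  # locus-sized coordinate frame
    variants = [
        VariantRecord(
            chrom="chr1",
            pos=start + int(round(v * span / max(config.n_sites, 1))),
            ref="A",
            alt="G",
            site_quality=100.0,
        )
        for v in range(config.n_sites)
    ]
    matrix = GenotypeMatrix(sample_ids, variants, calls).recompute_maf()
    sheet = CohortSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": groups,
                "age": ages,
                "sex": np.where(sex01 == 1, "F", "M"),
                config.trait_name: y,
            }
        )
    )
    truth = SyntheticTruth(
        frequencies=frequencies,
        causal_or=list(config.causal_or),
        causal_beta=list(config.causal_beta),
        n_draws_used=drawn,
    )
    return matrix, sheet, truth


def simulate_capture(
    frequencies: np.ndarray,
    n_a: int,
    n_b: int,
    s_a: float,
    s_b: float,
    seed: int,
    maf_split: float = 0.01,
) -> tuple[list, CaptureTruth]:
    """Two-study variant-capture process for mark-recapture estimation.

    A site is detected by a study iff at least one minor allele appears
    among its Binomial(2n, f) sampled alleles AND an independent
    Bernoulli(sensitivity) call succeeds.  Counts (n1, n2, m) are
    tallied per MAF stratum, with stratum membership assigned from the
    *study-A sample* frequency (folded), the field-realistic choice
    since true frequencies are unobservable; this only matters for
    sites near the stratum boundary.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("study sizes must be >= 1")
    for s in (s_a, s_b):
        if not 0 < s <= 1:
            raise ValueError("sensitivities must be in (0, 1]")
    f = np.asarray(frequencies, dtype=float)
    rng = np.random.default_rng(seed)
    k_a = rng.binomial(2 * n_a, f)
    k_b = rng.binomial(2 * n_b, f)
    det_a = (k_a > 0) & (rng.random(f.size) < s_a)
    det_b = (k_b > 0) & (rng.random(f.size) < s_b)
    f_a = k_a / (2.0 * n_a)
    maf_a = np.minimum(f_a, 1.0 - f_a)
    common_label = f"maf>={maf_split:g}"
    rare_label = f"maf<{maf_split:g}"
    stratum = np.where(maf_a >= maf_split, common_label, rare_label)
    counts = []
    for label in (common_label, rare_label):
        sel = stratum == label
        counts.append(
            CaptureCount(
                stratum=label,
                n1=int((det_a & sel).sum()),
                n2=int((det_b & sel).sum()),
                m=int((det_a & det_b & sel).sum()),
            )
        )
    return counts, CaptureTruth(f, det_a, det_b, stratum)


def simulate_pedigree(
    founder_freq: float,
    penetrance,
    n_children: int,
    seed: int,
    affected_label: str = "affected",
    unaffected_label: str = "unaffected",
) -> Pedigree:
    """Nuclear family at a single biallelic site.

    Founder genotypes are Hardy-Weinberg Binomial(2, f); each child
    inherits one uniformly chosen allele per parent; affection is
    Bernoulli(penetrance[genotype]).  Carrier status is genotype >= 1,
    so the ground truth is fully known.
    """
    penetrance = np.asarray(penetrance, dtype=float)
    if penetrance.shape != (3,) or np.any((penetrance < 0) | (penetrance > 1)):
        raise ValueError("penetrance must be three probabilities (for 0/1/2 copies)")
    if not 0 <= founder_freq <= 1:
        raise ValueError("founder_freq must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g_father, g_mother = rng.binomial(2, founder_freq, size=2)

    def member(mid, father, mother, sex, g):
        affected = rng.random() < penetrance[g]
        return PedigreeMember(
            member_id=mid,
            father=father,
            mother=mother,
            sex=sex,
            diagnosis=affected_label if affected else unaffected_label,
            carrier="carrier" if g >= 1 else "non-carrier",
            genotype=int(g),
        )

    members = [
        member("father", None, None, "M", g_father),
        member("mother", None, None, "F", g_mother),
    ]
    for i in range(n_children):
        allele_f = int(rng.random() < g_father / 2.0)
        allele_m = int(rng.random() < g_mother / 2.0)
        g_child = allele_f + allele_m
        members.append(
            member(f"child{i + 1}", "father", "mother",
                   "M" if rng.random() < 0.5 else "F", g_child)
        )
    return Pedigree(members)
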
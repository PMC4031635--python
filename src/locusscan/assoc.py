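"""Single-variant association with region-wide permutation significance.

Case-control association uses the allelic 2x2 Fisher exact test (minor
vs major allele counts in cases vs controls), with Woolf confidence
intervals on the odds ratio.  Region-wide (locus-wide) significance is
obtained by max-T permutation: case/control labels are shuffled R times,
the minimum raw p across all variants recorded for each shuffle, and
each variant's region-wide p is the plus-one-corrected fraction of
shuffles whose minimum beats its raw p.  The empirical 5%/1% region-wide
thresholds are the corresponding quantiles of that min-p distribution.

Quantitative traits are tested by two-stage least squares: the trait is
residualised on age and sex once, then the residuals are regressed on
minor-allele dosage per variant; empirical p-values come from permuting
the residuals (the covariate design is fixed, so stage-2 exchangeability
holds).

Pedigree co-segregation of a candidate allele with diagnosis is a
simple count-based check (perfect segregation and a consistency
fraction), reflecting how single-family evidence is weighed in practice.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .core import CohortSheet, GenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "ContingencyTable",
    "AssocResult",
    "SegregationResult",
    "UndefinedLDError",
    "fisher_exact_2x2",
    "odds_ratio_ci",
    "single_variant_scan",
    "region_wide_permutation",
    "qt_scan",
    "QtResult",
    "ld_r2",
    "segregation_check",
]

Z95 = 1.959963984540054
# Relative slack when summing point probabilities <= the observed one,
# matching the common tool convention for the two-sided Fisher test.
_REL_EPS = 1.0 + 1e-7


class UndefinedLDError(ValueError):
    """LD r^2 is undefined when a dosage vector is constant."""


@dataclass
class ContingencyTable:
    """Allelic 2x2 table: minor/major allele counts in cases/controls."""

    a: int  # minor alleles in cases
    b: int  # major alleles in cases
    c: int  # minor alleles in controls
    d: int  # major alleles in controls

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_2x2(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p by the point-probability method.

    The p-value is the sum of hypergeometric point probabilities not
    exceeding that of the observed table.  A table with a zero margin is
    degenerate (no contrast): p = 1.0 with a warning.
    """
    t = table
    if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1.0", stacklevel=2)
        return 1.0
    p = stats.fisher_exact(t.to_array(), alternative="two-sided")[1]
    return float(min(p, 1.0))


@dataclass
class ORResult:
    or_hat: float
    ci_low: float
    ci_high: float
    haldane_corrected: bool


def odds_ratio_ci(table: ContingencyTable) -> ORResult:
    """Odds ratio with Woolf 95% CI, exp(ln OR +/- 1.96*SE),
    SE = sqrt(1/a + 1/b + 1/c + 1/d).  Any zero cell triggers the
    Haldane-Anscombe +0.5 continuity correction (flagged)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_hat = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_hat) - Z95 * se)
    hi = math.exp(math.log(or_hat) + Z95 * se)
    return ORResult(or_hat, lo, hi, corrected)


@lru_cache(maxsize=200_000)
def _twosided_table(M: int, K: int, A: int) -> tuple[int, tuple]:
    """Two-sided Fisher p for every possible count a, given fixed margins.

    Margins: M total alleles, K total minor alleles, A case alleles.
    Returns (k_min, p) with p[a - k_min] the two-sided p for observing
    ``a`` minor alleles in cases.
    """
    k_min = max(0, A + K - M)
    k_max = min(K, A)
    ks = np.arange(k_min, k_max + 1)
    pmf = stats.hypergeom.pmf(ks, M, K, A)
    # p[i] = sum of point probabilities <= pmf[i]*(1+eps), via sorted cumsum
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    cum = np.cumsum(sorted_pmf)
    idx = np.searchsorted(sorted_pmf, pmf * _REL_EPS, side="right")
    p = np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0.0)
    return k_min, tuple(np.minimum(p, 1.0))


def _p_from_table(a: int, M: int, K: int, A: int) -> float:
    if K == 0 or K == M or A == 0 or A == M:
        return 1.0  # zero margin: degenerate
    k_min, p = _twosided_table(M, K, A)
    return p[a - k_min]


def _aligned(matrix: GenotypeMatrix, sheet: CohortSheet) -> None:
    if matrix.samples != sheet.sample_ids:
        raise ValueError("matrix samples and sample sheet must match in order")


def _allele_counts(dosage_col: np.ndarray, case: np.ndarray) -> ContingencyTable:
    ok = ~np.isnan(dosage_col)
    minor_case = int(np.nansum(dosage_col[ok & case]))
    minor_ctrl = int(np.nansum(dosage_col[ok & ~case]))
    n_case = int((ok & case).sum())
    n_ctrl = int((ok & ~case).sum())
    return ContingencyTable(
        a=minor_case,
        b=2 * n_case - minor_case,
        c=minor_ctrl,
        d=2 * n_ctrl - minor_ctrl,
    )


@dataclass
class AssocResult:
    variant_id: str
    table: ContingencyTable
    or_hat: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_regionwide: float | None = None
    n_permutations: int | None = None
    monomorphic: bool = False
    haldane_corrected: bool = False


def _one_result(variant_id: str, table: ContingencyTable) -> AssocResult:
    mono = table.a + table.c == 0 or table.b + table.d == 0
    if mono:
        return AssocResult(
            variant_id, table, math.nan, math.nan, math.nan, 1.0, monomorphic=True
        )
    orres = odds_ratio_ci(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = fisher_exact_2x2(table)
    return AssocResult(
        variant_id,
        table,
        orres.or_hat,
        orres.ci_low,
        orres.ci_high,
        p,
        haldane_corrected=orres.haldane_corrected,
    )


def single_variant_scan(
    matrix: GenotypeMatrix, sheet: CohortSheet, case_group: str = "all_cases"
) -> list[AssocResult]:
    """Allelic Fisher-exact scan of every variant for one diagnosis
    (or all cases pooled) against controls.  Missing calls are excluded
    per variant; monomorphic variants get p = 1 and an undefined OR."""
    _aligned(matrix, sheet)
    amask = sheet.analysis_mask(case_group)
    if not sheet.case_mask(case_group).any():
        raise ValueError(f"no samples in case group {case_group!r}")
    case = sheet.case_mask(case_group)[amask]
    D = matrix.minor_dosages()[amask, :]
    return [
        _one_result(v.variant_id, _allele_counts(D[:, j], case))
        for j, v in enumerate(matrix.variants)
    ]


def region_wide_permutation(
    matrix: GenotypeMatrix,
    sheet: CohortSheet,
    case_group: str = "all_cases",
    R: int = 1000,
    seed: int = 0,
    alphas: tuple = (0.05, 0.01),
):
    """Max-T permutation scan: raw Fisher p per variant plus region-wide
    empirical p and empirical significance thresholds.

    For each of R case/control label permutations (group totals
    preserved) the minimum raw p over all variants is recorded;
    ``p_regionwide(v) = (1 + #{r: min_p_r <= p_raw(v)}) / (R + 1)``.
    The returned thresholds are the empirical ``alpha``-quantiles of the
    min-p distribution (raw p at or below the 5% threshold is
    region-wide significant at 5%).

    Returns ``(results, thresholds)`` where ``thresholds`` maps each
    alpha to its min-p quantile.
    """
    if R < 100:
        raise ValueError("R must be at least 100 for stable empirical p-values")
    _aligned(matrix, sheet)
    rng = np.random.default_rng(seed)
    amask = sheet.analysis_mask(case_group)
    case = sheet.case_mask(case_group)[amask]
    if not case.any() or case.all():
        raise ValueError("need both cases and controls")
    D = matrix.minor_dosages()[amask, :]
    n, V = D.shape
    n_case = int(case.sum())

    miss = np.isnan(D)
    Dz = np.where(miss, 0.0, D)
    t_v = Dz.sum(axis=0).astype(int)  # total minor alleles (nonmissing)
    M_v = 2 * (n - miss.sum(axis=0)).astype(int)  # total alleles

    y = case.astype(float)
    perms = np.empty((R, n))
    for r in range(R):
        perms[r] = rng.permutation(y)

    def p_of(yvec: np.ndarray) -> np.ndarray:
        a = np.rint(yvec @ Dz).astype(int)
        A = 2 * (n_case - np.rint(yvec @ miss).astype(int))
        return np.array(
            [_p_from_table(a[j], M_v[j], t_v[j], A[j]) for j in range(V)]
        )

    p_raw = p_of(y)
    if not miss.any():
        # fast path: all margins fixed, p depends only on a
        A = 2 * n_case
        pad = int(t_v.max(initial=0)) + 1
        tab = np.ones((V, pad))
        for j in range(V):
            if 0 < t_v[j] < M_v[j] and 0 < A < M_v[j]:
                k_min, p = _twosided_table(M_v[j], t_v[j], A)
                for k, pv in enumerate(p, start=k_min):
                    if k < pad:
                        tab[j, k] = pv
        a_perm = np.rint(perms @ Dz).astype(int)
        p_perm = tab[np.arange(V)[None, :], a_perm]
        min_p = p_perm.min(axis=1) if V else np.ones(R)
    else:
        min_p = np.array([p_of(perms[r]).min() if V else 1.0 for r in range(R)])

    results = single_variant_scan(matrix, sheet, case_group)
    for j, res in enumerate(results):
        res.p_raw = float(p_raw[j])  # identical machinery as permutations
        res.p_regionwide = float((1 + (min_p <= p_raw[j]).sum()) / (R + 1))
        res.n_permutations = R
    thresholds = {
        float(alpha): float(np.quantile(min_p, alpha, method="lower"))
        for alpha in alphas
    }
    return results, thresholds


@dataclass
class QtResult:
    variant_id: str
    slope: float
    t_stat: float
    p_empirical: float
    n: int
    note: str = ""


def _residualize(sheet: CohortSheet, trait: str) -> tuple[np.ndarray, np.ndarray]:
    """Residuals of trait ~ 1 + age + sex on trait-nonmissing samples."""
    y = sheet.trait(trait)
    ok = ~np.isnan(y)
    if ok.sum() < 10:
        raise ValueError(f"trait {trait!r} has fewer than 10 non-missing values")
    X = sm.add_constant(np.column_stack([sheet.age[ok], sheet.sex01[ok]]))
    resid = sm.OLS(y[ok], X).fit().resid
    return resid, ok


def qt_scan(
    matrix: GenotypeMatrix,
    sheet: CohortSheet,
    trait: str,
    R: int = 1000,
    seed: int = 0,
    tail: str = "two",
) -> list[QtResult]:
    """Quantitative-trait scan with permutation empirical p-values.

    Stage 1 residualises the trait on age + sex (with intercept); stage
    2 regresses the residuals on minor-allele dosage per variant.  The
    empirical p compares the observed dosage-residual correlation with
    R permutations of the residual vector: two-sided on |corr|,
    one-sided (``tail="upper"``/``"lower"``) on the signed value.
    """
    if tail not in ("two", "upper", "lower"):
        raise ValueError("tail must be 'two', 'upper' or 'lower'")
    _aligned(matrix, sheet)
    rng = np.random.default_rng(seed)
    resid, ok = _residualize(sheet, trait)
    D = matrix.minor_dosages()[ok, :]
    n = resid.size
    perms = np.empty((R, n))
    for r in range(R):
        perms[r] = rng.permutation(resid)

    def corr_stats(rp: np.ndarray, g: np.ndarray) -> np.ndarray:
        """Pearson correlation of each row of rp with g (g already centred)."""
        num = rp @ g
        sr = rp.sum(axis=-1)
        srr = (rp**2).sum(axis=-1)
        ss_r = srr - sr**2 / g.size
        return num / np.sqrt(ss_r * (g @ g))

    results = []
    for j, v in enumerate(matrix.variants):
        col = D[:, j]
        mask = ~np.isnan(col)
        g = col[mask]
        nv = g.size
        if nv < 3 or np.ptp(g) == 0:
            results.append(
                QtResult(v.variant_id, math.nan, math.nan, math.nan, nv,
                         note="monomorphic or insufficient calls")
            )
            continue
        gc = g - g.mean()
        rv = resid[mask]
        c_obs = float(corr_stats(rv[None, :], gc)[0])
        c_perm = corr_stats(perms[:, mask], gc)
        if tail == "two":
            count = int((np.abs(c_perm) >= abs(c_obs) - 1e-12).sum())
        elif tail == "upper":
            count = int((c_perm >= c_obs - 1e-12).sum())
        else:
            count = int((c_perm <= c_obs + 1e-12).sum())
        p_emp = (1 + count) / (R + 1)
        slope = c_obs * rv.std(ddof=1) / g.std(ddof=1)
        r2 = min(c_obs**2, 1.0)
        t_stat = (
            math.copysign(math.inf, c_obs)
            if r2 >= 1.0
            else c_obs * math.sqrt((nv - 2) / (1 - r2))
        )
        results.append(QtResult(v.variant_id, slope, t_stat, p_emp, nv))
    return results


def ld_r2(dosages_1, dosages_2) -> float:
    """Squared Pearson correlation of two dosage vectors on the jointly
    non-missing samples (missing: nan or negative)."""
    g1 = np.asarray(dosages_1, dtype=float)
    g2 = np.asarray(dosages_2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = ~(np.isnan(g1) | (g1 < 0) | np.isnan(g2) | (g2 < 0))
    g1, g2 = g1[ok], g2[ok]
    if g1.size < 2:
        raise ValueError("need at least 2 jointly non-missing samples")
    if np.ptp(g1) == 0 or np.ptp(g2) == 0:
        raise UndefinedLDError("LD undefined: a dosage vector is constant")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


@dataclass
class SegregationResult:
    affected_carriers: int
    affected_noncarriers: int
    unaffected_carriers: int
    unaffected_noncarriers: int
    perfect: bool
    consistency: float

    @property
    def counted(self) -> int:
        return (
            self.affected_carriers
            + self.affected_noncarriers
            + self.unaffected_carriers
            + self.unaffected_noncarriers
        )


def segregation_check(pedigree: Pedigree, affected_labels: set) -> SegregationResult:
    """Co-segregation of carrier status with diagnosis in one family.

    Members with unknown carrier status or missing diagnosis are
    excluded.  ``perfect`` means every affected member is a carrier and
    every unaffected member is a non-carrier (with at least one affected
    carrier); ``consistency`` is the fraction of counted members on the
    diagonal (affected carriers + unaffected non-carriers)."""
    ac = an = uc = un = 0
    for m in pedigree:
        if m.carrier == "unknown" or m.diagnosis is None:
            continue
        affected = m.diagnosis in affected_labels
        carrier = m.carrier == "carrier"
        if affected and carrier:
            ac += 1
        elif affected:
            an += 1
        elif carrier:
            uc += 1
        else:
            un += 1
    counted = ac + an + uc + un
    if counted == 0:
        raise ValueError("no members with both carrier status and diagnosis")
    perfect = an == 0 and uc == 0 and ac >= 1
    return SegregationResult(ac, an, uc, un, perfect, (ac + un) / counted)
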
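"""Mark-recapture estimation of the total variant pool.

Two resequencing studies of the same locus each "capture" a subset of
the variants segregating in the source population.  Treating discovery
as capture, the Lincoln-Petersen estimator N = n1*n2/m and Chapman's
small-sample modification N = (n1+1)(n2+1)/(m+1) - 1 estimate the total
pool size from the per-study discovery counts (n1, n2) and their overlap
m.  Estimates are computed per MAF stratum (default: >= 1% and < 1%),
since capture probability differs sharply between common and rare
variants, and summed for a total with stratum variances added under an
independence assumption.

Chapman's variance
    var = (n1+1)(n2+1)(n1-m)(n2-m) / ((m+1)^2 (m+2))
yields the default normal-approximation 95% CI (N_hat +/- 1.96 SE); a
log-scale CI is available for small overlaps where the normal CI can dip
below the number of variants already known.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "ZeroOverlapError",
    "CaptureCount",
    "PoolEstimate",
    "StratifiedPool",
    "lincoln_petersen",
    "chapman",
    "stratified_pool",
    "undiscovered_fraction",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class ZeroOverlapError(ValueError):
    """Lincoln-Petersen is undefined when the studies share no variant."""


@dataclass
class CaptureCount:
    """Per-stratum capture counts: study-1 total, study-2 total, overlap."""

    stratum: str
    n1: int
    n2: int
    m: int

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.m) < 0:
            raise ValueError("capture counts must be non-negative")
        if self.m > min(self.n1, self.n2):
            raise ValueError(
                f"{self.stratum}: overlap m={self.m} exceeds min(n1, n2)"
            )

    @property
    def known_union(self) -> int:
        return self.n1 + self.n2 - self.m


@dataclass
class PoolEstimate:
    stratum: str
    estimator: str  # "lincoln_petersen" | "chapman"
    n_hat: float
    variance: float
    ci_low: float
    ci_high: float
    known_union: int
    undiscovered_fraction: float
    error: str | None = None  # set when the estimator failed for this stratum


def lincoln_petersen(n1: int, n2: int, m: int) -> float:
    """Classic two-occasion abundance estimate n1*n2/m (requires m >= 1)."""
    if m < 1:
        raise ZeroOverlapError("Lincoln-Petersen undefined with zero overlap (m = 0)")
    if m > min(n1, n2):
        raise ValueError("overlap m exceeds a study total")
    return n1 * n2 / m


def _lp_variance(n1: int, n2: int, m: int) -> float:
    # Seber's variance for the Lincoln-Petersen estimator.
    return n1 * n2 * (n1 - m) * (n2 - m) / m**3 if m >= 1 else math.nan


def chapman(
    n1: int, n2: int, m: int, stratum: str = "all", ci_method: str = "normal"
) -> PoolEstimate:
    """Chapman's bias-reduced pool estimate with 95% CI.

    Defined at m = 0.  ``ci_method="log"`` builds the interval on the
    log of the undetected count (useful when m is small and the normal
    CI would fall below the observed union); the interval is always
    truncated below at the known union.
    """
    count = CaptureCount(stratum, n1, n2, m)
    n_hat = (n1 + 1) * (n2 + 1) / (m + 1) - 1
    variance = (n1 + 1) * (n2 + 1) * (n1 - m) * (n2 - m) / ((m + 1) ** 2 * (m + 2))
    se = math.sqrt(variance)
    if ci_method == "normal":
        lo, hi = n_hat - Z95 * se, n_hat + Z95 * se
    elif ci_method == "log":
        # CI on the undetected count U = N - known, log-normal approx.
        u = max(n_hat - count.known_union, 1e-12)
        c = math.exp(Z95 * math.sqrt(math.log1p(variance / u**2)))
        lo, hi = count.known_union + u / c, count.known_union + u * c
    else:
        raise ValueError("ci_method must be 'normal' or 'log'")
    lo = max(lo, float(count.known_union))
    return PoolEstimate(
        stratum=stratum,
        estimator="chapman",
        n_hat=n_hat,
        variance=variance,
        ci_low=lo,
        ci_high=hi,
        known_union=count.known_union,
        undiscovered_fraction=undiscovered_fraction(count.known_union, n_hat)
        if n_hat > 0
        else 0.0,
    )


@dataclass
class StratifiedPool:
    strata: list  # of PoolEstimate
    total: PoolEstimate | None  # None if no stratum succeeded


def stratified_pool(counts, estimator: str = "chapman") -> StratifiedPool:
    """Per-stratum pool estimates plus a summed total.

    The total sums point estimates and variances across strata
    (independence assumption).  A stratum where the estimator is
    undefined (m = 0 for Lincoln-Petersen) is reported with its error
    message and excluded from the total instead of aborting the rest.
    """
    if not counts:
        raise ValueError("need at least one capture-count stratum")
    if estimator not in ("chapman", "lincoln_petersen"):
        raise ValueError("estimator must be 'chapman' or 'lincoln_petersen'")
    estimates: list[PoolEstimate] = []
    for c in counts:
        try:
            if estimator == "chapman":
                estimates.append(chapman(c.n1, c.n2, c.m, stratum=c.stratum))
            else:
                n_hat = lincoln_petersen(c.n1, c.n2, c.m)
                var = _lp_variance(c.n1, c.n2, c.m)
                se = math.sqrt(var)
                estimates.append(
                    PoolEstimate(
                        stratum=c.stratum,
                        estimator=estimator,
                        n_hat=n_hat,
                        variance=var,
                        ci_low=max(n_hat - Z95 * se, float(c.known_union)),
                        ci_high=n_hat + Z95 * se,
                        known_union=c.known_union,
                        undiscovered_fraction=undiscovered_fraction(c.known_union, n_hat),
                    )
                )
        except ZeroOverlapError as exc:
            estimates.append(
                PoolEstimate(
                    stratum=c.stratum,
                    estimator=estimator,
                    n_hat=math.nan,
                    variance=math.nan,
                    ci_low=math.nan,
                    ci_high=math.nan,
                    known_union=c.known_union,
                    undiscovered_fraction=math.nan,
                    error=str(exc),
                )
            )
    valid = [e for e in estimates if e.error is None]
    total: PoolEstimate | None = None
    if valid:
        n_hat = sum(e.n_hat for e in valid)
        var = sum(e.variance for e in valid)
        known = sum(e.known_union for e in valid)
        se = math.sqrt(var)
        total = PoolEstimate(
            stratum="total" if len(valid) == len(estimates) else "total(partial)",
            estimator=estimator,
            n_hat=n_hat,
            variance=var,
            ci_low=max(n_hat - Z95 * se, float(known)),
            ci_high=n_hat + Z95 * se,
            known_union=known,
            undiscovered_fraction=undiscovered_fraction(known, n_hat),
        )
    return StratifiedPool(strata=estimates, total=total)


def undiscovered_fraction(known: int, n_hat: float) -> float:
    """Fraction of the estimated pool not yet observed, clamped to >= 0."""
    if n_hat <= 0:
        raise ValueError("n_hat must be positive")
    if known < 0:
        raise ValueError("known count must be non-negative")
    if known > n_hat:
        warnings.warn(
            f"known count {known} exceeds pool estimate {n_hat:.1f} "
            "(estimator undershoot); reporting 0",
            stacklevel=2,
        )
        return 0.0
    return 1.0 - known / n_hat
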
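"""Two-group statistics and proteolysis/microbiology transforms.

The study design is two groups of three replicate cheeses (non-defective
NDC vs defective DC), every variable reported as mean ± SD.  Group
comparison follows a variance-gated scheme: an F-test for homogeneity of
variances decides between the pooled-variance Student's t-test
(homogeneous) and the Welch–Satterthwaite t-test (heterogeneous), both
two-sided at α = 0.05.  Because only summary statistics are published, the
whole scheme works from (n, mean, sd) triples as well as from raw samples.

Also here: corrected electrophoretic peak areas (area / migration time),
the four casein-fragment ratios used to track primary proteolysis, and the
log₁₀ CFU transform for plate counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "PeakRecord",
    "RatioTable",
    "f_homogeneity_test",
    "compare_groups",
    "corrected_area",
    "casein_ratios",
    "log_cfu",
    "holm_adjust",
]

DEFAULT_ALPHA = 0.05

#: ratio names as used for primary proteolysis tracking
RATIO_NAMES = ("as1I_over_as1", "as_f1_23_over_as1plus0", "as1PL_over_as1", "gamma_over_beta")


@dataclass
class GroupSummary:
    """n / mean / SD of one variable in one group."""

    label: str
    n: int
    mean: float
    sd: float
    variable: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("standard deviation must be >= 0")

    @classmethod
    def from_samples(cls, label: str, samples: Sequence[float], variable: str = "") -> "GroupSummary":
        x = np.asarray(samples, dtype=float)
        if x.size < 2:
            raise ValueError("need >= 2 samples")
        return cls(label=label, n=int(x.size), mean=float(x.mean()), sd=float(x.std(ddof=1)), variable=variable)


@dataclass
class ComparisonResult:
    test_used: str        # "student" | "welch"
    f_ratio: float
    f_p: float
    t_stat: float
    df: float
    p_value: float
    significant: bool
    alpha: float


@dataclass
class PeakRecord:
    """One electrophoretic peak; corrected area = raw area / migration time."""

    peak_id: str
    raw_area: float
    migration_time: float

    def __post_init__(self) -> None:
        if self.migration_time <= 0:
            raise ValueError("migration time must be positive")
        if self.raw_area < 0:
            raise ValueError("peak area must be >= 0")

    @property
    def corrected_area(self) -> float:
        return corrected_area(self.raw_area, self.migration_time)


@dataclass
class RatioTable:
    as1I_over_as1: float
    as_f1_23_over_as1plus0: float
    as1PL_over_as1: float
    gamma_over_beta: float

    def __post_init__(self) -> None:
        for name in RATIO_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RATIO_NAMES}


def _as_summary(g, variable: str = "") -> GroupSummary:
    if isinstance(g, GroupSummary):
        return g
    return GroupSummary.from_samples("group", g, variable=variable)


def f_homogeneity_test(
    a: GroupSummary | Sequence[float],
    b: GroupSummary | Sequence[float],
    alpha_homogeneity: float = DEFAULT_ALPHA,
) -> tuple[float, float, bool]:
    """Two-sided F-test of equal variances from group summaries.

    The statistic is the larger sample variance over the smaller, referred
    to the F distribution with (n−1, n−1) degrees of freedom; the two-sided
    p doubles the upper tail.  Returns (f_ratio, p, homogeneous).
    """
    a, b = _as_summary(a), _as_summary(b)
    va, vb = a.sd**2, b.sd**2
    if va == 0.0 and vb == 0.0:
        return 1.0, 1.0, True
    if va >= vb:
        f, dfn, dfd = (va / vb if vb > 0 else np.inf), a.n - 1, b.n - 1
    else:
        f, dfn, dfd = (vb / va if va > 0 else np.inf), b.n - 1, a.n - 1
    if np.isinf(f):
        return float("inf"), 0.0, False
    p = min(1.0, 2.0 * float(sps.f.sf(f, dfn, dfd)))
    return float(f), p, p >= alpha_homogeneity


def compare_groups(
    a: GroupSummary | Sequence[float],
    b: GroupSummary | Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    alpha_homogeneity: float = DEFAULT_ALPHA,
) -> ComparisonResult:
    """Variance-gated two-sample comparison.

    Student's pooled-variance t-test when the F-test accepts homogeneity,
    Welch–Satterthwaite otherwise; two-sided p; significant ⇔ p < α.
    Accepts summaries or raw samples interchangeably — summaries are
    sufficient statistics for both tests.
    """
    a, b = _as_summary(a), _as_summary(b)
    f_ratio, f_p, homogeneous = f_homogeneity_test(a, b, alpha_homogeneity)
    va, vb = a.sd**2, b.sd**2
    diff = a.mean - b.mean
    if homogeneous:
        test = "student"
        df = float(a.n + b.n - 2)
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    else:
        test = "welch"
        se = np.sqrt(va / a.n + vb / b.n)
        num = (va / a.n + vb / b.n) ** 2
        den = (va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1)
        df = float(num / den) if den > 0 else float(a.n + b.n - 2)
    if se == 0.0:
        t_stat = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0.0 else 0.0
    else:
        t_stat = float(diff / se)
        p = 2.0 * float(sps.t.sf(abs(t_stat), df))
    return ComparisonResult(
        test_used=test,
        f_ratio=f_ratio,
        f_p=f_p,
        t_stat=t_stat,
        df=df,
        p_value=min(p, 1.0),
        significant=p < alpha,
        alpha=alpha,
    )


def corrected_area(raw_area: float, migration_time: float) -> float:
    """Electrophoretic peak area divided by its migration time."""
    if migration_time <= 0:
        raise ValueError("migration time must be positive")
    return raw_area / migration_time


def casein_ratios(peaks: Sequence[PeakRecord]) -> RatioTable:
    """Casein-fragment ratios from a corrected-area peak table.

    Expected peak_ids: as1, as0, as1-I, as1-f1-23, as1-PL, beta, gamma.
    The αs(f1–23) denominator is the summed corrected area of αs₁ and αs₀.
    """
    areas: dict[str, float] = {}
    for p in peaks:
        areas[p.peak_id] = areas.get(p.peak_id, 0.0) + p.corrected_area

    def need(name: str) -> float:
        if name not in areas:
            raise KeyError(f"required peak '{name}' missing from the peak table")
        return areas[name]

    as1 = need("as1")
    as0 = need("as0")
    if as1 <= 0:
        raise ValueError("zero denominator: as1 corrected area")
    as1plus0 = as1 + as0
    if as1plus0 <= 0:
        raise ValueError("zero denominator: as1 + as0 corrected area")
    beta = need("beta")
    if beta <= 0:
        raise ValueError("zero denominator: beta corrected area")
    return RatioTable(
        as1I_over_as1=need("as1-I") / as1,
        as_f1_23_over_as1plus0=need("as1-f1-23") / as1plus0,
        as1PL_over_as1=need("as1-PL") / as1,
        gamma_over_beta=need("gamma") / beta,
    )


def log_cfu(
    count: float,
    dilution_factor: float,
    plated_volume_mL: float = 1.0,
    sample_mass_g: float | None = None,
) -> float | None:
    """log₁₀ CFU per mL of homogenate (or per g with ``sample_mass_g``).

    Returns None for zero colonies (below detection) rather than −∞.
    """
    if count < 0 or dilution_factor <= 0 or plated_volume_mL <= 0:
        raise ValueError("count must be >= 0; dilution and volume positive")
    if count == 0:
        return None
    cfu = count * dilution_factor / plated_volume_mL
    if sample_mass_g is not None:
        if sample_mass_g <= 0:
            raise ValueError("sample mass must be positive")
        cfu /= sample_mass_g
    return float(np.log10(cfu))


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default in the pipeline)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
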
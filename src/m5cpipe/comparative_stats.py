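"""Cross-site and cross-organism statistics.

Two questions recur when comparing methylated-site sets: are sites shifted
toward one end of their genes (relative position in [0, 1], 0 = 5' end), and
do two site sets differ in methylation level?  The first is answered with a
Welch two-sample t-test computed from first principles (means, variances,
Welch-Satterthwaite degrees of freedom); the second with a Mann-Whitney
rank-sum test, exact by enumeration when both samples are small (n <= 8) and
via the tie-corrected normal approximation with continuity correction
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .reference_prep import GeneFeature

EXACT_MAX_N = 8


@dataclass(frozen=True)
class RelativePosition:
    """Position of a site along its gene, 0 = 5' end, 1 = 3' end."""

    site_id: str
    gene_id: str
    value: float

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"relative position {self.value} outside [0, 1]")


def relative_position(site_pos: int, gene: GeneFeature, site_id: str = "") -> RelativePosition:
    """Strand-aware relative position of a site within a gene.

    Uses a (length - 1) denominator so both the first and the last base of
    the gene are attainable (0.0 and 1.0 exactly).
    """
    if not gene.start <= site_pos < gene.end:
        raise ValueError(
            f"site {site_pos} outside gene {gene.feature_id} [{gene.start}, {gene.end})"
        )
    if gene.length == 1:
        value = 0.0
    elif gene.strand == "+":
        value = (site_pos - gene.start) / (gene.length - 1)
    else:
        value = (gene.end - 1 - site_pos) / (gene.length - 1)
    return RelativePosition(site_id or str(site_pos), gene.feature_id, value)


class TestResult(NamedTuple):
    statistic: float
    p: float
    method: str


def position_shift_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch two-sample t-test for a location shift between two position sets.

    t = (mean_a - mean_b) / sqrt(va/na + vb/nb), with Welch-Satterthwaite
    degrees of freedom; the two-sided p comes from the t distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both sets need at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("degenerate: both sets have zero variance")
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(float(t), min(p, 1.0), "welch-t")


def _u_statistic(ranks: np.ndarray, idx_a, na: int) -> float:
    return float(ranks[list(idx_a)].sum() - na * (na + 1) / 2.0)


def level_shift_test(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
    exact: bool | None = None,
) -> TestResult:
    """Mann-Whitney U test for a shift in methylation levels.

    U counts, over all cross pairs, how often an observation from ``a``
    exceeds one from ``b`` (ties count one half).  With both n <= 8 (or
    ``exact=True``) the null distribution is enumerated over all
    C(na+nb, na) assignments of the pooled observations; otherwise the
    tie-corrected normal approximation with a 0.5 continuity correction is
    used.  Two-sided p is the probability of a U at least as far from the
    null mean as observed.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both sets need at least 1 observation")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    u = _u_statistic(ranks, range(na), na)
    mean = na * nb / 2.0
    if exact is None:
        exact = na <= EXACT_MAX_N and nb <= EXACT_MAX_N

    if exact:
        total = 0
        hits = 0
        eps = 1e-9
        for idx in combinations(range(na + nb), na):
            u_perm = _u_statistic(ranks, idx, na)
            total += 1
            if alternative == "two-sided":
                hits += abs(u_perm - mean) >= abs(u - mean) - eps
            elif alternative == "less":
                hits += u_perm <= u + eps
            else:
                hits += u_perm >= u - eps
        return TestResult(u, hits / total, "mann-whitney-exact")

    # tie-corrected normal approximation
    n = na + nb
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return TestResult(u, 1.0, "mann-whitney-normal")
    sigma = math.sqrt(sigma2)
    if alternative == "two-sided":
        z = max(0.0, abs(u - mean) - 0.5) / sigma
        p = 2.0 * float(stats.norm.sf(z))
    elif alternative == "less":
        z = (u - mean + 0.5) / sigma
        p = float(stats.norm.cdf(z))
    else:
        z = (u - mean - 0.5) / sigma
        p = float(stats.norm.sf(z))
    return TestResult(u, min(p, 1.0), "mann-whitney-normal")
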
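"""Cross-map statistics: shared intervals, heterochiasmy and synteny.

Two linkage maps for the same marker panel (two populations, or a study map
against a reference species map) are compared on the intervals they share:
marker pairs adjacent in both.  On those paired interval lengths the module
offers exact two-tailed sign tests (genome-wide directional bias), the
sexual dimorphism index SDI = (larger sex / smaller sex) - 1 signed
positive when the female map is longer, reduced major axis regression with
case-resampling bootstrap confidence intervals, a quadratic model of SDI
against relative centromere->telomere position, genome-coverage estimation
against a reference map, and order/synteny discrepancy reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .mapping import LinkageMap, MeiosisPanel, MultipointEvaluator


# ---------------------------------------------------------------------------
# shared intervals & SDI


@dataclass
class IntervalComparison:
    """One marker pair adjacent in both maps under comparison."""

    left: str
    right: str
    cm_a: float | None
    cm_b: float | None
    cm_a_f: float | None = None
    cm_a_m: float | None = None
    cm_b_f: float | None = None
    cm_b_m: float | None = None
    sdi_a: float | None = None
    sdi_b: float | None = None
    rel_position: float | None = None  # centromere 0 -> telomere 1

    @property
    def pair(self) -> frozenset:
        return frozenset((self.left, self.right))


def sdi(female_len: float, male_len: float) -> float:
    """Sexual dimorphism index: (max/min) - 1, positive when the female
    value is the larger.  Both lengths must be positive."""
    if female_len <= 0 or male_len <= 0:
        raise ValueError("SDI requires positive sex-specific lengths")
    if female_len == male_len:
        return 0.0
    if female_len > male_len:
        return female_len / male_len - 1.0
    return -(male_len / female_len - 1.0)


def _safe_sdi(f: float | None, m: float | None) -> float | None:
    if f is None or m is None or f <= 0 or m <= 0:
        return None
    return sdi(f, m)


def shared_intervals(map_a: LinkageMap, map_b: LinkageMap
                     ) -> list[IntervalComparison]:
    """Every marker pair adjacent in both maps, orientation-insensitive."""
    def index(lmap: LinkageMap) -> dict[frozenset, object]:
        out = {}
        for g in lmap.groups:
            for iv in g.intervals:
                out[frozenset((iv.left, iv.right))] = iv
        return out

    ib = index(map_b)
    out: list[IntervalComparison] = []
    for g in map_a.groups:
        for iv in g.intervals:
            other = ib.get(frozenset((iv.left, iv.right)))
            if other is None:
                continue
            out.append(IntervalComparison(
                left=iv.left, right=iv.right,
                cm_a=iv.cm_avg, cm_b=other.cm_avg,
                cm_a_f=iv.cm_f, cm_a_m=iv.cm_m,
                cm_b_f=other.cm_f, cm_b_m=other.cm_m,
                sdi_a=_safe_sdi(iv.cm_f, iv.cm_m),
                sdi_b=_safe_sdi(other.cm_f, other.cm_m)))
    return out


def annotate_positions(comparisons: Iterable[IntervalComparison],
                       reference_map: dict,
                       chrom_lengths: dict[str, float] | None = None
                       ) -> list[IntervalComparison]:
    """Attach each interval's relative centromere->telomere position: the
    midpoint of its span in the reference map divided by the reference
    chromosome length (chromosome start = centromere = 0)."""
    if chrom_lengths is None:
        chrom_lengths = {}
        for _m, (chrom, pos) in reference_map.items():
            chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0.0), pos)
    out = []
    for c in comparisons:
        if c.left in reference_map and c.right in reference_map:
            ch1, p1 = reference_map[c.left]
            ch2, p2 = reference_map[c.right]
            if ch1 == ch2 and chrom_lengths.get(ch1, 0.0) > 0:
                c.rel_position = (p1 + p2) / 2.0 / chrom_lengths[ch1]
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# sign test


def sign_test(k_greater_in_a: int, k_greater_in_b: int) -> float:
    """Exact two-tailed binomial sign test at p0 = 0.5.

    Doubled smaller tail capped at 1 (equal to the symmetric-sum definition
    at p0 = 0.5).  Ties must be excluded before the call.
    """
    n = k_greater_in_a + k_greater_in_b
    if n < 1:
        raise ValueError("sign test needs at least one untied pair")
    k = min(k_greater_in_a, k_greater_in_b)
    return min(1.0, 2.0 * float(sps.binom.cdf(k, n, 0.5)))


def directional_counts(values_a: Sequence[float | None],
                       values_b: Sequence[float | None]
                       ) -> tuple[int, int, int]:
    """(greater in a, greater in b, ties) over pairs with both defined;
    ties are reported so the caller can log their exclusion."""
    ka = kb = ties = 0
    for a, b in zip(values_a, values_b):
        if a is None or b is None:
            continue
        if a > b:
            ka += 1
        elif b > a:
            kb += 1
        else:
            ties += 1
    return ka, kb, ties


# ---------------------------------------------------------------------------
# reduced major axis regression


@dataclass
class RMAResult:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r2: float
    n: int
    ci_slope: tuple[float, float] | None = None
    ci_intercept: tuple[float, float] | None = None
    ci_r2: tuple[float, float] | None = None


def rma_regression(x: Sequence[float], y: Sequence[float],
                   n_boot: int = 10000,
                   seed: int | None = None) -> RMAResult:
    """Reduced major axis (standard major axis) regression.

    slope = sign(r) * s_y / s_x, intercept = ybar - slope * xbar,
    SE(slope) = |slope| * sqrt((1 - r^2) / (n - 2)).  Confidence intervals
    (95%, percentile) by case-resampling bootstrap, seeded; pass
    ``n_boot=0`` to skip the bootstrap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("RMA regression needs n >= 3 paired observations")

    def fit(xv: np.ndarray, yv: np.ndarray) -> tuple[float, float, float]:
        sx = xv.std(ddof=1)
        sy = yv.std(ddof=1)
        if sx == 0 or sy == 0:
            raise ValueError("RMA regression requires variance in x and y")
        r = float(np.corrcoef(xv, yv)[0, 1])
        slope = math.copysign(sy / sx, r if r != 0 else 1.0)
        intercept = float(yv.mean() - slope * xv.mean())
        return slope, intercept, r

    slope, intercept, r = fit(x, y)
    r2 = r * r
    se_slope = abs(slope) * math.sqrt((1.0 - r2) / (n - 2))
    sx = x.std(ddof=1)
    se_intercept = math.sqrt(
        (1.0 - r2) * y.var(ddof=1) * (n - 1) / (n - 2)
        * (1.0 / n + x.mean() ** 2 / ((n - 1) * sx * sx)))
    res = RMAResult(slope=slope, intercept=intercept, se_slope=se_slope,
                    se_intercept=se_intercept, r2=r2, n=n)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        bs, bi, br2 = [], [], []
        for _ in range(n_boot):
            idx = rng.integers(n, size=n)
            try:
                s, i0, rr = fit(x[idx], y[idx])
            except ValueError:
                continue
            bs.append(s)
            bi.append(i0)
            br2.append(rr * rr)
        if bs:
            res.ci_slope = tuple(np.percentile(bs, [2.5, 97.5]))
            res.ci_intercept = tuple(np.percentile(bi, [2.5, 97.5]))
            res.ci_r2 = tuple(np.percentile(br2, [2.5, 97.5]))
    return res


# ---------------------------------------------------------------------------
# SDI vs relative position


@dataclass
class SDIPositionModel:
    coefficients: tuple[float, float, float]  # intercept, linear, quadratic
    r2: float
    p_quadratic: float
    n: int


def sdi_position_model(comparisons: Iterable[IntervalComparison],
                       use: str = "a") -> SDIPositionModel:
    """OLS of interval SDI on (position, position^2), position being the
    interval's relative centromere->telomere location.  Reports r^2 and the
    quadratic coefficient's t-test p-value."""
    xs, ys = [], []
    for c in comparisons:
        s = c.sdi_a if use == "a" else c.sdi_b
        if s is None or c.rel_position is None:
            continue
        xs.append(c.rel_position)
        ys.append(s)
    if len(xs) < 4:
        raise ValueError("quadratic SDI model needs at least 4 intervals")
    x = np.asarray(xs)
    design = sm.add_constant(np.column_stack([x, x ** 2]))
    fit = sm.OLS(np.asarray(ys), design).fit()
    return SDIPositionModel(
        coefficients=tuple(fit.params),
        r2=float(fit.rsquared),
        p_quadratic=float(fit.pvalues[2]),
        n=len(xs))


# ---------------------------------------------------------------------------
# coverage, order and synteny


def coverage_estimate(shared: Iterable[IntervalComparison],
                      reference_map: dict,
                      reference_total_cm: float) -> float:
    """Fraction of the reference map spanned by the shared intervals: sum of
    the reference-map lengths of shared intervals / reference total."""
    if reference_total_cm <= 0:
        raise ValueError("reference total length must be positive")
    covered = 0.0
    for c in shared:
        if c.left in reference_map and c.right in reference_map:
            ch1, p1 = reference_map[c.left]
            ch2, p2 = reference_map[c.right]
            if ch1 == ch2:
                covered += abs(p2 - p1)
    return covered / reference_total_cm


def compare_orders(panel: MeiosisPanel, order_a: Sequence[str],
                   order_b: Sequence[str]) -> float:
    """Support for order A over order B as the difference of multipoint
    log10-likelihoods (A - B); both orders must cover the same markers."""
    if set(order_a) != set(order_b):
        raise ValueError("orders must cover the same marker set")
    ev = MultipointEvaluator(panel, sorted(order_a))
    return ev.loglik(list(order_a)) - ev.loglik(list(order_b))


@dataclass
class SyntenyReport:
    moved_markers: list[tuple[str, str, str]]      # marker, chrom A, chrom B
    order_discrepancies: list[tuple[str, list[str]]]  # chrom, residue markers


def _lcs(a: Sequence[str], b: Sequence[str]) -> set[str]:
    """Longest common subsequence membership (classic DP)."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if a[i] == b[j]:
                dp[i, j] = dp[i + 1, j + 1] + 1
            else:
                dp[i, j] = max(dp[i + 1, j], dp[i, j + 1])
    keep: set[str] = set()
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j]:
            keep.add(a[i])
            i += 1
            j += 1
        elif dp[i + 1, j] >= dp[i, j + 1]:
            i += 1
        else:
            j += 1
    return keep


def compare_synteny(map_a: LinkageMap, map_b: LinkageMap,
                    chrom_labels_a: dict[str, str],
                    chrom_labels_b: dict[str, str]) -> SyntenyReport:
    """Automated synteny/order comparison against a common chromosome
    nomenclature (``chrom_labels_*`` map group names to chromosome labels).

    Reports markers assigned to different chromosomes, and — per shared
    chromosome — the markers that fall outside the longest common
    subsequence of the two marker orders (order is compared up to whole
    sequence reversal).
    """
    def marker_chrom(lmap: LinkageMap, labels: dict[str, str]) -> dict[str, str]:
        return {m: labels.get(g.name, g.name)
                for g in lmap.groups for m in g.markers}

    def marker_order(lmap: LinkageMap, labels: dict[str, str]) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g in lmap.groups:
            out.setdefault(labels.get(g.name, g.name), []).extend(g.markers)
        return out

    ca = marker_chrom(map_a, chrom_labels_a)
    cb = marker_chrom(map_b, chrom_labels_b)
    moved = [(m, ca[m], cb[m]) for m in sorted(set(ca) & set(cb))
             if ca[m] != cb[m]]
    oa = marker_order(map_a, chrom_labels_a)
    ob = marker_order(map_b, chrom_labels_b)
    discrepancies: list[tuple[str, list[str]]] = []
    for chrom in sorted(set(oa) & set(ob)):
        shared = set(oa[chrom]) & set(ob[chrom])
        shared -= {m for m, _, _ in moved}
        sa = [m for m in oa[chrom] if m in shared]
        sb = [m for m in ob[chrom] if m in shared]
        if len(sa) < 2:
            continue
        keep = max(_lcs(sa, sb), _lcs(sa, sb[::-1]), key=len)
        residue = sorted(set(sa) - keep)
        if residue:
            discrepancies.append((chrom, residue))
    return SyntenyReport(moved_markers=moved,
                        order_discrepancies=discrepancies)
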
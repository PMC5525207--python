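"""Skew statistics for inside/outside residue counts and position
distributions, plus the Bahadur slope.

Conventions
-----------
* The Kruskal-Wallis H statistic is non-negative by construction; for
  inside-vs-outside comparisons this module attaches a **sign** from the
  direction of the group means (positive when the outside mean exceeds the
  inside mean), which is how skew tables are conventionally read.
* P values depend strongly on the sample size N; the **Bahadur slope**
  ``B = |ln p| / N`` is reported alongside every test as a sample-size-
  independent distance between the compared distributions.
* Two-group Kruskal-Wallis tests use the standard tie correction; below 9
  observations per group the p value is computed by exhaustive permutation
  instead of the chi-square approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

EXACT_KW_LIMIT = 9  # exact permutation p below this many observations per group


class DegenerateTestError(ValueError):
    """A test cannot be run on the given data (e.g. an empty group)."""


@dataclass
class StatTestResult:
    """Outcome of one statistical test.

    ``statistic`` carries the sign convention for skew direction where one
    applies (see module docstring); ``bahadur_slope`` is ``|ln p| / n``.
    """

    test: str
    statistic: float
    p_value: float
    n: int
    bahadur_slope: float
    group_sizes: tuple[int, int]
    direction: str = "none"  # inside_excess | outside_excess | none
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CountPair:
    """Inside and outside counts of a residue class for one helix/protein."""

    inside: int
    outside: int

    def __post_init__(self):
        if self.inside < 0 or self.outside < 0:
            raise ValueError("counts must be non-negative")


def bahadur_slope(p_value: float, n: int) -> float:
    """``B = |ln p| / N``; zero when p = 1, undefined (error) when p = 0."""
    if not (0 < p_value <= 1):
        raise ValueError(
            "p value must be in (0, 1]; report an underflowing p as a lower bound"
        )
    if n < 1:
        raise ValueError("N must be at least 1")
    return abs(math.log(p_value)) / n


# ---------------------------------------------------------------------------
# two-group Kruskal-Wallis with exact small-sample permutation p
# ---------------------------------------------------------------------------

def _kw_h(ranks: np.ndarray, n1: int, tie_term: float) -> float:
    n = ranks.size
    r1 = ranks[:n1].sum()
    r2 = ranks[n1:].sum()
    h = 12.0 / (n * (n + 1)) * (r1**2 / n1 + r2**2 / (n - n1)) - 3 * (n + 1)
    if tie_term < 1.0:
        h /= tie_term
    return h


def _tie_term(values: np.ndarray) -> float:
    n = values.size
    _, counts = np.unique(values, return_counts=True)
    return 1.0 - (counts**3 - counts).sum() / (n**3 - n)


def kruskal_two_group(
    x: Sequence[float], y: Sequence[float], exact_limit: int = EXACT_KW_LIMIT
) -> tuple[float, float]:
    """Two-group Kruskal-Wallis: returns (H, p).

    Tie-corrected; exact permutation p when both groups have fewer than
    ``exact_limit`` observations.  All-identical data yield (0, 1): no skew
    is detectable, the p value is reported as 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise DegenerateTestError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    tie = _tie_term(pooled)
    if tie <= 0:  # all values tied (handled above), defensive
        return 0.0, 1.0
    ranks = sps.rankdata(pooled)
    h_obs = _kw_h(ranks, x.size, tie)
    if x.size < exact_limit and y.size < exact_limit:
        n = pooled.size
        idx = np.arange(n)
        count = 0
        total = 0
        for comb in combinations(idx, x.size):
            sel = np.zeros(n, dtype=bool)
            sel[list(comb)] = True
            h = _kw_h(np.concatenate([ranks[sel], ranks[~sel]]), x.size, tie)
            if h >= h_obs - 1e-12:
                count += 1
            total += 1
        return h_obs, count / total
    p = sps.chi2.sf(h_obs, df=1)
    return h_obs, float(p)


def _directional_result(
    test: str,
    inside: np.ndarray,
    outside: np.ndarray,
    h: float,
    p: float,
) -> StatTestResult:
    mean_in, mean_out = float(np.mean(inside)), float(np.mean(outside))
    if mean_out > mean_in:
        direction, sign = "outside_excess", 1.0
    elif mean_in > mean_out:
        direction, sign = "inside_excess", -1.0
    else:
        direction, sign = "none", 0.0
    n = inside.size + outside.size
    return StatTestResult(
        test=test,
        statistic=sign * h if h != 0 else 0.0,
        p_value=p,
        n=n,
        bahadur_slope=bahadur_slope(p, n) if p > 0 else float("inf"),
        group_sizes=(int(inside.size), int(outside.size)),
        direction=direction,
        extra={"mean_inside": mean_in, "mean_outside": mean_out},
    )


def inside_outside_skew(
    pairs: Sequence[CountPair], test: str = "kruskal_wallis"
) -> StatTestResult:
    """Test for a skew between per-helix inside and outside counts.

    The inside-count sample and the outside-count sample are compared with a
    two-group rank test; the signed statistic is positive for an outside
    excess and negative for an inside excess.
    """
    if len(pairs) < 2:
        raise DegenerateTestError("need at least two helices")
    inside = np.array([p.inside for p in pairs], dtype=float)
    outside = np.array([p.outside for p in pairs], dtype=float)
    if test == "kruskal_wallis":
        h, p = kruskal_two_group(inside, outside)
    elif test == "t_two_sample":
        t, p = sps.ttest_ind(inside, outside, equal_var=False)
        h = abs(float(t)) if np.isfinite(t) else 0.0
        p = float(p) if np.isfinite(p) else 1.0
    else:
        raise ValueError(f"unsupported test {test!r}")
    result = _directional_result(test, inside, outside, h, p)
    result.extra["total_inside"] = int(inside.sum())
    result.extra["total_outside"] = int(outside.sum())
    return result


def leaflet_asymmetry(
    cores: Sequence[str],
    residue_type: str = "L",
    unit: str = "per_helix",
    accessions: Optional[Sequence[str]] = None,
    odd_center: str = "exclude",
) -> StatTestResult:
    """Asymmetry of a residue type between the inner and outer leaflet
    halves of TMH cores.

    Counts are per helix by default, or summed per protein when
    ``unit="per_protein"`` (requires ``accessions``).  The reported
    ``extra["percentage"]`` is ``100 * total_inner / total_outer`` (None if
    the outer total is zero).  Direction ``inside_excess`` means more of the
    residue in the inner (cytoplasmic-side) leaflet.
    """
    from .extraction import split_leaflets

    inner_counts: list[int] = []
    outer_counts: list[int] = []
    for core in cores:
        inner, outer = split_leaflets(core, odd_center)
        inner_counts.append(inner.count(residue_type))
        outer_counts.append(outer.count(residue_type))
    if unit == "per_protein":
        if accessions is None or len(accessions) != len(cores):
            raise ValueError("per_protein unit requires one accession per core")
        agg_in: dict[str, int] = {}
        agg_out: dict[str, int] = {}
        for acc, ci, co in zip(accessions, inner_counts, outer_counts):
            agg_in[acc] = agg_in.get(acc, 0) + ci
            agg_out[acc] = agg_out.get(acc, 0) + co
        keys = sorted(agg_in)
        inner_counts = [agg_in[k] for k in keys]
        outer_counts = [agg_out[k] for k in keys]
    elif unit != "per_helix":
        raise ValueError("unit must be 'per_helix' or 'per_protein'")

    inner = np.array(inner_counts, dtype=float)
    outer = np.array(outer_counts, dtype=float)
    if inner.size < 2:
        raise DegenerateTestError("need at least two units")
    h, p = kruskal_two_group(inner, outer)
    # Reuse the inside/outside machinery with inner as "inside".
    result = _directional_result("kruskal_wallis", inner, outer, h, p)
    total_in, total_out = int(inner.sum()), int(outer.sum())
    result.extra.update(
        total_inner=total_in,
        total_outer=total_out,
        percentage=(100.0 * total_in / total_out) if total_out else None,
        residue_type=residue_type,
        unit=unit,
    )
    return result


def acidic_content_test(
    per_helix_counts_sp: Sequence[int], per_helix_counts_mp: Sequence[int]
) -> StatTestResult:
    """Compare per-helix core residue counts between single-pass and
    multi-pass helices (rank test); reports the group means."""
    sp = np.asarray(per_helix_counts_sp, dtype=float)
    mp = np.asarray(per_helix_counts_mp, dtype=float)
    if sp.size == 0 or mp.size == 0:
        raise DegenerateTestError("both groups must be nonempty")
    h, p = kruskal_two_group(sp, mp)
    n = sp.size + mp.size
    return StatTestResult(
        test="kruskal_wallis",
        statistic=h,
        p_value=p,
        n=n,
        bahadur_slope=bahadur_slope(p, n) if p > 0 else float("inf"),
        group_sizes=(int(sp.size), int(mp.size)),
        direction="none",
        extra={"mu_sp": float(sp.mean()), "mu_mp": float(mp.mean())},
    )


# ---------------------------------------------------------------------------
# position-distribution comparisons (KS / KW / chi-square)
# ---------------------------------------------------------------------------

def _position_count_vectors(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo = int(min(a.min(), b.min()))
    hi = int(max(a.max(), b.max()))
    positions = np.arange(lo, hi + 1)
    ca = np.array([(a == p).sum() for p in positions], dtype=float)
    cb = np.array([(b == p).sum() for p in positions], dtype=float)
    return positions, ca, cb


def _pool_columns(
    ca: np.ndarray, cb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Pool adjacent columns left to right until all expected counts are >= 1.

    Returns pooled count vectors and the pooling map (number of original
    columns merged into each pooled column).
    """
    total = ca.sum() + cb.sum()
    row_a, row_b = ca.sum(), cb.sum()
    pooled_a: list[float] = []
    pooled_b: list[float] = []
    widths: list[int] = []
    acc_a = acc_b = 0.0
    width = 0
    for va, vb in zip(ca, cb):
        acc_a += va
        acc_b += vb
        width += 1
        col = acc_a + acc_b
        if row_a * col / total >= 1.0 and row_b * col / total >= 1.0:
            pooled_a.append(acc_a)
            pooled_b.append(acc_b)
            widths.append(width)
            acc_a = acc_b = 0.0
            width = 0
    if width:
        if pooled_a:
            pooled_a[-1] += acc_a
            pooled_b[-1] += acc_b
            widths[-1] += width
        else:
            pooled_a, pooled_b, widths = [acc_a], [acc_b], [width]
    return np.array(pooled_a), np.array(pooled_b), widths


def chi_square_homogeneity(
    a_counts: np.ndarray, b_counts: np.ndarray
) -> tuple[float, float, int, list[int]]:
    """Chi-square homogeneity test on a 2 x R count table with low-count
    column pooling; returns (statistic, p, df, pooling map)."""
    a_counts = np.asarray(a_counts, dtype=float)
    b_counts = np.asarray(b_counts, dtype=float)
    pa, pb, widths = _pool_columns(a_counts, b_counts)
    if pa.size < 2:
        raise DegenerateTestError(
            "chi-square table collapses below 2 columns after pooling; "
            "pool positions more coarsely"
        )
    total = pa.sum() + pb.sum()
    row_a, row_b = pa.sum(), pb.sum()
    col = pa + pb
    ea = row_a * col / total
    eb = row_b * col / total
    if (ea < 1).any() or (eb < 1).any():
        raise DegenerateTestError(
            "expected chi-square cell below 1 after pooling; pool positions "
            "more coarsely"
        )
    stat = float(((pa - ea) ** 2 / ea).sum() + ((pb - eb) ** 2 / eb).sum())
    df = pa.size - 1
    p = float(sps.chi2.sf(stat, df=df))
    return stat, p, df, widths


def position_distribution_test(
    group_a: Sequence[int],
    group_b: Sequence[int],
    test: str = "kolmogorov_smirnov",
    unit: str = "occurrence",
) -> StatTestResult:
    """Compare the positional distributions of a residue class between two
    segment groups.

    By default (``unit="occurrence"``) each residue occurrence contributes
    its aligned position as one observation, so N is the total residue-class
    count in both groups.  ``unit="position_summary"`` instead compares the
    per-position count vectors (one value per position).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateTestError("both groups must be nonempty")
    n = int(a.size + b.size)
    extra: dict = {"unit": unit}
    if unit == "position_summary":
        _, ca, cb = _position_count_vectors(a.astype(int), b.astype(int))
        a, b = ca, cb
        n = int(a.size + b.size)
    elif unit != "occurrence":
        raise ValueError("unit must be 'occurrence' or 'position_summary'")

    if test == "kolmogorov_smirnov":
        res = sps.ks_2samp(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "kruskal_wallis":
        stat, p = kruskal_two_group(a, b)
    elif test == "chi_square":
        if unit == "position_summary":
            ca, cb = a, b
        else:
            _, ca, cb = _position_count_vectors(
                np.asarray(group_a, dtype=int), np.asarray(group_b, dtype=int)
            )
        stat, p, df, widths = chi_square_homogeneity(ca, cb)
        extra.update(df=df, pooling=widths)
    else:
        raise ValueError(f"unsupported test {test!r}")
    p = min(max(p, 0.0), 1.0)
    return StatTestResult(
        test=test,
        statistic=stat,
        p_value=p,
        n=n,
        bahadur_slope=bahadur_slope(p, n) if p > 0 else float("inf"),
        group_sizes=(int(np.asarray(group_a).size), int(np.asarray(group_b).size)),
        direction="none",
        extra=extra,
    )


def positionwise_hydro_test(
    values_a_by_pos: dict[int, Sequence[float]],
    values_b_by_pos: dict[int, Sequence[float]],
    test: str = "kruskal_wallis",
) -> dict[int, StatTestResult]:
    """Per-position comparison of windowed hydrophobicity values between two
    segment groups (rank test or Welch t); positions with fewer than two
    values in either group are skipped."""
    out: dict[int, StatTestResult] = {}
    for pos in sorted(set(values_a_by_pos) & set(values_b_by_pos)):
        a = np.asarray(values_a_by_pos[pos], dtype=float)
        b = np.asarray(values_b_by_pos[pos], dtype=float)
        if a.size < 2 or b.size < 2:
            continue
        if test == "kruskal_wallis":
            stat, p = kruskal_two_group(a, b)
        elif test == "t_two_sample":
            t, p = sps.ttest_ind(a, b, equal_var=False)
            stat, p = float(t), float(p)
            if not np.isfinite(p):
                stat, p = 0.0, 1.0
        else:
            raise ValueError(f"unsupported test {test!r}")
        n = int(a.size + b.size)
        out[pos] = StatTestResult(
            test=test,
            statistic=stat,
            p_value=p,
            n=n,
            bahadur_slope=bahadur_slope(p, n) if p > 0 else float("inf"),
            group_sizes=(int(a.size), int(b.size)),
        )
    return out


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q values (optional extra column; raw p values are the
    primary report)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q
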
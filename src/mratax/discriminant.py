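"""Two-group discrimination in ratio space.

The discriminant machinery works in log-measurement space, where a ratio of
two characters j, k corresponds to the direction e_j - e_k.  The standard
distance along a direction r is

    D(r) = |r' (mu1 - mu2)| / sqrt(r' W r)

with W the pooled within-group covariance — the group-mean separation in
pooled within-group standard deviations.  The best-ratio search (the "LDA
ratio extractor" of taxonomic practice) simply maximizes D over all
p(p-1)/2 single-ratio directions, yielding key-ready diagnostic ratios
together with the raw-ratio range observed in each group.

The statistic delta compares discrimination along the isometric size axis
with discrimination in shape space: values near zero mean the separation is
carried by shape, not by size.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import MeasurementTable, TableValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DiscriminantReport",
    "pooled_within_covariance",
    "standard_distance",
    "best_ratio_search",
    "delta",
    "ratio_range",
    "comparison_suite",
]

REPORT_COLUMNS = (
    "comparison", "sex", "best_ratio",
    "range1_min", "range1_max", "range2_min", "range2_max",
    "standard_distance", "delta", "overlap_flag",
)


@dataclass(frozen=True)
class DiscriminantReport:
    """Best discriminating ratio for one two-group comparison.

    ``best_pair`` is (numerator, denominator), oriented so the pooled
    geometric-mean ratio is >= 1.  Ranges are min-max of the raw ratio
    within each group; ``overlap`` is True when the two ranges intersect.
    """

    group_1: str
    group_2: str
    sex: str
    best_pair: tuple[str, str]
    range_1: tuple[float, float]
    range_2: tuple[float, float]
    standard_distance: float
    delta: float
    n_1: int
    n_2: int

    @property
    def overlap(self) -> bool:
        return (self.range_1[0] <= self.range_2[1]) and (
            self.range_2[0] <= self.range_1[1]
        )

    def to_row(self) -> dict:
        return {
            "comparison": f"{self.group_1}-{self.group_2}",
            "sex": self.sex,
            "best_ratio": f"{self.best_pair[0]}:{self.best_pair[1]}",
            "range1_min": self.range_1[0],
            "range1_max": self.range_1[1],
            "range2_min": self.range_2[0],
            "range2_max": self.range_2[1],
            "standard_distance": self.standard_distance,
            "delta": self.delta,
            "overlap_flag": int(self.overlap),
        }


def _two_group_logs(
    table: MeasurementTable, group_1: str, group_2: str | list[str],
) -> tuple[np.ndarray, np.ndarray]:
    g2 = [group_2] if isinstance(group_2, str) else list(group_2)
    a = np.log(table.by_otu(group_1).values)
    b = np.log(table.by_otu(*g2).values)
    if len(a) < 2 or len(b) < 2:
        raise TableValidationError("each group needs at least 2 specimens")
    return a, b


def pooled_within_covariance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled within-group covariance of two log-data matrices.

    W = [(n1-1) S1 + (n2-1) S2] / (n1 + n2 - 2); symmetric PSD.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 rows")
    s1 = np.cov(a, rowvar=False)
    s2 = np.cov(b, rowvar=False)
    n1, n2 = len(a), len(b)
    w = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    return np.atleast_2d(w)


def standard_distance(
    direction: np.ndarray, a: np.ndarray, b: np.ndarray,
    w: np.ndarray | None = None,
) -> float:
    """Standard distance between two log-data groups along a direction.

    Invariant to rescaling of the direction and to global unit changes.
    Returns inf (flagged) when the within-group variance along the
    direction vanishes but the means differ.
    """
    r = np.asarray(direction, dtype=float)
    if not np.any(r):
        raise ValueError("direction must be nonzero")
    if w is None:
        w = pooled_within_covariance(a, b)
    diff = r @ (a.mean(axis=0) - b.mean(axis=0))
    denom = r @ w @ r
    if denom <= 0:
        if abs(diff) < 1e-12:
            return 0.0
        logger.warning("zero within-group variance along direction; "
                       "separation is infinite")
        return float("inf")
    return float(abs(diff) / np.sqrt(denom))


def delta(a: np.ndarray, b: np.ndarray) -> float:
    """Size-vs-shape discrimination ratio for two log-data groups.

    delta = D(u) / D(d_shape) with u the isometric axis (1,...,1)/sqrt(p)
    and d_shape = W_shape^+ (mu1 - mu2) the within-shape-space discriminant
    direction (pseudo-inverse; components along the isometric axis are
    projected out).  Zero when the group isosize means coincide; NaN
    (flagged) when shape does not separate the groups at all.
    """
    p = a.shape[1]
    u = np.full(p, 1.0 / np.sqrt(p))
    w = pooled_within_covariance(a, b)
    d_size = standard_distance(u, a, b, w=w)
    # shape space: remove each row's mean
    sa = a - a.mean(axis=1, keepdims=True)
    sb = b - b.mean(axis=1, keepdims=True)
    ws = pooled_within_covariance(sa, sb)
    mdiff = sa.mean(axis=0) - sb.mean(axis=0)
    d_dir = np.linalg.pinv(ws, rcond=1e-10) @ mdiff
    d_dir = d_dir - d_dir.mean()
    if not np.any(np.abs(d_dir) > 1e-14):
        logger.warning("no shape separation; delta undefined")
        return float("nan")
    d_shape = standard_distance(d_dir, sa, sb, w=ws)
    if d_shape == 0 or not np.isfinite(d_shape):
        logger.warning("degenerate shape discriminant; delta undefined")
        return float("nan")
    return float(d_size / d_shape)


def ratio_range(
    table: MeasurementTable, group: str | list[str], pair: tuple[str, str],
) -> tuple[float, float]:
    """Min and max of the raw ratio numerator/denominator within a group."""
    groups = [group] if isinstance(group, str) else list(group)
    sub = table.by_otu(*groups)
    if sub.n == 0:
        raise TableValidationError(f"group {group!r} is empty")
    num, den = pair
    j = table.characters.index(num)
    k = table.characters.index(den)
    ratios = sub.values[:, j] / sub.values[:, k]
    return float(ratios.min()), float(ratios.max())


def best_ratio_search(
    table: MeasurementTable, group_1: str, group_2: str | list[str],
    sex: str | None = None,
) -> DiscriminantReport:
    """Exhaustive best-ratio search over all character pairs.

    Evaluates the standard distance of direction e_j - e_k (the log ratio
    j/k) for every unordered pair and returns the maximizing pair with its
    raw-ratio ranges per group and delta.  Pairs with zero pooled
    within-group ratio variance are skipped with a warning.  Ties are broken
    by lexicographic character order, deterministically.
    """
    if sex is None:
        sex = table.single_sex()
    a, b = _two_group_logs(table, group_1, group_2)
    w = pooled_within_covariance(a, b)
    mdiff = a.mean(axis=0) - b.mean(axis=0)
    chars = table.characters
    best: tuple[float, tuple[str, str]] | None = None
    for j, k in itertools.combinations(range(len(chars)), 2):
        denom = w[j, j] + w[k, k] - 2 * w[j, k]
        diff = abs(mdiff[j] - mdiff[k])
        if denom <= 0:
            if diff > 1e-12:
                logger.warning(
                    "skipping pair %s:%s with zero within-group ratio "
                    "variance", chars[j], chars[k],
                )
            continue
        d = diff / np.sqrt(denom)
        # ties broken by lexicographic character-name order
        cand = (d, tuple(sorted((chars[j], chars[k]))))
        if best is None or d > best[0] or (d == best[0] and cand[1] < best[1]):
            best = cand
    if best is None:
        raise TableValidationError("no valid character pair (degenerate W)")
    d_best, (cj, ck) = best
    if d_best == 0:
        logger.warning("groups %s and %s are not separable (D = 0 for all "
                       "pairs)", group_1, group_2)
    # orientation: numerator so the pooled geometric-mean ratio >= 1
    pooled = np.vstack([a, b])
    jdx, kdx = chars.index(cj), chars.index(ck)
    if pooled[:, jdx].mean() - pooled[:, kdx].mean() < 0:
        cj, ck = ck, cj
    pair = (cj, ck)
    return DiscriminantReport(
        group_1=group_1,
        group_2=group_2 if isinstance(group_2, str) else "rest",
        sex=sex,
        best_pair=pair,
        range_1=ratio_range(table, group_1, pair),
        range_2=ratio_range(table, group_2, pair),
        standard_distance=float(d_best),
        delta=delta(a, b),
        n_1=len(a),
        n_2=len(b),
    )


def comparison_suite(
    table: MeasurementTable,
    comparisons: list[tuple[str, str, str]],
) -> pd.DataFrame:
    """Run a list of (sex, group_1, group_2-or-"rest") comparisons.

    "rest" pools every other OTU of that sex into a single comparison group
    (specimens concatenated, no reweighting).  Returns one row per
    comparison with a fixed column order.
    """
    if not comparisons:
        raise TableValidationError("empty comparison set")
    rows = []
    for sex, g1, g2 in comparisons:
        sub = table.by_sex(sex)
        otus = sorted(set(sub.otu))
        if g1 not in otus:
            raise TableValidationError(f"unknown OTU {g1!r} for sex {sex}")
        if g2 == "rest":
            others = [o for o in otus if o != g1]
            rep = best_ratio_search(sub, g1, others, sex=sex)
        else:
            if g2 not in otus:
                raise TableValidationError(f"unknown OTU {g2!r} for sex {sex}")
            rep = best_ratio_search(sub, g1, g2, sex=sex)
        rows.append(rep.to_row())
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
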
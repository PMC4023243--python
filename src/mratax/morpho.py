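"""Size/shape decomposition of measurement tables.

The decomposition follows the multivariate-ratio-analysis convention: the
isometric size of a specimen is the mean of the natural logs of its
measurements (the log of their geometric mean), and shape is the residual of
the log measurements after removing that isometric component.  A shape PCA
is then an ordinary covariance PCA of the log-shape matrix, i.e. a PCA of
log-measurement space restricted to the orthogonal complement of the
isometric direction (1, ..., 1)/sqrt(p) — equivalently, a PCA in the space
of all ratios.

Two one-dimensional diagnostics summarize which ratios matter:

* the PCA ratio spectrum places each character at its loading coefficient on
  a chosen shape PC; the ratio of the two characters at opposite extremes
  best tracks that PC;
* the allometry ratio spectrum places each character at the OLS slope of its
  log measurement on isosize; extreme slope differences mark the most
  allometric ratios.

Both spectra carry 68% percentile bootstrap intervals (specimens resampled
with replacement, replicate loadings sign-aligned to the point estimate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import MeasurementTable, TableValidationError

__all__ = [
    "ShapeDecomposition",
    "RatioSpectrum",
    "isosize",
    "geometric_mean",
    "log_shape_transform",
    "shape_pca",
    "scree",
    "size_shape_correlation",
    "pca_ratio_spectrum",
    "allometry_ratio_spectrum",
]


@dataclass(frozen=True)
class ShapeDecomposition:
    """Isosize + log-shape split of a measurement table, optionally with PCA.

    ``loadings`` has shape (p-1, p): one unit-norm, zero-sum loading vector
    per shape PC, ordered by decreasing variance.  ``scores`` has shape
    (n, p-1) and is column-centered.  ``var_fraction`` sums to 1 over the
    p-1 shape components (all-NaN when the table is purely isometric).
    """

    specimen_id: np.ndarray
    characters: tuple[str, ...]
    isosize: np.ndarray
    log_shape: np.ndarray = field(repr=False)
    loadings: np.ndarray | None = field(default=None, repr=False)
    scores: np.ndarray | None = field(default=None, repr=False)
    variances: np.ndarray | None = None
    var_fraction: np.ndarray | None = None

    @property
    def p(self) -> int:
        return len(self.characters)

    def scores_frame(self) -> pd.DataFrame:
        if self.scores is None:
            raise ValueError("decomposition has no PCA scores")
        df = pd.DataFrame(
            self.scores,
            columns=[f"pc{i + 1}" for i in range(self.scores.shape[1])],
        )
        df.insert(0, "isosize", self.isosize)
        df.insert(0, "specimen_id", self.specimen_id)
        return df


@dataclass(frozen=True)
class RatioSpectrum:
    """Per-character positions on a one-dimensional ratio axis.

    ``kind`` is "pca" (positions are shape-PC loadings) or "allometry"
    (positions are slopes of log character on isosize).  ``ci_low`` and
    ``ci_high`` are 68% percentile bootstrap bounds; replicates whose point
    estimate falls outside the raw percentile band widen it so that
    ci_low <= position <= ci_high always holds.
    """

    kind: str
    characters: tuple[str, ...]
    position: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    pc_index: int | None = None

    def to_frame(self) -> pd.DataFrame:
        """Spectrum table sorted by position (descending)."""
        df = pd.DataFrame(
            {
                "character": self.characters,
                "position": self.position,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )
        return df.sort_values(
            ["position", "character"], ascending=[False, True]
        ).reset_index(drop=True)

    def best_ratio(self) -> tuple[str, str]:
        """Characters at the two extremes (top, bottom); ties break
        lexicographically."""
        df = self.to_frame()
        return df["character"].iloc[0], df["character"].iloc[-1]


# ----------------------------------------------------------------------
# size and shape

def isosize(values: np.ndarray, characters: tuple[str, ...] | None = None):
    """Isometric size of one specimen or of each row of a matrix.

    Defined as the mean of natural logs, i.e. log of the geometric mean of
    all measurements.  Nonpositive or missing entries are rejected with the
    offending character named.
    """
    arr = np.asarray(values, dtype=float)
    flat = arr.ndim == 1
    mat = arr[None, :] if flat else arr
    bad = ~(np.isfinite(mat) & (mat > 0))
    if bad.any():
        j = int(np.argwhere(bad)[0][1])
        name = characters[j] if characters is not None else f"column {j}"
        raise ValueError(f"nonpositive or missing measurement in {name}")
    out = np.log(mat).mean(axis=1)
    return float(out[0]) if flat else out


def geometric_mean(values: np.ndarray) -> float | np.ndarray:
    """Geometric mean; exp of :func:`isosize`."""
    return np.exp(isosize(values))


def log_shape_transform(table: MeasurementTable) -> ShapeDecomposition:
    """Split log measurements into isosize and log-shape.

    Each log-shape row is log(values) minus its own row mean, so rows sum to
    zero and ``isosize * 1 + log_shape`` reconstructs the log data exactly.
    """
    if table.p < 2:
        raise TableValidationError("shape undefined for p < 2")
    logs = np.log(table.values)
    iso = logs.mean(axis=1)
    return ShapeDecomposition(
        specimen_id=table.specimen_id,
        characters=table.characters,
        isosize=iso,
        log_shape=logs - iso[:, None],
    )


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude coefficient of each loading positive."""
    out = loadings.copy()
    for k in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[k])))
        if out[k, j] < 0:
            out[k] = -out[k]
    return out


def shape_pca(
    table: MeasurementTable, allow_mixed_sex: bool = False,
) -> ShapeDecomposition:
    """Covariance PCA of the log-shape matrix (unsupervised, no group use).

    Exactly p-1 components can carry variance; the isometric direction is an
    exact null direction and is excluded.  Mixed-sex tables are refused
    unless ``allow_mixed_sex`` is set, since size/shape structure differs
    between sexes.
    """
    if table.n < 3:
        raise TableValidationError("shape PCA needs at least 3 specimens")
    if not allow_mixed_sex:
        table.single_sex()
    base = log_shape_transform(table)
    p = table.p
    z = base.log_shape - base.log_shape.mean(axis=0)
    cov = (z.T @ z) / (table.n - 1)
    # project out the isometric direction to remove numerical drift;
    # cov already annihilates it analytically (rows of log_shape sum to 0)
    proj = np.eye(p) - np.full((p, p), 1.0 / p)
    cov = proj @ cov @ proj
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # drop the component aligned with (1,...,1)/sqrt(p): it is the one with
    # the largest |mean| among the p eigenvectors
    iso_align = np.abs(evecs.mean(axis=0))
    keep = np.argsort(iso_align)[: p - 1]
    keep = np.sort(keep)  # preserve variance ordering
    evals, evecs = evals[keep], evecs[:, keep]
    evals = np.clip(evals, 0.0, None)
    loadings = _fix_signs(evecs.T)
    # re-impose exact zero-sum + unit norm (numerical hygiene)
    loadings = loadings - loadings.mean(axis=1, keepdims=True)
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    scores = z @ loadings.T
    total = evals.sum()
    var_fraction = evals / total if total > 0 else np.full(p - 1, np.nan)
    return ShapeDecomposition(
        specimen_id=table.specimen_id,
        characters=table.characters,
        isosize=base.isosize,
        log_shape=base.log_shape,
        loadings=loadings,
        scores=scores,
        variances=evals,
        var_fraction=var_fraction,
    )


def scree(decomp: ShapeDecomposition) -> pd.DataFrame:
    """Ordered variance table: variance, fraction and cumulative fraction."""
    if decomp.variances is None:
        raise ValueError("decomposition has no PCA variances; run shape_pca")
    frac = decomp.var_fraction
    df = pd.DataFrame(
        {
            "pc": np.arange(1, len(decomp.variances) + 1),
            "variance": decomp.variances,
            "fraction": frac,
            "cumulative": np.cumsum(frac),
        }
    )
    return df


def size_shape_correlation(decomp: ShapeDecomposition, pc_index: int) -> float:
    """Pearson correlation of isosize with the scores of one shape PC.

    Positive allometry in the data shows up as |correlation| well above 0.
    Returns NaN (flagged) when either variable is constant.
    """
    if decomp.scores is None:
        raise ValueError("decomposition has no PCA scores; run shape_pca")
    if not 1 <= pc_index <= decomp.scores.shape[1]:
        raise ValueError(f"pc_index {pc_index} out of range 1..{decomp.scores.shape[1]}")
    x = decomp.isosize
    y = decomp.scores[:, pc_index - 1]
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# ----------------------------------------------------------------------
# ratio spectra

def _boot_indices(rng: np.random.Generator, n: int) -> np.ndarray:
    """Resample specimen indices; redraw until >= 3 distinct specimens."""
    while True:
        idx = rng.integers(0, n, size=n)
        if len(np.unique(idx)) >= 3:
            return idx


def _percentile_band(
    replicates: np.ndarray, point: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """68% percentile interval per character, widened to cover the point
    estimate (its resample distribution includes the original sample)."""
    lo = np.percentile(replicates, 16, axis=0)
    hi = np.percentile(replicates, 84, axis=0)
    return np.minimum(lo, point), np.maximum(hi, point)


def pca_ratio_spectrum(
    table: MeasurementTable,
    pc_index: int = 1,
    n_boot: int = 1000,
    seed: int | None = None,
    allow_mixed_sex: bool = False,
) -> RatioSpectrum:
    """PCA ratio spectrum: loadings of one shape PC with bootstrap bands.

    Bootstrap replicates resample specimens with replacement, recompute the
    shape PCA, and are sign-aligned to the point-estimate loading by dot
    product before taking 16th/84th percentiles.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    decomp = shape_pca(table, allow_mixed_sex=allow_mixed_sex)
    if not 1 <= pc_index <= table.p - 1:
        raise ValueError(f"pc_index {pc_index} out of range 1..{table.p - 1}")
    point = decomp.loadings[pc_index - 1]
    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, table.p))
    for b in range(n_boot):
        idx = _boot_indices(rng, table.n)
        reps[b] = _shape_pca_loading(table.values[idx], pc_index)
        if reps[b] @ point < 0:
            reps[b] = -reps[b]
    lo, hi = _percentile_band(reps, point)
    return RatioSpectrum(
        kind="pca",
        characters=table.characters,
        position=point,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
        pc_index=pc_index,
    )


def _shape_pca_loading(values: np.ndarray, pc_index: int) -> np.ndarray:
    """Loading vector of one shape PC from raw values (no table checks)."""
    logs = np.log(values)
    ls = logs - logs.mean(axis=1, keepdims=True)
    z = ls - ls.mean(axis=0)
    p = values.shape[1]
    cov = (z.T @ z) / max(values.shape[0] - 1, 1)
    proj = np.eye(p) - np.full((p, p), 1.0 / p)
    evals, evecs = np.linalg.eigh(proj @ cov @ proj)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    iso_align = np.abs(evecs.mean(axis=0))
    keep = np.sort(np.argsort(iso_align)[: p - 1])
    evecs = evecs[:, keep]
    v = evecs[:, pc_index - 1]
    v = v - v.mean()
    nrm = np.linalg.norm(v)
    if nrm > 0:
        v = v / nrm
    j = int(np.argmax(np.abs(v)))
    return v if v[j] >= 0 else -v


def _allometry_slopes(values: np.ndarray) -> np.ndarray:
    """OLS slope of each log character on isosize."""
    logs = np.log(values)
    iso = logs.mean(axis=1)
    x = iso - iso.mean()
    ssx = x @ x
    if ssx == 0:
        return np.full(values.shape[1], np.nan)
    return (logs - logs.mean(axis=0)).T @ x / ssx


def allometry_ratio_spectrum(
    table: MeasurementTable,
    n_boot: int = 1000,
    seed: int | None = None,
    allow_mixed_sex: bool = False,
) -> RatioSpectrum:
    """Allometry ratio spectrum: per-character slope of log character on
    isosize, with 68% bootstrap bands.

    Under perfect isometry every slope is 1.  A zero-variance isosize makes
    the slopes undefined; positions are then NaN (flagged).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not allow_mixed_sex:
        table.single_sex()
    point = _allometry_slopes(table.values)
    rng = np.random.default_rng(seed)
    if np.isnan(point).all():
        nan = np.full(table.p, np.nan)
        return RatioSpectrum(
            kind="allometry", characters=table.characters,
            position=point, ci_low=nan, ci_high=nan, n_boot=n_boot,
        )
    reps = np.empty((n_boot, table.p))
    for b in range(n_boot):
        idx = _boot_indices(rng, table.n)
        reps[b] = _allometry_slopes(table.values[idx])
    lo, hi = _percentile_band(reps, point)
    return RatioSpectrum(
        kind="allometry",
        characters=table.characters,
        position=point,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
    )
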
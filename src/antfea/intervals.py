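"""The intervals method: stress-distribution profiles comparable across models.

Per-element Tresca stresses and areas are turned into per-model vectors of
area fractions falling in fixed stress intervals:

1. remove the top 2% highest-stress elements of each model (meshing
   artifacts concentrate there);
2. transform stresses to their natural logarithm;
3. fix an upper threshold T so the last interval holds only the top 2% of
   pooled transformed stresses; equal-width intervals cover [pooled min, T)
   and the last interval is [T, inf);
4. sum element areas per interval, normalise per model (rows sum to 1);
5. ordinate the models with a PCA on the (standardised) interval variables.

The interval count is selected by running the chain at several candidate
counts and regressing PC scores of consecutive candidates against each other
until the coefficient of determination stops increasing.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("model", "element_id", "tresca", "area_mm2")
DEFAULT_CANDIDATES = (5, 15, 25, 50, 75)


class IntervalsError(ValueError):
    pass


def validate_element_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise IntervalsError(f"element table missing columns {missing}")
    if len(table) == 0:
        raise IntervalsError("element table is empty")
    if (table["tresca"] <= 0).any() or (table["area_mm2"] <= 0).any():
        raise IntervalsError("stresses and areas must be positive")
    dup = table.duplicated(subset=["model", "element_id"])
    if dup.any():
        raise IntervalsError("element ids must be unique within each model")
    return table


def read_element_table(path: str) -> pd.DataFrame:
    """Read the canonical CSV dialect: model,element_id,tresca,area_mm2."""
    return validate_element_table(pd.read_csv(path))


def combine_stress_area(stress: pd.DataFrame, area: pd.DataFrame) -> pd.DataFrame:
    """Join separate per-element stress and area tables (supplementary-style
    two-file inputs) into the canonical element table.

    Both frames need ``model`` and ``element_id`` plus a single value column
    (any name); the stress value is taken from the first frame, the area from
    the second.
    """
    def _value_col(df: pd.DataFrame, label: str) -> str:
        extra = [c for c in df.columns if c not in ("model", "element_id")]
        if len(extra) != 1:
            raise IntervalsError(f"{label} table needs exactly one value column, got {extra}")
        return extra[0]

    s = stress.rename(columns={_value_col(stress, "stress"): "tresca"})
    a = area.rename(columns={_value_col(area, "area"): "area_mm2"})
    merged = s.merge(a, on=["model", "element_id"], how="inner")
    return validate_element_table(merged[list(REQUIRED_COLUMNS)])


# ---------------------------------------------------------------------------
# filtering and threshold
# ---------------------------------------------------------------------------

def filter_top_percent(table: pd.DataFrame, percent: float = 2.0) -> pd.DataFrame:
    """Drop the ceil(percent% * n) highest-stress elements of each model.

    Ties are broken by element id (stable), so the removed set is
    deterministic.  Raises on an empty model group.
    """
    validate_element_table(table)
    out = []
    for model, grp in table.groupby("model", sort=True):
        n_remove = math.ceil(percent / 100.0 * len(grp))
        kept = grp.sort_values(["tresca", "element_id"], kind="stable")
        out.append(kept.iloc[: len(grp) - n_remove])
    result = pd.concat(out).sort_values(["model", "element_id"], kind="stable")
    return result.reset_index(drop=True)


def fit_upper_threshold(filtered: pd.DataFrame, percent: float = 2.0) -> float:
    """Upper interval threshold on the ln scale: the (100 - percent) linear-
    interpolation percentile of the pooled transformed stresses, so the last
    interval holds only the top ``percent``% of all simulations' values."""
    validate_element_table(filtered)
    logs = np.log(filtered["tresca"].to_numpy())
    return float(np.percentile(logs, 100.0 - percent))


# ---------------------------------------------------------------------------
# interval scheme and area proportions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntervalScheme:
    """Equal-width intervals on ln stress: N - 1 bins on [lower, upper) plus
    an open last bin [upper, inf)."""

    lower: float
    upper_threshold: float
    n_intervals: int
    filter_percent: float = 2.0

    def __post_init__(self) -> None:
        if self.n_intervals < 2:
            raise IntervalsError("need at least 2 intervals")
        if not self.lower < self.upper_threshold:
            raise IntervalsError("lower bound must lie below the upper threshold")

    def edges(self) -> np.ndarray:
        """Interior bin edges (len N): boundaries of the N-1 equal bins and
        the upper threshold; used with searchsorted to index intervals."""
        inner = np.linspace(self.lower, self.upper_threshold, self.n_intervals)
        return inner  # last entry == upper threshold opens the final interval


def build_scheme(filtered: pd.DataFrame, n_intervals: int,
                 upper_threshold: float | None = None,
                 percent: float = 2.0) -> IntervalScheme:
    """Scheme with lower = pooled post-filter minimum of ln stress and the
    fitted (or supplied) upper threshold."""
    lower = float(np.log(filtered["tresca"].min()))
    upper = upper_threshold if upper_threshold is not None else fit_upper_threshold(filtered, percent)
    return IntervalScheme(lower=lower, upper_threshold=upper,
                          n_intervals=n_intervals, filter_percent=percent)


def area_proportions(table: pd.DataFrame, scheme: IntervalScheme) -> pd.DataFrame:
    """Models x intervals matrix of area fractions (rows sum to 1).

    Element areas are summed into the interval containing the element's ln
    stress; stresses below the scheme's lower bound are clamped into the
    first interval (logged, never fatal).
    """
    validate_element_table(table)
    edges = scheme.edges()
    logs = np.log(table["tresca"].to_numpy())
    below = logs < scheme.lower - 1e-12
    if below.any():
        logger.warning("%d elements below the interval lower bound; clamped "
                       "into the first interval", int(below.sum()))
    # bins: index i means [edge_{i-1}, edge_i); searchsorted on interior edges
    idx = np.searchsorted(edges[1:-1], logs, side="right")
    idx = np.clip(idx, 0, scheme.n_intervals - 1)
    # values >= upper threshold belong to the last, open interval
    idx[logs >= scheme.upper_threshold] = scheme.n_intervals - 1
    df = pd.DataFrame({"model": table["model"].to_numpy(), "interval": idx,
                       "area": table["area_mm2"].to_numpy()})
    mat = (df.pivot_table(index="model", columns="interval", values="area",
                          aggfunc="sum", fill_value=0.0)
             .reindex(columns=range(scheme.n_intervals), fill_value=0.0))
    mat = mat.div(mat.sum(axis=1), axis=0)
    mat.columns = [f"interval_{i + 1}" for i in range(scheme.n_intervals)]
    return mat


# ---------------------------------------------------------------------------
# PCA ordination
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame                 # models x components
    explained_variance_pct: np.ndarray   # per component, percent
    loadings: pd.DataFrame               # variables x components


def pca_profiles(matrix: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """PCA of the area-proportion matrix (variables centred and, by default,
    scaled to unit variance).  Zero-variance variables are dropped with a
    warning; if none remain, a 0-component result is returned."""
    if len(matrix) < 2:
        raise IntervalsError("PCA needs at least 2 models")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 1e-14
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance interval "
                      "variables before PCA", stacklevel=2)
    if not keep.any():
        warnings.warn("all interval variables have zero variance; returning "
                      "0 components", stacklevel=2)
        return PCAResult(scores=pd.DataFrame(index=matrix.index),
                         explained_variance_pct=np.empty(0),
                         loadings=pd.DataFrame(index=matrix.columns[:0]))
    xk = x[:, keep]
    xc = xk - xk.mean(axis=0)
    if standardize:
        xc = xc / xk.std(axis=0, ddof=1)
    n_comp = min(xc.shape[0] - 1, xc.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(xc)
    pct = 100.0 * pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=cols),
        explained_variance_pct=pct,
        loadings=pd.DataFrame(pca.components_.T,
                              index=matrix.columns[keep], columns=cols),
    )


# ---------------------------------------------------------------------------
# interval-count selection
# ---------------------------------------------------------------------------

def _r_squared(a: np.ndarray, b: np.ndarray) -> float:
    """R^2 of the simple regression a ~ b (= squared Pearson correlation,
    hence invariant to PC sign flips)."""
    if np.std(a) < 1e-300 or np.std(b) < 1e-300:
        return 1.0  # both constant: trivially converged
    return float(np.corrcoef(a, b)[0, 1] ** 2)


@dataclass
class IntervalSelection:
    n_intervals: int
    r2_per_pair: list[dict]       # {pair, r2_pc1, r2_pc2}
    converged: bool               # False if R^2 still increasing at the end


def select_interval_count(filtered: pd.DataFrame,
                          candidates: tuple[int, ...] = DEFAULT_CANDIDATES,
                          upper_threshold: float | None = None,
                          percent: float = 2.0,
                          standardize: bool = True) -> IntervalSelection:
    """Pick the interval count where PC scores converge.

    For each consecutive candidate pair the PC1 (and PC2) scores of the
    smaller-count dataset are regressed on those of the larger; the pair
    score is min(R^2_PC1, R^2_PC2).  The selected count is the smaller member
    of the first pair at which the score stops increasing (or the first
    candidate if the very first pair is already at R^2 = 1).  If the score
    increases through the last pair, the largest candidate is returned with
    ``converged=False`` and a warning.
    """
    if len(candidates) < 3:
        raise IntervalsError("need at least 3 candidate interval counts")
    results = {}
    for n in candidates:
        scheme = build_scheme(filtered, n, upper_threshold, percent)
        mat = area_proportions(filtered, scheme)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results[n] = pca_profiles(mat, standardize=standardize)
    pairs = []
    scores = []
    for small, large in zip(candidates, candidates[1:]):
        rs, rl = results[small], results[large]
        r1 = _r_squared(rs.scores["PC1"].to_numpy(), rl.scores["PC1"].to_numpy())
        r2 = (_r_squared(rs.scores["PC2"].to_numpy(), rl.scores["PC2"].to_numpy())
              if "PC2" in rs.scores and "PC2" in rl.scores else r1)
        pairs.append({"pair": (small, large), "r2_pc1": r1, "r2_pc2": r2})
        scores.append(min(r1, r2))
    if scores[0] >= 1.0 - 1e-9:
        return IntervalSelection(candidates[0], pairs, True)
    for j in range(1, len(scores)):
        if scores[j] <= scores[j - 1]:
            return IntervalSelection(candidates[j], pairs, True)
    warnings.warn("R^2 still increasing at the largest interval count; "
                  "returning it unconverged", stacklevel=2)
    return IntervalSelection(candidates[-1], pairs, False)


def run_intervals_chain(table: pd.DataFrame,
                        candidates: tuple[int, ...] = DEFAULT_CANDIDATES,
                        percent: float = 2.0,
                        upper_threshold: float | None = None,
                        standardize: bool = True) -> dict:
    """The full chain: filter, threshold, count selection, final PCA.

    Returns a dict with the filtered table, fitted threshold, selection
    report, final area-proportion matrix and PCA result.
    """
    filtered = filter_top_percent(table, percent)
    fitted_t = fit_upper_threshold(filtered, percent)
    upper = upper_threshold if upper_threshold is not None else fitted_t
    selection = select_interval_count(filtered, candidates, upper, percent, standardize)
    scheme = build_scheme(filtered, selection.n_intervals, upper, percent)
    matrix = area_proportions(filtered, scheme)
    pca = pca_profiles(matrix, standardize=standardize)
    return {"filtered": filtered, "upper_threshold": upper,
            "fitted_threshold": fitted_t, "selection": selection,
            "scheme": scheme, "matrix": matrix, "pca": pca}
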
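"""Group statistics on element stresses and head-sculpture categories.

Stress magnitudes are compared across models with a Kruskal-Wallis rank test
(tie-corrected) followed by pairwise Dunn z-tests with Bonferroni
correction; all tests operate on per-element Tresca tables *after* the
top-2% artifact filter.  Head-cuticle sculpturing (ordinal categories 0-3)
is compared between the two worker subcastes with a Pearson chi-squared test
on the 2x4 contingency table plus per-cell standardised-residual post hoc
tests, Bonferroni-corrected over the 8 cells.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import validate_element_table

logger = logging.getLogger(__name__)

SCULPTURE_COLUMNS = ("species", "subcaste", "category")
SUBCASTES = ("major", "minor")
CATEGORIES = (0, 1, 2, 3)


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# rank tests on element stresses
# ---------------------------------------------------------------------------

@dataclass
class RankTestResult:
    h_statistic: float
    df: int
    p_value: float
    pairwise_p: pd.DataFrame | None = None   # Bonferroni-adjusted Dunn p's


def _stress_groups(table: pd.DataFrame) -> dict[str, np.ndarray]:
    validate_element_table(table)
    groups = {m: g["tresca"].to_numpy() for m, g in table.groupby("model", sort=True)}
    if len(groups) < 2:
        raise StatsError("Kruskal-Wallis needs at least 2 models")
    return groups


def kruskal_wallis(table: pd.DataFrame) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H across models with a chi-square p."""
    groups = _stress_groups(table)
    h, p = sps.kruskal(*groups.values())
    return RankTestResult(h_statistic=float(h), df=len(groups) - 1, p_value=float(p))


def dunn_bonferroni(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Dunn z-tests from pooled midranks, Bonferroni-corrected.

    Returns a symmetric models x models matrix of adjusted two-sided p-values
    (diagonal = 1).  The tie correction subtracts sum(t^3 - t)/(12 (N - 1))
    from the null rank variance N (N + 1)/12.
    """
    groups = _stress_groups(table)
    names = list(groups)
    pooled = np.concatenate([groups[m] for m in names])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for m in names:
        n = len(groups[m])
        mean_ranks[m] = ranks[start:start + n].mean()
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    m_pairs = len(names) * (len(names) - 1) // 2
    p = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        adj = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m_pairs)
        p.loc[a, b] = p.loc[b, a] = adj
    return p


def mean_tresca(table: pd.DataFrame, model: str) -> float:
    """Arithmetic mean element Tresca stress of one model (MPa); apply after
    the 2% filter to obtain the mean Tresca equivalent stress value (MTESV)."""
    validate_element_table(table)
    grp = table.loc[table["model"] == model, "tresca"]
    if len(grp) == 0:
        raise StatsError(f"unknown model {model!r}")
    return float(grp.mean())


# ---------------------------------------------------------------------------
# sculpture categories
# ---------------------------------------------------------------------------

@dataclass
class ChiSqResult:
    chi2: float
    df: int
    p_value: float
    observed: pd.DataFrame
    expected: pd.DataFrame
    posthoc_p: pd.DataFrame        # per-cell adjusted p (standardised residuals)
    residuals: pd.DataFrame        # per-cell standardised residuals


def read_sculpture_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_sculpture_table(df)


def validate_sculpture_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCULPTURE_COLUMNS if c not in df.columns]
    if missing:
        raise StatsError(f"sculpture table missing columns {missing}")
    if not df["subcaste"].isin(SUBCASTES).all():
        raise StatsError(f"subcaste must be one of {SUBCASTES}")
    if not df["category"].isin(CATEGORIES).all():
        raise StatsError(f"category must be one of {CATEGORIES}")
    if df.duplicated(subset=["species", "subcaste"]).any():
        raise StatsError("one row per species x subcaste expected")
    return df


def sculpture_chisq(table: pd.DataFrame) -> ChiSqResult:
    """Pearson chi-squared (no continuity correction) on the subcaste-by-
    category contingency table, with per-cell standardised-residual post hoc
    tests Bonferroni-corrected over all cells."""
    validate_sculpture_table(table)
    obs = pd.crosstab(table["subcaste"], table["category"])
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise StatsError("contingency table needs >= 2 subcastes and >= 2 "
                         "observed categories")
    chi2, p, df, expected = sps.chi2_contingency(obs.to_numpy(), correction=False)
    exp = pd.DataFrame(expected, index=obs.index, columns=obs.columns)
    n = obs.to_numpy().sum()
    row_p = obs.sum(axis=1).to_numpy()[:, None] / n
    col_p = obs.sum(axis=0).to_numpy()[None, :] / n
    resid = (obs.to_numpy() - expected) / np.sqrt(expected * (1 - row_p) * (1 - col_p))
    n_cells = obs.size
    cell_p = np.minimum(1.0, 2.0 * sps.norm.sf(np.abs(resid)) * n_cells)
    return ChiSqResult(
        chi2=float(chi2), df=int(df), p_value=float(p), observed=obs, expected=exp,
        posthoc_p=pd.DataFrame(cell_p, index=obs.index, columns=obs.columns),
        residuals=pd.DataFrame(resid, index=obs.index, columns=obs.columns),
    )


def stats_report(table: pd.DataFrame) -> dict:
    """JSON-ready bundle of the rank tests on one (pre-filtered) table."""
    kw = kruskal_wallis(table)
    dunn = dunn_bonferroni(table)
    means = {m: mean_tresca(table, m) for m in sorted(table["model"].unique())}
    return {
        "kruskal_wallis": {"H": kw.h_statistic, "df": kw.df, "p": kw.p_value},
        "dunn_bonferroni": dunn.to_dict(),
        "mean_tresca": means,
    }
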
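"""Association statistics: group comparisons, rank correlations, expression breadth.

The questions these answer: do genes under positive selection sit at
different network positions than genes without such signatures (two-group
Mann-Whitney comparisons of degree/betweenness/closeness), and could any
difference be a byproduct of confounders (Spearman correlations of degree
with expression and study-bias covariates; partial rank correlation of
the LRT statistic with degree controlling for publication count)?

Conventions: two-sided P values throughout; mid-ranks for ties; genes on
which the selection test could not be run are a third status and are
excluded from comparisons.  The Mann-Whitney P is exact (full null
enumeration) when the smaller group has <= 8 observations and the pooled
data is tie-free, otherwise the normal approximation with tie and
continuity corrections is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

TISSUE_PREFIX = "tissue_"


@dataclass
class ComparisonResult:
    """Two-group comparison of one metric (selected vs tested-unselected)."""

    metric: str
    n_selected: int
    n_other: int
    mean_selected: float
    mean_other: float
    median_selected: float
    median_other: float
    u_statistic: float
    p_value: float


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact when min(n_a, n_b) <= 8 and there are no ties across the pooled
    sample; otherwise normal approximation with tie correction and
    continuity correction.  Returns (U for the first sample, P).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Tie-aware Spearman rank correlation with t-distribution P (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired data with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("zero rank variance")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def partial_spearman(x, y, control) -> tuple[float, float]:
    """Rank-based partial correlation of x and y controlling for one variable.

    All three vectors are rank-transformed (mid-ranks); the first-order
    partial Pearson correlation on ranks is

        (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

    with P from a t distribution on n - 3 degrees of freedom.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, control))
    if not (x.size == y.size == z.size) or x.size < 4:
        raise ValueError("need triple-wise complete data with n >= 4")
    if np.unique(z).size == 1:
        raise ValueError("control variable is constant (zero rank variance)")
    rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xz = np.corrcoef(rx, rz)[0, 1]
    r_yz = np.corrcoef(ry, rz)[0, 1]
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise ValueError("degenerate control: |correlation with control| = 1")
    rho = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    n = x.size
    df = n - 3
    rho_c = min(max(rho, -0.9999999999), 0.9999999999)
    t = rho_c * np.sqrt(df / (1 - rho_c**2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(rho), float(p)


def expression_breadth(replicate_counts, min_present: int = 3, n_replicates: int = 4) -> int:
    """Number of tissues where the gene is detected in >= min_present replicates."""
    counts = np.asarray(replicate_counts, dtype=int)
    if (counts < 0).any() or (counts > n_replicates).any():
        raise ValueError(f"replicate counts must be in [0, {n_replicates}]")
    return int((counts >= min_present).sum())


def add_breadth(gene_table: pd.DataFrame, min_present: int = 3, n_replicates: int = 4) -> pd.DataFrame:
    """Compute breadth from the tissue_* replicate-count columns."""
    tissue_cols = [c for c in gene_table.columns if c.startswith(TISSUE_PREFIX)]
    if not tissue_cols:
        raise ValueError("gene table has no tissue_* columns")
    out = gene_table.copy()
    counts = out[tissue_cols].to_numpy(dtype=int)
    if (counts < 0).any() or (counts > n_replicates).any():
        raise ValueError(f"replicate counts must be in [0, {n_replicates}]")
    out["breadth"] = (counts >= min_present).sum(axis=1)
    return out


def collapse_by_max(
    table: pd.DataFrame, group_col: str, reference_col: str
) -> pd.DataFrame:
    """Keep, per group, the row maximal in the reference column.

    The probe-to-gene rule: for genes matched by several probes, keep the
    probe with the highest whole-body abundance (ties: the later row in
    input order, deterministically, via a stable sort).
    """
    idx = (
        table.sort_values(reference_col, kind="mergesort")
        .groupby(group_col, sort=False)
        .tail(1)
        .index
    )
    return table.loc[table.index.isin(idx)].reset_index(drop=True)


def breadth_selection_trend(
    gene_table: pd.DataFrame, flag_col: str = "selected", breadth_col: str = "breadth"
) -> tuple[float, float]:
    """Spearman trend of per-breadth-bin selected fractions among tested genes.

    Bins with no tested genes are skipped; fewer than 3 usable bins is an
    error.  If every bin has the same fraction the correlation is
    undefined under ties and is reported as (0.0, 1.0).
    """
    tested = gene_table[gene_table["tested"]]
    frac = tested.groupby(breadth_col)[flag_col].mean()
    if len(frac) < 3:
        raise ValueError("need at least 3 nonempty breadth bins with tested genes")
    if np.unique(frac.to_numpy()).size == 1:
        return 0.0, 1.0  # all-tied fractions: no trend measurable
    return spearman(frac.index.to_numpy(dtype=float), frac.to_numpy())


def compare_groups(
    gene_table: pd.DataFrame, metric: str, flag_col: str = "selected"
) -> ComparisonResult:
    """Mann-Whitney comparison of one metric between selected and unselected.

    Only tested genes enter; the unselected group is "tested but not
    flagged".  Raises ValueError when either group is empty.
    """
    tested = gene_table[gene_table["tested"]]
    sel = tested.loc[tested[flag_col].astype(bool), metric].to_numpy(dtype=float)
    other = tested.loc[~tested[flag_col].astype(bool), metric].to_numpy(dtype=float)
    if sel.size == 0 or other.size == 0:
        raise ValueError(f"empty group for metric {metric}: comparison skipped")
    u, p = mann_whitney(sel, other)
    return ComparisonResult(
        metric=metric,
        n_selected=int(sel.size),
        n_other=int(other.size),
        mean_selected=float(sel.mean()),
        mean_other=float(other.mean()),
        median_selected=float(np.median(sel)),
        median_other=float(np.median(other)),
        u_statistic=u,
        p_value=p,
    )


def comparison_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
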
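"""Profile similarity and sex x genotype statistics.

Metabolite profiles (vectors of levels over a fixed panel) are compared
with the cosine similarity cos(theta); group effects on single responses
are tested by two-way ANOVA (sex x genotype, Type-II sums of squares for
unbalanced designs) with Bonferroni-adjusted pairwise cell comparisons.
Summaries are reported as mean +/- sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


def cos_theta(p: Sequence[float], q: Sequence[float]) -> float:
    """Cosine similarity of two non-negative profiles over the same panel.

    1 means identical relative profiles, 0 completely different (disjoint
    support).  Scale invariant, so absolute levels do not matter.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("profiles must share the same panel ordering and length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("profile levels must be non-negative")
    np_, nq = np.linalg.norm(p), np.linalg.norm(q)
    if np_ == 0 or nq == 0:
        raise ValueError("cannot compare a zero profile")
    return float(np.clip(p @ q / (np_ * nq), 0.0, 1.0))


def similarity_matrix(profiles: Mapping[str, Sequence[float]] | pd.DataFrame) -> pd.DataFrame:
    """Symmetric cos(theta) matrix across named profiles (unit diagonal)."""
    if isinstance(profiles, pd.DataFrame):
        items = {str(c): profiles[c].to_numpy() for c in profiles.columns}
    else:
        items = {k: np.asarray(v, dtype=float) for k, v in profiles.items()}
    if len(items) < 2:
        raise ValueError("need at least two profiles")
    names = list(items)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in combinations(names, 2):
        s = cos_theta(items[a], items[b])
        mat.loc[a, b] = mat.loc[b, a] = s
    return mat


@dataclass
class AnovaResult:
    """Two-way ANOVA table plus Bonferroni-adjusted pairwise comparisons."""

    table: pd.DataFrame      # effect, sum_sq, df, F, p
    pairwise: pd.DataFrame   # group1, group2, t, p_raw, p_adj, significant
    alpha: float = ALPHA


def _check_design(df: pd.DataFrame) -> None:
    cells = df.groupby(["sex", "genotype"], observed=True).size()
    thin = cells[cells < 2]
    if not thin.empty:
        sex, gt = thin.index[0]
        raise ValueError(f"cell {sex}/{gt} has fewer than 2 samples")
    # the interaction is estimable only on a complete factor crossing
    for sex in df["sex"].unique():
        for gt in df["genotype"].unique():
            if (sex, gt) not in cells.index:
                raise ValueError(f"cell {sex}/{gt} has no samples; "
                                 "two-way design is incomplete")


def two_way_anova_bonferroni(
    data: pd.DataFrame,
    response: str = "response",
    alpha: float = ALPHA,
    log_transform: bool = False,
) -> AnovaResult:
    """Sex x genotype ANOVA with Bonferroni-corrected cell comparisons.

    ``data`` needs columns sex, genotype and the response.  Type-II sums
    of squares are used so unbalanced group sizes are handled sensibly.
    Pairwise comparisons are pooled-variance t-tests between every pair of
    sex x genotype cells, with p-values multiplied by the number of
    comparisons (capped at 1).  Optionally the response is log10
    transformed first (concentrations spanning orders of magnitude).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data[["sex", "genotype", response]].dropna().copy()
    _check_design(df)
    df["_y"] = np.log10(df[response]) if log_transform else df[response]
    # degenerate all-equal responses: F undefined (0/0); report F=0, p=1
    if np.allclose(df["_y"], df["_y"].iloc[0]):
        effects = ["C(sex)", "C(genotype)", "C(sex):C(genotype)", "Residual"]
        table = pd.DataFrame({
            "sum_sq": [0.0] * 4, "df": [np.nan] * 4,
            "F": [0.0, 0.0, 0.0, np.nan], "PR(>F)": [1.0, 1.0, 1.0, np.nan],
        }, index=effects)
    else:
        model = smf.ols("_y ~ C(sex) * C(genotype)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
    df["cell"] = df["sex"].astype(str) + "_" + df["genotype"].astype(str)
    cells = sorted(df["cell"].unique())
    pairs = list(combinations(cells, 2))
    rows = []
    for g1, g2 in pairs:
        y1 = df.loc[df["cell"] == g1, "_y"].to_numpy()
        y2 = df.loc[df["cell"] == g2, "_y"].to_numpy()
        if np.ptp(np.concatenate([y1, y2])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(y1, y2, equal_var=True)
        p_adj = min(1.0, float(p) * len(pairs))
        rows.append({
            "group1": g1, "group2": g2, "t": float(t),
            "p_raw": float(p), "p_adj": p_adj, "significant": p_adj < alpha,
        })
    return AnovaResult(table=table, pairwise=pd.DataFrame(rows), alpha=alpha)


def pairwise_bonferroni_null_rate(
    n_per_cell: int = 6,
    n_cells: int = 6,
    n_replicates: int = 10_000,
    alpha: float = ALPHA,
    seed: int = 0,
) -> float:
    """Family-wise type-I error of the pairwise Bonferroni procedure.

    Simulates ``n_replicates`` null studies (all cells drawn from one
    normal distribution), runs every pairwise pooled t-test with
    Bonferroni adjustment, and returns the fraction of studies with at
    least one false rejection.  Vectorized so large replicate counts stay
    cheap.
    """
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_replicates, n_cells, n_per_cell))
    means = data.mean(axis=2)
    var = data.var(axis=2, ddof=1)
    n = n_per_cell
    dof = 2 * n - 2
    m = n_cells * (n_cells - 1) // 2
    any_reject = np.zeros(n_replicates, dtype=bool)
    for i, j in combinations(range(n_cells), 2):
        sp2 = (var[:, i] + var[:, j]) / 2
        t = (means[:, i] - means[:, j]) / np.sqrt(sp2 * 2 / n)
        p = 2 * sps.t.sf(np.abs(t), dof)
        any_reject |= np.minimum(1.0, p * m) < alpha
    return float(any_reject.mean())


def group_summary(
    data: pd.DataFrame,
    response: str = "response",
    by: Sequence[str] = ("sex", "genotype"),
) -> pd.DataFrame:
    """Mean +/- sample SD (n-1 denominator) of a response per group."""
    g = data.groupby(list(by), observed=True)[response]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
                n="count").reset_index()
    return out


def fold_ratio(numerator: pd.Series | Sequence[float],
               denominator: pd.Series | Sequence[float]) -> float:
    """Ratio of group means, e.g. summed metabolites over parent compound."""
    num = float(np.mean(np.asarray(numerator, dtype=float)))
    den = float(np.mean(np.asarray(denominator, dtype=float)))
    if den == 0:
        return np.inf
    return num / den
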
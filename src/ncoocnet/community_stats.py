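"""Alpha diversity, Bray-Curtis ordination, PERMANOVA, Mantel tests and
diversity-environment correlation matrices."""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from ncoocnet.tabular_io import AbundanceTable, SoilMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "permanova",
    "mantel",
    "diversity_env_correlations",
]


def _chao1(counts: np.ndarray) -> float:
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def alpha_diversity(table: AbundanceTable, tree=None) -> pd.DataFrame:
    """Per-sample richness/evenness indices (+ optional Faith PD).

    observed_otus, chao1 (classic estimator, bias-corrected when no
    doubletons), shannon (natural log), gini_simpson = 1 - sum p^2,
    evenness = shannon / ln(S) (NaN for single-OTU samples), and
    faith_pd when a scikit-bio ``TreeNode`` (or newick path) is given.
    """
    counts = table.counts.to_numpy(dtype=float)
    rows = []
    for k, sample in enumerate(table.sample_ids):
        c = counts[:, k]
        total = c.sum()
        if total <= 0:
            raise ValueError(f"sample {sample!r} has zero total count")
        p = c[c > 0] / total
        s_obs = int((c > 0).sum())
        shannon = float(-(p * np.log(p)).sum())
        gini = float(1.0 - (p**2).sum())
        evenness = shannon / math.log(s_obs) if s_obs > 1 else math.nan
        rows.append({
            "observed_otus": s_obs,
            "chao1": _chao1(c),
            "shannon": shannon,
            "gini_simpson": gini,
            "evenness": evenness,
        })
    df = pd.DataFrame(rows, index=table.sample_ids)
    if tree is not None:
        df["faith_pd"] = _faith_pd(table, tree)
    return df


def _faith_pd(table: AbundanceTable, tree) -> np.ndarray:
    from skbio import TreeNode
    from skbio.diversity import alpha_diversity as skbio_alpha

    if not isinstance(tree, TreeNode):
        # keep literal underscores in tip names (newick would read them
        # as spaces by default)
        tree = TreeNode.read(str(tree), convert_underscores=False)
    tip_names = {t.name for t in tree.tips()}
    missing = [o for o in table.otu_ids if o not in tip_names]
    if missing:
        raise ValueError(f"tree is missing OTUs present in the table: {missing}")
    mat = table.counts.to_numpy(dtype=int).T  # samples x otus
    res = skbio_alpha(
        "faith_pd", mat, ids=table.sample_ids, taxa=table.otu_ids, tree=tree
    )
    return res.to_numpy()


def bray_curtis(relabund: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis distances between sample columns: d = 1 - sum min(p, q)."""
    x = relabund.to_numpy(dtype=float).T  # samples x features
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=relabund.columns, columns=relabund.columns)


def pcoa(dist: pd.DataFrame):
    """Classical metric scaling of a distance matrix.

    Returns (coordinates, eigenvalues, proportion_explained).  Axes with
    positive eigenvalues carry coordinates, ordered by eigenvalue;
    negative eigenvalues are reported as-is (no correction), and the
    proportion explained uses the sum of positive eigenvalues.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need >= 3 samples for ordination")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    b = -0.5 * d**2
    b = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-12
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    pos_sum = vals[pos].sum()
    prop = vals[pos] / pos_sum if pos_sum > 0 else vals[pos]
    ids = list(dist.index) if isinstance(dist, pd.DataFrame) else list(range(n))
    coords = pd.DataFrame(
        coords, index=ids, columns=[f"PCo{k + 1}" for k in range(coords.shape[1])]
    )
    return coords, vals, prop


def permanova(
    dist: pd.DataFrame,
    groups,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
):
    """One-way PERMANOVA on a distance matrix.

    Returns (pseudo_F, R2, p).  The p-value uses label permutation with
    the add-one correction; raw (unranked) distances are used.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    labels = np.asarray(
        groups.reindex(dist.index) if isinstance(groups, pd.Series) else groups
    )
    if len(labels) != n:
        raise ValueError("group labels must match the distance matrix")
    uniq, inv = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("need >= 2 groups")
    sizes = np.bincount(inv)
    if (sizes < 2).any():
        small = [str(uniq[k]) for k in np.flatnonzero(sizes < 2)]
        raise ValueError(f"groups with a single sample: {small}")

    d2 = d**2
    iu = np.triu_indices(n, 1)

    def _f(inv_labels: np.ndarray) -> float:
        sst = d2[iu].sum() / n
        ssw = 0.0
        for g in range(a):
            mask = inv_labels == g
            sub = d2[np.ix_(mask, mask)]
            ssw += sub[np.triu_indices(mask.sum(), 1)].sum() / mask.sum()
        ssa = sst - ssw
        return (ssa / (a - 1)) / (ssw / (n - a)), ssa / sst

    f_obs, r2 = _f(inv)
    rng = rng or np.random.default_rng()
    count = 0
    for _ in range(n_perm):
        f_perm, _ = _f(rng.permutation(inv))
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(r2), float(p)


def mantel(
    dist_a: pd.DataFrame,
    dist_b: pd.DataFrame,
    method: str = "spearman",
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    alternative: str = "greater",
):
    """Mantel test between two distance matrices over the same samples.

    r correlates the upper-triangle entries (Spearman by default); p is
    one-tailed (r_perm >= r_obs) by permuting one matrix's sample
    labels, add-one corrected.  ``alternative="two-sided"`` doubles the
    smaller tail.
    """
    if isinstance(dist_a, pd.DataFrame) and isinstance(dist_b, pd.DataFrame):
        if list(dist_a.index) != list(dist_b.index):
            if set(dist_a.index) != set(dist_b.index):
                raise ValueError("distance matrices have mismatched sample ids")
            dist_b = dist_b.loc[dist_a.index, dist_a.index]
    da = np.asarray(dist_a, dtype=float)
    db = np.asarray(dist_b, dtype=float)
    if da.shape != db.shape:
        raise ValueError("distance matrices have mismatched shapes")
    n = da.shape[0]
    iu = np.triu_indices(n, 1)

    def _corr(x, y):
        if method == "spearman":
            return stats.spearmanr(x, y).statistic
        return stats.pearsonr(x, y).statistic

    r_obs = _corr(da[iu], db[iu])
    rng = rng or np.random.default_rng()
    count_ge = 0
    count_le = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = _corr(da[iu], db[np.ix_(perm, perm)][iu])
        if r_perm >= r_obs:
            count_ge += 1
        if r_perm <= r_obs:
            count_le += 1
    if alternative == "greater":
        p = (1 + count_ge) / (1 + n_perm)
    elif alternative == "two-sided":
        p = min(1.0, 2 * min(1 + count_ge, 1 + count_le) / (1 + n_perm))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(r_obs), float(p)


def diversity_env_correlations(
    alpha: pd.DataFrame, metadata: SoilMetadata
) -> pd.DataFrame:
    """Pairwise-complete Pearson r and two-tailed p per (index, variable).

    Cells with fewer than 3 complete pairs are left missing with a
    warning.  Stars: * p < 0.05, ** p < 0.01.
    """
    meta = metadata.data
    shared = [s for s in alpha.index if s in meta.index]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    rows = []
    for idx_name in alpha.columns:
        for var in meta.columns:
            x = alpha.loc[shared, idx_name].to_numpy(dtype=float)
            y = meta.loc[shared, var].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                logger.warning(
                    "fewer than 3 complete pairs for (%s, %s)", idx_name, var
                )
                r, p = math.nan, math.nan
            elif np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                r, p = math.nan, math.nan
            else:
                res = stats.pearsonr(x[ok], y[ok])
                r, p = float(res.statistic), float(res.pvalue)
            stars = ""
            if np.isfinite(p):
                stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
            rows.append({
                "index": idx_name, "variable": var, "r": r, "p": p, "stars": stars,
            })
    return pd.DataFrame(rows)
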
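"""Significant co-occurrence / co-exclusion networks from filtered tables.

Pipeline per treatment: Spearman score matrix -> candidate pairs with
|r| >= threshold -> per-candidate permutation null (row shuffles with a
compositional renormalization step) and bootstrap distribution (column
resampling) -> unstable-edge filter -> p-value from the bootstrap
Gaussian evaluated against the permutation mean -> Brown merge (identity
for the single-measure configuration) -> Benjamini-Hochberg -> keep
edges with q <= alpha.

Metadata variables may join as extra rows; they are scored like taxa but
are never renormalized, and their nodes carry ``node_class="metadata"``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ncoocnet._rng import substream
from ncoocnet.preprocess import to_relative_abundance
from ncoocnet.tabular_io import AbundanceTable, SoilMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeTest",
    "Network",
    "NetworkConfig",
    "spearman_score_matrix",
    "candidate_edges",
    "permutation_null",
    "bootstrap_distribution",
    "reboot_pvalue",
    "is_stable",
    "merge_pvalues",
    "bh_adjust",
    "build_network",
    "build_metadata_network",
]


@dataclass
class NetworkConfig:
    """All knobs of one network run (YAML-loadable)."""

    threshold: float = 0.7
    n_permutations: int = 1000
    n_bootstraps: int = 1000
    ci: float = 0.95
    alpha: float = 0.05
    renormalize: bool = True
    exact_enumeration_max_n: int = 6
    p_method: str = "gaussian"  # or "empirical"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw[k] for k in cls.__dataclass_fields__ if k in raw}
        return cls(**known)


@dataclass
class EdgeTest:
    """Full significance record for one candidate pair."""

    pair: tuple[str, str]
    observed_score: float
    null_mean: float = math.nan
    null_sd: float = math.nan
    boot_mean: float = math.nan
    boot_sd: float = math.nan
    boot_q025: float = math.nan
    boot_q975: float = math.nan
    stable: bool = False
    p_raw: float = math.nan
    p_merged: float = math.nan
    q_bh: float = math.nan

    @property
    def sign(self) -> str:
        return "positive" if self.observed_score >= 0 else "negative"


@dataclass
class Network:
    """Significant-edge graph for one treatment."""

    label: str
    graph: nx.Graph
    edge_tests: list[EdgeTest] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


# ---------------------------------------------------------------------------
# scoring


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=-1)


def _paired_spearman(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Spearman of two equally shaped (k, n) arrays."""
    ra, rb = _rank_rows(a), _rank_rows(b)
    ra = ra - ra.mean(axis=-1, keepdims=True)
    rb = rb - rb.mean(axis=-1, keepdims=True)
    num = (ra * rb).sum(axis=-1)
    den = np.sqrt((ra**2).sum(axis=-1) * (rb**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(den > 0, out, np.nan)


def spearman_score_matrix(relabund: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Spearman matrix over rows; ties get average ranks.

    Constant rows yield NaN off-diagonal (undefined score); the diagonal
    is 1 by convention.  Requires >= 3 samples.
    """
    if relabund.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation analysis")
    x = relabund.to_numpy(dtype=float)
    ranks = _rank_rows(x)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = centered / norms[:, None]
    corr = unit @ unit.T
    corr[norms == 0, :] = np.nan
    corr[:, norms == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=relabund.index, columns=relabund.index)


def candidate_edges(scores: pd.DataFrame, threshold: float = 0.7):
    """Unordered pairs with a defined score and |r| >= threshold (inclusive)."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    ids = list(scores.index)
    vals = scores.to_numpy()
    pairs = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = vals[i, j]
            if np.isfinite(r) and abs(r) >= threshold:
                pairs.append((ids[i], ids[j]))
    return pairs


# ---------------------------------------------------------------------------
# permutation null


def _null_scores_for_perms(
    xa: np.ndarray,
    xb: np.ndarray,
    perms_a: np.ndarray,
    perms_b: np.ndarray,
    rest: np.ndarray | None,
    renorm_a: bool,
    renorm_b: bool,
) -> np.ndarray:
    """Spearman for each (perm_a, perm_b) row pair, optionally renormalized.

    ``rest`` is the per-sample relative-abundance mass of all taxa other
    than the renormalized pair members; closing the permuted rows against
    it reproduces a full-table renormalization without touching the
    other rows (their own renormalized values never enter this pair's
    score).
    """
    pa = xa[perms_a]
    pb = xb[perms_b]
    if rest is not None and (renorm_a or renorm_b):
        denom = rest[None, :] + (pa if renorm_a else 0.0) + (pb if renorm_b else 0.0)
        if renorm_a:
            pa = pa / denom
        if renorm_b:
            pb = pb / denom
    return _paired_spearman(pa, pb)


def permutation_null(
    relabund: pd.DataFrame,
    pair: tuple[str, str],
    n_iter: int = 1000,
    renormalize: bool = True,
    rng: np.random.Generator | None = None,
    metadata_rows: set | frozenset = frozenset(),
    exact: bool = False,
) -> np.ndarray:
    """Null Spearman scores for ``pair`` under independent row shuffles.

    Each iteration permutes the two member rows independently across
    samples; with ``renormalize`` every sample column is re-closed over
    all taxon rows before rescoring (rows in ``metadata_rows`` are never
    renormalized).  With ``exact`` the full n!^2 space of row-order
    pairs is enumerated instead of sampled.
    """
    if n_iter < 1 and not exact:
        raise ValueError("n_iter must be >= 1")
    a, b = pair
    x = relabund.to_numpy(dtype=float)
    idx = {name: k for k, name in enumerate(relabund.index)}
    ia, ib = idx[a], idx[b]
    xa, xb = x[ia], x[ib]
    n = x.shape[1]
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise ValueError(f"pair {pair} has a constant row; score undefined")

    a_is_meta = a in metadata_rows
    b_is_meta = b in metadata_rows
    rest = None
    if renormalize:
        taxa_mask = np.array([name not in metadata_rows for name in relabund.index])
        colsum = x[taxa_mask].sum(axis=0)
        rest = colsum - (0 if a_is_meta else xa) - (0 if b_is_meta else xb)

    if rng is None:
        rng = np.random.default_rng()

    if exact:
        all_perms = np.array(list(itertools.permutations(range(n))))
        k = len(all_perms)
        perms_a = np.repeat(np.arange(k), k)
        perms_b = np.tile(np.arange(k), k)
        return _null_scores_for_perms(
            xa, xb, all_perms[perms_a], all_perms[perms_b],
            rest, renormalize and not a_is_meta, renormalize and not b_is_meta,
        )

    perms_a = np.argsort(rng.random((n_iter, n)), axis=1)
    perms_b = np.argsort(rng.random((n_iter, n)), axis=1)
    return _null_scores_for_perms(
        xa, xb, perms_a, perms_b,
        rest, renormalize and not a_is_meta, renormalize and not b_is_meta,
    )


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_distribution(
    relabund: pd.DataFrame,
    pair: tuple[str, str],
    n_iter: int = 1000,
    rng: np.random.Generator | None = None,
    max_retries: int = 10,
) -> np.ndarray:
    """Bootstrap Spearman scores for ``pair`` by resampling sample columns.

    Resamples in which either member row becomes constant are redrawn up
    to ``max_retries`` times and then recorded as NaN; more than 50%
    NaN is an error advising a larger sample size.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if relabund.shape[1] < 3:
        raise ValueError("need >= 3 samples to bootstrap")
    a, b = pair
    xa = relabund.loc[a].to_numpy(dtype=float)
    xb = relabund.loc[b].to_numpy(dtype=float)
    n = xa.size
    if rng is None:
        rng = np.random.default_rng()

    idx = rng.integers(0, n, size=(n_iter, n))
    sa, sb = xa[idx], xb[idx]
    bad = (np.ptp(sa, axis=1) == 0) | (np.ptp(sb, axis=1) == 0)
    tries = 0
    while bad.any() and tries < max_retries:
        redraw = rng.integers(0, n, size=(int(bad.sum()), n))
        sa[bad], sb[bad] = xa[redraw], xb[redraw]
        bad = (np.ptp(sa, axis=1) == 0) | (np.ptp(sb, axis=1) == 0)
        tries += 1
    scores = _paired_spearman(sa, sb)
    scores[bad] = np.nan
    if np.isnan(scores).mean() > 0.5:
        raise ValueError(
            "bootstrap degenerate for pair %r: >50%% of resamples constant; "
            "more samples needed" % (pair,)
        )
    return scores


# ---------------------------------------------------------------------------
# p-values


def reboot_pvalue(
    null_scores: np.ndarray,
    boot_scores: np.ndarray,
    method: str = "gaussian",
) -> float:
    """Two-tailed p for the permutation mean under the bootstrap Gaussian.

    z = (mean(null) - mean(boot)) / sd(boot).  The ``empirical``
    alternative uses the two-tailed empirical tail of the bootstrap mean
    within the null distribution (add-one corrected).
    """
    null = np.asarray(null_scores, dtype=float)
    boot = np.asarray(boot_scores, dtype=float)
    null = null[np.isfinite(null)]
    boot = boot[np.isfinite(boot)]
    if null.size < 2 or boot.size < 2:
        raise ValueError("need >= 2 defined scores in both distributions")
    if method == "empirical":
        nm = null.mean()
        shift = abs(boot.mean() - nm)
        k = int((np.abs(null - nm) >= shift).sum())
        return (1 + k) / (1 + null.size)
    sd = boot.std(ddof=1)
    if sd == 0:
        return 1.0 if null.mean() == boot.mean() else 0.0
    z = (null.mean() - boot.mean()) / sd
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def is_stable(
    boot_scores: np.ndarray, null_mean: float, ci: float = 0.95
) -> bool:
    """Edge is unstable iff the null mean sits inside the central
    ``ci`` bootstrap quantile interval (inclusive bounds)."""
    boot = np.asarray(boot_scores, dtype=float)
    boot = boot[np.isfinite(boot)]
    if boot.size < 2:
        raise ValueError("need >= 2 defined bootstrap scores")
    lo, hi = np.quantile(boot, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return not (lo <= null_mean <= hi)


def merge_pvalues(
    p_list,
    method: str = "brown",
    null_scores=None,
    cov: np.ndarray | None = None,
) -> float:
    """Combine per-measure p-values (identity for a single measure).

    Brown's method scales Fisher's statistic T = -2 sum ln p by the
    empirical covariance of the per-measure -2 ln p terms; the
    covariance is estimated either from an explicit ``cov`` matrix or
    from per-measure permutation score vectors (``null_scores``, one
    vector per measure, iterations aligned).  With no dependence
    information the measures are treated as independent (Fisher).
    """
    p = [float(v) for v in p_list]
    if not p:
        raise ValueError("empty p-value list")
    if any(not (0 <= v <= 1) for v in p):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 1:
        return p[0]
    if method == "fisher":
        cov = np.zeros((len(p), len(p)))
    k = len(p)
    t = -2.0 * np.sum(np.log(np.clip(p, 1e-300, 1.0)))
    if cov is None and null_scores is not None:
        cov = _empirical_logp_cov(null_scores)
    if cov is None:
        cov = np.zeros((k, k))
    expected = 2.0 * k
    var = 4.0 * k + 2.0 * np.sum(cov[np.triu_indices(k, 1)])
    var = max(var, 1e-12)
    c = var / (2.0 * expected)
    df = 2.0 * expected**2 / var
    return float(stats.chi2.sf(t / c, df))


def _empirical_logp_cov(null_scores) -> np.ndarray:
    """Covariance of -2 ln p across measures, p from each measure's own
    empirical null CDF (two-tailed around the null mean)."""
    mats = [np.asarray(v, dtype=float) for v in null_scores]
    n = min(v.size for v in mats)
    logps = []
    for v in mats:
        v = v[:n]
        dev = np.abs(v - v.mean())
        order = stats.rankdata(dev, method="max")
        p = 1.0 - (order - 1) / n
        logps.append(-2.0 * np.log(np.clip(p, 1e-300, 1.0)))
    return np.cov(np.vstack(logps))


def bh_adjust(p_vector) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(list(p_vector), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# network assembly


def _test_candidate(
    rel: pd.DataFrame,
    pair: tuple[str, str],
    score: float,
    config: NetworkConfig,
    metadata_rows: frozenset,
) -> EdgeTest:
    n = rel.shape[1]
    exact = n <= config.exact_enumeration_max_n
    null = permutation_null(
        rel,
        pair,
        n_iter=config.n_permutations,
        renormalize=config.renormalize,
        rng=substream(config.seed, f"perm:{pair[0]}|{pair[1]}"),
        metadata_rows=metadata_rows,
        exact=exact,
    )
    boot = bootstrap_distribution(
        rel,
        pair,
        n_iter=config.n_bootstraps,
        rng=substream(config.seed, f"boot:{pair[0]}|{pair[1]}"),
    )
    finite_null = null[np.isfinite(null)]
    finite_boot = boot[np.isfinite(boot)]
    et = EdgeTest(
        pair=pair,
        observed_score=float(score),
        null_mean=float(finite_null.mean()),
        null_sd=float(finite_null.std(ddof=1)) if finite_null.size > 1 else math.nan,
        boot_mean=float(finite_boot.mean()),
        boot_sd=float(finite_boot.std(ddof=1)) if finite_boot.size > 1 else math.nan,
        boot_q025=float(np.quantile(finite_boot, 0.025)),
        boot_q975=float(np.quantile(finite_boot, 0.975)),
    )
    et.stable = is_stable(boot, et.null_mean, ci=config.ci)
    if et.stable:
        et.p_raw = reboot_pvalue(null, boot, method=config.p_method)
        et.p_merged = merge_pvalues([et.p_raw])
    return et


def _assemble(
    label: str,
    rel: pd.DataFrame,
    tests: list[EdgeTest],
    config: NetworkConfig,
    genus: dict[str, str],
    metadata_rows: frozenset,
) -> Network:
    stable = [t for t in tests if t.stable]
    if stable:
        q = bh_adjust([t.p_merged for t in stable])
        for t, qv in zip(stable, q):
            t.q_bh = float(qv)
    kept = [t for t in stable if t.q_bh <= config.alpha]
    logger.info(
        "%s: %d candidates, %d stable, %d significant (alpha=%g)",
        label, len(tests), len(stable), len(kept), config.alpha,
    )
    g = nx.Graph()
    mean_rel = rel.mean(axis=1)
    for t in kept:
        for node in t.pair:
            if node not in g:
                is_meta = node in metadata_rows
                g.add_node(
                    node,
                    genus=genus.get(node, ""),
                    node_class="metadata" if is_meta else "taxon",
                    mean_relabund=float(mean_rel.get(node, math.nan)),
                )
        g.add_edge(
            t.pair[0], t.pair[1],
            sign=t.sign, score=t.observed_score, q=t.q_bh,
        )
    return Network(label=label, graph=g, edge_tests=tests)


def build_network(
    table: AbundanceTable,
    group: str,
    config: NetworkConfig | None = None,
) -> Network:
    """Full significance pipeline on one (already filtered) treatment table."""
    config = config or NetworkConfig()
    samples = [s for s in table.sample_ids if table.group[s] == group]
    sub = table.subset(samples=samples)
    rel = to_relative_abundance(sub)
    scores = spearman_score_matrix(rel)
    cands = candidate_edges(scores, config.threshold)
    if not cands:
        logger.warning("%s: no candidate edges at |r| >= %g", group, config.threshold)
        return Network(label=group, graph=nx.Graph(), edge_tests=[])
    tests = [
        _test_candidate(rel, pair, scores.loc[pair[0], pair[1]], config, frozenset())
        for pair in cands
    ]
    genus = dict(sub.genus)
    return _assemble(group, rel, tests, config, genus, frozenset())


def build_metadata_network(
    table: AbundanceTable,
    metadata: SoilMetadata,
    group: str,
    config: NetworkConfig | None = None,
) -> Network:
    """Like :func:`build_network`, with taxon-metadata candidate pairs.

    Metadata rows join the score matrix but are excluded from the
    renormalization step; constant variables produce no candidates and
    are warned about.  Metadata-metadata pairs are not tested.
    """
    config = config or NetworkConfig()
    samples = [s for s in table.sample_ids if table.group[s] == group]
    sub = table.subset(samples=samples)
    rel = to_relative_abundance(sub)

    meta = metadata.data.reindex(samples).T  # variables x samples
    const = meta.apply(lambda r: np.ptp(r.to_numpy()) == 0, axis=1)
    for var in meta.index[const]:
        logger.warning("metadata variable %r constant in group %s; skipped", var, group)
    meta = meta.loc[~const]
    clash = set(meta.index) & set(rel.index)
    if clash:
        raise ValueError(f"metadata variable names clash with OTU ids: {sorted(clash)}")
    combined = pd.concat([rel, meta])
    metadata_rows = frozenset(meta.index)

    scores = spearman_score_matrix(combined)
    cands = [
        p for p in candidate_edges(scores, config.threshold)
        if not (p[0] in metadata_rows and p[1] in metadata_rows)
    ]
    if not cands:
        logger.warning("%s: no candidate edges at |r| >= %g", group, config.threshold)
        return Network(label=group, graph=nx.Graph(), edge_tests=[])
    tests = [
        _test_candidate(
            combined, pair, scores.loc[pair[0], pair[1]], config, metadata_rows
        )
        for pair in cands
    ]
    genus = dict(sub.genus)
    return _assemble(group, combined, tests, config, genus, metadata_rows)
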
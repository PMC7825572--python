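"""Synthetic compositional communities with known ground truth.

Latent taxon abundances are log-normal marginals coupled by a Gaussian
copula, so a planted pair's population Spearman correlation equals its
target exactly (the Spearman target is converted to a Pearson latent
correlation via the bivariate-normal identity r = 2 sin(pi * rho / 6)).
Counts are drawn multinomially per sample at a Poisson-jittered depth,
which closes each sample to its drawn total and induces the sparsity
that motivates the renormalized permutation null downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ncoocnet._rng import substream
from ncoocnet.tabular_io import AbundanceTable, SoilMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "plant_copula_correlations",
    "draw_counts",
    "generate_soil_metadata",
    "generate_dataset",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``planted_edges`` is a list of ``(i, j, target_spearman)`` taxon-index
    pairs; ``group_effects`` maps group label -> {taxon index:
    multiplicative latent shift}; ``metadata_spec`` is a list of
    ``(variable, linked_taxon or None, target_pearson, mean, sd)``.
    """

    n_taxa: int
    n_groups: int = 2
    n_replicates: int = 5
    depth: int = 10_000
    planted_edges: list[tuple[int, int, float]] = field(default_factory=list)
    group_effects: dict[str, dict[int, float]] = field(default_factory=dict)
    metadata_spec: list[tuple] = field(default_factory=list)
    meanlog: float = 0.0
    sdlog: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_groups < 1 or self.n_replicates < 1:
            raise ValueError("n_taxa, n_groups and n_replicates must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        seen = set()
        for i, j, rho in self.planted_edges:
            if i == j:
                raise ValueError(f"planted edge ({i},{j}) is a self-pair")
            if not (0 <= i < self.n_taxa and 0 <= j < self.n_taxa):
                raise ValueError(f"planted edge ({i},{j}) out of range")
            key = frozenset((i, j))
            if key in seen:
                raise ValueError(f"duplicate planted pair ({i},{j})")
            seen.add(key)
            if abs(rho) > 1:
                raise ValueError(f"target Spearman {rho} outside [-1,1]")
        for spec in self.metadata_spec:
            _, linked, rho, _, sd = spec
            if linked is not None and not (0 <= linked < self.n_taxa):
                raise ValueError(f"metadata linked taxon {linked} out of range")
            if abs(rho) > 1:
                raise ValueError(f"target Pearson {rho} outside [-1,1]")
            if sd < 0:
                raise ValueError("metadata sd must be >= 0")

    @property
    def group_labels(self) -> list[str]:
        if self.n_groups == 2:
            return ["CK", "AR"]
        return [f"G{k + 1}" for k in range(self.n_groups)]


@dataclass
class GroundTruth:
    """Planted associations and latent state behind one dataset."""

    planted_edges: list[tuple[int, int, float]]
    latent: np.ndarray  # taxa x samples, strictly positive
    group: pd.Series  # sample id -> group label

    def edge_signs(self) -> list[tuple[int, int, int]]:
        return [(i, j, 1 if rho >= 0 else -1) for i, j, rho in self.planted_edges]


def spearman_to_pearson(rho: float) -> float:
    """Latent Pearson correlation giving Spearman ``rho`` under a Gaussian copula."""
    return 2.0 * np.sin(np.pi * rho / 6.0)


def _nearest_pd(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Higham-style eigenvalue clipping to the nearest PD correlation matrix."""
    vals, vecs = np.linalg.eigh(corr)
    vals = np.clip(vals, eps, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def plant_copula_correlations(
    n_taxa: int,
    n_samples: int,
    planted_edges,
    rng: np.random.Generator,
    meanlog: float = 0.0,
    sdlog: float = 1.0,
) -> np.ndarray:
    """Draw a strictly positive latent abundance matrix (taxa x samples).

    Planted pairs attain their target population Spearman correlation;
    all other pairs are independent.  If the implied latent correlation
    matrix is not positive definite it is repaired to the nearest PD
    matrix; a repair that moves any planted correlation by more than
    0.05 is a hard error naming the offending pairs.
    """
    corr = np.eye(n_taxa)
    for i, j, rho in planted_edges:
        r = spearman_to_pearson(rho)
        corr[i, j] = corr[j, i] = r
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        fixed = _nearest_pd(corr)
        bad = [
            (i, j)
            for i, j, rho in planted_edges
            if abs(fixed[i, j] - corr[i, j]) > 0.05
        ]
        if bad:
            raise ValueError(
                f"planted correlation matrix not positive definite; repair "
                f"moved pairs {bad} beyond tolerance"
            )
        logger.warning("correlation matrix repaired to nearest PD")
        chol = np.linalg.cholesky(fixed)
    z = chol @ rng.standard_normal((n_taxa, n_samples))
    # exp is monotone, so the Gaussian copula's Spearman survives untouched
    return np.exp(meanlog + sdlog * z)


def draw_counts(
    latent: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial counts per sample at a Poisson-jittered total ~ depth."""
    latent = np.asarray(latent, dtype=float)
    if not np.isfinite(latent).all():
        raise ValueError("latent matrix contains non-finite values")
    if (latent <= 0).any():
        raise ValueError("latent matrix must be strictly positive")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    n_taxa, n_samples = latent.shape
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    for s in range(n_samples):
        total = max(1, int(rng.poisson(depth)))
        p = latent[:, s] / latent[:, s].sum()
        counts[:, s] = rng.multinomial(total, p)
    return counts


def generate_soil_metadata(
    table: AbundanceTable,
    metadata_spec,
    rng: np.random.Generator,
) -> SoilMetadata:
    """Simulate per-sample soil variables, optionally tied to a taxon.

    A variable linked to taxon ``t`` with target Pearson ``rho`` is built
    as ``rho * z_t + sqrt(1 - rho^2) * noise`` on the standardized
    relative abundance of ``t``, then rescaled to the requested mean/sd.
    ``sd == 0`` produces a constant column, flagged in
    ``constant_flags`` since its correlations are undefined.
    """
    rel = table.counts.to_numpy(dtype=float)
    totals = rel.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("cannot link metadata to taxa with zero-depth samples")
    rel = rel / totals
    n_samples = rel.shape[1]
    cols: dict[str, np.ndarray] = {}
    constant_flags: dict[str, bool] = {}
    for name, linked, rho, mean, sd in metadata_spec:
        if abs(rho) > 1:
            raise ValueError(f"|target_pearson| > 1 for {name!r}")
        if sd == 0:
            cols[name] = np.full(n_samples, float(mean))
            constant_flags[name] = True
            logger.warning("metadata variable %r is constant (sd=0)", name)
            continue
        noise = rng.standard_normal(n_samples)
        if linked is None or rho == 0:
            raw = noise
        else:
            x = rel[linked]
            xs = x.std()
            if xs == 0:
                logger.warning(
                    "linked taxon %d has constant abundance; %r left unlinked",
                    linked, name,
                )
                raw = noise
            else:
                zx = (x - x.mean()) / xs
                raw = rho * zx + np.sqrt(1.0 - rho**2) * noise
        rs = raw.std()
        raw = (raw - raw.mean()) / (rs if rs > 0 else 1.0)
        cols[name] = mean + sd * raw
        constant_flags[name] = False
    df = pd.DataFrame(cols, index=table.sample_ids)
    return SoilMetadata(data=df, constant_flags=constant_flags)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[AbundanceTable, SoilMetadata, GroundTruth]:
    """Generate (AbundanceTable, SoilMetadata, GroundTruth) from a spec.

    Deterministic: the same spec (including seed) yields bit-identical
    outputs.  Samples are labeled ``<group>_<replicate>``.
    """
    n_samples = spec.n_groups * spec.n_replicates
    labels = spec.group_labels
    sample_ids = [
        f"{g}_{r + 1}" for g in labels for r in range(spec.n_replicates)
    ]
    group = pd.Series(
        [g for g in labels for _ in range(spec.n_replicates)], index=sample_ids
    )

    latent = plant_copula_correlations(
        spec.n_taxa,
        n_samples,
        spec.planted_edges,
        substream(spec.seed, "latent"),
        meanlog=spec.meanlog,
        sdlog=spec.sdlog,
    )
    for g_label, effects in spec.group_effects.items():
        mask = (group == g_label).to_numpy()
        for taxon, factor in effects.items():
            latent[taxon, mask] *= factor

    counts = draw_counts(latent, spec.depth, substream(spec.seed, "counts"))
    otu_ids = [f"OTU_{i + 1}" for i in range(spec.n_taxa)]
    taxonomy = pd.Series(
        [f"Bacteria;Genus_{i + 1}" for i in range(spec.n_taxa)], index=otu_ids
    )
    table = AbundanceTable(
        counts=pd.DataFrame(counts, index=otu_ids, columns=sample_ids),
        taxonomy=taxonomy,
        group=group,
    )
    metadata = generate_soil_metadata(
        table, spec.metadata_spec, substream(spec.seed, "metadata")
    )
    truth = GroundTruth(
        planted_edges=list(spec.planted_edges), latent=latent, group=group
    )
    return table, metadata, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Planted edges as a tab-delimited (taxon_i, taxon_j, target_spearman) list."""
    pd.DataFrame(
        truth.planted_edges, columns=["taxon_i", "taxon_j", "target_spearman"]
    ).to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> list[tuple[int, int, float]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (int(i), int(j), float(r))
        for i, j, r in df[["taxon_i", "taxon_j", "target_spearman"]].itertuples(
            index=False
        )
    ]
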
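"""End-to-end orchestration of the per-treatment analysis."""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import networkx
import numpy
import pandas as pd
import scipy
import yaml

from ncoocnet import __version__
from ncoocnet._rng import substream
from ncoocnet.community_stats import (
    alpha_diversity,
    bray_curtis,
    diversity_env_correlations,
    mantel,
    pcoa,
    permanova,
)
from ncoocnet.cooccurrence import (
    NetworkConfig,
    build_metadata_network,
    build_network,
)
from ncoocnet.preprocess import filter_otus, to_relative_abundance
from ncoocnet.tabular_io import (
    AbundanceTable,
    SoilMetadata,
    write_network,
    write_reports,
)
from ncoocnet.topology import (
    KEYSTONE_PRESETS,
    KeystoneCriteria,
    keystone_taxa,
    size_gate,
    topology_report,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_network_analysis", "run_community_analysis"]


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    out_dir: Path
    groups: list[str] | None = None
    network: NetworkConfig = field(default_factory=NetworkConfig)
    keystone_preset: str | None = None
    keystone_criteria: KeystoneCriteria | None = None
    min_sum_relabund: float = 1e-4
    min_nodes: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, out_dir) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        net_keys = set(NetworkConfig.__dataclass_fields__)
        net = NetworkConfig(**{k: v for k, v in raw.items() if k in net_keys})
        cfg = cls(out_dir=Path(out_dir), network=net)
        for k in ("groups", "keystone_preset", "min_sum_relabund", "min_nodes", "seed"):
            if k in raw:
                setattr(cfg, k, raw[k])
        if "seed" in raw:
            cfg.network.seed = raw["seed"]
        return cfg

    def resolve_criteria(self) -> KeystoneCriteria:
        if self.keystone_criteria is not None:
            return self.keystone_criteria
        if self.keystone_preset is not None:
            return KEYSTONE_PRESETS[self.keystone_preset]
        return KEYSTONE_PRESETS["nirS"]


def _manifest(config: RunConfig, extra: dict) -> dict:
    return {
        "tool": "ncoocnet",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "networkx": networkx.__version__,
        "seed": config.seed,
        "network_config": dataclasses.asdict(config.network),
        **extra,
    }


def run_network_analysis(
    table: AbundanceTable,
    config: RunConfig,
    metadata: SoilMetadata | None = None,
) -> dict:
    """filter -> build network -> size gate -> topology -> keystones -> write.

    A failure in one group is logged and that group skipped; other
    groups still run.  Returns {group: {...}} plus writes GraphML,
    edge lists, a combined topology report and a run manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = config.groups or table.groups()
    criteria = config.resolve_criteria()

    results: dict = {}
    topo_reports: dict = {}
    keystones: dict = {}
    exclusions: dict = {}
    for group in groups:
        try:
            filtered = filter_otus(table, group, config.min_sum_relabund)
            if metadata is not None:
                net = build_metadata_network(filtered, metadata, group, config.network)
            else:
                net = build_network(filtered, group, config.network)
            write_network(net, out / f"network_{group}.graphml", "graphml")
            write_network(net, out / f"network_{group}.tsv", "tsv")
            entry = {"network": net, "excluded": False}
            if size_gate(net, config.min_nodes):
                rep = topology_report(net)
                keys = keystone_taxa(net, criteria)
                topo_reports[group] = rep
                keystones[group] = keys
                entry.update(topology=rep, keystones=keys)
            else:
                entry["excluded"] = True
                exclusions[group] = (
                    f"network has {net.n_nodes} nodes (< {config.min_nodes}); "
                    "topology and keystone analysis skipped"
                )
            results[group] = entry
        except Exception:
            logger.exception("group %s failed; continuing", group)
            exclusions[group] = "stage error (see log)"
    write_reports(topo_reports, keystones, {}, out)
    manifest = _manifest(config, {"stage": "network", "exclusions": exclusions})
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return results


def run_community_analysis(
    table: AbundanceTable,
    config: RunConfig,
    metadata: SoilMetadata | None = None,
    tree=None,
) -> dict:
    """Alpha diversity, Bray-Curtis, PCoA, PERMANOVA, Mantel, Pearson matrix."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    alpha = alpha_diversity(table, tree=tree)
    rel = to_relative_abundance(table)
    dist = bray_curtis(rel)
    coords, eigvals, prop = pcoa(dist)
    f_stat, r2, p_perm = permanova(
        dist, table.group, rng=substream(config.seed, "permanova")
    )

    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    dist.to_csv(out / "bray_curtis.tsv", sep="\t")
    coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    pd.DataFrame(
        [{"pseudo_F": f_stat, "R2": r2, "p": p_perm}]
    ).to_csv(out / "permanova.tsv", sep="\t", index=False)

    result = {
        "alpha": alpha,
        "bray_curtis": dist,
        "pcoa": (coords, eigvals, prop),
        "permanova": (f_stat, r2, p_perm),
    }

    if metadata is not None:
        mantel_rows = []
        for var in metadata.variables:
            vals = metadata.data[var].reindex(table.sample_ids).to_numpy(dtype=float)
            if not numpy.isfinite(vals).all() or numpy.std(vals) == 0:
                logger.warning("Mantel skipped for %r (constant or missing)", var)
                continue
            env_d = numpy.abs(vals[:, None] - vals[None, :])
            env_df = pd.DataFrame(env_d, index=table.sample_ids, columns=table.sample_ids)
            r, p = mantel(
                dist, env_df, rng=substream(config.seed, f"mantel:{var}")
            )
            mantel_rows.append({"variable": var, "mantel_r": r, "p": p})
        pd.DataFrame(mantel_rows).to_csv(out / "mantel.tsv", sep="\t", index=False)
        corr = diversity_env_correlations(alpha, metadata)
        corr.to_csv(out / "diversity_env_correlations.tsv", sep="\t", index=False)
        result["mantel"] = mantel_rows
        result["diversity_env"] = corr
    else:
        logger.warning("no metadata supplied; Mantel/correlation stages skipped")

    manifest = _manifest(config, {"stage": "community"})
    (out / "community_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
    return result
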
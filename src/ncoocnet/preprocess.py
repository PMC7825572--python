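"""Per-treatment OTU retention filters and relative-abundance closure.

An OTU is retained for a treatment iff it has a nonzero count in every
replicate of that treatment AND the sum over the treatment's samples of
its per-sample relative abundances exceeds a threshold (default 1e-4,
i.e. 0.01%).  Filtering is applied per treatment on that treatment's
samples only, since networks are built one per treatment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ncoocnet.tabular_io import AbundanceTable

logger = logging.getLogger(__name__)

__all__ = ["to_relative_abundance", "filter_otus"]


def to_relative_abundance(table: AbundanceTable) -> pd.DataFrame:
    """Close each sample column to 1 by dividing by its total count."""
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        bad = [table.sample_ids[k] for k in zero]
        raise ValueError(f"zero-depth samples: {bad}")
    rel = counts / totals
    return pd.DataFrame(rel, index=table.counts.index, columns=table.counts.columns)


def filter_otus(
    table: AbundanceTable,
    group: str,
    min_sum_relabund: float = 1e-4,
    mode: str = "sum",
) -> AbundanceTable:
    """Restrict to one treatment's samples and apply the retention rules.

    Parameters
    ----------
    mode : {"sum", "mean"}
        Whether the abundance rule compares the sum (default) or the
        mean of per-sample proportions against ``min_sum_relabund``
        (strict inequality either way).
    """
    if group not in set(table.group):
        raise ValueError(f"unknown group {group!r}; have {sorted(set(table.group))}")
    samples = [s for s in table.sample_ids if table.group[s] == group]
    if len(samples) < 2:
        raise ValueError(f"group {group!r} has < 2 samples")
    sub = table.subset(samples=samples)
    rel = to_relative_abundance(sub).to_numpy()
    counts = sub.counts.to_numpy()

    present_everywhere = (counts > 0).all(axis=1)
    stat = rel.sum(axis=1) if mode == "sum" else rel.mean(axis=1)
    if mode not in ("sum", "mean"):
        raise ValueError(f"unknown filter mode {mode!r}")
    abundant = stat > min_sum_relabund
    keep = present_everywhere & abundant

    kept_ids = [otu for otu, k in zip(sub.otu_ids, keep) if k]
    logger.info(
        "group %s: retained %d/%d OTUs (presence fail %d, abundance fail %d)",
        group, len(kept_ids), len(sub.otu_ids),
        int((~present_everywhere).sum()), int((present_everywhere & ~abundant).sum()),
    )
    if not kept_ids:
        logger.warning("group %s: filter removed all OTUs", group)
    return sub.subset(otus=kept_ids)
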
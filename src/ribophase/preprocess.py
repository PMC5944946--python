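"""Filtering and normalization of OTU count tables.

The canonical order, applied per molecule dataset, is: drop dataset-wide
singletons (OTUs with exactly one read in the whole table, most likely
sequencing artefacts), drop metazoan OTUs (the survey targets microbial
eukaryotes), rarefy every library to a common depth without replacement,
then convert to relative read abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import OtuTable, TaxonomyMap, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RelAbundanceTable:
    """Per-sample relative read abundances (each row sums to 1)."""

    values: pd.DataFrame
    dates: pd.Series | None = None
    molecule: pd.Series | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.values.columns)


def remove_dataset_singletons(table: OtuTable) -> OtuTable:
    """Drop OTUs whose total count across all samples is exactly 1."""
    totals = table.counts.sum(axis=0)
    keep = totals != 1
    dropped = int((~keep).sum())
    if dropped:
        logger.info("removed %d dataset singletons", dropped)
    out = table.counts.loc[:, keep]
    if out.shape[1] == 0:
        logger.warning("all OTUs were dataset singletons; table is empty")
    return table.with_counts(out)


def remove_metazoa(table: OtuTable, tax: TaxonomyMap) -> OtuTable:
    """Drop OTU columns flagged as metazoan in the taxonomy."""
    missing = [o for o in table.otu_ids if o not in tax]
    if missing:
        raise ValidationError(f"OTUs absent from taxonomy: {missing}")
    flags = tax.table.loc[table.otu_ids, "is_metazoa"].to_numpy(dtype=bool)
    dropped = int(flags.sum())
    if dropped:
        logger.info("removed %d metazoan OTUs", dropped)
    return table.with_counts(table.counts.loc[:, ~flags])


def rarefy(
    table: OtuTable,
    depth: int | None = None,
    seed: int | None = None,
    drop_shallow: bool = False,
) -> OtuTable:
    """Subsample every library to ``depth`` reads without replacement.

    ``depth=None`` uses the minimum library total. Sampling is a
    multivariate hypergeometric draw per sample, deterministic given
    ``seed``. Samples shallower than ``depth`` raise unless
    ``drop_shallow`` removes them (logged).
    """
    totals = table.row_totals()
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    shallow = totals.index[totals < depth].tolist()
    counts = table.counts
    if shallow:
        if not drop_shallow:
            raise ValueError(
                f"samples shallower than depth {depth}: {shallow} (use drop_shallow)"
            )
        logger.warning("dropping %d samples shallower than %d", len(shallow), depth)
        counts = counts.drop(index=shallow)
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts.to_numpy())
    for i, row in enumerate(counts.to_numpy()):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    rarefied = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return table.with_counts(rarefied)


def relative_abundance(table: OtuTable) -> RelAbundanceTable:
    """Divide each sample's counts by its total reads."""
    totals = table.row_totals()
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"samples with zero total reads: {zero}")
    values = table.counts.div(totals, axis=0)
    return RelAbundanceTable(values, table.dates, table.molecule)
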
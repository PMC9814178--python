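"""MGS quantification: marker-mean abundances, cell-count correction,
taxonomic aggregation and richness.

The relative abundance of an MGS in a sample is the mean frequency of its
declared marker genes (zeros included); if strictly fewer than 10% of the
markers are seen (frequency > 0) the abundance is set to zero. Multiplying
relative abundances by a per-sample cell-count index (cell count divided by
the mean over measured samples, missing imputed to one) yields absolute
abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import RANKS, MgsDefinitionSet
from .errors import DataError

__all__ = [
    "MgsAbundanceMatrix",
    "mgs_relative_abundance",
    "cell_count_index",
    "to_absolute_abundance",
    "aggregate_taxa",
    "mgs_richness",
    "DETECTION_FRACTION",
]

logger = logging.getLogger(__name__)

#: Minimum fraction of marker genes that must be seen; strictly below -> 0.
DETECTION_FRACTION = 0.10


@dataclass
class MgsAbundanceMatrix:
    """MGS x sample abundances with an explicit scale tag."""

    values: pd.DataFrame
    scale: str = "relative"

    def __post_init__(self) -> None:
        if self.scale not in ("relative", "absolute"):
            raise DataError(f"unknown scale tag {self.scale!r}")
        if (self.values.to_numpy() < 0).any():
            raise DataError("abundances must be non-negative")

    @property
    def mgs_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def mgs_relative_abundance(freq: pd.DataFrame, defs: MgsDefinitionSet) -> MgsAbundanceMatrix:
    """Mean marker frequency per MGS with the <10%-seen zeroing rule.

    'Seen' means strictly positive frequency; the 10% bound is strict, so a
    sample with exactly 10% of markers seen keeps its mean abundance.
    """
    rows = {}
    for mgs_id in defs.mgs_ids:
        markers = defs.markers[mgs_id]
        if not markers:
            raise DataError(f"{mgs_id} declares zero marker genes")
        missing = set(markers) - set(freq.index)
        if missing:
            raise DataError(
                f"{mgs_id}: marker genes absent from frequency matrix: {sorted(missing)[:3]}"
            )
        sub = freq.loc[markers].to_numpy(dtype=float)
        mean = sub.mean(axis=0)
        seen = (sub > 0).sum(axis=0)
        mean[seen < DETECTION_FRACTION * len(markers)] = 0.0
        rows[mgs_id] = mean
    values = pd.DataFrame.from_dict(rows, orient="index", columns=freq.columns)
    return MgsAbundanceMatrix(values=values, scale="relative")


def cell_count_index(cells: pd.Series) -> pd.Series:
    """Cell count divided by the mean over measured samples; missing -> 1.

    The mean is taken over measured samples only. Imputed samples are
    logged.
    """
    measured = cells.dropna()
    if measured.empty:
        raise DataError("no measured cell counts")
    if (measured <= 0).any():
        bad = measured.index[measured <= 0][0]
        raise DataError(f"non-positive cell count for sample {bad!r}")
    index = cells / measured.mean()
    imputed = cells.index[cells.isna()]
    if len(imputed):
        logger.info("cell_count_index: imputing 1 for %d sample(s): %s",
                    len(imputed), ", ".join(map(str, imputed)))
    return index.fillna(1.0)


def to_absolute_abundance(rel: MgsAbundanceMatrix, index: pd.Series) -> MgsAbundanceMatrix:
    """Multiply relative abundances by the per-sample cell-count index."""
    if rel.scale != "relative":
        raise DataError("input already on the absolute scale (double correction)")
    missing = rel.sample_ids.difference(index.index)
    if len(missing):
        raise DataError(f"cell-count index missing for samples: {list(missing[:3])}")
    scaled = rel.values * index.reindex(rel.sample_ids)
    return MgsAbundanceMatrix(values=scaled, scale="absolute")


def aggregate_taxa(
    ab: MgsAbundanceMatrix, defs: MgsDefinitionSet, ranks: tuple[str, ...] = RANKS
) -> dict[str, MgsAbundanceMatrix]:
    """Sum member-MGS abundances per taxon at each requested rank.

    MGS unclassified at a rank fall into an ``unclassified_<parent>`` bin,
    where the parent is the nearest classified higher rank. The scale tag is
    propagated unchanged.
    """
    taxonomy = defs.taxonomy.reindex(ab.mgs_ids)
    out: dict[str, MgsAbundanceMatrix] = {}
    for rank in ranks:
        if rank not in taxonomy.columns:
            raise DataError(f"taxonomy lacks rank {rank!r}")
        labels = []
        rank_pos = list(RANKS).index(rank)
        for mgs_id in ab.mgs_ids:
            name = taxonomy.at[mgs_id, rank]
            if pd.isna(name) or str(name).lower().startswith("unclassified"):
                parent = "root"
                for higher in reversed(RANKS[:rank_pos]):
                    cand = taxonomy.at[mgs_id, higher]
                    if not (pd.isna(cand) or str(cand).lower().startswith("unclassified")):
                        parent = str(cand)
                        break
                name = f"unclassified_{parent}"
            labels.append(str(name))
        summed = ab.values.groupby(pd.Index(labels, name=rank), sort=True).sum()
        out[rank] = MgsAbundanceMatrix(values=summed, scale=ab.scale)
    return out


def mgs_richness(ab: MgsAbundanceMatrix) -> pd.Series:
    """Number of MGS with strictly positive abundance, per sample.

    Positivity is invariant under the (strictly positive) cell-count index,
    so relative and absolute inputs agree.
    """
    return (ab.values > 0).sum(axis=0).astype(int)
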
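"""Read-to-gene attribution, depth downsizing and frequency normalization.

The gene count table is produced in three steps: reads mapping a single
gene ("unique" reads) are tallied directly; reads mapping several genes at
equal best score ("shared" reads) are split across their candidates
proportionally to the candidates' unique counts in the same sample; the
resulting (fractional) count table is downsized to a fixed number of
mapped reads per sample and turned into a length-normalized frequency
matrix whose columns sum to one.

Notes on two points the attribution rule leaves open, both fixed here and
covered by tests: a shared read whose candidates all have zero unique
counts is split equally, and downsizing draws read-equivalents without
replacement after a largest-remainder integerization of fractional mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import GeneCatalog
from .errors import DataError

__all__ = [
    "ReadMappingTable",
    "attribute_reads",
    "downsize_counts",
    "to_frequency_matrix",
    "gene_richness",
]

logger = logging.getLogger(__name__)


@dataclass
class SampleMappings:
    """Mapping records of one sample, unique reads aggregated to counts."""

    unique: dict[str, int] = field(default_factory=dict)
    shared: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return int(sum(self.unique.values())) + len(self.shared)


class ReadMappingTable:
    """Per-sample read-mapping records.

    Each record is the set of candidate genes a read hit at equal best
    score. Unique records (one candidate) are stored aggregated as counts;
    shared records (two or more candidates) are kept individually.
    """

    def __init__(self) -> None:
        self._samples: dict[str, SampleMappings] = {}

    @property
    def sample_ids(self) -> list[str]:
        return list(self._samples)

    def __getitem__(self, sample: str) -> SampleMappings:
        return self._samples[sample]

    def __contains__(self, sample: str) -> bool:
        return sample in self._samples

    def __len__(self) -> int:
        return len(self._samples)

    def add_unique(self, sample: str, gene_id: str, count: int = 1) -> None:
        sm = self._samples.setdefault(sample, SampleMappings())
        sm.unique[gene_id] = sm.unique.get(gene_id, 0) + int(count)

    def add_shared(self, sample: str, genes: tuple[str, ...]) -> None:
        if len(genes) < 2:
            raise DataError("shared record needs >= 2 candidate genes")
        self._samples.setdefault(sample, SampleMappings()).shared.append(tuple(genes))

    def add_record(self, sample: str, genes) -> None:
        genes = tuple(genes)
        if not genes:
            raise DataError("empty mapping record")
        if len(genes) == 1:
            self.add_unique(sample, genes[0])
        else:
            self.add_shared(sample, genes)

    @classmethod
    def from_records(cls, records) -> "ReadMappingTable":
        """Build from an iterable of ``(sample_id, candidate_genes)`` pairs."""
        table = cls()
        for sample, genes in records:
            table.add_record(sample, genes)
        return table

    def n_records(self, sample: str) -> int:
        return self._samples[sample].n_records


def attribute_reads(mappings: ReadMappingTable, catalog: GeneCatalog) -> pd.DataFrame:
    """Attribute unique and shared reads to genes.

    Unique records add one read to their gene. A shared record distributes
    unit mass over its candidates proportionally to the candidates' unique
    counts in the same sample; when every candidate has zero unique counts
    the mass is split equally. Column sums equal the per-sample record
    counts exactly.

    Returns a gene x sample DataFrame over the full catalogue gene index.
    """
    gene_index = catalog.gene_ids
    pos = {g: i for i, g in enumerate(gene_index)}
    samples = mappings.sample_ids
    out = np.zeros((len(gene_index), len(samples)))

    for j, sample in enumerate(samples):
        sm = mappings[sample]
        col = out[:, j]
        unique = np.zeros(len(gene_index))
        for gene, cnt in sm.unique.items():
            i = pos.get(gene)
            if i is None:
                raise DataError(f"record references unknown gene {gene!r}")
            unique[i] = cnt
        col += unique

        pairs: list[tuple[int, int]] = []
        for rec in sm.shared:
            try:
                idx = [pos[g] for g in rec]
            except KeyError as exc:
                raise DataError(f"record references unknown gene {exc.args[0]!r}") from None
            if len(idx) == 2:
                pairs.append((idx[0], idx[1]))
            else:
                w = unique[idx]
                total = w.sum()
                share = w / total if total > 0 else np.full(len(idx), 1.0 / len(idx))
                np.add.at(col, idx, share)
        if pairs:
            a = np.fromiter((p[0] for p in pairs), dtype=np.intp, count=len(pairs))
            b = np.fromiter((p[1] for p in pairs), dtype=np.intp, count=len(pairs))
            ua, ub = unique[a], unique[b]
            tot = ua + ub
            wa = np.where(tot > 0, np.divide(ua, np.where(tot > 0, tot, 1.0)), 0.5)
            np.add.at(col, a, wa)
            np.add.at(col, b, 1.0 - wa)

    return pd.DataFrame(out, index=gene_index, columns=samples)


def _integerize_column(col: np.ndarray) -> np.ndarray:
    """Largest-remainder rounding preserving the (rounded) column total."""
    floors = np.floor(col).astype(np.int64)
    remainder = int(np.rint(col.sum())) - int(floors.sum())
    if remainder > 0:
        frac = col - floors
        top = np.argsort(-frac, kind="stable")[:remainder]
        floors[top] += 1
    return floors


def downsize_counts(
    counts: pd.DataFrame, depth: int, seed: int = 0, drop_short: bool = True
) -> pd.DataFrame:
    """Rarefy every column to exactly ``depth`` read-equivalents.

    Fractional attributed counts are integerized by largest-remainder
    rounding, then ``depth`` reads are drawn without replacement
    (multivariate hypergeometric). Samples with fewer than ``depth`` mapped
    reads are dropped and logged; if all samples fall short this is an
    error.
    """
    if depth < 1:
        raise DataError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    kept: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for sample in counts.columns:
        col = counts[sample].to_numpy(dtype=float)
        pool = _integerize_column(col)
        total = int(pool.sum())
        if total < depth:
            if not drop_short:
                raise DataError(f"sample {sample!r} has {total} < depth {depth} reads")
            dropped.append(sample)
            continue
        if total == depth:
            kept[sample] = pool.astype(float)
        else:
            kept[sample] = rng.multivariate_hypergeometric(pool, depth).astype(float)
    if dropped:
        logger.warning("downsize: dropped %d sample(s) below depth %d: %s",
                       len(dropped), depth, ", ".join(dropped))
    if not kept:
        raise DataError(f"all samples have fewer than {depth} mapped reads")
    return pd.DataFrame(kept, index=counts.index)


def to_frequency_matrix(counts: pd.DataFrame, catalog: GeneCatalog) -> pd.DataFrame:
    """Length-normalize counts and rescale each column to sum to one.

    f(g, s) = (c(g, s) / L(g)) / sum_g' (c(g', s) / L(g')). Absolute scale
    constants of FPKM cancel in the normalization and are omitted. Zero
    columns stay zero and are logged.
    """
    missing = counts.index.difference(catalog.gene_ids)
    if len(missing):
        raise DataError(f"genes without catalogue length: {list(missing[:3])}")
    lengths = catalog.lengths.reindex(counts.index).to_numpy(dtype=float)
    per_length = counts.to_numpy(dtype=float) / lengths[:, None]
    colsum = per_length.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        logger.warning("frequency: %d all-zero column(s): %s",
                       int(zero.sum()), ", ".join(counts.columns[zero]))
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(zero[None, :], 0.0, per_length / np.where(zero, 1.0, colsum)[None, :])
    return pd.DataFrame(freq, index=counts.index, columns=counts.columns)


def gene_richness(freq: pd.DataFrame) -> pd.Series:
    """Number of genes with strictly positive abundance, per sample."""
    return (freq > 0).sum(axis=0).astype(int)
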
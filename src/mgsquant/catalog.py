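"""Gene catalogue, MGS definitions and functional-module definitions.

A gene catalogue maps every gene to its length, the metagenomic species
(MGS) it belongs to, marker/core flags and functional-component annotations.
MGS definitions regroup the same information per species (marker, core and
accessory gene sets plus a seven-rank taxonomy); module definitions list,
per module, an ordered set of components where each component is satisfied
by any one of its alternative annotation ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["GeneCatalog", "MgsDefinitionSet", "Module", "ModuleCatalog", "RANKS"]

#: Fixed taxonomy ranks, highest first.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class GeneCatalog:
    """Per-gene annotations backed by a DataFrame indexed by gene id.

    Columns: ``length`` (nt, int), ``mgs_id`` (str), ``is_marker`` (bool),
    ``is_core`` (bool), ``components`` (frozenset of annotation ids).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"length", "mgs_id", "is_marker", "is_core", "components"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataError(f"catalogue missing columns: {sorted(missing)}")
        if (self.table["length"] <= 0).any():
            bad = self.table.index[self.table["length"] <= 0][0]
            raise DataError(f"gene {bad!r} has non-positive length")
        if (self.table["is_marker"] & ~self.table["is_core"]).any():
            bad = self.table.index[self.table["is_marker"] & ~self.table["is_core"]][0]
            raise DataError(f"gene {bad!r} is marker but not core")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def lengths(self) -> pd.Series:
        return self.table["length"]

    @property
    def n_genes(self) -> int:
        return len(self.table)

    def genes_of_mgs(self, mgs_id: str) -> pd.Index:
        return self.table.index[self.table["mgs_id"] == mgs_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.table.index


@dataclass
class MgsDefinitionSet:
    """Marker/core/accessory gene sets and taxonomy per MGS.

    ``taxonomy`` is indexed by MGS id with the seven :data:`RANKS` columns;
    unclassified levels hold the string ``"unclassified"``.
    """

    markers: dict[str, list[str]]
    core: dict[str, list[str]]
    accessory: dict[str, list[str]]
    taxonomy: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        for mgs_id in self.markers:
            marker_set = set(self.markers[mgs_id])
            core_set = set(self.core.get(mgs_id, ()))
            acc_set = set(self.accessory.get(mgs_id, ()))
            if not marker_set <= core_set | acc_set:
                raise DataError(f"{mgs_id}: markers not a subset of MGS genes")
            overlap = core_set & acc_set
            if overlap:
                raise DataError(f"{mgs_id}: core/accessory overlap: {sorted(overlap)[:3]}")

    @property
    def mgs_ids(self) -> list[str]:
        return list(self.markers)

    def genes_of(self, mgs_id: str) -> list[str]:
        return list(self.core.get(mgs_id, [])) + list(self.accessory.get(mgs_id, []))

    @classmethod
    def from_catalog(cls, catalog: GeneCatalog, taxonomy: pd.DataFrame | None = None) -> "MgsDefinitionSet":
        """Derive definitions from a catalogue's per-gene flags."""
        markers: dict[str, list[str]] = {}
        core: dict[str, list[str]] = {}
        accessory: dict[str, list[str]] = {}
        tbl = catalog.table
        for mgs_id, sub in tbl.groupby("mgs_id", sort=True):
            markers[str(mgs_id)] = list(sub.index[sub["is_marker"]])
            core[str(mgs_id)] = list(sub.index[sub["is_core"]])
            accessory[str(mgs_id)] = list(sub.index[~sub["is_core"]])
        if taxonomy is None:
            taxonomy = pd.DataFrame(
                "unclassified", index=sorted(markers), columns=list(RANKS)
            )
        return cls(markers=markers, core=core, accessory=accessory, taxonomy=taxonomy)


@dataclass(frozen=True)
class Module:
    """One functional module: an ordered list of components, each an
    alternative-set of annotation ids (any alternative satisfies it)."""

    module_id: str
    name: str
    components: tuple[frozenset[str], ...]
    database: str = "GMM"

    def __post_init__(self) -> None:
        if not self.components:
            raise DataError(f"module {self.module_id!r} has no components")
        if any(not c for c in self.components):
            raise DataError(f"module {self.module_id!r} has an empty component")

    @property
    def n_components(self) -> int:
        return len(self.components)


class ModuleCatalog:
    """Ordered collection of :class:`Module` keyed by module id."""

    def __init__(self, modules: list[Module] | None = None) -> None:
        self._modules: dict[str, Module] = {}
        for mod in modules or []:
            self.add(mod)

    def add(self, module: Module) -> None:
        if module.module_id in self._modules:
            raise DataError(f"duplicate module id {module.module_id!r}")
        self._modules[module.module_id] = module

    def __getitem__(self, module_id: str) -> Module:
        return self._modules[module_id]

    def __iter__(self):
        return iter(self._modules.values())

    def __len__(self) -> int:
        return len(self._modules)

    def __contains__(self, module_id: str) -> bool:
        return module_id in self._modules

    @property
    def module_ids(self) -> list[str]:
        return list(self._modules)
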
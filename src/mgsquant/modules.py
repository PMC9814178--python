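"""Functional-module presence per MGS and module potentials per sample.

A module is considered present in an MGS when at least 90% of its
components are covered by annotations of the MGS's core genes (a component
counts as covered when any of its alternative ids is present). That call is
then refined sample by sample by adding the MGS's accessory genes detected
in the sample, and the per-sample potential of a module is the summed
abundance of the MGS carrying it in that sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import GeneCatalog, Module, ModuleCatalog, MgsDefinitionSet
from .errors import DataError
from .quantify import MgsAbundanceMatrix, mgs_relative_abundance

__all__ = [
    "COVERAGE_THRESHOLD",
    "ModulePresence",
    "module_core_presence",
    "refine_presence_per_sample",
    "module_potential",
]

#: Fraction of components that must be covered; inclusive bound.
COVERAGE_THRESHOLD = 0.90


@dataclass
class ModulePresence:
    """Core-level and sample-refined module presence.

    ``core`` is an MGS x module boolean frame; ``per_sample`` maps each
    module id to an MGS x sample boolean frame. An MGS not detected in a
    sample is recorded absent there regardless of gene content.
    """

    core: pd.DataFrame
    per_sample: dict[str, pd.DataFrame]

    @property
    def module_ids(self) -> list[str]:
        return list(self.core.columns)


def _annotation_sets(catalog: GeneCatalog, gene_ids) -> set[str]:
    out: set[str] = set()
    comp = catalog.table["components"]
    for g in gene_ids:
        out |= set(comp[g])
    return out


def _covered_components(annotations: set[str], module: Module) -> np.ndarray:
    return np.array([bool(comp & annotations) for comp in module.components])


def module_core_presence(
    defs: MgsDefinitionSet, catalog: GeneCatalog, modules: ModuleCatalog
) -> pd.DataFrame:
    """MGS x module boolean frame of the core-gene 90% coverage rule."""
    mgs_ids = defs.mgs_ids
    data = np.zeros((len(mgs_ids), len(modules)), dtype=bool)
    for i, mgs_id in enumerate(mgs_ids):
        ann = _annotation_sets(catalog, defs.core.get(mgs_id, ()))
        for j, module in enumerate(modules):
            covered = _covered_components(ann, module).sum()
            data[i, j] = covered >= COVERAGE_THRESHOLD * module.n_components
    return pd.DataFrame(data, index=pd.Index(mgs_ids, name="mgs_id"),
                        columns=pd.Index(modules.module_ids, name="module_id"))


def refine_presence_per_sample(
    core_flags: pd.DataFrame,
    freq: pd.DataFrame,
    defs: MgsDefinitionSet,
    catalog: GeneCatalog,
    modules: ModuleCatalog,
    abundance: MgsAbundanceMatrix | None = None,
) -> ModulePresence:
    """Re-evaluate coverage per sample with detected accessory genes added.

    For sample ``s`` the component coverage of module ``M`` in MGS ``m`` is
    recomputed over the core genes plus the accessory genes of ``m`` with
    positive frequency in ``s``. Detection of the MGS itself (marker rule)
    gates the flag: undetected MGS are recorded absent. ``abundance`` may be
    passed to reuse an existing quantification; otherwise it is computed
    from ``freq``.
    """
    if abundance is None:
        abundance = mgs_relative_abundance(freq, defs)
    detected = abundance.values > 0
    samples = freq.columns
    mgs_ids = list(core_flags.index)

    per_sample: dict[str, pd.DataFrame] = {
        mid: pd.DataFrame(False, index=core_flags.index, columns=samples)
        for mid in core_flags.columns
    }
    freq_pos = freq > 0

    for mgs_id in mgs_ids:
        core_ann = _annotation_sets(catalog, defs.core.get(mgs_id, ()))
        accessory = [g for g in defs.accessory.get(mgs_id, ()) if g in freq.index]
        det_row = detected.loc[mgs_id].to_numpy()
        for module in modules:
            mid = module.module_id
            flags = per_sample[mid]
            if core_flags.at[mgs_id, mid]:
                # adding genes cannot remove coverage: present wherever detected
                flags.loc[mgs_id] = det_row
                continue
            core_cov = _covered_components(core_ann, module)
            n_needed = COVERAGE_THRESHOLD * module.n_components
            open_components = [c for c, cov in zip(module.components, core_cov) if not cov]
            # accessory genes that could close each open component
            closers = []
            for comp in open_components:
                genes = [g for g in accessory if set(catalog.table.at[g, "components"]) & comp]
                closers.append(genes)
            if not any(closers):
                continue
            base = int(core_cov.sum())
            closed = np.zeros(len(samples), dtype=int)
            for genes in closers:
                if genes:
                    closed += freq_pos.loc[genes].to_numpy().any(axis=0)
            flags.loc[mgs_id] = det_row & ((base + closed) >= n_needed)
    return ModulePresence(core=core_flags, per_sample=per_sample)


def module_potential(presence: ModulePresence, ab: MgsAbundanceMatrix) -> pd.DataFrame:
    """Module x sample matrix: summed abundance of carrier MGS per sample."""
    for mid, flags in presence.per_sample.items():
        if not flags.index.equals(ab.mgs_ids) or not flags.columns.equals(ab.sample_ids):
            raise DataError(f"presence/abundance index mismatch for module {mid!r}")
    rows = {
        mid: (ab.values.to_numpy() * flags.to_numpy()).sum(axis=0)
        for mid, flags in presence.per_sample.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=ab.sample_ids).rename_axis("module_id")
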
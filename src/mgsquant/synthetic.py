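"""Synthetic miniature cohorts for end-to-end testing of the pipeline.

Generates a small gene catalogue with MGS pangenome structure (markers are
core; genes carry functional-component annotations arranged so that module
carriage is known by construction), a case-control cohort with planted
differential species, a planted BMI-style confounder and a configurable
case/control total-cell-load ratio, plus multinomial read-mapping records
whose sampling probabilities follow gene length times MGS abundance.

The study the pipeline mirrors does not publish its cohort's abundance
distributions; the log-normal defaults here are free choices documented as
such, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .catalog import RANKS, GeneCatalog, MgsDefinitionSet, Module, ModuleCatalog
from .errors import ConfigurationError, DataError
from .modules import COVERAGE_THRESHOLD
from .profiling import ReadMappingTable

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_catalog",
    "generate_cohort",
    "simulate_read_mappings",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator. One seed drives every stage."""

    n_mgs: int = 20
    genes_per_mgs: int = 250
    n_markers_per_mgs: int = 100
    core_fraction: float = 0.6
    n_modules: int = 8
    components_per_module: int = 4
    n_cases: int = 20
    n_controls: int = 20
    n_da_mgs: int = 3
    effect_log2fc: float = 1.0
    load_ratio: float = 1.0
    confounder_strength: float = 0.0
    read_depth: int = 10_000
    shared_read_fraction: float = 0.1
    seed: int = 0
    # secondary knobs
    n_confounded_mgs: int = 0
    within_mgs_shared: float = 0.5
    missing_cellcount_fraction: float = 0.05
    load_mode: str = "uniform"  # "uniform" | "drivers"
    n_load_drivers: int = 2
    module_carriage_prob: float = 0.5
    accessory_module_fraction: float = 0.0
    n_cytokines: int = 6
    cytokine_corr: float = 0.5
    baseline_sigma: float = 1.5
    noise_sigma: float = 0.5

    def __post_init__(self) -> None:
        counts = {
            "n_mgs": self.n_mgs, "genes_per_mgs": self.genes_per_mgs,
            "n_markers_per_mgs": self.n_markers_per_mgs, "n_modules": self.n_modules,
            "components_per_module": self.components_per_module,
            "n_cases": self.n_cases, "n_controls": self.n_controls,
            "read_depth": self.read_depth,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {value}")
        if not 0 < self.core_fraction <= 1:
            raise ConfigurationError("core_fraction must lie in (0, 1]")
        for name in ("shared_read_fraction", "within_mgs_shared",
                     "missing_cellcount_fraction", "module_carriage_prob",
                     "accessory_module_fraction"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.shared_read_fraction >= 1:
            raise ConfigurationError("shared_read_fraction must be < 1")
        if self.n_da_mgs < 0 or self.n_da_mgs > self.n_mgs:
            raise ConfigurationError("n_da_mgs must lie in [0, n_mgs]")
        if self.n_confounded_mgs < 0 or self.n_da_mgs + self.n_confounded_mgs > self.n_mgs:
            raise ConfigurationError("n_da_mgs + n_confounded_mgs exceeds n_mgs")
        if self.load_ratio <= 0:
            raise ConfigurationError("load_ratio must be > 0")
        if self.load_mode not in ("uniform", "drivers"):
            raise ConfigurationError("load_mode must be 'uniform' or 'drivers'")
        n_core = int(round(self.genes_per_mgs * self.core_fraction))
        if self.n_markers_per_mgs > n_core:
            raise ConfigurationError(
                f"n_markers_per_mgs={self.n_markers_per_mgs} exceeds the "
                f"{n_core} core genes implied by genes_per_mgs * core_fraction"
            )


@dataclass
class GroundTruth:
    """Planted truth of a synthetic cohort."""

    true_absolute: pd.DataFrame
    da_mgs_ids: list[str]
    confounded_mgs_ids: list[str]
    module_carriage: pd.DataFrame = field(default_factory=pd.DataFrame)
    load_driver_ids: list[str] = field(default_factory=list)


def _mgs_id(i: int) -> str:
    return f"mgs{i:03d}"


def _component_id(module: int, component: int, alt: int = 0) -> str:
    suffix = "" if alt == 0 else f"_alt{alt}"
    return f"K{module:03d}{component:02d}{suffix}"


def generate_catalog(cfg: SyntheticConfig) -> tuple[GeneCatalog, MgsDefinitionSet, ModuleCatalog]:
    """Build the gene catalogue, MGS definitions and module definitions.

    Marker genes are the first ``n_markers_per_mgs`` core genes of each MGS.
    Module carriage is planted: a carrying MGS gets every component of the
    module annotated onto distinct genes (core genes, unless
    ``accessory_module_fraction`` moves some onto accessory genes); a
    non-carrying MGS gets only half the components, safely below the 90%
    coverage rule. Carriage is therefore recoverable from the catalogue.
    """
    rng = stage_rng(cfg.seed, "catalog")
    n_core = int(round(cfg.genes_per_mgs * cfg.core_fraction))

    modules = ModuleCatalog()
    for m in range(cfg.n_modules):
        components = []
        for c in range(cfg.components_per_module):
            alts = {_component_id(m, c)}
            if c == 0:
                alts.add(_component_id(m, c, alt=1))  # exercise alternative ids
            components.append(frozenset(alts))
        modules.add(Module(module_id=f"MOD{m:03d}", name=f"synthetic module {m}",
                           components=tuple(components), database="GMM"))

    carriage = rng.random((cfg.n_mgs, cfg.n_modules)) < cfg.module_carriage_prob
    # guarantee at least one carrier and one non-carrier per module when possible
    for m in range(cfg.n_modules):
        if cfg.n_mgs >= 2:
            carriage[m % cfg.n_mgs, m] = True
            carriage[(m + 1) % cfg.n_mgs, m] = False

    records = []
    taxonomy_rows = {}
    for i in range(cfg.n_mgs):
        mgs = _mgs_id(i)
        lengths = rng.integers(300, 3001, size=cfg.genes_per_mgs)
        annotations: list[set[str]] = [set() for _ in range(cfg.genes_per_mgs)]
        for m in range(cfg.n_modules):
            k = cfg.components_per_module
            n_assign = k if carriage[i, m] else k // 2
            for c in range(n_assign):
                if carriage[i, m] and rng.random() < cfg.accessory_module_fraction:
                    g = int(rng.integers(n_core, cfg.genes_per_mgs))
                else:
                    g = int(rng.integers(0, n_core))
                annotations[g].add(_component_id(m, c))
        for j in range(cfg.genes_per_mgs):
            records.append({
                "gene_id": f"{mgs}_g{j:04d}",
                "length": int(lengths[j]),
                "mgs_id": mgs,
                "is_marker": j < cfg.n_markers_per_mgs,
                "is_core": j < n_core,
                "components": frozenset(annotations[j]),
            })
        taxonomy_rows[mgs] = {
            "kingdom": "Bacteria",
            "phylum": f"phylum{i // 8:02d}",
            "class": f"class{i // 6:02d}",
            "order": f"order{i // 4:02d}",
            "family": f"family{i // 3:02d}",
            "genus": f"genus{i // 2:02d}",
            "species": f"species{i:03d}" if i % 5 else "unclassified",
        }

    table = pd.DataFrame.from_records(records).set_index("gene_id")
    catalog = GeneCatalog(table=table)
    taxonomy = pd.DataFrame.from_dict(taxonomy_rows, orient="index")[list(RANKS)]
    defs = MgsDefinitionSet.from_catalog(catalog, taxonomy=taxonomy)
    return catalog, defs, modules


def derive_module_carriage(
    catalog: GeneCatalog, defs: MgsDefinitionSet, modules: ModuleCatalog
) -> pd.DataFrame:
    """Carriage truth implied by the catalogue: coverage over ALL genes of
    the MGS (core and accessory) against the 90% rule."""
    comp = catalog.table["components"]
    data = {}
    for mgs_id in defs.mgs_ids:
        ann: set[str] = set()
        for g in defs.genes_of(mgs_id):
            ann |= set(comp[g])
        data[mgs_id] = [
            sum(bool(c & ann) for c in mod.components) >= COVERAGE_THRESHOLD * mod.n_components
            for mod in modules
        ]
    return pd.DataFrame.from_dict(data, orient="index", columns=modules.module_ids)


def generate_cohort(
    cfg: SyntheticConfig,
    catalog: GeneCatalog,
    defs: MgsDefinitionSet | None = None,
    modules: ModuleCatalog | None = None,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Draw metadata, cell counts and true absolute abundances.

    Plants: ``n_da_mgs`` species with a status effect of ``effect_log2fc``
    on the absolute scale; ``n_confounded_mgs`` species whose abundance is
    driven by BMI while BMI itself is shifted in cases by
    ``confounder_strength`` (so their status association is spurious); a
    case/control total-load ratio of ``load_ratio`` (uniform over species,
    or concentrated on ``n_load_drivers`` high-abundance species in
    ``load_mode='drivers'``); and a cytokine block correlated with the
    planted species block at ``cytokine_corr``.
    """
    if defs is None:
        defs = MgsDefinitionSet.from_catalog(catalog)
    rng = stage_rng(cfg.seed, "cohort")
    mgs_ids = defs.mgs_ids
    n = cfg.n_cases + cfg.n_controls
    samples = [f"S{i:04d}" for i in range(n)]
    is_case = np.array([True] * cfg.n_cases + [False] * cfg.n_controls)

    age = np.clip(rng.normal(36, 8.4, n), 18, 60).round(1)
    sex = np.where(rng.random(n) < 0.66, "F", "M")
    bmi = rng.normal(23.0, 3.0, n) + cfg.confounder_strength * is_case
    bmi = np.clip(bmi, 16, 45).round(1)
    smoking = rng.choice(["never", "previous", "current"], size=n, p=[0.45, 0.35, 0.2])
    fecal_water = np.clip(rng.normal(70, 10, n), 40, 95).round(1)
    treatment = np.where(
        is_case,
        rng.choice(["naive", "first_line", "second_line"], size=n, p=[0.36, 0.23, 0.41]),
        "none",
    )
    relapses = np.where(is_case, rng.poisson(0.8, n), 0)
    activity = np.where(~is_case, "", np.where(relapses >= 1, "CA", "CNA"))

    metadata = pd.DataFrame({
        "status": np.where(is_case, "MS", "HC"),
        "age": age, "sex": sex, "bmi": bmi, "smoking": smoking,
        "fecal_water": fecal_water, "treatment": treatment,
        "relapses": relapses, "activity": activity,
    }, index=pd.Index(samples, name="sample_id"))

    # planted feature sets
    special = rng.choice(cfg.n_mgs, size=cfg.n_da_mgs + cfg.n_confounded_mgs, replace=False)
    da_idx = special[:cfg.n_da_mgs]
    conf_idx = special[cfg.n_da_mgs:]
    da_ids = [mgs_ids[i] for i in da_idx]
    conf_ids = [mgs_ids[i] for i in conf_idx]

    baseline = rng.normal(0.0, cfg.baseline_sigma, cfg.n_mgs)
    log_ab = baseline[:, None] + rng.normal(0.0, cfg.noise_sigma, (cfg.n_mgs, n))
    log_ab[da_idx[:, None], np.flatnonzero(is_case)[None, :]] += (
        cfg.effect_log2fc * np.log(2.0)
    )
    if len(conf_idx):
        bmi_z = (bmi - 23.0) / 3.0
        log_ab[conf_idx[:, None], np.arange(n)[None, :]] += (
            cfg.confounder_strength * bmi_z[None, :] * np.log(2.0)
        )
    true_absolute = np.exp(log_ab)

    driver_ids: list[str] = []
    if cfg.load_ratio != 1.0:
        if cfg.load_mode == "uniform":
            true_absolute[:, is_case] *= cfg.load_ratio
        else:
            # scale a few abundant non-planted species so the expected total
            # load ratio matches load_ratio
            candidates = [i for i in np.argsort(-baseline) if i not in set(special)]
            drivers = candidates[: cfg.n_load_drivers]
            driver_ids = [mgs_ids[i] for i in drivers]
            totals = true_absolute.sum(axis=0)
            driver_mass = true_absolute[drivers, :].sum(axis=0)
            extra = (cfg.load_ratio - 1.0) * totals
            factor = 1.0 + extra / driver_mass
            for d in drivers:
                true_absolute[d, is_case] *= factor[is_case].mean()

    true_df = pd.DataFrame(true_absolute, index=pd.Index(mgs_ids, name="mgs_id"),
                           columns=samples)

    totals = true_df.sum(axis=0).to_numpy()
    cells = totals / totals.mean() * 2e10 * np.exp(rng.normal(0, 0.05, n))
    n_missing = int(round(cfg.missing_cellcount_fraction * n))
    cell_series = pd.Series(cells, index=samples, name="cells_per_gram")
    if n_missing >= n:
        n_missing = n - 1
    if n_missing:
        missing_at = rng.choice(n, size=n_missing, replace=False)
        cell_series.iloc[missing_at] = np.nan

    # cytokine block correlated with the planted-species block
    n_block = min(3, cfg.n_cytokines, cfg.n_mgs)
    block_targets = da_ids[:n_block] if len(da_ids) >= n_block else mgs_ids[:n_block]
    for k in range(cfg.n_cytokines):
        noise = rng.normal(0, 1, n)
        if k < n_block and cfg.cytokine_corr > 0:
            target = np.log(true_df.loc[block_targets[k]].to_numpy())
            z = (target - target.mean()) / (target.std() or 1.0)
            r = cfg.cytokine_corr
            signal = r * z + np.sqrt(max(0.0, 1 - r * r)) * noise
        else:
            signal = noise
        metadata[f"cytokine_{k:02d}"] = np.round(np.exp(signal), 5)

    carriage = (
        derive_module_carriage(catalog, defs, modules) if modules is not None else pd.DataFrame()
    )
    truth = GroundTruth(
        true_absolute=true_df, da_mgs_ids=da_ids, confounded_mgs_ids=conf_ids,
        module_carriage=carriage, load_driver_ids=driver_ids,
    )
    return metadata, cell_series, truth


def simulate_read_mappings(
    true_absolute: pd.DataFrame, catalog: GeneCatalog, cfg: SyntheticConfig
) -> ReadMappingTable:
    """Multinomial read records per sample.

    Each sample gets exactly ``read_depth`` records; a fraction
    ``shared_read_fraction`` of them list two candidate genes (the partner
    drawn from the same MGS with probability ``within_mgs_shared``, else
    from the whole catalogue), the rest exactly one. Source genes are drawn
    with probability proportional to gene length times the abundance of the
    gene's MGS. No base-level errors are modelled.
    """
    if true_absolute.empty:
        raise DataError("empty abundance matrix")
    rng = stage_rng(cfg.seed, "reads")
    gene_ids = np.asarray(catalog.gene_ids)
    lengths = catalog.lengths.to_numpy(dtype=float)
    gene_mgs = catalog.table["mgs_id"].to_numpy()
    mgs_index = {m: i for i, m in enumerate(true_absolute.index)}
    gene_mgs_idx = np.array([mgs_index[m] for m in gene_mgs])
    # genes of each MGS, for within-MGS partner draws
    mgs_gene_lists = {
        i: np.flatnonzero(gene_mgs_idx == i) for i in range(len(true_absolute.index))
    }

    n_shared = int(round(cfg.read_depth * cfg.shared_read_fraction))
    n_unique = cfg.read_depth - n_shared
    table = ReadMappingTable()

    for sample in true_absolute.columns:
        ab = true_absolute[sample].to_numpy(dtype=float)
        weights = lengths * ab[gene_mgs_idx]
        total = weights.sum()
        if total <= 0:
            raise DataError(f"sample {sample!r} has zero total gene mass")
        p = weights / total

        counts = rng.multinomial(n_unique, p)
        for g in np.flatnonzero(counts):
            table.add_unique(sample, gene_ids[g], int(counts[g]))

        if n_shared:
            primary = np.repeat(np.arange(len(p)), rng.multinomial(n_shared, p))
            rng.shuffle(primary)
            within = rng.random(n_shared) < cfg.within_mgs_shared
            partners = np.empty(n_shared, dtype=np.intp)
            n_cross = int((~within).sum())
            if n_cross:
                cross = rng.choice(len(p), size=n_cross, p=p)
                clash = cross == primary[~within]
                cross[clash] = (cross[clash] + 1) % len(p)
                partners[~within] = cross
            for r in np.flatnonzero(within):
                g1 = primary[r]
                pool = mgs_gene_lists[gene_mgs_idx[g1]]
                if pool.size > 1:
                    g2 = int(pool[rng.integers(pool.size)])
                    if g2 == g1:
                        g2 = int(pool[(np.searchsorted(pool, g1) + 1) % pool.size])
                else:
                    g2 = (g1 + 1) % len(p)
                partners[r] = g2
            for g1, g2 in zip(primary, partners):
                table.add_shared(sample, (gene_ids[g1], gene_ids[g2]))

    return table
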
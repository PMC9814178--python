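"""End-to-end orchestration: case/control contrast and disease-activity
analyses over the full quantification chain, with a run manifest.

``quantify_all`` runs read attribution, downsizing, frequency
normalization, MGS quantification with cell-count correction, taxonomic
aggregation and module potentials. ``run_case_control`` adds rank
contrasts with deconfounding, beta/alpha diversity and cytokine
correlation panels; ``run_activity_analysis`` restricts to treatment-naive
cases and contrasts clinically active (>= 1 relapse during follow-up)
against non-active cases, including covariate-adjusted richness versus
relapse counts.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import GeneCatalog, MgsDefinitionSet, ModuleCatalog
from .deconfound import deconfound_features
from .ecology import alpha_diversity, bray_curtis_log10, pairwise_permanova, pcoa, permanova
from .errors import DataError
from .io import write_abundance_tsv, write_matrix_tsv
from .modules import module_core_presence, module_potential, refine_presence_per_sample
from .profiling import ReadMappingTable, attribute_reads, downsize_counts, gene_richness, to_frequency_matrix
from .quantify import (
    MgsAbundanceMatrix, aggregate_taxa, cell_count_index, mgs_relative_abundance,
    mgs_richness, to_absolute_abundance,
)
from .stats import adjust_richness, contrast_table, spearman_panel

__all__ = ["AnalysisParams", "PipelineInputs", "Quantification",
           "quantify_all", "run_case_control", "run_activity_analysis"]

DEFAULT_COVARIATES = ("age", "sex", "bmi", "smoking", "fecal_water", "treatment")
ACTIVITY_COVARIATES = ("age", "sex", "bmi", "smoking", "fecal_water")


@dataclass
class AnalysisParams:
    """Knobs shared by the orchestrated analyses."""

    depth: int = 10_000
    pseudocount: float | None = None
    q_threshold: float = 0.1
    n_permutations: int = 999
    seed: int = 0
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    status_col: str = "status"
    # which deconfounding labels count as robust hits
    deconfound_scope: tuple[str, ...] = ("strictly deconfounded", "ambiguously deconfounded")

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise DataError("q_threshold must lie in (0, 1)")


@dataclass
class PipelineInputs:
    """Either raw mapping records or a pre-attributed gene count table."""

    catalog: GeneCatalog
    defs: MgsDefinitionSet
    modules: ModuleCatalog
    metadata: pd.DataFrame
    cells: pd.Series
    mappings: ReadMappingTable | None = None
    gene_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.mappings is None and self.gene_counts is None:
            raise DataError("need mapping records or a gene count table")


@dataclass
class Quantification:
    """All per-stage matrices of one quantification run."""

    gene_counts: pd.DataFrame
    frequencies: pd.DataFrame
    relative: MgsAbundanceMatrix
    absolute: MgsAbundanceMatrix
    potentials: pd.DataFrame
    taxa: dict[str, MgsAbundanceMatrix]
    gene_richness: pd.Series
    mgs_richness: pd.Series
    manifest: dict = field(default_factory=dict)


def _stage(manifest: dict, name: str, **info) -> None:
    manifest.setdefault("stages", {})[name] = info


def quantify_all(inputs: PipelineInputs, params: AnalysisParams) -> Quantification:
    """Run the gene-to-module quantification chain and record a manifest."""
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": params.seed,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(params).items()},
        "warnings": [],
    }
    try:
        counts = (inputs.gene_counts if inputs.gene_counts is not None
                  else attribute_reads(inputs.mappings, inputs.catalog))
        _stage(manifest, "attribution", genes=counts.shape[0], samples=counts.shape[1])
        downsized = downsize_counts(counts, params.depth, seed=params.seed)
        dropped = sorted(set(counts.columns) - set(downsized.columns))
        if dropped:
            manifest["warnings"].append(f"downsize dropped samples: {dropped}")
        _stage(manifest, "downsize", depth=params.depth, samples=downsized.shape[1])
        freq = to_frequency_matrix(downsized, inputs.catalog)
        rel = mgs_relative_abundance(freq, inputs.defs)
        index = cell_count_index(inputs.cells.reindex(freq.columns))
        absolute = to_absolute_abundance(rel, index)
        _stage(manifest, "quantify", mgs=rel.values.shape[0], samples=rel.values.shape[1])
        core_flags = module_core_presence(inputs.defs, inputs.catalog, inputs.modules)
        presence = refine_presence_per_sample(
            core_flags, freq, inputs.defs, inputs.catalog, inputs.modules, abundance=rel
        )
        potentials = module_potential(presence, absolute)
        _stage(manifest, "modules", modules=potentials.shape[0])
        taxa = aggregate_taxa(absolute, inputs.defs)
    except Exception as exc:
        raise DataError(f"quantification failed: {exc}") from exc
    return Quantification(
        gene_counts=downsized, frequencies=freq, relative=rel, absolute=absolute,
        potentials=potentials, taxa=taxa,
        gene_richness=gene_richness(freq), mgs_richness=mgs_richness(absolute),
        manifest=manifest,
    )


def _robust_hits(contrasts: pd.DataFrame, labels: pd.DataFrame, params: AnalysisParams) -> pd.DataFrame:
    merged = contrasts.join(labels[["label", "implicated_covariates"]], how="left")
    merged["robust"] = merged["significant"] & merged["label"].isin(params.deconfound_scope)
    return merged


def run_case_control(
    inputs: PipelineInputs, params: AnalysisParams, outdir: str | Path | None = None,
    quant: Quantification | None = None,
) -> dict:
    """Full case/control report bundle.

    Emits contrast tables with deconfounding labels (MGS, genus-level taxa,
    modules), ordination, overall and treatment-subgroup pairwise
    PERMANOVA, alpha diversity, richness and a cytokine correlation panel.
    """
    if quant is None:
        quant = quantify_all(inputs, params)
    meta = inputs.metadata.reindex(quant.absolute.sample_ids)
    status = meta[params.status_col]
    if status.nunique() < 2:
        raise DataError("status column has a single level")

    covs = [c for c in params.covariates if c in meta.columns]
    mgs_contrasts = contrast_table(quant.absolute.values, status, params.q_threshold)
    mgs_labels = deconfound_features(
        quant.absolute.values, meta, params.status_col, covs, params.q_threshold
    )
    mgs_table = _robust_hits(mgs_contrasts, mgs_labels, params)

    genus = quant.taxa["genus"].values
    genus_table = contrast_table(genus, status, params.q_threshold)
    module_table = contrast_table(quant.potentials, status, params.q_threshold)

    dist = bray_curtis_log10(quant.absolute, pseudocount=params.pseudocount)
    coords, eigvals = pcoa(dist, k=2)
    overall = permanova(dist, status, n_perm=params.n_permutations, seed=params.seed)
    subgroup = np.where(meta["status"] == "HC", "HC", meta.get("treatment", status))
    pairwise = pairwise_permanova(dist, subgroup, n_perm=params.n_permutations, seed=params.seed)

    alpha = alpha_diversity(quant.absolute.values)
    alpha["gene_richness"] = quant.gene_richness.reindex(alpha.index)

    cyto_cols = [c for c in meta.columns if c.startswith("cytokine_")]
    hits = mgs_table.index[mgs_table["significant"]]
    panel = None
    if len(hits) and cyto_cols:
        panel = spearman_panel(quant.absolute.values.loc[hits], meta[cyto_cols],
                               q_threshold=params.q_threshold)

    manifest = dict(quant.manifest)
    manifest["analysis"] = "case_control"
    manifest["q_threshold"] = params.q_threshold
    manifest["fdr_family"] = "one family per feature space (MGS / taxa / modules)"
    bundle = {
        "quantification": quant,
        "mgs_contrasts": mgs_table,
        "genus_contrasts": genus_table,
        "module_contrasts": module_table,
        "distance": dist,
        "pcoa": coords,
        "pcoa_eigenvalues": eigvals,
        "permanova": overall,
        "pairwise_permanova": pairwise,
        "alpha_diversity": alpha,
        "cytokine_panel": panel,
        "manifest": manifest,
    }
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def run_activity_analysis(
    inputs: PipelineInputs, params: AnalysisParams, outdir: str | Path | None = None,
    quant: Quantification | None = None, treatment_naive_only: bool = True,
) -> dict:
    """Disease-activity report bundle on (by default) treatment-naive cases.

    Covariate-adjusted species richness is correlated with relapse counts;
    CA (>= 1 relapse) vs CNA contrasts are run for species and modules with
    deconfounding over the activity covariate set.
    """
    if quant is None:
        quant = quantify_all(inputs, params)
    meta = inputs.metadata.reindex(quant.absolute.sample_ids)
    cases = meta[meta[params.status_col] != "HC"]
    if treatment_naive_only and "treatment" in meta.columns:
        cases = cases[cases["treatment"] == "naive"]
    if "relapses" not in cases.columns:
        raise DataError("metadata lacks a 'relapses' column")
    relapses = cases["relapses"].astype(float)
    activity = np.where(relapses >= 1, "CA", "CNA")
    n_ca, n_cna = int((activity == "CA").sum()), int((activity == "CNA").sum())
    if min(n_ca, n_cna) < 4:
        raise DataError(f"activity subset too small: CA={n_ca}, CNA={n_cna}")
    if relapses.nunique() < 2:
        raise DataError("relapse counts are constant; correlation undefined")

    covs = [c for c in ACTIVITY_COVARIATES if c in cases.columns]
    richness = quant.mgs_richness.reindex(cases.index)
    adjusted = adjust_richness(richness, cases[covs])
    from scipy.stats import spearmanr

    rho, p = spearmanr(adjusted, relapses.reindex(adjusted.index))

    sub_ab = quant.absolute.values[cases.index]
    activity_series = pd.Series(activity, index=cases.index)
    mgs_contrasts = contrast_table(sub_ab, activity_series, params.q_threshold)
    act_meta = cases.copy()
    act_meta["activity"] = activity_series
    mgs_labels = deconfound_features(sub_ab, act_meta, "activity", covs, params.q_threshold)
    mgs_table = _robust_hits(mgs_contrasts, mgs_labels, params)
    module_table = contrast_table(quant.potentials[cases.index], activity_series,
                                  params.q_threshold)

    cyto_cols = [c for c in cases.columns if c.startswith("cytokine_")]
    hits = mgs_table.index[mgs_table["p"] <= 0.05]
    panel = None
    if len(hits) and cyto_cols:
        panel = spearman_panel(sub_ab.loc[hits], cases[cyto_cols],
                               q_threshold=params.q_threshold)

    manifest = dict(quant.manifest)
    manifest["analysis"] = "activity"
    manifest["q_threshold"] = params.q_threshold
    bundle = {
        "quantification": quant,
        "adjusted_richness": adjusted,
        "richness_relapse_rho": float(rho),
        "richness_relapse_p": float(p),
        "activity": activity_series,
        "mgs_contrasts": mgs_table,
        "module_contrasts": module_table,
        "cytokine_panel": panel,
        "manifest": manifest,
    }
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    quant: Quantification = bundle["quantification"]
    write_abundance_tsv(quant.relative, outdir / "mgs_relative.tsv")
    write_abundance_tsv(quant.absolute, outdir / "mgs_absolute.tsv")
    write_matrix_tsv(quant.potentials, outdir / "module_potentials.tsv")
    for key in ("mgs_contrasts", "genus_contrasts", "module_contrasts",
                "alpha_diversity", "pairwise_permanova", "cytokine_panel"):
        obj = bundle.get(key)
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(outdir / f"{key}.tsv", sep="\t")
    if "distance" in bundle:
        bundle["distance"].to_csv(outdir / "bray_curtis.tsv", sep="\t")
    if "pcoa" in bundle:
        bundle["pcoa"].to_csv(outdir / "pcoa.tsv", sep="\t")
    if "adjusted_richness" in bundle:
        bundle["adjusted_richness"].to_csv(outdir / "adjusted_richness.tsv", sep="\t")
    manifest = dict(bundle["manifest"])
    if "permanova" in bundle:
        manifest["permanova"] = asdict(bundle["permanova"])
    if "richness_relapse_rho" in bundle:
        manifest["richness_relapse"] = {
            "rho": bundle["richness_relapse_rho"], "p": bundle["richness_relapse_p"],
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
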
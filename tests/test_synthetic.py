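import io

import numpy as np
import pandas as pd
import pytest

from mgsquant.errors import ConfigurationError, DataError
from mgsquant.io import write_catalog_tsv
from mgsquant.synthetic import (
    GroundTruth, SyntheticConfig, generate_catalog, generate_cohort, simulate_read_mappings,
)


class TestConfig:
    def test_counts_forced_by_construction(self):
        cfg = SyntheticConfig(n_mgs=5, genes_per_mgs=200, core_fraction=0.5,
                              n_markers_per_mgs=100)
        catalog, defs, modules = generate_catalog(cfg)
        assert catalog.n_genes == 1000
        assert catalog.table["is_marker"].sum() == 5 * 100
        assert catalog.table["is_core"].sum() == 5 * 100
        for mgs_id in defs.mgs_ids:
            assert len(defs.markers[mgs_id]) == 100
            assert set(defs.markers[mgs_id]) <= set(defs.core[mgs_id])

    def test_markers_exceeding_core_is_config_error(self):
        with pytest.raises(ConfigurationError, match="core"):
            SyntheticConfig(genes_per_mgs=200, core_fraction=0.5, n_markers_per_mgs=150)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(core_fraction=0.0)
        with pytest.raises(ConfigurationError):
            SyntheticConfig(shared_read_fraction=1.0)
        with pytest.raises(ConfigurationError):
            SyntheticConfig(n_da_mgs=50, n_mgs=10, genes_per_mgs=200)
        with pytest.raises(ConfigurationError):
            SyntheticConfig(load_ratio=0.0)

    def test_gene_lengths_in_range(self, small_cfg):
        catalog, _, _ = generate_catalog(small_cfg)
        assert catalog.lengths.between(300, 3000).all()

    def test_each_gene_in_exactly_one_mgs(self, small_cfg):
        catalog, defs, _ = generate_catalog(small_cfg)
        seen = []
        for mgs_id in defs.mgs_ids:
            seen.extend(defs.genes_of(mgs_id))
        assert len(seen) == len(set(seen)) == catalog.n_genes


class TestDeterminism:
    def test_catalog_byte_identical_across_runs(self, small_cfg):
        def render(cfg):
            catalog, _, _ = generate_catalog(cfg)
            buf = io.StringIO()
            table = catalog.table.copy()
            table["components"] = [",".join(sorted(c)) for c in table["components"]]
            table.to_csv(buf)
            return buf.getvalue()

        assert render(small_cfg) == render(small_cfg)

    def test_cohort_and_reads_identical_for_same_seed(self, small_cfg):
        catalog, defs, modules = generate_catalog(small_cfg)
        m1, c1, t1 = generate_cohort(small_cfg, catalog, defs, modules)
        m2, c2, t2 = generate_cohort(small_cfg, catalog, defs, modules)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_series_equal(c1, c2)
        pd.testing.assert_frame_equal(t1.true_absolute, t2.true_absolute)

        small = t1.true_absolute.iloc[:, :3]
        r1 = simulate_read_mappings(small, catalog, small_cfg)
        r2 = simulate_read_mappings(small, catalog, small_cfg)
        for s in r1.sample_ids:
            assert r1[s].unique == r2[s].unique
            assert r1[s].shared == r2[s].shared

    def test_different_seed_changes_output(self, small_cfg):
        import dataclasses

        catalog, defs, modules = generate_catalog(small_cfg)
        other = dataclasses.replace(small_cfg, seed=small_cfg.seed + 1)
        _, _, t1 = generate_cohort(small_cfg, catalog, defs, modules)
        _, _, t2 = generate_cohort(other, catalog, defs, modules)
        assert not np.allclose(t1.true_absolute, t2.true_absolute)


class TestCohort:
    def test_planted_da_count(self, small_world):
        truth: GroundTruth = small_world["truth"]
        assert len(truth.da_mgs_ids) == small_world["cfg"].n_da_mgs
        assert set(truth.da_mgs_ids) <= set(truth.true_absolute.index)

    def test_metadata_schema(self, small_world):
        meta = small_world["metadata"]
        for col in ("status", "age", "sex", "bmi", "smoking", "fecal_water",
                    "treatment", "relapses", "activity"):
            assert col in meta.columns
        assert set(meta["status"]) == {"MS", "HC"}
        cases = meta[meta["status"] == "MS"]
        assert ((cases["relapses"] >= 1) == (cases["activity"] == "CA")).all()

    def test_null_cohort_has_no_expected_effect(self):
        cfg = SyntheticConfig(n_mgs=30, genes_per_mgs=20, n_markers_per_mgs=5,
                              core_fraction=0.5, n_cases=150, n_controls=150,
                              n_da_mgs=0, effect_log2fc=0.0, load_ratio=1.0, seed=4)
        catalog, defs, modules = generate_catalog(cfg)
        meta, _, truth = generate_cohort(cfg, catalog, defs, modules)
        case = truth.true_absolute.loc[:, (meta["status"] == "MS").to_numpy()]
        ctrl = truth.true_absolute.loc[:, (meta["status"] == "HC").to_numpy()]
        lfc = np.log2(case.mean(axis=1) / ctrl.mean(axis=1))
        assert abs(lfc.mean()) < 0.15

    def test_uniform_load_ratio_preserves_composition(self):
        """Closed form: multiplying every taxon by a constant leaves the
        composition invariant while absolute abundances scale 2-fold."""
        base = SyntheticConfig(n_mgs=25, genes_per_mgs=20, n_markers_per_mgs=5,
                               core_fraction=0.5, n_cases=200, n_controls=200,
                               n_da_mgs=0, effect_log2fc=0.0, load_ratio=2.0, seed=9)
        catalog, defs, modules = generate_catalog(base)
        meta, _, truth = generate_cohort(base, catalog, defs, modules)
        case_mask = (meta["status"] == "MS").to_numpy()
        abs_case = truth.true_absolute.loc[:, case_mask]
        abs_ctrl = truth.true_absolute.loc[:, ~case_mask]
        ratio = (abs_case.mean(axis=1) / abs_ctrl.mean(axis=1)).to_numpy()
        assert np.allclose(np.median(ratio), 2.0, rtol=0.15)
        rel_case = abs_case / abs_case.sum(axis=0)
        rel_ctrl = abs_ctrl / abs_ctrl.sum(axis=0)
        rel_ratio = (rel_case.mean(axis=1) / rel_ctrl.mean(axis=1)).to_numpy()
        assert np.allclose(np.median(rel_ratio), 1.0, rtol=0.1)

    def test_effect_log2fc_planted_on_absolute_scale(self):
        cfg = SyntheticConfig(n_mgs=20, genes_per_mgs=20, n_markers_per_mgs=5,
                              core_fraction=0.5, n_cases=300, n_controls=300,
                              n_da_mgs=3, effect_log2fc=2.0, seed=5)
        catalog, defs, modules = generate_catalog(cfg)
        meta, _, truth = generate_cohort(cfg, catalog, defs, modules)
        case_mask = (meta["status"] == "MS").to_numpy()
        for mgs in truth.da_mgs_ids:
            row = truth.true_absolute.loc[mgs]
            lfc = np.log2(row[case_mask].mean() / row[~case_mask].mean())
            assert lfc == pytest.approx(2.0, abs=0.4)

    def test_cell_counts_track_total_load_with_missing(self, small_world):
        cells = small_world["cells"]
        truth = small_world["truth"]
        measured = cells.dropna()
        totals = truth.true_absolute.sum(axis=0).reindex(measured.index)
        rho = pd.Series(measured).corr(pd.Series(totals), method="spearman")
        assert rho > 0.9
        expected_missing = round(
            small_world["cfg"].missing_cellcount_fraction * len(cells))
        assert cells.isna().sum() == expected_missing

    def test_confounder_shifts_bmi_and_features(self):
        cfg = SyntheticConfig(n_mgs=15, genes_per_mgs=20, n_markers_per_mgs=5,
                              core_fraction=0.5, n_cases=200, n_controls=200,
                              n_da_mgs=0, n_confounded_mgs=2,
                              confounder_strength=2.0, seed=8)
        catalog, defs, modules = generate_catalog(cfg)
        meta, _, truth = generate_cohort(cfg, catalog, defs, modules)
        case_mask = (meta["status"] == "MS").to_numpy()
        assert meta.loc[case_mask, "bmi"].mean() - meta.loc[~case_mask, "bmi"].mean() > 1.0
        for mgs in truth.confounded_mgs_ids:
            rho = np.corrcoef(np.log(truth.true_absolute.loc[mgs]), meta["bmi"])[0, 1]
            assert rho > 0.5

    def test_cytokine_block_correlates_with_planted_species(self):
        cfg = SyntheticConfig(n_mgs=15, genes_per_mgs=20, n_markers_per_mgs=5,
                              core_fraction=0.5, n_cases=150, n_controls=150,
                              n_da_mgs=3, cytokine_corr=0.6, seed=12)
        catalog, defs, modules = generate_catalog(cfg)
        meta, _, truth = generate_cohort(cfg, catalog, defs, modules)
        target = np.log(truth.true_absolute.loc[truth.da_mgs_ids[0]])
        rho = pd.Series(np.log(meta["cytokine_00"])).corr(
            pd.Series(target.to_numpy(), index=meta.index), method="spearman")
        assert rho > 0.4


class TestReadSimulation:
    def narrow_cfg(self, **kw):
        defaults = dict(n_mgs=4, genes_per_mgs=10, n_markers_per_mgs=3,
                        core_fraction=0.5, n_cases=2, n_controls=2,
                        read_depth=2000, seed=3)
        defaults.update(kw)
        return SyntheticConfig(**defaults)

    def test_record_count_equals_depth(self):
        cfg = self.narrow_cfg(shared_read_fraction=0.2)
        catalog, defs, modules = generate_catalog(cfg)
        _, _, truth = generate_cohort(cfg, catalog, defs, modules)
        table = simulate_read_mappings(truth.true_absolute, catalog, cfg)
        for s in table.sample_ids:
            assert table.n_records(s) == cfg.read_depth
            assert len(table[s].shared) == round(0.2 * cfg.read_depth)

    def test_zero_shared_fraction_all_unique(self):
        cfg = self.narrow_cfg(shared_read_fraction=0.0)
        catalog, defs, modules = generate_catalog(cfg)
        _, _, truth = generate_cohort(cfg, catalog, defs, modules)
        table = simulate_read_mappings(truth.true_absolute, catalog, cfg)
        for s in table.sample_ids:
            assert table[s].shared == []

    def test_single_mgs_support_restriction(self):
        cfg = self.narrow_cfg(shared_read_fraction=0.0)
        catalog, defs, modules = generate_catalog(cfg)
        ab = pd.DataFrame(0.0, index=defs.mgs_ids, columns=["s0"])
        ab.loc[defs.mgs_ids[0], "s0"] = 1.0
        table = simulate_read_mappings(ab, catalog, cfg)
        genes = set(defs.genes_of(defs.mgs_ids[0]))
        assert set(table["s0"].unique) <= genes

    def test_sampling_proportional_to_length_times_abundance(self):
        cfg = self.narrow_cfg(shared_read_fraction=0.0, read_depth=200_000)
        catalog, defs, modules = generate_catalog(cfg)
        ab = pd.DataFrame(
            [[1.0], [3.0], [0.0], [0.0]], index=defs.mgs_ids, columns=["s0"])
        table = simulate_read_mappings(ab, catalog, cfg)
        counts = pd.Series(table["s0"].unique, dtype=float).reindex(
            catalog.gene_ids, fill_value=0.0)
        weights = catalog.lengths * catalog.table["mgs_id"].map(
            dict(zip(defs.mgs_ids, ab["s0"])))
        expect = weights / weights.sum() * cfg.read_depth
        big = expect > 50
        assert np.allclose(counts[big], expect[big], rtol=0.15)

    def test_empty_abundance_is_error(self):
        cfg = self.narrow_cfg()
        catalog, _, _ = generate_catalog(cfg)
        with pytest.raises(DataError):
            simulate_read_mappings(pd.DataFrame(), catalog, cfg)


class TestNullCalibration:
    def test_mann_whitney_p_uniform_on_null_cohort(self):
        """Kolmogorov-Smirnov on per-MGS Mann-Whitney p-values from a null
        cohort: 200 MGS, 50+50 samples."""
        from scipy.stats import kstest, mannwhitneyu

        cfg = SyntheticConfig(n_mgs=200, genes_per_mgs=4, n_markers_per_mgs=2,
                              core_fraction=0.5, n_cases=50, n_controls=50,
                              n_da_mgs=0, effect_log2fc=0.0, load_ratio=1.0, seed=21)
        catalog, defs, modules = generate_catalog(cfg)
        meta, _, truth = generate_cohort(cfg, catalog, defs, modules)
        case_mask = (meta["status"] == "MS").to_numpy()
        pvals = [
            mannwhitneyu(row[case_mask], row[~case_mask], alternative="two-sided").pvalue
            for row in truth.true_absolute.to_numpy()
        ]
        assert kstest(pvals, "uniform").pvalue > 0.01
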
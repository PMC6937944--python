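"""Read-category fractions, quartile trends, cell/gene filters, sample metrics."""

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import sparse

from scstability.cellqc import (
    CellQcThresholds,
    cell_metrics,
    filter_cells,
    filter_genes,
    high_mito_rate,
    quartile_extremes,
    read_category_fractions,
    sample_metrics,
)
from scstability.errors import InputError
from scstability.synthetic import DegradationParams, SimConfig, generate_experiment


def make_adata(counts, genes=None):
    counts = np.atleast_2d(np.asarray(counts))
    adata = AnnData(X=sparse.csr_matrix(counts))
    adata.obs_names = [f"bc{i:04d}" for i in range(counts.shape[0])]
    adata.var_names = genes or [f"g{j}" for j in range(counts.shape[1])]
    return adata


class TestReadCategoryFractions:
    def test_simple(self):
        df = pd.DataFrame({"exonic": [8], "intronic": [2], "intergenic": [0]})
        out = read_category_fractions(df)
        assert (out[["exonic_frac", "intronic_frac", "intergenic_frac"]].iloc[0] == [0.8, 0.2, 0.0]).all()

    def test_zero_total_flagged(self):
        out = read_category_fractions(
            pd.DataFrame({"exonic": [0, 5], "intronic": [0, 5], "intergenic": [0, 0]})
        )
        assert out["flagged"].tolist() == [True, False]
        assert np.isnan(out["exonic_frac"].iloc[0])

    @given(st.integers(min_value=1, max_value=1000))
    @settings(max_examples=25, deadline=None)
    def test_scaling_invariance(self, k):
        base = pd.DataFrame({"exonic": [6], "intronic": [3], "intergenic": [1]})
        a = read_category_fractions(base)
        b = read_category_fractions(base * k)
        for col in ("exonic_frac", "intronic_frac", "intergenic_frac"):
            assert a[col].iloc[0] == pytest.approx(b[col].iloc[0])

    def test_fractions_sum_to_one(self, rng):
        df = pd.DataFrame(rng.integers(0, 50, size=(100, 3)), columns=["exonic", "intronic", "intergenic"])
        out = read_category_fractions(df)
        sums = out.loc[~out["flagged"], ["exonic_frac", "intronic_frac", "intergenic_frac"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0)


class TestQuartileExtremes:
    @staticmethod
    def frame(fractions, sample="s1"):
        return pd.DataFrame(
            {
                "sample_id": sample,
                "barcode": [f"bc{i:03d}" for i in range(len(fractions))],
                "exonic_frac": fractions,
            }
        )

    def test_top_quartile_of_eight(self):
        out = quartile_extremes(self.frame([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]), "exonic")
        assert out.iloc[0]["top_mean"] == pytest.approx(0.75)
        assert out.iloc[0]["bottom_mean"] == pytest.approx(0.15)
        assert out.iloc[0]["quartile_size"] == 2

    def test_constant_fractions(self):
        out = quartile_extremes(self.frame([0.4] * 8), "exonic")
        assert out.iloc[0]["top_mean"] == out.iloc[0]["bottom_mean"] == pytest.approx(0.4)

    def test_small_sample_skipped(self):
        out = quartile_extremes(self.frame([0.1, 0.2, 0.3]), "exonic")
        assert out.empty

    def test_intron_shift_moves_bottom_exonic_quartile(self):
        cfg = SimConfig.default(
            n_donors=3, tissues=["spleen"], time_points_h=[0.0, 72.0],
            n_cells_per_sample=400, n_genes=40, n_ambient_droplets=0,
            n_debris_droplets=0, seed=17, mean_umis_per_cell=2000.0,
        )
        cfg.degradation = DegradationParams(intron_shift={("spleen", 72.0): 0.15})
        exp = generate_experiment(cfg)
        frames = []
        for s in exp.samples:
            rc = read_category_fractions(s.read_categories)
            rc = rc.assign(sample_id=s.meta.sample_id, time_h=s.meta.time_h)
            frames.append(rc.reset_index(drop=True))
        allrc = pd.concat(frames, ignore_index=True)
        ext = quartile_extremes(allrc, "exonic")
        ext = ext.merge(
            allrc[["sample_id", "time_h"]].drop_duplicates(), on="sample_id"
        )
        b0 = ext.loc[ext["time_h"] == 0.0, "bottom_mean"]
        b1 = ext.loc[ext["time_h"] == 72.0, "bottom_mean"]
        drop = b0.mean() - b1.mean()
        se = np.sqrt(b0.var() / len(b0) + b1.var() / len(b1))
        assert abs(drop - 0.15) <= 3 * se + 0.01


class TestFilterCells:
    def make_counts(self, n_genes_detected, n_counts, mt_frac, total_genes=600):
        """One cell with the stated detected genes, UMI count and MT share."""
        row = np.zeros(total_genes)
        mt_umis = int(round(mt_frac * n_counts))
        row[0] = mt_umis  # gene 0 is MT
        rest = n_counts - mt_umis
        k = n_genes_detected - (2 if mt_umis else 1)
        row[1] = rest - k  # bulk of remaining counts on gene 1
        row[2 : 2 + k] = 1
        return row

    def adata_for(self, cells):
        counts = np.vstack(cells)
        genes = ["MT-ND1"] + [f"g{j}" for j in range(1, counts.shape[1])]
        return make_adata(counts, genes)

    def test_boundaries(self):
        cells = [
            self.make_counts(250, 1000, 0.0),     # removed: min_genes
            self.make_counts(300, 1000, 0.0),     # kept: boundary
            self.make_counts(310, 1000, 0.101),   # removed: max_mt
            self.make_counts(310, 1000, 0.10),    # kept: exactly 10%
            self.make_counts(310, 21000, 0.0),    # removed: max_umi
            self.make_counts(310, 20000, 0.0),    # kept: boundary
        ]
        kept, metrics, removal = filter_cells(self.adata_for(cells), "lung")
        assert kept.n_obs == 3
        assert removal["rule"].tolist() == ["min_genes", "max_mt", "max_umi"]

    def test_esophagus_gene_limit(self):
        cell = self.make_counts(6000, 15000, 0.0, total_genes=7000)
        kept_e, _, _ = filter_cells(self.adata_for([cell]), "esophagus")
        kept_l, _, log_l = filter_cells(self.adata_for([cell]), "lung")
        assert kept_e.n_obs == 1 and kept_l.n_obs == 0
        assert log_l["rule"].iloc[0] == "max_genes"

    def test_unknown_tissue(self):
        with pytest.raises(InputError, match="unknown tissue"):
            filter_cells(self.adata_for([self.make_counts(400, 1000, 0.0)]), "liver")

    def test_log_reconciles(self, rng):
        counts = rng.integers(0, 4, size=(200, 400)) * (rng.random((200, 400)) < 0.6)
        adata = make_adata(counts, ["MT-ND1"] + [f"g{j}" for j in range(399)])
        kept, metrics, removal = filter_cells(adata, "spleen")
        assert kept.n_obs + len(removal) == adata.n_obs


class TestFilterGenes:
    def test_detection_threshold(self):
        counts = np.array([[1, 1, 0], [1, 1, 0], [0, 1, 0], [0, 0, 5]])
        out = filter_genes(make_adata(counts))
        assert list(out.var_names) == ["g1"]  # g0 in 2 cells, g2 in 1

    def test_idempotent(self, rng):
        counts = (rng.random((50, 80)) < 0.05).astype(int)
        once = filter_genes(make_adata(counts))
        twice = filter_genes(once)
        assert list(once.var_names) == list(twice.var_names)

    def test_empty_matrix(self):
        out = filter_genes(make_adata(np.zeros((3, 4))))
        assert out.n_vars == 0


class TestHighMitoRate:
    def test_strict_inequality(self):
        cells = pd.DataFrame({"sample_id": "s", "mt_pct": [5, 15, 25, 5]})
        assert high_mito_rate(cells)["s"] == pytest.approx(0.5)
        cells10 = pd.DataFrame({"sample_id": "s", "mt_pct": [10.0] * 4})
        assert high_mito_rate(cells10)["s"] == 0.0

    def test_mt_inflation_raises_rate_across_donors(self):
        cfg = SimConfig.default(
            n_donors=100, tissues=["spleen"], time_points_h=[0.0, 72.0],
            n_cells_per_sample=50, n_genes=40, n_ambient_droplets=0,
            n_debris_droplets=0, seed=29, mean_umis_per_cell=2000.0,
        )
        cfg.degradation = DegradationParams(
            mt_fold_change={("spleen", ct, 72.0): 3.0 for ct in cfg.cell_types}
        )
        exp = generate_experiment(cfg)
        rates = {}
        for s in exp.samples:
            cells = s.truth["droplet_class"] == "cellular"
            adata = make_adata(s.droplets.counts[cells.to_numpy()].toarray(),
                               s.droplets.features)
            m = cell_metrics(adata)
            rates[(s.meta.donor, s.meta.time_h)] = (m["mt_pct"] > 10).mean()
        wins = sum(
            rates[(d, 72.0)] > rates[(d, 0.0)] for d in {k[0] for k in rates}
        )
        assert wins >= 95


class TestSampleMetrics:
    @staticmethod
    def cells_frame(spec):
        rows = []
        for sid, donor, tissue, t, genes in spec:
            for i, g in enumerate(genes):
                rows.append(
                    {"sample_id": sid, "donor": donor, "tissue": tissue, "time_h": t,
                     "n_genes": g, "n_counts": 10 * g}
                )
        return pd.DataFrame(rows)

    def test_median_genes(self):
        cells = self.cells_frame([("s1", "D1", "spleen", 0, [100, 200])])
        metrics, _ = sample_metrics(cells)
        assert metrics["median_genes"].iloc[0] == 150

    def test_identical_metrics_give_p_one(self):
        spec = [
            (f"s{t}{d}", f"D{d}", "spleen", t, [100, 200, 300])
            for t in (0, 72)
            for d in range(3)
        ]
        metrics, tests = sample_metrics(self.cells_frame(spec))
        ok = tests[tests["status"] == "ok"]
        assert (ok["p_adj"] == 1.0).all()

    def test_single_sample_group_skipped(self):
        spec = [("a", "D1", "spleen", 0, [100]), ("b", "D2", "spleen", 0, [100]),
                ("c", "D1", "spleen", 72, [100])]
        _, tests = sample_metrics(self.cells_frame(spec))
        assert (tests["status"] == "skipped_single_sample").all()
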
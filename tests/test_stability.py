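"""Fold-change masking, composition tests, variance partitioning, dendrogram."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from scstability.errors import InputError
from scstability.stability import (
    composition_donor_anova,
    composition_proportions,
    composition_time_tests,
    crossorgan_dendrogram,
    mito_fold_change,
    significance_bins,
    variance_explained,
)
from scstability.synthetic import DegradationParams, SimConfig, generate_experiment


def cells_frame(strata):
    """strata: list of (tissue, cell_type, time_h, mt_pcts, donor, sample)."""
    rows = []
    for tissue, ct, t, mts, donor, sample in strata:
        for mt in mts:
            rows.append(
                {"tissue": tissue, "cell_type": ct, "time_h": t, "mt_pct": mt,
                 "donor": donor, "sample_id": sample}
            )
    return pd.DataFrame(rows)


class TestMitoFoldChange:
    def test_t0_baseline_is_unity(self):
        cells = cells_frame([("spleen", "T", 0.0, [1, 2, 3, 4, 5], "D1", "s0")])
        out = mito_fold_change(cells)
        row = out.iloc[0]
        assert row["fold_change"] == 1.0 and row["p_adj"] == 1.0 and row["status"] == "ok"

    def test_too_few_cells_masked(self):
        cells = cells_frame(
            [
                ("spleen", "T", 0.0, [1, 2, 3, 4, 5], "D1", "s0"),
                ("spleen", "T", 72.0, [9, 9, 9, 9], "D1", "s1"),  # only 4 cells
            ]
        )
        out = mito_fold_change(cells)
        row = out[(out["time_h"] == 72.0)].iloc[0]
        assert row["status"] == "too_few_cells"
        assert np.isnan(row["fold_change"]) and np.isnan(row["p_adj"])

    def test_missing_sample_marked(self):
        cells = cells_frame([("spleen", "T", 0.0, [1, 2, 3, 4, 5], "D1", "s0")])
        out = mito_fold_change(cells, expected_times=[0.0, 72.0])
        row = out[out["time_h"] == 72.0].iloc[0]
        assert row["status"] == "missing_sample"

    def test_masking_rule_is_exact(self, rng):
        # n_cells < 5 <=> too_few_cells, across a grid of stratum sizes
        strata = []
        for i, n in enumerate([1, 4, 5, 6, 30]):
            strata.append(("lung", f"ct{i}", 0.0, rng.uniform(1, 5, 10), "D1", "a"))
            strata.append(("lung", f"ct{i}", 72.0, rng.uniform(1, 5, n), "D1", "b"))
        out = mito_fold_change(cells_frame(strata))
        late = out[out["time_h"] == 72.0].set_index("cell_type")
        for i, n in enumerate([1, 4, 5, 6, 30]):
            expected = "too_few_cells" if n < 5 else "ok"
            assert late.loc[f"ct{i}", "status"] == expected

    def test_injected_fold_change_recovered(self):
        cfg = SimConfig.default(
            n_donors=1, tissues=["spleen"], time_points_h=[0.0, 72.0],
            n_cells_per_sample=1500, n_genes=60, n_ambient_droplets=0,
            n_debris_droplets=0, seed=47, mean_umis_per_cell=2000.0,
        )
        # equal thirds -> ~500 cells per stratum; one type degrades 2x
        cfg.cell_type_proportions = {
            "D1": {ct: 1 / 3 for ct in cfg.cell_types}
        }
        cfg.degradation = DegradationParams(
            mt_fold_change={("spleen", "T_cell", 72.0): 2.0}
        )
        exp = generate_experiment(cfg)
        rows = []
        mt_idx = cfg.mt_gene_indices
        for s in exp.samples:
            mask = (s.truth["droplet_class"] == "cellular").to_numpy()
            x = s.droplets.counts[mask].toarray()
            mt_pct = 100 * x[:, mt_idx].sum(axis=1) / x.sum(axis=1)
            rows.append(
                pd.DataFrame(
                    {"tissue": "spleen", "cell_type": s.truth.loc[mask, "cell_type"].to_numpy(),
                     "time_h": s.meta.time_h, "mt_pct": mt_pct, "donor": s.meta.donor,
                     "sample_id": s.meta.sample_id}
                )
            )
        out = mito_fold_change(pd.concat(rows, ignore_index=True))
        hit = out[(out["cell_type"] == "T_cell") & (out["time_h"] == 72.0)].iloc[0]
        assert hit["fold_change"] == pytest.approx(2.0, rel=0.1)
        assert hit["p_adj"] < 0.01
        null = out[(out["cell_type"] == "B_cell") & (out["time_h"] == 72.0)].iloc[0]
        assert null["fold_change"] == pytest.approx(1.0, rel=0.1)

    def test_significance_bins(self):
        assert significance_bins(0.5) == ""
        assert significance_bins(0.005) == "*"
        assert significance_bins(1e-6) == "**"
        assert significance_bins(1e-9) == "***"


class TestComposition:
    def test_proportions(self):
        cells = cells_frame(
            [
                ("spleen", "T", 0.0, [1, 1, 1], "D1", "s0"),
                ("spleen", "B", 0.0, [1], "D1", "s0"),
            ]
        )
        comp = composition_proportions(cells)
        by_type = comp.set_index("cell_type")["proportion"]
        assert by_type["T"] == 0.75 and by_type["B"] == 0.25

    def test_rows_sum_to_one_and_missing_types_zero(self, rng):
        cells = cells_frame(
            [
                ("spleen", "T", 0.0, rng.uniform(0, 5, 8), "D1", "s0"),
                ("spleen", "B", 0.0, rng.uniform(0, 5, 4), "D1", "s0"),
                ("spleen", "T", 72.0, rng.uniform(0, 5, 6), "D1", "s1"),
            ]
        )
        comp = composition_proportions(cells)
        sums = comp.groupby("sample_id")["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0)
        assert comp[(comp["sample_id"] == "s1") & (comp["cell_type"] == "B")]["proportion"].iloc[0] == 0.0

    def test_multinomial_recovery(self):
        cfg = SimConfig.default(
            n_donors=4, tissues=["spleen"], time_points_h=[0.0],
            n_cells_per_sample=500, n_genes=40, n_ambient_droplets=0,
            n_debris_droplets=0, seed=3, mean_umis_per_cell=1000.0,
        )
        exp = generate_experiment(cfg)
        rows = []
        for s in exp.samples:
            mask = (s.truth["droplet_class"] == "cellular").to_numpy()
            rows.append(
                pd.DataFrame(
                    {"tissue": "spleen", "cell_type": s.truth.loc[mask, "cell_type"],
                     "time_h": 0.0, "mt_pct": 0.0, "donor": s.meta.donor,
                     "sample_id": s.meta.sample_id}
                )
            )
        comp = composition_proportions(pd.concat(rows, ignore_index=True))
        n = cfg.n_cells_per_sample
        for _, row in comp.iterrows():
            pi = cfg.cell_type_proportions[row["donor"]][row["cell_type"]]
            se = np.sqrt(pi * (1 - pi) / n)
            assert abs(row["proportion"] - pi) <= 3 * se + 1e-9

    def test_identical_proportions_p_one(self):
        rows = []
        for d in range(4):
            for t in (0.0, 24.0, 72.0):
                rows.append(("spleen", "T", t, [0] * 3, f"D{d}", f"s{d}{t}"))
                rows.append(("spleen", "B", t, [0] * 1, f"D{d}", f"s{d}{t}"))
        out = composition_time_tests(composition_proportions(cells_frame(rows)))
        ok = out[out["status"] == "ok"]
        assert not ok.empty and (ok["p_adj"] == 1.0).all()

    def test_skips_one_sided_contrast(self):
        rows = [("spleen", "T", 0.0, [1, 1], "D1", "s0"),
                ("spleen", "T", 72.0, [1, 1], "D1", "s1")]
        out = composition_time_tests(composition_proportions(cells_frame(rows)))
        assert (out["status"] == "skipped").all()

    def test_halved_proportion_detected_by_combined_contrast(self):
        detected = 0
        runs = 25
        for seed in range(runs):
            cfg = SimConfig.default(
                n_donors=6, tissues=["spleen"], time_points_h=[0.0, 12.0, 24.0, 72.0],
                n_cells_per_sample=200, n_genes=40, n_ambient_droplets=0,
                n_debris_droplets=0, seed=1000 + seed, mean_umis_per_cell=500.0,
            )
            exp = generate_experiment(cfg)
            rows = []
            for s in exp.samples:
                mask = (s.truth["droplet_class"] == "cellular").to_numpy()
                ct = s.truth.loc[mask, "cell_type"].to_numpy()
                if s.meta.time_h == 72.0:
                    # halve T_cell representation by dropping half of them
                    t_idx = np.flatnonzero(ct == "T_cell")
                    drop = set(t_idx[::2])
                    keep = np.array([i for i in range(len(ct)) if i not in drop])
                    ct = ct[keep]
                rows.append(
                    pd.DataFrame(
                        {"tissue": "spleen", "cell_type": ct, "time_h": s.meta.time_h,
                         "mt_pct": 0.0, "donor": s.meta.donor, "sample_id": s.meta.sample_id}
                    )
                )
            comp = composition_proportions(pd.concat(rows, ignore_index=True))
            tests = composition_time_tests(comp)
            hit = tests[(tests["cell_type"] == "T_cell") & (tests["contrast"] == "combined_v72.0")]
            if not hit.empty and hit["p_adj"].iloc[0] < 0.05:
                detected += 1
        assert detected / runs >= 0.8


class TestDonorAnova:
    def test_degenerate_flagged(self):
        rows = []
        for d in range(3):
            for rep in range(2):
                rows.append(("spleen", "T", float(rep), [1] * 2, f"D{d}", f"s{d}{rep}"))
                rows.append(("spleen", "B", float(rep), [1] * 2, f"D{d}", f"s{d}{rep}"))
        table, n_sig = composition_donor_anova(composition_proportions(cells_frame(rows)))
        assert (table["status"] == "degenerate").all()
        assert n_sig == 0

    def test_single_donor_errors(self):
        rows = [("spleen", "T", 0.0, [1, 2], "D1", "s0"),
                ("spleen", "T", 72.0, [1, 2], "D1", "s1")]
        with pytest.raises(InputError):
            composition_donor_anova(composition_proportions(cells_frame(rows)))

    def test_calibration_and_power(self, rng):
        # null: i.i.d. donor proportions -> significant fraction near alpha;
        # signal: one donor far off -> detected nearly always
        null_sig, power_hits, runs = 0, 0, 60
        for _ in range(runs):
            def frame(shifted):
                rows = []
                for d in range(4):
                    mu = 0.4 if (shifted and d == 0) else 0.1
                    for rep in range(4):
                        rows.append(
                            {"tissue": "spleen", "cell_type": "T",
                             "sample_id": f"s{d}{rep}", "donor": f"D{d}",
                             "time_h": float(rep),
                             "proportion": rng.normal(mu, 0.02)}
                        )
                return pd.DataFrame(rows)

            t_null, n0 = composition_donor_anova(frame(False))
            t_sig, n1 = composition_donor_anova(frame(True))
            null_sig += n0
            power_hits += int(n1 > 0)
        assert null_sig / runs <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / runs)
        assert power_hits / runs >= 0.95


class TestVarianceExplained:
    def test_exact_fit_r2_one(self):
        factors = pd.DataFrame({"donor": ["a"] * 5 + ["b"] * 5})
        y = np.array([[1.0]] * 5 + [[3.0]] * 5)
        out = variance_explained(y, factors)
        assert out["donor"].iloc[0] == pytest.approx(1.0)

    def test_independent_factor_near_zero(self, rng):
        n = 1000
        factors = pd.DataFrame({"donor": rng.choice(["a", "b"], n)})
        y = rng.normal(size=(n, 20))
        out = variance_explained(y, factors)
        assert out["donor"].median() < 0.02

    def test_known_variance_share_recovered(self, rng):
        n = 2000
        donor = rng.choice(list("abcd"), n)
        means = {"a": -1.0, "b": -0.5, "c": 0.5, "d": 1.0}
        base = np.array([means[d] for d in donor])
        sigma = base.std()  # noise sd equal to signal sd -> R2 = 0.5
        y = np.column_stack([base + rng.normal(0, sigma, n) for _ in range(30)])
        out = variance_explained(y, pd.DataFrame({"donor": donor}))
        assert 0.45 <= out["donor"].median() <= 0.55

    def test_bijective_factors_same_r2(self, rng):
        n = 300
        donor = rng.choice(["a", "b", "c"], n)
        relabel = {"a": "z9", "b": "y8", "c": "x7"}
        y = rng.normal(size=(n, 10)) + (donor == "a")[:, None]
        out = variance_explained(
            y, pd.DataFrame({"donor": donor, "alias": [relabel[d] for d in donor]})
        )
        np.testing.assert_allclose(out["donor"], out["alias"], atol=1e-12)

    def test_constant_factor_errors(self):
        with pytest.raises(InputError, match="constant"):
            variance_explained(np.zeros((4, 2)), pd.DataFrame({"donor": ["a"] * 4}))

    def test_zero_variance_gene_nan(self):
        factors = pd.DataFrame({"donor": ["a", "a", "b", "b"]})
        y = np.column_stack([np.ones(4), [0, 1, 2, 3.0]])
        out = variance_explained(y, factors)
        assert np.isnan(out["donor"].iloc[0]) and np.isfinite(out["donor"].iloc[1])


class TestDendrogram:
    @staticmethod
    def labels(n, ct):
        return pd.DataFrame(
            {"cell_type": ct, "tissue": "spleen", "time_h": 0.0, "donor": "D1"},
            index=range(n),
        )

    def test_identical_cells_merge_first(self, rng):
        base = rng.normal(size=12)
        y = np.vstack([base, base, base + rng.normal(0, 5, 12), rng.normal(size=12)])
        lab = pd.DataFrame(
            {"cell_type": ["a", "a", "b", "c"], "tissue": "s", "time_h": 0.0,
             "donor": ["D1", "D2", "D1", "D1"]}
        )
        link, leaves = crossorgan_dendrogram(y, lab, n_hvg=12)
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}

    def test_stratum_subsampled_to_ten(self, rng):
        y = rng.normal(size=(40, 20))
        lab = pd.concat([self.labels(25, "a"), self.labels(15, "b")], ignore_index=True)
        link, leaves = crossorgan_dendrogram(y, lab, n_per_stratum=10, n_hvg=20)
        counts = leaves["cell_type"].value_counts()
        assert counts["a"] == 10 and counts["b"] == 10

    def test_separated_types_recovered(self, rng):
        blocks = []
        truth = []
        for i, ct in enumerate(["a", "b", "c"]):
            x = rng.normal(0, 1, size=(30, 60))
            x[:, i * 20 : (i + 1) * 20] += 6.0
            blocks.append(x)
            truth += [ct] * 30
        y = np.vstack(blocks)
        lab = pd.DataFrame(
            {"cell_type": truth, "tissue": "spleen", "time_h": 0.0,
             "donor": np.tile(["D1", "D2", "D3"], 30)}
        )
        link, leaves = crossorgan_dendrogram(y, lab, n_per_stratum=10, n_hvg=60)
        clusters = hierarchy.fcluster(link, t=3, criterion="maxclust")
        assert adjusted_rand_score(leaves["cell_type"], clusters) >= 0.9

    def test_single_stratum_errors(self, rng):
        with pytest.raises(InputError):
            crossorgan_dendrogram(rng.normal(size=(5, 10)), self.labels(5, "a"))
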
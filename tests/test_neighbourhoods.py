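import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import ecostruct as es
from ecostruct.errors import ParameterError
from ecostruct.neighbourhoods import build_windows, cluster_windows, cn_prevalence_and_enrichment

from conftest import make_cells


def _phenotype_cells(panel, xs, ys, phens, roi="R1"):
    return make_cells(
        pd.DataFrame({"x": xs, "y": ys, "phenotype": phens}), panel, roi_id=roi
    )


class TestBuildWindows:
    def test_radius_window_frequencies(self, tiny_panel):
        # centre cell with neighbours A, A, B inside 20 um
        cells = _phenotype_cells(
            tiny_panel, [0.0, 5.0, 10.0, 15.0], [0.0] * 4, ["C", "A", "A", "B"]
        )
        win = build_windows(cells, mode="radius", param=20.0, include_center=False)
        freqs = win.freqs[0]
        lookup = dict(zip(win.phenotypes, freqs))
        assert lookup["A"] == pytest.approx(2 / 3)
        assert lookup["B"] == pytest.approx(1 / 3)
        assert lookup["C"] == 0.0

    def test_isolated_cell_is_one_hot_with_center(self, tiny_panel):
        cells = _phenotype_cells(tiny_panel, [0.0, 500.0], [0.0, 500.0], ["A", "B"])
        win = build_windows(cells, mode="radius", param=10.0, include_center=True)
        a = win.freqs[0]
        assert a[win.phenotypes.index("A")] == 1.0
        assert a.sum() == 1.0

    def test_knn_on_21_cells_uses_everyone(self, tiny_panel):
        rng = np.random.default_rng(0)
        cells = _phenotype_cells(
            tiny_panel, rng.uniform(0, 50, 21), rng.uniform(0, 50, 21), ["A"] * 21
        )
        win = build_windows(cells, mode="knn", param=20, include_center=True)
        assert (win.counts.sum(axis=1) == 21).all()

    def test_invalid_parameters(self, tiny_panel):
        cells = _phenotype_cells(tiny_panel, [0.0], [0.0], ["A"])
        with pytest.raises(ParameterError):
            build_windows(cells, mode="radius", param=0)
        with pytest.raises(ParameterError):
            build_windows(cells, mode="wedge", param=5)

    def test_knn_matches_bruteforce_oracle(self, tiny_panel):
        """kNN neighbour sets equal a brute-force sorted-distance oracle
        (ties broken by cell id) on a random 300-cell instance."""
        rng = np.random.default_rng(7)
        n, k = 300, 10
        xs, ys = rng.uniform(0, 200, n), rng.uniform(0, 200, n)
        phens = rng.choice(list("ABC"), n)
        cells = _phenotype_cells(tiny_panel, xs, ys, phens)
        win = build_windows(cells, mode="knn", param=k, include_center=False)
        pts = np.column_stack([xs, ys])
        for i in rng.choice(n, 40, replace=False):
            d = np.hypot(*(pts - pts[i]).T)
            order = np.lexsort((np.arange(n), d))
            neigh = [j for j in order if j != i][:k]
            want = np.bincount(
                [win.phenotypes.index(phens[j]) for j in neigh], minlength=3
            )
            np.testing.assert_array_equal(win.counts[i], want)

    def test_windows_never_cross_rois(self, tiny_panel):
        a = pd.DataFrame({"x": [0.0, 1.0], "y": 0.0, "phenotype": ["A", "A"],
                          "roi_id": "R1", "patient_id": "P1",
                          "cell_id": [1, 2]})
        b = pd.DataFrame({"x": [0.5], "y": 0.0, "phenotype": ["B"],
                          "roi_id": "R2", "patient_id": "P2", "cell_id": [1]})
        cells = make_cells(pd.concat([a, b], ignore_index=True), tiny_panel)
        win = build_windows(cells, mode="radius", param=5.0, include_center=False)
        assert win.counts[0, win.phenotypes.index("B")] == 0

    def test_frequency_rows_invariant_to_row_order(self, tiny_panel):
        rng = np.random.default_rng(1)
        n = 150
        df = pd.DataFrame(
            {
                "x": rng.uniform(0, 100, n),
                "y": rng.uniform(0, 100, n),
                "phenotype": rng.choice(list("AB"), n),
                "cell_id": np.arange(1, n + 1),
            }
        )
        cells = make_cells(df, tiny_panel)
        win = build_windows(cells, mode="knn", param=8)
        perm = rng.permutation(n)
        shuffled = make_cells(df.iloc[perm].reset_index(drop=True), tiny_panel)
        win2 = build_windows(shuffled, mode="knn", param=8)
        np.testing.assert_allclose(win.freqs[perm], win2.freqs)


class TestClusterWindows:
    def _win(self, tiny_panel, n=400, seed=0):
        rng = np.random.default_rng(seed)
        half = n // 2
        phens = ["A"] * half + ["B"] * (n - half)
        xs = np.concatenate([rng.uniform(0, 50, half), 500 + rng.uniform(0, 50, n - half)])
        ys = rng.uniform(0, 50, n)
        cells = _phenotype_cells(tiny_panel, xs, ys, phens)
        return build_windows(cells, mode="knn", param=10)

    def test_deterministic_given_seed(self, tiny_panel):
        win = self._win(tiny_panel)
        a = cluster_windows(win, k=2, seed=0)
        b = cluster_windows(win, k=2, seed=0)
        np.testing.assert_array_equal(a, b)

    def test_two_planted_archetypes(self, tiny_panel):
        win = self._win(tiny_panel)
        labels = cluster_windows(win, k=2, seed=0)
        planted = np.repeat([0, 1], len(labels) // 2)
        assert adjusted_rand_score(planted, labels) == 1.0

    def test_too_few_distinct_rows(self, tiny_panel):
        cells = _phenotype_cells(tiny_panel, [0.0, 1.0, 2.0], [0.0] * 3, ["A"] * 3)
        win = build_windows(cells, mode="knn", param=2)
        with pytest.raises(ParameterError, match="smaller k|choose k"):
            cluster_windows(win, k=2)


class TestPrevalenceAndEnrichment:
    def test_single_cn_core_is_100_percent(self, tiny_panel):
        cells = _phenotype_cells(tiny_panel, [0.0, 5.0], [0.0] * 2, ["A", "A"])
        win = build_windows(cells, mode="radius", param=10)
        res = cn_prevalence_and_enrichment(np.array([1, 1]), win,
                                           cells.df["roi_id"].to_numpy())
        assert res.prevalence.loc["R1", "CN1"] == 100.0

    def test_constant_prevalence_gives_zero_z(self, tiny_panel):
        frames = []
        for r in range(3):
            frames.append(
                pd.DataFrame({"x": [0.0, 5.0], "y": 0.0, "phenotype": ["A", "B"],
                              "roi_id": f"R{r}", "patient_id": f"P{r}",
                              "cell_id": [1, 2]})
            )
        cells = make_cells(pd.concat(frames, ignore_index=True), tiny_panel)
        win = build_windows(cells, mode="radius", param=10)
        labels = np.tile([1, 2], 3)
        res = cn_prevalence_and_enrichment(labels, win, cells.df["roi_id"].to_numpy())
        assert (res.prevalence_z.to_numpy() == 0).all()

    def test_prevalence_conservation(self, tiny_panel):
        """Core prevalences weighted by core cell counts reproduce the
        global CN label distribution."""
        rng = np.random.default_rng(2)
        frames = []
        for r, n in enumerate((50, 80, 30)):
            frames.append(
                pd.DataFrame(
                    {"x": rng.uniform(0, 100, n), "y": rng.uniform(0, 100, n),
                     "phenotype": rng.choice(list("AB"), n), "roi_id": f"R{r}",
                     "patient_id": f"P{r}", "cell_id": np.arange(1, n + 1)}
                )
            )
        cells = make_cells(pd.concat(frames, ignore_index=True), tiny_panel)
        win = build_windows(cells, mode="knn", param=5)
        labels = rng.integers(1, 5, len(cells))
        cores = cells.df["roi_id"].to_numpy()
        res = cn_prevalence_and_enrichment(labels, win, cores)
        weights = pd.Series(cores).value_counts()
        weighted = (res.prevalence.mul(weights.reindex(res.prevalence.index), axis=0)).sum()
        weighted = weighted / weights.sum()
        global_pct = pd.Series(labels).value_counts(normalize=True) * 100
        for cn in res.prevalence.columns:
            assert weighted[cn] == pytest.approx(global_pct[int(cn[2:])])

    def test_planted_subtype_niche_shift_direction(self, annotated_cohort):
        """The subtype with a doubled immune-hub weight shows higher mean
        prevalence of the immune-dominated neighbourhood (two ROIs per
        subtype here; the powered version runs on larger cohorts below)."""
        cells, cohort, truth = annotated_cohort
        win = build_windows(cells, mode="knn", param=20)
        labels = cluster_windows(win, k=5, seed=0)
        sub = cohort.subtype_of()
        grouping = {
            roi: sub[pat]
            for roi, pat in cells.df.groupby("roi_id")["patient_id"].first().items()
        }
        res = cn_prevalence_and_enrichment(labels, win, cells.df["roi_id"].to_numpy(),
                                           grouping=grouping)
        # identify the CN dominated by planted immune-hub cells
        niche = truth.cells["niche"].to_numpy()
        immune_cn = pd.Series(labels[niche == "immune_hub"]).mode()[0]
        tests = res.group_tests
        row = tests[
            (tests["cn"] == f"CN{immune_cn}")
            & (tests["group_a"].isin(["POLE", "CNL"]))
            & (tests["group_b"].isin(["POLE", "CNL"]))
        ]
        assert len(row) == 1
        r = row.iloc[0]
        pole_mean = r["mean_a"] if r["group_a"] == "POLE" else r["mean_b"]
        cnl_mean = r["mean_b"] if r["group_a"] == "POLE" else r["mean_a"]
        assert pole_mean > cnl_mean


def test_planted_niche_shift_power(tiny_panel):
    """Across seeds, the doubled immune-hub weight in the hypermutated-like
    subtype yields a significant (adjusted p < 0.05) prevalence difference
    vs the copy-number-low-like subtype in >= 80 % of cohorts."""
    hits = 0
    n_seeds = 10
    for seed in range(n_seeds):
        cfg = es.small_config(seed=100 + seed, cells_per_roi=700.0,
                              patients_per_subtype=3, rois_per_patient=2)
        cells, cohort, truth = es.simulate_cohort(cfg)
        cells = cells.with_columns(phenotype=truth.cells["phenotype"].to_numpy())
        win = build_windows(cells, mode="knn", param=20)
        labels = cluster_windows(win, k=5, seed=0)
        sub = cohort.subtype_of()
        grouping = {
            roi: sub[pat]
            for roi, pat in cells.df.groupby("roi_id")["patient_id"].first().items()
        }
        res = cn_prevalence_and_enrichment(labels, win, cells.df["roi_id"].to_numpy(),
                                           grouping=grouping)
        niche = truth.cells["niche"].to_numpy()
        immune_cn = pd.Series(labels[niche == "immune_hub"]).mode()[0]
        tests = res.group_tests
        row = tests[
            (tests["cn"] == f"CN{immune_cn}")
            & (tests["group_a"].isin(["POLE", "CNL"]))
            & (tests["group_b"].isin(["POLE", "CNL"]))
        ]
        hits += bool(row["significant"].any())
    assert hits >= 0.8 * n_seeds
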
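import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import ecostruct as es
from ecostruct.errors import ConfigError, ParameterError, ValidationError
from ecostruct.preprocess import (
    SignatureTable,
    annotate_clusters,
    asinh_cofactor,
    cluster_profiles,
)

from conftest import make_cells


def _cells_with_intensity(panel, values, marker="m1"):
    n = len(values)
    df = pd.DataFrame({"x": np.arange(n, dtype=float), "y": 0.0, marker: values})
    return make_cells(df, panel)


class TestTransform:
    def test_zero_maps_to_zero(self, tiny_panel):
        cells = _cells_with_intensity(tiny_panel, [0.0, 1.0, 10.0])
        out = es.transform_intensities(cells, cofactor=5.0)
        assert out.df["m1"].iloc[0] == 0.0

    def test_cofactor_sinh_identity(self):
        assert asinh_cofactor(5.0 * np.sinh(1.0), cofactor=5.0) == pytest.approx(1.0)
        assert asinh_cofactor(0.0, cofactor=5.0) == 0.0

    def test_clipping_matches_order_statistic(self, tiny_panel):
        values = np.arange(1.0, 101.0)
        cells = _cells_with_intensity(tiny_panel, values)
        out = es.transform_intensities(cells, cofactor=5.0, clip_quantile=0.99)
        hi = np.quantile(values, 0.99)  # direct order-statistic oracle
        expect = np.arcsinh(np.minimum(values, hi) / 5.0)
        expect = (expect - expect.min()) / (expect.max() - expect.min())
        np.testing.assert_allclose(out.df["m1"].to_numpy(), expect)
        # everything above the quantile collapses onto it
        assert out.df["m1"].iloc[-1] == out.df["m1"].max()
        assert (out.df["m1"].to_numpy()[99] == expect[99])

    def test_invalid_parameters(self, tiny_panel):
        cells = _cells_with_intensity(tiny_panel, [1.0, 2.0])
        with pytest.raises(ParameterError):
            es.transform_intensities(cells, cofactor=0.0)
        with pytest.raises(ParameterError):
            es.transform_intensities(cells, clip_quantile=0.4)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 1e4), min_size=3, max_size=40))
    def test_monotone_below_clip(self, tiny_panel, values):
        cells = _cells_with_intensity(tiny_panel, values)
        out = es.transform_intensities(cells, clip_quantile=1.0)
        x = out.df["m1"].to_numpy()
        raw = np.asarray(values)
        order = np.argsort(raw, kind="stable")
        # raw order is preserved by the transform (monotone per channel)
        assert (np.diff(x[order]) >= -1e-12).all()


class TestBatchCorrection:
    def test_single_batch_identity(self, tiny_panel):
        cells = _cells_with_intensity(tiny_panel, [1.0, 2.0, 3.0])
        cells = es.transform_intensities(cells)
        out = es.correct_batches(cells)
        pd.testing.assert_frame_equal(out.df, cells.df)

    def test_planted_shift_removed_exactly(self, tiny_panel):
        rng = np.random.default_rng(0)
        base = rng.uniform(size=50)
        df = pd.DataFrame(
            {
                "x": 0.0,
                "y": 0.0,
                "roi_id": ["R1"] * 25 + ["R2"] * 25,
                "patient_id": ["P1"] * 25 + ["P2"] * 25,
                "m1": np.concatenate([base[:25], base[25:] + 0.7]),
            }
        )
        cells = make_cells(df, tiny_panel, raw=False)
        out = es.correct_batches(cells, batch_key="patient_id")
        means = out.df.groupby("patient_id")["m1"].mean()
        assert abs(means["P1"] - means["P2"]) < 1e-10

    def test_within_batch_rank_order_preserved(self, tiny_panel):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "x": 0.0,
                "y": 0.0,
                "roi_id": ["R1"] * 30 + ["R2"] * 30,
                "patient_id": ["P1"] * 30 + ["P2"] * 30,
                "m1": rng.uniform(size=60),
            }
        )
        cells = make_cells(df, tiny_panel, raw=False)
        out = es.correct_batches(cells, batch_key="patient_id")
        for pat in ("P1", "P2"):
            a = cells.df.loc[cells.df["patient_id"] == pat, "m1"].rank()
            b = out.df.loc[out.df["patient_id"] == pat, "m1"].rank()
            pd.testing.assert_series_equal(a, b)

    def test_singleton_batch_warns(self, tiny_panel):
        df = pd.DataFrame(
            {"x": [0.0, 0.0, 0.0], "y": 0.0, "m1": [1.0, 2.0, 3.0],
             "roi_id": ["R1", "R1", "R2"], "patient_id": ["P1", "P1", "P2"]}
        )
        cells = make_cells(df, tiny_panel, raw=False)
        with pytest.warns(UserWarning, match="single cell"):
            es.correct_batches(cells, batch_key="patient_id")

    def test_batch_centroid_distance_reduced(self, small_cohort):
        cells, _, _ = small_cohort
        t = es.transform_intensities(cells)
        corrected = es.correct_batches(t)
        markers = cells.panel.markers

        def spread(tbl):
            cent = tbl.df.groupby("patient_id")[markers].mean()
            return np.linalg.norm(cent - cent.mean(axis=0), axis=1).mean()

        assert spread(corrected) <= 0.1 * spread(t)


class TestClustering:
    def test_two_separated_blobs(self, tiny_panel):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "x": 0.0,
                "y": 0.0,
                "m1": np.concatenate([rng.normal(0, 0.05, 500), rng.normal(1, 0.05, 500)]),
                "m2": np.concatenate([rng.normal(1, 0.05, 500), rng.normal(0, 0.05, 500)]),
            }
        )
        cells = make_cells(df, tiny_panel, raw=False)
        labels = es.cluster_phenotypes(cells, markers=["m1", "m2"], k_neighbors=15,
                                       target_k=2, seed=0)
        planted = np.repeat([0, 1], 500)
        assert adjusted_rand_score(planted, labels) == 1.0

    def test_identical_cells_single_cluster(self, tiny_panel):
        df = pd.DataFrame({"x": 0.0, "y": 0.0, "m1": np.ones(100), "m2": np.ones(100)})
        cells = make_cells(df, tiny_panel, raw=False)
        labels = es.cluster_phenotypes(cells, markers=["m1", "m2"], k_neighbors=10, seed=0)
        assert len(np.unique(labels)) == 1

    def test_k_neighbors_bounds(self, tiny_panel):
        df = pd.DataFrame({"x": 0.0, "y": 0.0, "m1": [1.0, 2.0], "m2": [1.0, 2.0]})
        cells = make_cells(df, tiny_panel, raw=False)
        with pytest.raises(ParameterError):
            es.cluster_phenotypes(cells, markers=["m1"], k_neighbors=5)


class TestAnnotation:
    @pytest.fixture
    def signatures(self):
        return SignatureTable(
            pd.DataFrame(
                {
                    "E-cadherin": [1.0, 0.0, 0.1],
                    "panCK": [1.0, 0.0, 0.1],
                    "CD45": [0.0, 1.0, 0.1],
                },
                index=["epithelial", "immune", "other_sig"],
            )
        )

    def test_epithelial_profile(self, signatures):
        profiles = pd.DataFrame(
            {"E-cadherin": [0.9], "panCK": [0.8], "CD45": [0.05]}, index=[0]
        )
        out = annotate_clusters(profiles, signatures)
        assert out.loc[0, "phenotype"] == "epithelial"

    def test_zero_profile_is_other(self, signatures):
        profiles = pd.DataFrame({"E-cadherin": [0.0], "panCK": [0.0], "CD45": [0.0]})
        out = annotate_clusters(profiles, signatures)
        assert out.loc[0, "phenotype"] == "other"

    def test_tie_breaks_alphabetically_with_flag(self):
        sigs = SignatureTable(
            pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]}, index=["zeta", "alpha"])
        )
        profiles = pd.DataFrame({"a": [1.0], "b": [1.0]})
        out = annotate_clusters(profiles, sigs)
        assert out.loc[0, "phenotype"] == "alpha"
        assert bool(out.loc[0, "tie"])

    def test_empty_marker_overlap_raises(self, signatures):
        profiles = pd.DataFrame({"nope": [1.0]})
        with pytest.raises(ConfigError):
            annotate_clusters(profiles, signatures)

    def test_signature_validation(self):
        with pytest.raises(ValidationError):
            SignatureTable(pd.DataFrame({"a": [-1.0]}, index=["x"]))
        with pytest.raises(ValidationError):
            SignatureTable(pd.DataFrame({"a": [0.0]}, index=["x"]))


def test_full_chain_recovers_planted_phenotypes(small_cohort):
    """Transform -> batch-correct -> cluster -> annotate recovers the
    planted phenotypes (ARI >= 0.9) and per-ROI frequencies (MAE < 0.03)."""
    cells, _, truth = small_cohort
    t = es.correct_batches(es.transform_intensities(cells))
    ann = es.assign_phenotypes(t, es.signature_table(), target_k=10, seed=0)
    ari = adjusted_rand_score(truth.cells["phenotype"], ann.df["phenotype"])
    assert ari >= 0.9
    got = (
        ann.df.groupby("roi_id")["phenotype"].value_counts(normalize=True).unstack(fill_value=0)
    )
    want = (
        truth.cells.groupby("roi_id")["phenotype"].value_counts(normalize=True)
        .unstack(fill_value=0)
    )
    got, want = got.align(want, fill_value=0.0)
    assert (got - want).abs().to_numpy().mean() < 0.03


def test_recluster_subgroups_refines_major_groups(tiny_panel):
    rng = np.random.default_rng(3)
    # one major blob containing two sub-blobs separated only on m3
    df = pd.DataFrame(
        {
            "x": 0.0,
            "y": 0.0,
            "m1": rng.normal(1, 0.05, 400),
            "m2": rng.normal(0, 0.05, 400),
            "m3": np.concatenate([rng.normal(0, 0.05, 200), rng.normal(1, 0.05, 200)]),
        }
    )
    cells = make_cells(df, tiny_panel, raw=False)
    major = np.zeros(400, int)
    out = es.preprocess.recluster_subgroups(cells, major, {0: ["m3"]}, k_neighbors=15,
                                            target_k=2, seed=0)
    assert len(np.unique(out)) == 2
    assert all(lbl.startswith("0.") for lbl in out)
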
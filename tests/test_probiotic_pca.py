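"""Retention fractions, standardization and PCA algebra."""

import numpy as np
import pandas as pd
import pytest

from probiosurf.probiotic_pca import (
    FEATURE_COLUMNS,
    StressPanel,
    build_feature_matrix,
    pca,
    read_panel_tsv,
    retention_fraction,
    run_pca_pipeline,
    zscore_columns,
)
from probiosurf.synthetic_data import generate_stress_panel


def make_panel(iso, deltas, halo):
    return StressPanel(
        isolate_id=iso,
        log_cfu_initial={s: 8.0 for s in ("acid", "bile", "lysozyme")},
        log_cfu_final={s: 8.0 + d for s, d in deltas.items()},
        antagonism_mm=halo,
    )


class TestRetention:
    @pytest.mark.parametrize(
        "li,lf,expected",
        [(8.0, 8.0, 1.0), (8.0, 7.0, 0.1), (8.0, 8.0 - 0.30103, 0.5), (5.0, 6.0, 10.0)],
    )
    def test_known_fractions(self, li, lf, expected):
        assert retention_fraction(li, lf) == pytest.approx(expected, rel=1e-5)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            retention_fraction(float("nan"), 8.0)


class TestFeatureMatrix:
    def test_shape_and_column_order(self):
        panels = [
            make_panel("M1", {"acid": -1, "bile": -1, "lysozyme": -1}, 5.0),
            make_panel("M2", {"acid": -0.5, "bile": -0.2, "lysozyme": -0.1}, 9.0),
            make_panel("M4", {"acid": -2, "bile": -1.5, "lysozyme": -1.2}, 4.0),
        ]
        m = build_feature_matrix(panels)
        assert m.shape == (3, 4)
        assert tuple(m.columns) == FEATURE_COLUMNS
        assert list(m.index) == ["M1", "M2", "M4"]
        assert (m[list(FEATURE_COLUMNS[1:])] > 0).all().all()

    def test_missing_stressor_names_isolate(self):
        good = make_panel("M2", {"acid": -1, "bile": -1, "lysozyme": -1}, 5.0)
        bad = StressPanel("M1", {"acid": 8.0}, {"acid": 7.0}, 5.0)
        with pytest.raises(ValueError, match="isolate M1: bile"):
            build_feature_matrix([good, bad])

    def test_single_isolate_rejected(self):
        with pytest.raises(ValueError):
            build_feature_matrix([make_panel("M1", {"acid": -1, "bile": -1, "lysozyme": -1}, 5)])


class TestZscore:
    def test_population_sd_hand_example(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 9.0]})
        z = zscore_columns(m)
        assert z["a"].tolist() == pytest.approx([-1.224745, 0.0, 1.224745], abs=1e-6)

    def test_postconditions_and_idempotence(self, rng):
        m = pd.DataFrame(rng.normal(5, 3, size=(20, 4)), columns=list(FEATURE_COLUMNS))
        z = zscore_columns(m)
        assert np.all(np.abs(z.mean(axis=0)) < 1e-12)
        assert np.allclose(z.std(ddof=0, axis=0), 1.0, atol=1e-12)
        assert np.allclose(zscore_columns(z).to_numpy(), z.to_numpy(), atol=1e-12)

    def test_constant_column_rejected(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="a"):
            zscore_columns(m)


class TestPCA:
    def test_reconstruction_and_orthonormality(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, size=(10, 4)), columns=list(FEATURE_COLUMNS))
        z = zscore_columns(m)
        result = pca(z)
        loadings = result.loadings.to_numpy()
        assert np.allclose(loadings.T @ loadings, np.eye(loadings.shape[1]), atol=1e-9)
        centered = z.to_numpy() - z.to_numpy().mean(axis=0)
        recon = result.scores.to_numpy() @ loadings.T
        assert np.max(np.abs(recon - centered)) < 1e-9

    def test_matches_svd_oracle_eigenvalues(self, rng):
        """Explained-variance ratios equal normalized squared singular values."""
        m = pd.DataFrame(rng.normal(0, 1, size=(12, 4)), columns=list(FEATURE_COLUMNS))
        z = zscore_columns(m)
        centered = z.to_numpy() - z.to_numpy().mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        ref = sv**2 / np.sum(sv**2)
        assert np.allclose(result_ratios := pca(z).explained_variance_ratio, ref, atol=1e-9)
        assert np.all(np.diff(result_ratios) <= 1e-12)  # sorted non-increasing
        assert np.sum(result_ratios) == pytest.approx(1.0, abs=1e-9)

    def test_three_isolates_give_at_most_two_components(self):
        panels = generate_stress_panel(3, {"dominant": "M2"}, seed=3)
        result = run_pca_pipeline(panels)
        assert np.count_nonzero(result.explained_variance_ratio) <= 2

    def test_rank_one_matrix_pc1_ratio_is_one(self):
        base = np.array([1.0, -1.0, 2.0, 0.5])
        m = pd.DataFrame(np.outer([1.0, 2.0, 4.0], base), columns=list(FEATURE_COLUMNS))
        result = pca(m)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(result.explained_variance_ratio[1:] == 0.0)

    def test_sign_convention_largest_loading_positive(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, size=(8, 4)), columns=list(FEATURE_COLUMNS))
        result = pca(zscore_columns(m))
        for col in result.loadings.columns:
            v = result.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_row_permutation_invariance(self, rng):
        m = pd.DataFrame(
            rng.normal(0, 1, size=(9, 4)),
            columns=list(FEATURE_COLUMNS),
            index=[f"M{i}" for i in range(9)],
        )
        z = zscore_columns(m)
        perm = z.sample(frac=1.0, random_state=5)
        a, b = pca(z), pca(perm)
        assert np.allclose(
            a.scores.loc[z.index].to_numpy(), b.scores.loc[z.index].to_numpy(), atol=1e-9
        )
        assert np.allclose(a.loadings.to_numpy(), b.loadings.to_numpy(), atol=1e-9)

    def test_dominant_isolate_extreme_on_pc1_with_consonant_loadings(self):
        panels = generate_stress_panel(3, {"dominant": "M2"}, seed=11)
        result = run_pca_pipeline(panels)
        pc1 = result.scores["PC1"]
        assert abs(pc1["M2"]) == pytest.approx(pc1.abs().max())
        signs = np.sign(result.loadings["PC1"].to_numpy())
        assert np.all(signs == signs[0])
        # the dominant isolate sits on the same side the variables point to
        assert np.sign(pc1["M2"]) == signs[0]


class TestPanelIO:
    def test_tsv_round_trip(self, tmp_path):
        panels = generate_stress_panel(3, {"dominant": "M2"}, seed=1)
        rows = []
        for p in panels:
            for s in sorted(p.log_cfu_initial):
                rows.append(
                    {
                        "isolate": p.isolate_id,
                        "stressor": s,
                        "log_cfu_initial": p.log_cfu_initial[s],
                        "log_cfu_final": p.log_cfu_final[s],
                        "antagonism_mm": p.antagonism_mm,
                    }
                )
        path = tmp_path / "panel.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        back = read_panel_tsv(path)
        assert [p.isolate_id for p in back] == [p.isolate_id for p in panels]
        m1 = build_feature_matrix(panels)
        m2 = build_feature_matrix(back)
        assert np.allclose(m1.to_numpy(), m2.to_numpy(), atol=1e-12)
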
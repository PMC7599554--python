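"""Voxel fields, the NIPALS PLS core against oracles, statistics, maps."""

import numpy as np
import pytest

from agelascreen import qsar
from agelascreen.chem import generate_conformers, parse_structure
from agelascreen.qsar import (FIELD_CLASSES, GridFrame, VoxelField, build_field,
                              choose_components, contribution_map, export_dx,
                              fit_pls, fit_statistics, make_frame,
                              predict_activity)

from conftest import SEED


def synthetic_fields(n, shape=(4, 4, 4), seed=0, noise=0.0, beta=None,
                     n_active=None):
    """Random voxel fields with a planted linear activity.

    With ``n_active`` set, only that many voxel columns vary (the rest are
    zero and get dropped by the variance filter), giving a well-posed
    parameter-recovery problem; otherwise every column is random.
    """
    rng = np.random.default_rng(seed)
    frame = GridFrame(origin=(0.0, 0.0, 0.0), spacing=0.5, shape=shape)
    p = int(np.prod(shape)) * len(FIELD_CLASSES)
    if n_active is None:
        X = rng.normal(size=(n, p))
        if beta is None:
            beta = rng.normal(size=p)
    else:
        X = np.zeros((n, p))
        active = rng.choice(p, size=n_active, replace=False)
        X[:, active] = rng.normal(size=(n, n_active))
        if beta is None:
            beta = np.zeros(p)
            beta[active] = rng.normal(size=n_active)
    y = X @ beta + noise * rng.normal(size=n)
    fields = []
    for row in X:
        blocks, off = {}, 0
        for cls in FIELD_CLASSES:
            m = int(np.prod(shape))
            blocks[cls] = row[off:off + m].reshape(shape)
            off += m
        fields.append(VoxelField(frame=frame, blocks=blocks))
    return fields, y, beta


@pytest.fixture(scope="module")
def mol_conf():
    m = parse_structure("ClC(Cl)Cl", "chloroform")
    cs = generate_conformers(m, seed=SEED)
    return m, cs.heavy_coords(0)


class TestBuildField:
    def test_methane_blocks(self):
        m = parse_structure("C", "methane")
        frame = make_frame([np.zeros((1, 3))])
        f = build_field(m, np.zeros((1, 3)), frame)
        assert f.blocks["hydrophobic"].sum() > 0
        assert f.blocks["donor"].sum() == 0

    def test_frame_covariance(self, mol_conf):
        m, coords = mol_conf
        t = np.array([2.0, -1.0, 3.0])
        f1 = build_field(m, coords, make_frame([coords]))
        frame2 = GridFrame(
            origin=tuple(np.asarray(f1.frame.origin) + t),
            spacing=f1.frame.spacing, shape=f1.frame.shape)
        f2 = build_field(m, coords + t, frame2)
        for cls in FIELD_CLASSES:
            np.testing.assert_allclose(f1.blocks[cls], f2.blocks[cls], atol=1e-9)

    def test_charge_conservation(self, mol_conf):
        """The smearing kernel distributes each atom's charge, so the
        electrostatic block totals the molecular net charge (zero here)."""
        m, coords = mol_conf
        f = build_field(m, coords, make_frame([coords]))
        assert f.blocks["electrostatic"].sum() == pytest.approx(0.0, abs=1e-6)

    def test_out_of_frame_error(self, mol_conf):
        m, coords = mol_conf
        frame = make_frame([coords])
        with pytest.raises(ValueError):
            build_field(m, coords + 100.0, frame)


class TestPlsCore:
    def test_perfect_single_voxel_signal(self):
        """One informative voxel, y linear in it: a single component fits
        exactly."""
        fields, _, _ = synthetic_fields(8, seed=1, n_active=1)
        X = np.vstack([f.unfold() for f in fields])
        col = np.flatnonzero(X.var(axis=0))[0]
        y = 2.0 * X[:, col] + 1.0
        model = fit_pls(fields, y, n_components=1)
        assert model.stats.r2 == pytest.approx(1.0, abs=1e-8)

    def test_ols_equivalence_at_full_rank(self):
        """With p < n and components = p, PLS equals ordinary least squares."""
        rng = np.random.default_rng(2)
        n, p = 12, 5
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + 0.01 * rng.normal(size=n)
        Xc, yc = X - X.mean(0), y - y.mean()
        _, _, _, _, coef = qsar._nipals_pls1(Xc, yc, p)
        ols = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        np.testing.assert_allclose(coef, ols, atol=1e-8)

    def test_score_orthogonality(self):
        fields, y, _ = synthetic_fields(10, seed=3, noise=0.1)
        model = fit_pls(fields, y, n_components=4)
        T = model.scores
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_sklearn_cross_check(self):
        """Independent reference: scikit-learn's PLSRegression on the same
        centered data gives the same regression vector."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(4)
        n, p, k = 15, 40, 3
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + 0.05 * rng.normal(size=n)
        _, _, _, _, coef = qsar._nipals_pls1(X - X.mean(0), y - y.mean(), k)
        sk = PLSRegression(n_components=k, scale=False).fit(X, y)
        np.testing.assert_allclose(coef, sk.coef_.ravel(), atol=1e-6)

    def test_r2_nondecreasing_in_components(self):
        fields, y, _ = synthetic_fields(10, seed=5, noise=0.2)
        r2 = [fit_pls(fields, y, n_components=k).stats.r2 for k in (1, 2, 3, 4)]
        assert all(b >= a - 1e-10 for a, b in zip(r2, r2[1:]))

    def test_coefficient_recovery(self):
        """Planted linear coefficients are recovered (r > 0.95) from noisy
        synthetic fields (n = 20, sigma = 0.05)."""
        fields, y, beta = synthetic_fields(20, seed=6, noise=0.05, n_active=6)
        model = fit_pls(fields, y, n_components=6)
        full = np.zeros(model.col_mask.size)
        full[model.col_mask] = model.coef
        r = np.corrcoef(full, beta)[0, 1]
        assert r > 0.95

    def test_component_count_errors(self):
        fields, y, _ = synthetic_fields(5, seed=7)
        with pytest.raises(ValueError):
            fit_pls(fields, y, n_components=5)
        with pytest.raises(ValueError):
            fit_pls(fields[:2], y[:2], n_components=1)


class TestStatistics:
    def test_hand_arithmetic(self):
        y = np.array([1.0, 2.0, 3.0])
        yhat = np.array([1.1, 2.0, 2.9])
        resid = y - yhat
        ss_res = float(resid @ resid)
        assert ss_res == pytest.approx(0.02)
        r2 = 1 - ss_res / 2.0
        assert r2 == pytest.approx(0.99)
        rmse = np.sqrt(ss_res / 3)
        assert rmse == pytest.approx(0.0816, abs=1e-4)

    def test_perfect_fit_stats(self):
        fields, _, _ = synthetic_fields(8, seed=8, n_active=2)
        X = np.vstack([f.unfold() for f in fields])
        col = np.flatnonzero(X.var(axis=0))[0]
        y = X[:, col] * 1.5 - 0.5
        model = fit_pls(fields, y, n_components=2)
        s = fit_statistics(model, fields, y)
        assert s.r2 == pytest.approx(1.0, abs=1e-8)
        assert s.rmse == pytest.approx(0.0, abs=1e-6)
        assert s.pearson == pytest.approx(1.0, abs=1e-8)

    def test_zero_variance_activity_error(self):
        fields, y, _ = synthetic_fields(6, seed=9)
        model = fit_pls(fields, y, n_components=1)
        with pytest.raises(ValueError):
            fit_statistics(model, fields, np.ones(6))


class TestPredictionAndMaps:
    def test_training_members_reproduce_fitted_values(self):
        fields, y, _ = synthetic_fields(8, seed=10, noise=0.3)
        model = fit_pls(fields, y, n_components=2)
        yhat = np.array([predict_activity(model, f) for f in fields])
        # residuals sum to ~0 (centered fit)
        assert yhat.mean() == pytest.approx(y.mean(), abs=1e-8)

    def test_zero_field_predicts_intercept_like_value(self):
        fields, y, _ = synthetic_fields(8, seed=11)
        model = fit_pls(fields, y, n_components=2)
        zero = VoxelField(frame=fields[0].frame,
                          blocks={c: np.zeros(fields[0].frame.shape)
                                  for c in FIELD_CLASSES})
        expected = model.y_mean - model.x_mean @ model.coef
        assert predict_activity(model, zero) == pytest.approx(expected, abs=1e-9)

    def test_prediction_linearity(self):
        fields, y, _ = synthetic_fields(8, seed=12)
        model = fit_pls(fields, y, n_components=2)
        f = fields[0]
        f2 = VoxelField(frame=f.frame,
                        blocks={c: 2 * f.blocks[c] for c in FIELD_CLASSES})
        p0 = predict_activity(model, VoxelField(
            frame=f.frame, blocks={c: np.zeros(f.frame.shape)
                                   for c in FIELD_CLASSES}))
        assert predict_activity(model, f2) - p0 == pytest.approx(
            2 * (predict_activity(model, f) - p0), abs=1e-8)

    def test_frame_mismatch_error(self):
        fields, y, _ = synthetic_fields(8, seed=13)
        model = fit_pls(fields, y, n_components=2)
        other = GridFrame(origin=(9.0, 9.0, 9.0), spacing=0.5, shape=(4, 4, 4))
        bad = VoxelField(frame=other, blocks={c: np.zeros((4, 4, 4))
                                              for c in FIELD_CLASSES})
        with pytest.raises(ValueError):
            predict_activity(model, bad)

    def test_planted_two_voxel_signal_signs(self, tmp_path):
        """A +/- two-voxel signal reappears with both signs in the exported
        contribution map, and the top voxel is the strongest planted one."""
        frame = GridFrame(origin=(0.0, 0.0, 0.0), spacing=0.5, shape=(3, 3, 3))
        rng = np.random.default_rng(14)
        fields, ys = [], []
        for _ in range(12):
            blocks = {c: np.zeros((3, 3, 3)) for c in FIELD_CLASSES}
            a, b = rng.normal(), rng.normal()
            blocks["hydrophobic"][0, 0, 0] = a
            blocks["donor"][2, 2, 2] = b
            fields.append(VoxelField(frame=frame, blocks=blocks))
            ys.append(3.0 * a - 2.0 * b)
        model = fit_pls(fields, np.array(ys), n_components=2)
        lattices, summary = contribution_map(model, out_dir=tmp_path, top_n=5)
        assert lattices["hydrophobic"][0, 0, 0] > 0
        assert lattices["donor"][2, 2, 2] < 0
        assert summary[0]["class"] == "hydrophobic"
        assert (tmp_path / "coef_hydrophobic.dx").exists()
        dx_text = (tmp_path / "coef_hydrophobic.dx").read_text()
        assert "gridpositions counts 3 3 3" in dx_text

    def test_constant_fields_give_empty_map(self):
        frame = GridFrame(origin=(0.0, 0.0, 0.0), spacing=0.5, shape=(2, 2, 2))
        fields = [VoxelField(frame=frame,
                             blocks={c: np.ones((2, 2, 2))
                                     for c in FIELD_CLASSES})
                  for _ in range(5)]
        model = fit_pls(fields, np.arange(5.0), n_components=1)
        _, summary = contribution_map(model)
        assert summary == []

    def test_choose_components_plateau(self):
        fields, _, _ = synthetic_fields(10, seed=15)
        X = np.vstack([f.unfold() for f in fields])
        y = X[:, 0] + 0.5 * X[:, 1]
        k = choose_components(fields, y, max_components=7)
        assert 1 <= k <= 3  # a 2-factor signal plateaus early
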
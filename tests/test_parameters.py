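"""INI parameter extraction / PCA normalcy score and the MGS."""

import numpy as np
import pandas as pd
import pytest

from gaitsm.io import TrialRecording, segment_cycles, SENSOR_CONFIGURATIONS
from gaitsm.parameters import (
    DEFAULT_MGS_REGISTRY,
    INI_PARAMETERS,
    MGSRegistry,
    extract_ini_parameters,
    fit_pca_basis,
    ini_parameter_table,
    ini_score,
    mgs_parameters,
    mgs_score,
)


def programmed_cycle_recording():
    """One 1.2 s cycle with analytically known spatiotemporal geometry.

    Contact at sample 0 and 120 (100 Hz), toe-off at 60% of the cycle,
    swing arc apex 0.12 m above the stance height at 30 cm of forward travel.
    """
    rate, T = 100.0, 140
    t = np.arange(T)
    phase = t / 120.0
    st = 0.6
    swing = np.clip((phase - st) / (1 - st), 0.0, 1.0)
    x = 1.2 * swing**2 * (3 - 2 * swing)
    z = 0.05 + 0.12 * np.sin(np.pi * swing) ** 2
    pos = np.vstack([x, np.zeros(T), z])
    shank = 20.0 * np.sin(2 * np.pi * phase)
    abd = 5.0 * np.sin(2 * np.pi * phase) - 1.0
    return TrialRecording(
        participant_id="PRG",
        group="TT",
        rate=rate,
        sensors={"pelvis": np.zeros((6, T))},
        kinematics={"shank_angle_left": shank, "ankle_abduction_left": abd},
        positions={"ankle_left": pos},
        events=[(0, "left"), (120, "left")],
        toe_offs=[(72, "left")],
        passes=[(0, T)],
        prosthetic_side="left",
    ).validate()


class TestExtraction:
    def test_programmed_geometry_recovered(self):
        rec = programmed_cycle_recording()
        p = extract_ini_parameters(rec, 0, 120, "left")
        assert p.GD == pytest.approx(1.2)
        assert p.PSP == pytest.approx(40.0)
        assert p.MH == pytest.approx(0.12, abs=1e-3)
        apex = int(np.argmax(rec.positions["ankle_left"][2, :120]))
        assert p.MHD == pytest.approx(rec.positions["ankle_left"][0, apex], abs=1e-9)
        assert p.SL == pytest.approx(rec.positions["ankle_left"][0, 119], abs=1e-9)
        assert p.MAB == pytest.approx(4.0, abs=0.05)   # 5 sin - 1, max within cycle
        assert p.MAD == pytest.approx(6.0, abs=0.05)   # minus the minimum
        assert p.SRM > 0

    def test_missing_stream_names_blocked_parameter(self):
        rec = programmed_cycle_recording()
        del rec.positions["ankle_left"]
        with pytest.raises(ValueError, match="SL/MV/MH/MHD"):
            extract_ini_parameters(rec, 0, 120, "left")

    def test_missing_toe_off_blocks_psp(self):
        rec = programmed_cycle_recording()
        rec.toe_offs = []
        with pytest.raises(ValueError, match="PSP"):
            extract_ini_parameters(rec, 0, 120, "left")

    def test_participant_table_on_synthetic(self, patient_recording):
        table = ini_parameter_table(patient_recording, side="prosthetic")
        assert list(table.columns) == list(INI_PARAMETERS)
        assert len(table) > 5
        assert (table["GD"] > 0).all()
        assert table["PSP"].between(0, 100).all()


class TestINIScore:
    def _normative(self, rng, n=300, p=4):
        A = rng.normal(0, 1, (p, p))
        X = rng.normal(0, 1, (n, p)) @ A + rng.normal(0, 1, p)
        return pd.DataFrame(X, columns=[f"p{i}" for i in range(p)])

    def test_zero_at_normative_mean(self):
        rng = np.random.default_rng(0)
        norm = self._normative(rng)
        basis = fit_pca_basis(norm)
        assert ini_score(norm.mean().to_frame().T, basis) == pytest.approx(0.0, abs=1e-9)

    def test_identity_covariance_reduces_to_znorm(self):
        # 2-D toy whose normative covariance is exactly the identity
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(60, 2))
        raw -= raw.mean(axis=0)
        # exact whitening so the sample covariance (ddof=1) is identity
        C = np.cov(raw, rowvar=False, ddof=1)
        raw = raw @ np.linalg.inv(np.linalg.cholesky(C)).T
        norm = pd.DataFrame(raw, columns=["a", "b"])
        basis = fit_pca_basis(norm)
        point = pd.DataFrame([[1.2, -0.7]], columns=["a", "b"])
        assert ini_score(point, basis) == pytest.approx(np.hypot(1.2, -0.7), abs=1e-9)

    def test_equals_mahalanobis_distance(self):
        rng = np.random.default_rng(2)
        norm = self._normative(rng, n=200, p=5)
        basis = fit_pca_basis(norm)
        x = norm.iloc[[7]]
        z = (x.to_numpy() - norm.mean().to_numpy()) / norm.std(ddof=1).to_numpy()
        R = np.corrcoef((norm - norm.mean()).to_numpy(), rowvar=False)
        maha = float(np.sqrt((z @ np.linalg.inv(R) @ z.T).item()))
        assert ini_score(x, basis) == pytest.approx(maha, abs=1e-9)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        norm = self._normative(rng, n=150, p=3)
        x = pd.DataFrame(rng.normal(0, 2, (1, 3)), columns=norm.columns)
        base = ini_score(x, fit_pca_basis(norm))
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rot = lambda df: pd.DataFrame(df.to_numpy() @ Q, columns=norm.columns)
        rotated = ini_score(rot(x), fit_pca_basis(rot(norm)))
        assert rotated == pytest.approx(base, rel=1e-9)

    def test_zero_sd_rejected(self):
        norm = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="zero normative SD"):
            fit_pca_basis(norm)


def correlated_table(rng, n=40):
    """3 standardized columns whose sample correlation has eigenvalues 2, .7, .3."""
    t, s = np.sqrt(0.35), 0.3
    R = np.array([[1, t, t], [t, 1, s], [t, s, 1]])
    raw = rng.normal(size=(n, 3))
    raw -= raw.mean(axis=0)
    C = np.cov(raw, rowvar=False, ddof=1)
    white = raw @ np.linalg.inv(np.linalg.cholesky(C)).T
    X = white @ np.linalg.cholesky(R).T
    return pd.DataFrame(X, columns=["amp", "tem", "reg"])


class TestMGS:
    def test_eigenvalue_threshold_retains_one_component(self):
        basis = fit_pca_basis(correlated_table(np.random.default_rng(0)))
        np.testing.assert_allclose(
            np.sort(basis.eigenvalues), [0.3, 0.7, 2.0], atol=1e-9
        )
        assert int((basis.eigenvalues >= 1.0).sum()) == 1

    def test_zero_at_normative_mean(self):
        rng = np.random.default_rng(1)
        norm = correlated_table(rng)
        registry = MGSRegistry(
            aspects={"amplitude": ("amp",), "temporal": ("tem",), "regularity": ("reg",)}
        )
        table = pd.concat(
            [norm, norm.mean().to_frame().T.set_axis(["subject"])], axis=0
        )
        overall, aspects, _ = mgs_score(table, registry, normative_rows=list(norm.index))
        assert overall.loc["subject"] == pytest.approx(0.0, abs=1e-12)
        assert set(aspects.columns) == {"amplitude", "temporal", "regularity"}

    def test_saturation_at_z_cap(self):
        rng = np.random.default_rng(2)
        norm = correlated_table(rng)
        registry = MGSRegistry(aspects={"amplitude": ("amp",), "temporal": ("tem",)})
        far = norm.mean() + 100 * norm.std(ddof=1)
        table = pd.concat([norm, far.to_frame().T.set_axis(["far"])], axis=0)
        overall, _, _ = mgs_score(table, registry, normative_rows=list(norm.index))
        assert overall.loc["far"] == pytest.approx(1.0)

    def test_scale_invariance_of_units(self):
        rng = np.random.default_rng(3)
        norm = correlated_table(rng)
        subj = pd.DataFrame(
            rng.normal(0, 2, (4, 3)), columns=norm.columns,
            index=[f"s{i}" for i in range(4)],
        )
        table = pd.concat([norm, subj])
        base, _, _ = mgs_score(table, normative_rows=list(norm.index),
                               registry=MGSRegistry(aspects={
                                   "amplitude": ("amp",), "temporal": ("tem",),
                                   "regularity": ("reg",)}))
        scaled = table.copy()
        scaled["amp"] = scaled["amp"] * 1000 + 5
        res, _, _ = mgs_score(scaled, normative_rows=list(norm.index),
                              registry=MGSRegistry(aspects={
                                  "amplitude": ("amp",), "temporal": ("tem",),
                                  "regularity": ("reg",)}))
        pd.testing.assert_series_equal(base, res, atol=1e-9)

    def test_missing_aspect_warns_and_is_omitted(self):
        rng = np.random.default_rng(4)
        norm = correlated_table(rng)
        registry = MGSRegistry(
            aspects={"amplitude": ("amp",), "complexity": ("sample_entropy",)}
        )
        with pytest.warns(RuntimeWarning, match="complexity"):
            overall, aspects, _ = mgs_score(
                norm, registry, normative_rows=list(norm.index)
            )
        assert list(aspects.columns) == ["amplitude"]

    def test_parameter_vector_on_synthetic(self, patient_recording, lower_cfg):
        cycles = segment_cycles(patient_recording, "prosthetic", lower_cfg)
        params = mgs_parameters(patient_recording, cycles)
        assert set(DEFAULT_MGS_REGISTRY.parameters) <= set(params.index)
        assert np.isfinite(params[DEFAULT_MGS_REGISTRY.parameters].to_numpy()).all()
        assert params["cadence"] > 0
        assert 0 < params["swing_percent"] < 100
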
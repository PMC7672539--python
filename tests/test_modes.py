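"""Combined PCA, state partitioning, external projection and subspace overlap."""

import numpy as np
import pandas as pd
import pytest

from ensdyn.modes import (ModeSpace, combined_pca, mode_overlap,
                          partition_states, project_external,
                          variance_coverage)
from ensdyn.ensemble_io import CALPHA

from conftest import make_ensemble


def planted_system(rng, n_atoms, k):
    """A random base structure plus k orthonormal rigid-free mode fields.

    Rigid-body content is projected out of the modes so that superposition
    (which removes rigid motion) leaves the planted directions intact.
    """
    from ensdyn.synthetic import _rigid_basis

    base = rng.normal(scale=5.0, size=(n_atoms, 3))
    q = _rigid_basis(base)
    a = rng.normal(size=(3 * n_atoms, k))
    a -= q @ (q.T @ a)
    modes_q, _ = np.linalg.qr(a)
    return base, [modes_q[:, i] for i in range(k)]


def planted_ensemble(rng, n_models, base, modes, variances, noise=0.0,
                     state_label="", means=None):
    """Gaussian amplitudes along given orthonormal 3N modes, plus noise."""
    coords = np.tile(base.ravel(), (n_models, 1)).astype(float)
    for k, (u, v) in enumerate(zip(modes, variances)):
        amp = rng.normal(scale=np.sqrt(v), size=n_models)
        if means is not None:
            amp += means[k]
        coords += amp[:, None] * u[None]
    if noise:
        coords += rng.normal(scale=noise, size=coords.shape)
    return make_ensemble(coords.reshape(n_models, -1, 3), state_label=state_label)


def synthetic_mode_space(eigenvectors, eigenvalues, projections=None,
                         ensembles=None) -> ModeSpace:
    """Hand-assembled ModeSpace for operations that act on its fields only."""
    vec = np.asarray(eigenvectors, float)
    lam = np.asarray(eigenvalues, float)
    n_conf = 0 if projections is None else len(projections[0])
    table = {"ensemble": ensembles if ensembles is not None else ["e"] * n_conf,
             "replica": [-1] * n_conf, "model": list(range(n_conf))}
    for i in range(vec.shape[1]):
        table[f"pc{i + 1}"] = projections[i] if projections is not None else []
    return ModeSpace(mean=np.zeros((vec.shape[0] // 3, 3)), eigenvectors=vec,
                     eigenvalues=lam, total_variance=float(lam.sum()),
                     projections=pd.DataFrame(table))


class TestCombinedPCA:
    def test_single_planted_direction(self, rng):
        base, (u,) = planted_system(rng, 20, 1)
        e = planted_ensemble(rng, 200, base, [u], [2.0])
        m = combined_pca([e])
        assert m.n_modes == 1
        assert m.variance_fractions[0] == pytest.approx(1.0, rel=1e-9)
        assert abs(m.eigenvectors[:, 0] @ u) > 0.999

    def test_two_modes_variance_ratio(self, rng):
        """Planted orthogonal modes with 4:1 variances, n=808."""
        base, (u1, u2) = planted_system(rng, 20, 2)
        e = planted_ensemble(rng, 808, base, [u1, u2], [4.0, 1.0], noise=0.05)
        m = combined_pca([e])
        assert abs(m.eigenvectors[:, 0] @ u1) >= 0.95
        assert abs(m.eigenvectors[:, 1] @ u2) >= 0.95
        # eigenvalue ratio within sampling error (SE ~ sqrt(2/n)*sqrt(2) ~ 7%)
        assert m.eigenvalues[0] / m.eigenvalues[1] == pytest.approx(4.0, rel=0.25)

    def test_orthonormal_eigenvectors(self, rng):
        base, (u1, u2) = planted_system(rng, 10, 2)
        e = planted_ensemble(rng, 100, base, [u1, u2], [3.0, 1.0], noise=0.2)
        m = combined_pca([e])
        gram = m.eigenvectors.T @ m.eigenvectors
        np.testing.assert_allclose(gram, np.eye(m.n_modes), atol=1e-8)

    def test_eigenvalue_sum_equals_total_variance(self, rng):
        base, (u1, u2) = planted_system(rng, 8, 2)
        e = planted_ensemble(rng, 150, base, [u1, u2], [3.0, 1.0], noise=0.3)
        m = combined_pca([e])
        assert m.eigenvalues.sum() == pytest.approx(m.total_variance, rel=1e-6)

    def test_pooling_order_invariance(self, rng):
        base, (u1, u2) = planted_system(rng, 12, 2)
        a = planted_ensemble(rng, 60, base, [u1, u2], [3.0, 1.0], noise=0.2, state_label="cf")
        b = planted_ensemble(rng, 80, base, [u1, u2], [3.0, 1.0], noise=0.2, state_label="ff")
        m_ab = combined_pca([a, b])
        m_ba = combined_pca([b, a])
        np.testing.assert_allclose(m_ab.eigenvalues, m_ba.eigenvalues, rtol=1e-9)
        pa = m_ab.projections.query("ensemble == 'cf'").reset_index(drop=True)
        pb = m_ba.projections.query("ensemble == 'cf'").reset_index(drop=True)
        np.testing.assert_allclose(pa["pc1"], pb["pc1"], atol=1e-9)

    def test_layout_mismatch_error(self, rng, small_study):
        e1 = small_study.ensembles["ff"]
        base, (u,) = planted_system(rng, 4, 1)
        e2 = planted_ensemble(rng, 5, base, [u], [1.0])
        with pytest.raises(ValueError, match="mismatch|atoms"):
            combined_pca([e1, e2], CALPHA)


class TestVarianceCoverage:
    def test_single_mode_k10(self, rng):
        base, (u,) = planted_system(rng, 10, 1)
        m = combined_pca([planted_ensemble(rng, 50, base, [u], [2.0])])
        assert variance_coverage(m, 10)["pc1_share_of_first_k"] == pytest.approx(1.0)

    def test_hand_spectrum(self):
        m = synthetic_mode_space(np.eye(12)[:, :4], [4.0, 3.0, 2.0, 1.0])
        cov = variance_coverage(m, 4)
        assert cov["pc1_share_of_first_k"] == pytest.approx(0.4)
        assert cov["first_k_share_of_total"] == pytest.approx(1.0)

    def test_k_validation(self):
        m = synthetic_mode_space(np.eye(12)[:, :2], [2.0, 1.0])
        with pytest.raises(ValueError):
            variance_coverage(m, 0)


class TestPartition:
    @staticmethod
    def _space(p1, p2, ensembles=None, replicas=None):
        m = synthetic_mode_space(np.eye(12)[:, :2], [2.0, 1.0],
                                 projections=[list(p1), list(p2)],
                                 ensembles=ensembles)
        if replicas is not None:
            m.projections["replica"] = replicas
        return m

    def test_hand_listed_projections(self):
        part = partition_states(self._space([-1.0, 2.0, 3.0, -0.5], [1.0] * 4))
        row = part.occupancy.iloc[0]
        assert row["open"] == pytest.approx(0.5)
        assert row["closed"] == pytest.approx(0.5)

    def test_all_positive(self):
        part = partition_states(self._space([0.1, 2.0, 3.0], [1.0] * 3))
        assert part.occupancy.iloc[0]["open"] == pytest.approx(1.0)
        assert part.occupancy.iloc[0]["closed"] == pytest.approx(0.0)

    def test_threshold_tie_goes_negative(self):
        part = partition_states(self._space([0.0, 1.0], [0.0, -1.0]))
        labels = part.labels
        assert labels.loc[0, "mode1_state"] == "closed"  # exactly at threshold
        assert labels.loc[0, "mode2_state"] == "wide"

    def test_occupancy_sums_to_one(self):
        part = partition_states(self._space([-1, 1, 2, -2, 3], [1, -1, 2, -2, 3]))
        row = part.occupancy.iloc[0]
        assert row["open"] + row["closed"] == pytest.approx(1.0)
        assert row["narrow"] + row["wide"] == pytest.approx(1.0)

    def test_sign_correlated_co_occurrence(self):
        p1 = [1.0, -1.0, 2.0, -2.0]
        part = partition_states(self._space(p1, p1))
        assert part.co_occurrence["e"] == pytest.approx(1.0)
        # anti-correlated projections also give 1.0 under the symmetric rule
        part2 = partition_states(self._space(p1, [-x for x in p1]))
        assert part2.co_occurrence["e"] == pytest.approx(1.0)

    def test_mixture_occupancy_recovery(self, rng):
        """0.7/0.3 two-component mixture, means 3 SD apart, n=808."""
        base, (u1, u2) = planted_system(rng, 15, 2)
        comp = rng.random(808) < 0.7
        amp1 = np.where(comp, 3.0, -3.0) + rng.normal(scale=1.0, size=808)
        amp2 = rng.normal(scale=1.0, size=808)
        coords = (base.ravel()[None] + amp1[:, None] * u1[None] + amp2[:, None] * u2[None])
        e = make_ensemble(coords.reshape(808, 15, 3), state_label="ff")
        part = partition_states(combined_pca([e]))
        occ = part.occupancy.iloc[0]
        assert max(occ["open"], occ["closed"]) == pytest.approx(0.7, abs=0.05)

    def test_replica_occupancy_table(self):
        part = partition_states(self._space([1, -1, 2, -2], [1, 1, -1, -1],
                                            replicas=[0, 0, 1, 1]))
        rep = part.replica_occupancy
        assert rep is not None and len(rep) == 2
        assert set(rep["replica"]) == {0, 1}


class TestProjectExternal:
    @pytest.fixture
    def space(self, rng):
        base, (u1, u2) = planted_system(rng, 10, 2)
        e = planted_ensemble(rng, 120, base, [u1, u2], [3.0, 1.0], noise=0.1)
        return combined_pca([e]), e

    def test_mean_projects_to_zero(self, space):
        m, _ = space
        mean_e = make_ensemble(m.mean[None])
        np.testing.assert_allclose(project_external(m, mean_e), 0.0, atol=1e-9)

    def test_pooled_conformer_consistency(self, space):
        m, e = space
        proj = project_external(m, e.with_models([3]))
        stored = m.projection_matrix()[3]
        np.testing.assert_allclose(proj[0], stored, atol=1e-9)

    def test_constructed_displacement(self, space):
        m, _ = space
        ext = make_ensemble((m.mean.ravel() + 2.0 * m.eigenvectors[:, 0]).reshape(1, -1, 3))
        proj = project_external(m, ext)
        assert proj[0, 0] == pytest.approx(2.0, abs=1e-9)
        np.testing.assert_allclose(proj[0, 1:], 0.0, atol=1e-9)

    def test_atom_count_mismatch(self, space):
        m, _ = space
        with pytest.raises(ValueError, match="core"):
            project_external(m, make_ensemble(np.zeros((1, 4, 3))))


class TestOverlap:
    def test_self_overlap_identity(self, rng):
        u = np.linalg.qr(rng.normal(size=(30, 3)))[0]
        m = synthetic_mode_space(u, [3.0, 2.0, 1.0])
        rep = mode_overlap(m, m, 3)
        np.testing.assert_allclose(rep.overlap, np.eye(3), atol=1e-9)
        assert rep.rmsip == pytest.approx(1.0)

    def test_orthogonal_complements(self, rng):
        q = np.linalg.qr(rng.normal(size=(12, 4)))[0]
        a = synthetic_mode_space(q[:, :2], [2.0, 1.0])
        b = synthetic_mode_space(q[:, 2:], [2.0, 1.0])
        rep = mode_overlap(a, b, 2)
        np.testing.assert_allclose(rep.overlap, 0.0, atol=1e-9)
        assert rep.rmsip == pytest.approx(0.0, abs=1e-9)

    def test_in_plane_rotation(self, rng):
        """b = a rotated 45 deg within the top-2 plane: all overlaps sqrt(2)/2."""
        q = np.linalg.qr(rng.normal(size=(12, 2)))[0]
        c = np.sqrt(0.5)
        rotated = np.stack([c * q[:, 0] + c * q[:, 1],
                            -c * q[:, 0] + c * q[:, 1]], axis=1)
        a = synthetic_mode_space(q, [2.0, 1.0])
        b = synthetic_mode_space(rotated, [2.0, 1.0])
        rep = mode_overlap(a, b, 2)
        np.testing.assert_allclose(rep.overlap, c, atol=1e-9)
        assert rep.rmsip == pytest.approx(1.0, abs=1e-9)

    def test_dimension_mismatch(self, rng):
        a = synthetic_mode_space(np.eye(12)[:, :2], [2.0, 1.0])
        b = synthetic_mode_space(np.eye(9)[:, :2], [2.0, 1.0])
        with pytest.raises(ValueError, match="dimensionality"):
            mode_overlap(a, b, 2)

    def test_same_distribution_beats_disjoint_modes(self, rng):
        """RMSIP between resamples of one model exceeds RMSIP across models."""
        base, modes = planted_system(rng, 10, 4)
        same1 = combined_pca([planted_ensemble(rng, 300, base, modes[:2],
                                               [3.0, 1.0], noise=0.2)])
        same2 = combined_pca([planted_ensemble(rng, 300, base, modes[:2],
                                               [3.0, 1.0], noise=0.2)])
        other = combined_pca([planted_ensemble(rng, 300, base, modes[2:],
                                               [3.0, 1.0], noise=0.2)])
        assert mode_overlap(same1, same2, 2).rmsip > mode_overlap(same1, other, 2).rmsip
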
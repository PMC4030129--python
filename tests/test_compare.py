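import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enmdyn import (
    BFactorProfile,
    DCCM,
    anm_hessian,
    bfactor_delta,
    build_network,
    compute_modes,
    dccm_pair_report,
    mode_overlap_table,
    nma_dccm,
    normalize_bfactors,
    overlap,
)
from enmdyn.exceptions import (
    ParameterError,
    ShapeError,
    UndefinedOverlapError,
    ZeroVarianceError,
)


class TestOverlap:
    def test_self_overlap_is_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(12, 3))
        assert overlap(v, v) == pytest.approx(1.0)

    def test_sign_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(12, 3))
        assert overlap(v, -v) == pytest.approx(1.0)

    def test_orthogonal_fields(self):
        a = np.array([[1.0, 0.0, 0.0]])
        b = np.array([[0.0, 1.0, 0.0]])
        assert overlap(a, b) == 0.0

    def test_two_dimensional_closed_form(self):
        a = np.array([[1.0, 0.0, 0.0]])
        b = np.array([[1.0, 1.0, 0.0]]) / np.sqrt(2.0)
        assert overlap(a, b) == pytest.approx(0.70711, abs=1e-5)

    def test_zero_field_undefined(self):
        v = np.ones((4, 3))
        with pytest.raises(UndefinedOverlapError):
            overlap(v, np.zeros((4, 3)))

    def test_selection_restricts_sum(self):
        a = np.zeros((4, 3))
        a[0] = [1, 0, 0]
        a[3] = [0, 1, 0]
        b = np.zeros((4, 3))
        b[0] = [1, 0, 0]
        b[3] = [0, -1, 0]
        assert overlap(a, b, selection=[0]) == pytest.approx(1.0)
        assert overlap(a, b) == pytest.approx(0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6),
           scale=st.floats(1e-3, 1e3))
    def test_scale_and_permutation_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(9, 3))
        b = rng.normal(size=(9, 3))
        o = overlap(a, b)
        assert overlap(scale * a, b) == pytest.approx(o, rel=1e-9)
        perm = rng.permutation(9)
        assert overlap(a[perm], b[perm]) == pytest.approx(o, rel=1e-9)


@pytest.fixture(scope="module")
def modes(two_domain):
    model, _ = two_domain
    return compute_modes(anm_hessian(build_network(model, r_c=8.0)))


class TestModeOverlapTable:

    def test_set_against_itself_all_ones(self, modes, two_domain):
        _, idx = two_domain
        table = mode_overlap_table(modes, modes, n_modes=3, domains=idx)
        assert np.allclose(table.table["overlap"], 1.0)
        assert table.value("full", "average") == pytest.approx(1.0)

    def test_average_row_is_mean_of_modes(self, modes):
        rng = np.random.default_rng(3)
        # perturb eigenvectors to get non-trivial overlaps
        v = modes.eigenvectors + rng.normal(
            scale=0.05, size=modes.eigenvectors.shape)
        v, _ = np.linalg.qr(v)
        other = type(modes)(eigenvalues=modes.eigenvalues, eigenvectors=v,
                            n_zero=modes.n_zero, source="anm")
        table = mode_overlap_table(modes, other, n_modes=3)
        per_mode = [table.value("full", k) for k in (1, 2, 3)]
        assert table.value("full", "average") == pytest.approx(
            np.mean(per_mode))

    def test_zero_displacement_domain_noted_not_crashed(self, modes,
                                                        two_domain):
        model, _ = two_domain
        dead = type(modes)(
            eigenvalues=modes.eigenvalues,
            eigenvectors=np.where(
                np.repeat(np.arange(model.n_beads), 3)[:, None] < 5,
                modes.eigenvectors, 0.0),
            n_zero=modes.n_zero, source="anm")
        table = mode_overlap_table(modes, dead, n_modes=1,
                                   domains={"rigid": np.arange(10, 20)})
        row = table.table[(table.table["scope"] == "rigid")
                          & (table.table["mode"] == "1")]
        assert np.isnan(row["overlap"].iloc[0])
        assert "undefined" in row["note"].iloc[0]

    def test_overlaps_within_unit_interval(self, modes):
        table = mode_overlap_table(modes, modes, n_modes=3)
        vals = table.table["overlap"].dropna()
        assert ((vals >= 0) & (vals <= 1)).all()


class TestNormalizeBfactors:
    def test_closed_form_zscore(self):
        p = BFactorProfile(values=np.array([1.0, 2.0, 3.0]), source="nma")
        z = normalize_bfactors(p)
        np.testing.assert_allclose(z.values, [-1.2247, 0.0, 1.2247],
                                   atol=1e-4)
        assert z.normalization == "zscore"

    def test_constant_profile_rejected(self):
        p = BFactorProfile(values=np.full(5, 2.0), source="nma")
        with pytest.raises(ZeroVarianceError):
            normalize_bfactors(p)

    def test_idempotent(self):
        p = BFactorProfile(values=np.array([1.0, 4.0, 7.0]), source="nma")
        z1 = normalize_bfactors(p)
        z2 = normalize_bfactors(z1)
        np.testing.assert_array_equal(z1.values, z2.values)

    def test_preserves_pearson_correlation(self):
        rng = np.random.default_rng(7)
        a = BFactorProfile(values=rng.uniform(1, 50, 30), source="nma")
        b = BFactorProfile(values=rng.uniform(1, 50, 30), source="eda")
        r_raw = np.corrcoef(a.values, b.values)[0, 1]
        r_norm = np.corrcoef(normalize_bfactors(a).values,
                             normalize_bfactors(b).values)[0, 1]
        assert r_norm == pytest.approx(r_raw, abs=1e-12)

    def test_nan_entries_stay_undefined(self):
        p = BFactorProfile(values=np.array([1.0, np.nan, 3.0]),
                           source="crystal")
        z = normalize_bfactors(p)
        assert np.isnan(z.values[1])
        defined = z.values[[0, 2]]
        assert defined.mean() == pytest.approx(0.0, abs=1e-12)


class TestBfactorDelta:
    def _zprof(self, values, resids=None):
        return normalize_bfactors(
            BFactorProfile(values=np.asarray(values, dtype=float),
                           resids=resids))

    def test_identical_profiles_give_zero(self):
        p = self._zprof([1.0, 2.0, 3.0])
        np.testing.assert_allclose(bfactor_delta(p, p), 0.0)

    def test_antisymmetry(self):
        a = self._zprof([1.0, 2.0, 3.0])
        b = self._zprof([3.0, 1.0, 2.0])
        np.testing.assert_allclose(bfactor_delta(a, b),
                                   -bfactor_delta(b, a))

    def test_mismatched_resids_listed(self):
        a = self._zprof([1.0, 2.0, 3.0], resids=np.array([1, 2, 3]))
        b = self._zprof([1.0, 2.0, 3.0], resids=np.array([1, 2, 4]))
        with pytest.raises(ShapeError, match=r"\[3, 4\]"):
            bfactor_delta(a, b)

    def test_raw_profiles_rejected(self):
        p = BFactorProfile(values=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ParameterError):
            bfactor_delta(p, p)


class TestDccmPairReport:
    def test_identical_maps_symmetric_composite(self, two_domain):
        model, idx = two_domain
        modes = compute_modes(anm_hessian(build_network(model, r_c=8.0)))
        m = nma_dccm(modes, k_list=(1, 2, 3))
        comp, summary = dccm_pair_report(
            m, m, regions=[("ci", idx["core"], idx["insert"])])
        np.testing.assert_allclose(comp.matrix, comp.matrix.T)
        means = summary["mean_cc"].to_numpy()
        assert means[0] == pytest.approx(means[1])

    def test_anticorrelated_hinge_block_negative_for_both(self, two_domain):
        model, idx = two_domain
        modes = compute_modes(anm_hessian(build_network(model, r_c=8.0)))
        m1 = nma_dccm(modes, k_list=(1, 2, 3))
        m2 = nma_dccm(modes, k_list=(1, 2))
        _, summary = dccm_pair_report(
            m1, m2, regions=[("hinge", idx["core"], idx["insert"])])
        assert (summary["mean_cc"] < 0).all()

    def test_scaled_map_halves_block_magnitude(self):
        rng = np.random.default_rng(9)
        m = rng.uniform(-0.8, 0.8, size=(12, 12))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 1.0)
        half = m * 0.5
        np.fill_diagonal(half, 1.0)
        _, summary = dccm_pair_report(
            DCCM(matrix=m, method="a"), DCCM(matrix=half, method="b"),
            regions=[("blk", np.arange(0, 5), np.arange(6, 12))])
        a, b = summary["mean_abs_cc"].to_numpy()
        assert b / a == pytest.approx(0.5)
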
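import numpy as np
import pytest

from decflow.errors import ParameterError, StateError
from decflow.groupica import (
    ICAResult,
    Reduction,
    SelectionRules,
    back_reconstruct_and_select,
    infomax_unmix,
    low_frequency_fraction,
    reduce_concat,
)


def laplacian_sources(n, d, seed):
    rng = np.random.default_rng(seed)
    return rng.laplace(size=(n, d))


class TestReduceConcat:
    def test_exact_rank_explains_everything(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 6))
        data = rng.normal(size=(100, 2)) @ basis
        red = reduce_concat([data], n_pc=2)
        assert red.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)

    def test_white_data_rotation_reconstructs(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(500, 4))
        red = reduce_concat([data], n_pc=4)
        recon = red.scores @ red.basis.T + red.column_means
        np.testing.assert_allclose(recon, data, atol=1e-8)

    def test_explained_variance_matches_eigendecomposition(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(300, 10)) * np.linspace(3, 0.5, 10)
        red = reduce_concat([data], n_pc=5)
        centered = data - data.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(centered.T @ centered))[::-1]
        expected = eigvals[:5].sum() / eigvals.sum()
        assert red.explained_variance_ratio.sum() == pytest.approx(expected, abs=1e-10)

    def test_n_pc_exceeding_rank(self):
        rng = np.random.default_rng(3)
        basis = rng.normal(size=(2, 5))
        data = rng.normal(size=(50, 2)) @ basis  # rank 2
        with pytest.raises(ParameterError):
            reduce_concat([data], n_pc=3)

    def test_reconstruction_error_non_increasing_in_n_pc(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(200, 8)) * np.linspace(2, 0.2, 8)
        errors = []
        for n_pc in range(1, 9):
            red = reduce_concat([data], n_pc=n_pc)
            recon = red.scores @ red.basis.T + red.column_means
            errors.append(np.linalg.norm(recon - data))
        assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))

    def test_subject_slices_cover_concatenation(self):
        rng = np.random.default_rng(5)
        mats = [rng.normal(size=(t, 3)) for t in (40, 60, 30)]
        red = reduce_concat(mats, n_pc=3)
        assert [sl.stop - sl.start for sl in red.subject_slices] == [40, 60, 30]

    def test_inconsistent_features(self):
        with pytest.raises(ParameterError):
            reduce_concat([np.zeros((10, 3)), np.zeros((10, 4))], n_pc=2)


def recovery_correlation(sources_true, sources_est):
    """Best-match |correlation| per true source (permutation/sign invariant)."""
    c = np.corrcoef(sources_true.T, sources_est)[: sources_true.shape[1],
                                                 sources_true.shape[1]:]
    return np.abs(c).max(axis=1)


class TestInfomax:
    @pytest.mark.parametrize("seed", range(5))
    def test_laplacian_source_recovery(self, seed):
        rng = np.random.default_rng(100 + seed)
        s = laplacian_sources(2000, 2, seed)
        mixing = rng.normal(size=(2, 2)) + np.eye(2)
        x = s @ mixing.T
        red = reduce_concat([x], n_pc=2)
        ica = infomax_unmix(red, n_ic=2, seed=seed)
        corr = recovery_correlation(s, ica.sources)
        assert np.all(corr > 0.95)

    def test_identity_mixing_recovers_sources(self):
        s = laplacian_sources(3000, 3, 42)
        red = reduce_concat([s], n_pc=3)
        ica = infomax_unmix(red, n_ic=3, seed=0)
        corr = recovery_correlation(s, ica.sources)
        assert np.all(corr > 0.95)

    def test_gaussian_warns_non_identifiable(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(2000, 3))
        red = reduce_concat([x], n_pc=3)
        with pytest.warns(RuntimeWarning, match="not identifiable"):
            infomax_unmix(red, n_ic=3, seed=0)

    def test_non_convergence_flagged(self):
        s = laplacian_sources(500, 2, 7)
        red = reduce_concat([s], n_pc=2)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            ica = infomax_unmix(red, n_ic=2, max_iter=2, seed=0)
        assert not ica.converged

    def test_mixing_unmixing_identity(self):
        s = laplacian_sources(1000, 3, 8)
        red = reduce_concat([s], n_pc=3)
        ica = infomax_unmix(red, n_ic=3, seed=0)
        np.testing.assert_allclose(ica.mixing @ ica.unmixing, np.eye(3), atol=1e-6)

    def test_sign_convention(self):
        s = laplacian_sources(1500, 2, 9)
        red = reduce_concat([s], n_pc=2)
        ica = infomax_unmix(red, n_ic=2, seed=1)
        for c in range(ica.n_ic):
            peak = np.argmax(np.abs(ica.maps[c]))
            assert ica.maps[c][peak] > 0

    def test_n_ic_bounds(self):
        red = reduce_concat([laplacian_sources(100, 3, 10)], n_pc=3)
        with pytest.raises(ParameterError):
            infomax_unmix(red, n_ic=4)


def _synthetic_ica(freqs, n_time=400, tr=2.0, maps=None):
    """Hand-built ICAResult with sinusoidal sources at given frequencies (Hz)."""
    t = np.arange(n_time) * tr
    sources = np.array([
        np.cos(np.pi * np.arange(n_time)) if f == "nyquist" else np.sin(2 * np.pi * f * t)
        for f in freqs
    ])
    n_ic = len(freqs)
    if maps is None:
        maps = np.eye(n_ic)
    red = Reduction(
        scores=sources.T, basis=np.eye(maps.shape[1])[:, :n_ic],
        singular_values=np.ones(n_ic), column_means=np.zeros(maps.shape[1]),
        subject_slices=[slice(0, n_time)],
        explained_variance_ratio=np.full(n_ic, 1 / n_ic), n_pc=n_ic,
    )
    return ICAResult(unmixing=np.eye(n_ic), mixing=np.eye(n_ic), maps=np.asarray(maps),
                     sources=sources, reduction=red, n_pc=n_ic, n_ic=n_ic,
                     converged=True, n_iter=1)


class TestBackReconstructAndSelect:
    def test_single_subject_identity(self):
        s = laplacian_sources(800, 3, 11)
        red = reduce_concat([s], n_pc=3)
        ica = infomax_unmix(red, n_ic=3, seed=0)
        tcs, _, _ = back_reconstruct_and_select(ica)
        assert len(tcs) == 1
        np.testing.assert_allclose(tcs[0].T, ica.sources, atol=1e-12)

    def test_nyquist_component_rejected(self):
        ica = _synthetic_ica([0.02, "nyquist"])
        _, selected, report = back_reconstruct_and_select(ica)
        assert selected == [0]
        assert report["decisions"][1]["low_freq_fraction"] < 0.01

    def test_mask_and_frequency_selection(self):
        # 12 of 20 components are low-frequency AND peak inside the mask
        n_ic = 20
        freqs = [0.02 if i < 14 else "nyquist" for i in range(n_ic)]
        maps = np.zeros((n_ic, 30))
        for i in range(n_ic):
            maps[i, i] = 1.0
        mask = np.zeros(30, dtype=bool)
        mask[:12] = True  # components 12,13 are low-freq but out of mask
        ica = _synthetic_ica(freqs, maps=maps)
        _, selected, _ = back_reconstruct_and_select(
            ica, SelectionRules(mask=mask)
        )
        assert selected == list(range(12))

    def test_missing_operators_raise(self):
        ica = _synthetic_ica([0.02])
        ica.reduction = None
        with pytest.raises(StateError):
            back_reconstruct_and_select(ica)

    def test_multi_subject_slicing(self):
        rng = np.random.default_rng(12)
        mats = [rng.laplace(size=(t, 3)) for t in (50, 70)]
        red = reduce_concat(mats, n_pc=3)
        ica = infomax_unmix(red, n_ic=3, seed=0)
        tcs, _, _ = back_reconstruct_and_select(ica)
        assert [t.shape for t in tcs] == [(50, 3), (70, 3)]


class TestLowFrequencyFraction:
    def test_pure_slow_wave(self):
        t = np.arange(500) * 2.0
        x = np.sin(2 * np.pi * 0.01 * t)
        assert low_frequency_fraction(x, tr=2.0, cutoff_hz=0.1) > 0.99

    def test_alternation_has_no_low_power(self):
        x = np.cos(np.pi * np.arange(400))  # +1, -1, +1 ... at Nyquist
        assert low_frequency_fraction(x, tr=2.0, cutoff_hz=0.1) < 0.01
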
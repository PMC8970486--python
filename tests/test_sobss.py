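"""Blind source separation, ACF correctness, cycle-length machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afsource.signal_io import MultichannelSignal, normalize_channels
from afsource.sobss import (
    DegenerateSignalError,
    LagSet,
    RankDeficiencyError,
    dominant_cl,
    estimate_cl,
    extract_sources,
    joint_diagonalize,
    match_harmonics,
    offdiag_energy,
    source_cls,
    unbiased_acf,
    whiten,
)


def naive_unbiased_acf(s, taus):
    """Double-loop oracle of the corrected ACF definition."""
    s = np.asarray(s, dtype=float)
    T = s.size
    sbar = s.mean()
    denom = sum((s[t] - sbar) ** 2 for t in range(T))
    out = []
    for tau in taus:
        num = sum((s[t] - sbar) * (s[t + tau] - sbar) for t in range(T - tau))
        out.append((T - 1) / (T - tau - 1) * num / denom)
    return np.array(out)


class TestUnbiasedAcf:
    def test_lag_zero_is_one(self, rng):
        prof = unbiased_acf(rng.normal(size=500), [0])
        assert prof.values[0] == pytest.approx(1.0, abs=1e-12)

    def test_sinusoid_peaks_at_period(self):
        t = np.arange(5000)
        s = np.sin(2 * np.pi * t / 200.0)
        prof = unbiased_acf(s, [200])
        assert prof.values[0] == pytest.approx(1.0, abs=0.01)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(5):
            T = int(rng.integers(200, 1200))
            s = rng.normal(size=T)
            taus = rng.integers(0, T - 3, size=10)
            prof = unbiased_acf(s, taus)
            np.testing.assert_allclose(
                prof.values, naive_unbiased_acf(s, taus), atol=1e-10
            )

    def test_white_noise_mostly_inside_band(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=10000)
        taus = np.arange(1, 301)
        prof = unbiased_acf(s, taus)
        frac = np.mean(np.abs(prof.values) < 1.96 / np.sqrt(s.size))
        assert frac >= 0.93  # ~95% expected under the null

    def test_degenerate_and_range_errors(self):
        with pytest.raises(DegenerateSignalError):
            unbiased_acf(np.full(100, 3.0), [10])
        with pytest.raises(ValueError, match="lag"):
            unbiased_acf(np.random.default_rng(0).normal(size=50), [49])

    def test_ci_halfwidth_positive(self, rng):
        prof = unbiased_acf(rng.normal(size=1000), np.arange(1, 50))
        assert np.all(prof.ci_halfwidth > 0)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_acf_bounded_for_random_signals(self, seed):
        s = np.random.default_rng(seed).normal(size=300)
        prof = unbiased_acf(s, np.arange(0, 100))
        assert np.all(np.isfinite(prof.values))
        assert prof.values[0] == pytest.approx(1.0, abs=1e-12)


class TestWhiten:
    def test_diagonal_covariance_whitens_exactly(self, rng):
        X = np.vstack([2.0 * rng.normal(size=4000), rng.normal(size=4000)])
        Z, W = whiten(X - X.mean(axis=1, keepdims=True), 2)
        np.testing.assert_allclose(Z @ Z.T / Z.shape[1], np.eye(2), atol=1e-8)

    def test_rank_deficiency_reported(self, rng):
        base = rng.normal(size=1000)
        X = np.vstack([base, 2 * base])
        with pytest.raises(RankDeficiencyError, match="rank"):
            whiten(X - X.mean(axis=1, keepdims=True), 2)

    def test_transform_whitens_covariance(self, rng):
        X = rng.normal(size=(6, 3000))
        X = X - X.mean(axis=1, keepdims=True)
        Z, W = whiten(X, 6)
        C = X @ X.T / X.shape[1]
        np.testing.assert_allclose(W @ C @ W.T, np.eye(6), atol=1e-8)


class TestJointDiagonalize:
    def test_already_diagonal_is_fixed_point(self):
        mats = [np.diag([3.0, 1.0, 0.5]), np.diag([1.0, 2.0, 0.1])]
        R = joint_diagonalize(mats)
        # identity up to sign/permutation: |R| must be a permutation matrix
        perm = np.abs(R)
        np.testing.assert_allclose(perm @ perm.T, np.eye(3), atol=1e-8)
        assert offdiag_energy(mats, R) < 1e-16

    def test_single_matrix_equals_eigendecomposition(self, rng):
        A = rng.normal(size=(4, 4))
        C = A + A.T
        R = joint_diagonalize([C])
        D = R.T @ C @ R
        np.testing.assert_allclose(D - np.diag(np.diag(D)), 0.0, atol=1e-8)
        evals = np.sort(np.linalg.eigvalsh(C))
        np.testing.assert_allclose(np.sort(np.diag(D)), evals, atol=1e-8)

    def test_commuting_pair_from_shared_basis(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        mats = [Q @ np.diag(rng.normal(size=5)) @ Q.T for _ in range(2)]
        R = joint_diagonalize(mats)
        assert offdiag_energy(mats, R) < 1e-10

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_diagonalize([np.eye(3), np.eye(4)])


def _mixture_signal(cls_ms, rng, T=2000, L=12, fs=1000.0, phases=None):
    t = np.arange(T) / fs * 1000.0
    S = np.vstack(
        [np.sin(2 * np.pi * (t / cl) + (0 if phases is None else phases[i]))
         for i, cl in enumerate(cls_ms)]
    )
    A = rng.normal(size=(L, len(cls_ms)))
    X = (A @ S).T
    sig = MultichannelSignal(X, fs, [f"L{i}" for i in range(L)])
    return sig, S


class TestExtractSources:
    def test_two_tone_recovery(self, lags):
        rng = np.random.default_rng(0)
        sig, S = _mixture_signal([180.0, 240.0], rng)
        dec = extract_sources(normalize_channels(sig), 2, lags)
        cls = sorted(p[0] for p in source_cls(dec, lags))
        assert cls == [180.0, 240.0]
        corr = np.abs(np.corrcoef(np.vstack([dec.sources, S]))[:2, 2:])
        assert corr.max(axis=1).min() > 0.99

    def test_single_source_reproduced(self, lags):
        rng = np.random.default_rng(1)
        sig, S = _mixture_signal([200.0], rng)
        dec = extract_sources(normalize_channels(sig), 1, lags)
        assert abs(np.corrcoef(dec.sources[0], S[0])[0, 1]) > 0.999

    def test_deterministic(self, lags):
        rng = np.random.default_rng(2)
        sig, _ = _mixture_signal([150.0, 220.0], rng)
        sig = normalize_channels(sig)
        d1 = extract_sources(sig, 2, lags)
        d2 = extract_sources(sig, 2, lags)
        np.testing.assert_array_equal(d1.sources, d2.sources)

    def test_scale_invariant_features(self, lags):
        rng = np.random.default_rng(3)
        sig, _ = _mixture_signal([170.0, 250.0], rng)
        f1 = source_cls(extract_sources(normalize_channels(sig), 2, lags), lags)
        scaled = MultichannelSignal(sig.data * -7.3, sig.fs, sig.lead_labels)
        f2 = source_cls(extract_sources(normalize_channels(scaled), 2, lags), lags)
        for (c1, m1), (c2, m2) in zip(f1, f2):
            assert c1 == c2 and m1 == pytest.approx(m2, abs=1e-9)

    def test_lead_permutation_equivariance(self, lags):
        rng = np.random.default_rng(4)
        sig, _ = _mixture_signal([160.0, 230.0], rng)
        perm = rng.permutation(sig.n_leads)
        permuted = MultichannelSignal(
            sig.data[:, perm], sig.fs, [sig.lead_labels[i] for i in perm]
        )
        f1 = source_cls(extract_sources(normalize_channels(sig), 2, lags), lags)
        f2 = source_cls(extract_sources(normalize_channels(permuted), 2, lags), lags)
        for (c1, m1), (c2, m2) in zip(f1, f2):
            assert c1 == c2 and m1 == pytest.approx(m2, abs=1e-6)

    def test_unit_variance_and_reconstruction(self, lags):
        rng = np.random.default_rng(5)
        sig, _ = _mixture_signal([140.0, 260.0], rng, L=2)  # full rank
        sig = normalize_channels(sig)
        dec = extract_sources(sig, 2, lags)
        np.testing.assert_allclose(dec.sources.std(axis=1), 1.0, atol=1e-9)
        X = sig.data.T - sig.data.T.mean(axis=1, keepdims=True)
        recon = dec.mixing @ dec.sources
        rel = np.linalg.norm(recon - X) / np.linalg.norm(X)
        assert rel < 1e-6

    def test_white_noise_robustness(self, lags):
        # adding 10 dB SNR noise moves strong-source CLs by <= 5 ms
        hits = 0
        trials = 20
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            sig, _ = _mixture_signal([180.0, 240.0], rng)
            noise = rng.normal(0, 10 ** (-10 / 20) * sig.data.std(), sig.data.shape)
            noisy = MultichannelSignal(sig.data + noise, sig.fs, sig.lead_labels)
            clean_cls = sorted(
                p[0] for p in source_cls(extract_sources(normalize_channels(sig), 2, lags), lags)
            )
            noisy_cls = sorted(
                p[0] for p in source_cls(extract_sources(normalize_channels(noisy), 2, lags), lags)
            )
            if all(abs(a - b) <= 5.0 for a, b in zip(clean_cls, noisy_cls)):
                hits += 1
        assert hits >= 0.9 * trials


class TestCycleLength:
    def test_sinusoid_cl(self, lags):
        t = np.arange(3000)
        cl, maxac = estimate_cl(np.sin(2 * np.pi * t / 180.0), lags, 1000.0)
        assert cl == 180.0 and maxac >= 0.99

    def test_white_noise_maxac_small(self, lags):
        s = np.random.default_rng(6).normal(size=5000)
        cl, maxac = estimate_cl(s, lags, 1000.0)
        assert maxac < 3 * 1.96 / np.sqrt(s.size)

    def test_subharmonic_period_found_at_in_range_multiple(self, lags):
        # the 90 ms fundamental lies below the window; the ACF peaks at its
        # multiples, so the estimate lands on a harmonic and the harmonic
        # matcher recognizes it
        t = np.arange(4000)
        cl, maxac = estimate_cl(np.sin(2 * np.pi * t / 90.0), lags, 1000.0)
        assert min(cl % 90.0, 90.0 - cl % 90.0) <= 1.0
        assert maxac > 0.99
        assert match_harmonics(90.0, [cl])  # true period matched via cl/m

    def test_dominant_cl_strong_source(self, lags):
        rng = np.random.default_rng(7)
        sig, _ = _mixture_signal([210.0], rng)
        dec = extract_sources(normalize_channels(sig), 1, lags)
        assert dominant_cl(dec, lags) == pytest.approx(210.0, abs=2.0)

    def test_dominant_cl_none_for_noise(self, lags):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(5000, 5))
        sig = normalize_channels(
            MultichannelSignal(X, 1000.0, [f"L{i}" for i in range(5)])
        )
        dec = extract_sources(sig, 3, lags)
        assert dominant_cl(dec, lags) is None

    def test_dominant_cl_skips_unqualified_first_source(self, lags):
        """A noise source forced to rank 1 is skipped; the periodic source
        behind it supplies the dominant CL."""
        from dataclasses import replace

        rng = np.random.default_rng(9)
        sig, _ = _mixture_signal([190.0], rng, L=3)
        noisy = MultichannelSignal(
            np.column_stack([sig.data, rng.normal(size=sig.n_samples) * 5]),
            sig.fs,
            list(sig.lead_labels) + ["N"],
        )
        dec = extract_sources(normalize_channels(noisy), 2, lags)
        # force the noise source first regardless of its rank key
        order = np.argsort([np.abs(np.corrcoef(s, sig.data[:, 0])[0, 1])
                            for s in dec.sources])
        forced = replace(
            dec,
            sources=dec.sources[order],
            unmixing=dec.unmixing[order],
            mixing=dec.mixing[:, order],
            rank_key=dec.rank_key[order],
        )
        assert dominant_cl(forced, lags) == pytest.approx(190.0, abs=5.0)


class TestMatchHarmonics:
    @pytest.mark.parametrize(
        "focal,sources,expected",
        [
            (150.0, [225.0], False),
            (150.0, [300.0], True),  # subharmonic 300/2
            (180.0, [183.0], True),  # within 5 ms
            (210.0, [105.0], True),  # harmonic 105*2
            (180.0, [400.0], False),
            (120.0, [], False),
        ],
    )
    def test_arithmetic(self, focal, sources, expected):
        assert match_harmonics(focal, sources) is expected

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.floats(min_value=100.0, max_value=330.0),
        st.integers(min_value=1, max_value=3),
    )
    def test_exact_harmonics_always_match(self, cl, m):
        assert match_harmonics(cl * m, [cl])
        assert match_harmonics(cl / m, [cl])
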
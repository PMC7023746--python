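"""Burden test, profile statistics, SNR, cosine similarity, stability."""

import math

import numpy as np
import pytest

from subclonesig import (
    Catalog,
    SignatureProfile,
    burden_test,
    cosine_similarity,
    profile_stats,
    snr,
    stability_report,
)
from subclonesig.channels import ChannelScheme, sbs96_scheme
from subclonesig.errors import (
    InsufficientDataError,
    MissingControlsError,
    SchemeMismatchError,
    UndefinedSimilarityError,
    ZeroBurdenError,
)
from subclonesig.stats import bh_adjust

TWO = ChannelScheme("TWO", ("a", "b"), "SBS")
THREE = ChannelScheme("THREE", ("a", "b", "c"), "SBS")


class TestBurdenTest:
    def test_centred_statistic_gives_middling_p(self):
        res = burden_test([190, 210, 195, 205, 200, 200],
                          [200, 200, 200, 200, 200, 200], seed=1)
        assert 0.3 < res.p_value < 0.8
        assert not res.significant

    def test_strong_excess_reaches_permutation_floor(self):
        # with all experimental burdens far above all controls only the
        # permutations reproducing the observed split are as extreme:
        # about n_boot / C(12,6) of them
        res = burden_test([200] * 6, [800] * 6, n_boot=2000, seed=2)
        floor = (1 + 2000 / math.comb(12, 6)) / 2001
        assert res.p_value == pytest.approx(floor, rel=0.8)
        assert res.p_value >= 1 / 2001
        assert res.significant

    def test_reproducible_and_order_invariant(self):
        a = burden_test([180, 220, 190, 210], [260, 250], seed=9)
        b = burden_test([180, 220, 190, 210], [260, 250], seed=9)
        c = burden_test([220, 180, 210, 190], [260, 250], seed=9)
        assert a.p_value == b.p_value
        assert a.null_quantiles == b.null_quantiles
        # relabelling controls leaves the permutation pool unchanged
        assert a.p_value == c.p_value

    def test_single_control_rejected(self):
        with pytest.raises(MissingControlsError):
            burden_test([200], [300, 310], seed=0)

    def test_null_calibration(self):
        """Type-I error at p<=0.01 stays near nominal under a Poisson null."""
        rng = np.random.default_rng(20240917)
        hits = 0
        n_rep = 400
        for i in range(n_rep):
            ctrl = rng.poisson(200, size=6)
            exp = rng.poisson(200, size=6)
            res = burden_test(ctrl, exp, n_boot=2000, seed=int(rng.integers(2**31)))
            hits += res.significant
        assert hits / n_rep <= 0.025  # ~2x binomial slack on the 1% level

    def test_bh_adjustment_monotone(self):
        p = [0.001, 0.02, 0.5, 0.04]
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert adj.max() <= 1.0


class TestProfileStats:
    def _catalog(self, cols):
        cols = np.asarray(cols).T
        return Catalog(TWO, [f"s{i}" for i in range(cols.shape[1])], cols)

    def test_single_sample_sigma_zero(self):
        st = profile_stats(self._catalog([[3, 1]]), ["s0"])
        assert np.allclose(st.mu, [0.75, 0.25])
        assert np.allclose(st.sigma, 0)

    def test_identical_samples_sigma_zero(self):
        st = profile_stats(self._catalog([[5, 5], [50, 50]]), ["s0", "s1"])
        assert np.allclose(st.sigma, 0)

    def test_orthogonal_profiles(self):
        st = profile_stats(self._catalog([[7, 0], [0, 3]]), ["s0", "s1"])
        assert np.allclose(st.mu, [0.5, 0.5])
        assert np.allclose(st.sigma, [0.5, 0.5])  # population SD

    def test_zero_burden_sample_named(self):
        with pytest.raises(ZeroBurdenError, match="s1"):
            profile_stats(self._catalog([[1, 1], [0, 0]]), ["s0", "s1"])


class TestSNR:
    def _stats(self, mu, sigma):
        from subclonesig.stats import ProfileStats

        return ProfileStats("TWO", TWO.labels, np.asarray(mu, float),
                            np.asarray(sigma, float), 2)

    def test_worked_example(self):
        res = snr(self._stats([0.5, 0.5], [0.05, 0.05]),
                  self._stats([0.7, 0.3], [0.05, 0.05]))
        assert res.signal == pytest.approx(math.sqrt(0.08))
        assert res.noise == pytest.approx(0.1)
        assert res.snr == pytest.approx(math.sqrt(0.08) / 0.1)

    def test_equal_means_zero_snr(self):
        res = snr(self._stats([0.5, 0.5], [0.1, 0.1]),
                  self._stats([0.5, 0.5], [0.2, 0.2]))
        assert res.snr == 0.0

    def test_zero_noise_flagged_infinite(self):
        res = snr(self._stats([1, 0], [0, 0]), self._stats([0, 1], [0, 0]))
        assert res.infinite and math.isinf(res.snr)

    def test_symmetry_and_noise_scaling(self):
        a = self._stats([0.6, 0.4], [0.02, 0.04])
        b = self._stats([0.3, 0.7], [0.03, 0.01])
        assert snr(a, b).snr == pytest.approx(snr(b, a).snr)
        a3 = self._stats([0.6, 0.4], [0.06, 0.12])
        b3 = self._stats([0.3, 0.7], [0.09, 0.03])
        assert snr(a3, b3).snr == pytest.approx(snr(a, b).snr / 3)

    def test_scheme_mismatch(self):
        from subclonesig.stats import ProfileStats

        other = ProfileStats("THREE", THREE.labels, np.ones(3) / 3,
                             np.zeros(3), 2)
        with pytest.raises(SchemeMismatchError):
            snr(self._stats([1, 0], [0, 0]), other)


class TestCosine:
    def test_examples(self):
        p = SignatureProfile(THREE, np.array([0.5, 0.5, 0.0]))
        q = SignatureProfile(THREE, np.array([0.5, 0.0, 0.5]))
        assert cosine_similarity(p, p) == pytest.approx(1.0)
        assert cosine_similarity(p, q) == pytest.approx(0.5)
        r = SignatureProfile(THREE, np.array([0.0, 0.0, 1.0]))
        assert cosine_similarity(p, r) == pytest.approx(0.0)

    def test_scale_invariance_through_normalization(self):
        rng = np.random.default_rng(4)
        w = rng.dirichlet(np.ones(3))
        p = SignatureProfile(THREE, w)
        from subclonesig.catalog import SignatureProfile as SP

        q = SP.from_counts(THREE, (w * 1000).round())
        assert cosine_similarity(p, q) == pytest.approx(1.0, abs=1e-3)

    def test_zero_vector_rejected(self):
        z = SignatureProfile(THREE, np.zeros(3))
        p = SignatureProfile(THREE, np.ones(3) / 3)
        with pytest.raises(UndefinedSimilarityError):
            cosine_similarity(p, z)


class TestStability:
    def test_identical_signatures_stable(self, sbs96):
        sig = SignatureProfile(sbs96, np.full(96, 1 / 96))
        rep = stability_report([sig, sig, sig])
        assert rep.min_cosine == pytest.approx(1.0)
        assert rep.stable

    def test_orthogonal_outlier_not_stable(self):
        a = SignatureProfile(TWO, np.array([1.0, 0.0]))
        b = SignatureProfile(TWO, np.array([0.0, 1.0]))
        rep = stability_report([a, a, b])
        assert rep.min_cosine == pytest.approx(0.0)
        assert not rep.stable

    def test_replicates_from_one_signature_are_stable(self, treatment_sig, sbs96):
        rng = np.random.default_rng(11)
        sigs = [
            SignatureProfile.from_counts(
                sbs96, rng.multinomial(500, treatment_sig.weights)
            )
            for _ in range(4)
        ]
        assert stability_report(sigs).stable

    def test_needs_two(self, treatment_sig):
        with pytest.raises(InsufficientDataError):
            stability_report([treatment_sig])
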
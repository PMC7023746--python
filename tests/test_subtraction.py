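"""Background model fitting and bootstrap background subtraction."""

import numpy as np
import pytest
from scipy import stats as sps

from subclonesig import (
    Catalog,
    bootstrap_channel_distribution,
    cosine_similarity,
    fit_background,
    subtract_background,
)
from subclonesig.channels import ChannelScheme
from subclonesig.errors import EmptySampleError, MissingControlsError

from conftest import multinomial_catalog

TWO = ChannelScheme("TWO", ("a", "b"), "SBS")


class TestBootstrapChannels:
    def test_degenerate_single_channel(self):
        reps, ci = bootstrap_channel_distribution([40, 0], n_boot=1000, seed=0)
        assert (reps[:, 0] == 40).all()
        assert ci[0, 0] == ci[1, 0] == 40
        assert ci[0, 1] == ci[1, 1] == 0

    def test_ci_matches_exact_binomial_quantiles(self):
        """Multinomial(100, 1/2) channel counts vs the exact Binomial CI."""
        _, ci = bootstrap_channel_distribution([50, 50], n_boot=10_000, seed=1)
        lo, hi = sps.binom.ppf([0.005, 0.995], 100, 0.5)
        assert abs(ci[0, 0] - lo) <= 2
        assert abs(ci[1, 0] - hi) <= 2

    def test_reproducible(self):
        _, a = bootstrap_channel_distribution([30, 20], n_boot=2000, seed=5)
        _, b = bootstrap_channel_distribution([30, 20], n_boot=2000, seed=5)
        assert (a == b).all()

    def test_empty_sample(self):
        with pytest.raises(EmptySampleError):
            bootstrap_channel_distribution([0, 0], seed=0)


class TestFitBackground:
    def test_identical_controls(self):
        cat = Catalog(TWO, ["c1", "c2"], np.array([[30, 30], [10, 10]]))
        bg = fit_background(cat)
        assert np.allclose(bg.profile.weights, [0.75, 0.25])
        assert bg.burden == 40

    def test_profiles_averaged_equally_despite_burdens(self):
        cat = Catalog(TWO, ["c1", "c2"], np.array([[100, 0], [0, 100]]))
        bg = fit_background(cat)
        assert np.allclose(bg.profile.weights, [0.5, 0.5])
        assert bg.burden == 100

    def test_single_control_rejected(self):
        cat = Catalog(TWO, ["c1"], np.array([[10], [5]]))
        with pytest.raises(MissingControlsError):
            fit_background(cat)


class TestSubtractBackground:
    def test_zero_background_returns_centroid(self, sbs96, background_sig):
        cat = multinomial_catalog(sbs96, ["e1", "e2"], [(background_sig, 300)],
                                  seed=3)
        empty = Catalog(sbs96, ["c1", "c2"],
                        np.zeros((96, 2), dtype=int))
        # a zero-burden background built directly
        from subclonesig.subtraction import BackgroundModel
        from subclonesig.catalog import SignatureProfile

        bg = BackgroundModel(SignatureProfile(sbs96, np.zeros(96)), 0.0)
        res = subtract_background(cat, bg, seed=1)
        assert res.background_scale == 1.0
        assert res.attributed_burden == pytest.approx(
            cat.burdens().mean(), rel=1e-12
        )

    def test_null_experiment_attributes_little(self, sbs96, background_sig):
        ctrl = multinomial_catalog(sbs96, [f"c{i}" for i in range(4)],
                                   [(background_sig, 300)], seed=10)
        exp = multinomial_catalog(sbs96, [f"e{i}" for i in range(4)],
                                  [(background_sig, 300)], seed=11)
        res = subtract_background(exp, fit_background(ctrl), seed=12)
        # only clamp noise should remain; all residuals inside their CI
        assert res.attributed_burden < 0.3 * 300
        assert res.background_scale == 1.0
        width = res.channel_ci[1] - res.channel_ci[0]
        assert (np.abs(res.residuals) <= np.maximum(width, 1e-9) + 3).all()

    def test_planted_signature_recovered(self, sbs96, background_sig,
                                         treatment_sig):
        ctrl = multinomial_catalog(sbs96, [f"c{i}" for i in range(4)],
                                   [(background_sig, 200)], seed=20)
        exp = multinomial_catalog(
            sbs96, [f"e{i}" for i in range(4)],
            [(background_sig, 200), (treatment_sig, 600)], seed=21,
        )
        res = subtract_background(exp, fit_background(ctrl), seed=22)
        assert cosine_similarity(res.signature, treatment_sig) >= 0.95
        assert res.attributed_burden == pytest.approx(600, rel=0.15)

    def test_monotone_recovery_in_planted_burden(self, sbs96, background_sig,
                                                 treatment_sig):
        """More treatment mutations never hurt signature recovery (coarsely)."""
        cos = []
        for burden in (150, 400, 1000):
            ctrl = multinomial_catalog(sbs96, ["c1", "c2", "c3"],
                                       [(background_sig, 200)], seed=30)
            exp = multinomial_catalog(
                sbs96, ["e1", "e2", "e3"],
                [(background_sig, 200), (treatment_sig, burden)], seed=31,
            )
            res = subtract_background(exp, fit_background(ctrl), seed=32)
            cos.append(cosine_similarity(res.signature, treatment_sig))
        assert cos[0] <= cos[1] + 0.02 and cos[1] <= cos[2] + 0.02

    def test_deterministic_given_seed(self, sbs96, background_sig,
                                      treatment_sig):
        ctrl = multinomial_catalog(sbs96, ["c1", "c2"],
                                   [(background_sig, 200)], seed=40)
        exp = multinomial_catalog(
            sbs96, ["e1", "e2"],
            [(background_sig, 200), (treatment_sig, 400)], seed=41,
        )
        bg = fit_background(ctrl)
        a = subtract_background(exp, bg, n_boot=1500, seed=7)
        b = subtract_background(exp, bg, n_boot=1500, seed=7)
        assert (a.channel_ci == b.channel_ci).all()
        assert a.attributed_burden == b.attributed_burden
        assert a.background_scale == b.background_scale

    def test_output_signature_normalized_nonnegative(self, sbs96,
                                                     background_sig,
                                                     treatment_sig):
        ctrl = multinomial_catalog(sbs96, ["c1", "c2"],
                                   [(background_sig, 250)], seed=50)
        exp = multinomial_catalog(
            sbs96, ["e1", "e2"],
            [(background_sig, 250), (treatment_sig, 500)], seed=51,
        )
        res = subtract_background(exp, fit_background(ctrl), seed=52)
        assert (res.signature.weights >= 0).all()
        assert res.signature.weights.sum() == pytest.approx(1.0)
        assert 0 < res.background_scale <= 1.0
        # every clamped channel's shortfall lay within its CI tolerance
        for lab in res.zeroed_channels:
            i = sbs96.index(lab)
            assert res.residuals[i] < 0
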
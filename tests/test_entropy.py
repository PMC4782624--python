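import numpy as np
import pytest

from pcgkit import (
    AudioSignal,
    SampEnConfig,
    irregularity_index,
    sample_entropy,
    sample_entropy_bruteforce,
)
from pcgkit.entropy import _pair_counts_tree

# SampEn of the first 30 samples of uniform(-1,1) under default_rng(12345),
# m=2, r=0.2 absolute; value frozen from the brute-force pair-counting
# reference written independently of the fast implementation.
SAMPEN_UNIFORM_30 = 1.252762968495368


class TestSampleEntropy:
    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_constant_series_is_zero(self, m):
        assert sample_entropy(np.full(50, 3.3), SampEnConfig(m=m, r=0.2)) == 0.0

    def test_frozen_regression_value(self):
        s = np.random.default_rng(12345).uniform(-1, 1, 30)
        cfg = SampEnConfig(m=2, r=0.2, r_mode="absolute")
        assert sample_entropy(s, cfg) == pytest.approx(SAMPEN_UNIFORM_30, abs=1e-12)

    def test_periodic_below_white_noise(self, rng):
        n = 400
        sine = np.sin(2 * np.pi * np.arange(n) / 20)
        noise = rng.standard_normal(n) * sine.std()
        cfg = SampEnConfig(m=2, r=0.2, r_mode="std_relative")
        assert sample_entropy(sine, cfg) < sample_entropy(noise, cfg)

    @pytest.mark.parametrize("m", [1, 2, 3])
    @pytest.mark.parametrize("r", [0.1, 0.2, 0.5])
    def test_matches_bruteforce_oracle(self, rng, m, r):
        s = rng.uniform(-1, 1, 120)
        cfg = SampEnConfig(m=m, r=r, r_mode="absolute")
        assert sample_entropy(s, cfg) == pytest.approx(
            sample_entropy_bruteforce(s, cfg), abs=1e-12
        )

    def test_tree_path_matches_sweep_path(self, rng):
        """The KD-tree fallback and the sorted-sweep kernel agree exactly."""
        from numpy.lib.stride_tricks import sliding_window_view

        from pcgkit.entropy import _HAVE_NUMBA

        s = np.round(rng.uniform(-1, 1, 150), 2)  # rounding forces duplicates
        m, r = 2, 0.2
        B_tree, A_tree = _pair_counts_tree(s, m, r, len(s) - m)
        if _HAVE_NUMBA:
            from pcgkit.entropy import _count_pairs_sorted

            T = sliding_window_view(s, m + 1)
            T = np.ascontiguousarray(T[np.argsort(T[:, 0], kind="stable")])
            B_sweep, A_sweep = _count_pairs_sorted(T, r)
            assert (B_tree, A_tree) == (B_sweep, A_sweep)
        cfg = SampEnConfig(m=m, r=r, r_mode="absolute")
        assert -np.log(A_tree / B_tree) == pytest.approx(
            sample_entropy_bruteforce(s, cfg), abs=1e-12
        )

    def test_non_increasing_in_r(self, rng):
        s = rng.standard_normal(200)
        values = [
            sample_entropy(s, SampEnConfig(m=2, r=r, r_mode="absolute"))
            for r in [0.1, 0.2, 0.5, 1.0, 2.0]
        ]
        finite = [v for v in values if np.isfinite(v)]
        assert all(a >= b - 1e-12 for a, b in zip(finite, finite[1:]))

    def test_scale_invariant_in_std_relative_mode(self, rng):
        s = rng.standard_normal(150)
        cfg = SampEnConfig(m=2, r=0.2, r_mode="std_relative")
        assert sample_entropy(3.7 * s, cfg) == pytest.approx(
            sample_entropy(s, cfg), abs=1e-10
        )

    def test_nonnegative_when_defined(self, rng):
        for _ in range(20):
            v = sample_entropy(rng.standard_normal(80), SampEnConfig(m=2, r=0.15))
            if np.isfinite(v):
                assert v >= 0.0

    def test_undefined_returns_inf_with_warning(self):
        # (0,0) templates match at m=2 but never at m=3: C^{m+1} = 0
        s = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 2.0, 0.0, 0.0, 3.0])
        with pytest.warns(RuntimeWarning, match="undefined"):
            v = sample_entropy(s, SampEnConfig(m=2, r=0.1, r_mode="absolute"))
        assert v == np.inf

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            sample_entropy(np.arange(3.0), SampEnConfig(m=2, r=0.2))


class TestIrregularityIndex:
    def test_single_cycle_equals_its_sampen(self, rng):
        sig = AudioSignal(rng.standard_normal(500), 8000.0, source_id="x")
        cyc = sig.samples[:400]
        cfg = SampEnConfig()
        fv = irregularity_index(sig, [cyc], cfg)
        assert fv.sampen == sample_entropy(cyc, cfg)
        assert fv.n_cycles_used == 1

    def test_mean_over_cycles_excludes_infinite(self, rng):
        sig = AudioSignal(rng.standard_normal(500), 8000.0)
        good = rng.standard_normal(300)
        bad = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 2.0, 0.0, 0.0, 3.0])
        cfg = SampEnConfig(m=2, r=0.1, r_mode="absolute")
        with pytest.warns(RuntimeWarning):
            fv = irregularity_index(sig, [good, bad], cfg)
        assert fv.n_cycles_used == 1
        assert fv.sampen == sample_entropy(good, cfg)

    def test_no_cycles_rejected(self, rng):
        sig = AudioSignal(rng.standard_normal(100), 8000.0)
        with pytest.raises(ValueError, match="cycle"):
            irregularity_index(sig, [], SampEnConfig())
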
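import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluidcnv import (
    BinnedSample,
    CNVSpec,
    GenomeModel,
    SimulationParams,
    center_profile,
    default_gc_bias,
    gc_correct,
    make_bins,
    normalize_log2,
    simulate_sample,
    synthetic_gc,
)
from fluidcnv.ratio import AlignmentError, DegenerateInputError


@pytest.fixture
def small_genome():
    return GenomeModel((("A", 50_000), ("B", 50_000), ("noise", 10_000)), frozenset(), "noise")


@pytest.fixture
def small_bins(small_genome):
    return make_bins(small_genome, 1000)


def constant_sample(bins, value, sample_id="s"):
    return BinnedSample(sample_id, np.full(len(bins), value, dtype=np.int64))


class TestNormalizeLog2:
    def test_identity_gives_zero(self, small_genome, small_bins):
        s = constant_sample(small_bins, 1000)
        prof = normalize_log2(s, s, small_bins, small_genome)
        assert np.allclose(prof.log2[np.isfinite(prof.log2)], 0.0)

    def test_library_size_invariance(self, small_genome, small_bins):
        ref = constant_sample(small_bins, 1000, "ref")
        doubled = constant_sample(small_bins, 2000)
        prof = normalize_log2(doubled, ref, small_bins, small_genome)
        assert np.allclose(prof.log2[np.isfinite(prof.log2)], 0.0)

    @given(st.integers(2, 50), st.booleans())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance_any_constant(self, scale, scale_reference):
        g = GenomeModel((("A", 20_000), ("B", 20_000)))
        bins = make_bins(g, 1000)
        rng = np.random.default_rng(0)
        base = rng.integers(500, 1500, len(bins))
        ref_base = rng.integers(500, 1500, len(bins))
        a = normalize_log2(BinnedSample("s", base), BinnedSample("r", ref_base), bins, g)
        if scale_reference:
            b = normalize_log2(
                BinnedSample("s", base), BinnedSample("r", ref_base * scale), bins, g
            )
        else:
            b = normalize_log2(
                BinnedSample("s", base * scale), BinnedSample("r", ref_base), bins, g
            )
        assert np.allclose(a.log2, b.log2, equal_nan=True)

    def test_halved_chromosome_reads_minus_one(self):
        # the halved chromosome is a minority of the genome, so median
        # centering anchors the diploid majority at zero
        g = GenomeModel((("A", 150_000), ("B", 50_000)))
        bins = make_bins(g, 1000)
        ref = constant_sample(bins, 1000, "ref")
        counts = np.full(len(bins), 1000, dtype=np.int64)
        on_b = (bins["chromosome"].astype(str) == "B").to_numpy()
        counts[on_b] //= 2
        prof = normalize_log2(BinnedSample("s", counts), ref, bins, g)
        # centering puts the diploid majority at 0; B sits one doubling below
        assert np.nanmedian(prof.log2[~on_b]) == pytest.approx(0.0, abs=1e-9)
        assert np.nanmedian(prof.log2[on_b]) == pytest.approx(-1.0, abs=0.01)

    def test_masked_and_zero_reference_bins_missing(self, small_genome, small_bins):
        bins = small_bins.copy()
        bins.loc[0, "masked"] = True
        ref_counts = np.full(len(bins), 1000, dtype=np.int64)
        ref_counts[5] = 0
        prof = normalize_log2(
            constant_sample(bins, 1000), BinnedSample("ref", ref_counts), bins, small_genome
        )
        assert np.isnan(prof.log2[0])
        assert np.isnan(prof.log2[5])
        assert np.isfinite(prof.log2[1])

    def test_alignment_and_degenerate_errors(self, small_genome, small_bins):
        ref = constant_sample(small_bins, 1000, "ref")
        with pytest.raises(AlignmentError):
            normalize_log2(BinnedSample("s", np.ones(3, dtype=int)), ref, small_bins, small_genome)
        with pytest.raises(DegenerateInputError):
            normalize_log2(constant_sample(small_bins, 0), ref, small_bins, small_genome)


class TestGcCorrect:
    def test_no_gc_dependence_is_noop(self, small_genome, small_bins):
        bins = synthetic_gc(small_bins, small_genome, seed=2)
        ref = constant_sample(bins, 1000, "ref")
        prof = normalize_log2(constant_sample(bins, 1000), ref, bins, small_genome)
        corrected = gc_correct(prof, bins, small_genome)
        finite = np.isfinite(prof.log2)
        assert np.nanmax(np.abs(corrected.log2[finite] - prof.log2[finite])) < 0.02

    def test_recovers_injected_quadratic_bias(self, genome, bins):
        biased = simulate_sample(
            bins, CNVSpec.diploid(),
            SimulationParams(gc_bias=default_gc_bias, seed=21), genome,
        )
        ref = simulate_sample(bins, CNVSpec.diploid(), SimulationParams(seed=22), genome, "ref")
        prof = normalize_log2(biased, ref, bins, genome)
        corrected = gc_correct(prof, bins, genome)
        sel = np.isfinite(corrected.log2) & (~bins["masked"].to_numpy())
        dist = np.abs(bins["gc"].to_numpy()[sel] - 0.45)
        before = abs(np.corrcoef(dist, prof.log2[sel])[0, 1])
        after = abs(np.corrcoef(dist, corrected.log2[sel])[0, 1])
        assert before > 0.3  # the injected bias is visible...
        assert after < 0.1  # ...and removed

    def test_all_gc_missing_skips_with_warning(self, small_genome, small_bins, caplog):
        ref = constant_sample(small_bins, 1000, "ref")
        prof = normalize_log2(constant_sample(small_bins, 997), ref, small_bins, small_genome)
        with caplog.at_level(logging.WARNING, logger="fluidcnv.ratio"):
            out = gc_correct(prof, small_bins, small_genome)
        assert np.array_equal(out.log2, prof.log2, equal_nan=True)
        assert any("skipped" in r.message for r in caplog.records)


class TestCenterProfile:
    def test_constant_profile_centered_with_offset(self, small_genome, small_bins):
        from fluidcnv import CopyRatioProfile

        prof = CopyRatioProfile(np.full(len(small_bins), 0.7), "s", "ref")
        out = center_profile(prof, small_bins, small_genome)
        assert np.allclose(out.log2, 0.0)
        assert out.centering_offset == pytest.approx(0.7)

    def test_majority_mode_preserved(self, small_genome, small_bins):
        from fluidcnv import CopyRatioProfile

        # 60% of baseline bins at 0, 40% at -1: median centering keeps the mode
        x = np.zeros(len(small_bins))
        baseline = (small_bins["chromosome"].astype(str) != "noise").to_numpy()
        n_shift = int(0.4 * baseline.sum())
        x[np.flatnonzero(baseline)[:n_shift]] = -1.0
        out = center_profile(CopyRatioProfile(x, "s", "ref"), small_bins, small_genome)
        assert out.centering_offset == pytest.approx(0.0)
        assert np.median(out.log2[baseline]) == pytest.approx(0.0)

    def test_recentering_is_idempotent(self, small_genome, small_bins):
        from fluidcnv import CopyRatioProfile

        rng = np.random.default_rng(3)
        prof = CopyRatioProfile(rng.normal(0.4, 0.1, len(small_bins)), "s", "ref")
        once = center_profile(prof, small_bins, small_genome)
        twice = center_profile(once, small_bins, small_genome)
        assert twice.centering_offset == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(once.log2, twice.log2)

    def test_noise_chromosome_cannot_shift_baseline(self, small_genome, small_bins):
        from fluidcnv import CopyRatioProfile

        x = np.zeros(len(small_bins))
        on_noise = (small_bins["chromosome"].astype(str) == "noise").to_numpy()
        x[on_noise] = 5.0  # wildly shifted noise chromosome
        out = center_profile(CopyRatioProfile(x, "s", "ref"), small_bins, small_genome)
        assert out.centering_offset == pytest.approx(0.0)

    def test_no_eligible_bins_is_error(self, small_genome, small_bins):
        from fluidcnv import CopyRatioProfile

        with pytest.raises(DegenerateInputError):
            center_profile(
                CopyRatioProfile(np.full(len(small_bins), np.nan), "s", "ref"),
                small_bins,
                small_genome,
            )

    def test_missing_count_never_decreases(self, genome, bins, reference):
        smp = simulate_sample(
            bins, CNVSpec.diploid(),
            SimulationParams(gc_bias=default_gc_bias, seed=31), genome,
        )
        prof = normalize_log2(smp, reference, bins, genome)
        n0 = prof.n_missing
        prof2 = gc_correct(prof, bins, genome)
        prof3 = center_profile(prof2, bins, genome)
        assert prof2.n_missing >= n0
        assert prof3.n_missing >= prof2.n_missing
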
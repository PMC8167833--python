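"""Bin counts -> centered, GC-corrected log2 copy ratios.

Body-fluid specimens are normalized against a single healthy reference
specimen: each bin's library-size-normalized depth is divided by the
reference's, log2-transformed, and median-centered.  Totals for library
size are taken over unmasked autosomal bins only, so sex-chromosome
content (which differs by sex and is excluded from interpretation) does
not perturb the scale.  Centering additionally excludes the noise
chromosome so a noisy chr19 analogue cannot shift the diploid baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeModel, InvalidParameterError

__all__ = ["CopyRatioProfile", "normalize_log2", "gc_correct", "center_profile"]

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Sample and reference are not on the same bin list."""


class DegenerateInputError(ValueError):
    """Input carries no usable signal (e.g. all-zero counts)."""


@dataclass(frozen=True)
class CopyRatioProfile:
    """Per-bin log2 copy ratios; NaN marks masked/undefined bins.

    ``centering_offset`` is what the most recent centering subtracted.
    """

    log2: np.ndarray
    sample_id: str
    reference_id: str
    centering_offset: float = 0.0
    depth: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "log2", np.asarray(self.log2, dtype=float))

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.log2).sum())


def _autosomal_unmasked(bins: pd.DataFrame, genome: GenomeModel) -> np.ndarray:
    chroms = bins["chromosome"].astype(str)
    return (~bins["masked"].to_numpy()) & chroms.map(genome.is_autosome).to_numpy()


def _baseline_bins(bins: pd.DataFrame, genome: GenomeModel) -> np.ndarray:
    """Unmasked autosomal bins excluding the noise chromosome."""
    sel = _autosomal_unmasked(bins, genome)
    if genome.noise_chromosome is not None:
        sel &= (bins["chromosome"].astype(str) != genome.noise_chromosome).to_numpy()
    return sel


def normalize_log2(sample, reference, bins: pd.DataFrame, genome: GenomeModel) -> CopyRatioProfile:
    """log2 of sample-to-reference normalized depth, median-centered.

    ``r_b = log2((s_b/S) / (ref_b/R))`` with S, R summed over unmasked
    autosomal bins.  Bins that are masked, or where the reference has
    zero coverage, are missing (NaN) — never zero-filled.
    """
    if len(sample.counts) != len(bins) or len(reference.counts) != len(bins):
        raise AlignmentError(
            f"bin list ({len(bins)}) does not match sample ({len(sample.counts)}) "
            f"or reference ({len(reference.counts)})"
        )
    sel = _autosomal_unmasked(bins, genome)
    S = float(sample.counts[sel].sum())
    R = float(reference.counts[sel].sum())
    if R <= 0:
        raise DegenerateInputError("reference has zero autosomal coverage")
    if S <= 0:
        raise DegenerateInputError("sample has zero autosomal coverage")

    s = sample.counts.astype(float)
    r = reference.counts.astype(float)
    valid = (~bins["masked"].to_numpy()) & (r > 0) & (s > 0)
    log2 = np.full(len(bins), np.nan)
    log2[valid] = np.log2((s[valid] / S) / (r[valid] / R))
    prof = CopyRatioProfile(log2, sample.sample_id, reference.sample_id, 0.0, depth=s)
    return center_profile(prof, bins, genome)


def gc_correct(
    profile: CopyRatioProfile,
    bins: pd.DataFrame,
    genome: GenomeModel,
    min_gc_coverage: float = 0.8,
    window_fraction: float = 0.1,
) -> CopyRatioProfile:
    """Remove the depth-vs-GC trend by rolling-median regression.

    The trend is estimated on unmasked autosomal non-noise bins (sorted
    by GC, rolling median over ``window_fraction`` of them) and
    interpolated at every bin's GC.  Bins without GC are left untouched.
    If fewer than ``min_gc_coverage`` of unmasked bins carry GC, the
    correction is skipped with a warning — not an error.
    """
    gc = bins["gc"].to_numpy(dtype=float)
    unmasked = ~bins["masked"].to_numpy()
    frac = np.isfinite(gc[unmasked]).mean() if unmasked.any() else 0.0
    if frac < min_gc_coverage:
        logger.warning(
            "gc_correct skipped: %.0f%% of unmasked bins have GC (< %.0f%% required)",
            100 * frac,
            100 * min_gc_coverage,
        )
        return profile

    fit = _baseline_bins(bins, genome) & np.isfinite(gc) & np.isfinite(profile.log2)
    if fit.sum() < 30:
        logger.warning("gc_correct skipped: too few bins to fit a trend")
        return profile
    order = np.argsort(gc[fit], kind="stable")
    gc_sorted = gc[fit][order]
    y_sorted = profile.log2[fit][order]
    window = max(31, int(window_fraction * fit.sum()) | 1)
    trend = (
        pd.Series(y_sorted).rolling(window, center=True, min_periods=window // 3).median().to_numpy()
    )
    ok = np.isfinite(trend)
    corrected = profile.log2.copy()
    apply_to = np.isfinite(gc) & np.isfinite(profile.log2)
    corrected[apply_to] -= np.interp(gc[apply_to], gc_sorted[ok], trend[ok])
    return replace(profile, log2=corrected)


def center_profile(profile: CopyRatioProfile, bins: pd.DataFrame, genome: GenomeModel) -> CopyRatioProfile:
    """Subtract the median over unmasked autosomal non-noise bins.

    ``centering_offset`` records what this centering subtracted, so
    re-centering an already-centered profile stores an offset of ~0.
    """
    sel = _baseline_bins(bins, genome) & np.isfinite(profile.log2)
    if not sel.any():
        raise DegenerateInputError("no unmasked autosomal non-noise bins to center on")
    med = float(np.median(profile.log2[sel]))
    return replace(profile, log2=profile.log2 - med, centering_offset=med)
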
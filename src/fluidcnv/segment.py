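"""Circular binary segmentation of log2 copy-ratio profiles.

Each chromosome's unmasked bins are partitioned independently into
piecewise-constant segments: recursively find the arc maximizing the
circular two-sample t statistic, accept the split if a seeded permutation
test gives p < alpha, recurse into the sub-segments, then merge adjacent
segments whose mean difference is not supported by their bin noise.
Masked/missing bins are skipped — segments are defined over unmasked bin
indices, with genomic coordinates taken from the flanking retained bins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _kernels
from .genome import InvalidParameterError
from .ratio import CopyRatioProfile

__all__ = ["cbs_segment", "segment_means_from_bins", "SEGMENT_COLUMNS"]

SEGMENT_COLUMNS = ["chromosome", "start", "end", "mean_log2", "n_bins"]

_PERM_BLOCK = 250


def _is_significant(
    x: np.ndarray,
    t2_obs: float,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> bool:
    """Seeded permutation test of the observed max arc statistic.

    p = (e + 1) / (N + 1) with e the number of permutations whose own max
    statistic reaches the observed one.  Evaluation stops early once e is
    large enough that p cannot drop below alpha.
    """
    stop_at = int(np.floor(alpha * (n_perm + 1) - 1))
    if stop_at < 0:
        return False
    e = 0
    done = 0
    while done < n_perm:
        block = min(_PERM_BLOCK, n_perm - done)
        perms = rng.permuted(np.tile(x, (block, 1)), axis=1)
        e_blk, rows = _kernels.perm_exceed_count(perms, t2_obs, stop_at - e)
        e += e_blk
        done += rows
        if e > stop_at:
            return False
    return True


def _recurse(
    x: np.ndarray,
    lo: int,
    hi: int,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
    cuts: list[int],
) -> None:
    """Collect interior cut indices (local, bins split before each cut)."""
    n = hi - lo
    if n < 2:
        return
    t2, i, j = _kernels.max_arc_t2(x[lo:hi])
    if t2 <= 0.0:
        return
    if not _is_significant(x[lo:hi], t2, alpha, n_perm, rng):
        return
    inner = [lo + k for k in (i, j) if 0 < k < n]
    if not inner:
        return
    cuts.extend(inner)
    bounds = sorted({lo, *inner, hi})
    for a, b in zip(bounds, bounds[1:]):
        _recurse(x, a, b, alpha, n_perm, rng, cuts)


def _merge_cuts(x: np.ndarray, cuts: list[int], undo_sd: float = 3.0) -> list[int]:
    """Remove cuts whose flanking segments are not credibly different.

    Adjacent segments are merged when |Δmean| < undo_sd × s_p / sqrt(n_h),
    with s_p the pooled within-segment SD of their bins and n_h the
    harmonic mean of the two bin counts; the weakest boundary is removed
    first and the pass repeats until stable.
    """
    bounds = sorted({0, *cuts, len(x)})
    while len(bounds) > 2:
        worst_k, worst_margin = -1, 0.0
        for k in range(1, len(bounds) - 1):
            a, b, c = bounds[k - 1], bounds[k], bounds[k + 1]
            left, right = x[a:b], x[b:c]
            n1, n2 = len(left), len(right)
            d = abs(left.mean() - right.mean())
            df = n1 + n2 - 2
            ssd = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
            if df <= 0 or ssd <= 0:
                thresh = 0.0
            else:
                n_h = 2.0 / (1.0 / n1 + 1.0 / n2)
                thresh = undo_sd * np.sqrt(ssd / df) / np.sqrt(n_h)
            margin = thresh - d
            if margin > worst_margin:
                worst_margin, worst_k = margin, k
        if worst_k < 0:
            break
        del bounds[worst_k]
    return bounds[1:-1]


def cbs_segment(
    profile: CopyRatioProfile,
    bins: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    seed: int = 0,
    merge: bool = True,
) -> pd.DataFrame:
    """Segment a copy-ratio profile chromosome by chromosome.

    Returns a DataFrame with columns ``chromosome, start, end, mean_log2,
    n_bins`` — adjacent, sorted, covering every unmasked finite bin.
    Deterministic for a given seed.
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError(f"alpha must lie in (0, 1), got {alpha}")
    if n_perm < 100:
        raise InvalidParameterError(f"n_perm must be >= 100, got {n_perm}")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in bins["chromosome"].cat.categories:
        on = (bins["chromosome"] == chrom).to_numpy()
        keep = on & (~bins["masked"].to_numpy()) & np.isfinite(profile.log2)
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            continue
        x = profile.log2[idx]
        cuts: list[int] = []
        if idx.size >= 2:
            _recurse(x, 0, len(x), alpha, n_perm, rng, cuts)
            if merge and cuts:
                cuts = _merge_cuts(x, cuts)
        bounds = sorted({0, *cuts, len(x)})
        for a, b in zip(bounds, bounds[1:]):
            seg_bins = idx[a:b]
            rows.append(
                {
                    "chromosome": str(chrom),
                    "start": int(bins["start"].iloc[seg_bins[0]]),
                    "end": int(bins["end"].iloc[seg_bins[-1]]),
                    "mean_log2": float(x[a:b].mean()),
                    "n_bins": int(b - a),
                }
            )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def segment_means_from_bins(
    profile: CopyRatioProfile,
    bins: pd.DataFrame,
    breakpoints: dict[str, list[int]],
) -> pd.DataFrame:
    """Segment means for externally supplied breakpoints.

    ``breakpoints`` maps chromosome name to sorted cut positions in that
    chromosome's unmasked-bin index space (a cut at k starts a new
    segment at the k-th unmasked bin).  Means are plain arithmetic means
    of the unmasked bin ratios in each span.
    """
    rows = []
    for chrom in bins["chromosome"].cat.categories:
        on = (bins["chromosome"] == chrom).to_numpy()
        keep = on & (~bins["masked"].to_numpy()) & np.isfinite(profile.log2)
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            continue
        cuts = list(breakpoints.get(str(chrom), []))
        if any(not 0 < c < idx.size for c in cuts):
            raise InvalidParameterError(
                f"breakpoint out of range on {chrom}: {cuts} (n={idx.size})"
            )
        if sorted(cuts) != cuts:
            raise InvalidParameterError(f"breakpoints must be sorted on {chrom}")
        bounds = [0, *cuts, idx.size]
        x = profile.log2[idx]
        for a, b in zip(bounds, bounds[1:]):
            seg_bins = idx[a:b]
            rows.append(
                {
                    "chromosome": str(chrom),
                    "start": int(bins["start"].iloc[seg_bins[0]]),
                    "end": int(bins["end"].iloc[seg_bins[-1]]),
                    "mean_log2": float(x[a:b].mean()),
                    "n_bins": int(b - a),
                }
            )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
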
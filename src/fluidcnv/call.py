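"""Per-sample malignancy calling from segmented copy-ratio profiles.

A specimen is CNV-positive when at least one segment survives the
interpretation rule: autosomal, not on the noise chromosome, longer than
the minimum size (10 Mbp at real scale), deviating from the diploid
baseline beyond both an absolute floor and a noise-scaled threshold, and
abrupt (flanked by contrasting segments or a chromosome end) rather than
gradual.  Tumor fraction is estimated from the deviating segment's mean
log2 ratio under a single-copy-change assumption: gains are treated as
trisomic (assumed ploidy 3), losses as monosomic (assumed ploidy 1).

    tumor fraction = (1 - 2^(log2 ratio)) / (1 - assumed_ploidy / 2)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import DESK_SCALE_FACTOR, GenomeModel, InvalidParameterError
from .ratio import CopyRatioProfile, center_profile, gc_correct, normalize_log2
from .segment import cbs_segment
from .simulate import BinnedSample

__all__ = [
    "PipelineParams",
    "SampleCall",
    "noise_metric",
    "call_cnvs",
    "tumor_fraction",
    "run_sample",
    "CNV_COLUMNS",
]

logger = logging.getLogger(__name__)

CNV_COLUMNS = [
    "chromosome",
    "start",
    "end",
    "direction",
    "size",
    "mean_log2",
    "n_bins",
    "assumed_ploidy",
    "event_tumor_fraction",
]

#: Gaussian consistency factor for the median absolute deviation.
MAD_SCALE = 1.4826

#: CNV counts at or above this render as "5+".
CNV_COUNT_CAP = 5


@dataclass(frozen=True)
class PipelineParams:
    """Tunable parameters of the per-sample pipeline.

    ``min_size`` defaults to 10 Mbp divided by the desk-scale factor.
    ``min_reads`` (absolute) overrides ``min_read_fraction`` of the
    reference total, which models the real-scale 450,000-read floor
    against a 7.6M-read cohort median (~6%).  ``n_perm`` defaults to
    1,000, a p-value resolution of 0.001 against alpha = 0.01.
    """

    alpha: float = 0.01
    n_perm: int = 1_000
    seed: int = 0
    min_size: int = 10_000_000 // DESK_SCALE_FACTOR
    k: float = 3.0
    abs_floor: float = 0.1
    min_read_fraction: float = 0.06
    min_reads: int | None = None
    gc_correction: bool = True


@dataclass
class SampleCall:
    """One specimen's malignancy call and tumor-fraction estimate."""

    sample_id: str
    qc_pass: bool
    positive: bool | None
    cnv_count_display: str
    tumor_fraction: float
    noise_mad: float
    total_reads: int
    cnvs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=CNV_COLUMNS))
    segments: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "qc_pass": self.qc_pass,
            "positive": self.positive,
            "cnv_count_display": self.cnv_count_display,
            "tumor_fraction": self.tumor_fraction,
            "noise_mad": self.noise_mad,
            "total_reads": self.total_reads,
        }


def cnv_count_display(count: int) -> str:
    return f"{CNV_COUNT_CAP}+" if count >= CNV_COUNT_CAP else str(count)


def noise_metric(profile: CopyRatioProfile, bins: pd.DataFrame, genome: GenomeModel) -> float:
    """Per-sample noise: scaled MAD of the noise chromosome's bin ratios.

    The noise chromosome (chr19 analogue) is excluded from calling and
    instead gauges the extent of per-bin scatter.  With fewer than 10
    usable bins there, the metric falls back to the genome-wide MAD of
    residuals about per-chromosome medians (logged, not an error).
    """
    unmasked = (~bins["masked"].to_numpy()) & np.isfinite(profile.log2)
    chroms = bins["chromosome"].astype(str).to_numpy()
    if genome.noise_chromosome is not None:
        on_noise = unmasked & (chroms == genome.noise_chromosome)
        if on_noise.sum() >= 10:
            x = profile.log2[on_noise]
            return float(MAD_SCALE * np.median(np.abs(x - np.median(x))))
    logger.warning("too few noise-chromosome bins; using genome-wide residual MAD")
    residuals = []
    for chrom in bins["chromosome"].cat.categories:
        sel = unmasked & (chroms == str(chrom))
        if sel.any():
            x = profile.log2[sel]
            residuals.append(x - np.median(x))
    if not residuals:
        raise InvalidParameterError("no unmasked bins to estimate noise from")
    res = np.concatenate(residuals)
    return float(MAD_SCALE * np.median(np.abs(res)))


def tumor_fraction(mean_log2: float, assumed_ploidy: int) -> float:
    """Tumor fraction implied by a segment's mean log2 ratio.

    Inverts the diploid-host/tumor mixture: a clone at fraction f with
    ploidy p over the segment gives copy number 2(1-f) + f·p, hence
    ``f = (1 - 2^r) / (1 - p/2)``.  Clamped to [0, 1].
    """
    if assumed_ploidy == 2:
        raise InvalidParameterError("assumed_ploidy 2 leaves the tumor fraction undefined")
    f = (1.0 - 2.0**mean_log2) / (1.0 - assumed_ploidy / 2.0)
    return float(min(1.0, max(0.0, f)))


def call_cnvs(
    segments: pd.DataFrame,
    genome: GenomeModel,
    noise: float,
    min_size: int | None = None,
    k: float = 3.0,
    abs_floor: float = 0.1,
) -> pd.DataFrame:
    """Apply the interpretation rule to a segment table.

    A segment is called iff (i) its chromosome is autosomal and not the
    noise chromosome, (ii) ``end - start > min_size``, (iii) its mean
    deviates from baseline by at least ``max(abs_floor, k·noise/√n_bins)``
    (the noise MAD scaled to the segment-mean level), and (iv) the
    deviation is abrupt: on each side the segment either abuts the
    chromosome end or differs from its neighbour's mean by >= abs_floor.
    Direction and assumed ploidy follow the sign of the mean (gain -> 3,
    loss -> 1); each call carries its event tumor fraction.
    """
    if min_size is None:
        min_size = 10_000_000 // DESK_SCALE_FACTOR
    rows = []
    for chrom, group in segments.groupby("chromosome", sort=False):
        if not genome.is_reportable(str(chrom)):
            continue
        g = group.reset_index(drop=True)
        for i, seg in g.iterrows():
            size = int(seg["end"] - seg["start"])
            if size <= min_size:
                continue
            mean = float(seg["mean_log2"])
            threshold = max(abs_floor, k * noise / math.sqrt(max(1, int(seg["n_bins"]))))
            if abs(mean) < threshold:
                continue
            abrupt = True
            for j in (i - 1, i + 1):
                if 0 <= j < len(g) and abs(mean - float(g.loc[j, "mean_log2"])) < abs_floor:
                    abrupt = False
            if not abrupt:
                continue
            direction = "gain" if mean > 0 else "loss"
            ploidy = 3 if mean > 0 else 1
            rows.append(
                {
                    "chromosome": str(chrom),
                    "start": int(seg["start"]),
                    "end": int(seg["end"]),
                    "direction": direction,
                    "size": size,
                    "mean_log2": mean,
                    "n_bins": int(seg["n_bins"]),
                    "assumed_ploidy": ploidy,
                    "event_tumor_fraction": tumor_fraction(mean, ploidy),
                }
            )
    return pd.DataFrame(rows, columns=CNV_COLUMNS)


def run_sample(
    sample: BinnedSample,
    reference: BinnedSample,
    bins: pd.DataFrame,
    genome: GenomeModel,
    params: PipelineParams | None = None,
) -> SampleCall:
    """Full per-specimen pipeline: QC -> ratio -> segment -> call.

    Samples under the read floor fail QC and get an undefined (None)
    positivity.  Otherwise the stages chain normalize -> GC-correct ->
    center -> segment -> call; the sample tumor fraction is the maximum
    event tumor fraction over called CNVs (0 when negative).
    """
    params = params or PipelineParams()
    floor = params.min_reads
    if floor is None:
        floor = params.min_read_fraction * reference.total_reads
    if sample.total_reads < floor:
        logger.warning(
            "%s failed QC: %d reads < floor %.0f", sample.sample_id, sample.total_reads, floor
        )
        return SampleCall(
            sample_id=sample.sample_id,
            qc_pass=False,
            positive=None,
            cnv_count_display="0",
            tumor_fraction=0.0,
            noise_mad=float("nan"),
            total_reads=sample.total_reads,
        )

    profile = normalize_log2(sample, reference, bins, genome)
    if params.gc_correction:
        profile = gc_correct(profile, bins, genome)
    profile = center_profile(profile, bins, genome)
    segments = cbs_segment(
        profile, bins, alpha=params.alpha, n_perm=params.n_perm, seed=params.seed
    )
    noise = noise_metric(profile, bins, genome)
    cnvs = call_cnvs(
        segments, genome, noise, min_size=params.min_size, k=params.k, abs_floor=params.abs_floor
    )
    tf = float(cnvs["event_tumor_fraction"].max()) if len(cnvs) else 0.0
    return SampleCall(
        sample_id=sample.sample_id,
        qc_pass=True,
        positive=bool(len(cnvs) > 0),
        cnv_count_display=cnv_count_display(len(cnvs)),
        tumor_fraction=tf,
        noise_mad=noise,
        total_reads=sample.total_reads,
        cnvs=cnvs,
        segments=segments,
    )
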
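"""Readers and writers for the on-disk formats.

Counts travel as 4-column TSV (chromosome, start, end, count); bins as
BED (chromosome, start, end, masked flag, optional GC); copy ratios and
segments in the CNVkit-style ``.cnr``/``.cns`` tab-separated dialects so
third-party viewers can render them; sample calls as JSON; cohort truth
tables as CSV.  All writers are deterministic; every format round-trips
the fields it defines.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .call import CNV_COLUMNS, SampleCall
from .genome import GenomeModel
from .ratio import AlignmentError, CopyRatioProfile
from .segment import SEGMENT_COLUMNS
from .simulate import BinnedSample

__all__ = [
    "RunConfig",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_bins_bed",
    "read_bins_bed",
    "write_cnr",
    "read_cnr",
    "write_cns",
    "read_cns",
    "write_calls_json",
    "read_calls_json",
]

COUNT_COLUMNS = ["chromosome", "start", "end", "count"]


@dataclasses.dataclass
class RunConfig:
    """One plain-text config governing a full run; CLI flags override.

    Serializes losslessly to JSON.
    """

    genome: str = "desk-scale"
    bin_size: int = 1000
    alpha: float = 0.01
    n_perm: int = 1000
    seed: int = 0
    min_size: int = 20_000
    k: float = 3.0
    abs_floor: float = 0.1
    min_read_fraction: float = 0.06
    min_reads: int | None = None
    gc_correction: bool = True

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _has_header(path, first_field: str) -> bool:
    with open(path) as fh:
        head = fh.readline()
    return head.split("\t")[0].strip().lower() == first_field


def read_counts_tsv(path, bins: pd.DataFrame, sample_id: str | None = None) -> BinnedSample:
    """Load a per-bin count table aligned to ``bins``.

    Rows may arrive in any order (sorted on load); coordinates must match
    the bin list exactly, and counts must be non-negative.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        names=COUNT_COLUMNS,
        header=0 if _has_header(path, "chromosome") else None,
    )
    if (df["count"] < 0).any():
        bad = df.index[df["count"] < 0][0]
        raise ValueError(f"{path.name} line {bad + 1}: negative count {df['count'].iloc[bad]}")
    order = {name: i for i, name in enumerate(bins["chromosome"].cat.categories)}
    df["_corder"] = df["chromosome"].map(order)
    if df["_corder"].isna().any():
        unknown = df.loc[df["_corder"].isna(), "chromosome"].iloc[0]
        raise AlignmentError(f"{path.name}: unknown chromosome {unknown!r}")
    df = df.sort_values(["_corder", "start"], kind="stable").reset_index(drop=True)
    if len(df) != len(bins):
        raise AlignmentError(f"{path.name}: {len(df)} rows for {len(bins)} bins")
    same = (
        (df["chromosome"].to_numpy() == bins["chromosome"].astype(str).to_numpy())
        & (df["start"].to_numpy() == bins["start"].to_numpy())
        & (df["end"].to_numpy() == bins["end"].to_numpy())
    )
    if not same.all():
        i = int(np.flatnonzero(~same)[0])
        raise AlignmentError(
            f"{path.name} line {i + 1}: coordinates "
            f"{df['chromosome'].iloc[i]}:{df['start'].iloc[i]}-{df['end'].iloc[i]} "
            f"do not match bin {bins['chromosome'].iloc[i]}:{bins['start'].iloc[i]}"
            f"-{bins['end'].iloc[i]}"
        )
    return BinnedSample(sample_id or path.stem.replace(".counts", ""), df["count"].to_numpy())


def write_counts_tsv(sample: BinnedSample, bins: pd.DataFrame, path) -> None:
    out = bins[["chromosome", "start", "end"]].copy()
    out["count"] = sample.counts
    out.to_csv(path, sep="\t", index=False)


def write_bins_bed(bins: pd.DataFrame, path) -> None:
    """BED: chromosome, start, end, masked flag (0/1), optional GC."""
    out = bins[["chromosome", "start", "end"]].copy()
    out["masked"] = bins["masked"].astype(int)
    if bins["gc"].notna().any():
        out["gc"] = bins["gc"].map(lambda v: f"{v:.6f}" if np.isfinite(v) else "")
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bins_bed(path, genome: GenomeModel) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = ["chromosome", "start", "end", "masked", "gc"][: df.shape[1]]
    if "gc" not in df:
        df["gc"] = np.nan
    df["masked"] = df["masked"].astype(bool)
    df["gc"] = pd.to_numeric(df["gc"], errors="coerce")
    df["chromosome"] = pd.Categorical(df["chromosome"], categories=genome.names, ordered=True)
    return df[["chromosome", "start", "end", "gc", "masked"]]


# ----------------------------------------------------------------------
# CNVkit-style dialects
# ----------------------------------------------------------------------

def write_cnr(profile: CopyRatioProfile, bins: pd.DataFrame, path) -> None:
    """Per-bin copy ratios, CNVkit ``.cnr`` column order.

    Missing log2 values render as empty fields; masked bins get weight 0.
    """
    depth = profile.depth if profile.depth is not None else np.full(len(bins), np.nan)
    out = pd.DataFrame(
        {
            "chromosome": bins["chromosome"].astype(str),
            "start": bins["start"],
            "end": bins["end"],
            "gene": ".",
            "log2": [f"{v:.6f}" if np.isfinite(v) else "" for v in profile.log2],
            "depth": [f"{v:.1f}" if np.isfinite(v) else "" for v in depth],
            "weight": np.where(bins["masked"], 0.0, 1.0),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_cnr(path, genome: GenomeModel, sample_id: str | None = None):
    """Load a ``.cnr`` table -> (bins DataFrame, CopyRatioProfile)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    bins = pd.DataFrame(
        {
            "chromosome": pd.Categorical(df["chromosome"], categories=genome.names, ordered=True),
            "start": df["start"].astype(np.int64),
            "end": df["end"].astype(np.int64),
            "gc": np.nan,
            "masked": df.get("weight", pd.Series(1.0, index=df.index)).astype(float) <= 0,
        }
    )
    log2 = pd.to_numeric(df["log2"], errors="coerce").to_numpy()
    depth = pd.to_numeric(df.get("depth"), errors="coerce").to_numpy() if "depth" in df else None
    profile = CopyRatioProfile(log2, sample_id or path.stem, "external", 0.0, depth=depth)
    return bins, profile


def write_cns(segments: pd.DataFrame, path) -> None:
    """Segment table, CNVkit ``.cns`` column order (probes = n_bins)."""
    out = pd.DataFrame(
        {
            "chromosome": segments["chromosome"],
            "start": segments["start"],
            "end": segments["end"],
            "gene": ".",
            "log2": [f"{v:.6f}" for v in segments["mean_log2"]],
            "depth": "",
            "probes": segments["n_bins"],
            "weight": segments["n_bins"].astype(float),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_cns(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return pd.DataFrame(
        {
            "chromosome": df["chromosome"],
            "start": df["start"].astype(np.int64),
            "end": df["end"].astype(np.int64),
            "mean_log2": pd.to_numeric(df["log2"]),
            "n_bins": df["probes"].astype(int),
        }
    )[SEGMENT_COLUMNS]


# ----------------------------------------------------------------------
# sample calls
# ----------------------------------------------------------------------

def write_calls_json(calls: list[SampleCall] | SampleCall, path) -> None:
    if isinstance(calls, SampleCall):
        calls = [calls]
    with open(path, "w") as fh:
        json.dump([c.to_dict() for c in calls], fh, indent=2)
        fh.write("\n")


def read_calls_json(path) -> pd.DataFrame:
    with open(path) as fh:
        rows = json.load(fh)
    return pd.DataFrame(rows)


def write_cnvs_bed(cnvs: pd.DataFrame, path) -> None:
    """Called CNVs as BED+: chrom, start, end, direction, mean_log2, event TF."""
    cols = ["chromosome", "start", "end", "direction", "mean_log2", "event_tumor_fraction"]
    cnvs.reindex(columns=cols).to_csv(path, sep="\t", index=False, header=False)


def empty_cnvs() -> pd.DataFrame:
    return pd.DataFrame(columns=CNV_COLUMNS)
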
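"""Genome model and fixed-width binning.

All coordinates are 0-based, half-open (BED convention).

The default working genome is a desk-scale model: hg38 chromosome lengths
divided by 500, tiled with 1 kb bins (~6,200 bins genome-wide, ~5,800
autosomal).  Relative chromosome sizes — including the GC-rich, noisy
chr19 analogue — are preserved, so interpretation rules stated in physical
units (e.g. a 10 Mbp minimum CNV size) carry over after dividing by the
same factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "make_bins",
    "annotate_gc",
    "HG38_LENGTHS",
    "DESK_SCALE_FACTOR",
]

#: hg38 primary-assembly chromosome lengths (bp).
HG38_LENGTHS: dict[str, int] = {
    "chr1": 248_956_422,
    "chr2": 242_193_529,
    "chr3": 198_295_559,
    "chr4": 190_214_555,
    "chr5": 181_538_259,
    "chr6": 170_805_979,
    "chr7": 159_345_973,
    "chr8": 145_138_636,
    "chr9": 138_394_717,
    "chr10": 133_797_422,
    "chr11": 135_086_622,
    "chr12": 133_275_309,
    "chr13": 114_364_328,
    "chr14": 107_043_718,
    "chr15": 101_991_189,
    "chr16": 90_338_345,
    "chr17": 83_257_441,
    "chr18": 80_373_285,
    "chr19": 58_617_616,
    "chr20": 64_444_167,
    "chr21": 46_709_983,
    "chr22": 50_818_468,
    "chrX": 156_040_895,
    "chrY": 57_227_415,
}

#: Divisor applied to hg38 lengths for the desk-scale genome.
DESK_SCALE_FACTOR = 500

#: Fraction of ``bin_size`` below which a trailing partial bin is masked.
MIN_PARTIAL_BIN_FRACTION = 0.25


class InvalidParameterError(ValueError):
    """A parameter is outside its documented domain."""


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes with lengths plus interpretation role flags.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs; genome order is preserved
        everywhere downstream.
    sex_chromosomes
        Chromosomes excluded wholesale from CNV interpretation (sex is
        not accounted for when normalizing to a single reference).
    noise_chromosome
        Autosome used only as a per-sample noise gauge (the chr19
        analogue: GC-rich and systematically noisier than the rest),
        never as a source of CNV calls.
    """

    chromosomes: tuple[tuple[str, int], ...]
    sex_chromosomes: frozenset[str] = field(default_factory=frozenset)
    noise_chromosome: str | None = None

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise InvalidParameterError("duplicate chromosome names")
        if any(length < 1 for _, length in self.chromosomes):
            raise InvalidParameterError("chromosome lengths must be >= 1")
        missing = set(self.sex_chromosomes) - set(names)
        if missing:
            raise InvalidParameterError(f"sex chromosomes not in genome: {sorted(missing)}")
        if self.noise_chromosome is not None:
            if self.noise_chromosome not in names:
                raise InvalidParameterError(
                    f"noise chromosome {self.noise_chromosome!r} not in genome"
                )
            if self.noise_chromosome in self.sex_chromosomes:
                raise InvalidParameterError("noise chromosome cannot be a sex chromosome")
        # normalize container types for hashability / JSON round trips
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))
        object.__setattr__(self, "sex_chromosomes", frozenset(self.sex_chromosomes))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length(self, name: str) -> int:
        for n, l in self.chromosomes:
            if n == name:
                return l
        raise KeyError(name)

    def is_autosome(self, name: str) -> bool:
        return name not in self.sex_chromosomes

    def is_reportable(self, name: str) -> bool:
        """Whether CNV calls on this chromosome count toward positivity."""
        return self.is_autosome(name) and name != self.noise_chromosome

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    # ------------------------------------------------------------------
    # constructors / serialization
    # ------------------------------------------------------------------
    @classmethod
    def desk_scale(cls, factor: int = DESK_SCALE_FACTOR) -> "GenomeModel":
        """hg38 scaled 1:``factor`` with chrX/chrY flagged sex and the
        chr19 analogue flagged as the noise chromosome."""
        chroms = tuple((name, max(1, length // factor)) for name, length in HG38_LENGTHS.items())
        return cls(chroms, frozenset({"chrX", "chrY"}), "chr19")

    @classmethod
    def from_json(cls, path) -> "GenomeModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            tuple((c["name"], int(c["length"])) for c in obj["chromosomes"]),
            frozenset(obj.get("sex_chromosomes", ())),
            obj.get("noise_chromosome"),
        )

    def to_json(self, path) -> None:
        obj = {
            "chromosomes": [{"name": n, "length": l} for n, l in self.chromosomes],
            "sex_chromosomes": sorted(self.sex_chromosomes),
            "noise_chromosome": self.noise_chromosome,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_tsv(
        cls,
        path,
        sex_chromosomes: frozenset[str] = frozenset({"chrX", "chrY"}),
        noise_chromosome: str | None = "chr19",
    ) -> "GenomeModel":
        """Two-column name/length TSV (no header), role flags by convention."""
        df = pd.read_csv(path, sep="\t", header=None, names=["name", "length"])
        names = set(df["name"])
        return cls(
            tuple(zip(df["name"], df["length"].astype(int))),
            frozenset(sex_chromosomes & names),
            noise_chromosome if noise_chromosome in names else None,
        )


def make_bins(genome: GenomeModel, bin_size: int) -> pd.DataFrame:
    """Tile every chromosome with fixed-width bins.

    Returns a DataFrame with columns ``chromosome, start, end, gc, masked``
    in genome order.  The final bin of each chromosome is truncated to the
    chromosome end; trailing bins narrower than 25% of ``bin_size`` are
    kept but masked so they never drive calls.
    """
    if bin_size < 1:
        raise InvalidParameterError(f"bin_size must be >= 1, got {bin_size}")
    frames = []
    for name, length in genome.chromosomes:
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        widths = ends - starts
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": name,
                    "start": starts,
                    "end": ends,
                    "gc": np.nan,
                    "masked": widths < MIN_PARTIAL_BIN_FRACTION * bin_size,
                }
            )
        )
    bins = pd.concat(frames, ignore_index=True)
    bins["chromosome"] = pd.Categorical(bins["chromosome"], categories=genome.names, ordered=True)
    return bins


def annotate_gc(
    bins: pd.DataFrame,
    sequence_source,
    max_ambiguous_fraction: float = 0.5,
) -> pd.DataFrame:
    """Set per-bin GC fraction from sequences or a precomputed table.

    ``sequence_source`` is either a mapping/``pyfaidx.Fasta``-like object
    of chromosome name -> sequence string, or a DataFrame with columns
    ``chromosome, start, end, gc`` aligned to ``bins``.  Bins whose
    sequence is more than 50% ambiguous (non-ACGT) are flagged masked.
    Returns a new bins DataFrame; the input is not modified.
    """
    out = bins.copy()
    if isinstance(sequence_source, pd.DataFrame):
        src = sequence_source
        key = ["chromosome", "start", "end"]
        merged = out[key].astype({"chromosome": str}).merge(
            src.astype({"chromosome": str}), on=key, how="left", validate="one_to_one"
        )
        gc = merged["gc"].to_numpy(dtype=float)
        have = set(src["chromosome"].astype(str))
        missing = [c for c in out["chromosome"].astype(str).unique() if c not in have]
        if missing:
            raise KeyError(f"gc table missing chromosome(s): {missing}")
        out["gc"] = gc
    else:
        gc = np.full(len(out), np.nan)
        masked = out["masked"].to_numpy().copy()
        chroms = out["chromosome"].astype(str).to_numpy()
        starts = out["start"].to_numpy()
        ends = out["end"].to_numpy()
        for i in range(len(out)):
            try:
                seq = sequence_source[chroms[i]]
            except KeyError as exc:
                raise KeyError(f"sequence source missing chromosome {chroms[i]!r}") from exc
            sub = str(seq[starts[i] : ends[i]]).upper()
            if not sub:
                masked[i] = True
                continue
            n_gc = sub.count("G") + sub.count("C")
            n_at = sub.count("A") + sub.count("T")
            n_known = n_gc + n_at
            if n_known < (1.0 - max_ambiguous_fraction) * len(sub):
                masked[i] = True
            if n_known:
                gc[i] = n_gc / n_known
        out["gc"] = gc
        out["masked"] = masked
    bad = out["gc"].notna() & ((out["gc"] < 0) | (out["gc"] > 1))
    if bad.any():
        raise InvalidParameterError("gc fractions must lie in [0, 1]")
    return out
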
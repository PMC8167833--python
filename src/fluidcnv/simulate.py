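"""Synthetic binned-count cohorts with implanted clonal CNVs.

Emulates what shallow whole-genome sequencing of body-fluid cfDNA yields
after alignment, deduplication and fixed-width binning: one integer read
count per genomic bin, for a diploid reference specimen and for fluid
specimens carrying a single malignant clone at a given tumor fraction.

Count noise is negative-binomial (mean/size parameterization; infinite
size degenerates to Poisson).  The defaults model the study conditions:
~1,500 reads per 1 kb desk-scale bin (≈8.7M reads genome-wide, matching a
median of 7.6M reads per specimen at the real scale), overdispersion
giving a per-bin log2-ratio noise of ≈0.10, a doubled coefficient of
variation on the chr19 analogue, and an optional smooth GC bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import load_cytology_negative_cohort
from .genome import GenomeModel, InvalidParameterError

__all__ = [
    "CNVEvent",
    "CNVSpec",
    "SimulationParams",
    "BinnedSample",
    "expected_copy",
    "default_gc_bias",
    "synthetic_gc",
    "simulate_sample",
    "simulate_cohort",
    "case_control_design",
]


@dataclass(frozen=True)
class CNVEvent:
    """One clonal copy-number event: ``tumor_ploidy`` copies in the tumor
    clone over [start, end) — e.g. 1 for a monosomy, 3 for a trisomy."""

    chromosome: str
    start: int
    end: int
    tumor_ploidy: int

    def __post_init__(self) -> None:
        if self.tumor_ploidy == 2:
            raise InvalidParameterError("tumor_ploidy 2 is not a copy-number event")
        if self.tumor_ploidy < 0:
            raise InvalidParameterError("tumor_ploidy must be >= 0")
        if not 0 <= self.start < self.end:
            raise InvalidParameterError("need 0 <= start < end")


@dataclass(frozen=True)
class CNVSpec:
    """A clone's CNV events plus the tumor fraction of the specimen."""

    events: tuple[CNVEvent, ...]
    tumor_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise InvalidParameterError("tumor_fraction must lie in [0, 1]")
        object.__setattr__(self, "events", tuple(self.events))
        by_chrom: dict[str, list[CNVEvent]] = {}
        for ev in self.events:
            by_chrom.setdefault(ev.chromosome, []).append(ev)
        for chrom, evs in by_chrom.items():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if b.start < a.end:
                    raise InvalidParameterError(f"overlapping events on {chrom}")

    @classmethod
    def diploid(cls) -> "CNVSpec":
        return cls((), 0.0)


@dataclass(frozen=True)
class SimulationParams:
    """Noise model for one simulated specimen.

    ``dispersion`` is the negative-binomial size; ``np.inf`` gives
    Poisson counts.  ``noise_chr_extra_sd`` multiplies the count
    coefficient of variation on the genome's noise chromosome, emulating
    chr19's tendency to appear noisier than the rest of the genome.
    """

    mean_reads_per_bin: float = 1500.0
    dispersion: float = 600.0
    gc_bias: Callable[[np.ndarray], np.ndarray] | None = None
    noise_chr_extra_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_reads_per_bin <= 0:
            raise InvalidParameterError("mean_reads_per_bin must be > 0")
        if self.dispersion <= 0:
            raise InvalidParameterError("dispersion must be > 0")
        if self.noise_chr_extra_sd < 1:
            raise InvalidParameterError("noise_chr_extra_sd must be >= 1")


@dataclass
class BinnedSample:
    """Per-bin read counts for one specimen, aligned to a bin table."""

    sample_id: str
    counts: np.ndarray
    total_reads: int = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise InvalidParameterError("counts must be non-negative")
        self.total_reads = int(self.counts.sum())


def expected_copy(bins: pd.DataFrame, spec: CNVSpec) -> np.ndarray:
    """Per-bin expected copy number of the diploid-host/tumor mixture.

    A bin inside an event of tumor ploidy ``p`` has copy number
    ``2(1-f) + f*p``; all other bins are diploid.  Bins are assigned to
    an event by midpoint.
    """
    f = spec.tumor_fraction
    copy = np.full(len(bins), 2.0)
    if f == 0.0 or not spec.events:
        return copy
    chroms = bins["chromosome"].astype(str).to_numpy()
    mid = (bins["start"].to_numpy() + bins["end"].to_numpy()) // 2
    for ev in spec.events:
        inside = (chroms == ev.chromosome) & (mid >= ev.start) & (mid < ev.end)
        copy[inside] = 2.0 * (1.0 - f) + f * ev.tumor_ploidy
    return copy


def default_gc_bias(gc: np.ndarray) -> np.ndarray:
    """Unimodal quadratic depth multiplier peaking at GC 0.45, range [0.7, 1].

    Falls to its 0.7 floor at |GC - 0.45| = 0.2, so depth varies by up to
    ~30% across the GC range real bins occupy — a correctable bias of
    realistic size.
    """
    gc = np.asarray(gc, dtype=float)
    mult = 1.0 - 7.5 * (gc - 0.45) ** 2
    mult = np.clip(mult, 0.7, 1.0)
    return np.where(np.isfinite(gc), mult, 1.0)


def synthetic_gc(bins: pd.DataFrame, genome: GenomeModel, seed: int = 0) -> pd.DataFrame:
    """Attach a plausible per-bin GC fraction to a bin table.

    Genome-wide GC is drawn around 0.41 (sd 0.05) with the noise
    chromosome shifted to ≈0.48, mimicking chr19's GC richness.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    gc = rng.normal(0.41, 0.05, size=len(bins))
    if genome.noise_chromosome is not None:
        on_noise = (bins["chromosome"].astype(str) == genome.noise_chromosome).to_numpy()
        gc[on_noise] += 0.07
    out = bins.copy()
    out["gc"] = np.clip(gc, 0.25, 0.65)
    return out


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, inv_size: np.ndarray) -> np.ndarray:
    """Negative-binomial draws with per-bin mean and inverse size; zero
    inverse size means Poisson."""
    counts = np.empty(len(mu), dtype=np.int64)
    pois = inv_size <= 0
    if pois.any():
        counts[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        size = 1.0 / inv_size[~pois]
        m = mu[~pois]
        counts[~pois] = rng.negative_binomial(size, size / (size + m))
    return counts


def simulate_sample(
    bins: pd.DataFrame,
    spec: CNVSpec,
    params: SimulationParams,
    genome: GenomeModel,
    sample_id: str = "sample",
) -> BinnedSample:
    """Draw one specimen's per-bin counts.

    The per-bin mean is ``mean_reads_per_bin × gc_bias(gc) × copy/2``.
    On the noise chromosome the count coefficient of variation is
    inflated by ``noise_chr_extra_sd`` (variance re-parameterized so the
    CV scales exactly).  Masked bins are drawn like any other and left to
    downstream masking.  Identical seeds give identical samples.
    """
    rng = np.random.default_rng(params.seed)
    mu = np.full(len(bins), params.mean_reads_per_bin, dtype=float)
    if params.gc_bias is not None:
        mu = mu * params.gc_bias(bins["gc"].to_numpy(dtype=float))
    mu = mu * expected_copy(bins, spec) / 2.0
    mu = np.maximum(mu, 1e-9)

    inv_size = np.full(len(bins), 0.0 if np.isinf(params.dispersion) else 1.0 / params.dispersion)
    s = params.noise_chr_extra_sd
    if genome.noise_chromosome is not None and s > 1.0:
        on_noise = (bins["chromosome"].astype(str) == genome.noise_chromosome).to_numpy()
        # CV^2 = 1/mu + 1/size; scale total CV^2 by s^2 via the size term
        inv_size = np.where(on_noise, s**2 * (1.0 / mu + inv_size) - 1.0 / mu, inv_size)
    return BinnedSample(sample_id, _nb_counts(rng, mu, inv_size))


def simulate_cohort(
    design: Sequence[tuple[str, CNVSpec, SimulationParams]],
    bins: pd.DataFrame,
    genome: GenomeModel,
) -> tuple[list[BinnedSample], pd.DataFrame]:
    """Simulate a labeled cohort.

    ``design`` holds ``(truth_label, spec, params)`` entries; sample ids
    are assigned ``S001..`` in order.  Returns the samples plus a truth
    table with columns ``sample_id, truth_label, true_tumor_fraction``.
    """
    if not design:
        raise InvalidParameterError("empty cohort design")
    samples, rows = [], []
    for i, (label, spec, params) in enumerate(design, start=1):
        sid = f"S{i:03d}"
        samples.append(simulate_sample(bins, spec, params, genome, sample_id=sid))
        rows.append({"sample_id": sid, "truth_label": label, "true_tumor_fraction": spec.tumor_fraction})
    return samples, pd.DataFrame(rows)


def _random_events(
    rng: np.random.Generator,
    genome: GenomeModel,
    n_events: int,
    min_size: int,
    max_size: int,
) -> tuple[CNVEvent, ...]:
    """Place non-overlapping clonal events on distinct reportable chromosomes."""
    eligible = [
        (name, length)
        for name, length in genome.chromosomes
        if genome.is_reportable(name) and length >= int(1.5 * min_size)
    ]
    order = rng.permutation(len(eligible))
    events = []
    for idx in order[:n_events]:
        name, length = eligible[idx]
        size = int(rng.integers(min_size, min(max_size, int(0.8 * length)) + 1))
        start = int(rng.integers(0, length - size + 1))
        ploidy = int(rng.choice([1, 3]))
        events.append(CNVEvent(name, start, start + size, ploidy))
    return tuple(events)


def case_control_design(
    seed: int,
    genome: GenomeModel,
    n_positive: int = 36,
    n_negative: int = 59,
    params: SimulationParams | None = None,
    scale: int = 500,
) -> list[tuple[str, CNVSpec, SimulationParams]]:
    """The default case-control cohort preset.

    ``n_positive`` malignant specimens with tumor fractions resampled
    from the published nonzero values (0.056–0.96) and 1–6 clonal events
    of 20–75 Mbp (divided by ``scale``), plus ``n_negative`` CNV-free
    infectious controls.  Event-count weights follow the published capped
    CNV-count categories.  Fluid samples carry the default GC bias so the
    correction step is exercised; seeds derive from ``seed``.
    """
    base = params or SimulationParams()
    rng = np.random.default_rng(seed)
    ref = load_cytology_negative_cohort()
    tf_pool = ref.loc[ref["tumor_fraction"] > 0, "tumor_fraction"].to_numpy()
    # capped-category weights among published CNV-positive specimens
    count_values = [1, 2, 3, 4, 5, 6]
    count_weights = np.array([1, 1, 0.5, 2, 7, 8], dtype=float)
    count_weights /= count_weights.sum()
    min_size = 20_000_000 // scale
    max_size = 75_000_000 // scale

    design: list[tuple[str, CNVSpec, SimulationParams]] = []
    for _ in range(n_positive):
        f = float(rng.choice(tf_pool))
        n_ev = int(rng.choice(count_values, p=count_weights))
        spec = CNVSpec(_random_events(rng, genome, n_ev, min_size, max_size), f)
        p = SimulationParams(
            mean_reads_per_bin=base.mean_reads_per_bin,
            dispersion=base.dispersion,
            gc_bias=default_gc_bias,
            noise_chr_extra_sd=2.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        design.append(("cytology_positive", spec, p))
    for _ in range(n_negative):
        p = SimulationParams(
            mean_reads_per_bin=base.mean_reads_per_bin,
            dispersion=base.dispersion,
            gc_bias=default_gc_bias,
            noise_chr_extra_sd=2.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        design.append(("negative_control", CNVSpec.diploid(), p))
    return design
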
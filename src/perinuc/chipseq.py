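"""Spike-in normalization of ChIP coverage and replicate ribbon profiling.

The pipeline ingests per-base coverage (bedgraph or BED-like alignment
intervals), scales every sample by a factor derived from an ectopic spiked
reference locus, and summarizes replicate isolates into per-window
median/min/max "ribbon" profiles.

The scale factor for a sample is

    S = c / (m_spike - m_ref)

where ``m_spike`` is the median per-base depth over the spiked reference
locus (an ectopic ade6+ gene residing in pericentric heterochromatin of the
spike strain), ``m_ref`` the median per-base depth over a nearby euchromatic
interval, and ``c`` a fixed constant (default 10).  Because the spike strain
is mixed into every sample culture at a constant ratio, the spike signal is
a constant reference and normalized tracks are comparable across samples
without input-chromatin normalization (which is deliberately not applied).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeSpec, GenomicInterval

#: Default spike/reference intervals (S. pombe chr III, ade6 locus and the
#: adjacent euchromatic region), converted from 1-based inclusive spans.
DEFAULT_SPIKE_INTERVAL = GenomicInterval.from_one_based("III", 1316291, 1318035)
DEFAULT_REFERENCE_INTERVAL = GenomicInterval.from_one_based("III", 1304000, 1380000)
DEFAULT_SCALE_CONSTANT = 10.0


class SpikeEnrichmentError(ValueError):
    """Spike-locus median does not exceed the flanking euchromatin median."""


@dataclass
class CoverageTrack:
    """Per-base read depth per chromosome (0-based half-open coordinates)."""

    depths: dict[str, np.ndarray]
    normalized: bool = False

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for chrom, arr in self.depths.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"depth array for {chrom!r} must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"negative depths on {chrom!r}")
            clean[chrom] = arr
        self.depths = clean

    @property
    def chromosomes(self) -> list[str]:
        return list(self.depths)

    def length(self, chrom: str) -> int:
        return len(self.depths[chrom])

    def slice(self, interval: GenomicInterval) -> np.ndarray:
        arr = self.depths.get(interval.chrom)
        if arr is None:
            raise KeyError(f"track has no chromosome {interval.chrom!r}")
        if interval.end > len(arr):
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"outside track (length {len(arr)})"
            )
        return arr[interval.start : interval.end]

    def scaled(self, factor: float, normalized: bool | None = None) -> "CoverageTrack":
        return CoverageTrack(
            {c: a * factor for c, a in self.depths.items()},
            normalized=self.normalized if normalized is None else normalized,
        )


@dataclass
class SpikeNormConfig:
    """Intervals and constant entering the spike scale factor.

    The published reference interval encloses the spike locus; the median is
    robust to that overlap (the spike spans ~2% of the reference interval),
    but ``exclude_spike_from_reference`` removes the overlap if desired.
    """

    spike_interval: GenomicInterval = DEFAULT_SPIKE_INTERVAL
    reference_interval: GenomicInterval = DEFAULT_REFERENCE_INTERVAL
    scale_constant: float = DEFAULT_SCALE_CONSTANT
    exclude_spike_from_reference: bool = False

    def __post_init__(self) -> None:
        if self.spike_interval.chrom != self.reference_interval.chrom:
            raise ValueError("spike and reference intervals must share a chromosome")
        if self.scale_constant <= 0:
            raise ValueError("scale_constant must be positive")


def trim_reads(reads: Sequence[str], n_trim: int = 3) -> list[str]:
    """Trim ``n_trim`` bases from the 5' end of every read.

    Library construction adds template-switching bases at the 5' end; 50 bp
    raw reads become 47 bp post-trim.
    """
    if n_trim < 0:
        raise ValueError("n_trim must be >= 0")
    out = []
    for i, read in enumerate(reads):
        if len(read) <= n_trim:
            raise ValueError(
                f"read {i} (length {len(read)}) too short to trim {n_trim} bases"
            )
        out.append(read[n_trim:])
    return out


def compute_coverage(
    alignments: Iterable[tuple[str, int, int]],
    genome: GenomeSpec | dict[str, int],
) -> CoverageTrack:
    """Per-base depth from alignment intervals (each reported location counts once).

    Uses a difference array per chromosome, so runtime is O(reads + genome).
    """
    sizes = genome.sizes if isinstance(genome, GenomeSpec) else dict(genome)
    diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in sizes.items()}
    for chrom, start, end in alignments:
        if chrom not in diffs:
            raise ValueError(f"alignment on unknown chromosome {chrom!r}")
        if start < 0 or end > sizes[chrom] or end <= start:
            raise ValueError(
                f"alignment {chrom}:{start}-{end} outside chromosome bounds"
            )
        diffs[chrom][start] += 1
        diffs[chrom][end] -= 1
    return CoverageTrack({c: np.cumsum(d[:-1]).astype(float) for c, d in diffs.items()})


def spike_norm_stats(track: CoverageTrack, cfg: SpikeNormConfig) -> dict[str, float]:
    """Medians and scale factor for one sample (the per-sample log record)."""
    m_spike = float(np.median(track.slice(cfg.spike_interval)))
    ref = cfg.reference_interval
    if cfg.exclude_spike_from_reference:
        arr = track.slice(ref)
        lo = max(cfg.spike_interval.start, ref.start) - ref.start
        hi = min(cfg.spike_interval.end, ref.end) - ref.start
        keep = np.ones(len(arr), dtype=bool)
        if hi > lo:
            keep[lo:hi] = False
        m_ref = float(np.median(arr[keep]))
    else:
        m_ref = float(np.median(track.slice(ref)))
    stats = {"m_spike": m_spike, "m_ref": m_ref}
    if m_spike <= m_ref:
        raise SpikeEnrichmentError(
            f"no spike enrichment: m_spike={m_spike} <= m_ref={m_ref}; "
            "cannot form scale factor"
        )
    stats["scale_factor"] = cfg.scale_constant / (m_spike - m_ref)
    return stats


def spike_scale_factor(track: CoverageTrack, cfg: SpikeNormConfig | None = None) -> float:
    """Scale factor S = c / (m_spike - m_ref) for one coverage track."""
    return spike_norm_stats(track, cfg or SpikeNormConfig())["scale_factor"]


def normalize_track(track: CoverageTrack, scale_factor: float) -> CoverageTrack:
    """Multiply every depth by the spike scale factor; tags output as normalized."""
    if scale_factor <= 0:
        raise ValueError("scale factor must be positive")
    return track.scaled(scale_factor, normalized=True)


@dataclass
class RibbonProfile:
    """Per-window median/min/max across replicate isolates.

    ``windows`` columns: chrom, start, end, median, min, max (plus one
    ``isolate_<i>`` column per input track with its per-window summary).
    """

    windows: pd.DataFrame
    window: int
    step: int
    summary: str = "mean"

    def to_tsv(self, path) -> None:
        self.windows.to_csv(path, sep="\t", index=False)


def ribbon_profile(
    tracks: Sequence[CoverageTrack],
    window: int = 250,
    step: int = 25,
    region: GenomicInterval | None = None,
    summary: str = "mean",
) -> RibbonProfile:
    """Sliding-window replicate ribbon (median line, min-max range).

    Per window and isolate, per-base depth is summarized by ``summary``
    ("mean" default, "median" offered); the median/min/max of those values
    across isolates form the ribbon.  Default 250 bp windows sliding by
    25 bp; set ``step == window`` for non-overlapping windows.
    """
    if not tracks:
        raise ValueError("at least one track required")
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")
    if summary not in ("mean", "median"):
        raise ValueError("summary must be 'mean' or 'median'")
    chroms = tracks[0].chromosomes
    for t in tracks[1:]:
        if t.chromosomes != chroms or any(
            t.length(c) != tracks[0].length(c) for c in chroms
        ):
            raise ValueError("tracks must share chromosomes and lengths")
    if region is None:
        regions = [GenomicInterval(c, 0, tracks[0].length(c)) for c in chroms]
    else:
        if region.chrom not in chroms or region.end > tracks[0].length(region.chrom):
            raise ValueError("region outside track")
        regions = [region]

    rows = []
    reducer = np.mean if summary == "mean" else np.median
    for reg in regions:
        starts = np.arange(reg.start, reg.end - window + 1, step, dtype=int)
        if len(starts) == 0:
            continue
        mats = [t.slice(reg) for t in tracks]
        # cumulative sums give O(1) window means; medians fall back to a loop
        per_isolate = np.empty((len(tracks), len(starts)))
        for i, arr in enumerate(mats):
            if summary == "mean":
                cs = np.concatenate(([0.0], np.cumsum(arr)))
                s = starts - reg.start
                per_isolate[i] = (cs[s + window] - cs[s]) / window
            else:
                per_isolate[i] = [
                    reducer(arr[s : s + window]) for s in starts - reg.start
                ]
        med = np.median(per_isolate, axis=0)
        lo = per_isolate.min(axis=0)
        hi = per_isolate.max(axis=0)
        frame = {
            "chrom": reg.chrom,
            "start": starts,
            "end": starts + window,
            "median": med,
            "min": lo,
            "max": hi,
        }
        for i in range(len(tracks)):
            frame[f"isolate_{i}"] = per_isolate[i]
        rows.append(pd.DataFrame(frame))
    if not rows:
        raise ValueError("region shorter than one window")
    return RibbonProfile(
        pd.concat(rows, ignore_index=True), window=window, step=step, summary=summary
    )


# ---------------------------------------------------------------------------
# bedgraph I/O (4 columns: chrom, start, end, value; 0-based half-open)

def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a track as bedgraph, merging adjacent equal-value runs."""
    with open(path, "w") as fh:
        for chrom, arr in track.depths.items():
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                sval = f"{int(v)}" if float(v).is_integer() else repr(float(v))
                fh.write(f"{chrom}\t{s}\t{e}\t{sval}\n")


def read_bedgraph(path, sizes: dict[str, int] | None = None) -> CoverageTrack:
    """Read a bedgraph into a CoverageTrack.

    Overlapping records and malformed lines raise, reporting the line
    number.  Chromosome lengths default to the last covered base; pass
    ``sizes`` to pad to full chromosome lengths.
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom = parts[0]
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative value")
            intervals.setdefault(chrom, []).append((start, end, value))

    depths: dict[str, np.ndarray] = {}
    for chrom, recs in intervals.items():
        recs.sort()
        prev_end = -1
        for start, end, _ in recs:
            if start < prev_end:
                raise ValueError(f"overlapping bedgraph records on {chrom!r} at {start}")
            prev_end = end
        n = sizes[chrom] if sizes else recs[-1][1]
        if recs[-1][1] > n:
            raise ValueError(f"record beyond stated length of {chrom!r}")
        arr = np.zeros(n, dtype=float)
        for start, end, value in recs:
            arr[start:end] = value
        depths[chrom] = arr
    if sizes:
        for chrom, n in sizes.items():
            depths.setdefault(chrom, np.zeros(n, dtype=float))
    return CoverageTrack(depths)


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """Read BED3+ intervals (chrom, start, end), ignoring extra columns."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out
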
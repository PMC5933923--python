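"""Toy-genome descriptions shared by the simulator and the ChIP pipeline.

Coordinates are 0-based half-open throughout the package (the bedgraph
convention).  1-based inclusive interval strings, as printed in methods
sections and genome browsers, are converted on input via
:meth:`GenomicInterval.from_one_based`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DOMAIN_CLASSES = frozenset(
    {"subtelomere", "pericentromere", "mat", "euchromatin", "spike_locus"}
)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @classmethod
    def from_one_based(cls, chrom: str, start: int, end: int) -> "GenomicInterval":
        """Convert a 1-based inclusive span (e.g. 'chr III: 1316291-1318035')."""
        return cls(chrom, start - 1, end)

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class Domain:
    """A named chromatin domain with a class label used by the simulator."""

    name: str
    chrom: str
    start: int
    end: int
    domain_class: str

    def __post_init__(self) -> None:
        if self.domain_class not in DOMAIN_CLASSES:
            raise ValueError(f"unknown domain class {self.domain_class!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid domain interval {self.name}")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class GenomeSpec:
    """Chromosome sizes plus an annotation of chromatin domains.

    At most one domain may carry the ``spike_locus`` class: the ectopic
    reference locus contributed by the spike strain.  Bases not covered by
    any domain are treated as euchromatin.
    """

    chromosomes: list[tuple[str, int]]
    domains: list[Domain] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = dict(self.chromosomes)
        if len(sizes) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"zero-length chromosome {name!r}")
        for d in self.domains:
            if d.chrom not in sizes:
                raise ValueError(f"domain {d.name} on unknown chromosome {d.chrom}")
            if d.end > sizes[d.chrom]:
                raise ValueError(f"domain {d.name} exceeds chromosome bounds")
        n_spike = sum(d.domain_class == "spike_locus" for d in self.domains)
        if n_spike > 1:
            raise ValueError("spike_locus must appear at most once")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.sizes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def spike_locus(self) -> Domain | None:
        for d in self.domains:
            if d.domain_class == "spike_locus":
                return d
        return None

    def domains_of_class(self, domain_class: str) -> list[Domain]:
        return [d for d in self.domains if d.domain_class == domain_class]
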
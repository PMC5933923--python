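"""Synthetic inputs with the statistical structure the analyses assume.

Four generators emulate the study's raw data so that every pipeline stage is
testable without sequencing libraries or microscope images:

* ChIP coverage over a toy genome with heterochromatin-domain enrichment
  (subtelomeres, pericentromeres, mat) and a spiked reference locus
  contributed by a second strain mixed into every culture;
* per-cell locus positions inside spherical nuclei, either uniform or
  biased toward the peripheral (outermost equal-volume) shell;
* noisy one-phase-association FRAP recoveries with the raw ROI/background
  bookkeeping the quantitation expects;
* two-channel images with Gaussian foci over a nuclear disk and envelope
  ring on a noisy background.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chipseq import CoverageTrack
from .frap import FrapTrace, one_phase_association
from .genome import Domain, GenomeSpec
from .zoning import EARLY_MID_S, LATE_S_G2, LocusObservation, NucleusGeometry, zone_boundaries

LN2 = math.log(2.0)


def default_toy_genome() -> GenomeSpec:
    """A 280 kb three-chromosome genome with one domain of each class.

    Sized so whole-genome simulation stays fast while every domain has
    enough bases for stable medians.
    """
    return GenomeSpec(
        chromosomes=[("chrI", 120_000), ("chrII", 100_000), ("chrIII", 60_000)],
        domains=[
            Domain("subtel1L", "chrI", 0, 20_000, "subtelomere"),
            Domain("subtel1R", "chrI", 100_000, 120_000, "subtelomere"),
            Domain("pericen2", "chrII", 40_000, 60_000, "pericentromere"),
            Domain("mat", "chrIII", 5_000, 15_000, "mat"),
            Domain("ade6_spike", "chrIII", 30_000, 32_000, "spike_locus"),
        ],
    )


@dataclass
class EnrichmentModel:
    """Expected ChIP depth per domain class, plus spike and noise settings.

    Expected depth at a base of class c is ``baseline * multipliers[c]``;
    over the spike locus an extra ``baseline * multipliers['spike_locus'] *
    spike_mix_fraction`` is added, modeling the reference strain (whose
    ectopic ade6+ sits in pericentric heterochromatin) mixed into the
    culture.  The default mix fraction 0.25 reflects one part spike in four
    parts total.  Counts are negative-binomial with variance
    mu + overdispersion * mu^2, reducing to Poisson at overdispersion 0.
    """

    multipliers: dict[str, float] = field(
        default_factory=lambda: {
            "euchromatin": 1.0,
            "subtelomere": 6.0,
            "pericentromere": 8.0,
            "mat": 6.0,
            "spike_locus": 20.0,
        }
    )
    baseline: float = 10.0
    spike_mix_fraction: float = 0.25
    overdispersion: float = 0.05

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.multipliers.values()):
            raise ValueError("multipliers must be >= 0")
        if not 0.0 <= self.spike_mix_fraction <= 1.0:
            raise ValueError("spike_mix_fraction must be in [0, 1]")
        if self.baseline < 0 or self.overdispersion < 0:
            raise ValueError("baseline and overdispersion must be >= 0")


def expected_depth(genome: GenomeSpec, model: EnrichmentModel) -> dict[str, np.ndarray]:
    """Closed-form expected per-base depth (the oracle the sampler targets)."""
    mu = {
        chrom: np.full(n, model.baseline * model.multipliers.get("euchromatin", 1.0))
        for chrom, n in genome.chromosomes
    }
    for d in genome.domains:
        if d.domain_class == "spike_locus":
            continue
        m = model.multipliers.get(d.domain_class, 1.0)
        mu[d.chrom][d.start : d.end] = model.baseline * m
    spike = genome.spike_locus()
    if spike is not None:
        extra = (
            model.baseline
            * model.multipliers.get("spike_locus", 0.0)
            * model.spike_mix_fraction
        )
        mu[spike.chrom][spike.start : spike.end] += extra
    return mu


def _sample_counts(mu: np.ndarray, overdispersion: float, rng: np.random.Generator) -> np.ndarray:
    if overdispersion == 0.0:
        return rng.poisson(mu).astype(float)
    n = 1.0 / overdispersion  # NB shape: var = mu + mu^2 / n
    p = n / (n + mu)
    return rng.negative_binomial(n, p).astype(float)


def simulate_chip_coverage(
    genome: GenomeSpec,
    model: EnrichmentModel | None = None,
    n_isolates: int = 3,
    seed: int = 0,
) -> list[CoverageTrack]:
    """One coverage track per independent isolate of the same genotype."""
    model = model or EnrichmentModel()
    if n_isolates < 1:
        raise ValueError("n_isolates must be >= 1")
    if model.spike_mix_fraction > 0 and genome.spike_locus() is None:
        raise ValueError("spike_mix_fraction > 0 but genome has no spike_locus domain")
    mu = expected_depth(genome, model)
    rng = np.random.default_rng(seed)
    return [
        CoverageTrack(
            {c: _sample_counts(m, model.overdispersion, rng) for c, m in mu.items()}
        )
        for _ in range(n_isolates)
    ]


@dataclass
class NucleiSimConfig:
    """Population of spherical nuclei with optional peripheral locus bias.

    ``peripheral_bias`` is the probability a locus is drawn uniformly within
    the outermost equal-volume shell (Zone I) instead of uniformly in the
    whole sphere, so the expected Zone-I fraction is
    bias + (1 - bias) / 3.  Radius default 1.74 um, a typical fission-yeast
    nucleus.  ``stage_mix`` is the binucleate (early/mid-S) fraction.
    """

    n_cells: int = 200
    radius: float = 1.74
    peripheral_bias: float = 0.0
    stage_mix: float = 0.5
    seed: int = 0
    strain: str = "wt"
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        for p in (self.peripheral_bias, self.stage_mix):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


def simulate_nuclei(cfg: NucleiSimConfig) -> list[LocusObservation]:
    """Per-cell locus positions; reproducible given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    r1, _ = zone_boundaries(cfg.radius)
    nucleus = NucleusGeometry((0.0, 0.0, 0.0), cfg.radius)
    peripheral = rng.random(cfg.n_cells) < cfg.peripheral_bias
    u = rng.random(cfg.n_cells)
    # uniform-in-volume radial draws: whole sphere vs the outermost shell
    radii = np.where(
        peripheral,
        (r1**3 + u * (cfg.radius**3 - r1**3)) ** (1.0 / 3.0),
        cfg.radius * u ** (1.0 / 3.0),
    )
    direction = rng.normal(size=(cfg.n_cells, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    stages = np.where(rng.random(cfg.n_cells) < cfg.stage_mix, EARLY_MID_S, LATE_S_G2)
    return [
        LocusObservation(
            nucleus=nucleus,
            position=tuple(radii[i] * direction[i]),
            stage=str(stages[i]),
            replicate=f"rep{i % cfg.n_replicates + 1}",
            strain=cfg.strain,
        )
        for i in range(cfg.n_cells)
    ]


@dataclass
class FrapSimConfig:
    """Noisy one-phase-association recoveries.

    Defaults emulate a fast-recovering inner-NE protein: half-life ~5 s
    (k = ln2/5.03), images every 2 s for 2 min, 13 cells, Gaussian noise
    sd 0.05 on the normalized scale.
    """

    true_k: float = LN2 / 5.03
    true_plateau: float = 0.85
    true_y0: float = 0.2
    noise_sd: float = 0.05
    interval: float = 2.0
    n_timepoints: int = 60
    n_cells: int = 13
    seed: int = 0
    pre_background: float = 100.0
    pre_amplitude: float = 1000.0

    def __post_init__(self) -> None:
        if self.true_k <= 0:
            raise ValueError("true_k must be positive")
        if not 0.0 <= self.true_y0 <= self.true_plateau <= 1.2:
            raise ValueError("require 0 <= Y0 <= plateau <= 1.2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if self.n_timepoints < 4 or self.n_cells < 1:
            raise ValueError("need >= 4 timepoints and >= 1 cell")


def simulate_frap(cfg: FrapSimConfig) -> list[FrapTrace]:
    """Raw-ROI traces whose normalized form is the model curve plus noise.

    Background is constant and equals the pre-bleach background, so the
    background-subtracted normalization recovers the simulated curve and the
    pre-bleach reference is exactly 1.0.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(cfg.n_timepoints) * cfg.interval
    model = one_phase_association(t, cfg.true_k, cfg.true_y0, cfg.true_plateau)
    traces = []
    for i in range(cfg.n_cells):
        normalized = model + rng.normal(0.0, cfg.noise_sd, size=len(t))
        roi = cfg.pre_background + normalized * cfg.pre_amplitude
        traces.append(
            FrapTrace(
                times=t.copy(),
                roi_sum=roi,
                background_sum=np.full(len(t), cfg.pre_background),
                pre_roi_sum=cfg.pre_background + cfg.pre_amplitude,
                pre_background_sum=cfg.pre_background,
                cell_id=f"cell{i + 1}",
            )
        )
    return traces


@dataclass
class ImageSimConfig:
    """Two-channel image: Gaussian foci + nuclear disk and envelope ring.

    ``spots`` maps channel index (0/1) to a list of (row_px, col_px,
    amplitude).  The nucleus is a uniform disk (diffuse nucleoplasmic
    background) with a brighter Gaussian-profile rim at its radius.
    """

    shape: tuple[int, int] = (96, 96)
    pixel_size: float = 0.1  # um/px
    spots: dict[int, list[tuple[float, float, float]]] = field(default_factory=dict)
    psf_sigma: float = 1.5  # px
    nucleus_center: tuple[float, float] = (48.0, 48.0)
    nucleus_radius: float = 30.0  # px
    nucleoplasm_level: float = 40.0
    ring_amplitude: float = 30.0
    ring_sigma: float = 1.5  # px
    background_mean: float = 10.0
    background_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        for channel, spots in self.spots.items():
            for r, c, _ in spots:
                if not (0 <= r < self.shape[0] and 0 <= c < self.shape[1]):
                    raise ValueError(
                        f"spot ({r}, {c}) in channel {channel} outside image"
                    )


def simulate_image(cfg: ImageSimConfig) -> np.ndarray:
    """Render the two channels -> array of shape (2, H, W)."""
    rng = np.random.default_rng(cfg.seed)
    rows, cols = np.indices(cfg.shape, dtype=float)
    dist = np.hypot(rows - cfg.nucleus_center[0], cols - cfg.nucleus_center[1])
    nucleus = cfg.nucleoplasm_level * (dist <= cfg.nucleus_radius)
    ring = cfg.ring_amplitude * np.exp(
        -((dist - cfg.nucleus_radius) ** 2) / (2.0 * cfg.ring_sigma**2)
    )
    channels = []
    for channel in range(2):
        img = cfg.background_mean + nucleus + ring
        if cfg.background_sd > 0:
            img = img + rng.normal(0.0, cfg.background_sd, size=cfg.shape)
        for r, c, amplitude in cfg.spots.get(channel, []):
            img = img + amplitude * np.exp(
                -((rows - r) ** 2 + (cols - c) ** 2) / (2.0 * cfg.psf_sigma**2)
            )
        channels.append(img)
    return np.stack(channels)
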
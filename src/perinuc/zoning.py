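"""Nuclear zoning assay: locus-to-envelope distances and peripheral enrichment.

The nucleus is modeled as a sphere partitioned into three concentric shells
of equal volume.  Zone I, the outermost shell, extends inward from the
nuclear envelope (NE) by R(1 - (2/3)^(1/3)) — about 0.22 um for a typical
1.74 um fission-yeast nuclear radius.  A uniformly random locus lands in
Zone I in exactly 1/3 of cells (~33%), the null expectation against which
peripheral enrichment is tested.

Cell-cycle staging uses cell morphology: fission yeast completes mitosis
before cytokinesis, so interphase binucleate cells are in early/mid S phase
and mononucleate cells in late S/G2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EARLY_MID_S = "early_mid_S"
LATE_S_G2 = "late_S_G2"

#: Loci measured up to this fraction outside R are clamped to the surface
#: (segmentation jitter); beyond it the observation is rejected.
OUTSIDE_TOLERANCE = 0.02

#: Fraction of nuclear volume per zone => random Zone-I expectation.
RANDOM_ZONE1_EXPECTATION = 1.0 / 3.0


@dataclass(frozen=True)
class NucleusGeometry:
    """Sphere approximating one nucleus (center in um, radius R in um)."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("nuclear radius must be positive")


@dataclass(frozen=True)
class LocusObservation:
    """One scored cell: nucleus geometry, locus position, labels."""

    nucleus: NucleusGeometry
    position: tuple[float, float, float]
    stage: str = LATE_S_G2
    replicate: str = "rep1"
    strain: str = "wt"


def zone_boundaries(radius: float) -> tuple[float, float]:
    """Radii r1 > r2 splitting a sphere of radius R into three equal volumes.

    r1 = R (2/3)^(1/3), r2 = R (1/3)^(1/3); Zone I is radial coordinate
    >= r1, Zone II in [r2, r1), Zone III < r2.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    return radius * (2.0 / 3.0) ** (1.0 / 3.0), radius * (1.0 / 3.0) ** (1.0 / 3.0)


def radial_coordinate(obs: LocusObservation, tol: float = OUTSIDE_TOLERANCE) -> float:
    """Distance from nuclear center to locus, clamped to [0, R]."""
    r = math.dist(obs.position, obs.nucleus.center)
    radius = obs.nucleus.radius
    if r > radius * (1.0 + tol):
        raise ValueError(
            f"locus {r:.3f} um from center exceeds radius {radius:.3f} um "
            f"beyond {tol:.0%} tolerance"
        )
    return min(r, radius)


def locus_ne_distance(obs: LocusObservation, tol: float = OUTSIDE_TOLERANCE) -> float:
    """Distance from locus to the nuclear envelope: R - |position - center|."""
    return obs.nucleus.radius - radial_coordinate(obs, tol=tol)


def assign_zone(obs: LocusObservation, tol: float = OUTSIDE_TOLERANCE) -> str:
    """Zone label 'I' (peripheral), 'II' or 'III' (central).

    Boundary ties go to the more peripheral zone.
    """
    r = radial_coordinate(obs, tol=tol)
    r1, r2 = zone_boundaries(obs.nucleus.radius)
    if r >= r1:
        return "I"
    if r >= r2:
        return "II"
    return "III"


def classify_stage(n_nuclei_in_cell: int) -> str:
    """Stage from nucleate count: 2 -> early/mid S, 1 -> late S/G2."""
    if n_nuclei_in_cell == 2:
        return EARLY_MID_S
    if n_nuclei_in_cell == 1:
        return LATE_S_G2
    raise ValueError(
        f"{n_nuclei_in_cell} nuclei: cell is mitotic or aberrant, unclassifiable"
    )


def monte_carlo_random_zone1(n: int, seed: int | None = None) -> float:
    """Fraction of uniformly random nuclear positions landing in Zone I.

    Converges to 1/3 (the equal-volume construction) at rate 1/sqrt(n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    # radial CDF of a uniform point in a sphere is (r/R)^3
    radii = rng.random(n) ** (1.0 / 3.0)
    r1, _ = zone_boundaries(1.0)
    return float(np.mean(radii >= r1))


def binomial_two_sided_p(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value by tail doubling (capped at 1)."""
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass
class ZoningSummary:
    """Zone-I scoring for one (strain, stage) group, Table-style."""

    strain: str
    stage: str
    replicate_n: dict[str, int]
    replicate_zone1: dict[str, int]
    zone1_fraction: float
    expected: float
    p_value: float
    test_name: str
    note: str = ""

    @property
    def n_total(self) -> int:
        return sum(self.replicate_n.values())

    @property
    def zone1_total(self) -> int:
        return sum(self.replicate_zone1.values())


def test_zone1_enrichment(
    observations: Sequence[LocusObservation],
    expected: float = RANDOM_ZONE1_EXPECTATION,
    method: str = "ttest",
) -> ZoningSummary:
    """Test Zone-I occupancy of one group against the random expectation.

    ``method='ttest'`` runs a one-sample two-tailed t-test on the per-cell
    Zone-I indicator (pooled across replicates) against ``expected``;
    ``method='binomial'`` the exact two-sided binomial test.  A zero-variance
    indicator vector makes the t-test undefined, in which case the binomial
    test is substituted and noted.
    """
    if len(observations) < 2:
        raise ValueError("need at least 2 observations")
    if method not in ("ttest", "binomial"):
        raise ValueError("method must be 'ttest' or 'binomial'")
    strains = {o.strain for o in observations}
    stages = {o.stage for o in observations}

    indicator = np.array([assign_zone(o) == "I" for o in observations], dtype=float)
    rep_n: dict[str, int] = {}
    rep_k: dict[str, int] = {}
    for o, z in zip(observations, indicator):
        rep_n[o.replicate] = rep_n.get(o.replicate, 0) + 1
        rep_k[o.replicate] = rep_k.get(o.replicate, 0) + int(z)

    k, n = int(indicator.sum()), len(indicator)
    note = ""
    if method == "ttest":
        if np.ptp(indicator) == 0:
            p = binomial_two_sided_p(k, n, expected)
            test_name = "binomial (two-sided)"
            note = "t-test undefined for zero-variance indicators; used exact binomial"
        else:
            p = float(stats.ttest_1samp(indicator, expected).pvalue)
            test_name = "one-sample t-test (two-tailed)"
    else:
        p = binomial_two_sided_p(k, n, expected)
        test_name = "binomial (two-sided)"

    return ZoningSummary(
        strain=strains.pop() if len(strains) == 1 else "mixed",
        stage=stages.pop() if len(stages) == 1 else "mixed",
        replicate_n=rep_n,
        replicate_zone1=rep_k,
        zone1_fraction=k / n,
        expected=expected,
        p_value=p,
        test_name=test_name,
        note=note,
    )


def summarize_zoning(
    observations: Sequence[LocusObservation],
    expected: float = RANDOM_ZONE1_EXPECTATION,
    method: str = "ttest",
) -> pd.DataFrame:
    """Per-(strain, stage) Zone-I table with replicate n's and p-values."""
    groups: dict[tuple[str, str], list[LocusObservation]] = {}
    for o in observations:
        groups.setdefault((o.strain, o.stage), []).append(o)
    rows = []
    for (strain, stage), obs in sorted(groups.items()):
        s = test_zone1_enrichment(obs, expected=expected, method=method)
        reps = sorted(s.replicate_n)
        row = {
            "strain": strain,
            "stage": stage,
            "zone1_fraction": s.zone1_fraction,
            "expected": s.expected,
            "p_value": s.p_value,
            "test": s.test_name,
        }
        for i, r in enumerate(reps, start=1):
            row[f"n{i}"] = s.replicate_n[r]
            row[f"zone1_{i}"] = s.replicate_zone1[r]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV interchange (one row per scored cell)

NUCLEI_COLUMNS = [
    "strain", "replicate", "stage", "center_x", "center_y", "center_z",
    "radius", "locus_x", "locus_y", "locus_z",
]


def write_observations_tsv(observations: Iterable[LocusObservation], path) -> None:
    rows = [
        dict(
            strain=o.strain, replicate=o.replicate, stage=o.stage,
            center_x=o.nucleus.center[0], center_y=o.nucleus.center[1],
            center_z=o.nucleus.center[2], radius=o.nucleus.radius,
            locus_x=o.position[0], locus_y=o.position[1], locus_z=o.position[2],
        )
        for o in observations
    ]
    pd.DataFrame(rows, columns=NUCLEI_COLUMNS).to_csv(path, sep="\t", index=False)


def read_observations_tsv(path) -> list[LocusObservation]:
    df = pd.read_csv(path, sep="\t")
    missing = set(NUCLEI_COLUMNS) - set(df.columns)
    # allow staging by nucleate count instead of a stage label
    if "stage" in missing and "n_nuclei" in df.columns:
        df["stage"] = df["n_nuclei"].map(classify_stage)
        missing.discard("stage")
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        LocusObservation(
            nucleus=NucleusGeometry(
                (row.center_x, row.center_y, row.center_z), row.radius
            ),
            position=(row.locus_x, row.locus_y, row.locus_z),
            stage=row.stage,
            replicate=str(row.replicate),
            strain=str(row.strain),
        )
        for row in df.itertuples()
    ]
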
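# perinuc

Quantitative assays for chromatin organization at the nuclear periphery,
built for studies of fission-yeast heterochromatin (subtelomeres,
pericentromeres, the *mat* locus) and inner nuclear-envelope (NE) proteins.
The package bundles four analyses that are usually scattered across ad-hoc
scripts, each backed by a synthetic-data generator so the whole pipeline is
testable without sequencing libraries or raw micrographs:

1. **Spike-in normalized ChIP-seq coverage** (`perinuc.chipseq`).  Every
   ChIP sample is spiked with a reference strain carrying an ectopic
   *ade6*⁺ gene inside pericentric heterochromatin, mixed at a constant
   culture ratio.  The per-sample scale factor is

   *S* = *c* / (*m*<sub>spike</sub> − *m*<sub>ref</sub>),

   with *m*<sub>spike</sub> the median per-base depth over the spike locus,
   *m*<sub>ref</sub> the median over adjacent euchromatin, and *c* = 10.
   Because the spike is a constant reference, normalized tracks are
   comparable across samples with no input-chromatin normalization.
   Replicate isolates are summarized into 250 bp sliding-window ribbon
   profiles (across-isolate median line with min–max ribbon).

2. **Nuclear zoning assay** (`perinuc.zoning`).  The nucleus is modeled as
   a sphere split into three concentric shells of equal volume; Zone I, the
   outermost shell (depth *R*(1 − (2/3)^⅓) ≈ 0.22 µm for *R* = 1.74 µm),
   holds a randomly placed locus in exactly 33% of cells.  Zone-I
   occupancy per strain and cell-cycle stage (binucleate = early/mid S,
   mononucleate = late S/G2) is tested against that expectation with a
   one-sample t-test on per-cell indicators or an exact binomial test.

3. **FRAP quantitation** (`perinuc.frap`).  Recoveries are normalized as
   (ROI − background) / (pre-bleach ROI − background), averaged across
   cells, and fitted with the one-phase association model
   *Y*(*t*) = *Y₀* + (*P* − *Y₀*)(1 − e^(−*kt*)), reporting the rate *k*,
   half-life ln 2 / *k*, mobile fraction (plateau *P*) and *R*².

4. **Dot colocalization** (`perinuc.imaging`).  Constant-threshold
   detection of fluorescent foci, one-to-one cross-channel matching by
   ascending centroid distance, nuclear-boundary estimation from the
   nucleoplasmic background (least-squares circle fit), per-dot distance to
   the nuclear edge, and pixel-wise Pearson correlation.

## Worked example

```python
from perinuc import synthetic, chipseq, zoning, frap
from perinuc.genome import GenomicInterval

genome = synthetic.default_toy_genome()
tracks = synthetic.simulate_chip_coverage(
    genome, synthetic.EnrichmentModel(), n_isolates=3, seed=1)
cfg = chipseq.SpikeNormConfig(
    spike_interval=GenomicInterval("chrIII", 30_000, 32_000),
    reference_interval=GenomicInterval("chrIII", 20_000, 58_000))
norm = []
for i, t in enumerate(tracks, 1):
    s = chipseq.spike_norm_stats(t, cfg)
    print(f"isolate {i}: m_spike={s['m_spike']:.1f}  m_ref={s['m_ref']:.1f}  "
          f"S={s['scale_factor']:.4f}")
    norm.append(chipseq.normalize_track(t, s["scale_factor"]))
prof = chipseq.ribbon_profile(norm, window=250, step=25,
                              region=GenomicInterval("chrII", 40_000, 60_000))
print(f"pericentric ribbon: median={prof.windows['median'].mean():.2f}  "
      f"range=[{prof.windows['min'].mean():.2f}, {prof.windows['max'].mean():.2f}]")

obs = synthetic.simulate_nuclei(
    synthetic.NucleiSimConfig(n_cells=200, peripheral_bias=0.7, seed=2))
print(zoning.summarize_zoning(obs).to_string(index=False))

fit, t, mean, n = frap.fit_traces(
    synthetic.simulate_frap(synthetic.FrapSimConfig(seed=3)))
print(f"FRAP fit (n={n}): T1/2={fit.half_life:.2f} s  "
      f"mobile fraction={fit.plateau:.2f}  R^2={fit.r_squared:.3f}")
```

prints

```
isolate 1: m_spike=59.0  m_ref=10.0  S=0.2041
isolate 2: m_spike=58.5  m_ref=10.0  S=0.2062
isolate 3: m_spike=58.0  m_ref=10.0  S=0.2083
pericentric ribbon: median=16.50  range=[16.24, 16.78]
strain       stage  zone1_fraction  expected      p_value                           test  n1  zone1_1  n2  zone1_2
    wt early_mid_S        0.836957  0.333333 1.805852e-22 one-sample t-test (two-tailed)  44       35  48       42
    wt   late_S_G2        0.842593  0.333333 6.251124e-27 one-sample t-test (two-tailed)  56       48  52       43
FRAP fit (n=13): T1/2=5.16 s  mobile fraction=0.85  R^2=0.987
```

The per-isolate scale factors (~0.20–0.21) absorb sequencing-depth and
spike-recovery differences, so the three normalized pericentric ribbons
agree to within a few percent (a tight min–max ribbon around the median).
The zoning table reports per-replicate counts (n₁/n₂), the Zone-I fraction
against the 33% random expectation, and its p-value.  The FRAP fit recovers
the simulated half-life (~5 s) and mobile fraction (0.85) from 13 noisy
cells.

A `perinuc` command-line tool exposes the same stages
(`perinuc simulate chip|nuclei|frap|image`, `chip-normalize`, `ribbon`,
`zoning`, `frap-fit`, `coloc`); every run writes a provenance JSON with
parameters and seeds.

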
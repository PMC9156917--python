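# clinemap

Gridded allele-frequency mapping and geographic cline analysis for
dominance-scored colour-morph occurrence records.

## The problem

Warning-coloured species are expected to be locally monomorphic — predators
learn the common pattern — yet many, like the African monarch *Danaus
chrysippus*, are polymorphic across huge ranges. Testing how selection
shapes that variation needs range-wide allele-frequency surfaces built from
heterogeneous occurrence data: museum and field records alongside
citizen-science photographs, each butterfly scored at Mendelian
colour-pattern loci (here A: hindwing white, B: light/dark background,
C: forewing black tip). Because heterozygotes are not reliably scorable,
every locus is reduced to two phenotype classes, homozygous recessive
(e.g. *aa*) versus the combined dominant class (e.g. *A–*).

`clinemap` implements that analysis as a tested, reusable pipeline:

1. **Records → grid.** Validated occurrence records are pooled into
   latitude/longitude cells. Within a cell, the recessive-class frequency
   f = n_rec / n is converted to a recessive allele frequency under
   Hardy–Weinberg equilibrium, q̂ = √f. Cells are classified as
   near-fixed (q > 0.95), polymorphic (0.05 ≤ q ≤ 0.95) or near-absent,
   and research vs citizen grids can be regressed against each other to
   check scoring concordance.
2. **Grid → transect.** Cell centres are projected onto user-defined
   great-circle transects using exact spherical cross-track and along-track
   distances; cells within a 450 km corridor enter the cline fit at their
   cumulative along-path position.
3. **Cline fitting.** The classic hybrid-zone cline
   `p(x) = pmin + (pmax − pmin) / (1 + exp(−4(x − c)/w))`, optionally with
   exponential tails beyond offsets δL/δR (slope ratios τL/τR) and with
   scaling fixed to the observed extremes or freely estimated — six model
   variants compared by AICc. Maximum likelihood by multi-start bounded
   optimization; uncertainty from three independent Metropolis chains
   (10⁴ burn-in, 10⁵ generations by default) giving credible intervals for
   centre and width, the 95 % "fuzzy cline" envelope, and centre offsets
   between loci.
4. **Environmental association.** Per-cell morph frequency (dark-background
   class at B) is regressed on annual mean temperature (bio01), solar
   radiation (bio20), annual precipitation (bio12) and soil moisture
   (bio28) with generalized least squares whose residuals decay as
   exp(−d/ρ) in inter-cell distance and whose variance weights are 1/n per
   cell; all 15 covariate subsets plus the null model are ranked by AIC,
   with VIF and correlation/regression screens and a three-criterion
   verdict per covariate.
5. **Synthetic worlds.** A generator samples records from hotspot mixtures
   over ground-truth clines with full dominance, two record sources, ~50 %
   B-locus missingness in citizen records, and parametric covariate
   surfaces — so the whole pipeline is testable without any download.

## Worked example

```python
import numpy as np
import clinemap as cm

world = cm.WorldSpec(n_records=20_000, seed=42)   # loci A/C centred 1000 / 2500 km
ds = cm.sample_records(world)
grid = cm.build_grid(ds, cm.GridSpec(4.0))
transect = cm.Transect("axis", world.loci["A"].waypoints)

fits = {}
for locus in ("A", "C"):
    cells = cm.project_cells(grid, transect, locus)
    fits[locus] = cm.fitter_from_cells(cells, seed=42)
    p = fits[locus].params_
    print(locus, round(p.c, 1), round(p.w, 1),
          np.round(fits[locus].centre_ci_, 1))

print(cm.centre_offset(fits["A"], fits["C"], rng=42))
```

prints (intervals vary slightly with the MCMC seed):

```
A 999.4 531.6 [ 986.8 1011.6]
C 2518.0 527.3 [2503.4 2532.4]
{'offset_km': 1518.6524296518576, 'interval_km': (1499.433963105647, 1537.7196598355265)}
```

Locus A's cline is estimated at ~1000 km along the transect with width
~500 km, locus C at ~2500 km, and the centre offset between the two loci is
recovered at ~1500 km with a 95 % interval from paired posterior draws —
the mismatched-cline signature the pipeline is built to detect.

The same pipeline runs from the shell:

```bash
clinemap simulate --seed 42 --out-dir out/
clinemap grid out/records.csv --cell-size 4 --cell-size 2 --out-dir out/
clinemap cline out/grid_4deg.csv transect.json --locus A --out-dir out/
clinemap envassoc out/env.csv --out-dir out/
```

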
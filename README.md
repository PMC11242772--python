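# ribbonmap

Quantitative topography of immunogold labelling on synaptic ribbons.

Ribbon synapses of the retina and inner ear are organized around the
synaptic ribbon, a large electron-dense presynaptic structure that appears
bar-shaped in ultrathin EM cross-sections (~30–40 nm wide, several hundred
nm long). Post-embedding immunogold EM marks a protein epitope with a gold
particle, and the scientific question is *where on the ribbon* the label
sits — at the midline, toward the surface, or off the structure. Because
the apparent ribbon width depends on the section angle, absolute distances
in nm are not comparable across ribbons; `ribbonmap` implements the
normalized relative-distance analysis that corrects for this, for
microscopists and image analysts who annotate ribbons manually and want a
reproducible, scriptable pipeline from annotations to statistics and
figures.

## The method

Each ribbon is annotated with a closed outer-border polygon, an ordered
midline polyline (5–20 midpoints), and gold-particle coordinates. For a
particle, let `d1` be its minimal distance to the midline and `d2` its
minimal distance to the outer border. The relative distance is

- inside the ribbon:  `d_rel = d1 / (d1 + d2)` — 0 at the midline,
  1 at the border;
- outside the ribbon: `d_rel = d1 / (d1 − d2)` — > 1, growing with
  distance from the surface.

`d_rel` is invariant to rigid motion and uniform scaling, i.e. normalized
to the local ribbon half-width. Pooled `d_rel` histograms (bin width 0.1
over [0, 13]) are fitted with the four-parameter logistic

```
f(d_rel) = a2 + (a1 − a2) / (1 + (d_rel / c)^p)
```

with `a1 = f(0)` the midline count, `a2` the far asymptote, `c` the
half-decay point, and `p` the power. To compare antibodies with different
labelling intensities, curves are normalized so that `f(0) = 100%`.
Replicate-level (per-grid) inside/outside counts and percentages are
compared with a Kruskal–Wallis test followed by Dunn's post hoc pairwise
tests (Bonferroni-adjusted).

A synthetic-data generator produces annotated datasets with known ground
truth — bar-shaped ribbons, particles drawn from a chosen radial density
(uniform, logistic, or monotone gradients), Gaussian label displacement
(default σ = 10 nm, motivated by IgG dimensions of 8.5 × 14.5 × 4.0 nm
plus 5 nm colloidal gold), and a uniform nonspecific background — so the
whole pipeline is testable without micrographs.

## Worked example

Simulate a two-antibody study (labels `6F4` and `2D9`, radial densities
following logistic profiles with the published parameter sets), then fit:

```python
from ribbonmap import RibbonTopographyModel
from ribbonmap.simulate import LogisticDensity, SyntheticConfig, generate_dataset

study = []
for name, params, seed in [
    ("6F4", dict(a1=72.656, a2=-0.023, center=1.000, p=2.874), 1),
    ("2D9", dict(a1=153.587, a2=-0.072, center=1.087, p=3.5594), 2),
]:
    cfg = SyntheticConfig(antibody=name, density_model=LogisticDensity(**params),
                          n_particles=25.0, seed=seed)
    study.extend(generate_dataset(cfg)[0])

res = RibbonTopographyModel.from_annotations(study).fit()
print(res.summary())
```

prints

```
Ribbon particle topography
============================================================
 Logistic radial profile, pooled fit
======================================
group    a1     a2   center   p    n
--------------------------------------
  6F4 148.258 -0.529  1.216 2.737 2192
  2D9 159.388 -0.388  1.252 3.276 2289
--------------------------------------
==================================================
group % particles on ribbon (mean over replicates)
--------------------------------------------------
  2D9                                         63.6
  6F4                                         59.0
--------------------------------------------------
max |normalized curve difference| on [0, 1]: 5.428 (percent of midline value)
Kruskal-Wallis on particles per ribbon: H = 29.234, p = 1.999e-06; Dunn's post hoc (bonferroni (x6, capped at 1))
Kruskal-Wallis on percent of particles: H = 30.764, p = 9.532e-07; Dunn's post hoc (bonferroni (x6, capped at 1))
```

The fitted `center` and `p` recover the generating radial shapes (label
displacement broadens the profile slightly, which is why the fitted
centers sit a little above the generating ones and ~60% of particles land
on the ribbon under these noise settings); the normalized curves of the
two groups differ by at most ~5% of the midline value on [0, 1] — the two
labels share the same radial distribution even though `2D9` labels more
intensely. Each object is inspectable: `res.fits["6F4"]` carries the
parameters and diagnostics, `res.summary_table` the per-grid bookkeeping,
`res.comparison_percent` the full test results.

The same pipeline runs from the shell on config files, producing a report
bundle (CSVs, figures, manifest):

```sh
ribbonmap simulate -c synth.yaml -o dataset/
ribbonmap run -c run.yaml
ribbonmap parse-overlay marked.png --palette palette.yaml
```

`parse-overlay` converts colored raster overlays (traced border, midpoint
dots, inside/outside particle dots in distinct colors) into the JSON
annotation schema (`ribbonmap-annotation/1`).

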
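# scarmorph

Quantitative morphometry of skin-scar histology and timepoint
transcriptomics, built for studies that track how fibrotic tissue remodels
over a follow-up course (e.g. a baseline biopsy and 2/4/6-month
post-intervention biopsies).

Mature scars differ from healthy skin in a handful of measurable ways: a
thin epidermis over a flat epidermal–dermal junction (EDJ), a thin
basement membrane, low dermal cell and vessel density, and a dense network
of thick, strongly aligned collagen type I fibres. `scarmorph` turns
multi-channel section images (DAPI, Ki67, COLIV immunofluorescence, and
second-harmonic-generation collagen imaging) into exactly those read-outs,
and carries a four-timepoint expression matrix through differential-
expression filtering and set partitioning. Every measurement is validated
by parameter recovery on synthetic sections with recorded ground truth, so
the whole chain is testable without any imaging data.

## What it measures

**Epidermis / EDJ** — viable-epidermis thickness probed at regular
locations; Ki67-positive fraction of epidermal nuclei per 250 µm window;
EDJ interdigitation as the arc-chord ratio over equal-arc-length sections
(per-section arc length ÷ end-to-end distance, ≥ 1, = 1 for a flat
boundary); basement-membrane thickness and abundance as the FWHM and peak
of COLIV intensity profiles sampled along 25 µm trajectories normal to the
EDJ.

**Dermis** — cell density (nuclei/mm² from multiscale blob detection);
percentage vessel area from thresholded COLIV; three-class collagen
segmentation (background / thin / thick) where a fibre is *thin* when its
mean width along the skeleton — from a local-thickness (largest inscribed
disk) map — is ≤ 10 µm; total collagen fraction and thick-fibre
proportion; fibre orientation from the structure tensor with the alignment
coefficient

&nbsp;&nbsp;&nbsp;&nbsp;R = |Σ w·e^{2iθ}| / Σ w ∈ [0, 1]

(mean resultant length of doubled angles; 1 = perfectly aligned);
normalized SHG intensity (fibre mean ÷ background mean).

**Transcriptomics** — baseline-to-median transform; per-gene one-way ANOVA
across timepoints with the gate |FC| > 1.5, p < 0.01, FDR < 0.01
(Benjamini–Hochberg); pairwise 0-vs-t comparisons; unique/core Venn
partitioning; hierarchical clustering of samples (1 − Pearson, average
linkage); qPCR relative quantification RQ = 2^(−ΔΔCt).

**Statistics** — the decision tree used for the per-metric group
comparisons: D'Agostino–Pearson normality → F/Bartlett variance equality →
Student's t / ANOVA + Tukey, or Mann–Whitney / Kruskal–Wallis + Dunn;
Grubbs' single-outlier screen at α = 0.05.

## Worked example

```python
import numpy as np
from scarmorph import (SectionSpec, generate_section_image, segment_fibres,
                       collagen_fractions, orientation_field,
                       alignment_coefficient, detect_nuclei, vessel_mask,
                       vessel_density, section_masks, BoundaryCurve,
                       arc_chord_ratio)
from scarmorph.synthetic import edj_depth_um

spec = SectionSpec(seed=7)            # 600 x 450 um scar ROI, 0.5 um/px
image, truth = generate_section_image(spec)

edj = BoundaryCurve.from_function(lambda x: edj_depth_um(spec, x),
                                  0, spec.width_um)
acr, _, _ = arc_chord_ratio(edj, section_length_um=100.0)

ps = spec.pixel_size_um
r0 = int(round(truth.fibre_canvas_top_um / ps))
canvas = image.channels["SHG"][r0:, :]
fibres = segment_fibres(canvas, ps)
frac, thick, mean_w = collagen_fractions(fibres)
align = alignment_coefficient(orientation_field(canvas, fibres.labels > 0, ps))

_, _, dermal = section_masks(spec)
vmask, _ = vessel_mask(image.channels["COLIV"], dermal)
```

Printing each quantity next to the generator's recorded truth gives:

```
arc-chord ratio        1.091   (truth 1.092)
collagen fraction      0.251   (truth 0.251)
thick-fibre proportion 0.501   (truth 0.501)
mean fibre width (um)  10.07
alignment coefficient  0.934
vessel density (%)     6.03   (truth 6.03)
nuclei detected        206   (truth 206)
```

The arc-chord ratio of 1.09 says the EDJ path is 9% longer than its
chords — a mildly undulating junction. Half the collagen area sits in
fibres wider than 10 µm, the alignment coefficient of 0.93 reflects the
strongly oriented fibre field the section was generated with
(concentration κ = 5), and both densities and counts match their planted
values.

The same stages run end to end from the command line:

```
scarmorph run --seed 1 --out-dir out/
```

which simulates 3 subjects × 4 timepoints with the default remodelling
time course (epidermis thickening ×1.6/1.4/2.0, vessel density 6→10%,
thick-fibre share 52→35%, …), measures every metric, applies the
statistical decision tree per metric, runs the expression stage, and
writes tidy CSVs, figures, and a provenance JSON.

## Layout

```
src/scarmorph/
  synthetic.py        section & expression generators with ground truth
  segmentation.py     fibre classes, local thickness, nuclei, vessels
  epidermis.py        thickness, Ki67, arc-chord ratio, COLIV profiles
  dermis.py           densities, collagen fractions, orientation, alignment
  transcriptomics.py  DE filter, Venn partition, clustering, qPCR RQ
  stats.py            decision tree, post-hocs, Grubbs
  pipeline.py         end-to-end orchestration and reporting
  cli.py              `scarmorph` command-line entry point
docs/methods.md       model, conventions, parameter defaults, limitations
```
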
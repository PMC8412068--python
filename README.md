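# astrodomain

Quantification of bipartite synapse density and astrocytic-domain synapse
distributions in multi-channel fluorescence micrographs, with the
statistical workflow used for small neuropathology cohorts (PSP / CBD /
control), and a synthetic scene generator that makes the whole pipeline
testable against exact ground truth.

## The problem

In primary 4-repeat tauopathies (progressive supranuclear palsy, PSP;
corticobasal degeneration, CBD), astrocytes carry pathognomonic
hyperphosphorylated-tau inclusions — tufted astrocytes (TA) in PSP,
astrocytic plaques (AP) in CBD. Whether these inclusions degrade the
synapses inside an astrocyte's spatial territory (its "synaptic island",
~142 µm across in humans) is a morphometric question: count synaptic
puncta in confocal images, decide which pre/post pairs form structural
("bipartite") synapses, and map postsynaptic density as a function of
distance from an astrocyte's core.

This package implements that analysis end to end:

1. **Preprocessing** (`astrodomain.imgproc`) — rolling-ball background
   subtraction, difference-of-Gaussians bandpass, median despeckling,
   convolution sharpening, and automatic Yen thresholding, composed in
   that fixed order into a binary puncta mask.
2. **Puncta & synapse calling** (`astrodomain.puncta_quant`) — puncta are
   size-filtered 8-connected components; a bipartite synapse is a
   presynaptic punctum whose pixel footprint overlaps postsynaptic
   foreground by at least a fraction θ of its own area, with **θ = 0.33**.
   Densities are counts per µm² of analyzed (non-excluded) area.
3. **Domain analysis** (`astrodomain.domain_sholl`) — 17 square bins of
   27 µm side arranged on five Sholl-like concentric distance classes
   around the astrocyte core (`center` n=1 at 0 µm, then `close`, `mid`,
   `distant`, `out`, n=4 each at 30/60/90/120 µm). Total layout area
   17 × 27² = 12,393 µm²; the domain proper is the 9 center/close/mid bins
   (6,561 µm², radius 71 µm by a-priori knowledge). Somatic pixels are
   excluded by a disc of configurable radius; bins clipped by the field
   are normalized by valid area; class means in fixed center→out order
   form the "synapse density distribution" of one astrocyte.
4. **Statistics** (`astrodomain.stats_suite`) — Shapiro-Wilk-gated Welch
   t / Mann-Whitney U comparisons, Holm-Sidak step-down correction,
   one-way ANOVA + Tukey HSD, two-way ANOVA (cohort × distance class) with
   a median-centred Levene check, the Games-Howell post hoc test
   (Welch-Satterthwaite df + studentized-range distribution), one-way
   repeated-measures ANOVA with ω² effect size, and Pearson correlation of
   neuropathological trait counts (TA/AP, NFT, coiled bodies, neuropil
   thread grade) with synapse densities.
5. **Synthetic scenes** (`astrodomain.scene_sim`) — Gaussian-spot puncta
   placed by homogeneous or radially modulated Poisson processes, a
   controllable true colocalization fraction with centroid jitter,
   autofluorescence-like background/noise/blobs, and exact `GroundTruth`
   (centroids, radii, matched pairs) that never depends on rendering.

## Worked example

```bash
astrodomain make-fixtures --out fixtures
astrodomain all --config fixtures/demo_config.yaml --seed 1 --out runs/demo
```

The demo simulates three field cohorts (colocalization fractions 0.6 /
0.35 / 0.55 for Ctrl / PSP / CBD) and three astrocyte cohorts (control,
TA-like with a soma-proximal density dip, AP-like with a domain-wide
reduction recovering at `out`), then quantifies and tests them. Output from
the run above:

`synapse_densities.csv` (cohort means, puncta/µm²):

| cohort | pre   | post  | bipartite |
|--------|-------|-------|-----------|
| Ctrl   | 0.210 | 0.196 | 0.106     |
| PSP    | 0.201 | 0.146 | 0.069     |
| CBD    | 0.197 | 0.184 | 0.101     |

`group_comparisons.csv`: the PSP bipartite reduction is detected
(Ctrl : PSP Welch t = 4.49, Holm-Sidak adjusted p = 0.0046; CBD : Ctrl
p = 0.54, not significant) — the pattern the generator was configured to
produce.

`twoway_anova.csv` / `games_howell.csv` (bin-level domain densities):
cohort effect F(2, 138) = 91.3, p < 1e-25; Games-Howell CBD_AP : Ctrl mean
difference −0.025 puncta/µm² (p < 1e-4), PSP_TA : Ctrl −0.010 — the
AP-like cohort separates from controls far more strongly than the TA-like
cohort, the qualitative domain phenotype the scenes encode.

`rm_anova.csv`: within-cohort distributions, e.g. CBD_AP
F(4, 8) = 15.7, p = 0.0007, ω² = 0.83 with Holm-Sidak paired post hocs per
distance-class pair.

## Layout

```
src/astrodomain/
  image.py         Image container, multi-channel TIFF I/O (+ JSON sidecar)
  scene_sim.py     synthetic scenes with exact ground truth
  imgproc.py       preprocessing chain -> binary puncta mask
  puncta_quant.py  puncta detection, densities, bipartite pairing
  domain_sholl.py  17-bin Sholl-like layout, soma exclusion, distributions
  stats_suite.py   the full statistical workflow
  pipeline.py      YAML-driven stages: simulate | quantify | domain | stats
  cli.py           `astrodomain` command-line interface
  fixtures.py      packaged trait-count table, worked-example masks, demo config
docs/methods.md    model, parameters, and design notes
```
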
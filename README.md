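# epimux

Epitope-resolved quantification of multiplex α-synuclein immunofluorescence.

## The problem

In the α-synucleinopathies (Parkinson's disease, multiple system atrophy),
pathological α-synuclein is conventionally detected with a single antibody —
most often against phospho-Ser129 (pS129). Multiplex staining with antibodies
against different parts of the protein (N-terminus, pS129, C-terminus) shows
that each antibody sees a different, partially overlapping subset of the
aggregate landscape, and that a single marker can miss most of it. Turning
such multiplex sections into numbers requires: per-channel segmentation of
pathological staining, set algebra over the three binary masks, and cohort
statistics over cases and brain regions. `epimux` implements that pipeline
for neuropathologists and image analysts, together with a synthetic-section
simulator that provides per-pixel ground truth for validating every stage.

## The statistics at the core

Let N, P, C be the binary pathology masks of the N-terminus, pS129 and
C-terminus channels inside a tissue mask T, and let U = N ∪ P ∪ C. The three
masks induce seven disjoint Venn compartments (N-only, P-only, C-only, the
three pairwise-only overlaps, and the triple overlap), and the pipeline
reports, per section:

- **pathology load** = 100 · |U| / |T| — percentage of tissue area covered
  by any α-synuclein labelling;
- **total (individual) epitope labelling** = 100 · |X| / |U| for each
  X ∈ {N, P, C} — one antibody's area, overlap included, as a share of the
  union;
- **unique epitope-specific labelling** = 100 · |X \ (Y ∪ Z)| / |U| — area
  detected by exactly one antibody.

Conservation (the seven compartments partition U), `unique ≤ total`,
`Σ total ≥ 100` whenever U is nonempty, and `Σ unique ≤ 100` are enforced as
runtime assertions.

Segmentation per channel follows the standard workflow: Gaussian-blur
background subtraction (normalized within the tissue mask), Otsu
thresholding of the tissue-pixel histogram with a per-epitope threshold
floor (guarding against segmenting monomeric/background signal when a
channel has no true staining), and small-object removal. Cohort statistics:
Shapiro–Wilk normality routing, Pearson correlation, repeated-measures
one-way ANOVA with Tukey adjustment across regions, and unpaired Student's
t / Mann–Whitney U between disease groups; all summaries are mean ± SD.

## Worked example

```python
import epimux as em

cfg = em.build_preset("PD_like")            # PD-like aggregate taxonomy
section, truth = em.simulate_section(cfg)   # rendered 512x512 section + truth
maskset = em.segment_section(section, em.SegmentationParams())
rec = em.quantify_section(maskset, pixel_size_um=cfg.pixel_size_um)

print(f"pathology load : {rec.pathology_load_pct:.2f}% of tissue area")
for e in em.EPITOPES:
    print(f"{e:6s} total {rec.total_pct[e]:6.2f}%   unique {rec.unique_pct[e]:6.2f}%")
```

prints

```
pathology load : 4.69% of tissue area
Nterm  total  77.55%   unique  37.27%
pS129  total  58.60%   unique   5.43%
Cterm  total  57.30%   unique   3.95%
```

Read: 4.69 % of the simulated tissue area carries α-synuclein labelling; the
N-terminus antibody detects 77.6 % of that union and 37.3 % of the union is
seen by the N-terminus antibody alone, whereas only ~4–5 % of the pathology
is exclusive to pS129 or the C-terminus — the N-terminus-dominant structure
that the PD-like preset encodes (perinuclear, lysosomal and glial classes
carry only the N-terminus epitope, while Lewy bodies and neurites are seen
by all three antibodies).

The same pipeline runs from the shell over cohort directories:

```sh
epimux simulate --preset MSA_ION_like --n-cases 10 --seed 7 --out run/simulated
epimux quantify --in run/simulated --out run/quant
epimux stats --quant run/quant/quant.csv --out run/stats
```

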
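# Methods

`ctcscope` re-implements, as a tested pipeline, the image-cytometry workflow
used to enumerate circulating tumor cells (CTCs) and large tumor-derived
extracellular vesicles (tdEVs) in CellSearch-type cartridge images, and the
cohort statistics applied to the resulting per-patient counts. Because the
patient image data behind the published analysis is not publicly deposited,
the package ships a first-class synthetic-cartridge generator with planted
ground truth; every stage is validated against analytic oracles on that
synthetic data.

## Image and object model

A cartridge is an ordered set of frames, each acquired in four co-registered
fluorescence channels on a 12-bit camera (intensities in 0–4095 AU):
DAPI (DNA), PE (cytokeratin, CK), APC (CD45) and FITC. Gating uses five
logical channels; the fifth ("marker 1") maps to a constant-zero virtual
layer, because the gate table names five channels while the instrument
acquires four, and all marker-1 predicates are of the form "mean ≤ 5 AU"
that pass vacuously on an empty channel. The default pixel pitch is
0.64 µm/pixel; it is a configuration value, never hard-coded in the math.

### Synthetic objects

Every planted object is a set of uniform-intensity ("plateau") discs, one
per stained structure, on a flat background of 2 AU. Staining heterogeneity
is modelled by multiplying a mean-preserving sinusoidal texture
`1 + √2·cv·sin(·)` onto the plateau, which realizes a target intensity
coefficient of variation `cv` exactly. Discs were chosen over Gaussian
profiles deliberately: a Gaussian clipped at its 2σ footprint has an
intrinsic CV of ≈ 0.56 inside its own footprint, which would make the
homogeneous/heterogeneous CK distinction meaningless; plateau discs give
CV ≈ `cv` while keeping footprint area (πr²), channel overlap and image
moments analytically predictable.

Nine archetypes are generated (sizes sampled within windows chosen so the
archetypes separate from every gate and subclass threshold with margin):

| archetype | DAPI | CK | other |
|---|---|---|---|
| pretty CTC | 1 nucleus (6.5–8.5 µm) | smooth disc (cv ≈ 0.05) | |
| heterogeneous CTC | 1 nucleus | modulated disc (cv 0.4–0.6) | |
| CTC cluster | 2–4 intact nuclei, rims ≥ 2 px apart | one covering disc | |
| cleaved CTC | 1 intact nucleus (8.5–9.5 µm) | 3–4 round speckles ≤ 4 µm; one centred on the nucleus, the rest overlapping the nuclear rim | |
| fragmented CTC | nucleus split in 2 small fragments (< 20 µm² each), gap ≥ 2 px | intact disc | |
| cleaved + fragmented | 2 nuclear fragments | central speckle bridging the fragments + outer speckles on the fragment tips | |
| tdEV | none | disc, 1–12 µm (defaults 5–9.5 µm) | |
| leukocyte | 1 nucleus | none | CD45 membrane disc |
| debris | none | large smear (27–31 µm) | |

Two geometric constraints shape the apoptotic archetypes. First, the event
merger joins components within a 1-pixel gap, so all CK speckles must chain
to the nucleus/fragments through small overlaps, otherwise stray speckles
would segment as separate (tdEV-like) events. Second, the CTC gate requires
CK–DAPI overlay > 0.2, so a controlled fraction of the speckle area is
placed on nuclear material. The fragment-vs-nucleus size split (fragments
< 20 µm², nuclei ≥ 20 µm², thresholded at `min_nucleus_area_um2`) is what
makes a broken nucleus measurably different from a two-nucleus cluster.

Cartridges are assembled by rejection-sampling object centres with a
minimum centre distance of the two bounding radii plus a margin (default
8 px) and rendering additively; generation is bit-deterministic for a fixed
(config, seed). The default cartridge is scaled down to 4 frames of
512×512 (the reference instrument scans 175 frames); frame count and size
are configurable. Background noise is optional and defaults to 0, the
condition under which exact count recovery is asserted.

### Ground-truth labelling

Each object's *idealized FeatureVector* is computed without rendering:
areas and mean/max intensities in closed form from the disc layout;
CK eccentricity from the analytic inertia tensor of the disc union;
pixel-count features (CK perimeter, perimeter-to-area, CK–DAPI overlay)
by rasterizing the exact planted geometry at the object's sub-pixel
position, because these features are pixel-count conventions with no
continuous analogue (the continuous circle-lens overlay differs from the
pixel-counted one by up to ~0.1 for small speckles). The expected gate
label is then obtained by pushing this vector through the *same* gate set
used downstream — there is no independent labelling path, so a gate-config
change propagates consistently into the ground truth.

## Segmentation and events

Each channel of each frame is thresholded globally (triangle method on the
frame histogram by default, Otsu as an option) with a floor at
`median + 3 × 1.4826·MAD` — a robust background-plus-noise estimate; a
constant frame yields an empty mask. Components under 4 pixels are
removed. The triangle method suits sparse bright objects on a dark
background; because synthetic objects have sharp footprints well above
background, any threshold between background and the dimmest in-footprint
value reproduces the footprint exactly, which is what makes noise-free
count recovery exact rather than approximate.

Channel components merge into events transitively when separated by at
most `dilation_radius` background pixels (default 1 — a nucleus joins its
CK ring across a 1-pixel thresholding gap). Events must contain CK or DAPI
signal; CD45/FITC components never seed an event and only contribute
intensity measurements. Events are ordered by (frame, bounding-box corner)
for stable ids.

## Morphometry

Per channel, mean/max intensity over the channel's own mask
(background-inclusive — the gate thresholds are absolute AU values on
uncorrected images), area = pixel count × pixel-size². CK additionally:
eccentricity from central second moments (0 = circle); perimeter as the
count of mask pixels with a 4-connected background neighbour (the gate
states perimeter in pixels, implying a pixel-count convention);
perimeter-to-area as the ratio of those counts; CK–DAPI overlay as
|CK ∩ DAPI| / |CK| (denominator configurable: `ck|dapi|union`). Empty
channels report zeros plus an `empty_<ch>` flag rather than missing
values; strict ">" predicates then fail numerically, as intended.

## Gating and review

Gates are named conjunctions of one-sided predicates with exactly two
operators: `<=` inclusive and `>` strict, as printed. The shipped default
(`gates/table1.yaml`) encodes the published CTC gate (8 predicates, e.g.
mean CD45 ≤ 5, mean DAPI > 45, mean CK > 60, 16 < CK size ≤ 400 µm²,
overlay > 0.2) and tdEV gate (11 predicates, e.g. mean DAPI ≤ 5, max CK
> 90, CK area ≤ 150 µm², eccentricity ≤ 0.8, perimeter > 5 px). "Area CK"
and "CK size" are treated as aliases of the same measurement and both
predicates applied as printed. The two default gates are mutually
exclusive (DAPI > 45 vs ≤ 5); labelling priority is fixed CTC-before-tdEV
for custom gate sets. Review is an annotation layer (CSV of object id →
CONFIRMED/EXCLUDED_ARTIFACT); only CTC counts are corrected, mirroring the
workflow in which only CTC-gate passers were manually reviewed.

## Subclass cascade

The six morphological CTC classes were originally assigned by human
reviewers; the cascade operationalizes the verbal criteria with explicit,
configurable thresholds (defaults in parentheses):

1. ≥ 2 intact nuclei in CK, none broken → **cluster**;
2. speckled CK and ≥ 2 DNA fragments → **cleaved CK + fragmented DNA**;
3. speckled CK → **cleaved CK**;
4. fragmented DNA or non-speckle CK fragmentation → **fragmented**;
5. CK CV > τ_cv (0.25) or 1 − solidity > τ_shape (0.15) → **heterogeneous CK**;
6. otherwise → **pretty**.

Speckle flag: ≥ 3 CK components, each ≤ 16 µm² and eccentricity ≤ 0.8.
Intact nuclei: DAPI components ≥ 20 µm² with centroid inside the CK mask —
the size cut is required because a nucleus split in two inside an intact
CK disc is otherwise indistinguishable from a two-nucleus cluster.
"Protruding nuclei" is approximated by the solidity-based irregularity; a
dedicated protrusion metric is out of scope. The cascade is total (every
CTC gets exactly one label) and its order is part of the contract: a
speckled event with two intact nuclei is a cluster only because step 1
precedes the apoptotic steps.

## Cohort model

Per patient, a latent log-scale tumour burden `L ~ N(μ_stage, σ_stage)`
drives both markers: `ctc = ⌊exp(L + ε_c)⌋` and
`tdev = ⌊m·exp(L + ε_t)⌋` with independent noises (SD 0.5) and a
per-patient log-normal tdEV multiplier `m` (stage medians 7 and 12).
Defaults: CNPC μ = log 1.6, σ = 2.0; CRPC μ = log 4.2, σ = 1.9. The floor
of the wide log-normal produces the observed mass at zero CTCs
(≈ 40% / 22% per stage) without structural zero-inflation; a zero-inflation
probability exists (default 0) but burden-independent zeros would
decorrelate the two markers. The shared latent yields Spearman ρ ≈ 0.85–0.94
(target band 0.80–0.95). Subclass counts are multinomial splits of the CTC
count with stage-specific proportions (heterogeneous CK most abundant;
clusters relatively more frequent in CRPC).

Follow-up (post-ADT) patients draw a log-normal decline factor per marker
(median 0.15, log-SD 0.4). Their baseline burden uses narrower parameters
(μ = log 8, σ = 1.0), emulating the ≥ 3-CTC inclusion criterion of the
follow-up study; with the full heavy-tailed marginal, the paired t-test on
raw counts would have mean/SD of differences ≈ 0.14 and essentially no
power at n = 31, for any effect size — the restriction is what makes the
raw-scale paired comparison meaningful.

What the generator does *not* emulate: optics (PSF, chromatic aberration,
uneven illumination), cell declumping, staining variability between
cartridges, or reviewer disagreement. Passing tests therefore demonstrate
the correctness of segmentation/measurement/gating logic under the stated
image model, not detection performance on real cartridges.

## Statistical conventions

* **Mann–Whitney U**: midranks over the pooled sample; U reported for the
  first group; two-sided p from the tie-corrected normal approximation
  without continuity correction (consistent with common statistical
  packages), switching to exact enumeration of all group assignments when
  both groups have ≤ 8 observations (valid under ties; two-sided p is twice
  the smaller tail, capped at 1). Pooled mean ranks are reported alongside.
* **Spearman**: Pearson correlation of midranks, two-tailed p from the
  t-approximation with n − 2 df.
* **Chi-square (2×2)**: Pearson statistic without continuity correction,
  1 df, expected counts reported. On the published CTC-presence table
  (56/48 vs 48/18) this gives p = 0.0138 → 0.014 as printed; the
  Yates-corrected statistic gives ≈ 0.02, so the uncorrected form is the
  one consistent with the source analysis. The Monte-Carlo oracle check is
  run where the approximation is applicable (all expected counts ≥ 8),
  using the mid-p tie convention; below that regime the asymptotic p
  genuinely departs from the discrete null by ~0.03.
* **Paired t**: on raw count differences (a log(x+1) option exists, off by
  default), df = n − 1.
* Degenerate inputs (all-tied samples, zero-variance ranks or differences)
  return flagged results with p = 1 or NaN rather than raising.
* Reports round p-values to three decimals; CSV outputs keep full
  precision. No multiple-testing correction is applied across the battery,
  matching the source analysis.

## Numerical and format choices

0-based half-open bounding boxes everywhere; events CSV columns are
`<feature>_<channel>`. Cartridges are multi-page TIFF, frame-major /
channel-minor, with pixel size and channel order in the first page
description; a channel-order override handles foreign stacks. Tables are
CSV with a one-line `#` provenance header (config hash + seed); floats are
written as `%.17g` and parsed with round-trip precision so all artifacts
round-trip losslessly. Thumbnails are fixed-size composites (DAPI → blue,
CK → green, CD45 → red) with per-channel min–max scaling over the crop.

## Known limitations

* Exact count recovery is a noise-free property; with noise enabled the
  thresholds are robust but recovery is no longer guaranteed to be exact.
* The subclass thresholds separate the generator's archetypes with margin;
  they are starting points, not calibrated against reviewer consensus (no
  inter-rater data is available to calibrate against).
* Touching cells are not declumped beyond threshold-level separation, and
  the 175-frame mosaic is treated as independent frames (no stitching).
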
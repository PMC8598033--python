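# Methods

This note records the models, parameter choices and numerical conventions
behind `morphodyn`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## 1. Scene and cell-shape model

The simulator renders the 2-D fluorescent silhouette of each cell; the
physical cells deform in 3-D, but every downstream measurement is a 2-D image
feature, so only the projection is modelled. Well depth (35 µm) is carried as
metadata and never used.

A cell boundary is a truncated Fourier star-convex curve

r(θ, t) = r₀ · (1 + Σₖ aₖ cos(k(θ − ωt) − φₖ(t))),  k = 2…6,

with rigid rotation ω = 2π·f·60·t per minute (f = 0.1 Hz, i.e. six turns per
minute, so consecutive one-minute frames show whole turns), slow lobe-phase
drift φₖ(t) = φₖ(0) + δ·t, and transient protrusions — Gaussian bumps in
angle and time, arriving at a Poisson rate and co-rotating with the cell.
Amplitude draws are rejected (bounded retries) whenever Σ aₖ ≥ 0.5, which
keeps r > 0 everywhere; the curve is then star-convex about its centre and
therefore simple. This is the simplest parameterisation whose knobs map onto
the morphologies of interest (lobedness, protrusiveness, bleb-like
transients). The stock phenotypes differ in base radius, lobe-amplitude
distribution, drift, and protrusion rate/amplitude; each carries within-class
sub-modes as parameter offsets (4 epithelial-like, 3 mesenchymal-like).

Rendering: 0.5 µm pixels and an 80 µm well pitch, so a well spans a 160 px
box — resolvable cells with small files. Signal is constant background (100
counts) + faint triangular well outlines (+20) + filled silhouettes (~300);
noise is Poisson(signal) plus Gaussian read noise (σ = 3), the standard
fluorescence-camera model. Dead cells are rendered static (frozen at their
initial outline) in the fluorescence channel and are the only content of the
single end-of-run viability frame, mimicking terminal propidium-iodide
staining of cells that still carry GFP signal.

The simulation does **not** emulate: uneven illumination, focus drift,
photobleaching, cell debris, wells shared by touching cells of different
classes, or any correlation between a cell's texture and its class (texture
inside the silhouette is uniform up to noise). Tests passing on these scenes
therefore validate the machinery — geometry, delineation, feature
definitions, protocol plumbing — not robustness to real-microscope
artefacts.

## 2. Segmentation

Wells are cropped at known grid coordinates (stage positions are programmed;
no detection problem is invented). Delineation is Gaussian smoothing
(σ = 1 px) → Otsu threshold → 3×3 opening and closing → hole filling →
largest component, with two conventions:

* a **minimum-contrast floor** (50 counts between the Otsu foreground and
  background means) declares a crop empty rather than letting the threshold
  latch onto faint structure such as the well walls (~20 counts);
* component ties break toward the lower scan order; an empty mask is a valid
  result.

Occupancy is called per frame from the pre-cleanup component census
(min area 30 px); a well qualifies as a single cell only if it is single in
≥ 80 % of frames and multi in < 20 % — transient contact with a neighbour
disqualifies the well, the conservative reading of "single cells only". The
viability filter marks a well dead when > 0.5 % of its box exceeds the frame
median by 100 counts; a stained cell covers a few percent of its box at
hundreds of counts, so this is far from both failure modes (a box-mean
statistic was rejected: small cells lift the mean by single counts).

On noiseless scenes the retained set equals the ground-truth
{single ∧ alive} set exactly, and masks reach IoU ≥ 0.99 against the
rasterised truth; at the default noise level mean IoU stays above 0.8
(regression-tested with a fixed seed).

## 3. The 169-column feature manifest

The manifest is fixed at 26 shape + 30 Zernike + 104 Haralick + 9 intensity
= 169 columns, in a frozen order, so the pipeline dimensions (169 → 14) are
exact. It is a reconstruction: the measurement families are standard
CellProfiler-style outputs, but the exact list is this package's own.

Numerical conventions worth knowing:

* **Perimeter** uses the 4-direction Crofton estimator; the chain-code
  perimeter overestimates smooth boundaries enough to push a disk's form
  factor 4πA/P² down to ~0.91, while Crofton keeps it within a few percent
  of 1.
* **Zernike moments** map the mask to the unit disk centred at the binary
  centroid with radius = the maximum centroid-to-pixel distance (the shape
  always fits inside the disk; the equivalent-radius alternative was
  rejected because protrusive shapes would spill outside). Moments use the
  (n+1)/π normalisation with the pixel area element 1/R², approximating the
  continuous integral; magnitudes are rotation-invariant to within ~2 % on
  rasterised shapes. A rasterised disk retains the pixel lattice's dihedral
  symmetry, so its m ∉ 4ℤ moments vanish exactly while m ∈ {4, 8} keep an
  O(1/r) lattice residual — the oracle tests assert exactly this.
* **GLCM/Haralick**: in-mask intensities are quantised to 8 equal-width bins
  over the mask's min–max range (robust for small masks); each co-occurrence
  matrix is restricted to pixel pairs with both ends in the mask,
  symmetrised and normalised; 13 classical statistics per matrix at
  distances {1, 2} and angles {0°, 45°, 90°, 135°}. Natural logarithms
  throughout; correlation is defined as 0 at zero marginal variance; sum
  variance is taken about the sum average (the historical formula's use of
  sum entropy there is a known erratum); offsets with < 2 in-mask pairs
  yield 13 zeros (logged) so the ML stage never sees missing values.
* **Units**: lengths in µm via the pixel size; dimensionless descriptors are
  unit-free. The shape family's mass-displacement slot is a placeholder 0;
  the intensity-weighted version lives in the intensity family.

## 4. Fast-path feature generator

For the ML stages a parametric generator bypasses rendering. Each cell draws
a class, one of its sub-phenotype components, a per-cell random offset
(SD 0.5 per column), and an AR(1) temporal noise track (ρ = 0.6, stationary
SD 1), giving a per-column variance of 1.25 about the component centre;
"pooled SD" below means √1.25. Class 1 is shifted by `effect_size` pooled SD
on 10 designated columns.

The default sub-phenotype mixture plants 7 component centres (4 for class 0,
3 for class 1) on a one-dimensional latent chain with adjacent spacing
8 pooled SD and the classes interleaved (A,B,A,B,A,B,A). Three properties
motivate this geometry:

* all pairwise centre separations are ≥ 8 pooled SD;
* both class means sit at the chain midpoint, so the chain direction carries
  no class signal — classes are only distinguishable via the components
  themselves (or the explicit effect columns when `effect_size` > 0);
* geometric neighbours always belong to opposite classes, so any clustering
  too coarse to resolve the components must mix classes. This mirrors the
  empirical situation the clustering stage is built for: phenotype purity is
  only reachable at the granularity of the sub-phenotypes.

The chain direction is spread uniformly across all 159 non-effect columns.
This matters: the analysis space is per-column standardised, and structure
concentrated on few columns would be normalised away (each such column's SD
is dominated by the structure itself), collapsing the planted separation
below the noise floor of the remaining columns. Spread thinly, no single
column is structure-dominated, and the separation survives standardisation
essentially intact.

## 5. Classification protocol

* **Cell-level split** (all timepoint rows of a cell on one side), stratified
  by class with floor rounding of the 70 % train fraction — stratification is
  needed so extreme-imbalance runs keep minority test cells.
* **Time limit** keeps rows with t strictly below T.
* **Imbalance ratio** is defined over training example rows (timepoint
  granularity). Subsampling removes whole minority cells first, then trims
  the last kept cell (earliest timepoints kept) so the achieved ratio is
  exact to within one row; the test set is untouched.
* **Preprocessing** (per-feature z-score, constant columns given SD 1, then
  PCA to 14 components) is fit on training rows only and applied to both
  sides — a pure function of the training rows, property-tested as such.
* **AdaBoost** is the discrete two-class algorithm over depth-1 stumps:
  candidate thresholds are midpoints of consecutive distinct sorted values;
  each round takes the global weighted-error minimiser (ties → smallest
  feature index, then smallest threshold, then positive polarity);
  αₜ = ½ ln((1−εₜ)/εₜ) with ε clipped to [1e−12, 1−1e−12]; boosting stops at
  εₜ ≥ 0.5 (stump rejected) or εₜ = 0 (separable — stump kept, clipped α).
  100 rounds by default. The round-1 stump is oracle-tested against
  exhaustive search, and the training error is checked against the
  exponential-loss bound Πₜ 2√(εₜ(1−εₜ)).
* **Per-cell aggregation** defaults to majority vote over a cell's rows with
  exact ties falling to the general class 0; `mean_score` (sign of the mean
  boosted margin) and `per_row` are available because how per-cell confidence
  should accumulate over scans is genuinely open.
* 30 repeats of the whole loop (reshuffle → … → score) with means and SDs
  reported. All randomness flows from one seed through named substreams, so
  reports are bit-reproducible.

## 6. Sub-phenotype clustering

`kmeans` is plain Lloyd iteration from k distinct data points chosen at
random, best of 10 restarts by WCSS, assignment ties to the lowest cluster
index, and empty clusters reseeded at the point farthest from its assigned
centroid; WCSS is asserted non-increasing at every step. k-means++ seeding
exists as an option but is not the default. On tiny instances (n = 8) the
multi-restart optimum matches exhaustive partition enumeration in ≥ 95 % of
seeds.

The homogeneity score is 1 − H(A|C)/H(A) with the **cluster-size
denominator** n_mk/c_k inside the conditional-entropy log. The variant that
divides by the class size instead is exposed as `mode="as_printed"` for
comparison but is not the default: it scores a single all-points cluster as
1, which contradicts what a homogeneity measure must do (that degenerate
labelling should score 0). Logs are natural; the base cancels in the ratio.
A single true class yields homogeneity 1 by convention.

`select_k` runs k = 2…15, keeps the k whose minimum per-cluster purity
(majority-class fraction) exceeds 0.95 — the per-cluster reading of "every
cluster must be homogeneous", since the entropy score is global — and among
those returns the maximal global homogeneity, ties to the smallest k. If no
k qualifies, the global argmax is returned flagged `constraint_unmet`.
Min purity and global homogeneity are not ordered in general (a constructed
counterexample is tested), which is why both are reported.

Clustering operates on per-cell mean feature vectors in the same
standardised 14-component space the classifier uses; a per-row mode is
available via `prepare_cell_vectors` on the raw table. Per-cell averaging is
the default because sub-phenotypes are properties of cells, not of frames.

## 7. Problem sizes and determinism

The shipped benchmarks use: 550 cells/class × 10 timepoints for balanced
classification; 1500 + 180 cells × 20 timepoints for the 1/1500 imbalance
study (yielding ~54 held-out minority cells per repeat); 100 cells per
component (700 total) for sub-phenotype recovery over 30 clustering seeds;
and 5×5 or 6×6 well grids over 3–5 frames for image-level tests. These sizes
give stable Monte-Carlo estimates in minutes on one CPU while matching the
scale of a single experimental run (~10³ cells).

Every stage derives its generator from a single seed through CRC-named
substreams (`_rng.substream(seed, stage, index)`), so stages can be re-run in
isolation and whole pipelines are byte-reproducible (checksummed manifests
are compared in the test suite).

## 8. Known limitations

* The feature list reproduces the four measurement families and the total
  count of 169, not any particular instrument's exact export.
* Deformation magnitudes and timescales of real suspended cells are not
  measured anywhere we can fit to; the generator's distributions are
  stipulated, and the classification/clustering benchmarks quantify recovery
  under those stipulated, strongly separated conditions — they are upper
  bounds on behaviour, not field performance.
* The boundary model is star-convex: highly concave or fragmented
  morphologies (apoptotic blebbing, doublets) are outside it.
* Haralick features on a binary silhouette carry little information (texture
  enters only through noise); they become informative when real intensity
  crops are supplied.
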
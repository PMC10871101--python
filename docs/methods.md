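# Methods

This note documents the models and procedures implemented in
`hotspotnac`, the parameters that matter, the synthetic data they are
exercised on, and the numerical choices made where the design was open.

## Pipeline model

The unit of analysis is a patient with one or more 8000 × 8000 px image
regions, each carrying point detections of tumor cells (TC), stromal and
intratumoral TILs (sTIL, tTIL) in the H&E frame, and Ki67+/pH3+ signals
in per-channel serial-section frames. The pipeline maps IHC points into
the H&E frame, flags tumor cells by marker proximity, tiles regions into
1000 × 1000 px patches, ranks each patient's patches under a cell-class
metric, and classifies the top k patches, aggregating to a patient label
by maximum voting.

### Co-registration

Registration is posed as point-set alignment because the package's
inputs are detections, not pixels. The transform family is similarity
(rotation, isotropic scale, translation) — serial sections from one
block scanned on one instrument differ by a small rigid offset and a
near-unit scale; deformable warping is out of scope.

The estimator is trimmed ICP: each iteration matches every moving point
to its nearest reference neighbour (within its own region when region
labels are given; regions are disjoint fields sharing one slide-level
transform), keeps the closest `trim_fraction` (default 0.5) of matches,
and refits the similarity transform in closed form (Umeyama). The
monitored residual is the trimmed RMS nearest-neighbour distance, which
is non-increasing across iterations by the usual ICP argument; iteration
stops when it improves by less than `tol` (10⁻⁴ px).

ICP's convergence basin is roughly half the reference nearest-neighbour
spacing (~25 px at 100 tumor cells per patch). A dense moving set starts
inside it after centroid/RMS alignment, but a sparse one — a pH3 channel
has on the order of 10² mitotic points per region — has centroid
sampling error of hundreds of pixels, and plain ICP then stalls: wrong
nearest-neighbour matches reinforce whatever transform is current, and
the least-squares fit drags the scale down. The estimator therefore
escalates when the first ICP pass ends above `accept_residual_factor`
(0.25) × the reference spacing: a grid of (rotation, scale) candidates
is scored by the mode of moving-to-reference pairwise difference
vectors — the translation at which the two point densities coincide.
True correspondences concentrate in one ~50 px bin (support ≈ the number
of moving points) while mismatches spread uniformly, so the mode stands
out by several standard deviations even for ~100-point sets. The scale
grid is centred on 1 (the serial-section prior) rather than on the
RMS-radius ratio, whose ~5% sampling error for sparse subsets smears the
mode; grid steps are set so a within-cell error displaces mid-field
points by less than the peak window, top candidates are re-scored on a
3× finer local grid, and ICP reruns from the best starts. On default
synthetic cohorts every channel (152 per cohort) converges with residual
≈ the 2 px detection jitter and transform parameters recovered to ~10⁻⁴.

### Phenotyping

A tumor cell is Ki67+ (is_P) iff at least one registered Ki67 point lies
at Euclidean distance ≤ 40 px, and pH3+ (is_M) analogously; the boundary
is inclusive (the measure-zero choice is fixed for determinism), one IHC
point may flag several cells, and TILs are never phenotyped. The
implementation uses a KD-tree nearest-neighbour query but is tested to
be identical to all-pairs distance thresholding. Note the rule's
intrinsic behaviour at realistic density: a stained cell's coincidental
neighbours within 40 px are also flagged, so recovery against ground
truth has perfect recall (jitter is 2 px against a 40 px radius, a ~20σ
tail) but precision below 1; the same rule with the same property was
applied to the real data the pipeline targets. Membership of pH3+ cells
in the Ki67+ set is not enforced at assignment; the generator's ground
truth satisfies it by construction and the recovery report exposes any
violation introduced by registration error.

### Hotspots

Patches are half-open tiles [x₀, x₀+1000) × [y₀, y₀+1000), so every cell
lands in exactly one patch and patch sums conserve region totals. All of
a patient's patches (pooled over regions) are sorted in descending order
of the metric value — one of tTILs, sTILs, sTILs+tTILs, P, M, TCs; the
count equals the density because patch areas are equal — with ties
broken by (region, row, column) so selection is invariant to input
order. k defaults to 21 (odd, so binary majority votes cannot tie; an
even k draws a warning) and a patient with fewer than k patches
contributes all of them.

### Classifier

One row per hotspot with the five counts as features and the patient's
label attached. The candidate families and grids are fixed and explicit:

| family | grid | standardisation |
|---|---|---|
| LDA | svd; lsqr + auto shrinkage | none (scale-equivariant) |
| SVM | linear and RBF; C ∈ {0.1, 1, 10, 100}; γ ∈ {scale, 0.01, 0.1, 1} | z-score |
| MLP | 1 hidden layer ∈ {16, 64}; L2 ∈ {10⁻⁴, 10⁻²}; lbfgs, ≤500 iter | z-score |

lbfgs is used for the MLP because full-batch quasi-Newton is the fast,
deterministic choice at 10³ rows × ≤5 features; its random state derives
from the fit seed. Candidates are scored by mean hotspot-level accuracy
over patient-disjoint stratified 3-fold cross-validation (folding at
patient level avoids leakage between a patient's hotspots; z-scoring is
fitted inside each fold). Ties resolve by canonical grid order (LDA
before SVM before MLP, fixed parameter order). The winner is refitted on
all training hotspots.

Patients are split 75/25 before any fitting, stratified by outcome with
largest-remainder rounding — 44 pCR + 32 RD gives the canonical
33+24 = 57 train / 11+8 = 19 test. Prediction aggregates hotspot labels
by majority; the vote tie possible only under an even k resolves to pCR
(configurable). The patient ROC score is the pCR-vote fraction.

Fitted models serialise to JSON holding the selected family,
hyperparameters, per-feature standardisation and the family's fitted
arrays (linear weights; RBF support vectors and dual coefficients; MLP
layer weights). Loading reconstructs an independent forward pass rather
than rehydrating library internals; round-trip prediction equality is
tested per family.

### Evaluation

Confusion counts with pCR positive; accuracy, TPR, FPR, precision,
recall and F1 from their standard definitions. Zero-denominator
conventions: precision is 0 (with a warning) when nothing is predicted
positive; F1 is 0 when precision + recall is 0. ROC AUC is the
Mann–Whitney statistic with half credit for ties, equal to the
trapezoidal area under the empirical curve and to the pairwise brute
force it is tested against. Confusion matrices are also reported
row-normalised (rows = true class).

### Experiment runner

`run_experiment` executes the full metric × feature-configuration grid
on one cohort with a single patient split and a single CV seed shared
across cells, so rows are comparable; `run_replicates` repeats over
seeds (fresh cohort and split per seed) and reports mean ± sd, because a
19-patient test set makes single-split estimates high-variance.

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes:
76 patients (44 pCR, 32 RD), one 8000 × 8000 px region each by default,
per-patch cell counts as independent Poisson draws with class-specific
rates, positions uniform within the patch. Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| TC rate | 100 /patch | the density the hotspot size calculation assumes (21 × 100 ≈ 2100 cells) |
| sTIL rate | 15 /patch | mid-range TIL density; no class effect by default |
| tTIL rate | 20 (pCR) / 10 (RD) | elevated intratumoral TILs in responders; 2× is the package's default effect size |
| ki67_fraction | 0.20 | a cycling fraction in the usual TNBC range |
| ph3_fraction | 0.02 | mitotic cells are rare, an order of magnitude below Ki67+ |
| misalignment | θ = 0.02 rad, s = 1.01, t = (25, −18) px | a visible but small serial-section offset |
| jitter | 2 px | detector localisation noise, well inside the 40 px rule |

Every pH3+ cell is Ki67+ by construction (pH3 is drawn as a subset of
the Ki67+ cells with conditional probability ph3/ki67), and IHC channel
point lists are the flagged tumor-cell coordinates pushed through the
misalignment plus jitter. Ground truth (per-cell flags, per-channel
transforms) is emitted alongside. H&E coordinates lie in
[0, region_size); IHC coordinates live in the perturbed frame and may
fall slightly outside the nominal bounds — clipping them would corrupt
transform recovery. Cohorts are byte-reproducible from the seed, and the
CSV round trip is exact (`%.17g` writing, round-trip parsing).

What the generator does **not** model: spatial clustering of cells
(counts are Poisson, positions uniform — hotspots are order statistics
of exchangeable patches rather than biological niches), nuclear
morphology, detector false positives/negatives beyond coordinate
jitter, staining artifacts, or variable per-patient region counts.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and calibrated under its own assumptions, not that the
biological effect sizes on real tissue match.

## End-to-end behaviour checks and problem sizes

Two whole-pipeline suites bracket the classifier's behaviour:

- **Null calibration** — identical rates for both classes; pooled
  patient accuracy over 20 replicate cohorts must stay within 3 SE of
  the pooled majority-class baseline. Run at 40 patients (23/17) with
  5000 px regions, the package's chosen replicate size for this check.
- **Effect detection** — default 2× tTIL effect at the full 76-patient
  design over 10 seeds: mean patient accuracy ≥ 0.85 for tTIL hotspots
  with features (tTILs, sTILs, P, M), and the tTILs metric sharing or
  holding first place among the six metrics in a majority of seeds.
  Under the default effect size all metrics typically saturate near
  perfect patient accuracy, so first place is usually shared; the check
  is directional.

## Known limitations

- The registration escalation assumes near-unit relative scale between
  serial sections; strongly mismatched magnifications need
  `scale_center`/`scale_range` widened, at higher search cost.
- Proximity phenotyping over-assigns at high tumor-cell density (see
  above); P/M counts are upper bounds on the truly stained populations.
- Majority voting weighs all hotspots equally; no learned aggregation.
- With one region per patient the hotspot pool is 64 patches; patients
  with fewer than k patches are handled but never arise under defaults.
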
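# Methods

## Model overview

`swaps` treats each MS1 scan (the merged spectrum of one complete TIMS
ramp) as a matrix over (m/z, 1/K0) and assumes it is a nonnegative linear
combination of the isotope envelopes of the candidate precursors eluting at
that scan time. The deconvolution recovers, per scan and per 1/K0 column,
one activation coefficient per admitted candidate; a candidate's
activations over (scan × 1/K0) inside its search windows form its
activation image, which downstream models segment and score.

Assumptions worth stating explicitly:

- **Linearity and nonnegativity.** Signals superpose additively and
  abundances are nonnegative; we therefore solve non-negative least squares
  per 1/K0 column, with no sparsity penalty. Solver: `scipy.optimize.nnls`,
  max iterations 3 × #candidates (floor 30).
- **Envelope fidelity.** Theoretical isotopologue distributions (binned at
  the m/z bin width) describe the observed patterns. Abundances are
  probabilities of the total distribution, aggregated per bin *before* the
  1% threshold and never renormalized afterwards, so activation
  coefficients are comparable across candidates.
- **Separability of scans.** Scans are deconvoluted independently; no
  elution-shape coupling along RT is imposed.

## Dictionary construction

Libraries are merged on (modified sequence, charge); among duplicates the
highest-intensity record survives (ties prefer the experiment library).
For shared keys the merged record carries the reference library's 1/K0
coordinates (1/K0 is the more reproducible axis) and the experiment
library's RT coordinates (they define segmentation labels).

RT predictions come from one of three sources, in order of preference:
an external prediction table; a LOWESS alignment (statsmodels
implementation, `frac = 0.3`) of reference RT onto experiment RT fitted on
≥ 20 shared precursors; or, lacking both, the library's own observed
coordinates ("exact dictionary" mode, in which windows are the observed
feature extents and no model-based filtering or FDR control is applied —
appropriate when the library is itself FDR-controlled search output of the
same run).

Window half-widths are calibrated on a seeded uniform holdout (default
10%) of the experiment library: ΔRT95 and Δ1/K0-95 are 95th percentiles of
absolute prediction error, and L is the 99.9th percentile of 1/K0 feature
lengths. All percentiles use linear interpolation between order statistics
(`numpy.percentile`, default method), applied identically at 95 and 99.9.

**Decoys.** Round 1 mutates the second and second-to-last residue by a
total residue map (shipped as `data/mutation_map.tsv`, configurable; a
mutated residue sheds any residue-level modification). If the round-1
decoy's neutral monoisotopic mass is within `mz_bin_width × charge` of the
target's — i.e. the envelopes would occupy the same bins — the
third-to-last residue is mutated too. Decoys colliding with any target
sequence are removed; sequences shorter than 4 residues get no decoy and
are excluded from target–decoy competition. Decoys inherit their target's
predicted coordinates and windows and run through a separate search.

## Scan-wise activation

Frames are rasterized with `bin = floor(mz / width)` (default width
0.01 Th); intensities sharing a cell are summed; 1/K0 values snap to the
run-level grid (sorted union of observed values, or a configured fixed
grid) within half a grid step, otherwise the point is dropped and counted.
Per scan, the dictionary admits candidates with `t1 ≤ T_i ≤ t2`
(inclusive). The per-column NNLS objective separates exactly over
connected components of the bipartite bin–candidate graph
(`scipy.sparse.csgraph.connected_components` on the candidate adjacency),
so blocks are solved independently; the equivalence to the monolithic
solve is asserted to 1e-9 per coefficient in the tests. All-zero columns
and blocks without observed support short-circuit to zero.

## Segmentation and scoring networks

Inputs are built per candidate from the cropped activation image:
channel 1 min–max-scaled activation, channel 2 min–max-scaled
log10(activation + 1) (the +1 offset avoids −inf on empty pixels; scaling
is per image — the data are single-run and per-image scaling makes the
models exposure-invariant), channel 3 the hint channel (+1 at the
candidate's predicted (RT, 1/K0) pixel, −1 per isobaric competitor — same
monoisotopic m/z bin, intersecting windows — summed on collision). The
continuous channels are resized bilinearly to (image_size, image_size)
with an align-corners coordinate map; hints and label rectangles are
placed/rendered directly on the resized grid, never resampled, so ±1
values cannot leak through interpolation. Predicted masks map back to
native resolution by a majority-area rule (each resized pixel is assigned
to its nearest native pixel; a native pixel is on iff at least half of its
assigned pixels are on), chosen to conserve axis-aligned rectangles under
round-trip.

The segmentation network is a UNet: contracting/expansive paths of
(3×3 conv → batch norm → ReLU) blocks with skip concatenations, channel
width doubling per level (defaults: depth 6, first width 32), trained with
combo loss 1·BCE + 4·dice + 1·focal (dice smoothing 1.0; focal γ = 2,
α = 0.5 — the loss family is standard, the hyperparameters are ours).
The scorer reuses the encoder, followed by adaptive average pooling,
flattening and a linear head; sigmoid of the logit is the confidence
score. Both train with Adam under a one-cycle schedule (default max LR
1e-3, batch 32), an 8:1:1 seeded split, early stopping with patience 10,
max 100 epochs. Validation metrics: mean weighted IoU over nonempty-label
validation items for segmentation (empty-label decoy items are excluded
because a zero-intensity union defines weighted IoU as 0 and would only
dilute the signal), ROC AUC for the scorer. Early-stopping snapshots
include batch-norm running statistics. The whole stack — convolutions as
nine shifted tensor contractions, batch-norm and pooling backprop, Adam —
is implemented in NumPy and is bit-deterministic given the run seed.

Segmentation training pools contain the experiment-library targets (label:
the observed feature rectangle, rendered on the resized grid) and their
decoys (label: empty mask). Scorer pools use the same candidates with
binary target/decoy labels and the segmentation probability map as a
fourth input channel.

## Post-processing and FDR

The filter chain is fixed: intensity ≥ 100 (strictly-below removed) →
target–decoy competition (higher confidence wins; exact ties remove the
*target*, the conservative choice) → signal competition (same
monoisotopic bin, |Δrt_pred| < 2·ΔRT95, |Δ1/K0| < 2·Δ1/K0-95, and
|Δlog10 intensity| < 0.01 mark a pair as claiming one MS1 feature; the
lower-confidence member is removed; competitor pairs are processed in
descending max-confidence order and removed candidates cannot eliminate
others) → confidence threshold. `FDR = N_decoy / N_target` over
survivors; the chosen threshold is the smallest one with FDR ≤ the cap
(default 20%), or 0 when no thresholding is needed. FDR is reported
unmonotonized; a cumulative-minimum q-value-style column is available as a
clearly-labelled extension. Decoys surviving the sweep are written to the
report with their flag rather than silently dropped.

## Synthetic data

The generator emulates the inputs end to end. Libraries: tryptic-like
sequences (length 7–30, C-terminal K/R), charges 2–4 (60/30/10%),
RT apexes uniform over the gradient, 1/K0 linear in m/z and charge with
Gaussian scatter, log10 intensity ~ N(5.5, 0.6). Elution and 1/K0 feature
lengths are lognormal with median 0.16 min / 75th percentile 0.21 min and
median 0.072 / 75th percentile 0.096 respectively — the scales observed on
30 min gradients with a 100 ms TIMS ramp. Runs: each precursor deposits
`total × w_rt(frame) × w_im(grid) × envelope abundance` per point, with
discrete Gaussian weights normalized within a ±4σ truncation, so a
noiseless run conserves intensity exactly (σ_rt = elution length / 4,
matching the rectangle labels at ±2σ). Optional noise adds Poisson-count
points per frame (uniform m/z, exponential intensity) and never alters the
ledger. Species labels follow the mixture fractions by largest-remainder
quotas with a seeded shuffle, so every species is represented at toy n
while counts remain inside multinomial bands; condition pairs scale
per-species intensities by the fraction ratios (e.g. yeast 0.30:0.15 → 2).

What the generator does *not* emulate: chromatographic tailing, charge
envelopes across multiple states, m/z-dependent detector response,
centroiding artifacts, or correlated (chemical) noise. Passing tests on
synthetic data therefore demonstrate the correctness of the machinery —
deconvolution, windowing, masking, competition, calibration — not
real-data performance, which depends on prediction quality and
interference structure absent here.

## Problem sizes and numerical choices

Tests and the acceptance checks run the study at desk scale as a package
design choice: fixture runs use a 4 min gradient with one MS1 frame per
0.02 min, 40–60 precursors, a fixed 1/K0 grid at 0.005 spacing, and toy
network dimensions (64×64 inputs, depth 3, first width 8, ≤ 30 epochs,
batch 16). Prediction errors in the fixtures are sized so the ΔRT95
window (~0.4 min) clearly exceeds the elution length, mirroring the
identity-propagation regime where windows dwarf peaks; the separable
fixture suite additionally bounds prediction errors uniformly inside the
windows so every target image contains its full peak (the capacity check
for the models), while the `tiny` preset keeps honest Gaussian errors —
including the ~5% of labels that fall partly or fully outside their
windows, as happens in practice.

Degenerate inputs: constant images min–max-scale to all zeros; hints
outside the crop clip to the border pixel (logged); a candidate whose
windows miss the run entirely yields a flagged 1×1 zero image; FDR with
zero surviving targets is reported as NaN with a warning; percentile ties
and exact window boundaries are inclusive.

## Known limitations

- The NumPy networks are CPU-bound and sized for toy problems; the
  architecture matches the intended design (UNet depth 6, width 32) but
  training at full scale is out of scope.
- RT/IM prediction is a pluggable interface (external table or LOWESS
  alignment); no learned property predictor is bundled.
- Vendor raw formats are not read; MS1 data enter as a portable point
  list. Protein inference, MS2 handling, and cross-run model transfer are
  out of scope.
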
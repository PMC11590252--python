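# Methods

## Problem

Medium-resolution (5–10 Å) cryo-EM density maps resolve α-helices as
cylindrical rods but blur individual β-strands, so detecting secondary
structure — especially β-sheets — from the map alone is a hard,
class-imbalanced 3D segmentation problem.  `cryosse` segments each voxel of
a chain-sized, box-cropped map region into helix / sheet / background with
a small 3D U-Net, and its central scientific content is the comparison of
five training objectives that differ in how they handle class imbalance:
cross-entropy (CE), focal loss (FL), Dice loss (DL), and the additive
combinations CE_DL and FL_DL.

## Ground-truth construction

Residues are reduced to Cα atoms; secondary structure comes from DSSP codes
collapsed to three classes (H/G/I → helix, B/E → sheet, everything else —
including missing codes and all non-protein residues — background).  Since
helices and sheets are ~6 Å thick, a voxel is labeled helix (sheet) when
its center lies within 3.0 Å (inclusive) of a helix (sheet) Cα.  The
annotation source never specifies what happens when a voxel is within 3 Å
of *both* classes; we resolve conflicts by nearest Cα, with exact-distance
ties going to helix (helices are the higher-confidence class at these
resolutions).  The radius is a parameter (`radius=3.0`) and labeling is
verified against a brute-force per-voxel distance scan in the tests.

All geometry assumes a 1 Å isotropic working grid (anisotropic input maps
are resampled trilinearly on load with a warning); voxel index (i,j,k)
addresses the voxel *center* at `origin + index·spacing`, with 0-based
half-open ranges everywhere.

## Box cropping and padding

A training/evaluation case is the Cα bounding box of a structure expanded
by 34 Å per axis (17 Å per side), clipped at map boundaries with the
per-side padding actually applied recorded in a `BoxSpec`.  The padding
exists because the network's receptive field ("depth of field") is ~35–40
voxels: voxels near the crop faces lack context, so the training loss, all
evaluation, and the final exported segmentation are restricted to the
*center box* with the padding removed.  The padding convention ("34 Å per
dimension") is ambiguous between per-side and per-axis; we read it as 17 Å
per side (34 Å total per axis), which makes a lone Cα with 34 Å padding
produce a 35³ crop on the 1 Å grid.  The mask-based implementation makes
this testable by mutation: perturbing padding voxels changes neither the
loss nor any metric.

## Loss functions

With K = 3 classes (background deliberately the *last* channel), one-hot
labels y and softmax probabilities p, all sums running over center-box
voxels j:

- CE(y,p)  = −Σ_j Σ_k y_jk log p_jk
- FL(y,p)  = −Σ_j (1−p_t)^γ log p_t, where p_t is the probability assigned
  to the true class; γ ≥ 0, and FL(γ=0) ≡ CE exactly.
- D(y,p)   = 2 Σ_{k∈{helix,sheet}} (Σ_j y_jk p_jk)/(Σ_j y_jk + Σ_j p_jk),
  DL = 2 − D.  Background is excluded from D, so D ∈ [0,2]: a perfect
  foreground prediction gives each class ratio ½, hence D = 2, DL = 0.
- CE_DL = CE + DL and FL_DL = FL + DL.

Numerical choices: probabilities are clamped at ε = 1e−7 inside logarithms
(the losses are otherwise exact); a Dice class term with zero denominator
contributes 0 — no smoothing constant is added by default, to keep the
ratio form exact (a `dice_smooth` option exists, off by default).

The loss *values* default to **sums** over voxels, matching the defining
equations.  Training, however, uses the `reduction="mean"` mode, which
divides the CE/FL term by the center-box voxel count while leaving the
Dice term (a bounded, scale-free ratio) untouched.  This is a deliberate
design choice: with literal voxel sums over the ~10⁴–10⁵ voxels of a
chain-sized crop, CE and FL are three to four orders of magnitude larger
than DL ≤ 2, and the Dice term of a combined loss would be numerically
invisible — the combined losses only behave as intended (with the Dice
term of comparable or larger magnitude than CE/FL, which is also the
regime reported for this method in practice) when CE/FL are per-voxel
means.  Because Adam normalises per-parameter gradient scale, the
reduction affects only the *relative* weight of the two terms in a
combined loss, not effective learning rates of the single losses.

Because DL = 2 − D is only bounded for a single map and two
foreground classes, losses are computed per map and averaged over a batch;
in practice batch size is fixed at 1 because input volumes vary in size.

Gradients are analytic: dL/dp per loss, pushed through the softmax Jacobian
dz_k = p_k(g_k − Σ_m g_m p_m); the test suite checks all five losses
against central finite differences (step 1e−4, relative error < 1e−4) on 2³
volumes in float64.

## Network

A canonical two-level 3D U-Net with a bridge — five composite layers: two
encoder blocks (two 3³ conv + instance-norm + ReLU, then 2³ max-pool), a
bridge block, two decoder blocks (2³ transposed convolution, skip
concatenation, two conv layers), and a 1³ output convolution with channel
softmax.  All convolutions are same-padded, so output shape equals input
shape; arbitrary input sizes are zero-padded internally to divisibility by
4 and cropped back.  Instance normalisation is used because the batch size
is 1.  The receptive field, measured by support propagation through the
layer graph, is 44 voxels ≥ 35 Å at 1 Å spacing — the center box is fully
contextualised.  Default channel width is 8 at the top level (doubling per
level); the architecture is config-driven so wider or deeper variants drop
in without code changes.  Argmax ties at inference go to background
(conservative for downstream tracing).

The network, its backward pass and the Adam optimizer are implemented in
numpy: convolutions are evaluated as 27 shifted channel-matrix
multiplications (BLAS), which keeps a full training step on a 48³ volume
around one second on one CPU — ample for the package's synthetic-scale
experiments, and checked end-to-end against finite differences.

## Training protocol

Adam (default betas), batch size 1, loss masked to the center box.  The
hyperparameter grid is learning rate ∈ {1e−3, 1e−4, 1e−5} and, for the
focal losses, γ ∈ {1, 2, 5, 8}.  Model selection: after each epoch the
voxel-level helix and sheet F1 are computed per validation case, averaged
over cases (macro), then over the two classes; the best-epoch parameters
are kept, and grid search picks the cell with the best such score (ties
break toward the lower learning rate, then lower γ).  A per-class F1 that
is undefined on a validation case (class absent from both truth and
prediction) counts as 1.0 for selection — the model was right about the
absence.  Splits are seeded and stratified on a caller-supplied stratum key
(the synthetic data stratifies on a sheet-content band); strata smaller
than 3 fall back to a plain split with a warning.

## Evaluation

Per-class one-vs-rest precision/recall/F1 at two granularities, always on
the center box:

- Voxel level: predicted vs true voxel classes.
- Residue level: each center-box residue's predicted class is the plurality
  vote of predicted voxel labels whose centers lie within 3 Å of its Cα
  (vote by voxel count, not probability mass); plurality ties and empty
  spheres give background.

F1 is computed directly as 2TP/(2TP+FP+FN) and reported NA when that
denominator is zero.  Test-set aggregates are weighted averages, each case
weighted by its voxel (or residue) count for the class in question, so
sheet-free cases do not dilute the sheet score.  Residue-level F1 tends to
exceed voxel-level F1 empirically, but this is not asserted anywhere — it
is not a theorem.

## Synthetic data

Scenes are mixtures of idealised elements with canonical backbone geometry
(helix: radius 2.3 Å, rise 1.5 Å/residue, 100°/residue; sheets:
antiparallel strands, 3.3 Å rise, ±0.9 Å pleat, 4.8 Å strand spacing;
coils: self-avoiding 3.8 Å-step random walks with bend angles in
[60°, 150°]), placed with ≥ 3 Å inter-element clearance.  Element counts
are planned so realised residue fractions match the targets within ±0.05;
the default targets (helix 0.37, sheet 0.13) reproduce the class imbalance
of real chain datasets at medium resolution.  Density is a sum of
unit-amplitude Gaussians with FWHM equal to the nominal resolution
(default 8 Å) at each Cα plus consecutive-Cα midpoints (suppressing
beads-on-a-string artifacts); additive Gaussian noise at power SNR 10 is on
by default, with a noiseless mode for analytic tests.  This emulates the
shape and class statistics of real cases but none of the imaging physics —
no CTF, no B-factor falloff, no masking artifacts, no resolution
anisotropy — so passing tests demonstrate the correctness of the machinery
and the qualitative loss-function behaviour, not real-map accuracy.

## Scaled-down loss comparison

The five-loss comparison is reproduced *directionally* on synthetic data:
a seeded benchmark (10 training / 3 validation / 3 test cases of ~60
residues, sheet fraction ≈ 0.13; ~40³ volumes after a 12 Å pad), 10
epochs at learning rate 1e−3, three training seeds.  The asserted property
is the qualitative one: mean test sheet F1 under FL_DL ≥ under CE.  These
problem sizes are the package's chosen operating point for routine runs;
they are far below the ~1300-case scale at which absolute F1 values in the
50–60% range are obtained, and the absolute numbers from the synthetic
benchmark mean nothing beyond the comparison itself.  At this scale the
observed pattern is that CE is erratic on the sheet class across training
seeds (sometimes collapsing to near-zero sheet recall) while FL_DL is
consistently non-trivial — the seed-to-seed robustness, more than the mean
gap, is what the Dice term buys.

## Known limitations

- The exact composite-layer list of the reference architecture is not
  public; the U-Net here is a documented canonical stand-in with the same
  depth-of-field contract.
- The density model is geometric, not physical (see above).
- DSSP itself is not run; classes come from DSSP output files or
  per-residue annotation tables.
- Quality-bin stratification of real datasets is abstracted to a generic
  stratum key; helix-cylindricity scoring is out of scope.
- No GPU path; the numpy implementation targets chain-sized subregions,
  not whole maps.
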
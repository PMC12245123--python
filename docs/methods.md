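# Methods

`sersquant` implements the computational path of a dual-response SERS
(surface-enhanced Raman scattering) assay for glioma surgery: a gold-nanostar
probe whose reporter spectrum responds ratiometrically to reduced glutathione
(GSH, mM range) and hydrogen peroxide (H2O2, uM range), read out either
through peak-ratio calibration curves or through a convolutional regression
network, and finally through a two-step logistic classifier that calls each
sampled tissue point normal brain, IDH1-wild-type glioma, or IDH1-mutant
glioma.

## Spectral model and synthetic data

A probe spectrum is modeled as a sum of Lorentzian bands on a 400-1800 cm^-1
axis (2 cm^-1 spacing by default, 701 points).  Band assignments follow the
reporter chemistry: 542, 806, and 1023 cm^-1 rise with GSH; 628, 801, 1164,
1426, and 1617 cm^-1 fall with H2O2; 928 cm^-1 is analyte-invariant and is
the internal reference.  Responses are affine in concentration,

    A_up(c)   = A0 * (1 + k_g * c_GSH)          k_g = 0.30 / mM
    A_down(c) = A0 * max(f, 1 - k_h * c_H2O2)   k_h = 0.004 / uM, f = 0.05

so the GSH channel is linear over the validated 0.5-20 mM range and the H2O2
channel is linear over 5-200 uM with a non-negative floor far below the
calibration range.  The default amplitudes (0.20 at 542, 1.20 at 628, 1.00
at 928 cm^-1, FWHM 8 cm^-1 for all bands) were chosen so that the noiseless
peak ratios span the physiological ranges monotonically; they are simulator
parameters, not measurements of the real probe.  The H2O2 response form is
pluggable because the empirical decay shape (linear vs saturating) is not
fixed by the assay.

Noise is additive Gaussian (default SD 1% of the reference-band height) plus
a per-acquisition random quadratic baseline (coefficients uniform in
[0, 0.03]).  This is deliberately mild but non-trivial: it is what makes the
ratiometric reference correction and the network's denoising matter.
Negative intensities are clipped to zero, which slightly biases averages
where the clean signal is near zero; tests of replicate-averaging
convergence therefore exclude the near-zero region.

What the simulator does *not* model: electromagnetic enhancement physics,
probe uptake kinetics, tissue autofluorescence beyond a smooth baseline,
cosmic rays, axis miscalibration, and inter-batch instrument drift.  Passing
tests on synthetic data therefore demonstrate the correctness and internal
consistency of the computational pipeline, not the field performance of the
physical probe.

The calibration study design is 6 GSH levels {2,4,6,8,10,16} mM x 8 H2O2
levels {1,25,50,75,100,125,150,200} uM x 200 replicates = 9600 spectra.
Simulated tissue cohorts draw per-point concentrations from zero-truncated
normals with the reported in vivo statistics: GSH 12.08 +/- 0.53 mM (WT
tumor), 9.20 +/- 0.83 mM (MUT tumor), < 1 mM in normal brain (we use
0.8 +/- 0.15 mM); H2O2 68.54 +/- 4.51 uM (WT) and 109.3 +/- 9.44 uM (MUT).
Normal-brain H2O2 is not reported; we default to a low physiological
30 +/- 8 uM, which only affects the (easy) tumor-vs-normal stage.

## Preprocessing

The quantification protocol keeps points 50-336 (1-based, inclusive; 287
points) of the raw instrument axis and divides each spectrum by its maximum.
Both operations are exposed and parameterized; cropping composes and
max-normalization is idempotent and scale-invariant.  Dataset splitting
holds out 20% for test and divides the rest 9:1 train:val, with round-half-
even sizing and, when concentration labels are present, stratification per
(GSH, H2O2) cell via largest-remainder allocation so every cell appears in
every part.  A flag disables stratification since the original protocol does
not state it.

## Relative Position Matrix

A preprocessed spectrum x of length M maps to RPM[i,j] = x_i - x_j, an M x M
antisymmetric image with zero diagonal, invariant to constant offsets and
homogeneous of degree 1.  RPM is computed after crop + max-normalization
(the stated preprocessing order); the reverse order is testable through the
same API since both operations act on plain spectra.  RPM values are left
signed — no rescaling into [0,1] — and the network's first batch-norm layer
absorbs the scale.

## DBCNet and baselines

All models run on a small numpy layer library written for this package
(im2col convolutions, batch normalization, residual blocks, max/avg pooling,
Nadam) with exact hand-derived backward passes verified against central
finite differences.  Label vectors are scaled to comparable ranges (GSH in
mM, H2O2 in units of 10 uM) before the MAE loss so neither task dominates.

DBCNet = shared 2D residual backbone -> per-spectrum feature -> two
metabolite branches, each `Linear -> ReLU -> batch correlation -> Linear(1)`.
Batch correlation replaces each feature row F_i by a convex combination
`sum_k a_k F_k` with `a_k = softmax_k(sim(F_i, F_k) / tau)` over the
mini-batch, `sim` = cosine similarity (a sum-normalized positive-similarity
variant is selectable; the softmax form with the self term included is the
default).  Two numerical choices matter:

* temperature `tau`: post-ReLU features are non-negative, so their cosine
  similarities crowd into a narrow band near 1.  At `tau = 1` the weights are
  nearly uniform and every feature collapses toward the batch mean, which
  destroys per-sample regression.  The model default is `tau = 0.02`, below
  the typical similarity gap, so each feature mixes only with genuinely
  similar spectra (in practice: replicates and near-neighbors in
  concentration).  The functional `batch_correlation` op keeps `tau = 1` as
  its neutral default.
* inference mode: per-sample inference (the default) replicates the sample's
  own weight — batch correlation degenerates to the identity — so a clinical
  prediction never depends on unrelated co-batched spectra.  Cohort mode
  applies true batch statistics, matching training; it is the right mode
  when replicate or neighboring acquisitions are naturally batched (scan
  points of one specimen, replicate measurements of one solution) and is
  what the model-comparison checks use, since per-sample mode switches the
  compared mechanism off.

The 2D baseline is the same backbone with a single two-output linear head
and no batch correlation; the 1D baseline applies the analogous residual
Conv1d stack to the raw preprocessed spectra.  The full 18-layer topology
(7x7/2 stem, max-pool, four 2-block stages to 512 features) is available as
`backbone="paper_resnet18"`; the first-class desk-scale `reduced` backbone is
2x2 average pooling, a 5x5/4 stem (8 channels), one 8-channel residual
block, one strided 8->16 block, and global average pooling (16 features,
~5.7k parameters).  Regression heads are initialized at the mean scaled
training label so early epochs refine structure rather than walking the
output range.

The reference training protocol is Nadam, initial learning rate 1e-3,
MAE loss, batch size 32, learning-rate reduction on validation plateau
(patience 25, factor 0.1), early stopping (patience 30), best-validation
weights restored.  The full protocol runs 400 epochs; desk-scale runs cap
epochs at 60 (parameter recovery) or 120 (model comparison), sizes chosen so
the whole pipeline runs comfortably on a single CPU.  One integer seed
drives splitting, initialization, and batch order; numpy's single-threaded
kernels make runs bit-reproducible per seed.

## Ratiometric quantification

Peak intensity is the baseline-subtracted window maximum: within
center +/- 6 cm^-1 a straight line through the window's endpoint samples is
removed and the maximum of the residual taken.  With equal band widths the
three extracted intensities share the same shape factor, so the ratios
r1 = I542/I928 and r2 = I628/I928 equal the underlying amplitude ratios up
to tail cross-talk below 0.1%.  The +/- 6 cm^-1 default keeps the linear
baseline a good local model of neighboring-band tails; wider windows admit
more tail curvature.

Calibration fits an ordinary least-squares line ratio = a + b*c per channel
from single-analyte sweeps, enforcing b > 0 for GSH and b < 0 for H2O2
(a wrong sign signals a channel mix-up), and stores the concentration range
as validity bounds.  Quantification inverts the line; negative inversions
are clipped to zero and flagged, as is extrapolation beyond the bounds.
Concentration maps place per-point quantifications on the scan grid with an
H2O2/GSH layer computed from the quantified concentrations (uM/mM); a
raw-ratio mode (r2/r1) exists for sensitivity analysis.  Missing or
reference-failed points are masked in all layers.

## Two-step genotyping

Stage 1 is a logistic regression of tumor-vs-normal on r1 (GSH is elevated
in glioma); stage 2, fitted on tumor points only, separates MUT from WT on
r2 (the "ratios" recipe) or on the quantified H2O2/GSH ratio (the patient-
style recipe).  Fits are maximum likelihood; under (quasi-)perfect
separation — the expected situation for the well-separated cohorts — the fit
falls back to a documented L2-regularized estimate and the bundle carries a
separation flag.  The decision threshold is 0.5 per stage, ties resolving
toward tumor (sensitivity first); a Youden-optimal threshold is offered.
ROC curves are full threshold sweeps whose AUC equals the Mann-Whitney
statistic with ties counted half, confusion matrices report truth rows vs
call columns with per-class predictive values, and a one-step multinomial
variant exists for comparison.

## Known limitations

* The desk-scale network results quantify the pipeline on synthetic data;
  absolute errors on instrument data will differ.
* The batch-correlation weight normalization is implemented in two candidate
  forms; neither is asserted to be the original formulation, whose printed
  form is not machine-readable.
* The model comparison at desk scale shows DBCNet and the 2D baseline within
  a few percent of each other; the comparison checks direction (not worse),
  not large improvement percentages, which would require the full-scale
  instrument database.
* Logistic fits on fully separated cohorts are reported through the
  regularized fallback; coefficients are then shrinkage estimates, though
  calls and AUCs are unaffected.
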
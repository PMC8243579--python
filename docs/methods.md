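# Methods

This note documents the models, conventions and design choices behind
`iegkin`, and what the synthetic-data tests do and do not establish about
real data.

## Expression model

Activation of an immediate-early gene is modelled as a bolus of mRNA at the
triggering event followed by consecutive first-order synthesis and
degradation (mRNA →k_f protein →k_d degraded protein), with fluorescence
proportional to protein.  The unique solution of the coupled ODEs is

    F1(t) = A · k_f/(k_f − k_d) · (e^{−k_d t} − e^{−k_f t}),

and the double-activation profile superposes a second, identically
parameterised event at t_d: F2(t) = F1(t) + [t ≥ t_d]·F1(t − t_d).  The
shared amplitude and rates reflect that a single cell's translation and
degradation machinery does not change between two exposures an hour apart,
and keep the double-activation fit at four parameters.

Conventions:

- Time is laboratory time in minutes, t = 0 at the session's first
  triggering event.  "Delayed" fits shift the origin (t → t − 60 by
  default) instead of adding parameters.
- Fluorescence is background-referenced detector units (D.U.), so
  F1(0) = 0 and no offset parameter exists in the model.
- Equal rates: |k_f − k_d| < 1e−9·max(k_f, k_d) switches evaluation to the
  analytic limit A·k·t·e^{−kt}, avoiding catastrophic cancellation.
- Rate-swap aliasing: F1 is invariant under (k_f, k_d) → (k_d, k_f) with
  A → A·k_f/k_d.  Fits report the k_f ≥ k_d branch (formation faster than
  degradation, as in every observed cell for these constructs).
- Derived quantities: T_max = ln(k_f/k_d)/(k_f − k_d) (1/k in the limit),
  rise time 1/k_f, decay time 1/k_d.

## Fitting and model selection

Fits are unweighted least squares.  Because the amplitude enters linearly,
the optimiser works on (log k_f, log k_d[, t_d]) with A solved in closed
form at every step (variable projection), followed by a full-parameter
Levenberg–Marquardt-class refinement that supplies the covariance-based
standard errors.  Starting values follow the published protocol
(k_f = 0.01, k_d = 0.001 min⁻¹, t_d = 60 min, A at the maximum observed
fluorescence — subsumed by the closed-form amplitude); five additional
deterministic rate starts spanning the observed range
(0.0369/0.016, 0.04/0.006, 0.1/0.02, 0.3/0.05, 0.005/0.003 min⁻¹) guard
against the local minima that a single start falls into when the imaging
window begins after the expression peak (on the 90–300 min session, the
single-start fit of a zero-delay profile can converge 5 orders of magnitude
above the global optimum).  t_d starts only at the configured exposure
delay — it encodes the known experiment structure, not a free search — and
is bounded to [0, last time point]; rates are bounded below by 1e−6 min⁻¹.

If the optimum collapses to |k_f − k_d|/max < 1e−4, the two-parameter
equal-rate limit model is refitted and reported with a shared-rate flag
(the practical analogue of the evaluation-level degeneracy tolerance; such
cells exist in real data and are kept, with their common k, in population
histograms — excluding them truncates the slow-k_f tail and biases the
histogram mean upward by ~0.001 min⁻¹ in the simulated populations).

Goodness of fit is the adjusted R², 1 − (RSS/(n−p−1))/(TSS/(n−1)); a cell
is "activated" when a converged candidate reaches adj R² ≥ 0.5.  Candidates
are compared by the least-squares AIC, n·ln(RSS/n) + 2(p+1), counting the
noise variance as a parameter; only AIC differences matter and all
candidates of a trace share n.  Ties within 1e−6 go to the model with fewer
parameters.  Non-convergence is a recorded outcome, not an exception, so
population fractions can count it.

## Sessions, flags and categories

IS1 (20–180 min every 10 min, one exposure at t = 0) arbitrates
{single, double}; IS2 (90–300 min, exposures at 0 and 60 min) arbitrates
{single at 0, single delayed to 60, double with t_d ≈ 60} jointly, so a
cell is never simultaneously counted as a context-A and context-B single
activation.  The winner sets the flags (a1, a2, b) = (A in IS1, A in IS2,
B), which map bijectively onto the eight categories.  A double activation
in the single-exposure session flags only a1 (context plus spontaneous
event) and is noted in a diagnostics column.

Ensemble statistics: overlap fractions are emitted normalised both to all
ROIs and to the per-session activated subsets (the two conventions are both
in circulation; the keys say which is which).  Chance overlap is the product
of the two per-context fractions.  The double-activation fraction
comparison uses a one-tailed Welch t test over per-replicate (per-animal)
fractions; replicate labels are caller-supplied.  Reactivation probability
bins IS1-activated cells by fitted amplitude in half-open 500 D.U. bins and
reports n_fit/n_bin per bin, the Pearson correlation of bin centre vs
probability, and the slope of adj R² vs amplitude as the amplitude-bias
control.

## Population histograms

Fitted k_f, k_d and per-cell T_max are histogrammed in uniform bins from 0
(defaults 0.005, 0.002 min⁻¹ and 5 min — chosen to give ~10–20 retained bins
at populations of several hundred cells, and configurable); bins with
counts > 10 are retained.  One- and two-Gaussian curves are least-squares
fitted to the retained (centre, count) pairs and compared by AIC.  With
only ~10 bins the plain least-squares AIC lets the second component chase
Poisson count noise (unimodal samples were called bimodal two times out of
three), so the comparison uses the small-sample corrected penalty (AICc)
whenever its denominator n − k − 1 is positive for the richer candidate and
falls back to the plain penalty below that; measured on simulated
populations this selects one component on unimodal samples in 94/100 seeds
and two components on well-separated bimodal samples in 100/100.  The
histogram mean of per-cell T_max and the closed-form T_max evaluated at the
mean rates are different quantities; both are reported, labelled.

## Synthetic data

The generators define the study conditions the tests run under:

- Sampling: IS1 = 20–180 min, IS2 = 90–300 min, 10-min intervals.
- Rates: per-cell k_f ~ N(0.0369, 0.01) min⁻¹ truncated positive (centre
  from the fitted cfos-shGFP population; the SD is the cell-to-cell spread,
  not the ±4e−4 standard error of the population-mean estimate), k_d ~
  N(0.016, 0.002) min⁻¹ (the faster decay component with its printed ±).
- Amplitudes uniform on 500–5000 D.U., the scale of observed cells.
- Noise: multiplicative Gaussian, 5 % of the instantaneous signal, plus a
  2 D.U. additive floor (the detector noise statistics of the original
  instrument are not known; this stand-in keeps adj R² of true fits well
  above 0.5 and is configurable, with additive-Gaussian and Poisson
  alternatives).  Inactive cells yield floor noise around zero.
- Dual-session datasets take an exact category mix (largest-remainder
  apportionment) and draw one (A, k_f, k_d) per cell used in both sessions;
  the second exposure is 60 min after the first.

Image stacks render each nucleus as a 3D Gaussian blob.  The lateral sigma
is diameter/4.71, so the visibly bright region (above ~6 % of peak) spans
about one nominal diameter (~20 px); a full-width-half-maximum equal to the
diameter would spill ~18 % of the peak into the background annulus and make
the scene unreadable at the stated geometry.  The blob peak is calibrated
so the mean over the discrete ROI footprint at the central slice equals
baseline + model value — the quantity the extraction workflow reads out.
Nuclei sit on a jittered lattice (somata do not interpenetrate); a rigid
per-time-point lateral jitter emulates inter-time-point misalignment.  The
per-cell resting baseline (default 50 D.U.) stays in the rendered scene, so
extracted traces of rendered cells carry it; trace-level generators produce
background-referenced values directly.  Not emulated: scattering,
depth-dependent attenuation, motion blur within a frame, cross-day
vasculature registration.

## Extraction

Per time point: (1) re-centre the ROI on the intensity centre of mass of
the window-median-subtracted maximum-intensity projection around the old
centre (coordinates shift; images are never resampled), displacement capped
at the search radius (default: the ROI radius); (2) average the circular
footprint (voxel centres strictly within the radius, 0-based indices,
lateral only) per z slice; (3) fit offset + Gaussian to the z profile and
take offset + height as the activity (fewer than 5 slices, or optimiser
failure, falls back to the profile maximum, flagged); (4) subtract the
median of the annulus 1–2 radii out on the ROI's slice (or the global stack
median, per config).  The Gaussian offset plus annulus subtraction makes
the readout invariant to constant offsets and linear in the signal.  A
knife-edge exists for blobs centred exactly on a pixel with an integer
radius: footprint membership of boundary pixels can flip under infinitesimal
re-centering; generator scenes use sub-pixel centres, where fidelity is
~0.3 % (2 % bound in tests).

## Known limitations

- **Late-window identifiability.**  On the 90–300 min session, a delayed
  single activation reproduces a double activation (t_d = 60) to within
  ~4 % of the 5 %-noise residual floor, and the free t_d can absorb the
  large early-point residuals that unweighted least squares leaves under
  multiplicative noise.  Measured consequences at the default conditions:
  two-way single/double discrimination is ~68 % / ~92 % (single/double
  truth), and end-to-end category recovery is ~74 %, with confusions almost
  exclusively between the category pairs that differ only in the
  double-vs-delayed-single reading (all-contexts ↔ A1+B, A2+B ↔ B-only).
  The same discrimination on the 20–180 min window, where the peak is
  sampled, is 99–100 %.  1/σ²-weighted fitting raises the late-window
  two-way rates to ~87 / 88 % but is not the default (the published
  protocol is unweighted).  Conclusions that hinge on separating double
  activations from delayed singles in late-sampled sessions should be
  treated as probabilistic, not per-cell certainties.
- Passing synthetic tests shows the chain is self-consistent under the
  stated noise model and geometry; real detector noise, optical artefacts
  and segmentation errors are outside the emulation.
- At most two activation events per session; two imaging sessions; one
  IEG reporter.
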
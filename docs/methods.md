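# Methods

This note documents the models, defaults and design choices behind
`srmquant`, and what its simulation-based validation does and does not show.

## Signal model and synthetic batches

Each fragment transition of a compound is simulated as a Gaussian peak on a
uniform time grid covering a 12-minute run sampled every 0.5 s (1441 points;
a ±4σ window around a σ = 0.05 min peak holds ~60 points):

    I_k(t) = G · m · r_k · s · exp(−(t − t_R)² / 2σ²) + b + ε(t)

* `m` — on-column amount (fmol), from the extraction chain
  `conc[pM] · volume[mL] · efficiency · injection/resuspension`
  (pM·mL is exactly fmol, so the arithmetic is unit-exact).
* `G` — response gain, 1000 intensity units per fmol. No real instrument is
  reproduced; only linearity of response matters, and the gain cancels in
  calibration. The value is arbitrary and documented as such.
* `r_k` — fragment relative intensities (strictly positive, summing to 1).
* `ε(t)` — i.i.d. zero-mean Gaussian per point (default SD 5 intensity
  units) on a constant baseline `b` (default 20). This is the simplest model
  that supports S/N estimation and blank-based LOD machinery; counting
  (Poisson) noise is deliberately not modelled.
* `s` — optional multiplicative amplitude jitter: a common-mode factor per
  injection (`injection_cv`, emulating injection-volume variability, the
  component an internal standard can cancel) times an independent factor per
  injection×compound (`area_noise_cv`, "area noise"). Both default to 0.

The heavy ¹³C-B1 internal standard co-elutes exactly with B1 (isotope labels
do not shift retention). All m/z and retention-time constants in
`make_default_panel` are invented, mutually distinct fixture values; real
transition lists can be supplied as panel CSVs.

A batch (`simulate_batch`) injects every designed sample in duplicate
(configurable), runs a standard-addition series on each QC pool — spike
levels 0/25/50/250 fmol on column, 0/5/10/50 for HET, duplicate injections
per level — and logs a ground-truth ledger (true fmol, added fmol per
injection×compound). All randomness flows from one `numpy` generator seeded
by the batch seed, so identical designs are byte-identical.

QC pools mix equal portions of samples of one matrix group; the pool's vial
concentration per compound is the arithmetic mean of the members'
post-extraction vial concentrations.

## Integration and transition selection

Baseline: linear interpolation between the window-edge intensities —
parameter-free and standard for targeted assays. Area: trapezoidal rule on
the baseline-corrected residual; negative integrals clamp to 0 so amounts
stay non-negative. The default window half-width of 0.2 min mirrors the
retention-time tolerance of the sub-LOQ rule.

S/N is the baseline-corrected apex over a robust noise estimate, 1.4826 ×
the MAD of out-of-window intensities about their median (robust to peak
leakage into the noise region); a zero noise estimate returns `inf`.

Quantifier selection scores each fragment as
`mean S/N ÷ (1 + interference)`, where interference is the mean blank area
divided by the mean area of the lowest non-zero calibration level; ties
break toward the lower fragment index, and without blanks the score degrades
to S/N only (warned). The top fragment quantifies; all fragments remain for
identity checks.

## Calibration

Standard addition is fit by unweighted OLS of response on added amount
(duplicates as individual points, preserving residual degrees of freedom);
`1/x` weighting is available by argument. The calibration matrix's
endogenous amount is `intercept/slope`, clamped at 0 (noise can produce
slightly negative intercepts); a non-positive slope flags the curve invalid
and quantification refuses it.

Sample conversion uses the slope only (`area/slope`): the pool's endogenous
level is a property of the pool, not the sample. Whether the original
workflow subtracted a blank response before applying curves is not
documented anywhere recoverable, so a blank-subtraction mode is provided as
an explicit argument and the choice is visible in results.

IS normalization is decided empirically per compound from ≥3 QC-pool
replicate injections: adopt the area/IS ratio only if its RSD is strictly
smaller than the raw-area RSD. A 1e-9 relative guard keeps the
constant-divisor case (mathematically equal RSDs) from flipping on
floating-point rounding. Under simulated ±10% common-mode injection jitter
plus 2% independent noise, normalization is adopted in ≥95/100 replicates;
with independent-only noise it is declined, matching the behaviour expected
of compounds that do not share the internal standard's variability.

## Detection and recovery

LOD/LOQ use the blank-based guideline formulas `mean + 3·SD` and
`mean + 10·SD` over ≥3 blank determinations, converted to in-sample
concentration through the volume chain. The variant actually used by any
given lab differs; a calibration-residual alternative (3·residual SD/slope)
can be swapped in by computing thresholds from curve residuals instead.

The sub-LOQ rule accepts a peak only when all four criteria hold:
retention-time match to the authentic standard (anchored on the standard's
most intense fragment, ±0.2 min), ≥2 fragments with co-occurring apexes,
fragment intensity order matching the standard, and summed area ≥ 2× the
mean blank. With exactly two near-equal fragments the order criterion is
ambiguous; areas within 5% relative are treated as order-compatible. The
"authentic standard" reference in the pipeline is the mean of the top
calibration level's fragments.

Recovery is `100 · (measured_spiked − endogenous) / spike` from
concentration-matched spiked/unspiked pairs, per compound and matrix group;
values outside [10%, 150%] are flagged suspect (an artifact QC bound, not a
literature one). Where no pair exists a recovery may be asserted (e.g. the
~50% rate consistently observed for FAMP across C18 SPE methods) via
`assert_recovery`, which flags the estimate as asserted. All reported
concentrations are corrected as `conc · 100 / recovery`. Detection status is
classified on the corrected concentration by default (the reported tables
carry nd/nq on corrected values); a switch classifies on the uncorrected
scale instead.

Replicate injections are averaged on the amount scale, after calibration,
because responses may be IS-normalized and areas are then not directly
averageable.

## Reporting

Summaries print mean ± sample SD at 2 significant figures; the SD is
withheld when fewer than three independent replicates exist (technical
duplicates of one sample give a mean only). The dissolved-phase mass balance
is spent-medium mean minus blank mean. Uncertainty propagation defaults to
quadrature (√(s₁²+s₂²), correct for independent errors); a summed mode
(s₁+s₂) is also provided because the published culture budget's printed
"18 ± 11" corresponds to 9.8 + 1.6 = 11.4 rather than √(9.8²+1.6²) = 9.9 —
the golden display test therefore uses sum mode, and the discrepancy is
deliberate and documented here. The HMP budget row is excluded from golden
tests: the printed −0.56 can only arise from differencing unrounded means,
which are not recoverable from the rounded table.

## Validation studies and their limits

`srmquant.validation` runs the self-checks used by the test suite and the
acceptance script:

* **Recovery inversion** — noise-free spiked/unspiked pairs at simulated
  efficiencies 0.25/0.5/1.0 must measure back 25/50/100% within numerical
  integration error (<1%).
* **Parameter recovery** — 50 seeded batches, FAMP ladder 5/20/100/500 pM,
  efficiency 0.5, 5% area noise, recovery measured in-batch from a 400 pM
  spike pair; median absolute relative bias of the corrected concentration
  stays below 10% at every level above LOQ (observed ≈3%). Problem sizes
  (50 seeds, 4 levels, duplicate injections, 3 blanks) were chosen as a
  realistic desk-scale study; the study is the package's own calibration
  check, not a reproduction of any field dataset.

Passing these shows the pipeline inverts its own signal model without bias
under the stated noise. It does not show robustness to features the
generator omits: ion suppression and matrix-effect drift, asymmetric or
tailing peaks, co-eluting isomer interference, retention-time drift across
batches, or Poisson counting noise at very low signal. Field concentrations
(e.g. the seawater survey values) derive from real extracts and are not
reproducible by simulation; only the printed summary tables feed the
mass-balance checks.

## Degenerate inputs and tie-breaks

Zero amounts give flat (noise-only) traces; all-zero responses give an
invalid curve; zero-noise S/N returns `inf` (handled in selection by falling
back to the fragment-index tie-break); below-blank responses clamp to 0 fmol
and are flagged; blank means that drive LOD/LOQ negative clamp to 0; pooling
zero samples or mixed matrix groups is an error; injecting more than the
resuspension volume is an error.
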
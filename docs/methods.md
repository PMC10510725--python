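# Methods

## Scope and model

The package analyses methylation-dependent silencing of synthetic
promoters in a recruitment reporter system.  The core kinetic model is
single-step stochastic switching: while the methyltransferase is
recruited (the dox window), each cell's promoter transitions from
active to silent at a constant per-day hazard β, irreversibly, so the
active fraction decays as A(t) = exp(−β·t).  β is allowed to depend on
the promoter's CpG density c.  Cell proliferation needs no explicit
term because the expression state is heritable.

CpG density is defined as the percentage of bases participating in CG
dinucleotides, c = 100·2·#CG/length.  This "bases-in-CpG" convention is
a package-level definition, stated prominently because published
density figures do not always specify their formula.  Coordinates are
1-based on the forward strand of the supplied sequence; only
forward-strand CG occurrences are counted (CpG is its own reverse
complement, so one strand suffices).  CpGs are named `CpG<position>`.
Positions quoted against other references (plasmid maps) must be
re-anchored to the supplied sequence by the user.

## Synthetic data generator

The generator replaces raw cytometry and enzymatic
methylation-sequencing data with draws from the mechanisms the analysis
is meant to measure.  It is first-class, tested code, not a fixture.

**Flow channel.**  Each cell draws a silencing time
t_s = dox_start + Exp(1/β); cells with t_s past the end of the dox
window never silence.  Active cells emit fluorescence exp(N(μ_a, σ_a)).
A silenced cell's log-mean declines by ln 2 per division
(division time 22 h, i.e. (24/22)·ln 2 per day) from μ_a, floored at an
autofluorescence distribution 200-fold below the active mean.  Dilution
acts deterministically on the log-mean rather than via explicit
division events; cell-cycle asynchrony is absorbed into the silenced
peak's spread (a free parameter, defaulting to σ_a) because only the
population histogram matters downstream.  A configurable
background-silenced fraction (default 2% in pipeline runs) is present
in *both* arms: these are pre-existing silenced cells in the clonal
population, and having them in both arms is exactly what the
(S₊ − S₋)/(1 − S₋) normalization corrects; modelling them only in the
no-dox control would bias the corrected fraction.  Defaults:
μ_a = 9.2, σ_a = 0.20 (putting the μ−2σ gate at ≈66% of the mean,
inside the 54–71% band typical of tight single-peaked controls).

Randomness is keyed per sample by (seed, promoter, condition,
replicate, dox window, measurement time), so regenerating any one
sample never perturbs the others.  The silencing-fate stream is keyed
by the dox window but *not* the measurement time: re-measuring the same
induction after more release days reuses the identical
committed-silenced cells (irreversibility holds exactly, and the
silenced fraction is constant after release), while different induction
durations draw independent fates, modelling destructive flow
measurements of separate aliquots from a much larger culture.  This
independence matters statistically: it is what makes the regression
errors across timepoints independent, so the reported slope standard
error is meaningful.

The generator does not model: a commitment lag after dox removal (the
0–2 day transient), hazard persisting past the window, compensation or
multi-channel artefacts, instrument noise beyond the log-normal widths,
or any mechanistic coupling between the methylation channel and the
silencing hazard (reported as empirically decoupled in this class of
system).

**Methylation channel.**  For each sorted sample (group, day) and CpG
i, the per-read methylation probability is p_i = 1 − exp(−h_i·day) with
per-site, per-day hazard h_i; counts are Binomial(n_reads, p_i).  An
optional capacity C rescales the p_i multiplicatively whenever
Σ p_i > C, capping the expected number of methylated CpGs per promoter
— a minimal representation of saturating methylation capacity at the
locus (an alternative neighbour-inhibition mechanism is not modelled).
A "master" CpG can be given extra hazard applied only in
recently-silenced samples, planting a known differential signal.
Defaults chosen once as a realistic pooled design: base hazard
0.02 d⁻¹, 500 reads per CpG, 10 still-ON samples at days 3–30 and 6
recently-silenced samples at days 5–30, master extra hazard 0.2 d⁻¹.
No read-level simulation (no FASTQ, conversion errors, or alignment) is
attempted; the unit of output is the cytosine-report-style count table.

## Gating

The silencing gate is fitted on the matched no-dox control: a normal
distribution on log-fluorescence of the positive population, isolated
by iterative trimming at ±3 fitted SDs (converged when μ and σ move by
< 1e−6, at most 10 iterations, at least 50 events).  Trimming a normal
at ±cσ shrinks the sample SD by sqrt(1 − 2cφ(c)/(2Φ(c)−1)) (≈0.9866 at
c = 3); the fit divides by this truncated-normal consistency factor at
every iteration, so the converged σ is unbiased for a clean log-normal
control.  Without the correction the gate would sit at ≈ μ − 1.97σ and
the control's own below-gate fraction would exceed Φ(−2) by ~8%
relative — enough to distort background subtraction at low silenced
fractions.  The trim-based definition of "positive population" avoids
any free autofluorescence threshold; it assumes the control is single
peaked, and a contaminating sub-population ≳ a few log-SDs below the
peak (e.g. 5% of events 100-fold lower) is excluded after the first
iteration.  Identical inputs (σ below 1e−9) raise a degenerate-
distribution error rather than returning a zero-width gate.

Two gate modes share one fitted (μ, σ): `lognormal_2sigma` counts
events strictly below exp(μ − 2σ); `reduction_90` counts events below
0.1·exp(μ + σ²/2) (10% of the fitted arithmetic mean).  Ties at the
threshold count as not silenced; at flow sample sizes this affects at
most a handful of events.

## Normalization, empirical rates, and β fitting

The corrected silenced fraction is (S₊ − S₋)/(1 − S₋): background
subtraction plus renormalization by the fraction still available for
silencing.  Values are clamped to [0, 1]; negatives (control noisier
than sample) are logged before clamping.  Error bars come from the
pairwise bootstrap: each with-recruitment replicate normalized to each
control replicate (3×3 → 9 points), summarized by the sample SD
(ddof = 1; defined as 0 for a single point).

The empirical, model-free rate between neighbouring timepoints is
ΔS/(Δt·(1 − S_earlier)), the discrete analogue of the hazard
−ΔA/(Δt·A).  Using the earlier point's remaining fraction makes the
estimator the forward-difference hazard; at Δt = 1 d and β = 0.1 d⁻¹
it reads 1 − e^(−0.1) ≈ 0.0952, a known ~5% discretization bias that
vanishes as Δt → 0.  Pairs in which either fraction exceeds 80%
(configurable) are omitted — the conservative reading of the omission
rule — because the normalizing remaining fraction is too small.

β is the negative slope of the OLS regression of ln A(t) on t, with an
intercept (the measured t = 0 fraction need not be exactly 0 after
normalization; exclusion of t = 0 is opt-in for protocols without a
release phase before the first measurement).  Points with A ≤ 0 (no
active cells left) are dropped with a warning; the floor is
configurable.  The reported slope standard error is the larger of the
classical residual-based estimate and the HC3 heteroscedasticity-robust
estimate: counting noise in ln A grows as A shrinks, so the late, most
informative points are also the noisiest and carry high leverage, which
makes the classical SE anti-conservative, while HC3 alone is unstable
at ~10 points.  The conservative combination keeps the ±3·SE interval
honest (measured coverage 95–100% per 100 replicates across the
practical β range 0.032–0.274 d⁻¹ at 10,000 cells and 10 timepoints).
Weighted fits were considered and rejected: the binomial variance model
ignores gating-estimation noise, and misweighted WLS degraded coverage
at the low-β end.  Two fitted rates are compared by a Wald z-test,
z = (β₁ − β₂)/√(SE₁² + SE₂²), against the normal reference.

## Methylation statistics

Accumulation metrics per sample: methylation frequency
(Σ methylated / Σ total reads across CpGs, i.e. coverage-weighted),
expected methylated CpGs per promoter (frequency × N_CpG; "total
methylation" is interpreted as this expected count), and total per bp
(total / promoter length).  A zero-coverage sample yields NaN metrics
and a flag, never a silent drop.

The differential screen pools samples across days, exactly as in a
pooled FACS-sequencing design, and treats each sample's per-CpG
methylation percentage as the unit of analysis (coverage-weighted
within a sample, equal-weighted across samples).  Groups are compared
per CpG with a two-sided pooled-variance Student t-test; zero-coverage
samples are excluded per CpG, and a CpG whose group size falls below 2
is reported untestable rather than given a fabricated p.  Identical
constant groups return t = 0, p = 1.  Benjamini–Hochberg q-values are
computed and reported, but master-CpG selection uses raw p < α
(α = 0.05 by default) so that users can apply either rule.  Note the
calibration caveat: p-values are uniform under the null only when the
two groups' day designs are exchangeable; the pooled 10-vs-6 multi-day
default plan is deliberately not day-balanced (it mirrors the sorted
experimental design), so its per-CpG nulls are near-uniform only to the
extent the day profiles match.

## Pipeline and problem sizes

The pipeline default protocol induces for t days, releases for 2 days,
and measures at t + 2, for t ∈ {1, 3, …, 19}; 10,000 cells per sample,
3 sample and 3 control replicates, β assigned per promoter either
explicitly or by the linear law β = slope·c (default slope
0.0076 d⁻¹ per percent density, spanning ≈0.06–0.27 d⁻¹ over the 8–36%
library).  These sizes keep every analysis comfortably inside a
single-CPU run of seconds to a few minutes while leaving counting noise
visible; they are the sizes quoted for all coverage statements above.
Runs are deterministic: identical config and seed give byte-identical
reports.

## Known limitations

Synthetic promoters from `random_promoter` place CG dinucleotides on an
A/T backbone, so their base composition is unrealistic even though CpG
placement and density are exact; analyses here depend only on the
latter.  The flow model has no doublets, debris, or autofluorescence
tail into the active peak, so gating on real FCS-derived event tables
will be harder than on simulated ones.  Passing the parameter-recovery
and calibration tests demonstrates correctness of the estimators under
the stated generative model, not robustness to instrument artefacts.
The density→β law is a simulation input, not a fitted biological claim.
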
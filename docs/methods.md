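# Methods

## The measurement and the model

A circular plasmid incubated with a radionuclide accumulates single-strand
breaks (SSB) and double-strand breaks (DSB). The assay reads out only the
conformation of each molecule: supercoiled (no damage), open circular (≥1
SSB, no DSB) or linear (≥1 DSB). Both break types are modelled as
independent Poisson counts per plasmid with means X_SSB and X_DSB, giving
the forward map

    F_L  = 1 − e^(−X_DSB),   F_SC = e^(−(X_SSB + X_DSB)),   F_OC = rest.

The package implements its inverse as the primary estimators:
X_SSB = ln((1−F_L)/F_SC), which is exact under the model, and
X_DSB = F_L/(1−F_L), which is the first-order expansion of the exact
inverse −ln(1−F_L). The first-order form is kept as the primary estimator
because the assay's published yield tables are computed with it; the exact
form (`exact_poisson_dsb`) is available and documented — it is always the
smaller of the two, by e^X − 1 − X ≈ X²/2 relative to the mean, about 6%
at F_L = 0.23 — but it is never substituted silently.

## Decay normalisation

Per-decay yields divide the per-plasmid means by the decays each plasmid
experiences: d = D_total/N_plasmid with
D_total = (A₀/λ)(1 − e^(−λT)) and N_plasmid = m·N_A/(L·M_bp). Activities
are accepted in MBq and converted at 1 MBq = 10⁶ s⁻¹. The per-base-pair
molar mass defaults to 651.7 g/mol — calibrated so that 200 ng of a
2686 bp plasmid is 6.88·10¹⁰ molecules, the convention used when the
reference yields were produced — with the textbook 650 g/mol available
(`BP_MOLAR_MASS_TEXTBOOK`); the two differ by 0.3%. The equivalent yield
route X·N_plasmid/D_total is computed alongside X/d and asserted equal to
10⁻¹² as an internal consistency check.

Labeling stoichiometry treats the carrier ratio (long-lived ground-state
atoms per metastable atom) as a plain parameter, default 2.13, because it
depends on unrecorded generator-elution history; a decay-chain ingrowth
model was deliberately not built. Intercalation sites are counted at one
per 10 bp of minor groove and reported both raw (268.6 for 2686 bp) and
rounded to two significant figures (270).

## Censoring and non-detectability

Bands below the detection limit (default 1% of lane signal, the resolution
at which faint gel bands stop being quantifiable) are censored. A censored
linear band contributes a zero point estimate — SC and OC renormalised to
sum to one — plus an upper yield bound (limit/(1−limit))/d, ≈0.0016 at the
reference normalisation. A censored (absent) supercoiled band makes X_SSB
undefined; it propagates as a non-detectable marker, never as infinity,
and replicate summaries exclude such trials while reporting the exclusion
count. Replicate aggregation computes per-trial yields first and then
mean ± sample SD (n−1); averaging fractions first and inverting once gives
slightly different numbers, which is why recomputed values from mean
fraction tables can differ from published per-trial means in the last
digit (e.g. 0.71 vs 0.68 for the pertechnetate SSB yield, whose inversion
ln(0.90/0.01) is very sensitive to the 1% SC fraction).

## Densitometry

Lane quantification reimplements "integrate three bands, normalise to
100%": background subtraction (constant-minimum, or a linear baseline
through the mean of the outer 5% of samples; intensities clipped at zero),
trapezoidal integration over half-open [start, end) windows so shared
edges are deterministic, and normalisation of the three areas. Band
windows are labelled by conformation, not ordered, with the default
migration order OC < L < SC (open circular runs slowest) and configurable
geometry since gel conditions alter mobility. No staining-efficiency
correction between supercoiled and relaxed forms is applied by default,
matching the normalise-to-100% convention of the source data.

## The simulator and what it does (not) emulate

The forward simulator draws, per plasmid, n_DSB ~ Poisson(Y_DSB·d) and
n_SSB ~ Poisson(Y_SSB·d), classifying linear if n_DSB ≥ 1, else open
circular if n_SSB ≥ 1, else supercoiled — exactly the model the estimators
invert. Two deliberate simplifications: plasmids with ≥2 DSB still count
as one linear molecule (the gel reads a single L band; the multi-DSB count
is logged so the approximation is inspectable), and DSB form their own
Poisson channel rather than arising from opposite-strand SSB proximity,
since the inversion model defines no such mechanism. Measurement noise is
available as multinomial sampling of observed plasmids and as synthetic
gel lanes (Gaussian bands with areas proportional to fractions, constant
baseline, additive Gaussian noise). Passing tests therefore demonstrate
correctness of the inversion under its own assumptions — they do not
validate the Poisson assumption for real gels, nor staining nonlinearity,
lane distortion or diffuse smears.

Randomness uses one root `SeedSequence` spawning per-replicate child
streams; identical configs and seeds are bit-identical. The default
simulated sample is 68 800 plasmids — the assay's 6.88·10¹⁰ molecules
scaled by 10⁻⁶ — giving ~0.2% binomial error per fraction, which keeps
every study at desk scale while remaining far below the tolerances being
tested. The parameter-recovery study runs 20 seeds × 3 replicates ×
10⁵ plasmids; simulator-convergence checks use a single 10⁶-plasmid
sample.

## Numerical choices

- `expm1`/`log1p` forms for all decay and Poisson expressions, so the
  round-trip identities hold to 10⁻¹² across X_SSB ∈ [0,3], X_DSB ∈ [0,2].
- Fractions renormalised to sum to one within 10⁻⁹ at construction;
  all-zero lanes are errors, not NaNs.
- Yield-route consistency (X/d vs X·N/D) asserted at 10⁻¹²; a user-supplied
  d inconsistent with (N_plasmid, D_total) beyond 10⁻⁶ relative is a
  configuration error.
- Display rounds to two significant figures (the convention of the
  published tables); all stored output keeps full precision.
- DMSO percent reduction 100·(1 − Y₊/Y₋) is floored at zero (sampling
  noise can make the scavenged arm nominally larger) and undefined when
  the unscavenged yield is zero.

## Known limitations

- No error propagation beyond replicate SD: no delta-method intervals on
  yields, and published "±" values for per-trial averages cannot be
  recomputed from mean fraction tables alone.
- No dose (Gy) estimation, no Auger-electron track structure, no
  decay-chain ingrowth, no 2-D gel image analysis or lane finding.
- The OC channel is treated as noise-free given the other two fractions
  (it is the normalisation remainder), so systematic staining bias between
  conformations maps directly into yield bias.
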
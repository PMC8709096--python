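# Methods

## The measurement model

CE-MS urinary peptidomics reports, per sample, a *relative abundance* for
each detected peptide: signal intensity scaled so that a panel of stable
internal-standard peptides (collagen fragments in the original platform)
sums to a common target. Values are unitless and nonnegative; a peptide
below the platform's detection floor is *missing*, not zero, and the I/O
layer preserves that distinction everywhere. Downstream operations choose
their zero-vs-missing semantics explicitly (see below). A sample enters the
analysis only if at least one peptide of interest was detected; the matrix
reader drops empty samples and logs the count.

Coordinates are 1-based and inclusive on both ends throughout; the only
0-based representation is the optional BED-like region export, converted at
the boundary. The packaged annotation of the 23 complement fragments keeps
the printed values verbatim, including one internally inconsistent row
(e12606: a 23-residue sequence printed with a 22-residue span). The reader
reports such rows with their line numbers rather than repairing them;
strict rejection is available via `on_invalid="raise"`.

## Mutually exclusive fragment groups

Two fragments of one protein that share at least one residue cannot both
originate from the same parent molecule. Grouping therefore takes connected
components of the per-protein interval-overlap graph, computed by a sweep
over start-sorted intervals (verified in tests against exhaustive pairwise
closure on random instances). Adjacency without a shared residue
(`stop + 1 == start`) does **not** merge groups: exclusivity derives from
shared residues, not from proximity. For the packaged annotation this yields
one CFB region (residues 234–257, all seven fragments — the Bb part of the
alternative-pathway convertase), two C4B regions, one C4A region and four
C3 regions.

Combining is exposed at two granularities: `protein` (default — combined
abundance per parent protein, the variable the correction is defined on)
and `group` (per overlap region, a refinement available behind the same
flag in `combined_abundance`, `fit_all_slopes` and the CLI).

## Proteinuria correction

Per protein, the combined abundance `S` (sum over member fragments,
non-detections contributing zero; missing only when every member is
missing) is regressed on proteinuria on the double-log scale:

    log10 S = a + b · log10 PU .

Log base 10 is a convention choice — the base cancels in the correction —
chosen for the decade spans typical of both quantities. The fitting subset
takes samples with `S > 0` and `PU > floor`; the floor is 0.01 g/g
creatinine, below which measured proteinuria is treated as an assay
sentinel. Floored samples are excluded from *fitting* (a sentinel value
would bias b) but still *corrected* using the floored value, since corrected
abundances are wanted for every sample. Fits require n ≥ 3 and nonconstant
log-proteinuria; violations raise typed errors.

The fitted slope of a protein is then applied to each of its member
peptides:

    log10 x_corr = log10 x_obs − b · log10 PU ,

only where the peptide is detected and proteinuria is known; nothing is
imputed for non-detections, and skipped entries are counted in a report.
One shared b per protein both matches the defining procedure and avoids
fitting 23 separate slopes. Because the subtraction is exactly the OLS
slope term, re-estimating the slope of the corrected combined abundance on
log-proteinuria over the fitting samples returns 0 to floating precision —
the acceptance suite asserts `< 1e-10`.

## eGFR

The 2009 CKD-EPI creatinine equation (141 · min(Scr/κ,1)^α ·
max(Scr/κ,1)^−1.209 · 0.993^age · 1.018 if female; κ = 0.7/0.9,
α = −0.329/−0.411) is implemented race-free by default; the 1.159
coefficient is isolated in `EgfrParams` as an explicit opt-in, reflecting
current practice. Supplied eGFR values take precedence over recomputation;
where both exist, discrepancies above 5% are returned in a consistency
report. The equation is strictly monotone in creatinine, so it is inverted
branch-wise (`invert_ckd_epi`) — used by the synthetic generator to emit
creatinine values consistent with the drawn eGFR. A documented constant
(88.4) converts mg/dL to µmol/L.

## Associations and summaries

Spearman correlation uses midranks and the two-sided t-approximation
`t = ρ√((n−2)/(1−ρ²))` on n−2 degrees of freedom (the standard choice at
the n ≫ 10 of cohort data); `|ρ| = 1` reports the limiting p of 0, and an
exact permutation p is available for n ≤ 10, valid under ties. Pairs with a
missing abundance or covariate are dropped pairwise; peptides with fewer
than 3 usable pairs are omitted with a logged reason. Log-transforming
abundances and proteinuria before ranking is supported and, being monotone,
provably changes nothing — a test asserts the equality. Raw p-values are
the primary output; a Benjamini–Hochberg column (`p_bh`) is emitted
additionally as a clearly labelled extension.

Per-condition summaries divide each condition's mean (optionally median)
by the healthy-control value. Two missing policies exist for the means:
`zero-fill` (non-detection counts as zero — every subject of a condition
contributes) and `observed-only`. Defaults: zero-fill for raw abundances
and combined values; observed-only for proteinuria-corrected values, which
are undefined at non-detection. Corrected values live on the log10 scale
and are mapped back through `10^x` before averaging so adjusted and
unadjusted summaries share units. Mean is the default center with median
selectable; both conventions appear in the field and the choice is exposed
rather than resolved. Zero control means produce missing cells with a
warning. Peptide-level tables are ordered CFB → C4B → C4A → C3, then by
start position.

## Synthetic cohorts

The generator draws, per subject: a condition (multinomial over fractions
defaulting to the packaged 22-condition cohort proportions), eGFR from a
per-condition truncated normal on [5, 120] mL/min/1.73 m² (healthy ≈
100 ± 13, acute kidney injury ≈ 35 ± 20, etc. — marginal covariates, not a
mechanistic kidney model), age ~ N(55, 15²) clipped to [20, 90], sex
Bernoulli(½), and creatinine by inverting CKD-EPI so the clinical table is
internally consistent. Log10 proteinuria is linear in eGFR,
`c0 + c1·eGFR + N(0, σ_PU)` with defaults c0 = 0.5, c1 = −0.015 per
mL/min, σ_PU = 0.35 — about 0.1 g/g at eGFR 100 and 1.6 g/g at eGFR 20 —
then rounded to 0.01 g/g assay resolution (occasionally producing measured
zeros, which exercises the fitting floor).

Per protein, latent log10 combined abundance is

    µ + δ_condition + γ·(eGFR − 90) + b_true·log10 max(PU, floor) + N(0, σ) ,

with baselines µ matching the published per-protein abundance ordering
(C3 3.5, CFB 3.2, C4B 2.4, C4A 2.3 log10 units) and σ = 0.25. Default
leakage slopes are b_true = +0.8 (C3), +0.3 (C4A, C4B), −0.1 (CFB): the
direction pattern reported for patient data (C3 strongly proteinuria-
coupled, CFB weakly negative), magnitudes chosen as plausible round values
rather than estimates. Direct condition effects δ and direct eGFR effects γ
default to **zero**: out of the box, all abundance variation flows through
the filtration/leakage mechanism the correction targets, which keeps the
simple log-log OLS an unbiased estimator of b_true and makes parameter
recovery a well-posed test (nonzero δ or γ confound the fit through the
eGFR→proteinuria link — deliberately available, via `condition_spec` and
`egfr_effect_gamma`, for studying exactly that). The combined abundance is
allocated to fragments by symmetric Dirichlet(α = 2) shares over a
protein's groups and again over each group's members, drawn once per
cohort and held fixed, the simplest allocation honoring population-level
mutual exclusivity; per-subject resampling would decouple peptide-level
from combined-level analyses. Values below the detection limit (default
0.05, well under typical signals so censoring is a tail phenomenon) become
missing. Twenty-nine reference peptides are generated condition-independent
at level 1000 with σ = 0.05. All draws flow through one
`numpy.random.Generator`; a fixed seed gives bit-identical files, and a
truth record stores every parameter for recovery tests.

What the generator does *not* emulate: migration-time/ionization artifacts,
peptide-specific detection probabilities, correlated noise between
fragments beyond the shared combined variable, comorbidity structure, and
abundance-dependent censoring informativeness. Passing tests therefore
demonstrate correctness of the *procedure* under its stated model, not
robustness to real-data pathologies.

## Problem sizes and numerical choices

Default test/acceptance cohorts use n = 2000 subjects (comparable precision
structure to the subset of real datasets carrying proteinuria), 20 seeds
for slope recovery, and n = 10 000 for the law-of-large-numbers check on
the proteinuria link. Tolerances: residualization asserted to 1e−10
(achieved ~1e−15); slope recovery within 3 closed-form standard errors in
≥ 19/20 cohorts per protein; Spearman equality to a brute-force midrank
oracle at 1e−12 (ρ) and 1e−9 (p), enumerated over every tie pattern of
length ≤ 6 with up to three distinct values. Ties in `locate_peptide` break
to the leftmost match with a warning listing all matches, keeping output
deterministic on repetitive sequences.

## Known limitations

* The shipped protein sequences are synthetic stand-ins; absolute
  coordinates depend on the reference numbering (precursor vs mature
  chain), which published coordinate tables do not pin down.
* The correction assumes a single leakage elasticity per protein and
  log-linearity over the observed proteinuria range.
* Reported p-values assume independent samples; repeated measures per
  subject would require clustering corrections that are out of scope.
* The condition vocabulary is open: unknown labels warn and pass through,
  so upstream typos are surfaced but not rejected.
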
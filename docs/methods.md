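# Methods

This note documents the statistical models behind each pipeline, the
defaults and why, the synthetic-data generators and what they do and do
not emulate, and the open design choices we resolved.

## Growth kinetics

Growth is summarised as the trapezoidal AUC of background-corrected OD
over the recording window (OD·h; time parsed in minutes, stored in
hours). Background correction subtracts the per-time-point mean of the
blank wells; negative corrected values — common at early times when
blank drift exceeds signal — are floored at 0 and flagged rather than
rejected. Curves are replicate-averaged for plotting, but all AUC
statistics (standard errors, *t*-tests) use per-replicate AUCs, since
biological replicates are the unit of error.

Inhibition is 1 − AUC(d)/AUC(0) and is exactly 0 at dose 0 by
construction. The ICx is interpolated piecewise-linearly in
(log₁₀ dose, inhibition): dose grids in these assays are geometric, so
the log axis is the natural interpolation scale. The zero dose cannot
sit on a log axis; it serves only as the inhibition baseline, and a
target bracketed between dose 0 and the first dose is interpolated
linearly in dose. Unbracketed targets return the nearest measured dose
with an `extrapolated` flag (or raise, if extrapolation is disabled).
Group comparisons use the two-sided pooled-variance Student *t*-test;
the degenerate zero-pooled-variance case is resolved deterministically
(equal means → p = 1, unequal → p = 0). Sequential-dose significance
testing applies no multiplicity correction, matching how such assays
are conventionally annotated. Growth-model fitting (logistic/Gompertz
parameters, lag times) is out of scope.

## DSSA

**Preprocessing.** Probe signals above a configurable saturation
ceiling are winsorized to the ceiling and flagged (rank-preserving, and
it stops saturated probes from distorting ratios); signals are
log₂-transformed with a pseudocount of 1 signal unit (avoids −∞ on
empty probes). Chip background is estimated per array from the null
features — probes matching no strain barcode — by robust location and
scale: the median is subtracted (so null features center at 0 exactly)
and MAD × 1.4826 is retained as the array's background scale.

**Pairing and normalization.** Every treatment array is paired with
every control array of the same generation arm; 3 biological replicates
× 12 controls gives 36 pairs per condition. Each pair's log-ratio
M = t − c is detrended by a lowess fit of M on A = (t + c)/2
(span 0.4, 3 robustifying iterations — standard MA-normalization
defaults, configurable); below 30 genes the global median is subtracted
instead and the pair flagged.

**Alpha-outlier calls.** Most strains are unaffected in any one pair,
so the per-pair null is a robust Gaussian fit to the m-values
(median/MAD × 1.4826). Two-sided normal p-values are BH-corrected
across genes and a gene is an outlier at q ≤ α (default 0.05) with the
sign of its centered m-value. A zero scale (all m identical) yields no
calls. This realises "calls controlled at level alpha" in a fully
testable form; the null-calibration test confirms no inflation on pure
noise.

**Effective pairs.** Pairs whose robust residual variance exceeds the
Tukey fence Q3 + 1.5·IQR within their condition group are excluded —
the programmatic equivalent of screening per-pair box plots. A lag-1
autocorrelation of per-pair scale across pair order is reported as a
serial-correlation diagnostic but never auto-excludes; excluding every
pair is an error demanding manual review.

**Aggregation.** Per gene and condition, the dominant sign is the
strict-majority sign of m-values over effective pairs (exact tie → no
call). A pair is a success when the gene is an outlier there with the
dominant sign; with k successes of m pairs the raw p is the exact
binomial upper tail P(X ≥ k | m, π₀). The null per-pair success
probability π₀ defaults to 0.05 — the per-pair call level is the
natural Bernoulli rate under the null — and can be overridden by the
empirical mean per-pair call rate. q-values over genes use BH
(deterministic and reproducible; a Storey-type variant would need a π₀
estimate and adds nothing at these effect sizes). Strict mode
additionally requires success in *every* effective pair (k = m),
mirroring the simultaneous-significance reading of the rule; the
binomial tail over k is retained as the non-strict option, which the
recovery benchmarks use. Called genes are labelled by the sign of
their fitness score (mean adjusted log₂ signal, exposed minus control):
negative = sensitive, positive = resistant. Because aggregation uses
only per-pair ranks/calls, no between-pair scale normalization is
needed for the inference itself.

## Enrichment

The upper-tail hypergeometric p-value P(X ≥ k) for k of a K-member
category inside an n-gene test set from an N-gene reference is summed
from log-pmf terms for stability of small tails. Raw p-values are
thresholded at 0.01 with no cross-category correction — the convention
of the screening tables this reproduces — though a BH column is emitted
for information. Genes in the test set absent from the
reference/annotation are dropped from n with a logged count. Custom
reference sets (e.g. the bundled stress library) restrict N, n, K and k
to the reference, which is the correct null when only the library was
assayed. GO-graph ancestor propagation and term-redundancy reduction
are out of scope.

The bundled stress-library GMT transcribes a published 123-ORF
stress-response reporter ensemble; as printed, the five pathway groups
contain 122 distinct gene names (five genes appear in two groups), and
we ship the table as printed. A fully-hit 3-gene category under a
24-ORF test set gives p = 0.00686 at N = 122 versus 0.00669 at N = 123
— both 0.007 to one significant figure.

## Reporter PELI

Signals are corrected by subtracting the mean of medium-control wells
matched by dose (so chemical autofluorescence cancels; a single shared
medium blank is accepted when only one is present), floored at 10⁻⁴ of
each channel's dynamic range and flagged — early-time OD sits at the
medium background, and the floor keeps later ratios finite. P = GFP/OD
per time point; optional plate normalization divides P by the per-time
median P of designated internal-control wells, which makes downstream
ratios invariant to any plate-wide multiplicative factor (and is
skipped with a warning when no such wells exist). I(t) =
P_experiment/P_vehicle against the replicate-matched vehicle well
(falling back to the ORF's pooled vehicle wells if replicate matching
fails).

PELI integrates I over the full recorded window and divides by the
window length — a time-average — so PELI(vehicle) = 1 identically.
That identity is what makes a fixed signal-to-noise cutoff of 1.5
meaningful, and it resolves the ambiguity between "integral to t" and
"per exposure time" readings of the index. Replicates are summarised
as mean ± sample SD (n = 1 gets SD 0, flagged via n_rep); activation is
mean PELI > cutoff, a single call per ORF-dose rather than
per-replicate votes, matching how the index is reported. Exports are
numeric TSVs: the ln I heat-map matrix (ORFs × time, blocked by dose,
rows groupable by stress category) and per-dose rank profiles (mean
PELI descending, ties broken lexicographically by ORF id). Rendering
is left to plotting tools.

## Synthetic data

All generators are deterministic functions of (config, seed) via
`numpy.random.default_rng`.

**Pooled screens.** Strain abundance after g generations is
a_i0 · 2^{g(1−s_i)}, renormalized to relative abundance (sums to 1);
baseline abundances are lognormal (σ = 0.5) to emulate strain-to-strain
variation. Treatment pools apply the planted selection coefficients
(s > 0 depletes → sensitive; s < 0 enriches → resistant), controls use
s ≡ 0. The effective coefficient scales linearly with dose relative to
the top dose by default; a threshold mode applies full s at any
non-zero dose, emulating the sharp threshold behaviour such screens can
show. Hybridization is a saturating Michaelis-type map
y = y_max·a/(a + h) with h = 4×10⁻³ on the relative-abundance scale,
multiplicative lognormal noise (σ = 0.15) and additive Gaussian probe
background (mean 120, SD 40); null features carry background alone.
With these defaults a few percent of gene probes approach the
saturation ceiling, exercising the winsorization path. Default sizes —
4000 strains, 2000 null features, 3 replicates × 12 controls — are
structure-preserving scale-downs of a genome-scale screen (4757
strains, 18000 null features, reachable via the config) chosen so a
full pipeline run takes seconds-to-tens-of-seconds on one CPU. The
generator does not model PCR amplification bias, probe
cross-hybridization or spatial array artifacts, so passing recovery
tests demonstrate the statistics, not robustness to those artifacts.

**Reporter plates.** OD follows a logistic curve (od₀ = 0.2 → early
exponential phase, K = 1.0, r = 0.01 min⁻¹ over the 2-h window);
vehicle GFP = P_base·OD and experiment GFP = I*·P_base·OD with constant
true induction I*, so the true PELI equals I* exactly. Both channels
gain the medium background plus multiplicative Gaussian read noise
(recovery tests use 2 %). Time-varying induction trajectories,
GFP maturation lag and photobleaching are not modelled.

**Dose-response plates.** Each dose scales a shared logistic curve by
1 − d^h/(d^h + IC50^h), so AUC-based inhibition equals the Hill
inhibition exactly in the noiseless limit and the true ICx has the
closed form IC50·(f/(1−f))^{1/h}. Reads every 15 min for 24 h, three
replicates, additive read noise (SD 0.005 OD), constant blank 0.05 OD.
The benchmark grid (6 non-zero doses, factor 2 around IC50 = 500 µM,
h = 1.5) places the true IC20 (198.4 µM) off the dose grid so the
log-linear interpolation is actually exercised.

## Benchmarks and their problem sizes

`fitscreen.benchmarks` defines the recovery experiments run by the
test suite and usable standalone: DSSA on 4000-strain screens with 30
planted s = 0.3 strains (3 replicates × 12 controls), scored for
sensitivity and empirical FDR over 5 seeds; IC20 recovery over 10
seeds; reporter recovery of I* = 1.8 at 2 % noise with 24 planted among
48 reporters over 10 seeds; and null screens/plates for calibration.
These sizes keep a full suite run under two minutes on one CPU while
preserving the study design's replicate structure.

## Known limitations

* The alpha-outlier null is Gaussian after robust standardization;
  heavy-tailed pair noise would inflate per-pair calls (the binomial
  aggregation across 36 pairs buffers gene-level calls considerably).
* π₀ = 0.05 is conservative when effective pairs are correlated
  (they share control arrays); the empirical-rate override exists for
  that case.
* Enrichment treats categories independently and ignores the GO graph.
* The CLI is a thin wrapper; multi-plate reporter designs with distinct
  internal-control schemes should use the library API directly.
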
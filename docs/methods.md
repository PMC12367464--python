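# Methods

## Calibration model

A spiked sample's sequencing library contains molecules from two pools:
endogenous 16S amplicons, proportional to the sample's gene-copy load,
and exogenous spike amplicons, proportional to the known dose. Assuming
(i) the eluate is homogeneous, (ii) the spike and endogenous templates
amplify with equal efficiency, and (iii) reads are sampled from the
molecule pool without further bias, the expected reads of any taxon are
proportional to its molecule count in the spiked aliquot. The
copies-per-read ratio of the spike then transfers to every endogenous
taxon:

    k_s = (C_s / r_s) · (V_elution / V_aliquot) / m_feces
    x_ts = n_ts · k_s

`C_s / r_s` calibrates the aliquot; the volume ratio scales the aliquot
up to the whole eluate (conservation of copies under homogeneity); the
mass division yields per-gram units. The estimator is deliberately free
of pseudocounts: the scale factor must remain exactly linear in reads,
which is what the dose-doubling and linearity property tests assert. A
sample with zero spike reads has no defensible scale factor and is
flagged `no_spike_reads` with null estimates, never imputed.

### Dose semantics

The mass-to-molecules formula divides by the molar mass of a dsDNA
molecule of the configured reference length. Whether that length is the
genome or the amplicon, and whether the dose should additionally be
expressed in 16S gene copies (genome molecules × GCN), are configuration
switches (`dose_basis`, `dose_in_16s_copies`). The defaults are genome
basis with 16S dosing off: the shipped calibrant configuration (2.5 µL
at 4.31 ng/µL over ~4.24 Mb; 2.5 µL at 9.59 ng/µL over ~3.65 Mb)
reproduces the conventional ~2.3×10⁶ / ~6.0×10⁶ molecule doses under
that convention. Both conventions are supported because the community
literature is not consistent about which is meant; neither is asserted
as uniquely correct.

### Pooling two calibrants

With two (or more) spike strains the default pooling sums reads and sums
copies before taking the ratio — a read-weighted combination that is
robust when one strain is poorly detected. Mean pooling (average of
per-strain copies-per-read ratios over strains with at least one read)
is available; when the strains are concordant all pooling choices agree
exactly (a tested invariant). The per-sample discordance
`ln(estimate₁ / estimate₂)` is reported as a diagnostic: it is zero for
perfectly concordant strains, NaN-flagged when either strain has zero
reads, and systematic departures indicate strain-specific amplification
bias. The per-gram scaling cancels in the ratio, so the diagnostic is
computed at the aliquot scale.

### QC window

The spike share of total reads should sit between 0.1% and 10%: lower
shares make the calibration ratio noisy, higher shares waste sequencing
depth and perturb the community profile. Samples outside the window are
flagged (`fail_low` / `fail_high`) but still quantified; downstream
convenience functions operate on `pass` samples by default.

## qPCR bridge

Standard curves are ordinary least squares of Ct on log10 copies, the
canonical scale (a mass-based series is convertible through the same
mass-to-molecules formula). Efficiency is `10^(−1/slope) − 1`; values
outside [0.9, 1.1] and standard series spanning fewer than two decades
are warned about, a non-negative slope invalidates the curve. Replicate
Ct values are averaged (with SD reported) before conversion — the
conventional aggregation. Per-reaction copies scale to per-gram loads by
`× (V_elution / V_template) / m_feces`. Conversions below one copy per
reaction are flagged as below the quantification range rather than
clipped.

## Gated statistics

All branching uses a fixed P > 0.05 gate. Two groups: Shapiro-Wilk per
group, then t-test or two-sided Mann-Whitney U. Three or more groups:
Shapiro-Wilk per group plus Levene (mean-centred); a normality failure
routes to Kruskal-Wallis; with normality intact the `tukey` post-hoc
family runs classic ANOVA + Tukey HSD only when Levene passes and
escalates to Welch's ANOVA + Games-Howell when it fails, while the
`games_howell` family (the default for method comparisons) always takes
the Welch path, which remains valid under heteroscedasticity.
Correlation gates both variables through Shapiro-Wilk into Pearson or
Spearman; a constant vector is flagged undefined. Welch's ANOVA and
Games-Howell are computed in closed form with P values from scipy's
studentized-range distribution, and are verified against pingouin to
1e-6 in the test suite; the remaining tests delegate to scipy — the
package's contribution is the gating logic, not a re-derivation of the
reference statistics.

The rank-sum test enumerates the exact permutation distribution when the
combined sample is ≤ 10 and tie-free (the regime of per-genus group
comparisons in small cohorts) and otherwise uses the tie-corrected
normal approximation with continuity correction. Per-genus scans report
unadjusted P values with significance stars, matching common practice in
small-cohort studies; Benjamini-Hochberg adjustment is available behind
a flag.

Load-like comparisons are reported on both raw and log10 scales
(`compare_raw_and_log10`), since the branch taken can differ and the
choice of scale is a scientific, not statistical, decision.

## Composition analyses

Spike rows are removed before every composition analysis. The relative
basis is per-sample proportions; the absolute basis uses copies-per-gram
values directly, without re-normalization — the contrast between the two
is the point of the exercise. Rankings sum values over the scope's
samples and break ties by value descending then label, so reports are
deterministic. Shannon diversity (nats) is scale-invariant and therefore
identical between bases — a tested identity. Chao1 refuses non-integer
input because singleton/doubleton counts are meaningless after scaling;
the bias-corrected form `S + F₁(F₁−1)/(2(F₂+1))` is the default (defined
at F₂ = 0), the classic form is available. Bray-Curtis comes from
scipy's implementation with explicit guards for all-zero samples. PCoA
is classical scaling: double-centred squared distances,
eigendecomposition, coordinates on positive-eigenvalue axes; negative
eigenvalues are reported and excluded from the explained-variance
denominator by default (configurable), standard practice for
non-Euclidean dissimilarities. PERMANOVA computes the pseudo-F from the
among/within decomposition of squared distances and a seeded label
permutation null, `P = (1 + #{F* ≥ F}) / (1 + n_perm)` with
`n_perm = 999` by default; an exhaustive mode enumerates every distinct
label assignment and is tested to match brute-force enumeration exactly
(skbio's PERMANOVA serves as an independent cross-check of the
statistic, never as the implementation).

## The simulator

Each synthetic sample draws a true total 16S load per gram from
`10^N(μ_g, σ)` with group means 11.0 (mother) and 10.5 (infant) log10
copies/g and σ = 0.3 — a half-log gap at realistic fecal loads — and a
genus composition from group-specific Dirichlet distributions over a
14-genus pool (infant: Bifidobacterium/Escherichia-Shigella dominated;
mother: Blautia/Faecalibacterium and other strict anaerobes).
Reads are one multinomial draw over molecule expectations: endogenous
genus g contributes `E · u_g · bias_g` where `E` is the aliquot's 16S
copy total and `u_g` the GCN-weighted composition share; each spike
strain contributes its molecule dose × bias. Per-genus GCN values are
representative database-scale integers (3–7). Physical defaults (0.2 g
feces, 200 µL elution, 20 µL spiked aliquot, depth 5×10⁴ reads) place
the default doses inside the 0.1–10% window across the load
distribution. Companion measurements are truth × log-normal noise: qPCR
σ = 0.05 log10; flow cytometry ×7 overestimation (the reported
flow-vs-plate gap) with σ = 0.15; plate count σ = 0.15; total DNA is
proportional to load. One seeded generator drives every draw, so a fixed
seed is bit-reproducible.

Scenario presets: `baseline` as above; `low_biomass` (means 10.0/9.5,
concentrated Dirichlet with four rare genera) exercises the
detection-threshold regime where taxa below ~10⁵ copies/g are reported
as zeros; `biased_amplification` (spike bias ×2) demonstrates that a
shared amplification bias shifts every estimate by the same factor
(~0.5× truth) without adding scatter; `out_of_window_spike` (400×
overdose) trips the QC ceiling in essentially every sample.

What the simulator does **not** emulate: DNA extraction efficiency
differences (a wet-lab confounder the estimator cannot correct),
taxon-specific amplification bias of endogenous genera interacting with
primer chemistry, sequence-level artifacts (errors, chimeras — the
generator produces counts, not reads), overdispersion beyond
multinomial sampling, and host DNA contamination. Passing recovery tests
therefore demonstrate the estimator's correctness under its own
assumptions, not robustness to every real-data pathology.

## Problem sizes and numerical choices

The shipped checks use cohorts of 24 samples at 5×10⁴ reads (20 seeds
for recovery; 100 replicates for group-difference detection), 2,000
null simulations for the gate's type-I error, 999 permutations for
PERMANOVA (exhaustive enumeration on 6-sample fixtures), and ≥200
randomized cases for the invariance properties — sizes at which the
Monte-Carlo error of each summary is well inside the asserted margins.
Counts are validated as integers exactly (rounding tolerance zero);
symmetric-matrix checks use 1e-12 absolute tolerance; eigenvalues below
`1e-12 × max|λ|` are treated as zero. Ranking ties break by label;
permutation P values use the add-one convention so P = 0 is impossible.

## Known limitations

* The estimator trusts the configured dose; pipetting or quantification
  error in the spike DNA propagates multiplicatively into every
  estimate.
* A shared spike amplification bias rescales all loads by a constant
  factor — cross-group comparisons survive, absolute magnitudes do not
  (the `biased_amplification` scenario makes this measurable).
* Detection is bounded by depth: taxa below roughly 10⁵ copies/g are
  frequently reported as zero at typical depths, so total loads are
  slightly underestimated in low-biomass samples.
* Chao1 on absolute values is undefined by construction; richness is
  always computed on raw reads.
* The exact rank-sum branch requires tie-free data; heavily tied small
  samples fall back to the approximation, whose P values are less
  reliable at n < 8.
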
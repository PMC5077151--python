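# Methods

`spliceratio` analyses how the abundance ratio of a mutant splicing factor to
its wild-type counterpart — specifically U2AF1-S34F vs wild-type U2AF1 —
shapes 3' splice-site choice. This note records the models, the estimators,
the synthetic-data generator's assumptions, and the numerical choices, in the
order a run executes them.

## The competition model of ratio-dependent splicing

Alternative splicing of a cassette exon (or of competing acceptors) is
treated as a competition between a proximal and a distal 3' splice site for
U2AF-dependent recognition. Mutant and wild-type U2AF1 complexes bind each
site with different apparent association constants K_A, and both forms are
assumed functionally equivalent once bound. With mutant fraction
f = ρ/(1+ρ), where ρ is the mutant:wild-type (S34F:WT) gene-product ratio,
the proximal site's share of recognition — identified with the inclusion
fraction Ψ (PSI) of the proximal isoform — is the linear occupancy mixture

    Ψ(ρ) = [f·KAm_p + (1−f)·KAw_p] / ([f·KAm_p + (1−f)·KAw_p] + [f·KAm_d + (1−f)·KAw_d])

Two consequences anchor the whole package: Ψ depends on the *ratio* only
(total U2AF1 cancels), and Ψ is monotone in ρ with direction given by the
sign of KAm_p·KAw_d − KAm_d·KAw_p. No quantitative dose–response form is
experimentally established for this system; the linear mixture is the
simplest form consistent with ratio-controlled splicing and is a modelling
choice of this package, exposed as such.

## Synthetic cohorts

The generator stands in for tumor and cell-line transcriptomes that cannot
be redistributed. Defaults were fixed once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| events per panel | 2000 | genome-scale cassette-exon panel; a few hundred responsive events |
| responsive fraction | 0.2 | most exons do not respond to the mutant |
| −3 base composition | C .57 / T .27 / A .11 / G .05 | genomic acceptor consensus (CAG > TAG > AAG > GAG) |
| mutant proximal K_A fold | ×3 at −3C and −3A, ×1/5 at −3T, ×1 at −3G | few-fold in-vitro affinity shifts; strongest repression at UAG acceptors |
| wild-type K_A | log-normal, σ = 0.4 | baseline inclusion spread around Ψ ≈ 0.5 |
| WT / mutant samples | 30 / 13 | minority-mutant cohort |
| mutant ratios ρ | 13 values spanning 0.26–0.82 | observed tumor ratio range |
| junction depth | Poisson, mean 200/event | deep bulk RNA-seq after junction filtering |
| allele depth | 100 reads | variant-spanning coverage at a typical expressed locus |
| biological jitter | σ = 0.2 on logit Ψ | sample-to-sample variability beyond counting noise |

Counting noise is binomial: inclusion reads ~ Binomial(depth, Ψ) per
event×sample, variant (alt) reads ~ Binomial(allele depth, f) per mutant
sample; wild-type samples have f = 0. The logit-normal jitter is applied to
the model Ψ *before* sampling and is recorded in the truth file, so
estimator-recovery tests compare against the jittered per-sample truth.
Every generator call takes an explicit integer seed; there is no global
random state, and identical seeds give byte-identical output files.

What the generator does **not** emulate: read-level artefacts (mapping
bias, positional coverage), transcript-abundance variation, copy-number
change, sample purity, and correlated event behaviour within genes. Tests
passing on these cohorts therefore demonstrate correctness of the
estimators and decision rules under the stated statistical model, not
robustness to every property of real RNA-seq.

## PSI quantification

PSI is the junction-ratio estimator inc/(inc+exc) over isoform-assignable
("informative") junction reads. For cassette exons whose two inclusion
junctions are counted separately, the inclusion support is the mean of the
two counts (one read cannot span both). A cell is defined only when
informative reads ≥ `min_informative` (default 20; the threshold is not
standardised in the field, so it is configurable). Coordinates are 0-based
half-open, strand-aware; no length normalisation is applied because counts
arrive pre-summarised per junction. Upstream estimators that weight read
classes differently exist; the plain junction ratio is this package's
reimplementation choice and agrees with a per-read assignment oracle on toy
tables.

## Differential splicing and signature classification

Per query sample, ΔΨ = Ψ_query − median(Ψ_reference) per event, against a
mutation-free reference cohort; the median over an even count is the
midpoint of the central pair. Events undefined in the query or defined in
fewer than half the references are dropped. Calls use an inclusive
threshold at |ΔΨ| ≥ 0.10 (a 1e−9 float guard keeps "exactly ten percent"
inclusive). No multiple-testing correction is applied to event calls — the
decision rule thresholds effect size, not p-values.

Acceptor windows (default −20…+3 around the 3' splice-site AG; the −3
position is all the classifier needs, the window is cosmetic context) are
extracted strand-corrected and restricted to canonical GT-AG introns.
Position frequency matrices drop ambiguous bases per column with
renormalisation, and information content is IC = 2 + Σ_b f_b·log2 f_b bits
(0·log 0 := 0, no small-sample correction), so an invariant column scores
2 bits and a uniform one 0.

A sample is classified **typical_S34F** iff f_A > f_T at −3 of the promoted
set *and* f_T > f_C at −3 of the repressed set; any partial pattern
collapses to **quasi_WT**, and fewer than 10 windows (configurable) on
either side yields **undetermined**. The score
(f_A−f_T)_promoted + (f_T−f_C)_repressed grades the pattern. Signature
comparisons across conditions report per-direction overlap counts and, for
shared events, the enhancement ΔΨ_b − ΔΨ_a in waterfall order.

Group comparisons use the Mann-Whitney U test with the exact null
distribution when n_a·n_b ≤ 400 (ties tolerated without correction there)
and the tie-corrected normal approximation otherwise; Student's t is
available where a mean comparison is wanted. All p-values are two-sided,
reported raw at α = 0.05.

## Allelic ratios

From RNA-seq: ρ = alt/ref and f = alt/(alt+ref) over variant-spanning
reads; ref = 0 is encoded as ρ = ∞ (f = 1) and excluded from correlations
with a logged warning. From allele-sensitive qPCR: ρ = eff^(Ct_ref−Ct_alt).
When the mutant-specific probe detects the wild-type template at 1/x
efficiency, the raw ratio of a pure wild-type sample is 1/x; the linear
unmixing max(0, (raw − 1/x)/(1 − 1/x)) maps it to zero. The unmixing
formula is this package's construction — only the x ≈ 11-fold specificity
itself is an experimentally grounded quantity.

Ratio–PSI association uses Pearson's r across mutant samples (≥ 3 paired
finite observations; zero variance returns an undefined r with a reason).
Optionally one reference point (ρ = 0, reference-median Ψ) is appended
first — published plots show such a point but do not state whether it
enters r, so both modes exist and the flag defaults to off.

## Binding isotherms and competition predictions

Anisotropy titrations are fit to the two-state ligand-depletion isotherm

    A(P) = a_free + (a_bound − a_free)·FB(P)
    FB = [(P+R+K_D) − sqrt((P+R+K_D)² − 4PR)] / (2R)

with free parameters K_D, a_free, a_bound and fixed labelled-RNA
concentration R. The quadratic form (not the hyperbola) is used because the
labelled RNA is at finite concentration; in the trace limit R ≪ K_D it
reduces to the hyperbola, which the tests verify. Fitting is multistart
least squares: endpoints seeded at the observed extremes, K_D at the
midpoint-crossing concentration plus five log-spaced seeds across the
titration range, best residual kept. A fit is reported unconverged — never
silently — when the optimiser fails everywhere, the fitted signal does not
increase (a_bound ≤ a_free), the series is flat, or the K_D uncertainty
exceeds ten times the estimate.

Replicate affinities K_A = 1/K_D (≥ 3 per protein form) are compared by
Welch's t test on log K_A — affinities are ratio-scale — two-sided at
α = 0.05 with no multiplicity correction (a handful of planned per-site
comparisons). At triplicate size the Satterthwaite approximation is
conservative (empirical size ≈ 0.03 at nominal 0.05, matching R's
`t.test` under the same simulation); the calibration test asserts the size
never exceeds α rather than equality with it.

The direction rule: with per-site fold changes fc = K_A(mut)/K_A(wt), if
exactly one site changes significantly its sign decides (proximal gain →
increased proximal-isoform use; distal changes act inversely); if both
change, the net fold change fc_prox/fc_dist vs 1 decides; if neither, the
event is a `no_call`, which scores as discordant — a deliberately
conservative choice. The rule is antisymmetric under swapping the two
sites. Applied to the package's panel of seven characterized
S34F-responsive events — encoded as qualitative fold-change directions with
nominal magnitudes, since only direction and significance enter the rule —
it explains six of seven observed splicing directions; the one exception
(MED15: proximal affinity loss yet a promoted exon) marks the limit of a
pure affinity model.

## Problem sizes and determinism

Test and acceptance runs use panels of 300–2000 events, cohorts of ≤ 50
samples, 100 triplicate titrations, and 2000-replicate null simulations —
sizes at which every recovery bound in the test suite is comfortably
resolved on a single CPU in seconds. All randomness is seeded; reruns of
any pipeline config with the same seeds are byte-identical, including the
run manifest (which therefore contains no timestamps).

## Known limitations

- The occupancy mixture is one admissible dose–response; saturating or
  cooperative forms would change quantitative (not directional)
  predictions.
- The PSI estimator ignores read-class weighting used by some upstream
  tools; on pre-summarised junction counts the two coincide.
- The classifier reduces a full logo to two inequalities at −3; subtler
  composition shifts (e.g. at −5…−4) are not scored.
- Binding predictions assume equilibrium occupancy is rate-determining;
  kinetic/co-transcriptional effects enter only through the net-gain rule's
  interpretation of distal competition.
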
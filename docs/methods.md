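# Methods

This note documents the models, defaults and numerical choices behind
`metapress`, and what the synthetic-data studies do and do not demonstrate
about real data.

## Experimental model

The package assumes a three-stage continuous-cultivation (CSTR) design: a
defined community is stabilized, then exposed to a compound as a sustained
("press") perturbation, then allowed to recover after the compound is
washed out.  The default layout is four parallel 250-ml bioreactors sampled
daily from day 4 to day 17, with stage windows stabilization = days 4–6,
exposure = days 7–13, recovery = days 14–17.  Each bioreactor-day is
treated as one independent observation in all tests.  This mirrors common
practice in in-vitro microbiota studies but ignores the repeated-measures
structure (the same reactor is sampled on consecutive days); no
mixed-effects correction is applied, and p-values should be read with that
caveat.  A within-bioreactor restricted permutation mode for PERMANOVA
would be the statistically safer choice for strongly autocorrelated data
and is noted as future work.

## Dosing and washout

`scale_adi_dose` maps a regulatory Acceptable Daily Intake (mg per kg body
weight per day) to a working concentration by assuming the reactor hosts a
stated fraction (default 0.10) of the daily faecal microbial output of a
reference 70-kg adult: c = ADI·M·f/V.  The cell fraction is an explicit
input rather than something computed from CFU counts, because in practice
it is an assumption, not a measurement.  With the defaults (6 mg/kg/day,
70 kg, 0.10, 250 ml) the target is 0.168 mg/ml.

The recovery phase is modelled as ideal CSTR washout, c(t) = c₀·e^(−Dt),
with dilution rate D = 1 reactor volume per day implied by a 24-hour media
exchange.  No measured decay law is assumed; the exponential form is the
standard chemostat mass balance for a well-mixed, non-adsorbing solute.
Starting from a measured mean exposure concentration of 0.127 mg/ml, four
days of washout give 0.0023 mg/ml, i.e. 0.002 at the 3-decimal reporting
precision used throughout.  Note that measured supernatant levels in such
experiments typically sit below the calculated target (here 0.127/0.168 ≈
76 %) because part of the compound adsorbs to cells, vessel surfaces or
medium proteins; the model makes no attempt to partition that loss.

## Synthetic data generator

`metapress.synthetic` emulates the *statistical structure* of a DIA
metaproteomic time course, not the mass spectrometry itself:

* **Intensity model.**  Each protein group p of species s has a fixed base
  level b<sub>sp</sub>; per-species base levels are drawn log-normally
  (σ = 1) and normalized so species totals equal the community's baseline
  proportions.  A sample's intensity is
  x = b · m(stage, day) · exp(σz − σ²/2) with z ~ N(0,1).  The log-normal
  noise is the standard model for label-free LC–MS intensities; the
  −σ²/2 mean correction makes E[x] equal the deterministic part, so
  planted effects translate exactly into expected stage-mean fold changes.
  Default σ = 0.1.
* **Planted effects.**  Species effects are multiplicative folds on all of
  a species' proteins per stage; pathway effects multiply proteins
  annotated to the pathway by 2^β; pathway *trends* add a per-day slope
  2^(slope·(day − stage start)) within a stage.  Effects are applied to raw
  intensities *before* closure to relative abundance, so a planted
  intensity fold does not equal the resulting relative-abundance log₂FC:
  closure redistributes shares (one species up pushes all others down).
  The generator therefore records, per stage and stage pair, the *exact*
  expected species abundances and log₂FCs (and pathway log₂FCs on both the
  summed-intensity and relative-abundance bases) implied by the planted
  multipliers; recovery tests compare estimates to these, not to the raw
  folds.
* **Annotation space.**  40 pathways × 20 reference KOs by default, with
  each pathway sharing one KO with its neighbour (multi-pathway KOs exist);
  70 % of proteins carry a KO, mirroring the typical fraction of a
  metaproteome assignable by automated KEGG annotation.
* **Baseline community.**  The default 8-species proportions (0.05, 0.30,
  0.10, 0.15, 0.10, 0.05, 0.20, 0.05, dominated by *B. thetaiotaomicron*
  and *E. coli*) were fixed once as a plausible steady-state proteomic
  biomass profile for a SIHUMIx-like community.
* **Metabolites.**  A 10-compound SCFA panel (acetate 60, propionate 20,
  butyrate 15, lactate 5 mmol/l, …) with Gaussian noise at 5 % of baseline,
  clipped at zero, and 556 untargeted log-normal features.

What the generator does **not** emulate: peptide-level inference,
missingness patterns of DIA search engines (an optional dropout model was
considered and left out — defaults have no missing values), between-batch
normalization artefacts, compositional count noise, inter-species growth
dynamics, or correlated protein co-regulation within operons.  Passing
recovery tests therefore demonstrate correctness of the estimators and
screens under the stated noise model, not robustness to every failure mode
of real LC–MS data.

## Quantification choices

* "Coverage" of a pathway = distinct detected KOs ÷ reference KO count
  (default; a protein-based numerator is available via
  `coverage_basis="protein"`).  Both filter thresholds are inclusive:
  ≥ 5 protein groups and ≥ 15 % coverage.
* A protein group annotated to k pathways contributes its full intensity to
  each (no splitting); an optional fractional-split mode divides by k.
* Protein groups shared across species are rejected by default (species-
  specific databases should not produce them); `on_shared="split"` divides
  the intensity equally.
* Samples with zero total intensity are excluded with a warning; a zero
  species total makes that species' within-species profile missing (NaN)
  for the sample, dropped pairwise downstream.

## Statistics

* Kruskal-Wallis uses mid-ranks and the standard tie correction; a family
  where every pooled value is identical returns H = 0, p = 1.  The χ²
  approximation (k − 1 df) is coarse for tiny samples: against exhaustive
  permutation oracles at N ≤ 8 the absolute p-error can reach ~0.15 in the
  decision-relevant region, which the test suite documents and enforces as
  a bound.  At the design's actual group sizes (12/28/16 samples) the
  approximation is accurate (null rejection 5 % ± 2 pp, verified by
  simulation).
* Dunn's z uses the Kruskal-Wallis shared ranking with tie term
  Σ(t³ − t)/(12(N − 1)) and two-sided normal p-values.
* Benjamini-Hochberg adjustment is applied only to families larger than 20
  tests; smaller families keep raw p-values and are flagged unadjusted.
  This mirrors the convention of adjusting only "multiple comparisons
  involving more than 20 independent tests"; set `apply_threshold=0` to
  always adjust.
* log₂FC = log₂(mean(stage A)/mean(stage B)) over all samples of each
  stage; zero means make the value undefined (NaN, excluded from the fold
  screen with a warning).  For species and pathway *profiles* the fold
  change is computed on relative abundance; for pathway summed intensities
  and metabolites on the raw scale.  Both pathway bases are computed and
  reported side by side, since published analyses mix them.
* The screen requires p < 0.05 (strict) and |log₂FC| ≥ 0.175 (inclusive).
* PERMANOVA follows Anderson's formulation: SS_total = Σ d²/N over all
  pairs, SS_within from within-group pairs, pseudo-F =
  (SS_A/(a−1))/(SS_W/(N−a)), p = (1 + #{F\* ≥ F})/(1 + n_perm) with free
  label permutation, seeded.  With all pairwise distances equal this gives
  F = 1 and R² = (a−1)/(N−1), the adonis2 behaviour.  Default 999
  permutations, Euclidean distance on relative-abundance profiles;
  Bray-Curtis and Aitchison (CLR with pseudocount = half the minimum
  positive value, then Euclidean) are options.  PCA is centered-only by
  default (standardization available), computed by SVD with a
  deterministic sign convention (largest-magnitude loading positive).
* Spearman p-values use the t approximation with n − 2 df; for n ≤ 7 they
  agree with exhaustive permutation p within ~0.1 in the decision-relevant
  region (documented bound).  Days are integers, so samples from different
  bioreactors on the same day are genuine ties handled by mid-ranks.

## Temporal decoupling

The within-species pathway share divides by the species' own total, so it
is exactly invariant to any per-sample rescaling of that species'
intensities.  Spearman's ρ depends only on ranks, so the correlation
records are bit-identical under such rescaling — the property is tested as
exact equality, not approximate.  The BH family is the full set of tested
(species, pathway) pairs in one run; species contributing no proteins to
any candidate pathway are recorded as non-contributing rather than
silently dropped.  Candidate pathways default to the screened set from the
stage statistics; both lists can be supplied explicitly.

## Calibration and power studies

`metapress.calibration` runs the simulation studies reported by
`scripts/acceptance.py`, at a community size of 64 proteins per species and
20 pathways — chosen so that a 100-replicate study keeps ≥ 500 protein
features per run and completes in about a minute on one core:

* **Null calibration:** no planted effects, σ = 0.1; feature-wise KW
  rejection at α = 0.05 lands at ~4.8 % (51 200 tests), and PERMANOVA
  p-values on null species profiles are uniform (KS test).
* **Power:** planted species folds (one up 1.6×, four down 0.6–0.75×,
  implied |log₂FC| ≥ 0.3 after closure) and pathway effects (β from ±0.26
  to −1.0) are recovered by the screen with power 1.0 over 100 replicates;
  mean estimated log₂FCs sit within 0.002 of the exact implied truth.
  The pathway scenario plants no species folds, so each pathway's expected
  summed-intensity log₂FC equals the planted β exactly; when both effect
  types are planted together the implied expectations interact (a species
  fold shifts every pathway that species contributes to), which is why
  recovery is always judged against the generator's exact ground truth.

## Known limitations

* No repeated-measures modelling; see above.
* The χ²/normal/t approximations are asymptotic; per-day group sizes below
  ~5 samples should be interpreted via the documented approximation bounds.
* Relative-abundance log₂FCs are compositional: closure makes unperturbed
  features move when a dominant feature does.  The within-species
  normalization removes this for pathway-in-species questions; species-level
  conclusions should consider it.
* The washout model assumes instantaneous mixing and no desorption of
  compound bound to cells or surfaces; measured recovery concentrations may
  sit above the exponential prediction if bound compound re-enters the
  supernatant.
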
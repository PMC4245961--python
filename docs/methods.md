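# Methods

`palfork` models the fate of a long DNA palindrome inserted in the
*E. coli* chromosome (at *lacZ*) when the hairpin endonuclease SbcCD is
expressed. This note records the model, its assumptions, the tunable
parameters, the synthetic-data design, and the numerical choices.

## The per-replication-cycle survival model

A palindrome can fold back on itself wherever its DNA is single-stranded.
At a replication fork the lagging-strand template is transiently
single-stranded, and — for a *perfect* palindrome — enough single-stranded
DNA is exposed between helicase and leading-strand polymerase for a
hairpin to nucleate on the leading-strand template as well. SbcCD cleaves
hairpins, converting them into double-strand breaks on the respective
sister chromosome.

Per replication cycle, let `p` be the probability that the
leading-strand-template hairpin is cleaved and `q` the probability for
the lagging-strand-template hairpin. The two cuts land on different
sisters, so:

* **rec+ host** — a broken sister is repaired by RecBCD-dependent
  homologous recombination using the intact sister as template. The
  locus is lost only when both sisters are cut:
  `R+ = 1 − p·q` remaining per cycle.
* **recB host** — no repair; every cut chromosome leaves the intact
  band. Averaged over the two sisters the per-cycle *loss* is
  `(p + q)/2`, i.e. remaining `R− = 1 − (p + q)/2`. We write the recB
  expression as a remaining fraction `1 − (p+q)/2` because `(p+q)/2` is
  dimensionally a loss: at `p = q = 0` nothing can be lost.

Loss compounds multiplicatively. After `t` minutes at generation time
`τ` the remaining fraction is `R**(t/τ)`; generations are continuous
because sampling times need not be multiples of `τ`. An interrupted
palindrome (central asymmetry ≥ ~20 bp) folds only on the lagging
template, so it is the special case `p = 0`. With replication off
(a dnaA-ts host at 42 °C) no hairpin can form and `R = 1`.

Assumptions worth keeping in mind:

* repair in rec+ always succeeds when an intact sister exists, within
  the same cycle, and the repaired copy is not re-cleaved that cycle
  (re-cleavage scenarios are simulated explicitly, see below);
* the loading-control locus (*cysN*, on the opposite side of the
  chromosome) is never cleaved and doubles each cycle, so the
  probed:control signal ratio equals compounded remaining fraction;
* DNA of dead or arrested cells stays in the harvested culture (a
  Southern blot of a whole culture does not distinguish live from dead
  DNA). The `population` simulator mode relaxes this for cell counts.

## Mechanistic hypotheses and their signatures

Four mechanisms could explain death of rec+ cells carrying a perfect
palindrome; the simulator (`palfork.simulate`) implements each, and
`palfork.cleavage.discriminate` encodes their qualitative signatures:

| hypothesis | replication needed? | recB loss > interrupted? | Ruv needed? |
|---|---|---|---|
| A: cruciform extrusion + cleavage | no | — | possibly |
| B(i): re-cleavage cycle on one repaired sister | yes | no | no |
| B(ii): re-cleavage of both repaired sisters | yes | no | no |
| C: dual hairpins cleaved during replication | yes | yes | no |

The discriminating observations are replication dependence of the loss
(hypothesis A predicts loss without replication) and whether the recB
loss for the perfect palindrome exceeds the interrupted-palindrome
level (re-cleavage mechanisms act through repair, which recB lacks, so
they cannot produce excess recB loss; dual hairpins can). The observed
combination — loss in rec+, replication dependent, enhanced in recB,
Ruv-independent — selects hypothesis C uniquely.

## Simulator

`paper_simple` mode tracks chromosome counts through binomial draws:
every chromosome replicates each cycle, sisters are cut independently
with probabilities `p` and `q`, and the repair rule of the genotype is
applied. This is the exact Monte-Carlo counterpart of the closed form
and agrees with it within binomial error (tested at 4 standard errors
over a 5×5 probability grid, N = 10⁴–2·10⁴, generations 1–4).
`population` mode additionally arrests cells that cannot restore an
intact locus; their DNA is frozen into the harvested-culture counts.
B(i)'s within-cycle break/repair loop is capped at
`max_recleavage_rounds = 10` (per-sister probability of ending a cycle
broken is then `q**11`), which terminates the "endless" cycle while
preserving its phenotype of survival with chronic breakage. Hypothesis
A has no measured rate; `cruciform_cleavage_prob` defaults to 0.5 per
cycle-time and is used only for qualitative contrasts. One
`numpy.random.default_rng(seed)` generator per simulation, draws
consumed in a fixed order: the same seed gives bit-identical results.

## Blot quantification

Per lane: subtract the lane background from both band signals, divide
probed by control, then divide by the reference ratio — the same
strain's T0 lane, or the palindrome-free strain matched on treatment,
timepoint and replicate — and report `100·(1 − ratio)` % loss.
Background is per-lane (a gel-wide background is the degenerate case of
repeating one value). The normalization is scale-invariant by
construction. Negative loss estimates, which arise from noise, are
clipped to 0 with a warning because loss is reported on [0, 100].
Replicate summaries report mean, SEM (sample SD/√n; undefined at n = 1)
and n; no testing beyond mean ± SEM is provided.

## Inference

`fit_cleavage` minimises Σᵢ (R(p,q)^{tᵢ/τ} − (1 − lossᵢ/100))² on the
remaining-fraction scale. A log-scale objective would let observations
near 100 % loss dominate, and the linear scale matches how losses are
reported. The constrained 1-D problems (`lagging_only`: p = 0;
`equal_both`: p = q) are solved by grid search at resolution 0.001
followed by bounded scalar refinement; ties on flat regions resolve to
the smallest value. The `free` mode is reported but flagged
non-identifiable: recB data constrain only `p + q` and rec+ data only
`p·q`. The profile interval (parameter values with RSS ≤ 1.5·RSS_min)
is a quick identifiability readout, not a calibrated confidence
interval; at σ = 0.1 it covers the true parameter well under 90 % of
the time, and the package's recovery guarantee is instead the median
absolute error of the point estimate (≤ 0.05 at σ = 0.1, verified in
the test suite over 300 seeded time courses). Observed losses of 100 %
are handled by flooring the remaining fraction at 1e−12.

## Synthetic data

`GeneratorConfig` defaults encode the experimental design the analysis
targets: strains = {no palindrome, perfect 460 bp, interrupted 480 bp}
× {rec+, recB}; treatments arabinose (SbcCD induced) and glucose
(repressed, so p = q = 0); timepoints 0/30/60/120 min; three biological
replicates; generation times 23 min (rec+) and 56 min (recB). True
parameters default to `p = q = 0.75` for the perfect palindrome (the
symmetric level matching the observed rec+ loss) and `q = 0.7, p = 0`
for interrupted palindromes (inside the 50–75 % regime the interrupted
time courses support). Signals carry multiplicative lognormal noise
(σ = 0.1 by default — the real densitometry noise is unknown; this
value gives SEM magnitudes of a few percent, comparable to published
error bars) plus an additive per-lane background (level 10 on a base
signal scale of 1000). The dnaA-ts condition sets replication off and
halves total DNA yield; the yield factor cancels under control
normalization, as intended.

What the generator does *not* emulate: gel-image artefacts
(smearing, saturation), correlated noise between lanes of one gel,
partial SbcCD induction kinetics, and RecBCD degradation kinetics of
broken fragments. Passing round-trip tests therefore shows the analysis
chain is self-consistent under the stated noise model, not that it is
robust to every real-gel pathology.

## Sequence scanning

Palindrome sites are found by expanding exactly-complementary arms
outward from every candidate spacer placement (spacers 0..`max_spacer`),
keeping maximal arms ≥ `min_arm`, collapsing multiple decompositions of
one span to the maximal-arm one, and suppressing spans nested inside a
reported span. The scanner is verified in both directions against an
exhaustive span checker on sequences ≤ 2 kb. SbcCD susceptibility uses
a total-length threshold of 36 bp — the conservative upper end of the
enzyme's in-vitro lower size limit (20–36 bp) — so short genomic
palindromes are classified as untargeted. Spacers of 1–19 bp are
uncharacterised experimentally and are flagged `unknown` (treated as
lagging-only downstream) rather than silently classified.

## Problem sizes and determinism

Simulation-based checks use 10⁴–10⁵ chromosomes and 1–4 generations;
recovery studies use 300 seeded time courses; scanner cross-checks use
sequences of 250–1100 bp. All stochastic components take explicit
integer seeds. `scripts/acceptance.py` recomputes the headline
quantities (closed-form loss, grid correspondence, fitted cleavage
probabilities) deterministically and uses its `--seed` only for the
Monte-Carlo cross-check printed to stdout.

## Known limitations

* Exact arm matching only; mismatched quasi-palindromes, ambiguity
  codes, folding thermodynamics and supercoiling-dependent extrusion
  kinetics are out of scope.
* The viability classifier is qualitative (kill probability threshold
  0.05/generation, configurable); it does not model SOS induction,
  filamentation or growth curves.
* The free two-parameter fit is structurally non-identifiable from a
  single-genotype time course; only the constrained modes should be
  interpreted.
* recB cells with broken chromosomes may or may not continue residual
  replication before arrest; the two simulator modes bracket the
  possibilities.
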
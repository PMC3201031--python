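# Methods

## Scope and model structure

The package models translation reinitiation on a simplified *GCN4* mRNA
carrying only uORF1, uORF4 and the main ORF (removing uORF2/3 is known
not to change the regulatory behaviour, since ribosomes they would
capture are captured by uORF4 instead).  Three levels of description
share one parameterisation:

1. a **two-factor closed-form model** of the post-uORF1 binding race
   between scanning, ternary-complex (TC) acquisition and acquisition of
   a hypothetical extra factor X needed only at the main start codon;
2. a **one-factor reduction** without Factor X, adequate at natural
   intercistronic spacings;
3. a **lattice Gillespie simulator** adding 5'-initiation, 36-nt steric
   exclusion, 60S joining, codon-wise elongation and termination.

Common simplifying assumptions, shared by all tiers: no reverse
scanning, no scanning abortion, no leaky scanning (a ribosome holding
TC always initiates at the next start codon it reaches), no TC
dissociation, non-cooperative factor binding, constant scanning speed,
and full ribosome release after uORF4 or main-ORF termination.  mRNA
synthesis and decay are outside the model: the simulated mRNA lives
forever, so summaries describe the quasi-steady state of a persistent
transcript.

## The closed forms and their sample space

At every nucleotide, the embedded jump chain of the continuous-time
kinetics selects among the available reactions with probabilities
proportional to their propensities; survival of an `n`-step scan against
a competing process of rate `a_D` is `[a_S/(a_S+a_D)]^n`.  (The time
integral of the transit density `a_S^n t^n/n! · exp[−(a_S+a_D)t]` is
this survival probability divided by the total rate `a_S+a_D`; the
survival form is the quantity the models use.)  The two main-ORF paths
for the full uORF1+uORF4 construct are written as direct summations,
kept structurally identical to their defining equations rather than
reduced to geometric closed forms — all use cases have `n ≤ ~600`, where
direct summation is exact, fast and more legible.

One subtlety found while validating against the Monte-Carlo oracle: the
X-before-uORF4 path sums X-binding indices `0..n1` *inclusive*, so an X
binding exactly at the uORF4 position is shared with the `i = 0` term of
the bare-arrival path.  The two paths therefore overlap in a boundary
event of probability `P_S1^n1 · P_X1 · (1−P_S3^n2)` (≈0.5% of P2+P3 in
the fitted regimes, but dominant as binding ratios approach 1, where
P2+P3 can exceed P1).  The package reproduces the summations as defined
— they are what the published mutant predictions come from — and the
property tests assert the sharp corrected inequality
`P2 + P3 − shared ≤ P1`.

## Parameters

| symbol | meaning | default | notes |
| --- | --- | --- | --- |
| a_S | scanning rate | 30 nt/s | one 1-nt step per event |
| a_TC/a_S | TC binding ratio | 4.6% / 0.57% (two-factor, replete/starved); 4.5% / 0.66% (one-factor) | fitted condition profiles |
| a_X/a_S | Factor-X binding ratio | 0.72% / 5.4% | two-factor model only |
| a_I | 5'-initiation rate | 0.087 s⁻¹ | nominal replete operating point |
| rate_60S | 60S joining | 30 s⁻¹ | not rate limiting |
| codon rates | elongation per codon | uniform 30 | one 3-nt step per event |
| stop rate | termination | 30 s⁻¹ | uORF translation not limiting |
| p_resume | post-uORF1 resumption | 0.5 | "nearly half remain" |
| footprint | ribosome exclusion | 36 nt | position = 5'-most nt |
| protocol | duration/burn-in/replicates | 3600 s / 600 s / 50 | time-averaged over [burn-in, end] |

**Rate-unit convention.**  All rates are carried on a common "nt/s"
scale and interpreted as per-second propensities of their elementary
events: a scanning event advances 1 nt, an elongation event 3 nt.  This
makes the published ratio tables directly usable and treats "30 nt/s"
elongation as 30 codon-steps/s.  The alternative reading (propensity =
rate/3 for codon steps) would slow uORF translation three-fold; because
the uORF dwell time is the only part of 5'-residence that does not scale
in the joint-rescaling experiment, that choice measurably degrades the
ratio-invariance result, and the adopted convention is both the declared
and the better-behaved one.

**Default mRNA layout.**  1534 nt total; 5'-section nt 1–555; main ORF
556–1398; uORF1 at 175–189, uORF4 at 390–404 (each 4 sense codons +
stop), giving the natural spacings n1 = 200, n2 = 151; four in-frame
histidine codons at 700/901/1066/1240.  Only the section boundary, the
main-ORF start and the spacings are anchored in published coordinates;
the remaining positions are package defaults, and everything is
overridable through the YAML layout config or `layout_from_distances`.

## Simulator conventions

* Direct-method SSA; per-event propensity recomputation over the ≤ ~43
  resident ribosomes (cheap at these densities).  The hot loop is
  JIT-compiled with numba when available; a pure-Python fallback runs
  the identical code path.
* 5'-initiation fires only while nt 1–36 are unoccupied.  Loaded 43S
  complexes carry TC and always initiate at uORF1; TC re-acquisition
  events apply only to post-uORF1 resumed scanners.
* After uORF1 termination the resumed 40S continues from the stop-codon
  position (no repositioning hop, which would need its own exclusion
  rule).  The effective resume→uORF4 race distance is therefore
  `uorf4_start − (uorf1_end − 2)` = n1 + 3; the single-ribosome-limit
  tests use this distance in the one-factor closed form.
* A TC-less scanner arriving at the main-ORF start codon dissociates:
  there is no downstream start codon to serve, the closed forms count TC
  acquisition only up to that arrival, and 3'-section occupancy remains
  a measure of translating ribosomes.  (A scanner reaching the 3'
  lattice end also drops off, defensively.)
* Without a nucleotide sequence, the main ORF is decoded at the codon
  table's mean sense rate, with the annotated histidine positions using
  the CAU/CAC rates times the starvation fold.  A user codon table
  (whitespace-delimited `CODON RATE [STOP]`, all 61 sense codons
  required) refines these values but cannot recreate position-specific
  rate profiles; published coding-region figures that depend on the true
  codon order are consequently reproduced as qualitative properties
  (unimodality of the TC dependence, invariance of 5'-loading to
  histidine starvation, monotone growth of 3'-loading, bounded 3'/5'
  ratio), not as curves.
* Occupancies and the 5'-free probability are accumulated exactly per
  inter-event interval clipped to the analysis window — there is no
  sampling grid.  The time-averaging is validated by a Little's-law
  check against an analytic expectation in a sparse-loading regime.
* Replicate seeds are spawned from the master seed with numpy's
  `SeedSequence`, making every aggregate bit-for-bit reproducible.

## Fitting

Binding ratios are searched in log10 space within [1e-4, 1] by a
stochastic-ranking (μ,λ) evolution strategy (λ = 200, μ = λ/7, 200
generations by default; self-adaptive per-coordinate step sizes;
ranking pressure 0.45, the literature default for the method).  The
objective is the Euclidean distance between observed and predicted
percentages, one condition at a time.  Bound violations enter through
the stochastic-ranking comparison rather than rejection.  The
best-ever individual is returned, so the reported history is monotone.

Because the original reporter measurements are not redistributable, the
package ships a synthetic-dataset generator: model predictions at a
design of (construct class, n1, n2) points plus additive Gaussian noise
truncated at zero.  The default design uses eight uORF4-percentage
points with n1 spanning 32–350 nt at the natural n2 — the
experimentally probed range — plus four main-ORF points from
uORF4-less constructs, with noise SD 3 percentage points as a
realistic reporter-assay error.  Parameter-recovery tests on these data
show what the machinery can do (exact recovery noise-free; ±25% at
noise SD 3), not that the published ratios are re-derivable: real
reporter data carry normalisation and between-construct systematics the
generator does not emulate.  The extra-factor ratio is deliberately
left one-sided identifiable under starvation-like designs (the
objective is flat above ~0.4× the optimum), reproducing the published
identifiability structure.

## Problem sizes and tolerances

Closed forms are exact (float64; `1−p^k` via `expm1`, powers via log
space).  Oracle comparisons use 1e5 walkers and 3 binomial SE.  The
simulator's acceptance experiments use the full published protocol
(60 min, 10–60 min analysed, 50 replicates); unit tests use shorter
horizons (5–60 min, 2–20 replicates) chosen so each check retains ≥3-SE
discrimination.  The joint-scaling experiment spans folds 1–5 of the
nominal operating point with the TC ratio held fixed (i.e. a_TC scales
with a_S), so the reinitiation pattern is preserved while absolute
traffic scales.

## Known limitations

* The measured five-fold joint-scaling change in 5'-occupancy is ~12%
  rather than a few percent: the uORF dwell time (60S joining +
  elongation + termination) does not scale with scanning, and its
  absolute size depends on termination/elongation constants for which
  only scale-level information is published.  The qualitative
  conclusion — 5'-polysome size is set by a_I/a_S, not by either rate
  alone — is unaffected and is what the tests assert.
* Factor X is carried only by the closed forms; the simulator takes the
  one-factor parameterisation (natural spacings make X saturating).
* No mRNA turnover, no secondary structure, no sequence-resolved codon
  usage, no ribosome-profiling-style positional output.
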
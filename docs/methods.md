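# Methods

This note documents the models and procedures implemented in
`nloswitch`, their assumptions, the parameters that matter, and the
numerical and design choices made where the design was genuinely open.
All β and contrast magnitudes are atomic units (a.u.) throughout; no
SI/esu conversion is performed anywhere in the core operations.

## The design problem

A hexaphyrin redox switch interconverts between macrocycle states with
26, 28 and 30 π electrons (**26R**, **28R**, **30R**).  The 26R and 30R
states carry a large second-order NLO response ("ON"); the 28R state is
(often) centrosymmetric and silent ("OFF").  Chemical functionalization
— peripheral substituents on three symmetric pairs of meso bridges
(R1,4; R2,5; R3,6) and NH→O/S/Se replacement on two pairs of core
positions (X, Y) — tunes the contrast between states.  The package
searches this discrete functionalization space for patterns maximizing
a switch figure of merit.

The search space is combinatorial: a pattern assigns one library
fragment to each site set, and the space size is the product of the
per-site library sizes after validity rules.  Validity rules are data,
not code: the one shipped by default excludes O/S/Se on the X sites of
any scaffold containing the 26R state (those structures would be
charged), so 26R-based scaffolds print a fixed NH in the first position
of the canonical `X_Y_R1,4_R2,5_R3,6` name.  The default fragment
libraries (meso: H, CH3, F, OH, NH2, CN, NO2; core: NH, O, S, Se) are
configurable in code or YAML; the strong-donor set {OH, NH2} and
strong-acceptor set {CN, NO2} used by all composition statistics are
fixed by definition (F and CH3 are "weak" and never counted).

## HRS response

For plane-polarized incident light with the scattered beam collected
perpendicular to it, the hyper-Rayleigh-scattering response of a freely
tumbling molecule is

    βHRS = sqrt(⟨β²_ZZZ⟩ + ⟨β²_ZXX⟩),

the brackets denoting isotropic orientational averages of squared
laboratory-frame tensor components.  Both averages are quadratic forms
β·T·β in the 27 molecular-frame components.  Rather than transcribing
the published coefficient tables, the sixth-order moment tensors

    T1 = ⟨R_Zi R_Zj R_Zk R_Zl R_Zm R_Zn⟩,
    T2 = ⟨R_Zi R_Xj R_Xk R_Zl R_Xm R_Xn⟩

are constructed exactly from first principles: the Z row of a Haar-
random rotation is a uniform unit vector u whose even moments are
symmetrized Kronecker-delta sums (⟨u⊗6⟩ = Σ₁₅ pairings/105), and the X
row is, conditional on u, a uniform unit vector in the plane with
projector P = 1 − uuᵀ, whose conditional fourth moments are
(P⊗P symmetrized)/8.  Expanding and averaging over u gives T2 in
closed form.  Sanity anchors: a tensor with only β_zzz ≠ 0 yields
⟨β²_ZZZ⟩ = β²/7 and ⟨β²_ZXX⟩ = β²/35, hence βHRS = sqrt(6/35)·β.

No Kleinman (full index-permutation) symmetry is assumed at storage or
averaging level; `orientational_invariants(..., kleinman=True)`
symmetrizes explicitly for tensors tabulated in that convention.  An
independent Euler-angle quadrature (`numerical_orientational_average`,
uniform grids in the two periodic ZYZ angles, Gauss–Legendre with the
sin β/2 weight in the middle angle) arbitrates the closed form; the
test suite requires agreement to 1e-6 relative on random tensors and
rotational invariance to 1e-9 relative over 100 random rotations.
Centrosymmetric states have β ≡ 0 by parity and evaluate to exactly
zero.  The operational threshold for "effectively centrosymmetric" OFF
states is 10 a.u. (strict inequality), matching the legacy metric's
substitution rule.

## Figures of merit

Let βON, βOFF ≥ 0 be the responses of the two states.

* ratio: βON/βOFF.  Undefined at βOFF = 0; strict mode raises.
* legacy ratio: βOFF < 10 a.u. is replaced by 0.001 a.u. before
  dividing (the historical workaround; both constants configurable,
  cutoff > floor > 0 enforced, no substitution at the cutoff itself).
* difference: βON − βOFF (may be negative).
* revised: (βON − βOFF)²/(βON + βOFF), defined as 0 when both vanish.
  Identities: revised(c, 0) = c, revised(x, x) = 0; monotone in βON
  above βOFF; large OFF responses are penalized.

The three-state function for two ON states a, b sharing one OFF state
averages the two revised contrasts and divides by the dissimilarity
penalty max(βa, βb)/min(βa, βb) ≥ 1 (plain average when equal):
switches only score high when both ON channels respond comparably.
One vanishing ON response with the other nonzero is the infinite-
penalty limit; the function value is 0 and a warning is emitted.  The
per-channel contrast is the revised definition by default and is a
parameter (`three_state_contrast`), since other choices are plausible.
Two printed anchors pin this interpretation: the unsubstituted
three-state switch (contrasts 2.09e3/2.18e3, function 2.04e3, implying
a penalty of ~1.047) and the noncentrosymmetric NO2 pattern whose
independently printed OFF response (2.92e3 a.u.) is recovered to 0.3%
when the model is inverted against its printed metric triple.

## Property oracles

The package never computes electronic structure.  Oracles supply
βHRS(pattern, state):

* `LookupOracle` reads a tidy response table (pattern, state,
  beta_hrs_au).  Missing entries raise `MissingDataError` — an
  unevaluated pattern must never silently read as a centrosymmetric 0.
  When a full β tensor is attached to an entry, the scalar is computed
  through the HRS layer so there is a single source of truth.
* `SyntheticOracle` evaluates a `LandscapeSpec`: ON response = base +
  additive per-(site, fragment) effects + pairwise synergy terms +
  optional seeded Gaussian noise, clamped to [0, cap]; OFF response is
  exactly 0 unless symmetry is broken.  Everything is a pure function
  of (spec, pattern, state): string-keyed CRC32 seeds feed
  `numpy.random.SeedSequence`, so identical inputs give bit-identical
  responses across runs and platforms.

Default synthetic conditions emulate the observed data regime: ON
responses capped at 3e4 a.u. for the first ON state and 1.5e4 a.u. for
a second one (the 26R vs 30R scales); donor–acceptor pairs on distinct
meso sites receive positive synergies (the push–pull effect); OFF
symmetry breaks only when a designated substitution (NO2 on R1,4 or
NH2 on R2,5) occurs on a core-unmodified macrocycle, mimicking the
observed shielding of centrosymmetry by core modification, plus a 1%
seeded exception rate.  Under enumeration this leaves ≥90% of OFF
states exactly zero and the remainder ≤3e3 a.u., matching the reported
symmetry-broken OFF scale.  What the synthetic landscape does *not*
emulate: conformational/topology effects, frequency dispersion, any
correlation between ON and OFF magnitudes, and higher-than-pairwise
substituent coupling.  Tests passing on synthetic landscapes therefore
validate the search and analytics machinery, not quantum-chemical
accuracy.

Two curated fixtures back the replays of the published analyses.
`build_fixture_db()` materializes every printed reference value as a
per-state response table; rows printed only as metric values are
inverted to per-state responses (centrosymmetric rows trivially, the
rest by bracketing the OFF response so the penalty matches
average/function — a synthetic reconstruction consistent with print
rounding).  `fixture_landscape_26r()` is a deterministic additive +
pairwise-synergy landscape whose seven build-up anchor patterns
reproduce their printed contrasts exactly (the anchors fully determine
the parent value, three additive terms and three synergies); the
remaining fragment effects are chosen once to respect the published
qualitative site preferences and are not fitted to anything.

## Best-first search

One *site iteration* substitutes every allowed fragment on one site
set (incumbent included, so the candidate count equals the library
size), scores each candidate, and installs the argmax.  One *global
iteration* sweeps all modifiable sites in the configured sequence;
the run converges when a sweep returns its input pattern unchanged.
Defaults: `max_global_iterations=10` (observed runs converge in 2–4),
tie policy `keep-incumbent` (the incumbent survives unless strictly
beaten, which stabilizes the convergence test; `first-in-library` is
available — published runs never specify tie handling).  Fragments
excluded by validity rules are skipped, not scored at −∞, so
trajectory logs simply lack those rows.  Evaluations are cached by
canonical pattern name; caching cannot change a trajectory (verified
by a cache-disabled equivalence test) and makes incumbent
re-evaluation free.  Guarantees enforced by tests: accepted metric
values are non-decreasing; the search optimum never exceeds the
exhaustive maximum on enumerable spaces; on separable (additive,
centrosymmetric-OFF) landscapes it equals the exhaustive maximum from
any start within two global iterations.  The multi-start driver runs a
list of configurations, merges all evaluated patterns into one
deduplicated database and reports per-run optima plus the fraction of
runs reaching the best optimum found.

## Steepest-ascent attribution

Build-up analysis reconstructs an optimum from the parent: at each
step the candidates install the optimum's fragment at exactly one
not-yet-applied site (never arbitrary fragments), and the largest
metric wins.  The step count equals the number of sites where optimum
and parent differ.  Each candidate row carries

    %B    = 100·v/max,
    %(B-P) = 100·(v − parent)/(max − parent),
    %(CB)  = 100·(v − parent)/(step_best − parent),

stored at full precision and reported rounded to the nearest integer,
ties away from zero.  Negative %(CB) flags below-parent candidates.
The per-step increments of the chosen path's %(B-P) expose synergy:
a final step contributing far more than the same substitution did in
isolation means the groups act cooperatively.  Degenerate denominators
(optimum no better than parent; step best equal to parent) raise with
the offending quantity named.

## Database analytics

Quartile partitions use the 25/50/75 empirical percentiles with linear
interpolation (the convention is not dictated by any source; this is
numpy's default) and assign boundary ties to the lower group, making
the split deterministic.  A constant metric raises
`DegenerateDistributionError`.  Histograms use half-open bins
[k·w, (k+1)·w); threshold exceedance fractions are strict
inequalities.  Heatmaps count strong-donor vs strong-acceptor meso
pairs per record (each symmetric pair counts once).  All analytics are
pure functions of the input table.

## Chemical-space maps

Patterns become structures via templates.  The
`HexaphyrinTemplate` builds a hexaphyrin(1.1.1.1.1.1)-like macrocycle
atom by atom: six five-membered heterole rings 2,5-linked through six
meso carbons, with one consistent localized Kekulé assignment
(alternating pyrrole-type units and units with two exocyclic double
bonds), core sets replacing ring NH by O/S/Se and meso substituents
attached at both positions of each symmetric pair.  This is one
resonance structure of one redox state; aromaticity, ring currents and
state-dependent geometry are deliberately out of scope — the structures
exist to carry substitution topology into fingerprint space, and RDKit
canonicalization makes pattern → SMILES deterministic.  A
`SmilesTemplate` with `{site}` placeholders covers toy scaffolds.

Fingerprints are Morgan/ECFP, radius 2 and 2048 bits by default (the
common choice; no source dictates parameters).  Embeddings use t-SNE
on Jaccard (= 1 − Tanimoto) distances with a required seed; perplexity
defaults to 30 and is clamped below n_samples/3 for small inputs.  The
hand-drawn region annotation of published maps is not reproduced as a
computation; measures are exported alongside coordinates for plotting.
A one-hot site-assignment descriptor is provided as a clearly labeled
non-ECFP fallback; it carries no substructure information.

## Problem sizes and tolerances used by the test suite

Search property tests run on 4-site × 5-fragment spaces (625 patterns,
fully enumerable) with 20 random starts on separable landscapes and
seeded rugged landscapes; analytics tests use 500-record synthetic
databases; HRS tests use 20 random tensors at quadrature resolution
(16, 24, 16) and 100 random rotations.  These sizes keep the whole
suite under a few seconds while leaving every guarantee exactly
checkable.  Numerical tolerances: 1e-9 relative for rotational
invariance, 1e-6 relative for quadrature-vs-closed-form, exact
comparison for combinatorics, lookup values and printed-integer
recomputation.

## Known limitations

* Three integer percentage cells of the published build-up tables
  cannot be recovered from the printed three-significant-figure metric
  columns under any deterministic rounding (they were evidently
  computed from unrounded values); the affected cells are asserted at
  their recomputed values in the unit suite and documented where they
  occur.
* The published per-pattern databases (242/320/146 patterns) live in
  appendix material that is not included; database analytics are
  therefore exercised on synthetic landscapes and reconstructed
  fixtures, and the published group-level percentages (e.g. 6.25%,
  8%) are reproduced on constructed inputs, not re-derived from the
  original data.
* One representative switch used in the metric-comparison example has
  no printed ON response; it is fixed at 2.0e4 a.u. (the scale of its
  two companions).  Conclusions drawn from it are ordering claims that
  are robust over the full admissible range.
* The synthetic OFF-symmetry rule is a caricature of point-group
  analysis: real centrosymmetry depends on the full substitution
  pattern and conformation, not on single designated fragments.
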
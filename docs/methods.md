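# Methods

## Model

A secondary structure on `a = a1..an` is a set of base pairs `(i, j)`
drawn from {AU, UA, CG, GC, GU, UG}, nested (no pseudoknots), triple-free,
with `j - i > theta` (theta = 3 throughout; overridable for testing).
Energies follow the nearest-neighbor loop decomposition: each structure
splits uniquely into hairpin loops, internal loops (stacks and bulges as
degenerate cases, capped at 30 total unpaired bases), multiloops with the
affine cost `a + b*N_b + c*N_u` (N_b counts all stems including the closing
one), and the exterior loop.  Dangling ends and coaxial stacking are
excluded.  Tables are read from the Vienna `.par` v2.0 format; every
feature carries a (dG at 37 C, dH) pair and rescales linearly,
`dG(T) = dH - T (dH - dG37)/310.15`, with enthalpies assumed
temperature-independent.  Energies live on the integer 0.01 kcal/mol grid,
matching the established folding engines; the rescaled tables are truncated
back onto that grid except inside temperature profiles (below).
R = 1.98717e-3 kcal/(mol K).

### Evaluation conventions and the `classic` profile

Two convention profiles are shipped.  `STANDARD` reproduces Vienna-2.x
RNAeval with dangles disabled, verified exactly against ViennaRNA 2.7.2 on
randomized structures (400/400 within 0.005 kcal/mol).  `CLASSIC`, the
package default via the `turner2004-classic` parameter set, reproduces the
older evaluator style of the entropy literature: multiloop coefficients
`a, b, c = 3.4, 0.4, 0.0` kcal/mol and the terminal-AU penalty charged on
exterior stems and bulges but not on multiloop stems or triloop closing
pairs.  This profile was identified by matching published reference
entropies of a 42-nt hammerhead ribozyme (2.830), a 21-nt mRNA fragment
(2.146) and their 68-nt linker chimera (2.328); it reproduces all three to
at most 0.013 nats (0.6 %), while plain Vienna-d0 semantics deviate by up
to 0.26 nats on the chimera.  The 0.015-nat reproduction accuracy is the
tolerance asserted in the acceptance tests.

## Exact entropy (DP)

The inside recursions fill `Z, ZB, ZM, ZM1` in the usual McCaskill
decomposition (single source of truth for interval bounds, shared with the
min-plus and Q recursions).  In parallel the energy-weighted sums
`Q_ij = sum_s E(s) exp(-E(s)/RT)` and their `QB/QM/QM1` companions are
accumulated with the product rule: every term `w(e) * X * Y` of an inside
sum contributes `w(e) * (e*X*Y + QX*Y + X*QY)` to the Q analogue.  Then
`<E> = Q(1,n)/Z(1,n)` is exact and `H = <E>/RT + ln Z`.  Per-branch
multiloop costs `b` attach to every stem facing a multiloop including the
closing stem (total `a + b(k+1)` for k interior branches), and the unpaired
multiloop cost is `c*(j-k)` for trailing bases, consistent between the
`ZM1` and `QM1` recursions; exhaustive enumeration arbitrates all such
bookkeeping choices (agreement to 1e-15 in relative terms for n <= 25
across Turner, classic and Nussinov models).

Base-pair probabilities come from outside recursions with the three
enclosing contexts (exterior, internal loop, multiloop branch); the
multiloop outside sum is factorized through per-row accumulators so the
whole pass stays cubic.  `p*` extends `p` with unpaired probabilities on
the diagonal; row sums are verified to 1e-9.

The recursions are unscaled double precision, safe to n ~ 1300 at 37 C (a
homopolymer-stack bound); beyond that a `NumericRangeError` names the
offending length.  All shipped applications (100-nt windows, scans to a
few hundred nt) sit far below the limit, so Boltzmann-factor rescaling
machinery was deliberately omitted.

## Finite-difference entropy (FTD)

`ln Z` is evaluated at formal temperatures `T` and `T + dT` (uncentered,
default dT = 1e-7 K) or `T +- dT` (centered, default 1e-2 K) with the
tables fixed at the table temperature, and
`<E> ~ RT^2 * dlnZ/dT`.  As a function of the formal temperature, `ln Z`
is strictly decreasing (for stabilizing ensembles) and *convex* — its
second derivative contains the energy variance — so the systematic
finite-difference bias is O(dT) and negligible at the defaults; what
remains is double-precision differencing noise of order
`eps * ln Z / dT * RT^2`, about 1e-6 nats in H at dT = 1e-7.  A strict
mode escalates the noise-floor warning to an error when
`|delta ln Z| < 64 * eps * |ln Z|`.  DP and FTD agree to ~1e-4 nats on
hammerhead-sized inputs and to <0.05 nats on average for random 20-100-mers.

## Verification machinery

* `enumerate_structures` generates the complete structure set (cap n = 30,
  5e6 structures, refusal over silence) and `brute_force_summary` sums
  Z, <E>, H and pair frequencies directly — the oracle for everything else.
* `mfe` / `wuchty_suboptimals`: min-plus analogues of the same recursions;
  band enumeration backtracks partial structures whose optimistic
  completion bound stays within `MFE + band`, so the generated set is
  complete and duplicate-free (verified against filtered enumeration).
* `boltzmann_sample`: stochastic traceback of the inside matrices;
  seeded `numpy.random.default_rng`, reproducible draw-for-draw.
  Calibration: 50,000 draws on a 20-structure ensemble pass a chi-square
  goodness-of-fit against exact probabilities at alpha = 0.01.
* The two sampling approximations assemble `H` from the sampled mean
  energy plus the exact `ln Z` (sampling), or from the band-truncated
  ensemble with exact `ln Z` by default (`use_truncated_z` switches to
  `ln Z0`).

## Ensemble measures

Positional entropy, ensemble defect, expected base-pair distance, native
contacts, and the two structural diversities (base-pair-distance and
Morgan-Higgs Hamming forms) are closed-form functions of `p`/`p*`,
each verified against direct Boltzmann averages over the enumerated
ensemble to 1e-9.  `0 ln 0 := 0` everywhere.

## Temperature profiles and heat capacity

Temperature scans move table and formal temperature *together* (full
temperature), recomputing H, G and `<E>` per grid point (default 0-100 C,
step 1).  The heat capacity is the calorimetric
`C(T) = -T d2G/dT2`, which by Gibbs-Helmholtz equals the temperature
derivative of the Boltzmann-average enthalpy — distinct from the
formal-temperature-only derivative used by FTD; this distinction is the
central subtlety of the whole method.  Two numerical choices matter:
profiles rescale tables in real precision (no 0.01-grid truncation), since
quantization makes G(T) jagged and its second derivative pure noise; and
the second derivative is taken with a Savitzky-Golay local-parabola filter
(window 11, order 2).  With both, the integral of C over the melting
region matches the enumerated change of average enthalpy to <1 % on a
two-state hairpin.  The entropy slope `dH/dT = C/(RT) - (1/R) d<S_t>/dT`
peaks within a few Kelvin of the C(T) maximum but turns negative past the
melting midpoint, so peak proximity (not global correlation) is the tested
property.

## Genome scanning and null models

Window scans compute DP entropy per window (default 100 nt, step 10),
smooth with a centered moving average over an odd number of windows
(default 5), and report Z-scores of the smoothed profile against the mean
and population standard deviation of all windows of the same scan
(smoothing precedes standardization).  Degenerate scans (zero spread)
report Z = 0 with a warning.  Dinucleotide shuffles use the Eulerian-path
(Altschul-Erikson) construction — random last-edge tree, rejection until
connected, shuffled remaining edges — preserving first/last letters and
exact dinucleotide counts; empirical draws on a 9-mer with six valid
shuffles are uniform by chi-square.  Shuffle Z-scores use the sample
standard deviation of the null.  Hybridization entropy approximates a
two-strand complex by folding `strand1 + AAAAA + strand2`; single-strand
terms are computed on the bare strands (the linker enters only the
complex), matching the published arithmetic
`dH = -H(complex) + H(s1) + H(s2)`, `dS = k_B dH`, `-T dS = -RT dH`.

## Synthetic data

Random RNA is i.i.d. with user-specified composition (default uniform
0.25 per letter), seeded.  These sequences emulate the compositional
statistics of the random-RNA benchmarks but none of the covariation,
codon or repeat structure of biological sequences, so passing tests bound
algorithmic correctness, not biological generality.  The length-normalized
entropy level of such sequences (constant fit of the H/n profile over
lengths 50-300, 10 sequences per length) comes out at ~0.077-0.079
nats/nt under either convention profile, somewhat below the published
asymptotic slope of 0.087 fitted over lengths 20-500.

## Known limitations

* No dangles, coaxial stacking, pseudoknots, lonely-pair prohibition, or
  IUPAC ambiguity codes.
* Hybridization entropy via linker concatenation is an approximation; no
  true two-strand partition function.
* Unscaled recursions limit n to ~1300.
* The `classic` profile is a reconstruction calibrated on three published
  values; residual deviations of up to ~0.015 nats remain.
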
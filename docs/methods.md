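# Methods

## Motif arrangement grammar

A composite element is a core motif M (uppercase A/C/G/T, length ≥ 2)
arranged as a single copy, a direct tandem repeat (k ≥ 2 copies on the same
strand), an inverted tail-to-tail pair, or an everted head-to-head pair,
with an optional spacer of s ≥ 0 nucleotides between copies. Taking the
motif's 5′ end as its "head", the orientation convention is

* inverted (tail-to-tail): `M + spacer + reverse_complement(M)`
* everted (head-to-head): `reverse_complement(M) + spacer + M`

The exact probe sequences behind the published head-to-head/tail-to-tail
affinities are not public, so this convention is a package choice; it is a
pure relabelling (the two layouts swap), is recorded in output metadata, and
none of the downstream statistics depend on which name attaches to which
composite.

Scanning uses 0-based half-open coordinates (BED convention). Spacer
positions match any base (wildcard `N` in the pattern; genomes handled here
contain no literal N bases); when a composite is *expanded* into a concrete
probe (for planting in synthetic genomes), the spacer fill base defaults to
C, which does not occur in the TGAA/TAAT cores and therefore cannot create
accidental extra motif copies. All overlapping occurrences are reported.
Minus-strand occurrences are positions where the reverse complement of the
composite matches; a composite that equals its own reverse complement
(every spacer-0 inverted or everted pair is such a palindrome) is scanned
once so each interval appears a single time. The scanner is regex-based
with a look-ahead so overlaps are not swallowed; its contract is checked
against a naive position-by-position oracle in the tests.

## ChIP binding-probability curves

Each motif occurrence defines a window of ±25 bp (configurable) around the
site, clipped at chromosome ends. A read is assigned to every window it
overlaps by at least `min_overlap` bp (default 1); windows of different
classes count reads independently, duplicate reads are kept, and full read
intervals are used (not 5′ ends) — these policies are recorded in the run
manifest. Counting uses per-chromosome sorted-array bisection
(O((n+m) log n)) and is verified against an all-pairs oracle.

The per-class curve is the empirical CDF of window counts evaluated at the
distinct observed counts. An optional presentational smoother replaces the
ECDF by the integral of a Gaussian kernel density estimate, renormalized to
end at exactly 1 and forced monotone; class comparisons always use the raw
counts, never the smoothed curve. Pairwise class shifts are reported as the
median difference, the two-sided tie-corrected Mann–Whitney U test and the
two-sample Kolmogorov–Smirnov distance; the "right-shifted" class is the
one with the larger median. Two identical constant samples make the
rank-sum tie correction degenerate, so that case is short-circuited to
p = 1. For ordering more than two classes (synthetic recovery checks), the
mean window count per class is used: with small-integer Poisson-like
counts, per-class medians tie too readily to define a strict order.

## 1:1 depletion isotherm (MST)

The labeled species is held at a concentration (0.05 µM by default)
comparable to the dissociation constants of interest, so the free-ligand
approximation fails and the exact mass-balance solution is used:

    f_bound = (P_t + D_t + K_d − sqrt((P_t + D_t + K_d)² − 4 P_t D_t)) / (2 P_t)

The measured signal is an affine map `baseline + amplitude · f_bound`.
Fitting minimises squared residuals over (log10 K_d, baseline, amplitude)
with scipy's trust-region reflective solver from a fixed grid of eight
log-uniform K_d starts over 0.01–100 µM, making the fit deterministic given
the data. Replicates are pooled. The 95% interval on K_d comes from the
Gauss–Newton covariance of log10 K_d. Data whose fitted amplitude is
indistinguishable from zero, or whose K_d runs to the edge of the search
range, raise a fit error rather than returning a meaningless constant.
A multi-site probe fitted with this model yields an *apparent* K_d, which
is how single-K_d-per-probe summaries are produced for tandem elements.

## Sequential two-event model and ITC

A duplex D with two protein sites follows the macroscopic stepwise scheme
D + P ⇌ DP (K_d1), DP + P ⇌ DP2 (K_d2). With the binding polynomial
Z(p) = 1 + p/K_d1 + p²/(K_d1 K_d2), the DNA states are D_t/Z,
D_t (p/K_d1)/Z and D_t p²/(K_d1 K_d2)/Z, and free protein p solves
P_t = p + [DP] + 2[DP2]. The left side is strictly increasing in p, so the
root in [0, P_t] is unique; it is found by Brent bracketing to 1e-14
relative tolerance, and mass conservation holds to better than 1e-8.

The ITC forward model uses the standard perfusion-cell displacement
corrections. After cumulative injected volume V into a cell of volume V0,
with r = V/(2 V0):

    D_t = D0 (1 − r)/(1 + r),   P_t = P_s (V/V0)/(1 + r)

The total heat content is Q = V0 (ΔH1 [DP] + (ΔH1+ΔH2)[DP2]) (µcal via
1 µL·µM·kcal/mol = 1e-3 µcal), and the measured heat of injection i with
volume v_i is

    q_i = Q_i − Q_{i−1} + (v_i/V0)(Q_i + Q_{i−1})/2 + offset · v_i

with a constant per-volume dilution offset co-fitted. Past saturation the
binding increment per injection decays monotonically; a small second-order
(r²) displacement term remains in the exact model, which is why late
heats approach but do not exactly equal the dilution term.

Model selection between one and two binding events uses AICc
(n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)); the event count of the lower-AICc
model is reported as the protein:DNA stoichiometry. Two guards flag a
selection unreliable: ΔAICc < 2 between the binding models, or failure of
the selected model to beat a no-binding (dilution-offset-only) null model
by at least 2 AICc. The second guard exists because on pure noise AICc
prefers the smaller model by its parameter penalty alone (ΔAICc ≈ 3–7),
which would otherwise look like a confident one-event call.

The cooperativity factor is ω = 4 K_d1/K_d2: two identical independent
sites give K_d1/K_d2 = 1/4 from statistical factors (two ways to bind the
empty duplex, two ways to leave the full one), so ω = 1 means independence
and ω > 1 positive cooperativity, classified with 1e-6 relative tolerance.

## Synthetic data

Generators are pure functions of (specification, seed); seeds are split
per chromosome/site/replicate with numpy `SeedSequence.spawn`, and identical
inputs produce byte-identical outputs (a within-package contract, not a
cross-version one).

* **Genomes** — i.i.d. background bases at a configurable GC fraction
  (default 0.36, a plant-genome-like value); planted composites are placed
  uniformly at random without overlap and with a minimum spacing (default
  150 nt) so ±25 bp windows of different plants rarely collide; placement
  failures after 1000 retries raise an error. Accidental motif occurrences
  in the background are permitted by design: analyses scan the generated
  genome rather than trusting the truth table.
* **Reads** — single-end, fixed length (default 50 nt). Background reads
  are Poisson(rate·length) per chromosome, uniform; each planted site adds
  Poisson(enrichment_scale · θ) reads centered on the site with Gaussian
  positional jitter (sd 30 nt), clipped to chromosome bounds. Occupancy is
  the effective single-K_d form θ = P/(P + K_d) (default nuclear protein
  1 µM): the downstream ECDF comparison consumes only the rank ordering of
  enrichment, so the full two-site polynomial is deliberately not used
  here. Defaults of 2 background reads/kb and enrichment_scale 80 give
  clearly separated but overlapping class distributions with the measured
  affinity panel (0.27/1.90/2.21/3.17 µM); no published enrichment
  magnitude exists for this system, so these are calibration choices of the
  generator, stated once here.
* **Titrations** — signal = model curve × (1 + ε), ε ~ N(0, cv), default
  cv 3%, triplicate, 16 log-spaced DNA points over 0.001–100 µM at 0.05 µM
  labeled protein (the measurement design of the source experiments).
* **ITC** — heats = forward model + N(0, sd) with the default geometry
  19 × 2 µL injections, 200 µL cell, 30 µM DNA, 450 µM protein.

### ITC simulation parameters and identifiability

The published experiments report only the two dissociation constants
(1.24 and 0.82 µM, n = 3), not the step enthalpies, so the generator must
choose ΔH1/ΔH2. The choice matters for more than realism: a Cramér–Rao
analysis of the forward model at the default geometry and 2%-of-peak heat
noise shows that when ΔH1 ≈ ΔH2 the two events are thermally
indistinguishable and the intrinsic relative standard deviation of a
single-experiment K_d1 estimate is ≈ 40% — no estimator can resolve the
split. The defaults are ΔH1 = −3, ΔH2 = −17 kcal/mol: a total of
−20 kcal/mol is realistic for two HD–DNA binding events, and loading the
extra favorable enthalpy onto the second event reflects the mechanism —
the protein–protein dimer interface only forms when the second monomer
binds. With this contrast the single-experiment bound drops to ≈ 18%, and
the triplicate global fit used in the recovery analyses (matching the
n = 3 of the source measurements) has an empirical error below 20% for
both constants across all tested seeds.

### What the generators do not emulate

Real ChIP-seq mappability and GC bias, fragment-length distributions,
paired ends, input/IgG controls and duplicate artifacts are all absent;
background is i.i.d. sequence with uniform Poisson reads. Passing the
end-to-end recovery tests therefore shows the pipeline is correct and
well-calibrated under its stated statistical model, not that it is robust
to every artifact of real libraries. Similarly, MST temperature-jump
physics and ITC baseline drift are not modeled beyond multiplicative /
additive Gaussian noise and a constant dilution offset.

## Numerical and design notes

* Problem sizes in the test suite are chosen for fast, stable statistics:
  ordering recovery uses 20 seeds of a 1 × 80 kb genome with 60 planted
  sites per class; oracle equivalence uses ≤ 10 kb sequences and
  2000 × 150 read-window instances.
* Least-squares fits are deterministic: fixed start grids, no random
  restarts. K_d bounds are 1e-6–1e6 µM; hitting a bound is reported as
  unidentifiable rather than returned.
* Degenerate inputs: empty count vectors, classes with fewer than two
  windows, zero-amplitude titrations, and injections overfilling the cell
  all raise errors; zero reads produce a valid single-step ECDF at 0.
* `fold_change` is a labelled plain ratio; both orientations are the
  caller's responsibility to report.
* BED is the canonical interval format; GTF export shifts start by +1
  (1-based inclusive) and is provided for interoperability with
  feature-counting tools. Minimal SAM input support extracts chromosome,
  position and CIGAR reference length only.
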
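# coopbind

Quantitative analysis of cooperative transcription-factor–DNA binding, built
around the homeodomain (HD) case: proteins such as the plant stem-cell
regulator WUSCHEL recognise short core motifs (TAAT, TGAA, the G-Box
TCACGTGA), and their affinity depends strongly on how motif copies are
*arranged* — tandem direct repeats allow two HD monomers to dimerise on the
DNA and bind cooperatively, while inverted (tail-to-tail), everted
(head-to-head) or spacer-separated arrangements do not.

The package provides four connected layers:

1. **Motif grammar and genome scanning** (`coopbind.motif_grammar`) —
   arrangements of a core motif M are expanded into composite elements
   (direct: `M·M`, inverted tail-to-tail: `M·rc(M)`, everted head-to-head:
   `rc(M)·M`, with optional spacer nucleotides) and located on both strands
   of a FASTA genome with BED-convention coordinates.
2. **ChIP window occupancy** (`coopbind.chip_occupancy`) — ±25 bp windows
   around each motif occurrence, per-window aligned-read counts, and
   per-class empirical cumulative distribution ("binding probability")
   curves F(c) = P(reads ≤ c). A curve shifted right means the motif class
   sits in regions of higher in vivo occupancy; pairwise shifts are
   quantified by median difference, tie-corrected Wilcoxon rank-sum and the
   Kolmogorov–Smirnov distance.
3. **Equilibrium binding models** (`coopbind.binding_models`) —
   * the depletion-corrected 1:1 isotherm for MST-style titrations,
     f_bound = (P_t + D_t + K_d − √((P_t+D_t+K_d)² − 4 P_t D_t)) / 2 P_t,
     fitted by multi-start trust-region least squares with K_d on a log
     scale;
   * the sequential two-event binding polynomial for a two-site duplex,
     Z(p) = 1 + p/K_d1 + p²/(K_d1 K_d2), with an ITC injection-heat forward
     model (perfusion displacement corrections, per-volume dilution offset)
     and AICc selection between one- and two-event models;
   * the cooperativity factor ω = 4 K_d1/K_d2 (ω = 1 for two identical
     independent sites; ω > 1 is positive cooperativity) and labelled
     affinity fold changes.
4. **Synthetic data** (`coopbind.synthetic_data`) — genomes with planted
   arrangements of known per-class K_d, reads following background-plus-
   occupancy enrichment with θ = P/(P + K_d), noisy titrations and noisy
   ITC injection series, all pure functions of (spec, seed) with
   machine-readable truth tables.

## Worked example

Simulate a triplicate MST titration at K_d = 0.27 µM (16 DNA concentrations
log-spaced over 0.001–100 µM, 0.05 µM labeled protein, 3% multiplicative
noise) and refit it:

```bash
$ cat mst_spec.yaml
kd_uM: 0.27
noise_cv: 0.03
$ coopbind simulate mst --spec mst_spec.yaml --seed 11 --out sim
$ coopbind fit-mst --input sim/titration.csv --out fit
Kd = 0.2659 uM (95% CI 0.25 - 0.2827)
```

The recovered dissociation constant (0.266 µM) agrees with the generating
value within the precision the noise allows; the interval is the
Gauss–Newton 95% confidence band on log K_d.

Simulate an ITC experiment (19 × 2 µL injections of 450 µM protein into
200 µL of 30 µM two-site DNA) from the sequential model with K_d1 = 1.24 µM,
K_d2 = 0.82 µM and fit it with automatic event-count selection:

```bash
$ coopbind simulate itc --spec itc_spec.yaml --seed 12 --out simitc
$ coopbind fit-itc --input simitc/itc.csv --model auto --out fititc
selected 2 binding event(s), stoichiometry 2:1 (dAICc=96.59)
two_event_sequential: {'kd1_uM': 1.2239, 'kd2_uM': 0.9116, 'dh1_kcal': -3.129,
                       'dh2_kcal': -17.438, 'omega': 5.37,
                       'cooperativity': 'positive', ...}
```

AICc decisively prefers two binding events (2:1 protein:DNA); the
cooperativity factor ω = 4·K_d1/K_d2 ≈ 5.4 > 1 classifies the second binding
event as positively cooperative — the second monomer binds tighter than two
independent sites would allow, as expected when a protein–protein dimer
interface forms on the DNA.

The ChIP layer composes the same way:

```bash
coopbind scan --genome genome.fa --motifs motifs.yaml --out sites.bed
coopbind chip --genome genome.fa --reads reads.bed --motifs motifs.yaml \
              --flank 25 --out chipdir/
coopbind report --chip-dir chipdir/ --out curves.png
```

`chipdir/curves.csv` holds the per-class binding-probability curves and
`chipdir/comparisons.csv` the pairwise shift statistics.

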
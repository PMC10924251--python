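# Methods

## The assay model

The phage-propagation assay couples a variant's molecular activity to the
number of phage particles carrying it: cells expressing variant *v* produce
progeny in proportion to the variant's activity, so after one selection
period the expected share of *v* in the output library is

```
freq_out(v) ∝ freq_in(v) · 10^F(v)
```

with the reference fixed at *F* = 0. The real selection period (a ~24 h
low-MOI infection) spans several infection cycles; we collapse it into a
single multiplicative factor because the log-ratio statistic measures
exactly the *net* fold enrichment per assay, whatever the within-assay
dynamics. Selection applied twice with effects *F* and *G* equals one
application with *F + G* (log-additivity), which the test suite checks.

### The fitness estimator

`fitness.fitness_score` computes

```
F = log10(v_out / v_in) − log10(r_out / r_in)
```

Choices:

- **log10 throughout**, never natural log, so that −1 ↔ 10-fold and
  10^F is always the fold change.
- **Pseudocount** c = 0.5 is added to all four counts of a row *only when
  one of them is zero*; the row is then flagged `LOW_COUNT`. When all
  counts are positive the pure formula is used. The constant is
  configurable; 0.5 is the conventional half-integer continuity correction.
- **Standard error** by the delta method under Poisson counting noise:
  `se = (1/ln 10)·sqrt(1/v_in + 1/v_out + 1/r_in + 1/r_out)`; undefined
  (NaN) when any count is zero. At the 100-read coverage floor this is
  ≈ 0.045 log10 units, so individual estimates near that floor carry
  roughly ±0.1 at two standard errors — occasional >2σ deviations are
  expected somewhere in any full-library realization, which is why calls
  near thresholds should always be read together with `se`.
- **Replicates** are scored separately and combined by inverse-variance
  weighting (plain mean when weights are undefined). The combiner is a
  free choice; inverse-variance is the minimum-variance unbiased option
  under the Poisson error model.
- **Re-referencing** subtracts the new reference's score from every row;
  pairwise differences are invariant, which the suite verifies on random
  tables.

### The synonymous null and classification thresholds

Synonymous codon variants encode the wild-type protein, so their *F*
distribution is the measurement null. Each synonymous *codon* variant is
an independent observation (they are deliberately *not* pooled into the
wild type — pooling would destroy the SD the band needs; a pooled mode
exists but is off by default). The neutrality band is mean ± 3 SD, closed
at both endpoints; its half-width as a fold change is `10^(3·SD)`. The
band is always computed from the data of the same experiment, never
hard-coded: at high depth it can be as tight as ±1.1-fold, while noisier
assays give the ~3–5-fold bands typical of this assay family.

Beneficial calls use *F* ≥ log10(threshold_fold) with the boundary
included ("at least a 10-fold increase"), and gain-of-function positions
require ≥ 2 beneficial substitutions at one residue. Both comparators are
exposed because "at least 10-fold" (closed) and ">10-fold" (open) both
appear in common usage; the default is closed. Conditional neutrality
requires neutrality in background 1 *and* benefit in background 2;
variants measured in only one background are excluded, not imputed.

## The synthetic-data generator

What it emulates, stage by stage:

1. **Library unevenness**: input frequencies from a symmetric Dirichlet
   with concentration 1/dispersion (dispersion 0 → exactly uniform). The
   default dispersion 0.3 gives the few-fold spread typical of cloned
   plasmid pools.
2. **Selection**: deterministic reweighting by 10^F as above.
3. **Sequencing**: one multinomial draw per library at the configured
   depth (default 10⁶ reads). No overdispersion beyond multinomial.
4. **Reads**: one 2×`read_len` mate pair per sampled molecule of the
   variant amplicon, mate 2 reverse-complemented. Substitution errors are
   i.i.d. per amplicon base, injected once per molecule, so the merged
   pair equals the erroneous amplicon and the fraction of error-carrying
   molecules is exactly 1 − (1 − e)^L. Qualities are constant at the
   Phred encoding of the error rate (capped Q40).

What it does **not** emulate: burst-level infection dynamics, variant-
dependent recombination or cloning efficiency, PCR jackpotting/chimeras,
indels, position- or cycle-dependent quality, and biological replicate
scatter beyond counting noise. Consequently, passing recovery tests show
that the *estimator and counting stages* are correct and well calibrated
under sampling noise — not that real assays are free of the systematic
effects above. On real data the synonymous band is expected to be wider
than pure counting noise predicts, which is precisely why the band is
estimated from synonymous variants rather than from `se`.

## Read counting

Merging slides the reverse-complemented mate 2 against mate 1 over every
overlap length ≥ `min_overlap` (default 10) and keeps the overlap with the
lowest mismatch fraction, ties going to the longer overlap; pairs whose
best fraction exceeds `max_mismatch_frac` (default 0.1) are merge
failures, recorded, never raised. Disagreeing overlap bases resolve to
the higher-quality base, mate 1 winning quality ties. Assignment is
exact-match first, then the unique equal-length reference within Hamming
distance `max_hamming` (default 1); equidistant minima are AMBIGUOUS and
out-of-range reads UNASSIGNED. With single-codon designed variants,
distance-1 assignment cannot cross variants that differ at distinct
codons; within-codon distance-1 collisions land in AMBIGUOUS by
construction. Edit-distance (indel-tolerant) matching is deliberately out
of scope: designed amplicon libraries are fixed-length, and indel reads
would be unassignable anyway. `count_reads` preserves the conservation
invariant (assigned + unassigned + ambiguous + merge-failed = pairs) and
is independent of read order; a vectorized batch engine implements the
same semantics as the scalar functions, which a dedicated test enforces
read-for-read.

## Library design

Saturation libraries program all 19 substitutions per window position
using one codon per substitution — the most-used *E. coli* codon for the
incoming residue, from a usage table shipped in `codons.py`. This "one
codon per amino acid" policy makes the missense count exactly 19 × window
length (227 × 19 = 4,313 for a 228-residue protein scanned over positions
2–228). Up to *k* synonymous codons per position (default 1) populate the
neutrality null; Met and Trp positions have none. Stop codons are
excluded from the default design; numbering is 1-based from the initiator
Met.

## Directed evolution

Each round of `evolution.run_trial`: (i) multinomial amplification of the
founders to `burst_pop`, with genotype weights count·10^F — the
Wright–Fisher selection update, whose expectation
f′ = s·f / (s·f + 1 − f) the suite checks against simulation; (ii)
Poisson(rate · locus length) substitutions per replicated genome at
uniform positions (a 4×4 bias matrix is accepted, default uniform over
the three alternatives; the zero-truncated Poisson inner draw uses inverse
CDF); (iii) a multinomial bottleneck back to `founders`. Log fitness is
additive over a genome's amino-acid effects (no epistasis — the minimal
model when single-mutation sweeps dominate), synonymous changes are
neutral, unlisted missense changes default to ΔF = 0, and stop-gain
genomes are non-viable by default (a truncated replication protein cannot
support propagation). Only the evolvable locus mutates, mirroring what
locus-targeted Sanger sequencing can see. Defaults follow the assay this
emulates: 10 rounds, 10⁵ founders, consensus threshold 0.5, wild-type
polymerase error 2×10⁻⁸/base with a 1,000× mutator factor.

Dominant-mutation calling is Sanger-consensus-like: a mutation is called
in the first round its population frequency strictly exceeds the
threshold. Calls are per DNA substitution; equally fit alleles of the
same residue can therefore interfere clonally and leave a trial with no
call even though the site has swept — visible in the bench campaign,
where 13/15 trials call the planted hotspot and 2 split across its three
alleles.

## Problem sizes and determinism

The standard bench scenario is a 28-residue target (window 2–28: 513
missense + 27 synonymous + wild type; 84 nt amplicon, 2×50 nt reads) at
depth 10⁶ per library, and a 20-residue variant of it for the quick demo;
campaigns run 15 trials × 10 rounds at 10⁵ founders. These sizes keep
every analysis reproducible on a laptop while leaving all per-variant
counts deep enough for the estimator's asymptotics to apply. Every
stochastic entry point takes an explicit seed and uses `numpy`'s PCG64
generator; derived stages draw sub-seeds deterministically, so any script
rerun with the same seed reproduces its artifacts byte for byte.

## Known limitations

- The generator's noise floor is multinomial; real assays are
  overdispersed, so simulated neutrality bands are optimistically narrow
  at high depth.
- No epistasis in the evolution model; interactions between mutations on
  one genome are unconstrained by design.
- The quantifier does not model indels, quality trimming, or UMIs.
- Recovery guarantees are statistical: at the ≥100-output-read coverage
  floor the estimator's SE is ≈ 0.045 log10 units, so a full-library
  realization will occasionally place its worst-covered variant slightly
  beyond 2 SE of truth.
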
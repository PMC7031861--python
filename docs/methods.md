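# Methods

## Signal model and coordinate conventions

Alkaline hydrolysis cleaves RNA phosphodiester bonds approximately at
random; a 2'-O-methyl group on nucleotide *i* protects the bond 3' of
*i*. Sequencing the fragment library therefore yields, per bond, two
observable end counts: reads whose 5'-end starts at position *i + 1* and
reads whose 3'-end stops at position *i*. The combined count attributed
to nucleotide *i* (1-based) is

```
n_i = count5[i+1] + count3[i]
```

3'-ends are counted only for reads whose *aligned* query length is below
40 nt (`max_len_3p`): longer single-end reads terminate at the read
length, not at a cleavage site. Aligned length (soft clips excluded) is
compared rather than raw read length, since adapter/quality trimming
happens upstream; a flag can change the threshold. Reverse-strand,
unmapped, secondary and supplementary records are skipped and tallied
(the library is sense-stranded; antisense ends carry no bond signal), a
warning fires if reverse records exceed 10%, and duplicates are kept —
fragmentation is random, so recurring ends are signal, not PCR
artifacts. All file formats are 1-based; internal arrays are 0-based. At
the last position only the 3'-end component of `n` exists; since scoring
masks every position within a half-window of a terminus, this boundary
choice cannot affect calls.

## Scores

With half-width *w* and positive symmetric weights ω_j (unit by default;
window 6 ships the decreasing series 1.0, 1.0, 1.0, 0.9, 0.8, 0.7), the
side means are L_i and R_i and the directional relative drops are
`drop53 = max(0, 1 − n_i/L_i)` and `drop35 = max(0, 1 − n_i/R_i)`.
ScoreMAX is drop53; ScoreMAX-MAX the larger drop (one-sided if a single
side mean vanishes); ScoreMEAN their average; ScoreA the clamped
symmetric form `max(0, 1 − 2n_i/(L_i+R_i))`; MethScore the same quantity
unclamped, so a homogeneous profile scores 0, a fully protected bond
scores exactly 1, and over-cleaved positions go negative. ScoreD min-max
normalizes a ScoreA track and a ScoreMEAN track over their valid
positions and averages them; a constant track normalizes to zeros.
"Normalized sum" admitted several readings (rank averaging, z-scoring);
min-max scaling was chosen for boundedness and is isolated behind one
function.

Numerical policy: no pseudocounts — positions whose required side means
are zero are masked rather than scored, so dead zones cannot become
candidates; all accumulation is fixed-order vectorized arithmetic, with
no randomness anywhere in scoring. Scores are ratios of counts and are
exactly invariant to depth rescaling. The default window is ±2: a short
window estimates the local cleavage level from the nearest bonds, which
empirically discriminates Nm gaps from background better than the
historical ±6 window; `score_sweep` reproduces that comparison.

## Evaluation

Valid scored positions form the universe; annotated positions carry
status Nm, psi or other_mod and everything else is unmodified. Nm is the
positive class; pseudouridines and other modifications are negatives by
default because their ligation-bias gaps are exactly the false-positive
signals the evaluation must expose (an `exclude` option removes them for
sensitivity analyses). Annotated sites falling on masked positions are
excluded with a warning and tallied. References are pooled into one
ranked list by default; per-reference evaluation is a flag.

Thresholds are the distinct observed score values, a call is score ≥ t
(step-function ROC, no interpolation), MCC uses the standard formula
with the 0-when-any-factor-0 convention, ties in max MCC break toward
the higher threshold (fewer calls, conservative FDR), and FDR is the
empirical FP/(FP+TP) at the chosen point — not a multiple-testing
q-value. The trapezoidal AUC of this step ROC equals the Mann-Whitney
statistic, which the tests verify against an independent pairwise count.

## Simulator

The generator emulates the statistical structure the scores assume, not
sequence chemistry:

* per-bond cleavage propensity c_b ~ LogNormal(−σ²/2, σ), i.i.d. with
  unit mean; σ defaults to 0.3, which keeps uniform-null maxima below
  typical Nm scores at coverage 1000 while producing visibly
  heterogeneous profiles;
* bond intensity λ_b = coverage · c_b · (1 − m_b·π), with methylation
  fraction m per Nm site and protection efficiency π (default 1);
* count5[p] ~ Poisson(λ_{p−1}), count3[p] ~ Poisson(ratio_3p · λ_p);
  ratio_3p (default 0.4) is the fraction of fragments short enough to
  pass the 3'-end length filter — a free parameter, not a claim;
* pseudouridine ligation bias multiplies the 5'-end component of the
  combined count at the annotated ψ position by (1 − β), β default 0.5.
  The bias is injected where the false-positive signal appears in score
  space — at the ψ position itself — mirroring how ψ sites overlap the
  Nm score distribution in real data; only 5'-ends are affected, since
  fragment 5'-end ligation is the documented mechanism;
* Poisson noise is independent per track and position (chosen over
  multinomial for simplicity), so totals fluctuate.

Interior expectation: E[n_i] = (1 + ratio_3p)·coverage·c_i·(1 − m_i·π),
hence with homogeneous cleavage E[MethScore2] = m exactly, which the
recovery experiment measures (slope ≈ 1, Pearson r > 0.999 at coverage
1000 over 50 seeds per grid point).

`simulate_reads` emits concrete alignments: per-position read starts are
drawn from the same bond intensities, lengths uniform in a configurable
range (default 20–59 nt, straddling the 40 nt filter), and fragments
that would run past the reference are discarded — their 3'-end would be
the molecule's native terminus, not a cleavage bond — so coverage tapers
over the last read-length of positions. Records are written directly as
perfect forward-strand SAM against a seeded random FASTA; no aligner
runs, so re-counting the records recovers the intended counts exactly.

What the simulator does **not** model: sequence-specific cleavage
chemistry, reverse-transcription drop-off, PCR duplication, structural
(non-ψ) coverage dips, paired-end effects, and parameter fits to any
real dataset. Passing tests therefore demonstrate correctness of the
computations and the qualitative mechanisms (protection gaps, ψ false
positives, depth effects), not calibrated performance on biological
libraries.

## Problem sizes and defaults

Simulation-based tests use references of 50–420 nt at coverage ~1000
with 50–200 seeds per experiment; the recovery grid is m ∈ {0, 0.25,
0.5, 0.75, 1} × 50 seeds on a 41 nt reference. These sizes give standard
errors well inside the asserted tolerances while keeping the whole suite
under a minute. The miniature fixture trio (120/300/60 nt with 15 Nm and
6 ψ sites) stands in for the small/large/5.8S rRNA set at roughly 1/15
scale.

## Known limitations

* The historical score formulas were never printed in one place; the
  definitions above are this package's contract, chosen to satisfy every
  documented behavior (directionality of ScoreMAX, negative MethScore
  values, clamping, window/weight parameterization). Users comparing
  against legacy pipeline outputs should verify formula-level agreement.
* Variably modified sites are treated as full positives in evaluation;
  they inflate the false-negative count at high thresholds.
* No per-site significance model: the decision rule is
  threshold-on-score, as in the protocol this implements.
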
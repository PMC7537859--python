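# Methods

## The measurement problem

Many genomes carry dinucleotide motifs whose occurrences recur at spacings
concentrated on multiples of ~10–11 bp — close to the helical pitch of
B-DNA. `periodscope` measures this periodicity robustly: it estimates the
period to ~0.01-bp resolution, attaches a bootstrap variance to it, and
decides by an explicit goodness-of-fit threshold whether a periodic signal
is present at all.

## Pipeline

1. **Scanning.** Occurrences of each of the 100 dinucleotide patterns over
   the IUPAC subset {G, A, T, C, R, Y, W, S, M, K} are located on one
   strand; ambiguous genome bases never match. Complements follow the
   table G↔C, A↔T, R↔Y, W↔W, S↔S, M↔K, which partitions the 100 patterns
   into 10 palindromes and 45 complementary pairs (55 motif sets).
2. **Spacing collation.** For each pattern, start-to-start distances
   between *all* ordered occurrence pairs up to 202 bp are histogrammed.
   All-pairs (rather than adjacent-only) collation preserves the
   enrichment at 2×, 3×, … the period and makes the histogram independent
   of intervening occurrences. The "genomic" histogram pools all 100
   patterns; per-set histograms pool a pattern with its complement.
3. **Smoothing.** A sliding 3-term mean (value at s = mean of raw counts
   at s, s+1, s+2) cancels the 3-bp reading-frame signal of coding
   sequence; spacings below 6 bp are discarded because homopolymer runs
   dominate them. The reported series covers spacings 6…200.
4. **Autocorrelation.** The smoothed series is autocorrelated at integer
   lags 1…100 with the classic stationary-form estimator
   r(x) = Σ(vₛ−v̄)(vₛ₊ₓ−v̄) / Σ(vₛ−v̄)², using the global mean and
   variance. A per-slice Pearson variant (recomputing means and standard
   deviations for every shifted window) was evaluated and rejected: on
   the strongly nonstationary spacing series it distorts the curve shape
   away from the damped-sine family badly enough to push clean planted
   signals past the significance threshold.
5. **Damped-sine fit.** The model
   Y(x) = e^(−ln2·x/HL) · A · sin(2πx/λ + π/2)
   is fitted by exhaustive grid search, ignoring lags 1–9 (nucleotide
   repeats): λ over 6–16 bp in 0.25-bp steps, A from 0 to 120% of the
   maximum observed autocorrelation in 0.05 steps, HL over 5–60 bp in
   5-bp steps; then refined with λ in 0.01-bp steps within ±0.8 bp, A in
   0.02 steps within ±20%, and HL in steps of 2% of the estimate within
   ±20%. χ² is the raw sum of squared residuals over the fitted lags
   (autocorrelation values are signed and near zero, so Pearson-χ²
   denominators would be ill-posed). Ties break to the smallest λ, then
   A, then HL. Because χ² is quadratic in A for a fixed (λ, HL) template,
   the search evaluates template dot-products once per (λ, HL) and scans
   A analytically; the refined grid contains the coarse optimum, so
   refinement never increases χ².
6. **Significance.** GdF = χ²/σ, with σ the standard deviation (ddof 1)
   of the observed autocorrelation values over the fitted lags. GdF < 3.0
   (strict) declares robust periodicity. An empirical null is available
   by permuting the smoothed abundances across spacings, recomputing the
   autocorrelation and refitting: the resulting GdF distribution is
   approximately Gaussian (mean ≈ 5, sd ≈ 0.6 on pooled data), and the
   Gaussian tail supplies a p-value for the genuine GdF; the probability
   of a permuted data set reaching GdF < 3.0 is ~10⁻³–10⁻⁴, which is what
   justifies the fixed threshold. Permuting the autocorrelation values
   across lags instead was evaluated and rejected: it leaves both the
   total sum of squares and σ invariant, so the null GdF acquires a hard
   data-determined ceiling and a strong left skew, and can never be
   Gaussian.
7. **Bootstrap variance.** During collation each spacing is assigned
   round-robin, in discovery order (anchor position ascending, then
   partner distance), to one of 1000 subsets; discovery-order striping is
   essential — a distance-major assignment would make the subsets nearly
   identical and collapse the variance. A bootstrap iterate draws 1000
   subsets with replacement, sums them, re-smooths, re-autocorrelates and
   refits; the sd of the refitted periods estimates the period's sd. The
   estimate is insensitive to the subset count for k ≥ 50.
8. **Per-motif analysis.** Individual motif sets are fitted with λ held
   at the genomic period (only A and HL searched), giving a 55-entry
   GdF/amplitude/strength profile per genome; strength = ln(GdF/A),
   smaller meaning stronger. Profiles are compared by Pearson correlation
   of GdF vectors and by orthogonal Deming regression (error-variance
   ratio δ = 1, since both axes carry the same noisy statistic).
   Motif-level period differences from the genomic period are tested with
   Welch's two-sample t on the bootstrap distributions; the dispersion of
   variance-normalized periods (λᵢ−λ_genomic)/sdᵢ is tested against N(0,1)
   with a fully specified KS test.
9. **Fragments.** Randomly placed fragments (40 kb default) are fitted
   over λ ∈ genomic ± 5 bp using only the strongly periodic sets
   (GdF < 1.5 and amplitude > 0.2, both strict). Fragments within 0.6 bp
   of the genomic period are "genomic"; those in the outermost 1-bp bands
   of the window are "extreme". Catenation pools the spacing histograms
   of non-overlapping fragments (no junction spacings are fabricated) and
   refits.

## Synthetic genomes

The generators define the study conditions under which every claim is
tested; no external downloads are needed.

* **Planted genome.** An i.i.d. background at a configurable GC content
  with a dinucleotide motif written over it. Anchors sit on a lattice
  whose fractional pitch is accumulated and rounded per anchor, so the
  mean pitch equals the nominal period exactly; the lattice is thinned to
  the target density, and Gaussian jitter accumulates as a drift-free
  random walk along the chain of kept occurrences. The walk is the load-
  bearing choice: consecutive spacings then have sd exactly equal to the
  jitter parameter, and pairs k occurrences apart decohere as √k,
  reproducing the exponentially damped autocorrelation envelope that
  insertion/deletion drift imposes on real genomes. Independent per-anchor
  jitter was evaluated and rejected — it yields an *undamped* cosine that
  the model family cannot represent — as was a walk advancing per lattice
  anchor, which at jitter 1 decoheres so fast that the fit acquires a
  deterministic +0.02 bp bias (verified on analytically computed expected
  histograms). Degenerate motifs are instantiated per occurrence by a
  uniform draw from their match sets; motifs overwrite background bases so
  genome length stays exact.
* **Random genome.** i.i.d. bases at a given GC content — the trivial
  null.
* **Markov artificial genome.** The stringent null: gene lengths are
  resampled from a source genome's gene-length distribution, strands from
  its strand bias, coding sequence from an order-3 chain whose transition
  frequencies are conditioned on the codon position of the emitted base
  (falling back to order 2, 1, 0 on unseen contexts), and intergenic gaps
  from intergenic statistics. This preserves codon-position-specific
  dinucleotide through tetranucleotide frequencies but no long-range
  spacing structure. The model assumes strand-symmetric composition
  statistics; a source whose motif placement is strand-asymmetric (as a
  planted genome technically is) will be reproduced only up to that
  asymmetry.

What the generators do **not** emulate: real gene composition and codon
usage in the background, replication-strand skews, repeated elements,
multiple coexisting periods, and region-to-region variation in the
strength of selection. Passing tests therefore demonstrate that the
*measurement machinery* is correct and calibrated, not that any
particular biological genome is periodic.

## Problem sizes and defaults

| Quantity | Default | Why |
|---|---|---|
| max spacing | 202 bp | with 3-bp averaging, reports spacings 6–200 |
| autocorrelation lags | 1–100, fit on 10–100 | half the reported spacing range; first 9 lags dominated by repeats |
| period search | 6–16 bp | brackets the 10–11 bp phenomenon with margin |
| subsets (k) | 1000 | variance flat for k ≥ 50; 1000 gives fine-grained resampling |
| bootstrap iterates | 1000 (tests use 150–200) | sd of the sd ≈ 5% at 200 iterates |
| null iterations | 10000 (tests use 100–150) | Gaussian summary converges quickly |
| planted recovery | 500 kb, density 3/100 bp, jitter 1 bp | the positive-control condition: recovery within ±0.05 bp with GdF ≪ 3 |
| null panels | 100 random (300 kb) + 20 Markov genomes | the GdF of a non-periodic genome is essentially length-free (≈ n_lags·σ_r·(1−R²), with σ_r set by the 195-point series length), so 300 kb tests the same claim as multi-Mb genomes |
| fragment scan | 40 kb fragments, window ±5 bp, 0.6-bp genomic band, 1-bp extreme bands | weak-amplitude condition for catenation: 800 kb, density 0.8/100 bp, jitter 1 bp — the regime where genome-wide sets are strong but individual fragments are noise-limited |

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally, 1-based inclusive in
  files and reports.
* Grids are built from integer-scaled `arange` and rounded to 6 decimals,
  so on-grid optima are recovered exactly; λ refinement is clipped to the
  search range.
* A constant smoothed series (no occurrences, or a saturated one) is a
  zero-variance error at the autocorrelation step; profile building
  records NaN for such sets rather than failing the genome.
* strength is NaN when A = 0 or GdF = 0 (log undefined); significance
  flags are computed from GdF alone.
* Replicons are treated as linear strings; spacings across the FASTA
  junction (≤ 202 bp of a chromosome) are ignored. Replicore mode wraps
  at the stored-sequence end so each arc is contiguous, and histograms
  never span ori or ter.
* Multi-record FASTA files contribute only their largest replicon.
* All randomness flows through `numpy.random.Generator` seeds; identical
  seeds give bit-identical genomes, subsets, bootstraps and nulls.

## Known limitations

* The amplitude grid tops out at 120% of the maximum *observed*
  autocorrelation, so a true amplitude whose observable maximum is
  suppressed by fast decay cannot be represented exactly (the period is
  unaffected; the A·HL trade-off absorbs the difference).
* Uncertainty is quantified for the period only, not for A or HL.
* No Fourier/periodogram estimator is provided, and k > 2 motifs, PWMs
  and spliced gene models are out of scope.
* The Welch form is used for the motif-vs-genomic period test; with
  bootstrap distributions of equal size and similar spread it is
  equivalent to the pooled-variance form.
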
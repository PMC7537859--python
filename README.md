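# periodscope

Robust measurement of dinucleotide periodicity in genomes.

Prokaryotic and eukaryotic chromosomes carry dinucleotide motifs whose
occurrences recur at spacings concentrated on multiples of roughly 10–11
bp, near the helical pitch of B-DNA. `periodscope` is for genome
scientists who want to measure that period precisely, attach a variance
to it, decide whether it is statistically real, and compare the suites of
periodic motifs between genomes — without hand-tuned thresholds or
Fourier blurring.

## Method

For each of the 100 degenerate dinucleotides over {G, A, T, C, R, Y, W,
S, M, K}, start-to-start spacings between all occurrence pairs up to
202 bp are collated, averaged over a sliding 3-bp window (cancelling the
reading-frame signal), and autocorrelated at lags x = 1…100 bp. A damped
sine

&nbsp;&nbsp;&nbsp;&nbsp;Y(x) = e^(−ln2·x/HL) · A · sin(2πx/λ + π/2)

is fitted to the autocorrelation by exhaustive coarse-then-refined grid
search over the period λ, amplitude A and decay half-life HL (lags 1–9
ignored). Fit quality is the goodness of fit

&nbsp;&nbsp;&nbsp;&nbsp;GdF = χ²/σ

where χ² is the sum of squared residuals over the fitted lags and σ the
standard deviation of the observed autocorrelation there; **GdF < 3.0**
marks robust periodicity, a threshold calibrated against permutation
nulls (randomized spacing abundances yield Gaussian GdF ≈ 5.0 ± 0.6, so
GdF < 3.0 has tail probability ~10⁻³–10⁻⁴). The period's variance comes
from bootstrapping a 1000-way round-robin partition of the spacings.
Motif-level work fixes λ at the genomic period: the 55 palindromic or
complement-paired dinucleotide sets get per-genome GdF/amplitude/strength
profiles, compared across genomes by Pearson correlation and Deming
regression. Fragment-level scans classify 40-kb windows by their fitted
period and rescue weak signals by catenating (histogram-pooling)
fragments. Synthetic-genome generators — planted-period positive
controls with truth sidecars, i.i.d. nulls, and codon-structure-
preserving Markov shuffles — make every claim testable offline.

See `docs/methods.md` for the full model description, defaults and
limitations.

## Worked example

Plant a 10.5-bp period (3 motifs/100 bp, 1 bp jitter) in a 200-kb random
background, then measure it:

```sh
periodscope simulate planted --length 200000 --period 10.5 --density 3 \
    --jitter 1 --gc 0.5 --seed 17 --out demo.fa --truth demo_truth.json
periodscope period --fasta demo.fa --null-iters 200 --seed 17 --out demo_fit.json
```

prints

```json
{
  "genome": "planted_p10.5_d3.0",
  "period_bp": 10.48,
  "amplitude": 0.98,
  "half_life_bp": 72.0,
  "gdf": 0.19365448452624773,
  "significant": true,
  "null": {
    "mean": 4.933495030232444,
    "sd": 0.6080804950710115,
    "n_iter": 200,
    "p_gaussian": 3.2265914974780318e-15,
    "p_empirical": 0.0
  }
}
```

The fitted period (10.48 bp) recovers the planted 10.5 bp to within the
estimator's resolution at this genome size; GdF = 0.19 is far below the
3.0 significance threshold, while 200 spacing-randomized versions of the
same data fit no better than GdF ≈ 4.9 ± 0.6 — the planted signal is
~7 null standard deviations better than chance (Gaussian P ≈ 3×10⁻¹⁵).

The same analyses are available as library calls:

```python
import periodscope as ps

genome, truth = ps.planted_genome(200_000, period=10.5, density=3.0,
                                  jitter=1.0, seed=17)
series = ps.smooth(ps.pooled_histogram(genome))
fit = ps.fit_damped_sine(ps.autocorrelate(series))     # fit.lambda_bp, fit.gdf
boot = ps.bootstrap_period(ps.pooled_histogram(genome, n_subsets=1000),
                           n_iter=1000, seed=1)        # boot.mean, boot.sd
profile = ps.build_profile(genome)                     # 55-set GdF table
```

Other subcommands: `periodscope scan` (spacing histograms, replicore
splitting, codon-position filters), `periodscope bootstrap`,
`periodscope profile`, `periodscope fragments`, `periodscope compare`,
and `periodscope simulate shuffle` (Markov artificial genomes).

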
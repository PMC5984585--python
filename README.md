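# haplosmc

Characterization of tumor heterogeneity by latent haplotypes: a
sequential Monte Carlo toolkit.

Multi-region or longitudinal tumor sequencing yields, for `T` somatic
SNV loci in `S` samples, a matrix `Y` of variant read counts and a
matrix `V` of total read counts.  Because humans are diploid, more than
two haplotypes (scaffolds of SNVs on one homologous genome) in a sample
is evidence of subclonal heterogeneity.  `haplosmc` infers, jointly:

* `Z` — a `T x C` binary matrix of haplotype mutational profiles,
* `W` — a `(C+1) x S` matrix of haplotype proportions per sample
  (row 0 is a background pseudo-haplotype absorbing noise),
* `p` — the background noise rate,
* `C` — the number of haplotypes, which is not fixed in advance.

The model is a binomial feature-allocation / blind binary matrix
factorization: `y_ts ~ Binomial(v_ts, p_ts)` with expected
variant-allele frequency `p_ts = w_0s p + sum_c z_tc w_cs`, an Indian
buffet process prior on `Z`, and Gamma/Beta priors on the
re-parameterized proportions.  Inference is a bootstrap particle filter
that treats each SNV as one time step — so newly sequenced SNVs can be
folded into an existing fit without reprocessing old loci — followed by
rejuvenation sweeps that revisit every SNV (see `docs/methods.md`).

Intended users: cancer-genomics methods developers and analysts with
copy-number-neutral multi-sample SNV read counts.

## Worked example

```python
from haplosmc import (
    SimulationConfig, simulate, FilterConfig, run_filter, compute_errors,
)

data, truth = simulate(SimulationConfig(T=60, S=10, C=4, r=200, seed=11))
fit = run_filter(data, FilterConfig(n_particles=500, n_passes=5, seed=7))
report = compute_errors(fit, truth)
print(fit.C_hat, round(fit.p_hat, 4))
print(round(report.e_Z, 4), round(report.e_W, 4), round(report.e_pts, 4))
```

prints

```
4 0.0124
0.0 0.0068 0.0062
```

meaning: the filter recovered all 4 simulated haplotypes with not a
single wrong entry in the 60 x 4 profile matrix (`e_Z = 0`), estimated
every proportion to better than 0.7% absolute on average
(`e_W = 0.0068`), reconstructed the expected VAF surface to 0.6%
(`e_pts = 0.0062`), and put the noise rate near the simulated 0.02.
Errors are computed after exhaustively matching estimated to true
columns, since a blind factorization carries no canonical column order.

The same workflow from the shell:

```
haplosmc simulate -T 60 -S 10 -C 4 -r 200 --seed 11 -o sim/
haplosmc run -y sim/Y.tsv -t sim/V.tsv -N 500 --passes 5 --seed 7 -o fit/
haplosmc evaluate --fit-dir fit/ --truth-dir sim/
```

`run` writes `Z_hat.tsv`, `W_hat.tsv`, `summary.json` and a
`manifest.json` that makes the run reproducible.  `haplosmc
reproduce-table1` / `reproduce-table2` rerun the full simulation sweeps
(depth sweep at T=60, C=4, S=10; locus sweep at C=4, S=3), and
`haplosmc extend` continues an existing fit with newly sequenced SNVs.

Input format: tab-separated matrices with a locus-identifier first
column and a sample-name header row; `Y` and `V` must carry identical
labels and satisfy `0 <= y_ts <= v_ts` cell by cell.

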
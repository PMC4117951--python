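# bisclass

Bayesian posterior-odds calling of per-cytosine methylation status from
whole-genome bisulfite sequencing (methylC-seq / BS-seq) count data.

## The problem

After bisulfite conversion and mapping, each cytosine is summarized by `k`
methylated ("C") reads out of `N` total reads.  Deciding whether a site is
methylated at all — a *binary* call — is the central preprocessing step for
sparsely methylated genomes (most invertebrates and many plants, where well
under 1% of CpGs are methylated).  The standard *binomial method* tests the
null "not methylated" against Binomial(N, p₀), where p₀ is the
non-conversion error rate, and corrects p-values by the false discovery
rate.  Because p-values are bounded below by p₀ᴺ, this test has essentially
no power at low coverage: a site covered by a single C read can never reach
q < 0.05 unless about 4% of the genome is methylated (at p₀ = 0.002), and a
site with one C and two T reads needs about 12%.  Since realistic coverage
distributions are heavily overdispersed (shifted negative binomial,
variance ≈ 3× mean; about half of all sites under 4 reads), this discards a
large share of the genuinely methylated genome.

## The model

`bisclass` replaces the hypothesis test with a two-state Bayes classifier.
With p₀ the probability that a non-methylated C is read as C
(non-conversion) and p₁ the probability that a methylated C is read as C
(1 − over-conversion; sequencing error ε can be folded in as
p' = p(1−ε) + (1−p)ε), the posterior odds of methylation at a site are

    odds = π₁ᶜ / (1 − π₁ᶜ) · p₁ᵏ (1−p₁)^(N−k) / [ p₀ᵏ (1−p₀)^(N−k) ]

A site is called methylated when odds ≥ 19, which bounds the posterior
probability of a false methylated call by 0.05 (the analogue of q < 0.05).

The prior π₁ᶜ exploits the spatial clustering of methylation: methylation
levels of CpGs a few hundred bp to a few kb apart are strongly correlated.
The prior mixes a global and a kernel-smoothed local methylation level,

    π₁ᶜ = (1 − w)·π₁ᴳ + w·π₁ᴸ ,      w = 0.5 by default,
    π₁ᴸ = Σₖ K(dₖ) Lₖ cₖ / Σₖ K(dₖ) Lₖ ,   cₖ = clip((Fₖ − p₀)/(p₁ − p₀), 0, 1)

where K is a triangle kernel (bandwidth ≈ 1.5 kb, the distance at which the
spatial correlation of methylation decays below 0.2; gaussian and laplace
kernels are also available), K(0) = 0 excludes the focal site, Lₖ and Fₖ
are the neighbor's read count and fractional methylation, and π₁ᴳ inverts
the pooled C fraction through the error model.  The error rates themselves
are estimated directly from the counts by EM on a two-component binomial
mixture — no spike-in control required.

The package also ships the binomial baseline, a seeded synthetic methylome
simulator (shifted-negative-binomial coverage, homogeneous or clustered
methylation, error-injected reads), spatial-correlation diagnostics with
data-driven bandwidth selection, and the full benchmarking protocol
(sensitivity, methylated-normalized false-positive ratio, ROC/AUC,
coverage downsampling, replicate consistency).

## Worked example

Simulate a sparse clustered methylome (50,000 CpGs, mean coverage 4, global
methylation 0.5%, non-conversion 0.002, retention 0.7), estimate the error
rates by EM, and call methylation with both methods:

```
$ bisclass simulate --seed 42 --n-sites 50000 --mean-cov 4 --clustered \
      --pi 0.005 --out counts.tsv --truth-out truth.tsv
$ bisclass fit-errors --counts counts.tsv
{
  "p0": 0.0019533926725578722,
  "p1": 0.7265694145878588,
  "pi": 0.004710378306283849,
  "loglik": -3643.1810128267284,
  "n_iter": 15,
  "converged": true
}
$ bisclass classify --counts counts.tsv --p0 0.002 --p1 0.7 --out calls.tsv
$ bisclass binomial --counts counts.tsv --p0 0.002 --out binomial_calls.tsv
```

The EM estimates recover the simulation truth (p₀ = 0.002, p₁ = 0.7,
π = 0.005) to a few percent.  The call table carries one row per input site
with the per-site prior, the posterior odds and the three-way call
(`methylated` / `unmethylated` / `no_data`):

```
chrom   pos     strand  n_meth  n_total p_value q_value prior     odds         call
sim1    63541   +       2       3                       0.030488  1157.99      methylated
sim1    63916   +       5       5                       0.039723  2.17263e+11  methylated
sim1    64006   +       10      11                      0.034977  3.00552e+23  methylated
```

Note the first site: two C reads out of three, inside a methylated cluster
(prior 0.03 versus the global 0.005), called methylated at odds ≈ 1158.  In
this run the posterior-odds caller recovers 146 of the 238 truly methylated
sites with a single false positive; at low coverage and π = 0.5% most of the
remaining sites are covered by 0–1 reads and are irrecoverable by any
caller at this error bound, which is why ranking quality (AUC ≈ 0.99 versus
≈ 0.93 for the binomial baseline) is the sharper comparison.

Other entry points: `bisclass spatial` (correlation curve + bandwidth),
`bisclass smooth` (bedGraph methylation tracks), and
`bisclass evaluate benchmark|downsample|consistency` for the simulation
experiments.  Everything is also importable as a library
(`bisclass.classify_sites`, `bisclass.em_fit`, `bisclass.run_benchmark`, …).

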
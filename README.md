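# cistrio

Cis-regulatory QTL analysis for cohorts with matched genotype, mRNA and
protein measurements on the same individuals.

Genetic variants near a gene can shift its mRNA level (eQTLs), its
protein abundance (pQTLs), or its protein abundance *beyond* what the
mRNA explains (protein-specific QTLs, psQTLs). `cistrio` maps all three
classes of cis associations, then asks the mechanistic question behind
them: for a given variant–gene pair, *how* does the genotype act on the
two traits? It answers by likelihood comparison of six causal structures
among genotype S, mRNA R and protein N, and finishes with enrichment
summaries of where each class of regulatory variant sits in the genome.

It is written for statistical geneticists working with trios of
genotype + expression + proteome matrices (e.g. lymphoblastoid cell-line
panels), and ships a synthetic-cohort generator so the whole pipeline is
testable end to end without any external data.

## The model

For each candidate trio, individuals `i = 1..n` contribute genotype
class `S_i ∈ {0,1,2}` (alt-allele dosage), mRNA `R_i` and protein `N_i`
(both pre-normalized toward N(0,1)). Six factorizations of the joint
density are compared:

| # | factorization          | reading                                   |
|---|------------------------|-------------------------------------------|
| 1 | P(S) P(R\|S) P(N)      | variant affects mRNA only                 |
| 2 | P(S) P(R) P(N\|S)      | variant affects protein only              |
| 3 | P(S) P(R\|S) P(N\|S)   | both traits, by independent routes        |
| 4 | P(S) P(R\|S) P(N\|R)   | transcriptional mediation, S → R → N      |
| 5 | P(S) P(R) P(N\|S,R)    | post-transcriptional genetic effect       |
| 6 | P(S) P(R\|S) P(N\|R,S) | all three edges                           |

Components are Gaussian: `R|S_j ~ N(μ_RSj, σ_R²)`,
`N|S_j ~ N(μ_NSj, σ_N²)`, and the mRNA-conditioned protein densities use
the bivariate-normal regression form
`N|R(,S_j) ~ N(μ + ρ (σ_N/σ_R)(R − μ_R), (1 − ρ²) σ_N²)`.
Each model is scored with `BIC_i = −2 log L_i + k_i ln(n)` at fixed
parameter counts `k = (6, 6, 8, 8, 7, 10)` and converted to selection
weights `w_i = exp(−ΔBIC_i) / Σ_k exp(−ΔBIC_k)`; the minimum-BIC model
is the selected regulatory pattern.

psQTLs are found by a nested-model likelihood-ratio test,
`N ~ β₀ + β₁ S + β₂ R + ε` against `N ~ β₀ + β₂ R + ε`, with
`Λ = n ln(RSS₀/RSS₁)` referred to χ²(1). All QTL families are
thresholded by Benjamini–Hochberg at FDR 0.1 (separately per type).

## Worked example

```python
from cistrio import SimParams, simulate_trio, classify_trio

# a post-transcriptional variant: S -> N directly, R -> N separately
params = SimParams.for_pattern(5, effect=1.0, n_individuals=62, seed=42)
trio, truth = simulate_trio(params)
fit = classify_trio(trio)
print("selected pattern:", fit.selected_pattern)
for pid, (ll, bic, w) in enumerate(
    zip(fit.log_likelihoods, fit.bics, fit.weights), start=1
):
    print(f"  pattern {pid}: logL = {ll:8.3f}   BIC = {bic:8.3f}   weight = {w:.4f}")
```

prints

```
selected pattern: 5
  pattern 1: logL = -151.972   BIC =  328.707   weight = 0.0000
  pattern 2: logL = -138.245   BIC =  301.253   weight = 0.0000
  pattern 3: logL = -138.204   BIC =  309.425   weight = 0.0000
  pattern 4: logL = -144.931   BIC =  322.880   weight = 0.0000
  pattern 5: logL = -125.254   BIC =  279.397   weight = 1.0000
  pattern 6: logL = -125.212   BIC =  291.696   weight = 0.0000
```

The generative structure (pattern 5) wins decisively: pattern 6 matches
its log-likelihood almost exactly — it nests pattern 5 — but pays a
three-parameter BIC penalty (`3 ln 62 ≈ 12.4`), so the weight
concentrates on the simpler true model.

The same analysis from the shell, end to end:

```bash
cistrio simulate --seed 11 --out sim/
cistrio run --genotypes sim/genotypes.tsv --mrna sim/mrna.tsv \
            --protein sim/protein.tsv --genes sim/genes.bed \
            --mode extended --out results/
```

which writes `qtls.tsv` (every gene × cis-variant test),
`fdr_summary.tsv`, `patterns.tsv` (per-trio log-likelihoods, BICs,
weights, selected pattern), optional enrichment tables, and a
`manifest.json` recording the configuration hash.

## Acceptance script

`scripts/acceptance.py` simulates a 30-gene cohort (five genes per
pattern, 62 individuals, effect 1.0 SD per alt allele), runs the full
pipeline — normalization, cis-QTL mapping at FDR 0.1, trio
classification, truth-table comparison — and writes its JSON report:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
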
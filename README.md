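# cloneburst

Joint Bayesian tumor phylogeny inference from matched **bulk DNA sequencing**
and **single-cell RNA sequencing** read counts at somatic point mutations.

## The problem

A tumor is a mixture of subclones — cell populations that share sets of
somatic single-nucleotide variants (SNVs) accumulated along an evolutionary
tree. Bulk DNA-seq measures variant allele frequencies accurately but averages
over cells, so several tree configurations can explain the same frequencies.
Single-cell RNA-seq resolves individual cells but is riddled with zeros of
three distinct origins: the cell's clone genuinely lacks the mutation
(*non-cancerous* zero), the gene carrying the mutation was transcriptionally
silent when the cell was captured (*stochastic* zero, from transcriptional
bursting), or the transcript was expressed but not sequenced (*technical*
zero). `cloneburst` models both data types jointly so that each compensates
for the other's blind spots, and explicitly separates the three zero types.

## The model

For `M` mutations, `K` clones (clone 1 normal), `N` cells, and `T` bulk
samples, the latent structure is a rooted bifurcating clonal tree yielding a
binary mutation-to-clone matrix **Z** (M×K), a one-hot cell-to-clone
assignment **Pˢ** (K×N), and fractional bulk clonal compositions **Pᵇ** (K×T,
simplex columns). With carrier fractions **Qᵇ = Z Pᵇ** and carrier indicators
**Qˢ = Z Pˢ**, the observed alternative read counts are

- bulk: `rᵇₘₜ | xᵇₘₜ ~ Binom(xᵇₘₜ, qᵇₘₜ / 2)` (heterozygous,
  copy-number-neutral loci);
- single cell, carrier (`qˢₘₙ = 1`): `rˢₘₙ ~ Binom(xˢₘₙ, γₘ)` with bursting
  activity `γₘ ~ Beta(αₘ, βₘ)`;
- single cell, non-carrier (`qˢₘₙ = 0`): `rˢₘₙ ~ Binom(xˢₘₙ, ε)` with
  sequencing error `ε ~ Beta(κ, τ)`, default `(κ, τ) = (1, 999)` so
  `E[ε] = 0.001`.

Marginalizing `γₘ` and `ε` gives a piecewise beta-binomial likelihood for the
single cells. The bursting rates `(αₘ, βₘ)` are **not** estimated from the
mutation read counts (which would confound carrier status with expression);
they are fit per gene from independent expression measurements under a
beta-Poisson model `y ~ Poisson(s·sf·γ), γ ~ Beta(α, β)`, by closed-form
factorial-moment matching with a quadrature-based maximum-likelihood
fallback.

Posterior sampling over `(Z, Pˢ, Pᵇ)` uses Metropolis-within-Gibbs with flat
priors: exact Gibbs relocation of mutations over tree edges and exact Gibbs
cell reassignment (both enumerable, with the cell assignments collapsed out
of tree moves), nearest-neighbor-interchange topology moves optionally
coupled with a bulk-composition redraw, and Dirichlet random-walk
Metropolis-Hastings for the composition columns. The number of subclones is
chosen by a modified BIC,

```
BIC_MAP = −2 · Q3ⱼ( log p̂ⱼ(θ̂_MAP | y) ) + K · log(2MN + 2MT),
```

where the per-chain maximized log posterior is the mode of a kernel density
fitted to that chain's retained log joint densities and Q3 is the third
quartile across chains.

## Worked example

```python
import cloneburst as cb

cfg = cb.SimulationConfig(seed=7, regime="bursty")     # K=4, M=6, N=50, T=4
sim = cb.simulate_dataset(cfg)

# bursting kinetics from the (simulated) expression of each host gene
kin_hat, methods = cb.kinetics_for_mutations(
    sim.expression,
    dict(zip(sim.data.mutation_ids, sim.expression.gene_ids)),
    mutation_ids=sim.data.mutation_ids)

chains = cb.run_mcmc(sim.data, K=4, kinetics=kin_hat,
                     error_prior=cb.ErrorPrior(),
                     config=cb.SamplerConfig(n_iter=2000, n_chains=4, seed=11))
tree, cells, bulk, logdens = chains.best_state()
print(f"MAP log joint density: {logdens:.2f}")
print("MAP tree:", tree.newick())
err = cb.reconstruction_error((tree.Z, cells.P_s, bulk.P_b),
                              (sim.tree.Z, sim.cells.P_s, sim.bulk.P_b))
print(f"reconstruction error: Z={err.error_Z:.3f}  "
      f"Ps={err.error_Ps:.3f}  Pb={err.error_Pb:.3f}")
```

prints

```
MAP log joint density: -10229.05
MAP tree: (normal,(clone3,(clone2,clone4)));
reconstruction error: Z=0.000  Ps=0.010  Pb=0.064
```

The mutation-to-clone matrix is recovered exactly (`Z` error 0), the cell
assignments are 99% correct, and the bulk compositions are off by 6.4
percentage points on average — all scored modulo relabeling of the tumor
clones, since clone indices are arbitrary.

The same pipeline is available from the shell:

```bash
cloneburst simulate --seed 7 --out sim/
cloneburst estimate-bursting --expression sim/expression.tsv \
    --mutation-gene-map m2g.tsv --out kinetics.tsv
cloneburst run --counts sim/ --kinetics kinetics.tsv --K 4 --out fit/
cloneburst select-k --counts sim/ --kinetics kinetics.tsv --k-range 3:10 \
    --out bic.tsv
cloneburst diagnose --trace fit/chain0_trace.tsv --out diag.tsv
```

Other subcommands: `filter-snvs` (the eight-criterion somatic SNV QC filter)
and `assign-cells` (validates cell-to-clone assignments from observed
mutation profiles; cells whose profiles span diverging branches are reported
as unassigned).

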
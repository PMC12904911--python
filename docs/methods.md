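# Methods

This note documents the statistical model behind `cloneburst`, the design
choices made where several reasonable options existed, the numerical
conventions, and what the synthetic-data experiments do and do not
demonstrate.

## Model

### Clonal structure

A tumor with `K` clones is represented as a rooted bifurcating tree whose
leaves are the clones; leaf 1 is the normal, mutation-free population and the
remaining `K−1` leaves form the tumor subtree. Somatic mutations are placed on
edges of the tumor subtree (any edge except root→normal, including the
truncal edge above the tumor subtree); a clone carries every mutation on its
root-to-leaf path. The binary matrix `Z` (M×K) is *derived* from this
representation, which makes the perfect-phylogeny property — any two carrier
sets nested or disjoint — hold by construction rather than by rejection.
Storing the topology (not just `Z`) also makes tree-space moves and the
identifiability constraints natural to express.

**Identifiability.** Two constraints define the admissible state space:
(i) every internal tumor edge carries at least one mutation, and (ii) all `K`
columns of `Z` are pairwise distinct. Constraint (i) alone still allows
sibling leaf clones with empty pendant edges, which would be exact copies of
one another; (ii) is the minimal condition under which `K` clones are
distinguishable at all (it also rules out a tumor clone with an empty
mutation set, which would be indistinguishable from normal). Proposals
violating either are rejected; the simulator rejection-samples ground truths
under the same constraints, so inference and generation share one state
space.

### Observation model

Bulk alternative reads at mutation `m` in sample `t` are
`Binom(x, q/2)` with `q = (Z Pᵇ)ₘₜ` the carrier cell fraction — heterozygous,
copy-number-neutral loci, so a carrier fraction `q` translates to allele
fraction `q/2`. Single-cell alternative reads are `Binom(x, γₘ)` in carrier
cells, with the gene's transcriptional activity `γₘ ~ Beta(αₘ, βₘ)` (the
stationary activity of the two-state bursting model), and `Binom(x, ε)` in
non-carrier cells, `ε ~ Beta(κ, τ)`. Marginalizing the latent rates yields
beta-binomial masses in both branches, evaluated via log-beta (log-gamma
differences) throughout; no factorials or direct beta evaluations are ever
formed. The joint log density used by the sampler drops all binomial
coefficients: they depend only on the observed counts, cancel in every
Metropolis-Hastings ratio, and are identical across candidate `K` for fixed
data, so model comparison is unaffected. The normalized pmfs (with
coefficients) remain available behind an `include_constant` flag and are what
the normalization and marginalization tests exercise.

Entries with `x = r = 0` contribute their exact value rather than being
skipped — for the single-cell branch this value is nonzero and informative
(an empty cell is *evidence* under a bursty gene).

### Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| κ, τ | Beta prior of the sequencing error rate | 1, 999 | prior mean κ/(κ+τ) = 0.001, the commonly reported per-base error of short-read sequencing |
| αₘ, βₘ | gene activation / deactivation rates | estimated per gene | decoupled from carrier status by using independent expression data |
| s | beta-Poisson exposure scale | 300 (simulator) | typical full-transcript single-cell depth at an expressed locus |
| δ | positivity floor on Pᵇ entries | 1e-4 | `q = 0` with observed alternative reads has zero likelihood; QC guarantees ≥5 alt reads somewhere, so exact zeros must be excluded from the continuous state space |
| bulk depth | per-locus coverage | uniform 30–50x | shallow WES regime the method targets |

## Bursting-kinetics estimation

Expression counts for the gene hosting each mutation are modeled as
`y ~ Poisson(s · sf · γ)`, `γ ~ Beta(α, β)`, with library-size factors
`sf = total/median(total)` (cells with zero totals get factor 1 plus a
warning). Two estimators:

- **Moments.** The k-th factorial moment of the beta-Poisson is
  `sᵏ·Π(α+i)/(α+β+i)`, so the ratios `r₁ = m₁`, `r₂ = m₂/m₁`, `r₃ = m₃/m₂`
  give three linear relations that eliminate to a closed form for
  `(α, β, s)`. The closed form is verified in the test suite against an
  independent numeric root-finder on simulated data. Negative or non-finite
  solutions (common on noisy genes) are flagged invalid, never raised.
- **Maximum likelihood.** Direct Nelder-Mead optimization of
  `(log α, log β, log s)` with the mixture integral evaluated by fixed-order
  (50-node) Gauss-Jacobi quadrature over `γ ∈ (0,1)`; the Beta kernel is the
  Jacobi weight function, so endpoint singularities for `α<1` or `β<1` are
  handled exactly. Identical `(count, size-factor)` pairs are collapsed with
  multiplicities, keeping the cost independent of the number of cells for
  discrete data. A deterministic optimizer was chosen over stochastic
  sampling for reproducibility and speed; the estimator slot is pluggable by
  design.

Per mutation the pipeline tries moments, then MLE, then falls back to
`(α, β) = (0.5, 0.5)` — the bursty regime, a neutral default — with a
warning. Normalization by divide-and-round before the moment fit is a
package choice; other size-factor conventions would serve equally.

## Posterior sampling

Flat priors on tree space (topology + placement), on cell assignments, and on
each bulk-composition simplex. One sweep applies:

1. **M mutation/topology moves**, split 70/30 by default.
   *Mutation relocation* is an exact Gibbs draw: the full conditional of a
   mutation's edge is an enumerable categorical over the ~`2K−3` eligible
   edges (invalid candidates get zero mass; the current edge is always
   valid, so the support is never empty).
   *Topology moves* are rooted nearest-neighbor interchanges on the tumor
   subtree, mixed 50/50 with a tumor-leaf label swap (pendant-edge mutations
   stay on their physical branches); for `K = 3` no NNI exists and the move
   degenerates to the label swap, and for `K = 2` there is no topology move.
   Each component kernel is symmetric with a state-independent neighborhood
   size, so the mixture is symmetric.
2. **One exact Gibbs pass over all cells.** Cells are conditionally
   independent given the tree, so all `N` K-way categoricals are drawn
   jointly (Gumbel-max), which has lower autocorrelation than any
   Metropolis alternative.
3. **One Metropolis-Hastings pass over bulk columns** with a Dirichlet
   random-walk proposal `p′ ~ Dir(c·p)`, `c = 100` by default, floored at δ
   and projected back to the simplex; the Hastings ratio uses the Dirichlet
   densities at the pre-flooring values (the floor is essentially never
   active, so the approximation is negligible).

**Collapsing.** Tree moves are judged against the partially collapsed
posterior in which the cell assignments are summed out exactly (per cell, a
log-sum-exp over the K clones). Without this, assignments drawn under the
previous tree veto rearrangements and chains stall in local modes; with it,
the assignments re-equilibrate in the Gibbs pass immediately after, keeping
the scheme a valid partially collapsed Gibbs sampler. For the same reason,
half of the topology attempts jointly redraw all bulk columns from a
Dirichlet independence proposal centered at a deterministic non-negative
least-squares composition estimate under the candidate tree (normal clone
absorbing the slack), with the full Hastings correction; a composition
adapted to the wrong tree otherwise blocks the right one. The estimate is
memoized per `Z`, so the extra cost is two Dirichlet density evaluations per
attempt.

Chain `j` derives its generator from the seed key `(seed, j)` through
numpy's seed-sequence mechanism: runs are bit-reproducible and chains are
order-insensitive. Retained samples are recorded after a 20% burn-in with
optional thinning; every retained state satisfies all structural invariants
(spot-checked in the test suite). The reported point estimate is the
retained state of maximal log joint density across chains (the MAP draw).

## Model selection

Because the priors are flat, the posterior is proportional to the
likelihood and the MAP value can replace the maximized likelihood in a BIC.
Per chain, the maximized log posterior is estimated as the mode of a
Gaussian KDE (Silverman bandwidth, 512-point grid spanning the sample range
± 3 bandwidths) fitted to the retained log joint densities; numerically
constant samples short-circuit to their value. The third quartile across
chains (type-7 linear-interpolation quantile, stated for reproducibility)
enters `BIC = −2·Q3 + K·log n` with `n = 2MN + 2MT`, the aggregate dimension
of the four observed matrices. Ties break toward smaller `K`. Taking Q3 on
the log scale is equivalent to logging the Q3 of raw posteriors since log is
monotone. The raw maximum retained log density is available via a flag as an
alternative to the KDE mode.

Convergence diagnostics: per-chain traces, lag-ACF to lag 50 (NaN for
constant traces), KDE summaries, and a split rank-normalized R-hat across
chains, implemented directly (≈15 lines) rather than pulling in a posterior
analysis framework.

## Synthetic data

The simulator generates ground truths uniformly: random bifurcating topology
(sequential random edge addition, which is uniform over rooted labeled
topologies), uniform mutation placement subject to identifiability, uniform
cell-to-clone assignment, and symmetric Dirichlet(1) bulk compositions
floored at δ. Observed data follow the generative model above, with one
deliberate concretization: the per-(mutation, cell) bursting draw `γ` drives
*both* the coverage `x ~ Poisson(s·γ)` and the carrier success rate
`r ~ Binom(x, γ)`. Coupling coverage to mutational observability through the
same bursting mechanism is exactly the stochastic-zero phenomenon the model
is built to separate. The error rate `ε` is drawn once per dataset from
`Beta(κ, τ)` (matching the single latent `ε` of the model), with a fixed
override available (e.g. `ε = 0` for noise-free checks).

What the simulator does **not** emulate: doublets, ambient RNA, batch
effects, copy-number aberrations, amplification bias beyond the beta-Poisson,
or per-cell bursting covariates (cell size, ploidy). Passing recovery tests
therefore demonstrates correctness of the inference machinery under the
model's own assumptions, not robustness to every artifact of real single-cell
data.

## Problem sizes used in the automated checks

The test suite and `scripts/acceptance.py` run desk-scale versions of the
benchmark: 10 replicates of the default condition (K=4, M=6, N=50, T=4,
high expression) and 12 replicates of the 30-cell condition (3 regimes × 4
seeds), each fit with 4 chains × 2,000 iterations and 20% burn-in;
model selection uses candidates {3,4,5} with 4 chains × 1,500 iterations.
These sizes were chosen so the whole suite completes in minutes on a single
CPU while leaving the observed proportions within the binomial Monte-Carlo
slack of the large-replicate reference values (which use 20 chains, 10,000
iterations, and 100 seeds per regime). The full-scale grid remains available
through `simulate.run_benchmark_grid`.

## Known limitations

- Single-sweep mixing degrades for large `K` (many more topologies, deeper
  valleys); more chains and iterations are the remedy, and runs with `K > 6`
  should use substantially more iterations (50,000 is a reasonable default).
- The bulk model assumes heterozygous, copy-number-neutral SNVs; loci under
  CNAs violate the `q/2` allele-fraction mapping.
- Mean bulk-composition error depends strongly on how compositions are
  generated; symmetric Dirichlet(1) truths (used here) are easier to recover
  than highly skewed compositions.
- The QC filter consumes precomputed annotation columns (caller status,
  population-database membership, segmental-duplication overlap, LJB score
  availability); running the upstream callers/annotators is out of scope.
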
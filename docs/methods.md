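# Methods

## Model and estimation

`profilebin` models the cross-sample read counts of contig i,
x_i = (x_i1, …, x_iP) with total n_i, as a K-component multinomial mixture:
a latent species label z_i ~ Categorical(π) and
x_i | z_i = k ~ Multinomial(n_i, a_k), where a_k is species k's *sample
profile* (a point on the P-simplex). The assumptions this encodes:

- reads of one contig are a multinomial draw across samples, i.e. the
  per-sample counts are independent Poisson thinned from the contig's total —
  no over-dispersion beyond multinomial noise;
- all contigs of a species share one profile (true when mapping is unique
  and biases are shared across samples, since per-base biases cancel in the
  proportions);
- species are distinguishable only insofar as their profiles differ
  (*differential abundance*). Two species with proportional abundances
  everywhere are unidentifiable by construction; the negative-control test
  exercises exactly this.

Maximum likelihood is by EM. The E-step computes responsibilities
q_ik ∝ π_k Π_j a_kj^{x_ij} in log space with log-sum-exp — the literal
product underflows for realistic n_i (hundreds of reads). The M-step sets
π_k ∝ Σ_i q_ik and a_kj ∝ s + Σ_i q_ik x_ij with a pseudo-count s
(default 1e-10) keeping every profile entry positive, so no species is ever
assigned probability exactly zero in a sample merely because it drew no
reads there. Multinomial coefficients are dropped in every likelihood
expression; they are constant in k and θ, so responsibilities, likelihood
*differences*, and BIC comparisons are unaffected — only the absolute
log-likelihood scale differs from implementations that keep them.

Degenerate cases: a component whose responsibility mass Σ_i q_ik falls below
1e-12 has no data defining its profile; rather than produce NaN, its profile
is re-seeded with the empirical profile of the worst-fit contig (lowest max
posterior) while its weight stays ∝ Σ_i q_ik, i.e. effectively zero. A dead
component therefore stays dead within one fit — K is owned by the selection
loop, not the fit. Hard labels are the posterior argmax with lowest-index
tie-break.

Convergence: relative log-likelihood change below `tol` (default 1e-6), cap
`max_iter = 500`. Both are conventional; on the simulated regimes below EM
converges in well under 50 iterations from the hierarchical start.

## Initialization

EM is only locally convergent. The start is deterministic: take the
`top_fraction` (default 0.20, conventionally 0.10–0.30; a warning outside
that range) of contigs with the most mapped reads — their profiles have the
least multinomial noise — compute pairwise cosine distances
1 − ⟨x₁,x₂⟩/(‖x₁‖‖x₂‖) (scale-invariant, so it compares profiles rather than
depths), agglomerate (default average linkage; complete and Ward-on-
normalized-profiles available — no linkage is canonical for this task), cut
at K, and use cluster means of *row-normalized* vectors as initial profiles
(raw-count means would let deep contigs dominate) with cluster sizes as
initial weights. Optional restarts bootstrap the selected subset and keep
the best final log-likelihood; the default is the single deterministic
start, which on the tested regimes already reaches the best restart's
likelihood.

## Choosing K

BIC(K) = −2 log L + (KP + K) log N, minimized over an increasing scan that
stops at the first BIC rise (the BIC profile is near-convex in K here, so
the first rise brackets the minimum). The parameter count is the
unconstrained KP + K rather than the simplex-corrected (K−1) + K(P−1); the
difference, (P+1−K…) terms, is monotone in K and therefore only shifts all
penalties by a K-linear amount — kept for consistency and simplicity. For
large communities (hundreds to thousands of species) `select_k_geometric`
doubles K until the BIC turns, then refines linearly inside the bracket;
the stopping rule on the refined scan is unchanged. Each candidate K is
initialized independently (no warm starts), keeping candidates comparable.

## NMF cross-check

With noise ignored, X = M·E exactly: M[i,k] is the reads one copy of contig
i yields in species k, E[k,j] the abundance of species k in sample j, and
row-normalizing E recovers A. `nmf_factorize` minimizes ‖X − ME‖_F with
Lee–Seung multiplicative updates from seeded uniform(0,1] starts scaled to
X's mean; the residual trace is recorded and is non-increasing (checked in
tests). Labels are the argmax over M's columns. NMF offers no principled K
choice and no uncertainty, so it serves as an independent diagnostic route;
agreement with the EM labels (ARI ≥ 0.9 on separated simulations) is part
of the acceptance suite.

## Abundance normalization

b_kj = 10⁹ · â_kj · Σ_{i: ẑ_i=k} n_i / (L_k · T_j), with L_k the summed
lengths of bin k's contigs (a genome-length proxy) and T_j the library size.
T_j is the total read records per alignment file when counting from SAM/BAM
(mapped + unmapped), and defaults to column sums for bare count tables,
which cannot know the unmapped fraction. The 10⁹ factor only sets a
convenient scale. Significance: b_kj ≥ 0.1% of Σ_l b_lj, inclusive; below
that share the estimate is dominated by error. GC-bias correction is out of
scope — externally corrected counts can be passed straight in.

## Metrics

ARI, precision (Σ_i max_j n_ij / N), and recall (Σ_j max_i n_ij / N) are
computed from the exact contingency table. ARI uses `fractions.Fraction`
for the binomial sums: at large N the numerator is a tiny difference of
huge terms and floats cancel catastrophically. The doubly-trivial 0/0 case
(both partitions all-singletons or both single-cluster) is defined as 1 —
the partitions are then identical; a zero denominator with differing
partitions cannot occur.

## Synthetic communities

The generator draws profiles a_k ~ Dirichlet(α·1_P) (default α = 1, i.e.
uniform on the simplex — distinct, moderately separated profiles), labels
z_i ~ Categorical(π) (default uniform), lengths ~ LogNormal(log 1000, 0.5)
bp (median 1 kb with a right tail, resembling a post-filter short-read
assembly), totals n_i ~ Poisson(length_i · depth) coupling coverage to
length the way pooled sequencing does, and counts
x_i ~ Multinomial(n_i, a_{z_i}). Optional `missing_fraction` zeroes each
(species, sample) cell independently and renormalizes the row (species
absent from some samples); an explicit `profiles` matrix overrides the
Dirichlet draw (used to plant identical-profile species). Zero-read contigs
are dropped and counted. Fixed seed ⇒ bit-identical output.

What the generator does **not** emulate: read-level errors, assembly
chimerism and fragmentation, non-unique mapping, GC/positional bias,
over-dispersion, strain mixtures. Passing tests therefore demonstrate
correctness of the estimation machinery under the model's own assumptions —
not robustness to real-data violations of them.

Problem sizes used in tests and in `scripts/acceptance.py` (chosen as
desk-scale regimes where multinomial asymptotics are clearly in force):
recovery and NMF/abundance checks at K=5, P=20, N=2000, mean n_i = 200
(100 for the abundance check); model-selection scans at K ∈ {3,5,10},
P=20, N=1000, mean n_i = 200, 10 seeds each; trend grids at N=300 with 5
seeds per point (depth 50/200/800 mean reads, samples 5/20/80 at fixed
pooled depth, species 3/5/10 at fixed per-species depth); the
duplicate-profile control at K=4 (one pair identical), N=800.

## Known limitations

- Proportional-abundance species are unidentifiable (by design of the
  feature, not the implementation); more depth or more samples is the only
  remedy.
- A dead EM component cannot revive within a fit; with the hierarchical
  start this arises only when K exceeds the number of separable profile
  groups, which is exactly the signal the BIC scan uses to stop.
- The BIC stop-at-first-rise rule assumes a near-convex BIC profile; a
  rugged likelihood landscape (poor separation, tiny N) can stop early.
  Restarts mitigate this at cost.
- Library sizes from bare count tables undercount unmapped reads, biasing
  b_kj upward uniformly per sample; cross-sample *comparisons* are
  unaffected when mapping rates are similar.
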
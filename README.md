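# profilebin

Reference-free binning of metagenomic contigs from multiple samples, with
relative-abundance estimation.

## The problem

Shotgun metagenomic studies assemble the pooled reads of P environmental or
clinical samples into contigs, then need to group those contigs into putative
genomes (*bins*) — usually without reference genomes, since most microbial
species have none. Composition-based binners rely on k-mer statistics, which
degrade on short contigs and on genetically similar species; coverage-based
binners are sensitive to positional and GC sequencing bias.

`profilebin` instead clusters contigs by their **sample profile**: the vector
of proportions of a contig's mapped reads contributed by each of the P
samples. Contigs from the same genome share their genome's abundance pattern
across samples, so their profiles coincide regardless of contig length,
sequence similarity to other species, or per-base bias (biases are shared
across samples and cancel in the proportions). The only requirements are
multiple samples (preferably ≥ 10) and *differential abundance* — species
abundances must vary appreciably across samples.

## The model

Let X be the N×P read-count matrix (contigs × samples), x_i its rows with
totals n_i. Each contig carries a latent species label z_i with
P(z_i = k) = π_k, and

    x_i | z_i = k  ~  Multinomial(n_i, a_k),

where a_k ∈ Δ^(P−1) is species k's sample profile. The mixture θ = (π, A) is
fit by EM (log-space E-step with log-sum-exp; multinomial coefficients
dropped — they are constant in k and θ), initialized by hierarchical
clustering of the 10–30% highest-count contigs under the cosine distance.
The number of species K is chosen by minimizing

    BIC(K) = −2 log L(θ̂) + (KP + K) log N,

scanning K upward and stopping at the first BIC increase. Contigs are
assigned to their highest-posterior bin, and the relative abundance of bin k
in sample j is normalized RPKM-style:

    b_kj = 10⁹ · â_kj · Σ_{i: ẑ_i=k} n_i / (L_k · T_j),

with L_k the bin's summed contig length and T_j the sample's library size. A
species is *significant* in a sample when b_kj ≥ 0.1% of the sample's total.
An NMF factorization X ≈ M·E (Frobenius objective, multiplicative updates)
provides a likelihood-free cross-check of the bins, and partitions are scored
with the adjusted Rand index, precision, and recall computed in exact
rational arithmetic.

## Worked example

```python
import dataclasses
import profilebin as pb

base = pb.SimConfig(K=4, P=12, N=500, seed=11)
cfg = dataclasses.replace(base, depth=pb.depth_for_mean_reads(250, base))
cm, truth = pb.simulate_community(cfg)

est = pb.MultinomialMixtureBinner().fit(cm)   # K chosen by BIC
print("chosen K:", est.n_components_)
print("mixing weights:", est.weights_.round(3))
print(pb.evaluate_binning(est.labels_, truth.labels))
```

prints

```
chosen K: 4
mixing weights: [0.256 0.26  0.236 0.248]
{'ari': 1.0, 'precision': 1.0, 'recall': 1.0}
```

The BIC scan behind `est.selection_` decreases to K = 4 (515056.0) and turns
upward at K = 5 (515126.0), so the scan stops there and K = 4 is selected —
the generating number of species. The estimated mixing weights sit near the
uniform truth of 0.25, and all 500 contigs are binned exactly as simulated
(ARI = precision = recall = 1). Continuing,

```python
ab = pb.relative_abundance(
    pb.MixtureParams(est.weights_, est.profiles_), est.labels_, cm
)
print(ab.b[0, :4].round(3))          # bin 0 in the first 4 samples
print(pb.significant_species(ab))    # per-sample significant-species counts
```

```
[ 758.21  2170.069 2761.326  122.167]
[4 4 4 4 4 4 4 4 4 4 4 4]
```

The b values are dimensionless RPKM-like abundances (reads per bin-bp per
library read, ×10⁹); bin 0 is ~20× more abundant in sample 2 than in sample
3, and every bin clears the 0.1% significance share in every sample.

The same pipeline is available from the shell:

```bash
profilebin simulate --k 4 --samples 12 --contigs 500 --seed 11 --outdir sim/
profilebin bin --counts sim/counts.tsv --outdir bins/        # K auto by BIC
profilebin bin --alignments s1.bam --alignments s2.bam ...   # or from SAM/BAM
profilebin evaluate --pred bins/bins.tsv --truth sim/truth_labels.tsv
```

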
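# bimodalbind

Tools for dissecting transcription-factor (TF) DNA-binding specificity into
three sequence-level contributions — local GC-content, specific k-mers, and
short tandem repeats (STRs) — and for modeling how a cooperatively binding
competitor (a bivalent c-Myc-Max heterotetramer) can redistribute other TFs
between GC-rich and GC-poor genomic regions without any direct
protein-protein interaction.

It is aimed at regulatory-genomics analyses of ChIP-seq-style peak data
(peaks with intensities over a reference genome, plus TSS annotations and
optional CpG methylation calls). A first-class synthetic-data module
generates genomes and peak sets with the statistical structure the analysis
assumes, so the entire pipeline runs and is tested without downloads.

## The models

**Peak-over-background k-mer energy.** For each k-mer *s*, a statistical
binding energy (units of k<sub>B</sub>T) is estimated from held-out training
peaks and their flanking background windows:

```
U_k(s) = -ln[ (<N_k(s)>_peak + 1) / (<N_k(s)>_background + 1) ]
```

where `<N_k(s)>` is the mean count of *s* or its reverse complement per
100-bp peak-center window (palindromes counted once; +1 pseudocounts). A
test sequence of length L is scored by its free energy

```
F_k = -ln Σ_{i=1..L-k+1} exp(-U_k(s_i)),
```

lower F meaning more peak-like. ROC AUC of F over held-out peaks versus
backgrounds measures predictive power, and

```
ΔAUC = max_k AUC(k) - AUC(1)
```

isolates genuine k-mer recognition from the GC-content-only baseline
(k = 1). Computed separately for GC-poor (GC < 0.4) and GC-rich (GC > 0.6)
peak strata, ΔAUC reveals the bimodality of specificity: k-mer recognition
dominates in GC-poor regions, composition in GC-rich ones. The model is
exposed both as functions and as a scikit-learn estimator
(`KmerEnergyClassifier`) that plugs into sklearn pipelines.

**Composition-preserving pair correlations.** Repeat structure is measured
by

```
η_αβ(x) = [ N_αβ(x) - <N_αβ(x)>_shuffle ] / L
```

the per-bp excess of (α, β) nucleotide pairs at separation x over the mean
in 100 random shuffles of each sequence that preserve its base composition.
η_CC(6) detects periodic [CNNNNNC] repeats typical of GC-rich bound
regions; η_AA(1) detects poly(A) tracts typical of GC-poor ones. An exact
mode replaces sampling with the closed-form permutation expectation.

**Competitive equilibrium.** Mass-action equilibrium of a Myc-Max
heterodimer binding high-GC DNA (K₁ = 145 nM) and low-GC DNA
(K_L = 500 nM), dimerizing on high-GC DNA into a bivalent heterotetramer
(K₂ = 90 nM), in competition with a Smad1 homodimer (K̃_H = 10⁻¹⁴ M²,
K̃_L = 2.5·10⁻¹⁴ M²). Solved exactly by reduction to the two free
concentrations; sweeping total Myc shows a sharp, cooperative displacement
of Smad1 from high-GC DNA that the heterodimer-only control lacks.

## Worked example

```
$ bimodal synth --seed 1 --outdir data --n-peaks 2000 --chrom-length 2000000
wrote synthetic dataset to data

$ bimodal kmer-spec --peaks data/peaks.bed --genome data/genome.fa \
      --k-max 8 --min-peaks 500 --seed 1 --out kmer.tsv
low-GC: dAUC = 0.0092 (n = 976)
high-GC: dAUC = 0.0000 (n = 992)

$ bimodal equilibrium --sweep 1e-8:1e-5:200 --tetramer on
sharpness d[Smad2.DNAH]/dlog10(Myc): 1.734e-07 M/decade

$ bimodal equilibrium --sweep 1e-8:1e-5:200 --tetramer off
sharpness d[Smad2.DNAH]/dlog10(Myc): 9.045e-08 M/decade
```

The synthetic genome plants a consensus 6-mer only in GC-poor peaks, so the
GC-poor stratum shows positive k-mer specificity (ΔAUC = 0.0092) while the
GC-rich stratum, which differs from background in composition only, shows
none (ΔAUC = 0). The equilibrium sweep shows the tetramer-enabled
transition is ~1.9× sharper than the heterodimer-only control — the
cooperativity signature. `bimodal run-all` executes every stage end-to-end
and writes TSV outputs plus a reproducibility manifest.

As a library:

```python
from bimodalbind import SyntheticSpec, generate_dataset, stratified_specificity

data = generate_dataset(SyntheticSpec(seed=1))
for s in stratified_specificity(data["peaks"], data["genome"], min_peaks=500, seed=1):
    print(s.stratum, round(s.delta_auc, 4))
```

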
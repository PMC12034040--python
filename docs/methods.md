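# Methods

This note documents the statistical models, the numerical choices, and what
the synthetic benchmark does and does not establish.

## Peak-over-background energy model

Binding energies are defined per canonical k-mer (lexicographic minimum of
a k-mer and its reverse complement) as
`U = -ln((<N>_peak + 1)/(<N>_bg + 1))`, with `<N>` the mean per-sequence
count over 100-bp windows centered on peaks (training split) or over 100-bp
background windows. Counting is strand-symmetric: a window's count accrues
to its canonical class, so occurrences of a k-mer and of its reverse
complement pool together, while palindromes (e.g. CACGTG) are counted once
per matching window — naive two-strand scanning would double-count them and
bias their energies relative to non-palindromes. Windows containing N are
skipped. The +1 pseudocounts keep every energy finite and give unobserved
k-mers U = 0, so the table is total over the canonical k-mer space.

Sequences are scored by the log-sum-exp free energy over all k-windows,
computed with `scipy.special.logsumexp` for overflow safety. At k = 1 the
free energy is a strictly monotone function of window GC-content whenever
the C/G energy is below the A/T energy, which is what makes AUC(1) a pure
GC-composition baseline and ΔAUC = max_k AUC(k) − AUC(1) a
composition-corrected k-mer specificity measure.

Choices:

* **Backgrounds** are two 100-bp windows per peak, 100 bp outside each peak
  edge, kept only if fully on-chromosome and overlapping no peak of the
  set. Both flanks are used (one-sided sampling would halve the background
  at no benefit). An accessibility-matched alternative takes the 100-bp
  centers of open-chromatin peaks GC-matched to each stratum and disjoint
  from the ChIP peaks.
* **Train/test split** is at the peak level (default 80/20, seeded);
  background windows follow their source peak's side, so no genomic
  material leaks between training and evaluation.
* **ROC/AUC**: scores are ranked with ties handled as half-weights
  (Mann-Whitney convention); the reported AUC equals the trapezoidal area
  of the threshold-swept curve, and the two coincide exactly, ties
  included.
* **Stratification** uses the GC of the same 100-bp window the model
  scores (open intervals: GC < 0.4 / GC > 0.6; a peak at exactly the
  boundary joins neither stratum). Strata under `min_peaks` are omitted.
  Peaks shorter than the window, or whose window leaves the chromosome,
  are omitted rather than clipped, uniformly across all analyses.
* **k range** defaults to 1–8; 4^8 canonical classes is the largest table
  that is still cheap to hold dense, and the planted/known motifs of
  interest are 6–7 bp.

## Pair correlations

`η_αβ(x) = (N_αβ(x) − <N_αβ(x)>_rand)/L` with the null formed by
permuting each sequence's own letters (composition preserved by
construction; only non-N positions permute). The default is the literal
sampled null, 100 permutations per sequence, one spawned RNG stream per
sequence so results are independent of processing order. Because the
permutation mean has a closed form —
`E[N_αβ(x)] = n_α n_β (L−x)/(L(L−1))` for α ≠ β and
`n_α(n_α−1)(L−x)/(L(L−1))` for α = β, generalized to N-containing
sequences by conditioning on valid position pairs — an `exact=True` mode
replaces sampling; the two agree within shuffle noise and the exact mode
is what the sliding-window η metaprofile uses (per-window nulls would
otherwise cost a shuffle ensemble per offset per anchor).

Error bars throughout follow the subgroup recipe: the sequence (or anchor)
set is randomly split into 10 equal subgroups and the SD of the subgroup
means is reported, drawn as one SD each side. Set-level η weights
sequences equally (not pooled counts).

The homopolymer-tract panel reports η_AA(1), η_TT(1), η_CC(1), η_GG(1) on
deduplicated peaks (within any chain of mutually overlapping peaks across
stages, only the leftmost-start peak survives) in four cells: GC < 0.5 vs
GC > 0.5, crossed with peak center within vs beyond ±1000 bp of the
nearest TSS.

## Metaprofiles

Sliding windows are 50 bp wide, step 1 bp, centered on the offset. The
intensity profile uses a footprint convention — a peak contributes its
intensity at every offset its interval covers — with a point-mass
alternative. TSS bound/unbound classification supports both the
center-distance and nearest-edge conventions (degenerate 1-bp peaks make
them coincide). The profile-level Pearson R treats offsets as sample
units, over the full ±1000 bp span, with the exact t-transform p-value.

The joint GC × distance histogram uses 50 equal GC bins on [0, 1] and 49
log-spaced distance bins on [1, 10⁷] bp; zero distances are clamped to
1 bp for log binning and over-range distances fall in the top bin.

The methylation metaprofile is CpG-normalized: at each offset in the 4-kb
window around peak centers, summed methylation is divided by the number of
CpG sites observed at that offset — never by the number of peaks — so a
uniform-methylation track yields a flat profile regardless of CpG density,
and offsets with no CpG are undefined (NaN) rather than zero.

## Equilibrium competition model

Five equilibrium relations (heterodimer on DNAH with K₁ = 145 nM,
tetramerization with K₂ = 90 nM so the overall tetramer constant is
K_H = K₁²K₂, heterodimer on DNAL with K_L = 500 nM, Smad homodimer on
DNAH/DNAL with K̃_H = 10⁻¹⁴ M² and K̃_L = 2.5·10⁻¹⁴ M²) plus four
conservation laws. Defaults: total Smad 1 μM; total DNAH = DNAL shipped as
two presets, 0.5 μM and 1 μM. Each DNA unit carries one effective binding
site. All internal arithmetic is molar; the YAML parameter reader requires
unit suffixes precisely because K̃ is in M² and silent unit errors are
otherwise easy.

Numerics: the DNA species are eliminated exactly ([DNAL] is linear in its
conservation law; [DNAH] solves a quadratic whose positive root is
evaluated in the cancellation-free form 2·DNAH_tot/(b + √(b²+4a·DNAH_tot))),
reducing the system to the two free concentrations (m, s). These are found
by nested Brent bisection on the Myc and Smad conservation residuals, each
of which is monotone in its own unknown with a guaranteed sign change on
[0, total], so the solve needs no initialization and converges to machine
precision; solutions are rejected unless all relative conservation
residuals are below 10⁻⁹. The Myc_tot = 0 and Smad_tot = 0 boundaries are
handled exactly. An independent 2-D grid-refinement oracle (with free DNA
obtained by brute bisection rather than the closed form) and 100
random-start Newton solves confirm correctness and uniqueness in the test
suite.

Transition sharpness is the maximum |d[bound species]/d log₁₀(Myc_tot)|
by central differences on the default 200-point log grid over
[10 nM, 10 μM] — a range covering the ~4× drop in Myc level between the
pluripotent and differentiated states. The cooperativity signature is
quantified two ways: the sharpness ratio of the tetramer-enabled model to
the heterodimer-only control, and the effective Hill coefficient (max
logit-slope of DNAH occupancy versus free Myc), which approaches 2 with
the tetramer and stays ≤ 1 without it. A robustness scan perturbs each
dissociation constant ×10 and ÷10 and re-checks that the cooperative model
remains the sharper one.

## Synthetic benchmark

The generator emulates the features the analyses assume: a 2-Mb
single-chromosome genome of i.i.d. bases at GC 0.40 with Gaussian GC bumps
(amplitude 0.25, σ = 300 bp) at 500 TSSs; 2000 non-overlapping 200-bp
peaks drawn from an equal-weight two-mode GC mixture (0.30 ± 0.05 and
0.72 ± 0.05); a planted GGATTA consensus (random strand, probability 0.8)
plus 3 poly(A)/poly(T) runs of 5–8 bp in low-GC peaks; 2 periodic
30-bp [CNNNNNC]/[GNNNNNG] stretches in high-GC peaks; intensity
10·GC + N(0, 1) truncated at zero; CpG methylation at baseline 0.8 with
exponential valleys of depth 0.6 and length scale 500 bp at peak centers,
on a random half of genomic CG dinucleotides; 30% of peaks placed within
±500 bp of a TSS so intensity and promoter GC couple. Peak windows are
rewritten by per-base resampling to the mode's GC target before planting,
which decouples the composition signal from the motif signal. Everything
derives deterministically from one seed through spawned RNG streams.

Sizes were chosen so the full pipeline completes in seconds per seed on a
single CPU while leaving ≥ ~950 peaks per GC stratum.

What passing recovery tests shows: the pipeline detects each planted
signal — stronger k-mer specificity in the GC-poor stratum, η_CC(6)
enrichment confined to GC-rich peaks, η_AA(1) enrichment confined to
GC-poor peaks, a methylation valley at peak centers, and a positive
GC-intensity profile correlation at bound TSSs — reliably across seeds.
What it does not show: performance on real genomes, whose GC structure is
long-range correlated rather than i.i.d., whose peaks carry mixtures of
motif variants and cofactor motifs, and whose background regions are
shaped by chromatin accessibility. In particular the synthetic GC modes
separate peaks from background more cleanly than real data, so absolute
AUC values run high (AUC(1) ≈ 0.99) and ΔAUC magnitudes run small
compared to what genuinely motif-driven TFs show on real peak sets; only
the qualitative contrasts, not the absolute magnitudes, transfer.

## Known limitations

* Background windows may overlap each other (never a peak); extremely
  dense peak sets can therefore reuse flanking material.
* The sampled η null is Monte-Carlo noisy at the 1/(L√100) level; use the
  exact mode where bit-reproducibility across shuffle counts matters.
* The equilibrium model treats DNAH/DNAL as well-mixed species with a
  single effective site each; it makes no spatial or kinetic predictions,
  and the rate constants appear only through their ratios.
* Strand information in BED inputs is ignored; all sequence statistics are
  strand-symmetric by construction.
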
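# Methods

## The lattice model

One mRNA is a 1D nucleotide lattice built from five regions laid out
5'→3': a leader, one or two uORFs (each `3·L` nt of sense codons plus a
3 nt stop), inter-region spacers, the CDS (codons plus stop) and a 3' UTR.
Defaults: leader 150 nt, uORF 50 codons, spacer 150 nt, CDS 500 codons,
3' UTR 150 nt (2106 nt total for the single-uORF mRNA).

Two ribosome species move 3'-ward. A scanning 40S loads at position 0 with
probability `R_in` per action (blocked while the first `footprint_nt`
sites are occupied), advances 1 nt per update with probability `ν_s = 0.3`
and runs off the 3' end if it never initiates. On a start codon it
converts to an elongating 80S with the feature's initiation probability
(`I_uORF`, `I_uORF2`, `I_CDS`); on a failed draw it *commits to leaky
scanning* — it immediately attempts a normal 1 nt advance and never
re-attempts initiation at that same start codon, so the initiation
probability is per-encounter, not per-action-of-dwell. An 80S advances one
codon (3 nt) per update with probability `ν_Eu = 0.3` inside a uORF or
`ν_EC = 0.5` inside the CDS (uORFs are slower: they tend to encode
stalling peptides), and terminates — leaving the lattice and incrementing
`N_EU` or `N_EC` — when its advance reaches its feature's stop codon.
Termination at a uORF stop is final: no reinitiation and no 40S
reformation; CDS initiation happens only via leaky scanning.

One **action** = one loading attempt plus one event attempt per ribosome,
visited 3'→5' (ordered-sequential update: nobody advances into a site
vacated in the same action). Every probability is consumed from a single
seeded MT19937 stream in a fixed, documented order, so runs are
bit-reproducible and the optimized numba kernel and the naive per-site
reference simulator replay identical trajectories from a shared seed. As a
pure speed measure, an update whose every outcome is provably a no-op (a
jammed mover whose blocked advance can neither terminate nor trigger a
dissociation) spends no draw; the reference implements the same rule.

### Collisions and dissociation

An attempted move that would bring two ribosomes closer than
`footprint_nt` is a collision. Same-kind contacts (40S–40S, 80S–80S) just
block. In the *downstream* model an 80S blocked by a 40S removes that 40S
with probability `K_down` per blocked attempt; in the *upstream* model a
40S blocked by an 80S removes **itself** with probability `K_up`; the
*double* model applies both. When a dissociation fires the dislodged 40S
leaves in the current action and the mover does not also advance (one
event per ribosome per action).

### Parameter defaults and why

- `footprint_nt = 3` (one codon). Each ribosome is a point particle on a
  codon-sized exclusion grid — the classic TASEP convention. This also
  fixes the 5'-end loading capacity at `ν_s / footprint_nt = 0.1` per
  action, exactly spanning the standard loading ensemble U(0, 0.1); a
  30 nt steric footprint would cap loading at 0.01/action and saturate
  nearly the whole ensemble, erasing the loading-rate variability the
  model exists to study.
- `K_down = 0.02` per blocked attempt (and the same scale for `K_up` when
  used). A collision contact persists for tens to hundreds of actions
  (the 80S is ~3× faster than the 40S it chases and stays glued until it
  terminates), so per-attempt probabilities integrate to per-encounter
  dissociation probabilities of order one. 0.02 keeps the model in the
  partial-dissociation regime where collision losses respond smoothly to
  the loading rate. Much larger values (≥ 0.1) make every encounter
  lethal: CDS output collapses at high `I_uORF`, and its dependence on
  `R_in` overturns (uORF translation then *anti*-correlates with CDS
  output), which is not the regime of interest.
- `ν_s = ν_Eu = 0.3`, `ν_EC = 0.5`, `I_CDS = 0.8` are the standard
  reference values used throughout.

### Ensemble statistics

`sample_rin` draws the loading ensemble from U(0, 0.1) or from
Exponential(mean 1)/70 (draws above 1 are clamped and counted; probability
< 1e-30). The baseline cell is the single run at the ensemble's median
draw (lower median for even n). Per parameter set the sweep reports:

- **CV of `N_EC`** = sample sd / mean over the ensemble;
- **δ = log2(ΔN_EC/ΔN_EU)** per non-baseline draw. Two conventions for Δ
  are implemented. The default (*ratio*) takes fold-changes versus the
  baseline and excludes cells where either is nonpositive. Note a
  structural property: because the baseline sits at the median draw, the
  median of ratio-δ over the ensemble equals the response at the median
  draw — zero for any monotone noise-free response — so its observed
  median is a small noise-dominated quantity (±0.05 at 1e5 actions). The
  *difference* convention takes count increments; same-sign increment
  pairs give a defined δ whose median estimates the log2 *slope ratio*
  dN_EC/dN_EU at the operating point, a sharper measure of marginal
  buffering. Both are available via `compute_delta(..., mode=...)`.
- **Spearman ρ** between ΔN_EU and ΔN_EC (positive: uORF and CDS output
  respond to loading in the same direction).
- Per-cell seeds derive deterministically from (master seed, parameter-set
  id, draw index) via a CRC-tagged `SeedSequence` and are recorded in the
  sweep output for replay.

## Divergence statistics

TE = RPKM(Ribo-Seq P-sites) / RPKM(mRNA), with RPKM = count·10⁹/(len·lib).
When the mRNA RPKM is exactly 0 but the P-site RPKM positive, 0.1 is added
to both (a feature with both zero is undefined and propagates as missing).
Expressed genes: CDS mRNA RPKM > 0.1 in both species; translated uORFs:
TE > 0.1; the high-expression filter keeps genes whose CDS mRNA and RPF
RPKM both exceed their per-species medians.

Per feature and species, replicates are pooled and
`Var(log2 TE) = (1/ln2)² (1/S_rpf + 1/S_mrna + 2φ/R)` — a delta-method
variance under a negative-binomial count model with pooled counts `S`,
replicate number `R` and a common dispersion `φ` (the mean of per-feature
moment estimates `(s²−m)/m²` over both channels, clipped at zero after
aggregation; individual moment estimates from 2 replicates are far too
noisy to use per-feature). For samples without replicates an SE surface —
log SE regressed on B-spline bases in log10(mean count) and log2 TE, with
out-of-range inputs clipped to the training boundary — imputes SEs from
the replicated samples' fit.

Between species, `log2 β = log2 TE₂ − log2 TE₁` with
`SE = √(SE₁² + SE₂²)`; `log2 γ = log2 β_c − log2 β_u` with the four-term
root-sum-of-squares SE; both tested as Wald z against the standard normal,
BH-adjusted (uORFs and CDSs adjusted separately for β). The buffered-pair
screen requires, on FDR-adjusted q: |log2 β_u| > 1.5 (q < 0.05),
|log2 β_c| < 0.05 (q > 0.05) and |log2 γ| > 1.5 (q < 0.05).

Dominance and grouping: the dominant uORF of a multi-uORF gene is the
argmax-TE uORF per sample, ties to the 5'-most start; the consistency
statistic counts genes whose dominant uORF is identical across all
samples, against a null built by permuting each gene's uORF TEs within
each sample (1000 shuffles, 2.5/97.5 percentile envelope; eligibility
defaults to ≥ 2 uORFs with at least one translated in ≥ 5 samples).
Class I: some conserved uORF dominant in both species; Class II: some
conserved uORF translated in both but no class-I uORF; Class III:
everything else. Length groups: genes without translated uORFs are "No";
the rest split at the median total translated-uORF length, ties to
"short". CV of CDS TE across samples is compared between gene groups by
Wilcoxon rank-sum (signed-rank for paired orthologs).

## The synthetic translatome

`simulate_translatome` emulates a two-species, replicated bulk
mRNA-Seq/Ribo-Seq experiment: per gene a lognormal mRNA abundance
(RPKM-scale), a CDS of 600–3000 nt, uORFs (rate 0.5; 15% of carriers get a
second uORF) of 30–300 nt with lower TE than the CDS; interspecific
effects log2 β drawn normal(0, 0.25), with a configurable fraction of
uORF-bearing genes planted as strongly buffered pairs (|log2 β_u| = 2,
log2 β_c = 0, so log2 γ = −log2 β_u exactly); counts negative-binomial
with common dispersion 0.05 (≈ 22% biological CV) at library sizes 2×10⁷
(mRNA) and 10⁷ (RPF), two replicates. It reproduces bit-identically per
seed and returns the full truth table.

What it does *not* emulate: positional P-site profiles, read-level
artifacts, GC/length biases, correlated dispersion trends, ortholog
mis-mapping. Calibration results on it (type-I error, coverage, recovery
bias) therefore validate the statistical machinery, not the upstream read
processing of a real experiment.

## Problem sizes and numerical choices

The packaged analyses and tests run ensembles of 100 R_in draws at 1e5
actions per run (the full-scale study condition is 1000 draws at 1e6
actions; statistics at the packaged scale carry ~3× more count noise,
which matters mainly for the knife-edge ratio-δ median discussed above).
Counters are exact integers; ribosome conservation
(`loaded = completed + dissociated + runoff + on-lattice`) is asserted in
tests after every configuration. Degenerate inputs fail fast with
configuration errors (invalid probabilities, >2 uORFs, zero-length
features, empty ensembles, zero baselines).

## Known limitations

- Elongation is sequence-independent; no tRNA pools, no codon-specific
  stalling, no drop-off outside collisions, no reinitiation or IRES.
- The dissociation probabilities are per blocked attempt; mapping them to
  per-encounter probabilities depends on contact durations and hence on
  geometry and speeds (see parameter notes above).
- The SE model assumes a common NB dispersion across features; strongly
  gene-specific dispersion would mis-calibrate SEs for outlier genes.
- The ratio-δ median is structurally ~0 at the median-draw baseline; use
  the difference mode (slope ratio) to quantify marginal buffering.
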
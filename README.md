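# uorfbuffer

Upstream open reading frames (uORFs) are short ORFs in the 5' leaders of
eukaryotic mRNAs. Scanning 40S ribosomal subunits can initiate on them,
which represses the downstream coding sequence (CDS) — but it also makes
the uORF act as a "molecular dam": when ribosome availability fluctuates,
collisions between elongating (80S) and scanning (40S) ribosomes on and
around the uORF dissociate scanning subunits at a rate that rises and falls
with the loading rate, damping fluctuations of CDS output. `uorfbuffer` is
a toolkit for studying this buffering effect, for computational biologists
working on translational regulation. It has two halves:

**A stochastic lattice simulator** (TASEP-style exclusion process) of one
mRNA: 40S subunits load at the 5' end with probability `R_in` per action,
scan nucleotide-by-nucleotide (probability `ν_s`), initiate at uORF/CDS
start codons (probabilities `I_uORF`, `I_uORF2`, `I_CDS`), elongate
codon-by-codon as 80S (`ν_Eu` in uORFs, `ν_EC` in the CDS) and terminate at
stop codons, incrementing the completion counters `N_EU` (uORF) and `N_EC`
(CDS). Collisions follow one of three dissociation models: *downstream*
(an 80S blocked by a 40S removes it with probability `K_down`), *upstream*
(a 40S blocked by an 80S is itself removed with probability `K_up`), or
*double* (both). Ensembles of runs over an `R_in` distribution yield the
buffering statistics: the coefficient of variation CV(`N_EC`) = sd/mean,
and `δ = log2(ΔN_EC / ΔN_EU)` with changes taken against the run at the
median `R_in` draw.

**A comparative-translatome statistics module** for two-species
mRNA-Seq/Ribo-Seq count tables: translational efficiency
TE = RPKM(P-sites)/RPKM(mRNA), interspecific fold-changes
`β_u = TE_uORF,sp2/TE_uORF,sp1`, `β_c` likewise for the CDS, and
`γ = β_c/β_u`, each tested with a Wald z on the log2 scale using
propagated standard errors (`SE_log2γ` is the root-sum-of-squares of the
four log2 TE SEs) and Benjamini–Hochberg FDR control; plus the
buffered-pair screen (|log2 β_u| > 1.5 with q < 0.05, |log2 β_c| < 0.05
with q > 0.05, |log2 γ| > 1.5 with q < 0.05), dominant-uORF consistency
with a shuffle null, gene classes I/II/III, uORF-length grouping, and
CV-of-TE comparisons across samples. A seeded negative-binomial
translatome generator with full ground truth makes everything testable
without sequencing data.

## Worked example

```python
import uorfbuffer as ub

# default geometry: 150 nt leader, 50-codon uORF, 150 nt spacer,
# 500-codon CDS, 150 nt 3' UTR
layout = ub.build_layout()
params = ub.KineticParams(r_in=0.05, i_uorf=0.2, i_cds=0.8)  # downstream model
print(ub.run_simulation(layout, params, n_actions=100_000, seed=7))
```

```
SimCounters(n_ec=1429, n_eu=(623,), n_loaded=3248, n_dissoc_down=1133,
            n_dissoc_up=0, n_runoff=0, n_actions=100000, n_on_lattice=63)
```

Of 3248 loaded 40S subunits, 623 initiated and completed the uORF, 1133
were knocked off by elongating ribosomes (downstream dissociation), and
1429 completed the CDS — the translation-rate proxy `N_EC` (the rest were
still on the lattice when the run ended). Sweeping an `R_in` ensemble
shows the buffering:

```python
rin = ub.sample_rin("uniform_0_0.1", n=100, seed=1)
grid = {f"iu{i:g}": ub.KineticParams(i_uorf=i, i_cds=0.8) for i in (0.0, 0.5)}
table = ub.run_sweep({"default": layout}, grid, rin, n_actions=100_000, seed=42)
print({k: round(ub.summarize_cv(table, k), 3) for k in grid})
```

```
{'iu0': 0.422, 'iu0.5': 0.355}
```

CDS output varies less across the ribosome-availability ensemble when the
uORF is strongly initiated (CV 0.355 vs 0.422), even though its mean is
much lower — the repression/buffering trade-off at the heart of the model.

The statistics half consumes tidy TSVs (see `uorfbuffer synth` for the
dialect) or in-memory frames:

```python
from uorfbuffer import simulate_translatome, TranslatomeConfig
from uorfbuffer.stats import estimate_se_log2te, interspecies_divergence

counts, truth = simulate_translatome(TranslatomeConfig(n_genes=500), seed=5)
est = estimate_se_log2te(counts)
est = est.merge(counts[["feature_id", "feature_type"]].drop_duplicates())
beta, gamma = interspecies_divergence(est)   # per-feature and per-pair Wald tests
```

A `uorfbuffer` command-line tool exposes the same functionality:
subcommands `simulate`, `sweep`, `te`, `diverge`, `screen`, `classes`,
`synth`; every run writes a JSON manifest with the resolved configuration
and seed.

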
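# termpart

Tools for choosing, engineering and evaluating **transcription terminator
parts (3′UTR elements)** for nuclear transgene expression in the green alga
*Chlamydomonas reinhardtii*.

Obtaining reliable, high-level transgene expression in *C. reinhardtii* is
hard: integration is random, expression is frequently silenced over serial
subcultures, and regulatory parts differ widely in performance. The terminator
is an underexplored design variable. This package implements the
computational side of a systematic terminator screen, for synthetic
biologists and algal molecular biologists who want to:

1. **Survey the genome** — parse GFF3 gene models, measure 3′UTR/5′UTR/CDS
   size distributions (100-bp histograms), classify terminator lengths into
   short (<100 bp), medium (100–600 bp) and long (>600 bp) classes, and
   compute intergenic distances between adjacent genes.
2. **Rank expression** — order genes by mean FPKM across a diurnal RNA-seq
   time course (rank 1 = most expressed; ties take the minimum rank) and
   query how 3′UTR length relates to rank.
3. **Engineer parts** — select candidate terminators (rank ≤ 350 with named
   exceptions, length ≤ 1000 bp, carrying the *C. reinhardtii*
   polyadenylation motif **UGUAA** — DNA sense strand `TGTAA`), trim parts
   around the motif, *domesticate* them for MoClo/Golden Gate cloning by
   removing internal BsaI (`GGTCTC`) and BpiI (`GAAGAC`) sites with minimal
   substitutions, simulate type-IIS assemblies with 4-nt fusion sites, and
   verify plasmid-linearization cut uniqueness and flank lengths.
4. **Analyse plate screens** — transformation efficiency (colonies/µg, mean
   ± SEM over independent experiments with technical replicates averaged
   first), viability curves over three 7-day subcultures under selection,
   GFP-positive fractions among stable lines, and two-tailed Mann–Whitney
   U tests (exact enumeration or tie-corrected normal approximation,
   implemented from scratch and oracle-tested).
5. **Simulate everything** — a synthetic-data module generates genomes
   (FASTA + GFF3 with planted UTR lengths and motifs), diurnal FPKM
   matrices, and stochastic plate screens from per-construct parameters
   (Poisson colony counts, per-round Bernoulli survival, conditional GFP
   calls), each with a ground-truth sidecar.

## The statistics at the core

For a screen of construct *c*, each picked line survives subculture round
*r* with conditional probability *s_r*; round-3 viability is the marginal
*V = s₁s₂s₃* and is estimated as the fraction of the *n* picked lines still
growing, with binomial sampling error √(V(1−V)/n). GFP positivity is
Bernoulli(*g*) conditional on final viability, estimated over the realized
survivors. Transformation efficiency is Poisson-distributed colonies per µg;
constructs are compared with the two-tailed Mann–Whitney statistic
U = Σᵢⱼ [xᵢ > yⱼ] + ½[xᵢ = yⱼ], exact p by enumerating the null
distribution of U, with significance declared at p < 0.05.

## Worked example

```python
from termpart.presets import paper_screen_config
from termpart.synthetic_data import gen_screen
from termpart.screen_stats import (
    records_from_frame, counts_from_frame,
    stability_curve, gfp_fraction, transformation_efficiency,
)

sim = gen_screen(paper_screen_config(["RBCS2"], seed=1))
records = records_from_frame(sim.plates)
print("viability per round (%):", [round(v, 1) for v in stability_curve(records)])
print("GFP-positive of viable (%):", round(gfp_fraction(records).pct_positive, 1))
eff = transformation_efficiency(counts_from_frame(sim.colonies))
print("efficiency (colonies/ug):", round(eff.mean, 1), "+/-", round(eff.sem, 1))
```

prints

```
viability per round (%): [88.5, 80.2, 70.8]
GFP-positive of viable (%): 26.0
efficiency (colonies/ug): 2488.1 +/- 8.8
```

— three 96-line experiments with the baseline *RBCS2*-terminator
parameters: viability decays geometrically toward the ~74% round-3 target,
about a quarter of stable lines express GFP above threshold, and the
recovered efficiency sits within Poisson noise of the 2.47 × 10³
colonies/µg generating mean.

The same stages are scriptable from the shell:

```bash
termpart simulate screen --preset paper --seed 1 --out sim/
termpart analyze-screen --plates sim/plates.tsv --colonies sim/colonies.tsv \
    --baseline RBCS2 --out analysis/
termpart run --config run.yaml     # full simulate -> features -> rank -> select -> screen
```

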
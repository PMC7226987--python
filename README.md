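# puregulon

Inference of **PUM1/PUM2 RNA regulons** from RIP enrichment, knockdown
expression, motif scanning and protein-interactome data.

Mammalian Pumilio paralogues (PUM1, PUM2) are sequence-specific RNA-binding
proteins that recognize the same 8-nt PUM-binding element (PBE,
`UGUAHAUW`; H ∈ {A,C,U}, W ∈ {A,U}), typically in 3′UTRs, yet regulate
partially distinct mRNA pools — plausibly because each paralogue recruits a
different set of RBP cofactors. `puregulon` implements the full analysis
chain for dissecting such paralogue-specific post-transcriptional networks:

1. **Bound mRNAs** from RIP-seq abundance tables: a gene is *bound* when it
   is enriched ≥ 2-fold over both the IgG control and the transcriptome in
   **every** replicate, at BH-adjusted *p* < 0.05
   (`targets.rip_enrichment`).
2. **Regulated mRNAs** from knockdown RNA-seq: *repressed* when the level
   rises ≥ 20 % upon knockdown of its regulator (ratio ≥ 1.2, *q* < 0.05),
   *activated* when it falls ≥ 20 % (ratio ≤ 0.8); regulated targets are
   the intersection of bound and responsive genes
   (`targets.classify_kd`, `targets.intersect_regulated`).
3. **Motif content**: IUPAC and PWM scanning with an exact FIMO-style
   p-value → log-odds-threshold conversion (dynamic programming over the
   discretized background score distribution), 5′UTR/CDS/3′UTR
   attribution, dinucleotide-preserving shuffles, and exhaustive
   discriminative word discovery (`motifs`).
4. **Cofactors and the regulon**: PUM-interacting proteins from replicated
   co-IP mass-spectrometry presence tables (detected in all bait
   replicates, never in IgG; RNA dependence from ±RNase conditions);
   cofactor-motif co-occurrence enrichment in regulated targets against
   length-matched negatives with a length-correction coefficient
   c = mean L(targets) / mean L(negatives); hypergeometric term enrichment
   with Bonferroni and ClueGO-style filters; and the layered
   PUM → RBP cofactor → mRNA-group regulon graph (`cofactors`).
5. **RT-qPCR validation**: ΔΔCt quantification normalized to the geometric
   mean of two reference genes, Shapiro–Wilk + t-test significance
   (`qpcr`).

A first-class **synthetic-data generator** (`simulate`) produces every
input with known ground truth — negative-binomial counts with planted IP
enrichment and knockdown shifts, transcript sequences with planted
PBE/cofactor motifs, MS presence matrices, Ct tables — so the whole
pipeline is testable end to end without any external download.

## Worked example

```python
from puregulon import (SyntheticConfig, normalize_libraries, rip_enrichment,
                       classify_kd, intersect_regulated, venn_partition,
                       motif_set_stats)
from puregulon import simulate as sim

config = SyntheticConfig(seed=7, n_genes=1000)
records, truth = sim.generate_transcriptome(config)
tables = {**sim.generate_rip_tables(config, truth),
          **sim.generate_kd_tables(config, truth)}
norm = {k: normalize_libraries(v) for k, v in tables.items()}

bound, regulated = {}, {}
for pum, ip, si in (("PUM1", "IP_PUM1", "siPUM1"), ("PUM2", "IP_PUM2", "siPUM2")):
    enr = rip_enrichment(norm[ip], norm["IgG"], norm["transcriptome"])
    bound[pum] = {r.gene for r in enr if r.bound}
    calls = classify_kd(norm[si], norm["siControl"])
    regulated[pum] = intersect_regulated(bound[pum], calls)
    print(f"{pum}: {len(bound[pum])} bound, {len(regulated[pum])} regulated")

v = venn_partition(bound["PUM1"], bound["PUM2"])
print(f"bound overlap: {v.common} common of {v.union} ({v.pct_common_of_union:.1f}%)")

by_gene = {r.gene: r for r in records}
stats = motif_set_stats([by_gene[g] for g in regulated["PUM1"]], "UGUAHAUW")
print(f"PBE content of PUM1-regulated set: {stats.mean_hits_per_sequence:.2f}/mRNA, "
      f"{100*stats.frac_with_at_least_one:.1f}% with >=1 PBE, "
      f"{stats.region_pct[2]:.0f}% of PBEs in the 3'UTR")
```

prints

```
PUM1: 147 bound, 77 regulated
PUM2: 119 bound, 64 regulated
bound overlap: 48 common of 218 (22.0%)
PBE content of PUM1-regulated set: 2.52/mRNA, 92.2% with >=1 PBE, 94% of PBEs in the 3'UTR
```

i.e. the caller recovers the planted bound/regulated sets, the two
paralogues' target pools only partially overlap, and the regulated mRNAs
are PBE-rich with the elements concentrated in the 3′UTR — the signature
the pipeline is designed to detect.

The same stages are available from the shell:

```bash
puregulon simulate --seed 7 -o out            # synthetic inputs + ground truth
puregulon run-all --config pipeline.yaml      # simulate → targets → scan → cofactors → regulon → qpcr
puregulon scan --fasta t.fasta --regions r.tsv -o hits.tsv
```

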
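# mgrquant

Quantification of mitochondrial genome (mitogenome) rearrangement from gene
orders. Vertebrate mitogenomes carry 13 protein-coding genes, 2 rRNAs,
22 tRNAs and one control region (CR) on a circle; most species share the
ancestral "typical vertebrate" arrangement, but lineages such as
neobatrachian frogs have extensively rearranged orders. `mgrquant` is for
researchers who have gene orders (from GenBank annotations or tables) and a
phylogeny, and want to measure *where* and *how often* the genome is
rearranged, which arrangement patterns exist, whether rearranged species
cluster on the tree, and how old a shared pattern can be.

## The statistics

Against a reference arrangement in which every gene *g* is single-copy with
flanks (ℓ<sub>g</sub>, r<sub>g</sub>), each gene occurrence in a genome is
scored by its two nearest flanking neighbours:

- **Rearrangement score (RS)** per occurrence: number of changed flanks,
  RS ∈ {0, 1, 2}. Genome RS = Σ RS over all occurrences (CR included).
- **Rearrangement frequency (RF)** of gene *g* within a group:
  RF(g) = 100 · Σ RS(g) / (2 · n<sub>occ</sub>(g)) %, the accumulated score
  over its maximum attainable value. Runs of reference-adjacent genes with
  RF = 0 are *conserved segments*.
- **Pattern census**: genomes with identical circular orders (canonicalized
  to start at trnF) are merged; patterns occurring ≥ 3 times are *major*,
  ≤ 2 times *rare*. Local patterns restrict to the protein-coding genes or
  to hotspot regions (Region 1: nad4→rrnS, the nad5–nad6–cob + CR segment;
  Region 2: nad1→cox1, the IQM–WANCY tRNA clusters; Region 3: the
  nad5/nad6/cob order).
- **Phylogenetic clustering**: per-clade upper-tail hypergeometric
  enrichment of a binary tip label (e.g. rearranged vs typical),
  p = Σ<sub>i≥k</sub> C(K,i)·C(N−K,n−i)/C(N,n), Bonferroni-corrected over
  internal nodes; plus a single hypergeometric test of whether rare
  arrangements concentrate in thinly sampled families.
- **Pattern age bound**: the dated MRCA of the species sharing a pattern is
  the latest possible origin of that pattern (identical arrangements are
  assumed homologous).

A seeded simulator evolves gene orders along a phylogeny (tandem
duplication, tandem duplication–random loss, transposition, inversion,
single-gene loss; Poisson event counts per branch; hotspot-weighted
placement) and emits a ground-truth event log for parameter-recovery tests.

## Worked example

```python
>>> import mgrquant as mq
>>> mq.score_genome(mq.TYPICAL_NEOBATRACHIAN.order, mq.TYPICAL_VERTEBRATE)
GenomeScore(species_id='typical_neobatrachian', rs=10, n_rearranged_genes=8, n_rearranged_labels=8)
```

The typical neobatrachian arrangement differs from the vertebrate reference
only by the relocation of the L2–T–P–F tRNA cluster 3′ of the CR, yet eight
genes feel the change through their flanks, summing to genome RS = 10
(L2 and CR lose both flanks, scoring 2 each; S2, nad5, cob, T, P and F lose
one flank each).

The end-to-end demo simulates 60 genomes on a random coalescent tree,
scores them, and runs the census and the clustering test:

```sh
$ mgrquant demo --seed 3 --outdir demo_out
wrote 60 simulated orders and 7 events to demo_out
demo reports written to demo_out
```

With this seed, 7 events (5 tandem duplications, 1 TDRL, 1 gene loss)
produce 29 rearranged genomes. `demo_out/census.tsv` finds 4 major global
patterns (counts 31/12/11/4) plus one double and one single rare pattern;
`demo_out/rf.tsv` shows the hotspot structure (e.g. RF(CR) = 17.81 %,
RF(L2) = 7.75 %, RF(cox2) = 0.00 %); and `demo_out/phylo_test.tsv` reports
a minimum Bonferroni-adjusted clustering p of 5.07e-16 — the rearranged
genomes sit exactly where the event log placed their ancestral events.

Subcommands `score`, `rf`, `census`, `phylo-test`, `pattern-age` and
`simulate` expose the individual steps; every report embeds the reference
arrangement and comparison mode in its header.

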
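# bogforam

Curation and community analysis for freshwater-foraminifera 18S rRNA
metabarcoding.

Freshwater foraminifera are rare, poorly referenced protists that show up
in environmental amplicon surveys of *Sphagnum* bogs and similar habitats
as a handful of OTUs buried under contamination: failed libraries, marine
OTUs bled in from neighbouring lab work, PCR chimeras, and low-count
ghost cells created by index switching between multiplexed samples.
`bogforam` implements the bioinformatic workflow such a survey needs once
reads are merged:

- **OTU calling** — dereplication, swarm-style single-linkage clustering
  at edit distance 1, and removal of singletons, two-parent chimeras, and
  OTUs < 65% identical to the most abundant OTU;
- **table curation** — an audited cascade: drop samples < 500 reads and
  OTUs with < 100 reads or a single occurrence (iterated to a fixpoint),
  remove externally flagged contaminant OTUs/samples, re-check, rarefy
  each sample to 10,000 reads (hypergeometric, seeded), zero cells
  attributable to index switching (cells < 20 reads in OTUs > 1000 reads;
  single-read cells elsewhere), and keep OTUs with > 20 rarefied reads —
  with a step-by-step report that replays to the exact output;
- **community analysis** — weighted UniFrac
  `D(A,B) = Σᵢ bᵢ |pᵢ(A) − pᵢ(B)|` (optionally normalized to [0, 1]),
  classical PCoA with percent variance per axis,
  rare (< 25%) / intermediate (25–75%) / dominant (> 75%) classification
  of each OTU presence, and habitat-occupancy summaries;
- **a synthetic-community generator** with ground truth (injected failed
  samples, contaminants, switched reads, chimeras), so the entire
  pipeline is testable without sequencing data.

## Worked example

```python
from bogforam import (SimConfig, simulate_dataset, run_curation,
                      weighted_unifrac, pcoa, top_k_fraction, occupancy_summary)

table, metadata, truth = simulate_dataset(SimConfig(seed=1))
print(f"simulated: {table.shape[0]} OTUs x {table.shape[1]} samples, {table.total_reads()} reads")

curated, report = run_curation(table, flagged_otus=truth.contaminant_otu_ids, seed=1)
print(f"curated:   {curated.shape[0]} OTUs x {curated.shape[1]} samples, "
      f"{curated.total_reads()} rarefied reads")
print(f"removed samples: {sorted(report.removed_sample_ids())}")

frac, ids = top_k_fraction(curated, 5)
print(f"top-5 OTUs ({', '.join(ids)}) hold {100*frac:.1f}% of curated reads")

ordn = pcoa(weighted_unifrac(curated, truth.tree))
print(f"PCoA: PC1 {ordn.percent_variance[0]:.1f}%, PC2 {ordn.percent_variance[1]:.1f}% of variance")

summary, richness = occupancy_summary(curated, metadata)
print(f"specific OTUs: {(summary['specificity'] == 'specific').sum()} of {len(summary)}")
print(f"richness per location: {richness.to_dict()}")
```

prints:

```
simulated: 66 OTUs x 34 samples, 1335627 reads
curated:   42 OTUs x 30 samples, 189635 rarefied reads
removed samples: ['S11', 'S21', 'S27', 'S31']
top-5 OTUs (OTU33, OTU43, OTU39, OTU13, OTU42) hold 64.7% of curated reads
PCoA: PC1 54.6%, PC2 27.7% of variance
specific OTUs: 30 of 42
richness per location: {'acadia': 21, 'greenhouse': 20, 'hawley': 18, 'orono': 19}
```

Reading the numbers: the cascade removed the 4 failed libraries (all of
them injected — `truth.failed_sample_ids`) and all 6 flagged marine OTUs,
leaving a 42-OTU community in which five OTUs hold about two thirds of
the reads; the first two PCoA axes of the normalized weighted-UniFrac
matrix carry ~82% of the variance; and 30 surviving OTUs were detected in
exactly one location, matching the habitat restriction the generator
imposed.

The same workflow runs from the shell:

```bash
bogforam simulate --seed 1 --outdir sim/
bogforam curate --table sim/otu_table.tsv --flag-otus sim/flagged_otus.txt \
    --depth 10000 --seed 1 --out curated/
bogforam analyze --table curated/otu_table_curated.tsv --tree sim/tree.nwk \
    --metadata sim/metadata.tsv --out analysis/
```

and `bogforam call-otus --reads sim/reads.fasta --out called.tsv` covers
the calling stage for FASTA input with `>id;size=N;sample=S` headers.

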
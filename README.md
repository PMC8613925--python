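# nanoterm

Transcription-termination analysis of **full-length nascent-RNA long
reads** (FLEP-seq-style libraries: nuclear RNA ligated to a 3′ adapter,
reverse-transcribed with a template-switching oligo, and sequenced on a
long-read platform), plus a matched simulator so the whole pipeline can be
validated end to end without any external data.

## The problem

When RNA polymerase II reaches a gene's poly(A) site (pA) it does not stop:
the nascent transcript is cleaved and polyadenylated while Pol II continues
downstream, producing an uncapped 3′ fragment that a 5′→3′ "torpedo"
exonuclease degrades to dislodge the polymerase. Because each full-length
nascent read carries both its true 5′ end (marked by the template-switch
oligo, TSO) and its true 3′ end (marked by the ligated 3′ adapter), a single
read reveals which intermediate of this process it was:

| class | poly(A) tail | 5′ end | 3′ end |
|---|---|---|---|
| `POLYA` | > 15 nt | gene body | at pA |
| `READTHROUGH` | ≤ 15 nt | gene body (> 50 nt upstream of pA) | > 50 nt past pA |
| `CLEAVED_5P` | ≤ 15 nt | gene body | within ±50 nt of pA |
| `CLEAVED_3P` | ≤ 15 nt | within 500 nt past pA | > 50 nt past pA |

Non-poly(A) calls are trusted only when the 3′ adapter sits < 5 nt from the
aligned region. The per-gene **termination window** (TW) is the median
pA-to-3′-end distance of readthrough and 3′-cleavage reads ending > 50 nt
past the pA (≥ 15 such reads required); the **termination window end**
(TWE = pA + TW) is the modal Pol II release point. Between genotypes, TWs
are compared per gene with a two-sided Mann–Whitney *U* test (α = 0.001).

Poly(A) sites themselves are called from the aligned 3′ ends of
poly(A)-tailed reads: ends within 24 nt chain into a poly(A) site cluster
(PAC), clusters with fewer than 3 supporting reads are dropped, the
most-supported position is the representative site, and only single-PAC
genes enter termination analyses.

## Worked example

Simulate 40 genes (20% with downstream tRNAs) and run the pipeline:

```sh
nanoterm simulate --outdir demo --seed 11 --n-genes 40 \
    --reads-per-gene 80 --trna-fraction 0.2
nanoterm run --bam demo/reads.sam --annotation demo/genes.gff3 --outdir demo/out
```

which logs, on this seed:

```
annotation: 48 genes
ingest: 3200 alignments, 3200 primary, 3192 with both adapters
pA: 40 PACs, 40 single-PAC genes
classify: 3188/3192 classified; proportions {'POLYA': 0.599,
  'READTHROUGH': 0.247, 'CLEAVED_5P': 0.144, 'CLEAVED_3P': 0.009}
termination windows: 38 genes
38 genes with termination windows -> demo/out/tw.tsv
```

Reading the numbers: 8 of 3200 reads lost an adapter to the 5% base-error
model and were discarded (double-adapter rule), the recovered class mix
matches the configured (0.60, 0.25, 0.14, 0.01) proportions, and 38/40
genes cleared the 15-read threshold. `demo/out/tw.tsv` then holds one line
per gene, e.g.

```
gene_id    chrom   strand  pA     tw     twe    n_reads
gene0001   chrSim  +       7811   152.5  7964   18
gene0002   chrSim  -       11567  201.5  11365  24
```

— gene0001 terminates a median 152.5 nt past its poly(A) site at 7811, so
its TWE is 7964. Other outputs in `demo/out/`: per-read orientation and
tail tables, PACs and representative pA sites (BED), per-read classes,
TWE-to-tRNA distances, chimera calls, and a JSON run manifest with the
thresholds and stage counts.

The library surface mirrors the pipeline: `read_annotation`, `ingest_bam`,
`call_tail`, `cluster_pacs`, `classify_all`, `tw_table`, `compare_tw`,
`detect_chimeras`, `pair_genes_with_trnas` — see `docs/methods.md` for the
model and every threshold.

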
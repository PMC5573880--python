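# unitrans

Reference-genome-free reconstruction of full-length transcript models from
long-read transcript sequences — with isoform collapsing, model-based
alternative-splicing classification, and lncRNA identification.

## The problem

Full-length cDNA sequencing (PacBio Iso-Seq and kin) delivers complete
transcripts without assembly, which is transformative for species that have
no reference genome — medicinal plants, non-model crops, wild relatives.
But without a genome there is no coordinate system: isoforms of one gene
arrive as unrelated FASTA records, the consensus output is highly redundant,
and a "splice junction" has nowhere to live. `unitrans` rebuilds the missing
coordinate system from the reads themselves:

1. **correct** — hybrid error correction of long transcripts against a solid
   k-mer spectrum of accurate short reads (k=17, threshold 3);
2. **dedup** — greedy identity clustering removes redundant transcripts
   (identity ≥ 0.99, shorter-sequence coverage ≥ 0.99, ≤ 30 nt unaligned);
3. **families** — transcripts are partitioned into putative genes by k-mer
   profile similarity (24-mers, overlap coefficient, connected components);
4. **reconstruct** — each family becomes one (or, on conflict, several)
   **UniTransModel**: a pseudo-reference spelled by the maximum-weight path
   through the family's compacted De Bruijn graph (k=31), containing the
   ordered union of all segments observed across the family's isoforms;
5. **map / collapse / events** — transcripts are splice-aligned back onto
   their models; transcripts with identical junction chains collapse into
   isoforms; splicing differences between isoforms are classified into the
   six event types **SE, RI, A5, A3, AF, AL** in model coordinates;
6. **lncrna / stats** — a three-step noncoding screen (no protein homology
   hit at E ≤ 1e-3 → no ORF beyond 100 aa internal / 50 aa at ends →
   coding-potential score below threshold), plus N50, length histograms,
   full-length-ORF coverage classes and cross-tissue model matching.

A ground-truth-emitting simulator (`unitrans.sim`) generates gene regions
with exon/intron structure, isoform sets realized by the six event types,
noisy long reads and short reads for correction — so the entire pipeline is
testable with no external data. See `docs/methods.md` for the algorithms,
parameter rationale, and limitations.

## Worked example

Simulate six genes with 1% substitution noise plus 50× short-read coverage,
then run the in-memory pipeline:

```python
from unitrans import sim
from unitrans.pipeline import analyze_transcripts
from unitrans.isoforms import isoform_summary

ds = sim.simulate_dataset(6, seed=1, sub_rate=0.01, short_read_coverage=50)
res = analyze_transcripts(dict(ds.transcripts),
                          short_reads=[s for _, s in ds.short_reads])
print("transcripts in:      ", len(ds.transcripts))
print("non-redundant:       ", len(res["nonredundant"]))
print("families:            ", len(res["partition"].families))
print("UniTransModels:      ", len(res["models"]))
print("isoforms:            ", len(res["isoforms"]))
print("AS events:           ", [(e.type, e.coordinates) for e in res["events"]])
summ = isoform_summary(res["isoforms"])
print("multi-isoform models:", f"{100*summ['multi_isoform_fraction']:.0f}%")
```

prints

```
transcripts in:       15
non-redundant:        15
families:             6
UniTransModels:       6
isoforms:             15
AS events:            [('AF', (152, 403, 547)), ('RI', (152, 547)), ('RI', (403, 547)), ('RI', (439, 731)), ('RI', (1124, 1342)), ('A5', (368, 397, 436)), ('RI', (368, 436)), ('RI', (397, 436)), ('RI', (280, 510)), ('RI', (487, 745)), ('RI', (1005, 1229))]
multi-isoform models: 100%
```

The 15 noisy transcripts are corrected, stay distinct after dedup (they are
genuine isoforms, not duplicates), partition into the 6 true genes, and each
family reconstructs to a single model. Every event is reported in model
coordinates: `('RI', (439, 731))` means one isoform skips model positions
439–731 while another retains them — on a pseudo-reference a skipped exon
and a retained intron are the same observable, which is why RI dominates.
The `('A5', (368, 397, 436))` triple is two junctions sharing acceptor 436
with donors 368 and 397: an alternative donor site 29 nt apart.

The same stages are available as a CLI:

```bash
unitrans simulate --genes 20 --seed 1 --coverage 50 --out data/
unitrans correct --long data/transcripts.fasta --short data/short_reads.fastq --out corr.fasta
unitrans dedup --in corr.fasta --out nr.fasta --clusters clusters.tsv
unitrans families --in nr.fasta --out families.tsv
unitrans reconstruct --in nr.fasta --families families.tsv --out models.fasta
unitrans map --transcripts nr.fasta --models models.fasta --out aln.bed12
unitrans collapse --aln aln.bed12 --out isoforms.gtf
unitrans events --aln aln.bed12 --out events.tsv
unitrans run --transcripts data/transcripts.fasta --outdir out/   # end to end
```

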
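# primatx

Primary-transcriptome analysis for bacterial dRNA-seq: transcription
start site (TSS) detection, classification, 5'-UTR statistics,
differential promoter activity, CsrA-binding-site scanning and flexible
genomic island calling.

## Who this is for

Differential RNA sequencing (dRNA-seq) compares a library enriched for
primary 5' ends (terminator-exonuclease treated, "TEX+") against a
matched background library of processed 5' ends ("MINUS"). Peaks of
TEX+/MINUS enrichment locate TSSs at single-nucleotide resolution. From
there a primary-transcriptome study typically asks: where do promoters
sit relative to genes, how long are 5'-UTRs, which promoters change
activity between conditions, which 5'-UTRs carry post-transcriptional
regulator binding sites, and which genome regions are flexible between
related strains. `primatx` implements that whole desk pipeline on
standard file formats (FASTA, GFF3, bedGraph, BLAST tabular), plus a
synthetic-study generator with planted ground truth so every stage is
testable without any sequencing data.

## The methods

* **TSS detection, replicate-assisted.** Per position, enrichment
  `E = s_TEX / (s_MINUS + c)` on depth-scaled counts with pseudocount
  `c`; a position with raw TEX count >= `min_height` (default 10) is
  called in a condition when `E >= min_enrichment` (default 2) in both
  replicates (configurable rule). Jittered 5' ends within 5 nt are
  clustered (representative = highest TEX count); per-condition sets are
  merged into a union with per-condition activity flags.
* **Classification.** gTSS: same strand, 1-200 nt upstream of a CDS
  start (optionally extended beyond 200 nt where RNA-seq coverage is
  continuous to the start codon); iTSS: sense, inside a gene; aTSS:
  antisense, inside a gene +-50 nt; nTSS: intergenic or serving an
  ncRNA. Precedence gTSS > iTSS > aTSS > nTSS picks the reported
  category; all firing rules are retained.
* **Differential promoter activity.** Tag counts per TSS (+-5 nt),
  TMM normalization (trimmed mean of M-values, authored here and
  cross-checked against edgeR), common negative-binomial dispersion by
  conditional maximum likelihood, and a two-group exact NB test per TSS
  conditioning on its total count; Benjamini-Hochberg FDR with calls at
  |log2FC| >= 1 and FDR < 0.05.
* **CsrA-site scanning.** 5'-UTR suffixes matching
  `GGA[ACGT]{4,70}GGA[ACGT]{2,12}$` (two GGA cores with bounded spacers,
  anchored at the start codon), plus a generic IUPAC motif scanner.
* **Flexible genomic islands.** Long high-identity alignment hits are
  chained collinearly (length-weighted longest increasing subsequence on
  subject coordinates); every anchor-free query interval >= 10 kb is an
  island. Conserved proteins are flagged at e-value < 1e-5, > 80% query
  coverage, > 30% identity (all strict).

## Worked example

```python
import primatx

config = primatx.SimulationConfig(seed=42)
annotation, truth, tracks = primatx.simulate_bundle(config)

calls = primatx.detect_tss(tracks, primatx.DetectionConfig())
print(f"{len(calls)} TSSs called "
      f"({sum('A' in c.active_conditions for c in calls)} active in A, "
      f"{sum('B' in c.active_conditions for c in calls)} in B)")

rnaseq = next(t for t in tracks if t.meta.treatment == "RNASEQ")
cls = primatx.ClassificationConfig(use_coverage_extension=True)
records = primatx.classify_all(calls, annotation, cls, rnaseq)
census = primatx.summarize_tss_counts(records)["grand_total"]["union"]
for cat, (n, pct) in census["categories"].items():
    print(f"  {cat}: {n} ({pct}%)")

stats = primatx.compute_utr_statistics(records, cls)
print(f"median 5'-UTR {stats['median_utr']:.0f} nt, "
      f"{stats['leaderless']} leaderless, {stats['long_utr']} long (>200 nt)")

results = primatx.run_differential(records, tracks,
                                   dispersion_groups=["A", "A", "B", "B"])
n_up = sum(r.call == "up" for r in results)
n_down = sum(r.call == "down" for r in results)
print(f"{n_up} promoters up, {n_down} down at 43 vs 37 ppt-style contrast")

metrics = primatx.evaluate_detection(calls, truth, tolerance=5)
print(f"planted-TSS recall {metrics['recall']:.3f}, "
      f"precision {metrics['precision']:.3f}")
```

prints

```
198 TSSs called (188 active in A, 171 in B)
  gTSS: 131 (66.16%)
  iTSS: 43 (21.72%)
  aTSS: 5 (2.53%)
  nTSS: 19 (9.6%)
median 5'-UTR 61 nt, 1 leaderless, 1 long (>200 nt)
5 promoters up, 7 down at 43 vs 37 ppt-style contrast
planted-TSS recall 0.990, precision 1.000
```

Reading this: the detector recovered 198 of 200 planted promoters with
no false calls; two thirds lead annotated genes (gTSS) with a 61-nt
median leader, and the exact NB test flagged 12 promoters whose activity
shifts between the two simulated conditions.

The same pipeline runs from the shell:

```bash
primatx simulate --seed 42 --out fixtures/default
primatx detect --tex A1=... --minus A1=... --out tss.tsv
primatx classify --fasta genome.fasta --gff3 annotation.gff3 --tss tss.tsv
primatx diffexp --tex A1=... --fasta ... --gff3 ... --tss tss.tsv
primatx csra-scan --fasta utrs.fasta
primatx fgi --hits blast.tsv --genome-length 4630082 --out fgi.bed
```

## Layout

```
src/primatx/
  genome_model.py    FASTA/GFF3 model, 5'-UTR and promoter extraction
  end_coverage.py    strand-specific 5'-end count tracks (bedGraph, BAM)
  tss_detection.py   TEX/MINUS enrichment, replicate rules, clustering
  tss_annotation.py  gTSS/iTSS/aTSS/nTSS rules, UTR stats, census
  diffexp.py         TMM, qCML dispersion, exact NB test, BH calls
  motif_scan.py      CsrA regex scanner, IUPAC motif scanner
  comparative.py     conserved-protein filter, flexible-island caller
  synthetic.py       planted-truth study generator
  cli.py             `primatx` command-line interface
```

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
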
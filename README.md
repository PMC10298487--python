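# circkit

Characterization and microRNA-stimulation enrichment analysis of circular
RNA (circRNA) back-splice-junction catalogs.

Starting from upstream outputs — junction calls (DCC-style, BED or TSV), a
gene annotation (GTF), per-gene linear transcript abundances, a known-circRNA
database (BED) and per-condition differential-expression tables — circkit
produces:

- a **catalog**: host-gene assignment (containment + strand, deterministic
  tie-breaking), spliced lengths (union-exon intersection with intronic/
  intergenic fallback), novel-vs-known classification, and headline summary
  counts;
- **genome-distribution** tables: per-chromosome gene/circRNA counts with
  Spearman correlation, circRNAs-per-gene multiplicity, and host-structure
  vs abundance correlations;
- **circular-vs-linear** abundance trichotomy (lower / approximately equal /
  higher within a configurable fold window, pseudocount-guarded);
- **RNA-seq/qPCR concordance**: Spearman rho with an exact permutation
  p-value for n ≤ 10 (t-approximation beyond);
- the **length/exon ratio index**: host genes are classed by genomic-length /
  exon-count ratio against the genome-wide average, and overrepresentation
  of upregulated circRNAs in the low-ratio class is tested with a 2×2
  chi-squared test (optional Yates correction and seeded label-permutation
  p-value), plus microRNA target-site overlap counts and recurrent-responder
  detection across conditions;
- a **synthetic-data generator** that emits complete, internally consistent
  input bundles (GTF, calls, linear quant, known DB, DE tables, qPCR,
  target lists) with recoverable ground truth — byte-identical for a given
  seed — so the whole pipeline is testable without any external data.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact concordance
value, chi-squared closed-form identity, exact Spearman p vs brute-force
enumeration, conservation invariants, planted-effect recovery and type-I
calibration, truth round-trips). The simulation-heavy tests take ~2 minutes.

## CLI

```sh
# generate a seeded synthetic bundle (config optional, YAML)
circkit simulate --out bundle/ --seed 1

# catalog characterization
circkit characterize --gtf bundle/annotation.gtf \
    --circ bundle/circ_calls.tsv --dialect tsv \
    --known-db bundle/known_db.bed --linear bundle/linear_quant.tsv \
    --out results/

# RNA-seq vs qPCR concordance (packaged 10-circRNA validation panel)
circkit concordance --builtin-panel

# ratio-index enrichment per condition
circkit enrich --catalog results/catalog.tsv --gtf bundle/annotation.gtf \
    --de miR-191=bundle/de_miR-191.tsv --de miR-126=bundle/de_miR-126.tsv \
    --targets miR-191=bundle/targets_miR-191.txt \
    --out results/

# everything in one run
circkit report --gtf ... --circ ... --known-db ... --linear ... \
    --qpcr bundle/qpcr.tsv --de miR-191=bundle/de_miR-191.tsv --out results/
```

All outputs are TSV/JSON; a `manifest.json` records parameters and input
checksums so every number is reproducible from the recorded configuration.

## Conventions

- Internal coordinates are 1-based inclusive; BED and DCC inputs are
  converted on load.
- Junction identifiers are `chrom:start–end` (en dash; ASCII hyphen
  accepted on parse).
- Host assignment requires full containment of the junction in the gene
  span; ties go to larger reciprocal exon overlap, then smaller gene,
  then lexicographic id.
- Circ and linear abundances are compared on the read-count scale without
  length normalization; the fold window and pseudocount are configurable.
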
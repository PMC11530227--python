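# annopipe

Fast functional annotation of *de novo* assembled transcriptomes.

Deeply sequenced transcriptomes assembled without a reference genome
arrive as large, heavily redundant sets of transcripts with no biological
context. `annopipe` turns them into annotated sequences in one pass: it
optionally collapses redundant transcripts by linear-time greedy
clustering, searches each (representative) translated sequence against a
curated **protein sequence database** (Swiss-Prot-like: homolog
descriptions, GO terms, orthogroups) and against any number of **profile
databases** (Pfam/eggNOG-like: domain families as position-specific
scoring matrices built from multiple sequence alignments), and transfers
the annotations of significant matches back to the queries as a single
merged TSV plus a summary of the annotation rate.

It is aimed at researchers who need desk-scale, fully reproducible
annotation runs — custom databases are first-class, and a built-in fixture
generator produces complete synthetic reference databases with planted
ground truth, so the whole pipeline is testable without downloading
anything.

## Method

**Clustering.** Sequences are processed longest-first; each sequence
joins the first established cluster representative it shares a k-mer with
*and* verifies against by gapped local alignment (identity ≥
`min_seq_id`, default 0.9, computed as matches / alignment columns;
bidirectional coverage ≥ `min_cov`, default 0.8), otherwise it founds a
new cluster. At most `kmers_per_seq` candidate centres are
alignment-verified per sequence, so the work is linear — no all-vs-all
comparison. Clustering is optional (`--no-run-clust`); representative
annotations are propagated back to cluster members by default.

**Search.** Sequence databases are searched with a diagonal k-mer
prefilter (targets sharing ≥ 2 exact 5-mers within a diagonal band of ±4)
followed by Smith–Waterman local alignment under BLOSUM62 with affine gap
costs (a gap of length *k* costs 11 + *k*·1). Statistical significance
follows the Karlin–Altschul model,

    bit = (λS − ln K) / ln 2,    E = m · n · 2^(−bit),

with the published gapped BLOSUM62-11/1 parameters (λ = 0.267, K = 0.041)
and search space m·n = query length × database letters. Profiles are
compiled from MSAs into half-bit log-odds PSSMs over their match columns
(≤ 50 % gaps) with substitution-matrix pseudocounts, and aligned locally
against queries with the same affine gap model. Each profile's Gumbel
parameters (λ, K) are calibrated by scoring shuffled background-composition
sequences and fitting by the method of moments, so profile hits carry
E-values: E = K · L<sub>profile</sub> · m · e^(−λS). Repeated domains are
found by masked re-alignment. Only hits with **E < 1e-5** are kept.

**Retention and transfer.** Per query, a sequence database contributes at
most its single best hit (minimal E-value); a profile database contributes
a maximal set of non-overlapping hits along the query, selected greedily
by E-value, so distinct regions each receive a domain assignment. A query
counts as *annotated* if it has ≥ 1 retained match at ≥ 50 % identity in
any database; the annotation rate is the fraction of annotated queries.

## Worked example

Generate the synthetic demo data, compile both databases, and annotate:

```bash
python -c "from annopipe import fixtures; fixtures.make_default_fixture('.', seed=1)"

annopipe createdb seqdb/targets.fasta --metadata seqdb/targets.tsv \
    --role sequence --out dbs/sprot
annopipe createdb profdb/msas --metadata profdb/profiles.tsv \
    --role profile --out dbs/pfam --seed 1

annopipe annotate queries/queries.fasta \
    --db sprot:sequence:dbs/sprot --db pfam:profile:dbs/pfam \
    --outdir out --no-run-clust --seed 1
```

The log reports per-stage counts:

```
INFO loaded 40 query sequences
INFO loaded 2 databases: sprot, pfam
INFO clustering disabled; annotating all 40 queries
INFO db sprot: 36 hits below E=1e-05
INFO db pfam: 36 hits below E=1e-05
INFO wrote 72 annotation records; 36/40 queries annotated (90.0%)
```

`out/annotations.tsv` holds one row per retained hit (a query may own
several rows — one best sequence hit plus one row per tiled domain):

```
query_id  db_name  target_id  q_start  q_end  e_value   pct_identity  bit_score  domain_name
Q0004     sprot    T0028      3        241    3.85e-96  70.71         338.58
Q0005     pfam     PF001      304      391    3.77e-65  80.68         229.10     DOM_PF001
Q0005     sprot    T0040      1        289    3.63e-112 69.90         392.50
```

Q0005 is a planted homolog of target T0040 (mutated to ~70 % identity,
recovered at 69.9 %) carrying a planted copy of domain family PF001 at
query positions 304–391 — both are found, and nothing else is.
`out/summary.json` gives the totals: 36 of 40 queries annotated
(`annotation_rate` 0.9); the remaining 4 are the fixture's random decoys,
which correctly receive no annotation at E < 1e-5.

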
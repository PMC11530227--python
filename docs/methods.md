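# Methods

This note documents the models and algorithms behind `annopipe`, the
parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not demonstrate.

## Problem setting

Functional annotation of a transcriptome means associating each
(translated) transcript with the identity of its closest well-studied
homolog, its orthologous group and GO terms, and its domain architecture.
The pipeline assumes protein queries (FASTA); nucleotide sequences and
FASTQ reads are accepted and converted to protein queries by six-frame
translation and ORF extraction, at a substantial cost in query count and
run time.

## Input handling

- **Translation** uses the standard genetic code (translation table 1).
  No organism-specific code is configurable at present; mitochondrial or
  ciliate transcripts would be mistranslated at their reassigned codons.
- **ORFs** are maximal stop-free stretches across all six frames with
  length ≥ `min_orf_len` (default 30 aa). They deliberately do not
  require an initiator methionine: local homology search scores any frame
  segment, so stop-to-stop stretches are the faithful unit. Codons
  containing N translate to X; X scores 0 (neutral) against everything.
- **Paired-end FASTQ** is interleaved into one query set; mate ids get
  `/1`/`/2` suffixes when the two files reuse ids. Single-end input must
  be one pre-concatenated file — two single-end files are rejected with
  exit status 2. On the external-assembly path every read must be
  ≥ 100 nt; shorter reads abort the run before the assembler is invoked.

## Clustering

Greedy single-pass clustering over sequences sorted longest-first (ties
by id). Each sequence collects the established representatives it shares
a k-mer with (k = 10), ranked by shared-distinct-k-mer count, and is
alignment-verified against at most `kmers_per_seq` (20) of them; it joins
the first that verifies, else founds a new cluster. Consequences:

- the representative is always a longest member (ties: smallest id);
- verification work is ≤ n · 20 alignments (a counter on the result
  object asserts this, rather than trusting the design);
- every (representative, member) pair genuinely satisfies the thresholds
  — identity is matches / alignment columns (gap columns count against
  identity), and coverage is bidirectional: the local alignment must span
  ≥ `min_cov` of member *and* representative.

Defaults: `min_seq_id` 0.9, `min_cov` 0.8 — conservative collapsing of
near-identical isoforms. A permissive setting such as `--min-seq-id 0.3`
merges distant isoforms and is appropriate only when a non-redundant gene
catalogue is wanted. A seeded min-hash k-mer sketch (`select_kmers`, the
m smallest splitmix64-hashed k-mers) is provided as the subsampling
primitive for index growth beyond desk scale; at desk scale
representatives are indexed by all their k-mers, because with m = 20 and
k = 10 a sketch-vs-sketch probe can miss a true 90 %-identity member when
its mutations are well spread (~2 % of members), whereas a full-index
probe misses only if *no* k-mer is conserved.

## Search engine

### Sequence databases

Two stages. The **prefilter** indexes all target 5-mers and admits
targets sharing ≥ 2 exact 5-mers with the query on a common diagonal band
(diagonal = t_pos − q_pos, width ±4). Exact matching (no reduced
alphabet, no similar-k-mer generation) is a deliberate simplification:
at ≥ 60 % identity and realistic target lengths (150–400 aa) planted
homologs reliably pass, and the sensitivity loss on much shorter targets
is quantified by the test suite rather than hidden. **Verification** is
full Smith–Waterman with affine gaps (Gotoh three-state DP; gap of length
k costs `gap_open` + k·`gap_extend` = 11 + k). Scores are exact integers
under BLOSUM62 and are checked against an independent brute-force DP in
the tests.

E-values follow Karlin–Altschul: bit = (λS − ln K)/ln 2 and
E = m·n·2^(−bit) with the published gapped BLOSUM62-11/1 parameters
(λ = 0.267, K = 0.041). The search space is query length × total letters
of *that* database; each database is searched and filtered independently.

### Profile databases

Each MSA is compiled to a PSSM over its match columns (columns with
≤ 50 % gaps). Column frequencies are regularised with
substitution-matrix pseudocounts, f′ = (n·f + α·g)/(n + α) with α = 1,
where g is the BLOSUM62-conditional background implied by the observed
column (gₐ = Σ_b f_b·P(a|b), P(a|b) ∝ pₐ·2^(s(a,b)/2)); scores are
half-bit log-odds 2·log₂(f′ₐ/pₐ). The consensus is the argmax-score
residue per column, so the consensus always attains the column maximum —
an asserted invariant. Queries align locally against PSSM columns with
the same affine gap model; identity for profile hits is query-vs-consensus.

Because PSSM score systems have no published Gumbel parameters, each
profile is **calibrated**: 200 random sequences of length 100 drawn from
the BLOSUM62 background composition are aligned to the profile and the
score distribution fitted by moments (λ = π/(σ√6), μ = mean − γ/λ,
K = e^(λμ)/(L_profile·100)). Calibration is deterministic per seed, and
compiled databases store the fitted parameters. Null-score variance of
zero aborts with a calibration error. The moment fit is accurate to a few
percent at n = 200, which is ample against a pass threshold of E < 1e-5 —
planted domains score orders of magnitude below it.

Profile databases are searched without a prefilter (profile counts are
small at the intended scale). Repeated domains are found by masked
re-alignment: after each retained hit the aligned query span is replaced
by X (scoring 0 against all columns, so the masked region cannot seed or
bridge an alignment) and the query re-aligned, up to 10 iterations or
until the E-value threshold fails.

### Determinism and tie-breaking

All hit lists are ordered by (query id, database, E-value ascending, bit
score descending, target id). Inside the DP, ties prefer the diagonal
move, then a gap in the query, then a gap in the target, and the
alignment endpoint is the first maximum in row-major order — one specific
optimal alignment is always reproduced bit-identically. Two runs with the
same configuration and seed produce byte-identical output files.

## Retention policies and transfer

- **Sequence databases:** only the best hit per query is retained
  (minimal E-value; ties by maximal bit score, then smallest target id).
- **Profile databases:** a maximal non-overlapping set of hits along the
  query, selected greedily in (E-value, −bit, q_start, target id) order;
  a hit is accepted iff it shares ≤ `max_overlap` residues (default 0)
  with every accepted hit. Greedy selection is chosen over exact weighted
  interval scheduling for determinism and speed; the testable contract is
  that the result is pairwise non-overlapping, maximal (no rejected hit
  could be added), and covers at least the best single hit.
- **Propagation:** when clustering ran, each representative's records are
  copied to its members with an `inherited` column naming the
  representative (default on). On exact-duplicate inputs this makes
  clustering + propagation annotate exactly the same member ids as
  running unclustered.
- A query is **annotated** iff it owns ≥ 1 record with identity ≥ 50 %
  (the `identity_threshold`), in any database; the threshold is applied
  uniformly to sequence identity and profile-consensus identity.

Output: a 13-column TSV (1-based inclusive query coordinates, E-values
formatted `%.3g`), a summary JSON, an unannotated-query sidecar, the
cluster table, and optional per-database BLAST-tabular (M8) dumps.

## Synthetic fixtures: what they show and what they don't

The fixture generator emits random proteins from the BLOSUM62 background
composition; homologs and MSA rows are derived by point substitutions
drawn from the BLOSUM62-conditional probabilities, so a "70 % identity
homolog" is a biologically plausible one under the same model family the
scoring assumes. The default desk-scale conditions are 50 targets
(150–400 aa), 8 profile families (MSAs of 10 rows at 90 % identity,
60–120 columns), 40 queries with homologs planted at 70 % identity,
domains at 80 % consensus identity, and 10 % pure-random decoys.

Passing tests on these fixtures demonstrate that the machinery is
correct: planted signal at stated identities is recovered, decoys are
rejected at the E-value threshold, policies match their oracles exactly.
They do **not** demonstrate annotation rates on real data: real
transcriptomes contain fragmented ORFs, compositional bias, low-complexity
regions, gapped domain families, and true-but-remote homology near the
detection limit, none of which the generator simulates. Problem sizes
were chosen so the full test suite and the acceptance script complete in
minutes on a single CPU; they are the package's own study conditions, and
the acceptance script regenerates everything from a seed at run time.

## Other design choices and limitations

- `threads` is accepted for interface stability but the engine is
  single-threaded; the deterministic merge-order contract is therefore
  trivially satisfied. The DP kernels are pure Python tuned for desk
  scale (~10⁴–10⁵ cells/ms); large transcriptomes against large databases
  are out of the intended envelope.
- Assembly is an external-command hook (`--assembler-cmd`, with
  `{in1}`/`{in2}`/`{out}` placeholders), never reimplemented; without it,
  reads are translated and searched directly.
- Profiles are PSSMs with affine gaps, not HMMs: no per-position
  insert/delete probabilities, no forward-algorithm E-values. Gappy
  families lose their indel structure beyond the 50 % match-column rule.
- GO terms are transferred verbatim from target metadata; no propagation
  up the ontology DAG.
- An optional empirical recalibration of the sequence-search Gumbel
  parameters uses the same shuffling machinery as profile calibration
  (`refdb.fit_gumbel`); the shipped defaults are the published constants.
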
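"""End-to-end annotation pipeline orchestration.

The run proceeds: read input -> (translate/extract ORFs if nucleotide) ->
optional redundancy clustering -> search every configured database ->
apply retention policies and transfer annotations -> write the merged TSV,
summary JSON and sidecars.  The CLI is a thin wrapper around
:func:`run_annotate`; library users can call it directly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

from . import annotator, clusterer, refdb, search, seqio
from .errors import ConfigError, UserInputError

logger = logging.getLogger("annopipe")


@dataclasses.dataclass
class DbSpec:
    """One target database: (name, role, payload path(s))."""

    name: str
    role: str  # "sequence" | "profile"
    path: Path
    metadata_path: Optional[Path] = None  # None for compiled directories

    def __post_init__(self):
        if self.role not in ("sequence", "profile"):
            raise ConfigError(
                f"db {self.name!r}: role must be 'sequence' or 'profile', "
                f"got {self.role!r}")


@dataclasses.dataclass
class RunConfig:
    """Effective configuration of one annotation run."""

    input_paths: list[Path]
    db_specs: list[DbSpec]
    outdir: Path
    input_kind: str = "auto"  # auto|protein|nucleotide|fastq
    run_clust: bool = True
    propagate: bool = True
    min_seq_id: float = 0.9
    min_cov: float = 0.8
    max_evalue: float = 1e-5
    max_overlap: int = 0
    min_orf_len: int = seqio.DEFAULT_MIN_ORF_LEN
    seed: int = 42
    threads: int = 1
    write_m8: bool = False
    assembler_cmd: Optional[str] = None

    def search_params(self) -> search.SearchParams:
        return search.SearchParams(max_evalue=self.max_evalue)

    def cluster_params(self) -> clusterer.ClusterParams:
        return clusterer.ClusterParams(
            min_seq_id=self.min_seq_id, min_cov=self.min_cov, seed=self.seed)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for key in ("input_paths",):
            d[key] = [str(p) for p in d[key]]
        d["db_specs"] = [
            {k: (str(v) if v is not None and k.endswith("path") else v)
             for k, v in spec.items()}
            for spec in d["db_specs"]]
        d["outdir"] = str(d["outdir"])
        return json.dumps(d, indent=2, sort_keys=True)


def _sniff_kind(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("@"):
        return "fastq"
    if not first.startswith(">"):
        raise UserInputError(f"{path}: neither FASTA nor FASTQ")
    # FASTA: decide dna vs protein from the residue composition
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                if body:
                    break
                continue
            body.append(line.strip())
    residues = "".join(body).upper()
    if residues and set(residues) <= set("ACGTN"):
        return "nucleotide"
    return "protein"


def load_queries(config: RunConfig) -> list[seqio.SequenceRecord]:
    """Read the input files and produce the protein query set."""
    kind = config.input_kind
    if kind == "auto":
        kind = _sniff_kind(config.input_paths[0])
        logger.info("input kind auto-detected as %s", kind)
    if kind == "protein":
        if len(config.input_paths) != 1:
            raise ConfigError("protein FASTA input expects exactly one file")
        return seqio.read_fasta(config.input_paths[0], "protein")
    if kind == "nucleotide":
        if len(config.input_paths) != 1:
            raise ConfigError("nucleotide FASTA input expects exactly one file")
        logger.warning(
            "nucleotide input: running six-frame ORF extraction; expect a "
            "large run-time penalty compared to supplying translated "
            "amino-acid sequences")
        nt_records = seqio.read_fasta(config.input_paths[0], "dna")
        queries = []
        for rec in nt_records:
            for orf in seqio.extract_orfs(rec, config.min_orf_len):
                queries.append(orf.to_sequence_record())
        logger.info("extracted %d ORFs (>= %d aa) from %d nucleotide records",
                    len(queries), config.min_orf_len, len(nt_records))
        return queries
    if kind == "fastq":
        if len(config.input_paths) == 1:
            reads = seqio.read_fastq(config.input_paths[0])
        elif len(config.input_paths) == 2:
            reads = seqio.interleave_paired(
                seqio.read_fastq(config.input_paths[0]),
                seqio.read_fastq(config.input_paths[1]))
        else:
            raise ConfigError("FASTQ input expects one or two files")
        logger.info("translating %d reads to ORFs for direct search", len(reads))
        queries = []
        for rec in reads:
            for orf in seqio.extract_orfs(rec, config.min_orf_len):
                queries.append(orf.to_sequence_record())
        return queries
    raise ConfigError(f"unknown input kind {kind!r}")


def load_databases(config: RunConfig):
    """Load/compile every configured database; returns loaded db objects."""
    if not config.db_specs:
        raise ConfigError("at least one --db specification is required")
    dbs = []
    for spec in config.db_specs:
        if not Path(spec.path).exists():
            raise UserInputError(f"database {spec.name!r}: path {spec.path} not found")
        if spec.metadata_path is None:
            db = refdb.load_compiled_db(spec.path, logger)
            loaded_role = ("sequence" if isinstance(db, refdb.SequenceDatabase)
                           else "profile")
            if loaded_role != spec.role:
                raise ConfigError(
                    f"database {spec.name!r}: compiled role {loaded_role} does "
                    f"not match declared role {spec.role}")
            db.name = spec.name
        elif spec.role == "sequence":
            db = refdb.build_sequence_db(spec.path, spec.metadata_path,
                                         spec.name, logger=logger)
        else:
            db = refdb.load_profile_db(
                spec.path, spec.metadata_path, spec.name,
                refdb.CalibrationParams(seed=config.seed), logger=logger)
        dbs.append(db)
    return dbs


def run_annotate(config: RunConfig) -> annotator.AnnotationSummary:
    """Execute the full pipeline; writes all outputs into config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json() + "\n")

    queries = load_queries(config)
    logger.info("loaded %d query sequences", len(queries))
    dbs = load_databases(config)
    logger.info("loaded %d databases: %s", len(dbs),
                ", ".join(f"{d.name}" for d in dbs))

    if config.run_clust:
        cluster_set = clusterer.cluster(queries, config.cluster_params())
        clusterer.write_cluster_tsv(cluster_set, outdir / "clusters.tsv")
        reps = clusterer.representatives(cluster_set, queries)
        logger.info("clustered %d queries into %d clusters "
                    "(%d verification alignments)",
                    len(queries), len(cluster_set.clusters),
                    cluster_set.n_alignments)
    else:
        cluster_set = None
        reps = queries
        logger.info("clustering disabled; annotating all %d queries", len(reps))

    params = config.search_params()
    all_hits: list[search.SearchHit] = []
    for db in dbs:
        if isinstance(db, refdb.SequenceDatabase):
            hits = search.search_sequence_db(reps, db, params)
        else:
            hits = search.search_profile_db(reps, db, params)
        logger.info("db %s: %d hits below E=%g", db.name, len(hits),
                    config.max_evalue)
        if config.write_m8:
            search.write_m8(hits, outdir / f"{db.name}.m8")
        all_hits.extend(hits)

    query_order = [q.id for q in queries]
    records = annotator.assemble_annotations(
        all_hits, dbs, query_order, cluster_set,
        propagate=config.propagate, max_overlap=config.max_overlap,
        logger=logger)
    annotator.write_annotation_tsv(records, outdir / "annotations.tsv")
    annotator.write_unannotated(records, query_order,
                                outdir / "annotations.unannotated.txt")
    summary = annotator.summarize(records, query_order, logger=logger)
    annotator.write_summary_json(summary, outdir / "summary.json")
    logger.info("wrote %d annotation records; %d/%d queries annotated (%.1f%%)",
                len(records), summary.n_annotated, summary.n_queries,
                100.0 * summary.annotation_rate)
    return summary
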
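"""Hit-retention policies and annotation transfer.

Two retention policies turn raw search hits into annotations:

* **sequence databases** — only the single best hit per query is retained
  (minimal E-value; ties by maximal bit score, then smallest target id),
  and its homolog description/GO terms/orthogroup are transferred;
* **profile databases** — a maximal set of non-overlapping hits along the
  query is retained, so distinct query regions each receive a domain
  assignment.  Selection is greedy in (E-value asc, bit score desc,
  q_start asc, target id) order; a hit is accepted iff its query interval
  shares at most ``max_overlap`` residues (default 0) with every hit
  already accepted.

When clustering was run, a representative's annotations are propagated to
all cluster members (the ``inherited`` column names the representative).
A query counts as *annotated* if it owns at least one record at >= 50%
identity to its match, in any database — this is the definition behind the
reported annotation rate.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

from .clusterer import ClusterSet
from .refdb import AnnotationMeta
from .search import SearchHit

DEFAULT_IDENTITY_THRESHOLD = 0.5

TSV_COLUMNS = [
    "query_id", "db_name", "target_id", "q_start", "q_end", "e_value",
    "pct_identity", "bit_score", "description", "go_terms", "orthogroup",
    "domain_name", "inherited",
]


@dataclasses.dataclass(frozen=True)
class AnnotationRecord:
    """One output row: a target's annotations transferred to a query.

    Coordinates are 1-based inclusive (report convention); ``inherited``
    is empty for direct hits, else the representative the record was
    copied from.
    """

    query_id: str
    db_name: str
    db_role: str
    target_id: str
    q_start: int
    q_end: int
    e_value: float
    pct_identity: float
    bit_score: float
    description: str = ""
    go_terms: tuple[str, ...] = ()
    orthogroup: str = ""
    domain_name: str = ""
    inherited: str = ""


@dataclasses.dataclass
class AnnotationSummary:
    n_queries: int
    n_annotated: int
    annotation_rate: float
    per_db_counts: dict[str, int]
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "n_queries": self.n_queries,
            "n_annotated": self.n_annotated,
            "annotation_rate": self.annotation_rate,
            "per_db_counts": dict(sorted(self.per_db_counts.items())),
            "identity_threshold": self.identity_threshold,
        }


def best_hit(hits: Sequence[SearchHit]) -> SearchHit:
    """The most significant hit of one query in one sequence database."""
    if not hits:
        raise ValueError("best_hit requires a non-empty hit list")
    return min(hits, key=lambda h: (h.e_value, -h.bit_score, h.target_id))


def tile_nonoverlapping(hits: Sequence[SearchHit], max_overlap: int = 0
                        ) -> list[SearchHit]:
    """Greedy maximal non-overlapping hit selection along the query.

    The result is sorted by q_start and is maximal: no rejected hit could
    be added without exceeding ``max_overlap`` shared residues with an
    accepted one.
    """
    order = sorted(hits, key=lambda h: (h.e_value, -h.bit_score, h.q_start, h.target_id))
    accepted: list[SearchHit] = []
    for hit in order:
        ok = True
        for kept in accepted:
            overlap = min(hit.q_end, kept.q_end) - max(hit.q_start, kept.q_start)
            if overlap > max_overlap:
                ok = False
                break
        if ok:
            accepted.append(hit)
    return sorted(accepted, key=lambda h: h.q_start)


def _to_record(hit: SearchHit, meta: AnnotationMeta) -> AnnotationRecord:
    return AnnotationRecord(
        query_id=hit.query_id,
        db_name=hit.db_name,
        db_role=hit.db_role,
        target_id=hit.target_id,
        q_start=hit.q_start + 1,
        q_end=hit.q_end,
        e_value=hit.e_value,
        pct_identity=hit.pct_identity,
        bit_score=hit.bit_score,
        description=meta.description,
        go_terms=meta.go_terms,
        orthogroup=meta.orthogroup,
        domain_name=meta.domain_name,
    )


def assemble_annotations(hits: Sequence[SearchHit], databases: Sequence,
                         query_order: Sequence[str],
                         cluster_set: Optional[ClusterSet] = None,
                         propagate: bool = True,
                         max_overlap: int = 0,
                         logger=None) -> list[AnnotationRecord]:
    """Apply the retention policies and transfer target metadata to queries.

    ``databases`` supplies roles and metadata (any object with ``name``
    and ``meta_for``); ``query_order`` fixes the deterministic output
    order (input order, then database name, then q_start).  With a cluster
    set and ``propagate``, each representative's records are copied to its
    members with the ``inherited`` column set.
    """
    db_by_name = {db.name: db for db in databases}
    grouped: dict[tuple[str, str], list[SearchHit]] = {}
    for hit in hits:
        grouped.setdefault((hit.query_id, hit.db_name), []).append(hit)

    retained: list[SearchHit] = []
    for (qid, db_name), group in grouped.items():
        role = group[0].db_role
        if role == "sequence":
            retained.append(best_hit(group))
        else:
            retained.extend(tile_nonoverlapping(group, max_overlap=max_overlap))

    records: list[AnnotationRecord] = []
    for hit in retained:
        db = db_by_name.get(hit.db_name)
        if db is None:
            if logger is not None:
                logger.warning("hit references unknown database %r", hit.db_name)
            meta = AnnotationMeta.empty(hit.target_id)
        else:
            meta = db.meta_for(hit.target_id)
        records.append(_to_record(hit, meta))

    if cluster_set is not None and propagate:
        by_rep: dict[str, list[AnnotationRecord]] = {}
        for rec in records:
            by_rep.setdefault(rec.query_id, []).append(rec)
        for rep, members in cluster_set.clusters.items():
            rep_records = by_rep.get(rep, [])
            for member in members:
                if member == rep:
                    continue
                for rec in rep_records:
                    records.append(dataclasses.replace(
                        rec, query_id=member, inherited=rep))

    qpos = {qid: i for i, qid in enumerate(query_order)}
    records.sort(key=lambda r: (qpos.get(r.query_id, len(qpos)), r.query_id,
                                r.db_name, r.q_start, r.target_id))
    return records


def summarize(records: Sequence[AnnotationRecord], all_query_ids: Sequence[str],
              identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
              logger=None) -> AnnotationSummary:
    """Annotation-rate summary.

    A query is annotated iff it owns >= 1 record with identity at or above
    the threshold (default 50%) in any database.  ``per_db_counts`` counts
    the distinct queries holding at least one record per database
    (regardless of identity).
    """
    if not 0 <= identity_threshold <= 1:
        raise ValueError("identity_threshold must be in [0, 1]")
    n_queries = len(all_query_ids)
    if n_queries == 0 and logger is not None:
        logger.warning("summarize called with an empty query set")
    cutoff = 100.0 * identity_threshold
    annotated: set[str] = set()
    per_db: dict[str, set[str]] = {}
    for rec in records:
        per_db.setdefault(rec.db_name, set()).add(rec.query_id)
        if rec.pct_identity >= cutoff:
            annotated.add(rec.query_id)
    annotated &= set(all_query_ids)
    return AnnotationSummary(
        n_queries=n_queries,
        n_annotated=len(annotated),
        annotation_rate=len(annotated) / n_queries if n_queries else 0.0,
        per_db_counts={db: len(q) for db, q in per_db.items()},
        identity_threshold=identity_threshold,
    )


# ---------------------------------------------------------------------------
# output files

def write_annotation_tsv(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    """Write the merged annotation table (13 tab-separated columns + header)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.query_id}\t{r.db_name}\t{r.target_id}\t{r.q_start}\t{r.q_end}\t"
                f"{r.e_value:.3g}\t{r.pct_identity:.2f}\t{r.bit_score:.2f}\t"
                f"{r.description}\t{'|'.join(r.go_terms)}\t{r.orthogroup}\t"
                f"{r.domain_name}\t{r.inherited}\n"
            )


def read_annotation_tsv(path: str | Path) -> list[AnnotationRecord]:
    """Companion reader for :func:`write_annotation_tsv`."""
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TSV_COLUMNS:
            raise ValueError(f"{path}: unexpected annotation header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) != len(TSV_COLUMNS):
                raise ValueError(f"{path}: row with {len(f)} fields")
            records.append(AnnotationRecord(
                query_id=f[0], db_name=f[1], db_role="",
                target_id=f[2], q_start=int(f[3]), q_end=int(f[4]),
                e_value=float(f[5]), pct_identity=float(f[6]),
                bit_score=float(f[7]), description=f[8],
                go_terms=tuple(t for t in f[9].split("|") if t),
                orthogroup=f[10], domain_name=f[11], inherited=f[12],
            ))
    return records


def write_summary_json(summary: AnnotationSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")


def write_unannotated(records: Sequence[AnnotationRecord],
                      all_query_ids: Sequence[str], path: str | Path) -> None:
    """Sidecar listing queries with zero annotation records."""
    with_records = {r.query_id for r in records}
    with open(path, "w") as fh:
        for qid in all_query_ids:
            if qid not in with_records:
                fh.write(qid + "\n")
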
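"""Linear-time greedy redundancy clustering.

De novo transcriptomes are heavily redundant (many isoforms per locus), so
queries are optionally collapsed before annotation: sequences are grouped
by shared k-mers against the established cluster representatives,
candidate members are verified against a centre by gapped local
alignment, and only verified members join a cluster.  Each cluster's
representative is a longest member (ties broken by lexicographically
smallest id).  No all-vs-all comparison is performed: at most
``kmers_per_seq`` candidate centres are alignment-verified per sequence,
so the work is linear in the input size.

:func:`select_kmers` provides the seeded min-hash k-mer sketch (the m
k-mers with smallest hash); it is the subsampling primitive for scaling
the candidate-grouping index beyond desk scale.

Identity is matching residues / alignment columns (gap columns included);
coverage is bidirectional — the local alignment must span at least
``min_cov`` of both the member and the representative.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

from .errors import ConsistencyError
from .search import SearchParams, align_local
from .seqio import SequenceRecord


@dataclasses.dataclass(frozen=True)
class ClusterParams:
    """Clustering thresholds and k-mer sketch parameters."""

    min_seq_id: float = 0.9
    min_cov: float = 0.8
    kmer_len: int = 10
    kmers_per_seq: int = 20
    seed: int = 42

    def __post_init__(self):
        if not (0 < self.min_seq_id <= 1 and 0 < self.min_cov <= 1):
            raise ValueError("min_seq_id and min_cov must be in (0, 1]")
        if self.kmer_len < 4:
            raise ValueError("kmer_len must be >= 4")


@dataclasses.dataclass
class ClusterSet:
    """A partition of input ids into representative-led clusters.

    ``n_alignments`` counts the verification alignments performed, so the
    linear-work bound can be asserted rather than assumed.
    """

    clusters: dict[str, list[str]]
    params: ClusterParams
    n_alignments: int = 0

    @property
    def member_to_rep(self) -> dict[str, str]:
        return {m: rep for rep, members in self.clusters.items() for m in members}

    def all_ids(self) -> set[str]:
        return {m for members in self.clusters.values() for m in members}


def _mix64(x: int) -> int:
    """splitmix64 finalizer: a cheap, well-mixed 64-bit hash."""
    x &= 0xFFFFFFFFFFFFFFFF
    x ^= x >> 30
    x = (x * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    x ^= x >> 27
    x = (x * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    x ^= x >> 31
    return x


def _kmer_hash(kmer: str, seed: int) -> int:
    h = _mix64(seed ^ 0x9E3779B97F4A7C15)
    for ch in kmer.encode():
        h = _mix64(h ^ ch)
    return h


def select_kmers(residues: str, k: int, m: int, seed: int) -> set[tuple[str, int]]:
    """The m distinct k-mers of a sequence with smallest seeded hash.

    Returns (kmer, first_position) pairs; all k-mers when fewer than m
    distinct ones exist, the empty set when the sequence is shorter than k.
    """
    if len(residues) < k:
        return set()
    first_pos: dict[str, int] = {}
    for pos in range(len(residues) - k + 1):
        kmer = residues[pos:pos + k]
        if kmer not in first_pos:
            first_pos[kmer] = pos
    ranked = sorted(first_pos, key=lambda km: (_kmer_hash(km, seed), km))
    return {(km, first_pos[km]) for km in ranked[:m]}


def _verify(member: str, rep: str, params: ClusterParams,
            align_params: SearchParams) -> bool:
    """Does member align to rep at >= min_seq_id identity and bidirectional coverage?"""
    res = align_local(member, rep, align_params)
    if res is None:
        return False
    _, (qs, qe), (ts, te), pct_identity, _ = res
    cov_member = (qe - qs) / len(member)
    cov_rep = (te - ts) / len(rep)
    return (pct_identity / 100.0 >= params.min_seq_id
            and cov_member >= params.min_cov
            and cov_rep >= params.min_cov)


def cluster(queries: Sequence[SequenceRecord],
            params: ClusterParams = ClusterParams()) -> ClusterSet:
    """Greedy single-pass clustering.

    Sequences are processed longest-first (ties by id); each sequence is
    verified against the established representatives it shares a k-mer
    with, in order of shared-distinct-k-mer count (at most
    ``kmers_per_seq`` candidates are tried), and joins the first one that
    passes verification.  Otherwise it founds a new cluster.  This
    guarantees the representative is a longest member of its cluster and
    caps the number of verification alignments at n * kmers_per_seq.
    """
    ids = [q.id for q in queries]
    if len(set(ids)) != len(ids):
        raise ConsistencyError("query ids must be unique for clustering")
    align_params = SearchParams()
    clusters: dict[str, list[str]] = {}
    rep_residues: dict[str, str] = {}
    kmer_to_reps: dict[str, list[str]] = {}
    n_alignments = 0
    max_candidates = params.kmers_per_seq

    order = sorted(queries, key=lambda r: (-len(r.residues), r.id))
    k = params.kmer_len
    for rec in order:
        own_kmers = {rec.residues[p:p + k]
                     for p in range(len(rec.residues) - k + 1)}
        shared: dict[str, int] = {}
        for kmer in own_kmers:
            for rep_id in kmer_to_reps.get(kmer, ()):
                shared[rep_id] = shared.get(rep_id, 0) + 1
        candidates = sorted(shared, key=lambda r: (-shared[r], r))[:max_candidates]
        assigned = False
        for rep_id in candidates:
            n_alignments += 1
            if _verify(rec.residues, rep_residues[rep_id], params, align_params):
                clusters[rep_id].append(rec.id)
                assigned = True
                break
        if not assigned:
            clusters[rec.id] = [rec.id]
            rep_residues[rec.id] = rec.residues
            for kmer in own_kmers:
                kmer_to_reps.setdefault(kmer, []).append(rec.id)
    return ClusterSet(clusters=clusters, params=params, n_alignments=n_alignments)


def passthrough_clusters(queries: Sequence[SequenceRecord],
                         params: ClusterParams = ClusterParams()) -> ClusterSet:
    """Every sequence its own representative (clustering disabled)."""
    return ClusterSet(clusters={q.id: [q.id] for q in queries}, params=params)


def representatives(cs: ClusterSet, queries: Sequence[SequenceRecord]
                    ) -> list[SequenceRecord]:
    """One record per cluster, in the input order of the representatives."""
    if cs.all_ids() != {q.id for q in queries}:
        raise ConsistencyError("cluster set does not match the query set")
    reps = set(cs.clusters)
    return [q for q in queries if q.id in reps]


def write_cluster_tsv(cs: ClusterSet, path: str | Path) -> None:
    """Two-column cluster table: representative_id <TAB> member_id, one
    row per member (the shape emitted by common clustering tools)."""
    with open(path, "w") as fh:
        for rep in sorted(cs.clusters):
            for member in sorted(cs.clusters[rep]):
                fh.write(f"{rep}\t{member}\n")


def read_cluster_tsv(path: str | Path) -> dict[str, list[str]]:
    clusters: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            rep, member = line.rstrip("\n").split("\t")
            clusters.setdefault(rep, []).append(member)
    return clusters
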
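"""Synthetic reference databases and query sets with planted ground truth.

Every pipeline stage is testable without downloading any real database:
these generators emit exactly the formats the loaders consume (protein
FASTA, MSA directories, metadata TSVs) plus a JSON truth table recording,
for each query, which target it was mutated from and which profile
consensus segments were planted at which intervals.

Random proteins are drawn from the BLOSUM62 background composition (the
same null model the search engine calibrates against), and point mutations
are drawn from the BLOSUM62-conditional substitution probabilities — so a
copy "mutated to 70% identity" looks like a plausible 70%-identity homolog
rather than a uniformly scrambled string.  All generators are
deterministic for a fixed seed.

The default desk-scale fixture is 50 sequence targets of length 150-400,
8 profiles (MSAs of 10 rows at 90% within-MSA identity, length 60-120),
and 40 queries with 10% decoys.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .refdb import AnnotationMeta, write_metadata
from .scoring import AA, background_frequencies, conditional_substitution
from .seqio import SequenceRecord, write_fasta

# Default study conditions for the desk-scale fixture.
DEFAULT_N_TARGETS = 50
DEFAULT_TARGET_LEN_RANGE = (150, 400)
DEFAULT_N_PROFILES = 8
DEFAULT_MSA_ROWS = 10
DEFAULT_PROFILE_LEN_RANGE = (60, 120)
DEFAULT_MSA_IDENTITY = 0.9
DEFAULT_N_QUERIES = 40
DEFAULT_HOMOLOG_IDENTITY = 0.7
DEFAULT_DECOY_FRACTION = 0.1


def random_protein(rng: np.random.Generator, length: int) -> str:
    bg = background_frequencies()
    return "".join(rng.choice(list(AA), size=length, p=bg))


def mutate(residues: str, identity: float, rng: np.random.Generator) -> str:
    """Point-substitute a sequence down to the requested identity.

    The number of substituted positions is round((1-identity)*len); the
    replacement residue is drawn from the BLOSUM62-conditional
    distribution given the original residue, excluding the original, so
    realized alignment identity tracks the request closely.
    """
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    n_mut = round((1.0 - identity) * len(residues))
    if n_mut == 0:
        return residues
    cond = conditional_substitution()
    aa_index = {a: i for i, a in enumerate(AA)}
    positions = rng.choice(len(residues), size=n_mut, replace=False)
    out = list(residues)
    for pos in positions:
        b = aa_index[out[pos]]
        p = cond[b].copy()
        p[b] = 0.0
        p /= p.sum()
        out[pos] = AA[int(rng.choice(20, p=p))]
    return "".join(out)


# ---------------------------------------------------------------------------
# planted truth

@dataclasses.dataclass(frozen=True)
class PlantedDomain:
    profile_id: str
    q_start: int  # 0-based half-open on the query
    q_end: int


@dataclasses.dataclass(frozen=True)
class QueryTruth:
    query_id: str
    source_target_id: Optional[str]
    domains: tuple[PlantedDomain, ...]
    mutation_identity: float
    is_decoy: bool


@dataclasses.dataclass
class PlantedTruth:
    """Ground truth for a planted query fixture (JSON-serializable)."""

    queries: dict[str, QueryTruth]

    def validate(self, query_lengths: dict[str, int]) -> None:
        for qid, truth in self.queries.items():
            if not 0 < truth.mutation_identity <= 1:
                raise ValueError(f"{qid}: identity outside (0, 1]")
            for dom in truth.domains:
                if not (0 <= dom.q_start < dom.q_end <= query_lengths[qid]):
                    raise ValueError(f"{qid}: planted interval outside query")

    def to_json(self, path: str | Path) -> None:
        payload = {
            qid: {
                "source_target_id": t.source_target_id,
                "domains": [[d.profile_id, d.q_start, d.q_end] for d in t.domains],
                "mutation_identity": t.mutation_identity,
                "is_decoy": t.is_decoy,
            }
            for qid, t in self.queries.items()
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        queries = {}
        for qid, d in payload.items():
            queries[qid] = QueryTruth(
                query_id=qid,
                source_target_id=d["source_target_id"],
                domains=tuple(PlantedDomain(*dom) for dom in d["domains"]),
                mutation_identity=d["mutation_identity"],
                is_decoy=d["is_decoy"],
            )
        return cls(queries=queries)


# ---------------------------------------------------------------------------
# database fixtures

@dataclasses.dataclass
class SequenceDbFixture:
    fasta_path: Path
    metadata_path: Path
    records: list[SequenceRecord]


@dataclasses.dataclass
class ProfileDbFixture:
    msa_dir: Path
    metadata_path: Path
    masters: dict[str, str]  # profile id -> ungapped master sequence


def make_sequence_db_fixture(out_dir: str | Path, n_targets: int = DEFAULT_N_TARGETS,
                             len_range: tuple[int, int] = DEFAULT_TARGET_LEN_RANGE,
                             seed: int = 0) -> SequenceDbFixture:
    """Random protein targets plus synthetic annotation metadata."""
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, metas = [], []
    for i in range(n_targets):
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        tid = f"T{i:04d}"
        records.append(SequenceRecord(
            id=tid, description=f"synthetic target protein {i}",
            residues=random_protein(rng, length), alphabet="protein"))
        n_go = int(rng.integers(0, 4))
        go_terms = tuple(f"GO:{int(rng.integers(0, 10**7)):07d}" for _ in range(n_go))
        metas.append(AnnotationMeta(
            target_id=tid,
            description=f"hypothetical protein {tid}",
            go_terms=go_terms,
            orthogroup=f"OG{int(rng.integers(0, 10**4)):04d}",
        ))
    fasta_path = out_dir / "targets.fasta"
    metadata_path = out_dir / "targets.tsv"
    write_fasta(records, fasta_path)
    write_metadata(metas, metadata_path, role="sequence")
    return SequenceDbFixture(fasta_path, metadata_path, records)


def make_profile_db_fixture(out_dir: str | Path, n_profiles: int = DEFAULT_N_PROFILES,
                            n_seqs_per_msa: int = DEFAULT_MSA_ROWS,
                            len_range: tuple[int, int] = DEFAULT_PROFILE_LEN_RANGE,
                            within_msa_identity: float = DEFAULT_MSA_IDENTITY,
                            seed: int = 0) -> ProfileDbFixture:
    """A directory of gapless MSAs: one master plus mutated copies each."""
    if not 0.5 < within_msa_identity <= 1:
        raise ValueError("within_msa_identity must be in (0.5, 1]")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    msa_dir = out_dir / "msas"
    msa_dir.mkdir(parents=True, exist_ok=True)
    masters: dict[str, str] = {}
    metas = []
    for i in range(n_profiles):
        pid = f"PF{i:03d}"
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        master = random_protein(rng, length)
        masters[pid] = master
        rows = [SequenceRecord(f"{pid}_m0", "", master, "protein")]
        for j in range(1, n_seqs_per_msa):
            rows.append(SequenceRecord(
                f"{pid}_m{j}", "", mutate(master, within_msa_identity, rng), "protein"))
        write_fasta(rows, msa_dir / f"{pid}.fasta")
        n_go = int(rng.integers(0, 3))
        metas.append(AnnotationMeta(
            target_id=pid,
            description=f"synthetic domain family {pid}",
            go_terms=tuple(f"GO:{int(rng.integers(0, 10**7)):07d}" for _ in range(n_go)),
            domain_name=f"DOM_{pid}",
        ))
    metadata_path = out_dir / "profiles.tsv"
    write_metadata(metas, metadata_path, role="profile")
    return ProfileDbFixture(msa_dir, metadata_path, masters)


# ---------------------------------------------------------------------------
# query fixtures

def make_query_fixture(seq_db: SequenceDbFixture, profile_db: ProfileDbFixture,
                       out_dir: str | Path, n_queries: int = DEFAULT_N_QUERIES,
                       homolog_identity: float = DEFAULT_HOMOLOG_IDENTITY,
                       domain_layout: Optional[Sequence[Sequence[str]]] = None,
                       decoy_fraction: float = DEFAULT_DECOY_FRACTION,
                       domain_identity: float = 0.8,
                       seed: int = 0) -> tuple[Path, PlantedTruth]:
    """Queries with planted homologs and domain architectures.

    Each non-decoy query is a point-mutated copy of a random target (at
    ``homolog_identity``); profile consensus copies (at
    ``domain_identity``) are appended behind random linkers according to
    ``domain_layout`` (one list of profile ids per query, cycled; default:
    alternate zero/one/two planted domains).  Decoys are pure random
    sequences with no planted signal.  Returns the query FASTA path and
    the truth table (also written as ``truth.json`` next to the FASTA).
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profile_ids = sorted(profile_db.masters)
    if domain_layout is None:
        layouts = []
        for i in range(max(n_queries, 1)):
            k = i % 3
            if k == 0:
                layouts.append([])
            elif k == 1:
                layouts.append([profile_ids[i % len(profile_ids)]])
            else:
                layouts.append([profile_ids[i % len(profile_ids)],
                                profile_ids[(i + 3) % len(profile_ids)]])
        domain_layout = layouts
    n_decoys = round(decoy_fraction * n_queries)
    records: list[SequenceRecord] = []
    truths: dict[str, QueryTruth] = {}
    for i in range(n_queries):
        qid = f"Q{i:04d}"
        if i < n_decoys:
            length = int(rng.integers(150, 401))
            records.append(SequenceRecord(
                qid, "decoy", random_protein(rng, length), "protein"))
            truths[qid] = QueryTruth(qid, None, (), 1.0, True)
            continue
        target = seq_db.records[int(rng.integers(len(seq_db.records)))]
        body = mutate(target.residues, homolog_identity, rng)
        layout = domain_layout[(i - n_decoys) % len(domain_layout)]
        parts = [body]
        pos = len(body)
        domains = []
        for pid in layout:
            linker = random_protein(rng, int(rng.integers(10, 31)))
            dom = mutate(profile_db.masters[pid], domain_identity, rng)
            parts.extend((linker, dom))
            pos += len(linker)
            domains.append(PlantedDomain(pid, pos, pos + len(dom)))
            pos += len(dom)
        residues = "".join(parts)
        records.append(SequenceRecord(qid, f"from={target.id}", residues, "protein"))
        truths[qid] = QueryTruth(qid, target.id, tuple(domains),
                                 homolog_identity, False)
    fasta_path = out_dir / "queries.fasta"
    write_fasta(records, fasta_path)
    truth = PlantedTruth(queries=truths)
    truth.validate({r.id: len(r.residues) for r in records})
    truth.to_json(out_dir / "truth.json")
    return fasta_path, truth


def make_redundant_fixture(base_queries: Sequence[SequenceRecord],
                           copies_per_query: int, copy_identity: float,
                           seed: int = 0
                           ) -> tuple[list[SequenceRecord], dict[str, list[str]]]:
    """Replicate each base query with mutated copies; returns truth groups.

    Emulates isoform redundancy: the output contains each base plus
    ``copies_per_query - 1`` mutated copies at ``copy_identity``; groups
    map each base id to all ids of its group (base included).
    """
    if not 0 < copy_identity <= 1:
        raise ValueError("copy_identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    groups: dict[str, list[str]] = {}
    for base in base_queries:
        group = [base.id]
        records.append(base)
        for c in range(1, copies_per_query):
            cid = f"{base.id}_iso{c}"
            records.append(SequenceRecord(
                cid, f"copy_of={base.id}",
                mutate(base.residues, copy_identity, rng), "protein"))
            group.append(cid)
        groups[base.id] = group
    return records, groups


def make_default_fixture(out_dir: str | Path, seed: int = 0):
    """The default desk-scale end-to-end fixture (all three pieces)."""
    out_dir = Path(out_dir)
    seq_db = make_sequence_db_fixture(out_dir / "seqdb", seed=seed)
    profile_db = make_profile_db_fixture(out_dir / "profdb", seed=seed + 1)
    query_path, truth = make_query_fixture(
        seq_db, profile_db, out_dir / "queries", seed=seed + 2)
    return seq_db, profile_db, query_path, truth
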
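"""Annotation target databases.

Two kinds of target database are supported behind one uniform contract:

* **sequence databases** — a protein FASTA plus a metadata TSV
  (``target_id  description  go_terms  orthogroup``), indexed by k-mers
  for the search prefilter;
* **profile databases** — a directory of multiple sequence alignments
  (aligned FASTA or Stockholm), one per profile, plus a metadata TSV
  (``target_id  description  go_terms  domain_name``).  Each MSA is
  compiled into a position-specific scoring matrix (PSSM) over its match
  columns (columns with <= 50% gaps), with substitution-matrix pseudocount
  mixing, and calibrated against shuffled background sequences so profile
  hits carry E-values.

PSSM construction: for a match column with n observed residues and
frequencies f, the mixed frequency is f' = (n*f + alpha*g) / (n + alpha)
where g is the BLOSUM62-conditional background implied by f; the score of
residue a is 2*log2(f'_a / p_a) (half-bit log-odds).  The consensus is the
argmax-score residue per column.

Calibration fits a Gumbel (EVD) to the local-alignment scores of random
background-composition sequences by the method of moments:
lambda = pi / (sigma * sqrt(6)), mu = mean - gamma/lambda, and
K = exp(lambda*mu) / (L_profile * shuffle_len).

Databases can be compiled to an on-disk directory (a JSON manifest plus
text payloads) and re-loaded without re-reading the raw inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import re
import shutil
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import seqio
from .errors import CalibrationError, FormatError, UserInputError
from .scoring import (
    AA,
    EULER_GAMMA,
    background_frequencies,
    conditional_substitution,
)
from .seqio import SequenceRecord

DB_FORMAT_VERSION = 1
GO_PATTERN = re.compile(r"^GO:\d{7}$")
GAP_CHARS = {"-", "."}
MATCH_COLUMN_MAX_GAP = 0.5


@dataclasses.dataclass(frozen=True)
class AnnotationMeta:
    """Annotation payload attached to one database target."""

    target_id: str
    description: str = ""
    go_terms: tuple[str, ...] = ()
    orthogroup: str = ""
    domain_name: str = ""

    @classmethod
    def empty(cls, target_id: str) -> "AnnotationMeta":
        return cls(target_id=target_id)


@dataclasses.dataclass
class Profile:
    """A PSSM profile with calibrated Gumbel score statistics.

    ``pssm`` is a (length x 20) array of half-bit log-odds scores over the
    match columns; ``gumbel_lambda``/``gumbel_K`` are NaN until
    :func:`calibrate_profile` has run.
    """

    id: str
    length: int
    pssm: np.ndarray
    consensus: str
    gumbel_lambda: float = math.nan
    gumbel_K: float = math.nan

    @property
    def calibrated(self) -> bool:
        return math.isfinite(self.gumbel_lambda) and math.isfinite(self.gumbel_K)

    def score_rows(self) -> list[list[float]]:
        """Per-column score rows extended with a neutral X column (index 20)."""
        return [list(map(float, row)) + [0.0] for row in self.pssm]


@dataclasses.dataclass
class SequenceDatabase:
    name: str
    entries: list[SequenceRecord]
    metadata: dict[str, AnnotationMeta]
    kmer_index: dict[str, list[tuple[int, int]]]
    kmer_len: int

    @property
    def size_letters(self) -> int:
        return sum(len(e.residues) for e in self.entries)

    def meta_for(self, target_id: str) -> AnnotationMeta:
        return self.metadata.get(target_id, AnnotationMeta.empty(target_id))


@dataclasses.dataclass
class ProfileDatabase:
    name: str
    profiles: list[Profile]
    metadata: dict[str, AnnotationMeta]

    def meta_for(self, target_id: str) -> AnnotationMeta:
        return self.metadata.get(target_id, AnnotationMeta.empty(target_id))


# ---------------------------------------------------------------------------
# metadata

def read_metadata(path: str | Path) -> dict[str, AnnotationMeta]:
    """Parse a metadata TSV keyed by target_id.

    Requires a header starting with ``target_id``; recognised columns are
    description, go_terms (pipe-separated GO:NNNNNNN ids), orthogroup and
    domain_name.  Malformed GO identifiers raise :class:`FormatError`.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise FormatError(f"{path}: empty metadata file")
        header = header_line.split("\t")
        if header[0] != "target_id":
            raise FormatError(f"{path}: metadata header must start with 'target_id'")
        col = {name: i for i, name in enumerate(header)}
        out: dict[str, AnnotationMeta] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")

            def get(name: str) -> str:
                i = col.get(name)
                return fields[i] if i is not None else ""

            go_raw = get("go_terms")
            go_terms = tuple(t for t in go_raw.split("|") if t) if go_raw else ()
            for term in go_terms:
                if not GO_PATTERN.match(term):
                    raise FormatError(
                        f"{path}:{lineno}: malformed GO identifier {term!r}")
            out[fields[0]] = AnnotationMeta(
                target_id=fields[0],
                description=get("description"),
                go_terms=go_terms,
                orthogroup=get("orthogroup"),
                domain_name=get("domain_name"),
            )
    return out


def write_metadata(metas: Sequence[AnnotationMeta], path: str | Path,
                   role: str = "sequence") -> None:
    label = "orthogroup" if role == "sequence" else "domain_name"
    with open(path, "w") as fh:
        fh.write(f"target_id\tdescription\tgo_terms\t{label}\n")
        for m in metas:
            extra = m.orthogroup if role == "sequence" else m.domain_name
            fh.write(f"{m.target_id}\t{m.description}\t{'|'.join(m.go_terms)}\t{extra}\n")


# ---------------------------------------------------------------------------
# sequence databases

def build_kmer_index(entries: Sequence[SequenceRecord], kmer_len: int
                     ) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for ti, rec in enumerate(entries):
        residues = rec.residues
        for pos in range(len(residues) - kmer_len + 1):
            index.setdefault(residues[pos:pos + kmer_len], []).append((ti, pos))
    for postings in index.values():
        postings.sort()
    return index


def build_sequence_db(fasta_path: str | Path, metadata_path: str | Path,
                      name: str, kmer_len: int = 5,
                      logger=None) -> SequenceDatabase:
    """Build a k-mer-indexed sequence database with joined metadata.

    Metadata rows without a FASTA entry and FASTA entries without metadata
    are both tolerated with a warning; missing metadata becomes an empty
    annotation so the join is total.
    """
    entries = seqio.read_fasta(fasta_path, "protein")
    metadata = read_metadata(metadata_path)
    entry_ids = {e.id for e in entries}
    for mid in metadata:
        if mid not in entry_ids and logger is not None:
            logger.warning("metadata id %r has no FASTA entry in db %s", mid, name)
    for eid in entry_ids:
        if eid not in metadata:
            if logger is not None:
                logger.warning("db %s: entry %r has no metadata row; using empty", name, eid)
            metadata[eid] = AnnotationMeta.empty(eid)
    return SequenceDatabase(
        name=name,
        entries=entries,
        metadata=metadata,
        kmer_index=build_kmer_index(entries, kmer_len),
        kmer_len=kmer_len,
    )


# ---------------------------------------------------------------------------
# profiles

def build_profile(msa_records: Sequence[SequenceRecord], id: str,
                  pseudocount_alpha: float = 1.0,
                  background: Optional[np.ndarray] = None) -> Profile:
    """Compile an MSA into a PSSM profile (uncalibrated)."""
    if len(msa_records) < 2:
        raise FormatError(f"profile {id!r}: an MSA needs at least 2 rows")
    width = len(msa_records[0].residues)
    for rec in msa_records:
        if len(rec.residues) != width:
            raise FormatError(
                f"profile {id!r}: ragged alignment (row {rec.id!r} has length "
                f"{len(rec.residues)}, expected {width})")
    if background is None:
        background = background_frequencies()
    cond = conditional_substitution()
    aa_index = {a: i for i, a in enumerate(AA)}
    columns = []
    for c in range(width):
        col = [rec.residues[c] for rec in msa_records]
        n_gap = sum(ch in GAP_CHARS for ch in col)
        if n_gap / len(col) > MATCH_COLUMN_MAX_GAP:
            continue
        counts = np.zeros(20)
        for ch in col:
            k = aa_index.get(ch)
            if k is not None:
                counts[k] += 1
        columns.append(counts)
    if not columns:
        raise FormatError(f"profile {id!r}: no match columns (alignment too gappy)")
    pssm = np.zeros((len(columns), 20))
    consensus_chars = []
    alpha = pseudocount_alpha
    tiny = 1e-12
    for i, counts in enumerate(columns):
        n = counts.sum()
        f = counts / n if n else np.full(20, 1 / 20)
        g = f @ cond  # conditional background implied by the observed column
        f_mixed = (n * f + alpha * g) / (n + alpha) if (n + alpha) else f
        pssm[i] = 2.0 * np.log2(np.maximum(f_mixed, tiny) / background)
        consensus_chars.append(AA[int(np.argmax(pssm[i]))])
    return Profile(
        id=id,
        length=len(columns),
        pssm=pssm,
        consensus="".join(consensus_chars),
    )


def fit_gumbel(scores: Sequence[float]) -> tuple[float, float]:
    """Method-of-moments Gumbel fit: returns (lambda, mu).

    lambda = pi / (sigma * sqrt(6)); mu = mean - gamma / lambda.
    """
    arr = np.asarray(scores, dtype=float)
    sigma = float(arr.std(ddof=1))
    if sigma <= 0 or not math.isfinite(sigma):
        raise CalibrationError("null scores have zero variance")
    lam = math.pi / (sigma * math.sqrt(6.0))
    mu = float(arr.mean()) - EULER_GAMMA / lam
    return lam, mu


@dataclasses.dataclass(frozen=True)
class CalibrationParams:
    n_shuffles: int = 200
    shuffle_len: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_shuffles < 100:
            raise ValueError("calibration needs n_shuffles >= 100")


def calibrate_profile(profile: Profile, n_shuffles: int = 200,
                      shuffle_len: int = 100, seed: int = 0,
                      gap_open: int = 11, gap_extend: int = 1) -> Profile:
    """Fit the profile's Gumbel parameters against random null sequences.

    Null sequences are drawn from the background amino-acid composition;
    each is locally aligned to the PSSM and the score distribution is fit
    by moments.  K is anchored so that E = K * L_profile * m * exp(-lambda*S)
    at the calibration search-space size.  Deterministic for a fixed seed.
    """
    from .search import _dp_score_only  # local import avoids a cycle

    if n_shuffles < 100:
        raise ValueError("calibration needs n_shuffles >= 100")
    rng = np.random.default_rng(seed)
    bg = background_frequencies()
    rows = profile.score_rows()
    scores = []
    aa_codes = np.arange(20)
    for _ in range(n_shuffles):
        seq = rng.choice(aa_codes, size=shuffle_len, p=bg)
        scores.append(_dp_score_only(seq.tolist(), rows, gap_open, gap_extend))
    lam, mu = fit_gumbel(scores)
    K = math.exp(lam * mu) / (profile.length * shuffle_len)
    profile.gumbel_lambda = lam
    profile.gumbel_K = K
    return profile


_STOCKHOLM_AC = re.compile(r"^#=GF\s+AC\s+(\S+)")


def read_msa(path: str | Path) -> tuple[list[SequenceRecord], Optional[str]]:
    """Read one MSA file (aligned FASTA or Stockholm).

    Returns (rows, accession) where accession is the Stockholm ``#=GF AC``
    field when present (version suffixes like ``.18`` stripped), else None.
    Gap characters are preserved in the row residues.
    """
    path = Path(path)
    text = path.read_text()
    rows: list[SequenceRecord] = []
    accession = None
    if text.lstrip().startswith("# STOCKHOLM"):
        seqs: dict[str, list[str]] = {}
        order: list[str] = []
        for line in text.splitlines():
            m = _STOCKHOLM_AC.match(line)
            if m:
                accession = m.group(1).split(".")[0]
                continue
            if not line or line.startswith(("#", "//")):
                continue
            try:
                name, chunk = line.split(None, 1)
            except ValueError:
                raise FormatError(f"{path}: malformed Stockholm line {line!r}")
            if name not in seqs:
                seqs[name] = []
                order.append(name)
            seqs[name].append(chunk.strip())
        for name in order:
            rows.append(SequenceRecord(
                id=name.split("/")[0], description="",
                residues="".join(seqs[name]).upper().replace(".", "-"),
                alphabet="protein"))
    else:
        from Bio import SeqIO
        with open(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                rows.append(SequenceRecord(
                    id=rec.id, description="",
                    residues=str(rec.seq).upper().replace(".", "-"),
                    alphabet="protein"))
    if not rows:
        raise FormatError(f"{path}: no alignment rows found")
    return rows, accession


MSA_SUFFIXES = {".fasta", ".fa", ".afa", ".aln", ".sto", ".stk", ".stockholm"}


def load_profile_db(dir_path: str | Path, metadata_path: str | Path,
                    name: str, calib_params: CalibrationParams = CalibrationParams(),
                    pseudocount_alpha: float = 1.0,
                    logger=None) -> ProfileDatabase:
    """Build and calibrate every profile in a directory of MSA files.

    Profile ids default to file stems; a Stockholm ``#=GF AC`` accession
    overrides the stem.  Per-profile calibration seeds are derived from
    ``calib_params.seed`` so the database is deterministic as a whole.
    """
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise UserInputError(f"{dir_path}: not a directory of MSAs")
    files = sorted(p for p in dir_path.iterdir()
                   if p.suffix.lower() in MSA_SUFFIXES)
    if not files:
        raise UserInputError(f"{dir_path}: no MSA files found")
    metadata = read_metadata(metadata_path)
    profiles: list[Profile] = []
    for i, path in enumerate(files):
        try:
            rows, accession = read_msa(path)
            profile = build_profile(rows, accession or path.stem,
                                    pseudocount_alpha=pseudocount_alpha)
        except FormatError as exc:
            raise FormatError(f"{path.name}: {exc}") from exc
        calibrate_profile(profile,
                          n_shuffles=calib_params.n_shuffles,
                          shuffle_len=calib_params.shuffle_len,
                          seed=(calib_params.seed * 100003 + i) % (2**31))
        profiles.append(profile)
        if profile.id not in metadata:
            if logger is not None:
                logger.warning("profile db %s: no metadata for %r; using empty",
                               name, profile.id)
            metadata[profile.id] = AnnotationMeta.empty(profile.id)
    ids = [p.id for p in profiles]
    if len(set(ids)) != len(ids):
        raise FormatError(f"profile db {name}: duplicate profile ids")
    return ProfileDatabase(name=name, profiles=profiles, metadata=metadata)


# ---------------------------------------------------------------------------
# compiled on-disk databases

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def compile_sequence_db(fasta_path, metadata_path, name, out_dir,
                        kmer_len: int = 5, logger=None) -> Path:
    """Compile a sequence DB to a directory (FASTA + metadata + manifest)."""
    db = build_sequence_db(fasta_path, metadata_path, name, kmer_len, logger)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shutil.copyfile(fasta_path, out_dir / "sequences.fasta")
    shutil.copyfile(metadata_path, out_dir / "metadata.tsv")
    manifest = {
        "format_version": DB_FORMAT_VERSION,
        "name": name,
        "role": "sequence",
        "kmer_len": kmer_len,
        "n_entries": len(db.entries),
        "checksums": {
            "sequences.fasta": _sha256(out_dir / "sequences.fasta"),
            "metadata.tsv": _sha256(out_dir / "metadata.tsv"),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out_dir


def compile_profile_db(msa_dir, metadata_path, name, out_dir,
                       calib_params: CalibrationParams = CalibrationParams(),
                       logger=None) -> Path:
    """Compile a profile DB (profiles serialized to JSON + manifest)."""
    pdb = load_profile_db(msa_dir, metadata_path, name, calib_params, logger=logger)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = [
        {
            "id": p.id,
            "length": p.length,
            "consensus": p.consensus,
            "pssm": [[round(v, 6) for v in row] for row in p.pssm.tolist()],
            "gumbel_lambda": p.gumbel_lambda,
            "gumbel_K": p.gumbel_K,
        }
        for p in pdb.profiles
    ]
    (out_dir / "profiles.json").write_text(json.dumps(payload, sort_keys=True))
    shutil.copyfile(metadata_path, out_dir / "metadata.tsv")
    manifest = {
        "format_version": DB_FORMAT_VERSION,
        "name": name,
        "role": "profile",
        "n_profiles": len(pdb.profiles),
        "calibration": dataclasses.asdict(calib_params),
        "checksums": {
            "profiles.json": _sha256(out_dir / "profiles.json"),
            "metadata.tsv": _sha256(out_dir / "metadata.tsv"),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out_dir


def load_compiled_db(dir_path: str | Path, logger=None):
    """Load a compiled DB directory; returns SequenceDatabase or ProfileDatabase."""
    dir_path = Path(dir_path)
    manifest_path = dir_path / "manifest.json"
    if not manifest_path.exists():
        raise UserInputError(
            f"{dir_path}: not a compiled database (no manifest.json); "
            "build it with 'annopipe createdb'")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("role") == "sequence":
        return build_sequence_db(
            dir_path / "sequences.fasta", dir_path / "metadata.tsv",
            manifest["name"], manifest.get("kmer_len", 5), logger)
    if manifest.get("role") == "profile":
        metadata = read_metadata(dir_path / "metadata.tsv")
        profiles = []
        for d in json.loads((dir_path / "profiles.json").read_text()):
            profiles.append(Profile(
                id=d["id"], length=d["length"],
                pssm=np.asarray(d["pssm"], dtype=float),
                consensus=d["consensus"],
                gumbel_lambda=d["gumbel_lambda"],
                gumbel_K=d["gumbel_K"],
            ))
        for p in profiles:
            metadata.setdefault(p.id, AnnotationMeta.empty(p.id))
        return ProfileDatabase(manifest["name"], profiles, metadata)
    raise UserInputError(f"{dir_path}: unknown database role {manifest.get('role')!r}")
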
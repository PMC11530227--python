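"""Internal homology search engine.

Sequence databases are searched with a two-stage design: a diagonal k-mer
prefilter proposes candidate targets, and candidates are verified with a
full Smith-Waterman local alignment under BLOSUM62 with affine gap costs
(a gap of length k costs open + k*extend).  Profile databases are searched
by local alignment of the query against the profile's position-specific
scoring matrix (PSSM), without a prefilter (profile counts are small at
the scales this engine targets).

Statistical significance follows the Karlin-Altschul/Gumbel model:

* sequence hits:  bit = (lambda*S - ln K) / ln 2,  E = m * n * 2**(-bit),
  with the published gapped BLOSUM62-11/1 parameters and the pairwise
  search space m*n (query length x database letters);
* profile hits:   E = K * L_profile * m * exp(-lambda*S) with per-profile
  Gumbel parameters fitted by shuffling (see refdb.calibrate_profile).

Only hits below the configured E-value threshold (default 1e-5) are
returned.  Hit ordering is deterministic everywhere:
(query_id, db_name, E-value ascending, bit score descending, target id).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Literal, Optional, Sequence

from .errors import ConfigError
from .scoring import (
    GAPPED_BLOSUM62_K,
    GAPPED_BLOSUM62_LAMBDA,
    X_INDEX,
    blosum62_rows,
    encode,
)

LN2 = math.log(2.0)


@dataclasses.dataclass(frozen=True)
class SearchParams:
    """Engine parameters.

    ``min_diag_kmers`` is the number of shared k-mers required on a common
    diagonal band (width +-4) for a target to pass the prefilter.
    ``db_size_letters`` is filled per database at search time when 0.
    """

    kmer_len: int = 5
    min_diag_kmers: int = 2
    gap_open: int = 11
    gap_extend: int = 1
    substitution_matrix: str = "BLOSUM62"
    max_evalue: float = 1e-5
    db_size_letters: int = 0

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ConfigError("need gap_open >= gap_extend >= 1")
        if self.max_evalue <= 0:
            raise ConfigError("max_evalue must be > 0")


@dataclasses.dataclass(frozen=True)
class SearchHit:
    """A scored local match between a query and a sequence or profile target.

    Coordinates are 0-based half-open on both query and target; for profile
    hits the target coordinates index PSSM match columns and
    ``pct_identity`` is the query-versus-consensus identity.
    """

    query_id: str
    target_id: str
    db_name: str
    db_role: Literal["sequence", "profile"]
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    raw_score: float
    bit_score: float
    e_value: float
    pct_identity: float
    # alignment statistics carried for the BLAST-tabular dump
    aln_len: int = 0
    mismatches: int = 0
    gap_opens: int = 0


@dataclasses.dataclass(frozen=True)
class Alignment:
    """Result of one local alignment (0-based half-open intervals)."""

    score: float
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    n_match: int
    n_cols: int
    n_mismatch: int
    n_gap_opens: int
    pairs: tuple[tuple[int, int], ...]

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.n_match / self.n_cols if self.n_cols else 0.0


def _dp_score_only(q: Sequence[int], rows: Sequence[Sequence[float]],
                   gap_open: float, gap_extend: float) -> float:
    """Best local alignment score only (no traceback). Hot loop."""
    m = len(q)
    go = gap_open + gap_extend
    ge = gap_extend
    H_prev = [0.0] * (m + 1)
    E = [-math.inf] * (m + 1)
    best = 0.0
    for row in rows:
        H_cur = [0.0] * (m + 1)
        F = -math.inf
        hp = H_prev
        for j in range(1, m + 1):
            e = hp[j] - go
            e2 = E[j] - ge
            if e2 > e:
                e = e2
            E[j] = e
            f = H_cur[j - 1] - go
            f2 = F - ge
            if f2 > f:
                f = f2
            F = f
            h = hp[j - 1] + row[q[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H_cur[j] = h
            if h > best:
                best = h
        H_prev = H_cur
    return best


def _dp_traceback(q, rows, gap_open, gap_extend):
    """Full DP with traceback.

    Returns (best_score, end_i, end_j, tbH, tbE, tbF) where tbH holds
    0=stop, 1=diag, 2=from E (gap in query), 3=from F (gap in target),
    and tbE/tbF record whether the gap state opened (1) or extended (0).
    Ties in H prefer diag, then E, then F; the best cell is the first
    maximum in row-major order (smallest target, then query, end).
    """
    n = len(rows)
    m = len(q)
    go = gap_open + gap_extend
    ge = gap_extend
    H_prev = [0.0] * (m + 1)
    E = [-math.inf] * (m + 1)
    tbH = [bytearray(m + 1) for _ in range(n + 1)]
    tbE = [bytearray(m + 1) for _ in range(n + 1)]
    tbF = [bytearray(m + 1) for _ in range(n + 1)]
    best = 0.0
    bi = bj = 0
    for i in range(1, n + 1):
        row = rows[i - 1]
        H_cur = [0.0] * (m + 1)
        F = -math.inf
        hp = H_prev
        th = tbH[i]
        te = tbE[i]
        tf = tbF[i]
        for j in range(1, m + 1):
            e_open = hp[j] - go
            e_ext = E[j] - ge
            if e_open >= e_ext:
                e = e_open
                te[j] = 1
            else:
                e = e_ext
            E[j] = e
            f_open = H_cur[j - 1] - go
            f_ext = F - ge
            if f_open >= f_ext:
                f = f_open
                tf[j] = 1
            else:
                f = f_ext
            F = f
            h = hp[j - 1] + row[q[j - 1]]
            ptr = 1
            if e > h:
                h = e
                ptr = 2
            if f > h:
                h = f
                ptr = 3
            if h <= 0.0:
                h = 0.0
                ptr = 0
            H_cur[j] = h
            th[j] = ptr
            if h > best:
                best = h
                bi, bj = i, j
        H_prev = H_cur
    return best, bi, bj, tbH, tbE, tbF


def _align(q: Sequence[int], rows, ref: Optional[Sequence[int]],
           gap_open: float, gap_extend: float) -> Optional[Alignment]:
    """Local alignment of encoded query against per-position score rows.

    ``ref`` supplies the residue identities of the target positions for
    identity computation (the target itself for sequence alignment, the
    profile consensus for profile alignment).  Returns None when no
    positive-scoring alignment exists.
    """
    best, bi, bj, tbH, tbE, tbF = _dp_traceback(q, rows, gap_open, gap_extend)
    if best <= 0.0:
        return None
    pairs: list[tuple[int, int]] = []
    n_cols = n_match = n_mismatch = n_gap_opens = 0
    i, j = bi, bj
    state = "H"
    while True:
        if state == "H":
            ptr = tbH[i][j]
            if ptr == 0:
                break
            if ptr == 1:
                qi = q[j - 1]
                ti = ref[i - 1] if ref is not None else -1
                pairs.append((j - 1, i - 1))
                n_cols += 1
                if ref is not None:
                    if qi == ti and qi != X_INDEX:
                        n_match += 1
                    else:
                        n_mismatch += 1
                i -= 1
                j -= 1
            elif ptr == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in query: consume target position
            opened = tbE[i][j]
            n_cols += 1
            i -= 1
            if opened:
                n_gap_opens += 1
                state = "H"
        else:  # F: gap in target: consume query residue
            opened = tbF[i][j]
            n_cols += 1
            j -= 1
            if opened:
                n_gap_opens += 1
                state = "H"
    pairs.reverse()
    return Alignment(
        score=best,
        q_start=j,
        q_end=bj,
        t_start=i,
        t_end=bi,
        n_match=n_match,
        n_cols=n_cols,
        n_mismatch=n_mismatch,
        n_gap_opens=n_gap_opens,
        pairs=tuple(pairs),
    )


def align_local(q: str, t: str, params: SearchParams = SearchParams()):
    """Optimal gapped local alignment of two protein strings.

    Returns ``(raw_score, (q_start, q_end), (t_start, t_end),
    pct_identity, aligned_pairs)`` with integer raw score, or None when no
    residue pair scores positively.
    """
    if not q or not t:
        raise ValueError("align_local requires non-empty sequences")
    qe = encode(q)
    te = encode(t)
    mat = blosum62_rows()
    rows = [mat[ti] for ti in te]
    aln = _align(qe, rows, te, params.gap_open, params.gap_extend)
    if aln is None:
        return None
    return (
        int(aln.score),
        (aln.q_start, aln.q_end),
        (aln.t_start, aln.t_end),
        aln.pct_identity,
        aln.pairs,
    )


def align_profile(q: str, profile, gap_open: int = 11, gap_extend: int = 1):
    """Local alignment of a query against a profile's PSSM columns.

    The per-cell gain is ``pssm[column][residue]`` (X scores 0); identity
    is computed against the profile consensus.  Returns the same tuple
    shape as :func:`align_local` (raw score is real-valued) or None.
    """
    if not q:
        raise ValueError("align_profile requires a non-empty query")
    qe = encode(q)
    cons = encode(profile.consensus)
    aln = _align(qe, profile.score_rows(), cons, gap_open, gap_extend)
    if aln is None:
        return None
    return (
        aln.score,
        (aln.q_start, aln.q_end),
        (aln.t_start, aln.t_end),
        aln.pct_identity,
        aln.pairs,
    )


def evalue_sequence(raw_score: float, query_len: int, db_size_letters: int,
                    lam: float = GAPPED_BLOSUM62_LAMBDA,
                    K: float = GAPPED_BLOSUM62_K) -> tuple[float, float]:
    """Karlin-Altschul bit score and E-value for a sequence hit."""
    if query_len <= 0 or db_size_letters <= 0:
        raise ValueError("search-space dimensions must be positive")
    if lam <= 0 or K <= 0:
        raise ValueError("Gumbel parameters must be positive")
    bit = (lam * raw_score - math.log(K)) / LN2
    e_value = query_len * db_size_letters * math.pow(2.0, -bit)
    return bit, e_value


def prefilter(query, db, params: SearchParams = SearchParams()) -> list[str]:
    """Candidate targets sharing >= min_diag_kmers k-mers on a diagonal band.

    The diagonal of a k-mer match is t_pos - q_pos; matches are counted in
    the densest window of width +-4 around any diagonal.  Candidates come
    back ordered by descending count, ties broken by target id.
    """
    k = params.kmer_len
    residues = query.residues
    index = db.kmer_index
    per_target: dict[int, list[int]] = {}
    for qpos in range(len(residues) - k + 1):
        kmer = residues[qpos:qpos + k]
        for ti, tpos in index.get(kmer, ()):
            per_target.setdefault(ti, []).append(tpos - qpos)
    scored: list[tuple[int, str]] = []
    for ti, diags in per_target.items():
        diags.sort()
        best = 0
        lo = 0
        for hi in range(len(diags)):
            while diags[hi] - diags[lo] > 8:  # band width +-4
                lo += 1
            cnt = hi - lo + 1
            if cnt > best:
                best = cnt
        if best >= params.min_diag_kmers:
            scored.append((best, db.entries[ti].id))
    scored.sort(key=lambda x: (-x[0], x[1]))
    return [tid for _, tid in scored]


def search_sequence_db(queries, db, params: SearchParams = SearchParams()) -> list[SearchHit]:
    """Search queries against a sequence database (prefilter + alignment).

    Returns only hits with E-value below ``params.max_evalue``.
    """
    db_letters = params.db_size_letters or db.size_letters
    by_id = {rec.id: rec for rec in db.entries}
    hits: list[SearchHit] = []
    for query in queries:
        for target_id in prefilter(query, db, params):
            target = by_id[target_id]
            res = align_local(query.residues, target.residues, params)
            if res is None:
                continue
            raw, (qs, qe_), (ts, te_), pid, pairs = res
            bit, ev = evalue_sequence(raw, len(query.residues), db_letters)
            if ev >= params.max_evalue:
                continue
            aln_len = qe_ - qs + te_ - ts - len(pairs)
            n_match = round(pid * aln_len / 100.0)
            hits.append(
                SearchHit(
                    query_id=query.id,
                    target_id=target_id,
                    db_name=db.name,
                    db_role="sequence",
                    q_start=qs, q_end=qe_, t_start=ts, t_end=te_,
                    raw_score=raw,
                    bit_score=bit,
                    e_value=ev,
                    pct_identity=pid,
                    aln_len=aln_len,
                    mismatches=len(pairs) - n_match,
                    gap_opens=_gap_opens(qs, qe_, ts, te_, pairs),
                )
            )
    return sort_hits(hits)


MAX_DOMAIN_ITERATIONS = 10


def search_profile_db(queries, pdb, params: SearchParams = SearchParams()) -> list[SearchHit]:
    """Search queries against every profile of a profile database.

    Repeated domains are found by masked re-alignment: after each retained
    hit the aligned query span is replaced by X and the query re-aligned,
    up to MAX_DOMAIN_ITERATIONS times or until the E-value threshold fails.
    """
    hits: list[SearchHit] = []
    for query in queries:
        qlen = len(query.residues)
        for profile in pdb.profiles:
            masked = list(query.residues)
            for _ in range(MAX_DOMAIN_ITERATIONS):
                res = align_profile("".join(masked), profile,
                                    params.gap_open, params.gap_extend)
                if res is None:
                    break
                raw, (qs, qe_), (ts, te_), pid, pairs = res
                ev = profile.gumbel_K * profile.length * qlen * math.exp(
                    -profile.gumbel_lambda * raw)
                if ev >= params.max_evalue:
                    break
                bit = (profile.gumbel_lambda * raw
                       - math.log(profile.gumbel_K)) / LN2
                aln_len = qe_ - qs + te_ - ts - len(pairs)
                n_match = round(pid * aln_len / 100.0)
                hits.append(
                    SearchHit(
                        query_id=query.id,
                        target_id=profile.id,
                        db_name=pdb.name,
                        db_role="profile",
                        q_start=qs, q_end=qe_, t_start=ts, t_end=te_,
                        raw_score=raw,
                        bit_score=bit,
                        e_value=ev,
                        pct_identity=pid,
                        aln_len=aln_len,
                        mismatches=len(pairs) - n_match,
                        gap_opens=_gap_opens(qs, qe_, ts, te_, pairs),
                    )
                )
                masked[qs:qe_] = "X" * (qe_ - qs)
    return sort_hits(hits)


def _gap_opens(qs, qe, ts, te, pairs):
    """Gap-open count recovered from interval lengths vs aligned pairs."""
    # pairs cover the match columns; any coordinate jump > 1 is one gap run
    opens = 0
    prev_q, prev_t = None, None
    for qp, tp in pairs:
        if prev_q is not None:
            if qp - prev_q > 1:
                opens += 1
            if tp - prev_t > 1:
                opens += 1
        prev_q, prev_t = qp, tp
    return opens


def sort_hits(hits: list[SearchHit]) -> list[SearchHit]:
    """Deterministic global hit order."""
    return sorted(
        hits,
        key=lambda h: (h.query_id, h.db_name, h.e_value, -h.bit_score, h.target_id),
    )


# ---------------------------------------------------------------------------
# BLAST tabular (M8) dump: 12 columns, 1-based inclusive coordinates.

M8_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def write_m8(hits: Sequence[SearchHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.pct_identity:.2f}\t{h.aln_len}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.q_start + 1}\t{h.q_end}\t"
                f"{h.t_start + 1}\t{h.t_end}\t{h.e_value:.3g}\t{h.bit_score:.2f}\n"
            )


def read_m8(path: str | Path) -> list[dict]:
    """Parse an M8 file into dicts keyed by M8_COLUMNS (1-based coords kept)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 12:
                raise ValueError(f"{path}: M8 rows need 12 columns, got {len(parts)}")
            row = dict(zip(M8_COLUMNS, parts))
            for key in ("length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"):
                row[key] = int(row[key])
            row["pident"] = float(row["pident"])
            row["evalue"] = float(row["evalue"])
            row["bitscore"] = float(row["bitscore"])
            rows.append(row)
    return rows
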
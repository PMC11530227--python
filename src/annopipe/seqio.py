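"""Sequence input/output and translation.

Reads and writes FASTA/FASTQ through Biopython, with strict validation on
top: unique record identifiers, declared-alphabet checking, and FASTQ
structural checks.  Nucleotide inputs are turned into amino-acid queries by
six-frame translation and extraction of maximal stop-free open reading
frames (ORFs); ORFs are stop-to-stop stretches and need not start with
methionine, because downstream homology search scores any frame segment.

Internal coordinates are 0-based half-open throughout; only the final
report files use 1-based inclusive coordinates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import AlphabetError, DuplicateIdError, FormatError
from .scoring import DNA_ALPHABET, PROTEIN_ALPHABET

Alphabet = Literal["dna", "protein"]

#: Default minimum ORF length (amino acids) for nucleotide inputs.
DEFAULT_MIN_ORF_LEN = 30

#: Minimum read length (nt) accepted on the assembly path.
MIN_ASSEMBLY_READ_LEN = 100

_FRAMES = (1, 2, 3, -1, -2, -3)

# Standard genetic code (translation table 1).
_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_CODON_TABLE.forward_table)
_STOPS = set(_CODON_TABLE.stop_codons)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """One biological sequence.

    Attributes
    ----------
    id:
        Unique identifier (no whitespace).
    description:
        Free-text description (everything after the id on the header line).
    residues:
        Uppercase residue string.
    alphabet:
        ``"dna"`` (A/C/G/T/N) or ``"protein"`` (20 amino acids plus X and *).
    """

    id: str
    description: str
    residues: str
    alphabet: Alphabet

    def __len__(self) -> int:
        return len(self.residues)


@dataclasses.dataclass(frozen=True)
class OrfRecord:
    """A maximal stop-free stretch in one translation frame.

    ``orf_id`` is ``"<parent>_f<frame>_<k>"`` where k numbers the ORFs of a
    parent in a deterministic scan order; ``start_nt`` is the 0-based
    offset of the ORF's first codon on the forward strand.
    """

    parent_id: str
    frame: int
    start_nt: int
    length_aa: int
    residues: str
    orf_id: str

    def to_sequence_record(self) -> SequenceRecord:
        return SequenceRecord(
            id=self.orf_id,
            description=f"parent={self.parent_id} frame={self.frame:+d}",
            residues=self.residues,
            alphabet="protein",
        )


def _check_alphabet(record_id: str, residues: str, alphabet: Alphabet) -> None:
    allowed = DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET
    for pos, ch in enumerate(residues):
        if ch not in allowed:
            raise AlphabetError(
                f"record {record_id!r}: illegal {alphabet} residue {ch!r} "
                f"at position {pos}"
            )


def read_fasta(path: str | Path, alphabet: Alphabet) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    Residues are uppercased and wrapped lines joined.  Raises
    :class:`FormatError` for an empty file, :class:`DuplicateIdError` for
    repeated ids, and :class:`AlphabetError` for residues outside the
    declared alphabet.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise DuplicateIdError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            residues = str(rec.seq).upper()
            if not residues:
                raise FormatError(f"{path}: record {rec.id!r} has no residues")
            _check_alphabet(rec.id, residues, alphabet)
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(SequenceRecord(rec.id, desc, residues, alphabet))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read a 4-line-per-record FASTQ file; qualities are validated then dropped."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        with open(path) as handle:
            for rec in SeqIO.parse(handle, "fastq"):
                if rec.id in seen:
                    raise DuplicateIdError(f"{path}: duplicate read id {rec.id!r}")
                seen.add(rec.id)
                residues = str(rec.seq).upper()
                _check_alphabet(rec.id, residues, "dna")
                desc = rec.description
                if desc.startswith(rec.id):
                    desc = desc[len(rec.id):].strip()
                records.append(SequenceRecord(rec.id, desc, residues, "dna"))
    except ValueError as exc:  # Biopython signals truncation/length mismatch
        raise FormatError(f"{path}: malformed FASTQ ({exc})") from exc
    if not records:
        raise FormatError(f"{path}: no FASTQ records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA; round-trips through read_fasta."""
    path = Path(path)
    with open(path, "w") as handle:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n{rec.residues}\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate_frame(seq: str, frame: int) -> str:
    """Translate one frame; codons containing N render 'X', stops '*'."""
    if frame > 0:
        s = seq[frame - 1:]
    else:
        s = reverse_complement(seq)[-frame - 1:]
    out = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i:i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in _STOPS:
            out.append("*")
        else:
            out.append(_FORWARD[codon])
    return "".join(out)


def six_frame_translate(rec: SequenceRecord) -> dict[int, str]:
    """Translate a DNA record in all six frames (standard genetic code).

    Returns a mapping frame -> protein string for frames +1,+2,+3 on the
    forward strand and -1,-2,-3 on the reverse complement.  Trailing
    partial codons are dropped.
    """
    if rec.alphabet != "dna":
        raise AlphabetError(f"record {rec.id!r}: six-frame translation needs dna")
    return {frame: _translate_frame(rec.residues, frame) for frame in _FRAMES}


def extract_orfs(rec: SequenceRecord, min_len_aa: int = DEFAULT_MIN_ORF_LEN) -> list[OrfRecord]:
    """All maximal stop-free stretches of length >= min_len_aa in six frames.

    ORFs are reported in frame order (+1,+2,+3,-1,-2,-3) and left-to-right
    within a frame; ``start_nt`` is mapped back to the forward strand.
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    translations = six_frame_translate(rec)
    n = len(rec.residues)
    orfs: list[OrfRecord] = []
    for frame in _FRAMES:
        protein = translations[frame]
        counter = 0
        for start_aa, stretch in _stop_free_runs(protein):
            if len(stretch) < min_len_aa:
                continue
            counter += 1
            if frame > 0:
                start_nt = (frame - 1) + 3 * start_aa
            else:
                # position of the codon's last base from the 3' end maps to
                # the forward-strand offset of the codon's first base
                offset_on_rc = (-frame - 1) + 3 * start_aa
                start_nt = n - offset_on_rc - 3 * len(stretch)
            orfs.append(
                OrfRecord(
                    parent_id=rec.id,
                    frame=frame,
                    start_nt=start_nt,
                    length_aa=len(stretch),
                    residues=stretch,
                    orf_id=f"{rec.id}_f{frame:+d}_{counter}",
                )
            )
    return orfs


def _stop_free_runs(protein: str):
    """Yield (start, run) for maximal '*'-free runs of a translation."""
    start = 0
    for i, ch in enumerate(protein):
        if ch == "*":
            if i > start:
                yield start, protein[start:i]
            start = i + 1
    if len(protein) > start:
        yield start, protein[start:]


def interleave_paired(r1: list[SequenceRecord], r2: list[SequenceRecord]) -> list[SequenceRecord]:
    """Interleave two paired-end read lists into one query set.

    Mate ids are suffixed /1 and /2 when the two files reuse the same ids.
    """
    if len(r1) != len(r2):
        raise FormatError(
            f"paired-end files differ in read count ({len(r1)} vs {len(r2)})"
        )
    ids1 = {r.id for r in r1}
    suffix = any(r.id in ids1 for r in r2)
    out: list[SequenceRecord] = []
    for a, b in zip(r1, r2):
        if suffix:
            a = dataclasses.replace(a, id=a.id + "/1")
            b = dataclasses.replace(b, id=b.id + "/2")
        out.extend((a, b))
    return out
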
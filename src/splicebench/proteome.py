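"""Protein sequence databases: FASTA I/O, I/L collapsing, substring lookup, decoys.

A :class:`Proteome` is an ordered collection of protein entries over the 20
canonical amino-acid letters.  Because mass spectrometry cannot distinguish
isoleucine from leucine, databases are usually *I/L-collapsed* (every ``I``
rewritten to ``L``) before any splice mapping; the flag on the proteome records
that state so that mixed-state comparisons can be rejected early.

Decoy databases are produced by whole-protein sequence reversal and carry the
``DECOY_`` accession prefix, the classic target-decoy construction used for
FDR estimation in shotgun proteomics.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_right
from pathlib import Path
from typing import Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: 19-letter alphabet after I/L collapsing (no isoleucine).
COLLAPSED_AA = "ACDEFGHKLMNPQRSTVWY"
DECOY_TAG = "DECOY_"

_CANONICAL_SET = frozenset(CANONICAL_AA)


@dataclasses.dataclass(frozen=True)
class ProteinEntry:
    """One protein: a unique accession and an upper-case amino-acid sequence."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for accession {self.accession!r}")
        if not _CANONICAL_SET.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - _CANONICAL_SET)
            raise ValueError(
                f"non-canonical residue(s) {bad} in accession {self.accession!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class Occurrence:
    """An exact occurrence of a query peptide: 0-based, half-open coordinates."""

    accession: str
    start: int
    end: int

    def as_tuple(self) -> tuple[str, int, int]:
        return (self.accession, self.start, self.end)


class Proteome:
    """Ordered list of :class:`ProteinEntry` with unique accessions."""

    def __init__(self, entries: Sequence[ProteinEntry], il_collapsed: bool = False):
        entries = list(entries)
        seen: set[str] = set()
        for e in entries:
            if e.accession in seen:
                raise ValueError(f"duplicate accession {e.accession!r}")
            seen.add(e.accession)
        if il_collapsed:
            for e in entries:
                if "I" in e.sequence:
                    raise ValueError(
                        f"il_collapsed proteome contains I in {e.accession!r}"
                    )
        self.entries: list[ProteinEntry] = entries
        self.il_collapsed = il_collapsed
        self._by_accession = {e.accession: e for e in entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ProteinEntry]:
        return iter(self.entries)

    def get(self, accession: str) -> ProteinEntry:
        return self._by_accession[accession]

    @property
    def accessions(self) -> list[str]:
        return [e.accession for e in self.entries]

    def total_residues(self) -> int:
        return sum(len(e) for e in self.entries)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Proteome)
            and self.il_collapsed == other.il_collapsed
            and self.entries == other.entries
        )


def read_fasta(path: str | Path, on_noncanonical: str = "error") -> Proteome:
    """Read a FASTA protein database.

    The accession is the header token up to the first whitespace; sequences are
    upper-cased.  ``on_noncanonical`` is either ``"error"`` (default: raise,
    reporting the offending line) or ``"drop"`` (silently skip records whose
    sequence contains letters outside the 20-letter alphabet, e.g. B/J/O/U/X/Z).
    """
    if on_noncanonical not in ("error", "drop"):
        raise ValueError("on_noncanonical must be 'error' or 'drop'")
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    for rec in records:
        accession = rec.id
        seq = str(rec.seq).upper()
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        if not _CANONICAL_SET.issuperset(seq):
            if on_noncanonical == "drop":
                continue
            raise ValueError(
                f"non-amino-acid character in record {accession!r} "
                f"(line {_offending_line(path, accession, seq)}) in {path}"
            )
        seen.add(accession)
        entries.append(ProteinEntry(accession, seq))
    if not entries:
        raise ValueError(f"no records with canonical sequences in {path}")
    return Proteome(entries, il_collapsed=False)


def _offending_line(path: Path, accession: str, seq: str) -> int:
    """Locate the first line of *accession*'s record holding a non-canonical letter."""
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == accession if line[1:].split() else False
                continue
            if in_record and not _CANONICAL_SET.issuperset(line.strip().upper()):
                return lineno
    return -1


def write_fasta(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    """Write *proteome* as FASTA, wrapping sequence lines at *width* columns."""
    with open(path, "w") as fh:
        for e in proteome:
            fh.write(f">{e.accession}\n")
            for i in range(0, len(e.sequence), width):
                fh.write(e.sequence[i : i + width] + "\n")


def collapse_il(proteome: Proteome) -> Proteome:
    """Replace every isoleucine by leucine; idempotent."""
    entries = [
        ProteinEntry(e.accession, e.sequence.replace("I", "L")) for e in proteome
    ]
    return Proteome(entries, il_collapsed=True)


def collapse_peptide(peptide: str) -> str:
    return peptide.replace("I", "L")


def make_decoy(proteome: Proteome) -> Proteome:
    """Whole-protein reversal with a ``DECOY_`` accession prefix."""
    entries = [
        ProteinEntry(DECOY_TAG + e.accession, e.sequence[::-1]) for e in proteome
    ]
    return Proteome(entries, il_collapsed=proteome.il_collapsed)


class SubstringIndex:
    """Exact-occurrence lookup of short peptides over all proteome sequences.

    Internally the sequences are joined with a sentinel character so that one
    C-level ``str.find`` sweep serves every query; occurrences are reported in
    (accession order, start) order, matching a naive per-protein scan.
    """

    _SENTINEL = "#"

    def __init__(self, proteome: Proteome):
        if len(proteome) == 0:
            raise ValueError("cannot index an empty proteome")
        self.proteome = proteome
        self.il_collapsed = proteome.il_collapsed
        self._accessions = proteome.accessions
        self._sequences = [e.sequence for e in proteome]
        # offsets[i] = global start of protein i inside the joined text
        self._offsets: list[int] = []
        pos = 0
        parts: list[str] = []
        for seq in self._sequences:
            self._offsets.append(pos)
            parts.append(seq)
            pos += len(seq) + 1
        self._text = self._SENTINEL.join(parts)
        self._ends = [off + len(seq) for off, seq in zip(self._offsets, self._sequences)]

    def _locate(self, global_pos: int) -> int:
        """Index of the protein containing *global_pos*."""
        return bisect_right(self._offsets, global_pos) - 1

    def lookup(self, query: str) -> list[Occurrence]:
        """All occurrences of *query*, including overlapping ones."""
        if not query:
            raise ValueError("empty query")
        out: list[Occurrence] = []
        text = self._text
        pos = text.find(query)
        while pos != -1:
            i = self._locate(pos)
            end = pos + len(query)
            if end <= self._ends[i]:  # reject matches spanning the sentinel
                off = self._offsets[i]
                out.append(Occurrence(self._accessions[i], pos - off, end - off))
            pos = text.find(query, pos + 1)
        return out

    def contains(self, query: str) -> bool:
        """True iff *query* occurs in some protein."""
        text = self._text
        pos = text.find(query)
        while pos != -1:
            i = self._locate(pos)
            if pos + len(query) <= self._ends[i]:
                return True
            pos = text.find(query, pos + 1)
        return False

    def accession_probe(self, query: str, limit: int = 2) -> list[str]:
        """Up to *limit* distinct accessions containing *query* (accession order)."""
        found: list[str] = []
        text = self._text
        pos = text.find(query)
        while pos != -1 and len(found) < limit:
            i = self._locate(pos)
            if pos + len(query) <= self._ends[i]:
                acc = self._accessions[i]
                if acc not in found:
                    found.append(acc)
                # jump past this protein: one hit per protein suffices here
                pos = text.find(query, self._ends[i] + 1)
                continue
            pos = text.find(query, pos + 1)
        return found

    def occurrences_in(self, query: str, accession: str) -> list[tuple[int, int]]:
        """(start, end) occurrences of *query* inside one protein."""
        seq = self.proteome.get(accession).sequence
        out = []
        pos = seq.find(query)
        while pos != -1:
            out.append((pos, pos + len(query)))
            pos = seq.find(query, pos + 1)
        return out


def build_index(proteome: Proteome) -> SubstringIndex:
    """Build a :class:`SubstringIndex` over *proteome*."""
    return SubstringIndex(proteome)
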
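"""Haplotype abundance tables and their on-disk serializations.

A viral quasispecies sample, as produced by amplicon NGS haplotyping, is a
set of unique haplotypes with integer read counts.  Everything in this
package operates on that count vector: the sequences themselves are carried
as an optional payload but never interpreted.

Two serializations are supported: a two-column TSV count table and FASTA
with the abundance encoded in the header (the ``;size=N;`` dereplication
convention, or an ``id|N`` suffix).
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """A haplotype table violates its invariants."""


class ParseError(ValueError):
    """A serialized count table could not be parsed."""


class HaplotypeTable:
    """A quasispecies sample: unique haplotype IDs with positive read counts.

    Parameters
    ----------
    ids : sequence of str
        Unique haplotype identifiers (opaque strings).
    counts : sequence of int
        Reads per haplotype, aligned with `ids`; all >= 1.
    sequences : sequence of str, optional
        Nucleotide sequences aligned with `ids`.  Carried through
        serialization but ignored by every computation.

    Attributes
    ----------
    N : int
        Total reads (library size / coverage).
    H : int
        Number of haplotypes.
    """

    __slots__ = ("ids", "counts", "sequences")

    def __init__(self, ids, counts, sequences=None, *, validate: bool = True):
        if not (isinstance(ids, np.ndarray) and ids.dtype.kind == "U"):
            ids = np.asarray(list(ids), dtype=str)
        if not (isinstance(counts, np.ndarray) and counts.dtype == np.int64):
            counts = np.asarray(list(counts), dtype=np.int64)
        if sequences is not None:
            sequences = tuple(sequences)
        if validate:
            if ids.shape != counts.shape or ids.ndim != 1:
                raise ValidationError(
                    f"ids and counts must be equal-length 1-d sequences "
                    f"(got {ids.shape} vs {counts.shape})"
                )
            if counts.size == 0:
                raise ValidationError("a haplotype table cannot be empty")
            bad = counts < 1
            if bad.any():
                offender = ids[bad][0]
                raise ValidationError(
                    f"haplotype {offender!r} has count {int(counts[bad][0])}; "
                    "all counts must be >= 1"
                )
            if np.unique(ids).size != ids.size:
                uniq, n = np.unique(ids, return_counts=True)
                raise ValidationError(f"duplicate haplotype id {uniq[n > 1][0]!r}")
            if sequences is not None and len(sequences) != ids.size:
                raise ValidationError("sequences must align with ids")
        self.ids = ids
        self.counts = counts
        self.sequences = sequences

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def H(self) -> int:
        return int(self.counts.size)

    def __len__(self) -> int:
        return self.H

    def __eq__(self, other) -> bool:
        if not isinstance(other, HaplotypeTable):
            return NotImplemented
        return (
            self.ids.shape == other.ids.shape
            and bool((self.ids == other.ids).all())
            and bool((self.counts == other.counts).all())
        )

    def __repr__(self) -> str:
        return f"HaplotypeTable(H={self.H}, N={self.N})"

    def digest(self) -> str:
        """Stable hex digest of (ids, counts), for provenance metadata."""
        h = hashlib.sha1()
        for i, c in zip(self.ids, self.counts):
            h.update(str(i).encode())
            h.update(b"\t")
            h.update(str(int(c)).encode())
            h.update(b"\n")
        return h.hexdigest()

    def canonical_order(self) -> np.ndarray:
        """Indices sorted by descending count, ties broken by ascending ID."""
        return np.lexsort((self.ids, -self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"haplotype": self.ids, "count": self.counts})


@dataclass(frozen=True)
class FrequencyVector:
    """Relative haplotype frequencies p_i = count_i / N.

    `granularity` is the smallest representable frequency step, 1/N: with
    integer read counts only multiples of 1/N are attainable.
    """

    p: np.ndarray
    granularity: float

    def __post_init__(self):
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        s = float(self.p.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValidationError(f"frequencies sum to {s}, not 1")

    def __len__(self) -> int:
        return int(self.p.size)

    def __iter__(self):
        return iter(self.p)


def make_table(
    ids: Iterable[str],
    counts: Iterable[int],
    sequences: Sequence[str] | None = None,
) -> HaplotypeTable:
    """Build a validated :class:`HaplotypeTable` from aligned ids and counts."""
    return HaplotypeTable(ids, counts, sequences, validate=True)


def frequencies(t: HaplotypeTable) -> FrequencyVector:
    """Haplotype frequencies of `t` as fractions of the library size."""
    return FrequencyVector(t.counts / t.N, 1.0 / t.N)


# ---------------------------------------------------------------------------
# TSV count tables
# ---------------------------------------------------------------------------

_HEADER_HINT = ("haplotype", "id", "hpl", "name", "sequence")


def read_counts_tsv(path) -> HaplotypeTable:
    """Read a two-column (id, count) TSV; a non-numeric header row is detected.

    Raises :class:`ParseError` with the offending line number on malformed
    lines or non-integer counts (``12.5`` is rejected, not truncated).
    """
    ids: list[str] = []
    counts: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(parts)}"
                )
            hid, cnt = parts
            try:
                value = int(cnt)
            except ValueError:
                try:
                    float(cnt)
                except ValueError:
                    # Non-numeric second field: a header row on line 1 only.
                    if lineno == 1:
                        continue
                    raise ParseError(
                        f"{path}: line {lineno}: count {cnt!r} is not a number"
                    ) from None
                raise ParseError(
                    f"{path}: line {lineno}: count {cnt!r} is not an integer"
                ) from None
            ids.append(hid)
            counts.append(value)
    if not ids:
        raise ParseError(f"{path}: no count records found")
    try:
        return make_table(ids, counts)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_counts_tsv(t: HaplotypeTable, path, header: bool = True) -> None:
    """Write `t` in canonical order (count desc, id asc) as UTF-8 TSV."""
    order = t.canonical_order()
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("haplotype\tcount\n")
        for i in order:
            fh.write(f"{t.ids[i]}\t{int(t.counts[i])}\n")


# ---------------------------------------------------------------------------
# FASTA with abundance-annotated headers
# ---------------------------------------------------------------------------

_SIZE_RE = re.compile(r"^(?P<id>.+?);size=(?P<n>\d+);?$")
_PIPE_RE = re.compile(r"^(?P<id>.+)\|(?P<n>\d+)$")
_DIALECTS = {"size": _SIZE_RE, "pipe": _PIPE_RE}


def read_fasta_abundance(path, dialect: str = "size") -> HaplotypeTable:
    """Read dereplicated FASTA where the header carries the read count.

    Dialects: ``"size"`` for ``>id;size=N;`` (usearch/vsearch convention)
    and ``"pipe"`` for ``>id|N``.  Sequences are retained as payload.
    """
    from Bio import SeqIO

    try:
        pattern = _DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown FASTA abundance dialect {dialect!r}") from None
    ids, counts, seqs = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = pattern.match(rec.id)
        if m is None:
            raise ParseError(
                f"{path}: record {rec.id!r} has no parseable "
                f"{dialect!r}-dialect abundance annotation"
            )
        ids.append(m.group("id"))
        counts.append(int(m.group("n")))
        seqs.append(str(rec.seq))
    if not ids:
        raise ParseError(f"{path}: no FASTA records found")
    try:
        return make_table(ids, counts, seqs)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_fasta_abundance(t: HaplotypeTable, path, dialect: str = "size") -> None:
    """Write `t` as abundance-annotated FASTA in canonical order.

    When the table carries no sequences a single-``N`` placeholder is
    written, since downstream computations ignore sequence content.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown FASTA abundance dialect {dialect!r}")
    order = t.canonical_order()
    with open(path, "w", encoding="utf-8") as fh:
        for i in order:
            c = int(t.counts[i])
            label = f"{t.ids[i]};size={c};" if dialect == "size" else f"{t.ids[i]}|{c}"
            seq = t.sequences[i] if t.sequences is not None else "N"
            fh.write(f">{label}\n{seq}\n")
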
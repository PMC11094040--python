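"""Core domain types and file I/O for the ping-pong piRNA pipeline.

The pipeline revolves around a transposon (TE) panel, a reference piRNA
annotation anchored to TE coordinates, alignments of small-RNA reads onto
the panel, per-library count tables, and the final per-piRNA ping-pong
classification.  All of those live here, together with readers/writers for
the plain-text formats that carry them: FASTA (panel), FASTQ (reads,
optionally gzipped), BED6 (alignments), and TSV/JSON (result tables).

Coordinate conventions
----------------------
Alignments use 0-based half-open ``[start, end)`` intervals (the BED
convention).  Reference piRNA annotations use the 1-based coordinate of the
piRNA's 5' nucleotide on the TE, the convention of the biology literature.
:func:`five_prime_from_interval` and :func:`interval_start_for_five_prime`
are the only places the two systems meet.

All RNA sequences are stored in the DNA alphabet (U -> T) so that reads,
TEs and annotations share a single matching alphabet.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA-alphabet string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TESequence:
    """One transposon consensus sequence of the mapping panel.

    ``is_rrna_te`` flags a TE whose piRNAs must be excluded from the
    ping-pong analysis because the element carries rRNA sequence.
    """

    te_id: str
    sequence: str
    is_rrna_te: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"TE {self.te_id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"TE {self.te_id!r}: non-ACGT characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferencePiRNA:
    """An annotated reference piRNA species anchored to a TE coordinate.

    ``five_prime_pos`` is the 1-based TE coordinate of the piRNA's 5'
    nucleotide; for a minus-strand piRNA the body extends toward lower
    coordinates and the sequence is the reverse complement of the covered
    TE window.
    """

    pirna_id: str
    te_id: str
    strand: str  # "+" or "-"
    five_prime_pos: int
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.pirna_id}: strand must be '+' or '-'")
        if not 23 <= len(self.sequence) <= 32:
            raise ValueError(
                f"{self.pirna_id}: length {len(self.sequence)} outside 23-32"
            )
        if self.five_prime_pos < 1:
            raise ValueError(f"{self.pirna_id}: five_prime_pos must be >= 1")

    def validate_against(self, te: TESequence) -> None:
        """Check that the annotated sequence matches the TE window it names."""
        n = len(self.sequence)
        if self.strand == "+":
            s0 = self.five_prime_pos - 1
            window = te.sequence[s0:s0 + n]
        else:
            e = self.five_prime_pos  # 1-based 5' == 0-based exclusive end
            window = revcomp(te.sequence[e - n:e]) if e - n >= 0 else ""
        if window != self.sequence:
            raise ValueError(
                f"{self.pirna_id}: sequence does not match TE "
                f"{self.te_id} at {self.strand}{self.five_prime_pos}"
            )


@dataclass
class ReadRecord:
    """A sequencing read (or a collapsed unique molecule).

    ``count`` is 1 on raw reads and remains 1 per unique molecule after
    PCR-duplicate collapsing; aggregation over identical cores later turns
    it into a molecule count.
    """

    read_id: str
    sequence: str
    quality: Optional[str] = None
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length "
                f"{len(self.quality)} != sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class AlignmentHit:
    """Ungapped placement of a read on a TE (BED coordinates).

    A minus-strand hit means the reverse complement of the read matches
    ``TE[start:end]``.  ``five_prime_pos`` is derived, 1-based: ``start+1``
    on plus, ``end`` on minus.
    """

    read_id: str
    te_id: str
    strand: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    mismatches: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")

    @property
    def five_prime_pos(self) -> int:
        return five_prime_from_interval(self.start, self.end, self.strand)


def five_prime_from_interval(start: int, end: int, strand: str) -> int:
    """1-based 5' coordinate of a read placed at BED ``[start, end)``."""
    return start + 1 if strand == "+" else end


def interval_start_for_five_prime(five_prime_pos: int, length: int,
                                  strand: str) -> tuple[int, int]:
    """Invert :func:`five_prime_from_interval`: BED interval of a read of
    ``length`` whose 5' nucleotide sits at ``five_prime_pos``."""
    if strand == "+":
        start = five_prime_pos - 1
    else:
        start = five_prime_pos - length
    return start, start + length


@dataclass
class LibraryCounts:
    """Per-key (piRNA or TE) raw counts and RPM for one library.

    ``denominator_mode`` records what the normalization denominator was:
    ``genome_mapped`` (all reads with a best-stratum hit on the panel) or
    ``reference_matched`` (reads 5'-matching the reference piRNA set, the
    rule used for the PIWI-IP libraries).
    """

    library_id: str
    role: str  # control | kd | siwi_ip | ago3_ip
    counts: dict[str, float]
    denominator: float
    denominator_mode: str = "genome_mapped"

    def __post_init__(self) -> None:
        if self.role not in ("control", "kd", "siwi_ip", "ago3_ip"):
            raise ValueError(f"unknown library role {self.role!r}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative count")
        if self.denominator <= 0:
            raise ValueError(f"empty library {self.library_id!r}: denominator must be > 0")

    @property
    def rpm(self) -> dict[str, float]:
        d = self.denominator
        return {k: v / d * 1e6 for k, v in self.counts.items()}

    def rpm_of(self, key: str) -> float:
        return self.counts.get(key, 0.0) / self.denominator * 1e6


@dataclass
class PingPongRecord:
    """Final classification of one reference piRNA.

    ``klass`` is one of the three ping-pong classes (``A_to_S``, ``S_to_A``,
    ``S_to_S``), the optional ``A_to_A`` class, or an exclusion
    (``excl_rrna``, ``excl_undetermined``, ``excl_ambiguous``).
    """

    pirna_id: str
    own_piwi: str                    # S | A | undetermined
    partner_te_id: Optional[str]
    partner_strand: Optional[str]
    partner_five_prime_pos: Optional[int]
    partner_piwi: str                # S | A | undetermined
    klass: str

    CLASSES = ("A_to_S", "S_to_A", "S_to_S")
    EXCLUSIONS = ("excl_rrna", "excl_undetermined", "excl_ambiguous")

    def __post_init__(self) -> None:
        allowed = set(self.CLASSES) | set(self.EXCLUSIONS) | {"A_to_A"}
        if self.klass not in allowed:
            raise ValueError(f"unknown class {self.klass!r}")
        if self.klass in self.CLASSES and (
            self.own_piwi == "undetermined" or self.partner_piwi == "undetermined"
        ):
            raise ValueError(
                f"{self.pirna_id}: class {self.klass} requires determined calls"
            )


@dataclass
class TruthTable:
    """Ground truth emitted by the synthetic-data generator."""

    seed: int
    params: dict = field(default_factory=dict)
    # per planted species: see synthetic_data.PlantedSpecies
    species: list = field(default_factory=list)

    def reference_truth(self) -> dict[str, "object"]:
        """Planted species that are part of the reference annotation."""
        return {s.pirna_id: s for s in self.species if s.in_reference}


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def _maybe_gzip_open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path, rrna_te_ids: Iterable[str] = ()) -> list[TESequence]:
    """Read a TE panel FASTA into :class:`TESequence` records.

    Sequences are uppercased and U is normalized to T.  Records whose id is
    in ``rrna_te_ids`` get ``is_rrna_te=True``.  Any character outside ACGT
    after normalization is a :class:`FormatError`.
    """
    path = Path(path)
    rrna = set(rrna_te_ids)
    with _maybe_gzip_open(path) as fh:
        first = fh.read(1)
        if first == "":
            raise FormatError(f"{path}: empty FASTA file")
        if first != ">":
            raise FormatError(f"{path}: line 1: expected '>' header, got {first!r}")
    records: list[TESequence] = []
    seen: set[str] = set()
    with _maybe_gzip_open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper().replace("U", "T")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise FormatError(
                    f"{path}: record {rec.id!r}: disallowed characters {sorted(bad)!r}"
                )
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate te_id {rec.id!r}")
            seen.add(rec.id)
            records.append(TESequence(rec.id, seq, is_rrna_te=rec.id in rrna))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[TESequence], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.te_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a FASTQ file (gzip allowed) as :class:`ReadRecord` objects.

    Order-preserving; ``count`` starts at 1.  Truncated or malformed
    blocks raise :class:`FormatError` naming the record index.
    """
    i = 0
    with _maybe_gzip_open(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                if len(qual) != len(seq):
                    raise FormatError(
                        f"{path}: record {i}: quality length {len(qual)} "
                        f"!= sequence length {len(seq)}"
                    )
                yield ReadRecord(title.split()[0], seq.upper().replace("U", "T"),
                                 qual, 1)
                i += 1
        except ValueError as exc:  # Biopython: truncated / malformed block
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}: record {i}: {exc}") from exc


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec.sequence)
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Reference piRNA annotation (TSV)
# ---------------------------------------------------------------------------

REF_COLUMNS = ["pirna_id", "te_id", "strand", "five_prime_pos", "sequence"]


def read_reference_pirnas(path: str | Path,
                          panel: Optional[Sequence[TESequence]] = None
                          ) -> list[ReferencePiRNA]:
    """Read the reference piRNA annotation TSV.

    When ``panel`` is given, every record is validated against its TE
    (sequence identity at the annotated window, id existence).
    """
    df = pd.read_csv(path, sep="\t", dtype={"strand": str})
    missing = [c for c in REF_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    refs = [
        ReferencePiRNA(str(r.pirna_id), str(r.te_id), str(r.strand),
                       int(r.five_prime_pos), str(r.sequence))
        for r in df.itertuples(index=False)
    ]
    ids = [r.pirna_id for r in refs]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate pirna_id")
    if panel is not None:
        by_id = {t.te_id: t for t in panel}
        for ref in refs:
            if ref.te_id not in by_id:
                raise FormatError(f"{path}: {ref.pirna_id}: unknown TE {ref.te_id!r}")
            ref.validate_against(by_id[ref.te_id])
    return refs


def write_reference_pirnas(refs: Iterable[ReferencePiRNA], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in refs], columns=REF_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def write_bed(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write alignments as BED6 (score column = mismatch count)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.te_id}\t{h.start}\t{h.end}\t{h.read_id}"
                     f"\t{h.mismatches}\t{h.strand}\n")


def read_bed(path: str | Path) -> list[AlignmentHit]:
    hits = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}: line {ln}: expected 6 BED columns")
            chrom, start, end, name, score, strand = parts
            hits.append(AlignmentHit(name, chrom, strand,
                                     int(start), int(end), int(score)))
    return hits


# ---------------------------------------------------------------------------
# Generic tables
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence, columns: Optional[list[str]] = None
                     ) -> pd.DataFrame:
    """Dataclass records -> DataFrame with deterministic (field-order) columns."""
    if records:
        cols = columns or [f.name for f in fields(records[0])]
        return pd.DataFrame([asdict(r) for r in records], columns=cols)
    return pd.DataFrame(columns=columns or [])


def write_tables(records: Sequence, path: str | Path, format: str = "tsv",
                 columns: Optional[list[str]] = None) -> None:
    """Serialize dataclass records to TSV or JSON, round-trip losslessly.

    Column order follows dataclass field order, so output is deterministic.
    An empty record list with explicit ``columns`` yields a header-only TSV.
    """
    df = records_to_frame(records, columns)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        Path(path).write_text(
            json.dumps(df.to_dict(orient="records"), indent=1) + "\n"
        )
    else:
        raise ValueError(f"unknown table format {format!r}")


def read_table(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        return pd.DataFrame(json.loads(Path(path).read_text()))
    raise ValueError(f"unknown table format {format!r}")


PINGPONG_COLUMNS = ["pirna_id", "own_piwi", "partner_te_id", "partner_strand",
                    "partner_five_prime_pos", "partner_piwi", "klass"]


def read_pingpong_table(path: str | Path, format: str = "tsv"
                        ) -> list[PingPongRecord]:
    df = read_table(path, format)
    out = []
    for r in df.itertuples(index=False):
        pos = r.partner_five_prime_pos
        te = r.partner_te_id
        strand = r.partner_strand
        out.append(PingPongRecord(
            str(r.pirna_id), str(r.own_piwi),
            None if pd.isna(te) else str(te),
            None if pd.isna(strand) else str(strand),
            None if pd.isna(pos) else int(pos),
            str(r.partner_piwi), str(r.klass),
        ))
    return out
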
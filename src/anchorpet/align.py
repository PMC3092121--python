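"""Placement of short tags onto the target loci.

The mapping problem here is deliberately small: two extracted loci (a
breakpoint-cluster region and a partner gene) of a few kb to a few hundred kb,
and fixed-length tags (38 bp by default). At that scale an exact full-length
k-mer lookup over both strands, keeping only uniquely placed tags, reproduces
the "both tags mapping back uniquely to the target regions" filter that a
general-purpose gapped aligner would otherwise provide. Externally produced
alignments (SAM or a 6-column TSV) can be ingested instead.

Coordinates are 1-based inclusive; strand '-' means the tag sequence matches
the reverse complement of the locus interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import pysam
from Bio import SeqIO

from .sequtils import check_dna, revcomp

DEFAULT_TAG_LENGTH = 38


@dataclass(frozen=True)
class GenomeAnchor:
    """Optional placement of a locus on a reference genome.

    `offset` is the 1-based genome coordinate of locus position 1. For strand
    '-', locus coordinates count backwards from `offset`.
    """

    chrom: str
    offset: int
    strand: str = "+"

    def to_genome(self, local: int) -> int:
        if self.strand == "+":
            return self.offset + local - 1
        return self.offset - (local - 1)


@dataclass(frozen=True)
class TargetLocus:
    """A named target sequence with its own 1-based local coordinate system."""

    name: str
    sequence: str
    genome_anchor: Optional[GenomeAnchor] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"locus {self.name!r} has empty sequence")
        check_dna(self.sequence, allow_n=True, context=f"locus {self.name!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence by 1-based inclusive coordinates."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(
                f"coordinates {start}-{end} outside locus {self.name!r} "
                f"(length {self.length})"
            )
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class MappedTag:
    """A tag placed at a unique position on one locus."""

    read_id: str
    mate: int
    locus: str
    start: int
    end: int
    strand: str
    unique: bool = True

    def __post_init__(self) -> None:
        if self.mate not in (1, 2):
            raise ValueError(f"mate must be 1 or 2, got {self.mate}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid tag interval {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def five_prime(self) -> int:
        """Locus coordinate of the tag's 5'-most base in read orientation."""
        return self.start if self.strand == "+" else self.end


class Unmapped:
    """Sentinel: no full-length match on any locus."""

    def __repr__(self) -> str:  # pragma: no cover
        return "UNMAPPED"


class MultiMapped:
    """Sentinel: more than one full-length match (discarded downstream)."""

    def __repr__(self) -> str:  # pragma: no cover
        return "MULTI"


UNMAPPED = Unmapped()
MULTI = MultiMapped()

MapResult = Union[MappedTag, Unmapped, MultiMapped]


class TagIndex:
    """Exact-match lookup over both strands of a set of loci.

    Keys are all k-mers of every locus; a key seen at more than one
    (locus, position, strand) is marked ambiguous so `map_tag` can report
    MULTI without storing every hit.
    """

    def __init__(self, loci: Iterable[TargetLocus], k: int = DEFAULT_TAG_LENGTH):
        loci = list(loci)
        if not loci:
            raise ValueError("cannot build an index over an empty locus list")
        names = [loc.name for loc in loci]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate locus names: {names}")
        if k <= 0:
            raise ValueError(f"k must be positive, got {k}")
        self.k = k
        self.loci = {loc.name: loc for loc in loci}
        # key -> (locus, start, strand) or MULTI once ambiguous
        self._table: dict[str, object] = {}
        for loc in loci:
            fwd = loc.sequence
            rev = revcomp(fwd)
            n = loc.length
            for i in range(n - k + 1):
                self._add(fwd[i : i + k], (loc.name, i + 1, "+"))
                # rev[j:j+k] is the revcomp of fwd[n-k-j : n-j]; a tag equal to
                # it maps at 1-based start n-k-j+1 on the minus strand.
                self._add(rev[i : i + k], (loc.name, n - k - i + 1, "-"))

    def _add(self, key: str, hit: tuple) -> None:
        existing = self._table.get(key)
        if existing is None:
            self._table[key] = hit
        elif existing is not MULTI and existing != hit:
            self._table[key] = MULTI

    def __len__(self) -> int:
        return len(self._table)

    def lookup(self, seq: str):
        return self._table.get(seq)


def build_index(loci: Iterable[TargetLocus], k: int = DEFAULT_TAG_LENGTH) -> TagIndex:
    """Index both strands of all loci for exact full-length tag lookup."""
    return TagIndex(loci, k)


def map_tag(
    seq: str,
    index: TagIndex,
    read_id: str = "",
    mate: int = 1,
    *,
    mismatch_rescue: bool = False,
) -> MapResult:
    """Place one tag by exact full-length match on either strand.

    Exactly one hit across all loci/strands -> MappedTag(unique=True); more
    than one -> MULTI; none -> UNMAPPED. With `mismatch_rescue`, a tag with no
    exact hit is retried at Hamming distance 1 and accepted only if the rescue
    is unambiguous (a stand-in for an external aligner's mismatch tolerance;
    off by default).
    """
    if len(seq) < index.k:
        raise ValueError(f"tag shorter than index k={index.k}: {len(seq)} bp")
    seq = seq.upper()
    check_dna(seq, allow_n=True, context=f"tag {read_id!r}")
    key = seq[: index.k]
    hit = index.lookup(key)
    if hit is None and mismatch_rescue and "N" not in key:
        hit = _rescue_one_mismatch(key, index)
    if hit is None:
        return UNMAPPED
    if hit is MULTI:
        return MULTI
    locus, start, strand = hit
    return MappedTag(
        read_id=read_id,
        mate=mate,
        locus=locus,
        start=start,
        end=start + index.k - 1,
        strand=strand,
        unique=True,
    )


def _rescue_one_mismatch(key: str, index: TagIndex):
    found = None
    for pos in range(len(key)):
        for base in "ACGT":
            if base == key[pos]:
                continue
            hit = index.lookup(key[:pos] + base + key[pos + 1 :])
            if hit is None:
                continue
            if hit is MULTI or (found is not None and hit != found):
                return MULTI
            found = hit
    return found


def scan_locus(seq: str, locus: TargetLocus) -> list[tuple[int, int, str]]:
    """Brute-force full scan of one locus, both strands.

    Independent of TagIndex; used as the mapping oracle in tests and for
    ad-hoc verification. Returns (start, end, strand) for every match.
    """
    hits = []
    k = len(seq)
    rc = revcomp(seq)
    for i in range(locus.length - k + 1):
        window = locus.sequence[i : i + k]
        if window == seq:
            hits.append((i + 1, i + k, "+"))
        if window == rc:
            hits.append((i + 1, i + k, "-"))
    return hits


# ---------------------------------------------------------------------------
# ingestion of externally produced alignments
# ---------------------------------------------------------------------------


def read_loci_fasta(path: Union[str, Path]) -> list[TargetLocus]:
    """Load target loci from FASTA (whole-record sequences, upper-cased)."""
    loci = [
        TargetLocus(name=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not loci:
        raise ValueError(f"no FASTA records in {path}")
    return loci


def ingest_alignments(
    path: Union[str, Path], loci: Iterable[TargetLocus]
) -> Iterator[MappedTag]:
    """Yield MappedTags from a SAM file or a 6-column TSV.

    TSV columns: read_id, mate, locus, start (1-based), strand, length.
    SAM records use standard flag semantics (mate from READ1/READ2, strand
    from the reverse flag); secondary/supplementary records are marked
    non-unique. Reference names must match configured locus names.
    """
    path = Path(path)
    loci_by_name = {loc.name: loc for loc in loci}
    if path.suffix.lower() == ".sam":
        yield from _ingest_sam(path, loci_by_name)
    else:
        yield from _ingest_tsv(path, loci_by_name)


def _check_reference(name: str, loci_by_name: dict, where: str) -> TargetLocus:
    locus = loci_by_name.get(name)
    if locus is None:
        raise ValueError(
            f"{where}: unknown reference {name!r}; configured loci: "
            f"{sorted(loci_by_name)}"
        )
    return locus


def _ingest_sam(path: Path, loci_by_name: dict) -> Iterator[MappedTag]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            locus = _check_reference(rec.reference_name, loci_by_name, str(path))
            length = rec.query_length or rec.infer_query_length()
            if not length:
                raise ValueError(f"{path}: record {rec.query_name!r} has no length")
            start = rec.reference_start + 1  # pysam is 0-based
            end = start + length - 1
            if end > locus.length:
                raise ValueError(
                    f"{path}: record {rec.query_name!r} maps {start}-{end}, "
                    f"beyond locus {locus.name!r} (length {locus.length})"
                )
            mate = 2 if rec.is_read2 else 1
            yield MappedTag(
                read_id=rec.query_name,
                mate=mate,
                locus=locus.name,
                start=start,
                end=end,
                strand="-" if rec.is_reverse else "+",
                unique=not (rec.is_secondary or rec.is_supplementary),
            )


def _ingest_tsv(path: Path, loci_by_name: dict) -> Iterator[MappedTag]:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            read_id, mate_s, locus_name, start_s, strand, length_s = fields
            try:
                mate, start, length = int(mate_s), int(start_s), int(length_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed integer field") from exc
            locus = _check_reference(locus_name, loci_by_name, f"{path}:{lineno}")
            end = start + length - 1
            if not (1 <= start <= end <= locus.length):
                raise ValueError(
                    f"{path}:{lineno}: interval {start}-{end} outside locus "
                    f"{locus.name!r} (length {locus.length})"
                )
            yield MappedTag(
                read_id=read_id,
                mate=mate,
                locus=locus.name,
                start=start,
                end=end,
                strand=strand,
            )
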
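"""Inline-barcode demultiplexing of paired reads.

Each sample is tagged by a 4-bp barcode carried immediately 5' of the insert
on *both* mates (the Y-shaped adapter places the barcode after the sequencing
primer on each end). A read pair is assigned to a sample when both mates'
barcodes resolve to the same sample, allowing at most a single mismatch and
only at positions where the barcode set is degenerate (i.e., where not all
barcodes share the same base); anything else is left unassigned. Ties and N
bases always resolve to unassigned, never to a sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

from .sequtils import DNA_ALPHABET, DNA_ALPHABET_N, round_half_up
from .simulate import ReadPair

BARCODE_LENGTH = 4
UNASSIGNED = "UNASSIGNED"


class BarcodeCollisionWarning(UserWarning):
    """Two barcodes are closer than Hamming distance 3."""


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences of unequal length")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class BarcodeSet:
    """The sample -> barcode table of one sequencing run.

    ``degenerate_positions`` are the 0-based barcode positions at which not
    all barcodes in the set share the same base; the single-mismatch rescue is
    restricted to these. Any pair of barcodes at Hamming distance < 3 triggers
    a warning, and rescue is additionally disabled at the positions where such
    a pair differs (a 1-mismatch there could not be attributed safely).
    """

    entries: list[tuple[str, str]]
    degenerate_positions: frozenset[int] = field(init=False)
    rescue_positions: frozenset[int] = field(init=False)

    def __post_init__(self) -> None:
        samples = [s for s, _ in self.entries]
        barcodes = [b for _, b in self.entries]
        if len(set(samples)) != len(samples):
            raise ValueError(f"duplicate sample ids: {samples}")
        if len(set(barcodes)) != len(barcodes):
            raise ValueError(f"duplicate barcodes: {barcodes}")
        for bc in barcodes:
            if len(bc) != BARCODE_LENGTH or set(bc) - DNA_ALPHABET:
                raise ValueError(
                    f"barcode must be {BARCODE_LENGTH} bases over ACGT, got {bc!r}"
                )
        degenerate = frozenset(
            pos
            for pos in range(BARCODE_LENGTH)
            if len({bc[pos] for bc in barcodes}) > 1
        )
        disabled: set[int] = set()
        for i, x in enumerate(barcodes):
            for y in barcodes[i + 1 :]:
                d = hamming(x, y)
                if d < 3:
                    warnings.warn(
                        f"barcodes {x!r} and {y!r} are only {d} mismatches "
                        "apart; single-mismatch rescue is disabled at their "
                        "differing positions",
                        BarcodeCollisionWarning,
                        stacklevel=3,
                    )
                    disabled.update(p for p in range(BARCODE_LENGTH) if x[p] != y[p])
        object.__setattr__(self, "degenerate_positions", degenerate)
        object.__setattr__(self, "rescue_positions", degenerate - disabled)

    @classmethod
    def from_tsv(cls, path) -> "BarcodeSet":
        """Load a two-column TSV: sample_id<TAB>barcode."""
        entries = []
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected sample_id<TAB>barcode"
                    )
                entries.append((fields[0], fields[1].upper()))
        return cls(entries)


def assign_barcode(
    observed: str, barcode_set: BarcodeSet, *, allow_mismatch: bool = True
) -> str:
    """Assign a 4-base observed barcode to a sample id or UNASSIGNED.

    An exact match always wins. Otherwise, if exactly one barcode in the set
    matches with a single mismatch *and* that mismatch lies at a rescue
    position, the read is assigned to it; two 1-mismatch candidates, or a
    mismatch outside the rescue positions, leave it unassigned.
    """
    if len(observed) != BARCODE_LENGTH:
        raise ValueError(
            f"observed barcode must be {BARCODE_LENGTH} bases, got {observed!r}"
        )
    bad = set(observed) - DNA_ALPHABET_N
    if bad:
        raise ValueError(f"observed barcode has non-ACGTN characters: {sorted(bad)!r}")
    if "N" in observed:
        return UNASSIGNED
    for sample, bc in barcode_set.entries:
        if observed == bc:
            return sample
    if not allow_mismatch:
        return UNASSIGNED
    candidates = []
    for sample, bc in barcode_set.entries:
        diff = [p for p in range(BARCODE_LENGTH) if observed[p] != bc[p]]
        if len(diff) == 1 and diff[0] in barcode_set.rescue_positions:
            candidates.append(sample)
    if len(candidates) == 1:
        return candidates[0]
    return UNASSIGNED


@dataclass
class DemuxReport:
    """Per-sample pair counts and percentages of the total input."""

    counts: dict[str, int]
    total: int

    def percent(self, sample: str, ndigits: int = 0) -> Optional[float]:
        if self.total == 0:
            return None
        return round_half_up(100.0 * self.counts.get(sample, 0) / self.total, ndigits)

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write("sample\tcount\tpercent\n")
            for sample, count in self.counts.items():
                pct = "NA" if self.total == 0 else f"{100.0 * count / self.total:.2f}"
                out.write(f"{sample}\t{count}\t{pct}\n")


def demultiplex(
    pairs: Iterable[ReadPair],
    barcode_set: BarcodeSet,
    *,
    allow_mismatch: bool = True,
) -> tuple[dict[str, list[ReadPair]], DemuxReport]:
    """Partition read pairs by barcode, trimming it from assigned reads.

    The barcode is read from the first 4 bases of both mates; the mates must
    agree (after the mismatch rule) or the pair goes to the UNASSIGNED stream.
    Every input pair lands in exactly one output stream. An empty barcode set
    sends everything to UNASSIGNED untrimmed, so demultiplexing its own output
    again is a no-op.
    """
    streams: dict[str, list[ReadPair]] = {
        sample: [] for sample, _ in barcode_set.entries
    }
    streams[UNASSIGNED] = []
    total = 0
    for pair in pairs:
        total += 1
        if min(len(pair.seq1), len(pair.seq2)) < BARCODE_LENGTH + 1:
            raise ValueError(
                f"read pair {pair.read_id!r} shorter than barcode + 1 base"
            )
        sample = UNASSIGNED
        if barcode_set.entries:
            s1 = assign_barcode(
                pair.seq1[:BARCODE_LENGTH], barcode_set, allow_mismatch=allow_mismatch
            )
            s2 = assign_barcode(
                pair.seq2[:BARCODE_LENGTH], barcode_set, allow_mismatch=allow_mismatch
            )
            if s1 == s2:
                sample = s1
        if sample == UNASSIGNED:
            streams[UNASSIGNED].append(pair)
        else:
            streams[sample].append(
                ReadPair(
                    pair.read_id,
                    pair.seq1[BARCODE_LENGTH:],
                    pair.seq2[BARCODE_LENGTH:],
                )
            )
    report = DemuxReport(
        counts={sample: len(reads) for sample, reads in streams.items()},
        total=total,
    )
    return streams, report


def paired_records(
    pairs1: Iterable[tuple[str, str]], pairs2: Iterable[tuple[str, str]]
) -> Iterator[ReadPair]:
    """Zip two (read_id, sequence) streams into ReadPairs, checking id sync.

    Read ids may carry /1 and /2 suffixes, which are stripped before the
    comparison; a mismatch raises an error naming the offending record.
    """
    for (id1, seq1), (id2, seq2) in zip(pairs1, pairs2):
        base1 = id1[:-2] if id1.endswith(("/1", "/2")) else id1
        base2 = id2[:-2] if id2.endswith(("/1", "/2")) else id2
        if base1 != base2:
            raise ValueError(f"read id mismatch between mates: {id1!r} vs {id2!r}")
        yield ReadPair(base1, seq1, seq2)
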
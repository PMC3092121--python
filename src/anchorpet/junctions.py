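"""Quantitative characterization of translocation junctions.

Three questions about a predicted or sequenced junction are answered here:

1. how far a predicted breakpoint interval is from the validated junction
   (`prediction_distance`, the nearest-boundary gap, 0 on overlap);
2. whether the two reciprocal junctions of a balanced translocation imply
   sequence loss (deletion), sequence shared by both derivatives
   (duplication), or a clean balanced exchange at each locus
   (`classify_reciprocal`);
3. how far the exact ligation point can slide inside a window of sequence
   shared by both parental sides — the junction microhomology
   (`microhomology`).

Validated junctions are stored as the pair of flanking coordinates printed in
breakpoint tables (e.g. "110,299-110,300"): two consecutive positions with the
break between them, which avoids committing to "break after x" versus "break
before x+1".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .sequtils import check_dna


@dataclass(frozen=True)
class JunctionPair:
    """One fusion junction, as two flanking coordinates per donor locus.

    On the 5' locus the pair is (last retained base, first lost base); on the
    3' locus it is (last lost base, first retained base). Each pair holds two
    consecutive integers.
    """

    fusion: str  # "<5' locus>-><3' locus>"
    coord_5: tuple[int, int]
    coord_3: tuple[int, int]

    def __post_init__(self) -> None:
        for label, (x, y) in (("coord_5", self.coord_5), ("coord_3", self.coord_3)):
            if y != x + 1:
                raise ValueError(
                    f"{label} must be two consecutive coordinates, got {x}-{y}"
                )

    @property
    def five_last_retained(self) -> int:
        return self.coord_5[0]

    @property
    def three_first_retained(self) -> int:
        return self.coord_3[1]


class ReciprocalClass(enum.Enum):
    BALANCED = "BALANCED"
    DELETION = "DELETION"
    DUPLICATION = "DUPLICATION"


@dataclass(frozen=True)
class ReciprocalJunctionCall:
    locus: str
    classification: ReciprocalClass
    size: int

    def __post_init__(self) -> None:
        if (self.classification is ReciprocalClass.BALANCED) != (self.size == 0):
            raise ValueError("BALANCED iff size == 0")
        if self.size < 0:
            raise ValueError("size must be >= 0")


def prediction_distance(
    prediction: tuple[int, int], actual: tuple[int, int]
) -> int:
    """Distance in bp from a predicted interval to a validated junction.

    ``prediction`` is the called interval [a, b] (1-based inclusive) and
    ``actual`` the validated flanking pair (x, x+1), both on the same locus
    and coordinate system. Returns 0 when they overlap, otherwise the gap
    between the nearest predicted boundary and the nearest actual coordinate
    (x - b when the junction is downstream of the interval, a - (x + 1) when
    upstream); never negative.
    """
    a, b = prediction
    if a > b:
        raise ValueError(f"malformed prediction interval [{a}, {b}]")
    x, x1 = actual
    if x1 != x + 1:
        raise ValueError(f"actual junction must be (x, x+1), got ({x}, {x1})")
    if x1 >= a and x <= b:
        return 0
    if x > b:
        return x - b
    return a - x1


def classify_reciprocal(
    j_ab: JunctionPair,
    j_ba: JunctionPair,
    locus_lengths: Optional[tuple[int, int]] = None,
) -> tuple[ReciprocalJunctionCall, ReciprocalJunctionCall]:
    """Classify what each locus lost or duplicated across a reciprocal pair.

    ``j_ab`` is the A->B fusion junction (locus A supplies the 5' side) and
    ``j_ba`` the reciprocal B->A junction. For locus A, let c1 be the last A
    base retained in A->B and c2 the first A base retained in B->A:

    * c2 == c1 + 1  -> BALANCED (clean exchange),
    * c2 >  c1 + 1  -> DELETION of c2 - c1 - 1 bases (in neither derivative),
    * c2 <= c1      -> DUPLICATION of c1 - c2 + 1 bases (in both derivatives).

    Locus B is symmetric with the retained sides swapped. Returns the calls
    for (locus A, locus B).
    """
    locus_a, _, locus_b = j_ab.fusion.partition("->")
    rev_b, _, rev_a = j_ba.fusion.partition("->")
    if (locus_a, locus_b) != (rev_a, rev_b):
        raise ValueError(
            f"junctions are not reciprocal: {j_ab.fusion!r} vs {j_ba.fusion!r}"
        )
    c1 = j_ab.five_last_retained  # last A base in A->B
    c2 = j_ba.three_first_retained  # first A base in B->A
    d1 = j_ab.three_first_retained  # first B base in A->B
    d2 = j_ba.five_last_retained  # last B base in B->A
    if locus_lengths is not None:
        len_a, len_b = locus_lengths
        for coord, length, locus in ((c1, len_a, locus_a), (c2, len_a, locus_a),
                                     (d1, len_b, locus_b), (d2, len_b, locus_b)):
            if not 1 <= coord <= length:
                raise ValueError(
                    f"coordinate {coord} outside locus {locus!r} (length {length})"
                )
    return (
        _classify_one(locus_a, last_retained_5=c1, first_retained_3=c2),
        _classify_one(locus_b, last_retained_5=d2, first_retained_3=d1),
    )


def _classify_one(
    locus: str, *, last_retained_5: int, first_retained_3: int
) -> ReciprocalJunctionCall:
    if first_retained_3 == last_retained_5 + 1:
        return ReciprocalJunctionCall(locus, ReciprocalClass.BALANCED, 0)
    if first_retained_3 > last_retained_5 + 1:
        return ReciprocalJunctionCall(
            locus, ReciprocalClass.DELETION, first_retained_3 - last_retained_5 - 1
        )
    return ReciprocalJunctionCall(
        locus, ReciprocalClass.DUPLICATION, last_retained_5 - first_retained_3 + 1
    )


@dataclass(frozen=True)
class MicrohomologyResult:
    length: int
    sequence: str
    degenerate: bool = False  # homology spans an entire input side


def microhomology(
    seq_5: str,
    seq_3: str,
    break_5: Optional[int] = None,
    break_3: Optional[int] = None,
) -> MicrohomologyResult:
    """Length and sequence of the homologous window around a fusion junction.

    ``seq_5`` is sequence from the 5' donor with the break after position
    ``break_5`` (1-based; default: after its last base) and ``seq_3`` sequence
    from the 3' donor with the break before position ``break_3`` (default:
    before its first base). The junction can slide left by i when the last i
    retained bases of the 5' donor equal the i bases immediately 5' of the 3'
    donor's retained segment, and right by j symmetrically; the microhomology
    is the maximal such window (length i_max + j_max), the region within which
    the actual ligation point cannot be resolved. Returns length 0 when the
    junction is unambiguous.
    """
    check_dna(seq_5.upper(), allow_n=True, context="seq_5")
    check_dna(seq_3.upper(), allow_n=True, context="seq_3")
    seq_5, seq_3 = seq_5.upper(), seq_3.upper()
    if break_5 is None:
        break_5 = len(seq_5)
    if break_3 is None:
        break_3 = 1
    if not 0 <= break_5 <= len(seq_5):
        raise ValueError(f"break_5={break_5} outside seq_5 (length {len(seq_5)})")
    if not 1 <= break_3 <= len(seq_3) + 1:
        raise ValueError(f"break_3={break_3} outside seq_3 (length {len(seq_3)})")

    # slide left: seq_5[break_5 - i] must equal seq_3[break_3 - 1 - i] (both
    # 1-based), for i = 1, 2, ...
    left = 0
    while (
        break_5 - left >= 1
        and break_3 - 1 - left >= 1
        and seq_5[break_5 - left - 1] == seq_3[break_3 - left - 2]
    ):
        left += 1
    # slide right: seq_3[break_3 + j] must equal seq_5[break_5 + 1 + j]
    right = 0
    while (
        break_5 + right + 1 <= len(seq_5)
        and break_3 + right <= len(seq_3)
        and seq_5[break_5 + right] == seq_3[break_3 + right - 1]
    ):
        right += 1
    length = left + right
    sequence = seq_5[break_5 - left : break_5 + right]
    degenerate = length >= min(len(seq_5), len(seq_3))
    return MicrohomologyResult(length, sequence, degenerate)


def junction_microhomology(
    locus_5, locus_3, last_retained_5: int, first_retained_3: int
) -> MicrohomologyResult:
    """Microhomology of a junction given the two donor loci.

    ``locus_5`` supplies the fusion up to ``last_retained_5`` and ``locus_3``
    from ``first_retained_3`` on (both TargetLocus). The full donor sequences
    provide the context on both sides of the nominal junction, so the window
    can extend in either direction.
    """
    return microhomology(
        locus_5.sequence,
        locus_3.sequence,
        break_5=last_retained_5,
        break_3=first_retained_3,
    )
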
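"""Pairing mapped tags into chromPETs, classification, fragment-length model.

A chromPET is the pair of end tags of one sheared fragment. A pair whose tags
map uniquely to the *same* locus in forward/reverse orientation (the + tag
upstream) is a normal chromPET and yields a fragment-length observation; a
pair whose tags map uniquely to *different* loci is a junctional chromPET and
is the evidence used for breakpoint localization. Pairs with a missing,
multi-mapping, or orientation-inconsistent tag are discarded.

The normal chromPETs of all samples in a run are pooled to estimate the mean
and standard deviation of the fragment length; those two numbers set the
geometry of the breakpoint voting zones.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .align import MapResult, MappedTag
from .sequtils import round_half_up


class PetClass(enum.Enum):
    NORMAL = "NORMAL"
    JUNCTIONAL = "JUNCTIONAL"
    DISCARDED = "DISCARDED"


@dataclass(frozen=True)
class ChromPET:
    read_id: str
    tag1: Optional[MappedTag]
    tag2: Optional[MappedTag]
    sample_id: str
    klass: PetClass
    fragment_length: Optional[int] = None  # NORMAL only

    def tag_on(self, locus: str) -> Optional[MappedTag]:
        for tag in (self.tag1, self.tag2):
            if tag is not None and tag.locus == locus:
                return tag
        return None


def classify_pet(tag1: MappedTag, tag2: MappedTag) -> tuple[PetClass, Optional[int]]:
    """Classify a fully mapped pair; returns (class, fragment_length).

    Cross-locus pairs are junctional regardless of orientation. Same-locus
    pairs must be forward/reverse with the + tag upstream (FR) to count as
    normal; everted or same-strand pairs are discarded so they cannot corrupt
    the fragment-length model.
    """
    if tag1.locus != tag2.locus:
        return PetClass.JUNCTIONAL, None
    if tag1.strand == tag2.strand:
        return PetClass.DISCARDED, None
    plus, minus = (tag1, tag2) if tag1.strand == "+" else (tag2, tag1)
    if plus.start > minus.start:
        return PetClass.DISCARDED, None
    length = max(tag1.end, tag2.end) - min(tag1.start, tag2.start) + 1
    return PetClass.NORMAL, length


def pair_tags(
    results: Iterable[tuple[str, int, MapResult]],
    sample_id: str = "",
) -> list[ChromPET]:
    """Build exactly one ChromPET per read id from per-mate mapping results.

    `results` yields (read_id, mate, MapResult) where the result may be a
    MappedTag, UNMAPPED, or MULTI. A read id with a missing, unmapped, or
    multi-mapping mate is DISCARDED; three results for one read id is an
    input error.
    """
    by_read: dict[str, list] = {}
    order: list[str] = []
    for read_id, mate, result in results:
        slots = by_read.get(read_id)
        if slots is None:
            slots = [None, None]
            by_read[read_id] = slots
            order.append(read_id)
        if mate not in (1, 2):
            raise ValueError(f"read {read_id!r}: mate must be 1 or 2, got {mate}")
        if slots[mate - 1] is not None:
            raise ValueError(f"read {read_id!r}: more than one result for mate {mate}")
        slots[mate - 1] = result

    pets = []
    for read_id in order:
        r1, r2 = by_read[read_id]
        t1 = r1 if isinstance(r1, MappedTag) else None
        t2 = r2 if isinstance(r2, MappedTag) else None
        if t1 is None or t2 is None or not (t1.unique and t2.unique):
            pets.append(ChromPET(read_id, t1, t2, sample_id, PetClass.DISCARDED))
            continue
        klass, length = classify_pet(t1, t2)
        pets.append(ChromPET(read_id, t1, t2, sample_id, klass, length))
    return pets


@dataclass(frozen=True)
class FragmentLengthModel:
    """Mean and SD of the sheared-fragment length, in bp.

    Both are rounded to the nearest integer because they directly define the
    integer vote-zone widths on the locus coordinate grid.
    """

    mean: int
    sd: int
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


class InsufficientNormalPets(ValueError):
    """Too few normal chromPETs to estimate the fragment model.

    Configure a fallback FragmentLengthModel (e.g. from the size-selection
    target of the library prep) when a run cannot supply one.
    """


def estimate_fragment_model(
    normal_pets: Iterable[ChromPET],
    *,
    outlier_sd_mult: float = 10.0,
) -> FragmentLengthModel:
    """Estimate the fragment-length model from pooled normal chromPETs.

    Mean is the arithmetic mean, SD the sample standard deviation (n-1
    denominator), both rounded half-up to integer bp. Same-locus pairs with
    implausible spans (> mean + `outlier_sd_mult` * sd of the initial fit)
    are excluded and the model refit once — a guard against chimeric
    fragments; they are excluded from estimation only, not from pairing.
    """
    lengths = np.array(
        [
            pet.fragment_length
            for pet in normal_pets
            if pet.klass is PetClass.NORMAL and pet.fragment_length is not None
        ],
        dtype=float,
    )
    if lengths.size < 2:
        raise InsufficientNormalPets(
            f"need >= 2 normal chromPETs to estimate the fragment model, got "
            f"{lengths.size}; supply a configured fallback model instead"
        )
    mean, sd = lengths.mean(), lengths.std(ddof=1)
    kept = lengths[lengths <= mean + outlier_sd_mult * sd]
    if 2 <= kept.size < lengths.size:
        mean, sd = kept.mean(), kept.std(ddof=1)
        lengths = kept
    return FragmentLengthModel(
        mean=int(round_half_up(mean)),
        sd=int(round_half_up(sd)),
        n=int(lengths.size),
    )


@dataclass(frozen=True)
class SampleSummary:
    """Run-report row for one sample, mirroring the standard count table.

    ``total_anchored`` counts NORMAL + JUNCTIONAL chromPETs;
    ``unique_pairs`` additionally includes same-locus pairs rejected by the
    orientation filter (both numbers are reported because published count
    tables do not state which definition they use).
    """

    sample_id: str
    barcoded_reads: int
    mapped_tags: tuple[int, int]
    unique_tags: tuple[int, int]
    unique_pairs: int
    total_anchored: int
    junctional: int

    @property
    def percent_breakpoint(self) -> Optional[float]:
        """100 * junctional / total anchored, one decimal; None if no anchors."""
        if self.total_anchored == 0:
            return None
        return round_half_up(100.0 * self.junctional / self.total_anchored, 1)

    @property
    def apparent_sensitivity(self) -> Optional[float]:
        """100 * junctional / barcoded reads, two decimals."""
        if self.barcoded_reads == 0:
            return None
        return round_half_up(100.0 * self.junctional / self.barcoded_reads, 2)

    def barcode_fraction(self, total_reads: int) -> Optional[float]:
        """Percent of the run's read pairs assigned to this sample (integer)."""
        if total_reads == 0:
            return None
        return round_half_up(100.0 * self.barcoded_reads / total_reads)


def summarize_sample(
    sample_id: str,
    pets: Sequence[ChromPET],
    barcoded_reads: int,
    mapped_tags: tuple[int, int] = (0, 0),
    unique_tags: tuple[int, int] = (0, 0),
) -> SampleSummary:
    normal = sum(1 for p in pets if p.klass is PetClass.NORMAL)
    junctional = sum(1 for p in pets if p.klass is PetClass.JUNCTIONAL)
    unique_pairs = sum(
        1
        for p in pets
        if p.tag1 is not None
        and p.tag2 is not None
        and p.tag1.unique
        and p.tag2.unique
    )
    return SampleSummary(
        sample_id=sample_id,
        barcoded_reads=barcoded_reads,
        mapped_tags=mapped_tags,
        unique_tags=unique_tags,
        unique_pairs=unique_pairs,
        total_anchored=normal + junctional,
        junctional=junctional,
    )


def summarize_counts(
    pets_by_sample: Mapping[str, Sequence[ChromPET]],
    barcoded_by_sample: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Per-sample count table (one row per sample, table-style percentages)."""
    rows = []
    for sample_id, pets in pets_by_sample.items():
        barcoded = (barcoded_by_sample or {}).get(sample_id, len(pets))
        summary = summarize_sample(sample_id, list(pets), barcoded)
        rows.append(
            {
                "sample": sample_id,
                "barcoded_reads": summary.barcoded_reads,
                "unique_pairs": summary.unique_pairs,
                "total_anchored": summary.total_anchored,
                "junctional": summary.junctional,
                "percent_breakpoint": (
                    np.nan
                    if summary.percent_breakpoint is None
                    else summary.percent_breakpoint
                ),
                "apparent_sensitivity": (
                    np.nan
                    if summary.apparent_sensitivity is None
                    else summary.apparent_sensitivity
                ),
            }
        )
    return pd.DataFrame(rows)
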
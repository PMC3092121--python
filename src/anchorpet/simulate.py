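"""Synthetic data generator: loci, derivative chromosomes, barcoded read pairs.

The generator emulates the structure of a targeted paired-end-tag (chromPET)
sequencing run over two loci — a small breakpoint-cluster-region-like locus
("locus A", default 7 kb) and a large partner-gene-like locus ("locus B",
default 175 kb) — carrying one reciprocal translocation. Sheared ~0.5-kb
fragments are sampled from the intact loci and/or from the two derivative
chromosomes, and each fragment is reported as a barcoded 38-bp read pair, so
that every downstream stage (demultiplexing, mapping, pairing, vote-based
breakpoint localization, reciprocal-junction arithmetic) can be tested against
a known truth record.

The two reciprocal junctions can be planted balanced, with a deletion (bases
present in neither derivative), or with a duplication (bases present in both),
and with a forced microhomology of configurable length across each junction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .align import TargetLocus
from .sequtils import DNA_ALPHABET, check_dna, random_dna, revcomp

MAX_FRAGMENT_RETRIES = 1000


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulated sample.

    Junctions fall *between* ``breakpoint_x`` and ``breakpoint_x + 1`` on each
    locus. ``del_x``/``dup_x`` bases are lost from, or duplicated between, the
    two derivatives at the reciprocal junctions of locus x (at most one of the
    two may be nonzero per locus). ``microhomology_len`` bases on each side of
    each junction are forced identical between the donor loci.
    """

    locus_lengths: tuple[int, int] = (7_000, 175_000)
    locus_names: tuple[str, str] = ("locusA", "locusB")
    breakpoint_a: int = 3_000
    breakpoint_b: int = 90_000
    frag_mean: int = 500
    frag_sd: int = 50
    read_len: int = 38
    n_pairs: int = 2_000
    tumor_fraction: float = 1.0
    barcode: str = "ACGT"
    sample_id: str = "sample1"
    microhomology_len: int = 0
    del_a: int = 0
    del_b: int = 0
    dup_a: int = 0
    dup_b: int = 0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        len_a, len_b = self.locus_lengths
        if len_a <= 0 or len_b <= 0:
            raise ConfigurationError(
                f"locus lengths must be positive, got {self.locus_lengths}"
            )
        if self.frag_mean <= self.read_len:
            raise ConfigurationError(
                f"frag_mean ({self.frag_mean}) must exceed read_len ({self.read_len})"
            )
        if self.frag_sd < 0:
            raise ConfigurationError("frag_sd must be >= 0")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ConfigurationError(
                f"tumor_fraction must be in [0, 1], got {self.tumor_fraction}"
            )
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigurationError("error_rate must be in [0, 1)")
        if len(self.barcode) != 4 or set(self.barcode) - DNA_ALPHABET:
            raise ConfigurationError(
                f"barcode must be 4 bases over ACGT, got {self.barcode!r}"
            )
        for name, d, p in (("a", self.del_a, self.dup_a), ("b", self.del_b, self.dup_b)):
            if d < 0 or p < 0:
                raise ConfigurationError(f"del_{name}/dup_{name} must be >= 0")
            if d > 0 and p > 0:
                raise ConfigurationError(
                    f"at most one of del_{name}/dup_{name} may be nonzero"
                )
        if self.microhomology_len < 0:
            raise ConfigurationError("microhomology_len must be >= 0")
        m = self.microhomology_len
        # breakpoints strictly inside the loci, with room for del/dup and the
        # planted homology windows on both sides of each junction
        for label, bp, length, dele, dup in (
            ("a", self.breakpoint_a, len_a, self.del_a, self.dup_a),
            ("b", self.breakpoint_b, len_b, self.del_b, self.dup_b),
        ):
            lo = max(m + 1, dup + m + 1)
            hi = length - 1 - dele - m
            if not lo <= bp <= hi:
                raise ConfigurationError(
                    f"breakpoint_{label}={bp} leaves no room inside locus "
                    f"(length {length}, del={dele}, dup={dup}, homology={m}); "
                    f"need {lo} <= breakpoint <= {hi}"
                )

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("locus_lengths", "locus_names"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass(frozen=True)
class JunctionTruth:
    """One planted junction, stored as the flanking coordinates on each donor.

    ``five_locus`` supplies the 5' side of the fusion up to and including
    ``five_last_retained``; ``three_locus`` supplies everything from
    ``three_first_retained`` on.
    """

    five_locus: str
    five_last_retained: int
    three_locus: str
    three_first_retained: int


@dataclass(frozen=True)
class TranslocationTruth:
    """Complete description of the planted reciprocal translocation."""

    junction_ab: JunctionTruth  # derivative 1: locusA 5' + locusB 3'
    junction_ba: JunctionTruth  # derivative 2: locusB 5' + locusA 3'
    del_a: int
    del_b: int
    dup_a: int
    dup_b: int
    microhomology_len: int
    microhomology_seq: str
    der1_junction: int  # junction between this derivative position and +1
    der2_junction: int

    def retained_intervals(self, locus_index: int) -> tuple[tuple[int, int], ...]:
        """1-based inclusive intervals of this locus retained in (der1, der2)."""
        if locus_index == 0:
            return (
                (1, self.junction_ab.five_last_retained),
                (self.junction_ba.three_first_retained, -1),
            )
        return (
            (self.junction_ab.three_first_retained, -1),
            (1, self.junction_ba.five_last_retained),
        )


@dataclass(frozen=True)
class FragmentTruth:
    """Provenance of one simulated fragment / read pair."""

    read_id: str
    sample_id: str
    source: str  # locus or derivative name
    start: int  # 1-based inclusive, source coordinates
    end: int
    spans_junction: bool


@dataclass
class SimulatedSample:
    config: SimulationConfig
    loci: list[TargetLocus]
    derivatives: list[TargetLocus]
    truth: TranslocationTruth
    pairs: list  # list[ReadPair]
    fragments: list[FragmentTruth]


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    seq2: str


def make_reference(
    config: SimulationConfig, seed: Optional[int] = None
) -> list[TargetLocus]:
    """Two uniformly random DNA loci of the configured lengths.

    Deterministic for a fixed seed (defaults to ``config.seed``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return [
        TargetLocus(name=name, sequence=random_dna(length, rng))
        for name, length in zip(config.locus_names, config.locus_lengths)
    ]


def plant_translocation(
    loci: list[TargetLocus], config: SimulationConfig
) -> tuple[list[TargetLocus], list[TargetLocus], TranslocationTruth]:
    """Build the two derivative chromosomes of a reciprocal translocation.

    Returns ``(loci, derivatives, truth)``. When a microhomology is requested
    the donor loci themselves are rewritten around the junctions (the planted
    homology is real sequence shared by both donors), so downstream mapping
    must use the returned loci, not the originals.

    Coordinate scheme, with a = breakpoint_a, b = breakpoint_b:

    * derivative 1 = A[1..a1] + B[b2..lenB]
    * derivative 2 = B[1..b1] + A[a2..lenA]

    where a1 = a and a2 = a + del_a + 1 (deletion: del_a bases of A in neither
    derivative) or a2 = a - dup_a + 1 (duplication: dup_a bases of A in both);
    b1/b2 symmetric on locus B.
    """
    if len(loci) != 2:
        raise ConfigurationError(f"expected exactly two loci, got {len(loci)}")
    locus_a, locus_b = loci
    a1 = config.breakpoint_a
    b1 = config.breakpoint_b
    a2 = a1 + config.del_a + 1 if config.dup_a == 0 else a1 - config.dup_a + 1
    b2 = b1 + config.del_b + 1 if config.dup_b == 0 else b1 - config.dup_b + 1

    seq_a, seq_b = locus_a.sequence, locus_b.sequence
    m = config.microhomology_len
    homology = ""
    if m > 0:
        seq_a, seq_b, homology = _plant_microhomology(seq_a, seq_b, a1, a2, b1, b2, m, config)
        locus_a = TargetLocus(locus_a.name, seq_a, locus_a.genome_anchor)
        locus_b = TargetLocus(locus_b.name, seq_b, locus_b.genome_anchor)

    der1_seq = seq_a[:a1] + seq_b[b2 - 1 :]
    der2_seq = seq_b[:b1] + seq_a[a2 - 1 :]
    truth = TranslocationTruth(
        junction_ab=JunctionTruth(locus_a.name, a1, locus_b.name, b2),
        junction_ba=JunctionTruth(locus_b.name, b1, locus_a.name, a2),
        del_a=config.del_a,
        del_b=config.del_b,
        dup_a=config.dup_a,
        dup_b=config.dup_b,
        microhomology_len=m,
        microhomology_seq=homology,
        der1_junction=a1,
        der2_junction=b1,
    )
    derivatives = [
        TargetLocus(name="der1", sequence=der1_seq),
        TargetLocus(name="der2", sequence=der2_seq),
    ]
    return [locus_a, locus_b], derivatives, truth


def _plant_microhomology(
    seq_a: str,
    seq_b: str,
    a1: int,
    a2: int,
    b1: int,
    b2: int,
    m: int,
    config: SimulationConfig,
) -> tuple[str, str, str]:
    """Force identical m-mers across both junctions, then pin the boundaries.

    One shared m-mer is written at the four flank sites (last m retained bases
    of each 5' donor segment and the m bases immediately 5' of each retained
    3' segment), so each junction carries exactly the same homologous window.
    The bases immediately outside each window are then forced to *differ*
    between donors so the detected homology is exactly m, never longer.
    """
    rng = np.random.default_rng(config.seed + 7)
    motif = random_dna(m, rng)
    a = np.frombuffer(seq_a.encode(), dtype="S1").copy()
    b = np.frombuffer(seq_b.encode(), dtype="S1").copy()

    # (array, 1-based start, 1-based end) for the four homology sites
    sites = [
        (a, a1 - m + 1, a1),  # 5' donor of junction A->B
        (b, b2 - m, b2 - 1),  # 3' donor context of junction A->B
        (b, b1 - m + 1, b1),  # 5' donor of junction B->A
        (a, a2 - m, a2 - 1),  # 3' donor context of junction B->A
    ]
    for arr, start, end in sites:
        if start < 1 or end > len(arr):
            raise ConfigurationError(
                "microhomology window falls outside a locus; move the "
                "breakpoints inward"
            )
    # overlapping sites on the same array must coincide exactly, otherwise the
    # two junctions would demand conflicting sequence
    for arr, start, end in sites:
        for (other_arr, other_start, other_end) in sites:
            if arr is other_arr and start != other_start:
                if max(start, other_start) <= min(end, other_end):
                    raise ConfigurationError(
                        "microhomology windows of the two junctions overlap "
                        "at different offsets; increase the del/dup size or "
                        "reduce microhomology_len"
                    )
    for arr, start, end in sites:
        arr[start - 1 : end] = np.frombuffer(motif.encode(), dtype="S1")

    # boundary pins: each pair of positions must hold different bases so the
    # homology cannot extend past the planted window
    constraints = [
        ((a, a1 - m), (b, b2 - m - 1)),  # left extension of junction A->B
        ((a, a1 + 1), (b, b2)),  # right extension of junction A->B
        ((b, b1 - m), (a, a2 - m - 1)),  # left extension of junction B->A
        ((b, b1 + 1), (a, a2)),  # right extension of junction B->A
    ]
    site_positions = {
        (id(arr), pos) for arr, start, end in sites for pos in range(start, end + 1)
    }
    for (arr_x, x), (arr_y, y) in constraints:
        for arr, pos in ((arr_x, x), (arr_y, y)):
            if not 1 <= pos <= len(arr):
                raise ConfigurationError(
                    "microhomology boundary falls outside a locus; move the "
                    "breakpoints inward"
                )
            if (id(arr), pos) in site_positions:
                raise ConfigurationError(
                    "microhomology boundary overlaps a homology window; "
                    "increase the del/dup size or reduce microhomology_len"
                )
    # neighbour map, then one greedy pass (each position avoids all partners;
    # later assignments see earlier ones, so a single ordered pass suffices)
    neighbours: dict[tuple[int, int], list[tuple]] = {}
    arrays = {id(a): a, id(b): b}
    for (arr_x, x), (arr_y, y) in constraints:
        neighbours.setdefault((id(arr_x), x), []).append((id(arr_y), y))
        neighbours.setdefault((id(arr_y), y), []).append((id(arr_x), x))
    for key in sorted(neighbours):
        arr_id, pos = key
        arr = arrays[arr_id]
        taken = {arrays[nid][npos - 1] for nid, npos in neighbours[key]}
        if arr[pos - 1] in taken:
            for base in (b"A", b"C", b"G", b"T"):
                if base not in taken:
                    arr[pos - 1] = base
                    break
    return a.tobytes().decode(), b.tobytes().decode(), motif


def simulate_pets(
    loci: list[TargetLocus],
    derivatives: list[TargetLocus],
    config: SimulationConfig,
    truth: Optional[TranslocationTruth] = None,
    seed: Optional[int] = None,
) -> tuple[list[ReadPair], list[FragmentTruth]]:
    """Sample `n_pairs` sheared fragments and report their barcoded read pairs.

    Each fragment comes from a derivative chromosome with probability
    ``tumor_fraction`` and from an intact locus otherwise; within each
    category the source is chosen proportional to its length (uniform
    shearing of equimolar molecules). Fragment length is Normal(frag_mean,
    frag_sd) rounded to the nearest bp and resampled until it fits in
    [2*read_len, source length]; the fragment start is uniform. Read 1 is the
    first ``read_len`` bases of the fragment, read 2 the reverse complement of
    the last ``read_len``, and both are prefixed with the sample barcode.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    junction_by_source = {}
    if truth is not None:
        junction_by_source = {"der1": truth.der1_junction, "der2": truth.der2_junction}

    tumor_sources = derivatives if config.tumor_fraction > 0 else []
    normal_sources = loci
    tumor_lengths = np.array([s.length for s in tumor_sources], dtype=float)
    normal_lengths = np.array([s.length for s in normal_sources], dtype=float)

    pairs: list[ReadPair] = []
    fragments: list[FragmentTruth] = []
    rl = config.read_len
    for i in range(config.n_pairs):
        if tumor_sources and rng.random() < config.tumor_fraction:
            pool, weights = tumor_sources, tumor_lengths
        else:
            pool, weights = normal_sources, normal_lengths
        source = pool[rng.choice(len(pool), p=weights / weights.sum())]
        length = _draw_fragment_length(rng, config, source.length)
        start = int(rng.integers(1, source.length - length + 2))
        end = start + length - 1
        frag = source.fetch(start, end)
        read1 = frag[:rl]
        read2 = revcomp(frag[-rl:])
        if config.error_rate > 0:
            read1 = _mutate(read1, config.error_rate, rng)
            read2 = _mutate(read2, config.error_rate, rng)
        read_id = f"{config.sample_id}.frag{i:06d}"
        pairs.append(
            ReadPair(read_id, config.barcode + read1, config.barcode + read2)
        )
        junction = junction_by_source.get(source.name)
        spans = junction is not None and start <= junction < end
        fragments.append(
            FragmentTruth(read_id, config.sample_id, source.name, start, end, spans)
        )
    return pairs, fragments


def _draw_fragment_length(
    rng: np.random.Generator, config: SimulationConfig, source_length: int
) -> int:
    lo = 2 * config.read_len
    if source_length < lo:
        raise ConfigurationError(
            f"source of length {source_length} cannot hold a fragment of "
            f">= {lo} bp"
        )
    for _ in range(MAX_FRAGMENT_RETRIES):
        length = int(round(rng.normal(config.frag_mean, config.frag_sd)))
        if lo <= length <= source_length:
            return length
    raise ConfigurationError(
        f"could not draw a fragment length in [{lo}, {source_length}] after "
        f"{MAX_FRAGMENT_RETRIES} tries (frag_mean={config.frag_mean}, "
        f"frag_sd={config.frag_sd})"
    )


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        current = arr[i]
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != current]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def simulate_sample(
    config: SimulationConfig, seed: Optional[int] = None
) -> SimulatedSample:
    """Full single-sample simulation: reference, translocation, read pairs."""
    if seed is not None:
        config = replace(config, seed=seed)
    loci = make_reference(config)
    loci, derivatives, truth = plant_translocation(loci, config)
    pairs, fragments = simulate_pets(loci, derivatives, config, truth)
    return SimulatedSample(config, loci, derivatives, truth, pairs, fragments)
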
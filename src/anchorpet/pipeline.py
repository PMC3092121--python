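"""End-to-end orchestration: demultiplex -> map -> pair -> vote -> report.

`analyze_run` is the in-memory core used by tests and simulations;
`run_pipeline` wraps it with file input/output and writes the standard
artifact set (per-sample count summary, per-orientation predictions, vote
profiles as bedGraph, primer-target BED). `mix_samples` interleaves reads
from several simulated samples at given fractions to emulate multiplexed
lanes and dilution series.

Everything here is deterministic given its inputs (and the seed, where one
applies), so re-running a configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from . import io as apio
from .align import (
    MULTI,
    MappedTag,
    TargetLocus,
    build_index,
    ingest_alignments,
    map_tag,
)
from .breakpoints import (
    BreakpointPrediction,
    CallStatus,
    CallThresholds,
    predict_all,
    vote_profiles,
)
from .demux import UNASSIGNED, BarcodeSet, demultiplex
from .petcall import (
    ChromPET,
    FragmentLengthModel,
    InsufficientNormalPets,
    PetClass,
    estimate_fragment_model,
    pair_tags,
    summarize_counts,
)
from .simulate import ReadPair, SimulatedSample, SimulationConfig, simulate_sample

logger = logging.getLogger("anchorpet")

DEFAULT_PRIMER_FLANK = 500


@dataclass
class RunConfig:
    """File-level configuration of one pipeline run."""

    loci_fasta: Union[str, Path]
    barcodes_tsv: Optional[Union[str, Path]] = None
    fastq1: Optional[Union[str, Path]] = None
    fastq2: Optional[Union[str, Path]] = None
    alignments: Optional[Union[str, Path]] = None
    output_dir: Union[str, Path] = "anchorpet_out"
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    fallback_model: Optional[FragmentLengthModel] = None
    primer_flank: int = DEFAULT_PRIMER_FLANK
    mismatch_rescue: bool = False
    allow_barcode_mismatch: bool = True

    def __post_init__(self) -> None:
        if self.primer_flank < 0:
            raise ValueError("primer_flank must be >= 0")
        have_fastq = self.fastq1 is not None and self.fastq2 is not None
        if not have_fastq and self.alignments is None:
            raise ValueError("need either a FASTQ pair or an alignment file")
        for path in (self.loci_fasta, self.barcodes_tsv, self.fastq1, self.fastq2,
                     self.alignments):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input file not found: {path}")


@dataclass
class RunResult:
    """Everything a run produced, in memory."""

    loci: list[TargetLocus]
    demux_counts: dict[str, int]
    total_pairs: int
    pets_by_sample: dict[str, list[ChromPET]]
    mapped_by_sample: dict[str, tuple[int, int]]
    unique_by_sample: dict[str, tuple[int, int]]
    model: FragmentLengthModel
    model_source: str  # "estimated" or "fallback"
    predictions: dict[str, dict[str, dict[str, BreakpointPrediction]]]
    # predictions[sample][orientation][locus]

    def summary_table(self):
        barcoded = {s: self.demux_counts.get(s, 0) for s in self.pets_by_sample}
        return summarize_counts(self.pets_by_sample, barcoded)

    def called(self, sample: str) -> list[BreakpointPrediction]:
        return [
            pred
            for by_locus in self.predictions.get(sample, {}).values()
            for pred in by_locus.values()
            if pred.status is CallStatus.CALLED
        ]


def map_pairs(
    pairs: Iterable[ReadPair], index, *, mismatch_rescue: bool = False
) -> tuple[list, tuple[int, int], tuple[int, int]]:
    """Map both mates of every pair; returns (results, mapped, unique) counts."""
    results = []
    mapped = [0, 0]
    unique = [0, 0]
    for pair in pairs:
        for mate, seq in ((1, pair.seq1), (2, pair.seq2)):
            res = map_tag(
                seq, index, pair.read_id, mate, mismatch_rescue=mismatch_rescue
            )
            results.append((pair.read_id, mate, res))
            if isinstance(res, MappedTag):
                mapped[mate - 1] += 1
                unique[mate - 1] += 1
            elif res is MULTI:
                # MULTI counts as mapped but not unique; UNMAPPED as neither
                mapped[mate - 1] += 1
    return results, (mapped[0], mapped[1]), (unique[0], unique[1])


def analyze_run(
    pairs: Iterable[ReadPair],
    loci: Sequence[TargetLocus],
    barcode_set: BarcodeSet,
    thresholds: CallThresholds = CallThresholds(),
    *,
    fallback_model: Optional[FragmentLengthModel] = None,
    mismatch_rescue: bool = False,
    allow_barcode_mismatch: bool = True,
) -> RunResult:
    """The full in-memory pipeline on an iterable of raw (barcoded) pairs.

    The fragment-length model is estimated from the normal chromPETs pooled
    across all samples of the run; `fallback_model` is used when fewer than
    two are available.
    """
    streams, report = demultiplex(
        pairs, barcode_set, allow_mismatch=allow_barcode_mismatch
    )
    logger.info("demultiplexed %d pairs: %s", report.total, report.counts)
    index = build_index(loci)
    pets_by_sample: dict[str, list[ChromPET]] = {}
    mapped_by_sample: dict[str, tuple[int, int]] = {}
    unique_by_sample: dict[str, tuple[int, int]] = {}
    for sample, sample_pairs in streams.items():
        if sample == UNASSIGNED:
            continue
        results, mapped, unique = map_pairs(
            sample_pairs, index, mismatch_rescue=mismatch_rescue
        )
        pets = pair_tags(results, sample)
        pets_by_sample[sample] = pets
        mapped_by_sample[sample] = mapped
        unique_by_sample[sample] = unique
        logger.info(
            "sample %s: %d pairs, %d normal, %d junctional",
            sample,
            len(sample_pairs),
            sum(p.klass is PetClass.NORMAL for p in pets),
            sum(p.klass is PetClass.JUNCTIONAL for p in pets),
        )
    all_normal = [
        pet
        for pets in pets_by_sample.values()
        for pet in pets
        if pet.klass is PetClass.NORMAL
    ]
    try:
        model = estimate_fragment_model(all_normal)
        model_source = "estimated"
    except InsufficientNormalPets:
        if fallback_model is None:
            raise
        model, model_source = fallback_model, "fallback"
    logger.info(
        "fragment model: mean=%d sd=%d n=%d (%s)",
        model.mean, model.sd, model.n, model_source,
    )
    predictions = {
        sample: predict_all(pets, loci, model, thresholds)
        for sample, pets in pets_by_sample.items()
    }
    return RunResult(
        loci=list(loci),
        demux_counts=report.counts,
        total_pairs=report.total,
        pets_by_sample=pets_by_sample,
        mapped_by_sample=mapped_by_sample,
        unique_by_sample=unique_by_sample,
        model=model,
        model_source=model_source,
        predictions=predictions,
    )


def analyze_alignments(
    tags: Iterable[MappedTag],
    loci: Sequence[TargetLocus],
    thresholds: CallThresholds = CallThresholds(),
    *,
    sample_id: str = "ingested",
    fallback_model: Optional[FragmentLengthModel] = None,
) -> RunResult:
    """Pipeline from pre-computed alignments (single, already-demuxed sample)."""
    results = [(t.read_id, t.mate, t) for t in tags]
    pets = pair_tags(results, sample_id)
    normal = [p for p in pets if p.klass is PetClass.NORMAL]
    try:
        model = estimate_fragment_model(normal)
        model_source = "estimated"
    except InsufficientNormalPets:
        if fallback_model is None:
            raise
        model, model_source = fallback_model, "fallback"
    predictions = {sample_id: predict_all(pets, loci, model, thresholds)}
    n_unique = [
        sum(1 for _, m, t in results if m == mate and t.unique) for mate in (1, 2)
    ]
    return RunResult(
        loci=list(loci),
        demux_counts={sample_id: len(pets)},
        total_pairs=len(pets),
        pets_by_sample={sample_id: pets},
        mapped_by_sample={sample_id: (n_unique[0], n_unique[1])},
        unique_by_sample={sample_id: (n_unique[0], n_unique[1])},
        model=model,
        model_source=model_source,
        predictions=predictions,
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """File-level pipeline: read inputs, analyze, write the artifact set.

    Outputs in `config.output_dir`: summary.tsv (per-sample counts),
    predictions.tsv (per orientation/locus, "start-end" intervals),
    predictions.bed, primer_targets.bed (CALLED intervals +/- primer_flank,
    for junction-PCR design), and profiles/<sample>_<orientation>_<locus>.bedGraph.
    """
    from .align import read_loci_fasta

    loci = read_loci_fasta(config.loci_fasta)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.alignments is not None:
        tags = ingest_alignments(config.alignments, loci)
        result = analyze_alignments(
            tags, loci, config.thresholds, fallback_model=config.fallback_model
        )
    else:
        if config.barcodes_tsv is None:
            raise ValueError("FASTQ input requires a barcode table")
        barcode_set = BarcodeSet.from_tsv(config.barcodes_tsv)
        pairs = apio.read_fastq_pair(config.fastq1, config.fastq2)
        result = analyze_run(
            pairs,
            loci,
            barcode_set,
            config.thresholds,
            fallback_model=config.fallback_model,
            mismatch_rescue=config.mismatch_rescue,
            allow_barcode_mismatch=config.allow_barcode_mismatch,
        )
    _write_outputs(result, outdir, config.primer_flank)
    return result


def _write_outputs(result: RunResult, outdir: Path, primer_flank: int) -> None:
    result.summary_table().to_csv(outdir / "summary.tsv", sep="\t", index=False)
    loci_by_name = {loc.name: loc for loc in result.loci}
    with open(outdir / "predictions.tsv", "w") as out:
        out.write("sample\torientation\tlocus\tstatus\tinterval\tmax_vote\t"
                  "support\tgenome_interval\n")
        for sample in sorted(result.predictions):
            for orientation, by_locus in result.predictions[sample].items():
                for locus_name, pred in by_locus.items():
                    anchor = loci_by_name[locus_name].genome_anchor
                    if pred.interval is not None and anchor is not None:
                        gstart, gend = sorted(
                            (anchor.to_genome(pred.interval[0]),
                             anchor.to_genome(pred.interval[1]))
                        )
                        genome = f"{anchor.chrom}:{gstart}-{gend}"
                    else:
                        genome = "NA"
                    out.write(
                        f"{sample}\t{orientation}\t{locus_name}\t"
                        f"{pred.status.value}\t{pred.format_interval()}\t"
                        f"{pred.max_vote}\t{pred.support}\t{genome}\n"
                    )
    with open(outdir / "predictions.bed", "w") as bed, open(
        outdir / "primer_targets.bed", "w"
    ) as primers:
        for sample in sorted(result.predictions):
            for orientation, by_locus in result.predictions[sample].items():
                for locus_name, pred in by_locus.items():
                    if pred.status is not CallStatus.CALLED:
                        continue
                    start, end = pred.interval
                    name = f"{sample}|{orientation}|{locus_name}"
                    bed.write(f"{locus_name}\t{start - 1}\t{end}\t{name}\t"
                              f"{pred.max_vote}\n")
                    locus = loci_by_name[locus_name]
                    pstart = max(1, start - primer_flank)
                    pend = min(locus.length, end + primer_flank)
                    primers.write(
                        f"{locus_name}\t{pstart - 1}\t{pend}\t{name}_primer_target\n"
                    )
    profile_dir = outdir / "profiles"
    profile_dir.mkdir(exist_ok=True)
    for sample, pets in sorted(result.pets_by_sample.items()):
        junctional = [p for p in pets if p.klass is PetClass.JUNCTIONAL]
        if not junctional:
            continue
        for orientation, by_locus in vote_profiles(
            junctional, result.loci, result.model
        ).items():
            for locus_name, profile in by_locus.items():
                safe = orientation.replace("->", "_to_")
                apio.write_bedgraph(
                    profile, profile_dir / f"{sample}_{safe}_{locus_name}.bedGraph"
                )


def mix_samples(
    sample_pairs: Sequence[Sequence[ReadPair]],
    fractions: Sequence[float],
    seed: int,
    n_out: Optional[int] = None,
) -> list[ReadPair]:
    """Interleave reads from several samples at the given fractions.

    Each emitted pair is drawn from sample i with probability fractions[i],
    consuming that sample's stream in order; emission stops after `n_out`
    pairs (default: the total available) or when the drawn stream is
    exhausted. A single sample at fraction 1 reproduces its own stream
    order-preserved.
    """
    if len(sample_pairs) != len(fractions):
        raise ValueError("one fraction per sample required")
    fractions = np.asarray(fractions, dtype=float)
    if fractions.min() < 0 or not np.isclose(fractions.sum(), 1.0):
        raise ValueError(f"fractions must be >= 0 and sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    queues = [list(reversed(list(pairs))) for pairs in sample_pairs]
    if n_out is None:
        n_out = sum(len(q) for q in queues)
    mixed: list[ReadPair] = []
    for _ in range(n_out):
        i = int(rng.choice(len(queues), p=fractions))
        if not queues[i]:
            break
        mixed.append(queues[i].pop())
    return mixed


# ---------------------------------------------------------------------------
# simulation-driven replicates (used by the validation suite)
# ---------------------------------------------------------------------------


@dataclass
class ReplicateResult:
    sample: SimulatedSample
    run: RunResult
    n_junctional: int


def run_simulated_replicate(
    config: SimulationConfig,
    seed: int,
    *,
    min_junctional: int = 0,
    max_attempts: int = 50,
    thresholds: CallThresholds = CallThresholds(),
) -> ReplicateResult:
    """Simulate one sample and push it through the full pipeline.

    With `min_junctional` > 0, re-simulates under a derived seed until the
    run yields at least that many junctional chromPETs — the conditioning
    used by validation experiments that require a minimum evidence level per
    replicate.
    """
    barcode_set = BarcodeSet([(config.sample_id, config.barcode)])
    for attempt in range(max_attempts):
        attempt_seed = seed + attempt * 1_000_003
        sample = simulate_sample(replace(config, seed=attempt_seed))
        run = analyze_run(sample.pairs, sample.loci, barcode_set, thresholds)
        pets = run.pets_by_sample[config.sample_id]
        n_junctional = sum(1 for p in pets if p.klass is PetClass.JUNCTIONAL)
        if n_junctional >= min_junctional:
            return ReplicateResult(sample, run, n_junctional)
    raise RuntimeError(
        f"no replicate with >= {min_junctional} junctional chromPETs in "
        f"{max_attempts} attempts from seed {seed}"
    )
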
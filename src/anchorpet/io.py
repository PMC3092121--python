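"""File-format boundaries: FASTA, FASTQ, BED, bedGraph, TSV.

Internal coordinates are 1-based inclusive everywhere in the package; the
writers here convert to 0-based half-open only when emitting BED/bedGraph.
Quality strings are constant 'I' (Phred 40): the simulator does not model
base qualities and none of the downstream stages consume them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import TargetLocus
from .breakpoints import VoteProfile
from .simulate import FragmentTruth, ReadPair

PathLike = Union[str, Path]


def write_fasta(loci: Iterable[TargetLocus], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(locus.sequence), id=locus.name, description="")
        for locus in loci
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fastq_pair(
    pairs: Iterable[ReadPair], path1: PathLike, path2: PathLike
) -> None:
    """Write read pairs as two FASTQ files with /1 and /2 id suffixes."""

    def records(mate: int) -> Iterator[SeqRecord]:
        for pair in pairs:
            seq = pair.seq1 if mate == 1 else pair.seq2
            rec = SeqRecord(Seq(seq), id=f"{pair.read_id}/{mate}", description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            yield rec

    pairs = list(pairs)
    SeqIO.write(records(1), str(path1), "fastq")
    SeqIO.write(records(2), str(path2), "fastq")


def read_fastq_pair(path1: PathLike, path2: PathLike) -> Iterator[ReadPair]:
    """Stream read pairs from two FASTQ files, checking id synchrony."""
    from .demux import paired_records

    stream1 = ((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path1), "fastq"))
    stream2 = ((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path2), "fastq"))
    yield from paired_records(stream1, stream2)


def write_truth_tsv(fragments: Iterable[FragmentTruth], path: PathLike) -> None:
    with open(path, "w") as out:
        out.write("read_id\tsample_id\tsource\tstart\tend\tlength\tspans_junction\n")
        for frag in fragments:
            out.write(
                f"{frag.read_id}\t{frag.sample_id}\t{frag.source}\t{frag.start}\t"
                f"{frag.end}\t{frag.end - frag.start + 1}\t"
                f"{int(frag.spans_junction)}\n"
            )


def write_junctions_bed(truth, path: PathLike) -> None:
    """Planted junction flanks as BED (0-based half-open).

    Each of the four junction flanking-coordinate pairs becomes one 2-bp BED
    feature on its locus, named by fusion and side.
    """
    rows = []
    for fusion_name, junction in (("der1", truth.junction_ab), ("der2", truth.junction_ba)):
        rows.append(
            (junction.five_locus, junction.five_last_retained,
             f"{fusion_name}_5prime_{junction.five_locus}")
        )
        rows.append(
            (junction.three_locus, junction.three_first_retained - 1,
             f"{fusion_name}_3prime_{junction.three_locus}")
        )
    with open(path, "w") as out:
        for chrom, last_before_break, name in rows:
            # flanking pair (x, x+1), 1-based -> BED [x-1, x+1)
            out.write(f"{chrom}\t{last_before_break - 1}\t{last_before_break + 1}\t{name}\n")


def write_bedgraph(profile: VoteProfile, path: PathLike) -> None:
    """Vote profile as bedGraph (0-based half-open, zero runs skipped)."""
    votes = profile.votes
    with open(path, "w") as out:
        out.write(f'track type=bedGraph name="{profile.locus}_votes"\n')
        if votes.size == 0:
            return
        run_start = 0
        current = votes[0]
        for i in range(1, votes.size + 1):
            value = votes[i] if i < votes.size else None
            if value != current:
                if current != 0:
                    out.write(f"{profile.locus}\t{run_start}\t{i}\t{int(current)}\n")
                run_start, current = i, value


def write_mapped_tags_tsv(tags, path: PathLike) -> None:
    with open(path, "w") as out:
        out.write("# read_id\tmate\tlocus\tstart\tstrand\tlength\n")
        for tag in tags:
            out.write(
                f"{tag.read_id}\t{tag.mate}\t{tag.locus}\t{tag.start}\t"
                f"{tag.strand}\t{tag.length}\n"
            )
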
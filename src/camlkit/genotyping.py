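"""Per-sample microsatellite genotyping from aligned short reads.

An allele is a specific tract length at a cataloged locus; a genotype is the
unordered pair of allele lengths carried by one sample.  Tract length is
measured on the read sequence by exact flank anchoring — the read must
contain the anchor word adjacent to each side of the tract — rather than by
CIGAR arithmetic, which keeps the measurement independent of how the aligner
places indels inside the repeat.

Calling rules: read-level observations are aggregated per distinct tract
length; low-support lengths are discarded as stutter noise; a locus-sample
needs at least ``min_depth`` (default 15) surviving spanning reads to be
called, and is dropped as ambiguous when more than two allele lengths
survive.  One surviving length is reported as a homozygote ``(L, L)``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .errors import InputError, ParseError
from .repeat_catalog import MicrosatelliteLocus

logger = logging.getLogger(__name__)


class CallStatus(str, Enum):
    CALLED = "called"
    NO_CALL_DEPTH = "no_call_depth"
    NO_CALL_MULTIALLELIC = "no_call_multiallelic"
    NO_CALL_NOSPAN = "no_call_nospan"


@dataclass(frozen=True)
class AlleleObservation:
    """Read support for one tract length at one locus."""

    locus_id: str
    tract_length: int
    read_count: int

    def __post_init__(self):
        if self.tract_length < 0:
            raise InputError("tract_length must be >= 0")
        if self.read_count < 1:
            raise InputError("read_count must be >= 1")


@dataclass(frozen=True)
class GenotypingParams:
    """Thresholds for allele calling.

    min_depth
        Minimum surviving spanning reads for a call (15, matching the
        depth-of-coverage floor applied to all cohorts).
    min_allele_fraction, min_allele_reads
        Stutter-noise gate: an allele length must be supported by at least
        this many reads and this fraction of spanning reads.  The defaults
        let a balanced heterozygote at depth 15 pass while single stutter
        reads do not.
    flank_match_len
        Length of the exact-match anchor word taken from each flank.
    min_mapping_quality
        Reads below this MAPQ (plus unmapped/duplicate/secondary/
        supplementary reads) are skipped.
    """

    min_depth: int = 15
    min_allele_fraction: float = 0.2
    min_allele_reads: int = 2
    flank_match_len: int = 10
    min_mapping_quality: int = 20

    def __post_init__(self):
        if not (0 < self.min_allele_fraction <= 0.5):
            raise InputError("min_allele_fraction must be in (0, 0.5]")
        if self.min_depth < 1 or self.min_allele_reads < 1:
            raise InputError("depth/read thresholds must be >= 1")


@dataclass(frozen=True)
class SampleGenotype:
    """Unordered pair of allele tract lengths at one locus in one sample."""

    locus_id: str
    sample_id: str
    alleles: tuple[int, int] | None
    depth: int
    status: CallStatus

    def __post_init__(self):
        if self.status is CallStatus.CALLED:
            if self.alleles is None:
                raise InputError("called genotype requires alleles")
            if self.alleles[0] > self.alleles[1]:
                object.__setattr__(
                    self, "alleles", (self.alleles[1], self.alleles[0])
                )
        elif self.alleles is not None:
            raise InputError("no-call genotype must not carry alleles")

    @property
    def called(self) -> bool:
        return self.status is CallStatus.CALLED


def measure_read_tract(
    read_sequence: str,
    locus: MicrosatelliteLocus,
    params: GenotypingParams | None = None,
) -> int | None:
    """Measure the tract length carried by one read, or None if non-spanning.

    The left anchor is the ``flank_match_len`` nt of flank adjacent to the
    tract's left boundary, the right anchor the ``flank_match_len`` nt
    adjacent to its right boundary.  Both must occur exactly and in order;
    the leftmost occurrence of the left anchor is used, then the leftmost
    occurrence of the right anchor after it.  The returned length is the
    distance between the anchors (0 for a fully deleted tract).
    """
    params = params or GenotypingParams()
    m = params.flank_match_len
    left_anchor = locus.left_flank[-m:]
    right_anchor = locus.right_flank[:m]
    if len(left_anchor) < m or len(right_anchor) < m:
        return None  # flank clipped at contig edge: cannot anchor reliably
    i = read_sequence.find(left_anchor)
    if i == -1:
        return None
    j = read_sequence.find(right_anchor, i + m)
    if j == -1:
        return None
    return j - (i + m)


def genotype_locus(
    observations: Sequence[AlleleObservation],
    params: GenotypingParams | None = None,
    locus_id: str | None = None,
    sample_id: str = "",
) -> SampleGenotype:
    """Call one locus in one sample from aggregated allele observations."""
    params = params or GenotypingParams()
    if locus_id is None:
        locus_id = observations[0].locus_id if observations else ""
    if not observations:
        return SampleGenotype(locus_id, sample_id, None, 0, CallStatus.NO_CALL_NOSPAN)

    counts: Counter[int] = Counter()
    for obs in observations:
        counts[obs.tract_length] += obs.read_count
    total = sum(counts.values())
    surviving = {
        length: n
        for length, n in counts.items()
        if n >= params.min_allele_reads and n / total >= params.min_allele_fraction
    }
    depth = sum(surviving.values())
    if depth < params.min_depth:
        return SampleGenotype(locus_id, sample_id, None, depth, CallStatus.NO_CALL_DEPTH)
    if len(surviving) > 2:
        return SampleGenotype(
            locus_id, sample_id, None, depth, CallStatus.NO_CALL_MULTIALLELIC
        )
    lengths = sorted(surviving)
    if len(lengths) == 1:
        alleles = (lengths[0], lengths[0])
    else:
        alleles = (lengths[0], lengths[1])
    return SampleGenotype(locus_id, sample_id, alleles, depth, CallStatus.CALLED)


def _skip_read(read: pysam.AlignedSegment, params: GenotypingParams) -> bool:
    return (
        read.is_unmapped
        or read.is_duplicate
        or read.is_secondary
        or read.is_supplementary
        or (read.mapping_quality or 0) < params.min_mapping_quality
    )


def genotype_sample(
    alignments: pysam.AlignmentFile | str | Path,
    catalog: Sequence[MicrosatelliteLocus],
    sample_id: str,
    params: GenotypingParams | None = None,
) -> list[SampleGenotype]:
    """Genotype every cataloged locus of one sample from its alignments.

    ``alignments`` is a coordinate-sorted, indexed BAM (path or open
    handle).  Reads overlapping the locus extended by its flanks are
    fetched; unmapped, duplicate, secondary, supplementary and low-MAPQ
    reads are skipped; the remainder are measured with
    :func:`measure_read_tract`.
    """
    params = params or GenotypingParams()
    own_handle = not isinstance(alignments, pysam.AlignmentFile)
    bam = (
        pysam.AlignmentFile(str(alignments)) if own_handle else alignments
    )
    try:
        references = set(bam.references)
        genotypes = []
        for locus in catalog:
            if locus.contig not in references:
                raise InputError(
                    f"contig {locus.contig!r} absent from alignment header "
                    f"(has: {sorted(references)[:5]}...)"
                )
            fetch_start = max(0, locus.start - len(locus.left_flank))
            fetch_end = locus.end + len(locus.right_flank)
            lengths: Counter[int] = Counter()
            for read in bam.fetch(locus.contig, fetch_start, fetch_end):
                if _skip_read(read, params):
                    continue
                seq = read.query_sequence
                if not seq:
                    continue
                tract = measure_read_tract(seq, locus, params)
                if tract is not None:
                    lengths[tract] += 1
            observations = [
                AlleleObservation(locus.locus_id, length, n)
                for length, n in sorted(lengths.items())
            ]
            genotypes.append(
                genotype_locus(observations, params, locus.locus_id, sample_id)
            )
        return genotypes
    finally:
        if own_handle:
            bam.close()


# ---------------------------------------------------------------------------
# genotype TSV I/O
# ---------------------------------------------------------------------------

_GENO_COLUMNS = ["sample_id", "locus_id", "allele_a", "allele_b", "depth", "status"]


def write_genotypes(
    genotypes: Iterable[SampleGenotype], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENO_COLUMNS) + "\n")
        for g in genotypes:
            a = "" if g.alleles is None else str(g.alleles[0])
            b = "" if g.alleles is None else str(g.alleles[1])
            fh.write(
                f"{g.sample_id}\t{g.locus_id}\t{a}\t{b}\t{g.depth}\t"
                f"{g.status.value}\n"
            )


def read_genotypes(path: str | Path) -> list[SampleGenotype]:
    genotypes = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GENO_COLUMNS:
            raise ParseError(f"unexpected genotype header {header!r}", 1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_GENO_COLUMNS):
                raise ParseError(
                    f"expected {len(_GENO_COLUMNS)} fields, got {len(fields)}",
                    lineno,
                )
            sample_id, locus_id, a, b, depth_s, status_s = fields
            key = (sample_id, locus_id)
            if key in seen:
                raise ParseError(
                    f"duplicate genotype row for sample {sample_id!r}, "
                    f"locus {locus_id!r}",
                    lineno,
                )
            seen.add(key)
            try:
                status = CallStatus(status_s)
                depth = int(depth_s)
                alleles = (int(a), int(b)) if a != "" and b != "" else None
            except ValueError:
                raise ParseError(f"malformed genotype row {fields!r}", lineno) from None
            genotypes.append(
                SampleGenotype(locus_id, sample_id, alleles, depth, status)
            )
    return genotypes
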
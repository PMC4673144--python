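"""Microsatellite locus discovery and catalog management.

A microsatellite is a tandem repeat of a short (1-7 nt) motif.  This module
scans reference sequence for such tracts, normalises motifs to a canonical
rotation/strand form (so that AC, CA, GT and TG name one locus class),
filters the resulting catalog down to loci that can be genotyped
unambiguously from short reads (unique flanking sequence, tract length
bounds), and round-trips catalogs through a BED + TSV sidecar representation.

Coordinates are 0-based half-open internally and in BED output; the human
readable ``locus_id`` renders 1-based inclusive coordinates
(``chr15:63040517-63040532`` style).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import InputError, ParseError

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")
_VALID_SCAN = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif(motif: str) -> str:
    """Canonical form of a repeat motif.

    Returns the lexicographically least string among all rotations of the
    motif and of its reverse complement, so that every phase and strand of
    one repeat class maps to a single name (e.g. TG, GT, CA and AC all
    canonicalise to ``AC``).  Idempotent by construction.
    """
    if not motif:
        raise InputError("motif must be non-empty")
    if not set(motif) <= _VALID_BASES:
        raise InputError(f"motif {motif!r} contains characters outside ACGT")
    rc = reverse_complement(motif)
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def is_primitive(motif: str) -> bool:
    """True when the motif is not a whole-number repetition of a shorter one."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """A cataloged repeat tract; the unit of all downstream statistics.

    ``motif`` is the canonical (rotation/strand normalised, primitive) motif;
    ``repeat_unit`` is the leading motif-length word of the tract as it
    appears on the reference forward strand (needed to reconstruct tract
    sequence, e.g. when simulating reads).
    """

    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    motif: str
    left_flank: str = ""
    right_flank: str = ""
    repeat_unit: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise InputError(
                f"locus end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def ref_tract_length(self) -> int:
        return self.end - self.start

    @property
    def locus_id(self) -> str:
        # 1-based inclusive rendering
        return f"{self.contig}:{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class ScanParams:
    """Parameters of the tandem-repeat scanner.

    ``min_purity`` of 1.0 admits perfect repeats only; lower values admit
    interrupted repeats scored as (matching positions)/(tract length) under
    the phase set by the tract's leading motif copy.
    """

    min_motif_len: int = 1
    max_motif_len: int = 7
    min_tract_length: int = 6
    max_tract_length: int | None = None
    min_purity: float = 1.0
    flank_len: int = 20

    def __post_init__(self):
        if self.min_motif_len < 1 or self.min_motif_len > self.max_motif_len:
            raise InputError("require 1 <= min_motif_len <= max_motif_len")
        if self.min_tract_length < 2 * self.min_motif_len:
            raise InputError("min_tract_length must be >= 2 * min_motif_len")
        if not (0.0 < self.min_purity <= 1.0):
            raise InputError("min_purity must be in (0, 1]")
        if self.max_tract_length is not None and (
            self.max_tract_length < self.min_tract_length
        ):
            raise InputError("max_tract_length must be >= min_tract_length")


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    for offset, ch in enumerate(seq):
        if ch not in _VALID_SCAN:
            raise InputError(
                f"invalid character {ch!r} in sequence at offset {offset}"
            )
    return seq


def _perfect_candidates(seq: str, k: int) -> list[tuple[int, int]]:
    """Maximal intervals [i, j) with period k and perfect tandem purity."""
    n = len(seq)
    out = []
    i = 0
    limit = n - k
    while i < limit:
        if seq[i] == seq[i + k]:
            j = i
            while j < limit and seq[j] == seq[j + k]:
                j += 1
            # run of matches at offsets [i, j) -> tract [i, j + k)
            out.append((i, j + k))
            i = j + 1
        else:
            i += 1
    return out


def _impure_candidates(seq: str, k: int, min_purity: float, min_len: int):
    """Greedy maximal interrupted-repeat intervals for motif length k.

    From every start, extend rightwards counting positions that match the
    base one period earlier; mismatches are absorbed while the running
    purity (matches / length, the leading motif copy counting as matched)
    stays at or above ``min_purity``.  Tracts never end on a mismatch.
    """
    n = len(seq)
    out = []
    for i in range(n - 2 * k + 1):
        matches = k
        best_j = None
        for j in range(i + k, n):
            if seq[j] == seq[j - k]:
                matches += 1
                if matches / (j - i + 1) >= min_purity:
                    best_j = j + 1
        if best_j is not None and best_j - i >= max(min_len, 2 * k):
            out.append((i, best_j))
    return out


def find_repeats(
    sequence: str, contig_name: str, params: ScanParams | None = None
) -> list[MicrosatelliteLocus]:
    """Scan one contig for maximal non-overlapping microsatellite tracts.

    Candidate tracts are enumerated for every motif length in the configured
    range; competition between overlapping candidates is resolved
    longest-first, ties by smaller start, then shorter motif, yielding a
    deterministic maximal decomposition.  Tracts containing N are excluded,
    as are tracts whose repeat unit is non-primitive (those are reported at
    their true, shorter period).
    """
    params = params or ScanParams()
    if not sequence:
        return []
    seq = _validate_sequence(sequence)
    n = len(seq)

    candidates: list[tuple[int, int, int]] = []  # (start, end, motif_len)
    for k in range(params.min_motif_len, params.max_motif_len + 1):
        if params.min_purity >= 1.0:
            intervals = _perfect_candidates(seq, k)
        else:
            intervals = _impure_candidates(
                seq, k, params.min_purity, params.min_tract_length
            )
        for i, j in intervals:
            if j - i < max(params.min_tract_length, 2 * k):
                continue
            if params.max_tract_length is not None and j - i > params.max_tract_length:
                continue
            unit = seq[i : i + k]
            if "N" in seq[i:j]:
                continue
            if not is_primitive(unit):
                continue
            candidates.append((i, j, k))

    # longest first, then leftmost, then shortest motif
    candidates.sort(key=lambda t: (-(t[1] - t[0]), t[0], t[2]))
    chosen: list[tuple[int, int, int]] = []
    occupied: list[tuple[int, int]] = []
    for i, j, k in candidates:
        if any(i < e and s < j for s, e in occupied):
            continue
        occupied.append((i, j))
        chosen.append((i, j, k))
    chosen.sort(key=lambda t: t[0])

    loci = []
    for i, j, k in chosen:
        unit = seq[i : i + k]
        loci.append(
            MicrosatelliteLocus(
                contig=contig_name,
                start=i,
                end=j,
                motif=canonical_motif(unit),
                repeat_unit=unit,
                left_flank=seq[max(0, i - params.flank_len) : i],
                right_flank=seq[j : j + params.flank_len],
            )
        )
    return loci


def scan_reference(
    contigs: Mapping[str, str], params: ScanParams | None = None
) -> list[MicrosatelliteLocus]:
    """Run ``find_repeats`` over every contig, sorted by (contig, start)."""
    loci = []
    for name in sorted(contigs):
        loci.extend(find_repeats(contigs[name], name, params))
    return loci


# ---------------------------------------------------------------------------
# catalog filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterRules:
    """Locus-level acceptance rules applied after scanning.

    ``require_unique_flanks`` drops loci whose exact flank pair (left flank
    followed, within ``max_flank_separation`` nt, by the right flank) occurs
    more than once in the reference — such loci cannot be anchored uniquely
    by flank matching.  Loci with an empty flank are likewise dropped under
    this rule.  ``min/max_tract_length`` re-check tract length bounds.
    """

    min_tract_length: int | None = None
    max_tract_length: int | None = None
    require_unique_flanks: bool = True
    max_flank_separation: int = 200


def _count_flank_pairs(
    contigs: Mapping[str, str], left: str, right: str, max_sep: int
) -> int:
    count = 0
    for seq in contigs.values():
        pos = seq.find(left)
        while pos != -1:
            window_end = pos + len(left) + max_sep + len(right)
            if seq.find(right, pos + len(left), window_end) != -1:
                count += 1
                if count > 1:
                    return count
            pos = seq.find(left, pos + 1)
    return count


def filter_catalog(
    loci: Iterable[MicrosatelliteLocus],
    reference: Mapping[str, str],
    rules: FilterRules | None = None,
    return_counts: bool = False,
):
    """Filter a scanned catalog to genotypable loci (pure subset operation).

    Returns the surviving loci in input order; with ``return_counts=True``
    also returns a per-rule drop-count dict.  Per-rule counts are logged.
    """
    rules = rules or FilterRules()
    loci = list(loci)
    drops = {"length": 0, "flank_n": 0, "flank_uniqueness": 0}
    survivors = []
    for locus in loci:
        if locus.contig not in reference:
            raise InputError(f"contig {locus.contig!r} not in reference")
        contig_len = len(reference[locus.contig])
        if locus.end > contig_len or locus.start < 0:
            raise InputError(
                f"locus {locus.locus_id} outside contig {locus.contig!r} "
                f"(length {contig_len})"
            )
        tract = locus.ref_tract_length
        if rules.min_tract_length is not None and tract < rules.min_tract_length:
            drops["length"] += 1
            continue
        if rules.max_tract_length is not None and tract > rules.max_tract_length:
            drops["length"] += 1
            continue
        if "N" in locus.left_flank or "N" in locus.right_flank:
            drops["flank_n"] += 1
            continue
        if rules.require_unique_flanks:
            if not locus.left_flank or not locus.right_flank:
                drops["flank_uniqueness"] += 1
                continue
            n_hits = _count_flank_pairs(
                reference,
                locus.left_flank,
                locus.right_flank,
                rules.max_flank_separation,
            )
            if n_hits > 1:
                drops["flank_uniqueness"] += 1
                continue
        survivors.append(locus)
    for rule, n in drops.items():
        if n:
            logger.info("filter_catalog: dropped %d loci by rule %r", n, rule)
    logger.info(
        "filter_catalog: %d loci in, %d retained", len(loci), len(survivors)
    )
    if return_counts:
        return survivors, drops
    return survivors


# ---------------------------------------------------------------------------
# catalog I/O: BED6 + TSV sidecar
# ---------------------------------------------------------------------------

_SIDE_COLUMNS = [
    "locus_id",
    "motif",
    "canonical_motif",
    "tract_length",
    "left_flank",
    "right_flank",
]


def sidecar_path(bed_path: str | Path) -> Path:
    bed_path = Path(bed_path)
    if bed_path.suffix == ".bed":
        return bed_path.with_suffix(".tsv")
    return bed_path.with_name(bed_path.name + ".tsv")


def write_catalog(loci: Iterable[MicrosatelliteLocus], path: str | Path) -> None:
    """Write a catalog as BED6 (name=locus_id, score=tract length) + sidecar TSV."""
    path = Path(path)
    loci = list(loci)
    with open(path, "w") as bed:
        for loc in loci:
            bed.write(
                f"{loc.contig}\t{loc.start}\t{loc.end}\t{loc.locus_id}\t"
                f"{loc.ref_tract_length}\t+\n"
            )
    with open(sidecar_path(path), "w") as side:
        side.write("\t".join(_SIDE_COLUMNS) + "\n")
        for loc in loci:
            side.write(
                f"{loc.locus_id}\t{loc.repeat_unit or loc.motif}\t{loc.motif}\t"
                f"{loc.ref_tract_length}\t{loc.left_flank}\t{loc.right_flank}\n"
            )


def read_catalog(path: str | Path) -> list[MicrosatelliteLocus]:
    """Read a catalog written by :func:`write_catalog` (lossless round-trip)."""
    path = Path(path)
    side = sidecar_path(path)
    meta: dict[str, dict[str, str]] = {}
    with open(side) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SIDE_COLUMNS:
            raise ParseError(f"unexpected sidecar header {header!r}", 1)
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_SIDE_COLUMNS):
                raise ParseError(
                    f"expected {len(_SIDE_COLUMNS)} sidecar fields, got "
                    f"{len(fields)}",
                    lineno,
                )
            meta[fields[0]] = dict(zip(_SIDE_COLUMNS, fields))

    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ParseError("BED line has fewer than 5 fields", lineno)
            contig, start_s, end_s, locus_id = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError("non-integer BED coordinates", lineno) from None
            if start < 0 or start >= end:
                raise ParseError(
                    f"invalid BED interval [{start}, {end})", lineno
                )
            row = meta.get(locus_id)
            if row is None:
                raise ParseError(
                    f"locus {locus_id!r} missing from sidecar {side}", lineno
                )
            loci.append(
                MicrosatelliteLocus(
                    contig=contig,
                    start=start,
                    end=end,
                    motif=row["canonical_motif"],
                    repeat_unit=row["motif"],
                    left_flank=row["left_flank"],
                    right_flank=row["right_flank"],
                )
            )
    return loci
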
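"""Cross-cancer comparison of signature and non-signature CAML sets.

Given per-cancer signature sets, this module computes pairwise
shared-signature percentages (the denominator is the union of the two
signatures, i.e. Jaccard x 100, with the minimum-set-size denominator
available as an option), the proportion of shared significant loci that are
non-signature in at least one of the two cancers, and an enrichment p-value
for a three-set intersection.

The three-set test asks how probable an intersection at least as large as
the observed ``|A n B n C|`` is when each set is an independent uniform draw
of its size from a shared universe of jointly tested loci.  It is evaluated
exactly by conditioning on the first-stage overlap: ``|A n B|`` is
hypergeometric, and given ``|A n B| = j`` the pool of j loci plays the role
of the drawn class versus C, so the triple intersection is again
hypergeometric.  The tail sum over j gives the p-value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .association import LocusAssociation, LocusClass, SignatureSet
from .errors import InputError, ParseError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    labels: tuple[str, ...]
    shared_loci: frozenset[str]
    percent_shared: float
    universe_size: int
    p_value: float | None = None
    venn_counts: dict | None = None

    @property
    def shared_count(self) -> int:
        return len(self.shared_loci)


def pairwise_shared(
    sig_a: SignatureSet,
    sig_b: SignatureSet,
    denominator: str = "union",
) -> OverlapResult:
    """Shared signature loci between two cancers.

    ``percent_shared`` is 100 * |A n B| / |A u B| by default; with
    ``denominator="min"`` the smaller set's size is used instead.
    Symmetric in its arguments.
    """
    if denominator not in ("union", "min"):
        raise InputError(f"unknown denominator {denominator!r}")
    inter = frozenset(sig_a.loci & sig_b.loci)
    if denominator == "union":
        denom = len(sig_a.loci | sig_b.loci)
    else:
        denom = min(len(sig_a.loci), len(sig_b.loci))
    percent = 100.0 * len(inter) / denom if denom else 0.0
    return OverlapResult(
        labels=(sig_a.cancer_label, sig_b.cancer_label),
        shared_loci=inter,
        percent_shared=percent,
        universe_size=len(sig_a.loci | sig_b.loci),
    )


def _significant_loci(associations: Sequence[LocusAssociation]) -> dict[str, LocusClass]:
    out = {}
    for x in associations:
        if x.klass is None:
            raise InputError(
                f"association for locus {x.locus_id!r} is unclassified"
            )
        if x.klass in (LocusClass.SIGNATURE, LocusClass.NON_SIGNATURE):
            out[x.locus_id] = x.klass
    return out


def nonsignature_shared_proportion(
    assoc_a: Sequence[LocusAssociation],
    assoc_b: Sequence[LocusAssociation],
) -> float:
    """Percent of shared significant loci that are non-signature somewhere.

    The shared pool is the intersection of the two cancers' significant
    loci (signature plus non-signature); the numerator counts pool members
    classed non_signature in at least one of the two cancers.  Returns 0
    with a warning when the shared pool is empty.  Symmetric.
    """
    sig_a = _significant_loci(assoc_a)
    sig_b = _significant_loci(assoc_b)
    shared = set(sig_a) & set(sig_b)
    if not shared:
        warnings.warn(
            "no significant loci shared between the two cancers; "
            "returning 0%",
            stacklevel=2,
        )
        return 0.0
    n_nonsig = sum(
        1
        for locus in shared
        if sig_a[locus] is LocusClass.NON_SIGNATURE
        or sig_b[locus] is LocusClass.NON_SIGNATURE
    )
    return 100.0 * n_nonsig / len(shared)


def venn_region_counts(
    set_a: frozenset[str] | set[str],
    set_b: frozenset[str] | set[str],
    set_c: frozenset[str] | set[str],
) -> dict[str, int]:
    """Counts of the 7 Venn regions of three sets (keys like '110')."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    return {
        "100": len(a - b - c),
        "010": len(b - a - c),
        "001": len(c - a - b),
        "110": len((a & b) - c),
        "101": len((a & c) - b),
        "011": len((b & c) - a),
        "111": len(a & b & c),
    }


def three_set_intersection_pvalue(
    n_a: int, n_b: int, n_c: int, k_triple: int, universe_size: int
) -> float:
    """P(|A n B n C| >= k_triple) for independent uniform draws.

    Exact two-stage evaluation: sum over j of
    P(|A n B| = j) * P(Hypergeom(universe, j, n_c) >= k_triple).
    """
    if k_triple <= 0:
        return 1.0
    n = universe_size
    j_lo = max(0, n_a + n_b - n)
    j_hi = min(n_a, n_b)
    j = np.arange(j_lo, j_hi + 1)
    stage1 = hypergeom.pmf(j, n, n_a, n_b)
    stage2 = hypergeom.sf(k_triple - 1, n, j, n_c)
    return float(min(1.0, np.dot(stage1, stage2)))


def three_set_overlap_test(
    sets: Sequence[SignatureSet | frozenset | set],
    universe_size: int,
    labels: Sequence[str] | None = None,
) -> OverlapResult:
    """Enrichment test for the triple intersection of three locus sets.

    ``universe_size`` should be the number of loci jointly tested in all
    three cohorts; it must not be smaller than the union of the sets.
    """
    if len(sets) != 3:
        raise InputError("exactly three sets required")
    plain = []
    out_labels = []
    for i, s in enumerate(sets):
        if isinstance(s, SignatureSet):
            plain.append(set(s.loci))
            out_labels.append(s.cancer_label)
        else:
            plain.append(set(s))
            out_labels.append(labels[i] if labels else f"set{i + 1}")
    a, b, c = plain
    union = a | b | c
    if universe_size < len(union):
        raise InputError(
            f"universe_size {universe_size} smaller than union {len(union)}"
        )
    triple = frozenset(a & b & c)
    p = three_set_intersection_pvalue(
        len(a), len(b), len(c), len(triple), universe_size
    )
    percent = 100.0 * len(triple) / len(union) if union else 0.0
    return OverlapResult(
        labels=tuple(out_labels),
        shared_loci=triple,
        percent_shared=percent,
        universe_size=universe_size,
        p_value=p,
        venn_counts=venn_region_counts(a, b, c),
    )


def overlap_matrix(
    signatures: Sequence[SignatureSet], denominator: str = "union"
) -> pd.DataFrame:
    """Symmetric matrix of pairwise shared-signature percentages."""
    if len(signatures) < 2:
        raise InputError("need at least two signatures")
    labels = [s.cancer_label for s in signatures]
    if len(set(labels)) != len(labels):
        raise InputError(f"duplicate cancer labels in {labels}")
    mat = pd.DataFrame(
        np.full((len(labels), len(labels)), 100.0), index=labels, columns=labels
    )
    for i, si in enumerate(signatures):
        for j in range(i + 1, len(signatures)):
            pct = pairwise_shared(si, signatures[j], denominator).percent_shared
            mat.iloc[i, j] = pct
            mat.iloc[j, i] = pct
    return mat


# ---------------------------------------------------------------------------
# locus-to-gene annotation
# ---------------------------------------------------------------------------


def parse_locus_id(locus_id: str) -> tuple[str, int, int]:
    """Split 'contig:start-end' (1-based inclusive) into 0-based half-open."""
    try:
        contig, span = locus_id.rsplit(":", 1)
        start_s, end_s = span.split("-")
        start, end = int(start_s) - 1, int(end_s)
    except ValueError:
        raise InputError(f"malformed locus_id {locus_id!r}") from None
    if start < 0 or end <= start:
        raise InputError(f"malformed locus_id {locus_id!r}")
    return contig, start, end


def _gff3_attr_name(attrs: str) -> str | None:
    fields = dict(
        kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
    )
    for key in ("Name", "gene_name", "gene", "ID"):
        if key in fields:
            return fields[key]
    return None


def read_annotation(
    path: str | Path, feature_types: set[str] | None = None
) -> list[tuple[str, int, int, str]]:
    """Read gene intervals (contig, start, end, name) from GFF3 or BED."""
    path = Path(path)
    intervals = []
    is_gff = path.suffix.lower() in (".gff", ".gff3")
    feature_types = feature_types or {"gene"}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if is_gff:
                if len(fields) != 9:
                    raise ParseError(
                        f"GFF3 line has {len(fields)} fields, expected 9",
                        lineno,
                    )
                contig, _, ftype, start_s, end_s = fields[:5]
                if ftype not in feature_types:
                    continue
                try:
                    start, end = int(start_s) - 1, int(end_s)
                except ValueError:
                    raise ParseError("non-integer GFF3 coordinates", lineno) from None
                name = _gff3_attr_name(fields[8]) or f"{contig}:{start}-{end}"
            else:
                if len(fields) < 3:
                    raise ParseError("BED line has fewer than 3 fields", lineno)
                contig = fields[0]
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError:
                    raise ParseError("non-integer BED coordinates", lineno) from None
                name = fields[3] if len(fields) > 3 else f"{contig}:{start}-{end}"
            if end <= start:
                raise ParseError(f"empty interval [{start}, {end})", lineno)
            intervals.append((contig, start, end, name))
    return intervals


def annotate_loci(
    loci: Iterable[str],
    annotation: str | Path | Sequence[tuple[str, int, int, str]],
) -> dict[str, list[str]]:
    """Map each locus_id to overlapping gene names ('intergenic' if none).

    Overlap uses half-open interval semantics; gene names are reported in
    deterministic sorted order.
    """
    if isinstance(annotation, (str, Path)):
        intervals = read_annotation(annotation)
    else:
        intervals = list(annotation)
    by_contig: dict[str, list[tuple[int, int, str]]] = {}
    for contig, start, end, name in intervals:
        by_contig.setdefault(contig, []).append((start, end, name))

    result: dict[str, list[str]] = {}
    for locus_id in sorted(set(loci)):
        contig, start, end = parse_locus_id(locus_id)
        hits = sorted(
            {
                name
                for g_start, g_end, name in by_contig.get(contig, [])
                if start < g_end and g_start < end
            }
        )
        result[locus_id] = hits if hits else ["intergenic"]
    return result
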
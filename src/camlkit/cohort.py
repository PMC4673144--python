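"""Cohort assembly and the control population's predominant genotype.

A cohort is a loci x samples matrix of unordered genotype calls for one
population (a cancer, or the non-cancer control set).  The control cohort
defines, per locus, the consensus or predominant genotype: the modal
unordered allele pair among called samples.  Samples whose whole genotype
pair differs from the predominant pair are "non-predominant" (variant)
carriers; those counts feed the per-locus case-control tables.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import InputError, ParseError
from .genotyping import SampleGenotype, read_genotypes

logger = logging.getLogger(__name__)

DEFAULT_MIN_CALLED = 10


@dataclass
class CohortTable:
    """Genotype matrix for one cohort.

    ``genotypes`` maps ``(locus_id, sample_id)`` to the call; absent keys
    are no-calls.  Only genotypes of declared samples may be present.
    """

    cohort_label: str
    samples: list[str] = field(default_factory=list)
    genotypes: dict[tuple[str, str], SampleGenotype] = field(default_factory=dict)

    def __post_init__(self):
        declared = set(self.samples)
        if len(declared) != len(self.samples):
            raise InputError("duplicate sample_id in cohort sample list")
        for (locus_id, sample_id) in self.genotypes:
            if sample_id not in declared:
                raise InputError(
                    f"genotype references undeclared sample {sample_id!r}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def loci(self) -> list[str]:
        return sorted({locus_id for locus_id, _ in self.genotypes})

    def called_pairs(self, locus_id: str) -> list[tuple[int, int]]:
        """Allele pairs of all samples called at the locus."""
        out = []
        for sample_id in self.samples:
            g = self.genotypes.get((locus_id, sample_id))
            if g is not None and g.called:
                out.append(g.alleles)
        return out

    def n_called(self, locus_id: str) -> int:
        return len(self.called_pairs(locus_id))

    @classmethod
    def from_genotypes(
        cls, genotypes: Iterable[SampleGenotype], cohort_label: str
    ) -> "CohortTable":
        table: dict[tuple[str, str], SampleGenotype] = {}
        samples: list[str] = []
        seen = set()
        for g in genotypes:
            key = (g.locus_id, g.sample_id)
            if key in table:
                raise InputError(
                    f"duplicate genotype for locus {g.locus_id!r}, "
                    f"sample {g.sample_id!r}"
                )
            table[key] = g
            if g.sample_id not in seen:
                seen.add(g.sample_id)
                samples.append(g.sample_id)
        return cls(cohort_label, samples, table)


def build_cohort(
    genotype_files: Sequence[str | Path], cohort_label: str
) -> CohortTable:
    """Merge per-sample genotype TSVs into one cohort table.

    The locus set is the union across files; cells missing for a sample are
    treated as no-calls.  A sample_id appearing in more than one file is an
    input error.
    """
    table: dict[tuple[str, str], SampleGenotype] = {}
    samples: list[str] = []
    for path in genotype_files:
        file_samples = set()
        for g in read_genotypes(path):
            file_samples.add(g.sample_id)
            table[(g.locus_id, g.sample_id)] = g
        overlap = file_samples & set(samples)
        if overlap:
            raise InputError(
                f"duplicate sample_id(s) {sorted(overlap)} in {path}"
            )
        samples.extend(sorted(file_samples))
    return CohortTable(cohort_label, samples, table)


def build_cohorts_from_manifest(
    manifest_path: str | Path,
) -> dict[str, CohortTable]:
    """Build one CohortTable per cohort_label from a manifest TSV.

    Columns: sample_id, path, cohort_label.  Relative paths are resolved
    against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    by_label: dict[str, list[Path]] = {}
    with open(manifest_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sample_id", "path", "cohort_label"]:
            raise ParseError(f"unexpected manifest header {header!r}", 1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ParseError("manifest row needs 3 fields", lineno)
            _, path_s, label = fields
            path = Path(path_s)
            if not path.is_absolute():
                path = manifest_path.parent / path
            by_label.setdefault(label, []).append(path)
    return {
        label: build_cohort(paths, label) for label, paths in by_label.items()
    }


@dataclass(frozen=True)
class PredominantGenotype:
    """The modal control genotype at a locus.

    ``tied`` records that more than one genotype attained the modal count;
    ties are broken deterministically towards the pair with the smaller
    total allele length, then the smaller first allele.
    """

    locus_id: str
    genotype: tuple[int, int]
    support_count: int
    call_count: int
    tied: bool

    def __post_init__(self):
        if self.support_count > self.call_count:
            raise InputError("support_count cannot exceed call_count")


def predominant_genotype(
    control: CohortTable,
    locus_id: str,
    min_called: int = DEFAULT_MIN_CALLED,
) -> PredominantGenotype | None:
    """Modal unordered genotype among called control samples, or None.

    Returns None when the control cohort has fewer than ``min_called``
    called genotypes at the locus; such loci are unevaluable and excluded
    from association testing.
    """
    pairs = control.called_pairs(locus_id)
    if len(pairs) < min_called:
        return None
    counts = Counter(pairs)
    top = max(counts.values())
    modal = [g for g, n in counts.items() if n == top]
    winner = min(modal, key=lambda g: (g[0] + g[1], g[0]))
    return PredominantGenotype(
        locus_id=locus_id,
        genotype=winner,
        support_count=top,
        call_count=len(pairs),
        tied=len(modal) > 1,
    )


def nonpredominant_counts(
    cohort: CohortTable,
    predominant: PredominantGenotype | None,
    locus_id: str,
) -> tuple[int, int, int]:
    """(n_variant, n_predominant, n_called) over called samples at a locus.

    A sample is a variant (non-predominant) carrier when its unordered
    genotype pair differs from the predominant pair; comparison is
    genotype-level, so a heterozygote equals the predominant pair in either
    allele order.
    """
    if predominant is None:
        raise InputError(
            f"no predominant genotype defined for locus {locus_id!r}"
        )
    pairs = cohort.called_pairs(locus_id)
    n_pred = sum(1 for pair in pairs if pair == predominant.genotype)
    n_var = len(pairs) - n_pred
    return n_var, n_pred, len(pairs)


# ---------------------------------------------------------------------------
# predominant-genotype TSV I/O
# ---------------------------------------------------------------------------

_PRED_COLUMNS = ["locus_id", "allele_a", "allele_b", "support", "calls", "tied"]


def write_predominant(
    predominants: Iterable[PredominantGenotype], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PRED_COLUMNS) + "\n")
        for p in predominants:
            fh.write(
                f"{p.locus_id}\t{p.genotype[0]}\t{p.genotype[1]}\t"
                f"{p.support_count}\t{p.call_count}\t{int(p.tied)}\n"
            )


def read_predominant(path: str | Path) -> dict[str, PredominantGenotype]:
    out: dict[str, PredominantGenotype] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PRED_COLUMNS:
            raise ParseError(f"unexpected header {header!r}", 1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_PRED_COLUMNS):
                raise ParseError("wrong field count", lineno)
            locus_id, a, b, support, calls, tied = fields
            if locus_id in out:
                raise ParseError(f"duplicate locus {locus_id!r}", lineno)
            try:
                out[locus_id] = PredominantGenotype(
                    locus_id,
                    (int(a), int(b)),
                    int(support),
                    int(calls),
                    bool(int(tied)),
                )
            except ValueError:
                raise ParseError(f"malformed row {fields!r}", lineno) from None
    return out
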
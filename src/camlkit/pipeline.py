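"""End-to-end study runner: scan -> genotype -> cohort -> associate -> overlap.

Drives the whole discovery pipeline from on-disk inputs (reference FASTA,
optional catalog, cohort manifest of per-sample BAMs) to per-cancer
association tables, signature sets and cross-set overlap summaries.  Each
stage is the corresponding library function; this module only sequences
them and writes their outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from Bio import SeqIO

from .association import (
    AssociationResult,
    DEFAULT_ALPHA,
    SignatureSet,
    run_association,
    write_associations,
    write_signature,
)
from .cohort import (
    CohortTable,
    DEFAULT_MIN_CALLED,
    predominant_genotype,
    write_predominant,
)
from .errors import InputError, ParseError
from .genotyping import GenotypingParams, genotype_sample, write_genotypes
from .overlap import OverlapResult, overlap_matrix, pairwise_shared, three_set_overlap_test
from .repeat_catalog import (
    FilterRules,
    MicrosatelliteLocus,
    ScanParams,
    filter_catalog,
    read_catalog,
    scan_reference,
    write_catalog,
)

logger = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def read_manifest(path: str | Path) -> list[tuple[str, Path, str]]:
    """Rows of (sample_id, bam_path, cohort_label); paths resolved."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sample_id", "path", "cohort_label"]:
            raise ParseError(f"unexpected manifest header {header!r}", 1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ParseError("manifest row needs 3 fields", lineno)
            sample_id, p, label = fields
            bam = Path(p)
            if not bam.is_absolute():
                bam = path.parent / bam
            rows.append((sample_id, bam, label))
    return rows


@dataclass
class StudyResult:
    catalog: list[MicrosatelliteLocus]
    cohorts: dict[str, CohortTable]
    associations: dict[str, AssociationResult]
    signatures: dict[str, SignatureSet]
    overlaps: list[OverlapResult] = field(default_factory=list)
    overlap_table: object | None = None  # pandas DataFrame when >= 2 sets


def run_study(
    fasta: str | Path,
    manifest: str | Path,
    out_dir: str | Path,
    catalog_bed: str | Path | None = None,
    control_label: str = "control",
    scan_params: ScanParams | None = None,
    filter_rules: FilterRules | None = None,
    genotyping_params: GenotypingParams | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_called: int = DEFAULT_MIN_CALLED,
    reference_sets: Mapping[str, frozenset | set] | None = None,
) -> StudyResult:
    """Run the full pipeline, writing every stage's output under out_dir.

    When ``catalog_bed`` is given the catalog is loaded instead of scanned.
    ``reference_sets`` are externally supplied locus lists (e.g. previously
    published CAML) included alongside the discovered signatures in the
    overlap stage.  The three-set overlap test runs whenever at least three
    sets are available, with the first cancer's tested-locus count as the
    draw universe.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- scan ---
    if catalog_bed is not None:
        catalog = read_catalog(catalog_bed)
    else:
        contigs = read_fasta(fasta)
        catalog = scan_reference(contigs, scan_params)
        catalog = filter_catalog(catalog, contigs, filter_rules)
        write_catalog(catalog, out_dir / "catalog.bed")
    if not catalog:
        raise InputError("empty locus catalog")
    logger.info("catalog: %d loci", len(catalog))

    # --- genotype ---
    geno_dir = out_dir / "genotypes"
    geno_dir.mkdir(exist_ok=True)
    by_label: dict[str, list] = {}
    for sample_id, bam, label in read_manifest(manifest):
        genotypes = genotype_sample(bam, catalog, sample_id, genotyping_params)
        write_genotypes(genotypes, geno_dir / f"{sample_id}.geno.tsv")
        by_label.setdefault(label, []).extend(genotypes)
    if control_label not in by_label:
        raise InputError(
            f"manifest has no cohort labeled {control_label!r} "
            f"(labels: {sorted(by_label)})"
        )

    # --- cohorts & consensus ---
    cohorts = {
        label: CohortTable.from_genotypes(genos, label)
        for label, genos in by_label.items()
    }
    control = cohorts[control_label]
    predominant = {}
    for locus in catalog:
        pg = predominant_genotype(control, locus.locus_id, min_called)
        if pg is not None:
            predominant[locus.locus_id] = pg
    write_predominant(
        [predominant[k] for k in sorted(predominant)],
        out_dir / "predominant.tsv",
    )

    # --- association per cancer ---
    associations: dict[str, AssociationResult] = {}
    signatures: dict[str, SignatureSet] = {}
    for label, table in cohorts.items():
        if label == control_label:
            continue
        result = run_association(table, control, predominant, alpha, min_called)
        associations[label] = result
        signatures[label] = result.signature
        write_associations(result.associations, out_dir / f"{label}.assoc.tsv")
        write_signature(result.signature, out_dir / f"{label}.sig")
        with open(out_dir / f"{label}.summary.json", "w") as fh:
            json.dump(result.summary, fh, indent=2, sort_keys=True)

    # --- overlap ---
    all_sets: list[SignatureSet] = [signatures[k] for k in sorted(signatures)]
    for name in sorted(reference_sets or {}):
        all_sets.append(
            SignatureSet(name, frozenset(reference_sets[name]), alpha, 0)
        )
    overlaps: list[OverlapResult] = []
    table = None
    if len(all_sets) >= 2:
        table = overlap_matrix(all_sets)
        table.to_csv(out_dir / "overlap_matrix.tsv", sep="\t")
        for i in range(len(all_sets)):
            for j in range(i + 1, len(all_sets)):
                overlaps.append(pairwise_shared(all_sets[i], all_sets[j]))
    if len(all_sets) >= 3:
        universe = next(iter(associations.values())).summary["n_tested"]
        result = three_set_overlap_test(all_sets[:3], universe)
        overlaps.append(result)
        with open(out_dir / "venn.json", "w") as fh:
            json.dump(
                {
                    "labels": list(result.labels),
                    "venn_counts": result.venn_counts,
                    "p_value": result.p_value,
                    "universe_size": result.universe_size,
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    return StudyResult(catalog, cohorts, associations, signatures, overlaps, table)
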
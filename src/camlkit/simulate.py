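"""Synthetic study generator: references, cohorts and spanning reads.

The real study genotyped controlled-access exomes (cancer cohorts plus
population controls).  This module generates a fully self-contained stand-in
at desk scale: reference contigs of repeat-free background with planted
microsatellite tracts, diploid repeat-length genotypes drawn per cohort from
an allele-ladder model with optional planted case/control frequency
differences, and spanning reads with optional tract-length slippage noise.
Every operation is deterministic given the configured seed.

Model summary
-------------
* Reference: background sequence is rejection-sampled so that the scanner
  detects exactly the planted tracts and nothing else; each planted tract
  has a primitive 1-3 nt motif repeated to 8-18 nt.
* Genotypes: at each locus the control-predominant genotype is the
  homozygous reference-length pair.  A sample is a variant carrier with its
  cohort's variant frequency; variant genotypes draw two alleles i.i.d.
  (Hardy-Weinberg pairing) from a ladder centred on the reference length
  with steps of one motif unit and geometrically decaying weight,
  conditioned on the pair differing from the predominant pair.
* Reads: per locus, spanning-read depth follows a configurable
  mean/dispersion model; each read carries one of the sample's two alleles
  (50/50) and, with probability ``noise_epsilon``, slips by one motif unit
  in either direction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pysam

from .errors import ConfigError
from .genotyping import CallStatus, SampleGenotype
from .repeat_catalog import (
    FilterRules,
    MicrosatelliteLocus,
    ScanParams,
    canonical_motif,
    filter_catalog,
    find_repeats,
    is_primitive,
)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedEffect:
    """A locus with different variant-genotype frequencies per cohort."""

    locus_index: int
    control_variant_freq: float
    case_variant_freq: float

    def __post_init__(self):
        for f in (self.control_variant_freq, self.case_variant_freq):
            if not (0.0 <= f <= 1.0):
                raise ConfigError("variant frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation parameters.

    Cohort sizes default to the real study's control arm (390 samples) and
    its largest single-disease glioma cohort (252); the desk-scale fixture
    (:func:`default_fixture_config`) overrides them.  ``depth_dispersion``
    is the variance-to-mean ratio of spanning-read depth: 0 gives constant
    depth, 1 Poisson, >1 negative binomial.
    """

    seed: int = 0
    n_loci: int = 1000
    n_cases: int = 252
    n_controls: int = 390
    planted_effect_loci: tuple[PlantedEffect, ...] = ()
    background_variant_freq: float = 0.05
    modal_allele_prob: float = 0.6
    ladder_decay: float = 0.5
    ladder_span: int = 2
    mean_depth: float = 30.0
    depth_dispersion: float = 1.0
    noise_epsilon: float = 0.0
    read_length: int = 100
    locus_spacing: int = 60
    contig_name: str = "sim1"
    case_label: str = "case"
    control_label: str = "control"

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigError("cohort sizes must be >= 1")
        if not (0.0 <= self.background_variant_freq <= 1.0):
            raise ConfigError("background_variant_freq must lie in [0, 1]")
        if not (0.0 <= self.noise_epsilon < 1.0):
            raise ConfigError("noise_epsilon must lie in [0, 1)")
        if not (0.0 < self.modal_allele_prob < 1.0):
            raise ConfigError("modal_allele_prob must lie in (0, 1)")
        for eff in self.planted_effect_loci:
            if not (0 <= eff.locus_index < self.n_loci):
                raise ConfigError(
                    f"planted locus index {eff.locus_index} out of range"
                )


@dataclass
class SimulatedReference:
    """A simulated reference contig with its planted locus catalog."""

    contig_name: str
    sequence: str
    catalog: list[MicrosatelliteLocus]

    @property
    def contigs(self) -> dict[str, str]:
        return {self.contig_name: self.sequence}


@dataclass
class TruthTable:
    """Ground truth of one simulated study."""

    predominant: dict[str, tuple[int, int]]
    genotypes: dict[tuple[str, str], tuple[int, int]]
    planted: list[tuple[str, float, float]]  # locus_id, control vf, case vf
    cohorts: dict[str, list[str]]


def _rng(config: SimulationConfig, *stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stage])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _random_motif(rng: np.random.Generator) -> tuple[str, int]:
    """A primitive repeat unit and a copy count giving an 8-18 nt tract."""
    k = int(rng.integers(1, 4))
    while True:
        unit = _random_seq(rng, k)
        if is_primitive(unit):
            break
    copies = {1: (8, 12), 2: (6, 9), 3: (4, 6)}[k]
    c = int(rng.integers(copies[0], copies[1] + 1))
    return unit, c


def simulate_reference(
    config: SimulationConfig, scan_params: ScanParams | None = None
) -> SimulatedReference:
    """Simulate a contig whose scanner output is exactly the planted catalog.

    Background chunks are rejection-resampled until a full-contig scan
    detects the planted tracts and nothing else (this guards against chance
    background repeats and against background bases extending a planted
    tract's repeat phase), and until every planted locus passes the flank
    uniqueness filter.
    """
    scan_params = scan_params or ScanParams()
    rng = _rng(config, 1)
    n = config.n_loci

    units = []
    tracts = []
    for _ in range(n):
        unit, copies = _random_motif(rng)
        units.append(unit)
        tracts.append(unit * copies)

    def clean_chunk(length: int) -> str:
        # locally repeat-free background; junction effects are handled by
        # the global verification loop below
        for _ in range(200):
            s = _random_seq(rng, length)
            if not find_repeats(s, "c", scan_params):
                return s
        raise ConfigError(
            "could not sample repeat-free background; relax scan params"
        )

    # leading/trailing chunks are read_length long so reads never run off
    pad = max(config.locus_spacing, config.read_length)
    chunk_lens = [pad] + [config.locus_spacing] * max(0, n - 1) + [pad]
    chunks = [clean_chunk(ln) for ln in chunk_lens]

    # fixed layout: chunk[0] tract[0] chunk[1] tract[1] ... chunk[n]
    starts = []
    pos = 0
    for i in range(n):
        pos += chunk_lens[i]
        starts.append(pos)
        pos += len(tracts[i])
    planted_intervals = [
        (starts[i], starts[i] + len(tracts[i])) for i in range(n)
    ]

    def assemble() -> str:
        parts = []
        for i in range(n):
            parts.append(chunks[i])
            parts.append(tracts[i])
        parts.append(chunks[n])
        return "".join(parts)

    def chunk_span(idx: int) -> tuple[int, int]:
        s = sum(chunk_lens[:idx]) + sum(len(t) for t in tracts[:idx])
        return s, s + chunk_lens[idx]

    planted_set = set(planted_intervals)
    for attempt in range(200):
        seq = assemble()
        found = {
            (loc.start, loc.end) for loc in find_repeats(seq, "x", scan_params)
        }
        if found == planted_set:
            break
        # resample only chunks whose sequence participates in a spurious or
        # boundary-extended detection; planted intervals missing from the
        # scan overlap no chunk and are fixed via their detected counterpart
        resample = set()
        for s, e in found - planted_set:
            for idx in range(n + 1):
                cs, ce = chunk_span(idx)
                if s < ce and cs < e:
                    resample.add(idx)
        if not resample:  # pragma: no cover - should not happen
            raise ConfigError("reference simulation failed to converge")
        for idx in resample:
            chunks[idx] = clean_chunk(chunk_lens[idx])
    else:
        raise ConfigError(
            "could not place loci without spurious repeats at the requested "
            "density; increase locus_spacing"
        )

    seq = assemble()
    catalog = []
    for (s, e), unit in zip(planted_intervals, units):
        catalog.append(
            MicrosatelliteLocus(
                contig=config.contig_name,
                start=s,
                end=e,
                motif=canonical_motif(unit),
                repeat_unit=unit,
                left_flank=seq[max(0, s - scan_params.flank_len) : s],
                right_flank=seq[e : e + scan_params.flank_len],
            )
        )

    ref = SimulatedReference(config.contig_name, seq, catalog)
    if n:
        kept = filter_catalog(catalog, ref.contigs, FilterRules())
        if len(kept) != len(catalog):  # pragma: no cover - vanishingly rare
            raise ConfigError(
                "simulated flanks are not unique; re-run with another seed"
            )
    return ref


# ---------------------------------------------------------------------------
# cohort genotypes
# ---------------------------------------------------------------------------


def _ladder(config: SimulationConfig, motif_len: int, ref_len: int):
    """Allele lengths and probabilities of the per-locus ladder model."""
    span = config.ladder_span
    offsets = [m for m in range(-span, span + 1)]
    weights = []
    for m in offsets:
        if m == 0:
            weights.append(config.modal_allele_prob)
        else:
            weights.append(config.ladder_decay ** (abs(m) - 1))
    w = np.array(weights, dtype=float)
    side = w[np.array(offsets) != 0]
    w[np.array(offsets) != 0] = (
        (1.0 - config.modal_allele_prob) * side / side.sum()
    )
    lengths = np.array(
        [max(0, ref_len + m * motif_len) for m in offsets], dtype=int
    )
    return lengths, w


def _draw_variant_pairs(
    rng: np.random.Generator,
    lengths: np.ndarray,
    probs: np.ndarray,
    modal: int,
    size: int,
) -> list[tuple[int, int]]:
    """I.i.d. allele pairs conditioned on differing from (modal, modal)."""
    pairs: list[tuple[int, int]] = []
    need = size
    while need > 0:
        a = rng.choice(lengths, size=2 * need, p=probs).reshape(-1, 2)
        for x, y in a:
            if x == modal and y == modal:
                continue
            pairs.append((int(min(x, y)), int(max(x, y))))
            if len(pairs) == size:
                break
        need = size - len(pairs)
    return pairs


def simulate_cohort_genotypes(
    config: SimulationConfig, ref: SimulatedReference
) -> tuple[dict[str, list[SampleGenotype]], TruthTable]:
    """Draw diploid genotypes for the control and case cohorts.

    Returns per-cohort genotype lists (every sample called at every locus)
    and the truth table recording predominant pairs, per-sample genotypes
    and planted effect loci.
    """
    rng = _rng(config, 2)
    controls = [f"ctrl{i:04d}" for i in range(config.n_controls)]
    cases = [f"{config.case_label}{i:04d}" for i in range(config.n_cases)]
    cohorts = {config.control_label: controls, config.case_label: cases}
    planted = {e.locus_index: e for e in config.planted_effect_loci}

    depth = int(round(config.mean_depth))
    genotype_lists: dict[str, list[SampleGenotype]] = {
        config.control_label: [],
        config.case_label: [],
    }
    truth_geno: dict[tuple[str, str], tuple[int, int]] = {}
    predominant: dict[str, tuple[int, int]] = {}
    planted_records: list[tuple[str, float, float]] = []

    for idx, locus in enumerate(ref.catalog):
        ref_len = locus.ref_tract_length
        lengths, probs = _ladder(config, len(locus.repeat_unit), ref_len)
        predominant[locus.locus_id] = (ref_len, ref_len)
        effect = planted.get(idx)
        if effect is not None:
            planted_records.append(
                (
                    locus.locus_id,
                    effect.control_variant_freq,
                    effect.case_variant_freq,
                )
            )
        for label, samples in (
            (config.control_label, controls),
            (config.case_label, cases),
        ):
            if effect is None:
                vf = config.background_variant_freq
            elif label == config.control_label:
                vf = effect.control_variant_freq
            else:
                vf = effect.case_variant_freq
            is_variant = rng.random(len(samples)) < vf
            n_var = int(is_variant.sum())
            variant_pairs = _draw_variant_pairs(
                rng, lengths, probs, ref_len, n_var
            )
            vi = 0
            for sample_id, variant in zip(samples, is_variant):
                pair = variant_pairs[vi] if variant else (ref_len, ref_len)
                if variant:
                    vi += 1
                truth_geno[(locus.locus_id, sample_id)] = pair
                genotype_lists[label].append(
                    SampleGenotype(
                        locus.locus_id, sample_id, pair, depth, CallStatus.CALLED
                    )
                )

    truth = TruthTable(predominant, truth_geno, planted_records, cohorts)
    return genotype_lists, truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def _draw_depth(config: SimulationConfig, rng: np.random.Generator) -> int:
    mu = config.mean_depth
    d = config.depth_dispersion
    if d <= 0:
        return int(round(mu))
    if d == 1.0:
        return int(rng.poisson(mu))
    r = mu / (d - 1.0)
    return int(rng.negative_binomial(r, 1.0 / d))


def simulate_reads(
    config: SimulationConfig,
    ref: SimulatedReference,
    truth: TruthTable,
    sample_id: str,
    out_path: str | Path,
    sample_index: int = 0,
) -> Path:
    """Write spanning reads for one sample as sorted BAM (or SAM) + index.

    Each locus receives ``depth_model`` spanning reads; a read carries one
    of the sample's two alleles (chosen 50/50), slipping one motif unit with
    probability ``noise_epsilon``.  Roughly half the reads are flagged
    reverse-strand (sequence stored in reference orientation, as alignments
    do).  Deterministic given the config seed and sample index.
    """
    out_path = Path(out_path)
    rng = _rng(config, 3, sample_index)
    seq = ref.sequence
    anchor_pad = 12  # anchor word (10 nt) + margin inside the read

    reads = []  # (pos, name, flag, read_seq, cigartuples)
    for li, locus in enumerate(ref.catalog):
        pair = truth.genotypes.get((locus.locus_id, sample_id))
        if pair is None:
            continue
        k = len(locus.repeat_unit)
        ref_len = locus.ref_tract_length
        max_allele = max(pair) + k  # worst case after one slip
        if config.read_length < max_allele + 2 * anchor_pad:
            raise ConfigError(
                f"read_length {config.read_length} too short to span locus "
                f"{locus.locus_id} (allele up to {max_allele} nt)"
            )
        depth = _draw_depth(config, rng)
        # balanced-random allele assignment: each read carries either allele
        # with equal marginal probability, but counts split evenly so a
        # noise-free heterozygote at calling depth is recovered by
        # construction (a per-read coin flip can starve one allele below
        # the stutter gate)
        allele_vec = [pair[0]] * ((depth + 1) // 2) + [pair[1]] * (depth // 2)
        allele_vec = list(rng.permuted(np.array(allele_vec, dtype=int)))
        for ri in range(depth):
            allele = int(allele_vec[ri])
            if config.noise_epsilon and rng.random() < config.noise_epsilon:
                allele = max(0, allele + (k if rng.random() < 0.5 else -k))
            tract_seq = (locus.repeat_unit * (allele // k + 2))[:allele]
            m_left_max = min(config.read_length - allele - anchor_pad, locus.start)
            m_left = int(rng.integers(anchor_pad, m_left_max + 1))
            right_len = config.read_length - m_left - allele
            read_seq = (
                seq[locus.start - m_left : locus.start]
                + tract_seq
                + seq[locus.end : locus.end + right_len]
            )
            cig = [(0, m_left + min(allele, ref_len))]
            if allele > ref_len:
                cig.append((1, allele - ref_len))
            elif allele < ref_len:
                cig.append((2, ref_len - allele))
            cig.append((0, right_len))
            flag = 16 if rng.random() < 0.5 else 0
            reads.append(
                (
                    locus.start - m_left,
                    f"{sample_id}.L{li}.{ri}",
                    flag,
                    read_seq,
                    cig,
                )
            )

    reads.sort(key=lambda r: (r[0], r[1]))
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref.contig_name, "LN": len(seq)}],
    }
    mode = "w" if out_path.suffix == ".sam" else "wb"
    with pysam.AlignmentFile(str(out_path), mode, header=header) as bam:
        for pos, name, flag, read_seq, cig in reads:
            seg = pysam.AlignedSegment(bam.header)
            seg.query_name = name
            seg.flag = flag
            seg.reference_name = ref.contig_name
            seg.reference_start = pos
            seg.mapping_quality = 60
            seg.cigartuples = cig
            seg.query_sequence = read_seq
            bam.write(seg)
    if mode == "wb":
        pysam.index(str(out_path))
    return out_path


# ---------------------------------------------------------------------------
# end-to-end fixture
# ---------------------------------------------------------------------------


@dataclass
class FixtureBundle:
    """Paths and truth for one simulated desk-scale study."""

    config: SimulationConfig
    fasta: Path
    catalog_bed: Path
    manifest: Path
    truth_json: Path
    bam_dir: Path
    reference: SimulatedReference
    truth: TruthTable


def write_fasta(contigs: Mapping[str, str], path: str | Path, width: int = 60):
    with open(path, "w") as fh:
        for name in contigs:
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_json(truth: TruthTable, path: str | Path) -> None:
    payload = {
        "predominant": {k: list(v) for k, v in truth.predominant.items()},
        "genotypes": {
            f"{locus}|{sample}": list(pair)
            for (locus, sample), pair in truth.genotypes.items()
        },
        "planted": [list(p) for p in truth.planted],
        "cohorts": truth.cohorts,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=None, sort_keys=True)


def read_truth_json(path: str | Path) -> TruthTable:
    with open(path) as fh:
        payload = json.load(fh)
    return TruthTable(
        predominant={
            k: (v[0], v[1]) for k, v in payload["predominant"].items()
        },
        genotypes={
            (k.split("|")[0], k.split("|")[1]): (v[0], v[1])
            for k, v in payload["genotypes"].items()
        },
        planted=[(p[0], p[1], p[2]) for p in payload["planted"]],
        cohorts=payload["cohorts"],
    )


def default_fixture_config(seed: int = 0) -> SimulationConfig:
    """The standard desk-scale study: 300 loci, 60+60 samples, 10 effects.

    Ten planted loci (evenly spaced through the catalog) carry a strong
    case/control difference (variant genotype frequency 0.55 vs 0.05); a
    binomial power calculation puts per-locus recovery above 99% at
    60-sample cohorts under the FDR < 1/X cutoff, so the fixture serves as
    a stable regression baseline.  The remaining 290 loci are null at the
    background frequency.
    """
    n_loci = 300
    planted = tuple(
        PlantedEffect(idx, 0.05, 0.55)
        for idx in range(15, n_loci, 30)
    )
    return SimulationConfig(
        seed=seed,
        n_loci=n_loci,
        n_cases=60,
        n_controls=60,
        planted_effect_loci=planted,
        background_variant_freq=0.05,
        mean_depth=30.0,
        depth_dispersion=1.0,
        noise_epsilon=0.01,
    )


def end_to_end_fixture(
    out_dir: str | Path, config: SimulationConfig | None = None
) -> FixtureBundle:
    """Generate one complete simulated study on disk.

    Writes the reference FASTA, the truth catalog (BED + sidecar), one
    sorted+indexed BAM per sample, a cohort manifest TSV and the truth
    JSON.  Deterministic given ``config.seed``.
    """
    from .repeat_catalog import write_catalog

    config = config or default_fixture_config()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bam_dir = out_dir / "bams"
    bam_dir.mkdir(exist_ok=True)

    ref = simulate_reference(config)
    fasta = out_dir / "reference.fasta"
    write_fasta(ref.contigs, fasta)
    catalog_bed = out_dir / "catalog.bed"
    write_catalog(ref.catalog, catalog_bed)

    _, truth = simulate_cohort_genotypes(config, ref)

    manifest = out_dir / "manifest.tsv"
    sample_index = 0
    with open(manifest, "w") as mf:
        mf.write("sample_id\tpath\tcohort_label\n")
        for label, samples in truth.cohorts.items():
            for sample_id in samples:
                bam_path = bam_dir / f"{sample_id}.bam"
                simulate_reads(
                    config, ref, truth, sample_id, bam_path, sample_index
                )
                mf.write(f"{sample_id}\tbams/{sample_id}.bam\t{label}\n")
                sample_index += 1

    truth_json = out_dir / "truth.json"
    write_truth_json(truth, truth_json)
    logger.info(
        "fixture written to %s: %d loci, %d samples",
        out_dir,
        config.n_loci,
        sum(len(s) for s in truth.cohorts.values()),
    )
    return FixtureBundle(
        config, fasta, catalog_bed, manifest, truth_json, bam_dir, ref, truth
    )
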
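"""Per-locus case-control association and signature construction.

For every locus evaluable in both cohorts, the 2x2 table

    a = cancer samples with a non-predominant genotype
    b = cancer samples with the predominant genotype
    c = control samples with a non-predominant genotype
    d = control samples with the predominant genotype

is tested with a two-sided Fisher exact test.  P-values are adjusted by
Benjamini-Hochberg, and a locus enters the cancer's signature when it is
significant (p <= alpha, default 0.01) AND its adjusted p-value passes the
FDR cutoff ``1/X``, where X is the number of tested loci with p < 1.  Loci
significant at alpha but failing the cutoff form the non-signature set —
suggestive loci that may reach signature status in larger cohorts.
Relative risk is the ratio of non-predominant carrier percentages, cancer
over control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .cohort import (
    CohortTable,
    DEFAULT_MIN_CALLED,
    PredominantGenotype,
    nonpredominant_counts,
    predominant_genotype,
)
from .errors import InputError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01

#: relative tolerance used when comparing table probabilities to the
#: observed table's probability in the two-sided (point-probability) rule
FISHER_RELATIVE_TOL = 1e-7


class LocusClass(str, Enum):
    SIGNATURE = "signature"
    NON_SIGNATURE = "non_signature"
    NON_SIGNIFICANT = "non_significant"


@lru_cache(maxsize=1 << 16)
def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value by the point-probability rule.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's (within
    relative tolerance ``FISHER_RELATIVE_TOL``).
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise InputError("cells must be non-negative integers")
    n_total = a + b + c + d
    if n_total == 0:
        raise InputError("empty 2x2 table")
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 - (n_total - col1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n_total, col1, row1)
    p_obs = pmf[a - lo]
    include = pmf <= p_obs * (1.0 + FISHER_RELATIVE_TOL)
    if include.all():
        return 1.0  # observed table is modal: the tail is the whole mass
    return min(1.0, float(pmf[include].sum()))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adjusted(i) = min over ranks k >= rank(i) of p(k) * n / k, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, n + 1)
    raw = p[order] * n / ranks
    adjusted_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(n)
    adjusted[order] = adjusted_sorted
    return adjusted


def signature_cutoff(
    p_values: Sequence[float],
    adjusted: Sequence[float] | None = None,
) -> np.ndarray:
    """Per-locus boolean FDR decisions under the ``FDR < 1/X`` rule.

    X is the number of loci with p < 1; a locus passes the cutoff iff its
    BH-adjusted p-value is below 1/X.  With X == 0 no locus passes (empty
    signature).
    """
    p = np.asarray(p_values, dtype=float)
    adj = bh_adjust(p) if adjusted is None else np.asarray(adjusted, dtype=float)
    x = int(np.sum(p < 1.0))
    if x == 0:
        return np.zeros(p.size, dtype=bool)
    return adj < 1.0 / x


def relative_risk(a: int, b: int, c: int, d: int) -> float:
    """Ratio of non-predominant carrier fractions, cancer over control.

    Returns ``inf`` when only the cancer cohort carries variants (c == 0,
    a > 0) and ``nan`` (serialized "NA") when neither cohort does.
    """
    if a + b == 0 or c + d == 0:
        raise InputError("relative risk needs both cohort margins positive")
    if a == 0 and c == 0:
        return math.nan
    if c == 0:
        return math.inf
    return (a / (a + b)) / (c / (c + d))


def format_rr(rr: float) -> str:
    if math.isnan(rr):
        return "NA"
    if math.isinf(rr):
        return "Inf"
    return f"{rr:.6g}"


@dataclass
class LocusAssociation:
    """Per-locus 2x2 counts, test results and class label."""

    locus_id: str
    a: int
    b: int
    c: int
    d: int
    p_value: float
    p_adjusted: float = math.nan
    rr: float = math.nan
    klass: LocusClass | None = None


@dataclass(frozen=True)
class SignatureSet:
    """The cancer-associated microsatellite loci (CAML) of one cancer."""

    cancer_label: str
    loci: frozenset[str]
    alpha: float
    n_tested: int

    def __len__(self) -> int:
        return len(self.loci)


def classify_loci(
    associations: Sequence[LocusAssociation],
    alpha: float = DEFAULT_ALPHA,
    cutoff_decisions: Sequence[bool] | None = None,
) -> list[LocusAssociation]:
    """Assign each tested locus to exactly one class (in place).

    signature: p <= alpha and the FDR cutoff passes; non_signature:
    p <= alpha but the cutoff fails; otherwise non_significant.
    """
    if cutoff_decisions is None:
        cutoff_decisions = signature_cutoff(
            [x.p_value for x in associations],
            [x.p_adjusted for x in associations],
        )
    for assoc, passes in zip(associations, cutoff_decisions):
        if assoc.p_value <= alpha:
            assoc.klass = (
                LocusClass.SIGNATURE if passes else LocusClass.NON_SIGNATURE
            )
        else:
            assoc.klass = LocusClass.NON_SIGNIFICANT
    return list(associations)


@dataclass(frozen=True)
class AssociationResult:
    associations: list[LocusAssociation]
    signature: SignatureSet
    summary: dict


def run_association(
    cancer: CohortTable,
    control: CohortTable,
    predominant: Mapping[str, PredominantGenotype] | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_called: int = DEFAULT_MIN_CALLED,
) -> AssociationResult:
    """Test every jointly evaluable locus and assemble the signature.

    A locus is tested when both cohorts have at least ``min_called`` called
    genotypes and the control predominant genotype is defined.
    """
    loci = sorted(set(control.loci()) & set(cancer.loci()))
    if predominant is None:
        predominant = {}
        for locus_id in loci:
            pg = predominant_genotype(control, locus_id, min_called)
            if pg is not None:
                predominant[locus_id] = pg

    associations: list[LocusAssociation] = []
    for locus_id in loci:
        pg = predominant.get(locus_id)
        if pg is None:
            continue
        if cancer.n_called(locus_id) < min_called:
            continue
        a, b, n1 = nonpredominant_counts(cancer, pg, locus_id)
        c, d, n0 = nonpredominant_counts(control, pg, locus_id)
        if n0 < min_called:
            continue
        p = fisher_exact_two_sided(a, b, c, d)
        associations.append(
            LocusAssociation(locus_id, a, b, c, d, p, rr=relative_risk(a, b, c, d))
        )
    if not associations:
        raise InputError(
            f"no locus is evaluable in both {cancer.cohort_label!r} and "
            f"{control.cohort_label!r}"
        )

    p_values = [x.p_value for x in associations]
    adjusted = bh_adjust(p_values)
    for assoc, adj in zip(associations, adjusted):
        assoc.p_adjusted = float(adj)
    decisions = signature_cutoff(p_values, adjusted)
    classify_loci(associations, alpha, decisions)

    signature = SignatureSet(
        cancer_label=cancer.cohort_label,
        loci=frozenset(
            x.locus_id for x in associations if x.klass is LocusClass.SIGNATURE
        ),
        alpha=alpha,
        n_tested=len(associations),
    )
    x_count = int(np.sum(np.asarray(p_values) < 1.0))
    summary = {
        "cancer_label": cancer.cohort_label,
        "control_label": control.cohort_label,
        "n_tested": len(associations),
        "n_significant": sum(1 for x in associations if x.p_value <= alpha),
        "n_signature": len(signature),
        "n_non_signature": sum(
            1 for x in associations if x.klass is LocusClass.NON_SIGNATURE
        ),
        "alpha": alpha,
        "X": x_count,
        "fdr_cutoff": (1.0 / x_count) if x_count else None,
    }
    logger.info(
        "%s vs %s: %d loci tested, %d significant, %d signature CAML",
        cancer.cohort_label,
        control.cohort_label,
        summary["n_tested"],
        summary["n_significant"],
        summary["n_signature"],
    )
    return AssociationResult(associations, signature, summary)


# ---------------------------------------------------------------------------
# association TSV I/O
# ---------------------------------------------------------------------------

_ASSOC_COLUMNS = [
    "locus_id", "a", "b", "c", "d", "p", "p_adj", "RR", "class",
]


def write_associations(
    associations: Iterable[LocusAssociation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ASSOC_COLUMNS) + "\n")
        for x in associations:
            klass = x.klass.value if x.klass is not None else ""
            fh.write(
                f"{x.locus_id}\t{x.a}\t{x.b}\t{x.c}\t{x.d}\t"
                f"{x.p_value:.6e}\t{x.p_adjusted:.6e}\t{format_rr(x.rr)}\t"
                f"{klass}\n"
            )


def read_associations(path: str | Path) -> list[LocusAssociation]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ASSOC_COLUMNS:
            raise InputError(f"unexpected association header {header!r}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rr = {"NA": math.nan, "Inf": math.inf}.get(f[7])
            if rr is None:
                rr = float(f[7])
            out.append(
                LocusAssociation(
                    f[0], int(f[1]), int(f[2]), int(f[3]), int(f[4]),
                    float(f[5]), float(f[6]), rr,
                    LocusClass(f[8]) if f[8] else None,
                )
            )
    return out


def write_signature(signature: SignatureSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for locus_id in sorted(signature.loci):
            fh.write(locus_id + "\n")


def read_signature(
    path: str | Path, cancer_label: str, alpha: float = DEFAULT_ALPHA,
    n_tested: int = 0,
) -> SignatureSet:
    with open(path) as fh:
        loci = frozenset(line.strip() for line in fh if line.strip())
    return SignatureSet(cancer_label, loci, alpha, n_tested)
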
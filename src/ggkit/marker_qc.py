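"""Two-stage marker quality control.

Stage 1 (:func:`filter_candidates`) screens annotated candidate SNPs on
contig-level discovery criteria: design score, read/EST support, minor-allele
read support, and spacing to other candidates in the same contig.

Stage 2 (:func:`filter_panel`) screens genotyped loci on panel-level
criteria computed from the genotype matrix (call rate, MAF, heterozygote
fraction, missing count) plus platform scores when supplied.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genotype_io import GenotypeMatrix, LocusMeta

logger = logging.getLogger(__name__)


@dataclass
class QcThresholds:
    """Thresholds of the two-stage marker funnel.

    Strictness of comparisons follows the source wording: score and
    frequency criteria are strict inequalities ("higher than" / "lower
    than"), read/EST/spacing supports are inclusive minima, and loci with a
    missing-call count above ``max_missing_count`` are excluded (i.e. a
    count equal to the maximum is kept).
    """

    min_designability: float = 0.6
    min_contig_reads: int = 8
    min_contig_ests: int = 4
    min_minor_allele_reads: int = 2
    min_snp_spacing_bp: int = 50
    min_gentrain: float = 0.5
    min_call_frequency: float = 0.9
    min_maf: float = 0.06
    max_het_excess: float = 0.8
    min_call_rate: float = 0.8
    max_missing_count: int = 22

    def __post_init__(self) -> None:
        for name in ("min_designability", "min_gentrain", "min_call_frequency",
                     "min_maf", "max_het_excess", "min_call_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("min_contig_reads", "min_contig_ests", "min_minor_allele_reads",
                     "min_snp_spacing_bp", "max_missing_count"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")


@dataclass
class QcReport:
    """Per-locus pass/fail outcome of one QC stage.

    ``table`` has one row per input locus with columns ``locus_id``,
    ``passed``, ``first_fail`` (name of the first failing criterion, empty
    when passed) and ``failed`` (all failing criteria, ';'-joined).
    """

    table: pd.DataFrame
    criterion_counts: dict[str, int]
    retained: list[str]
    skipped_criteria: list[str] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.table)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def to_dataframe(self) -> pd.DataFrame:
        return self.table

    def _check(self) -> None:
        n_failed = int((~self.table["passed"]).sum())
        assert self.n_retained + n_failed == self.n_input
        assert (self.table.loc[~self.table["passed"], "failed"] != "").all()


def _build_report(
    locus_ids: Sequence[str],
    failures: Mapping[str, list[str]],
    skipped: Sequence[str],
) -> QcReport:
    rows = []
    counts: dict[str, int] = defaultdict(int)
    retained = []
    for lid in locus_ids:
        fails = failures.get(lid, [])
        for c in fails:
            counts[c] += 1
        passed = not fails
        if passed:
            retained.append(lid)
        rows.append(
            {
                "locus_id": lid,
                "passed": passed,
                "first_fail": fails[0] if fails else "",
                "failed": ";".join(fails),
            }
        )
    report = QcReport(pd.DataFrame(rows), dict(counts), retained, list(skipped))
    report._check()
    return report


# ---------------------------------------------------------------------------
# stage 1: contig-level discovery criteria
# ---------------------------------------------------------------------------

def filter_candidates(
    loci: Sequence[LocusMeta], thresholds: QcThresholds | None = None
) -> QcReport:
    """Apply contig-level discovery criteria to annotated candidate SNPs.

    A locus passes iff designability > ``min_designability``, contig read
    count >= ``min_contig_reads``, contig EST count >= ``min_contig_ests``,
    minor-allele read count >= ``min_minor_allele_reads``, and it lies at
    least ``min_snp_spacing_bp`` from every other candidate in its contig
    (both members of a too-close pair fail).  Criteria whose annotation is
    absent for a locus are skipped with a logged warning.
    """
    thr = thresholds or QcThresholds()
    failures: dict[str, list[str]] = defaultdict(list)
    skipped: set[str] = set()

    def check(lid: str, crit: str, value, ok) -> None:
        if value is None:
            skipped.add(crit)
            return
        if not ok(value):
            failures[lid].append(crit)

    by_contig: dict[str, list[LocusMeta]] = defaultdict(list)
    for m in loci:
        check(m.locus_id, "designability", m.designability, lambda v: v > thr.min_designability)
        check(m.locus_id, "contig_reads", m.n_reads, lambda v: v >= thr.min_contig_reads)
        check(m.locus_id, "contig_ests", m.n_est, lambda v: v >= thr.min_contig_ests)
        check(m.locus_id, "minor_allele_reads", m.minor_allele_reads,
              lambda v: v >= thr.min_minor_allele_reads)
        if m.contig_id is not None and m.position_in_contig is not None:
            by_contig[m.contig_id].append(m)

    for contig, members in by_contig.items():
        members = sorted(members, key=lambda m: m.position_in_contig)
        for a, b in zip(members, members[1:]):
            gap = b.position_in_contig - a.position_in_contig
            if gap == 0:
                raise ValidationError(
                    f"contig {contig!r}: candidates {a.locus_id!r} and "
                    f"{b.locus_id!r} share position {a.position_in_contig}"
                )
            if gap < thr.min_snp_spacing_bp:
                for m in (a, b):
                    if "spacing" not in failures[m.locus_id]:
                        failures[m.locus_id].append("spacing")

    for crit in sorted(skipped):
        logger.warning("candidate QC: criterion %r skipped for loci lacking annotation", crit)
    return _build_report([m.locus_id for m in loci], failures, sorted(skipped))


# ---------------------------------------------------------------------------
# stage 2: panel-level genotype-data criteria
# ---------------------------------------------------------------------------

def panel_locus_metrics(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus call rate, missing count, MAF and heterozygote fraction."""
    miss = matrix.missing_mask()
    n = matrix.n_samples
    n_missing = miss.sum(axis=0)
    n_typed = n - n_missing
    call_rate = np.divide(n_typed, n, out=np.zeros(matrix.n_loci), where=n > 0)
    dos = matrix.dosage().astype(np.float64)
    dos[dos == -1] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nansum(dos, axis=0) / (2.0 * np.maximum(n_typed, 1))
        het = np.nansum(dos == 1, axis=0) / np.maximum(n_typed, 1)
    maf = np.minimum(p, 1.0 - p)
    maf[n_typed == 0] = np.nan
    het = np.where(n_typed == 0, np.nan, het)
    return pd.DataFrame(
        {
            "locus_id": matrix.locus_ids,
            "n_typed": n_typed,
            "n_missing": n_missing,
            "call_rate": call_rate,
            "maf": maf,
            "het_fraction": het,
        }
    )


def filter_panel(
    matrix: GenotypeMatrix,
    loci: Sequence[LocusMeta] | None = None,
    thresholds: QcThresholds | None = None,
    call_frequency: Mapping[str, float] | None = None,
) -> tuple[QcReport, GenotypeMatrix]:
    """Apply panel-level filters; returns the report and the filtered matrix.

    Criteria (in evaluation order): gentrain > ``min_gentrain`` (skipped
    when no score is supplied), call frequency > ``min_call_frequency``
    (platform score when given, otherwise the observed call rate is reused
    with a warning), MAF > ``min_maf`` (monomorphic loci fail this
    criterion), heterozygote fraction < ``max_het_excess``, call rate >
    ``min_call_rate``, missing count <= ``max_missing_count``.
    """
    if matrix.n_samples == 0 or matrix.n_loci == 0:
        raise ValidationError("panel QC requires a non-empty genotype matrix")
    thr = thresholds or QcThresholds()
    metrics = panel_locus_metrics(matrix).set_index("locus_id")
    gentrain = {m.locus_id: m.gentrain for m in (loci or []) if m.gentrain is not None}
    failures: dict[str, list[str]] = defaultdict(list)
    skipped: set[str] = set()
    if not gentrain:
        skipped.add("gentrain")
    if call_frequency is None:
        skipped.add("call_frequency_score")
        logger.warning("panel QC: no call-frequency score supplied; reusing call rate")

    for lid in matrix.locus_ids:
        row = metrics.loc[lid]
        fails = failures[lid]
        if gentrain:
            g = gentrain.get(lid)
            if g is not None and not g > thr.min_gentrain:
                fails.append("gentrain")
        cf = call_frequency.get(lid, row["call_rate"]) if call_frequency else row["call_rate"]
        if not cf > thr.min_call_frequency:
            fails.append("call_frequency")
        maf = row["maf"]
        if not (np.isfinite(maf) and maf > thr.min_maf):
            fails.append("maf")
        het = row["het_fraction"]
        if not (np.isfinite(het) and het < thr.max_het_excess):
            fails.append("het_excess")
        if not row["call_rate"] > thr.min_call_rate:
            fails.append("call_rate")
        if not row["n_missing"] <= thr.max_missing_count:
            fails.append("missing_count")

    report = _build_report(matrix.locus_ids, failures, sorted(skipped))
    return report, matrix.subset_loci(report.retained)
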
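"""Genotype matrices, sample/locus metadata, and their text-format I/O.

The central object is :class:`GenotypeMatrix`: samples x loci diploid calls.
Internally each call is an unordered pair of per-locus allele indices stored
as a sorted ``(lo, hi)`` int pair; missing calls are ``(-1, -1)``.  Text
formats (delimited genotype tables, VCF) are views over this encoding.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Sentinel allele index for a missing call.
MISSING = -1

#: Default text token for a missing genotype in delimited tables.
DEFAULT_MISSING_TOKEN = "--"


# ---------------------------------------------------------------------------
# metadata records
# ---------------------------------------------------------------------------

@dataclass
class SampleMeta:
    """Per-sample collection metadata.

    ``register_number`` is expected to be unique per accession entry (a
    collection register number is never reused); ``category`` is one of
    ``cultivar``, ``wild``, ``progeny`` when known.
    """

    sample_id: str
    accession_name: str | None = None
    register_number: str | None = None
    category: str | None = None
    group_label: str | None = None

    CATEGORIES = ("cultivar", "wild", "progeny")

    def __post_init__(self) -> None:
        if self.category is not None and self.category not in self.CATEGORIES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown category {self.category!r}"
            )


@dataclass
class LocusMeta:
    """Per-locus annotation: contig placement plus platform QC scores.

    All score/count fields are optional; a ``None`` means the annotation is
    absent and any QC criterion depending on it is skipped for that locus.
    """

    locus_id: str
    contig_id: str | None = None
    position_in_contig: int | None = None
    ref_allele: str | None = None
    alt_allele: str | None = None
    designability: float | None = None
    gentrain: float | None = None
    n_reads: int | None = None
    n_est: int | None = None
    minor_allele_reads: int | None = None

    def __post_init__(self) -> None:
        if self.position_in_contig is not None and self.position_in_contig < 1:
            raise ValidationError(
                f"locus {self.locus_id!r}: position_in_contig must be >= 1 "
                f"(got {self.position_in_contig})"
            )
        if (
            self.ref_allele is not None
            and self.alt_allele is not None
            and self.ref_allele == self.alt_allele
        ):
            raise ValidationError(
                f"locus {self.locus_id!r}: ref_allele equals alt_allele "
                f"({self.ref_allele!r})"
            )


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

class GenotypeMatrix:
    """Rectangular samples x loci matrix of unordered diploid calls.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique sample identifiers (row order is preserved everywhere).
    locus_ids : sequence of str
        Unique locus identifiers (column order is preserved everywhere).
    calls : ndarray of shape (n_samples, n_loci, 2), integer
        Per-call pair of allele indices into ``alleles[locus]``; missing
        calls are ``(-1, -1)``.  Pairs are normalized to ascending order so
        heterozygote representation is unique ("AB" == "BA").
    alleles : sequence of sequences of str
        Per-locus allele codes; ``alleles[l][k]`` is the text code of allele
        index ``k`` at locus ``l``.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        locus_ids: Sequence[str],
        calls: np.ndarray,
        alleles: Sequence[Sequence[str]],
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.locus_ids = list(locus_ids)
        calls = np.asarray(calls, dtype=np.int16)
        if calls.ndim != 3 or calls.shape[2] != 2:
            raise ValidationError(f"calls must have shape (N, L, 2), got {calls.shape}")
        # normalize unordered pairs at construction time
        self.calls = np.sort(calls, axis=2)
        self.alleles = [tuple(a) for a in alleles]
        self._validate()

    # -- structure ----------------------------------------------------------

    def _validate(self) -> None:
        n, l = len(self.sample_ids), len(self.locus_ids)
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.locus_ids)) != l:
            raise ValidationError("duplicate locus ids")
        if self.calls.shape[:2] != (n, l):
            raise ValidationError(
                f"calls shape {self.calls.shape[:2]} does not match "
                f"({n} samples, {l} loci)"
            )
        if len(self.alleles) != l:
            raise ValidationError("alleles list length does not match locus count")
        lo = self.calls[..., 0]
        hi = self.calls[..., 1]
        half_missing = (lo == MISSING) != (hi == MISSING)
        if half_missing.any():
            raise ValidationError("call with exactly one missing allele")
        if l:
            n_alleles = np.array([len(a) for a in self.alleles])
            if (hi.max(axis=0, initial=-1) >= n_alleles).any():
                bad = self.locus_ids[
                    int(np.nonzero(hi.max(axis=0) >= n_alleles)[0][0])
                ]
                raise ValidationError(
                    f"locus {bad!r}: call uses an allele index outside the "
                    f"registered allele set"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_samples, self.n_loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (N, L) array, True where the call is missing."""
        return self.calls[..., 0] == MISSING

    def is_biallelic(self) -> np.ndarray:
        """Boolean (L,) array, True where the locus has <= 2 registered alleles."""
        return np.array([len(a) <= 2 for a in self.alleles])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and self.alleles == other.alleles
            and np.array_equal(self.calls, other.calls)
        )

    # -- converters ---------------------------------------------------------

    @classmethod
    def from_dosage(
        cls,
        sample_ids: Sequence[str],
        locus_ids: Sequence[str],
        dosage: np.ndarray,
        alleles: Sequence[str] = ("A", "B"),
    ) -> "GenotypeMatrix":
        """Build a biallelic matrix from a (N, L) dosage array.

        Dosage counts copies of allele index 1; ``-1`` marks a missing call.
        """
        dosage = np.asarray(dosage)
        pair_for = np.array(
            [[MISSING, MISSING], [0, 0], [0, 1], [1, 1]], dtype=np.int16
        )
        if dosage.size and (dosage.min() < -1 or dosage.max() > 2):
            raise ValidationError("dosage values must be in {-1, 0, 1, 2}")
        calls = pair_for[dosage.astype(np.int64) + 1]
        return cls(sample_ids, locus_ids, calls, [tuple(alleles)] * len(locus_ids))

    def dosage(self) -> np.ndarray:
        """Return the (N, L) count of allele index 1; -1 where missing.

        Only meaningful for biallelic loci.
        """
        d = self.calls.sum(axis=2)
        d[self.missing_mask()] = MISSING
        return d.astype(np.int8)

    def call_text(self, i: int, l: int, missing_token: str = DEFAULT_MISSING_TOKEN) -> str:
        a, b = self.calls[i, l]
        if a == MISSING:
            return missing_token
        codes = self.alleles[l]
        return codes[a] + codes[b]

    # -- subsetting ---------------------------------------------------------

    def subset_samples(self, ids: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            self.locus_ids,
            self.calls[idx],
            self.alleles,
        )

    def subset_loci(self, ids: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.locus_ids.index(l) for l in ids]
        return GenotypeMatrix(
            self.sample_ids,
            [self.locus_ids[i] for i in idx],
            self.calls[:, idx],
            [self.alleles[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# delimited genotype tables
# ---------------------------------------------------------------------------

def _parse_call_token(token: str, missing_token: str) -> tuple[str, str] | None:
    """Split a call token into its two allele codes, or None if missing."""
    token = token.strip()
    if token == missing_token or token == "":
        return None
    if "/" in token:
        parts = token.split("/")
        if len(parts) != 2 or not all(parts):
            raise ParseError(f"malformed call token {token!r}")
        a, b = parts
    elif len(token) == 2:
        a, b = token[0], token[1]
    else:
        raise ParseError(f"malformed call token {token!r}")
    return (a, b) if a <= b else (b, a)


def read_genotype_table(
    path: str | os.PathLike,
    delimiter: str = "\t",
    missing_token: str = DEFAULT_MISSING_TOKEN,
    multiallelic: bool = False,
) -> tuple[GenotypeMatrix, list[SampleMeta]]:
    """Read a delimited genotype table (header = locus ids, col 1 = sample id).

    Calls are two-character strings (``AA``, ``AB``) or slash pairs
    (``A/B``); allele sets are inferred per locus.  Loci showing more than
    two alleles are rejected unless ``multiallelic`` is set.

    Returns the matrix plus a stub :class:`SampleMeta` list (one record per
    sample; only ``sample_id`` is populated — join richer metadata with
    :func:`read_sample_metadata`).
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty genotype table")
    header = lines[0].split(delimiter)
    locus_ids = header[1:]
    n_cols = len(header)
    sample_ids: list[str] = []
    token_rows: list[list[tuple[str, str] | None]] = []
    for row_no, line in enumerate(lines[1:], start=2):
        cells = line.split(delimiter)
        if len(cells) != n_cols:
            raise ParseError(
                f"{path}: row {row_no} has {len(cells)} columns, expected {n_cols}"
            )
        sample_ids.append(cells[0])
        row = []
        for locus, cell in zip(locus_ids, cells[1:]):
            try:
                row.append(_parse_call_token(cell, missing_token))
            except ParseError as exc:
                raise ParseError(
                    f"{path}: sample {cells[0]!r}, locus {locus!r}: {exc}"
                ) from None
        token_rows.append(row)

    # infer allele sets per locus, then index calls
    alleles: list[tuple[str, ...]] = []
    for j, locus in enumerate(locus_ids):
        seen = sorted({a for row in token_rows for pair in [row[j]] if pair for a in pair})
        if len(seen) > 2 and not multiallelic:
            raise ValidationError(
                f"{path}: locus {locus!r} shows {len(seen)} alleles "
                f"({', '.join(seen)}) in biallelic mode"
            )
        alleles.append(tuple(seen) if seen else ("A", "B"))

    calls = np.full((len(sample_ids), len(locus_ids), 2), MISSING, dtype=np.int16)
    for i, row in enumerate(token_rows):
        for j, pair in enumerate(row):
            if pair is not None:
                code = alleles[j]
                calls[i, j] = (code.index(pair[0]), code.index(pair[1]))
    matrix = GenotypeMatrix(sample_ids, locus_ids, calls, alleles)
    metas = [SampleMeta(sample_id=s) for s in sample_ids]
    return matrix, metas


def write_genotype_table(
    matrix: GenotypeMatrix,
    path: str | os.PathLike,
    delimiter: str = "\t",
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> None:
    """Write a matrix as a delimited table that round-trips through
    :func:`read_genotype_table` (calls, sample order and locus order)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(delimiter.join(["sample_id", *matrix.locus_ids]) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            cells = [
                matrix.call_text(i, l, missing_token) for l in range(matrix.n_loci)
            ]
            fh.write(delimiter.join([sid, *cells]) + "\n")


# ---------------------------------------------------------------------------
# sample / locus metadata tables
# ---------------------------------------------------------------------------

_SAMPLE_META_COLS = [f.name for f in dc_fields(SampleMeta)]
_LOCUS_META_COLS = [f.name for f in dc_fields(LocusMeta)]


def read_sample_metadata(path: str | os.PathLike) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str).where(lambda d: d.notna(), None)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'sample_id'")
    known = [c for c in _SAMPLE_META_COLS if c in df.columns]
    return [SampleMeta(**{c: row[c] for c in known}) for _, row in df.iterrows()]


def write_sample_metadata(metas: Sequence[SampleMeta], path: str | os.PathLike) -> None:
    df = pd.DataFrame([{c: getattr(m, c) for c in _SAMPLE_META_COLS} for m in metas])
    df.to_csv(path, sep="\t", index=False)


_LOCUS_INT_FIELDS = {"position_in_contig", "n_reads", "n_est", "minor_allele_reads"}
_LOCUS_FLOAT_FIELDS = {"designability", "gentrain"}


def read_locus_metadata(path: str | os.PathLike) -> list[LocusMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "locus_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'locus_id'")
    known = [c for c in _LOCUS_META_COLS if c in df.columns]
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for c in known:
            val = row[c]
            if pd.isna(val) or val == "":
                kwargs[c] = None
            elif c in _LOCUS_INT_FIELDS:
                kwargs[c] = int(float(val))
            elif c in _LOCUS_FLOAT_FIELDS:
                kwargs[c] = float(val)
            else:
                kwargs[c] = val
        out.append(LocusMeta(**kwargs))
    return out


def write_locus_metadata(loci: Sequence[LocusMeta], path: str | os.PathLike) -> None:
    df = pd.DataFrame([{c: getattr(m, c) for c in _LOCUS_META_COLS} for m in loci])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF import / export
# ---------------------------------------------------------------------------

@dataclass
class VcfImportLog:
    """Counts of records skipped while importing a VCF."""

    n_imported: int = 0
    n_multiallelic_skipped: int = 0
    n_nondiploid_skipped: int = 0


def read_vcf(path: str | os.PathLike) -> tuple[GenotypeMatrix, list[LocusMeta], VcfImportLog]:
    """Import diploid GT calls from a VCF (only biallelic records).

    GT ``0/0``, ``0/1``, ``1/1`` map to ref-hom / het / alt-hom; ``./.``
    maps to MISSING.  Multi-allelic records and records with a haploid or
    polyploid GT are skipped and counted in the returned log.
    """
    import pysam

    log = VcfImportLog()
    with pysam.VariantFile(os.fspath(path)) as vf:
        if "GT" not in vf.header.formats:
            raise ParseError(f"{path}: VCF has no GT format definition")
        samples = list(vf.header.samples)
        locus_ids: list[str] = []
        loci: list[LocusMeta] = []
        rows: list[np.ndarray] = []
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                log.n_multiallelic_skipped += 1
                continue
            calls = np.full((len(samples), 2), MISSING, dtype=np.int16)
            bad_ploidy = False
            for si, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or all(a is None for a in gt):
                    continue  # missing call
                if len(gt) != 2 or any(a is None for a in gt):
                    bad_ploidy = True
                    break
                calls[si] = sorted(gt)
            if bad_ploidy:
                log.n_nondiploid_skipped += 1
                continue
            locus_id = rec.id or f"{rec.chrom}:{rec.pos}"
            locus_ids.append(locus_id)
            loci.append(
                LocusMeta(
                    locus_id=locus_id,
                    contig_id=rec.chrom,
                    position_in_contig=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alts[0],
                )
            )
            rows.append(calls)
            log.n_imported += 1
    if log.n_multiallelic_skipped:
        logger.info(
            "%s: skipped %d non-biallelic record(s)", path, log.n_multiallelic_skipped
        )
    if rows:
        calls_arr = np.stack(rows, axis=1)
    else:
        calls_arr = np.empty((len(samples), 0, 2), dtype=np.int16)
    alleles = [(m.ref_allele, m.alt_allele) for m in loci]
    return GenotypeMatrix(samples, locus_ids, calls_arr, alleles), loci, log


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | os.PathLike,
    loci: Sequence[LocusMeta] | None = None,
) -> None:
    """Export the biallelic subset of a matrix as an uncompressed VCF 4.2.

    Allele index 0 becomes REF and index 1 ALT.  Contig/position default to
    the locus id at position 1 unless ``loci`` metadata supplies them.
    """
    meta_by_id = {m.locus_id: m for m in (loci or [])}
    gt_for = {(MISSING, MISSING): "./.", (0, 0): "0/0", (0, 1): "0/1", (1, 1): "1/1"}
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = []
        for lid in matrix.locus_ids:
            m = meta_by_id.get(lid)
            contig = m.contig_id if m and m.contig_id else lid
            if contig not in contigs:
                contigs.append(contig)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, lid in enumerate(matrix.locus_ids):
            codes = matrix.alleles[j]
            if len(codes) != 2:
                continue
            m = meta_by_id.get(lid)
            contig = m.contig_id if m and m.contig_id else lid
            pos = m.position_in_contig if m and m.position_in_contig else 1
            gts = [gt_for[tuple(matrix.calls[i, j])] for i in range(matrix.n_samples)]
            fh.write(
                f"{contig}\t{pos}\t{lid}\t{codes[0]}\t{codes[1]}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------

def _frame_to_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def write_reports(results: Mapping[str, object], out_dir: str | os.PathLike) -> list[str]:
    """Serialize analysis results deterministically into ``out_dir``.

    ``results`` maps a basename (without extension) to any of: a pandas
    DataFrame, an object with ``to_dataframe()`` (PairDistanceSet,
    RedundancyReport, QcReport, GapResult, AmovaResult, ...), or a PhyloTree
    (written as newick).  Re-running on identical inputs yields
    byte-identical files.  Returns the list of paths written (sorted).
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []
    for name in sorted(results):
        obj = results[name]
        if hasattr(obj, "to_newick"):
            path = os.path.join(out_dir, f"{name}.nwk")
            with open(path, "wt", encoding="utf-8") as fh:
                fh.write(obj.to_newick() + "\n")
        else:
            if hasattr(obj, "to_dataframe"):
                df = obj.to_dataframe()
            elif isinstance(obj, pd.DataFrame):
                df = obj
            else:
                raise TypeError(f"cannot serialize result {name!r}: {type(obj)!r}")
            path = os.path.join(out_dir, f"{name}.tsv")
            _frame_to_tsv(df, path)
        written.append(path)
    return written
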
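"""Expression quantification from SAM alignments.

Expression of a locus is measured as *coverage*: the total number of read
bases mapped to it. Only reads that mapped completely (full read length,
no clipping, no indels) to a single locus tag are counted. Coverage is
normalized to locus length and to the total bases counted in the experiment,
then log2-transformed; zero-coverage loci are dropped from the expression
vector. RPKM is provided as an alternative measure for robustness checks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

DEFAULT_SCALE = 1e9

_CIGAR_RE = re.compile(r"^(?:\d+[MIDNSHP=X])+$|^\*$")

# CIGAR operation codes (pysam numeric): which consume read bases, which
# are clips, which are indels.
_QUERY_OPS = {0, 1, 4, 7, 8}  # M, I, S, =, X
_ALIGNED_OPS = {0, 7, 8}  # M, =, X
_CLIP_OPS = {4, 5}  # S, H
_INDEL_OPS = {1, 2}  # I, D


class SamFormatError(ValueError):
    """Raised for a structurally invalid SAM line, naming the line number."""


class UnknownLocusError(KeyError):
    """Raised when an alignment targets a reference absent from the annotation."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment line of one read (mate), with per-read aggregates.

    ``n_loci_hit`` is the number of *distinct* locus tags this read aligns
    to across all its alignment lines; ``read_length`` is the full read
    length including any clipped bases, ``aligned_span`` the read bases in
    aligned (M/=/X) operations.
    """

    read_id: str
    target_locus: str
    read_length: int
    aligned_span: int
    n_loci_hit: int
    is_clipped: bool
    has_indel: bool = False


@dataclass
class CoverageTable:
    """Per-locus raw mapped-base counts, read counts and locus lengths."""

    frame: pd.DataFrame  # index: locus_tag; columns: raw_bases, n_reads, length

    def __post_init__(self) -> None:
        required = {"raw_bases", "n_reads", "length"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"coverage table missing columns: {sorted(missing)}")
        if (self.frame["raw_bases"] < 0).any():
            raise ValueError("raw_bases must be non-negative")
        if (self.frame["length"] < 1).any():
            raise ValueError("locus lengths must be >= 1")

    @property
    def raw_bases(self) -> pd.Series:
        return self.frame["raw_bases"]

    @property
    def n_reads(self) -> pd.Series:
        return self.frame["n_reads"]

    @property
    def lengths(self) -> pd.Series:
        return self.frame["length"]

    @property
    def total_bases(self) -> int:
        return int(self.frame["raw_bases"].sum())

    @property
    def total_reads(self) -> int:
        return int(self.frame["n_reads"].sum())


@dataclass
class ExpressionVector:
    """Normalized log2 expression keyed by locus tag; zero-coverage loci excluded."""

    values: pd.Series  # index: locus_tag, float log2 values

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.values)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# annotation loading


def _validate_annotation(lengths: dict[str, int]) -> dict[str, int]:
    for tag, length in lengths.items():
        if length < 1:
            raise ValueError(f"locus {tag!r} has length {length} < 1")
    return lengths


def read_annotation_fasta(path: str | Path) -> dict[str, int]:
    """Locus lengths from a per-locus reference FASTA (mRNA or CDS sequences)."""
    lengths: dict[str, int] = {}
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            if entry.name in lengths:
                raise ValueError(f"duplicate locus tag {entry.name!r} in annotation")
            lengths[entry.name] = len(entry.sequence)
    if not lengths:
        raise ValueError(f"no sequences in annotation FASTA {path}")
    return _validate_annotation(lengths)


def read_annotation_tsv(path: str | Path) -> dict[str, int]:
    """Locus lengths from a two-column TSV (locus_tag, length); header optional."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("annotation TSV needs two columns: locus_tag, length")
    first = str(frame.iloc[0, 1])
    if not first.lstrip("-").isdigit():  # header row
        frame = frame.iloc[1:]
    tags = frame.iloc[:, 0].astype(str)
    if tags.duplicated().any():
        dup = tags[tags.duplicated()].iloc[0]
        raise ValueError(f"duplicate locus tag {dup!r} in annotation")
    lengths = dict(zip(tags, frame.iloc[:, 1].astype(int)))
    return _validate_annotation(lengths)


# ---------------------------------------------------------------------------
# SAM ingestion


def _prevalidate_sam(path: Path) -> None:
    """Structural check of SAM text so parse errors carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("@") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise SamFormatError(
                    f"line {lineno}: expected >= 11 tab-separated fields, got {len(fields)}"
                )
            for idx, name in ((1, "FLAG"), (3, "POS"), (4, "MAPQ")):
                if not fields[idx].lstrip("-").isdigit():
                    raise SamFormatError(f"line {lineno}: non-numeric {name} field {fields[idx]!r}")
            if not _CIGAR_RE.match(fields[5]):
                raise SamFormatError(f"line {lineno}: malformed CIGAR {fields[5]!r}")


def _read_key(aln: pysam.AlignedSegment) -> str:
    # Mates of a pair are treated as independent reads.
    if aln.is_paired:
        return f"{aln.query_name}/{1 if aln.is_read1 else 2}"
    return aln.query_name


def read_alignments(
    sam_path: str | Path,
    annotation: Mapping[str, int] | None = None,
) -> list[AlignmentRecord]:
    """Parse a SAM file into one record per mapped alignment line.

    ``n_loci_hit`` is aggregated per read over all its alignment lines
    (primary, secondary, supplementary). Unmapped lines are dropped. If an
    ``annotation`` is given, an alignment to a reference it does not contain
    is a hard error.
    """
    path = Path(sam_path)
    _prevalidate_sam(path)

    raw: list[tuple[str, str, int, int, bool, bool]] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            locus = aln.reference_name
            if annotation is not None and locus not in annotation:
                raise UnknownLocusError(
                    f"read {aln.query_name!r} aligned to {locus!r}, absent from annotation"
                )
            cig = aln.cigartuples or []
            read_length = sum(n for op, n in cig if op in _QUERY_OPS or op == 5)
            if not read_length:
                read_length = aln.query_length or len(aln.query_sequence or "")
            aligned_span = sum(n for op, n in cig if op in _ALIGNED_OPS)
            is_clipped = any(op in _CLIP_OPS for op, _ in cig)
            has_indel = any(op in _INDEL_OPS for op, _ in cig)
            raw.append((_read_key(aln), locus, read_length, aligned_span, is_clipped, has_indel))

    loci_per_read: dict[str, set[str]] = {}
    for key, locus, *_ in raw:
        loci_per_read.setdefault(key, set()).add(locus)

    return [
        AlignmentRecord(
            read_id=key,
            target_locus=locus,
            read_length=read_length,
            aligned_span=aligned_span,
            n_loci_hit=len(loci_per_read[key]),
            is_clipped=is_clipped,
            has_indel=has_indel,
        )
        for key, locus, read_length, aligned_span, is_clipped, has_indel in raw
    ]


def filter_full_single_locus(records: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep reads mapped completely (entire length, no clips/indels) to a single locus."""
    return [
        r
        for r in records
        if r.n_loci_hit == 1
        and r.aligned_span == r.read_length
        and not r.is_clipped
        and not r.has_indel
    ]


def count_base_coverage(
    records: Iterable[AlignmentRecord],
    annotation: Mapping[str, int],
) -> CoverageTable:
    """Count every base of each retained read toward its locus.

    A read with several alignment lines to the same locus is counted once.
    Every annotated locus appears in the output, with zero allowed.
    """
    seen: set[str] = set()
    bases: dict[str, int] = {tag: 0 for tag in annotation}
    reads: dict[str, int] = {tag: 0 for tag in annotation}
    for rec in records:
        if rec.target_locus not in annotation:
            raise UnknownLocusError(
                f"read {rec.read_id!r} aligned to {rec.target_locus!r}, absent from annotation"
            )
        if rec.read_id in seen:
            continue
        seen.add(rec.read_id)
        bases[rec.target_locus] += rec.read_length
        reads[rec.target_locus] += 1
    frame = pd.DataFrame(
        {
            "raw_bases": pd.Series(bases, dtype=int),
            "n_reads": pd.Series(reads, dtype=int),
            "length": pd.Series(dict(annotation), dtype=int),
        }
    )
    frame.index.name = "locus_tag"
    return CoverageTable(frame)


def count_reads(records: Iterable[AlignmentRecord], annotation: Mapping[str, int]) -> pd.Series:
    """Per-locus retained-read counts (each read once)."""
    return count_base_coverage(records, annotation).n_reads


# ---------------------------------------------------------------------------
# normalization


def normalize_coverage(table: CoverageTable, scale_constant: float = DEFAULT_SCALE) -> pd.Series:
    """Normalize raw base coverage to locus length and library size.

    norm(locus) = raw_bases / (length * total_bases) * scale_constant.
    Returned for all loci, zeros included. The scale constant is a pure
    multiplicative factor (additive in log2) and cannot change peak
    structure; the default 1e9 makes values comparable to per-kilobase,
    per-gigabase rates.
    """
    total = table.total_bases
    if total == 0:
        raise ValueError("empty experiment: no bases counted on any locus")
    return (
        table.raw_bases.astype(float)
        / (table.lengths.astype(float) * float(total))
        * float(scale_constant)
    )


def to_expression_vector(normalized: pd.Series) -> ExpressionVector:
    """log2-transform normalized coverage; loci without coverage are dropped."""
    if (normalized < 0).any():
        raise ValueError("normalized coverage must be non-negative")
    nonzero = normalized[normalized > 0]
    return ExpressionVector(np.log2(nonzero.astype(float)))


def compute_rpkm(
    read_counts: pd.Series,
    annotation: Mapping[str, int],
    total_reads: int | None = None,
) -> pd.Series:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm(locus) = reads * 1e9 / (length * total_reads).
    """
    if total_reads is None:
        total_reads = int(read_counts.sum())
    if total_reads <= 0:
        raise ValueError("empty experiment: zero mapped reads")
    lengths = pd.Series(dict(annotation), dtype=float).reindex(read_counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise UnknownLocusError(f"locus {missing!r} absent from annotation")
    return read_counts.astype(float) * 1e9 / (lengths * float(total_reads))


# ---------------------------------------------------------------------------
# tabular I/O


def write_expression_table(
    path: str | Path,
    table: CoverageTable,
    scale_constant: float = DEFAULT_SCALE,
) -> pd.DataFrame:
    """Write the per-locus quantification TSV (raw, normalized, log2 columns)."""
    norm = normalize_coverage(table, scale_constant)
    log2_norm = pd.Series(np.nan, index=norm.index)
    log2_norm[norm > 0] = np.log2(norm[norm > 0])
    out = pd.DataFrame(
        {
            "raw_bases": table.raw_bases,
            "length": table.lengths,
            "norm": norm,
            "log2_norm": log2_norm,
        }
    )
    out.index.name = "locus_tag"
    out.to_csv(path, sep="\t", float_format="%.10g")
    return out


def write_expression_vector(path: str | Path, vector: ExpressionVector) -> None:
    out = vector.values.rename("log2_norm").to_frame()
    out.index.name = "locus_tag"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_expression_tsv(path: str | Path) -> ExpressionVector:
    """Load an expression vector from a TSV with locus_tag and log2_norm columns."""
    frame = pd.read_csv(path, sep="\t")
    if "locus_tag" not in frame.columns or "log2_norm" not in frame.columns:
        raise ValueError("expression TSV needs 'locus_tag' and 'log2_norm' columns")
    series = frame.set_index("locus_tag")["log2_norm"].dropna().astype(float)
    return ExpressionVector(series)
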
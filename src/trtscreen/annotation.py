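"""Gene models and adjacent gene-pair enumeration.

Read-through transcription extends past a gene's transcription termination
site (TTS) into the neighbouring intergenic region, so the unit of screening
is a *directed* adjacent gene pair: an upstream gene whose TTS borders the
intergenic gap, and the next gene body beyond the gap.  Pairs on the same
strand are *cis* candidates, pairs on opposite strands *trans* candidates.

Coordinates are 0-based half-open everywhere inside the package; GTF/GFF3
1-based inclusive coordinates are converted at the I/O boundary.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "GenePair",
    "AnnotationFormatError",
    "read_gene_models",
    "enumerate_adjacent_pairs",
    "pairs_to_frame",
    "write_pairs_tsv",
    "read_pairs_tsv",
]


class AnnotationFormatError(ValueError):
    """Raised when an annotation file does not parse as the named format."""


@dataclass(frozen=True)
class GeneModel:
    """A gene span: the unit of pair enumeration.

    ``start``/``end`` are 0-based half-open.  ``biotype`` distinguishes
    protein-coding from lncRNA genes where the annotation provides it.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def tts(self) -> int:
        """Transcription termination site: 3' boundary of the gene span."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class GenePair:
    """A directed adjacent gene pair with its intergenic interval.

    The intergenic interval lies strictly between the two gene bodies and
    abuts the upstream gene's TTS.  ``pair_class`` is ``cis`` when both genes
    share a strand, ``trans`` otherwise.
    """

    upstream: GeneModel
    downstream: GeneModel
    intergenic_start: int
    intergenic_end: int

    def __post_init__(self) -> None:
        if self.upstream.chrom != self.downstream.chrom:
            raise ValueError("pair genes must share a chromosome")
        if self.intergenic_start >= self.intergenic_end:
            raise ValueError("intergenic interval must have positive length")

    @property
    def chrom(self) -> str:
        return self.upstream.chrom

    @property
    def pair_class(self) -> str:
        return "cis" if self.upstream.strand == self.downstream.strand else "trans"

    @property
    def pair_id(self) -> str:
        return f"{self.upstream.gene_id}__{self.downstream.gene_id}"

    @property
    def key(self) -> tuple:
        """Direction-free identity, for union (total) burden counting."""
        return tuple(sorted((self.upstream.gene_id, self.downstream.gene_id)))

    @property
    def intergenic_length_bp(self) -> int:
        return self.intergenic_end - self.intergenic_start


# ---------------------------------------------------------------------------
# Readers


def _infer_format(path: str) -> str:
    lower = path.lower()
    for ext, fmt in ((".gtf", "gtf"), (".gff3", "gff3"), (".gff", "gff3"), (".bed", "bed12")):
        if lower.endswith(ext):
            return fmt
    raise AnnotationFormatError(f"cannot infer annotation format from file name: {path}")


def _validate_gff_lines(path: str) -> None:
    """Cheap structural pass so format errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AnnotationFormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationFormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc


def _read_gff(path: str, dialect: str) -> list[GeneModel]:
    import gffutils

    _validate_gff_lines(path)
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils error surface varies
        raise AnnotationFormatError(f"{path}: failed to parse as {dialect}: {exc}") from exc

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        attrs = dict(feat.attributes)
        if "gene_id" in attrs:
            gene_id = attrs["gene_id"][0]
        elif "ID" in attrs:
            gene_id = attrs["ID"][0].removeprefix("gene:")
        else:
            raise AnnotationFormatError(
                f"{path}: gene feature at {feat.seqid}:{feat.start} lacks gene_id/ID"
            )
        if gene_id in seen:
            raise AnnotationFormatError(f"{path}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        biotype = None
        for key in ("gene_biotype", "gene_type", "biotype"):
            if key in attrs:
                biotype = attrs[key][0]
                break
        # GFF 1-based inclusive -> 0-based half-open
        start, end = feat.start - 1, feat.end
        if start >= end:
            raise AnnotationFormatError(
                f"{path}: gene {gene_id}: start >= end after coordinate conversion"
            )
        if feat.strand not in ("+", "-"):
            raise AnnotationFormatError(f"{path}: gene {gene_id}: strand must be + or -")
        genes.append(GeneModel(gene_id, feat.seqid, start, end, feat.strand, biotype))
    return genes


def _read_bed(path: str) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationFormatError(
                    f"{path}: line {lineno}: BED needs >= 6 fields, got {len(fields)}"
                )
            chrom, name, strand = fields[0], fields[3], fields[5]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AnnotationFormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise AnnotationFormatError(f"{path}: line {lineno}: start >= end")
            if strand not in ("+", "-"):
                raise AnnotationFormatError(f"{path}: line {lineno}: strand must be + or -")
            if name in seen:
                raise AnnotationFormatError(f"{path}: duplicate gene_id {name!r}")
            seen.add(name)
            genes.append(GeneModel(name, chrom, start, end, strand))
    return genes


def read_gene_models(path: str, format: Optional[str] = None) -> list[GeneModel]:
    """Read gene spans from GTF, GFF3 or BED12 (BED6+) into :class:`GeneModel` s.

    GTF/GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; BED is already 0-based half-open.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt in ("gtf", "gff3"):
        return _read_gff(path, fmt)
    if fmt == "bed12":
        return _read_bed(path)
    raise AnnotationFormatError(f"unknown annotation format {fmt!r}")


# ---------------------------------------------------------------------------
# Pair enumeration


def enumerate_adjacent_pairs(
    genes: Sequence[GeneModel],
    min_intergenic_bp: int = 1,
    max_intergenic_bp: Optional[int] = None,
) -> list[GenePair]:
    """Enumerate directed adjacent gene pairs per chromosome.

    "Adjacent" means consecutive in coordinate order regardless of strand.
    A gene is eligible as *upstream* only when its TTS borders the gap
    (read-through by definition runs past the TTS):

    * ``+/+``: one cis pair, left gene upstream;
    * ``-/-``: one cis pair, right gene upstream;
    * ``+/-`` (convergent): two trans pairs, one per direction;
    * ``-/+`` (divergent): no pair (neither TTS faces the gap).

    Overlapping or abutting gene bodies yield no pair (no intergenic
    interval); gaps outside ``[min_intergenic_bp, max_intergenic_bp]`` are
    excluded.  Output is independent of the input gene ordering.
    """
    if min_intergenic_bp < 1:
        raise ValueError("min_intergenic_bp must be >= 1")
    pairs: list[GenePair] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        for left, right in zip(ordered, ordered[1:]):
            gap_start, gap_end = left.end, right.start
            gap = gap_end - gap_start
            if gap < min_intergenic_bp:
                continue
            if max_intergenic_bp is not None and gap > max_intergenic_bp:
                continue
            if left.strand == "+":
                pairs.append(GenePair(left, right, gap_start, gap_end))
            if right.strand == "-":
                pairs.append(GenePair(right, left, gap_start, gap_end))
    return pairs


# ---------------------------------------------------------------------------
# Tabular output


_PAIR_COLUMNS = [
    "pair_id",
    "upstream_gene",
    "downstream_gene",
    "chrom",
    "pair_class",
    "intergenic_start",
    "intergenic_end",
    "intergenic_length",
]


def pairs_to_frame(pairs: Iterable[GenePair]) -> pd.DataFrame:
    rows = [
        (
            p.pair_id,
            p.upstream.gene_id,
            p.downstream.gene_id,
            p.chrom,
            p.pair_class,
            p.intergenic_start,
            p.intergenic_end,
            p.intergenic_length_bp,
        )
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=_PAIR_COLUMNS)


def write_pairs_tsv(pairs: Iterable[GenePair], path: str) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationFormatError(f"{path}: pairs table missing columns {sorted(missing)}")
    return df


def write_intergenic_bed(pairs: Iterable[GenePair], path: str) -> None:
    """BED6 of intergenic intervals; name is the pair id, strand the upstream strand."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                f"{p.chrom}\t{p.intergenic_start}\t{p.intergenic_end}"
                f"\t{p.pair_id}\t0\t{p.upstream.strand}\n"
            )
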
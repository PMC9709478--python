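"""Fragment counting over genomic features and FPKM conversion.

Counting follows bedtools-coverage semantics: a fragment counts toward a
feature when the two intervals overlap by at least one base (half-open
coordinates), with an optional strand match for strand-specific libraries.
A *fragment* is the outer span of a properly paired read pair; unpaired
reads count as single fragments.

FPKM = count / ((feature length / 1e3) * (library size / 1e6)), where the
library size is the number of retained fragments in the sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenePair

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentSet",
    "ExpressionMatrix",
    "count_overlaps",
    "fpkm",
    "quantify_features",
    "load_expression_table",
    "read_fragments_bed",
    "read_fragments_bam",
]

_FRAG_COLUMNS = ["chrom", "start", "end", "strand"]


@dataclass
class FragmentSet:
    """Aligned fragments of one sample.

    ``fragments`` is a DataFrame with columns chrom/start/end/strand
    (half-open coordinates).  ``library_size`` defaults to the number of
    stored fragments; it may exceed it when fragments were pre-filtered.
    """

    sample_id: str
    fragments: pd.DataFrame
    library_size: Optional[int] = None

    def __post_init__(self) -> None:
        if not isinstance(self.fragments, pd.DataFrame):
            self.fragments = pd.DataFrame(
                list(self.fragments), columns=_FRAG_COLUMNS
            )
        missing = set(_FRAG_COLUMNS) - set(self.fragments.columns)
        if missing:
            raise ValueError(f"fragment table missing columns {sorted(missing)}")
        if len(self.fragments) and not (
            self.fragments["start"] < self.fragments["end"]
        ).all():
            raise ValueError(f"sample {self.sample_id}: fragment with start >= end")
        if self.library_size is None:
            self.library_size = len(self.fragments)
        if self.library_size < len(self.fragments):
            raise ValueError(
                f"sample {self.sample_id}: library_size smaller than stored fragments"
            )

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass
class ExpressionMatrix:
    """FPKM per feature (gene or pair intergenic interval) per sample."""

    fpkm: pd.DataFrame  # features x samples
    library_sizes: pd.Series  # per sample

    def __post_init__(self) -> None:
        self.library_sizes = self.library_sizes.reindex(self.fpkm.columns)
        if self.fpkm.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fpkm.columns)

    def write_tsv(self, path: str, library_sizes_path: Optional[str] = None) -> None:
        self.fpkm.rename_axis("feature_id").to_csv(path, sep="\t", float_format="%.6g")
        if library_sizes_path is not None:
            self.library_sizes.rename("library_size").rename_axis("sample_id").to_csv(
                library_sizes_path, sep="\t"
            )


def count_overlaps(
    interval: tuple, fragments: FragmentSet, stranded: bool = True
) -> int:
    """Number of fragments overlapping ``(chrom, start, end, strand)`` by >= 1 bp."""
    chrom, start, end = interval[0], int(interval[1]), int(interval[2])
    if start >= end:
        raise ValueError("interval must have positive length")
    frags = fragments.fragments
    mask = frags["chrom"] == chrom
    if stranded:
        strand = interval[3]
        mask &= frags["strand"] == strand
    sub = frags.loc[mask]
    return int(((sub["start"] < end) & (sub["end"] > start)).sum())


def fpkm(count: float, length_bp: int, library_size: int) -> float:
    """Fragments per kilobase of feature per million mapped fragments."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count / ((length_bp / 1e3) * (library_size / 1e6))


def _feature_table(
    genes: Sequence[GeneModel], pairs: Sequence[GenePair]
) -> pd.DataFrame:
    """Genes plus pair intergenic intervals; intergenic strand = upstream strand."""
    rows = [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes]
    rows += [
        (p.pair_id, p.chrom, p.intergenic_start, p.intergenic_end, p.upstream.strand)
        for p in pairs
    ]
    df = pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end", "strand"])
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise ValueError(f"duplicate feature id {dup!r}")
    return df


def _count_sample(
    features: pd.DataFrame, frags: pd.DataFrame, stranded: bool
) -> np.ndarray:
    """Vectorised interval-overlap counting via sorted endpoints.

    For half-open intervals, a fragment overlaps [S, E) iff start < E and
    end > S, hence count = #(frag starts < E) - #(frag ends <= S): every
    fragment ending at or before S necessarily also starts before E.
    """
    counts = np.zeros(len(features), dtype=np.int64)
    group_cols = ["chrom", "strand"] if stranded else ["chrom"]
    frag_groups = dict(iter(frags.groupby(group_cols, sort=False, observed=True)))
    for key, feat in features.groupby(group_cols, sort=False, observed=True):
        sub = frag_groups.get(key)
        if sub is None:
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        n_start_before = np.searchsorted(starts, feat["end"].to_numpy(), side="left")
        n_end_before = np.searchsorted(ends, feat["start"].to_numpy(), side="right")
        counts[feat.index.to_numpy()] = n_start_before - n_end_before
    return counts


def quantify_features(
    genes: Sequence[GeneModel],
    pairs: Sequence[GenePair],
    samples: Sequence[FragmentSet],
    stranded: bool = True,
) -> ExpressionMatrix:
    """FPKM matrix over all genes plus all pair intergenic intervals.

    Fragments on chromosomes absent from the annotation are ignored with a
    logged warning; an empty sample (library size 0) is an error.
    """
    features = _feature_table(genes, pairs).reset_index(drop=True)
    known_chroms = set(features["chrom"])
    columns = {}
    lib_sizes = {}
    lengths = (features["end"] - features["start"]).to_numpy()
    for sample in samples:
        if sample.library_size == 0:
            raise ValueError(f"sample {sample.sample_id!r} has library size 0")
        frags = sample.fragments
        unknown = set(frags["chrom"]) - known_chroms
        if unknown:
            logger.warning(
                "sample %s: ignoring %d fragments on chromosomes absent from the "
                "annotation (%s)",
                sample.sample_id,
                int(frags["chrom"].isin(unknown).sum()),
                ", ".join(sorted(unknown)[:5]),
            )
            frags = frags.loc[~frags["chrom"].isin(unknown)]
        counts = _count_sample(features, frags, stranded)
        columns[sample.sample_id] = counts / (
            (lengths / 1e3) * (sample.library_size / 1e6)
        )
        lib_sizes[sample.sample_id] = sample.library_size
    mat = pd.DataFrame(columns, index=features["feature_id"])
    mat.index.name = "feature_id"
    return ExpressionMatrix(mat, pd.Series(lib_sizes, dtype=np.int64))


# ---------------------------------------------------------------------------
# I/O


def load_expression_table(
    path: str, library_sizes_path: Optional[str] = None
) -> ExpressionMatrix:
    """Load a feature x sample FPKM TSV (first column feature id, header samples).

    Library sizes come from a sidecar TSV (sample_id, library_size); without
    one they are set to 1 with a warning — fold-change-based screening steps
    are library-size-free given FPKM input.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: empty expression table")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric FPKM values") from exc
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in expression table")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative FPKM values")
    if library_sizes_path is not None:
        ls = pd.read_csv(library_sizes_path, sep="\t", comment="#", index_col=0)[
            "library_size"
        ]
        missing = set(df.columns) - set(ls.index)
        if missing:
            raise ValueError(f"{library_sizes_path}: missing samples {sorted(missing)}")
        lib = ls.reindex(df.columns).astype(np.int64)
    else:
        logger.warning(
            "%s: no library-size sidecar; setting all library sizes to 1", path
        )
        lib = pd.Series(1, index=df.columns, dtype=np.int64)
    return ExpressionMatrix(df, lib)


def read_fragments_bed(path: str, sample_id: str) -> FragmentSet:
    """Fragments from a BED6 file (name/score columns ignored)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    return FragmentSet(sample_id, df)


def read_fragments_bam(
    path: str,
    sample_id: str,
    mapq_min: int = 0,
    flip_strand: bool = False,
) -> FragmentSet:
    """Fragments from a coordinate-sorted BAM.

    Properly paired reads contribute one fragment per pair (the outer span,
    taken from the leftmost mate's template length); unpaired or improperly
    paired reads count as single fragments.  ``flip_strand`` accommodates
    dUTP-style libraries where the fragment strand is opposite read 1.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(path, "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < mapq_min:
                continue
            if read.is_proper_pair:
                # count the pair once, from the leftmost mate
                if read.template_length <= 0:
                    continue
                start = read.reference_start
                end = start + read.template_length
                # fragment strand follows read 1 orientation
                read1_reverse = (
                    read.is_reverse if read.is_read1 else not read.is_reverse
                )
                strand = "-" if read1_reverse else "+"
                if flip_strand:
                    strand = "-" if strand == "+" else "+"
                rows.append((read.reference_name, start, end, strand))
            else:
                strand = "-" if read.is_reverse else "+"
                if flip_strand:
                    strand = "-" if strand == "+" else "+"
                rows.append(
                    (read.reference_name, read.reference_start, read.reference_end, strand)
                )
    df = pd.DataFrame(rows, columns=_FRAG_COLUMNS)
    return FragmentSet(sample_id, df)
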
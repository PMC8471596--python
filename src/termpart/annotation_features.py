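"""Gene-model parsing and annotation feature-size statistics.

Parses GFF3 gene models (gene -> mRNA -> CDS / five_prime_UTR /
three_prime_UTR) into light-weight :class:`GeneModel` records and computes
the descriptive statistics that motivate terminator-part selection:
per-gene feature lengths, 100-bp length histograms, the short/medium/long
size classification used for 3'UTR terminator elements, and intergenic
distances between genomically adjacent genes.

All coordinates follow the GFF3 convention: 1-based, inclusive on both
ends, so an interval's length is ``end - start + 1``.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gffutils

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "LengthHistogram",
    "IntergenicDistance",
    "FeatureLengths",
    "LengthSummary",
    "GFF3ParseError",
    "SIZE_CLASS_SHORT_LT",
    "SIZE_CLASS_LONG_GT",
    "parse_gff3",
    "feature_lengths",
    "length_histogram",
    "classify_length",
    "intergenic_distances",
    "summarize_lengths",
]

#: size-class boundaries for 3'UTR/terminator elements (bp):
#: short < 100, 100 <= medium <= 600, long > 600
SIZE_CLASS_SHORT_LT = 100
SIZE_CLASS_LONG_GT = 600


class GFF3ParseError(ValueError):
    """Raised for malformed GFF3 input or unresolvable Parent references."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, inclusive interval on a chromosome/scaffold."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneModel:
    """One gene's representative-transcript structure.

    ``utr3_length`` sums interval lengths; genes without an annotated
    3'UTR carry length 0 and ``has_utr3`` False.
    """

    gene_id: str
    transcript_id: str
    span: GenomicInterval
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def feature_intervals(self, kind: str) -> list[GenomicInterval]:
        try:
            return {"cds": self.cds, "utr5": self.utr5, "utr3": self.utr3}[kind]
        except KeyError:
            raise ValueError(f"unknown feature kind {kind!r}") from None

    def feature_length(self, kind: str) -> int:
        return sum(iv.length for iv in self.feature_intervals(kind))

    @property
    def utr3_length(self) -> int:
        return self.feature_length("utr3")

    @property
    def has_utr3(self) -> bool:
        return bool(self.utr3)

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand


@dataclass
class LengthHistogram:
    """Counts of lengths in half-open bins ``[i*binsize, (i+1)*binsize)``."""

    binsize: int
    counts: dict[int, int]
    n_total: int

    def count_in_range(self, lo: int, hi: int) -> int:
        """Total count over bins fully covering ``[lo, hi)``.

        ``lo``/``hi`` must be multiples of ``binsize``.
        """
        if lo % self.binsize or hi % self.binsize:
            raise ValueError("range bounds must be multiples of binsize")
        return sum(
            self.counts.get(i, 0)
            for i in range(lo // self.binsize, hi // self.binsize)
        )

    def to_rows(self) -> list[tuple[int, int, int]]:
        """(bin_lo, bin_hi, count) rows for non-empty bins, ascending."""
        return [
            (i * self.binsize, (i + 1) * self.binsize, self.counts[i])
            for i in sorted(self.counts)
        ]


@dataclass(frozen=True)
class IntergenicDistance:
    """Gap between two genomically adjacent genes on the same chromosome.

    ``distance = downstream_boundary_start - upstream_boundary_end - 1``;
    negative values indicate overlapping annotations and are retained.
    """

    upstream_gene: str
    downstream_gene: str
    distance: int


@dataclass
class FeatureLengths:
    """Per-gene feature lengths plus the count of genes lacking the feature."""

    kind: str
    lengths: list[tuple[str, int]]
    n_excluded: int


@dataclass
class LengthSummary:
    n: int
    median: int | float
    mean: float
    fraction_above: dict[int, float]


def _children_of(db: gffutils.FeatureDB, parent_id: str, featuretype: str):
    return list(db.children(parent_id, featuretype=featuretype, order_by="start"))


def _intervals(features) -> list[GenomicInterval]:
    return [
        GenomicInterval(f.seqid, f.start, f.end, f.strand if f.strand in "+-" else "+")
        for f in features
    ]


def parse_gff3(
    path: str | Path,
    transcript_policy: Literal["longest", "primary"] = "longest",
) -> list[GeneModel]:
    """Parse a GFF3 file into one :class:`GeneModel` per gene.

    The representative transcript is chosen per ``transcript_policy``:

    ``longest``
        largest total exonic length (CDS + UTRs), ties broken by the
        lexicographically smallest transcript id;
    ``primary``
        the transcript flagged ``longest=1`` (Phytozome dialect) if
        present, else the lexicographically smallest transcript id.

    Raises :class:`GFF3ParseError` on malformed lines (with the line
    number where available) or on child features whose ``Parent`` does
    not exist in the file.
    """
    path = Path(path)
    has_features = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise GFF3ParseError(
                    f"{path.name}: malformed GFF3 line {lineno}: expected 9 "
                    f"tab-separated fields"
                )
            has_features = True
    if not has_features:
        return []
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted error types
        raise GFF3ParseError(f"failed to parse {path.name}: {exc}") from exc

    known_ids = {f.id for f in db.all_features()}
    orphans = sorted(
        {
            pid
            for f in db.all_features()
            for pid in f.attributes.get("Parent", [])
            if pid not in known_ids
        }
    )
    if orphans:
        raise GFF3ParseError(
            "child features reference unknown Parent id(s): " + ", ".join(orphans)
        )

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = _children_of(db, gene.id, "mRNA")
        if not mrnas:
            continue
        chosen = _choose_transcript(db, mrnas, transcript_policy)
        cds = _intervals(_children_of(db, chosen.id, "CDS"))
        utr5 = _intervals(_children_of(db, chosen.id, "five_prime_UTR"))
        utr3 = _intervals(_children_of(db, chosen.id, "three_prime_UTR"))
        span = GenomicInterval(
            gene.seqid, gene.start, gene.end, gene.strand if gene.strand in "+-" else "+"
        )
        models.append(
            GeneModel(
                gene_id=gene.id,
                transcript_id=chosen.id,
                span=span,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return models


def _choose_transcript(db, mrnas, policy):
    if policy == "primary":
        flagged = [m for m in mrnas if m.attributes.get("longest", ["0"])[0] == "1"]
        pool = flagged or mrnas
        return min(pool, key=lambda m: m.id)
    if policy == "longest":
        def exonic(m):
            total = 0
            for ft in ("CDS", "five_prime_UTR", "three_prime_UTR"):
                total += sum(f.end - f.start + 1 for f in _children_of(db, m.id, ft))
            return total

        return min(mrnas, key=lambda m: (-exonic(m), m.id))
    raise ValueError(f"unknown transcript_policy {policy!r}")


def feature_lengths(
    models: Iterable[GeneModel], kind: Literal["utr3", "utr5", "cds"]
) -> FeatureLengths:
    """Per-gene total length of one feature kind.

    Genes without any interval of that kind are excluded from the list
    and tallied in ``n_excluded`` (never reported as length 0).
    """
    if kind not in ("utr3", "utr5", "cds"):
        raise ValueError(f"unknown feature kind {kind!r}")
    lengths: list[tuple[str, int]] = []
    n_excluded = 0
    for m in models:
        if m.feature_intervals(kind):
            lengths.append((m.gene_id, m.feature_length(kind)))
        else:
            n_excluded += 1
    return FeatureLengths(kind=kind, lengths=lengths, n_excluded=n_excluded)


def length_histogram(lengths: Sequence[int], binsize: int = 100) -> LengthHistogram:
    """Bin lengths into half-open bins of width ``binsize`` bp."""
    if binsize <= 0:
        raise ValueError(f"binsize must be positive, got {binsize}")
    counts: Counter[int] = Counter()
    for length in lengths:
        if length < 0:
            raise ValueError(f"negative length {length}")
        counts[length // binsize] += 1
    return LengthHistogram(binsize=binsize, counts=dict(counts), n_total=len(lengths))


def classify_length(length: int) -> str:
    """Size class of a terminator/3'UTR: short (<100), medium (100-600
    inclusive) or long (>600)."""
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    if length < SIZE_CLASS_SHORT_LT:
        return "short"
    if length <= SIZE_CLASS_LONG_GT:
        return "medium"
    return "long"


def _utr_bounds(model: GeneModel) -> tuple[int, int]:
    # genomic extent of all annotated UTR intervals; falls back to the
    # gene span on a side with no UTR annotation
    utrs = model.utr5 + model.utr3
    if not utrs:
        return model.span.start, model.span.end
    return min(iv.start for iv in utrs), max(iv.end for iv in utrs)


def intergenic_distances(
    models: Iterable[GeneModel],
    mode: Literal["utr_to_utr", "span_to_span"] = "utr_to_utr",
) -> list[IntergenicDistance]:
    """Distances between genomically adjacent genes, per chromosome.

    Genes are ordered by span start regardless of strand.  In
    ``utr_to_utr`` mode the gap runs from the genomic end of the
    upstream gene's terminal annotated UTR to the genomic start of the
    downstream gene's first annotated UTR (on the forward axis); genes
    lacking UTR annotation contribute their span boundary.  Overlapping
    annotations yield negative distances, which are retained.
    """
    if mode not in ("utr_to_utr", "span_to_span"):
        raise ValueError(f"unknown mode {mode!r}")
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    out: list[IntergenicDistance] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda m: (m.span.start, m.span.end, m.gene_id))
        for up, down in zip(genes, genes[1:]):
            if mode == "span_to_span":
                up_end, down_start = up.span.end, down.span.start
            else:
                up_end = _utr_bounds(up)[1]
                down_start = _utr_bounds(down)[0]
            out.append(
                IntergenicDistance(
                    upstream_gene=up.gene_id,
                    downstream_gene=down.gene_id,
                    distance=down_start - up_end - 1,
                )
            )
    return out


def summarize_lengths(
    lengths: Sequence[int],
    thresholds: Sequence[int] = (1000,),
    median_convention: Literal["lower", "interpolate"] = "lower",
) -> LengthSummary:
    """n, median, mean and fraction-above-threshold for a length sample.

    The default median convention returns the lower middle element for
    even n (so the median of an integer sample stays an integer);
    ``interpolate`` gives the usual midpoint.
    """
    if not lengths:
        raise ValueError("cannot summarize an empty length list")
    ordered = sorted(lengths)
    n = len(ordered)
    if median_convention == "lower":
        med: int | float = ordered[(n - 1) // 2]
    elif median_convention == "interpolate":
        med = statistics.median(ordered)
    else:
        raise ValueError(f"unknown median_convention {median_convention!r}")
    return LengthSummary(
        n=n,
        median=med,
        mean=sum(ordered) / n,
        fraction_above={t: sum(1 for x in ordered if x > t) / n for t in thresholds},
    )
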
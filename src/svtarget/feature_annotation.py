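"""Canonical-transcript selection, intron/exon/UTR feature tables,
site-to-feature assignment, length-normalised feature percentages, and
metagene profiles.

All internal intervals are 0-based half-open; the GTF reader/writer in
:mod:`svtarget.io` converts to/from the 1-based closed on-disk convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnnotationError, ConsistencyError, CoordinateError

Interval = tuple[int, int]

FEATURE_CLASSES = ("intron", "exon", "UTR5", "UTR3", "UTR5/exon", "UTR3/exon")
JUNCTION_CLASSES = ("UTR5/exon", "UTR3/exon")

#: GTF tag values counted as transcript-confidence evidence. The allowlist is
#: configuration; these cover the common confidence-style tags.
DEFAULT_TAG_ALLOWLIST = frozenset({
    "basic", "Ensembl_canonical", "MANE_Select", "CCDS",
    "appris_principal_1", "GENCODE_Primary",
})


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    exons: tuple[Interval, ...]
    utr5: tuple[Interval, ...] = ()
    utr3: tuple[Interval, ...] = ()
    tags: tuple[str, ...] = ()

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    @property
    def span(self) -> Interval:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return (min(starts), max(ends))


@dataclass(frozen=True)
class FeatureRecord:
    gene_id: str
    feature: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FeatureTable:
    records: list[FeatureRecord]
    total_length: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.total_length:
            totals: dict[str, int] = {}
            for rec in self.records:
                totals[rec.feature] = totals.get(rec.feature, 0) + rec.length
            self.total_length = totals


@dataclass(frozen=True)
class MetageneProfile:
    n_bins: int
    density: np.ndarray


def select_canonical(genes: list[GeneModel],
                     tag_allowlist: frozenset[str] = DEFAULT_TAG_ALLOWLIST
                     ) -> dict[str, str]:
    """One transcript per gene: maximal allowlisted-tag count, ties broken by
    lexicographically smaller transcript ID."""
    chosen: dict[str, str] = {}
    for gene in genes:
        if not gene.transcripts:
            raise AnnotationError(f"gene {gene.gene_id!r} has no transcripts")
        ranked = sorted(
            gene.transcripts,
            key=lambda t: (-len(set(t.tags) & tag_allowlist), t.transcript_id),
        )
        chosen[gene.gene_id] = ranked[0].transcript_id
    return chosen


def build_feature_table(genes: list[GeneModel], canonical_map: dict[str, str],
                        junction_halfwidth: int = 10) -> FeatureTable:
    """Intron/exon/UTR/junction intervals per canonical transcript.

    Introns are the gaps between consecutive exons. Exon records exclude UTR
    portions so that intron+exon+UTR5+UTR3 tile the transcript span; junction
    records (UTR5/exon, UTR3/exon) are fixed-width windows around each
    UTR-CDS boundary and deliberately overlap their neighbours.
    """
    records: list[FeatureRecord] = []
    for gene in genes:
        tx = _resolve_canonical(gene, canonical_map)
        exons = sorted(tx.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"transcript {tx.transcript_id!r}: overlapping exons "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
            if s2 > e1:
                records.append(FeatureRecord(gene.gene_id, "intron", e1, s2))

        utr = sorted(tx.utr5) + sorted(tx.utr3)
        for s, e in exons:
            for cs, ce in _subtract(s, e, utr):
                records.append(FeatureRecord(gene.gene_id, "exon", cs, ce))
        for name, intervals in (("UTR5", tx.utr5), ("UTR3", tx.utr3)):
            for s, e in intervals:
                records.append(FeatureRecord(gene.gene_id, name, s, e))
                boundary = e if name == "UTR5" else s
                lo = max(tx.span[0], boundary - junction_halfwidth)
                hi = min(tx.span[1], boundary + junction_halfwidth)
                if hi > lo:
                    records.append(
                        FeatureRecord(gene.gene_id, f"{name}/exon", lo, hi)
                    )
    records.sort(key=lambda r: (r.gene_id, r.start, r.feature))
    return FeatureTable(records=records)


def _resolve_canonical(gene: GeneModel, canonical_map: dict[str, str]) -> TranscriptModel:
    tx_id = canonical_map.get(gene.gene_id)
    for tx in gene.transcripts:
        if tx.transcript_id == tx_id:
            return tx
    raise AnnotationError(
        f"gene {gene.gene_id!r}: canonical transcript {tx_id!r} not found"
    )


def _subtract(start: int, end: int, cuts: list[Interval]) -> list[Interval]:
    """Interval [start, end) minus a sorted list of intervals."""
    out = []
    cursor = start
    for cs, ce in cuts:
        if ce <= cursor or cs >= end:
            continue
        if cs > cursor:
            out.append((cursor, min(cs, end)))
        cursor = max(cursor, ce)
    if cursor < end:
        out.append((cursor, end))
    return out


def annotate_sites(sites: list, table: FeatureTable,
                   include_junctions: bool = False
                   ) -> list[tuple[object, FeatureRecord | None]]:
    """Left-outer-join of sites onto the feature table.

    Every site appears at least once; a site overlapping no feature carries a
    null feature, and a site overlapping several features yields one row per
    overlap. Sites need ``gene_id``/``start``/``end`` attributes or are
    ``(gene_id, start, end)`` tuples. Junction records are excluded from the
    join by default so that tiling features partition each site.
    """
    by_gene: dict[str, list[FeatureRecord]] = {}
    for rec in table.records:
        if not include_junctions and rec.feature in JUNCTION_CLASSES:
            continue
        by_gene.setdefault(rec.gene_id, []).append(rec)

    rows: list[tuple[object, FeatureRecord | None]] = []
    for site in sites:
        gene_id, start, end = _site_coords(site)
        overlaps = [
            rec for rec in by_gene.get(gene_id, ())
            if rec.start < end and start < rec.end
        ]
        if overlaps:
            rows.extend((site, rec) for rec in overlaps)
        else:
            rows.append((site, None))
    return rows


def _site_coords(site) -> tuple[str, int, int]:
    if isinstance(site, tuple):
        return site[0], site[1], site[2]
    return site.gene_id, site.start, site.end


def feature_percentages(annotated_sites: list[tuple[object, FeatureRecord | None]],
                        table: FeatureTable) -> dict[str, float]:
    """Length-normalised feature shares.

    Per-feature density = site count / total feature length; percentages are
    densities rescaled to sum to 100.
    """
    counts: dict[str, int] = {}
    for _, rec in annotated_sites:
        if rec is not None:
            counts[rec.feature] = counts.get(rec.feature, 0) + 1
    densities: dict[str, float] = {}
    for feature, count in counts.items():
        total = table.total_length.get(feature, 0)
        if total == 0:
            raise ConsistencyError(
                f"feature class {feature!r} has zero total length but "
                f"{count} assigned sites"
            )
        densities[feature] = count / total
    denom = sum(densities.values())
    if denom == 0:
        return {}
    return {f: 100.0 * d / denom for f, d in densities.items()}


def metagene_profile(sites: list, genes: list[GeneModel],
                     canonical_map: dict[str, str],
                     n_bins: int = 100) -> MetageneProfile:
    """Distribution of site midpoints along normalised transcript length.

    Midpoints map to a relative position in [0, 1) on the canonical
    transcript, flipped for minus-strand genes so that bin 0 is always the
    transcript 5' end; the binned density sums to 1 when any site exists.
    """
    spans: dict[str, tuple[Interval, str]] = {}
    for gene in genes:
        tx = _resolve_canonical(gene, canonical_map)
        spans[gene.gene_id] = (tx.span, gene.strand)

    density = np.zeros(n_bins)
    for site in sites:
        gene_id, start, end = _site_coords(site)
        if gene_id not in spans:
            raise CoordinateError(f"site on unknown gene {gene_id!r}")
        (tx_start, tx_end), strand = spans[gene_id]
        mid = (start + end) / 2.0
        if not (tx_start <= mid <= tx_end):
            raise CoordinateError(
                f"site midpoint {mid} outside transcript span "
                f"[{tx_start}, {tx_end}) of gene {gene_id!r}"
            )
        rel = (mid - tx_start) / (tx_end - tx_start)
        if strand == "-":
            rel = 1.0 - rel
        density[min(int(rel * n_bins), n_bins - 1)] += 1
    total = density.sum()
    if total > 0:
        density = density / total
    return MetageneProfile(n_bins=n_bins, density=density)
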
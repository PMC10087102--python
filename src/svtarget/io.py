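"""On-disk formats.

GTF is 1-based closed on disk and converted to the internal 0-based half-open
convention on read (and back on write); the converters are bijective. BED is
0-based half-open in both places. All outputs are plain text.
"""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError
from .feature_annotation import FeatureRecord, FeatureTable, GeneModel, TranscriptModel
from .fragment_coverage import CoverageProfile, FragmentCall
from .synthetic_data import PlantedSite, Read

_GTF_FEATURE_NAMES = {"UTR5": "five_prime_utr", "UTR3": "three_prime_utr"}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_gtf(genes: list[GeneModel], path: str | Path) -> None:
    """gene/transcript/exon/UTR records with gene_id, transcript_id and tag
    attributes; 1-based closed coordinates."""
    with open(path, "w") as fh:
        for gene in genes:
            gs, ge = gene.span
            fh.write(_gtf_line(gene.chrom, "gene", gs, ge, gene.strand,
                               f'gene_id "{gene.gene_id}";'))
            for tx in gene.transcripts:
                ts, te = tx.span
                attrs = (f'gene_id "{gene.gene_id}"; '
                         f'transcript_id "{tx.transcript_id}";')
                for tag in tx.tags:
                    attrs += f' tag "{tag}";'
                fh.write(_gtf_line(gene.chrom, "transcript", ts, te,
                                   gene.strand, attrs))
                base = (f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{tx.transcript_id}";')
                for s, e in tx.exons:
                    fh.write(_gtf_line(gene.chrom, "exon", s, e, gene.strand, base))
                for name, intervals in (("five_prime_utr", tx.utr5),
                                        ("three_prime_utr", tx.utr3)):
                    for s, e in intervals:
                        fh.write(_gtf_line(gene.chrom, name, s, e,
                                           gene.strand, base))


def _gtf_line(chrom: str, feature: str, start0: int, end0: int, strand: str,
              attrs: str) -> str:
    # 0-based half-open -> 1-based closed
    return (f"{chrom}\tsvtarget\t{feature}\t{start0 + 1}\t{end0}\t.\t"
            f"{strand}\t.\t{attrs}\n")


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read a GTF back into gene models (inverse of :func:`write_gtf`)."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attr_str = fields
            attrs = _parse_attrs(attr_str)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id")
            if gene_id not in genes:
                genes[gene_id] = {"chrom": chrom, "strand": strand, "tx": {}}
                order.append(gene_id)
            if feature == "gene":
                continue
            tx_id = attrs.get("transcript_id")
            if tx_id is None:
                raise ParseError(f"{path}:{lineno}: missing transcript_id")
            tx = genes[gene_id]["tx"].setdefault(
                tx_id, {"exons": [], "utr5": [], "utr3": [], "tags": []})
            iv = (int(start) - 1, int(end))  # 1-based closed -> half-open
            if feature == "exon":
                tx["exons"].append(iv)
            elif feature == "five_prime_utr":
                tx["utr5"].append(iv)
            elif feature == "three_prime_utr":
                tx["utr3"].append(iv)
            elif feature == "transcript":
                tx["tags"] = attrs.get("tags", [])
    out = []
    for gene_id in order:
        info = genes[gene_id]
        transcripts = tuple(
            TranscriptModel(
                transcript_id=tx_id,
                exons=tuple(sorted(tx["exons"])),
                utr5=tuple(sorted(tx["utr5"])),
                utr3=tuple(sorted(tx["utr3"])),
                tags=tuple(tx["tags"]),
            )
            for tx_id, tx in info["tx"].items()
        )
        out.append(GeneModel(gene_id=gene_id, chrom=info["chrom"],
                             strand=info["strand"], transcripts=transcripts))
    return out


def _parse_attrs(attr_str: str) -> dict:
    attrs: dict = {"tags": []}
    for chunk in attr_str.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        value = value.strip().strip('"')
        if key == "tag":
            attrs["tags"].append(value)
        else:
            attrs[key] = value
    return attrs


def write_reads_bed(reads: list[Read], reference_id: str,
                    path: str | Path) -> None:
    """6-column BED: chrom, start, end, name(condition), score, strand."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"{reference_id}\t{read.start}\t{read.end}\t"
                     f"{read.condition}.{i}\t0\t+\n")


def read_reads_bed(path: str | Path) -> list[Read]:
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            condition = "WT"
            if len(fields) >= 4:
                condition = fields[3].rsplit(".", 1)[0]
            reads.append(Read(start=int(fields[1]), end=int(fields[2]),
                              condition=condition))
    return reads


def write_coverage_tsv(profile: CoverageProfile, path: str | Path) -> None:
    """Two-column (position, depth) dump of non-zero positions."""
    with open(path, "w") as fh:
        for pos, depth in enumerate(profile.values):
            if depth != 0:
                fh.write(f"{pos}\t{depth:g}\n")


def write_fragment_calls(calls: list[FragmentCall], reference_id: str,
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tmean_wt\tmean_kd\tdepletion_ratio\t"
                 "dicer_dependent\n")
        for call in calls:
            fh.write(f"{reference_id}\t{call.start}\t{call.end}\t"
                     f"{call.mean_wt:.4g}\t{call.mean_kd:.4g}\t"
                     f"{call.depletion_ratio:.4g}\t"
                     f"{int(call.dicer_dependent)}\n")


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]


def write_planted_sites(sites: list[PlantedSite], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_id", "start", "end", "feature", "architecture",
                         "guide_id", "loop_sequence"])
        for s in sites:
            writer.writerow([s.gene_id, s.start, s.end, s.feature,
                             s.architecture, s.guide_id, s.loop_sequence])


def write_sites_tsv(sites, path: str | Path) -> None:
    """Predicted target sites with alignment score/energy."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_id", "transcript_id", "guide_id", "start",
                         "end", "score", "energy"])
        for s in sites:
            writer.writerow([s.gene_id, s.transcript_id, s.guide_id,
                             s.start, s.end, f"{s.alignment.score:g}",
                             f"{s.alignment.energy:.2f}"])


def read_sites_tsv(path: str | Path) -> list[tuple[str, int, int]]:
    """Sites as (gene_id, start, end) tuples for feature annotation."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append((row["gene_id"], int(row["start"]), int(row["end"])))
    return out


def write_feature_table_bed(table: FeatureTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in table.records:
            fh.write(f"{rec.gene_id}\t{rec.start}\t{rec.end}\t{rec.feature}\n")


def read_feature_table_bed(path: str | Path) -> FeatureTable:
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, feature = line.split("\t")[:4]
            records.append(FeatureRecord(chrom, feature.strip(),
                                         int(start), int(end)))
    return FeatureTable(records=records)
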
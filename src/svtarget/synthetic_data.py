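"""Synthetic inputs for the whole pipeline.

Generates (a) a transcriptome with UTR/exon/intron structure, (b) planted
guide-binding sites with the duplex architectures the scanner is expected to
recover, (c) small-RNA read pileups with a Dicer-dependent 3'-fragment peak,
and (d) gene universes with sets of configurable overlap. Everything is
deterministic for a fixed ``rng_seed``.

Architectures
-------------
``no_loop``
    The planted window is the reverse complement of guide positions 2..L
    (length L-1; 23 nt for a 24-nt guide).
``canonical_loop``
    As ``no_loop`` plus a single unpaired 5-nt insertion on the target strand
    opposite guide positions 11-12, drawn from {CAUCA, CAUUA} (length L+4;
    28 nt for a 24-nt guide).
``seed_only``
    Only guide positions 2-8 find complementary bases; the remaining window
    positions are chosen to neither WC- nor wobble-pair with the guide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .errors import ConfigurationError, PlacementError
from ._seq import anti_pair_bases, revcomp_rna, to_dna, to_rna
from .feature_annotation import FeatureRecord, GeneModel, TranscriptModel
from .guide_model import GuideRNA

ARCHITECTURES = ("canonical_loop", "no_loop", "seed_only")
LOOP_SEQUENCES = ("CAUCA", "CAUUA")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for every generator in this module. See invariants in
    :meth:`validate`; ``validate`` is called by each generator."""

    rng_seed: int = 0
    n_genes: int = 20
    intron_fraction: float = 0.8
    site_architecture_mix: dict = field(
        default_factory=lambda: {"canonical_loop": 0.6, "no_loop": 0.3,
                                 "seed_only": 0.1})
    loop_sequence_mix: dict = field(
        default_factory=lambda: {"CAUCA": 0.6, "CAUUA": 0.4})
    site_feature_mix: dict = field(
        default_factory=lambda: {"intron": 0.9, "exon": 0.1})
    planted_sites_per_gene: int = 1
    fragment_length_range: tuple[int, int] = (22, 24)
    dicer_depletion_factor: float = 4.0
    n_reads: int = 5000
    background_read_fraction: float = 0.1
    universe_size: int = 14759
    set_sizes: tuple[int, int] = (227, 584)
    forced_overlap: int = 29

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes: must be >= 1")
        if not (0.0 <= self.intron_fraction < 1.0):
            raise ConfigurationError("intron_fraction: must be in [0, 1)")
        for name, mix in (("site_architecture_mix", self.site_architecture_mix),
                          ("loop_sequence_mix", self.loop_sequence_mix),
                          ("site_feature_mix", self.site_feature_mix)):
            if mix and abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name}: fractions must sum to 1")
        unknown = set(self.site_architecture_mix) - set(ARCHITECTURES)
        if unknown:
            raise ConfigurationError(
                f"site_architecture_mix: unknown architectures {sorted(unknown)}")
        lo, hi = self.fragment_length_range
        if not (15 <= lo <= hi <= 30):
            raise ConfigurationError(
                "fragment_length_range: must lie within the read-length "
                "filter window [15, 30]")
        if self.dicer_depletion_factor < 1:
            raise ConfigurationError("dicer_depletion_factor: must be >= 1")
        n1, n2 = self.set_sizes
        if n1 > self.universe_size or n2 > self.universe_size:
            raise ConfigurationError("set_sizes: must be <= universe_size")
        if self.forced_overlap > min(n1, n2):
            raise ConfigurationError(
                "forced_overlap: must be <= min(set_sizes)")
        if self.forced_overlap < 0:
            raise ConfigurationError("forced_overlap: must be >= 0")
        if n1 + n2 - self.forced_overlap > self.universe_size:
            raise ConfigurationError(
                "forced_overlap: sets cannot fit in the universe")
        if self.planted_sites_per_gene < 0:
            raise ConfigurationError("planted_sites_per_gene: must be >= 0")
        if not (0.0 <= self.background_read_fraction <= 1.0):
            raise ConfigurationError(
                "background_read_fraction: must be in [0, 1]")


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth record for one planted guide-binding window."""

    gene_id: str
    start: int
    end: int
    feature: str
    architecture: str
    guide_id: str
    loop_sequence: str = ""

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Read:
    """A BED-like aligned read interval on a reference's local coordinates."""

    start: int
    end: int
    condition: str = "WT"

    @property
    def length(self) -> int:
        return self.end - self.start


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def generate_transcriptome(config: SyntheticConfig
                           ) -> tuple[list[GeneModel], dict[str, str]]:
    """Gene models plus per-gene pre-mRNA sequences (DNA letters).

    Each gene gets one transcript laid out as UTR5 - exon/intron alternation -
    UTR3 on its own reference (chrom = gene_id, plus strand); intron length is
    allocated so that the intronic share of each gene matches
    ``intron_fraction``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    genes: list[GeneModel] = []
    sequences: dict[str, str] = {}
    for gi in range(config.n_genes):
        gene_id = f"g{gi:05d}"
        f = config.intron_fraction
        n_exons = 1 if f == 0 else int(rng.integers(2, 6))
        exon_lens = rng.integers(150, 400, size=n_exons)
        exonic = int(exon_lens.sum())
        intron_total = 0 if f == 0 else int(round(exonic * f / (1.0 - f)))
        if n_exons > 1:
            weights = rng.dirichlet(np.ones(n_exons - 1))
            intron_lens = np.maximum(
                40, np.round(weights * intron_total).astype(int))
        else:
            intron_lens = np.array([], dtype=int)

        exons = []
        cursor = 0
        for j, elen in enumerate(exon_lens):
            exons.append((cursor, cursor + int(elen)))
            cursor += int(elen)
            if j < n_exons - 1:
                cursor += int(intron_lens[j])
        span_end = exons[-1][1]

        u5 = int(rng.integers(30, min(100, exon_lens[0] - 30)))
        u3 = int(rng.integers(30, min(100, exon_lens[-1] - 30)))
        tx = TranscriptModel(
            transcript_id=f"{gene_id}.t1",
            exons=tuple(exons),
            utr5=((0, u5),),
            utr3=((span_end - u3, span_end),),
            tags=("basic",),
        )
        genes.append(GeneModel(gene_id=gene_id, chrom=gene_id, strand="+",
                               transcripts=(tx,)))
        sequences[gene_id] = _random_dna(rng, span_end)
    return genes, sequences


def _target_window(guide: GuideRNA, architecture: str, loop_seq: str,
                   rng: np.random.Generator) -> str:
    """Build the target-strand window (RNA, 5'->3') for one architecture."""
    g = guide.sequence
    L = len(g)
    core = revcomp_rna(g[1:])  # pairs guide positions 2..L; window[k] <-> guide L-k
    if architecture == "no_loop":
        return core
    if architecture == "canonical_loop":
        # insertion point: between the bases pairing guide positions 12 and 11
        # (window indices L-13 and L-12 before insertion), so the loop sits
        # opposite the guide 11-12 junction
        cut = L - 11
        return core[:cut] + loop_seq + core[cut:]
    if architecture == "seed_only":
        chars = []
        for k in range(len(core)):
            p = L - k  # guide position paired by window index k
            if 2 <= p <= 8:
                chars.append(core[k])
            else:
                options = anti_pair_bases(g[p - 1])
                chars.append(options[rng.integers(0, len(options))])
        return "".join(chars)
    raise ConfigurationError(f"architecture: unknown {architecture!r}")


def plant_sites(genes: list[GeneModel], sequences: dict[str, str],
                guide: GuideRNA, config: SyntheticConfig
                ) -> tuple[dict[str, str], list[PlantedSite]]:
    """Write guide-binding windows into gene sequences and return the truth.

    Sites are placed uniformly inside a feature drawn from
    ``site_feature_mix`` of the gene's first transcript and never overlap each
    other. Raises :class:`PlacementError` when a window cannot fit.
    """
    config.validate()
    if len(guide) < 19:
        raise ConfigurationError(
            "guide: must be >= 19 nt so that positions 2-18 exist")
    rng = np.random.default_rng(config.rng_seed + 1)
    arch_names = sorted(config.site_architecture_mix)
    arch_probs = [config.site_architecture_mix[a] for a in arch_names]
    loop_names = sorted(config.loop_sequence_mix)
    loop_probs = [config.loop_sequence_mix[a] for a in loop_names]
    feat_names = sorted(config.site_feature_mix)
    feat_probs = [config.site_feature_mix[a] for a in feat_names]

    out_sequences = dict(sequences)
    sites: list[PlantedSite] = []
    for gene in genes:
        tx = gene.transcripts[0]
        occupied: list[tuple[int, int]] = []
        for _ in range(config.planted_sites_per_gene):
            architecture = arch_names[rng.choice(len(arch_names), p=arch_probs)]
            loop_seq = ""
            if architecture == "canonical_loop":
                loop_seq = loop_names[rng.choice(len(loop_names), p=loop_probs)]
            window = _target_window(guide, architecture, loop_seq, rng)
            feature = feat_names[rng.choice(len(feat_names), p=feat_probs)]
            interval = _place_window(tx, feature, len(window), occupied, rng)
            start, end = interval
            occupied.append(interval)
            seq = out_sequences[gene.gene_id]
            out_sequences[gene.gene_id] = (
                seq[:start] + to_dna(window) + seq[end:])
            sites.append(PlantedSite(
                gene_id=gene.gene_id, start=start, end=end, feature=feature,
                architecture=architecture, guide_id=guide.id,
                loop_sequence=loop_seq))
    return out_sequences, sites


def _feature_intervals(tx: TranscriptModel, feature: str) -> list[tuple[int, int]]:
    if feature == "intron":
        exons = sorted(tx.exons)
        return [(e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:]) if s2 > e1]
    if feature == "exon":
        cuts = sorted(tx.utr5) + sorted(tx.utr3)
        out = []
        for s, e in sorted(tx.exons):
            cursor = s
            for cs, ce in cuts:
                if ce <= cursor or cs >= e:
                    continue
                if cs > cursor:
                    out.append((cursor, cs))
                cursor = max(cursor, ce)
            if cursor < e:
                out.append((cursor, e))
        return out
    if feature == "UTR5":
        return list(tx.utr5)
    if feature == "UTR3":
        return list(tx.utr3)
    raise ConfigurationError(f"site_feature_mix: unknown feature {feature!r}")


def _place_window(tx: TranscriptModel, feature: str, wlen: int,
                  occupied: list[tuple[int, int]],
                  rng: np.random.Generator, max_tries: int = 50
                  ) -> tuple[int, int]:
    intervals = [iv for iv in _feature_intervals(tx, feature)
                 if iv[1] - iv[0] >= wlen]
    if not intervals:
        raise PlacementError(
            f"transcript {tx.transcript_id!r}: no {feature} interval can hold "
            f"a {wlen}-nt window")
    for _ in range(max_tries):
        fs, fe = intervals[rng.integers(0, len(intervals))]
        start = int(rng.integers(fs, fe - wlen + 1))
        end = start + wlen
        if not any(start < oe and os_ < end for os_, oe in occupied):
            return (start, end)
    raise PlacementError(
        f"transcript {tx.transcript_id!r}: could not place a {wlen}-nt window "
        f"in {feature} after {max_tries} tries")


def generate_reads(vault_sequence: str, config: SyntheticConfig
                   ) -> list[Read]:
    """Small-RNA reads over a vault gene for WT and DicerKD conditions.

    Signal reads are anchored at the 3' end with lengths drawn uniformly from
    ``fragment_length_range``; the DicerKD signal count is the WT count
    divided by ``dicer_depletion_factor``. A ``background_read_fraction``
    share of extra reads per condition is scattered 5' of the fragment window.
    """
    config.validate()
    seq = to_rna(vault_sequence)
    lo, hi = config.fragment_length_range
    L = len(seq)
    if L < hi:
        raise ConfigurationError(
            "fragment_length_range: vault sequence shorter than max fragment")
    rng = np.random.default_rng(config.rng_seed + 2)
    reads: list[Read] = []
    n_signal = {"WT": config.n_reads,
                "DicerKD": int(round(config.n_reads /
                                     config.dicer_depletion_factor))}
    n_background = int(round(config.n_reads * config.background_read_fraction))
    for condition in ("WT", "DicerKD"):
        lengths = rng.integers(lo, hi + 1, size=n_signal[condition])
        reads.extend(Read(start=L - int(l), end=L, condition=condition)
                     for l in lengths)
        if L - hi - lo > 0 and n_background > 0:
            blens = rng.integers(lo, hi + 1, size=n_background)
            for bl in blens:
                bstart = int(rng.integers(0, L - hi - int(bl) + 1))
                reads.append(Read(start=bstart, end=bstart + int(bl),
                                  condition=condition))
    return reads


def generate_gene_sets(config: SyntheticConfig
                       ) -> tuple[list[str], list[str], list[str]]:
    """A gene universe and two member sets with an exactly forced overlap."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed + 3)
    n1, n2 = config.set_sizes
    k = config.forced_overlap
    universe = [f"gene{i:05d}" for i in range(config.universe_size)]
    idx = rng.permutation(config.universe_size)
    shared = idx[:k]
    only_a = idx[k:k + (n1 - k)]
    only_b = idx[k + (n1 - k):k + (n1 - k) + (n2 - k)]
    set_a = sorted(universe[i] for i in np.concatenate([shared, only_a]))
    set_b = sorted(universe[i] for i in np.concatenate([shared, only_b]))
    return universe, set_a, set_b


def truth_feature_records(sites: list[PlantedSite]) -> list[FeatureRecord]:
    """Planted sites as feature-annotation-ready interval records."""
    return [FeatureRecord(s.gene_id, s.feature, s.start, s.end) for s in sites]
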
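"""Wobble-aware, seed-weighted duplex alignment and architecture classification.

The aligner performs a local dynamic-programming alignment of a guide RNA
against a target window in antiparallel orientation: guide position p pairs a
target position that decreases as p increases. Watson-Crick pairs and G:U
wobbles score positively (seed positions are up-weighted), mismatches and gaps
are penalised with affine gap costs. Candidate sites must clear a score
threshold, a nearest-neighbour duplex free-energy threshold, and (optionally)
a strict-seed requirement before they are reported.

Architecture classification summarises each accepted duplex: seed pairing,
wobble positions, pairing extent, the central pair scheme at guide positions
10-12, and any target-side loop (a run of unpaired target nucleotides bulging
out of the duplex), including its sequence for consensus counting.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, ConsistencyError
from ._seq import pair_type, to_rna
from .guide_model import GuideRNA

NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignParams:
    """Scoring and filtering parameters for the duplex scanner.

    The score/energy thresholds and the strict-seed switch correspond to the
    conventional "-sc 150 -en -30 -strict" settings; scoring constants mirror
    commonly used seed-weighted alignment defaults and are all configurable.
    """

    score_threshold: float = 150.0
    energy_threshold: float = -30.0
    strict_seed: bool = True
    seed_range: tuple[int, int] = (2, 8)
    extension_boundary: int = 18
    central_positions: tuple[int, int, int] = (10, 11, 12)
    match_score: float = 5.0
    wobble_score: float = 1.0
    mismatch_penalty: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_scale: float = 4.0
    max_target_loop: int = 6
    max_seed_wobbles: int = 1

    def __post_init__(self) -> None:
        if self.score_threshold <= 0:
            raise ConfigurationError("score_threshold: must be > 0")
        if self.energy_threshold >= 0:
            raise ConfigurationError("energy_threshold: must be < 0")
        if self.seed_scale < 1:
            raise ConfigurationError("seed_scale: must be >= 1")
        lo, hi = self.seed_range
        if lo < 2 or hi < lo:
            raise ConfigurationError("seed_range: must lie within [2, guide length]")


@dataclass(frozen=True)
class DuplexAlignment:
    """A guide-target duplex.

    ``guide_pairs`` lists paired positions only — ``(guide_pos, target_pos,
    'WC'|'wobble')`` with guide positions 1-based and strictly increasing,
    target positions 0-based and strictly decreasing (antiparallel). Aligned
    but mismatched oppositions are kept in ``columns`` (pair type None) for
    energy and architecture computation.
    """

    guide_pairs: tuple[tuple[int, int, str], ...]
    columns: tuple[tuple[int | None, int | None, str | None], ...]
    target_span: tuple[int, int]
    guide_span: tuple[int, int]
    score: float
    energy: float | None = field(default=None)

    @property
    def n_paired(self) -> int:
        return len(self.guide_pairs)

    @property
    def target_length(self) -> int:
        return self.target_span[1] - self.target_span[0]


@dataclass(frozen=True)
class TargetSite:
    """A predicted guide-binding locus on a transcript."""

    gene_id: str
    transcript_id: str
    guide_id: str
    alignment: DuplexAlignment
    passes_thresholds: bool

    @property
    def start(self) -> int:
        return self.alignment.target_span[0]

    @property
    def end(self) -> int:
        return self.alignment.target_span[1]


@dataclass(frozen=True)
class ArchitectureReport:
    seed_paired: bool
    wobble_positions: tuple[int, ...]
    pairing_extent: int
    loop_length: int
    loop_guide_anchor: tuple[int, int] | None
    loop_sequence: str
    central_scheme: tuple[str, str, str]
    alignment_length_target: int


def _position_score(guide_pos: int, ptype: str | None, params: AlignParams) -> float:
    if ptype == "WC":
        base = params.match_score
    elif ptype == "wobble":
        base = params.wobble_score
    else:
        base = params.mismatch_penalty
    lo, hi = params.seed_range
    if lo <= guide_pos <= hi:
        base *= params.seed_scale
    return base


def align_window(guide: GuideRNA, target_window: str,
                 params: AlignParams | None = None) -> DuplexAlignment | None:
    """Best local antiparallel alignment of ``guide`` against a target window.

    Returns None when no alignment scores above zero. Guide position 1 is
    never required (or allowed) to pair. The alignment always starts and ends
    on a paired column.
    """
    params = params or AlignParams()
    g = guide.sequence
    w = to_rna(target_window)
    n, m = len(g), len(w)
    seed_len = params.seed_range[1] - params.seed_range[0] + 1
    if n < 2 or m < seed_len:
        return None

    # Align guide (i = 1..n, 1-based) against the reversed window
    # (k = 1..m, R[k] = w[m-k]); a pair (i, k) is guide_pos i opposite
    # target_pos m-k, so target positions decrease as i increases.
    r = w[::-1]

    # Gotoh affine DP. M: column ends in an opposition (pair or mismatch);
    # X: gap in guide (unpaired target base = target-side insertion);
    # Y: gap in target (unpaired guide base).
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)

    ptypes: list[list[str | None]] = [[None] * (m + 1) for _ in range(n + 1)]
    for i in range(2, n + 1):  # position 1 never pairs
        gi = g[i - 1]
        for k in range(1, m + 1):
            ptypes[i][k] = pair_type(gi, r[k - 1])

    best = 0.0
    best_cell = None
    for i in range(2, n + 1):
        for k in range(1, m + 1):
            sub = _position_score(i, ptypes[i][k], params)
            prev = max(0.0, M[i - 1, k - 1], X[i - 1, k - 1], Y[i - 1, k - 1])
            M[i, k] = prev + sub
            X[i, k] = max(M[i, k - 1] + params.gap_open,
                          X[i, k - 1] + params.gap_extend)
            Y[i, k] = max(M[i - 1, k] + params.gap_open,
                          Y[i - 1, k] + params.gap_extend)
            # a local alignment must end on a pair, not a mismatch or gap
            if ptypes[i][k] is not None and M[i, k] > best:
                best = M[i, k]
                best_cell = (i, k)

    if best_cell is None or best <= 0:
        return None

    # Traceback from the best M cell.
    columns: list[tuple[int | None, int | None, str | None]] = []
    i, k = best_cell
    state = "M"
    while i > 0 and k > 0:
        if state == "M":
            score_here = M[i, k]
            sub = _position_score(i, ptypes[i][k], params)
            columns.append((i, m - k, ptypes[i][k]))
            prev = score_here - sub
            if abs(prev) < 1e-9:
                break
            if abs(prev - M[i - 1, k - 1]) < 1e-9:
                state = "M"
            elif abs(prev - X[i - 1, k - 1]) < 1e-9:
                state = "X"
            else:
                state = "Y"
            i, k = i - 1, k - 1
        elif state == "X":
            columns.append((None, m - k, None))
            if abs(X[i, k] - (M[i, k - 1] + params.gap_open)) < 1e-9:
                state = "M"
            k -= 1
        else:  # Y
            columns.append((i, None, None))
            if abs(Y[i, k] - (M[i - 1, k] + params.gap_open)) < 1e-9:
                state = "M"
            i -= 1

    columns.reverse()
    # Trim leading/trailing non-pair columns (local alignment ends on pairs).
    while columns and columns[0][2] is None:
        columns.pop(0)
    while columns and columns[-1][2] is None:
        columns.pop()
    if not columns:
        return None

    pairs = tuple((gi_, tj, pt) for gi_, tj, pt in columns if pt is not None)
    target_positions = [tj for _, tj, _ in columns if tj is not None]
    guide_positions = [gi_ for gi_, _, _ in columns if gi_ is not None]
    return DuplexAlignment(
        guide_pairs=pairs,
        columns=tuple(columns),
        target_span=(min(target_positions), max(target_positions) + 1),
        guide_span=(min(guide_positions), max(guide_positions)),
        score=float(best),
    )


# ---------------------------------------------------------------------------
# Nearest-neighbour duplex free energy
# ---------------------------------------------------------------------------

# Watson-Crick stack free energies (kcal/mol, 37C), keyed by
# "XY/ZW": top strand 5'-XY-3' over bottom strand 3'-ZW-5'.
_WC_STACKS = {
    "AA/UU": -0.93, "UU/AA": -0.93,
    "AU/UA": -1.10,
    "UA/AU": -1.33,
    "CU/GA": -2.08, "AG/UC": -2.08,
    "CA/GU": -2.11, "UG/AC": -2.11,
    "GU/CA": -2.24, "AC/UG": -2.24,
    "GA/CU": -2.35, "UC/AG": -2.35,
    "CG/GC": -2.36,
    "GG/CC": -3.26, "CC/GG": -3.26,
    "GC/CG": -3.42,
}
#: Stacks with at least one G:U pair are weakly stabilising on average; a
#: single representative value keeps the model monotone without claiming
#: parity with any folding package.
_WOBBLE_STACK = -0.5

_DUPLEX_INITIATION = 4.09
_TERMINAL_AU_PENALTY = 0.45

#: Internal/bulge loop penalties for small loops; larger loops extrapolate
#: logarithmically.
_LOOP_PENALTY = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}


def _loop_penalty(length: int) -> float:
    if length <= 0:
        return 0.0
    if length in _LOOP_PENALTY:
        return _LOOP_PENALTY[length]
    return _LOOP_PENALTY[6] + 1.08 * math.log(length / 6.0)


def _stack_energy(pair1: tuple[str, str], pair2: tuple[str, str]) -> float:
    key = f"{pair1[0]}{pair2[0]}/{pair1[1]}{pair2[1]}"
    if key in _WC_STACKS:
        return _WC_STACKS[key]
    return _WOBBLE_STACK


def duplex_energy(alignment: DuplexAlignment, guide: GuideRNA,
                  target_window: str, window_offset: int = 0) -> float:
    """Nearest-neighbour free energy (kcal/mol) of an aligned duplex.

    Stacking terms are summed over consecutive pair steps; interruptions
    (mismatches, bulges, target loops) contribute a loop penalty instead of a
    stack. Duplex initiation and terminal A:U/G:U penalties are added. Zero
    pairs is defined as 0 (no duplex). ``window_offset`` translates alignment
    target coordinates into ``target_window`` indices.
    """
    pairs = alignment.guide_pairs
    if not pairs:
        return 0.0
    w = to_rna(target_window)
    g = guide.sequence

    def bases(p: tuple[int, int, str]) -> tuple[str, str]:
        i, j, _ = p
        return g[i - 1], w[j - window_offset]

    for (i1, j1, _), (i2, j2, _) in zip(pairs, pairs[1:]):
        if i2 <= i1 or j2 >= j1:
            raise ConsistencyError("pairs not chainable in antiparallel order")

    energy = _DUPLEX_INITIATION
    for p1, p2 in zip(pairs, pairs[1:]):
        gap_g = p2[0] - p1[0] - 1   # unpaired guide bases between the pairs
        gap_t = p1[1] - p2[1] - 1   # unpaired target bases between the pairs
        if gap_g == 0 and gap_t == 0:
            energy += _stack_energy(bases(p1), bases(p2))
        else:
            energy += _loop_penalty(gap_g + gap_t)

    for end in (pairs[0], pairs[-1]):
        gb, tb = bases(end)
        if {gb, tb} != {"G", "C"}:
            energy += _TERMINAL_AU_PENALTY
    return energy


# ---------------------------------------------------------------------------
# Transcript scanning
# ---------------------------------------------------------------------------

def _seed_ok(alignment: DuplexAlignment, params: AlignParams) -> bool:
    """Strict-seed test: seed positions contiguously paired (consecutive
    target positions, no gaps), no mismatches, and at most
    ``max_seed_wobbles`` wobbles."""
    lo, hi = params.seed_range
    by_pos = {i: (j, pt) for i, j, pt in alignment.guide_pairs}
    wobbles = 0
    prev_j = None
    for p in range(lo, hi + 1):
        if p not in by_pos:
            return False
        j, pt = by_pos[p]
        if pt == "wobble":
            wobbles += 1
        if prev_j is not None and j != prev_j - 1:
            return False
        prev_j = j
    return wobbles <= params.max_seed_wobbles


def _passes(alignment: DuplexAlignment, params: AlignParams) -> bool:
    if alignment.score < params.score_threshold:
        return False
    if alignment.energy is None or alignment.energy > params.energy_threshold:
        return False
    if params.strict_seed and not _seed_ok(alignment, params):
        return False
    return True


def _seed_anchor_patterns(guide: GuideRNA, params: AlignParams) -> set[str]:
    """Target-strand 5'->3' k-mers compatible with a strict seed match."""
    lo, hi = params.seed_range
    seed = guide.sequence[lo - 1:hi]
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    wob = {"G": "U", "U": "G"}
    # target 5'->3' pairs the seed read 3'->5'
    rev_seed = seed[::-1]
    patterns = {"".join(comp[b] for b in rev_seed)}
    if params.max_seed_wobbles >= 1:
        for idx, b in enumerate(rev_seed):
            if b in wob:
                base = list(comp[c] for c in rev_seed)
                base[idx] = wob[b]
                patterns.add("".join(base))
    return patterns


def _candidate_windows(guide: GuideRNA, seq: str,
                       params: AlignParams) -> list[tuple[int, int]]:
    n = len(guide)
    L = len(seq)
    slack = 4
    width = n + params.max_target_loop + slack
    if not params.strict_seed:
        return [(s, min(s + width, L)) for s in range(0, max(L - 7, 1))]
    lo, hi = params.seed_range
    patterns = _seed_anchor_patterns(guide, params)
    klen = hi - lo + 1
    starts = []
    for t0 in range(L - klen + 1):
        if seq[t0:t0 + klen] in patterns:
            starts.append(t0)
    windows = []
    for t0 in starts:
        # guide position hi pairs target t0; positions hi+1..n extend 5'-ward
        # on the target, positions lo-1..2 extend 3'-ward.
        wstart = t0 - (n - hi) - params.max_target_loop - slack
        wend = t0 + klen + (lo - 2) + slack
        windows.append((max(0, wstart), min(L, wend)))
    return windows


def scan_transcript(guide: GuideRNA, transcript_sequence: str,
                    params: AlignParams | None = None,
                    gene_id: str = "", transcript_id: str = "") -> list[TargetSite]:
    """Scan the sense strand of a (pre-m)RNA sequence for guide-binding sites.

    Every returned site passes the score, energy, and (if enabled) strict-seed
    thresholds. Overlapping hits are resolved greedily to local score maxima;
    ties break toward the 5'-most target coordinate.
    """
    params = params or AlignParams()
    seq = to_rna(transcript_sequence)
    hits: list[DuplexAlignment] = []
    for wstart, wend in _candidate_windows(guide, seq, params):
        aln = align_window(guide, seq[wstart:wend], params)
        if aln is None:
            continue
        aln = _shift_alignment(aln, wstart)
        aln = replace(aln, energy=duplex_energy(aln, guide, seq))
        if _passes(aln, params):
            hits.append(aln)

    hits.sort(key=lambda a: (-a.score, a.target_span[0]))
    chosen: list[DuplexAlignment] = []
    occupied: list[tuple[int, int]] = []
    for aln in hits:
        s, e = aln.target_span
        if any(s < oe and os_ < e for os_, oe in occupied):
            continue
        # identical duplicates from overlapping candidate windows collapse here
        chosen.append(aln)
        occupied.append((s, e))
    chosen.sort(key=lambda a: a.target_span[0])
    return [
        TargetSite(gene_id=gene_id, transcript_id=transcript_id,
                   guide_id=guide.id, alignment=a, passes_thresholds=True)
        for a in chosen
    ]


def _shift_alignment(aln: DuplexAlignment, offset: int) -> DuplexAlignment:
    if offset == 0:
        return aln
    return DuplexAlignment(
        guide_pairs=tuple((i, j + offset, t) for i, j, t in aln.guide_pairs),
        columns=tuple((i, None if j is None else j + offset, t)
                      for i, j, t in aln.columns),
        target_span=(aln.target_span[0] + offset, aln.target_span[1] + offset),
        guide_span=aln.guide_span,
        score=aln.score,
        energy=aln.energy,
    )


def classify_architecture(site: TargetSite, target_sequence: str,
                          params: AlignParams | None = None) -> ArchitectureReport:
    """Per-duplex pairing features for an accepted site.

    ``loop_length`` counts unpaired target nucleotides between the paired
    flanks of the duplex (the target-side loop); ``loop_sequence`` reports the
    target strand 5'->3'.
    """
    params = params or AlignParams()
    aln = site.alignment
    seq = to_rna(target_sequence)
    pairs = aln.guide_pairs
    by_pos = {i: (j, pt) for i, j, pt in pairs}

    lo, hi = params.seed_range
    seed_paired = all(p in by_pos for p in range(lo, hi + 1))
    wobbles = tuple(i for i, _, pt in pairs if pt == "wobble")

    extent = 0
    p = lo
    while p in by_pos:
        extent = p
        p += 1

    # unpaired target positions internal to the duplex
    paired_targets = {j for _, j, _ in pairs}
    span_lo, span_hi = aln.target_span
    unpaired = [j for j in range(span_lo, span_hi) if j not in paired_targets]
    loop_length = len(unpaired)

    anchor = None
    loop_seq = ""
    if unpaired:
        # longest contiguous unpaired run defines the loop anchors/sequence
        runs: list[list[int]] = [[unpaired[0]]]
        for j in sorted(unpaired)[1:]:
            if j == runs[-1][-1] + 1:
                runs[-1].append(j)
            else:
                runs.append([j])
        longest = max(runs, key=len)
        loop_seq = seq[longest[0]:longest[-1] + 1]
        flank5 = [i for i, j, _ in pairs if j > longest[-1]]
        flank3 = [i for i, j, _ in pairs if j < longest[0]]
        if flank5 and flank3:
            anchor = (max(flank5), min(flank3))
        else:  # loop at the duplex edge: not internal, report no anchor
            anchor = None

    central = tuple(
        (by_pos[p][1] if p in by_pos else "none")
        for p in params.central_positions
    )
    return ArchitectureReport(
        seed_paired=seed_paired,
        wobble_positions=wobbles,
        pairing_extent=extent,
        loop_length=loop_length,
        loop_guide_anchor=anchor,
        loop_sequence=loop_seq,
        central_scheme=central,  # type: ignore[arg-type]
        alignment_length_target=aln.target_length,
    )


def loop_consensus(sites: list[TargetSite], sequences: dict[str, str],
                   params: AlignParams | None = None) -> dict[str, int]:
    """Count target-strand loop 5-mers over sites with a 5-nt loop.

    ``sequences`` maps gene_id to the transcript sequence each site was
    predicted on.
    """
    params = params or AlignParams()
    counts: Counter[str] = Counter()
    for site in sites:
        report = classify_architecture(site, sequences[site.gene_id], params)
        if report.loop_length == 5 and len(report.loop_sequence) == 5:
            counts[to_rna(report.loop_sequence)] += 1
    return dict(counts)


def format_alignment(site: TargetSite, target_sequence: str) -> str:
    """Three-line text rendering: guide, pairing marks ('|' WC, ':' wobble),
    target (5'->3' on the guide line, 3'->5' on the target line)."""
    aln = site.alignment
    seq = to_rna(target_sequence)
    gl, ml, tl = [], [], []
    for i, j, pt in aln.columns:
        gb = "-" if i is None else _guide_base(site, i)
        tb = "-" if j is None else seq[j]
        mark = {"WC": "|", "wobble": ":"}.get(pt, " ")
        gl.append(gb)
        ml.append(mark)
        tl.append(tb)
    return (
        f"guide  5' {''.join(gl)} 3'\n"
        f"          {''.join(ml)}\n"
        f"target 3' {''.join(tl)} 5'"
    )


_GUIDE_CACHE: dict[str, str] = {}


def _guide_base(site: TargetSite, pos: int) -> str:
    seq = _GUIDE_CACHE.get(site.guide_id)
    if seq is None:
        return "N"
    return seq[pos - 1]


def register_guide(guide: GuideRNA) -> None:
    """Make a guide's sequence available to :func:`format_alignment`."""
    _GUIDE_CACHE[guide.id] = guide.sequence
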
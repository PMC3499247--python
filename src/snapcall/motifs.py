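"""Promoter-element matrices and scans for snRNA-type promoters.

snRNA-type promoters (pol II snRNA genes and type 3 pol III genes) are built
from a small vocabulary of elements: the PSE (SNAPc binding site) near
-55/-66, a TATA box at about -30 in the pol III case, and an enhancer region
further upstream typically carrying an octamer (POU2F1), a Z-motif (ZNF143)
and sometimes a GA-motif (GABP).  Pol II genes are additionally followed by a
3' box RNA-processing signal, a gapped consensus a few bp downstream of the
RNA-coding sequence.

This module builds position weight matrices from user-supplied site
alignments, scans sequences with PWMs, degenerate (IUPAC) consensuses and the
gapped 3'-box consensus, and assembles per-locus promoter architecture maps.
De novo motif discovery is out of scope: matrices come from alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .utils import IUPAC, revcomp

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

# --------------------------------------------------------------------------
# Canonical element sequences.  The concrete strings are used by the
# synthetic-genome builder when planting promoters; the IUPAC consensuses are
# the default scanning patterns and admit the concrete strings exactly.
# --------------------------------------------------------------------------
CANONICAL_ELEMENTS: dict[str, str] = {
    "PSE_POL2": "TTACCGTAACTTGAAAGT",
    "PSE_POL3": "TTACCATAACTTGAAAGG",
    "TATA": "TTATAA",
    "OCT": "ATGCAAAT",
    "Z": "TTCCCAGAATGCATTG",
    "GA": "ACCGGAAGTG",
}

DEFAULT_CONSENSUS: dict[str, str] = {
    "PSE": "TTACCRTAACTTGAAAGN",
    "TATA": "TTATAA",
    "OCT": "ATGCAAAT",
    "Z": "TTCCCANAATGCANTG",
    "GA": "NCCGGAAGTN",
}

#: Element name -> ChIP'd activator whose peak can mark the element occupied.
ELEMENT_FACTOR: dict[str, str] = {"OCT": "POU2F1", "Z": "ZNF143", "GA": "GABPA"}


@dataclass
class MotifHit:
    """One motif match inside a scanned sequence.

    ``offset`` is 0-based within the scanned (already oriented) sequence;
    ``strand`` is '+' when the motif matches the scanned strand, '-' for its
    reverse complement.  Exactly one of ``score`` (PWM log-likelihood ratio,
    bits) or ``mismatches`` (consensus Hamming distance) is meaningful.
    """

    element: str
    offset: int
    length: int
    strand: str
    score: float = float("nan")
    mismatches: int = -1
    gap: int = 0


@dataclass
class PWM:
    """Position weight matrix over ACGT with pseudocount-smoothed columns."""

    matrix: np.ndarray  # (L, 4) probabilities, rows sum to 1
    source: str = ""

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def info_content(self) -> np.ndarray:
        """Per-position information content, ``2 - H(column)`` bits."""
        p = self.matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
        return 2.0 - h

    def max_score(self) -> float:
        return float(np.log2(self.matrix.max(axis=1) / 0.25).sum())

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))


def build_pwm(aligned_sites: Sequence[str], pseudocount: float = 0.5,
              source: str = "") -> PWM:
    """Build a PWM from an ungapped alignment of equal-length sites."""
    if len(aligned_sites) < 2:
        raise ValueError("need at least 2 aligned sites")
    L = len(aligned_sites[0])
    if L < 4:
        raise ValueError("alignment shorter than 4 columns")
    if any(len(s) != L for s in aligned_sites):
        raise ValueError("ragged alignment: sites differ in length")
    counts = np.full((L, 4), pseudocount, dtype=float)
    for site in aligned_sites:
        for j, base in enumerate(site.upper()):
            if base in _BASE_INDEX:
                counts[j, _BASE_INDEX[base]] += 1
            else:  # degenerate base spreads its count
                admitted = IUPAC.get(base, _BASES)
                for b in admitted:
                    counts[j, _BASE_INDEX[b]] += 1.0 / len(admitted)
    return PWM(counts / counts.sum(axis=1, keepdims=True), source=source)


def write_pwm_tsv(pwm: PWM, path: str) -> None:
    """Write a PWM as a minimal JASPAR-like position-frequency TSV."""
    with open(path, "w") as fh:
        fh.write("pos\tA\tC\tG\tT\tIC_bits\n")
        ic = pwm.info_content()
        for i, row in enumerate(pwm.matrix, start=1):
            fh.write(f"{i}\t" + "\t".join(f"{v:.4f}" for v in row) +
                     f"\t{ic[i - 1]:.3f}\n")


def _pwm_site_score(pwm: PWM, site: str) -> float:
    """Log2 likelihood ratio of a site vs the uniform background."""
    score = 0.0
    for j, base in enumerate(site):
        i = _BASE_INDEX.get(base)
        if i is None:
            return -math.inf  # N runs: no hit through them
        score += math.log2(pwm.matrix[j, i] / 0.25)
    return score


def scan_pwm(sequence: str, pwm: PWM, score_floor: float | None = None,
             element: str = "PWM", both_strands: bool = True) -> list[MotifHit]:
    """Scan a sequence with a PWM; keep hits scoring >= ``score_floor``.

    The default floor is 60% of the maximum attainable score.  Windows
    containing non-ACGT characters are skipped.  Hits are sorted by
    decreasing score, ties by offset then strand.
    """
    seq = sequence.upper()
    L = len(pwm)
    if score_floor is None:
        score_floor = 0.6 * pwm.max_score()
    hits: list[MotifHit] = []
    strands = ("+", "-") if both_strands else ("+",)
    for off in range(len(seq) - L + 1):
        window = seq[off:off + L]
        for strand in strands:
            site = window if strand == "+" else revcomp(window)
            s = _pwm_site_score(pwm, site)
            if s >= score_floor:
                hits.append(MotifHit(element, off, L, strand, score=s))
    hits.sort(key=lambda h: (-h.score, h.offset, h.strand))
    return hits


def _consensus_mismatches(consensus: str, site: str) -> int:
    mm = 0
    for code, base in zip(consensus, site):
        if base not in IUPAC.get(code, ""):
            mm += 1
    return mm


def scan_consensus(sequence: str, consensus: str, max_mismatch: int = 0,
                   element: str = "consensus",
                   both_strands: bool = True) -> list[MotifHit]:
    """All placements of an IUPAC consensus with <= ``max_mismatch`` mismatches.

    Both strands are scanned; hits are sorted by mismatch count then position.
    Non-ACGT sequence characters count as mismatches unless the consensus
    position is N.
    """
    seq = sequence.upper()
    cons = consensus.upper()
    L = len(cons)
    hits: list[MotifHit] = []
    strands = ("+", "-") if both_strands else ("+",)
    for off in range(len(seq) - L + 1):
        window = seq[off:off + L]
        for strand in strands:
            site = window if strand == "+" else revcomp(window)
            mm = _consensus_mismatches(cons, site)
            if mm <= max_mismatch:
                hits.append(MotifHit(element, off, L, strand, mismatches=mm))
    hits.sort(key=lambda h: (h.mismatches, h.offset, h.strand))
    return hits


@dataclass(frozen=True)
class GappedConsensus:
    """Two literal IUPAC segments separated by a variable-length gap."""

    prefix: str
    gap_min: int
    gap_max: int
    suffix: str

    def __post_init__(self):
        if self.gap_min > self.gap_max or self.gap_min < 0:
            raise ValueError("need 0 <= gap_min <= gap_max")

    def span(self, gap: int) -> int:
        return len(self.prefix) + gap + len(self.suffix)


#: The 3' box RNA-processing signal: GTTT N(1-4) AANA[A/G]NAGA.
BOX3_CONSENSUS = GappedConsensus("GTTT", 1, 4, "AANARNAGA")


def scan_gapped(sequence: str, consensus: GappedConsensus,
                max_mismatch: int = 0, element: str = "BOX3") -> list[MotifHit]:
    """Enumerate all gap lengths and placements of a gapped consensus.

    Forward strand only (the 3' box acts on the nascent transcript, so it is
    meaningful on the coding strand).  Hits sorted by mismatches, then offset,
    then gap length.
    """
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for gap in range(consensus.gap_min, consensus.gap_max + 1):
        L = consensus.span(gap)
        pat = consensus.prefix + "N" * gap + consensus.suffix
        for off in range(len(seq) - L + 1):
            mm = _consensus_mismatches(pat, seq[off:off + L])
            if mm <= max_mismatch:
                hits.append(MotifHit(element, off, L, "+", mismatches=mm, gap=gap))
    hits.sort(key=lambda h: (h.mismatches, h.offset, h.gap))
    return hits


def scan_3prime_box(sequence_after_rna_end: str,
                    consensus: GappedConsensus = BOX3_CONSENSUS,
                    window: int = 100, max_mismatch: int = 0) -> list[MotifHit]:
    """Search the +1..+window 3' flank for the gapped 3'-box consensus.

    ``sequence_after_rna_end`` starts at the first base past the RNA-coding
    sequence (position +1).  Hit offsets are 0-based into that sequence, so a
    hit at offset ``o`` starts at position ``+o+1``.  If the available
    sequence is shorter than the window the scan is truncated with a warning.
    """
    if len(sequence_after_rna_end) < window:
        import warnings

        warnings.warn("3' flank shorter than scan window; truncated scan")
    seq = sequence_after_rna_end[:window]
    return scan_gapped(seq, consensus, max_mismatch=max_mismatch)


# --------------------------------------------------------------------------
# Promoter architecture maps
# --------------------------------------------------------------------------

@dataclass
class ArchitectureEntry:
    element: str
    start_rel: int  # no-zero TSS-relative coordinate of the first base
    end_rel: int    # coordinate of the last base
    strand: str
    occupied: bool | None  # None for basal elements (PSE/TATA)
    score: float = float("nan")
    mismatches: int = -1


@dataclass
class PromoterArchitecture:
    locus_id: str
    entries: list[ArchitectureEntry] = field(default_factory=list)

    def elements(self, occupied_only: bool = False) -> list[str]:
        return [e.element for e in self.entries
                if not occupied_only or e.occupied]


def _rel_coord(window_start: int, offset: int) -> int:
    """Map a 0-based offset in a window starting at promoter coordinate
    ``window_start`` (< 0) to the no-zero TSS-relative convention
    (-1 immediately upstream of +1; no position 0)."""
    pos = window_start + offset
    return pos if pos < 0 else pos + 1


def promoter_sequence(genome: Mapping[str, str], chrom: str, tss: int,
                      strand: str, upstream: int = 400) -> str:
    """Oriented promoter sequence covering positions -upstream..-1.

    ``tss`` is the 0-based genomic position of the +1 base.  Index ``i`` of
    the returned string is promoter position ``-upstream + i``.
    """
    seq = genome[chrom]
    if strand == "+":
        lo = max(0, tss - upstream)
        return seq[lo:tss]
    hi = min(len(seq), tss + 1 + upstream)
    return revcomp(seq[tss + 1:hi])


def three_prime_flank(genome: Mapping[str, str], chrom: str, end3: int,
                      strand: str, length: int = 100) -> str:
    """Oriented sequence of the +1..+length flank past the RNA 3' end.

    ``end3`` is the half-open genomic boundary of the RNA-coding interval on
    the forward strand (for '-' genes this is the interval start).
    """
    seq = genome[chrom]
    if strand == "+":
        return seq[end3:end3 + length]
    return revcomp(seq[max(0, end3 - length):end3])


#: Default mismatch allowance per consensus element.  Short low-information
#: elements (TATA) are scanned exactly; enhancer-region elements follow the
#: two-mismatch octamer convention.
ELEMENT_MISMATCH: dict[str, int] = {"TATA": 0, "PSE": 1}


def annotate_promoter(locus_id: str, genome: Mapping[str, str], chrom: str,
                      tss: int, strand: str,
                      element_set: Mapping[str, object] | None = None,
                      activator_summits: Mapping[str, Sequence[int]] | None = None,
                      upstream: int = 400, consensus_mismatch: int = 2,
                      summit_resolution: int = 40, summit_margin: int = 100,
                      box3_end: int | None = None) -> PromoterArchitecture:
    """Best per-element hits in the -upstream..-1 promoter window.

    ``element_set`` maps element name -> PWM | IUPAC consensus string.
    ``activator_summits`` maps factor name -> ``(chrom, summit)`` pairs of its
    called peaks; an activator element's hit is marked occupied iff a peak of
    the matching factor exists and the hit is the element hit closest to that
    peak's summit.  Hits failing that test are reported crossed-out
    (occupied=False).  Basal elements carry ``occupied=None``.  When
    ``box3_end`` (genomic 3'-end boundary) is given, the 3' box is also
    searched in the +1..+100 flank.

    Called peak summits have finite positional resolution, so summit
    distances are compared in units of ``summit_resolution`` bp; among hits
    in the same distance band the better match (fewer mismatches / higher
    score) wins.
    """
    if chrom not in genome:
        raise ValueError(f"missing sequence for chromosome {chrom!r}")
    element_set = dict(element_set or DEFAULT_CONSENSUS)
    summits = activator_summits or {}
    window = promoter_sequence(genome, chrom, tss, strand, upstream)
    win_start = -len(window)  # promoter coordinate of window[0]
    arch = PromoterArchitecture(locus_id)

    def genomic_pos(offset: int) -> int:
        # genomic position of window[offset]
        return tss + win_start + offset if strand == "+" else tss - win_start - offset

    for element, pattern in element_set.items():
        if isinstance(pattern, PWM):
            hits = scan_pwm(window, pattern, element=element)
        else:
            mm = ELEMENT_MISMATCH.get(element, consensus_mismatch)
            hits = scan_consensus(window, str(pattern),
                                  max_mismatch=mm, element=element)
        if not hits:
            continue
        factor = ELEMENT_FACTOR.get(element)
        if factor is None:
            best = hits[0]
            arch.entries.append(_entry(best, win_start, occupied=None))
            continue
        # only peaks over this promoter can mark its motifs occupied
        g_lo = min(genomic_pos(0), genomic_pos(len(window) - 1)) - summit_margin
        g_hi = max(genomic_pos(0), genomic_pos(len(window) - 1)) + summit_margin
        peak_summits = [pos for c, pos in summits.get(factor, [])
                        if c == chrom and g_lo <= pos <= g_hi]
        if not peak_summits:
            for h in hits:
                arch.entries.append(_entry(h, win_start, occupied=False))
            continue
        # the hit closest to a factor summit is occupied; others crossed out
        def dist(h: MotifHit) -> int:
            center = genomic_pos(h.offset) + (h.length // 2 if strand == "+"
                                              else -(h.length // 2))
            return min(abs(center - s) for s in peak_summits)

        closest = min(hits, key=lambda h: (dist(h) // max(summit_resolution, 1),
                                           h.mismatches if h.mismatches >= 0
                                           else -h.score, dist(h)))
        for h in hits:
            arch.entries.append(_entry(h, win_start, occupied=h is closest))
    if box3_end is not None:
        flank = three_prime_flank(genome, chrom, box3_end, strand)
        box_hits = scan_3prime_box(flank)
        if box_hits:
            b = box_hits[0]
            arch.entries.append(ArchitectureEntry(
                "BOX3", b.offset + 1, b.offset + b.length, b.strand,
                occupied=None, mismatches=b.mismatches))
    arch.entries.sort(key=lambda e: e.start_rel)
    return arch


def _entry(hit: MotifHit, win_start: int, occupied: bool | None) -> ArchitectureEntry:
    return ArchitectureEntry(hit.element,
                             _rel_coord(win_start, hit.offset),
                             _rel_coord(win_start, hit.offset + hit.length - 1),
                             hit.strand, occupied,
                             score=hit.score, mismatches=hit.mismatches)
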
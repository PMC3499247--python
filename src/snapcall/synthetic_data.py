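"""Toy genomes with planted repetitive snRNA-like gene families, and a
multi-factor ChIP-seq tag simulator with known truth.

The human pol II snRNA genes and type 3 pol III genes occur in families of
near-identical copies, so a large fraction of ChIP-seq tags over them map to
multiple genomic locations.  The generator reproduces that statistical
structure: each family has one gene-body sequence shared verbatim by all its
copies (forcing multi-mapping), embedded in unique random flanks that carry
identical planted promoter elements (PSE, TATA, octamer, Z-motif, GA-motif)
and, for pol II genes, a 3' box downstream of the RNA-coding sequence.

Factor tags are drawn from a mixture of uniform Poisson background and
factor-specific shapes: point sources for promoter-bound factors, uniform
gene-body occupancy for polymerases, optionally extended by a linearly
decaying downstream termination zone (pol II runs on for over a kilobase
past the RNA 3' end; pol III stops almost immediately).  Each emitted tag
records its true genome-wide perfect-match multiplicity, obtained by exact
k-mer lookup against the emitted genome, so downstream modules can be tested
without running an aligner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import motifs
from .tag_model import make_tags
from .utils import revcomp

GENE_COLUMNS = ["gene_id", "family", "chrom", "start", "end", "strand", "pol_class"]

POL2, POL3, DUAL, NONE = "POL2", "POL3", "DUAL", "NONE"


class PlacementError(ValueError):
    """Raised when a gene family cannot be placed inside the genome."""


@dataclass(frozen=True)
class GenomeSpec:
    """Dimensions and background statistics of the toy genome."""

    chrom_lengths: Mapping[str, int]
    seed: int = 0
    background_rate: float = 0.005  # expected background tags / bp / factor

    def __post_init__(self):
        if any(L <= 0 for L in self.chrom_lengths.values()):
            raise ValueError("all chromosome lengths must be > 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass(frozen=True)
class PromoterElement:
    """A promoter element planted relative to the TSS.

    ``offset`` is the TSS-relative coordinate of the element's first base in
    the no-zero convention (-55 = 55 bp upstream of +1).
    """

    name: str
    offset: int
    sequence: str


@dataclass(frozen=True)
class GeneFamilySpec:
    """A family of sequence-identical gene copies.

    Pol III (and DUAL) families carry PSE + TATA promoters; pol II families a
    PSE only.  ``downstream_elements`` are planted relative to the RNA 3' end
    (+1 = first base past the coding sequence), e.g. the 3' box.
    """

    family_name: str
    n_copies: int
    gene_length: int
    polymerase_class: str = POL2
    promoter_elements: tuple[PromoterElement, ...] = ()
    downstream_elements: tuple[PromoterElement, ...] = ()
    downstream_decay_bp: int = 0
    strands: tuple[str, ...] | None = None  # per-copy; random when None

    def __post_init__(self):
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        if self.polymerase_class not in (POL2, POL3, DUAL, NONE):
            raise ValueError(f"unknown polymerase_class {self.polymerase_class!r}")


@dataclass(frozen=True)
class FactorProfileSpec:
    """Positional signal of one factor over one gene family.

    shape: ``point`` (promoter factor at a fixed TSS offset), ``body``
    (uniform over the RNA-coding sequence) or ``body_decay`` (body plus a
    linearly decaying downstream termination zone of the family's
    ``downstream_decay_bp``).  ``n_tags`` is the total signal tag count over
    all copies of the family; when None it is derived from
    ``fold_enrichment`` x background rate x footprint.  ``fold_enrichment=0``
    disables the profile entirely (indistinguishable from background).
    """

    factor: str
    family: str
    shape: str = "point"
    center_offset: int = 0
    spread: float = 20.0
    fold_enrichment: float = 20.0
    n_tags: int | None = None
    downstream_fraction: float = 0.35  # body_decay: share of tags past 3' end

    def __post_init__(self):
        if self.shape not in ("point", "body", "body_decay"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be >= 0")
        if not self.factor:
            raise ValueError("factor name must be non-empty")


@dataclass
class SimulationTruth:
    """Planted ground truth: gene table plus per-locus factor sets."""

    genes: pd.DataFrame
    factor_table: pd.DataFrame  # gene_id x factor booleans
    rho_spearman: float | None = None


# --------------------------------------------------------------------------
# Genome construction
# --------------------------------------------------------------------------

_UP_MARGIN = 600      # promoter real estate reserved upstream of each TSS
_DOWN_EXTRA = 2400    # quiet zone past the decay region (metagene tails)
_GENE_GAP = 500


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASE_ARR[codes].tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    codes = lut[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def tss_position(start: int, end: int, strand: str) -> int:
    """0-based genomic position of the +1 base."""
    return start if strand == "+" else end - 1


def end3_boundary(start: int, end: int, strand: str) -> int:
    """Half-open genomic boundary just past the RNA 3' end.

    For '+' genes this is ``end`` (first downstream base = end); for '-'
    genes it is ``start`` (first downstream base = start - 1).
    """
    return end if strand == "+" else start


def build_toy_genome(genome_spec: GenomeSpec,
                     family_specs: Sequence[GeneFamilySpec],
                     ) -> tuple[dict[str, str], pd.DataFrame]:
    """Emit a genome (chrom -> sequence) and its truth gene annotation.

    Copies of a family share the gene-body sequence and all planted elements;
    the remaining flank sequence is unique per copy.  Copies are laid out
    round-robin over chromosomes with generous margins; overflowing the
    genome raises :class:`PlacementError` naming the family.
    """
    rng = np.random.default_rng(genome_spec.seed)
    chroms = {name: _random_seq(rng, L)
              for name, L in genome_spec.chrom_lengths.items()}
    cursors = {name: 1000 for name in chroms}
    order = list(chroms)
    rows = []
    turn = 0
    for fam in family_specs:
        body = _random_seq(rng, fam.gene_length)
        span = (_UP_MARGIN + fam.gene_length + fam.downstream_decay_bp
                + _DOWN_EXTRA + _GENE_GAP)
        for copy_i in range(fam.n_copies):
            placed = False
            for _ in range(len(order)):
                chrom = order[turn % len(order)]
                turn += 1
                if cursors[chrom] + span < genome_spec.chrom_lengths[chrom] - 1000:
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"cannot place copy {copy_i + 1} of family "
                    f"{fam.family_name!r}: genome exhausted")
            if fam.strands is not None:
                strand = fam.strands[copy_i % len(fam.strands)]
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            anchor = cursors[chrom] + _UP_MARGIN
            cursors[chrom] += span
            # Build the locus in gene orientation then drop it in.
            seq = chroms[chrom]
            if strand == "+":
                start, end = anchor, anchor + fam.gene_length
                seq[start:end] = body
                tss = start
                for el in fam.promoter_elements:
                    g0 = tss + el.offset  # offset < 0, no-zero convention
                    seq[g0:g0 + len(el.sequence)] = _encode(el.sequence)
                for el in fam.downstream_elements:
                    g0 = end + el.offset - 1  # +1 = first downstream base
                    seq[g0:g0 + len(el.sequence)] = _encode(el.sequence)
            else:
                start, end = anchor, anchor + fam.gene_length
                seq[start:end] = _encode(revcomp(_to_str(body)))
                tss = end - 1
                for el in fam.promoter_elements:
                    enc = _encode(revcomp(el.sequence))
                    g_last = tss - el.offset  # element runs upstream = rightward
                    seq[g_last - len(enc) + 1:g_last + 1] = enc
                for el in fam.downstream_elements:
                    enc = _encode(revcomp(el.sequence))
                    g_last = start - el.offset  # +1 = start-1, extending left
                    seq[g_last - len(enc) + 1:g_last + 1] = enc
            rows.append((f"{fam.family_name}_{copy_i + 1}", fam.family_name,
                         chrom, start, end, strand, fam.polymerase_class))
    genome = {name: _to_str(codes) for name, codes in chroms.items()}
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    genes = genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return genome, genes


# --------------------------------------------------------------------------
# Multiplicity bookkeeping
# --------------------------------------------------------------------------

def kmer_counts(genome: Mapping[str, str], k: int) -> dict[str, int]:
    """Exact forward-strand occurrence counts of every k-mer in the genome."""
    counts: dict[str, int] = {}
    for seq in genome.values():
        s = seq.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i:i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def sequence_multiplicity(seq: str, counts: Mapping[str, int]) -> int:
    """Genome-wide perfect-match count of a tag sequence on either strand."""
    rc = revcomp(seq)
    n = counts.get(seq, 0)
    if rc != seq:
        n += counts.get(rc, 0)
    return max(n, 1)


# --------------------------------------------------------------------------
# Tag simulation
# --------------------------------------------------------------------------

def _sample_points(rng: np.random.Generator, profile: FactorProfileSpec,
                   gene: pd.Series, fam: GeneFamilySpec, n: int) -> np.ndarray:
    """Genomic coordinates of binding/occupancy points for one gene copy."""
    start, end, strand = int(gene.start), int(gene.end), gene.strand
    tss = tss_position(start, end, strand)
    sign = 1 if strand == "+" else -1
    if profile.shape == "point":
        off = profile.center_offset
        # no-zero promoter convention: -1 abuts +1
        rel = off + 1 if off < 0 else off
        return np.full(n, tss + sign * (rel - 1), dtype=np.int64)
    body = rng.integers(start, end, size=n)
    if profile.shape == "body" or fam.downstream_decay_bp <= 0:
        return body
    # body_decay: a fixed fraction of tags falls downstream of the 3' end
    # with linearly decaying density over downstream_decay_bp.
    n_down = rng.binomial(n, profile.downstream_fraction)
    u = rng.random(n_down)
    depth = (fam.downstream_decay_bp * (1.0 - np.sqrt(u))).astype(np.int64)
    b3 = end3_boundary(start, end, strand)
    down = b3 + depth if strand == "+" else b3 - 1 - depth
    pts = body.copy()
    if n_down:
        pts[:n_down] = down
    return pts


def simulate_tags(genome: Mapping[str, str], genes: pd.DataFrame,
                  factor_profiles: Sequence[FactorProfileSpec],
                  genome_spec: GenomeSpec, seed: int | None = None,
                  tag_length: int = 36, fragment_length: int = 150,
                  duplication_rate: float = 0.0,
                  families: Mapping[str, GeneFamilySpec] | None = None,
                  ) -> pd.DataFrame:
    """Simulate per-factor aligned tags with true multiplicities.

    Per factor, a uniform Poisson background (``background_rate`` tags/bp) is
    merged with the factor's planted profiles.  Fragment ends are emulated:
    each tag is sense or antisense with probability 1/2; sense tags start
    about half a fragment upstream of their source point, antisense tags end
    about half a fragment downstream.  ``n_matches`` of every emitted tag is
    its exact perfect-match count in the emitted genome (either strand).
    """
    rng = np.random.default_rng(genome_spec.seed if seed is None else seed)
    known_families = set(genes["family"])
    for p in factor_profiles:
        if p.family not in known_families:
            raise ValueError(f"profile references unknown family {p.family!r}")
    counts = kmer_counts(genome, tag_length)
    chrom_names = list(genome)
    chrom_lengths = {c: len(genome[c]) for c in chrom_names}
    factors: list[str] = []
    for p in factor_profiles:
        if p.factor not in factors:
            factors.append(p.factor)
    records: list[tuple] = []

    def emit(chrom: str, point: int, factor: str, idx: int) -> None:
        if rng.random() < 0.5:
            strand = "+"
            fp = point - int(round(rng.normal(fragment_length / 2,
                                              max(1e-9, float(spread)))))
            start = fp
        else:
            strand = "-"
            fp = point + int(round(rng.normal(fragment_length / 2,
                                              max(1e-9, float(spread)))))
            start = fp - tag_length + 1
        end = start + tag_length
        if start < 0 or end > chrom_lengths[chrom]:
            start = min(max(start, 0), chrom_lengths[chrom] - tag_length)
            end = start + tag_length
        seq = genome[chrom][start:end]
        if strand == "-":
            seq = revcomp(seq)
        times = 1 + (rng.poisson(duplication_rate) if duplication_rate > 0 else 0)
        records.append((chrom, start, end, f"{factor}_{idx}", times, strand,
                        sequence_multiplicity(seq, counts), factor, False))

    fam_by_name = dict(families) if families else {}
    for factor in factors:
        idx = 0
        # background
        spread = 20.0
        for chrom in chrom_names:
            n_bg = rng.poisson(genome_spec.background_rate * chrom_lengths[chrom])
            pos = rng.integers(0, chrom_lengths[chrom] - tag_length, size=n_bg)
            for point in pos:
                emit(chrom, int(point) + fragment_length // 2, factor, idx)
                idx += 1
        # planted profiles of this factor
        for profile in factor_profiles:
            if profile.factor != factor or profile.fold_enrichment == 0:
                continue
            copies = genes[genes["family"] == profile.family]
            fam = fam_by_name.get(profile.family)
            if fam is None:
                fam = _family_stub(profile.family, copies)
                fam_by_name[profile.family] = fam
            n_total = profile.n_tags
            if n_total is None:
                footprint = (2 * profile.spread if profile.shape == "point"
                             else fam.gene_length + fam.downstream_decay_bp / 2)
                n_total = int(round(profile.fold_enrichment
                                    * genome_spec.background_rate
                                    * footprint * len(copies)))
            split = rng.multinomial(n_total, [1.0 / len(copies)] * len(copies))
            spread = profile.spread
            for (_, gene), n_copy in zip(copies.iterrows(), split):
                for point in _sample_points(rng, profile, gene, fam, int(n_copy)):
                    emit(gene.chrom, int(point), factor, idx)
                    idx += 1
    tags = make_tags(records) if records else make_tags([])
    return tags.sort_values(["source_factor", "chrom", "start"],
                            kind="stable").reset_index(drop=True)


def _family_stub(name: str, copies: pd.DataFrame) -> GeneFamilySpec:
    """Minimal family view reconstructed from the gene table."""
    length = int(copies.iloc[0]["end"] - copies.iloc[0]["start"])
    cls = copies.iloc[0]["pol_class"]
    decay = 1200 if cls in (POL2, DUAL) else (50 if cls == POL3 else 0)
    return GeneFamilySpec(name, len(copies), length, cls,
                          downstream_decay_bp=decay)


def simulate(genome_spec: GenomeSpec, family_specs: Sequence[GeneFamilySpec],
             factor_profiles: Sequence[FactorProfileSpec],
             seed: int | None = None, **kwargs):
    """Convenience wrapper: build the genome and simulate tags in one call."""
    genome, genes = build_toy_genome(genome_spec, family_specs)
    fams = {f.family_name: f for f in family_specs}
    tags = simulate_tags(genome, genes, factor_profiles, genome_spec,
                         seed=seed, families=fams, **kwargs)
    truth = SimulationTruth(genes, truth_factor_table(genes, factor_profiles))
    return genome, genes, tags, truth


def truth_factor_table(genes: pd.DataFrame,
                       factor_profiles: Sequence[FactorProfileSpec]) -> pd.DataFrame:
    """gene_id x factor boolean table of planted (enriched) factors."""
    factors = []
    for p in factor_profiles:
        if p.factor not in factors:
            factors.append(p.factor)
    table = pd.DataFrame(False, index=genes["gene_id"], columns=factors)
    by_family = genes.groupby("family")["gene_id"]
    for p in factor_profiles:
        if p.fold_enrichment == 0:
            continue
        if (p.n_tags or 0) == 0 and p.n_tags is not None:
            continue
        for gid in by_family.get_group(p.family):
            table.loc[gid, p.factor] = True
    return table


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(path, as_raw=True)
    try:
        return {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()


def write_genes_gff3(genes: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = (f"ID={g.gene_id};family={g.family};"
                     f"pol_class={g.pol_class}")
            fh.write(f"{g.chrom}\tsnapcall\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")


def read_genes_gff3(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append((attrs.get("ID", ""), attrs.get("family", ""), f[0],
                         int(f[3]) - 1, int(f[4]), f[6],
                         attrs.get("pol_class", NONE)))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


# --------------------------------------------------------------------------
# The default synthetic benchmark
# --------------------------------------------------------------------------

SNAPC_SUBUNITS = ("SNAPC1", "SNAPC2", "SNAPC4", "SNAPC5")

#: Per-locus activator combinations planted in the default benchmark
#: (POU2F1, ZNF143, GABPA).  15/16 loci carry POU2F1 (93.8%), 13/16 ZNF143
#: (81.3%), 7/16 GABPA (43.8%).
_BENCH_COMBOS: dict[str, tuple[bool, bool, bool]] = {
    "P1": (True, True, True), "P2": (True, True, True),
    "P3": (True, True, True), "P4": (True, True, True),
    "P8": (True, True, True),           # 3 copies
    "P5": (True, True, False), "P7": (True, True, False),
    "Q1": (True, True, False), "Q2": (True, True, False),
    "Q4": (True, True, False),          # 2 copies
    "D1": (True, False, False), "Q3": (True, False, False),
    "P6": (False, False, False),
}


def _pol2_elements(combo) -> tuple[PromoterElement, ...]:
    p, z, ga = combo
    els = []
    if ga:
        els.append(PromoterElement("GA", -300, motifs.CANONICAL_ELEMENTS["GA"]))
    if p:
        els.append(PromoterElement("OCT", -220, motifs.CANONICAL_ELEMENTS["OCT"]))
    if z:
        els.append(PromoterElement("Z", -180, motifs.CANONICAL_ELEMENTS["Z"]))
    els.append(PromoterElement("PSE", -55, motifs.CANONICAL_ELEMENTS["PSE_POL2"]))
    return tuple(els)


def _pol3_elements(combo) -> tuple[PromoterElement, ...]:
    p, z, ga = combo
    els = []
    if ga:
        els.append(PromoterElement("GA", -300, motifs.CANONICAL_ELEMENTS["GA"]))
    if p:
        els.append(PromoterElement("OCT", -220, motifs.CANONICAL_ELEMENTS["OCT"]))
    if z:
        els.append(PromoterElement("Z", -180, motifs.CANONICAL_ELEMENTS["Z"]))
    els.append(PromoterElement("PSE", -66, motifs.CANONICAL_ELEMENTS["PSE_POL3"]))
    els.append(PromoterElement("TATA", -30, motifs.CANONICAL_ELEMENTS["TATA"]))
    return tuple(els)


_BOX3 = (PromoterElement("BOX3", 9, "GTTTCTAATAAGAGA"),)


def default_benchmark(seed: int = 0):
    """Specs of the default benchmark: 16 loci over two chromosomes.

    10 pol II loci (families P1-P7 single-copy, P8 with three identical
    copies), 5 pol III loci (Q1-Q3 single-copy, Q4 with two copies) and one
    single-copy dual-polymerase locus D1 modelled on RPPH1 (type 3 promoter,
    occupied by both polymerase machineries).  Pol II termination zones decay
    over 1200 bp; pol III over 50 bp.
    """
    gspec = GenomeSpec({"chr1": 200_000, "chr2": 100_000}, seed=seed,
                       background_rate=0.005)
    fams: list[GeneFamilySpec] = []
    for name in ("P1", "P2", "P3", "P4", "P5", "P6", "P7"):
        fams.append(GeneFamilySpec(name, 1, 164, POL2,
                                   _pol2_elements(_BENCH_COMBOS[name]),
                                   _BOX3, downstream_decay_bp=1200))
    fams.append(GeneFamilySpec("P8", 3, 164, POL2,
                               _pol2_elements(_BENCH_COMBOS["P8"]),
                               _BOX3, downstream_decay_bp=1200))
    for name in ("Q1", "Q2", "Q3"):
        fams.append(GeneFamilySpec(name, 1, 107, POL3,
                                   _pol3_elements(_BENCH_COMBOS[name]),
                                   downstream_decay_bp=50))
    fams.append(GeneFamilySpec("Q4", 2, 107, POL3,
                               _pol3_elements(_BENCH_COMBOS["Q4"]),
                               downstream_decay_bp=50))
    fams.append(GeneFamilySpec("D1", 1, 340, DUAL,
                               _pol3_elements(_BENCH_COMBOS["D1"]),
                               downstream_decay_bp=1200))

    profiles: list[FactorProfileSpec] = []
    for fam in fams:
        n = fam.n_copies
        combo = _BENCH_COMBOS[fam.family_name]
        pol2_like = fam.polymerase_class in (POL2, DUAL)
        pol3_like = fam.polymerase_class in (POL3, DUAL)
        pse_center = -46 if pol2_like and fam.polymerase_class != DUAL else -57
        if pol2_like:
            profiles.append(FactorProfileSpec("POLR2B", fam.family_name,
                                              "body_decay", fold_enrichment=10,
                                              n_tags=300 * n,
                                              downstream_fraction=0.5))
            profiles.append(FactorProfileSpec("GTF2B", fam.family_name, "point",
                                              center_offset=-5, n_tags=120 * n))
        if pol3_like:
            decay_profile = FactorProfileSpec("POLR3D", fam.family_name,
                                              "body_decay", fold_enrichment=10,
                                              n_tags=300 * n,
                                              downstream_fraction=0.5 if
                                              fam.polymerase_class == DUAL else 0.15)
            profiles.append(decay_profile)
            profiles.append(FactorProfileSpec("BRF2", fam.family_name, "point",
                                              center_offset=-5, n_tags=120 * n))
        for subunit in ("SNAPC1", "SNAPC4", "SNAPC5"):
            profiles.append(FactorProfileSpec(subunit, fam.family_name, "point",
                                              center_offset=pse_center,
                                              n_tags=100 * n))
        profiles.append(FactorProfileSpec("SNAPC2", fam.family_name, "point",
                                          center_offset=-100, n_tags=100 * n))
        for present, factor, off in zip(combo, ("POU2F1", "ZNF143", "GABPA"),
                                        (-216, -172, -295)):
            if present:
                profiles.append(FactorProfileSpec(factor, fam.family_name,
                                                  "point", center_offset=off,
                                                  n_tags=100 * n))
    return gspec, fams, profiles


def simulate_benchmark(seed: int = 0, **kwargs):
    """Build the default benchmark and simulate its tags (deterministic)."""
    gspec, fams, profiles = default_benchmark(seed=seed)
    return simulate(gspec, fams, profiles, **kwargs)


def correlated_score_benchmark(n_loci: int = 60, rho_spearman: float = 0.85,
                               seed: int = 0):
    """Two factors with latent per-locus intensities of known rank correlation.

    Each of ``n_loci`` single-copy genes receives tag counts for factors
    FAC_A and FAC_B driven by a bivariate log-normal latent whose Gaussian
    correlation is chosen so the latent Spearman correlation equals
    ``rho_spearman`` (Pearson rho = 2 sin(pi rho_s / 6)).
    """
    rng = np.random.default_rng(seed)
    gspec = GenomeSpec({"chr1": n_loci * 4000 + 20_000}, seed=seed,
                       background_rate=0.002)
    fams = [GeneFamilySpec(f"L{i + 1}", 1, 200, NONE) for i in range(n_loci)]
    rho_p = 2.0 * math.sin(math.pi * rho_spearman / 6.0)
    cov = np.array([[1.0, rho_p], [rho_p, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_loci)
    n_a = np.clip(np.round(80.0 * np.exp(0.7 * z[:, 0])), 8, 2000).astype(int)
    n_b = np.clip(np.round(80.0 * np.exp(0.7 * z[:, 1])), 8, 2000).astype(int)
    profiles = []
    for i, fam in enumerate(fams):
        profiles.append(FactorProfileSpec("FAC_A", fam.family_name, "point",
                                          center_offset=100, n_tags=int(n_a[i])))
        profiles.append(FactorProfileSpec("FAC_B", fam.family_name, "point",
                                          center_offset=100, n_tags=int(n_b[i])))
    genome, genes, tags, truth = simulate(gspec, fams, profiles,
                                          seed=seed + 1)
    truth.rho_spearman = rho_spearman
    return genome, genes, tags, truth
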
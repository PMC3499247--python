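"""Toy genome construction and tag simulation with known truth."""

import numpy as np
import pandas as pd
import pytest

from snapcall import synthetic_data as sd
from snapcall.utils import revcomp


def _brute_occurrences(genome, seq):
    """Independent occurrence count of a sequence on either genome strand."""
    n = 0
    for s in genome.values():
        for probe in {seq, revcomp(seq)}:
            i = s.find(probe)
            while i != -1:
                n += 1
                i = s.find(probe, i + 1)
    return n


def _one_family(n_copies, gene_length=200, cls=sd.POL2, decay=0, L=60_000):
    gspec = sd.GenomeSpec({"chr1": L}, seed=5, background_rate=0.0)
    fam = sd.GeneFamilySpec("FAM", n_copies, gene_length, cls,
                            downstream_decay_bp=decay)
    return gspec, [fam]


class TestBuildToyGenome:
    def test_single_copy_body_kmers_unique(self):
        gspec, fams = _one_family(1)
        genome, genes = sd.build_toy_genome(gspec, fams)
        assert len(genes) == 1
        g = genes.iloc[0]
        body = genome[g.chrom][g.start:g.end]
        counts = sd.kmer_counts(genome, 20)
        assert all(sd.sequence_multiplicity(body[i:i + 20], counts) == 1
                   for i in range(0, len(body) - 20 + 1))

    def test_five_copies_body_kmers_repeated(self):
        gspec, fams = _one_family(5)
        genome, genes = sd.build_toy_genome(gspec, fams)
        assert len(genes) == 5
        g = genes[genes.strand == "+"].iloc[0] if (genes.strand == "+").any() \
            else genes.iloc[0]
        body = genome[g.chrom][g.start:g.end]
        if g.strand == "-":
            body = revcomp(body)
        counts = sd.kmer_counts(genome, 20)
        for i in range(0, len(body) - 20 + 1, 7):
            assert sd.sequence_multiplicity(body[i:i + 20], counts) >= 5

    def test_dual_family_truth_has_both_machineries(self):
        gspec, fams, profiles = sd.default_benchmark(seed=0)
        genome, genes = sd.build_toy_genome(gspec, fams)
        truth = sd.truth_factor_table(genes, profiles)
        dual = truth.loc["D1_1"]
        assert dual[["POLR2B", "GTF2B", "POLR3D", "BRF2"]].all()
        pol2_only = truth.loc["P1_1"]
        assert pol2_only[["POLR2B", "GTF2B"]].all()
        assert not pol2_only[["POLR3D", "BRF2"]].any()

    def test_placement_overflow_names_family(self):
        gspec = sd.GenomeSpec({"chr1": 9_000}, seed=0)
        fams = [sd.GeneFamilySpec("BIG", 5, 500)]
        with pytest.raises(sd.PlacementError, match="BIG"):
            sd.build_toy_genome(gspec, fams)

    def test_identical_seed_identical_output(self):
        gspec, fams, profiles = sd.default_benchmark(seed=9)
        a = sd.simulate(gspec, fams, profiles)
        b = sd.simulate(gspec, fams, profiles)
        assert a[0] == b[0]
        assert a[1].equals(b[1])
        assert a[2].equals(b[2])

    def test_promoter_elements_planted_at_offsets(self):
        gspec = sd.GenomeSpec({"chr1": 60_000}, seed=3)
        el = sd.PromoterElement("TATA", -30, "TTATAA")
        fams = [sd.GeneFamilySpec("F", 2, 150, sd.POL3, (el,),
                                  strands=("+", "-"))]
        genome, genes = sd.build_toy_genome(gspec, fams)
        for _, g in genes.iterrows():
            tss = sd.tss_position(g.start, g.end, g.strand)
            if g.strand == "+":
                assert genome[g.chrom][tss - 30:tss - 24] == "TTATAA"
            else:
                assert revcomp(genome[g.chrom][tss + 25:tss + 31]) == "TTATAA"


class TestSimulateTags:
    def test_no_enrichment_is_poisson_background(self):
        gspec = sd.GenomeSpec({"chr1": 100_000}, seed=0, background_rate=0.01)
        fams = [sd.GeneFamilySpec("F", 1, 200)]
        genome, genes = sd.build_toy_genome(gspec, fams)
        prof = [sd.FactorProfileSpec("X", "F", "point", fold_enrichment=0.0,
                                     n_tags=500)]
        counts = []
        for seed in range(30):
            tags = sd.simulate_tags(genome, genes, prof, gspec, seed=seed)
            counts.append(len(tags))
        lam = 0.01 * 100_000
        mean = np.mean(counts)
        assert abs(mean - lam) < 4 * np.sqrt(lam / 30)

    def test_conservation_without_background(self):
        gspec, fams = _one_family(2, gene_length=400)
        genome, genes = sd.build_toy_genome(gspec, fams)
        prof = [sd.FactorProfileSpec("X", "FAM", "point", center_offset=200,
                                     n_tags=250)]
        tags = sd.simulate_tags(genome, genes, prof, gspec, seed=1)
        assert len(tags) == 250

    def test_multiplicity_matches_exhaustive_search(self):
        gspec, fams = _one_family(3, gene_length=300, L=40_000)
        gspec = sd.GenomeSpec({"chr1": 40_000}, seed=5, background_rate=0.002)
        genome, genes = sd.build_toy_genome(gspec, fams)
        prof = [sd.FactorProfileSpec("X", "FAM", "body", n_tags=60)]
        tags = sd.simulate_tags(genome, genes, prof, gspec, seed=2)
        for _, t in tags.iterrows():
            seq = genome[t.chrom][t.start:t.end]
            if t.strand == "-":
                seq = revcomp(seq)
            assert t.n_matches == _brute_occurrences(genome, seq)

    def test_point_factor_splits_tags_over_copies(self):
        # 3 identical copies, 300 tags: ~100 per copy, interior tags multi=3
        gspec, fams = _one_family(3, gene_length=600, L=60_000)
        genome, genes = sd.build_toy_genome(gspec, fams)
        prof = [sd.FactorProfileSpec("X", "FAM", "point", center_offset=300,
                                     spread=5.0, n_tags=300)]
        per_copy = np.zeros((100, 3))
        for seed in range(100):
            tags = sd.simulate_tags(genome, genes, prof, gspec, seed=seed)
            for j, (_, g) in enumerate(genes.iterrows()):
                sel = (tags.chrom == g.chrom) & (tags.start >= g.start - 500) \
                    & (tags.end <= g.end + 500)
                per_copy[seed, j] = sel.sum()
        assert np.allclose(per_copy.mean(axis=0), 100, atol=3)
        # interior tags carry the family's copy number as multiplicity
        tags = sd.simulate_tags(genome, genes, prof, gspec, seed=0)
        g = genes.iloc[0]
        interior = tags[(tags.start >= g.start + 5) & (tags.end <= g.end - 5)
                        & (tags.chrom == g.chrom)]
        assert len(interior) > 10
        assert (interior.n_matches == 3).all()

    def test_decay_signal_bounded_by_schedule(self):
        gspec, fams = _one_family(1, gene_length=300, decay=1200, L=60_000)
        genome, genes = sd.build_toy_genome(gspec, fams)
        prof = [sd.FactorProfileSpec("X", "FAM", "body_decay", n_tags=2000,
                                     downstream_fraction=0.5)]
        tags = sd.simulate_tags(genome, genes, prof, gspec, seed=4)
        g = genes.iloc[0]
        b3 = sd.end3_boundary(g.start, g.end, g.strand)
        mid = np.where(tags.strand == "+", tags.start + 75, tags.end - 1 - 75)
        down = (mid - b3) if g.strand == "+" else (b3 - 1 - mid)
        # density at +1200 has decayed to (near) zero: only the fragment-model
        # jitter can push reconstructed midpoints past the planted ramp
        assert (down > 1200 + 100).sum() == 0
        assert (down > 600).sum() < (down > 0).sum() * 0.5

    def test_unknown_family_raises(self):
        gspec, fams = _one_family(1)
        genome, genes = sd.build_toy_genome(gspec, fams)
        prof = [sd.FactorProfileSpec("X", "NOPE", "point", n_tags=10)]
        with pytest.raises(ValueError, match="NOPE"):
            sd.simulate_tags(genome, genes, prof, gspec, seed=0)

    def test_fasta_gff_roundtrip(self, tmp_path):
        gspec, fams = _one_family(2, L=30_000)
        genome, genes = sd.build_toy_genome(gspec, fams)
        fa, gff = tmp_path / "g.fa", tmp_path / "g.gff3"
        sd.write_fasta(genome, str(fa))
        sd.write_genes_gff3(genes, str(gff))
        genome2 = sd.read_fasta(str(fa))
        genes2 = sd.read_genes_gff3(str(gff))
        assert genome2 == genome
        pd.testing.assert_frame_equal(
            genes2, genes[genes2.columns], check_dtype=False)
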
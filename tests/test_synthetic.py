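"""Tests of the synthetic locus / read / repertoire generators."""
import numpy as np
import pytest
from Bio.Seq import Seq

from ignar.models import RepertoireConfig
from ignar.synthetic import (
    DEFAULT_FRAMEWORK,
    LocusConfig,
    build_locus,
    default_repertoire_config,
    generate_repertoire,
    mask_gap,
    simulate_genomic_reads,
    simulate_spliced_reads,
)


class TestBuildLocus:
    def test_packaged_architectures(self, ignar1, ignar2):
        """Ten exons with VNAR at exon 2 and C1-C5 at exons 4-8; nine exons
        with C1-C5 at exons 3-7 for the hinge-less locus."""
        loc1, loc2 = ignar1[0], ignar2[0]
        assert loc1.model.n_exons == 10
        assert loc2.model.n_exons == 9
        for loc, c_exons in ((loc1, range(3, 8)), (loc2, range(2, 7))):
            assert loc.model.domain_map[1] == "VNAR"
            assert [loc.model.domain_map[i] for i in c_exons] == [
                "C1", "C2", "C3", "C4", "C5"]

    def test_coding_exons_stay_in_frame(self, ignar1, ignar2):
        """Every exon contributes a whole number of codons, so any
        exon-skipping chain preserves the reading frame."""
        for loc, _ in (ignar1, ignar2):
            for a, b in loc.exon_aa_spans:
                assert b >= a

    def test_frame_closure_over_all_packaged_isoforms(self, ignar1, ignar2):
        """Spliced coding sequences are stop-free multiples of three."""
        for loc, isoforms in (ignar1, ignar2):
            for iso in isoforms:
                cds = loc.coding_seq(iso.chain)
                assert len(cds) % 3 == 0
                assert "*" not in Seq(cds).translate()

    def test_zero_intron_config_rejected(self):
        with pytest.raises(ValueError, match="intron"):
            build_locus(LocusConfig(intron_lengths=(0,) * 9))

    def test_non_codon_constant_exon_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            build_locus(LocusConfig(constant_domain_nt={"C2": 296}))

    def test_deterministic_given_seed(self):
        a = build_locus(LocusConfig(seed=3))
        b = build_locus(LocusConfig(seed=3))
        assert a.scaffold == b.scaffold
        assert a.model == b.model


@pytest.mark.parametrize(
    "scaffold, span, expected, truth",
    [
        ("ACGTACGT", (2, 4), "ACNNACGT", "GT"),
        ("ACGTACGT", (3, 3), "ACGTACGT", ""),
        ("ACGT", (0, 4), "NNNN", "ACGT"),
    ],
)
def test_mask_gap(scaffold, span, expected, truth):
    gapped, hidden = mask_gap(scaffold, span)
    assert gapped == expected
    assert hidden == truth
    assert len(gapped) == len(scaffold)


def test_mask_gap_out_of_bounds():
    with pytest.raises(ValueError):
        mask_gap("ACGT", (2, 9))


class TestGenomicReads:
    def test_pair_count_follows_coverage_formula(self):
        rng = np.random.default_rng(0)
        scaffold = "".join(rng.choice(list("ACGT"), size=10_000))
        reads = simulate_genomic_reads(scaffold, coverage=30, read_len=100,
                                       insert=300, seed=1)
        assert abs(len(reads.pairs) - 1500) <= 150

    def test_error_free_reads_are_exact_substrings(self):
        rng = np.random.default_rng(1)
        scaffold = "".join(rng.choice(list("ACGT"), size=3000))
        reads = simulate_genomic_reads(scaffold, coverage=5, err=0.0, seed=2)
        from ignar.synthetic import revcomp

        for p in reads.pairs:
            assert scaffold[p.pos1:p.pos1 + 100] == p.seq1
            assert scaffold[p.pos2:p.pos2 + 100] == revcomp(p.seq2)

    def test_same_seed_gives_byte_identical_fastq(self, tmp_path):
        rng = np.random.default_rng(2)
        scaffold = "".join(rng.choice(list("ACGT"), size=2000))
        files = []
        for run in ("a", "b"):
            reads = simulate_genomic_reads(scaffold, coverage=10, err=0.01,
                                           seed=7)
            p1, p2 = tmp_path / f"{run}_1.fq", tmp_path / f"{run}_2.fq"
            reads.write_fastq(p1, p2)
            files.append((p1.read_bytes(), p2.read_bytes()))
        assert files[0] == files[1]

    def test_invalid_error_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_genomic_reads("ACGT" * 300, err=1.5)


class TestSplicedReads:
    def test_blocks_are_subintervals_of_source_exons(self, ignar1):
        loc, isoforms = ignar1
        reads = simulate_spliced_reads(isoforms, 300, seed=4)
        by_name = {iso.name: iso for iso in isoforms}
        for aln, src in zip(reads.alignments, reads.source):
            iso = by_name[src]
            exons = [loc.model.exons[i] for i in iso.chain]
            assert len(aln.blocks) == len(exons)
            for (bs, be), (es, ee) in zip(aln.blocks, exons):
                assert es <= bs < be <= ee
            assert aln.junctions() == iso.junctions()

    def test_degenerate_abundance_vector(self, ignar1):
        loc, isoforms = ignar1
        import dataclasses

        two = [dataclasses.replace(isoforms[0], abundance=1.0),
               dataclasses.replace(isoforms[1], abundance=0.0)]
        reads = simulate_spliced_reads(two, 200, seed=5)
        assert set(reads.source) == {two[0].name}

    def test_single_isoform_closure(self, ignar2):
        loc, isoforms = ignar2
        reads = simulate_spliced_reads(isoforms[:1], 100, seed=6)
        junctions = {j for a in reads.alignments for j in a.junctions()}
        assert junctions == set(isoforms[0].junctions())

    def test_every_planted_junction_observed_at_depth(self, ignar1):
        """At 10,000 fragments over eleven isoforms, every planted junction
        is seen at least twice (coupon-collector check at this depth)."""
        loc, isoforms = ignar1
        reads = simulate_spliced_reads(isoforms, 10_000, seed=1)
        counts: dict = {}
        for aln in reads.alignments:
            for j in aln.junctions():
                counts[j] = counts.get(j, 0) + 1
        planted = {j for iso in isoforms for j in iso.junctions()}
        assert set(counts) == planted
        assert min(counts.values()) >= 2

    def test_read_len_longer_than_shortest_isoform_rejected(self, ignar1):
        _, isoforms = ignar1
        with pytest.raises(ValueError, match="read_len"):
            simulate_spliced_reads(isoforms, 10, read_len=10_000)


class TestRepertoire:
    def test_zero_mutation_rate_gives_identical_fixed_regions(self):
        cfg = default_repertoire_config(
            n_sequences=20, hv_mut_rate=0.0,
            cdr3_length_dist={12: 1.0}, cdr3_cys_dist={2: 1.0}, seed=1)
        rep = generate_repertoire(cfg)
        fixed_total = 88
        assert len({s[:fixed_total] for s in rep.sequences}) == 1

    def test_framework_positions_never_mutate(self):
        cfg = default_repertoire_config(n_sequences=50, hv_mut_rate=1.0, seed=2)
        rep = generate_repertoire(cfg)
        fr1 = DEFAULT_FRAMEWORK["FR1"]
        fr3b = DEFAULT_FRAMEWORK["FR3b"]
        for seq, truth in zip(rep.sequences, rep.truth):
            assert seq[truth["FR1_start"]:truth["FR1_end"]] == fr1
            assert seq[truth["FR3b_start"]:truth["FR3b_end"]] == fr3b
            # canonical cysteines always present
            assert seq[truth["FR1_start"] + 21] == "C"
            assert seq[truth["FR3b_start"] + 10] == "C"

    def test_constant_total_fixed_region_length(self):
        cfg = default_repertoire_config(n_sequences=200, hv_mut_rate=0.5, seed=3)
        rep = generate_repertoire(cfg)
        assert len({t["FR3b_end"] - t["FR1_start"] for t in rep.truth}) == 1

    def test_point_mass_cysteine_distribution(self):
        cfg = default_repertoire_config(
            n_sequences=100, cdr3_cys_dist={2: 1.0}, fr2_cys=True, seed=4)
        rep = generate_repertoire(cfg)
        assert all(t["cdr3_cys"] == 2 for t in rep.truth)

    def test_cysteine_count_frequencies_concentrate(self):
        """Empirical CDR3 cysteine-count fractions match the generator's
        distribution within +/-0.03 at n=2000."""
        cfg = default_repertoire_config(
            n_sequences=2000, cdr3_cys_dist={1: 0.7, 2: 0.3}, seed=5)
        rep = generate_repertoire(cfg)
        counts = [t["cdr3_cys"] for t in rep.truth]
        assert abs(counts.count(1) / 2000 - 0.7) <= 0.03
        assert abs(counts.count(2) / 2000 - 0.3) <= 0.03

    def test_invalid_mutation_rate_rejected(self):
        with pytest.raises(ValueError):
            default_repertoire_config(hv_mut_rate=1.5)

    def test_distributions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            default_repertoire_config(cdr3_cys_dist={1: 0.5, 2: 0.4})

    def test_fasta_round_trip(self, tmp_path):
        from Bio import SeqIO

        rep = generate_repertoire(default_repertoire_config(n_sequences=10))
        path = tmp_path / "rep.fasta"
        rep.write_fasta(path)
        records = list(SeqIO.parse(str(path), "fasta"))
        assert [str(r.seq) for r in records] == list(rep.sequences)
        assert [r.id for r in records] == list(rep.names)
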
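"""Tests of ORF extraction, VNAR annotation, typing, census and PCR."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ignar.models import PrimerSpec, VnarScheme
from ignar.synthetic import (
    default_repertoire_config,
    generate_repertoire,
    revcomp,
)
from ignar.vnar import (
    annotate_vnar,
    census,
    check_constant_domains,
    classify_type,
    in_silico_pcr,
    longest_orf,
)

REGIONS = ("FR1", "CDR1", "FR2", "HV2", "FR3a", "HV4", "FR3b", "CDR3", "FR4")


class TestLongestOrf:
    def test_simple_orf(self):
        res = longest_orf("ATGAAATAG")
        assert (res.protein, res.frame, res.status) == ("MK", 1, "ok")

    def test_tie_broken_by_leftmost_start(self):
        res = longest_orf("CCATGAAATAGATGGGGTAA")
        assert res.protein == "MK"
        assert res.span[0] == 2

    def test_no_start_codon(self):
        res = longest_orf("CCCCCCCCC")
        assert res.status == "no-start"
        assert res.protein == ""

    def test_open_ended_orf_runs_to_frame_end(self):
        res = longest_orf("ATGAAAGGG")
        assert res.protein == "MKG"

    def test_orf_from_synthetic_leader_vnar_transcript(self, ignar1):
        """The longest ORF of the spliced leader+VNAR transcript starts at
        the leader's initiator and contains the planted VNAR framework."""
        loc, _ = ignar1
        vnar_exon = loc.model.exon_of_domain("VNAR")
        transcript = loc.transcript_seq((0, vnar_exon))
        res = longest_orf(transcript)
        assert res.status == "ok"
        assert loc.vnar_protein in res.protein

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            longest_orf("AT")


class TestAnnotateVnar:
    def test_planted_regions_recovered(self):
        """Annotation of generator output matches the planted truth spans."""
        cfg = default_repertoire_config(n_sequences=100, fr2_cys=True,
                                        cdr3_cys_dist={2: 1.0}, seed=10)
        rep = generate_repertoire(cfg)
        for seq, truth in zip(rep.sequences, rep.truth):
            ann = annotate_vnar(seq)
            for region in REGIONS:
                assert ann.regions[region] == (
                    truth[f"{region}_start"], truth[f"{region}_end"])
            assert ann.cdr3_cys_count == truth["cdr3_cys"]

    def test_region_spans_tile_the_sequence(self):
        cfg = default_repertoire_config(n_sequences=20, seed=11)
        rep = generate_repertoire(cfg)
        for seq in rep.sequences:
            ann = annotate_vnar(seq)
            spans = sorted(ann.regions.values())
            assert spans[0][0] == 0
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 == s2
            rebuilt = "".join(seq[s:e] for s, e in spans)
            assert rebuilt == seq[:spans[-1][1]]

    def test_missing_canonical_cysteines_unclassified(self):
        cfg = default_repertoire_config(n_sequences=1, hv_mut_rate=0.0, seed=1)
        seq = generate_repertoire(cfg).sequences[0]
        broken = seq.replace("C", "S")
        ann = annotate_vnar(broken)
        assert ann.type_call == "unclassified"
        assert "missing-canonical-cysteine" in ann.flags

    def test_no_fr4_anchor_extends_cdr3_to_terminus(self):
        cfg = default_repertoire_config(n_sequences=1, hv_mut_rate=0.0, seed=1)
        seq = generate_repertoire(cfg).sequences[0]
        truncated = seq[:88] + "ASDEK"  # CDR3-like tail, no anchor
        ann = annotate_vnar(truncated)
        assert "no-fr4-anchor" in ann.flags
        assert ann.regions["CDR3"] == (88, len(truncated))

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            annotate_vnar("MKV")


class TestClassifyType:
    def test_type_rules_and_bond_counts(self):
        """Type I (FR2 + >=2 CDR3 cysteines) predicts three bonds; type II
        (CDR1 + >=1) predicts two; canonical-only predicts one."""
        t1 = generate_repertoire(default_repertoire_config(
            n_sequences=1, fr2_cys=True, cdr1_cys=False,
            cdr3_cys_dist={2: 1.0}, seed=1)).sequences[0]
        t2 = generate_repertoire(default_repertoire_config(
            n_sequences=1, fr2_cys=False, cdr1_cys=True, fr4_cys=False,
            cdr3_cys_dist={1: 1.0}, seed=2)).sequences[0]
        c0 = generate_repertoire(default_repertoire_config(
            n_sequences=1, fr2_cys=False, cdr1_cys=False, fr4_cys=False,
            cdr3_cys_dist={0: 1.0}, seed=3)).sequences[0]
        a1, a2, a0 = annotate_vnar(t1), annotate_vnar(t2), annotate_vnar(c0)
        assert (a1.type_call, len(a1.predicted_bonds)) == ("I", 3)
        assert (a2.type_call, len(a2.predicted_bonds)) == ("II", 2)
        assert (a0.type_call, len(a0.predicted_bonds)) == ("canonical-only", 1)

    def test_type_i_bond_partners(self):
        seq = generate_repertoire(default_repertoire_config(
            n_sequences=1, fr2_cys=True, cdr3_cys_dist={2: 1.0},
            seed=4)).sequences[0]
        ann = annotate_vnar(seq)
        regions = [frozenset((b.residue_a[0], b.residue_b[0]))
                   for b in ann.predicted_bonds]
        assert frozenset({"FR1", "FR3b"}) in regions
        assert frozenset({"FR2", "CDR3"}) in regions
        assert frozenset({"CDR3", "FR4"}) in regions

    def test_ambiguous_fr2_and_cdr1_unclassified(self):
        seq = generate_repertoire(default_repertoire_config(
            n_sequences=1, fr2_cys=True, cdr1_cys=True,
            cdr3_cys_dist={2: 1.0}, seed=5)).sequences[0]
        ann = annotate_vnar(seq)
        assert ann.type_call == "unclassified"
        result = classify_type(ann)
        assert set(result.candidates) == {"I", "II"}

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_call_depends_only_on_cysteine_placement(self, shuffle_seed):
        """Permuting non-cysteine residues inside the hypervariable regions
        and CDR3 never changes the type call or bond count."""
        seq = generate_repertoire(default_repertoire_config(
            n_sequences=1, fr2_cys=True, cdr3_cys_dist={2: 1.0},
            seed=6)).sequences[0]
        base = annotate_vnar(seq)
        rng = np.random.default_rng(shuffle_seed)
        chars = list(seq)
        for region in ("CDR1", "HV2", "HV4", "CDR3"):
            s, e = base.regions[region]
            idx = [i for i in range(s, e) if chars[i] != "C"]
            vals = [chars[i] for i in idx]
            rng.shuffle(vals)
            for i, v in zip(idx, vals):
                chars[i] = v
        permuted = annotate_vnar("".join(chars))
        assert permuted.type_call == base.type_call
        assert len(permuted.predicted_bonds) == len(base.predicted_bonds)


class TestCensus:
    def test_fractions_recover_generator_probabilities(self):
        cfg = default_repertoire_config(
            n_sequences=2000, cdr3_cys_dist={1: 0.7, 2: 0.3}, seed=7)
        rep = generate_repertoire(cfg)
        result = census([annotate_vnar(s) for s in rep.sequences])
        assert abs(result.fraction_eq(1) - 0.7) <= 0.03
        assert abs(result.fraction_eq(2) - 0.3) <= 0.03
        assert result.fraction_ge(1) == pytest.approx(1.0)

    def test_singleton_and_empty(self):
        seq = generate_repertoire(default_repertoire_config(
            n_sequences=1, cdr3_cys_dist={2: 1.0}, seed=8)).sequences[0]
        result = census([annotate_vnar(seq)])
        assert result.histogram == {2: 1}
        empty = census([])
        assert empty.n == 0 and empty.histogram == {}

    def test_histogram_totals_match_sequence_count(self):
        cfg = default_repertoire_config(n_sequences=150, seed=9)
        rep = generate_repertoire(cfg)
        result = census([annotate_vnar(s) for s in rep.sequences])
        assert sum(result.histogram.values()) == 150


class TestCheckConstantDomains:
    def test_planted_counts_and_linker_flag(self, ignar1):
        """Three cysteines in C1, two in C2-C5, one in the C3-C4 linker."""
        loc, _ = ignar1
        chain = loc.full_chain()
        protein, spans = loc.protein_for_chain(chain)
        report = check_constant_domains(protein, spans,
                                        loc.linker_span_for_chain(chain))
        assert report.cys_counts == {"C1": 3, "C2": 2, "C3": 2, "C4": 2,
                                     "C5": 2}
        assert report.linker_cys

    def test_no_linker_cysteine(self):
        from ignar.synthetic import gcignar1_locus

        loc = gcignar1_locus(linker_cys=False)
        chain = loc.full_chain()
        protein, spans = loc.protein_for_chain(chain)
        c3 = spans["C3"]
        report = check_constant_domains(
            protein, spans, (c3[1] - loc.config.linker_aa, c3[1]))
        assert not report.linker_cys

    def test_short_form_reports_c1_to_c3_only(self, ignar1):
        loc, isoforms = ignar1
        short = next(iso for iso in isoforms if iso.short_form)
        protein, spans = loc.protein_for_chain(short.chain)
        report = check_constant_domains(protein, spans,
                                        loc.linker_span_for_chain(short.chain))
        assert set(report.cys_counts) == {"C1", "C2", "C3"}

    def test_missing_boundaries_rejected(self):
        with pytest.raises(ValueError):
            check_constant_domains("MKV", {})


class TestInSilicoPcr:
    TEMPLATE = ("GGGG" + "ATGCATGCATGCATGCATGC" + "T" * 400
                + "GGATCCGGATCCGGATCC" + "AAAA")

    def _primers(self, fwd="ATGCATGCATGCATGCATGC",
                 rev=None, **kw):
        rev = rev or revcomp("GGATCCGGATCCGGATCC")
        return (PrimerSpec("f", fwd, "forward", **kw),
                PrimerSpec("r", rev, "reverse", **kw))

    def test_exact_primer_pair_yields_one_amplicon(self):
        fwd, rev = self._primers()
        products = in_silico_pcr(self.TEMPLATE, fwd, rev)
        assert len(products) == 1
        amp = products[0]
        assert amp.length == 20 + 400 + 18
        assert amp.seq.startswith("ATGCATGC")
        assert amp.seq.endswith("GGATCC")

    def test_iupac_n_matches_any_base(self):
        fwd, rev = self._primers(fwd="ATGCATGCNTGCATGCATGC")
        products = in_silico_pcr(self.TEMPLATE, fwd, rev)
        assert len(products) == 1

    def test_three_prime_mismatch_kills_the_hit(self):
        bad_fwd = "ATGCATGCATGCATGCATGA"  # mismatch at the 3' base
        fwd, rev = self._primers(fwd=bad_fwd, max_mismatch=2,
                                 three_prime_exact=3)
        assert in_silico_pcr(self.TEMPLATE, fwd, rev) == []

    def test_internal_mismatch_tolerated_within_budget(self):
        mm_fwd = "ATGCATGCGTGCATGCATGC"  # one internal mismatch
        fwd, rev = self._primers(fwd=mm_fwd, max_mismatch=1)
        assert len(in_silico_pcr(self.TEMPLATE, fwd, rev)) == 1

    def test_no_products_is_empty_list(self):
        fwd, rev = self._primers(fwd="TTTTTTTTTTGGGGGGGGGG")
        assert in_silico_pcr("ACGT" * 50, fwd, rev) == []

    def test_vnar_amplicon_from_synthetic_locus(self, ignar1):
        """Primers in FR1 and at the start of C1 amplify across the VNAR."""
        loc, _ = ignar1
        cds = loc.cds
        fr1_aa = loc.domain_aa_spans["VNAR"][0]
        c1_aa = loc.domain_aa_spans["C1"][0]
        fwd_seq = cds[3 * fr1_aa: 3 * fr1_aa + 21]
        rev_seq = revcomp(cds[3 * c1_aa: 3 * c1_aa + 21])
        fwd = PrimerSpec("GcVNAR_F", fwd_seq, "forward")
        rev = PrimerSpec("GcVNAR_R", rev_seq, "reverse")
        products = in_silico_pcr(cds, fwd, rev)
        assert len(products) == 1
        assert products[0].length == 3 * (c1_aa - fr1_aa) + 21
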
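"""Precursor processing grammar: signal stripping, cleavage, amidation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venomsig.mass_core import mh_plus
from venomsig.maturation import (
    PrecursorRecord,
    Strategy,
    apply_processing,
    expand_alleles,
    find_basic_sites,
    mature_candidates,
    strip_signal,
)

AA = "ACDEFGHIKLMNPQRSTVWY"

EI4_PRECURSOR = (
    "MKWCTVFMFCLVILVHEFQDVYG"
    "EKEGYPLDATRNIYQCYDLGENDYCEKKCKEFGGHGYCYGFACYCKYIRDDVKIWKG"
)
AMP_EI2A_CHAIN = "ILSDIWNGIKGLFGKRGLFPQRPLINRDQFDDVFDDDLSAADLKFLQELLK"
AMP_EI1_CHAIN = "FWGFLAKLATKVVPSLFGSSSEKSKREIENFFEPYQKDLDLELDRFDRFLSKLDLN"


class TestStripSignal:
    def test_signal_boundary(self):
        rec = PrecursorRecord(id="Ei4", sequence=EI4_PRECURSOR, signal_end=23)
        assert strip_signal(rec).startswith("EKEGYPLDATRN")

    def test_minimal_chain(self):
        rec = PrecursorRecord(id="x", sequence="MG", signal_end=1)
        assert strip_signal(rec) == "G"

    def test_empty_mature_chain_forbidden(self):
        with pytest.raises(ValueError):
            PrecursorRecord(id="x", sequence="MAG", signal_end=3)


class TestFindBasicSites:
    def test_terminal_tribasic(self):
        sites = find_basic_sites("GWINEDKELSYRRK")
        terminal = sites[-1]
        assert terminal.kind == "tribasic"
        assert terminal.position == 11

    def test_dibasic_kr(self):
        sites = find_basic_sites("ILSDIWNGIAGLFGKR")
        assert [s.kind for s in sites] == ["dibasic"]
        assert sites[0].position == 14

    def test_no_basics(self):
        assert find_basic_sites("ILSDIWNGIAGLF") == []

    def test_long_run_collapses_to_tribasic(self):
        sites = find_basic_sites("AAAKRKRAAA")
        assert sites == [s for s in sites]
        assert sites[0].kind == "tribasic"
        assert sites[0].position == 4  # C-terminal three of the run

    def test_quadruplet_flag_on_spaced_arg(self):
        (site,) = find_basic_sites("IENGRAAAA".replace("A", "Q"))
        assert site.kind == "quadruplet"


class TestApplyProcessing:
    def test_n_term_region_with_gly_amidation(self):
        (p,) = apply_processing(AMP_EI2A_CHAIN, Strategy.N_TERM_REGION)
        assert p.sequence == "ILSDIWNGIKGLF"
        assert p.amidated

    def test_n_term_region_amp_ei1(self):
        (p,) = apply_processing(AMP_EI1_CHAIN, Strategy.N_TERM_REGION)
        assert p.sequence.endswith("SSEKS")
        assert not p.amidated
        assert mh_plus(p.sequence) == pytest.approx(2586.38, abs=0.1)

    def test_full_chain_keeps_everything(self):
        chain = "KKTFMEKAKSVFSKAGNKIKEIAGKSEYMCPVVSSFCEQHCARQEKSGECDFNKCTCS"
        (p,) = apply_processing(chain, Strategy.FULL_CHAIN)
        assert p.sequence == chain
        assert p.n_disulfides == 3
        assert not p.amidated

    def test_gly_amide_requires_terminal_gly(self):
        assert apply_processing("AKNDE", Strategy.FULL_CHAIN_GLY_AMIDE) == []

    def test_gly_amide_consumes_terminal_gly(self):
        (p,) = apply_processing("AKNDEG", Strategy.FULL_CHAIN_GLY_AMIDE)
        assert p.sequence == "AKNDE"
        assert p.amidated

    def test_c_term_cleave_excludes_basic_run(self):
        chain = "AQDNSELSYRRK"
        products = apply_processing(chain, Strategy.C_TERM_BASIC_CLEAVE)
        assert any(p.sequence == "AQDNSELSY" for p in products)

    def test_quadruplet_requires_spacer(self):
        # Arg at position 0: no spacer, strategy inapplicable
        assert apply_processing("RAAAQ", Strategy.N_TERM_QUADRUPLET) == []

    def test_quadruplet_releases_c_terminal_segment(self):
        (p,) = apply_processing("IENGRKSPNFQEG", Strategy.N_TERM_QUADRUPLET)
        assert p.sequence == "KSPNFQE"
        assert p.amidated


class TestExpandAlleles:
    def test_two_alleles(self):
        assert expand_alleles("LKEKEK/EKE") == ["LKEKEKKE", "LKEKEEKE"]

    def test_plain_sequence_singleton(self):
        assert expand_alleles("ACDEF") == ["ACDEF"]

    def test_multiple_markers_rejected(self):
        with pytest.raises(ValueError):
            expand_alleles("AK/ECD/EG")


class TestTable1Derivations:
    def test_auto_contains_every_printed_mature_peptide(
        self, table1_precursors, table1_matures
    ):
        """AUTO enumeration recovers the displayed mature region of every
        fixture row, with its printed mass reproduced within 0.1 Da."""
        for rec in table1_precursors:
            candidates = mature_candidates(rec, Strategy.AUTO)
            got = {(c.sequence, c.amidated) for c in candidates}
            for seq, amidated, n_ds, printed in table1_matures[rec.id]:
                assert (seq, amidated) in got, rec.id
                assert mh_plus(seq, amidated, n_ds) == pytest.approx(
                    printed, abs=0.1
                ), rec.id

    def test_annotated_strategy_yields_printed_mature(
        self, table1_precursors, table1_matures
    ):
        for rec in table1_precursors:
            got = {
                (c.sequence, c.amidated)
                for c in mature_candidates(rec)  # uses annotated strategy
            }
            for seq, amidated, *_ in table1_matures[rec.id]:
                assert (seq, amidated) in got, rec.id


@st.composite
def chains(draw):
    return draw(st.text(alphabet=AA, min_size=2, max_size=80))


class TestGrammarProperties:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(chain=chains())
    def test_products_are_contiguous_substrings(self, chain):
        """Every product, after restoring a consumed terminal Gly, is a
        contiguous substring of the chain."""
        for p in apply_processing(chain, Strategy.AUTO):
            restored = p.sequence + ("G" if p.amidated else "")
            assert restored in chain or p.sequence in chain

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(chain=chains())
    def test_amidation_only_from_consumed_gly(self, chain):
        for p in apply_processing(chain, Strategy.AUTO):
            if p.amidated:
                assert p.sequence + "G" in chain

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(chain=chains())
    def test_sites_are_maximal_basic_runs(self, chain):
        for s in find_basic_sites(chain):
            run = chain[s.position : s.position + s.basic_run_length]
            assert set(run) <= {"K", "R"}
            # maximal: not extensible to the right
            end = s.position + s.basic_run_length
            if end < len(chain):
                assert chain[end] not in "KR"

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(chain=chains())
    def test_auto_has_no_duplicate_products(self, chain):
        products = apply_processing(chain, Strategy.AUTO)
        keys = [(p.sequence, p.amidated) for p in products]
        assert len(keys) == len(set(keys))
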
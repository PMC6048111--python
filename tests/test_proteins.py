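"""Coordinate conversion, junction phases against a translation oracle, and
domain retention arithmetic."""

import numpy as np
import pytest

from fusionsieve.model import ProteinDomain, TranscriptModel, ValidationError
from fusionsieve.proteins import (
    build_fusion_protein,
    cds_to_genomic,
    domain_retention,
    genomic_to_cds,
    junction_phases,
)

from .helpers import build_locus, fused_frame_oracle, random_cds


def simple_tx(strand="+", exons=((101, 200),), cds_start=111, cds_end=170):
    return TranscriptModel("G", "G.t1", "chr1", strand, exons, cds_start, cds_end)


class TestCoordinates:
    def test_plus_strand_cds_start_is_offset_zero(self):
        tx = simple_tx("+")
        assert genomic_to_cds(tx, tx.cds_start) == 0

    def test_minus_strand_cds_end_is_offset_zero(self):
        tx = simple_tx("-")
        assert genomic_to_cds(tx, tx.cds_end) == 0

    def test_two_exon_offset_counts_across_intron(self):
        # exon1 contributes 10 coding bases (141-150), exon2 20 (301-320);
        # the 3rd base of exon2's coding part sits at overall offset 12
        tx = TranscriptModel("G", "G.t1", "chr1", "+",
                             exons=((101, 150), (301, 340)),
                             cds_start=141, cds_end=320)
        assert tx.cds_length == 30
        assert genomic_to_cds(tx, 303) == 12

    def test_intron_position_maps_to_none_with_description(self):
        tx = TranscriptModel("G", "G.t1", "chr1", "+",
                             exons=((101, 150), (301, 340)),
                             cds_start=141, cds_end=320)
        from fusionsieve.proteins import describe_position

        assert genomic_to_cds(tx, 200) is None
        assert "intronic" in describe_position(tx, 200)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_cds_to_genomic_inverts_genomic_to_cds(self, strand, rng):
        for _ in range(20):
            cds = random_cds(rng, int(rng.integers(10, 60)))
            tx, pos_of = build_locus(rng, cds, strand)
            for off in rng.integers(0, len(cds), size=10):
                pos = cds_to_genomic(tx, int(off))
                assert pos == pos_of[off]
                assert genomic_to_cds(tx, pos) == off


class TestJunctionPhases:
    def test_codon_multiple_retention_is_in_frame(self, rng):
        donor_cds = random_cds(rng, 120)
        acc_cds = random_cds(rng, 100)
        dtx, dpos = build_locus(rng, donor_cds, "+", gene="DON", chrom="chrD")
        atx, apos = build_locus(rng, acc_cds, "+", gene="ACC", chrom="chrA")
        res = junction_phases(dtx, dpos[300 - 1], atx, apos[0])
        assert (res.donor_phase, res.acceptor_phase, res.in_frame) == (0, 0, True)

    def test_mismatched_phases_are_out_of_frame(self, rng):
        donor_cds = random_cds(rng, 120)
        acc_cds = random_cds(rng, 100)
        dtx, dpos = build_locus(rng, donor_cds, "+", gene="DON", chrom="chrD")
        atx, apos = build_locus(rng, acc_cds, "+", gene="ACC", chrom="chrA")
        res = junction_phases(dtx, dpos[301 - 1], atx, apos[2])
        assert (res.donor_phase, res.acceptor_phase) == (1, 2)
        assert res.in_frame is False
        assert res.label == "1->2"

    def test_intronic_breakpoint_gives_undefined_phase_with_reason(self, rng):
        cds = random_cds(rng, 60)
        while True:
            dtx, dpos = build_locus(rng, cds, "+", gene="DON")
            if len(dtx.exons) > 1:
                break
        intron_pos = dtx.exons[0][1] + 1
        atx, apos = build_locus(rng, random_cds(rng, 60), "+", gene="ACC")
        res = junction_phases(dtx, intron_pos, atx, apos[0])
        assert res.donor_phase is None and res.in_frame is False
        assert "intronic" in res.reason

    def test_promoter_swap_flagged_and_in_frame_only_at_phase_zero(self, rng):
        cds = random_cds(rng, 60)
        dtx, dpos = build_locus(rng, cds, "+", gene="DON")
        utr5_pos = dtx.cds_start - 1 if dtx.strand == "+" else dtx.cds_end + 1
        atx, apos = build_locus(rng, random_cds(rng, 60), "+", gene="ACC")
        res0 = junction_phases(dtx, utr5_pos, atx, apos[0])
        assert res0.promoter_swap and res0.in_frame
        res1 = junction_phases(dtx, utr5_pos, atx, apos[1])
        assert res1.promoter_swap and not res1.in_frame

    def test_agrees_with_translation_oracle(self, rng):
        """Phase equality must coincide with the brute-force translation
        oracle (acceptor C-terminal peptide preserved) on random toy
        fusions across strands and exon structures."""
        disagreements = 0
        for _ in range(300):
            donor_cds = random_cds(rng, int(rng.integers(15, 80)))
            acc_cds = random_cds(rng, int(rng.integers(15, 80)))
            dtx, dpos = build_locus(rng, donor_cds, "+-"[rng.integers(0, 2)],
                                    gene="DON", chrom="chrD")
            atx, apos = build_locus(rng, acc_cds, "+-"[rng.integers(0, 2)],
                                    gene="ACC", chrom="chrA")
            ld = int(rng.integers(1, len(donor_cds) + 1))
            da = int(rng.integers(0, len(acc_cds) - 18))
            res = junction_phases(dtx, dpos[ld - 1], atx, apos[da])
            oracle = fused_frame_oracle(donor_cds, ld, acc_cds, da)
            disagreements += res.in_frame != oracle
        assert disagreements == 0

    def test_strand_symmetry_of_phases(self, rng):
        """Reverse-complementing a locus (mirroring coordinates, flipping
        the strand) leaves every phase result unchanged."""

        def mirror(tx, pos_of, mirror_at=10_000_000):
            exons = tuple(sorted((mirror_at - e, mirror_at - s) for s, e in tx.exons))
            flipped = TranscriptModel(
                tx.gene, tx.transcript_id, tx.chrom,
                "-" if tx.strand == "+" else "+",
                exons, mirror_at - tx.cds_end, mirror_at - tx.cds_start,
            )
            return flipped, [mirror_at - p for p in pos_of]

        for _ in range(25):
            donor_cds = random_cds(rng, int(rng.integers(15, 60)))
            acc_cds = random_cds(rng, int(rng.integers(15, 60)))
            dtx, dpos = build_locus(rng, donor_cds, "+", gene="DON", chrom="chrD")
            atx, apos = build_locus(rng, acc_cds, "+", gene="ACC", chrom="chrA")
            ld = int(rng.integers(1, len(donor_cds) + 1))
            da = int(rng.integers(0, len(acc_cds) - 3))
            res = junction_phases(dtx, dpos[ld - 1], atx, apos[da])

            mdtx, mdpos = mirror(dtx, dpos)
            matx, mapos = mirror(atx, apos)
            mres = junction_phases(mdtx, mdpos[ld - 1], matx, mapos[da])
            assert (res.donor_phase, res.acceptor_phase, res.in_frame) == (
                mres.donor_phase, mres.acceptor_phase, mres.in_frame,
            )


class TestDomainRetention:
    def test_downstream_kinase_domain_fully_retained(self):
        pk = ProteinDomain("ALK", "PK", 400, 600)
        (status,) = domain_retention("acceptor", 100, [pk], protein_length=700)
        assert status.status == "retained" and status.fraction == 1.0

    def test_published_suppressor_truncation_fractions(self):
        """Breakpoints inside annotated suppressor regions reproduce the
        published retained fractions (293/325 and 179/253)."""
        apc_region = ProteinDomain("APC", "SUP", 1, 325)
        (s,) = domain_retention("donor", 293, [apc_region], protein_length=2843)
        assert s.status == "truncated"
        assert s.fraction == pytest.approx(293 / 325)

        rasa1_region = ProteinDomain("RASA1", "SUP", 1, 253)
        (s,) = domain_retention("donor", 179, [rasa1_region], protein_length=1047)
        assert s.status == "truncated"
        assert s.fraction == pytest.approx(179 / 253)

    def test_statuses_partition_every_domain(self, rng):
        for _ in range(50):
            plen = int(rng.integers(50, 500))
            bp = int(rng.integers(1, plen + 1))
            s = int(rng.integers(1, plen + 1))
            dom = ProteinDomain("G", "D", s, int(rng.integers(s, plen + 1)))
            side = "donor" if rng.random() < 0.5 else "acceptor"
            (status,) = domain_retention(side, bp, [dom], protein_length=plen)
            assert status.status in ("retained", "lost", "truncated")
            assert (status.status == "retained") == (status.fraction == 1.0)
            assert (status.status == "lost") == (status.fraction == 0.0)

    def test_domain_beyond_protein_length_is_annotation_error(self):
        dom = ProteinDomain("G", "D", 10, 900)
        with pytest.raises(ValidationError, match="beyond"):
            domain_retention("donor", 5, [dom], protein_length=500)


class TestFusionProtein:
    def test_segment_lengths_sum_for_in_frame_fusions(self, rng):
        for _ in range(30):
            donor_cds = random_cds(rng, int(rng.integers(15, 60)))
            acc_cds = random_cds(rng, int(rng.integers(15, 60)))
            dtx, dpos = build_locus(rng, donor_cds, "+", gene="DON", chrom="chrD")
            atx, apos = build_locus(rng, acc_cds, "-", gene="ACC", chrom="chrA")
            ld = int(rng.integers(1, len(donor_cds)))
            da_base = int(rng.integers(0, len(acc_cds) - 6))
            da = da_base + (ld - da_base) % 3  # force in-frame
            fp = build_fusion_protein(dtx, dpos[ld - 1], atx, apos[da])
            assert fp.in_frame
            expected_total = (ld + len(acc_cds) - da) // 3
            assert fp.total_aa == expected_total

    def test_domains_attached_to_both_sides(self, rng):
        donor_cds = random_cds(rng, 60)
        acc_cds = random_cds(rng, 60)
        dtx, dpos = build_locus(rng, donor_cds, "+", gene="DON", chrom="chrD")
        atx, apos = build_locus(rng, acc_cds, "+", gene="ACC", chrom="chrA")
        domains = [ProteinDomain("DON", "NT", 1, 10), ProteinDomain("ACC", "PK", 40, 55)]
        fp = build_fusion_protein(dtx, dpos[29], atx, apos[0], domains)  # ld=30, da=0
        assert fp.retained_domains[("DON", "NT")].status == "retained"
        assert fp.retained_domains[("ACC", "PK")].status == "retained"
        assert fp.min_retained_fraction("DON") == 1.0
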
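import numpy as np
import pytest

from lncraft.homology import HomologyEngine
from lncraft.lncrna import (
    antisense_overlaps,
    build_nat_pairs,
    classify_nat_vs_linc,
    find_linc_targets,
    length_stats,
    match_noncoding_dbs,
)
from lncraft.coding import CodingVerdict
from lncraft.lncrna import LncVerdict
from lncraft.models import GenomeAnnotation, SequenceLibrary, TranscriptModel


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def tx(tid, exons, strand="+", gene=None, seq=None, chrom="chr1"):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene or f"g_{tid}", chrom=chrom,
        strand=strand, exons=exons, sequence=seq, class_code="reference",
    )


class TestMatchNoncodingDbs:
    @pytest.fixture()
    def dbs(self):
        rng = np.random.default_rng(0)
        small = SequenceLibrary("s", "smallrna", {"sr1": rand_seq(rng, 120)})
        te = SequenceLibrary(
            "t", "te", {"te1": rand_seq(rng, 600)}, {"te1": ("Gyma", "RLG")}
        )
        return small, te

    def test_planted_smallrna_copy(self, engine, dbs):
        rng = np.random.default_rng(1)
        small, te = dbs
        seq = rand_seq(rng, 150) + small.entries["sr1"][:40] + rand_seq(rng, 150)
        v = match_noncoding_dbs(tx("t", [(0, len(seq))], seq=seq), small, te, engine)
        assert v.subcategory == "siRNA_precursor"
        assert v.evidence == ["sr1"]

    def test_precedence_smallrna_over_te(self, engine, dbs):
        rng = np.random.default_rng(2)
        small, te = dbs
        seq = (
            rand_seq(rng, 100) + small.entries["sr1"][:40]
            + te.entries["te1"][:60] + rand_seq(rng, 100)
        )
        t = tx("t", [(0, len(seq))], seq=seq)
        assert match_noncoding_dbs(t, small, te, engine).subcategory == "siRNA_precursor"
        # order flipped: the TE match wins, confirming both would match
        assert match_noncoding_dbs(
            t, small, te, engine, smallrna_first=False
        ).subcategory == "TE_derived"

    def test_no_match_is_truly_lncrna(self, engine, dbs):
        rng = np.random.default_rng(3)
        small, te = dbs
        v = match_noncoding_dbs(
            tx("t", [(0, 300)], seq=rand_seq(rng, 300)), small, te, engine
        )
        assert v.subcategory == "lncRNA"


class TestNatVsLinc:
    @pytest.mark.parametrize("overlap,expected", [(10, "lncNAT"), (9, "lincRNA")])
    def test_10_nt_overlap_boundary(self, overlap, expected):
        partner = tx("mrna", [(1_000, 2_000)], "+", gene="gA")
        lnc = tx("lnc", [(2_000 - overlap, 2_500)], "-", gene="gB")
        ann = GenomeAnnotation([partner, lnc])
        kind, partners = classify_nat_vs_linc(lnc, ann)
        assert kind == expected

    def test_same_strand_overlap_is_lincRNA(self):
        partner = tx("mrna", [(1_000, 2_000)], "+", gene="gA")
        lnc = tx("lnc", [(1_500, 2_500)], "+", gene="gB")
        ann = GenomeAnnotation([partner, lnc])
        assert classify_nat_vs_linc(lnc, ann)[0] == "lincRNA"

    def test_own_gene_is_not_a_partner(self):
        a = tx("iso1", [(0, 500)], "+", gene="gA")
        b = tx("iso2", [(100, 600)], "-", gene="gA")
        ann = GenomeAnnotation([a, b])
        assert classify_nat_vs_linc(b, ann)[0] == "lincRNA"

    def test_unknown_strand_warns_and_is_excluded(self):
        lnc = tx("lnc", [(0, 300)], ".")
        ann = GenomeAnnotation([lnc, tx("mrna", [(100, 400)], "+", gene="gB")])
        with pytest.warns(UserWarning):
            assert antisense_overlaps(lnc, ann) == []

    def test_symmetry_of_antisense_overlap(self):
        a = tx("a", [(0, 300), (500, 800)], "+", gene="gA")
        b = tx("b", [(250, 600)], "-", gene="gB")
        ann = GenomeAnnotation([a, b])
        ov_ab = dict(antisense_overlaps(a, ann))["b"]
        ov_ba = dict(antisense_overlaps(b, ann))["a"]
        assert ov_ab == ov_ba == 100

    def test_matches_per_base_brute_force_on_random_placements(self):
        """Classification equals a per-base opposite-strand contiguous
        overlap count on random exon placements."""
        rng = np.random.default_rng(4)
        for trial in range(300):
            txs = []
            for i in range(int(rng.integers(2, 6))):
                pos = int(rng.integers(0, 3_000))
                exons = []
                for _ in range(int(rng.integers(1, 4))):
                    L = int(rng.integers(20, 400))
                    exons.append((pos, pos + L))
                    pos += L + int(rng.integers(2, 200))
                strand = "+" if rng.random() < 0.5 else "-"
                txs.append(tx(f"t{trial}_{i}", exons, strand, gene=f"g{i}"))
            ann = GenomeAnnotation(txs)
            lnc = txs[0]
            got_kind, got_partners = classify_nat_vs_linc(lnc, ann)
            lnc_bases = {p for a, b in lnc.exons for p in range(a, b)}
            expect = {}
            for other in txs[1:]:
                if other.strand == lnc.strand or other.gene_id == lnc.gene_id:
                    continue
                shared = sorted(
                    lnc_bases & {p for a, b in other.exons for p in range(a, b)}
                )
                best = run = 0
                for i, p in enumerate(shared):
                    run = run + 1 if i and shared[i - 1] == p - 1 else 1
                    best = max(best, run)
                if best >= 10:
                    expect[other.transcript_id] = best
            assert dict(got_partners) == expect
            assert got_kind == ("lncNAT" if expect else "lincRNA")


class TestNatPairs:
    def test_kinds_and_dedup(self):
        coding_verdicts = {"mrna": CodingVerdict("mrna", "coding", "long_orf")}
        lnc_verdicts = {
            "lncA": LncVerdict("lncA", "lncRNA", "lncNAT"),
            "lncB": LncVerdict("lncB", "lncRNA", "lncNAT"),
            "prec": LncVerdict("prec", "siRNA_precursor"),
        }
        partners = {
            "lncA": [("mrna", 50), ("lncB", 20)],
            "lncB": [("lncA", 20), ("prec", 15)],
        }
        pairs = build_nat_pairs(partners, coding_verdicts, lnc_verdicts)
        kinds = sorted(p.partner_kind for p in pairs)
        assert kinds == ["coding_mRNA", "lncNAT", "siRNA_precursor"]
        nat_nat = [p for p in pairs if p.partner_kind == "lncNAT"]
        assert len(nat_nat) == 1  # unordered pair counted once


class TestLincTargets:
    @pytest.fixture()
    def cds_lib(self):
        rng = np.random.default_rng(5)
        return SequenceLibrary("cds", "cds", {"cds1": rand_seq(rng, 900)}), rng

    def _linc(self, insert, rng, tid="linc"):
        seq = rand_seq(rng, 120) + insert + rand_seq(rng, 120)
        return tx(tid, [(0, len(seq))], seq=seq)

    def test_planted_exact_fragment_is_perfect(self, engine, cds_lib):
        lib, rng = cds_lib
        frag = lib.entries["cds1"][200:350]
        (t,) = find_linc_targets([self._linc(frag, rng)], lib, engine)
        assert t.match_class == "perfect" and t.overlap_nt >= 100

    def test_four_mismatches_in_150_is_near_exact(self, engine, cds_lib):
        lib, rng = cds_lib
        frag = list(lib.entries["cds1"][200:350])
        for p in (30, 60, 90, 120):
            frag[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[p]]
        (t,) = find_linc_targets([self._linc("".join(frag), rng)], lib, engine)
        assert t.match_class == "near_exact"
        assert t.identity_pct == pytest.approx(100 * 146 / 150, abs=0.5)

    def test_eight_mismatches_in_150_is_below_threshold(self, engine, cds_lib):
        lib, rng = cds_lib
        frag = list(lib.entries["cds1"][200:350])
        for p in range(15, 150, 17):
            frag[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[p]]
        assert len(range(15, 150, 17)) == 8
        targets = find_linc_targets([self._linc("".join(frag), rng)], lib, engine)
        # 142/150 = 94.7 % identity: no qualifying target at > 95 %
        assert all(t.identity_pct > 95 for t in targets)
        assert not any(t.match_class == "near_exact" and t.overlap_nt >= 140
                       for t in targets)


class TestLengthStats:
    def test_single_transcript(self):
        assert length_stats([tx("t", [(0, 300)])]) == (300, 300, 300.0)

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            length_stats([])

    def test_planted_length_distribution_recovered(self, default_sim, default_pipeline):
        """Mean lengths of the recovered lncNAT and lincRNA groups sit in
        the configured ranges (201 to 4,179 nt, means a few hundred nt)."""
        ann = default_pipeline.annotation
        for kind in ("lncNAT", "lincRNA"):
            group = [
                ann.get(tid)
                for tid, v in default_pipeline.lnc_verdicts.items()
                if v.lnc_type == kind
            ]
            lo, hi, mean = length_stats(group)
            assert lo >= 200 and hi <= 4_179
            assert 200 < mean < 1_500
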
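import numpy as np
import pytest

from lncraft.curation import (
    CurationParams,
    cluster_monoexonic,
    curate,
    filter_min_length,
    integrate_external,
    merge_duplicate_reference,
    rename_by_class,
)
from lncraft.models import GenomeAnnotation, TranscriptModel


def tx(tid, exons, strand="+", code="reference", gene=None, chrom="chr1"):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene or f"g_{tid}", chrom=chrom,
        strand=strand, exons=exons, class_code=code,
    )


class TestMergeDuplicates:
    def test_identical_chains_collapse_with_aliases(self):
        ann = GenomeAnnotation([
            tx("GRMZM2G000001_T01", [(100, 250)]),
            tx("zma-MIR001_T01", [(100, 250)]),
        ])
        merged, log = merge_duplicate_reference(ann)
        assert len(merged) == 1
        keep = merged.get("GRMZM2G000001_T01")
        assert "zma-MIR001_T01" in keep.aliases
        assert log == [["GRMZM2G000001_T01", "zma-MIR001_T01"]]

    def test_opposite_strands_not_merged(self):
        ann = GenomeAnnotation([
            tx("a", [(100, 250)], "+"), tx("b", [(100, 250)], "-"),
        ])
        merged, log = merge_duplicate_reference(ann)
        assert len(merged) == 2 and log == []

    def test_count_matches_set_based_oracle(self):
        rng = np.random.default_rng(0)
        txs = []
        chains = []
        for i in range(100):
            a = int(rng.integers(0, 10_000))
            chain = [(a, a + int(rng.integers(50, 300)))]
            strand = "+" if rng.random() < 0.5 else "-"
            chains.append(("chr1", strand, tuple(chain)))
            txs.append(tx(f"t{i}", chain, strand))
            if rng.random() < 0.3:  # planted duplicate
                txs.append(tx(f"t{i}_dup", chain, strand))
                chains.append(("chr1", strand, tuple(chain)))
        merged, _ = merge_duplicate_reference(GenomeAnnotation(txs))
        assert len(merged) == len(set(chains))


class TestLengthFilter:
    @pytest.mark.parametrize(
        "length,code,kept",
        [(56, "U", False), (57, "U", True), (56, "J", False),
         (30, "reference", True), (30, "EST", True)],
    )
    def test_57_nt_boundary_and_reference_exemption(self, length, code, kept):
        ann = GenomeAnnotation([tx("t", [(0, length)], code=code)])
        out, removed = filter_min_length(ann, CurationParams())
        assert ("t" in out) is kept
        assert (removed == ["t"]) is not kept

    def test_matches_brute_force_on_random_mix(self):
        rng = np.random.default_rng(1)
        codes = ["reference", "J", "O", "X", "U", "EST"]
        txs = [
            tx(f"t{i}", [(i * 500, i * 500 + int(rng.integers(10, 120)))],
               code=codes[int(rng.integers(0, 6))])
            for i in range(200)
        ]
        out, removed = filter_min_length(GenomeAnnotation(txs), CurationParams())
        expected_removed = {
            t.transcript_id for t in txs
            if t.class_code in ("J", "O", "X", "U") and t.length_nt < 57
        }
        assert set(removed) == expected_removed
        assert len(out) == len(txs) - len(expected_removed)


class TestRename:
    def _locus(self):
        host = tx("GRMZM2G046615_T01", [(1000, 1400), (1600, 2200)],
                  gene="GRMZM2G046615")
        novel = [
            tx(f"CUFF.{i}.1", [(1000 + 10 * i, 1400), (1600, 2200)],
               code="J", gene="GRMZM2G046615")
            for i in range(1, 4)
        ]
        return GenomeAnnotation([host] + novel)

    def test_j_isoforms_numbered_in_genomic_order(self):
        out, id_map = rename_by_class(self._locus())
        assert id_map["CUFF.1.1"] == "GRMZM2G046615_T01_j_1"
        assert id_map["CUFF.3.1"] == "GRMZM2G046615_T01_j_3"

    def test_u_transcripts_get_tcons_ids(self):
        ann = GenomeAnnotation([tx("CUFF.9.1", [(0, 300)], code="U")])
        out, id_map = rename_by_class(ann)
        assert id_map["CUFF.9.1"].startswith("TCONS_")
        assert len(id_map["CUFF.9.1"]) == len("TCONS_00000001")

    def test_renaming_injective_and_idempotent(self):
        out, id_map = rename_by_class(self._locus())
        assert len(set(id_map.values())) == len(id_map)
        again, id_map2 = rename_by_class(out)
        assert all(old == new for old, new in id_map2.items())

    def test_antisense_novel_named_after_opposite_strand_host(self):
        host = tx("GRMZM2G000002_T01", [(0, 500)], "+", gene="GRMZM2G000002")
        x = tx("CUFF.5.1", [(400, 800)], "-", code="X", gene="XLOC_1")
        out, id_map = rename_by_class(GenomeAnnotation([host, x]))
        assert id_map["CUFF.5.1"] == "GRMZM2G000002_T01_X_1"


class TestClusterMonoexonic:
    def u(self, tid, start, end, strand="+"):
        return tx(tid, [(start, end)], strand, code="U")

    @pytest.mark.parametrize("gap,fused", [(499, True), (500, False)])
    def test_500_bp_boundary_is_strict(self, gap, fused):
        ann = GenomeAnnotation([
            self.u("a", 0, 100), self.u("b", 100 + gap, 100 + gap + 80),
        ])
        out, clusters = cluster_monoexonic(ann, CurationParams())
        assert (len(clusters) == 1) is fused
        if fused:
            assert clusters[0].member_ids == ["a", "b"]
            assert clusters[0].fused_interval == (0, 100 + gap + 80)

    def test_chain_of_three_is_transitive(self):
        ann = GenomeAnnotation([
            self.u("a", 0, 100), self.u("b", 200, 300), self.u("c", 400, 500),
        ])
        out, clusters = cluster_monoexonic(ann, CurationParams())
        assert len(clusters) == 1
        assert clusters[0].member_ids == ["a", "b", "c"]
        assert "Cluster_t_1" in out

    def test_strand_and_class_guards(self):
        ann = GenomeAnnotation([
            self.u("a", 0, 100), self.u("b", 150, 250, strand="-"),
            tx("ref", [(300, 380)]),  # reference, never clustered
        ])
        _, clusters = cluster_monoexonic(ann, CurationParams())
        assert clusters == []

    def test_partition_matches_single_linkage_oracle(self):
        """Cluster partition equals brute-force single linkage at the gap
        threshold on random non-overlapping placements."""
        rng = np.random.default_rng(3)
        for trial in range(30):
            txs, pos = [], 0
            for i in range(int(rng.integers(5, 25))):
                pos += int(rng.integers(1, 1_200))
                length = int(rng.integers(60, 200))
                txs.append(self.u(f"u{trial}_{i}", pos, pos + length))
                pos += length
            ann = GenomeAnnotation(txs)
            _, clusters = cluster_monoexonic(ann, CurationParams())
            # union-find over all pairs with gap < 500
            parent = {t.transcript_id: t.transcript_id for t in txs}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for a in txs:
                for b in txs:
                    if a is b:
                        continue
                    gap = max(a.start, b.start) - min(a.end, b.end)
                    if gap < 500:
                        parent[find(a.transcript_id)] = find(b.transcript_id)
            groups = {}
            for t in txs:
                groups.setdefault(find(t.transcript_id), set()).add(t.transcript_id)
            expected = {frozenset(g) for g in groups.values() if len(g) >= 2}
            got = {frozenset(c.member_ids) for c in clusters}
            assert got == expected


class TestIntegrateExternal:
    def test_duplicate_est_dropped_and_novel_added(self):
        ann = GenomeAnnotation([tx("t1", [(0, 300)])])
        est = GenomeAnnotation([
            tx("e_dup", [(0, 300)], code="EST"),
            tx("e_new", [(1_000, 1_400)], code="EST"),
        ])
        out, added = integrate_external(ann, est)
        assert added == ["e_new"]
        assert len(out) == 2

    def test_counts_match_union_minus_duplicates(self):
        rng = np.random.default_rng(4)
        base = [tx(f"t{i}", [(i * 400, i * 400 + 200)]) for i in range(30)]
        ests, est_chains = [], set()
        for i in range(20):
            if rng.random() < 0.4:
                src = base[int(rng.integers(0, 30))]
                chain = src.exons
            else:
                a = 50_000 + i * 500
                chain = [(a, a + 150)]
            ests.append(tx(f"e{i}", chain, code="EST"))
        out, added = integrate_external(GenomeAnnotation(base), GenomeAnnotation(ests))
        base_chains = {t.exon_chain_key() for t in base}
        seen = set(base_chains)
        expected = 0
        for e in ests:
            if e.exon_chain_key() not in seen:
                expected += 1
                seen.add(e.exon_chain_key())
        assert len(added) == expected


class TestFullCuration:
    def test_idempotent_on_own_output(self):
        ann = GenomeAnnotation([
            tx("GRMZM2G000001_T01", [(0, 400)], gene="GRMZM2G000001"),
            tx("dup_of_1", [(0, 400)], gene="dupg"),
            tx("CUFF.1.1", [(0, 350)], code="J", gene="GRMZM2G000001"),
            tx("CUFF.2.1", [(2_000, 2_030)], code="U"),  # short, removed
            tx("CUFF.3.1", [(5_000, 5_100)], code="U"),
            tx("CUFF.4.1", [(5_200, 5_300)], code="U"),  # fuses with above
        ])
        res1 = curate(ann)
        res2 = curate(res1.annotation)
        assert sorted(t.transcript_id for t in res1.annotation) == sorted(
            t.transcript_id for t in res2.annotation
        )
        assert res2.merge_log == [] and res2.removed_short == []
        assert res2.clusters == []

    def test_exon_coordinates_of_survivors_unchanged(self):
        ann = GenomeAnnotation([
            tx("r", [(0, 400), (600, 900)]),
            tx("CUFF.1.1", [(10_000, 10_300)], code="U"),
        ])
        res = curate(ann)
        assert res.annotation.get("r").exons == [(0, 400), (600, 900)]
        new_id = res.id_map["CUFF.1.1"]
        assert res.annotation.get(new_id).exons == [(10_000, 10_300)]
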
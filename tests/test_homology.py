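import numpy as np
import pytest

from lncraft.homology import (
    SearchParams,
    best_hit,
    bit_score,
    e_value,
    exact_match_params,
    protein_match_params,
)
from lncraft.models import SequenceLibrary


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def nt_lib(**entries):
    return SequenceLibrary("lib", "cds", entries)


class TestExactMode:
    def test_full_length_identity(self, engine):
        rng = np.random.default_rng(0)
        s = rand_seq(rng, 200)
        hits = engine.search(s, nt_lib(ref=s), exact_match_params())
        assert len(hits) == 1
        h = hits[0]
        assert h.identity_pct == 100.0
        assert h.aln_len == 200
        assert h.query_coverage_pct == 100.0

    def test_shared_10mer_below_word_size(self, engine):
        rng = np.random.default_rng(1)
        core = rand_seq(rng, 10)
        query = rand_seq(rng, 50) + core + rand_seq(rng, 50)
        subject = rand_seq(rng, 100) + core + rand_seq(rng, 100)
        hits = engine.search(query, nt_lib(s=subject), exact_match_params())
        assert all(h.aln_len >= 16 for h in hits)
        # the planted 10-mer itself can never seed
        assert not any(h.aln_len == 10 for h in hits)

    def test_query_shorter_than_word_warns_and_returns_empty(self, engine):
        with pytest.warns(UserWarning):
            assert engine.search("ACGT", nt_lib(s="ACGTACGTACGTACGTACGT"),
                                 exact_match_params()) == []

    def test_equals_substring_enumeration_oracle(self, engine):
        """Exact mode returns exactly the maximal common substrings of
        length >= word size that pass the E-value cutoff."""
        rng = np.random.default_rng(2)
        for trial in range(20):
            subject = rand_seq(rng, 1_000)
            # embed query fragments in the subject to create real matches
            q_parts = [rand_seq(rng, 30)]
            for _ in range(3):
                a = int(rng.integers(0, 900))
                q_parts.append(subject[a : a + int(rng.integers(16, 80))])
                q_parts.append(rand_seq(rng, 20))
            query = "".join(q_parts)
            lib = nt_lib(s=subject)
            params = exact_match_params()
            got = {
                (h.q_start, h.q_end, h.s_start)
                for h in engine.search(query, lib, params)
            }
            expected = set()
            m, n = len(query), len(subject)
            for i in range(m):
                for j in range(n):
                    if query[i] != subject[j]:
                        continue
                    if i > 0 and j > 0 and query[i - 1] == subject[j - 1]:
                        continue  # not the start of a maximal run
                    k = 0
                    while i + k < m and j + k < n and query[i + k] == subject[j + k]:
                        k += 1
                    if k >= params.word_size:
                        bit = bit_score(k, *params.constants)
                        if e_value(bit, m, n) < params.max_evalue:
                            expected.add((i, i + k, j))
            assert got == expected


class TestAnyIdentityMode:
    def test_equals_diagonal_segment_oracle(self, engine):
        """Hit set equals a brute-force enumeration of optimal ungapped
        segments per seeded diagonal on the same +1/-2 scoring."""
        rng = np.random.default_rng(3)
        params = SearchParams(word_size=16, max_evalue=0.01)
        for trial in range(15):
            subject = rand_seq(rng, 800)
            a = int(rng.integers(0, 500))
            planted = list(subject[a : a + 120])
            for p in rng.integers(20, 100, 4):  # a few interior mismatches
                planted[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[planted[p]]
            query = rand_seq(rng, 30) + "".join(planted) + rand_seq(rng, 30)
            lib = nt_lib(s=subject)
            hits = engine.search(query, lib, params)
            got = {(h.q_start - h.s_start, h.raw_score) for h in hits}
            m, n = len(query), len(subject)
            # every reported segment must really have its claimed score
            for h in hits:
                s = sum(
                    1 if query[i] == subject[i - (h.q_start - h.s_start)] else -2
                    for i in range(h.q_start, h.q_end)
                )
                assert s == h.raw_score
            expected = set()
            for diag in range(-(n - 1), m):
                q0, q1 = max(0, diag), min(m, n + diag)
                if q1 - q0 < params.word_size:
                    continue
                vals = [1 if query[i] == subject[i - diag] else -2
                        for i in range(q0, q1)]
                # brute-force best segment over all (start, end) pairs
                best = (0, None, None)
                for i in range(len(vals)):
                    acc = 0
                    for j in range(i, len(vals)):
                        acc += vals[j]
                        if acc > best[0]:
                            best = (acc, i, j + 1)
                raw, i, j = best
                if i is None:
                    continue
                run = ok = 0
                for p in range(i, j):
                    run = run + 1 if vals[p] == 1 else 0
                    if run >= params.word_size:
                        ok = 1
                        break
                if not ok:
                    continue
                bit = bit_score(raw, *params.constants)
                if e_value(bit, m, n) < params.max_evalue:
                    expected.add((diag, raw))
            assert got == expected


class TestStatistics:
    def test_evalue_decreases_with_raw_score(self):
        params = SearchParams()
        lam, k = params.constants
        es = [e_value(bit_score(s, lam, k), 500, 50_000) for s in range(20, 200, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_doubling_library_doubles_evalue(self):
        lam, k = SearchParams().constants
        bit = bit_score(50, lam, k)
        assert e_value(bit, 500, 100_000) == pytest.approx(
            2 * e_value(bit, 500, 50_000)
        )

    def test_hc_threshold_scale(self):
        """~270 exact matches sit at the HC bit cutoff under the pinned
        nucleotide constants."""
        lam, k = SearchParams().constants
        assert bit_score(270, lam, k) < 500 < bit_score(271, lam, k)


class TestBestHit:
    def test_empty(self):
        assert best_hit([]) is None

    def test_highest_bit_then_aln_len_then_subject(self, engine):
        from lncraft.homology import HomologyHit

        def hit(sid, bit, aln):
            return HomologyHit("q", sid, 0, aln, 0, aln, 100.0, aln, aln, bit,
                               1e-5, 50.0)

        hits = [hit("b", 520.0, 100), hit("a", 410.0, 300)]
        assert best_hit(hits).subject_id == "b"
        tied = [hit("z", 500.0, 200), hit("a", 500.0, 100), hit("m", 500.0, 200)]
        # exhaustive comparator: max by (bit, aln_len, -lex subject)
        expected = sorted(tied, key=lambda h: (-h.bit_score, -h.aln_len, h.subject_id))[0]
        assert best_hit(tied) is expected


class TestTranslatedSearch:
    def test_planted_orf_peptide_matches_library(self, engine):
        rng = np.random.default_rng(5)
        codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                  if a + b + c not in ("TAA", "TAG", "TGA", "ATG")]
        cds = "ATG" + "".join(codons[i] for i in rng.integers(0, len(codons), 80)) + "TAA"
        from Bio.Seq import Seq

        protein = str(Seq(cds[:-3]).translate())
        lib = SequenceLibrary("prot", "protein", {"p1": protein})
        hits = engine.search_translated(cds, lib, protein_match_params(), frames=(1,))
        assert hits and hits[0].identity_pct == 100.0

    def test_empty_protein_library(self, engine):
        assert engine.search_translated(
            "ATGAAATTTGGGCCC", SequenceLibrary("prot", "protein", {}),
            protein_match_params(), frames=(1,),
        ) == []

    def test_non_nucleotide_characters_rejected(self, engine):
        with pytest.raises(ValueError):
            engine.search_translated(
                "ATGXXT", SequenceLibrary("prot", "protein", {"p": "MKL"}),
                protein_match_params(),
            )

    def test_null_evalue_calibration(self, engine):
        """Random peptides vs a shuffled library: the fraction of queries
        with any E < 0.01 hit stays near the null expectation (well under
        a few per cent)."""
        rng = np.random.default_rng(11)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        lib = SequenceLibrary(
            "prot", "protein",
            {f"p{i}": "".join(aas[j] for j in rng.integers(0, 20, 200))
             for i in range(30)},
        )
        params = SearchParams(word_size=4, max_evalue=0.01, mode="translated-query")
        n_hit = sum(
            bool(engine.search_peptide(
                "".join(aas[j] for j in rng.integers(0, 20, 60)), lib, params))
            for _ in range(200)
        )
        assert n_hit / 200 <= 0.03
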
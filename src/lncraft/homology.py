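"""Seed-and-extend local similarity search with Karlin–Altschul statistics.

The pipeline's three homology steps (smallRNA/TE matching of candidate
lncRNAs, lincRNA target search against coding CDSs, and protein matching of
predicted ORF peptides) all run through this engine, so no external aligner
is needed. Two nucleotide modes are provided:

* exact mode (``min_identity_pct == 100``): every hit is a *maximal* common
  substring of query and subject of length >= ``word_size`` (seeded by
  hashed ``word_size``-mers and extended while bases match), mirroring a
  100 %-identity blastn restriction;
* any-identity mode: for each (subject, diagonal) holding at least one
  exact ``word_size``-mer seed, the optimal ungapped segment on that
  diagonal is found under match/mismatch scoring.

Translated mode seeds exact amino-acid words and extends ungapped under
BLOSUM62.

Scores are normalised to bit scores ``S' = (lambda*S - ln K) / ln 2`` and
E-values ``E = m * n * 2**(-S')`` with ``m`` the query length and ``n`` the
summed library length. Search is on the query strand as given (sense);
reverse-strand homology is the caller's concern.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .models import SequenceLibrary

# Pinned ungapped Karlin-Altschul constants: nucleotide +1/-2, BLOSUM62.
NT_LAMBDA, NT_K = 1.28, 0.46
AA_LAMBDA, AA_K = 0.3176, 0.134

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class SearchParams:
    """Thresholds and scoring for one search.

    ``gap_open``/``gap_extend`` are carried for interface completeness; the
    engine extends ungapped (see package methods note).
    """

    word_size: int = 16
    min_identity_pct: float = 0.0
    max_evalue: float = 10.0
    min_aln_len: Optional[int] = None
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    mode: str = "nucleotide"  # nucleotide | translated-query
    ka_lambda: Optional[float] = None
    ka_k: Optional[float] = None

    def __post_init__(self) -> None:
        if self.word_size < 2:
            raise ValueError("word_size too small")
        if self.min_aln_len is not None and self.word_size > self.min_aln_len:
            raise ValueError("word_size must be <= min_aln_len")
        if self.mode not in ("nucleotide", "translated-query"):
            raise ValueError(f"bad mode {self.mode!r}")

    @property
    def constants(self) -> Tuple[float, float]:
        lam = self.ka_lambda if self.ka_lambda is not None else (
            AA_LAMBDA if self.mode == "translated-query" else NT_LAMBDA
        )
        k = self.ka_k if self.ka_k is not None else (
            AA_K if self.mode == "translated-query" else NT_K
        )
        return lam, k


@dataclass
class HomologyHit:
    """One ungapped local alignment between a query and a library entry."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identity_pct: float
    aln_len: int
    raw_score: int
    bit_score: float
    e_value: float
    query_coverage_pct: float
    mismatches: int = 0
    frame: int = 0  # translated-query hits: query frame (+1..+3)


def bit_score(raw_score: float, lam: float, k: float) -> float:
    return (lam * raw_score - math.log(k)) / math.log(2)


def e_value(bit: float, query_len: int, library_len: int) -> float:
    return query_len * library_len * 2.0 ** (-bit)


def _sort_hits(hits: List[HomologyHit]) -> List[HomologyHit]:
    return sorted(
        hits, key=lambda h: (-h.bit_score, h.subject_id, h.q_start, h.s_start)
    )


class HomologyEngine:
    """Stateless search front-end with per-library word-index caching."""

    def __init__(self) -> None:
        self._index_cache: Dict[Tuple[int, int], Dict[str, List[Tuple[str, int]]]] = {}

    # ------------------------------------------------------------------ index
    def _index(self, library: SequenceLibrary, word: int):
        key = (id(library), word)
        idx = self._index_cache.get(key)
        if idx is None:
            idx = {}
            for sid, seq in library.entries.items():
                for i in range(len(seq) - word + 1):
                    idx.setdefault(seq[i : i + word], []).append((sid, i))
            self._index_cache[key] = idx
        return idx

    # ----------------------------------------------------------------- search
    def search(
        self,
        query: str,
        library: SequenceLibrary,
        params: SearchParams,
        query_id: str = "query",
    ) -> List[HomologyHit]:
        """Nucleotide search of ``query`` against every library entry.

        Returns hits passing all thresholds in ``params``, sorted by
        descending bit score then subject id. A query shorter than the word
        size yields an empty list with a warning.
        """
        query = query.upper()
        m = len(query)
        if m < params.word_size:
            warnings.warn(
                f"query {query_id!r} shorter than word size; no search performed"
            )
            return []
        if not library.entries:
            return []
        n_total = library.total_length
        lam, k = params.constants
        idx = self._index(library, params.word_size)
        exact = params.min_identity_pct >= 100.0

        seen_runs = set()
        seen_diags = set()
        hits: List[HomologyHit] = []
        for qpos in range(m - params.word_size + 1):
            word = query[qpos : qpos + params.word_size]
            for sid, spos in idx.get(word, ()):
                if exact:
                    run = self._extend_exact(query, library.entries[sid], qpos, spos)
                    if run in seen_runs:
                        continue
                    seen_runs.add(run)
                    qs, qe, ss = run
                    length = qe - qs
                    hit = self._make_hit(
                        query_id, sid, qs, qe, ss, ss + length, length, 0,
                        length * params.match, m, n_total, lam, k,
                    )
                    hits.append(hit)
                else:
                    diag_key = (sid, qpos - spos)
                    if diag_key in seen_diags:
                        continue
                    seen_diags.add(diag_key)
                    hit = self._best_diagonal_segment(
                        query, library.entries[sid], qpos - spos,
                        params, query_id, sid, m, n_total, lam, k,
                    )
                    if hit is not None:
                        hits.append(hit)
        return _sort_hits([h for h in hits if self._passes(h, params)])

    @staticmethod
    def _extend_exact(q: str, s: str, qpos: int, spos: int) -> Tuple[int, int, int]:
        """Maximal identical run through the seed at (qpos, spos)."""
        a, b = qpos, spos
        while a > 0 and b > 0 and q[a - 1] == s[b - 1]:
            a -= 1
            b -= 1
        c, d = qpos, spos
        n_q, n_s = len(q), len(s)
        while c < n_q and d < n_s and q[c] == s[d]:
            c += 1
            d += 1
        return (a, c, b)

    def _best_diagonal_segment(
        self, q, s, diag, params, query_id, sid, m, n_total, lam, k
    ) -> Optional[HomologyHit]:
        """Optimal ungapped segment on one diagonal (Kadane over +match/
        -mismatch values), reported only if it contains a full word seed."""
        # overlap of the diagonal with both sequences
        q0 = max(0, diag)
        q1 = min(len(q), len(s) + diag)
        if q1 - q0 < params.word_size:
            return None
        best = (0, -1, -1)  # score, start, end (query coords, half-open)
        score, start = 0, q0
        for i in range(q0, q1):
            val = params.match if q[i] == s[i - diag] else params.mismatch
            if score <= 0:
                score, start = val, i
            else:
                score += val
            if score > best[0]:
                best = (score, start, i + 1)
        raw, qs, qe = best
        if qe <= qs:
            return None
        # require an exact word-size run inside the segment (the seed)
        run = 0
        ok = False
        for i in range(qs, qe):
            run = run + 1 if q[i] == s[i - diag] else 0
            if run >= params.word_size:
                ok = True
                break
        if not ok:
            return None
        length = qe - qs
        matches = sum(1 for i in range(qs, qe) if q[i] == s[i - diag])
        return self._make_hit(
            query_id, sid, qs, qe, qs - diag, qe - diag, length,
            length - matches, raw, m, n_total, lam, k,
        )

    @staticmethod
    def _make_hit(
        query_id, sid, qs, qe, ss, se, length, mismatches, raw, m, n_total, lam, k,
        frame=0,
    ) -> HomologyHit:
        bit = bit_score(raw, lam, k)
        return HomologyHit(
            query_id=query_id,
            subject_id=sid,
            q_start=qs,
            q_end=qe,
            s_start=ss,
            s_end=se,
            identity_pct=100.0 * (length - mismatches) / length,
            aln_len=length,
            raw_score=raw,
            bit_score=bit,
            e_value=e_value(bit, m, n_total),
            query_coverage_pct=100.0 * (qe - qs) / m,
            mismatches=mismatches,
            frame=frame,
        )

    @staticmethod
    def _passes(hit: HomologyHit, params: SearchParams) -> bool:
        if hit.identity_pct < params.min_identity_pct - 1e-9:
            return False
        if hit.e_value >= params.max_evalue:
            return False
        if params.min_aln_len is not None and hit.aln_len < params.min_aln_len:
            return False
        return True

    # ----------------------------------------------------- translated search
    def search_translated(
        self,
        query: str,
        protein_library: SequenceLibrary,
        params: SearchParams,
        frames: Sequence[int] = (1, 2, 3),
        query_id: str = "query",
    ) -> List[HomologyHit]:
        """Translate ``query`` in the given (+) frames and search each
        peptide against a protein library under BLOSUM62."""
        if params.mode != "translated-query":
            raise ValueError("search_translated requires mode='translated-query'")
        query = query.upper()
        bad = set(query) - set("ACGTN")
        if bad:
            raise ValueError(f"non-nucleotide characters in query: {sorted(bad)}")
        hits: List[HomologyHit] = []
        for frame in frames:
            if frame not in (1, 2, 3):
                raise ValueError("translated search supports sense frames 1..3")
            sub = query[frame - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) < 3:
                continue
            peptide = str(Seq(sub).translate())  # stops stay as '*'; never seed
            hits.extend(
                self.search_peptide(peptide, protein_library, params, query_id, frame)
            )
        return _sort_hits(hits)

    def search_peptide(
        self,
        peptide: str,
        protein_library: SequenceLibrary,
        params: SearchParams,
        query_id: str = "query",
        frame: int = 1,
    ) -> List[HomologyHit]:
        """Ungapped BLOSUM62 search of one peptide (exact word seeds)."""
        m = len(peptide)
        if m < params.word_size:
            warnings.warn(f"peptide {query_id!r} shorter than word size; skipped")
            return []
        if not protein_library.entries:
            return []
        lam, k = params.constants
        n_total = protein_library.total_length
        idx = self._index(protein_library, params.word_size)
        seen = set()
        hits: List[HomologyHit] = []
        for qpos in range(m - params.word_size + 1):
            for sid, spos in idx.get(peptide[qpos : qpos + params.word_size], ()):
                key = (sid, qpos - spos)
                if key in seen:
                    continue
                seen.add(key)
                hit = self._best_blosum_segment(
                    peptide, protein_library.entries[sid], qpos - spos,
                    params, query_id, sid, m, n_total, lam, k, frame,
                )
                if hit is not None and self._passes(hit, params):
                    hits.append(hit)
        return _sort_hits(hits)

    def _best_blosum_segment(
        self, q, s, diag, params, query_id, sid, m, n_total, lam, k, frame
    ) -> Optional[HomologyHit]:
        q0 = max(0, diag)
        q1 = min(len(q), len(s) + diag)
        if q1 - q0 < params.word_size:
            return None
        best = (0.0, -1, -1)
        score, start = 0.0, q0
        for i in range(q0, q1):
            try:
                val = _BLOSUM62[q[i]][s[i - diag]]
            except (KeyError, IndexError):
                val = -4.0
            if score <= 0:
                score, start = val, i
            else:
                score += val
            if score > best[0]:
                best = (score, start, i + 1)
        raw, qs, qe = best
        if qe <= qs or raw <= 0:
            return None
        # seed requirement: exact word inside segment
        run, ok = 0, False
        for i in range(qs, qe):
            run = run + 1 if q[i] == s[i - diag] else 0
            if run >= params.word_size:
                ok = True
                break
        if not ok:
            return None
        length = qe - qs
        mismatches = sum(1 for i in range(qs, qe) if q[i] != s[i - diag])
        return self._make_hit(
            query_id, sid, qs, qe, qs - diag, qe - diag, length,
            mismatches, raw, m, n_total, lam, k, frame,
        )


def best_hit(hits: Sequence[HomologyHit]) -> Optional[HomologyHit]:
    """Deterministic best hit: highest bit score, ties by larger aln_len,
    then lexicographically smallest subject id."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.bit_score, -h.aln_len, h.subject_id))


def hits_to_tabular(hits: Sequence[HomologyHit]) -> List[str]:
    """BLAST outfmt-6-style rows (1-based closed subject/query coords)."""
    rows = []
    for h in hits:
        rows.append(
            "\t".join(
                str(x)
                for x in (
                    h.query_id, h.subject_id, f"{h.identity_pct:.2f}", h.aln_len,
                    h.mismatches, 0, h.q_start + 1, h.q_end, h.s_start + 1,
                    h.s_end, f"{h.e_value:.2g}", f"{h.bit_score:.1f}",
                )
            )
        )
    return rows


# default parameter sets used by the classification stages
def exact_match_params() -> SearchParams:
    """blastn-style: word 16, 100 % identity, E < 0.01."""
    return SearchParams(word_size=16, min_identity_pct=100.0, max_evalue=0.01)


def linc_target_params() -> SearchParams:
    """lincRNA target search: >95 % identity, overlap >= 100 bp."""
    return SearchParams(
        word_size=12, min_identity_pct=95.0, max_evalue=0.01, min_aln_len=100
    )


def protein_match_params() -> SearchParams:
    """Translated ORF-peptide search (pinned default E < 1e-3)."""
    return SearchParams(word_size=4, max_evalue=1e-3, mode="translated-query")


def te_search_params() -> SearchParams:
    """Any-identity TE best-hit search (blastn-like default E cutoff)."""
    return SearchParams(word_size=16, max_evalue=10.0)
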
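"""Subclassification of potential lncRNAs.

A pot-lncRNA is first screened by exact homology (word 16, 100 % identity,
E < 0.01) against a smallRNA-precursor library and then a TE library: a
smallRNA match makes it a siRNA precursor, a TE match a TE-derived
transcript, anything else a "truly" lncRNA. Truly lncRNAs split into
lncNATs (a contiguous exonic overlap of >= 10 nt with an opposite-strand
transcript of another gene) and lincRNAs; lncNATs are typed by partner
(coding mRNA / lncNAT / siRNA precursor) and lincRNAs are searched against
coding CDSs for perfect (100 % identity, >= 100 bp) or near-exact (> 95 %
identity) targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .coding import CodingVerdict
from .homology import (
    HomologyEngine,
    SearchParams,
    exact_match_params,
    linc_target_params,
)
from .models import GenomeAnnotation, SequenceLibrary, TranscriptModel


@dataclass
class LncVerdict:
    transcript_id: str
    subcategory: str  # siRNA_precursor | TE_derived | lncRNA
    lnc_type: Optional[str] = None  # lncNAT | lincRNA (subcategory == lncRNA)
    evidence: List[str] = field(default_factory=list)


@dataclass
class NatPair:
    lncnat_id: str
    partner_id: str
    partner_kind: str  # coding_mRNA | lncNAT | siRNA_precursor
    overlap_nt: int


@dataclass
class LincTarget:
    lincrna_id: str
    target_transcript_id: str
    match_class: str  # perfect | near_exact
    identity_pct: float
    overlap_nt: int


def match_noncoding_dbs(
    transcript: TranscriptModel,
    smallrna_db: SequenceLibrary,
    te_db: SequenceLibrary,
    engine: HomologyEngine,
    params: Optional[SearchParams] = None,
    smallrna_first: bool = True,
) -> LncVerdict:
    """Exact-homology screen of one pot-lncRNA; smallRNA matches take
    precedence over TE matches (configurable), keeping the categories
    disjoint."""
    if transcript.sequence is None:
        raise ValueError(f"transcript {transcript.transcript_id} has no sequence")
    params = params or exact_match_params()
    order = (
        [(smallrna_db, "siRNA_precursor"), (te_db, "TE_derived")]
        if smallrna_first
        else [(te_db, "TE_derived"), (smallrna_db, "siRNA_precursor")]
    )
    for db, label in order:
        hits = engine.search(
            transcript.sequence, db, params, query_id=transcript.transcript_id
        )
        if hits:
            return LncVerdict(
                transcript.transcript_id,
                label,
                evidence=sorted({h.subject_id for h in hits}),
            )
    return LncVerdict(transcript.transcript_id, "lncRNA")


def antisense_overlaps(
    lnc: TranscriptModel,
    annotation: GenomeAnnotation,
    min_overlap: int = 10,
) -> List[Tuple[str, int]]:
    """Qualifying antisense partners: transcripts of *another* gene on the
    opposite strand with a contiguous exon-to-exon genomic overlap of at
    least ``min_overlap`` nt. Returns (partner_id, longest qualifying
    overlap) sorted by id."""
    if lnc.strand not in ("+", "-"):
        warnings.warn(
            f"transcript {lnc.transcript_id} has unknown strand; "
            "excluded from antisense classification"
        )
        return []
    other_strand = "-" if lnc.strand == "+" else "+"
    best: Dict[str, int] = {}
    for a, b in lnc.exons:
        for tid in annotation.overlapping_exons(lnc.chrom, other_strand, a, b):
            partner = annotation.get(tid)
            if partner.gene_id == lnc.gene_id or tid == lnc.transcript_id:
                continue
            for c, d in partner.exons:
                ov = min(b, d) - max(a, c)
                if ov >= min_overlap:
                    best[tid] = max(best.get(tid, 0), ov)
    return sorted(best.items())


def classify_nat_vs_linc(
    lnc: TranscriptModel,
    annotation: GenomeAnnotation,
    min_overlap: int = 10,
) -> Tuple[str, List[Tuple[str, int]]]:
    """lncNAT if any qualifying antisense partner exists, else lincRNA."""
    partners = antisense_overlaps(lnc, annotation, min_overlap)
    return ("lncNAT" if partners else "lincRNA"), partners


def build_nat_pairs(
    lncnat_partners: Dict[str, List[Tuple[str, int]]],
    coding_verdicts: Dict[str, CodingVerdict],
    lnc_verdicts: Dict[str, LncVerdict],
) -> List[NatPair]:
    """One pair per (lncNAT, qualifying partner), typed by the partner's
    own verdict; lncNAT-lncNAT pairs are deduplicated as unordered pairs.
    Partners outside the coding/lncNAT/siRNA-precursor typology are
    dropped."""
    pairs: List[NatPair] = []
    seen_nat_nat = set()
    for lnc_id in sorted(lncnat_partners):
        for partner_id, overlap in lncnat_partners[lnc_id]:
            cv = coding_verdicts.get(partner_id)
            lv = lnc_verdicts.get(partner_id)
            if cv is not None and cv.category == "coding":
                kind = "coding_mRNA"
            elif lv is not None and lv.subcategory == "siRNA_precursor":
                kind = "siRNA_precursor"
            elif lv is not None and lv.lnc_type == "lncNAT":
                kind = "lncNAT"
                key = frozenset((lnc_id, partner_id))
                if key in seen_nat_nat:
                    continue
                seen_nat_nat.add(key)
            else:
                continue
            pairs.append(NatPair(lnc_id, partner_id, kind, overlap))
    return pairs


def find_linc_targets(
    lincrnas: Sequence[TranscriptModel],
    cds_lib: SequenceLibrary,
    engine: HomologyEngine,
    params: Optional[SearchParams] = None,
) -> List[LincTarget]:
    """CDS-homology targets of lincRNAs.

    Hits with >= 100 nt overlap are split into perfect (100 % identity) and
    near-exact (> 95 %); a lincRNA with any perfect hit is counted perfect
    only, and each lincRNA contributes at most one target record per
    class per subject."""
    params = params or linc_target_params()
    out: List[LincTarget] = []
    for lnc in sorted(lincrnas, key=lambda t: t.transcript_id):
        if lnc.sequence is None:
            raise ValueError(f"lincRNA {lnc.transcript_id} has no sequence")
        hits = engine.search(lnc.sequence, cds_lib, params, query_id=lnc.transcript_id)
        perfect = [h for h in hits if h.identity_pct >= 100.0 - 1e-9]
        near = [h for h in hits if 95.0 < h.identity_pct < 100.0 - 1e-9]
        chosen = perfect if perfect else near
        cls = "perfect" if perfect else "near_exact"
        seen = set()
        for h in chosen:
            if h.subject_id in seen:
                continue
            seen.add(h.subject_id)
            out.append(
                LincTarget(
                    lincrna_id=lnc.transcript_id,
                    target_transcript_id=h.subject_id,
                    match_class=cls,
                    identity_pct=h.identity_pct,
                    overlap_nt=h.aln_len,
                )
            )
    return out


def length_stats(group: Sequence[TranscriptModel]) -> Tuple[int, int, float]:
    """(min, max, mean) spliced length of a non-empty transcript group."""
    if not group:
        raise ValueError("empty transcript group")
    lengths = [tx.length_nt for tx in group]
    return min(lengths), max(lengths), sum(lengths) / len(lengths)


def classify_lnc_all(
    pot_lnc: Sequence[TranscriptModel],
    annotation: GenomeAnnotation,
    smallrna_db: SequenceLibrary,
    te_db: SequenceLibrary,
    engine: HomologyEngine,
    min_overlap: int = 10,
    params: Optional[SearchParams] = None,
) -> Tuple[Dict[str, LncVerdict], Dict[str, List[Tuple[str, int]]]]:
    """Full subclassification of a pot-lncRNA set; returns verdicts and the
    antisense partner map of the lncNATs."""
    verdicts: Dict[str, LncVerdict] = {}
    nat_partners: Dict[str, List[Tuple[str, int]]] = {}
    for tx in sorted(pot_lnc, key=lambda t: t.transcript_id):
        v = match_noncoding_dbs(tx, smallrna_db, te_db, engine, params)
        if v.subcategory == "lncRNA":
            lnc_type, partners = classify_nat_vs_linc(tx, annotation, min_overlap)
            v.lnc_type = lnc_type
            if lnc_type == "lncNAT":
                nat_partners[tx.transcript_id] = partners
                v.evidence = [p for p, _ in partners]
        verdicts[tx.transcript_id] = v
    return verdicts, nat_partners
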
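"""ORF discovery and the three-criterion coding vs pot-lncRNA decision.

A transcript is a *potential* long non-coding RNA when (i) it is at least
200 nt long, (ii) it carries no open reading frame of 120 amino acids or
more, and (iii) if it has any ORF, the predicted peptide of its longest ORF
matches no protein in the supplied library. Everything else lands in the
coding bucket, so the two categories partition the transcriptome.

An ORF runs from an ATG to the first in-frame stop codon (stop included in
the nucleotide span, excluded from ``aa_length``); an ATG with no downstream
in-frame stop yields a 3'-partial ORF (``partial=True``), which counts
toward the long-ORF criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Seq import Seq

from .homology import HomologyEngine, SearchParams, protein_match_params
from .models import GenomeAnnotation, SequenceLibrary, TranscriptModel

STOPS = {"TAA", "TAG", "TGA"}
_VALID = set("ACGTN")


@dataclass
class OrfCall:
    """One open reading frame in transcript coordinates.

    For negative frames the coordinates refer to the reverse complement of
    the input sequence. ``aa_length`` excludes the stop codon.
    """

    frame: int  # +1,+2,+3,-1,-2,-3
    start: int
    end: int  # half-open, includes the stop codon when complete
    aa_length: int
    peptide: str
    partial: bool = False


@dataclass
class CodingVerdict:
    transcript_id: str
    category: str  # coding | pot_lncRNA
    reason: str  # long_orf | protein_match | short_transcript | passes_lnc_criteria
    longest_orf: Optional[OrfCall] = None


def find_orfs(
    sequence: str,
    frames: Sequence[int] = (1, 2, 3),
    include_partial: bool = True,
) -> List[OrfCall]:
    """All ATG -> first-in-frame-stop ORFs per requested frame, sorted by
    descending amino-acid length (ties by frame then start)."""
    sequence = sequence.upper()
    bad = set(sequence) - _VALID
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one codon")
    calls: List[OrfCall] = []
    rc = str(Seq(sequence).reverse_complement())
    for frame in frames:
        if frame not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"bad frame {frame}")
        seq = sequence if frame > 0 else rc
        off = abs(frame) - 1
        # first in-frame stop at or after each codon index, scanned right to left
        codons = [seq[i : i + 3] for i in range(off, len(seq) - 2, 3)]
        next_stop: List[Optional[int]] = [None] * len(codons)
        last = None
        for ci in range(len(codons) - 1, -1, -1):
            if codons[ci] in STOPS:
                last = ci
            next_stop[ci] = last
        for ci, codon in enumerate(codons):
            if codon != "ATG":
                continue
            stop = next_stop[ci]
            start = off + 3 * ci
            if stop is not None:
                end = off + 3 * (stop + 1)
                aa = stop - ci
                pep = str(Seq(seq[start : end - 3]).translate())
                calls.append(OrfCall(frame, start, end, aa, pep, partial=False))
            elif include_partial:
                end = off + 3 * len(codons)
                if end <= start:
                    continue
                aa = (end - start) // 3
                pep = str(Seq(seq[start:end]).translate())
                calls.append(OrfCall(frame, start, end, aa, pep, partial=True))
    calls.sort(key=lambda o: (-o.aa_length, abs(o.frame), o.frame < 0, o.start))
    return calls


def longest_orf(
    sequence: str, frames: Sequence[int] = (1, 2, 3)
) -> Optional[OrfCall]:
    calls = find_orfs(sequence, frames)
    return calls[0] if calls else None


@dataclass
class CodingParams:
    min_lnc_len: int = 200
    orf_aa_max: int = 120  # ORFs of this many aa or more mean coding
    frames: Tuple[int, ...] = (1, 2, 3)
    protein_params: SearchParams = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.protein_params is None:
            self.protein_params = protein_match_params()


def classify_coding(
    transcript: TranscriptModel,
    protein_db: SequenceLibrary,
    engine: HomologyEngine,
    params: Optional[CodingParams] = None,
) -> CodingVerdict:
    """Apply the decision tree to one transcript (sequence required)."""
    params = params or CodingParams()
    if transcript.sequence is None:
        raise ValueError(f"transcript {transcript.transcript_id} has no sequence")
    orfs = find_orfs(transcript.sequence, params.frames)
    top = orfs[0] if orfs else None
    if top is not None and top.aa_length >= params.orf_aa_max:
        return CodingVerdict(transcript.transcript_id, "coding", "long_orf", top)
    if transcript.length_nt < params.min_lnc_len:
        return CodingVerdict(
            transcript.transcript_id, "coding", "short_transcript", top
        )
    if top is not None and top.aa_length >= params.protein_params.word_size:
        hits = engine.search_peptide(
            top.peptide, protein_db, params.protein_params,
            query_id=transcript.transcript_id,
        )
        if hits:
            return CodingVerdict(
                transcript.transcript_id, "coding", "protein_match", top
            )
    return CodingVerdict(
        transcript.transcript_id, "pot_lncRNA", "passes_lnc_criteria", top
    )


def classify_all(
    annotation: GenomeAnnotation,
    protein_db: SequenceLibrary,
    engine: HomologyEngine,
    params: Optional[CodingParams] = None,
) -> Tuple[Dict[str, CodingVerdict], Dict[str, Dict[str, int]]]:
    """One verdict per transcript plus per-class-code coding/pot-lncRNA
    counts (the two-way split behind the classification summary table)."""
    params = params or CodingParams()
    verdicts: Dict[str, CodingVerdict] = {}
    summary: Dict[str, Dict[str, int]] = {}
    for tx in annotation.sorted_transcripts():
        v = classify_coding(tx, protein_db, engine, params)
        verdicts[tx.transcript_id] = v
        row = summary.setdefault(tx.class_code, {"coding": 0, "pot_lncRNA": 0})
        row[v.category] += 1
    return verdicts, summary
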
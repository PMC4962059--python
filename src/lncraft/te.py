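"""Best-hit TE classification with the HC/PR dual-threshold scheme.

Every transcript is searched against a curated full-length TE library; its
best hit (highest bit score) decides the confidence class:

* HC (high-confidence TE): bit score > 500 AND query coverage > 50 %;
* PR (putative/relic TE): not HC, and bit score > 250 OR coverage > 30 %;
* none otherwise.

Coverage is *query* coverage — the fraction of the transcript covered by
the alignment — since the question asked is how much of a transcript is
TE-derived. All thresholds are strict, and every HC-qualifying hit also
satisfies the PR clause, so precedence (HC first) keeps the classes
disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .homology import HomologyEngine, HomologyHit, SearchParams, best_hit, te_search_params
from .models import GenomeAnnotation, SequenceLibrary, TranscriptModel
from .reporting import round_half_up

HC_MIN_BIT = 500.0
HC_MIN_COVERAGE = 50.0
PR_MIN_BIT = 250.0
PR_MIN_COVERAGE = 30.0

# canonical superfamily ordering for reports
SUPERFAMILY_ORDER = (
    "RLG", "RLC", "RLX", "RIL", "DTA", "DTC", "DHH", "DTM", "DTH", "DTT", "RST",
)


@dataclass
class TEAnnotation:
    transcript_id: str
    hit: Optional[HomologyHit]
    confidence: str  # HC | PR | none
    family: str = ""
    superfamily: str = ""


def confidence_for(bit_score: float, query_coverage_pct: float) -> str:
    """HC/PR/none decision for one best hit (strict thresholds, HC first)."""
    if bit_score > HC_MIN_BIT and query_coverage_pct > HC_MIN_COVERAGE:
        return "HC"
    if bit_score > PR_MIN_BIT or query_coverage_pct > PR_MIN_COVERAGE:
        return "PR"
    return "none"


def _confidence(hit: Optional[HomologyHit]) -> str:
    if hit is None:
        return "none"
    return confidence_for(hit.bit_score, hit.query_coverage_pct)


def classify_te(
    transcript: TranscriptModel,
    te_db: SequenceLibrary,
    engine: HomologyEngine,
    params: Optional[SearchParams] = None,
) -> TEAnnotation:
    """Best-hit TE classification of one transcript."""
    if transcript.sequence is None:
        raise ValueError(f"transcript {transcript.transcript_id} has no sequence")
    params = params or te_search_params()
    hits = engine.search(
        transcript.sequence, te_db, params, query_id=transcript.transcript_id
    )
    top = best_hit(hits)
    conf = _confidence(top)
    family = superfamily = ""
    if top is not None and conf != "none":
        family, superfamily = te_db.te_meta[top.subject_id]
    return TEAnnotation(transcript.transcript_id, top, conf, family, superfamily)


def classify_te_all(
    annotation: GenomeAnnotation,
    te_db: SequenceLibrary,
    engine: HomologyEngine,
    params: Optional[SearchParams] = None,
) -> Dict[str, TEAnnotation]:
    return {
        tx.transcript_id: classify_te(tx, te_db, engine, params)
        for tx in annotation.sorted_transcripts()
    }


def te_fraction(
    te_annotations: Dict[str, TEAnnotation], id_subset: Sequence[str]
) -> Tuple[int, float]:
    """(count, percent to 1 dp) of TE-related transcripts in a subset."""
    if not id_subset:
        raise ValueError("empty id subset")
    missing = [i for i in id_subset if i not in te_annotations]
    if missing:
        raise ValueError(f"ids not TE-annotated: {missing[:3]}")
    count = sum(1 for i in id_subset if te_annotations[i].confidence != "none")
    return count, round_half_up(100.0 * count / len(id_subset), 1)


def superfamily_table(
    te_annotations: Dict[str, TEAnnotation], id_subset: Sequence[str]
) -> pd.DataFrame:
    """Per-superfamily counts and percentages of the TE-related transcripts
    in a subset, rows in the canonical superfamily order."""
    te_ids = [i for i in id_subset if te_annotations[i].confidence != "none"]
    counts: Dict[str, int] = {}
    for i in te_ids:
        sf = te_annotations[i].superfamily
        counts[sf] = counts.get(sf, 0) + 1
    order = list(SUPERFAMILY_ORDER) + sorted(
        set(counts) - set(SUPERFAMILY_ORDER)
    )
    rows = []
    total = len(te_ids)
    for sf in order:
        n = counts.get(sf, 0)
        pct = round_half_up(100.0 * n / total, 1) if total else 0.0
        rows.append({"superfamily": sf, "count": n, "percent_of_te_related": pct})
    return pd.DataFrame(rows)
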
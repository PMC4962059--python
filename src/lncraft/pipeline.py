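"""End-to-end orchestration: curation -> sequence extraction -> coding
filter -> lncRNA subclassification -> NAT pairing -> lincRNA targets -> TE
classification (-> optional DE filtering)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from .coding import CodingParams, CodingVerdict, classify_all
from .curation import CurationParams, CurationResult, curate
from .de import DEFilterParams, filter_de
from .formats_io import extract_transcript_sequences
from .homology import HomologyEngine
from .lncrna import LincTarget, LncVerdict, NatPair, build_nat_pairs, classify_lnc_all, find_linc_targets
from .models import DERecord, GenomeAnnotation, SequenceLibrary
from .te import TEAnnotation, classify_te_all


@dataclass
class PipelineResult:
    annotation: GenomeAnnotation
    curation: CurationResult
    coding_verdicts: Dict[str, CodingVerdict]
    coding_summary: Dict[str, Dict[str, int]]
    lnc_verdicts: Dict[str, LncVerdict]
    nat_pairs: List[NatPair]
    linc_targets: List[LincTarget]
    te_annotations: Dict[str, TEAnnotation]
    de_significant: List[DERecord] = field(default_factory=list)
    de_up: List[DERecord] = field(default_factory=list)
    de_down: List[DERecord] = field(default_factory=list)

    def category_of(self, transcript_id: str) -> str:
        """Final category label: coding | short | siRNA_precursor |
        TE_derived | lncNAT | lincRNA."""
        cv = self.coding_verdicts[transcript_id]
        if cv.category == "coding":
            return "short" if cv.reason == "short_transcript" else "coding"
        lv = self.lnc_verdicts[transcript_id]
        if lv.subcategory == "lncRNA":
            return lv.lnc_type or "lincRNA"
        return lv.subcategory


def run_pipeline(
    genome: Mapping[str, str],
    annotation: GenomeAnnotation,
    libraries: Mapping[str, SequenceLibrary],
    est_set: Optional[GenomeAnnotation] = None,
    de_records: Optional[List[DERecord]] = None,
    curation_params: Optional[CurationParams] = None,
    coding_params: Optional[CodingParams] = None,
    de_params: Optional[DEFilterParams] = None,
    min_nat_overlap: int = 10,
    engine: Optional[HomologyEngine] = None,
) -> PipelineResult:
    engine = engine or HomologyEngine()
    cur = curate(
        annotation, curation_params, est_set=est_set, engine=engine, genome=genome
    )
    ann = cur.annotation
    extract_transcript_sequences(ann, genome)
    coding_verdicts, summary = classify_all(
        ann, libraries["protein"], engine, coding_params
    )
    pot_lnc = [
        ann.get(tid)
        for tid, v in coding_verdicts.items()
        if v.category == "pot_lncRNA"
    ]
    lnc_verdicts, nat_partners = classify_lnc_all(
        pot_lnc, ann, libraries["smallrna"], libraries["te"], engine,
        min_overlap=min_nat_overlap,
    )
    pairs = build_nat_pairs(nat_partners, coding_verdicts, lnc_verdicts)
    lincs = [
        ann.get(tid)
        for tid, v in lnc_verdicts.items()
        if v.subcategory == "lncRNA" and v.lnc_type == "lincRNA"
    ]
    targets = find_linc_targets(lincs, libraries["cds"], engine)
    te_annotations = classify_te_all(ann, libraries["te"], engine)
    sig: List[DERecord] = []
    up: List[DERecord] = []
    down: List[DERecord] = []
    if de_records is not None:
        sig, up, down = filter_de(de_records, de_params)
    return PipelineResult(
        annotation=ann,
        curation=cur,
        coding_verdicts=coding_verdicts,
        coding_summary=summary,
        lnc_verdicts=lnc_verdicts,
        nat_pairs=pairs,
        linc_targets=targets,
        te_annotations=te_annotations,
        de_significant=sig,
        de_up=up,
        de_down=down,
    )
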
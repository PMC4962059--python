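"""Post-assembly curation of a merged RABT annotation.

Fixed pipeline order: merge duplicated reference records -> drop short novel
transcripts -> rename novel transcripts by class code -> fuse nearby
monoexonic intergenic transcripts -> integrate external (EST) transcripts.
Re-running the pipeline on its own output is a no-op.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from .models import GenomeAnnotation, TranscriptModel


@dataclass
class CurationParams:
    min_novel_len: int = 57  # discard strictly shorter novel transcripts
    max_cluster_gap: int = 500  # fuse monoexonic U gaps strictly below this
    verify_clusters: bool = False

    def __post_init__(self) -> None:
        if self.min_novel_len <= 0 or self.max_cluster_gap <= 0:
            raise ValueError("curation thresholds must be positive")


@dataclass
class ClusterRecord:
    cluster_id: str
    member_ids: List[str]
    chrom: str
    strand: str
    fused_interval: Tuple[int, int]

    @property
    def fused_length(self) -> int:
        return self.fused_interval[1] - self.fused_interval[0]


def _rebuild(transcripts) -> GenomeAnnotation:
    ann = GenomeAnnotation()
    for tx in transcripts:
        ann.add(tx)
    return ann


def merge_duplicate_reference(
    annotation: GenomeAnnotation,
) -> Tuple[GenomeAnnotation, List[List[str]]]:
    """Collapse transcripts with identical (chrom, strand, exon chain) into
    one record; the survivor (lexicographically smallest id) keeps the other
    ids as aliases. Returns the merged annotation and the collapse log."""
    groups: Dict[Tuple, List[TranscriptModel]] = {}
    for tx in annotation.sorted_transcripts():
        groups.setdefault(tx.exon_chain_key(), []).append(tx)
    merged: List[TranscriptModel] = []
    log: List[List[str]] = []
    for key in sorted(groups, key=str):
        members = sorted(groups[key], key=lambda t: t.transcript_id)
        keep = members[0]
        if len(members) > 1:
            keep.aliases = sorted(
                set(keep.aliases)
                | {m.transcript_id for m in members[1:]}
                | {a for m in members for a in m.aliases}
            )
            log.append([m.transcript_id for m in members])
        merged.append(keep)
    return _rebuild(merged), log


def filter_min_length(
    annotation: GenomeAnnotation, params: CurationParams
) -> Tuple[GenomeAnnotation, List[str]]:
    """Drop novel (J/O/X/U) transcripts shorter than ``min_novel_len``;
    reference and EST records are never removed."""
    kept, removed = [], []
    for tx in annotation.sorted_transcripts():
        if tx.is_novel and tx.length_nt < params.min_novel_len:
            removed.append(tx.transcript_id)
        else:
            kept.append(tx)
    return _rebuild(kept), removed


_J_PAT = re.compile(r"_j_\d+$")
_O_PAT = re.compile(r"_O_\d+$")
_X_PAT = re.compile(r"_X_\d+$")
_U_PAT = re.compile(r"^(TCONS_\d{8}|Cluster_t_\d+)$")


def _already_named(tx: TranscriptModel) -> bool:
    tid = tx.transcript_id
    if tx.class_code == "J":
        return bool(_J_PAT.search(tid))
    if tx.class_code == "O":
        return bool(_O_PAT.search(tid))
    if tx.class_code == "X":
        return bool(_X_PAT.search(tid))
    if tx.class_code == "U":
        return bool(_U_PAT.match(tid))
    return True


def _host_transcript(
    tx: TranscriptModel, annotation: GenomeAnnotation
) -> Optional[TranscriptModel]:
    """Reference transcript the novel record hangs off: same locus for J,
    best-overlapping reference transcript for O (same strand) and X
    (opposite strand)."""
    if tx.class_code == "J":
        refs = [
            t
            for t in annotation.transcripts_of_gene(tx.gene_id)
            if t.class_code == "reference"
        ]
        refs.sort(key=lambda t: (t.start, t.transcript_id))
        return refs[0] if refs else None
    want_strand = tx.strand if tx.class_code == "O" else (
        "-" if tx.strand == "+" else "+"
    )
    best, best_ov = None, 0
    for a, b in tx.exons:
        for tid in annotation.overlapping_exons(tx.chrom, want_strand, a, b):
            other = annotation.get(tid)
            if other.class_code != "reference":
                continue
            ov = sum(
                max(0, min(b, d) - max(a, c))
                for c, d in other.exons
            )
            if ov > best_ov or (ov == best_ov and best and tid < best.transcript_id):
                best, best_ov = other, ov
    return best


def rename_by_class(
    annotation: GenomeAnnotation,
) -> Tuple[GenomeAnnotation, Dict[str, str]]:
    """Apply the class-suffix naming scheme to novel transcripts.

    J/O/X records become ``<hostTranscript>_<code>_<k>`` with ``k`` counted
    in genomic order per host; U records (and J/O/X without a locatable
    host) become ``TCONS_<8 digits>`` numbered in genomic order. Ids already
    matching their scheme are kept, making renaming idempotent."""
    id_map: Dict[str, str] = {}
    counters: Dict[Tuple[str, str], int] = {}
    # existing TCONS numbers must not be reused
    used_tcons = {
        int(m.group(1))
        for tx in annotation
        for m in [re.match(r"^TCONS_(\d{8})$", tx.transcript_id)]
        if m
    }
    next_tcons = max(used_tcons, default=0) + 1
    new_txs: List[TranscriptModel] = []
    for tx in annotation.sorted_transcripts():
        if not tx.is_novel or _already_named(tx):
            new_txs.append(tx)
            id_map[tx.transcript_id] = tx.transcript_id
            continue
        new_id = None
        if tx.class_code in ("J", "O", "X"):
            host = _host_transcript(tx, annotation)
            if host is not None:
                code = "j" if tx.class_code == "J" else tx.class_code
                key = (host.transcript_id, code)
                counters[key] = counters.get(key, 0) + 1
                new_id = f"{host.transcript_id}_{code}_{counters[key]}"
        if new_id is None:
            new_id = f"TCONS_{next_tcons:08d}"
            next_tcons += 1
        id_map[tx.transcript_id] = new_id
        new_txs.append(
            TranscriptModel(
                transcript_id=new_id,
                gene_id=tx.gene_id,
                chrom=tx.chrom,
                strand=tx.strand,
                exons=tx.exons,
                class_code=tx.class_code,
                sequence=tx.sequence,
                aliases=tx.aliases + [tx.transcript_id],
            )
        )
    return _rebuild(new_txs), id_map


def cluster_monoexonic(
    annotation: GenomeAnnotation,
    params: CurationParams,
    engine=None,
    genome: Optional[Mapping[str, str]] = None,
) -> Tuple[GenomeAnnotation, List[ClusterRecord]]:
    """Fuse chains of monoexonic intergenic (class U) transcripts whose
    consecutive genomic gaps are strictly below ``max_cluster_gap``.

    Chains are maximal single-linkage runs per (chrom, strand). Each fused
    record is a new monoexonic U transcript spanning the chain. With
    ``verify_clusters`` and a genome, fusion additionally requires every
    member's sequence to be an exact substring of the fused genomic
    sequence (a sanity check of the merged sequence)."""
    candidates = [
        tx
        for tx in annotation.sorted_transcripts()
        if tx.class_code == "U" and tx.is_monoexonic
        and not tx.transcript_id.startswith("Cluster_t_")
    ]
    by_group: Dict[Tuple[str, str], List[TranscriptModel]] = {}
    for tx in candidates:
        by_group.setdefault((tx.chrom, tx.strand), []).append(tx)

    used_cluster_ids = {
        int(m.group(1))
        for tx in annotation
        for m in [re.match(r"^Cluster_t_(\d+)$", tx.transcript_id)]
        if m
    }
    counter = max(used_cluster_ids, default=0)
    clusters: List[ClusterRecord] = []
    replaced: Dict[str, TranscriptModel] = {}
    drop: set = set()
    for key in sorted(by_group):
        chrom, strand = key
        txs = sorted(by_group[key], key=lambda t: (t.start, t.end, t.transcript_id))
        chain: List[TranscriptModel] = []
        for tx in txs + [None]:  # sentinel flushes the last chain
            if chain and (
                tx is None or tx.start - chain[-1].end >= params.max_cluster_gap
            ):
                if len(chain) >= 2:
                    span = (chain[0].start, max(t.end for t in chain))
                    ok = True
                    if params.verify_clusters and genome is not None:
                        merged_seq = str(genome[chrom][span[0] : span[1]]).upper()
                        for t in chain:
                            sub = str(genome[chrom][t.start : t.end]).upper()
                            if sub not in merged_seq:
                                ok = False
                    if ok:
                        counter += 1
                        cid = f"Cluster_t_{counter}"
                        clusters.append(
                            ClusterRecord(
                                cluster_id=cid,
                                member_ids=[t.transcript_id for t in chain],
                                chrom=chrom,
                                strand=strand,
                                fused_interval=span,
                            )
                        )
                        gene = f"XLOC_{cid}"
                        replaced[cid] = TranscriptModel(
                            transcript_id=cid,
                            gene_id=gene,
                            chrom=chrom,
                            strand=strand,
                            exons=[span],
                            class_code="U",
                            aliases=[t.transcript_id for t in chain],
                        )
                        drop.update(t.transcript_id for t in chain)
                chain = []
            if tx is not None:
                chain.append(tx)
    out = [
        tx for tx in annotation.sorted_transcripts() if tx.transcript_id not in drop
    ] + list(replaced.values())
    return _rebuild(out), clusters


def integrate_external(
    annotation: GenomeAnnotation, est_set: GenomeAnnotation
) -> Tuple[GenomeAnnotation, List[str]]:
    """Append EST transcripts, dropping those whose exon chain duplicates an
    existing record. Returns (annotation, added ids)."""
    existing = {tx.exon_chain_key() for tx in annotation}
    added = []
    out = list(annotation.sorted_transcripts())
    for est in est_set.sorted_transcripts():
        if est.class_code != "EST":
            raise ValueError(f"external transcript {est.transcript_id} not class EST")
        if est.exon_chain_key() in existing:
            continue
        out.append(est)
        existing.add(est.exon_chain_key())
        added.append(est.transcript_id)
    return _rebuild(out), added


@dataclass
class CurationResult:
    annotation: GenomeAnnotation
    merge_log: List[List[str]] = field(default_factory=list)
    removed_short: List[str] = field(default_factory=list)
    id_map: Dict[str, str] = field(default_factory=dict)
    clusters: List[ClusterRecord] = field(default_factory=list)
    added_est: List[str] = field(default_factory=list)


def curate(
    annotation: GenomeAnnotation,
    params: Optional[CurationParams] = None,
    est_set: Optional[GenomeAnnotation] = None,
    engine=None,
    genome: Optional[Mapping[str, str]] = None,
) -> CurationResult:
    """Run the full curation pipeline in its fixed order."""
    params = params or CurationParams()
    ann, merge_log = merge_duplicate_reference(annotation)
    ann, removed = filter_min_length(ann, params)
    ann, id_map = rename_by_class(ann)
    ann, clusters = cluster_monoexonic(ann, params, engine=engine, genome=genome)
    for rec in clusters:
        for member in rec.member_ids:
            # member ids are post-rename; route originals to the fused record
            for orig, new in list(id_map.items()):
                if new == member:
                    id_map[orig] = rec.cluster_id
            id_map[member] = rec.cluster_id
    added: List[str] = []
    if est_set is not None:
        ann, added = integrate_external(ann, est_set)
    return CurationResult(ann, merge_log, removed, id_map, clusters, added)
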
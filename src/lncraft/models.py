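"""Core containers shared by every pipeline stage.

Coordinates are 0-based, half-open everywhere inside the package; the GTF
reader/writer converts at the boundary. Strand is ``+``, ``-`` or ``.``
(unknown). Class codes follow the Cufflinks transfrag convention used for
RABT reannotations: ``reference`` (present in the guide annotation), ``J``
(novel isoform at a known locus), ``O`` (generic exonic overlap), ``X``
(antisense overlap), ``U`` (intergenic) plus ``EST`` for externally
integrated transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from intervaltree import IntervalTree

CLASS_CODES = ("reference", "J", "O", "X", "U", "EST")
NOVEL_CLASSES = ("J", "O", "X", "U")
STRANDS = ("+", "-", ".")


@dataclass
class TranscriptModel:
    """One transcript: exon chain, strand, class code, spliced sequence."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    class_code: str = "reference"
    sequence: Optional[str] = None
    aliases: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r} for {self.transcript_id}")
        if self.class_code not in CLASS_CODES:
            raise ValueError(
                f"bad class code {self.class_code!r} for {self.transcript_id}"
            )
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in exons:
            if b <= a:
                raise ValueError(f"empty exon {(a, b)} in {self.transcript_id}")
        for (_, b), (c, _) in zip(exons, exons[1:]):
            if c < b:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        self.exons = exons
        if self.length_nt < 1:
            raise ValueError(f"zero-length transcript {self.transcript_id}")
        if self.sequence is not None and len(self.sequence) != self.length_nt:
            raise ValueError(
                f"sequence length {len(self.sequence)} != exon sum "
                f"{self.length_nt} for {self.transcript_id}"
            )

    @property
    def length_nt(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_monoexonic(self) -> bool:
        return len(self.exons) == 1

    @property
    def is_novel(self) -> bool:
        return self.class_code in NOVEL_CLASSES

    def exon_chain_key(self) -> Tuple:
        return (self.chrom, self.strand, tuple(self.exons))


class GenomeAnnotation:
    """A set of transcripts with a per-(chrom, strand) exon interval index."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self._transcripts: Dict[str, TranscriptModel] = {}
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        self._loci: Dict[str, List[str]] = {}
        for tx in transcripts:
            self.add(tx)

    def add(self, tx: TranscriptModel) -> None:
        if tx.transcript_id in self._transcripts:
            raise ValueError(f"duplicate transcript id {tx.transcript_id}")
        self._transcripts[tx.transcript_id] = tx
        self._loci.setdefault(tx.gene_id, []).append(tx.transcript_id)
        tree = self._trees.setdefault((tx.chrom, tx.strand), IntervalTree())
        for a, b in tx.exons:
            tree.addi(a, b, tx.transcript_id)

    def remove(self, transcript_id: str) -> TranscriptModel:
        tx = self._transcripts.pop(transcript_id)
        self._loci[tx.gene_id].remove(transcript_id)
        if not self._loci[tx.gene_id]:
            del self._loci[tx.gene_id]
        tree = self._trees[(tx.chrom, tx.strand)]
        for a, b in tx.exons:
            tree.removei(a, b, transcript_id)
        return tx

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def get(self, transcript_id: str) -> TranscriptModel:
        return self._transcripts[transcript_id]

    @property
    def transcript_ids(self) -> List[str]:
        return list(self._transcripts)

    @property
    def gene_ids(self) -> List[str]:
        return list(self._loci)

    def transcripts_of_gene(self, gene_id: str) -> List[TranscriptModel]:
        return [self._transcripts[t] for t in self._loci.get(gene_id, [])]

    def sorted_transcripts(self) -> List[TranscriptModel]:
        """Genomic order: chrom, start, end, id (deterministic)."""
        return sorted(
            self._transcripts.values(),
            key=lambda t: (t.chrom, t.start, t.end, t.transcript_id),
        )

    def overlapping_exons(
        self, chrom: str, strand: str, start: int, end: int
    ) -> List[str]:
        """Transcript ids with >=1 exon overlapping [start, end) on strand."""
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end)})


@dataclass
class SequenceLibrary:
    """Named id -> sequence store; TE libraries carry family/superfamily."""

    name: str
    role: str  # protein | smallrna | te | cds
    entries: Dict[str, str] = field(default_factory=dict)
    te_meta: Dict[str, Tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ("protein", "smallrna", "te", "cds"):
            raise ValueError(f"bad library role {self.role!r}")
        if self.role == "te":
            missing = [k for k in self.entries if k not in self.te_meta]
            if missing:
                raise ValueError(f"TE entries without family metadata: {missing[:3]}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.entries.values())


@dataclass
class DERecord:
    """One differential-expression test for a gene or transcript."""

    feature_id: str
    status: str  # OK | NOTEST | LOWDATA | other
    rpkm_a: float = float("nan")
    rpkm_b: float = float("nan")
    log2fc: float = float("nan")
    q_value: float = float("nan")
    level: str = "transcript"
    chrom: Optional[str] = None
    position: Optional[int] = None
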
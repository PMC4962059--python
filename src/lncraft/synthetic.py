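"""Synthetic genomes, annotations, sequence libraries and DE tables with
planted ground truth.

The generator emulates the inputs of a maize-style total-transcriptome
reannotation so every pipeline stage runs without downloads: coding
transcripts embed long (>= 120 aa) ORFs whose translations populate the
protein library; siRNA-precursor transcripts carry exact copies of
smallRNA-library entries; TE transcripts are (optionally mutated) copies of
TE-library fragments sized to land in the HC or PR confidence class;
antisense lncRNAs overlap a partner gene's exons by amounts straddling the
10-nt rule; monoexonic intergenic fragments are laid out with gaps
straddling the 500-bp clustering threshold; and a DE table plants fold
changes, q-values, NOTEST/LOWDATA rows and exclusion-region features.

Every planted label is enforced by construction (rejection sampling): a
transcript labelled non-coding genuinely has no ORF of 120 aa or more and
no qualifying exact match to the smallRNA/TE libraries, so a correct
pipeline must recover the truth table exactly when the mutation rate is 0.
All randomness flows from one seed through named child streams, making
outputs byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio.Seq import Seq

from .coding import longest_orf
from .formats_io import revcomp, write_fasta, write_gtf
from .homology import HomologyEngine, exact_match_params, protein_match_params

_PROTEIN_PARAMS = protein_match_params()
from .models import DERecord, GenomeAnnotation, SequenceLibrary, TranscriptModel

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
# internal codons exclude stops and ATG so planted CDS fragments cannot
# carry an in-frame start codon (keeps lincRNA-target planting clean)
_INTERNAL_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS and a + b + c != "ATG"
)

# TE family/superfamily vocabulary used for the synthetic library
_TE_FAMILIES = (
    ("Gyma", "RLG"), ("Huck", "RLG"), ("Cinful", "RLG"),
    ("Ji", "RLC"), ("Opie", "RLC"),
    ("Xilon", "RLX"), ("Leo", "RIL"),
    ("hATx", "DTA"), ("Cacta1", "DTC"), ("Helia", "DHH"),
    ("MuDR", "DTM"), ("Pifa", "DTH"), ("Mar1", "DTT"), ("Rst1", "RST"),
)


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic dataset.

    Counts give roughly 250 transcripts on a 2 x 1 Mb genome. lncRNA
    lengths are drawn as 201 + Exp(mean - 201) capped at 4,179 nt so both
    the observed range (201-4,179) and the category means (~535 nt for
    antisense, ~465 nt for intergenic lncRNAs) match the study the pipeline
    reimplements.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 1_000_000
    # transcript category counts
    n_coding: int = 48
    n_j_isoforms: int = 6
    n_o_overlap: int = 4
    n_lincrna: int = 24
    n_linc_perfect_target: int = 6
    n_linc_near_target: int = 6
    n_nat_coding: int = 10
    n_nat_decoy: int = 5
    n_nat_nat_pairs: int = 4
    n_nat_sirna: int = 4
    n_sirna: int = 18
    n_te_hc: int = 10
    n_te_pr: int = 10
    n_u_chains: int = 5
    n_u_isolated: int = 8
    n_dup_ref_pairs: int = 3
    n_short_novel: int = 4
    n_est: int = 6  # half duplicate existing chains, half novel
    # libraries
    te_lib_n: int = 20
    te_lib_len: Tuple[int, int] = (600, 2_500)
    smallrna_lib_n: int = 20
    smallrna_len: Tuple[int, int] = (60, 300)
    n_protein_decoys: int = 20
    # sequence shape
    orf_aa_range: Tuple[int, int] = (130, 400)
    lnc_len_cap: int = 4_179
    nat_len_mean: float = 535.0
    linc_len_mean: float = 465.0
    te_mutation_rate: float = 0.0
    nat_overlap_range: Tuple[int, int] = (10, 30)
    nat_decoy_overlap_range: Tuple[int, int] = (5, 9)
    cluster_gap_range: Tuple[int, int] = (50, 480)  # strictly under 500
    unit_gap_range: Tuple[int, int] = (600, 1_400)  # keeps units unfused
    # differential expression
    n_de_features: int = 60
    exclusion_region_width: int = 100_000
    de_q_sig: Tuple[float, float] = (0.001, 0.05)
    de_lfc_sig: Tuple[float, float] = (1.0, 4.0)

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if isinstance(value, int) and name.startswith("n_") and value < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.te_mutation_rate < 1:
            raise ValueError("te_mutation_rate must be in [0, 1)")


@dataclass
class TruthRecord:
    transcript_id: str
    category: str  # coding | short | siRNA_precursor | TE_derived | lncNAT | lincRNA
    class_code: str = "reference"
    te_confidence: str = "none"  # HC | PR | none
    te_family: str = ""
    te_superfamily: str = ""
    nat_partners: List[str] = field(default_factory=list)
    nat_partner_kinds: List[str] = field(default_factory=list)
    linc_target_class: str = ""  # perfect | near_exact | ''
    fate: str = "kept"  # kept | removed_short | merged_duplicate


@dataclass
class TruthTable:
    records: Dict[str, TruthRecord] = field(default_factory=dict)
    clusters: List[Dict] = field(default_factory=list)  # {members, category}
    de_truth: Dict[str, str] = field(default_factory=dict)
    # up | down | not_sig | excluded | not_expressed


@dataclass
class SimResult:
    genome: Dict[str, str]
    annotation: GenomeAnnotation
    est_set: GenomeAnnotation
    libraries: Dict[str, SequenceLibrary]
    de_records: List[DERecord]
    exclusion_region: Tuple[str, int, int]
    truth: TruthTable
    config: SimConfig


# --------------------------------------------------------------------- utils
def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def mutate_sequence(seq: str, rate: float, rng) -> str:
    """I.i.d. substitutions to a different base at the given rate."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return seq
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        alt = [b for b in _BASES if b != out[i]]
        out[i] = alt[rng.integers(0, 3)]
    return "".join(out)


def _orf_free(seq: str, max_aa: int = 119) -> bool:
    top = longest_orf(seq)
    return top is None or top.aa_length <= max_aa


class _Screens:
    """Rejection-sampling helpers against the generated libraries."""

    def __init__(self, smallrna: SequenceLibrary, te: SequenceLibrary) -> None:
        self.engine = HomologyEngine()
        self.smallrna = smallrna
        self.te = te
        self.params = exact_match_params()

    def lib_clean(self, seq: str, check_smallrna: bool = True, check_te: bool = True) -> bool:
        if check_smallrna and self.engine.search(seq, self.smallrna, self.params):
            return False
        if check_te and self.engine.search(seq, self.te, self.params):
            return False
        return True

    def clean_lnc(self, seq: str) -> bool:
        return _orf_free(seq) and self.lib_clean(seq)


def _draw_lnc_len(rng: np.random.Generator, mean: float, cap: int) -> int:
    return int(min(cap, 201 + math.floor(rng.exponential(mean - 201))))


def _sample_clean(rng, length, screens: Optional[_Screens], need_orf_free=True,
                  max_tries=200) -> str:
    for _ in range(max_tries):
        seq = _rand_seq(rng, length)
        if need_orf_free and not _orf_free(seq):
            continue
        if screens is not None and not screens.lib_clean(seq):
            continue
        return seq
    raise RuntimeError("could not sample a clean sequence (library too dense?)")


# ---------------------------------------------------------------- unit model
@dataclass
class _TxSpec:
    transcript_id: str
    gene_id: str
    strand: str
    exons: List[Tuple[int, int]]  # unit-local coordinates
    class_code: str


@dataclass
class _Unit:
    buffer: str
    transcripts: List[_TxSpec]


def _paste(buffer: List[str], exons: Sequence[Tuple[int, int]], strand: str,
           seq: str) -> None:
    """Write a spliced transcript sequence into a unit buffer."""
    if strand == "-":
        seq = revcomp(seq)
    pos = 0
    for a, b in exons:
        buffer[a:b] = list(seq[pos : pos + (b - a)])
        pos += b - a
    assert pos == len(seq)


def _split_exons(rng, total_len: int, n_exons: int,
                 intron_range=(60, 300)) -> Tuple[List[Tuple[int, int]], int]:
    """Random exon chain of total exonic length ``total_len``; returns
    unit-local exons and the genomic span."""
    n_exons = max(1, min(n_exons, total_len // 40))
    cuts = sorted(rng.choice(np.arange(1, total_len), size=n_exons - 1,
                             replace=False)) if n_exons > 1 else []
    lens = np.diff([0, *cuts, total_len])
    exons = []
    pos = 0
    for i, L in enumerate(lens):
        if i > 0:
            pos += int(rng.integers(*intron_range))
        exons.append((pos, pos + int(L)))
        pos += int(L)
    return exons, pos


# ------------------------------------------------------------------ builders
class _Generator:
    def __init__(self, config: SimConfig) -> None:
        self.cfg = config
        streams = np.random.SeedSequence(config.seed).spawn(5)
        self.rng_lib = np.random.default_rng(streams[0])
        self.rng_tx = np.random.default_rng(streams[1])
        self.rng_layout = np.random.default_rng(streams[2])
        self.rng_de = np.random.default_rng(streams[3])
        self.rng_genome = np.random.default_rng(streams[4])
        self.truth = TruthTable()
        self.units: List[_Unit] = []
        self.est_units: List[Tuple[_Unit, bool]] = []  # (unit, novel?)
        self.proteins: Dict[str, str] = {}
        self.cds: Dict[str, str] = {}
        self._gene_counter = 0
        self._tcons_counter = 0
        self._cuff_counter = 0

    # ------------------------------------------------------------- id helpers
    def _gene_id(self, prefix: str = "GRMZM2G") -> str:
        self._gene_counter += 1
        return f"{prefix}{self._gene_counter:06d}"

    def _tcons_id(self) -> str:
        self._tcons_counter += 1
        return f"TCONS_{self._tcons_counter:08d}"

    def _cuff_id(self) -> str:
        self._cuff_counter += 1
        return f"CUFF.{self._cuff_counter}.1"

    # ------------------------------------------------------------- libraries
    def build_libraries(self) -> None:
        cfg, rng = self.cfg, self.rng_lib
        te_entries, te_meta = {}, {}
        for i in range(cfg.te_lib_n):
            fam, sf = _TE_FAMILIES[i % len(_TE_FAMILIES)]
            length = int(rng.integers(*cfg.te_lib_len))
            seq = _sample_clean(rng, length, None)  # ORF-free only
            tid = f"TE{i + 1:04d}_{fam}"
            te_entries[tid] = seq
            te_meta[tid] = (fam, sf)
        self.te_lib = SequenceLibrary("maizeTE_synthetic", "te", te_entries, te_meta)

        small_entries = {}
        guard = _Screens(SequenceLibrary("empty", "smallrna"), self.te_lib)
        for i in range(cfg.smallrna_lib_n):
            length = int(rng.integers(*cfg.smallrna_len))
            for _ in range(100):
                seq = _rand_seq(rng, length)
                if _orf_free(seq) and guard.lib_clean(seq, check_smallrna=False):
                    break
            small_entries[f"sRNAprec{i + 1:04d}"] = seq
        self.smallrna_lib = SequenceLibrary(
            "smallrna_precursors_synthetic", "smallrna", small_entries
        )
        self.screens = _Screens(self.smallrna_lib, self.te_lib)

    # ---------------------------------------------------------- coding units
    def _make_coding_parts(self) -> Tuple[str, int, int]:
        """(sequence, utr5_len, cds_len) for one coding transcript."""
        rng = self.rng_tx
        aa = int(rng.integers(*self.cfg.orf_aa_range))
        cds = "ATG" + "".join(
            _INTERNAL_CODONS[i]
            for i in rng.integers(0, len(_INTERNAL_CODONS), aa - 1)
        ) + _STOPS[rng.integers(0, 3)]
        utr5 = _rand_seq(rng, int(rng.integers(20, 150)))
        utr3 = _rand_seq(rng, int(rng.integers(50, 300)))
        return utr5 + cds + utr3, len(utr5), len(cds)

    def add_coding_unit(self, strand: Optional[str] = None,
                        with_j: bool = False, with_o: bool = False) -> str:
        rng = self.rng_tx
        seq, utr5_len, cds_len = self._make_coding_parts()
        if strand is None:
            strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 6))
        exons, span = _split_exons(rng, len(seq), n_ex)
        gid = self._gene_id()
        tid = f"{gid}_T01"
        self.proteins[f"P_{tid}"] = str(Seq(seq[utr5_len : utr5_len + cds_len - 3]).translate())
        self.cds[f"CDS_{tid}"] = seq[utr5_len : utr5_len + cds_len]
        buffer = list(_rand_seq(rng, span))
        _paste(buffer, exons, strand, seq)
        specs = [_TxSpec(tid, gid, strand, exons, "reference")]
        self.truth.records[tid] = TruthRecord(tid, "coding")

        if with_j:  # novel isoform keeping >= 400 nt of CDS (a 3'-partial ORF)
            target = utr5_len + min(cds_len - 3, int(rng.integers(420, 700)))
            j_exons, acc = [], 0
            for a, b in exons:
                if acc + (b - a) >= target:
                    j_exons.append((a, a + (target - acc)))
                    break
                j_exons.append((a, b))
                acc += b - a
            raw = self._cuff_id()
            specs.append(_TxSpec(raw, gid, strand, j_exons, "J"))
            self.truth.records[raw] = TruthRecord(raw, "coding", class_code="J")
        if with_o:  # same-strand overlap of the 3' UTR, extending beyond
            last_a, last_b = exons[-1]
            o_len = 60
            ext = int(rng.integers(160, 360))
            o_exon = (last_b - o_len, last_b + ext)
            if len(buffer) < o_exon[1]:
                buffer.extend(_rand_seq(rng, o_exon[1] - len(buffer)))
            overlap_part = "".join(buffer[o_exon[0] : last_b])
            for _ in range(200):
                tail = _rand_seq(rng, ext)
                o_seq = overlap_part + tail  # host is '+', O is same strand
                if self.screens.clean_lnc(o_seq):
                    break
            else:
                raise RuntimeError("could not build O-class overlap transcript")
            buffer[last_b : o_exon[1]] = list(tail)
            raw = self._cuff_id()
            specs.append(_TxSpec(raw, self._gene_id("XLOC_O"), strand, [o_exon], "O"))
            self.truth.records[raw] = TruthRecord(raw, "lincRNA", class_code="O")
        self.units.append(_Unit("".join(buffer), specs))
        return tid

    # ------------------------------------------------------------- NAT units
    def add_nat_unit(self, partner_kind: str, qualifying: bool = True) -> None:
        """An antisense lncRNA over the genomic 3' end of a partner
        transcript (coding mRNA or siRNA precursor)."""
        rng = self.rng_tx
        cfg = self.cfg
        if partner_kind == "coding_mRNA":
            seq, utr5_len, cds_len = self._make_coding_parts()
            strand = "+"
            for _ in range(100):  # last exon must host the full overlap
                exons, span = _split_exons(rng, len(seq), int(rng.integers(1, 4)))
                if exons[-1][1] - exons[-1][0] >= 35:
                    break
            gid = self._gene_id()
            ptid = f"{gid}_T01"
            self.proteins[f"P_{ptid}"] = str(
                Seq(seq[utr5_len : utr5_len + cds_len - 3]).translate()
            )
            self.cds[f"CDS_{ptid}"] = seq[utr5_len : utr5_len + cds_len]
            self.truth.records[ptid] = TruthRecord(ptid, "coding")
        else:  # siRNA precursor partner ('+' strand, insert near the 5' end)
            insert_id = list(self.smallrna_lib.entries)[
                int(rng.integers(0, len(self.smallrna_lib.entries)))
            ]
            insert = self.smallrna_lib.entries[insert_id]
            for _ in range(200):
                flank5 = _rand_seq(rng, int(rng.integers(30, 80)))
                flank3 = _rand_seq(rng, int(rng.integers(150, 400)))
                seq = flank5 + insert + flank3
                if _orf_free(seq) and self.screens.lib_clean(seq, check_te=True,
                                                             check_smallrna=False):
                    break
            else:
                raise RuntimeError("could not build siRNA-precursor NAT partner")
            strand = "+"
            exons, span = [(0, len(seq))], len(seq)
            gid = self._gene_id("GRMZM5G")
            ptid = f"{gid}_T01"
            self.truth.records[ptid] = TruthRecord(ptid, "siRNA_precursor")

        overlap = int(
            rng.integers(*(cfg.nat_overlap_range if qualifying
                           else cfg.nat_decoy_overlap_range))
        )
        lnc_len = _draw_lnc_len(rng, cfg.nat_len_mean, cfg.lnc_len_cap)
        p_end = exons[-1][1]
        lnc_exon = (p_end - overlap, p_end - overlap + lnc_len)
        total = max(span, lnc_exon[1]) + 10
        buffer = list(_rand_seq(rng, total))
        _paste(buffer, exons, strand, seq)
        # the lncRNA reads the partner's bases in the overlap; resample only
        # its private tail until the extracted sequence is clean
        raw = self._cuff_id()
        for _ in range(200):
            genomic = "".join(buffer[lnc_exon[0] : lnc_exon[1]])
            lnc_seq = revcomp(genomic)  # lnc is on '-', partner on '+'
            if self.screens.clean_lnc(lnc_seq):
                break
            tail = _rand_seq(rng, lnc_exon[1] - p_end)
            buffer[p_end : lnc_exon[1]] = list(tail)
        else:
            raise RuntimeError("could not build antisense lncRNA")
        specs = [
            _TxSpec(ptid, gid, strand, exons, "reference"),
            _TxSpec(raw, self._gene_id("XLOC_X"), "-", [lnc_exon], "X"),
        ]
        if qualifying:
            self.truth.records[raw] = TruthRecord(
                raw, "lncNAT", class_code="X",
                nat_partners=[ptid], nat_partner_kinds=[partner_kind],
            )
        else:
            self.truth.records[raw] = TruthRecord(raw, "lincRNA", class_code="X")
        self.units.append(_Unit("".join(buffer), specs))

    def add_nat_nat_unit(self) -> None:
        """Two mutually antisense intergenic lncRNAs (one NAT pair)."""
        rng, cfg = self.rng_tx, self.cfg
        o = int(rng.integers(*cfg.nat_overlap_range))
        l1 = _draw_lnc_len(rng, cfg.nat_len_mean, cfg.lnc_len_cap)
        l2 = _draw_lnc_len(rng, cfg.nat_len_mean, cfg.lnc_len_cap)
        e1 = (0, l1)
        e2 = (l1 - o, l1 - o + l2)
        total = e2[1] + 10
        id_a, id_b = self._tcons_id(), self._tcons_id()
        for _ in range(200):
            buffer = list(_rand_seq(rng, total))
            seq_a = "".join(buffer[e1[0] : e1[1]])
            seq_b = revcomp("".join(buffer[e2[0] : e2[1]]))
            if self.screens.clean_lnc(seq_a) and self.screens.clean_lnc(seq_b):
                break
        else:
            raise RuntimeError("could not build NAT-NAT pair")
        self.units.append(
            _Unit(
                "".join(buffer),
                [
                    _TxSpec(id_a, self._gene_id("XLOC_U"), "+", [e1], "U"),
                    _TxSpec(id_b, self._gene_id("XLOC_U"), "-", [e2], "U"),
                ],
            )
        )
        self.truth.records[id_a] = TruthRecord(
            id_a, "lncNAT", class_code="U",
            nat_partners=[id_b], nat_partner_kinds=["lncNAT"],
        )
        self.truth.records[id_b] = TruthRecord(
            id_b, "lncNAT", class_code="U",
            nat_partners=[id_a], nat_partner_kinds=["lncNAT"],
        )

    # -------------------------------------------------- plain non-coding txs
    def add_lincrna_unit(self, target: str = "") -> None:
        """Intergenic lncRNA; optionally embeds a CDS fragment producing a
        perfect or near-exact target match."""
        rng, cfg = self.rng_tx, self.cfg
        length = _draw_lnc_len(rng, cfg.linc_len_mean, cfg.lnc_len_cap)
        frag = guard_left = guard_right = None
        if target:
            length = max(length, 450)
            donor_id = sorted(self.cds)[int(rng.integers(0, len(self.cds)))]
            donor = self.cds[donor_id]
            frag_len = int(rng.integers(110, 161))
            start = int(rng.integers(12, len(donor) - frag_len - 12))
            frag = donor[start : start + frag_len]
            if target == "near_exact":
                # interior mismatches, well separated, identity in (95, 100)
                nm = int(rng.integers(2, 6))
                positions = sorted(
                    rng.choice(np.arange(25, frag_len - 25, 12), nm, replace=False)
                )
                fl = list(frag)
                for p in positions:
                    fl[p] = [b for b in _BASES if b != fl[p]][int(rng.integers(0, 3))]
                frag = "".join(fl)
            # guard bases that mismatch the donor's continuation so the
            # alignment cannot extend past the planted fragment
            guard_left = "".join(
                [b for b in _BASES if b != donor[start - 1 - i]][int(rng.integers(0, 3))]
                for i in range(6)
            )[::-1]
            guard_right = "".join(
                [b for b in _BASES if b != donor[start + frag_len + i]][
                    int(rng.integers(0, 3))
                ]
                for i in range(6)
            )

        use_ref_class = rng.random() < 0.5 and not target
        # a flank ATG could read into the planted fragment in the donor's
        # frame, making the longest ORF's peptide match the donor protein;
        # resample flanks until the non-coding label genuinely holds
        prot_lib = (
            SequenceLibrary("proteins_so_far", "protein", dict(self.proteins))
            if target else None
        )
        for _ in range(200):
            if frag is not None:
                budget = length - len(frag) - 12
                left = int(rng.integers(30, max(31, budget - 30)))
                seq = (
                    _rand_seq(rng, left) + guard_left + frag + guard_right
                    + _rand_seq(rng, budget - left)
                )
            else:
                seq = _rand_seq(rng, length)
            if not (_orf_free(seq) and self.screens.lib_clean(seq)):
                continue
            if prot_lib is not None:
                top = longest_orf(seq)
                if top is not None and len(top.peptide) >= 4 and \
                        self.screens.engine.search_peptide(
                            top.peptide, prot_lib, _PROTEIN_PARAMS):
                    continue
            break
        else:
            raise RuntimeError("could not build lincRNA")
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 3)) if len(seq) > 400 else 1
        exons, span = _split_exons(rng, len(seq), n_ex)
        if use_ref_class:
            gid = self._gene_id("GRMZM5G")
            tid = f"{gid}_T01"
            code = "reference"
        else:
            gid = self._gene_id("XLOC_U")
            tid = self._tcons_id()
            code = "U"
            exons, span = [(0, len(seq))], len(seq)  # novel intergenic: monoexonic
        buffer = list(_rand_seq(rng, span))
        _paste(buffer, exons, strand, seq)
        self.units.append(_Unit("".join(buffer), [_TxSpec(tid, gid, strand, exons, code)]))
        self.truth.records[tid] = TruthRecord(
            tid, "lincRNA", class_code=code, linc_target_class=target
        )

    def add_sirna_unit(self) -> None:
        rng = self.rng_tx
        insert_id = list(self.smallrna_lib.entries)[
            int(rng.integers(0, len(self.smallrna_lib.entries)))
        ]
        insert = self.smallrna_lib.entries[insert_id]
        for _ in range(200):
            seq = (
                _rand_seq(rng, int(rng.integers(80, 400)))
                + insert
                + _rand_seq(rng, int(rng.integers(80, 400)))
            )
            if _orf_free(seq) and self.screens.lib_clean(seq, check_smallrna=False):
                break
        else:
            raise RuntimeError("could not build siRNA precursor")
        strand = "+" if rng.random() < 0.5 else "-"
        exons, span = _split_exons(rng, len(seq), int(rng.integers(1, 3)))
        gid = self._gene_id("GRMZM5G")
        tid = f"{gid}_T01"
        buffer = list(_rand_seq(rng, span))
        _paste(buffer, exons, strand, seq)
        self.units.append(_Unit("".join(buffer), [_TxSpec(tid, gid, strand, exons, "reference")]))
        self.truth.records[tid] = TruthRecord(tid, "siRNA_precursor")

    def add_te_unit(self, confidence: str) -> None:
        """Transcript expressed from a TE: an HC design (long fragment,
        coverage > 50 %) or a PR design (150-255 nt fragment, bit score
        between the PR and HC cutoffs)."""
        rng, cfg = self.rng_tx, self.cfg
        te_id = list(self.te_lib.entries)[int(rng.integers(0, len(self.te_lib.entries)))]
        entry = self.te_lib.entries[te_id]
        if confidence == "HC":
            frag_len = int(rng.integers(350, min(1_000, len(entry) - 1)))
            flank_total = int(frag_len * rng.uniform(0.15, 0.45))
        else:
            # raw score stays comfortably below the HC bit cutoff (~270
            # matches) even after incidental flank extension
            frag_len = int(rng.integers(150, 240))
            flank_total = int(rng.integers(300, 800))
        start = int(rng.integers(0, len(entry) - frag_len))
        frag = mutate_sequence(entry[start : start + frag_len],
                               cfg.te_mutation_rate, rng)
        for _ in range(200):
            left = int(rng.integers(20, max(21, flank_total - 20)))
            seq = _rand_seq(rng, left) + frag + _rand_seq(rng, flank_total - left)
            if _orf_free(seq) and self.screens.lib_clean(seq, check_te=False):
                break
        else:
            raise RuntimeError("could not build TE transcript")
        strand = "+" if rng.random() < 0.5 else "-"
        use_ref = rng.random() < 0.5
        if use_ref:
            gid = self._gene_id("GRMZM5G")
            tid = f"{gid}_T01"
            code = "reference"
            exons, span = _split_exons(rng, len(seq), 1)
        else:
            gid = self._gene_id("XLOC_U")
            tid = self._tcons_id()
            code = "U"
            exons, span = [(0, len(seq))], len(seq)
        buffer = list(_rand_seq(rng, span))
        _paste(buffer, exons, strand, seq)
        self.units.append(_Unit("".join(buffer), [_TxSpec(tid, gid, strand, exons, code)]))
        fam, sf = self.te_lib.te_meta[te_id]
        self.truth.records[tid] = TruthRecord(
            tid, "TE_derived", class_code=code,
            te_confidence=confidence, te_family=fam, te_superfamily=sf,
        )

    # ------------------------------------------------- curation-target units
    def add_u_chain_unit(self) -> None:
        """2-3 monoexonic intergenic fragments with gaps under 500 bp; the
        curation stage must fuse them into one cluster."""
        rng, cfg = self.rng_tx, self.cfg
        n = int(rng.integers(2, 4))
        strand = "+" if rng.random() < 0.5 else "-"
        for _ in range(200):
            exons, pos = [], 0
            for i in range(n):
                if i > 0:
                    pos += int(rng.integers(*cfg.cluster_gap_range))
                L = int(rng.integers(80, 250))
                exons.append((pos, pos + L))
                pos += L
            buffer = _rand_seq(rng, pos)
            span_seq = buffer if strand == "+" else revcomp(buffer)
            if self.screens.clean_lnc(span_seq):
                break
        else:
            raise RuntimeError("could not build U-fragment chain")
        specs, members = [], []
        for a, b in exons:
            tid = self._tcons_id()
            members.append(tid)
            specs.append(_TxSpec(tid, self._gene_id("XLOC_U"), strand, [(a, b)], "U"))
            self.truth.records[tid] = TruthRecord(
                tid, "lincRNA", class_code="U", fate="fused"
            )
        self.units.append(_Unit(buffer, specs))
        self.truth.clusters.append({"members": members, "category": "lincRNA"})

    def add_u_isolated_unit(self) -> None:
        rng = self.rng_tx
        L = int(rng.integers(80, 250))
        category = "short" if L < 200 else "lincRNA"
        for _ in range(200):
            seq = _rand_seq(rng, L)
            if category == "short" or self.screens.clean_lnc(seq):
                break
        else:
            raise RuntimeError("could not build isolated U fragment")
        strand = "+" if rng.random() < 0.5 else "-"
        tid = self._tcons_id()
        buffer = seq if strand == "+" else revcomp(seq)
        self.units.append(
            _Unit(buffer, [_TxSpec(tid, self._gene_id("XLOC_U"), strand, [(0, L)], "U")])
        )
        self.truth.records[tid] = TruthRecord(tid, category, class_code="U")

    def add_dup_ref_unit(self) -> None:
        """The same short ncRNA locus annotated under two gene ids."""
        rng = self.rng_tx
        L = int(rng.integers(90, 180))
        seq = _rand_seq(rng, L)
        strand = "+"
        gid_a = self._gene_id()
        gid_b = f"zma-MIR{self._gene_counter:03d}"
        tid_a, tid_b = f"{gid_a}_T01", f"{gid_b}_T01"
        specs = [
            _TxSpec(tid_a, gid_a, strand, [(0, L)], "reference"),
            _TxSpec(tid_b, gid_b, strand, [(0, L)], "reference"),
        ]
        self.units.append(_Unit(seq, specs))
        keep, drop = sorted([tid_a, tid_b])
        self.truth.records[keep] = TruthRecord(keep, "short")
        self.truth.records[drop] = TruthRecord(drop, "short", fate="merged_duplicate")

    def add_short_novel_unit(self) -> None:
        rng = self.rng_tx
        L = int(rng.integers(20, 57))  # strictly under the 57-nt cutoff
        seq = _rand_seq(rng, L)
        tid = self._cuff_id()
        self.units.append(
            _Unit(seq, [_TxSpec(tid, self._gene_id("XLOC_U"), "+", [(0, L)], "U")])
        )
        self.truth.records[tid] = TruthRecord(
            tid, "short", class_code="U", fate="removed_short"
        )

    def add_est_unit(self) -> None:
        """A novel external EST (integrated by curation)."""
        rng = self.rng_tx
        L = int(rng.integers(250, 600))
        for _ in range(200):
            seq = _rand_seq(rng, L)
            if self.screens.clean_lnc(seq):
                break
        strand = "+" if rng.random() < 0.5 else "-"
        tid = f"EST{len(self.est_units) + 1:04d}"
        buffer = seq if strand == "+" else revcomp(seq)
        unit = _Unit(buffer, [_TxSpec(tid, f"ESTG{len(self.est_units) + 1:04d}",
                                      strand, [(0, L)], "EST")])
        self.est_units.append((unit, True))
        self.truth.records[tid] = TruthRecord(tid, "lincRNA", class_code="EST")

    # --------------------------------------------------------------- layout
    def place_units(self) -> Tuple[Dict[str, str], GenomeAnnotation, GenomeAnnotation]:
        cfg = self.cfg
        chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
        genomes = {
            c: list(_rand_seq(self.rng_genome, cfg.chrom_len)) for c in chrom_names
        }
        annotation = GenomeAnnotation()
        est_set = GenomeAnnotation()
        cursors = {c: int(self.rng_layout.integers(*cfg.unit_gap_range))
                   for c in chrom_names}
        ci = 0
        placements: List[Tuple[_Unit, bool]] = [(u, False) for u in self.units]
        placements += self.est_units
        for unit, is_est in placements:
            placed = False
            for _ in range(cfg.n_chrom):
                chrom = chrom_names[ci % cfg.n_chrom]
                if cursors[chrom] + len(unit.buffer) < cfg.chrom_len - 1_000:
                    offset = cursors[chrom]
                    genomes[chrom][offset : offset + len(unit.buffer)] = list(unit.buffer)
                    cursors[chrom] = (
                        offset + len(unit.buffer)
                        + int(self.rng_layout.integers(*cfg.unit_gap_range))
                    )
                    target = est_set if is_est else annotation
                    for spec in unit.transcripts:
                        target.add(
                            TranscriptModel(
                                transcript_id=spec.transcript_id,
                                gene_id=spec.gene_id,
                                chrom=chrom,
                                strand=spec.strand,
                                exons=[(a + offset, b + offset) for a, b in spec.exons],
                                class_code=spec.class_code,
                            )
                        )
                    placed = True
                    ci += 1
                    break
                ci += 1
            if not placed:
                raise ValueError("chromosomes too small for the configured units")
        genome = {c: "".join(s) for c, s in genomes.items()}
        return genome, annotation, est_set

    # ---------------------------------------------------- duplicate-EST pass
    def add_duplicate_ests(self, annotation: GenomeAnnotation) -> GenomeAnnotation:
        """ESTs that exactly duplicate existing transcript chains (must be
        dropped on integration)."""
        est = GenomeAnnotation()
        n_dup = self.cfg.n_est - self.cfg.n_est // 2
        candidates = [
            tx for tx in annotation.sorted_transcripts()
            if tx.class_code == "reference" and self.truth.records.get(
                tx.transcript_id, TruthRecord("", "")
            ).category in ("lincRNA", "siRNA_precursor")
        ][:n_dup]
        for i, tx in enumerate(candidates):
            tid = f"ESTDUP{i + 1:04d}"
            est.add(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=f"ESTDUPG{i + 1:04d}",
                    chrom=tx.chrom,
                    strand=tx.strand,
                    exons=list(tx.exons),
                    class_code="EST",
                )
            )
            self.truth.records[tid] = TruthRecord(
                tid, self.truth.records[tx.transcript_id].category,
                class_code="EST", fate="est_duplicate",
            )
        return est

    # ------------------------------------------------------------------- DE
    def build_de_table(
        self, annotation: GenomeAnnotation, exclusion_region: Tuple[str, int, int]
    ) -> List[DERecord]:
        rng, cfg = self.rng_de, self.cfg
        eligible = [
            tx for tx in annotation.sorted_transcripts()
            if tx.class_code == "reference"
            and self.truth.records.get(tx.transcript_id,
                                       TruthRecord("", "")).fate == "kept"
        ]
        chosen = eligible[: cfg.n_de_features]
        records: List[DERecord] = []
        for tx in chosen:
            tid = tx.transcript_id
            in_region = (
                tx.chrom == exclusion_region[0]
                and exclusion_region[1] <= tx.start < exclusion_region[2]
            )
            pattern = rng.choice(
                ["up", "down", "null", "discordant", "notest", "lowdata"],
                p=[0.30, 0.15, 0.25, 0.10, 0.12, 0.08],
            )
            rpkm_a = float(np.round(rng.lognormal(2.0, 1.0), 2)) + 0.01
            if pattern in ("up", "down"):
                lfc = float(rng.uniform(*cfg.de_lfc_sig))
                lfc = lfc if pattern == "up" else -lfc
                q = float(rng.uniform(*cfg.de_q_sig))
                status = "OK"
                self.truth.de_truth[tid] = "excluded" if in_region else pattern
            elif pattern == "null":
                lfc = float(rng.uniform(-0.99, 0.99))
                q = float(rng.uniform(0.06, 1.0))
                status = "OK"
                self.truth.de_truth[tid] = "not_sig"
            elif pattern == "discordant":
                lfc = float(rng.uniform(1.0, 3.0)) * (1 if rng.random() < 0.5 else -1)
                q = float(rng.uniform(0.06, 1.0))
                status = "OK"
                self.truth.de_truth[tid] = "not_sig"
            else:
                status = pattern.upper()
                self.truth.de_truth[tid] = "not_expressed"
                records.append(
                    DERecord(feature_id=tid, status=status, chrom=tx.chrom,
                             position=tx.start)
                )
                continue
            rpkm_b = rpkm_a * 2.0 ** lfc
            records.append(
                DERecord(
                    feature_id=tid, status=status, rpkm_a=rpkm_a, rpkm_b=rpkm_b,
                    log2fc=lfc, q_value=q, chrom=tx.chrom, position=tx.start,
                )
            )
        return records

    # ------------------------------------------------------------------ run
    def run(self) -> SimResult:
        cfg = self.cfg
        self.build_libraries()
        n_plain_coding = max(0, cfg.n_coding - cfg.n_j_isoforms - cfg.n_o_overlap)
        for i in range(cfg.n_j_isoforms):
            self.add_coding_unit(strand="+", with_j=True)
        for i in range(cfg.n_o_overlap):
            self.add_coding_unit(strand="+", with_o=True)
        for i in range(n_plain_coding):
            self.add_coding_unit()
        for _ in range(cfg.n_nat_coding):
            self.add_nat_unit("coding_mRNA", qualifying=True)
        for _ in range(cfg.n_nat_decoy):
            self.add_nat_unit("coding_mRNA", qualifying=False)
        for _ in range(cfg.n_nat_sirna):
            self.add_nat_unit("siRNA_precursor", qualifying=True)
        for _ in range(cfg.n_nat_nat_pairs):
            self.add_nat_nat_unit()
        for _ in range(cfg.n_lincrna):
            self.add_lincrna_unit()
        for _ in range(cfg.n_linc_perfect_target):
            self.add_lincrna_unit(target="perfect")
        for _ in range(cfg.n_linc_near_target):
            self.add_lincrna_unit(target="near_exact")
        for _ in range(cfg.n_sirna):
            self.add_sirna_unit()
        for _ in range(cfg.n_te_hc):
            self.add_te_unit("HC")
        for _ in range(cfg.n_te_pr):
            self.add_te_unit("PR")
        for _ in range(cfg.n_u_chains):
            self.add_u_chain_unit()
        for _ in range(cfg.n_u_isolated):
            self.add_u_isolated_unit()
        for _ in range(cfg.n_dup_ref_pairs):
            self.add_dup_ref_unit()
        for _ in range(cfg.n_short_novel):
            self.add_short_novel_unit()
        for _ in range(cfg.n_est // 2):
            self.add_est_unit()

        genome, annotation, est_novel = self.place_units()
        est_dup = self.add_duplicate_ests(annotation)
        est_set = GenomeAnnotation(
            list(est_novel.sorted_transcripts()) + list(est_dup.sorted_transcripts())
        )
        exclusion_region = ("chr1", 0, cfg.exclusion_region_width)
        de_records = self.build_de_table(annotation, exclusion_region)

        protein_entries = dict(self.proteins)
        rngp = self.rng_lib
        for i in range(cfg.n_protein_decoys):
            aa_len = int(rngp.integers(100, 400))
            aas = "ACDEFGHIKLNPQRSTVWY"  # Met-free decoys
            protein_entries[f"P_decoy{i + 1:04d}"] = "".join(
                aas[j] for j in rngp.integers(0, len(aas), aa_len)
            )
        libraries = {
            "smallrna": self.smallrna_lib,
            "te": self.te_lib,
            "protein": SequenceLibrary("proteins_synthetic", "protein", protein_entries),
            "cds": SequenceLibrary("coding_cds_synthetic", "cds", dict(self.cds)),
        }
        return SimResult(
            genome=genome,
            annotation=annotation,
            est_set=est_set,
            libraries=libraries,
            de_records=de_records,
            exclusion_region=exclusion_region,
            truth=self.truth,
            config=cfg,
        )


def simulate(config: Optional[SimConfig] = None) -> SimResult:
    """Generate a full synthetic dataset with planted ground truth."""
    return _Generator(config or SimConfig()).run()


def write_outputs(result: SimResult, outdir: Union[str, Path]) -> Dict[str, Path]:
    """Write genome FASTA, annotation GTFs, libraries, DE table and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    write_fasta(result.genome, paths["genome"])
    paths["annotation"] = outdir / "annotation.gtf"
    write_gtf(result.annotation, paths["annotation"])
    paths["est"] = outdir / "est.gtf"
    write_gtf(result.est_set, paths["est"])
    for key, lib in result.libraries.items():
        p = outdir / f"{key}.fa"
        if lib.role == "te":
            entries = {
                f"{k}#{lib.te_meta[k][0]}#{lib.te_meta[k][1]}": v
                for k, v in lib.entries.items()
            }
        else:
            entries = lib.entries
        write_fasta(entries, p)
        paths[key] = p
    paths["de_table"] = outdir / "de_table.tsv"
    with open(paths["de_table"], "w") as fh:
        fh.write("feature_id\tstatus\trpkm_a\trpkm_b\tlog2fc\tq_value\tchrom\tposition\n")
        for r in result.de_records:
            fh.write(
                f"{r.feature_id}\t{r.status}\t{_fmt(r.rpkm_a)}\t{_fmt(r.rpkm_b)}\t"
                f"{_fmt(r.log2fc)}\t{_fmt(r.q_value)}\t{r.chrom or ''}\t"
                f"{'' if r.position is None else r.position}\n"
            )
    paths["truth"] = outdir / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write(
            "transcript_id\tcategory\tclass_code\tte_confidence\tte_superfamily\t"
            "nat_partners\tlinc_target_class\tfate\n"
        )
        for tid in sorted(result.truth.records):
            t = result.truth.records[tid]
            fh.write(
                f"{tid}\t{t.category}\t{t.class_code}\t{t.te_confidence}\t"
                f"{t.te_superfamily}\t{','.join(t.nat_partners)}\t"
                f"{t.linc_target_class}\t{t.fate}\n"
            )
    return paths


def _fmt(x: float) -> str:
    return "" if (x is None or (isinstance(x, float) and math.isnan(x))) else f"{x:.6g}"
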
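"""GTF / FASTA / DE-table I/O and transcript sequence extraction.

GTF is 1-based with closed intervals; the reader converts to the package's
0-based half-open convention and the writer converts back, so a
read -> write -> read round trip is lossless for every parsed field.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .models import CLASS_CODES, DERecord, GenomeAnnotation, SequenceLibrary, TranscriptModel

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(
    path: Union[str, Path],
    source_tag: str = "lncraft",
    class_code_attr: str = "class_code",
) -> GenomeAnnotation:
    """Read exon records from a GTF file into a :class:`GenomeAnnotation`.

    Exons sharing a ``transcript_id`` are grouped into one transcript; the
    class code is read from ``class_code_attr`` (defaulting to ``reference``
    when the attribute is absent). Malformed lines raise with their line
    number.
    """
    groups: Dict[str, dict] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GTF line {lineno}: expected 9 fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}: malformed GTF line {lineno}: bad coordinates")
            if strand not in ("+", "-", "."):
                raise ValueError(f"{path}: malformed GTF line {lineno}: bad strand {strand!r}")
            attr = _parse_attributes(attrs)
            tid = attr.get("transcript_id")
            if not tid:
                raise ValueError(f"{path}: GTF line {lineno}: exon without transcript_id")
            gid = attr.get("gene_id", tid)
            code = attr.get(class_code_attr, "reference")
            if code not in CLASS_CODES:
                raise ValueError(
                    f"{path}: GTF line {lineno}: unknown class code {code!r}"
                )
            rec = groups.get(tid)
            if rec is None:
                rec = groups[tid] = {
                    "gene_id": gid,
                    "chrom": chrom,
                    "strand": strand,
                    "class_code": code,
                    "exons": [],
                }
                order.append(tid)
            rec["exons"].append((start_i - 1, end_i))  # 1-based closed -> 0-based half-open
    ann = GenomeAnnotation()
    for tid in order:
        rec = groups[tid]
        ann.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=rec["exons"],
                class_code=rec["class_code"],
            )
        )
    return ann


def write_gtf(
    annotation: GenomeAnnotation,
    path: Union[str, Path],
    source_tag: str = "lncraft",
    class_code_attr: str = "class_code",
) -> None:
    """Write one exon line per exon, 1-based closed coordinates."""
    with open(path, "w") as fh:
        fh.write("##gtf produced by lncraft\n")
        for tx in annotation.sorted_transcripts():
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            if tx.class_code != "reference":
                attrs += f' {class_code_attr} "{tx.class_code}";'
            if tx.aliases:
                attrs += f' aliases "{",".join(tx.aliases)}";'
            for a, b in tx.exons:
                fh.write(
                    f"{tx.chrom}\t{source_tag}\texon\t{a + 1}\t{b}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def write_bed(annotation: GenomeAnnotation, path: Union[str, Path]) -> None:
    """BED6 export (one line per transcript span)."""
    with open(path, "w") as fh:
        for tx in annotation.sorted_transcripts():
            strand = tx.strand if tx.strand in ("+", "-") else "."
            fh.write(
                f"{tx.chrom}\t{tx.start}\t{tx.end}\t{tx.transcript_id}\t0\t{strand}\n"
            )


def read_fasta(
    path: Union[str, Path], name: str = "", role: str = "cds"
) -> SequenceLibrary:
    """Load a FASTA file into a :class:`SequenceLibrary`.

    For ``role="te"``, family and superfamily are parsed from headers of the
    form ``>id#family#superfamily``.
    """
    entries: Dict[str, str] = {}
    te_meta: Dict[str, tuple] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if role == "te":
            parts = record.id.split("#")
            if len(parts) < 3:
                raise ValueError(
                    f"TE FASTA header without family/superfamily: {record.id}"
                )
            entries[parts[0]] = seq
            te_meta[parts[0]] = (parts[1], parts[2])
        else:
            entries[record.id] = seq
    return SequenceLibrary(
        name=name or Path(path).stem, role=role, entries=entries, te_meta=te_meta
    )


def write_fasta(entries: Mapping[str, str], path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in entries.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_transcript_sequences(
    annotation: GenomeAnnotation, genome: Mapping[str, str]
) -> GenomeAnnotation:
    """Fill ``sequence`` for every transcript: concatenated exon sequence,
    reverse-complemented for ``-`` strand. Modifies in place and returns the
    annotation."""
    for tx in annotation:
        if tx.chrom not in genome:
            raise ValueError(f"transcript {tx.transcript_id}: unknown contig {tx.chrom}")
        contig = genome[tx.chrom]
        if tx.end > len(contig):
            raise ValueError(
                f"transcript {tx.transcript_id}: exon beyond end of {tx.chrom}"
            )
        parts = [str(contig[a:b]) for a, b in tx.exons]
        seq = "".join(parts).upper()
        if tx.strand == "-":
            seq = revcomp(seq)
        if len(seq) != tx.length_nt:
            raise ValueError(f"transcript {tx.transcript_id}: sequence length mismatch")
        tx.sequence = seq
    return annotation


_DE_COLUMNS = {
    "feature_id": ("feature_id", "id", "isoform", "gene", "test_id"),
    "status": ("status",),
    "rpkm_a": ("rpkm_a", "value_1", "control"),
    "rpkm_b": ("rpkm_b", "value_2", "stress"),
    "log2fc": ("log2fc", "log2_fold_change", "log2 fc", "log2fc_b_vs_a"),
    "q_value": ("q_value", "q",),
    "level": ("level",),
    "chrom": ("chrom",),
    "position": ("position",),
}


def _to_float(x) -> float:
    """Parse a decimal that may use a comma separator (as printed in some
    tables, e.g. ``10,14`` for 10.14). Blank -> NaN."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    s = str(x).strip()
    if not s or s.lower() == "nan":
        return float("nan")
    if "," in s and "." not in s:
        s = s.replace(",", ".")
    return float(s)


def read_de_table(
    path: Union[str, Path],
    columns: Optional[Mapping[str, str]] = None,
) -> List[DERecord]:
    """Read a Cuffdiff-style TSV of differential-expression tests.

    Column names are matched case-insensitively against common aliases
    (feature_id/isoform/gene, status, rpkm_a/value_1, rpkm_b/value_2,
    log2fc, q_value); ``columns`` maps canonical name -> actual header to
    override. Decimal commas are accepted.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    lower = {c.lower().strip(): c for c in df.columns}
    resolved: Dict[str, str] = {}
    for canon, aliases in _DE_COLUMNS.items():
        if columns and canon in columns:
            resolved[canon] = columns[canon]
            continue
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    for required in ("feature_id", "status"):
        if required not in resolved:
            raise ValueError(f"{path}: missing required DE column {required!r}")
    records: List[DERecord] = []
    for _, row in df.iterrows():
        def col(name, default=None):
            c = resolved.get(name)
            return row[c] if c is not None else default

        status = str(col("status")).strip().upper()
        rec = DERecord(
            feature_id=str(col("feature_id")).strip(),
            status=status,
            rpkm_a=_to_float(col("rpkm_a")),
            rpkm_b=_to_float(col("rpkm_b")),
            log2fc=_to_float(col("log2fc")),
            q_value=_to_float(col("q_value")),
            level=str(col("level", "transcript")).strip(),
            chrom=(str(col("chrom")).strip() if pd.notna(col("chrom", float("nan"))) else None),
            position=(
                int(float(col("position")))
                if pd.notna(_to_float(col("position")))
                else None
            ),
        )
        records.append(rec)
    return records


def write_report(
    tables: Mapping[str, pd.DataFrame], outdir: Union[str, Path]
) -> List[Path]:
    """Write each named table as a TSV with deterministic order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        path = outdir / f"{name}.tsv"
        tables[name].to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
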
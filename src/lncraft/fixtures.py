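"""Reference fixture tables from the maize B73 leaf total-transcriptome
reannotation that this pipeline reimplements.

These are the published summary numbers of that analysis at full scale
(160,488 transcripts): the per-class coding/non-coding classification
counts, the TE-superfamily tabulation of up-regulated transcripts in the
three differential-expression comparisons, and RPKM worked examples for
selected loci. They serve as arithmetic fixtures — consistency of totals,
recomputation of printed percentages and fold changes — not as outputs the
desk-scale synthetic pipeline could regenerate.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Union

import pandas as pd

# classification summary: transcripts per annotation class, split into
# coding vs potential lncRNA, with the pot-lncRNA subclassification
CLASSIFICATION_SUMMARY_ROWS = [
    # class, coding, pot_lncRNA, lncRNA, siRNA_prec, TEs
    ("Equal", 102_299, 31_364, 11_815, 18_526, 1_023),
    ("Class J", 19_796, 1_603, 386, 1_181, 36),
    ("Class U", 995, 1_669, 625, 1_005, 39),
    ("Class O", 627, 363, 96, 257, 10),
    ("Class X", 103, 288, 116, 164, 8),
    ("Previously annotated ncRNAs", 517, 864, 349, 491, 24),
]
CLASSIFICATION_SUMMARY_TOTALS = {
    "coding": 124_337,
    "pot_lncRNA": 36_151,
    "lncRNA": 13_387,
    "siRNA_prec": 21_624,
    "TEs": 1_140,
}

# reference-annotation vs RABT pot-lncRNA shares
POT_LNC_SHARES = {
    "reference": {"pot_lncRNA": 31_364, "total": 133_663},
    "rabt": {"pot_lncRNA": 3_923, "total": 25_444},
}

# truly-lncRNA split and published length statistics
NAT_LINC_SPLIT = {"lncNAT": 3_012, "lincRNA": 10_375}
NAT_PAIR_COUNTS = {"coding_mRNA": 2_157, "lncNAT": 750, "siRNA_precursor": 330}
LINC_TARGET_COUNTS = {"perfect": 575, "near_exact": 1_780}
LENGTH_STATS = {
    "lncNAT": {"min": 201, "max": 3_780, "mean": 535},
    "lincRNA": {"min": 201, "max": 4_179, "mean": 465},
}

# TE-superfamily tabulation of up-regulated transcripts per DE comparison
TE_SUPERFAMILY_ROWS = [
    # superfamily, b73_stress, rmr6_stress, rmr6_vs_b73 (counts)
    ("RLG-Gypsy", 28, 21, 42),
    ("RLC-Copia", 6, 7, 35),
    ("RLX-Unknown LTR", 9, 2, 12),
    ("RIL-L1", 1, 0, 0),
    ("DTA-hAT", 13, 3, 4),
    ("DTC-CACTA", 4, 4, 10),
    ("DHH-Helitron", 2, 3, 1),
    ("DTM-Mutator", 3, 0, 5),
    ("DTH-PIF/Harbinger", 3, 2, 5),
    ("DTT-Tc1/Mariner", 1, 1, 1),
    ("RST-tRNA", 0, 0, 2),
]
TE_TOTALS = {
    "b73_stress": {"te_related": 70, "de_transcripts": 1_094},
    "rmr6_stress": {"te_related": 43, "de_transcripts": 310},
    "rmr6_vs_b73": {"te_related": 117, "de_transcripts": 622},
}

# RPKM worked examples (TSV text kept verbatim, including one decimal-comma
# cell, to exercise the DE-table dialect handling)
RPKM_TPS_LOCUS_TSV = """\
feature_id\tstatus\trpkm_a\trpkm_b\tlog2fc\tcomparison
GRMZM2G046615\tOK\t7.68\t45.13\t2.55\tB73
GRMZM2G046615\tOK\t10,14\t25.32\t1.32\trmr6
GRMZM2G046615_T01\tNOTEST\t0\t0.12\t\tB73
GRMZM2G046615_T01_j_1\tNOTEST\t0\t0.14\t\tB73
GRMZM2G046615_T01_j_2\tNOTEST\t0\t0.14\t\tB73
GRMZM2G046615_T01_j_3\tOK\t7.67\t44.73\t2.54\tB73
GRMZM2G046615_T01_j_3\tOK\t10.08\t25.15\t1.32\trmr6
"""

RPKM_TCONS_TSV = """\
feature_id\tstatus\trpkm_a\trpkm_b\tlog2fc\tcomparison
TCONS_00086791\tOK\t0\t1.08\t6.77\tB73
TCONS_00086791\tOK\t1.26\t1.53\t0.28\trmr6
TCONS_00073784\tOK\t0\t1.14\t6.84\tB73
TCONS_00073784\tOK\t0\t3.27\t8.36\trmr6
Cluster_t_304\tOK\t0.94\t5.30\t2.47\tB73
Cluster_t_304\tOK\t1.08\t4.07\t2.17\trmr6
"""

RPKM_LNCRNA_TARGETS_TSV = """\
feature_id\tstatus\trpkm_a\trpkm_b\tlog2fc\tcomparison
GRMZM6G851663_T01\tOK\t16.88\t65.19\t1.95\tB73
GRMZM6G851663_T01\tOK\t29.35\t85.30\t1.54\trmr6
GRMZM2G320373_T01\tOK\t4.26\t26.37\t2.62\tB73
GRMZM2G320373_T01\tOK\t8.62\t30.94\t1.84\trmr6
GRMZM2G004909_T01\tOK\t17.25\t62.71\t1.86\tB73
GRMZM2G137329_T01\tOK\t70.10\t199.62\t1.51\tB73
GRMZM2G170044_T01\tOK\t10.59\t24.52\t1.21\tB73
"""


def classification_summary() -> pd.DataFrame:
    return pd.DataFrame(
        CLASSIFICATION_SUMMARY_ROWS,
        columns=["transcript_class", "coding", "pot_lncRNA", "lncRNA", "siRNA_prec", "TEs"],
    )


def te_superfamily_counts() -> pd.DataFrame:
    return pd.DataFrame(
        TE_SUPERFAMILY_ROWS,
        columns=["superfamily", "b73_stress", "rmr6_stress", "rmr6_vs_b73"],
    )


def emit_fixture_tables(outdir: Union[str, Path]) -> Dict[str, Path]:
    """Write the fixture tables as TSVs; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    paths["classification_summary"] = outdir / "classification_summary.tsv"
    classification_summary().to_csv(paths["classification_summary"], sep="\t", index=False)
    paths["te_superfamilies"] = outdir / "te_superfamilies.tsv"
    te_superfamily_counts().to_csv(paths["te_superfamilies"], sep="\t", index=False)
    for name, text in (
        ("rpkm_tps_locus", RPKM_TPS_LOCUS_TSV),
        ("rpkm_tcons", RPKM_TCONS_TSV),
        ("rpkm_lncrna_targets", RPKM_LNCRNA_TARGETS_TSV),
    ):
        paths[name] = outdir / f"{name}.tsv"
        paths[name].write_text(text)
    return paths
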
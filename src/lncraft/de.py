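"""Differential-expression table filtering and cross-tabulation.

Significance filter: test status OK, |log2FC| >= 1 and FDR-adjusted
q <= 0.05 (both bounds inclusive), outside an optional genomic exclusion
region (used to drop genes around an introgressed mutant locus whose
apparent misregulation reflects sequence polymorphism rather than biology).
Features with status NOTEST or LOWDATA are treated as not expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
from scipy import stats

from .models import DERecord


@dataclass
class DEFilterParams:
    min_abs_log2fc: float = 1.0
    max_q: float = 0.05
    excluded_statuses: Set[str] = field(default_factory=lambda: {"NOTEST", "LOWDATA"})
    exclusion_region: Optional[Tuple[str, int, int]] = None

    def __post_init__(self) -> None:
        if self.min_abs_log2fc <= 0 or self.max_q <= 0:
            raise ValueError("DE thresholds must be positive")
        if self.exclusion_region is not None:
            chrom, start, end = self.exclusion_region
            if end <= start:
                raise ValueError("malformed exclusion region")


def compute_log2fc(rpkm_a: float, rpkm_b: float) -> float:
    """log2(rpkm_b / rpkm_a); both values must be positive (a zero baseline
    has no ratio-arithmetic fold change and is flagged by the caller)."""
    if not (rpkm_a > 0 and rpkm_b > 0):
        raise ValueError("RPKM values must be positive to form a fold change")
    return math.log2(rpkm_b / rpkm_a)


def _in_region(rec: DERecord, region: Optional[Tuple[str, int, int]]) -> bool:
    if region is None or rec.chrom is None or rec.position is None:
        return False
    chrom, start, end = region
    return rec.chrom == chrom and start <= rec.position < end


def filter_de(
    records: Sequence[DERecord], params: Optional[DEFilterParams] = None
) -> Tuple[List[DERecord], List[DERecord], List[DERecord]]:
    """(significant, up, down) under the standard significance thresholds."""
    params = params or DEFilterParams()
    significant: List[DERecord] = []
    for rec in records:
        if rec.status != "OK" or rec.status in params.excluded_statuses:
            continue
        if math.isnan(rec.log2fc) or math.isnan(rec.q_value):
            continue
        if abs(rec.log2fc) < params.min_abs_log2fc:
            continue
        if rec.q_value > params.max_q:
            continue
        if _in_region(rec, params.exclusion_region):
            continue
        significant.append(rec)
    up = [r for r in significant if r.log2fc > 0]
    down = [r for r in significant if r.log2fc < 0]
    return significant, up, down


def cross_tabulate(
    significant: Sequence[DERecord],
    categories: Mapping[str, str],
    by: str = "category",
) -> pd.DataFrame:
    """Up/down counts per feature category.

    ``categories`` maps feature id to a label (an annotation class code or
    a coding/lncRNA/siRNA-precursor/TE-related category); unknown features
    are tabulated under ``unclassified``."""
    counts: Dict[str, Dict[str, int]] = {}
    for rec in significant:
        label = categories.get(rec.feature_id, "unclassified")
        row = counts.setdefault(label, {"up": 0, "down": 0})
        row["up" if rec.log2fc > 0 else "down"] += 1
    rows = [
        {by: label, "up": c["up"], "down": c["down"], "total": c["up"] + c["down"]}
        for label, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=[by, "up", "down", "total"])


def intersect_sets(sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Sizes of every non-empty combination of the named sets (the numbers
    behind a Venn diagram), both as plain intersections and as exclusive
    regions."""
    named = {k: set(v) for k, v in sets.items()}
    if len(named) < 2:
        raise ValueError("need at least two sets")
    names = sorted(named)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(named[c] for c in combo))
            exclusive = inter - set.union(
                set(), *(named[n] for n in names if n not in combo)
            )
            rows.append(
                {
                    "sets": "&".join(combo),
                    "intersection": len(inter),
                    "exclusive": len(exclusive),
                }
            )
    return pd.DataFrame(rows)


def correlate_lfc(pairs: Sequence[Tuple[float, float]]) -> float:
    """Pearson product-moment correlation of paired fold changes."""
    if len(pairs) < 3:
        raise ValueError("need at least three pairs")
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise ValueError("zero variance in one coordinate")
    r, _ = stats.pearsonr(xs, ys)
    return float(r)
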
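"""Clonal relatedness of tumor pairs from focal CNV sets.

Two tumors from the same animal are compared by matching their focal CNV
segments (same chromosome, same sign, >= 50% reciprocal overlap by default)
and computing the Jaccard index J = m / (|a| + |b| - m) over matched
segments. Each tumor's J against its partner is then standardized against
that tumor's own null — its Jaccard indices against every tumor from other
animals — giving two Z-scores per pair. A pair is strongly related if both
Z > 1.96, weakly related if exactly one is, and unrelated otherwise.

The test is deliberately asymmetric: a small tumor nested inside a large
one can look exceptional from the small tumor's side only, which is why it
is run in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acgh import CNVSegment

Z_CRITICAL = 1.96  # 95% two-sided normal critical value


def merge_segments(segments: list[CNVSegment]) -> list[CNVSegment]:
    """Merge overlapping same-sign segments on the same chromosome."""
    out: list[CNVSegment] = []
    key = lambda s: (s.chrom, s.sign, s.start, s.end)
    for seg in sorted(segments, key=key):
        if out and out[-1].chrom == seg.chrom and out[-1].sign == seg.sign and seg.start < out[-1].end:
            prev = out.pop()
            seg = CNVSegment(
                prev.chrom, prev.start, max(prev.end, seg.end), prev.sign,
                (prev.mean_ratio + seg.mean_ratio) / 2, prev.n_probes + seg.n_probes,
            )
        out.append(seg)
    return out


@dataclass
class TumorCNVSet:
    """One tumor's focal CNV segments with mouse grouping metadata."""

    tumor_id: str
    mouse_id: str
    tumor_class: str
    segments: list[CNVSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mouse_id:
            raise ValueError("mouse_id must be non-empty")
        self.segments = merge_segments(self.segments)

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class PairRelatedness:
    tumor_a: str
    tumor_b: str
    jaccard: float
    z_a: float
    z_b: float
    classification: str  # unrelated | weak | strong


def _reciprocal_overlap(a: CNVSegment, b: CNVSegment) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def match_segments(
    a: TumorCNVSet,
    b: TumorCNVSet,
    min_reciprocal_overlap: float = 0.5,
) -> list[tuple[CNVSegment, CNVSegment]]:
    """Greedy one-to-one matching of same-sign, same-chromosome segments.

    Candidate pairs with reciprocal overlap >= the threshold are accepted in
    descending overlap order, each segment matched at most once.
    """
    if not (0 < min_reciprocal_overlap <= 1):
        raise ValueError("min_reciprocal_overlap must be in (0, 1]")
    candidates = []
    for i, sa in enumerate(a.segments):
        for j, sb in enumerate(b.segments):
            if sa.chrom != sb.chrom or sa.sign != sb.sign:
                continue
            ov = _reciprocal_overlap(sa, sb)
            if ov >= min_reciprocal_overlap:
                candidates.append((ov, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((a.segments[i], b.segments[j]))
    return matches


def jaccard_index(
    a: TumorCNVSet,
    b: TumorCNVSet,
    min_reciprocal_overlap: float = 0.5,
) -> float:
    """J = m / (|a| + |b| - m) over matched segments; error if both empty."""
    if len(a) == 0 and len(b) == 0:
        raise ValueError("Jaccard undefined for two empty CNV sets")
    m = len(match_segments(a, b, min_reciprocal_overlap))
    return m / (len(a) + len(b) - m)


def tumor_z_score(
    t: TumorCNVSet,
    partner: TumorCNVSet,
    cohort: list[TumorCNVSet],
    min_reciprocal_overlap: float = 0.5,
) -> float:
    """Z-score of J(t, partner) against t's cross-mouse Jaccard null.

    The null sample is J(t, v) for every cohort tumor v from a different
    mouse than t; the Z uses the sample (n-1) standard deviation.
    """
    null = [
        jaccard_index(t, v, min_reciprocal_overlap)
        for v in cohort
        if v.mouse_id != t.mouse_id
    ]
    if len(null) < 2:
        raise ValueError("need >= 2 tumors from other mice for the null")
    null_arr = np.asarray(null, dtype=float)
    sd = float(null_arr.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate null: all cross-mouse Jaccard values equal")
    j = jaccard_index(t, partner, min_reciprocal_overlap)
    return (j - float(null_arr.mean())) / sd


def classify_pair(z_a: float, z_b: float, z_crit: float = Z_CRITICAL) -> str:
    """strong if both Z > z*, weak if exactly one, else unrelated."""
    n_sig = int(z_a > z_crit) + int(z_b > z_crit)
    return {2: "strong", 1: "weak", 0: "unrelated"}[n_sig]


@dataclass
class RelatednessResults:
    """Per-pair relatedness table plus cohort-level classification counts."""

    table: pd.DataFrame
    z_crit: float
    min_reciprocal_overlap: float

    @property
    def counts(self) -> dict[str, int]:
        c = self.table["classification"].value_counts()
        return {k: int(c.get(k, 0)) for k in ("strong", "weak", "unrelated")}

    def summary(self) -> str:
        lines = [
            "Tumor pair relatedness (two-way Jaccard Z test)",
            f"  z* = {self.z_crit:g}, reciprocal overlap >= {self.min_reciprocal_overlap:g}",
            "",
            f"{'mouse':<10}{'tumor A':<10}{'Z_A':>8}{'tumor B':<12}{'Z_B':>8}  call",
        ]
        stars = {"strong": "**", "weak": "*", "unrelated": ""}
        for _, row in self.table.iterrows():
            lines.append(
                f"{row['mouse_id']:<10}{row['tumor_a']:<10}{row['z_a']:>8.2f}"
                f"  {row['tumor_b']:<10}{row['z_b']:>8.2f}  "
                f"{row['classification']}{stars[row['classification']]}"
            )
        c = self.counts
        lines.append("")
        lines.append(
            f"  strong: {c['strong']}  weak: {c['weak']}  unrelated: {c['unrelated']}"
        )
        return "\n".join(lines)


def relatedness_report(
    cohort: list[TumorCNVSet],
    pairs: list[tuple[str, str]] | None = None,
    min_reciprocal_overlap: float = 0.5,
    z_crit: float = Z_CRITICAL,
) -> RelatednessResults:
    """Run the two-way test for every within-mouse tumor pair.

    ``pairs`` is an optional explicit list of (tumor_id, tumor_id); when
    omitted, every within-mouse pair in the cohort is tested. Every pair must
    lie within one mouse.
    """
    by_id = {t.tumor_id: t for t in cohort}
    if pairs is None:
        pairs = []
        by_mouse: dict[str, list[TumorCNVSet]] = {}
        for t in cohort:
            by_mouse.setdefault(t.mouse_id, []).append(t)
        for tumors in by_mouse.values():
            for i in range(len(tumors)):
                for j in range(i + 1, len(tumors)):
                    pairs.append((tumors[i].tumor_id, tumors[j].tumor_id))
    rows = []
    for id_a, id_b in pairs:
        a, b = by_id[id_a], by_id[id_b]
        if a.mouse_id != b.mouse_id:
            raise ValueError(f"pair ({id_a}, {id_b}) spans two mice")
        j = jaccard_index(a, b, min_reciprocal_overlap)
        z_a = tumor_z_score(a, b, cohort, min_reciprocal_overlap)
        z_b = tumor_z_score(b, a, cohort, min_reciprocal_overlap)
        rows.append(
            {
                "mouse_id": a.mouse_id,
                "tumor_a": id_a,
                "tumor_b": id_b,
                "jaccard": j,
                "z_a": z_a,
                "z_b": z_b,
                "classification": classify_pair(z_a, z_b, z_crit),
            }
        )
    return RelatednessResults(pd.DataFrame(rows), z_crit, min_reciprocal_overlap)
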
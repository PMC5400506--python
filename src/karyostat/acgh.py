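"""Bulk aCGH scoring.

Input is a probe-level log2 tumor/normal ratio profile ("aCGH ratio"), assumed
pre-normalized. The operations here reproduce a threshold-based karyotype
workflow:

* per-chromosome mean ratio with a symmetric +/- tau call cut-off
  (tau = 0.3 log2 units by default),
* within-chromosome normalization (probe ratio minus the chromosome mean),
  which isolates focal events from whole-chromosome dosage,
* focal amplification/deletion segments as runs of consecutive normalized
  (optionally smoothed) probes beyond +/- tau,
* aneuploidy burden as the sum over chromosomes of |mean ratio|,
* dosage--expression Pearson correlation across chromosomes,
* a cohort overlay counting tumors beyond the threshold per genomic bin,
* a three-probe test of locus recombination (one probe inside a deleted
  fragment, flanking probes on each side).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeLayout


@dataclass(frozen=True)
class CNVSegment:
    """A focal amplification or deletion interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    sign: str  # "amplification" | "deletion"
    mean_ratio: float = 0.0
    n_probes: int = 0
    gene_count: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must be < end")
        if self.sign not in ("amplification", "deletion"):
            raise ValueError(f"invalid sign {self.sign!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ScoringParams:
    """Thresholds and windows for aCGH scoring.

    threshold : call cut-off tau on the log2 scale (gain at >= +tau,
        loss at <= -tau, both inclusive).
    window : centered moving-average window (probes) applied to the
        chromosome-normalized ratio before focal detection only; window 1
        means no smoothing. Never applied to chromosome means.
    min_probes : minimum consecutive probes beyond the cut-off required to
        report a focal segment.
    autosomes_only : drop probes on chrX/chrY before any scoring.
    """

    threshold: float = 0.3
    window: int = 3
    min_probes: int = 3
    autosomes_only: bool = True
    deletion_threshold: float = 0.8  # tau_del for the recombination probe test

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd integer")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")


_PROBE_COLUMNS = ["probe_id", "chrom", "start", "end", "log2_ratio"]
_SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass
class ProbeProfile:
    """Ordered probe-level log2 tumor/normal ratios for one sample."""

    sample_id: str
    probes: pd.DataFrame
    chrom_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in _PROBE_COLUMNS if c not in self.probes.columns]
        if missing:
            raise ValueError(f"probe table missing columns: {missing}")
        if not self.chrom_order:
            self.chrom_order = list(dict.fromkeys(self.probes["chrom"]))
        if not np.isfinite(self.probes["log2_ratio"].to_numpy(dtype=float)).all():
            raise ValueError("log2 ratios must be finite")
        order = {c: i for i, c in enumerate(self.chrom_order)}
        codes = self.probes["chrom"].map(order)
        if codes.isna().any():
            bad = sorted(set(self.probes.loc[codes.isna(), "chrom"]))
            raise ValueError(f"chromosomes not in declared order: {bad}")
        srt = np.lexsort((self.probes["start"].to_numpy(), codes.to_numpy()))
        if not np.array_equal(srt, np.arange(len(srt))):
            self.probes = self.probes.iloc[srt].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.probes)

    def autosomal(self) -> "ProbeProfile":
        keep = ~self.probes["chrom"].isin(_SEX_CHROMS)
        return ProbeProfile(
            self.sample_id,
            self.probes.loc[keep].reset_index(drop=True),
            [c for c in self.chrom_order if c not in _SEX_CHROMS],
        )


@dataclass
class ChromosomeScoreSet:
    """Per-chromosome mean ratio, gain/loss/neutral call and probe count."""

    sample_id: str
    scores: pd.DataFrame  # chrom, mean_ratio, call, n_probes
    threshold: float

    def mean_ratios(self) -> pd.Series:
        return self.scores.set_index("chrom")["mean_ratio"]

    def calls(self) -> pd.Series:
        return self.scores.set_index("chrom")["call"]


@dataclass
class AneuploidyBurden:
    """Sum over chromosomes of the absolute mean aCGH ratio."""

    sample_id: str
    per_chromosome: pd.Series  # |mean_ratio| indexed by chrom
    total: float


def _scored_profile(profile: ProbeProfile, params: ScoringParams) -> ProbeProfile:
    return profile.autosomal() if params.autosomes_only else profile


def chromosome_scores(profile: ProbeProfile, params: ScoringParams | None = None) -> ChromosomeScoreSet:
    """Mean log2 ratio per chromosome with the +/- tau call rule.

    The call is gain if the mean is >= +tau, loss if <= -tau (both
    inclusive), neutral otherwise. Chromosomes without probes are absent
    from the result rather than reported as zero.
    """
    params = params or ScoringParams()
    profile = _scored_profile(profile, params)
    if len(profile) == 0:
        raise ValueError("empty probe profile")
    grp = profile.probes.groupby("chrom", sort=False)["log2_ratio"]
    means = grp.mean()
    counts = grp.size()
    tau = params.threshold
    call = np.where(means >= tau, "gain", np.where(means <= -tau, "loss", "neutral"))
    scores = pd.DataFrame(
        {
            "chrom": means.index,
            "mean_ratio": means.to_numpy(),
            "call": call,
            "n_probes": counts.to_numpy(),
        }
    ).reset_index(drop=True)
    return ChromosomeScoreSet(profile.sample_id, scores, tau)


def count_whole_chromosome_events(scores: ChromosomeScoreSet) -> int:
    """Number of chromosomes called gained or lost."""
    return int((scores.scores["call"] != "neutral").sum())


def normalize_within_chromosome(profile: ProbeProfile) -> ProbeProfile:
    """Subtract each chromosome's mean ratio from its probes.

    The resulting "chromosome-normalized ratio" has mean zero on every
    chromosome, so whole-chromosome gains/losses vanish and focal events
    stand out against a flat background.
    """
    if len(profile) == 0:
        raise ValueError("empty probe profile")
    probes = profile.probes.copy()
    means = probes.groupby("chrom", sort=False)["log2_ratio"].transform("mean")
    probes["log2_ratio"] = probes["log2_ratio"] - means
    return ProbeProfile(profile.sample_id, probes, list(profile.chrom_order))


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, truncated (not wrapped) at the ends."""
    if window == 1:
        return np.asarray(values, dtype=float)
    half = window // 2
    csum = np.cumsum(np.concatenate([[0.0], np.asarray(values, dtype=float)]))
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def detect_focal_cnvs(
    normalized: ProbeProfile,
    params: ScoringParams | None = None,
    gene_map: pd.DataFrame | None = None,
) -> list[CNVSegment]:
    """Focal amplification/deletion segments from a normalized profile.

    Per chromosome, the normalized ratio is smoothed with a centered moving
    average (``params.window`` probes, truncated at chromosome ends); a
    segment is a maximal run of >= ``params.min_probes`` consecutive probes
    all >= +tau (amplification) or all <= -tau (deletion). Segment bounds
    span the first to last probe interval of the run.

    ``gene_map`` is an optional BED-like frame (chrom, start, end, name);
    genes overlapping a segment by >= 1 bp are counted into ``gene_count``.
    """
    params = params or ScoringParams()
    profile = _scored_profile(normalized, params)
    segments: list[CNVSegment] = []
    for chrom, sub in profile.probes.groupby("chrom", sort=False):
        vals = moving_average(sub["log2_ratio"].to_numpy(), params.window)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        state = np.where(vals >= params.threshold, 1, np.where(vals <= -params.threshold, -1, 0))
        i = 0
        n = len(state)
        while i < n:
            if state[i] == 0:
                i += 1
                continue
            j = i
            while j < n and state[j] == state[i]:
                j += 1
            if j - i >= params.min_probes:
                segments.append(
                    CNVSegment(
                        chrom=str(chrom),
                        start=int(starts[i]),
                        end=int(ends[j - 1]),
                        sign="amplification" if state[i] > 0 else "deletion",
                        mean_ratio=float(vals[i:j].mean()),
                        n_probes=int(j - i),
                    )
                )
            i = j
    if gene_map is not None:
        segments = [
            CNVSegment(
                s.chrom, s.start, s.end, s.sign, s.mean_ratio, s.n_probes,
                gene_count=int(
                    (
                        (gene_map["chrom"] == s.chrom)
                        & (gene_map["start"] < s.end)
                        & (gene_map["end"] > s.start)
                    ).sum()
                ),
            )
            for s in segments
        ]
    return segments


def aneuploidy_burden(scores: ChromosomeScoreSet) -> AneuploidyBurden:
    """Sum of |per-chromosome mean aCGH ratio| — the aneuploidy burden."""
    per_chrom = scores.mean_ratios().abs()
    return AneuploidyBurden(scores.sample_id, per_chrom, float(per_chrom.sum()))


def dosage_correlation(
    chrom_acgh: pd.Series | dict[str, float],
    chrom_mrna: pd.Series | dict[str, float],
) -> tuple[float, float]:
    """Pearson correlation of per-chromosome aCGH ratio vs mean mRNA ratio.

    Returns (r, two-sided p). Requires >= 3 chromosomes present in both
    inputs and nonzero variance in each.
    """
    a = pd.Series(chrom_acgh, dtype=float)
    m = pd.Series(chrom_mrna, dtype=float)
    common = a.index.intersection(m.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired chromosomes")
    x = a.loc[common].to_numpy()
    y = m.loc[common].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in dosage or expression vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def cohort_threshold_overlay(
    profiles: list[ProbeProfile],
    params: ScoringParams | None = None,
    layout: GenomeLayout | None = None,
) -> pd.DataFrame:
    """Per-bin counts of tumors beyond the +/- tau threshold.

    Each profile is mapped onto the shared bin grid by averaging the probes
    falling in each bin; a tumor counts as a gain at a bin if its binned
    value is >= +tau and a loss if <= -tau. Returns a frame with chrom,
    start, end, gain_count, loss_count, n_tumors.
    """
    params = params or ScoringParams()
    if not profiles:
        raise ValueError("empty cohort")
    if layout is None:
        raise ValueError("a GenomeLayout bin grid is required")
    bins = layout.bins.copy()
    gain = np.zeros(len(bins), dtype=int)
    loss = np.zeros(len(bins), dtype=int)
    keys = pd.MultiIndex.from_frame(bins[["chrom", "start"]])
    bin_pos = {k: i for i, k in enumerate(keys)}
    width = layout.bin_width
    for profile in profiles:
        prof = _scored_profile(profile, params)
        probes = prof.probes
        bstart = (probes["start"].to_numpy() // width) * width
        binned = (
            pd.DataFrame({"chrom": probes["chrom"], "start": bstart, "v": probes["log2_ratio"]})
            .groupby(["chrom", "start"], sort=False)["v"]
            .mean()
        )
        for (chrom, start), v in binned.items():
            i = bin_pos.get((chrom, start))
            if i is None:
                continue
            if v >= params.threshold:
                gain[i] += 1
            elif v <= -params.threshold:
                loss[i] += 1
    bins["gain_count"] = gain
    bins["loss_count"] = loss
    bins["n_tumors"] = len(profiles)
    return bins


def assess_locus_recombination(
    profile: ProbeProfile,
    locus: tuple[str, int, int],
    params: ScoringParams | None = None,
) -> dict:
    """Classify a conditional locus as recombined / partially recombined / not.

    Uses the mean of probes inside the locus and the means of the flanking
    probes on each side (nearest probe on the same chromosome). With
    tau_del = ``params.deletion_threshold``:

    * recombined: inside mean <= -tau_del and both flank means within +/- tau
    * unrecombined: inside mean within +/- tau
    * partially_recombined: otherwise (intermediate inside-probe values, the
      signature of a mixed tumor/normal sample)
    """
    params = params or ScoringParams()
    chrom, start, end = locus
    probes = profile.probes[profile.probes["chrom"] == chrom]
    if probes.empty:
        raise ValueError(f"no probes on {chrom}")
    inside = probes[(probes["start"] >= start) & (probes["start"] < end)]
    left = probes[probes["start"] < start]
    right = probes[probes["start"] >= end]
    if inside.empty:
        raise ValueError("no probe inside locus")
    if left.empty or right.empty:
        raise ValueError("missing flanking probe on one side")
    inside_mean = float(inside["log2_ratio"].mean())
    left_mean = float(left.iloc[-1]["log2_ratio"])
    right_mean = float(right.iloc[0]["log2_ratio"])
    tau = params.threshold
    flanks_neutral = abs(left_mean) <= tau and abs(right_mean) <= tau
    if inside_mean <= -params.deletion_threshold and flanks_neutral:
        status = "recombined"
    elif abs(inside_mean) <= tau:
        status = "unrecombined"
    else:
        status = "partially_recombined"
    return {
        "status": status,
        "inside_mean": inside_mean,
        "left_flank": left_mean,
        "right_flank": right_mean,
    }
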
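"""Generative model of chromosome-instability (CIN) tumor lineages.

A clonal tumor is grown from a euploid founder through ``divisions``
synchronous division rounds. At each division every chromosome of every cell
independently mis-segregates with probability ``p_mis``; a mis-segregation is
reciprocal — one daughter gains a copy, the other loses one. Cells that lose
all copies of any chromosome (nullisomy) are non-viable; an optional fitness
map can weight other karyotypes. The terminal population is collapsed to a
clone table (unique karyotypes with weights).

Downstream renderers turn a clone table into the two observable data types:

* single-cell binned read counts — each cell draws its clone from the clone
  weights and scatters a fixed read budget over genomic bins proportional to
  bin copy number x bin width (shallow-sequencing multinomial model);
* pseudo-bulk aCGH probe profiles — the clone mixture is diluted with
  normal cells at purity ``f`` and each probe reports
  log2((f * sum_c w_c * s_cp + (1-f) * P) / P) plus Gaussian noise.

A cohort generator emits per-mouse tumor pairs whose focal CNV sets share a
configured fraction of ancestral segments, for exercising the relatedness
test against a truth-labelled cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from .acgh import CNVSegment, ProbeProfile
from .genome import GenomeLayout, mouse_autosomes
from .relatedness import TumorCNVSet

# Copy-number floor replacing zero numerators before log2; keeps homozygous
# deletions strongly negative (log2(0.05/2) ~ -5.3) without producing -inf.
COPY_FLOOR = 0.05


@dataclass
class SimConfig:
    """Full parameterization of the CIN lineage generator.

    ploidy : founder copy number per chromosome (2 = diploid).
    p_mis : per-chromosome per-division mis-segregation probability.
    divisions : synchronous division rounds from the founder.
    fitness : optional map karyotype tuple -> relative weight; nullisomic
        karyotypes always get weight 0 regardless.
    focal_rate : expected (Poisson) count of private focal CNVs per clone
        lineage.
    focal_size_bp : mean focal segment size (exponential, floored at 200 kb).
    shared_fraction : fraction of each tumor's focal segments that are
        ancestral (shared within a related pair).
    purity : fraction of tumor cells in a bulk sample.
    noise_sd : Gaussian probe noise sd on the log2 scale.
    reads_per_cell : total reads sampled per single cell.
    n_cells : cells sampled per tumor in single-cell rendering.
    n_cnv_loci : size of the recurrent focal-CNV locus catalog from which
        cohort tumors draw their segments.
    segments_per_tumor : focal segments per tumor in cohort generation.
    seed : RNG seed; every generator is deterministic given it.
    """

    ploidy: int = 2
    p_mis: float = 0.0
    divisions: int = 10
    fitness: Callable[[tuple[int, ...]], float] | None = None
    focal_rate: float = 0.0
    focal_size_bp: float = 3_000_000.0
    shared_fraction: float = 0.0
    purity: float = 1.0
    noise_sd: float = 0.0
    reads_per_cell: int = 20_000
    n_cells: int = 45
    n_cnv_loci: int = 200
    segments_per_tumor: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_mis <= 1):
            raise ValueError("p_mis must be in [0, 1]")
        if not (0 <= self.shared_fraction <= 1):
            raise ValueError("shared_fraction must be in [0, 1]")
        if not (0 <= self.purity <= 1):
            raise ValueError("purity must be in [0, 1]")
        if self.divisions < 0:
            raise ValueError("divisions must be >= 0")
        if self.reads_per_cell <= 0:
            raise ValueError("reads_per_cell must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if self.focal_rate < 0:
            raise ValueError("focal_rate must be >= 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class CloneTable:
    """Unique karyotypes with population weights and focal CNV lists."""

    chromosomes: list[str]
    karyotypes: np.ndarray  # (n_clones, n_chromosomes) int
    weights: np.ndarray  # (n_clones,) float, sums to 1
    focal: list[list[CNVSegment]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.karyotypes = np.asarray(self.karyotypes, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.karyotypes.ndim != 2 or self.karyotypes.shape[1] != len(self.chromosomes):
            raise ValueError("karyotype matrix shape mismatch")
        if len(self.weights) != len(self.karyotypes):
            raise ValueError("weights length mismatch")
        if (self.weights < 0).any():
            raise ValueError("weights must be >= 0")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        if not self.focal:
            self.focal = [[] for _ in range(len(self.weights))]

    @property
    def n_clones(self) -> int:
        return len(self.weights)

    def euploid_fraction(self, ploidy: int = 2) -> float:
        mask = (self.karyotypes == ploidy).all(axis=1)
        return float(self.weights[mask].sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.karyotypes, columns=self.chromosomes)
        df.insert(0, "clone_id", [f"clone{i:03d}" for i in range(self.n_clones)])
        df["weight"] = self.weights
        df["n_focal"] = [len(f) for f in self.focal]
        return df


def _fitness_weights(
    karyotypes: np.ndarray, fitness: Callable[[tuple[int, ...]], float] | None
) -> np.ndarray:
    viable = (karyotypes > 0).all(axis=1).astype(float)
    if fitness is None:
        return viable
    w = np.array([fitness(tuple(k)) for k in karyotypes], dtype=float)
    if (w < 0).any():
        raise ValueError("fitness map assigned a negative weight")
    return w * viable


def simulate_lineage(config: SimConfig, layout: GenomeLayout | None = None) -> CloneTable:
    """Grow a clone table by ``divisions`` rounds of reciprocal mis-segregation.

    The full binary lineage tree is simulated (2^divisions terminal cells);
    nullisomic cells are removed, fitness re-weights the survivors, and
    identical karyotypes are merged with summed weights.
    """
    layout = layout or mouse_autosomes()
    n_chrom = layout.n_chromosomes
    rng = config.rng(stream=1)
    cells = np.full((1, n_chrom), config.ploidy, dtype=int)
    for _ in range(config.divisions):
        n = len(cells)
        mis = rng.random((n, n_chrom)) < config.p_mis
        sign = rng.choice([-1, 1], size=(n, n_chrom))
        delta = mis * sign
        cells = np.concatenate([cells + delta, cells - delta], axis=0)
    w = _fitness_weights(cells, config.fitness)
    if w.sum() == 0:
        raise ValueError("no viable cells remain after selection")
    karyos, inverse = np.unique(cells, axis=0, return_inverse=True)
    weights = np.bincount(inverse, weights=w, minlength=len(karyos))
    keep = weights > 0
    karyos, weights = karyos[keep], weights[keep]
    return CloneTable(layout.chromosomes, karyos, weights / weights.sum())


def _random_segment(
    rng: np.random.Generator, layout: GenomeLayout, mean_size: float
) -> CNVSegment:
    lengths = np.array(list(layout.lengths.values()), dtype=float)
    ci = rng.choice(len(lengths), p=lengths / lengths.sum())
    chrom = layout.chromosomes[ci]
    chrom_len = int(lengths[ci])
    size = int(max(500_000, rng.exponential(mean_size)))
    size = min(size, chrom_len - 1)
    start = int(rng.integers(0, chrom_len - size))
    sign = "amplification" if rng.random() < 0.5 else "deletion"
    return CNVSegment(chrom, start, start + size, sign)


def impose_focal_cnvs(
    clones: CloneTable,
    config: SimConfig,
    layout: GenomeLayout | None = None,
    shared_set: list[CNVSegment] | None = None,
) -> CloneTable:
    """Add ancestral (shared) and private Poisson-count focal CNVs to clones.

    Segments in ``shared_set`` appear in every clone; each clone additionally
    receives Poisson(``focal_rate``) private segments drawn uniformly over
    the genome.
    """
    layout = layout or mouse_autosomes()
    shared = list(shared_set or [])
    for seg in shared:
        if seg.chrom not in layout.lengths:
            raise ValueError(f"segment chromosome {seg.chrom} not in layout")
        if seg.end > layout.lengths[seg.chrom] or seg.start < 0:
            raise ValueError(f"segment {seg.chrom}:{seg.start}-{seg.end} outside bounds")
    rng = config.rng(stream=2)
    focal = []
    for _ in range(clones.n_clones):
        k = rng.poisson(config.focal_rate)
        private = [_random_segment(rng, layout, config.focal_size_bp) for _ in range(k)]
        focal.append(shared + private)
    return CloneTable(clones.chromosomes, clones.karyotypes.copy(), clones.weights.copy(), focal)


def _clone_bin_states(
    clones: CloneTable, layout: GenomeLayout
) -> np.ndarray:
    """Integer copy state per clone per bin (whole-chromosome + focal)."""
    codes = layout.bin_chrom_codes()
    bins = layout.bins
    mid = ((bins["start"] + bins["end"]) // 2).to_numpy()
    chrom_arr = bins["chrom"].to_numpy()
    states = clones.karyotypes[:, codes].astype(int)
    for i, segs in enumerate(clones.focal):
        for seg in segs:
            hit = (chrom_arr == seg.chrom) & (mid >= seg.start) & (mid < seg.end)
            states[i, hit] += 1 if seg.sign == "amplification" else -1
    return np.maximum(states, 0)


def render_single_cell_counts(
    clones: CloneTable,
    layout: GenomeLayout,
    config: SimConfig,
    sampling: str = "multinomial",
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Render shallow single-cell read counts from the clone mixture.

    ``sampling="multinomial"`` (default) scatters each cell's read budget
    multinomially over bins — the shallow-sequencing shot-noise regime.
    ``sampling="expected"`` emits the rounded expected counts instead, the
    noise-free limit used for caller-recovery checks (per-bin rounding of a
    shot-noise signal at ~10 reads/bin is otherwise noise-dominated and
    would need an HMM over bins, which is out of scope here).

    Returns (counts, truth_states, clone_index): a cells x bins integer count
    frame (cell ids as index, bin labels as columns), the true integer copy
    state of every cell at every bin, and each cell's clone assignment.
    """
    if clones.n_clones == 0:
        raise ValueError("empty clone table")
    if sampling not in ("multinomial", "expected"):
        raise ValueError("sampling must be 'multinomial' or 'expected'")
    rng = config.rng(stream=3)
    states = _clone_bin_states(clones, layout)
    widths = layout.bin_widths.astype(float)
    assign = rng.choice(clones.n_clones, size=config.n_cells, p=clones.weights)
    counts = np.zeros((config.n_cells, states.shape[1]), dtype=int)
    for i, ci in enumerate(assign):
        p = states[ci] * widths
        if sampling == "multinomial":
            counts[i] = rng.multinomial(config.reads_per_cell, p / p.sum())
        else:
            counts[i] = np.round(config.reads_per_cell * p / p.sum()).astype(int)
    bins = layout.bins
    cols = [f"{c}:{s}-{e}" for c, s, e in zip(bins["chrom"], bins["start"], bins["end"])]
    frame = pd.DataFrame(counts, columns=cols, index=[f"cell{i:03d}" for i in range(config.n_cells)])
    return frame, states[assign], assign


def render_bulk_acgh(
    clones: CloneTable,
    layout: GenomeLayout,
    probes: pd.DataFrame,
    config: SimConfig,
    sample_id: str = "sim",
) -> ProbeProfile:
    """Render a pseudo-bulk aCGH log2-ratio profile from the clone mixture.

    Each probe's tumor copy number is the clone-weighted mean state at its
    position; the bulk sample mixes tumor at ``purity`` with diploid normal
    cells, and Gaussian noise (``noise_sd``) is added on the log2 scale.
    Numerators below the copy floor (0.05 copies) are floored before log2.
    """
    rng = config.rng(stream=4)
    pos = probes["start"].to_numpy()
    chrom_arr = probes["chrom"].to_numpy()
    chrom_idx = {c: i for i, c in enumerate(clones.chromosomes)}
    codes = np.array([chrom_idx[c] for c in chrom_arr])
    probe_states = clones.karyotypes[:, codes].astype(float)
    for i, segs in enumerate(clones.focal):
        for seg in segs:
            hit = (chrom_arr == seg.chrom) & (pos >= seg.start) & (pos < seg.end)
            probe_states[i, hit] += 1 if seg.sign == "amplification" else -1
    probe_states = np.maximum(probe_states, 0)
    mean_state = clones.weights @ probe_states
    f, p0 = config.purity, config.ploidy
    numerator = np.maximum(f * mean_state + (1 - f) * p0, COPY_FLOOR)
    ratio = np.log2(numerator / p0)
    if config.noise_sd > 0:
        ratio = ratio + rng.normal(0, config.noise_sd, size=len(ratio))
    out = probes[["probe_id", "chrom", "start", "end"]].copy()
    out["log2_ratio"] = ratio
    return ProbeProfile(sample_id, out, list(clones.chromosomes))


def _locus_catalog(
    rng: np.random.Generator, layout: GenomeLayout, n_loci: int, mean_size: float
) -> list[CNVSegment]:
    """Non-overlapping recurrent CNV loci; tumors draw their segments here.

    A finite catalog makes cross-tumor segment matches possible by chance,
    which is what gives the per-tumor Jaccard null nonzero variance.
    """
    catalog: list[CNVSegment] = []
    attempts = 0
    while len(catalog) < n_loci and attempts < 100 * n_loci:
        attempts += 1
        seg = _random_segment(rng, layout, mean_size)
        if any(s.chrom == seg.chrom and s.start < seg.end and seg.start < s.end for s in catalog):
            continue
        catalog.append(seg)
    if len(catalog) < n_loci:
        raise ValueError("could not place non-overlapping locus catalog; reduce n_cnv_loci")
    return catalog


def make_relatedness_cohort(
    n_mice: int,
    related_fraction: float,
    config: SimConfig,
    layout: GenomeLayout | None = None,
) -> list[TumorCNVSet]:
    """A cohort of per-mouse tumor pairs with a known shared-CNV fraction.

    Every mouse carries one benign (HCA) and one malignant (HCC) tumor. Each
    tumor holds ``config.segments_per_tumor`` focal segments drawn from a
    common recurrent-locus catalog; within a mouse the first
    round(related_fraction x segments_per_tumor) are ancestral (identical in
    both tumors), the rest private draws. Across mice, segments coincide only
    by chance of drawing the same catalog locus.
    """
    if n_mice < 3:
        raise ValueError("n_mice must be >= 3 (Z null needs >= 2 unrelated tumors)")
    if not (0 <= related_fraction <= 1):
        raise ValueError("related_fraction must be in [0, 1]")
    layout = layout or mouse_autosomes()
    rng = config.rng(stream=5)
    n_seg = config.segments_per_tumor
    if config.n_cnv_loci < 2 * n_seg:
        raise ValueError("n_cnv_loci must be >= 2 x segments_per_tumor")
    catalog = _locus_catalog(rng, layout, config.n_cnv_loci, config.focal_size_bp)
    n_shared = int(round(related_fraction * n_seg))
    cohort: list[TumorCNVSet] = []
    for m in range(n_mice):
        mouse = f"mouse{m:02d}"
        shared_idx = rng.choice(len(catalog), size=n_shared, replace=False)
        rest = np.setdiff1d(np.arange(len(catalog)), shared_idx)
        for t, cls in enumerate(("HCA", "HCC")):
            private_idx = rng.choice(rest, size=n_seg - n_shared, replace=False)
            segs = [catalog[i] for i in np.concatenate([shared_idx, private_idx]).astype(int)]
            cohort.append(
                TumorCNVSet(
                    tumor_id=f"{mouse}_{cls}1",
                    mouse_id=mouse,
                    tumor_class=cls,
                    segments=segs,
                )
            )
    return cohort


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["fitness"] = None if config.fitness is None else "custom"
    return d
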
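"""Single-cell copy-number states and population karyotype statistics.

Integer copy states are called per cell and bin from shallow binned read
counts by comparing each bin's count to its euploid expectation (reads
proportional to bin width) and rounding the scaled ratio. On clean data the
caller is exact; it makes no attempt at GC correction or breakpoint
refinement.

Three population scores summarize a tumor:

* aneuploidy score A — mean absolute deviation of state from ploidy across
  cells and bins (copies);
* heterogeneity score H — mean per-bin Gini–Simpson diversity of states
  across cells (in [0, 1)); a clonal but aneuploid population has H = 0 with
  A > 0, so the two axes separate clonal aberration from ongoing instability;
* unique-karyotype fraction U — fraction of cells whose whole-chromosome
  karyotype vector occurs exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeLayout

S_MAX = 10  # state clamp; guards against division artifacts in tiny bins


@dataclass
class CellStateMatrix:
    """Integer copy-number state per cell and genomic bin."""

    cell_ids: list[str]
    bins: pd.DataFrame  # chrom, start, end
    states: np.ndarray  # (n_cells, n_bins) int
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if self.states.shape != (len(self.cell_ids), len(self.bins)):
            raise ValueError("state matrix shape mismatch")
        if (self.states < 0).any():
            raise ValueError("states must be >= 0")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))


@dataclass
class PopulationScores:
    aneuploidy: float  # A, copies
    heterogeneity: float  # H, in [0, 1)
    unique_fraction: float  # U, in [0, 1]
    n_cells: int


def call_cell_states(
    counts: pd.DataFrame,
    layout: GenomeLayout,
    ploidy: int = 2,
) -> CellStateMatrix:
    """Call integer copy states from a cells x bins count matrix.

    For each cell, the euploid expectation of bin b is
    total_reads x width_b / genome_width; the raw state is
    ploidy x count_b / expectation_b, rounded half-away-from-zero and clamped
    to [0, 10]. Cells with zero total reads are dropped with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.shape[1] != len(layout.bins):
        raise ValueError("count matrix does not match layout bins")
    totals = mat.sum(axis=1)
    dead = totals == 0
    if dead.any():
        dropped = [str(counts.index[i]) for i in np.flatnonzero(dead)]
        warnings.warn(f"dropping {len(dropped)} zero-read cell(s): {dropped}", stacklevel=2)
        mat = mat[~dead]
        totals = totals[~dead]
    if len(mat) == 0:
        raise ValueError("no cells with reads")
    widths = layout.bin_widths.astype(float)
    expected = totals[:, None] * (widths / widths.sum())[None, :]
    raw = ploidy * mat / expected
    states = np.floor(raw + 0.5).astype(int)  # half-away-from-zero for raw >= 0
    states = np.clip(states, 0, S_MAX)
    cell_ids = [str(c) for c, d in zip(counts.index, dead) if not d]
    return CellStateMatrix(cell_ids, layout.bins.copy(), states, ploidy)


def whole_chromosome_karyotype(states: CellStateMatrix) -> pd.DataFrame:
    """Per-cell modal copy state per chromosome.

    Ties among modal states are broken toward the state closest to the
    baseline ploidy, then toward the lower state.
    """
    chroms = states.chromosomes()
    chrom_arr = states.bins["chrom"].to_numpy()
    out = np.zeros((states.n_cells, len(chroms)), dtype=int)
    for j, chrom in enumerate(chroms):
        sub = states.states[:, chrom_arr == chrom]
        for i in range(states.n_cells):
            vals, cnt = np.unique(sub[i], return_counts=True)
            top = vals[cnt == cnt.max()]
            out[i, j] = min(top, key=lambda s: (abs(s - states.ploidy), s))
    return pd.DataFrame(out, index=states.cell_ids, columns=chroms)


def population_scores(states: CellStateMatrix) -> PopulationScores:
    """Aneuploidy A, heterogeneity H, and unique-karyotype fraction U."""
    if states.n_cells < 2:
        raise ValueError("population scores need >= 2 cells")
    s = states.states
    a = float(np.abs(s - states.ploidy).mean())
    # per-bin Gini-Simpson: 1 - sum_k p_k^2 over the state distribution
    h_terms = []
    for b in range(s.shape[1]):
        _, cnt = np.unique(s[:, b], return_counts=True)
        p = cnt / cnt.sum()
        h_terms.append(1.0 - float((p**2).sum()))
    h = float(np.mean(h_terms))
    karyos = whole_chromosome_karyotype(states)
    _, inverse, counts = np.unique(
        karyos.to_numpy(), axis=0, return_inverse=True, return_counts=True
    )
    u = float((counts[inverse] == 1).mean())
    return PopulationScores(a, h, u, states.n_cells)
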
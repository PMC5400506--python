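"""Genome layout: chromosome table and bin tiling.

All coordinates are 0-based, half-open throughout the package. The default
layout is the 19 mouse autosomes (approximate mm10 lengths); sex chromosomes
are omitted because bulk profiles in this workflow use sex-mismatched normal
reference DNA, which makes X/Y ratios uninterpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Approximate mm10 autosome lengths in bp.
MOUSE_AUTOSOME_LENGTHS: dict[str, int] = {
    "chr1": 195_500_000,
    "chr2": 182_100_000,
    "chr3": 160_000_000,
    "chr4": 156_500_000,
    "chr5": 151_800_000,
    "chr6": 149_700_000,
    "chr7": 145_400_000,
    "chr8": 129_400_000,
    "chr9": 124_600_000,
    "chr10": 130_700_000,
    "chr11": 122_100_000,
    "chr12": 120_100_000,
    "chr13": 120_400_000,
    "chr14": 124_900_000,
    "chr15": 104_000_000,
    "chr16": 98_200_000,
    "chr17": 95_000_000,
    "chr18": 90_700_000,
    "chr19": 61_400_000,
}

DEFAULT_BIN_WIDTH = 1_000_000


@dataclass
class GenomeLayout:
    """Ordered chromosomes with lengths, tiled into fixed-width bins.

    Parameters
    ----------
    lengths : dict
        Mapping of chromosome name -> length in bp, in chromosome order.
    bin_width : int
        Width of the tiling bins in bp; the terminal bin of each chromosome
        may be shorter.
    """

    lengths: dict[str, int]
    bin_width: int = DEFAULT_BIN_WIDTH
    _bins: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("layout needs at least one chromosome")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        rows = []
        for chrom, length in self.lengths.items():
            starts = np.arange(0, length, self.bin_width, dtype=np.int64)
            ends = np.minimum(starts + self.bin_width, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        self._bins = pd.concat(rows, ignore_index=True)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def n_chromosomes(self) -> int:
        return len(self.lengths)

    @property
    def bins(self) -> pd.DataFrame:
        """Bin table with columns chrom, start, end (0-based half-open)."""
        return self._bins

    @property
    def bin_widths(self) -> np.ndarray:
        return (self._bins["end"] - self._bins["start"]).to_numpy()

    @property
    def genome_length(self) -> int:
        return int(sum(self.lengths.values()))

    def chrom_index(self, chrom: str) -> int:
        return self.chromosomes.index(chrom)

    def bin_chrom_codes(self) -> np.ndarray:
        """Integer chromosome index for each bin, in bin order."""
        order = {c: i for i, c in enumerate(self.chromosomes)}
        return self._bins["chrom"].map(order).to_numpy()

    def uniform_probes(self, spacing: int) -> pd.DataFrame:
        """Probe coordinates at uniform spacing along every chromosome.

        Returns a frame with probe_id, chrom, start, end where each probe is
        a 1 bp feature at the sampled position (half-open end = start + 1).
        """
        if spacing <= 0:
            raise ValueError("spacing must be positive")
        rows = []
        for chrom, length in self.lengths.items():
            pos = np.arange(spacing // 2, length, spacing, dtype=np.int64)
            rows.append(pd.DataFrame({"chrom": chrom, "start": pos, "end": pos + 1}))
        probes = pd.concat(rows, ignore_index=True)
        probes.insert(0, "probe_id", [f"P{i:06d}" for i in range(len(probes))])
        return probes


def mouse_autosomes(bin_width: int = DEFAULT_BIN_WIDTH) -> GenomeLayout:
    """The default 19-autosome mouse layout."""
    return GenomeLayout(dict(MOUSE_AUTOSOME_LENGTHS), bin_width=bin_width)
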
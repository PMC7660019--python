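"""Per-population allele counts and genomic-block assignment.

These are the sufficient statistics for every f- and D-statistic: for each
(population, site) the derived-allele count ``d`` and the number of alleles
observed ``n`` (so the frequency estimate is ``p = d/n``), plus an
assignment of consecutive variants to genomic blocks for the weighted
block jackknife.  Blocks are runs of a fixed number of consecutive
variants within one chromosome; the trailing block on each chromosome
keeps the remainder, and the jackknife weights absorb the unequal sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeError, GenotypeMatrix, PopulationPanel


@dataclass
class FreqTable:
    """Derived-allele counts per (population, variant).

    ``d`` and ``n`` are ``(n_populations, n_variants)`` integer arrays;
    ``p = d/n`` where ``n > 0`` and NaN where a population has no observed
    alleles at a site.
    """

    populations: list[str]
    variants: pd.DataFrame
    d: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.populations)) != len(self.populations):
            raise GenotypeError("duplicate population labels")
        if np.any(self.d < 0) or np.any(self.d > self.n):
            raise GenotypeError("invalid allele counts (need 0 <= d <= n)")
        self._index = {p: i for i, p in enumerate(self.populations)}

    @property
    def p(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n > 0, self.d / np.maximum(self.n, 1), np.nan)

    def row(self, population: str) -> int:
        try:
            return self._index[population]
        except KeyError:
            raise GenotypeError(f"unknown population {population!r}") from None

    def freq(self, population: str) -> np.ndarray:
        i = self.row(population)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n[i] > 0, self.d[i] / np.maximum(self.n[i], 1), np.nan)

    def size(self, population: str) -> np.ndarray:
        return self.n[self.row(population)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        p = self.p
        for i, pop in enumerate(self.populations):
            rows.append(
                pd.DataFrame(
                    {
                        "population": pop,
                        "chrom": self.variants["chrom"],
                        "pos": self.variants["pos"],
                        "d": self.d[i],
                        "n": self.n[i],
                        "p": p[i],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class BlockSpec:
    """Assignment of variants to consecutive genomic blocks.

    ``block_index`` holds, per variant, a block id in ``0..g-1``; ``sizes``
    holds the number of variants per block.  Blocks never span a
    chromosome boundary.
    """

    block_index: np.ndarray
    sizes: np.ndarray

    def __post_init__(self) -> None:
        if self.sizes.sum() != len(self.block_index):
            raise GenotypeError("block sizes do not sum to number of variants")

    @property
    def n_blocks(self) -> int:
        return len(self.sizes)

    @property
    def n_variants(self) -> int:
        return len(self.block_index)


def population_counts(g: GenotypeMatrix, panel: PopulationPanel) -> FreqTable:
    """Collapse genotypes to per-population derived counts and sizes.

    Missing cells contribute to neither ``d`` nor ``n``.
    """
    pops = panel.populations()
    sample_pop = []
    for s in g.samples:
        if s not in panel.table.index:
            raise GenotypeError(f"sample {s!r} missing from panel")
        sample_pop.append(panel.table.at[s, "population"])
    membership = np.zeros((len(pops), g.n_samples), dtype=np.int64)
    pop_index = {p: i for i, p in enumerate(pops)}
    for j, p in enumerate(sample_pop):
        membership[pop_index[p], j] = 1
    present = membership.sum(axis=1)
    empty = [p for p, c in zip(pops, present) if c == 0]
    if empty:
        raise GenotypeError(f"population(s) with zero samples: {empty}")
    derived = np.where(g.ploidy > 0, g.derived, 0).astype(np.int64)
    d = membership @ derived
    n = membership @ g.ploidy.astype(np.int64)
    return FreqTable(pops, g.variants.copy(), d, n)


def assign_blocks(variants: pd.DataFrame, target_size: int = 100) -> BlockSpec:
    """Assign consecutive variants to blocks of ``target_size``.

    The block counter runs across chromosomes but no block spans a
    chromosome boundary; the final block on each chromosome holds the
    remainder.  Requires variants sorted by (chrom, pos).
    """
    if target_size < 2:
        raise ValueError("target_size must be >= 2")
    chrom = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    keys = list(zip(chrom, pos))
    if keys != sorted(keys):
        raise GenotypeError("variants must be sorted by (chrom, pos)")
    block_index = np.empty(len(variants), dtype=np.int64)
    sizes: list[int] = []
    block = -1
    i = 0
    while i < len(variants):
        # span of the current chromosome
        j = i
        while j < len(variants) and chrom[j] == chrom[i]:
            j += 1
        for start in range(i, j, target_size):
            block += 1
            end = min(start + target_size, j)
            block_index[start:end] = block
            sizes.append(end - start)
        i = j
    return BlockSpec(block_index, np.asarray(sizes, dtype=np.int64))


def write_freq_table(freq: FreqTable, path: str | Path) -> None:
    from .genotype_io import write_table

    write_table(freq.to_frame(), path)
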
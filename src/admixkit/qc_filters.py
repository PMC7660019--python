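"""Variant- and sample-level quality filters.

Variants are dropped when their overall missing-genotype rate exceeds a
threshold (default 25%) and, optionally, when their pooled minor-allele
frequency falls below a floor (default 1%; useful before PCA-style analyses
but deliberately off for f/D statistics, which need rare variants).
Samples are dropped when their combined Native American plus Ancient Native
American ancestry proportion, taken from a precomputed unsupervised
clustering table, falls below a threshold (default 90%); outgroup and
Australasian reference samples are exempt because they anchor the tests
rather than being tested.

All thresholds are strict in the direction their wording implies: a variant
missing in exactly 25% of samples survives, a sample at exactly 90% native
ancestry survives.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import (
    GenotypeError,
    GenotypeMatrix,
    PopulationPanel,
    REFERENCE_REGIONS,
)

NATIVE_COMPONENTS = ("NativeAmerican", "AncientNativeAmerican")


@dataclass
class FilterConfig:
    max_variant_missing_rate: float = 0.25
    min_maf: float = 0.01
    min_native_ancestry: float = 0.90

    def __post_init__(self) -> None:
        for name in ("max_variant_missing_rate", "min_maf", "min_native_ancestry"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class AncestryTable:
    """Per-sample proportions over K putative ancestral components."""

    table: pd.DataFrame  # index: sample; columns: component labels

    def __post_init__(self) -> None:
        sums = self.table.sum(axis=1)
        bad = sums.index[np.abs(sums - 1.0) > 1e-6]
        if len(bad):
            raise ValueError(
                f"ancestry proportions do not sum to 1 for: {list(bad)}"
            )
        if ((self.table < 0) | (self.table > 1)).any().any():
            raise ValueError("ancestry proportions outside [0, 1]")

    def native_fraction(self, sample: str) -> float:
        cols = [c for c in NATIVE_COMPONENTS if c in self.table.columns]
        return float(self.table.loc[sample, cols].sum()) if cols else 0.0


def read_ancestry_table(path: str | Path) -> AncestryTable:
    t = pd.read_csv(path, sep="\t", dtype={"sample": str}).set_index("sample")
    return AncestryTable(t)


def variant_missing_rate(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of samples with no call, per variant."""
    return (g.ploidy == 0).mean(axis=0)


def pooled_maf(g: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency pooling all samples, per variant.

    Sites with no observed alleles get MAF 0 (they are removed by the
    missingness filter at any threshold below 1 anyway).
    """
    observed = g.ploidy > 0
    d = np.where(observed, g.derived, 0).sum(axis=0)
    n = g.ploidy.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, d / np.maximum(n, 1), 0.0)
    return np.minimum(p, 1.0 - p)


def filter_variants(
    g: GenotypeMatrix, cfg: FilterConfig | None = None, apply_maf: bool = False
) -> GenotypeMatrix:
    """Drop variants by missingness (and optionally pooled MAF).

    Removal is strict: a variant is removed only when its missing rate is
    strictly above ``max_variant_missing_rate``, or (with ``apply_maf``)
    its pooled minor-allele frequency strictly below ``min_maf``.
    """
    cfg = cfg or FilterConfig()
    keep = variant_missing_rate(g) <= cfg.max_variant_missing_rate
    if apply_maf:
        keep &= pooled_maf(g) >= cfg.min_maf
    if not keep.any():
        raise GenotypeError(
            "all variants removed by filters; review thresholds "
            f"(max_missing={cfg.max_variant_missing_rate}, min_maf={cfg.min_maf})"
        )
    return g.subset_variants(keep)


def filter_samples_by_ancestry(
    g: GenotypeMatrix,
    panel: PopulationPanel,
    anc: AncestryTable,
    cfg: FilterConfig | None = None,
) -> GenotypeMatrix:
    """Drop test samples whose native ancestry falls below the threshold.

    A sample is kept when its NativeAmerican + AncientNativeAmerican
    proportion is at least ``min_native_ancestry`` (strictly-below removal).
    Samples in reference regions (Outgroup, Australasian) are always kept.
    """
    cfg = cfg or FilterConfig()
    missing = [s for s in g.samples if s not in anc.table.index
               and panel.table.at[s, "region"] not in REFERENCE_REGIONS]
    if missing:
        raise GenotypeError(f"samples absent from ancestry table: {missing}")
    keep = [
        s
        for s in g.samples
        if panel.table.at[s, "region"] in REFERENCE_REGIONS
        or anc.native_fraction(s) >= cfg.min_native_ancestry
    ]
    if not keep:
        raise GenotypeError("all samples removed by ancestry filter")
    return g.subset_samples(keep)
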
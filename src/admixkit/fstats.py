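"""Unbiased f-statistics and Patterson's D with weighted block jackknife.

All statistics are functions of per-population derived-allele frequencies
``p = d/n``.  The "unbiased" f2 and f3 subtract finite-sample
heterozygosity terms ``h/n`` with ``h = p(1-p) n/(n-1)``, so populations
represented by few sampled alleles do not inflate apparent drift.  f4 and
D need no such correction (their cross-population products are already
unbiased).

D is a ratio of sums over jointly usable sites::

    D = sum_s (w-x)(y-z)  /  sum_s (w+x-2wx)(y+z-2yz)

Standard errors come from a weighted delete-one-block jackknife over
genomic blocks of consecutive variants: with block weights ``m_j`` (usable
sites), total ``M``, whole-data estimate ``t`` and leave-block-out
estimates ``t_j``, the inverse weights are ``h_j = M/m_j``, pseudo-values
``p_j = h_j t - (h_j - 1) t_j``, the jackknife mean is
``t_J = g t - sum_j (1 - m_j/M) t_j`` and the variance is
``(1/g) sum_j (p_j - t_J)^2 / (h_j - 1)``.  With equal block weights this
reduces exactly to the classic delete-one jackknife.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeError
from .popfreq import BlockSpec, FreqTable

__all__ = [
    "FStatResult",
    "JackknifeInput",
    "block_jackknife",
    "f2_per_site",
    "f2_stat",
    "f3_stat",
    "f4_stat",
    "d_stat",
]


@dataclass
class FStatResult:
    """Point estimate, jackknife mean/SE and Z-score of one statistic."""

    stat_name: str
    populations: tuple[str, ...]
    estimate: float
    jackknife_mean: float
    se: float
    z: float
    n_blocks: int
    n_sites: int

    def to_row(self) -> dict:
        labels = list(self.populations) + [""] * (4 - len(self.populations))
        return {
            "stat": self.stat_name,
            "W": labels[0],
            "X": labels[1],
            "Y": labels[2],
            "Z": labels[3],
            "estimate": self.estimate,
            "se": self.se,
            "z": self.z,
            "n_blocks": self.n_blocks,
            "n_sites": self.n_sites,
        }


@dataclass
class JackknifeInput:
    """Per-block numerator/denominator sums and usable-site weights."""

    num: np.ndarray  # N_j
    den: np.ndarray  # D_j (site counts for mean statistics)
    m: np.ndarray    # usable sites per block

    def __post_init__(self) -> None:
        if np.any(self.m < 0):
            raise ValueError("negative block weights")


def block_jackknife(jk: JackknifeInput) -> tuple[float, float, float, float]:
    """Weighted delete-one-block jackknife for a ratio of sums.

    Returns ``(estimate, jackknife_mean, se, z)``.  Blocks with zero
    weight are dropped; at least two weighted blocks are required.  When
    every leave-one-out estimate equals the full estimate the SE is 0 and
    z is reported as signed infinity with a warning.
    """
    keep = jk.m > 0
    num, den, m = jk.num[keep], jk.den[keep], jk.m[keep]
    g = len(m)
    if g < 2:
        raise GenotypeError(f"need >= 2 non-empty blocks for the jackknife, got {g}")
    N, D, M = num.sum(), den.sum(), m.sum()
    if D == 0:
        raise GenotypeError("monomorphic input: total denominator is zero")
    theta = N / D
    loo_den = D - den
    if np.any(loo_den == 0):
        raise GenotypeError("a single block carries the whole denominator")
    theta_j = (N - num) / loo_den
    h = M / m
    pseudo = h * theta - (h - 1.0) * theta_j
    theta_jack = g * theta - float(np.sum((1.0 - m / M) * theta_j))
    var = float(np.mean((pseudo - theta_jack) ** 2 / (h - 1.0)))
    se = float(np.sqrt(var))
    if se == 0.0:
        warnings.warn(
            "jackknife SE is zero (all leave-one-out estimates identical); "
            "z reported as signed infinity",
            RuntimeWarning,
            stacklevel=2,
        )
        z = float(np.sign(theta) * np.inf) if theta != 0 else np.nan
    else:
        z = float(theta / se)
    return float(theta), float(theta_jack), se, z


def _block_sums(
    blocks: BlockSpec, usable: np.ndarray, num: np.ndarray, den: np.ndarray
) -> JackknifeInput:
    g = blocks.n_blocks
    idx = blocks.block_index[usable]
    return JackknifeInput(
        num=np.bincount(idx, weights=num[usable], minlength=g),
        den=np.bincount(idx, weights=den[usable], minlength=g),
        m=np.bincount(idx, minlength=g).astype(float),
    )


def _unbiased_het(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """h = p(1-p) n/(n-1); unbiased heterozygosity, defined for n >= 2."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return p * (1.0 - p) * n / np.maximum(n - 1.0, 1e-300)


def f2_per_site(
    pa: np.ndarray, na: np.ndarray, pb: np.ndarray, nb: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased per-site f2 values and their usability mask.

    ``(a-b)^2 - h_a/n_a - h_b/n_b``; a site is usable when both
    populations have at least two observed alleles.
    """
    usable = (na >= 2) & (nb >= 2) & np.isfinite(pa) & np.isfinite(pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = (pa - pb) ** 2 - _unbiased_het(pa, na) / na - _unbiased_het(pb, nb) / nb
    return np.where(usable, val, 0.0), usable


def _finalize(
    name: str,
    pops: tuple[str, ...],
    blocks: BlockSpec,
    usable: np.ndarray,
    num: np.ndarray,
    den: np.ndarray,
) -> FStatResult:
    n_sites = int(usable.sum())
    if n_sites == 0:
        raise GenotypeError(f"no usable sites for {name}{pops}")
    jk = _block_sums(blocks, usable, num, den)
    est, jmean, se, z = block_jackknife(jk)
    return FStatResult(name, pops, est, jmean, se, z, int((jk.m > 0).sum()), n_sites)


def f2_stat(freq: FreqTable, blocks: BlockSpec, a: str, b: str) -> FStatResult:
    """Unbiased f2(A, B): mean per-site value with jackknife SE."""
    pa, na = freq.freq(a), freq.size(a)
    pb, nb = freq.freq(b), freq.size(b)
    val, usable = f2_per_site(pa, na, pb, nb)
    return _finalize("f2", (a, b), blocks, usable, val, usable.astype(float))


def f3_stat(freq: FreqTable, blocks: BlockSpec, c: str, a: str, b: str) -> FStatResult:
    """Unbiased admixture f3(C; A, B).

    Per-site ``(c-a)(c-b) - h_c/n_c``; significantly negative values are
    the classic signal that C is a mixture of sources related to A and B.
    Requires at least two observed alleles in C (for the correction) and
    one in A and B.
    """
    pc, nc = freq.freq(c), freq.size(c)
    pa, na = freq.freq(a), freq.size(a)
    pb, nb = freq.freq(b), freq.size(b)
    usable = (nc >= 2) & (na >= 1) & (nb >= 1)
    usable &= np.isfinite(pc) & np.isfinite(pa) & np.isfinite(pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = (pc - pa) * (pc - pb) - _unbiased_het(pc, nc) / nc
    val = np.where(usable, val, 0.0)
    return _finalize("f3", (c, a, b), blocks, usable, val, usable.astype(float))


def f4_stat(
    freq: FreqTable, blocks: BlockSpec, a: str, b: str, c: str, d: str
) -> FStatResult:
    """f4(A, B; C, D): mean per-site ``(a-b)(c-d)`` with jackknife SE."""
    ps = [freq.freq(x) for x in (a, b, c, d)]
    ns = [freq.size(x) for x in (a, b, c, d)]
    usable = np.logical_and.reduce([n >= 1 for n in ns])
    usable &= np.logical_and.reduce([np.isfinite(p) for p in ps])
    pa, pb, pc, pd = ps
    val = np.where(usable, (pa - pb) * (pc - pd), 0.0)
    return _finalize("f4", (a, b, c, d), blocks, usable, val, usable.astype(float))


def d_stat(
    freq: FreqTable, blocks: BlockSpec, w: str, x: str, y: str, z: str
) -> FStatResult:
    """Patterson's D(W, X; Y, Z) as a ratio of sums over usable sites.

    Positive D (Z > 0) indicates excess allele sharing between X and Z
    relative to Y, with W the outgroup.  The jackknife deletes block sums
    from numerator and denominator jointly.
    """
    ps = [freq.freq(q) for q in (w, x, y, z)]
    ns = [freq.size(q) for q in (w, x, y, z)]
    usable = np.logical_and.reduce([n >= 1 for n in ns])
    usable &= np.logical_and.reduce([np.isfinite(p) for p in ps])
    pw, px, py, pz = ps
    num = np.where(usable, (pw - px) * (py - pz), 0.0)
    den = np.where(
        usable, (pw + px - 2.0 * pw * px) * (py + pz - 2.0 * py * pz), 0.0
    )
    return _finalize("D", (w, x, y, z), blocks, usable, num, den)
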
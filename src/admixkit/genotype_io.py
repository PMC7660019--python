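"""Genotype and sample-metadata ingestion.

The in-memory substrate for every downstream analysis is a
:class:`GenotypeMatrix`: samples x biallelic single-nucleotide variants,
storing for each cell the number of derived (ALT) alleles observed and the
number of alleles observed at all (the "observed ploidy").  Low-coverage or
ancient samples that are represented by a single randomly drawn allele per
site (pseudo-haploid calls) carry an observed ploidy of 1, so the
finite-sample corrections of the unbiased f-statistics see the true number
of sampled alleles.

Two standard on-disk formats are supported: VCF (GT field only) and the
EIGENSTRAT geno/snp/ind triple used by the ADMIXTOOLS ecosystem.  Sample
metadata (population, geographic region, age class, coordinates) comes from
a tab-separated panel file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

VALID_BASES = frozenset("ACGT")

REGIONS = frozenset(
    {
        "Eskimo",
        "NorthAmerica",
        "CentralAmerica",
        "Amazon",
        "WestAndes",
        "SoutheastAmerica",
        "SouthernAmerica",
        "Outgroup",
        "Australasian",
        "Other",
    }
)

AGE_CLASSES = frozenset({"contemporary", "ancient"})

#: regions whose samples serve as reference panels rather than test subjects
REFERENCE_REGIONS = frozenset({"Outgroup", "Australasian"})


class GenotypeError(ValueError):
    """Raised for malformed or inconsistent genotype data."""


@dataclass(frozen=True)
class Variant:
    """A biallelic single-nucleotide variant at a 1-based position."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise GenotypeError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise GenotypeError(
                f"alleles must be single bases in ACGT, got "
                f"{self.ref_allele}/{self.alt_allele} at {self.chrom}:{self.pos}"
            )
        if self.ref_allele == self.alt_allele:
            raise GenotypeError(
                f"ref and alt alleles identical at {self.chrom}:{self.pos}"
            )


def _variants_frame(variants: Iterable[Variant]) -> pd.DataFrame:
    rows = [(v.chrom, v.pos, v.ref_allele, v.alt_allele, v.id) for v in variants]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "id"])


@dataclass
class GenotypeMatrix:
    """Samples x variants matrix of derived-allele counts.

    Attributes
    ----------
    variants
        DataFrame with columns ``chrom, pos, ref, alt, id`` sorted by
        (chrom, pos).
    samples
        Ordered unique sample identifiers.
    derived
        ``(n_samples, n_variants)`` int16 array of derived-allele counts;
        ``MISSING`` (-1) where no call was made.
    ploidy
        ``(n_samples, n_variants)`` int8 array of alleles observed per
        call: 0 (missing), 1 (pseudo-haploid) or 2 (diploid).
    """

    variants: pd.DataFrame
    samples: list[str]
    derived: np.ndarray
    ploidy: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        n_s, n_v = len(self.samples), len(self.variants)
        if self.derived.shape != (n_s, n_v) or self.ploidy.shape != (n_s, n_v):
            raise GenotypeError(
                f"genotype array shape {self.derived.shape} does not match "
                f"{n_s} samples x {n_v} variants"
            )
        if len(set(self.samples)) != n_s:
            raise GenotypeError("duplicate sample ids")
        keys = list(zip(self.variants["chrom"], self.variants["pos"]))
        if len(set(keys)) != n_v:
            raise GenotypeError("duplicate (chrom, pos) pairs")
        if keys != sorted(keys):
            raise GenotypeError("variants not sorted by (chrom, pos)")
        observed = self.ploidy > 0
        if np.any(self.derived[observed] > self.ploidy[observed]):
            raise GenotypeError("derived count exceeds observed ploidy")
        if np.any(self.derived[observed] < 0):
            raise GenotypeError("negative derived count on an observed call")
        if np.any(self.derived[~observed] != MISSING):
            raise GenotypeError("ploidy 0 cell without MISSING derived count")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        rows = [index[s] for s in keep]
        return GenotypeMatrix(
            self.variants.copy(), list(keep), self.derived[rows], self.ploidy[rows]
        )

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            self.variants.loc[mask].reset_index(drop=True),
            list(self.samples),
            self.derived[:, mask],
            self.ploidy[:, mask],
        )


@dataclass
class PopulationPanel:
    """Sample metadata: population, region, age class and coordinates."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("population", "region", "age_class")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise GenotypeError(f"panel missing required column {col!r}")
        for col in ("latitude", "longitude"):
            if col not in t.columns:
                t[col] = np.nan
        bad_region = t.loc[~t["region"].isin(REGIONS)]
        if len(bad_region):
            raise GenotypeError(
                "unknown region value(s): "
                + ", ".join(f"{s}={r}" for s, r in bad_region["region"].items())
            )
        bad_age = t.loc[~t["age_class"].isin(AGE_CLASSES)]
        if len(bad_age):
            raise GenotypeError(
                "unknown age_class value(s): "
                + ", ".join(f"{s}={r}" for s, r in bad_age["age_class"].items())
            )
        lat, lon = t["latitude"], t["longitude"]
        if np.any((lat < -90) | (lat > 90)) or np.any((lon < -180) | (lon > 180)):
            raise GenotypeError("coordinates outside valid ranges")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def population_of(self, sample: str) -> str:
        return self.table.at[sample, "population"]

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.table["population"]:
            seen.setdefault(p, None)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        return list(self.table.index[self.table["population"] == population])

    def region_of_population(self, population: str) -> str:
        regions = set(self.table.loc[self.table["population"] == population, "region"])
        if len(regions) != 1:
            raise GenotypeError(
                f"population {population!r} maps to regions {sorted(regions)}"
            )
        return regions.pop()

    def populations_in_region(self, region: str) -> list[str]:
        sub = self.table.loc[self.table["region"] == region, "population"]
        seen: dict[str, None] = {}
        for p in sub:
            seen.setdefault(p, None)
        return list(seen)

    def coordinates_of_population(self, population: str) -> tuple[float, float] | None:
        sub = self.table.loc[self.table["population"] == population]
        lat = sub["latitude"].dropna()
        lon = sub["longitude"].dropna()
        if lat.empty or lon.empty:
            return None
        return float(lat.mean()), float(lon.mean())


def read_panel(path: str | Path) -> PopulationPanel:
    """Read a tab-separated sample panel.

    Expected header: ``sample  population  region  age_class  latitude
    longitude`` (``lat``/``lon`` accepted as aliases); coordinates may be
    ``NA``.
    """
    t = pd.read_csv(path, sep="\t", dtype={"sample": str}, na_values=["NA", ""])
    t = t.rename(columns={"lat": "latitude", "lon": "longitude"})
    if "sample" not in t.columns:
        raise GenotypeError("panel file must have a 'sample' column")
    if t["sample"].duplicated().any():
        dupes = t.loc[t["sample"].duplicated(), "sample"].tolist()
        raise GenotypeError(f"duplicate sample ids in panel: {dupes}")
    t = t.set_index("sample")
    return PopulationPanel(t)


def write_panel(panel: PopulationPanel, path: str | Path) -> None:
    panel.table.to_csv(path, sep="\t", index_label="sample", na_rep="NA")


# ---------------------------------------------------------------------------
# VCF ingestion

def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    variants: list[Variant] = []
    derived_cols: list[np.ndarray] = []
    ploidy_cols: list[np.ndarray] = []
    seen: set[tuple[str, int]] = set()
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            continue
        if ref not in VALID_BASES or alt not in VALID_BASES or ref == alt:
            continue
        key = (rec.CHROM, rec.POS)
        if key in seen:
            raise GenotypeError(f"duplicate (chrom,pos) in VCF: {key}")
        seen.add(key)
        d = np.empty(len(samples), dtype=np.int16)
        p = np.empty(len(samples), dtype=np.int8)
        for i, call in enumerate(rec.genotypes):
            alleles = [a for a in call[:-1] if a >= 0]
            p[i] = len(alleles)
            d[i] = sum(1 for a in alleles if a == 1) if alleles else MISSING
        variants.append(Variant(rec.CHROM, rec.POS, ref, alt, rec.ID))
        derived_cols.append(d)
        ploidy_cols.append(p)
    vframe = _variants_frame(variants)
    if len(vframe):
        derived = np.stack(derived_cols, axis=1)
        ploidy = np.stack(ploidy_cols, axis=1)
        order = np.lexsort((vframe["pos"].to_numpy(), vframe["chrom"].to_numpy()))
        vframe = vframe.iloc[order]
        derived, ploidy = derived[:, order], ploidy[:, order]
    else:
        derived = np.empty((len(samples), 0), dtype=np.int16)
        ploidy = np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(vframe, samples, derived, ploidy)


# ---------------------------------------------------------------------------
# EIGENSTRAT ingestion / output
#
# geno: one line per SNP, one digit per sample counting REFERENCE alleles
#       (0, 1, 2) with 9 for missing.
# snp:  id chrom genetic_pos physical_pos ref alt
# ind:  id sex population

def _eigenstrat_paths(prefix: str | Path) -> tuple[Path, Path, Path]:
    triple = tuple(Path(str(prefix) + ext) for ext in (".geno", ".snp", ".ind"))
    for p in triple:
        if not p.exists():
            raise FileNotFoundError(f"EIGENSTRAT file not found: {p}")
    return triple


def _read_eigenstrat(
    prefix: str | Path, haploid_samples: Iterable[str] = ()
) -> GenotypeMatrix:
    geno_path, snp_path, ind_path = _eigenstrat_paths(prefix)
    ind = pd.read_csv(
        ind_path, sep=r"\s+", header=None, names=["sample", "sex", "population"],
        dtype=str,
    )
    samples = list(ind["sample"])
    snp = pd.read_csv(
        snp_path, sep=r"\s+", header=None,
        names=["id", "chrom", "gpos", "pos", "ref", "alt"],
        dtype={"id": str, "chrom": str},
    )
    variants = [
        Variant(str(r.chrom), int(r.pos), r.ref, r.alt, r.id)
        for r in snp.itertuples()
    ]
    lines = Path(geno_path).read_text().split()
    if len(lines) != len(variants):
        raise GenotypeError(
            f"{geno_path}: {len(lines)} genotype lines for {len(variants)} snp records"
        )
    n_s = len(samples)
    derived = np.empty((n_s, len(variants)), dtype=np.int16)
    ploidy = np.empty((n_s, len(variants)), dtype=np.int8)
    haploid = np.array([s in set(haploid_samples) for s in samples])
    for j, line in enumerate(lines):
        if len(line) != n_s:
            raise GenotypeError(
                f"{geno_path} line {j + 1}: {len(line)} genotypes for {n_s} samples"
            )
        col = (np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")).astype(np.int16)
        if np.any((col > 2) & (col != 9)):
            raise GenotypeError(f"{geno_path} line {j + 1}: invalid genotype code")
        missing = col == 9
        # geno digit counts reference alleles; derived count = ploidy - digit
        derived[:, j] = np.where(missing, MISSING, 2 - col)
        ploidy[:, j] = np.where(missing, 0, 2)
        if haploid.any():
            hap_bad = haploid & (col == 1)
            if hap_bad.any():
                raise GenotypeError(
                    f"{geno_path} line {j + 1}: heterozygous call for "
                    "pseudo-haploid sample"
                )
            hm = haploid & ~missing
            derived[hm, j] = (2 - col[hm]) // 2
            ploidy[hm, j] = 1
    keys = list(zip(snp["chrom"], snp["pos"]))
    if len(set(keys)) != len(keys):
        raise GenotypeError(f"duplicate (chrom,pos) in {snp_path}")
    vframe = _variants_frame(variants)
    order = np.lexsort((vframe["pos"].to_numpy(), vframe["chrom"].to_numpy()))
    return GenotypeMatrix(vframe.iloc[order], samples, derived[:, order], ploidy[:, order])


def read_genotypes(
    path: str | Path,
    format: str = "vcf",
    haploid_samples: Iterable[str] = (),
) -> GenotypeMatrix:
    """Read genotypes from a VCF file or an EIGENSTRAT prefix.

    Only biallelic single-nucleotide variants are retained; multiallelic
    records and indels are dropped.  ``haploid_samples`` (EIGENSTRAT only)
    names samples whose homozygous-coded genotypes represent single-allele
    pseudo-haploid calls; they are stored with observed ploidy 1.
    """
    if format == "vcf":
        if haploid_samples:
            raise GenotypeError("haploid_samples only applies to EIGENSTRAT input")
        return _read_vcf(path)
    if format == "eigenstrat":
        return _read_eigenstrat(path, haploid_samples)
    raise GenotypeError(f"unknown format {format!r}")


def write_eigenstrat(g: GenotypeMatrix, prefix: str | Path,
                     populations: dict[str, str] | None = None) -> None:
    """Write a GenotypeMatrix as an EIGENSTRAT geno/snp/ind triple.

    Pseudo-haploid calls (ploidy 1) are encoded as the corresponding
    homozygote; reading them back with ``haploid_samples`` restores the
    single-allele representation exactly.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    populations = populations or {}
    with open(str(prefix) + ".ind", "w") as fh:
        for s in g.samples:
            fh.write(f"{s}\tU\t{populations.get(s, 'POP')}\n")
    with open(str(prefix) + ".snp", "w") as fh:
        for r in g.variants.itertuples():
            vid = r.id if r.id else f"{r.chrom}_{r.pos}"
            fh.write(f"{vid}\t{r.chrom}\t0.0\t{r.pos}\t{r.ref}\t{r.alt}\n")
    # digit = reference-allele count on the diploid encoding
    scale = np.where(g.ploidy == 1, 2, 1)
    digits = np.where(g.ploidy == 0, 9, (g.ploidy - g.derived) * scale)
    lookup = np.array(list("0123456789"))
    with open(str(prefix) + ".geno", "w") as fh:
        for j in range(g.n_variants):
            fh.write("".join(lookup[digits[:, j]]) + "\n")


# ---------------------------------------------------------------------------
# dataset harmonization

def intersect_datasets(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Merge two datasets on shared sites, concatenating samples.

    Sites present in both matrices at identical (chrom, pos) are kept when
    their allele pairs match either directly or with ref/alt swapped; in the
    swapped case b's derived counts are recoded as ``ploidy - derived``.
    Sites with incompatible allele pairs are dropped.  The output follows
    a's allele orientation.
    """
    overlap = set(a.samples) & set(b.samples)
    if overlap:
        raise GenotypeError(f"overlapping sample ids: {sorted(overlap)}")
    akey = a.variants.set_index(["chrom", "pos"])
    bkey = b.variants.set_index(["chrom", "pos"])
    common = akey.index.intersection(bkey.index)
    ai = akey.index.get_indexer(common)
    bi = bkey.index.get_indexer(common)
    aref = a.variants["ref"].to_numpy()[ai]
    aalt = a.variants["alt"].to_numpy()[ai]
    bref = b.variants["ref"].to_numpy()[bi]
    balt = b.variants["alt"].to_numpy()[bi]
    same = (aref == bref) & (aalt == balt)
    swapped = (aref == balt) & (aalt == bref)
    keep = same | swapped
    ai, bi, swapped = ai[keep], bi[keep], swapped[keep]
    b_derived = b.derived[:, bi].copy()
    b_ploidy = b.ploidy[:, bi]
    if swapped.any():
        cols = np.where(swapped)[0]
        obs = b_ploidy[:, cols] > 0
        recoded = b_ploidy[:, cols] - b_derived[:, cols]
        b_derived[:, cols] = np.where(obs, recoded, MISSING)
    derived = np.concatenate([a.derived[:, ai], b_derived], axis=0)
    ploidy = np.concatenate([a.ploidy[:, ai], b_ploidy], axis=0)
    variants = a.variants.iloc[ai].reset_index(drop=True)
    return GenotypeMatrix(variants, list(a.samples) + list(b.samples), derived, ploidy)


# ---------------------------------------------------------------------------
# tabular output

def write_table(rows, path: str | Path) -> None:
    """Write tabular results as TSV with floats at 6 significant digits.

    ``rows`` may be a DataFrame, a list of dataclasses with ``to_row``
    methods, or a list of dicts.  An empty list of known column structure
    yields a header-only file only when given a DataFrame.
    """
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        records = []
        for r in rows:
            records.append(r.to_row() if hasattr(r, "to_row") else dict(r))
        frame = pd.DataFrame(records)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
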
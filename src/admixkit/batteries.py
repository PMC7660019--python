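"""Designed D-statistic test suites.

Two batteries probe gene flow in a panel of Native American populations:

* the Australasian battery computes ``D(outgroup, Australasian; anchor, X)``
  for every test population X against a panel of Australasian populations,
  summarizing each X by the median and 2.5%/97.5% quantiles of the
  Z-scores — a median Z above 3 flags an Australasian ("Population Y")
  signal in X;
* the regional batteries compute ``D(outgroup, X; Y, Z)`` with Y and Z
  drawn from two geographic region groups, testing which regional lineage
  a population X shares more drift with.  Z > 3 means X is closer to the
  Z-group, Z < -3 closer to the Y-group.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fstats import FStatResult, d_stat
from .genotype_io import GenotypeError, PopulationPanel
from .popfreq import BlockSpec, FreqTable

__all__ = [
    "AustralasianBatteryRow",
    "RegionalTestSpec",
    "REGIONAL_TESTS",
    "australasian_battery",
    "regional_battery",
    "summarize_z",
]


@dataclass
class AustralasianBatteryRow:
    """Summary of D(outgroup, Australasian; anchor, X) over Australasians."""

    test_population: str
    z_values: dict[str, float] = field(repr=False)
    median_z: float = 0.0
    q025_z: float = 0.0
    q975_z: float = 0.0
    signal: bool = False

    def to_row(self) -> dict:
        return {
            "test_population": self.test_population,
            "median_z": self.median_z,
            "q2.5_z": self.q025_z,
            "q97.5_z": self.q975_z,
            "signal": self.signal,
            "n_australasian": len(self.z_values),
        }


def summarize_z(values: np.ndarray | list[float]) -> tuple[float, float, float]:
    """Median and 2.5%/97.5% quantiles (linear interpolation) of Z-scores."""
    q025, med, q975 = np.quantile(np.asarray(values, dtype=float), [0.025, 0.5, 0.975])
    return float(med), float(q025), float(q975)


def australasian_battery(
    freq: FreqTable,
    blocks: BlockSpec,
    panel: PopulationPanel,
    test_pops: list[str],
    aus_pops: list[str] | None = None,
    outgroup: str = "Mbuti",
    anchor: str = "Mixe",
) -> list[AustralasianBatteryRow]:
    """Run D(outgroup, Australasian; anchor, X) for every test population.

    ``aus_pops`` defaults to every population in the panel's Australasian
    region.  Per X, the Z-scores across the Australasian panel are
    summarized by their median and 2.5/97.5% quantiles (linear
    interpolation); ``signal`` flags a median above 3.
    """
    if aus_pops is None:
        aus_pops = panel.populations_in_region("Australasian")
    if len(aus_pops) < 1:
        raise GenotypeError("need at least one Australasian population")
    rows = []
    for x in test_pops:
        zs = {
            aus: d_stat(freq, blocks, outgroup, aus, anchor, x).z
            for aus in aus_pops
        }
        med, q025, q975 = summarize_z(list(zs.values()))
        rows.append(
            AustralasianBatteryRow(
                test_population=x,
                z_values=zs,
                median_z=float(med),
                q025_z=float(q025),
                q975_z=float(q975),
                signal=bool(med > 3.0),
            )
        )
    return rows


@dataclass(frozen=True)
class RegionalTestSpec:
    """One of the three regional gene-flow D-test designs.

    ``D(outgroup, X; Y-group, Z-group)`` with Y/Z population pairs
    enumerated from two region labels.
    """

    label: str
    y_region: str
    z_region: str
    outgroup: str = "Mbuti"

    def __post_init__(self) -> None:
        if self.y_region == self.z_region:
            raise ValueError("Y and Z region groups must differ")


#: the three designed tests: A contrasts Amazon vs Southern ancestry,
#: B Amazon vs West Andes, C Southern vs West Andes.
REGIONAL_TESTS = {
    "A": RegionalTestSpec("A", "Amazon", "SouthernAmerica"),
    "B": RegionalTestSpec("B", "Amazon", "WestAndes"),
    "C": RegionalTestSpec("C", "SouthernAmerica", "WestAndes"),
}


def regional_battery(
    freq: FreqTable,
    blocks: BlockSpec,
    panel: PopulationPanel,
    spec: RegionalTestSpec,
    test_pops: list[str],
    outgroup: str | None = None,
) -> tuple[list[FStatResult], pd.DataFrame]:
    """Enumerate D(outgroup, X; Y, Z) over region-group population pairs.

    Returns the individual statistics and a per-X summary table with the
    median Z across pairs.  Pairs in which X itself appears are skipped
    with a warning.
    """
    outgroup = outgroup or spec.outgroup
    y_pops = panel.populations_in_region(spec.y_region)
    z_pops = panel.populations_in_region(spec.z_region)
    if not y_pops or not z_pops:
        raise GenotypeError(
            f"empty region group for test {spec.label}: "
            f"{spec.y_region}={y_pops}, {spec.z_region}={z_pops}"
        )
    results: list[FStatResult] = []
    summary_rows = []
    for x in test_pops:
        zs = []
        for y, z in itertools.product(y_pops, z_pops):
            if x in (y, z):
                warnings.warn(
                    f"test {spec.label}: skipping pair ({y}, {z}) containing "
                    f"test population {x}",
                    stacklevel=2,
                )
                continue
            r = d_stat(freq, blocks, outgroup, x, y, z)
            results.append(r)
            zs.append(r.z)
        if not zs:
            raise GenotypeError(
                f"test {spec.label}: no valid (Y, Z) pairs for {x}"
            )
        summary_rows.append(
            {"test": spec.label, "test_population": x,
             "median_z": float(np.median(zs)), "n_pairs": len(zs)}
        )
    return results, pd.DataFrame(summary_rows)
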
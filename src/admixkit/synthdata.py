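"""Synthetic genotype datasets with known truth.

Per-site derived-allele frequencies drift along an admixture graph under
the Balding-Nichols model: a child population at drift distance ``c`` from
its parent draws its frequency from ``Beta(p(1-c)/c, (1-p)(1-c)/c)``,
which has mean ``p`` and variance ``c p(1-p)``; an admixture node mixes
its parents' frequencies linearly with weight ``alpha``.  Root
frequencies are i.i.d. Uniform.  Contemporary samples are diploid
(Binomial(2, p) derived counts); "ancient" samples are pseudo-haploid
(one Bernoulli(p) allele per site, observed ploidy 1).  Genotype cells go
missing independently at a configurable rate, and sites are distributed
round-robin over a configurable number of chromosomes so the jackknife
block structure is exercised.

Every random stream is keyed by (seed, stage, name-hash), so datasets are
bit-reproducible and two simulations sharing a seed share draws for the
graph nodes and populations they have in common (common random numbers
across, e.g., a gene-flow dose sweep).

Sites are simulated independently (no linkage disequilibrium): what the
jackknife's blocking defends against in real data is deliberately absent,
so calibration checks here validate the estimator's algebra, not its LD
robustness.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .admixgraph import AdmixtureGraph, ScenarioSpec
from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    PopulationPanel,
    write_eigenstrat,
    write_panel,
)

__all__ = [
    "PopulationSpec",
    "SimulationConfig",
    "simulate_frequencies",
    "sample_genotypes",
    "simulate_dataset",
    "scenario_graph",
    "scenario_simulation_graph",
    "scenario_spec",
    "default_scenario_config",
    "four_population_graph",
    "admixed_target_graph",
    "make_scenario_fixture",
]


@dataclass(frozen=True)
class PopulationSpec:
    """How one population is sampled: sizes, age class and coordinates."""

    name: str
    region: str = "Other"
    n_diploid: int = 10
    n_pseudohaploid: int = 0
    latitude: float | None = None
    longitude: float | None = None


@dataclass
class SimulationConfig:
    graph: AdmixtureGraph
    populations: list[PopulationSpec]
    n_sites: int = 50_000
    root_lo: float = 0.05
    root_hi: float = 0.95
    missing_rate: float = 0.05
    n_chromosomes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if not 0.0 <= self.root_lo < self.root_hi <= 1.0:
            raise ValueError("root frequency bounds must satisfy 0 <= lo < hi <= 1")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        leaves = set(self.graph.leaves)
        for spec in self.populations:
            if spec.name not in leaves:
                raise ValueError(f"population {spec.name!r} is not a graph leaf")


def _rng(seed: int, stage: int, name: str) -> np.random.Generator:
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, stage, key]))


def simulate_frequencies(cfg: SimulationConfig) -> dict[str, np.ndarray]:
    """Drift per-site frequencies down the graph; returns every node's vector."""
    graph = cfg.graph
    params = graph.default_params()
    freqs: dict[str, np.ndarray] = {}
    for node in nx.topological_sort(graph._dg):
        if node == graph.root:
            freqs[node] = _rng(cfg.seed, 0, node).uniform(
                cfg.root_lo, cfg.root_hi, cfg.n_sites
            )
        elif node in graph.admixtures:
            pa, pb, alpha = graph.admixtures[node]
            freqs[node] = alpha * freqs[pa] + (1.0 - alpha) * freqs[pb]
        else:
            (parent,) = graph._dg.predecessors(node)
            c = params.drift[(parent, node)]
            if c >= 1.0:
                raise ValueError(
                    f"drift on edge {parent}->{node} must be < 1 for the "
                    f"Balding-Nichols model, got {c}"
                )
            p = freqs[parent]
            if c == 0.0:
                freqs[node] = p.copy()
            else:
                k = (1.0 - c) / c
                p = np.clip(p, 1e-12, 1.0 - 1e-12)
                freqs[node] = _rng(cfg.seed, 0, node).beta(p * k, (1.0 - p) * k)
    return freqs


def _variant_frame(n_sites: int, n_chromosomes: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Round-robin site->chromosome assignment, returned in sorted order.

    The permutation maps simulation site order to sorted variant order.
    """
    idx = np.arange(n_sites)
    chrom_i = idx % n_chromosomes
    pos = idx // n_chromosomes + 1
    order = np.lexsort((pos, chrom_i))
    bases = np.array(["A", "C", "G", "T"])
    # deterministic alternating ref/alt pair; alleles carry no signal here
    ref = bases[idx % 2 * 2]        # A, G, A, G ...
    alt = bases[idx % 2 * 2 + 1]    # C, T, C, T ...
    frame = pd.DataFrame(
        {
            "chrom": np.char.add("c", np.char.zfill((chrom_i + 1).astype(str), 2))[order],
            "pos": pos[order],
            "ref": ref[order],
            "alt": alt[order],
            "id": [f"s{i}" for i in idx[order]],
        }
    )
    return frame, order


def sample_genotypes(
    freqs: dict[str, np.ndarray], cfg: SimulationConfig
) -> tuple[GenotypeMatrix, PopulationPanel]:
    """Draw diploid and pseudo-haploid genotype calls from leaf frequencies."""
    frame, order = _variant_frame(cfg.n_sites, cfg.n_chromosomes)
    sample_ids: list[str] = []
    panel_rows: list[dict[str, Any]] = []
    derived_parts: list[np.ndarray] = []
    ploidy_parts: list[np.ndarray] = []
    for spec in cfg.populations:
        if spec.name not in freqs:
            raise ValueError(f"population {spec.name!r} absent from frequencies")
        p = freqs[spec.name][None, None, :]
        n_total = spec.n_diploid + spec.n_pseudohaploid
        if n_total == 0:
            continue
        derived = np.empty((n_total, cfg.n_sites), dtype=np.int16)
        ploidy = np.empty((n_total, cfg.n_sites), dtype=np.int8)
        if spec.n_diploid:
            u = _rng(cfg.seed, 1, spec.name).random((spec.n_diploid, 2, cfg.n_sites))
            derived[: spec.n_diploid] = (u < p).sum(axis=1)
            ploidy[: spec.n_diploid] = 2
        if spec.n_pseudohaploid:
            u = _rng(cfg.seed, 2, spec.name).random(
                (spec.n_pseudohaploid, 1, cfg.n_sites)
            )
            derived[spec.n_diploid:] = (u < p).sum(axis=1)
            ploidy[spec.n_diploid:] = 1
        if cfg.missing_rate > 0:
            miss = (
                _rng(cfg.seed, 3, spec.name).random((n_total, cfg.n_sites))
                < cfg.missing_rate
            )
            derived[miss] = MISSING
            ploidy[miss] = 0
        derived_parts.append(derived[:, order])
        ploidy_parts.append(ploidy[:, order])
        for i in range(spec.n_diploid):
            sid = f"{spec.name}_{i:02d}"
            sample_ids.append(sid)
            panel_rows.append(
                {"sample": sid, "population": spec.name, "region": spec.region,
                 "age_class": "contemporary", "latitude": spec.latitude,
                 "longitude": spec.longitude}
            )
        for i in range(spec.n_pseudohaploid):
            sid = f"{spec.name}_a{i:02d}"
            sample_ids.append(sid)
            panel_rows.append(
                {"sample": sid, "population": spec.name, "region": spec.region,
                 "age_class": "ancient", "latitude": spec.latitude,
                 "longitude": spec.longitude}
            )
    g = GenotypeMatrix(
        frame,
        sample_ids,
        np.concatenate(derived_parts, axis=0),
        np.concatenate(ploidy_parts, axis=0),
    )
    panel = PopulationPanel(pd.DataFrame(panel_rows).set_index("sample"))
    return g, panel


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, PopulationPanel, dict[str, np.ndarray]]:
    """Simulate frequencies and genotypes; truth frequencies returned in the
    matrix's (sorted) variant order."""
    freqs = simulate_frequencies(cfg)
    g, panel = sample_genotypes(freqs, cfg)
    _, order = _variant_frame(cfg.n_sites, cfg.n_chromosomes)
    return g, panel, {k: v[order] for k, v in freqs.items()}


# ---------------------------------------------------------------------------
# canonical demographic scenarios
#
# All three share a backbone: an outgroup splits first, then a northern
# reference lineage, then the South American radiation.  They differ in how
# the Amazon, West Andes, Southeast and Southern leaves attach:
#   1 (Atlantic route): Amazon and Southeast form an eastern clade;
#     Southern derives mostly from the Southeast lineage with an admixture
#     contribution from the West Andes lineage.
#   2 (Pacific route): eastern populations split off the Andean lineage in
#     successive north-to-south waves (Amazon first, then Southeast, with
#     Southern closest to West Andes); no admixture.
#   3 (Andes-south-then-north): an eastern clade of Amazon, Southeast and
#     Southern, with Southeast receiving an admixture edge from West Andes.

_BACKBONE = """
root    Outgroup 0.15
root    x1       0.02
x1      amr      0.08
amr     NorthRef 0.05
amr     sa       0.03
"""

_SCENARIO_TAILS = {
    1: """
sa      wa1       0.04
wa1     WestAndes 0.02
sa      e1        0.02
e1      Amazon    0.03
e1      e2        0.02
e2      Southeast 0.02
admix   sAnc wa1 e2 {alpha}
sAnc    Southern  0.02
""",
    2: """
sa      w1        0.02
w1      Amazon    0.03
w1      w2        0.02
w2      Southeast 0.02
w2      w3        0.02
w3      Southern  0.02
w3      WestAndes 0.02
""",
    3: """
sa      wa1       0.04
wa1     WestAndes 0.02
sa      c1        0.02
c1      Amazon    0.03
c1      c2        0.02
c2      Southern  0.02
admix   seAnc wa1 c2 {alpha}
seAnc   Southeast 0.02
""",
}

#: leaf roles common to all scenarios
SCENARIO_ROLES = ("Outgroup", "NorthRef", "Amazon", "WestAndes", "Southeast", "Southern")


def scenario_graph(scenario_id: int, alpha: float = 0.4) -> AdmixtureGraph:
    """The fitting topology for one of the three peopling scenarios."""
    if scenario_id not in _SCENARIO_TAILS:
        raise ValueError(f"unknown scenario {scenario_id!r}; choose 1, 2 or 3")
    text = _BACKBONE + _SCENARIO_TAILS[scenario_id].format(alpha=alpha)
    return AdmixtureGraph.from_edge_list(text)


def scenario_spec(
    scenario_id: int, candidates: dict[str, list[str]] | None = None
) -> ScenarioSpec:
    """ScenarioSpec with each role's candidate list defaulting to itself."""
    graph = scenario_graph(scenario_id)
    if candidates is None:
        candidates = {role: [role] for role in graph.leaves}
    return ScenarioSpec(scenario_id, graph, candidates)


_AUS_SUBTREE = """
x1      ausanc  0.10
ausanc  Aus1    0.03
ausanc  Aus2    0.03
ausanc  Aus3    0.03
"""


def scenario_simulation_graph(
    scenario_id: int,
    alpha: float = 0.4,
    aus_gamma: float | None = None,
) -> AdmixtureGraph:
    """A scenario graph extended with an Australasian clade for simulation.

    ``aus_gamma``, when given, routes that fraction of the Amazon leaf's
    ancestry through the Australasian ancestor (the "Population Y" style
    gene-flow override); 0.0 keeps the node structure so dose sweeps share
    random draws.
    """
    base = scenario_graph(scenario_id, alpha=alpha)
    text = base.to_edge_list() + _AUS_SUBTREE
    g = AdmixtureGraph.from_edge_list(text)
    if aus_gamma is None:
        return g
    amazon_parent = next(p for (p, c) in g.drift_edges if c == "Amazon")
    drift = dict(g.drift_edges)
    # move the Amazon leaf drift above the admixture event so the leaf
    # frequency is an exact linear mixture (keeps dose sweeps on a shared
    # seed perfectly coupled)
    leaf_drift = drift.pop((amazon_parent, "Amazon"))
    drift[(amazon_parent, "amzSrc")] = leaf_drift
    admix = dict(g.admixtures)
    admix["Amazon"] = ("ausanc", "amzSrc", float(aus_gamma))
    return AdmixtureGraph(drift, admix)


DEFAULT_POPULATIONS = (
    PopulationSpec("Outgroup", "Outgroup"),
    PopulationSpec("NorthRef", "CentralAmerica", latitude=17.0, longitude=-96.0),
    PopulationSpec("Amazon", "Amazon", latitude=-3.5, longitude=-52.5),
    PopulationSpec("WestAndes", "WestAndes", latitude=-13.5, longitude=-72.0),
    PopulationSpec(
        "Southeast", "SoutheastAmerica", n_pseudohaploid=2,
        latitude=-20.0, longitude=-44.0,
    ),
    PopulationSpec("Southern", "SouthernAmerica", latitude=-38.0, longitude=-65.0),
    PopulationSpec("Aus1", "Australasian"),
    PopulationSpec("Aus2", "Australasian"),
    PopulationSpec("Aus3", "Australasian"),
)


def default_scenario_config(
    scenario_id: int = 1,
    seed: int = 0,
    n_sites: int = 50_000,
    missing_rate: float = 0.05,
    alpha: float = 0.4,
    aus_gamma: float | None = None,
    **overrides: Any,
) -> SimulationConfig:
    """The bundled study-style dataset: 7+ populations (outgroup, northern
    anchor, Australasian proxies and the four South American regions),
    10 diploids per population plus 2 pseudo-haploid ancients in the
    Southeast, 5% missingness, 10 chromosomes."""
    graph = scenario_simulation_graph(scenario_id, alpha=alpha, aus_gamma=aus_gamma)
    cfg = SimulationConfig(
        graph=graph,
        populations=list(DEFAULT_POPULATIONS),
        n_sites=n_sites,
        missing_rate=missing_rate,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# small purpose-built graphs for estimator checks


def four_population_graph(gamma: float | None = None) -> AdmixtureGraph:
    """(O, (X, (Y, Z))) with optional gene flow from the Z lineage into X.

    The admixture source sits low on the Z branch (after most of its
    drift), emulating relatively recent gene flow; ``gamma`` is the
    fraction of X's ancestry drawn from it.  D(O, X; Y, Z) is 0 in
    expectation at ``gamma`` None/0 and positive for ``gamma > 0``.
    """
    drift = {
        ("root", "O"): 0.15,
        ("root", "anc1"): 0.02,
        ("anc1", "yz"): 0.03,
        ("yz", "Y"): 0.04,
        ("yz", "zmid"): 0.08,
        ("zmid", "Z"): 0.02,
    }
    admix = {}
    if gamma is None:
        drift[("anc1", "xsrc")] = 0.04
        drift[("xsrc", "X")] = 0.01
    else:
        drift[("anc1", "xsrc")] = 0.04
        admix["xanc"] = ("zmid", "xsrc", float(gamma))
        drift[("xanc", "X")] = 0.01
    return AdmixtureGraph(drift, admix)


def admixed_target_graph(alpha: float = 0.5) -> AdmixtureGraph:
    """Two diverged sources A and B with target C = alpha A' + (1-alpha) B'.

    C carries little post-admixture drift, so the admixture f3(C; A, B)
    signal is strongly negative.
    """
    drift = {
        ("root", "aanc"): 0.08,
        ("root", "banc"): 0.08,
        ("aanc", "A"): 0.02,
        ("banc", "B"): 0.02,
        ("canc", "C"): 0.005,
    }
    admix = {"canc": ("aanc", "banc", float(alpha))}
    return AdmixtureGraph(drift, admix)


# ---------------------------------------------------------------------------


def make_scenario_fixture(
    scenario_id: int,
    out_dir: str | Path,
    seed: int = 0,
    overrides: dict[str, Any] | None = None,
) -> dict[str, Path]:
    """Write a complete on-disk dataset for one scenario.

    Produces an EIGENSTRAT triple, a panel TSV and a truth YAML (graph,
    admixture proportions, seed and sizes) under ``out_dir``; identical
    inputs produce byte-identical files.
    """
    overrides = dict(overrides or {})
    cfg = default_scenario_config(scenario_id, seed=seed, **overrides)
    g, panel, _ = simulate_dataset(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = out_dir / f"scenario{scenario_id}"
    pops = {s: panel.table.at[s, "population"] for s in g.samples}
    write_eigenstrat(g, prefix, populations=pops)
    panel_path = out_dir / f"scenario{scenario_id}_panel.tsv"
    write_panel(panel, panel_path)
    truth = {
        "scenario": scenario_id,
        "seed": seed,
        "n_sites": cfg.n_sites,
        "missing_rate": cfg.missing_rate,
        "n_chromosomes": cfg.n_chromosomes,
        "alpha": {n: a for n, (_, _, a) in cfg.graph.admixtures.items()},
        "graph": cfg.graph.to_edge_list(),
        "populations": [
            {"name": s.name, "region": s.region, "n_diploid": s.n_diploid,
             "n_pseudohaploid": s.n_pseudohaploid}
            for s in cfg.populations
        ],
    }
    truth_path = out_dir / f"scenario{scenario_id}_truth.yaml"
    truth_path.write_text(yaml.safe_dump(truth, sort_keys=True))
    return {
        "prefix": prefix,
        "geno": Path(str(prefix) + ".geno"),
        "snp": Path(str(prefix) + ".snp"),
        "ind": Path(str(prefix) + ".ind"),
        "panel": panel_path,
        "truth": truth_path,
    }
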
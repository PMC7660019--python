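"""Ingest a genotype dataset from disk and apply the standard QC filters.

Writes a small simulated EIGENSTRAT dataset, reads it back (declaring the
ancient samples pseudo-haploid from the panel's age-class column), and
filters variants by missingness.
"""

import tempfile
from pathlib import Path

import admixkit as ak

out = Path(tempfile.mkdtemp(prefix="admixkit_example_"))
files = ak.make_scenario_fixture(1, out, seed=5, overrides={"n_sites": 5_000})
print(f"wrote fixture under {out}")

panel = ak.read_panel(files["panel"])
haploid = [s for s in panel.samples if panel.table.at[s, "age_class"] == "ancient"]
g = ak.read_genotypes(files["prefix"], "eigenstrat", haploid_samples=haploid)
print(f"read {g.n_samples} samples x {g.n_variants} variants "
      f"({len(haploid)} pseudo-haploid ancients)")

filtered = ak.filter_variants(g, ak.FilterConfig(max_variant_missing_rate=0.25))
print(f"missingness filter (>25% dropped): {g.n_variants} -> "
      f"{filtered.n_variants} variants")
# At the default 5% simulated missing rate virtually every variant
# survives; rerun the fixture with a higher missing_rate to see drops.
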
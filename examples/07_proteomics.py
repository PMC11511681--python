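"""Phosphoproteomics differential analysis and kinase-substrate networks.

Peptide tables (3 technical runs x 4 aliquots per half) are aggregated to
proteins, loess-normalized, averaged over runs, and tested with a
moderated t; differential phosphosites are joined to a kinase-substrate
interaction table with exact site matching.
"""

import numpy as np
import pandas as pd

from avekit.proteomics import (aggregate_peptides, average_runs,
                               differential_proteins,
                               kinase_substrate_network, normalize_loess)

rng = np.random.default_rng(0)
proteins = [f"PROT{i}" for i in range(60)]
cols = [f"{side}{a}_r{r}" for side in ("emb", "ab")
        for a in range(4) for r in range(3)]
base = rng.lognormal(6, 1, (120, 1)) * rng.lognormal(0, 0.1, (120, len(cols)))
base[:20, :12] *= 8.0  # first 10 proteins (2 peptides each) up in emb
table = pd.DataFrame(base, columns=cols)
table.insert(0, "protein", np.repeat(proteins, 2))
table.insert(0, "peptide", [f"pep{i}" for i in range(120)])

mat = aggregate_peptides(table)
mat = normalize_loess(mat)
run_map = {c: c.rsplit("_", 1)[0] for c in mat.columns}
mat = average_runs(mat, run_map)
groups = {c: ("embryonic" if c.startswith("emb") else "abembryonic")
          for c in mat.columns}
de = differential_proteins(mat, groups)
print(f"differential proteins: {int(de['de'].sum())} "
      f"(10 were planted with an 8-fold shift)")
print(de[de["de"]].head(3).round(3).to_string())

de_sites = pd.DataFrame({
    "protein": de.index[de["de"]][:3],
    "site": ["S23", "S431", "T18"],
    "side": ["embryonic"] * 3})
interactions = pd.DataFrame({
    "kinase": ["AKT1", "CAMK2", "PKC"],
    "substrate": de_sites["protein"],
    "site": ["s23", "S431", "T19"]})   # third site mismatches
nets = kinase_substrate_network(de_sites, interactions)
print("embryonic network edges:", sorted(nets["embryonic"].edges()))
# only interactions whose phosphosite matches exactly become edges;
# T18 vs T19 is excluded
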
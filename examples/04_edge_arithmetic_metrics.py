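"""Edge arithmetic and network metrics on ground-truth edge lists.

Cleans the two intercropping networks of bare-soil and sole-crop
interference edges, intersects them into unique and common fractions,
and summarizes each fraction (degree, betweenness, sign ratio,
modules, keystones).
"""

import rhizonet as rz
from rhizonet.algebra import clean_ic_network, split_fractions
from rhizonet.metrics import metrics_report

design = rz.default_design(seed=11)
_, truth = rz.simulate_study(design)

interference = [truth.networks[c] for c in ("bare_soil", "wheat_SC", "pea_SC")]
cleaned_wheat = clean_ic_network(truth.networks["wheat_IC"], interference)
cleaned_pea = clean_ic_network(truth.networks["pea_IC"], interference)
unique_wheat, unique_pea, common = split_fractions(cleaned_wheat, cleaned_pea)

print(f"wheat IC: {truth.networks['wheat_IC'].n_edges} edges "
      f"-> {cleaned_wheat.n_edges} after cleaning")
print(f"pea   IC: {truth.networks['pea_IC'].n_edges} edges "
      f"-> {cleaned_pea.n_edges} after cleaning")
print(f"fractions: unique wheat {unique_wheat.n_edges}, "
      f"unique pea {unique_pea.n_edges}, common {common.n_edges}")
assert common.edge_pairs() == truth.fractions["common"].edge_pairs()
print("common fraction == planted common-IC set (exact)")

taxonomy = {o: ("Acidobacteria" if i % 3 == 0 else
                "Alphaproteobacteria" if i % 3 == 1 else "Bacteroidetes")
            for i, o in enumerate(design.otu_ids())}
rep = metrics_report(truth.networks["wheat_IC"], taxonomy=taxonomy, seed=0)
print(f"\nwheat IC truth network: {rep.n_nodes} nodes, {rep.n_edges} edges, "
      f"mean degree {rep.mean_degree:.1f}")
print(f"  sign ratio {rep.pos_neg_ratio:.1f}, "
      f"mean node betweenness {rep.mean_node_betweenness:.1f}, "
      f"modularity {rep.modularity:.2f} "
      f"({len(set(rep.modules.values()))} modules)")
print(f"  phylum fractions: "
      + ", ".join(f"{t} {f:.0%}" for t, f in rep.taxon_composition.items()))
# Keystones (degree > mean + 3 SD) are rare in sparse random-planted
# graphs; an empty list here is the expected answer.
print(f"  keystones: {rep.keystones or 'none'}")
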
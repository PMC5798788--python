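"""Mantel tests: do related species, or populations from similar climates,
germinate similarly?

Trait distances (Euclidean, over the 8 treatment proportions) are compared
against phylogenetic distances (cophenetic, expanded to population pairs
with conspecific distance 0) and climatic distances (log-transformed
bioclim variables).
"""

import phylogerm as pg
from phylogerm import climate, mantel, simulate

cfg = pg.SimulationConfig(seed=1)
records, truth = pg.simulate_germination(cfg)
traits_total = pg.build_trait_matrix(records, "total")
d_traits = pg.euclidean_distances(traits_total)

tree = pg.parse_newick(truth.tree_newick)
pop_map = {r.population_id: r.species_code for r in records}
d_phylo = pg.expand_species_distances(pg.cophenetic_distances(tree), pop_map)

monthly = simulate.simulate_climate(truth.populations, seed=2)
logbio = climate.log_transform(climate.compute_bioclim(monthly))
d_climate = pg.euclidean_distances(logbio.loc[d_traits.index])
d_temp = pg.euclidean_distances(
    climate.subset_variables(logbio, "temperature").loc[d_traits.index]
)

for name, other in [("phylogeny", d_phylo), ("climate (all)", d_climate),
                    ("temperature", d_temp)]:
    res = pg.mantel_test(d_traits, other, n_permutations=10000, seed=42)
    print(f"traits vs {name:14s}: r = {res.r:+.3f}, one-tailed p = {res.p_one_tailed:.4f}")

print(
    "\nr is the Pearson correlation between the paired off-diagonal "
    "distances; p comes from 10000 joint row/column permutations of the "
    "second matrix.  A small p with positive r means populations that are "
    "close on that axis (related species / similar climates) also have "
    "similar germination profiles."
)
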
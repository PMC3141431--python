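"""Haplotype genealogy and TMRCA of a deep two-clade region.

Generates a balanced region (two 50/50 clades joined 5 MY ago), screens
it for infinite-sites violations, builds the median-joining network and
the perfect-phylogeny gene tree, and dates the root with the moment
estimator and the coalescent importance sampler. Both estimates should
recover a TMRCA far beyond the ~1 MY neutral expectation.
"""

from balsel.genealogy import (
    build_gene_tree,
    estimate_tmrca,
    four_gamete_screen,
    median_joining_network,
)
from balsel.synthgen import BalancedRegionSpec, generate_balanced_region

spec = BalancedRegionSpec(seed=44)
aln, truth = generate_balanced_region(spec)

screen = four_gamete_screen(aln)
print(f"four-gamete screen: {len(screen.incompatible_pairs)} incompatible "
      f"pairs, {len(screen.removed_sites)} sites removed")

net = median_joining_network(screen.filtered)
print(f"network: {len(net.observed_nodes())} observed haplotypes, "
      f"{len(net.median_nodes())} inferred medians, "
      f"total weight {net.total_weight} mutations")

tree = build_gene_tree(screen.filtered)
deep = max(tree.mutation_clades(), key=len)
print(f"gene tree: deepest mutation-bearing clade spans {len(deep)}/"
      f"{aln.n} haplotypes (the balanced bipartition)")

moment = estimate_tmrca(screen.filtered, mu=spec.mu)
sampler = estimate_tmrca(screen.filtered, mu=spec.mu,
                         method="coalescent_ml", n_proposals=20_000, seed=1)
print(f"\nTMRCA (moment):        {moment.t_years / 1e6:.2f} MY "
      f"(t = {moment.t_scaled:.2f} x 2Ne, Ne = {moment.N_e:,.0f})")
print(f"TMRCA (coalescent IS): {sampler.t_years / 1e6:.2f} MY "
      f"(MC SE {sampler.mc_se:.2f} in 2Ne units)")
print(f"truth:                 {truth['tmrca_years'] / 1e6:.2f} MY")
print("\nNeutral autosomal loci coalesce within ~0.8-1.5 MY; estimates "
      "beyond 4 MY are the classic balancing-selection depth.")
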
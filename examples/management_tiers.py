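"""Cut a large ranking into management tiers.

Epidemic-control use case: rank every individual in a contact network,
then split the ranking at fixed rank boundaries into priority groups —
top 30 primary, ranks 31-183 secondary, 184-248 tertiary, 249-382
quaternary, the rest ordinary — so protective resources can be
allocated tier by tier.
"""

from klnrank import RunConfig, random_graph, rank_table, tiers_table

g = random_graph("BA", seed=3, n=1204, m=3)
print(f"contact network: {g.number_of_nodes()} nodes, "
      f"{g.number_of_edges()} edges")

ranking = rank_table(g, "kln")
tiers = tiers_table(ranking, RunConfig())  # default boundaries 30/183/248/382

sizes = tiers["tier"].value_counts().sort_index()
names = {1: "primary", 2: "secondary", 3: "tertiary",
         4: "quaternary", 5: "ordinary"}
print("\ntier sizes:")
for t, size in sizes.items():
    print(f"  tier {t} ({names[t]}): {size} nodes")
print("\nhighest-priority individuals (tier 1 head):")
print(tiers.head(5).to_string(index=False))
print("\nTier 1 members are the ranking's most influential spreaders; "
      "vaccinating or monitoring them first curbs propagation most.")
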
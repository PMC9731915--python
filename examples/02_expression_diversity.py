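"""Gene expression diversity (GED): wild vs weedy.

CV of TPM per transcript within each habitat group; a rank test for which
habitat is more variable; and the pairwise more-than-twofold filter that
extracts the genes driving the difference.
"""

from ambropop import ged
from ambropop.simulate import (SimulationConfig, adjacent_pairs,
                               simulate_expression, simulate_panel)

cfg = SimulationConfig(seed=42)
panel = simulate_panel(cfg).drop_replicate_duplicates()
expr, truth = simulate_expression(cfg, panel)

table = ged.ged_cv(expr, panel, "by_habitat_within_region")
for region in ("OH", "IAMN"):
    cw = table.loc[table["group_id"] == f"{region}:weedy", "cv"]
    cx = table.loc[table["group_id"] == f"{region}:wild", "cv"]
    stat, p, higher = ged.compare_ged_groups(cw, cx)
    print(f"{region}: Kruskal-Wallis H = {stat:.1f}, p = {p:.2e}, "
          f"higher-median habitat = {higher}")
print("(the generator plants 2x dispersion in wild populations on "
      f"{cfg.n_ged_genes} genes, so 'wild' is the expected answer)")

pairs = adjacent_pairs(panel)
union_wild = set()
for row in pairs.itertuples(index=False):
    flags = ged.pairwise_twofold_ged(expr, panel,
                                     (row.weedy_pop, row.wild_pop), seed=42)
    union_wild |= set(flags["wild_higher"])
planted = set(truth["ged_genes"])
recovered = len(union_wild & planted)
print(f"\ntwofold filter across {len(pairs)} weedy-wild pairs: "
      f"{recovered}/{len(planted)} planted high-wild-GED genes recovered "
      f"({len(union_wild) - recovered} other transcripts also flagged)")
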
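"""Population-unique transcripts and shared homolog families.

For each population: drop transcripts that map (k-mer containment >= 0.8)
to the reference or to the paired population, keep coding survivors
(ORF >= 100 aa), then group homologs across weedy populations and list the
families present in every weedy population of a region.
"""

from ambropop import unique as u
from ambropop.simulate import SimulationConfig, simulate_bundle

bundle = simulate_bundle(SimulationConfig(seed=42))
panel = bundle.panel
pair_of = {}
for row in bundle.pairs.itertuples(index=False):
    pair_of[row.weedy_pop] = row.wild_pop
    pair_of.setdefault(row.wild_pop, row.weedy_pop)

uniques = {}
for pop, coll in bundle.populations.items():
    if pop not in pair_of:
        continue
    uq = u.extract_unique(coll, bundle.reference, bundle.populations[pair_of[pop]])
    uq, _ = u.orf_filter(uq)
    uniques[pop] = uq

truth = bundle.truth["unique_transcripts"]
pop = next(p for p in uniques if panel.habitat_of(p) == "weedy")
planted = set(truth.loc[truth["population_id"] == pop, "transcript_id"])
found = set(uniques[pop].names())
print(f"{pop}: {len(found)} unique coding transcripts recovered; "
      f"{len(found & planted)}/{len(planted)} planted (precision "
      f"{len(found & planted) / len(found):.2f})")

for region in ("OH", "IAMN"):
    weedy = [p for p in uniques if panel.region_of(p) == region
             and panel.habitat_of(p) == "weedy"]
    groups = u.homolog_grouping({p: uniques[p] for p in weedy})
    shared = u.shared_by_all(groups, weedy)
    terms = u.group_terms(shared, bundle.annotation)
    print(f"{region}: {len(groups)} homolog groups, {len(shared)} shared by "
          f"all {len(weedy)} weedy populations, annotated with "
          f"{len(terms)} functional terms")
print("(the generator plants 5 homolog families per region across all weedy "
      "populations at 2-5 % nucleotide divergence)")
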
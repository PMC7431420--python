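"""Breeding structure and dispersal: nest overlap, neighbours, fidelity.

For every nest: how many other nests incubated concurrently (shared at
least one day between laying and incubation end), how far away they
were, and how many sat within 100 m.  For birds breeding in consecutive
years: did they stay in the same habitat, and how far did they move?
"""
from plovernet import breeding, synthetic
from plovernet.config import PopulationConfig

sim = synthetic.simulate_dataset(PopulationConfig(seed=1))

ctx = breeding.focal_context(sim.nests)
print(f"{len(ctx)} nests; "
      f"mean concurrent nests {ctx.n_overlapping.mean():.1f}; "
      f"mean of mean distances {ctx.mean_dist_overlapping.mean():.0f} m; "
      f"mean neighbours within 100 m "
      f"{ctx.n_overlapping_within_100m.mean():.2f}")

recs = breeding.dispersal_records(sim.nests)
summary = breeding.dispersal_summary(recs)
for flag, (stayed, total) in sorted(summary["by_prev_success"].items()):
    label = "successful" if flag else "failed"
    print(f"previously {label:10s}: {stayed}/{total} "
          f"({100 * stayed / total:.1f}%) stayed in the same habitat")
for hab, (stayed, total) in sorted(summary["by_prev_habitat"].items()):
    print(f"  {hab:12s} {stayed}/{total} stayed")
print("\nSuccess-dependent fidelity: failed breeders disperse to a new "
      "habitat more often than successful ones.")
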
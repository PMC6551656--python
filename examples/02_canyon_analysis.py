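"""Canyon calling and the size-normalized meta-profile.

Simulates a WGBS-like CpG track with planted hypomethylated canyons and a
matched cohort whose mutant group gains a uniform +0.014 beta at canyon
probes, then calls canyons, maps probes and profiles the shift.
"""

import methylotype as mt

sim = mt.simulate_canyon_cohort(seed=3)

canyons = mt.call_canyons(sim["track"])
print(f"{len(canyons)} canyons called (planted: {len(sim['track_truth'].canyon_intervals)})")
print(canyons.intervals[["chrom", "start", "end", "length", "n_cpgs"]].to_string(index=False))

assign = mt.map_probes(canyons, sim["manifest"])
labels = sim["sheet"]["idh_status"]
gm = mt.canyon_group_means(assign, sim["beta"], labels)
print(f"\n{gm['n_probes']} canyon-associated probes")
print(f"canyon delta beta (MUT - WT): {gm['delta_beta']:.4f}  (Welch p = {gm['welch_p']:.2g})")

profile = mt.size_normalized_profile(canyons, assign, sim["beta"], labels, n_bins=10)
wide = profile.pivot(index="bin", columns="group", values="mean")
wide["diff"] = wide["MUT"] - wide["WT"]
print("\nsize-normalized meta-profile (10 bins):")
print(wide.round(4).to_string())

# The per-bin difference sits near the planted 0.014 in every bin: the
# canyon methylation gain is evenly distributed along the canyon, not
# concentrated at the borders.
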
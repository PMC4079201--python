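"""Tandem period estimation, consensus building, family grouping."""

import satscan as ss

genome, _, truth = ss.simulate_genome(
    ss.SimConfig(seed=11, focal_length=400_000,
                 background_lengths=(300_000, 300_000),
                 n_loci_focal=6, n_loci_background=1)
)
focal_table = ss.count_kmers(genome.focal, 13)
background_table = ss.count_kmers(genome.background, 13)
profile = ss.relative_profile(genome.focal[0], focal_table, background_table)
clusters = ss.call_clusters(profile, chromosome=genome.focal[0])

monomers = []
for i, cluster in enumerate(clusters, 1):
    period = ss.top_period(cluster.sequence)
    if period is None:
        continue
    monomers.append(ss.build_consensus(cluster.sequence, period,
                                       monomer_id=f"mono_{i}"))
    print(f"cluster {i}: period {period} bp, "
          f"{monomers[-1].copy_number_in_source:.1f} copies")

families = ss.group_families(monomers)
print(f"families: {sorted(set(families.values()))}")
rep = ss.representative(monomers, monomers[0].family)
match = sum(a == b for a, b in zip(rep.consensus, truth.monomer))
print(f"representative consensus matches planted monomer at "
      f"{100 * match / len(truth.monomer):.1f}% of sites")
# All clusters descend from one planted monomer, so they group into a
# single family whose representative recovers the planted unit.
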
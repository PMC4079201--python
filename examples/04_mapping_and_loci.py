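"""Genome-wide monomer mapping, coverage statistics, and the 1-kb locus rule."""

import satscan as ss

genome, _, truth = ss.simulate_genome(
    ss.SimConfig(seed=11, focal_length=400_000,
                 background_lengths=(300_000, 300_000),
                 n_loci_focal=6, n_loci_background=1)
)
monomer = ss.Monomer("planted", truth.monomer, 0)
hits = ss.search(monomer, genome, evalue_threshold=1e-4)
print(f"{len(hits)} hits at E < 1e-4 "
      f"(planted copies: {len(truth.copies)})")

table = ss.coverage(hits, genome)
print(table.rows.to_string(index=False))
print(f"focal/background coverage ratio: {table.ratio:.1f}")

loci = ss.group_loci(hits, max_gap=1000)
print(f"{len(loci)} loci (hits within 1 kb share a locus); "
      f"planted loci: {len(truth.loci)}")
# The ratio line is the per-comparison average of the focal coverage
# percent over each background chromosome's percent — the statistic that
# quantifies X-chromosome enrichment of a satellite.
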
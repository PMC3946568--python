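"""Detect poly(A) cleavage sites and score the TGTAA signal.

Reads failing full-length alignment but carrying a poly(A)/(T) extremity
pinpoint the pre-mRNA cleavage site (CS). Pentamer enrichment in the 50 nt
upstream of validated sites is scored against a per-sequence shuffle null.
"""

from earlyburst import polya
from earlyburst.formats import dedupe_to_species
from earlyburst.pipeline import RunConfig, two_step_mapping
from earlyburst.simulate import SimConfig, simulate_experiment

cfg = SimConfig(n_genes=20, base_depth=12_000, host_len=25_000,
                tgtaa_fraction=0.72)
genome, truth, readsets, host = simulate_experiment(cfg, seed=2)
reads = [(r.sequence, tp) for tp, rs in readsets.items() for r in rs.reads]
species = dedupe_to_species(reads)
_, _, unmapped = two_step_mapping(species, genome, host, RunConfig(sim=cfg))

evidence = polya.find_tail_reads(unmapped, genome)
sites = polya.call_cleavage_sites(evidence, min_species=2, genome=genome)
truth_keys = {(c.position, c.strand) for c in truth.cleavage_sites}
hits = sum((s.position, s.strand) in truth_keys for s in sites)
print(f"validated cleavage sites: {len(sites)} "
      f"({hits} match the planted truth exactly)")

seqs = [s for _, s, _ in polya.upstream_sequences(sites, genome, (-50, -1))]
enr = polya.pentamer_enrichment(seqs, n_shuffles=1000, seed=2)
print("\ntop pentamers by z-score (observed vs shuffle null):")
print(enr.head(3)[["word", "observed", "null_mean", "null_sd", "z"]]
      .to_string(index=False))

dist = polya.motif_positional_distribution(
    [s for _, s, _ in polya.upstream_sequences(sites, genome, (-100, -1))],
    "TGTAA", (-100, -1))
peak = dist.loc[dist["count"].idxmax()]
print(f"\nTGTAA occurrences peak at position {int(peak.position)} "
      f"(-1 = last templated base); the signal was planted at -17.")
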
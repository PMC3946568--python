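"""Discover splice junctions and estimate per-junction splicing frequency.

Split reads propose candidate introns; a junction-contig library remaps all
reads across the seams; junctions validated by >=5 read species are
classified by motif, strand and protein-level consequence, and their
splicing frequency is estimated as J/(J+M) from junction reads J and the
intron's median coverage M.
"""

from earlyburst import expression, splicing
from earlyburst.formats import dedupe_to_species
from earlyburst.pipeline import RunConfig, two_step_mapping
from earlyburst.simulate import SimConfig, simulate_experiment

cfg = SimConfig(n_genes=12, base_depth=20_000, host_len=20_000,
                error_rate=0.0, n_intron_genes=5, amplitude_sigma=0.0)
genome, truth, readsets, host = simulate_experiment(cfg, seed=3)
reads = [(r.sequence, tp) for tp, rs in readsets.items() for r in rs.reads]
species = dedupe_to_species(reads)
alignments, split_hits, _ = two_step_mapping(species, genome, host,
                                             RunConfig(sim=cfg))

jx_alns = [a for a in alignments if len(a.blocks) == 2]
junctions = splicing.discover_junctions(split_hits, jx_alns, genome)
track = expression.build_coverage(
    alignments, {"virus": len(genome), "host": len(host)}, list(truth.depth))
pooled = track.pooled("virus")
planted = {(i.intron_start, i.intron_end): i for i in truth.introns}

print("validated junctions (>=5 species):")
for j in junctions:
    splicing.splicing_frequency(j, pooled)
    splicing.classify_consequence(j, genome)
    t = planted.get((j.intron_start, j.intron_end))
    true_f = f"{t.frequency:.2f}" if t else "not planted"
    print(f"  {j.intron_start}-{j.intron_end} {j.motif_class} "
          f"strand={j.inferred_strand} species={j.n_species} "
          f"f_est={j.frequency:.2f} (planted {true_f}) {j.consequence}")
# f_est is the estimated fraction of the gene's transcripts with the intron
# excised; J/(J+M) is bounded by 1, unlike the literal ratio J/M.
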
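"""Generate the synthetic study fixture and look at its ground truth.

The generator emits labeled protein families (GR types sharing a common
core, TF hard negatives, random negatives), one binding motif per GR
type, and small genomes whose promoter windows carry planted motif
instances at known offsets.
"""

from grmine.synthetic import SyntheticConfig, gen_fixture

bundle = gen_fixture(SyntheticConfig(seed=0))

n_gr = sum(1 for p in bundle.proteins if p.is_gr)
n_tf = sum(1 for p in bundle.proteins if p.label == "tf")
n_rand = sum(1 for p in bundle.proteins if p.label == "other:random")
print(f"proteins: {n_gr} GR across {bundle.config.n_gr_types} types, "
      f"{n_tf} TF hard negatives, {n_rand} random negatives")
print(f"genomes: {len(bundle.genomes)} x {bundle.config.genes_per_genome} genes, "
      f"{len(bundle.truth.planted_sites)} planted binding sites")

site = bundle.truth.planted_sites[0]
print(f"example planted site: motif {site.motif_id} at offset {site.offset} "
      f"in the upstream window of {site.genome_id}:{site.gene_id}")
print(f"designed GR-GR cross-regulation edges: {sorted(bundle.truth.cross_edges)}")
# Each edge (A, B) means regulator A's motif was planted upstream of the
# gene encoding regulator B; these are what network reconstruction must find.
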
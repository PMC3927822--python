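"""Split GluRS alignments into N/C domains and census the HIGH motif.

The domain boundary is projected from a reference row (residue 322 by
default); the class-I synthetase 'HIGH' signature H[IVL]G[GNSTLM] is then
sought near the start of each catalytic domain.
"""

import numpy as np

from glxrs import domains, simulate

rng = np.random.default_rng(0)

# A small aligned family: a 468-residue reference and three relatives.
ref = simulate.random_protein(468, rng)
ref = ref[:10] + "HIGG" + ref[14:]  # plant the canonical motif variant
ids, rows = ["ref"], [ref]
for i, variant in enumerate(["HIGG", "HVGN", "HVGT"]):
    seq = simulate._mutate_str(ref, 0.2, rng)
    rows.append(seq[:10] + variant + seq[14:])
    ids.append(f"seq{i}")

aln = domains.AlignedSet(ids=ids, rows=rows, reference_id="ref")
splits = domains.split_domains(aln, boundary_residue=322)
print(f"split column {splits[0].split_column}: "
      f"N={len(splits[0].n_domain)} aa, C={len(splits[0].c_domain)} aa")

calls = [domains.find_high_motif(s.n_domain, seq_id=s.id) for s in splits]
groups = {"ref": "canonical", "seq0": "canonical",
          "seq1": "GluRS2-like", "seq2": "outlier-like"}
print(domains.motif_census(calls, groups))
# HphiGG marks canonical GluRS; HphiGN / HphiGT variants flag copies whose
# catalytic domain did not arise by duplication of the canonical gene.
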
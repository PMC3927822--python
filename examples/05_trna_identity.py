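"""Profile tRNA(Gln) identity elements and the U32-U38/A37 signature.

Two simulated clades differ in their anticodon-loop signature probability
(0.95 vs 0.05) while the acceptor-stem determinants (U1-A72, G2-C71, G3-C70)
and G10 are always canonical.
"""

from glxrs import evaluation

frames = evaluation.trna_signature_experiment(seed=2, n_per_clade=200)
print(frames["signature"].to_string(index=False))
print()
print(frames["pairs"].to_string(index=False))
# The signature fraction tracks each clade's generating probability; the
# acceptor pairs are reported as Watson-Crick match fractions and stay at
# 1.0 -- 'absolutely conserved' in every group.
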
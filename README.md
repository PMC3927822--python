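# glxrs

A Python toolkit for studying the evolution of the bacterial
Gln-tRNA^Gln^-synthesis machinery: glutamyl-tRNA synthetase (GluRS, gene
*gltX*), glutaminyl-tRNA synthetase (GlnRS, gene *glnS*) and the
amidotransferase gatCAB (*gatA*/*gatB*/*gatC*).

Bacteria make Gln-tRNA^Gln^ either directly (GlnRS) or indirectly (a
non-discriminating GluRS mischarges tRNA^Gln^ with Glu, which gatCAB then
amidates). Some lineages carry a second GluRS copy, GluRS2, that charges
only tRNA^Gln^. Whether such a copy arose by in-genome duplication, by
full-length horizontal gene transfer (HGT), or by independent acquisition of
its two domains — a *chimera* — can be read off dual phylogenies built
separately from the N-terminal catalytic and C-terminal anticodon-binding
domains. This package implements that whole inference chain on desk-scale,
fully reproducible inputs, for molecular evolutionists who want the logic as
tested, composable functions rather than a one-off analysis.

## What it does

- **`glxrs.genomes`** — bin each genome into one of the five co-occurrence
  groups `⟨copies|GlnRS|gatCAB⟩` (`1|-|+`, `2|-|+`, `2|+|+`, `1|+|+`,
  `1|+|-`), assign GluRS functional types (ND, D⁻, D⁺, GluRS1/GluRS2), label
  copies against annotated reference isoforms, and tabulate phylum × group
  counts. A packaged fixture reproduces a 366-genome, 20-phylum/class survey
  cell by cell.
- **`glxrs.domains`** — split aligned GluRS at a reference boundary
  (1–322 / 323–468 by default) into N/C domains; scan for the class-I
  synthetase HIGH motif `H[IVL]G[GNSTLM]` (HϕGG vs HϕGN vs HϕGT…); detect
  the ~140-residue Yqey paralog appended to some GlnRS C-termini.
- **`glxrs.phylo`** — p/Poisson distances with pairwise gap deletion,
  deterministic neighbor joining, nonparametric bootstrap supports, outgroup
  rooting, Newick I/O (trees from external ML software drop in anywhere).
- **`glxrs.concordance`** — sister-clade placement, monophyly tests, and the
  origin verdicts `duplication | full_length_hgt | chimera |
  concordant_native | ambiguous` from N- vs C-domain tree comparison, plus
  Robinson–Foulds distances.
- **`glxrs.trna`** — tRNA^Gln^ identity-element profiles on canonically
  numbered alignments: acceptor-stem determinants (U1-A72, G2-C71, G3-C70,
  G10), anticodon isotypes (UUG → Gln1, CUG → Gln2) and the U32-U38/A37
  anticodon-loop signature (three-valued: gaps give a no-call, not a
  negative).
- **`glxrs.simulate`** — a ground-truth generator: clade-structured Yule
  species trees, 20-state Jukes–Cantor protein evolution, configurable
  duplication / loss / full-length- and single-domain-HGT / Yqey-graft
  events, and tRNA sets with per-clade signature probabilities. Every
  emitted sequence has exactly one truth record, so verdict accuracy is
  measurable exactly.
- **`glxrs.pipeline` / the `glxrs` CLI** — one-command orchestration from
  simulation or an inventory TSV to a summary report.

## Worked example

`examples/04_chimera_verdicts.py` simulates the three hypothesised gene
histories and recovers them from NJ trees of the two domains:

```
B_0.gltX2: observed=chimera            truth=chimera            N-donor=B C-donor=D
C_0.gltX1: observed=full_length_hgt    truth=full_length_hgt    N-donor=D C-donor=D
A_1.gltX1: observed=concordant_native  truth=concordant_native  N-donor=A C-donor=A
A_0.gltX2 duplication test: duplication (truth: duplication)
```

`B_0.gltX2`'s catalytic domain sits with its own clade B while its
anticodon-binding domain sits inside clade D — mismatched donors, hence a
chimera. `C_0.gltX1` shows the same foreign donor (D) in both trees: a
full-length transfer. `A_0.gltX2` forms a cherry with its sibling copy: a
duplication.

Classifying the packaged survey (`examples/01_classify_survey.py`) prints
the phylum × group table with grand total 366, e.g. 45 γ-proteobacteria in
`1|+|-` (GlnRS present, gatCAB absent — their GlnRS is necessarily
functional) and 47 α-proteobacteria carrying a GluRS2 copy.

Other examples cover domain splitting + motif census (02), bootstrap
supports (03) and tRNA identity profiling (05); each prints a short
interpretation alongside its numbers.

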
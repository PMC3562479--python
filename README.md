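# fvpack

Analysis of how antibody heavy- and light-chain variable domains (VH, VL)
pack against each other, and what the packing mode implies for the
antigen-binding site.

The antigen-binding site of an antibody Fv is shaped not only by its six
hypervariable loops but by the relative orientation of the two variable
domains. `fvpack` implements a complete, reusable pipeline for detecting
and characterising the two dominant VH–VL packing modes:

1. **Curation** — remove single-chain entries, scFvs, exact V-region
   duplicates (best resolution kept) and structures worse than 3 Å, with
   optional κ-chain redundancy reduction by greedy interface-identity
   clustering (80% threshold over the 20 interface positions).
2. **Structural distance** — every pair of Fvs is compared over the 20
   canonical Kabat–Chothia interface positions (L34, L36, L38, L43, L44,
   L46, L87, L89, L98, L100, H35, H37, H39, H44, H45, H47, H91, H93,
   H103, H105) with the high-accuracy global distance test,

       GDT_HA = (GDT_P0.5 + GDT_P1 + GDT_P2 + GDT_P4) / 4,

   where GDT_Pn is the largest fraction of position-paired Cα atoms that
   some rigid superposition brings within n Å; the distance is 1 − GDT_HA.
3. **Clustering** — DIANA (divisive) and average/complete/Ward/single
   agglomerative hierarchies over the distance matrix; the flat partition
   (method × k) with the highest mean silhouette width wins. The two
   packing modes surface as cluster A (proline at L44, *trans*, wider
   binding site) and cluster B (medium/large hydrophobic residue at L44,
   narrower site with a central pocket).
4. **Sequence determinants** — positions are ranked by mean Gini impurity
   decrease in a random forest on one-hot encoded positions; a
   single-residue rule (Pro-L44 → type A) and a nearest-centroid
   classifier on 1 − GDT_HA distances reproduce the mode assignment from
   sequence or structure alone.
5. **Binding-site and antigen statistics** — binding-site width from the
   L55–H57 / L24–H25 Cα diagonals and their rhomboid area d₁·d₂/2;
   antigen size as the exact radical-plane (power) Voronoi volume of the
   bound antigen (surface cells capped at vdW + 1.4 Å probe, Bondi
   radii); small-antigen (hapten, < 505 Å³) enrichment inside a cluster
   scored with the exact hypergeometric upper tail
   P(X ≥ k) = Σᵢ C(K,i)·C(N−K,n−i)/C(N,n); distance distributions
   compared with a binned Pearson χ² test.

A synthetic-data module generates Fv-like structures with two planted
packing modes — mode-specific distance distributions, mode-linked residue
profiles, and bimodal antigen volumes — so the whole pipeline is testable
end-to-end without any structure downloads. See `docs/methods.md` for the
models, parameters and design choices.

## Worked example

Generate a small synthetic study (10 mode-A and 8 mode-B antibodies) and
run the full pipeline:

```bash
fvpack synth --n-a 10 --n-b 8 --seed 7 --out demo_data
# wrote 18 structures to demo_data
fvpack all --input-dir demo_data --out demo_out
# reports written to demo_out
```

`demo_out/silhouette_by_k.tsv` shows the model selection — two packing
modes are clearly preferred:

```
method  k   silhouette
diana   2   0.485853
diana   3   0.344366
diana   4   0.124787
```

`demo_out/clustering.tsv` gives, per structure, the assigned mode, the
1 − GDT_HA distances to the two cluster centroids, and the sequence-rule
call (agreeing with the structural assignment here):

```
id      label  d_A     d_B     rule_call  outlier
syn000  A      0       0.2625  A          False
syn001  A      0.0875  0.275   A          False
syn002  B      0.2875  0.1625  B          False
```

`demo_out/enrichment.tsv` holds the antigen-size contingency tables: of
the 13 antigen-bound antibodies, 3 bind a small antigen (volume < 505 Å³)
and all 3 sit in cluster B — an upper-tail hypergeometric probability of
0.07 at this toy sample size (the full-scale study below reaches
7 × 10⁻⁶):

```
cluster  N   K  n  k  p
A        13  3  7  0  1
B        13  3  6  3  0.0699301
```

Other reports: the distance matrix, a Newick dendrogram, per-position
Gini importances (L44 and its covarying neighbours at the top),
Table-style per-cluster distance means ± sd stratified by bound/unbound,
χ² comparisons, per-antigen Voronoi volumes, and a machine-readable run
manifest. Re-running the same configuration reproduces every report byte
for byte.

The same pipeline runs on real, Kabat–Chothia-numbered PDB/mmCIF files:
point `--input-dir` at the coordinate files plus a `metadata.tsv`
(id, light_type, species, resolution, bound) and, for author-numbered
files, per-structure numbering maps (TSV: chain, author_resid,
kabat_chothia_position).

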
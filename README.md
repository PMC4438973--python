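# shapealign

Structure-informed RNA sequence alignment from SHAPE chemical probing data.

## The problem

Homologous RNAs conserve structure more strongly than sequence, but
structure-aware sequence comparison usually depends on error-prone *de novo*
secondary-structure prediction. SHAPE probing offers a model-free,
per-nucleotide readout of local backbone flexibility: paired nucleotides are
lowly reactive, flexible ones highly reactive. Because related nucleotides in
homologous RNAs tend to have similar SHAPE reactivities, the reactivity
profile itself can drive sequence alignment — with no structure model at all.

`shapealign` is for RNA biologists and bioinformaticians who have
nucleotide-resolution SHAPE(-MaP) reactivity profiles for homologous RNAs and
want to (1) align them globally, using reactivities alone or combined with
base identity, (2) benchmark those alignments against curated references, and
(3) use the alignments plus reactivities to model consensus secondary
structures through the ViennaRNA engine.

## The method

Two profiles x and y are aligned by a global affine-gap dynamic program
(Gotoh). Aligning positions i and j contributes a clipped linear score in the
absolute reactivity difference,

    s(x_i, y_j) = max( m·|x_i − y_j| + b ,  m + b )

with slope m = −2 and intercept b = 2 by default, so identical reactivities
score +2, the score falls linearly with |Δ|, and floors at 0 for |Δ| ≥ 1.
Unprobed positions score 0 (neutral). In *combined* mode a base-identity term
(MATCH = +2 / MISMATCH = −2) is added. Gap runs of length L cost GOP + L·GEP
(GOP = −5, GEP = −0.25 for SHAPE-only; GOP = −6, GEP = −1 for combined).
Alignment sensitivity is the percentage of reference matched-nucleotide pairs
recovered.

For structure modeling, the alignment is folded with `RNAalifold`
(partition function, ribosum scoring, SHAPE pseudo-free energies, maximum
pair span 600 nt); consensus pairs with pairing probability > 0.95 are mapped
onto each sequence and enforced as hard constraints in an individual
`RNAfold` refold. Predicted structures are scored against reference models by
sensitivity/PPV with a 5-nt local refolding allowance: a reference pair
(x, y) matches a predicted pair (x′, y′) if one end coincides and the other
differs by at most 5 nt. Pseudoknots and non-canonical pairs (G-U excepted)
are excluded from both sides.

## Worked example

Simulate a homologous pair with a known true alignment, align it both ways,
and check recovery:

```python
from shapealign import (SimConfig, make_homologous_pair, gotoh_align,
                        alignment_sensitivity, SHAPE_ONLY_DEFAULTS,
                        COMBINED_DEFAULTS)

ancestor, descendant, truth = make_homologous_pair(SimConfig())
for params in (SHAPE_ONLY_DEFAULTS, COMBINED_DEFAULTS):
    aln = gotoh_align(ancestor, descendant, params)
    sens = alignment_sensitivity(aln.aligned_pairs(), truth)
    print(f"{params.mode}: score {aln.score:.1f}, recovery {sens:.1f}%")
```

prints

```
shape_only: score 1804.7, recovery 88.2%
combined: score 3093.0, recovery 97.3%
```

i.e. on a 1,500-nt pair with 25% substitutions and 2% indels, reactivities
alone recover 88.2% of the true matched pairs, and adding base identity
raises recovery to 97.3% — the combined mode strictly improves on either
signal alone. The same workflows are available from the shell:

```bash
shapealign simulate --seed 7 --out fixtures/
shapealign align --seq1 fixtures/ancestor.fasta --shape1 fixtures/ancestor.shape \
                 --seq2 fixtures/descendant.fasta --shape2 fixtures/descendant.shape \
                 --mode combined --out aln/
shapealign evaluate --kind alignment --test aln/alignment.fasta \
                    --reference fixtures/true_alignment.fasta
```

Other subcommands: `histogram` (related vs randomized |Δ reactivity|
distribution with permutation control and Welch t-test), `optimize`
(exhaustive parameter grid search against training alignments) and `fold`
(the two-step consensus structure pipeline).

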
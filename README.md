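# kinsca

Statistical coupling analysis (SCA) of protein-kinase multiple sequence
alignments: which residues of the catalytic domain co-evolved with which,
and where do the coupled pairs sit on the kinase fold?

`kinsca` is a library for the sequence-based SCA workflow applied to the
human kinome: score every column of an anchored alignment for evolutionary
conservation, perturb a site *in silico* by restricting the alignment to the
sequences sharing the anchor protein's residue there, measure how every other
column's amino-acid distribution shifts, extract the position pairs that rank
each other first (reciprocal coupling pairs), compare pair sets across
kinases (Pak2, PKA, Src) through a curated residue-equivalence table, and map
scores and pair distances onto crystal structures. A synthetic-alignment
generator with planted conservation and planted covarying pairs makes every
stage testable at desk scale without downloading anything.

## The statistics

For an alignment column *i* with *n<sub>i</sub>* non-gap residues, each amino
acid *x* (background rate *q<sub>x</sub>*, eukaryotic Swiss-Prot composition)
contributes a binomial log-likelihood ratio between the observed count and
the count implied by the alignment-wide frequency of *x*:

    R_i(x) = ln P[c_i(x); n_i, q_x] − ln P[round(f_MSA(x) · n_i); n_i, q_x]

where `P[k; n, q]` is the binomial PMF. The conservation value of the column
is the Euclidean norm of that 20-vector:

    ΔE_i = sqrt( Σ_x R_i(x)² )

A perturbation at site *j* keeps only the sequences carrying the anchor's
residue there; recomputing `R` on the subset (with the subset's own
alignment-wide frequencies and depths) gives the coupling of site *i* to the
perturbation:

    ΔΔE_{i,j} = sqrt( Σ_x [ R_{i|j}(x) − R_i(x) ]² )

Both are non-negative and carry the arbitrary unit kT\* ≡ 1. Two positions
form a **reciprocal pair** when each lies in the other's top-10 couplings;
the pair is **major** when each is the other's single strongest coupling.

## Worked example

```python
from kinsca import full_coupling_matrix, swissprot_background
from kinsca.reciprocal import find_reciprocal_pairs
from kinsca.synthetic import CoupledPair, SyntheticSpec, generate

aln, _ = generate(SyntheticSpec(
    n_sequences=500, n_columns=30,
    coupled_pairs=(CoupledPair(5, 12, "C", "H", 0.9),),
    gap_rate=0.03, seed=3,
))
matrix = full_coupling_matrix(aln, swissprot_background())
for p in find_reciprocal_pairs(matrix, k=10):
    if p.klass == "major":
        print(p.pos_a, p.pos_b, round(p.ddE_ab, 2), round(p.ddE_ba, 2), p.klass)
```

prints

```
5 12 73.99 36.77 major
```

the planted covarying pair (90% of sequences carry Cys5+His12 jointly)
recovered as the single major reciprocal pair; the two coupling values are
the ΔΔE of each member under the other's perturbation. The scripts in
`examples/` walk through each capability the same way — conservation
profiling, perturbation tables, cross-kinase pair comparison (the three
kinases share exactly 4 common pair classes, Pak2 numbering E294-R367,
N373-D386, W427-G439, E413-R488), and structure distance mapping — each
printing the numbers it computes and what they mean.

There is also a thin CLI (`sca load | conserve | perturb | matrix | pairs |
compare | distances | synth | run`) for shell use; `sca run --config
run.yaml` executes the whole workflow and writes TSV reports plus a hashed
run manifest.

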
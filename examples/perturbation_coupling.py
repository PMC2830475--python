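"""Statistical coupling (ΔΔE) of one perturbation site.

Plants a covarying column pair (8, 23): 85% of sequences carry Cys8+His23
jointly, the rest draw both columns from the background.  Perturbing
column 8 at the anchor's Cys restricts the alignment to the Cys-carrying
subset and asks which positions' amino-acid distributions shift.
"""

from kinsca import full_coupling_matrix, perturbation_subset, swissprot_background
from kinsca.reciprocal import top_k_partners
from kinsca.synthetic import CoupledPair, SyntheticSpec, generate

aln, _ = generate(
    SyntheticSpec(
        n_sequences=500,
        n_columns=40,
        coupled_pairs=(CoupledPair(8, 23, "C", "H", 0.85),),
        gap_rate=0.03,
        seed=7,
    )
)
bg = swissprot_background()

_, spec = perturbation_subset(aln, 8, "C")
print(
    f"perturbation C8: subset {spec.subset_size}/{spec.n_effective_at_site} "
    f"sequences ({spec.conservation_percent:.1f}% conserved)"
)

matrix = full_coupling_matrix(aln, bg)
print(f"mean ddE over all positions: {matrix.column_mean(8):.2f}\n")
print("rank  position  ddE")
for rank, (pos, value) in enumerate(top_k_partners(matrix, 8, k=5), start=1):
    print(f"{rank:>4}  {pos:>8}  {value:6.2f}")

# The planted partner (column 23) heads the ranking: conditioning on Cys8
# drives His23 from its ~2% background rate to near fixation, the largest
# distribution shift in the alignment.  The mean over all positions is the
# low baseline produced by subsampling noise alone.
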
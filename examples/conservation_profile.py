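"""Per-position conservation (ΔE) on a synthetic kinase-like alignment.

Generates a 300 x 40 anchored alignment with one strongly conserved column
planted at position 12, scores every column against the shipped eukaryotic
background composition, and prints the five most conserved positions.
"""

import numpy as np

from kinsca import conservation_profile, swissprot_background
from kinsca.synthetic import ConservedColumn, SyntheticSpec, generate

aln, truth = generate(
    SyntheticSpec(
        n_sequences=300,
        n_columns=40,
        conserved_columns=(ConservedColumn(12, "W", 0.97),),
        seed=42,
    )
)
profile = conservation_profile(aln, swissprot_background())

order = np.argsort(-profile.delta_E)
print("column  dE      %max")
for c in order[:5]:
    print(f"{c:>6}  {profile.delta_E[c]:7.2f} {profile.normalized_percent[c]:6.1f}")
print(f"\nplanted conserved column: {truth['conserved_columns'][0]['column']}")

# The planted column tops the profile by a wide margin: a column that is ~97%
# tryptophan is wildly improbable under the ~1% background rate, which the
# binomial log-ratio turns into a large conservation value. The unplanted
# columns form the low, noisy baseline.
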
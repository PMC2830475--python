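# Methods

## Model

The package implements sequence-based statistical coupling analysis in the
Lockless–Ranganathan tradition. The working assumption is that a protein
family's alignment is a record of a long natural mutagenesis experiment:
positions whose amino-acid distribution is far from the background
composition of proteins are conserved for structural or functional reasons,
and position pairs whose distributions shift *together* when the family is
restricted to a subset are evolutionarily coupled. Phylogenetic correlation
between sequences is deliberately ignored (every sequence counts once); this
is a known simplification of the method, not an accident of this
implementation.

### Conservation (ΔE)

Column *i* holds counts `c_i(x)` of each amino acid *x* over `n_i` non-gap
characters. Each count is scored by the binomial log-PMF at the background
rate `q_x`, and referenced against the count implied by the alignment-wide
frequency `f_MSA(x)` at the same depth:

    R_i(x) = ln P[c_i(x); n_i, q_x] − ln P[round(f_MSA(x) · n_i); n_i, q_x]
    ΔE_i   = || R_i ||_2

Conventions, each of which changes printed values and is therefore pinned:

* **Background table** — the ExPASy UniProtKB/Swiss-Prot amino-acid
  composition, shipped as a versioned JSON data file, renormalised to sum
  to 1. Pipeline manifests record its checksum. Values are sensitive to the
  table at roughly the ±0.1 level across releases.
* **Reference count** — `f_MSA(x) · n_i` rounded half-away-from-zero (the
  PMF needs an integer; ties-to-even would make the reference depend on
  parity). `f_MSA` is the global frequency over all columns of the
  alignment being scored — for the coupling statistic, the subset alignment
  supplies its own `f` and `n`.
* **Gaps** — excluded from counts and depths; a column with no residues has
  no ΔE (error in the profile, missing value inside a subset). Gap symbols
  `-` and `.` are normalised to `-`; ambiguity codes are rejected by
  default (`strict`) or read as gaps (`lenient`), protecting the 20-letter
  binomial alphabet.
* **Units** — kT* ≡ 1, values unitless. Percent normalisation of a profile
  is 100·ΔE/max ΔE; an all-zero profile stays zero (a single-column
  alignment is necessarily all-zero, because its column composition *is*
  the alignment-wide composition).

All PMFs are evaluated in log space via log-gamma, so the statistics are
finite at any depth. The functional form lives in one routine
(`core._log_ratio_vectors`) so an alternative normalisation can be swapped
in without touching anything else.

Note the statistic is *extensive*: ΔE of an invariant column grows roughly
linearly with alignment depth (the binomial sharpens), and values for a
482-sequence alignment reach the thousands. Only relative comparisons
within one alignment are meaningful; profiles are reported alongside their
percent-of-maximum normalisation for that reason.

### Coupling (ΔΔE) and its confounding

A perturbation at site *j* restricts the alignment to the sequences carrying
a fixed residue at *j* (by default the anchor protein's residue), and

    ΔΔE_{i,j} = || R_{i|subset} − R_i ||_2 .

The full matrix is oriented rows = affected position *i*, columns =
perturbation *j*; the diagonal is computed but excluded from rankings and
averages; subsets smaller than 20 sequences trigger a warning but are still
scored (moderately conserved sites with ~35% subsets are a designed use
case). When *j* is 100% conserved and gap-free the subset is the whole
alignment and its column is exactly zero.

Because `R` is extensive, ΔΔE conflates two effects: the composition shift
at *i* induced by conditioning on *j* (the signal of interest) and the mere
depth change `n_i → n_{i|subset}`, which moves `R_i` for every conserved
column regardless of any dependence on *j*. Consequences, verified
numerically on the synthetic benchmarks and documented because they shape
what the tests can honestly claim:

* a single planted covarying pair in an otherwise-background alignment is
  recovered as the major reciprocal pair essentially always (20/20 seeds at
  ρ = 0.8, n = 500): unconserved null columns have `R ≈ 0` at any depth, so
  the partner has no competition;
* with several strongly conserved columns present (e.g. nine co-planted
  pairs), every conserved column lights up under every perturbation and the
  depth artifact exceeds the partner's composition signal, so mutual rank-1
  recovery of all pairs simultaneously is not achievable under this
  functional form. The detection property that does survive — and the one
  asserted at benchmark scale — is that the planted partner's ΔΔE exceeds
  the 99th percentile of the ΔΔE of unplanted columns under the same
  perturbation (18/18 on the 482 × 252 benchmark).

The same confounding is visible in real kinase data, where the strongest
reciprocal pair joins the two most conserved catalytic-domain residues (the
F-helix tryptophan and glycine).

### Reciprocal pairs

Per perturbation, positions are ranked by ΔΔE descending, ties broken by
ascending residue number (a total, deterministic order). A pair is
reciprocal when each member is in the other's top-k (k = 10 by default),
major when both ranks are 1, minor otherwise. A tie for a column's top value
marks every pair carrying that value as `ambiguous` rather than silently
promoting one candidate — a silent tie-break could fabricate or destroy a
major pair. Major pairs should form a partial matching (each position has
one rank-1 partner); `check_major_matching` reports violations instead of
dropping them. Perturbations whose column is undefined are excluded and the
exclusion is visible in `CouplingMatrix.column_defined`.

### Cross-kinase comparison

Pair sets from different proteins are compared through a residue-equivalence
table (one column per protein, one row per shared alignment position); a
pair's equivalence class is *common* when present in every compared protein,
*specific* otherwise, and an unmapped residue is an error naming the
residue. The shipped table covers the Pak2/PKA/Src catalytic-domain residues
appearing in conservation and coupling reports (e.g. Pak2 Trp427 ↔ PKA
Trp222 ↔ Src Trp446); it is curated and partial by construction, and the
optional path argument accepts a user table for other protein sets.

### Structures

"Closest distance" is the minimum heavy-atom–heavy-atom Euclidean distance
between two residues, reported to 0.1 Å — the convention of Swiss-Pdb
Viewer-style measurements on hydrogen-free X-ray structures. Hydrogens and
waters are excluded at load; other hetero residues are kept; altlocs follow
Biopython's highest-occupancy default; model 0 is read unless asked
otherwise. Score annotation writes per-residue values into the
temperature-factor column (sentinel 0.00 for unscored residues) so a viewer
colours the map directly. Numbering offsets between the analysed protein
and the crystallised homologue are explicit `ResidueMapping` objects; the
shipped Pak2→Pak1 table maps the catalytic domain 249–500 at +21 (Pak2
Thr402 ↔ Pak1 Thr423, Lys278 ↔ Lys299) — the offset is region dependent
because of Pak1's extra N-terminal residues, which is why it is a table and
not a number.

## Synthetic data

The generator emulates an anchored kinome-scale alignment: N×L i.i.d. draws
from the background composition, with three kinds of planted structure —

* **conserved column**: residue emitted with probability `p_c`, background
  otherwise;
* **coupled pair** (ρ-mixture): with probability ρ the joint state
  `(residue_a, residue_b)`, else both columns independent background.
  Conditioning on `residue_a` then enriches `residue_b` to
  ρ/(ρ + (1−ρ)q_a), an analytically checkable shift;
* **gaps**: i.i.d. at `gap_rate`, never in the anchor row (row 0), which
  also carries every planted residue so that anchor-residue perturbations
  probe the planted structure.

One seeded generator per call; no global state; identical seeds give
byte-identical alignments. Defaults mirror the real study's shape: 482
sequences × 252 retained columns, and the full-scale benchmark plants nine
covarying pairs to mirror the nine reciprocal pairs reported for Pak2
(counts mirrored, values synthetic). Star phylogeny, i.i.d. gaps and
single-residue coupling states are deliberate simplifications: passing
recovery tests show the statistics detect the planted dependence structure
at realistic size and noise, not that they would resolve phylogenetic
confounding or alignment error in real data.

## Problem sizes and runtimes

The coupling matrix is vectorised (subset counts for all L perturbations via
one boolean-mask × one-hot matrix product, then one batched log-PMF over the
L×L×20 array); a full 482 × 252 matrix takes about 1.5 s, so the benchmark
suite, the 20-replicate recovery study (n = 500, L = 30) and the whole test
suite run in well under a minute. Toy oracle comparisons (≤ 10 × 8) use
mpmath at 50 significant digits and agree with the vectorised path to
better than 1e-9 relative error.

## Known limitations

* The conservation/coupling scale is extensive in alignment depth (see
  above); cross-alignment comparisons of raw values are not meaningful.
* No statistical significance is attached to ΔΔE values or pair calls; the
  null-percentile detection criterion used on benchmarks is a synthetic-data
  device, not an inference procedure.
* The residue-equivalence and Pak2→Pak1 tables are curated fixtures covering
  the reported kinase residues, not general-purpose homology maps; the
  pairwise-alignment route to building such tables is out of scope.
* The published kinome alignments and the PDB entries they are scored
  against are external inputs supplied by the user.
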
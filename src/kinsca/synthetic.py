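"""Synthetic anchored alignments with known statistical structure.

The generator emulates the shape of a kinase-family alignment — a few hundred
sequences over a few hundred columns, background-distributed residues, a
handful of strongly conserved columns, covarying column pairs and scattered
gaps — with every planted feature recorded in a truth record so recovery can
be asserted.  Sequences are drawn independently (star phylogeny): like the
coupling analysis itself, the generator ignores phylogenetic correlation.

The coupling model for a planted pair (a, b) is a two-state mixture: with
probability ρ a sequence takes the joint state (residue_a, residue_b), else
both columns are drawn independently from the background.  Restricting to the
sequences carrying residue_a at column a therefore enriches residue_b at
column b from its background rate q_b to ρ / (ρ + (1 − ρ) q_a) — an
analytically transparent subset shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .alignment import AA_ALPHABET, AA_INDEX, Alignment
from .background import BackgroundFrequencies, swissprot_background

__all__ = ["ConservedColumn", "CoupledPair", "SyntheticSpec", "generate", "benchmark_suite"]


@dataclass(frozen=True)
class ConservedColumn:
    column: int
    residue: str
    conservation: float  # probability a sequence carries `residue` here

    def __post_init__(self) -> None:
        if self.residue not in AA_INDEX:
            raise ValueError(f"unknown residue {self.residue!r}")
        if not (0.0 <= self.conservation <= 1.0):
            raise ValueError("conservation must lie in [0, 1]")


@dataclass(frozen=True)
class CoupledPair:
    col_a: int
    col_b: int
    residue_a: str
    residue_b: str
    rho: float  # probability of the jointly fixed state

    def __post_init__(self) -> None:
        if self.col_a == self.col_b:
            raise ValueError("coupled pair must span two distinct columns")
        for r in (self.residue_a, self.residue_b):
            if r not in AA_INDEX:
                raise ValueError(f"unknown residue {r!r}")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic anchored alignment."""

    n_sequences: int = 482
    n_columns: int = 252
    background: BackgroundFrequencies | None = None
    conserved_columns: tuple[ConservedColumn, ...] = ()
    coupled_pairs: tuple[CoupledPair, ...] = ()
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.n_columns < 1:
            raise ValueError("alignment dimensions must be positive")
        if not (0.0 <= self.gap_rate <= 1.0):
            raise ValueError("gap_rate must lie in [0, 1]")
        planted = [c.column for c in self.conserved_columns]
        for p in self.coupled_pairs:
            planted += [p.col_a, p.col_b]
        if len(planted) != len(set(planted)):
            raise ValueError("a column may be planted at most once")
        for col in planted:
            if not (0 <= col < self.n_columns):
                raise ValueError(f"planted column {col} out of range")


def generate(spec: SyntheticSpec) -> tuple[Alignment, dict]:
    """Draw one alignment from a spec; deterministic under its seed.

    Row 0 is the gap-free anchor and carries every planted residue at its
    planted column, so perturbing a planted column at the anchor's residue
    probes the planted structure.  The truth record echoes the spec's planted
    positions (and the seed) for downstream assertions.
    """
    rng = np.random.default_rng(spec.seed)
    bg = spec.background or swissprot_background()
    N, L = spec.n_sequences, spec.n_columns

    idx = rng.choice(20, size=(N, L), p=bg.freq).astype(np.int8)

    for cc in spec.conserved_columns:
        hit = rng.random(N) < cc.conservation
        idx[hit, cc.column] = AA_INDEX[cc.residue]

    for cp in spec.coupled_pairs:
        joint = rng.random(N) < cp.rho
        idx[joint, cp.col_a] = AA_INDEX[cp.residue_a]
        idx[joint, cp.col_b] = AA_INDEX[cp.residue_b]

    # anchor carries the planted residues and stays gap free
    for cc in spec.conserved_columns:
        idx[0, cc.column] = AA_INDEX[cc.residue]
    for cp in spec.coupled_pairs:
        idx[0, cp.col_a] = AA_INDEX[cp.residue_a]
        idx[0, cp.col_b] = AA_INDEX[cp.residue_b]

    if spec.gap_rate > 0:
        gaps = rng.random((N, L)) < spec.gap_rate
        gaps[0, :] = False
        idx = np.where(gaps, -1, idx)

    letters = np.array(list(AA_ALPHABET + "-"))
    rows = tuple("".join(letters[idx[s]]) for s in range(N))
    ids = ("ANCHOR",) + tuple(f"seq{k:04d}" for k in range(1, N))
    aln = Alignment(ids=ids, rows=rows, anchor_index=0)

    truth = {
        "seed": spec.seed,
        "n_sequences": N,
        "n_columns": L,
        "gap_rate": spec.gap_rate,
        "conserved_columns": [asdict(c) for c in spec.conserved_columns],
        "coupled_pairs": [asdict(p) for p in spec.coupled_pairs],
    }
    return aln, truth


def benchmark_suite(
    seeds: list[int], include_full_scale: bool = True
) -> dict[str, tuple[Alignment, dict]]:
    """Named fixtures used by the acceptance checks.

    Per seed: a *small* fixture (120 sequences × 40 columns, one conserved
    column, two coupled pairs, 3% gaps) for fast end-to-end runs, and — when
    ``include_full_scale`` is set — a *full* fixture at the scale of the real
    kinase alignments (482 × 252) carrying nine coupled pairs, mirroring the
    nine reciprocal coupling pairs the analysis reports on real kinases.
    """
    suite: dict[str, tuple[Alignment, dict]] = {}
    for seed in seeds:
        small = SyntheticSpec(
            n_sequences=120,
            n_columns=40,
            conserved_columns=(ConservedColumn(7, "W", 0.97),),
            coupled_pairs=(
                CoupledPair(3, 21, "C", "H", 0.85),
                CoupledPair(12, 30, "E", "R", 0.85),
            ),
            gap_rate=0.03,
            seed=seed,
        )
        suite[f"small_seed{seed}"] = generate(small)
        if include_full_scale:
            pair_slots = [(10, 150), (25, 200), (40, 90), (60, 220), (75, 130),
                          (100, 240), (115, 170), (140, 190), (160, 230)]
            residues = [("C", "H"), ("E", "R"), ("W", "G"), ("N", "D"), ("F", "Y"),
                        ("K", "E"), ("M", "L"), ("T", "S"), ("P", "G")]
            full = SyntheticSpec(
                n_sequences=482,
                n_columns=252,
                conserved_columns=(ConservedColumn(177, "W", 0.98),),
                coupled_pairs=tuple(
                    CoupledPair(a, b, ra, rb, 0.85)
                    for (a, b), (ra, rb) in zip(pair_slots, residues)
                ),
                gap_rate=0.03,
                seed=seed,
            )
            suite[f"full_seed{seed}"] = generate(full)
    return suite
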
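"""Reciprocal coupling pairs and their comparison across kinases.

A perturbation at site j ranks every other position by its coupling ΔΔE_{i,j}.
Two positions form a *reciprocal* pair when each lies in the other's top-k
(k = 10 by default); the pair is *major* when each is the other's single
strongest coupling, *minor* otherwise.  Pair sets computed for different
kinases are compared through a curated residue-equivalence table and split
into pairs common to all kinases versus pairs specific to some.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CouplingMatrix

__all__ = [
    "ReciprocalPair",
    "PairComparison",
    "EquivalenceTable",
    "top_k_partners",
    "find_reciprocal_pairs",
    "compare_across_proteins",
    "load_equivalence",
    "pairs_to_frame",
    "pairs_from_frame",
]

DEFAULT_K = 10


@dataclass(frozen=True)
class ReciprocalPair:
    """A mutually top-ranked position pair, in anchor residue numbers.

    ``rank_ab`` is the rank of b within perturbation-a's ranking (so
    ``ddE_ab`` is the matrix entry [affected=b, perturbed=a]); ``rank_ba`` and
    ``ddE_ba`` mirror it.  ``ambiguous`` flags a tie at rank 1 in either
    ranking, where the major/minor call depends on tie-breaking.
    """

    pos_a: int
    pos_b: int
    rank_ab: int
    rank_ba: int
    ddE_ab: float
    ddE_ba: float
    klass: str  # "major" | "minor"
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.pos_a >= self.pos_b:
            raise ValueError("pairs are stored canonically with pos_a < pos_b")
        if self.klass not in ("major", "minor"):
            raise ValueError(f"unknown pair class {self.klass!r}")
        is_major = self.rank_ab == 1 and self.rank_ba == 1
        if is_major != (self.klass == "major"):
            raise ValueError("class inconsistent with ranks")

    @property
    def positions(self) -> tuple[int, int]:
        return (self.pos_a, self.pos_b)


def top_k_partners(
    matrix: CouplingMatrix, site_j: int, k: int = DEFAULT_K
) -> list[tuple[int, float]]:
    """The k positions most strongly coupled to a perturbation, descending.

    ``site_j`` is an anchor residue number.  The self-coupling diagonal entry
    and undefined (NaN) entries are excluded; ties are broken by ascending
    residue number so the ranking is total and deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    j = matrix.index_of(site_j)
    if not matrix.column_defined[j]:
        raise ValueError(f"perturbation at residue {site_j} is undefined (empty subset)")
    col = matrix.ddE[:, j]
    nums = matrix.anchor_residue_numbers
    entries = [
        (nums[i], float(col[i]))
        for i in range(len(nums))
        if i != j and not np.isnan(col[i])
    ]
    entries.sort(key=lambda t: (-t[1], t[0]))
    return entries[:k]


def find_reciprocal_pairs(matrix: CouplingMatrix, k: int = DEFAULT_K) -> list[ReciprocalPair]:
    """All mutually-top-k pairs of a coupling matrix, canonically ordered.

    Perturbations with undefined columns are excluded.  A tie for the single
    strongest coupling within a column marks every pair touching that column's
    rank 1 as ambiguous rather than silently promoting or demoting it.
    """
    nums = matrix.anchor_residue_numbers
    ranks: dict[int, dict[int, tuple[int, float]]] = {}
    top_value: dict[int, float] = {}
    tied_top: set[int] = set()
    for j, num_j in enumerate(nums):
        if not matrix.column_defined[j]:
            continue
        top = top_k_partners(matrix, num_j, k=k)
        ranks[num_j] = {pos: (r + 1, val) for r, (pos, val) in enumerate(top)}
        col = matrix.ddE[:, j]
        finite = np.delete(col, j)
        finite = finite[~np.isnan(finite)]
        if top:
            top_value[num_j] = top[0][1]
            if np.sum(np.isclose(finite, top[0][1])) > 1:
                tied_top.add(num_j)

    pairs: list[ReciprocalPair] = []
    for a in ranks:
        for b, (rank_ab, ddE_ab) in ranks[a].items():
            if b <= a or b not in ranks or a not in ranks[b]:
                continue
            rank_ba, ddE_ba = ranks[b][a]
            klass = "major" if (rank_ab == 1 and rank_ba == 1) else "minor"
            pairs.append(
                ReciprocalPair(
                    pos_a=a,
                    pos_b=b,
                    rank_ab=rank_ab,
                    rank_ba=rank_ba,
                    ddE_ab=ddE_ab,
                    ddE_ba=ddE_ba,
                    klass=klass,
                    ambiguous=(a in tied_top and np.isclose(ddE_ab, top_value[a]))
                    or (b in tied_top and np.isclose(ddE_ba, top_value[b])),
                )
            )
    pairs.sort(key=lambda p: (p.klass != "major", p.pos_a, p.pos_b))
    return pairs


def major_pairs(pairs: list[ReciprocalPair]) -> list[ReciprocalPair]:
    return [p for p in pairs if p.klass == "major"]


def check_major_matching(pairs: list[ReciprocalPair]) -> list[int]:
    """Positions violating the partial-matching property of major pairs.

    Each position has a single rank-1 partner, so no position can belong to two
    major pairs unless rankings were inconsistent; violations are returned for
    reporting rather than silently dropped.
    """
    seen: dict[int, int] = {}
    bad: list[int] = []
    for p in major_pairs(pairs):
        for pos in p.positions:
            seen[pos] = seen.get(pos, 0) + 1
            if seen[pos] == 2:
                bad.append(pos)
    return bad


# ---------------------------------------------------------------------------
# Cross-protein comparison


_EQUIV_RESOURCE = "kinase_residue_equivalence.tsv"


class EquivalenceTable:
    """Residue correspondences between kinases, from a curated alignment.

    Each row of the underlying table is one shared alignment position; a blank
    cell means the residue has no curated equivalent in that kinase.  The
    shipped default covers the catalytic-domain residues of Pak2, PKA and Src
    that participate in conservation or coupling reports (e.g. Pak2 Trp427 ↔
    PKA Trp222 ↔ Src Trp446); it is partial by construction.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame
        self.proteins = list(frame.columns)
        self._lookup: dict[str, dict[int, int]] = {}
        for prot in self.proteins:
            col = frame[prot]
            self._lookup[prot] = {
                int(v): row for row, v in col.items() if pd.notna(v)
            }

    def shared_position(self, protein: str, residue: int) -> int:
        """Row index (shared coordinate) of a residue; KeyError if unmapped."""
        if protein not in self._lookup:
            raise KeyError(f"unknown protein label {protein!r}")
        try:
            return self._lookup[protein][residue]
        except KeyError:
            raise KeyError(
                f"residue {residue} of {protein!r} is not in the equivalence table"
            ) from None


def load_equivalence(path: str | Path | None = None) -> EquivalenceTable:
    """Load a residue-equivalence TSV (one column per protein), or the shipped default."""
    if path is None:
        with resources.as_file(
            resources.files("kinsca.data").joinpath(_EQUIV_RESOURCE)
        ) as p:
            frame = pd.read_csv(p, sep="\t", comment="#")
    else:
        frame = pd.read_csv(path, sep="\t", comment="#")
    return EquivalenceTable(frame)


@dataclass(frozen=True)
class PairComparison:
    """One equivalence-class pair with the kinases it appears in."""

    shared_pair: tuple[int, int]  # shared-coordinate row indices, sorted
    positions: dict  # protein -> (pos_a, pos_b) where present
    present_in: frozenset
    klass: str  # "common" | "specific"


def compare_across_proteins(
    pair_sets: dict[str, list[ReciprocalPair]], equivalence: EquivalenceTable
) -> list[PairComparison]:
    """Classify reciprocal pairs as common to all kinases or specific to some.

    Every pair of every protein is mapped into shared coordinates; a pair is
    *common* when its equivalence class is present in every protein of
    ``pair_sets``, *specific* otherwise.  An unmapped residue raises, naming
    the residue, rather than silently changing a pair's class.

    ``pair_sets`` values may hold :class:`ReciprocalPair` objects or bare
    ``(pos_a, pos_b)`` tuples (curated pair lists).
    """
    classes: dict[tuple[int, int], dict[str, tuple[int, int]]] = {}
    for protein, pairs in pair_sets.items():
        for p in pairs:
            pos = p.positions if isinstance(p, ReciprocalPair) else (int(p[0]), int(p[1]))
            key = tuple(
                sorted(
                    (
                        equivalence.shared_position(protein, pos[0]),
                        equivalence.shared_position(protein, pos[1]),
                    )
                )
            )
            classes.setdefault(key, {})[protein] = pos
    out = []
    all_proteins = set(pair_sets)
    for key in sorted(classes):
        members = classes[key]
        present = frozenset(members)
        out.append(
            PairComparison(
                shared_pair=key,
                positions=dict(members),
                present_in=present,
                klass="common" if present == all_proteins else "specific",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tabular round-trip


def pairs_to_frame(pairs: list[ReciprocalPair], protein: str | None = None) -> pd.DataFrame:
    rows = [
        {
            **({"protein": protein} if protein else {}),
            "pos_a": p.pos_a,
            "pos_b": p.pos_b,
            "ddE_ab": p.ddE_ab,
            "ddE_ba": p.ddE_ba,
            "rank_ab": p.rank_ab,
            "rank_ba": p.rank_ba,
            "class": p.klass,
            "ambiguous": p.ambiguous,
        }
        for p in pairs
    ]
    cols = (["protein"] if protein else []) + [
        "pos_a", "pos_b", "ddE_ab", "ddE_ba", "rank_ab", "rank_ba", "class", "ambiguous",
    ]
    return pd.DataFrame(rows, columns=cols)


def pairs_from_frame(frame: pd.DataFrame) -> list[ReciprocalPair]:
    return [
        ReciprocalPair(
            pos_a=int(r["pos_a"]),
            pos_b=int(r["pos_b"]),
            rank_ab=int(r["rank_ab"]),
            rank_ba=int(r["rank_ba"]),
            ddE_ab=float(r["ddE_ab"]),
            ddE_ba=float(r["ddE_ba"]),
            klass=str(r["class"]),
            ambiguous=bool(r.get("ambiguous", False)),
        )
        for r in frame.to_dict("records")
    ]
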
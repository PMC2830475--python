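"""Mapping scores and residue pairs onto crystal structures.

Closest inter-residue distance is defined as the minimum heavy-atom/heavy-atom
Euclidean distance, the convention used by Swiss-Pdb Viewer style distance
measurements on hydrogen-free X-ray structures.  Per-residue scores (e.g. a
conservation profile in percent of maximum) can be written into the PDB
temperature-factor column for colouring in any molecular viewer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, PDBParser, Select

__all__ = [
    "StructureModel",
    "ResidueMapping",
    "load_structure",
    "closest_distance",
    "annotate_scores",
    "pair_distance_table",
    "load_pak2_to_pak1_mapping",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

ResidueKey = tuple[str, int]


@dataclass
class StructureModel:
    """Heavy-atom coordinates of one model of a PDB entry, indexed by residue."""

    residues: dict  # (chain_id, residue_number) -> (n_atoms, 3) float array
    label: str
    model_index: int = 0
    _bio_model: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for key, coords in self.residues.items():
            if len(coords) == 0:
                raise ValueError(f"residue {key} has no atoms")
            if not np.all(np.isfinite(coords)):
                raise ValueError(f"residue {key} has non-finite coordinates")

    @property
    def chains(self) -> set[str]:
        return {chain for chain, _ in self.residues}

    def resolve(self, key: "ResidueKey | int") -> ResidueKey:
        """Accept a bare residue number when the model holds a single chain."""
        if isinstance(key, tuple):
            return key
        chains = self.chains
        if len(chains) != 1:
            raise KeyError(
                f"residue {key} is ambiguous: model has chains {sorted(chains)}; "
                "pass a (chain, residue) pair"
            )
        return (next(iter(chains)), int(key))

    def coords(self, key: "ResidueKey | int") -> np.ndarray:
        key = self.resolve(key)
        try:
            return self.residues[key]
        except KeyError:
            raise KeyError(f"residue {key} not present in structure {self.label}") from None


def load_structure(
    path: str | Path,
    chain: str | None = None,
    model: int = 0,
    label: str | None = None,
) -> StructureModel:
    """Read heavy atoms of one model from a PDB file.

    Hydrogens/deuteriums and water molecules are excluded; other hetero
    residues (ligands, ions) are kept under their residue numbers.  For
    disordered atoms Biopython's default altloc selection (highest occupancy)
    applies.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(label or path.stem, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models found")
    if model >= len(models):
        raise IndexError(f"{path}: model {model} not present ({len(models)} models)")
    bio_model = models[model]
    chain_ids = [c.id for c in bio_model]
    if chain is not None and chain not in chain_ids:
        raise KeyError(f"{path}: chain {chain!r} not found (have {chain_ids})")

    residues: dict[ResidueKey, np.ndarray] = {}
    for bio_chain in bio_model:
        if chain is not None and bio_chain.id != chain:
            continue
        for res in bio_chain:
            if res.get_resname().strip() in _WATER_NAMES:
                continue
            coords = [
                atom.get_coord()
                for atom in res
                if (atom.element or "").strip().upper() not in ("H", "D")
            ]
            if coords:
                residues[(bio_chain.id, res.get_id()[1])] = np.asarray(coords, dtype=float)
    if not residues:
        raise ValueError(f"{path}: no heavy-atom residues found (waters/hydrogens excluded)")
    return StructureModel(
        residues=residues, label=label or path.stem, model_index=model, _bio_model=bio_model
    )


def closest_distance(model: StructureModel, res_a, res_b) -> float:
    """Minimum heavy-atom distance between two residues, in Å to 0.1 precision."""
    a = model.coords(res_a)
    b = model.coords(res_b)
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=2)
    return round(float(np.sqrt(d2.min())), 1)


@dataclass(frozen=True)
class ResidueMapping:
    """Anchor residue numbers → structure (chain, residue number).

    Numbering offsets between the analysed protein and the crystallised
    homologue (e.g. Pak2 positions on a Pak1 structure) are made explicit here
    rather than applied silently.
    """

    label: str
    mapping: dict  # anchor residue number -> (chain, structure residue number)

    def __post_init__(self) -> None:
        per_chain: dict[str, set[int]] = {}
        for target in self.mapping.values():
            chain, num = target
            seen = per_chain.setdefault(chain, set())
            if num in seen:
                raise ValueError(f"mapping {self.label!r} is not injective: duplicate {target}")
            seen.add(num)

    def __getitem__(self, anchor_residue: int) -> ResidueKey:
        try:
            return self.mapping[anchor_residue]
        except KeyError:
            raise KeyError(
                f"residue {anchor_residue} has no entry in mapping {self.label!r}"
            ) from None

    def __contains__(self, anchor_residue: int) -> bool:
        return anchor_residue in self.mapping

    @classmethod
    def from_offset(
        cls, label: str, chain: str, offset: int, anchor_range: range
    ) -> "ResidueMapping":
        return cls(label, {i: (chain, i + offset) for i in anchor_range})

    @classmethod
    def from_tsv(cls, path: str | Path, chain: str = "A", label: str | None = None):
        frame = pd.read_csv(path, sep="\t", comment="#")
        mapping = {
            int(r["anchor_residue"]): (str(r.get("chain", chain)), int(r["structure_residue"]))
            for r in frame.to_dict("records")
        }
        return cls(label or Path(path).stem, mapping)


def load_pak2_to_pak1_mapping(chain: str = "A") -> ResidueMapping:
    """Pak2 catalytic-domain residues (249-500) on a Pak1 structure.

    Pak1 carries N-terminal insertions relative to Pak2, so the numbering
    offset is region dependent: +3 near the kinase-inhibitory segment
    (Pak2 Lys138 ↔ Pak1 Lys141) but +21 throughout the catalytic domain
    (Pak2 Thr402 ↔ Pak1 Thr423, Pak2 Lys278 ↔ Pak1 Lys299).  This mapping
    covers the catalytic domain only.
    """
    with resources.as_file(
        resources.files("kinsca.data").joinpath("pak2_to_pak1_catalytic.tsv")
    ) as p:
        frame = pd.read_csv(p, sep="\t", comment="#")
    mapping = {
        int(r["anchor_residue"]): (chain, int(r["structure_residue"]))
        for r in frame.to_dict("records")
    }
    return ResidueMapping("pak2_to_pak1_catalytic", mapping)


class _HeavySelect(Select):
    def accept_atom(self, atom):  # pragma: no cover - thin Biopython hook
        return (atom.element or "").strip().upper() not in ("H", "D")


def annotate_scores(
    model: StructureModel,
    scores: dict,
    mapping: ResidueMapping,
    out_path: str | Path,
    sentinel: float = 0.0,
) -> list[int]:
    """Write a PDB with per-residue scores in the temperature-factor column.

    ``scores`` is keyed by anchor residue numbers; each mapped residue's atoms
    all carry its score, every other atom carries ``sentinel``.  Returns the
    anchor residues whose mapped residue is absent from the structure (they are
    skipped with a warning; the file is still written).
    """
    if model._bio_model is None:
        raise ValueError("StructureModel was built without a PDB entity; reload from file")
    targets: dict[ResidueKey, float] = {}
    skipped: list[int] = []
    for anchor_residue, score in scores.items():
        key = mapping[anchor_residue]
        if key in model.residues:
            targets[key] = float(score)
        else:
            skipped.append(anchor_residue)
    if skipped:
        warnings.warn(
            f"{len(skipped)} scored residues absent from structure {model.label}: {skipped}",
            stacklevel=2,
        )
    for bio_chain in model._bio_model:
        for res in bio_chain:
            value = targets.get((bio_chain.id, res.get_id()[1]), sentinel)
            for atom in res:
                atom.set_bfactor(value)
    io = PDBIO()
    io.set_structure(model._bio_model)
    io.save(str(out_path), select=_HeavySelect())
    return skipped


def pair_distance_table(
    model: StructureModel,
    pairs,
    mapping: ResidueMapping,
) -> pd.DataFrame:
    """Closest distance for each reciprocal pair, with per-class mean summary.

    ``pairs`` is a list of :class:`~kinsca.reciprocal.ReciprocalPair`.  Pairs
    with a member missing from the mapping or from the structure are excluded
    from the means and reported with a NaN distance and a warning.
    """
    rows = []
    for p in pairs:
        record = {
            "pos_a": p.pos_a,
            "pos_b": p.pos_b,
            "class": p.klass,
            "distance_A": np.nan,
        }
        try:
            record["distance_A"] = closest_distance(model, mapping[p.pos_a], mapping[p.pos_b])
        except KeyError as exc:
            warnings.warn(f"pair ({p.pos_a}, {p.pos_b}) excluded: {exc}", stacklevel=2)
        rows.append(record)
    frame = pd.DataFrame(rows, columns=["pos_a", "pos_b", "class", "distance_A"])
    if len(frame):
        means = frame.groupby("class")["distance_A"].mean()
        for klass, value in means.items():
            frame = pd.concat(
                [
                    frame,
                    pd.DataFrame(
                        [{"pos_a": -1, "pos_b": -1, "class": f"mean_{klass}",
                          "distance_A": round(float(value), 1)}]
                    ),
                ],
                ignore_index=True,
            )
    return frame
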
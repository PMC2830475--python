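"""Curated reference tables shipped with the package.

Two small text tables support cross-kinase work without any external download:
the residue-equivalence table (see :mod:`kinsca.reciprocal`) and the published
closest heavy-atom distances between reciprocal-coupling pairs of Pak2, PKA and
Src, measured on the crystal structures 1YHV, 1ATP and 2SRC.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["load_pair_distances", "distance_class_means", "reference_pair_sets"]

_DIST_RESOURCE = "kinase_pair_distances.tsv"


def load_pair_distances(path: str | Path | None = None) -> pd.DataFrame:
    """The curated pair-distance table (protein, pair_no, class, pos_a, pos_b, Å)."""
    if path is None:
        with resources.as_file(resources.files("kinsca.data").joinpath(_DIST_RESOURCE)) as p:
            return pd.read_csv(p, sep="\t", comment="#")
    return pd.read_csv(path, sep="\t", comment="#")


def distance_class_means(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean pair distance per (protein, pair class), in Å.

    Index is a (protein, class) MultiIndex; values are plain arithmetic means
    of the per-pair closest distances.
    """
    if table is None:
        table = load_pair_distances()
    return table.groupby(["protein", "class"])["distance_A"].mean().to_frame("mean_distance_A")


def reference_pair_sets(table: pd.DataFrame | None = None) -> dict[str, list[tuple[int, int]]]:
    """Per-kinase reciprocal pair positions from the curated distance table."""
    if table is None:
        table = load_pair_distances()
    out: dict[str, list[tuple[int, int]]] = {}
    for r in table.to_dict("records"):
        out.setdefault(str(r["protein"]), []).append((int(r["pos_a"]), int(r["pos_b"])))
    return out
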
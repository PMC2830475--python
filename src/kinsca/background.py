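"""Background amino-acid frequencies used as the binomial reference rate.

The conservation statistic compares each column's composition against what a
"generic" eukaryotic protein would show; the reference composition shipped with
the package is the UniProtKB/Swiss-Prot amino-acid composition published by
ExPASy.  Printed conservation values are sensitive to this table at roughly the
±0.1 level across table releases, so the table is pinned as a versioned data
file and its checksum is recorded in pipeline manifests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

from .alignment import AA_ALPHABET, AA_INDEX

__all__ = ["BackgroundFrequencies", "swissprot_background", "load_background"]

_DEFAULT_RESOURCE = "expasy_swissprot_composition.json"


@dataclass(frozen=True)
class BackgroundFrequencies:
    """A strictly positive probability vector over the 20 amino acids."""

    freq: np.ndarray  # shape (20,), ordered as AA_ALPHABET
    source_label: str = "custom"

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        if freq.shape != (20,):
            raise ValueError("background frequencies must be a 20-vector")
        if np.any(freq <= 0):
            raise ValueError("background frequencies must all be > 0")
        total = freq.sum()
        if abs(total - 1.0) > 1e-6:
            freq = freq / total
        object.__setattr__(self, "freq", freq)

    def __getitem__(self, residue: str) -> float:
        return float(self.freq[AA_INDEX[residue]])

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float], source_label: str = "custom"):
        missing = [aa for aa in AA_ALPHABET if aa not in mapping]
        if missing:
            raise ValueError(f"background table missing residues: {missing}")
        return cls(np.array([mapping[aa] for aa in AA_ALPHABET], dtype=float), source_label)


def swissprot_background() -> BackgroundFrequencies:
    """The pinned ExPASy (UniProtKB/Swiss-Prot) eukaryotic composition."""
    text = resources.files("kinsca.data").joinpath(_DEFAULT_RESOURCE).read_text()
    payload = json.loads(text)
    return BackgroundFrequencies.from_mapping(
        payload["composition_percent"], source_label=payload["label"]
    )


def load_background(path: str | Path | None = None) -> BackgroundFrequencies:
    """Load a background table from a JSON file, or the shipped default if None.

    The JSON must contain a ``composition_percent`` mapping of one-letter codes
    to relative abundances (any positive scale; normalised on load) and may
    carry a ``label``.
    """
    if path is None:
        return swissprot_background()
    payload = json.loads(Path(path).read_text())
    return BackgroundFrequencies.from_mapping(
        payload["composition_percent"], source_label=payload.get("label", str(path))
    )
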
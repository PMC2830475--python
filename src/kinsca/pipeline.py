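"""End-to-end orchestration: alignment → profile → matrix → pairs → structure.

A run is described by a :class:`RunConfig` (usually loaded from YAML) naming
one or more anchored alignments.  For each protein the pipeline writes a
conservation-profile TSV, the full coupling matrix, a top-k table per requested
perturbation site, and the reciprocal-pair list; with more than one protein and
an equivalence table it adds the common/specific comparison, and with a
structure block a pair-distance table.  A JSON manifest records input hashes,
the echoed config and package versions so identical inputs give identical
outputs (all report values are rounded: two decimals for ΔE/ΔΔE, one for Å).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import read_alignment, reduce_to_anchor
from .background import load_background
from .core import conservation_profile, full_coupling_matrix
from .reciprocal import (
    DEFAULT_K,
    compare_across_proteins,
    find_reciprocal_pairs,
    load_equivalence,
    pairs_to_frame,
    top_k_partners,
)
from .structure import ResidueMapping, load_structure, pair_distance_table

__all__ = ["ProteinConfig", "RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class StructureConfig:
    pdb: str
    chain: str | None = None
    mapping_tsv: str | None = None  # anchor_residue/structure_residue TSV; identity if None


@dataclass(frozen=True)
class ProteinConfig:
    label: str
    msa: str
    anchor: str | int = 0
    first_residue: int = 1
    perturb_sites: tuple[int, ...] = ()  # anchor residue numbers
    structure: StructureConfig | None = None


@dataclass(frozen=True)
class RunConfig:
    proteins: tuple[ProteinConfig, ...]
    out_dir: str
    background: str | None = None  # JSON table; shipped default if None
    equivalence: str | None = None  # TSV; shipped default if None
    k: int = DEFAULT_K
    seed: int = 0
    strict_alphabet: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        proteins = []
        for p in raw.get("proteins", []):
            structure = None
            if p.get("structure"):
                structure = StructureConfig(
                    pdb=p["structure"]["pdb"],
                    chain=p["structure"].get("chain"),
                    mapping_tsv=p["structure"].get("mapping_tsv"),
                )
            proteins.append(
                ProteinConfig(
                    label=p["label"],
                    msa=p["msa"],
                    anchor=p.get("anchor", 0),
                    first_residue=int(p.get("first_residue", 1)),
                    perturb_sites=tuple(p.get("perturb_sites", [])),
                    structure=structure,
                )
            )
        return cls(
            proteins=tuple(proteins),
            out_dir=raw["out_dir"],
            background=raw.get("background"),
            equivalence=raw.get("equivalence"),
            k=int(raw.get("k", DEFAULT_K)),
            seed=int(raw.get("seed", 0)),
            strict_alphabet=bool(raw.get("strict_alphabet", True)),
        )


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, float_format: str = "%.2f") -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to the out dir)."""
    # -- validation before any compute
    missing = [p.msa for p in config.proteins if not Path(p.msa).exists()]
    for opt in (config.background, config.equivalence):
        if opt is not None and not Path(opt).exists():
            missing.append(opt)
    for p in config.proteins:
        if p.structure is not None:
            if not Path(p.structure.pdb).exists():
                missing.append(p.structure.pdb)
            if p.structure.mapping_tsv and not Path(p.structure.mapping_tsv).exists():
                missing.append(p.structure.mapping_tsv)
    if missing:
        raise PipelineError("validate", f"missing input files: {missing}")
    if not config.proteins:
        raise PipelineError("validate", "no proteins configured")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bg = load_background(config.background)

    manifest: dict = {
        "kinsca_version": __version__,
        "numpy_version": np.__version__,
        "background": {"label": bg.source_label,
                       "sha256": _sha256(config.background) if config.background else None},
        "config": {
            "k": config.k,
            "seed": config.seed,
            "strict_alphabet": config.strict_alphabet,
            "background": config.background,
            "equivalence": config.equivalence,
        },
        "proteins": {},
        "outputs": [],
    }
    if config.background is None:
        from importlib import resources

        with resources.as_file(
            resources.files("kinsca.data").joinpath("expasy_swissprot_composition.json")
        ) as p:
            manifest["background"]["sha256"] = _sha256(p)

    pair_sets = {}
    for prot in config.proteins:
        info: dict = {"msa_sha256": _sha256(prot.msa)}
        try:
            aln = read_alignment(prot.msa, prot.anchor, strict=config.strict_alphabet)
            reduced, cmap = reduce_to_anchor(aln, prot.first_residue)
        except Exception as exc:
            raise PipelineError("load", f"{prot.label}: {exc}") from exc
        info.update(
            n_sequences=aln.n_sequences,
            n_columns_input=aln.n_columns,
            n_columns_retained=len(cmap),
        )

        try:
            profile = conservation_profile(reduced, bg, cmap.anchor_residue_numbers)
        except Exception as exc:
            raise PipelineError("conservation", f"{prot.label}: {exc}") from exc
        prof_path = out_dir / f"{prot.label}_conservation.tsv"
        _write_tsv(profile.to_frame(), prof_path)

        try:
            matrix = full_coupling_matrix(reduced, bg, cmap.anchor_residue_numbers)
        except Exception as exc:
            raise PipelineError("coupling_matrix", f"{prot.label}: {exc}") from exc
        mat_path = out_dir / f"{prot.label}_coupling_matrix.tsv"
        matrix.to_tsv(mat_path, float_format="%.2f")

        topk_paths = []
        for site in prot.perturb_sites:
            try:
                partners = top_k_partners(matrix, site, k=config.k)
                spec = matrix.perturbations[matrix.index_of(site)]
            except Exception as exc:
                raise PipelineError("perturbation", f"{prot.label} site {site}: {exc}") from exc
            frame = pd.DataFrame(partners, columns=["residue", "ddE"])
            frame.insert(0, "perturbed_site", site)
            frame.insert(1, "perturbed_residue", spec.residue_x)
            tk_path = out_dir / f"{prot.label}_top{config.k}_{site}.tsv"
            _write_tsv(frame, tk_path)
            topk_paths.append(str(tk_path))
            info[f"perturbation_{site}"] = {
                "residue": spec.residue_x,
                "subset_size": spec.subset_size,
                "conservation_percent": round(spec.conservation_percent, 1),
                "mean_ddE": round(matrix.column_mean(site), 2),
            }

        try:
            pairs = find_reciprocal_pairs(matrix, k=config.k)
        except Exception as exc:
            raise PipelineError("reciprocal_pairs", f"{prot.label}: {exc}") from exc
        pair_sets[prot.label] = pairs
        pairs_path = out_dir / f"{prot.label}_reciprocal_pairs.tsv"
        _write_tsv(pairs_to_frame(pairs, protein=prot.label), pairs_path)
        info["n_reciprocal_pairs"] = len(pairs)
        info["n_major_pairs"] = sum(1 for p in pairs if p.klass == "major")

        if prot.structure is not None:
            try:
                model = load_structure(prot.structure.pdb, chain=prot.structure.chain)
                if prot.structure.mapping_tsv:
                    mapping = ResidueMapping.from_tsv(
                        prot.structure.mapping_tsv,
                        chain=prot.structure.chain or next(iter(model.chains)),
                    )
                else:
                    chain = prot.structure.chain or next(iter(sorted(model.chains)))
                    mapping = ResidueMapping(
                        "identity", {num: (chain, num) for (_, num) in model.residues}
                    )
                dist = pair_distance_table(model, pairs, mapping)
            except Exception as exc:
                raise PipelineError("structure", f"{prot.label}: {exc}") from exc
            dist_path = out_dir / f"{prot.label}_pair_distances.tsv"
            _write_tsv(dist, dist_path, float_format="%.1f")
            manifest["outputs"].append(str(dist_path))

        manifest["proteins"][prot.label] = info
        manifest["outputs"] += [str(prof_path), str(mat_path), str(pairs_path)] + topk_paths

    if len(config.proteins) > 1:
        try:
            equivalence = load_equivalence(config.equivalence)
            comparisons = compare_across_proteins(pair_sets, equivalence)
        except Exception as exc:
            raise PipelineError("compare", str(exc)) from exc
        rows = [
            {
                "shared_a": c.shared_pair[0],
                "shared_b": c.shared_pair[1],
                "class": c.klass,
                "present_in": ",".join(sorted(c.present_in)),
                **{
                    f"{prot}_pair": (
                        f"{c.positions[prot][0]}-{c.positions[prot][1]}"
                        if prot in c.positions
                        else ""
                    )
                    for prot in pair_sets
                },
            }
            for c in comparisons
        ]
        cmp_path = out_dir / "pair_comparison.tsv"
        _write_tsv(pd.DataFrame(rows), cmp_path)
        manifest["outputs"].append(str(cmp_path))
        manifest["n_common_pairs"] = sum(1 for c in comparisons if c.klass == "common")

    manifest_path = out_dir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
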
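"""Mapping perturbed residues onto structure-defined binding grooves.

Two default groove definitions are shipped for BAK (author/PDB numbering,
as in PDB 2IMS): the canonical a3/a4/a5 BH3-binding groove and the
noncanonical a4/a6/a7 groove.  Groove membership is residue-set based;
enrichment of perturbed residues in a groove is scored with a permutation
test over the assigned residues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from Bio.PDB import PDBParser

from .csp import CSPProfile

__all__ = [
    "StructureModel",
    "GrooveDefinition",
    "GrooveMapping",
    "EnrichmentReport",
    "load_structure",
    "default_grooves",
    "grooves_from_yaml",
    "map_perturbations",
    "groove_enrichment",
    "write_painted_pdb",
]

# Canonical a3/a4/a5 groove residues perturbed by the canonical-binder control
# peptide; numbering follows the author numbering of the structure.
CANONICAL_RESIDUES = frozenset(
    {82, 83, 85, 89, 90, 91, 93, 94, 95, 96, 97, 98, 99, 108, 113, 114, 118,
     126, 130, 131, 132, 133, 134}
)
# Noncanonical a4/a6/a7 groove residues: shared a3/a4 members plus the
# a6/a7 set (F157..A168).
NONCANONICAL_RESIDUES = frozenset(
    {96, 98, 99, 113, 114, 118, 157, 161, 162, 163, 164, 165, 166, 168}
)


@dataclass
class StructureModel:
    """One CA coordinate per residue of a single chain/model."""

    residues: list[tuple[int, np.ndarray]]
    chain_id: str
    source: str

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.residues]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate residue ids in structure chain")
        for rid, xyz in self.residues:
            if not np.all(np.isfinite(xyz)):
                raise ValueError(f"non-finite coordinates at residue {rid}")

    @property
    def residue_ids(self) -> set[int]:
        return {rid for rid, _ in self.residues}

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GrooveDefinition:
    name: str
    residue_ids: frozenset[int]
    helix_labels: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.residue_ids:
            raise ValueError(f"groove {self.name!r} has an empty residue set")


@dataclass
class GrooveMapping:
    """Per-groove perturbation counts over residues assigned in both profile and structure."""

    assigned: set[int]
    perturbed: set[int]
    grooves: list[GrooveDefinition]
    per_groove: dict[str, dict] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = []
        for g in self.grooves:
            d = self.per_groove[g.name]
            rows.append({"groove": g.name, **d})
        return pd.DataFrame(rows)


@dataclass
class EnrichmentReport:
    mapping: GrooveMapping
    n_permutations: int
    seed: int
    p_values: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_assigned_total": len(self.mapping.assigned),
            "n_perturbed_total": len(self.mapping.perturbed),
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "grooves": {
                name: {**self.mapping.per_groove[name], "permutation_p": self.p_values[name]}
                for name in self.p_values
            },
        }

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path


def load_structure(
    path: str | Path, chain: Optional[str] = None, model_index: int = 0
) -> StructureModel:
    """Load one CA trace from a PDB file.

    Residue numbering is taken verbatim from the file.  Disordered (altloc)
    CA atoms resolve to the highest-occupancy location (tie: first altloc id);
    residues lacking a CA are skipped.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if model_index >= len(models):
        raise ValueError(f"model index {model_index} out of range ({len(models)} models)")
    model = models[model_index]
    chains = {c.id: c for c in model}
    if chain is None:
        chain = next(iter(chains))
    if chain not in chains:
        raise ValueError(
            f"chain {chain!r} not found in {path}; available chains: {sorted(chains)}"
        )
    residues: list[tuple[int, np.ndarray]] = []
    for res in chains[chain]:
        if res.id[0] != " ":  # skip hetero/water
            continue
        if "CA" not in res:
            continue
        atom = res["CA"]
        if atom.is_disordered():
            children = sorted(
                atom.disordered_get_list(),
                key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
            )
            atom = children[0]
        residues.append((res.id[1], np.asarray(atom.get_coord(), dtype=float)))
    if not residues:
        raise ValueError(f"no CA atoms found in chain {chain!r} of {path}")
    return StructureModel(residues=residues, chain_id=chain, source=str(path))


def default_grooves() -> tuple[GrooveDefinition, GrooveDefinition]:
    """The two shipped groove definitions (canonical first)."""
    canonical = GrooveDefinition(
        name="canonical",
        residue_ids=CANONICAL_RESIDUES,
        helix_labels="a3/a4/a5",
        provenance=(
            "residues perturbed by the canonical-groove binder control: a3 "
            "G82,D83,I85,Y89,D90,S91,F93,Q94,T95,M96,L97,Q98,H99; a4 "
            "Y108,K113,I114,L118; a5 G126,A130,L131,L132,G133,F134"
        ),
    )
    noncanonical = GrooveDefinition(
        name="noncanonical",
        residue_ids=NONCANONICAL_RESIDUES,
        helix_labels="a4/a6/a7",
        provenance=(
            "residues with prominent perturbations from the alternative-groove "
            "binders: a3 M96,Q98,H99; a4 K113,I114,L118; a6 "
            "F157,F161,M162,L163,H164,H165,C166; a7 A168"
        ),
    )
    return canonical, noncanonical


def grooves_from_yaml(path: str | Path) -> list[GrooveDefinition]:
    """Read groove overrides from YAML: ``{name: [residue, ...], ...}``."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError("groove YAML must map groove name -> residue list")
    grooves = []
    for name, ids in data.items():
        grooves.append(
            GrooveDefinition(name=str(name), residue_ids=frozenset(int(i) for i in ids))
        )
    return grooves


def map_perturbations(
    profile: CSPProfile,
    structure: StructureModel,
    grooves: Optional[list[GrooveDefinition]] = None,
) -> GrooveMapping:
    """Count perturbed residues (shifted or attenuated) per groove.

    Only residues both assigned in the profile and present in the structure
    participate.  Residues in the overlap of two groove sets count toward
    both grooves.
    """
    if grooves is None:
        grooves = list(default_grooves())
    assigned = profile.assigned & structure.residue_ids
    if not assigned:
        raise ValueError(
            "no overlap between profile residues and structure numbering "
            "(numbering mismatch?)"
        )
    perturbed = profile.perturbed & assigned
    mapping = GrooveMapping(assigned=assigned, perturbed=perturbed, grooves=list(grooves))
    for g in grooves:
        groove_assigned = g.residue_ids & assigned
        in_groove = perturbed & groove_assigned
        mapping.per_groove[g.name] = {
            "n_groove": len(groove_assigned),
            "n_perturbed_in_groove": len(in_groove),
            "fraction": len(in_groove) / len(groove_assigned) if groove_assigned else 0.0,
        }
    return mapping


def groove_enrichment(
    mapping: GrooveMapping, n_permutations: int = 9999, seed: int = 0
) -> EnrichmentReport:
    """Permutation test for per-groove perturbation enrichment.

    The null draws ``|perturbed|`` residues uniformly without replacement from
    the assigned residues; p = (1 + #{null >= observed}) / (1 + B).
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    assigned = np.array(sorted(mapping.assigned))
    k = len(mapping.perturbed)
    if k > len(assigned):
        raise ValueError("more perturbed residues than assigned residues")
    rng = np.random.default_rng(seed)
    groove_sets = {g.name: g.residue_ids & mapping.assigned for g in mapping.grooves}
    observed = {
        name: mapping.per_groove[name]["n_perturbed_in_groove"] for name in groove_sets
    }
    p_values: dict[str, float] = {}
    if k == 0:
        p_values = {name: 1.0 for name in groove_sets}
    else:
        exceed = {name: 0 for name in groove_sets}
        masks = {
            name: np.isin(assigned, sorted(resids)) for name, resids in groove_sets.items()
        }
        for _ in range(n_permutations):
            draw = rng.choice(len(assigned), size=k, replace=False)
            for name, mask in masks.items():
                if int(mask[draw].sum()) >= observed[name]:
                    exceed[name] += 1
        p_values = {
            name: (1 + exceed[name]) / (1 + n_permutations) for name in groove_sets
        }
    return EnrichmentReport(
        mapping=mapping, n_permutations=n_permutations, seed=seed, p_values=p_values
    )


def write_painted_pdb(
    structure_path: str | Path,
    chain: str,
    perturbed: set[int],
    out_path: str | Path,
) -> Path:
    """Write a copy of the PDB with B-factors set to 1 for perturbed residues, else 0."""
    from Bio.PDB import PDBIO

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("paint", str(structure_path))
    for model in structure:
        for ch in model:
            for res in ch:
                flag = 1.0 if (ch.id == chain and res.id[1] in perturbed) else 0.0
                for atom in res:
                    atom.set_bfactor(flag)
    io = PDBIO()
    io.set_structure(structure)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    io.save(str(out_path))
    return out_path
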
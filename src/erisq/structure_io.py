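"""Structure parsing, assembly-state selection and lysine-site extraction.

Loads mmCIF/PDB models (via gemmi), filters them down to the heavy-atom
obstacle set used by the accessibility probe, carves out named assembly
states by chain selection (e.g. the free 60S large subunit versus the
complete 80S ribosome), and locates the NZ (epsilon-amino) atoms of
requested lysines — the ubiquitin acceptor atoms whose reachability is
under study.

Residue numbers follow author numbering throughout, because published
ubiquitination sites (e.g. Rpl4 K55) are protein-sequence positions; a
per-chain offset table can reconcile depositions whose author numbering
is shifted relative to the protein sequence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: van der Waals radii (Angstrom) for the elements that dominate
#: ribonucleoprotein assemblies; anything else falls back to DEFAULT_VDW.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "MG": 1.73,
}
DEFAULT_VDW = 1.70


class StructureError(Exception):
    """Raised for unreadable files, empty models or unmapped selections."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom of an assembly (position in Angstrom)."""

    position: tuple[float, float, float]
    element: str
    vdw_radius: float
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str = ""
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be positive, got {self.vdw_radius}")


@dataclass
class AssemblyState:
    """A named set of atoms defining one structural state.

    ``chain_map`` translates chain ids to protein names (user-curated;
    entity names in depositions are too inconsistent to rely on).
    """

    name: str
    atoms: list[Atom]
    chain_map: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"assembly state {self.name!r} has no atoms")
        unmapped = {a.chain_id for a in self.atoms} - set(self.chain_map)
        if unmapped:
            logger.warning(
                "state %s: chains without protein mapping: %s",
                self.name,
                sorted(unmapped),
            )

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class LysineSite:
    """A candidate ubiquitination site: one lysine's NZ atom, if modelled."""

    protein: str
    chain_id: str
    residue_number: int
    nz_position: tuple[float, float, float] | None = None

    @property
    def resolved(self) -> bool:
        return self.nz_position is not None


def vdw_radius_for(element: str) -> float:
    """vdW radius for an element symbol; unknown elements get the default."""
    el = element.strip().upper()
    if el in VDW_RADII:
        return VDW_RADII[el]
    logger.warning("unknown element %r: using default radius %.2f A", element, DEFAULT_VDW)
    return DEFAULT_VDW


_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def load_structure(
    path: str | Path,
    fmt: str = "auto",
    *,
    keep_hetero: bool = True,
) -> tuple[list[Atom], dict]:
    """Load a structure file and return its filtered heavy-atom list.

    Filtering: hydrogens and waters are dropped, only the first alternate
    conformer of each atom is kept, zero-occupancy atoms are dropped, and
    every atom is assigned a vdW radius from its element. Metal ions and
    modified residues are kept by default (they are physical obstacles);
    pass ``keep_hetero=False`` to drop HETATM-style records.

    Returns ``(atoms, metadata)``; metadata records the source path,
    model name and per-chain entity descriptions (useful when curating a
    chain -> protein map).
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"structure file not found: {path}")
    try:
        if fmt == "auto":
            st = gemmi.read_structure(str(path))
        elif fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    atoms: list[Atom] = []
    if len(st) == 0:
        raise StructureError(f"{path}: structure contains no models")
    model = st[0]
    for chain in model:
        for residue in chain:
            if residue.name in _WATER_NAMES or residue.is_water():
                continue
            if not keep_hetero and residue.het_flag == "H" and not residue.name == "MSE":
                continue
            seen_names: set[str] = set()
            for atom in residue:
                el = atom.element.name.upper()
                if el == "H" or el == "D":
                    continue
                if atom.occ <= 0.0:
                    continue
                # first conformer wins for alternate locations
                if atom.name in seen_names:
                    continue
                seen_names.add(atom.name)
                atoms.append(
                    Atom(
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        element=el,
                        vdw_radius=vdw_radius_for(el),
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        altloc=atom.altloc or "",
                        occupancy=atom.occ,
                    )
                )
    if not atoms:
        raise StructureError(f"{path}: no atoms remain after filtering")
    meta = {
        "path": str(path),
        "name": st.name,
        "n_atoms": len(atoms),
        "chains": sorted({a.chain_id for a in atoms}),
        "entities": entity_descriptions(st),
    }
    return atoms, meta


def entity_descriptions(st: gemmi.Structure) -> dict[str, str]:
    """Chain id -> entity description, as deposited (a curation aid only)."""
    out: dict[str, str] = {}
    for ent in st.entities:
        desc = (ent.name or "").strip()
        for sub in ent.subchains:
            out.setdefault(sub, desc)
    return out


def chain_map_template(meta: Mapping) -> pd.DataFrame:
    """Emit a chain->protein mapping template from load metadata.

    The protein column is pre-filled with the deposition's entity
    description where one exists; it is meant for manual curation, not
    for blind use.
    """
    ents = meta.get("entities", {})
    rows = [
        {"chain_id": c, "protein": ents.get(c, "")}
        for c in meta.get("chains", [])
    ]
    return pd.DataFrame(rows, columns=["chain_id", "protein"])


def select_state(
    atoms: Sequence[Atom],
    chain_ids: Iterable[str],
    name: str,
    chain_map: Mapping[str, str] | None = None,
    source: str = "",
) -> AssemblyState:
    """Carve a named assembly state out of a loaded atom list by chain.

    Requested chains absent from the model trigger a warning, not an
    error; selecting zero atoms is an error (an empty state has no
    physical meaning as an obstacle set).
    """
    wanted = set(chain_ids)
    if not wanted:
        raise StructureError("select_state: empty chain selection")
    present = {a.chain_id for a in atoms}
    missing = wanted - present
    if missing:
        warnings.warn(
            f"state {name!r}: requested chains absent from model: {sorted(missing)}",
            stacklevel=2,
        )
    selected = [a for a in atoms if a.chain_id in wanted]
    if not selected:
        raise StructureError(f"state {name!r}: selection matched no atoms")
    cmap = dict(chain_map) if chain_map else {}
    return AssemblyState(name=name, atoms=selected, chain_map=cmap, source=source)


def find_lysine_sites(
    state: AssemblyState,
    requested: Sequence[tuple[str, int]],
    offsets: Mapping[str, int] | None = None,
) -> list[LysineSite]:
    """Locate the NZ atom of each requested (protein, residue_number) lysine.

    ``offsets`` maps chain id -> number to ADD to the requested sequence
    position to obtain the model's author numbering. Sites whose residue
    or NZ atom is absent from the model come back unresolved rather than
    raising — missing density is a data property, not an error. A protein
    name with no chain in the state's chain_map is an error.
    """
    offsets = offsets or {}
    protein_chains: dict[str, list[str]] = {}
    for chain_id, protein in state.chain_map.items():
        protein_chains.setdefault(protein, []).append(chain_id)

    nz_index: dict[tuple[str, int], tuple[float, float, float]] = {
        (a.chain_id, a.residue_number): a.position
        for a in state.atoms
        if a.residue_name == "LYS" and a.atom_name == "NZ"
    }

    sites: list[LysineSite] = []
    for protein, resnum in requested:
        chains = protein_chains.get(protein)
        if not chains:
            raise StructureError(
                f"protein {protein!r} not present in the chain map of state {state.name!r}"
            )
        if len(chains) > 1:
            logger.info(
                "protein %s maps to chains %s; using %s", protein, chains, chains[0]
            )
        chain_id = chains[0]
        model_resnum = resnum + offsets.get(chain_id, 0)
        pos = nz_index.get((chain_id, model_resnum))
        sites.append(
            LysineSite(
                protein=protein,
                chain_id=chain_id,
                residue_number=resnum,
                nz_position=pos,
            )
        )
    return sites


def state_summary(state: AssemblyState) -> pd.DataFrame:
    """Per-chain atom counts for a state, as a tidy frame (TSV-ready)."""
    counts: dict[str, int] = {}
    for a in state.atoms:
        counts[a.chain_id] = counts.get(a.chain_id, 0) + 1
    rows = [
        {
            "state": state.name,
            "chain_id": c,
            "protein": state.chain_map.get(c, ""),
            "n_atoms": n,
        }
        for c, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def write_pdb(atoms: Sequence[Atom], path: str | Path) -> None:
    """Write an atom list as a minimal PDB file (round-trip support)."""
    lines = []
    for i, a in enumerate(atoms, start=1):
        x, y, z = a.position
        name = a.atom_name or a.element
        # names of atoms with one-letter element symbols start in column 14
        name4 = name if len(name) >= 4 else f" {name:<3s}"
        lines.append(
            f"ATOM  {i:5d} {name4:4s} {a.residue_name:>3s} {a.chain_id[:1]}"
            f"{a.residue_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
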
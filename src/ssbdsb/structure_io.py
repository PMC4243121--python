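"""Reading, cleaning and annotating protein structures.

Structures arrive as PDB or mmCIF files (parsed with :mod:`gemmi`); the rest
of the pipeline only ever sees :class:`ProteinChain` objects: heavy protein
atoms of a single polypeptide chain, with van der Waals radii attached, plus
the ordered C-alpha trace used by the structural aligner.

Cleaning rules: model 1 only for multi-model (NMR) files; waters, nucleic
acids, other hetero compounds and hydrogens are removed; alternate locations
are resolved to the highest-occupancy conformer (ties keep the first one
encountered). Bound DNA is always stripped, so DNA-bound (HOLO) and DNA-free
(APO) structures are processed identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Bondi (1964) van der Waals radii, Angstrom. Elements missing from the
#: table fall back to the carbon radius with a warning.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

DEFAULT_RADIUS = VDW_RADII["C"]

RADIUS_SETS: dict[str, dict[str, float]] = {"bondi": VDW_RADII}

VALID_LABELS = frozenset({"SSB", "DSB", "UNKNOWN"})
VALID_FORMS = frozenset({"HOLO", "APO"})


class StructureError(ValueError):
    """Raised for unreadable or protein-free structure files."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a protein chain."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: tuple[float, float, float]
    radius: float = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.serial}")
        if self.radius <= 0:
            raise ValueError(f"non-positive radius for atom {self.serial}")


@dataclass(frozen=True)
class ProteinChain:
    """Cleaned single polypeptide chain: heavy atoms + C-alpha trace."""

    chain_id: str
    atoms: tuple[AtomRecord, ...]
    residues: tuple[tuple[int, str], ...]  # (author index, 3-letter code)
    ca_coords: np.ndarray  # (n_res, 3) float64

    def __post_init__(self) -> None:
        ca = np.asarray(self.ca_coords, dtype=float)
        object.__setattr__(self, "ca_coords", ca)
        if len(self.residues) != len(ca):
            raise ValueError("residue list and CA trace lengths differ")
        if any(a.chain_id != self.chain_id for a in self.atoms):
            raise ValueError("atom with foreign chain_id")

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class ManifestEntry:
    structure_path: str
    chain_id: str
    label: str = "UNKNOWN"
    form: str = "HOLO"

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {sorted(VALID_LABELS)}, got {self.label!r}")
        if self.form not in VALID_FORMS:
            raise ValueError(f"form must be one of {sorted(VALID_FORMS)}, got {self.form!r}")


@dataclass(frozen=True)
class DatasetManifest:
    entries: tuple[ManifestEntry, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def _is_protein_residue(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.found():
        return info.is_amino_acid()
    # unknown residue names: accept only if a CA atom is present
    return res.find_atom("CA", "*") is not None


def _pick_altloc(atoms: Iterable[gemmi.Atom]) -> gemmi.Atom:
    best = None
    for a in atoms:
        if best is None or a.occ > best.occ:
            best = a
    return best


def read_structure(path: str | Path, fmt: str | None = None) -> list[ProteinChain]:
    """Read a PDB or mmCIF file into cleaned per-chain :class:`ProteinChain`.

    ``fmt`` may be ``"pdb"`` or ``"mmcif"``; by default it is inferred from
    the file suffix. Only model 1 of multi-model files is used.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"structure file not found: {path}")
    coor = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}.get(
        fmt or "", gemmi.CoorFormat.Detect
    )
    try:
        st = gemmi.read_structure(str(path), format=coor)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]

    chains: list[ProteinChain] = []
    for ch in model:
        atoms: list[AtomRecord] = []
        residues: list[tuple[int, str]] = []
        ca: list[tuple[float, float, float]] = []
        for res in ch:
            if res.is_water() or not _is_protein_residue(res):
                continue
            # group altlocs by atom name, keep highest occupancy
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                if at.element.is_hydrogen:
                    continue
                by_name.setdefault(at.name, []).append(at)
            if not by_name:
                continue
            residues.append((res.seqid.num, res.name))
            ca_pos = None
            for name, group in by_name.items():
                at = _pick_altloc(group)
                pos = (at.pos.x, at.pos.y, at.pos.z)
                atoms.append(
                    AtomRecord(
                        serial=at.serial,
                        name=name,
                        element=at.element.name.upper(),
                        residue_name=res.name,
                        residue_index=res.seqid.num,
                        chain_id=ch.name,
                        position=pos,
                    )
                )
                if name == "CA":
                    ca_pos = pos
            if ca_pos is None:
                # residue without CA cannot enter the trace; drop it from
                # the residue list but keep its atoms for the sphere model
                residues.pop()
                continue
            ca.append(ca_pos)
        if residues:
            chains.append(
                ProteinChain(
                    chain_id=ch.name,
                    atoms=tuple(atoms),
                    residues=tuple(residues),
                    ca_coords=np.array(ca, dtype=float),
                )
            )
    if not chains:
        raise StructureError(f"{path}: no protein chains after cleaning")
    return chains


def select_chain(chains: Sequence[ProteinChain], chain_id: str | None = None) -> ProteinChain:
    """Pick the named chain, or the longest protein chain when unnamed."""
    if chain_id:
        for ch in chains:
            if ch.chain_id == chain_id:
                return ch
        raise StructureError(
            f"chain {chain_id!r} not found; available: {[c.chain_id for c in chains]}"
        )
    return max(chains, key=lambda c: c.length)


def assign_radii(chain: ProteinChain, radius_set: str = "bondi") -> ProteinChain:
    """Return a copy of ``chain`` with van der Waals radii per element.

    Unknown elements receive the carbon radius and a logged warning.
    """
    table = RADIUS_SETS[radius_set]
    atoms = []
    for a in chain.atoms:
        r = table.get(a.element.upper())
        if r is None:
            logger.warning(
                "element %r of atom %d not in radius set %r; using carbon %.2f",
                a.element, a.serial, radius_set, DEFAULT_RADIUS,
            )
            r = DEFAULT_RADIUS
        atoms.append(replace(a, radius=r))
    return replace(chain, atoms=tuple(atoms))


def write_pdb(chains: Sequence[ProteinChain] | ProteinChain, path: str | Path) -> None:
    """Write chains as fixed-column PDB ATOM records (3-decimal coordinates)."""
    if isinstance(chains, ProteinChain):
        chains = [chains]
    with open(path, "w") as fh:
        serial = 0
        for ch in chains:
            for a in ch.atoms:
                serial += 1
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                x, y, z = a.position
                fh.write(
                    f"ATOM  {serial:5d} {name:<4s} {a.residue_name:<3s} "
                    f"{ch.chain_id[:1]:1s}{a.residue_index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element[:1]:>2s}\n"
                )
            fh.write("TER\n")
        fh.write("END\n")


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a TSV dataset manifest: columns path, chain, label, form.

    Lines starting with ``#`` are comments; a header line is optional.
    """
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0].lower() in {"path", "structure_path"}:
                continue
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least path and chain columns")
            label = cols[2].upper() if len(cols) > 2 and cols[2] else "UNKNOWN"
            form = cols[3].upper() if len(cols) > 3 and cols[3] else "HOLO"
            entries.append(ManifestEntry(cols[0], cols[1], label, form))
    return DatasetManifest(tuple(entries))


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("path\tchain\tlabel\tform\n")
        for e in manifest:
            fh.write(f"{e.structure_path}\t{e.chain_id}\t{e.label}\t{e.form}\n")


def filter_manifest(manifest: DatasetManifest, min_length: int = 40) -> DatasetManifest:
    """Drop entries whose chain is not strictly longer than ``min_length``
    residues (the dataset filter used for non-redundant protein sets).

    Unreadable structure files are dropped with a warning, never a crash.
    """
    kept = []
    for entry in manifest:
        try:
            chains = read_structure(entry.structure_path)
            chain = select_chain(chains, entry.chain_id or None)
        except (StructureError, OSError) as exc:
            logger.warning("dropping manifest entry %s: %s", entry.structure_path, exc)
            continue
        if chain.length > min_length:
            kept.append(entry)
    return DatasetManifest(tuple(kept))
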
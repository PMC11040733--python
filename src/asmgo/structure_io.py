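"""Reading, validating and writing protein structures.

Parses PDB and mmCIF files (via gemmi) into light-weight conformation
objects: one :class:`Conformation` per model, each an ordered list of chains
of standard amino-acid residues with their atoms. Validation enforces the
preparation rules the coarse-graining pipeline relies on: only the 20
standard amino acids, exactly one Calpha per residue, known elements.

Alternate locations are resolved to the highest-occupancy conformer (ties
broken by file order). Waters, ligands and other non-amino-acid HETATM
records are dropped with a log message.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .constants import STANDARD_AA, vdw_radius

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord", "Residue", "Chain", "Conformation",
    "read_structure", "write_pdb", "check_hydrogens", "MissingHydrogensWarning",
]


class MissingHydrogensWarning(UserWarning):
    """Raised when a structure carries no hydrogens.

    The default contact criterion assumes hydrogens are present; without
    them the effective amino-acid surfaces shrink and the contact scale
    should be adjusted.
    """


@dataclass
class AtomRecord:
    """One atom: name, element, Cartesian coordinates (A)."""

    name: str
    element: str
    coords: np.ndarray
    residue_index: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element")
        if self.residue_index < 0:
            raise ValueError("residue_index must be >= 0")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def vdw_radius(self) -> float:
        return vdw_radius(self.element)


@dataclass
class Residue:
    """One standard amino-acid residue with its atoms."""

    name: str                       # three-letter code
    atoms: list[AtomRecord]
    index: int = 0                  # 0-based position within the chain

    @property
    def one_letter(self) -> str:
        return STANDARD_AA[self.name]

    @property
    def ca(self) -> AtomRecord:
        for atom in self.atoms:
            if atom.name == "CA":
                return atom
        raise ValueError(f"residue {self.name} {self.index} has no CA atom")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca.coords for r in self.residues])

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Conformation:
    """All chains of one structure model (one native conformation)."""

    model_id: int
    chains: list[Chain] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def sequences(self) -> list[str]:
        return [c.sequence for c in self.chains]

    def validate(self) -> None:
        if not self.chains:
            raise ValueError(f"model {self.model_id}: no protein chains found")
        for chain in self.chains:
            if not chain.residues:
                raise ValueError(f"chain {chain.chain_id}: empty")
            for residue in chain.residues:
                residue.ca  # raises if absent
                n_ca = sum(1 for a in residue.atoms if a.name == "CA")
                if n_ca != 1:
                    raise ValueError(
                        f"chain {chain.chain_id} residue {residue.index} "
                        f"({residue.name}): {n_ca} CA atoms"
                    )


def _select_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations to the highest-occupancy conformer.

    Atoms sharing a name are grouped; the kept altloc is the one with the
    highest occupancy, ties resolved by file order.
    """
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > best[atom.name].occ:
            best[atom.name] = atom
    return [best[name] for name in order]


def _convert_model(model: gemmi.Model, model_id: int) -> Conformation:
    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            info = gemmi.find_tabulated_residue(gres.name)
            if gres.name not in STANDARD_AA:
                if gres.het_flag == "A" or (info is not None and info.is_amino_acid()):
                    raise ValueError(
                        f"nonstandard amino acid {gres.name!r} in chain "
                        f"{gchain.name} (residue {gres.seqid.num}); remove or "
                        "substitute it by the corresponding standard residue"
                    )
                logger.info(
                    "dropping non-amino-acid record %s %s in chain %s",
                    gres.name, gres.seqid.num, gchain.name,
                )
                continue
            atoms = []
            for gatom in _select_altloc(gres):
                element = gatom.element.name if gatom.element else ""
                atoms.append(AtomRecord(
                    name=gatom.name,
                    element=element,
                    coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    residue_index=len(residues),
                ))
                atoms[-1].vdw_radius  # unknown element -> KeyError here
            residues.append(Residue(name=gres.name, atoms=atoms, index=len(residues)))
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))
    return Conformation(model_id=model_id, chains=chains)


def read_structure(path: str | Path, fmt: str | None = None) -> list[Conformation]:
    """Read a PDB or mmCIF file into one :class:`Conformation` per model.

    Parameters
    ----------
    path
        Input file. The format is detected from the extension unless *fmt*
        (``"pdb"`` or ``"mmcif"``) is given.

    Raises
    ------
    ValueError
        On nonstandard amino acids, residues without Calpha, or empty models.
    KeyError
        On elements without a tabulated van-der-Waals radius.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        structure = gemmi.read_structure(str(path))
    else:
        fmt_map = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}
        try:
            coor_fmt = fmt_map[fmt.lower().replace("cif", "cif")]
        except KeyError:
            raise ValueError(f"unsupported format {fmt!r}; use 'pdb' or 'mmcif'") from None
        structure = gemmi.read_structure(str(path), format=coor_fmt)
    structure.setup_entities()

    conformations = []
    for model_id, model in enumerate(structure):
        conf = _convert_model(model, model_id)
        conf.validate()
        conformations.append(conf)
    if not conformations:
        raise ValueError(f"{path}: no models found")
    return conformations


def check_hydrogens(conformation: Conformation) -> bool:
    """Warn if the structure carries no hydrogen atoms.

    The default contact detection assumes hydrogens are present. Returns
    True if hydrogens were found.
    """
    has_h = any(
        atom.is_hydrogen
        for chain in conformation.chains
        for residue in chain.residues
        for atom in residue.atoms
    )
    if not has_h:
        warnings.warn(
            "structure contains no hydrogen atoms; the default contact "
            "criterion assumes protonated input — either add hydrogens or "
            "increase contact_scale",
            MissingHydrogensWarning,
            stacklevel=2,
        )
    return has_h


def write_pdb(conformations: list[Conformation] | Conformation, path: str | Path) -> None:
    """Write conformations as a (multi-model) PDB file."""
    if isinstance(conformations, Conformation):
        conformations = [conformations]
    lines: list[str] = []
    multi = len(conformations) > 1
    for conf in conformations:
        if multi:
            lines.append(f"MODEL     {conf.model_id + 1:>4d}")
        serial = 1
        for chain in conf.chains:
            for residue in chain.residues:
                for atom in residue.atoms:
                    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                    x, y, z = atom.coords
                    lines.append(
                        f"ATOM  {serial:>5d} {name:<4s}{residue.name:>4s} "
                        f"{chain.chain_id[:1]:1s}{(residue.index + 1) % 10000:>4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                        f"          {atom.element.upper():>2s}"
                    )
                    serial += 1
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
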
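"""Minimal structural data model and PDB I/O.

A :class:`Conformer` is a single-chain, full- or partial-atom model of a
peptide with 1-based contiguous residue numbering — the shape of model that
the grid integrator and the coil-ensemble machinery consume.  PDB reading
and writing go through :mod:`gemmi`; only the ATOM/MODEL subset of the
format is supported (single chain, canonical residues, no insertion codes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "AtomSite",
    "Conformer",
    "read_pdb",
    "write_pdb",
    "select_atoms",
    "ATOM_ROLES",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: role selectors understood by :func:`select_atoms`
ATOM_ROLES = ("HN", "HA", "HB", "CA", "all-protons", "all-heavy")


@dataclass(frozen=True)
class AtomSite:
    """One atom of a conformer.

    ``position`` is in Å; ``residue_index`` is 1-based.  Atom names follow
    PDB v3 conventions ("CA", "HA", "HB2", ...).
    """

    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite or malformed coordinates for {self.atom_name}")
        object.__setattr__(self, "position", pos)
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")


class Conformer:
    """A single-chain atomic model with an associated 1-letter sequence."""

    def __init__(self, sequence: str, atoms: list[AtomSite], label: str = ""):
        self.sequence = sequence
        self.atoms = list(atoms)
        self.label = label
        self._validate()
        self._coords_cache: np.ndarray | None = None

    def _validate(self) -> None:
        seen: set[tuple[int, str]] = set()
        present: dict[int, set[str]] = {}
        for a in self.atoms:
            if a.residue_index > len(self.sequence):
                raise ValueError(
                    f"atom {a.atom_name} at residue {a.residue_index} exceeds "
                    f"sequence length {len(self.sequence)}"
                )
            expected = ONE_TO_THREE.get(self.sequence[a.residue_index - 1])
            if expected is None:
                raise ValueError(f"noncanonical residue letter {self.sequence[a.residue_index - 1]!r}")
            if a.residue_name != expected:
                raise ValueError(
                    f"residue {a.residue_index}: atom says {a.residue_name}, "
                    f"sequence says {expected}"
                )
            key = (a.residue_index, a.atom_name)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)
            present.setdefault(a.residue_index, set()).add(a.atom_name)
        for i in range(1, len(self.sequence) + 1):
            if not {"N", "CA", "C"} <= present.get(i, set()):
                warnings.warn(
                    f"residue {i} has an incomplete backbone", stacklevel=3
                )

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, cached."""
        if self._coords_cache is None:
            self._coords_cache = np.array([a.position for a in self.atoms])
        return self._coords_cache

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return (
            f"Conformer({self.sequence!r}, {len(self.atoms)} atoms"
            + (f", label={self.label!r})" if self.label else ")")
        )


def _normalize_atom_name(name: str) -> str:
    # old-style hydrogen names put the branch digit first ("1HB2" / "1HB");
    # move it to the end to obtain the v3 spelling
    name = name.strip()
    if name and name[0].isdigit():
        name = name[1:] + name[0]
    return name


def _element_of(name: str, element_hint: str = "") -> str:
    if element_hint:
        return element_hint.strip().capitalize()
    # PDB v3: hydrogens start with H (after digit normalization)
    if name.startswith("H"):
        return "H"
    for sym in ("CL", "BR"):  # not expected in peptides, but be safe
        if name.startswith(sym):
            return sym.capitalize()
    return name[0]


def read_pdb(path: str | Path) -> list[Conformer]:
    """Read a PDB file into one :class:`Conformer` per MODEL.

    Accepts both PDB v3 ("HB2") and old-style ("1HB") hydrogen names;
    old-style names are normalized to v3.  Multi-chain models, insertion
    codes and nonstandard residues are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = gemmi.read_pdb(str(path))
    conformers: list[Conformer] = []
    for model in structure:
        if len(model) != 1:
            raise ValueError(f"expected a single chain, found {len(model)}")
        chain = model[0]
        atoms: list[AtomSite] = []
        letters: list[str] = []
        prev_idx = 0
        for res in chain:
            if res.seqid.icode not in ("", " "):
                raise ValueError("insertion codes are not supported")
            if res.name not in THREE_TO_ONE:
                raise ValueError(f"nonstandard residue {res.name!r}")
            idx = res.seqid.num
            if idx != prev_idx + 1:
                raise ValueError(
                    f"residue numbering must be 1-based and contiguous "
                    f"(got {idx} after {prev_idx})"
                )
            prev_idx = idx
            letters.append(THREE_TO_ONE[res.name])
            for at in res:
                name = _normalize_atom_name(at.name)
                atoms.append(
                    AtomSite(
                        atom_name=name,
                        element=_element_of(name, at.element.name),
                        residue_index=idx,
                        residue_name=res.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    )
                )
        conformers.append(Conformer("".join(letters), atoms, label=str(model.num)))
    if not conformers:
        raise ValueError(f"no ATOM records found in {path}")
    return conformers


def write_pdb(conformers: list[Conformer] | Conformer, path: str | Path) -> None:
    """Write conformers as a fixed-column PDB file.

    A single conformer is written as bare ATOM records; several conformers
    are wrapped in MODEL/ENDMDL blocks.  Atom names are emitted in PDB v3
    spelling at 0.001 Å precision.
    """
    if isinstance(conformers, Conformer):
        conformers = [conformers]
    if not conformers:
        raise ValueError("no conformers to write")
    structure = gemmi.Structure()
    for m, conf in enumerate(conformers, start=1):
        model = gemmi.Model(m)
        chain = gemmi.Chain("A")
        # gemmi add_* methods store copies, so each residue is finished
        # before it is attached
        by_residue: dict[int, list[AtomSite]] = {}
        for a in conf.atoms:
            by_residue.setdefault(a.residue_index, []).append(a)
        for idx in sorted(by_residue):
            res = gemmi.Residue()
            res.name = by_residue[idx][0].residue_name
            res.seqid = gemmi.SeqId(idx, " ")
            for a in by_residue[idx]:
                atom = gemmi.Atom()
                atom.name = a.atom_name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.position)
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        structure.add_model(model)
    structure.setup_entities()
    doc_path = Path(path)
    doc_path.parent.mkdir(parents=True, exist_ok=True)
    structure.write_pdb(str(doc_path))


def _role_match(role: str, atom: AtomSite) -> bool:
    if role == "HN":
        return atom.atom_name == "H"
    if role == "HA":
        return atom.atom_name in ("HA", "HA2", "HA3")
    if role == "HB":
        return atom.atom_name in ("HB", "HB1", "HB2", "HB3")
    if role == "CA":
        return atom.atom_name == "CA"
    if role == "all-protons":
        return atom.element == "H"
    if role == "all-heavy":
        return atom.element != "H"
    raise ValueError(f"unknown atom-role selector {role!r}; known: {ATOM_ROLES}")


def select_atoms(conformer: Conformer, role: str) -> list[AtomSite]:
    """Select atoms of a conformer by role.

    Roles: ``HN`` (backbone amide H), ``HA`` (alpha H, incl. glycine
    HA2/HA3), ``HB`` (beta H), ``CA``, ``all-protons``, ``all-heavy``.
    """
    if role not in ATOM_ROLES:
        raise ValueError(f"unknown atom-role selector {role!r}; known: {ATOM_ROLES}")
    return [a for a in conformer.atoms if _role_match(role, a)]
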
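"""PDB structure I/O and the torsion-space backbone contract.

The design pipeline operates in torsion space only: structures are reduced to
per-residue (phi, psi, omega) triples and rebuilt with idealized bond lengths
and angles. This removes the bond-length/angle noise that experimental
structures carry, so that grafted fragments combine seamlessly. Reading uses
Bio.PDB; writing emits standard fixed-width ATOM/TER records.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.Data.PDBData import protein_letters_3to1

from . import geometry as geom
from .geometry import (
    ANGLE_C_N_CA,
    ANGLE_CA_C_N,
    ANGLE_CA_C_O,
    ANGLE_C_CA_CB,
    ANGLE_N_CA_C,
    BOND_C_N,
    BOND_C_O,
    BOND_CA_C,
    BOND_CA_CB,
    BOND_N_CA,
    PEPTIDE_BOND_RANGE,
    TORSION_N_C_CA_CB,
    dihedral,
    place_atom,
)

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")
ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, float))
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    aa: str
    chain: str
    seqnum: int
    icode: str = ""
    atoms: dict = field(default_factory=dict)

    def coord(self, name: str) -> np.ndarray:
        return self.atoms[name].coords

    def has(self, name: str) -> bool:
        return name in self.atoms


@dataclass
class BackboneModel:
    """An ordered single-chain backbone with recorded discontinuities.

    ``breaks`` holds 0-based indices i meaning the peptide bond between
    residues i−1 and i is absent (C–N distance outside 1.2–1.5 Å, or residues
    were dropped in between).
    """

    source_id: str
    residues: list
    breaks: list = field(default_factory=list)

    def __len__(self):
        return len(self.residues)

    @property
    def seq(self) -> str:
        return "".join(r.aa for r in self.residues)

    def coords(self, atom_names=("N", "CA", "C")) -> np.ndarray:
        """(n_res * n_atoms, 3) array; raises KeyError on missing atoms."""
        return np.array(
            [r.coord(a) for r in self.residues for a in atom_names], float
        )

    def ca_coords(self) -> np.ndarray:
        return np.array([r.coord("CA") for r in self.residues], float)

    def backbone_frame(self, index: int) -> np.ndarray:
        """(3, 3) N, CA, C coordinates of one residue — an anchor frame."""
        r = self.residues[index]
        return np.array([r.coord("N"), r.coord("CA"), r.coord("C")], float)


@dataclass(frozen=True)
class TorsionTriple:
    """Backbone dihedrals of one residue in degrees; ``None`` marks an angle
    undefined at a chain terminus or across a recorded break."""

    phi: float | None
    psi: float | None
    omega: float | None

    def defined(self) -> bool:
        return None not in (self.phi, self.psi, self.omega)


class MissingChainError(KeyError):
    pass


def _pick_altloc(atom):
    """Resolve a possibly disordered Bio.PDB atom: highest occupancy, ties → 'A'."""
    if not atom.is_disordered():
        return atom
    children = list(atom.child_dict.values())
    children.sort(key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))
    return children[0]


def read_pdb(path, chain: str | None = None, source_id: str | None = None) -> BackboneModel:
    """Read one chain of a PDB file into a :class:`BackboneModel`.

    HETATM records are ignored; alternate locations are resolved to the
    highest-occupancy conformer (ties broken toward altloc 'A'); residues
    missing any of N/CA/C are dropped with a warning and a recorded break.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    model = next(structure.get_models())
    chains = {c.id: c for c in model.get_chains()}
    if chain is None:
        if len(chains) != 1:
            raise MissingChainError(
                f"file has chains {sorted(chains)}; specify one explicitly"
            )
        chain = next(iter(chains))
    if chain not in chains:
        raise MissingChainError(
            f"chain {chain!r} not found; available chains: {sorted(chains)}"
        )

    residues = []
    dropped_before_next = False
    breaks = []
    for res in chains[chain].get_residues():
        hetflag, seqnum, icode = res.id
        if hetflag.strip():
            continue  # HETATM / water
        atoms = {}
        for atom in res.get_atoms():
            picked = _pick_altloc(atom)
            name = picked.get_name()
            if name not in ("N", "CA", "C", "O", "CB"):
                continue
            atoms[name] = AtomRecord(
                name=name,
                element=(picked.element or name[0]).strip(),
                coords=picked.get_coord(),
                occupancy=picked.get_occupancy() or 1.0,
                altloc=(picked.get_altloc() or "").strip(),
            )
        if not all(a in atoms for a in ("N", "CA", "C")):
            logger.warning(
                "dropping residue %s%s of %s: incomplete backbone", seqnum, icode.strip(), path
            )
            dropped_before_next = True
            continue
        aa = protein_letters_3to1.get(res.get_resname().strip(), "X")
        if len(aa) != 1:
            aa = "X"
        residues.append(
            Residue(aa=aa, chain=chain, seqnum=seqnum, icode=icode.strip(), atoms=atoms)
        )
        if dropped_before_next and len(residues) > 1:
            breaks.append(len(residues) - 1)
        dropped_before_next = False

    bm = BackboneModel(
        source_id=source_id or str(path), residues=residues, breaks=breaks
    )
    _detect_breaks(bm)
    return bm


def _detect_breaks(model: BackboneModel) -> None:
    """Add break indices wherever the peptide C–N distance is non-physical."""
    lo, hi = PEPTIDE_BOND_RANGE
    found = set(model.breaks)
    for i in range(1, len(model.residues)):
        d = np.linalg.norm(
            model.residues[i].coord("N") - model.residues[i - 1].coord("C")
        )
        if not (lo <= d <= hi):
            found.add(i)
    model.breaks = sorted(found)


def extract_torsions(model: BackboneModel) -> list:
    """Per-residue (phi, psi, omega) with the standard four-atom conventions.

    phi(i) = C(i−1)–N(i)–CA(i)–C(i); psi(i) = N(i)–CA(i)–C(i)–N(i+1);
    omega(i) = CA(i)–C(i)–N(i+1)–CA(i+1). Angles spanning a chain terminus or
    a recorded break are undefined (None).
    """
    n = len(model.residues)
    if n < 2:
        raise ValueError("need at least 2 residues to define torsions")
    breaks = set(model.breaks)
    out = []
    for i, res in enumerate(model.residues):
        phi = psi = omega = None
        if i > 0 and i not in breaks:
            phi = dihedral(
                model.residues[i - 1].coord("C"),
                res.coord("N"),
                res.coord("CA"),
                res.coord("C"),
            )
        if i < n - 1 and (i + 1) not in breaks:
            nxt = model.residues[i + 1]
            psi = dihedral(res.coord("N"), res.coord("CA"), res.coord("C"), nxt.coord("N"))
            omega = dihedral(res.coord("CA"), res.coord("C"), nxt.coord("N"), nxt.coord("CA"))
        out.append(TorsionTriple(phi=phi, psi=psi, omega=omega))
    return out


def _add_oxygen(residue: Residue, next_n: np.ndarray | None) -> None:
    """Place the carbonyl O trans to the next N; terminal O uses a fixed
    180° torsion from N (arbitrary but deterministic)."""
    n, ca, c = residue.coord("N"), residue.coord("CA"), residue.coord("C")
    if next_n is not None:
        psi = dihedral(n, ca, c, next_n)
        tor = geom.normalize_angle(psi + 180.0)
    else:
        tor = 180.0
    o = place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, tor)
    residue.atoms["O"] = AtomRecord(name="O", element="O", coords=o)


def _add_cb(residue: Residue) -> None:
    if residue.aa == "G":
        return
    n, ca, c = residue.coord("N"), residue.coord("CA"), residue.coord("C")
    cb = place_atom(n, c, ca, BOND_CA_CB, ANGLE_C_CA_CB, TORSION_N_C_CA_CB)
    residue.atoms["CB"] = AtomRecord(name="CB", element="C", coords=cb)


def default_anchor_frame() -> np.ndarray:
    """Identity placement of the first residue: N at origin, CA on +x,
    C in the xy-plane at the ideal N–CA–C angle."""
    n = np.zeros(3)
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(ANGLE_N_CA_C)
    c = ca + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    return np.array([n, ca, c])


def rebuild_backbone(
    torsions: list,
    seq: str,
    anchor_frame: np.ndarray | None = None,
    source_id: str = "rebuilt",
    chain: str = "A",
    first_seqnum: int = 1,
) -> BackboneModel:
    """Rebuild idealized backbone coordinates from torsions (NeRF construction).

    Bond lengths and angles are fixed at the idealized values in
    :mod:`bbassembly.geometry`; only the supplied dihedrals vary, so
    ``extract_torsions(rebuild_backbone(T, ...))`` reproduces ``T``.
    ``anchor_frame`` is a (3, 3) array of N, CA, C coordinates placing the
    first residue; identity frame if omitted.
    """
    n_res = len(torsions)
    if n_res != len(seq):
        raise ValueError("torsion list and sequence must have the same length")
    if n_res < 1:
        raise ValueError("empty model")
    for i, t in enumerate(torsions):
        missing = []
        if t.phi is None and i > 0:
            missing.append("phi")
        if i < n_res - 1 and (t.psi is None or t.omega is None):
            missing += [a for a, v in (("psi", t.psi), ("omega", t.omega)) if v is None]
        if missing:
            raise ValueError(f"undefined interior torsion {missing} at residue {i}")

    frame = default_anchor_frame() if anchor_frame is None else np.asarray(anchor_frame, float)
    if frame.shape != (3, 3):
        raise ValueError("anchor_frame must be a (3, 3) array of N, CA, C coordinates")

    coords = np.empty((n_res, 3, 3))  # residue × (N, CA, C) × xyz
    coords[0] = frame
    for i in range(1, n_res):
        prev_n, prev_ca, prev_c = coords[i - 1]
        psi = torsions[i - 1].psi
        omega = torsions[i - 1].omega
        phi = torsions[i].phi
        n_i = place_atom(prev_n, prev_ca, prev_c, BOND_C_N, ANGLE_CA_C_N, psi)
        ca_i = place_atom(prev_ca, prev_c, n_i, BOND_N_CA, ANGLE_C_N_CA, omega)
        c_i = place_atom(prev_c, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        coords[i] = (n_i, ca_i, c_i)

    residues = []
    for i, aa in enumerate(seq):
        atoms = {
            name: AtomRecord(name=name, element=name[0], coords=coords[i, j])
            for j, name in enumerate(("N", "CA", "C"))
        }
        residues.append(
            Residue(aa=aa, chain=chain, seqnum=first_seqnum + i, atoms=atoms)
        )
    for i, res in enumerate(residues):
        next_n = coords[i + 1, 0] if i + 1 < n_res else None
        _add_oxygen(res, next_n)
        _add_cb(res)
    return BackboneModel(source_id=source_id, residues=residues, breaks=[])


def write_pdb(model: BackboneModel, path) -> None:
    """Write standard fixed-width ATOM records; TER is emitted at each
    recorded break and at the chain end."""
    if len(model.residues) == 0:
        raise ValueError("refusing to write an empty model")
    breaks = set(model.breaks)
    lines = []
    serial = 1
    order = ("N", "CA", "C", "O", "CB")
    for i, res in enumerate(model.residues):
        if i in breaks:
            lines.append("TER")
        resname = ONE_TO_THREE.get(res.aa, "UNK")
        for name in order:
            if name not in res.atoms:
                continue
            a = res.atoms[name]
            x, y, z = a.coords
            name_field = name if len(name) == 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name_field:4s} {resname:>3s} {res.chain:1s}"
                f"{res.seqnum:4d}{(res.icode or ' '):1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
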
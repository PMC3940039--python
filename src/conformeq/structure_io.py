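"""Coordinate I/O and rigid geometry for methyl/probe interaction models.

Reads PDB or mmCIF coordinate files (via gemmi), applies an alternate-location
policy, builds idealized methyl protons on the staggered rotamer, and extracts
the distances and angle matrices consumed by the dipolar jump model, plus the
inter-conformer bond-vector angle after least-squares superposition.

Crystal structures rarely contain refined methyl hydrogens, so protons are
built with idealized geometry by default (|C-H| = 1.09 Angstrom, tetrahedral
H-C-antecedent angle, staggered rotor phase).  Only ratios of predicted NOE
volumes matter downstream, which makes the analysis insensitive to the exact
bond-length convention.
"""

from __future__ import annotations

import fnmatch
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError, MappingError, ParseError, TopologyError

# Idealized methyl geometry.
CH_BOND = 1.09  # Angstrom
TETRAHEDRAL_ANGLE = 109.47  # degrees, H-C-antecedent
STAGGER_DIHEDRALS = (180.0, 60.0, -60.0)  # H-C-antecedent-reference, degrees

#: methyl carbon -> (antecedent heavy atom, reference substituent of the
#: antecedent used to phase the staggered rotamer), per standard residue
#: topology.
METHYL_TOPOLOGY: dict[str, dict[str, tuple[str, str]]] = {
    "ALA": {"CB": ("CA", "N")},
    "VAL": {"CG1": ("CB", "CA"), "CG2": ("CB", "CA")},
    "LEU": {"CD1": ("CG", "CB"), "CD2": ("CG", "CB")},
    "ILE": {"CD1": ("CG1", "CB"), "CG2": ("CB", "CA")},
    "THR": {"CG2": ("CB", "CA")},
    "MET": {"CE": ("SD", "CG")},
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, position (Angstrom), occupancy and altloc."""

    chain: str
    resnum: int
    resname: str
    name: str
    pos: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    element: str = ""

    def __post_init__(self):
        pos = np.asarray(self.pos, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "pos", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Structure:
    """An ordered collection of atoms from one model of a coordinate file."""

    label: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("structure must contain at least one atom")
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.resnum, a.name, a.altloc)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in {self.label}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def find(self, chain: str, resnum: int, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.chain == chain and a.resnum == resnum and a.name == name:
                return a
        raise KeyError(f"atom {chain}:{resnum}:{name} not in {self.label}")

    def select(self, pattern: str) -> list[AtomRecord]:
        """Select atoms by a ``chain:resnum:atomname`` pattern with ``*`` wildcards."""
        chain, resnum, name = parse_selection(pattern)
        out = []
        for a in self.atoms:
            if chain not in ("*", a.chain):
                continue
            if resnum not in ("*", str(a.resnum)):
                continue
            if not fnmatch.fnmatchcase(a.name, name):
                continue
            out.append(a)
        return out

    def residues(self) -> list[tuple[str, int, str]]:
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.resnum, a.resname), None)
        return list(seen)

    def with_atoms(self, extra: Iterable[AtomRecord]) -> "Structure":
        return Structure(self.label, list(self.atoms) + list(extra))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return Structure(
            self.label, [replace(a, pos=R @ a.pos + t) for a in self.atoms]
        )

    def to_pdb_string(self) -> str:
        lines = []
        for i, a in enumerate(self.atoms, start=1):
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            elem = a.element or a.name[0]
            lines.append(
                f"ATOM  {i:5d} {name}{a.altloc or ' '}{a.resname:>3s} "
                f"{a.chain[:1] or 'A'}{a.resnum:4d}    "
                f"{a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {elem:>2s}"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"

    def write_pdb(self, path) -> None:
        Path(path).write_text(self.to_pdb_string())


@dataclass(frozen=True)
class MethylGroup:
    """A methyl carbon with its three (built or read) proton positions."""

    residue: tuple[str, int, str]  # (chain, resnum, resname)
    carbon_name: str
    carbon: np.ndarray
    antecedent: np.ndarray
    protons: np.ndarray  # (3, 3)
    provenance: str = "built-ideal"  # or "read-from-file"

    def __post_init__(self):
        protons = np.asarray(self.protons, float)
        if protons.shape != (3, 3):
            raise ValueError("a methyl group carries exactly three protons")
        object.__setattr__(self, "protons", protons)
        object.__setattr__(self, "carbon", np.asarray(self.carbon, float))
        object.__setattr__(self, "antecedent", np.asarray(self.antecedent, float))

    @property
    def mean_proton(self) -> np.ndarray:
        return self.protons.mean(axis=0)


@dataclass(frozen=True)
class ProbeSite:
    """A distal proton (e.g. the Trp indole H-Ne1) and its bonded heavy atom."""

    residue: tuple[str, int, str]
    atom_name: str
    pos: np.ndarray
    heavy_pos: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "pos", np.asarray(self.pos, float))
        object.__setattr__(self, "heavy_pos", np.asarray(self.heavy_pos, float))
        blen = float(np.linalg.norm(self.pos - self.heavy_pos))
        if not 0.8 <= blen <= 1.2:
            raise ValueError(
                f"probe H-heavy bond length {blen:.3f} A outside [0.8, 1.2] A"
            )

    @property
    def bond_vector(self) -> np.ndarray:
        return self.pos - self.heavy_pos


@dataclass(frozen=True)
class InteractionGeometry:
    """Probe-methyl geometry: distances r_i and the probe-vertex angle matrix."""

    distances: np.ndarray  # (3,), Angstrom
    angles: np.ndarray  # (3, 3), degrees, symmetric, zero diagonal


def parse_selection(pattern: str) -> tuple[str, str, str]:
    parts = pattern.split(":")
    if len(parts) != 3:
        raise ValueError(
            f"selection {pattern!r} must have the form chain:resnum:atomname"
        )
    return parts[0], parts[1], parts[2]


def load_structure(path, model_index: int = 0, altloc: str = "highest-occupancy") -> Structure:
    """Read one model from a PDB or mmCIF file.

    Parameters
    ----------
    path
        Coordinate file; format detected from content/extension by gemmi.
    model_index
        Zero-based model to extract.
    altloc
        Policy for alternate locations: ``highest-occupancy`` keeps the best
        occupied conformer of each atom (ties to the earlier altloc letter),
        ``A`` keeps blank-or-'A' records, ``error`` refuses any altloc.
    """
    import gemmi

    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    if not 0 <= model_index < len(st):
        raise IndexError(
            f"model index {model_index} out of range (file has {len(st)} model(s))"
        )
    model = st[model_index]
    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            for atom in res:
                atoms.append(
                    AtomRecord(
                        chain=chain.name,
                        resnum=res.seqid.num,
                        resname=res.name,
                        name=atom.name,
                        pos=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        altloc=atom.altloc.strip("\0") if atom.altloc else "",
                        element=atom.element.name,
                    )
                )
    if not atoms:
        raise ParseError(f"{path}: no atoms in model {model_index}")
    return Structure(st.name or path.stem, _apply_altloc_policy(atoms, altloc))


def _apply_altloc_policy(atoms: Sequence[AtomRecord], policy: str) -> list[AtomRecord]:
    if policy == "error":
        for a in atoms:
            if a.altloc:
                raise ValueError(
                    f"altloc {a.altloc!r} present at {a.chain}:{a.resnum}:{a.name} "
                    "with policy 'error'"
                )
        return list(atoms)
    if policy == "A":
        kept = [a for a in atoms if a.altloc in ("", "A")]
        return [replace(a, altloc="") for a in kept]
    if policy == "highest-occupancy":
        best: dict[tuple, AtomRecord] = {}
        order: list[tuple] = []
        for a in atoms:
            key = (a.chain, a.resnum, a.name)
            if key not in best:
                best[key] = a
                order.append(key)
            else:
                b = best[key]
                if (a.occupancy, -ord(a.altloc or "~")) > (b.occupancy, -ord(b.altloc or "~")):
                    best[key] = a
        return [replace(best[k], altloc="") for k in order]
    raise ValueError(f"unknown altloc policy {policy!r}")


def place_atom(
    r: np.ndarray, a: np.ndarray, c: np.ndarray,
    length: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Position a new atom D bonded to C given internal coordinates.

    |C-D| = ``length``, angle D-C-A = ``angle_deg``, dihedral D-C-A-R =
    ``dihedral_deg`` (standard NeRF construction).
    """
    r, a, c = (np.asarray(x, float) for x in (r, a, c))
    bc = c - a
    nbc = np.linalg.norm(bc)
    if nbc == 0:
        raise GeometryError("coincident antecedent and carbon")
    bc /= nbc
    ab = a - r
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise GeometryError("collinear reference frame for atom placement")
    n /= nn
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    d_local = np.array(
        [
            -length * math.cos(ang),
            length * math.sin(ang) * math.cos(dih),
            length * math.sin(ang) * math.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def methyl_proton_names(carbon_name: str) -> list[str]:
    # CD1 -> HD11, HD12, HD13; CB -> HB1...; CE -> HE1...
    stem = "H" + carbon_name[1:]
    return [f"{stem}{i}" for i in (1, 2, 3)]


def build_methyl_protons(
    structure: Structure,
    selection: str = "*:*:*",
    use_explicit: bool = False,
) -> list[MethylGroup]:
    """Build (or read) methyl protons for every selected methyl carbon.

    Protons are placed at the idealized staggered-rotamer geometry unless
    ``use_explicit`` is set and the file already carries all three protons,
    in which case the file positions are used verbatim.
    """
    groups: list[MethylGroup] = []
    sel_chain, sel_resnum, sel_name = parse_selection(selection)
    for chain, resnum, resname in structure.residues():
        topo = METHYL_TOPOLOGY.get(resname)
        if topo is None:
            continue
        if sel_chain not in ("*", chain) or sel_resnum not in ("*", str(resnum)):
            continue
        for carbon_name, (ante_name, ref_name) in topo.items():
            if not fnmatch.fnmatchcase(carbon_name, sel_name):
                continue
            try:
                carbon = structure.find(chain, resnum, carbon_name)
            except KeyError:
                continue  # residue truncated before the methyl; nothing to build
            try:
                ante = structure.find(chain, resnum, ante_name)
            except KeyError:
                raise TopologyError(
                    f"{resname}{resnum} ({chain}): methyl {carbon_name} lacks "
                    f"antecedent {ante_name}"
                ) from None
            explicit = None
            if use_explicit:
                try:
                    explicit = np.array(
                        [structure.find(chain, resnum, n).pos
                         for n in methyl_proton_names(carbon_name)]
                    )
                except KeyError:
                    explicit = None
            if explicit is not None:
                protons, provenance = explicit, "read-from-file"
            else:
                try:
                    ref = structure.find(chain, resnum, ref_name)
                except KeyError:
                    raise TopologyError(
                        f"{resname}{resnum} ({chain}): cannot phase methyl "
                        f"{carbon_name}; reference atom {ref_name} missing"
                    ) from None
                protons = np.array(
                    [
                        place_atom(ref.pos, ante.pos, carbon.pos,
                                   CH_BOND, TETRAHEDRAL_ANGLE, dih)
                        for dih in STAGGER_DIHEDRALS
                    ]
                )
                provenance = "built-ideal"
            groups.append(
                MethylGroup(
                    residue=(chain, resnum, resname),
                    carbon_name=carbon_name,
                    carbon=carbon.pos,
                    antecedent=ante.pos,
                    protons=protons,
                    provenance=provenance,
                )
            )
    return groups


def probe_from_structure(
    structure: Structure, proton: str, heavy: str
) -> ProbeSite:
    """Resolve a probe proton and its bonded heavy atom from selections."""
    h_atoms = structure.select(proton)
    n_atoms = structure.select(heavy)
    if len(h_atoms) != 1 or len(n_atoms) != 1:
        raise MappingError(
            f"probe selections must each match exactly one atom "
            f"({proton!r} -> {len(h_atoms)}, {heavy!r} -> {len(n_atoms)})"
        )
    h, n = h_atoms[0], n_atoms[0]
    return ProbeSite((h.chain, h.resnum, h.resname), h.name, h.pos, n.pos)


def build_planar_proton(
    heavy: np.ndarray, neighbor1: np.ndarray, neighbor2: np.ndarray,
    length: float = 0.98,
) -> np.ndarray:
    """Place an in-plane H on a trigonal heavy atom along the exterior bisector.

    Used for the indole N-H when the deposited model lacks hydrogens.
    """
    heavy = np.asarray(heavy, float)
    u1 = heavy - np.asarray(neighbor1, float)
    u2 = heavy - np.asarray(neighbor2, float)
    n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
    if n1 == 0 or n2 == 0:
        raise GeometryError("coincident neighbor in planar-proton construction")
    d = u1 / n1 + u2 / n2
    nd = np.linalg.norm(d)
    if nd == 0:
        raise GeometryError("collinear neighbors in planar-proton construction")
    return heavy + length * d / nd


def methyl_probe_geometry(methyl: MethylGroup, probe: ProbeSite) -> InteractionGeometry:
    """Distances r_i from the probe to each methyl proton and the matrix of
    angles theta_ij subtended at the probe by proton pairs."""
    vecs = methyl.protons - probe.pos
    r = np.linalg.norm(vecs, axis=1)
    if np.any(r <= 1e-9):
        raise GeometryError("probe coincides with a methyl proton")
    unit = vecs / r[:, None]
    cosang = np.clip(unit @ unit.T, -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    np.fill_diagonal(angles, 0.0)
    angles = 0.5 * (angles + angles.T)
    return InteractionGeometry(distances=r, angles=angles)


def superposition_rotation(ref_moving: np.ndarray, ref_fixed: np.ndarray) -> np.ndarray:
    """Least-squares (Kabsch) rotation taking the moving reference set onto the
    fixed one after centering; returns the 3x3 rotation matrix."""
    ref_moving = np.asarray(ref_moving, float)
    ref_fixed = np.asarray(ref_fixed, float)
    if ref_moving.shape != ref_fixed.shape or ref_moving.ndim != 2:
        raise MappingError(
            f"reference sets must have equal shape, got {ref_moving.shape} "
            f"vs {ref_fixed.shape}"
        )
    a = ref_fixed - ref_fixed.mean(axis=0)
    b = ref_moving - ref_moving.mean(axis=0)
    rot, _ = Rotation.align_vectors(a, b)
    return rot.as_matrix()


def bond_vector_angle(
    site_a: ProbeSite,
    site_b: ProbeSite,
    ref_a: np.ndarray,
    ref_b: np.ndarray,
) -> float:
    """Angle (degrees) between two H-heavy bond vectors after rigid-body
    superposition of the two structures' reference atom sets.

    ``ref_a``/``ref_b`` are (N, 3) coordinate arrays mapping one-to-one.
    Structure B is superposed onto A before the angle is measured.
    """
    R = superposition_rotation(ref_b, ref_a)
    va = site_a.bond_vector
    vb = R @ site_b.bond_vector
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise GeometryError("zero-length bond vector")
    cosang = np.clip(float(va @ vb) / (na * nb), -1.0, 1.0)
    return math.degrees(math.acos(cosang))
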
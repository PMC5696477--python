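"""Structural typing of gas-phase dipeptide conformers.

A conformer of a dipeptide (e.g. Tyr-Gly, Trp-Gly, Gly-Trp) is summarised by a
four-part structural type label::

    <terminus>-<backbone>(<fold>)-<swing>/<orientation>

* ``terminus`` — A1, A2 or B: the swing direction and hydrogen-bond pattern of
  the free amino terminus (B when the amino N-H donates to the peptide-bond
  carbonyl instead of the peptide N-H donating back to the amino nitrogen).
* ``backbone`` — the Ramachandran class of the C-terminal residue's
  (phi2, psi2) dihedrals: gamma_D / gamma_L (folded, C7 gamma-turn) or
  beta / epsilon_D / epsilon_L / alpha_L (extended).
* ``fold`` — F for gamma backbones, E otherwise (redundant annotation).
* ``swing`` — side-chain chi1 (N-CA-CB-CG) class: g+ near +180 deg, g- near
  +60 deg, a near -60 deg.
* ``orientation`` — sign (+/-) of a residue-specific side-chain dihedral
  (phenol O-H torsion for Tyr, chi2 for Trp).

Hydrogen bonds are assigned geometrically: a polar hydrogen within a cutoff
distance (default 2.8 Angstrom) of an N/O acceptor or an aromatic ring
centroid (pi acceptor), excluding contacts fewer than four covalent bonds
apart.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Geometry",
    "HBond",
    "StructuralType",
    "DihedralSet",
    "MoleculeRoles",
    "GeometryError",
    "TypingError",
    "dihedral",
    "detect_hbonds",
    "classify_swing",
    "classify_backbone",
    "classify_terminus",
    "type_label",
    "infer_roles",
    "BACKBONE_CENTERS",
    "SWING_CENTERS",
    "HBOND_CUTOFF",
]

HBOND_CUTOFF = 2.8  # Angstrom, H...acceptor
_DONOR_COVALENT_MAX = 1.2  # Angstrom, H covalently bonded to N/O

ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es "
    "Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og".split()
)

_COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05}


class GeometryError(ValueError):
    """Invalid or degenerate molecular geometry."""


class TypingError(ValueError):
    """A structural type could not be assigned."""


@dataclass
class Geometry:
    """A single conformer: element symbols plus Cartesian coordinates (A)."""

    label: str
    symbols: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.symbols) < 1:
            raise GeometryError(f"{self.label!r}: geometry must contain at least one atom")
        if self.coords.shape != (len(self.symbols), 3):
            raise GeometryError(
                f"{self.label!r}: coordinate array shape {self.coords.shape} does not "
                f"match {len(self.symbols)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError(f"{self.label!r}: non-finite coordinates")
        bad = [s for s in self.symbols if s not in ELEMENTS]
        if bad:
            raise GeometryError(f"{self.label!r}: unknown element symbols {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def atoms(self) -> list[tuple[str, float, float, float]]:
        return [(s, *map(float, xyz)) for s, xyz in zip(self.symbols, self.coords)]


@dataclass(frozen=True)
class HBond:
    """A geometric hydrogen bond D-H...A (A may be an aromatic ring centroid)."""

    donor_atom: int
    hydrogen: int
    acceptor_atom: int | None  # None for a pi (ring-centroid) acceptor
    distance: float
    label: str


@dataclass(frozen=True)
class StructuralType:
    """Four-part conformer type, e.g. ``A1-γ_D(F)-g+/+``."""

    terminus: str  # A1 | A2 | B | U
    backbone: str  # γ_D | γ_L | β | ε_D | ε_L | α_L
    swing: str  # g+ | g− | a
    orientation: str  # + | −

    _LABEL_RE = re.compile(
        r"^(A1|A2|B|U)-(γ_D|γ_L|β|ε_D|ε_L|α_L)\((F|E)\)-(g\+|g−|g-|a)/([+−-])$"
    )

    def __post_init__(self) -> None:
        if self.terminus not in {"A1", "A2", "B", "U"}:
            raise TypingError(f"bad terminus class {self.terminus!r}")
        if self.backbone not in BACKBONE_CENTERS:
            raise TypingError(f"bad backbone class {self.backbone!r}")
        # normalise ASCII hyphen-minus to the typographic minus used in labels
        object.__setattr__(self, "swing", self.swing.replace("g-", "g−"))
        object.__setattr__(self, "orientation", self.orientation.replace("-", "−"))
        if self.swing not in {"g+", "g−", "a"}:
            raise TypingError(f"bad swing class {self.swing!r}")
        if self.orientation not in {"+", "−"}:
            raise TypingError(f"bad orientation {self.orientation!r}")

    @property
    def fold(self) -> str:
        return "F" if self.backbone in FOLDED_BACKBONES else "E"

    @property
    def folded(self) -> bool:
        return self.fold == "F"

    @property
    def side_chain(self) -> str:
        """Side-chain structural type, e.g. ``g+/+``."""
        return f"{self.swing}/{self.orientation}"

    @property
    def label(self) -> str:
        return f"{self.terminus}-{self.backbone}({self.fold})-{self.swing}/{self.orientation}"

    def __str__(self) -> str:
        return self.label

    @classmethod
    def from_label(cls, label: str) -> "StructuralType":
        m = cls._LABEL_RE.match(label.strip())
        if m is None:
            raise TypingError(f"unparseable structural type label {label!r}")
        terminus, backbone, fold, swing, orient = m.groups()
        st = cls(terminus=terminus, backbone=backbone, swing=swing, orientation=orient)
        if st.fold != fold:
            raise TypingError(
                f"{label!r}: fold annotation ({fold}) inconsistent with backbone "
                f"{backbone} (expected {st.fold})"
            )
        return st


@dataclass
class DihedralSet:
    """Named torsions of a dipeptide (degrees, in (-180, 180])."""

    phi2: float  # C_PB - N_PB - CA2 - C_T
    psi2: float  # N_PB - CA2 - C_T - O_T
    chi1: float  # N - CA - CB - CG of the side-chain-bearing residue
    orient_dihedral: float  # side-chain orientation torsion (residue specific)
    amino_swing: float = 60.0  # torsion orienting the terminal NH2
    psi1: float = 150.0  # N_1 - CA1 - C_PB - N_PB
    omega: float = 180.0  # CA1 - C_PB - N_PB - CA2 (peptide bond)
    chi2: float = 90.0  # CA - CB - CG - CD1 (aromatic ring tilt)
    carboxyl: float = 0.0  # CA2 - C_T - O_T - H

    def __post_init__(self) -> None:
        for name in ("phi2", "psi2", "chi1", "orient_dihedral", "amino_swing",
                     "psi1", "omega", "chi2", "carboxyl"):
            setattr(self, name, wrap_angle(getattr(self, name)))

    def mirrored(self) -> "DihedralSet":
        """The dihedral set of the mirror-image geometry (all torsions negated)."""
        return DihedralSet(**{k: -v for k, v in self.__dict__.items()})


# --- basic torsion geometry ------------------------------------------------

def wrap_angle(a: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def circular_difference(a: float, b: float) -> float:
    """Signed smallest difference a-b on the circle, degrees in (-180, 180]."""
    return wrap_angle(a - b)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention.

    Looking from p2 towards p3, the angle is positive when p4 is rotated
    clockwise from p1. Returned in (-180, 180].
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear points: torsion undefined")
    b2n = b2 / np.linalg.norm(b2)
    ang = math.degrees(math.atan2(np.dot(np.cross(n1, n2), b2n), np.dot(n1, n2)))
    return wrap_angle(ang)


# --- covalent bonding & role assignment ------------------------------------

def bond_graph(geom: Geometry, slack: float = 0.45) -> nx.Graph:
    """Covalent bond graph from pairwise distances vs covalent radii."""
    g = nx.Graph()
    g.add_nodes_from(range(len(geom)))
    coords, syms = geom.coords, geom.symbols
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for i in range(len(geom)):
        for j in range(i + 1, len(geom)):
            if syms[i] == "H" and syms[j] == "H":
                continue
            rmax = _COVALENT_RADII.get(syms[i], 1.1) + _COVALENT_RADII.get(syms[j], 1.1) + slack
            if d[i, j] <= rmax:
                g.add_edge(i, j)
    return g


@dataclass
class MoleculeRoles:
    """Atom-role map of a dipeptide (indices into the geometry).

    Roles follow the spectroscopy-table naming: ``N_1`` (amino-terminal N),
    ``N_PB`` (peptide-bond N), ``O_T`` (C-terminal hydroxyl O), ``OC_PB``
    (peptide-bond carbonyl O), ``OC_T`` (C-terminal carbonyl O), ``O_S``
    (side-chain hydroxyl O), ``N_ind`` (indole N). ``rings`` lists aromatic
    rings as tuples of heavy-atom indices.
    """

    roles: dict[str, int] = field(default_factory=dict)
    rings: list[tuple[int, ...]] = field(default_factory=list)
    graph: nx.Graph | None = None

    def __getitem__(self, role: str) -> int:
        return self.roles[role]

    def __contains__(self, role: str) -> bool:
        return role in self.roles

    def get(self, role: str, default=None):
        return self.roles.get(role, default)

    def role_of(self, index: int) -> str | None:
        for r, i in self.roles.items():
            if i == index:
                return r
        return None


def infer_roles(geom: Geometry) -> MoleculeRoles:
    """Assign dipeptide atom roles from connectivity.

    Expects an uncapped dipeptide H2N-CHR-CO-NH-CHR'-COOH; raises
    :class:`TypingError` when the expected functional groups are absent.
    """
    g = bond_graph(geom)
    syms = geom.symbols
    roles: dict[str, int] = {}

    def neighbors(i, sym=None):
        return [j for j in g.neighbors(i) if sym is None or syms[j] == sym]

    # carboxyl group: C bonded to an OH oxygen and a bare (carbonyl) oxygen
    for c in (i for i, s in enumerate(syms) if s == "C"):
        oxy = neighbors(c, "O")
        if len(oxy) != 2:
            continue
        oh = [o for o in oxy if neighbors(o, "H")]
        if len(oh) == 1:
            roles["C_T"] = c
            roles["O_T"] = oh[0]
            roles["OC_T"] = next(o for o in oxy if o != oh[0])
            break
    if "C_T" not in roles:
        raise TypingError(f"{geom.label!r}: no carboxyl group found")

    # peptide bond: non-carboxyl C with a carbonyl O and an amide N
    for c in (i for i, s in enumerate(syms) if s == "C" and i != roles["C_T"]):
        oxy = [o for o in neighbors(c, "O") if not neighbors(o, "H")]
        nit = neighbors(c, "N")
        if len(oxy) == 1 and len(nit) == 1:
            roles["C_PB"] = c
            roles["OC_PB"] = oxy[0]
            roles["N_PB"] = nit[0]
            break
    if "C_PB" not in roles:
        raise TypingError(f"{geom.label!r}: no peptide bond found")

    # amino terminus: N (not the amide N) carrying two hydrogens
    for n in (i for i, s in enumerate(syms) if s == "N" and i != roles["N_PB"]):
        if len(neighbors(n, "H")) >= 2:
            roles["N_1"] = n
            break
    if "N_1" not in roles:
        raise TypingError(f"{geom.label!r}: no amino terminus (NH2) found")

    # alpha carbons
    ca1 = set(neighbors(roles["N_1"], "C")) & set(neighbors(roles["C_PB"], "C"))
    ca2 = set(neighbors(roles["N_PB"], "C")) & set(neighbors(roles["C_T"], "C"))
    if not ca1 or not ca2:
        raise TypingError(f"{geom.label!r}: backbone alpha carbons not found")
    roles["CA1"], roles["CA2"] = min(ca1), min(ca2)

    # side chain: the alpha carbon carrying a carbon substituent
    backbone = {roles[r] for r in ("C_T", "C_PB")}
    for ca, n_of_ca in ((roles["CA1"], roles["N_1"]), (roles["CA2"], roles["N_PB"])):
        cb = [j for j in neighbors(ca, "C") if j not in backbone]
        if cb:
            roles["CB"] = min(cb)
            roles["CA_SC"] = ca
            roles["N_SC"] = n_of_ca
            cg = [j for j in neighbors(roles["CB"], "C") if j != ca]
            if cg:
                roles["CG"] = min(cg)
            break

    # aromatic rings (5/6-membered, C/N only)
    heavy = g.subgraph([i for i, s in enumerate(syms) if s != "H"])
    rings = [
        tuple(sorted(cy))
        for cy in nx.cycle_basis(heavy)
        if len(cy) in (5, 6) and all(syms[i] in ("C", "N") for i in cy)
    ]

    ring_atoms = {i for cy in rings for i in cy}
    # phenol hydroxyl (Tyr): ring-attached O-H
    for o in (i for i, s in enumerate(syms) if s == "O"):
        if o in (roles["O_T"], roles["OC_T"], roles["OC_PB"]):
            continue
        ring_nb = [j for j in neighbors(o) if j in ring_atoms]
        if neighbors(o, "H") and ring_nb:
            roles["O_S"] = o
            roles["CZ"] = min(ring_nb)
            break
    # indole N-H (Trp)
    for n in (i for i, s in enumerate(syms) if s == "N"):
        if n in (roles["N_1"], roles["N_PB"]):
            continue
        if n in ring_atoms and neighbors(n, "H"):
            roles["N_ind"] = n
            break

    return MoleculeRoles(roles=roles, rings=rings, graph=g)


# --- hydrogen-bond detection -------------------------------------------------

def _atom_label(i: int, geom: Geometry, roles: MoleculeRoles | None) -> str:
    if roles is not None:
        r = roles.role_of(i)
        if r is not None:
            return r
    return f"{geom.symbols[i]}{i + 1}"


def detect_hbonds(
    geom: Geometry,
    cutoff: float = HBOND_CUTOFF,
    roles: MoleculeRoles | None = None,
) -> list[HBond]:
    """Geometric hydrogen bonds: polar H within ``cutoff`` of an acceptor.

    Donors are hydrogens covalently bonded (<= 1.2 A) to N or O. Acceptors are
    every O atom, every N atom with an available lone pair (amide nitrogens,
    whose lone pair is delocalised into the carbonyl, and pyrrole-type ring
    N-H are excluded), plus the centroid of each aromatic ring (pi acceptor).
    Contacts separated by three or fewer covalent bonds are excluded, as are
    pi contacts from a donor attached to (or inside) the ring itself. The
    cutoff comparison is inclusive and measured H...acceptor.
    """
    if roles is None:
        try:
            roles = infer_roles(geom)
        except TypingError:
            roles = MoleculeRoles(graph=bond_graph(geom))
    g = roles.graph if roles.graph is not None else bond_graph(geom)
    syms, coords = geom.symbols, geom.coords
    ring_atoms = {i for ring in roles.rings for i in ring}

    def _is_acceptor(i: int) -> bool:
        if syms[i] == "O":
            return True
        if syms[i] != "N":
            return False
        for c in g.neighbors(i):  # amide N: bonded to a carbonyl carbon
            if syms[c] == "C" and any(
                syms[o] == "O" and len(list(g.neighbors(o))) == 1
                for o in g.neighbors(c)
            ):
                return False
        if i in ring_atoms and any(syms[j] == "H" for j in g.neighbors(i)):
            return False  # pyrrole-type N-H
        return True

    donors = []  # (hydrogen index, donor heavy index)
    for h in (i for i, s in enumerate(syms) if s == "H"):
        for j in g.neighbors(h):
            if syms[j] in ("N", "O") and np.linalg.norm(coords[h] - coords[j]) <= _DONOR_COVALENT_MAX:
                donors.append((h, j))
                break

    out: list[HBond] = []
    for h, d in donors:
        path = nx.single_source_shortest_path_length(g, h, cutoff=3)
        dlab = _atom_label(d, geom, roles) + "_H"
        for a in (i for i, s in enumerate(syms) if s in ("N", "O")):
            if a == d or a in path or not _is_acceptor(a):
                continue
            dist = float(np.linalg.norm(coords[h] - coords[a]))
            if dist <= cutoff:
                out.append(HBond(d, h, a, dist, f"{dlab}···{_atom_label(a, geom, roles)}"))
        for ring in roles.rings:
            if d in ring or any(nb in ring for nb in g.neighbors(d)):
                continue
            centroid = coords[list(ring)].mean(axis=0)
            dist = float(np.linalg.norm(coords[h] - centroid))
            if dist <= cutoff:
                out.append(HBond(d, h, None, dist, f"{dlab}···π"))
    out.sort(key=lambda hb: (hb.hydrogen, hb.distance))
    return out


# --- classification ----------------------------------------------------------

# Ramachandran class centres (phi2, psi2) in degrees. Gamma classes are the
# folded C7 turns; beta/epsilon/alpha are extended. Fixed constants of this
# package (the conformer-letter convention of Csaszar & Perczel).
BACKBONE_CENTERS: dict[str, tuple[float, float]] = {
    "γ_L": (-84.0, 68.0),
    "γ_D": (84.0, -68.0),
    "β": (-180.0, 180.0),
    "ε_L": (-75.0, 160.0),
    "ε_D": (75.0, -160.0),
    "α_L": (60.0, 45.0),
}
FOLDED_BACKBONES = frozenset({"γ_L", "γ_D"})

# chi1 (N-CA-CB-CG) canonical values; note the field's literal convention:
# g+ near +180, g- near +60, a near -60 degrees.
SWING_CENTERS: dict[str, float] = {"g+": 180.0, "g−": 60.0, "a": -60.0}


def classify_swing(chi1: float) -> str:
    """Nearest swing class on the circle; ties resolved towards g+."""
    best, best_d = None, math.inf
    for name in ("g+", "g−", "a"):
        dd = abs(circular_difference(chi1, SWING_CENTERS[name]))
        if dd < best_d - 1e-12:
            best, best_d = name, dd
    return best


def classify_backbone(phi2: float, psi2: float) -> tuple[str, str]:
    """Nearest Ramachandran class centre on the (phi, psi) torus.

    Returns ``(backbone, fold)`` with fold F for gamma classes, E otherwise.
    """
    best, best_d = None, math.inf
    for name, (pc, sc) in BACKBONE_CENTERS.items():
        dd = math.hypot(circular_difference(phi2, pc), circular_difference(psi2, sc))
        if dd < best_d - 1e-12:
            best, best_d = name, dd
    return best, ("F" if best in FOLDED_BACKBONES else "E")


def classify_terminus(hbonds: list[HBond] | set[str], amino_swing_dihedral: float) -> str:
    """Amino-terminus class from the diagnostic hydrogen bonds.

    B when the amino N-H donates to the peptide carbonyl (``N_1_H···OC_PB``)
    and the reverse ``N_PB_H···N_1`` bond is absent; otherwise the A family,
    split into A1/A2 by the sign of the amino-swing dihedral (positive = A1).
    Returns "U" (untyped) when neither diagnostic bond is present.
    """
    labels = {hb.label if isinstance(hb, HBond) else str(hb) for hb in hbonds}
    labels = {l.replace("N_1H", "N_1_H") for l in labels}
    if "N_1_H···OC_PB" in labels and "N_PB_H···N_1" not in labels:
        return "B"
    if "N_PB_H···N_1" in labels:
        return "A1" if amino_swing_dihedral > 0 else "A2"
    return "U"


def extract_dihedrals(geom: Geometry, roles: MoleculeRoles | None = None) -> DihedralSet:
    """Measure the typing dihedrals (phi2, psi2, chi1, orientation, amino swing)."""
    if roles is None:
        roles = infer_roles(geom)
    c = geom.coords
    r = roles.roles

    def dih(*names_or_idx):
        pts = [c[r[x]] if isinstance(x, str) else c[x] for x in names_or_idx]
        return dihedral(*pts)

    phi2 = dih("C_PB", "N_PB", "CA2", "C_T")
    psi2 = dih("N_PB", "CA2", "C_T", "O_T")
    if "CG" not in roles:
        raise TypingError(f"{geom.label!r}: no side chain CB-CG found; cannot assign chi1")
    chi1 = dih("N_SC", "CA_SC", "CB", "CG")

    g = roles.graph
    if "O_S" in roles:  # Tyr: phenol hydroxyl torsion C_ring-CZ-O-H
        h_os = min(j for j in g.neighbors(r["O_S"]) if geom.symbols[j] == "H")
        ring_nb = min(
            j for j in g.neighbors(r["CZ"]) if geom.symbols[j] == "C" and j != r["O_S"]
        )
        orient = dih(ring_nb, "CZ", "O_S", h_os)
    else:  # Trp (or other aromatics): chi2 = CA-CB-CG-(first ring neighbour)
        cg_nb = min(
            j for j in g.neighbors(r["CG"]) if geom.symbols[j] != "H" and j != r["CB"]
        )
        orient = dih("CA_SC", "CB", "CG", cg_nb)

    h_n1 = min(j for j in g.neighbors(r["N_1"]) if geom.symbols[j] == "H")
    amino_swing = dih("C_PB", "CA1", "N_1", h_n1)

    return DihedralSet(
        phi2=phi2, psi2=psi2, chi1=chi1, orient_dihedral=orient, amino_swing=amino_swing
    )


def type_label(
    geom: Geometry,
    cutoff: float = HBOND_CUTOFF,
    roles: MoleculeRoles | None = None,
) -> StructuralType:
    """Full four-part structural type of a dipeptide conformer geometry."""
    if roles is None:
        roles = infer_roles(geom)
    dih = extract_dihedrals(geom, roles)
    hbonds = detect_hbonds(geom, cutoff=cutoff, roles=roles)
    backbone, _fold = classify_backbone(dih.phi2, dih.psi2)
    swing = classify_swing(dih.chi1)
    orientation = "+" if dih.orient_dihedral > 0 else "−"
    terminus = classify_terminus(hbonds, dih.amino_swing)
    return StructuralType(
        terminus=terminus, backbone=backbone, swing=swing, orientation=orientation
    )
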
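"""Synthetic ensembles, toy dipeptide geometries and the packaged YG table.

Three kinds of test data, all generated in code:

* :func:`generate_ensemble` — random conformer ensembles with the structure
  seen in jet-cooling studies of aromatic dipeptides: a few folded low-energy
  conformers (each kinetically isolated), plus families of extended
  conformers grouped by side-chain type; intra-group barriers are low,
  inter-group barriers medium, and anything involving a folded conformer
  high. The ground-truth basin partition and pooled 450 K populations are
  emitted alongside, computed by construction.
* :func:`build_dipeptide_geometry` — an idealised internal-coordinate builder
  (natural extension reference frame) producing toy 3D dipeptide geometries
  that realise requested torsions exactly, for typing round-trip tests.
* :func:`table1_fixture` — the published 37-row YG reference table (relative
  electronic energies, hydrogen-bond networks, structural types and
  equilibrium distributions at 98/298/450 K), packaged as CSV data.
"""

from __future__ import annotations

import hashlib
import itertools
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .ensemble_io import BarrierRecord, EnergyRecord, ValidationError
from .structure import DihedralSet, Geometry, StructuralType, wrap_angle
from .thermo import KB_KCAL_PER_MOL_K

__all__ = [
    "SyntheticSpec",
    "SyntheticEnsemble",
    "GroundTruthBasin",
    "generate_ensemble",
    "build_dipeptide_geometry",
    "enumerate_trial_dihedrals",
    "table1_fixture",
    "yg_reference_basins",
    "yg_side_chain_groups",
    "table1_low_t_free_energies",
    "table1_checksum",
    "TABLE1_SHA256",
    "YG1_FOLD_DIHEDRALS",
    "YG26_EXTENDED_DIHEDRALS",
    "YG6_B_DIHEDRALS",
]

# --- synthetic ensembles -----------------------------------------------------

_SIDE_CHAIN_TYPES = ("g+/+", "g+/−", "g−/+", "g−/−", "a/+", "a/−")
_EXTENDED_BACKBONES = ("β", "ε_D", "ε_L")
_FOLDED_BACKBONES = ("γ_D", "γ_L")


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic conformer ensemble.

    Defaults mirror the ensemble structure of the YG reference system: four
    extended side-chain families of sizes (4, 3, 6, 7) plus a handful of
    folded low-energy conformers; electronic energies spanning a few kcal/mol
    with the folded structures lowest; a free-energy correction giving
    extended conformers an entropy advantage that grows linearly with
    temperature (so the ensemble inverts from folded-dominated at ~100 K to
    extended-dominated at room temperature and above).
    """

    n_folded: int = 5
    group_layout: dict[str, int] = field(
        default_factory=lambda: {"g+/+": 4, "g+/−": 3, "g−/+": 6, "g−/−": 7}
    )
    energy_scale: float = 4.0  # kcal/mol span of the ensemble
    g_corr_entropy_bias: float = 1.2  # kcal/mol favouring extended at 450 K
    barrier_draws: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"low": (0.0, 2.0), "medium": (2.01, 7.99), "high": (8.0, 15.0)}
    )
    seed: int = 0
    temperatures: tuple[float, ...] = (10.0, 98.0, 298.0, 450.0)

    @property
    def n_extended(self) -> int:
        return sum(self.group_layout.values())

    def validate(self) -> None:
        if self.n_folded < 0 or any(v < 0 for v in self.group_layout.values()):
            raise ValidationError("conformer counts must be non-negative")
        lo, hi = self.barrier_draws["low"], self.barrier_draws["high"]
        med = self.barrier_draws["medium"]
        if not (lo[0] >= 0 and lo[1] <= 2.0 and med[0] > 2.0 and med[1] < 8.0 and hi[0] >= 8.0):
            raise ValidationError(
                "barrier intervals must respect the class thresholds "
                "(low within [0,2], medium within (2,8), high >= 8 kcal/mol)"
            )
        for sc in self.group_layout:
            if sc not in _SIDE_CHAIN_TYPES:
                raise ValidationError(f"unknown side-chain type {sc!r}")
        if self.n_folded > 2 * len(_SIDE_CHAIN_TYPES):
            raise ValidationError(
                f"at most {2 * len(_SIDE_CHAIN_TYPES)} mutually isolated folded "
                "conformers are constructible"
            )


@dataclass(frozen=True)
class GroundTruthBasin:
    members: frozenset[str]
    sink: str
    pooled_population: float  # percent at 450 K


@dataclass
class SyntheticEnsemble:
    records: list[EnergyRecord]
    types: dict[str, StructuralType]
    barriers: list[BarrierRecord]
    truth: list[GroundTruthBasin]
    seed: int


def _boltzmann_percent(g: dict[str, float], T: float) -> dict[str, float]:
    # direct summation, kept local so the ground truth is computed by construction
    gmin = min(g.values())
    w = {k: math.exp(-(v - gmin) / (KB_KCAL_PER_MOL_K * T)) for k, v in g.items()}
    z = sum(w.values())
    return {k: 100.0 * v / z for k, v in w.items()}


def generate_ensemble(spec: SyntheticSpec) -> SyntheticEnsemble:
    """Deterministic synthetic ensemble with known basin structure.

    Conformer ids are assigned by ascending electronic energy (``c1`` is the
    global minimum), following the field's naming convention. Folded
    conformers are drawn at the bottom of the energy range and carry no
    entropic correction; extended conformers sit higher but gain
    ``-g_corr_entropy_bias * T/450`` kcal/mol of free energy, which inverts
    the ensemble at high temperature.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_folded + spec.n_extended
    if n_total == 0:
        return SyntheticEnsemble(records=[], types={}, barriers=[], truth=[], seed=spec.seed)

    # draw energies: folded low, extended higher
    e_folded = np.sort(rng.uniform(0.0, 0.55 * spec.energy_scale, spec.n_folded))
    e_extended = np.sort(rng.uniform(0.4 * spec.energy_scale, spec.energy_scale, spec.n_extended))
    raw = [("folded", i, e) for i, e in enumerate(e_folded)]
    ext_iter = iter(e_extended)
    groups: dict[str, list] = {}
    for sc, count in spec.group_layout.items():
        groups[sc] = []
        for _ in range(count):
            raw.append(("extended", sc, next(ext_iter)))

    # assign ids by ascending energy, re-referenced to the minimum
    raw.sort(key=lambda t: t[2])
    e0 = raw[0][2]
    ids = [f"c{k + 1}" for k in range(len(raw))]

    # structural types: folded conformers get pairwise-distinct
    # (backbone, side-chain) combos so the heuristic keeps them isolated
    folded_combos = [
        (bb, sc) for sc, bb in itertools.product(_SIDE_CHAIN_TYPES, _FOLDED_BACKBONES)
    ]
    records, types = [], {}
    fold_i = 0
    termini = itertools.cycle(("A1", "A2"))
    ext_bb = {sc: itertools.cycle(_EXTENDED_BACKBONES) for sc in spec.group_layout}
    for cid, (kind, tag, e) in zip(ids, raw):
        e_rel = float(e - e0)
        if kind == "folded":
            bb, sc = folded_combos[fold_i]
            fold_i += 1
            g_corr = {T: 0.0 for T in spec.temperatures}
        else:
            sc = tag
            bb = next(ext_bb[sc])
            groups[sc].append(cid)
            g_corr = {
                T: -spec.g_corr_entropy_bias * T / 450.0 for T in spec.temperatures
            }
        swing, orient = sc.split("/")
        types[cid] = StructuralType(
            terminus=next(termini), backbone=bb, swing=swing, orientation=orient
        )
        records.append(EnergyRecord(conformer_id=cid, e_rel=e_rel, g_corr=g_corr))

    # barriers for every unordered pair, classed by construction
    by_id = {r.conformer_id: r for r in records}
    barriers = []
    member_group = {cid: sc for sc, mem in groups.items() for cid in mem}
    for a, b in itertools.combinations(ids, 2):
        a_ext, b_ext = a in member_group, b in member_group
        if not a_ext or not b_ext:
            cls = "high"
        elif member_group[a] == member_group[b]:
            cls = "low"
        else:
            cls = "medium"
        lo, hi = spec.barrier_draws[cls]
        barriers.append(BarrierRecord(pair=(a, b), dg_barrier=float(rng.uniform(lo, hi))))

    # ground truth, by construction: each side-chain family is one basin,
    # every folded conformer its own singleton
    g450 = {r.conformer_id: r.e_rel + r.g_corr.get(450.0, 0.0) for r in records}
    pops450 = _boltzmann_percent(g450, 450.0)
    g10 = {r.conformer_id: r.e_rel + r.g_corr.get(10.0, 0.0) for r in records}
    truth = []
    for sc, members in groups.items():
        if not members:
            continue
        sink = min(members, key=lambda c: (g10[c], by_id[c].e_rel, c))
        truth.append(
            GroundTruthBasin(
                members=frozenset(members),
                sink=sink,
                pooled_population=sum(pops450[c] for c in members),
            )
        )
    for cid in ids:
        if cid not in member_group:
            truth.append(
                GroundTruthBasin(
                    members=frozenset({cid}), sink=cid, pooled_population=pops450[cid]
                )
            )
    truth.sort(key=lambda b: -b.pooled_population)
    return SyntheticEnsemble(
        records=records, types=types, barriers=barriers, truth=truth, seed=spec.seed
    )


# --- trial-structure enumeration ----------------------------------------------

def enumerate_trial_dihedrals(bond_grid: dict[str, list[float]]) -> list[dict[str, float]]:
    """All combinations of rotatable-bond grid values, lexicographic order.

    ``bond_grid`` maps a rotatable-bond name (e.g. ``phi2``) to its candidate
    angles; the result has ``prod(len(v))`` dictionaries, suitable for seeding
    :func:`build_dipeptide_geometry`.
    """
    if not bond_grid:
        return [{}]
    for bond, angles in bond_grid.items():
        if not angles:
            raise ValidationError(f"empty angle grid for rotatable bond {bond!r}")
    names = list(bond_grid)
    return [
        dict(zip(names, combo))
        for combo in itertools.product(*(bond_grid[n] for n in names))
    ]


# --- toy geometry builder ------------------------------------------------------

def _nerf(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D bonded to c with angle(b,c,D) and dihedral(a,b,c,D)."""
    a, b, c = map(np.asarray, (a, b, c))
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _tyr_side_chain(ca, n, c):
    """Phenol side chain attached at alpha carbon ``ca`` (backbone n, c given)."""
    return [
        ("CB", "C", (c, n, ca), 1.53, 110.5, ("_branch", -122.0)),
        ("HA", "H", (c, n, ca), 1.09, 108.0, ("_branch", 118.0)),
        ("CG", "C", (n, ca, "CB"), 1.51, 114.0, ("chi1", 0.0)),
        ("HB1", "H", (n, ca, "CB"), 1.09, 109.0, ("chi1", 120.0)),
        ("HB2", "H", (n, ca, "CB"), 1.09, 109.0, ("chi1", -120.0)),
        ("CD1", "C", (ca, "CB", "CG"), 1.40, 120.9, ("chi2", 0.0)),
        ("CD2", "C", (ca, "CB", "CG"), 1.40, 120.9, ("chi2", 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
        ("OS", "O", ("CD1", "CE1", "CZ"), 1.37, 120.0, 180.0),
        ("HOS", "H", ("CE1", "CZ", "OS"), 0.96, 110.0, ("oh", 0.0)),
        ("HD1", "H", ("CB", "CG", "CD1"), 1.08, 120.0, 0.0),
        ("HD2", "H", ("CB", "CG", "CD2"), 1.08, 120.0, 0.0),
        ("HE1", "H", ("CG", "CD1", "CE1"), 1.08, 120.0, 180.0),
        ("HE2", "H", ("CG", "CD2", "CE2"), 1.08, 120.0, 180.0),
    ]


def _trp_side_chain(ca, n, c):
    """Indole side chain attached at alpha carbon ``ca``."""
    return [
        ("CB", "C", (c, n, ca), 1.53, 110.5, ("_branch", -122.0)),
        ("HA", "H", (c, n, ca), 1.09, 108.0, ("_branch", 118.0)),
        ("CG", "C", (n, ca, "CB"), 1.50, 114.0, ("chi1", 0.0)),
        ("HB1", "H", (n, ca, "CB"), 1.09, 109.0, ("chi1", 120.0)),
        ("HB2", "H", (n, ca, "CB"), 1.09, 109.0, ("chi1", -120.0)),
        ("CD1", "C", (ca, "CB", "CG"), 1.37, 126.9, ("chi2", 0.0)),
        ("CD2", "C", (ca, "CB", "CG"), 1.43, 126.9, ("chi2", 180.0)),
        ("NE1", "N", ("CB", "CG", "CD1"), 1.38, 110.2, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.41, 107.2, 180.0),
        ("HNE", "H", ("CG", "CD1", "NE1"), 1.01, 125.0, 180.0),
        ("HD1", "H", ("CB", "CG", "CD1"), 1.08, 125.0, 0.0),
        ("CE3", "C", ("CB", "CG", "CD2"), 1.40, 133.5, 0.0),
        ("CZ2", "C", ("CG", "CD2", "CE2"), 1.40, 122.3, 180.0),
        ("CZ3", "C", ("CE2", "CD2", "CE3"), 1.40, 118.5, 0.0),
        ("CH2", "C", ("CD2", "CE3", "CZ3"), 1.40, 121.0, 0.0),
        ("HE3", "H", ("CG", "CD2", "CE3"), 1.08, 120.0, 0.0),
        ("HZ2", "H", ("CD2", "CE2", "CZ2"), 1.08, 120.0, 180.0),
        ("HZ3", "H", ("CD2", "CE3", "CZ3"), 1.08, 120.0, 180.0),
        ("HH2", "H", ("CE3", "CZ3", "CH2"), 1.08, 120.0, 180.0),
    ]


def _gly_alpha_hydrogens(ca, n, c, h1, h2):
    return [
        (h1, "H", (c, n, ca), 1.09, 109.0, ("_branch", -120.0)),
        (h2, "H", (c, n, ca), 1.09, 109.0, ("_branch", 120.0)),
    ]


def _dipeptide_template(residue: str):
    """Atom placement list for YG, WG or GW (side chain on residue 1 or 2)."""
    residue = residue.upper()
    if residue not in ("YG", "WG", "GW"):
        raise ValidationError(f"unknown dipeptide template {residue!r} (YG, WG or GW)")
    atoms = [
        # backbone: H2N-CA1(H/R)-C1(=O)-N2(H)-CA2(H/R)-C2(=O)(OH)
        ("N1", "N", None, None, None, None),
        ("CA1", "C", ("N1",), 1.47, None, None),
        ("C1", "C", ("N1", "CA1"), 1.53, 110.5, None),
        ("N2", "N", ("N1", "CA1", "C1"), 1.34, 114.5, ("psi1", 0.0)),
        ("O1", "O", ("N1", "CA1", "C1"), 1.23, 121.0, ("psi1", 180.0)),
        ("CA2", "C", ("CA1", "C1", "N2"), 1.45, 121.9, ("omega", 0.0)),
        ("H2", "H", ("CA1", "C1", "N2"), 1.01, 119.0, ("omega", 180.0)),
        ("C2", "C", ("C1", "N2", "CA2"), 1.52, 110.0, ("phi2", 0.0)),
        ("OT", "O", ("N2", "CA2", "C2"), 1.34, 111.0, ("psi2", 0.0)),
        ("O2", "O", ("N2", "CA2", "C2"), 1.21, 125.0, ("psi2", 180.0)),
        ("HOT", "H", ("CA2", "C2", "OT"), 0.97, 106.0, ("carboxyl", 0.0)),
        ("H11", "H", ("C1", "CA1", "N1"), 1.01, 109.5, ("amino_swing", 0.0)),
        ("H12", "H", ("C1", "CA1", "N1"), 1.01, 109.5, ("amino_swing", 120.0)),
    ]
    if residue in ("YG", "WG"):
        sc = _tyr_side_chain if residue == "YG" else _trp_side_chain
        atoms += sc("CA1", "N1", "C1")
        atoms += _gly_alpha_hydrogens("CA2", "N2", "C2", "HA21", "HA22")
    else:  # GW: glycine first, tryptophan second
        atoms += _gly_alpha_hydrogens("CA1", "N1", "C1", "HA11", "HA12")
        atoms += _trp_side_chain("CA2", "N2", "C2")
    return atoms


def build_dipeptide_geometry(
    dihedrals: DihedralSet, residue: str = "YG", label: str | None = None
) -> Geometry:
    """Toy dipeptide geometry realising the requested torsions exactly.

    Ideal bond lengths and angles; the named torsions of ``dihedrals``
    (phi2, psi2, chi1, orientation, amino swing, psi1, omega, chi2, carboxyl)
    are reproduced to well under 1e-3 degrees by construction. Non-bonded
    contacts closer than 0.7 Angstrom trigger a warning, not an error.
    """
    var = {
        "phi2": dihedrals.phi2,
        "psi2": dihedrals.psi2,
        "chi1": dihedrals.chi1,
        "oh": dihedrals.orient_dihedral,
        "chi2": dihedrals.chi2 if residue.upper() != "WG" else dihedrals.orient_dihedral,
        "amino_swing": dihedrals.amino_swing,
        "psi1": dihedrals.psi1,
        "omega": dihedrals.omega,
        "carboxyl": dihedrals.carboxyl,
        "_branch": 0.0,
    }
    if residue.upper() == "GW":
        # orientation torsion of Trp is chi2 itself
        var["chi2"] = dihedrals.orient_dihedral

    pos: dict[str, np.ndarray] = {}
    symbols, coords, names = [], [], []
    for name, el, refs, bond, angle, tors in _dipeptide_template(residue):
        if refs is None:  # first atom
            p = np.zeros(3)
        elif angle is None:  # second atom
            p = pos[refs[0]] + np.array([bond, 0.0, 0.0])
        elif tors is None:  # third atom, placed in the xy-plane
            b, c = pos[refs[0]], pos[refs[1]]
            p = _nerf(c + np.array([0.0, 1.0, 0.0]), b, c, bond, angle, 0.0)
        else:
            vname, offset = tors if isinstance(tors, tuple) else (None, tors)
            t = (var[vname] + offset) if vname is not None else offset
            a, b, c = pos[refs[0]], pos[refs[1]], pos[refs[2]]
            p = _nerf(a, b, c, bond, angle, wrap_angle(t))
        pos[name] = p
        names.append(name)
        symbols.append(el)
        coords.append(p)

    geom = Geometry(
        label=label or f"{residue.lower()}_toy", symbols=symbols, coords=np.array(coords)
    )
    d = np.linalg.norm(geom.coords[:, None, :] - geom.coords[None, :, :], axis=-1)
    close = (d < 0.7) & ~np.eye(len(geom), dtype=bool)
    if close.any():
        i, j = np.argwhere(close)[0]
        warnings.warn(
            f"{geom.label}: steric clash {names[i]}-{names[j]} at {d[i, j]:.2f} A",
            stacklevel=2,
        )
    return geom


#: Torsions of a folded (gamma_D) Tyr-Gly toy conformer showing the
#: gamma-turn hydrogen-bond pattern {N_PB_H···N_1, O_T_H···OC_PB} with an
#: A1 terminus and g+/+ side chain. Values tuned once against the builder;
#: see docs/methods.md for why the NH···pi contact cannot coexist with an
#: anti chi1 in a rigid ideal-valence geometry.
YG1_FOLD_DIHEDRALS = DihedralSet(
    phi2=84.0,
    psi2=-68.0,
    chi1=175.0,
    orient_dihedral=5.0,
    amino_swing=35.0,
    psi1=10.0,
    omega=180.0,
    chi2=80.0,
    carboxyl=0.0,
)

#: Extended (epsilon_D) toy conformer with a gauche side chain folding the
#: phenol ring over the amino group: hydrogen bonds {N_PB_H···N_1, N_1_H···π},
#: type A2-ε_D(E)-g−/+ (the pairing seen for such rows in the reference table).
YG26_EXTENDED_DIHEDRALS = DihedralSet(
    phi2=75.0,
    psi2=-160.0,
    chi1=30.0,
    orient_dihedral=5.0,
    amino_swing=-30.0,
    psi1=0.0,
    omega=180.0,
    chi2=90.0,
    carboxyl=180.0,
)

#: Folded (gamma_L) toy conformer with the B-type amino terminus donating to
#: the peptide carbonyl: hydrogen bonds {N_1_H···OC_PB, O_T_H···OC_PB},
#: type B-γ_L(F)-a/−.
YG6_B_DIHEDRALS = DihedralSet(
    phi2=-84.0,
    psi2=68.0,
    chi1=-60.0,
    orient_dihedral=-5.0,
    amino_swing=35.0,
    psi1=160.0,
    omega=180.0,
    chi2=80.0,
    carboxyl=0.0,
)


# --- packaged reference table ---------------------------------------------------

#: Pinned checksum of the packaged YG reference table.
TABLE1_SHA256 = "cc979c86cdf3a914991beca58424e2dd3674ab1ca35d38e8c0ff73c59c214709"


def _data_path(name: str):
    return resources.files("jetcool.data").joinpath(name)


def table1_checksum() -> str:
    return hashlib.sha256(_data_path("table1_yg.csv").read_bytes()).hexdigest()


def table1_fixture():
    """The 37-row YG reference table.

    Returns ``(records, types, distributions)``: energy records (no
    free-energy corrections — the published corrections are not printed, so
    the distribution columns are data, not a recomputation target), structural
    types by conformer id, and a DataFrame of equilibrium distributions (%) at
    98/298/450 K with NaN for entries below 1% (printed as an em dash).
    """
    df = pd.read_csv(_data_path("table1_yg.csv"))
    records = [
        EnergyRecord(conformer_id=row.conformer, e_rel=float(row.e_rel))
        for row in df.itertuples()
    ]
    types = {
        row.conformer: StructuralType.from_label(row.type) for row in df.itertuples()
    }
    dist = df.set_index("conformer")[["pop@98", "pop@298", "pop@450"]]
    dist.columns = [98.0, 298.0, 450.0]
    return records, types, dist


def yg_side_chain_groups() -> list[dict]:
    """Published YG side-chain families and their low-temperature sinks.

    Each entry has ``name`` (side-chain type), ``sink`` (the family's local
    free-energy minimum identified by the published low-temperature
    free-energy profiles) and ``members``.
    """
    df = pd.read_csv(_data_path("yg_groups.csv"))
    return [
        {"name": r.group, "sink": r.sink, "members": r.members.split()}
        for r in df.itertuples()
    ]


def yg_reference_basins(observable_threshold: float = 8.0, use_types: bool = False):
    """Kinetic basins of the YG reference ensemble at 450 K.

    Pools the published 450 K equilibrium distributions over the published
    side-chain family memberships (``use_types=False``, the default) or over
    the conversion graph predicted from the structural types
    (``use_types=True``; this additionally picks up family members omitted
    from the published lists, e.g. yg26). Conformers below the 1% reporting
    cutoff contribute zero. Returns a list of
    :class:`~jetcool.kinetics.BasinResult`.
    """
    import networkx as nx

    from . import kinetics

    records, types, dist = table1_fixture()
    pops = dist[450.0].fillna(0.0).to_dict()
    e_rel = {r.conformer_id: r.e_rel for r in records}
    if use_types:
        graph = kinetics.build_conversion_graph(list(dist.index), types=types)
    else:
        graph = nx.Graph()
        graph.add_nodes_from(dist.index)
        for grp in yg_side_chain_groups():
            members = grp["members"]
            graph.add_edges_from(zip(members, members[1:]))
    return kinetics.pool_populations(
        graph,
        pops,
        g_at_tref=table1_low_t_free_energies(),
        e_rel=e_rel,
        observable_threshold=observable_threshold,
    )


def table1_low_t_free_energies() -> dict[str, float]:
    """Synthetic ordinal 10 K free energies for the YG reference ensemble.

    The reference table prints no low-temperature free energies; this
    stand-in encodes only the *ordering* implied by the published
    free-energy profiles (each family's sink lowest, remaining members ranked
    by electronic energy) so that sink selection in pooling is well defined.
    The magnitudes are synthetic and must not be used quantitatively.
    """
    records, _, _ = table1_fixture()
    e_rel = {r.conformer_id: r.e_rel for r in records}
    g: dict[str, float] = {}
    for grp in yg_side_chain_groups():
        others = sorted(
            (m for m in grp["members"] if m != grp["sink"]), key=lambda m: e_rel[m]
        )
        g[grp["sink"]] = 0.0
        for k, m in enumerate(others, start=1):
            g[m] = 0.5 * k
    for cid, e in e_rel.items():
        g.setdefault(cid, e)
    return g
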
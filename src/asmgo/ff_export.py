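"""GROMACS-compatible export of the coarse-grained force field.

Writes a ``system.top`` with one included ``.itp`` per merged molecule type,
a ``.gro`` coordinate file, tabulated bonded ``.xvg`` files for
multi-minimum terms, and an interaction-group report. Conventions:

* one atom type per (merged type, residue position), named ``T<t>R<r>`` —
  intermolecular native pairs become ``[ nonbond_params ]`` overrides
  between these types, so they bind *any* two copies of the matching
  molecule types (permutation invariance);
* the default nonbonded interaction is purely repulsive: every atom type
  carries C6 = 0 and C12 = eps * sigma_R^12 (combination rule 1 then yields
  the same C12 for every non-native pair);
* intramolecular native pairs are ``[ pairs ]`` entries with C6 = 2 eps r0^6,
  C12 = eps r0^12 (12-6 LJ with minimum -eps exactly at r0) plus exclusions;
* when a type-level intermolecular pair relates two positions of the *same*
  molecule type, the override would also attract that residue pair inside
  one copy; an exclusion plus a repulsion-only ``[ pairs ]`` entry restores
  the default behavior there;
* energies: eps = 1 kJ/mol; distances exported in nm (internal A / 10);
  the harmonic constants are doubled on export (internal V = k x^2 vs
  GROMACS V = k/2 x^2).

``load_system`` parses these files back into an :class:`ExpandedSystem`,
which the test-suite uses as a round-trip oracle against the in-memory
topology.
"""
from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .constants import ONE_TO_THREE
from .merging import TabulatedPotential
from .params import ForceFieldParams
from .topology import CGTopology, ExpandedSystem, _as_idx

__all__ = ["write_topology", "write_gro", "read_gro", "place_random", "load_system"]

_EPS_FILE = 1.0  # eps in kJ/mol


def _atom_type(type_id: int, res: int) -> str:
    return f"T{type_id}R{res}"


def _parse_atom_type(name: str) -> tuple[int, int]:
    t, r = name[1:].split("R")
    return int(t), int(r)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _collect_tables(topology: CGTopology):
    """Deduplicate tabulated terms into numbered table classes."""
    angle_tables: dict[tuple, int] = {}
    dihedral_tables: dict[tuple, int] = {}
    table_objects: dict[tuple[str, int], TabulatedPotential] = {}
    for ctype in topology.types:
        for term in ctype.angles + ctype.dihedrals:
            if not term.is_tabulated:
                continue
            key = tuple(round(e, 12) for e in term.equilibria)
            registry = angle_tables if term.kind == "angle" else dihedral_tables
            if key not in registry:
                registry[key] = len(registry)
                table_objects[(term.kind, registry[key])] = term.table
    return angle_tables, dihedral_tables, table_objects


def _table_number(term, angle_tables, dihedral_tables) -> int:
    key = tuple(round(e, 12) for e in term.equilibria)
    return (angle_tables if term.kind == "angle" else dihedral_tables)[key]


def _write_table_file(path: Path, table: TabulatedPotential) -> None:
    # bonded tables use degrees; force column is -dE/dx per degree
    deg = np.degrees(table.x)
    minus_deriv = table.minus_derivative * math.pi / 180.0
    lines = [
        f"{x:14.6f} {e:18.12e} {f:18.12e}"
        for x, e, f in zip(deg, table.energy, minus_deriv)
    ]
    path.write_text("\n".join(lines) + "\n")


def _itp_text(ctype, params: ForceFieldParams, angle_tables, dihedral_tables,
              same_type_sig_pairs: set[tuple[int, int]]) -> str:
    lines = ["[ moleculetype ]", f"; molname  nrexcl", f"MOL{ctype.type_id}  3", ""]

    lines += ["[ atoms ]", ";  nr  type  resnr  residue  atom  cgnr  charge  mass"]
    for i, one in enumerate(ctype.sequence):
        lines.append(
            f"{i + 1:>6d}  {_atom_type(ctype.type_id, i):>10s}  {i + 1:>5d}  "
            f"{ONE_TO_THREE[one]:>4s}    CA  {i + 1:>5d}   0.000   1.000"
        )
    lines.append("")

    lines += ["[ bonds ]", ";  i   j  funct  b0(nm)  kb"]
    for i, j, b0, k in ctype.bonds:
        lines.append(f"{i + 1:>6d} {j + 1:>6d}  1  {b0 / 10.0:.12f}  {2.0 * k * 100.0:.9e}")
    lines.append("")

    lines += ["[ angles ]", ";  i   j   k  funct  (theta0(deg) ka | table k)"]
    for term in ctype.angles:
        i, j, k = (x + 1 for x in term.idx)
        if term.is_tabulated:
            n = _table_number(term, angle_tables, dihedral_tables)
            lines.append(f"{i:>6d} {j:>6d} {k:>6d}  8  {n}  1.0")
        else:
            theta0 = math.degrees(term.equilibria[0])
            lines.append(f"{i:>6d} {j:>6d} {k:>6d}  1  {theta0:.12f}  {2.0 * ctype.k_angle:.9e}")
    lines.append("")

    lines += ["[ dihedrals ]", ";  i   j   k   l  funct  (phase(deg) kd mult | table k)"]
    for term in ctype.dihedrals:
        i, j, k, l = (x + 1 for x in term.idx)
        if term.is_tabulated:
            n = _table_number(term, angle_tables, dihedral_tables)
            lines.append(f"{i:>6d} {j:>6d} {k:>6d} {l:>6d}  8  {n}  1.0")
        else:
            phi0 = math.degrees(term.equilibria[0])
            phase1 = (phi0 + 180.0) % 360.0
            phase3 = (3.0 * phi0 + 180.0) % 360.0
            lines.append(f"{i:>6d} {j:>6d} {k:>6d} {l:>6d}  1  {phase1:.12f}  "
                         f"{ctype.k_dihedral_1:.9e}  1")
            lines.append(f"{i:>6d} {j:>6d} {k:>6d} {l:>6d}  1  {phase3:.12f}  "
                         f"{ctype.k_dihedral_3:.9e}  3")
    lines.append("")

    intra_set = {(i, j) for i, j, *_ in ctype.intra_pairs}
    lines += ["[ pairs ]", ";  i   j  funct  C6  C12"]
    for i, j, r0, scale in ctype.intra_pairs:
        eps = _EPS_FILE * params.epsilon_intra * scale
        r0_nm = r0 / 10.0
        lines.append(f"{i + 1:>6d} {j + 1:>6d}  1  {2.0 * eps * r0_nm ** 6:.12e}  "
                     f"{eps * r0_nm ** 12:.12e}")
    sigma_nm = params.sigma_repulsive / 10.0
    c12_rep = _EPS_FILE * sigma_nm ** 12
    for i, j in sorted(same_type_sig_pairs - intra_set):
        # restore plain repulsion where a type-level intermolecular override
        # would otherwise act inside one chain copy
        lines.append(f"{i + 1:>6d} {j + 1:>6d}  1  {0.0:.12e}  {c12_rep:.12e}")
    lines.append("")

    lines += ["[ exclusions ]"]
    for i, j in sorted(intra_set | same_type_sig_pairs):
        lines.append(f"{i + 1:>6d} {j + 1:>6d}")
    lines.append("")
    return "\n".join(lines)


def write_topology(topology: CGTopology, out_dir: str | Path,
                   system_name: str = "cg-complex") -> dict[str, Path]:
    """Write system.top, per-type .itp files, tables and the group report.

    Output is deterministic: identical topology and parameters give
    byte-identical files. Returns a mapping of logical names to paths.
    """
    if topology.n_beads == 0:
        raise ValueError("cannot export a topology with zero beads")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = topology.params

    angle_tables, dihedral_tables, table_objects = _collect_tables(topology)
    files: dict[str, Path] = {}
    for (kind, n), table in table_objects.items():
        prefix = "table_a" if kind == "angle" else "table_d"
        path = out / f"{prefix}{n}.xvg"
        _write_table_file(path, table)
        files[f"{prefix}{n}"] = path

    # same-type intermolecular signatures needing intra-copy repulsion fixes
    same_type_sig: dict[int, set[tuple[int, int]]] = {t.type_id: set() for t in topology.types}
    for pair in topology.inter_pairs:
        if pair.type_a == pair.type_b and pair.res_a != pair.res_b:
            i, j = sorted((pair.res_a, pair.res_b))
            if j - i > 3:   # closer pairs are excluded by nrexcl anyway
                same_type_sig[pair.type_a].add((i, j))

    for ctype in topology.types:
        path = out / f"mol_{ctype.type_id}.itp"
        path.write_text(_itp_text(ctype, params, angle_tables, dihedral_tables,
                                  same_type_sig[ctype.type_id]))
        files[f"mol_{ctype.type_id}"] = path

    sigma_nm = params.sigma_repulsive / 10.0
    top = ["[ defaults ]", "; nbfunc  comb-rule  gen-pairs", "1  1  no", ""]
    top += ["[ atomtypes ]", "; name  mass  charge  ptype  C6  C12"]
    for ctype in topology.types:
        for i in range(ctype.n_residues):
            top.append(f"{_atom_type(ctype.type_id, i):>10s}  1.000  0.000  A  "
                       f"{0.0:.12e}  {_EPS_FILE * sigma_nm ** 12:.12e}")
    top.append("")

    top += ["[ nonbond_params ]", ";  typei  typej  funct  C6  C12"]
    for pair in sorted(topology.inter_pairs, key=lambda p: p.key):
        eps = _EPS_FILE * params.epsilon_inter * pair.epsilon_scale
        r0_nm = pair.r0 / 10.0
        top.append(f"{_atom_type(pair.type_a, pair.res_a):>10s}  "
                   f"{_atom_type(pair.type_b, pair.res_b):>10s}  1  "
                   f"{2.0 * eps * r0_nm ** 6:.12e}  {eps * r0_nm ** 12:.12e}")
    top.append("")

    for ctype in topology.types:
        top.append(f'#include "mol_{ctype.type_id}.itp"')
    top += ["", "[ system ]", system_name, "", "[ molecules ]", "; molname  count"]
    # run-length encode the instance sequence (order defines coordinate order)
    run_type, run_len = None, 0
    for inst in topology.instances + [None]:
        t = None if inst is None else inst.type_id
        if t == run_type:
            run_len += 1
            continue
        if run_type is not None:
            top.append(f"MOL{run_type}  {run_len}")
        run_type, run_len = t, 1
    top.append("")

    top_path = out / "system.top"
    top_path.write_text("\n".join(top))
    files["top"] = top_path

    report = ["# interaction groups", "# group_id  instance_a  instance_b  type_id  n_pairs  scale"]
    for g in topology.groups:
        report.append(f"{g.group_id}  {g.instance_a}  {g.instance_b}  "
                      f"{g.group_type_id}  {g.n_pairs}  {g.scale:.6f}")
    report.append(f"# {len(topology.group_types)} group type(s)")
    (out / "interaction_groups.txt").write_text("\n".join(report) + "\n")
    files["groups"] = out / "interaction_groups.txt"
    return files


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def write_gro(topology: CGTopology, coords: np.ndarray, path: str | Path,
              box: np.ndarray | float, title: str = "cg coordinates") -> None:
    """GRO coordinate file; *coords* in A, *box* in A (scalar = cubic)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topology.n_beads, 3):
        raise ValueError("coordinate count does not match topology")
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,))
    lines = [title, f"{topology.n_beads:>5d}"]
    serial = 0
    resnr = 0
    for inst in topology.instances:
        seq = topology.types[inst.type_id].sequence
        for i in range(inst.n_residues):
            x, y, z = coords[serial] / 10.0
            resnr += 1
            lines.append(
                f"{resnr % 100000:>5d}{ONE_TO_THREE[seq[i]]:<5s}"
                f"{'CA':>5s}{(serial + 1) % 100000:>5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}"
            )
            serial += 1
    lines.append(f"{box[0] / 10.0:10.5f}{box[1] / 10.0:10.5f}{box[2] / 10.0:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gro(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a GRO file; returns (coords_A, box_A)."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[1])
    coords = np.array([
        [float(line[20:28]), float(line[28:36]), float(line[36:44])]
        for line in lines[2:2 + n]
    ]) * 10.0
    box = np.array([float(v) for v in lines[2 + n].split()[:3]]) * 10.0
    return coords, box


def place_random(
    topology: CGTopology,
    box: float | np.ndarray,
    seed: int = 0,
    min_dist: float = 4.0,
    max_attempts: int = 2000,
) -> np.ndarray:
    """Random non-overlapping placement of all chains inside a periodic box.

    Each chain keeps its native internal conformation and receives a uniform
    random rotation and position; a placement is rejected while any bead
    comes within *min_dist* A (minimum image) of an already placed bead.
    Deterministic given *seed*.
    """
    rng = np.random.default_rng(seed)
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    placed: list[np.ndarray] = []
    for inst in topology.instances:
        body = topology.native_coords[inst.offset:inst.offset + inst.n_residues]
        body = body - body.mean(axis=0)
        others = np.concatenate(placed) if placed else None
        tree = cKDTree(np.mod(others, box), boxsize=box) if others is not None else None
        for attempt in range(max_attempts):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.uniform(0.0, box)
            candidate = body @ rot.T + shift
            if tree is None:
                break
            hits = tree.query_ball_point(np.mod(candidate, box), min_dist)
            if not any(hits):
                break
        else:
            raise RuntimeError(
                f"could not place chain {inst.instance_id} without overlaps; "
                "the box is too small or min_dist too large")
        placed.append(candidate)
    return np.concatenate(placed)


# ---------------------------------------------------------------------------
# reading the written force field back (round-trip oracle)
# ---------------------------------------------------------------------------

def _strip(line: str) -> str:
    return line.split(";")[0].strip()


def _sections(text: str):
    current = None
    for raw in text.splitlines():
        line = _strip(raw)
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            current = line.strip("[] ").lower()
            continue
        yield current, line


def _read_table(path: Path, kind: str) -> TabulatedPotential:
    data = np.loadtxt(path)
    return TabulatedPotential(
        kind=kind,
        x=np.radians(data[:, 0]),
        energy=data[:, 1],
        minus_derivative=data[:, 2] * 180.0 / math.pi,
    )


def load_system(out_dir: str | Path) -> ExpandedSystem:
    """Rebuild an evaluation-ready system from written topology files.

    Parses system.top, the included .itp files and the table .xvg files of
    this package's own dialect; used to verify that the exported files
    encode exactly the same potential as the in-memory topology.
    """
    out = Path(out_dir)
    text = (out / "system.top").read_text()

    atomtype_c12: dict[str, float] = {}
    nonbond: list[tuple] = []
    molecule_counts: list[tuple[str, int]] = []
    includes: list[str] = []
    for raw in text.splitlines():
        line = _strip(raw)
        if line.startswith("#include"):
            includes.append(line.split('"')[1])
    for section, line in _sections(text):
        fields = line.split()
        if section == "atomtypes":
            atomtype_c12[fields[0]] = float(fields[5])
        elif section == "nonbond_params":
            c6, c12 = float(fields[3]), float(fields[4])
            r0_nm = (2.0 * c12 / c6) ** (1.0 / 6.0)
            eps = c6 ** 2 / (4.0 * c12)
            nonbond.append((*_parse_atom_type(fields[0]), *_parse_atom_type(fields[1]),
                            r0_nm * 10.0, eps / _EPS_FILE))
        elif section == "molecules":
            molecule_counts.append((fields[0], int(fields[1])))

    sigma_rep = (max(atomtype_c12.values()) / _EPS_FILE) ** (1.0 / 12.0) * 10.0

    # per-molecule-type data from the itp files
    mol: dict[str, dict] = {}
    for name in includes:
        data = {"bonds": [], "angles": [], "tab_angles": [], "dihedrals": {},
                "tab_dihedrals": [], "pairs": [], "rep_pairs": [],
                "exclusions": [], "n_atoms": 0}
        molname = None
        for section, line in _sections((out / name).read_text()):
            f = line.split()
            if section == "moleculetype":
                molname = f[0]
            elif section == "atoms":
                data["n_atoms"] += 1
            elif section == "bonds":
                i, j = int(f[0]) - 1, int(f[1]) - 1
                data["bonds"].append((i, j, float(f[3]) * 10.0, float(f[4]) / 200.0))
            elif section == "angles":
                idx = tuple(int(x) - 1 for x in f[:3])
                if f[3] == "8":
                    data["tab_angles"].append((idx, int(f[4])))
                else:
                    data["angles"].append((*idx, math.radians(float(f[4])), float(f[5]) / 2.0))
            elif section == "dihedrals":
                idx = tuple(int(x) - 1 for x in f[:4])
                if f[4] == "8":
                    data["tab_dihedrals"].append((idx, int(f[5])))
                else:
                    phase, k, mult = float(f[5]), float(f[6]), int(f[7])
                    entry = data["dihedrals"].setdefault(idx, {})
                    if mult == 1:
                        entry["phi0"] = math.radians(phase - 180.0)
                        entry["k1"] = k
                    else:
                        entry["k3"] = k
            elif section == "pairs":
                i, j = int(f[0]) - 1, int(f[1]) - 1
                c6, c12 = float(f[3]), float(f[4])
                if c6 == 0.0:
                    data["rep_pairs"].append((i, j))
                else:
                    r0_nm = (2.0 * c12 / c6) ** (1.0 / 6.0)
                    data["pairs"].append((i, j, r0_nm * 10.0, c6 ** 2 / (4.0 * c12) / _EPS_FILE))
            elif section == "exclusions":
                data["exclusions"].append((int(f[0]) - 1, int(f[1]) - 1))
        mol[molname] = data

    tables: dict[tuple[str, int], TabulatedPotential] = {}

    def get_table(kind: str, number: int) -> TabulatedPotential:
        if (kind, number) not in tables:
            prefix = "table_a" if kind == "angle" else "table_d"
            tables[(kind, number)] = _read_table(out / f"{prefix}{number}.xvg", kind)
        return tables[(kind, number)]

    # expand molecules into global beads
    instances = []
    offset = 0
    for molname, count in molecule_counts:
        type_id = int(molname[3:])
        for _ in range(count):
            instances.append((type_id, molname, offset, mol[molname]["n_atoms"]))
            offset += mol[molname]["n_atoms"]
    n_beads = offset

    bonds, angles, dihedrals, tab_angles, tab_dihedrals = [], [], [], [], []
    intra, exclusions = [], set()
    chain_of = np.zeros(n_beads, dtype=int)
    for inst_id, (type_id, molname, off, n_atoms) in enumerate(instances):
        data = mol[molname]
        chain_of[off:off + n_atoms] = inst_id
        for i, j, b0, k in data["bonds"]:
            bonds.append((off + i, off + j, b0, k))
        for i, j, k, theta0, ka in data["angles"]:
            angles.append((off + i, off + j, off + k, theta0, ka))
        for idx, num in data["tab_angles"]:
            tab_angles.append((tuple(off + x for x in idx), get_table("angle", num)))
        for idx, entry in data["dihedrals"].items():
            dihedrals.append((*(off + x for x in idx),
                              entry["phi0"], entry["k1"], entry["k3"]))
        for idx, num in data["tab_dihedrals"]:
            tab_dihedrals.append((tuple(off + x for x in idx), get_table("dihedral", num)))
        for i, j, r0, eps in data["pairs"]:
            intra.append((off + i, off + j, r0, eps))
        rep = set(map(tuple, data["rep_pairs"]))
        for i, j in data["exclusions"]:
            if (i, j) not in rep:   # repulsion-restored pairs behave as default
                exclusions.add((off + min(i, j), off + max(i, j)))
        for i in range(n_atoms):
            for j in range(i + 1, min(i + 4, n_atoms)):
                exclusions.add((off + i, off + j))

    inter, seen = [], set()
    for ai, (ta_id, _na, off_a, _n) in enumerate(instances):
        for bi, (tb_id, _nb, off_b, _m) in enumerate(instances):
            if ai >= bi:
                continue
            for (ta, ra, tb, rb, r0, eps) in nonbond:
                for (xa, ia, xb, ib) in ((ta, ra, tb, rb), (tb, rb, ta, ra)):
                    if ta_id == xa and tb_id == xb:
                        gi, gj = off_a + ia, off_b + ib
                        key = (min(gi, gj), max(gi, gj))
                        if key not in seen:
                            seen.add(key)
                            inter.append((*key, r0, eps))

    for i, j, *_ in intra + inter:
        exclusions.add((min(i, j), max(i, j)))

    return ExpandedSystem(
        n_beads=n_beads,
        bond_idx=_as_idx([r[:2] for r in bonds], 2),
        bond_b0=np.array([r[2] for r in bonds]),
        bond_k=np.array([r[3] for r in bonds]),
        angle_idx=_as_idx([r[:3] for r in angles], 3),
        angle_theta0=np.array([r[3] for r in angles]),
        angle_k=np.array([r[4] for r in angles]),
        dihedral_idx=_as_idx([r[:4] for r in dihedrals], 4),
        dihedral_phi0=np.array([r[4] for r in dihedrals]),
        dihedral_k1=np.array([r[5] for r in dihedrals]),
        dihedral_k3=np.array([r[6] for r in dihedrals]),
        tab_angle_idx=_as_idx([idx for idx, _ in tab_angles], 3),
        tab_angle_tables=[t for _, t in tab_angles],
        tab_dihedral_idx=_as_idx([idx for idx, _ in tab_dihedrals], 4),
        tab_dihedral_tables=[t for _, t in tab_dihedrals],
        intra_idx=_as_idx([r[:2] for r in intra], 2),
        intra_r0=np.array([r[2] for r in intra]),
        intra_eps=np.array([r[3] for r in intra]),
        inter_idx=_as_idx([r[:2] for r in inter], 2),
        inter_r0=np.array([r[2] for r in inter]),
        inter_eps=np.array([r[3] for r in inter]),
        sigma_repulsive=sigma_rep,
        epsilon_repulsive=1.0,
        exclusions=exclusions,
        chain_of_bead=chain_of,
    )
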
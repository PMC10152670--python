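"""Van der Waals contact and steric-clash analysis for protein-DNA models.

The WRKY DNA-binding domain reads the W-box element partly through a van
der Waals contact between the conserved WRKYGQK tyrosine and the C5 edge
of the cytosine at motif position 4.  Adding a 5-methyl group to that
cytosine (5mC) places a bulky carbon exactly where the tyrosine ring sits,
producing a steric clash.  This module provides the geometric layer for
that analysis: a fixed-width PDB reader/writer for multi-model ensembles,
Kabsch superposition, in-silico C5 methylation of cytosines, and
exhaustive contact/clash enumeration with Bondi radii.

Definitions (configurable): a pair of atoms is a *contact* when their
distance is at most the sum of van der Waals radii plus ``contact_tol``
(default 0.5 A); a *clash* when the distance is below the sum of radii
minus ``overlap_thresh`` (default 0.4 A, the conventional severe-overlap
criterion).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "StructureEnsemble",
    "VdwTable",
    "ContactPair",
    "ContactReport",
    "read_pdb",
    "write_pdb",
    "kabsch_superpose",
    "superpose_ensemble",
    "methylate_cytosine",
    "vdw_contacts",
    "detect_clashes",
    "contact_persistence",
    "make_selection",
    "parse_selection",
]

BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass(frozen=True)
class Atom:
    """One PDB atom record."""

    serial: int
    name: str
    resname: str
    chain: str
    resnum: int
    x: float
    y: float
    z: float
    element: str = ""
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("atom coordinates must be finite")
        if not self.element:
            object.__setattr__(self, "element", element_from_name(self.name))

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name (C5, OH, CE1, C5M -> C/O/C/C)."""
    stripped = re.sub(r"[0-9'\"]", "", name.strip())
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    return stripped[0].upper()


@dataclass
class StructureEnsemble:
    """One or more models of the same molecular system.

    ``shared_topology`` is true when every model has the same atom count
    with matching (chain, resnum, name) in the same order, which
    per-model analyses such as contact persistence rely on.
    """

    models: list[list[Atom]]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble must contain at least one model")

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def shared_topology(self) -> bool:
        key = [(a.chain, a.resnum, a.name) for a in self.models[0]]
        return all(
            [(a.chain, a.resnum, a.name) for a in m] == key
            for m in self.models[1:])

    def coordinates(self, model_index: int = 0) -> np.ndarray:
        return np.array([a.coords for a in self.models[model_index]])


# ---------------------------------------------------------------------------
# van der Waals radii
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VdwTable:
    """Element -> van der Waals radius (A), Bondi values by default.

    Hydrogens are typically absent from the models analyzed here, so the
    C5-methyl carbon ("C5M") uses a united-atom radius (default 2.00 A)
    approximating the full CH3 group; set ``methyl_radius`` to 1.70 for
    explicit-carbon treatment.
    """

    radii: dict = field(default_factory=lambda: {
        "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80, "H": 1.20,
    })
    methyl_radius: float = 2.00
    methyl_atom_name: str = "C5M"

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()) or self.methyl_radius <= 0:
            raise ValueError("van der Waals radii must be positive")

    def radius(self, atom: Atom) -> float:
        if atom.name.strip() == self.methyl_atom_name:
            return self.methyl_radius
        try:
            return self.radii[atom.element]
        except KeyError:
            raise KeyError(
                f"no van der Waals radius for element {atom.element!r}")


# ---------------------------------------------------------------------------
# PDB I/O (fixed-width v3; multi-model via MODEL/ENDMDL)
# ---------------------------------------------------------------------------

def read_pdb(text: str) -> StructureEnsemble:
    """Parse ATOM/HETATM records into an ensemble; 'A'/blank altlocs kept.

    Malformed fixed-width lines raise ValueError naming the line number.
    """
    models: list[list[Atom]] = []
    current: list[Atom] = []
    in_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if current and not in_model:
                models.append(current)
            current = []
            in_model = True
        elif rec == "ENDMDL":
            models.append(current)
            current = []
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            try:
                altloc = line[16].strip()
                if altloc not in ("", "A"):
                    continue
                atom = Atom(
                    serial=int(line[6:11]),
                    name=line[12:16].strip(),
                    resname=line[17:20].strip(),
                    chain=line[21].strip(),
                    resnum=int(line[22:26]),
                    x=float(line[30:38]),
                    y=float(line[38:46]),
                    z=float(line[46:54]),
                    element=line[76:78].strip() if len(line) >= 78 else "",
                    occupancy=float(line[54:60]) if line[54:60].strip() else 1.0,
                    altloc=altloc,
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"malformed PDB record at line {lineno}: {line!r}"
                ) from exc
            current.append(atom)
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise ValueError("no ATOM/HETATM records found")
    return StructureEnsemble(models)


def write_pdb(ensemble: StructureEnsemble) -> str:
    """Serialize an ensemble as fixed-width PDB text (1e-3 A precision)."""
    lines: list[str] = []
    multi = ensemble.n_models > 1
    for i, model in enumerate(ensemble.models, start=1):
        if multi:
            lines.append(f"MODEL     {i:4d}")
        for serial, atom in enumerate(model, start=1):
            name = atom.name
            # standard alignment: 1-letter elements start in column 14
            padded = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 \
                else f"{name:<4s}"
            lines.append(
                f"ATOM  {serial:5d} {padded}{atom.altloc or ' ':1s}"
                f"{atom.resname:>3s} {atom.chain:1s}{atom.resnum:4d}    "
                f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                f"{atom.occupancy:6.2f}{0.0:6.2f}          "
                f"{atom.element:>2s}")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired coordinate sets.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best fits ``reference``; the
    rotation is proper (det = +1).  Requires >= 3 non-collinear pairs.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (N, 3)")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 atom pairs")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise ValueError("selection is collinear; superposition is degenerate")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    fitted = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Q) ** 2, axis=1))))
    return R, t, rmsd


def superpose_ensemble(
    ensemble: StructureEnsemble,
    reference_index: int = 0,
    selection: Callable[[Atom], bool] | None = None,
) -> tuple[StructureEnsemble, list[float]]:
    """Superpose every model onto one reference model.

    The fit uses ``selection`` (default: protein backbone atoms N, CA, C)
    and is applied to all atoms of each model.  Returns the transformed
    ensemble and the per-model RMSD over the selection.
    """
    if selection is None:
        selection = lambda a: a.name in BACKBONE_ATOMS  # noqa: E731
    if not ensemble.shared_topology:
        raise ValueError("superposition requires shared topology")
    ref = ensemble.models[reference_index]
    idx = [i for i, a in enumerate(ref) if selection(a)]
    if len(idx) < 3:
        raise ValueError("selection must cover at least 3 atoms")
    ref_xyz = np.array([ref[i].coords for i in idx])
    new_models, rmsds = [], []
    for model in ensemble.models:
        mob_xyz = np.array([model[i].coords for i in idx])
        R, t, rmsd = kabsch_superpose(mob_xyz, ref_xyz)
        moved = []
        for a in model:
            xyz = R @ a.coords + t
            moved.append(replace(a, x=xyz[0], y=xyz[1], z=xyz[2]))
        new_models.append(moved)
        rmsds.append(rmsd)
    return StructureEnsemble(new_models), rmsds


# ---------------------------------------------------------------------------
# in-silico methylation
# ---------------------------------------------------------------------------

_CYTOSINE_RESNAMES = {"DC", "C", "CYT"}


def methylate_cytosine(
    model: Sequence[Atom],
    chain: str,
    residue_number: int,
    bond_length: float = 1.50,
) -> list[Atom]:
    """Add a C5-methyl carbon ("C5M") to a cytosine residue.

    The new carbon is placed in the base plane along the external bisector
    of the C4-C5-C6 ring angle at the given C5-C bond length, mimicking
    the thymine-like C5 substituent geometry of 5-methylcytosine.  No
    other atoms move and no hydrogens are generated.  Calling it twice on
    the same residue is an error rather than a silent duplicate.
    """
    residue = [a for a in model
               if a.chain == chain and a.resnum == residue_number]
    if not residue:
        raise ValueError(f"no residue {chain}:{residue_number} in model")
    resname = residue[0].resname
    if resname not in _CYTOSINE_RESNAMES:
        raise ValueError(
            f"residue {chain}:{residue_number} is {resname}, not a cytosine")
    if any(a.name == "C5M" for a in residue):
        raise ValueError(
            f"residue {chain}:{residue_number} already carries a C5M atom")
    ring = {a.name: a for a in residue}
    missing = [n for n in ("C4", "C5", "C6") if n not in ring]
    if missing:
        raise ValueError(f"cytosine ring atoms missing: {missing}")
    c4, c5, c6 = (ring[n].coords for n in ("C4", "C5", "C6"))
    v4 = (c4 - c5) / np.linalg.norm(c4 - c5)
    v6 = (c6 - c5) / np.linalg.norm(c6 - c5)
    bisector = v4 + v6
    u = -bisector / np.linalg.norm(bisector)
    pos = c5 + bond_length * u
    c5m = Atom(serial=max(a.serial for a in model) + 1, name="C5M",
               resname=resname, chain=chain, resnum=residue_number,
               x=pos[0], y=pos[1], z=pos[2], element="C")
    out = list(model)
    insert_at = max(i for i, a in enumerate(out)
                    if a.chain == chain and a.resnum == residue_number) + 1
    out.insert(insert_at, c5m)
    return out


# ---------------------------------------------------------------------------
# contacts and clashes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactPair:
    atom_a: Atom
    atom_b: Atom
    distance: float
    radii_sum: float
    classification: str  # contact | clash | none

    @property
    def gap(self) -> float:
        """Distance minus sum of radii (negative = overlapping)."""
        return self.distance - self.radii_sum

    @property
    def overlap(self) -> float:
        return -self.gap


@dataclass
class ContactReport:
    pairs: list[ContactPair]

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_contacts(self) -> int:
        return sum(p.classification in ("contact", "clash")
                   for p in self.pairs)

    @property
    def n_clashes(self) -> int:
        return sum(p.classification == "clash" for p in self.pairs)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([{
            "atom_a": f"{p.atom_a.chain}:{p.atom_a.resnum}:{p.atom_a.name}",
            "atom_b": f"{p.atom_b.chain}:{p.atom_b.resnum}:{p.atom_b.name}",
            "distance": p.distance, "radii_sum": p.radii_sum,
            "gap": p.gap, "classification": p.classification,
        } for p in self.pairs])


Selection = Callable[[Atom], bool]


def make_selection(chain: str | None = None,
                   resnum: int | Iterable[int] | None = None,
                   atoms: Iterable[str] | None = None) -> Selection:
    """Build an atom predicate from chain / residue-number / atom-name sets."""
    resnums = None if resnum is None else (
        {resnum} if isinstance(resnum, int) else set(resnum))
    names = None if atoms is None else {a.strip() for a in atoms}

    def predicate(atom: Atom) -> bool:
        if chain is not None and atom.chain != chain:
            return False
        if resnums is not None and atom.resnum not in resnums:
            return False
        if names is not None and atom.name not in names:
            return False
        return True

    return predicate


def parse_selection(spec: str) -> Selection:
    """Parse the CLI selection syntax ``chain[:resnum[:atom1,atom2]]``."""
    parts = spec.split(":")
    chain = parts[0] or None
    resnum = int(parts[1]) if len(parts) > 1 and parts[1] else None
    atoms = parts[2].split(",") if len(parts) > 2 and parts[2] else None
    return make_selection(chain, resnum, atoms)


def _classify_pairs(
    model: Sequence[Atom],
    selection_a: Selection,
    selection_b: Selection,
    vdw: VdwTable,
    contact_tol: float,
    overlap_thresh: float,
) -> list[ContactPair]:
    group_a = [a for a in model if selection_a(a)]
    group_b = [b for b in model if selection_b(b)]
    if not group_a or not group_b:
        raise ValueError("both selections must be non-empty")
    overlap_ids = {id(a) for a in group_a} & {id(b) for b in group_b}
    if overlap_ids:
        raise ValueError("selections must be disjoint")
    pairs = []
    for a in group_a:
        ra = vdw.radius(a)
        for b in group_b:
            d = float(np.linalg.norm(a.coords - b.coords))
            rsum = ra + vdw.radius(b)
            if d < rsum - overlap_thresh:
                cls = "clash"
            elif d <= rsum + contact_tol:
                cls = "contact"
            else:
                cls = "none"
            pairs.append(ContactPair(a, b, d, rsum, cls))
    return pairs


def vdw_contacts(
    model: Sequence[Atom],
    selection_a: Selection,
    selection_b: Selection,
    vdw: VdwTable | None = None,
    contact_tol: float = 0.5,
    overlap_thresh: float = 0.4,
) -> ContactReport:
    """All van der Waals contacts between two disjoint atom selections.

    A pair qualifies when its distance is at most the sum of radii plus
    ``contact_tol``; qualifying pairs that also interpenetrate beyond
    ``overlap_thresh`` are classified as clashes.
    """
    vdw = vdw or VdwTable()
    pairs = _classify_pairs(model, selection_a, selection_b, vdw,
                            contact_tol, overlap_thresh)
    return ContactReport([p for p in pairs if p.classification != "none"])


def detect_clashes(
    model: Sequence[Atom],
    selection_a: Selection,
    selection_b: Selection,
    vdw: VdwTable | None = None,
    overlap_thresh: float = 0.4,
) -> ContactReport:
    """Steric clashes only: pairs overlapping by more than ``overlap_thresh``."""
    vdw = vdw or VdwTable()
    pairs = _classify_pairs(model, selection_a, selection_b, vdw,
                            contact_tol=0.0, overlap_thresh=overlap_thresh)
    return ContactReport([p for p in pairs if p.classification == "clash"])


def contact_persistence(
    ensemble: StructureEnsemble,
    selection_a: Selection,
    selection_b: Selection,
    vdw: VdwTable | None = None,
    contact_tol: float = 0.5,
) -> float:
    """Fraction of ensemble models with >= 1 contact between two groups."""
    if not ensemble.shared_topology:
        raise ValueError("contact persistence requires shared topology")
    hits = 0
    for model in ensemble.models:
        report = vdw_contacts(model, selection_a, selection_b, vdw,
                              contact_tol=contact_tol)
        if report.n_contacts >= 1:
            hits += 1
    return hits / ensemble.n_models
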
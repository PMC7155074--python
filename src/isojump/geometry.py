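"""Backbone geometry of multi-stranded antiparallel beta-sheets.

Builds idealized flat sheets (or reads PDB-format backbones) and derives, for
every residue, the carbonyl position, the amide I transition-dipole direction,
the strand membership and whether the C=O points into the sheet or out toward
the solvent.  These per-residue "amide units" are the oscillator basis for the
exciton Hamiltonian in :mod:`isojump.exciton`.

Conventions
-----------
* Coordinates are in angstroms; residue indices are 1-based and match the
  peptide's own numbering (e.g. Leu4 is residue 4).
* Within a strand, consecutive carbonyls alternate direction; the per-strand
  alternation phase is chosen so that cross-strand neighbors carry opposite
  carbonyl directions, which reproduces the canonical pattern of an
  antiparallel sheet (outer-strand C=O groups alternately hydrogen bond across
  a strand or point to the solvent).
* The transition dipole is tilted a configurable angle (default 20 degrees)
  from the C=O bond toward the C-N bond of the peptide link, the common
  amide I convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import RangeError, StructureError

__all__ = [
    "AmideUnit",
    "GeometryParams",
    "LabelScheme",
    "PeptideStructure",
    "build_ideal_sheet",
    "classify_orientation",
    "read_backbone",
    "write_pdb",
]

#: Map one-letter codes (B = 2-aminoisobutyric acid) to PDB residue names.
THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "B": "AIB",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}


@dataclass
class AmideUnit:
    """One backbone C=O oscillator."""

    residue_index: int
    residue_name: str
    strand_id: int | str          # 1-based strand number, or "turn"
    c_pos: np.ndarray
    o_pos: np.ndarray
    n_next_pos: np.ndarray
    dipole_dir: np.ndarray
    orientation: str = "turn"     # "inward" | "outward" | "turn"
    labeled: bool = False

    def __post_init__(self) -> None:
        self.c_pos = np.asarray(self.c_pos, dtype=float)
        self.o_pos = np.asarray(self.o_pos, dtype=float)
        self.n_next_pos = np.asarray(self.n_next_pos, dtype=float)
        self.dipole_dir = np.asarray(self.dipole_dir, dtype=float)
        if np.allclose(self.c_pos, self.o_pos):
            raise StructureError(
                f"residue {self.residue_index}: C and O coincide"
            )
        n = np.linalg.norm(self.dipole_dir)
        if abs(n - 1.0) > 1e-9:
            self.dipole_dir = self.dipole_dir / n

    @property
    def co_vector(self) -> np.ndarray:
        return self.o_pos - self.c_pos


@dataclass(frozen=True)
class GeometryParams:
    """Idealized-sheet builder parameters (angstroms / degrees).

    ``rise`` is the per-residue translation along the strand, ``strand_spacing``
    the distance between adjacent strand axes, ``pleat_deg`` the out-of-plane
    C-alpha zigzag.  Carbonyl C and O atoms stay in the sheet plane.
    """

    rise: float = 3.47
    strand_spacing: float = 4.8
    pleat_deg: float = 25.0
    co_length: float = 1.23
    turn_clearance: float = 4.0

    def __post_init__(self) -> None:
        if min(self.rise, self.strand_spacing, self.co_length) <= 0:
            raise StructureError("geometry parameters must be positive")


@dataclass(frozen=True)
class LabelScheme:
    """A named set of 13C-labeled residue positions, e.g. 1W-4-13."""

    name: str
    labeled_positions: frozenset[int] = frozenset()

    @classmethod
    def from_positions(cls, positions=(), prefix: str = "1W") -> "LabelScheme":
        positions = frozenset(int(p) for p in positions)
        name = prefix + "".join(f"-{p}" for p in sorted(positions))
        return cls(name, positions)


@dataclass
class PeptideStructure:
    """Ordered amide units plus the cross-strand carbonyl pairing."""

    sequence: str
    units: list[AmideUnit]
    cross_strand_pairs: list[tuple[int, int]] = field(default_factory=list)
    # Full backbone N/CA records (residue -> xyz), kept for PDB round trips.
    n_positions: dict[int, np.ndarray] = field(default_factory=dict)
    ca_positions: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.units) != len(self.sequence):
            raise StructureError(
                f"{len(self.units)} amide units for a "
                f"{len(self.sequence)}-residue sequence"
            )

    def unit(self, residue_index: int) -> AmideUnit:
        for u in self.units:
            if u.residue_index == residue_index:
                return u
        raise RangeError(f"no residue {residue_index} in structure")

    @property
    def strand_ids(self) -> list[int]:
        return sorted({u.strand_id for u in self.units
                       if isinstance(u.strand_id, int)})

    def apply_labels(self, scheme: LabelScheme) -> "PeptideStructure":
        """Return a copy with ``labeled`` flags set from ``scheme``."""
        missing = scheme.labeled_positions - {u.residue_index for u in self.units}
        if missing:
            raise StructureError(
                f"label scheme {scheme.name}: residues {sorted(missing)} "
                "not present in structure"
            )
        units = [replace(u, labeled=u.residue_index in scheme.labeled_positions)
                 for u in self.units]
        return PeptideStructure(self.sequence, units,
                                list(self.cross_strand_pairs),
                                dict(self.n_positions), dict(self.ca_positions))


def _unit_vector(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise StructureError("zero-length vector")
    return v / n


def _dipole_direction(c_pos, o_pos, n_next_pos, tilt_deg: float) -> np.ndarray:
    """Tilt the C=O unit vector toward C->N(next) by ``tilt_deg``."""
    u_co = _unit_vector(o_pos - c_pos)
    u_cn = _unit_vector(n_next_pos - c_pos)
    w = u_cn - (u_cn @ u_co) * u_co
    wn = np.linalg.norm(w)
    if wn < 1e-9 or tilt_deg == 0.0:
        return u_co
    t = math.radians(tilt_deg)
    return math.cos(t) * u_co + math.sin(t) * (w / wn)


def _strand_of(residue: int, strand_layout) -> int | str:
    for s, (a, b) in enumerate(strand_layout, start=1):
        if a <= residue <= b:
            return s
    return "turn"


def build_ideal_sheet(sequence: str,
                      strand_layout,
                      geometry_params: GeometryParams | None = None,
                      tilt_deg: float = 20.0) -> PeptideStructure:
    """Build a flat, untwisted antiparallel sheet.

    Parameters
    ----------
    sequence
        One-letter residue codes (B = Aib).
    strand_layout
        Ordered, disjoint 1-based residue ranges, e.g.
        ``[(1, 7), (10, 15), (18, 23)]``; residues outside any range become
        turn units.
    geometry_params
        Rise, strand spacing, pleat; defaults are typical beta-strand values.
    tilt_deg
        Transition-dipole tilt from the C=O bond.
    """
    p = geometry_params or GeometryParams()
    nres = len(sequence)
    layout = [tuple(map(int, rng)) for rng in strand_layout]
    last = 0
    for a, b in layout:
        if a > b or a <= last:
            raise StructureError("strand_layout ranges must be ordered and disjoint")
        last = b
    if layout and layout[-1][1] > nres:
        raise StructureError(
            f"strand_layout extends to residue {layout[-1][1]} but the "
            f"sequence has only {nres} residues"
        )

    # --- C-alpha scaffold ---------------------------------------------------
    ca: dict[int, np.ndarray] = {}
    direction: dict[int, int] = {}      # strand direction (+1/-1 along x)
    pleat_dz = 0.5 * p.rise * math.tan(math.radians(p.pleat_deg) / 2.0)
    end_x = 0.0
    for s, (a, b) in enumerate(layout):
        d = 1 if s % 2 == 0 else -1
        n = b - a + 1
        start_x = end_x if s > 0 else 0.0
        for j, r in enumerate(range(a, b + 1)):
            x = start_x + d * j * p.rise
            ca[r] = np.array([x, s * p.strand_spacing, pleat_dz * (-1) ** j])
            direction[r] = d
        end_x = start_x + d * (n - 1) * p.rise

    # turns: arc between the flanking strand ends, bulging outward in x
    for s in range(len(layout) - 1):
        a_prev, b_prev = layout[s]
        a_next, _ = layout[s + 1]
        turn_res = list(range(b_prev + 1, a_next))
        if not turn_res:
            continue
        x_anchor = ca[b_prev][0]
        bulge = 1 if s % 2 == 0 else -1
        for i, r in enumerate(turn_res):
            t = (i + 1) / (len(turn_res) + 1)
            ca[r] = np.array([
                x_anchor + bulge * p.turn_clearance * math.sin(math.pi * t),
                (s + t) * p.strand_spacing,
                0.0,
            ])
            direction[r] = bulge
    if len(ca) != nres:
        raise StructureError("strand_layout leaves leading/trailing residues "
                             "unplaced; layout must start at residue 1")

    # chain tangent at each residue (next CA minus previous CA)
    def tangent(r: int) -> np.ndarray:
        lo, hi = max(1, r - 1), min(nres, r + 1)
        return _unit_vector(ca[hi] - ca[lo]) if hi > lo else np.array([1.0, 0, 0])

    # --- carbonyl alternation phases ----------------------------------------
    # Phase per strand chosen so nearest cross-strand CA neighbors carry
    # opposite carbonyl directions.
    phases = {1: 1}
    for s in range(2, len(layout) + 1):
        a, b = layout[s - 1]
        pa, pb = layout[s - 2]
        pairs = [(r, q) for r in range(a, b + 1) for q in range(pa, pb + 1)
                 if abs(ca[r][0] - ca[q][0]) < 1e-6]
        r, q = pairs[0] if pairs else (a, pa)
        sign_q = phases[s - 1] * (-1) ** (q - pa)
        phases[s] = -sign_q * (-1) ** (r - a)

    def co_sign(r: int) -> int:
        s = _strand_of(r, layout)
        if s == "turn":
            return 0
        a = layout[s - 1][0]
        return phases[s] * (-1) ** (r - a)

    # --- backbone atoms and units -------------------------------------------
    n_pos: dict[int, np.ndarray] = {}
    c_pos: dict[int, np.ndarray] = {}
    o_pos: dict[int, np.ndarray] = {}
    for r in range(1, nres + 1):
        s = _strand_of(r, layout)
        tang = (np.array([float(direction[r]), 0, 0]) if s != "turn"
                else tangent(r))
        base = np.array([ca[r][0], ca[r][1], 0.0])   # carbonyls in-plane
        n_pos[r] = base - 0.35 * p.rise * tang
        c_pos[r] = base + 0.50 * p.rise * tang
        sign = co_sign(r)
        if sign != 0:
            o_dir = np.array([0.0, float(sign), 0.0])
        else:   # turn carbonyls point radially outward in x
            o_dir = np.array([float(direction[r]), 0.0, 0.0])
        o_pos[r] = c_pos[r] + p.co_length * o_dir

    units = []
    for r in range(1, nres + 1):
        if r < nres:
            n_next = n_pos[r + 1]
        else:   # C-terminal amide nitrogen, extrapolated along the chain
            n_next = c_pos[r] + 1.32 * tangent(r)
        units.append(AmideUnit(
            residue_index=r,
            residue_name=THREE_LETTER.get(sequence[r - 1], "UNK"),
            strand_id=_strand_of(r, layout),
            c_pos=c_pos[r], o_pos=o_pos[r], n_next_pos=n_next,
            dipole_dir=_dipole_direction(c_pos[r], o_pos[r], n_next, tilt_deg),
        ))

    # --- cross-strand carbonyl pairing --------------------------------------
    pairs = []
    for i, ui in enumerate(units):
        for uj in units[i + 1:]:
            if not (isinstance(ui.strand_id, int) and isinstance(uj.strand_id, int)):
                continue
            if abs(ui.strand_id - uj.strand_id) != 1:
                continue
            if abs(np.linalg.norm(ui.c_pos - uj.c_pos) - p.strand_spacing) <= 0.2:
                pairs.append((ui.residue_index, uj.residue_index))

    structure = PeptideStructure(sequence, units, pairs, n_pos, ca)
    return classify_orientation(structure)


def classify_orientation(structure: PeptideStructure) -> PeptideStructure:
    """Assign inward/outward/turn orientation from the geometry.

    Edge-strand carbonyls are inward when the C=O vector points toward the
    sheet centroid (perpendicular to the strand axis), outward otherwise;
    central-strand carbonyls are inward by definition; turn units stay "turn".
    The classification is a pure function of the coordinates, hence idempotent.
    """
    strand_units: dict[int, list[AmideUnit]] = {}
    for u in structure.units:
        if isinstance(u.strand_id, int):
            strand_units.setdefault(u.strand_id, []).append(u)
    if not strand_units:
        return structure
    centroid = np.mean([u.c_pos for us in strand_units.values() for u in us],
                       axis=0)
    edge = {min(strand_units), max(strand_units)}
    for sid, us in strand_units.items():
        s_centroid = np.mean([u.c_pos for u in us], axis=0)
        axis = _unit_vector(us[-1].c_pos - us[0].c_pos) if len(us) > 1 \
            else np.array([1.0, 0, 0])
        interior = centroid - s_centroid
        interior = interior - (interior @ axis) * axis
        for u in us:
            if sid not in edge or len(strand_units) == 1:
                u.orientation = "inward"
                continue
            co = u.co_vector - (u.co_vector @ axis) * axis
            u.orientation = "inward" if co @ interior > 0 else "outward"
    for u in structure.units:
        if u.strand_id == "turn":
            u.orientation = "turn"
    return structure


# ---------------------------------------------------------------------------
# PDB input / output (Bio.PDB)
# ---------------------------------------------------------------------------

def write_pdb(structure: PeptideStructure, path) -> None:
    """Write backbone N/CA/C/O records (single MODEL) in PDB format."""
    from Bio.PDB import PDBIO, StructureBuilder

    sb = StructureBuilder.StructureBuilder()
    sb.init_structure("shet")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    for u in structure.units:
        r = u.residue_index
        sb.init_residue(u.residue_name, " ", r, " ")
        ca = structure.ca_positions.get(r)
        n = structure.n_positions.get(r)
        if ca is None:   # fall back to a point between N and C
            ca = 0.5 * (u.c_pos + (n if n is not None else u.c_pos - 1.5))
        if n is None:
            n = ca - 0.4 * (u.c_pos - ca)
        for name, pos in (("N", n), ("CA", ca), ("C", u.c_pos), ("O", u.o_pos)):
            sb.init_atom(name, np.asarray(pos, dtype=float), 0.0, 1.0, " ",
                         name, element=name[0])
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))


def read_backbone(path, model_index: int = 0,
                  strand_layout=None, tilt_deg: float = 20.0,
                  sequence: str | None = None) -> PeptideStructure:
    """Read one model of a PDB-format backbone into a :class:`PeptideStructure`.

    ``strand_layout`` assigns strand membership (same convention as the
    builder); without it every residue is classified as "turn".  When a residue
    has alternate locations the alphabetically first conformer is used.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    models = list(parser.get_structure("pdb", str(path)))
    if not -len(models) <= model_index < len(models):
        raise RangeError(
            f"model_index {model_index} out of range for a "
            f"{len(models)}-model file"
        )
    chain = next(iter(models[model_index]))

    def coord(residue, name):
        if name not in residue:
            raise StructureError(
                f"residue {residue.get_id()[1]} ({residue.get_resname()}) "
                f"is missing backbone atom {name}"
            )
        atom = residue[name]
        if atom.is_disordered():
            alt = sorted(a.get_altloc() for a in atom.disordered_get_list())[0]
            atom = atom.disordered_get(alt)
        return np.array(atom.get_coord(), dtype=float)

    residues = [res for res in chain if "CA" in res or res.get_id()[0] == " "]
    seq, n_pos, ca_pos, c_pos, o_pos, names = "", {}, {}, {}, {}, {}
    for i, res in enumerate(residues, start=1):
        names[i] = res.get_resname().strip()
        seq += ONE_LETTER.get(names[i], "X")
        n_pos[i] = coord(res, "N")
        ca_pos[i] = coord(res, "CA")
        c_pos[i] = coord(res, "C")
        o_pos[i] = coord(res, "O")
    nres = len(residues)
    if nres == 0:
        raise StructureError(f"no residues found in {path}")
    if sequence is not None:
        if len(sequence) != nres:
            raise StructureError("given sequence length does not match file")
        seq = sequence

    layout = [tuple(map(int, rng)) for rng in (strand_layout or [])]
    units = []
    for r in range(1, nres + 1):
        if r < nres:
            n_next = n_pos[r + 1]
        else:
            n_next = c_pos[r] + 1.32 * _unit_vector(c_pos[r] - ca_pos[r])
        units.append(AmideUnit(
            residue_index=r, residue_name=names[r],
            strand_id=_strand_of(r, layout) if layout else "turn",
            c_pos=c_pos[r], o_pos=o_pos[r], n_next_pos=n_next,
            dipole_dir=_dipole_direction(c_pos[r], o_pos[r], n_next, tilt_deg),
        ))
    structure = PeptideStructure(seq, units, [], n_pos, ca_pos)
    if layout:
        spacings = [np.linalg.norm(ui.c_pos - uj.c_pos)
                    for i, ui in enumerate(units) for uj in units[i + 1:]
                    if isinstance(ui.strand_id, int)
                    and isinstance(uj.strand_id, int)
                    and abs(ui.strand_id - uj.strand_id) == 1]
        if spacings:
            spacing = min(spacings)
            structure.cross_strand_pairs = [
                (ui.residue_index, uj.residue_index)
                for i, ui in enumerate(units) for uj in units[i + 1:]
                if isinstance(ui.strand_id, int)
                and isinstance(uj.strand_id, int)
                and abs(ui.strand_id - uj.strand_id) == 1
                and abs(np.linalg.norm(ui.c_pos - uj.c_pos) - spacing) <= 0.2
            ]
        structure = classify_orientation(structure)
    return structure
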
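"""Restraint generation for QDH structure calculation.

Four restraint classes drive the calculation, mirroring standard solution
NMR practice for nucleic acids:

* **NOE distance restraints** — flat-bottom windows assigned by cross-peak
  intensity class.  Non-exchangeable protons: strong 2.7 +/- 0.8 A, medium
  3.8 +/- 0.9 A, weak 5.5 +/- 1.7 A.  Exchangeable protons: 4.0 +/- 1.0,
  4.8 +/- 1.4 and 5.5 +/- 1.7 A.  Distances to thymine methyl protons are
  redirected to the methyl carbon with both bounds loosened by 0.5 A.
* **Hydrogen-bond restraints** — four distances per cyclic Hoogsteen G->G
  edge of a G-tetrad (H21-N7 2.0 +/- 0.2, N2-N7 2.9 +/- 0.3, H1-O6
  2.0 +/- 0.2, N1-O6 2.9 +/- 0.3 A) and six per Watson-Crick G.C pair
  (H21-O2, H1-N3, O6-H41 at 2.0 +/- 0.2; N2-O2, N1-N3, O6-N4 at
  2.9 +/- 0.3 A).  G.C.G.C-tetrad members are restrained as Watson-Crick
  pairs.
* **Chi dihedral restraints** — O4'-C1'-N9-C4 (purines) / O4'-C1'-N1-C2
  (pyrimidines), centered at 60 deg for syn and 240 deg for anti residues,
  halfwidth 70 deg (or 40 deg when tightened).
* **Planarity restraints** — one unit per G-tetrad, per G.C.G.C tetrad,
  and per Watson-Crick pair not already inside a G.C.G.C tetrad.

Which residues carry dihedral restraints is a modelling rule of this
package: every G/C residue that belongs to a tetrad or a Watson-Crick
pair, plus any residue explicitly marked syn in the topology (this covers
Form 1's syn 5'-terminal G1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .topology import QDHTopology, validate_topology

__all__ = [
    "AtomRef",
    "DistanceRestraint",
    "DihedralRestraint",
    "PlanarityRestraint",
    "RestraintSummary",
    "classify_noe",
    "hbond_restraints",
    "dihedral_restraints",
    "planarity_restraints",
    "restraint_summary",
    "read_peaks_tsv",
    "peaks_to_restraints",
    "restraints_to_tsv",
    "restraints_from_tsv",
    "restraints_to_xplor",
]

AtomRef = tuple[int, str]  # (1-based residue index, atom name)

# intensity class -> (target, minus, plus), Angstrom
NONEXCHANGEABLE_WINDOWS = {
    "strong": (2.7, 0.8, 0.8),
    "medium": (3.8, 0.9, 0.9),
    "weak": (5.5, 1.7, 1.7),
}
EXCHANGEABLE_WINDOWS = {
    "strong": (4.0, 1.0, 1.0),
    "medium": (4.8, 1.4, 1.4),
    "weak": (5.5, 1.7, 1.7),
}
METHYL_LOOSENING = 0.5  # Angstrom, applied to both bounds

# Hoogsteen G(donor)->G(acceptor) edge distances
HOOGSTEEN_DISTANCES = (
    ("H21", "N7", 2.0, 0.2),
    ("N2", "N7", 2.9, 0.3),
    ("H1", "O6", 2.0, 0.2),
    ("N1", "O6", 2.9, 0.3),
)
# Watson-Crick G.C distances, (G atom, C atom)
WATSON_CRICK_DISTANCES = (
    ("H21", "O2", 2.0, 0.2),
    ("H1", "N3", 2.0, 0.2),
    ("O6", "H41", 2.0, 0.2),
    ("N2", "O2", 2.9, 0.3),
    ("N1", "N3", 2.9, 0.3),
    ("O6", "N4", 2.9, 0.3),
)

CHI_CENTER = {"syn": 60.0, "anti": 240.0}
# chi atom quartet by base type
CHI_ATOMS = {
    "G": ("O4'", "C1'", "N9", "C4"),
    "A": ("O4'", "C1'", "N9", "C4"),
    "C": ("O4'", "C1'", "N1", "C2"),
    "T": ("O4'", "C1'", "N1", "C2"),
}

# ring heavy atoms used for planarity units
PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


@dataclass(frozen=True)
class DistanceRestraint:
    atom_a: AtomRef
    atom_b: AtomRef
    target: float
    minus: float
    plus: float
    class_label: str  # strong / medium / weak / hbond
    exchangeable: bool = False
    origin: str = "inter-residue"  # intra-residue / inter-residue / hydrogen-bond

    def __post_init__(self):
        if self.target - self.minus <= 0:
            raise ValueError(
                f"restraint {self.atom_a}-{self.atom_b}: lower bound "
                f"{self.target - self.minus:.2f} A must be positive"
            )
        if self.minus < 0 or self.plus < 0:
            raise ValueError("window half-widths must be non-negative")

    @property
    def lower(self) -> float:
        return self.target - self.minus

    @property
    def upper(self) -> float:
        return self.target + self.plus


@dataclass(frozen=True)
class DihedralRestraint:
    residue: int
    atoms: tuple[str, str, str, str]
    center: float  # degrees
    halfwidth: float  # degrees, 40 or 70

    def __post_init__(self):
        if self.halfwidth not in (40.0, 70.0):
            raise ValueError(f"halfwidth must be 40 or 70 deg, got {self.halfwidth}")
        if self.center not in (60.0, 240.0):
            raise ValueError(f"chi center must be 60 or 240 deg, got {self.center}")


@dataclass(frozen=True)
class PlanarityRestraint:
    label: str
    members: tuple[tuple[int, tuple[str, ...]], ...]  # (residue, ring atoms)

    def __post_init__(self):
        if len(self.members) not in (2, 4):
            raise ValueError("planarity unit must have 2 or 4 member residues")


@dataclass(frozen=True)
class RestraintSummary:
    intra_residue_d2o: int = 0
    inter_residue_d2o: int = 0
    inter_residue_h2o: int = 0
    hydrogen_bond: int = 0
    dihedral_angle: int = 0
    planarity: int = 0


def classify_noe(
    intensity_class: str,
    exchangeable: bool,
    involves_thymine_methyl: bool,
    atom_a: AtomRef,
    atom_b: AtomRef,
    origin: str | None = None,
) -> DistanceRestraint:
    """Turn one classed NOE cross-peak into a flat-bottom distance restraint.

    When the peak involves a thymine methyl, the proton selector on the
    methyl side (H71/H72/H73, or a pseudo-atom name containing "7") is
    replaced by the methyl carbon C7 and both bounds loosen by 0.5 A.
    """
    table = EXCHANGEABLE_WINDOWS if exchangeable else NONEXCHANGEABLE_WINDOWS
    try:
        target, minus, plus = table[intensity_class]
    except KeyError:
        raise ValueError(
            f"unknown NOE intensity class {intensity_class!r}; "
            "expected strong/medium/weak"
        ) from None
    if involves_thymine_methyl:
        atom_a, atom_b = (_to_methyl_carbon(a) for a in (atom_a, atom_b))
        minus += METHYL_LOOSENING
        plus += METHYL_LOOSENING
    if origin is None:
        origin = "intra-residue" if atom_a[0] == atom_b[0] else "inter-residue"
    return DistanceRestraint(
        atom_a, atom_b, target, minus, plus, intensity_class, exchangeable, origin
    )


def _to_methyl_carbon(atom: AtomRef) -> AtomRef:
    res, name = atom
    if name.upper() in ("H71", "H72", "H73", "M7", "Q7", "H7#", "H7"):
        return (res, "C7")
    return atom


def hbond_restraints(t: QDHTopology) -> list[DistanceRestraint]:
    """Hydrogen-bond distance restraints for every tetrad and pair.

    4 restraints per Hoogsteen edge x 4 edges per G-tetrad, 6 per
    Watson-Crick pair (G.C.G.C-tetrad member pairs included via
    ``t.pairs``, where they are listed as junction pairs).
    """
    out: list[DistanceRestraint] = []
    for tet in t.tetrads:
        if tet.kind != "G-tetrad":
            continue  # GCGC members are restrained through their WC pairs
        for m in tet.members:
            if t.base(m) != "G":
                raise ValueError(f"G-tetrad member {m} is {t.base(m)}, not G")
        for i in range(4):
            donor, acceptor = tet.members[i], tet.members[(i + 1) % 4]
            for a_name, b_name, target, width in HOOGSTEEN_DISTANCES:
                out.append(
                    DistanceRestraint(
                        (donor, a_name), (acceptor, b_name),
                        target, width, width, "hbond",
                        exchangeable=a_name.startswith("H"),
                        origin="hydrogen-bond",
                    )
                )
    for p in t.pairs:
        for g_name, c_name, target, width in WATSON_CRICK_DISTANCES:
            out.append(
                DistanceRestraint(
                    (p.g_index, g_name), (p.c_index, c_name),
                    target, width, width, "hbond",
                    exchangeable=g_name.startswith("H") or c_name.startswith("H"),
                    origin="hydrogen-bond",
                )
            )
    return out


def dihedral_restraints(
    t: QDHTopology,
    tight: bool = False,
    tight_residues: frozenset[int] | set[int] = frozenset(),
) -> list[DihedralRestraint]:
    """Chi restraints for tetrad/pair G and C residues plus syn-marked extras.

    ``tight`` switches every restraint to the +/-40 deg halfwidth;
    ``tight_residues`` tightens individual residues (the position-dependent
    choice is left to the user, defaulting to the loose +/-70 deg window).
    """
    restrained: set[int] = set()
    for tet in t.tetrads:
        restrained.update(tet.members)
    for p in t.pairs:
        restrained.update((p.g_index, p.c_index))
    restrained.update(t.syn_residues)

    out = []
    for idx in sorted(restrained):
        base = t.base(idx)
        if base not in ("G", "C"):
            raise ValueError(
                f"chi restraint target residue {idx} is {base}; only G/C "
                "residues are restrained"
            )
        state = t.residue(idx).glycosidic
        center = CHI_CENTER["syn" if state == "syn" else "anti"]
        halfwidth = 40.0 if (tight or idx in tight_residues) else 70.0
        out.append(DihedralRestraint(idx, CHI_ATOMS[base], center, halfwidth))
    return out


def planarity_restraints(t: QDHTopology) -> list[PlanarityRestraint]:
    """One planarity unit per tetrad and per stand-alone Watson-Crick pair."""
    out: list[PlanarityRestraint] = []
    gcgc_pairs = {
        frozenset((p.g_index, p.c_index)) for p in t.gcgc_member_pairs()
    }

    def ring(idx: int) -> tuple[int, tuple[str, ...]]:
        base = t.base(idx)
        return idx, (PURINE_RING if base in "GA" else PYRIMIDINE_RING)

    for tet in t.tetrads:
        label = ("G-tetrad " if tet.kind == "G-tetrad" else "GCGC-tetrad ") + (
            ".".join(str(m) for m in tet.members)
        )
        out.append(PlanarityRestraint(label, tuple(ring(m) for m in tet.members)))
    for p in t.pairs:
        if frozenset((p.g_index, p.c_index)) in gcgc_pairs:
            continue  # already planar inside the tetrad unit
        out.append(
            PlanarityRestraint(
                f"pair G{p.g_index}.C{p.c_index}",
                (ring(p.g_index), ring(p.c_index)),
            )
        )
    return out


def restraint_summary(
    noe: list[DistanceRestraint],
    hbond: list[DistanceRestraint],
    dihedral: list[DihedralRestraint],
    planarity: list[PlanarityRestraint],
) -> RestraintSummary:
    """Bookkeeping by category: NOEs split intra/inter-residue and by
    solvent (exchangeable-proton peaks are observed in H2O, the rest in
    D2O); hydrogen-bond, dihedral and planarity counted whole."""
    intra_d2o = sum(
        1 for r in noe if r.origin == "intra-residue" and not r.exchangeable
    )
    inter_d2o = sum(
        1 for r in noe if r.origin != "intra-residue" and not r.exchangeable
    )
    inter_h2o = sum(1 for r in noe if r.origin != "intra-residue" and r.exchangeable)
    return RestraintSummary(
        intra_residue_d2o=intra_d2o,
        inter_residue_d2o=inter_d2o,
        inter_residue_h2o=inter_h2o,
        hydrogen_bond=len(hbond),
        dihedral_angle=len(dihedral),
        planarity=len(planarity),
    )


# ---------------------------------------------------------------------------
# Tabular I/O.  Canonical dialect: TSV with a single header row.

PEAK_COLUMNS = (
    "residue_a", "atom_a", "residue_b", "atom_b", "class", "exchangeable", "methyl"
)


def read_peaks_tsv(path) -> list[dict]:
    """Read a classed NOE peak list (TSV, columns ``residue_a atom_a
    residue_b atom_b class exchangeable methyl``)."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PEAK_COLUMNS:
            raise ValueError(
                f"bad peak-list header {header!r}; expected {list(PEAK_COLUMNS)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(PEAK_COLUMNS):
                raise ValueError(f"line {lineno}: expected {len(PEAK_COLUMNS)} fields")
            rows.append(
                {
                    "residue_a": int(parts[0]),
                    "atom_a": parts[1],
                    "residue_b": int(parts[2]),
                    "atom_b": parts[3],
                    "class": parts[4],
                    "exchangeable": bool(int(parts[5])),
                    "methyl": bool(int(parts[6])),
                }
            )
    return rows


def peaks_to_restraints(rows: list[dict]) -> list[DistanceRestraint]:
    return [
        classify_noe(
            row["class"],
            row["exchangeable"],
            row["methyl"],
            (row["residue_a"], row["atom_a"]),
            (row["residue_b"], row["atom_b"]),
        )
        for row in rows
    ]


def restraints_to_tsv(restraints: list[DistanceRestraint]) -> str:
    lines = ["residue_a\tatom_a\tresidue_b\tatom_b\ttarget\tminus\tplus\tclass\texchangeable\torigin"]
    for r in restraints:
        lines.append(
            f"{r.atom_a[0]}\t{r.atom_a[1]}\t{r.atom_b[0]}\t{r.atom_b[1]}\t"
            f"{r.target:.2f}\t{r.minus:.2f}\t{r.plus:.2f}\t{r.class_label}\t"
            f"{int(r.exchangeable)}\t{r.origin}"
        )
    return "\n".join(lines) + "\n"


def restraints_from_tsv(text: str) -> list[DistanceRestraint]:
    lines = text.splitlines()
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        out.append(
            DistanceRestraint(
                (int(f[0]), f[1]), (int(f[2]), f[3]),
                float(f[4]), float(f[5]), float(f[6]),
                f[7], bool(int(f[8])), f[9],
            )
        )
    return out


def restraints_to_xplor(restraints: list[DistanceRestraint]) -> str:
    """XPLOR-style ``assign`` statements, for interoperability."""
    lines = []
    for r in restraints:
        lines.append(
            f"assign (residue {r.atom_a[0]} and name {r.atom_a[1]}) "
            f"(residue {r.atom_b[0]} and name {r.atom_b[1]}) "
            f"{r.target:.2f} {r.minus:.2f} {r.plus:.2f}"
        )
    return "\n".join(lines) + "\n"
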
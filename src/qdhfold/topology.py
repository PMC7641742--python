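"""Declarative models of quadruplex-duplex hybrid (QDH) folds.

A QDH combines a G-tetrad core with a Watson-Crick duplex stem.  The two
folds adopted by the stem-loop-containing quadruplex sequence of the human
*PIM1* gene are built in:

* **Form 1** — a three-tetrad (3+1) G-quadruplex on
  ``GCGGGAGGGCGCGCCAGCGGGGTCGGG`` with a propeller loop, a lateral loop and
  a three-base-pair hairpin stem stacked coaxially under the core.
* **Form 2** — a chair-type (antiparallel) two-tetrad G-quadruplex on
  ``GGGAGGGCGCGCCAGCGGGGTCGGGC`` whose junction G.C pairs align into a
  slipped G.C.G.C tetrad between core and stem.

Topologies are plain declarative data (residues, tetrads, pairs, loops,
grooves); they carry no coordinates.  ``validate_topology`` checks the
structural bookkeeping invariants, and ``imino_census`` predicts the
imino-proton peak counts (one slowly-exchanging guanine H1 per tetrad
guanine, one per Watson-Crick G.C pair) that identify each fold in a 1D
spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import yaml

__all__ = [
    "ResidueSpec",
    "TetradSpec",
    "BasePairSpec",
    "LoopSpec",
    "QDHTopology",
    "build_form1_topology",
    "build_form2_topology",
    "validate_topology",
    "imino_census",
    "topology_to_yaml",
    "topology_from_yaml",
]

FORM1_SEQUENCE = "GCGGGAGGGCGCGCCAGCGGGGTCGGG"
FORM2_SEQUENCE = "GGGAGGGCGCGCCAGCGGGGTCGGGC"


@dataclass(frozen=True)
class ResidueSpec:
    """One nucleotide of the construct.

    ``index`` is 1-based on the construct sequence (G1 ... G27 style naming);
    ``glycosidic`` records the chi rotamer class deduced from intra-residue
    H8-H1' NOE intensity (*syn* guanines give strong cross-peaks).
    """

    index: int
    base: str
    glycosidic: str = "unspecified"  # syn / anti / unspecified


@dataclass(frozen=True)
class TetradSpec:
    """A planar four-base unit.

    For a G-tetrad the member order is cyclic Hoogsteen donor -> acceptor
    (each guanine donates H1/H21 to the O6/N7 of the next member).  For a
    G.C.G.C tetrad the order is G,C,G,C with (members[0], members[1]) and
    (members[2], members[3]) the two Watson-Crick pairs; ``slipped`` marks
    the offset alignment geometry.
    """

    members: tuple[int, int, int, int]
    kind: str = "G-tetrad"  # G-tetrad / GCGC-tetrad
    hbond_direction: str = "unspecified"  # clockwise / anticlockwise / unspecified
    slipped: bool = False


@dataclass(frozen=True)
class BasePairSpec:
    """A Watson-Crick G.C pair; ``role`` is ``stem`` or ``junction``."""

    g_index: int
    c_index: int
    role: str = "stem"


@dataclass(frozen=True)
class LoopSpec:
    """A loop segment: ``kind`` in {propeller, lateral, stem-loop}."""

    kind: str
    start: int
    end: int

    @property
    def residues(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class QDHTopology:
    name: str
    sequence: str
    residues: tuple[ResidueSpec, ...]
    tetrads: tuple[TetradSpec, ...] = ()
    pairs: tuple[BasePairSpec, ...] = ()
    loops: tuple[LoopSpec, ...] = ()
    grooves: tuple[str, ...] = ()

    def residue(self, index: int) -> ResidueSpec:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"no residue with index {index}")

    def base(self, index: int) -> str:
        return self.sequence[index - 1]

    @property
    def syn_residues(self) -> frozenset[int]:
        return frozenset(r.index for r in self.residues if r.glycosidic == "syn")

    @property
    def g_tetrads(self) -> tuple[TetradSpec, ...]:
        return tuple(t for t in self.tetrads if t.kind == "G-tetrad")

    @property
    def gcgc_tetrads(self) -> tuple[TetradSpec, ...]:
        return tuple(t for t in self.tetrads if t.kind == "GCGC-tetrad")

    def gcgc_member_pairs(self) -> tuple[BasePairSpec, ...]:
        """The Watson-Crick pairs that live inside a G.C.G.C tetrad."""
        inside = set()
        for t in self.gcgc_tetrads:
            g1, c1, g2, c2 = t.members
            inside.add(frozenset((g1, c1)))
            inside.add(frozenset((g2, c2)))
        return tuple(
            p for p in self.pairs if frozenset((p.g_index, p.c_index)) in inside
        )


def _residues(sequence: str, syn: Iterable[int]) -> tuple[ResidueSpec, ...]:
    syn = set(syn)
    return tuple(
        ResidueSpec(i, b, "syn" if i in syn else "anti")
        for i, b in enumerate(sequence, start=1)
    )


def build_form1_topology() -> QDHTopology:
    """The Form 1 (3+1) quadruplex-duplex hybrid of *PIM1-SLQS07*.

    Three stacked G-tetrads (G3.G25.G22.G7, G4.G8.G21.G26, G5.G9.G20.G27,
    hydrogen-bond directionality anticlockwise/clockwise/clockwise), three
    stem pairs G19.C10, G11.C18, G17.C12 capped by the hairpin loop
    G13-C14-C15-A16, a single-residue propeller loop A6, a lateral loop
    T23-C24, and a syn set {G1, G3, G7, G20, G21, G25} (the 5'-terminal G1
    is syn although it joins no tetrad).
    """
    return QDHTopology(
        name="PIM1-SLQS07 Form 1",
        sequence=FORM1_SEQUENCE,
        residues=_residues(FORM1_SEQUENCE, syn={1, 3, 7, 20, 21, 25}),
        tetrads=(
            TetradSpec((3, 25, 22, 7), "G-tetrad", "anticlockwise"),
            TetradSpec((4, 8, 21, 26), "G-tetrad", "clockwise"),
            TetradSpec((5, 9, 20, 27), "G-tetrad", "clockwise"),
        ),
        pairs=(
            BasePairSpec(19, 10, "junction"),
            BasePairSpec(11, 18, "stem"),
            BasePairSpec(17, 12, "stem"),
        ),
        loops=(
            LoopSpec("propeller", 6, 6),
            LoopSpec("lateral", 23, 24),
            LoopSpec("stem-loop", 13, 16),
        ),
        grooves=("wide", "medium", "medium", "narrow"),
    )


def build_form2_topology() -> QDHTopology:
    """The Form 2 chair-type quadruplex-duplex hybrid of *PIM1-SLQS02*.

    Two antiparallel G-tetrads (G2.G7.G18.G25, G3.G24.G19.G6) stacked on a
    slipped G.C.G.C tetrad built from the junction pairs G1.C26 and G17.C8;
    the stem continues with G9.C16 and G15.C10 under the hairpin loop
    G11-C12-C13-A14, with lateral loops A4-G5 and G20-T21-C22-G23.
    """
    return QDHTopology(
        name="PIM1-SLQS02 Form 2",
        sequence=FORM2_SEQUENCE,
        residues=_residues(FORM2_SEQUENCE, syn={2, 6, 18, 24}),
        tetrads=(
            TetradSpec((2, 7, 18, 25), "G-tetrad"),
            TetradSpec((3, 24, 19, 6), "G-tetrad"),
            TetradSpec((1, 26, 17, 8), "GCGC-tetrad", slipped=True),
        ),
        pairs=(
            BasePairSpec(1, 26, "junction"),
            BasePairSpec(17, 8, "junction"),
            BasePairSpec(9, 16, "stem"),
            BasePairSpec(15, 10, "stem"),
        ),
        loops=(
            LoopSpec("lateral", 4, 5),
            LoopSpec("stem-loop", 11, 14),
            LoopSpec("lateral", 20, 23),
        ),
        grooves=("wide", "narrow", "wide", "narrow"),
    )


def validate_topology(t: QDHTopology) -> list[str]:
    """Check the structural bookkeeping invariants; return one message per
    violation (empty list when the topology is internally consistent)."""
    msgs: list[str] = []
    n = len(t.sequence)

    seen: set[int] = set()
    for r in t.residues:
        if r.index in seen:
            msgs.append(f"duplicate residue index {r.index}")
        seen.add(r.index)
        if not 1 <= r.index <= n:
            msgs.append(f"residue index {r.index} outside 1..{n}")
        elif r.base != t.sequence[r.index - 1]:
            msgs.append(
                f"residue {r.index} declared {r.base} but sequence has "
                f"{t.sequence[r.index - 1]}"
            )
        if r.glycosidic not in ("syn", "anti", "unspecified"):
            msgs.append(f"residue {r.index} has unknown glycosidic state {r.glycosidic!r}")

    tetrad_members: set[int] = set()
    for t_i, tet in enumerate(t.tetrads):
        for m in tet.members:
            if not 1 <= m <= n:
                msgs.append(f"tetrad {t_i} member {m} outside 1..{n}")
                continue
            if m in tetrad_members:
                msgs.append(f"residue {m} belongs to more than one tetrad")
            tetrad_members.add(m)
        inside = [m for m in tet.members if 1 <= m <= n]
        bases = "".join(t.sequence[m - 1] for m in inside)
        if tet.kind == "G-tetrad":
            if bases != "G" * len(inside):
                bad = [m for m in inside if t.sequence[m - 1] != "G"]
                msgs.append(f"G-tetrad {t_i} has non-G member(s) {bad}")
        elif tet.kind == "GCGC-tetrad":
            if len(inside) == 4 and bases != "GCGC":
                msgs.append(f"GCGC-tetrad {t_i} members are {bases}, expected GCGC order")
        else:
            msgs.append(f"tetrad {t_i} has unknown kind {tet.kind!r}")

    gcgc_members = {m for tet in t.gcgc_tetrads for m in tet.members}
    pair_keys: set[frozenset[int]] = set()
    for p in t.pairs:
        for idx, want in ((p.g_index, "G"), (p.c_index, "C")):
            if not 1 <= idx <= n:
                msgs.append(f"pair {p.g_index}.{p.c_index} index {idx} outside 1..{n}")
            elif t.sequence[idx - 1] != want:
                msgs.append(
                    f"pair {p.g_index}.{p.c_index}: residue {idx} is "
                    f"{t.sequence[idx - 1]}, expected {want}"
                )
        key = frozenset((p.g_index, p.c_index))
        if key in pair_keys:
            msgs.append(f"duplicate pair {p.g_index}.{p.c_index}")
        pair_keys.add(key)
        # overlap with a tetrad is only legitimate for GCGC-tetrad members
        for idx in (p.g_index, p.c_index):
            if idx in tetrad_members and idx not in gcgc_members:
                msgs.append(
                    f"residue {idx} is both a tetrad member and a stem-pair member"
                )

    for lp in t.loops:
        if lp.kind not in ("propeller", "lateral", "stem-loop"):
            msgs.append(f"loop {lp.start}-{lp.end} has unknown kind {lp.kind!r}")
        if not (1 <= lp.start <= lp.end <= n):
            msgs.append(f"loop range {lp.start}-{lp.end} outside 1..{n}")

    for g in t.grooves:
        if g not in ("wide", "medium", "narrow"):
            msgs.append(f"unknown groove label {g!r}")

    return msgs


def imino_census(t: QDHTopology) -> tuple[int, int]:
    """Predicted imino-proton peak counts ``(n_tetrad_G, n_watson_crick)``.

    Each guanine in a G-tetrad contributes one Hoogsteen-protected imino
    (10.8-12 ppm region); each Watson-Crick G.C pair contributes one
    (12.7-14 ppm region).  Guanines of a G.C.G.C tetrad are hydrogen-bonded
    to their cytosines, so they land in the Watson-Crick tally.
    """
    problems = validate_topology(t)
    if problems:
        raise ValueError("invalid topology: " + "; ".join(problems))
    n_tetrad = sum(4 for tet in t.tetrads if tet.kind == "G-tetrad")
    return n_tetrad, len(t.pairs)


# ---------------------------------------------------------------------------
# On-disk schema (YAML, one document per fold)

def topology_to_yaml(t: QDHTopology) -> str:
    doc = {
        "name": t.name,
        "sequence": t.sequence,
        "syn": sorted(t.syn_residues),
        "tetrads": [
            {
                "members": list(tet.members),
                "kind": tet.kind,
                "hbond_direction": tet.hbond_direction,
                "slipped": tet.slipped,
            }
            for tet in t.tetrads
        ],
        "pairs": [
            {"g": p.g_index, "c": p.c_index, "role": p.role} for p in t.pairs
        ],
        "loops": [
            {"kind": lp.kind, "start": lp.start, "end": lp.end} for lp in t.loops
        ],
        "grooves": list(t.grooves),
    }
    return yaml.safe_dump(doc, sort_keys=False)


def topology_from_yaml(text: str) -> QDHTopology:
    doc = yaml.safe_load(text)
    seq = doc["sequence"]
    return QDHTopology(
        name=doc.get("name", "unnamed"),
        sequence=seq,
        residues=_residues(seq, doc.get("syn", [])),
        tetrads=tuple(
            TetradSpec(
                tuple(d["members"]),
                d.get("kind", "G-tetrad"),
                d.get("hbond_direction", "unspecified"),
                bool(d.get("slipped", False)),
            )
            for d in doc.get("tetrads", [])
        ),
        pairs=tuple(
            BasePairSpec(d["g"], d["c"], d.get("role", "stem"))
            for d in doc.get("pairs", [])
        ),
        loops=tuple(
            LoopSpec(d["kind"], d["start"], d["end"]) for d in doc.get("loops", [])
        ),
        grooves=tuple(doc.get("grooves", [])),
    )


def load_topology(path) -> QDHTopology:
    with open(path) as fh:
        return topology_from_yaml(fh.read())


def save_topology(t: QDHTopology, path) -> None:
    with open(path, "w") as fh:
        fh.write(topology_to_yaml(t))
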
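"""PDB and configuration I/O.

Conformers are written as standard ATOM records (chain A, 1-based residue
numbering, wwPDB DA/DC/DG/DT residue names, element column, TER record);
ensembles as multi-MODEL files.  The reader is deliberately strict and
reports the offending line number on malformed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .chem import Conformer, Ensemble

__all__ = ["read_pdb", "write_pdb", "RunConfig", "PDBFormatError"]

_ELEMENT_FROM_NAME = {"H": "H", "C": "C", "N": "N", "O": "O", "P": "P"}


class PDBFormatError(ValueError):
    pass


def _format_atom(serial: int, name: str, resname: str, resseq: int,
                 xyz: np.ndarray, element: str) -> str:
    # columns per the PDB v3 fixed-width ATOM record
    if len(name) < 4 and not name[0].isdigit():
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (
        f"ATOM  {serial:>5d} {name_field} {resname:>3s} A{resseq:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def write_pdb(obj: Conformer | Ensemble, path) -> None:
    """Write a conformer (single model) or ensemble (multi-MODEL) PDB file."""
    conformers = obj.conformers if isinstance(obj, Ensemble) else [obj]
    multi = len(conformers) > 1
    with open(path, "w") as fh:
        for model_i, conf in enumerate(conformers, start=1):
            if multi:
                fh.write(f"MODEL     {model_i:>4d}\n")
            serial = 0
            for i in range(conf.n_atoms):
                serial += 1
                fh.write(
                    _format_atom(
                        serial, str(conf.atom_name[i]), str(conf.res_name[i]),
                        int(conf.res_index[i]), conf.coord[i], str(conf.element[i]),
                    )
                    + "\n"
                )
            fh.write(f"TER   {serial + 1:>5d}      {conf.res_name[-1]:>3s} "
                     f"A{int(conf.res_index[-1]):>4d}\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def _parse_atom_line(line: str, lineno: int):
    if len(line.rstrip("\n")) < 54:
        raise PDBFormatError(
            f"line {lineno}: truncated ATOM record "
            f"({len(line.rstrip())} chars, need at least 54)"
        )
    try:
        name = line[12:16].strip()
        resname = line[17:20].strip()
        resseq = int(line[22:26])
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
    except ValueError as err:
        raise PDBFormatError(f"line {lineno}: malformed ATOM record ({err})") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _ELEMENT_FROM_NAME.get(name.lstrip("0123456789")[:1], "C")
    return name, resname, resseq, xyz, element.capitalize()


def _conformer_from_rows(rows) -> Conformer:
    return Conformer(
        np.array([r[2] for r in rows], int),
        np.array([r[1] for r in rows], dtype=object),
        np.array([r[0] for r in rows], dtype=object),
        np.array([r[4] for r in rows], dtype=object),
        np.array([r[3] for r in rows], float),
    )


def read_pdb(path) -> Conformer | Ensemble:
    """Read a PDB file; returns a Conformer for single-model files and an
    Ensemble for multi-MODEL files.  Raises PDBFormatError naming the
    line on malformed records."""
    models: list[list] = []
    current: list = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if current:
                    models.append(current)
                current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
            elif rec in ("ATOM", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
            elif rec in ("TER", "END", "REMARK", "HEADER", "TITLE", "CRYST1", ""):
                continue
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBFormatError("no ATOM records found")
    conformers = [_conformer_from_rows(m) for m in models]
    if len(conformers) > 1:
        n0 = conformers[0].n_atoms
        for k, c in enumerate(conformers[1:], start=2):
            if c.n_atoms != n0:
                raise PDBFormatError(
                    f"model {k} has {c.n_atoms} atoms, expected {n0}"
                )
        return Ensemble(conformers)
    return conformers[0]


@dataclass
class RunConfig:
    """Run configuration for the folding pipeline (YAML-serialisable)."""

    topology_path: str = ""
    peaks_path: str = ""
    out_path: str = "ensemble.pdb"
    n_structures: int = 100
    n_select: int = 10
    seed: int = 0
    scale_factor: float = 1.0
    schedule_overrides: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self):
        if self.n_select > self.n_structures:
            raise ValueError("n_select cannot exceed n_structures")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.__dict__, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**(yaml.safe_load(text) or {}))
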
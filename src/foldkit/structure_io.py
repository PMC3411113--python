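"""Reading and writing protein structures in PDB format.

The unit consumed by every analysis in this package is the
:class:`StructureModel` — an ordered list of atoms with names, residue
numbers, chain identifiers and Cartesian coordinates in Ångström.  A
multi-model PDB file (e.g. a trajectory snapshot series or a conformer
ensemble) becomes an :class:`Ensemble` of such models sharing one residue
numbering.  Parsing and serialisation are delegated to :mod:`gemmi`, which
implements the fixed-column PDB conventions; this module adds the domain
types, a line-numbered validation pass, the single-conformer altLoc policy
and CA-trace extraction.

Conventions
-----------
* altLoc: records with blank or ``'A'`` alternate-location indicators are
  kept, all others dropped (standard single-conformer convention).
* HETATM records and waters are excluded — analyses here concern the
  polypeptide only.
* Author residue numbering (1-based, possibly with insertion codes) is
  preserved; insertion codes are treated as distinct residues in file
  order.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger("foldkit")

__all__ = [
    "Atom",
    "StructureModel",
    "Ensemble",
    "CATrace",
    "ResidueView",
    "PDBFormatError",
    "PDBParseError",
    "ChainNotFoundError",
    "read_pdb",
    "read_pdb_text",
    "write_pdb",
    "write_pdb_text",
    "extract_ca_trace",
    "group_residues",
]

BACKBONE_ATOMS = ("N", "CA", "C")


class PDBFormatError(ValueError):
    """The input is not usable PDB text (e.g. contains no ATOM records)."""


class PDBParseError(ValueError):
    """A record could not be parsed; the message names the line number."""


class ChainNotFoundError(KeyError):
    """The requested chain identifier does not occur in the model."""


@dataclass
class Atom:
    """One atom site: name, element, residue context and position (Å)."""

    name: str
    element: str
    res_index: int
    res_name: str
    chain_id: str
    coord: np.ndarray
    alt_loc: str = ""
    icode: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")


@dataclass
class StructureModel:
    """An ordered collection of atoms forming one conformer."""

    atoms: list[Atom]
    model_id: int = 1

    def chain_ids(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: list[str] = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def n_residues(self, chain_id: str | None = None) -> int:
        return len(group_residues(self, chain_id))

    def copy(self) -> "StructureModel":
        return StructureModel(
            [
                Atom(a.name, a.element, a.res_index, a.res_name, a.chain_id,
                     a.coord.copy(), a.alt_loc, a.icode)
                for a in self.atoms
            ],
            self.model_id,
        )

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (a copy)."""
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class Ensemble:
    """Ordered models sharing one residue numbering (e.g. a trajectory)."""

    models: list[StructureModel]

    def __post_init__(self) -> None:
        if not self.models:
            raise PDBFormatError("ensemble must contain at least one model")
        counts = {m.n_residues() for m in self.models}
        if len(counts) > 1:
            raise PDBFormatError(
                f"models disagree on residue count: {sorted(counts)}"
            )

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, i: int) -> StructureModel:
        return self.models[i]

    def __iter__(self):
        return iter(self.models)


@dataclass
class CATrace:
    """Ordered alpha-carbon coordinates of one chain (Å)."""

    coords: np.ndarray
    res_indices: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.res_indices = np.asarray(self.res_indices, dtype=int)
        if len(self.res_indices) != len(self.coords):
            raise ValueError("coords and res_indices must have equal length")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class ResidueView:
    """All atoms of one residue, keyed by atom name."""

    chain_id: str
    res_index: int
    icode: str
    res_name: str
    atoms: dict[str, Atom] = field(default_factory=dict)

    def has(self, *names: str) -> bool:
        return all(n in self.atoms for n in names)

    def coord(self, name: str) -> np.ndarray:
        return self.atoms[name].coord


def group_residues(model: StructureModel, chain_id: str | None = None) -> list[ResidueView]:
    """Group a model's atoms into residues, preserving file order.

    Residues are keyed by (chain, residue number, insertion code); an
    insertion-coded residue counts as distinct from its un-coded
    neighbour.  If *chain_id* is None the first chain in file order is
    used.
    """
    if chain_id is None:
        ids = model.chain_ids()
        if not ids:
            return []
        chain_id = ids[0]
    out: list[ResidueView] = []
    key = None
    for a in model.atoms:
        if a.chain_id != chain_id:
            continue
        k = (a.res_index, a.icode)
        if k != key:
            out.append(ResidueView(chain_id, a.res_index, a.icode, a.res_name))
            key = k
        out[-1].atoms.setdefault(a.name, a)
    if not out and chain_id not in model.chain_ids():
        raise ChainNotFoundError(f"chain {chain_id!r} not present in model")
    return out


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _validate_lines(text: str) -> None:
    n_atom = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            if rec == "ATOM":
                n_atom += 1
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fieldtxt = line[lo:hi].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: malformed {what} coordinate field {fieldtxt!r}"
                    ) from None
    if n_atom == 0:
        raise PDBFormatError("no ATOM records found in input")


_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def _convert_model(gm: gemmi.Model) -> StructureModel:
    atoms: list[Atom] = []
    for chain in gm:
        for res in chain:
            if res.het_flag == "H" or res.name in _WATER_NAMES:
                continue
            for at in res:
                if at.altloc not in ("\0", "", "A"):
                    continue
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name,
                        res_index=res.seqid.num,
                        res_name=res.name,
                        chain_id=chain.name,
                        coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        alt_loc="" if at.altloc == "\0" else at.altloc,
                        icode="" if res.seqid.icode in (" ", "\0") else res.seqid.icode,
                    )
                )
    return StructureModel(atoms, model_id=int(gm.num))


def read_pdb_text(text: str) -> Ensemble:
    """Parse PDB-format text into an :class:`Ensemble` (one model per
    MODEL block; a single model if the file has none)."""
    _validate_lines(text)
    st = gemmi.read_pdb_string(text)
    models = [_convert_model(gm) for gm in st]
    models = [m for m in models if m.atoms]
    if not models:
        raise PDBFormatError("no polymer atoms after filtering HETATM/waters")
    return Ensemble(models)


def read_pdb(source) -> Ensemble:
    """Read a PDB file from a path or an open text stream."""
    if hasattr(source, "read"):
        return read_pdb_text(source.read())
    return read_pdb_text(open(os.fspath(source)).read())


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _to_gemmi(ensemble: Ensemble) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "foldkit"
    for model in ensemble.models:
        gm = gemmi.Model(int(model.model_id))
        chain = None
        res = None
        res_key = None
        for a in model.atoms:
            if chain is None or chain.name != a.chain_id:
                gm.add_chain(gemmi.Chain(a.chain_id))
                chain = gm[len(gm) - 1]
                res_key = None
            k = (a.res_index, a.icode)
            if k != res_key:
                r = gemmi.Residue()
                r.name = a.res_name
                r.seqid = gemmi.SeqId(a.res_index, a.icode or " ")
                chain.add_residue(r)
                res = chain[len(chain) - 1]
                res_key = k
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element or a.name[:1])
            ga.pos = gemmi.Position(*a.coord)
            ga.altloc = a.alt_loc or "\0"
            ga.occ = 1.0
            ga.b_iso = 0.0
            res.add_atom(ga)
        st.add_model(gm)
    st.setup_entities()
    return st


def write_pdb_text(ensemble: Ensemble | StructureModel) -> str:
    """Serialise to PDB text (MODEL/ENDMDL blocks when more than one
    model); coordinates at the format's fixed 3-decimal precision."""
    if isinstance(ensemble, StructureModel):
        ensemble = Ensemble([ensemble])
    return _to_gemmi(ensemble).make_pdb_string()


def write_pdb(ensemble: Ensemble | StructureModel, sink) -> None:
    """Write PDB text to a path or an open text stream."""
    text = write_pdb_text(ensemble)
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        try:
            with open(os.fspath(sink), "w") as fh:
                fh.write(text)
        except OSError as exc:
            raise IOError(f"cannot write PDB to {sink}: {exc}") from exc


# ---------------------------------------------------------------------------
# CA trace
# ---------------------------------------------------------------------------

def extract_ca_trace(model: StructureModel, chain_id: str | None = None) -> CATrace:
    """Extract the ordered CA trace of one chain.

    Residues lacking a CA atom are skipped with a warning; order follows
    the chain order in the file.
    """
    residues = group_residues(model, chain_id)
    if not residues:
        raise ChainNotFoundError(f"chain {chain_id!r} not present in model")
    coords = []
    indices = []
    for r in residues:
        if "CA" in r.atoms:
            coords.append(r.coord("CA"))
            indices.append(r.res_index)
        else:
            logger.warning(
                "residue %s%d%s has no CA atom; skipped in trace",
                r.res_name, r.res_index, r.icode,
            )
    return CATrace(np.array(coords, dtype=float).reshape(-1, 3), np.array(indices, dtype=int))


def model_from_arrays(
    coords: np.ndarray,
    atom_names: Sequence[str],
    res_indices: Sequence[int],
    res_names: Sequence[str],
    elements: Sequence[str] | None = None,
    chain_id: str = "A",
    model_id: int = 1,
) -> StructureModel:
    """Assemble a StructureModel from parallel per-atom arrays."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if elements is None:
        elements = [n[:1] for n in atom_names]
    atoms = [
        Atom(str(nm), str(el), int(ri), str(rn), chain_id, c)
        for nm, el, ri, rn, c in zip(atom_names, elements, res_indices, res_names, coords)
    ]
    return StructureModel(atoms, model_id=model_id)


def ca_model(trace: CATrace, res_name: str = "ALA", chain_id: str = "A",
             model_id: int = 1) -> StructureModel:
    """Wrap a CA trace as a CA-only StructureModel (bead representation)."""
    n = len(trace)
    return model_from_arrays(
        trace.coords, ["CA"] * n, trace.res_indices, [res_name] * n,
        ["C"] * n, chain_id, model_id,
    )
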
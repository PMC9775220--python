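"""Structural model and SAXS-profile I/O.

Domain containers (:class:`Atom`, :class:`Residue`, :class:`Conformer`,
:class:`ConformerEnsemble`) use author residue numbering as the canonical
addressing scheme, because that is how residues are referred to throughout
the structural literature on this enzyme family (e.g. "residue 449",
"segment 327-355").  Coordinates are Å throughout; momentum transfer *s*
is stored in inverse-Å with an explicit unit flag at read time, since
synchrotron deposits frequently use inverse-nm and silent unit mix-ups
are the dominant failure mode when scoring theoretical curves.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Conformer",
    "ConformerEnsemble",
    "PDBParseError",
    "TopologyError",
    "SelectionError",
    "ProfileFormatError",
    "read_pdb_models",
    "write_pdb_models",
    "read_saxs_profile",
    "write_saxs_profile",
    "select_subset",
]


class PDBParseError(ValueError):
    """Malformed coordinate record; message names the offending line."""


class TopologyError(ValueError):
    """Models of one ensemble do not share a residue topology."""


class SelectionError(KeyError):
    """An atom/residue selection matched nothing."""


class ProfileFormatError(ValueError):
    """A scattering-profile text file is not 3-column (s, I, sigma)."""


@dataclass
class Atom:
    """A single atom: name, element, position (Å), occupancy, isotropic ADP (Å²)."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    adp: float = 0.0
    het: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element")


@dataclass
class Residue:
    """A residue addressed by (chain, author number, insertion code)."""

    chain: str
    number: int
    name: str
    atoms: list[Atom]
    icode: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.key}: no atoms")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)

    @property
    def identity(self) -> tuple[str, int, str, str]:
        """Addressing key plus residue name; the unit of topology comparison."""
        return (self.chain, self.number, self.icode, self.name)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise SelectionError(f"residue {self.key} has no atom {name!r}")

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


@dataclass
class Conformer:
    """One structural model: an ordered list of residues."""

    model_id: int
    residues: list[Residue]

    def __post_init__(self) -> None:
        if self.model_id < 1:
            raise ValueError("model_id must be >= 1")

    @property
    def identity_sequence(self) -> tuple[tuple[str, int, str, str], ...]:
        return tuple(r.identity for r in self.residues)

    def atoms(self) -> Iterable[Atom]:
        for r in self.residues:
            yield from r.atoms

    def coords(self) -> np.ndarray:
        """All atom positions, residue order then atom order, as (N, 3)."""
        return np.array([a.position for a in self.atoms()])

    def residue(self, chain: str, number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.key == (chain, number, icode):
                return r
        raise SelectionError(f"no residue {(chain, number, icode)} in model {self.model_id}")


@dataclass
class ConformerEnsemble:
    """An ordered pool of conformers sharing one residue topology."""

    conformers: list[Conformer]
    topology_hash: str = field(default="")

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("ensemble must contain at least one conformer")
        ref = self.conformers[0].identity_sequence
        for c in self.conformers[1:]:
            if c.identity_sequence != ref:
                raise TopologyError(
                    f"model {c.model_id} residue topology differs from model "
                    f"{self.conformers[0].model_id}"
                )
        if not self.topology_hash:
            self.topology_hash = _topology_hash(ref)

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def __getitem__(self, i: int) -> Conformer:
        return self.conformers[i]


def _topology_hash(identity_sequence) -> str:
    text = ";".join("|".join(map(str, t)) for t in identity_sequence)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:2].upper() in {"FE", "CU", "ZN", "MG", "MN", "NA", "CL", "BR", "CA"} and len(name) >= 2:
        return name[:2].capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_atom_line(line: str, lineno: int) -> tuple[str, str, int, str, str, Atom]:
    """Parse one ATOM/HETATM fixed-column record.

    Returns (altloc, chain, resnum, icode, resname, Atom).
    """
    try:
        name = line[12:16].strip()
        altloc = line[16:17].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip()
        resnum = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        b_field = line[60:66].strip()
        bfac = float(b_field) if b_field else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    if not element:
        element = _guess_element(name)
    # B-factor column carries the isotropic displacement parameter.
    atom = Atom(
        name=name,
        element=element,
        position=np.array([x, y, z]),
        occupancy=min(max(occupancy, 0.0), 1.0),
        adp=bfac,
        het=line.startswith("HETATM"),
    )
    return altloc, chain, resnum, icode, resname, atom


def _resolve_altlocs(records: list[tuple[str, Atom]]) -> list[Atom]:
    """Keep the highest-occupancy altloc per atom name; ties by altloc letter."""
    by_name: dict[str, list[tuple[str, Atom]]] = {}
    order: list[str] = []
    for altloc, atom in records:
        if atom.name not in by_name:
            order.append(atom.name)
        by_name.setdefault(atom.name, []).append((altloc, atom))
    out = []
    for name in order:
        cands = by_name[name]
        cands.sort(key=lambda t: (-t[1].occupancy, t[0]))
        out.append(cands[0][1])
    return out


def read_pdb_models(path: str | Path, keep_hetatm: bool = True) -> ConformerEnsemble:
    """Read a (possibly multi-model) PDB file into a :class:`ConformerEnsemble`.

    One conformer per MODEL block; a file without MODEL records yields a
    single conformer.  HETATM records are retained (flagged on the atom)
    unless ``keep_hetatm`` is false.  Waters are dropped.  Altlocs collapse
    to the highest-occupancy conformation.  Topology consistency across
    models is verified and violations raise :class:`TopologyError`.
    """
    path = Path(path)
    models: list[Conformer] = []
    current: list[Residue] | None = None
    pending: dict[tuple, list[tuple[str, Atom]]] = {}
    pending_meta: dict[tuple, str] = {}
    res_order: list[tuple] = []
    model_id = 1
    in_model = False

    def flush_model():
        nonlocal pending, res_order
        residues = []
        for key in res_order:
            atoms = _resolve_altlocs(pending[key])
            chain, num, icode = key
            residues.append(Residue(chain=chain, number=num, icode=icode,
                                    name=pending_meta[key], atoms=atoms))
        pending = {}
        pending_meta.clear()
        res_order = []
        return residues

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                in_model = True
                if res_order:  # unterminated previous model
                    models.append(Conformer(model_id=model_id, residues=flush_model()))
                    model_id += 1
                try:
                    model_id = int(line[6:].strip() or model_id)
                except ValueError:
                    pass
            elif rec == "ENDMDL":
                models.append(Conformer(model_id=model_id, residues=flush_model()))
                model_id += 1
            elif rec in ("ATOM  ", "HETATM"):
                altloc, chain, resnum, icode, resname, atom = _parse_atom_line(line, lineno)
                if resname == "HOH":
                    continue
                if atom.het and not keep_hetatm:
                    continue
                key = (chain, resnum, icode)
                if key not in pending:
                    pending[key] = []
                    pending_meta[key] = resname
                    res_order.append(key)
                pending[key].append((altloc, atom))

    if res_order:
        models.append(Conformer(model_id=model_id if in_model else 1, residues=flush_model()))
    if not models:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    return ConformerEnsemble(conformers=models)


def write_pdb_models(ens: ConformerEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file (single model → no MODEL records)."""
    path = Path(path)
    multi = len(ens) > 1
    with open(path, "w") as fh:
        for conf in ens:
            if multi:
                fh.write(f"MODEL {conf.model_id:>8d}\n")
            serial = 1
            for res in conf.residues:
                for a in res.atoms:
                    rec = "HETATM" if a.het else "ATOM  "
                    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                    x, y, z = a.position
                    fh.write(
                        f"{rec}{serial:>5d} {name:<4.4s} {res.name:<3.3s} "
                        f"{res.chain:1.1s}{res.number:>4d}{res.icode:1.1s}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.adp:6.2f}"
                        f"          {a.element:>2.2s}\n"
                    )
                    serial += 1
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# SAXS profile I/O
# ---------------------------------------------------------------------------

def read_saxs_profile(path: str | Path, s_unit: str = "inverse-angstrom"):
    """Read a 3-column (s, I, sigma) text profile.

    Lines starting with '#' are comments.  ``s_unit`` is either
    ``"inverse-angstrom"`` or ``"inverse-nm"``; inverse-nm values are
    divided by 10 on input so the in-memory grid is always inverse-Å.
    Rows with sigma <= 0 are dropped (counted in a log message).
    """
    from .saxs import SAXSProfile  # local import to avoid a cycle

    if s_unit not in ("inverse-angstrom", "inverse-nm"):
        raise ValueError(f"unknown s unit {s_unit!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            if len(parts) < 3:
                raise ProfileFormatError(
                    f"{path}: line {lineno} has {len(parts)} columns, need 3 (s, I, sigma)"
                )
            rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
    data = np.array(rows, dtype=float)
    if data.size == 0:
        raise ProfileFormatError(f"{path}: no data rows")
    if s_unit == "inverse-nm":
        data[:, 0] = data[:, 0] / 10.0
    keep = data[:, 2] > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: dropped %d rows with sigma <= 0", path, dropped)
    data = data[keep]
    if data.shape[0] == 0:
        raise ProfileFormatError(f"{path}: empty profile after filtering sigma <= 0")
    return SAXSProfile(s=data[:, 0], intensity=data[:, 1], sigma=data[:, 2])


def write_saxs_profile(profile, path: str | Path, header: str = "") -> None:
    """Write a profile (or a 2-column theoretical curve) as '.dat' text in inverse-Å."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        sigma = getattr(profile, "sigma", None)
        for i, (s, inten) in enumerate(zip(profile.s, profile.intensity)):
            if sigma is not None:
                fh.write(f"{s:.8e} {inten:.8e} {sigma[i]:.8e}\n")
            else:
                fh.write(f"{s:.8e} {inten:.8e}\n")


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_subset(
    ens: ConformerEnsemble,
    chain: str | None = None,
    residue_range: tuple[int, int] | None = None,
    atom_names: Sequence[str] | None = None,
) -> ConformerEnsemble:
    """Restrict an ensemble to matching chain / residue-number range / atom names.

    The original ensemble is untouched.  An empty selection raises
    :class:`SelectionError` rather than returning an empty ensemble.
    """
    if residue_range is not None and residue_range[0] > residue_range[1]:
        raise ValueError(f"empty residue range {residue_range}")
    names = set(atom_names) if atom_names is not None else None
    out_models = []
    for conf in ens:
        residues = []
        for res in conf.residues:
            if chain is not None and res.chain != chain:
                continue
            if residue_range is not None and not (residue_range[0] <= res.number <= residue_range[1]):
                continue
            atoms = res.atoms if names is None else [a for a in res.atoms if a.name in names]
            if not atoms:
                continue
            residues.append(replace(res, atoms=list(atoms)))
        if not residues:
            raise SelectionError(
                f"selection (chain={chain!r}, range={residue_range}, atoms={atom_names}) "
                f"matched nothing in model {conf.model_id}"
            )
        out_models.append(Conformer(model_id=conf.model_id, residues=residues))
    return ConformerEnsemble(conformers=out_models)
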
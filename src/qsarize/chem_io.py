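"""Reading and writing structures and activities.

Structures are exchanged as V2000 SDF files; activities either as a CSV file
whose rows are rank-ordered identically to the SDF, or as a named SDF property
on every molecule. Alignment between molecules and activities is purely
positional — nothing is matched by name — so parse failures abort the run
rather than silently shifting the order.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from rdkit import Chem, RDLogger

from .errors import AlignmentError, ParseError

# RDKit logs every rejected molblock to stderr; errors are raised as
# exceptions here instead, so the C++ log is noise.
RDLogger.DisableLog("rdApp.error")

_Z_TOL = 1e-6

_BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 4,
}


@dataclass
class MoleculeRecord:
    """One structure parsed from an SDF file.

    ``index`` is the 1-based position in the source file. ``bonds`` holds
    ``(atom_i, atom_j, order)`` with 1-based atom indices and molblock order
    conventions (4 = aromatic). ``has_3d`` is true iff any atom sits off the
    z = 0 plane.
    """

    index: int
    title: str
    atom_coordinates: list[tuple[float, float, float]]
    element_symbols: list[str]
    bonds: list[tuple[int, int, int]]
    properties: dict[str, str]
    has_3d: bool
    mol: Chem.Mol = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        if len(self.atom_coordinates) != len(self.element_symbols):
            raise ValueError("atom_coordinates and element_symbols differ in length")
        if len(self.element_symbols) < 1:
            raise ValueError("a molecule needs at least one atom")

    @classmethod
    def from_mol(cls, mol: Chem.Mol, index: int) -> "MoleculeRecord":
        """Build a record from a sanitized RDKit molecule with a conformer."""
        conf = mol.GetConformer()
        coords = [
            (p.x, p.y, p.z)
            for p in (conf.GetAtomPosition(i) for i in range(mol.GetNumAtoms()))
        ]
        symbols = [a.GetSymbol() for a in mol.GetAtoms()]
        bonds = [
            (b.GetBeginAtomIdx() + 1, b.GetEndAtomIdx() + 1,
             _BOND_ORDER.get(b.GetBondType(), 1))
            for b in mol.GetBonds()
        ]
        props = {name: mol.GetProp(name) for name in mol.GetPropNames()}
        title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        has_3d = any(abs(z) > _Z_TOL for _, _, z in coords)
        return cls(index=index, title=title, atom_coordinates=coords,
                   element_symbols=symbols, bonds=bonds, properties=props,
                   has_3d=has_3d, mol=mol)


@dataclass
class ActivityRecord:
    """One activity value on the pIC50 scale.

    ``raw_scale`` records how the value arrived ("pIC50" or "IC50"); IC50
    inputs (µM) are converted on read, so ``value`` is always pIC50.
    """

    index: int
    value: float
    raw_scale: str = "pIC50"

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise ValueError(f"activity {self.index} is not finite")


@dataclass
class Dataset:
    """Molecules and their positionally aligned activities."""

    molecules: list[MoleculeRecord]
    activities: list[ActivityRecord]
    name: str = ""

    def __post_init__(self):
        if len(self.molecules) != len(self.activities):
            raise AlignmentError(
                f"{len(self.molecules)} molecules but "
                f"{len(self.activities)} activities"
            )

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def activity_values(self):
        import numpy as np

        return np.array([a.value for a in self.activities], dtype=float)


def read_sdf(path: str | Path) -> list[MoleculeRecord]:
    """Read a V2000 SDF file into a list of MoleculeRecords, in file order.

    Raises FileNotFoundError for a missing file and :class:`ParseError`,
    citing the 1-based record index, for any block RDKit cannot parse.
    Nothing is skipped: a single bad record aborts the read so that
    positional activity alignment can never shift silently.
    """
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"SDF file not found: {p}")
    supplier = Chem.SDMolSupplier(str(p), sanitize=True, removeHs=False)
    records: list[MoleculeRecord] = []
    for i, mol in enumerate(supplier, start=1):
        if mol is None:
            raise ParseError(f"could not parse SDF record {i} in {p}", record_index=i)
        records.append(MoleculeRecord.from_mol(mol, i))
    if not records:
        raise ParseError(f"no molecules found in {p}")
    return records


def write_sdf(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write records to a V2000 SDF file, preserving titles and properties."""
    writer = Chem.SDWriter(str(path))
    try:
        for rec in records:
            mol = Chem.Mol(rec.mol)
            if rec.title:
                mol.SetProp("_Name", rec.title)
            for key, val in rec.properties.items():
                mol.SetProp(key, str(val))
            writer.write(mol)
    finally:
        writer.close()


def ic50_to_pic50(ic50_um: float) -> float:
    """Convert an IC50 in µM to pIC50 = −log10(IC50/µM)."""
    if not math.isfinite(ic50_um) or ic50_um <= 0:
        raise ValueError(f"IC50 must be a positive finite number (µM), got {ic50_um}")
    return -math.log10(ic50_um)


def _normalize_key(name: str) -> str:
    return name.replace("_", "").replace(" ", "").casefold()


def _find_activity_property(mol_props: dict[str, str], field_name: str) -> str | None:
    """Match an SDF property name case-insensitively, ignoring underscores.

    Property keys like "IC_50_" are typography for "IC50".
    """
    wanted = _normalize_key(field_name)
    for key in mol_props:
        if _normalize_key(key) == wanted:
            return key
    return None


def read_activities(
    source,
    *,
    field_name: str = "IC50",
    scale: str = "pIC50",
    n_expected: int | None = None,
) -> list[ActivityRecord]:
    """Read activities from a CSV file or from SDF properties.

    ``source`` is either a CSV path (one header row; the first data column is
    the activity, extra columns ignored; rows rank-ordered like the SDF) or a
    list of MoleculeRecords carrying a property matching ``field_name``
    (case-insensitive, underscores ignored).

    ``scale`` declares the scale of the raw numbers: "pIC50" values are taken
    as-is, "IC50" values (µM) are converted with :func:`ic50_to_pic50`.
    ``n_expected`` (molecule count) triggers an :class:`AlignmentError` on a
    row-count mismatch.
    """
    if scale not in ("pIC50", "IC50"):
        raise ValueError(f"scale must be 'pIC50' or 'IC50', got {scale!r}")

    raw: list[tuple[int, str]] = []  # (1-based data row, cell text)
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            rows = [r for r in csv.reader(fh) if r]
        if len(rows) < 2:
            raise ParseError(f"activity CSV {source} has no data rows")
        for i, row in enumerate(rows[1:], start=1):  # rows[0] is the header
            raw.append((i, row[0]))
    else:
        molecules: Sequence[MoleculeRecord] = source
        for i, rec in enumerate(molecules, start=1):
            key = _find_activity_property(rec.properties, field_name)
            if key is None:
                alt = _find_activity_property(rec.properties, "pIC50")
                if alt is None:
                    raise AlignmentError(
                        f"molecule {i} lacks an activity property matching "
                        f"{field_name!r}"
                    )
                key = alt
            raw.append((i, rec.properties[key]))

    if n_expected is not None and len(raw) != n_expected:
        raise AlignmentError(
            f"{len(raw)} activity rows for {n_expected} molecules"
        )

    records: list[ActivityRecord] = []
    for i, cell in raw:
        try:
            value = float(cell)
        except ValueError:
            raise ParseError(
                f"non-numeric activity {cell!r} at data row {i}", record_index=i
            ) from None
        if scale == "IC50":
            value = ic50_to_pic50(value)
        records.append(ActivityRecord(index=i, value=value, raw_scale=scale))
    return records
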
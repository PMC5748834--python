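"""Molecular descriptor and fingerprint calculation.

2D descriptors are always computed; 3D (geometrical) descriptors are computed
only when *every* molecule in the set carries 3D coordinates, and are filled
with zeros otherwise so that a training set and a prediction set always share
the same column layout. Each descriptor is tagged into one of the five
classical groups — topological, geometrical, hybrid, constitutional,
electronic — by a static name-based lookup.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import Descriptors, Descriptors3D, rdMolDescriptors

from .chem_io import MoleculeRecord

DESCRIPTOR_GROUPS = ("topological", "geometrical", "hybrid", "constitutional",
                     "electronic")

_NAMES_2D: list[str] = [name for name, _ in Descriptors._descList]

_FUNCS_3D = {
    "Asphericity": Descriptors3D.Asphericity,
    "Eccentricity": Descriptors3D.Eccentricity,
    "InertialShapeFactor": Descriptors3D.InertialShapeFactor,
    "NPR1": Descriptors3D.NPR1,
    "NPR2": Descriptors3D.NPR2,
    "PMI1": Descriptors3D.PMI1,
    "PMI2": Descriptors3D.PMI2,
    "PMI3": Descriptors3D.PMI3,
    "RadiusOfGyration": Descriptors3D.RadiusOfGyration,
    "SpherocityIndex": Descriptors3D.SpherocityIndex,
    "PBF": rdMolDescriptors.CalcPBF,
}
_NAMES_3D = list(_FUNCS_3D)

_TOPOLOGICAL_PREFIXES = ("Chi", "Kappa", "BalabanJ", "BertzCT", "HallKierAlpha",
                         "Ipc", "AvgIpc", "Phi")
_ELECTRONIC_PREFIXES = ("MaxEStateIndex", "MinEStateIndex", "MaxAbsEStateIndex",
                        "MinAbsEStateIndex", "MaxPartialCharge",
                        "MinPartialCharge", "MaxAbsPartialCharge",
                        "MinAbsPartialCharge", "NumRadicalElectrons",
                        "NumValenceElectrons")
_CONSTITUTIONAL_PREFIXES = ("MolWt", "ExactMolWt", "HeavyAtomMolWt",
                            "HeavyAtomCount", "NHOHCount", "NOCount", "Num",
                            "RingCount", "fr_", "FractionCSP3")


def classify_descriptor(name: str, is_3d: bool = False) -> str:
    """Assign a descriptor name to one of the five classical groups."""
    if is_3d:
        return "geometrical"
    if name.startswith(_TOPOLOGICAL_PREFIXES):
        return "topological"
    if name.startswith(_ELECTRONIC_PREFIXES):
        return "electronic"
    if name.startswith(_CONSTITUTIONAL_PREFIXES):
        return "constitutional"
    return "hybrid"  # LogP/MR, surface-area (VSA) terms, BCUTs, TPSA, ...


@dataclass
class DescriptorMatrix:
    """Compounds × named numeric descriptors, with group and 3D tags.

    ``values`` is a float matrix with NaN marking descriptors the engine
    could not compute for a molecule; those are resolved downstream
    (preprocessing), never imputed here.
    """

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    groups: dict[str, str]
    is_3d: dict[str, bool]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.descriptor_names)):
            raise ValueError("values shape does not match ids × names")
        for name in self.descriptor_names:
            if self.groups.get(name) not in DESCRIPTOR_GROUPS:
                raise ValueError(f"descriptor {name!r} lacks a valid group tag")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids,
                            columns=self.descriptor_names)

    def restrict(self, names: Sequence[str]) -> "DescriptorMatrix":
        """Column subset in the given order; unknown names raise KeyError."""
        pos = []
        for n in names:
            try:
                pos.append(self.descriptor_names.index(n))
            except ValueError:
                raise KeyError(f"descriptor {n!r} not in matrix") from None
        return DescriptorMatrix(
            compound_ids=list(self.compound_ids),
            descriptor_names=list(names),
            values=self.values[:, pos],
            groups={n: self.groups[n] for n in names},
            is_3d={n: self.is_3d[n] for n in names},
        )

    def subset_rows(self, positions: Sequence[int]) -> "DescriptorMatrix":
        """Row subset by 0-based positions, order preserved as given."""
        positions = list(positions)
        return DescriptorMatrix(
            compound_ids=[self.compound_ids[i] for i in positions],
            descriptor_names=list(self.descriptor_names),
            values=self.values[positions, :],
            groups=dict(self.groups),
            is_3d=dict(self.is_3d),
        )


@dataclass
class FingerprintSet:
    """Fixed-length binary fingerprints, one row per compound."""

    compound_ids: list[str]
    bits: np.ndarray  # (n_compounds, n_bits) uint8 in {0, 1}
    n_bits: int

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape != (len(self.compound_ids),
                                                      self.n_bits):
            raise ValueError("bits must be (n_compounds, n_bits)")

    def subset_rows(self, positions: Sequence[int]) -> "FingerprintSet":
        positions = list(positions)
        return FingerprintSet(
            compound_ids=[self.compound_ids[i] for i in positions],
            bits=self.bits[positions, :],
            n_bits=self.n_bits,
        )


def _compound_ids(molecules: Sequence[MoleculeRecord]) -> list[str]:
    return [m.title if m.title else f"mol{m.index}" for m in molecules]


def compute_descriptors(molecules: Sequence[MoleculeRecord]) -> DescriptorMatrix:
    """Compute the full 2D (+3D when available) descriptor table.

    3D columns are computed only when every molecule has 3D coordinates;
    otherwise they are identically zero (a mixed set triggers a warning).
    Values the backend cannot compute come back as NaN. Deterministic:
    identical input gives a bitwise-identical matrix.
    """
    if not molecules:
        raise ValueError("compute_descriptors needs at least one molecule")

    n3d = sum(m.has_3d for m in molecules)
    use_3d = n3d == len(molecules)
    if 0 < n3d < len(molecules):
        warnings.warn(
            "mixed 2D/3D input: 3D descriptors set to zero for all molecules",
            stacklevel=2,
        )

    rows = []
    for rec in molecules:
        vals2d = Descriptors.CalcMolDescriptors(rec.mol, missingVal=math.nan,
                                                silent=True)
        row = [vals2d[name] for name in _NAMES_2D]
        if use_3d:
            for name in _NAMES_3D:
                try:
                    row.append(float(_FUNCS_3D[name](rec.mol)))
                except Exception:
                    row.append(math.nan)
        else:
            row.extend(0.0 for _ in _NAMES_3D)
        rows.append(row)

    values = np.array(rows, dtype=float)
    # overflow artefacts (e.g. information-content indices on large graphs)
    # are treated as missing, not as numbers
    values[~np.isfinite(values) & ~np.isnan(values)] = np.nan

    names = _NAMES_2D + _NAMES_3D
    is_3d = {n: (n in _FUNCS_3D) for n in names}
    groups = {n: classify_descriptor(n, is_3d[n]) for n in names}
    return DescriptorMatrix(
        compound_ids=_compound_ids(molecules),
        descriptor_names=names,
        values=values,
        groups=groups,
        is_3d=is_3d,
    )


def compute_fingerprints(molecules: Sequence[MoleculeRecord],
                         n_bits: int = 1024) -> FingerprintSet:
    """Hashed path-based (Daylight-style) fingerprints, one per molecule."""
    if not molecules:
        raise ValueError("compute_fingerprints needs at least one molecule")
    if n_bits < 1:
        raise ValueError("n_bits must be positive")
    bits = np.zeros((len(molecules), n_bits), dtype=np.uint8)
    for k, rec in enumerate(molecules):
        fp = Chem.RDKFingerprint(rec.mol, fpSize=n_bits)
        arr = np.zeros((n_bits,), dtype=np.int8)
        DataStructs.ConvertToNumpyArray(fp, arr)
        bits[k] = arr
    return FingerprintSet(compound_ids=_compound_ids(molecules), bits=bits,
                          n_bits=n_bits)


def write_descriptor_csv(matrix: DescriptorMatrix, path: str | Path) -> None:
    """Write the descriptor table as CSV (header of descriptor names, one
    row per compound, compound id as the first column)."""
    if not matrix.descriptor_names:
        raise ValueError("descriptor matrix has no columns to write")
    matrix.to_frame().to_csv(path, index_label="compound")
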
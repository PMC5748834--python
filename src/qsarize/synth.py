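"""Synthetic congeneric series with a planted structure–activity relationship.

The generator enumerates a common scaffold decorated with one variable
substituent (R-group), computes real molecular descriptors for the series,
and plants a linear activity on a few of them:

    pIC50 = a0 + Σ effect_i · z_i + N(0, noise_sd)

where z_i are *standardized* descriptor values, so effect sizes are
scale-free regardless of each descriptor's raw units. The chosen descriptors,
their training statistics and the coefficients are returned (and written as
JSON) as ground truth, which makes descriptor-recovery and calibration tests
possible without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from . import chem_io, descriptors, preprocessing
from .chem_io import MoleculeRecord

#: para-substituted benzanilide scaffold; {R} marks the attachment point
DEFAULT_SCAFFOLD = "O=C(Nc1ccc({R})cc1)c1ccccc1"

#: R-group vocabulary: the small substituents typical of a lead-optimization
#: series (methyl, ethyl, i-propyl, t-butyl, cyclopropyl, cyclohexyl, phenyl,
#: CF3, halogens, small ethers/amines/acceptors), as fragment SMILES. Ring
#: closures use digits ≥ 5 so fragments never collide with open scaffold rings.
DEFAULT_SUBSTITUENT_POOL: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "CCCC", "CC(C)C", "C(C)(C)C", "CCCCC",
    "CC(C)(C)C", "C(C)CC",
    "C5CC5", "C5CCC5", "C5CCCC5", "C5CCCCC5", "CC5CC5", "C5CCOC5",
    "c5ccccc5", "Cc5ccccc5", "Oc5ccccc5", "c5ccncc5", "c5ccco5", "c5cccs5",
    "F", "Cl", "Br", "I", "C(F)(F)F", "C(F)F", "CCl", "CBr",
    "O", "OC", "OCC", "OC(C)C", "COC", "CCOC", "CCO", "C(C)O",
    "N", "NC", "N(C)C", "C#N", "CC#N", "[N+](=O)[O-]",
    "S", "SC", "C(=O)C", "C(=O)OC", "C(=O)N", "C=C", "C#C", "CC=C",
)

#: substituents far outside the pool's size range, used to build
#: out-of-domain prediction sets
_OUT_OF_DOMAIN_FRAGMENTS: tuple[str, ...] = (
    "CCCCCCCCCCCCCCCCCCCCCCCC",                       # C24 chain
    "C(CCCCCCCCCCCC)(CCCCCCCCCCCC)CCCCCCCCCCCC",      # branched C37
    "C5CCC(CCCCCCCCCCCCCCCC)CC5",                     # cyclohexyl + C16 tail
)


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic congeneric series.

    ``noise_sd`` is in pIC50 units. Defaults give a clearly modelable series:
    three informative descriptors with standardized effects (1.0, −0.8, 0.6)
    against 0.1 pIC50 of noise, i.e. effect-to-noise ratios of 6 and up, and
    an intercept in the middle of a typical 1.5–4 pIC50 assay window.
    """

    n_compounds: int = 40
    scaffold: str = DEFAULT_SCAFFOLD
    substituent_pool: tuple[str, ...] = DEFAULT_SUBSTITUENT_POOL
    k_true: int = 3
    effect_sizes: tuple[float, ...] = (1.0, -0.8, 0.6)
    noise_sd: float = 0.1
    intercept: float = 2.8
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.effect_sizes) != self.k_true:
            raise ValueError("need one effect size per informative descriptor")
        if self.n_compounds > len(self.substituent_pool):
            raise ValueError(
                f"n_compounds={self.n_compounds} exceeds the "
                f"{len(self.substituent_pool)} available substituents"
            )
        if self.n_compounds < self.k_true + 2:
            raise ValueError("too few compounds for the requested k_true")


@dataclass
class GroundTruth:
    """What was planted: descriptors, coefficients, and series statistics."""

    true_descriptors: list[str]
    effect_sizes: list[float]
    intercept: float
    noise_sd: float
    descriptor_means: list[float]
    descriptor_sds: list[float]
    substituents: list[str]
    activities: list[float]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2)


@dataclass
class SeriesFiles:
    sdf: Path
    activities_csv: Path
    ground_truth_json: Path


def _build_molecules(scaffold: str, substituents: Sequence[str],
                     prefix: str) -> list[MoleculeRecord]:
    records = []
    for i, frag in enumerate(substituents, start=1):
        smiles = scaffold.format(R=frag)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"substituent {frag!r} yields invalid SMILES "
                             f"{smiles!r}")
        AllChem.Compute2DCoords(mol)
        mol.SetProp("_Name", f"{prefix}{i:02d}")
        records.append(MoleculeRecord.from_mol(mol, i))
    return records


def _pick_informative(matrix, k: int, rng: np.random.Generator,
                      max_abs_corr: float = 0.5) -> list[str]:
    """Seeded pick of k well-behaved, mutually near-uncorrelated columns."""
    vals = matrix.values
    n = vals.shape[0]
    usable = [j for j, _ in enumerate(matrix.descriptor_names)
              if len(np.unique(vals[:, j])) >= max(5, n // 4)]
    if len(usable) < k:
        raise ValueError("not enough varied descriptors to plant a signal")
    order = rng.permutation(len(usable))
    chosen: list[int] = []
    corr = np.corrcoef(vals, rowvar=False)
    for idx in order:
        j = usable[idx]
        if all(abs(corr[j, c]) < max_abs_corr for c in chosen):
            chosen.append(j)
        if len(chosen) == k:
            break
    if len(chosen) < k:
        raise ValueError("could not find k mutually uncorrelated descriptors")
    return [matrix.descriptor_names[j] for j in chosen]


def generate_series(spec: SyntheticSpec, outdir: str | Path
                    ) -> tuple[SeriesFiles, GroundTruth]:
    """Write a synthetic series (SDF + activity CSV + ground-truth JSON).

    Deterministic: the same spec produces byte-identical files. The SDF also
    carries each activity as a ``pIC50`` property so the SDF-property input
    route can be exercised on the same data.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    pool = list(spec.substituent_pool)
    picked = rng.choice(len(pool), size=spec.n_compounds, replace=False)
    substituents = [pool[i] for i in picked]
    records = _build_molecules(spec.scaffold, substituents, prefix="syn")

    matrix = descriptors.compute_descriptors(records)
    clean, _ = preprocessing.drop_invalid(matrix)
    true_names = _pick_informative(clean, spec.k_true, rng)
    sub = clean.restrict(true_names)
    means = sub.values.mean(axis=0)
    sds = sub.values.std(axis=0, ddof=1)
    z = (sub.values - means) / sds

    effects = np.asarray(spec.effect_sizes, dtype=float)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_compounds)
    y = spec.intercept + z @ effects + noise

    for rec, act in zip(records, y):
        rec.properties["pIC50"] = f"{act:.6f}"

    sdf_path = outdir / "series.sdf"
    csv_path = outdir / "activities.csv"
    truth_path = outdir / "ground_truth.json"
    chem_io.write_sdf(records, sdf_path)
    with open(csv_path, "w", encoding="utf-8") as fh:
        fh.write("pIC50\n")
        fh.writelines(f"{v:.6f}\n" for v in y)

    truth = GroundTruth(
        true_descriptors=true_names,
        effect_sizes=[float(e) for e in effects],
        intercept=spec.intercept,
        noise_sd=spec.noise_sd,
        descriptor_means=[float(m) for m in means],
        descriptor_sds=[float(s) for s in sds],
        substituents=substituents,
        activities=[float(v) for v in y],
    )
    truth.to_json(truth_path)
    return SeriesFiles(sdf=sdf_path, activities_csv=csv_path,
                       ground_truth_json=truth_path), truth


def generate_newset(spec: SyntheticSpec, truth: GroundTruth,
                    mode: str, outdir: str | Path, n: int = 3) -> Path:
    """Write a small prediction set mirroring a lead-optimization follow-up.

    ``in_domain`` re-uses substituents of mid-activity training compounds, so
    every descriptor value lies inside the training range; ``out_of_domain``
    grafts substituents far larger than anything in the pool, pushing
    size-sensitive descriptors many training standard deviations out.
    Activities follow the planted relationship (standardized against the
    *training* series statistics) and are embedded as a ``pIC50`` property.
    """
    if mode not in ("in_domain", "out_of_domain"):
        raise ValueError(f"mode must be 'in_domain' or 'out_of_domain', got {mode!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)

    if mode == "in_domain":
        order = np.argsort(truth.activities, kind="stable")
        third = max(n, len(order) // 3)
        middle = order[len(order) // 2 - third // 2:
                       len(order) // 2 - third // 2 + third]
        if len(middle) < n:
            raise ValueError("series too small to draw an in-domain new set")
        picked = rng.choice(middle, size=n, replace=False)
        frags = [truth.substituents[i] for i in picked]
    else:
        if n > len(_OUT_OF_DOMAIN_FRAGMENTS):
            raise ValueError(
                f"at most {len(_OUT_OF_DOMAIN_FRAGMENTS)} out-of-domain "
                "compounds available"
            )
        frags = list(_OUT_OF_DOMAIN_FRAGMENTS[:n])

    records = _build_molecules(spec.scaffold, frags, prefix=f"new_{mode}_")
    matrix = descriptors.compute_descriptors(records)
    sub = matrix.restrict(truth.true_descriptors)
    z = (sub.values - np.asarray(truth.descriptor_means)) / np.asarray(
        truth.descriptor_sds)
    y = (truth.intercept + z @ np.asarray(truth.effect_sizes)
         + rng.normal(0.0, truth.noise_sd, size=n))
    for rec, act in zip(records, y):
        rec.properties["pIC50"] = f"{act:.6f}"

    path = outdir / f"newset_{mode}.sdf"
    chem_io.write_sdf(records, path)
    return path
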
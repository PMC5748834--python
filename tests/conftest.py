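"""Shared fixtures: a synthetic congeneric series, reused at session scope.

Everything is generated programmatically from the package's own synthetic
generator so the suite runs without any external data.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import settings
from rdkit import Chem
from rdkit.Chem import AllChem

import qsarize as q

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


def mols_from_smiles(smiles_list, props=None):
    """Build MoleculeRecords directly from SMILES (2D coordinates)."""
    records = []
    for i, smi in enumerate(smiles_list, start=1):
        mol = Chem.MolFromSmiles(smi)
        assert mol is not None, smi
        AllChem.Compute2DCoords(mol)
        mol.SetProp("_Name", f"fix{i}")
        rec = q.MoleculeRecord.from_mol(mol, i)
        if props:
            rec.properties.update(props[i - 1])
        records.append(rec)
    return records


def make_matrix(values, names=None, ids=None, group="hybrid"):
    """Hand-built DescriptorMatrix for numeric-only tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    names = names or [f"D{j + 1}" for j in range(p)]
    ids = ids or [f"c{i + 1}" for i in range(n)]
    return q.DescriptorMatrix(
        compound_ids=ids, descriptor_names=names, values=values,
        groups={nm: group for nm in names},
        is_3d={nm: False for nm in names},
    )


@pytest.fixture(scope="session")
def series(tmp_path_factory):
    """Default synthetic series: 40 compounds, 3 informative descriptors."""
    spec = q.SyntheticSpec()
    outdir = tmp_path_factory.mktemp("series")
    files, truth = q.generate_series(spec, outdir)
    return SimpleNamespace(spec=spec, files=files, truth=truth, dir=outdir)


@pytest.fixture(scope="session")
def newsets(series):
    in_path = q.generate_newset(series.spec, series.truth, "in_domain",
                                series.dir)
    out_path = q.generate_newset(series.spec, series.truth, "out_of_domain",
                                 series.dir)
    return SimpleNamespace(in_domain=in_path, out_of_domain=out_path)


@pytest.fixture(scope="session")
def pipeline_config(series, newsets, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    return q.PipelineConfig(
        sdf_path=series.files.sdf,
        activity_path=series.files.activities_csv,
        newset_paths=(newsets.in_domain, newsets.out_of_domain),
        seed=1,
        output_dir=outdir,
    )


@pytest.fixture(scope="session")
def prepared(pipeline_config):
    from qsarize.pipeline import prepare

    return prepare(pipeline_config)


@pytest.fixture(scope="session")
def bundle(prepared, pipeline_config):
    from qsarize.pipeline import _write_artifacts, build_model

    b = build_model(prepared, pipeline_config)
    _write_artifacts(b, prepared, pipeline_config.output_dir)
    return b
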
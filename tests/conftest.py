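import numpy as np
import pandas as pd
import pytest

from phosphokin import mq_io, preprocess
from phosphokin.core import DesignTable, KineticsMatrix
from phosphokin import simulate as sim

TIMEPOINTS = [0, 15, 30, 120, 300, 600]


def make_design(reps=("A", "B", "C", "D"), conds=TIMEPOINTS, n_tech=1,
                enrichment="TiO2", dataset="CD4"):
    rows = []
    for r in reps:
        for t in conds:
            for k in range(1, n_tech + 1):
                rows.append(
                    {
                        "run_id": f"{r}_{enrichment}_{t}s_r{k}",
                        "dataset": dataset,
                        "enrichment": enrichment,
                        "bio_rep": r,
                        "timepoint_s": t,
                        "tech_rep": k,
                    }
                )
    return DesignTable(pd.DataFrame(rows))


def matrix_from_array(arr, reps=None, conds=None, site_ids=None, stage="tech_averaged"):
    """Tech-averaged KineticsMatrix from a (site, rep, cond) array."""
    arr = np.asarray(arr, dtype=float)
    S, R, C = arr.shape
    reps = list(reps) if reps is not None else [chr(ord("A") + i) for i in range(R)]
    conds = list(conds) if conds is not None else TIMEPOINTS[:C]
    site_ids = site_ids or [f"site{i:04d}" for i in range(S)]
    design = make_design(reps=reps, conds=conds)
    cols = pd.MultiIndex.from_product([reps, conds], names=["bio_rep", "timepoint_s"])
    data = pd.DataFrame(arr.reshape(S, R * C), index=pd.Index(site_ids, name="site_id"),
                        columns=cols)
    meta = pd.DataFrame(
        {
            "site_key": site_ids,
            "residues": "S",
            "residue_class": "ST",
            "positions": "1",
            "protein": "P1",
            "gene_name": "G",
            "multiplicity": 1,
            "loc_class": 1,
        },
        index=data.index,
    )
    return KineticsMatrix(data=data, design=design, stage=stage, site_meta=meta)


@pytest.fixture(scope="session")
def matrix_factory():
    return matrix_from_array


@pytest.fixture(scope="session")
def design_factory():
    return make_design


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small generated dataset written to disk, shared across tests."""
    cfg = sim.GeneratorConfig(n_sites=250, seed=11)
    ds = sim.generate(cfg)
    outdir = tmp_path_factory.mktemp("synth")
    paths = ds.write(outdir)
    return {"ds": ds, "paths": paths, "design": ds.design_table(), "cfg": cfg}


@pytest.fixture(scope="session")
def small_records(small_dataset):
    return mq_io.parse_site_table(
        small_dataset["paths"]["sites"], small_dataset["design"]
    )
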
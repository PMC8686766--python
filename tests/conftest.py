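import numpy as np
import pandas as pd
import pytest

from proteotype.data import ClinicalTable, ProbeAnnotation, ProteomeMatrix


def make_annotation(probe_ids, locations=None, qc=None, multi=()):
    """Minimal valid annotation for a list of probe ids."""
    n = len(probe_ids)
    locations = locations or ["cytoplasm"] * n
    qc = [True] * n if qc is None else qc
    symbols = [
        (f"SYM_{p}", f"SYM_{p}_B") if p in multi else (f"SYM_{p}",) for p in probe_ids
    ]
    table = pd.DataFrame(
        {
            "protein_symbols": symbols,
            "uniprot": [(f"U_{p}",) for p in probe_ids],
            "cellular_location": locations,
            "qc_pass": qc,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ProbeAnnotation(table)


def make_matrix(values, probe_ids=None, subject_ids=None, log=False):
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"P{i:03d}" for i in range(values.shape[0])]
    subject_ids = subject_ids or [f"S{i:03d}" for i in range(values.shape[1])]
    return ProteomeMatrix(
        pd.DataFrame(values, index=probe_ids, columns=subject_ids), log_transformed=log
    )


@pytest.fixture
def tiny_matrix():
    return make_matrix([[10.0, 20.0], [30.0, 40.0], [50.0, 60.0]])


@pytest.fixture
def tiny_annotation(tiny_matrix):
    return make_annotation(tiny_matrix.probe_ids)


def make_clinical(n, diseases=None, seed=0, **columns):
    rng = np.random.default_rng(seed)
    sids = [f"S{i:03d}" for i in range(n)]
    diseases = diseases or ["COPD"] * (n // 2) + ["asthma"] * (n - n // 2)
    df = pd.DataFrame(
        {
            "disease": diseases,
            "age": rng.normal(60, 10, n),
            "sex": rng.choice(["F", "M"], n),
            "bmi": rng.normal(24, 4, n),
            "storage_days": rng.uniform(1000, 5000, n),
        },
        index=pd.Index(sids, name="subject_id"),
    )
    for k, v in columns.items():
        df[k] = v
    return ClinicalTable(df)
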
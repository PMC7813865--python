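import numpy as np
import pandas as pd
import pytest

from methylstage import simulate_annotation, simulate_methylome
from methylstage.io_formats import BetaMatrix, SampleSheet
from methylstage.preprocess import beta_to_m
from methylstage.synthetic import attach_genes


@pytest.fixture(scope="session")
def sim():
    """Small planted-effect methylome shared across tests (read-only)."""
    beta, sheet, truth = simulate_methylome(
        n_probes=800, n_dmp=40, n_dvp=40, seed=7)
    ann, tss = simulate_annotation(beta.probe_ids,
                                   planted_probes=truth.probes(), seed=8)
    truth = attach_genes(truth, ann)
    return {"beta": beta, "sheet": sheet, "truth": truth,
            "annotation": ann, "tss": tss, "m": beta_to_m(beta)}


def make_two_group_beta(control_vals, disease_vals, n_probes=1,
                        control_n=None, disease_n=None, seed=0):
    """Build a BetaMatrix + SampleSheet with explicit per-group values.

    ``control_vals``/``disease_vals`` are 1-D per-sample beta values
    applied to every probe (plus per-probe tiny jitter when n_probes>1).
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(control_vals, dtype=float)
    d = np.asarray(disease_vals, dtype=float)
    vals = np.tile(np.concatenate([c, d]), (n_probes, 1))
    if n_probes > 1:
        vals = np.clip(vals + rng.normal(0, 1e-3, vals.shape), 1e-6, 1 - 1e-6)
    samples = [f"HD_{i}" for i in range(len(c))] + [f"MM_{i}" for i in range(len(d))]
    probes = [f"cg{i:04d}" for i in range(n_probes)]
    beta = BetaMatrix(pd.DataFrame(vals, index=probes, columns=samples))
    sheet = SampleSheet(pd.DataFrame(
        {"group": ["HD"] * len(c) + ["MM"] * len(d)},
        index=pd.Index(samples, name="sample_id")))
    return beta, sheet
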
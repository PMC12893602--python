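import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_edge_tables(rng, n_tf=None, n_gene=None, n_mirna=None, density=0.3):
    """Random calibration-ready pair tables (all attributes passing)."""
    n_tf = n_tf or int(rng.integers(2, 8))
    n_gene = n_gene or int(rng.integers(2, 12))
    n_mirna = n_mirna or int(rng.integers(2, 8))
    tfs = [f"T{i}" for i in range(n_tf)]
    genes = [f"G{i}" for i in range(n_gene)]
    mirs = [f"m{i}" for i in range(n_mirna)]

    def pairs(src, tgt):
        mask = rng.random((len(src), len(tgt))) < density
        return [(src[i], tgt[j]) for i, j in zip(*np.where(mask))]

    tf_gene = pd.DataFrame(pairs(tfs, genes), columns=["tf", "gene"])
    tf_gene["p_value"] = rng.uniform(0.001, 0.049, len(tf_gene))
    mir_gene = pd.DataFrame(pairs(mirs, genes), columns=["mirna", "target"])
    mir_gene["target_role"] = "mRNA"
    mir_tf = pd.DataFrame(pairs(mirs, tfs), columns=["mirna", "target"])
    mir_tf["target_role"] = "TF"
    for t in (mir_gene, mir_tf):
        t["score"] = rng.uniform(0.951, 0.999, len(t))
        t["binding_region"] = "3UTR"
    return tf_gene, mir_gene, mir_tf


def brute_force_ffls(tf_gene, mir_gene, mir_tf):
    """Independent triple-loop FFL oracle over the raw pair tables."""
    tg = set(zip(tf_gene["tf"], tf_gene["gene"]))
    mg = set(zip(mir_gene["mirna"], mir_gene["target"]))
    mt = set(zip(mir_tf["mirna"], mir_tf["target"]))
    tfs = {t for t, _ in tg} | {t for _, t in mt}
    genes = {g for _, g in tg} | {g for _, g in mg}
    mirs = {m for m, _ in mg} | {m for m, _ in mt}
    found = []
    for t in sorted(tfs):
        for g in sorted(genes):
            for m in sorted(mirs):
                if (t, g) in tg and (m, t) in mt and (m, g) in mg:
                    found.append((t, g, m))
    return found
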
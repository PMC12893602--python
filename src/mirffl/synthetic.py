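"""Synthetic inputs with planted ground truth for the whole pipeline.

Every generator is a pure function of its parameters and an integer seed:
log-scale Gaussian expression with a planted fraction of mean-shifted
features, Bernoulli regulatory-interaction tables with a planted
high-degree feed-forward-loop motif, exponential survival times with an
expression-dependent hazard and independent exponential censoring, and
Beta-distributed CpG methylation values.

The emitted tables mimic the shapes of the real-world sources they stand
in for (two-channel GEO expression series, a ChEA-style TF-gene table, a
miRWalk-style miRNA-target table with scores and binding regions), so the
downstream filtering and network stages can be validated against known
truth without any download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix

logger = logging.getLogger(__name__)

REGION_3UTR = "3UTR"


def tf_ids(n: int) -> list[str]:
    return [f"TF{i:03d}" for i in range(1, n + 1)]

def gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]

def mirna_ids(n: int) -> list[str]:
    return [f"miR-{i:04d}" for i in range(1, n + 1)]

def cpg_ids(n: int) -> list[str]:
    return [f"cg{i:06d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class PlantedMotif:
    """Ground-truth dominant FFL: tf->gene, mirna-|tf, mirna-|gene.

    ``extra_degree`` is the number of additional filter-passing edges
    attached to each member so that its degree exceeds the background
    expectation and the motif tops the degree-centrality ranking.
    """

    tf: str
    gene: str
    mirna: str
    extra_degree: int = 0

    def __post_init__(self) -> None:
        if self.extra_degree < 0:
            raise ValueError("extra_degree must be >= 0")


# -- expression ---------------------------------------------------------------

def generate_expression(
    n_features: int,
    n_case: int,
    n_control: int,
    frac_de: float = 0.2,
    effect: float = 0.75,
    sd: float = 0.4,
    seed: int = 0,
    feature_prefix: str = "F",
    feature_names: list[str] | None = None,
    forced_de: tuple[str, ...] = (),
):
    """Log2 expression with a planted fraction of mean-shifted features.

    Each value is base_i + group shift + N(0, sd) on the log2 scale; DE
    features shift the case group by +-``effect``, split evenly between up
    and down. ``forced_de`` ids are always among the planted DE features.
    Returns ``(ExpressionMatrix, truth)`` where truth has one row per
    feature: feature_id, is_de, true_log2fc, direction (up/down/none).
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("each group needs at least 2 samples")
    if not 0 <= frac_de <= 1:
        raise ValueError("frac_de must lie in [0, 1]")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if effect < 0:
        raise ValueError("effect is a magnitude and must be >= 0")
    rng = np.random.default_rng(seed)
    if feature_names is None:
        feature_names = [f"{feature_prefix}{i:05d}" for i in range(1, n_features + 1)]
    if len(feature_names) != n_features:
        raise ValueError("feature_names length must equal n_features")
    name_pos = {f: i for i, f in enumerate(feature_names)}
    unknown = [f for f in forced_de if f not in name_pos]
    if unknown:
        raise ValueError(f"forced_de ids not in feature namespace: {unknown}")

    n_de = int(round(n_features * frac_de))
    n_de = max(n_de, len(forced_de))
    forced_idx = [name_pos[f] for f in forced_de]
    remaining = np.setdiff1d(np.arange(n_features), forced_idx)
    chosen = rng.choice(remaining, size=n_de - len(forced_idx), replace=False)
    de_idx = np.concatenate([np.asarray(forced_idx, dtype=int), chosen.astype(int)])
    rng.shuffle(de_idx)
    n_up = (n_de + 1) // 2
    up_idx, down_idx = de_idx[:n_up], de_idx[n_up:]
    # forced features must be detectably shifted in either direction; keep
    # them wherever the shuffle put them (direction is not promised)

    true_fc = np.zeros(n_features)
    true_fc[up_idx] = effect
    true_fc[down_idx] = -effect

    base = rng.normal(7.0, 1.5, size=n_features)
    noise = rng.normal(0.0, sd, size=(n_features, n_case + n_control))
    values = base[:, None] + noise
    values[:, :n_case] += true_fc[:, None]

    samples = [f"case_{i:03d}" for i in range(1, n_case + 1)] + [
        f"ctrl_{i:03d}" for i in range(1, n_control + 1)
    ]
    groups = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples, name="group")
    matrix = ExpressionMatrix(pd.DataFrame(values, index=feature_names, columns=samples), groups)

    direction = np.where(true_fc > 0, "up", np.where(true_fc < 0, "down", "none"))
    truth = pd.DataFrame(
        {
            "feature_id": feature_names,
            "is_de": true_fc != 0,
            "true_log2fc": true_fc,
            "direction": direction,
        }
    )
    logger.info("generate_expression: %d features (%d DE), %d+%d samples, seed=%d",
                n_features, n_de, n_case, n_control, seed)
    return matrix, truth


# -- regulatory interaction tables -------------------------------------------

def _passing_tf_attrs(rng, k):
    return rng.uniform(0.001, 0.0499, size=k)

def _failing_tf_attrs(rng, k):
    return rng.uniform(0.05, 0.999, size=k)


def _mir_attrs(rng, passing: np.ndarray):
    """Scores and binding regions on either side of the miRWalk filter."""
    k = len(passing)
    score = np.where(passing, rng.uniform(0.9501, 0.9999, size=k), rng.uniform(0.5, 0.95, size=k))
    region = np.full(k, REGION_3UTR, dtype=object)
    # half of the failing edges fail on region instead of score
    fail = ~passing
    region_fail = fail & (rng.random(k) < 0.5)
    score[region_fail] = rng.uniform(0.9501, 0.9999, size=int(region_fail.sum()))
    extra = rng.choice(["3UTR;CDS", "3UTR;5UTR", "CDS"], size=k)
    region[region_fail] = extra[region_fail]
    return score, region


def generate_regulatory_tables(
    n_tf: int,
    n_gene: int,
    n_mirna: int,
    edge_prob: float = 0.04,
    planted: PlantedMotif | None = None,
    pass_prob: float = 1.0,
    seed: int = 0,
):
    """ChEA-style TF-gene and miRWalk-style miRNA-target tables.

    Background edges are sampled independently per pair type with
    probability ``edge_prob``; each receives filter-passing attributes
    (p < 0.05 / score > 0.95 and exclusive 3'UTR binding) with probability
    ``pass_prob``, otherwise failing ones. The planted motif's three
    defining edges and its ``extra_degree`` additional edges per member are
    always emitted with passing attributes. No (source, target) pair is
    duplicated within a type.

    Returns ``(tf_gene, mir_targets, planted)``; the miRNA table carries a
    ``target_role`` column (TF vs mRNA) derived from the target namespace.
    """
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must lie in [0, 1]")
    if not 0 <= pass_prob <= 1:
        raise ValueError("pass_prob must lie in [0, 1]")
    tfs, genes, mirs = tf_ids(n_tf), gene_ids(n_gene), mirna_ids(n_mirna)
    rng = np.random.default_rng(seed)

    tg = {(t, g) for t, g in zip(*np.where(rng.random((n_tf, n_gene)) < edge_prob))}
    mt = {(m, t) for m, t in zip(*np.where(rng.random((n_mirna, n_tf)) < edge_prob))}
    mg = {(m, g) for m, g in zip(*np.where(rng.random((n_mirna, n_gene)) < edge_prob))}
    forced_tg, forced_mt, forced_mg = set(), set(), set()

    if planted is not None:
        for pid, names, what in ((planted.tf, tfs, "tf"), (planted.gene, genes, "gene"),
                                 (planted.mirna, mirs, "mirna")):
            if pid not in names:
                raise ValueError(f"planted {what} id {pid!r} outside the generated namespace")
        ti, gi, mi = tfs.index(planted.tf), genes.index(planted.gene), mirs.index(planted.mirna)
        forced_tg.add((ti, gi))
        forced_mt.add((mi, ti))
        forced_mg.add((mi, gi))
        k = planted.extra_degree
        if k:
            def pick(pool, existing, size):
                avail = [x for x in pool if x not in existing]
                if len(avail) < size:
                    raise ValueError("extra_degree exceeds the available partner namespace")
                return rng.choice(len(avail), size=size, replace=False), avail

            idx, avail = pick(range(n_gene), {g for t, g in tg | forced_tg if t == ti}, k)
            forced_tg.update((ti, avail[j]) for j in idx)
            idx, avail = pick(range(n_mirna), {m for m, g in mg | forced_mg if g == gi}, k)
            forced_mg.update((avail[j], gi) for j in idx)
            taken_t = {t for m, t in mt | forced_mt if m == mi}
            taken_g = {g for m, g in mg | forced_mg if m == mi}
            pool = [("t", t) for t in range(n_tf) if t not in taken_t] + [
                ("g", g) for g in range(n_gene) if g not in taken_g
            ]
            if len(pool) < k:
                raise ValueError("extra_degree exceeds the available partner namespace")
            for j in rng.choice(len(pool), size=k, replace=False):
                kind, x = pool[j]
                (forced_mt if kind == "t" else forced_mg).add((mi, x))

    tg |= forced_tg
    mt |= forced_mt
    mg |= forced_mg

    tg_rows = sorted(tg)
    passing = rng.random(len(tg_rows)) < pass_prob
    passing |= np.array([pair in forced_tg for pair in tg_rows], dtype=bool)
    pvals = np.where(passing, _passing_tf_attrs(rng, len(tg_rows)), _failing_tf_attrs(rng, len(tg_rows)))
    tf_gene = pd.DataFrame(
        {"tf": [tfs[t] for t, _ in tg_rows], "gene": [genes[g] for _, g in tg_rows], "p_value": pvals}
    )

    mir_rows = sorted([(m, "t", t) for m, t in mt] + [(m, "g", g) for m, g in mg])
    passing = rng.random(len(mir_rows)) < pass_prob
    passing |= np.array(
        [
            (m, x) in (forced_mt if kind == "t" else forced_mg)
            for m, kind, x in mir_rows
        ],
        dtype=bool,
    )
    score, region = _mir_attrs(rng, passing)
    mir_targets = pd.DataFrame(
        {
            "mirna": [mirs[m] for m, _, _ in mir_rows],
            "target": [tfs[x] if kind == "t" else genes[x] for _, kind, x in mir_rows],
            "target_role": ["TF" if kind == "t" else "mRNA" for _, kind, _ in mir_rows],
            "score": score,
            "binding_region": region,
        }
    )
    logger.info("generate_regulatory_tables: %d tf-gene, %d mir-target edges, seed=%d",
                len(tf_gene), len(mir_targets), seed)
    return tf_gene, mir_targets, planted


def generate_fixed_count_tables(
    n_tf: int,
    n_gene: int,
    n_mirna: int,
    n_tf_gene: int,
    n_mir_tf: int,
    n_mir_gene: int,
    seed: int = 0,
):
    """Tables with exact unique-edge counts per pair type, all passing.

    Used for scale-matched node/edge bookkeeping: each pair type receives
    exactly the requested number of distinct (source, target) rows sampled
    uniformly without replacement from the pair space.
    """
    rng = np.random.default_rng(seed)
    tfs, genes, mirs = tf_ids(n_tf), gene_ids(n_gene), mirna_ids(n_mirna)

    def sample_pairs(n_src, n_tgt, k):
        if k > n_src * n_tgt:
            raise ValueError("requested more unique edges than the pair space holds")
        flat = rng.choice(n_src * n_tgt, size=k, replace=False)
        return flat // n_tgt, flat % n_tgt

    ti, gi = sample_pairs(n_tf, n_gene, n_tf_gene)
    tf_gene = pd.DataFrame(
        {"tf": np.array(tfs)[ti], "gene": np.array(genes)[gi],
         "p_value": _passing_tf_attrs(rng, n_tf_gene)}
    )
    mi, ti = sample_pairs(n_mirna, n_tf, n_mir_tf)
    mir_tf = pd.DataFrame(
        {"mirna": np.array(mirs)[mi], "target": np.array(tfs)[ti], "target_role": "TF"}
    )
    mi, gi = sample_pairs(n_mirna, n_gene, n_mir_gene)
    mir_gene = pd.DataFrame(
        {"mirna": np.array(mirs)[mi], "target": np.array(genes)[gi], "target_role": "mRNA"}
    )
    mir_targets = pd.concat([mir_tf, mir_gene], ignore_index=True)
    k = len(mir_targets)
    score, region = _mir_attrs(rng, np.ones(k, dtype=bool))
    mir_targets["score"] = score
    mir_targets["binding_region"] = region
    return tf_gene, mir_targets


# -- survival -----------------------------------------------------------------

def generate_survival(
    n: int,
    baseline_rate: float = 0.02,
    log_hr: float = 0.0,
    covariate=None,
    censor_rate: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival with a covariate-dependent hazard.

    Event times are exponential with rate ``baseline_rate * exp(log_hr *
    z)`` where z is the standardized covariate; censoring times are
    exponential with ``censor_rate``; the recorded time is the minimum and
    the event flag marks deaths. Times are in months by convention.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if baseline_rate <= 0 or censor_rate <= 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    if covariate is None:
        covariate = rng.standard_normal(n)
    covariate = np.asarray(covariate, dtype=float)
    if covariate.shape != (n,):
        raise ValueError(f"covariate must have length {n}, got shape {covariate.shape}")
    s = covariate.std()
    z = (covariate - covariate.mean()) / s if s > 0 else np.zeros(n)
    rate = baseline_rate * np.exp(log_hr * z)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.exponential(1.0 / censor_rate, size=n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return pd.DataFrame(
        {
            "sample": [f"S{i:04d}" for i in range(1, n + 1)],
            "time": time,
            "event": event,
            "covariate": covariate,
        }
    )


# -- methylation --------------------------------------------------------------

def generate_methylation(
    n_cpg: int, n_samples: int, alpha: float = 2.0, beta: float = 5.0, seed: int = 0
) -> pd.DataFrame:
    """CpG x samples matrix of i.i.d. Beta(alpha, beta) beta-values."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("Beta shape parameters must be positive")
    rng = np.random.default_rng(seed)
    values = rng.beta(alpha, beta, size=(n_cpg, n_samples))
    return pd.DataFrame(
        values, index=cpg_ids(n_cpg), columns=[f"S{i:04d}" for i in range(1, n_samples + 1)]
    )


# -- gene sets ----------------------------------------------------------------

def generate_gene_sets(
    universe: list[str],
    n_sets: int = 20,
    set_size: int = 25,
    seed: int = 0,
    enriched_from: list[str] | None = None,
    n_enriched: int = 0,
    enrich_frac: float = 0.6,
):
    """Random gene sets over a universe, optionally with planted enrichment.

    The first ``n_enriched`` sets draw ``enrich_frac`` of their members
    from ``enriched_from`` (e.g. the true DE genes) and the rest from the
    remaining universe; other sets are uniform draws.
    """
    from .enrichment import GeneSet

    rng = np.random.default_rng(seed)
    universe = list(universe)
    if set_size > len(universe):
        raise ValueError("set_size exceeds the universe")
    sets = []
    for i in range(n_sets):
        if i < n_enriched and enriched_from:
            pool_in = [g for g in enriched_from if g in set(universe)]
            k_in = min(int(round(set_size * enrich_frac)), len(pool_in))
            members = list(rng.choice(pool_in, size=k_in, replace=False))
            rest = [g for g in universe if g not in set(members)]
            members += list(rng.choice(rest, size=set_size - k_in, replace=False))
        else:
            members = list(rng.choice(universe, size=set_size, replace=False))
        sets.append(GeneSet(name=f"SET{i + 1:03d}", description="synthetic",
                            members=frozenset(members)))
    return sets
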
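"""Threshold filters and mutual calibration of regulatory interaction pairs.

TF-gene edges are kept when their significance p-value is strictly below
0.05 and the target gene is differentially expressed; miRNA-target edges
when their prediction score is strictly above 0.95 and they bind the
3'UTR exclusively. Calibration then mutually restricts the three tables
(TF-gene, miRNA-gene, miRNA-TF) to the *common* miRNAs — those repressing
both an mRNA and a TF — and to TFs that survive on both sides, iterated
to a fixed point, so that the surviving edges form the raw material of
the feed-forward-loop network.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_REGION_SEPARATORS = ";,|"


def parse_regions(text) -> frozenset[str]:
    """'3UTR;CDS' (any of ; , |) -> frozenset({'3UTR', 'CDS'})."""
    s = str(text)
    for sep in _REGION_SEPARATORS[1:]:
        s = s.replace(sep, _REGION_SEPARATORS[0])
    parts = frozenset(p.strip() for p in s.split(_REGION_SEPARATORS[0]) if p.strip())
    if not parts:
        raise ValueError(f"empty binding_region value {text!r}")
    return parts


def split_mir_table(mir_targets: pd.DataFrame):
    """Split a combined miRNA-target table into (mir_gene, mir_tf) by role."""
    role = mir_targets["target_role"]
    return (
        mir_targets[role == "mRNA"].reset_index(drop=True),
        mir_targets[role == "TF"].reset_index(drop=True),
    )


def filter_tf_edges(
    edges: pd.DataFrame, p_thresh: float = 0.05, allowed_genes=None
) -> pd.DataFrame:
    """Keep TF-gene edges with p < p_thresh (strict) targeting allowed genes."""
    keep = edges["p_value"] < p_thresh
    if allowed_genes is not None:
        keep &= edges["gene"].isin(set(allowed_genes))
    out = edges[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("filter_tf_edges: no edges survive (of %d)", len(edges))
    return out


def filter_mir_edges(edges: pd.DataFrame, score_thresh: float = 0.95) -> pd.DataFrame:
    """Keep miRNA-target edges with score > thresh (strict) binding 3'UTR only.

    'Exclusively 3'UTR' is enforced as region-set equality with {3UTR},
    not mere membership.
    """
    regions = edges["binding_region"].map(parse_regions)
    keep = (edges["score"] > score_thresh) & (regions == frozenset({"3UTR"}))
    out = edges[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("filter_mir_edges: no edges survive (of %d)", len(edges))
    return out


def common_mirnas(mir_gene: pd.DataFrame, mir_tf: pd.DataFrame) -> set[str]:
    """miRNAs with >= 1 retained edge to an mRNA AND >= 1 to a TF."""
    return set(mir_gene["mirna"]) & set(mir_tf["mirna"])


def _ffl_support_prune(tf_gene, mir_gene, mir_tf):
    """Drop edges that cannot sit in any (tf, gene, mirna) triangle."""
    genes_of_tf = tf_gene.groupby("tf")["gene"].agg(set).to_dict()
    tfs_of_gene = tf_gene.groupby("gene")["tf"].agg(set).to_dict()
    mirs_of_tf = mir_tf.groupby("target")["mirna"].agg(set).to_dict()
    mirs_of_gene = mir_gene.groupby("target")["mirna"].agg(set).to_dict()
    gene_targets = mir_gene.groupby("mirna")["target"].agg(set).to_dict()
    tf_targets = mir_tf.groupby("mirna")["target"].agg(set).to_dict()
    empty: set = set()

    def mask(flags, n):
        return np.fromiter(flags, dtype=bool, count=n)

    tg_keep = mask(
        (bool(mirs_of_tf.get(t, empty) & mirs_of_gene.get(g, empty))
         for t, g in zip(tf_gene["tf"], tf_gene["gene"])),
        len(tf_gene),
    )
    mt_keep = mask(
        (bool(genes_of_tf.get(t, empty) & gene_targets.get(m, empty))
         for m, t in zip(mir_tf["mirna"], mir_tf["target"])),
        len(mir_tf),
    )
    mg_keep = mask(
        (bool(tfs_of_gene.get(g, empty) & tf_targets.get(m, empty))
         for m, g in zip(mir_gene["mirna"], mir_gene["target"])),
        len(mir_gene),
    )
    return tf_gene[tg_keep], mir_gene[mg_keep], mir_tf[mt_keep]


def calibrate_pairs(
    tf_gene: pd.DataFrame,
    mir_gene: pd.DataFrame,
    mir_tf: pd.DataFrame,
    mode: str = "fixed_point",
    ffl_support: bool = False,
):
    """Mutually restrict the three pair tables to shared miRNAs and TFs.

    One restriction pass keeps miRNA edges of common miRNAs only, miRNA-TF
    edges whose TF appears in the TF-gene table, and TF-gene edges whose
    TF and gene are each targeted by >= 1 common miRNA. ``fixed_point``
    (default) iterates the pass until nothing changes; ``single_pass``
    applies it once. With ``ffl_support=True`` edges that cannot
    participate in any enumerable FFL triangle are additionally pruned
    (a strictly stronger fixed point).
    """
    if mode not in {"fixed_point", "single_pass"}:
        raise ValueError(f"unknown calibration mode {mode!r}")

    def one_pass(tg, mg, mt):
        common = set(mg["mirna"]) & set(mt["mirna"])
        mg = mg[mg["mirna"].isin(common)]
        mt = mt[mt["mirna"].isin(common)]
        mt = mt[mt["target"].isin(set(tg["tf"]))]
        tfs_hit = set(mt["target"])
        genes_hit = set(mg["target"])
        tg = tg[tg["tf"].isin(tfs_hit) & tg["gene"].isin(genes_hit)]
        if ffl_support:
            tg, mg, mt = _ffl_support_prune(tg, mg, mt)
        return tg, mg, mt

    tg, mg, mt = tf_gene, mir_gene, mir_tf
    max_iter = len(tg) + len(mg) + len(mt) + 1
    for _ in range(max_iter):
        sizes = (len(tg), len(mg), len(mt))
        tg, mg, mt = one_pass(tg, mg, mt)
        if mode == "single_pass" or (len(tg), len(mg), len(mt)) == sizes:
            break
    if len(tg) == 0:
        logger.warning("calibrate_pairs: empty fixed point")
    logger.info(
        "calibrate_pairs(%s): tf_gene %d->%d, mir_gene %d->%d, mir_tf %d->%d",
        mode, len(tf_gene), len(tg), len(mir_gene), len(mg), len(mir_tf), len(mt),
    )
    return tg.reset_index(drop=True), mg.reset_index(drop=True), mt.reset_index(drop=True)
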
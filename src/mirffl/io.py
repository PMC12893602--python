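"""Readers and writers for the pipeline's on-disk formats.

Expression matrices travel either as plain TSV with a two-line header
(sample ids, then group labels) or as a simplified GEO-series-matrix
dialect ("!"-prefixed metadata lines around a ``!series_matrix_table_begin``
/ ``!series_matrix_table_end`` block). Interaction, survival and
enrichment tables are plain CSV with fixed column orders; methylation is a
TSV matrix; gene sets are standard GMT.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .diffexpr import ExpressionMatrix

logger = logging.getLogger(__name__)

TF_EDGE_COLUMNS = ["tf", "gene", "p_value"]
MIR_EDGE_COLUMNS = ["mirna", "target", "target_role", "score", "binding_region"]
SURVIVAL_COLUMNS = ["sample", "time", "event", "covariate"]


# -- expression ---------------------------------------------------------------

def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    """TSV with two header lines: sample ids, then their group labels."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("feature_id\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        fh.write("!group\t" + "\t".join(matrix.groups.astype(str)) + "\n")
        matrix.values.to_csv(fh, sep="\t", header=False)


def read_expression_tsv(path) -> ExpressionMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        group_line = fh.readline().rstrip("\n").split("\t")
        if not group_line or group_line[0] != "!group":
            raise ValueError(f"{path}: expected a '!group' line after the sample header")
        values = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    samples = header[1:]
    values.columns = samples
    values.index.name = None
    groups = pd.Series(group_line[1:], index=samples, name="group")
    return ExpressionMatrix(values, groups)


def write_series_matrix(matrix: ExpressionMatrix, path, seed: int | None = None) -> None:
    """Simplified GEO series-matrix: metadata comments + delimited table."""
    path = Path(path)

    def quoted(items) -> str:
        return "\t".join(f'"{x}"' for x in items)

    with path.open("w") as fh:
        fh.write('!Series_title\t"synthetic expression series"\n')
        if seed is not None:
            fh.write(f'!Series_seed\t"{seed}"\n')
        fh.write("!Sample_geo_accession\t" + quoted(matrix.sample_ids) + "\n")
        fh.write("!Sample_group\t" + quoted(matrix.groups.astype(str)) + "\n")
        fh.write("!series_matrix_table_begin\n")
        fh.write('"ID_REF"\t' + quoted(matrix.sample_ids) + "\n")
        matrix.values.to_csv(fh, sep="\t", header=False)
        fh.write("!series_matrix_table_end\n")


def read_series_matrix(path) -> ExpressionMatrix:
    path = Path(path)
    groups_line = None
    table_lines: list[str] = []
    in_table = False
    for line in path.read_text().splitlines():
        if line.startswith("!series_matrix_table_begin"):
            in_table = True
        elif line.startswith("!series_matrix_table_end"):
            in_table = False
        elif in_table:
            table_lines.append(line)
        elif line.startswith("!Sample_group"):
            groups_line = line
    if not table_lines:
        raise ValueError(f"{path}: no series-matrix table block found")
    if groups_line is None:
        raise ValueError(f"{path}: no !Sample_group line found")

    def unquote(x: str) -> str:
        return x.strip().strip('"')

    header = [unquote(x) for x in table_lines[0].split("\t")][1:]
    rows = [ln.split("\t") for ln in table_lines[1:] if ln.strip()]
    values = pd.DataFrame(
        [[float(v) for v in r[1:]] for r in rows],
        index=[unquote(r[0]) for r in rows],
        columns=header,
    )
    groups = pd.Series(
        [unquote(x) for x in groups_line.split("\t")[1:]], index=header, name="group"
    )
    return ExpressionMatrix(values, groups)


def read_expression(path) -> ExpressionMatrix:
    """Dispatch on content: series-matrix if the file starts with '!'."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("!"):
        return read_series_matrix(path)
    return read_expression_tsv(path)


# -- interaction / survival / methylation tables ------------------------------

def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns {missing}")
    return df[required + [c for c in df.columns if c not in required]]

def read_tf_edges(path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path), TF_EDGE_COLUMNS, "TF-gene")

def read_mir_edges(path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path), MIR_EDGE_COLUMNS, "miRNA-target")

def read_survival(path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path), SURVIVAL_COLUMNS, "survival")

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)

def write_methylation(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="cpg_id")

def read_methylation(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index.name = None
    return matrix


# -- gene sets (GMT) ----------------------------------------------------------

def read_gmt(path):
    """Parse a GMT file into GeneSet records (name, description, members)."""
    from .enrichment import GeneSet

    path = Path(path)
    sets = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, description = fields[0], fields[1]
        members = []
        seen = set()
        for m in fields[2:]:
            if m and m not in seen:
                members.append(m)
                seen.add(m)
        sets.append(GeneSet(name=name, description=description, members=frozenset(members)))
    return sets


def write_gmt(sets, path) -> None:
    with Path(path).open("w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")
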
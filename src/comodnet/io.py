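"""TSV / YAML / graph I/O shared by all pipeline stages.

Result tables use 12 significant digits and the token ``NA`` for missing
values; expression matrices are written with full float precision so read
-> write round trips are exact. The expression dialect is: a header comment line recording
the scale (``# scale=intensity``), an ID column (``spot_id`` when a
replicate map is present, else ``feature_id``), optional ``feature_id`` and
``replicate`` columns for spot-level matrices, then one column per sample.
Spot flags, being per spot x sample, are stored losslessly in a sidecar
file ``<path>.flags.tsv`` with the same row/column layout and 0/1 entries.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import StudyDesign
from .errors import InputError
from .matrix import ExpressionMatrix

NA = "NA"
_FMT = "%.12g"
_FMT_EXACT = "%.17g"  # expression matrices round-trip exactly


def _fmt(x, fmt: str = _FMT) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return NA
    if isinstance(x, (float, np.floating)):
        return fmt % x
    return str(x)


def _write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(df.columns)
        for row in df.itertuples(index=False):
            w.writerow([_fmt(v) for v in row])


def write_table_tsv(df: pd.DataFrame, path) -> None:
    """Write a generic results table as TSV (12 significant digits, NA token)."""
    _write_table(df, path)


def read_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    """Write an ExpressionMatrix in the comodnet TSV dialect (see module docs)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    spot_level = m.replicate_map is not None
    with open(path, "w", newline="") as fh:
        fh.write(f"# scale={m.scale}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if spot_level:
            header = ["spot_id", "feature_id", "replicate"] + m.sample_ids
        else:
            header = ["feature_id"] + m.sample_ids
        w.writerow(header)
        for spot in m.values.index:
            vals = [_fmt(v, _FMT_EXACT) for v in m.values.loc[spot]]
            if spot_level:
                feat = m.replicate_map[spot]
                rep = spot.rsplit("::r", 1)[1] if "::r" in str(spot) else "1"
                w.writerow([spot, feat, rep] + vals)
            else:
                w.writerow([spot] + vals)
    if m.flags is not None:
        with open(f"{path}.flags.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["id"] + m.sample_ids)
            for spot in m.flags.index:
                w.writerow([spot] + [int(v) for v in m.flags.loc[spot]])


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read the comodnet expression TSV dialect with line-numbered errors."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: file not found")
    with open(path) as fh:
        lines = fh.read().splitlines()
    scale = "intensity"
    start = 0
    for ln in lines:
        if ln.startswith("#"):
            start += 1
            if ln.strip().startswith("# scale="):
                scale = ln.strip().split("=", 1)[1]
        else:
            break
    body = lines[start:]
    if not body or not body[0].strip():
        raise InputError(f"{path}: empty file")
    rows = [r for r in csv.reader(body, delimiter="\t")]
    header = rows[0]
    n_cols = len(header)
    spot_level = header[:3] == ["spot_id", "feature_id", "replicate"]
    meta_n = 3 if spot_level else 1
    sample_ids = header[meta_n:]
    if len(set(sample_ids)) != len(sample_ids):
        raise InputError(f"{path}: duplicate sample IDs in header")
    if not sample_ids:
        raise InputError(f"{path}: no sample columns")
    ids, feats, data = [], [], []
    for k, row in enumerate(rows[1:], start=start + 2):
        if len(row) != n_cols:
            raise InputError(f"{path}:{k}: expected {n_cols} columns, got {len(row)}")
        ids.append(row[0])
        if spot_level:
            feats.append(row[1])
        vals = []
        for c, cell in zip(sample_ids, row[meta_n:]):
            if cell == NA:
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise InputError(f"{path}:{k}: non-numeric cell {cell!r} in column {c}") from None
        data.append(vals)
    values = pd.DataFrame(data, index=ids, columns=sample_ids)
    rep_map = pd.Series(feats, index=ids, name="feature_id") if spot_level else None
    flags = None
    flag_path = Path(f"{path}.flags.tsv")
    if flag_path.exists():
        fdf = pd.read_csv(flag_path, sep="\t", index_col=0)
        flags = fdf.astype(bool)
    return ExpressionMatrix(values=values, scale=scale, flags=flags, replicate_map=rep_map)


def write_design_tsv(design: StudyDesign, path) -> None:
    _write_table(design.table, path)


def read_design_tsv(path) -> StudyDesign:
    return StudyDesign(read_table_tsv(path))


def write_graph(g, graphml_path=None, sif_path=None) -> None:
    """Export the integrative graph as GraphML (full attributes) and/or SIF."""
    import networkx as nx

    if graphml_path is not None:
        Path(graphml_path).parent.mkdir(parents=True, exist_ok=True)
        nx.write_graphml(g, graphml_path)
    if sif_path is not None:
        Path(sif_path).parent.mkdir(parents=True, exist_ok=True)
        with open(sif_path, "w") as fh:
            for a, b, d in sorted(g.edges(data=True)):
                fh.write(f"{a}\t{d.get('type', 'edge')}\t{b}\n")
            for node in sorted(nx.isolates(g)):
                fh.write(f"{node}\n")


def load_yaml(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if out is None:
        return {}
    if not isinstance(out, dict):
        raise InputError(f"{path}: expected a YAML mapping")
    return out


def dump_yaml(data: dict) -> str:
    buf = _io.StringIO()
    yaml.safe_dump(data, buf, sort_keys=True)
    return buf.getvalue()
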
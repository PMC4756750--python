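"""Readers and writers for the three data families.

* measurement tables — CSV with a header row of variable names, one row per
  specimen; blank cells, "NA" and "?" all mean missing,
* discrete character matrices — NEXUS DATA blocks, TNT ``xread``, or plain
  CSV, with "?" for missing and "-"/"−" for inapplicable,
* trees — Newick, with internal-node annotations written in the label
  position (``)98:`` style) for widest parser compatibility.

All readers round-trip bit-exactly through the matching writer.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .containers import (INAPPLICABLE, MISSING, CharacterMatrix,
                         MeasurementMatrix, parse_symbol, state_symbol)

__all__ = [
    "read_measurements",
    "write_measurements",
    "read_characters",
    "write_characters",
    "read_newick",
    "write_newick",
]

_NA_SPELLINGS = {"", "na", "n/a", "nan", "?"}

_TAXON_COL = "specimen"
_LABEL_COL = "taxon"


def _as_text(source) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str) and ("\n" in source or "," in source or ";" in source):
        return source
    p = Path(str(source))
    if p.exists():
        return p.read_text()
    return str(source)


# ---------------------------------------------------------------------------
# measurements (CSV)
# ---------------------------------------------------------------------------

def read_measurements(source, angle_variables=None) -> MeasurementMatrix:
    """Read a specimen-by-variable CSV table.

    The first column holds specimen ids; an optional second column named
    ``taxon`` holds genus/species labels; remaining columns are numeric
    measurement variables.  Blank, "NA" and "?" cells are missing.
    """
    text = _as_text(source)
    raw = pd.read_csv(_io.StringIO(text), dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise ValueError("measurement table needs an id column and at least one variable")
    id_col = raw.columns[0]
    ids = raw[id_col].astype(str).str.strip()
    if ids.duplicated().any():
        raise ValueError(f"duplicate specimen id(s): {sorted(ids[ids.duplicated()])}")
    labels = None
    var_cols = list(raw.columns[1:])
    if var_cols and var_cols[0].strip().lower() == _LABEL_COL:
        labels = raw[var_cols[0]].astype(str).tolist()
        var_cols = var_cols[1:]
    if not var_cols:
        raise ValueError("measurement table has no measurement variables")

    values = np.full((len(raw), len(var_cols)), np.nan)
    for j, col in enumerate(var_cols):
        for i, cell in enumerate(raw[col]):
            s = str(cell).strip()
            if s.lower() in _NA_SPELLINGS:
                continue
            try:
                values[i, j] = float(s)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {s!r} at specimen {ids.iloc[i]!r}, variable {col!r}"
                ) from None
    df = pd.DataFrame(values, index=ids.tolist(), columns=[c.strip() for c in var_cols])
    return MeasurementMatrix(df, labels, angle_variables)


def write_measurements(m: MeasurementMatrix, path=None) -> str:
    df = m.data.copy()
    out = pd.DataFrame(index=df.index)
    out.index.name = _TAXON_COL
    if any(m.taxon_labels):
        out[_LABEL_COL] = m.taxon_labels
    for c in df.columns:
        out[c] = df[c]
    text = out.to_csv(na_rep="")
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# character matrices (NEXUS / TNT / CSV)
# ---------------------------------------------------------------------------

def read_characters(source, dialect: str) -> CharacterMatrix:
    """Read a taxa-by-characters matrix in one of three dialects.

    "?" maps to MISSING, "-" (or a true minus sign) to INAPPLICABLE.
    """
    text = _as_text(source)
    dialect = dialect.lower()
    if dialect == "nexus":
        return _read_nexus(text)
    if dialect == "tnt":
        return _read_tnt(text)
    if dialect == "csv":
        return _read_char_csv(text)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_characters(m: CharacterMatrix, dialect: str, path=None) -> str:
    dialect = dialect.lower()
    if dialect == "nexus":
        text = _write_nexus(m)
    elif dialect == "tnt":
        text = _write_tnt(m)
    elif dialect == "csv":
        text = _write_char_csv(m)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if path is not None:
        Path(path).write_text(text)
    return text


def _quote_taxon(name: str) -> str:
    return name.replace(" ", "_")


def _rows_to_matrix(names, rows, declared_ntax=None, declared_nchar=None) -> CharacterMatrix:
    if declared_ntax is not None and len(names) != declared_ntax:
        raise ValueError(f"taxon count {len(names)} does not match declared ntax {declared_ntax}")
    nchar = {len(r) for r in rows}
    if len(nchar) != 1:
        raise ValueError("rows have unequal character counts")
    nchar = nchar.pop()
    if declared_nchar is not None and nchar != declared_nchar:
        raise ValueError(f"character count {nchar} does not match declared nchar {declared_nchar}")
    cells = np.empty((len(names), nchar), dtype=np.int8)
    for i, row in enumerate(rows):
        for j, sym in enumerate(row):
            cells[i, j] = parse_symbol(sym)
    return CharacterMatrix(names, cells)


def _read_nexus(text: str) -> CharacterMatrix:
    dataset = dendropy.DataSet.get(data=text, schema="nexus")
    if not dataset.char_matrices:
        raise ValueError("no character matrix found in NEXUS input")
    cm = dataset.char_matrices[0]
    names, rows = [], []
    for taxon in cm.taxon_namespace:
        seq = cm[taxon]
        names.append(taxon.label)
        rows.append([str(s.symbol) for s in seq])
    return _rows_to_matrix(names, rows)


def _write_nexus(m: CharacterMatrix) -> str:
    width = max(len(_quote_taxon(t)) for t in m.taxon_names) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_characters};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="0 1 2 3 4" MISSING=? GAP=-;',
        "    MATRIX",
    ]
    for i, name in enumerate(m.taxon_names):
        row = "".join(state_symbol(c) for c in m.cells[i])
        lines.append(f"        {_quote_taxon(name):<{width}}{row}")
    lines += ["    ;", "END;", ""]
    return "\n".join(lines)


def _read_tnt(text: str) -> CharacterMatrix:
    body = re.sub(r"'[^']*'", "", text)  # strip quoted title
    mo = re.search(r"xread\s+(\d+)\s+(\d+)\s*(.*?);", body, re.S | re.I)
    if mo is None:
        raise ValueError("no xread block found in TNT input")
    nchar, ntax = int(mo.group(1)), int(mo.group(2))
    names, rows = [], []
    for line in mo.group(3).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"malformed TNT matrix row: {line!r}")
        names.append(parts[0].replace("_", " "))
        rows.append(list(parts[1].replace(" ", "")))
    return _rows_to_matrix(names, rows, declared_ntax=ntax, declared_nchar=nchar)


def _write_tnt(m: CharacterMatrix) -> str:
    width = max(len(_quote_taxon(t)) for t in m.taxon_names) + 2
    lines = ["xread", f"{m.n_characters} {m.n_taxa}"]
    for i, name in enumerate(m.taxon_names):
        row = "".join(state_symbol(c) for c in m.cells[i])
        lines.append(f"{_quote_taxon(name):<{width}}{row}")
    lines += [";", "proc /;", ""]
    return "\n".join(lines)


def _read_char_csv(text: str) -> CharacterMatrix:
    raw = pd.read_csv(_io.StringIO(text), dtype=str, keep_default_na=False, index_col=0)
    names = [str(n) for n in raw.index]
    rows = [[str(raw.iloc[i, j]) for j in range(raw.shape[1])] for i in range(raw.shape[0])]
    return _rows_to_matrix(names, rows)


def _write_char_csv(m: CharacterMatrix) -> str:
    df = m.to_frame()
    df.index.name = _TAXON_COL
    return df.to_csv()


# ---------------------------------------------------------------------------
# trees (Newick)
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, with_annotations: bool = True, path=None) -> str:
    """Serialise a tree as Newick.

    Internal-node support/frequency annotations (stored as the node label)
    are written in the label position, e.g. ``(A,B)98:1.0``.  Every leaf
    must be labelled.
    """
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("unlabeled leaf in tree")
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_internal_node_labels=not with_annotations,
        unquoted_underscores=True,
    ).strip() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_newick(source) -> dendropy.Tree:
    text = _as_text(source)
    return dendropy.Tree.get(data=text, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
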
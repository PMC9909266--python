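"""Readers and writers for the tabular inputs and tree outputs.

All tabular formats are delimited text (UTF-8), comma- or tab-separated
with the dialect auto-detected from the file extension (``.tsv``/``.tab``
-> tab, anything else -> comma). Band matrices and trait tables carry
their column metadata in ``#``-prefixed annotation rows immediately after
the header:

* band matrix: ``#primer`` row assigning every band to its primer;
* trait table: ``#type`` row (quantitative/qualitative) and an optional
  ``#levels`` row with ``|``-separated ordered level lists.

Missing values use a configurable token (default ``NA``). Trees are
written as standard Newick with ultrametric branch lengths, so the path
length between two leaves equals their cophenetic distance (a merge at
height h places the node at depth h/2).
"""

from __future__ import annotations

import csv
import io
import os
from decimal import ROUND_HALF_UP, Decimal

import dendropy
import numpy as np
import pandas as pd

from .errors import AlphabetError, EncodingError, FormatError
from .tables import (
    QUALITATIVE,
    QUANTITATIVE,
    BandMatrix,
    ColorTable,
    PrimerPanel,
    PrimerRecord,
    TraitTable,
)
from .tree import Dendrogram

DEFAULT_MISSING = "NA"

_VALID_BASES = frozenset("ACGT")


def _delimiter(path) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    return "\t" if ext in (".tsv", ".tab") else ","


def gc_content(seq: str) -> float:
    """GC percentage of a primer sequence, half-up rounded to one decimal.

    Parameters
    ----------
    seq : str
        Non-empty nucleotide sequence over {A, C, G, T} (case-insensitive).

    Returns
    -------
    float
        100 * (#G + #C) / len(seq), rounded half-up to one decimal, the
        convention under which every printed GC% in standard primer tables
        is reproduced exactly.
    """
    s = seq.strip().upper()
    if not s:
        raise AlphabetError("empty sequence")
    bad = set(s) - _VALID_BASES
    if bad:
        raise AlphabetError(f"invalid nucleotide characters: {sorted(bad)}")
    raw = 100.0 * (s.count("G") + s.count("C")) / len(s)
    return float(Decimal(repr(raw)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------- band matrix


def read_band_matrix(source, missing_code: str = DEFAULT_MISSING) -> BandMatrix:
    """Read a genotypes x bands 0/1 matrix with its ``#primer`` row.

    ``source`` is a path or open text handle. The first column holds
    genotype ids, the header row band ids; a ``#primer`` annotation row
    (or a ``primer_map`` passed to the writer) assigns bands to primers.
    """
    rows, delim = _read_rows(source)
    if len(rows) < 2:
        raise FormatError("band matrix file has no data rows")
    header = rows[0]
    band_ids = [c.strip() for c in header[1:]]
    primer_row = None
    data_rows = []
    for row in rows[1:]:
        if row and row[0].strip() == "#primer":
            primer_row = [c.strip() for c in row[1:]]
        elif row and row[0].strip().startswith("#"):
            continue
        elif row:
            data_rows.append(row)
    if primer_row is None:
        raise FormatError("band matrix file lacks a '#primer' assignment row")
    if len(primer_row) != len(band_ids):
        raise FormatError("'#primer' row length does not match band count")
    primer_of_band = dict(zip(band_ids, primer_row))

    genotype_ids = []
    calls = np.empty((len(data_rows), len(band_ids)))
    for i, row in enumerate(data_rows):
        if len(row) != len(band_ids) + 1:
            raise FormatError(f"row {row[0]!r}: expected {len(band_ids) + 1} fields")
        genotype_ids.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell == missing_code:
                calls[i, j] = np.nan
            elif cell in ("0", "1"):
                calls[i, j] = float(cell)
            else:
                raise EncodingError(
                    f"non-binary band call {cell!r} at genotype "
                    f"{genotype_ids[-1]!r}, band {band_ids[j]!r}"
                )
    return BandMatrix(genotype_ids, band_ids, primer_of_band, calls)


def write_band_matrix(m: BandMatrix, dest, missing_code: str = DEFAULT_MISSING) -> None:
    delim = _delimiter(dest) if not hasattr(dest, "write") else ","
    with _open_out(dest) as fh:
        w = csv.writer(fh, delimiter=delim, lineterminator="\n")
        w.writerow(["genotype", *m.band_ids])
        w.writerow(["#primer", *[m.primer_of_band[b] for b in m.band_ids]])
        for i, g in enumerate(m.genotype_ids):
            cells = [
                missing_code if np.isnan(v) else str(int(v)) for v in m.calls[i]
            ]
            w.writerow([g, *cells])


# ---------------------------------------------------------------- trait table


def read_trait_table(source, missing_code: str = DEFAULT_MISSING) -> TraitTable:
    rows, _ = _read_rows(source)
    if len(rows) < 3:
        raise FormatError("trait table needs header, #type row and data rows")
    header = rows[0]
    variables = [c.strip() for c in header[1:]]
    type_row = None
    level_row = None
    data_rows = []
    for row in rows[1:]:
        tag = row[0].strip() if row else ""
        if tag == "#type":
            type_row = [c.strip() for c in row[1:]]
        elif tag == "#levels":
            level_row = [c.strip() for c in row[1:]]
        elif tag.startswith("#"):
            continue
        elif row:
            data_rows.append(row)
    if type_row is None:
        raise FormatError("trait table lacks a '#type' row")
    if len(type_row) != len(variables):
        raise FormatError("'#type' row length does not match variable count")
    var_types = {}
    for var, t in zip(variables, type_row):
        if t not in (QUANTITATIVE, QUALITATIVE):
            raise FormatError(f"variable {var!r}: unknown type {t!r}")
        var_types[var] = t
    levels = {}
    if level_row is not None:
        for var, spec in zip(variables, level_row):
            if spec:
                levels[var] = spec.split("|")

    genotype_ids = [r[0].strip() for r in data_rows]
    raw = {}
    for j, var in enumerate(variables):
        col = []
        for r in data_rows:
            cell = r[j + 1].strip()
            if cell == missing_code or cell == "":
                col.append(np.nan if var_types[var] == QUANTITATIVE else None)
            elif var_types[var] == QUANTITATIVE:
                try:
                    col.append(float(cell))
                except ValueError as exc:
                    raise EncodingError(
                        f"non-numeric value {cell!r} for quantitative "
                        f"variable {var!r}"
                    ) from exc
            else:
                col.append(cell)
        raw[var] = col
    values = pd.DataFrame(raw, index=genotype_ids)
    return TraitTable(values, var_types, levels)


def write_trait_table(t: TraitTable, dest, missing_code: str = DEFAULT_MISSING) -> None:
    delim = _delimiter(dest) if not hasattr(dest, "write") else ","
    variables = list(t.values.columns)
    with _open_out(dest) as fh:
        w = csv.writer(fh, delimiter=delim, lineterminator="\n")
        w.writerow(["genotype", *variables])
        w.writerow(["#type", *[t.var_types[v] for v in variables]])
        w.writerow(
            ["#levels", *["|".join(t.levels.get(v, [])) for v in variables]]
        )
        for g in t.values.index:
            cells = []
            for v in variables:
                val = t.values.at[g, v]
                if pd.isna(val):
                    cells.append(missing_code)
                elif t.var_types[v] == QUANTITATIVE:
                    cells.append(repr(float(val)))
                else:
                    cells.append(str(val))
            w.writerow([g, *cells])


# ---------------------------------------------------------------- color table


def read_color_table(source) -> ColorTable:
    delim = _delimiter(source) if not hasattr(source, "read") else ","
    df = pd.read_csv(source, sep=delim)
    return ColorTable(df)


def write_color_table(t: ColorTable, dest) -> None:
    delim = _delimiter(dest) if not hasattr(dest, "write") else ","
    t.data.to_csv(dest, sep=delim, index=False)


# ---------------------------------------------------------------- primer panel


def read_primer_panel(source) -> PrimerPanel:
    rows, _ = _read_rows(source)
    if not rows:
        raise FormatError("empty primer file")
    header = [c.strip().lower() for c in rows[0]]
    if "primer" not in header or "sequence" not in header:
        raise FormatError("primer file needs 'primer' and 'sequence' columns")
    i_name = header.index("primer")
    i_seq = header.index("sequence")
    i_ann = header.index("annotation") if "annotation" in header else None
    records = []
    for row in rows[1:]:
        if not row or not row[0].strip():
            continue
        ann = row[i_ann].strip() if i_ann is not None and len(row) > i_ann else ""
        records.append(PrimerRecord(row[i_name].strip(), row[i_seq].strip(), ann))
    return PrimerPanel(records)


def write_primer_panel(panel: PrimerPanel, dest) -> None:
    delim = _delimiter(dest) if not hasattr(dest, "write") else ","
    with _open_out(dest) as fh:
        w = csv.writer(fh, delimiter=delim, lineterminator="\n")
        w.writerow(["primer", "sequence", "gc_percent", "annotation"])
        for r in panel:
            w.writerow([r.name, r.sequence, r.gc_percent, r.annotation])


# ---------------------------------------------------------------- newick trees


def write_newick(tree: Dendrogram, dest) -> None:
    """Write an ultrametric Newick file: node at merge height h -> depth h/2."""
    for lab in tree.labels:
        if not str(lab).strip():
            raise FormatError("unlabeled leaf")

    def render(node: int, parent_h: float) -> str:
        length = (parent_h - tree.height(node)) / 2.0
        if node < tree.n_leaves:
            return f"{_quote(tree.labels[node])}:{length:.12g}"
        a, b = tree.children(node)
        h = tree.height(node)
        return f"({render(a, h)},{render(b, h)}):{length:.12g}"

    root = tree.root
    a, b = tree.children(root)
    h = tree.height(root)
    text = f"({render(a, h)},{render(b, h)});\n"
    with _open_out(dest) as fh:
        fh.write(text)


def read_newick(source) -> Dendrogram:
    """Parse an ultrametric binary Newick file back into a Dendrogram."""
    if hasattr(source, "read"):
        data = source.read()
    else:
        with open(source, encoding="utf-8") as fh:
            data = fh.read()
    dt = dendropy.Tree.get(data=data, schema="newick")
    root = dt.seed_node

    heights: dict = {}

    def depth_below(node) -> float:
        """Ultrametric depth from node down to its leaves; checks binarity."""
        ch = node.child_nodes()
        if not ch:
            heights[node] = 0.0
            return 0.0
        if len(ch) != 2:
            raise FormatError("tree is not binary")
        d0 = depth_below(ch[0]) + (ch[0].edge.length or 0.0)
        depth_below(ch[1])
        heights[node] = 2.0 * d0
        return d0

    depth_below(root)

    leaves = [lf for lf in root.leaf_iter()]
    labels = tuple(lf.taxon.label if lf.taxon else "" for lf in leaves)
    if any(not lab for lab in labels):
        raise FormatError("unlabeled leaf in Newick input")
    leaf_index = {id(lf): i for i, lf in enumerate(leaves)}

    internals = [nd for nd in root.postorder_iter() if nd.child_nodes()]
    internals.sort(key=lambda nd: heights[nd])  # stable: children before parents
    node_id: dict[int, int] = dict(leaf_index)
    for lf in leaves:
        node_id[id(lf)] = leaf_index[id(lf)]
    merges = []
    n = len(leaves)
    for k, nd in enumerate(internals):
        a, b = nd.child_nodes()
        merges.append((node_id[id(a)], node_id[id(b)], heights[nd]))
        node_id[id(nd)] = n + k
    return Dendrogram(labels, tuple(merges))


# ---------------------------------------------------------------- helpers


def _quote(label: str) -> str:
    if any(c in label for c in "(),:;'\" \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _read_rows(source):
    if hasattr(source, "read"):
        text = source.read()
        delim = "\t" if "\t" in text.splitlines()[0] else ","
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
        delim = _delimiter(source)
    rows = [r for r in csv.reader(io.StringIO(text), delimiter=delim) if r]
    return rows, delim


class _open_out:
    """Context manager accepting either a path or an open text handle."""

    def __init__(self, dest):
        self.dest = dest
        self.fh = None
        self.owns = False

    def __enter__(self):
        if hasattr(self.dest, "write"):
            self.fh = self.dest
        else:
            self.fh = open(self.dest, "w", encoding="utf-8", newline="")
            self.owns = True
        return self.fh

    def __exit__(self, *exc):
        if self.owns:
            self.fh.close()
        return False
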
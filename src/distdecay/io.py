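"""Readers and writers for on-disk artifacts.

Supported formats:

* count tables — mothur ``.shared``-style TSV (``label  Group  numOtus  taxon...``)
  and plain wide TSV (first column sample id, header of taxon ids);
* taxonomy — mothur ``.taxonomy``-style two-column TSV with semicolon-delimited
  lineages, optional ``(bootstrap)`` annotations stripped on load;
* study design — sample and facility metadata TSVs;
* trees — newick with branch lengths (via scikit-bio);
* distance matrices — labelled square TSV and phylip lower-triangle dialects.

All loaders validate the data-model invariants on entry, so downstream code
never re-checks them.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .model import (
    RANKS,
    UNCLASSIFIED,
    CountTable,
    DataModelError,
    StudyDesign,
    as_distance_matrix,
)

_BOOTSTRAP_RE = re.compile(r"\(\d+(?:\.\d+)?\)")


class LoadError(DataModelError):
    """Raised when an on-disk artifact cannot be parsed."""


# ---------------------------------------------------------------------------
# count tables + taxonomy
# ---------------------------------------------------------------------------

def parse_lineage(raw: str) -> tuple[str, ...]:
    """Parse a semicolon-delimited lineage, stripping bootstrap annotations.

    ``"Bacteria(100);Proteobacteria(98);"`` → ``("Bacteria", "Proteobacteria",
    "unclassified", ...)`` padded/truncated to the six standard ranks.
    """
    cleaned = _BOOTSTRAP_RE.sub("", raw.strip())
    parts = [p.strip() for p in cleaned.split(";") if p.strip()]
    parts = parts[: len(RANKS)]
    parts += [UNCLASSIFIED] * (len(RANKS) - len(parts))
    return tuple(parts)


def load_taxonomy(path: str | Path) -> pd.DataFrame:
    """Load a two-column (taxon TAB lineage) taxonomy TSV."""
    rows = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.lower().startswith(("otu\t", "taxon\t")):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise LoadError(f"{path}: line {lineno}: expected 2 columns")
            rows[fields[0]] = parse_lineage(fields[1])
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))


def load_count_table(
    path: str | Path,
    dialect: str = "wide_tsv",
    taxonomy_path: str | Path | None = None,
) -> CountTable:
    """Load a count table in ``mothur_shared`` or ``wide_tsv`` dialect.

    Taxa absent from the taxonomy file (or when no taxonomy is given) get an
    all-``unclassified`` lineage.  Duplicate sample ids, non-integer counts
    and an inconsistent ``numOtus`` column are load errors naming the line.
    """
    path = Path(path)
    if dialect == "mothur_shared":
        counts = _read_mothur_shared(path)
    elif dialect == "wide_tsv":
        counts = _read_wide_tsv(path)
    else:
        raise LoadError(f"unknown count-table dialect: {dialect!r}")

    if taxonomy_path is not None:
        lineages = load_taxonomy(taxonomy_path)
    else:
        lineages = pd.DataFrame(columns=list(RANKS))
    table = CountTable(counts, lineages)
    if (table.totals() == 0).any():
        bad = table.totals().idxmin()
        raise LoadError(f"{path}: sample {bad!r} has zero total count")
    return table


def _check_counts(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.index[vals.isna()][0]
            raise LoadError(f"{path}: non-numeric count for sample {bad!r}, taxon {col!r}")
        if not np.allclose(vals, np.round(vals)):
            bad = df.index[~np.isclose(vals, np.round(vals))][0]
            raise LoadError(f"{path}: non-integer count for sample {bad!r}, taxon {col!r}")
        df[col] = vals.astype(np.int64)
    return df


def _read_mothur_shared(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.lower() for h in header[:3]] != ["label", "group", "numotus"]:
            raise LoadError(f"{path}: not a mothur shared file (header {header[:3]})")
        taxa = header[3:]
        rows, index = [], []
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            sample = fields[1]
            n_otus = int(fields[2])
            if n_otus != len(taxa) or len(fields) - 3 != len(taxa):
                raise LoadError(
                    f"{path}: line {lineno}: numOtus={n_otus} inconsistent "
                    f"with {len(fields) - 3} count columns ({len(taxa)} taxa in header)"
                )
            if sample in index:
                raise LoadError(f"{path}: line {lineno}: duplicate sample id {sample!r}")
            index.append(sample)
            rows.append(fields[3:])
    df = pd.DataFrame(rows, index=index, columns=taxa)
    return _check_counts(df, path)


def _read_wide_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        line = list(df.index).index(dup) + 3  # header + first occurrence
        raise LoadError(f"{path}: line {line}: duplicate sample id {dup!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return _check_counts(df, path)


def write_count_table(table: CountTable, path: str | Path,
                      taxonomy_path: str | Path | None = None) -> None:
    """Write a wide TSV count table (and optionally its taxonomy TSV)."""
    out = table.counts.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
    if taxonomy_path is not None:
        lineage = table.lineage_strings()
        with open(taxonomy_path, "w") as fh:
            for taxon, lin in lineage.items():
                fh.write(f"{taxon}\t{lin};\n")


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

def month_index(year: int, month: int, y0: int, m0: int) -> int:
    """Convert a calendar (year, month) to a 0-based study month index."""
    return (year - y0) * 12 + (month - m0)


def load_study_design(sample_meta_path: str | Path,
                      facility_meta_path: str | Path) -> StudyDesign:
    """Load sample and facility metadata TSVs into a StudyDesign.

    The sample table needs ``sample_id``, ``facility``, ``bioreactor``,
    ``month``; the facility table needs ``facility``, ``latitude``,
    ``longitude``.  Any further facility columns are captured by name as
    environmental variables; blank cells become missing values (NaN).
    """
    samples = pd.read_csv(sample_meta_path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "facility", "bioreactor", "month"):
        if col not in samples.columns:
            raise LoadError(f"{sample_meta_path}: missing column {col!r}")
    samples = samples.set_index("sample_id")
    samples["month"] = samples["month"].astype(int)

    facilities = pd.read_csv(facility_meta_path, sep="\t")
    if "facility" not in facilities.columns:
        raise LoadError(f"{facility_meta_path}: missing column 'facility'")
    facilities = facilities.set_index("facility")
    for col in facilities.columns:
        facilities[col] = pd.to_numeric(facilities[col], errors="coerce")
    return StudyDesign(samples, facilities)


def write_study_design(design: StudyDesign, sample_meta_path: str | Path,
                       facility_meta_path: str | Path) -> None:
    s = design.samples.copy()
    s.index.name = "sample_id"
    s.to_csv(sample_meta_path, sep="\t")
    f = design.facilities.copy()
    f.index.name = "facility"
    f.to_csv(facility_meta_path, sep="\t")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def load_tree(path: str | Path) -> TreeNode:
    """Load a rooted newick tree, checking leaf uniqueness and branch lengths."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise LoadError(f"{path}: unparseable newick: {exc}") from exc
    names = [tip.name for tip in tree.tips()]
    if len(names) != len(set(names)):
        dup = next(n for n in names if names.count(n) > 1)
        raise LoadError(f"{path}: duplicate leaf name {dup!r}")
    for node in tree.traverse(include_self=False):
        if node.length is not None and (not np.isfinite(node.length) or node.length < 0):
            raise LoadError(f"{path}: negative or non-finite branch length on {node.name!r}")
    return tree


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def write_square_matrix(m: DistanceMatrix, path: str | Path) -> None:
    """Write a labelled square TSV at 10 significant digits."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(m.ids) + "\n")
        for i, label in enumerate(m.ids):
            row = "\t".join(format(v, ".10g") for v in m.data[i])
            fh.write(f"{label}\t{row}\n")


def load_square_matrix(path: str | Path, tol: float = 1e-9) -> DistanceMatrix:
    """Read a square TSV or phylip lower-triangle distance matrix."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.strip() and len(first.split()) == 1 and first.split()[0].isdigit():
        return _read_phylip_lower(path, tol)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise LoadError(f"{path}: row and column labels differ")
    return as_distance_matrix(df.to_numpy(float), [str(x) for x in df.index], tol=tol)


def _read_phylip_lower(path: Path, tol: float) -> DistanceMatrix:
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        labels, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            fields = line.split()
            labels.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    if len(labels) != n:
        raise LoadError(f"{path}: header says {n} entities, found {len(labels)}")
    full = np.zeros((n, n))
    for i, row in enumerate(rows):
        if len(row) != i:
            raise LoadError(f"{path}: row {labels[i]!r} has {len(row)} entries, expected {i}")
        full[i, :i] = row
    full = full + full.T
    return as_distance_matrix(full, labels, tol=tol)


def write_phylip_lower(m: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(m.ids)}\n")
        for i, label in enumerate(m.ids):
            vals = " ".join(format(v, ".10g") for v in m.data[i, :i])
            fh.write(f"{label} {vals}".rstrip() + "\n")
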
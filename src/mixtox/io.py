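"""Readers and writers for the package's delimited-text formats.

Conventions (bit-exact): tab-separated values, '.' decimal separator, 'NA'
as the missing marker, UTF-8, one header row.  Annotation maps use the GMT
layout (term, description, tab-separated member ids).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import AnnotationMap
from .errors import ValidationError
from .synthetic import PeptideCountMatrix

__all__ = [
    "read_endpoint_table",
    "write_endpoint_table",
    "read_count_matrix",
    "write_count_matrix",
    "read_gmt",
    "write_gmt",
    "read_id_list",
    "write_id_list",
]

NA = "NA"


def read_endpoint_table(path, known_groups=None) -> pd.DataFrame:
    """Read a subject/group/value endpoint table.

    Raises with the offending row number on non-numeric values and, when
    ``known_groups`` is given, on unknown group labels.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"subject", "group", "value"} - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path.name}: missing column(s) {sorted(missing)}"
        )
    values = []
    for i, raw in enumerate(df["value"], start=2):  # header is line 1
        try:
            v = float(raw)
        except ValueError:
            raise ValidationError(
                f"{path.name}: non-numeric value {raw!r} at line {i}"
            ) from None
        if not np.isfinite(v):
            raise ValidationError(f"{path.name}: non-finite value at line {i}")
        values.append(v)
    if known_groups is not None:
        known = set(known_groups)
        for i, g in enumerate(df["group"], start=2):
            if g not in known:
                raise ValidationError(
                    f"{path.name}: unknown group {g!r} at line {i}"
                )
    out = pd.DataFrame(
        {"subject": df["subject"], "group": df["group"], "value": values}
    )
    return out


def write_endpoint_table(table: pd.DataFrame, path) -> None:
    table[["subject", "group", "value"]].to_csv(
        path, sep="\t", index=False, na_rep=NA
    )


def read_count_matrix(path, map_path, design_path) -> PeptideCountMatrix:
    """Assemble a PeptideCountMatrix from matrix + peptide map + design TSVs.

    The matrix has peptides in rows (first column ``peptide``) and samples
    in columns; empty cells and 'NA' parse as missing.  The map has columns
    ``peptide``, ``protein``; the design ``sample``, ``condition``,
    ``biorep``.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA, ""])
    counts.index.name = None
    pmap_df = pd.read_csv(map_path, sep="\t", dtype=str)
    design = pd.read_csv(design_path, sep="\t", dtype={"sample": str, "condition": str})
    for col in ("peptide", "protein"):
        if col not in pmap_df.columns:
            raise ValidationError(f"peptide map missing column '{col}'")
    for col in ("sample", "condition", "biorep"):
        if col not in design.columns:
            raise ValidationError(f"design missing column '{col}'")
    pmap = pd.Series(
        pmap_df["protein"].to_numpy(), index=pmap_df["peptide"], name="protein"
    )
    orphans = sorted(set(counts.index) - set(pmap.index))
    if orphans:
        raise ValidationError(f"peptides without protein mapping: {orphans[:10]}")
    stray = sorted(set(counts.columns) - set(design["sample"]))
    if stray:
        raise ValidationError(f"samples absent from design: {stray[:10]}")
    return PeptideCountMatrix(counts, pmap.loc[counts.index], design)


def write_count_matrix(matrix: PeptideCountMatrix, path, map_path, design_path) -> None:
    out = matrix.counts.copy()
    out.index.name = "peptide"
    out.to_csv(path, sep="\t", na_rep=NA)
    pd.DataFrame(
        {"peptide": matrix.protein_map.index, "protein": matrix.protein_map.to_numpy()}
    ).to_csv(map_path, sep="\t", index=False)
    matrix.design.to_csv(design_path, sep="\t", index=False)


def read_gmt(path, universe=None) -> AnnotationMap:
    """Read a GMT annotation file (term, description, members...).

    When ``universe`` is omitted it defaults to the union of all members.
    """
    terms: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(
                f"GMT line {lineno}: expected term, description and >=1 member"
            )
        term, desc, *members = parts
        members = [m for m in members if m]
        if not members:
            raise ValidationError(f"GMT line {lineno}: term '{term}' has no members")
        terms[term] = frozenset(members)
        names[term] = desc
    if universe is None:
        universe = frozenset().union(*terms.values()) if terms else frozenset()
    return AnnotationMap(terms=terms, names=names, universe=frozenset(universe))


def write_gmt(annotation: AnnotationMap, path) -> None:
    lines = []
    for term in sorted(annotation.terms):
        members = "\t".join(sorted(annotation.terms[term]))
        lines.append(f"{term}\t{annotation.names.get(term, '')}\t{members}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_id_list(path) -> list[str]:
    """One identifier per line; blank lines ignored."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_id_list(ids, path) -> None:
    ids = [str(i) for i in ids]
    Path(path).write_text("\n".join(ids) + ("\n" if ids else ""))
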
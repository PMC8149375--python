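"""Readers and writers for the pipeline's plain-text formats.

Long-format dose CSV, 6 x 8 dose-matrix CSV with dose-0 margins, counts and
design TSV, GMT annotation sets (with a +/- member-suffix convention for
regulon modes), RNK ranked lists, and SIF / TSV edge lists.  All writers use
UTF-8, LF line endings and dot decimals so repeated runs are byte-identical,
and every writer has a paired reader that round-trips to an equal structure.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dose_response import DoseSeries
from .enrichment import AnnotationSet, RankedList
from .errors import SchemaError
from .synergy import DoseMatrix

__all__ = [
    "read_dose_table", "write_dose_table", "group_series_pairs",
    "read_dose_matrix", "write_dose_matrix",
    "read_gmt", "write_gmt", "read_rnk", "write_rnk",
    "read_edge_list", "write_sif", "write_tsv",
]

DOSE_COLUMNS = ["drug_id", "cell_line", "condition", "dose_molar", "replicate", "viability"]


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    """Deterministic TSV: UTF-8, LF, dot decimal, repr-precision floats."""
    df.to_csv(path, sep="\t", index=index, lineterminator="\n", encoding="utf-8")


def read_dose_table(path) -> list[DoseSeries]:
    """Parse a long-format dose CSV into validated dose series.

    Required columns: drug_id, cell_line, condition, dose_molar, replicate,
    viability.  Replicates are averaged per dose.  Duplicate
    (drug, line, condition, dose, replicate) rows and non-numeric doses are
    rejected with the offending row named.
    """
    df = pd.read_csv(path)
    missing = [c for c in DOSE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in ("dose_molar", "viability"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based incl. header
            raise SchemaError(f"{path}: non-numeric {col} at line {row}")
        df[col] = pd.to_numeric(df[col])
    key = ["drug_id", "cell_line", "condition", "dose_molar", "replicate"]
    dup = df.duplicated(subset=key)
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise SchemaError(f"{path}: duplicate measurement row at line {row}")
    series = []
    group_cols = ["drug_id", "cell_line", "condition"]
    for (drug, line, cond), sub in df.groupby(group_cols, sort=True):
        avg = sub.groupby("dose_molar", sort=True)["viability"].mean()
        series.append(DoseSeries(str(drug), str(line), str(cond),
                                 avg.index.to_numpy(), avg.to_numpy()))
    return series


def write_dose_table(series: list[DoseSeries], path) -> None:
    rows = []
    for s in series:
        for d, v in zip(s.doses, s.viability):
            rows.append({"drug_id": s.drug_id, "cell_line": s.cell_line,
                         "condition": s.condition, "dose_molar": d,
                         "replicate": 1, "viability": v})
    pd.DataFrame(rows, columns=DOSE_COLUMNS).to_csv(
        path, index=False, lineterminator="\n", encoding="utf-8")


def group_series_pairs(series: list[DoseSeries]) -> dict[tuple[str, str], tuple[DoseSeries, DoseSeries]]:
    """Group a series list into (single, combo) pairs keyed by (drug, line)."""
    by_key: dict[tuple[str, str], dict[str, DoseSeries]] = {}
    for s in series:
        by_key.setdefault((s.drug_id, s.cell_line), {})[s.condition] = s
    pairs = {}
    for key, conds in sorted(by_key.items()):
        if "alone" in conds and "plus_anchor" in conds:
            pairs[key] = (conds["alone"], conds["plus_anchor"])
    return pairs


def write_dose_matrix(matrix: DoseMatrix, path) -> None:
    """CSV layout: first row drug doses with a leading 0, first column anchor
    doses with a leading 0; the dose-0 row/column hold single-agent margins
    and cell (0, 0) is 0."""
    grid = np.zeros((len(matrix.anchor_doses) + 1, len(matrix.drug_doses) + 1))
    grid[0, 1:] = matrix.drug_alone
    grid[1:, 0] = matrix.anchor_alone
    grid[1:, 1:] = matrix.inhibition
    df = pd.DataFrame(grid,
                      index=[0.0, *matrix.anchor_doses],
                      columns=[0.0, *matrix.drug_doses])
    df.index.name = f"{matrix.combination_id}|{matrix.cell_line}"
    df.to_csv(path, lineterminator="\n", encoding="utf-8")


def read_dose_matrix(path) -> DoseMatrix:
    df = pd.read_csv(path, index_col=0)
    name = df.index.name or "matrix|unknown"
    comb_id, _, line = name.partition("|")
    try:
        anchor_doses = df.index.to_numpy(dtype=float)
        drug_doses = df.columns.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: dose axes must be numeric ({exc})") from exc
    if anchor_doses[0] != 0 or drug_doses[0] != 0:
        raise SchemaError(f"{path}: first row/column must be the dose-0 margins")
    vals = df.to_numpy(dtype=float)
    return DoseMatrix(comb_id or "matrix", line or "unknown",
                      anchor_doses[1:], drug_doses[1:], vals[1:, 1:],
                      vals[1:, 0], vals[0, 1:])


def read_gmt(path) -> dict[str, AnnotationSet]:
    """GMT parser: name, description, then members.

    A trailing ``+`` or ``-`` on a member encodes the regulon mode (+1 / -1);
    unsuffixed members default to +1 and the modes dict is omitted when no
    member carries a suffix.  Empty set lines and duplicate members raise
    with the line number.
    """
    sets: dict[str, AnnotationSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"{path}:{lineno}: empty set line (no members)")
            name = parts[0]
            if name in sets:
                raise SchemaError(f"{path}:{lineno}: duplicate set name {name!r}")
            members, modes, any_mode = [], {}, False
            for raw in parts[2:]:
                raw = raw.strip()
                if not raw:
                    continue
                if raw[-1] in "+-" and len(raw) > 1:
                    member, mode = raw[:-1], (1 if raw[-1] == "+" else -1)
                    any_mode = True
                else:
                    member, mode = raw, 1
                if member in modes:
                    raise SchemaError(
                        f"{path}:{lineno}: duplicate member {member!r} in {name!r}")
                members.append(member)
                modes[member] = mode
            if not members:
                raise SchemaError(f"{path}:{lineno}: empty set line (no members)")
            sets[name] = AnnotationSet(name, tuple(members),
                                       modes if any_mode else None)
    return sets


def write_gmt(sets: dict[str, AnnotationSet], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in sets:
            aset = sets[name]
            if aset.modes is None:
                members = list(aset.members)
            else:
                members = [m + ("+" if aset.mode_of(m) == 1 else "-")
                           for m in aset.members]
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_rnk(path) -> RankedList:
    """Two-column RNK (id, score).  Ties keep a stable id order (warned)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "score"],
                     comment="#")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise SchemaError(f"{path}: duplicate identifier {dup!r}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        row = int(df.index[scores.isna()][0]) + 1
        raise SchemaError(f"{path}: non-numeric score at line {row}")
    if scores.duplicated().any():
        warnings.warn(f"{path}: tied scores; order within ties is by identifier")
    return RankedList.from_scores(pd.Series(scores.to_numpy(), index=df["id"]))


def write_rnk(ranked: RankedList, path) -> None:
    pd.DataFrame({"id": ranked.ids, "score": ranked.scores}).to_csv(
        path, sep="\t", header=False, index=False,
        lineterminator="\n", encoding="utf-8")


def read_edge_list(path) -> nx.Graph:
    """SIF ('A interaction B [B2 ...]') or 2/3-column TSV edge list.

    Whitespace-delimited three-field lines are read as (source, type,
    target); two-field lines as (source, target).  Self-loops are dropped
    (count warned); 'A pp B' and 'A<TAB>B' yield the same edge.
    """
    g = nx.Graph()
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) == 1:
                g.add_node(parts[0])
                continue
            if len(parts) == 2:
                src, targets, etype = parts[0], [parts[1]], None
            else:
                src, etype, targets = parts[0], parts[1], parts[2:]
            for dst in targets:
                if src == dst:
                    dropped += 1
                    continue
                if etype is None:
                    g.add_edge(src, dst)
                else:
                    g.add_edge(src, dst, interaction=etype)
    if dropped:
        warnings.warn(f"{path}: dropped {dropped} self-loop(s)")
    return g


def write_sif(g: nx.Graph, path, default_type: str = "pp") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for src, dst, data in sorted(g.edges(data=True)):
            etype = data.get("interaction", default_type)
            fh.write(f"{src}\t{etype}\t{dst}\n")
        for node in sorted(nx.isolates(g)):
            fh.write(f"{node}\n")
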
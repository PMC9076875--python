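"""Reading and writing the delimited community and metadata tables.

Community tables are plots x taxa delimited text (TSV by default, comma
accepted) with a header row of taxon ids and the plot id in the first
column.  Validation failures (negative abundances, duplicated plots,
non-numeric cells) are reported with row/column coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import (
    GROUPS,
    MICROBIAL_GROUPS,
    CommunityTable,
    CommunityTableError,
    PlotFrame,
)
from .simulate import GroundTruth, read_ground_truth

__all__ = [
    "read_community_table",
    "write_community_table",
    "read_plot_frame",
    "read_tables",
    "read_dataset",
    "default_semantics",
]


def default_semantics(group: str) -> str:
    return "cover" if group in ("vascular_plants", "bryophytes") else "count"


def _sniff_sep(path: Path) -> str:
    head = path.open().readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    return df


def read_community_table(
    path: str | Path, group: str, semantics: str | None = None
) -> CommunityTable:
    """Read one group's plots x taxa table with validation."""
    df = _read_delimited(path)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise CommunityTableError(f"{path}: duplicated plot rows {dups}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise CommunityTableError(
                f"{path}: non-numeric cell at plot {bad[0]!r}, taxon {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        r, c = next(zip(*df.isna().to_numpy().nonzero()))
        raise CommunityTableError(
            f"{path}: missing value at plot {df.index[r]!r}, taxon {df.columns[c]!r}"
        )
    neg = df.lt(0)
    if neg.any().any():
        r, c = next(zip(*neg.to_numpy().nonzero()))
        raise CommunityTableError(
            f"{path}: negative abundance at plot {df.index[r]!r}, taxon {df.columns[c]!r}"
        )
    return CommunityTable(df, group, semantics or default_semantics(group))


def write_community_table(table: CommunityTable, path: str | Path, sep: str = "\t") -> None:
    df = table.data.copy()
    df.index.name = "plot_id"
    df.to_csv(path, sep=sep)


def read_plot_frame(path: str | Path) -> PlotFrame:
    """Read the plot metadata table, ordered by gradient index."""
    df = _read_delimited(path)
    pf = PlotFrame(df)
    return PlotFrame(df.sort_values("gradient_index"))


def read_tables(
    paths: dict[str, str | Path],
    metadata_path: str | Path,
    semantics: dict[str, str] | None = None,
) -> tuple[list[CommunityTable], PlotFrame]:
    """Read per-group tables plus metadata, aligned on the gradient order.

    ``paths`` maps group name to file path.  Plot ordering is taken from the
    metadata's gradient index; every table must cover those plots.
    """
    unknown = set(paths) - set(GROUPS)
    if unknown:
        raise CommunityTableError(f"unknown groups {sorted(unknown)}")
    plots = read_plot_frame(metadata_path)
    semantics = semantics or {}
    tables = []
    for g, p in paths.items():
        t = read_community_table(p, g, semantics.get(g))
        tables.append(t.subset(list(plots.plot_ids)))
    tables.sort(key=lambda t: GROUPS.index(t.group))
    return tables, plots


def read_dataset(
    directory: str | Path,
) -> tuple[list[CommunityTable], PlotFrame, GroundTruth | None]:
    """Read a directory written by :func:`multidiv.simulate.write_dataset`."""
    d = Path(directory)
    sem_file = d / "semantics.json"
    semantics = json.loads(sem_file.read_text()) if sem_file.exists() else {}
    paths = {g: d / f"{g}.tsv" for g in GROUPS if (d / f"{g}.tsv").exists()}
    tables, plots = read_tables(paths, d / "plots.tsv", semantics)
    gt = d / "ground_truth.json"
    truth = read_ground_truth(gt) if gt.exists() else None
    return tables, plots, truth
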
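"""Core data containers for multi-taxa community analysis.

A :class:`CommunityTable` holds one organismal group's plots-by-taxa abundance
matrix together with its abundance semantics (sequence counts, percent cover,
or normalised values).  A :class:`PlotFrame` holds the per-plot metadata of the
chronosequence: position along the gradient, time since deglaciation, mean
growth-season soil temperature, and planar coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUPS = ("vascular_plants", "bryophytes", "invertebrates", "fungi", "bacteria")

#: groups whose raw tables are sequence counts (need CSS / rarefaction)
MICROBIAL_GROUPS = ("fungi", "bacteria")

VALID_SEMANTICS = ("count", "cover", "normalized")


class CommunityTableError(ValueError):
    """Raised when a community table violates its invariants."""


@dataclass
class CommunityTable:
    """Plots x taxa abundance matrix for one organismal group.

    Parameters
    ----------
    data
        DataFrame indexed by plot id (gradient order), columns are taxon ids,
        values are non-negative abundances.
    group
        One of :data:`GROUPS`.
    semantics
        ``"count"`` (integer counts), ``"cover"`` (percent cover) or
        ``"normalized"`` (e.g. CSS-scaled counts).
    """

    data: pd.DataFrame
    group: str
    semantics: str = "count"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CommunityTableError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if self.semantics not in VALID_SEMANTICS:
            raise CommunityTableError(
                f"unknown semantics {self.semantics!r}; expected one of {VALID_SEMANTICS}"
            )
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise CommunityTableError(f"{self.group}: non-finite abundances")
        if values.size and (values < 0).any():
            rows, cols = np.nonzero(values < 0)
            raise CommunityTableError(
                f"{self.group}: negative abundance at plot "
                f"{self.data.index[rows[0]]!r}, taxon {self.data.columns[cols[0]]!r}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise CommunityTableError(f"{self.group}: duplicated plot ids {dups}")
        if self.semantics == "count" and values.size:
            if not np.allclose(values, np.round(values)):
                raise CommunityTableError(
                    f"{self.group}: count semantics requires integer abundances"
                )

    @property
    def plot_ids(self) -> pd.Index:
        return self.data.index

    @property
    def taxon_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def abundance(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_plots(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def subset(self, plot_ids) -> "CommunityTable":
        """Restrict the table to ``plot_ids`` (kept in the given order)."""
        missing = [p for p in plot_ids if p not in self.data.index]
        if missing:
            raise CommunityTableError(
                f"{self.group}: plots {missing} absent from table"
            )
        return CommunityTable(self.data.loc[list(plot_ids)], self.group, self.semantics)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return (
            self.group == other.group
            and self.semantics == other.semantics
            and self.data.equals(other.data)
        )


@dataclass
class PlotFrame:
    """Per-plot chronosequence metadata.

    ``data`` is indexed by plot id and carries at least the columns
    ``gradient_index`` (1-based position along the transect), ``age_years``
    (time since deglaciation), ``temperature`` (mean growth-season soil
    temperature, deg C) and ``x_m``/``y_m`` (planar coordinates in metres).
    Optional covariates (``ph``, ``nutrients`` ...) ride along untouched.
    """

    data: pd.DataFrame

    REQUIRED = ("gradient_index", "age_years", "temperature", "x_m", "y_m")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise CommunityTableError(f"plot metadata missing columns {missing}")
        if self.data.index.has_duplicates:
            raise CommunityTableError("plot metadata has duplicated plot ids")

    @property
    def plot_ids(self) -> pd.Index:
        return self.data.index

    @property
    def ages(self) -> np.ndarray:
        return self.data["age_years"].to_numpy(dtype=float)

    @property
    def gradient_index(self) -> np.ndarray:
        return self.data["gradient_index"].to_numpy(dtype=float)

    @property
    def temperature(self) -> np.ndarray:
        return self.data["temperature"].to_numpy(dtype=float)

    @property
    def coords(self) -> np.ndarray:
        return self.data[["x_m", "y_m"]].to_numpy(dtype=float)

    @property
    def n_plots(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, PlotFrame):
            return NotImplemented
        return self.data.equals(other.data)


def align_tables(tables: list[CommunityTable], plots: PlotFrame) -> list[CommunityTable]:
    """Align community tables on the plot ordering of ``plots``.

    Raises :class:`CommunityTableError` listing offending plots when a table
    does not cover the metadata's plot set.
    """
    order = list(plots.plot_ids)
    aligned = []
    for t in tables:
        missing = [p for p in order if p not in t.data.index]
        if missing:
            raise CommunityTableError(
                f"{t.group}: plots {missing[:5]}{'...' if len(missing) > 5 else ''} "
                "missing from community table"
            )
        aligned.append(t.subset(order))
    return aligned
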
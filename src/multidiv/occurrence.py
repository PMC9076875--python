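"""Temporally ordered multi-taxa occurrence table.

For every taxon occurring on enough plots, the abundance optimum (the
abundance-weighted mean plot of occurrence), the range size (the
abundance-weighted variance of occurrence plots), and the rescaled z-score
relative abundance profile are computed; taxa are then ordered along the
gradient by their optima, yielding the community-wide turnover table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MICROBIAL_GROUPS, CommunityTable
from .diversity import EmptyCommunityError, css_normalize

__all__ = [
    "abundance_optimum",
    "rescaled_relative_abundance",
    "range_size",
    "order_community",
    "TaxonProfile",
]


def _weights(abund, positions) -> tuple[np.ndarray, np.ndarray]:
    w = np.asarray(abund, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if w.shape != pos.shape or w.ndim != 1:
        raise ValueError("abundances and positions must be 1-D of equal length")
    if (w < 0).any():
        raise ValueError("negative abundances")
    if w.sum() <= 0:
        raise EmptyCommunityError("taxon absent from every plot")
    return w, pos


def abundance_optimum(abund, positions) -> float:
    """Abundance-weighted mean position of occurrence.

    optimum = sum(w_i * pos_i) / sum(w_i), with the taxon's abundance as the
    weight (cover for plants/bryophytes, counts for invertebrates,
    CSS-normalised reads for microbes).
    """
    w, pos = _weights(abund, positions)
    return float((w * pos).sum() / w.sum())


def range_size(abund, positions) -> float:
    """Abundance-weighted variance of occurrence positions (population-style).

    range = sum w_i (pos_i - optimum)^2 / sum w_i; zero for a taxon confined
    to a single plot, increasing as the same total abundance spreads over a
    wider span of the gradient.
    """
    w, pos = _weights(abund, positions)
    opt = (w * pos).sum() / w.sum()
    return float((w * (pos - opt) ** 2).sum() / w.sum())


def rescaled_relative_abundance(abund) -> np.ndarray:
    """Per-plot z-scores rescaled so the extremes reach +-1.

    z = (x - mean) / sd, then divided by max |z|; the mean abundance maps to 0
    and the most extreme plot to +1 or -1, making profiles comparable across
    taxa of very different absolute abundance.  A constant profile maps to
    all zeros.
    """
    x = np.asarray(abund, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector of at least 2 plots")
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    z = (x - x.mean()) / sd
    return z / np.abs(z).max()


@dataclass(frozen=True)
class TaxonProfile:
    """Gradient profile of one taxon."""

    taxon_id: str
    group: str
    optimum: float
    range_size: float
    n_plots_present: int
    rescaled_z: np.ndarray


def order_community(
    tables: list[CommunityTable],
    positions=None,
    min_plots: int = 3,
    normalize_microbial: bool = True,
) -> pd.DataFrame:
    """Long-format occurrence table ordered by abundance optimum.

    Taxa present (abundance > 0) on fewer than ``min_plots`` plots are
    excluded.  Microbial count tables are CSS-normalised first so read depth
    does not distort the weighting.  Ties in optimum are broken by
    (group, taxon_id).  ``positions`` defaults to 1..n_plots (gradient plot
    index).

    Returns a DataFrame with one row per retained taxon x plot:
    taxon, group, optimum, range_size, n_plots_present, plot, rescaled_z.
    """
    if not tables:
        raise ValueError("no community tables given")
    n = tables[0].n_plots
    pos = (
        np.arange(1, n + 1, dtype=float)
        if positions is None
        else np.asarray(positions, dtype=float)
    )
    profiles: list[TaxonProfile] = []
    for t in tables:
        if t.n_plots != n:
            raise ValueError("tables must be aligned on the same plots")
        tt = t
        if normalize_microbial and t.group in MICROBIAL_GROUPS and t.semantics == "count":
            tt = css_normalize(t)
        a = tt.abundance
        for j, taxon in enumerate(tt.taxon_ids):
            col = a[:, j]
            present = int((col > 0).sum())
            if present < min_plots:
                continue
            profiles.append(
                TaxonProfile(
                    taxon_id=str(taxon),
                    group=tt.group,
                    optimum=abundance_optimum(col, pos),
                    range_size=range_size(col, pos),
                    n_plots_present=present,
                    rescaled_z=rescaled_relative_abundance(col),
                )
            )
    if not profiles:
        warnings.warn(
            f"no taxon occurs on >= {min_plots} plots", RuntimeWarning, stacklevel=2
        )
        return pd.DataFrame(
            columns=[
                "taxon", "group", "optimum", "range_size",
                "n_plots_present", "plot", "rescaled_z",
            ]
        )
    profiles.sort(key=lambda p: (p.optimum, p.group, p.taxon_id))
    plot_ids = list(tables[0].plot_ids)
    rows = []
    for p in profiles:
        for plot, z in zip(plot_ids, p.rescaled_z):
            rows.append(
                {
                    "taxon": p.taxon_id,
                    "group": p.group,
                    "optimum": p.optimum,
                    "range_size": p.range_size,
                    "n_plots_present": p.n_plots_present,
                    "plot": plot,
                    "rescaled_z": float(z),
                }
            )
    return pd.DataFrame(rows)
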
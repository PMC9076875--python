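"""Diversity indices for the multi-taxa chronosequence analysis.

Implements per-group Shannon diversity (optionally under multiple rarefaction
or cumulative-sum-scaling normalisation), the rank-based multidiversity index
mD, and Bray-Curtis based betadiversity and multi-betadiversity (mbD).

Multidiversity aggregates the diversities of several organismal groups into a
single per-plot index: plots are ranked by increasing Shannon diversity within
each group (so every group contributes on the same scale regardless of its
absolute diversity values), the per-plot mean rank is taken across groups, and
the mean ranks are min-max normalised to [0, 1],

    x' = (x - min(x)) / (max(x) - min(x)).

Multi-betadiversity mbD of a plot pair is the unweighted mean of that pair's
Bray-Curtis dissimilarities across the surveyed organismal groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

from .containers import GROUPS, MICROBIAL_GROUPS, CommunityTable, CommunityTableError

__all__ = [
    "shannon",
    "shannon_per_plot",
    "rarefied_shannon",
    "css_normalize",
    "diversity_matrix",
    "multidiversity",
    "MultidiversityVector",
    "bray_curtis",
    "multi_betadiversity",
    "BetaResult",
    "EmptyCommunityError",
    "RarefactionDepthError",
]


class EmptyCommunityError(ValueError):
    """An all-zero abundance vector has no defined diversity."""


class RarefactionDepthError(ValueError):
    """Requested rarefaction depth exceeds at least one plot total."""


class DegenerateNormalizationError(ValueError):
    """All plots have identical mean rank; Eq-style min-max scaling undefined."""


def shannon(abundances) -> float:
    """Shannon diversity H (nats) of one community.

    H = -sum p_i ln p_i over taxa with positive abundance, p_i = x_i / sum x.
    H is zero iff at most one taxon is present and is invariant to rescaling
    all abundances by a positive constant.

    Raises
    ------
    EmptyCommunityError
        If every abundance is zero; the caller decides whether to exclude the
        plot or treat the group as missing.
    """
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 1:
        raise ValueError("shannon expects a 1-D abundance vector")
    if (x < 0).any():
        raise ValueError("negative abundances")
    total = x.sum()
    if total <= 0:
        raise EmptyCommunityError("all-zero community")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_plot(table: CommunityTable) -> pd.Series:
    """Shannon H (nats) for every plot of a community table."""
    return pd.Series(
        [shannon(row) for row in table.abundance],
        index=table.plot_ids,
        name=table.group,
    )


def rarefied_shannon(
    table: CommunityTable,
    depth: int | None = None,
    n_iter: int = 999,
    seed: int | np.random.Generator | None = None,
) -> pd.Series:
    """Mean Shannon diversity under multiple rarefaction.

    Each plot's counts are subsampled without replacement to ``depth``
    individuals (default: the minimum plot total, so every plot can be
    rarefied), Shannon H is computed on each subsample, and the mean over
    ``n_iter`` iterations is returned per plot.  Rarefaction corrects for
    unequal sequencing depth / trapping effort; it is applied to the raw
    counts, not to normalised tables.

    Raises
    ------
    RarefactionDepthError
        If ``depth`` exceeds some plot total; the offending plots are listed.
    """
    if table.semantics != "count":
        raise CommunityTableError(
            f"rarefaction requires count semantics, got {table.semantics!r}"
        )
    counts = np.round(table.abundance).astype(np.int64)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empty = table.plot_ids[totals == 0].tolist()
        raise EmptyCommunityError(f"all-zero plots cannot be rarefied: {empty}")
    if depth is None:
        depth = int(totals.min())
    if depth < 1:
        raise RarefactionDepthError("depth must be >= 1")
    too_shallow = table.plot_ids[totals < depth].tolist()
    if too_shallow:
        raise RarefactionDepthError(
            f"depth {depth} exceeds plot totals for plots {too_shallow}"
        )
    rng = np.random.default_rng(seed)
    means = np.empty(table.n_plots)
    for i, row in enumerate(counts):
        if totals[i] == depth:
            # subsampling at full depth returns the plot itself every time
            means[i] = shannon(row)
            continue
        acc = 0.0
        for _ in range(n_iter):
            sub = rng.multivariate_hypergeometric(row, depth)
            acc += shannon(sub)
        means[i] = acc / n_iter
    return pd.Series(means, index=table.plot_ids, name=table.group)


def css_normalize(table: CommunityTable, quantile: float = 0.5) -> CommunityTable:
    """Cumulative sum scaling (CSS) normalisation of a count table.

    For each plot the scaling factor is the cumulative sum of its counts up to
    the chosen quantile of the plot's positive count distribution; counts are
    divided by that factor and rescaled by the median scaling factor across
    plots so the output stays on a count-like scale.  CSS is robust to the
    preferential amplification of dominant taxa that makes total-sum scaling
    misleading for amplicon data.

    A degenerate table (a single taxon, where the quantile sum equals the
    total) falls back to total-sum scaling with a warning.
    """
    if table.semantics != "count":
        raise CommunityTableError(
            f"CSS normalisation requires count semantics, got {table.semantics!r}"
        )
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    counts = table.abundance
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empty = table.plot_ids[totals == 0].tolist()
        raise EmptyCommunityError(f"all-zero plots cannot be normalised: {empty}")

    if table.n_taxa < 2:
        warnings.warn(
            f"{table.group}: single-taxon table, falling back to total-sum scaling",
            RuntimeWarning,
            stacklevel=2,
        )
        scale = totals
    else:
        scale = np.empty(table.n_plots)
        for i, row in enumerate(counts):
            pos = row[row > 0]
            q = np.quantile(pos, quantile)
            scale[i] = row[(row > 0) & (row <= q)].sum()
        if (scale == 0).any():  # pathological rounding; keep plots finite
            scale[scale == 0] = totals[scale == 0]
    norm = counts / scale[:, None] * np.median(scale)
    return CommunityTable(
        pd.DataFrame(norm, index=table.plot_ids, columns=table.taxon_ids),
        table.group,
        "normalized",
    )


def diversity_matrix(
    tables: list[CommunityTable],
    rarefy: bool = True,
    n_iter: int = 999,
    depth: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Plots x groups matrix of Shannon diversities (nats).

    Count tables (microbes, invertebrates) are rarefied from raw counts when
    ``rarefy`` is set; cover tables enter as-is.  Column order follows the
    canonical group order.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for t in sorted(tables, key=lambda t: GROUPS.index(t.group)):
        if rarefy and t.semantics == "count":
            cols[t.group] = rarefied_shannon(t, depth=depth, n_iter=n_iter, seed=rng)
        else:
            cols[t.group] = shannon_per_plot(t)
    return pd.DataFrame(cols)


@dataclass
class MultidiversityVector:
    """Per-plot multidiversity with its rank intermediates.

    ``md`` is the min-max normalised mean rank in [0, 1]; ``mean_ranks`` the
    raw per-plot mean of within-group ranks; ``ranks`` the plots x groups rank
    matrix (average ranks on ties).
    """

    md: pd.Series
    mean_ranks: pd.Series
    ranks: pd.DataFrame

    def __post_init__(self) -> None:
        self.md.name = "mD"


def multidiversity(
    div: pd.DataFrame, allow_missing: bool = False
) -> MultidiversityVector:
    """Rank-based multidiversity mD from a plots x groups diversity matrix.

    Plots are ranked by increasing diversity within each group (ties receive
    average ranks so no group is up- or down-weighted), the per-plot mean rank
    across groups is taken, and mean ranks are min-max normalised to [0, 1].
    The result is invariant under any strictly monotone transform of a group's
    diversities.

    Parameters
    ----------
    div
        Shannon matrix; NaN marks a plot with no community in that group.
    allow_missing
        If False (default), NaNs raise; if True, a plot's mean rank is taken
        over the groups where it is present.
    """
    if div.shape[0] < 2:
        raise ValueError("multidiversity needs at least 2 plots")
    if div.isna().any().any() and not allow_missing:
        bad = div.index[div.isna().any(axis=1)].tolist()
        raise EmptyCommunityError(
            f"plots with missing group diversities: {bad}; "
            "pass allow_missing=True to rank over available groups"
        )
    ranks = div.rank(axis=0, method="average", na_option="keep")
    mean_ranks = ranks.mean(axis=1, skipna=True)
    lo, hi = mean_ranks.min(), mean_ranks.max()
    if hi == lo:
        raise DegenerateNormalizationError(
            "all plots have identical mean rank; min-max scaling undefined"
        )
    md = (mean_ranks - lo) / (hi - lo)
    return MultidiversityVector(md=md, mean_ranks=mean_ranks, ranks=ranks)


def bray_curtis(table: CommunityTable, plot_subset=None) -> np.ndarray:
    """Condensed pairwise Bray-Curtis dissimilarities, d in [0, 1].

    d(x, y) = sum |x_i - y_i| / sum (x_i + y_i).  Microbial tables should be
    CSS-normalised first; cover and count tables enter on their native scale.

    Raises on a pair of all-zero plots (0/0 undefined).
    """
    t = table if plot_subset is None else table.subset(plot_subset)
    if t.n_plots < 2:
        raise ValueError("bray_curtis needs at least 2 plots")
    x = t.abundance
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise EmptyCommunityError(
            f"{t.group}: Bray-Curtis undefined for all-zero plot pairs "
            f"{t.plot_ids[zero].tolist()}"
        )
    return pdist(x, metric="braycurtis")


@dataclass
class BetaResult:
    """Per-group Bray-Curtis matrices and the pooled multi-betadiversity.

    ``per_group`` maps group name to a condensed dissimilarity vector over
    ``plot_ids`` (scipy condensed order); ``mbd`` is the per-pair mean across
    groups.  Stage summaries and tests operate on within-stage pairs only.
    """

    plot_ids: list
    per_group: dict[str, np.ndarray]
    mbd: np.ndarray

    def mbd_square(self) -> pd.DataFrame:
        m = squareform(self.mbd)
        return pd.DataFrame(m, index=self.plot_ids, columns=self.plot_ids)

    def _pair_index(self) -> tuple[np.ndarray, np.ndarray]:
        n = len(self.plot_ids)
        iu = np.triu_indices(n, k=1)
        return iu

    def within_stage_values(self, stage_mask) -> tuple[np.ndarray, np.ndarray]:
        """(early, late) mbD values over pairs lying within one stage.

        ``stage_mask`` is a boolean array over plots, True = early stage.
        Cross-stage pairs are excluded, mirroring a per-stage split of the
        community tables before computing dissimilarities.
        """
        mask = np.asarray(stage_mask, dtype=bool)
        i, j = self._pair_index()
        early = self.mbd[mask[i] & mask[j]]
        late = self.mbd[~mask[i] & ~mask[j]]
        return early, late

    def stage_summary(self, stage_mask) -> pd.DataFrame:
        """Mean +- SD of pair dissimilarity per stage, per group and pooled."""
        mask = np.asarray(stage_mask, dtype=bool)
        i, j = self._pair_index()
        sel_e = mask[i] & mask[j]
        sel_l = ~mask[i] & ~mask[j]
        rows = []
        for name, d in list(self.per_group.items()) + [("multi_betadiversity", self.mbd)]:
            for stage, sel in (("early", sel_e), ("late", sel_l)):
                vals = d[sel]
                rows.append(
                    {
                        "group": name,
                        "stage": stage,
                        "mean": float(vals.mean()) if vals.size else np.nan,
                        "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                        "n_pairs": int(vals.size),
                    }
                )
        return pd.DataFrame(rows)

    def stage_test(
        self,
        stage_mask,
        n_perm: int = 999,
        seed: int | np.random.Generator | None = None,
    ) -> dict:
        """Early-vs-late test of mean mbD.

        Reports a two-sided Mann-Whitney U over within-stage pair values and
        a plot-label permutation test: plot stage labels are shuffled, the
        within-stage pair means are recomputed, and the permutation p-value
        is the +1-corrected fraction of |mean difference| at least as large
        as observed.

        The permutation null is *exchangeability of plots*.  When pair
        dissimilarity also varies with gradient distance (compositional
        turnover) and the stages are contiguous, the test is conservative:
        shuffled pseudo-stages mix short- and long-distance pairs, widening
        the permutation distribution relative to the contiguous observed
        split.  It is exactly calibrated when plots are exchangeable (no
        turnover along the gradient).
        """
        mask = np.asarray(stage_mask, dtype=bool)
        early, late = self.within_stage_values(mask)
        if early.size < 2 or late.size < 2:
            raise ValueError("each stage needs at least 2 within-stage pairs")
        u, p_mw = mannwhitneyu(early, late, alternative="two-sided")
        obs = early.mean() - late.mean()
        rng = np.random.default_rng(seed)
        i, j = self._pair_index()
        n_extreme = 0
        for _ in range(n_perm):
            perm = rng.permutation(mask)
            e = self.mbd[perm[i] & perm[j]]
            l = self.mbd[~perm[i] & ~perm[j]]
            if abs(e.mean() - l.mean()) >= abs(obs) - 1e-15:
                n_extreme += 1
        return {
            "mean_early": float(early.mean()),
            "mean_late": float(late.mean()),
            "difference": float(obs),
            "mannwhitney_u": float(u),
            "mannwhitney_p": float(p_mw),
            "perm_p": (1 + n_extreme) / (n_perm + 1),
            "n_perm": n_perm,
        }


def multi_betadiversity(
    tables: list[CommunityTable], plot_subset=None
) -> BetaResult:
    """Multi-betadiversity: per-pair mean Bray-Curtis across organismal groups.

    All tables must cover the same plots (or the requested subset).  Microbial
    count tables are CSS-normalised before computing dissimilarities; other
    tables enter on their native scale.
    """
    if not tables:
        raise ValueError("no community tables given")
    ref = list(plot_subset) if plot_subset is not None else list(tables[0].plot_ids)
    per_group = {}
    for t in tables:
        missing = [p for p in ref if p not in t.data.index]
        if missing:
            raise CommunityTableError(
                f"{t.group}: plots {missing} missing; tables must align"
            )
        tt = t.subset(ref)
        if tt.group in MICROBIAL_GROUPS and tt.semantics == "count":
            tt = css_normalize(tt)
        per_group[tt.group] = pdist(tt.abundance, metric="braycurtis")
    mbd = np.mean(np.vstack(list(per_group.values())), axis=0)
    return BetaResult(plot_ids=ref, per_group=per_group, mbd=mbd)
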
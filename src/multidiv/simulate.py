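"""Synthetic multi-taxa successional datasets with known ground truth.

The generator emulates a glacier-forefield chronosequence: ~110 plots laid
out along a 1-D transect, each with a time since deglaciation spanning a
~170-year gradient, surveyed for five organismal groups (vascular plants and
bryophytes as percent cover; invertebrates, fungi and bacteria as counts).
The community obeys a two-stage assembly regime with a sharp threshold:

* before the breakpoint, each group's expected Shannon diversity rises
  linearly with age (stochastic accumulation of colonisers);
* after the breakpoint, expected diversity is flat, responds to soil
  temperature, and group diversities share a latent residual factor that
  induces positive pairwise covariance (the biotic-interaction signal);
* taxa have unimodal (Gaussian) expected abundance optima along the
  gradient, and late-stage composition can share a taxon-level co-structure
  that lowers late-stage betadiversity.

Taxon tables are generated to be *consistent* with the target diversity
trajectories: each plot's composition is the niche-model composition raised
to a temperature (solved by bisection) so its Shannon diversity hits the
target exactly before observation noise.  Every random quantity flows from
the single seed in the config; the same config is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GROUPS, CommunityTable, PlotFrame

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "write_dataset",
    "read_ground_truth",
    "simulate_broken_stick",
    "simulate_path_data",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


DEFAULT_TAXA = {
    "vascular_plants": 35,
    "bryophytes": 18,
    "invertebrates": 14,
    "fungi": 90,
    "bacteria": 180,
}

DEFAULT_DEPTH = {"invertebrates": 300, "fungi": 4000, "bacteria": 8000}

COVER_GROUPS = ("vascular_plants", "bryophytes")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic chronosequence.

    Parameters
    ----------
    n_plots
        Number of plots along the gradient (study design: 110).
    age_range
        (min, max) time since deglaciation in years (~170-year gradient).
    true_breakpoint
        Age (years) of the assembly threshold.
    n_taxa_per_group
        Taxon richness per organismal group.
    early_slope
        Gain of each group's expected Shannon diversity (nats per year)
        before the breakpoint.
    noise_sd
        Residual SD (nats) of group diversities around their expectation;
        0 switches the generator to its deterministic limit (expected
        abundances emitted directly, no sampling noise).
    temp_effect_late
        Effect (nats per SD of temperature) of mean growth-season soil
        temperature on every group's diversity, acting after the breakpoint
        only.
    latent_cov_late
        Target pairwise residual correlation among late-stage group
        diversities, induced by one shared Gaussian factor; in [0, 1).
    late_costructure
        Fraction of compositional log-noise variance shared across all
        late-stage plots per taxon; lowers late-stage betadiversity without
        touching early plots.  0 switches late co-structure off (early and
        late pair dissimilarities then exchangeable).
    composition_noise_sd
        SD of the lognormal plot-by-taxon compositional noise.
    abundance_model
        ``"negative_binomial"`` draws per-plot sequencing/trapping depths
        from a negative binomial and counts from a multinomial;
        ``"cover"`` emits expected relative abundances scaled to percent
        cover for every group.
    spacing_median, spacing_sd, spacing_min
        Inter-plot spacing on the transect in metres (field design:
        median 19 m, SD 6.3 m, minimum 5 m).
    """

    n_plots: int = 110
    age_range: tuple[float, float] = (5.0, 170.0)
    true_breakpoint: float = 60.0
    n_taxa_per_group: dict = field(default_factory=lambda: dict(DEFAULT_TAXA))
    early_slope: float = 0.02
    noise_sd: float = 0.15
    temp_effect_late: float = 0.1
    latent_cov_late: float = 0.4
    late_costructure: float = 0.5
    composition_noise_sd: float = 0.6
    abundance_model: str = "negative_binomial"
    niche_width_frac: float = 0.35
    base_diversity: float | None = None  # nats; default 0.45 ln(richness) per group
    cover_range: tuple[float, float] = (5.0, 95.0)  # total % cover at age min/max
    depth_mean: dict = field(default_factory=lambda: dict(DEFAULT_DEPTH))
    depth_dispersion: float = 10.0
    spacing_median: float = 19.0
    spacing_sd: float = 6.3
    spacing_min: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_plots < 10:
            raise ConfigError("n_plots must be >= 10")
        lo, hi = self.age_range
        if not lo < self.true_breakpoint < hi:
            raise ConfigError(
                f"true_breakpoint {self.true_breakpoint} outside age range ({lo}, {hi})"
            )
        if not 0 <= self.latent_cov_late < 1:
            raise ConfigError("latent_cov_late must be in [0, 1)")
        if not 0 <= self.late_costructure < 1:
            raise ConfigError("late_costructure must be in [0, 1)")
        if self.abundance_model not in ("negative_binomial", "cover"):
            raise ConfigError("abundance_model must be 'negative_binomial' or 'cover'")
        if self.noise_sd < 0 or self.early_slope < 0:
            raise ConfigError("noise_sd and early_slope must be non-negative")
        unknown = set(self.n_taxa_per_group) - set(GROUPS)
        if unknown:
            raise ConfigError(f"unknown groups in n_taxa_per_group: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Exact parameters the generator used, serialised beside the dataset."""

    true_breakpoint: float
    true_path_coefficients: dict
    true_residual_correlations: dict
    taxon_optima: dict
    target_diversity: dict  # group -> per-plot target Shannon (nats)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# helpers


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _calibrate_composition(v: np.ndarray, target_h: float) -> np.ndarray:
    """Raise weights ``v`` to a power so the Shannon of the normalised
    composition equals ``target_h`` (bisection; H is monotone decreasing in
    the exponent)."""
    v = v / v.max()
    k = v.size
    h_max = np.log(k)
    target = min(max(target_h, 1e-3), h_max - 1e-9)

    def h_at(tau: float) -> float:
        w = v**tau
        return _shannon(w / w.sum())

    lo, hi = 0.0, 1.0
    while h_at(hi) > target and hi < 1e4:
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if h_at(mid) > target:
            lo = mid
        else:
            hi = mid
    tau = 0.5 * (lo + hi)
    w = v**tau
    return w / w.sum()


# ---------------------------------------------------------------------------
# generator


def generate_dataset(
    config: SimulationConfig,
) -> tuple[list[CommunityTable], PlotFrame, GroundTruth]:
    """Generate community tables, plot metadata, and the ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD1CE]))
    n = config.n_plots
    lo, hi = config.age_range
    cp = config.true_breakpoint

    # plot ages: approximately uniform in time (the design's linear gradient)
    step = (hi - lo) / n
    ages = lo + (np.arange(n) + 0.5) * step + rng.uniform(-0.4, 0.4, n) * step
    ages = np.sort(np.clip(ages, lo, hi))
    late = ages > cp

    # transect coordinates: spacing around the field design's median
    spacing = np.maximum(
        rng.normal(config.spacing_median, config.spacing_sd, n - 1),
        config.spacing_min,
    )
    x_m = np.concatenate([[0.0], np.cumsum(spacing)])
    y_m = np.zeros(n)

    # mean growth-season soil temperature: warms away from the glacier
    temp = 4.0 + 0.02 * ages + rng.normal(0.0, 1.0, n)
    z_temp = (temp - temp.mean()) / temp.std()

    # latent residual structure of group diversities
    groups = [g for g in GROUPS if config.n_taxa_per_group.get(g, 0) > 0]
    rho = config.latent_cov_late
    shared = rng.standard_normal(n)
    eps = rng.standard_normal((n, len(groups)))
    resid = np.where(
        late[:, None],
        config.noise_sd * (np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * eps),
        config.noise_sd * eps,
    )

    target_h = {}
    tables = []
    optima_all: dict[str, dict[str, float]] = {}
    positions = np.arange(1, n + 1, dtype=float)
    for gi, g in enumerate(groups):
        k = int(config.n_taxa_per_group[g])
        h_max = np.log(k)
        base = (
            0.45 * h_max if config.base_diversity is None else config.base_diversity
        )
        mu = (
            base
            + config.early_slope * (np.minimum(ages, cp) - lo)
            + np.where(late, config.temp_effect_late * z_temp, 0.0)
        )
        h = np.clip(mu + resid[:, gi], 0.05, h_max - 0.05)
        target_h[g] = h

        # unimodal niche curves on the gradient (plot-index scale)
        opt = np.linspace(1, n, k) + rng.uniform(-0.5, 0.5, k) * (n / k)
        opt = np.clip(opt, 1, n)
        width = config.niche_width_frac * n
        curves = np.exp(
            -0.5 * ((positions[:, None] - opt[None, :]) / width) ** 2
        ) + 1e-3

        # evenness calibrated to the target Shannon, then multiplicative
        # compositional noise; applying noise after calibration keeps the
        # expected pair dissimilarity independent of the evenness level, so
        # early and late stages are exchangeable when co-structure is off
        comp = np.vstack(
            [_calibrate_composition(curves[p], h[p]) for p in range(n)]
        )
        if config.noise_sd > 0:
            rc = config.late_costructure
            shared_tax = rng.standard_normal(k)
            idio = rng.standard_normal((n, k))
            logn = config.composition_noise_sd * np.where(
                late[:, None],
                np.sqrt(rc) * shared_tax[None, :] + np.sqrt(1 - rc) * idio,
                idio,
            )
            comp = comp * np.exp(logn)
            comp = comp / comp.sum(axis=1, keepdims=True)

        taxa = [f"{g}_t{j + 1:03d}" for j in range(k)]
        optima_all[g] = {t: float(o) for t, o in zip(taxa, opt)}
        plot_ids = [f"plot_{i + 1:03d}" for i in range(n)]

        as_cover = g in COVER_GROUPS or config.abundance_model == "cover"
        if as_cover or config.noise_sd == 0:
            c0, c1 = config.cover_range
            total = np.clip(c0 + (c1 - c0) * (ages - lo) / (hi - lo), 0.5, 100.0)
            ab = comp * total[:, None]
            if config.noise_sd > 0 and g in COVER_GROUPS:
                # visual cover surveys resolve 0.1%; applies to the plant
                # groups only, not to count groups rendered as percentages
                ab = np.round(ab, 1)
                dead = ab.sum(axis=1) == 0
                if dead.any():
                    ab[dead, np.argmax(comp[dead], axis=1)] = 0.1
            # the zero-noise limit emits exact expected abundances so the
            # realized Shannon is the deterministic piecewise target
            semantics = "cover" if as_cover else "normalized"
            tables.append(
                CommunityTable(
                    pd.DataFrame(ab, index=plot_ids, columns=taxa), g, semantics
                )
            )
        else:
            mean_depth = config.depth_mean.get(g, 1000)
            r = config.depth_dispersion
            depths = rng.negative_binomial(r, r / (r + mean_depth), n) + 50
            counts = np.vstack(
                [rng.multinomial(depths[p], comp[p]) for p in range(n)]
            )
            tables.append(
                CommunityTable(
                    pd.DataFrame(counts, index=plot_ids, columns=taxa), g, "count"
                )
            )

    meta = pd.DataFrame(
        {
            "gradient_index": np.arange(1, n + 1),
            "age_years": ages,
            "temperature": temp,
            "x_m": x_m,
            "y_m": y_m,
        },
        index=pd.Index([f"plot_{i + 1:03d}" for i in range(n)], name="plot_id"),
    )
    truth = GroundTruth(
        true_breakpoint=cp,
        true_path_coefficients={
            "age_early_slope_nats_per_year": {g: config.early_slope for g in groups},
            "temperature_late_nats_per_sd": {
                g: config.temp_effect_late for g in groups
            },
        },
        true_residual_correlations={
            f"{a}~~{b}": (config.latent_cov_late)
            for i, a in enumerate(groups)
            for b in groups[i + 1 :]
        },
        taxon_optima=optima_all,
        target_diversity={g: target_h[g].tolist() for g in groups},
    )
    return tables, PlotFrame(meta), truth


# ---------------------------------------------------------------------------
# i/o


def write_dataset(
    dataset: tuple[list[CommunityTable], PlotFrame, GroundTruth],
    out_dir: str | Path,
    sep: str = "\t",
) -> dict[str, Path]:
    """Write one delimited table per group, plot metadata, and the truth
    sidecar; round-trips losslessly through :mod:`multidiv.io`."""
    tables, plots, truth = dataset
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for t in tables:
        p = out / f"{t.group}.tsv"
        df = t.data.copy()
        df.index.name = "plot_id"
        df.to_csv(p, sep=sep)
        written[t.group] = p
    pm = out / "plots.tsv"
    plots.data.to_csv(pm, sep=sep)
    written["plots"] = pm
    gt = out / "ground_truth.json"
    gt.write_text(truth.to_json())
    written["ground_truth"] = gt
    manifest = out / "semantics.json"
    manifest.write_text(
        json.dumps({t.group: t.semantics for t in tables}, indent=1, sort_keys=True)
    )
    written["semantics"] = manifest
    return written


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# targeted simulators for model validation


def simulate_broken_stick(
    n: int = 110,
    cp: float = 60.0,
    intercept: float = 0.15,
    slope_early: float = 0.01,
    slope_late: float = 0.0,
    noise_sd: float = 0.05,
    age_range: tuple[float, float] = (5.0, 170.0),
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Broken-stick response (e.g. multidiversity) along age, with noise.

    The mean is continuous at the change point: intercept + slope_early * x
    up to cp, then continuing with slope_late.  Defaults give the study-like
    regime of a clear early rise flattening after 60 years, with the early
    trend dominating the residual noise.
    """
    rng = np.random.default_rng(seed)
    lo, hi = age_range
    x = np.sort(rng.uniform(lo, hi, n))
    mu = intercept + slope_early * np.minimum(x, cp) + slope_late * np.maximum(x - cp, 0.0)
    return x, mu + rng.normal(0.0, noise_sd, n)


def simulate_path_data(
    n: int = 500,
    a: dict[str, dict[str, float]] | None = None,
    b: dict[str, float] | None = None,
    resid_corr: float = 0.3,
    exo_corr: float = 0.3,
    outcome: str = "mD",
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Standardised data drawn from a known recursive path model.

    ``a`` maps exogenous -> {mediator -> coefficient}; ``b`` maps mediator ->
    outcome coefficient.  All variables have unit population variance, so the
    coefficients are standardised path coefficients; mediator residuals share
    the pairwise correlation ``resid_corr``.  Returns the data and the truth
    (coefficients plus the implied residual covariances).
    """
    if a is None:
        a = {
            "time": {
                "vascular_plants": 0.5, "bryophytes": 0.6, "invertebrates": 0.4,
                "fungi": 0.3, "bacteria": 0.35,
            },
            "temperature": {
                "vascular_plants": 0.2, "bryophytes": 0.1, "invertebrates": 0.3,
                "fungi": 0.25, "bacteria": 0.15,
            },
        }
    if b is None:
        b = {
            "vascular_plants": 0.25, "bryophytes": 0.2, "invertebrates": 0.2,
            "fungi": 0.15, "bacteria": 0.2,
        }
    exo = list(a)
    meds = list(next(iter(a.values())))
    q, m = len(exo), len(meds)
    A = np.array([[a[e][g] for e in exo] for g in meds])  # m x q
    bvec = np.array([b[g] for g in meds])
    Phi = np.full((q, q), exo_corr)
    np.fill_diagonal(Phi, 1.0)
    # residual variances making every mediator unit-variance
    explained = np.einsum("iq,qr,ir->i", A, Phi, A)
    if (explained >= 1).any():
        raise ConfigError("path coefficients imply mediator variance > 1")
    resid_sd = np.sqrt(1.0 - explained)
    Psi = resid_corr * np.outer(resid_sd, resid_sd)
    np.fill_diagonal(Psi, resid_sd**2)
    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(np.zeros(q), Phi, size=n)
    E = rng.multivariate_normal(np.zeros(m), Psi, size=n)
    M = X @ A.T + E
    cov_m = A @ Phi @ A.T + Psi
    var_out_explained = float(bvec @ cov_m @ bvec)
    if var_out_explained >= 1:
        raise ConfigError("outcome coefficients imply variance > 1")
    y = M @ bvec + rng.normal(0.0, np.sqrt(1.0 - var_out_explained), n)
    data = pd.DataFrame(
        np.column_stack([X, M, y]), columns=exo + meds + [outcome]
    )
    truth = {
        "a": a,
        "b": b,
        "resid_corr": resid_corr,
        "exo_corr": exo_corr,
        "residual_cov": {
            f"{meds[i]}~~{meds[j]}": float(Psi[i, j])
            for i in range(m)
            for j in range(i + 1, m)
        },
        "indirect": {
            e: float(sum(a[e][g] * b[g] for g in meds)) for e in exo
        },
    }
    return data, truth
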
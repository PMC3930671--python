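"""Synthetic stem maps and fire-scar chronologies.

Generates 4-ha-scale stem maps with the statistical structure the analyses
assume: homogeneous Poisson (CSR) patterns at 1000–1500 stems per 4 ha,
Thomas cluster patterns with a known closed-form pair correlation, and
inhomogeneous Poisson patterns with a log-linear intensity trend.  Marks
(species, DBH, live/snag status) are attached from configurable mixtures
so that size-class proportions, species compositions and snag fractions
mimic old-growth Jeffrey pine-mixed conifer plots.

Every operation takes an explicit integer seed; a master seed is split
into named per-stage streams so stages can be re-run independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core import FireScarRecordSet, FireScarSample, PlotWindow, StemMap, TreeRecord

__all__ = [
    "PointProcessSpec",
    "MarkModelSpec",
    "SITE_SPECIES_MIXES",
    "SITE_SNAG_FRACTIONS",
    "simulate_points",
    "thomas_pcf_closed_form",
    "attach_marks",
    "simulate_stemmap",
    "simulate_fire_history",
    "stream",
]

#: Species mixture presets (proportions of stems > 5 cm DBH) for the four
#: study-site archetypes; codes are JP Jeffrey pine, WF white fir, IC incense
#: cedar, SP sugar pine, LP lodgepole pine, SJ western juniper, QA quaking
#: aspen, QU oak.
SITE_SPECIES_MIXES: dict[str, dict[str, float]] = {
    "lost_cannon": {"JP": 0.444, "WF": 0.297, "SJ": 0.181, "QA": 0.057, "LP": 0.021},
    "teakettle": {"WF": 0.521, "IC": 0.280, "JP": 0.085, "SP": 0.078, "QU": 0.036},
    "sspm_gran": {"JP": 0.844, "WF": 0.125, "SP": 0.023, "LP": 0.008},
    "sspm_meta": {"JP": 0.995, "QU": 0.004, "WF": 0.001},
}

#: Snag fraction presets = snag density / (live + snag density) per site.
SITE_SNAG_FRACTIONS: dict[str, float] = {
    "lost_cannon": 21.5 / (337.8 + 21.5),
    "teakettle": 27.8 / (346.3 + 27.8),
    "sspm_gran": 3.5 / (185.5 + 3.5),
    "sspm_meta": 9.8 / (345.5 + 9.8),
}


def stream(seed: int, name: str) -> np.random.Generator:
    """Named random stream derived from a master seed.

    Distinct names give independent generators; the same (seed, name) pair
    always yields the same stream.
    """
    h = np.random.SeedSequence([seed, zlib.crc32(name.encode()) % (2**31)])
    return np.random.default_rng(h)


@dataclass(frozen=True)
class PointProcessSpec:
    """Point-process recipe for stem locations.

    model 'csr': homogeneous Poisson with intensity ``intensity`` (stems/m²);
    the default 0.0325 yields ~1300 stems on a 4-ha plot.
    model 'thomas': Poisson(kappa·area) parents, Poisson(mu) offspring per
    parent displaced by an isotropic Gaussian(sigma); parents are drawn on
    the window dilated by 4*sigma so the restriction to the window is the
    stationary process; offspring outside the window are discarded.
    model 'inhomogeneous_poisson': thinning of a dominating homogeneous
    process under a log-linear intensity log λ(x,y) = a + bx·x + by·y scaled
    so the window-mean intensity equals ``intensity``; the default x-slope
    gives a max/min intensity ratio of ~3 across the window.
    """

    model: str = "csr"
    intensity: float = 0.0325
    kappa: float = 5e-4
    mu: float = 8.0
    sigma: float = 5.0
    trend: tuple[float, float] | None = None  # (bx, by) per metre, log scale

    def __post_init__(self) -> None:
        if self.model not in ("csr", "thomas", "inhomogeneous_poisson"):
            raise ValueError(f"unknown model {self.model!r}")
        if min(self.intensity, self.kappa, self.mu, self.sigma) <= 0:
            raise ValueError("all rates and scales must be positive")


def thomas_pcf_closed_form(r, kappa: float, sigma: float):
    """Pair correlation of the (modified) Thomas process.

    g(r) = 1 + exp(-r²/(4σ²)) / (4πσ²κ): independence (g = 1) at long
    range, maximal aggregation at r = 0, monotone decreasing in r.
    """
    r = np.asarray(r, dtype=float)
    return 1.0 + np.exp(-(r**2) / (4.0 * sigma**2)) / (4.0 * np.pi * sigma**2 * kappa)


def default_trend_slope(window: PlotWindow, ratio: float = 3.0) -> tuple[float, float]:
    """Log-linear x-slope giving max/min intensity ``ratio`` across the window."""
    return (np.log(ratio) / window.width, 0.0)


def intensity_function(spec: PointProcessSpec, window: PlotWindow):
    """The (normalized) intensity λ(x, y) of an inhomogeneous_poisson spec.

    Returns a vectorized callable whose mean over the window equals
    ``spec.intensity`` (computed exactly for the separable log-linear form).
    """
    bx, by = spec.trend if spec.trend is not None else default_trend_slope(window)

    def _mean_exp(b: float, lo: float, hi: float) -> float:
        if b == 0.0:
            return 1.0
        return (np.exp(b * hi) - np.exp(b * lo)) / (b * (hi - lo))

    norm = _mean_exp(bx, window.x_min, window.x_max) * _mean_exp(
        by, window.y_min, window.y_max
    )
    lam0 = spec.intensity / norm

    def lam(x, y):
        return lam0 * np.exp(bx * np.asarray(x, float) + by * np.asarray(y, float))

    return lam


def simulate_points(
    window: PlotWindow, spec: PointProcessSpec, seed: int | np.random.Generator
) -> np.ndarray:
    """Simulate stem locations; returns an (n, 2) coordinate array.

    Identical seed → identical output.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def _uniform(n: int, win: PlotWindow) -> np.ndarray:
        x = rng.uniform(win.x_min, win.x_max, n)
        y = rng.uniform(win.y_min, win.y_max, n)
        return np.column_stack([x, y])

    if spec.model == "csr":
        n = rng.poisson(spec.intensity * window.area)
        return _uniform(n, window)

    if spec.model == "thomas":
        pad = 4.0 * spec.sigma
        big = PlotWindow(
            window.x_min - pad, window.y_min - pad,
            window.x_max + pad, window.y_max + pad, buffer_width=0.0,
        )
        n_par = rng.poisson(spec.kappa * big.area)
        parents = _uniform(n_par, big)
        counts = rng.poisson(spec.mu, n_par)
        centres = np.repeat(parents, counts, axis=0)
        pts = centres + rng.normal(0.0, spec.sigma, size=centres.shape)
        keep = window.contains(pts[:, 0], pts[:, 1])
        return pts[keep]

    # inhomogeneous_poisson: thinning of a dominating homogeneous process
    lam = intensity_function(spec, window)
    gx = np.linspace(window.x_min, window.x_max, 101)
    gy = np.linspace(window.y_min, window.y_max, 101)
    lam_max = float(np.max(lam(gx[:, None], gy[None, :])))
    n = rng.poisson(lam_max * window.area)
    pts = _uniform(n, window)
    keep = rng.uniform(0.0, 1.0, n) < lam(pts[:, 0], pts[:, 1]) / lam_max
    return pts[keep]


# ---------------------------------------------------------------------------
# Marks


@dataclass(frozen=True)
class MarkModelSpec:
    """Mark recipe: species mixture, DBH distribution, snag labelling.

    DBH is drawn from a Weibull(shape, scale) truncated below at 5 cm —
    a right-skewed family whose small-class share P(DBH < 25 | DBH > 5)
    is the calibrated quantity (``small_fraction``); size distributions in
    these forests are strongly skewed toward the small classes.  Snags get
    an independent (typically larger-shifted) scale multiplier.

    ``snag_mode`` 'random_label' assigns snag status as an i.i.d. label —
    the null of the random-labelling test; 'clustered' preferentially
    labels trees in high local-density neighbourhoods (Gaussian kernel,
    ``snag_cluster_bandwidth`` m) to give that test a true positive.
    """

    species_mix: dict[str, float] = field(
        default_factory=lambda: dict(SITE_SPECIES_MIXES["sspm_meta"])
    )
    snag_fraction: float = SITE_SNAG_FRACTIONS["sspm_meta"]
    snag_mode: str = "random_label"
    snag_cluster_bandwidth: float = 10.0
    dbh_shape: float = 1.2
    small_fraction: float = 0.6
    snag_dbh_scale: float = 1.0

    def __post_init__(self) -> None:
        tot = sum(self.species_mix.values())
        if not np.isclose(tot, 1.0, atol=1e-6):
            raise ValueError("species mixture proportions must sum to 1")
        if not (0.0 <= self.snag_fraction < 1.0):
            raise ValueError("snag fraction must be in [0, 1)")
        if self.snag_mode not in ("random_label", "clustered"):
            raise ValueError(f"unknown snag_mode {self.snag_mode!r}")


def _weibull_scale_for_small_fraction(shape: float, small_fraction: float,
                                      lo: float = 5.0, cut: float = 25.0) -> float:
    """Weibull scale such that P(X < cut | X > lo) = small_fraction."""

    def f(scale: float) -> float:
        sf = stats.weibull_min.sf([lo, cut], shape, scale=scale)
        return (1.0 - sf[1] / sf[0]) - small_fraction

    # conditional small-class share is monotone decreasing in the scale;
    # bracket avoids survival-function underflow at tiny scales
    return float(optimize.brentq(f, 0.5, 1e3))


def _truncated_weibull(rng: np.random.Generator, n: int, shape: float,
                       scale: float, lo: float = 5.0) -> np.ndarray:
    sf_lo = stats.weibull_min.sf(lo, shape, scale=scale)
    u = rng.uniform(0.0, 1.0, n)
    return stats.weibull_min.isf(u * sf_lo, shape, scale=scale)


def attach_marks(
    points: np.ndarray,
    spec: MarkModelSpec,
    window: PlotWindow,
    seed: int | np.random.Generator,
    site_label: str = "synthetic",
) -> StemMap:
    """Attach species, DBH, height and live/snag status to stem locations."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(points)
    if n == 0:
        return StemMap(window, [], site_label=site_label)

    codes = list(spec.species_mix)
    probs = np.array([spec.species_mix[c] for c in codes], dtype=float)
    species = rng.choice(codes, size=n, p=probs / probs.sum())

    # snag labels
    n_snag = int(round(spec.snag_fraction * n))
    snag = np.zeros(n, dtype=bool)
    if n_snag > 0:
        if spec.snag_mode == "random_label":
            snag[rng.choice(n, n_snag, replace=False)] = True
        else:
            # clustered: weight by Gaussian-kernel local density rank
            d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
            h2 = spec.snag_cluster_bandwidth**2
            dens = np.exp(-d2 / (2.0 * h2)).sum(1)
            w = dens**3
            snag[rng.choice(n, n_snag, replace=False, p=w / w.sum())] = True

    scale = _weibull_scale_for_small_fraction(spec.dbh_shape, spec.small_fraction)
    dbh = _truncated_weibull(rng, n, spec.dbh_shape, scale)
    dbh[snag] = 5.0 + (dbh[snag] - 5.0) * spec.snag_dbh_scale
    dbh = np.maximum(dbh, 5.0 + 1e-9)

    # monotone-in-DBH height / crown base defaults (not allometric fits)
    height = 1.37 + 18.0 * (1.0 - np.exp(-0.035 * dbh))
    crown_base = height * rng.uniform(0.25, 0.5, n)

    trees = [
        TreeRecord(
            id=f"t{i:05d}", x=float(points[i, 0]), y=float(points[i, 1]),
            species=str(species[i]), dbh=float(dbh[i]), height=float(height[i]),
            crown_base_height=float(crown_base[i]),
            status="snag" if snag[i] else "live",
        )
        for i in range(n)
    ]
    return StemMap(window, trees, site_label=site_label)


def simulate_stemmap(
    window: PlotWindow,
    process: PointProcessSpec,
    marks: MarkModelSpec,
    seed: int,
    site_label: str = "synthetic",
) -> StemMap:
    """Locations then marks, each on its own named stream from ``seed``."""
    pts = simulate_points(window, process, stream(seed, "points"))
    return attach_marks(pts, marks, window, stream(seed, "marks"), site_label)


# ---------------------------------------------------------------------------
# Fire history


def simulate_fire_history(
    n_samples: int,
    fire_years: list[int],
    recording_spans: list[tuple[int, int]] | tuple[int, int],
    scar_probability: float,
    seed: int | np.random.Generator,
) -> FireScarRecordSet:
    """Ground-truth fire chronology with per-sample Bernoulli scarring.

    Each sample records each fire year independently with probability
    ``scar_probability`` while its recording span covers that year.
    ``recording_spans`` is either one (start, end) applied to every sample
    or a per-sample list.
    """
    if not (0.0 <= scar_probability <= 1.0):
        raise ValueError("scar probability must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(recording_spans, tuple):
        spans = [recording_spans] * n_samples
    else:
        spans = list(recording_spans)
        if len(spans) != n_samples:
            raise ValueError("need one recording span per sample")
    samples = []
    for i in range(n_samples):
        a, b = spans[i]
        years = [
            y for y in fire_years
            if a <= y <= b and rng.uniform() < scar_probability
        ]
        samples.append(FireScarSample(f"s{i:03d}", years, [(a, b)]))
    return FireScarRecordSet(samples)
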
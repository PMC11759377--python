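"""Rank-size and allometric scaling analysis of urban health-resource panels.

The package studies how hospital beds and doctors are distributed across the
cities of an urban agglomeration and how those resources scale with each
city's economy.  Two classical tools from urban systems research drive the
whole analysis:

* the **rank-size (Zipf) rule**  ``P_i = P_1 * R_i**(-q)`` — the log-log
  slope magnitude ``q`` of size against rank measures how concentrated a
  year's resource distribution is (``q < 1`` balanced, ``q = 1`` canonical
  Zipf, ``q > 1`` concentrated);
* the **allometric scaling model**  ``A = k * G**b`` — the exponent ``b`` of
  a resource ``A`` against economic output ``G`` measures the resource's
  growth rate relative to the economy, estimated *vertically* (across cities
  within one year) or *horizontally* (across years within one city) and
  banded into six ordered levels (thresholds 2, 1, 0.85, 0.5, 0).

Both models are fit by ordinary least squares on natural logarithms.  The
module is organised in the order the pipeline runs: configuration and
errors, the synthetic panel generator, rank-size estimation, allometric
estimation and the grade-change typology, then panel I/O, the map-preparation
transforms (percent-of-total normalisation, Jenks natural breaks) and the
study orchestrator.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("healthscaling")

__all__ = [
    "HealthScalingError",
    "ConfigurationError",
    "InsufficientDataError",
    "DegenerateInputError",
    "SchemaError",
    "IntegrityError",
    "ContractError",
    "SyntheticConfig",
    "generate_panel",
    "generate_zipf_sizes",
    "RankSizeFit",
    "rank_size_fit",
    "interpret_q",
    "rank_size_series",
    "AllometricLevel",
    "AllometricFit",
    "AllometricChange",
    "allometric_fit",
    "classify_level",
    "vertical_allometry",
    "horizontal_allometry",
    "change_typology",
    "window_summary",
    "read_panel",
    "percent_total_normalize",
    "natural_breaks",
    "BreaksClassification",
    "percent_change",
    "run_study",
    "write_panel",
    "RESOURCE_COLUMNS",
]

# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------


class HealthScalingError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(HealthScalingError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class InsufficientDataError(HealthScalingError, ValueError):
    """Too few valid observations for the requested fit or summary."""


class DegenerateInputError(HealthScalingError, ValueError):
    """Input with no usable variation (zero-variance predictor, all-zero sum)."""


class SchemaError(HealthScalingError, ValueError):
    """A panel file or frame is missing required columns or is empty."""


class IntegrityError(HealthScalingError, ValueError):
    """A panel violates its uniqueness contract (duplicate city-year rows)."""


class ContractError(HealthScalingError, ValueError):
    """Two objects that must refer to the same city/resource do not."""


#: canonical resource labels -> panel column names
RESOURCE_COLUMNS: dict[str, str] = {"beds": "beds", "doctors": "doctors"}

PANEL_COLUMNS = ["city_id", "city_name", "year", "gdp", "beds", "doctors"]


# --------------------------------------------------------------------------
# Synthetic city-year panels
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic city-year panel generator.

    The generator emulates a yearbook-style panel of ``n_cities`` cities
    observed every year from ``year_start`` to ``year_end`` inclusive, each
    with a strictly positive GDP, bed count and doctor count.  City base
    GDPs follow a heavy-tailed size law (lognormal by default, Pareto
    optionally) and evolve by i.i.d. lognormal growth factors; resources are
    tied to GDP through the allometric power law ``ln A = k + b * ln G + eps``
    with Gaussian noise ``eps`` on the log scale, so log-log OLS is the
    correct estimator and recovery tests are exact when ``noise_sd = 0``.

    Parameters
    ----------
    n_cities
        Number of cities (>= 3; a log-log regression needs residual df).
    year_start, year_end
        Inclusive year range of the panel.
    true_b_beds, true_b_doctors
        Ground-truth allometric exponents (dimensionless).
    true_k_beds, true_k_doctors
        Ground-truth log-scale intercepts.
    gdp_law
        ``"lognormal"`` (log-mean ``gdp_log_mean``, log-sd ``gdp_log_sd``) or
        ``"pareto"`` (tail exponent ``gdp_pareto_alpha``, scale
        ``gdp_pareto_scale``) for the base-year city GDP draws.
    noise_sd
        Standard deviation of the additive log-scale noise on resources
        (>= 0; 0 gives an exactly log-linear panel).
    gdp_growth_mean, gdp_growth_sd
        Mean and sd of the per-year log growth factor of each city's GDP.
    b_drift_per_year
        Additive change in both true exponents per elapsed year (default 0).
    seed
        RNG seed.  Identical config + seed gives a bit-identical panel;
        per-city substreams are derived from ``(seed, city index)`` so
        adding cities never perturbs existing ones.
    """

    n_cities: int = 41
    year_start: int = 2009
    year_end: int = 2022
    true_b_beds: float = 1.2
    true_b_doctors: float = 1.25
    true_k_beds: float = 5.0
    true_k_doctors: float = 5.8
    gdp_law: str = "lognormal"
    gdp_log_mean: float = 9.0
    gdp_log_sd: float = 1.0
    gdp_pareto_alpha: float = 1.0
    gdp_pareto_scale: float = 1000.0
    noise_sd: float = 0.3
    gdp_growth_mean: float = 0.10
    gdp_growth_sd: float = 0.05
    b_drift_per_year: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cities < 3:
            raise ConfigurationError(f"n_cities must be >= 3, got {self.n_cities}")
        if self.year_end < self.year_start:
            raise ConfigurationError(
                f"year_end ({self.year_end}) precedes year_start ({self.year_start})"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.gdp_growth_sd < 0:
            raise ConfigurationError(
                f"gdp_growth_sd must be >= 0, got {self.gdp_growth_sd}"
            )
        if self.gdp_law not in ("lognormal", "pareto"):
            raise ConfigurationError(
                f"gdp_law must be 'lognormal' or 'pareto', got {self.gdp_law!r}"
            )
        if self.gdp_law == "lognormal" and self.gdp_log_sd < 0:
            raise ConfigurationError(f"gdp_log_sd must be >= 0, got {self.gdp_log_sd}")
        if self.gdp_law == "pareto" and (
            self.gdp_pareto_alpha <= 0 or self.gdp_pareto_scale <= 0
        ):
            raise ConfigurationError(
                "gdp_pareto_alpha and gdp_pareto_scale must be > 0"
            )

    @property
    def years(self) -> range:
        """The inclusive year range as a ``range`` object."""
        return range(self.year_start, self.year_end + 1)


def generate_panel(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a synthetic city-year panel under ``config``.

    Returns a frame with columns ``city_id, city_name, year, gdp, beds,
    doctors`` and one row per city-year (``n_cities * |years|`` rows), all
    size variables strictly positive.  For each city-year,

        ``ln(resource) = k + b_year * ln(GDP) + eps``,  eps ~ N(0, noise_sd²),

    where ``b_year = true_b + b_drift_per_year * (year - year_start)`` and
    each city's GDP evolves from its base-year draw by i.i.d. lognormal
    growth factors.
    """
    years = np.asarray(config.years)
    n_years = len(years)
    b_beds = config.true_b_beds + config.b_drift_per_year * (years - config.year_start)
    b_docs = config.true_b_doctors + config.b_drift_per_year * (
        years - config.year_start
    )

    rows = []
    for i in range(config.n_cities):
        # independent substream per city: stable under n_cities changes
        rng = np.random.default_rng([config.seed, i])
        if config.gdp_law == "lognormal":
            gdp0 = float(
                np.exp(rng.normal(config.gdp_log_mean, config.gdp_log_sd))
            )
        else:
            gdp0 = float(
                config.gdp_pareto_scale
                * (1.0 + rng.pareto(config.gdp_pareto_alpha))
            )
        log_growth = rng.normal(
            config.gdp_growth_mean, config.gdp_growth_sd, size=n_years - 1
        )
        log_gdp = np.log(gdp0) + np.concatenate([[0.0], np.cumsum(log_growth)])
        eps_beds = rng.normal(0.0, config.noise_sd, size=n_years)
        eps_docs = rng.normal(0.0, config.noise_sd, size=n_years)
        beds = np.exp(config.true_k_beds + b_beds * log_gdp + eps_beds)
        doctors = np.exp(config.true_k_doctors + b_docs * log_gdp + eps_docs)
        for t, year in enumerate(years):
            rows.append(
                (
                    f"C{i + 1:03d}",
                    f"City {i + 1:03d}",
                    int(year),
                    float(np.exp(log_gdp[t])),
                    float(beds[t]),
                    float(doctors[t]),
                )
            )
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def generate_zipf_sizes(n: int, q: float, p1: float = 1000.0) -> np.ndarray:
    """Exact rank-size series ``p1 * i**(-q)`` for ranks ``i = 1..n``.

    Strictly decreasing for ``q > 0``; used to exercise the rank-size
    estimator on noiseless inputs.
    """
    if n < 2:
        raise ConfigurationError(f"n must be >= 2, got {n}")
    if q <= 0:
        raise ConfigurationError(f"q must be > 0, got {q}")
    if p1 <= 0:
        raise ConfigurationError(f"p1 must be > 0, got {p1}")
    ranks = np.arange(1, n + 1, dtype=float)
    return p1 * ranks ** (-q)


def write_panel(panel: pd.DataFrame, path: str | Path) -> Path:
    """Write a panel as UTF-8 CSV with the canonical header."""
    path = Path(path)
    panel.to_csv(path, index=False, encoding="utf-8")
    return path


# --------------------------------------------------------------------------
# Rank-size (Zipf) estimation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RankSizeFit:
    """A fitted rank-size (Zipf) regression for one year's distribution.

    ``q`` is the magnitude of the log-log slope of size on rank (positive
    for size hierarchies that decrease with rank); ``ln_p1`` the fitted
    intercept, i.e. the log of the extrapolated leading size.  ``convention``
    records the rank transform used: ``"plain"`` regresses on ``ln(R)``,
    ``"shifted"`` on ``ln(R - 0.5)``, a standard correction that reduces the
    small-sample bias of the slope estimator.
    """

    resource: str
    year: int | None
    q: float
    ln_p1: float
    r2: float
    slope_p_value: float
    n_used: int
    n_dropped: int
    convention: str
    degenerate: bool = False

    def interpretation(self) -> str:
        return interpret_q(self.q) if self.q > 0 else "balanced"


def rank_size_fit(
    sizes: Sequence[float] | np.ndarray,
    convention: str = "shifted",
    *,
    resource: str = "other",
    year: int | None = None,
) -> RankSizeFit:
    """Estimate the Zipf exponent ``q`` of one size distribution.

    Sizes are sorted descending (stable, so ties keep input order), assigned
    ranks ``1..n``, and ``ln(size)`` is regressed on ``ln(rank)`` (plain) or
    ``ln(rank - 0.5)`` (shifted) by OLS; ``q`` is the negated slope.
    Non-positive sizes are excluded and counted in ``n_dropped``.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 strictly positive sizes remain.
    ConfigurationError
        Unknown rank convention.
    """
    if convention not in ("plain", "shifted"):
        raise ConfigurationError(
            f"convention must be 'plain' or 'shifted', got {convention!r}"
        )
    arr = np.asarray(sizes, dtype=float)
    finite_pos = np.isfinite(arr) & (arr > 0)
    n_dropped = int(arr.size - finite_pos.sum())
    vals = arr[finite_pos]
    if vals.size < 3:
        raise InsufficientDataError(
            f"need >= 3 positive sizes, got {vals.size} (dropped {n_dropped})"
        )
    order = np.argsort(-vals, kind="stable")
    vals = vals[order]
    n = vals.size

    if np.ptp(vals) == 0.0:
        # all sizes equal: a perfectly flat hierarchy, slope undefined/zero
        return RankSizeFit(
            resource=resource,
            year=year,
            q=0.0,
            ln_p1=float(np.log(vals[0])),
            r2=0.0,
            slope_p_value=float("nan"),
            n_used=n,
            n_dropped=n_dropped,
            convention=convention,
            degenerate=True,
        )

    ranks = np.arange(1, n + 1, dtype=float)
    if convention == "shifted":
        ranks = ranks - 0.5
    res = stats.linregress(np.log(ranks), np.log(vals))
    return RankSizeFit(
        resource=resource,
        year=year,
        q=float(-res.slope),
        ln_p1=float(res.intercept),
        r2=float(res.rvalue**2),
        slope_p_value=float(res.pvalue),
        n_used=n,
        n_dropped=n_dropped,
        convention=convention,
    )


def interpret_q(q: float) -> str:
    """Interpret a Zipf exponent: ``balanced`` (q<1), ``zipf_optimal``
    (q=1 within 1e-9, the canonical rank-size distribution), or
    ``concentrated`` (q>1, a primate/Pareto hierarchy)."""
    if not math.isfinite(q) or q <= 0:
        raise ValueError(f"q must be a positive finite number, got {q}")
    if abs(q - 1.0) <= 1e-9:
        return "zipf_optimal"
    return "balanced" if q < 1.0 else "concentrated"


def rank_size_series(
    panel: pd.DataFrame, resource: str, convention: str = "shifted"
) -> list[RankSizeFit]:
    """Per-year rank-size fits of one resource across a panel.

    Returns one :class:`RankSizeFit` per distinct year, in year order.
    Years with fewer than 3 positive values are skipped with a log message.
    """
    column = RESOURCE_COLUMNS.get(resource)
    if column is None or column not in panel.columns:
        raise ConfigurationError(
            f"unknown resource {resource!r}; expected one of {sorted(RESOURCE_COLUMNS)}"
        )
    if panel.empty:
        raise SchemaError("panel is empty")
    fits: list[RankSizeFit] = []
    for year, grp in panel.groupby("year", sort=True):
        vals = grp[column].to_numpy(dtype=float)
        n_pos = int(np.sum(np.isfinite(vals) & (vals > 0)))
        if n_pos < 3:
            logger.warning(
                "skipping year %s for %s: only %d positive values", year, resource, n_pos
            )
            continue
        fits.append(
            rank_size_fit(vals, convention, resource=resource, year=int(year))
        )
    return fits


# --------------------------------------------------------------------------
# Allometric scaling: fits, six-level classification, change typology
# --------------------------------------------------------------------------


class AllometricLevel(enum.IntEnum):
    """Six ordered allometric levels; the integer value is the grade.

    Grades order Negative3 < Negative2 < Negative1 < Positive1 < Positive2
    < Positive3.  ``Positive`` levels mean the resource grows faster than
    the economy (exponent at or above the 0.85 equal-rate threshold),
    ``Negative`` levels slower (or shrinking, for Negative3).
    """

    NEGATIVE3 = 1
    NEGATIVE2 = 2
    NEGATIVE1 = 3
    POSITIVE1 = 4
    POSITIVE2 = 5
    POSITIVE3 = 6

    @property
    def label(self) -> str:
        return self.name.capitalize()  # e.g. 'Negative3'

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def classify_level(b: float) -> AllometricLevel:
    """Band an allometric exponent into the six-level taxonomy.

    Thresholds (lower bounds inclusive): ``b >= 2`` Positive3; ``2 > b >= 1``
    Positive2; ``1 > b >= 0.85`` Positive1; ``0.85 > b >= 0.5`` Negative1;
    ``0.5 > b >= 0`` Negative2; ``b < 0`` Negative3.
    """
    if not math.isfinite(b):
        raise ValueError(f"b must be finite, got {b}")
    if b >= 2.0:
        return AllometricLevel.POSITIVE3
    if b >= 1.0:
        return AllometricLevel.POSITIVE2
    if b >= 0.85:
        return AllometricLevel.POSITIVE1
    if b >= 0.5:
        return AllometricLevel.NEGATIVE1
    if b >= 0.0:
        return AllometricLevel.NEGATIVE2
    return AllometricLevel.NEGATIVE3


@dataclass(frozen=True)
class AllometricFit:
    """One fitted allometric scaling relation ``ln A = k + b ln G``.

    ``orientation`` is ``"vertical"`` (across cities in one ``year``) or
    ``"horizontal"`` (across years of one ``city_id`` in a ``window``);
    ``level`` is always consistent with ``classify_level(b)``.
    """

    orientation: str
    resource: str
    b: float
    k: float
    r2: float
    n_used: int
    level: AllometricLevel
    year: int | None = None
    city_id: str | None = None
    window: str | None = None


@dataclass(frozen=True)
class AllometricChange:
    """A city's movement between allometric levels across two windows.

    ``grade_delta`` is the signed difference on the 6-point grade scale;
    a move of two or more grades counts as *fast* in either direction.
    """

    city_id: str
    resource: str
    level_before: AllometricLevel
    level_after: AllometricLevel
    grade_delta: int
    change_type: str


def allometric_fit(
    g: Sequence[float] | np.ndarray, a: Sequence[float] | np.ndarray
) -> tuple[float, float, float]:
    """OLS fit of ``ln(a)`` on ``ln(g)``; returns ``(b, k, r2)``.

    Pairs in which either member is non-positive or non-finite are dropped.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 valid pairs remain.
    DegenerateInputError
        ``ln(g)`` has zero variance (undefined slope).
    """
    g = np.asarray(g, dtype=float)
    a = np.asarray(a, dtype=float)
    if g.shape != a.shape:
        raise ContractError(f"g and a differ in length: {g.size} vs {a.size}")
    ok = np.isfinite(g) & np.isfinite(a) & (g > 0) & (a > 0)
    g, a = g[ok], a[ok]
    if g.size < 3:
        raise InsufficientDataError(f"need >= 3 valid pairs, got {g.size}")
    lg, la = np.log(g), np.log(a)
    if np.ptp(lg) == 0.0:
        raise DegenerateInputError("ln(g) has zero variance; slope undefined")
    if np.ptp(la) == 0.0:
        # flat response: exact zero slope, intercept at the constant level
        return 0.0, float(la[0]), 0.0
    res = stats.linregress(lg, la)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def vertical_allometry(
    panel: pd.DataFrame, resource: str, year: int
) -> AllometricFit:
    """Cross-sectional allometric fit of one resource against GDP in one year."""
    column = _resource_column(panel, resource)
    sub = panel.loc[panel["year"] == year]
    if sub.empty:
        raise InsufficientDataError(f"no observations for year {year}")
    b, k, r2 = allometric_fit(sub["gdp"].to_numpy(), sub[column].to_numpy())
    n_used = _n_valid_pairs(sub["gdp"].to_numpy(), sub[column].to_numpy())
    return AllometricFit(
        orientation="vertical",
        resource=resource,
        b=b,
        k=k,
        r2=r2,
        n_used=n_used,
        level=classify_level(b),
        year=int(year),
    )


def horizontal_allometry(
    panel: pd.DataFrame,
    resource: str,
    city: str,
    window: tuple[int, int],
    estimator: str = "ols",
) -> AllometricFit:
    """Longitudinal allometric fit for one city over an inclusive year window.

    The default estimator pools the city's in-window years into a single
    log-log OLS.  ``estimator="endpoint"`` instead uses the growth-rate
    ratio ``ln(A_end/A_start) / ln(G_end/G_start)`` between the window's
    first and last valid years, a sensitivity check with no R².
    """
    column = _resource_column(panel, resource)
    if estimator not in ("ols", "endpoint"):
        raise ConfigurationError(
            f"estimator must be 'ols' or 'endpoint', got {estimator!r}"
        )
    sub = panel.loc[panel["city_id"] == city]
    if sub.empty:
        raise KeyError(f"unknown city {city!r}")
    lo, hi = window
    sub = sub.loc[(sub["year"] >= lo) & (sub["year"] <= hi)].sort_values("year")
    g = sub["gdp"].to_numpy(dtype=float)
    a = sub[column].to_numpy(dtype=float)
    label = f"{lo}-{hi}"
    if estimator == "ols":
        b, k, r2 = allometric_fit(g, a)
        n_used = _n_valid_pairs(g, a)
    else:
        ok = np.isfinite(g) & np.isfinite(a) & (g > 0) & (a > 0)
        g, a = g[ok], a[ok]
        if g.size < 2:
            raise InsufficientDataError(
                f"need >= 2 valid in-window years, got {g.size}"
            )
        if g[-1] == g[0]:
            raise DegenerateInputError("no GDP change between window endpoints")
        b = float(np.log(a[-1] / a[0]) / np.log(g[-1] / g[0]))
        k = float(np.log(a[-1]) - b * np.log(g[-1]))
        r2 = float("nan")
        n_used = int(g.size)
    return AllometricFit(
        orientation="horizontal",
        resource=resource,
        b=b,
        k=k,
        r2=r2,
        n_used=n_used,
        level=classify_level(b),
        city_id=city,
        window=label,
    )


def change_typology(
    fit_before: AllometricFit, fit_after: AllometricFit
) -> AllometricChange:
    """Type a city's transition between allometric levels in two windows.

    ``grade_delta = 0`` is *stable*; ``+1``/``-1`` an *upgrade*/*decline*;
    a move of two or more grades in either direction is *fast_upgrade* /
    *fast_decline*.
    """
    if fit_before.city_id != fit_after.city_id:
        raise ContractError(
            f"city mismatch: {fit_before.city_id!r} vs {fit_after.city_id!r}"
        )
    if fit_before.resource != fit_after.resource:
        raise ContractError(
            f"resource mismatch: {fit_before.resource!r} vs {fit_after.resource!r}"
        )
    delta = int(fit_after.level) - int(fit_before.level)
    if delta == 0:
        kind = "stable"
    elif delta == 1:
        kind = "upgrade"
    elif delta >= 2:
        kind = "fast_upgrade"
    elif delta == -1:
        kind = "decline"
    else:
        kind = "fast_decline"
    return AllometricChange(
        city_id=str(fit_before.city_id),
        resource=fit_before.resource,
        level_before=fit_before.level,
        level_after=fit_after.level,
        grade_delta=delta,
        change_type=kind,
    )


CHANGE_TYPES = ("stable", "upgrade", "fast_upgrade", "decline", "fast_decline")


def window_summary(changes: Sequence[AllometricChange]) -> dict:
    """Counts and percentage shares per change type and per level.

    Shares are ``count / total * 100`` rounded to 2 decimals and sum to 100
    within rounding.  Also reports the aggregate share of non-stable cities.
    """
    if not changes:
        raise InsufficientDataError("empty change list")
    total = len(changes)

    def tally(keys: Iterable[str], universe: Sequence[str]) -> dict:
        counts = {u: 0 for u in universe}
        for key in keys:
            counts[key] = counts.get(key, 0) + 1
        return {
            u: {"count": c, "share": round(c / total * 100, 2)}
            for u, c in counts.items()
        }

    levels = [lv.label for lv in AllometricLevel]
    n_changed = sum(1 for c in changes if c.change_type != "stable")
    return {
        "n": total,
        "n_changed": n_changed,
        "changed_share": round(n_changed / total * 100, 2),
        "change_type": tally((c.change_type for c in changes), CHANGE_TYPES),
        "level_before": tally((c.level_before.label for c in changes), levels),
        "level_after": tally((c.level_after.label for c in changes), levels),
    }


def _resource_column(panel: pd.DataFrame, resource: str) -> str:
    column = RESOURCE_COLUMNS.get(resource)
    if column is None or column not in panel.columns:
        raise ConfigurationError(
            f"unknown resource {resource!r}; expected one of {sorted(RESOURCE_COLUMNS)}"
        )
    return column


def _n_valid_pairs(g: np.ndarray, a: np.ndarray) -> int:
    g = np.asarray(g, dtype=float)
    a = np.asarray(a, dtype=float)
    return int(np.sum(np.isfinite(g) & np.isfinite(a) & (g > 0) & (a > 0)))


# --------------------------------------------------------------------------
# Panel I/O
# --------------------------------------------------------------------------

_CANONICAL_NAMES = {
    "city": "city_id",
    "city_id": "city_id",
    "cityid": "city_id",
    "city_name": "city_name",
    "cityname": "city_name",
    "name": "city_name",
    "year": "year",
    "gdp": "gdp",
    "beds": "beds",
    "doctors": "doctors",
}


def read_panel(
    path: str | Path,
    format: str | None = None,
    *,
    sheet: str | int = 0,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a city-year panel from CSV or XLSX.

    Column names are matched case-insensitively against
    ``city / city_id, city_name, year, gdp, beds, doctors``; ``column_map``
    supplies extra source-name -> canonical-name mappings.  Rows with
    unparseable numerics are excluded with a logged count (blank cells stay
    as missing); non-positive GDP values are set to missing.  Duplicate
    ``(city_id, year)`` pairs raise :class:`IntegrityError`.
    """
    path = Path(path)
    if format is None:
        format = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if format == "csv":
        raw = pd.read_csv(path, dtype=str, encoding="utf-8")
    elif format == "xlsx":
        raw = pd.read_excel(path, sheet_name=sheet, dtype=str)
    else:
        raise ConfigurationError(f"format must be 'csv' or 'xlsx', got {format!r}")
    return validate_panel_frame(raw, column_map=column_map)


def validate_panel_frame(
    raw: pd.DataFrame, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Apply the panel schema to an already-loaded frame (see read_panel)."""
    rename: dict[str, str] = {}
    mapping = dict(_CANONICAL_NAMES)
    if column_map:
        mapping.update({k.strip().lower(): v for k, v in column_map.items()})
    for col in raw.columns:
        canon = mapping.get(str(col).strip().lower())
        if canon is not None and canon not in rename.values():
            rename[col] = canon
    df = raw.rename(columns=rename)

    required = ["city_id", "year", "gdp", "beds", "doctors"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"panel is missing required columns: {missing}")
    if df.empty:
        raise SchemaError("panel has no data rows")
    if "city_name" not in df.columns:
        df["city_name"] = df["city_id"]

    df = df[PANEL_COLUMNS].copy()
    n_bad = 0
    for col in ("year", "gdp", "beds", "doctors"):
        text = df[col].astype("string").str.strip()
        coerced = pd.to_numeric(text, errors="coerce")
        bad = (text.notna() & (text != "") & coerced.isna()).fillna(False).astype(bool)
        n_bad += int(bad.sum())
        df = df.loc[~bad]
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if n_bad:
        logger.warning("excluded %d rows with unparseable numeric cells", n_bad)
    df = df.loc[df["year"].notna()]
    if df.empty:
        raise SchemaError("panel has no parseable data rows")
    df["year"] = df["year"].astype(int)
    nonpos_gdp = df["gdp"].notna() & (df["gdp"] <= 0)
    if nonpos_gdp.any():
        logger.warning("set %d non-positive GDP values to missing", int(nonpos_gdp.sum()))
        df.loc[nonpos_gdp, "gdp"] = np.nan

    dup = df.duplicated(subset=["city_id", "year"])
    if dup.any():
        pairs = df.loc[dup, ["city_id", "year"]].to_records(index=False).tolist()
        raise IntegrityError(f"duplicate (city, year) rows: {pairs[:5]}")
    return df.sort_values(["city_id", "year"], kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# Map-preparation transforms
# --------------------------------------------------------------------------


def percent_total_normalize(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Percent-of-total normalisation: ``value / sum * 100``.

    Output sums to 100 within 1e-9.  All inputs must be non-negative and at
    least one must be positive.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("empty input")
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("values must be finite and non-negative")
    total = arr.sum()
    if total == 0:
        raise DegenerateInputError("all values are zero; shares undefined")
    return arr / total * 100.0


@dataclass(frozen=True)
class BreaksClassification:
    """A fitted Jenks natural-breaks classification.

    ``breaks`` holds the ``k - 1`` interior cut values (each the maximum of
    its class); ``labels`` the ordered class names from lowest to highest;
    ``sse`` the achieved total within-class sum of squared deviations.
    """

    breaks: tuple[float, ...]
    labels: tuple[str, ...]
    sse: float

    def assign(self, values: Sequence[float] | np.ndarray) -> np.ndarray:
        """Class index (0-based, non-decreasing in value) of each value."""
        arr = np.asarray(values, dtype=float)
        return np.searchsorted(np.asarray(self.breaks), arr, side="left")

    def label_of(self, value: float) -> str:
        return self.labels[int(self.assign([value])[0])]


_DEFAULT_5_LABELS = ("lagging", "low", "intermediate", "good", "leading")


def natural_breaks(
    values: Sequence[float] | np.ndarray,
    k: int = 5,
    labels: Sequence[str] | None = None,
) -> BreaksClassification:
    """Jenks natural-breaks classification into ``k`` contiguous classes.

    Solves the exact optimisation — among all contiguous partitions of the
    sorted values into ``k`` classes, pick the one minimising total
    within-class sum of squared deviations — by dynamic programming
    (O(n²k)).  Ties are broken deterministically in favour of earlier
    (smaller) break values.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if np.unique(arr).size < k:
        raise InsufficientDataError(
            f"need >= {k} distinct values, got {np.unique(arr).size}"
        )
    if labels is None:
        labels = _DEFAULT_5_LABELS if k == 5 else tuple(f"class{j+1}" for j in range(k))
    elif len(labels) != k:
        raise ConfigurationError(f"need {k} labels, got {len(labels)}")

    # prefix sums for O(1) segment SSE: sse(i, j) over arr[i:j]
    csum = np.concatenate([[0.0], np.cumsum(arr)])
    csq = np.concatenate([[0.0], np.cumsum(arr * arr)])

    def seg_sse(i: int, j: int) -> float:
        s = csum[j] - csum[i]
        return float(csq[j] - csq[i] - s * s / (j - i))

    INF = float("inf")
    cost = [[INF] * (n + 1) for _ in range(k + 1)]
    split = [[0] * (n + 1) for _ in range(k + 1)]
    cost[0][0] = 0.0
    for j in range(1, k + 1):
        for i in range(j, n + 1):
            best, best_m = INF, j - 1
            for m in range(j - 1, i):
                c = cost[j - 1][m] + seg_sse(m, i)
                if c < best - 1e-12:  # strict improvement keeps smallest m on ties
                    best, best_m = c, m
            cost[j][i] = best
            split[j][i] = best_m

    cuts = []
    i = n
    for j in range(k, 1, -1):
        i = split[j][i]
        cuts.append(i)
    cuts.reverse()
    breaks = tuple(float(arr[c - 1]) for c in cuts)
    return BreaksClassification(breaks=breaks, labels=tuple(labels), sse=cost[k][n])


def percent_change(start: float, end: float) -> float:
    """Signed percent change ``(end - start) / start * 100`` (unrounded;
    reports round to 2 decimals)."""
    if start == 0:
        raise ValueError("start must be non-zero")
    return (end - start) / start * 100.0


# --------------------------------------------------------------------------
# Study orchestration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyConfig:
    """Options of a full study run over a panel."""

    resources: tuple[str, ...] = ("beds", "doctors")
    convention: str = "shifted"
    window_a: tuple[int, int] = (2009, 2015)
    window_b: tuple[int, int] = (2016, 2022)
    seed: int | None = None


def run_study(
    panel: pd.DataFrame,
    out_dir: str | Path,
    config: StudyConfig = StudyConfig(),
) -> dict:
    """Run the full replication pipeline on a validated panel.

    For each resource: per-year rank-size fits; per-year vertical allometric
    fits; per-city horizontal fits over both windows; the grade-change
    typology between windows; headline percent-change statistics; per-year
    totals.  Everything is written as CSVs under ``out_dir`` together with
    a machine-readable ``manifest.json``; the same tables are returned as
    DataFrames keyed by file stem.

    Coefficients are rounded to 4 decimals and percentages to 2 in the
    written reports; returned frames carry the same rounding so re-runs are
    byte-identical.
    """
    if panel is None or panel.empty:
        raise SchemaError("panel has no data rows")
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise SchemaError(f"panel is missing required columns: {missing}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ranksize_rows, vertical_rows, horizontal_rows, change_rows, summary_rows = (
        [],
        [],
        [],
        [],
        [],
    )
    years = sorted(panel["year"].unique())
    cities = sorted(panel["city_id"].unique())

    for resource in config.resources:
        fits = rank_size_series(panel, resource, config.convention)
        for f in fits:
            ranksize_rows.append(
                {
                    "resource": resource,
                    "year": f.year,
                    "q": round(f.q, 4),
                    "ln_p1": round(f.ln_p1, 4),
                    "r2": round(f.r2, 4),
                    "p_value": round(f.slope_p_value, 6)
                    if math.isfinite(f.slope_p_value)
                    else "",
                    "n_used": f.n_used,
                    "n_dropped": f.n_dropped,
                    "convention": f.convention,
                }
            )
        if fits:
            summary_rows.append(
                {
                    "resource": resource,
                    "metric": "zipf_q_change_pct",
                    "value": round(percent_change(fits[0].q, fits[-1].q), 2),
                }
            )

        vfits = []
        for year in years:
            try:
                vf = vertical_allometry(panel, resource, int(year))
            except (InsufficientDataError, DegenerateInputError) as exc:
                logger.warning("vertical fit skipped (%s, %s): %s", resource, year, exc)
                continue
            vfits.append(vf)
            vertical_rows.append(
                {
                    "resource": resource,
                    "year": vf.year,
                    "b": round(vf.b, 4),
                    "k": round(vf.k, 4),
                    "r2": round(vf.r2, 4),
                    "n_used": vf.n_used,
                    "level": vf.level.label,
                }
            )
        if vfits:
            summary_rows.append(
                {
                    "resource": resource,
                    "metric": "vertical_b_change_pct",
                    "value": round(percent_change(vfits[0].b, vfits[-1].b), 2),
                }
            )

        changes = []
        for city in cities:
            pair = []
            for window in (config.window_a, config.window_b):
                try:
                    pair.append(
                        horizontal_allometry(panel, resource, city, window)
                    )
                except (InsufficientDataError, DegenerateInputError, KeyError) as exc:
                    logger.warning(
                        "horizontal fit skipped (%s, %s, %s): %s",
                        resource,
                        city,
                        window,
                        exc,
                    )
                    pair.append(None)
            for hf in pair:
                if hf is not None:
                    horizontal_rows.append(
                        {
                            "resource": resource,
                            "city_id": hf.city_id,
                            "window": hf.window,
                            "b": round(hf.b, 4),
                            "k": round(hf.k, 4),
                            "r2": round(hf.r2, 4),
                            "n_used": hf.n_used,
                            "level": hf.level.label,
                        }
                    )
            if pair[0] is not None and pair[1] is not None:
                changes.append(change_typology(pair[0], pair[1]))
        for ch in changes:
            change_rows.append(
                {
                    "resource": resource,
                    "city_id": ch.city_id,
                    "level_before": ch.level_before.label,
                    "level_after": ch.level_after.label,
                    "grade_delta": ch.grade_delta,
                    "change_type": ch.change_type,
                }
            )
        if changes:
            summ = window_summary(changes)
            summary_rows.append(
                {
                    "resource": resource,
                    "metric": "changed_share_pct",
                    "value": summ["changed_share"],
                }
            )
            for kind in CHANGE_TYPES:
                summary_rows.append(
                    {
                        "resource": resource,
                        "metric": f"share_{kind}_pct",
                        "value": summ["change_type"][kind]["share"],
                    }
                )

    # per-year Series.sum so totals equal column sums of year slices exactly
    totals = pd.DataFrame(
        [
            {
                "year": int(year),
                "gdp_total": panel.loc[panel["year"] == year, "gdp"].sum(min_count=1),
                "beds_total": panel.loc[panel["year"] == year, "beds"].sum(min_count=1),
                "doctors_total": panel.loc[panel["year"] == year, "doctors"].sum(min_count=1),
            }
            for year in years
        ]
    )

    tables = {
        "ranksize": pd.DataFrame(ranksize_rows),
        "vertical": pd.DataFrame(vertical_rows),
        "horizontal": pd.DataFrame(horizontal_rows),
        "changes": pd.DataFrame(change_rows),
        "summary": pd.DataFrame(summary_rows),
        "totals": totals,
    }
    manifest = {
        "config": {
            "resources": list(config.resources),
            "convention": config.convention,
            "window_a": list(config.window_a),
            "window_b": list(config.window_b),
            "seed": config.seed,
        },
        "n_cities": len(cities),
        "years": [int(years[0]), int(years[-1])] if years else [],
        "files": {},
    }
    for stem, frame in tables.items():
        path = out_dir / f"{stem}.csv"
        frame.to_csv(path, index=False, encoding="utf-8")
        manifest["files"][f"{stem}.csv"] = int(len(frame))
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    tables["manifest"] = manifest
    return tables
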
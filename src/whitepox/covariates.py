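"""Design-matrix construction for the eight tested covariates.

The eight covariates screened for association with disease presence are:
colony northing and easting (UTM metres), colony size (cm^3), the running
count of the colony's previous disease incidences (zero at the study start),
distance to the nearest neighbouring colony, distance to the nearest colony
that showed disease at the previous occasion, trailing 30-day mean water
temperature, and solar insolation.  Together with an intercept this gives a
p = 9 design.

Colony size and the two distance covariates are log10-transformed by default
(they span orders of magnitude); every continuous covariate is then z-scored
over the observed cells so that coefficients are comparable across covariates
with wildly different raw units.  The transform and the (mean, sd) actually
used are recorded on the returned matrix so new data can be projected onto the
identical scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .panel import ColonyRecord, SurveyPanel

__all__ = [
    "COVARIATE_NAMES",
    "DesignOptions",
    "CovariateMatrix",
    "previous_incidences",
    "distance_nearest_neighbor",
    "distance_previously_infected",
    "temperature_trailing_mean",
    "build_design",
]

#: design-column order; intercept first, then the eight covariates
COVARIATE_NAMES: tuple[str, ...] = (
    "intercept",
    "northing",
    "easting",
    "colony_size",
    "previous_incidences",
    "distance_nearest",
    "distance_prev_infected",
    "water_temperature",
    "solar_insolation",
)

#: covariates log10-transformed before z-scoring (default)
LOG10_COVARIATES: tuple[str, ...] = (
    "colony_size",
    "distance_nearest",
    "distance_prev_infected",
)


class StandardizationError(ValueError):
    """A covariate has zero variance and cannot be z-scored."""


class UndefinedCovariateError(ValueError):
    """A covariate is undefined for the given panel (e.g. a single colony)."""


@dataclass(frozen=True)
class DesignOptions:
    """Configuration for :func:`build_design`.

    standardize:
        z-score continuous covariates over observed cells (default True).
    log10_size, log10_distances:
        apply log10 before z-scoring to colony size / the distance pair.
    episode_counting:
        count distinct disease episodes (0->1 onsets) instead of cumulative
        presence-months for previous_incidences.
    prev_infected_fill:
        value used when no colony was diseased at the previous occasion:
        "max_pairwise" (default) or "domain_diagonal".
    """

    standardize: bool = True
    log10_size: bool = True
    log10_distances: bool = True
    episode_counting: bool = False
    prev_infected_fill: str = "max_pairwise"

    def __post_init__(self) -> None:
        if self.prev_infected_fill not in ("max_pairwise", "domain_diagonal"):
            raise ValueError("prev_infected_fill must be max_pairwise or domain_diagonal")


@dataclass
class CovariateMatrix:
    """Standardized design z(s_i, t): (colony, occasion, p) with metadata.

    ``standardization[name] = (mean, sd)`` records the z-scoring constants on
    the transformed scale ((1.0, 0.0) meaning untouched); ``transform_log``
    flags covariates that were log10-transformed first.
    """

    names: tuple[str, ...]
    values: np.ndarray
    standardization: dict[str, tuple[float, float]]
    transform_log: dict[str, bool]
    options: DesignOptions = dataclass_field(default_factory=DesignOptions)

    @property
    def p(self) -> int:
        return self.values.shape[2]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, :, self.names.index(name)]

    def flat(self, observed: np.ndarray | None = None) -> np.ndarray:
        """Occasion-major flattening to (n*T, p) rows; optionally masked."""
        n, T, p = self.values.shape
        z = self.values.transpose(1, 0, 2).reshape(n * T, p)
        if observed is not None:
            z = z[observed.T.ravel()]
        return z


def previous_incidences(presence: np.ndarray, episodes: bool = False) -> np.ndarray:
    """Running count of a colony's previous disease incidences.

    Cell (i, t) counts the survey occasions t' < t at which colony i showed
    disease (missing occasions contribute nothing); every colony starts at
    zero at the first occasion.  With ``episodes=True`` distinct 0->1 onsets
    are counted instead of presence-months.
    """
    presence = np.asarray(presence, dtype=float)
    obs = np.nan_to_num(presence, nan=0.0)
    if episodes:
        prev = np.concatenate([np.zeros((presence.shape[0], 1)), obs[:, :-1]], axis=1)
        onsets = (obs == 1) & (prev != 1)
        obs = onsets.astype(float)
    cum = np.cumsum(obs, axis=1)
    out = np.concatenate([np.zeros((presence.shape[0], 1)), cum[:, :-1]], axis=1)
    return out


def distance_nearest_neighbor(colonies: list[ColonyRecord]) -> np.ndarray:
    """Per-colony distance (m) to its nearest neighbouring colony."""
    if len(colonies) < 2:
        raise UndefinedCovariateError(
            "distance to nearest neighbour is undefined with fewer than 2 colonies"
        )
    xy = np.array([[c.easting, c.northing] for c in colonies])
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def distance_previously_infected(
    presence: np.ndarray,
    colonies: list[ColonyRecord],
    fill: str = "max_pairwise",
    domain: tuple[float, float] | None = None,
) -> np.ndarray:
    """Distance (m) from each colony to the nearest colony diseased at t-1.

    A colony's own previous infection does not count as a source (self is
    excluded).  When no colony was diseased at t-1 — and at the first
    occasion — the cell takes a fill value encoding "no nearby source": the
    maximum observed pairwise distance (default) or the domain diagonal.
    """
    presence = np.asarray(presence, dtype=float)
    n, T = presence.shape
    xy = np.array([[c.easting, c.northing] for c in colonies])
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1))
    if fill == "max_pairwise":
        fill_value = float(d.max())
    elif fill == "domain_diagonal":
        if domain is None:
            ext = xy.max(axis=0) - xy.min(axis=0)
        else:
            ext = np.asarray(domain, dtype=float)
        fill_value = float(np.sqrt((ext**2).sum()))
    else:
        raise ValueError(f"unknown fill rule: {fill}")

    out = np.full((n, T), fill_value)
    d_self = d.copy()
    np.fill_diagonal(d_self, np.inf)
    for t in range(1, T):
        infected = np.where(presence[:, t - 1] == 1)[0]
        if infected.size == 0:
            continue
        dmin = d_self[:, infected].min(axis=1)
        out[:, t] = np.where(np.isfinite(dmin), dmin, fill_value)
    return out


def temperature_trailing_mean(
    times: np.ndarray,
    values: np.ndarray,
    survey_dates,
    window_days: float = 30.0,
) -> np.ndarray:
    """Trailing mean of a logger series over [date - window, date) per survey.

    Occasions whose window holds no readings come back as NaN (flagged
    missing) rather than raising.
    """
    import pandas as pd

    times = pd.DatetimeIndex(times)
    values = np.asarray(values, dtype=float)
    if len(times) == 0:
        raise ValueError("empty temperature series")
    if len(times) != len(values):
        raise ValueError("times and values must align")
    order = np.argsort(times.values)
    times = times[order]
    values = values[order]
    out = np.full(len(survey_dates), np.nan)
    window = pd.Timedelta(days=window_days)
    for j, date in enumerate(pd.DatetimeIndex(survey_dates)):
        lo = times.searchsorted(date - window, side="left")
        hi = times.searchsorted(date, side="left")
        if hi > lo:
            out[j] = values[lo:hi].mean()
    return out


def _standardize(
    raw: np.ndarray, observed: np.ndarray, name: str
) -> tuple[np.ndarray, tuple[float, float]]:
    vals = raw[observed]
    mean = float(vals.mean())
    sd = float(vals.std())
    if sd < 1e-12:
        raise StandardizationError(f"covariate '{name}' has zero variance")
    return (raw - mean) / sd, (mean, sd)


def build_design(
    panel: SurveyPanel,
    options: DesignOptions | None = None,
    reference: dict[str, tuple[float, float]] | None = None,
) -> CovariateMatrix:
    """Assemble the standardized (colony, occasion, p = 9) design matrix.

    ``reference`` optionally supplies fixed (mean, sd) constants (on the
    transformed scale) instead of the panel's own sample statistics — used to
    project new data, or by the simulator, onto a previously fitted scale.
    """
    options = options or DesignOptions()
    n, T = panel.n_colonies, panel.n_occasions
    observed = panel.observed

    raw: dict[str, np.ndarray] = {}
    raw["northing"] = np.repeat(
        np.array([c.northing for c in panel.colonies])[:, None], T, axis=1
    )
    raw["easting"] = np.repeat(
        np.array([c.easting for c in panel.colonies])[:, None], T, axis=1
    )
    raw["colony_size"] = panel.size.copy()
    raw["previous_incidences"] = previous_incidences(
        panel.presence, episodes=options.episode_counting
    )
    raw["distance_nearest"] = np.repeat(
        distance_nearest_neighbor(panel.colonies)[:, None], T, axis=1
    )
    raw["distance_prev_infected"] = distance_previously_infected(
        panel.presence, panel.colonies, fill=options.prev_infected_fill
    )
    raw["water_temperature"] = np.repeat(panel.temperature[None, :], n, axis=0)
    raw["solar_insolation"] = np.repeat(panel.insolation[None, :], n, axis=0)

    transform_log = {name: False for name in COVARIATE_NAMES}
    if options.log10_size:
        transform_log["colony_size"] = True
    if options.log10_distances:
        transform_log["distance_nearest"] = True
        transform_log["distance_prev_infected"] = True

    values = np.empty((n, T, len(COVARIATE_NAMES)))
    standardization: dict[str, tuple[float, float]] = {"intercept": (0.0, 1.0)}
    values[:, :, 0] = 1.0
    for k, name in enumerate(COVARIATE_NAMES[1:], start=1):
        x = raw[name]
        if transform_log[name]:
            if np.any(x[observed] <= 0):
                raise ValueError(f"covariate '{name}': log10 of non-positive value")
            x = np.log10(x)
        if options.standardize:
            if reference is not None and name in reference:
                mean, sd = reference[name]
                if sd <= 0:
                    raise StandardizationError(
                        f"reference sd for '{name}' must be positive"
                    )
                values[:, :, k] = (x - mean) / sd
                standardization[name] = (float(mean), float(sd))
            else:
                values[:, :, k], standardization[name] = _standardize(
                    x, observed, name
                )
        else:
            values[:, :, k] = x
            standardization[name] = (0.0, 1.0)

    return CovariateMatrix(
        names=COVARIATE_NAMES,
        values=values,
        standardization=standardization,
        transform_log=transform_log,
        options=options,
    )
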
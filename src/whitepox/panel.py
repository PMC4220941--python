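"""Survey-panel container and CSV round-trip.

A survey panel is the long-format record of monthly presence/absence surveys
of tagged coral colonies: one row per (colony, survey date) carrying the
colony's planar UTM location, its size, the 0/1 disease indicator, and the two
site-wide environmental series (trailing 30-day mean water temperature and
solar insolation, identical for every colony within an occasion).

Missing surveys are first-class: a blank presence field is retained as a
missing cell, excluded from the likelihood downstream, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ColonyRecord",
    "SurveyPanel",
    "SchemaError",
    "IntegrityError",
    "DEFAULT_SCHEMA",
    "read_panel",
    "write_panel",
]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is absent from the input CSV."""


class IntegrityError(ValueError):
    """The input violates panel integrity (e.g. duplicated colony-date rows)."""


#: canonical field -> default CSV column name
DEFAULT_SCHEMA: dict[str, str] = {
    "colony_id": "colony_id",
    "easting": "easting",
    "northing": "northing",
    "date": "date",
    "size": "size_cm3",
    "presence": "presence",
    "temperature": "temperature_c",
    "insolation": "insolation",
}


@dataclass(frozen=True)
class ColonyRecord:
    """A tagged colony: identifier, UTM location (m) and initial size (cm^3)."""

    colony_id: str
    easting: float
    northing: float
    initial_size: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.easting) and np.isfinite(self.northing)):
            raise ValueError(f"colony {self.colony_id}: non-finite coordinates")
        if not self.initial_size > 0:
            raise ValueError(f"colony {self.colony_id}: initial_size must be > 0")


@dataclass
class SurveyPanel:
    """Colony x survey-occasion grid of disease presence with covariate inputs.

    Attributes
    ----------
    colonies:
        One :class:`ColonyRecord` per tagged colony; ids unique.
    occasions:
        Strictly increasing survey dates (pandas DatetimeIndex), one per
        monthly occasion.
    presence:
        (n_colonies, n_occasions) float array in {0, 1, NaN}; NaN marks a
        missing survey.
    temperature:
        Per-occasion trailing 30-day mean water temperature, deg C.
    insolation:
        Per-occasion solar insolation, kW m^-2 day^-1.
    size:
        (n_colonies, n_occasions) colony size in cm^3; constant per colony
        when sizes were recorded once.
    """

    colonies: list[ColonyRecord]
    occasions: pd.DatetimeIndex
    presence: np.ndarray
    temperature: np.ndarray
    insolation: np.ndarray
    size: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ids = [c.colony_id for c in self.colonies]
        if len(set(ids)) != len(ids):
            raise IntegrityError("colony ids are not unique")
        self.occasions = pd.DatetimeIndex(self.occasions)
        if len(self.occasions) > 1 and not self.occasions.is_monotonic_increasing:
            raise ValueError("occasions must be increasing in time")
        if self.occasions.has_duplicates:
            raise IntegrityError("duplicated survey occasions")
        self.presence = np.asarray(self.presence, dtype=float)
        if self.presence.shape != (len(self.colonies), len(self.occasions)):
            raise ValueError(
                f"presence shape {self.presence.shape} != "
                f"({len(self.colonies)}, {len(self.occasions)})"
            )
        obs = self.presence[~np.isnan(self.presence)]
        if not np.isin(obs, (0.0, 1.0)).all():
            raise ValueError("presence values must be 0, 1 or missing")
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.insolation = np.asarray(self.insolation, dtype=float)
        if self.temperature.shape != (len(self.occasions),):
            raise ValueError("temperature must have one value per occasion")
        if self.insolation.shape != (len(self.occasions),):
            raise ValueError("insolation must have one value per occasion")
        if self.size is None:
            self.size = np.repeat(
                np.array([c.initial_size for c in self.colonies])[:, None],
                len(self.occasions),
                axis=1,
            )
        self.size = np.asarray(self.size, dtype=float)
        if self.size.shape != self.presence.shape:
            raise ValueError("size must be colony x occasion")

    @property
    def n_colonies(self) -> int:
        return len(self.colonies)

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of observed (non-missing) cells."""
        return ~np.isnan(self.presence)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.presence).sum())

    @property
    def coordinates(self) -> np.ndarray:
        """(n_colonies, 2) easting/northing in metres."""
        return np.array([[c.easting, c.northing] for c in self.colonies])

    def distance_matrix(self) -> np.ndarray:
        xy = self.coordinates
        d = xy[:, None, :] - xy[None, :, :]
        return np.sqrt((d**2).sum(axis=-1))

    def equals(self, other: "SurveyPanel", rtol: float = 1e-9) -> bool:
        if self.n_colonies != other.n_colonies or self.n_occasions != other.n_occasions:
            return False
        if [c.colony_id for c in self.colonies] != [c.colony_id for c in other.colonies]:
            return False
        if not (self.occasions == other.occasions).all():
            return False
        same = np.allclose(self.coordinates, other.coordinates, rtol=rtol)
        same &= np.allclose(self.presence, other.presence, rtol=rtol, equal_nan=True)
        same &= np.allclose(self.temperature, other.temperature, rtol=rtol)
        same &= np.allclose(self.insolation, other.insolation, rtol=rtol)
        same &= np.allclose(self.size, other.size, rtol=rtol)
        return bool(same)


def read_panel(
    path,
    schema: dict[str, str] | None = None,
    temperature_tol: float = 1e-6,
) -> SurveyPanel:
    """Read and validate a long-format survey CSV into a :class:`SurveyPanel`.

    Parameters
    ----------
    path:
        CSV with one row per (colony, survey date); header row; ISO dates.
    schema:
        Optional mapping from canonical field names
        (``colony_id, easting, northing, date, size, presence, temperature,
        insolation``) to the column names actually used in the file.

    Raises
    ------
    SchemaError
        If a required column is missing (the message names it).
    IntegrityError
        On duplicated (colony, date) rows or inconsistent per-occasion
        environmental values.
    ValueError
        On non-binary presence values.
    """
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        unknown = set(schema) - set(DEFAULT_SCHEMA)
        if unknown:
            raise SchemaError(f"unknown schema fields: {sorted(unknown)}")
        cols.update(schema)

    df = pd.read_csv(path)
    for canon, name in cols.items():
        if name not in df.columns:
            raise SchemaError(f"required column '{name}' ({canon}) not found")
    df = df.rename(columns={v: k for k, v in cols.items()})
    df["date"] = pd.to_datetime(df["date"])

    dup = df.duplicated(subset=["colony_id", "date"])
    if dup.any():
        first = df.loc[dup, ["colony_id", "date"]].iloc[0]
        raise IntegrityError(
            f"duplicated (colony, date) row: {first.colony_id} @ {first.date.date()}"
        )
    obs_presence = df["presence"].dropna()
    if not obs_presence.isin([0, 1]).all():
        bad = obs_presence[~obs_presence.isin([0, 1])].iloc[0]
        raise ValueError(f"non-binary presence value: {bad!r}")

    occasions = pd.DatetimeIndex(sorted(df["date"].unique()))
    colony_ids = list(pd.unique(df["colony_id"].astype(str)))
    df["colony_id"] = df["colony_id"].astype(str)
    t_index = {d: j for j, d in enumerate(occasions)}
    c_index = {c: i for i, c in enumerate(colony_ids)}

    n, T = len(colony_ids), len(occasions)
    presence = np.full((n, T), np.nan)
    size = np.full((n, T), np.nan)
    temperature = np.full(T, np.nan)
    insolation = np.full(T, np.nan)

    colonies = []
    for cid, grp in df.groupby("colony_id", sort=False):
        e = grp["easting"].iloc[0]
        nn = grp["northing"].iloc[0]
        if grp["easting"].nunique() > 1 or grp["northing"].nunique() > 1:
            raise IntegrityError(f"colony {cid}: location varies across rows")
        first_size = grp.sort_values("date")["size"].iloc[0]
        colonies.append(ColonyRecord(str(cid), float(e), float(nn), float(first_size)))
    colonies.sort(key=lambda c: c_index[c.colony_id])

    for row in df.itertuples(index=False):
        i, j = c_index[row.colony_id], t_index[row.date]
        presence[i, j] = row.presence if pd.notna(row.presence) else np.nan
        size[i, j] = row.size
        for arr, val, label in (
            (temperature, row.temperature, "temperature"),
            (insolation, row.insolation, "insolation"),
        ):
            if np.isnan(arr[j]):
                arr[j] = val
            elif abs(arr[j] - val) > temperature_tol:
                raise IntegrityError(
                    f"{label} differs across colonies at {occasions[j].date()}"
                )

    # colonies absent at an occasion: carry size forward/backward
    size_df = pd.DataFrame(size).ffill(axis=1).bfill(axis=1)
    size = size_df.to_numpy()

    panel = SurveyPanel(
        colonies=colonies,
        occasions=occasions,
        presence=presence,
        temperature=temperature,
        insolation=insolation,
        size=size,
    )
    logger.info(
        "loaded panel: %d colonies, %d occasions, %d missing presence cells",
        panel.n_colonies,
        panel.n_occasions,
        panel.n_missing,
    )
    return panel


def write_panel(panel: SurveyPanel, path, schema: dict[str, str] | None = None):
    """Write a panel back to the long CSV dialect; read_panel round-trips it."""
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    rows = []
    for i, col in enumerate(panel.colonies):
        for j, date in enumerate(panel.occasions):
            p = panel.presence[i, j]
            rows.append(
                {
                    cols["colony_id"]: col.colony_id,
                    cols["easting"]: col.easting,
                    cols["northing"]: col.northing,
                    cols["date"]: date.date().isoformat(),
                    cols["size"]: panel.size[i, j],
                    cols["presence"]: "" if np.isnan(p) else int(p),
                    cols["temperature"]: panel.temperature[j],
                    cols["insolation"]: panel.insolation[j],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
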
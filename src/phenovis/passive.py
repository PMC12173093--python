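"""Passive-data features: significant locations, home time, daily dwell.

GPS pings are reduced to a small set of **significant locations** — spatial
clusters where the patient repeatedly dwells — by k-means over a local planar
projection of the coordinates. "Home" is the location with the most total
dwell. Each ping's dwell contribution is the time gap to the next ping,
capped so that long recording outages do not dominate; this makes the
features robust to uneven sampling rates.

Per local calendar day the module reports the fraction of dwell spent at
each significant location (plus an "other" bucket) and the **home-time
percentage**, the headline passive marker: elevated home time in the month
before a relapse is the expected behavioral signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import GpsTable, ValidationError

METERS_PER_DEG_LAT = 111_320.0
OTHER_ID = "other"


@dataclass(frozen=True)
class PassiveConfig:
    max_locations: int = 6
    radius_m: float = 200.0
    max_gap_minutes: float = 60.0
    min_dwell_fraction: float = 0.01
    seed: int = 0


@dataclass
class SignificantLocationSet:
    """Ranked dwell clusters for one patient.

    ``locations`` has one row per significant location: id, centroid
    latitude/longitude in degrees, total dwell_minutes, rank (1 = home).
    ``origin`` is the projection reference point used when the set was
    fitted; ping assignment reuses it so distances are consistent.
    """

    locations: pd.DataFrame
    home_id: str
    origin: tuple[float, float]  # (lat0, lon0) of the equirectangular projection

    def __len__(self) -> int:
        return len(self.locations)


def _project(lat: np.ndarray, lon: np.ndarray, origin: tuple[float, float]) -> np.ndarray:
    """Equirectangular projection to meters about *origin* — adequate at
    city scale, and keeps k-means in plain Euclidean geometry."""
    lat0, lon0 = origin
    x = (lon - lon0) * METERS_PER_DEG_LAT * np.cos(np.deg2rad(lat0))
    y = (lat - lat0) * METERS_PER_DEG_LAT
    return np.column_stack([x, y])


def _dwell_minutes(timestamps: pd.Series, cap_minutes: float) -> np.ndarray:
    """Per-ping dwell weight: gap to the next ping, capped. The last ping's
    dwell is unobserved and is imputed with the median capped gap (so a
    uniformly sampled trace weights every ping equally)."""
    t = timestamps.to_numpy()
    gaps = np.empty(len(t))
    if len(t) > 1:
        deltas = (t[1:] - t[:-1]) / np.timedelta64(60, "s")
        gaps[:-1] = np.minimum(deltas.astype(float), cap_minutes)
        gaps[-1] = float(np.median(gaps[:-1]))
    else:
        gaps[-1] = cap_minutes
    return gaps


def _merge_close_clusters(
    xy: np.ndarray,
    dwell: np.ndarray,
    labels: np.ndarray,
    centers: np.ndarray,
    radius_m: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Union clusters whose centroids are within *radius_m*, iterating until
    stable; merged centroids are dwell-weighted means of member pings."""
    while True:
        k = len(centers)
        if k <= 1:
            break
        d = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        i, j = divmod(int(d.argmin()), k)
        if d[i, j] > radius_m:
            break
        a, b = min(i, j), max(i, j)
        labels = np.where(labels == b, a, labels)
        labels = np.where(labels > b, labels - 1, labels)
        new_centers = []
        for c in range(k - 1):
            mask = labels == c
            new_centers.append(np.average(xy[mask], axis=0, weights=dwell[mask]))
        centers = np.asarray(new_centers)
    return labels, centers


def find_significant_locations(
    gps: GpsTable, config: PassiveConfig | None = None
) -> SignificantLocationSet:
    """Cluster one patient's pings into dwell-ranked significant locations.

    k-means runs on locally projected planar coordinates with per-ping dwell
    weights, for k = min(max_locations, number of distinct ~radius-sized
    cells occupied). Clusters holding less than ``min_dwell_fraction`` of
    total dwell are dropped (their pings will fall into the "other" bucket).
    Home is the top-dwell cluster; exact dwell ties break toward the
    earliest first visit. Deterministic given ``config.seed``.
    """
    config = config or PassiveConfig()
    df = gps.df
    if df.empty:
        raise ValidationError("cannot derive significant locations from zero pings")
    if df["patient_id"].nunique() > 1:
        raise ValidationError("significant locations are fitted per patient")

    lat = df["latitude"].to_numpy()
    lon = df["longitude"].to_numpy()
    origin = (float(np.median(lat)), float(np.median(lon)))
    xy = _project(lat, lon, origin)
    dwell = _dwell_minutes(df["timestamp"], config.max_gap_minutes)

    # distinct-cell heuristic: how many ~radius-sized grid cells are occupied
    cells = np.unique(np.round(xy / config.radius_m).astype(int), axis=0)
    k = int(min(config.max_locations, len(cells)))

    if k == 1:
        labels = np.zeros(len(df), dtype=int)
        centers_xy = np.average(xy, axis=0, weights=dwell)[None, :]
    else:
        model = KMeans(n_clusters=k, n_init=10, random_state=config.seed)
        labels = model.fit_predict(xy, sample_weight=dwell)
        centers_xy = model.cluster_centers_
        # k-means can over-split a single dwell cloud; fuse clusters whose
        # centroids sit within one radius of each other
        labels, centers_xy = _merge_close_clusters(
            xy, dwell, labels, centers_xy, config.radius_m
        )
        k = len(centers_xy)

    total = dwell.sum()
    rows = []
    for j in range(k):
        mask = labels == j
        if not mask.any():
            continue
        d = float(dwell[mask].sum())
        if d < config.min_dwell_fraction * total:
            continue  # negligible dwell: not a significant location
        first_visit = df["timestamp"].to_numpy()[mask].min()
        rows.append((j, centers_xy[j], d, first_visit))
    if not rows:  # all clusters tiny (cannot happen with k>=1 and one big cluster)
        j = int(np.argmax([dwell[labels == i].sum() for i in range(k)]))
        rows = [
            (j, centers_xy[j], float(dwell[labels == j].sum()),
             df["timestamp"].to_numpy()[labels == j].min())
        ]

    rows.sort(key=lambda r: (-r[2], r[3]))
    lat0, lon0 = origin
    records = []
    for rank, (j, cxy, d, first_visit) in enumerate(rows, start=1):
        records.append(
            {
                "location_id": f"loc{rank}",
                "latitude": lat0 + cxy[1] / METERS_PER_DEG_LAT,
                "longitude": lon0
                + cxy[0] / (METERS_PER_DEG_LAT * np.cos(np.deg2rad(lat0))),
                "dwell_minutes": d,
                "rank": rank,
                "first_visit": pd.Timestamp(first_visit),
            }
        )
    locations = pd.DataFrame.from_records(records)
    return SignificantLocationSet(
        locations=locations, home_id="loc1", origin=origin
    )


def assign_pings(
    gps: GpsTable, locations: SignificantLocationSet, radius_m: float = 200.0
) -> pd.Series:
    """Label each ping with its nearest significant location within
    *radius_m*, else the "other" bucket."""
    df = gps.df
    xy = _project(
        df["latitude"].to_numpy(), df["longitude"].to_numpy(), locations.origin
    )
    cxy = _project(
        locations.locations["latitude"].to_numpy(),
        locations.locations["longitude"].to_numpy(),
        locations.origin,
    )
    d2 = ((xy[:, None, :] - cxy[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    within = np.sqrt(d2[np.arange(len(df)), nearest]) <= radius_m
    ids = locations.locations["location_id"].to_numpy()
    out = np.where(within, ids[nearest], OTHER_ID)
    return pd.Series(out, index=df.index, name="location_id")


def daily_summaries(
    gps: GpsTable,
    locations: SignificantLocationSet,
    config: PassiveConfig | None = None,
) -> pd.DataFrame:
    """Per-local-day dwell fractions over significant locations and the
    home-time percentage.

    Returns a frame indexed by date with columns ``ping_count``,
    ``home_time_pct``, one ``frac_<location_id>`` per significant location,
    and ``frac_other``. Fractions sum to 1 on days with pings; days inside
    the observed span with zero pings appear with ping_count 0 and NaN
    fractions (rendered as blank calendar cells downstream).
    """
    config = config or PassiveConfig()
    df = gps.df
    if df.empty:
        raise ValidationError("no pings to summarize")
    labels = assign_pings(gps, locations, config.radius_m)
    dwell = _dwell_minutes(df["timestamp"], config.max_gap_minutes)
    ts = df["timestamp"]
    if ts.dt.tz is not None:
        day = ts.dt.tz_localize(None).dt.normalize()
    else:
        day = ts.dt.normalize()

    work = pd.DataFrame({"day": day, "location_id": labels, "dwell": dwell})
    loc_ids = list(locations.locations["location_id"]) + [OTHER_ID]
    per_day = (
        work.pivot_table(
            index="day", columns="location_id", values="dwell", aggfunc="sum"
        )
        .reindex(columns=loc_ids)
        .fillna(0.0)
    )
    fractions = per_day.div(per_day.sum(axis=1), axis=0)
    counts = work.groupby("day").size()

    full_days = pd.date_range(day.min(), day.max(), freq="D")
    fractions = fractions.reindex(full_days)
    counts = counts.reindex(full_days, fill_value=0)

    out = pd.DataFrame(index=full_days)
    out["ping_count"] = counts.astype(int)
    out["home_time_pct"] = 100.0 * fractions[locations.home_id]
    for lid in loc_ids:
        out[f"frac_{lid}"] = fractions[lid]
    out.index.name = "date"
    return out
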
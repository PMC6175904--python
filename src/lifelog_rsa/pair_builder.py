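"""Stimulus-pair enumeration, covariates, exclusion filters, neural distances.

Every analysis in this package is pair-level: for each participant, all
unordered pairs of scanned events are enumerated and annotated with

* ``hamm``        — Hamming distance between the two events' tag vectors,
* ``vis_sim``     — Euclidean distance between normalized image features,
* ``space_m``     — great-circle distance between the GPS fixes (meters),
* ``time_s``      — absolute difference of real-world clock times (seconds),
* ``scanner_dt``  — absolute difference of scanner presentation onsets and
  ``log10_scanner`` its base-10 log (memory effects follow a power law),
* ``vivid_code``  — 0 / 0.5 / 1 for both / one / neither member vivid.

Pairs are then filtered: closer than 100 m (below GPS reliability), farther
than 30 km (out-of-town trips), or closer in lived time than 15.6 h (the
overnight discontinuity in lifelog sampling) are excluded, as are pairs
touching an unusable, non-remembered, or vividness-undefined event.  The
neural side is 1 minus the Pearson correlation between single-trial beta
patterns, z-scored within participant.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tag_semantics import TagVocabulary, encode_tagset, hamming
from .visual_features import FeatureVector, visual_distance

__all__ = [
    "EventRecord",
    "PairFilterConfig",
    "NeuralDistanceVector",
    "geodesic_distance",
    "vivid_code",
    "build_pairs",
    "exclusion_counts",
    "neural_distances",
    "read_events_csv",
    "events_to_csv",
]

#: mean Earth radius in meters (IUGG); configurable in geodesic_distance
EARTH_RADIUS_M = 6_371_008.8

#: exclusion reason labels, in the precedence order they are assigned
EXCLUSION_REASONS = (
    "unusable_event",
    "not_remembered",
    "vividness_undefined",
    "space_lt_100m",
    "space_gt_30km",
    "time_lt_15p6h",
)


@dataclass
class EventRecord:
    """One lifelogged episode as presented in the scanner."""

    event_id: str
    participant_id: str
    clock_time: float  # seconds since epoch
    lat: float
    lon: float
    tagvec: np.ndarray  # binary tag presence vector
    remembered: bool
    vivid: bool | None  # defined only when remembered
    scanner_onset: float  # seconds from session start
    run_index: int = 0
    usable: bool = True

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")
        if not self.remembered and self.vivid is not None:
            raise ValueError("vividness is defined only for remembered events")


@dataclass(frozen=True)
class PairFilterConfig:
    """Pair exclusion thresholds (defaults: 100 m, 30 km, 15.6 h)."""

    min_space_m: float = 100.0
    max_space_m: float = 30_000.0
    min_time_s: float = 15.6 * 3600.0
    require_remembered: bool = True
    require_vividness: bool = True


def geodesic_distance(
    a: tuple[float, float],
    b: tuple[float, float],
    radius_m: float = EARTH_RADIUS_M,
) -> float:
    """Great-circle (haversine) distance in meters between (lat, lon) pairs.

    Coordinates are in degrees.  The haversine formula on a sphere of the
    given radius is accurate to a few tenths of a percent of the ellipsoidal
    distance, far inside the GPS noise floor the 100 m filter guards against.
    """
    for lat, lon in (a, b):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude out of range: {lat}")
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude out of range: {lon}")
    la1, lo1, la2, lo2 = map(math.radians, (*a, *b))
    s = (
        math.sin((la2 - la1) / 2) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
    )
    return 2.0 * radius_m * math.asin(min(1.0, math.sqrt(s)))


def vivid_code(vivid_i: bool | None, vivid_j: bool | None) -> float:
    """Pair-level vividness covariate: 0 both vivid, 0.5 one, 1 neither."""
    if vivid_i is None or vivid_j is None:
        raise ValueError("vividness undefined for at least one event")
    return (2 - int(bool(vivid_i)) - int(bool(vivid_j))) / 2.0


def build_pairs(
    events: Sequence[EventRecord],
    features: Sequence[FeatureVector] | Mapping[int, FeatureVector] | None,
    config: PairFilterConfig = PairFilterConfig(),
) -> pd.DataFrame:
    """Enumerate all unordered event pairs with covariates and filters.

    ``events`` must all belong to one participant; their order defines the
    trial indices ``i`` / ``j`` used to address beta volumes.  ``features``
    supplies one image feature vector per event (any representation, raw or
    normalized); pass None to skip the visual covariate (``vis_sim`` = NaN),
    which is only appropriate for models without the VisSim term.

    The returned frame has one row per pair with ``included`` and, where
    False, the first matching ``exclusion_reason`` from
    :data:`EXCLUSION_REASONS`.  The filters are pure functions of each pair's
    own covariates, hence order-independent and idempotent.
    """
    n = len(events)
    pids = {e.participant_id for e in events}
    if len(pids) > 1:
        raise ValueError(f"events from multiple participants: {sorted(pids)}")
    feats: list[FeatureVector | None]
    if features is None:
        feats = [None] * n
    elif isinstance(features, Mapping):
        feats = []
        for k in range(n):
            if k not in features:
                raise ValueError(f"missing features for event {events[k].event_id!r}")
            feats.append(features[k])
    else:
        if len(features) != n:
            raise ValueError("features must align one-to-one with events")
        feats = list(features)
    norm = [f.normalized() if f is not None else None for f in feats]

    rows = []
    for i in range(n):
        ei = events[i]
        for j in range(i + 1, n):
            ej = events[j]
            space_m = geodesic_distance((ei.lat, ei.lon), (ej.lat, ej.lon))
            time_s = abs(ei.clock_time - ej.clock_time)
            scanner_dt = abs(ei.scanner_onset - ej.scanner_onset)
            hamm = hamming(ei.tagvec, ej.tagvec)
            if norm[i] is not None:
                vis = visual_distance(norm[i], norm[j])
            else:
                vis = np.nan
            vivid_ok = ei.vivid is not None and ej.vivid is not None
            vcode = vivid_code(ei.vivid, ej.vivid) if vivid_ok else np.nan

            reason = None
            if not (ei.usable and ej.usable):
                reason = "unusable_event"
            elif config.require_remembered and not (ei.remembered and ej.remembered):
                reason = "not_remembered"
            elif config.require_vividness and not vivid_ok:
                reason = "vividness_undefined"
            elif space_m < config.min_space_m:
                reason = "space_lt_100m"
            elif space_m > config.max_space_m:
                reason = "space_gt_30km"
            elif time_s < config.min_time_s:
                reason = "time_lt_15p6h"

            rows.append(
                {
                    "i": i,
                    "j": j,
                    "event_i": ei.event_id,
                    "event_j": ej.event_id,
                    "hamm": hamm,
                    "vis_sim": vis,
                    "space_m": space_m,
                    "time_s": time_s,
                    "scanner_dt": scanner_dt,
                    "log10_scanner": np.log10(scanner_dt) if scanner_dt > 0 else np.nan,
                    "vivid_code": vcode,
                    "included": reason is None,
                    "exclusion_reason": reason,
                }
            )
    return pd.DataFrame(rows)


def exclusion_counts(pairs: pd.DataFrame) -> dict[str, int]:
    """Count pairs per exclusion reason (plus the included total)."""
    out = {"included": int(pairs["included"].sum())}
    vc = pairs.loc[~pairs["included"], "exclusion_reason"].value_counts()
    for reason in EXCLUSION_REASONS:
        out[reason] = int(vc.get(reason, 0))
    return out


@dataclass
class NeuralDistanceVector:
    """Z-scored correlation distances for the included pairs of one sphere."""

    values: np.ndarray  # z-scored, aligned with pair_index
    raw: np.ndarray  # 1 - Pearson r, in [0, 2]
    pair_index: np.ndarray  # row labels into the pair table
    dropped: list[tuple[int, str]] = field(default_factory=list)


def _pattern_matrix(betas, sphere) -> np.ndarray:
    """Coerce input to a (n_voxels, n_trials) pattern matrix."""
    data = getattr(betas, "data", betas)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 4:
        if sphere is None:
            raise ValueError("4-D betas require a sphere voxel index set")
        vox = np.asarray(sphere)
        if vox.size == 0:
            raise ValueError("empty sphere")
        return arr[vox[:, 0], vox[:, 1], vox[:, 2], :]
    if arr.ndim == 2:
        return arr
    raise ValueError("betas must be a 2-D pattern matrix or 4-D volume")


def neural_distances(
    betas,
    sphere,
    pairs: pd.DataFrame,
    ddof: int = 0,
) -> NeuralDistanceVector:
    """Neural pattern distances (1 - Pearson r) for the included pairs.

    ``betas`` is a 4-D (x, y, z, trial) array/volume with ``sphere`` an
    (n, 3) voxel index array, or directly a (voxels, trials) matrix with
    ``sphere=None``.  At least two voxels are needed for a defined
    correlation.  Trials whose pattern has zero variance across voxels yield
    undefined distances; their pairs are dropped and logged.  The surviving
    raw distances are z-scored across this participant's included pairs
    (mean 0, sd 1).
    """
    X = _pattern_matrix(betas, sphere)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 voxels for a defined correlation")
    inc = pairs[pairs["included"]]
    Z = X - X.mean(axis=0, keepdims=True)
    sd = Z.std(axis=0)
    ok_trial = sd > 0
    Zn = np.zeros_like(Z)
    Zn[:, ok_trial] = Z[:, ok_trial] / (sd[ok_trial] * np.sqrt(X.shape[0]))
    corr = Zn.T @ Zn

    raw, keep_idx, dropped = [], [], []
    for row_label, row in inc.iterrows():
        i, j = int(row["i"]), int(row["j"])
        if not (ok_trial[i] and ok_trial[j]):
            dropped.append((row_label, "zero_variance_pattern"))
            continue
        raw.append(1.0 - corr[i, j])
        keep_idx.append(row_label)
    raw_arr = np.asarray(raw, dtype=float)
    if raw_arr.size == 0:
        return NeuralDistanceVector(raw_arr, raw_arr, np.asarray(keep_idx), dropped)
    sd_raw = raw_arr.std(ddof=ddof)
    if sd_raw == 0:
        raise ValueError("neural distances are constant; cannot z-score")
    z = (raw_arr - raw_arr.mean()) / sd_raw
    return NeuralDistanceVector(z, raw_arr, np.asarray(keep_idx), dropped)


# ---------------------------------------------------------------------------
# event table I/O
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = [
    "event_id",
    "participant_id",
    "clock_time",
    "lat",
    "lon",
    "tags",
    "remembered",
    "vivid",
    "scanner_onset",
    "run_index",
    "usable",
]


def read_events_csv(
    path: str | Path, vocab: TagVocabulary, tag_sep: str = ";"
) -> list[EventRecord]:
    """Read an event table from CSV.

    Expected columns: event_id, participant_id, clock_time (s), lat, lon,
    tags (``tag_sep``-separated labels from the vocabulary), remembered
    (0/1), vivid (0/1, empty when undefined), scanner_onset (s), run_index,
    usable (0/1).
    """
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            tags = [t for t in row["tags"].split(tag_sep) if t]
            vivid_raw = row.get("vivid", "").strip()
            records.append(
                EventRecord(
                    event_id=row["event_id"],
                    participant_id=row["participant_id"],
                    clock_time=float(row["clock_time"]),
                    lat=float(row["lat"]),
                    lon=float(row["lon"]),
                    tagvec=encode_tagset(tags, vocab),
                    remembered=bool(int(row["remembered"])),
                    vivid=bool(int(vivid_raw)) if vivid_raw else None,
                    scanner_onset=float(row["scanner_onset"]),
                    run_index=int(row.get("run_index", 0) or 0),
                    usable=bool(int(row.get("usable", 1) or 1)),
                )
            )
    return records


def events_to_csv(
    events: Sequence[EventRecord],
    vocab: TagVocabulary,
    path: str | Path,
    tag_sep: str = ";",
) -> None:
    """Write events as CSV, decoding tag vectors back to labels."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_EVENT_COLUMNS)
        for e in events:
            labels = [vocab.tags[i] for i in np.flatnonzero(e.tagvec)]
            w.writerow(
                [
                    e.event_id,
                    e.participant_id,
                    f"{e.clock_time:.3f}",
                    f"{e.lat:.8f}",
                    f"{e.lon:.8f}",
                    tag_sep.join(labels),
                    int(e.remembered),
                    "" if e.vivid is None else int(e.vivid),
                    f"{e.scanner_onset:.3f}",
                    e.run_index,
                    int(e.usable),
                ]
            )
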
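"""Zone-occupancy endpoints: novel tank, mirror biting, social preference.

All endpoints reduce to per-frame zone labels on a calibrated trajectory:

* entries — transitions from outside a zone to inside it (a fish already
  inside at the first frame counts as one initial entry);
* time in zone — frames inside / fps;
* distance in zone — each inter-frame segment is attributed to the zone of
  its earlier endpoint;
* latency — time of the first in-zone frame, or ``inf`` if never entered.

Mirror endpoints follow the contact/approach geometry: biting frequency is
the number of entries into the contact strip (within 1.5 cm of the mirror)
and biting duration the time spent there; the approach area (AA) spans
1.5-5 cm from the mirror.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import Trajectory, ZonePartition, assign_zones

__all__ = [
    "ZoneOccupancy",
    "SocialPreferenceResult",
    "zone_occupancy",
    "mirror_biting_metrics",
    "social_preference",
]

#: Latency sentinel for "never entered the zone".
NEVER = math.inf


@dataclass(frozen=True)
class ZoneOccupancy:
    zone: str
    n_entries: int
    time_in_zone: float  # s
    distance_in_zone: float  # cm
    latency_to_first_entry: float  # s, inf if never entered

    def __post_init__(self) -> None:
        if self.time_in_zone > 0 and self.n_entries < 1:
            raise ValueError("time in zone without any entry")


def _occupancy_from_labels(
    traj: Trajectory, labels: np.ndarray, zone: str, debounce_frames: int = 0
) -> ZoneOccupancy:
    inside = labels == zone
    t = traj.t
    if debounce_frames > 0:
        # suppress visits shorter than the debounce window
        inside = inside.copy()
        i = 0
        n = inside.size
        while i < n:
            if inside[i]:
                j = i
                while j < n and inside[j]:
                    j += 1
                if j - i < debounce_frames:
                    inside[i:j] = False
                i = j
            else:
                i += 1
    n_entries = int(inside[0]) + int(np.sum(~inside[:-1] & inside[1:]))
    time_in = float(np.sum(inside) / traj.fps)
    seg = np.linalg.norm(np.diff(traj.xy, axis=0), axis=1)
    dist_in = float(np.sum(seg[inside[:-1]]))  # earlier-endpoint attribution
    if inside.any():
        latency = float(t[int(np.argmax(inside))])
    else:
        latency = NEVER
    return ZoneOccupancy(
        zone=zone,
        n_entries=n_entries,
        time_in_zone=time_in,
        distance_in_zone=dist_in,
        latency_to_first_entry=latency,
    )


def zone_occupancy(
    traj: Trajectory,
    zones: ZonePartition,
    zone: str,
    debounce_frames: int = 0,
) -> ZoneOccupancy:
    """Occupancy endpoints for one named zone.

    ``debounce_frames`` > 0 discards visits shorter than that many frames
    before counting entries/time (default 0: every crossing counts).
    """
    if zone not in zones.zones:
        raise KeyError(f"unknown zone {zone!r}; partition has {zones.names()}")
    labels = assign_zones(traj.xy, zones)
    return _occupancy_from_labels(traj, labels, zone, debounce_frames)


def mirror_biting_metrics(
    traj: Trajectory, mirror_zones: ZonePartition, debounce_frames: int = 0
) -> dict[str, ZoneOccupancy]:
    """Contact ("biting") and approach-area occupancy for the mirror test.

    The returned dict has keys ``"contact"`` and ``"approach"``; biting
    frequency is ``contact.n_entries`` and biting duration
    ``contact.time_in_zone``. Approach-area time, distance and latency
    refer to the 1.5-5 cm band proper, but an approach *entry* is a sortie
    into the whole within-5-cm region: a fish continuing from the band
    into the contact strip and back does not recount as a new approach.
    """
    for required in ("contact", "approach"):
        if required not in mirror_zones.zones:
            raise KeyError(f"mirror partition must define a {required!r} zone")
    labels = assign_zones(traj.xy, mirror_zones)
    contact = _occupancy_from_labels(traj, labels, "contact", debounce_frames)
    approach = _occupancy_from_labels(traj, labels, "approach", debounce_frames)
    near = np.isin(labels, ("contact", "approach"))
    n_sorties = int(near[0]) + int(np.sum(~near[:-1] & near[1:]))
    approach = ZoneOccupancy(
        zone="approach",
        n_entries=n_sorties,
        time_in_zone=approach.time_in_zone,
        distance_in_zone=approach.distance_in_zone,
        latency_to_first_entry=approach.latency_to_first_entry,
    )
    return {"contact": contact, "approach": approach}


@dataclass(frozen=True)
class SocialPreferenceResult:
    """Conspecific-sector (CS) vs empty-sector (ES) endpoints.

    ``preference_value`` is the signed normalized time difference
    (time_CS - time_ES)/(time_CS + time_ES) in [-1, 1]; it negates exactly
    under a CS/ES swap. ``ratio_time_CS`` and ``ratio_distance_CS`` are the
    unsigned fractions in [0, 1].
    """

    time_CS: float
    time_ES: float
    distance_CS: float
    distance_ES: float
    preference_value: float
    ratio_time_CS: float
    ratio_distance_CS: float


def social_preference(
    traj: Trajectory, cs_es_partition: ZonePartition
) -> SocialPreferenceResult:
    """Score the focal fish's preference for the conspecific half.

    The partition must name its zones ``CS`` and ``ES`` and cover the
    chamber fully.
    """
    for required in ("CS", "ES"):
        if required not in cs_es_partition.zones:
            raise KeyError(f"partition must define zone {required!r}")
    labels = assign_zones(traj.xy, cs_es_partition)
    occ_cs = _occupancy_from_labels(traj, labels, "CS")
    occ_es = _occupancy_from_labels(traj, labels, "ES")
    t_total = occ_cs.time_in_zone + occ_es.time_in_zone
    if t_total <= 0:
        raise ValueError("fish spent no time in CS or ES; cannot score preference")
    d_total = occ_cs.distance_in_zone + occ_es.distance_in_zone
    return SocialPreferenceResult(
        time_CS=occ_cs.time_in_zone,
        time_ES=occ_es.time_in_zone,
        distance_CS=occ_cs.distance_in_zone,
        distance_ES=occ_es.distance_in_zone,
        preference_value=(occ_cs.time_in_zone - occ_es.time_in_zone) / t_total,
        ratio_time_CS=occ_cs.time_in_zone / t_total,
        ratio_distance_CS=occ_cs.distance_in_zone / d_total if d_total else float("nan"),
    )


def occupancy_table(results: dict[str, ZoneOccupancy]) -> pd.DataFrame:
    """Flatten named ZoneOccupancy results into a one-row-per-zone table."""
    return pd.DataFrame(
        [
            {
                "zone": occ.zone,
                "n_entries": occ.n_entries,
                "time_in_zone_s": occ.time_in_zone,
                "distance_in_zone_cm": occ.distance_in_zone,
                "latency_s": occ.latency_to_first_entry,
            }
            for occ in results.values()
        ]
    )
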
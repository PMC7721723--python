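"""Craniofacial landmark morphometry: the linear-distance battery and hyoid metrics.

A subject is a set of named 3-D landmarks (numeric ids 1-28 by convention, or
functional names) placed on a skull/mandible reconstruction. The standard
battery is 26 Euclidean distances: 23 skull and mandible measures (a-w) plus
the three hyoid-position measures (x, y, z) taken among the hyoid (28), the
caudal edge of the hard palate (17... see pair map) in the midsagittal plane.
Distances are isometry-invariant, so no registration between subjects is
needed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import GroupSummary, welch_from_summary

log = logging.getLogger(__name__)

__all__ = [
    "LandmarkSet",
    "DistanceTable",
    "DEFAULT_PAIR_MAP",
    "measure_distances",
    "hyoid_metrics",
    "cohort_compare",
]

# measure id -> (landmark, landmark).  a-f dorsal skull, g-l ventral skull,
# m-n lateral skull, o-w mandible, x-z hyoid position (17 = caudal edge of
# the hard palate, 27 = ventral point of the basisphenoid-occipital suture,
# 28 = hyoid).
DEFAULT_PAIR_MAP = {
    "a": (1, 3), "b": (3, 6), "c": (6, 9), "d": (2, 4), "e": (5, 7), "f": (8, 10),
    "g": (11, 15), "h": (12, 16), "i": (15, 16), "j": (13, 18), "k": (13, 14),
    "l": (14, 17), "m": (1, 18), "n": (3, 13),
    "o": (19, 21), "p": (20, 22), "q": (21, 23), "r": (22, 24), "s": (19, 23),
    "t": (20, 24), "u": (23, 25), "v": (24, 26), "w": (23, 24),
    "x": (17, 28), "y": (17, 27), "z": (27, 28),
}


@dataclass
class LandmarkSet:
    """Named 3-D points (mm) for one subject."""

    points: dict
    subject_id: str = "subject"
    group: str | None = None

    def __post_init__(self):
        self.points = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}

    def get(self, key):
        return self.points.get(key)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, subject_id="subject", group=None):
        pts = {
            _coerce_id(r["id"]): (r["x_mm"], r["y_mm"], r["z_mm"]) for _, r in df.iterrows()
        }
        return cls(points=pts, subject_id=subject_id, group=group)


def _coerce_id(x):
    try:
        return int(x)
    except (TypeError, ValueError):
        return str(x)


@dataclass
class DistanceTable:
    """Per-subject linear distances (mm), NaN where a landmark was missing."""

    values: dict
    subject_id: str = "subject"
    group: str | None = None

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.subject_id, dtype=float)


def measure_distances(landmarks: LandmarkSet, pair_map: dict | None = None) -> DistanceTable:
    """Euclidean distance for every measure in ``pair_map`` (default battery).

    A measure whose landmarks are absent is recorded as NaN and logged, so a
    subject with an excluded region (e.g. bone measures dropped for one
    animal) still yields a table for the remaining measures.
    """
    pair_map = DEFAULT_PAIR_MAP if pair_map is None else pair_map
    values = {}
    for measure, (a, b) in pair_map.items():
        pa, pb = landmarks.get(a), landmarks.get(b)
        if pa is None or pb is None:
            log.info(
                "subject %s: measure %s skipped (missing landmark %s)",
                landmarks.subject_id, measure, a if pa is None else b,
            )
            values[measure] = float("nan")
        else:
            values[measure] = float(np.linalg.norm(pa - pb))
    return DistanceTable(values=values, subject_id=landmarks.subject_id, group=landmarks.group)


def hyoid_metrics(landmarks: LandmarkSet):
    """Hyoid-position triangle (x, y, z) in mm.

    x = |17-28| (hard palate to hyoid), y = |17-27| (hard palate to the
    basisphenoid-occipital suture point), z = |27-28| (suture point to
    hyoid).  Any missing landmark yields NaN for the metrics that use it.
    """
    out = []
    for a, b in ((17, 28), (17, 27), (27, 28)):
        pa, pb = landmarks.get(a), landmarks.get(b)
        out.append(
            float("nan") if pa is None or pb is None else float(np.linalg.norm(pa - pb))
        )
    return tuple(out)


def _tables_to_frame(tables) -> pd.DataFrame:
    return pd.DataFrame({t.subject_id: t.as_series() for t in tables}).T


def cohort_compare(tables_g1, tables_g2, group_names=("group1", "group2")) -> pd.DataFrame:
    """Per-measure Welch comparison of two cohorts of distance tables.

    Missing values are excluded per measure (not per subject), mirroring the
    practice of dropping a single animal from one measurement family only.
    Measures with fewer than two valid subjects in either group are flagged
    ``untestable`` and carry NaN statistics.
    """
    f1, f2 = _tables_to_frame(tables_g1), _tables_to_frame(tables_g2)
    measures = list(dict.fromkeys(list(f1.columns) + list(f2.columns)))
    rows = []
    for m in measures:
        x = f1[m].dropna() if m in f1 else pd.Series(dtype=float)
        y = f2[m].dropna() if m in f2 else pd.Series(dtype=float)
        row = dict(
            measure=m,
            mean1=x.mean(), sd1=x.std(ddof=1), n1=int(x.size),
            mean2=y.mean(), sd2=y.std(ddof=1), n2=int(y.size),
        )
        if x.size < 2 or y.size < 2:
            row.update(t=np.nan, df=np.nan, p=np.nan, significant=False, untestable=True)
        else:
            res = welch_from_summary(
                GroupSummary(row["mean1"], row["sd1"], row["n1"]),
                GroupSummary(row["mean2"], row["sd2"], row["n2"]),
            )
            row.update(
                t=res.t_statistic, df=res.df, p=res.p_two_sided,
                significant=res.significant_at_0_05, untestable=False,
            )
        rows.append(row)
    report = pd.DataFrame(rows)
    report.attrs["group_names"] = tuple(group_names)
    return report


def load_landmark_csv(path) -> list[LandmarkSet]:
    """Read a cohort landmark CSV (subject,group,id,x_mm,y_mm,z_mm)."""
    df = pd.read_csv(path)
    sets = []
    for (subject, group), sub in df.groupby(["subject", "group"], sort=False):
        sets.append(LandmarkSet.from_dataframe(sub, subject_id=str(subject), group=str(group)))
    return sets


def save_landmark_csv(landmark_sets, path) -> None:
    rows = []
    for ls in landmark_sets:
        for lid, p in ls.points.items():
            rows.append(
                dict(subject=ls.subject_id, group=ls.group, id=lid,
                     x_mm=p[0], y_mm=p[1], z_mm=p[2])
            )
    pd.DataFrame(rows).to_csv(path, index=False)
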
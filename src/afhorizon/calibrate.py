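"""Per-age-group isotonic calibration of raw risk scores.

A monotone non-parametric map from raw model scores to the probability of
observing AF in the monitoring window, fitted by pool-adjacent-violators on
the natural-prevalence calibration cohort. Evaluation between knots is
stepwise-constant (each PAVA block carries one fitted probability), with
scores outside the knot range clipped to the boundary values. Because each
age group's model is calibrated against the same kind of natural cohort,
the calibrated probabilities are comparable across groups even when the raw
score scales are not.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression

__all__ = ["CalibrationMap", "fit_calibration", "calibrate_score",
           "save_maps", "load_maps"]


@dataclass(frozen=True)
class CalibrationMap:
    age_group: str
    breakpoints: np.ndarray   # left edge of each PAVA block (increasing)
    values: np.ndarray        # block probabilities (non-decreasing, in [0,1])
    n: int = 0
    prevalence: float = 0.0

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, float)
        v = np.asarray(self.values, float)
        if bp.shape != v.shape or bp.ndim != 1 or bp.size == 0:
            raise ValueError("breakpoints and values must be matching 1-d")
        if np.any(np.diff(bp) < 0) or np.any(np.diff(v) < 0):
            raise ValueError("breakpoints and values must be non-decreasing")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("values must be probabilities")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", v)

    def __call__(self, raw) -> np.ndarray:
        raw = np.asarray(raw, float)
        idx = np.searchsorted(self.breakpoints, raw, side="right") - 1
        return self.values[np.clip(idx, 0, self.values.size - 1)]


def fit_calibration(raw_scores, labels, age_group: str = "all"
                    ) -> CalibrationMap:
    """Isotonic (PAVA) fit of outcome on raw score for one age group.

    The mean of the fitted values equals the calibration prevalence exactly
    (a normal-equation property of isotonic least squares). A single-class
    input degrades to a constant map at the observed prevalence, with a
    warning.
    """
    s = np.asarray(raw_scores, float)
    y = np.asarray(labels, float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be matching 1-d arrays")
    prev = float(np.mean(y))
    if prev in (0.0, 1.0):
        warnings.warn(f"single-class calibration input for {age_group}; "
                      "using a constant map at the observed prevalence")
        return CalibrationMap(age_group, np.array([0.0]), np.array([prev]),
                              n=s.size, prevalence=prev)
    iso = IsotonicRegression(out_of_bounds="clip")
    iso.fit(s, y)
    fitted = iso.predict(np.sort(np.unique(s)))
    knots_x = np.sort(np.unique(s))
    # collapse to one (left-edge, value) pair per PAVA block
    change = np.concatenate(([True], np.diff(fitted) != 0))
    return CalibrationMap(age_group, knots_x[change], fitted[change],
                          n=s.size, prevalence=prev)


def calibrate_score(raw, maps, age_group: str = "all"):
    """Map raw scores to calibrated probabilities using the group's map.

    ``maps`` may be a single CalibrationMap or a dict keyed by age group;
    a missing group raises a KeyError naming it.
    """
    if isinstance(maps, CalibrationMap):
        cal = maps
    else:
        if age_group not in maps:
            raise KeyError(f"no calibration map for age group {age_group!r}")
        cal = maps[age_group]
    return cal(raw)


def save_maps(maps: dict[str, CalibrationMap], path):
    payload = {
        g: {"breakpoints": m.breakpoints.tolist(),
            "values": m.values.tolist(), "n": m.n,
            "prevalence": m.prevalence}
        for g, m in maps.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_maps(path) -> dict[str, CalibrationMap]:
    with open(path) as fh:
        payload = json.load(fh)
    return {g: CalibrationMap(g, np.asarray(d["breakpoints"]),
                              np.asarray(d["values"]), d["n"],
                              d["prevalence"])
            for g, d in payload.items()}
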
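"""Printer-calibration mathematics for printed-activity phantoms.

The printing chain is characterised by two fitted curves: grey level
specified to the printer -> deposited ink weight (third-degree polynomial),
and deposited ink x activity concentration -> decay-corrected detector
counts (linear).  Composing the two and inverting numerically yields the
grey level to print for a requested relative activity, which is how the
non-linear ink deposition of the printer is compensated.

All counts are used in relative terms (the phantom models uptake ratios,
not absolute activity), so a single free scale factor is implied throughout
and the inversion works on the response normalised to its maximum.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as P

__all__ = [
    "F18_HALF_LIFE_MIN",
    "CalibrationCurve",
    "CalibrationSample",
    "fit_grey_to_ink",
    "fit_ink_to_counts",
    "decay_correct",
    "grey_for_target_activity",
    "read_samples_csv",
]

#: Half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77


@dataclass(frozen=True)
class CalibrationCurve:
    """Polynomial calibration curve, constant coefficient first.

    ``kind`` is ``"cubic"`` (4 coefficients) or ``"linear"`` (2); the curve
    must be monotone non-decreasing on ``domain`` so it can be inverted.
    """

    kind: str
    coefficients: tuple[float, ...]
    r_squared: float
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        n = {"cubic": 4, "linear": 2}.get(self.kind)
        if n is None:
            raise ValueError("kind must be 'cubic' or 'linear'")
        if len(self.coefficients) != n:
            raise ValueError(f"{self.kind} curve needs {n} coefficients")
        if self.domain[1] <= self.domain[0]:
            raise ValueError("empty domain")

    def __call__(self, x):
        return P.polyval(np.asarray(x, dtype=float), np.asarray(self.coefficients))

    def is_monotone(self, n: int = 2001) -> bool:
        g = np.linspace(self.domain[0], self.domain[1], n)
        y = self(g)
        scale = max(abs(y).max(), 1.0)
        return bool(np.all(np.diff(y) >= -1e-12 * scale))

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "coefficients": list(self.coefficients),
                "r_squared": self.r_squared,
                "domain": list(self.domain),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationCurve":
        d = json.loads(text)
        return cls(d["kind"], tuple(d["coefficients"]), d["r_squared"], tuple(d["domain"]))


@dataclass(frozen=True)
class CalibrationSample:
    """One calibration measurement.

    ``grey_level`` is the fraction of maximum printed intensity in [0, 1];
    ``counts`` are decay-corrected to a common time point;
    ``activity_concentration`` is the relative activity of the ink mixture.
    """

    grey_level: float
    ink_weight: float = float("nan")
    counts: float = float("nan")
    activity_concentration: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.grey_level <= 1.0:
            raise ValueError("grey_level must be in [0, 1]")
        if np.isfinite(self.counts) and self.counts < 0:
            raise ValueError("counts must be >= 0")


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_grey_to_ink(samples: list[CalibrationSample]) -> CalibrationCurve:
    """Least-squares cubic for deposited ink weight as a function of grey level.

    Requires at least five distinct grey levels; all replicates enter the
    fit.  The fitted cubic must be monotone non-decreasing on the sampled
    grey range, otherwise the design needs denser sampling and an error is
    raised.
    """
    g = np.array([s.grey_level for s in samples], dtype=float)
    w = np.array([s.ink_weight for s in samples], dtype=float)
    if np.unique(g).size < 5:
        raise ValueError("need at least 5 distinct grey levels for the cubic fit")
    if not np.all(np.isfinite(w)):
        raise ValueError("all samples need an ink weight")
    coef = P.polyfit(g, w, 3)
    curve = CalibrationCurve(
        "cubic", tuple(coef), _r_squared(w, P.polyval(g, coef)), (float(g.min()), float(g.max()))
    )
    if not curve.is_monotone():
        raise ValueError(
            "fitted grey-to-ink cubic is not monotone on the sampled range; "
            "densify the grey-level sampling"
        )
    return curve


def fit_ink_to_counts(samples: list[CalibrationSample]) -> CalibrationCurve:
    """Least-squares line through pooled (ink x activity, counts) pairs.

    Samples from different activity concentrations are pooled by using the
    product ``ink_weight x activity_concentration`` as abscissa; counts must
    already be decay-corrected to a common time.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for the linear fit")
    x = np.array([s.ink_weight * s.activity_concentration for s in samples], dtype=float)
    y = np.array([s.counts for s in samples], dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("all samples need ink weight, activity and counts")
    if np.ptp(x) == 0:
        if np.ptp(y) == 0:
            # degenerate but consistent design, e.g. all-zero-activity samples
            return CalibrationCurve(
                "linear", (float(y[0]), 0.0), 1.0, (float(x[0]), float(x[0]) + 1.0)
            )
        raise ValueError("no variation in ink x activity; cannot fit a line")
    coef = P.polyfit(x, y, 1)
    return CalibrationCurve(
        "linear", tuple(coef), _r_squared(y, P.polyval(x, coef)), (float(x.min()), float(x.max()))
    )


def decay_correct(counts, elapsed_minutes: float, half_life_minutes: float = F18_HALF_LIFE_MIN):
    """Back-correct counts measured ``elapsed_minutes`` after the reference time.

    Returns ``counts * 2**(elapsed / half_life)``: a reading taken one
    half-life late is doubled.  Negative elapsed times apply forward decay
    (the reading pre-dates the reference), halving after one half-life.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    out = counts * 2.0 ** (elapsed_minutes / half_life_minutes)
    return float(out) if out.ndim == 0 else out


def grey_for_target_activity(
    target: float,
    grey_to_ink: CalibrationCurve,
    ink_to_counts: CalibrationCurve,
    tol: float = 1e-6,
) -> float:
    """Grey level whose normalised composed response equals ``target``.

    The composed response ``counts(g) = ink_to_counts(grey_to_ink(g))`` is
    normalised by its value at the top of the grey domain, so ``target`` is
    a relative activity in (0, 1].  Inversion is by bisection to ``tol`` in
    grey level, which is robust for the composed cubic-in-linear form.
    """
    if not (grey_to_ink.is_monotone() and ink_to_counts.is_monotone()):
        raise ValueError("both calibration curves must be monotone for inversion")
    lo, hi = grey_to_ink.domain

    def response(g: float) -> float:
        return float(ink_to_counts(grey_to_ink(g)))

    cmax = response(hi)
    if cmax <= 0:
        raise ValueError("composed response is non-positive at the top of the domain")
    fmin, fmax = response(lo) / cmax, 1.0
    if not (fmin - 1e-12 <= target <= fmax + 1e-12):
        raise ValueError(
            f"target {target} outside the achievable relative range [{fmin:.6g}, {fmax:.6g}]"
        )
    a, b = lo, hi
    fa = response(a) / cmax - target
    if fa >= 0:
        return float(a)
    while b - a > tol:
        m = 0.5 * (a + b)
        if response(m) / cmax - target < 0:
            a = m
        else:
            b = m
    return float(0.5 * (a + b))


def read_samples_csv(path) -> list[CalibrationSample]:
    """Read calibration samples from CSV.

    Expected columns: ``grey_level, ink_weight_mg, counts, activity_rel,
    elapsed_min``; counts are decay-corrected on the fly using
    ``elapsed_min`` when that column is present.
    """
    samples = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            counts = float(row.get("counts", "nan"))
            elapsed = float(row.get("elapsed_min", 0.0) or 0.0)
            if np.isfinite(counts) and elapsed:
                counts = decay_correct(counts, elapsed)
            samples.append(
                CalibrationSample(
                    grey_level=float(row["grey_level"]),
                    ink_weight=float(row.get("ink_weight_mg", "nan")),
                    counts=counts,
                    activity_concentration=float(row.get("activity_rel", 1.0) or 1.0),
                )
            )
    return samples
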
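"""Substitution-rate estimation and molecular-clock divergence dating.

The rate is a raw p-distance scaled to substitutions per 100 bp: mismatched
ungapped columns over all ungapped columns, with gap and ambiguity columns
excluded from both numerator and denominator.  No multiple-hit correction is
applied by default — at the sub-percent divergences this is built for, the
Jukes-Cantor correction is far below the counting noise; a corrected variant
is available behind a flag.  Dating scales a calibration interval (from an
independently dated species pair measured on the same gene set) by the ratio
of the focal to the calibrator rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

_VALID = set("ACGT")


@dataclass
class DivergenceEstimate:
    focal_rate: float  # substitutions per 100 bp
    calibrator_rate: float
    rate_ratio: float  # calibrator / focal
    calibration_mya: tuple[float, float]
    interval_mya: tuple[float, float]  # rounded to 1 decimal
    interval_mya_raw: tuple[float, float]
    focal_sites: int
    calibrator_sites: int

    def to_dict(self) -> dict:
        return {
            "focal_rate_per_100bp": self.focal_rate,
            "calibrator_rate_per_100bp": self.calibrator_rate,
            "rate_ratio": self.rate_ratio,
            "calibration_mya": list(self.calibration_mya),
            "interval_mya": list(self.interval_mya),
            "interval_mya_raw": list(self.interval_mya_raw),
            "focal_sites": self.focal_sites,
            "calibrator_sites": self.calibrator_sites,
        }


def _pairs_iter(pairs: Iterable) -> Iterable[tuple[str, str]]:
    for item in pairs:
        if len(item) == 3:  # (id, a, b)
            yield item[1], item[2]
        else:
            yield item


def substitution_rate(pairs: Iterable, jukes_cantor: bool = False) -> tuple[float, int]:
    """Substitutions per 100 bp across a set of aligned sequence pairs.

    ``pairs`` yields ``(a, b)`` or ``(id, a, b)`` with equal-length aligned
    sequences (gaps as ``-``).  Returns ``(rate, ungapped_columns)``.
    """
    mismatches = 0
    sites = 0
    for a, b in _pairs_iter(pairs):
        if len(a) != len(b):
            raise ValueError("aligned sequences differ in length")
        for x, y in zip(a.upper(), b.upper()):
            if x in _VALID and y in _VALID:
                sites += 1
                if x != y:
                    mismatches += 1
    if sites == 0:
        raise ValueError("no ungapped aligned columns")
    p = mismatches / sites
    if jukes_cantor:
        if p >= 0.75:
            raise ValueError("p-distance too large for Jukes-Cantor correction")
        p = -0.75 * math.log(1 - 4.0 * p / 3.0)
    return 100.0 * p, sites


def clock_interval(
    rate_focal: float,
    rate_calibrator: float,
    calibration_mya: tuple[float, float],
) -> tuple[float, float]:
    """Scale a calibrated divergence interval by the rate ratio, one decimal.

    Each bound becomes ``bound * rate_focal / rate_calibrator``.
    """
    lo, hi = calibration_mya
    if rate_calibrator <= 0:
        raise ValueError("calibrator rate must be positive")
    if rate_focal < 0:
        raise ValueError("focal rate must be non-negative")
    if lo > hi:
        raise ValueError("calibration interval bounds out of order")
    scale = rate_focal / rate_calibrator
    if scale == 1.0:  # no scaling: return the calibration verbatim, unrounded
        return (lo, hi)
    return (round(lo * scale, 1), round(hi * scale, 1))


def estimate_divergence(
    focal_pairs: Iterable,
    calibrator_pairs: Iterable,
    calibration_mya: tuple[float, float],
    jukes_cantor: bool = False,
) -> DivergenceEstimate:
    """Full dating analysis from two aligned ortholog sets."""
    focal_rate, n_focal = substitution_rate(focal_pairs, jukes_cantor)
    calib_rate, n_calib = substitution_rate(calibrator_pairs, jukes_cantor)
    interval = clock_interval(focal_rate, calib_rate, calibration_mya)
    scale = focal_rate / calib_rate
    raw = (calibration_mya[0] * scale, calibration_mya[1] * scale)
    return DivergenceEstimate(
        focal_rate=focal_rate,
        calibrator_rate=calib_rate,
        rate_ratio=calib_rate / focal_rate if focal_rate else float("inf"),
        calibration_mya=tuple(calibration_mya),
        interval_mya=interval,
        interval_mya_raw=raw,
        focal_sites=n_focal,
        calibrator_sites=n_calib,
    )
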
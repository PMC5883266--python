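"""Dose-volume histograms and the DVH indices used in plan comparison.

A :class:`DVH` stores binned dose-volume data for a single structure in one
of two forms:

* ``cumulative``: ``volume[i]`` is the fraction of the structure receiving at
  least ``dose_bins[i]`` Gy.  The curve is non-increasing and starts at or
  below 1.0.
* ``differential``: ``volume[i]`` is the fraction receiving a dose in the bin
  whose left edge is ``dose_bins[i]``.

All volumes are unitless fractions; absolute-volume (cc) or percent data are
normalized at the IO boundary.  Dose is always in Gy.

Point queries (Dq, Vd) use piecewise-linear interpolation on the cumulative
curve; queries beyond the binned range clamp to the nearest endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .errors import DomainError, ValidationError

_TOL = 1e-9

Kind = Literal["cumulative", "differential"]


@dataclass(frozen=True)
class DVH:
    """Binned dose-volume histogram for one structure.

    Parameters
    ----------
    structure_id : str
        Label of the anatomical structure (e.g. ``"PTV"``, ``"Spinal cord"``).
    kind : {"cumulative", "differential"}
        Representation of ``volume`` (see module docstring).
    dose_bins : array-like of float
        Strictly increasing dose values in Gy, first entry >= 0, length >= 2.
    volume : array-like of float
        Volume fractions, same length as ``dose_bins``.
    """

    structure_id: str
    kind: Kind
    dose_bins: np.ndarray
    volume: np.ndarray

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose_bins, dtype=float)
        vol = np.asarray(self.volume, dtype=float)
        object.__setattr__(self, "dose_bins", dose)
        object.__setattr__(self, "volume", vol)
        if self.kind not in ("cumulative", "differential"):
            raise ValidationError(f"unknown DVH kind {self.kind!r}")
        if dose.ndim != 1 or vol.ndim != 1 or dose.size != vol.size:
            raise ValidationError("dose_bins and volume must be 1-D and the same length")
        if dose.size < 2:
            raise ValidationError("a DVH needs at least 2 dose bins")
        if dose[0] < 0:
            raise ValidationError("dose bins must be non-negative")
        if np.any(np.diff(dose) <= 0):
            raise ValidationError("dose bins must be strictly increasing")
        if self.kind == "cumulative":
            if np.any(vol < -_TOL) or np.any(vol > 1.0 + _TOL):
                raise ValidationError("cumulative volume fractions must lie in [0, 1]")
            if np.any(np.diff(vol) > _TOL):
                raise ValidationError("cumulative volume must be non-increasing")
        else:
            if np.any(vol < -_TOL):
                raise ValidationError("differential bin volumes must be non-negative")
            if vol.sum() > 1.0 + 1e-6:
                raise ValidationError("differential bin volumes must sum to at most 1")

    @property
    def total_fraction(self) -> float:
        """Total structure fraction covered by the histogram."""
        if self.kind == "cumulative":
            return float(self.volume[0])
        return float(self.volume.sum())


def to_differential(dvh: DVH) -> DVH:
    """Convert a cumulative DVH to differential form.

    Bin volumes are the successive decrements of the cumulative curve; the
    remaining fraction at the highest dose point stays in the last bin, so the
    differential volumes sum to ``cumulative[0]``.
    """
    if dvh.kind != "cumulative":
        raise ValidationError("to_differential expects a cumulative DVH")
    dec = -np.diff(dvh.volume)
    vol = np.append(dec, dvh.volume[-1])
    vol = np.clip(vol, 0.0, None)  # guard float dust; monotonicity already checked
    return replace(dvh, kind="differential", volume=vol)


def to_cumulative(dvh: DVH) -> DVH:
    """Convert a differential DVH to cumulative form (reverse cumulative sum)."""
    if dvh.kind != "differential":
        raise ValidationError("to_cumulative expects a differential DVH")
    vol = np.cumsum(dvh.volume[::-1])[::-1]
    return replace(dvh, kind="cumulative", volume=vol)


def _as_cumulative(dvh: DVH) -> DVH:
    return dvh if dvh.kind == "cumulative" else to_cumulative(dvh)


def dose_at_volume(dvh: DVH, q: float) -> float:
    """Dose Dq received by at least the volume fraction ``q`` (q in (0, 1]).

    This is the standard DVH index: ``dose_at_volume(dvh, 0.95)`` is D95%.
    Linear interpolation between cumulative points; on a plateau the highest
    dose still covering ``q`` is returned, and ``q`` above the total covered
    fraction clamps to the lowest bin.
    """
    if not (0.0 < q <= 1.0):
        raise DomainError("volume fraction q must lie in (0, 1]")
    cum = _as_cumulative(dvh)
    d, v = cum.dose_bins, cum.volume
    above = np.nonzero(v >= q - _TOL)[0]
    if above.size == 0:
        return float(d[0])
    i = int(above[-1])
    if i == d.size - 1:
        return float(d[-1])
    # v[i] >= q > v[i+1]; interpolate on the strictly decreasing segment
    t = (v[i] - q) / (v[i] - v[i + 1])
    return float(d[i] + t * (d[i + 1] - d[i]))


def volume_at_dose(dvh: DVH, d: float) -> float:
    """Volume fraction Vd receiving at least dose ``d`` Gy.

    ``volume_at_dose(dvh, 0)`` equals the total covered fraction; doses above
    the last bin return 0.
    """
    if d < 0:
        raise DomainError("dose must be non-negative")
    cum = _as_cumulative(dvh)
    if d > cum.dose_bins[-1]:
        return 0.0
    return float(np.interp(d, cum.dose_bins, cum.volume, left=cum.volume[0]))


def mean_dose(dvh: DVH) -> float:
    """Mean structure dose: sum of v_i * D_i over the differential form."""
    diff = dvh if dvh.kind == "differential" else to_differential(dvh)
    return float(np.dot(diff.volume, diff.dose_bins))


def scale_dose(dvh: DVH, k: float) -> DVH:
    """Multiply every dose bin by ``k`` > 0, volumes unchanged.

    Models an MU-linear rescaling of the plan (dose is proportional to
    monitor units for fixed geometry), so every dose-type DVH index scales
    by exactly ``k``.
    """
    if k <= 0:
        raise DomainError("dose scale factor must be positive")
    return replace(dvh, dose_bins=dvh.dose_bins * k)
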
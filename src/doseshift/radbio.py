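"""EUD-based radiobiological models: generalized equivalent uniform dose,
logistic TCP/NTCP dose-response curves, their inverses, and dose-limit checks.

Model summary
-------------
The generalized equivalent uniform dose of a heterogeneous dose distribution
with fractional volumes ``v_i`` at doses ``D_i`` is the power mean

    EUD = (sum_i v_i * D_i**a) ** (1/a)

where ``a`` is the tissue-specific volume-effect exponent: negative for
tumors (penalizing cold spots), close to 1 for parallel organs such as lung
(EUD -> Dmean), and large for serial organs such as spinal cord
(EUD -> near-maximum dose).

Tumor control and normal-tissue complication probabilities follow the
logistic dose-response form

    TCP  = 1 / (1 + (TCD50/EUD)**(4*gamma50))
    NTCP = 1 / (1 + (TD50 /EUD)**(4*gamma50))

with midpoint dose D50 (TCD50 for targets, TD50 for organs at risk) and
unitless slope gamma50 (the normalized dose-response gradient at D50).

The bundled organ parameter table (``data/organ_parameters.csv``) carries
Lyman-Kutcher-Burman-derived ``a = 1/n`` exponents and D50 values for the
thoracic organs relevant to lung radiotherapy, together with gamma50 slopes
derived by inverting the published EUD limit at NTCP = 1% (the slope is
rarely tabulated directly; the provenance column records the derivation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .dvh import DVH, dose_at_volume, mean_dose, to_differential
from .errors import DomainError, ValidationError

OrganClass = Literal["target", "serial", "parallel"]

#: a-exponent ranges used for EUD confidence intervals when the tissue
#: exponent itself cannot be calibrated.
A_RANGE_PARALLEL = (0.5, 3.0)
A_RANGE_SERIAL = (4.0, 15.0)


class ZeroDoseWarning(UserWarning):
    """Signalled when EUD with a < 0 hits volume at zero dose (EUD -> 0)."""


@dataclass(frozen=True)
class OrganModel:
    """Radiobiological parameter set for one structure.

    ``d50`` is TCD50 for targets and TD50 for organs at risk, in Gy.
    ``gamma50`` is the unitless slope of the dose-response curve at D50.
    ``a`` is the volume-effect exponent (negative for targets, >= 1 typical
    for organs at risk).
    """

    name: str
    organ_class: OrganClass
    d50: float
    gamma50: float
    a: float
    endpoint: str = ""

    def __post_init__(self) -> None:
        if self.organ_class not in ("target", "serial", "parallel"):
            raise ValidationError(f"unknown organ class {self.organ_class!r}")
        if self.d50 <= 0:
            raise ValidationError("d50 must be positive")
        if self.gamma50 <= 0:
            raise ValidationError("gamma50 must be positive")
        if self.a == 0:
            raise ValidationError("volume-effect exponent a must be nonzero")
        if self.organ_class == "target" and self.a >= 0:
            raise ValidationError("targets require a negative volume-effect exponent")


@dataclass(frozen=True)
class EUDInterval:
    """EUD bounds over a class-specific range of volume-effect exponents."""

    low: float
    high: float
    a_low: float
    a_high: float

    def __post_init__(self) -> None:
        if self.low > self.high + 1e-12:
            raise ValidationError("EUD interval low bound exceeds high bound")


@dataclass(frozen=True)
class DoseLimitRecord:
    """Planning dose limits for one organ at risk.

    ``classic_limits`` holds ``(metric, comparator, value)`` triples where
    metric is one of ``Dmean``, ``D2%``, ``D95%``, ``V95%``; a range limit
    such as "Dmean < 15-20 Gy" is expressed with a ``(low, high)`` tuple and
    checked against the conservative bound by default.
    """

    organ: str
    eud_max_1pct: float
    eud_max_5pct: float
    classic_limits: tuple = ()

    def __post_init__(self) -> None:
        if not (0 < self.eud_max_1pct < self.eud_max_5pct):
            raise ValidationError("require 0 < eud_max_1pct < eud_max_5pct")


def eud(dvh: DVH, a: float) -> float:
    """Generalized equivalent uniform dose of ``dvh`` with exponent ``a``.

    Zero-volume bins are dropped before exponentiation.  If ``a`` < 0 and a
    nonzero fraction sits at exactly zero dose the mathematical limit is 0:
    that value is returned and :class:`ZeroDoseWarning` is emitted.  The power
    mean is evaluated in log space after factoring out the extreme dose so
    that exponents of magnitude 10-20 do not overflow.
    """
    if a == 0:
        raise DomainError("EUD exponent a must be nonzero")
    diff = dvh if dvh.kind == "differential" else to_differential(dvh)
    v = diff.volume
    d = diff.dose_bins
    keep = v > 0
    v, d = v[keep], d[keep]
    if v.size == 0:
        return 0.0
    if a < 0 and np.any(d == 0):
        warnings.warn(
            f"structure {dvh.structure_id!r}: volume at zero dose with a < 0; EUD is 0",
            ZeroDoseWarning,
            stacklevel=2,
        )
        return 0.0
    if np.all(d == d[0]):
        return float(d[0] * v.sum() ** (1.0 / a))
    ref = d.max() if a > 0 else d[d > 0].min()
    with np.errstate(divide="ignore"):
        logterm = a * np.log(d / ref)
    s = float(np.dot(v, np.exp(logterm)))
    return float(ref * np.exp(np.log(s) / a))


def _response(eud_value: float, d50: float, gamma50: float) -> float:
    # 1/(1 + (d50/EUD)^{4 g}) evaluated as a logistic in log dose (no overflow)
    if eud_value < 0:
        raise DomainError("EUD must be non-negative")
    if eud_value == 0:
        return 0.0
    return float(expit(4.0 * gamma50 * np.log(eud_value / d50)))


def tcp(eud_value: float, model: OrganModel) -> float:
    """Tumor control probability for a target EUD under the logistic model."""
    if model.organ_class != "target":
        raise DomainError("tcp requires a target organ model")
    return _response(eud_value, model.d50, model.gamma50)


def ntcp(eud_value: float, model: OrganModel) -> float:
    """Normal-tissue complication probability for an OAR EUD."""
    if model.organ_class not in ("serial", "parallel"):
        raise DomainError("ntcp requires a serial or parallel organ model")
    return _response(eud_value, model.d50, model.gamma50)


def eud_for_probability(p: float, model: OrganModel) -> float:
    """EUD giving response probability ``p``: the inverse of tcp/ntcp.

    ``EUD = D50 / (1/p - 1)**(1 / (4*gamma50))``.
    """
    if not (0.0 < p < 1.0):
        raise DomainError("probability must lie strictly in (0, 1)")
    return float(model.d50 * np.exp(logit(p) / (4.0 * model.gamma50)))


def derive_gamma50(d50: float, eud_value: float, p: float) -> float:
    """Slope gamma50 implied by one (EUD, probability) point on the curve.

    Used to recover unpublished slopes from tabulated EUD limits, e.g. the
    EUD at NTCP = 1%:  gamma50 = ln(1/p - 1) / (4 ln(D50/EUD)).
    """
    if not (0.0 < p < 1.0) or p == 0.5:
        raise DomainError("probability must lie in (0, 1) and differ from 0.5")
    if d50 <= 0 or eud_value <= 0 or eud_value == d50:
        raise DomainError("d50 and eud must be positive and distinct")
    return float(np.log(1.0 / p - 1.0) / (4.0 * np.log(d50 / eud_value)))


def eud_interval(dvh: DVH, organ_class: OrganClass) -> EUDInterval:
    """EUD confidence interval over the class's a-range.

    Uses a in [0.5, 3.0] for parallel organs and [4.0, 15.0] for serial
    organs.  EUD is non-decreasing in ``a`` (power-mean inequality), so the
    endpoints bound the interval.
    """
    if organ_class == "parallel":
        a_lo, a_hi = A_RANGE_PARALLEL
    elif organ_class == "serial":
        a_lo, a_hi = A_RANGE_SERIAL
    else:
        raise DomainError("EUD intervals are defined for serial and parallel organs only")
    return EUDInterval(low=eud(dvh, a_lo), high=eud(dvh, a_hi), a_low=a_lo, a_high=a_hi)


@dataclass(frozen=True)
class LimitCheck:
    metric: str
    comparator: str
    limit: float
    value: float
    passed: bool


@dataclass(frozen=True)
class ComplianceReport:
    organ: str
    eud_value: float
    eud_class: Literal["within_1pct", "within_5pct", "exceeds_5pct"]
    limit_checks: tuple[LimitCheck, ...]

    @property
    def all_pass(self) -> bool:
        return all(c.passed for c in self.limit_checks)


_METRIC_FRACTION = {"D2%": 0.02, "D95%": 0.95, "D98%": 0.98}


def _metric_value(dvh: DVH, metric: str, dpr: float | None) -> float:
    if metric == "Dmean":
        return mean_dose(dvh)
    if metric in _METRIC_FRACTION:
        return dose_at_volume(dvh, _METRIC_FRACTION[metric])
    if metric == "V95%":
        if dpr is None:
            raise DomainError("V95% limit check needs the prescription dose")
        from .dvh import volume_at_dose

        return volume_at_dose(dvh, 0.95 * dpr)
    raise DomainError(f"unsupported limit metric {metric!r}")


def check_dose_limits(
    dvh: DVH,
    record: DoseLimitRecord,
    model: OrganModel,
    dpr: float | None = None,
    conservative: bool = True,
) -> ComplianceReport:
    """Check a DVH against classic dose limits and the tabulated EUD caps.

    Range limits (e.g. "Dmean < 15-20 Gy") use the lower (conservative)
    bound when ``conservative`` is true, the upper bound otherwise.  The EUD
    computed with the organ's own exponent is classified against the 1% and
    5% NTCP caps.
    """
    checks = []
    for metric, comparator, value in record.classic_limits:
        limit = float(value[0] if conservative else value[1]) if isinstance(
            value, (tuple, list)
        ) else float(value)
        observed = _metric_value(dvh, metric, dpr)
        if comparator == "<":
            ok = observed < limit
        elif comparator == "<=":
            ok = observed <= limit
        elif comparator == ">":
            ok = observed > limit
        elif comparator == ">=":
            ok = observed >= limit
        else:
            raise DomainError(f"unsupported comparator {comparator!r}")
        checks.append(LimitCheck(metric, comparator, limit, observed, ok))
    eud_value = eud(dvh, model.a)
    if eud_value <= record.eud_max_1pct:
        eud_class = "within_1pct"
    elif eud_value <= record.eud_max_5pct:
        eud_class = "within_5pct"
    else:
        eud_class = "exceeds_5pct"
    return ComplianceReport(
        organ=record.organ,
        eud_value=eud_value,
        eud_class=eud_class,
        limit_checks=tuple(checks),
    )


# ---------------------------------------------------------------------------
# Bundled parameter table


def load_organ_table() -> pd.DataFrame:
    """Load the bundled thoracic organ parameter table as a DataFrame."""
    with resources.files("doseshift.data").joinpath("organ_parameters.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def _parse_limits(cell: str) -> tuple:
    # encoded as e.g. "Dmean<15..20;D2%<69"
    if not isinstance(cell, str) or not cell.strip():
        return ()
    out = []
    for part in cell.split(";"):
        part = part.strip()
        for comp in ("<=", ">=", "<", ">"):
            if comp in part:
                metric, val = part.split(comp)
                if ".." in val:
                    lo, hi = val.split("..")
                    out.append((metric.strip(), comp, (float(lo), float(hi))))
                else:
                    out.append((metric.strip(), comp, float(val)))
                break
        else:
            raise ValidationError(f"cannot parse dose limit {part!r}")
    return tuple(out)


def default_organ_models() -> dict[str, OrganModel]:
    """Organ models built from the bundled parameter table, keyed by name."""
    table = load_organ_table()
    return {
        row["name"]: OrganModel(
            name=row["name"],
            organ_class=row["organ_class"],
            d50=row["d50"],
            gamma50=row["gamma50"],
            a=row["a"],
            endpoint=row["endpoint"],
        )
        for _, row in table.iterrows()
    }


def default_dose_limits() -> dict[str, DoseLimitRecord]:
    """Dose-limit records for the organs at risk in the bundled table."""
    table = load_organ_table()
    out: dict[str, DoseLimitRecord] = {}
    for _, row in table.iterrows():
        if row["organ_class"] == "target" or pd.isna(row["eud_max_1pct"]):
            continue
        out[row["name"]] = DoseLimitRecord(
            organ=row["name"],
            eud_max_1pct=row["eud_max_1pct"],
            eud_max_5pct=row["eud_max_5pct"],
            classic_limits=_parse_limits(row.get("dose_limits", "")),
        )
    return out
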
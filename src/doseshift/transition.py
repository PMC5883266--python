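"""Plan 1/2/3 comparison workflow and the prescription-adjustment decision.

The QA workflow compares three plans when a department changes its dose
engine:

* Plan 1 - the reference plan, computed with the old algorithm and
  normalized so the isocentre receives the prescription dose Dpr.
* Plan 2 - the same beams recalculated with the new algorithm for the same
  Dpr (monitor units are re-derived by the new engine).
* Plan 3 - the new algorithm evaluated with Plan 1's exact MUs, showing what
  the historically delivered treatment looks like under the new engine.

Plan 3 cannot be recomputed here without a treatment planning system; it is
emulated by MU-linear rescaling of Plan 2's dose quantities (dose is
proportional to MU for fixed geometry), using the global factor
k = sum(MU1)/sum(MU2).

The decision engine keeps the prescription when (i) the paired MU comparison
shows no significant difference, (ii) the target D95% shift is within
tolerance, and (iii) every gamma criterion reaches its pass-rate goal;
otherwise it recommends adjusting Dpr to the Plan 3 target EUD - the
equivalent uniform dose actually delivered by the historical MUs as seen by
the new algorithm - and flags changes falling in the 5-10% band typical of
transitions from older pencil-beam-era algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from . import dvh as dvh_mod
from . import radbio
from .dvh import DVH, dose_at_volume, mean_dose, scale_dose, volume_at_dose
from .errors import DomainError, ValidationError
from .gamma import DoseGrid, GammaCriteria, compute_gamma
from .stats import PairedSample, spearman_rho, wilcoxon_signed_rank

PlanLabel = Literal["plan1", "plan2", "plan3"]


@dataclass(frozen=True)
class Beam:
    beam_id: str
    mu: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValidationError(f"beam {self.beam_id!r}: MU must be positive")


@dataclass(frozen=True)
class PlanRecord:
    """A treatment plan's dose bookkeeping for the transition comparison."""

    label: PlanLabel
    algorithm: str
    dose_mode: Literal["Dw", "Dm"]
    dpr: float
    diso: float
    beams: tuple[Beam, ...]
    dvhs: Mapping[str, DVH] = field(default_factory=dict)
    dose_grid: DoseGrid | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "beams", tuple(self.beams))
        object.__setattr__(self, "dvhs", dict(self.dvhs))
        if self.dpr <= 0:
            raise ValidationError("prescription dose must be positive")
        ids = [b.beam_id for b in self.beams]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate beam_id in plan")

    @property
    def total_mu(self) -> float:
        return float(sum(b.mu for b in self.beams))

    def mu_by_beam(self) -> dict[str, float]:
        return {b.beam_id: b.mu for b in self.beams}


@dataclass(frozen=True)
class DecisionRules:
    """Thresholds of the prescription-adjustment decision."""

    d95_tolerance_percent: float = 2.0
    gamma_criteria_list: tuple[tuple[float, float], ...] = ((2.0, 2.0), (3.0, 3.0))
    gamma_pass_goal: float = 0.95
    alpha: float = 0.05
    suggestion_basis: Literal["eud", "d95"] = "eud"

    def __post_init__(self) -> None:
        if self.d95_tolerance_percent <= 0 or self.alpha <= 0:
            raise ValidationError("tolerances must be positive")
        if not (0 < self.gamma_pass_goal <= 1):
            raise ValidationError("gamma_pass_goal must lie in (0, 1]")


@dataclass(frozen=True)
class DeltaMU:
    """Per-beam and total MU differences, reference minus test."""

    per_beam: dict[str, float]
    per_beam_percent: dict[str, float]
    total_plan1: float
    total_plan2: float

    @property
    def total(self) -> float:
        return self.total_plan1 - self.total_plan2

    @property
    def total_percent(self) -> float:
        return 100.0 * self.total / self.total_plan1


@dataclass(frozen=True)
class MetricDelta:
    ref: float
    test: float

    @property
    def delta(self) -> float:
        return self.test - self.ref

    @property
    def delta_percent(self) -> float:
        return 100.0 * self.delta / self.ref if self.ref != 0 else float("nan")


@dataclass(frozen=True)
class StructureDelta:
    """Per-structure DVH index, EUD and TCP/NTCP differences."""

    structure: str
    metrics: dict[str, MetricDelta]
    eud: MetricDelta | None = None
    probability: MetricDelta | None = None
    probability_kind: Literal["tcp", "ntcp"] | None = None
    model_missing: bool = False


@dataclass(frozen=True)
class GammaSummary:
    dd_percent: float
    dta_mm: float
    pass_rate: float
    evaluated_count: int


@dataclass(frozen=True)
class DecisionOutcome:
    decision: Literal["keep_dpr", "consider_adjustment", "insufficient_evidence"]
    suggested_dpr: float | None = None
    percent_change: float | None = None
    in_5_10_band: bool | None = None
    reasons: tuple[str, ...] = ()


@dataclass
class TransitionReport:
    """All quantities the decision draws on, for one algorithm transition."""

    delta_mu: DeltaMU | None = None
    plan3_diso: float | None = None
    dvh_deltas_same_dpr: dict[str, StructureDelta] = field(default_factory=dict)
    dvh_deltas_same_mu: dict[str, StructureDelta] = field(default_factory=dict)
    gamma_summaries: list[GammaSummary] = field(default_factory=list)
    wilcoxon_p: float | None = None
    wilcoxon_note: str = ""
    spearman: float | None = None
    d95_delta_percent: float | None = None
    d95_flag: Literal["no_adjustment", "consider_adjustment"] | None = None
    target_structure: str = "PTV"
    decision: DecisionOutcome | None = None


def delta_mu(plan1: PlanRecord, plan2: PlanRecord) -> DeltaMU:
    """MU differences, reference Plan 1 minus tested Plan 2.

    A positive delta means the old algorithm needed more MUs, so re-using the
    old MUs (Plan 3) will raise the isocentre dose under the new algorithm.
    """
    mu1, mu2 = plan1.mu_by_beam(), plan2.mu_by_beam()
    if set(mu1) != set(mu2):
        raise ValidationError("plans do not share the same beam_ids")
    per_beam = {bid: mu1[bid] - mu2[bid] for bid in mu1}
    per_pct = {bid: 100.0 * (mu1[bid] - mu2[bid]) / mu1[bid] for bid in mu1}
    return DeltaMU(
        per_beam=per_beam,
        per_beam_percent=per_pct,
        total_plan1=plan1.total_mu,
        total_plan2=plan2.total_mu,
    )


def build_plan3(plan1: PlanRecord, plan2: PlanRecord) -> PlanRecord:
    """Emulate Plan 3: the new algorithm evaluated with Plan 1's MUs.

    Plan 2's dose quantities (DVHs, isocentre dose, grid) are rescaled by
    the global MU-transfer factor k = sum(MU1)/sum(MU2); dose is treated as
    strictly proportional to delivered MU.
    """
    if not plan2.dvhs:
        raise ValidationError("plan2 carries no DVHs; cannot build plan3")
    dm = delta_mu(plan1, plan2)  # also validates matching beams
    k = dm.total_plan1 / dm.total_plan2
    dvhs = {s: scale_dose(d, k) for s, d in plan2.dvhs.items()}
    grid = None
    if plan2.dose_grid is not None:
        grid = replace(plan2.dose_grid, values=plan2.dose_grid.values * k)
    return PlanRecord(
        label="plan3",
        algorithm=plan2.algorithm,
        dose_mode=plan2.dose_mode,
        dpr=plan1.dpr,
        diso=plan2.diso * k,
        beams=plan1.beams,
        dvhs=dvhs,
        dose_grid=grid,
    )


_DVH_METRICS: dict[str, float] = {"D98%": 0.98, "D95%": 0.95, "D2%": 0.02}


def _structure_delta(
    structure: str,
    ref: DVH,
    test: DVH,
    dpr: float,
    model: radbio.OrganModel | None,
) -> StructureDelta:
    metrics = {
        name: MetricDelta(dose_at_volume(ref, q), dose_at_volume(test, q))
        for name, q in _DVH_METRICS.items()
    }
    metrics["Dmean"] = MetricDelta(mean_dose(ref), mean_dose(test))
    v95_dose = 0.95 * dpr
    metrics["V95%"] = MetricDelta(
        volume_at_dose(ref, v95_dose), volume_at_dose(test, v95_dose)
    )
    if model is None:
        return StructureDelta(structure=structure, metrics=metrics, model_missing=True)
    eud_pair = MetricDelta(radbio.eud(ref, model.a), radbio.eud(test, model.a))
    if model.organ_class == "target":
        prob = MetricDelta(
            radbio.tcp(eud_pair.ref, model), radbio.tcp(eud_pair.test, model)
        )
        kind: Literal["tcp", "ntcp"] = "tcp"
    else:
        prob = MetricDelta(
            radbio.ntcp(eud_pair.ref, model), radbio.ntcp(eud_pair.test, model)
        )
        kind = "ntcp"
    return StructureDelta(
        structure=structure,
        metrics=metrics,
        eud=eud_pair,
        probability=prob,
        probability_kind=kind,
    )


def dvh_delta_report(
    ref: PlanRecord,
    test: PlanRecord,
    models: Mapping[str, radbio.OrganModel] | None = None,
) -> dict[str, StructureDelta]:
    """Per-structure deltas of D98%, D2%, Dmean, D95%, V95%, EUD, TCP/NTCP.

    Structures present in both plans are compared; a structure without an
    organ model gets a metrics-only row flagged ``model_missing``.
    """
    models = models or {}
    shared = sorted(set(ref.dvhs) & set(test.dvhs))
    if not shared:
        raise ValidationError("plans share no structures")
    return {
        s: _structure_delta(s, ref.dvhs[s], test.dvhs[s], ref.dpr, models.get(s))
        for s in shared
    }


def d95_adjustment_flag(
    ref: PlanRecord,
    test: PlanRecord,
    rules: DecisionRules,
    target_structure: str = "PTV",
) -> tuple[Literal["no_adjustment", "consider_adjustment"], float]:
    """Target D95% shift flag: within tolerance means no adjustment needed.

    Returns the flag and the signed percent change.  The tolerance is strict:
    a shift exactly at the threshold is treated as actionable.
    """
    for plan in (ref, test):
        if target_structure not in plan.dvhs:
            raise ValidationError(f"plan {plan.label} lacks target DVH {target_structure!r}")
    d95_ref = dose_at_volume(ref.dvhs[target_structure], 0.95)
    d95_test = dose_at_volume(test.dvhs[target_structure], 0.95)
    pct = 100.0 * (d95_test - d95_ref) / d95_ref
    flag = "no_adjustment" if abs(pct) < rules.d95_tolerance_percent else "consider_adjustment"
    return flag, pct


def recommend_prescription(
    report: TransitionReport,
    plan1: PlanRecord,
    plan3: PlanRecord,
    rules: DecisionRules,
    models: Mapping[str, radbio.OrganModel] | None = None,
) -> DecisionOutcome:
    """Prescription decision from the assembled evidence.

    Keep Dpr when the Wilcoxon p is at or above alpha AND the target D95%
    shift is within tolerance AND every gamma criterion meets the pass-rate
    goal.  Otherwise suggest a new Dpr equal to the Plan 3 target EUD (the
    dose the historical MUs really deliver per the new algorithm), or the
    Plan 3 D95% when ``rules.suggestion_basis == "d95"``.  Missing evidence
    yields ``insufficient_evidence``.
    """
    missing = []
    if report.wilcoxon_p is None:
        missing.append("paired MU statistics")
    if report.d95_delta_percent is None:
        missing.append("target D95% delta")
    if not report.gamma_summaries:
        missing.append("gamma summaries")
    target = report.target_structure
    target_dvh = plan3.dvhs.get(target)
    if target_dvh is None:
        missing.append(f"plan3 target DVH {target!r}")
    if missing:
        return DecisionOutcome(
            decision="insufficient_evidence",
            reasons=tuple(f"missing {m}" for m in missing),
        )

    reasons = []
    if report.wilcoxon_p < rules.alpha:
        reasons.append(
            f"significant paired MU difference (p={report.wilcoxon_p:.4g} < {rules.alpha})"
        )
    if abs(report.d95_delta_percent) >= rules.d95_tolerance_percent:
        reasons.append(
            f"target D95% shift {report.d95_delta_percent:+.2f}% at or beyond "
            f"{rules.d95_tolerance_percent}% tolerance"
        )
    for gs in report.gamma_summaries:
        if gs.pass_rate < rules.gamma_pass_goal:
            reasons.append(
                f"gamma {gs.dd_percent:g}%/{gs.dta_mm:g}mm pass rate "
                f"{100 * gs.pass_rate:.1f}% below goal {100 * rules.gamma_pass_goal:.0f}%"
            )
    if not reasons:
        return DecisionOutcome(decision="keep_dpr", reasons=("all criteria satisfied",))

    if rules.suggestion_basis == "d95":
        suggested = dose_at_volume(target_dvh, 0.95)
    else:
        model = (models or {}).get(target)
        a_target = model.a if model is not None else -10.0
        suggested = radbio.eud(target_dvh, a_target)
    pct = 100.0 * (suggested - plan1.dpr) / plan1.dpr
    return DecisionOutcome(
        decision="consider_adjustment",
        suggested_dpr=suggested,
        percent_change=pct,
        in_5_10_band=5.0 <= abs(pct) <= 10.0,
        reasons=tuple(reasons),
    )


def compare_plans(
    plan1: PlanRecord,
    plan2: PlanRecord,
    models: Mapping[str, radbio.OrganModel] | None = None,
    rules: DecisionRules | None = None,
    target_structure: str = "PTV",
    gamma_norm_dose: float | None = None,
) -> TransitionReport:
    """Run the full transition comparison and fill a :class:`TransitionReport`.

    Computes MU deltas, builds Plan 3, compares DVH indices both at the same
    prescription (Plan 1 vs Plan 2) and at the same MUs (Plan 1 vs Plan 3),
    runs the gamma criteria on the dose grids when both plans carry one
    (global normalization to Plan 1's prescription by default), applies the
    paired Wilcoxon/Spearman statistics to the per-beam MUs, and evaluates
    the prescription decision.  The D95% adjustment flag follows the
    same-prescription comparison (Plan 2), since that is the quantity a
    planner re-normalizing to the new algorithm would see; all-zero MU
    differences are recorded as p = 1 (no detectable difference).
    """
    rules = rules or DecisionRules()
    report = TransitionReport(target_structure=target_structure)
    report.delta_mu = delta_mu(plan1, plan2)
    plan3 = build_plan3(plan1, plan2)
    report.plan3_diso = plan3.diso
    report.dvh_deltas_same_dpr = dvh_delta_report(plan1, plan2, models)
    report.dvh_deltas_same_mu = dvh_delta_report(plan1, plan3, models)

    mu1 = [b.mu for b in plan1.beams]
    mu2 = [plan2.mu_by_beam()[b.beam_id] for b in plan1.beams]
    sample = PairedSample(reference=mu1, test=mu2, unit="MU")
    if np.all(sample.differences == 0):
        report.wilcoxon_p = 1.0
        report.wilcoxon_note = "all paired MU differences are zero"
    else:
        report.wilcoxon_p = wilcoxon_signed_rank(sample).pvalue
        try:
            report.spearman = spearman_rho(sample)
        except DomainError:
            report.spearman = None

    if plan1.dose_grid is not None and plan2.dose_grid is not None:
        norm = gamma_norm_dose if gamma_norm_dose is not None else plan1.dpr
        for dd, dta in rules.gamma_criteria_list:
            crit = GammaCriteria(dd_percent=dd, dta_mm=dta, norm_dose=norm)
            res = compute_gamma(plan1.dose_grid, plan2.dose_grid, crit)
            report.gamma_summaries.append(
                GammaSummary(dd, dta, res.pass_rate, res.evaluated_count)
            )

    if target_structure in plan1.dvhs and target_structure in plan2.dvhs:
        report.d95_flag, report.d95_delta_percent = d95_adjustment_flag(
            plan1, plan2, rules, target_structure
        )

    report.decision = recommend_prescription(report, plan1, plan3, rules, models)
    return report
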
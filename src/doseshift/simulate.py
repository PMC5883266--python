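"""Synthetic plans, dose grids, DVHs and MU sets for an algorithm transition.

Nothing here simulates radiation transport.  The generators target the
*statistical signature* a dose-engine change leaves in exported plan data:

* a global multiplicative dose shift (the new engine computes a different
  dose per MU, so a plan renormalized to the same prescription needs
  proportionally different MUs), and
* a localized additive perturbation (heterogeneity handling differs most in
  low-density regions such as lung), plus per-beam MU noise.

A :class:`TransitionScenario` bundles these knobs.  ``global_scale`` is the
new engine's dose-per-MU relative to the reference (e.g. 0.97 for a 3% lower
dose); ``mu_shift_percent`` adds any *extra* systematic MU difference on top
of the renormalization implied by ``global_scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .dvh import DVH
from .errors import DomainError, ValidationError
from .gamma import DoseGrid
from .stats import PairedSample
from .transition import Beam, PlanRecord


@dataclass(frozen=True)
class LocalPerturbation:
    """Additive dose perturbation inside a spherical region (mm coordinates)."""

    center_mm: tuple[float, ...]
    radius_mm: float
    amplitude_gy: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValidationError("perturbation radius must be positive")


@dataclass(frozen=True)
class TransitionScenario:
    """Study conditions of one emulated algorithm transition."""

    dpr: float
    global_scale: float = 1.0
    local_perturbation: LocalPerturbation | None = None
    mu_shift_percent: float = 0.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.global_scale <= 0:
            raise ValidationError("global_scale must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.dpr <= 0:
            raise ValidationError("prescription dose must be positive")


def make_phantom_grid(
    shape: Sequence[int],
    spacing_mm: Sequence[float],
    dpr: float,
    target_radius_mm: float,
    penumbra_sigma_mm: float,
    seed: int | None = None,
) -> DoseGrid:
    """Stand-in for a TPS dose export: a flat high-dose core with a smooth
    Gaussian penumbra.

    The dose equals ``dpr`` within ``target_radius_mm`` of the grid center
    and falls off as ``dpr * exp(-(r - R)^2 / (2 sigma^2))`` outside.  The
    construction is deterministic; ``seed`` is accepted for API symmetry
    with the stochastic generators.
    """
    shape = tuple(int(n) for n in shape)
    spacing = tuple(float(s) for s in spacing_mm)
    if len(shape) != len(spacing):
        raise ValidationError("shape and spacing must have the same dimensionality")
    if target_radius_mm <= 0 or penumbra_sigma_mm <= 0:
        raise DomainError("geometry parameters must be positive")
    half_extent = min((n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    if target_radius_mm >= half_extent:
        raise DomainError("target radius exceeds the grid half-extent")
    axes = [s * (np.arange(n) - (n - 1) / 2.0) for n, s in zip(shape, spacing)]
    mesh = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(sum(m**2 for m in mesh))
    excess = np.clip(r - target_radius_mm, 0.0, None)
    values = dpr * np.exp(-(excess**2) / (2.0 * penumbra_sigma_mm**2))
    origin = tuple(float(a[0]) for a in axes)
    return DoseGrid(values=values, spacing=spacing, origin=origin)


def _perturb(grid: DoseGrid, pert: LocalPerturbation) -> np.ndarray:
    axes = grid.axes()
    lo = [a[0] for a in axes]
    hi = [a[-1] for a in axes]
    if len(pert.center_mm) != grid.values.ndim:
        raise ValidationError("perturbation center dimensionality mismatch")
    if any(c < l or c > h for c, l, h in zip(pert.center_mm, lo, hi)):
        raise DomainError("perturbation region lies outside the grid")
    mesh = np.meshgrid(*axes, indexing="ij")
    r2 = sum((m - c) ** 2 for m, c in zip(mesh, pert.center_mm))
    values = grid.values.copy()
    values[r2 <= pert.radius_mm**2] += pert.amplitude_gy
    return np.clip(values, 0.0, None)


def apply_transition_grid(grid: DoseGrid, scenario: TransitionScenario) -> DoseGrid:
    """The new engine's recalculation of ``grid`` at the *same MUs*:
    dose scaled by ``global_scale`` plus the local perturbation."""
    out = replace(grid, values=grid.values * scenario.global_scale)
    if scenario.local_perturbation is not None:
        out = replace(out, values=_perturb(out, scenario.local_perturbation))
    return out


def apply_transition_plan(plan1: PlanRecord, scenario: TransitionScenario) -> PlanRecord:
    """Build Plan 2: the new engine's plan renormalized to the same Dpr.

    Renormalization makes MU inversely proportional to the engine's
    dose-per-MU, so ``MU2 = MU1 * (1 + mu_shift/100) / global_scale`` plus
    Gaussian per-beam noise.  Dose quantities stay at the prescription level:
    DVHs are carried over unchanged and the dose grid only picks up the
    local perturbation (renormalization absorbs the global scale).
    """
    rng = np.random.default_rng(scenario.seed)
    factor = (1.0 + scenario.mu_shift_percent / 100.0) / scenario.global_scale
    beams = []
    for b in plan1.beams:
        mu = b.mu * factor + rng.normal(0.0, scenario.noise_sd)
        if mu <= 0:
            raise ValidationError("scenario noise drove a beam MU non-positive")
        beams.append(Beam(beam_id=b.beam_id, mu=mu))
    grid = None
    if plan1.dose_grid is not None:
        grid = plan1.dose_grid
        if scenario.local_perturbation is not None:
            grid = replace(grid, values=_perturb(grid, scenario.local_perturbation))
    return PlanRecord(
        label="plan2",
        algorithm="new",
        dose_mode="Dm",
        dpr=plan1.dpr,
        diso=plan1.diso,
        beams=tuple(beams),
        dvhs=dict(plan1.dvhs),
        dose_grid=grid,
    )


def apply_transition(obj, scenario: TransitionScenario):
    """Dispatch: grids get the same-MU recalculation, plans get Plan 2."""
    if isinstance(obj, DoseGrid):
        return apply_transition_grid(obj, scenario)
    if isinstance(obj, PlanRecord):
        return apply_transition_plan(obj, scenario)
    raise ValidationError("apply_transition expects a DoseGrid or PlanRecord")


def make_sigmoid_dvh(
    structure: str,
    d50_gy: float,
    steepness: float,
    seed: int | None = None,
    n_bins: int = 240,
    d_min_gy: float = 0.5,
) -> DVH:
    """Parametric cumulative DVH with a logistic falloff around ``d50_gy``.

    ``V(D) = expit(-steepness * (D - d50))``: a steep curve approximates a
    structure uniformly irradiated at d50 (target-like); a shallow one a
    broad dose spread (OAR-like).  Bins start at a small positive dose so
    target EUDs with negative exponents stay finite.  Deterministic; ``seed``
    is accepted for API symmetry.
    """
    if d50_gy <= 0 or steepness <= 0:
        raise DomainError("d50 and steepness must be positive")
    dose = np.linspace(d_min_gy, 2.0 * d50_gy, n_bins)
    vol = expit(-steepness * (dose - d50_gy))
    return DVH(structure_id=structure, kind="cumulative", dose_bins=dose, volume=vol)


def make_paired_mu(
    m_beams: int,
    mu_shift_percent: float,
    noise_sd: float,
    seed: int | None = None,
    mu_range: tuple[float, float] = (60.0, 160.0),
) -> PairedSample:
    """Paired per-beam MU sets: test = reference*(1 + shift/100) + noise."""
    if m_beams < 2:
        raise DomainError("need at least 2 beams")
    rng = np.random.default_rng(seed)
    ref = rng.uniform(*mu_range, size=m_beams)
    test = ref * (1.0 + mu_shift_percent / 100.0) + rng.normal(0.0, noise_sd, size=m_beams)
    return PairedSample(reference=ref, test=test, unit="MU")


#: Structure set produced by make_transition_plans: (name, d50 relative to
#: dpr, steepness per Gy).  The target is near-uniform at the prescription;
#: OARs sit at clinically plausible fractions of it.
_DEFAULT_STRUCTURES: tuple[tuple[str, float, float], ...] = (
    ("PTV", 1.0, 2.0),
    ("Lungs", 0.22, 0.25),
    ("Spinal cord", 0.45, 0.35),
)


def make_transition_plans(
    scenario: TransitionScenario,
    n_beams: int = 10,
    grid_shape: tuple[int, int] = (32, 32),
    grid_spacing_mm: tuple[float, float] = (3.0, 3.0),
    structures: Sequence[tuple[str, float, float]] = _DEFAULT_STRUCTURES,
) -> tuple[PlanRecord, PlanRecord]:
    """Generate a complete (Plan 1, Plan 2) pair for a scenario.

    Plan 1 carries seeded per-beam MUs, sigmoid DVHs for a target and two
    organs at risk, and a 2-D phantom dose grid normalized so the isocentre
    (grid center) receives the prescription.
    """
    rng = np.random.default_rng(scenario.seed)
    mu_ref = rng.uniform(60.0, 160.0, size=n_beams)
    beams = tuple(Beam(beam_id=f"B{i + 1}", mu=float(m)) for i, m in enumerate(mu_ref))
    dvhs = {
        name: make_sigmoid_dvh(name, rel_d50 * scenario.dpr, steep)
        for name, rel_d50, steep in structures
    }
    extent = min((n - 1) * s for n, s in zip(grid_shape, grid_spacing_mm))
    grid = make_phantom_grid(
        shape=grid_shape,
        spacing_mm=grid_spacing_mm,
        dpr=scenario.dpr,
        target_radius_mm=extent / 6.0,
        penumbra_sigma_mm=extent / 10.0,
    )
    plan1 = PlanRecord(
        label="plan1",
        algorithm="reference",
        dose_mode="Dw",
        dpr=scenario.dpr,
        diso=scenario.dpr,
        beams=beams,
        dvhs=dvhs,
        dose_grid=grid,
    )
    plan2 = apply_transition_plan(plan1, scenario)
    return plan1, plan2
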
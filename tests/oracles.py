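"""Independent brute-force oracles used to validate the fast implementations.

These deliberately use different algorithms from the package code: exhaustive
search over a finely subsampled grid for gamma, and full enumeration of all
2^n sign assignments for the Wilcoxon signed-rank null distribution.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import rankdata


def gamma_bruteforce(ref, eval_grid, criteria, fine_step_mm: float | None = None) -> np.ndarray:
    """Exhaustive gamma search over a finely subsampled evaluated grid.

    Resamples the whole evaluated grid at ``fine_step_mm`` (default dta/10)
    with linear interpolation, then for each reference point takes the exact
    minimum of the gamma integrand over every fine point within the search
    cap.  O(N_ref * N_fine): for tiny grids only.
    """
    step = fine_step_mm if fine_step_mm is not None else criteria.dta_mm / 10.0
    cap = criteria.cap_mm
    axes = eval_grid.axes()
    fine_axes = [
        np.linspace(a[0], a[-1], int(round((a[-1] - a[0]) / step)) + 1) for a in axes
    ]
    interp = RegularGridInterpolator(axes, eval_grid.values, method="linear")
    mesh = np.meshgrid(*fine_axes, indexing="ij")
    fine_pts = np.stack([m.ravel() for m in mesh], axis=-1)
    fine_dose = interp(fine_pts)

    ref_axes = ref.axes()
    ref_mesh = np.meshgrid(*ref_axes, indexing="ij")
    ref_pts = np.stack([m.ravel() for m in ref_mesh], axis=-1)
    ref_dose = ref.values.ravel()

    if criteria.normalization == "global":
        delta_d = np.full(ref_dose.size, criteria.dd_percent / 100.0 * criteria.norm_dose)
    else:
        delta_d = criteria.dd_percent / 100.0 * ref_dose

    out = np.full(ref_dose.size, np.nan)
    for i in range(ref_dose.size):
        if delta_d[i] <= 0:
            continue
        d2 = np.sum((fine_pts - ref_pts[i]) ** 2, axis=1)
        near = d2 <= cap**2 + 1e-9
        dose_term = ((fine_dose[near] - ref_dose[i]) / delta_d[i]) ** 2
        dist_term = d2[near] / criteria.dta_mm**2
        out[i] = np.sqrt(np.min(dose_term + dist_term))
    return out.reshape(ref.values.shape)


def wilcoxon_enumeration_p(differences) -> float:
    """Exact two-sided Wilcoxon p by enumerating all 2^n sign assignments."""
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product([0, 1], repeat=n)]
    )
    p_le = np.count_nonzero(w_all <= w_obs + 1e-9) / 2**n
    p_ge = np.count_nonzero(w_all >= w_obs - 1e-9) / 2**n
    return min(1.0, 2.0 * min(p_le, p_ge))
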
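"""Calibration of the EVB parameters against a reference reaction.

The adiabatic surface depends on where the two diabats sit relative to
each other, which is controlled by the gas shift α and the coupling H₁₂.
Standard EVB practice fixes them by requiring the simulated profile of a
*reference* reaction (for a proton transfer: the uncatalyzed reaction in
water, whose energetics are known from experiment and pKa considerations)
to reproduce the known activation and reaction free energies.  The
calibrated parameters are then held fixed when the environment changes.

The fit is a two-level fixed point:

* outer loop — alternate the two one-dimensional solves below, then verify
  both targets on a freshly seeded sample;
* ΔG₀ ← α by secant iteration (under linear response ΔG₀ responds to a
  uniform shift of diabat 2 with unit slope, so the first step is a
  unit-slope Newton step);
* ΔG‡ ← H₁₂ by bisection on [0, barrier at H₁₂=0] (the barrier is
  monotonically non-increasing in the coupling).

Sampling is redone whenever α changes (the mapping potential contains α)
but reused across the H₁₂ bisection: the mapping ensemble does not depend
on the off-diagonal coupling, so that reuse is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import EVBParameters, MappingSchedule
from .errors import CalibrationError
from .fepus import extract_result, fep_accumulate, us_profile
from .seeds import derive_seed

__all__ = ["CalibrationResult", "calibrate"]


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated parameters plus the per-iteration trace (for audit)."""

    params: EVBParameters
    trace: pd.DataFrame
    converged: bool
    n_samplings: int


def _schedule_from_frames(frames: pd.DataFrame) -> MappingSchedule:
    thetas = tuple(sorted(frames["theta"].unique().tolist()))
    return MappingSchedule(thetas=thetas, includes_md_window=False)


def _measure(frames, schedule, params, bins, min_count, min_frames):
    dg_m = fep_accumulate(frames, schedule, params, min_frames=min_frames)
    prof = us_profile(frames, dg_m, params, surface="ground",
                      bins=bins, min_count=min_count)
    res = extract_result(prof)
    return res.dG_act, res.dG_rxn


def calibrate(
    reference_runner: Callable[[EVBParameters, int], pd.DataFrame],
    targets: Tuple[float, float],
    tol: float = 0.1,
    seed: int = 0,
    initial: Optional[EVBParameters] = None,
    max_outer: int = 20,
    max_secant: int = 8,
    max_bisect: int = 40,
    bins: int = 50,
    min_count: int = 10,
    min_frames: int = 100,
) -> CalibrationResult:
    """Fit (α, H₁₂) so the FEP/US pipeline reproduces ``targets``.

    Parameters
    ----------
    reference_runner
        ``runner(params, seed) -> frame table`` sampling the reference
        system under the given parameters (see
        :func:`evbscreen.surrogate.make_reference_runner`).
    targets
        (ΔG‡, ΔG₀) of the reference reaction, kcal/mol.
    tol
        Both targets must be met within this on a freshly seeded
        verification sample, kcal/mol.

    Raises :class:`CalibrationError` (carrying the trace) when the outer
    loop does not converge within ``max_outer`` iterations.
    """
    target_act, target_rxn = float(targets[0]), float(targets[1])
    if not (np.isfinite(target_act) and np.isfinite(target_rxn)):
        raise CalibrationError("targets must be finite")
    params = initial if initial is not None else EVBParameters()
    if params.coupling_mode != "constant":
        raise CalibrationError(
            "calibrate fits h12_const; pass constant-coupling parameters"
        )

    trace_rows = []
    n_samplings = 0
    schedule = None

    def sample(p: EVBParameters):
        nonlocal n_samplings, schedule
        s = derive_seed(seed, "calibration", n_samplings)
        frames = reference_runner(p, s)
        n_samplings += 1
        if schedule is None:
            schedule = _schedule_from_frames(frames)
        return frames, s

    def log(stage, p, act, rxn, s):
        trace_rows.append({
            "stage": stage, "alpha": p.alpha, "h12": p.h12_const,
            "dG_act": act, "dG_rxn": rxn, "seed": s,
        })

    for outer in range(max_outer):
        # --- secant on alpha targeting dG_rxn (h12 held) ------------------
        frames, s = sample(params)
        act, rxn = _measure(frames, schedule, params, bins, min_count,
                            min_frames)
        log(f"outer{outer}/alpha", params, act, rxn, s)
        a0 = f0 = None
        a1, f1 = params.alpha, rxn - target_rxn
        for _ in range(max_secant):
            if abs(f1) <= tol:
                break
            if a0 is None or a1 == a0 or f1 == f0:
                a_new = a1 - f1  # unit-slope Newton step
            else:
                slope = (f1 - f0) / (a1 - a0)
                a_new = (a1 - f1 / slope
                         if np.isfinite(slope) and abs(slope) > 0.2
                         else a1 - f1)
            params = params.replace(alpha=a_new)
            frames, s = sample(params)
            act, rxn = _measure(frames, schedule, params, bins, min_count,
                                min_frames)
            log(f"outer{outer}/alpha", params, act, rxn, s)
            a0, f0 = a1, f1
            a1, f1 = a_new, rxn - target_rxn

        # --- bisection on h12 targeting dG_act (frames reused) ------------
        p0 = params.replace(h12_const=0.0)
        act0, rxn0 = _measure(frames, schedule, p0, bins, min_count,
                              min_frames)
        if act0 <= target_act + tol:
            # no coupling needed (or target unreachable from above)
            params = p0
            log(f"outer{outer}/h12", params, act0, rxn0, s)
        else:
            lo_h, hi_h = 0.0, act0  # coupling lowers the barrier ~1:1
            for _ in range(max_bisect):
                mid = 0.5 * (lo_h + hi_h)
                params = params.replace(h12_const=mid)
                act_m, rxn_m = _measure(frames, schedule, params, bins,
                                        min_count, min_frames)
                if act_m > target_act:
                    lo_h = mid
                else:
                    hi_h = mid
                if abs(act_m - target_act) <= 0.25 * tol or (
                        hi_h - lo_h) < 1e-4:
                    break
            log(f"outer{outer}/h12", params, act_m, rxn_m, s)

        # --- verification on a fresh seed ---------------------------------
        frames_v, s_v = sample(params)
        act_v, rxn_v = _measure(frames_v, schedule, params, bins, min_count,
                                min_frames)
        log(f"outer{outer}/verify", params, act_v, rxn_v, s_v)
        if abs(act_v - target_act) <= tol and abs(rxn_v - target_rxn) <= tol:
            return CalibrationResult(
                params=params,
                trace=pd.DataFrame(trace_rows),
                converged=True,
                n_samplings=n_samplings,
            )

    raise CalibrationError(
        f"calibration did not converge within {max_outer} outer iterations "
        f"(targets dG_act={target_act}, dG_rxn={target_rxn}, tol={tol})",
        trace=pd.DataFrame(trace_rows),
    )
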
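"""Linear-response surrogate sampler with analytic ground truth.

Stands in for the MD engine: two harmonic, equal-curvature diabats on a
single scalar "solvent" coordinate s,

    ε₁(s) = ½k(s−s₁)² + c₁        ε₂(s) = ½k(s−s₂)² + c₂

This is the textbook linear-response picture, and everything the FEP/US
pipeline estimates has a closed form against which it can be checked:

    λ      = ½k(s₂−s₁)²                    (reorganization energy)
    ΔG₀    = c₂ − c₁                       (reaction free energy)
    ΔG‡    = (λ+ΔG₀)²/(4λ)                 (diabatic crossing barrier)
    ΔG(θ)  = θ(ΔG₀+α) + λθ(1−θ)           (mapping free energy)

Sampling is a seeded Metropolis random walk on the mapping potential
(1−θ)ε₁ + θ(ε₂+α); frames record the *raw* diabat energies (the gas shift
α is an analysis-side parameter).  A per-substitution effect model turns
the surrogate into a synthetic mutant library so the whole campaign layer
is testable end to end with known ground truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from numba import njit

from .core import DEFAULT_TEMPERATURE, EVBParameters, KB, MappingSchedule
from .errors import InvalidInputError
from .seeds import derive_seed

__all__ = [
    "SurrogateModel",
    "EffectModel",
    "AnalyticTruth",
    "LambdaFlooredWarning",
    "analytic_truth",
    "sample_window",
    "run_evb_protocol",
    "variant_model",
    "make_reference_runner",
]

#: λ is never driven below this by an effect-model shift (kcal/mol).
LAMBDA_MIN = 1.0

#: fraction of a chain discarded as burn-in, and the frame-recording stride
BURN_IN_FRACTION = 0.2
RECORD_STRIDE = 5

#: proposal half-width in units of the thermal width sqrt(kT/k); chosen for
#: roughly 40% Metropolis acceptance on a harmonic well
PROPOSAL_SCALE = 2.5


class LambdaFlooredWarning(UserWarning):
    """An effect-model shift tried to drive λ to or below zero."""


@dataclass(frozen=True)
class SurrogateModel:
    """Equal-curvature harmonic diabats on one scalar coordinate."""

    k: float = 20.0  # curvature, kcal/mol per (coordinate unit)^2
    s1: float = 0.0
    s2: float = 2.0
    c1: float = 0.0
    c2: float = 0.0
    h12: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE
    restraint_k: float = 0.0  # optional harmonic restraint on s
    restraint_center: float = 0.0

    def __post_init__(self):
        if self.k <= 0:
            raise InvalidInputError("curvature k must be > 0")
        if self.temperature <= 0:
            raise InvalidInputError("temperature must be > 0")
        if self.h12 < 0 or self.restraint_k < 0:
            raise InvalidInputError("h12 and restraint_k must be >= 0")

    @property
    def lam(self) -> float:
        return 0.5 * self.k * (self.s2 - self.s1) ** 2

    @property
    def dG0(self) -> float:
        return self.c2 - self.c1

    def replace(self, **kw) -> "SurrogateModel":
        from dataclasses import replace as _replace

        return _replace(self, **kw)

    @classmethod
    def from_targets(cls, lam: float, dG0: float, k: float = 20.0,
                     **kw) -> "SurrogateModel":
        """Model with prescribed λ and ΔG₀ (minima placed symmetrically)."""
        if lam <= 0:
            raise InvalidInputError("lam must be > 0")
        d = math.sqrt(2.0 * lam / k)
        return cls(k=k, s1=0.0, s2=d, c1=0.0, c2=dG0, **kw)


class AnalyticTruth(NamedTuple):
    """Closed-form reference values of a surrogate model."""

    lam: float
    dG0: float
    diabatic_barrier: float  # (λ+ΔG₀)²/(4λ); nan when degenerate
    degenerate: bool  # s1 == s2: no reorganization, no crossing


def analytic_truth(model: SurrogateModel) -> AnalyticTruth:
    """λ, ΔG₀ and the diabatic crossing barrier of the model."""
    lam, dg0 = model.lam, model.dG0
    if lam == 0.0:
        return AnalyticTruth(0.0, dg0, math.nan, True)
    return AnalyticTruth(lam, dg0, (lam + dg0) ** 2 / (4.0 * lam), False)


@njit(cache=True, nogil=True)
def _metropolis_chain(s0, k, s1, s2, c1, c2s, theta, kr, sr, beta,
                      props, logu):  # pragma: no cover - jit
    n = props.shape[0]
    traj = np.empty(n)
    s = s0
    u_cur = ((1.0 - theta) * (0.5 * k * (s - s1) ** 2 + c1)
             + theta * (0.5 * k * (s - s2) ** 2 + c2s)
             + 0.5 * kr * (s - sr) ** 2)
    for i in range(n):
        sp = s + props[i]
        u_new = ((1.0 - theta) * (0.5 * k * (sp - s1) ** 2 + c1)
                 + theta * (0.5 * k * (sp - s2) ** 2 + c2s)
                 + 0.5 * kr * (sp - sr) ** 2)
        if -beta * (u_new - u_cur) > logu[i]:
            s = sp
            u_cur = u_new
        traj[i] = s
    return traj


def _n_recorded(n_steps: int) -> int:
    return max(1, int(math.floor((1.0 - BURN_IN_FRACTION) * n_steps
                                 / RECORD_STRIDE)))


def sample_window(
    model: SurrogateModel,
    theta: float,
    n_steps: int,
    seed: int,
    alpha: float = 0.0,
    window_index: int = 0,
) -> pd.DataFrame:
    """Metropolis samples of one mapping window.

    The chain walks on (1−θ)ε₁ + θ(ε₂+α) (+ restraint) at the model
    temperature, starting from the potential minimum.  Frames are retained
    every ``RECORD_STRIDE`` steps counting back from the final step, which
    discards at least the burn-in fraction of the chain; at least one frame
    is always retained.  Identical arguments give identical output.

    Returns a frame table with the *unshifted* diabat energies ε₁, ε₂.
    """
    if n_steps < 1:
        raise InvalidInputError("n_steps must be >= 1")
    if not (0.0 <= theta <= 1.0):
        raise InvalidInputError("theta must be in [0, 1]")
    kt = KB * model.temperature
    beta = 1.0 / kt
    k, kr = model.k, model.restraint_k
    c2s = model.c2 + alpha
    # start at the minimum of the combined harmonic potential
    s_map = (1.0 - theta) * model.s1 + theta * model.s2
    s0 = (k * s_map + kr * model.restraint_center) / (k + kr)
    step = PROPOSAL_SCALE * math.sqrt(kt / (k + kr))

    rng = np.random.Generator(np.random.PCG64(seed))
    props = rng.uniform(-step, step, size=n_steps)
    logu = np.log(rng.uniform(0.0, 1.0, size=n_steps))
    traj = _metropolis_chain(
        s0, k, model.s1, model.s2, model.c1, c2s, theta,
        kr, model.restraint_center, beta, props, logu,
    )
    n_rec = _n_recorded(n_steps)
    first = (n_steps - 1) - RECORD_STRIDE * (n_rec - 1)
    s = traj[first::RECORD_STRIDE]

    e1 = 0.5 * k * (s - model.s1) ** 2 + model.c1
    e2 = 0.5 * k * (s - model.s2) ** 2 + model.c2
    return pd.DataFrame(
        {
            "window": np.full(len(s), window_index, dtype=np.int64),
            "theta": np.full(len(s), float(theta)),
            "e1": e1,
            "e2": e2,
        }
    )


def run_evb_protocol(
    model: SurrogateModel,
    schedule: MappingSchedule,
    params: EVBParameters,
    n_steps_per_window: int,
    seed: int,
) -> pd.DataFrame:
    """One full EVB run: every window of the schedule, one frame table.

    When the schedule declares an MD stream, the θ = 0.5 pseudo-window is
    sampled like any other window and spliced into the accumulation order
    (it emulates the equilibration trajectory run at the midpoint mapping
    potential).  Window seeds derive from ``seed`` and the window index.
    """
    thetas = schedule.accumulation_thetas()
    parts = []
    for w, th in enumerate(thetas):
        parts.append(
            sample_window(
                model, th, n_steps_per_window,
                seed=derive_seed(seed, "window", w),
                alpha=params.alpha, window_index=w,
            )
        )
    return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class EffectModel:
    """Per-substitution energetic effects for synthetic mutant libraries.

    ``shifts`` maps a substitution label (e.g. ``"L93A"``) to
    (δΔG₀, δλ) in kcal/mol; substitutions not listed draw both shifts
    deterministically from ``master_seed`` via a normal law with standard
    deviation ``noise_sd``.  ``epistasis`` maps a sorted position pair to
    an extra ΔG₀ term applied when both positions are mutated together.
    """

    shifts: dict = field(default_factory=dict)
    epistasis: dict = field(default_factory=dict)
    noise_sd: float = 1.5
    master_seed: int = 0

    def substitution_effect(self, sub_label: str):
        if sub_label in self.shifts:
            d_dg0, d_lam = self.shifts[sub_label]
            return float(d_dg0), float(d_lam)
        rng = np.random.Generator(np.random.PCG64(
            derive_seed(self.master_seed, "sub", sub_label)
        ))
        draw = rng.normal(0.0, self.noise_sd, size=2)
        return float(draw[0]), float(draw[1])


def variant_model(
    base: SurrogateModel,
    variant,
    effects: EffectModel,
) -> SurrogateModel:
    """Surrogate model of a variant: additive shifts plus epistasis.

    ΔG₀ shifts move c₂; λ shifts rescale the minima separation (keeping
    its sign and the curvature), floored at ``LAMBDA_MIN`` with a
    :class:`LambdaFlooredWarning`.  ``variant`` is a
    :class:`~evbscreen.variants.Variant` (or anything with
    ``substitutions``/``sub_labels``); an empty variant returns ``base``
    unchanged.  Deterministic in (variant, effects.master_seed).
    """
    subs = list(getattr(variant, "substitutions", ()))
    if not subs:
        return base
    d_dg0 = 0.0
    d_lam = 0.0
    for sub in subs:
        label = f"{sub.wt_aa}{sub.position}{sub.new_aa}"
        a, b = effects.substitution_effect(label)
        d_dg0 += a
        d_lam += b
    positions = sorted(s.position for s in subs)
    for i, p in enumerate(positions):
        for q in positions[i + 1:]:
            d_dg0 += effects.epistasis.get((p, q), 0.0)

    new_lam = base.lam + d_lam
    if new_lam < LAMBDA_MIN:
        warnings.warn(
            f"variant {getattr(variant, 'label', subs)}: λ shift gives "
            f"{new_lam:.3g} <= 0; floored at {LAMBDA_MIN}",
            LambdaFlooredWarning,
        )
        new_lam = LAMBDA_MIN
    sign = 1.0 if base.s2 >= base.s1 else -1.0
    new_s2 = base.s1 + sign * math.sqrt(2.0 * new_lam / base.k)
    return base.replace(s2=new_s2, c2=base.c1 + base.dG0 + d_dg0)


def make_reference_runner(
    model: SurrogateModel,
    schedule: MappingSchedule,
    n_steps_per_window: int,
):
    """Sampling contract for :func:`evbscreen.calibration.calibrate`.

    Returns ``runner(params, seed) -> frame table`` over the fixed model
    and schedule; α flows from ``params`` into the mapping potential.
    """

    def runner(params: EVBParameters, seed: int) -> pd.DataFrame:
        return run_evb_protocol(model, schedule, params,
                                n_steps_per_window, seed)

    return runner
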
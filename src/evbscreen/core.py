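"""Two-state empirical valence bond (EVB) primitives.

An EVB description of a reaction step represents the reacting system by two
diabatic (valence-bond) states with energies ε₁ (reactant-like) and ε₂
(product-like), evaluated on the same geometry, plus an off-diagonal
coupling H₁₂.  The adiabatic ground state is the lowest eigenvalue of the
2×2 Hamiltonian

    H = [[ε₁, H₁₂], [H₁₂, ε₂ + α]]

where the gas shift α is a calibration constant added to the product
diabat.  Sampling between the states is driven by the mapping potential
ε_m = (1−θ)ε₁ + θ(ε₂+α), with θ stepped from 0 to 1 over a window
schedule.  The reaction coordinate throughout is the energy gap
x = ε₁ − (ε₂+α): it projects the full configuration space onto one
dimension while retaining the environment's electrostatic response.

This module holds the parameter containers and the pointwise algebra;
window accumulation and profile construction live in :mod:`evbscreen.fepus`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .errors import InvalidInputError, InvertedRegionError, MissingFieldError

#: Boltzmann constant, kcal·mol⁻¹·K⁻¹.
KB = 0.0019872041

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 300.0


class FrameRecord(NamedTuple):
    """One sampled configuration's diabatic energies under a mapping window.

    Frame *collections* are carried as :class:`pandas.DataFrame` objects with
    columns ``window, theta, e1, e2[, r_da]`` (see :mod:`evbscreen.frames`);
    this record type documents the per-row schema and is convenient for
    constructing tiny hand-written tables in tests.
    """

    window_index: int
    theta: float
    e1: float
    e2: float
    r_da: Optional[float] = None


@dataclass(frozen=True)
class EVBParameters:
    """Calibratable EVB quantities.

    Parameters
    ----------
    alpha
        Gas shift added to the product diabat ε₂ before every mapping and
        eigenvalue operation, kcal/mol.
    coupling_mode
        ``"constant"`` (H₁₂ = ``h12_const``) or ``"exponential"``
        (H₁₂ = A·exp(−μ·(r_DA − r₀)), a function of the donor–acceptor
        distance).
    temperature
        Kelvin; β = 1/(k_B T) is derived from it.
    """

    alpha: float = 0.0
    coupling_mode: str = "constant"
    h12_const: float = 0.0
    coupling_A: float = 0.0
    coupling_mu: float = 0.0
    coupling_r0: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if not math.isfinite(self.alpha):
            raise InvalidInputError("alpha must be finite")
        if self.coupling_mode not in ("constant", "exponential"):
            raise InvalidInputError(
                f"unknown coupling_mode {self.coupling_mode!r}"
            )
        if self.h12_const < 0 or self.coupling_A < 0 or self.coupling_mu < 0:
            raise InvalidInputError("coupling parameters must be >= 0")
        if self.temperature <= 0:
            raise InvalidInputError("temperature must be positive")

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)

    def replace(self, **kw) -> "EVBParameters":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


@dataclass(frozen=True)
class MappingSchedule:
    """Ordered θ values of the mapping windows.

    ``includes_md_window`` marks that frames at θ = 0.5 are supplied by a
    preceding equilibration (MD) stream rather than a dedicated window; the
    accumulator inserts that stream between the windows bracketing 0.5.
    """

    thetas: tuple
    window_length: float = 20.0  # ps
    includes_md_window: bool = False

    def __post_init__(self):
        th = tuple(float(t) for t in self.thetas)
        object.__setattr__(self, "thetas", th)
        if len(th) < 2:
            raise InvalidInputError("schedule needs at least two windows")
        if any(b <= a for a, b in zip(th, th[1:])):
            raise InvalidInputError("thetas must be strictly increasing")
        if th[0] != 0.0 or th[-1] != 1.0:
            raise InvalidInputError("thetas must start at 0 and end at 1")
        if self.includes_md_window and 0.5 in th:
            raise InvalidInputError(
                "theta=0.5 listed explicitly and as MD stream"
            )

    @property
    def n_windows(self) -> int:
        return len(self.thetas)

    def accumulation_thetas(self) -> tuple:
        """θ values in accumulation order, MD stream (0.5) spliced in."""
        if not self.includes_md_window:
            return self.thetas
        out = []
        inserted = False
        for t in self.thetas:
            if not inserted and t > 0.5:
                out.append(0.5)
                inserted = True
            out.append(t)
        if not inserted:  # pragma: no cover - schedule always ends at 1 > 0.5
            out.append(0.5)
        return tuple(out)


@dataclass(frozen=True)
class MarcusInputs:
    """Inputs of the modified Marcus expression for the activation barrier.

    ``w_r`` is the work term (free energy of pre-assembling the reactant
    pair; 0 for an intramolecular or pre-organized step) and ``gamma`` the
    nuclear quantum correction, fixed at 1 in this classical implementation.
    """

    dG0: float
    lam: float
    h12_ts: float = 0.0
    h12_rs: float = 0.0
    w_r: float = 0.0
    gamma: float = 1.0

    def __post_init__(self):
        if not (self.lam > 0):
            raise InvalidInputError("reorganization energy lam must be > 0")
        if self.h12_ts < 0 or self.h12_rs < 0:
            raise InvalidInputError("couplings must be >= 0")


def ground_state_energy(e1, e2, h12):
    """Lowest eigenvalue of the two-state EVB Hamiltonian.

    E_g = ½(ε₁+ε₂) − ½√((ε₁−ε₂)² + 4H₁₂²).  Accepts scalars or numpy
    arrays (broadcast).  E_g ≤ min(ε₁, ε₂), with equality iff H₁₂ = 0.
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    h12 = np.asarray(h12, dtype=float)
    if not (np.all(np.isfinite(e1)) and np.all(np.isfinite(e2))
            and np.all(np.isfinite(h12))):
        raise InvalidInputError("ground_state_energy: non-finite input")
    if np.any(h12 < 0):
        raise InvalidInputError("ground_state_energy: h12 must be >= 0")
    out = 0.5 * (e1 + e2) - 0.5 * np.sqrt((e1 - e2) ** 2 + 4.0 * h12 ** 2)
    return float(out) if out.ndim == 0 else out


def coupling(params: EVBParameters, r_da=None):
    """Off-diagonal coupling H₁₂ under the given parameters.

    Constant mode ignores ``r_da``; exponential mode evaluates
    A·exp(−μ·(r_DA − r₀)) and requires the donor–acceptor distance.
    """
    if params.coupling_mode == "constant":
        return params.h12_const
    if r_da is None:
        raise MissingFieldError(
            "exponential coupling requires the donor-acceptor distance r_da"
        )
    r = np.asarray(r_da, dtype=float)
    if not np.all(np.isfinite(r)):
        raise InvalidInputError("coupling: non-finite r_da")
    out = params.coupling_A * np.exp(
        -params.coupling_mu * (r - params.coupling_r0)
    )
    return float(out) if out.ndim == 0 else out


def mapping_energy(e1, e2_shifted, theta):
    """Mapping potential ε_m = (1−θ)ε₁ + θ(ε₂+α).

    ``e2_shifted`` must already include the gas shift α.
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0) or np.any(th > 1) or not np.all(np.isfinite(th)):
        raise InvalidInputError("mapping_energy: theta must be in [0, 1]")
    e1 = np.asarray(e1, dtype=float)
    e2s = np.asarray(e2_shifted, dtype=float)
    if not (np.all(np.isfinite(e1)) and np.all(np.isfinite(e2s))):
        raise InvalidInputError("mapping_energy: non-finite energies")
    out = (1.0 - th) * e1 + th * e2s
    return float(out) if out.ndim == 0 else out


def marcus_barrier(m: MarcusInputs) -> float:
    """Activation barrier from the modified Marcus expression.

    ΔG‡ ≈ w_r + (ΔG0 + λ)²/(4λ) − H₁₂(TS) + H₁₂(RS)²/(ΔG0 + λ)

    The classical limit (Γ = 1) is used; the nuclear quantum correction
    would multiply the result.
    """
    denom = m.dG0 + m.lam
    if denom <= 0:
        raise InvertedRegionError(
            f"dG0 + lam = {denom:.4g} <= 0: inverted region, the crossing "
            "no longer lies between the minima"
        )
    barrier = (
        m.w_r
        + denom ** 2 / (4.0 * m.lam)
        - m.h12_ts
        + m.h12_rs ** 2 / denom
    )
    return m.gamma * barrier


def validate_frames(frames, require_r_da: bool = False) -> None:
    """Check a frame table against the FrameRecord invariants.

    Raises :class:`InvalidInputError` on non-finite energies, θ outside
    [0, 1], or a window index mapped to more than one θ.
    """
    import pandas as pd

    if not isinstance(frames, pd.DataFrame):
        raise InvalidInputError("frames must be a pandas DataFrame")
    needed = {"window", "theta", "e1", "e2"}
    missing = needed - set(frames.columns)
    if missing:
        raise MissingFieldError(f"frame table missing columns {sorted(missing)}")
    if require_r_da and "r_da" not in frames.columns:
        raise MissingFieldError(
            "exponential coupling requires an r_da column in the frame table"
        )
    if len(frames) == 0:
        return
    for col in ("e1", "e2"):
        if not np.all(np.isfinite(frames[col].to_numpy(float))):
            raise InvalidInputError(f"non-finite values in column {col!r}")
    th = frames["theta"].to_numpy(float)
    if np.any(th < 0) or np.any(th > 1) or not np.all(np.isfinite(th)):
        raise InvalidInputError("theta values must lie in [0, 1]")
    per_window = frames.groupby("window")["theta"].nunique()
    bad = per_window[per_window > 1]
    if len(bad):
        raise InvalidInputError(
            f"windows with inconsistent theta: {list(bad.index)}"
        )
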
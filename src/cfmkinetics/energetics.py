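"""Bell-Evans force dependence and base-stacking free energies.

Under the Bell-Evans picture a single-barrier bond under constant force F
dissociates at

    k(F) = k_thermal * exp(F / f),      f = k_B T / x_dagger,

so ln k is linear in force: the intercept extrapolates to the zero-force
(thermal) off-rate and the slope gives the force scale f, equivalently the
transition-state distance x_dagger = k_B T / f along the pulling axis.

Two constructs that differ only by one terminal base stack share the same
transition state, so the stack changes only the activation energy and the
stacking free energy follows from the off-rate ratio at any common force:

    dG_stack = R T ln(k_stack / k_control)

(negative when the stack slows dissociation).  Uncertainty is propagated to
first order from the replicate scatter of the two off-rates:
dG_err = R T sqrt((sd_s/k_s)^2 + (sd_c/k_c)^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinetics import OffRateEstimate
from .physics import CONSTANTS, thermal_energy

__all__ = [
    "BellEvansFit",
    "StackingEnergy",
    "bell_evans_fit",
    "transition_distance",
    "delta_g_stack",
    "delta_g_by_force",
    "ForceConsistencyTable",
]


@dataclass(frozen=True)
class BellEvansFit:
    """Weighted log-linear fit of off-rate versus force.

    ``covariance`` is the 2x2 covariance of (ln k_thermal, slope) where
    slope = 1/force_scale; ``positive_slope`` is False when the fitted
    slope is non-positive (no single-barrier interpretation).
    """

    k_thermal: float
    force_scale: float  # pN; k(F) = k_thermal * exp(F / force_scale)
    x_dagger: float  # nm; k_B T / force_scale
    covariance: np.ndarray
    temperature: float
    positive_slope: bool = True

    @property
    def force_scale_err(self) -> float:
        """1-sigma error of the force scale via the delta method."""
        slope = 1.0 / self.force_scale
        return float(math.sqrt(self.covariance[1, 1]) / slope**2)

    def predict(self, force_pN: np.ndarray) -> np.ndarray:
        """Off-rate at the given forces under the fitted model."""
        return self.k_thermal * np.exp(np.asarray(force_pN, float) / self.force_scale)


@dataclass(frozen=True)
class StackingEnergy:
    """Free energy of one terminal base stack from an off-rate ratio."""

    dG: float  # kcal/mol, negative = stabilizing
    dG_err: float  # kcal/mol, first-order propagated
    construct_pair: tuple[str, str]
    force: float  # pN
    temperature: float  # K


def bell_evans_fit(
    estimates: list[OffRateEstimate], temperature: float
) -> BellEvansFit:
    """Fit ln k_mean versus force by weighted linear least squares.

    Weights are the inverse delta-method variances of ln k,
    1 / (k_sd/k_mean)^2; unit weights are used if any estimate has zero sd.
    Requires at least three distinct forces with positive rates.
    """
    forces = np.array([e.force for e in estimates], dtype=float)
    k = np.array([e.k_mean for e in estimates], dtype=float)
    sd = np.array([e.k_sd for e in estimates], dtype=float)
    if len(np.unique(forces)) < 3:
        raise ValueError("need off-rates at >= 3 distinct forces")
    if np.any(k <= 0) or not np.all(np.isfinite(forces)):
        raise ValueError("all off-rates must be positive and forces finite")

    y = np.log(k)
    if np.any(sd <= 0):
        w = np.ones_like(y)
    else:
        w = (k / sd) ** 2  # 1 / var(ln k), delta method

    X = np.column_stack([np.ones_like(forces), forces])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ y)
    cov = np.linalg.inv(xtwx)
    intercept, slope = beta

    kbt = thermal_energy(temperature)
    positive = slope > 0
    force_scale = 1.0 / slope if positive else float("inf")
    return BellEvansFit(
        k_thermal=float(np.exp(intercept)),
        force_scale=float(force_scale),
        x_dagger=float(kbt * slope),
        covariance=cov,
        temperature=temperature,
        positive_slope=bool(positive),
    )


def transition_distance(force_scale: float, temperature: float) -> float:
    """Transition-state distance x_dagger = k_B T / f, in nm."""
    if force_scale <= 0 or not math.isfinite(force_scale):
        raise ValueError("force_scale must be finite and > 0")
    return thermal_energy(temperature) / force_scale


def delta_g_stack(
    k_stack: OffRateEstimate,
    k_control: OffRateEstimate,
    temperature: float,
) -> StackingEnergy:
    """Stacking free energy dG = R T ln(k_stack / k_control), kcal/mol.

    Equal on-rates for the two constructs are assumed, so the activation-
    energy difference is the stack's free-energy contribution.  The error is
    the first-order propagation of the two relative off-rate uncertainties.
    Exactly antisymmetric under swapping the pair.
    """
    if k_stack.k_mean <= 0 or k_control.k_mean <= 0:
        raise ValueError("off-rates must be positive")
    if temperature <= 0 or not math.isfinite(temperature):
        raise ValueError("temperature must be finite and > 0")
    rt = CONSTANTS.gas_constant * temperature
    # difference of logs (not log of ratio) keeps swap-antisymmetry exact
    dg = rt * (math.log(k_stack.k_mean) - math.log(k_control.k_mean))
    rel = math.hypot(
        k_stack.k_sd / k_stack.k_mean, k_control.k_sd / k_control.k_mean
    )
    return StackingEnergy(
        dG=dg,
        dG_err=rt * rel,
        construct_pair=(k_stack.construct, k_control.construct),
        force=k_stack.force,
        temperature=temperature,
    )


@dataclass(frozen=True)
class ForceConsistencyTable:
    """Per-force stacking energies and their mutual +/-1-sigma overlap."""

    entries: list[StackingEnergy]
    consistent: bool
    flagged_pairs: list[tuple[float, float]]


def delta_g_by_force(
    stack_estimates: list[OffRateEstimate],
    control_estimates: list[OffRateEstimate],
    temperature: float,
) -> ForceConsistencyTable:
    """Stacking energy at every force common to both constructs.

    dG should be force-independent when the two constructs share a
    transition state; any pair of forces whose dG +/- err intervals fail to
    overlap is flagged.
    """
    stack_by_f = {round(e.force, 6): e for e in stack_estimates}
    ctrl_by_f = {round(e.force, 6): e for e in control_estimates}
    common = sorted(set(stack_by_f) & set(ctrl_by_f))
    if not common:
        raise ValueError("no common forces between the two constructs")
    entries = [
        delta_g_stack(stack_by_f[f], ctrl_by_f[f], temperature) for f in common
    ]
    flagged = []
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            a, b = entries[i], entries[j]
            if a.dG + a.dG_err < b.dG - b.dG_err or b.dG + b.dG_err < a.dG - a.dG_err:
                flagged.append((a.force, b.force))
    return ForceConsistencyTable(
        entries=entries, consistent=not flagged, flagged_pairs=flagged
    )
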
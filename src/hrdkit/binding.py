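"""1:1 protein–metal binding from dose–response series.

Models the generic microscale-thermophoresis-style experiment: a
two-fold ligand dilution series (plus a no-ligand control) is mixed 1:1
with protein, and a signal (arbitrary units) is read per well.  The
signal is modeled as

    signal(L) = s_unbound + (s_bound − s_unbound) · f_bound(P, L, Kd)

where ``f_bound`` is the exact 1:1 mass-action fraction of protein
bound, solved from the binding quadratic rather than the hyperbolic
approximation L/(Kd+L): at the tens-of-micromolar protein
concentrations typical of these assays, protein depletion is not
negligible against Kd values of the same order.

The fit is ordinary least squares over (log Kd, s_unbound, s_bound);
the log parameterization enforces Kd > 0 and the optimizer starts at
the geometric mean of the nonzero concentrations, a deterministic and
scale-appropriate initial guess.  The Kd standard error comes from the
Jacobian at the optimum via the delta method.  Series whose fitted
amplitude does not exceed a configurable multiple (default 3×) of the
residual standard deviation are reported categorically as "no
binding", mirroring how flat dose–response curves are reported in
practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


class FitError(RuntimeError):
    """Raised when the isotherm fit fails to converge."""


@dataclass(frozen=True)
class DoseResponseSeries:
    """One titration: ligand concentrations (M, after mixing) and signals."""

    ligand_concentrations: tuple[float, ...]
    signals: tuple[float, ...]
    protein_concentration: float  # M, after mixing
    metal: str | None = None
    buffer: str | None = None

    def __post_init__(self) -> None:
        conc = self.ligand_concentrations
        if len(conc) != len(self.signals):
            raise ValueError("concentrations and signals differ in length")
        if any(c < 0 for c in conc):
            raise ValueError("concentrations must be non-negative")
        nonzero = conc[:-1] if conc and conc[-1] == 0 else conc
        if any(b >= a for a, b in zip(nonzero, nonzero[1:])):
            raise ValueError(
                "concentrations must be strictly decreasing "
                "(apart from a final no-ligand control)"
            )


@dataclass(frozen=True)
class BindingFit:
    """Result of a 1:1 isotherm fit.

    For a "no binding" outcome ``no_binding`` is True and the Kd fields
    are NaN; the endpoint and residual fields still describe the
    degenerate fit.
    """

    kd: float  # M
    signal_unbound: float
    signal_bound: float
    residual_norm: float
    kd_standard_error: float  # M
    no_binding: bool = False


def design_dilution_series(
    top: float, steps: int = 15, mix_ratio: float = 0.5
) -> list[float]:
    """Two-fold dilution series plus a final no-ligand control.

    ``top`` is the pre-mix top concentration; each of the ``steps``
    points halves the previous one and all are scaled by ``mix_ratio``
    (0.5 for the usual 1:1 mix with protein).  A trailing 0 is the
    control.  The default design is the fifteen-step series from a
    20 mM top used in the metal-binding assays.
    """
    if top <= 0:
        raise ValueError("top concentration must be positive")
    if steps < 1:
        raise ValueError("steps must be at least 1")
    series = [top * mix_ratio / (2 ** i) for i in range(steps)]
    series.append(0.0)
    return series


def fraction_bound(p: float, l: float, kd: float) -> float:
    """Fraction of protein bound under exact 1:1 mass action.

    Solves the binding quadratic for the complex concentration with
    protein depletion accounted for:

        f = ((p + l + kd) − sqrt((p + l + kd)² − 4·p·l)) / (2·p)

    Always in [0, 1].
    """
    if p <= 0:
        raise ValueError("protein concentration must be positive")
    if l < 0:
        raise ValueError("ligand concentration must be non-negative")
    if kd <= 0:
        raise ValueError("kd must be positive")
    s = p + l + kd
    disc = s * s - 4.0 * p * l
    f = (s - math.sqrt(max(disc, 0.0))) / (2.0 * p)
    return min(max(f, 0.0), 1.0)


def _model(log_kd: float, s_u: float, s_b: float, p: float,
           conc: np.ndarray) -> np.ndarray:
    kd = math.exp(log_kd)
    f = np.array([fraction_bound(p, c, kd) for c in conc])
    return s_u + (s_b - s_u) * f


def fit_binding(
    series: DoseResponseSeries,
    no_binding_threshold: float = 3.0,
) -> BindingFit:
    """Least-squares fit of the 1:1 isotherm to a dose–response series.

    Requires at least four points.  Returns a "no binding" result when
    the fitted amplitude |s_bound − s_unbound| does not exceed
    ``no_binding_threshold`` times the residual standard deviation.
    Raises :class:`FitError` on non-convergence.
    """
    conc = np.asarray(series.ligand_concentrations, dtype=float)
    sig = np.asarray(series.signals, dtype=float)
    p = series.protein_concentration
    if conc.size < 4:
        raise ValueError("need at least 4 points to fit")

    nonzero = conc[conc > 0]
    log_kd0 = float(np.mean(np.log(nonzero)))
    s_u0 = float(sig[np.argmin(conc)])
    s_b0 = float(sig[np.argmax(conc)])
    if s_u0 == s_b0:
        s_b0 = s_u0 + 1e-6 * (abs(s_u0) + 1.0)  # avoid a degenerate start

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _model(theta[0], theta[1], theta[2], p, conc) - sig

    result = least_squares(
        residuals, x0=np.array([log_kd0, s_u0, s_b0]), method="lm"
    )
    if not result.success:
        raise FitError(
            f"isotherm fit did not converge: {result.message} "
            f"(status {result.status}, cost {result.cost:.3g})"
        )

    log_kd, s_u, s_b = result.x
    kd = math.exp(log_kd)
    resid = result.fun
    dof = max(conc.size - 3, 1)
    resid_sd = float(np.sqrt(resid @ resid / dof))
    amplitude = abs(s_b - s_u)

    # covariance of (log_kd, s_u, s_b) from the Jacobian at the optimum
    jac = result.jac
    try:
        cov = np.linalg.inv(jac.T @ jac) * resid_sd ** 2
        se_log_kd = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se_log_kd = float("inf")
    kd_se = kd * se_log_kd  # delta method for the log parameterization

    # absolute floor makes the rule well defined for noiseless flat series
    # (resid_sd = 0); scales with the signals, so the classification is
    # unchanged when all signals are multiplied by a constant
    amp_floor = 1e-8 * (float(np.max(np.abs(sig))) + 1e-300)
    if amplitude <= no_binding_threshold * resid_sd + amp_floor:
        return BindingFit(
            kd=float("nan"),
            signal_unbound=s_u,
            signal_bound=s_b,
            residual_norm=float(np.linalg.norm(resid)),
            kd_standard_error=float("nan"),
            no_binding=True,
        )
    return BindingFit(
        kd=kd,
        signal_unbound=s_u,
        signal_bound=s_b,
        residual_norm=float(np.linalg.norm(resid)),
        kd_standard_error=kd_se,
        no_binding=False,
    )
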
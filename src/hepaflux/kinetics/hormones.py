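"""Glucose-coupled hormone and NEFA transfer functions.

Plasma glucose, insulin, glucagon and non-esterified fatty acids (NEFA) are
not independent: pancreatic hormone release and adipose lipolysis respond to
glycemia.  The engine therefore derives the whole regulatory state of the
liver from a single driving variable, the plasma glucose concentration:

* insulin rises sigmoidally with glucose,
* glucagon falls sigmoidally with glucose,
* NEFA falls with glucose and is calibrated so that the fasted state
  (3 mM glucose) carries 1.0 mM NEFA and the fed state (12 mM glucose)
  carries 0.2 mM NEFA,
* the phosphorylated fraction ``gamma`` of interconvertible enzymes is a
  sigmoid of the glucagon share of total hormone signal (high when fasted,
  low when fed).

All outputs are dimensionless relative hormone levels in [0, 1] except NEFA,
which is a plasma concentration in mM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HormoneState",
    "PhosphorylationState",
    "hormone_transfer",
    "phosphorylation_state",
    "GLUCOSE_RANGE",
]

#: Validity range of the transfer functions (mM plasma glucose).
GLUCOSE_RANGE = (2.0, 14.0)

# Sigmoid midpoints/steepness for the pancreatic responses.
_INS_K, _INS_N = 7.0, 4.0
_GCG_K, _GCG_N = 6.5, 4.0
# NEFA response shape; the two free amplitude coefficients are solved exactly
# from the fasted/fed anchors below.
_NEFA_K, _NEFA_N = 7.5, 4.0
_NEFA_ANCHORS = ((3.0, 1.0), (12.0, 0.2))  # (glucose mM, NEFA mM)
# Phosphorylation sigmoid on the glucagon share r = gcg / (gcg + ins).
_GAMMA_K, _GAMMA_N = 0.35, 3.0


@dataclass(frozen=True)
class HormoneState:
    """Relative insulin/glucagon levels and plasma NEFA at one glucose level."""

    insulin: float
    glucagon: float
    nefa: float


@dataclass(frozen=True)
class PhosphorylationState:
    """Shared phosphorylated fraction of interconvertible enzymes."""

    gamma: float


def _hill_up(x: float, k: float, n: float) -> float:
    xn = x**n
    return xn / (k**n + xn)


def _hill_down(x: float, k: float, n: float) -> float:
    kn = k**n
    return kn / (kn + x**n)


def _nefa_coefficients() -> tuple[float, float]:
    # Solve nefa(g) = c0 + c1 * hill_down(g) exactly at the two anchors.
    (g_lo, n_lo), (g_hi, n_hi) = _NEFA_ANCHORS
    s_lo = _hill_down(g_lo, _NEFA_K, _NEFA_N)
    s_hi = _hill_down(g_hi, _NEFA_K, _NEFA_N)
    c1 = (n_lo - n_hi) / (s_lo - s_hi)
    c0 = n_hi - c1 * s_hi
    return c0, c1


_NEFA_C0, _NEFA_C1 = _nefa_coefficients()


def hormone_transfer(glucose: float) -> HormoneState:
    """Map plasma glucose (mM) to the coupled hormone/NEFA state.

    Parameters
    ----------
    glucose
        Plasma glucose concentration in mM, within ``GLUCOSE_RANGE``.

    Returns
    -------
    HormoneState
        Relative insulin and glucagon in [0, 1] and NEFA in mM.  Anchored so
        that ``nefa == 1.0`` at 3 mM and ``nefa == 0.2`` at 12 mM glucose.
    """
    g = float(glucose)
    lo, hi = GLUCOSE_RANGE
    if not np.isfinite(g) or g < lo or g > hi:
        raise ValueError(
            f"plasma glucose {glucose!r} mM outside transfer-function range {GLUCOSE_RANGE}"
        )
    insulin = _hill_up(g, _INS_K, _INS_N)
    glucagon = _hill_down(g, _GCG_K, _GCG_N)
    nefa = _NEFA_C0 + _NEFA_C1 * _hill_down(g, _NEFA_K, _NEFA_N)
    return HormoneState(insulin=insulin, glucagon=glucagon, nefa=nefa)


def phosphorylation_state(hormones: HormoneState) -> PhosphorylationState:
    """Translate the hormone state into the phosphorylated enzyme fraction.

    ``gamma`` is a sigmoid of the glucagon share ``r = glucagon / (glucagon +
    insulin)``; it is strictly increasing in glucagon and strictly decreasing
    in insulin, close to 1 in the severely fasted state and close to 0 in the
    well-fed state, but never exactly 0 or 1.
    """
    ins = float(hormones.insulin)
    gcg = float(hormones.glucagon)
    if ins < 0 or gcg < 0:
        raise ValueError("hormone levels must be non-negative")
    r = gcg / (gcg + ins) if (gcg + ins) > 0 else 0.5
    gamma = _hill_up(r, _GAMMA_K, _GAMMA_N)
    return PhosphorylationState(gamma=float(gamma))


def gamma_at_glucose(glucose: float) -> float:
    """Convenience composition: phosphorylated fraction at a glucose level."""
    return phosphorylation_state(hormone_transfer(glucose)).gamma
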
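"""Reduced-form enzymatic rate laws.

Four rate-law kinds cover the lumped network:

``irreversible_mm``
    v = vmax * prod_s S_s / (Km_s + S_s) over all substrates.
``reversible_mm``
    v = vmax * (S - P/Keq) / Kms / (1 + S/Kms + P/Kmp)  (single
    substrate/product pair, Haldane-consistent: zero exactly at
    thermodynamic equilibrium P = Keq * S).
``ghk_transport``
    Goldman-Hodgkin-Katz electrodiffusion flux with a fixed reduced membrane
    potential u:  v = vmax * z * u * (S - P * exp(-u)) / (1 - exp(-u)).
    In the limit u -> 0 this tends to vmax * z * (S - P).
``hill_modulated``
    An irreversible MM core whose modulators do the work; kept as an alias of
    ``irreversible_mm`` since every rate may carry Hill modulators.

Every rate is proportional to its vmax, so uniformly scaling all maximal
activities leaves the steady-state concentrations unchanged and scales every
flux by the same factor (flux homogeneity).

Hill modulators multiply the core rate:
activation  X^n / (K^n + X^n);  inhibition  K^n / (K^n + X^n).

Phosphorylation sensitivity interpolates between the fully phosphorylated and
fully dephosphorylated enzyme forms with the shared fraction ``gamma``; the
inactive form is assigned zero activity, so the multiplier is ``gamma`` for
``active_when_phospho`` enzymes and ``1 - gamma`` for
``active_when_dephospho`` enzymes.
"""

from __future__ import annotations

import math
from typing import Mapping

__all__ = ["evaluate_rate", "RATE_LAW_KINDS", "PHOSPHO_KINDS"]

RATE_LAW_KINDS = ("irreversible_mm", "reversible_mm", "hill_modulated", "ghk_transport")
PHOSPHO_KINDS = ("none", "active_when_phospho", "active_when_dephospho")


def _modulator_factor(reaction, conc: Mapping[str, float]) -> float:
    f = 1.0
    for mod in reaction.modulators:
        x = conc[mod.metabolite]
        if x < 0:
            raise ValueError(f"negative concentration for modulator {mod.metabolite}")
        xn = x**mod.n
        kn = mod.k**mod.n
        f *= xn / (kn + xn) if mod.kind == "activation" else kn / (kn + xn)
    return f


def _phospho_factor(reaction, gamma: float) -> float:
    if reaction.phospho == "none":
        return 1.0
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma {gamma} outside [0, 1]")
    active = gamma if reaction.phospho == "active_when_phospho" else 1.0 - gamma
    # Optional residual activity of the inactive phosphoform (e.g. pyruvate
    # kinase retains flux under feed-forward activation even when
    # phosphorylated); v = active_fraction + residual * inactive_fraction.
    residual = reaction.params.get("residual", 0.0)
    return active + residual * (1.0 - active)


def evaluate_rate(reaction, concentrations: Mapping[str, float], vmax: float, gamma: float) -> float:
    """Evaluate one reaction's flux (µmol·h⁻¹·g⁻¹) at given concentrations.

    Parameters
    ----------
    reaction
        A :class:`~hepaflux.kinetics.model.Reaction`.
    concentrations
        Metabolite id -> concentration (mM; stores in µmol/g).  Must cover
        every species the rate law and its modulators reference.
    vmax
        Maximal activity (µmol·h⁻¹·g⁻¹) for this reaction instance.
    gamma
        Shared phosphorylated fraction in [0, 1].
    """
    for met in reaction.rate_species():
        if concentrations[met] < 0:
            raise ValueError(f"negative concentration for {met}")

    kind = reaction.rate_law
    p = reaction.params
    if kind in ("irreversible_mm", "hill_modulated"):
        core = 1.0
        for met, km in reaction.substrate_kms():
            s = concentrations[met]
            core *= s / (km + s)
    elif kind == "reversible_mm":
        s = concentrations[reaction.substrate]
        pr = concentrations[reaction.product]
        kms, kmp, keq = p["km_s"], p["km_p"], p["keq"]
        # Haldane-consistent drive: zero exactly at equilibrium P = Keq * S.
        core = (s - pr / keq) / kms / (1.0 + s / kms + pr / kmp)
    elif kind == "ghk_transport":
        s = concentrations[reaction.substrate]
        pr = concentrations[reaction.product]
        u = p.get("u", 5.0)
        z = p.get("z", 1.0)
        if abs(u) < 1e-12:
            core = z * (s - pr)
        else:
            core = z * u * (s - pr * math.exp(-u)) / (1.0 - math.exp(-u))
    else:  # pragma: no cover - guarded at model validation
        raise ValueError(f"unknown rate-law kind {kind!r}")

    return vmax * core * _modulator_factor(reaction, concentrations) * _phospho_factor(reaction, gamma)
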
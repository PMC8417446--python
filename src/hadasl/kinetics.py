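"""Forward ASL signal models (general kinetic model).

The general kinetic model (GKM) describes the ASL difference signal as a
plug-flow bolus of labeled blood water that arrives at a voxel after the
arterial transit time ``att``, accrues while the bolus flows in, and decays
with the apparent tissue T1 afterwards.  Two labeling geometries are covered:

* pCASL sub-boli: label created at the labeling plane over a block of
  duration ``tau``; every labeled spin spends ``att`` in transit, decaying
  with the blood T1, then relaxes with the apparent tissue T1 (``t1_tissue``).
* PASL (FAIR) with a fixed bolus length: all label created at the inversion
  (t = 0), decaying with blood T1 until arrival.

CBF is expressed in ml/100 g/min at every interface and converted to ml/g/s
internally.  All functions broadcast over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PerfusionState",
    "AcquisitionModel",
    "gkm_pcasl_signal",
    "gkm_pasl_signal",
    "subbolus_signals",
]

#: ml/100 g/min -> ml/g/s
CBF_UNIT = 1.0 / 6000.0


@dataclass(frozen=True)
class PerfusionState:
    """Voxel hemodynamics: CBF ``f`` (ml/100 g/min), transit time ``att`` (s)."""

    f: float
    att: float

    def __post_init__(self):
        if np.any(np.asarray(self.f) < 0):
            raise ValueError("f must be >= 0")
        if np.any(np.asarray(self.att) <= 0):
            raise ValueError("att must be > 0")


@dataclass(frozen=True)
class AcquisitionModel:
    """Fixed physical parameters of the acquisition.

    Parameters
    ----------
    t1_blood : float
        Longitudinal relaxation time of arterial blood (s).
    t1_tissue : float
        Apparent tissue T1 governing post-arrival decay (s).  Treated as a
        fixed constant, not flow-dependent.
    lambda_partition : float
        Blood-tissue water partition coefficient (ml/g).
    alpha : float
        Labeling efficiency.
    m0_arterial : float
        Equilibrium magnetization of arterial blood, in signal units.
    """

    t1_blood: float = 1.65
    t1_tissue: float = 1.3
    lambda_partition: float = 0.9
    alpha: float = 0.85
    m0_arterial: float = 1.0

    def __post_init__(self):
        if self.t1_blood <= 0 or self.t1_tissue <= 0:
            raise ValueError("time constants must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.lambda_partition < 2:
            raise ValueError("lambda_partition must be in (0, 2)")


def gkm_pcasl_signal(t, tau, f, att, model: AcquisitionModel):
    """GKM difference signal for a pCASL sub-bolus of duration ``tau``.

    ``t`` is time since that sub-bolus's label onset.  Piecewise:
    zero before arrival; inflow saturation
    ``2 M0a f alpha T1t exp(-att/T1b) (1 - exp(-(t-att)/T1t))`` during the
    bolus; exponential tissue decay afterwards.  Continuous in ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if np.any(np.asarray(tau) <= 0):
        raise ValueError("tau must be > 0")
    f = np.asarray(f, dtype=float)
    att = np.asarray(att, dtype=float)
    t1b, t1t = model.t1_blood, model.t1_tissue
    amp = 2.0 * model.m0_arterial * f * CBF_UNIT * model.alpha * t1t \
        * np.exp(-att / t1b)
    # time since arrival, clipped to the bolus passage [0, tau]
    since_arrival = np.clip(t - att, 0.0, None)
    inflow = -np.expm1(-np.minimum(since_arrival, tau) / t1t)
    decay = np.exp(-np.clip(since_arrival - tau, 0.0, None) / t1t)
    return amp * inflow * decay


def gkm_pasl_signal(ti, f, att, bolus_length, model: AcquisitionModel):
    """GKM difference signal for pulsed ASL with a fixed bolus length.

    All label is created at inversion (t = 0) and decays with blood T1 until
    it arrives (between ``att`` and ``att + bolus_length``, Q2TIPS-truncated),
    then with the apparent tissue T1.  For ``t1_tissue == t1_blood`` this
    collapses to ``2 M0a f alpha exp(-ti/T1b) * min(ti - att, BL)``.
    """
    ti = np.asarray(ti, dtype=float)
    if np.any(ti < 0):
        raise ValueError("ti must be >= 0")
    if np.any(np.asarray(bolus_length) <= 0):
        raise ValueError("bolus_length must be > 0")
    f = np.asarray(f, dtype=float)
    att = np.asarray(att, dtype=float)
    t1b, t1t = model.t1_blood, model.t1_tissue
    amp = 2.0 * model.m0_arterial * f * CBF_UNIT * model.alpha
    # integral over arrival times s in [att, min(ti, att+BL)] of
    #   exp(-s/T1b) exp(-(ti-s)/T1t)
    upper = np.minimum(ti, att + bolus_length)
    width = np.clip(upper - att, 0.0, None)
    k = 1.0 / t1t - 1.0 / t1b
    if abs(k) < 1e-12:
        integral = np.exp(-ti / t1b) * width
    else:
        # exp(-ti/T1t) * (exp(k*upper) - exp(k*att)) / k, written via expm1
        # so the k -> 0 limit stays well conditioned
        integral = np.exp(-ti / t1t) * np.exp(k * att) * np.expm1(k * width) / k
    return amp * np.where(ti > att, integral, 0.0)


def subbolus_signals(scheme, f, att, model: AcquisitionModel) -> np.ndarray:
    """Decoded difference signal per sub-bolus, in play order.

    Sub-bolus ``i`` is read out ``tau_i + PLD_i(effective)`` after its own
    label onset, so its decoded perfusion-weighted value is the pCASL GKM
    evaluated at that time with bolus duration ``tau_i``.

    ``f`` and ``att`` may be scalars or arrays of voxels; the sub-bolus axis
    is appended last.
    """
    tau = np.asarray(scheme.block_durations, dtype=float)
    t = tau + scheme.effective_plds
    f = np.asarray(f, dtype=float)[..., None]
    att = np.asarray(att, dtype=float)[..., None]
    out = gkm_pcasl_signal(t, tau, f, att, model)
    return out
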
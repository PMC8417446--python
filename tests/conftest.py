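"""Shared fixtures: reference scheme, kinetic model, small phantom."""

import numpy as np
import pytest

from hadasl.cohort import generate_phantom
from hadasl.kinetics import AcquisitionModel
from hadasl.scheme import EncodingScheme

#: printed reference timing, ms
REFERENCE_DURATIONS_MS = (1175, 683, 482, 374, 305, 257, 224)
REFERENCE_EFFECTIVE_PLDS_MS = (2825, 2142, 1660, 1286, 981, 724, 500)


@pytest.fixture(scope="session")
def scheme():
    return EncodingScheme.reference_seven_block()


@pytest.fixture(scope="session")
def model():
    return AcquisitionModel()


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(dims=(24, 24, 12), seed=11)


@pytest.fixture(scope="session")
def phantom_default():
    return generate_phantom(seed=1)


def gkm_quadrature_oracle(t, tau, f, att, model):
    """Independent delivery-decay integral for the pCASL difference signal.

    Numeric quadrature of label delivered between arrival and bolus end,
    each increment decaying with the apparent tissue T1 until readout.
    """
    from scipy.integrate import quad

    if t <= att:
        return 0.0
    upper = min(t, att + tau)
    val, _ = quad(
        lambda s: np.exp(-(t - s) / model.t1_tissue), att, upper,
        epsabs=1e-14, epsrel=1e-12,
    )
    return (2.0 * model.m0_arterial * (f / 6000.0) * model.alpha
            * np.exp(-att / model.t1_blood) * val)


def pasl_quadrature_oracle(ti, f, att, bolus_length, model):
    """Pulsed-label analog: label decays with blood T1 until its arrival."""
    from scipy.integrate import quad

    if ti <= att:
        return 0.0
    upper = min(ti, att + bolus_length)
    val, _ = quad(
        lambda s: np.exp(-s / model.t1_blood)
        * np.exp(-(ti - s) / model.t1_tissue),
        att, upper, epsabs=1e-14, epsrel=1e-12,
    )
    return 2.0 * model.m0_arterial * (f / 6000.0) * model.alpha * val
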
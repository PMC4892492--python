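"""Kinetic models of the multiphase inter-slice-labeled difference signal.

In the ALADDIN scheme every slice's RF train labels arterial blood flowing
toward subsequent slices, so the arterial input to a voxel is a constant
delivery 2 alpha M0 F exp(-ATT/T1b) that ends at t = ATT (t = 0 is the start
of the slice's own acquisition).  Labeled signal is removed by three
mechanisms: washout from the arterial compartment (exponential residue
function with transit time delta), T1 recovery, and — once the readout is
running — the bSSFP pulse train, which drives labeled and unlabeled blood to
a common steady state with per-TR decay factor rho.

Two model variants are provided:

* :func:`t1_model` — RF perturbation ignored; decay is T1 and washout only.
* :func:`bssfp_model` — in-slice decay follows the continuous bSSFP
  envelope rho^(t/TR).  The default "physical" reading applies T1 decay
  only to label accumulated before the acquisition starts; behind
  ``literal_mode=True`` the convolution is evaluated exactly as written,
  with T1 decay continuing alongside the RF-driven decay after t = 0 (the
  two readings differ and are deliberately not merged; only the physical
  one reduces to the T1 model as FA -> 0).

Fitting either model to a nine-phase curve yields (F, delta, ATT), and the
arterial cerebral blood volume follows as aCBV = F * delta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .signal_models import (
    ARTERY,
    CompartmentParams,
    SequenceParams,
    bssfp_decay_rate,
)

__all__ = [
    "KineticParams",
    "AcbvValue",
    "aif",
    "residue",
    "t1_model",
    "bssfp_model",
    "acbv_from_fit",
]

#: mL/100 mL/min -> volume fraction delivered per ms
_F_TO_PER_MS = 1.0 / 100.0 / 60000.0


@dataclass(frozen=True)
class KineticParams:
    """Kinetic unknowns (F, delta, ATT) plus fixed labeling constants.

    F is the flow parameter in mL of blood per minute per 100 mL of voxel
    volume; delta (ms) the transit time through the arterial compartment;
    ATT (ms) the travel time from the labeling plane to the imaging slice;
    alpha the labeling efficiency; label_duration (ms) the span of labeled
    delivery; t1_b (ms) the blood longitudinal relaxation time.
    """

    f: float
    delta: float
    att: float
    alpha: float = 1.0
    label_duration: float = 2000.0
    t1_b: float = 1664.0

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("F must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.att < 0:
            raise ValueError("ATT must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.label_duration <= 0:
            raise ValueError("label_duration must be > 0")
        if self.t1_b <= 0:
            raise ValueError("t1_b must be > 0")

    @property
    def acbv(self) -> float:
        """aCBV = F * delta, in mL/100 mL."""
        return self.f * self.delta / 60000.0

    def with_(self, **kwargs) -> "KineticParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class AcbvValue:
    """Arterial cerebral blood volume in mL per 100 mL of tissue."""

    acbv: float

    def __post_init__(self) -> None:
        if self.acbv < 0:
            raise ValueError("aCBV must be >= 0")


def aif(t, kp: KineticParams, m0_b: float = 1.0):
    """Arterial input function: labeled-spin concentration per ms.

    Constant 2 alpha M0 F exp(-ATT/T1b) on the delivery window
    [ATT - label_duration, ATT), zero elsewhere (all prior slices label
    continuously, so delivery is flat and simply stops once the last
    labeled blood has covered the gap).
    """
    t = np.asarray(t, dtype=float)
    amp = 2.0 * kp.alpha * m0_b * kp.f * _F_TO_PER_MS * math.exp(-kp.att / kp.t1_b)
    out = np.where((t < kp.att) & (t >= kp.att - kp.label_duration), amp, 0.0)
    return out if out.ndim else float(out)


def residue(t, delta: float):
    """Fraction of labeled blood still in the arterial compartment.

    First-order exponential, R(t) = exp(-t/delta) for t >= 0, 0 for t < 0.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, np.exp(-np.minimum(t, 700.0 * delta) / delta), 0.0)
    return out if out.ndim else float(out)


def t1_model(t, kp: KineticParams):
    """Normalized difference dS(t)/S0 with T1 decay and washout only.

    Piecewise: a plateau 2 alpha F' delta T1b/(T1b+delta) exp(-ATT/T1b) for
    0 <= t <= ATT, then the same value times
    exp(-(t-ATT)(T1b+delta)/(delta T1b)); continuous at t = ATT.  The
    delivery window is treated as semi-infinite (delta, T1b << label
    duration), so the truncation error is exp(-label_duration*(1/delta+1/T1b)).
    """
    t = np.asarray(t, dtype=float)
    k = 1.0 / kp.delta + 1.0 / kp.t1_b
    plateau = 2.0 * kp.alpha * kp.f * _F_TO_PER_MS / k * math.exp(-kp.att / kp.t1_b)
    out = np.where(
        t <= kp.att,
        plateau,
        plateau * np.exp(-np.clip((t - kp.att) * k, None, 700.0)),
    )
    out = np.where(t < kp.att - kp.label_duration, 0.0, out)
    return out if out.ndim else float(out)


def bssfp_model(
    t,
    kp: KineticParams,
    seq: SequenceParams,
    comp: CompartmentParams = ARTERY,
    literal_mode: bool = False,
):
    """Normalized difference dS(t)/S0 including the bSSFP RF perturbation.

    dS/S0 = 2 alpha F' exp(-ATT/T1b) [term1(t) + term2(t)], with the
    in-slice RF-driven decay modeled as the continuous envelope rho^(t/TR):

    * term1 — label that arrived before the acquisition started
      (T1-decayed until t = 0), washing out as exp(-t/delta) and decaying
      under the pulse train:  (delta T1b/(delta+T1b)) exp(-t/delta) rho^(t/TR).
      In ``literal_mode`` an extra exp(-t/T1b) is kept, exactly as the
      printed convolution reads.
    * term2 — label arriving during [0, ATT]: the closed-form convolution
      of the rectangular delivery with exp(-s/delta) rho^(s/TR); with
      k2 = 1/delta - ln(rho)/TR it is (1/k2)(1 - exp(-k2 t)) up to t = ATT
      and (1/k2)(exp(-k2 (t-ATT)) - exp(-k2 t)) afterwards.
    """
    t = np.asarray(t, dtype=float)
    rho = bssfp_decay_rate(seq, comp)
    if rho >= 1.0:
        raise ValueError(f"bSSFP decay factor rho={rho} must be < 1")
    log_rho_per_ms = math.log(rho) / seq.tr

    k1 = 1.0 / kp.delta - log_rho_per_ms
    if literal_mode:
        k1 = k1 + 1.0 / kp.t1_b
    pre_amp = kp.delta * kp.t1_b / (kp.delta + kp.t1_b)
    term1 = pre_amp * np.exp(-np.clip(k1 * t, None, 700.0))

    k2 = 1.0 / kp.delta - log_rho_per_ms
    k2t = np.clip(k2 * t, None, 700.0)
    term2 = np.where(
        t <= kp.att,
        (1.0 - np.exp(-k2t)) / k2,
        (np.exp(-np.clip(k2 * (t - kp.att), None, 700.0)) - np.exp(-k2t)) / k2,
    )
    amp = 2.0 * kp.alpha * kp.f * _F_TO_PER_MS * math.exp(-kp.att / kp.t1_b)
    out = amp * (term1 + term2)
    return out if out.ndim else float(out)


def acbv_from_fit(f: float, delta: float) -> AcbvValue:
    """aCBV = F * delta, with delta converted from ms to minutes.

    F in mL/100 mL/min and delta in ms give aCBV = F * delta / 60000 in
    mL per 100 mL of tissue.
    """
    if f < 0:
        raise ValueError("F must be >= 0")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    return AcbvValue(acbv=f * delta / 60000.0)
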
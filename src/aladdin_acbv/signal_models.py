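"""Balanced-SSFP signal primitives.

A balanced steady-state free precession (bSSFP) readout applies a long train
of alternating-sign RF pulses (flip angle ``FA``) every ``TR`` milliseconds.
On resonance, with an FA/2 catalyzation, the transverse magnetization sampled
once per TR decays mono-exponentially from ``M0*sin(FA/2)`` toward the bSSFP
steady state with a per-pulse decay factor

    rho = exp(-TR/T2) * sin^2(FA/2) + exp(-TR/T1) * cos^2(FA/2)

These three quantities (decay rate, steady state, transient response) are the
building blocks used by the kinetic models, the venous-labeling model, and
the Bloch simulator that cross-validates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SequenceParams",
    "CompartmentParams",
    "BssfpResponse",
    "ARTERY",
    "VEIN",
    "GM_TISSUE",
    "bssfp_decay_rate",
    "bssfp_steady_state",
    "bssfp_transient",
    "bssfp_response",
]


@dataclass(frozen=True)
class SequenceParams:
    """Timing and geometry of the multiphase ALADDIN bSSFP acquisition.

    Parameters
    ----------
    tr : float
        Repetition time in ms.
    fa : float
        Flip angle in degrees, in [0, 180].
    n_dummy : int
        Number of discarded startup excitations (linearly ramped flip
        angles, used as catalyzation).
    lines_per_segment : int
        Phase-encode lines acquired per k-space segment (= per temporal
        phase) in one measurement.
    n_segments : int
        Number of k-space segments, i.e. temporal phases.
    lines_per_kspace : int
        Total phase-encode lines per k-space (filled over several
        measurements); bookkeeping only.
    slice_thickness : float
        Slice thickness in mm.
    gap_percent : float
        Inter-slice gap as a percentage of the slice thickness.
    td : float
        Inter-slice time delay in ms.
    n_slices : int
        Number of slices in the stack.
    rf_phase_alternation : bool
        Alternating +/-FA pulse phases (assumed ideal, on-resonance).
    """

    tr: float = 4.15
    fa: float = 60.0
    n_dummy: int = 10
    lines_per_segment: int = 32
    n_segments: int = 9
    lines_per_kspace: int = 96
    slice_thickness: float = 8.0
    gap_percent: float = 450.0
    td: float = 0.0
    n_slices: int = 7
    rf_phase_alternation: bool = True

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not 0.0 <= self.fa <= 180.0:
            raise ValueError(f"fa must be in [0, 180] degrees, got {self.fa}")
        if self.n_dummy < 0:
            raise ValueError("n_dummy must be >= 0")
        if self.lines_per_segment <= 0 or self.n_segments <= 0:
            raise ValueError("segmentation counts must be positive")
        if self.gap_percent < 0:
            raise ValueError("gap_percent must be >= 0")
        if self.td < 0:
            raise ValueError("td must be >= 0")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")

    @property
    def lines_per_measurement(self) -> int:
        """Phase-encode lines per measurement (288 with the defaults)."""
        return self.lines_per_segment * self.n_segments

    @property
    def gap_mm(self) -> float:
        """Inter-slice gap in mm."""
        return self.slice_thickness * self.gap_percent / 100.0

    @property
    def fa_rad(self) -> float:
        return float(np.deg2rad(self.fa))

    def with_(self, **kwargs) -> "SequenceParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CompartmentParams:
    """Relaxation and geometry of one blood/tissue compartment.

    ``lambda_partition`` (brain-blood partition coefficient, mL/g) is only
    used when steady-state tissue magnetization is converted to inflowing
    venous blood magnetization.
    """

    role: str = "artery"  # one of {"artery", "vein", "tissue"}
    t1: float = 1664.0  # ms
    t2: float = 120.0  # ms
    m0: float = 1.0  # arbitrary units
    velocity: float = 0.0  # mm/s, 0 for tissue
    angle_phi: float = 0.0  # degrees from slice normal
    lambda_partition: float = 0.9  # mL/g

    def __post_init__(self) -> None:
        if self.role not in ("artery", "vein", "tissue"):
            raise ValueError(f"unknown compartment role {self.role!r}")
        if not self.t1 > self.t2 > 0:
            raise ValueError(
                f"need T1 > T2 > 0, got T1={self.t1}, T2={self.t2}"
            )
        if self.m0 < 0:
            raise ValueError("m0 must be >= 0")
        if self.velocity < 0:
            raise ValueError("velocity must be >= 0")
        if not 0.0 <= self.angle_phi < 90.0:
            raise ValueError("angle_phi must be in [0, 90) degrees")


#: Arterial blood at 3 T (T1 = 1664 ms, T2 = 120 ms).
ARTERY = CompartmentParams(role="artery", t1=1664.0, t2=120.0)
#: Venous blood at 3 T (T1 = 1584 ms, T2 = 54 ms), nominal SSS velocity 13 cm/s.
VEIN = CompartmentParams(role="vein", t1=1584.0, t2=54.0, velocity=130.0)
#: Gray-matter tissue at 3 T (T1 = 1331 ms, T2 = 80 ms).
GM_TISSUE = CompartmentParams(role="tissue", t1=1331.0, t2=80.0)


@dataclass(frozen=True)
class BssfpResponse:
    """Transient bSSFP response summary: M(n) = (M_init - M_ss) rho^n + M_ss."""

    rho: float
    m_ss: float
    m_init: float


def _e1_e2(seq: SequenceParams, comp: CompartmentParams) -> tuple[float, float]:
    return float(np.exp(-seq.tr / comp.t1)), float(np.exp(-seq.tr / comp.t2))


def bssfp_decay_rate(seq: SequenceParams, comp: CompartmentParams) -> float:
    """Per-TR decay factor of the transient bSSFP response.

    rho = E2 sin^2(FA/2) + E1 cos^2(FA/2) with E_i = exp(-TR/T_i); it lies
    strictly between E2 and E1 for 0 < FA < 180.
    """
    e1, e2 = _e1_e2(seq, comp)
    half = seq.fa_rad / 2.0
    return e2 * np.sin(half) ** 2 + e1 * np.cos(half) ** 2


def bssfp_steady_state(seq: SequenceParams, comp: CompartmentParams) -> float:
    """On-resonance bSSFP steady-state transverse magnetization.

    M_ss = M0 sin(FA) (1 - E1) / (1 - (E1 - E2) cos(FA) - E1 E2),
    sampled immediately after an RF pulse. This is the exact fixed point of
    the alternating-pulse Bloch recursion (see :mod:`aladdin_acbv.bloch_sim`).
    """
    e1, e2 = _e1_e2(seq, comp)
    fa = seq.fa_rad
    denom = 1.0 - (e1 - e2) * np.cos(fa) - e1 * e2
    if denom <= 0:  # cannot occur for valid E1, E2 < 1; numeric guard
        raise FloatingPointError("degenerate bSSFP steady-state denominator")
    return comp.m0 * np.sin(fa) * (1.0 - e1) / denom


def bssfp_transient(
    n, seq: SequenceParams, comp: CompartmentParams
):
    """Transverse magnetization after ``n`` pulses of the bSSFP train.

    M(n) = (M0 sin(FA/2) - M_ss) rho^n + M_ss.  ``n`` may be a float or an
    array; non-integer n evaluates the continuous decay envelope rho^(t/TR),
    which is how the kinetic models use it.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("pulse count n must be >= 0")
    resp = bssfp_response(seq, comp)
    out = (resp.m_init - resp.m_ss) * resp.rho**n + resp.m_ss
    return out if out.ndim else float(out)


def bssfp_response(seq: SequenceParams, comp: CompartmentParams) -> BssfpResponse:
    """Bundle (rho, M_ss, M_init) for the given sequence and compartment."""
    return BssfpResponse(
        rho=float(bssfp_decay_rate(seq, comp)),
        m_ss=float(bssfp_steady_state(seq, comp)),
        m_init=float(comp.m0 * np.sin(seq.fa_rad / 2.0)),
    )
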
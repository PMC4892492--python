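"""ALADDIN dataset combination, phase timing, and S0 estimation.

The ALADDIN acquisition interleaves ascending and descending slice orders
with both slice-select gradient polarities and both readout polarities,
giving 8 image types per slice.  Ascending/descending play the roles of
control/label on the arterial side; gradient-sign averaging cancels the MT
asymmetry and readout-polarity averaging cancels eddy-current offsets, so
the combined difference

    dS = ((Ds- + Ds+) - (As- + As+)) / 2

isolates the inter-slice blood-labeling signal.  Each of the nine temporal
phases is timestamped at the center line of its linearly-ordered k-space
segment, counted from the first dummy pulse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .signal_models import SequenceParams

__all__ = [
    "MultiphaseSignal",
    "AladdinDataset",
    "ORDERS",
    "SS_SIGNS",
    "RO_SIGNS",
    "phase_times",
    "combine_aladdin",
    "estimate_s0b",
]

ORDERS = ("ascending", "descending")
SS_SIGNS = ("+", "-")
RO_SIGNS = ("+", "-")


@dataclass
class MultiphaseSignal:
    """Nine (time, dS) samples plus the normalization reference S0."""

    times: np.ndarray  # ms, strictly increasing
    ds: np.ndarray  # signal difference per phase (raw or normalized)
    s0: float = 1.0
    all_noise: bool = False  # set when ATT fell beyond the window

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ds = np.asarray(self.ds, dtype=float)
        if self.times.shape != self.ds.shape:
            raise ValueError("times and ds must have matching length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("phase times must be strictly increasing")

    @property
    def normalized(self) -> np.ndarray:
        """dS / S0."""
        return self.ds / self.s0

    def to_csv(self, path) -> None:
        """Write the curve as CSV with columns t_ms, dS_over_S0."""
        import pandas as pd

        pd.DataFrame({"t_ms": self.times,
                      "dS_over_S0": self.normalized}).to_csv(path, index=False)


@dataclass
class AladdinDataset:
    """8-type multiphase image stack keyed by (order, ss_gradient, readout).

    ``images`` maps ``(order, ss, ro)`` — or ``(order, ss)`` when readout
    polarities were pre-averaged — to ``[phase, row, col]`` arrays.  All
    stacks must share one shape with ``seq.n_segments`` phases.
    """

    images: dict
    seq: SequenceParams = field(default_factory=SequenceParams)
    spacing: tuple = (1.72, 2.29, 8.0)  # mm, (row, col, slice)
    readout_averaged: bool = False

    def __post_init__(self) -> None:
        keys = set(self.images)
        if self.readout_averaged:
            expected = set(product(ORDERS, SS_SIGNS))
        else:
            expected = set(product(ORDERS, SS_SIGNS, RO_SIGNS))
        missing = expected - keys
        if missing:
            raise ValueError(
                "missing ALADDIN image types: "
                + ", ".join(map(str, sorted(missing)))
            )
        shapes = {np.asarray(v).shape for v in self.images.values()}
        if len(shapes) != 1:
            raise ValueError(f"image stacks have inconsistent shapes: {shapes}")
        (shape,) = shapes
        if shape[0] != self.seq.n_segments:
            raise ValueError(
                f"stacks have {shape[0]} phases but the sequence defines "
                f"{self.seq.n_segments} segments"
            )

    @property
    def shape(self) -> tuple:
        return next(iter(self.images.values())).shape

    def readout_mean(self, order: str, ss: str) -> np.ndarray:
        """Average the two readout polarities (eddy-current suppression)."""
        if self.readout_averaged:
            return np.asarray(self.images[(order, ss)], dtype=float)
        return 0.5 * (
            np.asarray(self.images[(order, ss, "+")], dtype=float)
            + np.asarray(self.images[(order, ss, "-")], dtype=float)
        )


def phase_times(seq: SequenceParams) -> np.ndarray:
    """Center-of-segment timestamps of the temporal phases, in ms.

    Phase p (1-based) is stamped at
    ``(n_dummy + (p-1)*lines_per_segment + lines_per_segment/2) * TR``
    measured from the first dummy pulse; with the defaults the nine phases
    run 107.9 -> 1170.3 ms in 132.8-ms steps.
    """
    p = np.arange(seq.n_segments)
    lines = seq.n_dummy + p * seq.lines_per_segment + seq.lines_per_segment / 2.0
    return lines * seq.tr


def combine_aladdin(ds: AladdinDataset, venous: bool = False) -> np.ndarray:
    """Label/control combination of the 8 (or pre-averaged 4) image types.

    Returns ``((Ds- + Ds+) - (As- + As+)) / 2`` per phase (readout
    polarities averaged pairwise first).  With ``venous=True`` the reversed
    difference ``As - Ds`` is returned, which highlights descending venous
    flow (e.g. the superior sagittal sinus).
    """
    asc = ds.readout_mean("ascending", "+") + ds.readout_mean("ascending", "-")
    desc = ds.readout_mean("descending", "+") + ds.readout_mean("descending", "-")
    diff = 0.5 * (desc - asc)
    return -diff if venous else diff


def estimate_s0b(
    ds: AladdinDataset, sss_roi: np.ndarray, phases: slice | None = None
) -> float:
    """Blood equilibrium signal S0 from the SSS ROI of ascending images.

    The baseline blood signal cannot be measured in small arteries, so it is
    replaced by the mean ascending-order signal in the superior sagittal
    sinus (venous flow opposes the ascending order, so these images carry no
    labeling).  Readout polarities and both gradient signs are averaged;
    ``phases`` selects which temporal phases enter the mean (default: all).
    """
    sss_roi = np.asarray(sss_roi, dtype=bool)
    if not sss_roi.any():
        raise ValueError("SSS ROI mask is empty")
    if sss_roi.shape != ds.shape[1:]:
        raise ValueError(
            f"mask shape {sss_roi.shape} does not match image plane {ds.shape[1:]}"
        )
    asc = 0.5 * (
        ds.readout_mean("ascending", "+") + ds.readout_mean("ascending", "-")
    )
    if phases is not None:
        asc = asc[phases]
    return float(asc[:, sss_roi].mean())
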
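"""Digital phantom generator for the full multiphase ALADDIN pipeline.

The phantom is a 2D head-like slice with a gray-matter ribbon, a
white-matter core, a few bright arterial voxels, a superior-sagittal-sinus
voxel cluster, and background.  Each perfused region carries known
(F, delta, ATT) kinetics; its descending-ascending difference curves follow
the bSSFP kinetic model, while the SSS cluster follows the venous labeling
model with the opposite direction convention.  The generator emits the full
8-type image stack (ascending/descending x slice-select gradient sign x
readout polarity) with optional MT-asymmetry and eddy-current confounds
(additive offsets flipping sign with gradient sign and readout polarity
respectively, which the combination scheme must cancel exactly) plus
Gaussian noise, together with the ground truth needed for round-trip tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .kinetic_models import KineticParams, bssfp_model
from .recon import AladdinDataset, MultiphaseSignal, phase_times
from .signal_models import ARTERY, CompartmentParams, SequenceParams
from .sss_model import make_sss_params, sss_difference

__all__ = ["PhantomSpec", "PhantomTruth", "default_region_masks",
           "make_phantom", "make_sss_curve"]


def default_region_masks(shape=(64, 64)) -> dict:
    """Disjoint region masks: GM ribbon, WM core, arteries, SSS, background."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = ny / 2.0 - 4.0, nx / 2.0
    r = np.hypot(yy - cy, xx - cx)
    head = r <= min(ny, nx) * 0.40
    gm = (r >= min(ny, nx) * 0.28) & head
    wm = r < min(ny, nx) * 0.28
    artery = np.zeros(shape, dtype=bool)
    for dy, dx in ((0, -6), (0, 6), (4, 0), (-3, -3)):
        artery[int(cy + dy), int(cx + dx)] = True
    wm &= ~artery
    gm &= ~artery
    sss = np.zeros(shape, dtype=bool)
    sy = int(cy + min(ny, nx) * 0.40) + 3
    sss[sy:sy + 2, int(cx) - 1:int(cx) + 1] = True
    background = ~(gm | wm | artery | sss)
    return {"gm": gm, "wm": wm, "artery": artery, "sss": sss,
            "background": background}


@dataclass
class PhantomSpec:
    """Phantom layout, per-region kinetics, confounds and noise.

    Default gray matter uses the measured GM means for the 450%-gap /
    0-ms-delay condition (F = 197 mL/100 mL/min, delta = 661 ms,
    ATT = 628 ms); arteries carry 3x the GM flow; white matter a weakly
    perfused compartment.  Baselines are arbitrary units (GM 1.0, WM 0.8,
    SSS 0.5).  ``mt_asymmetry_amplitude`` flips sign with the slice-select
    gradient, ``eddy_amplitude`` with the readout polarity; both are
    additive.  ``noise_snr`` is peak-signal SNR of the per-type images
    (``inf`` for noiseless).
    """

    shape: tuple = (64, 64)
    region_masks: dict | None = None
    kinetics: dict = field(default_factory=lambda: {
        "gm": KineticParams(f=197.0, delta=661.0, att=628.0, alpha=0.208),
        "wm": KineticParams(f=60.0, delta=500.0, att=900.0, alpha=0.208),
        "artery": KineticParams(f=591.0, delta=661.0, att=628.0, alpha=0.208),
    })
    baselines: dict = field(default_factory=lambda: {
        "gm": 1.0, "wm": 0.8, "artery": 1.0, "sss": 0.5, "background": 0.05})
    comp: CompartmentParams = ARTERY
    mt_asymmetry_amplitude: float = 0.0
    eddy_amplitude: float = 0.0
    noise_snr: float = float("inf")
    rng_seed: int = 0
    sss_velocity: float = 130.0  # mm/s

    def masks(self) -> dict:
        m = self.region_masks or default_region_masks(self.shape)
        overlap = sum(v.astype(int) for v in m.values())
        if (overlap > 1).any():
            raise ValueError("region masks must be disjoint")
        return m


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    f_map: np.ndarray
    delta_map: np.ndarray
    att_map: np.ndarray
    acbv_map: np.ndarray
    alpha: float
    s0_b: float
    noiseless_diff: np.ndarray  # [phase, row, col], arterial convention
    masks: dict


def make_phantom(
    spec: PhantomSpec, seq: SequenceParams
) -> tuple[AladdinDataset, PhantomTruth]:
    """Generate the 8-type multiphase dataset and its ground truth.

    Arterial blood flows with the ascending order, so ascending images are
    the labeled ones: perfused voxels lose S0_b * bssfp_model(t) relative
    to their baseline there, while descending images stay at baseline
    (control).  The SSS is the opposite: descending images are labeled and
    lose S0_b * sss_difference(t).  The combined descending-minus-ascending
    difference therefore equals the arterial model curve in perfused
    voxels and minus the venous curve in the SSS.  Confounds and noise are
    added per image type, so the combination step can be verified to
    cancel them.
    """
    masks = spec.masks()
    times = phase_times(seq)
    n_ph = len(times)
    shape = spec.shape
    rng = np.random.default_rng(spec.rng_seed)

    s0_b = spec.baselines["sss"]
    alpha = None

    f_map = np.zeros(shape)
    delta_map = np.full(shape, np.nan)
    att_map = np.full(shape, np.nan)
    label_asc = np.zeros((n_ph,) + shape)  # signal lost in ascending images
    label_desc = np.zeros((n_ph,) + shape)  # signal lost in descending images

    for region, kp in spec.kinetics.items():
        mask = masks[region]
        if not mask.any():
            continue
        if alpha is None:
            alpha = kp.alpha
        curve = s0_b * bssfp_model(times, kp, seq, spec.comp)
        label_asc[:, mask] = curve[:, None]
        f_map[mask] = kp.f
        delta_map[mask] = kp.delta
        att_map[mask] = kp.att

    # SSS: venous labeling affects the descending order (As - Ds > 0)
    sssp = make_sss_params(seq, velocity=spec.sss_velocity)
    sss_curve = s0_b * sss_difference(times + seq.td, sssp, seq)
    label_desc[:, masks["sss"]] = sss_curve[:, None]

    diff = label_asc - label_desc  # descending - ascending convention

    baseline = np.zeros(shape)
    for region, b in spec.baselines.items():
        baseline[masks[region]] = b

    images = {}
    noise_sd = 0.0
    if np.isfinite(spec.noise_snr):
        noise_sd = float(np.max(np.abs(diff)) / spec.noise_snr)
    for order, ss, ro in product(("ascending", "descending"), "+-", "+-"):
        lost = label_asc if order == "ascending" else label_desc
        img = baseline[None] - lost
        img = img + (1.0 if ss == "+" else -1.0) * spec.mt_asymmetry_amplitude
        img = img + (1.0 if ro == "+" else -1.0) * spec.eddy_amplitude
        if noise_sd:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        images[(order, ss, ro)] = img

    ds = AladdinDataset(images=images, seq=seq)
    truth = PhantomTruth(
        f_map=f_map, delta_map=delta_map, att_map=att_map,
        acbv_map=f_map * np.nan_to_num(delta_map) / 60000.0,
        alpha=alpha if alpha is not None else 0.0,
        s0_b=s0_b, noiseless_diff=diff, masks=masks,
    )
    return ds, truth


def make_sss_curve(spec: PhantomSpec, seq: SequenceParams) -> MultiphaseSignal:
    """Nine-phase normalized SSS difference curve for (FA, TD, gap) of ``seq``.

    The inter-slice delay TD shifts the time elapsed since labeling, so the
    curve is the SSS model evaluated at t + TD; with TD = 500 ms the
    vein-labeled bolus has cleared the gap before the first phase and only
    the tissue branch remains.
    """
    times = phase_times(seq)
    sssp = make_sss_params(seq, velocity=spec.sss_velocity)
    ds = sss_difference(times + seq.td, sssp, seq)
    return MultiphaseSignal(times=times, ds=ds, s0=1.0)
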
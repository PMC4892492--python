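"""File I/O: NIfTI volumes with JSON sidecars, CSV tables, atomic writes.

Datasets live in a directory of NIfTI-1 volumes, one per ALADDIN image
type, named ``{order}_{ssgrad}_{ro}.nii.gz`` (e.g. ``ascending_p_m.nii.gz``)
with a ``sequence.json`` sidecar holding the sequence parameters and phase
times.  Image stacks are stored as (row, col, 1, phase) 4D volumes so the
temporal phases map onto the NIfTI time axis.  All writes are atomic
(write to a temporary file in the target directory, then rename).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from contextlib import contextmanager
from itertools import product
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .recon import AladdinDataset, phase_times
from .signal_models import SequenceParams

__all__ = [
    "atomic_write_bytes",
    "write_json",
    "read_json",
    "save_nifti",
    "load_nifti",
    "save_dataset",
    "load_dataset",
    "provenance_record",
]

_SIGN = {"+": "p", "-": "m"}
_SIGN_BACK = {"p": "+", "m": "-"}


@contextmanager
def _atomic(path: Path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix="".join(path.suffixes))
    os.close(fd)
    try:
        yield Path(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def atomic_write_bytes(path, data: bytes) -> None:
    with _atomic(Path(path)) as tmp:
        tmp.write_bytes(data)


def write_json(path, obj) -> None:
    atomic_write_bytes(path, (json.dumps(obj, indent=2, sort_keys=True,
                                         default=_json_default) + "\n").encode())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def save_nifti(path, stack: np.ndarray, spacing=(1.72, 2.29, 8.0)) -> None:
    """Save a [phase, row, col] stack as a (row, col, 1, phase) NIfTI-1."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        data = stack[:, :, None]
    else:
        data = stack.transpose(1, 2, 0)[:, :, None, :]
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    with _atomic(Path(path)) as tmp:
        nib.save(img, str(tmp))


def load_nifti(path) -> np.ndarray:
    """Load a NIfTI written by :func:`save_nifti` back to [phase, row, col]."""
    data = np.asarray(nib.load(str(path)).dataobj)
    if data.ndim == 4:
        return data[:, :, 0, :].transpose(2, 0, 1)
    if data.ndim == 3 and data.shape[2] == 1:
        return data[:, :, 0]
    return data


def _type_filename(order: str, ss: str, ro: str) -> str:
    return f"{order}_{_SIGN[ss]}_{_SIGN[ro]}.nii.gz"


def save_dataset(ds: AladdinDataset, out_dir) -> None:
    """Write the 8-type dataset plus the sequence sidecar to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, stack in ds.images.items():
        if len(key) == 2:
            order, ss = key
            name = f"{order}_{_SIGN[ss]}.nii.gz"
        else:
            order, ss, ro = key
            name = _type_filename(order, ss, ro)
        save_nifti(out / name, np.asarray(stack), ds.spacing)
    sidecar = dataclasses.asdict(ds.seq)
    sidecar["phase_times_ms"] = phase_times(ds.seq).tolist()
    sidecar["spacing_mm"] = list(ds.spacing)
    sidecar["readout_averaged"] = ds.readout_averaged
    write_json(out / "sequence.json", sidecar)


def load_dataset(in_dir) -> AladdinDataset:
    """Load a dataset directory written by :func:`save_dataset`."""
    d = Path(in_dir)
    side = read_json(d / "sequence.json")
    readout_averaged = bool(side.pop("readout_averaged", False))
    spacing = tuple(side.pop("spacing_mm", (1.72, 2.29, 8.0)))
    side.pop("phase_times_ms", None)
    seq = SequenceParams(**side)
    images = {}
    if readout_averaged:
        for order, ss in product(("ascending", "descending"), "+-"):
            path = d / f"{order}_{_SIGN[ss]}.nii.gz"
            if not path.exists():
                raise FileNotFoundError(
                    f"missing image type ({order}, {ss}): {path.name}")
            images[(order, ss)] = load_nifti(path)
    else:
        for order, ss, ro in product(("ascending", "descending"), "+-", "+-"):
            path = d / _type_filename(order, ss, ro)
            if not path.exists():
                raise FileNotFoundError(
                    f"missing image type ({order}, {ss}, {ro}): {path.name}")
            images[(order, ss, ro)] = load_nifti(path)
    return AladdinDataset(images=images, seq=seq, spacing=spacing,
                          readout_averaged=readout_averaged)


def provenance_record(config_obj, seed) -> dict:
    """Machine-readable record sufficient to reproduce a run."""
    blob = json.dumps(config_obj, sort_keys=True, default=_json_default)
    return {
        "config": config_obj,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "rng_seed": seed,
        "package_version": __version__,
    }
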
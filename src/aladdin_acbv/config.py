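"""Run-configuration schema (pydantic) for the command-line interface.

A single YAML or JSON file configures a run; unknown keys are rejected so
typos fail loudly before any computation.  Each block mirrors one of the
library's parameter objects and converts to it via ``to_domain``-style
helpers.  CLI flags override config keys.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .bloch_sim import McGrid
from .fitting import FitConfig
from .kinetic_models import KineticParams
from .signal_models import CompartmentParams, SequenceParams
from .synthetic_data import PhantomSpec

__all__ = ["RunConfig", "load_config"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SequenceBlock(_Block):
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

    def to_domain(self) -> SequenceParams:
        return SequenceParams(**self.model_dump())


class CompartmentBlock(_Block):
    role: str = "artery"
    t1: float = 1664.0
    t2: float = 120.0
    m0: float = 1.0
    velocity: float = 0.0
    angle_phi: float = 0.0
    lambda_partition: float = 0.9

    def to_domain(self) -> CompartmentParams:
        return CompartmentParams(**self.model_dump())


class KineticBlock(_Block):
    f: float = 197.0
    delta: float = 661.0
    att: float = 628.0
    alpha: float = 0.208
    label_duration: float = 2000.0
    t1_b: float = 1664.0

    def to_domain(self) -> KineticParams:
        return KineticParams(**self.model_dump())


class FitBlock(_Block):
    model: str = "bssfp"
    f_bounds: tuple[float, float] = (0.0, 600.0)
    delta_bounds: tuple[float, float] = (50.0, 3000.0)
    att_bounds: tuple[float, float] = (0.0, 3000.0)
    starts: str = "grid3"
    alpha: float = 0.208
    s0_b: float = 1.0
    literal_mode: bool = False

    def to_domain(self) -> FitConfig:
        return FitConfig(**self.model_dump())


class McBlock(_Block):
    f_values: list[float] = [100.0, 150.0, 200.0, 250.0, 300.0]
    delta_values: list[float] = [200.0, 400.0, 600.0, 800.0, 1000.0]
    velocity_values: list[float] = [6.0, 9.0, 12.0, 15.0]
    phi_values: list[float] = [0.0, 20.0, 40.0, 60.0, 80.0]
    snr_values: list[float] = [5.0, 10.0, 15.0, 20.0]
    n_reps: int = 1000
    gap_mm: float = 30.0
    n_spins: int = 2000
    curve_source: str = "bloch"

    def to_domain(self, rng_seed: int) -> McGrid:
        d = self.model_dump()
        return McGrid(rng_seed=rng_seed, **{k: tuple(v) if isinstance(v, list)
                                            else v for k, v in d.items()})


class PhantomBlock(_Block):
    shape: tuple[int, int] = (64, 64)
    gm: KineticBlock = Field(default_factory=KineticBlock)
    wm: KineticBlock = Field(default_factory=lambda: KineticBlock(
        f=60.0, delta=500.0, att=900.0))
    artery: KineticBlock = Field(default_factory=lambda: KineticBlock(f=591.0))
    mt_asymmetry_amplitude: float = 0.0
    eddy_amplitude: float = 0.0
    noise_snr: float = float("inf")
    sss_velocity: float = 130.0

    def to_domain(self, rng_seed: int) -> PhantomSpec:
        return PhantomSpec(
            shape=tuple(self.shape),
            kinetics={"gm": self.gm.to_domain(), "wm": self.wm.to_domain(),
                      "artery": self.artery.to_domain()},
            mt_asymmetry_amplitude=self.mt_asymmetry_amplitude,
            eddy_amplitude=self.eddy_amplitude,
            noise_snr=self.noise_snr,
            rng_seed=rng_seed,
            sss_velocity=self.sss_velocity,
        )


class RunConfig(_Block):
    """Top-level run configuration; blocks are optional with full defaults."""

    rng_seed: int = 0
    log_level: str = "INFO"
    sequence: SequenceBlock = Field(default_factory=SequenceBlock)
    compartment: CompartmentBlock = Field(default_factory=CompartmentBlock)
    fit: FitBlock = Field(default_factory=FitBlock)
    montecarlo: McBlock = Field(default_factory=McBlock)
    phantom: PhantomBlock = Field(default_factory=PhantomBlock)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML/JSON config file; ``overrides`` win."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        node = data
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    return RunConfig.model_validate(data)
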
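"""Validated configuration models for the CLI and experiment runners."""

from __future__ import annotations

from pydantic import BaseModel, Field, field_validator

from imsde.experiments import (
    BLOOD_MEAN_VELOCITY,
    BLOOD_T1,
    BLOOD_T2,
    GEL_T2_VALUES,
    M1_GRID,
    SIN_MAX_AMPLITUDE,
    SLEW_MAX,
    TRAP_AMPLITUDE,
)


class HardwareConfig(BaseModel):
    max_grad_mT_per_m: float = Field(TRAP_AMPLITUDE, gt=0)
    sin_max_grad_mT_per_m: float = Field(SIN_MAX_AMPLITUDE, gt=0)
    ramp_ms: float = Field(0.5, ge=0)
    slew_mT_per_m_per_ms: float = Field(SLEW_MAX, gt=0)


class DesignConfig(BaseModel):
    target_m1: float = Field(..., ge=0)
    shape: str = "trapezoid"
    permutation: str = "NOCP"
    gap_ms: float = Field(0.1, ge=0)


class EddyConfig(BaseModel):
    amplitude: float = Field(0.005, ge=0)
    time_constant_ms: float = Field(1.0, gt=0)


class PhantomSweepConfig(BaseModel):
    t2_values: list[float] = list(GEL_T2_VALUES)
    m1_values: list[float] = list(M1_GRID)
    shapes: list[str] = ["trapezoid", "sinusoid"]
    permutation: str = "CP180"
    eddy: EddyConfig = EddyConfig()

    @field_validator("t2_values", "m1_values")
    @classmethod
    def _positive(cls, v):
        if any(x < 0 for x in v):
            raise ValueError("values must be >= 0")
        return v


class SuppressionConfig(BaseModel):
    m1_values: list[float] = list(M1_GRID)
    mean_velocity_m_per_s: float = BLOOD_MEAN_VELOCITY
    shape: str = "sinusoid"
    permutation: str = "CP180"
    blood_t1_ms: float = BLOOD_T1
    blood_t2_ms: float = BLOOD_T2
    n_radial: int = Field(201, ge=1)
    threshold: float = Field(0.05, gt=0)


class B1MapConfig(BaseModel):
    permutations: list[str] = ["NOCP", "CP90", "CP180", "CP180_90"]
    b1_min: float = Field(0.7, gt=0)
    b1_max: float = 1.3
    n_b1: int = Field(25, ge=1)
    t2_ms: float = Field(50.0, gt=0)
    m1: float = Field(487.0, ge=0)
    shape: str = "sinusoid"


class FixtureConfig(BaseModel):
    compartment_means: dict[str, float] = {}
    noise_sd: float = Field(10.0, ge=0)
    image_shape: tuple[int, int] = (128, 128)
    seed: int = 0


class SimulationConfig(BaseModel):
    """One config to drive all experiment runners."""

    hardware: HardwareConfig = HardwareConfig()
    phantom: PhantomSweepConfig = PhantomSweepConfig()
    suppression: SuppressionConfig = SuppressionConfig()
    b1_map: B1MapConfig = B1MapConfig()
    fixture: FixtureConfig = FixtureConfig()
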
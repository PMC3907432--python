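"""Run configuration: schema-validated parameter blocks.

Every field has a packaged default (the published parameter table or a
documented model choice); unknown keys are rejected.  Configs load from YAML
or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import constants
from .dynamics import ExcitationSpec, FeedingMode, FrequencyLaw
from .geometry import CellGeometry, RingSpec, SpindleParams
from .medium import MediumModel


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RingConfig(_Block):
    n_protofilaments: int = constants.N_PROTOFILAMENTS
    axial_shift_nm: float = constants.AXIAL_SHIFT_NM
    ring_diameter_nm: float = constants.RING_DIAMETER_NM
    leading_angle_deg: float = constants.LEADING_ANGLE_DEG
    heterodimer_length_nm: float = constants.HETERODIMER_LENGTH_NM
    outer_wall_radius_nm: float = constants.OUTER_WALL_RADIUS_NM
    spiral_phase0_rad: float = 0.0
    alpha_toward_minus: bool = True

    def to_spec(self) -> RingSpec:
        return RingSpec(self.n_protofilaments, self.axial_shift_nm,
                        self.ring_diameter_nm, self.leading_angle_deg,
                        self.heterodimer_length_nm, self.outer_wall_radius_nm,
                        self.spiral_phase0_rad, self.alpha_toward_minus)


class GeometryConfig(_Block):
    a_nm: float = constants.SEMI_MAJOR_NM
    b_nm: float = constants.SEMI_MINOR_NM
    R_equiv_nm: float = constants.EQUIV_RADIUS_NM
    c_nm: float = constants.MTOC_OFFSET_NM
    rho_nm: float = constants.MTOC_DIAMETER_NM
    scale: float = Field(1.0, gt=0, description="isotropic a, b, c, R scaling")
    ring: RingConfig = Field(default_factory=RingConfig)
    n_astral_per_mtoc: int = constants.N_ASTRAL_PER_MTOC
    n_kinetochore_per_mtoc: int = constants.N_KINETOCHORE_PER_MTOC
    n_polar_per_mtoc: int = constants.N_POLAR_PER_MTOC
    kappa_astral: int = constants.KAPPA_ASTRAL
    omega_astral_sr: float = constants.OMEGA_ASTRAL_SR
    kappa_kp: int = constants.KAPPA_KP
    omega_kp_sr: float = constants.OMEGA_KP_SR
    spread: float = constants.EQUATORIAL_SPREAD
    scenario: Literal["fixed", "free"] = "fixed"
    thomson_tol: float = 1e-9

    def to_params(self) -> SpindleParams:
        cell = CellGeometry(self.a_nm, self.b_nm, self.R_equiv_nm,
                            self.c_nm, self.rho_nm)
        if self.scale != 1.0:
            cell = cell.scaled(self.scale)
        return SpindleParams(
            cell=cell, ring_spec=self.ring.to_spec(),
            n_astral_per_mtoc=self.n_astral_per_mtoc,
            n_kinetochore_per_mtoc=self.n_kinetochore_per_mtoc,
            n_polar_per_mtoc=self.n_polar_per_mtoc,
            kappa_astral=self.kappa_astral, omega_astral=self.omega_astral_sr,
            kappa_kp=self.kappa_kp, omega_kp=self.omega_kp_sr,
            spread=self.spread, scenario=self.scenario,
            thomson_tol=self.thomson_tol)


class FrequencyConfig(_Block):
    k1_hz: float = constants.FREQ_K1_HZ
    k2_hz: float = constants.FREQ_K2_HZ
    lTH_nm: float = constants.HETERODIMER_LENGTH_NM
    bc_factor_fixed: float = constants.BC_FACTOR_FIXED
    bc_factor_free: float = constants.BC_FACTOR_FREE

    def to_law(self) -> FrequencyLaw:
        return FrequencyLaw(self.k1_hz, self.k2_hz, self.lTH_nm,
                            self.bc_factor_fixed, self.bc_factor_free)


class ExcitationConfig(_Block):
    mode: Literal["pulsed", "random"] = "pulsed"
    amplitude_nm: float = constants.ANTINODE_AMPLITUDE_NM
    Q: float = constants.Q_DEFAULT
    damped: bool = False
    seed: int = 0

    def to_spec(self) -> ExcitationSpec:
        return ExcitationSpec(FeedingMode(self.mode), self.amplitude_nm,
                              self.Q, self.damped, self.seed)


class MediumConfig(_Block):
    eps_static: float = constants.EPS_STATIC
    eps_inf: float = constants.EPS_INF
    tau_s: float = constants.DEBYE_TAU_S
    conductivity_s_m: float = constants.CONDUCTIVITY_S_M
    mu_r: float = constants.MU_R

    def to_model(self) -> MediumModel:
        return MediumModel(self.eps_static, self.eps_inf, self.tau_s,
                           self.conductivity_s_m, self.mu_r)


class GridConfig(_Block):
    kind: Literal["points", "plane", "volume"] = "plane"
    plane_axis: int = 0
    plane_offset_nm: float = 0.0
    plane_center_nm: tuple[float, float] = (0.0, 0.0)
    plane_half_span_nm: float = 500.0
    pitch_nm: float = constants.VOXEL_EDGE_NM
    volume_origin_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    volume_spans_nm: tuple[float, float, float] = (500.0, 500.0, 500.0)
    points_nm: list[tuple[float, float, float]] | None = None

    def to_grid(self):
        from . import field
        if self.kind == "plane":
            return field.plane_grid(self.plane_axis, self.plane_offset_nm,
                                    self.plane_center_nm,
                                    self.plane_half_span_nm, self.pitch_nm)
        if self.kind == "volume":
            return field.volume_grid(self.volume_origin_nm,
                                     self.volume_spans_nm, self.pitch_nm)
        if not self.points_nm:
            raise ValueError("points grid requires points_nm")
        return field.points_grid(self.points_nm)


class AnalysisConfig(_Block):
    Q: float = constants.Q_DEFAULT
    fmin_hz: float = 0.0
    fmax_hz: float = 25e9
    n_freq: int = 2000
    edge_threshold: float = 0.5
    normalization: Literal["peak", "area"] = "peak"
    n_realizations: int = constants.N_REALIZATIONS_DEFAULT
    n_samples: int = constants.N_SAMPLES_DEFAULT
    n_periods: int = constants.N_PERIODS_DEFAULT
    max_separation_nm: float = 500.0


class RunConfig(_Block):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    frequency_law: FrequencyConfig = Field(default_factory=FrequencyConfig)
    excitation: ExcitationConfig = Field(default_factory=ExcitationConfig)
    medium: MediumConfig = Field(default_factory=MediumConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    seed: int = 0
    output_dir: str = "."


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration (unknown keys rejected)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.model_validate(data or {})
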
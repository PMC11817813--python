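"""Typed, validated parameter model for vectorial PSF simulations.

Single source of truth for units and conventions:

* all lengths are stored in **nanometers**,
* all angles are stored in **radians**,
* beam waist, beam/mask offsets and the ring-mask radius are expressed as
  **fractions of the pupil radius**, so the physical front-pupil radius never
  needs calibration (only ratios enter the optics).

Values given as strings may carry an explicit unit suffix, e.g. ``"170um"``,
``"0.17mm"``, ``"640nm"`` for lengths and ``"1deg"`` / ``"0.02rad"`` for
angles; bare numbers are taken in the internal unit.
"""

from __future__ import annotations

import math
from typing import Annotated, Literal, Optional, Sequence, Union

import yaml
from pydantic import (
    BaseModel,
    BeforeValidator,
    ConfigDict,
    Field,
    field_validator,
    model_validator,
)

__all__ = [
    "OpticalSystem",
    "InputBeam",
    "Polarization",
    "PhaseMaskSpec",
    "SimulationGrid",
    "SimulationConfig",
    "ZernikeTerm",
    "validate",
    "load_config",
    "save_config",
]

_LENGTH_SUFFIXES = {"nm": 1.0, "um": 1e3, "µm": 1e3, "mm": 1e6, "m": 1e9}
_ANGLE_SUFFIXES = {"rad": 1.0, "deg": math.pi / 180.0}


def _parse_with_suffix(value, table, what):
    if isinstance(value, str):
        s = value.strip()
        for suffix in sorted(table, key=len, reverse=True):
            if s.endswith(suffix):
                return float(s[: -len(suffix)]) * table[suffix]
        try:
            return float(s)
        except ValueError:
            raise ValueError(f"cannot parse {what} value {value!r}") from None
    return value


def _parse_length(value):
    return _parse_with_suffix(value, _LENGTH_SUFFIXES, "length")


def _parse_angle(value):
    return _parse_with_suffix(value, _ANGLE_SUFFIXES, "angle")


Length = Annotated[float, BeforeValidator(_parse_length)]
Angle = Annotated[float, BeforeValidator(_parse_angle)]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class OpticalSystem(_Model):
    """Objective, immersion/coverslip/sample stack and in vivo geometry.

    The three-layer stack is immersion medium (index ``n1``), coverslip
    (``n2``, thickness ``thickness_t``) and sample (``n3``); the beam focuses
    a depth ``depth_d`` below the coverslip.  ``window_theta_c`` is the
    half-angle of the marginal ray transmitted by a cranial window (``None``
    means no window); ``tilt_gamma`` tilts the coverslip about the y axis
    (tilt plane x-z).
    """

    na: float = 1.0
    n1: float = 1.33
    n2: float = 1.33
    n3: float = 1.33
    thickness_t: Length = 1.7e5  # nm, standard #1.5 coverslip
    depth_d: Length = 0.0  # nm below the coverslip
    collar_depth: Union[Length, Literal["off"]] = "off"
    tilt_gamma: Angle = 0.0
    window_theta_c: Optional[Angle] = None  # None = no window
    pupil_radius_rpup: float = 1.0  # arbitrary unit; only ratios are used

    @property
    def alpha(self) -> float:
        """Marginal-ray half angle arcsin(NA / n1), radians."""
        return math.asin(self.na / self.n1)

    @property
    def collar_active(self) -> bool:
        return self.collar_depth != "off"

    @model_validator(mode="after")
    def _check(self) -> "OpticalSystem":
        if not (0.0 < self.na <= self.n1):
            raise ValueError("NA exceeds n1 (need 0 < NA <= n1 for a real aperture angle)")
        for name in ("n1", "n2", "n3"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")
        if self.thickness_t < 0:
            raise ValueError("thickness_t must be >= 0")
        if self.depth_d < 0:
            raise ValueError("depth_d must be >= 0")
        if abs(self.tilt_gamma) >= math.pi / 2 - self.alpha:
            raise ValueError("tilt_gamma too large: |gamma| must be < pi/2 - alpha")
        if self.window_theta_c is not None:
            hi = self.alpha + abs(self.tilt_gamma)
            if not (0.0 <= self.window_theta_c <= hi + 1e-12):
                raise ValueError("window_theta_c must lie in [0, alpha + |tilt_gamma|]")
        return self


class PhaseMaskSpec(_Model):
    """Beam-shaping phase mask imprinted on the input beam.

    ``vortex`` (0..2πq azimuthal ramp) produces a donut, ``ring`` (π-phase
    disk of radius ``ring_radius_rR``, odd charge) a bottle beam; ``mixed``
    combines both PSFs incoherently with donut weight ``mix_p``.
    """

    kind: Literal["none", "vortex", "ring", "mixed"] = "none"
    charge_q: int = 1
    ring_radius_rR: float = 0.55  # fraction of the pupil radius
    mask_offset: tuple[float, float] = (0.0, 0.0)  # fractions of pupil radius
    mix_p: float = 0.5

    @model_validator(mode="after")
    def _check(self) -> "PhaseMaskSpec":
        if self.kind in ("ring", "mixed"):
            if not (0.0 < self.ring_radius_rR <= 1.0):
                raise ValueError("ring_radius_rR must lie in (0, 1]")
            if self.charge_q % 2 == 0:
                raise ValueError("ring mask charge_q must be odd to form a bottle beam")
        if not (0.0 <= self.mix_p <= 1.0):
            raise ValueError("mix_p must lie in [0, 1]")
        return self


class Polarization(_Model):
    """Input polarization state.

    ``elliptical`` is parameterized by ellipticity ``epsilon`` (-pi/4 right
    circular, 0 linear, +pi/4 left circular) and orientation ``psi``
    (counter-clockwise rotation of the ellipse axes about the optical axis).
    """

    kind: Literal["elliptical", "radial", "azimuthal"] = "elliptical"
    epsilon: Angle = 0.0
    psi: Angle = 0.0

    @model_validator(mode="after")
    def _check(self) -> "Polarization":
        if not (-math.pi / 4 - 1e-12 <= self.epsilon <= math.pi / 4 + 1e-12):
            raise ValueError("epsilon must lie in [-pi/4, pi/4]")
        return self


class ZernikeTerm(_Model):
    """One Zernike aberration mode (n, m) with coefficient C in radians
    of phase at unit pupil radius (modes normalized to R_n^m(1) = 1)."""

    n: int
    m: int
    coeff: float

    @model_validator(mode="after")
    def _check(self) -> "ZernikeTerm":
        if self.n < 0 or abs(self.m) > self.n or (self.n - abs(self.m)) % 2 != 0:
            raise ValueError(
                f"invalid Zernike index (n={self.n}, m={self.m}): "
                "need n >= 0, |m| <= n, n - |m| even"
            )
        return self


def _coerce_zernike(value):
    if isinstance(value, Sequence):
        out = []
        for item in value:
            if isinstance(item, (tuple, list)) and len(item) == 3:
                out.append({"n": item[0], "m": item[1], "coeff": item[2]})
            else:
                out.append(item)
        return out
    return value


class InputBeam(_Model):
    """Laser beam incident on the back pupil of the objective."""

    wavelength: Length = 640.0  # vacuum wavelength, nm
    waist_w: float = 1.0  # Gaussian waist as fraction of pupil radius
    offset: tuple[float, float] = (0.0, 0.0)  # fractions of pupil radius
    polarization: Polarization = Field(default_factory=Polarization)
    zernike: Annotated[list[ZernikeTerm], BeforeValidator(_coerce_zernike)] = Field(
        default_factory=list
    )
    mask: PhaseMaskSpec = Field(default_factory=PhaseMaskSpec)

    @field_validator("wavelength", "waist_w")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0")
        return v


class SimulationGrid(_Model):
    """Voxel grid centered on the geometrical focus O plus angular sampling.

    Voxel (i, j, k) maps to ``x = (i - (nx-1)/2) dx`` etc.; extents are
    half-extents in nm, so the volume spans ``[-extent, +extent]`` per axis.
    Angular sampling uses ``n_theta`` x ``n_phi`` plane waves.
    """

    nx: int = 31
    ny: int = 31
    nz: int = 31
    extent_xy: Length = 1000.0  # nm half-extent (2x2 um field)
    extent_z: Length = 2000.0  # nm half-extent (2x4 um axial field)
    n_theta: int = 31
    n_phi: int = 31
    normalize: bool = True

    @field_validator("nx", "ny", "nz", "n_theta", "n_phi")
    @classmethod
    def _counts(cls, v, info):
        if v < 1:
            raise ValueError(f"{info.field_name} must be >= 1")
        return v

    @field_validator("extent_xy", "extent_z")
    @classmethod
    def _extents(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0")
        return v

    def axis(self, name: str):
        """Physical coordinates (nm) along one axis ('x', 'y' or 'z')."""
        import numpy as np

        n = {"x": self.nx, "y": self.ny, "z": self.nz}[name]
        extent = self.extent_z if name == "z" else self.extent_xy
        if n == 1:
            return np.zeros(1)
        step = 2.0 * extent / (n - 1)
        return (np.arange(n) - (n - 1) / 2.0) * step


class SimulationConfig(_Model):
    """Full parameter set for one PSF simulation."""

    system: OpticalSystem = Field(default_factory=OpticalSystem)
    beam: InputBeam = Field(default_factory=InputBeam)
    grid: SimulationGrid = Field(default_factory=SimulationGrid)
    # sqrt_cos is the standard aplanatic sine-condition apodization
    apodization: Literal["sqrt_cos", "cos"] = "sqrt_cos"
    # midpoint theta sampling by default: the polar integrand ends abruptly at
    # the aperture edge, so left-endpoint sampling (theta_1 = 0, available as
    # "left") effectively shrinks the aperture by half a step and converges
    # only first-order; midpoints remove that edge bias
    theta_sampling: Literal["left", "midpoint"] = "midpoint"
    # donut/bottle mixing convention: which beam the weight p multiplies
    p_convention: Literal["p_donut", "p_bottle"] = "p_donut"
    refocus: Literal["none", "axial_shift"] = "none"


def validate(raw) -> SimulationConfig:
    """Validate a raw parameter mapping (or config object) into a normalized
    :class:`SimulationConfig` with defaults filled, lengths in nm and angles
    in radians.

    Raises :class:`pydantic.ValidationError` naming the offending field(s)
    on any invariant violation.
    """
    if isinstance(raw, SimulationConfig):
        return SimulationConfig.model_validate(raw.model_dump())
    if raw is None:
        raw = {}
    return SimulationConfig.model_validate(raw)


def set_by_path(config: SimulationConfig, path: str, value) -> SimulationConfig:
    """Return a copy of *config* with the dotted-path key set, e.g.
    ``set_by_path(cfg, "system.na", 1.2)``.  The result is re-validated."""
    data = config.model_dump()
    parts = path.split(".")
    node = data
    for p in parts[:-1]:
        if p not in node:
            raise KeyError(f"unknown config section {p!r} in path {path!r}")
        node = node[p]
    if parts[-1] not in node:
        raise KeyError(f"unknown config key {path!r}")
    node[parts[-1]] = value
    return SimulationConfig.model_validate(data)


def load_config(path) -> SimulationConfig:
    """Load a YAML config file (one section per module, keys mirror the CLI)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return validate(data)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
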
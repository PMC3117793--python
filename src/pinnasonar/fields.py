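"""Synthetic directional gain fields: emission beams, ear sensitivities, AHRTFs.

The model needs, per frequency, an emission directivity and a hearing
directivity per ear on a common hemisphere partition.  This module generates
parametric stand-ins with the structural features the analysis exploits:
beams narrow as frequency rises (beamwidth proportional to wavelength over
aperture), the two ear axes are offset laterally and upward, ear gain is
capped, and the emission axis drifts to slightly higher elevations with
frequency.  A two-isotropic-source emitter (monopole pair at the nostril
spacing) serves as the morphology-free control.

Gains are in dB; emission fields are normalized so their linear power
integrates to 1 over the frontal hemisphere, which makes template gain
directly interpretable as (inverse) directivity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np

from .sphere import Direction, SpherePartition, angular_distance

__all__ = [
    "DirectionalField",
    "SyntheticHeadConfig",
    "wavelength_mm",
    "nodes_per_wavelength",
    "two_source_emission",
    "parametric_beam",
    "normalize_emission",
    "combine_ahrtf",
    "synthetic_head_fields",
]

FIELD_ROLES = ("emission", "hearing_left", "hearing_right", "ahrtf_left", "ahrtf_right")

#: Default lower bound on any stored gain, dB.  Keeps templates bounded and
#: the likelihood well conditioned.
DEFAULT_FLOOR_DB = -60.0


@dataclass(frozen=True)
class DirectionalField:
    """Per-frequency directional gain (dB) on a hemisphere partition."""

    partition: SpherePartition
    frequency_khz: float
    gain_db: np.ndarray
    role: str = "emission"
    floor_db: float = DEFAULT_FLOOR_DB

    def __post_init__(self) -> None:
        if self.role not in FIELD_ROLES:
            raise ValueError(f"unknown field role {self.role!r}")
        g = np.asarray(self.gain_db, dtype=float)
        if g.shape != (self.partition.n_cells,):
            raise ValueError(
                f"gain_db has shape {g.shape}, expected ({self.partition.n_cells},)"
            )
        if not np.all(np.isfinite(g)):
            raise ValueError("gain_db contains non-finite values")
        object.__setattr__(self, "gain_db", g)

    @property
    def linear_power(self) -> np.ndarray:
        return 10.0 ** (self.gain_db / 10.0)


@dataclass(frozen=True)
class SyntheticHeadConfig:
    """Geometry and acoustic parameters of the synthetic head.

    ``source_spacing_mm`` is the separation of the isotropic emitter pair
    (nostril spacing, 4.2 mm); ``ear_gain_cap_db`` bounds the pinna gain
    (12 dB); apertures set how quickly beams narrow with frequency.
    """

    emission_aperture_mm: float = 9.0
    hearing_aperture_mm: float = 12.0
    ear_axis_offset_deg: tuple[float, float] = (15.0, 10.0)
    ear_gain_cap_db: float = 12.0
    source_spacing_mm: float = 4.2
    speed_of_sound_m_s: float = 343.0
    emission_axis_el_deg: float = 5.0
    emission_axis_el_drift_deg_per_khz: float = 0.05
    #: sidelobe level below the lobe peak at which a beam flattens out;
    #: measured pinna directivities do not keep falling off-axis but level
    #: out a few tens of dB under the main lobe
    beam_dynamic_range_db: float = 15.0
    #: the facial morphology concentrates emitted energy much harder than
    #: the pinnae collect it: the emission lobe's plateau sits deeper
    emission_dynamic_range_db: float = 45.0
    #: amplitude of the diffraction-like ripple on the sidelobe plateau
    sidelobe_ripple_db: float = 4.0
    floor_db: float = DEFAULT_FLOOR_DB

    def __post_init__(self) -> None:
        if self.emission_aperture_mm <= 0 or self.hearing_aperture_mm <= 0:
            raise ValueError("apertures must be positive")
        if self.ear_gain_cap_db < 0:
            raise ValueError("ear_gain_cap_db must be >= 0")


def wavelength_mm(frequency_khz: float, speed_of_sound_m_s: float = 343.0) -> float:
    """Acoustic wavelength in mm at the given frequency."""
    if frequency_khz <= 0:
        raise ValueError("frequency must be positive")
    return speed_of_sound_m_s / frequency_khz  # (m/s)/(kHz) == mm


def nodes_per_wavelength(
    edge_length_mm: float, frequency_khz: float, speed_of_sound_m_s: float = 343.0
) -> float:
    """Mesh sampling density: wavelengths spanned per element edge, inverted.

    Boundary-element acoustics needs several nodes per wavelength for stable
    fields; this utility checks an edge length against a frequency.
    """
    if edge_length_mm <= 0:
        raise ValueError("edge length must be positive")
    return wavelength_mm(frequency_khz, speed_of_sound_m_s) / edge_length_mm


def two_source_emission(
    cfg: SyntheticHeadConfig, frequency_khz: float, partition: SpherePartition
) -> DirectionalField:
    """Emission pattern of two in-phase isotropic sources on the interaural axis.

    Far-field interference of two monopoles separated by
    ``cfg.source_spacing_mm``: the gain in direction ``d`` is
    ``20*log10|2 cos(k s/2 * sin(az) cos(el))|``, maximal straight ahead and
    with its first null where ``sin(az) = lambda / (2 s)``.  The ideal
    pattern's nulls are infinitely deep; they are clipped at the beam
    dynamic range below the peak, as in any measured field.  The result is
    power-normalized over the hemisphere.
    """
    if frequency_khz <= 0:
        raise ValueError("frequency must be positive")
    lam = wavelength_mm(frequency_khz, cfg.speed_of_sound_m_s)
    k = 2.0 * np.pi / lam  # rad/mm
    u_y = partition.unit_vectors[:, 1]  # projection on the interaural axis
    amp = 2.0 * np.abs(np.cos(k * cfg.source_spacing_mm / 2.0 * u_y))
    floor_amp = 2.0 * 10.0 ** (-cfg.beam_dynamic_range_db / 20.0)
    gain = 20.0 * np.log10(np.maximum(amp, floor_amp))
    raw = DirectionalField(partition, frequency_khz, gain, "emission", cfg.floor_db)
    return normalize_emission(raw)


def parametric_beam(
    aperture_mm: float,
    frequency_khz: float,
    axis: Direction,
    gain_cap_db: float,
    partition: SpherePartition,
    floor_db: float = DEFAULT_FLOOR_DB,
    role: str = "emission",
    speed_of_sound_m_s: float = 343.0,
    sidelobe_level_db: float | None = None,
    sidelobe_ripple_db: float = 0.0,
) -> DirectionalField:
    """Gaussian-lobe directional field with wavelength-scaled beamwidth.

    The half-power (full) beamwidth is ``60 deg * lambda / aperture``, the
    diffraction scaling of a radiating aperture; the gain on the axis equals
    ``gain_cap_db`` exactly and falls off as a Gaussian of off-axis angle,
    floored at ``floor_db``.

    With ``sidelobe_level_db`` set, the fall-off levels out at
    ``gain_cap_db - sidelobe_level_db`` with a diffraction-like ripple of
    amplitude ``sidelobe_ripple_db`` whose angular period is the beamwidth —
    the bounded, structured off-axis response of a measured field rather
    than an unbounded Gaussian tail.
    """
    if aperture_mm <= 0 or frequency_khz <= 0:
        raise ValueError("aperture and frequency must be positive")
    lam = wavelength_mm(frequency_khz, speed_of_sound_m_s)
    hpbw_deg = 60.0 * lam / aperture_mm
    psi = np.array(
        [
            angular_distance(axis, Direction(az, el))
            for az, el in partition.cell_centers
        ]
    )
    gain = gain_cap_db - 3.0 * (2.0 * psi / hpbw_deg) ** 2
    if sidelobe_level_db is not None:
        plateau = (
            gain_cap_db
            - sidelobe_level_db
            + sidelobe_ripple_db * np.cos(2.0 * np.pi * psi / hpbw_deg)
        )
        gain = np.maximum(gain, plateau)
    gain = np.maximum(gain, floor_db)
    return DirectionalField(partition, frequency_khz, gain, role, floor_db)


def normalize_emission(field: DirectionalField) -> DirectionalField:
    """Scale an emission field so its linear power integrates to 1 over 2*pi sr.

    All emitted energy is assumed to stay in the frontal hemisphere, so the
    per-frequency beam pattern is a probability density of emitted power over
    direction.  Idempotent.
    """
    if field.role != "emission":
        raise ValueError("normalize_emission applies to emission fields only")
    total = float(np.sum(field.linear_power) * field.partition.cell_solid_angle_sr)
    if not np.isfinite(total) or total <= 0.0:
        raise ValueError("cannot normalize a field with zero total power")
    return dataclasses.replace(field, gain_db=field.gain_db - 10.0 * np.log10(total))


def combine_ahrtf(
    emission: DirectionalField, hearing: DirectionalField
) -> DirectionalField:
    """Combine emission and hearing directivities into the round-trip AHRTF.

    Linear magnitudes multiply pointwise over direction, i.e. dB gains add
    cellwise.
    """
    if emission.partition != hearing.partition:
        raise ValueError("fields are defined on different partitions")
    if emission.frequency_khz != hearing.frequency_khz:
        raise ValueError("fields are at different frequencies")
    if hearing.role == "hearing_right":
        role = "ahrtf_right"
    elif hearing.role == "hearing_left":
        role = "ahrtf_left"
    else:
        role = hearing.role
    return dataclasses.replace(
        hearing, gain_db=emission.gain_db + hearing.gain_db, role=role
    )


def synthetic_head_fields(
    cfg: SyntheticHeadConfig,
    frequency_khz: float,
    partition: SpherePartition,
    variant: str = "focused",
) -> tuple[DirectionalField, DirectionalField, DirectionalField]:
    """Emission and left/right hearing fields of the synthetic head.

    ``variant="focused"`` uses the directional parametric emission beam whose
    axis drifts to higher elevation with frequency; ``variant="isotropic_pair"``
    replaces it by the two-isotropic-source control.  Hearing beams point
    up-and-outward (axes at ``(-/+15, +10)`` degrees by default) with peak
    gain at the ear-gain cap.
    """
    if variant == "focused":
        axis_el = (
            cfg.emission_axis_el_deg
            + cfg.emission_axis_el_drift_deg_per_khz * frequency_khz
        )
        emission = parametric_beam(
            cfg.emission_aperture_mm,
            frequency_khz,
            Direction(0.0, axis_el),
            0.0,
            partition,
            cfg.floor_db,
            role="emission",
            speed_of_sound_m_s=cfg.speed_of_sound_m_s,
            sidelobe_level_db=cfg.emission_dynamic_range_db,
            sidelobe_ripple_db=cfg.sidelobe_ripple_db,
        )
        emission = normalize_emission(emission)
    elif variant == "isotropic_pair":
        emission = two_source_emission(cfg, frequency_khz, partition)
    else:
        raise ValueError(f"unknown head variant {variant!r}")

    d_az, d_el = cfg.ear_axis_offset_deg
    hearing = {}
    for side, sign in (("left", -1.0), ("right", 1.0)):
        hearing[side] = parametric_beam(
            cfg.hearing_aperture_mm,
            frequency_khz,
            Direction(sign * d_az, d_el),
            cfg.ear_gain_cap_db,
            partition,
            cfg.floor_db,
            role=f"hearing_{side}",
            speed_of_sound_m_s=cfg.speed_of_sound_m_s,
            sidelobe_level_db=cfg.beam_dynamic_range_db,
            sidelobe_ripple_db=cfg.sidelobe_ripple_db,
        )
    return emission, hearing["left"], hearing["right"]
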
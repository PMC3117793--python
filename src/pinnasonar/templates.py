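"""Binaural templates from the anti-phase pinna sweep.

For each candidate direction the bat stores the amplitude-modulation pattern
its moving pinnae imprint on an echo from that direction: the hearing field
is rigidly rotated through the sweep positions (the emission beam stays
fixed to the head), the round-trip gain at the candidate cell is read off at
each position for each ear, and the left- and right-ear sequences are
concatenated into one template vector.  With the default sweep of 7
positions per ear a template has 14 elements.

Templates are stored zero-mean over their elements; the removed row mean is
the position's gain and is reported separately, so the unknown mean echo
strength and the modulation shape enter the measurement model as orthogonal
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .fields import DirectionalField
from .sphere import SpherePartition, rotate_field

__all__ = [
    "EarSweepProtocol",
    "TemplateSet",
    "build_templates",
    "template_gain",
    "modulation_interval",
]


def _default_angles() -> tuple[tuple[float, float], ...]:
    return tuple((float(a), float(a)) for a in range(-15, 16, 5))


@dataclass(frozen=True)
class EarSweepProtocol:
    """Pinna sweep: rotation offsets per ear position.

    The default is the diagonal sweep from (-15, -15) to (+15, +15) degrees
    in steps of 5 — seven positions — with the right ear moving in
    anti-phase (negated offsets).
    """

    angles: tuple[tuple[float, float], ...] = dc_field(default_factory=_default_angles)
    antiphase: bool = True

    @property
    def n_positions(self) -> int:
        return len(self.angles)

    @staticmethod
    def diagonal(extent_deg: float = 15.0, step_deg: float = 5.0) -> "EarSweepProtocol":
        offs = np.arange(-extent_deg, extent_deg + step_deg / 2, step_deg)
        return EarSweepProtocol(tuple((float(a), float(a)) for a in offs))

    @staticmethod
    def azimuth_only(extent_deg: float = 15.0, step_deg: float = 5.0) -> "EarSweepProtocol":
        offs = np.arange(-extent_deg, extent_deg + step_deg / 2, step_deg)
        return EarSweepProtocol(tuple((float(a), 0.0) for a in offs))

    @staticmethod
    def elevation_only(extent_deg: float = 15.0, step_deg: float = 5.0) -> "EarSweepProtocol":
        offs = np.arange(-extent_deg, extent_deg + step_deg / 2, step_deg)
        return EarSweepProtocol(tuple((0.0, float(a)) for a in offs))


@dataclass(frozen=True)
class TemplateSet:
    """Zero-mean binaural templates for one frequency.

    ``templates`` is ``(n_cells, 2 * n_positions)``; columns are left-ear
    sweep positions followed by right-ear positions.  ``position_gain_db``
    holds the removed per-template mean raw gain; ``max_raw_gain_db`` is the
    largest raw element across all templates (the per-frequency reporting
    anchor).
    """

    frequency_khz: float
    partition: SpherePartition
    templates: np.ndarray
    position_gain_db: np.ndarray
    max_raw_gain_db: float
    protocol: EarSweepProtocol

    @property
    def n_elements(self) -> int:
        return self.templates.shape[1]

    @property
    def relative_gain_db(self) -> np.ndarray:
        """Per-cell mean raw gain relative to the 0 dB normalization anchor.

        The anchor is the highest raw gain across all templates at this
        frequency, so values are <= 0: a cell's relative gain is how much
        weaker an echo from it arrives compared to the best-served
        direction.  This is what converts a nominal echo strength into the
        received strength per cell.
        """
        return self.position_gain_db - self.max_raw_gain_db


def build_templates(
    emission: DirectionalField,
    hearing_left: DirectionalField,
    hearing_right: DirectionalField,
    protocol: EarSweepProtocol | None = None,
    interpolation: str = "nearest",
) -> TemplateSet:
    """Sweep the hearing fields through the protocol and assemble templates.

    The hearing field of each ear is rotated by each sweep offset (the right
    ear by the negated offset when the protocol is anti-phase) while the
    emission field stays at the un-rotated head pose; the dB sum of emission
    and rotated hearing at every cell gives the raw template matrix, which
    is then split into a zero-mean modulation part and a per-cell mean gain.
    """
    protocol = protocol or EarSweepProtocol()
    for f in (hearing_left, hearing_right):
        if f.partition != emission.partition:
            raise ValueError("fields are defined on different partitions")
        if f.frequency_khz != emission.frequency_khz:
            raise ValueError("fields are at different frequencies")
    part = emission.partition
    n_pos = protocol.n_positions
    raw = np.empty((part.n_cells, 2 * n_pos))
    for k, (d_az, d_el) in enumerate(protocol.angles):
        rot_l = rotate_field(hearing_left, (d_az, d_el), interpolation)
        off_r = (-d_az, -d_el) if protocol.antiphase else (d_az, d_el)
        rot_r = rotate_field(hearing_right, off_r, interpolation)
        raw[:, k] = emission.gain_db + rot_l.gain_db
        raw[:, n_pos + k] = emission.gain_db + rot_r.gain_db
    means = raw.mean(axis=1)
    return TemplateSet(
        frequency_khz=emission.frequency_khz,
        partition=part,
        templates=raw - means[:, None],
        position_gain_db=means,
        max_raw_gain_db=float(raw.max()),
        protocol=protocol,
    )


def template_gain(ts: TemplateSet) -> np.ndarray:
    """Per-cell mean raw gain, referenced to the per-frequency best cell.

    Normalized so the best position is 0 dB and everything else <= 0; for a
    power-normalized emission this is the inverse of the directivity index:
    the narrower the beam, the more negative the hemisphere average.
    """
    g = ts.position_gain_db
    return g - g.max()


def modulation_interval(ts: TemplateSet) -> np.ndarray:
    """Per-cell range (max - min, dB) of the template elements.

    The modulation the moving pinnae imprint on an echo from each cell; it
    depends only on the hearing-field rotation, not on the emission pattern,
    because the static emission gain cancels in the within-template range.
    """
    return ts.templates.max(axis=1) - ts.templates.min(axis=1)
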
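"""Anthropometric tables for the 14-segment rigid-body model.

The body is modelled as 14 rigid segments — head (He), trunk (Tr), left/right
upper arms (LUA, RUA), forearms (LFA, RFA), hands (LA, RA), thighs (LT, RT),
shanks (LS, RS) and feet (LF, RF).  Each segment is endowed with inertial
properties through three dimensionless ratios (mass, COM position and radius
of gyration, Winter-style), plus a length fraction of body height used by the
synthetic generator.  A default table is bundled; any table with the same
schema can be substituted.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

#: Canonical segment order used by every matrix in the package.
SEGMENTS: tuple[str, ...] = (
    "He", "Tr", "LUA", "RUA", "LFA", "RFA", "LA",
    "RA", "LT", "RT", "LS", "RS", "LF", "RF",
)

#: Proximal neighbour of each segment; the trunk's reference is the lab z-axis.
PARENTS: dict[str, str | None] = {
    "He": "Tr", "Tr": None,
    "LUA": "Tr", "RUA": "Tr", "LFA": "LUA", "RFA": "RUA", "LA": "LFA", "RA": "RFA",
    "LT": "Tr", "RT": "Tr", "LS": "LT", "RS": "RT", "LF": "LS", "RF": "RS",
}

_MASS_SUM_TOL = 0.02


class AnthropometryError(ValueError):
    """Raised for malformed anthropometric tables."""


@dataclass(frozen=True)
class SegmentFractions:
    """Dimensionless ratios describing one segment."""

    mass_fraction: float
    com_fraction: float
    gyration_fraction: float
    length_fraction: float


class AnthropometricTable:
    """Per-segment mass / COM / gyration / length fractions.

    Invariants enforced at construction: exactly the 14 canonical segment
    names, every fraction strictly inside (0, 1), and mass fractions summing
    to 1 within ±0.02 (published tables are approximate; the residual is
    reported via :attr:`mass_residual`).
    """

    def __init__(self, entries: dict[str, SegmentFractions]):
        if set(entries) != set(SEGMENTS):
            missing = set(SEGMENTS) - set(entries)
            extra = set(entries) - set(SEGMENTS)
            raise AnthropometryError(
                f"table must contain exactly the 14 canonical segments; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        for name, frac in entries.items():
            for field in ("mass_fraction", "com_fraction",
                          "gyration_fraction", "length_fraction"):
                value = getattr(frac, field)
                if not 0.0 < value < 1.0:
                    raise AnthropometryError(
                        f"{name}.{field} = {value!r} outside (0, 1)")
        total = sum(entries[s].mass_fraction for s in SEGMENTS)
        if abs(total - 1.0) > _MASS_SUM_TOL:
            raise AnthropometryError(
                f"mass fractions sum to {total:.4f}, outside 1 ± {_MASS_SUM_TOL}")
        self._entries = {s: entries[s] for s in SEGMENTS}
        self.mass_residual = total - 1.0

    def __getitem__(self, segment: str) -> SegmentFractions:
        return self._entries[segment]

    @property
    def mass_fractions(self) -> np.ndarray:
        return np.array([self._entries[s].mass_fraction for s in SEGMENTS])

    @property
    def com_fractions(self) -> np.ndarray:
        return np.array([self._entries[s].com_fraction for s in SEGMENTS])

    @property
    def gyration_fractions(self) -> np.ndarray:
        return np.array([self._entries[s].gyration_fraction for s in SEGMENTS])

    @property
    def length_fractions(self) -> np.ndarray:
        return np.array([self._entries[s].length_fraction for s in SEGMENTS])

    def segment_masses(self, body_mass: float) -> np.ndarray:
        """Segment masses in kg for a participant of ``body_mass`` kg."""
        return body_mass * self.mass_fractions

    @classmethod
    def from_mapping(cls, raw: dict) -> "AnthropometricTable":
        entries = {}
        for name, row in raw.items():
            try:
                entries[name] = SegmentFractions(
                    mass_fraction=float(row["mass_fraction"]),
                    com_fraction=float(row["com_fraction"]),
                    gyration_fraction=float(row["gyration_fraction"]),
                    length_fraction=float(row["length_fraction"]),
                )
            except KeyError as exc:
                raise AnthropometryError(
                    f"segment {name!r}: missing field {exc.args[0]!r}") from exc
        return cls(entries)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnthropometricTable":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "AnthropometricTable":
        """The bundled Winter-style table."""
        text = (resources.files("beamwalk") / "data" / "anthropometry.yaml").read_text()
        return cls.from_mapping(yaml.safe_load(text))
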
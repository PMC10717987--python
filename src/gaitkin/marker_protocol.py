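"""Plugin (16-marker) and Redundant (38-marker) lower-body marker sets.

The Plugin set is the standard lower-body protocol (4 pelvis markers plus
THI, KNE, TIB, ANK, HEE, TOE per leg, Vicon Plug-in-Gait labels).  The
Redundant set adds 11 markers per side: three extra thigh markers placed
inferior/anterior/posterior to THI, three extra tibia markers likewise
around TIB, the iliac crest (IC), the medial femoral epicondyle (KNE_M),
the dorsal 5th metatarsal (M5), the dorsal tarsal (T) and the medial
malleolus (ANK_M).

.. note::
   The source protocol enumerates ten of its eleven extra markers per side;
   the eleventh is defined *here* as the medial malleolus (ANK_M), the
   conventional medial partner of KNE_M.  It is isolated in the template
   table below so it can be swapped if a different placement is preferred.

Marker offsets are expressed in the parent segment's frame (mm).  Axial
coordinates are parameterized by the segment's length so that a protocol
resolved against a scaled model places markers at anatomically homologous
points; this is what makes segment lengths observable from a standing trial.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml

from . import kinematic_model as km
from .exceptions import ProtocolError

PLUGIN = "plugin"
REDUNDANT = "redundant"


@dataclass(frozen=True)
class MarkerAttachment:
    """A marker riding on a segment at a constant local offset (mm)."""

    name: str
    segment: str
    local_offset: np.ndarray
    side: str  # L / R / M

    def __post_init__(self):
        object.__setattr__(self, "local_offset",
                           np.asarray(self.local_offset, dtype=float))


@dataclass(frozen=True)
class MarkerProtocol:
    """An ordered, named collection of marker attachments."""

    name: str
    markers: tuple[MarkerAttachment, ...]

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, name: str) -> MarkerAttachment:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Template table
# ---------------------------------------------------------------------------
# (base name, segment base, in_plugin, x, lateral, axial) where for leg
# segments `axial` is a fraction of the segment length parameter (measured
# distally along the segment's long axis) and `lateral` is mm toward the
# subject's outside; pelvis lateral and foot axial entries are fractions of
# pelvic width resp. foot length.  Full marker name = side prefix + base.

_PELVIS_TEMPLATES = [
    # base, plugin, x_mm, lateral_frac_of_pw, extra_lat_mm, z_mm
    ("ASI", True, 70.0, 0.50, 0.0, 0.0),
    ("PSI", True, -90.0, 0.19, 0.0, 15.0),
    ("IC", False, 0.0, 0.50, 15.0, 60.0),
]

_FEMUR_TEMPLATES = [
    # base, plugin, x_mm, lateral_mm, axial_frac_of_thigh
    ("THI", True, 15.0, 70.0, 0.40),
    ("THI_I", False, 15.0, 72.0, 0.52),
    ("THI_A", False, 55.0, 45.0, 0.40),
    ("THI_P", False, -45.0, 55.0, 0.40),
    ("KNE", True, 0.0, 55.0, 0.98),
    ("KNE_M", False, 0.0, -50.0, 0.98),
]

_SHANK_TEMPLATES = [
    ("TIB", True, 10.0, 55.0, 0.42),
    ("TIB_I", False, 10.0, 52.0, 0.55),
    ("TIB_A", False, 45.0, 35.0, 0.42),
    ("TIB_P", False, -40.0, 40.0, 0.42),
    ("ANK", True, 0.0, 45.0, 0.96),
    ("ANK_M", False, 0.0, -40.0, 0.96),  # the protocol's unlisted 11th extra
]

_FOOT_TEMPLATES = [
    # base, plugin, axial_frac_of_foot (along +X), lateral_mm, z_mm
    ("TOE", True, 0.85, 15.0, -45.0),
    ("HEE", True, -0.20, 0.0, -40.0),
    ("M5", False, 0.55, 45.0, -35.0),
    ("T", False, 0.30, 5.0, -10.0),
]


def _resolve(side: str, lengths: dict[str, float], plugin_only: bool) -> list[MarkerAttachment]:
    s = 1.0 if side == "L" else -1.0  # lateral direction along +/-Y
    out: list[MarkerAttachment] = []
    pw = lengths["pelvic_width"]
    for base, in_plugin, x, lat_frac, lat_mm, z in _PELVIS_TEMPLATES:
        if plugin_only and not in_plugin:
            continue
        out.append(MarkerAttachment(side + base, "pelvis",
                                    [x, s * (lat_frac * pw + lat_mm), z], side))
    for base, in_plugin, x, lat, frac in _FEMUR_TEMPLATES:
        if plugin_only and not in_plugin:
            continue
        out.append(MarkerAttachment(side + base, f"femur_{side}",
                                    [x, s * lat, -frac * lengths[f"thigh_{side}"]], side))
    for base, in_plugin, x, lat, frac in _SHANK_TEMPLATES:
        if plugin_only and not in_plugin:
            continue
        out.append(MarkerAttachment(side + base, f"shank_{side}",
                                    [x, s * lat, -frac * lengths[f"shank_{side}"]], side))
    for base, in_plugin, frac, lat, z in _FOOT_TEMPLATES:
        if plugin_only and not in_plugin:
            continue
        out.append(MarkerAttachment(side + base, f"foot_{side}",
                                    [frac * lengths[f"foot_{side}"], s * lat, z], side))
    return out


#: Long axis of each segment base, used to validate that markers sit near
#: the segment surface (off-axis distance bounded, not distance to origin).
_LONG_AXIS = {"pelvis": np.array([0.0, 1.0, 0.0]),
              "femur": np.array([0.0, 0.0, 1.0]),
              "shank": np.array([0.0, 0.0, 1.0]),
              "talus": np.array([0.0, 0.0, 1.0]),
              "foot": np.array([1.0, 0.0, 0.0])}

MAX_OFF_AXIS_MM = 200.0


def validate_protocol(protocol: MarkerProtocol) -> None:
    """Check name uniqueness and that offsets are finite and near-surface."""
    names = protocol.marker_names
    if len(set(names)) != len(names):
        raise ProtocolError(f"duplicate marker names in protocol {protocol.name!r}")
    for m in protocol.markers:
        off = m.local_offset
        if not np.all(np.isfinite(off)):
            raise ProtocolError(f"marker {m.name!r} has non-finite offset")
        axis = _LONG_AXIS[m.segment.split("_")[0]]
        radial = off - axis * (off @ axis)
        if np.linalg.norm(radial) >= MAX_OFF_AXIS_MM:
            raise ProtocolError(
                f"marker {m.name!r} offset {off} lies {np.linalg.norm(radial):.0f} mm "
                f"off the {m.segment} long axis (limit {MAX_OFF_AXIS_MM:.0f} mm)")


def _build(name: str, model: km.ScaledModel | None, plugin_only: bool) -> MarkerProtocol:
    lengths = (model or km.build_model()).lengths
    markers: list[MarkerAttachment] = []
    # pelvis midline block first (PiG order), then right leg, then left leg
    for side in ("L", "R"):
        markers += [m for m in _resolve(side, lengths, plugin_only) if m.segment == "pelvis"]
    markers.sort(key=lambda m: (m.name[1:] != "ASI", m.name[1:] != "PSI", m.name))
    for side in ("R", "L"):
        markers += [m for m in _resolve(side, lengths, plugin_only) if m.segment != "pelvis"]
    proto = MarkerProtocol(name, tuple(markers))
    validate_protocol(proto)
    return proto


def plugin_marker_set(model: km.ScaledModel | None = None) -> MarkerProtocol:
    """The 16-marker Plugin protocol (4 pelvis + 6 per leg)."""
    return _build(PLUGIN, model, plugin_only=True)


def redundant_marker_set(model: km.ScaledModel | None = None) -> MarkerProtocol:
    """The 38-marker Redundant protocol (Plugin + 11 extras per side)."""
    return _build(REDUNDANT, model, plugin_only=False)


def get_protocol(name: str, model: km.ScaledModel | None = None) -> MarkerProtocol:
    if name == PLUGIN:
        return plugin_marker_set(model)
    if name == REDUNDANT:
        return redundant_marker_set(model)
    raise ProtocolError(f"unknown protocol {name!r}")


def extra_marker_names(model: km.ScaledModel | None = None) -> tuple[str, ...]:
    """Names of the 22 redundant-set markers absent from the Plugin set."""
    plugin = set(plugin_marker_set(model).marker_names)
    return tuple(n for n in redundant_marker_set(model).marker_names if n not in plugin)


# ---------------------------------------------------------------------------
# Reduction to the Plugin subset
# ---------------------------------------------------------------------------

def reduce_to_plugin(data):
    """Drop the 22 extra markers, keeping the 16 Plugin markers untouched.

    Accepts a :class:`MarkerProtocol`, an iterable of
    :class:`MarkerAttachment`, or any trajectory container exposing
    ``marker_names`` and a ``select(names)`` method (duck-typed so marker
    data and model attachments go through the same reduction).
    """
    plugin_names = plugin_marker_set().marker_names
    if isinstance(data, MarkerProtocol):
        missing = [n for n in plugin_names if n not in data.marker_names]
        if missing:
            raise ProtocolError(f"missing plugin markers: {', '.join(missing)}")
        keep = tuple(m for m in data.markers if m.name in plugin_names)
        return MarkerProtocol(PLUGIN, keep)
    if hasattr(data, "select") and hasattr(data, "marker_names"):
        missing = [n for n in plugin_names if n not in data.marker_names]
        if missing:
            raise ProtocolError(f"missing plugin markers: {', '.join(missing)}")
        return data.select([n for n in data.marker_names if n in plugin_names])
    # plain iterable of attachments
    atts = list(data)
    have = {m.name for m in atts}
    missing = [n for n in plugin_names if n not in have]
    if missing:
        raise ProtocolError(f"missing plugin markers: {', '.join(missing)}")
    return [m for m in atts if m.name in plugin_names]


# ---------------------------------------------------------------------------
# YAML serialization
# ---------------------------------------------------------------------------

def protocol_to_yaml(protocol: MarkerProtocol) -> str:
    doc = {"name": protocol.name,
           "markers": [{"name": m.name, "segment": m.segment,
                        "offset_mm": [float(v) for v in m.local_offset],
                        "side": m.side}
                       for m in protocol.markers]}
    return yaml.safe_dump(doc, sort_keys=False)


def protocol_from_yaml(text: str) -> MarkerProtocol:
    doc = yaml.safe_load(text)
    markers = tuple(MarkerAttachment(m["name"], m["segment"], m["offset_mm"], m["side"])
                    for m in doc["markers"])
    proto = MarkerProtocol(doc["name"], markers)
    validate_protocol(proto)
    return proto


def with_offsets(protocol: MarkerProtocol,
                 offsets: dict[str, np.ndarray]) -> MarkerProtocol:
    """A copy of ``protocol`` with (some) marker offsets replaced."""
    markers = tuple(replace(m, local_offset=np.asarray(offsets[m.name], float))
                    if m.name in offsets else m for m in protocol.markers)
    return MarkerProtocol(protocol.name, markers)
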
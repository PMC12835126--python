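"""Electrode layouts: construction, spatial downsampling, and JSON I/O.

Coordinate convention: ``y`` is depth along the probe shank (increasing
toward the tip, origin at the topmost electrode), ``x`` runs across the
shank, ``z`` is out of the probe plane (0 for planar probes).  All
coordinates are micrometres.

Two presets mirror the probes behind the study conditions:

``rodent``
    256-channel single-shank probe, two columns in a zig-zag pattern;
    6 μm row pitch and 6 μm column offset give the 8.5 μm
    nearest-neighbour pitch (each column has a 12 μm vertical pitch).
``human``
    The rightmost two columns of a Neuropixels probe, 192 electrodes in
    a checkerboard; 20 μm row advance per electrode and 16 μm column
    offset give the 25.6 μm nearest-neighbour pitch.

Spatially downsampling these by keeping every k-th electrode along the
shank reproduces the sparser virtual probes used to emulate lower-
resolution recordings (e.g. rodent keep-every-8 → 32 channels at 48 μm).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Electrode",
    "ElectrodeLayout",
    "LayoutError",
    "linear_layout",
    "zigzag_layout",
    "preset_layout",
    "downsample",
    "enumerate_shifted_configs",
    "read_layout",
    "write_layout",
    "preset_series",
    "PRESETS",
    "SERIES_KEEP_EVERY",
]


class LayoutError(ValueError):
    """Raised for malformed layout definitions (JSON or constructed)."""


@dataclass(frozen=True)
class Electrode:
    id: int
    x: float
    y: float
    z: float = 0.0


@dataclass(frozen=True)
class ElectrodeLayout:
    """A set of electrode centers with unique ids, ordered along the shank."""

    electrodes: tuple[Electrode, ...]
    name: str = "layout"
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.electrodes) == 0:
            raise LayoutError("layout must contain at least one electrode")
        ids = [e.id for e in self.electrodes]
        dup_ids = {i for i in ids if ids.count(i) > 1}
        if dup_ids:
            raise LayoutError(f"duplicate electrode id(s): {sorted(dup_ids)}")
        pos = [(e.x, e.y, e.z) for e in self.electrodes]
        if len(set(pos)) != len(pos):
            seen: set = set()
            dups = []
            for p in pos:
                if p in seen:
                    dups.append(p)
                seen.add(p)
            raise LayoutError(f"duplicate electrode position(s): {dups}")

    @property
    def m(self) -> int:
        """Channel count."""
        return len(self.electrodes)

    @property
    def positions(self) -> np.ndarray:
        """(m, 3) float array of electrode centers (μm)."""
        return np.array([(e.x, e.y, e.z) for e in self.electrodes], dtype=float)

    @property
    def d_nn(self) -> float:
        """Nearest-neighbour distance (μm); the layout's effective pitch.

        Undefined for a single electrode (raises ``LayoutError``).
        """
        if self.m < 2:
            raise LayoutError("d_nn is undefined for a single-electrode layout")
        p = self.positions
        # pairwise minimum; layouts are small so O(m^2) is fine
        diff = p[:, None, :] - p[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
        np.fill_diagonal(dist, np.inf)
        return float(dist.min())

    def is_linear_equidistant(self, rel_tol: float = 1e-9) -> bool:
        """True if the electrodes are collinear with uniform spacing."""
        if self.m < 2:
            return False
        p = self.positions
        order = np.argsort(p[:, 1], kind="stable")
        p = p[order]
        steps = np.diff(p, axis=0)
        first = steps[0]
        norm = np.linalg.norm(first)
        if norm == 0:
            return False
        tol = rel_tol * norm + 1e-9
        return bool(np.all(np.abs(steps - first) <= tol))

    def content_hash(self) -> str:
        """Stable hash of electrode positions (cache key for volume tables)."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.positions).tobytes())
        return h.hexdigest()[:16]


def linear_layout(m: int, d: float, name: str | None = None) -> ElectrodeLayout:
    """Collinear electrodes spaced ``d`` μm apart along the shank axis."""
    if m < 1:
        raise LayoutError(f"m must be >= 1, got {m}")
    if d <= 0:
        raise LayoutError(f"d must be > 0, got {d}")
    electrodes = tuple(Electrode(id=i, x=0.0, y=i * d) for i in range(m))
    return ElectrodeLayout(electrodes, name=name or f"linear_{m}ch_{d:g}um")


def zigzag_layout(
    m: int, row_pitch: float, col_offset: float, name: str | None = None
) -> ElectrodeLayout:
    """Two-column zig-zag: electrodes alternate between ``x = 0`` and
    ``x = col_offset`` while ``y`` advances by ``row_pitch`` per electrode.

    Nearest-neighbour pitch is ``sqrt(row_pitch² + col_offset²)``; with
    ``col_offset = 0`` this degenerates to :func:`linear_layout`.
    """
    if m < 2:
        raise LayoutError(f"zig-zag layout needs m >= 2, got {m}")
    if row_pitch <= 0:
        raise LayoutError(f"row_pitch must be > 0, got {row_pitch}")
    if col_offset < 0:
        raise LayoutError(f"col_offset must be >= 0, got {col_offset}")
    electrodes = tuple(
        Electrode(id=i, x=(i % 2) * col_offset, y=i * row_pitch) for i in range(m)
    )
    return ElectrodeLayout(
        electrodes, name=name or f"zigzag_{m}ch_{row_pitch:g}x{col_offset:g}um"
    )


#: preset name -> (constructor args); see module docstring for provenance
PRESETS: dict[str, dict] = {
    "rodent": dict(m=256, row_pitch=6.0, col_offset=6.0),
    "human": dict(m=192, row_pitch=20.0, col_offset=16.0),
}


def preset_layout(name: str) -> ElectrodeLayout:
    """Construct one of the named probe presets (``rodent`` or ``human``)."""
    try:
        args = PRESETS[name]
    except KeyError:
        raise LayoutError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return zigzag_layout(name=name, **args)


def downsample(
    layout: ElectrodeLayout, keep_every: int, offset: int = 0
) -> ElectrodeLayout:
    """Retain electrodes at shank-order indices ≡ ``offset`` (mod ``keep_every``).

    Electrodes are taken in their stored order, which for all constructors
    here is the shank order.  ``keep_every = 1`` is the identity.
    """
    if keep_every < 1:
        raise LayoutError(f"keep_every must be >= 1, got {keep_every}")
    if not 0 <= offset < keep_every:
        raise LayoutError(
            f"offset must satisfy 0 <= offset < keep_every, got {offset}"
        )
    kept = tuple(
        e for i, e in enumerate(layout.electrodes) if i % keep_every == offset
    )
    if not kept:
        raise LayoutError(
            f"downsampling {layout.name} by {keep_every} (offset {offset}) "
            "leaves no electrodes"
        )
    return ElectrodeLayout(
        kept, name=f"{layout.name}_every{keep_every}_off{offset}"
    )


def enumerate_shifted_configs(
    layout: ElectrodeLayout, keep_every: int
) -> list[ElectrodeLayout]:
    """All ``keep_every`` vertically shifted variants of one downsampling.

    The variants share the same effective pitch (up to boundary effects)
    and differ only in which channels they retain; they emulate building
    every possible equidistant configuration for a given channel count.
    """
    return [downsample(layout, keep_every, off) for off in range(keep_every)]


#: spatial-downsampling factors of the virtual-probe series emulating the
#: study's recordings (1 = the original high-density layout)
SERIES_KEEP_EVERY: dict[str, tuple[int, ...]] = {
    "rodent": (1, 2, 4, 8, 16),
    "human": (1, 2, 3, 4, 5, 10),
}


def preset_series(name: str) -> list[tuple[str, ElectrodeLayout]]:
    """The full downsampling series of a preset probe, as (label, layout) pairs.

    Rodent: 256/128/64/32/16 channels at 8.5/12/24/48/96 μm pitch.
    Human: 192/96/64/48/38/19 channels at 25.6/40/62.1/80/101.3/200 μm.
    The downsampling offset is ``m mod keep_every``, which reproduces the
    published channel counts for every member of both series.
    """
    base = preset_layout(name)
    series = []
    for k in SERIES_KEEP_EVERY[name]:
        lay = base if k == 1 else downsample(base, k, offset=base.m % k)
        series.append((f"{lay.m}ch", lay))
    return series


# --------------------------------------------------------------------------
# JSON dialect: {"name": str, "units": "um",
#                "electrodes": [{"id": int, "x": f, "y": f, "z": f}, ...]}
# Unknown top-level fields are preserved on round trip.


def _parse_electrode(rec: object, index: int) -> Electrode:
    if not isinstance(rec, dict):
        raise LayoutError(f"electrode record {index} is not an object: {rec!r}")
    missing = [k for k in ("id", "x", "y") if k not in rec]
    if missing:
        raise LayoutError(
            f"electrode record {index} missing field(s) {missing}: {rec!r}"
        )
    eid = rec["id"]
    if not isinstance(eid, int) or isinstance(eid, bool):
        raise LayoutError(f"electrode record {index}: id must be an integer, got {eid!r}")
    try:
        x, y = float(rec["x"]), float(rec["y"])
        z = float(rec.get("z", 0.0))
    except (TypeError, ValueError) as exc:
        raise LayoutError(f"electrode record {index}: non-numeric coordinate ({exc})")
    if not all(math.isfinite(v) for v in (x, y, z)):
        raise LayoutError(f"electrode record {index}: non-finite coordinate")
    return Electrode(id=eid, x=x, y=y, z=z)


def read_layout(path: str | Path) -> ElectrodeLayout:
    """Read an electrode layout from the package's JSON dialect.

    Raises :class:`LayoutError` naming the offending record for schema
    violations (missing fields, duplicate ids, non-numeric coordinates).
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise LayoutError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise LayoutError(f"{path}: top-level JSON value must be an object")
    units = doc.get("units", "um")
    if units != "um":
        raise LayoutError(f"{path}: unsupported units {units!r} (expected 'um')")
    recs = doc.get("electrodes")
    if not isinstance(recs, list) or not recs:
        raise LayoutError(f"{path}: 'electrodes' must be a non-empty list")
    electrodes = [_parse_electrode(r, i) for i, r in enumerate(recs)]
    seen: set[int] = set()
    for e in electrodes:
        if e.id in seen:
            raise LayoutError(f"{path}: duplicate electrode id {e.id}")
        seen.add(e.id)
    extra = {
        k: v for k, v in doc.items() if k not in ("name", "units", "electrodes")
    }
    return ElectrodeLayout(
        tuple(electrodes), name=str(doc.get("name", path.stem)), extra=extra
    )


def write_layout(layout: ElectrodeLayout, path: str | Path) -> None:
    """Write a layout to the JSON dialect (round-trips with :func:`read_layout`)."""
    doc = {
        "name": layout.name,
        "units": "um",
        "electrodes": [
            {"id": e.id, "x": e.x, "y": e.y, "z": e.z} for e in layout.electrodes
        ],
        **layout.extra,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")
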
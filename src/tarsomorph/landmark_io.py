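"""Reading, writing and normalising 2D landmark data in TPS format.

The TPS dialect accepted here is the plain landmark-record form produced by
the tpsUtil/tpsDig family: an ``LM=`` header, one whitespace-separated
``x y`` row per point, and optional trailing ``IMAGE=``, ``ID=`` and
``SCALE=`` lines.  Curve/outline extensions (``CURVES=``, ``POINTS=``) are
deliberately rejected rather than silently dropped.

Coordinates are stored in millimetres after the ``SCALE=`` factor has been
applied, with the mathematical axis convention: y increases upward
("dorsal" = +y) and, once every specimen has been mirrored to the left
side, "medial" = -x.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "LandmarkConfiguration",
    "LandmarkScheme",
    "LandmarkDataset",
    "TpsParseError",
    "read_tps",
    "write_tps",
    "mirror_configuration",
    "default_tarsus_scheme",
    "scheme_to_yaml",
    "scheme_from_yaml",
]

SIDES = ("left", "right", "unknown")


class TpsParseError(ValueError):
    """Raised when a TPS stream is malformed."""


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2D landmark configuration.

    Equality compares the shape data identity (specimen_id and exact
    coordinates); ``side`` and ``source_scale`` are carrying metadata that a
    TPS round trip does not preserve and are excluded from ``==``.
    """

    specimen_id: str
    coords: np.ndarray
    side: str = "unknown"
    source_scale: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"{self.specimen_id!r}: coords must be a (p, 2) array, "
                f"got shape {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError(f"{self.specimen_id!r}: configuration has no points")
        if not np.isfinite(self.coords).all():
            raise ValueError(f"{self.specimen_id!r}: non-finite coordinate")
        if self.side not in SIDES:
            raise ValueError(f"{self.specimen_id!r}: side must be one of {SIDES}")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkConfiguration):
            return NotImplemented
        return (
            self.specimen_id == other.specimen_id
            and self.coords.shape == other.coords.shape
            and bool(np.array_equal(self.coords, other.coords))
        )

    __hash__ = None  # type: ignore[assignment]


def mirror_configuration(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Reflect a right-side configuration about the vertical axis.

    x coordinates are negated, y is untouched and the point order is
    preserved, so all inter-point distances (and hence centroid size) are
    unchanged.  Mirroring anything other than a right-side configuration is
    an error: it would silently flip an already-left specimen.
    """
    if config.side != "right":
        raise ValueError(
            f"{config.specimen_id!r}: can only mirror a right-side configuration "
            f"(side={config.side!r})"
        )
    coords = config.coords.copy()
    coords[:, 0] = -coords[:, 0]
    return LandmarkConfiguration(
        specimen_id=config.specimen_id,
        coords=coords,
        side="left",
        source_scale=config.source_scale,
    )


# ---------------------------------------------------------------------------
# Landmark scheme


@dataclass(frozen=True)
class LandmarkScheme:
    """Declares which points slide, along what, and named point subsets.

    Point indices are 0-based over the concatenated sequence of fixed
    landmarks followed by semilandmarks; a scheme with ``n_landmarks=9`` and
    ``n_semilandmarks=2`` therefore has semilandmarks at indices 9 and 10.
    ``semilandmark_neighbours[k]`` gives the ordered pair of point indices
    whose chord defines the tangent of semilandmark ``k``.
    """

    n_landmarks: int
    n_semilandmarks: int = 0
    semilandmark_neighbours: tuple[tuple[int, int], ...] = ()
    subsets: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "semilandmark_neighbours",
            tuple(tuple(int(i) for i in pair) for pair in self.semilandmark_neighbours),
        )
        object.__setattr__(
            self,
            "subsets",
            {str(k): tuple(int(i) for i in v) for k, v in dict(self.subsets).items()},
        )
        self.validate()

    @property
    def n_points(self) -> int:
        return self.n_landmarks + self.n_semilandmarks

    def semilandmark_indices(self) -> tuple[int, ...]:
        return tuple(range(self.n_landmarks, self.n_points))

    def validate(self) -> None:
        if self.n_landmarks < 0 or self.n_semilandmarks < 0 or self.n_points < 1:
            raise ValueError("scheme must declare at least one point")
        if len(self.semilandmark_neighbours) != self.n_semilandmarks:
            raise ValueError(
                f"{self.n_semilandmarks} semilandmarks but "
                f"{len(self.semilandmark_neighbours)} neighbour pairs"
            )
        for k, (a, b) in enumerate(self.semilandmark_neighbours):
            sl = self.n_landmarks + k
            if a == b:
                raise ValueError(f"semilandmark {k}: neighbours must be distinct")
            for idx in (a, b):
                if not 0 <= idx < self.n_points:
                    raise ValueError(f"semilandmark {k}: neighbour {idx} out of range")
                if idx == sl:
                    raise ValueError(f"semilandmark {k}: cannot neighbour itself")
        for name, idx in self.subsets.items():
            for i in idx:
                if not 0 <= i < self.n_points:
                    raise ValueError(f"subset {name!r}: index {i} out of range")


def default_tarsus_scheme() -> LandmarkScheme:
    """The 11-point proximal-tarsus scheme: 9 fixed landmarks, 2 sliders.

    The medial subset is {LM2, LM6, LM9, SL1, SL2} (0-based indices
    1, 5, 8, 9, 10) — the five points sampling the medial margin of the
    astragalus and/or centrale.  SL1 slides on the LM2-LM6 chord, SL2 on
    LM6-LM9, tracing the medial outline.
    """
    return LandmarkScheme(
        n_landmarks=9,
        n_semilandmarks=2,
        semilandmark_neighbours=((1, 5), (5, 8)),
        subsets={"medial": (1, 5, 8, 9, 10)},
    )


def scheme_to_yaml(scheme: LandmarkScheme) -> str:
    doc = {
        "n_landmarks": scheme.n_landmarks,
        "n_semilandmarks": scheme.n_semilandmarks,
        "semilandmark_neighbours": [list(p) for p in scheme.semilandmark_neighbours],
        "subsets": {k: list(v) for k, v in scheme.subsets.items()},
    }
    return yaml.safe_dump(doc, sort_keys=True)


def scheme_from_yaml(text: str) -> LandmarkScheme:
    doc = yaml.safe_load(text)
    return LandmarkScheme(
        n_landmarks=int(doc["n_landmarks"]),
        n_semilandmarks=int(doc.get("n_semilandmarks", 0)),
        semilandmark_neighbours=tuple(
            tuple(p) for p in doc.get("semilandmark_neighbours", [])
        ),
        subsets={k: tuple(v) for k, v in doc.get("subsets", {}).items()},
    )


# ---------------------------------------------------------------------------
# Dataset

CONFIGURATION_LABELS = ("astragalus_plus_centrale", "astragalus_only", "other")


@dataclass
class LandmarkDataset:
    """A scheme plus one configuration per specimen."""

    scheme: LandmarkScheme
    configurations: list[LandmarkConfiguration]
    configuration_label: str = "other"

    def __post_init__(self) -> None:
        if self.configuration_label not in CONFIGURATION_LABELS:
            raise ValueError(
                f"configuration_label must be one of {CONFIGURATION_LABELS}"
            )
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for c in self.configurations:
            if c.specimen_id in seen:
                raise ValueError(f"duplicate specimen_id {c.specimen_id!r}")
            seen.add(c.specimen_id)
            if c.n_points != self.scheme.n_points:
                raise ValueError(
                    f"{c.specimen_id!r}: {c.n_points} points but scheme "
                    f"declares {self.scheme.n_points}"
                )

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    @property
    def n_specimens(self) -> int:
        return len(self.configurations)

    def coords_array(self) -> np.ndarray:
        """(n, p, 2) stack in specimen order."""
        return np.stack([c.coords for c in self.configurations])

    def __getitem__(self, specimen_id: str) -> LandmarkConfiguration:
        for c in self.configurations:
            if c.specimen_id == specimen_id:
                return c
        raise KeyError(specimen_id)


# ---------------------------------------------------------------------------
# TPS I/O

_LM_RE = re.compile(r"LM\s*=\s*(\d+)\s*$", re.IGNORECASE)
_KEY_RE = re.compile(r"^([A-Za-z]+)\s*=\s*(.*)$")


def read_tps(source: str | IO[str]) -> list[LandmarkConfiguration]:
    """Parse a TPS stream into configurations.

    ``SCALE=`` multiplies every coordinate of its record (converting
    digitising units to mm); ``ID=`` names the specimen, with ``IMAGE=``
    (extension stripped) as fallback.  Point order is preserved.
    """
    text = source.read() if hasattr(source, "read") else source
    lines = text.splitlines()
    out: list[LandmarkConfiguration] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        stripped = lines[i].strip()
        if not stripped:
            i += 1
            continue
        m = _LM_RE.match(stripped)
        if m is None:
            raise TpsParseError(
                f"line {i + 1}: expected an LM= record header, got {stripped!r}"
            )
        n_pts = int(m.group(1))
        record = len(out) + 1
        i += 1
        rows: list[tuple[float, float]] = []
        while i < n_lines and len(rows) < n_pts:
            s = lines[i].strip()
            if not s:
                i += 1
                continue
            if _KEY_RE.match(s) and not _is_coordinate_row(s):
                break
            parts = s.split()
            if len(parts) != 2:
                raise TpsParseError(
                    f"line {i + 1} (record {record}): expected 'x y', got {s!r}"
                )
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TpsParseError(
                    f"line {i + 1} (record {record}): non-numeric coordinate {s!r}"
                ) from exc
            i += 1
        if len(rows) < n_pts:
            raise TpsParseError(
                f"record {record}: header declares LM={n_pts} but only "
                f"{len(rows)} coordinate rows found"
            )
        spec_id: str | None = None
        image: str | None = None
        scale: float | None = None
        while i < n_lines:
            s = lines[i].strip()
            if not s:
                i += 1
                continue
            if _LM_RE.match(s):
                break
            km = _KEY_RE.match(s)
            if km is None:
                raise TpsParseError(
                    f"line {i + 1} (record {record}): unexpected content {s!r}"
                )
            key = km.group(1).upper()
            val = km.group(2).strip()
            if key == "ID":
                spec_id = val
            elif key == "IMAGE":
                image = val
            elif key == "SCALE":
                try:
                    scale = float(val)
                except ValueError as exc:
                    raise TpsParseError(
                        f"line {i + 1} (record {record}): non-numeric SCALE {val!r}"
                    ) from exc
            elif key in ("CURVES", "POINTS"):
                raise TpsParseError(
                    f"line {i + 1} (record {record}): curve/outline TPS records "
                    f"({key}=) are not supported"
                )
            else:
                raise TpsParseError(
                    f"line {i + 1} (record {record}): unsupported TPS key {key}="
                )
            i += 1
        coords = np.asarray(rows, dtype=float)
        if scale is not None:
            coords = coords * scale
        if spec_id is None:
            spec_id = re.sub(r"\.[^.]*$", "", image) if image else f"specimen_{record}"
        out.append(
            LandmarkConfiguration(specimen_id=spec_id, coords=coords, source_scale=scale)
        )
    return out


def _is_coordinate_row(s: str) -> bool:
    parts = s.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0])
        float(parts[1])
    except ValueError:
        return False
    return True


def write_tps(configs: Sequence[LandmarkConfiguration] | Iterable[LandmarkConfiguration]) -> str:
    """Serialise configurations to TPS text at full (round-trip) precision.

    Coordinates are already in mm, so ``SCALE=1.0`` is emitted.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("cannot write an empty TPS file")
    chunks: list[str] = []
    for c in configs:
        rows = "\n".join(f"{x:.17g} {y:.17g}" for x, y in c.coords)
        chunks.append(f"LM={c.n_points}\n{rows}\nID={c.specimen_id}\nSCALE=1.0\n")
    return "\n".join(chunks)
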
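"""Landmark configurations and TPS file I/O.

A shell is digitised as 20 two-dimensional Cartesian landmarks (apex,
suture/outline intersections, body-whorl extremes, aperture extremes and
auxiliary points).  Coordinates are stored in mm after applying the file's
SCALE factor, so centroid size is in mm as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical landmark scheme: apex (1), suture points (2-7), body-whorl
#: extremes (8-9), aperture extremes (10-13), auxiliary points (14-20).
LANDMARK_LABELS: tuple[str, ...] = (
    "apex",
    *[f"suture_{i}" for i in range(1, 7)],
    "body_whorl_right",
    "body_whorl_left",
    "aperture_top",
    "aperture_right",
    "aperture_left",
    "aperture_bottom",
    *[f"aux_{i}" for i in range(1, 8)],
)

N_LANDMARKS = 20


class TPSParseError(ValueError):
    """Raised for a malformed TPS record (names the record index)."""


class LandmarkSchemaError(ValueError):
    """Raised when a configuration has an unexpected landmark count."""


class DegenerateConfigurationError(ValueError):
    """Raised when all landmarks coincide (centroid size would be 0)."""


@dataclass
class LandmarkConfiguration:
    """One specimen's landmark configuration.

    Parameters
    ----------
    specimen_id : str
        Identifier of the specimen (TPS ``ID=`` record).
    points : ndarray of shape (k, 2)
        Landmark coordinates in mm (scale already applied).
    scale : float
        mm-per-unit factor that was applied to the raw coordinates.
    extra_records : dict
        Unknown TPS keywords, preserved on round-trip.
    """

    specimen_id: str
    points: np.ndarray
    scale: float = 1.0
    image: str | None = None
    extra_records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise LandmarkSchemaError(
                f"{self.specimen_id}: points must be (k, 2), got {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinates")

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[0]

    def validate_scheme(self, n_landmarks: int = N_LANDMARKS) -> None:
        if self.n_landmarks != n_landmarks:
            raise LandmarkSchemaError(
                f"{self.specimen_id}: expected {n_landmarks} landmarks, "
                f"got {self.n_landmarks}"
            )


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    Invariant to translation and rotation; scales linearly under uniform
    scaling.  Raises :class:`DegenerateConfigurationError` if all points
    coincide.
    """
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centered = pts - pts.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0.0:
        raise DegenerateConfigurationError("all landmarks coincide; centroid size is 0")
    return cs


def read_tps(path, require_landmarks: int | None = N_LANDMARKS) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file.

    Supports ``LM=``, coordinate lines, and optional ``ID=``, ``IMAGE=`` and
    ``SCALE=`` records; keywords are case-insensitive, line endings may be LF
    or CRLF, and unknown ``KEY=value`` records are preserved.  Coordinates
    are multiplied by SCALE when present.  Set ``require_landmarks=None`` to
    accept arbitrary landmark counts.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]

    configs: list[LandmarkConfiguration] = []
    i = 0
    record_index = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSParseError(f"record {record_index}: expected LM=, got {line!r}")
        try:
            n_lm = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"record {record_index}: bad LM count {line!r}") from exc
        i += 1
        coords = []
        while i < len(lines) and len(coords) < n_lm:
            ln = lines[i].strip()
            if not ln:
                i += 1
                continue
            parts = ln.split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"record {record_index}: expected {n_lm} coordinate lines, "
                    f"found non-coordinate line {ln!r} after {len(coords)}"
                )
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TPSParseError(f"record {record_index}: bad coordinates {ln!r}") from exc
            i += 1
        if len(coords) != n_lm:
            raise TPSParseError(
                f"record {record_index}: LM={n_lm} but only {len(coords)} coordinate lines"
            )
        specimen_id = str(record_index)
        scale = 1.0
        image = None
        extra: dict[str, str] = {}
        while i < len(lines):
            ln = lines[i].strip()
            if not ln:
                i += 1
                continue
            if ln.upper().startswith("LM="):
                break
            if "=" not in ln:
                raise TPSParseError(f"record {record_index}: stray line {ln!r}")
            key, val = ln.split("=", 1)
            key_u = key.strip().upper()
            if key_u == "ID":
                specimen_id = val.strip()
            elif key_u == "SCALE":
                scale = float(val)
            elif key_u == "IMAGE":
                image = val.strip()
            else:
                extra[key.strip()] = val.strip()
            i += 1
        points = np.asarray(coords, float) * scale
        config = LandmarkConfiguration(
            specimen_id=specimen_id, points=points, scale=scale,
            image=image, extra_records=extra,
        )
        if require_landmarks is not None:
            config.validate_scheme(require_landmarks)
        configs.append(config)
        record_index += 1
    return configs


def write_tps(configs: list[LandmarkConfiguration], path) -> None:
    """Write configurations to a TPS file re-readable by :func:`read_tps`.

    Coordinates are divided by the stored scale so that SCALE round-trips.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for cfg in configs:
            fh.write(f"LM={cfg.n_landmarks}\n")
            raw = cfg.points / cfg.scale
            for x, y in raw:
                fh.write(f"{x:.6f} {y:.6f}\n")
            if cfg.image is not None:
                fh.write(f"IMAGE={cfg.image}\n")
            fh.write(f"ID={cfg.specimen_id}\n")
            if cfg.scale != 1.0:
                fh.write(f"SCALE={cfg.scale}\n")
            for key, val in cfg.extra_records.items():
                fh.write(f"{key}={val}\n")
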
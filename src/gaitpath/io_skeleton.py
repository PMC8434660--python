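"""Skeleton trajectory containers and the versioned CSV/JSON file dialects.

A recording is a stream of timestamped 25-joint skeletons expressed in the
sensor frame (x lateral, y vertical, z depth; meters, seconds).  The
container is array-backed — ``t`` (n,), ``xyz`` (n, 25, 3), ``state``
(n, 25) — with a per-frame view available through :meth:`SkeletonSequence.frames`.

File dialects (version 1):

* CSV — wide, one row per frame.  First line is a comment header declaring
  the dialect and version plus ``source_id``/``nominal_rate_hz``; then a
  normal header row with columns ``t``, ``<Joint>_x,_y,_z`` for all 25
  joints in canonical order, then ``<Joint>_state``.  Decimal point, comma
  separator, UTF-8.  Floats are written at full ``repr`` precision so a
  round trip is lossless.
* JSON — an object with ``format``, ``version``, ``source_id``,
  ``nominal_rate_hz``, ``joints`` (the vocabulary, in order) and ``frames``.

Missing / not-tracked joints carry their last-observed position plus the
``not_tracked`` flag rather than NaN, keeping downstream filters total.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .joints import JOINT_NAMES, JOINT_INDEX, N_JOINTS, STATE_CODE, TRACKING_STATES

CSV_MAGIC = "gaitpath-skeleton-csv"
JSON_MAGIC = "gaitpath-skeleton-json"
FORMAT_VERSION = 1

MAX_ABS_DEPTH_M = 10.0


@dataclass(frozen=True)
class SkeletonFrame:
    """One tracked skeleton: a timestamp plus 25 named joint positions."""

    t: float
    joints: dict[str, tuple[float, float, float]]
    tracked: dict[str, str]


@dataclass
class SessionMeta:
    """Clinical metadata attached to a recording session."""

    subject_id: str = ""
    paretic_side: Literal["left", "right", "none"] = "none"
    tug_time_s: float | None = None
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.paretic_side not in ("left", "right", "none"):
            raise ValidationError(f"paretic_side must be left/right/none, got {self.paretic_side!r}")
        if self.tug_time_s is not None and not self.tug_time_s > 0:
            raise ValidationError(f"tug_time_s must be > 0 when present, got {self.tug_time_s}")


@dataclass
class SkeletonSequence:
    """A validated, time-ordered 25-joint trajectory stream.

    Invariants (enforced by :meth:`validate`): strictly increasing
    timestamps; finite coordinates with |z| <= 10 m; state codes in
    {not_tracked, inferred, tracked}.
    """

    t: np.ndarray                     # (n,) seconds from recording start
    xyz: np.ndarray                   # (n, 25, 3) meters, canonical joint order
    state: np.ndarray                 # (n, 25) uint8 codes into TRACKING_STATES
    source_id: str = ""
    nominal_rate_hz: float = 30.0
    meta: SessionMeta = field(default_factory=SessionMeta)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.state is None:
            self.state = np.full(self.xyz.shape[:2], STATE_CODE["tracked"], dtype=np.uint8)
        self.state = np.asarray(self.state, dtype=np.uint8)
        self.validate()

    # -- structure ---------------------------------------------------------

    def __len__(self) -> int:
        return self.t.shape[0]

    def validate(self) -> None:
        n = self.t.shape[0]
        if self.xyz.shape != (n, N_JOINTS, 3):
            raise ValidationError(
                f"xyz shape {self.xyz.shape} does not match ({n}, {N_JOINTS}, 3)"
            )
        if self.state.shape != (n, N_JOINTS):
            raise ValidationError(f"state shape {self.state.shape} does not match ({n}, {N_JOINTS})")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            k = int(np.argmax(dt <= 0))
            raise ValidationError(
                f"timestamps not strictly increasing at frame {k + 1} "
                f"(t[{k}]={self.t[k]:.6f}, t[{k + 1}]={self.t[k + 1]:.6f})"
            )
        if not np.all(np.isfinite(self.xyz)):
            bad = np.argwhere(~np.isfinite(self.xyz))[0]
            raise ValidationError(f"non-finite coordinate at frame {bad[0]}, joint {JOINT_NAMES[bad[1]]}")
        zmax = float(np.abs(self.xyz[:, :, 2]).max(initial=0.0))
        if zmax > MAX_ABS_DEPTH_M:
            raise ValidationError(f"|z| exceeds {MAX_ABS_DEPTH_M} m (max {zmax:.3f} m)")
        if self.state.max(initial=0) >= len(TRACKING_STATES):
            raise ValidationError("unknown tracking-state code")

    # -- accessors ---------------------------------------------------------

    def joint(self, name: str) -> np.ndarray:
        """Return the (n, 3) trajectory of a named joint (a view)."""
        try:
            return self.xyz[:, JOINT_INDEX[name], :]
        except KeyError:
            raise ValidationError(f"unknown joint name {name!r}") from None

    def joint_state(self, name: str) -> np.ndarray:
        return self.state[:, JOINT_INDEX[name]]

    def tracked_fraction(self, name: str) -> float:
        """Fraction of frames in which the joint is not ``not_tracked``."""
        return float(np.mean(self.joint_state(name) != STATE_CODE["not_tracked"]))

    @property
    def frames(self) -> Iterator[SkeletonFrame]:
        for k in range(len(self)):
            yield SkeletonFrame(
                t=float(self.t[k]),
                joints={name: tuple(self.xyz[k, i]) for i, name in enumerate(JOINT_NAMES)},
                tracked={name: TRACKING_STATES[self.state[k, i]] for i, name in enumerate(JOINT_NAMES)},
            )

    def window(self, t_lo: float, t_hi: float) -> np.ndarray:
        """Boolean mask of frames with t in [t_lo, t_hi]."""
        return (self.t >= t_lo) & (self.t <= t_hi)

    def with_xyz(self, xyz: np.ndarray) -> "SkeletonSequence":
        return replace(self, xyz=np.asarray(xyz, dtype=float))


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _csv_columns() -> list[str]:
    cols = ["t"]
    for name in JOINT_NAMES:
        cols += [f"{name}_x", f"{name}_y", f"{name}_z"]
    cols += [f"{name}_state" for name in JOINT_NAMES]
    return cols


def _parse_header_line(line: str, magic: str) -> dict[str, str]:
    if not line.startswith("#"):
        raise FormatError(f"missing dialect header line (expected '# {magic} v{FORMAT_VERSION} ...')")
    tokens = line.lstrip("#").split()
    if not tokens or tokens[0] != magic:
        raise FormatError(f"wrong dialect magic {tokens[:1]} (expected {magic!r})")
    if len(tokens) < 2 or tokens[1] != f"v{FORMAT_VERSION}":
        raise FormatError(f"unsupported format version {tokens[1:2]} (expected v{FORMAT_VERSION})")
    kv: dict[str, str] = {}
    for tok in tokens[2:]:
        if "=" in tok:
            key, val = tok.split("=", 1)
            kv[key] = val
    return kv


def write_skeleton(seq: SkeletonSequence, path: str | Path, format: str | None = None) -> None:
    """Serialize a sequence to the versioned CSV or JSON dialect.

    The format is inferred from the file suffix when not given.  Round trip
    through :func:`read_skeleton` is lossless (coordinates exact, flags exact).
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if len(seq) == 0:
        raise ValidationError("refusing to serialize an empty sequence (no frames)")
    if fmt == "csv":
        _write_csv(seq, path)
    elif fmt == "json":
        _write_json(seq, path)
    else:
        raise FormatError(f"unknown skeleton format {fmt!r}")


def _write_csv(seq: SkeletonSequence, path: Path) -> None:
    n = len(seq)
    flat = seq.xyz.reshape(n, N_JOINTS * 3)
    data: dict[str, object] = {"t": seq.t}
    cols = _csv_columns()
    for j, col in enumerate(cols[1 : 1 + 3 * N_JOINTS]):
        data[col] = flat[:, j]
    for i, name in enumerate(JOINT_NAMES):
        data[f"{name}_state"] = [TRACKING_STATES[c] for c in seq.state[:, i]]
    df = pd.DataFrame(data, columns=cols)
    buf = io.StringIO()
    buf.write(
        f"# {CSV_MAGIC} v{FORMAT_VERSION} source_id={seq.source_id or '-'} "
        f"nominal_rate_hz={seq.nominal_rate_hz!r}\n"
    )
    # full-precision floats: repr round-trips exactly
    df.to_csv(buf, index=False, float_format=None)
    path.write_text(buf.getvalue(), encoding="utf-8")


def _write_json(seq: SkeletonSequence, path: Path) -> None:
    obj = {
        "format": JSON_MAGIC,
        "version": FORMAT_VERSION,
        "source_id": seq.source_id,
        "nominal_rate_hz": seq.nominal_rate_hz,
        "joints": list(JOINT_NAMES),
        "frames": [
            {
                "t": float(seq.t[k]),
                "xyz": seq.xyz[k].tolist(),
                "state": [TRACKING_STATES[c] for c in seq.state[k]],
            }
            for k in range(len(seq))
        ],
    }
    path.write_text(json.dumps(obj), encoding="utf-8")


def read_skeleton(path: str | Path, format: str | None = None) -> SkeletonSequence:
    """Read a skeleton recording written in the versioned CSV or JSON dialect.

    Frames are returned exactly as stored (no reordering, interpolation or
    dropping); a non-monotone timestamp raises a :class:`ValidationError`
    naming the first offending frame.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "json":
        return _read_json(path)
    raise FormatError(f"unknown skeleton format {fmt!r}")


def _read_csv(path: Path) -> SkeletonSequence:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        kv = _parse_header_line(header, CSV_MAGIC)
        df = pd.read_csv(fh)
    expected = _csv_columns()
    if list(df.columns) != expected:
        unknown = [c for c in df.columns if c not in expected]
        if unknown:
            raise ValidationError(f"unknown joint column(s): {unknown[:3]}")
        missing = [c for c in expected if c not in df.columns]
        raise FormatError(f"column set/order mismatch; first missing: {missing[:3]}")
    n = len(df)
    if n == 0:
        raise FormatError("file contains no frames")
    t = df["t"].to_numpy(dtype=float)
    xyz = df[expected[1 : 1 + 3 * N_JOINTS]].to_numpy(dtype=float).reshape(n, N_JOINTS, 3)
    state = np.empty((n, N_JOINTS), dtype=np.uint8)
    for i, name in enumerate(JOINT_NAMES):
        col = df[f"{name}_state"]
        try:
            state[:, i] = [STATE_CODE[s] for s in col]
        except KeyError as exc:
            raise ValidationError(f"unknown tracking state {exc.args[0]!r} for joint {name}") from None
    rate = float(kv.get("nominal_rate_hz", "30"))
    source = kv.get("source_id", "")
    source = "" if source == "-" else source
    return SkeletonSequence(t=t, xyz=xyz, state=state, source_id=source, nominal_rate_hz=rate)


def _read_json(path: Path) -> SkeletonSequence:
    try:
        obj = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed JSON: {exc}") from None
    if obj.get("format") != JSON_MAGIC:
        raise FormatError(f"wrong dialect magic {obj.get('format')!r}")
    if obj.get("version") != FORMAT_VERSION:
        raise FormatError(f"unsupported format version {obj.get('version')!r}")
    joints = obj.get("joints")
    if tuple(joints) != JOINT_NAMES:
        bad = [j for j in joints if j not in JOINT_INDEX]
        raise ValidationError(f"joint vocabulary mismatch; unknown: {bad[:3]}")
    frames = obj.get("frames", [])
    if not frames:
        raise FormatError("file contains no frames")
    n = len(frames)
    t = np.array([f["t"] for f in frames], dtype=float)
    xyz = np.array([f["xyz"] for f in frames], dtype=float)
    state = np.empty((n, N_JOINTS), dtype=np.uint8)
    for k, f in enumerate(frames):
        try:
            state[k] = [STATE_CODE[s] for s in f["state"]]
        except KeyError as exc:
            raise ValidationError(f"unknown tracking state {exc.args[0]!r} at frame {k}") from None
    return SkeletonSequence(
        t=t,
        xyz=xyz,
        state=state,
        source_id=obj.get("source_id", ""),
        nominal_rate_hz=float(obj.get("nominal_rate_hz", 30.0)),
    )
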
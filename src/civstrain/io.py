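"""Readers/writers and pipeline configuration.

Formats: grayscale PNG/TIFF images (8- or 16-bit, intensities mapped
linearly to [0, 1] on read), TSV vector fields (``x y u v corr flag``),
CSV strain curves (``segment,time_ms,eps_rr,eps_tt``) and landmark tracks
(``landmark,frame,x,y``), and JSON/YAML configuration.  Every artifact
writer can drop a JSON sidecar recording the full parameter set that
produced it, so any output is reproducible from its sidecar alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .civcore import CivParams, VectorField
from .exceptions import DataError, ParameterError
from .kinematics import LandmarkTrack, SegmentModel, StrainCurve
from .synthgen import AnalyticFlow, GridSpec

__all__ = [
    "read_image", "write_image", "read_field", "write_field",
    "read_landmarks", "write_landmarks", "write_curves", "read_curves",
    "read_mask", "load_config", "PipelineConfig", "write_sidecar",
]

FIELD_COLUMNS = ["x", "y", "u", "v", "corr", "flag"]


def read_image(path) -> np.ndarray:
    """Read a grayscale image and map intensities linearly onto [0, 1]."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:  # collapse RGB(A) by luminance-free average
        arr = arr[..., :3].mean(axis=-1)
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        return arr.astype(float) / scale
    out = arr.astype(float)
    if out.size and out.max() > 1.0:
        out = out / out.max()
    return out


def write_image(path, img, bits: int = 16) -> None:
    """Write a [0, 1] image as 8- or 16-bit grayscale PNG/TIFF."""
    if bits not in (8, 16):
        raise ParameterError(f"bits must be 8 or 16, got {bits}")
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    dtype = np.uint8 if bits == 8 else np.uint16
    scaled = np.round(arr * np.iinfo(dtype).max).astype(dtype)
    iio.imwrite(Path(path), scaled)


def read_mask(path) -> np.ndarray:
    """Read a binary mask image (any nonzero intensity counts as tissue)."""
    return read_image(path) > 0.5


def write_field(path, field: VectorField) -> None:
    """Write a vector field as TSV (``x y u v corr flag``, LF endings)."""
    df = field.to_dataframe()
    df.to_csv(Path(path), sep="\t", index=False, lineterminator="\n",
              float_format="%.6f")


def read_field(path) -> VectorField:
    """Read a TSV vector field; raises on malformed tables."""
    try:
        df = pd.read_csv(Path(path), sep="\t")
    except Exception as err:  # pragma: no cover - pandas error text varies
        raise DataError(f"cannot parse field file {path}: {err}") from err
    missing = [c for c in FIELD_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"field file {path} missing columns {missing}")
    return VectorField.from_dataframe(df)


def write_landmarks(path, track: LandmarkTrack) -> None:
    track.to_dataframe().to_csv(Path(path), index=False, lineterminator="\n")


def read_landmarks(path) -> np.ndarray:
    """Read a landmark CSV into a ``(n_frames, n_landmarks, 2)`` array.

    Every landmark must have exactly one position per frame; a missing
    frame raises a :class:`DataError` naming the landmark.
    """
    df = pd.read_csv(Path(path))
    for col in ("landmark", "frame", "x", "y"):
        if col not in df.columns:
            raise DataError(f"landmark file {path} missing column {col!r}")
    frames = sorted(df["frame"].unique())
    landmarks = sorted(df["landmark"].unique())
    out = np.full((len(frames), len(landmarks), 2), np.nan)
    fidx = {f: i for i, f in enumerate(frames)}
    lidx = {l: i for i, l in enumerate(landmarks)}
    for _, row in df.iterrows():
        out[fidx[row["frame"]], lidx[row["landmark"]]] = (row["x"], row["y"])
    for l in landmarks:
        got = df.loc[df["landmark"] == l, "frame"].tolist()
        lost = sorted(set(frames) - set(got))
        if lost:
            raise DataError(
                f"landmark {l} missing frame(s) {', '.join(str(f) for f in lost)}"
            )
    return out


def write_curves(path, curve: StrainCurve) -> None:
    curve.to_dataframe().to_csv(Path(path), index=False, lineterminator="\n",
                                float_format="%.6f")


def read_curves(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    for col in ("segment", "time_ms", "eps_rr", "eps_tt"):
        if col not in df.columns:
            raise DataError(f"curve file {path} missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class PipelineConfig:
    """Parameter groups for the end-to-end pipeline.

    Sections mirror the processing stages; unknown keys are rejected so
    that typos fail fast.  ``pairing_interval`` is the number of frames
    coalesced into one displacement-estimation pair (default 1 =
    consecutive frames); ``frame_interval_ms`` is the acquisition frame
    spacing used for strain-curve time axes.
    """

    grid: GridSpec = dataclasses.field(default_factory=GridSpec)
    flow: AnalyticFlow = dataclasses.field(default_factory=AnalyticFlow)
    civ: CivParams = dataclasses.field(default_factory=CivParams)
    extract: dict = dataclasses.field(default_factory=dict)
    segment_center: tuple[float, float] | None = None
    segment_level: str = "mid"
    reference_angle: float = -np.pi / 2.0
    pairing_interval: int = 1
    frame_interval_ms: float = 30.0
    frames: list[str] = dataclasses.field(default_factory=list)
    mask: str | None = None
    out_dir: str = "."
    log_level: str = "INFO"

    def segment_model(self) -> SegmentModel:
        if self.segment_center is None:
            raise ParameterError("segment_center is required for strain averaging")
        return SegmentModel(tuple(self.segment_center), self.segment_level,
                            self.reference_angle)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        sections = {"grid": GridSpec, "civ": CivParams}
        for key, typ in sections.items():
            if key in data:
                sub = data.pop(key)
                valid = {f.name for f in dataclasses.fields(typ)}
                bad = set(sub) - valid
                if bad:
                    raise ParameterError(f"unknown {key} config keys: {sorted(bad)}")
                kwargs[key] = typ(**sub)
        if "flow" in data:
            sub = dict(data.pop("flow"))
            cx = sub.pop("center_x", 256.0)
            cy = sub.pop("center_y", 256.0)
            sub.setdefault("center", (cx, cy))
            valid = {f.name for f in dataclasses.fields(AnalyticFlow)}
            bad = set(sub) - valid
            if bad:
                raise ParameterError(f"unknown flow config keys: {sorted(bad)}")
            kwargs["flow"] = AnalyticFlow(**sub)
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - valid
        if bad:
            raise ParameterError(f"unknown config keys: {sorted(bad)}")
        kwargs.update(data)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, (tuple, list)):
                return [enc(o) for o in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}


def load_config(path) -> PipelineConfig:
    """Load a YAML or JSON pipeline configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise DataError(f"config {path} must be a mapping")
    return PipelineConfig.from_dict(data)


def write_sidecar(artifact_path, parameters: dict) -> None:
    """Record the parameter set that produced an artifact next to it."""
    side = Path(str(artifact_path) + ".meta.json")
    side.write_text(json.dumps(parameters, indent=2, sort_keys=True,
                               default=str) + "\n")
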
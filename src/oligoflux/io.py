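"""Readers and writers for the pipeline's plain-text and TIFF interchange formats.

* ThT traces: long CSV (time_min, well, condition, replicate, signal) or the
  plate reader's wide export (time_min + one column per well).
* Binding titrations: CSV (concentration_uM, response).
* BLI sensorgrams: CSV (time_s, signal_nm, phase).
* Localizations: Thunderstorm-compatible CSV ("x [nm]", "y [nm]", frame,
  intensity).
* Image stacks: multi-page TIFF via :mod:`tifffile`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .binding import BindingCurve, BliTrace
from .exceptions import InvalidInputError
from .imaging import AggregateShape, ImageStack, LocalizationTable, SpotSet
from .kinetics import ThTTrace

THUNDERSTORM_COLUMNS = ["x [nm]", "y [nm]", "frame", "intensity"]


# -- ThT traces -------------------------------------------------------------


def write_traces_csv(traces: Sequence[ThTTrace], path) -> None:
    rows = []
    for i, tr in enumerate(traces):
        rows.append(
            pd.DataFrame(
                {
                    "time_min": tr.time,
                    "well": f"W{i:03d}",
                    "condition": tr.condition,
                    "replicate": tr.replicate,
                    "signal": tr.signal,
                    "normalized": tr.normalized,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path) -> list[ThTTrace]:
    df = pd.read_csv(path)
    required = {"time_min", "condition", "replicate", "signal"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"trace CSV must have columns {sorted(required)}")
    traces = []
    keys = ["condition", "replicate"] + (["well"] if "well" in df.columns else [])
    for _, grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("time_min")
        traces.append(
            ThTTrace(
                time=grp["time_min"].to_numpy(),
                signal=grp["signal"].to_numpy(),
                condition=str(grp["condition"].iloc[0]),
                replicate=int(grp["replicate"].iloc[0]),
                normalized=bool(grp["normalized"].iloc[0])
                if "normalized" in grp.columns
                else False,
            )
        )
    return traces


def read_platereader_wide(path, normalized: bool = False) -> list[ThTTrace]:
    """Read a wide plate-reader export: time_min + one column per well."""
    df = pd.read_csv(path)
    if "time_min" not in df.columns:
        raise InvalidInputError("wide CSV must have a 'time_min' column")
    t = df["time_min"].to_numpy(dtype=float)
    return [
        ThTTrace(time=t, signal=df[col].to_numpy(dtype=float), condition=col,
                 normalized=normalized)
        for col in df.columns
        if col != "time_min"
    ]


# -- binding ---------------------------------------------------------------


def write_binding_csv(curve: BindingCurve, path) -> None:
    pd.DataFrame({"concentration_uM": curve.x, "response": curve.y}).to_csv(
        path, index=False
    )


def read_binding_csv(path) -> BindingCurve:
    df = pd.read_csv(path)
    if not {"concentration_uM", "response"}.issubset(df.columns):
        raise InvalidInputError(
            "binding CSV must have concentration_uM and response columns"
        )
    return BindingCurve(
        x=df["concentration_uM"].to_numpy(), y=df["response"].to_numpy()
    )


def write_bli_csv(trace: BliTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.t, "signal_nm": trace.signal, "phase": trace.phase}
    ).to_csv(path, index=False)


def read_bli_csv(path) -> BliTrace:
    df = pd.read_csv(path)
    if not {"time_s", "signal_nm", "phase"}.issubset(df.columns):
        raise InvalidInputError("BLI CSV must have time_s, signal_nm, phase")
    return BliTrace(
        t=df["time_s"].to_numpy(),
        signal=df["signal_nm"].to_numpy(),
        phase=df["phase"].to_numpy(dtype=object),
    )


# -- imaging ---------------------------------------------------------------


def write_stack_tiff(stack: ImageStack, path) -> None:
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")


def read_stack_tiff(path, pixel_nm: float | None = None) -> ImageStack:
    frames = np.asarray(tifffile.imread(path), dtype=float)
    if frames.ndim == 2:
        frames = frames[None, ...]
    kwargs = {"pixel_nm": pixel_nm} if pixel_nm else {}
    return ImageStack(frames=frames, metadata={"source": str(path)}, **kwargs)


def write_localizations_csv(table: LocalizationTable, path) -> None:
    pd.DataFrame(
        {
            "x [nm]": table.x_nm,
            "y [nm]": table.y_nm,
            "frame": table.frame,
            "intensity": table.intensity,
        }
    ).to_csv(path, index=False)


def read_localizations_csv(path) -> LocalizationTable:
    df = pd.read_csv(path)
    if not set(THUNDERSTORM_COLUMNS).issubset(df.columns):
        raise InvalidInputError(
            f"localization CSV must have columns {THUNDERSTORM_COLUMNS}"
        )
    return LocalizationTable(
        x_nm=df["x [nm]"].to_numpy(),
        y_nm=df["y [nm]"].to_numpy(),
        frame=df["frame"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
    )


def write_spots_csv(spotsets: Sequence[SpotSet], path) -> None:
    rows = []
    for ss in spotsets:
        for r, c, v in ss.spots:
            rows.append({"fov_id": ss.fov_id, "row": r, "col": c, "intensity": v})
        if not ss.spots:
            rows.append(
                {"fov_id": ss.fov_id, "row": np.nan, "col": np.nan, "intensity": np.nan}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_shapes_csv(shapes: Sequence[AggregateShape], path) -> None:
    pd.DataFrame(
        [
            {
                "length_nm": s.length_nm,
                "area_nm2": s.area_nm2,
                "eccentricity": s.eccentricity,
                "circularity": s.circularity,
                "n_localizations": s.n_localizations,
                "degenerate": s.degenerate,
            }
            for s in shapes
        ]
    ).to_csv(path, index=False)
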
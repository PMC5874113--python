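"""Reading frames, writing traces/reports/plots, and run configuration."""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .analysis import Trace, ValidationReport
from .grids import ImageGrid

__all__ = [
    "RunConfig",
    "read_frames",
    "write_frames",
    "write_traces",
    "read_traces",
    "write_report",
    "plot_traces",
]

_FRAME_EXTENSIONS = (".png", ".tif", ".tiff")

# ITU-R BT.601 luminance weights for RGB -> single channel
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class RunConfig:
    """Validated configuration of a tracking run.

    Built from a plain-text YAML mapping; unknown keys are rejected so a
    typo in a config file fails loudly instead of silently using a
    default.
    """

    input_path: str = ""
    fps: float = 30.0
    pixel_scale_px_per_mm: float = 10.0
    k1: float = 0.0
    k2: float = 0.0
    n_levels: int = 3
    window_halfwidth: int = 7
    min_area_px: int = 25
    min_contrast: float = 0.1
    gate_threshold_mm: float = 5.0
    max_drift_mm: float = 1.0
    max_step_discrepancy_mm: float = 0.5
    output_dir: str = "out"
    seed: int = 0

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _to_intensity(arr: np.ndarray) -> np.ndarray:
    """Convert a decoded image to single-channel float in [0, 1]."""
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    return arr


def _numeric_key(path: Path) -> tuple:
    m = re.findall(r"\d+", path.stem)
    return (int(m[-1]) if m else 0, path.name)


def read_frames(
    source: str | Path,
    fps: float = 30.0,
    reader: Callable[[Path], Iterator[np.ndarray]] | None = None,
) -> list[ImageGrid]:
    """Read a frame sequence as single-channel float intensities in [0, 1].

    ``source`` is a directory of numbered PNG/TIFF frames (sorted by the
    trailing number in the file name), or any file a caller-supplied
    ``reader`` plugin can decode into an iterator of arrays (the hook
    for container video formats).  Timestamps are ``index / fps``.
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(f"input source does not exist: {source}")
    if source.is_dir():
        files = sorted(
            (p for p in source.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS),
            key=_numeric_key,
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {source}")
        frames = []
        for k, path in enumerate(files):
            try:
                arr = iio.imread(path)
            except Exception as exc:
                raise IOError(f"unreadable frame #{k} ({path.name}): {exc}") from exc
            frames.append(ImageGrid(_to_intensity(arr), k / fps))
        return frames
    if reader is not None:
        return [
            ImageGrid(_to_intensity(arr), k / fps)
            for k, arr in enumerate(reader(source))
        ]
    raise ValueError(
        f"{source} is not a frame directory; container video needs a reader plugin"
    )


def write_frames(frames: Sequence[ImageGrid], out_dir: str | Path) -> list[Path]:
    """Write frames as zero-padded 8-bit PNGs; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, frame in enumerate(frames):
        path = out_dir / f"frame_{k:06d}.png"
        data = np.clip(np.round(frame.pixels * 255.0), 0, 255).astype(np.uint8)
        iio.imwrite(path, data)
        paths.append(path)
    return paths


def traces_to_dataframe(
    traces: Sequence[Trace],
    positions_px: dict[int, np.ndarray] | None = None,
    statuses: dict[int, np.ndarray] | None = None,
    alerts: dict[int, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Long-format table: one row per marker per frame."""
    rows = []
    for tr in traces:
        n = tr.n_frames
        pos = positions_px.get(tr.marker_id) if positions_px else None
        stat = statuses.get(tr.marker_id) if statuses else None
        alert = alerts.get(tr.marker_id) if alerts else None
        for k in range(n):
            rows.append(
                {
                    "frame": k,
                    "time_s": tr.timestamps_s[k],
                    "marker_id": tr.marker_id,
                    "x_px": pos[k, 0] if pos is not None else np.nan,
                    "y_px": pos[k, 1] if pos is not None else np.nan,
                    "ap_mm": tr.displacement_mm.get("AP", np.full(n, np.nan))[k],
                    "si_mm": tr.displacement_mm.get("SI", np.full(n, np.nan))[k],
                    "lr_mm": tr.displacement_mm.get("LR", np.full(n, np.nan))[k],
                    "status": stat[k] if stat is not None else "ok",
                    "alert": bool(alert[k]) if alert is not None else False,
                }
            )
    return pd.DataFrame(rows)


def write_traces(
    traces: Sequence[Trace],
    out_dir: str | Path,
    report: ValidationReport | None = None,
    positions_px: dict[int, np.ndarray] | None = None,
    statuses: dict[int, np.ndarray] | None = None,
    alerts: dict[int, np.ndarray] | None = None,
    plot: bool = True,
) -> dict[str, Path]:
    """Write the run outputs: traces CSV, JSON report, trace plot."""
    if not traces:
        raise ValueError("no traces to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    df = traces_to_dataframe(traces, positions_px, statuses, alerts)
    csv_path = out_dir / "traces.csv"
    df.to_csv(csv_path, index=False, float_format="%.9g")
    outputs["traces"] = csv_path
    if report is not None:
        outputs["report"] = write_report(report, out_dir / "report.json")
    if plot:
        outputs["plot"] = plot_traces(traces, out_dir / "traces.png")
    return outputs


def read_traces(csv_path: str | Path) -> list[Trace]:
    """Rebuild traces from a traces CSV."""
    df = pd.read_csv(csv_path)
    traces = []
    for mid, group in df.groupby("marker_id"):
        group = group.sort_values("frame")
        disp = {}
        for ax, col in (("AP", "ap_mm"), ("SI", "si_mm"), ("LR", "lr_mm")):
            vals = group[col].to_numpy(dtype=np.float64)
            if np.any(np.isfinite(vals)):
                disp[ax] = vals
        traces.append(Trace(int(mid), group["time_s"].to_numpy(), disp))
    return traces


def write_report(report: ValidationReport, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    return path


def plot_traces(traces: Sequence[Trace], path: str | Path) -> Path:
    """Plot displacement per axis over time, one line per marker."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    axes_present = sorted({ax for tr in traces for ax in tr.axes})
    fig, axs = plt.subplots(
        len(axes_present), 1, figsize=(9, 2.5 * len(axes_present)), squeeze=False
    )
    for row, ax_name in enumerate(axes_present):
        ax = axs[row][0]
        for tr in traces:
            if ax_name in tr.displacement_mm:
                ax.plot(
                    tr.timestamps_s,
                    tr.displacement_mm[ax_name],
                    label=f"marker {tr.marker_id}",
                    lw=0.8,
                )
        ax.set_ylabel(f"{ax_name} (mm)")
        ax.legend(loc="upper right", fontsize=7)
    axs[-1][0].set_xlabel("time (s)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
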
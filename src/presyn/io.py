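"""Reading and writing of traces, stimulus protocols, image stacks and analysis
configuration.

All electrophysiology is carried in :class:`CurrentTrace` objects: uniformly
sampled membrane current in pA, inward currents negative, time origin at the
trace start.  Protocol times are absolute in trace time.  The on-disk trace
format is a two-column CSV (``time_s,current_pA``) with a JSON sidecar holding
the sampling rate, units and free-form metadata; an equivalent single-file
HDF5 container is also supported.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np


class TraceFormatError(Exception):
    """Raised when an on-disk trace/protocol file is malformed."""


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


class ConfigurationError(ValueError):
    """Raised when an analysis or simulation configuration is unusable."""


class NumericalError(ArithmeticError):
    """Raised when a numerical procedure fails (instability, divergence)."""


#: Standard post-train recovery test-pulse intervals (s after the train end).
STANDARD_RECOVERY_INTERVALS = (0.020, 0.050, 0.150, 0.350, 0.650, 1.150, 2.150, 4.150)


# ---------------------------------------------------------------------------
# CurrentTrace
# ---------------------------------------------------------------------------

@dataclass
class CurrentTrace:
    """Uniformly sampled membrane-current time series.

    Parameters
    ----------
    samples : ndarray
        Current in pA; inward currents are negative.
    sampling_rate : float
        Samples per second (Hz).
    start_time : float
        Time of the first sample (s); 0 by convention.
    channel_label : str
        Free-form channel name.
    metadata : dict
        Key-value annotations (holding potential, cell id, condition tags
        such as "EGTA", "TEA", "EnglerinA", drug windows, ...).
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    channel_label: str = "Im"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValidationError("trace needs at least 2 samples in a 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("trace contains non-finite samples")
        if not (self.sampling_rate > 0 and math.isfinite(self.sampling_rate)):
            raise ValidationError("sampling_rate must be positive and finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Trace duration in seconds (count / sampling rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Sample index of absolute time ``t`` (floor)."""
        return int(np.floor((t - self.start_time) * self.sampling_rate))

    def covers(self, t_end: float) -> bool:
        return t_end <= self.start_time + self.duration + 0.5 / self.sampling_rate

    def require_covers(self, t_end: float, what: str = "analysis window") -> None:
        if not self.covers(t_end):
            raise ValidationError(
                f"trace of duration {self.duration:.4f} s does not cover the "
                f"{what} ending at {t_end:.4f} s"
            )


def write_trace(trace: CurrentTrace, path) -> Path:
    """Write a trace as CSV + JSON sidecar (or single HDF5 if ``.h5``)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _write_trace_h5(trace, path)
    times = trace.times
    header = "time_s,current_pA"
    data = np.column_stack([times, trace.samples])
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.9g")
    sidecar = {
        "sampling_rate": trace.sampling_rate,
        "units": "pA",
        "start_time": trace.start_time,
        "channel_label": trace.channel_label,
        "metadata": trace.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_trace(path) -> CurrentTrace:
    """Read a trace written by :func:`write_trace`.

    The sidecar must declare ``sampling_rate`` and ``units`` ("pA" or "nA");
    nA samples are converted to pA on read.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_trace_h5(path)
    if not path.exists():
        raise TraceFormatError(f"trace file not found: {path}")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise TraceFormatError(f"missing JSON sidecar for {path}")
    sidecar = json.loads(sidecar_path.read_text())
    if "sampling_rate" not in sidecar or "units" not in sidecar:
        raise TraceFormatError("sidecar must declare sampling_rate and units")
    rate = float(sidecar["sampling_rate"])
    if not rate > 0:
        raise ValidationError("declared sampling_rate must be positive")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    samples = data[:, 1]
    units = sidecar["units"]
    if units == "nA":
        samples = samples * 1000.0
    elif units != "pA":
        raise TraceFormatError(f"unsupported current units {units!r}")
    return CurrentTrace(
        samples=samples,
        sampling_rate=rate,
        start_time=float(sidecar.get("start_time", 0.0)),
        channel_label=sidecar.get("channel_label", "Im"),
        metadata=sidecar.get("metadata", {}),
    )


def _write_trace_h5(trace: CurrentTrace, path: Path) -> Path:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("current_pA", data=trace.samples)
        d.attrs["sampling_rate"] = trace.sampling_rate
        d.attrs["units"] = "pA"
        d.attrs["start_time"] = trace.start_time
        d.attrs["channel_label"] = trace.channel_label
        f.attrs["metadata_json"] = json.dumps(trace.metadata)
    return path


def _read_trace_h5(path: Path) -> CurrentTrace:
    import h5py

    if not path.exists():
        raise TraceFormatError(f"trace file not found: {path}")
    with h5py.File(path, "r") as f:
        if "current_pA" not in f:
            raise TraceFormatError("HDF5 trace lacks a current_pA dataset")
        d = f["current_pA"]
        samples = d[...]
        if d.attrs.get("units", "pA") == "nA":
            samples = samples * 1000.0
        return CurrentTrace(
            samples=samples,
            sampling_rate=float(d.attrs["sampling_rate"]),
            start_time=float(d.attrs.get("start_time", 0.0)),
            channel_label=str(d.attrs.get("channel_label", "Im")),
            metadata=json.loads(f.attrs.get("metadata_json", "{}")),
        )


# ---------------------------------------------------------------------------
# StimulusProtocol
# ---------------------------------------------------------------------------

@dataclass
class StimulusProtocol:
    """Stimulation timing: AP train, recovery test pulses, drug/sucrose epochs.

    ``ap_times`` are the action-potential times of the high-frequency train
    (absolute, s).  ``recovery_intervals`` are measured from the end of the
    train (time of the last train AP); recovery test-pulse times are
    ``last_ap + interval``.
    """

    ap_times: np.ndarray
    train_frequency: float = 20.0
    train_count: Optional[int] = None
    recovery_intervals: tuple = ()
    sucrose_window: Optional[tuple] = None
    drug_windows: list = field(default_factory=list)
    basal_frequency: float = 0.2

    def __post_init__(self):
        self.ap_times = np.asarray(self.ap_times, dtype=float)
        if self.train_count is None:
            self.train_count = int(self.ap_times.size)
        if self.ap_times.size:
            if np.any(np.diff(self.ap_times) <= 0):
                raise ValidationError("ap_times must be strictly increasing")
            if self.train_count >= 2 and self.train_frequency > 0:
                isi = np.diff(self.ap_times[: self.train_count])
                if np.any(np.abs(isi - 1.0 / self.train_frequency) > 1e-6 + 1e-3 / self.train_frequency):
                    raise ValidationError(
                        "train ap_times inconsistent with train_frequency"
                    )
        elif self.train_count:
            raise ValidationError("train_count > 0 but no ap_times given")
        ivals = tuple(float(v) for v in self.recovery_intervals)
        if ivals:
            if any(v <= 0 for v in ivals) or any(
                b <= a for a, b in zip(ivals, ivals[1:])
            ):
                raise ValidationError("recovery_intervals must be positive and strictly increasing")
        self.recovery_intervals = ivals
        wins = [(str(lbl), float(a), float(b)) for (lbl, a, b) in self.drug_windows]
        for lbl, a, b in wins:
            if b <= a:
                raise ValidationError(f"drug window {lbl!r} has non-positive length")
        for i, (_, a1, b1) in enumerate(wins):
            for _, a2, b2 in wins[i + 1:]:
                if a1 < b2 and a2 < b1:
                    raise ValidationError("drug windows overlap")
        self.drug_windows = wins
        if self.sucrose_window is not None:
            a, b = self.sucrose_window
            if not b > a:
                raise ValidationError("sucrose_window must have positive length")
            self.sucrose_window = (float(a), float(b))

    @classmethod
    def train(
        cls,
        frequency: float = 20.0,
        count: int = 40,
        t0: float = 0.1,
        recovery_intervals: Sequence[float] = (),
        **kw,
    ) -> "StimulusProtocol":
        """Regular AP train: ``count`` APs at ``frequency`` starting at ``t0``."""
        if count < 1:
            raise ValidationError("train count must be >= 1")
        if frequency <= 0:
            raise ValidationError("train frequency must be positive")
        ap = t0 + np.arange(count) / frequency
        return cls(
            ap_times=ap,
            train_frequency=frequency,
            train_count=count,
            recovery_intervals=tuple(recovery_intervals),
            **kw,
        )

    @property
    def train_end(self) -> float:
        """Time of the last train AP (s)."""
        return float(self.ap_times[self.train_count - 1])

    @property
    def recovery_times(self) -> np.ndarray:
        return self.train_end + np.asarray(self.recovery_intervals)

    @property
    def interstimulus_interval(self) -> float:
        return 1.0 / self.train_frequency

    def duration_needed(self) -> float:
        """End of the last window any analysis of this protocol touches."""
        t = 0.0
        if self.ap_times.size:
            t = self.train_end + self.interstimulus_interval
        if self.recovery_intervals:
            t = max(t, float(self.recovery_times[-1]) + 0.05)
        if self.sucrose_window:
            t = max(t, self.sucrose_window[1])
        for _, _, b in self.drug_windows:
            t = max(t, b)
        return t

    def to_json(self) -> dict:
        return {
            "ap_times": list(map(float, self.ap_times)),
            "train_frequency": self.train_frequency,
            "train_count": self.train_count,
            "recovery_intervals": list(self.recovery_intervals),
            "sucrose_window": list(self.sucrose_window) if self.sucrose_window else None,
            "drug_windows": [list(w) for w in self.drug_windows],
            "basal_frequency": self.basal_frequency,
        }


def load_protocol(path_or_dict) -> StimulusProtocol:
    """Load a protocol from JSON.

    Two forms are accepted: explicit fields (``ap_times`` etc.) or the
    shorthand ``{"train": {"frequency": 20, "count": 40, "t0": 0.1}}``.  The
    shorthand key ``"recovery": "standard"`` expands to the eight standard
    test-pulse intervals, 20 ms to 4.15 s.
    """
    if isinstance(path_or_dict, dict):
        doc = path_or_dict
    else:
        doc = json.loads(Path(path_or_dict).read_text())
    doc = dict(doc)
    recovery = doc.pop("recovery", doc.pop("recovery_intervals", ()))
    if isinstance(recovery, str):
        if recovery in ("standard", "default"):
            recovery = STANDARD_RECOVERY_INTERVALS
        else:
            raise TraceFormatError(f"unknown recovery shorthand {recovery!r}")
    if "train" in doc:
        tr = doc.pop("train")
        return StimulusProtocol.train(
            frequency=float(tr.get("frequency", tr.get("freq", 20.0))),
            count=int(tr["count"]),
            t0=float(tr.get("t0", 0.1)),
            recovery_intervals=recovery,
            sucrose_window=tuple(doc["sucrose_window"]) if doc.get("sucrose_window") else None,
            drug_windows=[tuple(w) for w in doc.get("drug_windows", [])],
            basal_frequency=float(doc.get("basal_frequency", 0.2)),
        )
    return StimulusProtocol(
        ap_times=np.asarray(doc.get("ap_times", []), dtype=float),
        train_frequency=float(doc.get("train_frequency", 20.0)),
        train_count=doc.get("train_count"),
        recovery_intervals=recovery,
        sucrose_window=tuple(doc["sucrose_window"]) if doc.get("sucrose_window") else None,
        drug_windows=[tuple(w) for w in doc.get("drug_windows", [])],
        basal_frequency=float(doc.get("basal_frequency", 0.2)),
    )


def write_protocol(protocol: StimulusProtocol, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(protocol.to_json(), indent=1))
    return path


# ---------------------------------------------------------------------------
# ImagingStack
# ---------------------------------------------------------------------------

@dataclass
class ImagingStack:
    """Multi-frame fluorescence stack (frame, row, col), counts >= 0."""

    frames: np.ndarray
    frame_rate: float = 5.0
    prestimulus_frames: int = 3
    pixel_size: float = 0.4  # um

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be a 3-D (frame, row, col) array")
        if self.frames.shape[0] < self.prestimulus_frames + 1:
            raise ValidationError("stack must extend beyond the prestimulus frames")
        if np.any(self.frames < 0) or not np.all(np.isfinite(self.frames)):
            raise ValidationError("pixel values must be finite and >= 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


def write_stack(stack: ImagingStack, path) -> Path:
    import tifffile

    path = Path(path)
    tifffile.imwrite(
        path,
        stack.frames.astype(np.float32),
        metadata={
            "frame_rate": stack.frame_rate,
            "prestimulus_frames": stack.prestimulus_frames,
            "pixel_size": stack.pixel_size,
        },
    )
    return path


def read_stack(path, frame_rate: float = 5.0, prestimulus_frames: int = 3,
               pixel_size: float = 0.4) -> ImagingStack:
    import tifffile

    path = Path(path)
    if not path.exists():
        raise TraceFormatError(f"stack file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    return ImagingStack(
        frames=np.atleast_3d(frames) if frames.ndim == 3 else frames[None],
        frame_rate=float(meta.get("frame_rate", frame_rate)),
        prestimulus_frames=int(meta.get("prestimulus_frames", prestimulus_frames)),
        pixel_size=float(meta.get("pixel_size", pixel_size)),
    )


# ---------------------------------------------------------------------------
# AnalysisConfig
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Fixed analysis constants.

    The defaults encode the standard measurement conventions used throughout
    the package: back-extrapolation over the last 5 cumulative points, a 5-ms
    steady-state window at the end of each interstimulus interval, mEPSC
    acceptance at 5x the baseline noise SD plus a 25-fC charge criterion,
    4x4-pixel imaging ROIs with a 3-SD responsiveness threshold, and
    during-/post-train fluorescence slopes over data points 6-13 and 14-20
    (1-based, whole acquired series).
    """

    regression_points_sync: int = 5
    regression_points_total: int = 5
    steady_state_window: float = 0.005  # s, end of each interstimulus interval
    amplitude_search_window: float = 0.010  # s after each AP
    artifact_blank: float = 0.001  # s blanked after each AP
    baseline_window: float = 0.001  # s of pre-stimulus baseline
    amplitude_baseline: str = "local"  # "local" or "global"
    steady_state_tolerance: float = 0.15
    mini_amp_sd_mult: float = 5.0
    mini_charge_min: float = 25.0  # fC
    mini_deriv_sd_mult: float = 3.5
    mini_refractory: float = 0.002  # s
    mini_charge_cap: float = 0.050  # s integration cap
    mini_smooth_sigma: float = 0.0003  # s
    responder_fold_threshold: float = 1.2
    dff_roi_size: int = 4
    dff_sd_mult: float = 3.0
    slope_hfs_points: tuple = (6, 13)
    slope_post_points: tuple = (14, 20)

    def __post_init__(self):
        for name in ("steady_state_window", "amplitude_search_window",
                     "baseline_window", "mini_refractory", "mini_charge_cap"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.artifact_blank < 0:
            raise ConfigurationError("artifact_blank must be >= 0")
        if self.regression_points_sync < 2 or self.regression_points_total < 2:
            raise ConfigurationError("regression point counts must be >= 2")
        if self.amplitude_baseline not in ("local", "global"):
            raise ConfigurationError("amplitude_baseline must be 'local' or 'global'")
        self.slope_hfs_points = tuple(int(v) for v in self.slope_hfs_points)
        self.slope_post_points = tuple(int(v) for v in self.slope_post_points)

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["slope_hfs_points"] = list(self.slope_hfs_points)
        d["slope_post_points"] = list(self.slope_post_points)
        return d

    @classmethod
    def from_json(cls, doc) -> "AnalysisConfig":
        if not isinstance(doc, dict):
            doc = json.loads(Path(doc).read_text())
        return cls(**doc)


def load_config(path_or_dict) -> AnalysisConfig:
    return AnalysisConfig.from_json(path_or_dict)
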
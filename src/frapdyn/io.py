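"""Reading, background correction and normalization of FRAP intensity traces.

The pipeline starts at intensity tables (one ROI trace and one background
trace per cell); extracting intensities from images is out of scope.  Two
normalizations are provided, both matching the conventions used for
confocal photobleaching series:

* percent-of-prebleach: ``ROI(t) = (I_t - I_bg) / (I_o - I_bg) * 100`` with
  I_o the mean pre-bleach ROI intensity and I_bg the background measured
  outside the nucleus;
* full-scale: ``F_norm(t) = (F(t) - F0) / (F_prebleach - F0)`` on
  background-corrected intensities, so the bleach nadir maps to 0 and full
  recovery to 1.  This is the form the two-state model is fitted to.

Background correction is applied frame-wise before either normalization.
The pre-bleach reference is the mean over all pre-bleach frames.  F0 is the
first post-bleach frame (the bleach, ~30 ms, is collapsed to the instant
t = 0).  No acquisition-photofading correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FrapTrace",
    "NormalizedCurve",
    "MeanCurve",
    "FormatError",
    "TraceValidationError",
    "DegenerateTraceError",
    "read_frap_traces",
    "roi_percent",
    "normalize_full_scale",
    "average_curves",
    "write_normalized_curves",
]

MIN_PREBLEACH_FRAMES = 2
MIN_POSTBLEACH_FRAMES = 10


class FormatError(ValueError):
    """Input table does not have the expected columns/layout."""


class TraceValidationError(ValueError):
    """A trace violates the FrapTrace invariants."""


class DegenerateTraceError(ValueError):
    """A trace carries no usable bleach signal (no intensity drop)."""


@dataclass
class FrapTrace:
    """Raw per-cell FRAP intensity time series.

    Times are in seconds with the bleach event at t = 0: pre-bleach frames
    have t < 0, post-bleach frames t >= 0 (the first post-bleach frame is
    the bleach nadir).  ``roi_intensity`` and ``bg_intensity`` are
    fluorescence counts per frame, same length as ``time_s``.
    """

    cell_id: str
    time_s: np.ndarray
    roi_intensity: np.ndarray
    bg_intensity: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.roi_intensity = np.asarray(self.roi_intensity, dtype=float)
        self.bg_intensity = np.asarray(self.bg_intensity, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.time_s)
        if len(self.roi_intensity) != n or len(self.bg_intensity) != n:
            raise TraceValidationError(
                f"{self.cell_id}: intensity arrays must match time length {n}"
            )
        for name, a in (
            ("time_s", self.time_s),
            ("roi_intensity", self.roi_intensity),
            ("bg_intensity", self.bg_intensity),
        ):
            if not np.all(np.isfinite(a)):
                raise TraceValidationError(f"{self.cell_id}: {name} has non-finite values")
        if np.any(self.roi_intensity < 0) or np.any(self.bg_intensity < 0):
            raise TraceValidationError(f"{self.cell_id}: negative intensities")
        if np.any(np.diff(self.time_s) <= 0):
            raise TraceValidationError(f"{self.cell_id}: time_s not strictly increasing")
        if self.n_prebleach < MIN_PREBLEACH_FRAMES:
            raise TraceValidationError(
                f"{self.cell_id}: need >= {MIN_PREBLEACH_FRAMES} pre-bleach frames, "
                f"got {self.n_prebleach}"
            )
        if self.n_postbleach < MIN_POSTBLEACH_FRAMES:
            raise TraceValidationError(
                f"{self.cell_id}: need >= {MIN_POSTBLEACH_FRAMES} post-bleach frames, "
                f"got {self.n_postbleach}"
            )

    @property
    def prebleach_mask(self) -> np.ndarray:
        return self.time_s < 0

    @property
    def n_prebleach(self) -> int:
        return int(np.sum(self.time_s < 0))

    @property
    def n_postbleach(self) -> int:
        return int(np.sum(self.time_s >= 0))


@dataclass
class NormalizedCurve:
    """Full-scale-normalized post-bleach recovery curve of one cell.

    ``f_norm`` is 0 at the first post-bleach frame by construction and
    approaches the mobile fraction at long times.  ``time_s`` is re-zeroed
    so the bleach event is t = 0.
    """

    cell_id: str
    time_s: np.ndarray
    f_norm: np.ndarray
    f_prebleach: float
    f_zero: float
    n_prebleach_frames: int
    condition: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f_norm = np.asarray(self.f_norm, dtype=float)
        if len(self.time_s) != len(self.f_norm):
            raise TraceValidationError(f"{self.cell_id}: time/f_norm length mismatch")
        if not np.all(np.isfinite(self.f_norm)):
            raise TraceValidationError(f"{self.cell_id}: non-finite f_norm")


@dataclass
class MeanCurve:
    """Pointwise mean of several normalized curves on a common time grid."""

    time_s: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int
    cell_ids: list = field(default_factory=list)


_DEFAULT_DIALECT = {
    "cell_id": "cell_id",
    "time_s": "time_s",
    "roi": "roi",
    "background": "background",
    "phase": "phase",
    "condition": "condition",
}


def read_frap_traces(path, dialect: dict | None = None):
    """Read per-cell FRAP traces from a long-format CSV.

    The file must have a header row with columns mappable (via ``dialect``,
    a {canonical: actual} column-name mapping) to ``cell_id``, ``time_s``,
    ``roi`` and ``background``.  Pre/post phases are taken from a ``phase``
    column (values ``pre``/``post``) when present, from a declared
    ``bleach_index`` in the dialect otherwise, or inferred from the sign of
    ``time_s``.  Times are shifted so the first post-bleach frame is t = 0.

    Traces violating the FrapTrace invariants are skipped and reported,
    never silently dropped.

    Returns
    -------
    traces : list of FrapTrace
    rejected : list of dict
        One record ``{"cell_id": ..., "reason": ...}`` per skipped trace.
    """
    d = dict(_DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    bleach_index = d.pop("bleach_index", None)
    layout = d.pop("format", "long")

    df = pd.read_csv(path)
    if layout == "wide":
        # one time column, one shared background column, one ROI column per
        # cell; phases from bleach_index or the sign of time
        for key in ("time_s", "background"):
            if d[key] not in df.columns:
                raise FormatError(f"missing mandatory column '{d[key]}' (maps to {key})")
        cells = [c for c in df.columns if c not in (d["time_s"], d["background"])]
        if not cells:
            raise FormatError("wide format needs at least one cell column")
        df = df.melt(
            id_vars=[d["time_s"], d["background"]],
            value_vars=cells,
            var_name=d["cell_id"],
            value_name=d["roi"],
        )
    for key in ("cell_id", "time_s", "roi", "background"):
        if d[key] not in df.columns:
            raise FormatError(f"missing mandatory column '{d[key]}' (maps to {key})")

    has_phase = d["phase"] in df.columns
    has_condition = d["condition"] in df.columns

    traces: list[FrapTrace] = []
    rejected: list[dict] = []
    for cell_id, g in df.groupby(d["cell_id"], sort=False):
        time = g[d["time_s"]].to_numpy(dtype=float)
        roi = g[d["roi"]].to_numpy(dtype=float)
        bg = g[d["background"]].to_numpy(dtype=float)
        condition = str(g[d["condition"]].iloc[0]) if has_condition else ""
        try:
            if has_phase:
                phase = g[d["phase"]].astype(str).str.lower().to_numpy()
                post = phase == "post"
                if not post.any():
                    raise TraceValidationError(f"{cell_id}: no post-bleach frames")
                t0 = time[post][0]
            elif bleach_index is not None:
                t0 = time[int(bleach_index)]
            else:
                nonneg = time >= 0
                if not nonneg.any():
                    raise TraceValidationError(f"{cell_id}: no post-bleach frames")
                t0 = time[nonneg][0]
            trace = FrapTrace(
                cell_id=str(cell_id),
                time_s=time - t0,
                roi_intensity=roi,
                bg_intensity=bg,
                condition=condition,
            )
            traces.append(trace)
        except TraceValidationError as exc:
            rejected.append({"cell_id": str(cell_id), "reason": str(exc)})
    return traces, rejected


def roi_percent(trace: FrapTrace) -> np.ndarray:
    """Percent-of-prebleach normalization ``(I_t - I_bg)/(I_o - I_bg) * 100``.

    I_o is the mean ROI intensity over the pre-bleach frames and the
    denominator background is the mean pre-bleach background; the numerator
    is background-corrected frame-wise.  Returned for all frames, pre- and
    post-bleach.
    """
    pre = trace.prebleach_mask
    i_o = float(np.mean(trace.roi_intensity[pre]))
    bg_ref = float(np.mean(trace.bg_intensity[pre]))
    denom = i_o - bg_ref
    if denom <= 0:
        raise DegenerateTraceError(
            f"{trace.cell_id}: pre-bleach ROI intensity ({i_o:.3g}) does not exceed "
            f"background ({bg_ref:.3g})"
        )
    return (trace.roi_intensity - trace.bg_intensity) / denom * 100.0


def normalize_full_scale(trace: FrapTrace) -> NormalizedCurve:
    """Full-scale normalization ``F_norm(t) = (F(t) - F0)/(F_prebleach - F0)``.

    F is the background-corrected intensity, F_prebleach the mean over all
    pre-bleach frames and F0 the first post-bleach frame.  Only post-bleach
    frames are returned, with times re-zeroed to the bleach event.

    Raises
    ------
    DegenerateTraceError
        If F_prebleach <= F0, i.e. no bleach-induced intensity drop.
    """
    f = trace.roi_intensity - trace.bg_intensity
    pre = trace.prebleach_mask
    post = ~pre
    f_prebleach = float(np.mean(f[pre]))
    f_post = f[post]
    t_post = trace.time_s[post]
    f_zero = float(f_post[0])
    if f_prebleach <= f_zero:
        raise DegenerateTraceError(
            f"{trace.cell_id}: no bleach detected (F_prebleach={f_prebleach:.4g} "
            f"<= F0={f_zero:.4g})"
        )
    f_norm = (f_post - f_zero) / (f_prebleach - f_zero)
    return NormalizedCurve(
        cell_id=trace.cell_id,
        time_s=t_post - t_post[0],
        f_norm=f_norm,
        f_prebleach=f_prebleach,
        f_zero=f_zero,
        n_prebleach_frames=int(np.sum(pre)),
        condition=trace.condition,
    )


def average_curves(curves) -> MeanCurve:
    """Pointwise mean, sample SD and n of curves sharing one time grid.

    Resampling is out of scope: curves on mismatched grids raise a
    ValueError naming the offending cells.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    ref = curves[0].time_s
    bad = [
        c.cell_id
        for c in curves[1:]
        if len(c.time_s) != len(ref) or not np.allclose(c.time_s, ref, atol=1e-9)
    ]
    if bad:
        raise ValueError(f"curves on mismatched time grids: {bad}")
    stack = np.vstack([c.f_norm for c in curves])
    sd = stack.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros_like(ref)
    return MeanCurve(
        time_s=ref.copy(),
        mean=stack.mean(axis=0),
        sd=sd,
        n=len(curves),
        cell_ids=[c.cell_id for c in curves],
    )


def write_normalized_curves(curves, path) -> None:
    """Write normalized curves to CSV (cell_id,time_s,f_norm)."""
    rows = []
    for c in curves:
        rows.append(
            pd.DataFrame(
                {"cell_id": c.cell_id, "time_s": c.time_s, "f_norm": c.f_norm}
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
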
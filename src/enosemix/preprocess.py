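"""Response segmentation and maximum-variation-rate feature extraction.

The pipeline turns each raw sensor-array recording into one normalized
8 x n x n feature tensor per exposure cycle:

1. per channel, find strict local maxima of the response series;
2. cluster peaks whose index gap is below a threshold (set by the sampling
   rate and the recovery time), keeping each cluster's largest peak — one
   peak per exposure cycle;
3. slice a fixed window around each max peak (left offset into the response
   phase, right offset into early recovery);
4. within each slice, scan a sliding window of width w (a perfect square)
   and keep the start that maximizes the variation rate
   ``R_t = (1/w) * sum_{i=t}^{t+w-1} |y[i+1] - y[i]|``;
5. min-max normalize each selected window onto [0, 1] and reshape it
   row-major to sqrt(w) x sqrt(w); stack the 8 channels.

All indices are 0-based with half-open ranges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import peak_prominences

from .simulate import SensorArrayRecording, classify_composition, scheme_label

logger = logging.getLogger(__name__)


class DegenerateWindowError(ValueError):
    """A feature window is constant, so min-max normalization is undefined."""


@dataclass(frozen=True)
class PeakSet:
    """Strict local maxima of one series (endpoints excluded)."""
    indices: np.ndarray        # strictly increasing sample indices
    source_length: int


@dataclass(frozen=True)
class PeakGrouping:
    """Partition of a PeakSet into runs of nearby peaks."""
    groups: tuple[tuple[int, ...], ...]
    d_threshold: int


@dataclass(frozen=True)
class ResponseSegment:
    """A slice y[pmax - loffset : pmax + roffset) around one cycle's max peak."""
    pmax: int
    loffset: int
    roffset: int
    values: np.ndarray

    def __post_init__(self):
        assert len(self.values) == self.loffset + self.roffset


@dataclass(frozen=True)
class FeatureWindow:
    """The maximum-variation-rate window within one segment."""
    tmax: int                  # start index within the segment
    width: int                 # w = n**2 samples
    step: int
    rate: float                # R_t at tmax
    values: np.ndarray


@dataclass
class LabeledSample:
    """One training example: 8 x n x n tensor + class + ppm target pair.

    `conc` is ordered (propanol_ppm, ethanol_ppm), matching the regression
    head and the per-task losses.
    """
    tensor: np.ndarray
    label: int
    conc: tuple[float, float]
    scheme_id: str
    repeat_index: int
    cycle_index: int


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable constants of the featurization pipeline.

    Defaults correspond to 2 Hz sampling with 5 min exposure / 5 min
    recovery: the left offset covers the whole 600-sample response phase
    plus margin, the right offset reaches into early recovery where the
    settled response level still separates mixing ratios, and the peak
    cluster threshold equals the 600-sample recovery phase.
    """
    loffset: int = 700
    roffset: int = 400
    d_threshold: int = 600
    window: int = 256                  # w, a perfect square
    step_s: float = 0.5                # sliding-window step in seconds
    prominence_rel: float | None = 0.05  # min peak prominence, fraction of range

    def step_samples(self, sample_rate_hz: float) -> int:
        return max(1, int(round(self.step_s * sample_rate_hz)))


# -- stage operations ------------------------------------------------------

def detect_peaks(y: np.ndarray, prominence: float | None = None) -> PeakSet:
    """Indices i with y[i] > y[i-1] and y[i] > y[i+1] (strict on both sides).

    Endpoints never qualify; plateau tops are not peaks.  If `prominence`
    is given, peaks whose topographic prominence falls below it are
    discarded (useful on noisy series where every wiggle is a strict local
    maximum).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("series must be 1-D with at least 3 samples")
    core = y[1:-1]
    mask = (core > y[:-2]) & (core > y[2:])
    idx = np.nonzero(mask)[0] + 1
    if prominence is not None and len(idx) > 0:
        prom = peak_prominences(y, idx)[0]
        idx = idx[prom >= prominence]
    return PeakSet(indices=idx, source_length=len(y))


def group_peaks(peaks: PeakSet, d_threshold: int) -> PeakGrouping:
    """Greedy left-to-right clustering: a new group starts whenever the gap
    to the previous peak is >= d_threshold."""
    if d_threshold <= 0:
        raise ValueError("d_threshold must be positive")
    idx = peaks.indices
    if len(idx) == 0:
        return PeakGrouping(groups=(), d_threshold=d_threshold)
    cuts = np.nonzero(np.diff(idx) >= d_threshold)[0] + 1
    groups = tuple(tuple(int(i) for i in part) for part in np.split(idx, cuts))
    return PeakGrouping(groups=groups, d_threshold=d_threshold)


def max_peak_per_group(grouping: PeakGrouping, y: np.ndarray) -> list[int]:
    """The argmax-of-y peak in each group; ties go to the smallest index."""
    y = np.asarray(y, dtype=float)
    out = []
    for g in grouping.groups:
        vals = y[list(g)]
        out.append(int(g[int(np.argmax(vals))]))  # np.argmax: first max wins
    return out


def extract_segments(
    y: np.ndarray,
    pmax_list: list[int],
    loffset: int = 700,
    roffset: int = 400,
) -> list[ResponseSegment]:
    """Slice y[pmax - loffset : pmax + roffset) around each max peak.

    Peaks too close to either end of the series are skipped (and logged),
    never padded — padding would fabricate response values.
    """
    if loffset <= 0 or roffset <= 0:
        raise ValueError("offsets must be positive")
    y = np.asarray(y, dtype=float)
    segments = []
    for pmax in pmax_list:
        lo, hi = pmax - loffset, pmax + roffset
        if lo < 0 or hi > len(y):
            logger.warning("segment at pmax=%d clipped by boundary, skipped", pmax)
            continue
        segments.append(ResponseSegment(pmax=int(pmax), loffset=loffset,
                                        roffset=roffset, values=y[lo:hi].copy()))
    return segments


def max_variation_window(values: np.ndarray, w: int, step: int = 1) -> FeatureWindow:
    """The width-w window with the largest mean absolute one-step variation.

    The rate at start t sums the w absolute first differences
    |y[i+1] - y[i]| for i in [t, t+w), so a series of at least w+1 samples
    is required; the extracted values are the w points y[t : t+w).  Ties go
    to the smallest admissible t.

    Any positive width is accepted here; the perfect-square constraint is
    enforced where windows are reshaped into feature layers.
    """
    y = np.asarray(values, dtype=float)
    if w < 1:
        raise ValueError("window width must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    if len(y) < w + 1:
        raise ValueError(f"segment of {len(y)} samples is shorter than w+1={w + 1}")
    cum = np.concatenate(([0.0], np.cumsum(np.abs(np.diff(y)))))
    starts = np.arange(0, len(y) - w, step)
    rates = (cum[starts + w] - cum[starts]) / w
    best = int(starts[int(np.argmax(rates))])
    return FeatureWindow(tmax=best, width=w, step=step,
                         rate=float(rates[int(np.argmax(rates))]),
                         values=y[best:best + w].copy())


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Affine map onto [0, 1]: min -> 0, max -> 1."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise DegenerateWindowError("constant window: min equals max")
    return (v - lo) / (hi - lo)


def assemble_tensor(windows: np.ndarray) -> np.ndarray:
    """Stack 8 normalized windows of length w = n*n into an 8 x n x n tensor.

    Each window is reshaped row-major; channel order is the fixed sensor
    order of the array.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 2:
        raise ValueError("expected a 2-D array of per-sensor windows")
    c, w = windows.shape
    n = int(math.isqrt(w))
    if n * n != w:
        raise ValueError(f"window length {w} is not a perfect square")
    return windows.reshape(c, n, n)


# -- recording-level pipeline ---------------------------------------------

def featurize_recording(
    rec: SensorArrayRecording,
    params: PreprocessParams = PreprocessParams(),
    label_by: str = "composition",
) -> list[LabeledSample]:
    """Run the full per-channel pipeline on one recording.

    Peaks are detected independently per sensor; cycles are paired across
    sensors by order and labeled by locating the first sensor's max peak in
    the recording's concentration schedule.
    """
    step = params.step_samples(rec.sample_rate_hz)
    per_sensor: list[list[ResponseSegment]] = []
    for si in range(rec.n_sensors):
        y = rec.response[si]
        prom = None
        if params.prominence_rel is not None:
            prom = params.prominence_rel * (y.max() - y.min())
        peaks = detect_peaks(y, prominence=prom)
        grouping = group_peaks(peaks, params.d_threshold)
        pmax = max_peak_per_group(grouping, y)
        per_sensor.append(extract_segments(y, pmax, params.loffset, params.roffset))

    counts = {len(s) for s in per_sensor}
    if len(counts) != 1:
        raise ValueError(
            f"sensors disagree on cycle count in {rec.scheme_id} rep "
            f"{rec.repeat_index}: {sorted(len(s) for s in per_sensor)}"
        )
    n_cycles = counts.pop()

    samples = []
    for ci in range(n_cycles):
        windows = np.empty((rec.n_sensors, params.window))
        for si in range(rec.n_sensors):
            seg = per_sensor[si][ci]
            try:
                win = max_variation_window(seg.values, params.window, step)
                windows[si] = minmax_normalize(win.values)
            except DegenerateWindowError as err:
                raise DegenerateWindowError(
                    f"sensor {rec.sensor_ids[si]}, segment at pmax={seg.pmax}: {err}"
                ) from err
        anchor = per_sensor[0][ci].pmax
        entry = _schedule_entry(rec, anchor)
        eth, prop = entry["ethanol_ppm"], entry["propanol_ppm"]
        label = scheme_label(rec.scheme_id) if label_by == "scheme" \
            else classify_composition(eth, prop)
        if label is None:
            logger.warning("clean-air cycle at pmax=%d left unlabeled, skipped", anchor)
            continue
        samples.append(LabeledSample(
            tensor=assemble_tensor(windows),
            label=int(label),
            conc=(float(prop), float(eth)),
            scheme_id=rec.scheme_id,
            repeat_index=rec.repeat_index,
            cycle_index=ci,
        ))
    return samples


@dataclass
class LabeledDataset:
    """Arrays for training: tensors, class labels, ppm targets, CV groups."""

    X: np.ndarray                # (N, 8, n, n) in [0, 1]
    y_class: np.ndarray          # (N,) int, see simulate.CLASS_NAMES
    y_conc: np.ndarray           # (N, 2) ppm, columns (propanol, ethanol)
    scheme_ids: list[str] = field(default_factory=list)
    repeat_index: np.ndarray | None = None
    cycle_index: np.ndarray | None = None

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return LabeledDataset(
            X=self.X[idx],
            y_class=self.y_class[idx],
            y_conc=self.y_conc[idx],
            scheme_ids=[self.scheme_ids[i] for i in np.atleast_1d(idx)],
            repeat_index=None if self.repeat_index is None else self.repeat_index[idx],
            cycle_index=None if self.cycle_index is None else self.cycle_index[idx],
        )

    def save_npz(self, path) -> None:
        np.savez(
            path, X=self.X, y_class=self.y_class, y_conc=self.y_conc,
            scheme_ids=np.array(self.scheme_ids),
            repeat_index=self.repeat_index, cycle_index=self.cycle_index,
        )

    @classmethod
    def load_npz(cls, path) -> "LabeledDataset":
        z = np.load(path, allow_pickle=False)
        return cls(
            X=z["X"], y_class=z["y_class"], y_conc=z["y_conc"],
            scheme_ids=[str(s) for s in z["scheme_ids"]],
            repeat_index=z["repeat_index"], cycle_index=z["cycle_index"],
        )


def preprocess_campaign(
    recordings: list[SensorArrayRecording],
    params: PreprocessParams = PreprocessParams(),
    label_by: str = "composition",
) -> LabeledDataset:
    """Featurize a list of recordings into one stacked dataset."""
    all_samples: list[LabeledSample] = []
    for rec in recordings:
        all_samples.extend(featurize_recording(rec, params, label_by))
    if not all_samples:
        raise ValueError("no labeled samples produced")
    logger.info("preprocess: %d recordings -> %d samples",
                len(recordings), len(all_samples))
    return LabeledDataset(
        X=np.stack([s.tensor for s in all_samples]),
        y_class=np.array([s.label for s in all_samples], dtype=np.int64),
        y_conc=np.array([s.conc for s in all_samples], dtype=float),
        scheme_ids=[s.scheme_id for s in all_samples],
        repeat_index=np.array([s.repeat_index for s in all_samples], dtype=np.int64),
        cycle_index=np.array([s.cycle_index for s in all_samples], dtype=np.int64),
    )


def _schedule_entry(rec: SensorArrayRecording, sample: int) -> dict:
    for entry in rec.schedule:
        if entry["start_sample"] <= sample < entry["end_sample"]:
            return entry
    raise ValueError(f"sample {sample} outside every scheduled cycle")
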
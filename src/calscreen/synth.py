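"""Synthetic fluo-4 plate generator.

Emulates 384-well high-content recordings of ATP-evoked intracellular
Ca2+ responses: per-cell traces (380 frames at 2 Hz), labeled training
sets, whole plates with ATP-dependent phenotype mixtures, and multi-frame
image stacks (696 x 520 px after 2x2 binning) with elliptical cells.

Three response archetypes mirror the phenotype classes used throughout
the package:

``OscillationAndPeak``
    intermediate Ca2+ oscillations (a windowed sinusoidal burst) followed
    by a sustained rise, the signature of combined P2X4/P2X7 activation;
``Peak``
    the sustained (logistic) rise alone, indicating macropore formation;
``Other``
    baseline, optionally with one small decaying transient, plus noise.

All randomness flows from explicit integer seeds through
``numpy.random.SeedSequence`` so that identical configuration yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .traces import TraceSeries

__all__ = [
    "PhenotypeClass",
    "TraceArchetypeParams",
    "WellSpec",
    "PlateConfig",
    "CellGeometry",
    "DEFAULT_MIXTURE",
    "archetype_curve",
    "dynamic_range",
    "make_trace",
    "params_for_class",
    "make_training_set",
    "make_plate",
    "random_cell_geometries",
    "make_image_stack",
]


class PhenotypeClass(str, Enum):
    """The three functional phenotype classes of ATP-evoked responses."""

    OSC_PEAK = "OscillationAndPeak"
    PEAK = "Peak"
    OTHER = "Other"


# Logistic rises from 10% to 90% over 2*ln(9) ~ 4.394 scale units.
_LOGISTIC_1090 = 2.0 * np.log(9.0)


@dataclass(frozen=True)
class TraceArchetypeParams:
    """Shape parameters of the synthetic response archetypes.

    Amplitudes and the baseline are in raw-fluorescence arbitrary units;
    times in seconds; frequencies in Hz. The defaults are the study
    conditions used throughout the tests: a resting intensity around the
    control regime (~420 a.u.), a sustained rise of 400 a.u. starting
    90 s into the recording (rise_time is the 10-90% duration), and a
    0.2 Hz oscillation burst of 80 a.u. between 10 s and 80 s.
    """

    baseline: float = 420.0
    peak_amplitude: float = 400.0
    rise_time: float = 40.0
    rise_onset: float = 90.0
    osc_frequency: float = 0.25
    osc_amplitude: float = 80.0
    osc_window: tuple[float, float] = (10.0, 80.0)
    osc_taper: float = 0.25
    transient_amplitude: float = 40.0
    transient_onset: float = 40.0
    transient_decay: float = 10.0
    noise_sd: float = 0.0
    n_frames: int = 380
    sampling_rate: float = 2.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        duration = self.n_frames / self.sampling_rate
        w0, w1 = self.osc_window
        if not (0.0 <= w0 < w1 <= duration):
            raise ValueError(
                f"osc_window {self.osc_window} must lie inside [0, {duration}]"
            )
        if self.rise_time <= 0:
            raise ValueError("rise_time must be positive")
        if not 0.0 <= self.osc_taper <= 1.0:
            raise ValueError("osc_taper must be in [0, 1]")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_rate


def _tukey(n: int, alpha: float) -> np.ndarray:
    # Tapered-cosine (raised-cosine) envelope; alpha = tapered fraction.
    if n <= 1:
        return np.ones(n)
    if alpha <= 0:
        return np.ones(n)
    x = np.linspace(0.0, 1.0, n)
    w = np.ones(n)
    edge = alpha / 2.0
    lo = x < edge
    hi = x > 1.0 - edge
    w[lo] = 0.5 * (1.0 + np.cos(np.pi * (2.0 * x[lo] / alpha - 1.0)))
    w[hi] = 0.5 * (1.0 + np.cos(np.pi * (2.0 * (x[hi] - 1.0) / alpha + 1.0)))
    return w


def _logistic_rise(t: np.ndarray, params: TraceArchetypeParams) -> np.ndarray:
    scale = params.rise_time / _LOGISTIC_1090
    return params.peak_amplitude / (1.0 + np.exp(-(t - params.rise_onset) / scale))


def _osc_burst(t: np.ndarray, params: TraceArchetypeParams) -> np.ndarray:
    w0, w1 = params.osc_window
    burst = np.zeros_like(t)
    inside = (t >= w0) & (t <= w1)
    n_in = int(inside.sum())
    if n_in == 0:
        return burst
    env = _tukey(n_in, params.osc_taper)
    phase = 2.0 * np.pi * params.osc_frequency * (t[inside] - w0)
    burst[inside] = params.osc_amplitude * np.sin(phase) * env
    return burst


def _transient(t: np.ndarray, params: TraceArchetypeParams) -> np.ndarray:
    if params.transient_amplitude <= 0:
        return np.zeros_like(t)
    dt = t - params.transient_onset
    out = np.zeros_like(t)
    after = dt >= 0
    out[after] = params.transient_amplitude * np.exp(-dt[after] / params.transient_decay)
    return out


def archetype_curve(cls: PhenotypeClass, params: TraceArchetypeParams) -> np.ndarray:
    """Noise-free response curve of an archetype (the trace's expectation)."""
    t = params.time
    base = np.full(params.n_frames, params.baseline, dtype=float)
    if cls is PhenotypeClass.OSC_PEAK:
        return base + _osc_burst(t, params) + _logistic_rise(t, params)
    if cls is PhenotypeClass.PEAK:
        return base + _logistic_rise(t, params)
    if cls is PhenotypeClass.OTHER:
        return base + _transient(t, params)
    raise ValueError(f"unknown phenotype class {cls!r}")


def dynamic_range(cls: PhenotypeClass, params: TraceArchetypeParams) -> float:
    """Max minus min of the noise-free archetype curve."""
    curve = archetype_curve(cls, params)
    return float(curve.max() - curve.min())


def make_trace(
    cls: PhenotypeClass,
    params: TraceArchetypeParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    *,
    well_id: str = "synthetic",
    cell_id: int = 0,
) -> TraceSeries:
    """Generate one labeled synthetic trace.

    Identical ``(cls, params, seed)`` always produce the identical trace.
    Gaussian noise of standard deviation ``params.noise_sd`` is added
    i.i.d. per frame.
    """
    params = params or TraceArchetypeParams()
    curve = archetype_curve(cls, params)
    rng = np.random.default_rng(seed)
    if params.noise_sd > 0:
        curve = curve + rng.normal(0.0, params.noise_sd, size=params.n_frames)
    return TraceSeries(well_id, cell_id, curve, params.sampling_rate)


def params_for_class(
    cls: PhenotypeClass,
    base: TraceArchetypeParams | None = None,
    *,
    noise_frac: float = 0.05,
    jitter: float = 0.10,
    rng: np.random.Generator | None = None,
) -> TraceArchetypeParams:
    """Per-cell parameter draw for a class.

    ``noise_frac`` sets the noise level as a fraction of the archetype's
    dynamic range (its noise-free max minus min); ``jitter`` applies
    relative Gaussian cell-to-cell variability to the amplitudes and a
    small absolute jitter to the event onsets, emulating the spread of
    real single-cell responses.
    """
    base = base or TraceArchetypeParams()
    if rng is not None and jitter > 0:
        def rel(x: float) -> float:
            return float(x * max(0.1, 1.0 + jitter * rng.standard_normal()))

        w0, w1 = base.osc_window
        shift = float(np.clip(jitter * 50.0 * rng.standard_normal(), -w0, 20.0))
        base = replace(
            base,
            baseline=rel(base.baseline),
            peak_amplitude=rel(base.peak_amplitude),
            osc_amplitude=rel(base.osc_amplitude),
            transient_amplitude=rel(base.transient_amplitude),
            rise_onset=float(
                np.clip(
                    base.rise_onset + jitter * 30.0 * rng.standard_normal(),
                    w1 + shift,
                    base.n_frames / base.sampling_rate - 2 * base.rise_time,
                )
            ),
            osc_window=(w0 + shift, w1 + shift),
        )
    sd = noise_frac * dynamic_range(cls, base)
    return replace(base, noise_sd=sd)


def make_training_set(
    n_per_class: tuple[int, int, int] = (333, 536, 840),
    *,
    base: TraceArchetypeParams | None = None,
    noise_frac: float = 0.05,
    jitter: float = 0.10,
    seed: int = 42,
) -> tuple[list[TraceSeries], list[PhenotypeClass]]:
    """Labeled synthetic training set.

    The default composition (333 OscillationAndPeak / 536 Peak /
    840 Other, 1,709 traces in total) mirrors the hand-labeled set the
    classifier is benchmarked against.
    """
    classes = (PhenotypeClass.OSC_PEAK, PhenotypeClass.PEAK, PhenotypeClass.OTHER)
    master = np.random.SeedSequence(seed)
    streams = master.spawn(sum(n_per_class))
    traces: list[TraceSeries] = []
    labels: list[PhenotypeClass] = []
    i = 0
    for cls, n in zip(classes, n_per_class):
        for _ in range(n):
            ss = streams[i]
            rng = np.random.default_rng(ss)
            p = params_for_class(cls, base, noise_frac=noise_frac, jitter=jitter, rng=rng)
            traces.append(
                make_trace(cls, p, ss.spawn(1)[0], well_id="train", cell_id=i)
            )
            labels.append(cls)
            i += 1
    return traces, labels


# ---------------------------------------------------------------------------
# Plates

#: Qualitative dose-response mixture: the Other fraction decreases with
#: ATP while the two responding classes grow. The 1,000 uM row equals the
#: control-condition fractions of the drug screen (0.27 / 0.52 / 0.19 as
#: OscillationAndPeak / Peak / Other).
DEFAULT_MIXTURE: dict[float, tuple[float, float, float]] = {
    0.0: (0.03, 0.07, 0.90),
    1.0: (0.10, 0.15, 0.75),
    10.0: (0.17, 0.28, 0.55),
    100.0: (0.23, 0.42, 0.35),
    1000.0: (0.27, 0.52, 0.21),
}


@dataclass(frozen=True)
class WellSpec:
    well_id: str
    atp_um: float
    drug: str = "none"
    drug_um: float = 0.0


@dataclass
class PlateConfig:
    """Layout and statistical structure of a synthetic plate.

    ``mixture`` maps ATP concentration (uM) to the class-probability
    triple (OscillationAndPeak, Peak, Other); each triple must sum to 1.
    ``cells_per_well`` is the inclusive range the per-well cell count is
    drawn from (fields typically contain 100-500 fluorescent cells).
    """

    wells: list[WellSpec]
    mixture: Mapping[float, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )
    cells_per_well: tuple[int, int] = (100, 500)
    seed: int = 0
    noise_frac: float = 0.05
    jitter: float = 0.10
    base_params: TraceArchetypeParams = field(default_factory=TraceArchetypeParams)

    def __post_init__(self) -> None:
        for atp, probs in self.mixture.items():
            if len(probs) != 3 or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(
                    f"class probabilities for {atp} uM must sum to 1, got {probs}"
                )
            if any(p < 0 for p in probs):
                raise ValueError("class probabilities must be non-negative")
        lo, hi = self.cells_per_well
        if not (1 <= lo <= hi):
            raise ValueError("cells_per_well must be an increasing positive range")
        for w in self.wells:
            if w.atp_um not in self.mixture:
                raise ValueError(
                    f"well {w.well_id}: ATP concentration {w.atp_um} uM "
                    "absent from the mixture map"
                )


@dataclass
class SyntheticWell:
    spec: WellSpec
    traces: list[TraceSeries]
    labels: list[PhenotypeClass]


def make_plate(config: PlateConfig) -> list[SyntheticWell]:
    """Generate labeled traces for every well of a plate.

    Per well, the cell count is drawn uniformly from ``cells_per_well``
    and class labels from the mixture of that well's ATP concentration.
    A single master seed deterministically derives independent per-well
    and per-cell random streams.
    """
    classes = (PhenotypeClass.OSC_PEAK, PhenotypeClass.PEAK, PhenotypeClass.OTHER)
    master = np.random.SeedSequence(config.seed)
    well_streams = master.spawn(len(config.wells))
    out: list[SyntheticWell] = []
    for spec, ss in zip(config.wells, well_streams):
        rng = np.random.default_rng(ss)
        lo, hi = config.cells_per_well
        n_cells = int(rng.integers(lo, hi + 1))
        probs = np.asarray(config.mixture[spec.atp_um], dtype=float)
        idx = rng.choice(3, size=n_cells, p=probs)
        cell_streams = ss.spawn(n_cells)
        traces: list[TraceSeries] = []
        labels: list[PhenotypeClass] = []
        for cell_id, (k, cs) in enumerate(zip(idx, cell_streams)):
            cls = classes[k]
            crng = np.random.default_rng(cs)
            p = params_for_class(
                cls,
                config.base_params,
                noise_frac=config.noise_frac,
                jitter=config.jitter,
                rng=crng,
            )
            traces.append(
                make_trace(cls, p, cs.spawn(1)[0], well_id=spec.well_id, cell_id=cell_id)
            )
            labels.append(cls)
        out.append(SyntheticWell(spec, traces, labels))
    return out


# ---------------------------------------------------------------------------
# Image stacks


@dataclass(frozen=True)
class CellGeometry:
    """An elliptical cell footprint: center (row, col), semi-axes, angle."""

    center: tuple[float, float]
    axes: tuple[float, float]
    orientation: float = 0.0  # radians, counter-clockwise from the row axis

    def mask(self, frame_shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0 : frame_shape[0], 0 : frame_shape[1]]
        dr = rr - self.center[0]
        dc = cc - self.center[1]
        co, si = np.cos(self.orientation), np.sin(self.orientation)
        u = dr * co + dc * si
        v = -dr * si + dc * co
        a, b = self.axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def random_cell_geometries(
    n: int,
    frame_shape: tuple[int, int] = (520, 696),
    *,
    axes_range: tuple[float, float] = (4.0, 9.0),
    margin: float = 2.0,
    rng: np.random.Generator | None = None,
    max_tries: int = 200_000,
) -> list[CellGeometry]:
    """Place ``n`` non-overlapping random ellipses inside the frame."""
    rng = rng or np.random.default_rng(0)
    placed: list[CellGeometry] = []
    centers = np.empty((0, 2))
    radii = np.empty(0)
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} non-overlapping cells in {frame_shape}"
            )
        a = rng.uniform(*axes_range)
        b = rng.uniform(axes_range[0], a)
        r = a
        row = rng.uniform(r + margin, frame_shape[0] - r - margin)
        col = rng.uniform(r + margin, frame_shape[1] - r - margin)
        if centers.size:
            d = np.hypot(centers[:, 0] - row, centers[:, 1] - col)
            if np.any(d < radii + r + margin):
                continue
        theta = rng.uniform(0, np.pi)
        placed.append(CellGeometry((row, col), (a, b), theta))
        centers = np.vstack([centers, [row, col]])
        radii = np.append(radii, r)
    return placed


def make_image_stack(
    cell_geometries: Sequence[CellGeometry],
    traces: Sequence[TraceSeries],
    frame_shape: tuple[int, int] = (520, 696),
    seed: int | np.random.SeedSequence = 0,
    *,
    background: float = 10.0,
    noise_sd: float = 0.0,
    allow_overlap: bool = False,
    dtype=np.uint16,
) -> np.ndarray:
    """Render an image stack: one frame per time point.

    Pixels inside a cell carry that cell's trace value at the frame's
    time; all other pixels carry the background level. Gaussian read
    noise of ``noise_sd`` is added everywhere. The stack is returned as
    ``(n_frames, rows, cols)``, clipped to the dtype's range.
    """
    if len(cell_geometries) != len(traces):
        raise ValueError("need exactly one trace per cell geometry")
    n_frames = traces[0].n_frames if traces else 0
    if any(t.n_frames != n_frames for t in traces):
        raise ValueError("all traces must have the same length")

    # Label image: 0 = background, i+1 = cell i.
    label = np.zeros(frame_shape, dtype=np.int32)
    for i, geom in enumerate(cell_geometries):
        m = geom.mask(frame_shape)
        if not m.any():
            raise ValueError(f"cell {i} lies outside the frame")
        if not allow_overlap and np.any(label[m] != 0):
            raise ValueError(f"cell {i} overlaps a previously placed cell")
        label[m] = i + 1

    rng = np.random.default_rng(seed)
    info = np.iinfo(dtype) if np.issubdtype(np.dtype(dtype), np.integer) else None
    stack = np.empty((n_frames, *frame_shape), dtype=dtype)
    values = np.empty(len(traces) + 1)
    for t in range(n_frames):
        values[0] = background
        for i, tr in enumerate(traces):
            values[i + 1] = tr.values[t]
        frame = values[label]
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame_shape)
        if info is not None:
            frame = np.clip(np.rint(frame), info.min, info.max)
        stack[t] = frame.astype(dtype)
    return stack
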
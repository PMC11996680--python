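"""Stochastic bidirectional-motor track simulator with ground truth.

The generator emulates a single-molecule TIRF motility assay: motor
complexes land on a microtubule as a Poisson process (intensity per µm per
second, positions uniform along the lattice), then evolve by a
continuous-time Markov chain over three motion states — plus-end run,
minus-end run, pause — with exponential state dwells, per-state detachment
rates, and per-state speeds drawn from a truncated normal (signs enforced
by state).  Paths are truncated at the microtubule ends and at the movie
end, then sampled at the camera frame interval with independent Gaussian
localization noise.

Every track carries ground truth: its population, its exact state sequence
with switch times, and the class label the segmentation rules assign to the
noise-free path (the recovery target for the pipeline).

The state process is a phenomenological generator of run/pause/switch
behavior, not a mechanochemical motor model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from kymotility.io_model import ExperimentManifest, KymographContext, Track, TrackVertex
from kymotility.segmentation import (
    BIDIRECTIONAL_NM,
    STATIC_SPEED_NM_S,
    STATIC_TOTAL_NM,
    TrackClassification,
    classify_track,
    compute_segments,
    segment_runs,
)

__all__ = [
    "PopulationSpec",
    "SimulationParams",
    "GroundTruth",
    "simulate_trackset",
    "true_class",
    "trace_tracks",
    "render_kymograph",
    "preset",
    "PRESETS",
]

STATES = ("plus_run", "minus_run", "pause")


@dataclass(frozen=True)
class PopulationSpec:
    """One motor population of the mixture.

    ``speed_mean_nm_s`` is signed per state (positive for plus runs,
    negative for minus runs, 0 for pause); speeds are drawn once per state
    visit from a normal with the given CV, truncated so the sign never
    flips within a state.  ``dwell_mean_s`` are exponential state dwell
    means; ``switch`` rows give the destination probabilities when a dwell
    ends without detachment; ``detach_rate_s`` are competing exponential
    detachment rates.
    """

    name: str
    weight: float
    speed_mean_nm_s: dict[str, float]
    dwell_mean_s: dict[str, float]
    switch: dict[str, dict[str, float]]
    detach_rate_s: dict[str, float]
    initial_state: dict[str, float]
    speed_cv: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.weight <= 1:
            raise ValueError(f"population {self.name!r}: weight must be in [0,1]")
        for st in self.initial_state:
            if st not in STATES:
                raise ValueError(f"unknown state {st!r}")
        if self.speed_mean_nm_s.get("plus_run", 0.0) < 0 or self.speed_mean_nm_s.get("minus_run", 0.0) > 0:
            raise ValueError(f"population {self.name!r}: speed signs inconsistent with state direction")
        for st, rate in self.detach_rate_s.items():
            if rate < 0:
                raise ValueError(f"population {self.name!r}: negative detach rate for {st}")


@dataclass(frozen=True)
class SimulationParams:
    """Assay geometry, landing intensity, population mixture, and sampling."""

    landing_rate_um_s: float
    populations: tuple[PopulationSpec, ...]
    mt_length_nm: float = 15_000.0
    duration_s: float = 120.0
    frame_interval_s: float = 0.1
    pixel_size_nm: float = 105.0
    noise_sigma_nm: float = 20.0
    n_microtubules: int = 1
    n_experiments: int = 1
    condition: str = "simulated"
    landing_window_s: float | None = None  # restrict landings to [0, w]; None = whole movie
    seed: int = 0

    def __post_init__(self) -> None:
        if self.landing_rate_um_s < 0:
            raise ValueError("landing rate must be >= 0")
        if not self.populations:
            raise ValueError("at least one population required")
        w = sum(p.weight for p in self.populations)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"population weights must sum to 1, got {w}")
        if min(self.mt_length_nm, self.duration_s, self.frame_interval_s, self.pixel_size_nm) <= 0:
            raise ValueError("geometry and sampling parameters must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Exact generative record for one landed complex."""

    track_id: str
    context_id: str
    population: str
    t_land: float
    x_land: float
    # breakpoints of the exact piecewise-linear path: (t, x) pairs
    path_t: tuple[float, ...]
    path_x: tuple[float, ...]
    states: tuple[str, ...]  # one state per path interval
    detached: bool
    left_microtubule: bool
    observed: bool  # True if >= 2 frames were sampled

    def noise_free_track(self) -> Track:
        verts = tuple(TrackVertex(t=t, x=x) for t, x in zip(self.path_t, self.path_x))
        return Track(track_id=self.track_id, vertices=verts, context_id=self.context_id)


def _draw_speed(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Speed for one state visit; resampled so the sign never flips."""
    if mean == 0.0:
        return 0.0
    sd = abs(mean) * cv
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v * mean > 0:
            return v
    return mean


def _simulate_path(
    pop: PopulationSpec,
    t0: float,
    x0: float,
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[list[float], list[float], list[str], bool, bool]:
    """Evolve one complex from landing until detachment, MT end, or movie end."""
    states = list(pop.initial_state)
    probs = np.array([pop.initial_state[s] for s in states], dtype=float)
    state = states[int(rng.choice(len(states), p=probs / probs.sum()))]
    t, x = t0, x0
    path_t, path_x, path_states = [t0], [x0], []
    detached = left = False
    while t < params.duration_s:
        dwell = rng.exponential(pop.dwell_mean_s[state])
        d_rate = pop.detach_rate_s.get(state, 0.0)
        t_detach = rng.exponential(1.0 / d_rate) if d_rate > 0 else math.inf
        dt = min(dwell, t_detach)
        ends_by_detach = t_detach < dwell
        if t + dt > params.duration_s:
            dt = params.duration_s - t
            ends_by_detach = False
            end_of_movie = True
        else:
            end_of_movie = False
        v = _draw_speed(rng, pop.speed_mean_nm_s.get(state, 0.0), pop.speed_cv)
        x_new = x + v * dt
        if x_new < 0.0 or x_new > params.mt_length_nm:
            # clip at the microtubule end and terminate there
            bound = 0.0 if x_new < 0.0 else params.mt_length_nm
            dt = (bound - x) / v
            x_new = bound
            left = True
        if dt > 0:
            t += dt
            x = x_new
            path_t.append(t)
            path_x.append(x)
            path_states.append(state)
        if left or end_of_movie:
            break
        if ends_by_detach:
            detached = True
            break
        # dwell ended: switch state
        row = pop.switch.get(state)
        if not row:
            continue
        dests = list(row)
        p = np.array([row[d] for d in dests], dtype=float)
        state = dests[int(rng.choice(len(dests), p=p / p.sum()))]
    return path_t, path_x, path_states, detached, left


def _sample_frames(
    path_t: Sequence[float],
    path_x: Sequence[float],
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    t_start, t_end = path_t[0], path_t[-1]
    dt = params.frame_interval_s
    if t_end - t_start < dt:  # shorter than one frame: not visible as a track
        return np.array([]), np.array([])
    first = math.ceil(t_start / dt - 1e-12)
    last = math.floor(t_end / dt + 1e-12)
    frames = np.arange(first, last + 1) * dt
    # a trace spans the track's full visible extent, so the appearance and
    # disappearance times are vertices even when off the frame grid
    if frames.size == 0 or frames[0] - t_start > 1e-9:
        frames = np.concatenate(([t_start], frames))
    if t_end - frames[-1] > 1e-9:
        frames = np.concatenate((frames, [t_end]))
    if frames.size < 2:
        return np.array([]), np.array([])
    x = np.interp(frames, path_t, path_x)
    if params.noise_sigma_nm > 0:
        x = x + rng.normal(0.0, params.noise_sigma_nm, size=x.size)
    return frames, x


def simulate_trackset(
    params: SimulationParams,
) -> tuple[list[Track], dict[str, KymographContext], ExperimentManifest, list[GroundTruth]]:
    """Simulate a full dataset of frame-sampled tracks over one or more kymographs.

    Landing counts per microtubule are Poisson with mean
    ``landing_rate_um_s × mt_length_µm × window_s``; identical parameters
    and seed give bit-identical output.
    """
    import pandas as pd

    rng = np.random.default_rng(params.seed)
    weights = np.array([p.weight for p in params.populations])
    window = params.landing_window_s if params.landing_window_s is not None else params.duration_s
    window = min(window, params.duration_s)
    mean_landings = params.landing_rate_um_s * (params.mt_length_nm / 1000.0) * window

    tracks: list[Track] = []
    contexts: dict[str, KymographContext] = {}
    truths: list[GroundTruth] = []
    manifest_rows = []
    per_exp = max(1, math.ceil(params.n_microtubules / params.n_experiments))
    for m in range(params.n_microtubules):
        cid = f"mt{m + 1:04d}"
        exp_id = f"exp{m // per_exp + 1}"
        movie_id = f"movie{m + 1:04d}"
        contexts[cid] = KymographContext(
            context_id=cid,
            mt_length_nm=params.mt_length_nm,
            duration_s=params.duration_s,
            pixel_size_nm=params.pixel_size_nm,
            frame_interval_s=params.frame_interval_s,
            polarity="plus_right",
        )
        n_land = rng.poisson(mean_landings)
        for i in range(n_land):
            tid = f"{cid}_trk{i + 1:04d}"
            t0 = float(rng.uniform(0.0, window))
            x0 = float(rng.uniform(0.0, params.mt_length_nm))
            pop = params.populations[int(rng.choice(len(weights), p=weights))]
            pt, px, pstates, detached, left = _simulate_path(pop, t0, x0, params, rng)
            frames, xs = _sample_frames(pt, px, params, rng)
            observed = frames.size >= 2
            truths.append(
                GroundTruth(
                    track_id=tid,
                    context_id=cid,
                    population=pop.name,
                    t_land=t0,
                    x_land=x0,
                    path_t=tuple(pt),
                    path_x=tuple(px),
                    states=tuple(pstates),
                    detached=detached,
                    left_microtubule=left,
                    observed=observed,
                )
            )
            if not observed:
                continue
            verts = tuple(TrackVertex(t=float(t), x=float(x)) for t, x in zip(frames, xs))
            tracks.append(Track(track_id=tid, vertices=verts, context_id=cid))
            manifest_rows.append((params.condition, exp_id, movie_id, cid, tid))
    manifest = ExperimentManifest(
        pd.DataFrame(manifest_rows, columns=["condition", "experiment_id", "movie_id", "context_id", "track_id"])
    )
    return tracks, contexts, manifest, truths


def true_class(
    ground_truth: GroundTruth,
    static_speed_nm_s: float = STATIC_SPEED_NM_S,
    static_total_nm: float = STATIC_TOTAL_NM,
    bidirectional_nm: float = BIDIRECTIONAL_NM,
) -> TrackClassification:
    """Classification of the exact noise-free, unsampled path.

    Applies the same segmentation rules the pipeline uses, but to the true
    piecewise-linear path, so it serves as the recovery target.
    """
    if len(ground_truth.path_t) < 2:
        return TrackClassification(label="static", plus_total_nm=0.0, minus_total_nm=0.0)
    track = ground_truth.noise_free_track()
    runs, _ = segment_runs(compute_segments(track), static_speed_nm_s=static_speed_nm_s)
    return classify_track(runs, static_total_nm=static_total_nm, bidirectional_nm=bidirectional_nm)


def _simplify(t: np.ndarray, x: np.ndarray, eps: float) -> np.ndarray:
    """Indices of a polyline simplification keeping |x - chord(t)| <= eps.

    Distance is measured vertically (position error at equal time), which
    matches how a human tracer lays straight segments over a kymograph.
    """
    keep = [0, len(t) - 1]
    stack = [(0, len(t) - 1)]
    while stack:
        a, b = stack.pop()
        if b - a < 2:
            continue
        chord = x[a] + (x[b] - x[a]) * (t[a + 1 : b] - t[a]) / (t[b] - t[a])
        dev = np.abs(x[a + 1 : b] - chord)
        imax = int(np.argmax(dev))
        if dev[imax] > eps:
            mid = a + 1 + imax
            keep.append(mid)
            stack.append((a, mid))
            stack.append((mid, b))
    return np.array(sorted(set(keep)))


def trace_tracks(tracks: Sequence[Track], epsilon_nm: float = 50.0) -> list[Track]:
    """Emulate manual kymograph tracing of frame-sampled tracks.

    Manual tracing draws a few straight segments through the noisy per-frame
    signal; this reduces each sampled track to the minimal polyline whose
    vertical deviation from the samples stays within *epsilon_nm*.  Feeding
    traced tracks (rather than raw frames) to the segmentation rules mirrors
    the intended input of the analysis.
    """
    out = []
    for tr in tracks:
        t = np.array([v.t for v in tr.vertices])
        x = np.array([v.x for v in tr.vertices])
        idx = _simplify(t, x, epsilon_nm)
        verts = tuple(TrackVertex(t=float(t[i]), x=float(x[i])) for i in idx)
        out.append(replace(tr, vertices=verts))
    return out


def render_kymograph(
    tracks: Sequence[Track],
    context: KymographContext,
    psf_sigma_px: float = 1.3,
    background: float = 20.0,
    photon_scale: float = 200.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a synthetic kymograph image (rows = frames, columns = pixels).

    Each track contributes a 1-D Gaussian intensity profile centered at its
    (interpolated) position in every frame it spans; Poisson photon noise
    is applied on top of a constant background.  Deterministic under seed.
    """
    rng = np.random.default_rng(seed)
    n_px = int(math.ceil(context.mt_length_nm / context.pixel_size_nm))
    n_frames = int(math.ceil(context.duration_s / context.frame_interval_s))
    img = np.full((n_frames, n_px), float(background))
    px_centers = (np.arange(n_px) + 0.5) * context.pixel_size_nm
    frame_times = np.arange(n_frames) * context.frame_interval_s
    sigma_nm = psf_sigma_px * context.pixel_size_nm
    for tr in tracks:
        t = np.array([v.t for v in tr.vertices])
        x = np.array([v.x for v in tr.vertices])
        mask = (frame_times >= t[0]) & (frame_times <= t[-1])
        if not mask.any():
            continue
        xi = np.interp(frame_times[mask], t, x)
        prof = photon_scale * np.exp(-0.5 * ((px_centers[None, :] - xi[:, None]) / sigma_nm) ** 2)
        img[mask] += prof
    return rng.poisson(img).astype(np.float64)


def _unidirectional(name: str, weight: float, speed: float, dwell_s: float, detach_s: float,
                    pause_frac: float = 0.0, pause_dwell_s: float = 1.0) -> PopulationSpec:
    state = "plus_run" if speed > 0 else "minus_run"
    if pause_frac > 0:
        switch = {state: {"pause": 1.0}, "pause": {state: 1.0}}
        dwell = {state: dwell_s, "pause": pause_dwell_s}
        init = {state: 1.0 - pause_frac, "pause": pause_frac}
        detach = {state: 1.0 / detach_s, "pause": 1.0 / (4.0 * detach_s)}
    else:
        switch = {state: {state: 1.0}}
        dwell = {state: dwell_s}
        init = {state: 1.0}
        detach = {state: 1.0 / detach_s}
    return PopulationSpec(
        name=name, weight=weight,
        speed_mean_nm_s={state: speed, "pause": 0.0},
        dwell_mean_s=dwell, switch=switch, detach_rate_s=detach, initial_state=init,
    )


def _static(name: str, weight: float, dwell_s: float = 8.0) -> PopulationSpec:
    return PopulationSpec(
        name=name, weight=weight,
        speed_mean_nm_s={"pause": 0.0},
        dwell_mean_s={"pause": dwell_s},
        switch={"pause": {"pause": 1.0}},
        detach_rate_s={"pause": 1.0 / dwell_s},
        initial_state={"pause": 1.0},
    )


def _switcher(name: str, weight: float, minus_speed: float, plus_speed: float,
              dwell_s: float, detach_s: float) -> PopulationSpec:
    return PopulationSpec(
        name=name, weight=weight,
        speed_mean_nm_s={"minus_run": minus_speed, "plus_run": plus_speed, "pause": 0.0},
        dwell_mean_s={"minus_run": dwell_s, "plus_run": dwell_s, "pause": 0.5},
        switch={
            "minus_run": {"plus_run": 0.7, "pause": 0.3},
            "plus_run": {"minus_run": 0.7, "pause": 0.3},
            "pause": {"minus_run": 0.5, "plus_run": 0.5},
        },
        detach_rate_s={"minus_run": 1.0 / detach_s, "plus_run": 1.0 / detach_s, "pause": 0.1},
        initial_state={"minus_run": 0.5, "plus_run": 0.5},
    )


def _build_presets() -> dict[str, SimulationParams]:
    # Mixture weights for the mixed condition follow the observed class
    # proportions of dynein/kinesin cocomplexes (~83% minus-directed, ~13%
    # plus-directed, ~1.6% static, ~1.7% direction switchers).  Speeds are
    # round free choices (dynein-driven 500 nm/s, kinesin-driven 700 nm/s);
    # run dwells put mean run lengths in the several-thousand-nm range the
    # assays report.
    ddh = SimulationParams(
        landing_rate_um_s=0.05,
        populations=(
            _unidirectional("dynein_minus", 0.97, -500.0, dwell_s=6.0, detach_s=10.0, pause_frac=0.2),
            _static("static", 0.03),
        ),
        condition="DDH",
    )
    hk = SimulationParams(
        landing_rate_um_s=0.04,
        populations=(
            _unidirectional("kinesin_plus", 0.97, +700.0, dwell_s=5.0, detach_s=8.0, pause_frac=0.2),
            _static("static", 0.03),
        ),
        condition="HK",
    )
    ddhk = SimulationParams(
        landing_rate_um_s=0.08,
        populations=(
            _unidirectional("dynein_minus", 0.833, -500.0, dwell_s=6.0, detach_s=10.0, pause_frac=0.2),
            _unidirectional("kinesin_plus", 0.134, +700.0, dwell_s=5.0, detach_s=8.0, pause_frac=0.2),
            _static("static", 0.016),
            _switcher("switcher", 0.017, -500.0, +700.0, dwell_s=6.0, detach_s=15.0),
        ),
        condition="DDHK",
    )
    # FHF assay geometry: 105 nm pixels, 0.136 s frames, 500-frame movies.
    fhf = SimulationParams(
        landing_rate_um_s=0.065,
        populations=(
            _unidirectional("dynein_minus", 1.0, -500.0, dwell_s=13.0, detach_s=13.0),
        ),
        duration_s=68.0,
        frame_interval_s=0.136,
        pixel_size_nm=105.0,
        condition="FHF",
    )
    return {"ddh": ddh, "hk": hk, "ddhk": ddhk, "fhf": fhf}


PRESETS = _build_presets()


def preset(name: str, **overrides) -> SimulationParams:
    """Named demo scenario; override any SimulationParams field by keyword."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[name]
    return replace(p, **overrides) if overrides else p
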
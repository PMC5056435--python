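"""Ground-truth generator for axial single-molecule dynamics above GO.

Emulates the study system: a dye-labelled peptide hopping among discrete
transmembrane heights in a supported bilayer 3–8 nm above a graphene-oxide
quencher, imaged at 30 frames per second with EMCCD-like noise, bleaching in
a single step, and diffusing laterally with a state-dependent mobility
(motion is freer at the membrane surface than deep in the bilayer).

The axial state sequence is an exact continuous-time Markov chain
(Gillespie) realisation; per frame, the instantaneous height is drawn around
the state position, pushed through the quenching law, and corrupted with
multiplicative gain noise plus an additive background. Movies render each
live molecule as an integrated 2-D Gaussian PSF on a Poisson background.

Everything is seeded and bit-reproducible; every simulated object carries
its ground truth so downstream stages can be scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .quench import QuenchModel, relative_intensity

__all__ = [
    "StateModel",
    "NoiseModel",
    "StatePath",
    "GroundTruth",
    "IntensityTrace",
    "MovieGroundTruth",
    "simulate_state_path",
    "simulate_trace",
    "simulate_movie",
    "sample_dwell_mixture",
    "stationary_distribution",
    "default_quench_model",
    "five_state_model",
    "two_state_go_model",
    "single_state_model",
    "traces_to_dataframe",
    "write_traces_csv",
    "read_traces_csv",
]

# Printed characteristic quenching distance of the UV-tuned GO monolayers
# and a bright-molecule emission scale in camera counts.
DEFAULT_D0_NM = 4.0
DEFAULT_I0_AU = 1000.0


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def default_quench_model() -> QuenchModel:
    return QuenchModel(d0=DEFAULT_D0_NM, i0=DEFAULT_I0_AU)


# --------------------------------------------------------------------------
# models

@dataclass(frozen=True)
class StateModel:
    """K discrete axial states with Markov switching.

    positions : state heights above GO, nm, strictly increasing
    position_sds : axial spread around each state, nm (the observed width of
        each preferred position, instrument noise included)
    rates : K x K transition rate matrix, 1/s; off-diagonal entries are
        jump rates, each diagonal entry the negative row sum
    bleach_rate : single-step photobleaching rate, 1/s
    diffusion_coeffs : per-state lateral diffusion coefficient, um^2/s
    """

    positions: tuple
    position_sds: tuple
    rates: tuple
    bleach_rate: float = 0.1
    diffusion_coeffs: Optional[tuple] = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, float)
        sds = np.asarray(self.position_sds, float)
        q = self.rate_matrix
        k = len(pos)
        if k < 1:
            raise ValueError("need at least one state")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if len(sds) != k or np.any(sds < 0):
            raise ValueError("position_sds must be K non-negative values")
        if q.shape != (k, k):
            raise ValueError(f"rate matrix must be {k}x{k}")
        off = q[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        if not np.allclose(q.sum(axis=1), 0.0, atol=1e-9):
            raise ValueError("rate-matrix rows must sum to zero")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be non-negative")
        if self.diffusion_coeffs is not None and len(self.diffusion_coeffs) != k:
            raise ValueError("diffusion_coeffs must have one entry per state")

    @property
    def n_states(self) -> int:
        return len(self.positions)

    @property
    def rate_matrix(self) -> np.ndarray:
        return np.asarray(self.rates, dtype=float)


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise surrogate: additive Gaussian background plus
    multiplicative Gaussian gain noise, sampled once per frame."""

    background_mean: float = 50.0
    background_sd: float = 10.0
    gain_sd_fraction: float = 0.02
    frame_interval: float = 1.0 / 30.0

    def __post_init__(self) -> None:
        if self.background_sd < 0 or self.gain_sd_fraction < 0:
            raise ValueError("noise sds must be non-negative")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")


def _chain_rates(k: int, up: float, down: float) -> tuple:
    q = np.zeros((k, k))
    for i in range(k - 1):
        q[i, i + 1] = up
        q[i + 1, i] = down
    np.fill_diagonal(q, -q.sum(axis=1))
    return tuple(map(tuple, q))


def five_state_model(bleach_rate: float = 0.1) -> StateModel:
    """Default five-state parameterisation of the lifted (GO-BSA) bilayer.

    Heights and spreads follow the fitted preferred positions of the
    N-labelled peptide: bottom surface, lower leaflet, centre, upper leaflet
    and top surface of the bilayer. Kinetics are a nearest-neighbour chain
    (the peptide cannot skip a leaflet within one jump); the symmetric 4/s
    hopping rate gives dwells of a few video frames and a uniform stationary
    occupancy, so every state is well sampled in minutes of footage.
    """
    return StateModel(
        positions=(3.4, 4.2, 5.2, 6.2, 7.5),
        position_sds=(0.4, 0.4, 0.4, 0.4, 0.9),
        rates=_chain_rates(5, up=4.0, down=4.0),
        bleach_rate=bleach_rate,
        diffusion_coeffs=(0.01, 0.02, 0.05, 0.1, 0.3),
    )


def two_state_go_model(
    tau_fast: float = 0.060,
    tau_slow: float = 0.260,
    amp_fast: float = 0.5,
    bleach_rate: float = 0.1,
) -> StateModel:
    """Three-state model of the unlifted (GO-supported) bilayer.

    Two resolvable heights — 3.1 nm (the peptide inside the pore) and
    4.0 nm (the peptide at the membrane surface) — plus a blind state deep
    in the quenched zone. The two bright states exchange only through the
    blind state, and re-entry lands in either with probability ``amp_fast``
    / ``1 - amp_fast``, so each bright visit is a single exponential dwell
    and the composite bright-state dwell distribution is exactly the
    two-exponential mixture amp_fast*Exp(tau_fast) + (1-amp_fast)*Exp(tau_slow).

    The blind state stands in for every sub-detection height (lower leaflet
    and bilayer bottom); it sits at 0.8 nm with a tight spread so that its
    emission is genuinely indistinguishable from the camera background, as
    in the real system, and dwells there for 250 ms on average.
    """
    k_exit = 4.0  # 1/s, exit rate of the blind state (250 ms mean)
    q = np.zeros((3, 3))
    q[0, 1] = amp_fast * k_exit
    q[0, 2] = (1.0 - amp_fast) * k_exit
    q[1, 0] = 1.0 / tau_fast
    q[2, 0] = 1.0 / tau_slow
    np.fill_diagonal(q, -q.sum(axis=1))
    return StateModel(
        positions=(0.8, 3.1, 4.0),
        position_sds=(0.15, 0.4, 0.4),
        rates=tuple(map(tuple, q)),
        bleach_rate=bleach_rate,
        diffusion_coeffs=(0.01, 0.05, 0.3),
    )


def single_state_model(height: float, sd: float = 0.0, bleach_rate: float = 0.0) -> StateModel:
    return StateModel(
        positions=(height,),
        position_sds=(sd,),
        rates=((0.0,),),
        bleach_rate=bleach_rate,
        diffusion_coeffs=(0.0,),
    )


def stationary_distribution(model: StateModel) -> np.ndarray:
    """Stationary occupancy of the switching chain (left null vector of Q)."""
    q = model.rate_matrix
    w, v = np.linalg.eig(q.T)
    idx = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


# --------------------------------------------------------------------------
# state paths

@dataclass(frozen=True)
class StatePath:
    """One continuous-time realisation: ``states[i]`` holds on
    ``[jump_times[i], jump_times[i+1])``; the last state holds to ``duration``."""

    jump_times: np.ndarray  # s, starts at 0.0
    states: np.ndarray  # int state index per interval
    duration: float

    def state_at(self, t) -> np.ndarray:
        idx = np.searchsorted(self.jump_times, np.asarray(t, float), side="right") - 1
        return self.states[np.clip(idx, 0, len(self.states) - 1)]

    def dwell_times(self) -> np.ndarray:
        edges = np.append(self.jump_times, self.duration)
        return np.diff(edges)


def simulate_state_path(model: StateModel, duration: float, seed) -> StatePath:
    """Exact Gillespie realisation of the axial switching chain.

    The initial state is drawn from the stationary distribution so that
    finite traces are unbiased samples of the equilibrium dynamics.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed)
    q = model.rate_matrix
    k = model.n_states
    state = int(rng.choice(k, p=stationary_distribution(model))) if k > 1 else 0

    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        exit_rate = -q[state, state]
        if exit_rate <= 0:
            break
        t += rng.exponential(1.0 / exit_rate)
        if t >= duration:
            break
        probs = q[state].copy()
        probs[state] = 0.0
        probs /= exit_rate
        state = int(rng.choice(k, p=probs))
        times.append(t)
        states.append(state)
    return StatePath(np.asarray(times), np.asarray(states, dtype=int), duration)


# --------------------------------------------------------------------------
# traces

@dataclass
class GroundTruth:
    """Per-frame truth for one simulated molecule."""

    state: np.ndarray  # int index per frame
    height_nm: np.ndarray  # instantaneous axial position per frame
    xy_um: np.ndarray  # (n_frames, 2) lateral position
    bleach_frame: Optional[int]  # first frame emitting background only


@dataclass
class IntensityTrace:
    """One molecule's intensity record at fixed frame interval."""

    intensity: np.ndarray  # a.u., raw (background included)
    frame_interval: float  # s
    bleach_index: Optional[int] = None  # first bleached frame, None if alive
    x_um: Optional[np.ndarray] = None
    y_um: Optional[np.ndarray] = None
    trace_id: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.intensity)

    @property
    def time(self) -> np.ndarray:
        return (np.arange(self.n_frames) + 0.5) * self.frame_interval

    def live_intensity(self) -> np.ndarray:
        """Frames before the bleach step (all frames if no bleach)."""
        stop = self.n_frames if self.bleach_index is None else self.bleach_index
        return self.intensity[:stop]


def _emit_frames(
    path: StatePath,
    model: StateModel,
    quench: QuenchModel,
    noise: NoiseModel,
    n_frames: int,
    rng: np.random.Generator,
):
    """Signal amplitude (background-free) and truth per frame midpoint."""
    mid = (np.arange(n_frames) + 0.5) * noise.frame_interval
    states = path.state_at(mid)
    pos = np.asarray(model.positions)[states]
    sds = np.asarray(model.position_sds)[states]
    heights = rng.normal(pos, sds)
    heights = np.clip(heights, 1e-3, None)  # quench law needs d > 0
    signal = quench.i0 * relative_intensity(heights, quench)
    if noise.gain_sd_fraction > 0:
        signal = signal * (1.0 + rng.normal(0.0, noise.gain_sd_fraction, n_frames))

    if model.bleach_rate > 0:
        t_bleach = rng.exponential(1.0 / model.bleach_rate)
    else:
        t_bleach = np.inf
    bleached = mid >= t_bleach
    signal[bleached] = 0.0
    bleach_frame = int(np.argmax(bleached)) if bleached.any() else None
    return signal, states, heights, bleach_frame


def _diffuse_xy(
    states: np.ndarray,
    model: StateModel,
    frame_interval: float,
    rng: np.random.Generator,
    origin=(0.0, 0.0),
) -> np.ndarray:
    n = len(states)
    xy = np.zeros((n, 2))
    xy[0] = origin
    if model.diffusion_coeffs is None:
        return xy + origin
    d = np.asarray(model.diffusion_coeffs)[states[:-1]]
    step_sd = np.sqrt(2.0 * d * frame_interval)
    steps = rng.normal(0.0, step_sd[:, None], (n - 1, 2)) if n > 1 else np.zeros((0, 2))
    xy[1:] = origin + np.cumsum(steps, axis=0)
    return xy


def simulate_trace(
    path: StatePath,
    model: StateModel,
    quench: QuenchModel,
    noise: NoiseModel,
    seed,
    trace_id: int = 0,
) -> tuple[IntensityTrace, GroundTruth]:
    """Forward model of the measurement: heights to camera counts.

    Per frame midpoint the height is Normal(state position, state sd); the
    emitted amplitude is ``i0 * I/I0(height)`` times ``1 + gain noise``; the
    recorded value adds Normal(background_mean, background_sd). After the
    single-step bleach time the record is a pure background draw.
    """
    rng = _rng(seed)
    n_frames = int(np.floor(path.duration / noise.frame_interval))
    if n_frames < 1:
        raise ValueError("duration shorter than one frame")
    signal, states, heights, bleach_frame = _emit_frames(
        path, model, quench, noise, n_frames, rng
    )
    background = (
        rng.normal(noise.background_mean, noise.background_sd, n_frames)
        if noise.background_sd > 0
        else np.full(n_frames, noise.background_mean)
    )
    intensity = signal + background
    xy = _diffuse_xy(states, model, noise.frame_interval, rng)
    if bleach_frame is not None:
        heights = heights.copy()
        heights[bleach_frame:] = np.nan
    trace = IntensityTrace(
        intensity=intensity,
        frame_interval=noise.frame_interval,
        bleach_index=bleach_frame,
        x_um=xy[:, 0],
        y_um=xy[:, 1],
        trace_id=trace_id,
    )
    truth = GroundTruth(state=states, height_nm=heights, xy_um=xy, bleach_frame=bleach_frame)
    return trace, truth


def simulate_traces(
    model: StateModel,
    quench: QuenchModel,
    noise: NoiseModel,
    n_traces: int,
    duration: float,
    seed,
) -> tuple[list[IntensityTrace], list[GroundTruth]]:
    """Convenience ensemble generator with per-trace child seeds."""
    if isinstance(seed, np.random.Generator):
        raise TypeError("pass an integer seed for reproducible ensembles")
    seq = np.random.SeedSequence(seed)
    traces, truths = [], []
    for i, child in enumerate(seq.spawn(n_traces)):
        rng = np.random.default_rng(child)
        path = simulate_state_path(model, duration, rng)
        tr, gt = simulate_trace(path, model, quench, noise, rng, trace_id=i)
        traces.append(tr)
        truths.append(gt)
    return traces, truths


# --------------------------------------------------------------------------
# movies

@dataclass
class MovieGroundTruth:
    """Truth for one rendered molecule: pixel path and emitted amplitude."""

    xy_px: np.ndarray  # (n_frames, 2) true centre, x = column, y = row
    amplitude: np.ndarray  # integrated counts per frame (background-free)
    state: np.ndarray
    bleach_frame: Optional[int]


def _render_spot(frame: np.ndarray, x: float, y: float, amplitude: float, psf_sigma: float):
    """Add an integrated-Gaussian spot; patch is renormalised so the added
    counts equal ``amplitude`` exactly (photometry conservation)."""
    if amplitude <= 0:
        return
    h, w = frame.shape
    r = max(int(np.ceil(5 * psf_sigma)), 3)
    x0, x1 = int(np.floor(x)) - r, int(np.floor(x)) + r + 1
    y0, y1 = int(np.floor(y)) - r, int(np.floor(y)) + r + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c)
    ys = np.arange(y0c, y1c)
    gx = np.exp(-0.5 * ((xs - x) / psf_sigma) ** 2)
    gy = np.exp(-0.5 * ((ys - y) / psf_sigma) ** 2)
    patch = np.outer(gy, gx)
    frame[y0c:y1c, x0c:x1c] += amplitude * patch / patch.sum()


def simulate_movie(
    model: StateModel,
    quench: QuenchModel,
    noise: NoiseModel,
    n_spots: int,
    n_frames: int,
    shape: tuple[int, int],
    seed,
    psf_sigma: float = 1.1,
    pixel_size: float = 0.16,
    background_per_px: float = 10.0,
    poisson_noise: bool = True,
) -> tuple[np.ndarray, list[MovieGroundTruth]]:
    """Render a TIRF movie of diffusing, switching, bleaching molecules.

    Spots start on a jittered grid with a safety margin; each follows its
    own axial chain and per-state Brownian lateral walk. ``pixel_size`` is
    um per px; diffusion steps are converted accordingly. Returns a float
    stack (n_frames, H, W) and one ground-truth record per molecule.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    rng = _rng(seed)
    h, w = shape
    duration = n_frames * noise.frame_interval
    margin = max(int(np.ceil(6 * psf_sigma)), 5)
    if 2 * margin >= min(h, w):
        raise ValueError("frame too small for the PSF margin")

    # jittered grid placement
    n_side = int(np.ceil(np.sqrt(n_spots)))
    gx = np.linspace(margin, w - 1 - margin, n_side)
    gy = np.linspace(margin, h - 1 - margin, n_side)
    grid = [(x, y) for y in gy for x in gx][:n_spots]
    jitter = rng.uniform(-1.0, 1.0, (n_spots, 2))
    starts = np.asarray(grid) + jitter

    truths: list[MovieGroundTruth] = []
    for i in range(n_spots):
        path = simulate_state_path(model, duration, rng)
        amplitude, states, _, bleach_frame = _emit_frames(
            path, model, quench, noise, n_frames, rng
        )
        xy_um = _diffuse_xy(states, model, noise.frame_interval, rng)
        xy_px = starts[i] + xy_um / pixel_size
        xy_px[:, 0] = np.clip(xy_px[:, 0], margin, w - 1 - margin)
        xy_px[:, 1] = np.clip(xy_px[:, 1], margin, h - 1 - margin)
        truths.append(MovieGroundTruth(xy_px, amplitude, states, bleach_frame))

    first = np.array([t.xy_px[0] for t in truths])
    if len(first) > 1:
        from scipy.spatial.distance import pdist

        if pdist(first).min() < 4 * psf_sigma:
            warnings.warn("spots closer than 4 PSF sigmas; traces may mix", stacklevel=2)

    movie = np.empty((n_frames, h, w), dtype=float)
    for f in range(n_frames):
        frame = (
            rng.poisson(background_per_px, (h, w)).astype(float)
            if poisson_noise
            else np.full((h, w), float(background_per_px))
        )
        for t in truths:
            _render_spot(frame, t.xy_px[f, 0], t.xy_px[f, 1], t.amplitude[f], psf_sigma)
        movie[f] = frame
    return movie, truths


# --------------------------------------------------------------------------
# dwell samples

def sample_dwell_mixture(
    n: int, tau_fast: float, tau_slow: float, amp_fast: float = 0.5, seed=None
) -> np.ndarray:
    """Draw continuous dwell times from a two-exponential mixture (s)."""
    if not 0.0 <= amp_fast <= 1.0:
        raise ValueError("amp_fast must be a fraction")
    rng = _rng(seed)
    fast = rng.random(n) < amp_fast
    out = np.where(
        fast, rng.exponential(tau_fast, n), rng.exponential(tau_slow, n)
    )
    return out


# --------------------------------------------------------------------------
# CSV plumbing

def traces_to_dataframe(
    traces: Sequence[IntensityTrace], truths: Optional[Sequence[GroundTruth]] = None
) -> pd.DataFrame:
    rows = []
    for i, tr in enumerate(traces):
        df = pd.DataFrame(
            {
                "trace_id": tr.trace_id,
                "frame": np.arange(tr.n_frames),
                "time_s": tr.time,
                "x_um": tr.x_um if tr.x_um is not None else np.nan,
                "y_um": tr.y_um if tr.y_um is not None else np.nan,
                "intensity_au": tr.intensity,
            }
        )
        df["bleach_index"] = -1 if tr.bleach_index is None else tr.bleach_index
        if truths is not None:
            df["true_state"] = truths[i].state
            df["true_height_nm"] = truths[i].height_nm
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def write_traces_csv(path, traces, truths=None) -> None:
    traces_to_dataframe(traces, truths).to_csv(path, index=False)


def read_traces_csv(path) -> list[IntensityTrace]:
    df = pd.read_csv(path)
    traces = []
    for tid, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("frame")
        dt = float(np.median(np.diff(grp["time_s"]))) if len(grp) > 1 else 1.0 / 30.0
        bleach = int(grp["bleach_index"].iloc[0]) if "bleach_index" in grp else -1
        traces.append(
            IntensityTrace(
                intensity=grp["intensity_au"].to_numpy(),
                frame_interval=dt,
                bleach_index=None if bleach < 0 else bleach,
                x_um=grp["x_um"].to_numpy() if "x_um" in grp else None,
                y_um=grp["y_um"].to_numpy() if "y_um" in grp else None,
                trace_id=int(tid),
            )
        )
    return traces
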
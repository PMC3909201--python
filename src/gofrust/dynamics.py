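"""Langevin dynamics and the adaptive-temperature sampling protocol.

Constant-temperature runs use the BAOAB splitting of underdamped Langevin
dynamics (unit bead mass, k_B = 1).  The variable-temperature protocol
removes the need to locate the collapse temperature T_θ beforehand: every
N_T steps the cumulative histogram of the native-contact count Q (bin width
1) is inspected; if the non-native peak is higher the temperature drops by
ΔT (stabilizing the folded state), if the native peak is higher it rises by
ΔT, and exact ties are broken randomly.  The post-burn-in average of the
window temperatures estimates T_θ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .analysis import SelectionError, find_two_peaks, kept_flags, smooth_histogram
from .energy import ModelArrays, ModelParameters, NumericError, pack_model
from .structures import FrustrationSet, InputError, NativeTopology

logger = logging.getLogger(__name__)


class InstabilityError(RuntimeError):
    """Integration blew up (per-step displacement > 1 Å): reduce dt."""


@dataclass
class LangevinConfig:
    """Integrator settings in reduced units (τ = time unit, k_B = 1)."""

    dt: float = 0.005            # τ
    gamma: float = 1.0           # 1/τ, high-friction regime
    mass: float = 1.0            # reduced bead mass
    temperature: float = 0.3     # reduced
    n_steps: int = 1_000_000
    stride: int = 100            # snapshot thinning
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.gamma <= 0 or self.temperature < 0:
            raise InputError("dt, gamma must be positive; temperature >= 0")
        if self.mass <= 0:
            raise InputError("mass must be positive")
        if self.stride < 1 or self.n_steps < 1:
            raise InputError("n_steps and stride must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class VariTempConfig:
    """Adaptive-temperature protocol settings."""

    t_init: float = 0.3          # starting guess for T_θ
    delta_t: float = 0.002       # ΔT per adjustment
    n_t: int = 20_000            # steps per adjustment window
    bin_width: int = 1           # Q histogram bin width
    burn_in: float = 0.3         # fraction of windows dropped for T_θ
    cumulative: bool = True      # paper-style up-to-now histogram
    compare: str = "mass"        # "mass": compare basin occupancies across
                                 # the valley (the protocol's stated goal of
                                 # equal opportunity to stay in either
                                 # state); "peak": compare raw peak heights

    def __post_init__(self) -> None:
        if self.delta_t < 0:
            raise InputError("delta_t must be >= 0")
        if self.n_t < 1000:
            raise InputError("n_t (steps per window) must be >= 1000")
        if self.bin_width != 1:
            raise InputError("only bin width 1 (contact counts) is supported")
        if not 0 <= self.burn_in < 1:
            raise InputError("burn_in must be in [0, 1)")
        if self.compare not in ("mass", "peak"):
            raise InputError("compare must be 'mass' or 'peak'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Trajectory:
    """Thinned snapshot series from one simulation."""

    steps: np.ndarray            # global step index of each snapshot
    coords: np.ndarray           # (m, n, 3) Cα positions
    temperatures: np.ndarray     # instantaneous T per snapshot
    q_counts: np.ndarray         # kept-contact count per snapshot
    kept: np.ndarray             # (m, n_contacts) kept flags
    nc: int
    seed: int
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.steps) <= 0):
            raise InputError("snapshot steps must be strictly increasing")
        if not np.array_equal(self.q_counts, self.kept.sum(axis=1)):
            raise InputError("Q counts inconsistent with kept flags")

    def __len__(self) -> int:
        return len(self.steps)

    def qtrace(self):
        from .analysis import QTrace
        return QTrace(q_counts=self.q_counts, nc=self.nc)

    def save(self, path) -> None:
        import json
        np.savez_compressed(
            path, steps=self.steps, coords=self.coords,
            temperatures=self.temperatures, q_counts=self.q_counts,
            kept=self.kept, nc=self.nc, seed=self.seed,
            config=json.dumps(self.config),
        )

    @classmethod
    def load(cls, path) -> "Trajectory":
        import json
        z = np.load(path, allow_pickle=False)
        return cls(
            steps=z["steps"], coords=z["coords"],
            temperatures=z["temperatures"], q_counts=z["q_counts"],
            kept=z["kept"], nc=int(z["nc"]), seed=int(z["seed"]),
            config=json.loads(str(z["config"])),
        )


@dataclass
class TemperatureTrace:
    """Window temperatures of a variable-temperature run."""

    temperatures: np.ndarray     # T during each window
    t_init: float
    delta_t: float

    def __len__(self) -> int:
        return len(self.temperatures)


# ---------------------------------------------------------------------------
# Single-step integrator (reference path, used by the physics micro-tests)


def step_langevin(x, v, f, force_fn, cfg: LangevinConfig, rng: np.random.Generator):
    """One BAOAB update.  ``force_fn(x) -> forces``; returns (x, v, f_new).

    Deterministic given the generator state; raises InstabilityError when a
    bead moves more than 1 Å in the step.
    """
    m = cfg.mass
    c1 = np.exp(-cfg.gamma * cfg.dt)
    c2 = np.sqrt((1.0 - c1 * c1) * cfg.temperature / m)
    half = 0.5 * cfg.dt
    x0 = x
    v = v + half * f / m
    x = x + half * v
    v = c1 * v + c2 * rng.standard_normal(v.shape)
    x = x + half * v
    f = force_fn(x)
    v = v + half * f / m
    if np.max(np.abs(x - x0)) > 1.0 or not np.all(np.isfinite(x)):
        raise InstabilityError(
            "bead displacement exceeded 1 Å in a single step; reduce dt"
        )
    return x, v, f


def _window_seed(seed: int, window: int) -> np.uint32:
    ss = np.random.SeedSequence([int(seed), int(window)])
    return np.uint32(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _run_segments(
    arrays: ModelArrays,
    x: np.ndarray,
    v: np.ndarray,
    cfg: LangevinConfig,
    temperature: float,
    n_steps: int,
    seed: np.uint32,
) -> np.ndarray:
    """Drive the compiled BAOAB kernel for one segment; returns snapshots."""
    n_snap = n_steps // cfg.stride
    snap = np.empty((n_snap, x.shape[0], 3))
    nsnap, status = _kernels.run_protein_segment(
        x, v, *arrays.kernel_args(), cfg.dt, cfg.gamma, temperature, cfg.mass,
        n_steps, cfg.stride, seed, snap,
    )
    if status >= 0:
        raise InstabilityError(
            f"integration unstable at step {status} (displacement > 1 Å); "
            "reduce dt or check the starting configuration"
        )
    return snap[:nsnap]


def run_constant_temperature(
    topo: NativeTopology,
    fset: FrustrationSet | None,
    p: ModelParameters,
    cfg: LangevinConfig,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Constant-temperature Langevin run (default start: the native state).

    ``x0`` selects a different starting configuration — e.g. an unfolded
    snapshot from a previous run, for two-sided (folding + unfolding)
    sampling around coexistence.
    """
    arrays = pack_model(topo, fset, p)
    x = topo.ca0.copy() if x0 is None else np.array(x0, dtype=float)
    if x.shape != topo.ca0.shape:
        raise InputError("x0 has the wrong shape")
    v = np.zeros_like(x)
    snaps = _run_segments(arrays, x, v, cfg, cfg.temperature, cfg.n_steps,
                          _window_seed(cfg.seed, 0))
    kept = kept_flags(snaps, topo)
    steps = cfg.stride * np.arange(1, len(snaps) + 1)
    return Trajectory(
        steps=steps, coords=snaps,
        temperatures=np.full(len(snaps), cfg.temperature),
        q_counts=kept.sum(axis=1), kept=kept, nc=topo.n_contacts,
        seed=cfg.seed,
        config={"mode": "const", "langevin": cfg.to_dict(),
                "model": p.to_dict()},
    )


# ---------------------------------------------------------------------------
# Adaptive temperature


def update_temperature(
    histogram: np.ndarray,
    temperature: float,
    delta_t: float,
    rng: np.random.Generator,
    compare: str = "mass",
) -> tuple[float, dict]:
    """One feedback decision from the Q-count histogram (bin width 1).

    The histogram is lightly smoothed (3-bin moving average) and its
    non-native (low-Q) and native (high-Q) modes are located on either side
    of the deepest valley.  With ``compare="mass"`` (default) the two basins
    are weighed by their total occupancy across the valley — the protocol's
    goal is an equal opportunity to stay in either state; ``compare="peak"``
    weighs the raw peak heights instead.  A heavier non-native side cools
    the system by ΔT, a heavier native side heats it, and exact ties are
    resolved randomly.  The temperature never drops below ΔT.
    """
    if delta_t == 0:
        return temperature, {"direction": 0, "fallback": False}
    counts = np.asarray(histogram, dtype=float)
    info: dict = {"fallback": False}
    try:
        low_peak, valley, high_peak, sm = find_two_peaks(counts)
        if compare == "mass":
            h_nonnative = counts[:valley].sum() + 0.5 * counts[valley]
            h_native = counts[valley + 1:].sum() + 0.5 * counts[valley]
        else:
            h_nonnative = sm[low_peak]
            h_native = sm[high_peak]
        info.update(low_peak=int(low_peak), valley=int(valley),
                    high_peak=int(high_peak))
    except SelectionError:
        # Unimodal: classify the single mode against the native anchor.  The
        # native basin lives near Q = NC (within the kept tolerance); a lone
        # mode below ~0.75·NC is a (partially) unfolded population, even if
        # it sits above NC/2 — for systems whose unfolded state retains
        # local structure the naive midpoint misclassifies it.
        info["fallback"] = True
        total = counts.sum()
        if total == 0:
            return temperature, {**info, "direction": 0}
        median_bin = int(np.searchsorted(np.cumsum(counts), total / 2.0))
        native_floor = 0.75 * (len(counts) - 1)
        logger.info(
            "unimodal Q histogram: median at bin %d (native floor %.1f)",
            median_bin, native_floor,
        )
        if median_bin < native_floor:
            h_nonnative, h_native = 1.0, 0.0
        elif median_bin > native_floor:
            h_nonnative, h_native = 0.0, 1.0
        else:
            h_nonnative = h_native = 1.0
    if h_nonnative > h_native:
        direction = -1
    elif h_native > h_nonnative:
        direction = +1
    else:
        direction = int(rng.choice([-1, 1]))
        info["tie"] = True
    new_t = temperature + direction * delta_t
    if new_t < 0.5 * delta_t:
        new_t = temperature       # floor: never cool below ΔT
        direction = 0
    info["direction"] = direction
    return new_t, info


def run_variable_temperature(
    topo: NativeTopology,
    fset: FrustrationSet | None,
    p: ModelParameters,
    cfg: LangevinConfig,
    vt: VariTempConfig,
) -> tuple[Trajectory, TemperatureTrace]:
    """Adaptive-temperature run: windows of ``vt.n_t`` steps with the
    feedback rule applied to the up-to-now Q histogram after each window.

    All snapshots (from every window) are retained for analysis.
    """
    arrays = pack_model(topo, fset, p)
    x = topo.ca0.copy()
    v = np.zeros_like(x)
    rng = np.random.default_rng(_window_seed(cfg.seed, 0x7FFF))
    n_windows = cfg.n_steps // vt.n_t
    if n_windows < 1:
        raise InputError("n_steps shorter than one adjustment window")

    temperature = vt.t_init
    all_snaps: list[np.ndarray] = []
    all_q: list[np.ndarray] = []
    all_kept: list[np.ndarray] = []
    snap_temps: list[np.ndarray] = []
    window_temps = np.empty(n_windows)
    cum_hist = np.zeros(topo.n_contacts + 1)
    windowed_hist = np.zeros_like(cum_hist)

    for w in range(n_windows):
        window_temps[w] = temperature
        snaps = _run_segments(arrays, x, v, cfg, temperature, vt.n_t,
                              _window_seed(cfg.seed, w))
        kept = kept_flags(snaps, topo)
        q = kept.sum(axis=1)
        all_snaps.append(snaps)
        all_kept.append(kept)
        all_q.append(q)
        snap_temps.append(np.full(len(snaps), temperature))
        windowed_hist = np.bincount(q, minlength=topo.n_contacts + 1).astype(float)
        cum_hist += windowed_hist
        hist = cum_hist if vt.cumulative else windowed_hist
        if vt.delta_t > 0:
            temperature, info = update_temperature(
                hist, temperature, vt.delta_t, rng, compare=vt.compare
            )
            logger.debug("window %d: T -> %.4f (%s)", w, temperature, info)

    coords = np.concatenate(all_snaps)
    kept = np.concatenate(all_kept)
    steps = cfg.stride * np.arange(1, len(coords) + 1)
    traj = Trajectory(
        steps=steps, coords=coords,
        temperatures=np.concatenate(snap_temps),
        q_counts=np.concatenate(all_q), kept=kept, nc=topo.n_contacts,
        seed=cfg.seed,
        config={"mode": "vari", "langevin": cfg.to_dict(),
                "varitemp": vt.to_dict(), "model": p.to_dict()},
    )
    trace = TemperatureTrace(
        temperatures=window_temps, t_init=vt.t_init, delta_t=vt.delta_t,
    )
    return traj, trace


def transition_temperature(traj: Trajectory, tse) -> tuple[float, float]:
    """T_θ as the mean instantaneous temperature of the transition-region
    snapshots (the temperatures at which barrier crossings are actually
    visited).  Less sensitive to the controller's slow temperature
    oscillations than the plain trace average; returns (mean, std)."""
    temps = traj.temperatures[tse.indices]
    if len(temps) == 0:
        raise InputError("empty transition-state selection")
    return float(np.mean(temps)), float(np.std(temps))


def estimate_T_theta(trace: TemperatureTrace,
                     burn_in: float = 0.3) -> tuple[float, float]:
    """Mean and standard error of post-burn-in window temperatures."""
    if not 0 <= burn_in < 1:
        raise InputError("burn_in must be in [0, 1)")
    n = len(trace.temperatures)
    start = int(np.ceil(burn_in * n))
    tail = trace.temperatures[start:]
    if len(tail) == 0:
        raise InputError("no windows remain after burn-in")
    se = float(np.std(tail, ddof=1) / np.sqrt(len(tail))) if len(tail) > 1 else 0.0
    return float(np.mean(tail)), se
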
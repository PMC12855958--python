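"""EDR-wired stochastic Hopfield dynamics on a 2-D cortical-sheet lattice.

The model is a lattice of +/-1 units. Anatomical connectivity follows the
exponential distance rule (EDR): an unordered pair (i, j) at Euclidean
lattice distance d_ij is connected with probability exp(-lambda * d_ij).
Functional weights come from a Hebbian / anti-Hebbian rule over four stored
+/-1 memory patterns (face / object / body / place clusters):

    w_ij = (gamma_ij / N) * sum_mu x_i^mu x_j^mu

Dynamics are asynchronous Glauber-like updates: one uniformly random unit
per iteration flips to +1 with probability sigmoid(beta * b_i), where the
local field b_i = sum_j w_ij (s_j + H_j) includes an external input H
(bottom-up stimulus drive, top-down perturbation, or resting-state noise).
The Lyapunov energy is H = -1/2 sum_ij w_ij s_i s_j.

``lambda`` is quoted in inverse lattice units of the full-scale 200 x 200
sheet; :func:`scale_lambda` rescales it for smaller lattices so that
exp(-lambda * d) is preserved at the cluster length scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit

from .geometry import anchor_geometry
from .synth import PatternSet, StimulusEncoding, encode_stimulus, generate_lattice_patterns

__all__ = [
    "LatticeConfig",
    "CouplingMatrix",
    "ExternalFieldSchedule",
    "Trajectory",
    "UpdateEvent",
    "half_height_width",
    "scale_lambda",
    "connection_probability",
    "sample_adjacency",
    "build_weights",
    "build_coupling",
    "async_update",
    "energy",
    "run",
    "run_stimulus",
    "cluster_activation",
    "lambda_sweep",
    "perturbation_experiment",
    "resting_state_run",
    "SPECIFICITY_BATTERY",
    "GENERALIZATION_BATTERY",
]

FULL_SCALE = 200  # lattice side at which lambda values are quoted


@dataclass(frozen=True)
class LatticeConfig:
    """Lattice geometry and dynamics parameters.

    ``lam`` is the EDR decay constant in inverse lattice units (default
    0.023, the model-corrected human-cortex wiring length); ``beta`` is the
    inverse-noise gain of the sigmoid update rule (100 = near-deterministic).
    """

    height: int = 200
    width: int = 200
    lam: float = 0.023
    beta: float = 100.0
    seed: int = 0
    self_connections: bool = False
    symmetric_sampling: bool = True

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("lattice dimensions must be positive")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")

    @property
    def n_sites(self) -> int:
        return self.height * self.width


@dataclass
class CouplingMatrix:
    """Sampled adjacency and Hebbian weights on the lattice."""

    height: int
    width: int
    adjacency: sp.csr_matrix  # 0/1
    weights: sp.csr_matrix | None = None
    n_norm: int | None = None  # the N of the weight normalization

    @property
    def n_sites(self) -> int:
        return self.height * self.width

    def distances(self) -> np.ndarray:
        """Dense Euclidean distance matrix (small lattices only)."""
        if self.n_sites > 4096:
            raise ValueError("dense distance matrix only supported for <= 4096 sites")
        coords = _site_coords(self.height, self.width)
        diff = coords[:, None, :] - coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))


@dataclass
class ExternalFieldSchedule:
    """Ordered, non-overlapping (start, end, field-per-site) epochs."""

    epochs: list[tuple[int, int, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end, fld in self.epochs:
            if start < 0 or end <= start:
                raise ValueError("epochs must satisfy 0 <= start < end")
            if start < prev_end:
                raise ValueError("epochs must be ordered and non-overlapping")
            prev_end = end
            np.asarray(fld)  # must be array-like

    @property
    def max_step(self) -> int:
        return max((end for _, end, _ in self.epochs), default=0)


@dataclass
class UpdateEvent:
    site: int
    local_field: float
    new_state: int


@dataclass
class Trajectory:
    """Recorded lattice states with energies and cluster activations."""

    steps: np.ndarray  # strictly increasing sample steps
    states: np.ndarray  # (n_samples, n_sites) int8
    energies: np.ndarray
    cluster_activations: dict[str, np.ndarray]  # name -> mean state per sample
    final_state: np.ndarray
    last_local_field: float
    record_every: int
    n_steps: int

    def activation_fraction(self, cluster: str) -> np.ndarray:
        """Fraction of +1 units in a cluster, per sample (in [0, 1])."""
        return 0.5 * (self.cluster_activations[cluster] + 1.0)


def half_height_width(lam: float) -> float:
    """Distance at which the EDR connection probability falls to 1/2:
    ln(2) / lambda (6.93 length units at lambda = 0.1)."""
    if lam <= 0:
        raise ValueError("half-height width is infinite at lambda <= 0")
    return float(np.log(2.0) / lam)


def scale_lambda(lam: float, height: int, full_scale: int = FULL_SCALE) -> float:
    """Rescale a full-scale (200 x 200) lambda to a smaller lattice so that
    exp(-lambda d) is preserved at the cluster length scale."""
    return lam * full_scale / height


def connection_probability(lam: float, d) -> np.ndarray:
    """EDR connection probability exp(-lambda * d)."""
    return np.exp(-lam * np.asarray(d, dtype=float))


def _site_coords(height: int, width: int) -> np.ndarray:
    rows, cols = np.divmod(np.arange(height * width), width)
    return np.stack([rows, cols], axis=1).astype(float)


def sample_adjacency(cfg: LatticeConfig, lam: float | None = None) -> CouplingMatrix:
    """Sample the EDR adjacency: each unordered pair (i, j) is connected
    independently with probability exp(-lambda d_ij); the diagonal is empty
    unless ``self_connections``. Deterministic given ``cfg.seed``."""
    lam = cfg.lam if lam is None else lam
    n = cfg.n_sites
    coords = _site_coords(cfg.height, cfg.width)
    rng = np.random.default_rng(cfg.seed)
    rows_out: list[np.ndarray] = []
    cols_out: list[np.ndarray] = []
    chunk = max(1, min(512, n))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = np.sqrt(
            ((coords[start:stop, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        )
        p = np.exp(-lam * d)
        draws = rng.random(p.shape) < p
        if cfg.symmetric_sampling:
            # keep only j > i; mirrored below
            ii = np.arange(start, stop)[:, None]
            jj = np.arange(n)[None, :]
            draws &= jj > ii
        elif not cfg.self_connections:
            ii = np.arange(start, stop)[:, None]
            draws &= np.arange(n)[None, :] != ii
        r, c = np.nonzero(draws)
        rows_out.append(r + start)
        cols_out.append(c)
    rows = np.concatenate(rows_out)
    cols = np.concatenate(cols_out)
    if cfg.symmetric_sampling:
        rows, cols = np.concatenate([rows, cols]), np.concatenate([cols, rows])
        if cfg.self_connections:
            diag = np.arange(n)
            rows = np.concatenate([rows, diag])
            cols = np.concatenate([cols, diag])
    adj = sp.csr_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    return CouplingMatrix(cfg.height, cfg.width, adj)


def build_weights(
    patterns: PatternSet, coupling: CouplingMatrix, n_norm: int | None = None
) -> CouplingMatrix:
    """Hebbian / anti-Hebbian weights w_ij = (gamma_ij / N) sum_mu x_i x_j.

    ``n_norm`` defaults to the number of lattice sites. The diagonal is
    forced to zero when absent from the adjacency. Structural zeros
    (exactly cancelling pattern sums) are dropped from the sparse matrix.
    """
    if patterns.n_sites != coupling.n_sites:
        raise ValueError("patterns and adjacency must share the lattice shape")
    n_norm = coupling.n_sites if n_norm is None else int(n_norm)
    if n_norm == 0:
        raise ValueError("normalizer N must be nonzero")
    x = patterns.pattern_matrix().astype(np.int32)  # (n_patterns, n_sites)
    adj = coupling.adjacency.tocoo()
    s = (x[:, adj.row] * x[:, adj.col]).sum(axis=0).astype(float)
    w = sp.csr_matrix((s / n_norm, (adj.row, adj.col)), shape=adj.shape)
    w.eliminate_zeros()
    coupling.weights = w
    coupling.n_norm = n_norm
    return coupling


def build_coupling(
    cfg: LatticeConfig, patterns: PatternSet | None = None, lam: float | None = None
) -> CouplingMatrix:
    """Convenience: sample the EDR adjacency and build Hebbian weights."""
    if patterns is None:
        patterns = generate_lattice_patterns(cfg.height, cfg.width)
    coupling = sample_adjacency(cfg, lam=lam)
    return build_weights(patterns, coupling)


def energy(state: np.ndarray, coupling: CouplingMatrix) -> float:
    """Hopfield energy H = -1/2 sum_ij w_ij s_i s_j."""
    s = np.asarray(state, dtype=float).ravel()
    return float(-0.5 * s @ (coupling.weights @ s))


def async_update(
    state: np.ndarray,
    coupling: CouplingMatrix,
    beta: float,
    fld: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> UpdateEvent:
    """One asynchronous update (in place): pick a uniform random unit i,
    compute b_i = sum_j w_ij (s_j + H_j), and set s_i = +1 with probability
    sigmoid(beta * b_i). ``beta = inf`` gives the deterministic sign rule
    (ties keep the current state)."""
    rng = rng or np.random.default_rng()
    s = state.ravel()
    i = int(rng.integers(0, s.size))
    w = coupling.weights
    row = slice(w.indptr[i], w.indptr[i + 1])
    idx = w.indices[row]
    drive = s[idx].astype(float)
    if fld is not None:
        drive = drive + np.asarray(fld).ravel()[idx]
    b = float(w.data[row] @ drive)
    if np.isinf(beta):
        new = 1 if b > 0 else (-1 if b < 0 else int(s[i]))
    else:
        new = 1 if rng.random() < 1.0 / (1.0 + np.exp(-beta * b)) else -1
    s[i] = new
    return UpdateEvent(site=i, local_field=b, new_state=new)


@njit(cache=False)
def _run_kernel(
    indptr,
    indices,
    data,
    state,
    n_steps,
    record_every,
    epoch_starts,
    epoch_ends,
    epoch_fields,
    beta,
    seed,
    resting_noise,
    direct_field,
    rec_states,
):
    np.random.seed(seed)
    n = state.size
    rec_i = 0
    last_b = 0.0
    deterministic = beta > 1e30
    for t in range(n_steps):
        h_idx = -1
        for e in range(epoch_starts.size):
            if epoch_starts[e] <= t < epoch_ends[e]:
                h_idx = e
                break
        i = np.random.randint(0, n)
        b = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            j = indices[k]
            hj = 0.0
            if not direct_field and h_idx >= 0:
                hj += epoch_fields[h_idx, j]
            if resting_noise:
                hj += 1.0 if np.random.random() < 0.5 else -1.0
            b += data[k] * (state[j] + hj)
        if direct_field and h_idx >= 0:
            b += epoch_fields[h_idx, i]
        last_b = b
        if deterministic:
            if b > 0:
                state[i] = 1
            elif b < 0:
                state[i] = -1
        else:
            z = beta * b
            if z > 35.0:
                p = 1.0
            elif z < -35.0:
                p = 0.0
            else:
                p = 1.0 / (1.0 + np.exp(-z))
            state[i] = 1 if np.random.random() < p else -1
        if (t + 1) % record_every == 0 and rec_i < rec_states.shape[0]:
            for q in range(n):
                rec_states[rec_i, q] = state[q]
            rec_i += 1
    return last_b


def run(
    state0: np.ndarray,
    coupling: CouplingMatrix,
    beta: float = 100.0,
    n_steps: int = 150_000,
    schedule: ExternalFieldSchedule | None = None,
    record_every: int = 10_000,
    seed: int = 0,
    patterns: PatternSet | None = None,
    resting_noise: bool = False,
    field_mode: str = "neighbors",
) -> Trajectory:
    """Run asynchronous dynamics for ``n_steps`` single-unit updates.

    States are recorded every ``record_every`` steps (floor(n_steps /
    record_every) samples). ``field_mode='neighbors'`` applies the external
    field through the weighted neighbor sum (b_i = sum_j w_ij (s_j + H_j));
    ``'direct'`` adds H_i to b_i instead. With ``resting_noise`` every
    weight input receives an independent per-iteration Rademacher (+/-1)
    field. Deterministic given ``seed``.
    """
    if coupling.weights is None:
        raise ValueError("coupling has no weights; call build_weights first")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if field_mode not in ("neighbors", "direct"):
        raise ValueError("field_mode must be 'neighbors' or 'direct'")
    if schedule is not None and schedule.max_step > n_steps:
        raise ValueError("schedule extends beyond n_steps")

    n = coupling.n_sites
    state = np.asarray(state0).ravel().astype(np.int8).copy()
    if state.size != n:
        raise ValueError("initial state does not match the lattice size")
    if schedule is None or not schedule.epochs:
        starts = np.empty(0, dtype=np.int64)
        ends = np.empty(0, dtype=np.int64)
        fields = np.empty((0, n), dtype=np.float64)
    else:
        starts = np.array([e[0] for e in schedule.epochs], dtype=np.int64)
        ends = np.array([e[1] for e in schedule.epochs], dtype=np.int64)
        fields = np.stack(
            [np.asarray(e[2], dtype=np.float64).ravel() for e in schedule.epochs]
        )

    n_rec = n_steps // record_every
    rec_states = np.empty((n_rec, n), dtype=np.int8)
    w = coupling.weights
    last_b = _run_kernel(
        w.indptr,
        w.indices,
        w.data,
        state,
        n_steps,
        record_every,
        starts,
        ends,
        fields,
        float(beta),
        int(seed) % (2**31 - 1),
        resting_noise,
        field_mode == "direct",
        rec_states,
    )
    steps = (np.arange(n_rec) + 1) * record_every
    energies = np.array(
        [-0.5 * s @ (w @ s.astype(float)) for s in rec_states.astype(float)]
    )
    activations: dict[str, np.ndarray] = {}
    if patterns is not None:
        for name, idx in patterns.mask_indices().items():
            activations[name] = rec_states[:, idx].mean(axis=1) if n_rec else np.empty(0)
    return Trajectory(
        steps=steps,
        states=rec_states,
        energies=energies,
        cluster_activations=activations,
        final_state=state,
        last_local_field=float(last_b),
        record_every=record_every,
        n_steps=n_steps,
    )


def cluster_activation(state: np.ndarray, patterns: PatternSet, cluster: str) -> float:
    """Fraction of +1 units in a cluster for a single state (in [0, 1])."""
    idx = patterns.mask_indices()[cluster]
    return float(0.5 * (np.asarray(state).ravel()[idx].mean() + 1.0))


# ---------------------------------------------------------------------------
# stimulus batteries and headline experimental protocols
# ---------------------------------------------------------------------------

#: Face-specificity battery: per-cluster +1 fill fractions of the stimulus
#: encodings and the spatial scales of their activation blobs. Non-face
#: stimuli partially recruit the face cluster through shared *coarse*
#: (shape/configural) structure, so their face-cluster trace survives only
#: under wiring local enough to preserve those scales; the familiar-object
#: control barely recruits the face cluster at all.
SPECIFICITY_BATTERY: dict[str, dict] = {
    "human_face": {"overlaps": {"face": 0.9, "object": 0.05}},
    "shape_sharing_object": {
        "overlaps": {"face": 0.55, "object": 0.85},
        "field_scales": (2.0, 4.0),
    },
    "config_sharing_object": {
        "overlaps": {"face": 0.52, "object": 0.85},
        "field_scales": (2.0, 4.0),
    },
    "familiar_object": {"overlaps": {"face": 0.05, "object": 0.9}},
}

#: Face-generalization battery: faces of other species and rotated views
#: share the face cluster but differ from the frontal human face in *fine*
#: spatial detail, which only short-range wiring retains.
#: Face-generalization battery: faces of other species and rotated views
#: share the face cluster but differ from the frontal human face at
#: intermediate-fine spatial scales, which only short-range wiring retains.
GENERALIZATION_BATTERY: dict[str, dict] = {
    "face_front": {"overlaps": {"face": 0.9, "object": 0.05}, "field_scales": (1.0, 2.0)},
    "face_profile": {"overlaps": {"face": 0.8, "object": 0.05}, "field_scales": (1.0, 2.0)},
    "face_cheek": {"overlaps": {"face": 0.7, "object": 0.05}, "field_scales": (1.0, 2.0)},
    "face_back": {"overlaps": {"face": 0.6, "object": 0.05}, "field_scales": (1.0, 2.0)},
    "cross_species_cat": {"overlaps": {"face": 0.65, "object": 0.05}, "field_scales": (1.0, 2.0)},
    "cross_species_dog": {"overlaps": {"face": 0.6, "object": 0.05}, "field_scales": (1.0, 2.0)},
}


def run_stimulus(
    coupling: CouplingMatrix,
    patterns: PatternSet,
    encoding: StimulusEncoding,
    beta: float = 100.0,
    n_steps: int = 20_000,
    record_every: int = 1000,
    seed: int = 0,
    bottom_up_amplitude: float = 1.0,
) -> Trajectory:
    """Encode a stimulus, use it both as the initial state and as a
    sustained bottom-up field of amplitude ``bottom_up_amplitude``, and run
    to stabilization."""
    state0 = encode_stimulus(encoding, patterns)
    fld = bottom_up_amplitude * state0.ravel().astype(float)
    schedule = ExternalFieldSchedule([(0, n_steps, fld)])
    return run(
        state0,
        coupling,
        beta=beta,
        n_steps=n_steps,
        schedule=schedule,
        record_every=record_every,
        seed=seed,
        patterns=patterns,
    )


def _battery_activations(
    coupling: CouplingMatrix,
    patterns: PatternSet,
    battery: Mapping[str, Mapping[str, float]],
    beta: float,
    n_steps: int,
    record_every: int,
    seed: int,
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """Final face-cluster activation fraction per battery stimulus, plus the
    stabilized states."""
    fracs: dict[str, float] = {}
    finals: dict[str, np.ndarray] = {}
    for k, (name, stim) in enumerate(battery.items()):
        kwargs = {"field_scales": tuple(stim["field_scales"])} if "field_scales" in stim else {}
        enc = StimulusEncoding(
            overlaps=dict(stim["overlaps"]), flip_noise=0.02, seed=seed + k,
            mode="field", **kwargs,
        )
        traj = run_stimulus(
            coupling,
            patterns,
            enc,
            beta=beta,
            n_steps=n_steps,
            record_every=record_every,
            seed=seed + 31 * k,
        )
        # average over the last third of samples to damp single-snapshot noise
        fr = traj.activation_fraction("face")
        k = max(1, fr.size // 3)
        fracs[name] = float(fr[-k:].mean())
        finals[name] = traj.final_state.astype(float)
    return fracs, finals


def lambda_sweep(
    lams: Sequence[float],
    height: int = 40,
    width: int = 40,
    beta: float = 100.0,
    n_repeats: int = 10,
    n_steps: int = 20_000,
    record_every: int = 2000,
    seed: int = 0,
    patterns: PatternSet | None = None,
    spec_battery: Mapping[str, Mapping[str, float]] | None = None,
    gen_battery: Mapping[str, Mapping[str, float]] | None = None,
    n_probes: int = 200,
) -> pd.DataFrame:
    """Specificity, generalization, and manifold D/R per wiring length.

    ``lams`` are nominal (200 x 200-scale) lambda values; each is rescaled
    to the simulated lattice. Per (lambda, repeat): sample the EDR
    adjacency, build weights, run the face-specificity and
    face-generalization stimulus batteries, and measure anchor geometry of
    the stabilized states. Returns one row per (lambda, repeat).
    """
    if len(lams) < 2:
        raise ValueError("need at least two lambda values")
    patterns = patterns or generate_lattice_patterns(height, width)
    spec_battery = spec_battery or SPECIFICITY_BATTERY
    gen_battery = gen_battery or GENERALIZATION_BATTERY
    rows = []
    for li, lam in enumerate(lams):
        lam_scaled = scale_lambda(lam, height)
        for rep in range(n_repeats):
            # common random numbers across lambda: the same repeat index uses
            # the same adjacency draws, stimulus encodings, and update noise
            # at every lambda, so per-repeat lambda contrasts are paired
            sub = int(
                np.random.SeedSequence(seed, spawn_key=(rep,)).generate_state(1)[0]
                % (2**31 - 1)
            )
            cfg = LatticeConfig(height=height, width=width, lam=lam_scaled, beta=beta, seed=sub)
            coupling = build_coupling(cfg, patterns)
            spec_fr, spec_states = _battery_activations(
                coupling, patterns, spec_battery, beta, n_steps, record_every, sub + 1
            )
            gen_fr, gen_states = _battery_activations(
                coupling, patterns, gen_battery, beta, n_steps, record_every, sub + 2
            )
            eps = 1e-3
            others = [v for k, v in spec_fr.items() if k != "human_face"]
            specificity = spec_fr["human_face"] / max(max(others), eps)
            gvals = np.array(list(gen_fr.values()))
            generalization = gvals.min() / max(gvals.max(), eps)
            # manifold geometry of the face point cloud: stabilized states of
            # all face-family stimuli (collapses to a point under global wiring)
            face_states = np.stack(
                [spec_states["human_face"], *gen_states.values()]
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d_m, r_m = anchor_geometry(face_states, n_probes=n_probes, seed=sub + 3)
            rows.append(
                {
                    "lam": lam,
                    "lam_scaled": lam_scaled,
                    "repeat": rep,
                    "specificity": specificity,
                    "generalization": generalization,
                    "dimension": d_m,
                    "radius": r_m,
                    **{f"act_{k}": v for k, v in {**spec_fr}.items()},
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PerturbationResult:
    trajectory: Trajectory
    control: Trajectory
    epoch_bounds: tuple[int, int, int]
    condition: str

    def face_activation(self) -> np.ndarray:
        return self.trajectory.activation_fraction("face")

    def control_activation(self) -> np.ndarray:
        return self.control.activation_fraction("face")


def perturbation_experiment(
    coupling: CouplingMatrix,
    patterns: PatternSet,
    condition: str = "false_alarm",
    amplitude: float = 2.0,
    epoch_steps: tuple[int, int, int] = (80_000, 80_000, 250_000),
    beta: float = 100.0,
    record_every: int = 1000,
    seed: int = 0,
    bottom_up_amplitude: float = 1.0,
) -> PerturbationResult:
    """Top-down perturbation protocol with three epochs.

    * ``false_alarm``: a non-face object is presented bottom-up throughout,
      and during epoch 2 a top-down face signal (+amplitude on the face
      cluster, -amplitude elsewhere) is added.
    * ``miss``: a face is presented bottom-up, and during epoch 2 a
      top-down object signal is added.

    The face-cluster mean activation is recorded every ``record_every``
    steps; a control run with top-down amplitude 0 uses the same seed.
    """
    if condition not in ("false_alarm", "miss"):
        raise ValueError("condition must be 'false_alarm' or 'miss'")
    t1, t2, t3 = epoch_steps
    n_steps = t1 + t2 + t3
    if condition == "false_alarm":
        stim = StimulusEncoding({"object": 0.9, "face": 0.05}, flip_noise=0.02, seed=seed)
        target = "face"
    else:
        stim = StimulusEncoding({"face": 0.9, "object": 0.05}, flip_noise=0.02, seed=seed)
        target = "object"
    state0 = encode_stimulus(stim, patterns)
    bottom = bottom_up_amplitude * state0.ravel().astype(float)
    top = np.full(coupling.n_sites, -amplitude)
    top[patterns.mask_indices()[target]] = amplitude

    def _schedule(amp_on: bool) -> ExternalFieldSchedule:
        mid = bottom + top if amp_on else bottom
        return ExternalFieldSchedule(
            [(0, t1, bottom), (t1, t1 + t2, mid), (t1 + t2, n_steps, bottom)]
        )

    kwargs = dict(
        beta=beta, n_steps=n_steps, record_every=record_every, seed=seed, patterns=patterns
    )
    traj = run(state0, coupling, schedule=_schedule(True), **kwargs)
    control = run(state0, coupling, schedule=_schedule(False), **kwargs)
    return PerturbationResult(traj, control, (t1, t1 + t2, n_steps), condition)


def resting_state_run(
    coupling: CouplingMatrix,
    beta: float = 100.0,
    n_steps: int = 300_000,
    record_every: int = 100,
    seed: int = 0,
    patterns: PatternSet | None = None,
) -> Trajectory:
    """Resting-state protocol: every weight input carries an independent
    per-iteration Rademacher (+/-1) noise field; snapshots every
    ``record_every`` steps (3000 snapshots at the full protocol). The
    initial state is random +/-1."""
    rng = np.random.default_rng(seed)
    state0 = rng.choice(np.array([-1, 1], dtype=np.int8), size=coupling.n_sites)
    return run(
        state0,
        coupling,
        beta=beta,
        n_steps=n_steps,
        record_every=record_every,
        seed=seed + 1,
        patterns=patterns,
        resting_noise=True,
    )
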
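"""Energy-representation manifold: parametric 2-D embedding, interpolated
energy surface, and trajectory path lengths.

High-dimensional lattice states are projected to 2-D with a neighbor-graph
embedding (UMAP); a small feedforward regressor (1000 -> 100 -> 2 units,
rectifier nonlinearity) is fitted to reproduce the embedding so that new
states — e.g. every waypoint of a relaxation trajectory — can be mapped
parametrically. Adding each state's Hopfield energy as a third axis and
interpolating over the 2-D plane yields the energy surface; summing
consecutive embedded waypoint distances yields the path length a stimulus
travels to its attractor basin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError
from sklearn.neural_network import MLPRegressor

from .lattice import Trajectory

__all__ = [
    "EmbeddingModel",
    "EnergySurface",
    "PathLengthResult",
    "fit_embedding",
    "build_surface",
    "path_length",
    "mean_path_length",
    "excess_path_length",
    "path_length_sweep",
]


@dataclass
class EmbeddingModel:
    """Parametric 2-D embedding: sampled input sites + fitted regressor."""

    site_idx: np.ndarray  # lattice sites fed to the regressor
    regressor: MLPRegressor
    train_embedding: np.ndarray  # (n_states, 2) neighbor-graph coordinates
    fit_mse: float

    def transform(self, states: np.ndarray) -> np.ndarray:
        """Map states (n, n_sites) to 2-D coordinates."""
        x = np.atleast_2d(np.asarray(states, dtype=float))
        return self.regressor.predict(x[:, self.site_idx])


@dataclass
class EnergySurface:
    grid_x: np.ndarray
    grid_y: np.ndarray
    values: np.ndarray  # NaN outside the convex hull
    interpolator: LinearNDInterpolator


@dataclass
class PathLengthResult:
    lengths: np.ndarray  # per-stimulus path length (embedded units)
    waypoint_counts: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.lengths))

    @property
    def sd(self) -> float:
        return float(np.std(self.lengths))


def fit_embedding(
    states: np.ndarray,
    n_input_sites: int = 1000,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
    max_iter: int = 2000,
) -> EmbeddingModel:
    """Fit the parametric embedding on a set of lattice states.

    A UMAP neighbor-graph embedding provides the 2-D training targets; an
    MLP with hidden layers (1000, 100), ReLU activations, and a 2-unit
    output is fitted to reproduce them. The regressor input is the state
    restricted to ``n_input_sites`` uniformly sampled lattice sites.
    """
    import umap  # deferred: numba compilation on first import

    x = np.asarray(states, dtype=float)
    if x.ndim != 2 or x.shape[0] < 50:
        raise ValueError("need at least 50 states to fit the embedding")
    if x.shape[0] <= n_neighbors:
        raise ValueError("need more states than the neighbor count")
    rng = np.random.default_rng(seed)
    if x.shape[1] > n_input_sites:
        site_idx = np.sort(rng.choice(x.shape[1], size=n_input_sites, replace=False))
    else:
        site_idx = np.arange(x.shape[1])
    xin = x[:, site_idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            n_components=2,
            random_state=seed,
        )
        y = reducer.fit_transform(xin)
        reg = MLPRegressor(
            hidden_layer_sizes=(1000, 100),
            activation="relu",
            random_state=seed,
            max_iter=max_iter,
            tol=1e-7,
        )
        reg.fit(xin, y)
    mse = float(np.mean((reg.predict(xin) - y) ** 2))
    return EmbeddingModel(site_idx, reg, np.asarray(y), mse)


def build_surface(
    embedded: np.ndarray, energies: np.ndarray, grid_size: int = 50
) -> EnergySurface:
    """Triangulation-based linear interpolation of energies onto a regular
    grid over the embedded plane; points outside the hull are NaN."""
    pts = np.asarray(embedded, dtype=float)
    e = np.asarray(energies, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least three 2-D points")
    try:
        interp = LinearNDInterpolator(pts, e)
    except QhullError as err:
        raise ValueError("degenerate (collinear) embedding points") from err
    if interp.tri.nsimplex == 0:
        raise ValueError("degenerate (collinear) embedding points")
    gx = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid_size)
    gy = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid_size)
    mx, my = np.meshgrid(gx, gy)
    vals = interp(mx, my)
    return EnergySurface(gx, gy, vals, interp)


def path_length(
    traj: Trajectory | np.ndarray,
    model: EmbeddingModel,
    record_interval: int | None = None,
) -> float:
    """Length of one trajectory in the embedded plane: the sum of Euclidean
    distances between consecutive waypoints.

    Waypoints are the recorded states, optionally thinned so that one
    waypoint is kept every ``record_interval`` dynamics steps.
    """
    if isinstance(traj, Trajectory):
        states = traj.states
        if record_interval is not None:
            stride = max(1, record_interval // traj.record_every)
            states = states[stride - 1 :: stride]
    else:
        states = np.asarray(traj)
    if states.shape[0] < 2:
        warnings.warn("single waypoint: path length is 0")
        return 0.0
    coords = model.transform(states.astype(float))
    return float(np.sum(np.linalg.norm(np.diff(coords, axis=0), axis=1)))


def excess_path_length(waypoints: np.ndarray) -> float:
    """Relaxation path length above the stationary noise floor.

    The total path of a stochastic trajectory mixes directed relaxation
    toward the attractor with stationary boundary flicker and wall
    diffusion; the latter contribute a roughly constant hop size once the
    state has settled. This statistic subtracts each trajectory's own
    floor — the median hop length over the second half of the recording —
    from every hop and sums the positive part, leaving the directed
    (basin-settling) component.
    """
    w = np.asarray(waypoints, dtype=float)
    if w.shape[0] < 3:
        return 0.0
    hops = np.linalg.norm(np.diff(w, axis=0), axis=1)
    floor = np.median(hops[hops.size // 2 :])
    return float(np.maximum(hops - floor, 0.0).sum())


def path_length_sweep(
    lams,
    height: int = 40,
    width: int = 40,
    n_stimuli: int = 12,
    n_steps: int = 15_000,
    record_every: int = 1000,
    beta: float = 100.0,
    seed: int = 0,
):
    """Mean relaxation path length per wiring length lambda.

    A battery of diverse stimuli (random per-cluster fills, contiguous
    block encodings) is run under sustained bottom-up drive at each
    (nominal) lambda; the per-stimulus excess path length in the native
    state space is averaged. Deep global attractors (small lambda) pull
    states far from their inputs, giving long relaxation paths; local
    wiring leaves states near their inputs. Returns ``{lam: mean path}``.
    """
    from . import lattice as lat
    from .synth import StimulusEncoding, encode_stimulus, generate_lattice_patterns

    patterns = generate_lattice_patterns(height, width)
    rng = np.random.default_rng(seed)
    encs = []
    for _ in range(n_stimuli):
        fills = {name: float(rng.uniform(0.05, 0.95)) for name in patterns.names}
        enc = StimulusEncoding(fills, 0.0, int(rng.integers(2**31 - 1)), mode="block")
        encs.append(encode_stimulus(enc, patterns).ravel().astype(float))
    out = {}
    for lam in lams:
        cfg = lat.LatticeConfig(
            height=height, width=width, lam=lat.scale_lambda(lam, height), beta=beta, seed=seed
        )
        coupling = lat.build_coupling(cfg, patterns)
        lengths = []
        for k, e in enumerate(encs):
            sch = lat.ExternalFieldSchedule([(0, n_steps, e)])
            traj = lat.run(
                e.astype(np.int8), coupling, beta=beta, n_steps=n_steps,
                schedule=sch, record_every=record_every, seed=seed + 97 * k,
            )
            lengths.append(excess_path_length(np.vstack([e, traj.states.astype(float)])))
        out[float(lam)] = float(np.mean(lengths))
    return out


def mean_path_length(
    trajs: list[Trajectory],
    model: EmbeddingModel,
    record_interval: int | None = None,
) -> PathLengthResult:
    """Per-stimulus path lengths and their mean/SD over a battery."""
    lengths = []
    counts = []
    for t in trajs:
        lengths.append(path_length(t, model, record_interval))
        n = t.states.shape[0]
        if record_interval is not None:
            n = len(range(max(1, record_interval // t.record_every) - 1, n,
                          max(1, record_interval // t.record_every)))
        counts.append(n)
    return PathLengthResult(np.asarray(lengths), np.asarray(counts))
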
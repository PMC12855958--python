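"""Synthetic inputs: IT-like recordings, lattice memory patterns, stimulus encodings.

This module generates every input the analysis pipeline consumes, with known
ground truth:

* :func:`make_stimulus_design` / :func:`generate_population` emulate the
  structure of a passive-viewing single-unit experiment — a population of
  rate neurons responding to categories x exemplars x views, with a tunable
  category gain, exemplar/view variability, a low-rank shared latent that
  stands in for dense lateral interconnectivity, and additive noise.
* :func:`generate_lattice_patterns` builds the four +/-1 memory patterns
  (face / object / body / place clusters) stored by the attractor lattice.
* :func:`encode_stimulus` maps an abstract stimulus onto an initial +/-1
  lattice state via per-cluster overlap fractions.

All generators are deterministic given an integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "StimulusDesign",
    "PopulationSpec",
    "RecordingTable",
    "PatternSet",
    "StimulusEncoding",
    "make_stimulus_design",
    "generate_population",
    "generate_lattice_patterns",
    "default_cluster_layout",
    "encode_stimulus",
    "write_recording",
    "read_recording",
    "save_patterns",
    "load_patterns",
]

#: Default category names of the passive-viewing experiment.
DEFAULT_CATEGORIES = ("animal", "vehicle", "face", "vegetable", "house", "tool")

#: Default exemplar counts per category (4-11 each, 51 in total; the animal
#: category has 9 exemplars).
DEFAULT_EXEMPLARS = (9, 8, 10, 8, 5, 11)

#: Default number of views per exemplar.
DEFAULT_N_VIEWS = 24

#: Default number of spiky exemplars (of the 51).
DEFAULT_N_SPIKY = 11

#: Names of the four lattice clusters.
CLUSTER_NAMES = ("face", "object", "body", "place")


@dataclass(frozen=True)
class StimulusDesign:
    """Enumeration of all (category, exemplar, view) conditions."""

    categories: tuple[str, ...]
    exemplars_per_category: tuple[int, ...]
    n_views: int
    spiky_flags: tuple[bool, ...]  # one flag per exemplar, global exemplar order

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.exemplars_per_category):
            raise ValueError("one exemplar count required per category")
        if any(n <= 0 for n in self.exemplars_per_category):
            raise ValueError("exemplar counts must be positive")
        if self.n_views <= 0:
            raise ValueError("n_views must be positive")
        if len(self.spiky_flags) != self.n_exemplars:
            raise ValueError("one spiky flag required per exemplar")

    @property
    def n_exemplars(self) -> int:
        return int(sum(self.exemplars_per_category))

    @property
    def n_conditions(self) -> int:
        return self.n_exemplars * self.n_views

    def table(self) -> pd.DataFrame:
        """All conditions in deterministic order (category, exemplar, view)."""
        rows = []
        ex_global = 0
        for cat, n_ex in zip(self.categories, self.exemplars_per_category):
            for _ in range(n_ex):
                for view in range(self.n_views):
                    rows.append(
                        (
                            f"c{ex_global:03d}v{view:02d}",
                            cat,
                            ex_global,
                            view,
                            int(self.spiky_flags[ex_global]),
                        )
                    )
                ex_global += 1
        return pd.DataFrame(
            rows, columns=["condition_id", "category", "exemplar", "view", "spiky"]
        )


@dataclass(frozen=True)
class PopulationSpec:
    """Generative parameters for a synthetic neuron population.

    ``gain_ratio`` is the ratio of the mean response to the preferred
    category over the mean response to non-preferred categories;
    ``shared_factor_weight`` mixes a low-rank latent into every neuron and is
    the recording-side proxy for dense lateral interconnectivity (higher
    weight -> more correlated population -> lower dimensionality).
    """

    n_neurons: int
    gain_ratio: float = 2.0
    exemplar_sd: float = 0.0
    view_sd: float = 0.0
    shared_factor_weight: float = 0.0
    noise_sd: float = 0.0
    baseline: float = 1.0
    preferred_category: str | None = None  # None -> spread across categories
    spiky_fraction: float = 0.0  # fraction of neurons preferring spiky stimuli
    spiky_gain: float = 1.0  # multiplicative gain on spiky conditions
    n_shared_factors: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons <= 0:
            raise ValueError("n_neurons must be positive")
        if self.gain_ratio < 1:
            raise ValueError("gain_ratio must be >= 1")
        for name in ("exemplar_sd", "view_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.shared_factor_weight <= 1.0:
            raise ValueError("shared_factor_weight must lie in [0, 1]")
        if not 0.0 <= self.spiky_fraction <= 1.0:
            raise ValueError("spiky_fraction must lie in [0, 1]")


@dataclass
class RecordingTable:
    """Neurons x conditions firing-rate matrix with stimulus metadata."""

    responses: np.ndarray  # (n_neurons, n_conditions), nonnegative rates
    design: StimulusDesign
    region_label: str = "synthetic"
    ground_truth: PopulationSpec | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-D matrix")
        if self.responses.shape[1] != self.design.n_conditions:
            raise ValueError(
                f"responses have {self.responses.shape[1]} columns but the "
                f"design enumerates {self.design.n_conditions} conditions"
            )
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[0]

    @property
    def metadata(self) -> pd.DataFrame:
        return self.design.table()


@dataclass
class PatternSet:
    """The mu-indexed +/-1 memory patterns defining clusters on the lattice."""

    lattice_height: int
    lattice_width: int
    cluster_masks: dict[str, np.ndarray]  # name -> boolean (H, W)
    patterns: dict[str, np.ndarray] = field(default_factory=dict)  # +/-1 int8

    def __post_init__(self) -> None:
        shape = (self.lattice_height, self.lattice_width)
        total = np.zeros(shape, dtype=int)
        for name, mask in self.cluster_masks.items():
            if mask.shape != shape:
                raise ValueError(f"cluster mask {name!r} has wrong shape")
            total += mask.astype(int)
        if total.max() > 1:
            raise ValueError("cluster masks must be pairwise disjoint")
        if not self.patterns:
            for name, mask in self.cluster_masks.items():
                self.patterns[name] = np.where(mask, 1, -1).astype(np.int8)
        for name, pat in self.patterns.items():
            if not np.all(np.isin(pat, (-1, 1))):
                raise ValueError(f"pattern {name!r} has entries outside {{-1,+1}}")

    @property
    def n_sites(self) -> int:
        return self.lattice_height * self.lattice_width

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.cluster_masks)

    def pattern_matrix(self) -> np.ndarray:
        """Stack the patterns into a (n_patterns, n_sites) +/-1 matrix."""
        return np.stack([self.patterns[n].ravel() for n in self.names]).astype(
            np.int8
        )

    def mask_indices(self) -> dict[str, np.ndarray]:
        return {n: np.flatnonzero(m.ravel()) for n, m in self.cluster_masks.items()}


@dataclass(frozen=True)
class StimulusEncoding:
    """Overlap-based stimulus -> lattice-state code.

    ``overlaps[name]`` is the fraction of sites in cluster ``name`` set to
    +1; sites outside all clusters are -1 except for independent
    ``flip_noise`` flips.
    """

    overlaps: Mapping[str, float]
    flip_noise: float = 0.0
    seed: int = 0
    mode: str = "scatter"  # 'scatter' | 'block' | 'field' (multi-scale blobs)
    field_scales: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0)  # blob scales

    def __post_init__(self) -> None:
        for name, frac in self.overlaps.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"overlap for {name!r} must lie in [0, 1]")
        if not 0.0 <= self.flip_noise <= 1.0:
            raise ValueError("flip_noise must lie in [0, 1]")
        if self.mode not in ("scatter", "block", "field"):
            raise ValueError("mode must be 'scatter', 'block', or 'field'")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def make_stimulus_design(
    categories: Sequence[str] = DEFAULT_CATEGORIES,
    exemplars_per_category: Sequence[int] = DEFAULT_EXEMPLARS,
    n_views: int = DEFAULT_N_VIEWS,
    spiky_flags: Sequence[bool] | None = None,
    n_spiky: int | None = None,
) -> StimulusDesign:
    """Enumerate the full condition set of a passive-viewing experiment.

    The default configuration is the 6-category / 51-exemplar / 24-view
    design (1224 conditions). ``n_spiky`` marks the first ``n_spiky``
    exemplars (in enumeration order) as spiky when explicit flags are not
    given.
    """
    n_exemplars = int(sum(exemplars_per_category))
    if spiky_flags is None:
        if n_spiky is None:
            n_spiky = DEFAULT_N_SPIKY if n_exemplars >= DEFAULT_N_SPIKY else 0
        spiky_flags = tuple(i < n_spiky for i in range(n_exemplars))
    return StimulusDesign(
        categories=tuple(categories),
        exemplars_per_category=tuple(int(n) for n in exemplars_per_category),
        n_views=int(n_views),
        spiky_flags=tuple(bool(f) for f in spiky_flags),
    )


def generate_population(spec: PopulationSpec, design: StimulusDesign) -> RecordingTable:
    """Draw a synthetic neurons x conditions rate table.

    The response of neuron *n* to condition *s* is

    ``baseline + (1 - w) * (signal_ns + noise) + w * (a_n . z_s)``

    rectified at zero, with private tuning ``signal_ns = gain_n *
    1[cat(s) = pref(n)] * (1 + eps_exemplar + eps_view)`` (times the spiky
    gain where applicable), ``w = shared_factor_weight``, and a low-rank
    shared latent ``z_s`` with category-level structure. ``gain_n =
    baseline * (gain_ratio - 1)`` so that in the noiseless unmixed case the
    preferred-category mean is exactly ``gain_ratio`` times the
    non-preferred mean.
    """
    rng = np.random.default_rng(spec.seed)
    meta = design.table()
    n_cond = design.n_conditions
    cats = list(design.categories)

    if spec.preferred_category is not None:
        pref = np.full(spec.n_neurons, cats.index(spec.preferred_category))
    else:
        pref = rng.integers(0, len(cats), size=spec.n_neurons)

    cat_idx = meta["category"].map({c: i for i, c in enumerate(cats)}).to_numpy()
    exemplar = meta["exemplar"].to_numpy()
    spiky = meta["spiky"].to_numpy().astype(bool)

    gain = spec.baseline * (spec.gain_ratio - 1.0)
    preferred = pref[:, None] == cat_idx[None, :]  # (neurons, conditions)

    eps_ex = rng.normal(0.0, spec.exemplar_sd, size=(spec.n_neurons, design.n_exemplars))
    eps_view = rng.normal(0.0, spec.view_sd, size=(spec.n_neurons, n_cond))
    modulation = 1.0 + eps_ex[:, exemplar] + eps_view

    signal = gain * preferred * modulation

    if spec.spiky_fraction > 0:
        n_spiky_pref = int(round(spec.spiky_fraction * spec.n_neurons))
        spiky_pref = np.zeros(spec.n_neurons, dtype=bool)
        spiky_pref[rng.choice(spec.n_neurons, size=n_spiky_pref, replace=False)] = True
        factor = np.where(spiky_pref[:, None] & spiky[None, :], spec.spiky_gain, 1.0)
        signal = (spec.baseline + signal) * factor - spec.baseline

    if spec.shared_factor_weight > 0:
        # interconnectivity proxy: lateral pooling convexly mixes each
        # neuron's private tuning with a population-shared low-rank latent.
        # The latent is organized at the category level (raising
        # within-category similarity and the between-category centroid
        # separation, hence compressing the normalized radius) with a weaker
        # condition-level part (concentrating within-manifold variance on few
        # dimensions, hence compressing the effective dimension); the private
        # signal and noise shrink as (1 - w), as pooling averages them out.
        w_mix = spec.shared_factor_weight
        k = spec.n_shared_factors
        z_cat = np.abs(rng.normal(size=(k + 2, len(cats))))
        z_cond = rng.normal(size=(k, n_cond))
        z = np.vstack([2.0 * z_cat[:, cat_idx], 0.15 * z_cond])
        a_cat = np.abs(rng.normal(size=(spec.n_neurons, k + 2)))
        a_cond = rng.normal(size=(spec.n_neurons, k))
        a = np.hstack([a_cat, a_cond])
        noise = rng.normal(0.0, spec.noise_sd, size=signal.shape) if spec.noise_sd > 0 else 0.0
        resp = spec.baseline + (1.0 - w_mix) * (signal + noise) + w_mix * (a @ z)
    else:
        resp = spec.baseline + signal
        if spec.noise_sd > 0:
            resp = resp + rng.normal(0.0, spec.noise_sd, size=signal.shape)

    resp = np.clip(resp, 0.0, None)
    return RecordingTable(resp, design, region_label="synthetic", ground_truth=spec)


def default_cluster_layout(
    height: int, width: int
) -> dict[str, tuple[int, int, int, int]]:
    """Four rectangular clusters tiling the lattice into quadrants.

    Exhaustive tiling makes the four stored +/-1 patterns mutually
    orthogonal (each pattern is +1 on its own quadrant, -1 on the rest), so
    they are genuine Hopfield attractors. Returns ``name -> (row, col, h, w)``.
    """
    h2, w2 = height // 2, width // 2
    return {
        "face": (0, 0, h2, w2),
        "object": (0, w2, h2, width - w2),
        "body": (h2, 0, height - h2, w2),
        "place": (h2, w2, height - h2, width - w2),
    }


def corner_cluster_layout(
    height: int, width: int, cluster_frac: float = 0.3
) -> dict[str, tuple[int, int, int, int]]:
    """Four square clusters near the corners, leaving background units.

    Background sites are -1 in every pattern, which couples them positively
    to each other and to every cluster and makes the stored patterns
    correlated; use this layout to study background-mediated interactions
    rather than clean pattern retrieval.
    """
    side = max(2, int(round(cluster_frac * min(height, width))))
    m = max(1, side // 3)  # inset from the borders
    return {
        "face": (m, m, side, side),
        "object": (m, width - m - side, side, side),
        "body": (height - m - side, m, side, side),
        "place": (height - m - side, width - m - side, side, side),
    }


def generate_lattice_patterns(
    height: int,
    width: int,
    cluster_layout: Mapping[str, tuple[int, int, int, int]] | None = None,
    seed: int = 0,
) -> PatternSet:
    """Build the four +/-1 memory patterns from rectangular cluster blocks.

    ``cluster_layout`` maps cluster name -> (row, col, h, w); the default is
    four corner squares. Pattern mu is +1 exactly on cluster mu and -1
    elsewhere. Overlapping or out-of-bounds clusters raise ``ValueError``.
    """
    del seed  # rectangular layouts are deterministic; kept for API symmetry
    if height <= 0 or width <= 0:
        raise ValueError("lattice dimensions must be positive")
    if cluster_layout is None:
        cluster_layout = default_cluster_layout(height, width)
    masks: dict[str, np.ndarray] = {}
    for name, (r, c, h, w) in cluster_layout.items():
        if r < 0 or c < 0 or r + h > height or c + w > width:
            raise ValueError(f"cluster {name!r} does not fit inside the lattice")
        mask = np.zeros((height, width), dtype=bool)
        mask[r : r + h, c : c + w] = True
        masks[name] = mask
    return PatternSet(height, width, masks)


def _multiscale_topk(
    idx: np.ndarray,
    lattice_width: int,
    k: int,
    rng: np.random.Generator,
    scales: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0),
) -> np.ndarray:
    """Positions (within ``idx``) of the k largest values of a multi-scale
    Gaussian random field over the cluster's bounding box."""
    from scipy.ndimage import gaussian_filter

    rows, cols = np.divmod(idx, lattice_width)
    r0, c0 = rows.min(), cols.min()
    h, w = rows.max() - r0 + 1, cols.max() - c0 + 1
    fld = np.zeros((h, w))
    for sigma in scales:
        g = gaussian_filter(rng.standard_normal((h, w)), sigma, mode="reflect")
        sd = g.std()
        if sd > 0:
            fld += g / sd
    vals = fld[rows - r0, cols - c0]
    return np.argsort(vals)[::-1][:k]


def encode_stimulus(enc: StimulusEncoding, patterns: PatternSet) -> np.ndarray:
    """Map a stimulus encoding to a +/-1 lattice state of shape (H, W).

    Within cluster ``mu`` exactly ``floor(overlaps[mu] * |mu|)`` sites are
    set to +1; all other cluster sites are -1. In ``'scatter'`` mode the +1
    sites are a seeded random subset; in ``'block'`` mode they form a
    contiguous region grown row-major from a seeded corner of the cluster
    (a single spatially coherent activation blob); in ``'field'`` mode they
    are the top-k cells of a seeded multi-scale Gaussian random field over
    the cluster, giving coherent blobs at several spatial scales (so that
    lateral couplings of different ranges preserve different amounts of
    stimulus detail). Sites outside every cluster are -1, independently
    flipped to +1 with probability ``flip_noise``.
    """
    unknown = set(enc.overlaps) - set(patterns.names)
    if unknown:
        raise ValueError(f"overlaps refer to unknown clusters: {sorted(unknown)}")
    rng = np.random.default_rng(enc.seed)
    state = np.full(patterns.n_sites, -1, dtype=np.int8)
    outside = np.ones(patterns.n_sites, dtype=bool)
    for name, idx in patterns.mask_indices().items():
        outside[idx] = False
        frac = float(enc.overlaps.get(name, 0.0))
        k = int(np.floor(frac * idx.size))
        if k > 0:
            if enc.mode == "block":
                rows, cols = np.divmod(idx, patterns.lattice_width)
                flip_r, flip_c = rng.integers(0, 2, size=2)
                order = np.lexsort(
                    (cols if not flip_c else -cols, rows if not flip_r else -rows)
                )
                state[idx[order[:k]]] = 1
            elif enc.mode == "field":
                top = _multiscale_topk(
                    idx, patterns.lattice_width, k, rng, enc.field_scales
                )
                state[idx[top]] = 1
            else:
                state[rng.choice(idx, size=k, replace=False)] = 1
    if enc.flip_noise > 0:
        out_idx = np.flatnonzero(outside)
        flips = rng.random(out_idx.size) < enc.flip_noise
        state[out_idx[flips]] = 1
    return state.reshape(patterns.lattice_height, patterns.lattice_width)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def write_recording(rec: RecordingTable, responses_path, metadata_path) -> None:
    """Write a recording as a responses TSV + metadata TSV pair."""
    meta = rec.metadata
    df = pd.DataFrame(
        rec.responses,
        index=[f"n{i:04d}" for i in range(rec.n_neurons)],
        columns=meta["condition_id"],
    )
    df.index.name = "neuron_id"
    df.to_csv(responses_path, sep="\t")
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_recording(responses_path, metadata_path, region_label="file") -> RecordingTable:
    """Read a recording written by :func:`write_recording`."""
    df = pd.read_csv(responses_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    cats: list[str] = []
    counts: list[int] = []
    for cat, grp in meta.groupby("category", sort=False):
        cats.append(cat)
        counts.append(grp["exemplar"].nunique())
    n_views = int(meta["view"].nunique())
    spiky = (
        meta.drop_duplicates("exemplar").sort_values("exemplar")["spiky"].astype(bool)
    )
    design = StimulusDesign(tuple(cats), tuple(counts), n_views, tuple(spiky))
    order = meta["condition_id"].tolist()
    return RecordingTable(df[order].to_numpy(), design, region_label=region_label)


def save_patterns(patterns: PatternSet, path) -> None:
    """Persist a :class:`PatternSet` to an HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["lattice_height"] = patterns.lattice_height
        f.attrs["lattice_width"] = patterns.lattice_width
        f.attrs["names"] = json.dumps(list(patterns.names))
        g = f.create_group("cluster_masks")
        for name, mask in patterns.cluster_masks.items():
            g.create_dataset(name, data=mask.astype(np.int8))


def load_patterns(path) -> PatternSet:
    with h5py.File(path, "r") as f:
        names = json.loads(f.attrs["names"])
        masks = {name: f["cluster_masks"][name][()].astype(bool) for name in names}
        return PatternSet(int(f.attrs["lattice_height"]), int(f.attrs["lattice_width"]), masks)
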
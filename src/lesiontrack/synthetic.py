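"""Synthetic cohort, phantom, recruitment and spatial-profiling generators.

Every input the analysis pipeline consumes can be generated here with known
ground truth: lesion volume trajectories with progressing / regressing /
stable kinetics, first-order Markov behavior sequences over the four myeloid
organizational states, multichannel 3D voxel phantoms (TdTomato epithelium,
GFP myeloid, SHG collagen, NADH), peri-lesion GFP recruitment time series, and
negative-binomial AOI x gene count matrices with compartment enrichment and
planted differential expression.

Defaults encode the study conditions of the mouse tongue carcinogenesis
cohort: mean weekly volumetric growth of progressing lesions 24 +/- 10 % per
week; per-state behavior change probabilities 0.49 (basally confined), 0.32
(scattered), 0.58 (multifocal), 0.59 (confluent) per biweekly session; imaging
stacks covering the most superficial 150 um at a 2 um z-step; GFP hotspots
ramping up ~2 weeks before lesion onset; and a 250 um recruitment radius
downstream. All generators are bit-reproducible given (config, seed): one
seed spawns independent per-generator substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MYELOID_STATES, VoxelVolume

__all__ = [
    "CohortConfig",
    "BehaviorConfig",
    "LesionSpec",
    "MyeloidSpec",
    "NadhSpec",
    "NoiseSpec",
    "PhantomConfig",
    "HotspotSpec",
    "RecruitmentConfig",
    "DSPConfig",
    "generate_trajectory_cohort",
    "generate_behavior_sequences",
    "generate_voxel_phantom",
    "generate_recruitment_series",
    "generate_dsp_counts",
]


def _check_finite(name: str, *values) -> None:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name}: non-finite configuration value")


# ---------------------------------------------------------------------------
# Trajectory cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level parameters for trajectory generation.

    ``lesions_per_mouse_by_fate`` gives the Poisson means of per-mouse lesion
    counts for (progressing, regressing, stable); the defaults put the
    expected fate mix near 64/20/16 % with 3–5 progressing, 1–2 regressing
    and about one stable lesion per animal. ``weekly_growth_mean/sd`` are in
    percent per week (defaults 24 and 10). Volume noise is multiplicative
    log-normal with coefficient of variation ``noise_cv``.
    """

    n_mice: int = 8
    lesions_per_mouse_by_fate: tuple[float, float, float] = (3.8, 1.2, 0.95)
    weekly_growth_mean: float = 24.0
    weekly_growth_sd: float = 10.0
    noise_cv: float = 0.10
    session_interval: float = 2.0
    onset_window: tuple[float, float] = (4.0, 12.0)
    endpoint_week: float = 24.0
    detection_floor: float = 1.0e4
    initial_volume_um3: float = 5.0e4
    initial_volume_log2_sd: float = 0.5
    stable_walk_sd: float = 0.10
    p_complete_regression: float = 5.0 / 11.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_finite(
            "CohortConfig",
            self.weekly_growth_mean,
            self.weekly_growth_sd,
            self.noise_cv,
            self.session_interval,
            *self.onset_window,
            self.endpoint_week,
            self.detection_floor,
            self.initial_volume_um3,
            *self.lesions_per_mouse_by_fate,
        )
        if self.n_mice < 0:
            raise ValueError("n_mice must be non-negative")
        if any(m < 0 for m in self.lesions_per_mouse_by_fate):
            raise ValueError("lesion means must be non-negative")
        if self.weekly_growth_sd < 0 or self.noise_cv < 0:
            raise ValueError("rates must be non-negative")
        if self.session_interval <= 0:
            raise ValueError("session_interval must be positive")
        if self.onset_window[0] > self.onset_window[1]:
            raise ValueError("onset_window must be ordered [min, max]")
        if self.endpoint_week <= self.onset_window[1]:
            raise ValueError("endpoint_week must exceed the onset window maximum")


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _lesion_sessions(cfg: CohortConfig, onset: float) -> np.ndarray:
    step = cfg.session_interval
    first = np.ceil(onset / step) * step
    return np.arange(first, cfg.endpoint_week + 0.5 * step, step)


def _progressing_path(cfg, rng, weeks, v0):
    g = rng.normal(cfg.weekly_growth_mean, cfg.weekly_growth_sd)
    g = max(g, -90.0)
    v = v0 * (1.0 + g / 100.0) ** (weeks - weeks[0])
    return v, g


def _regressing_path(cfg, rng, weeks, v0):
    n = weeks.size
    g = max(rng.normal(cfg.weekly_growth_mean, cfg.weekly_growth_sd), 5.0)
    complete = bool(rng.random() < cfg.p_complete_regression)
    peak_idx = int(rng.integers(max(1, n // 3), max(2, 2 * n // 3))) if n > 2 else max(n - 2, 0)
    v = np.empty(n)
    v[: peak_idx + 1] = v0 * (1.0 + g / 100.0) ** (weeks[: peak_idx + 1] - weeks[0])
    peak = v[peak_idx]
    if complete:
        target = cfg.detection_floor * 0.1
    else:
        target = peak * rng.uniform(0.05, 0.22)
    if n - 1 > peak_idx:
        # geometric decay from peak to the target endpoint
        steps = np.arange(1, n - peak_idx)
        frac = (target / peak) ** (steps / (n - 1 - peak_idx))
        v[peak_idx + 1 :] = peak * frac
    else:
        v[-1] = target
    return v, g, complete


def _stable_path(cfg, rng, weeks, v0):
    steps = rng.normal(0.0, cfg.stable_walk_sd, size=weeks.size - 1)
    log2v = np.concatenate([[np.log2(v0)], np.log2(v0) + np.cumsum(steps)])
    return np.power(2.0, log2v)


def generate_trajectory_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-lesion volume trajectories with ground-truth fates.

    Returns
    -------
    trajectories : DataFrame
        Columns ``mouse_id``, ``lesion_id``, ``week``, ``volume_um3``,
        ``censored``. Volumes below the detection floor are reported at the
        floor with ``censored=True``.
    truth : DataFrame
        One row per lesion: ``mouse_id``, ``lesion_id``, ``fate`` (one of
        progressing / regressing_partial / regressing_complete / stable) and
        ``true_weekly_growth_pct`` (NaN for stable lesions).

    Regressing lesions satisfy endpoint <= 25 % of observed peak by
    construction; complete regressors end below the detection floor.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    traj_rows: list[dict] = []
    truth_rows: list[dict] = []
    fate_names = ("progressing", "regressing", "stable")
    for m, child in enumerate(root.spawn(max(cfg.n_mice, 1))[: cfg.n_mice]):
        rng = np.random.default_rng(child)
        mouse = f"m{m:03d}"
        counts = [rng.poisson(mu) for mu in cfg.lesions_per_mouse_by_fate]
        lesion_no = 0
        for fate, k in zip(fate_names, counts):
            for _ in range(k):
                lesion_no += 1
                lesion = f"{mouse}_L{lesion_no:03d}"
                onset = rng.uniform(*cfg.onset_window)
                weeks = _lesion_sessions(cfg, onset)
                if weeks.size < 3:
                    continue
                v0 = cfg.initial_volume_um3 * 2.0 ** rng.normal(0.0, cfg.initial_volume_log2_sd)
                growth = np.nan
                complete = False
                if fate == "progressing":
                    v, growth = _progressing_path(cfg, rng, weeks, v0)
                elif fate == "regressing":
                    v, growth, complete = _regressing_path(cfg, rng, weeks, v0)
                else:
                    v = _stable_path(cfg, rng, weeks, v0)
                v = v * _lognormal_noise(rng, cfg.noise_cv, weeks.size)
                if fate == "regressing":
                    # enforce the endpoint <= 25% of observed peak invariant
                    peak_obs = v[:-1].max()
                    limit = (0.1 * cfg.detection_floor) if complete else 0.22 * peak_obs
                    v[-1] = min(v[-1], limit)
                    peak_obs = max(peak_obs, v[-1])
                censored = v < cfg.detection_floor
                v_rep = np.where(censored, cfg.detection_floor, v)
                label = fate
                if fate == "regressing":
                    label = "regressing_complete" if complete else "regressing_partial"
                for w, vol, c in zip(weeks, v_rep, censored):
                    traj_rows.append(
                        {
                            "mouse_id": mouse,
                            "lesion_id": lesion,
                            "week": float(w),
                            "volume_um3": float(vol),
                            "censored": bool(c),
                        }
                    )
                truth_rows.append(
                    {
                        "mouse_id": mouse,
                        "lesion_id": lesion,
                        "fate": label,
                        "true_weekly_growth_pct": float(growth),
                    }
                )
    traj_cols = ["mouse_id", "lesion_id", "week", "volume_um3", "censored"]
    truth_cols = ["mouse_id", "lesion_id", "fate", "true_weekly_growth_pct"]
    if not traj_rows:
        return pd.DataFrame(columns=traj_cols), pd.DataFrame(columns=truth_cols)
    return pd.DataFrame(traj_rows)[traj_cols], pd.DataFrame(truth_rows)[truth_cols]


# ---------------------------------------------------------------------------
# Behavior sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorConfig:
    """First-order Markov model over the four myeloid organizational states.

    ``change_prob_by_state`` is the per-session probability of leaving each
    state (defaults 0.49 / 0.32 / 0.58 / 0.59 for basally confined, scattered,
    multifocal, confluent). When a change occurs from a non-basal state, a
    ``revert_bias`` fraction of the change mass targets the basally confined
    configuration and the rest splits evenly over the remaining states; from
    the basal state the change mass splits evenly over the other three.
    """

    change_prob_by_state: dict = field(
        default_factory=lambda: {
            "basally_confined": 0.49,
            "scattered": 0.32,
            "multifocal": 0.58,
            "confluent": 0.59,
        }
    )
    revert_bias: float = 0.6
    sequence_length: int = 9
    n_lesions: int = 40
    n_mice: int = 8
    session_interval: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.change_prob_by_state) - set(MYELOID_STATES)
        if unknown:
            raise ValueError(f"unknown state names: {sorted(unknown)}")
        missing = set(MYELOID_STATES) - set(self.change_prob_by_state)
        if missing:
            raise ValueError(f"missing change probabilities for: {sorted(missing)}")
        probs = list(self.change_prob_by_state.values()) + [self.revert_bias]
        _check_finite("BehaviorConfig", *probs)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.sequence_length < 1 or self.n_lesions < 0 or self.n_mice < 1:
            raise ValueError("sequence_length, n_lesions, n_mice out of range")

    def transition_matrix(self) -> pd.DataFrame:
        """Row-stochastic true transition matrix implied by the config."""
        states = MYELOID_STATES
        P = pd.DataFrame(0.0, index=states, columns=states)
        for s in states:
            c = self.change_prob_by_state[s]
            P.loc[s, s] = 1.0 - c
            others = [t for t in states if t != s]
            if s == "basally_confined":
                for t in others:
                    P.loc[s, t] = c / 3.0
            else:
                non_basal = [t for t in others if t != "basally_confined"]
                P.loc[s, "basally_confined"] = c * self.revert_bias
                for t in non_basal:
                    P.loc[s, t] = c * (1.0 - self.revert_bias) / len(non_basal)
        return P


def generate_behavior_sequences(config: BehaviorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate behavior-state sequences from the configured Markov chain.

    Returns (sequences, true transition matrix). ``sequences`` has columns
    ``lesion_id``, ``mouse_id``, ``session``, ``week``, ``lesion_age``,
    ``state``; initial states are drawn uniformly.
    """
    cfg = config
    P = cfg.transition_matrix()
    states = list(P.index)
    cum = P.to_numpy().cumsum(axis=1)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    rows = []
    for i in range(cfg.n_lesions):
        mouse = f"m{i % cfg.n_mice:03d}"
        lesion = f"L{i:04d}"
        s = int(rng.integers(len(states)))
        for session in range(cfg.sequence_length):
            rows.append(
                {
                    "lesion_id": lesion,
                    "mouse_id": mouse,
                    "session": session,
                    "week": session * cfg.session_interval,
                    "lesion_age": session * cfg.session_interval,
                    "state": states[s],
                }
            )
            s = int(np.searchsorted(cum[s], rng.random(), side="right"))
    cols = ["lesion_id", "mouse_id", "session", "week", "lesion_age", "state"]
    return (pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)), P


# ---------------------------------------------------------------------------
# Voxel phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LesionSpec:
    """Ellipsoidal lesion: center and semi-axes in um (z, y, x) plus fate."""

    center_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    fate: str = "progressing"


@dataclass(frozen=True)
class MyeloidSpec:
    """Myeloid content of one lesion: organizational state and cell geometry."""

    state: str = "scattered"
    cell_radius_um: float = 4.0
    count: int = 25
    n_clusters: int = 3
    cluster_radius_um: float = 13.0

    def __post_init__(self) -> None:
        if self.state not in MYELOID_STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.cell_radius_um <= 0 or self.cluster_radius_um <= 0:
            raise ValueError("radii must be positive")
        if self.count < 0 or self.n_clusters < 1:
            raise ValueError("count/n_clusters out of range")

    @classmethod
    def for_state(cls, state: str) -> "MyeloidSpec":
        """State defaults with cell density rising from basal to confluent."""
        counts = {"basally_confined": 12, "scattered": 25, "multifocal": 25, "confluent": 25}
        return cls(state=state, count=counts[state])


@dataclass(frozen=True)
class NadhSpec:
    baseline: float = 100.0
    decline_week: float | None = None
    decline_fraction: float = 0.5


@dataclass(frozen=True)
class NoiseSpec:
    gaussian_sd: float = 0.0
    poisson_scale: float = 0.0  # 0 disables shot noise


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry of a multichannel imaging phantom.

    Defaults reproduce the acquisition geometry: a 150 um deep stack at a
    2 um z-step (75 slices) with 1 um lateral sampling. The epithelium spans
    the top ``epithelium_thickness`` um, the basement membrane is the flat
    surface at that depth and fibrillar collagen forms a slab beneath it.
    """

    grid_shape: tuple[int, int, int] = (75, 128, 128)
    voxel_size: tuple[float, float, float] = (2.0, 1.0, 1.0)
    epithelium_thickness: float = 60.0
    collagen_thickness: float = 20.0
    lesion_spec: tuple[LesionSpec, ...] = (
        LesionSpec(center_um=(30.0, 64.0, 64.0), semi_axes_um=(25.0, 55.0, 55.0)),
    )
    myeloid_spec: tuple[MyeloidSpec, ...] = (MyeloidSpec(),)
    nadh_spec: NadhSpec = field(default_factory=NadhSpec)
    noise_spec: NoiseSpec = field(default_factory=NoiseSpec)
    week: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lesion_spec) != len(self.myeloid_spec):
            raise ValueError("need one myeloid spec per lesion")
        extent = tuple(n * s for n, s in zip(self.grid_shape, self.voxel_size))
        for les in self.lesion_spec:
            for c, a, e in zip(les.center_um, les.semi_axes_um, extent):
                if a <= 0:
                    raise ValueError("semi-axes must be positive")
                if c - a < 0 or c + a > e:
                    raise ValueError(f"lesion ellipsoid {les} does not fit inside the grid")
        if self.noise_spec.gaussian_sd < 0 or self.noise_spec.poisson_scale < 0:
            raise ValueError("noise parameters must be non-negative")


def _coord_grids(shape, voxel_size):
    z = np.arange(shape[0], dtype=float)[:, None, None] * voxel_size[0]
    y = np.arange(shape[1], dtype=float)[None, :, None] * voxel_size[1]
    x = np.arange(shape[2], dtype=float)[None, None, :] * voxel_size[2]
    return z, y, x


def _ellipsoid_mask(shape, voxel_size, center, semi_axes):
    z, y, x = _coord_grids(shape, voxel_size)
    return (
        ((z - center[0]) / semi_axes[0]) ** 2
        + ((y - center[1]) / semi_axes[1]) ** 2
        + ((x - center[2]) / semi_axes[2]) ** 2
    ) <= 1.0


def _sphere_mask(shape, voxel_size, center, radius):
    return _ellipsoid_mask(shape, voxel_size, center, (radius, radius, radius))


def _place_myeloid(
    cfg: PhantomConfig, les: LesionSpec, mye: MyeloidSpec, rng: np.random.Generator
):
    """Return a list of (center_um, radius_um) objects realizing the state.

    Scattered cells are rejection-sampled with a separation margin so planted
    objects stay distinct connected components; clusters/aggregates are
    rendered as single spheres.
    """
    cz, cy, cx = les.center_um
    az, ay, ax = les.semi_axes_um
    membrane = cfg.epithelium_thickness
    objs: list[tuple[tuple[float, float, float], float]] = []

    def sample_inside(radius, z_range=None, max_tries=2000):
        margin = 2.0 * radius + 3.0
        for _ in range(max_tries):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = rng.uniform(0, 1) ** (1 / 3)
            p = np.array([cz, cy, cx]) + r * u * (np.array([az, ay, ax]) - radius - 1.0)
            if z_range is not None:
                p[0] = rng.uniform(*z_range)
            if all(np.linalg.norm(p - np.array(o[0])) >= margin + o[1] for o in objs):
                return tuple(p)
        raise RuntimeError("could not place myeloid object without overlap")

    r = mye.cell_radius_um
    if mye.state == "basally_confined":
        band = (max(membrane - 12.0, cz - az + r), membrane - r - 1.0)
        for _ in range(mye.count):
            objs.append((sample_inside(r, z_range=band), r))
    elif mye.state == "scattered":
        for _ in range(mye.count):
            objs.append((sample_inside(r), r))
    elif mye.state == "multifocal":
        for _ in range(mye.n_clusters):
            objs.append((sample_inside(mye.cluster_radius_um), mye.cluster_radius_um))
    else:  # confluent: one dominant aggregate plus a few stragglers
        big = 1.7 * mye.cluster_radius_um
        objs.append((sample_inside(big), big))
        for _ in range(min(mye.count, 8)):
            objs.append((sample_inside(r), r))
    return objs


def generate_voxel_phantom(config: PhantomConfig) -> tuple[dict, dict]:
    """Render the four-channel phantom plus ground-truth labels.

    Returns
    -------
    channels : dict of str -> VoxelVolume
        Keys ``tdtomato``, ``gfp``, ``shg``, ``nadh``.
    truth : dict
        ``lesion_mask`` (bool, union of lesions), ``lesion_masks`` (list per
        lesion), ``membrane_depth_um`` (scalar), ``myeloid_labels`` (int
        volume, one id per planted object), ``components`` (DataFrame:
        component_id, voxel_count, volume_um3, state, lesion_index — volumes
        are exactly voxel_count x voxel volume), ``states`` (list per lesion).
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    shape, vs = cfg.grid_shape, cfg.voxel_size
    z_um, _, _ = _coord_grids(shape, vs)
    voxvol = float(np.prod(vs))

    epi = np.broadcast_to(z_um < cfg.epithelium_thickness, shape)
    collagen = np.broadcast_to(
        (z_um >= cfg.epithelium_thickness)
        & (z_um < cfg.epithelium_thickness + cfg.collagen_thickness),
        shape,
    )

    lesion_masks = [
        _ellipsoid_mask(shape, vs, les.center_um, les.semi_axes_um) for les in cfg.lesion_spec
    ]
    lesion_mask = np.logical_or.reduce(lesion_masks) if lesion_masks else np.zeros(shape, bool)

    tdt = np.where(epi, 150.0, 10.0)
    tdt[lesion_mask] = 200.0
    shg = np.where(collagen, 50.0, 0.0)

    gfp = np.ones(shape)  # faint autofluorescence background
    labels = np.zeros(shape, dtype=np.int32)
    comp_rows = []
    states = []
    next_id = 1
    for li, (les, mye) in enumerate(zip(cfg.lesion_spec, cfg.myeloid_spec)):
        states.append(mye.state)
        if mye.count == 0 and mye.state != "multifocal":
            continue
        for center, radius in _place_myeloid(cfg, les, mye, rng):
            m = _sphere_mask(shape, vs, center, radius)
            if not m.any():
                continue
            gfp[m] = 200.0
            labels[m] = next_id
            comp_rows.append(
                {
                    "component_id": next_id,
                    "voxel_count": int(m.sum()),
                    "volume_um3": float(m.sum()) * voxvol,
                    "state": mye.state,
                    "lesion_index": li,
                }
            )
            next_id += 1

    nadh = np.where(epi, cfg.nadh_spec.baseline, 0.0)
    if cfg.nadh_spec.decline_week is not None and cfg.week >= cfg.nadh_spec.decline_week:
        nadh[lesion_mask] = cfg.nadh_spec.baseline * cfg.nadh_spec.decline_fraction

    def add_noise(arr):
        out = arr.astype(float)
        ns = cfg.noise_spec
        if ns.poisson_scale > 0:
            out = rng.poisson(out * ns.poisson_scale) / ns.poisson_scale
        if ns.gaussian_sd > 0:
            out = out + rng.normal(0.0, ns.gaussian_sd, size=out.shape)
        return np.clip(out, 0.0, None)

    channels = {
        "tdtomato": VoxelVolume(add_noise(tdt), vs, "TdTomato", cfg.week),
        "gfp": VoxelVolume(add_noise(gfp), vs, "GFP", cfg.week),
        "shg": VoxelVolume(add_noise(shg), vs, "SHG", cfg.week),
        "nadh": VoxelVolume(add_noise(nadh), vs, "NADH", cfg.week),
    }
    comp_cols = ["component_id", "voxel_count", "volume_um3", "state", "lesion_index"]
    truth = {
        "lesion_mask": lesion_mask,
        "lesion_masks": lesion_masks,
        "membrane_depth_um": cfg.epithelium_thickness,
        "myeloid_labels": labels,
        "components": pd.DataFrame(comp_rows, columns=comp_cols),
        "states": states,
    }
    return channels, truth


# ---------------------------------------------------------------------------
# Recruitment series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HotspotSpec:
    """Gaussian GFP hotspot preceding a lesion onset."""

    center_um: tuple[float, float]
    amplitude: float = 80.0
    sigma_um: float = 120.0
    onset_week: float = 8.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("hotspot amplitude must be non-negative")
        if self.sigma_um <= 0:
            raise ValueError("hotspot sigma must be positive")


@dataclass(frozen=True)
class RecruitmentConfig:
    """2D sum-projection time series with pre-onset GFP hotspots.

    Hotspot amplitude ramps linearly from zero starting ``lead_time_weeks``
    (default 2) before each lesion's onset and saturates at onset.
    """

    field_shape: tuple[int, int] = (200, 280)
    pixel_size_um: float = 5.0
    background: float = 100.0
    hotspots: tuple[HotspotSpec, ...] = (HotspotSpec(center_um=(500.0, 700.0)),)
    lead_time_weeks: float = 2.0
    weeks: tuple[float, ...] = tuple(float(w) for w in range(0, 25, 2))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lead_time_weeks < 0 or self.noise_sd < 0 or self.background < 0:
            raise ValueError("config values must be non-negative")

    def tongue_mask(self) -> np.ndarray:
        """Elliptical tongue footprint inset from the field borders."""
        ny, nx = self.field_shape
        yy, xx = np.indices(self.field_shape, dtype=float)
        return ((yy - ny / 2) / (0.46 * ny)) ** 2 + ((xx - nx / 2) / (0.46 * nx)) ** 2 <= 1.0


def generate_recruitment_series(config: RecruitmentConfig) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Simulate the weekly GFP sum-projection series around lesion onsets.

    Returns (stack of 2D images, weeks x Y x X; tongue mask; onset table with
    columns ``lesion_id``, ``onset_week``, ``cy_um``, ``cx_um``).
    """
    cfg = config
    mask = cfg.tongue_mask()
    yy, xx = np.indices(cfg.field_shape, dtype=float)
    yy, xx = yy * cfg.pixel_size_um, xx * cfg.pixel_size_um
    for h in cfg.hotspots:
        iy = int(round(h.center_um[0] / cfg.pixel_size_um))
        ix = int(round(h.center_um[1] / cfg.pixel_size_um))
        if not (0 <= iy < cfg.field_shape[0] and 0 <= ix < cfg.field_shape[1] and mask[iy, ix]):
            raise ValueError(f"hotspot center {h.center_um} lies outside the tongue mask")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    frames = []
    for week in cfg.weeks:
        img = np.full(cfg.field_shape, cfg.background, dtype=float)
        for h in cfg.hotspots:
            if cfg.lead_time_weeks == 0:
                ramp = 1.0 if week >= h.onset_week else 0.0
            else:
                ramp = np.clip((week - (h.onset_week - cfg.lead_time_weeks)) / cfg.lead_time_weeks, 0.0, 1.0)
            if ramp > 0:
                r2 = (yy - h.center_um[0]) ** 2 + (xx - h.center_um[1]) ** 2
                img += ramp * h.amplitude * np.exp(-r2 / (2.0 * h.sigma_um**2))
        if cfg.noise_sd > 0:
            img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
        img[~mask] = 0.0
        frames.append(np.clip(img, 0.0, None))
    onsets = pd.DataFrame(
        {
            "lesion_id": [f"L{i:03d}" for i in range(len(cfg.hotspots))],
            "onset_week": [h.onset_week for h in cfg.hotspots],
            "cy_um": [h.center_um[0] for h in cfg.hotspots],
            "cx_um": [h.center_um[1] for h in cfg.hotspots],
        }
    )
    return np.stack(frames), mask, onsets


# ---------------------------------------------------------------------------
# DSP counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DSPConfig:
    """Negative-binomial AOI x gene count matrix with planted structure.

    Genes belong to one of three compartments (myeloid / epithelial / other);
    a gene's mean is multiplied by ``compartment_enrichment`` in AOIs of its
    own class. ``de_log2fc`` plants clustered-vs-scattered differential
    expression in myeloid AOIs: positive values are up in clustered lesions
    (interferon-program genes Cxcl9/Cxcl10/Isg15/Irf7 by default), negative
    values up in scattered lesions (Mmp12/Apoe/Lipa). Gene and AOI counts are
    scaled down from the full profiling experiment for tractable simulation;
    the compartment proportions echo the real partition.
    """

    n_genes: dict = field(
        default_factory=lambda: {"myeloid": 120, "epithelial": 230, "other": 50}
    )
    n_aois_per_class: int = 24
    nb_mean: float = 50.0
    nb_dispersion: float = 2.0
    compartment_enrichment: float = 4.0
    gene_mean_log2_sd: float = 0.5
    aoi_size_log2_sd: float = 0.3
    de_log2fc: dict = field(
        default_factory=lambda: {
            "Cxcl9": 2.0,
            "Cxcl10": 2.0,
            "Isg15": 1.5,
            "Irf7": 1.5,
            "Mmp12": -2.0,
            "Apoe": -2.0,
            "Lipa": -2.0,
        }
    )
    aois_per_lesion: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.compartment_enrichment < 1.0:
            raise ValueError("compartment_enrichment must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.nb_mean <= 0:
            raise ValueError("nb_mean must be positive")
        if set(self.n_genes) != {"myeloid", "epithelial", "other"}:
            raise ValueError("n_genes must key myeloid/epithelial/other")
        if self.n_aois_per_class < 1 or self.aois_per_lesion < 1:
            raise ValueError("AOI counts out of range")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, k: float) -> np.ndarray:
    """NB draws parameterized by mean m and dispersion k (var = m + m^2/k)."""
    p = k / (k + mean)
    return rng.negative_binomial(k, p)


def generate_dsp_counts(config: DSPConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate the AOI x gene count matrix with ground truth.

    Returns
    -------
    counts : DataFrame, genes x AOIs.
    annotation : DataFrame indexed by AOI id with columns ``class``
        (myeloid / epithelial / other), ``lesion_id`` and ``group``
        (clustered / scattered for myeloid AOIs, none otherwise).
    truth : dict with ``compartments`` (Series gene -> compartment) and
        ``de_log2fc`` (the planted myeloid DE effects).
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    genes, compartments = [], []
    de_names = list(cfg.de_log2fc)
    for i, name in enumerate(de_names):
        genes.append(name)
        compartments.append("myeloid")
    for comp in ("myeloid", "epithelial", "other"):
        n = cfg.n_genes[comp] - (len(de_names) if comp == "myeloid" else 0)
        if n < 0:
            raise ValueError("n_genes['myeloid'] smaller than the planted DE set")
        tag = {"myeloid": "My", "epithelial": "Ep", "other": "Ot"}[comp]
        for i in range(n):
            genes.append(f"{tag}{i:04d}")
            compartments.append(comp)
    compartments = pd.Series(compartments, index=genes, name="compartment")

    aoi_ids, aoi_class, aoi_lesion, aoi_group = [], [], [], []
    for comp in ("myeloid", "epithelial", "other"):
        n_lesions = int(np.ceil(cfg.n_aois_per_class / cfg.aois_per_lesion))
        for j in range(cfg.n_aois_per_class):
            lesion_no = j // cfg.aois_per_lesion
            aoi_ids.append(f"{comp[:2]}_aoi{j:03d}")
            aoi_class.append(comp)
            aoi_lesion.append(f"{comp[:2]}_les{lesion_no}")
            if comp == "myeloid":
                aoi_group.append("clustered" if lesion_no % 2 == 0 else "scattered")
            else:
                aoi_group.append("none")
        del n_lesions
    annotation = pd.DataFrame(
        {"class": aoi_class, "lesion_id": aoi_lesion, "group": aoi_group},
        index=pd.Index(aoi_ids, name="aoi_id"),
    )

    base_mean = cfg.nb_mean * 2.0 ** rng.normal(0.0, cfg.gene_mean_log2_sd, size=len(genes))
    size_factor = 2.0 ** rng.normal(0.0, cfg.aoi_size_log2_sd, size=len(aoi_ids))

    mean = np.tile(base_mean[:, None], (1, len(aoi_ids)))
    comp_arr = compartments.to_numpy()
    class_arr = annotation["class"].to_numpy()
    group_arr = annotation["group"].to_numpy()
    mean *= np.where(comp_arr[:, None] == class_arr[None, :], cfg.compartment_enrichment, 1.0)
    for name, lfc in cfg.de_log2fc.items():
        gi = genes.index(name)
        myeloid_cols = class_arr == "myeloid"
        mean[gi, myeloid_cols & (group_arr == "clustered")] *= 2.0 ** (lfc / 2.0)
        mean[gi, myeloid_cols & (group_arr == "scattered")] *= 2.0 ** (-lfc / 2.0)
    mean *= size_factor[None, :]

    counts = pd.DataFrame(
        _nb_sample(rng, mean, cfg.nb_dispersion),
        index=pd.Index(genes, name="gene"),
        columns=annotation.index,
    )
    truth = {"compartments": compartments, "de_log2fc": dict(cfg.de_log2fc)}
    return counts, annotation, truth
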
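"""Synthetic phantom head and cohort generator.

Every algorithm and metric in the package is testable without MRI data via a
phantom: a spherical head containing a folded cortical shell, an analytic
distance-to-scalp map, a two-network parcellation, and multi-session BOLD
time series with planted seed-coupled blobs.

The signal model is deliberately minimal but captures exactly the structure
the targeting algorithms exploit:

* the seed signal is a unit-variance white Gaussian process (an AR(1) option
  adds temporal smoothness for realism; the algorithms are insensitive to it);
* each voxel's series is ``coupling(x) * seed + noise``, where ``coupling``
  is a sum of signed Gaussian bumps at planted centres — so the population
  Pearson correlation with the seed is ``c / sqrt(c^2 + sigma^2)``, giving a
  closed-form check on every connectivity estimate;
* between-subject variability is a rigid jitter plus amplitude scaling of the
  bumps (shared across that subject's sessions), within-subject variability
  is fresh session noise — enough to make inter- and intra-individual
  distances meaningfully different without diffeomorphic warps;
* the cortical shell's outer surface is modulated sinusoidally, creating
  gyral (shallow) and sulcal (deep) territory so near-scalp selection has
  something to select.

All randomness flows from explicit integer seeds; equal spec + seeds give
bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .connectivity import SeedTimecourse, TimeSeriesVolume, WeightMap
from .volumes import LabelMap, Mask, ScalarMap, VolumeGrid, isotropic_grid, sphere_mask


@dataclass(frozen=True)
class PlantedBlob:
    """A seed-coupled Gaussian bump: the ground-truth target (or distractor)."""

    center_mm: tuple[float, float, float]
    amplitude: float  # signed coupling at the centre; negative = anticorrelated
    sigma_mm: float = 6.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic head and its signal model.

    Defaults describe the standard study condition: a 40^3 grid of 2 mm
    voxels, a 36 mm-radius head, a 10 mm cortical shell whose outer surface
    sits 6 +/- 3 mm below the scalp (3 mm fold amplitude, 4 angular cycles),
    one near-scalp anticorrelated blob of coupling -0.8 planted on a gyral
    crown, unit noise, and 240-frame runs.
    """

    shape: tuple[int, int, int] = (40, 40, 40)
    voxel_mm: float = 2.0
    head_radius_mm: float = 36.0
    shell_gap_mm: float = 6.0          # scalp to outer gray surface (at fold = 0)
    shell_thickness_mm: float = 10.0
    fold_frequency: int = 4            # angular cycles of the gyral folds
    fold_amplitude_mm: float = 3.0
    planted: tuple[PlantedBlob, ...] = ()
    seed_region_center_mm: tuple[float, float, float] | None = None
    seed_region_radius_mm: float = 8.0
    seed_region_coupling: float = 0.9
    network_radius_mm: float = 18.0    # target-network blob around each planted centre
    search_radius_mm: float = 22.0     # anatomical search mask around planted centres
    subject_jitter_mm: float = 3.0
    amplitude_jitter_sd: float = 0.1
    noise_sigma: float = 1.0
    T: int = 240
    seed_ar1: float = 0.0              # 0 = white seed process
    seed: int = 0

    @property
    def center_mm(self) -> np.ndarray:
        return np.array(self.shape, float) * self.voxel_mm / 2.0

    def grid(self) -> VolumeGrid:
        return isotropic_grid(self.shape, self.voxel_mm)


def _fold(theta: np.ndarray, phi: np.ndarray, frequency: int) -> np.ndarray:
    """Smooth fold field in [-1, 1]: sinusoidal in azimuth, tapered at poles."""
    return np.sin(frequency * theta) * np.sin(phi) ** 2


def gyral_direction(spec: PhantomSpec) -> np.ndarray:
    """Unit vector toward a gyral crown (fold field = +1, on the equator)."""
    theta = np.pi / (2 * spec.fold_frequency)
    return np.array([np.cos(theta), np.sin(theta), 0.0])


def sulcal_direction(spec: PhantomSpec) -> np.ndarray:
    """Unit vector toward a sulcal fundus (fold field = -1, on the equator)."""
    theta = -np.pi / (2 * spec.fold_frequency)
    return np.array([np.cos(theta), np.sin(theta), 0.0])


def default_spec(two_blob: bool = False, **overrides) -> PhantomSpec:
    """Standard study conditions with concretely placed blobs.

    The single-blob phantom plants one unambiguous near-scalp anticorrelated
    blob on a gyral crown. The two-blob phantom adds a *stronger* blob at a
    sulcal fundus — connectivity alone prefers the deep blob, so algorithms
    that ignore scalp proximity are pulled away from the shallow one.
    """
    base = PhantomSpec(**overrides)
    c = base.center_mm
    r_gyral = base.head_radius_mm - base.shell_gap_mm + base.fold_amplitude_mm
    r_sulcal = base.head_radius_mm - base.shell_gap_mm - base.fold_amplitude_mm
    # the near-scalp truth sits on the gyral crown, in the shallow band the
    # depth thresholds retain (~1 voxel below the outer cortical surface)
    shallow = tuple(c + gyral_direction(base) * (r_gyral - 1.0))
    blobs = [PlantedBlob(shallow, amplitude=-0.8)]
    if two_blob:
        deep = tuple(c + sulcal_direction(base)
                     * (r_sulcal - base.shell_thickness_mm + 4.0))
        blobs = [PlantedBlob(shallow, amplitude=-0.55),
                 PlantedBlob(deep, amplitude=-0.95)]
    seed_center = tuple(c - gyral_direction(base)
                        * (base.head_radius_mm - base.shell_gap_mm
                           - base.shell_thickness_mm / 2.0))
    return replace(base, planted=tuple(blobs),
                   seed_region_center_mm=seed_center)


@dataclass
class PhantomSubject:
    """One synthetic participant: anatomy, signals, and the planted truth."""

    spec: PhantomSpec
    grid: VolumeGrid
    head: Mask
    gray: Mask
    depth: ScalarMap                   # analytic distance-to-scalp on gray
    outer_surface: Mask                # gray voxels at the outer shell surface
    parcellation: LabelMap             # 1 = target network, 2 = other gray
    search_mask: Mask                  # anatomical search region (group-level)
    weight_map: WeightMap              # group-weight analog for the deep seed
    sessions: list[TimeSeriesVolume]
    seed_timecourses: list[SeedTimecourse]  # generating seed signal per session
    truth_mm: np.ndarray               # jittered planted centres, (n_blobs, 3)
    target_networks: tuple[int, ...] = (1,)


# ---------------------------------------------------------------------------
# Anatomy
# ---------------------------------------------------------------------------


def make_head(spec: PhantomSpec) -> tuple[Mask, Mask, ScalarMap, Mask]:
    """Build head mask, folded gray shell, analytic depth, and outer surface.

    The head is the ball of ``head_radius_mm``; the gray shell spans
    ``[r_out - thickness, r_out]`` where ``r_out`` is the fold-modulated
    outer cortical radius. Analytic distance-to-scalp of an interior point at
    radius ``r`` is ``R - r`` (nearest scalp point lies on the same ray).
    """
    if spec.shell_thickness_mm < spec.voxel_mm:
        raise ValueError("cortical shell thinner than one voxel")
    if spec.shell_gap_mm <= spec.fold_amplitude_mm:
        raise ValueError("folds would pierce the scalp: need gap > amplitude")
    grid = spec.grid()
    coords = grid.all_world_coords() - spec.center_mm
    r = np.linalg.norm(coords, axis=-1)
    with np.errstate(invalid="ignore"):
        theta = np.arctan2(coords[..., 1], coords[..., 0])
        phi = np.arccos(np.clip(np.divide(coords[..., 2], r,
                                          out=np.zeros_like(r), where=r > 0),
                                -1, 1))
    g = _fold(theta, phi, spec.fold_frequency)
    r_out = spec.head_radius_mm - spec.shell_gap_mm + spec.fold_amplitude_mm * g
    r_in = r_out - spec.shell_thickness_mm

    head = Mask(grid, r <= spec.head_radius_mm)
    gray = Mask(grid, (r >= r_in) & (r <= r_out))
    depth_val = np.where(gray.member, spec.head_radius_mm - r, np.nan)
    depth = ScalarMap(grid, depth_val, Mask(grid, gray.member.copy()))
    outer = Mask(grid, gray.member & (r >= r_out - spec.voxel_mm))
    return head, gray, depth, outer


# ---------------------------------------------------------------------------
# Signals
# ---------------------------------------------------------------------------


def _seed_process(rng: np.random.Generator, T: int, ar1: float) -> np.ndarray:
    s = rng.standard_normal(T)
    if ar1 > 0:
        for t in range(1, T):
            s[t] = ar1 * s[t - 1] + np.sqrt(1 - ar1 ** 2) * s[t]
    return s


def coupling_field(spec: PhantomSpec, grid: VolumeGrid, gray: Mask,
                   centers_mm: np.ndarray, amplitudes: np.ndarray) -> np.ndarray:
    """Sum of signed Gaussian bumps, plus the positively coupled seed region."""
    coords = grid.all_world_coords()
    c = np.zeros(grid.shape)
    for center, amp, blob in zip(centers_mm, amplitudes, spec.planted):
        d2 = ((coords - center) ** 2).sum(axis=-1)
        c += amp * np.exp(-d2 / (2 * blob.sigma_mm ** 2))
    if spec.seed_region_center_mm is not None:
        d2 = ((coords - np.asarray(spec.seed_region_center_mm)) ** 2).sum(axis=-1)
        inside = d2 <= spec.seed_region_radius_mm ** 2
        c = np.where(inside, spec.seed_region_coupling, c)
    return np.where(gray.member, c, 0.0)


def make_subject(spec: PhantomSpec, subject_seed: int,
                 session_seeds: Sequence[int]) -> PhantomSubject:
    """Generate one subject with ``len(session_seeds)`` sessions.

    The subject seed fixes the between-subject perturbation (blob jitter and
    amplitude scale, network-blob jitter); each session seed fixes that
    session's seed process and voxel noise. Anatomy is shared across the
    cohort (identity registration between phantom subjects).
    """
    if not spec.planted:
        raise ValueError("spec plants no blobs; use default_spec()")
    if not session_seeds:
        raise ValueError("need at least one session seed")
    head, gray, depth, outer = make_head(spec)
    grid = spec.grid()

    srng = np.random.default_rng([spec.seed, int(subject_seed)])
    jitter = srng.uniform(-spec.subject_jitter_mm, spec.subject_jitter_mm, 3)
    scale = float(np.clip(1.0 + spec.amplitude_jitter_sd * srng.standard_normal(),
                          0.2, None))
    # between-subject displacement acts along the cortical sheet: project the
    # jitter onto the tangent plane of each blob's radial direction so blobs
    # stay at their cortical depth instead of drifting out of the tissue
    centers = np.array([b.center_mm for b in spec.planted], dtype=float)
    for i in range(len(centers)):
        radial = centers[i] - spec.center_mm
        u = radial / np.linalg.norm(radial)
        centers[i] += jitter - (jitter @ u) * u
    amps = np.array([b.amplitude for b in spec.planted]) * scale

    coupling = coupling_field(spec, grid, gray, centers, amps)

    # parcellation: target network = gray near any (jittered) planted centre
    in_network = np.zeros(grid.shape, dtype=bool)
    for center in centers:
        in_network |= sphere_mask(grid, center, spec.network_radius_mm).member
    labels = np.zeros(grid.shape, dtype=np.int32)
    labels[gray.member] = 2
    labels[gray.member & in_network] = 1
    parcellation = LabelMap(grid, labels)

    # anatomical search mask: spheres at the *nominal* (group-level) centres
    search = np.zeros(grid.shape, dtype=bool)
    for blob in spec.planted:
        search |= sphere_mask(grid, blob.center_mm, spec.search_radius_mm).member
    search_mask = Mask(grid, search & gray.member)

    # group-weight analog: uniform weight on the deep seed region, with the
    # search mask excluded from the weighted average
    wvals = np.zeros(grid.shape)
    if spec.seed_region_center_mm is not None:
        wvals[sphere_mask(grid, spec.seed_region_center_mm,
                          spec.seed_region_radius_mm).member] = 1.0
    weight_map = WeightMap(
        ScalarMap(grid, wvals, Mask(grid, np.ones(grid.shape, bool))),
        exclusion=Mask(grid, search_mask.member.copy()),
    )

    sessions, seed_tcs = [], []
    for s_seed in session_seeds:
        rng = np.random.default_rng([spec.seed, int(subject_seed), int(s_seed)])
        s = _seed_process(rng, spec.T, spec.seed_ar1)
        series = np.zeros((*grid.shape, spec.T), dtype=np.float32)
        gsel = gray.member
        n_gray = int(gsel.sum())
        noise = rng.standard_normal((n_gray, spec.T), dtype=np.float32)
        series[gsel] = (coupling[gsel, None] * s).astype(np.float32) \
            + spec.noise_sigma * noise
        sessions.append(TimeSeriesVolume(grid, series,
                                         Mask(grid, gray.member.copy())))
        seed_tcs.append(SeedTimecourse(s, {"session_seed": int(s_seed)}))

    return PhantomSubject(
        spec=spec, grid=grid, head=head, gray=gray, depth=depth,
        outer_surface=outer, parcellation=parcellation,
        search_mask=search_mask, weight_map=weight_map,
        sessions=sessions, seed_timecourses=seed_tcs, truth_mm=centers,
    )


def make_cohort(spec: PhantomSpec, n_subjects: int,
                base_seed: int) -> list[PhantomSubject]:
    """A reproducible cohort; identity transforms stand in for registration."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(n_subjects)
    cohort = []
    for child in children:
        state = child.generate_state(3)
        subject_seed = int(state[0] % 2**31)
        session_seeds = [int(state[1] % 2**31), int(state[2] % 2**31)]
        cohort.append(make_subject(spec, subject_seed, session_seeds))
    return cohort
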
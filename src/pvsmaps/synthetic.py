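"""Synthetic test substrates: T1w-like phantoms and simulated cohorts.

Two generators make the whole stack testable without patient data.

``generate_phantom`` builds a brain-like ellipsoid (CSF shell, GM shell,
WM core, central ventricles) containing hypointense straight tubes with
known geometry — the ground-truth perivascular spaces — plus optional
spherical distractor blobs that an elongation filter should reject. Image
degradation emulates a clinical T1w acquisition: additive Gaussian
acquisition noise followed by Gaussian smoothing (reconstruction,
partial-volume and motion blur), so the noise reaching the detector is
spatially correlated the way reconstructed MRI noise is.

``generate_cohort`` simulates a two-visit longitudinal cohort in which a
latent severity drives PVS burden, and cognition / CSF t-tau / NfL depend
on that burden through specified linear effects with subject-level random
intercepts — the substrate for parameter-recovery testing of the
association models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .maskprep import SearchDomain, build_search_domain, expand_ventricles
from .morphology import _principal_axes
from .volume_io import Mask, Volume

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of a tubular-PVS phantom.

    Intensities are on a [0, 1] T1w-like scale: bright WM, intermediate
    GM, dark CSF. ``pvs_contrast`` is the intensity drop of a PVS below
    the surrounding WM and must be positive (PVS are hypointense on T1w).
    ``noise_sd`` is the sd of additive acquisition noise applied before
    the ``blur_fwhm`` smoothing, so the effective image noise is
    correlated and somewhat smaller than ``noise_sd``.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    wm_intensity: float = 0.7
    gm_intensity: float = 0.45
    csf_intensity: float = 0.15
    n_tubes: int = 8
    radius_range: tuple[float, float] = (0.6, 1.2)
    length_range: tuple[float, float] = (6.0, 25.0)
    pvs_contrast: float = 0.3
    n_blobs: int = 0
    blob_radius: float = 2.5
    noise_sd: float = 0.0
    blur_fwhm: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pvs_contrast <= 0:
            raise ValueError("pvs_contrast must be positive (PVS are hypointense on T1w)")
        if self.radius_range[0] > self.radius_range[1] or self.radius_range[0] <= 0:
            raise ValueError("invalid radius_range")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] <= 0:
            raise ValueError("invalid length_range")
        if self.noise_sd < 0 or self.blur_fwhm < 0:
            raise ValueError("noise_sd and blur_fwhm must be >= 0")


def _ellipsoid(shape: tuple[int, ...], center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    d = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return d <= 1.0


def _rasterize_segment(shape, p0, p1, radius) -> np.ndarray | None:
    """Voxel indices whose centers lie within ``radius`` of segment p0-p1."""
    lo = np.maximum(np.floor(np.minimum(p0, p1) - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius + 1).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return None
    grids = np.stack(
        np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij"), axis=-1
    ).astype(float)
    d = p1 - p0
    dd = float(d @ d)
    if dd == 0:
        dist = np.linalg.norm(grids - p0, axis=-1)
    else:
        t = np.clip(((grids - p0) @ d) / dd, 0.0, 1.0)
        nearest = p0 + t[..., None] * d
        dist = np.linalg.norm(grids - nearest, axis=-1)
    pts = np.argwhere(dist <= radius)
    if len(pts) == 0:
        return None
    return pts + lo


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


_CHEB = ndimage.generate_binary_structure(3, 3)


def _place_structures(
    rng: np.random.Generator,
    allowed: np.ndarray,
    interior: np.ndarray,
    spec: PhantomSpec,
) -> tuple[list[dict], np.ndarray]:
    """Place disjoint tubes and blobs; returns records and occupancy grid.

    Structures are kept >= 2 voxels (Chebyshev) apart so they remain
    distinct 26-connected components even after mild smoothing.
    """
    shape = spec.shape
    occupied = np.zeros(shape, dtype=bool)  # structures dilated by 2
    records: list[dict] = []
    centers = np.argwhere(allowed)
    if (spec.n_tubes or spec.n_blobs) and len(centers) == 0:
        raise RuntimeError(
            "could not place structures: the eroded WM compartment is empty at "
            f"shape={tuple(shape)}"
        )

    jobs = [("tube", i) for i in range(spec.n_tubes)] + [("blob", i) for i in range(spec.n_blobs)]
    for kind, _ in jobs:
        for attempt in range(300):
            c = centers[rng.integers(len(centers))].astype(float)
            if kind == "tube":
                direction = _random_unit_vector(rng)
                length = rng.uniform(*spec.length_range)
                radius = rng.uniform(*spec.radius_range)
                p0 = c - direction * length / 2.0
                p1 = c + direction * length / 2.0
                vox = _rasterize_segment(shape, p0, p1, radius)
            else:
                radius = spec.blob_radius
                p0 = p1 = c
                vox = _rasterize_segment(shape, c, c, radius)
            if vox is None or len(vox) < 5:
                continue
            # a thin oblique tube can rasterize into disconnected fragments;
            # require a single 26-connected component so truth clusters are tubes
            sub = np.zeros(vox.max(axis=0) - vox.min(axis=0) + 1, dtype=bool)
            sub[tuple((vox - vox.min(axis=0)).T)] = True
            if ndimage.label(sub, structure=_CHEB)[1] != 1:
                continue
            idx = tuple(vox.T)
            if not interior[idx].all():
                continue
            if occupied[idx].any():
                continue
            new = np.zeros(shape, dtype=bool)
            new[idx] = True
            occupied |= ndimage.binary_dilation(new, structure=_CHEB, iterations=2)
            evals, _ = _principal_axes(vox) if len(vox) >= 3 else (np.array([1.0, 0, 0]), None)
            total = evals.sum()
            records.append(
                {
                    "kind": kind,
                    "p0_i": p0[0], "p0_j": p0[1], "p0_k": p0[2],
                    "p1_i": p1[0], "p1_j": p1[1], "p1_k": p1[2],
                    "radius": radius,
                    "n_voxels": len(vox),
                    "linearity": 1.0 if total == 0 else float(evals[0] / total),
                    "_voxels": vox,
                }
            )
            break
        else:
            raise RuntimeError(
                f"could not place {kind} after 300 attempts: disjointness within the "
                f"eroded WM compartment cannot be satisfied (n_tubes={spec.n_tubes}, "
                f"n_blobs={spec.n_blobs}, shape={shape})"
            )
    return records, occupied


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[Volume, Mask, dict[str, Mask], pd.DataFrame]:
    """Generate a phantom volume with ground truth.

    Returns ``(volume, truth, tissue, table)`` where ``truth`` is the
    union of rasterized tubes (blobs are distractors, not truth),
    ``tissue`` maps {brain, WM, GM, ventricles, CSF} to masks, and
    ``table`` lists every placed structure (kind, endpoints, radius,
    voxel count, analytic linearity). Deterministic given ``spec.seed``.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_place, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]
    shape = np.asarray(spec.shape)
    center = (shape - 1) / 2.0

    brain_semi = 0.45 * shape
    brain = _ellipsoid(spec.shape, center, brain_semi)
    gm_outer = _ellipsoid(spec.shape, center, brain_semi - 2)
    wm_core = _ellipsoid(spec.shape, center, brain_semi - 5)
    ventricle_semi = shape * np.array([5.0, 9.0, 5.0]) / 96.0  # scales with grid
    ventricles = _ellipsoid(spec.shape, center, ventricle_semi) & wm_core
    wm = wm_core & ~ventricles
    gm = gm_outer & ~wm_core
    csf = (brain & ~gm_outer) | ventricles

    # tubes must sit well inside WM, clear of the GM shell and ventricles
    interior = ndimage.binary_erosion(wm_core, structure=_CHEB, iterations=3) & ~ndimage.binary_dilation(
        ventricles, structure=_CHEB, iterations=3
    )
    allowed = ndimage.binary_erosion(interior, structure=_CHEB, iterations=2)
    records, _ = _place_structures(rng_place, allowed, interior, spec)

    vol = np.zeros(spec.shape)
    vol[csf] = spec.csf_intensity
    vol[gm] = spec.gm_intensity
    vol[wm] = spec.wm_intensity
    truth = np.zeros(spec.shape, dtype=bool)
    for rec in records:
        idx = tuple(rec.pop("_voxels").T)
        vol[idx] = spec.wm_intensity - spec.pvs_contrast
        if rec["kind"] == "tube":
            truth[idx] = True

    if spec.noise_sd > 0:
        vol = vol + rng_noise.normal(0.0, spec.noise_sd, spec.shape)
    if spec.blur_fwhm > 0:
        vol = ndimage.gaussian_filter(vol, spec.blur_fwhm * _FWHM_TO_SIGMA)

    def mk(data, label):
        return Mask(data, label=label)

    tissue = {
        "brain": mk(brain, "brain"),
        "WM": mk(wm, "WM"),
        "GM": mk(gm, "GM"),
        "ventricles": mk(ventricles, "ventricles"),
        "CSF": mk(csf, "CSF"),
    }
    table = pd.DataFrame(records)
    if len(table):
        table.insert(0, "id", np.arange(1, len(table) + 1))
    volume = Volume(vol, id=f"phantom-seed{spec.seed}")
    truth_mask = mk(truth, "PVS_manual")
    return volume, truth_mask, tissue, table


def phantom_search_domain(tissue: dict[str, Mask]) -> SearchDomain:
    """Standard search domain for a generated phantom."""
    expanded = expand_ventricles(tissue["ventricles"], tissue["CSF"])
    return build_search_domain(tissue["brain"], tissue, expanded)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Parameters of a simulated two-visit longitudinal cohort.

    The effect sizes default to the association magnitudes this package's
    statistics module is meant to recover: cognition declines with PVS
    volume (``beta_cognition`` per voxel), CSF t-tau rises with PVS
    cluster count (``beta_ttau`` ng/mL per cluster), and the week-52
    change in NfL tracks the change in PVS volume (``beta_nfl``).
    Group-mean annual brain-volume decreases default to 5.25%
    (progressors) and 1.24% (non-progressors), on either side of the
    1.8% progression rule; draws are truncated so no subject crosses
    the rule's boundary.
    """

    n_subjects: int = 10
    visits: int = 2
    beta_cognition: float = -1.30e-3
    beta_ttau: float = 2.845
    beta_nfl: float = 1.40
    noise_sds: dict = field(
        default_factory=lambda: {"cognition": 2.0, "ttau": 20.0, "nfl": 150.0}
    )
    intercept_sds: dict = field(
        default_factory=lambda: {"cognition": 2.0, "ttau": 30.0, "nfl": 400.0}
    )
    atrophy_pct_progressor: float = 5.25
    atrophy_pct_nonprogressor: float = 1.24
    atrophy_sd_progressor: float = 0.8
    atrophy_sd_nonprogressor: float = 0.25
    progressor_fraction: float = 0.3
    # PVS burden process (whole-group two-visit means and spreads)
    count_baseline_mean: float = 214.0
    count_baseline_sd: float = 90.0
    count_change_mean: float = -69.0
    count_change_sd: float = 35.0
    mean_cluster_size: float = 11.8
    # covariate distributions
    age_mean: float = 62.0
    age_sd: float = 6.5
    smoking_prevalence: float = 0.4
    bp_mean: float = 95.0
    bp_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.visits != 2:
            raise ValueError("the cohort design is two visits (baseline, week 52)")
        if not (0 <= self.progressor_fraction <= 1):
            raise ValueError("progressor_fraction must be in [0, 1]")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")


VISIT_NAMES = ("baseline", "week52")
PROGRESSION_CUTOFF_PCT = 1.8  # % brain-volume decrease separating progressors


def _truncated_normal(rng, mean, sd, low, high, size):
    """Rejection-sampled truncated normal; cheap at these mild truncations."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a subject-visit table (one row per subject and visit).

    A latent per-subject severity drives PVS burden; cognition, CSF
    t-tau and NfL then depend on burden through ``beta_cognition``,
    ``beta_ttau`` and ``beta_nfl`` plus subject random intercepts and
    Gaussian noise. Covariates (age, smoking history, mean arterial
    pressure, time of day) are drawn independently and carry no outcome
    effect, so the adjusted fits remain unbiased for the betas.
    """
    ss = np.random.SeedSequence(spec.seed)
    rngs = {name: np.random.default_rng(s) for name, s in
            zip(["subject", "burden", "outcome", "covariate", "atrophy"], ss.spawn(5))}
    n = spec.n_subjects
    r_sub, r_bur, r_out, r_cov, r_atr = (
        rngs["subject"], rngs["burden"], rngs["outcome"], rngs["covariate"], rngs["atrophy"]
    )

    n_prog = int(round(spec.progressor_fraction * n))
    progressor = np.zeros(n, dtype=bool)
    progressor[r_sub.permutation(n)[:n_prog]] = True

    severity = r_sub.standard_normal(n)
    u = {k: (r_sub.standard_normal(n) * sd if sd else np.zeros(n))
         for k, sd in spec.intercept_sds.items()}
    noise = {k: spec.noise_sds.get(k, 0.0) for k in ("cognition", "ttau", "nfl")}

    count_bl = np.maximum(
        np.rint(spec.count_baseline_mean + spec.count_baseline_sd * severity
                + r_bur.normal(0, 20, n)), 10
    )
    # decline scales with baseline burden so the count floor rarely binds
    drift = spec.count_change_mean * count_bl / spec.count_baseline_mean
    count_fu = np.maximum(
        np.rint(count_bl + drift + r_bur.normal(0, spec.count_change_sd, n)), 5
    )
    counts = np.stack([count_bl, count_fu], axis=1)
    volumes = np.maximum(
        np.rint(counts * spec.mean_cluster_size + r_bur.normal(0, 150, (n, 2))),
        counts * 5,
    )

    age = np.clip(r_cov.normal(spec.age_mean, spec.age_sd, n), 45, 80)
    smoking = (r_cov.random(n) < spec.smoking_prevalence).astype(int)
    bp = r_cov.normal(spec.bp_mean, spec.bp_sd, n)
    tod = r_cov.uniform(480, 1080, (n, 2))  # minutes since midnight

    gm_bl = r_cov.normal(600_000, 50_000, n)
    wm_bl = r_cov.normal(480_000, 40_000, n)
    atrophy = np.where(
        progressor,
        _truncated_normal(r_atr, spec.atrophy_pct_progressor,
                          spec.atrophy_sd_progressor, PROGRESSION_CUTOFF_PCT + 0.01, np.inf, n),
        _truncated_normal(r_atr, spec.atrophy_pct_nonprogressor,
                          spec.atrophy_sd_nonprogressor, 0.05, PROGRESSION_CUTOFF_PCT - 0.01, n),
    )
    shrink = 1.0 - atrophy / 100.0

    nfl_bl = 2200 + 500 * severity + (r_out.normal(0, 300, n) if noise["nfl"] else 0.0)
    nfl_fu = (
        nfl_bl
        + spec.beta_nfl * (volumes[:, 1] - volumes[:, 0])
        + (r_out.normal(0, noise["nfl"], n) if noise["nfl"] else 0.0)
    )
    nfl = np.stack([nfl_bl, nfl_fu], axis=1)

    rows = []
    for i in range(n):
        for v, visit in enumerate(VISIT_NAMES):
            count, vol = counts[i, v], volumes[i, v]
            cognition = (
                120.0 + spec.beta_cognition * (vol - 2500.0) + u["cognition"][i]
                + (r_out.normal(0, noise["cognition"]) if noise["cognition"] else 0.0)
            )
            ttau = (
                150.0 + spec.beta_ttau * (count - 214.0) + u["ttau"][i]
                + (r_out.normal(0, noise["ttau"]) if noise["ttau"] else 0.0)
            )
            gm = gm_bl[i] * (1.0 if v == 0 else shrink[i])
            wm = wm_bl[i] * (1.0 if v == 0 else shrink[i])
            rows.append(
                {
                    "subject": f"S{i + 1:03d}",
                    "visit": visit,
                    "cluster_count": count,
                    "pvs_volume": vol,
                    "wm_volume_mm3": wm,
                    "gm_volume_mm3": gm,
                    "adjusted_count": count / (wm / 1000.0) * 100.0,
                    "adjusted_volume": vol / (wm / 1000.0) * 100.0,
                    "nucog": float(np.clip(74 - 8 * v + r_out.normal(0, 10), 0, 100)),
                    "cognition_composite": cognition,
                    "cbs": float(np.clip(40 + 5 * v + r_out.normal(0, 8), 0, 88)),
                    "csf_ttau": ttau,
                    "serum_ttau": max(r_out.normal(0.8, 0.4), 0.02),
                    "plasma_ttau": max(r_out.normal(3.3, 1.0), 0.5),
                    "nfl": nfl[i, v],
                    "age": age[i],
                    "smoking": smoking[i],
                    "bp": bp[i],
                    "time_of_day": tod[i, v],
                    "brain_volume_mm3": gm + wm,
                    "brain_volume_change_pct": -atrophy[i],
                    "progressor": bool(progressor[i]),
                }
            )
    return pd.DataFrame(rows)
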
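"""Synthetic CIVET-like cortical cohorts with known gender-by-hemisphere effects.

Generates, per subject, two hemispheric point clouds on unit spheres whose
vertices carry anatomical region labels (39 AAL-style cortical regions per
hemisphere) and cortical thickness values in mm.  Thickness is modelled as

    thickness(v) = mu(region(v)) + field(v) + eps(v)

where ``mu`` is a fixed per-region mean shared by both hemispheres and all
subjects of a cohort, ``field`` is a smooth spatially autocorrelated random
field on the sphere (a random low-order spherical-harmonic expansion, drawn
independently per subject and hemisphere), and ``eps`` is i.i.d. vertex noise.
With no injected effects the left and right thickness distributions of every
region are identical in expectation, so every downstream asymmetry index is
symmetric about zero by construction.  Effects (mean shifts and/or spread
scalings restricted to one gender, hemisphere and region) break that symmetry
in a controlled, documented way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AAL_REGIONS",
    "EffectSpec",
    "GeneratorConfig",
    "generate_surface",
    "generate_cohort",
]

#: The 39 cortical AAL region abbreviations used per hemisphere (78 total).
AAL_REGIONS: tuple[str, ...] = (
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBsupmed", "REC", "INS",
    "ACG", "MCG", "PCG", "PHG", "CAL", "CUN", "LING", "SOG", "MOG", "IOG",
    "FFG", "PoCG", "SPG", "IPL", "SMG", "ANG", "PCUN", "PCL", "HES", "STG",
    "TPOsup", "MTG", "TPOmid", "ITG",
)

VERTEX_COLUMNS = ("vertex_id", "hemisphere", "x", "y", "z", "region", "thickness")

#: Hard floor (mm) applied to generated thickness so densities stay proper.
THICKNESS_FLOOR = 0.1


class ConfigurationError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


@dataclass(frozen=True)
class EffectSpec:
    """A localized group effect on the thickness field.

    ``dmean`` shifts the mean thickness (mm) and ``sd_scale`` multiplies the
    subject-level variation (smooth field + vertex noise) of every vertex in
    ``region`` of ``hemisphere``, for subjects of ``gender`` only.
    """

    region: str
    hemisphere: str  # 'L' or 'R'
    gender: str      # 'F' or 'M'
    dmean: float = 0.0
    sd_scale: float = 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    n_female: int = 10
    n_male: int = 10
    n_regions_per_hemisphere: int = 39
    vertices_per_region: int = 600
    thickness_mean_range: tuple[float, float] = (1.5, 4.5)
    within_region_sd: float | tuple[float, float] = (0.15, 0.50)
    field_sd: float = 0.30
    spatial_autocorrelation_length: float = 0.25
    effect_specs: tuple[EffectSpec, ...] = ()
    age_range: tuple[int, int] = (22, 36)
    handedness_min: int = 50
    seed: int = 0
    #: Seed for the anatomy (surface partition and per-region thickness
    #: parameters).  None means "use ``seed``".  Keeping it fixed while
    #: varying ``seed`` redraws participants on the same cortex, the way
    #: repeated studies sample new subjects but share one anatomy.
    anatomy_seed: int | None = None
    region_names: tuple[str, ...] | None = None

    def resolved_anatomy_seed(self) -> int:
        return self.seed if self.anatomy_seed is None else self.anatomy_seed

    def sd_interval(self) -> tuple[float, float]:
        """Per-region vertex-noise SD range (a scalar collapses the interval).

        Real anatomical regions differ in how variable their thickness is;
        drawing each region's noise SD from this interval gives regional
        distributions heterogeneous widths, which is what lets broad-
        distribution regions overlap many others and act as network hubs.
        """
        sd = self.within_region_sd
        if isinstance(sd, (int, float)):
            return float(sd), float(sd)
        lo, hi = sd
        return float(lo), float(hi)

    def resolved_region_names(self) -> tuple[str, ...]:
        if self.region_names is not None:
            return tuple(self.region_names)
        if self.n_regions_per_hemisphere > len(AAL_REGIONS):
            raise ConfigurationError(
                f"no default names for {self.n_regions_per_hemisphere} regions; "
                "pass region_names explicitly"
            )
        return AAL_REGIONS[: self.n_regions_per_hemisphere]

    def validate(self) -> None:
        names = self.resolved_region_names()
        if len(names) != self.n_regions_per_hemisphere:
            raise ConfigurationError(
                "region_names length must equal n_regions_per_hemisphere"
            )
        if len(set(names)) != len(names):
            raise ConfigurationError("region names must be unique")
        if self.n_female < 0 or self.n_male < 0:
            raise ConfigurationError("cohort sizes must be nonnegative")
        if self.n_regions_per_hemisphere < 1:
            raise ConfigurationError("need at least one region per hemisphere")
        if self.vertices_per_region < 2:
            raise ConfigurationError("need at least 2 vertices per region")
        lo, hi = self.thickness_mean_range
        if not (0 < lo <= hi):
            raise ConfigurationError("thickness_mean_range must be positive")
        lo_sd, hi_sd = self.sd_interval()
        if lo_sd <= 0 or hi_sd < lo_sd or self.field_sd < 0:
            raise ConfigurationError("thickness spread parameters must be positive")
        if self.spatial_autocorrelation_length <= 0:
            raise ConfigurationError("spatial_autocorrelation_length must be > 0")
        if self.handedness_min < 50:
            raise ConfigurationError(
                "handedness_min below 50 would generate subjects the cohort "
                "filter is required to remove"
            )
        if not (self.age_range[0] <= self.age_range[1]):
            raise ConfigurationError("invalid age_range")
        for eff in self.effect_specs:
            if eff.region not in names:
                raise ConfigurationError(f"effect names unknown region {eff.region!r}")
            if eff.hemisphere not in ("L", "R"):
                raise ConfigurationError(f"bad hemisphere {eff.hemisphere!r}")
            if eff.gender not in ("F", "M"):
                raise ConfigurationError(f"bad gender {eff.gender!r}")
            if eff.sd_scale <= 0:
                raise ConfigurationError("sd_scale must be positive")


# ---------------------------------------------------------------------------
# surface template
# ---------------------------------------------------------------------------

def _unit_sphere_points(n: int, rng: np.random.Generator) -> np.ndarray:
    pts = rng.standard_normal((n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def _farthest_point_seeds(points: np.ndarray, k: int) -> np.ndarray:
    """Indices of k seeds chosen by deterministic farthest-point traversal."""
    n = len(points)
    seeds = np.empty(k, dtype=np.int64)
    seeds[0] = 0
    d = points @ points[0]
    # maximize chordal distance == minimize dot product on the unit sphere
    for i in range(1, k):
        nxt = int(np.argmin(d))
        seeds[i] = nxt
        d = np.maximum(d, points @ points[nxt])
    return seeds


def generate_surface(config: GeneratorConfig) -> pd.DataFrame:
    """Build the labeled two-hemisphere vertex template (no thickness yet).

    One hemisphere's point cloud is generated on the unit sphere and
    partitioned into contiguous regions by nearest-of-k seed assignment; the
    other hemisphere reuses the same coordinates and labels on its own sphere,
    so homologous regions are geometrically identical by construction.
    """
    config.validate()
    names = config.resolved_region_names()
    k = config.n_regions_per_hemisphere
    n_hemi = k * config.vertices_per_region

    rng = np.random.default_rng(
        np.random.SeedSequence([config.resolved_anatomy_seed(), 0x5F]))
    pts = _unit_sphere_points(n_hemi, rng)
    seed_idx = _farthest_point_seeds(pts, k)
    # nearest seed by maximal cosine similarity
    sims = pts @ pts[seed_idx].T
    labels = np.argmax(sims, axis=1)

    counts = np.bincount(labels, minlength=k)
    if counts.min() < 2:
        raise ConfigurationError(
            "degenerate region partition: a region received fewer than 2 vertices"
        )

    frames = []
    for hi, hemi in enumerate(("L", "R")):
        frames.append(pd.DataFrame({
            "vertex_id": np.arange(n_hemi) + hi * n_hemi,
            "hemisphere": hemi,
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
            "region": np.asarray(names, dtype=object)[labels],
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# smooth random fields on the sphere
# ---------------------------------------------------------------------------

def _real_sph_harm(l: int, m: int, polar: np.ndarray, azimuth: np.ndarray) -> np.ndarray:
    try:  # scipy >= 1.15
        from scipy.special import sph_harm_y
        y = sph_harm_y(l, abs(m), polar, azimuth)
    except ImportError:  # pragma: no cover - older scipy
        from scipy.special import sph_harm
        y = sph_harm(abs(m), l, azimuth, polar)
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * np.real(y)
    if m < 0:
        return np.sqrt(2.0) * (-1.0) ** m * np.imag(y)
    return np.real(y)


def _harmonic_basis(points: np.ndarray, l_max: int) -> np.ndarray:
    """(n_points, n_harmonics) real spherical-harmonic design matrix, scaled
    so that a standard-normal coefficient vector yields unit pointwise variance."""
    x, y, z = points.T
    polar = np.arccos(np.clip(z, -1.0, 1.0))
    azimuth = np.arctan2(y, x)
    cols = []
    for l in range(1, l_max + 1):  # skip l=0: constant offset lives in mu
        for m in range(-l, l + 1):
            cols.append(_real_sph_harm(l, m, polar, azimuth))
    basis = np.column_stack(cols)
    # addition theorem: sum_lm Y_lm(x)^2 = sum_l (2l+1)/(4 pi), independent of x
    total = sum((2 * l + 1) for l in range(1, l_max + 1)) / (4.0 * np.pi)
    return basis / np.sqrt(total)


def _l_max_for(length: float) -> int:
    return max(1, int(round(1.0 / length)))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    template: pd.DataFrame, config: GeneratorConfig
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Draw per-subject thickness fields on ``template`` plus a cohort manifest.

    Returns the list of per-subject vertex tables (template columns plus
    ``thickness``) in manifest row order, and the manifest itself
    (subject_id, gender, age, handedness, family_id).
    """
    config.validate()
    names = config.resolved_region_names()
    missing = set(template["region"]) - set(names)
    if missing:
        raise ConfigurationError(f"template regions not in config: {sorted(missing)}")

    ss = np.random.SeedSequence([config.seed, 0xC0])
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])

    # anatomy-level parameters: one mean and one noise SD per anatomical
    # region, shared L/R so homologous regions are exchangeable under the null
    anat_rng = np.random.default_rng(
        np.random.SeedSequence([config.resolved_anatomy_seed(), 0xA7]))
    lo, hi = config.thickness_mean_range
    mu = dict(zip(names, anat_rng.uniform(lo, hi, size=len(names))))
    sd_lo, sd_hi = config.sd_interval()
    region_sd = dict(zip(names, anat_rng.uniform(sd_lo, sd_hi, size=len(names))))

    n_total = config.n_female + config.n_male
    genders = ["F"] * config.n_female + ["M"] * config.n_male
    subject_ids = [
        f"{g}{i + 1:03d}"
        for g, n in (("F", config.n_female), ("M", config.n_male))
        for i in range(n)
    ]
    ages = cohort_rng.integers(config.age_range[0], config.age_range[1] + 1, n_total)
    handed = cohort_rng.integers(config.handedness_min, 101, n_total)
    manifest = pd.DataFrame({
        "subject_id": subject_ids,
        "gender": genders,
        "age": ages,
        "handedness": handed,
        "family_id": [f"FAM{i + 1:04d}" for i in range(n_total)],
    })

    # precompute per-hemisphere harmonic basis (identical coords both sides)
    l_max = _l_max_for(config.spatial_autocorrelation_length)
    hemi_masks = {h: (template["hemisphere"] == h).to_numpy() for h in ("L", "R")}
    coords = template[["x", "y", "z"]].to_numpy()
    basis = {h: _harmonic_basis(coords[hemi_masks[h]], l_max) for h in ("L", "R")}

    region_col = template["region"].to_numpy()
    base_mu = np.array([mu[r] for r in region_col])
    base_sd = np.array([region_sd[r] for r in region_col])

    subject_seeds = ss.spawn(n_total + 1)[1:]
    tables: list[pd.DataFrame] = []
    for sid, gender, sseed in zip(subject_ids, genders, subject_seeds):
        srng = np.random.default_rng(sseed)
        thickness = base_mu.copy()
        variation = np.empty(len(template))
        for h in ("L", "R"):
            m = hemi_masks[h]
            coeffs = srng.standard_normal(basis[h].shape[1])
            smooth = config.field_sd * (basis[h] @ coeffs)
            noise = base_sd[m] * srng.standard_normal(int(m.sum()))
            variation[m] = smooth + noise
        dmean = np.zeros(len(template))
        sd_scale = np.ones(len(template))
        for eff in config.effect_specs:
            if eff.gender != gender:
                continue
            sel = hemi_masks[eff.hemisphere] & (region_col == eff.region)
            dmean[sel] += eff.dmean
            sd_scale[sel] *= eff.sd_scale
        thickness = base_mu + dmean + sd_scale * variation
        np.maximum(thickness, THICKNESS_FLOOR, out=thickness)

        table = template.copy()
        table["thickness"] = thickness
        table.attrs["subject_id"] = sid
        tables.append(table)

    return tables, manifest
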
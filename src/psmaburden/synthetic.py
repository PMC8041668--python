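"""Synthetic phantoms and cohorts for every stage of the pipeline.

Two generators:

* :func:`generate_phantom` builds voxel phantoms — a liver ellipsoid with
  configurable SUVmean/SUVsd and spherical lesions of known analytic volume
  and uptake profile — so segmentation accuracy is measured against
  geometry, not against voxel counts.
* :func:`generate_cohort` simulates patient cohorts whose whole-body burden
  metrics drive overall survival through an exponential proportional-hazards
  model (hazard multiplicative in ``exp(beta * log2 covariate)``) and whose
  PSA/LDH values are linked log-linearly to log2 tumor volume with noise
  calibrated to a target Spearman correlation.

Both are fully deterministic given their seed (numpy ``default_rng``,
PCG64).  Neither emulates scanner physics (attenuation, scatter,
reconstruction blur) or anatomy beyond the liver ellipsoid.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from psmaburden.metrics import compute_burden
from psmaburden.segmentation import Lesion
from psmaburden.volume import RegionMask, SUVVolume, write_mask, write_volume

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "CohortSpec",
    "PhantomSpecError",
    "generate_phantom",
    "generate_cohort",
    "fixture_suite",
]

LN2 = math.log(2.0)


class PhantomSpecError(ValueError):
    """Phantom structures overlap or parameters are out of domain."""


def sphere_radius_mm(volume_ml: float) -> float:
    """Radius in mm of a sphere with the given volume in ml."""
    return (3.0 * volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def sphere_volume_ml(radius_mm: float) -> float:
    return 4.0 / 3.0 * math.pi * radius_mm**3 / 1000.0


@dataclass(frozen=True)
class LesionSpec:
    """One spherical lesion: center (mm), size, peak SUV and radial profile.

    Exactly one of ``radius_mm`` or ``volume_ml`` must be given.  Profiles:
    ``uniform`` (peak everywhere inside), ``linear`` (peak falling linearly
    to 0 at the radius) and ``gaussian`` (sigma = radius/2, approximating
    PET point-spread blur).
    """

    center_mm: tuple[float, float, float]
    peak_suv: float
    radius_mm: float | None = None
    volume_ml: float | None = None
    profile: str = "gaussian"

    def __post_init__(self) -> None:
        if (self.radius_mm is None) == (self.volume_ml is None):
            raise PhantomSpecError("give exactly one of radius_mm or volume_ml")
        if self.profile not in ("uniform", "linear", "gaussian"):
            raise PhantomSpecError(f"unknown profile {self.profile!r}")
        if self.peak_suv <= 0:
            raise PhantomSpecError("peak SUV must be positive")

    @property
    def radius(self) -> float:
        return self.radius_mm if self.radius_mm is not None else sphere_radius_mm(self.volume_ml)

    @property
    def analytic_volume_ml(self) -> float:
        return sphere_volume_ml(self.radius)

    @property
    def halfmax_radius_mm(self) -> float:
        """Radius of the 50%-of-peak isocontour for this profile."""
        if self.profile == "uniform":
            return self.radius
        if self.profile == "linear":
            return self.radius / 2.0
        sigma = self.radius / 2.0
        return sigma * math.sqrt(2.0 * LN2)

    @property
    def halfmax_volume_ml(self) -> float:
        return sphere_volume_ml(self.halfmax_radius_mm)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity specification of one voxel phantom."""

    shape: tuple[int, int, int] = (96, 96, 160)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_mean: float = 0.4
    background_sd: float = 0.15
    liver_center_mm: tuple[float, float, float] = (96.0, 96.0, 80.0)
    liver_radii_mm: tuple[float, float, float] = (40.0, 32.0, 28.0)
    liver_suv_mean: float = 4.3
    liver_suv_sd: float = 0.3
    lesions: tuple[LesionSpec, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.liver_suv_mean <= 0:
            raise PhantomSpecError("liver SUVmean must be positive")
        object.__setattr__(self, "lesions", tuple(self.lesions))
        # lesions must not overlap each other or the liver
        for i, a in enumerate(self.lesions):
            ca = np.asarray(a.center_mm)
            rel = (ca - np.asarray(self.liver_center_mm)) / np.asarray(self.liver_radii_mm)
            if np.sum(rel**2) <= (1.0 + a.radius / min(self.liver_radii_mm)) ** 2:
                raise PhantomSpecError(f"lesion {i} overlaps the liver ellipsoid")
            for j, b in enumerate(self.lesions[:i]):
                dist = float(np.linalg.norm(ca - np.asarray(b.center_mm)))
                if dist <= a.radius + b.radius:
                    raise PhantomSpecError(f"lesions {j} and {i} overlap")


def _grid_mm(shape, spacing):
    axes = [np.arange(s) * d for s, d in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def generate_phantom(spec: PhantomSpec):
    """Render a phantom volume plus its liver mask and ground-truth table.

    Returns ``(SUVVolume, RegionMask, DataFrame)`` where the table lists
    each lesion's analytic sphere volume, the analytic volume of its
    half-maximum isocontour (the quantity the 50 % segmentation recovers),
    and its peak SUV.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    gx, gy, gz = _grid_mm(spec.shape, spec.spacing)

    values = rng.normal(spec.background_mean, spec.background_sd, size=spec.shape)

    rel = (
        ((gx - spec.liver_center_mm[0]) / spec.liver_radii_mm[0]) ** 2
        + ((gy - spec.liver_center_mm[1]) / spec.liver_radii_mm[1]) ** 2
        + ((gz - spec.liver_center_mm[2]) / spec.liver_radii_mm[2]) ** 2
    )
    liver = rel <= 1.0
    values[liver] = rng.normal(spec.liver_suv_mean, spec.liver_suv_sd, size=int(liver.sum()))

    rows = []
    for k, les in enumerate(spec.lesions, start=1):
        r2 = (
            (gx - les.center_mm[0]) ** 2
            + (gy - les.center_mm[1]) ** 2
            + (gz - les.center_mm[2]) ** 2
        )
        R = les.radius
        if les.profile == "uniform":
            inside = r2 <= R**2
            profile = np.where(inside, les.peak_suv, 0.0)
        elif les.profile == "linear":
            r = np.sqrt(r2)
            profile = np.where(r <= R, les.peak_suv * (1.0 - r / R), 0.0)
        else:  # gaussian, sigma = R/2, truncated at 2.5 sigma
            sigma = R / 2.0
            profile = np.where(
                r2 <= (2.5 * sigma) ** 2, les.peak_suv * np.exp(-r2 / (2.0 * sigma**2)), 0.0
            )
        hot = profile > values
        values[hot] = profile[hot]
        if spec.noise_sd > 0:
            values[hot] += rng.normal(0.0, spec.noise_sd, size=int(hot.sum()))
        rows.append(
            {
                "lesion_id": k,
                "center_x_mm": les.center_mm[0],
                "center_y_mm": les.center_mm[1],
                "center_z_mm": les.center_mm[2],
                "radius_mm": R,
                "volume_ml": les.analytic_volume_ml,
                "halfmax_volume_ml": les.halfmax_volume_ml,
                "peak_suv": les.peak_suv,
                "profile": les.profile,
            }
        )

    np.clip(values, 0.0, None, out=values)
    volume = SUVVolume(values=values, spacing=spec.spacing)
    liver_mask = RegionMask(values=liver, label="liver", spacing=spec.spacing)
    truth = pd.DataFrame(
        rows,
        columns=[
            "lesion_id", "center_x_mm", "center_y_mm", "center_z_mm", "radius_mm",
            "volume_ml", "halfmax_volume_ml", "peak_suv", "profile",
        ],
    )
    return volume, liver_mask, truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Statistical structure of a simulated patient cohort.

    Lesion counts are negative-binomial (over-dispersed, matching skewed
    real-world burden distributions); per-lesion volumes and SUVmeans are
    log-normal.  Survival times are exponential with hazard
    ``baseline_hazard * exp(sum_k beta_k * (log2 x_k - median log2 x_k))``
    so the baseline is the hazard of the median patient; censoring is an
    administrative uniform window.  PSA and LDH are log-linear in log2
    tumor volume with noise calibrated so the Spearman correlation with
    PSMA-TV hits the target (via the bivariate-normal identity
    ``rho_S = (6/pi) asin(r/2)``).
    """

    n: int = 110
    lesion_count_mean: float = 10.0
    lesion_count_dispersion: float = 1.2
    lesion_volume_log_mu: float = math.log(3.0)     # ml, median 3 ml
    lesion_volume_log_sigma: float = 1.0
    lesion_suvmean_log_mu: float = math.log(8.0)    # SUV, median 8
    lesion_suvmean_log_sigma: float = 0.35
    baseline_hazard: float = LN2 / 11.0             # per month; median-patient OS 11 months
    betas: tuple[tuple[str, float], ...] = (("psma_tlq", math.log(1.33)),)  # HR 1.33 per doubling
    censor_window_months: tuple[float, float] = (6.0, 42.0)
    psa_spearman_target: float = 0.6
    psa_median: float = 231.0                       # ng/ml
    psa_log2_sd: float = 2.5                        # wide spread: IQR of hundreds of ng/ml
    ldh_spearman_target: float = 0.4
    ldh_median: float = 317.0                       # U/l
    ldh_log2_sd: float = 0.6                        # physiologic range ~150-800 U/l
    min_lesion_volume_ml: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.lesion_count_mean <= 0 or self.lesion_count_dispersion <= 0:
            raise ValueError("lesion count parameters must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        lo, hi = self.censor_window_months
        if not 0 < lo <= hi:
            raise ValueError("censor window must satisfy 0 < lo <= hi")
        object.__setattr__(self, "betas", tuple(self.betas))


def _linked_marker(
    rng, log2_tv: np.ndarray, rho_target: float, median: float, log2_sd: float
) -> np.ndarray:
    """Blood marker log-linear in log2(TV) with Spearman-calibrated noise.

    The standardized log2(TV) signal is mixed with independent Gaussian
    noise at the latent Pearson weight ``r = 2 sin(pi * rho / 6)`` (the
    bivariate-normal rank-correlation identity), then rescaled to the
    marker's own log2 spread — the correlation depends only on the
    signal-to-noise ratio, not on the marker's scale.
    """
    n = len(log2_tv)
    signal_sd = float(np.std(log2_tv))
    eps = rng.normal(0.0, 1.0, size=n)
    if rho_target <= 0 or signal_sd == 0:
        latent = eps
    else:
        r = 2.0 * math.sin(math.pi * rho_target / 6.0)
        z = (log2_tv - np.mean(log2_tv)) / signal_sd
        latent = r * z + math.sqrt(1.0 - r**2) * eps
    return np.exp2(math.log2(median) + log2_sd * latent)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a patient table with burden metrics, PSA, LDH and survival.

    Per-patient metrics are computed through :func:`compute_burden` from the
    sampled lesion lists (not shortcut formulas), so the whole-body sums sit
    on the data path.  Columns: patient_id, lesion_count, psma_tv_ml,
    psma_tlu, psma_tlq, psa, ldh, time_months, event.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    k = spec.lesion_count_dispersion
    p = k / (k + spec.lesion_count_mean)
    counts = rng.negative_binomial(k, p, size=n)
    counts = np.maximum(counts, 1)  # every included patient has avid disease

    burdens = []
    for i in range(n):
        vols = rng.lognormal(spec.lesion_volume_log_mu, spec.lesion_volume_log_sigma, counts[i])
        suvs = rng.lognormal(spec.lesion_suvmean_log_mu, spec.lesion_suvmean_log_sigma, counts[i])
        keep = vols >= spec.min_lesion_volume_ml
        if not keep.any():
            keep[np.argmax(vols)] = True
            vols[np.argmax(vols)] = spec.min_lesion_volume_ml
        lesions = [
            Lesion(
                volume_ml=float(v),
                suv_max=float(s * 1.6),
                suv_mean=float(s),
                suv_peak=float(s * 1.3),
            )
            for v, s in zip(vols[keep], suvs[keep])
        ]
        burdens.append(compute_burden(f"P{i + 1:04d}", lesions))

    table = pd.DataFrame(
        {
            "patient_id": [b.patient_id for b in burdens],
            "lesion_count": [b.lesion_count for b in burdens],
            "psma_tv_ml": [b.psma_tv for b in burdens],
            "psma_tlu": [b.psma_tlu for b in burdens],
            "psma_tlq": [b.psma_tlq for b in burdens],
        }
    )
    log2_tv = np.log2(table["psma_tv_ml"].to_numpy())
    table["psa"] = _linked_marker(
        rng, log2_tv, spec.psa_spearman_target, spec.psa_median, spec.psa_log2_sd
    )
    table["ldh"] = _linked_marker(
        rng, log2_tv, spec.ldh_spearman_target, spec.ldh_median, spec.ldh_log2_sd
    )

    log_hr = np.zeros(n)
    for name, beta in spec.betas:
        if name not in table.columns:
            raise KeyError(f"beta refers to unknown covariate {name!r}")
        x = np.log2(table[name].to_numpy(dtype=float))
        log_hr += beta * (x - np.median(x))
    hazard = spec.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    censor = rng.uniform(*spec.censor_window_months, size=n)
    table["time_months"] = np.minimum(t_event, censor)
    table["event"] = (t_event <= censor).astype(int)
    return table


# ---------------------------------------------------------------------------
# canonical fixture suite
# ---------------------------------------------------------------------------

def accuracy_phantom_spec(spacing_mm: float = 2.0, seed: int = 0) -> PhantomSpec:
    """Noise-free uniform-sphere phantom (1-20 ml) for volume-recovery tests."""
    n = int(round(128.0 / spacing_mm)), int(round(128.0 / spacing_mm)), int(round(192.0 / spacing_mm))
    lesions = tuple(
        LesionSpec(center_mm=c, volume_ml=v, peak_suv=s, profile="uniform")
        for c, v, s in [
            ((30.0, 30.0, 110.0), 1.0, 8.0),
            ((95.0, 30.0, 110.0), 3.0, 12.0),
            ((30.0, 95.0, 112.0), 6.0, 16.0),
            ((95.0, 95.0, 114.0), 12.0, 20.0),
            ((64.0, 64.0, 155.0), 20.0, 25.0),
        ]
    )
    return PhantomSpec(
        shape=n,
        spacing=(spacing_mm,) * 3,
        background_mean=0.0,
        background_sd=0.0,
        liver_center_mm=(64.0, 64.0, 40.0),
        liver_radii_mm=(28.0, 24.0, 20.0),
        liver_suv_mean=4.3,
        liver_suv_sd=0.4,
        lesions=lesions,
        noise_sd=0.0,
        seed=seed,
    )


def imaging_cohort_specs(n_patients: int = 5, seed: int = 0) -> list[PhantomSpec]:
    """Small per-patient phantoms (48^3, 1-3 gaussian lesions) for end-to-end runs."""
    specs = []
    rng = np.random.default_rng(seed)
    centers = [(24.0, 24.0, 70.0), (70.0, 24.0, 70.0), (24.0, 70.0, 70.0), (70.0, 70.0, 72.0)]
    for i in range(n_patients):
        n_lesions = int(rng.integers(0, 4)) if n_patients > 1 else 2
        lesions = tuple(
            LesionSpec(
                center_mm=centers[j],
                volume_ml=float(rng.uniform(2.0, 15.0)),
                peak_suv=float(rng.uniform(10.0, 25.0)),
                profile="gaussian",
            )
            for j in range(n_lesions)
        )
        specs.append(
            PhantomSpec(
                shape=(48, 48, 48),
                spacing=(2.0, 2.0, 2.0),
                background_mean=0.4,
                background_sd=0.1,
                liver_center_mm=(48.0, 48.0, 24.0),
                liver_radii_mm=(20.0, 18.0, 14.0),
                liver_suv_mean=4.3,
                liver_suv_sd=0.3,
                lesions=lesions,
                noise_sd=0.2,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def fixture_suite(out_dir, seed: int = 0, n_patients: int = 5, cohort_n: int = 110) -> dict:
    """Write the canonical test fixtures and a manifest of seeds and checksums.

    Produces per-patient NIfTI phantoms with liver masks and ground-truth
    CSVs plus a simulated cohort CSV.  Rerunning with the same seed yields
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(seed), "files": {}, "patients": []}

    specs = imaging_cohort_specs(n_patients=n_patients, seed=seed)
    for i, spec in enumerate(specs, start=1):
        pid = f"P{i:03d}"
        volume, liver_mask, truth = generate_phantom(spec)
        vol_path = out / f"{pid}_suv.nii.gz"
        liv_path = out / f"{pid}_liver.nii.gz"
        truth_path = out / f"{pid}_truth.csv"
        write_volume(volume, vol_path)
        write_mask(liver_mask, liv_path, reference=volume)
        truth.to_csv(truth_path, index=False)
        manifest["patients"].append(
            {
                "patient_id": pid,
                "volume": vol_path.name,
                "liver_mask": liv_path.name,
                "truth": truth_path.name,
                "phantom_seed": spec.seed,
                "n_lesions": len(spec.lesions),
            }
        )
        for path in (vol_path, liv_path, truth_path):
            manifest["files"][path.name] = _sha256(path)

    cohort = generate_cohort(CohortSpec(n=cohort_n, seed=seed))
    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False, float_format="%.10g")
    manifest["files"][cohort_path.name] = _sha256(cohort_path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
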
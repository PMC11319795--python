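"""Synthetic cohorts, ultrasound-like images and force-plate recordings.

Everything downstream of data acquisition can be exercised without the real
study data: this module generates

* **cohorts** — young/old groups with demographics, eight ultrasound
  variables per subject drawn from per-group distributions matching the
  published group summaries, and per-condition sway SDs with a controllable
  latent coupling between muscle quality and sway magnitude;
* **ultrasound-like images** — layered speckle images (skin, subcutaneous
  fat, aponeuroses, muscle) whose mean intensity and textural heterogeneity
  are set by a phenotype, together with the ground-truth landmarks and ROIs
  used to synthesize them;
* **force-plate recordings** — band-limited Gaussian COP processes with an
  exactly controlled sway SD, converted to plate moments by inverting the
  COP equations.

The cohort generator uses a Gaussian copula: a joint multivariate normal
over latent ultrasound and sway factors is mapped to the requested marginals
(normal, or moment-matched lognormal for strongly skewed features such as
ASM, whose SD exceeds its mean).  Latent correlations of lognormal variables
are pre-compensated for the attenuation the exponential map induces, so the
post-transform Pearson correlations hit their targets (exactly for
normal-lognormal pairs, to first order for lognormal-lognormal pairs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .posturography import CONDITIONS
from .us_image import GrayImage, LandmarkSet, PolygonROI, RectROI

__all__ = [
    "US_VARIABLES",
    "QUALITY_SIGNS",
    "GroupParams",
    "CohortSpec",
    "ImagePhenotype",
    "SwaySpec",
    "generate_cohort",
    "cohort_to_long",
    "write_cohort_csv",
    "generate_us_image",
    "generate_forceplate_recording",
]

#: ultrasound variables simulated per subject (order fixed)
US_VARIABLES = ("MT", "EI", "SAT", "ASM", "Contrast", "Correlation", "IDM", "Entropy")

#: +1 when a larger value indicates *better* muscle composition (thicker,
#: leaner, more homogeneous muscle), matching the observed young-vs-old
#: direction of each variable
QUALITY_SIGNS = {
    "MT": +1, "EI": -1, "SAT": -1, "ASM": +1,
    "Contrast": -1, "Correlation": +1, "IDM": +1, "Entropy": -1,
}

#: variables through which the latent muscle-quality factor couples to sway —
#: the five parameters carrying the age/quality signal (the same set the
#: association analysis uses); SAT, Contrast and Correlation are simulated
#: but uncoupled, mirroring their weak discriminative performance
COUPLED_VARIABLES = ("MT", "EI", "ASM", "IDM", "Entropy")

# published group summaries (VL): mean, SD per variable
_YOUNG_US = {
    "MT": (2.21, 0.48), "EI": (32.3, 7.1), "SAT": (0.98, 0.48),
    "ASM": (0.008, 0.02), "Contrast": (66.9, 25.9), "Correlation": (0.001, 0.0006),
    "IDM": (0.295, 0.06), "Entropy": (7.17, 0.50),
}
_OLD_US = {
    "MT": (1.38, 0.33), "EI": (56.0, 9.2), "SAT": (0.93, 0.49),
    "ASM": (0.001, 0.0003), "Contrast": (86.1, 30.6), "Correlation": (0.001, 0.0004),
    "IDM": (0.224, 0.03), "Entropy": (7.77, 0.31),
}

# per-condition raw sdCOP_AP targets (mm).  Chosen so conditions order
# EOhard < EChard < EOfoam < ECfoam in both groups, older subjects sway more
# in every condition, and the old/young gap is largest (~57%) on foam with
# eyes closed.
_YOUNG_SWAY = {"EOhard": 3.5, "EChard": 4.0, "EOfoam": 4.6, "ECfoam": 5.5}
_OLD_SWAY = {"EOhard": 4.6, "EChard": 5.4, "EOfoam": 6.3, "ECfoam": 8.6}

# demographics: (height mean, height sd, weight mean, weight sd, n_female/n)
_YOUNG_DEMO = dict(age_range=(19.0, 31.0), height=(173.0, 10.0), weight=(74.8, 14.6), female=15)
_OLD_DEMO = dict(age_range=(65.0, 85.0), height=(166.4, 9.4), weight=(72.0, 12.2), female=18)


@dataclass(frozen=True)
class GroupParams:
    """Distributional targets for one group."""

    n: int
    us_means: dict
    us_sds: dict
    sway_means: dict
    sway_sds: dict
    coupling_rho: float
    age_range: tuple[float, float]
    height: tuple[float, float]
    weight: tuple[float, float]
    n_female: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if abs(self.coupling_rho) > 1:
            raise ValueError("|coupling_rho| must be <= 1")
        for v in US_VARIABLES:
            if self.us_sds[v] <= 0:
                raise ValueError(f"SD for {v} must be positive")
        for c in CONDITIONS:
            if self.sway_sds[c] <= 0:
                raise ValueError(f"sway SD for {c} must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Full two-group cohort specification.

    ``us_corr`` is the within-group correlation matrix among the eight
    ultrasound variables (identity by default: the within-group correlation
    structure of the real data is unknown, and independence is the
    documented neutral assumption).  ``sway_corr`` is the within-subject
    correlation among the four condition sway SDs.  ``coupling_rho`` per
    group sets the Pearson correlation between the sign-corrected mean of
    the standardized ultrasound variables and the mean of the standardized
    sway SDs.
    """

    young: GroupParams = None
    old: GroupParams = None
    us_corr: np.ndarray = None
    sway_corr: np.ndarray = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.young is None:
            object.__setattr__(self, "young", default_group("young"))
        if self.old is None:
            object.__setattr__(self, "old", default_group("old"))
        p, q = len(US_VARIABLES), len(CONDITIONS)
        if self.us_corr is None:
            object.__setattr__(self, "us_corr", np.eye(p))
        if self.sway_corr is None:
            object.__setattr__(self, "sway_corr", _exchangeable(q, 0.5))
        for name, mat, dim in (("us_corr", self.us_corr, p), ("sway_corr", self.sway_corr, q)):
            m = np.asarray(mat, dtype=float)
            if m.shape != (dim, dim) or not np.allclose(m, m.T):
                raise ValueError(f"{name} must be a symmetric {dim}x{dim} matrix")
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ValueError(f"{name} is not positive semi-definite")
            object.__setattr__(self, name, m)


def _exchangeable(q: int, rho: float) -> np.ndarray:
    return np.full((q, q), rho) + (1 - rho) * np.eye(q)


def default_group(which: str, coupling_rho: float | None = None) -> GroupParams:
    """Group parameters from the published young/old summaries.

    Default couplings emulate the reported findings: a moderate positive
    association (0.53) between muscle quality and sway in the young group,
    none in the old group.
    """
    if which == "young":
        us, demo, sway = _YOUNG_US, _YOUNG_DEMO, _YOUNG_SWAY
        n, rho = 32, 0.53 if coupling_rho is None else coupling_rho
    elif which == "old":
        us, demo, sway = _OLD_US, _OLD_DEMO, _OLD_SWAY
        n, rho = 34, 0.0 if coupling_rho is None else coupling_rho
    else:
        raise ValueError("group must be 'young' or 'old'")
    return GroupParams(
        n=n,
        us_means={v: us[v][0] for v in US_VARIABLES},
        us_sds={v: us[v][1] for v in US_VARIABLES},
        sway_means=dict(sway),
        sway_sds={c: 0.25 * sway[c] for c in CONDITIONS},
        coupling_rho=rho,
        age_range=demo["age_range"],
        height=demo["height"],
        weight=demo["weight"],
        n_female=demo["female"],
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _lognormal_sigma(mean: float, sd: float) -> float:
    return math.sqrt(math.log(1.0 + (sd / mean) ** 2))


def _is_lognormal(mean: float, sd: float) -> bool:
    """Use a log-scale draw when a normal at mean/SD would go negative
    within the 2.5 SD working range."""
    return mean - 2.5 * sd <= 0


def _attenuation(mean: float, sd: float) -> float:
    """Pearson attenuation factor of corr(latent Z, moment-matched exp(sigma Z))."""
    if not _is_lognormal(mean, sd):
        return 1.0
    s = _lognormal_sigma(mean, sd)
    return s / math.sqrt(math.expm1(s**2))


def _group_latent_cov(group: GroupParams, us_corr: np.ndarray, sway_corr: np.ndarray) -> np.ndarray:
    """Joint latent correlation over (8 US, 4 sway) standardized factors.

    Cross-covariances are rank-1 along the quality signs and scaled so the
    pooled US score and pooled sway score correlate at coupling_rho; latent
    entries of lognormal variables are divided by the attenuation factor so
    the post-transform Pearson correlations land on target.
    """
    p, q = len(US_VARIABLES), len(CONDITIONS)
    signs = np.array(
        [QUALITY_SIGNS[v] if v in COUPLED_VARIABLES else 0.0 for v in US_VARIABLES]
    )
    gam = np.array([_attenuation(group.us_means[v], group.us_sds[v]) for v in US_VARIABLES])
    n_coupled = len(COUPLED_VARIABLES)
    a = signs / n_coupled
    var_us = float(a @ us_corr @ a)
    ones = np.ones(q) / q
    var_sw = float(ones @ sway_corr @ ones)
    k = group.coupling_rho * math.sqrt(var_us * var_sw)
    C = np.empty((p + q, p + q))
    # US block: compensate pairwise attenuation (first-order for LN-LN pairs)
    us_latent = us_corr / np.outer(gam, gam)
    np.fill_diagonal(us_latent, 1.0)
    C[:p, :p] = us_latent
    C[p:, p:] = sway_corr
    cross = np.outer(k * signs / gam, np.ones(q))
    C[:p, p:] = cross
    C[p:, :p] = cross.T
    ev = np.linalg.eigvalsh(C)
    if ev.min() < -1e-10:
        raise ValueError(
            "joint latent correlation matrix (us_corr + coupling) is not positive "
            "semi-definite; weaken coupling_rho or the us_corr entries"
        )
    return C


def _mvn_factor(C: np.ndarray) -> np.ndarray:
    ev, U = np.linalg.eigh(C)
    ev = np.clip(ev, 0.0, None)
    return U * np.sqrt(ev)


def _simulate_group(group: GroupParams, us_corr, sway_corr, label: str,
                    rng: np.random.Generator, id_offset: int) -> pd.DataFrame:
    p, q = len(US_VARIABLES), len(CONDITIONS)
    L = _mvn_factor(_group_latent_cov(group, us_corr, sway_corr))
    Z = rng.standard_normal((group.n, p + q)) @ L.T
    data = {}
    for j, v in enumerate(US_VARIABLES):
        m, s = group.us_means[v], group.us_sds[v]
        if _is_lognormal(m, s):
            sig = _lognormal_sigma(m, s)
            mu = math.log(m) - 0.5 * sig**2
            data[v] = np.exp(mu + sig * Z[:, j])
        else:
            data[v] = m + s * Z[:, j]
    for c_idx, c in enumerate(CONDITIONS):
        data[f"sdCOP_AP_{c}"] = np.maximum(
            group.sway_means[c] + group.sway_sds[c] * Z[:, p + c_idx], 0.05
        )
    n = group.n
    age = rng.uniform(*group.age_range, size=n)
    sex = np.array(["F"] * group.n_female + ["M"] * (n - group.n_female))
    rng.shuffle(sex)
    height_cm = rng.normal(group.height[0], group.height[1], size=n)
    weight_kg = rng.normal(group.weight[0], group.weight[1], size=n)
    df = pd.DataFrame(
        {
            "subject_id": [f"S{id_offset + i:03d}" for i in range(n)],
            "group": label,
            "age": age,
            "sex": sex,
            "height_cm": height_cm,
            "height_m": height_cm / 100.0,
            "weight_kg": weight_kg,
            **data,
        }
    )
    for c in CONDITIONS:
        df[f"sdCOP_AP_norm_{c}"] = df[f"sdCOP_AP_{c}"] / df["height_m"]
    return df


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per subject: demographics, eight US variables, per-condition
    sdCOP_AP (raw mm, and normalized by height in m).  Deterministic given
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    young = _simulate_group(spec.young, spec.us_corr, spec.sway_corr, "young", rng, 0)
    old = _simulate_group(spec.old, spec.us_corr, spec.sway_corr, "old", rng, spec.young.n)
    return pd.concat([young, old], ignore_index=True)


def pooled_scores(cohort: pd.DataFrame,
                  variables=COUPLED_VARIABLES) -> tuple[np.ndarray, np.ndarray]:
    """Sign-corrected mean of z-scored US variables and mean z-scored sway.

    Computed within the given table (z-scores use its own means/SDs) over
    the coupled variable set by default; this is the quantity whose
    correlation the generator's ``coupling_rho`` controls.
    """
    z = lambda col: (col - col.mean()) / col.std(ddof=1)
    us = np.column_stack([QUALITY_SIGNS[v] * z(cohort[v].to_numpy()) for v in variables])
    sway = np.column_stack([z(cohort[f"sdCOP_AP_{c}"].to_numpy()) for c in CONDITIONS])
    return us.mean(axis=1), sway.mean(axis=1)


def cohort_to_long(cohort: pd.DataFrame) -> pd.DataFrame:
    """Long table with one row per subject x condition (for the sway ANOVA)."""
    rows = []
    for c in CONDITIONS:
        part = cohort[["subject_id", "group", "age", "sex", "height_m"]].copy()
        part["condition"] = c
        part["sdCOP_AP"] = cohort[f"sdCOP_AP_{c}"]
        part["sdCOP_AP_norm"] = cohort[f"sdCOP_AP_norm_{c}"]
        rows.append(part)
    out = pd.concat(rows, ignore_index=True)
    return out.rename(columns={"subject_id": "subject"})


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Long-format CSV (one row per subject x condition) with a header
    comment documenting the columns."""
    long = cohort_to_long(cohort)
    header = (
        "# synthetic cohort; one row per subject x condition\n"
        "# subject: id; group: young|old; age: years; sex: F|M; height_m: m\n"
        "# condition: EOhard|EChard|EOfoam|ECfoam\n"
        "# sdCOP_AP: mm; sdCOP_AP_norm: mm per m of height\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        long.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# ultrasound-like images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagePhenotype:
    """Appearance parameters of a synthetic muscle image.

    ``mean_intensity`` is the target mean gray level of the muscle region;
    ``heterogeneity_scale`` the SD of coarse intensity clutter emulating
    fat/connective-tissue infiltration; ``speckle_corr_len`` the correlation
    length (pixels) of the fine speckle.
    """

    mean_intensity: float = 32.0
    heterogeneity_scale: float = 6.0
    speckle_corr_len: float = 2.0
    skin_depth_px: int = 50
    sat_thickness_px: int = 98
    muscle_thickness_px: int = 221
    pixel_spacing: float = 0.01
    image_size: tuple[int, int] = (420, 320)

    def __post_init__(self) -> None:
        if not (0 <= self.mean_intensity <= 255):
            raise ValueError("mean_intensity must be in [0, 255]")
        if self.heterogeneity_scale < 0:
            raise ValueError("heterogeneity_scale must be >= 0")
        rows, _ = self.image_size
        deep = self.skin_depth_px + self.sat_thickness_px + self.muscle_thickness_px
        if deep + 10 > rows:
            raise ValueError(
                f"tissue layers (deep boundary at {deep}px) do not fit in {rows} rows"
            )
        if self.muscle_thickness_px < 30:
            raise ValueError("muscle region too thin to carry the texture ROIs")

    @staticmethod
    def young(**overrides) -> "ImagePhenotype":
        """Defaults emulating a young muscle: dark, homogeneous speckle."""
        return ImagePhenotype(**{"mean_intensity": 32.0, "heterogeneity_scale": 6.0,
                                 "speckle_corr_len": 2.0, "muscle_thickness_px": 221,
                                 **overrides})

    @staticmethod
    def old(**overrides) -> "ImagePhenotype":
        """Defaults emulating an older muscle: brighter, heterogeneous,
        shorter speckle correlation (infiltrated tissue scatters finely)."""
        return ImagePhenotype(**{"mean_intensity": 56.0, "heterogeneity_scale": 20.0,
                                 "speckle_corr_len": 1.2, "muscle_thickness_px": 138,
                                 **overrides})


def _correlated_noise(shape, corr_len: float, rng: np.random.Generator) -> np.ndarray:
    w = rng.standard_normal(shape)
    if corr_len > 0:
        w = gaussian_filter(w, sigma=corr_len, mode="reflect")
    sd = w.std()
    return w / sd if sd > 0 else w


def generate_us_image(
    phenotype: ImagePhenotype, seed: int
) -> tuple[GrayImage, LandmarkSet, PolygonROI, RectROI]:
    """Layered synthetic image plus the ground-truth annotations.

    Layout (top to bottom): gel, bright skin band, darker subcutaneous fat,
    bright superficial aponeurosis, muscle speckle, bright deep boundary.
    The muscle-region mean is driven to within ±2 gray levels of the
    phenotype's ``mean_intensity`` (clipping to 8 bits shifts the mean, so
    an offset is iterated against the clipped result).
    """
    rng = np.random.default_rng(seed)
    rows, cols = phenotype.image_size
    skin = phenotype.skin_depth_px
    apo = skin + phenotype.sat_thickness_px
    deep = apo + phenotype.muscle_thickness_px

    img = np.full((rows, cols), 12.0)
    img += 2.0 * rng.standard_normal((rows, cols))
    img[skin : skin + 6, :] = 185.0 + 8.0 * rng.standard_normal((min(6, rows - skin), cols))
    img[skin + 6 : apo, :] = 26.0 + 4.0 * rng.standard_normal((max(0, apo - skin - 6), cols))
    img[apo : apo + 4, :] = 215.0 + 6.0 * rng.standard_normal((4, cols))
    img[deep : min(deep + 5, rows), :] = 225.0 + 6.0 * rng.standard_normal(
        (min(deep + 5, rows) - deep, cols)
    )
    if deep + 5 < rows:
        img[deep + 5 :, :] = 18.0 + 3.0 * rng.standard_normal((rows - deep - 5, cols))

    m_top, m_bot = apo + 4, deep  # muscle speckle block
    block_shape = (m_bot - m_top, cols)
    # zero-mean texture = fine speckle + coarse clutter, passed through a
    # tanh soft limiter scaled to keep every pixel strictly inside [0, 255]:
    # hard clipping would pile probability mass on gray level 0 at strong
    # heterogeneity, creating spurious textural uniformity
    speckle = 12.0 * _correlated_noise(block_shape, phenotype.speckle_corr_len, rng)
    clutter = phenotype.heterogeneity_scale * _correlated_noise(block_shape, 6.0, rng)
    fine = 0.25 * phenotype.heterogeneity_scale * rng.standard_normal(block_shape)
    amp = 0.95 * min(phenotype.mean_intensity, 255.0 - phenotype.mean_intensity)
    if amp > 0:
        field = phenotype.mean_intensity + amp * np.tanh((speckle + clutter + fine) / amp)
    else:
        field = np.full(block_shape, phenotype.mean_intensity)

    polygon = PolygonROI(
        vertices=(
            (m_top + 2, 8.0),
            (m_top + 2, cols - 9.0),
            (m_bot - 3, cols - 21.0),
            (m_bot - 3, 20.0),
        )
    )
    mask = polygon.mask((rows, cols))[m_top:m_bot, :]
    field += phenotype.mean_intensity - field[mask].mean()
    img[m_top:m_bot, :] = np.clip(field, 0, 255)

    rect = RectROI(
        row0=m_top + 4,
        col0=40,
        height=max(2, (m_bot - m_top) - 12),
        width=cols - 80,
    )
    landmarks = LandmarkSet(skin_depth=skin, superficial_apo_depth=apo, deep_boundary_depth=deep)
    gray = GrayImage(
        pixels=np.clip(np.round(img), 0, 255).astype(np.uint8),
        pixel_spacing=phenotype.pixel_spacing,
        id=f"synthetic_{seed}",
    )
    return gray, landmarks, polygon, rect


# ---------------------------------------------------------------------------
# force-plate recordings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwaySpec:
    """Targets for one synthetic quiet-stance recording."""

    target_sd_ap: float = 5.0
    target_sd_ml: float = 3.0
    band: tuple[float, float] = (0.1, 10.0)
    duration: float = 300.0
    fs: float = 1000.0
    body_weight: float = 700.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_sd_ap < 0 or self.target_sd_ml < 0:
            raise ValueError("target sway SDs must be >= 0")
        low, high = self.band
        if not (0 < low < high):
            raise ValueError("band must satisfy 0 < low < high")
        if self.fs <= 2 * high:
            raise ValueError("sampling rate must exceed twice the band's upper edge")
        if self.duration * self.fs < 200:
            raise ValueError("recording shorter than the filter warm-up length")
        if self.body_weight <= 100:
            raise ValueError("body weight must be a plausible stance load (N)")


def _bandlimited_noise(n: int, band, fs: float, target_sd: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise spectrally confined to an inner sub-band of ``band``.

    The power is placed on [2.5*low, 0.6*high] (via an FFT brick wall) so the
    analysis band-pass at ``band`` itself passes the signal with gain ~1 and
    the planted SD survives the processing chain; real COP power likewise
    concentrates well inside the analysis band.
    """
    if target_sd == 0:
        return np.zeros(n)
    low, high = band
    lo_inner = 2.5 * low
    hi_inner = 0.6 * high
    if not lo_inner < hi_inner:
        lo_inner, hi_inner = low, high
    w = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    w[(freqs < lo_inner) | (freqs > hi_inner)] = 0.0
    x = np.fft.irfft(w, n)
    x = x - x.mean()
    return x * (target_sd / x.std(ddof=1))


def generate_forceplate_recording(spec: SwaySpec):
    """Synthetic plate channels whose reconstructed COP has the target SDs.

    The latent COP per axis is white Gaussian noise band-passed to
    ``spec.band`` and rescaled to the target SD, then converted to moments
    by inverting the COP equations around a constant vertical load:
    Mx = COP_AP·Fz, My = −COP_ML·Fz (COP in meters).  Deterministic given
    ``spec.seed``.
    """
    from .posturography import ForcePlateRecording

    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    cop_ap_mm = _bandlimited_noise(n, spec.band, spec.fs, spec.target_sd_ap, rng)
    cop_ml_mm = _bandlimited_noise(n, spec.band, spec.fs, spec.target_sd_ml, rng)
    t = np.arange(n) / spec.fs
    fz = np.full(n, float(spec.body_weight))
    mx = (cop_ap_mm / 1000.0) * fz
    my = -(cop_ml_mm / 1000.0) * fz
    zeros = np.zeros(n)
    return ForcePlateRecording(
        fs=spec.fs, t=t, Fx=zeros, Fy=zeros, Fz=fz, Mx=mx, My=my, Mz=zeros
    )
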
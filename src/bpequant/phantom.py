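"""Synthetic DCE-MRI phantoms and measure-level matched cohorts.

Two generators live here:

``generate_phantom``
    Builds a digital breast phantom — two half-ellipsoid breasts attached to
    a body slab on an axial grid — together with a four-sequence DCE study
    (one pre-contrast, three post-contrast volumes).  Designed enhancing
    voxels receive a multiplicative signal increase, so their enhancement
    ratio R% equals the design ratio exactly at zero noise.  Ground-truth
    masks and the exact designed measures are returned alongside, which lets
    every downstream quantification stage be validated to machine precision.

``generate_cohort``
    Draws a measure-level 1:1 age-matched case-control cohort whose per-SUB
    BPE% distributions follow configurable group means/SDs, with correlated
    bilateral breasts for controls.  An optional logistic assignment mode
    plants a known conditional log-odds effect so estimator recovery can be
    checked against the generating model.

Randomness: each generator consumes a single ``numpy.random.default_rng``
seeded from its params. Stream order for the phantom is pre-contrast noise,
then post-contrast noise in SUB order; for the cohort it is documented in
``generate_cohort``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError
from .image import DceStudy, ImageVolume, voxel_volume_cm3

__all__ = [
    "PhantomParams",
    "PhantomTruth",
    "DesignedMeasures",
    "CohortParams",
    "generate_phantom",
    "generate_cohort",
    "write_phantom",
    "COHORT_COLUMNS",
]

SIDES = ("left", "right")


@dataclass
class PhantomParams:
    """Design parameters of the digital breast phantom.

    Defaults emulate a bilateral axial fat-suppressed T1 acquisition with
    2 mm slices and 1 mm in-plane resolution.
    """

    grid_shape: tuple[int, int, int] = (64, 128, 128)
    spacing_mm: tuple[float, float, float] = (2.0, 1.0, 1.0)
    #: per-axis ellipsoid semi-axes (slice, row, column) in mm, per breast
    breast_half_axes_mm: tuple[float, float, float] = (40.0, 55.0, 28.0)
    fat_intensity: float = 60.0
    fgt_intensity: float = 200.0
    #: target FGT% of breast volume
    fgt_fraction: float = 15.0
    #: target BPE% of breast volume at the designed enhancement ratio
    enhancing_fraction: float = 40.0
    #: designed R% per post-contrast sequence, non-decreasing
    enhancement_ratio_per_sub: tuple[float, float, float] = (30.0, 40.0, 50.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive ints, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if any(a <= 0 for a in self.breast_half_axes_mm):
            raise ValueError("breast_half_axes_mm must be positive")
        if not (0 <= self.fgt_fraction <= 100 and 0 <= self.enhancing_fraction <= 100):
            raise ValueError("fgt_fraction and enhancing_fraction must lie in [0, 100]")
        r = self.enhancement_ratio_per_sub
        if len(r) != 3 or not (r[0] <= r[1] <= r[2]):
            raise ValueError("enhancement_ratio_per_sub must be three non-decreasing values")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class DesignedMeasures:
    """Exact zero-noise measures implied by the phantom design (one side)."""

    breast_cm3: float
    fgt_cm3: float
    fgt_pct: float
    bpe_cm3_per_sub: tuple[float, float, float]
    bpe_pct_per_sub: tuple[float, float, float]


@dataclass
class PhantomTruth:
    """Ground-truth masks and exact designed measures for a phantom study."""

    breast_mask: dict[str, np.ndarray]  # per side
    fgt_mask: np.ndarray  # bilateral
    enhancing_mask_per_sub: tuple[np.ndarray, np.ndarray, np.ndarray]
    designed_measures: dict[str, DesignedMeasures]  # per side
    spacing_mm: tuple[float, float, float] = (2.0, 1.0, 1.0)

    def fgt_mask_side(self, side: str) -> np.ndarray:
        return self.fgt_mask & self.breast_mask[side]


def _phantom_geometry(params: PhantomParams):
    """Coordinate bookkeeping for the two half-ellipsoid breasts.

    The chest-wall plane sits between voxel rows so each breast is an exact
    half ellipsoid of analytic volume (2/3)*pi*a*b*c.
    """
    nz, ny, nx = params.grid_shape
    sz, sy, sx = params.spacing_mm
    az, ay, ax = params.breast_half_axes_mm

    chest_row = int(np.ceil(ay / sy)) + 4  # rows >= chest_row are body slab
    zc = (nz - 1) / 2.0 * sz
    yc = (chest_row - 0.5) * sy  # plane between rows chest_row-1 and chest_row
    xc = {"left": (nx - 1) * 0.25 * sx, "right": (nx - 1) * 0.75 * sx}

    # containment checks (breast must fit strictly inside the grid)
    if chest_row >= ny - 1:
        raise GeometryError("breast depth exceeds grid rows")
    if zc - az < 0 or zc + az > (nz - 1) * sz:
        raise GeometryError("breast slice extent exceeds grid")
    if xc["left"] - ax < 0 or xc["right"] + ax > (nx - 1) * sx:
        raise GeometryError("breast column extent exceeds grid")
    if xc["left"] + ax >= xc["right"] - ax:
        raise GeometryError("left and right breasts overlap")
    return chest_row, zc, yc, xc


def generate_phantom(params: PhantomParams) -> tuple[DceStudy, PhantomTruth]:
    """Generate a DCE study with known ground truth.

    Pre-contrast signal is ``fat_intensity`` in fat/body and
    ``fgt_intensity`` in FGT. Post-contrast sequence k multiplies the
    pre-contrast signal of designed enhancing voxels by
    ``1 + enhancement_ratio_per_sub[k]/100`` and leaves all other voxels
    unchanged; independent Gaussian noise is then added to every sequence.
    Deterministic given ``params.seed``.
    """
    nz, ny, nx = params.grid_shape
    sz, sy, sx = params.spacing_mm
    az, ay, ax = params.breast_half_axes_mm
    chest_row, zc, yc, xcs = _phantom_geometry(params)

    z = np.arange(nz)[:, None, None] * sz
    y = np.arange(ny)[None, :, None] * sy
    x = np.arange(nx)[None, None, :] * sx
    anterior = np.broadcast_to(np.arange(ny)[None, :, None] < chest_row, (nz, ny, nx))

    breast_mask: dict[str, np.ndarray] = {}
    rho2: dict[str, np.ndarray] = {}
    rho2_shift: dict[str, np.ndarray] = {}
    for side in SIDES:
        xc = xcs[side]
        r2 = ((z - zc) / az) ** 2 + ((y - yc) / ay) ** 2 + ((x - xc) / ax) ** 2
        breast_mask[side] = (r2 <= 1.0) & anterior
        rho2[side] = r2
        # enhancing region is ranked about a centre shifted anteriorly by ay/3
        rho2_shift[side] = (
            ((z - zc) / az) ** 2 + ((y - (yc - ay / 3.0)) / ay) ** 2 + ((x - xc) / ax) ** 2
        )

    vv = voxel_volume_cm3(params.spacing_mm)
    fgt_mask = np.zeros(params.grid_shape, dtype=bool)
    enh_mask = np.zeros(params.grid_shape, dtype=bool)
    designed: dict[str, DesignedMeasures] = {}
    for side in SIDES:
        bm = breast_mask[side]
        n_side = int(np.count_nonzero(bm))
        if n_side == 0:
            raise GeometryError(f"{side} breast contains no voxels")
        idx = np.flatnonzero(bm.ravel())
        # innermost-by-radius voxel ranking gives exact designed counts
        k_f = int(round(params.fgt_fraction / 100.0 * n_side))
        order_f = idx[np.argsort(rho2[side].ravel()[idx], kind="stable")]
        fgt_flat = order_f[:k_f]
        k_e = int(round(params.enhancing_fraction / 100.0 * n_side))
        order_e = idx[np.argsort(rho2_shift[side].ravel()[idx], kind="stable")]
        enh_flat = order_e[:k_e]
        fgt_mask.ravel()[fgt_flat] = True
        enh_mask.ravel()[enh_flat] = True
        designed[side] = DesignedMeasures(
            breast_cm3=n_side * vv,
            fgt_cm3=k_f * vv,
            fgt_pct=100.0 * k_f / n_side,
            bpe_cm3_per_sub=(k_e * vv,) * 3,
            bpe_pct_per_sub=(100.0 * k_e / n_side,) * 3,
        )

    body = np.broadcast_to(np.arange(ny)[None, :, None] >= chest_row, (nz, ny, nx))
    pre = np.zeros(params.grid_shape, dtype=np.float64)
    pre[body] = params.fat_intensity
    pre[breast_mask["left"] | breast_mask["right"]] = params.fat_intensity
    pre[fgt_mask] = params.fgt_intensity

    posts = []
    for r in params.enhancement_ratio_per_sub:
        post = pre.copy()
        post[enh_mask] *= 1.0 + r / 100.0
        posts.append(post)

    rng = np.random.default_rng(params.seed)
    if params.noise_sd > 0:
        pre = pre + rng.normal(0.0, params.noise_sd, size=pre.shape)
        posts = [p + rng.normal(0.0, params.noise_sd, size=p.shape) for p in posts]

    study = DceStudy(
        pre=ImageVolume(pre, params.spacing_mm),
        posts=tuple(ImageVolume(p, params.spacing_mm) for p in posts),
    )
    truth = PhantomTruth(
        breast_mask=breast_mask,
        fgt_mask=fgt_mask,
        enhancing_mask_per_sub=(enh_mask.copy(), enh_mask.copy(), enh_mask.copy()),
        designed_measures=designed,
        spacing_mm=params.spacing_mm,
    )
    return study, truth


def write_phantom(study: DceStudy, truth: PhantomTruth, out_dir) -> None:
    """Write a phantom study as NIfTI volumes plus a JSON truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.pre.to_nifti(out / "pre.nii.gz")
    for k, post in enumerate(study.posts, start=1):
        post.to_nifti(out / f"post{k}.nii.gz")
    affine_spacing = truth.spacing_mm
    for side in SIDES:
        ImageVolume(truth.breast_mask[side].astype(float), affine_spacing).to_nifti(
            out / f"breast_mask_{side}.nii.gz"
        )
    ImageVolume(truth.fgt_mask.astype(float), affine_spacing).to_nifti(out / "fgt_mask.nii.gz")
    for k, m in enumerate(truth.enhancing_mask_per_sub, start=1):
        ImageVolume(m.astype(float), affine_spacing).to_nifti(out / f"enhancing_mask_sub{k}.nii.gz")
    manifest = {
        "spacing_mm": list(truth.spacing_mm),
        "designed_measures": {s: asdict(m) for s, m in truth.designed_measures.items()},
    }
    (out / "truth.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# Measure-level cohort generator
# ---------------------------------------------------------------------------

#: Documented cohort CSV column dictionary. Measures are per breast
#: ("contra" = contralateral/disease-free side, "benign" = biopsy-proven
#: benign side, controls only) and per subtraction sequence.
COHORT_COLUMNS = {
    "subject_id": "unique subject identifier",
    "group": "case | control",
    "pair_id": "1:1 matched-pair identifier",
    "age": "age in years",
    "menopausal": "0 = premenopausal, 1 = postmenopausal",
    "family_history": "0/1 family history of breast cancer",
    "density_category": "ordinal mammographic density 1-4",
    "breast_cm3_contra": "|Breast| of the contralateral breast, cm^3",
    "fgt_cm3_contra": "|FGT| contralateral, cm^3",
    "fgt_pct_contra": "FGT% contralateral, %",
    "bpe_cm3_sub1_contra": "|BPE| from SUB1, contralateral, cm^3",
    "bpe_cm3_sub2_contra": "|BPE| from SUB2, contralateral, cm^3",
    "bpe_cm3_sub3_contra": "|BPE| from SUB3, contralateral, cm^3",
    "bpe_pct_sub1_contra": "BPE% from SUB1, contralateral, %",
    "bpe_pct_sub2_contra": "BPE% from SUB2, contralateral, %",
    "bpe_pct_sub3_contra": "BPE% from SUB3, contralateral, %",
    "breast_cm3_benign": "|Breast| of the benign-lesion breast (controls), cm^3",
    "fgt_cm3_benign": "|FGT| benign side, cm^3",
    "fgt_pct_benign": "FGT% benign side, %",
    "bpe_cm3_sub1_benign": "|BPE| from SUB1, benign side, cm^3",
    "bpe_cm3_sub2_benign": "|BPE| from SUB2, benign side, cm^3",
    "bpe_cm3_sub3_benign": "|BPE| from SUB3, benign side, cm^3",
    "bpe_pct_sub1_benign": "BPE% from SUB1, benign side, %",
    "bpe_pct_sub2_benign": "BPE% from SUB2, benign side, %",
    "bpe_pct_sub3_benign": "BPE% from SUB3, benign side, %",
}


@dataclass
class CohortParams:
    """Distributional design of a simulated 1:1 matched case-control cohort.

    BPE% means/SDs default to the contralateral-breast summaries of a
    51-pair screening-age cohort (cases 45/58/62 +- 9/11/11 across
    SUB1..SUB3; controls 40/51/56 +- 11/13/14).
    """

    n_pairs: int = 51
    case_bpe_mean_per_sub: tuple[float, float, float] = (45.0, 58.0, 62.0)
    case_bpe_sd_per_sub: tuple[float, float, float] = (9.0, 11.0, 11.0)
    control_bpe_mean_per_sub: tuple[float, float, float] = (40.0, 51.0, 56.0)
    control_bpe_sd_per_sub: tuple[float, float, float] = (11.0, 13.0, 14.0)
    #: |Breast| mean and SD in cm^3 (implied by |BPE| / BPE% ratios)
    breast_volume_mean_sd: tuple[float, float] = (1000.0, 250.0)
    fgt_percent_mean_sd: tuple[float, float] = (13.5, 7.5)
    #: correlation of BPE% between a woman's two breasts
    bilateral_corr_bpe: float = 0.56
    #: correlation of FGT% (and |Breast|) between a woman's two breasts
    bilateral_corr_fgt: float = 0.86
    #: correlation of BPE% across the three SUBs within one breast
    sub_corr: float = 0.8
    age_range: tuple[int, int] = (31, 60)
    menopausal_prop: float = 0.43
    family_history_prop: float = 0.56
    density_probs: tuple[float, float, float, float] = (0.03, 0.26, 0.64, 0.07)
    age_match_tolerance_years: int = 3
    #: if set, case status is assigned by a conditional logistic model with
    #: this log-odds per one SUB1 BPE% point (both pair members then drawn
    #: from the control distribution) — used for estimator-recovery checks
    effect_log_or_per_unit: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        for sds in (self.case_bpe_sd_per_sub, self.control_bpe_sd_per_sub):
            if any(s <= 0 for s in sds):
                raise ValueError("BPE% SDs must be positive")
        if self.breast_volume_mean_sd[1] <= 0 or self.fgt_percent_mean_sd[1] <= 0:
            raise ValueError("SDs must be positive")
        for p in (self.menopausal_prop, self.family_history_prop, *self.density_probs):
            if not 0 <= p <= 1:
                raise ValueError("proportions must lie in [0, 1]")
        if not np.isclose(sum(self.density_probs), 1.0):
            raise ValueError("density_probs must sum to 1")
        for r in (self.bilateral_corr_bpe, self.bilateral_corr_fgt, self.sub_corr):
            if not -1 < r < 1:
                raise ValueError("correlations must lie in (-1, 1)")


def _equicorr(k: int, rho: float) -> np.ndarray:
    return np.full((k, k), rho) + (1 - rho) * np.eye(k)


def _bilateral_cov(sds: np.ndarray, sub_corr: float, bilat_corr: float) -> np.ndarray:
    """6x6 covariance: (contra, benign) x (SUB1..3), Kronecker structure."""
    c3 = _equicorr(3, sub_corr)
    c2 = _equicorr(2, bilat_corr)
    corr = np.kron(c2, c3)
    s = np.concatenate([sds, sds])
    return corr * np.outer(s, s)


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw a matched case-control cohort table.

    Stream order per pair: ages, covariates (case then control), breast
    volumes, FGT%, BPE% triples, then (in logistic mode) the case-assignment
    uniform. Deterministic given ``params.seed``. All BPE%/FGT% values are
    clipped to [0, 100]; volumes are truncated below at 200 cm^3.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.age_range
    rows = []
    c3 = _equicorr(3, params.sub_corr)
    case_cov = c3 * np.outer(params.case_bpe_sd_per_sub, params.case_bpe_sd_per_sub)
    ctrl_cov6 = _bilateral_cov(
        np.asarray(params.control_bpe_sd_per_sub, dtype=float),
        params.sub_corr,
        params.bilateral_corr_bpe,
    )
    fgt_cov2 = _equicorr(2, params.bilateral_corr_fgt) * params.fgt_percent_mean_sd[1] ** 2
    vol_cov2 = _equicorr(2, params.bilateral_corr_fgt) * params.breast_volume_mean_sd[1] ** 2

    for j in range(params.n_pairs):
        age_case = int(rng.integers(lo, hi + 1))
        tol = params.age_match_tolerance_years
        age_ctrl = int(np.clip(age_case + rng.integers(-tol, tol + 1), lo, hi))

        cov = {}
        for who in ("case", "control"):
            cov[who] = dict(
                menopausal=int(rng.random() < params.menopausal_prop),
                family_history=int(rng.random() < params.family_history_prop),
                density_category=int(rng.choice(4, p=params.density_probs)) + 1,
            )

        vols = np.maximum(
            rng.multivariate_normal([params.breast_volume_mean_sd[0]] * 2, vol_cov2, size=2),
            200.0,
        )  # rows: case, control; cols: contra, benign
        fgts = np.clip(
            rng.multivariate_normal([params.fgt_percent_mean_sd[0]] * 2, fgt_cov2, size=2),
            0.0,
            100.0,
        )

        if params.effect_log_or_per_unit is None:
            bpe_case = np.clip(
                rng.multivariate_normal(params.case_bpe_mean_per_sub, case_cov), 0, 100
            )
            bpe_ctrl6 = np.clip(
                rng.multivariate_normal(list(params.control_bpe_mean_per_sub) * 2, ctrl_cov6),
                0,
                100,
            )
            case_is_first = True
        else:
            # both members from the control distribution; case status follows
            # the 1:1 conditional logistic model at the configured log-odds
            b1 = np.clip(
                rng.multivariate_normal(list(params.control_bpe_mean_per_sub) * 2, ctrl_cov6),
                0,
                100,
            )
            b2 = np.clip(
                rng.multivariate_normal(list(params.control_bpe_mean_per_sub) * 2, ctrl_cov6),
                0,
                100,
            )
            beta = params.effect_log_or_per_unit
            p_first = 1.0 / (1.0 + np.exp(-beta * (b1[0] - b2[0])))
            case_is_first = bool(rng.random() < p_first)
            bpe_case = (b1 if case_is_first else b2)[:3]
            bpe_ctrl6 = b2 if case_is_first else b1

        def record(who, age, bpe_contra, bpe_benign, vol_row, fgt_row, sid):
            rec = dict(
                subject_id=sid,
                group=who,
                pair_id=f"P{j:04d}",
                age=age,
                **cov[who],
            )
            for b, (bpe, vol, fgt) in (
                ("contra", (bpe_contra, vol_row[0], fgt_row[0])),
                ("benign", (bpe_benign, vol_row[1], fgt_row[1])),
            ):
                if bpe is None:
                    for k in (1, 2, 3):
                        rec[f"bpe_cm3_sub{k}_{b}"] = np.nan
                        rec[f"bpe_pct_sub{k}_{b}"] = np.nan
                    rec[f"breast_cm3_{b}"] = np.nan
                    rec[f"fgt_cm3_{b}"] = np.nan
                    rec[f"fgt_pct_{b}"] = np.nan
                    continue
                rec[f"breast_cm3_{b}"] = vol
                rec[f"fgt_pct_{b}"] = fgt
                rec[f"fgt_cm3_{b}"] = fgt * vol / 100.0
                for k in (1, 2, 3):
                    rec[f"bpe_pct_sub{k}_{b}"] = bpe[k - 1]
                    rec[f"bpe_cm3_sub{k}_{b}"] = bpe[k - 1] * vol / 100.0
            return rec

        rows.append(
            record("case", age_case, bpe_case[:3], None, vols[0], fgts[0], f"S{2 * j:04d}")
        )
        rows.append(
            record(
                "control", age_ctrl, bpe_ctrl6[:3], bpe_ctrl6[3:], vols[1], fgts[1], f"S{2 * j + 1:04d}"
            )
        )

    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return df
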
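"""End-to-end orchestration: I/O, configuration, and the study report.

``run_study`` executes the four-step analysis battery on a matched cohort
(correlations, conditional-logistic odds ratios with FDR adjustment,
unconditional-logistic AUCs with DeLong comparisons, and the basic-factors
versus basic+BPE nested-model comparison), or — in phantom/image modes —
drives segmentation and quantification of volumetric studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import CohortValidationError
from .image import BreastMask, FgtMask, ImageVolume, DceStudy
from .phantom import COHORT_COLUMNS, CohortParams, PhantomParams, generate_cohort, generate_phantom
from .quantify import quantify_study
from .segment import segment_breast, segment_fgt
from . import stats as bstats

__all__ = [
    "StudyConfig",
    "StudyReport",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "run_study",
    "write_report",
    "BASIC_FACTORS",
    "CLR_COVARIATES",
]

#: basic clinical risk factors used in the nested-model comparison
BASIC_FACTORS = ["age", "menopausal", "family_history", "density_category"]
#: adjustment set of the multivariable conditional logistic models
CLR_COVARIATES = ["menopausal", "family_history", "density_category", "fgt_cm3", "fgt_pct"]

_SUBS = (1, 2, 3)
_PCT_COLUMNS = [c for c in COHORT_COLUMNS if "pct" in c]


@dataclass
class StudyConfig:
    """Configuration of one study run.

    ``mode`` selects the input kind: ``"phantom"`` (synthesise a DCE study
    and quantify it), ``"images"`` (quantify NIfTI volumes from disk) or
    ``"measures"`` (statistical analysis of a cohort table; generated from
    ``cohort_params`` when ``cohort_path`` is absent).
    """

    mode: str = "measures"
    cohort_path: str | None = None
    pre_path: str | None = None
    post_paths: tuple[str, str, str] | None = None
    r_cutoffs: tuple[float, ...] = (20.0, 30.0, 40.0)
    comparison: str = "both"  # "A" | "B" | "both"
    pre_floor: float = 0.0
    seed: int = 0
    out_dir: str | None = None
    verbosity: int = 1
    phantom_params: PhantomParams = field(default_factory=PhantomParams)
    cohort_params: CohortParams = field(default_factory=CohortParams)

    def __post_init__(self) -> None:
        if self.mode not in ("phantom", "images", "measures"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if any(c <= 0 for c in self.r_cutoffs):
            raise ValueError("r_cutoffs must be positive")
        if self.comparison not in ("A", "B", "both"):
            raise ValueError("comparison must be 'A', 'B' or 'both'")
        if self.mode == "images" and (self.pre_path is None or self.post_paths is None):
            raise ValueError("images mode requires pre_path and post_paths")

    @property
    def comparisons(self) -> tuple[str, ...]:
        return ("A", "B") if self.comparison == "both" else (self.comparison,)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a YAML mapping")
        for key, ptype in (("phantom_params", PhantomParams), ("cohort_params", CohortParams)):
            if key in raw and isinstance(raw[key], dict):
                sub = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in raw[key].items()
                }
                raw[key] = ptype(**sub)
        for key in ("r_cutoffs", "post_paths"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def validate_cohort(df: pd.DataFrame) -> None:
    """Schema and integrity validation of a cohort table.

    Raises :class:`CohortValidationError` on unknown/missing columns, type
    or range violations, duplicate subject ids, or broken 1:1 pairing.
    """
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortValidationError(f"missing columns: {sorted(missing)}")
    unknown = set(df.columns) - set(COHORT_COLUMNS)
    if unknown:
        raise CohortValidationError(f"unknown columns: {sorted(unknown)}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortValidationError(f"duplicate subject ids: {dups}")
    bad_group = set(df["group"].unique()) - {"case", "control"}
    if bad_group:
        raise CohortValidationError(f"invalid group labels: {sorted(bad_group)}")
    for col in _PCT_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        out_of_range = vals[(vals < 0) | (vals > 100)]
        if len(out_of_range):
            raise CohortValidationError(
                f"{col} outside [0, 100]: e.g. {out_of_range.iloc[0]!r}"
            )
    for col in ("age", "menopausal", "family_history", "density_category", "breast_cm3_contra"):
        if pd.to_numeric(df[col], errors="coerce").isna().any():
            raise CohortValidationError(f"non-numeric or missing values in {col!r}")
    vols = df["breast_cm3_contra"]
    if (vols <= 0).any():
        raise CohortValidationError("breast volumes must be positive")
    for pair_id, grp in df.groupby("pair_id"):
        n_case = int((grp["group"] == "case").sum())
        n_ctrl = int((grp["group"] == "control").sum())
        if n_case != 1 or n_ctrl != 1:
            raise CohortValidationError(
                f"pair {pair_id!r} has {n_case} case(s) and {n_ctrl} control(s); expected 1:1"
            )


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (schema in ``phantom.COHORT_COLUMNS``)."""
    df = pd.read_csv(path)
    validate_cohort(df)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    validate_cohort(df)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# the study report
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    """Serializable study outputs; ``fits`` keeps the underlying fit objects
    in memory for cross-checking but is not serialized."""

    provenance: dict
    sections: dict
    fits: dict = field(default_factory=dict, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {"provenance": self.provenance, "sections": self.sections}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, default=_jsonable, **kw)

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        d = json.loads(text)
        return cls(provenance=d["provenance"], sections=d["sections"])


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _summary_stats(v: np.ndarray) -> dict:
    v = np.asarray(v, dtype=float)
    return {
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)),
        "min": float(np.min(v)),
        "max": float(np.max(v)),
    }


def _measure_columns() -> list[str]:
    cols = ["fgt_cm3", "fgt_pct"]
    for m in ("bpe_cm3", "bpe_pct"):
        cols += [f"{m}_sub{k}" for k in _SUBS]
    return cols


def _correlation_section(cohort: pd.DataFrame) -> dict:
    """Spearman correlations among density, FGT and BPE (contralateral)."""
    res = {}
    c = bstats.select_breast(cohort, "A")
    pairs = [("density_category", "fgt_pct"), ("density_category", "bpe_pct_sub1")]
    pairs += [(f"fgt_cm3", f"bpe_cm3_sub{k}") for k in _SUBS]
    pairs += [(f"fgt_pct", f"bpe_pct_sub{k}") for k in _SUBS]
    for a, b in pairs:
        rho, p = bstats.spearman(c[a], c[b])
        res[f"{a}__vs__{b}"] = {"rho": rho, "p": p}
    ctrl = cohort[cohort["group"] == "control"]
    for base in ("bpe_pct_sub1", "fgt_pct"):
        a = ctrl[f"{base}_contra"].to_numpy(dtype=float)
        b = ctrl[f"{base}_benign"].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() >= 3:
            rho, p = bstats.spearman(a[ok], b[ok])
            res[f"bilateral__{base}"] = {"rho": rho, "p": p}
    return res


def _table2_section(cohort: pd.DataFrame, comparison: str) -> dict:
    c = bstats.select_breast(cohort, comparison)
    cases = c[c["group"] == "case"].sort_values("pair_id")
    ctrls = c[c["group"] == "control"].sort_values("pair_id")
    out = {}
    for col in ["breast_cm3"] + _measure_columns():
        tt = bstats.paired_t(cases[col].to_numpy(float), ctrls[col].to_numpy(float))
        out[col] = {
            "cases": _summary_stats(cases[col]),
            "controls": _summary_stats(ctrls[col]),
            "paired_t_p": tt.p,
        }
    return out


def _or_section(cohort: pd.DataFrame, comparison: str, fits: dict) -> dict:
    """Table-3-shaped conditional-logistic odds ratios with BH adjustment.

    The FDR families are the six univariate and the six multivariable
    analyses (2 BPE measures x 3 SUBs) within each comparison.
    """
    out = {"univariate": {}, "multivariable": {}}
    for kind, covs in (("univariate", []), ("multivariable", CLR_COVARIATES)):
        cells = []
        for measure in ("bpe_cm3", "bpe_pct"):
            for k in _SUBS:
                exposure = f"{measure}_sub{k}"
                model = bstats.ConditionalLogit.from_cohort(
                    cohort, exposure, covs, comparison=comparison
                )
                fit = model.fit()
                fits[f"{comparison}:{kind}:{exposure}"] = fit
                entry = {
                    "exposure": exposure,
                    "converged": fit.converged,
                    "flags": list(fit.flags),
                    "coef": float(fit.params[exposure]),
                    "se": float(fit.bse[exposure]),
                    "p": float(fit.pvalues[exposure]),
                }
                if "separation" not in fit.flags:
                    ors = fit.or_per_increment().loc[exposure]
                    entry.update(
                        increment=float(ors["increment"]),
                        odds_ratio=float(ors["odds_ratio"]),
                        ci_lower=float(ors["ci_lower"]),
                        ci_upper=float(ors["ci_upper"]),
                    )
                cells.append(entry)
        adj = bstats.bh_fdr([c["p"] for c in cells])
        for cell, q in zip(cells, adj):
            cell["p_fdr"] = float(q)
            out[kind][cell["exposure"]] = cell
    return out


def _auc_section(cohort: pd.DataFrame, comparison: str, fits: dict) -> dict:
    """Table-4-shaped AUCs from unconditional logistic regression, with
    DeLong comparisons across SUBs and across measures."""
    c = bstats.select_breast(cohort, comparison)
    y = (c["group"] == "case").to_numpy()
    predictor_sets: dict[str, list[str]] = {}
    for k in _SUBS:
        predictor_sets[f"bpe_cm3:sub{k}"] = [f"bpe_cm3_sub{k}"]
        predictor_sets[f"bpe_pct:sub{k}"] = [f"bpe_pct_sub{k}"]
        predictor_sets[f"combined:sub{k}"] = [f"bpe_cm3_sub{k}", f"bpe_pct_sub{k}"]
    for m in ("bpe_cm3", "bpe_pct"):
        predictor_sets[f"{m}:allsubs"] = [f"{m}_sub{k}" for k in _SUBS]
    predictor_sets["combined:allsubs"] = [
        f"{m}_sub{k}" for m in ("bpe_cm3", "bpe_pct") for k in _SUBS
    ]

    scores = {}
    aucs = {}
    for name, preds in predictor_sets.items():
        fit = bstats.unconditional_logistic(c, preds)
        fits[f"{comparison}:auc:{name}"] = fit
        scores[name] = fit.fitted
        aucs[name] = bstats.roc_auc(fit.fitted, y)

    delong = {}
    # across SUBs (and the all-SUB combination) within each measure row
    for m in ("bpe_cm3", "bpe_pct", "combined"):
        cols = [f"{m}:sub{k}" for k in _SUBS] + [f"{m}:allsubs"]
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                delong[f"{a}__vs__{b}"] = bstats.delong_test(scores[a], scores[b], y).p
    # across measures within each SUB column
    for k in list(_SUBS) + ["allsubs"]:
        suffix = f"sub{k}" if k in _SUBS else "allsubs"
        rows = [f"bpe_cm3:{suffix}", f"bpe_pct:{suffix}", f"combined:{suffix}"]
        for i, a in enumerate(rows):
            for b in rows[i + 1:]:
                delong[f"{a}__vs__{b}"] = bstats.delong_test(scores[a], scores[b], y).p
    return {"auc": aucs, "delong_p": delong}


def _basic_factors_section(cohort: pd.DataFrame, comparison: str, fits: dict) -> dict:
    """Nested-model comparison: basic risk factors vs basic + SUB2 BPE."""
    c = bstats.select_breast(cohort, comparison)
    y = (c["group"] == "case").to_numpy()
    base = bstats.unconditional_logistic(c, BASIC_FACTORS)
    full = bstats.unconditional_logistic(
        c, BASIC_FACTORS + ["bpe_cm3_sub2", "bpe_pct_sub2"]
    )
    chi2, df, p = bstats.lr_test(base, full)
    fits[f"{comparison}:basic"] = base
    fits[f"{comparison}:basic_plus_bpe"] = full
    return {
        "auc_basic": bstats.roc_auc(base.fitted, y),
        "auc_basic_plus_bpe": bstats.roc_auc(full.fitted, y),
        "lrt_chi2": chi2,
        "lrt_df": df,
        "lrt_p": p,
    }


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    return float(2.0 * np.logical_and(a, b).sum() / denom) if denom else 1.0


def _phantom_section(config: StudyConfig) -> dict:
    params = PhantomParams(**{**asdict(config.phantom_params), "seed": config.seed})
    study, truth = generate_phantom(params)
    left, right = segment_breast(study.pre)
    seg = {"left": left, "right": right}
    section: dict = {"segmentation": {}, "measures": {}, "designed": {}}
    truth_masks = {
        s: BreastMask(truth.breast_mask[s], s, params.spacing_mm) for s in ("left", "right")
    }
    fgt_masks = {
        s: FgtMask(truth.fgt_mask_side(s), truth_masks[s]) for s in ("left", "right")
    }
    for s in ("left", "right"):
        section["segmentation"][s] = {
            "dice_breast": _dice(seg[s].mask, truth.breast_mask[s]),
            "dice_fgt": _dice(
                segment_fgt(study.pre, seg[s]).mask if not seg[s].is_empty else np.zeros(1),
                truth.fgt_mask_side(s),
            ),
        }
        section["designed"][s] = asdict(truth.designed_measures[s])
    # quantification runs on the ground-truth masks: exact by design at zero noise
    records = quantify_study(
        study, truth_masks, fgt_masks, r_cutoffs=tuple(config.r_cutoffs),
        pre_floor=config.pre_floor,
    )
    section["measures"] = records
    return section


def _images_section(config: StudyConfig) -> dict:
    pre = ImageVolume.from_nifti(config.pre_path)
    posts = tuple(ImageVolume.from_nifti(p) for p in config.post_paths)
    study = DceStudy(pre, posts)
    left, right = segment_breast(pre)
    breasts = {s.side: s for s in (left, right) if not s.is_empty}
    fgts = {side: segment_fgt(pre, b) for side, b in breasts.items()}
    records = quantify_study(
        study, breasts, fgts, r_cutoffs=tuple(config.r_cutoffs), pre_floor=config.pre_floor
    )
    return {"measures": records}


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the configured study and return its report.

    Measures mode runs, in order: (1) Spearman correlations among density,
    FGT and BPE; (2) univariate and multivariable conditional-logistic odds
    ratios per SUB with BH-FDR adjustment; (3) unconditional-logistic AUCs
    with DeLong comparisons; (4) the basic-factors vs basic+BPE nested-model
    comparison.  Deterministic given ``config.seed``.
    """
    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config": _provenance_config(config),
    }
    fits: dict = {}
    sections: dict = {}
    if config.mode == "phantom":
        sections["phantom"] = _phantom_section(config)
    elif config.mode == "images":
        sections["images"] = _images_section(config)
    else:
        if config.cohort_path is not None:
            cohort = read_cohort(config.cohort_path)
        else:
            cp = CohortParams(**{**asdict(config.cohort_params), "seed": config.seed})
            cohort = generate_cohort(cp)
        validate_cohort(cohort)
        sections["correlations"] = _correlation_section(cohort)
        for comparison in config.comparisons:
            sections[f"comparison_{comparison}"] = {
                "summary": _table2_section(cohort, comparison),
                "odds_ratios": _or_section(cohort, comparison, fits),
                "auc": _auc_section(cohort, comparison, fits),
                "basic_factors": _basic_factors_section(cohort, comparison, fits),
            }
    return StudyReport(provenance=provenance, sections=sections, fits=fits)


def _provenance_config(config: StudyConfig) -> dict:
    d = asdict(config)
    for key in ("phantom_params", "cohort_params"):
        d[key] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d[key].items()}
    d["r_cutoffs"] = list(d["r_cutoffs"])
    return d


def write_report(report: StudyReport, out_dir) -> None:
    """Write the report as JSON plus tabular CSVs and a text summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json(indent=2))
    for name, section in report.sections.items():
        if name in ("phantom", "images") and "measures" in section:
            pd.DataFrame(section["measures"]).to_csv(out / "measures.csv", index=False)
        if name.startswith("comparison_"):
            rows = []
            for kind, cells in section["odds_ratios"].items():
                for exposure, cell in cells.items():
                    rows.append({"comparison": name[-1], "model": kind, **cell})
            pd.DataFrame(rows).to_csv(out / f"odds_ratios_{name[-1]}.csv", index=False)
    (out / "summary.txt").write_text(_human_summary(report))


def _human_summary(report: StudyReport) -> str:
    lines = [f"bpequant study report (version {report.provenance['version']}, "
             f"seed {report.provenance['seed']})"]
    for name, section in report.sections.items():
        lines.append(f"\n== {name} ==")
        if name.startswith("comparison_"):
            for kind, cells in section["odds_ratios"].items():
                lines.append(f"  {kind} conditional logistic odds ratios:")
                for exposure, cell in cells.items():
                    if "odds_ratio" in cell:
                        lines.append(
                            f"    {exposure:<16} OR {cell['odds_ratio']:.2f} "
                            f"({cell['ci_lower']:.2f}, {cell['ci_upper']:.2f}); "
                            f"p = {cell['p']:.4f}, FDR-adjusted {cell['p_fdr']:.4f}"
                        )
            auc = section["auc"]["auc"]
            lines.append("  AUCs: " + ", ".join(f"{k} {v:.3f}" for k, v in sorted(auc.items())))
            bf = section["basic_factors"]
            lines.append(
                f"  basic factors AUC {bf['auc_basic']:.3f} -> with BPE "
                f"{bf['auc_basic_plus_bpe']:.3f} (LRT p = {bf['lrt_p']:.4g})"
            )
        elif name == "phantom":
            for side, d in section["segmentation"].items():
                lines.append(
                    f"  {side}: Dice breast {d['dice_breast']:.4f}, FGT {d['dice_fgt']:.4f}"
                )
    return "\n".join(lines) + "\n"
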
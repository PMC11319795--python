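"""End-to-end orchestration: simulate -> texture -> posture -> stats -> ROC -> CCA.

``run_pipeline`` executes the full analysis chain on a synthetic cohort (or
a cohort CSV) with one master seed, writing machine-readable JSON results
and human-readable CSV tables.  Every output embeds the package version and
a hash of the configuration that produced it.  Randomness flows from the
master seed through named substreams so stages are individually
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import cca as _cca
from . import group_stats as gs
from . import posturography as post
from . import roc as _roc
from . import synthetic as syn
from . import us_image as usi

__all__ = ["RunConfig", "run_pipeline", "seed_substream"]

log = logging.getLogger("echosway")

#: the five ultrasound parameters entering the CCA block
CCA_US_VARS = ["EI", "MT", "ASM", "IDM", "Entropy"]

#: VL parameters entering the ROC analysis
ROC_PARAMS = ["EI", "MT", "SAT", "ASM", "Contrast", "Correlation", "IDM", "Entropy"]


def seed_substream(master_seed: int, name: str) -> int:
    """Stable per-stage seed derived from the master seed and a stream name."""
    h = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Pipeline configuration; all stages honour ``master_seed``."""

    output_dir: str = "echosway_out"
    cohort_csv: str | None = None  # analyze an existing cohort instead of simulating
    master_seed: int = 0
    n_young: int = 32
    n_old: int = 34
    coupling_young: float = 0.53
    coupling_old: float = 0.0
    n_perm: int = 1000
    winsor_sd: float = 2.5
    lambda_grid: tuple = _cca.DEFAULT_LAMBDA_GRID
    filter_band: tuple[float, float] = (0.1, 10.0)
    n_demo_images: int = 2          # per group, texture-stage demonstration
    n_demo_recordings: int = 2      # posture-stage demonstration
    demo_recording_fs: float = 250.0
    demo_recording_duration: float = 60.0
    glcm: usi.GLCMConfig = field(default_factory=usi.GLCMConfig)

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("config: n_perm must be >= 1")
        if self.winsor_sd <= 0:
            raise ValueError("config: winsor_sd must be positive")
        low, high = self.filter_band
        if not 0 < low < high:
            raise ValueError("config: filter band must satisfy 0 < low < high")
        if self.cohort_csv is None and (self.n_young < 2 or self.n_old < 2):
            raise ValueError("config: group sizes must be >= 2")

    def config_hash(self) -> str:
        # hash only settings that influence the numbers, not I/O locations
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("glcm", "output_dir", "cohort_csv")}
        payload["glcm"] = asdict(self.glcm)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _stage(name: str):
    log.info("stage: %s", name)


def simulate_stage(cfg: RunConfig) -> pd.DataFrame:
    spec = syn.CohortSpec(
        young=syn.default_group("young", cfg.coupling_young),
        old=syn.default_group("old", cfg.coupling_old),
        seed=seed_substream(cfg.master_seed, "cohort"),
    )
    # group sizes may deviate from the defaults
    from dataclasses import replace
    spec = syn.CohortSpec(
        young=replace(spec.young, n=cfg.n_young,
                      n_female=min(spec.young.n_female, cfg.n_young)),
        old=replace(spec.old, n=cfg.n_old,
                    n_female=min(spec.old.n_female, cfg.n_old)),
        seed=spec.seed,
    )
    return syn.generate_cohort(spec)


def texture_stage(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    """Generate a few phenotype images per group and measure them."""
    rows = []
    for group, phen_factory in (("young", syn.ImagePhenotype.young), ("old", syn.ImagePhenotype.old)):
        for i in range(cfg.n_demo_images):
            seed = seed_substream(cfg.master_seed, f"image:{group}:{i}")
            img, lm, poly, rect = syn.generate_us_image(phen_factory(), seed)
            mt, sat = usi.measure_thickness(lm, img.pixel_spacing)
            ei = usi.compute_ei(img, poly)
            feats = usi.glcm_features(img, rect, cfg.glcm)
            rows.append({"group": group, "image": img.id, "MT_cm": mt, "SAT_cm": sat, "EI": ei,
                         "ASM": feats.ASM, "Contrast": feats.Contrast,
                         "Correlation": feats.Correlation, "IDM": feats.IDM,
                         "Entropy": feats.Entropy})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "texture_demo_features.csv", index=False)
    return df


def posture_stage(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    """Generate demonstration recordings and recover their sway summaries."""
    rows = []
    for i in range(cfg.n_demo_recordings):
        seed = seed_substream(cfg.master_seed, f"plate:{i}")
        target = 4.0 + 1.5 * i
        spec = syn.SwaySpec(target_sd_ap=target, target_sd_ml=0.6 * target,
                            fs=cfg.demo_recording_fs, duration=cfg.demo_recording_duration,
                            band=cfg.filter_band, seed=seed)
        rec = syn.generate_forceplate_recording(spec)
        cop = post.bandpass_cop(post.compute_cop(rec), *cfg.filter_band)
        summ = post.sway_summary(cop, height_m=1.70, condition="EOhard", subject_id=f"demo{i}")
        rows.append({"subject": f"demo{i}", "target_sd_ap_mm": target,
                     "recovered_sdCOP_AP_mm": summ.sdCOP_AP,
                     "recovered_sdCOP_ML_mm": summ.sdCOP_ML})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "posture_demo_recovery.csv", index=False)
    return df


def group_tables_stage(cohort: pd.DataFrame, outdir: Path) -> dict:
    young = cohort[cohort["group"] == "young"]
    old = cohort[cohort["group"] == "old"]
    rows = []
    for var in ROC_PARAMS + ["height_cm", "weight_kg", "age"]:
        res = gs.ttest_raw(young[var], old[var], variable=var)
        rows.append({"variable": var, "young_mean": young[var].mean(), "young_sd": young[var].std(ddof=1),
                     "old_mean": old[var].mean(), "old_sd": old[var].std(ddof=1),
                     "t": res.t, "df": res.df, "p": res.p, "cohens_d": res.cohens_d,
                     "method": res.method})
    ttable = pd.DataFrame(rows)
    ttable.to_csv(outdir / "group_comparisons.csv", index=False)

    n_f_young = int((young["sex"] == "F").sum())
    n_f_old = int((old["sex"] == "F").sum())
    sex_p = gs.fisher_exact_2x2(n_f_young, len(young) - n_f_young, n_f_old, len(old) - n_f_old)

    long = syn.cohort_to_long(cohort)
    aov = gs.anova_condition_by_age(long)
    aov.effects.to_csv(outdir / "anova_effects.csv")
    aov.posthoc.to_csv(outdir / "anova_posthoc.csv", index=False)
    return {
        "sex_fisher_p": sex_p,
        "anova": {eff: dict(aov.effects.loc[eff]) for eff in aov.effects.index},
    }


def roc_stage(cohort: pd.DataFrame, outdir: Path) -> dict:
    aucs = {}
    points = []
    for parm in ROC_PARAMS:
        res = _roc.classify_parameter(cohort, parm)
        aucs[parm] = res.auc
        points.append(pd.DataFrame({"parameter": parm, "fpr": res.fpr, "tpr": res.tpr}))
    pd.concat(points, ignore_index=True).to_csv(outdir / "roc_points.csv", index=False)
    matrix = _roc.pairwise_auc_matrix(cohort, ROC_PARAMS)
    matrix.to_csv(outdir / "auc_comparisons.csv", index=False)
    return aucs


def cca_stage(cfg: RunConfig, cohort: pd.DataFrame, outdir: Path) -> dict:
    out = {}
    for group in ("young", "old"):
        sub = cohort[cohort["group"] == group]
        X = sub[CCA_US_VARS].to_numpy()
        Y = sub[[f"sdCOP_AP_norm_{c}" for c in post.CONDITIONS]].to_numpy()
        seed = seed_substream(cfg.master_seed, f"cca:{group}")
        res, pooled = _cca.run_cca_analysis(
            X, Y, sub["age"].to_numpy(),
            cfg=_cca.PreprocConfig(winsor_sd=cfg.winsor_sd),
            grid=cfg.lambda_grid, n_perm=cfg.n_perm, seed=seed, us_names=CCA_US_VARS,
        )
        out[group] = {
            "r": res.r, "perm_p": res.perm_p, "n_perm": res.n_perm,
            "lambda_x": res.lambda_x, "lambda_y": res.lambda_y,
            "wx": dict(zip(CCA_US_VARS, res.wx.tolist())),
            "wy": dict(zip(post.CONDITIONS, res.wy.tolist())),
            "pooled_pearson_r": pooled.pearson_r, "pooled_p": pooled.p,
            "pooled_strength": gs.label_correlation_strength(pooled.pearson_r),
            "seed": seed,
            "lambda_reselected_per_perm": res.lambda_reselected_per_perm,
        }
        pd.DataFrame({"pooled_us": pooled.pooled_us, "pooled_sway": pooled.pooled_sway}).to_csv(
            outdir / f"pooled_scores_{group}.csv", index=False
        )
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the results bundle."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.master_seed,
    }
    stage = "simulate"
    try:
        if cfg.cohort_csv is not None:
            cohort = pd.read_csv(cfg.cohort_csv, comment="#")
        else:
            _stage(stage)
            cohort = simulate_stage(cfg)
        syn.write_cohort_csv(cohort, outdir / "cohort_long.csv")
        cohort.to_csv(outdir / "cohort_wide.csv", index=False)

        if cfg.n_demo_images > 0:
            stage = "texture"
            _stage(stage)
            texture_stage(cfg, outdir)
        if cfg.n_demo_recordings > 0:
            stage = "posture"
            _stage(stage)
            posture_stage(cfg, outdir)

        stage = "group_tables"
        _stage(stage)
        results["group_stats"] = group_tables_stage(cohort, outdir)

        stage = "roc"
        _stage(stage)
        results["auc"] = roc_stage(cohort, outdir)

        stage = "cca"
        _stage(stage)
        results["cca"] = cca_stage(cfg, cohort, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "results.json").write_text(json.dumps(results, indent=1, default=float))
    return results
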
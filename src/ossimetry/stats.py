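"""Group statistics (unpaired Welch two-sample t-test) and the cohort study
runner that exercises the full simulate -> reconstruct -> segment -> measure
chain and compares control vs arthritis morphometry per ossicle class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import forward_model as fm
from . import morphometry as mm
from . import recon as rc
from . import segmentation as seg
from .config import PipelineConfig
from .errors import OssimetryError, StatsError, StudyError

PARAMETERS = ("BV_TV", "BS_BV", "BS_TV")

#: Report footer: raw p-values are reported without multiple-testing
#: correction across parameters and ossicle classes.
FOOTER = (
    "p-values are raw two-sided Welch t-test probabilities; no "
    "multiple-testing correction is applied across parameters or classes."
)


@dataclass(frozen=True)
class WelchResult:
    """Unequal-variance two-sample t-test with Welch-Satterthwaite df."""

    t: float
    df: float
    p: float
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    n1: int
    n2: int

    @property
    def percent_change(self) -> float:
        """100 x (mean2 - mean1) / mean1."""
        return 100.0 * (self.mean2 - self.mean1) / self.mean1


def welch_t_test(group1, group2) -> WelchResult:
    """Welch's unpaired two-sample t-test (two-sided).

    t  = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2)
    df = (s1^2/n1 + s2^2/n2)^2 /
         [ (s1^2/n1)^2/(n1-1) + (s2^2/n2)^2/(n2-1) ]

    Sample variances use the n-1 denominator. Identical groups give t = 0,
    p = 1; a group with fewer than two values or zero variance is an error.
    """
    g1 = np.asarray(group1, dtype=np.float64)
    g2 = np.asarray(group2, dtype=np.float64)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise StatsError(f"each group needs n >= 2 (got {n1}, {n2})")
    v1 = float(g1.var(ddof=1))
    v2 = float(g2.var(ddof=1))
    if v1 == 0.0 or v2 == 0.0:
        raise StatsError("degenerate group with zero variance")
    m1, m2 = float(g1.mean()), float(g2.mean())
    se1, se2 = v1 / n1, v2 / n2
    t = (m1 - m2) / math.sqrt(se1 + se2)
    df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return WelchResult(t=t, df=df, p=p, mean1=m1, mean2=m2,
                       sd1=math.sqrt(v1), sd2=math.sqrt(v2), n1=n1, n2=n2)


# ---------------------------------------------------------------------------
# cohort study
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    samples: pd.DataFrame        # per-sample morphometry
    summary: pd.DataFrame        # per class x parameter group comparison
    log: list[str] = field(default_factory=list)
    footer: str = FOOTER

    def to_csv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(out / "samples.csv", index=False)
        self.summary.to_csv(out / "group_summary.csv", index=False)
        (out / "study_log.txt").write_text(
            "\n".join(self.log + ["", self.footer]) + "\n"
        )


def process_phantom(p, cfg: PipelineConfig, noise_seed: int) -> list[dict]:
    """Run one phantom through the full measurement chain.

    project -> propagate -> [extended-FOV split] -> noise -> flat correct ->
    [stitch] -> phase retrieve -> FBP -> median -> Otsu -> label -> VOI match
    -> morphometry. Returns one row per matched ossicle.
    """
    g = fm.Geometry(
        pixel_size_um=p.voxel_size_um,
        distance_cm=cfg.geometry.distance_cm,
        energy_keV=cfg.geometry.energy_keV,
        n_projections=cfg.geometry.n_projections,
        angular_range_deg=cfg.geometry.angular_range_deg,
    )
    sim = cfg.simulation
    ps = fm.project(p, sim.mu_bone_mm, sim.mu_background_mm, g,
                    flat_value=sim.flat_value)
    ps = fm.propagate(ps, cfg.retrieval.delta_beta)
    if sim.use_extended_fov:
        ps = fm.split_extended_fov(ps, cfg.geometry.fov_offset_px)
    ps = fm.add_noise(ps, sim.mean_counts, seed=noise_seed,
                      read_noise_counts=sim.read_noise_counts)
    ps = rc.flat_correct(ps)
    if sim.use_extended_fov:
        ps = rc.stitch_360(ps)
    ps = rc.phase_retrieve(ps, cfg.retrieval.delta_beta)
    vol = rc.fbp_reconstruct(ps)
    lv = seg.segment_volume(
        vol, median_radius=cfg.segmentation.median_radius,
        n_bins=cfg.segmentation.n_bins, min_voxels=cfg.segmentation.min_voxels,
    )
    match = seg.select_voi(lv, p.labels)
    rows = []
    for seg_label, ref_label in match.mapping.items():
        res = mm.MorphometryResult(
            label=ref_label,
            BV=mm.bone_volume(lv, seg_label),
            BS=mm.bone_surface(lv, seg_label),
            TV=mm.total_volume(lv, seg_label),
        )
        rows.append({
            "sample_id": p.meta.get("sample_id", "sample"),
            "group": p.meta.get("group", ""),
            "ossicle_class": p.meta.get("ossicle_class", "anterior"),
            "label": ref_label,
            "BV_mm3": res.BV,
            "BS_mm2": res.BS,
            "TV_mm3": res.TV,
            "BV_TV": res.BV_TV,
            "BS_BV_mm-1": res.BS_BV,
            "BS_TV_mm-1": res.BS_TV,
            "overlap_fraction": match.overlap_fraction[seg_label],
            "threshold_used": lv.threshold_used,
        })
    return rows


def run_cohort_study(cohort, cfg: PipelineConfig) -> StudyReport:
    """Full per-phantom measurement chain plus per-parameter Welch tests.

    ``cohort`` is a sequence of ``(Phantom, group)`` pairs as produced by
    :func:`ossimetry.phantom.make_cohort` (one or more ossicle classes).
    A phantom whose chain raises is logged and dropped; the study aborts if
    any group of any class falls below two samples.
    """
    log: list[str] = [f"config_hash={cfg.config_hash()}", f"seed={cfg.seed}"]
    rows: list[dict] = []
    for i, (p, group) in enumerate(cohort):
        p.meta["group"] = group
        noise_seed = cfg.seed + 104729 + 31 * i
        try:
            sample_rows = process_phantom(p, cfg, noise_seed)
            rows.extend(sample_rows)
            log.append(
                f"sample={p.meta.get('sample_id', i)} group={group} "
                f"ossicles={len(sample_rows)} noise_seed={noise_seed}"
            )
        except OssimetryError as exc:
            log.append(f"sample={p.meta.get('sample_id', i)} FAILED: {exc}")
    if not rows:
        raise StudyError("no phantom survived the pipeline")
    samples = pd.DataFrame(rows)

    summary_rows = []
    column_of = {"BV_TV": "BV_TV", "BS_BV": "BS_BV_mm-1", "BS_TV": "BS_TV_mm-1"}
    for klass, sub in samples.groupby("ossicle_class", sort=True):
        ctrl = sub[sub["group"] == "control"]
        arth = sub[sub["group"] == "arthritis"]
        if len(ctrl) < 2 or len(arth) < 2:
            raise StudyError(
                f"class {klass!r}: groups below n=2 "
                f"(control={len(ctrl)}, arthritis={len(arth)})"
            )
        for param in PARAMETERS:
            col = column_of[param]
            res = welch_t_test(ctrl[col].to_numpy(), arth[col].to_numpy())
            summary_rows.append({
                "ossicle_class": klass,
                "parameter": param,
                "mean_control": res.mean1,
                "sd_control": res.sd1,
                "n_control": res.n1,
                "mean_arthritis": res.mean2,
                "sd_arthritis": res.sd2,
                "n_arthritis": res.n2,
                "percent_change": res.percent_change,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "significant": res.p < 0.05,
            })
    summary = pd.DataFrame(summary_rows)
    return StudyReport(samples=samples, summary=summary, log=log)
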
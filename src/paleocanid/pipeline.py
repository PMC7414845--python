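"""Pipeline orchestration: configuration, stage dispatch, report assembly.

``run_pipeline`` executes the analysis stages (biometry, tissue, outline,
damage, calibrate) in dependency order on either user-supplied inputs or
self-generated synthetic data, and assembles a machine-readable JSON
report stamped with the seed and a hash of the configuration, plus a
short human-readable summary.  Every random operation derives its seed
from the single configured seed, so a given configuration is
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import biometry as bm
from . import damage as dmg
from . import microct as mc
from . import outline as ol
from . import radiocarbon as rc
from . import synthetic as syn

ALL_STAGES = ["biometry", "tissue", "outline", "damage", "calibrate"]

_KNOWN_KEYS = {
    "seed",
    "outdir",
    "stages",
    "wear_frac",
    "bvtv_threshold",
    "hpd_mass",
    "sliding_mode",
    "preset",
    "inputs",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Unknown keys are rejected; every random operation takes its seed from
    ``seed``.  ``preset`` selects the synthetic problem sizes: ``demo``
    (fast smoke-test sizes) or ``paper-like`` (the study sample sizes:
    21 + 23 outlines and teeth, 50,000 reads).
    """

    seed: int = 0
    outdir: str = "paleocanid_run"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    wear_frac: float = 0.5
    bvtv_threshold: float = 0.65
    hpd_mass: float = 0.954
    sliding_mode: str = "bending_energy"
    preset: str = "demo"
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = [s for s in cfg.stages if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}; valid: {ALL_STAGES}")
        if cfg.preset not in ("demo", "paper-like"):
            raise ValueError("preset must be 'demo' or 'paper-like'")
        for path in cfg.inputs.values():
            if not Path(path).exists():
                raise FileNotFoundError(f"input path does not exist: {path}")
        return cfg

    def canonical(self) -> dict:
        return {
            "seed": self.seed,
            "stages": sorted(self.stages),
            "wear_frac": self.wear_frac,
            "bvtv_threshold": self.bvtv_threshold,
            "hpd_mass": self.hpd_mass,
            "sliding_mode": self.sliding_mode,
            "preset": self.preset,
            "inputs": {k: str(v) for k, v in sorted(self.inputs.items())},
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _round_floats(obj, nd=6):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), nd)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_biometry(cfg: RunConfig) -> dict:
    table, truth = syn.gen_measurement_table(
        [("dog", 0.8, 8), ("wolf", 1.0, 8)], noise_cv=0.04, seed=cfg.seed + 11
    )
    # flag a few rows the way field material would be flagged
    table.loc[table.index[:2], "flags"] = "burnt"
    kept, report = bm.apply_exclusions(table)
    profile = bm.log_shape_ratio(kept, syn.STANDARD_WOLF)
    summary = bm.summarize_population(profile, order=["dog", "wolf"])
    pop_means = profile.groupby("population")["log_ratio"].mean()
    return {
        "n_rows": int(len(table)),
        "n_excluded": int(len(report)),
        "population_mean_log_ratio": {k: float(v) for k, v in pop_means.items()},
        "expected_mean_log_ratio": truth["expected_mean_log_ratio"],
        "n_summary_rows": int(len(summary)),
    }


def _stage_tissue(cfg: RunConfig) -> dict:
    thick = syn.ToothPhantomConfig(enamel_thickness_mm=0.40, seed=cfg.seed + 21)
    gray, labels, truth = syn.gen_tooth_phantom(thick)
    seg, thresholds = mc.segment_tissues(gray, n_classes=3)
    plane = mc.fit_cervix_plane(
        mc.extract_cervix_points(labels),
        toward=labels.coords_mm(labels.mask("enamel")).mean(axis=0),
    )
    sl = mc.extract_crown_slice(labels, plane)
    tp = mc.dentine_percent(sl)
    wear = mc.detect_wear(labels, plane, level2=sl.level2, thin_frac=cfg.wear_frac)
    agree = float((seg.data == labels.data).mean())

    epi_young, t_y = syn.gen_epiphysis_phantom(
        syn.EpiphysisPhantomConfig(porosity=0.5, seed=cfg.seed + 22)
    )
    epi_adult, t_a = syn.gen_epiphysis_phantom(
        syn.EpiphysisPhantomConfig(porosity=0.2, seed=cfg.seed + 23)
    )
    bv_y = mc.bv_tv(epi_young, t_y["separation_plane"],
                    maturity_threshold=cfg.bvtv_threshold)
    bv_a = mc.bv_tv(epi_adult, t_a["separation_plane"],
                    maturity_threshold=cfg.bvtv_threshold)
    return {
        "segmentation_agreement": agree,
        "thresholds": [float(t) for t in thresholds],
        "dentine_percent": tp.percent,
        "worn": bool(wear.worn),
        "bvtv_young": bv_y.ratio,
        "bvtv_adult": bv_a.ratio,
        "calls": [bv_y.maturity_call, bv_a.maturity_call],
    }


def _stage_outline(cfg: RunConfig) -> dict:
    n = (21, 23) if cfg.preset == "paper-like" else (8, 9)
    ocfg = syn.OutlinePopConfig(n_per_group=n, seed=cfg.seed + 31)
    outlines, truth = syn.gen_outline_population(ocfg)
    configs = np.array([ol.resample_outline(o) for o in outlines])
    slid = ol.slide_semilandmarks(
        configs, ol.anchor_indices(), mode=cfg.sliding_mode, max_iter=5
    )
    shapes = ol.ShapeSet(
        coords=slid.configs,
        centroid_sizes=slid.centroid_sizes,
        specimen_ids=[o.specimen_id for o in outlines],
        groups=[o.group for o in outlines],
    )
    model = ol.bgpca(shapes)
    contrast = syn.contrast_configuration(
        truth, reference=slid.mean_shape, mode=cfg.sliding_mode
    )
    axis = model.components_[0]
    cosine = float(
        abs(axis @ contrast) / (np.linalg.norm(axis) * np.linalg.norm(contrast))
    )
    allo = ol.test_allometry(model.scores_, shapes.centroid_sizes)
    return {
        "n_specimens": int(len(outlines)),
        "n_points": int(configs.shape[1]),
        "bgpc1_contrast_cosine": cosine,
        "objective_path_len": len(slid.objective_path),
        "allometry": allo.as_dict(),
    }


def _stage_damage(cfg: RunConfig) -> dict:
    n_reads = 50_000 if cfg.preset == "paper-like" else 3000
    rcfg = syn.ReadSimConfig(n_reads=n_reads, seed=cfg.seed + 41)
    reads, truth = syn.gen_ancient_reads(rcfg)
    stats = dmg.fragment_length_stats(reads)
    prof = dmg.damage_profile(reads, k=25)
    cov = dmg.coverage_summary(dmg.depth_vector(reads))
    return {
        "n_reads": stats["n"],
        "mean_length": stats["mean"],
        "ct5_position1": float(prof.ct5[0]),
        "ga3_position1": float(prof.ga3[0]),
        "fraction_covered": cov["fraction_covered"],
        "mean_depth": cov["mean_depth"],
    }


def _stage_calibrate(cfg: RunConfig) -> dict:
    curve, truth = syn.gen_calibration_curve(syn.CurveSimConfig(seed=cfg.seed + 51))
    m1 = rc.RadiocarbonMeasurement(12000.0, 50.0, "lab-a")
    m2 = rc.RadiocarbonMeasurement(12080.0, 60.0, "lab-b")
    combined, report = rc.combine_measurements([m1, m2])
    cal = rc.calibrate(combined, curve, mass=cfg.hpd_mass)
    return {
        "combined_age": combined.age,
        "combined_sigma": combined.sigma,
        "consistent": bool(report["consistent"]),
        "mode_cal_bp": cal.mode,
        "hpd_ranges": [
            {"older": o, "younger": y, "mass": m} for o, y, m in cal.hpd_ranges
        ],
    }


_STAGE_FUNCS = {
    "biometry": _stage_biometry,
    "tissue": _stage_tissue,
    "outline": _stage_outline,
    "damage": _stage_damage,
    "calibrate": _stage_calibrate,
}


def run_pipeline(config: dict | RunConfig) -> dict:
    """Run the configured stages and write the report bundle.

    Returns the report dict; raises RuntimeError at the end if any stage
    failed (after running the independent remaining stages).
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": cfg.canonical(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    failures = []
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        try:
            report["stages"][stage] = _round_floats(_STAGE_FUNCS[stage](cfg))
        except Exception as exc:  # independent stages continue
            failures.append(stage)
            report["stages"][stage] = {"error": f"{type(exc).__name__}: {exc}"}
    report["ok"] = not failures

    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    lines = [f"paleocanid run (seed={cfg.seed}, hash={cfg.config_hash()})"]
    for stage, body in report["stages"].items():
        status = "FAILED" if "error" in body else "ok"
        lines.append(f"  {stage}: {status}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    if failures:
        raise RuntimeError(f"stages failed: {failures}")
    return report


def emit_fixture_set(outdir: str | Path, seed: int = 0,
                     preset: str = "paper-like") -> dict:
    """Write the full synthetic fixture set to disk.

    Emits the two-group outline sample (TPS + CSV), a tooth and an
    epiphysis phantom (TIFF + sidecar), measurement tables (CSV), the
    simulated read set (TSV + FASTA reference) and a synthetic
    calibration curve (CSV), each with a JSON ground-truth sidecar where
    meaningful.  Returns the file inventory.
    """
    from . import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inv: dict = {}

    n = (21, 23) if preset == "paper-like" else (6, 6)
    outlines, _ = syn.gen_outline_population(
        syn.OutlinePopConfig(n_per_group=n, seed=seed)
    )
    pio.write_tps(outlines, outdir / "outlines.tps")
    pio.write_outlines_csv(outlines, outdir / "outlines.csv")
    inv["outlines"] = ["outlines.tps", "outlines.csv"]

    gray, labels, truth = syn.gen_tooth_phantom(syn.ToothPhantomConfig(seed=seed))
    pio.save_volume(gray, outdir / "tooth_gray.tif")
    pio.save_volume(labels, outdir / "tooth_labels.tif")
    (outdir / "tooth_truth.json").write_text(
        json.dumps(
            _round_floats(
                {
                    "level1": truth["level1"],
                    "level2": truth["level2"],
                    "counts_unworn": truth["counts_unworn"],
                }
            ),
            indent=1,
        )
    )
    inv["tooth"] = ["tooth_gray.tif", "tooth_labels.tif", "tooth_truth.json"]

    epi, etruth = syn.gen_epiphysis_phantom(
        syn.EpiphysisPhantomConfig(porosity=0.4, seed=seed)
    )
    pio.save_volume(epi, outdir / "epiphysis.tif")
    inv["epiphysis"] = ["epiphysis.tif"]

    table, _ = syn.gen_measurement_table(
        [("dog", 0.8, 10), ("wolf", 1.0, 10)], seed=seed
    )
    table.to_csv(outdir / "measurements.csv", index=False)
    syn.STANDARD_WOLF.to_csv(outdir / "standard.csv", index=False)
    inv["measurements"] = ["measurements.csv", "standard.csv"]

    n_reads = 50_000 if preset == "paper-like" else 2000
    reads, _ = syn.gen_ancient_reads(
        syn.ReadSimConfig(n_reads=n_reads, seed=seed)
    )
    pio.write_reads_tsv(reads, outdir / "reads.tsv")
    pio.write_fasta(reads.reference, outdir / "reference.fa")
    inv["reads"] = ["reads.tsv", "reference.fa"]

    curve, _ = syn.gen_calibration_curve(syn.CurveSimConfig(seed=seed))
    curve.to_csv(outdir / "curve.14c")
    inv["curve"] = ["curve.14c"]
    return inv
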
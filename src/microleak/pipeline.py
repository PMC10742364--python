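"""Study-level orchestration: images + metadata in, measurements + tests out.

`run_specimen` takes one cross-section image with its metadata (group
label, margin anchor, optional die-centre landmark, delamination flag)
through the full measurement chain: dye thresholding, marker extraction,
quartic fit, calibrated arc-length penetration, and — when a restoration
RGB box is configured — cement-thickness stations.  `run_study` maps a
manifest CSV over `run_specimen`, applies the delamination policy, and
produces the per-specimen results table, group summaries, and the
omnibus/pairwise test report.

Everything is deterministic given the configuration and inputs.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import curvefit, segmentation, stats, synthetic, thickness

logger = logging.getLogger("microleak")

MANIFEST_COLUMNS = [
    "specimen_id",
    "group",
    "image_path",
    "margin_row",
    "margin_col",
    "center_row",
    "center_col",
    "delaminated",
]


@dataclass
class StudyConfig:
    """All tunables of the measurement and statistics pipeline."""

    threshold: segmentation.DyeThreshold = field(
        default_factory=segmentation.DyeThreshold
    )
    calibration: curvefit.CalibrationSpec = field(
        default_factory=curvefit.CalibrationSpec
    )
    degree: int = 4
    bin_width: float = 5.0
    n_thickness_stations: int = 3
    delamination_policy: str = "exclude"  # or "assign_cap"
    alpha: float = 0.05
    seed: int = 0
    resto_threshold: segmentation.DyeThreshold | None = None
    write_overlays: bool = False

    def __post_init__(self) -> None:
        if self.delamination_policy not in ("exclude", "assign_cap"):
            raise ValueError(
                f"delamination_policy must be 'exclude' or 'assign_cap', "
                f"got {self.delamination_policy!r}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "threshold" in d and isinstance(d["threshold"], dict):
            d["threshold"] = segmentation.DyeThreshold(**d["threshold"])
        if "calibration" in d and isinstance(d["calibration"], dict):
            d["calibration"] = curvefit.CalibrationSpec(**d["calibration"])
        if d.get("resto_threshold") is not None and isinstance(
            d["resto_threshold"], dict
        ):
            d["resto_threshold"] = segmentation.DyeThreshold(**d["resto_threshold"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class SpecimenMeta:
    specimen_id: str
    group: str
    margin: tuple[float, float]
    center: tuple[float, float] | None = None
    delaminated: bool = False


@dataclass
class SpecimenRecord:
    specimen_id: str
    group: str
    status: str
    arc_length_px: float
    penetration_mm: float
    capped: bool
    degree_used: int
    thickness_mean_um: float | None = None
    thickness_sd_um: float | None = None
    thickness_stations_um: list[float] | None = None


def _resto_interface_trace(
    image: np.ndarray, config: StudyConfig
) -> segmentation.MarkerTrace | None:
    """Trace the cement-facing boundary of the restoration region.

    The restoration region is segmented with the configured RGB box; its
    boundary pixels (region pixels with a non-region 4-neighbour, image
    border excluded) are the cement--restoration interface.
    """
    if config.resto_threshold is None:
        return None
    mask = segmentation.classify_dye_pixels(image, config.resto_threshold)
    if not mask.any():
        return None
    interior = np.zeros_like(mask)
    interior[1:-1, 1:-1] = (
        mask[1:-1, 1:-1]
        & mask[:-2, 1:-1]
        & mask[2:, 1:-1]
        & mask[1:-1, :-2]
        & mask[1:-1, 2:]
    )
    boundary = mask & ~interior
    boundary[0, :] = boundary[-1, :] = False
    boundary[:, 0] = boundary[:, -1] = False
    if not boundary.any():
        return None
    rows, cols = np.nonzero(boundary)
    # keep the cement-facing (max-row per column) edge of the region
    edge = np.zeros_like(boundary)
    for c in np.unique(cols):
        edge[rows[cols == c].max(), c] = True
    anchor = (int(np.nonzero(edge[:, edge.any(axis=0).argmax()])[0][0]),
              int(edge.any(axis=0).argmax()))
    return segmentation.extract_interface_markers(edge, anchor, config.bin_width)


def run_specimen(
    image_path: str | Path,
    meta: SpecimenMeta,
    config: StudyConfig | None = None,
    out_dir: str | Path | None = None,
) -> SpecimenRecord:
    """Measure one specimen; write the marker/curve overlay when requested."""
    config = config or StudyConfig()
    t0 = time.perf_counter()

    if meta.delaminated:
        logger.info("%s: delaminated; no measurement attempted", meta.specimen_id)
        return SpecimenRecord(
            meta.specimen_id, meta.group, curvefit.STATUS_DELAMINATED,
            float("nan"), float("nan"), False, 0,
        )

    image = segmentation.load_image(image_path)
    mask = segmentation.classify_dye_pixels(image, config.threshold)
    trace = segmentation.extract_interface_markers(
        mask, meta.margin, config.bin_width
    )
    result = curvefit.measure_penetration(
        trace, config.calibration, die_center=meta.center, degree=config.degree
    )
    if 0 < result.degree_used < config.degree:
        logger.warning(
            "%s: only %d markers; fit degree reduced to %d",
            meta.specimen_id, len(trace), result.degree_used,
        )

    record = SpecimenRecord(
        meta.specimen_id, meta.group, result.status,
        result.arc_length_px, result.penetration_mm, result.capped,
        result.degree_used,
    )

    resto_trace = _resto_interface_trace(image, config)
    if resto_trace is not None and len(resto_trace) >= 2 and len(trace) >= 2:
        die_curve = curvefit.fit_interface_curve(trace, config.degree)
        resto_curve = curvefit.fit_interface_curve(resto_trace, config.degree)
        with warnings.catch_warnings():
            warnings.simplefilter("always")
            th = thickness.measure_cement_thickness(
                die_curve, resto_curve, config.calibration,
                config.n_thickness_stations,
            )
        if th.missing_stations:
            logger.warning(
                "%s: thickness stations %s missing",
                meta.specimen_id, th.missing_stations,
            )
        record.thickness_mean_um = th.mean_um
        record.thickness_sd_um = th.sd_um
        record.thickness_stations_um = th.station_thickness_um
    elif config.resto_threshold is None:
        logger.info(
            "%s: no restoration RGB box configured; thickness skipped",
            meta.specimen_id,
        )

    if out_dir is not None and config.write_overlays and len(trace) >= 2:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        curve = curvefit.fit_interface_curve(trace, config.degree)
        overlay = curvefit.render_overlay(
            segmentation.render_markers(image, trace), curve
        )
        segmentation.save_image(out_dir / f"{meta.specimen_id}_overlay.png", overlay)

    logger.info(
        "%s: %s %.4f mm in %.2f s",
        meta.specimen_id, record.status, record.penetration_mm,
        time.perf_counter() - t0,
    )
    return record


def _meta_from_row(row: pd.Series, base: Path) -> tuple[Path, SpecimenMeta]:
    for col in ("specimen_id", "group", "image_path", "margin_row", "margin_col"):
        if col not in row or pd.isna(row[col]):
            raise ValueError(f"manifest row missing required field {col!r}")
    center = None
    if "center_row" in row and not pd.isna(row.get("center_row")):
        center = (float(row["center_row"]), float(row["center_col"]))
    path = Path(row["image_path"])
    if not path.is_absolute():
        path = base / path
    meta = SpecimenMeta(
        specimen_id=str(row["specimen_id"]),
        group=str(row["group"]),
        margin=(float(row["margin_row"]), float(row["margin_col"])),
        center=center,
        delaminated=bool(int(row.get("delaminated", 0) or 0)),
    )
    return path, meta


def build_group_study(
    records: list[SpecimenRecord], config: StudyConfig
) -> stats.GroupStudy:
    """Aggregate specimen records into a group study under the delamination policy."""
    groups: dict[str, list[float]] = {}
    delam: dict[str, int] = {}
    complete: dict[str, int] = {}
    for r in records:
        groups.setdefault(r.group, [])
        delam.setdefault(r.group, 0)
        complete.setdefault(r.group, 0)
        if r.status == curvefit.STATUS_DELAMINATED:
            delam[r.group] += 1
            if config.delamination_policy == "assign_cap":
                groups[r.group].append(config.calibration.cap_mm)
            continue
        if r.status == curvefit.STATUS_COMPLETE:
            complete[r.group] += 1
        groups[r.group].append(r.penetration_mm)
    return stats.GroupStudy(groups, delam, complete)


def run_study(
    manifest_path: str | Path,
    config: StudyConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run a whole manifest and return (results table, statistics report).

    Writes ``results.csv`` and ``stats.json`` into ``out_dir`` when given.
    """
    config = config or StudyConfig()
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    if manifest["group"].nunique() < 2:
        raise ValueError("need >= 2 groups for statistical testing")

    records = []
    for _, row in manifest.iterrows():
        path, meta = _meta_from_row(row, manifest_path.parent)
        records.append(run_specimen(path, meta, config, out_dir))

    table = pd.DataFrame([asdict(r) for r in records])
    study = build_group_study(records, config)

    measurable = {g: v for g, v in study.groups.items() if len(v) >= 3}
    report: dict = {"config": config.to_dict()}
    summary = stats.summarize(
        stats.GroupStudy(
            {g: v for g, v in study.groups.items() if v},
            study.delaminated_counts,
            study.complete_penetration_counts,
        )
    )
    report["groups"] = summary
    if len(measurable) >= 2:
        sub = stats.GroupStudy(measurable)
        shapiro_p, flag = stats.shapiro_gate(sub, config.alpha)
        h, p = stats.kruskal_wallis(sub)
        pairwise = stats.dunn_bonferroni(sub)
        report["shapiro_p"] = shapiro_p
        report["nonparametric"] = flag
        report["kruskal_wallis"] = {"H": h, "p": p}
        report["pairwise_adjusted_p"] = {
            f"{a} vs {b}": v for (a, b), v in pairwise.items()
        }
    else:
        logger.warning("fewer than 2 groups with n >= 3; tests skipped")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "results.csv", index=False)
        (out_dir / "stats.json").write_text(json.dumps(report, indent=1))
    return table, report


def simulate_study(
    out_dir: str | Path,
    n_per_group: int = 5,
    group_means_mm: dict[str, float] | None = None,
    group_sds_mm: dict[str, float] | None = None,
    mm_per_pixel: float = 0.02,
    image_size: tuple[int, int] = (220, 560),
    noise_sd: float = 4.0,
    seed: int = 0,
) -> Path:
    """Write a synthetic study (images + sidecars + manifest + config).

    The calibration is scaled up (default 0.02 mm/pixel) so that the
    7.18 mm complete-penetration distance fits inside a small image: the
    die centre sits at 7.18 / mm_per_pixel = 359 px of interface arc.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    group_means_mm = group_means_mm or {"printed": 2.2, "milled": 4.7, "molded": 6.8}
    group_sds_mm = group_sds_mm or {g: 1.0 for g in group_means_mm}
    cap_mm = 7.18

    config = StudyConfig(
        calibration=curvefit.CalibrationSpec(mm_per_pixel=mm_per_pixel, cap_mm=cap_mm),
        resto_threshold=segmentation.DyeThreshold(255, 255, 205, 215),
        seed=seed,
    )
    cap_px = cap_mm / mm_per_pixel
    rng = np.random.default_rng(seed)
    rows = []
    for label, mean in group_means_mm.items():
        sd = group_sds_mm[label]
        for i in range(n_per_group):
            name = f"{label}_{i:03d}"
            extent_mm = float(np.clip(rng.normal(mean, sd), 0.05, cap_mm))
            spec = synthetic.SceneSpec(
                image_size=image_size,
                die_curve_coeffs=(120.0, -0.02, 5.0e-5),
                cement_gap_um=(1800.0, 2200.0),
                dye_extent_px=extent_mm / mm_per_pixel,
                texture="stepped" if label == "printed" else "smooth",
                noise_sd=noise_sd,
                mm_per_pixel=mm_per_pixel,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            image, truth = synthetic.generate_cross_section(spec)
            synthetic.write_fixture(out_dir, name, image, truth)
            center = _point_at_arc(spec, cap_px, image_size)
            rows.append(
                {
                    "specimen_id": name,
                    "group": label,
                    "image_path": f"{name}.png",
                    "margin_row": truth.margin_anchor[0],
                    "margin_col": truth.margin_anchor[1],
                    "center_row": center[0],
                    "center_col": center[1],
                    "delaminated": 0,
                }
            )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    config.to_yaml(out_dir / "config.yaml")
    return manifest


def _point_at_arc(
    spec: synthetic.SceneSpec, arc_px: float, image_size: tuple[int, int]
) -> tuple[float, float]:
    """Die-centre landmark at a given interface arc length (may lie off-image)."""
    coeffs = np.asarray(spec.die_curve_coeffs, float)
    w = image_size[1]
    total = synthetic.polynomial_arc_length(coeffs, 0.0, float(w - 1))
    if arc_px >= total:
        # extrapolate along the end tangent
        der = np.polynomial.polynomial.polyder(coeffs)
        m = float(np.polynomial.polynomial.polyval(w - 1.0, der))
        extra = (arc_px - total) / np.hypot(1.0, m)
        x = w - 1.0 + extra
    else:
        x = synthetic._invert_arc_length(coeffs, arc_px, float(w - 1))
    y = float(np.polynomial.polynomial.polyval(x, coeffs))
    return (y, x)
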
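"""Camera-subset validation study: model and results objects.

:class:`ValidationStudy` is built from data (a calibrated rig, a 2D
detection set, and the rigid-object geometry); :meth:`ValidationStudy.fit`
runs the whole analysis — triangulation per camera subset, inter-keypoint
error, deviation from the full-rig reference, boxplot summaries,
bias/variance, the error-vs-image-centre correlation and the configuration
ANOVA — and returns a :class:`ValidationResults` carrying every statistic
with a ``summary()`` table, JSON export and a boxplot figure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import evaluate as ev
from .cameras import RigCalibration, triangulate_series
from .detections import DetectionSet, Pose3DSeries
from .testobject import TestObjectSpec

__all__ = ["ValidationStudy", "ValidationResults", "run_validation"]


class ValidationStudy:
    """Validation of a multi-camera rig against a rigid object of known geometry.

    Parameters
    ----------
    rig
        Calibrated cameras sharing one world frame (mm).
    detections
        2D keypoint observations per (frame, camera, keypoint).
    object_spec
        Rigid-object geometry supplying ground-truth pair distances; pass
        ``None`` to run a reference-deviation-only study (no rigid truth,
        as with live animals).
    bottom_id
        Camera id of the below-floor camera; defaults to the last camera.
    reference_subset
        Camera ids of the reference configuration (default: all cameras).
    """

    def __init__(
        self,
        rig: RigCalibration,
        detections: DetectionSet,
        object_spec: TestObjectSpec | None = None,
        *,
        bottom_id: str | None = None,
        reference_subset: list[str] | None = None,
        min_views: int = 2,
        confidence_threshold: float = 0.5,
        min_config_size: int = 2,
        vector_pairs: list | None = None,
        border_threshold: float = ev.DEFAULT_BORDER_THRESHOLD,
        view_aggregation: str = "mean",
        refine: bool = True,
    ):
        self.rig = rig
        self.detections = detections
        self.object_spec = object_spec
        self.bottom_id = bottom_id if bottom_id is not None else rig.camera_ids[-1]
        if self.bottom_id not in rig.camera_ids:
            raise ev.ConfigurationError(f"unknown bottom camera: {self.bottom_id!r}")
        self.reference_subset = reference_subset or rig.camera_ids
        self.min_views = min_views
        self.confidence_threshold = confidence_threshold
        self.min_config_size = min_config_size
        self.vector_pairs = vector_pairs
        self.border_threshold = border_threshold
        self.view_aggregation = view_aggregation
        self.refine = refine

    def fit(self) -> "ValidationResults":
        configs = ev.enumerate_configs(self.rig, self.bottom_id, self.min_config_size)
        series: dict[str, Pose3DSeries] = {}
        for cfg in configs:
            series[cfg.config_id] = triangulate_series(
                self.rig,
                self.detections,
                subset=list(cfg.member_ids),
                min_views=self.min_views,
                confidence_threshold=self.confidence_threshold,
                refine=self.refine,
            )
        ref_id = "+".join(sorted(self.reference_subset))
        if ref_id not in series:
            series[ref_id] = triangulate_series(
                self.rig, self.detections, subset=list(self.reference_subset),
                min_views=self.min_views,
                confidence_threshold=self.confidence_threshold, refine=self.refine,
            )
        reference = series[ref_id]

        ik_parts, dev_parts, angle_parts = [], [], []
        coverage: dict[str, list[float]] = {}
        for cfg in configs:
            s = series[cfg.config_id]
            coverage.setdefault(cfg.symmetry_class, []).append(s.coverage_fraction())
            if self.object_spec is not None:
                ik_parts.append(
                    ev.interkeypoint_error(
                        s, self.object_spec, cfg.symmetry_class, cfg.config_id
                    )
                )
                if self.vector_pairs:
                    ang = ev.angle_error(s, self.object_spec, self.vector_pairs)
                    ang.table["symmetry_class"] = cfg.symmetry_class
                    ang.table["config_id"] = cfg.config_id
                    angle_parts.append(ang)
            dev_parts.append(
                ev.deviation_from_reference(
                    s, reference, cfg.symmetry_class, cfg.config_id
                )
            )

        interkeypoint = ev.ErrorTable.concat(ik_parts) if ik_parts else None
        deviation = ev.ErrorTable.concat(dev_parts) if dev_parts else None
        angles = ev.ErrorTable.concat(angle_parts) if angle_parts else None

        class_stats: dict[str, dict] = {}
        for cfg_class in dict.fromkeys(c.symmetry_class for c in configs):
            entry: dict = {"coverage": float(np.mean(coverage[cfg_class]))}
            if interkeypoint is not None:
                sub = interkeypoint.table[
                    interkeypoint.table["symmetry_class"] == cfg_class
                ]
                entry["n_interkeypoint"] = len(sub)
                entry["boxplot"] = (
                    ev.boxplot_stats(sub["abs_error"]) if len(sub) else None
                )
            sub_dev = deviation.table[deviation.table["symmetry_class"] == cfg_class]
            entry["n_deviation"] = len(sub_dev)
            entry["deviation_boxplot"] = (
                ev.boxplot_stats(sub_dev["abs_error"]) if len(sub_dev) else None
            )
            class_stats[cfg_class] = entry

        bv = None
        if interkeypoint is not None:
            full = interkeypoint.table[
                interkeypoint.table["config_id"] == ref_id
            ]
            if len(full):
                bv = ev.bias_variance(ev.ErrorTable(full.copy()))

        spearman = None
        if interkeypoint is not None:
            full_errors = interkeypoint.table[interkeypoint.table["config_id"] == ref_id]
            if len(full_errors) >= 3:
                try:
                    spearman = ev.error_vs_image_center(
                        ev.ErrorTable(full_errors.copy()),
                        self.detections,
                        self.rig,
                        border_threshold=self.border_threshold,
                        view_aggregation=self.view_aggregation,
                    )
                except ev.InsufficientDataError:
                    spearman = None

        # ANOVA on deviation from the reference, over the proper subsets only
        # (the reference compared with itself is identically zero)
        anova = None
        proper = deviation.table[deviation.table["config_id"] != ref_id]
        if len(proper):
            try:
                anova = ev.config_anova(ev.ErrorTable(proper.copy()))
            except (ev.InsufficientDataError, ev.EmptyResultError):
                anova = None

        return ValidationResults(
            study=self,
            configs=configs,
            series=series,
            reference_id=ref_id,
            interkeypoint=interkeypoint,
            deviation=deviation,
            angles=angles,
            class_stats=class_stats,
            bias_variance=bv,
            spearman=spearman,
            anova=anova,
        )


@dataclass
class ValidationResults:
    """Fitted validation statistics; see :class:`ValidationStudy`."""

    study: ValidationStudy
    configs: list[ev.CameraConfig]
    series: dict[str, Pose3DSeries]
    reference_id: str
    interkeypoint: ev.ErrorTable | None
    deviation: ev.ErrorTable | None
    angles: ev.ErrorTable | None
    class_stats: dict[str, dict]
    bias_variance: list[ev.BiasVariance] | None
    spearman: ev.CorrelationResult | None
    anova: ev.AnovaResult | None

    def median_abs_error(self, symmetry_class: str | None = None,
                         metric: str = "interkeypoint") -> float:
        """Median absolute error (mm) for one symmetry class or pooled."""
        tab = {"interkeypoint": self.interkeypoint,
               "reference_deviation": self.deviation}[metric]
        if tab is None:
            raise ValueError(f"no {metric} errors in these results")
        t = tab.table
        if symmetry_class is not None:
            t = t[t["symmetry_class"] == symmetry_class]
        if t.empty:
            raise ValueError(f"no records for class {symmetry_class!r}")
        return float(t["abs_error"].median())

    def summary(self) -> str:
        lines = ["Camera-subset validation", "=" * 60]
        lines.append(f"reference configuration: {self.reference_id}")
        header = (
            f"{'class':>8} {'n_err':>7} {'median':>9} {'Q1':>9} {'Q3':>9} "
            f"{'dev med':>9} {'coverage':>9}"
        )
        lines.append(header)
        lines.append("-" * len(header))
        for label, st in self.class_stats.items():
            bp = st.get("boxplot")
            dbp = st.get("deviation_boxplot")
            med = f"{bp.median:9.4f}" if bp else f"{'--':>9}"
            q1 = f"{bp.Q1:9.4f}" if bp else f"{'--':>9}"
            q3 = f"{bp.Q3:9.4f}" if bp else f"{'--':>9}"
            dmed = f"{dbp.median:9.4f}" if dbp else f"{'--':>9}"
            lines.append(
                f"{label:>8} {st.get('n_interkeypoint', 0):>7d} {med} {q1} {q3} "
                f"{dmed} {st['coverage']:9.3f}"
            )
        if self.bias_variance:
            lines.append("")
            lines.append("bias/variance per pair (reference configuration):")
            for bv in self.bias_variance:
                var = f"{bv.variance:.4f}" if bv.variance_defined else "undefined"
                lines.append(
                    f"  {bv.pair:>16}: bias {bv.bias:+.4f} mm, variance {var} mm^2"
                    f" (n={bv.n})"
                )
        if self.spearman:
            s = self.spearman
            lines.append("")
            lines.append(
                f"error vs image centre: Spearman rho={s.rho:.3f}, p={s.p_value:.3g}, "
                f"n={s.n}; {s.n_flagged_beyond_border} beyond {s.border_threshold:.0f} px"
            )
        if self.anova:
            a = self.anova
            lines.append("")
            lines.append(
                "two-way ANOVA on deviation (camera count x bottom presence"
                + (", main effects only" if a.main_effects_only else "")
                + "):"
            )
            lines.append(
                f"  camera number: F={a.F_camera_number:.3f}, p={a.p_camera_number:.3g}"
            )
            lines.append(
                f"  configuration: F={a.F_configuration:.3f}, p={a.p_configuration:.3g}"
            )
            if np.isfinite(a.F_interaction):
                lines.append(
                    f"  interaction:   F={a.F_interaction:.3f}, p={a.p_interaction:.3g}"
                )
        return "\n".join(lines)

    def to_report(self) -> dict:
        """Machine-readable report (JSON-safe)."""
        classes = {}
        for label, st in self.class_stats.items():
            entry = {"coverage": st["coverage"],
                     "n_interkeypoint": int(st.get("n_interkeypoint", 0)),
                     "n_deviation": int(st["n_deviation"])}
            for key in ("boxplot", "deviation_boxplot"):
                bp = st.get(key)
                entry[key] = bp.to_dict() if bp else None
            classes[label] = entry
        report = {
            "reference": self.reference_id,
            "classes": classes,
            "bias_variance": [
                {
                    "pair": bv.pair,
                    "bias_mm": bv.bias,
                    "variance_mm2": bv.variance if bv.variance_defined else None,
                    "n": bv.n,
                }
                for bv in (self.bias_variance or [])
            ],
            "spearman": (
                {
                    "rho": self.spearman.rho,
                    "p_value": self.spearman.p_value,
                    "n": self.spearman.n,
                    "border_threshold_px": self.spearman.border_threshold,
                    "n_flagged_beyond_border": self.spearman.n_flagged_beyond_border,
                }
                if self.spearman
                else None
            ),
            "anova": (
                {
                    "F_camera_number": self.anova.F_camera_number,
                    "F_configuration": self.anova.F_configuration,
                    "F_interaction": _nan_to_none(self.anova.F_interaction),
                    "p_camera_number": self.anova.p_camera_number,
                    "p_configuration": self.anova.p_configuration,
                    "p_interaction": _nan_to_none(self.anova.p_interaction),
                    "main_effects_only": self.anova.main_effects_only,
                    "tukey": self.anova.tukey_table.to_dict(orient="records"),
                }
                if self.anova
                else None
            ),
        }
        return report

    def save_report(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_report(), indent=2, default=float) + "\n")

    def plot_boxplots(self, metric: str = "interkeypoint", ax=None):
        """Boxplot of absolute error per symmetry class (outliers hidden),
        mirroring the whisker definition used by :func:`rigval.evaluate.boxplot_stats`."""
        import matplotlib

        if ax is None:
            matplotlib.use("Agg", force=False)
            import matplotlib.pyplot as plt

            _, ax = plt.subplots(figsize=(7, 4))
        tab = {"interkeypoint": self.interkeypoint,
               "reference_deviation": self.deviation}[metric]
        if tab is None:
            raise ValueError(f"no {metric} errors in these results")
        labels, data = [], []
        for label in self.class_stats:
            vals = tab.table.loc[tab.table["symmetry_class"] == label, "abs_error"]
            if len(vals):
                labels.append(label)
                data.append(vals.to_numpy())
        ax.boxplot(data, tick_labels=labels, whis=1.5, showfliers=False)
        ax.set_xlabel("camera configuration (symmetry class)")
        ax.set_ylabel("absolute error (mm)")
        ax.set_title(f"{metric} error by camera configuration")
        return ax


def _nan_to_none(x: float):
    return None if not np.isfinite(x) else float(x)


def run_validation(
    rig: RigCalibration,
    detections: DetectionSet,
    spec: TestObjectSpec | None = None,
    **options,
) -> ValidationResults:
    """Functional wrapper: build a :class:`ValidationStudy` and fit it."""
    return ValidationStudy(rig, detections, spec, **options).fit()
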
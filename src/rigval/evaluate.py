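"""Validation statistics for multi-camera 3D reconstruction.

Accuracy on a rigid object of known geometry is judged by proxies that need
no external ground truth alignment:

* inter-keypoint distance error — the reconstructed distance between two
  keypoints minus its known object-frame value (signed, mm);
* deviation from reference — the Euclidean gap between a camera-subset
  reconstruction and the full-rig reconstruction of the same keypoint, used
  when no rigid ground truth exists (live animals);
* angle error — the discrepancy between reconstructed and true angles of
  vector pairs on the rigid body.

Camera subsets are grouped into symmetry classes "(n side cameras, bottom
present)" because equally spaced side cameras are geometrically
interchangeable. Summary machinery: whisker boxplot statistics
(Q0 = Q1 - 1.5 IQR, Q4 = Q3 + 1.5 IQR, clipped to the data), bias/variance
per pair, Spearman correlation of error against distance from the image
centre, and a two-way ANOVA (camera count x bottom-camera presence) with
Tukey HSD post-hoc contrasts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cameras import ConfigurationError, RigCalibration
from .detections import DetectionSet, Pose3DSeries
from .testobject import TestObjectSpec

__all__ = [
    "AnovaResult",
    "BiasVariance",
    "BoxplotStats",
    "CameraConfig",
    "CorrelationResult",
    "EmptyResultError",
    "ErrorTable",
    "InsufficientDataError",
    "angle_error",
    "bias_variance",
    "boxplot_stats",
    "config_anova",
    "deviation_from_reference",
    "enumerate_configs",
    "error_vs_image_center",
    "interkeypoint_error",
    "parse_symmetry_class",
]

ERROR_COLUMNS = [
    "frame",
    "label",
    "symmetry_class",
    "config_id",
    "signed_error",
    "abs_error",
    "metric_kind",
]

#: pixel radius beyond which the field of view is flagged as unreliable
DEFAULT_BORDER_THRESHOLD = 486.0


class EmptyResultError(ValueError):
    """The inputs share no usable frames/keypoints."""


class InsufficientDataError(ValueError):
    """Too few usable observations for the requested statistic."""


# ---------------------------------------------------------------------------
# camera configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CameraConfig:
    """One camera subset, labelled by its symmetry class."""

    member_ids: tuple[str, ...]
    includes_bottom: bool
    symmetry_class: str

    @property
    def n_cameras(self) -> int:
        return len(self.member_ids)

    @property
    def config_id(self) -> str:
        return "+".join(self.member_ids)


def _class_label(n_side: int, includes_bottom: bool) -> str:
    return f"{n_side}s+b" if includes_bottom else f"{n_side}s"


def parse_symmetry_class(label: str) -> tuple[int, bool]:
    """Inverse of the class label: returns (n_side_cameras, includes_bottom)."""
    if label.endswith("s+b"):
        return int(label[:-3]), True
    if label.endswith("s"):
        return int(label[:-1]), False
    raise ValueError(f"not a symmetry-class label: {label!r}")


def enumerate_configs(
    rig: RigCalibration,
    bottom_id: str,
    min_size: int = 2,
) -> list[CameraConfig]:
    """All camera subsets of size >= ``min_size``, each tagged with its
    symmetry class ``(n_side)s[+b]``. Deterministic order: by size, then by
    member ids."""
    ids = rig.camera_ids
    if bottom_id not in ids:
        raise ConfigurationError(f"unknown bottom camera id: {bottom_id!r}")
    configs = []
    for size in range(min_size, len(ids) + 1):
        for combo in itertools.combinations(sorted(ids), size):
            has_bottom = bottom_id in combo
            n_side = size - int(has_bottom)
            configs.append(
                CameraConfig(tuple(combo), has_bottom, _class_label(n_side, has_bottom))
            )
    return configs


# ---------------------------------------------------------------------------
# error tables
# ---------------------------------------------------------------------------

@dataclass
class ErrorTable:
    """Long-form error records; ``label`` is ``"a|b"`` for pair metrics and a
    keypoint name for per-keypoint metrics."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = set(ERROR_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"ErrorTable lacks columns: {sorted(missing)}")
        self.table = self.table[ERROR_COLUMNS].reset_index(drop=True)
        with_sign = self.table["signed_error"].notna()
        if not np.allclose(
            self.table.loc[with_sign, "abs_error"],
            self.table.loc[with_sign, "signed_error"].abs(),
        ):
            raise ValueError("abs_error must equal |signed_error| where both defined")
        if (self.table["abs_error"].dropna() < 0).any():
            raise ValueError("abs_error must be non-negative")

    @classmethod
    def concat(cls, parts: list["ErrorTable"]) -> "ErrorTable":
        return cls(pd.concat([p.table for p in parts], ignore_index=True))

    def __len__(self) -> int:
        return len(self.table)


def _pair_label(a: str, b: str) -> str:
    return f"{a}|{b}"


def interkeypoint_error(
    series: Pose3DSeries,
    spec: TestObjectSpec,
    symmetry_class: str = "",
    config_id: str = "",
) -> ErrorTable:
    """Signed inter-keypoint distance error per frame and configured pair.

    ``signed_error = d_reconstructed - d_ground_truth`` (mm). Frames where
    either endpoint lacks a valid 3D estimate are excluded.
    """
    valid = series.valid_table()
    shared = set(valid["keypoint"]) & set(spec.keypoint_names)
    if not shared:
        raise EmptyResultError("series and object spec share no keypoints")
    coords = valid.set_index(["frame", "keypoint"])[["x", "y", "z"]]
    rows = []
    for a, b in spec.pairs:
        if a not in shared or b not in shared:
            continue
        pa = coords.xs(a, level="keypoint")
        pb = coords.xs(b, level="keypoint")
        joined = pa.join(pb, lsuffix="_a", rsuffix="_b", how="inner")
        if joined.empty:
            continue
        d_obs = np.linalg.norm(
            joined[["x_a", "y_a", "z_a"]].to_numpy()
            - joined[["x_b", "y_b", "z_b"]].to_numpy(),
            axis=1,
        )
        signed = d_obs - spec.pair_distance(a, b)
        for f, s in zip(joined.index, signed):
            rows.append((f, _pair_label(a, b), symmetry_class, config_id,
                         s, abs(s), "interkeypoint"))
    return ErrorTable(pd.DataFrame(rows, columns=ERROR_COLUMNS))


def deviation_from_reference(
    series: Pose3DSeries,
    reference: Pose3DSeries,
    symmetry_class: str = "",
    config_id: str = "",
) -> ErrorTable:
    """Unsigned Euclidean gap (mm) between two reconstructions of the same
    keypoints, per frame/keypoint valid in both. The reference is typically
    the full-rig reconstruction standing in for ground truth."""
    a = series.valid_table().set_index(["frame", "keypoint"])[["x", "y", "z"]]
    b = reference.valid_table().set_index(["frame", "keypoint"])[["x", "y", "z"]]
    if not (set(series.table["keypoint"]) & set(reference.table["keypoint"])):
        raise EmptyResultError("series and reference share no keypoints")
    joined = a.join(b, lsuffix="_s", rsuffix="_r", how="inner")
    dist = np.linalg.norm(
        joined[["x_s", "y_s", "z_s"]].to_numpy() - joined[["x_r", "y_r", "z_r"]].to_numpy(),
        axis=1,
    )
    rows = [
        (f, kp, symmetry_class, config_id, np.nan, d, "reference_deviation")
        for (f, kp), d in zip(joined.index, dist)
    ]
    return ErrorTable(pd.DataFrame(rows, columns=ERROR_COLUMNS))


def angle_error(
    series: Pose3DSeries,
    spec: TestObjectSpec,
    vector_pairs: list[tuple[tuple[str, str], tuple[str, str]]],
) -> ErrorTable:
    """Absolute angular discrepancy (degrees) between reconstructed and true
    angles of configured vector pairs on the rigid body.

    Each vector pair is ``((a1, a2), (b1, b2))``: the angle between vectors
    a2-a1 and b2-b1. Frames with any invalid endpoint, or a degenerate
    (zero-length) reconstructed vector, are excluded."""
    valid = series.valid_table().set_index(["frame", "keypoint"])[["x", "y", "z"]]
    rows = []
    for (a1, a2), (b1, b2) in vector_pairs:
        for name in (a1, a2, b1, b2):
            if name not in spec.keypoints:
                raise ValueError(f"unknown keypoint {name!r} in vector pair")
        va_t = spec.keypoints[a2] - spec.keypoints[a1]
        vb_t = spec.keypoints[b2] - spec.keypoints[b1]
        angle_true = _angle_deg(va_t, vb_t)
        label = f"{a1}>{a2}^{b1}>{b2}"
        frames = valid.index.get_level_values("frame").unique()
        for f in frames:
            try:
                p = {k: valid.loc[(f, k)].to_numpy() for k in (a1, a2, b1, b2)}
            except KeyError:
                continue
            va, vb = p[a2] - p[a1], p[b2] - p[b1]
            if np.linalg.norm(va) < 1e-12 or np.linalg.norm(vb) < 1e-12:
                continue
            err = abs(_angle_deg(va, vb) - angle_true)
            rows.append((f, label, "", "", np.nan, err, "angle"))
    return ErrorTable(pd.DataFrame(rows, columns=ERROR_COLUMNS))


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class BoxplotStats:
    """Whisker-boxplot summary: quartiles by linear interpolation, whiskers
    Q1 - 1.5 IQR / Q3 + 1.5 IQR clipped to the most extreme data point inside
    the fences; points beyond the fences are counted as outliers."""

    Q0: float
    Q1: float
    median: float
    Q3: float
    Q4: float
    IQR: float
    n: int
    n_outliers: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("Q0", "Q1", "median", "Q3", "Q4", "IQR", "n", "n_outliers")}


def boxplot_stats(values) -> BoxplotStats:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise InsufficientDataError("boxplot_stats needs at least one finite value")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    q0 = float(inside.min()) if inside.size else float(v.min())
    q4 = float(inside.max()) if inside.size else float(v.max())
    n_out = int(np.sum((v < lo_fence) | (v > hi_fence)))
    return BoxplotStats(q0, float(q1), float(med), float(q3), q4, float(iqr),
                        int(v.size), n_out)


@dataclass
class BiasVariance:
    """Per-pair decomposition of the inter-keypoint error: ``bias`` is the
    mean signed error (mm); ``variance`` the sample variance (mm^2, n-1
    denominator) of the repeated distance measurements across frames."""

    pair: str
    bias: float
    variance: float
    n: int
    variance_defined: bool


def bias_variance(errors: ErrorTable) -> list[BiasVariance]:
    tab = errors.table
    tab = tab[tab["metric_kind"] == "interkeypoint"]
    if tab.empty:
        raise EmptyResultError("no inter-keypoint records")
    out = []
    for label, grp in tab.groupby("label", sort=True):
        s = grp["signed_error"].to_numpy()
        bias = float(np.mean(s))
        if len(s) >= 2:
            # var of observed distances == var of signed errors (truth constant)
            out.append(BiasVariance(label, bias, float(np.var(s, ddof=1)), len(s), True))
        else:
            out.append(BiasVariance(label, bias, float("nan"), len(s), False))
    return out


# ---------------------------------------------------------------------------
# error vs. image centre
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """Spearman rank correlation of error against pixel distance from the
    image centre, with a count of observations beyond the border threshold."""

    rho: float
    p_value: float
    n: int
    border_threshold: float
    n_flagged_beyond_border: int


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rho with tie-averaged ranks; p-value from the large-sample
    normal approximation ``z = rho * sqrt(n - 1)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = float(np.sqrt((rx @ rx) * (ry @ ry)))
    if denom == 0:
        return float("nan"), float("nan")
    rho = float(rx @ ry / denom)
    n = len(x)
    z = rho * np.sqrt(max(n - 1, 1))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return rho, p


def error_vs_image_center(
    errors: ErrorTable,
    detections: DetectionSet,
    rig: RigCalibration,
    border_threshold: float = DEFAULT_BORDER_THRESHOLD,
    view_aggregation: str = "mean",
) -> CorrelationResult:
    """Correlate per-frame pair errors with distance from the image centre.

    For each inter-keypoint error record, the covariate is the pixel distance
    of the pair's midpoint observation from the principal point, aggregated
    over every camera that saw both endpoints in that frame (``"mean"``,
    default, or ``"worst"`` for the single most peripheral view). Spearman
    rho uses tie-averaged ranks; observations whose covariate exceeds
    ``border_threshold`` px are counted as beyond the reliable field.
    """
    if view_aggregation not in ("mean", "worst"):
        raise ValueError("view_aggregation must be 'mean' or 'worst'")
    err = errors.table[errors.table["metric_kind"] == "interkeypoint"].copy()
    if err.empty:
        raise InsufficientDataError("no inter-keypoint error records")
    err = err.reset_index(drop=True)
    err["eid"] = err.index
    kp = err["label"].str.split("|", expand=True)
    err["kp_a"], err["kp_b"] = kp[0], kp[1]

    det = detections.present()[["frame", "camera_id", "keypoint", "u", "v"]]
    pp = {c.camera_id: c.intrinsics.principal_point for c in rig.cameras}

    da = err[["eid", "frame", "kp_a"]].merge(
        det, left_on=["frame", "kp_a"], right_on=["frame", "keypoint"]
    )
    db = err[["eid", "frame", "kp_b"]].merge(
        det, left_on=["frame", "kp_b"], right_on=["frame", "keypoint"]
    )
    both = da.merge(db, on=["eid", "frame", "camera_id"], suffixes=("_a", "_b"))
    if both.empty:
        raise InsufficientDataError("errors and detections share no frames")
    mid_u = (both["u_a"] + both["u_b"]) / 2.0
    mid_v = (both["v_a"] + both["v_b"]) / 2.0
    pp_arr = np.array([pp[c] for c in both["camera_id"]])
    both["center_dist"] = np.hypot(mid_u - pp_arr[:, 0], mid_v - pp_arr[:, 1])

    agg = "mean" if view_aggregation == "mean" else "max"
    cov = both.groupby("eid")["center_dist"].agg(agg)
    matched = err.set_index("eid").loc[cov.index]
    if len(cov) < 3:
        raise InsufficientDataError("need at least 3 matched observations")
    rho, p = spearman_rho(cov.to_numpy(), matched["abs_error"].to_numpy())
    n_flagged = int((cov > border_threshold).sum())
    return CorrelationResult(rho, p, len(cov), border_threshold, n_flagged)


# ---------------------------------------------------------------------------
# two-way ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Two-way ANOVA of absolute error on camera count x bottom-camera
    presence (type-II sums of squares), plus Tukey HSD contrasts between
    symmetry classes. ``main_effects_only`` flags the fallback used when the
    factorial design has empty cells."""

    F_camera_number: float
    F_configuration: float
    F_interaction: float
    p_camera_number: float
    p_configuration: float
    p_interaction: float
    tukey_table: pd.DataFrame
    main_effects_only: bool = False


def config_anova(errors: ErrorTable) -> AnovaResult:
    """Two-way type-II ANOVA of ``abs_error`` on (camera count, bottom
    presence), with Tukey HSD comparisons across symmetry classes.

    Factor levels are derived from each record's symmetry class. If the
    camera-count x bottom-presence crossing has empty cells the interaction
    is not estimable and a main-effects model is fitted instead (flagged)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tab = errors.table.dropna(subset=["abs_error"]).copy()
    if tab.empty:
        raise EmptyResultError("no error records")
    parsed = tab["symmetry_class"].map(parse_symmetry_class)
    tab["n_cameras"] = [n + int(b) for n, b in parsed]
    tab["bottom"] = ["with_bottom" if b else "no_bottom" for _, b in parsed]
    if tab["n_cameras"].nunique() < 2 or tab["bottom"].nunique() < 2:
        raise InsufficientDataError("both factors need at least 2 levels")

    cells = tab.groupby(["n_cameras", "bottom"]).size().unstack()
    has_empty = cells.isna().any().any()
    formula = (
        "abs_error ~ C(n_cameras) + C(bottom)"
        if has_empty
        else "abs_error ~ C(n_cameras) * C(bottom)"
    )
    if has_empty:
        warnings.warn(
            "empty cells in camera-count x bottom design; "
            "fitting main effects only",
            stacklevel=2,
        )
    model = ols(formula, data=tab).fit()
    table = sm.stats.anova_lm(model, typ=2)
    f_cam = float(table.loc["C(n_cameras)", "F"])
    p_cam = float(table.loc["C(n_cameras)", "PR(>F)"])
    f_cfg = float(table.loc["C(bottom)", "F"])
    p_cfg = float(table.loc["C(bottom)", "PR(>F)"])
    if has_empty:
        f_int = p_int = float("nan")
    else:
        f_int = float(table.loc["C(n_cameras):C(bottom)", "F"])
        p_int = float(table.loc["C(n_cameras):C(bottom)", "PR(>F)"])

    tk = pairwise_tukeyhsd(tab["abs_error"].to_numpy(), tab["symmetry_class"].to_numpy())
    pairs = list(itertools.combinations(tk.groupsunique, 2))
    tukey = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "mean_difference_mm": tk.meandiffs,
            "adjusted_p": tk.pvalues,
        }
    )
    return AnovaResult(f_cam, f_cfg, f_int, p_cam, p_cfg, p_int, tukey, has_empty)
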
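"""Quality control, transformation and imputation of the biomarker matrix.

The pipeline order is fixed: marker-level QC -> below-LOD substitution
(LOD / sqrt(2)) -> per-marker natural log where the Fisher-Pearson skewness
exceeds 1 -> z-scoring over the pooled case+control sample -> winsorisation at
+/-4 SD -> K-nearest-neighbour imputation (k = 7) of missing cells (including
duplicate measurements whose CV exceeded 20%). Covariate residualisation, the
final step before clustering, fits sex/BMI effects on controls only and
removes them from everyone.

Conventions fixed here so results are exactly testable: skewness is the
unadjusted moment ratio g1 = m3 / m2^(3/2); z-scores use the sample (n-1) SD;
the CV of a duplicate pair is the pair's sample SD over its mean; KNN
distances are Euclidean over mutually observed markers, rescaled by the
number of shared dimensions, with ties at the k-th neighbour broken by
subject order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MarkerPanel
from .synthetic import CohortTable

__all__ = [
    "QCConfig",
    "PreprocessedMatrix",
    "qc_filter_markers",
    "substitute_below_lod",
    "fisher_pearson_skewness",
    "conditional_log_transform",
    "zscore_winsorise",
    "knn_impute",
    "residualise_covariates",
    "run_preprocess",
]


@dataclass
class QCConfig:
    """Quality-control and transformation thresholds."""

    min_frac_above_lod: float = 0.80
    max_cv: float = 0.20
    min_frac_cv_ok: float = 0.80
    skew_threshold: float = 1.0
    winsor_sd: float = 4.0
    knn_k: int = 7

    def __post_init__(self) -> None:
        for name in ("min_frac_above_lod", "max_cv", "min_frac_cv_ok"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.winsor_sd <= 0:
            raise ValueError("winsor_sd must be positive")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


@dataclass
class PreprocessedMatrix:
    """Standardised, fully imputed subjects x markers matrix with provenance.

    ``cell_flags`` holds per-cell provenance in
    {"observed", "below_lod_substituted", "imputed"}.
    """

    values: pd.DataFrame
    cell_flags: pd.DataFrame
    marker_log_flags: pd.Series
    excluded_markers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("preprocessed matrix must contain no missing values")
        if not self.values.index.equals(self.cell_flags.index) or not (
            self.values.columns.equals(self.cell_flags.columns)
        ):
            raise ValueError("cell_flags must be aligned with values")

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(outdir / "matrix.tsv", sep="\t")
        self.cell_flags.to_csv(outdir / "provenance.tsv", sep="\t")
        meta = pd.DataFrame(
            {
                "marker": self.values.columns,
                "log_transformed": [
                    bool(self.marker_log_flags[m]) for m in self.values.columns
                ],
            }
        )
        for m, reason in self.excluded_markers.items():
            meta = pd.concat(
                [meta, pd.DataFrame({"marker": [m], "log_transformed": [None],
                                     "excluded": [reason]})],
                ignore_index=True,
            )
        meta.to_csv(outdir / "markers.tsv", sep="\t", index=False)


def _pair_cv(rep1: float, rep2: float) -> float:
    """CV of a duplicate pair: sample SD (n-1 denominator) over mean."""
    pair = np.array([rep1, rep2], dtype=float)
    mean = pair.mean()
    if mean == 0:
        return np.inf
    return pair.std(ddof=1) / abs(mean)


def qc_filter_markers(
    measurements: pd.DataFrame, panel: MarkerPanel, qc: QCConfig
) -> tuple[list[str], dict[str, str]]:
    """Apply marker-level inclusion rules.

    A marker is retained iff the fraction of its measured values above the LOD
    is >= ``min_frac_above_lod`` (inclusive) and, for duplicate-assayed
    markers only, the fraction of values with duplicate CV <= ``max_cv`` is
    >= ``min_frac_cv_ok``.
    """
    included: list[str] = []
    excluded: dict[str, str] = {}
    lod = panel.lod
    dup = panel.duplicate_assayed
    for marker in panel.markers:
        sub = measurements[measurements["marker"] == marker]
        observed = sub[sub["value"].notna()]
        if len(observed) == 0:
            excluded[marker] = "no data"
            continue
        if "below_lod" in observed.columns:
            above = ~observed["below_lod"].astype(bool)
        else:
            above = observed["value"] >= lod[marker]
        frac_above = above.mean()
        if frac_above < qc.min_frac_above_lod:
            excluded[marker] = (
                f"only {frac_above:.1%} of values above LOD "
                f"(requires >= {qc.min_frac_above_lod:.0%})"
            )
            continue
        if dup[marker]:
            pairs = observed[observed["rep1"].notna() & observed["rep2"].notna()]
            if len(pairs) == 0:
                excluded[marker] = "duplicate-assayed marker with no duplicates"
                continue
            cvs = np.array(
                [_pair_cv(r1, r2) for r1, r2 in zip(pairs["rep1"], pairs["rep2"])]
            )
            frac_ok = float((cvs <= qc.max_cv).mean())
            if frac_ok < qc.min_frac_cv_ok:
                excluded[marker] = (
                    f"only {frac_ok:.1%} of duplicate CVs <= {qc.max_cv:.0%} "
                    f"(requires >= {qc.min_frac_cv_ok:.0%})"
                )
                continue
        included.append(marker)
    return included, excluded


def substitute_below_lod(
    values: pd.Series | np.ndarray, lod: float, below_mask=None
) -> tuple[np.ndarray, np.ndarray]:
    """Replace below-LOD (or flagged non-detected) values with LOD / sqrt(2).

    Returns the substituted values and a boolean mask of substituted cells.
    Missing cells are left missing.
    """
    if lod <= 0:
        raise ValueError("lod must be positive")
    arr = np.asarray(values, dtype=float).copy()
    if below_mask is None:
        below_mask = arr < lod
    below_mask = np.asarray(below_mask, dtype=bool) & ~np.isnan(arr)
    detected = ~below_mask & ~np.isnan(arr)
    if np.any(arr[detected] < 0):
        raise ValueError("negative concentrations are not valid")
    arr[below_mask] = lod / np.sqrt(2.0)
    return arr, below_mask


def fisher_pearson_skewness(values) -> float:
    """Unadjusted Fisher-Pearson moment coefficient g1 = m3 / m2^(3/2)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) < 3:
        raise ValueError("skewness needs at least 3 values")
    centred = arr - arr.mean()
    m2 = np.mean(centred**2)
    if m2 == 0:
        raise ValueError("skewness undefined for zero variance")
    m3 = np.mean(centred**3)
    return float(m3 / m2**1.5)


def conditional_log_transform(
    matrix: pd.DataFrame, skew_threshold: float = 1.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Natural-log transform each marker whose skewness strictly exceeds the
    threshold. Markers at exactly the threshold are left untouched."""
    out = matrix.copy()
    flags = pd.Series(False, index=matrix.columns, name="log_transformed")
    for marker in matrix.columns:
        col = matrix[marker]
        g1 = fisher_pearson_skewness(col)
        if g1 > skew_threshold:
            if (col <= 0).any():
                raise ValueError(
                    f"marker {marker!r} has non-positive values; cannot log"
                )
            out[marker] = np.log(col)
            flags[marker] = True
    return out, flags


def zscore_winsorise(matrix: pd.DataFrame, winsor_sd: float = 4.0) -> pd.DataFrame:
    """Standardise each marker over the pooled sample (sample SD, ddof=1),
    then clip to [-winsor_sd, +winsor_sd] without re-standardising."""
    out = matrix.copy()
    for marker in matrix.columns:
        col = matrix[marker]
        sd = col.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"marker {marker!r} is constant; cannot z-score")
        out[marker] = ((col - col.mean()) / sd).clip(-winsor_sd, winsor_sd)
    return out


def knn_impute(matrix: pd.DataFrame, k: int = 7) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute missing cells by the unweighted mean of the k nearest donors.

    Distance between two subjects is the Euclidean distance over their
    mutually observed markers, rescaled by sqrt(p / n_shared) so subjects with
    few shared markers are not spuriously close. Donors for a cell must have
    the target marker observed; ties at the k-th neighbour are broken by row
    order (stable sort).
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all():
        raise ValueError("a subject with no observed markers cannot be imputed")
    mask = pd.DataFrame(~obs, index=matrix.index, columns=matrix.columns)
    if obs.all():
        return matrix.copy(), mask

    # pairwise rescaled Euclidean distances over shared markers
    Xz = np.where(obs, X, 0.0)
    sq = Xz**2
    cross = Xz @ Xz.T
    obs_f = obs.astype(float)
    shared = obs_f @ obs_f.T
    d2 = (sq @ obs_f.T) + (obs_f @ sq.T) - 2 * cross
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(shared > 0, d2 * (p / shared), np.inf)
    d2 = np.maximum(d2, 0.0)

    out = X.copy()
    for i, j in zip(*np.where(~obs)):
        donors = np.where(obs[:, j])[0]
        donors = donors[donors != i]
        finite = donors[np.isfinite(d2[i, donors])]
        if len(finite) < k:
            raise ValueError(
                f"fewer than k={k} donors for subject {matrix.index[i]!r}, "
                f"marker {matrix.columns[j]!r}"
            )
        order = finite[np.argsort(d2[i, finite], kind="stable")]
        out[i, j] = X[order[:k], j].mean()
    return (
        pd.DataFrame(out, index=matrix.index, columns=matrix.columns),
        mask,
    )


def residualise_covariates(
    matrix: pd.DataFrame, covariates: pd.DataFrame, control_mask
) -> pd.DataFrame:
    """Remove covariate effects estimated on controls from all subjects.

    Per marker, an ordinary least-squares model (intercept + covariates) is
    fitted on controls only; the fitted covariate contribution (relative to
    the control covariate means, so overall levels are preserved) is then
    subtracted from every subject.
    """
    control_mask = np.asarray(control_mask, dtype=bool)
    if covariates.isna().any().any():
        raise ValueError("covariates must be complete")
    C = covariates.to_numpy(dtype=float)
    keep = C[control_mask].std(axis=0) > 0
    dropped = [c for c, k in zip(covariates.columns, keep) if not k]
    C = C[:, keep]
    names = [c for c, k in zip(covariates.columns, keep) if k]
    design = np.column_stack([np.ones(control_mask.sum()), C[control_mask]])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify the first covariate whose addition does not raise the rank
        for idx in range(len(names)):
            sub = np.column_stack(
                [np.ones(control_mask.sum()), C[control_mask][:, : idx + 1]]
            )
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                raise ValueError(
                    f"covariate design rank-deficient among controls: "
                    f"{names[idx]!r} is collinear"
                )
        raise ValueError("covariate design rank-deficient among controls")
    Y = matrix.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, Y[control_mask], rcond=None)
    centred = C - C[control_mask].mean(axis=0)
    adjusted = Y - centred @ beta[1:]
    out = pd.DataFrame(adjusted, index=matrix.index, columns=matrix.columns)
    if dropped:
        out.attrs["dropped_covariates"] = dropped
    return out


def run_preprocess(
    cohort: CohortTable, qc: QCConfig | None = None
) -> PreprocessedMatrix:
    """Full preprocessing of a cohort's measurement table.

    Duplicate measurements with CV above ``qc.max_cv`` are blanked and later
    imputed, alongside cells missing at source.
    """
    qc = qc or QCConfig()
    included, excluded = qc_filter_markers(cohort.measurements, cohort.panel, qc)
    if not included:
        raise ValueError("no markers passed quality control")

    meas = cohort.measurements
    subjects = list(cohort.participants["subject_id"])
    wide = cohort.values_wide()[included]
    flags = pd.DataFrame("observed", index=wide.index, columns=wide.columns)
    flags[wide.isna()] = "imputed"

    lod = cohort.panel.lod
    dup = cohort.panel.duplicate_assayed
    for marker in included:
        sub = meas[meas["marker"] == marker].set_index("subject_id")
        sub = sub.loc[subjects]
        col = wide[marker].to_numpy(dtype=float)
        # high-CV duplicates are treated as unreliable and sent to imputation
        if dup[marker] and {"rep1", "rep2"}.issubset(sub.columns):
            pairs = sub["rep1"].notna() & sub["rep2"].notna()
            cv = np.full(len(sub), np.nan)
            cv[pairs.to_numpy()] = [
                _pair_cv(r1, r2)
                for r1, r2 in zip(sub.loc[pairs, "rep1"], sub.loc[pairs, "rep2"])
            ]
            bad = (cv > qc.max_cv) & ~np.isnan(col)
            col[bad] = np.nan
            flags.loc[bad, marker] = "imputed"
        below = (
            sub["below_lod"].astype(bool).to_numpy()
            if "below_lod" in sub.columns
            else col < lod[marker]
        )
        col, substituted = substitute_below_lod(col, float(lod[marker]), below)
        wide[marker] = col
        flags.loc[substituted, marker] = "below_lod_substituted"

    logged, log_flags = conditional_log_transform(wide, qc.skew_threshold)
    standardised = zscore_winsorise(logged, qc.winsor_sd)
    imputed, imputed_mask = knn_impute(standardised, qc.knn_k)
    flags[imputed_mask] = "imputed"
    return PreprocessedMatrix(
        values=imputed,
        cell_flags=flags,
        marker_log_flags=log_flags,
        excluded_markers=excluded,
    )
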
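"""Synthetic case-control cohort generator for the inflammatory panel.

Emulates a nested case-control sample (default 380 psychiatric-disorder cases,
399 controls) with plasma concentrations of the 17-marker panel. Cases carry
two latent subgroups whose standardised mean separations follow the observed
ordering of the target analysis (TNFR2 largest ... IFN-gamma smallest);
controls carry none. Concentrations are simulated on a latent Gaussian scale
with residual correlation and exponentiated for the skewed (ELISA) markers, so
the right-skew that triggers the log-transform rule of the preprocessing
pipeline arises naturally. Assay artefacts are layered on top: lower-quantile
LOD censoring, duplicate replicates with CV noise for the multiplex markers,
and missing cells.

Ground-truth subgroup labels are returned separately and never written into
the cohort tables, so the pipeline under test cannot leak them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import EFFECT_SIZES, MARKERS, MarkerPanel, default_panel

__all__ = ["SyntheticConfig", "CohortTable", "generate_cohort", "generate_null_cohort"]


# Latent-to-concentration maps. Skewed markers: conc = exp(mu + sigma*z)
# (log-normal, right-skewed); PEA markers are kept linear on an NPX-like
# log-scale: conc = loc + scale*z.
_MARKER_SCALES: dict[str, tuple[float, float]] = {
    # (mu, sigma) on the log scale for ELISA markers
    "IFN-gamma": (1.4, 0.5),
    "TNF-alpha": (0.8, 0.5),
    "IL-6": (0.2, 0.5),
    "IL-8": (1.6, 0.5),
    "IL-10": (-0.9, 0.5),
    "CRP": (0.0, 0.8),
    "sICAM-1": (5.5, 0.25),
    "sVCAM-1": (6.0, 0.25),
    "suPAR": (1.1, 0.45),
    "A2M": (5.0, 0.4),
    # (loc, scale) on the linear NPX-like scale for PEA markers
    "IL-1RT1": (6.0, 1.0),
    "IL-1RT2": (5.0, 1.0),
    "IL-2RA": (4.0, 1.0),
    "IL-6RA": (8.0, 1.0),
    "TNFR1": (7.0, 1.0),
    "TNFR2": (6.5, 1.0),
    "CD93": (8.5, 1.0),
}

_DEFAULT_SKEW = tuple(MARKERS[:10])  # the ELISA-measured concentrations

# Per-subgroup phenotype prevalences; "case" entries are (subgroup 1,
# subgroup 2). Categorical characteristics map category -> probability.
_DEFAULT_PHENOTYPES: dict = {
    "daily_smoker": {"case": (0.161, 0.276), "control": 0.15},
    "neet": {"case": (0.083, 0.215), "control": 0.05},
    "psychotic_experiences": {"case": (0.157, 0.270), "control": 0.0},
    "medication": {"case": (0.180, 0.258), "control": 0.0},
    "physical_condition": {"case": (0.023, 0.025), "control": 0.02},
    "psychotic_disorder": {"case": (0.083, 0.135), "control": 0.0},
    "depressive_disorder": {"case": (0.521, 0.546), "control": 0.0},
    "gad": {"case": (0.724, 0.681), "control": 0.0},
    "sleep_problems": {
        "case": (
            {"none": 0.341, "1-3": 0.350, "4+": 0.309},
            {"none": 0.350, "1-3": 0.380, "4+": 0.270},
        ),
        "control": {"none": 0.55, "1-3": 0.30, "4+": 0.15},
    },
    "anhedonia": {
        "case": (
            {"usual": 0.299, "less": 0.664, "none": 0.037},
            {"usual": 0.313, "less": 0.601, "none": 0.086},
        ),
        "control": {"usual": 0.79, "less": 0.20, "none": 0.01},
    },
}

# Sex and BMI marginals: female fraction and BMI mean/SD per stratum.
_DEFAULT_COVARIATES: dict = {
    "female": {"case": (0.733, 0.761), "control": 0.524},
    "bmi": {"case": ((24.6, 4.9), (26.3, 7.0)), "control": (24.1, 4.3)},
    "age": {"case": (24.1, 0.8), "control": (24.0, 0.8)},
}


def _default_correlation(n: int = len(MARKERS)) -> np.ndarray:
    """Residual (within-subgroup) marker correlation: weak within-platform
    blocks. Marginal correlations in a generated cohort are larger because the
    latent subgroup axis and shared covariate effects add to them."""
    blocks = [range(0, 8), range(8, 10), range(10, 17)]
    corr = np.zeros((n, n))
    for block in blocks:
        for i in block:
            for j in block:
                corr[i, j] = 0.05
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class SyntheticConfig:
    """Study conditions for cohort generation.

    ``effect_vector`` holds the per-marker standardised mean shift of case
    subgroup 2 relative to subgroup 1 on the observed (pooled z-score) scale;
    it is internally mapped to a latent within-subgroup shift
    ``delta = e / sqrt(1 - f(1-f) e^2)`` so that pooled standardisation of the
    generated cases reproduces the requested differences.
    """

    n_cases: int = 380
    n_controls: int = 399
    k_true: int = 2
    subgroup_fraction: float = 163 / 380
    effect_vector: dict[str, float] = field(default_factory=lambda: dict(EFFECT_SIZES))
    marker_correlation: np.ndarray | None = None
    skew_markers: tuple[str, ...] = _DEFAULT_SKEW
    lod_censor_rate: float = 0.02
    cv_noise_sd: float = 0.05
    missing_rate: float = 0.012
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"female": 0.2, "bmi": 0.04}
    )
    phenotype_rates: dict = field(default_factory=lambda: _DEFAULT_PHENOTYPES)
    covariate_params: dict = field(default_factory=lambda: _DEFAULT_COVARIATES)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be positive")
        if self.k_true not in (1, 2):
            raise ValueError("k_true must be 1 or 2")
        if not 0.0 <= self.subgroup_fraction <= 1.0:
            raise ValueError("subgroup_fraction must lie in [0, 1]")
        for rate in (self.lod_censor_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if set(self.effect_vector) != set(MARKERS):
            raise ValueError("effect_vector must cover exactly the panel markers")
        if self.marker_correlation is None:
            self.marker_correlation = _default_correlation()
        corr = np.asarray(self.marker_correlation, dtype=float)
        if corr.shape != (len(MARKERS), len(MARKERS)):
            raise ValueError("marker_correlation must be 17x17")
        if not np.allclose(corr, corr.T):
            raise ValueError("marker_correlation must be symmetric")
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as err:
            raise ValueError("marker_correlation must be positive-definite") from err
        self.marker_correlation = corr

    def to_yaml(self, path) -> None:
        data = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("marker_correlation", "phenotype_rates", "covariate_params")
        }
        data["skew_markers"] = list(self.skew_markers)
        data["marker_correlation"] = np.asarray(self.marker_correlation).tolist()
        data["phenotype_rates"] = self.phenotype_rates
        data["covariate_params"] = self.covariate_params
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class CohortTable:
    """Participant phenotypes plus the paired long-form measurement table."""

    participants: pd.DataFrame
    measurements: pd.DataFrame
    panel: MarkerPanel

    @property
    def case_ids(self) -> list[str]:
        p = self.participants
        return list(p.loc[p["group"] == "case", "subject_id"])

    def values_wide(self) -> pd.DataFrame:
        """Subjects x markers matrix of measured values (NaN where missing)."""
        wide = self.measurements.pivot(
            index="subject_id", columns="marker", values="value"
        )
        return wide.loc[self.participants["subject_id"], list(self.panel.markers)]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(outdir / "participants.tsv", sep="\t", index=False)
        self.measurements.to_csv(outdir / "measurements.tsv", sep="\t", index=False)
        self.panel.to_tsv(outdir / "panel.tsv")

    @classmethod
    def read(cls, indir) -> "CohortTable":
        indir = Path(indir)
        return cls(
            participants=pd.read_csv(indir / "participants.tsv", sep="\t"),
            measurements=pd.read_csv(indir / "measurements.tsv", sep="\t"),
            panel=MarkerPanel.from_tsv(indir / "panel.tsv"),
        )


def _draw_categorical(rng, probs: dict[str, float], n: int) -> np.ndarray:
    cats = list(probs)
    p = np.asarray([probs[c] for c in cats], dtype=float)
    p = p / p.sum()
    return rng.choice(cats, size=n, p=p)


def generate_cohort(config: SyntheticConfig) -> tuple[CohortTable, pd.Series]:
    """Generate a cohort and its ground-truth case subgroup labels.

    Returns
    -------
    cohort : CohortTable
    truth : pandas.Series
        Subgroup label (1 or 2) indexed by case subject_id. Kept out of the
        cohort tables by design.
    """
    rng = np.random.default_rng(config.seed)
    n_cases, n_controls = config.n_cases, config.n_controls
    n = n_cases + n_controls
    markers = list(MARKERS)
    p = len(markers)

    subject_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    group = np.array(["case"] * n_cases + ["control"] * n_controls)

    # latent subgroup labels for cases (exact counts, random placement)
    if config.k_true == 2:
        n2 = int(round(config.subgroup_fraction * n_cases))
        labels = np.ones(n_cases, dtype=int)
        labels[rng.permutation(n_cases)[:n2]] = 2
    else:
        labels = np.ones(n_cases, dtype=int)

    # covariates
    cov = config.covariate_params
    female = np.empty(n)
    bmi = np.empty(n)
    age = np.empty(n)
    f1, f2 = cov["female"]["case"]
    female[:n_cases] = rng.random(n_cases) < np.where(labels == 1, f1, f2)
    female[n_cases:] = rng.random(n_controls) < cov["female"]["control"]
    (m1, s1), (m2, s2) = cov["bmi"]["case"]
    bmi[:n_cases] = np.where(
        labels == 1,
        rng.normal(m1, s1, n_cases),
        rng.normal(m2, s2, n_cases),
    )
    mc, sc = cov["bmi"]["control"]
    bmi[n_cases:] = rng.normal(mc, sc, n_controls)
    bmi = np.clip(bmi, 15.0, None)
    ma, sa = cov["age"]["case"]
    age[:n_cases] = rng.normal(ma, sa, n_cases)
    ma, sa = cov["age"]["control"]
    age[n_cases:] = rng.normal(ma, sa, n_controls)

    # latent marker matrix: subgroup shift + covariate loadings + correlated noise
    e = np.array([config.effect_vector[m] for m in markers])
    f = config.subgroup_fraction if config.k_true == 2 else 0.0
    with np.errstate(invalid="raise"):
        denom = 1.0 - f * (1.0 - f) * e**2
        if np.any(denom <= 0):
            raise ValueError("effect_vector too large for pooled-scale calibration")
        delta = e / np.sqrt(denom)
    shift = np.zeros((n, p))
    if config.k_true == 2:
        shift[:n_cases] = np.where(
            (labels == 2)[:, None], (1.0 - f) * delta, -f * delta
        )
    chol = np.linalg.cholesky(config.marker_correlation)
    z = shift + rng.standard_normal((n, p)) @ chol.T
    z += config.covariate_effects.get("female", 0.0) * female[:, None]
    z += config.covariate_effects.get("bmi", 0.0) * (bmi - 24.5)[:, None]

    # map to concentrations
    conc = np.empty_like(z)
    for j, m in enumerate(markers):
        a, b = _MARKER_SCALES[m]
        if m in config.skew_markers:
            conc[:, j] = np.exp(a + b * z[:, j])
        else:
            # extreme negative draws are non-detects; floor keeps the
            # concentration scale physical and they fall below the LOD anyway
            conc[:, j] = np.maximum(a + b * z[:, j], a / 100.0)

    # assay noise: duplicate replicates for multiplex markers, single
    # multiplicative CV draw otherwise; analysis value = replicate mean
    panel = default_panel()
    dup = panel.duplicate_assayed
    rep1 = np.full_like(conc, np.nan)
    rep2 = np.full_like(conc, np.nan)
    value = np.empty_like(conc)
    for j, m in enumerate(markers):
        if dup[m]:
            r1 = conc[:, j] * (1 + config.cv_noise_sd * rng.standard_normal(n))
            r2 = conc[:, j] * (1 + config.cv_noise_sd * rng.standard_normal(n))
            rep1[:, j], rep2[:, j] = r1, r2
            value[:, j] = (r1 + r2) / 2
        else:
            value[:, j] = conc[:, j] * (
                1 + config.cv_noise_sd * rng.standard_normal(n)
            )

    # LOD = lower quantile of each marker's marginal; flag censored values
    lods = {
        m: float(np.quantile(value[:, j], config.lod_censor_rate))
        for j, m in enumerate(markers)
    }
    panel = default_panel(lod=lods)

    # missingness (insufficient sample volume etc.), MCAR over cells
    missing = rng.random((n, p)) < config.missing_rate

    rows = []
    for j, m in enumerate(markers):
        below = value[:, j] < lods[m]
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject_ids,
                    "marker": m,
                    "value": np.where(missing[:, j], np.nan, value[:, j]),
                    "rep1": np.where(missing[:, j], np.nan, rep1[:, j]),
                    "rep2": np.where(missing[:, j], np.nan, rep2[:, j]),
                    "below_lod": below & ~missing[:, j],
                }
            )
        )
    measurements = pd.concat(rows, ignore_index=True)

    # phenotypes
    participants = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": group,
            "female": female.astype(int),
            "bmi": bmi,
            "age": age,
        }
    )
    for name, spec_ in config.phenotype_rates.items():
        case_spec, control_spec = spec_["case"], spec_["control"]
        if isinstance(control_spec, dict):  # categorical
            col = np.empty(n, dtype=object)
            for sub, probs in zip((1, 2), case_spec):
                mask = labels == sub
                col[:n_cases][mask] = _draw_categorical(rng, probs, int(mask.sum()))
            col[n_cases:] = _draw_categorical(rng, control_spec, n_controls)
        else:
            col = np.zeros(n, dtype=int)
            p1, p2 = case_spec
            col[:n_cases] = rng.random(n_cases) < np.where(labels == 1, p1, p2)
            col[n_cases:] = rng.random(n_controls) < control_spec
        participants[name] = col

    # shuffle subject order so cases and controls interleave as in a real table
    order = rng.permutation(n)
    participants = participants.iloc[order].reset_index(drop=True)
    measurements["subject_id"] = pd.Categorical(
        measurements["subject_id"], categories=list(participants["subject_id"])
    )
    measurements = (
        measurements.sort_values(["marker", "subject_id"])
        .reset_index(drop=True)
        .astype({"subject_id": str})
    )

    truth = pd.Series(
        labels, index=pd.Index(subject_ids[:n_cases], name="subject_id"), name="subgroup"
    )
    truth = truth.loc[[s for s in participants["subject_id"] if s in truth.index]]
    return CohortTable(participants, measurements, panel), truth


def generate_null_cohort(config: SyntheticConfig) -> CohortTable:
    """Cohort with no case subgroup structure (zero effect vector).

    Case marker distributions equal control distributions up to covariate
    effects; used as the negative control for stability and significance
    analyses.
    """
    null_config = replace(
        config,
        k_true=1,
        effect_vector={m: 0.0 for m in MARKERS},
        phenotype_rates={
            name: {"case": (spec_["case"][0], spec_["case"][0]), "control": spec_["control"]}
            for name, spec_ in config.phenotype_rates.items()
        },
        covariate_params={
            "female": config.covariate_params["female"],
            "bmi": {
                "case": (
                    config.covariate_params["bmi"]["case"][0],
                    config.covariate_params["bmi"]["case"][0],
                ),
                "control": config.covariate_params["bmi"]["control"],
            },
            "age": config.covariate_params["age"],
        },
    )
    cohort, _ = generate_cohort(null_config)
    return cohort
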
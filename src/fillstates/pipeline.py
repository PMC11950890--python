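"""Cohort-level pipeline: control model fitting, per-subject markers, and
the marker-comparison report bundle (staging, ROC/DeLong, partial
correlations, regression models 1-4)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core
from . import stats as st
from .volume import MaskVolume, VolumeGrid, load_volume

logger = logging.getLogger(__name__)

MODALITIES = ("amyloid", "tau", "neurodegeneration")
SCORE_COLUMNS = ("score_global", "score_memory", "score_executive")
COVARIATES = ("age", "sex", "education")

#: conventional florbetapir amyloid-positivity SUVR threshold (config-overridable)
DEFAULT_AMYLOID_SUVR_THRESHOLD = 1.11

MARKER_COLUMNS = [
    "subject_id", "modality", "roi_label", "cutoff", "direction",
    "fill_state_pct", "suvr", "abnormal_intensity",
    "n_roi_voxels", "n_abnormal_voxels",
]


@dataclass
class PipelineConfig:
    cutoffs: dict = field(default_factory=lambda: dict(core.DEFAULT_CUTOFFS))
    directions: dict = field(default_factory=lambda: dict(core.DEFAULT_DIRECTIONS))
    amyloid_suvr_threshold: float = DEFAULT_AMYLOID_SUVR_THRESHOLD
    reflect_sqrt_scores: bool = True
    bonferroni_m: int = 3


class VolumeStore:
    """Uniform access to per-(subject, modality) volumes, in memory or on disk."""

    def __init__(self, volumes: dict | None = None, directory: str | Path | None = None):
        if (volumes is None) == (directory is None):
            raise ValueError("provide exactly one of volumes / directory")
        self._volumes = volumes
        self._dir = Path(directory) if directory else None

    def get(self, subject_id: str, modality: str) -> VolumeGrid:
        if self._volumes is not None:
            try:
                return self._volumes[(subject_id, modality)]
            except KeyError:
                raise FileNotFoundError(f"no volume for subject {subject_id} ({modality})")
        for ext in (".nii.gz", ".nii"):
            p = self._dir / f"{subject_id}_{modality}{ext}"
            if p.exists():
                return load_volume(p, modality)
        raise FileNotFoundError(
            f"no volume for subject {subject_id} ({modality}) under {self._dir}"
        )


def select_controls(cohort: pd.DataFrame) -> pd.DataFrame:
    """Amyloid-negative cognitively normal subjects define the normative model."""
    ctrl = cohort[(cohort["group"] == "CN") & (cohort["amyloid_status"] == "negative")]
    if ctrl.empty:
        raise ValueError("no amyloid-negative CN controls in the cohort table")
    return ctrl


def compute_cohort_markers(
    store: VolumeStore,
    cohort: pd.DataFrame,
    roi: MaskVolume,
    config: PipelineConfig | None = None,
    modalities=MODALITIES,
) -> pd.DataFrame:
    """Fit per-modality control models and compute markers for every patient.

    Patients are all subjects outside the control set. The returned tidy
    table has one row per patient per modality, plus an
    ``amyloid_positive`` flag from the configured SUVR threshold.
    """
    config = config or PipelineConfig()
    controls = select_controls(cohort)
    patient_ids = [s for s in cohort["subject_id"] if s not in set(controls["subject_id"])]

    models = {}
    for modality in modalities:
        ctrl_vols = [store.get(sid, modality) for sid in controls["subject_id"]]
        models[modality] = core.fit_control_model(ctrl_vols, modality)
        logger.info(
            "control model %s: n=%d, %d SD-floored voxels",
            modality, len(ctrl_vols), models[modality].n_floored_voxels,
        )

    rows = []
    amyloid_suvr: dict[str, float] = {}
    for sid in patient_ids:
        for modality in modalities:
            vol = store.get(sid, modality)
            ms = core.compute_markers(
                vol,
                models[modality],
                roi,
                cutoff=config.cutoffs.get(modality, core.DEFAULT_CUTOFF),
                direction=config.directions.get(modality, "greater"),
            )
            if modality == "amyloid":
                amyloid_suvr[sid] = ms.suvr
            rows.append(
                {
                    "subject_id": sid,
                    "modality": modality,
                    "roi_label": ms.roi_label,
                    "cutoff": ms.cutoff,
                    "direction": ms.direction,
                    "fill_state_pct": ms.fill_state,
                    "suvr": ms.suvr,
                    "abnormal_intensity": ms.abnormal_intensity,
                    "n_roi_voxels": ms.n_roi_voxels,
                    "n_abnormal_voxels": ms.n_abnormal_voxels,
                }
            )
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    if not markers.empty:
        markers["amyloid_positive"] = markers["subject_id"].map(
            lambda s: bool(amyloid_suvr.get(s, np.nan) > config.amyloid_suvr_threshold)
        )
    return markers


def _wide_markers(markers: pd.DataFrame) -> pd.DataFrame:
    wide = markers.pivot(
        index="subject_id", columns="modality", values=["fill_state_pct", "suvr"]
    )
    wide.columns = [f"{metric}_{mod}" for metric, mod in wide.columns]
    return wide.reset_index()


def join_markers_cohort(markers: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Wide per-subject table: fill states and SUVRs per modality + covariates."""
    return _wide_markers(markers).merge(cohort, on="subject_id", how="inner")


def run_stats(
    markers: pd.DataFrame, cohort: pd.DataFrame, config: PipelineConfig | None = None
) -> dict:
    """The full marker-comparison battery on a joined marker/cohort table.

    Returns a dict of DataFrames: ``staging`` (Kruskal-Wallis + post hoc
    Mann-Whitney per marker per modality), ``roc_delong`` (fill state vs
    SUVR per modality for impairment = MCI+dementia vs SCD),
    ``partial_correlations`` (each marker x each cognitive score, adjusted
    for age/sex/education), and ``regressions`` (models 1-4: multivariate
    term tests + univariate coefficients). Analyses with insufficient data
    are skipped with a log entry.
    """
    config = config or PipelineConfig()
    data = join_markers_cohort(markers, cohort)
    alpha_bonf = st.bonferroni(0.05, config.bonferroni_m)
    modalities = sorted(markers["modality"].unique())

    # -- staging: Kruskal-Wallis across SCD/MCI/dementia + pairwise MW U ----
    staging_rows = []
    stage_groups = [g for g in ("SCD", "MCI", "dementia") if (data["group"] == g).any()]
    for modality in modalities:
        for metric in ("fill_state_pct", "suvr"):
            col = f"{metric}_{modality}"
            sub = data[data["group"].isin(stage_groups)].dropna(subset=[col])
            if sub["group"].nunique() < 2:
                logger.warning("staging skipped for %s (need >= 2 groups)", col)
                continue
            h, p = st.kruskal_wallis(sub[col].to_numpy(), sub["group"].to_numpy())
            staging_rows.append(
                {"modality": modality, "marker": metric, "test": "kruskal_wallis",
                 "groups": "|".join(stage_groups), "statistic": h, "p": p,
                 "n": len(sub), **st.significance_tiers(p, config.bonferroni_m)}
            )
            for i in range(len(stage_groups)):
                for j in range(i + 1, len(stage_groups)):
                    a = sub.loc[sub["group"] == stage_groups[i], col].to_numpy()
                    b = sub.loc[sub["group"] == stage_groups[j], col].to_numpy()
                    u, pu = st.mann_whitney(a, b)
                    staging_rows.append(
                        {"modality": modality, "marker": metric, "test": "mann_whitney",
                         "groups": f"{stage_groups[i]}|{stage_groups[j]}",
                         "statistic": u, "p": pu, "n": len(a) + len(b),
                         **st.significance_tiers(pu, config.bonferroni_m)}
                    )
    staging = pd.DataFrame(staging_rows)

    # -- ROC / DeLong: impairment (MCI+dementia) vs no impairment (SCD) -----
    roc_rows = []
    roc_data = data[data["group"].isin(("SCD", "MCI", "dementia"))]
    labels = roc_data["group"].isin(("MCI", "dementia")).to_numpy()
    for modality in modalities:
        f_col, s_col = f"fill_state_pct_{modality}", f"suvr_{modality}"
        sub = roc_data.dropna(subset=[f_col, s_col])
        y = sub["group"].isin(("MCI", "dementia")).to_numpy()
        if y.all() or not y.any():
            logger.warning("ROC skipped for %s (one class absent)", modality)
            continue
        direction = config.directions.get(modality, "greater")
        sign = 1.0 if direction == "greater" else -1.0
        # fill state grows with pathology in either direction; SUVR follows
        # the modality's pathologic direction
        cmp = st.delong_test(
            sub[f_col].to_numpy(), sign * sub[s_col].to_numpy(), y
        )
        roc_rows.append(
            {"modality": modality, "auc_fill_state": cmp.auc_a, "auc_suvr": cmp.auc_b,
             "delong_z": cmp.delong_z, "p": cmp.p_value,
             "n_pos": cmp.n_pos, "n_neg": cmp.n_neg, "degenerate": cmp.degenerate,
             **st.significance_tiers(cmp.p_value, config.bonferroni_m)}
        )
    roc_delong = pd.DataFrame(roc_rows)

    # -- partial Spearman: marker x cognitive score | age, sex, education ---
    pc_rows = []
    score_cols = [c for c in SCORE_COLUMNS if c in data.columns]
    for modality in modalities:
        for metric in ("fill_state_pct", "suvr"):
            col = f"{metric}_{modality}"
            for score in score_cols:
                sub = data.dropna(subset=[col, score, *COVARIATES])
                if len(sub) < len(COVARIATES) + 3:
                    logger.warning("partial correlation skipped for %s/%s", col, score)
                    continue
                pc = st.partial_spearman(
                    sub[col].to_numpy(), sub[score].to_numpy(),
                    sub[list(COVARIATES)].to_numpy(), covariate_names=list(COVARIATES),
                )
                pc_rows.append(
                    {"modality": modality, "marker": metric, "score": score,
                     "rho": pc.rho, "p": pc.p_value, "n": pc.n,
                     **st.significance_tiers(pc.p_value, config.bonferroni_m)}
                )
    partial_correlations = pd.DataFrame(pc_rows)

    # -- regression models 1-4 ----------------------------------------------
    reg = data.copy()
    dep_cols = list(score_cols)
    if config.reflect_sqrt_scores:
        for c in score_cols:
            reg[f"{c}_t"] = st.reflect_sqrt_transform(reg[c].to_numpy())
        dep_cols = [f"{c}_t" for c in score_cols]
    mv_rows, uni_frames = [], []
    model_terms = {}
    for i, modality in enumerate(MODALITIES, start=1):
        model_terms[f"model{i}"] = [
            f"fill_state_pct_{modality}", f"suvr_{modality}", "age", "sex", "education"
        ]
    model_terms["model4"] = [f"fill_state_pct_{m}" for m in MODALITIES] + [
        "age", "sex", "education"
    ]
    for name, terms in model_terms.items():
        if not all(t in reg.columns for t in terms):
            logger.warning("%s skipped (missing columns)", name)
            continue
        sub = reg.dropna(subset=dep_cols + terms)
        if len(sub) <= len(terms) + len(dep_cols) + 2:
            logger.warning("%s skipped (n=%d too small)", name, len(sub))
            continue
        try:
            res = st.fit_regression(st.RegressionSpec(dep_cols, terms), sub)
        except st.DegenerateDesignError as exc:
            logger.warning("%s skipped: %s", name, exc)
            continue
        mv = res.multivariate.reset_index()
        mv.insert(0, "model", name)
        mv["n"] = res.n
        for _, r in mv.iterrows():
            mv_rows.append({**r.to_dict(), **st.significance_tiers(r["p"], config.bonferroni_m)})
        uni = res.univariate.copy()
        uni.insert(0, "model", name)
        uni_frames.append(uni)
    regressions_mv = pd.DataFrame(mv_rows)
    regressions_uni = (
        pd.concat(uni_frames, ignore_index=True) if uni_frames else pd.DataFrame()
    )

    return {
        "staging": staging,
        "roc_delong": roc_delong,
        "partial_correlations": partial_correlations,
        "regressions_multivariate": regressions_mv,
        "regressions_univariate": regressions_uni,
        "alpha_tiers": pd.DataFrame(
            [{"alpha": 0.05, "alpha_bonferroni": alpha_bonf, "alpha_strict": 0.001}]
        ),
    }


def write_report_bundle(reports: dict, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in reports.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    return written
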
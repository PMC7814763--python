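"""Analysis battery: stratified TBSS-style contrasts and regressions.

Couples the sigmoid progression model to the voxel-wise permutation engine:
fits every patient, derives the MRI-time disease state (rD50, cFS, cFL,
phase, aggressiveness), and runs the study's standard battery of designs —
case-control, phase and aggressiveness contrasts, and clinical-parameter
regressions — each with its covariate recipe and significance tier, on all
four DTI metrics and both contrast directions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import progression as prog
from .progression import (
    PatientRecord,
    D50Fit,
    classify_aggressiveness,
    pair_alsfrs_to_mri,
    progression_rate,
    state_at,
)
from .voxelwise import (
    DesignMatrix,
    PermutationResult,
    SkeletonDataset,
    TFCEParams,
    build_design,
    permutation_maxtfce,
    threshold_report,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisRecipe",
    "RecipeResult",
    "RunManifest",
    "cohort_covariates",
    "builtin_recipes",
    "select_subjects",
    "run_recipe",
    "compare_group_demographics",
    "report",
]

METRICS = ("FA", "MD", "AD", "RD")


@dataclass(frozen=True)
class AnalysisRecipe:
    """One entry of the analysis battery.

    ``kind`` is ``group_contrast`` (two-level ``group_col``) or
    ``regression`` (continuous ``regressor``); age and sex are always among
    the nuisance covariates.  ``phase_in`` restricts the patient subset by
    disease phase, ``require_paired`` to patients with an ALSFRS-R
    assessment within the MRI pairing window.
    """

    name: str
    kind: str
    alpha: float
    covariates: tuple[str, ...]
    group_col: str | None = None
    regressor: str | None = None
    metrics: tuple[str, ...] = METRICS
    patients_only: bool = True
    phase_in: tuple[str, ...] | None = None
    require_paired: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.kind not in ("group_contrast", "regression"):
            raise ValueError(f"unknown recipe kind {self.kind}")
        if (self.group_col is None) == (self.regressor is None):
            raise ValueError("recipe needs exactly one of group_col/regressor")


@dataclass
class RecipeResult:
    """All permutation results and threshold reports of one recipe."""

    recipe: AnalysisRecipe
    n_subjects: int
    subject_ids: list[str]
    results: dict[tuple[str, str], PermutationResult]
    reports: dict[tuple[str, str], dict]

    def total_significant(self) -> int:
        return sum(r["n_significant"] for r in self.reports.values())


@dataclass
class RunManifest:
    """Reproducibility snapshot of one pipeline run."""

    seed: int | None
    n_perm: int
    tfce: dict
    recipes: list[str]
    design_hashes: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


# ---------------------------------------------------------------------------
# per-subject covariate assembly
# ---------------------------------------------------------------------------


def cohort_covariates(
    records: list[PatientRecord], fits: dict[str, D50Fit | None]
) -> pd.DataFrame:
    """Per-subject covariate table joining demographics and model state at MRI.

    Controls carry NaN for the disease-model columns.  ``symptom_duration``
    is the time from onset to MRI; ``alsfrs_r_at_mri`` and ``pr`` are filled
    only for patients with an assessment inside the pairing window.
    """
    rows = []
    for rec in records:
        fit = fits.get(rec.id)
        row: dict = {
            "patient_id": rec.id,
            "group": rec.group,
            "age": rec.age_at_mri,
            "sex": rec.sex,
            "onset_type": rec.onset_type,
            "handedness": rec.handedness,
            "symptom_duration": rec.mri_t_months if rec.group == "patient" else np.nan,
            "d50": np.nan, "dx": np.nan, "rd50": np.nan, "cfs": np.nan,
            "cfl": np.nan, "phase": "", "aggressiveness": "",
            "alsfrs_r_at_mri": np.nan, "pr": np.nan,
        }
        if fit is not None and rec.group == "patient":
            st = state_at(fit, rec.mri_t_months)
            row.update(
                d50=fit.d50, dx=fit.dx, rd50=st.rd50, cfs=st.cfs, cfl=st.cfl,
                phase=st.phase, aggressiveness=classify_aggressiveness(fit.d50),
            )
            paired = pair_alsfrs_to_mri(rec)
            if paired is not None and rec.mri_t_months > 0:
                row["alsfrs_r_at_mri"] = paired.score
                row["pr"] = progression_rate(paired.score, rec.mri_t_months)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the battery
# ---------------------------------------------------------------------------


def builtin_recipes(include_phase3: bool = False) -> list[AnalysisRecipe]:
    """The standard analysis battery with its covariate and alpha tiers.

    1. case-control per metric (age + sex; alpha .001);
    2. Phase I vs II (+ D50 covariate; alpha .05) — Phase III/IV patients are
       excluded unless ``include_phase3`` (sensitivity variant);
    3. high vs low aggressiveness (D50 < 30) (+ cFS + onset-type; alpha .05);
    4. whole-cohort regressions: rD50, cFS, cFL, D50, symptom duration
       (alpha .001);
    5. the same regressions within Phase I and within Phase II (alpha .05);
    6. regressions in the MRI-paired subcohort: ALSFRS-R, cFS, D50, PR
       (alpha .01).
    """
    base = ("age", "sex")
    phases = ("I", "II", "III_IV") if include_phase3 else ("I", "II")
    recipes = [
        AnalysisRecipe(
            name="case_control", kind="group_contrast", group_col="group",
            covariates=base, alpha=0.001, patients_only=False,
        ),
        AnalysisRecipe(
            name="phase_I_vs_II", kind="group_contrast", group_col="phase",
            covariates=base + ("d50",), alpha=0.05, phase_in=phases,
        ),
        AnalysisRecipe(
            name="aggressiveness_high_vs_low", kind="group_contrast",
            group_col="aggressiveness", covariates=base + ("cfs", "onset_type"),
            alpha=0.05,
        ),
    ]
    for reg in ("rd50", "cfs", "cfl", "d50", "symptom_duration"):
        recipes.append(
            AnalysisRecipe(
                name=f"regression_{reg}", kind="regression", regressor=reg,
                covariates=base, alpha=0.001,
            )
        )
        for phase in ("I", "II"):
            recipes.append(
                AnalysisRecipe(
                    name=f"regression_{reg}_phase_{phase}", kind="regression",
                    regressor=reg, covariates=base, alpha=0.05, phase_in=(phase,),
                )
            )
    for reg in ("alsfrs_r_at_mri", "cfs", "d50", "pr"):
        recipes.append(
            AnalysisRecipe(
                name=f"paired_regression_{reg}", kind="regression", regressor=reg,
                covariates=base, alpha=0.01, require_paired=True,
            )
        )
    return recipes


def select_subjects(recipe: AnalysisRecipe, covariates: pd.DataFrame) -> pd.DataFrame:
    """Apply the recipe's subject filter; errors name the failing filter."""
    table = covariates
    if recipe.patients_only:
        table = table[table["group"] == "patient"]
    if recipe.phase_in is not None:
        phases = set(recipe.phase_in)
        sel = table["phase"].isin(phases)
        table = table[sel]
        if recipe.group_col == "phase" and "III_IV" in phases:
            # sensitivity variant: late-phase patients join the Phase II arm
            table = table.assign(phase=table["phase"].replace({"III_IV": "II"}))
    if recipe.require_paired:
        table = table[table["alsfrs_r_at_mri"].notna()]
    if table.empty:
        raise ValueError(f"recipe '{recipe.name}': subject filter selected nobody")
    if recipe.kind == "group_contrast":
        counts = table[recipe.group_col].value_counts()
        if len(counts) != 2 or counts.min() < 2:
            raise ValueError(
                f"recipe '{recipe.name}': need two groups with >= 2 subjects, "
                f"got {counts.to_dict()}"
            )
    return table.reset_index(drop=True)


def _design_for(recipe: AnalysisRecipe, table: pd.DataFrame) -> DesignMatrix:
    if recipe.kind == "group_contrast":
        return build_design(table, group=recipe.group_col, covariates=recipe.covariates)
    return build_design(table, regressor=recipe.regressor, covariates=recipe.covariates)


def run_recipe(
    recipe: AnalysisRecipe,
    covariates: pd.DataFrame,
    datasets: dict[str, SkeletonDataset],
    params: TFCEParams | None = None,
    n_perm: int = 5000,
    seed: int | None = 0,
    metrics: tuple[str, ...] | None = None,
    directions: tuple[str, ...] = ("positive", "negative"),
) -> RecipeResult:
    """Run one recipe over the requested metrics and contrast directions.

    Each direction of the contrast is tested as its own one-sided
    permutation run on the negated contrast; reports are thresholded at the
    recipe's alpha on FWE-corrected p-values.
    """
    table = select_subjects(recipe, covariates)
    design = _design_for(recipe, table)
    contrast = next(iter(design.contrasts.values()))
    ids = table["patient_id"].astype(str).tolist()

    results: dict[tuple[str, str], PermutationResult] = {}
    reports: dict[tuple[str, str], dict] = {}
    for mi, metric in enumerate(metrics or recipe.metrics):
        ds = datasets[metric]
        if ds.subject_ids is None:
            raise ValueError("datasets must carry subject_ids for alignment")
        pos = {sid: i for i, sid in enumerate(ds.subject_ids)}
        missing = [sid for sid in ids if sid not in pos]
        if missing:
            raise ValueError(f"recipe '{recipe.name}': no maps for subjects {missing}")
        sub = ds.select_subjects(np.array([pos[sid] for sid in ids]))
        for di, direction in enumerate(directions):
            c = contrast if direction == "positive" else -contrast
            run_seed = None if seed is None else seed + 1000 * mi + di
            res = permutation_maxtfce(
                sub, design, c, params=params, n_perm=n_perm, seed=run_seed
            )
            results[(metric, direction)] = res
            reports[(metric, direction)] = threshold_report(
                res, recipe.alpha, mask=ds.mask
            )
    return RecipeResult(
        recipe=recipe, n_subjects=len(table), subject_ids=ids,
        results=results, reports=reports,
    )


# ---------------------------------------------------------------------------
# demographics comparison utilities
# ---------------------------------------------------------------------------


def compare_group_demographics(
    table: pd.DataFrame,
    grouping: str,
    variables: list[str] | None = None,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Between-group tests per variable, dispatched by type and normality.

    Continuous variables use Student's t when a Lilliefors screen does not
    reject normality in either group, otherwise the Mann-Whitney U;
    categorical variables use the chi-square test on the contingency table.
    """
    from statsmodels.stats.diagnostic import lilliefors

    groups = [g for g, _ in table.groupby(grouping, sort=True)]
    if len(groups) < 2:
        raise ValueError(f"grouping '{grouping}' has a single level")
    if len(groups) != 2:
        raise ValueError("exactly two groups are supported")
    a = table[table[grouping] == groups[0]]
    b = table[table[grouping] == groups[1]]
    if variables is None:
        variables = [c for c in table.columns if c not in (grouping, "patient_id")]

    def normalish(x: np.ndarray) -> bool:
        if x.size < 4 or np.std(x) == 0:
            return True
        return lilliefors(x, dist="norm")[1] > normality_alpha

    rows = []
    for var in variables:
        va, vb = a[var].dropna(), b[var].dropna()
        if table[var].dtype == object or table[var].dtype == bool:
            ct = pd.crosstab(table[grouping], table[var])
            stat, p, _, _ = stats.chi2_contingency(ct)
            test = "chi2"
        else:
            xa, xb = va.to_numpy(float), vb.to_numpy(float)
            if xa.size < 2 or xb.size < 2:
                continue
            if normalish(xa) and normalish(xb):
                stat, p = stats.ttest_ind(xa, xb)
                test = "t"
            else:
                stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
                test = "mannwhitneyu"
        rows.append({"variable": var, "test": test, "statistic": float(stat),
                     "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def _region_overlap(report_entry: dict, geometry, mask: np.ndarray) -> pd.DataFrame:
    """Voxel overlap of significant findings with the named regions."""
    sig = report_entry["significant"]
    rows = []
    for name in sorted(geometry.regions):
        overlap = int(np.sum(sig & geometry.region_mask_vector(name)))
        if overlap:
            rows.append({"region": name, "n_voxels": overlap})
    return pd.DataFrame(rows, columns=["region", "n_voxels"])


def report(
    recipe_results: list[RecipeResult],
    out_dir: str | Path,
    geometry=None,
    cohort_table: pd.DataFrame | None = None,
) -> Path:
    """Write TSV/JSON/HTML summaries of a battery run; returns the out dir.

    Per recipe: suprathreshold-voxel histograms by p-level, component tables
    and (when the skeleton geometry is given) region-overlap tables; plus a
    cohort summary and model-parameter histograms when a cohort table is
    supplied.  Recipes without suprathreshold voxels get an explicit
    "no suprathreshold voxels" entry.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"recipes": {}}
    html = ["<html><body><h1>d50tracts analysis report</h1>"]
    for rr in recipe_results:
        rdir = out / rr.recipe.name
        rdir.mkdir(exist_ok=True)
        entry: dict = {"n_subjects": rr.n_subjects, "alpha": rr.recipe.alpha,
                       "findings": {}}
        html.append(f"<h2>{rr.recipe.name}</h2><ul>")
        for (metric, direction), rep in rr.reports.items():
            key = f"{metric}_{direction}"
            rep["histogram"].to_csv(rdir / f"{key}_histogram.tsv", sep="\t", index=False)
            if rep["components"]:
                pd.DataFrame(rep["components"]).to_csv(
                    rdir / f"{key}_components.tsv", sep="\t", index=False
                )
            if geometry is not None:
                ov = _region_overlap(rep, geometry, None)
                if not ov.empty:
                    ov.to_csv(rdir / f"{key}_regions.tsv", sep="\t", index=False)
            n_sig = rep["n_significant"]
            entry["findings"][key] = n_sig if n_sig else "no suprathreshold voxels"
            html.append(f"<li>{key}: {n_sig or 'no suprathreshold voxels'}</li>")
        html.append("</ul>")
        summary["recipes"][rr.recipe.name] = entry
    if cohort_table is not None:
        prog.summarize_cohort(cohort_table.drop(columns=["patient_id"], errors="ignore")).to_csv(
            out / "cohort_summary.tsv", sep="\t", index=False
        )
        for col in ("d50", "dx", "rd50", "cfs", "cfl"):
            if col in cohort_table and cohort_table[col].notna().any():
                counts, edges = np.histogram(cohort_table[col].dropna(), bins=12)
                pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                              "count": counts}).to_csv(
                    out / f"hist_{col}.tsv", sep="\t", index=False
                )
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    html.append("</body></html>")
    (out / "index.html").write_text("\n".join(html))
    return out


def design_hash(design: DesignMatrix) -> str:
    payload = design.matrix.tobytes() + ",".join(design.columns).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
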
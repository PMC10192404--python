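"""End-to-end validation-study pipeline and report rendering.

Runs the psychometric evaluation in study order:

1. score picture-sort diets for every subject x timepoint;
2. score the child psychosocial scales;
3. internal consistency (Cronbach alpha) with the single-item removal rule;
4. convergent validity at baseline (index x reference correlations);
5. retention filtering (p <= 0.1 with the expected sign, against the
   5-item self-efficacy reference in children and against the FFQ F&V /
   obesogenic references in adults);
6. Bland-Altman test-retest reliability of the retained indices;
7. completion-rate summary (proportion completing follow-up).

The report is a pure function of (inputs, config): re-running the same
configuration reproduces it byte for byte.  Rounding to display precision
happens only in the markdown renderer; CSV and JSON are full precision.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .adult_reference_measures import load_adult_survey, score_adult_survey
from .diet_scoring import (
    INDEX_COLUMNS,
    default_standards,
    load_standards,
    score_cohort,
)
from .food_registry import (
    default_dialects,
    default_registry,
    load_dialects,
    load_food_registry,
    load_response_table,
)
from .psychosocial_scoring import (
    REMOVAL_THRESHOLD,
    alpha_item_removal,
    coefficient_of_variation,
    default_scales,
    load_scales,
    score_scales,
)
from .reliability import bland_altman
from .validity import (
    RETENTION_P,
    convergent_validity_matrix,
    decisions_frame,
    retained_indices,
    retention_filter,
)

#: Child psychosocial score columns offered as Table-3-style references.
CHILD_REFERENCE_SCALES = [
    "tendency_fruits", "tendency_vegetables", "tendency_fv",
    "se_fruits_eat", "se_veg_4", "se_fv_5", "se_fv_8",
]
CHILD_RETENTION_REFERENCE = "se_fv_5"
ADULT_REFERENCE_SPEC = {"ffq_fv": "+", "obesogenic_index": "-"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Input paths and analysis thresholds for one pipeline run.

    Any path left ``None`` falls back to the packaged default (registry,
    dialects, standards, scales) — response/likert/survey paths have no
    default and must be provided.
    """

    responses: Path | str
    likert: Optional[Path | str] = None
    adult_survey: Optional[Path | str] = None
    registry: Optional[Path | str] = None
    dialects: Optional[Path | str] = None
    standards: Optional[Path | str] = None
    scales: Optional[Path | str] = None
    retention_p: float = RETENTION_P
    alpha_removal_threshold: float = REMOVAL_THRESHOLD
    diff_sign: str = "followup_minus_baseline"
    include_salad: bool = True

    def __post_init__(self) -> None:
        for name in ("retention_p", "alpha_removal_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class ValidationStudyReport:
    """All stage outputs of one run, table per study-report section."""

    descriptives: pd.DataFrame
    internal_consistency: pd.DataFrame
    correlations: pd.DataFrame  # long, with cohort column
    reliability: pd.DataFrame
    retained: dict  # cohort -> [index, ...]
    completion: dict  # cohort -> {n_baseline, n_followup, rate_pct}
    indices: pd.DataFrame = field(repr=False, default=None)
    provenance: dict = field(default_factory=dict)


def completion_rate(n_baseline: int, n_followup: int) -> float:
    """Percentage of baseline respondents completing follow-up."""
    if n_baseline <= 0:
        return math.nan
    return 100.0 * n_followup / n_baseline


# ---------------------------------------------------------------------------

def run_validation_study(cfg: RunConfig) -> ValidationStudyReport:
    """Execute the full pipeline from input files (see module docstring)."""
    try:
        registry = (
            load_food_registry(cfg.registry) if cfg.registry else default_registry()
        )
        dialects = load_dialects(cfg.dialects) if cfg.dialects else default_dialects()
        standards = (
            load_standards(cfg.standards) if cfg.standards else default_standards()
        )
        scales = load_scales(cfg.scales) if cfg.scales else default_scales()
        responses, report = load_response_table(cfg.responses, registry=registry)
        if not report.ok:
            locs = "; ".join(f"{loc}: {rule}" for loc, rule in report.errors[:5])
            raise ValueError(f"response table invalid ({locs})")
        likert = pd.read_csv(cfg.likert, dtype={"subject_id": str}) if cfg.likert else None
        survey = load_adult_survey(cfg.adult_survey) if cfg.adult_survey else None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load_inputs", str(exc)) from exc

    report = run_on_tables(
        responses=responses,
        likert=likert,
        adult_survey=survey,
        registry=registry,
        dialects=dialects,
        standards=standards,
        scales=scales,
        retention_p=cfg.retention_p,
        alpha_removal_threshold=cfg.alpha_removal_threshold,
        diff_sign=cfg.diff_sign,
        include_salad=cfg.include_salad,
    )
    report.provenance["config"] = {
        k: (str(v) if isinstance(v, Path) else v) for k, v in asdict(cfg).items()
    }
    report.provenance["config_hash"] = hashlib.sha256(
        json.dumps(report.provenance["config"], sort_keys=True, default=str).encode()
    ).hexdigest()
    return report


def run_on_tables(
    responses: pd.DataFrame,
    likert: Optional[pd.DataFrame],
    adult_survey: Optional[pd.DataFrame],
    registry=None,
    dialects=None,
    standards=None,
    scales=None,
    retention_p: float = RETENTION_P,
    alpha_removal_threshold: float = REMOVAL_THRESHOLD,
    diff_sign: str = "followup_minus_baseline",
    include_salad: bool = True,
) -> ValidationStudyReport:
    """Core pipeline on in-memory tables (what the file-based entry wraps)."""
    registry = registry or default_registry()
    dialects = dialects or default_dialects()
    standards = standards or default_standards()
    scales = scales or default_scales()

    # -- stage: diet scoring ----------------------------------------------
    try:
        indices = score_cohort(
            responses, registry, dialects, standards, include_salad=include_salad
        )
    except Exception as exc:
        raise PipelineError("diet_scoring", str(exc)) from exc

    # -- stage: psychosocial scoring + internal consistency ----------------
    scale_scores = None
    consistency_rows = []
    if likert is not None and not likert.empty:
        try:
            scale_scores = score_scales(likert, scales)
            base = likert[likert["timepoint"] == "baseline"]
            wide = base.pivot_table(
                index="subject_id", columns="item_id", values="response",
                aggfunc="first",
            )
            base_scores = scale_scores[scale_scores["timepoint"] == "baseline"]
            for scale_id, sd in scales.items():
                present = [i for i in sd.item_ids if i in wide.columns]
                if len(present) < 2:
                    continue
                mat = wide[present].to_numpy(dtype=float)
                rep = alpha_item_removal(
                    mat, present, scale_id, alpha_removal_threshold
                )
                vals = base_scores[scale_id]
                resc = base_scores[f"{scale_id}__rescaled"]
                finite_loo = [a for a in rep.loo_alphas.values()
                              if not math.isnan(a)]
                consistency_rows.append(
                    {
                        "scale_id": scale_id,
                        "n_items": len(present),
                        "mean": vals.mean(),
                        "sd": vals.std(ddof=1),
                        "min": vals.min(),
                        "max": vals.max(),
                        "cov_rescaled": coefficient_of_variation(resc),
                        "alpha": rep.alpha,
                        "alpha_if_deleted_best": max(finite_loo)
                        if finite_loo else math.nan,
                        "removed_item": rep.removed_item or "",
                        "alpha_after": rep.alpha_after
                        if rep.alpha_after is not None else math.nan,
                        "n_subjects": rep.n_subjects,
                    }
                )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("psychosocial_scoring", str(exc)) from exc
    internal_consistency = pd.DataFrame(consistency_rows)

    # -- stage: reference measures -----------------------------------------
    reference = None
    if adult_survey is not None and not adult_survey.empty:
        try:
            reference = score_adult_survey(adult_survey)
        except Exception as exc:
            raise PipelineError("adult_reference_measures", str(exc)) from exc

    # -- stage: convergent validity at baseline ----------------------------
    corr_frames = []
    retained: dict[str, list[str]] = {}
    try:
        ix_base = indices[indices["timepoint"] == "baseline"]
        child_ix = ix_base[ix_base["role"] == "child"].set_index("subject_id")[
            INDEX_COLUMNS
        ]
        adult_ix = ix_base[ix_base["role"] == "adult"].set_index("subject_id")[
            INDEX_COLUMNS
        ]
        if scale_scores is not None and not child_ix.empty:
            child_ref = (
                scale_scores[scale_scores["timepoint"] == "baseline"]
                .set_index("subject_id")
            )
            ref_cols = [c for c in CHILD_REFERENCE_SCALES if c in child_ref.columns]
            corr = convergent_validity_matrix(child_ix, child_ref[ref_cols])
            corr.insert(0, "cohort", "child")
            corr_frames.append(corr)
            decisions = retention_filter(
                corr, {CHILD_RETENTION_REFERENCE: "+"},
                indices=INDEX_COLUMNS, p_threshold=retention_p,
            )
            retained["child"] = retained_indices(decisions)
            child_decisions = decisions_frame(decisions).assign(cohort="child")
        else:
            child_decisions = None
        if reference is not None and not adult_ix.empty:
            adult_ref = (
                reference[reference["timepoint"] == "baseline"]
                .set_index("subject_id")
                [["ffq_fruits", "ffq_vegetables", "ffq_fv", "obesogenic_index"]]
            )
            corr = convergent_validity_matrix(adult_ix, adult_ref)
            corr.insert(0, "cohort", "adult")
            corr_frames.append(corr)
            decisions = retention_filter(
                corr, ADULT_REFERENCE_SPEC,
                indices=INDEX_COLUMNS, p_threshold=retention_p,
            )
            retained["adult"] = retained_indices(decisions)
            adult_decisions = decisions_frame(decisions).assign(cohort="adult")
        else:
            adult_decisions = None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("convergent_validity", str(exc)) from exc
    correlations = (
        pd.concat(corr_frames, ignore_index=True)
        if corr_frames
        else pd.DataFrame(columns=["cohort", "var_x", "var_y", "r", "p", "n", "flag"])
    )

    # -- stage: test-retest reliability of retained indices ----------------
    reliability_rows = []
    try:
        for cohort, idx_list in retained.items():
            sub = indices[indices["role"] == cohort]
            base = sub[sub["timepoint"] == "baseline"].set_index("subject_id")
            fu = sub[sub["timepoint"] == "followup"].set_index("subject_id")
            if fu.empty:
                continue
            for index_name in idx_list:
                res = bland_altman(
                    base[index_name], fu[index_name], diff_sign=diff_sign
                )
                common = base.index.intersection(fu.index)
                reliability_rows.append(
                    {
                        "cohort": cohort,
                        "index": index_name,
                        "n": res.n,
                        "baseline_mean": base.loc[common, index_name].mean(),
                        "baseline_sd": base.loc[common, index_name].std(ddof=1),
                        "followup_mean": fu.loc[common, index_name].mean(),
                        "followup_sd": fu.loc[common, index_name].std(ddof=1),
                        "mean_diff": res.mean_diff,
                        "sd_diff": res.sd_diff,
                        "repeatability": res.repeatability,
                        "loa_lower": res.loa_lower,
                        "loa_upper": res.loa_upper,
                        "pct_within": res.pct_within,
                        "reliability_coefficient": res.reliability_coefficient,
                    }
                )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("reliability", str(exc)) from exc
    reliability = pd.DataFrame(reliability_rows)

    # -- stage: descriptives + completion ----------------------------------
    try:
        desc_rows = []
        for cohort in ("child", "adult"):
            sub = ix_base[ix_base["role"] == cohort]
            if sub.empty:
                continue
            for col in [
                "fruit_excl_juice", "vegetables", "fv_excl_juice",
                "ratio_healthy_total", "fv_score", "healthy_foods_score",
                "modified_ahei_total",
            ]:
                desc_rows.append(
                    {
                        "cohort": cohort,
                        "measure": col,
                        "n": sub[col].notna().sum(),
                        "mean": sub[col].mean(),
                        "sd": sub[col].std(ddof=1),
                    }
                )
        if reference is not None:
            ref_base = reference[reference["timepoint"] == "baseline"]
            for col in ["ffq_fruits", "ffq_vegetables", "ffq_fv",
                        "obesogenic_index"]:
                desc_rows.append(
                    {
                        "cohort": "adult",
                        "measure": col,
                        "n": ref_base[col].notna().sum(),
                        "mean": ref_base[col].mean(),
                        "sd": ref_base[col].std(ddof=1),
                    }
                )
        descriptives = pd.DataFrame(desc_rows)

        completion = {}
        for cohort in ("child", "adult"):
            sub = indices[indices["role"] == cohort]
            nb = sub.loc[sub["timepoint"] == "baseline", "subject_id"].nunique()
            nf = sub.loc[sub["timepoint"] == "followup", "subject_id"].nunique()
            if nb:
                completion[cohort] = {
                    "n_baseline": int(nb),
                    "n_followup": int(nf),
                    "rate_pct": completion_rate(nb, nf),
                }
    except Exception as exc:
        raise PipelineError("descriptives", str(exc)) from exc

    provenance = {
        "package_version": __version__,
        "retention_p": retention_p,
        "alpha_removal_threshold": alpha_removal_threshold,
        "diff_sign": diff_sign,
        "reliability_coefficient_note": (
            "reliability coefficient computed as 1 - (SD(diff)^2/2) / "
            "pooled two-timepoint variance; this estimator is an "
            "interpretation documented in docs/methods.md"
        ),
    }
    return ValidationStudyReport(
        descriptives=descriptives,
        internal_consistency=internal_consistency,
        correlations=correlations,
        reliability=reliability,
        retained=retained,
        completion=completion,
        indices=indices,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Rendering

_TABLES = ("descriptives", "internal_consistency", "correlations", "reliability")


def render_report(
    report: ValidationStudyReport,
    fmt: str,
    outdir: str | Path,
) -> list[Path]:
    """Write the report under ``outdir`` as csv, json or markdown.

    csv/json are lossless; markdown rounds to display precision (1
    decimal for scores, 2 for correlations and ratios).  On error,
    partially written files are removed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        if fmt == "csv":
            for name in _TABLES:
                path = outdir / f"{name}.csv"
                getattr(report, name).to_csv(path, index=False)
                written.append(path)
            path = outdir / "indices.csv"
            report.indices.to_csv(path, index=False)
            written.append(path)
            path = outdir / "summary.json"
            _write_json(_summary_payload(report), path)
            written.append(path)
        elif fmt == "json":
            path = outdir / "report.json"
            _write_json(report_to_json(report), path)
            written.append(path)
        elif fmt == "markdown":
            path = outdir / "report.md"
            path.write_text(render_markdown(report), encoding="utf-8")
            written.append(path)
        else:
            raise ValueError(f"unknown format {fmt!r} (csv | json | markdown)")
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return written


def _summary_payload(report: ValidationStudyReport) -> dict:
    return {
        "retained": report.retained,
        "completion": report.completion,
        "provenance": report.provenance,
    }


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, default=float, sort_keys=True)
        fh.write("\n")


def report_to_json(report: ValidationStudyReport) -> dict:
    payload = _summary_payload(report)
    for name in _TABLES + ("indices",):
        frame = getattr(report, name)
        payload[name] = json.loads(frame.to_json(orient="split", index=False))
    return payload


def report_from_json(payload: Mapping) -> ValidationStudyReport:
    tables = {
        name: pd.DataFrame(
            payload[name]["data"], columns=payload[name]["columns"]
        )
        for name in _TABLES + ("indices",)
    }
    return ValidationStudyReport(
        descriptives=tables["descriptives"],
        internal_consistency=tables["internal_consistency"],
        correlations=tables["correlations"],
        reliability=tables["reliability"],
        retained={k: list(v) for k, v in payload["retained"].items()},
        completion={k: dict(v) for k, v in payload["completion"].items()},
        indices=tables["indices"],
        provenance=dict(payload["provenance"]),
    )


def _md_table(frame: pd.DataFrame, round_map: Mapping[str, int]) -> str:
    shown = frame.copy()
    for col, nd in round_map.items():
        if col in shown.columns:
            shown[col] = shown[col].map(
                lambda v: "" if (isinstance(v, float) and math.isnan(v))
                else f"{v:.{nd}f}"
            )
    header = "| " + " | ".join(str(c) for c in shown.columns) + " |"
    sep = "|" + "|".join(" --- " for _ in shown.columns) + "|"
    rows = [
        "| " + " | ".join(str(v) for v in rec) + " |"
        for rec in shown.itertuples(index=False)
    ]
    return "\n".join([header, sep] + rows)


def render_markdown(report: ValidationStudyReport) -> str:
    """Study-style report: descriptives, internal consistency,
    correlation matrix with significance flags, reliability table."""
    score_round = {"mean": 1, "sd": 1, "min": 1, "max": 1,
                   "baseline_mean": 1, "baseline_sd": 1,
                   "followup_mean": 1, "followup_sd": 1,
                   "mean_diff": 1, "sd_diff": 1, "repeatability": 2,
                   "loa_lower": 2, "loa_upper": 2, "pct_within": 0,
                   "reliability_coefficient": 2,
                   "alpha": 2, "alpha_if_deleted_best": 2, "alpha_after": 2,
                   "cov_rescaled": 2, "r": 2, "p": 3}
    parts = ["# Picture-sort validation study report", ""]
    parts += ["## Completion", ""]
    for cohort, c in report.completion.items():
        parts.append(
            f"- {cohort}: {c['n_baseline']} baseline, {c['n_followup']} "
            f"follow-up ({c['rate_pct']:.0f}% completion)"
        )
    parts += ["", "## Descriptive statistics (baseline)", "",
              _md_table(report.descriptives, score_round), ""]
    if not report.internal_consistency.empty:
        parts += ["## Internal consistency of psychosocial scales", "",
                  _md_table(report.internal_consistency, score_round), ""]
    if not report.correlations.empty:
        parts += ["## Convergent validity (Pearson r; + p<0.1, * p<0.05, "
                  "** p<=0.01, *** p<0.001)", "",
                  _md_table(report.correlations, score_round), ""]
    parts += ["## Retained indices", ""]
    for cohort, idx in report.retained.items():
        parts.append(f"- {cohort}: {', '.join(idx) if idx else '(none)'}")
    if not report.reliability.empty:
        parts += ["", "## Test-retest reliability (Bland-Altman)", "",
                  _md_table(report.reliability, score_round), ""]
    parts += [
        "",
        "Note: the reliability coefficient is 1 - (SD(diff)^2/2) / pooled "
        "two-timepoint variance; see docs/methods.md for the rationale "
        "behind this interpretation.",
        "",
    ]
    return "\n".join(parts)


__all__ = [
    "ADULT_REFERENCE_SPEC",
    "CHILD_REFERENCE_SCALES",
    "CHILD_RETENTION_REFERENCE",
    "PipelineError",
    "RunConfig",
    "ValidationStudyReport",
    "completion_rate",
    "render_markdown",
    "render_report",
    "report_from_json",
    "report_to_json",
    "run_on_tables",
    "run_validation_study",
]
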
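"""End-to-end analysis: score -> group statistics -> thresholds -> imaging.

The stage order mirrors how the diagnostic thresholds were derived for
this instrument: rank-based group comparisons first, then ROC/Youden
cut-off derivation for the group pairs whose post-hoc Dunn test was
significant (case group vs control group), then covariate-adjusted
regional imaging correlations on the imaging subcohort if a regional
table is supplied.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .group_stats import group_score_tests
from .imaging import RegionalTable, regional_association
from .scoring import (
    DIAGNOSTIC_GROUPS,
    SCORE_FIELDS,
    read_cohort_csv,
    score_cohort,
)
from .thresholds import threshold_table

logger = logging.getLogger("camdexds.pipeline")

#: Case groups are compared against control groups for threshold derivation.
CASE_GROUPS = ("prodromal", "dementia")
CONTROL_GROUPS = ("asymptomatic", "mentalhealth")


@dataclass
class PipelineReport:
    """Structured result of a full pipeline run."""

    cohort_summary: dict
    score_summaries: pd.DataFrame
    group_tests: pd.DataFrame
    pairwise_tests: pd.DataFrame
    thresholds: pd.DataFrame
    imaging: pd.DataFrame | None
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        out = {
            "cohort_summary": self.cohort_summary,
            "score_summaries": self.score_summaries.to_dict(orient="records"),
            "group_tests": self.group_tests.to_dict(orient="records"),
            "pairwise_tests": self.pairwise_tests.to_dict(orient="records"),
            "thresholds": self.thresholds.to_dict(orient="records"),
            "imaging": (
                self.imaging.to_dict(orient="records") if self.imaging is not None else None
            ),
            "provenance": self.provenance,
        }
        return out

    def write(self, out_dir: str | Path, stem: str = "report") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / f"{stem}.json").write_text(
            json.dumps(self.to_json_dict(), indent=2, default=_json_default) + "\n"
        )
        (out_dir / f"{stem}.md").write_text(self.to_markdown())
        self.group_tests.to_csv(out_dir / "group_tests.csv", index=False)
        self.pairwise_tests.to_csv(out_dir / "pairwise_tests.csv", index=False)
        self.thresholds.to_csv(out_dir / "thresholds.csv", index=False)
        if self.imaging is not None:
            self.imaging.to_csv(out_dir / "imaging_associations.csv", index=False)

    def to_markdown(self) -> str:
        lines = ["# CAMDEX-DS analysis report", ""]
        cs = self.cohort_summary
        lines.append(f"Cohort: n = {cs['n_total']} "
                     f"({', '.join(f'{g}: {n}' for g, n in cs['group_sizes'].items())})")
        lines.append("")
        lines.append("## Group score summaries")
        lines.append(self.score_summaries.round(2).to_markdown(index=False))
        lines.append("")
        lines.append("## Kruskal-Wallis tests")
        lines.append(
            self.group_tests.assign(
                epsilon_squared=self.group_tests["epsilon_squared"].round(3),
                statistic_h=self.group_tests["statistic_h"].round(3),
            ).to_markdown(index=False)
        )
        lines.append("")
        lines.append("## Derived thresholds")
        if len(self.thresholds):
            t = self.thresholds.copy()
            for c in ("auc", "ci_low", "ci_high"):
                t[c] = t[c].round(3)
            t["youden_max"] = t["youden_max"].round(1)
            lines.append(t.to_markdown(index=False))
        else:
            lines.append("(no comparison passed the significance gate)")
        if self.imaging is not None:
            lines.append("")
            lines.append("## Regional associations (top 10 by |rho|)")
            im = self.imaging.head(10).copy()
            im["rho"] = im["rho"].round(3)
            lines.append(im.to_markdown(index=False))
        lines.append("")
        return "\n".join(lines)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _cohort_summary(scored: pd.DataFrame) -> dict:
    groups = [g for g in DIAGNOSTIC_GROUPS if (scored["diagnostic_group"] == g).any()]
    return {
        "n_total": int(len(scored)),
        "group_sizes": {
            g: int((scored["diagnostic_group"] == g).sum()) for g in groups
        },
        "age": {
            g: {
                "mean": float(scored.loc[scored.diagnostic_group == g, "age"].mean()),
                "sd": float(scored.loc[scored.diagnostic_group == g, "age"].std(ddof=1))
                if (scored.diagnostic_group == g).sum() > 1 else 0.0,
            }
            for g in groups
        },
        "n_female": int((scored["sex"] == "female").sum()),
        "id_level_counts": scored["id_level"].value_counts().to_dict(),
    }


def _score_summaries(scored: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for g, sub in scored.groupby("diagnostic_group", sort=False):
        for f in SCORE_FIELDS:
            rows.append(
                {
                    "diagnostic_group": g,
                    "score_field": f,
                    "n": len(sub),
                    "mean": float(sub[f].mean()),
                    "sd": float(sub[f].std(ddof=1)) if len(sub) > 1 else 0.0,
                    "median": float(sub[f].median()),
                    "min": float(sub[f].min()),
                    "max": float(sub[f].max()),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    cohort: str | Path | pd.DataFrame,
    imaging: str | Path | Mapping[str, RegionalTable] | None = None,
    roc: str = "gated",
    significance_level: float = 0.05,
    score_fields: Sequence[str] = SCORE_FIELDS,
    effective_n: int | None = None,
    config_digest: str | None = None,
    seed: int | None = None,
) -> PipelineReport:
    """Run the full analysis and return a :class:`PipelineReport`.

    Parameters
    ----------
    cohort
        Path to a cohort CSV (validated on read) or an already-scored
        cohort frame.
    imaging
        Optional path to a regional-table CSV (wide or long, both
        measures allowed) or a mapping measure -> RegionalTable.
    roc
        ``"gated"`` (default) derives thresholds only for case-vs-control
        pairs whose Dunn-adjusted p <= ``significance_level`` for that
        score field; ``"all"`` derives every case-vs-control pair.
    """
    if roc not in ("gated", "all"):
        raise ValueError(f"roc must be 'gated' or 'all', got {roc!r}")
    if isinstance(cohort, (str, Path)):
        records = read_cohort_csv(cohort)
        logger.info("read %d records from %s", len(records), cohort)
        scored = score_cohort(records)
    else:
        scored = cohort.copy()
    missing = [f for f in score_fields if f not in scored.columns]
    if missing:
        raise ValueError(f"scored cohort lacks score columns {missing}")

    present_groups = [g for g in DIAGNOSTIC_GROUPS if (scored.diagnostic_group == g).any()]
    logger.info("stage 1: scoring complete, n=%d, groups=%s", len(scored), present_groups)

    group_tests, pairwise = group_score_tests(
        scored, score_fields, group_order=present_groups
    )
    logger.info("stage 2: group tests on %d variables, %d pairwise rows",
                len(group_tests), len(pairwise))

    comparisons_by_field: dict[str, list[tuple[str, str]]] = {}
    for f in score_fields:
        pairs = []
        for case in CASE_GROUPS:
            for control in CONTROL_GROUPS:
                if case not in present_groups or control not in present_groups:
                    continue
                if roc == "all":
                    pairs.append((case, control))
                    continue
                row = pairwise[
                    (pairwise.variable == f)
                    & (
                        ((pairwise.group_i == case) & (pairwise.group_j == control))
                        | ((pairwise.group_i == control) & (pairwise.group_j == case))
                    )
                ]
                if len(row) and float(row.iloc[0].p_adjusted) <= significance_level:
                    pairs.append((case, control))
        comparisons_by_field[f] = pairs

    thr_frames = []
    for f, pairs in comparisons_by_field.items():
        if pairs:
            thr_frames.append(
                threshold_table(scored, pairs, score_fields=[f], effective_n=effective_n)
            )
    thresholds = (
        pd.concat(thr_frames, ignore_index=True)
        if thr_frames
        else pd.DataFrame(
            columns=[
                "positive_group", "negative_group", "score_field", "auc", "ci_low",
                "ci_high", "ci_method", "cutoff", "youden_max", "sens_at_cutoff",
                "spec_at_cutoff", "n_positive", "n_negative", "effective_n",
            ]
        )
    )
    logger.info("stage 3: %d threshold rows", len(thresholds))

    imaging_out = None
    if imaging is not None:
        if isinstance(imaging, (str, Path)):
            tables = RegionalTable.from_csv(imaging)
        else:
            tables = dict(imaging)
        frames = []
        for measure in sorted(tables):
            assoc = regional_association(scored, tables[measure])
            n_overlap = int(assoc["n"].iloc[0]) if len(assoc) else 0
            logger.info(
                "stage 4: measure %s, %d regions, %d/%d participants with imaging",
                measure, len(assoc), n_overlap, len(scored),
            )
            frames.append(assoc)
        imaging_out = pd.concat(frames, ignore_index=True)

    provenance = {
        "package_version": _version(),
        "config_digest": config_digest or _digest(scored),
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "n_records_in": int(len(scored)),
        "n_records_excluded": 0,
    }
    return PipelineReport(
        cohort_summary=_cohort_summary(scored),
        score_summaries=_score_summaries(scored),
        group_tests=group_tests,
        pairwise_tests=pairwise,
        thresholds=thresholds,
        imaging=imaging_out,
        provenance=provenance,
    )


def _version() -> str:
    from . import __version__

    return __version__


def _digest(scored: pd.DataFrame) -> str:
    return hashlib.sha256(
        scored.to_csv(index=False).encode("utf-8")
    ).hexdigest()[:16]
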
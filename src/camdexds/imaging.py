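"""Association of interview scores with regional imaging measures.

Correlates the interview total score with per-region amyloid binding
potential (BP_ND, unitless, from PiB PET) and cortical thickness (mm,
from structural MRI) via Spearman partial correlations adjusted for age
and intellectual-disability level, Bonferroni-corrected across regions.

The partial Spearman correlation is the standard rank-then-residualise
construction: every variable is converted to average ranks, the ranks of
x and y are residualised on the rank-transformed covariates (with an
intercept) by least squares, and the Pearson correlation of the
residuals is taken.  The p-value uses a t reference with
n - 2 - n_covariates degrees of freedom; an exact permutation p is
available for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegionalTable",
    "RegionalAssociation",
    "encode_id_level",
    "spearman_partial",
    "regional_association",
]

MEASURES = ("bp_nd", "thickness")

_ID_LEVEL_CODES = {"mild": 1, "moderate": 2, "severe": 3}


def encode_id_level(levels: Sequence[str]) -> np.ndarray:
    """Ordinal coding of intellectual-disability level: mild=1, moderate=2, severe=3."""
    try:
        return np.array([_ID_LEVEL_CODES[l] for l in levels], dtype=float)
    except KeyError as exc:
        raise ValueError(f"unknown id_level {exc.args[0]!r}") from exc


@dataclass
class RegionalTable:
    """Per-participant regional values for one imaging measure.

    ``values`` is indexed by participant_id with one column per region.
    Thickness values must be strictly positive (they are distances in
    mm); BP_ND may be near zero or slightly negative from measurement
    noise, bounded below by ``bp_nd_floor``.
    """

    measure: str
    values: pd.DataFrame
    bp_nd_floor: float = -0.5

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"measure must be one of {MEASURES}, got {self.measure!r}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate region names: {dupes}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate participant_ids in regional table")
        arr = self.values.to_numpy(dtype=float)
        if self.measure == "thickness" and np.any(arr <= 0):
            raise ValueError("cortical thickness values must be strictly positive")
        if self.measure == "bp_nd" and np.any(arr < self.bp_nd_floor):
            raise ValueError(f"BP_ND values below the configured floor {self.bp_nd_floor}")

    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)

    def to_long(self) -> pd.DataFrame:
        long = self.values.reset_index(names="participant_id").melt(
            id_vars="participant_id", var_name="region", value_name="value"
        )
        long.insert(1, "measure", self.measure)
        return long

    @classmethod
    def from_csv(cls, path: str | Path, measure: str | None = None) -> "dict[str, RegionalTable]":
        """Read regional tables from CSV, wide or long format.

        Wide: participant_id, measure, then one column per region.
        Long: participant_id, measure, region, value.
        Returns a dict measure -> table (one or both measures).
        """
        df = pd.read_csv(path)
        if "measure" not in df.columns:
            if measure is None:
                raise ValueError(f"{path}: no 'measure' column and no measure given")
            df["measure"] = measure
        tables = {}
        long_format = {"region", "value"} <= set(df.columns)
        for m, sub in df.groupby("measure"):
            if long_format:
                wide = sub.pivot(index="participant_id", columns="region", values="value")
                wide.columns.name = None
            else:
                wide = sub.drop(columns="measure").set_index("participant_id")
            tables[str(m)] = cls(str(m), wide.astype(float))
        return tables


@dataclass(frozen=True)
class RegionalAssociation:
    """Partial Spearman rho of one region's values with the total score."""

    region: str
    rho: float
    p_raw: float
    p_bonferroni: float
    n: int
    n_covariates: int


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v)


def spearman_partial(
    x,
    y,
    covariates=None,
    method: str = "t",
    n_permutations: int = 10000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Spearman partial correlation of x and y given covariates.

    ``covariates`` is an (n, k) matrix (or None/empty for the plain
    Spearman correlation).  ``method`` is ``"t"`` (default) for the
    t-reference p-value or ``"permutation"`` for an exact Monte-Carlo p
    obtained by permuting the residualised x ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((x.size, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    n, k = cov.shape[0] if cov.size else x.size, cov.shape[1]
    if not (x.size == y.size == n):
        raise ValueError("x, y and covariates must have equal lengths")
    if n < k + 3:
        raise ValueError(f"need at least n_covariates + 3 = {k + 3} observations, got {n}")
    rx, ry = _rank(x), _rank(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValueError("correlation undefined: x or y constant after ranking")
    design = np.column_stack([np.ones(n)] + [_rank(cov[:, j]) for j in range(k)])
    rank_def = np.linalg.matrix_rank(design)
    if rank_def < design.shape[1]:
        raise ValueError(
            "rank-deficient covariates: some covariate columns are collinear "
            "(with each other or constant) after rank transformation"
        )
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    denom = np.sqrt((ex**2).sum() * (ey**2).sum())
    if denom == 0:
        raise ValueError("correlation undefined: residuals have zero variance")
    rho = float(np.clip((ex * ey).sum() / denom, -1.0, 1.0))
    if method == "t":
        df = n - 2 - k
        if df <= 0:
            raise ValueError(f"not enough observations for a t p-value (df={df})")
        if 1.0 - rho * rho < 1e-14:
            p = 0.0
        else:
            t = rho * np.sqrt(df / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df))
    elif method == "permutation":
        rng = rng if rng is not None else np.random.default_rng()
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            r_perm = (ex[perm] * ey).sum() / denom
            if abs(r_perm) >= abs(rho) - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"method must be 't' or 'permutation', got {method!r}")
    return rho, min(1.0, p)


def regional_association(
    scored: pd.DataFrame,
    table: RegionalTable,
    covariate_columns: Sequence[str] = ("age", "id_level"),
    score_field: str = "total",
    method: str = "t",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Partial Spearman correlation of the score with every region.

    Participants lacking imaging are excluded from this stage only (the
    imaging subcohort).  The Bonferroni family is the set of regions in
    the supplied table (one family per measure); output rows are sorted
    by |rho| descending.
    """
    merged = scored.set_index("participant_id").join(table.values, how="inner")
    k = len(covariate_columns)
    if len(merged) < k + 3:
        raise ValueError(
            f"only {len(merged)} participants overlap between cohort and imaging "
            f"table; need at least {k + 3}"
        )
    cov = np.column_stack(
        [
            encode_id_level(merged[c]) if c == "id_level" else merged[c].to_numpy(float)
            for c in covariate_columns
        ]
    ) if k else None
    score = merged[score_field].to_numpy(float)
    m = len(table.regions)
    rows = []
    for region in table.regions:
        rho, p = spearman_partial(
            score, merged[region].to_numpy(float), cov, method=method, rng=rng
        )
        rows.append(
            {
                "region": region,
                "measure": table.measure,
                "rho": rho,
                "p_raw": p,
                "p_bonferroni": min(1.0, m * p),
                "n": len(merged),
                "n_covariates": k,
                "m_regions": m,
            }
        )
    out = pd.DataFrame(rows)
    return out.reindex(out["rho"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )
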
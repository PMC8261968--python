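"""Four-model confounder strategy and the model-strength summary table.

Because PLS latent components mix predictor variance, confounding cannot be
partialled out coefficient-by-coefficient as in multiple linear regression.
Instead four PLS models are fitted per response:

1. spectrum + confounders as predictors,
2. spectrum only,
3. confounders only,
4. spectrum against the response residualized on the confounders
   (all shared response variance ascribed to the confounders — the net
   activity association).

Each model's strength is its Monte-Carlo cross-validated R², with complexity
chosen by the half-SD backwards rule and significance from a permutation
test. The summary table reports the four strengths per response with
significance markers at p < 0.05 (*) and p < 0.01 (**).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import PLS, select_components, cv_r2, permutation_test

logger = logging.getLogger(__name__)

__all__ = [
    "ConfounderDesign",
    "dummy_code",
    "residualize",
    "ModelSuite",
    "ModelSuiteResults",
    "MODEL_LABELS",
]

MODEL_LABELS = (
    "PA and confounders",
    "PA only",
    "Confounders only",
    "PA vs residuals",
)


@dataclass
class ConfounderDesign:
    """Dummy-coded confounder matrix with dropped reference levels."""

    matrix: pd.DataFrame
    categorical: dict  # column -> levels (reference level first)
    continuous: list

    @property
    def column_names(self) -> list:
        return list(self.matrix.columns)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Code a new table with the levels learned at construction."""
        return _code(table, self.categorical, self.continuous,
                     self.matrix.attrs.get("cont_stats", {}))[0].matrix


def _code(table, categorical, continuous, cont_stats=None):
    cols = {}
    stats = {}
    for c in continuous:
        v = table[c].astype(float)
        if cont_stats and c in cont_stats:
            mu, sd = cont_stats[c]
        else:
            mu, sd = v.mean(), v.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            raise ValueError(f"continuous confounder {c!r} is constant")
        stats[c] = (mu, sd)
        cols[c] = (v - mu) / sd
    for c, levels in categorical.items():
        seen = set(pd.unique(table[c].dropna()))
        unseen = seen - set(levels)
        if unseen:
            raise ValueError(f"unseen level(s) {sorted(unseen)} in column {c!r}")
        for lev in levels[1:]:  # reference level dropped
            cols[f"{c}[{lev}]"] = (table[c] == lev).astype(float)
    mat = pd.DataFrame(cols, index=table.index)
    design = ConfounderDesign(mat, categorical, list(continuous))
    mat.attrs["cont_stats"] = stats
    return design, stats


def dummy_code(
    table: pd.DataFrame,
    categorical: list | None = None,
    continuous: list | None = None,
) -> ConfounderDesign:
    """One-hot-minus-reference coding of confounders.

    Categorical columns get ``levels − 1`` indicator columns (first observed
    level is the reference); continuous columns are standardized. Column
    order and levels are recorded so new data can be coded identically.
    """
    if categorical is None:
        categorical = [c for c in table.columns
                       if table[c].dtype == object or isinstance(table[c].dtype, pd.CategoricalDtype)]
    if continuous is None:
        continuous = [c for c in table.columns if c not in categorical]
    cat_levels = {}
    for c in categorical:
        levels = list(pd.unique(table[c].dropna()))
        if len(levels) < 2:
            raise ValueError(f"categorical confounder {c!r} has < 2 levels")
        cat_levels[c] = levels
    design, _ = _code(table, cat_levels, continuous)
    return design


def residualize(y, design: ConfounderDesign | pd.DataFrame | np.ndarray,
                restandardize: bool = True) -> np.ndarray:
    """Remove the confounder association from a response by OLS.

    Fits ordinary least squares of ``y`` on the design (with intercept) and
    returns the residuals, re-standardized by default so downstream model
    strengths stay comparable. Raises on rank deficiency, naming the
    collinear columns.
    """
    mat = design.matrix if isinstance(design, ConfounderDesign) else pd.DataFrame(design)
    y = np.asarray(y, dtype=float).ravel()
    X = np.column_stack([np.ones(len(mat)), mat.to_numpy(dtype=float)])
    if y.shape[0] != X.shape[0]:
        raise ValueError("y and design must align")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        kept = X[:, :1]
        for j, name in enumerate(mat.columns):
            cand = np.column_stack([kept, X[:, j + 1]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(name)
            else:
                kept = cand
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    if restandardize:
        sd = resid.std(ddof=1)
        if sd > 0:
            resid = (resid - resid.mean()) / sd
    return resid


@dataclass
class _ModelCell:
    response: str
    label: str
    strength: float          # cross-validated R^2
    p_value: float
    n_components: int
    n_obs: int

    @property
    def stars(self) -> str:
        return "**" if self.p_value < 0.01 else ("*" if self.p_value < 0.05 else "")


class ModelSuite:
    """The four-model confounder strategy for a set of responses.

    Parameters
    ----------
    spectrum_z : subjects × bins standardized intensity spectrum.
    confounders : raw confounder table (dummy-coded internally).
    responses : subjects × responses outcome table (z-scores or raw).
    """

    def __init__(
        self,
        spectrum_z: pd.DataFrame,
        confounders: pd.DataFrame,
        responses: pd.DataFrame,
        categorical: list | None = None,
        continuous: list | None = None,
        min_complete_n: int = 50,
    ):
        if not (len(spectrum_z) == len(confounders) == len(responses)):
            raise ValueError("spectrum, confounders and responses must align")
        self.spectrum_z = spectrum_z
        self.design = dummy_code(confounders, categorical, continuous)
        self.responses = responses
        self.min_complete_n = min_complete_n

    def fit(
        self,
        a_max: int = 10,
        cv_reps: int = 1000,
        n_perm: int = 10_000,
        perm_reps: int = 100,
        holdout_fraction: float = 0.2,
        cutoff_sd: float = 0.5,
        seed: int = 0,
    ) -> "ModelSuiteResults":
        """Fit all 4 × n_responses models; returns the strength table."""
        spec = self.spectrum_z.to_numpy(dtype=float)
        conf = self.design.matrix.to_numpy(dtype=float)
        cells = []
        fits = {}
        for r_i, resp in enumerate(self.responses.columns):
            yfull = self.responses[resp].to_numpy(dtype=float)
            ok = ~np.isnan(yfull)
            ok &= ~np.isnan(spec).any(axis=1) & ~np.isnan(conf).any(axis=1)
            n_ok = int(ok.sum())
            if n_ok < self.min_complete_n:
                logger.warning("response %r skipped: only %d complete cases",
                               resp, n_ok)
                continue
            y = yfull[ok]
            Xs, Xc = spec[ok], conf[ok]
            resid = residualize(y, pd.DataFrame(Xc, columns=self.design.column_names))
            predictor_sets = {
                MODEL_LABELS[0]: (np.hstack([Xs, Xc]), y),
                MODEL_LABELS[1]: (Xs, y),
                MODEL_LABELS[2]: (Xc, y),
                MODEL_LABELS[3]: (Xs, resid),
            }
            for m_i, (label, (X, yy)) in enumerate(predictor_sets.items()):
                sub_seed = (seed * 131 + r_i * 17 + m_i) % (2**31 - 1)
                cvres = select_components(
                    X, yy, a_max=a_max, n_reps=cv_reps, cutoff_sd=cutoff_sd,
                    holdout_fraction=holdout_fraction, seed=sub_seed)
                perm = permutation_test(
                    X, yy, cvres.selected_a, n_perm=n_perm, seed=sub_seed + 1,
                    n_reps=perm_reps, holdout_fraction=holdout_fraction)
                cells.append(_ModelCell(resp, label, cvres.selected_q2,
                                        perm.p_value, cvres.selected_a, n_ok))
                names = (list(self.spectrum_z.columns) + self.design.column_names
                         if m_i == 0 else
                         list(self.spectrum_z.columns) if m_i in (1, 3)
                         else self.design.column_names)
                res = PLS(yy, X, exog_names=names).fit(
                    n_components=cvres.selected_a, cv_reps=max(cv_reps // 5, 20),
                    holdout_fraction=holdout_fraction, seed=sub_seed)
                res.cv_r2 = cvres.selected_q2
                res.fitted.cv_r2 = cvres.selected_q2
                fits[(resp, label)] = res
        return ModelSuiteResults(cells, fits)


class ModelSuiteResults:
    """Strength table plus access to the underlying per-model PLS results."""

    def __init__(self, cells: list, fits: dict):
        self.cells = cells
        self.fits = fits

    def strength_table(self, percent: bool = True) -> pd.DataFrame:
        """Responses × four-model table of cross-validated R² (optionally %)."""
        rows = {}
        for c in self.cells:
            scale = 100.0 if percent else 1.0
            rows.setdefault(c.response, {})[c.label] = c.strength * scale
        return pd.DataFrame(rows).T.reindex(columns=list(MODEL_LABELS))

    def p_table(self) -> pd.DataFrame:
        rows = {}
        for c in self.cells:
            rows.setdefault(c.response, {})[c.label] = c.p_value
        return pd.DataFrame(rows).T.reindex(columns=list(MODEL_LABELS))

    def complexity_table(self) -> pd.DataFrame:
        rows = {}
        for c in self.cells:
            rows.setdefault(c.response, {})[c.label] = c.n_components
        return pd.DataFrame(rows).T.reindex(columns=list(MODEL_LABELS))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per response × model."""
        return pd.DataFrame([
            {"response": c.response, "model": c.label,
             "cv_r2_pct": c.strength * 100.0, "p_perm": c.p_value,
             "signif": c.stars, "n_components": c.n_components, "n": c.n_obs}
            for c in self.cells
        ])

    def summary(self) -> str:
        """Formatted model-strength table with significance markers."""
        if not self.cells:
            return "Strength of PLS models: no responses had enough complete cases"
        strengths = self.strength_table()
        marks = {(c.response, c.label): c.stars for c in self.cells}
        width = max(len(r) for r in strengths.index) + 2
        head = "Strength of PLS models (cross-validated R^2, %)"
        cols = "".join(f"{label:>22s}" for label in MODEL_LABELS)
        lines = [head, "=" * len(head), " " * width + cols]
        for resp in strengths.index:
            cells = []
            for label in MODEL_LABELS:
                v = strengths.loc[resp, label]
                cells.append(f"{v:>19.1f}{marks.get((resp, label), ''):<3s}")
            lines.append(f"{resp:<{width}s}" + "".join(cells))
        lines.append("* p < 0.05, ** p < 0.01 (permutation test)")
        return "\n".join(lines)
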
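"""Metabolic risk factors: HOMA-IR, stratified z-scores, composite MetS score.

Risk factors (BMI, waist circumference, blood pressure, HDL, triglycerides,
insulin resistance) are standardized to age- and sex-specific z-scores and
combined into a metabolic-syndrome score in which adiposity, insulin
resistance, blood pressure and blood lipids are weighted equally; HDL enters
reversed because higher HDL means better health. Higher score = worse
cardiometabolic profile.

Standardization here is internal to the analysed sample (within age-band ×
sex strata, 2-year bands by default) rather than against external paediatric
reference populations, so each z-column has mean 0 / SD 1 within its stratum
by construction. Blood pressure is additionally adjusted for height by
within-stratum linear regression before standardization.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "RISK_FACTOR_COLUMNS",
    "homa_ir",
    "zscore_panel",
    "mets_score",
    "build_zpanel",
]

#: expected raw panel columns and their units
RISK_FACTOR_COLUMNS = {
    "bmi": "kg/m^2",
    "waist": "cm",
    "sbp": "mmHg",
    "dbp": "mmHg",
    "hdl": "mg/dl",
    "triglycerides": "mg/dl",
    "glucose": "mg/dl",
    "insulin": "uU/ml",
    "height": "cm",
}

#: MetS component weights: waist and IR enter alone, the blood-pressure pair
#: and the lipid pair are averaged, HDL reversed
METS_WEIGHTS = {
    "z_waist": 1.0, "z_ir": 1.0,
    "z_sbp": 0.5, "z_dbp": 0.5,
    "z_tg": 0.5, "z_hdl": -0.5,
}

_HOMA_DENOMINATOR = 405.0  # mass-unit HOMA1-IR: glucose [mg/dl] x insulin [uU/ml] / 405


def homa_ir(glucose_mg_dl, insulin_uu_ml):
    """Homeostatic-model-assessment insulin resistance from fasting values.

    ``IR = glucose [mg/dl] * insulin [uU/ml] / 405``. Non-positive or missing
    inputs propagate to a missing IR (with a warning for non-positive values).
    """
    g = np.asarray(glucose_mg_dl, dtype=float)
    i = np.asarray(insulin_uu_ml, dtype=float)
    bad = ((g <= 0) | (i <= 0)) & ~(np.isnan(g) | np.isnan(i))
    if np.any(bad):
        warnings.warn(f"{int(np.sum(bad))} non-positive glucose/insulin values set to missing")
    ir = g * i / _HOMA_DENOMINATOR
    ir = np.where(bad, np.nan, ir)
    return float(ir) if ir.ndim == 0 else ir


def _age_strata(age: pd.Series, sex: pd.Series, band_years: float,
                min_n: int) -> pd.Series:
    """Assign (sex, age-band) stratum labels, merging bands below min_n.

    Bands are merged upward into their older neighbour (within sex) until
    every stratum holds at least ``min_n`` subjects.
    """
    band = np.floor(age / band_years).astype(int)
    labels = pd.Series(list(zip(sex, band)), index=age.index)
    for s in pd.unique(sex):
        mask = sex == s
        counts = labels[mask].value_counts().sort_index()
        bands = sorted(b for (_, b) in counts.index)
        merged: dict[int, int] = {}
        current, n_cur = [], 0
        for b in bands:
            current.append(b)
            n_cur += counts[(s, b)]
            if n_cur >= min_n:
                for bb in current:
                    merged[bb] = current[-1]
                current, n_cur = [], 0
        if current:  # leftover small tail -> merge into previous stratum
            tail_target = merged[bands[0]] if merged else current[-1]
            targets = sorted(set(merged.values()))
            target = targets[-1] if targets else current[-1]
            for bb in current:
                merged[bb] = target
            if not targets and n_cur < min_n:
                warnings.warn(
                    f"stratum sex={s!r} has only n={n_cur} subjects in total"
                )
        new = labels[mask].map(lambda t: (t[0], merged.get(t[1], t[1])))
        labels[mask] = new
    return labels


def _z_within(values: pd.Series, strata: pd.Series, name: str) -> pd.Series:
    out = pd.Series(np.nan, index=values.index, dtype=float)
    for s, idx in values.groupby(strata).groups.items():
        v = values.loc[idx]
        ok = v.notna()
        if ok.sum() < 2:
            continue
        sd = v[ok].std(ddof=1)
        if sd == 0 or np.isnan(sd):
            warnings.warn(f"{name}: constant within stratum {s!r}; left missing")
            continue
        out.loc[idx] = (v - v[ok].mean()) / sd
    return out


def _height_adjust(values: pd.Series, height: pd.Series, strata: pd.Series) -> pd.Series:
    """Residualize on height within stratum (ordinary least squares)."""
    out = values.copy().astype(float)
    for _, idx in values.groupby(strata).groups.items():
        v = values.loc[idx].to_numpy(float)
        h = height.loc[idx].to_numpy(float)
        ok = ~(np.isnan(v) | np.isnan(h))
        if ok.sum() < 3 or np.std(h[ok]) == 0:
            continue
        X = np.column_stack([np.ones(ok.sum()), h[ok]])
        beta, *_ = np.linalg.lstsq(X, v[ok], rcond=None)
        resid = np.full_like(v, np.nan)
        resid[ok] = v[ok] - X @ beta
        out.loc[idx] = resid
    return out


def zscore_panel(
    panel: pd.DataFrame,
    age_col: str = "age",
    sex_col: str = "sex",
    band_years: float = 2.0,
    min_stratum_n: int = 10,
) -> pd.DataFrame:
    """Standardize the risk-factor panel to age- and sex-specific z-scores.

    Returns a DataFrame with columns z_bmi, z_waist, z_sbp, z_dbp, z_hdl,
    z_tg, z_ir (those present in the input). IR is computed from glucose and
    insulin if not already a column. SBP/DBP are height-adjusted within
    stratum before standardization when a height column is present.
    Missingness propagates per factor.
    """
    if age_col not in panel or sex_col not in panel:
        raise ValueError(f"panel must contain {age_col!r} and {sex_col!r}")
    strata = _age_strata(panel[age_col], panel[sex_col], band_years, min_stratum_n)
    out = pd.DataFrame(index=panel.index)
    out["stratum"] = strata

    ir = panel["ir"] if "ir" in panel else (
        pd.Series(homa_ir(panel["glucose"], panel["insulin"]), index=panel.index)
        if {"glucose", "insulin"} <= set(panel.columns) else None
    )

    sources = {
        "z_bmi": panel.get("bmi"),
        "z_waist": panel.get("waist"),
        "z_sbp": panel.get("sbp"),
        "z_dbp": panel.get("dbp"),
        "z_hdl": panel.get("hdl"),
        "z_tg": panel.get("triglycerides"),
        "z_ir": ir,
    }
    for name, col in sources.items():
        if col is None:
            continue
        col = col.astype(float)
        if name in ("z_sbp", "z_dbp") and "height" in panel:
            col = _height_adjust(col, panel["height"].astype(float), strata)
        out[name] = _z_within(col, strata, name)
    return out


def mets_score(zpanel: pd.DataFrame) -> pd.Series:
    """Composite metabolic-syndrome score.

    ``mets = z_waist + z_ir + (z_sbp + z_dbp)/2 + (z_tg - z_hdl)/2``.
    Missing in any component -> missing score.
    """
    needed = list(METS_WEIGHTS)
    missing_cols = [c for c in needed if c not in zpanel]
    if missing_cols:
        raise ValueError(f"zpanel lacks MetS components: {missing_cols}")
    score = sum(w * zpanel[c] for c, w in METS_WEIGHTS.items())
    return score.rename("mets")


def build_zpanel(panel: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Z-score the panel and append the MetS score (missing where incomplete)."""
    z = zscore_panel(panel, **kwargs)
    if all(c in z for c in METS_WEIGHTS):
        z["mets"] = mets_score(z)
    return z
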
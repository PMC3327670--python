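"""Differential gene expression between paired conditions.

Genes expressed at >= 2 RPKM are tested with a two-sided, equal-variance
Student's t-test on raw RPKM values across replicates; a gene is called
up/down when p < 0.05 and |log1.5 fold change| >= 1 (i.e. fold change
>= 1.5 in either direction).  P-values are reported raw — no
multiple-testing correction by default, with Benjamini-Hochberg
available as an option.

On top of the per-contrast calls sit two classifiers:

* *turned-on* genes — essentially silent (< 2 RPKM) in both the sham and
  exercise-trained heart but up-called and expressed (>= 2 RPKM) under
  pressure overload (TAC); transcriptional activation from a near-zero
  baseline.
* *oppositely regulated* genes — significant in both the pathological
  (sham vs TAC) and physiological (sedentary vs exercise) contrasts,
  with discordant signs.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

DEG_COLUMNS = ["gene_id", "mean_control", "mean_treatment", "fold_change",
               "log15_fc", "t", "p", "tested", "call"]


def student_t(xs, ys, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided Student's t-test; returns ``(t, p)`` with t for xs - ys.

    Degenerate limits: identical constant groups give (0, 1); zero
    pooled variance with unequal means gives (+-inf, 0).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 2 or ys.size < 2:
        raise ValueError("need at least 2 replicates per group")
    n1, n2 = xs.size, ys.size
    d = xs.mean() - ys.mean()
    if equal_var:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * xs.var(ddof=1) + (n2 - 1) * ys.var(ddof=1)) / df
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        v1, v2 = xs.var(ddof=1) / n1, ys.var(ddof=1) / n2
        se = math.sqrt(v1 + v2)
        df = ((v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
              if v1 + v2 > 0 else n1 + n2 - 2)
    if se == 0:
        return (0.0, 1.0) if d == 0 else (math.copysign(math.inf, d), 0.0)
    t = d / se
    return float(t), float(2.0 * stats.t.sf(abs(t), df))


def fold_change(mean_treatment: float, mean_control: float,
                pseudocount: float = 0.25) -> tuple[float, float]:
    """Pseudocounted fold change treatment/control and its log base 1.5."""
    if mean_treatment < 0 or mean_control < 0:
        raise ValueError("means must be non-negative")
    fc = (mean_treatment + pseudocount) / (mean_control + pseudocount)
    return fc, math.log(fc) / math.log(1.5)


def _vector_t(x: np.ndarray, y: np.ndarray, equal_var: bool) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise t-test of x (treatment) minus y (control) with degenerate
    rows handled per :func:`student_t`."""
    n1, n2 = x.shape[1], y.shape[1]
    d = x.mean(axis=1) - y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1)
    v2 = y.var(axis=1, ddof=1)
    if equal_var:
        df = np.full(d.shape, n1 + n2 - 2, dtype=float)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        a, b = v1 / n1, v2 / n2
        se = np.sqrt(a + b)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (a + b) ** 2 / (a ** 2 / (n1 - 1) + b ** 2 / (n2 - 1))
        df = np.where(np.isfinite(df), df, n1 + n2 - 2)
    t = np.zeros_like(d)
    p = np.ones_like(d)
    ok = se > 0
    t[ok] = d[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    degen = ~ok & (d != 0)
    t[degen] = np.sign(d[degen]) * np.inf
    p[degen] = 0.0
    return t, p


def call_degs(rpkm: pd.DataFrame, control_samples, treatment_samples,
              alpha: float = 0.05, min_abs_log15fc: float = 1.0,
              floor: float = 2.0, pseudocount: float = 0.25,
              equal_var: bool = True, bh_correction: bool = False) -> pd.DataFrame:
    """Call DEGs treatment-vs-control on a gene-level RPKM matrix.

    A gene is tested only when the larger of its two group means reaches
    the expression floor; untested genes carry call ``ns`` and NaN
    statistics.  Calls require p < alpha (BH-adjusted if requested) and
    |log1.5 FC| >= ``min_abs_log15fc``.
    """
    control_samples = list(control_samples)
    treatment_samples = list(treatment_samples)
    if set(control_samples) & set(treatment_samples):
        raise ValueError("control and treatment sample sets overlap")
    x = rpkm[treatment_samples].to_numpy(dtype=float)
    y = rpkm[control_samples].to_numpy(dtype=float)
    mean_t = x.mean(axis=1)
    mean_c = y.mean(axis=1)
    fc = (mean_t + pseudocount) / (mean_c + pseudocount)
    l15 = np.log(fc) / np.log(1.5)
    tested = np.maximum(mean_t, mean_c) >= floor

    t = np.full(len(rpkm), np.nan)
    p = np.full(len(rpkm), np.nan)
    if tested.any():
        t[tested], p[tested] = _vector_t(x[tested], y[tested], equal_var)
    p_eff = p.copy()
    if bh_correction and tested.any():
        p_eff[tested] = _bh_adjust(p[tested])

    call = np.full(len(rpkm), "ns", dtype=object)
    with np.errstate(invalid="ignore"):
        sig = tested & (p_eff < alpha)
        call[sig & (l15 >= min_abs_log15fc)] = "up"
        call[sig & (l15 <= -min_abs_log15fc)] = "down"

    return pd.DataFrame({
        "gene_id": rpkm.index, "mean_control": mean_c, "mean_treatment": mean_t,
        "fold_change": fc, "log15_fc": l15, "t": t, "p": p,
        "tested": tested, "call": call,
    }).set_index("gene_id", drop=False)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def classify_turned_on(degs_pah: pd.DataFrame, rpkm: pd.DataFrame,
                       sham_samples, tac_samples, exercise_samples=None,
                       floor: float = 2.0) -> set[str]:
    """Genes activated from near-silence under pressure overload.

    Up-called in sham-vs-TAC, mean < floor RPKM in sham (and in exercise
    when that arm is present), mean >= floor in TAC.
    """
    sham_mean = rpkm[list(sham_samples)].mean(axis=1)
    tac_mean = rpkm[list(tac_samples)].mean(axis=1)
    mask = (degs_pah["call"] == "up") \
        & (sham_mean.reindex(degs_pah.index) < floor) \
        & (tac_mean.reindex(degs_pah.index) >= floor)
    if exercise_samples is not None:
        ex_mean = rpkm[list(exercise_samples)].mean(axis=1)
        mask &= ex_mean.reindex(degs_pah.index) < floor
    return set(degs_pah.index[mask])


def classify_opposite(degs_pah: pd.DataFrame, degs_phh: pd.DataFrame) -> set[str]:
    """Genes significantly regulated in both contrasts with opposite signs."""
    common = degs_pah.index.intersection(degs_phh.index)
    a = degs_pah.loc[common, "call"]
    b = degs_phh.loc[common, "call"]
    opp = ((a == "up") & (b == "down")) | ((a == "down") & (b == "up"))
    return set(common[opp])


def flag_degs(degs_pah: pd.DataFrame, turned_on: set[str],
              opposite: set[str]) -> pd.DataFrame:
    """Attach turned_on/opposite flag columns to a DEG table."""
    out = degs_pah.copy()
    out["turned_on"] = out.index.isin(turned_on)
    out["opposite"] = out.index.isin(opposite)
    return out
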
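"""Exon inclusion/exclusion calling between paired conditions.

For each expressed exon (>= 10 RPKM in at least one of the two compared
conditions) a 2x2 contingency table is built from pooled replicate
counts::

                     control   treatment
        exon reads      a          b
        rest of gene    c          d

Contrasting the exon against the *rest of its gene* (rather than the
whole library) removes gene-level differential expression, so a
significant table reflects a change in exon *usage*.  Significance is a
two-sided Fisher exact test (p < 0.05) combined with a Bayesian
sign-error rate e <= 0.1: with independent posteriors
theta_ctrl ~ Beta(a+1, c+1) and theta_trt ~ Beta(b+1, d+1) under uniform
priors, e is the posterior probability that the apparent direction of
the usage change is wrong.  Surviving exons are reported only when they
carry a knownAlt label, with direction *inclusion* when usage is higher
in the treated condition (TAC / exercise) and *exclusion* when higher in
the control (sham / sedentary).
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import integrate, stats

#: Relative tolerance used when comparing table probabilities for the
#: two-sided tail (near-equal probabilities count as ties).
FISHER_TIE_RTOL = 1e-7

VARIANT_COLUMNS = ["exon_id", "gene_id", "a", "b", "c", "d",
                   "fisher_p", "bayes_e", "direction", "alt_types", "contrast"]


# -- Fisher's exact test ----------------------------------------------------

def _check_table(table) -> tuple[int, int, int, int]:
    (a, b), (c, d) = table
    vals = (int(a), int(b), int(c), int(d))
    if any(v < 0 for v in vals):
        raise ValueError("contingency table entries must be non-negative")
    return vals

def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table ``[[a, b], [c, d]]``.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's
    (within relative tolerance 1e-7 for ties).  A zero margin gives
    p = 1.
    """
    a, b, c, d = _check_table(table)
    return float(fisher_exact_two_sided_batch(
        np.array([a]), np.array([b]), np.array([c]), np.array([d]))[0])


def fisher_exact_two_sided_batch(a, b, c, d) -> np.ndarray:
    """Vectorized :func:`fisher_exact_two_sided` over arrays a, b, c, d."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    out = np.ones(a.shape, dtype=float)
    r1 = a + b
    c1 = a + c
    n = a + b + c + d
    nondegen = (r1 > 0) & (r1 < n) & (c1 > 0) & (c1 < n)
    for i in np.flatnonzero(nondegen):
        ni, r1i, c1i, ai = int(n[i]), int(r1[i]), int(c1[i]), int(a[i])
        amin = max(0, r1i + c1i - ni)
        amax = min(r1i, c1i)
        support = np.arange(amin, amax + 1)
        pmf = _hypergeom_pmf(support, ni, r1i, c1i)
        p_obs = pmf[ai - amin]
        out[i] = min(1.0, float(pmf[pmf <= p_obs * (1.0 + FISHER_TIE_RTOL)].sum()))
    return out


def _hypergeom_pmf(k: np.ndarray, n: int, r1: int, c1: int) -> np.ndarray:
    """Hypergeometric pmf over a support vector via log-gamma (fast and
    accurate to ~1e-14 relative)."""
    logp = (_log_comb(r1, k) + _log_comb(n - r1, c1 - k) - _log_comb(n, c1))
    return np.exp(logp)


def _log_comb(n, k) -> np.ndarray:
    from scipy.special import gammaln
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_upper(table) -> float:
    """One-sided (upper tail) Fisher exact p: P(X >= a) at fixed margins."""
    a, b, c, d = _check_table(table)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(a - 1, n, r1, c1)))


# -- Bayesian sign-error rate ------------------------------------------------

def bayes_error_rate(table, prior: tuple[float, float] = (1.0, 1.0),
                     method: str = "quad", n_draws: int = 200_000,
                     rng=None) -> float:
    """Posterior probability that the apparent usage direction is wrong.

    theta_ctrl ~ Beta(a + prior[0], c + prior[1]) and
    theta_trt ~ Beta(b + prior[0], d + prior[1]) independently;
    e = min(P(theta_trt > theta_ctrl), P(theta_trt < theta_ctrl)).

    ``method="quad"`` (default, deterministic) integrates the smaller
    tail directly, so extreme tables yield accurate tiny values;
    ``method="mc"`` uses seeded Monte Carlo sampling.
    """
    a, b, c, d = _check_table(table)
    a1, b1 = a + prior[0], c + prior[1]   # control Beta params
    a2, b2 = b + prior[0], d + prior[1]   # treatment Beta params

    if method == "mc":
        rng = np.random.default_rng(rng)
        th_c = rng.beta(a1, b1, size=n_draws)
        th_t = rng.beta(a2, b2, size=n_draws)
        p_hi = float(np.mean(th_t > th_c))
        return min(p_hi, 1.0 - p_hi)
    if method != "quad":
        raise ValueError(f"unknown method {method!r}")

    mean_c = a1 / (a1 + b1)
    mean_t = a2 / (a2 + b2)
    # Integrate the probability of the *less* likely ordering directly —
    # P(theta_trt < theta_ctrl) = int f_trt(y) * SF_ctrl(y) dy — to avoid
    # the 1 - (almost 1) cancellation on extreme tables.
    if mean_t >= mean_c:
        lo_a, lo_b, hi_a, hi_b = a2, b2, a1, b1   # error: trt below ctrl
    else:
        lo_a, lo_b, hi_a, hi_b = a1, b1, a2, b2
    f = lambda y: stats.beta.pdf(y, lo_a, lo_b) * stats.beta.sf(y, hi_a, hi_b)
    # Restrict to where the pdf factor carries mass; the discarded tails
    # contribute at most ~2e-16 in absolute terms.
    left = float(stats.beta.ppf(1e-16, lo_a, lo_b))
    right = float(stats.beta.ppf(1.0 - 1e-16, lo_a, lo_b))
    pts = [x for x in (lo_a / (lo_a + lo_b), hi_a / (hi_a + hi_b))
           if left < x < right]
    e, _ = integrate.quad(f, left, right, points=sorted(set(pts)) or None,
                          limit=200, epsabs=1e-14, epsrel=1e-10)
    return float(min(max(e, 0.0), 1.0))


# -- filter cascade ----------------------------------------------------------

def exon_rpkm_filter(rpkm_exon: pd.DataFrame, control_samples,
                     treatment_samples, threshold: float = 10.0) -> pd.Index:
    """Exons testable for the contrast: mean RPKM >= threshold in at
    least one of the two compared conditions."""
    mc = rpkm_exon[list(control_samples)].mean(axis=1)
    mt = rpkm_exon[list(treatment_samples)].mean(axis=1)
    return rpkm_exon.index[(mc >= threshold) | (mt >= threshold)]


def build_contingency(exon_counts: pd.DataFrame, gene_counts: pd.DataFrame,
                      exon_gene: pd.Series, control_samples,
                      treatment_samples,
                      exons: pd.Index | None = None) -> pd.DataFrame:
    """Pooled exon-vs-rest-of-gene tables for one contrast.

    Replicates are summed within condition.  Non-testable exons are
    dropped: single-exon genes (no rest-of-gene) and genes with zero
    reads in either condition (degenerate margin).
    """
    if exons is None:
        exons = exon_counts.index
    ec = exon_counts.loc[exons]
    a = ec[list(control_samples)].sum(axis=1)
    b = ec[list(treatment_samples)].sum(axis=1)
    genes = exon_gene.reindex(exons)
    g_ctrl = gene_counts[list(control_samples)].sum(axis=1).reindex(genes).to_numpy()
    g_trt = gene_counts[list(treatment_samples)].sum(axis=1).reindex(genes).to_numpy()
    c = g_ctrl - a.to_numpy()
    d = g_trt - b.to_numpy()
    if (c < 0).any() or (d < 0).any():
        raise ValueError("exon counts exceed gene counts")
    df = pd.DataFrame({"exon_id": exons, "gene_id": genes.to_numpy(),
                       "a": a.to_numpy(), "b": b.to_numpy(), "c": c, "d": d})
    # drop degenerate tables: no rest-of-gene, or a condition without reads
    keep = ((df["c"] + df["d"]) > 0) & ((df["a"] + df["c"]) > 0) \
        & ((df["b"] + df["d"]) > 0)
    return df.loc[keep].set_index("exon_id", drop=False)


def call_exon_variants(contingency: pd.DataFrame,
                       alt_types: Mapping[str, frozenset],
                       contrast: str, alpha: float = 0.05,
                       e_max: float = 0.1,
                       bayes_method: str = "quad",
                       rng=None) -> pd.DataFrame:
    """Apply the Fisher + Bayes-error + knownAlt cascade to contingencies.

    Direction is *inclusion* when pooled exon usage is higher in the
    treated condition, *exclusion* otherwise.  Only exons with a
    non-empty knownAlt label set are reported.
    """
    df = contingency
    fisher_p = fisher_exact_two_sided_batch(
        df["a"].to_numpy(), df["b"].to_numpy(),
        df["c"].to_numpy(), df["d"].to_numpy())
    # the Bayes error only matters for tables that already pass Fisher
    bayes_e = np.ones(len(df))
    for i in np.flatnonzero(fisher_p < alpha):
        r = df.iloc[i]
        bayes_e[i] = bayes_error_rate(
            ((int(r["a"]), int(r["b"])), (int(r["c"]), int(r["d"]))),
            method=bayes_method, rng=rng)
    usage_c = df["a"] / (df["a"] + df["c"])
    usage_t = df["b"] / (df["b"] + df["d"])
    direction = np.where(usage_t.to_numpy() > usage_c.to_numpy(),
                         "inclusion", "exclusion")
    types = [alt_types.get(x, frozenset()) for x in df["exon_id"]]
    keep = (fisher_p < alpha) & (bayes_e <= e_max) \
        & np.array([len(t) > 0 for t in types])
    out = pd.DataFrame({
        "exon_id": df["exon_id"].to_numpy(), "gene_id": df["gene_id"].to_numpy(),
        "a": df["a"].to_numpy(), "b": df["b"].to_numpy(),
        "c": df["c"].to_numpy(), "d": df["d"].to_numpy(),
        "fisher_p": fisher_p, "bayes_e": bayes_e, "direction": direction,
        "alt_types": [",".join(sorted(t)) for t in types],
        "contrast": contrast,
    })
    return out.loc[keep].set_index("exon_id", drop=False)


def detect_exon_variants(exon_counts: pd.DataFrame, gene_counts: pd.DataFrame,
                         rpkm_exon: pd.DataFrame, annotation,
                         samples: pd.DataFrame,
                         contrasts: Mapping[str, tuple[str, str]] | None = None,
                         rpkm_threshold: float = 10.0, alpha: float = 0.05,
                         e_max: float = 0.1,
                         bayes_method: str = "quad", rng=None) -> pd.DataFrame:
    """Full per-contrast cascade: RPKM filter -> contingency -> calls."""
    from .quantify import CONTRASTS
    if contrasts is None:
        contrasts = CONTRASTS
    exon_gene = annotation.exon_gene_map()
    alt = annotation.alt_types_map()
    frames = []
    for name, (ctrl_cond, trt_cond) in contrasts.items():
        ctrl = samples.loc[samples["condition"] == ctrl_cond, "sample_id"].tolist()
        trt = samples.loc[samples["condition"] == trt_cond, "sample_id"].tolist()
        testable = exon_rpkm_filter(rpkm_exon, ctrl, trt, threshold=rpkm_threshold)
        tables = build_contingency(exon_counts, gene_counts, exon_gene,
                                   ctrl, trt, exons=testable)
        frames.append(call_exon_variants(tables, alt, name, alpha=alpha,
                                         e_max=e_max, bayes_method=bayes_method,
                                         rng=rng))
    if not frames:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    return pd.concat(frames, axis=0, ignore_index=True)


def summarize_variant_types(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-contrast counts of inclusions/exclusions and the AS-type mix.

    An exon carrying k knownAlt labels contributes 1/k to each of its
    types, so type proportions sum to 1 within a contrast.
    """
    rows = []
    if len(calls) == 0:
        return pd.DataFrame(columns=["contrast", "n_calls", "n_inclusion",
                                     "n_exclusion", "alt_type", "weight",
                                     "proportion"])
    for contrast, sub in calls.groupby("contrast", sort=False):
        n_inc = int((sub["direction"] == "inclusion").sum())
        n_exc = int((sub["direction"] == "exclusion").sum())
        weights: dict[str, float] = {}
        for ts in sub["alt_types"]:
            labels = [t for t in str(ts).split(",") if t]
            for t in labels:
                weights[t] = weights.get(t, 0.0) + 1.0 / len(labels)
        total = sum(weights.values())
        for t in sorted(weights):
            rows.append({"contrast": contrast, "n_calls": len(sub),
                         "n_inclusion": n_inc, "n_exclusion": n_exc,
                         "alt_type": t, "weight": weights[t],
                         "proportion": weights[t] / total})
    return pd.DataFrame(rows)
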
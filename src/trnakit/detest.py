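"""Differential expression at sequence-group level.

The pipeline follows the classic count-based recipe: TMM normalization
(trimmed mean of M-values), a pooled method-of-moments estimate of the
negative-binomial dispersion phi (variance = mu + phi * mu^2), and a
two-sided exact test on the conditional distribution of the group-A count sum
given the total, with Benjamini-Hochberg control of the false discovery rate.
A feature is called differentially expressed only when both the p-value and
the FDR are <= alpha.

Before testing, a treatment-aware prefilter keeps a feature iff its CPM reaches
the threshold in ALL control samples, or in ALL ART-normal samples, or in at
least ``los_min`` ART-LOS samples.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom, nbinom
from statsmodels.stats.multitest import multipletests

from trnakit.quantify import CountMatrix, cpm, validate_sample_sheet

log = logging.getLogger(__name__)

ROLES = ("control", "normal", "los")


def _samples_by_role(meta: pd.DataFrame, role_map: Mapping[str, str], tissue=None):
    """role -> list of sample ids; ``role_map`` maps treatment label -> role."""
    meta = validate_sample_sheet(meta)
    if tissue is not None:
        meta = meta[meta["tissue"] == tissue]
    present = set(meta["treatment"])
    unmapped = present - set(role_map)
    if unmapped:
        raise ValueError(f"treatment labels without a role mapping: {sorted(unmapped)}")
    out = {r: [] for r in ROLES}
    for sid, row in meta.iterrows():
        out[role_map[row["treatment"]]].append(sid)
    return out


def de_prefilter(
    matrix: CountMatrix,
    meta: pd.DataFrame,
    role_map: Mapping[str, str],
    cpm_threshold: float = 5.0,
    los_min: int = 2,
    tissue=None,
) -> list:
    """Features kept for DE: CPM >= threshold (inclusive) in all control
    samples, OR all normal samples, OR >= ``los_min`` LOS samples."""
    by_role = _samples_by_role(meta, role_map, tissue)
    c = cpm(matrix).values

    def _all_of(role):
        cols = by_role[role]
        if not cols:                      # absent group cannot satisfy the clause
            return pd.Series(False, index=c.index)
        return (c[cols] >= cpm_threshold).all(axis=1)

    keep_los = (c[by_role["los"]] >= cpm_threshold).sum(axis=1) >= los_min
    kept = c.index[_all_of("control") | _all_of("normal") | keep_los]
    return list(kept)


def tmm_factors(
    matrix: CountMatrix,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors.

    The reference sample is the column whose upper quartile of scaled counts
    is closest to the mean upper quartile (lowest index on ties).  For each
    sample, log2 ratios M against the reference are trimmed by
    ``logratio_trim`` on each side and by ``abs_trim`` on absolute intensity
    A, then averaged with precision weights; factors are rescaled so their
    geometric mean is 1.  All-zero columns get factor 1 with a warning.
    """
    counts = matrix.values.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    samples = list(matrix.values.columns)
    n = len(samples)
    if n < 2:
        raise ValueError("TMM needs at least 2 samples")

    zero_cols = lib == 0
    if zero_cols.any():
        log.warning("all-zero columns %s get TMM factor 1",
                    [samples[i] for i in np.flatnonzero(zero_cols)])
    safe_lib = np.where(zero_cols, 1.0, lib)
    frac = counts / safe_lib

    uq = np.array([
        np.quantile(frac[counts[:, j] > 0, j], 0.75) if (counts[:, j] > 0).any() else 0.0
        for j in range(n)
    ])
    ref = int(np.argmin(np.abs(uq - uq.mean())))   # argmin takes lowest index on ties

    factors = np.ones(n)
    fr, lr = frac[:, ref], lib[ref]
    for j in range(n):
        if j == ref or zero_cols[j]:
            continue
        fj, lj = frac[:, j], lib[j]
        ok = (counts[:, j] > 0) & (counts[:, ref] > 0)
        if ok.sum() == 0:
            continue
        m = np.log2(fj[ok] / fr[ok])
        a = 0.5 * np.log2(fj[ok] * fr[ok])
        # asymptotic (delta-method) variance of M
        w = (lj - counts[ok, j]) / (lj * counts[ok, j]) + \
            (lr - counts[ok, ref]) / (lr * counts[ok, ref])
        # double trim: central portion by M and by A
        lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(a, [abs_trim, 1 - abs_trim])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0:
            keep = np.ones_like(m, dtype=bool)
        factors[j] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))

    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples)


def effective_library_sizes(matrix: CountMatrix, factors: pd.Series | None = None) -> pd.Series:
    lib = matrix.library_sizes().astype(float)
    if factors is not None:
        lib = lib * factors.reindex(lib.index)
    return lib


def _scaled_counts(matrix: CountMatrix, samples: Sequence, factors=None) -> pd.DataFrame:
    """Counts rescaled to a common effective library size, rounded
    deterministically (nearest integer, half to even)."""
    eff = effective_library_sizes(matrix, factors)[list(samples)]
    eff = eff.replace(0, 1.0)
    common = float(np.exp(np.mean(np.log(eff))))
    return np.rint(matrix.values[list(samples)] * (common / eff)).astype(int)


def common_dispersion(
    matrix: CountMatrix,
    groups: Mapping[str, Sequence] | pd.Series,
    factors: pd.Series | None = None,
) -> float:
    """Pooled method-of-moments NB dispersion across features.

    After rescaling samples to a common effective library size, within-group
    sample means mu and variances s^2 satisfy E[s^2 - mu] = phi * mu^2 under
    the NB model; phi is estimated as the ratio of pooled sums (weighted by
    within-group degrees of freedom) and floored at 0.
    """
    if isinstance(groups, pd.Series):
        group_map: dict = {}
        for sid, lab in groups.items():
            group_map.setdefault(lab, []).append(sid)
    else:
        group_map = {k: list(v) for k, v in groups.items()}

    num = 0.0
    den = 0.0
    any_replicated = False
    for label, samples in group_map.items():
        if len(samples) < 2:
            continue
        any_replicated = True
        scaled = _scaled_counts(matrix, samples, factors).to_numpy(dtype=float)
        mu = scaled.mean(axis=1)
        s2 = scaled.var(axis=1, ddof=1)
        df = len(samples) - 1
        num += df * float(np.sum(s2 - mu))
        den += df * float(np.sum(mu**2))
    if not any_replicated:
        log.warning("no group has >= 2 samples; dispersion set to 0")
        return 0.0
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def _exact_p(ya: int, yb: int, na: int, nb: int, phi: float) -> float:
    """Two-sided exact p for a group-A sum of ``ya`` given total ya+yb.

    Conditional on the total, the A-sum follows the ratio of NB(na*mu, phi/na)
    x NB(nb*mu, phi/nb) masses (binomial split when phi = 0); the p-value sums
    the probabilities of all outcomes no more likely than the observed one,
    which makes the test symmetric in the two groups.
    """
    total = ya + yb
    if total == 0:
        return 1.0
    k = np.arange(total + 1)
    if phi <= 0:
        logp = binom.logpmf(k, total, na / (na + nb))
    else:
        mu = total / (na + nb)
        ra, rb = na / phi, nb / phi
        la = nbinom.logpmf(k, ra, ra / (ra + na * mu))
        lb = nbinom.logpmf(total - k, rb, rb / (rb + nb * mu))
        logp = la + lb
        logp = logp - logsumexp(logp)
    obs = logp[ya]
    p = float(np.exp(logsumexp(logp[logp <= obs + 1e-10])))
    return min(1.0, p)


def nb_exact_test(
    matrix: CountMatrix,
    samples_a: Sequence,
    samples_b: Sequence,
    phi: float,
    factors: pd.Series | None = None,
) -> pd.Series:
    """Per-feature two-sided exact NB p-values for group A vs group B.

    Counts are first rescaled to a common TMM-adjusted library size with
    deterministic rounding; features all-zero in both groups get p = 1.
    """
    sa = _scaled_counts(matrix, samples_a, factors)
    sb = _scaled_counts(matrix, samples_b, factors)
    na, nb = len(list(samples_a)), len(list(samples_b))
    ya = sa.sum(axis=1)
    yb = sb.sum(axis=1)
    pvals = [
        _exact_p(int(a), int(b), na, nb, phi) for a, b in zip(ya, yb)
    ]
    return pd.Series(pvals, index=matrix.values.index, name="p_value")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Set ``called`` (p <= alpha AND fdr <= alpha, inclusive) and
    ``direction`` from the sign of the log2 fold change."""
    out = results.copy()
    out["called"] = (out["p_value"] <= alpha) & (out["fdr"] <= alpha)
    out["direction"] = np.where(
        ~out["called"], "none", np.where(out["log2_fold_change"] > 0, "up", "down")
    )
    return out


def differential_expression(
    matrix: CountMatrix,
    meta: pd.DataFrame,
    role_map: Mapping[str, str],
    contrast: tuple = ("control", "los"),
    tissue=None,
    phi: float | None = None,
    cpm_threshold: float = 5.0,
    los_min: int = 2,
    alpha: float = 0.05,
    prefilter: bool = True,
) -> pd.DataFrame:
    """End-to-end DE for one contrast: prefilter, TMM, dispersion, exact test,
    BH, calling.  ``contrast`` names two roles; fold changes are B over A on
    mean CPM with a 0.5 pseudocount.
    """
    role_a, role_b = contrast
    meta = validate_sample_sheet(meta)
    by_role = _samples_by_role(meta, role_map, tissue)
    sa, sb = by_role[role_a], by_role[role_b]
    used = sa + sb
    sub = CountMatrix(values=matrix.values[used], scale="raw")
    meta_tissue = meta[meta["tissue"] == tissue] if tissue is not None else meta

    features = (
        de_prefilter(CountMatrix(values=matrix.values[list(meta_tissue.index)], scale="raw"),
                     meta_tissue, role_map, cpm_threshold, los_min)
        if prefilter else list(sub.values.index)
    )
    sub = CountMatrix(values=sub.values.loc[features], scale="raw")

    factors = tmm_factors(sub) if len(used) >= 2 else None
    if phi is None:
        phi = common_dispersion(sub, {role_a: sa, role_b: sb}, factors)

    p = nb_exact_test(sub, sa, sb, phi, factors)
    c = cpm(sub).values
    mean_a = c[sa].mean(axis=1)
    mean_b = c[sb].mean(axis=1)
    res = pd.DataFrame(
        {
            "mean_cpm_a": mean_a,
            "mean_cpm_b": mean_b,
            "log2_fold_change": np.log2((mean_b + 0.5) / (mean_a + 0.5)),
            "p_value": p,
            "fdr": bh_adjust(p.to_numpy()),
        },
        index=sub.values.index,
    )
    res.attrs["phi"] = phi
    return call_de(res, alpha)
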
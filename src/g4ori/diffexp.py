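"""Differential origin activity and five-class response assignment.

Counts per origin and sample are modelled as negative binomial.  Samples
are normalized with median-of-ratios size factors, a method-of-moments
dispersion is estimated, and a Wald test on the log2 fold change (treated
vs control) yields per-origin p-values that are Benjamini-Hochberg
adjusted.  Origins are then assigned to one of five response classes —
insensitive, new, reinforced, reduced, suppressed — from the fold change,
the FDR, and per-condition peak reproducibility:

* ``new``        significant up   and absent in control
* ``suppressed`` significant down and absent in treated
* ``reinforced`` significant up   and present in both conditions
* ``reduced``    significant down and present in both conditions
* ``insensitive`` everything else

where significant means FDR <= 0.01 and |log2FC| >= 1 by default.

With two or three replicates per condition a per-origin dispersion is
essentially unidentifiable, so the default estimator pools the
method-of-moments dispersion across all origins (and both conditions)
into a single common value; a per-origin estimator is available via
``dispersion="per-origin"``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import ValidationError

__all__ = [
    "CLASS_LABELS",
    "normalize_counts",
    "nb_differential",
    "bh_adjust",
    "classify_origins",
    "class_summary",
    "class_summary_from_percentages",
]

logger = logging.getLogger(__name__)

CLASS_LABELS = ("insensitive", "new", "reinforced", "reduced", "suppressed")

_LOG2FC_PSEUDOCOUNT = 0.5  # added to normalized means so new/suppressed have finite FC
_DISPERSION_FLOOR = 1e-8


def _check_design(counts: pd.DataFrame, conditions: dict[str, str]) -> tuple[list, list]:
    ctrl = [s for s in counts.columns if conditions.get(s) == "control"]
    trt = [s for s in counts.columns if conditions.get(s) == "treated"]
    missing = [s for s in counts.columns if s not in conditions]
    if missing:
        raise ValidationError(f"samples missing from condition map: {missing}")
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValidationError(
            f"need >=2 samples per condition, got {len(ctrl)} control / {len(trt)} treated"
        )
    return ctrl, trt


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    The pseudo-reference is the per-origin geometric mean over samples,
    computed on origins with all-positive counts; each sample's size
    factor is the median ratio of its counts to the reference.  When no
    origin has all-positive counts, total-count scaling is used instead
    (with a warning).
    """
    m = counts.to_numpy(dtype=np.float64)
    if (m < 0).any():
        raise ValidationError("negative counts")
    if (m.sum(axis=0) == 0).any():
        raise ValidationError("a sample has no counts at all")
    all_pos = (m > 0).all(axis=1)
    if all_pos.any():
        logref = np.mean(np.log(m[all_pos]), axis=1)  # log geometric mean
        ratios = np.log(m[all_pos]) - logref[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    else:
        warnings.warn(
            "no origin with all-positive counts; falling back to total-count scaling"
        )
        totals = m.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    sf = pd.Series(factors, index=counts.columns, name="size_factor")
    return sf, counts / factors


def _common_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> float:
    """Global method-of-moments NB dispersion pooled over origins and conditions.

    Solves sum(df * (s^2 - mu)) = alpha * sum(df * mu^2) over all origins
    and both conditions, clipping at the floor.
    """
    num = 0.0
    den = 0.0
    for idx in groups:
        sub = norm[:, idx]
        n = sub.shape[1]
        if n < 2:
            continue
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        df = n - 1
        num += df * float(np.sum(s2 - mu))
        den += df * float(np.sum(mu**2))
    if den <= 0:
        return _DISPERSION_FLOOR
    return max(num / den, _DISPERSION_FLOOR)


def _per_origin_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for idx in groups:
        sub = norm[:, idx]
        n = sub.shape[1]
        if n < 2:
            continue
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        df = n - 1
        num += df * (s2 - mu)
        den += df * mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, _DISPERSION_FLOOR)
    return np.maximum(alpha, _DISPERSION_FLOOR)


def nb_differential(
    counts: pd.DataFrame,
    conditions: dict[str, str],
    dispersion: str = "common",
) -> pd.DataFrame:
    """Negative-binomial Wald test of treated vs control per origin.

    Returns a DataFrame indexed like ``counts`` with columns baseMeanCtrl,
    baseMeanTrt, log2FC, pvalue, FDR.  log2FC is the log2 ratio of
    normalized condition means with a pseudo-count of 0.5; the Wald
    standard error comes from the delta method with NB variance
    ``mu + alpha * mu^2``.  Origins with zero counts in both conditions
    get log2FC 0 and p 1.
    """
    ctrl, trt = _check_design(counts, conditions)
    if dispersion not in ("common", "per-origin"):
        raise ValidationError(f"unknown dispersion mode {dispersion!r}")
    _, norm_df = normalize_counts(counts)
    norm = norm_df.to_numpy(dtype=np.float64)
    idx_c = np.array([counts.columns.get_loc(s) for s in ctrl])
    idx_t = np.array([counts.columns.get_loc(s) for s in trt])
    groups = [idx_c, idx_t]
    if dispersion == "common":
        alpha = np.full(norm.shape[0], _common_dispersion(norm, groups))
    else:
        alpha = _per_origin_dispersion(norm, groups)

    mu_c = norm[:, idx_c].mean(axis=1)
    mu_t = norm[:, idx_t].mean(axis=1)
    nc, nt = len(idx_c), len(idx_t)
    pc = _LOG2FC_PSEUDOCOUNT
    lfc = np.log2(mu_t + pc) - np.log2(mu_c + pc)
    # delta method on log2 of the condition mean: Var(log2 m) ~ Var(m)/((m+pc) ln2)^2
    var_mc = (mu_c + alpha * mu_c**2) / nc
    var_mt = (mu_t + alpha * mu_t**2) / nt
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt((var_mc / (mu_c + pc) ** 2 + var_mt / (mu_t + pc) ** 2) / ln2sq)
    both_zero = (mu_c == 0) & (mu_t == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    pvalue = 2 * stats.norm.sf(np.abs(z))
    pvalue = np.where(both_zero, 1.0, pvalue)
    lfc = np.where(both_zero, 0.0, lfc)
    out = pd.DataFrame(
        {
            "baseMeanCtrl": mu_c,
            "baseMeanTrt": mu_t,
            "log2FC": lfc,
            "pvalue": pvalue,
        },
        index=counts.index,
    )
    out["FDR"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.ndim != 1:
        raise ValidationError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]  # step-up monotonicity
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def classify_origins(
    diff: pd.DataFrame,
    presence: pd.DataFrame,
    fdr_max: float = 0.01,
    lfc_min: float = 1.0,
) -> pd.Series:
    """Assign each origin to one of the five response classes.

    ``presence`` must carry boolean columns ``present_ctrl`` and
    ``present_trt`` aligned with ``diff``.  Origins whose flags contradict
    their fold change direction (significant up yet absent in treated, or
    significant down yet absent in control) are assigned ``insensitive``
    and logged.
    """
    for col in ("present_ctrl", "present_trt"):
        if col not in presence.columns:
            raise ValidationError(f"presence table lacks column {col!r}")
    pc = presence["present_ctrl"].to_numpy(bool)
    pt = presence["present_trt"].to_numpy(bool)
    lfc = diff["log2FC"].to_numpy()
    fdr = diff["FDR"].to_numpy()
    sig = (fdr <= fdr_max) & (np.abs(lfc) >= lfc_min)
    up = sig & (lfc > 0)
    down = sig & (lfc < 0)

    labels = np.full(len(diff), "insensitive", dtype=object)
    labels[up & ~pc] = "new"
    labels[up & pc & pt] = "reinforced"
    labels[down & ~pt] = "suppressed"
    labels[down & pc & pt] = "reduced"
    inconsistent = (up & ~pt & pc) | (down & ~pc & pt)
    if inconsistent.any():
        n_bad = int(inconsistent.sum())
        logger.warning(
            "%d origins with presence flags contradicting fold change; "
            "assigned insensitive", n_bad,
        )
        labels[inconsistent] = "insensitive"
    return pd.Series(labels, index=diff.index, name="class")


def class_summary(classes: pd.Series) -> pd.DataFrame:
    """Per-class counts, percent of all origins, and percent of affected.

    Affected origins are all non-insensitive ones; each class's share of
    the affected set is reported in ``pct_of_affected`` (0 for the
    insensitive row, and 0 with a flag when nothing is affected).
    """
    if len(classes) == 0:
        raise ValidationError("empty classification")
    total = len(classes)
    n_affected = int((classes != "insensitive").sum())
    rows = []
    for label in CLASS_LABELS:
        n = int((classes == label).sum())
        share = (
            100.0 * n / n_affected
            if (n_affected > 0 and label != "insensitive")
            else 0.0
        )
        rows.append(
            {
                "class": label,
                "count": n,
                "pct_of_all": 100.0 * n / total,
                "pct_of_affected": share,
            }
        )
    out = pd.DataFrame(rows).set_index("class")
    out.attrs["n_affected"] = n_affected
    out.attrs["no_affected_flag"] = n_affected == 0
    return out


def class_summary_from_percentages(pct_of_all: dict[str, float]) -> pd.DataFrame:
    """Share-of-affected arithmetic from per-class percentages.

    Accepts percentages of all origins for at least four classes; a single
    missing class is filled by complement to 100.  Returns the same layout
    as :func:`class_summary` minus counts.
    """
    pct = dict(pct_of_all)
    missing = [c for c in CLASS_LABELS if c not in pct]
    if len(missing) > 1:
        raise ValidationError(f"more than one class percentage missing: {missing}")
    if missing:
        pct[missing[0]] = 100.0 - sum(pct.values())
    total = sum(pct.values())
    if not np.isclose(total, 100.0, atol=0.5):
        raise ValidationError(f"class percentages sum to {total}, expected ~100")
    affected = sum(v for c, v in pct.items() if c != "insensitive")
    rows = []
    for label in CLASS_LABELS:
        share = (
            100.0 * pct[label] / affected
            if (affected > 0 and label != "insensitive")
            else 0.0
        )
        rows.append(
            {"class": label, "pct_of_all": pct[label], "pct_of_affected": share}
        )
    return pd.DataFrame(rows).set_index("class")
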
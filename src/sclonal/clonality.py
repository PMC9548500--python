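"""Tumor clonality testing from CNA-profile correlations.

Two lesions that derive from one ancestral clone inherit its chromosomal
gains and losses, so their mean CNA profiles are strongly concordant. The
similarity statistic is the Pearson correlation between tumors' mean CNA
vectors; the null is the set of correlations among designated *unrelated*
tumor pairs, and the one-sided (upper-tail) p-value asks whether the tested
pair is more similar than unrelated pairs can explain.

Two p-value recipes are provided: an empirical plus-one tail fraction, and a
gaussian tail fitted to the Fisher-z-transformed null (default — finer
granularity than the empirical fraction over a handful of unrelated pairs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cna import TumorProfileSet

__all__ = ["ClonalityResult", "cna_correlation_matrix", "null_distribution", "clonality_pvalues", "test_clonality"]


@dataclass
class ClonalityResult:
    """Correlation matrix, unrelated-pair null sample, and per-pair p-values."""

    labels: list[str]
    r_matrix: pd.DataFrame
    null_sample: np.ndarray
    tested_pairs: list[tuple[str, str]]
    related_pairs: list[tuple[str, str]]
    pvalues: pd.DataFrame  # columns: label_a, label_b, r, p, method

    def summary(self) -> str:
        lines = [
            f"Clonality test over {len(self.labels)} tumor profiles",
            f"null sample: {len(self.null_sample)} unrelated-pair correlations "
            f"(median r = {np.median(self.null_sample):.3f})",
        ]
        for _, row in self.pvalues.iterrows():
            lines.append(
                f"  {row['label_a']} ~ {row['label_b']}: r = {row['r']:.3f}, "
                f"one-sided p = {row['p']:.4g} ({row['method']})"
            )
        return "\n".join(lines)


def cna_correlation_matrix(profiles: TumorProfileSet) -> pd.DataFrame:
    """Pearson correlation between every pair of mean CNA profiles.

    Profiles are restricted to the common gene index. A zero-variance profile
    has undefined correlations; these are reported as NaN with a warning.
    """
    P = profiles.profiles.dropna()
    if P.shape[1] < 2:
        raise ValueError("need at least 2 profiles")
    if P.shape[0] < 3:
        raise ValueError("common gene index too short (< 3 genes)")
    sd = P.std(axis=0, ddof=0)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        warnings.warn(f"zero-variance profiles (correlation undefined): {degenerate}")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(P.to_numpy().T)
    np.fill_diagonal(r, 1.0)
    r[np.ix_([P.columns.get_loc(c) for c in degenerate], range(P.shape[1]))] = np.nan
    r[np.ix_(range(P.shape[1]), [P.columns.get_loc(c) for c in degenerate])] = np.nan
    return pd.DataFrame(r, index=P.columns, columns=P.columns)


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def null_distribution(
    r_matrix: pd.DataFrame,
    related_pairs=(),
    tested_labels=(),
) -> np.ndarray:
    """Off-diagonal correlations of pairs with BOTH members outside the tested
    set and not designated as related — the empirical unrelated-pair null."""
    labels = list(r_matrix.columns)
    related = {_norm_pair(*p) for p in related_pairs}
    tested = set(tested_labels)
    null = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if a in tested or b in tested:
                continue
            if _norm_pair(a, b) in related:
                continue
            null.append(r_matrix.loc[a, b])
    null = np.asarray(null, dtype=float)
    null = null[~np.isnan(null)]
    if len(null) == 0:
        raise ValueError("empty null distribution: every pair is tested or related")
    return null


def clonality_pvalues(
    r_obs: dict[tuple[str, str], float],
    null_sample: np.ndarray,
    method: str = "gaussian",
    fisher_z: bool = True,
) -> pd.DataFrame:
    """One-sided upper-tail p-value per tested pair.

    empirical: p = (1 + #{null >= r_obs}) / (1 + N).
    gaussian: fit a normal to the (optionally Fisher-z transformed) null and
    take its upper tail at the transformed observed r.
    """
    null_sample = np.asarray(null_sample, dtype=float)
    if len(null_sample) == 0:
        raise ValueError("null sample is empty")
    if method not in ("empirical", "gaussian"):
        raise ValueError("method must be 'empirical' or 'gaussian'")
    if method == "gaussian" and len(null_sample) < 3:
        raise ValueError("gaussian method needs at least 3 null values")

    rows = []
    method_tag = method + ("+fisher_z" if method == "gaussian" and fisher_z else "")
    if method == "gaussian":
        z_null = np.arctanh(np.clip(null_sample, -1 + 1e-15, 1 - 1e-15)) if fisher_z else null_sample
        mu, sd = z_null.mean(), z_null.std(ddof=1)
    for (a, b), r in r_obs.items():
        if r is None or (isinstance(r, float) and np.isnan(r)):
            p = np.nan
        elif method == "empirical":
            p = (1.0 + np.sum(null_sample >= r)) / (1.0 + len(null_sample))
        else:
            z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)) if fisher_z else r
            p = float(stats.norm.sf((z - mu) / sd))
        rows.append((a, b, r, p, method_tag))
    return pd.DataFrame(rows, columns=["label_a", "label_b", "r", "p", "method"])


def test_clonality(
    profiles: TumorProfileSet,
    tested_pairs: list[tuple[str, str]],
    related_pairs: list[tuple[str, str]] = (),
    method: str = "gaussian",
    fisher_z: bool = True,
) -> ClonalityResult:
    """End-to-end: correlation matrix, unrelated-pair null, per-pair p-values.

    Tumors appearing in ``tested_pairs`` are excluded from the null entirely
    (both members of a null pair must be outside the tested set), as are
    ``related_pairs`` (e.g. known primary/metastasis pairs).
    """
    r = cna_correlation_matrix(profiles)
    tested_labels = {l for pair in tested_pairs for l in pair}
    null = null_distribution(r, related_pairs=related_pairs, tested_labels=tested_labels)
    r_obs = {(a, b): float(r.loc[a, b]) for a, b in tested_pairs}
    pvals = clonality_pvalues(r_obs, null, method=method, fisher_z=fisher_z)
    return ClonalityResult(
        labels=list(r.columns),
        r_matrix=r,
        null_sample=null,
        tested_pairs=[tuple(p) for p in tested_pairs],
        related_pairs=[tuple(p) for p in related_pairs],
        pvalues=pvals,
    )
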
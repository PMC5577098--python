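"""Differential-expression screening and DE-pathway construction.

Genes are screened on the training set with a two-sample moderated t-test:
per-gene pooled variances are shrunk toward a common prior fitted by
empirical Bayes (the scaled-F moment-matching scheme used for two-group
microarray designs), which stabilises variance estimates when samples are
few. A plain Welch t-test is available as an alternative. A gene is called
DE when its raw p-value falls below ``alpha`` (no multiplicity correction by
default, matching the nominal-cutoff protocol; Benjamini-Hochberg can be
switched on).

Each pathway is then intersected with the DE gene list; pathways with a
non-empty intersection become *DE pathways*, the feature sets of the base
classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import DataError, ExpressionDataset, GeneSetCollection

__all__ = [
    "DEResult",
    "DEPathway",
    "NoDEPathwayError",
    "screen_de_genes",
    "map_pathways_to_de",
]


class NoDEPathwayError(DataError):
    """No pathway retains any DE gene; the pipeline cannot proceed."""


@dataclass(frozen=True)
class DEResult:
    """Per-gene two-sample test results on the training set."""

    gene_ids: tuple[str, ...]
    statistic: np.ndarray
    p_value: np.ndarray
    is_de: np.ndarray
    alpha: float
    method: str
    df_prior: float = np.nan
    s2_prior: float = np.nan

    @property
    def de_genes(self) -> tuple[str, ...]:
        return tuple(g for g, d in zip(self.gene_ids, self.is_de) if d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.gene_ids),
                "statistic": self.statistic,
                "p_value": self.p_value,
                "is_de": self.is_de,
            }
        )


@dataclass(frozen=True)
class DEPathway:
    """A pathway restricted to its differentially expressed member genes."""

    pathway_id: str
    name: str
    feature_genes: tuple[str, ...]  # pathway order, filtered
    n_pathway_genes: int

    def __post_init__(self) -> None:
        if len(self.feature_genes) == 0:
            raise DataError(f"DE pathway {self.pathway_id!r} has no feature genes")


def trigamma_inverse(x: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(-dif / y) < 1e-8:
            break
    return y


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to observed variances.

    Returns (df_prior, s2_prior) such that s2 ~ s2_prior * F(df, df_prior).
    Genes with zero variance are excluded from the fit.
    """
    s2 = s2[s2 > 0]
    if len(s2) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    e_var -= float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        df_prior = float(2.0 * trigamma_inverse(e_var)[0])
        s2_prior = float(np.exp(e_mean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)))
    else:
        df_prior = np.inf
        s2_prior = float(np.exp(e_mean))
    return df_prior, s2_prior


def screen_de_genes(
    train: ExpressionDataset,
    alpha: float = 0.05,
    method: str = "moderated",
    adjust: bool = False,
) -> DEResult:
    """Two-sample DE screen of every gene on the (full, unbalanced) training set.

    Parameters
    ----------
    alpha
        Raw (or, with ``adjust=True``, BH-adjusted) p-value cutoff; default 0.05.
    method
        ``"moderated"`` (empirical-Bayes shrunken pooled variance, default) or
        ``"welch"`` (ordinary unequal-variance t).
    """
    if not (0 < alpha < 1):
        raise DataError(f"alpha must be in (0, 1), got {alpha}")
    if method not in ("moderated", "welch"):
        raise DataError(f"unknown DE method {method!r}")
    y = train.y()
    n1, n2 = int(y.sum()), int((~y).sum())
    if min(n1, n2) < 2:
        raise DataError("DE screening needs >= 2 training samples per class")
    x1 = train.values[:, y]
    x2 = train.values[:, ~y]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    diff = m1 - m2
    degenerate = (v1 == 0) & (v2 == 0)

    df_prior, s2_prior = np.nan, np.nan
    if method == "moderated":
        df_resid = float(n1 + n2 - 2)
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
        df_prior, s2_prior = _fit_f_dist(s2, df_resid)
        if np.isfinite(df_prior):
            s2_post = (df_prior * s2_prior + df_resid * s2) / (df_prior + df_resid)
            df_total = df_resid + df_prior
        else:
            s2_post = np.full_like(s2, s2_prior)
            df_total = np.inf
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / se
        if np.isfinite(df_total):
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        else:
            p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(x1, x2, axis=1, equal_var=False)
        t = np.asarray(t)
        p = np.asarray(p)

    # a gene with zero variance in both classes is uninformative by definition
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    p = np.nan_to_num(p, nan=1.0)
    p = np.clip(p, 0.0, 1.0)

    p_for_cut = p
    if adjust:
        from statsmodels.stats.multitest import multipletests

        p_for_cut = multipletests(p, method="fdr_bh")[1]
    is_de = p_for_cut < alpha
    return DEResult(
        gene_ids=train.gene_ids,
        statistic=np.asarray(t, dtype=float),
        p_value=np.asarray(p, dtype=float),
        is_de=is_de,
        alpha=alpha,
        method=method,
        df_prior=df_prior,
        s2_prior=s2_prior,
    )


def map_pathways_to_de(
    pathways: GeneSetCollection,
    de: DEResult,
    universe: tuple[str, ...] | None = None,
) -> list[DEPathway]:
    """Intersect each pathway with the DE gene list (exact ID match).

    Pathways with empty intersection are dropped; input order is preserved.
    Raises :class:`NoDEPathwayError` when nothing survives.
    """
    if universe is None:
        universe = de.gene_ids
    universe_set = set(universe)
    de_set = set(de.de_genes)
    out: list[DEPathway] = []
    for gs in pathways:
        features = tuple(g for g in gs.genes if g in de_set and g in universe_set)
        if features:
            out.append(
                DEPathway(
                    pathway_id=gs.pathway_id,
                    name=gs.name,
                    feature_genes=features,
                    n_pathway_genes=len(gs.genes),
                )
            )
    if not out:
        raise NoDEPathwayError("no DE pathway: no pathway retains any differentially expressed gene")
    return out
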
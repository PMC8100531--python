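"""Differential piRNA expression between two libraries without replicates.

The design of the motivating study pools all ejaculates per condition, so
each species contributes exactly one fresh and one frozen-thawed library.
With n = 1 vs n = 1, differential expression is necessarily exploratory:
overdispersion cannot be estimated per condition, so it is estimated
"blind" — both libraries are treated as a pooled pseudo-group — and a
parametric mean–dispersion trend ``alpha(mu) = a0 + a1/mu`` is fitted
across features.  Each feature is then tested with a two-sided exact
negative-binomial test on its (size-factor normalised, rounded) count pair:
conditioning on the pair total ``s``, the p-value is the probability mass of
all splits ``(x, s - x)`` no more probable than the observed one, with both
margins NB(mean ``s/2``, dispersion from the trend).

Benjamini–Hochberg adjustment and the strict thresholds adjusted p < 0.01,
|log2FC| > 1 classify features as up (higher in frozen-thawed), down or ns.

The module's primary API is statsmodels-style::

    model = PiRNADEModel(counts)           # features x 2 count DataFrame
    res = model.fit()
    res.summary()                          # text table
    res.table                              # per-feature DataFrame
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster import hierarchy
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests

_MIN_DISP = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library scale factors.

    ``factor_j = median_i(count_ij / geometric_mean_i)`` over features with
    no zero count.  Raises if no feature is nonzero in every library.
    """
    arr = counts.to_numpy(dtype=float)
    nonzero = (arr > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no feature has nonzero counts in all libraries")
    sub = arr[nonzero]
    geomean = np.exp(np.log(sub).mean(axis=1, keepdims=True))
    factors = np.median(sub / geomean, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


@dataclass
class DispersionModel:
    """Blind per-feature dispersions plus a fitted a0 + a1/mean trend."""

    raw: pd.Series
    coef: tuple[float, float]
    sharing_mode: str = "fit-only"

    def fitted(self, mean: np.ndarray | float) -> np.ndarray | float:
        a0, a1 = self.coef
        return np.clip(a0 + a1 / np.maximum(np.asarray(mean, dtype=float), 1e-12),
                       _MIN_DISP, None)

    def dispersion(self, mean: np.ndarray | float, raw: np.ndarray | float | None = None):
        """Per-feature dispersion under the configured sharing mode."""
        fit = self.fitted(mean)
        if self.sharing_mode == "fit-only" or raw is None:
            return fit
        if self.sharing_mode == "maximum":
            return np.maximum(np.asarray(raw, dtype=float), fit)
        raise ValueError(f"unknown sharing mode {self.sharing_mode!r}")


def fit_dispersion(norm_counts: pd.DataFrame, sharing_mode: str = "fit-only") -> DispersionModel:
    """Method-of-moments blind dispersion with a robust parametric trend.

    Per feature: mean m and variance v across the two libraries (labels
    ignored); raw dispersion = max((v - m)/m², 0).  The trend a0 + a1/m is
    fitted by Huber robust regression so that strongly differential
    features (whose raw dispersion is confounded with the condition effect)
    do not drag the trend up.
    """
    arr = norm_counts.to_numpy(dtype=float)
    m = arr.mean(axis=1)
    v = arr.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(m > 0, (v - m) / np.maximum(m, 1e-12) ** 2, 0.0)
    raw = np.clip(raw, 0.0, None)

    use = m > 0
    if use.sum() >= 3:
        X = sm.add_constant(1.0 / m[use])
        fit = sm.RLM(raw[use], X, M=sm.robust.norms.HuberT()).fit()
        a0, a1 = float(fit.params[0]), float(fit.params[1])
    else:
        a0, a1 = float(np.mean(raw[use])) if use.any() else 0.1, 0.0
    a0 = max(a0, _MIN_DISP)
    a1 = max(a1, 0.0)
    return DispersionModel(pd.Series(raw, index=norm_counts.index, name="raw_dispersion"),
                           (a0, a1), sharing_mode)


def nb_exact_test(count_a: int, count_b: int, dispersion: float) -> float:
    """Two-sided exact NB test of an equal-means null for one count pair.

    Conditions on ``s = count_a + count_b``: with both margins
    NB(mean s/2, dispersion), sums the joint probability of every split
    ``(x, s - x)`` whose probability does not exceed the observed split's,
    normalised by the total over all splits.  ``s = 0`` gives p = 1.
    """
    a, b = int(count_a), int(count_b)
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    s = a + b
    if s == 0:
        return 1.0
    alpha = max(float(dispersion), _MIN_DISP)
    mu = s / 2.0
    r = 1.0 / alpha
    p_nb = r / (r + mu)
    x = np.arange(s + 1)
    logpmf = nbinom.logpmf(x, r, p_nb)
    joint = logpmf + logpmf[::-1]          # log P(x) + log P(s - x)
    obs = joint[a]
    with np.errstate(over="ignore"):
        weights = np.exp(joint - joint.max())
    num = weights[joint <= obs + 1e-10].sum()
    den = weights.sum()
    return float(min(1.0, num / den))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(table: pd.DataFrame, padj_cut: float = 0.01, lfc_cut: float = 1.0) -> pd.Series:
    """Classify each feature as up/down/ns with strict inequalities."""
    call = pd.Series("ns", index=table.index, name="call")
    sig = table["padj"] < padj_cut
    call[sig & (table["log2fc"] > lfc_cut)] = "up"
    call[sig & (table["log2fc"] < -lfc_cut)] = "down"
    return call


def cluster_heatmap_order(tpm: pd.DataFrame) -> tuple[list[int], pd.DataFrame]:
    """Row order for the DE heatmap: hierarchical clustering of
    log10(TPM + 1) rows (Euclidean distance, complete linkage), with
    scipy's deterministic leaf order.  Fewer than two rows: identity.
    """
    transformed = np.log10(tpm + 1.0)
    if len(transformed) < 2:
        return list(range(len(transformed))), transformed
    linkage = hierarchy.linkage(transformed.to_numpy(), method="complete", metric="euclidean")
    order = hierarchy.leaves_list(linkage).tolist()
    return order, transformed


class PiRNADEModel:
    """Exact NB differential-expression model for one fresh/frozen pair.

    Parameters
    ----------
    counts : DataFrame
        Features (piRNA sequences) × exactly two libraries of raw counts.
    fresh, frozen : str, optional
        Column names of the reference (fresh) and treatment (frozen-thawed)
        libraries; default the first and second column.
    """

    def __init__(self, counts: pd.DataFrame, fresh: str | None = None, frozen: str | None = None):
        if counts.shape[1] != 2:
            raise ValueError("expected a count matrix with exactly two libraries")
        self.counts = counts.astype(float)
        self.fresh = fresh or counts.columns[0]
        self.frozen = frozen or counts.columns[1]
        if {self.fresh, self.frozen} != set(counts.columns):
            raise ValueError("fresh/frozen labels must name the two count columns")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fresh: str, frozen: str,
                       feature_col: str | None = None) -> "PiRNADEModel":
        if feature_col is not None:
            df = df.set_index(feature_col)
        return cls(df[[fresh, frozen]], fresh=fresh, frozen=frozen)

    def fit(self, sharing_mode: str = "fit-only", padj_cut: float = 0.01,
            lfc_cut: float = 1.0, pseudocount: float = 1.0) -> "DEResults":
        sf = size_factors(self.counts)
        norm = self.counts / sf
        disp_model = fit_dispersion(norm, sharing_mode=sharing_mode)

        a = np.rint(norm[self.fresh].to_numpy()).astype(int)
        b = np.rint(norm[self.frozen].to_numpy()).astype(int)
        mean = (a + b) / 2.0
        disp = np.asarray(disp_model.dispersion(np.maximum(mean, 1e-12),
                                                disp_model.raw.to_numpy()))
        pvals = np.array([nb_exact_test(ai, bi, di) for ai, bi, di in zip(a, b, disp)])

        table = pd.DataFrame(index=self.counts.index)
        table["norm_count_fresh"] = norm[self.fresh]
        table["norm_count_frozen"] = norm[self.frozen]
        table["log2fc"] = np.log2((norm[self.frozen] + pseudocount)
                                  / (norm[self.fresh] + pseudocount))
        table["p"] = pvals
        table["padj"] = bh_adjust(pvals)
        table["call"] = call_de(table, padj_cut, lfc_cut)
        return DEResults(self, table, sf, disp_model, padj_cut, lfc_cut)


class DEResults:
    """Fitted differential-expression results with a summary table."""

    def __init__(self, model: PiRNADEModel, table: pd.DataFrame, sf: pd.Series,
                 dispersion_model: DispersionModel, padj_cut: float, lfc_cut: float):
        self.model = model
        self.table = table
        self.size_factors = sf
        self.dispersion_model = dispersion_model
        self.padj_cut = padj_cut
        self.lfc_cut = lfc_cut

    @property
    def up(self) -> pd.Index:
        return self.table.index[self.table["call"] == "up"]

    @property
    def down(self) -> pd.Index:
        return self.table.index[self.table["call"] == "down"]

    @property
    def n_de(self) -> int:
        return int((self.table["call"] != "ns").sum())

    def heatmap(self, tpm: pd.DataFrame) -> tuple[list[int], pd.DataFrame]:
        """log10(TPM+1)-transformed matrix and dendrogram row order for the
        DE features only."""
        de = self.table.index[self.table["call"] != "ns"]
        return cluster_heatmap_order(tpm.loc[de])

    def summary(self) -> str:
        a0, a1 = self.dispersion_model.coef
        lines = [
            "Exact negative-binomial differential expression (no replicates)",
            "=" * 63,
            f"features tested:        {len(self.table)}",
            f"libraries:              {self.model.fresh} (fresh) vs {self.model.frozen} (frozen-thawed)",
            f"size factors:           {self.size_factors[self.model.fresh]:.4f}, "
            f"{self.size_factors[self.model.frozen]:.4f}",
            f"dispersion trend:       alpha(mu) = {a0:.4g} + {a1:.4g}/mu "
            f"({self.dispersion_model.sharing_mode})",
            f"thresholds:             padj < {self.padj_cut}, |log2FC| > {self.lfc_cut}",
            f"DE piRNAs:              {self.n_de} ({len(self.up)} up, {len(self.down)} down)",
        ]
        return "\n".join(lines)
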
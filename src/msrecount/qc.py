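"""Per-sample diagnostics for cut-site count tables.

Library size versus cut-site yield flags samples with failed digests or poor
libraries; PCA on log-CPM screens for outliers; and a negative-binomial
goodness-of-fit check justifies the count model used for differential
testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .counts import CutSiteCountTable

__all__ = [
    "SampleSummary",
    "sample_summary",
    "pca_logcpm",
    "nb_goodness_of_fit",
    "plot_counts",
    "plot_pca",
]


@dataclass(frozen=True)
class SampleSummary:
    sample: str
    library_size: int
    n_cut_sites: int
    group: str


def sample_summary(table: CutSiteCountTable) -> list[SampleSummary]:
    """Library size (column total) and number of sites with >= 1 read, per sample."""
    if not table.samples:
        raise ValueError("count table has no samples")
    groups = dict(zip(table.sample_meta["sample"], table.sample_meta["group"]))
    lib = table.counts.sum(axis=0)
    nsites = (table.counts >= 1).sum(axis=0)
    return [
        SampleSummary(s, int(lib[j]), int(nsites[j]), str(groups.get(s, "")))
        for j, s in enumerate(table.samples)
    ]


def log_cpm(counts: np.ndarray, prior_count: float = 0.5) -> np.ndarray:
    """log2(CPM + prior_count) with CPM = count / library size * 1e6."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    return np.log2(counts / lib * 1e6 + prior_count)


def pca_logcpm(
    table: CutSiteCountTable, prior_count: float = 0.5, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on site-centred log2-CPM values.

    Zero-variance sites are dropped before centring. Returns per-sample
    component scores and the variance-explained fractions (non-increasing,
    summing to <= 1).
    """
    if len(table.samples) < 2:
        raise ValueError("PCA needs at least 2 samples")
    if table.n_sites < 2:
        raise ValueError("PCA needs at least 2 sites")
    x = log_cpm(table.counts, prior_count)  # sites x samples
    x = x[x.var(axis=1) > 0]
    centred = x - x.mean(axis=1, keepdims=True)
    # SVD of samples-by-sites matrix: rows are observations (samples)
    u, s, _ = np.linalg.svd(centred.T, full_matrices=False)
    k = n_components or min(len(table.samples), centred.shape[0])
    k = min(k, len(s))
    scores = u[:, :k] * s[:k]
    var = s**2 / max(centred.shape[0] - 0, 1)
    explained = (var / var.sum())[:k] if var.sum() > 0 else np.zeros(k)
    df = pd.DataFrame(
        scores, columns=[f"PC{i + 1}" for i in range(k)], index=table.samples
    )
    df.insert(0, "sample", table.samples)
    df = df.reset_index(drop=True)
    return df, explained


def _nb_negloglik(log_size: float, counts: np.ndarray, mu: float) -> float:
    size = np.exp(log_size)
    return -stats.nbinom.logpmf(counts, size, size / (size + mu)).sum()


def fit_nb_ml(counts: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood (size, mu) of a negative binomial.

    For the NB with a free mean, the ML mean is the sample mean; the size
    (inverse dispersion) is profiled out numerically.
    """
    counts = np.asarray(counts)
    mu = counts.mean()
    if counts.var() <= 0:
        raise ValueError("degenerate sample: all counts identical")
    # method-of-moments start: var = mu + mu^2/size
    mom = mu**2 / max(counts.var(ddof=1) - mu, 1e-8)
    res = optimize.minimize_scalar(
        _nb_negloglik,
        bounds=(np.log(mom) - 8, np.log(mom) + 8),
        args=(counts, mu),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x)), float(mu)


def nb_goodness_of_fit(counts: np.ndarray) -> tuple[float, float, float, float]:
    """Pearson chi-square goodness of fit of one sample's counts to a NB.

    Counts are binned into categories 0..K with the right tail pooled until
    every expected frequency is >= 5; the statistic is referred to a
    chi-square with (categories - 1 - 2) degrees of freedom, the 2 accounting
    for the fitted size and mean. Returns (size, mu, statistic, p_value).
    """
    counts = np.asarray(counts)
    size, mu = fit_nb_ml(counts)
    n = len(counts)
    kmax = int(counts.max())
    ks = np.arange(kmax + 1)
    probs = stats.nbinom.pmf(ks, size, size / (size + mu))
    tail = 1.0 - probs.sum()
    expected = np.append(probs * n, max(tail, 0.0) * n)  # last cell = > kmax
    observed = np.append(np.bincount(counts, minlength=kmax + 1), 0)
    # pool boundary cells (the NB pmf is unimodal, so the smallest expected
    # frequencies sit at the ends) until every cell holds >= 5
    exp_list, obs_list = list(expected), list(observed)
    while len(exp_list) > 4 and min(exp_list) < 5:
        if exp_list[0] <= exp_list[-1]:
            e, o = exp_list.pop(0), obs_list.pop(0)
            exp_list[0] += e
            obs_list[0] += o
        else:
            e, o = exp_list.pop(), obs_list.pop()
            exp_list[-1] += e
            obs_list[-1] += o
    exp_arr, obs_arr = np.array(exp_list), np.array(obs_list)
    statistic = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    df = len(exp_arr) - 1 - 2
    if df < 1:
        raise ValueError("too few count categories for a NB goodness-of-fit test")
    p = float(stats.chi2.sf(statistic, df))
    return size, mu, statistic, p


def plot_counts(summaries: list[SampleSummary], path: str | Path) -> None:
    """Scatter of library size vs number of cut sites, coloured by group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    groups = sorted({s.group for s in summaries})
    for g in groups:
        xs = [s.library_size for s in summaries if s.group == g]
        ys = [s.n_cut_sites for s in summaries if s.group == g]
        ax.scatter(xs, ys, label=g or "(all)", alpha=0.8)
    ax.set_xlabel("library size (reads)")
    ax.set_ylabel("cut sites with ≥ 1 read")
    ax.legend(title="group")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca(
    scores: pd.DataFrame, explained: np.ndarray, groups: dict[str, str], path: str | Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    labels = sorted(set(groups.values()))
    for g in labels:
        sel = scores["sample"].map(groups) == g
        ax.scatter(scores.loc[sel, "PC1"], scores.loc[sel, "PC2"], label=g, alpha=0.8)
    ax.set_xlabel(f"PC1 ({explained[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({explained[1] * 100:.1f}%)" if len(explained) > 1 else "PC2")
    ax.legend(title="group")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
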
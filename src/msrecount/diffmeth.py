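"""Differential methylation from cut-site read counts.

Counts at methylation-sensitive cut sites behave like other sequencing count
data: overdispersed relative to Poisson, well described by a negative
binomial with variance mu + phi*mu^2. The analysis here mirrors the standard
count-based differential pipeline: low-count filtering, trimmed-mean-of-M
(TMM) between-sample normalization, NB dispersion estimation by Cox-Reid
adjusted profile likelihood with shrinkage toward a common value, a
conditional NB exact test for simple two-group designs, an NB GLM
likelihood-ratio test for designs with blocking factors, and
Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .counts import CutSiteCountTable

__all__ = [
    "NormFactors",
    "filter_low",
    "tmm_norm_factors",
    "build_design",
    "fit_nb_glm",
    "estimate_dispersions",
    "exact_test_two_group",
    "glm_lrt",
    "bh_adjust",
    "diff_meth",
]

_MAX_IRLS_ITER = 50
_IRLS_TOL = 1e-8  # relative deviance change
_MIN_PHI = 1e-8


class DiffMethError(ValueError):
    pass


# ---------------------------------------------------------------------------
# filtering


def filter_low_mask(
    counts: np.ndarray,
    lib_sizes: np.ndarray,
    cpm_threshold: float = 1.0,
    min_samples: int = 1,
) -> np.ndarray:
    """Boolean mask of rows with CPM > threshold in at least ``min_samples``."""
    counts = np.asarray(counts, dtype=float)
    if cpm_threshold < 0:
        raise DiffMethError("cpm_threshold must be >= 0")
    if not 1 <= min_samples <= counts.shape[1]:
        raise DiffMethError(
            f"min_samples {min_samples} outside [1, {counts.shape[1]}]"
        )
    cpm = counts / np.asarray(lib_sizes, dtype=float) * 1e6
    return (cpm > cpm_threshold).sum(axis=1) >= min_samples


def filter_low(
    table: CutSiteCountTable,
    cpm_threshold: float = 1.0,
    min_samples: int | None = None,
) -> CutSiteCountTable:
    """Drop sites too weakly covered to test.

    Default ``min_samples`` is the size of the smallest group in the sample
    metadata. CPM uses raw library sizes (column totals).
    """
    if min_samples is None:
        min_samples = int(table.sample_meta.groupby("group").size().min())
    mask = filter_low_mask(
        table.counts, table.library_sizes(), cpm_threshold, min_samples
    )
    return table.subset_rows(mask)


# ---------------------------------------------------------------------------
# TMM normalization


@dataclass(frozen=True)
class NormFactors:
    """Per-sample TMM (or unit) scale factors; geometric mean is 1."""

    factors: np.ndarray
    lib_sizes: np.ndarray

    @property
    def effective_sizes(self) -> np.ndarray:
        return self.factors * self.lib_sizes


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference.

    M = log2 ratio of count fractions, A = mean log2 abundance; the 30% most
    extreme M and 5% most extreme A are trimmed two-sidedly and the factor is
    2^(weighted mean M) with inverse delta-method binomial variances
    1/n_s - 1/N_s + 1/n_r - 1/N_r as weights.
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    fin = (obs > 0) & (ref > 0)
    if not fin.any():
        raise DiffMethError(
            "sample shares no positive site with the reference; "
            "use library-size-only normalization"
        )
    o, r = obs[fin], ref[fin]
    log_r = np.log2((o / n_obs) / (r / n_ref))
    abs_e = (np.log2(o / n_obs) + np.log2(r / n_ref)) / 2
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = len(log_r)
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2**f)


def tmm_norm_factors(
    counts: np.ndarray,
    lib_sizes: np.ndarray | None = None,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> NormFactors:
    """Trimmed mean of M-values normalization factors for a count matrix.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions across samples. Factors are
    rescaled so their geometric mean is exactly 1.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[1] < 2:
        raise DiffMethError("TMM needs at least 2 samples")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if (lib_sizes <= 0).any():
        raise DiffMethError("library sizes must be positive")
    f75 = np.quantile(counts / lib_sizes, 0.75, axis=0)
    if np.median(f75) < 1e-20:
        ref = int(np.argmax(np.sqrt(counts).sum(axis=0)))
    else:
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        factors[j] = _tmm_pair_factor(
            counts[:, j], counts[:, ref], lib_sizes[j], lib_sizes[ref],
            logratio_trim, sum_trim,
        )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(factors=factors, lib_sizes=lib_sizes)


def unit_norm_factors(lib_sizes: np.ndarray) -> NormFactors:
    """Library-size-only normalization (all factors 1)."""
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    return NormFactors(factors=np.ones(len(lib_sizes)), lib_sizes=lib_sizes)


# ---------------------------------------------------------------------------
# design matrices


def build_design(
    sample_meta: pd.DataFrame,
    condition1: str,
    condition2: str,
    block: str | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Intercept + optional block dummies + group indicator (condition2 = 1).

    Returns (design, coefficient names, row mask selecting the samples of
    the two conditions in table order). The fitted group coefficient is the
    natural-log fold change of condition2 over condition1.
    """
    groups = sample_meta["group"].astype(str)
    mask = groups.isin([condition1, condition2]).to_numpy()
    if mask.sum() == 0 or (groups[mask] == condition2).sum() == 0 or (
        groups[mask] == condition1
    ).sum() == 0:
        raise DiffMethError(
            f"conditions {condition1!r}/{condition2!r} not both present"
        )
    sub = sample_meta.loc[mask]
    cols = [np.ones(len(sub))]
    names = ["intercept"]
    if block is not None:
        levels = sorted(set(sub[block].astype(str)))
        for lev in levels[1:]:
            cols.append((sub[block].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{block}_{lev}")
    cols.append((sub["group"].astype(str) == condition2).to_numpy(dtype=float))
    names.append(f"group_{condition2}")
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DiffMethError("design matrix is not of full column rank")
    return design, names, mask


# ---------------------------------------------------------------------------
# NB GLM machinery (batched over sites)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Per-site NB log-likelihood (Poisson when phi == 0); y, mu are G x n."""
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (y.shape[0],))
    ll = np.empty(y.shape[0])
    pois = phi <= _MIN_PHI
    if pois.any():
        ll[pois] = stats.poisson.logpmf(y[pois], np.maximum(mu[pois], 1e-300)).sum(axis=1)
    if (~pois).any():
        r = 1.0 / phi[~pois]
        m = np.maximum(mu[~pois], 1e-300)
        yy = y[~pois]
        rr = r[:, None]
        ll[~pois] = (
            special.gammaln(yy + rr)
            - special.gammaln(rr)
            - special.gammaln(yy + 1)
            + rr * np.log(rr / (rr + m))
            + yy * np.log(m / (rr + m))
        ).sum(axis=1)
    return ll


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (y.shape[0],))[:, None]
    mu = np.maximum(mu, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    small = phi <= _MIN_PHI
    r = 1.0 / np.where(small, 1.0, phi)
    nb_term = (y + r) * np.log((y + r) / (mu + r))
    pois_term = y - mu
    term2 = np.where(small, pois_term, nb_term)
    return 2.0 * (term1 - term2).sum(axis=1)


def fit_nb_glm(
    y: np.ndarray,
    design: np.ndarray,
    offset: np.ndarray,
    phi,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit log-link NB GLMs with offsets to every site at once by IRLS.

    ``y`` is sites x samples, ``design`` samples x p, ``offset`` per sample
    (log effective library size), ``phi`` scalar or per-site dispersion.
    Returns (beta, mu, deviance, converged). Fisher-scoring weights
    mu/(1 + phi*mu); convergence on relative deviance change < 1e-8 within
    50 iterations.
    """
    y = np.asarray(y, dtype=float)
    g, n = y.shape
    p = design.shape[1]
    phi_vec = np.broadcast_to(np.asarray(phi, dtype=float), (g,))
    mu = np.maximum(y, 0.0) + np.mean(y, axis=1, keepdims=True) * 0.1 + 0.1
    eta = np.log(mu)
    beta = np.zeros((g, p))
    dev = _nb_deviance(y, mu, phi_vec)
    converged = np.zeros(g, dtype=bool)
    active = np.ones(g, dtype=bool)
    for _ in range(_MAX_IRLS_ITER):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        mu_a = mu[idx]
        w = mu_a / (1.0 + phi_vec[idx, None] * mu_a)
        z = (eta[idx] - offset[None, :]) + (y[idx] - mu_a) / mu_a
        xtwx = np.einsum("ni,an,nj->aij", design, w, design)
        xtwz = np.einsum("ni,an,an->ai", design, w, z)
        xtwx += 1e-10 * np.eye(p)[None, :, :]
        new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        new_eta = new_beta @ design.T + offset[None, :]
        new_eta = np.clip(new_eta, -700, 700)
        new_mu = np.exp(new_eta)
        new_dev = _nb_deviance(y[idx], new_mu, phi_vec[idx])
        # step-halve any site whose deviance increased or went non-finite
        bad = ~np.isfinite(new_dev) | (new_dev > dev[idx] + 1e-6)
        halvings = 0
        while bad.any() and halvings < 10:
            new_beta[bad] = (new_beta[bad] + beta[idx][bad]) / 2
            new_eta[bad] = np.clip(new_beta[bad] @ design.T + offset[None, :], -700, 700)
            new_mu[bad] = np.exp(new_eta[bad])
            new_dev[bad] = _nb_deviance(y[idx][bad], new_mu[bad], phi_vec[idx][bad])
            bad = ~np.isfinite(new_dev) | (new_dev > dev[idx] + 1e-6)
            halvings += 1
        beta[idx] = new_beta
        eta[idx] = new_eta
        mu[idx] = new_mu
        rel = np.abs(dev[idx] - new_dev) / (np.abs(new_dev) + 1.0)
        done = rel < _IRLS_TOL
        dev[idx] = new_dev
        converged[idx[done]] = True
        active[idx[done]] = False
    return beta, mu, dev, converged


def _cox_reid_apl(
    y: np.ndarray, design: np.ndarray, offset: np.ndarray, phi
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per site at dispersion phi:
    loglik at the fitted coefficients minus half the log-determinant of the
    Fisher information X' W X."""
    _, mu, _, _ = fit_nb_glm(y, design, offset, phi)
    g = y.shape[0]
    phi_vec = np.broadcast_to(np.asarray(phi, dtype=float), (g,))
    w = mu / (1.0 + phi_vec[:, None] * mu)
    xtwx = np.einsum("ni,an,nj->aij", design, w, design)
    xtwx += 1e-10 * np.eye(design.shape[1])[None, :, :]
    sign, logdet = np.linalg.slogdet(xtwx)
    ll = _nb_loglik(y, mu, phi_vec)
    return ll - 0.5 * logdet


def estimate_dispersions(
    counts: np.ndarray,
    design: np.ndarray,
    offset: np.ndarray | None = None,
    prior_df: float = 10.0,
    grid_points: int = 21,
    grid_span: float = 6.0,
) -> tuple[float, np.ndarray]:
    """Common and tagwise NB dispersions by Cox-Reid adjusted profile likelihood.

    The common dispersion maximizes the summed adjusted profile likelihood
    over all sites. Tagwise values maximize each site's likelihood plus
    (prior_df / residual_df) times the average likelihood over all sites,
    shrinking site estimates toward the common value; evaluated on a log2
    grid spanning ``2**±grid_span`` around the common value with quadratic
    interpolation at the grid maximum. No abundance trend is fitted.
    """
    y = np.asarray(counts, dtype=float)
    n, p = design.shape
    if y.shape[1] != n:
        raise DiffMethError("counts / design sample dimension mismatch")
    resid_df = n - p
    if resid_df < 1:
        raise DiffMethError("saturated design: no residual degrees of freedom")
    if offset is None:
        offset = np.log(np.maximum(y.sum(axis=0), 1.0))

    def neg_total(log10_phi: float) -> float:
        return -float(_cox_reid_apl(y, design, offset, 10.0**log10_phi).sum())

    res = optimize.minimize_scalar(
        neg_total, bounds=(-8.0, 1.5), method="bounded", options={"xatol": 1e-4}
    )
    common = float(10.0 ** res.x)
    if common < 1e-7:
        common_out = 0.0
    else:
        common_out = common

    # tagwise: weighted likelihood on a grid around the common value
    centre = max(common, 1e-6)
    grid = centre * 2.0 ** np.linspace(-grid_span, grid_span, grid_points)
    apl = np.column_stack([_cox_reid_apl(y, design, offset, g) for g in grid])
    prior_n = prior_df / resid_df
    weighted = apl + prior_n * apl.mean(axis=0, keepdims=True)
    best = np.argmax(weighted, axis=1)
    log_grid = np.log2(grid)
    tagwise = np.empty(y.shape[0])
    for i, b in enumerate(best):
        if b == 0 or b == len(grid) - 1:
            tagwise[i] = grid[b]
            continue
        # quadratic interpolation through the maximum and its neighbours
        x0, x1, x2 = log_grid[b - 1 : b + 2]
        f0, f1, f2 = weighted[i, b - 1 : b + 2]
        denom = f0 - 2 * f1 + f2
        if denom >= 0:  # not locally concave; keep the grid point
            tagwise[i] = grid[b]
        else:
            h = (x2 - x0) / 2
            xv = x1 + 0.5 * h * (f0 - f2) / denom
            tagwise[i] = 2.0 ** np.clip(xv, log_grid[0], log_grid[-1])
    return common_out, tagwise


# ---------------------------------------------------------------------------
# exact conditional test (two groups)


def _exact_p_one_site(t: int, s_obs: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided minimum-likelihood exact p-value for the split (s_obs, t-s_obs).

    Conditional on the total t, the group sums are NB with means proportional
    to the summed (equalized) library sizes and group-sum dispersion phi/n_g;
    phi = 0 degenerates to the Binomial(t, n1/(n1+n2)) conditional test.
    """
    if t == 0:
        return 1.0
    a = np.arange(t + 1)
    if phi <= _MIN_PHI:
        logp = stats.binom.logpmf(a, t, n1 / (n1 + n2))
    else:
        mu = t / (n1 + n2)
        r1, r2 = n1 / phi, n2 / phi
        mu1, mu2 = n1 * mu, n2 * mu
        logp = stats.nbinom.logpmf(a, r1, r1 / (r1 + mu1)) + stats.nbinom.logpmf(
            t - a, r2, r2 / (r2 + mu2)
        )
        logp -= special.logsumexp(logp)
    p_obs = logp[s_obs]
    keep = logp <= p_obs + 1e-10
    return float(min(1.0, np.exp(special.logsumexp(logp[keep]))))


def exact_test_two_group(
    counts: np.ndarray,
    norm: NormFactors,
    group_labels,
    dispersion,
) -> np.ndarray:
    """Conditional NB exact test of two groups, one p-value per site.

    Counts are first rescaled to the geometric-mean effective library size
    (deterministic expected-value scaling), then group sums are compared
    conditionally on their total.
    """
    y = np.asarray(counts, dtype=float)
    labels = np.asarray([str(l) for l in group_labels])
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise DiffMethError(
            f"exact test needs exactly 2 groups, got {uniq}; use glm_lrt"
        )
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float), (y.shape[0],))
    if (disp < 0).any():
        raise DiffMethError("negative dispersion")
    eff = norm.effective_sizes
    n_star = float(np.exp(np.mean(np.log(eff))))
    pseudo = y * (n_star / eff)[None, :]
    g1, g2 = labels == uniq[0], labels == uniq[1]
    s1 = np.round(pseudo[:, g1].sum(axis=1)).astype(int)
    s2 = np.round(pseudo[:, g2].sum(axis=1)).astype(int)
    n1, n2 = int(g1.sum()), int(g2.sum())
    return np.array(
        [
            _exact_p_one_site(int(s1[i] + s2[i]), int(s1[i]), n1, n2, float(disp[i]))
            for i in range(y.shape[0])
        ]
    )


# ---------------------------------------------------------------------------
# GLM likelihood-ratio test


def glm_lrt(
    counts: np.ndarray,
    design: np.ndarray,
    coef_idx: int | list[int],
    norm: NormFactors,
    dispersion,
) -> pd.DataFrame:
    """NB GLM likelihood-ratio test dropping the given coefficient(s).

    Both models use offset log(effective library size) and the supplied
    (typically tagwise) dispersions. Returns per-site logFC (log2 of the
    dropped coefficient when a single one is dropped), average log2-CPM,
    dispersion, LR statistic and p-value; non-converged sites get p = NaN.
    """
    y = np.asarray(counts, dtype=float)
    drop = [coef_idx] if np.isscalar(coef_idx) else list(coef_idx)
    keep_cols = [j for j in range(design.shape[1]) if j not in drop]
    null_design = design[:, keep_cols]
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DiffMethError("design not of full column rank")
    if np.linalg.matrix_rank(null_design) < null_design.shape[1]:
        raise DiffMethError("null design not of full column rank")
    offset = np.log(norm.effective_sizes)
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float), (y.shape[0],))
    beta_f, mu_f, _, conv_f = fit_nb_glm(y, design, offset, disp)
    _, mu_n, _, conv_n = fit_nb_glm(y, null_design, offset, disp)
    ll_f = _nb_loglik(y, mu_f, disp)
    ll_n = _nb_loglik(y, mu_n, disp)
    lr = np.maximum(2.0 * (ll_f - ll_n), 0.0)
    df = len(drop)
    p = stats.chi2.sf(lr, df)
    ok = conv_f & conv_n
    p = np.where(ok, p, np.nan)
    logfc = beta_f[:, drop[0]] / np.log(2.0) if len(drop) == 1 else np.full(len(y), np.nan)
    cpm = y / norm.lib_sizes[None, :] * 1e6
    ave_logcpm = np.log2(cpm.mean(axis=1) + 0.5)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "logCPM": ave_logcpm,
            "dispersion": disp,
            "lr_statistic": lr,
            "p_value": p,
        }
    )


# ---------------------------------------------------------------------------
# FDR


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    NaN entries (untested sites) propagate as NaN and are excluded from m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise DiffMethError("p-values outside [0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[valid] = res
    return out


# ---------------------------------------------------------------------------
# top-level wrapper


def diff_meth(
    table: CutSiteCountTable,
    condition1: str,
    condition2: str,
    block: str | None = None,
    normalization: str = "tmm",
    method: str = "auto",
    cpm_threshold: float = 1.0,
    min_samples: int | None = None,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Filter, normalize, estimate dispersions and test condition2 vs condition1.

    ``method`` 'exact' (two groups, no block), 'glm' (always valid) or 'auto'
    (exact without a block, glm with one). Returns the site keys with logFC,
    logCPM, dispersion, p_value and fdr, sorted by p-value.
    """
    design, names, mask = build_design(table.sample_meta, condition1, condition2, block)
    sub_cols = np.flatnonzero(mask)
    sub = CutSiteCountTable(
        sites=table.sites.copy(),
        counts=table.counts[:, sub_cols],
        samples=[table.samples[j] for j in sub_cols],
        sample_meta=table.sample_meta.loc[mask].reset_index(drop=True),
        verified=table.verified,
        contig_order=list(table.contig_order),
    )
    sub = filter_low(sub, cpm_threshold, min_samples)
    if sub.n_sites == 0:
        raise DiffMethError("no sites left after low-count filtering")
    lib = sub.library_sizes()
    if normalization == "tmm":
        norm = tmm_norm_factors(sub.counts, lib)
    elif normalization == "libsize":
        norm = unit_norm_factors(lib)
    else:
        raise DiffMethError(f"unknown normalization {normalization!r}")
    offset = np.log(norm.effective_sizes)
    common, tagwise = estimate_dispersions(sub.counts, design, offset, prior_df)
    if method == "auto":
        method = "glm" if block is not None else "exact"
    coef = names.index(f"group_{condition2}")
    if method == "glm":
        res = glm_lrt(sub.counts, design, coef, norm, tagwise)
    elif method == "exact":
        if block is not None:
            raise DiffMethError("exact test cannot adjust for a blocking factor")
        groups = sub.sample_meta["group"].astype(str).tolist()
        p = exact_test_two_group(sub.counts, norm, groups, tagwise)
        cpm = sub.counts / norm.effective_sizes[None, :] * 1e6
        g2 = np.asarray(groups) == condition2
        logfc = np.log2((cpm[:, g2].mean(axis=1) + 0.5) / (cpm[:, ~g2].mean(axis=1) + 0.5))
        res = pd.DataFrame(
            {
                "logFC": logfc,
                "logCPM": np.log2((sub.counts / norm.lib_sizes[None, :] * 1e6).mean(axis=1) + 0.5),
                "dispersion": tagwise,
                "lr_statistic": np.nan,
                "p_value": p,
            }
        )
    else:
        raise DiffMethError(f"unknown method {method!r}")
    res["fdr"] = bh_adjust(res["p_value"].to_numpy())
    out = pd.concat([sub.sites.reset_index(drop=True), res], axis=1)
    out.attrs["common_dispersion"] = common
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
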
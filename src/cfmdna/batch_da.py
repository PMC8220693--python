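"""Criterion (i): per-ASV differential abundance across technical variables.

The screen asks whether an ASV's abundance depends on sequencing run,
DNA-extraction batch (DEB) or extraction day — the signatures of reagent
contamination.  Counts are TMM-normalised, transformed to log2-CPM with
precision weights estimated from an empirical mean-variance trend, fitted
ASV-wise by (generalised) least squares with an optional block-
equicorrelated patient covariance, and tested with empirical-Bayes
moderated t statistics.  Because extraction day is nested in DEB which is
nested in run, a single model with day as the only factor is fitted and
every comparison of interest is expressed as a contrast of day means.
An ASV significant (BH FDR <= 0.05) in any contrast of any technical
variable is flagged as batch-affected; criterion (i) passers are the rest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess

from .tables import AsvCountTable, StudyDesign

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------

@dataclass
class NormalizationFactors:
    """Per-sample TMM factor and raw library size; geometric mean of
    factors is 1 by convention."""

    factors: pd.Series
    library_sizes: pd.Series

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.factors


def _tmm_pair(obs, lib_obs, ref, lib_ref, trim_m, trim_a):
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        raise ValueError("sample shares no co-detected ASV with the reference")
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic delta-method variance of M
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    # double trim by rank, as in the standard TMM recipe
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    table: AsvCountTable,
    ref: str = "auto",
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalisation factors.

    ``ref="auto"`` picks the sample whose upper-quartile CPM is closest to
    the mean upper quartile, the usual reference heuristic.
    """
    counts = table.counts
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    if ref == "auto":
        q75 = counts.div(lib, axis=1).quantile(0.75)
        ref = (q75 - q75.mean()).abs().idxmin()
    refcol = counts[ref].to_numpy()
    libref = float(lib[ref])
    facs = {}
    for s in table.sample_ids:
        if s == ref:
            facs[s] = 1.0
        else:
            facs[s] = _tmm_pair(counts[s].to_numpy(), float(lib[s]), refcol, libref, trim_m, trim_a)
    f = pd.Series(facs)[table.sample_ids]
    f = f / np.exp(np.mean(np.log(f)))
    return NormalizationFactors(f, counts.sum(axis=0))


# ---------------------------------------------------------------------------
# voom-style precision weights
# ---------------------------------------------------------------------------

@dataclass
class VoomMatrices:
    """log2-CPM values with matching inverse-variance precision weights."""

    logcpm: pd.DataFrame
    weights: pd.DataFrame
    trend: tuple = field(default=None)  # (mean logcpm grid, sqrt-sd fit)


def _design_matrix(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("design must be a 2-D model matrix")
    return x


def voom_weights(
    table: AsvCountTable,
    factors: NormalizationFactors,
    design: np.ndarray,
    span: float = 0.5,
    min_nonzero_for_trend: int = 3,
) -> VoomMatrices:
    """log2-CPM with precision weights from the mean-variance trend.

    Residual sqrt standard deviations from an ASV-wise least-squares fit
    are smoothed against mean log2-CPM (lowess); each observation's weight
    is the inverse fourth power of the trend evaluated at its fitted
    log2-CPM.  Very sparse ASVs (< ``min_nonzero_for_trend`` nonzero
    samples) are excluded from trend *fitting* but still receive weights
    from the fitted trend.
    """
    x = _design_matrix(design)
    counts = table.counts.to_numpy(dtype=float)
    n_asv, n_samp = counts.shape
    if n_samp < x.shape[1] + 1:
        raise ValueError("fewer samples than design columns + 1")
    eff_lib = factors.effective_library_sizes.loc[table.sample_ids].to_numpy(dtype=float)
    logcpm = np.log2(1e6 * (counts + 0.5) / (eff_lib + 1.0))

    # ASV-wise OLS fit for residual sqrt-sd
    q, _ = np.linalg.qr(x)
    fitted = (logcpm @ q) @ q.T
    resid = logcpm - fitted
    df_resid = n_samp - np.linalg.matrix_rank(x)
    sigma = np.sqrt((resid**2).sum(axis=1) / df_resid)
    sqrt_sd = np.sqrt(sigma)
    mean_logcpm = logcpm.mean(axis=1)

    nonzero = (counts > 0).sum(axis=1)
    use = (nonzero >= min_nonzero_for_trend) & (sigma > 0)
    if use.sum() < 10:
        warnings.warn("too few ASVs for a mean-variance trend; flat trend used")
        grid_x = np.array([mean_logcpm.min(), mean_logcpm.max()])
        grid_y = np.array([sqrt_sd.mean(), sqrt_sd.mean()])
    else:
        lo = lowess(sqrt_sd[use], mean_logcpm[use], frac=span, return_sorted=True)
        grid_x, grid_y = lo[:, 0], lo[:, 1]
    pred = np.interp(fitted, grid_x, grid_y)  # flat extrapolation at ends
    pred = np.clip(pred, 1e-6, None)
    w = pred**-4.0

    idx, cols = table.asv_ids, table.sample_ids
    return VoomMatrices(
        pd.DataFrame(logcpm, index=idx, columns=cols),
        pd.DataFrame(w, index=idx, columns=cols),
        trend=(grid_x, grid_y),
    )


# ---------------------------------------------------------------------------
# consensus correlation (repeated measures of the same patient)
# ---------------------------------------------------------------------------

def consensus_correlation(
    vm: VoomMatrices, design: np.ndarray, blocks, trim: float = 0.15
) -> float:
    """Single consensus within-block residual correlation across ASVs.

    Per ASV the average product of standardised residuals over all
    within-block pairs estimates the intra-block correlation; the
    estimates are pooled by a trimmed mean on Fisher's z scale.
    """
    blocks = np.asarray(blocks)
    x = _design_matrix(design)
    y = vm.logcpm.to_numpy()
    labels, counts = np.unique(blocks, return_counts=True)
    multi = labels[counts >= 2]
    if len(multi) < 2:
        warnings.warn("fewer than two multi-sample blocks; consensus rho = 0")
        return 0.0
    q, _ = np.linalg.qr(x)
    resid = y - (y @ q) @ q.T
    sd = resid.std(axis=1, ddof=x.shape[1])
    ok = sd > 0
    z = resid[ok] / sd[ok][:, None]
    # accumulate within-block pair products
    pair_sum = np.zeros(z.shape[0])
    n_pairs = 0
    for b in multi:
        idx = np.flatnonzero(blocks == b)
        zb = z[:, idx]
        s = zb.sum(axis=1)
        sq = (zb**2).sum(axis=1)
        pair_sum += 0.5 * (s**2 - sq)
        n_pairs += len(idx) * (len(idx) - 1) // 2
    rho_g = np.clip(pair_sum / n_pairs, -0.99, 0.99)
    zf = np.arctanh(rho_g)
    return float(np.tanh(stats.trim_mean(zf, trim)))


# ---------------------------------------------------------------------------
# moderated fit
# ---------------------------------------------------------------------------

@dataclass
class ModeratedFit:
    """Per-(ASV, contrast) moderated statistics plus the shared prior."""

    table: pd.DataFrame  # columns: asv_id, contrast, logFC, t, p, fdr
    prior_df: float
    prior_var: float
    rho: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-matched scaled-F prior (d0, s0^2) for residual variances.

    Follows the classical empirical-Bayes recipe on log s^2; a negative
    excess-variance estimate falls back to an infinite prior df with
    s0^2 = mean(s^2).
    """
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[s2 > 0])) if (s2 > 0).any() else 1.0
    z = np.log(s2[ok])
    d = df[ok].astype(float)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        return d0, s0
    logger.warning("negative prior-variance moment; falling back to d0 = inf")
    return np.inf, float(np.mean(s2[ok]))


def _block_cholesky(blocks, rho: float) -> np.ndarray:
    blocks = np.asarray(blocks)
    n = len(blocks)
    r = np.eye(n)
    same = blocks[:, None] == blocks[None, :]
    r[same] = rho
    np.fill_diagonal(r, 1.0)
    return cholesky(r, lower=True)


def fit_moderated(
    vm: VoomMatrices,
    design: np.ndarray,
    contrasts: dict[str, np.ndarray],
    rho: float = 0.0,
    blocks=None,
    groups=None,
    detected=None,
    prior: tuple[float, float] | None = None,
) -> ModeratedFit:
    """Weighted (optionally block-correlated) least squares with
    empirical-Bayes variance moderation.

    Parameters
    ----------
    contrasts
        Mapping contrast name -> coefficient-space vector.
    groups
        Optional per-sample group labels (e.g. the day factor); for each
        ASV the residual df is reduced by the number of groups whose
        counts are identically zero, guarding against zero-variance cells
        in sparse data.
    prior
        Optional fixed (d0, s0^2) overriding the estimated prior (d0=0
        reproduces ordinary t statistics).
    """
    x = _design_matrix(design)
    y = vm.logcpm.to_numpy()
    w = vm.weights.to_numpy()
    n_asv, n = y.shape
    p = np.linalg.matrix_rank(x)
    base_df = n - p
    if base_df <= 0:
        raise ValueError("no residual degrees of freedom")

    l_r = _block_cholesky(blocks, rho) if (blocks is not None and rho != 0.0) else None

    zero_groups = np.zeros(n_asv, dtype=int)
    if groups is not None and detected is not None:
        groups = np.asarray(groups)
        det = np.asarray(detected, dtype=bool)
        for g in np.unique(groups):
            idx = np.flatnonzero(groups == g)
            zero_groups += (~det[:, idx].any(axis=1)).astype(int)

    cnames = list(contrasts)
    cmat = np.column_stack([np.asarray(contrasts[c], float) for c in cnames])
    if cmat.shape[0] != x.shape[1]:
        raise ValueError("contrast length does not match design columns")

    est = np.zeros((n_asv, len(cnames)))
    se_unscaled = np.zeros_like(est)
    s2 = np.zeros(n_asv)
    dfs = np.maximum(base_df - zero_groups, 1).astype(float)

    for g in range(n_asv):
        sw = np.sqrt(w[g])
        if l_r is None:
            xw = x * sw[:, None]
            yw = y[g] * sw
        else:
            # V = S R S with S = diag(1/sqrt(w)); whitening solves (S L_R) z = v
            xw = solve_triangular(l_r, x * sw[:, None], lower=True)
            yw = solve_triangular(l_r, y[g] * sw, lower=True)
        xtx = xw.T @ xw
        c_fac = cho_factor(xtx)
        beta = cho_solve(c_fac, xw.T @ yw)
        rss = float(np.sum((yw - xw @ beta) ** 2))
        s2[g] = rss / dfs[g]
        xtx_inv_c = cho_solve(c_fac, cmat)
        est[g] = beta @ cmat
        se_unscaled[g] = np.sqrt(np.einsum("ij,ij->j", cmat, xtx_inv_c))

    d0, s0 = estimate_prior(s2, dfs) if prior is None else prior
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.full_like(dfs, np.inf)
    else:
        s2_post = (d0 * s0 + dfs * s2) / (d0 + dfs)
        df_total = d0 + dfs
    s2_post = np.where(s2_post > 0, s2_post, s0 if s0 > 0 else 1e-12)

    rows = []
    for j, cname in enumerate(cnames):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est[:, j] / (se_unscaled[:, j] * np.sqrt(s2_post))
        if np.isinf(d0):
            pvals = 2.0 * stats.norm.sf(np.abs(t))
        else:
            pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
        pvals = np.where(np.isfinite(t), pvals, 1.0)
        for g, asv in enumerate(vm.logcpm.index):
            rows.append((asv, cname, est[g, j], t[g], pvals[g]))
    out = pd.DataFrame(rows, columns=["asv_id", "contrast", "logFC", "t", "p"])
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return ModeratedFit(out, d0, s0, rho)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# technical-variable screen (criterion i)
# ---------------------------------------------------------------------------

def _day_model(design: StudyDesign, sample_ids) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    frame = design.frame.loc[sample_ids]
    days = frame["extraction_day"].astype(str)
    levels = sorted(days.unique())
    x = np.column_stack([(days == lv).to_numpy(float) for lv in levels])
    return x, levels, frame


def technical_contrasts(design: StudyDesign, sample_ids) -> tuple[np.ndarray, dict[str, dict[str, np.ndarray]], list[str]]:
    """One-hot day-means model and the contrast families for run, DEB and day.

    Because day is nested in DEB which is nested in run, every technical
    comparison is a contrast of day means: run and DEB contrasts average
    the day coefficients of each level; day contrasts compare only days
    sharing a DEB.
    """
    x, levels, frame = _day_model(design, sample_ids)
    pos = {lv: i for i, lv in enumerate(levels)}
    meta = (
        frame.assign(extraction_day=frame["extraction_day"].astype(str))
        .groupby("extraction_day", observed=True)
        .agg(batch=("extraction_batch", "first"), run=("sequencing_run", "first"))
    )

    def mean_vec(day_set) -> np.ndarray:
        v = np.zeros(len(levels))
        for d in day_set:
            v[pos[d]] = 1.0 / len(day_set)
        return v

    import itertools as it

    families: dict[str, dict[str, np.ndarray]] = {}
    runs = sorted(meta["run"].dropna().astype(str).unique())
    if len(runs) >= 2:
        fam = {}
        for a, b in it.combinations(runs, 2):
            da = list(meta.index[meta["run"].astype(str) == a])
            db = list(meta.index[meta["run"].astype(str) == b])
            fam[f"run:{a}-vs-{b}"] = mean_vec(da) - mean_vec(db)
        families["sequencing_run"] = fam
    batches = sorted(meta["batch"].dropna().astype(str).unique())
    if len(batches) >= 2:
        fam = {}
        for a, b in it.combinations(batches, 2):
            da = list(meta.index[meta["batch"].astype(str) == a])
            db = list(meta.index[meta["batch"].astype(str) == b])
            fam[f"batch:{a}-vs-{b}"] = mean_vec(da) - mean_vec(db)
        families["extraction_batch"] = fam
    day_fam = {}
    for b in batches:
        days_b = sorted(meta.index[meta["batch"].astype(str) == b])
        for a, c in it.combinations(days_b, 2):
            day_fam[f"day:{a}-vs-{c}"] = mean_vec([a]) - mean_vec([c])
    if day_fam:
        families["extraction_day"] = day_fam
    return x, families, levels


def batch_effect_flags(
    fits: dict[str, ModeratedFit], asv_ids, fdr_cut: float = 0.05
) -> pd.Series:
    """Flag = significant (FDR <= cut) in ANY contrast of ANY technical
    variable; criterion (i) passers are the unflagged ASVs."""
    flags = pd.Series(False, index=list(asv_ids))
    if not fits:
        warnings.warn("no technical-variable contrasts available; all ASVs pass")
        return flags
    for fit in fits.values():
        hit = fit.table.loc[fit.table["fdr"] <= fdr_cut, "asv_id"].unique()
        flags.loc[flags.index.intersection(hit)] = True
    return flags


def technical_variable_screen(
    table: AsvCountTable,
    design: StudyDesign,
    fdr_cut: float = 0.05,
    include_dencs: bool = False,
    block_on_patient: bool = True,
) -> tuple[pd.Series, dict[str, ModeratedFit]]:
    """Full criterion (i) screen on plasma samples.

    Returns the per-ASV batch-effect flag (True = batch-affected) and the
    per-variable moderated fits.  DNA-extraction negative controls are
    excluded by default: the criterion concerns abundance differences
    among plasma samples across technical variables.
    """
    types = ("plasma", "plasma_denc") if include_dencs else ("plasma",)
    ids = [s for s in table.sample_ids if design.frame.loc[s, "sample_type"] in types]
    sub = table.subset_samples(ids)
    x, families, levels = technical_contrasts(design, ids)
    if not families:
        warnings.warn("single batch/run/day: no technical contrasts; all ASVs pass")
        return pd.Series(False, index=table.asv_ids), {}

    nf = tmm_factors(sub)
    vm = voom_weights(sub, nf, x)

    rho = 0.0
    blocks = None
    patients = design.frame.loc[ids, "patient_id"]
    if block_on_patient and patients.notna().any() and patients.nunique() < len(ids):
        blocks = patients.fillna("__none__").astype(str).to_numpy()
        rho = consensus_correlation(vm, x, blocks)

    day_groups = design.frame.loc[ids, "extraction_day"].astype(str).to_numpy()
    fits = {}
    for var, fam in families.items():
        fits[var] = fit_moderated(
            vm, x, fam, rho=rho, blocks=blocks, groups=day_groups, detected=sub.matrix > 0
        )
    flags = batch_effect_flags(fits, table.asv_ids, fdr_cut=fdr_cut)
    return flags, fits
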
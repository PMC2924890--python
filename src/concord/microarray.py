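"""Two-channel microarray normalization and SAM differential expression.

The arrays follow a common-reference design: every treatment sample is
hybridised against one pooled control, so each array yields per-spot log2
ratios M = log2(treat/ref) that are directly comparable across arrays, and
differential expression is a one-class test of the replicate M values
against zero.

Normalization is a Generalized Procrustes Analysis on each array's (A, M)
point configuration (A = mean log2 intensity, M = log2 ratio, one point per
spot): configurations are centred (translation), brought to a common
Frobenius norm (isotropic scaling) and then iteratively rotated to the
evolving consensus until the consensus stops moving. Each step solves a
least-squares subproblem, so the consensus residual is non-increasing.

The DE statistic is the SAM moderated t: d_i = rbar_i / (s_i + s0), with
permutation q-values obtained by sign-flipping arrays (the one-class null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from .errors import InputError, NormalizationError

ARRAY_COLUMNS = ["array_id", "treatment", "dye_swapped", "spot_id",
                 "gene_id", "ch_treat", "ch_ref"]


def orient_dye_swaps(arrays: pd.DataFrame) -> pd.DataFrame:
    """Swap the channel columns of dye-reversal arrays back into treatment
    orientation and clear the flag."""
    out = arrays.copy()
    sw = out["dye_swapped"].astype(bool)
    out.loc[sw, ["ch_treat", "ch_ref"]] = \
        out.loc[sw, ["ch_ref", "ch_treat"]].to_numpy()
    out["dye_swapped"] = False
    return out


def _to_am(sub: pd.DataFrame) -> np.ndarray:
    t = sub["ch_treat"].to_numpy(dtype=float)
    r = sub["ch_ref"].to_numpy(dtype=float)
    lt, lr = np.log2(t), np.log2(r)
    return np.column_stack([(lt + lr) / 2.0, lt - lr])


def gpa_normalize(arrays: pd.DataFrame, tol: float = 1e-10,
                  max_iter: int = 100) -> pd.DataFrame:
    """Generalized Procrustes normalization of a set of arrays.

    Expects the spot table of one treatment (or any set of >= 2 arrays
    covering the same spots). Dye-reversal arrays are re-oriented first.
    Returns a table of the same schema with back-transformed intensities.
    """
    if (arrays[["ch_treat", "ch_ref"]].to_numpy() <= 0).any():
        raise InputError("non-positive intensity in input")
    arrays = orient_dye_swaps(arrays)
    ids = sorted(arrays["array_id"].unique())
    if len(ids) < 2:
        raise NormalizationError("GPA needs at least 2 arrays")

    subs = {a: arrays[arrays["array_id"] == a].sort_values("spot_id")
            for a in ids}
    spot_sets = [tuple(s["spot_id"]) for s in subs.values()]
    if len(set(spot_sets)) != 1:
        raise InputError("arrays do not cover the same spot set")

    configs = [_to_am(subs[a]) for a in ids]
    means = [c.mean(axis=0) for c in configs]
    centred = [c - m for c, m in zip(configs, means)]
    norms = [np.linalg.norm(c) for c in centred]
    target_norm = float(np.mean(norms))
    scaled = [c * (target_norm / n) if n > 0 else c.copy()
              for c, n in zip(centred, norms)]

    consensus = np.mean(scaled, axis=0)
    prev = np.inf
    for _ in range(max_iter):
        rotated = []
        for c in scaled:
            R, _ = orthogonal_procrustes(c, consensus)
            rotated.append(c @ R)
        consensus = np.mean(rotated, axis=0)
        resid = float(sum(np.linalg.norm(c - consensus) ** 2 for c in rotated))
        scaled = rotated
        if prev - resid < tol * max(1.0, abs(prev)):
            break
        prev = resid

    # Back-transform: restore a common intensity location (grand mean of
    # the per-array A means) and rebuild the two channels. The M location
    # is restored so each array ends *median*-centred in M: the mean
    # translation used for alignment absorbs the net log-ratio of the
    # regulated genes (a real signal component) along with the dye/gain
    # offset, and re-adding (mean - median) puts the signal back while the
    # robust location, dominated by unregulated genes, stays at zero.
    m_back = float(np.mean([
        c[:, 1].mean() - np.median(c[:, 1]) for c in configs]))
    grand = np.array([float(np.mean([m[0] for m in means])), m_back])
    frames = []
    for a, c in zip(ids, scaled):
        am = c + grand
        A, M = am[:, 0], am[:, 1]
        sub = subs[a].copy()
        sub["ch_treat"] = 2.0 ** (A + M / 2.0)
        sub["ch_ref"] = 2.0 ** (A - M / 2.0)
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def gpa_residual(arrays: pd.DataFrame) -> float:
    """Consensus residual sum of squares of the (centred) configurations."""
    arrays = orient_dye_swaps(arrays)
    configs = [(_to_am(sub.sort_values("spot_id")))
               for _, sub in arrays.groupby("array_id")]
    centred = [c - c.mean(axis=0) for c in configs]
    consensus = np.mean(centred, axis=0)
    return float(sum(np.linalg.norm(c - consensus) ** 2 for c in centred))


def collapse_replicates(arrays: pd.DataFrame,
                        treatment: str | None = None) -> pd.DataFrame:
    """Per-gene, per-array mean log2 ratio (duplicate spots averaged).

    Returns a genes x arrays DataFrame of M values, treatment-oriented
    (dye swaps corrected).
    """
    sub = arrays if treatment is None else arrays[arrays["treatment"] == treatment]
    if sub.empty:
        raise InputError(f"no arrays for treatment {treatment!r}")
    sub = orient_dye_swaps(sub)
    m = np.log2(sub["ch_treat"].to_numpy() / sub["ch_ref"].to_numpy())
    tmp = pd.DataFrame({"gene_id": sub["gene_id"].to_numpy(),
                        "array_id": sub["array_id"].to_numpy(), "M": m})
    return tmp.pivot_table(index="gene_id", columns="array_id", values="M",
                           aggfunc="mean")


@dataclass
class SamResult:
    """Per-gene SAM statistics plus the fudge factor used."""

    stats: pd.DataFrame  # index gene_id; columns mean, s, d, excluded
    s0: float


def _fudge_factor_tusher(means: np.ndarray, s: np.ndarray) -> float:
    """Coefficient-of-variation minimisation for s0 over an s-percentile grid.

    For each candidate s0, the d statistics are binned by s-quantile and the
    coefficient of variation of their median absolute deviation across bins
    is minimised: the s0 that makes the spread of d least dependent on s.
    """
    qs = np.percentile(s, np.arange(0, 101, 5))
    cand = np.unique(qs)
    edges = np.percentile(s, np.arange(0, 101, 10))
    best, best_cv = cand[0], np.inf
    for s0 in cand:
        d = means / (s + s0)
        mads = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (s >= lo) & (s <= hi)
            if sel.sum() >= 2:
                di = d[sel]
                mads.append(np.median(np.abs(di - np.median(di))) / 0.6745)
        mads = np.asarray(mads)
        if len(mads) < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv:
            best_cv, best = cv, s0
    return float(best)


def sam_statistic(M: pd.DataFrame, s0: float | None = None,
                  s0_method: str = "percentile") -> SamResult:
    """One-class SAM statistic per gene.

    ``M`` is a genes x replicate-arrays frame of log2 ratios. For each gene,
    d = mean / (se + s0) with se the standard error across replicates.
    ``s0`` defaults to the 5th percentile of the se distribution
    (``s0_method="percentile"``) or the coefficient-of-variation minimiser
    (``s0_method="tusher"``). Genes with fewer than 2 finite replicates are
    excluded (d and s set to NaN).
    """
    import warnings as _warnings

    X = M.to_numpy(dtype=float)
    n_fin = np.isfinite(X).sum(axis=1)
    excluded = n_fin < 2
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # excluded rows
        mean = np.nanmean(np.where(np.isfinite(X), X, np.nan), axis=1)
        sd = np.nanstd(np.where(np.isfinite(X), X, np.nan), axis=1, ddof=1)
    s = sd / np.sqrt(np.maximum(n_fin, 1))
    mean[excluded] = np.nan
    s[excluded] = np.nan

    ok = ~excluded
    if s0 is None:
        if s0_method == "percentile":
            s0 = float(np.percentile(s[ok], 5))
        elif s0_method == "tusher":
            s0 = _fudge_factor_tusher(mean[ok], s[ok])
        else:
            raise InputError(f"unknown s0_method {s0_method!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        d = mean / (s + s0)  # s == s0 == 0 with mean != 0 -> +-inf guard
    d[ok & (s + s0 == 0) & (mean == 0)] = 0.0

    stats = pd.DataFrame({"mean": mean, "s": s, "d": d, "excluded": excluded},
                         index=M.index)
    return SamResult(stats, float(s0))


def _d_from_matrix(X: np.ndarray, s0: float) -> np.ndarray:
    mean = X.mean(axis=1)
    s = X.std(axis=1, ddof=1) / np.sqrt(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        d = mean / (s + s0)
    d[(s + s0 == 0) & (mean == 0)] = 0.0
    return d


def sam_qvalues(M: pd.DataFrame, sam: SamResult, n_perm: int = 200,
                seed: int = 0) -> pd.Series:
    """Permutation q-values for the one-class SAM statistic.

    Null d distributions come from random sign-flips of whole replicate
    arrays. For each gene, the estimated FDR at threshold t = |d_i| is the
    median over permutations of #{|d*| >= t} divided by the observed
    #{|d| >= t}; the q-value is the minimum estimated FDR over all
    thresholds at which the gene is still called, which makes q monotone
    non-increasing in |d| rank. Excluded genes get q = NaN.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    ok = ~sam.stats["excluded"].to_numpy()
    X = M.to_numpy(dtype=float)[ok]
    d_obs = sam.stats["d"].to_numpy()[ok]
    n_genes, n_arr = X.shape

    rng = np.random.default_rng(seed)
    abs_obs = np.abs(d_obs)
    order = np.argsort(-abs_obs, kind="stable")
    thresholds = abs_obs[order]                     # descending
    obs_counts = np.arange(1, n_genes + 1, dtype=float)
    # ties: every gene with the same |d| shares the largest count
    for i in range(n_genes - 2, -1, -1):
        if thresholds[i] == thresholds[i + 1]:
            obs_counts[i] = obs_counts[i + 1]

    null_counts = np.empty((n_perm, n_genes))
    for b in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_arr)
        d_null = np.sort(np.abs(_d_from_matrix(X * signs, sam.s0)))
        # #{|d*| >= t} for each descending threshold t
        null_counts[b] = n_genes - np.searchsorted(d_null, thresholds,
                                                   side="left")
    med = np.median(null_counts, axis=0)
    fdr = np.clip(med / obs_counts, 0.0, 1.0)
    # q_i = min FDR over thresholds <= |d_i| (suffix minimum in rank order)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(n_genes)
    q[order] = q_sorted

    out = pd.Series(np.nan, index=M.index, name="q")
    out.iloc[np.flatnonzero(ok)] = q
    return out


def signed_fold_change(ratio):
    """Map a positive expression ratio to the signed fold-change convention.

    Ratios >= 1 stay as-is; ratios < 1 become -1/ratio, so a halving is -2.
    Negative values mean a decrease relative to control; |FC| >= 1 always.
    """
    r = np.asarray(ratio, dtype=float)
    if np.any(r <= 0):
        raise InputError("ratio must be strictly positive")
    out = np.where(r >= 1.0, r, -1.0 / r)
    return float(out) if np.isscalar(ratio) or out.ndim == 0 else out


def de_transcripts(arrays: pd.DataFrame, treatment: str,
                   q_threshold: float = 0.05, n_perm: int = 200,
                   seed: int = 0, normalize: bool = True,
                   s0: float | None = None) -> pd.DataFrame:
    """Full DE call for one treatment: normalize, SAM, q-values, selection.

    Returns a per-gene table (gene_id, treatment, mean_log2, signed_fc, d,
    s, q, is_de) sorted by (q, -|d|, gene_id).
    """
    sub = arrays[arrays["treatment"] == treatment]
    if normalize:
        sub = gpa_normalize(sub)
    M = collapse_replicates(sub)
    sam = sam_statistic(M, s0=s0)
    q = sam_qvalues(M, sam, n_perm=n_perm, seed=seed)
    res = sam.stats.copy()
    res["q"] = q
    res["treatment"] = treatment
    res["signed_fc"] = np.nan
    ok = ~res["excluded"]
    res.loc[ok, "signed_fc"] = signed_fold_change(
        2.0 ** res.loc[ok, "mean"].to_numpy())
    res["is_de"] = ok & (res["q"] < q_threshold)
    res = res.rename(columns={"mean": "mean_log2"}).reset_index()
    res["abs_d"] = res["d"].abs()
    res = res.sort_values(["q", "abs_d", "gene_id"],
                          ascending=[True, False, True],
                          ignore_index=True).drop(columns="abs_d")
    return res[["gene_id", "treatment", "mean_log2", "signed_fc", "d", "s",
                "q", "is_de"]]


def select_de(results: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Genes with q < threshold, sorted by q then |d| (descending)."""
    sel = results[results["q"] < q_threshold].copy()
    sel["abs_d"] = sel["d"].abs()
    sel = sel.sort_values(["q", "abs_d", "gene_id"],
                          ascending=[True, False, True],
                          ignore_index=True).drop(columns="abs_d")
    return sel
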
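"""iTRAQ reporter-ion quantitation: PSM filters, protein ratios, error
factors, p-values and reversed-database FDR.

A PSM contributes one log2 reporter ratio per treatment (label 115 or 117
over the control label 114). A protein's ratio is the mean of its PSM log
ratios back-transformed to the ratio scale; the error factor EF is the
multiplicative half-width of the Student-t 95% interval on that mean, so the
true ratio lies in [ratio/EF, ratio*EF] with 95% confidence, and the
p-value is the dual two-sided one-sample t-test of the mean log ratio
against zero (p < 0.05 iff 1 lies outside the EF interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import TREATMENTS, TREATMENT_LABELS
from .errors import InputError, QuantitationError

#: Reason string attached to proteins with too few quantifiable spectra.
REFUSAL_LOW_SIGNAL = "peptide signal was too low"


def filter_spectra(psms: pd.DataFrame, confidence_min: float = 0.95,
                   sn_min: float = 9.0) -> pd.DataFrame:
    """Quantitation filter: confidence >= threshold, signal-to-noise sum
    strictly > threshold, shared peptides excluded. Order preserved."""
    keep = ((psms["confidence"] >= confidence_min)
            & (psms["sn_sum"] > sn_min)
            & (~psms["is_shared"].astype(bool)))
    return psms[keep]


def score_from_confidence(confidence, max_score: float = 10.0):
    """Identification score -log10(1 - confidence); 0.95 maps to ~1.301.

    A confidence of exactly 1 is capped at ``max_score``.
    """
    c = np.asarray(confidence, dtype=float)
    if np.any((c < 0) | (c > 1)):
        raise InputError("confidence must be in [0, 1]")
    with np.errstate(divide="ignore"):
        s = -np.log10(1.0 - c)
    s = np.where(np.isfinite(s), np.minimum(s, max_score), max_score)
    return float(s) if np.isscalar(confidence) or s.ndim == 0 else s


@dataclass
class DecoyFdr:
    """Reversed-database FDR estimate at one score threshold."""

    n_targets: int
    n_decoys: int
    fdr: float | None  # None when no target exceeds the threshold

    @property
    def defined(self) -> bool:
        return self.fdr is not None


def decoy_fdr(psms: pd.DataFrame, score_threshold: float,
              max_score: float = 10.0) -> DecoyFdr:
    """FDR = decoys above threshold / targets above threshold.

    Scores derive from the confidence column. Not monotone in the threshold
    in general; callers must not assume it is.
    """
    scores = score_from_confidence(psms["confidence"].to_numpy(), max_score)
    above = scores >= score_threshold
    decoy = psms["is_decoy"].astype(bool).to_numpy()
    n_d = int((above & decoy).sum())
    n_t = int((above & ~decoy).sum())
    return DecoyFdr(n_t, n_d, (n_d / n_t) if n_t > 0 else None)


@dataclass
class ProteinQuant:
    """Per-protein, per-treatment quantitation."""

    protein_id: str
    treatment: str
    ratio: float
    log2_ratio: float
    ef: float
    p: float
    n_spectra: int
    tier: str               # "confident" (>=3 spectra) or "reported" (2)
    zero_variance: bool = False


def protein_ratio(psms: pd.DataFrame, treatment: str) -> ProteinQuant:
    """Aggregate the PSMs of one protein into a treatment ratio.

    Per-PSM log ratio is log2(i_label / i114) with the label given by the
    treatment (115 for LY, 117 for SKF). The protein log ratio is their
    arithmetic mean; EF = 2**(t_{0.975, n-1} * SE); p is the two-sided
    one-sample t-test of the log ratios against 0. Fewer than 2 spectra
    refuse quantitation; zero scatter with n >= 2 is guarded (EF = 1,
    p = 0, flagged).
    """
    if treatment not in TREATMENTS:
        raise InputError(f"unknown treatment {treatment!r}")
    label = TREATMENT_LABELS[treatment]
    n = len(psms)
    if n < 2:
        raise QuantitationError(
            f"protein with {n} spectra not quantified: {REFUSAL_LOW_SIGNAL}")
    logr = np.log2(psms[f"i{label}"].to_numpy(dtype=float)
                   / psms["i114"].to_numpy(dtype=float))
    mean = float(logr.mean())
    sd = float(logr.std(ddof=1))
    pid = str(psms["protein_id"].iloc[0])
    tier = "confident" if n >= 3 else "reported"
    if sd == 0.0:
        return ProteinQuant(pid, treatment, 2.0 ** mean, mean, 1.0, 0.0,
                            n, tier, zero_variance=True)
    se = sd / np.sqrt(n)
    tcrit = float(stats.t.ppf(0.975, n - 1))
    ef = float(2.0 ** (tcrit * se))
    p = float(stats.ttest_1samp(logr, 0.0).pvalue)
    return ProteinQuant(pid, treatment, 2.0 ** mean, mean, ef, p, n, tier)


def quantify_proteins(psms: pd.DataFrame, confidence_min: float = 0.95,
                      sn_min: float = 9.0, apply_filter: bool = True,
                      bh_adjust: bool = False) -> pd.DataFrame:
    """Protein-level table for both treatments from a PSM table.

    Applies the spectrum filter (optionally), drops decoy PSMs, and
    aggregates per protein. Proteins with a single surviving spectrum are
    reported with NaN statistics and the refusal reason. With
    ``bh_adjust``, a Benjamini-Hochberg adjusted column ``p_bh`` is added
    per treatment (computed across quantified proteins).
    """
    work = filter_spectra(psms, confidence_min, sn_min) if apply_filter else psms
    work = work[~work["is_decoy"].astype(bool)]
    rows = []
    for pid, grp in work.groupby("protein_id", sort=True):
        for t in TREATMENTS:
            try:
                pq = protein_ratio(grp, t)
            except QuantitationError:
                rows.append({"protein_id": pid, "treatment": t,
                             "ratio": np.nan, "log2_ratio": np.nan,
                             "ef": np.nan, "p": np.nan,
                             "n_spectra": len(grp), "tier": "",
                             "zero_variance": False,
                             "reason": REFUSAL_LOW_SIGNAL})
                continue
            rows.append({**pq.__dict__, "reason": ""})
    out = pd.DataFrame(rows)
    if bh_adjust and not out.empty:
        out["p_bh"] = np.nan
        for t in TREATMENTS:
            sel = (out["treatment"] == t) & out["p"].notna()
            out.loc[sel, "p_bh"] = _bh(out.loc[sel, "p"].to_numpy())
    return out


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.clip(adj, 0.0, 1.0)


def bias_correct(quants: pd.DataFrame) -> pd.DataFrame:
    """Global labelling-bias correction: re-centre each treatment channel so
    the median protein log ratio is zero. Requires >= 10 quantified
    proteins. Off by default in the pipeline."""
    out = quants.copy()
    for t in TREATMENTS:
        sel = (out["treatment"] == t) & out["log2_ratio"].notna()
        if sel.sum() < 10:
            raise QuantitationError(
                f"bias correction needs >= 10 quantified proteins for {t}")
        med = float(out.loc[sel, "log2_ratio"].median())
        out.loc[sel, "log2_ratio"] = out.loc[sel, "log2_ratio"] - med
        out.loc[sel, "ratio"] = 2.0 ** out.loc[sel, "log2_ratio"]
    return out


def select_de_proteins(quants: pd.DataFrame, p_threshold: float = 0.05,
                       use_bh: bool = False) -> pd.DataFrame:
    """Proteins significant (p < threshold, strict) in at least one
    treatment, one row per protein with a signed fold change per treatment
    (NaN where that treatment is not significant)."""
    from .microarray import signed_fold_change

    pcol = "p_bh" if use_bh else "p"
    rows = {}
    for _, r in quants.iterrows():
        if pd.isna(r[pcol]) or not (r[pcol] < p_threshold):
            continue
        entry = rows.setdefault(r["protein_id"], {
            "protein_id": r["protein_id"],
            "fc_skf": np.nan, "fc_ly": np.nan,
            "p_skf": np.nan, "p_ly": np.nan,
            "tier": r["tier"]})
        tl = r["treatment"].lower()
        entry[f"fc_{tl}"] = signed_fold_change(float(r["ratio"]))
        entry[f"p_{tl}"] = float(r[pcol])
    cols = ["protein_id", "fc_skf", "fc_ly", "p_skf", "p_ly", "tier"]
    return pd.DataFrame(list(rows.values()), columns=cols) \
        .sort_values("protein_id", ignore_index=True)
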
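"""Synthetic two-omics data generator.

Emulates the measurement structure the downstream analysis assumes:

* a per-gene hidden truth (coding sequence, its translated protein, and true
  log2 treatment effects on mRNA and protein, with a tunable probability
  that the two layers share an effect sign);
* two-channel common-reference microarrays, duplicate spots per gene,
  replicate arrays with one dye-reversal, multiplicative lognormal noise and
  per-array scale/gain distortions;
* iTRAQ 4-plex peptide-spectrum matches: in-silico tryptic peptides of the
  true proteins, reporter intensities for labels 114/115/117 whose expected
  log ratios equal the true protein effects, plus reversed-sequence decoy
  PSMs and an equal expected number of incorrect target PSMs (both with low
  confidence scores) so that decoy-based FDR estimation is exercised against
  a real false-identification rate.

All randomness derives from ``SimConfig.seed`` through fixed per-table
streams, so adding arrays never perturbs the PSM table and regeneration is
bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .config import SimConfig, TREATMENTS
from .errors import ConfigurationError

#: Fraction of incorrect identifications that are confidently wrong
#: (confidence drawn Uniform(0.9, 1) instead of Beta(1, 8)).
_HIGH_CONF_ERROR_RATE = 0.15

# Fixed sub-stream offsets from the master seed (one stream per output).
_STREAM_TRUTH = 0
_STREAM_ARRAYS = 1
_STREAM_PSMS = 2

# The 61 sense codons of the standard genetic code.
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [a + b + c
                 for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in _STOPS]


@dataclass
class GroundTruth:
    """Hidden state of a simulation: one row per gene.

    Columns: ``gene_id``, ``protein_acc``, ``coding_seq``, ``protein_seq``,
    and per treatment ``mrna_<t>``, ``prot_<t>`` (true log2 effects, exactly
    0 for non-DE genes) with boolean flags ``de_mrna_<t>``, ``de_prot_<t>``.
    """

    table: pd.DataFrame

    def effects(self, layer: str, treatment: str) -> pd.Series:
        """True log2 effects for one layer ('mrna'|'prot') and treatment."""
        key = "gene_id" if layer == "mrna" else "protein_acc"
        col = f"{layer}_{treatment.lower()}"
        return self.table.set_index(key)[col]

    def de_ids(self, layer: str, treatment: str) -> set:
        key = "gene_id" if layer == "mrna" else "protein_acc"
        flag = f"de_{layer}_{treatment.lower()}"
        return set(self.table.loc[self.table[flag], key])


def _random_coding_sequence(rng: np.random.Generator, n_residues: int) -> str:
    """ATG followed by random sense codons: no internal stops by design."""
    body = rng.choice(len(_SENSE_CODONS), size=n_residues - 1)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body)


def generate_ground_truth(config: SimConfig) -> GroundTruth:
    """Draw the hidden per-gene truth table.

    Exactly ``round(n_genes * frac_de_mrna)`` genes receive a nonzero mRNA
    effect per treatment (similarly for proteins). Effect magnitude is fixed
    at ``effect_size_log2``; the mRNA sign is a fair coin, and for genes DE
    in both layers the protein sign equals the mRNA sign with probability
    ``concordance_rate`` (otherwise random).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_TRUTH])
    n = config.n_genes

    lengths = rng.integers(config.protein_len_min, config.protein_len_max + 1,
                           size=n)
    coding = [_random_coding_sequence(rng, int(L)) for L in lengths]
    proteins = [str(Seq(c).translate()) for c in coding]

    rows: dict[str, np.ndarray | list] = {
        "gene_id": [f"G{i:05d}" for i in range(n)],
        "protein_acc": [f"P{i:05d}" for i in range(n)],
        "coding_seq": coding,
        "protein_seq": proteins,
    }

    n_de_m = int(round(n * config.frac_de_mrna))
    n_de_p = int(round(n * config.frac_de_protein))
    eff = config.effect_size_log2
    for t in TREATMENTS:
        tl = t.lower()
        de_m = np.zeros(n, dtype=bool)
        de_m[rng.choice(n, size=n_de_m, replace=False)] = True
        de_p = np.zeros(n, dtype=bool)
        de_p[rng.choice(n, size=n_de_p, replace=False)] = True

        sign_m = rng.choice([-1.0, 1.0], size=n)
        # Protein sign: tied to the mRNA sign at the concordance rate for
        # genes DE in both layers; independent coin otherwise.
        agree = rng.random(n) < config.concordance_rate
        indep = rng.choice([-1.0, 1.0], size=n)
        sign_p = np.where(de_m & de_p, np.where(agree, sign_m, -sign_m), indep)

        rows[f"mrna_{tl}"] = np.where(de_m, sign_m * eff, 0.0)
        rows[f"prot_{tl}"] = np.where(de_p, sign_p * eff, 0.0)
        rows[f"de_mrna_{tl}"] = de_m
        rows[f"de_prot_{tl}"] = de_p

    return GroundTruth(pd.DataFrame(rows))


def simulate_microarray(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Simulate the two-channel common-reference arrays for both treatments.

    Returns the spot-level table (one row per spot per array) with columns
    ``array_id, treatment, dye_swapped, spot_id, gene_id, ch_treat, ch_ref``.
    Each gene is printed in duplicate; the last array of each treatment is a
    dye-reversal (its two channel columns are swapped). Intensities are
    strictly positive; the expected log2(treat/ref) of a spot equals the
    gene's true mRNA effect.
    """
    rng = np.random.default_rng([config.seed, _STREAM_ARRAYS])
    n = len(truth.table)
    base = rng.normal(10.0, 1.5, size=n)  # per-gene log2 abundance
    spot_sd = config.array_noise_sd / np.sqrt(2.0)  # per channel

    frames = []
    for t in TREATMENTS:
        eff = truth.table[f"mrna_{t.lower()}"].to_numpy()
        for a in range(config.n_arrays_per_treatment):
            swapped = a == config.n_arrays_per_treatment - 1
            scale = rng.normal(0.0, config.array_scale_sd)
            gain = rng.normal(0.0, config.channel_gain_sd)
            for dup in range(2):
                log_ref = (base + scale
                           + rng.normal(0.0, spot_sd, size=n))
                log_tr = (base + eff + scale + gain
                          + rng.normal(0.0, spot_sd, size=n))
                ch_tr, ch_ref = 2.0 ** log_tr, 2.0 ** log_ref
                if swapped:
                    ch_tr, ch_ref = ch_ref, ch_tr
                frames.append(pd.DataFrame({
                    "array_id": f"{t}_A{a + 1}",
                    "treatment": t,
                    "dye_swapped": swapped,
                    "spot_id": [f"S{i:05d}_{dup}" for i in range(n)],
                    "gene_id": truth.table["gene_id"].to_numpy(),
                    "ch_treat": ch_tr,
                    "ch_ref": ch_ref,
                }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["treatment", "array_id", "spot_id"],
                           ignore_index=True)


def tryptic_digest(protein: str, min_len: int = 6, max_len: int = 30,
                   ) -> list[str]:
    """In-silico tryptic peptides: cleave after K/R unless followed by P.

    No missed cleavages; only peptides inside the length window are kept.
    """
    peptides, start = [], 0
    for i, aa in enumerate(protein):
        last = i == len(protein) - 1
        if last or (aa in "KR" and protein[i + 1] != "P"):
            pep = protein[start:i + 1]
            if min_len <= len(pep) <= max_len:
                peptides.append(pep)
            start = i + 1
    return peptides


def simulate_itraq(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Simulate the 4-plex PSM table (labels 114 control / 115 LY / 117 SKF).

    One row per identified spectrum with columns ``psm_id, protein_id,
    peptide_seq, is_decoy, is_shared, is_correct, confidence, sn_sum, i114,
    i115, i117``. ``is_correct`` is hidden truth (False for decoys and for
    incorrect target identifications); estimators must not read it.

    Genes whose protein yields no peptide in the length window are skipped
    with a warning. Spectrum counts are ``spectra_per_protein`` per protein
    (Poisson or fixed); decoy and false-target PSMs are each drawn
    ``Binomial(T, f/(1-f))`` on top of the T genuine PSMs so the expected
    decoy share of the table equals ``decoy_fraction``.
    """
    rng = np.random.default_rng([config.seed, _STREAM_PSMS])
    tt = truth.table
    digests = {}
    for acc, protein in zip(tt["protein_acc"], tt["protein_seq"]):
        peps = tryptic_digest(protein, config.min_peptide_len,
                              config.max_peptide_len)
        if not peps:
            warnings.warn(f"protein {acc}: no tryptic peptide in "
                          f"[{config.min_peptide_len}, {config.max_peptide_len}]"
                          " window; gene skipped")
            continue
        digests[acc] = peps

    # Shared peptides: identical peptide sequence arising from >1 protein.
    counts: dict[str, int] = {}
    for peps in digests.values():
        for p in set(peps):
            counts[p] = counts.get(p, 0) + 1

    eff_ly = tt.set_index("protein_acc")["prot_ly"]
    eff_skf = tt.set_index("protein_acc")["prot_skf"]
    accs = list(digests)

    if config.spectra_distribution == "poisson":
        n_spec = rng.poisson(config.spectra_per_protein, size=len(accs))
    else:
        n_spec = np.full(len(accs), int(config.spectra_per_protein))

    chan_sd = config.reporter_cv / np.sqrt(2.0)  # per-channel log2 sd

    def incorrect_confidence() -> float:
        # Incorrect identifications (decoy or false-target) score low on
        # the whole, but a minority are confidently wrong: without that
        # high tail no incorrect hit would ever cross the 95% confidence
        # threshold and decoy-based FDR estimation would be vacuous.
        if rng.random() < _HIGH_CONF_ERROR_RATE:
            return float(rng.uniform(0.9, 1.0))
        return float(rng.beta(1, 8))

    def reporter_row(d_ly: float, d_skf: float) -> tuple[float, float, float]:
        b = float(np.exp(rng.normal(np.log(500.0), 0.7)))
        e = rng.normal(0.0, chan_sd, size=3)
        return (b * 2.0 ** e[0],
                b * 2.0 ** (d_ly + e[1]),
                b * 2.0 ** (d_skf + e[2]))

    records = []

    def emit(protein_id, pep, decoy, correct, conf, d_ly, d_skf):
        i114, i115, i117 = reporter_row(d_ly, d_skf)
        records.append((protein_id, pep, decoy,
                        counts.get(pep, 1) > 1 and not decoy,
                        correct, conf,
                        float(np.exp(rng.normal(3.0, 0.8))),
                        i114, i115, i117))

    for acc, k in zip(accs, n_spec):
        peps = digests[acc]
        for _ in range(int(k)):
            pep = peps[rng.integers(len(peps))]
            emit(acc, pep, False, True, float(rng.beta(8, 1)),
                 float(eff_ly[acc]), float(eff_skf[acc]))

    total_true = int(n_spec.sum())
    f = config.decoy_fraction
    if f > 0 and total_true > 0:
        p_extra = f / (1.0 - f)
        n_decoy = int(rng.binomial(total_true, p_extra))
        n_false = int(rng.binomial(total_true, p_extra))
        for _ in range(n_decoy):
            acc = accs[rng.integers(len(accs))]
            rev = digests[acc][rng.integers(len(digests[acc]))][::-1]
            emit("DECOY_" + acc, rev, True, False, incorrect_confidence(),
                 0.0, 0.0)
        for _ in range(n_false):
            acc = accs[rng.integers(len(accs))]
            pep = digests[acc][rng.integers(len(digests[acc]))]
            emit(acc, pep, False, False, incorrect_confidence(), 0.0, 0.0)

    df = pd.DataFrame(records, columns=[
        "protein_id", "peptide_seq", "is_decoy", "is_shared", "is_correct",
        "confidence", "sn_sum", "i114", "i115", "i117"])
    df.insert(0, "psm_id", [f"PSM{i:06d}" for i in range(len(df))])
    return df


def simulate_all(config: SimConfig) -> tuple[GroundTruth, pd.DataFrame, pd.DataFrame]:
    """Convenience: truth, array table and PSM table in one call."""
    truth = generate_ground_truth(config)
    return truth, simulate_microarray(truth, config), simulate_itraq(truth, config)
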
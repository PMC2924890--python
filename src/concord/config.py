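"""Configuration objects for the simulator and the end-to-end pipeline.

Treatment naming follows the two dopamine-agonist arms of the study design
this package models: ``SKF`` (D1-specific agonist, iTRAQ reporter label 117)
and ``LY`` (D2-specific agonist, label 115), each measured against a common
saline/vehicle control (label 114; pooled reference channel on the arrays).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigurationError

#: Treatment arms, in canonical order.
TREATMENTS = ("SKF", "LY")

#: iTRAQ reporter label carrying each treatment (114 is the control label).
TREATMENT_LABELS = {"SKF": "117", "LY": "115"}
CONTROL_LABEL = "114"


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must be in [0, 1], got {value!r}")


@dataclass
class SimConfig:
    """Parameters of the synthetic two-omics experiment.

    The defaults emulate the study design the downstream statistics assume:
    four single-channel-pair arrays per treatment hybridised against a common
    reference pool (one of them a dye-reversal), duplicate spots per gene,
    and 4-plex iTRAQ peptide evidence with a handful of spectra per protein.

    Parameters
    ----------
    n_genes
        Number of simulated genes (each contributes one EST printed in
        duplicate and one protein).
    frac_de_mrna, frac_de_protein
        Fraction of genes with a true nonzero effect per layer, per
        treatment. Exactly ``round(n_genes * frac)`` genes are drawn.
    concordance_rate
        Probability that a gene differentially expressed in *both* layers
        under the same treatment carries the same effect sign in both.
        This is the quantity the full pipeline is asked to recover.
    effect_size_log2
        Magnitude of every true effect, in log2 units; signs are random.
    n_arrays_per_treatment
        Replicate arrays per treatment; the last one is flagged as a
        dye-reversal (channels swapped).
    array_noise_sd
        Log2 standard deviation of the per-spot log-ratio noise.
    array_scale_sd, channel_gain_sd
        Per-array distortions the normalization step is expected to remove:
        a global intensity scale (shifts A, both channels) and a
        treatment-channel gain (shifts M by an array-specific constant).
    spectra_per_protein, spectra_distribution
        Mean spectrum count per protein and the count law ("poisson" or
        "fixed"). The default of 14 reflects the spectra-per-identified-
        protein depth of the study design being emulated; after the
        confidence and signal-to-noise filters a protein typically retains
        a handful of quantifiable spectra.
    reporter_cv
        Log2 standard deviation of a per-PSM reporter *ratio* (115:114 or
        117:114). Implemented as independent per-channel lognormal noise of
        sd ``reporter_cv / sqrt(2)`` so each ratio has exactly this sd.
    decoy_fraction
        Expected fraction of all PSMs that are reversed-database (decoy)
        hits; an equal expected number of incorrect *target* PSMs is drawn
        so the decoy FDR estimator has a real quantity to estimate.
    min_peptide_len, max_peptide_len
        Tryptic peptide length window retained after in-silico digestion.
    protein_len_min, protein_len_max
        Uniform range of simulated protein lengths (residues).
    seed
        Master seed; fully determines every output table.
    """

    n_genes: int = 500
    frac_de_mrna: float = 0.35
    frac_de_protein: float = 0.10
    concordance_rate: float = 0.57
    effect_size_log2: float = 1.0
    n_arrays_per_treatment: int = 4
    array_noise_sd: float = 0.2
    array_scale_sd: float = 0.3
    channel_gain_sd: float = 0.15
    spectra_per_protein: float = 14.0
    spectra_distribution: str = "poisson"
    reporter_cv: float = 0.3
    decoy_fraction: float = 0.1
    min_peptide_len: int = 6
    max_peptide_len: int = 30
    protein_len_min: int = 80
    protein_len_max: int = 160
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("frac_de_mrna", "frac_de_protein", "concordance_rate",
                     "decoy_fraction"):
            _check_fraction(name, getattr(self, name))
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.effect_size_log2 <= 0:
            raise ConfigurationError("effect_size_log2 must be positive")
        if self.n_arrays_per_treatment < 2:
            raise ConfigurationError("need at least 2 arrays per treatment")
        if self.reporter_cv <= 0 or self.array_noise_sd < 0:
            raise ConfigurationError("noise scales must be positive")
        if self.spectra_distribution not in ("poisson", "fixed"):
            raise ConfigurationError(
                f"unknown spectra_distribution {self.spectra_distribution!r}")
        if not (0 < self.min_peptide_len <= self.max_peptide_len):
            raise ConfigurationError("invalid peptide length window")
        if not (3 <= self.protein_len_min <= self.protein_len_max):
            raise ConfigurationError("invalid protein length range")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings: thresholds, permutations, paths.

    Thresholds default to the study's published filters: transcripts called
    at q < 0.05 (SAM), proteins at raw p < 0.05, PSMs kept at confidence
    >= 0.95 and signal-to-noise sum > 9, translated-alignment hits at
    E <= 1e-5 with an annotation-grade flag at E <= 1e-8.
    """

    out_dir: Path = Path("concord_out")
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    q_threshold: float = 0.05
    p_threshold: float = 0.05
    e_blast: float = 1e-5
    e_annot: float = 1e-8
    sn_min: float = 9.0
    confidence_min: float = 0.95
    n_perm: int = 200
    bias_correct: bool = False
    bh_adjust: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if isinstance(self.sim, dict):
            self.sim = SimConfig.from_dict(self.sim)
        self.validate()

    def validate(self) -> None:
        _check_fraction("q_threshold", self.q_threshold)
        _check_fraction("p_threshold", self.p_threshold)
        _check_fraction("confidence_min", self.confidence_min)
        if self.e_blast <= 0 or self.e_annot <= 0:
            raise ConfigurationError("E-value thresholds must be positive")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML (or JSON, a YAML subset) pipeline configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} did not parse to a mapping")
    try:
        return PipelineConfig.from_dict(data)
    except TypeError as exc:
        raise ConfigurationError(f"bad config field: {exc}") from exc


def load_sim_config(path: str | Path) -> SimConfig:
    """Read a YAML/JSON file mapping 1:1 onto :class:`SimConfig` fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} did not parse to a mapping")
    try:
        return SimConfig.from_dict(data)
    except TypeError as exc:
        raise ConfigurationError(f"bad config field: {exc}") from exc
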
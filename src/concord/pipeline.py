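"""End-to-end pipeline: simulate -> normalize -> DE -> quant -> match ->
concordance, with every intermediate written as TSV and a JSON summary.

Each stage is wrapped so a failure aborts with the stage name while partial
outputs remain on disk. All randomness flows from ``PipelineConfig.seed``
(the simulator uses ``sim.seed``; permutation seeds derive from the
pipeline seed), and two runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, TREATMENTS
from .errors import PipelineStageError
from . import concordance as conc
from . import io as cio
from . import itraq
from . import microarray as ma
from . import seqmatch
from . import synthetic

log = logging.getLogger("concord")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate and rethrow
                raise PipelineStageError(name, exc) from exc
        return wrapper
    return deco


@_stage("simulate")
def stage_simulate(cfg: PipelineConfig):
    truth, arrays, psms = synthetic.simulate_all(cfg.sim)
    out = cfg.out_dir
    cio.write_table(truth.table, out / "truth.tsv")
    cio.write_table(arrays, out / "arrays.tsv")
    cio.write_table(psms, out / "psms.tsv")
    cio.write_fasta(cio.frame_to_records(truth.table, "gene_id", "coding_seq"),
                    out / "transcripts.fasta")
    cio.write_fasta(cio.frame_to_records(truth.table, "protein_acc",
                                         "protein_seq"),
                    out / "proteins.fasta")
    return truth, arrays, psms


@_stage("de")
def stage_de(cfg: PipelineConfig, arrays: pd.DataFrame) -> pd.DataFrame:
    results = []
    for i, t in enumerate(TREATMENTS):
        res = ma.de_transcripts(arrays, t, q_threshold=cfg.q_threshold,
                                n_perm=cfg.n_perm, seed=cfg.seed + i)
        results.append(res)
    allres = pd.concat(results, ignore_index=True)
    de = allres[allres["is_de"]]
    cio.write_table(de[["gene_id", "treatment", "signed_fc", "d", "q"]],
                    cfg.out_dir / "de_transcripts.tsv")
    return allres


@_stage("quant")
def stage_quant(cfg: PipelineConfig, psms: pd.DataFrame):
    quants = itraq.quantify_proteins(psms, confidence_min=cfg.confidence_min,
                                     sn_min=cfg.sn_min,
                                     bh_adjust=cfg.bh_adjust)
    if cfg.bias_correct:
        quants = itraq.bias_correct(quants)
    cio.write_table(
        quants[["protein_id", "treatment", "ratio", "ef", "p", "n_spectra",
                "tier"] + (["p_bh"] if cfg.bh_adjust else [])],
        cfg.out_dir / "protein_quant.tsv")
    de_prot = itraq.select_de_proteins(quants, p_threshold=cfg.p_threshold,
                                       use_bh=cfg.bh_adjust)
    cio.write_table(de_prot, cfg.out_dir / "de_proteins.tsv")
    return quants, de_prot


@_stage("match")
def stage_match(cfg: PipelineConfig, de_results: pd.DataFrame,
                de_prot: pd.DataFrame, transcripts: dict[str, str],
                proteins: dict[str, str]):
    db = seqmatch.build_protein_db(
        (acc, "", proteins[acc]) for acc in de_prot["protein_id"])
    de_ids = sorted(set(de_results.loc[de_results["is_de"], "gene_id"]))
    hits = seqmatch.match_ests(((g, transcripts[g]) for g in de_ids), db,
                               e_blast=cfg.e_blast, e_annot=cfg.e_annot)
    est_fc = _est_fold_changes(de_results)
    matches = seqmatch.dedup_pairs(hits, est_fc)
    cio.write_table(matches, cfg.out_dir / "matches.tsv")
    return matches


def _est_fold_changes(de_results: pd.DataFrame) -> pd.DataFrame:
    """Signed FC per DE EST per treatment (NaN where not significant)."""
    de = de_results[de_results["is_de"]]
    if de.empty:
        return pd.DataFrame(columns=["fc_skf", "fc_ly"])
    wide = de.pivot_table(index="gene_id", columns="treatment",
                          values="signed_fc", aggfunc="first")
    out = pd.DataFrame(index=wide.index)
    for t in TREATMENTS:
        out[f"fc_{t.lower()}"] = wide[t] if t in wide else np.nan
    return out


@_stage("concordance")
def stage_concordance(cfg: PipelineConfig, de_prot: pd.DataFrame,
                      matches: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    table = conc.build_pair_table(de_prot, matches)
    cio.write_pair_table(table, cfg.out_dir / "concordance.tsv")
    summary = conc.summarize(table)
    return table, summary


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage on freshly simulated data; returns the summary dict
    (also written to ``summary.json``) and leaves all intermediates in
    ``cfg.out_dir``."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_log(out / "pipeline.log", cfg)

    truth, arrays, psms = stage_simulate(cfg)
    de_results = stage_de(cfg, arrays)
    quants, de_prot = stage_quant(cfg, psms)
    transcripts = dict(zip(truth.table["gene_id"], truth.table["coding_seq"]))
    proteins = dict(zip(truth.table["protein_acc"],
                        truth.table["protein_seq"]))
    matches = stage_match(cfg, de_results, de_prot, transcripts, proteins)
    table, summary = stage_concordance(cfg, de_prot, matches)

    de = de_results[de_results["is_de"]]
    summary["venn"] = conc.venn_counts(de["gene_id"], de_prot["protein_id"],
                                       table)
    summary["seed"] = cfg.seed
    summary["config"] = cio.nan_to_none(cfg.to_dict())
    with open(out / "summary.json", "w") as fh:
        json.dump(cio.nan_to_none(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("summary: %s", summary["treatments"])
    return summary


def _setup_log(path: Path, cfg: PipelineConfig) -> None:
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
            h.close()
    handler = logging.FileHandler(path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.setLevel(logging.INFO)
    log.addHandler(handler)
    log.info("concord %s (python %s)", __version__, platform.python_version())
    log.info("seed=%s thresholds: q<%s p<%s E<=%s (annot %s) S/N>%s conf>=%s",
             cfg.seed, cfg.q_threshold, cfg.p_threshold, cfg.e_blast,
             cfg.e_annot, cfg.sn_min, cfg.confidence_min)
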
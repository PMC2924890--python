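"""Translated cross-omics sequence matching.

Differentially expressed EST nucleotide sequences are matched against a
small database built from differentially expressed protein sequences, the
way a BLASTx search would: six-frame translation, local alignment with
BLOSUM62 and affine gaps (BLAST's 11/1 defaults), and Karlin-Altschul
E-values E = K*m*n*exp(-lambda*S) with the published gapped BLOSUM62
constants. Because the databases here are desk-scale (tens of proteins),
the search runs full Smith-Waterman on every frame segment instead of a
seeded heuristic, which makes scores exactly testable.

Alignments never cross stop codons: each frame translation is split into
open segments at '*' and segments are aligned independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .errors import InputError

#: Gapped BLOSUM62 Karlin-Altschul parameters (gap open 11, extend 1).
LAMBDA = 0.267
KAPPA = 0.041

_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
FRAMES = (1, 2, 3, -1, -2, -3)


def _make_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST 11/1: a gap of length k costs 11 + k.
    al.open_gap_score = -12.0
    al.extend_gap_score = -1.0
    return al


_ALIGNER = _make_aligner()


@dataclass
class ProteinDB:
    """Searchable protein database with the cumulative residue count used
    as the E-value search-space size."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)
    # acc -> (description, sequence)

    @property
    def total_residues(self) -> int:
        return sum(len(seq) for _, seq in self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)


def build_protein_db(records) -> ProteinDB:
    """Index protein records (iterable of (accession, description, seq)).

    Duplicate accessions are an error; records with residues outside the
    20-letter alphabet (+X) are rejected with a warning.
    """
    db = ProteinDB()
    for acc, desc, seq in records:
        seq = str(seq).upper()
        if acc in db.entries:
            raise InputError(f"duplicate accession {acc!r}")
        if not set(seq) <= _PROTEIN_ALPHABET:
            bad = sorted(set(seq) - _PROTEIN_ALPHABET)
            warnings.warn(f"record {acc!r} rejected: illegal residues {bad}")
            continue
        db.entries[acc] = (desc, seq)
    if not db.entries:
        raise InputError("protein database is empty")
    return db


def translate_six_frames(nt: str) -> dict[int, str]:
    """Standard-genetic-code translation in frames +1..+3 and -1..-3.

    Reverse frames read the reverse complement. Stop codons appear as '*';
    codons containing N translate to 'X'.
    """
    nt = str(nt).upper()
    if len(nt) < 3:
        raise InputError("sequence shorter than one codon")
    if not set(nt) <= set("ACGTN"):
        raise InputError("sequence contains characters outside {A,C,G,T,N}")
    fwd = Seq(nt)
    rev = fwd.reverse_complement()
    out = {}
    for f in (1, 2, 3):
        for strand, seq in ((f, fwd), (-f, rev)):
            sub = seq[f - 1:]
            sub = sub[:len(sub) - len(sub) % 3]
            out[strand] = str(sub.translate()) if len(sub) else ""
    return out


def _segments(aa: str, min_len: int = 1):
    """Open reading segments between stop codons, with their offsets."""
    start = 0
    for i, c in enumerate(aa + "*"):
        if c == "*":
            if i - start >= min_len:
                yield start, aa[start:i]
            start = i + 1


def local_align(query: str, target: str):
    """Optimal Smith-Waterman local alignment (BLOSUM62, gap 11/1).

    Returns ``(score, (q_start, q_end), (t_start, t_end))`` with 0-based
    half-open coordinates; the reported alignment is the aligner's first,
    which is deterministic for fixed inputs.
    """
    if not query or not target:
        raise InputError("empty sequence in local_align")
    alns = _ALIGNER.align(query, target)
    best = alns[0]
    q, t = best.aligned
    return float(best.score), (int(q[0][0]), int(q[-1][1])), \
        (int(t[0][0]), int(t[-1][1]))


def local_align_score(query: str, target: str) -> float:
    """Score-only Smith-Waterman (faster than :func:`local_align`)."""
    if not query or not target:
        raise InputError("empty sequence in local_align")
    return float(_ALIGNER.score(query, target))


def evalue(raw_score: float, query_len: int, db_residues: int,
           lam: float = LAMBDA, kappa: float = KAPPA) -> float:
    """Karlin-Altschul expected number of chance hits at score >= S."""
    if query_len < 1 or db_residues < 1:
        raise InputError("query and database lengths must be >= 1")
    return float(kappa * query_len * db_residues * np.exp(-lam * raw_score))


def bit_score(raw_score: float, lam: float = LAMBDA,
              kappa: float = KAPPA) -> float:
    """Normalised bit score (lambda*S - ln K) / ln 2."""
    return float((lam * raw_score - np.log(kappa)) / np.log(2.0))


@dataclass
class AlignmentHit:
    """Best translated hit of one EST against the protein database."""

    est_id: str
    protein_acc: str
    frame: int
    score: float
    bitscore: float
    evalue: float
    q_start: int  # aa coordinates within the frame translation, 0-based
    q_end: int
    t_start: int
    t_end: int
    annotation_grade: bool


def match_ests(ests, db: ProteinDB, e_blast: float = 1e-5,
               e_annot: float = 1e-8, min_segment: int = 4) -> pd.DataFrame:
    """Best protein hit per EST by translated local alignment.

    ``ests`` is an iterable of ``(est_id, nucleotide_sequence)``. For each
    EST every stop-free segment of every frame is Smith-Waterman aligned to
    every database entry; the best hit (highest score, ties broken by
    accession then frame order) is kept when its E-value is <= ``e_blast``
    and flagged annotation-grade when E <= ``e_annot``. ESTs with no
    qualifying hit are absent from the output.
    """
    hits = []
    for est_id, nt in ests:
        frames = translate_six_frames(nt)
        best = None  # (-score, acc, frame_order) for tie-break
        for fi, frame in enumerate(FRAMES):
            aa = frames[frame]
            if not aa:
                continue
            for off, seg in _segments(aa, min_segment):
                for acc in sorted(db.entries):
                    _, tseq = db.entries[acc]
                    s = local_align_score(seg, tseq)
                    key = (-s, acc, fi)
                    if best is None or key < best[0]:
                        best = (key, frame, acc, off, seg, len(aa))
        if best is None:
            continue
        (negs, _, _), frame, acc, off, seg, m = best
        score = -negs
        e = evalue(score, m, db.total_residues)
        if e > e_blast:
            continue
        _, tseq = db.entries[acc]
        score2, (qs, qe), (ts, te) = local_align(seg, tseq)
        hits.append(AlignmentHit(est_id, acc, frame, score,
                                 bit_score(score), e,
                                 off + qs, off + qe, ts, te,
                                 e <= e_annot))
    cols = ["est_id", "protein_acc", "frame", "score", "bitscore", "evalue",
            "q_start", "q_end", "t_start", "t_end", "annotation_grade"]
    return pd.DataFrame([h.__dict__ for h in hits], columns=cols)


def dedup_pairs(hits: pd.DataFrame, est_fc: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple ESTs matching one protein by expression similarity.

    ``est_fc`` is indexed by est_id with columns ``fc_skf``/``fc_ly``
    (signed fold changes, NaN where the EST is not DE in that treatment).
    When several ESTs hit the same protein, they are collapsed only if
    their expression profiles are similar: measured under the same set of
    treatments with the same sign in each, in which case the EST with the
    largest |FC| survives. Any profile difference (an opposite sign, or
    regulation under different treatments) keeps all of them, flagged
    ``starred``: they may represent distinct genes.
    """
    out = hits.merge(est_fc, left_on="est_id", right_index=True, how="left")
    out["starred"] = False
    keep = np.ones(len(out), dtype=bool)

    def profile(row):
        return tuple(0 if pd.isna(row[c]) else int(np.sign(row[c]))
                     for c in ("fc_skf", "fc_ly"))

    for _, idx in out.groupby("protein_acc").groups.items():
        idx = list(idx)
        if len(idx) < 2:
            continue
        grp = out.loc[idx]
        conflict = len({profile(r) for _, r in grp.iterrows()}) > 1
        if conflict:
            out.loc[idx, "starred"] = True
        else:
            mag = grp[["fc_skf", "fc_ly"]].abs().max(axis=1).fillna(0.0)
            ranked = grp.assign(_mag=mag).sort_values(
                ["_mag", "est_id"], ascending=[False, True], kind="stable")
            winner = ranked.index[0]
            for i in idx:
                if i != winner:
                    keep[out.index.get_loc(i)] = False
    return out[keep].reset_index(drop=True)
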
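"""Splice-site strength scoring, recursive-donor scanning, and EJC windows.

Two scorer kinds share one interface:

* ``maxent_tables`` — the maximum-entropy splice-site models of Yeo &
  Burge, driven by their published table files.  The donor model scores a
  9-mer (3 exonic + 6 intronic nt) as log2 of consensus-position odds at
  the GT core times a table lookup over the remaining 7 positions
  (``me2x5``); the acceptor model scores a 23-mer (20 intronic + 3 exonic
  nt) as log2 of AG-core odds times a 9-submodel decomposition
  (``me2x3acc1..9``) over overlapping windows of the remaining 21
  positions.  Given the same tables, scores match the reference
  implementation exactly.
* ``pwm`` — a position weight matrix trained on the annotation's own
  splice sites (pseudocount 1, uniform background), scoring
  sum of log2(p_pos(base)/0.25).  Used when no MaxEnt tables are on disk.

The recursive-donor threshold of 5.52 (the MaxEnt score above which 90%
of human canonical 5' splice sites fall) is only meaningful in MaxEnt
units; with a PWM model the scan instead reports a percentile-based
threshold computed from the annotation's real donors, clearly labelled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats as sps

from .core_model import ExonCategory, GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "SpliceModel",
    "SiteScore",
    "RecursiveScanResult",
    "train_pwm_model",
    "load_maxent_model",
    "score_site",
    "extract_site_sequences",
    "extract_donor_9mer",
    "extract_acceptor_23mer",
    "scan_recursive_5ss",
    "extract_ejc_window",
    "compare_categories",
]

DONOR_LEN = 9   # 3 exonic + 6 intronic
ACCEPTOR_LEN = 23  # 20 intronic + 3 exonic
RECURSIVE_THRESHOLD = 5.52
EJC_OFFSET_NT = 24
EJC_WINDOW_NT = 10

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# consensus-position odds of the MaxEnt donor (GT at positions 4-5) and
# acceptor (AG at positions 19-20) models; background {A,T}=0.27 {C,G}=0.23
_BGD = {"A": 0.27, "C": 0.23, "G": 0.23, "T": 0.27}
_DONOR_CONS1 = {"A": 0.004, "C": 0.0032, "G": 0.9896, "T": 0.0044}
_DONOR_CONS2 = {"A": 0.0034, "C": 0.0039, "G": 0.0042, "T": 0.9896}
_ACC_CONS1 = {"A": 0.9903, "C": 0.0032, "G": 0.0034, "T": 0.0030}
_ACC_CONS2 = {"A": 0.0027, "C": 0.0037, "G": 0.9905, "T": 0.0030}

# windows of the 21-mer (23-mer minus the AG core) scored by the nine
# acceptor submodels; the first five multiply, the last four divide
_ACC_WINDOWS = [
    (0, 7), (7, 14), (14, 21), (4, 11), (11, 18),  # numerator
    (4, 7), (7, 11), (11, 14), (14, 18),           # denominator
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _kmer_index(seq: str) -> int:
    idx = 0
    for base in seq:
        idx = idx * 4 + _BASE_INDEX[base]
    return idx


@dataclass
class SpliceModel:
    """Position-dependent splice-site scorer (MaxEnt tables or PWM)."""

    kind: str  # "maxent_tables" | "pwm"
    donor_pwm: Optional[np.ndarray] = None      # shape (9, 4), log2 odds
    acceptor_pwm: Optional[np.ndarray] = None   # shape (23, 4)
    me2x5: Optional[np.ndarray] = None          # 4**7 donor table
    acc_tables: Optional[list[np.ndarray]] = None  # nine acceptor tables
    donor_reference_scores: Optional[np.ndarray] = None  # annotation donors

    def __post_init__(self) -> None:
        if self.kind not in ("maxent_tables", "pwm"):
            raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass
class SiteScore:
    gene_id: str
    exon_index: int
    side: str  # "donor" | "acceptor"
    sequence: str
    score: Optional[float]  # None when the sequence contains N


@dataclass
class RecursiveScanResult:
    gene_id: str
    exon_index: int
    recursive_9mer: str
    score: Optional[float]
    threshold: float
    above_threshold: bool
    threshold_kind: str  # "maxent" | "pwm_percentile"


# ---------------------------------------------------------------------------
# model construction


def _train_pwm(seqs: Sequence[str], length: int, pseudocount: float = 1.0) -> np.ndarray:
    counts = np.full((length, 4), pseudocount)
    for s in seqs:
        if len(s) != length:
            raise ValueError(f"sequence length {len(s)} != {length}")
        for pos, base in enumerate(s.upper()):
            if base in _BASE_INDEX:
                counts[pos, _BASE_INDEX[base]] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    return np.log2(probs / 0.25)


def train_pwm_model(
    donor_seqs: Sequence[str], acceptor_seqs: Sequence[str]
) -> SpliceModel:
    """Train the PWM fallback from observed donor 9-mers / acceptor 23-mers."""
    model = SpliceModel(
        kind="pwm",
        donor_pwm=_train_pwm(donor_seqs, DONOR_LEN),
        acceptor_pwm=_train_pwm(acceptor_seqs, ACCEPTOR_LEN),
    )
    model.donor_reference_scores = np.array(
        [score_site(s, "donor", model) for s in donor_seqs]
    )
    return model


def load_maxent_model(table_dir: Union[str, Path]) -> SpliceModel:
    """Load MaxEnt table files (``me2x5`` and ``me2x3acc1..9``).

    Each file holds one probability per line, 4**7 = 16384 lines, indexed
    by the k-mer in base-4 (A=0, C=1, G=2, T=3).  The acceptor files for
    3- and 4-mer windows only use their leading 64 / 256 entries.
    """
    table_dir = Path(table_dir)
    me2x5 = np.loadtxt(table_dir / "me2x5", dtype=float, ndmin=1)
    acc_tables = [
        np.loadtxt(table_dir / f"me2x3acc{i}", dtype=float, ndmin=1)
        for i in range(1, 10)
    ]
    return SpliceModel(kind="maxent_tables", me2x5=me2x5, acc_tables=acc_tables)


# ---------------------------------------------------------------------------
# scoring


def _validate_seq(seq: str, side: str) -> str:
    expected = DONOR_LEN if side == "donor" else ACCEPTOR_LEN
    if side not in ("donor", "acceptor"):
        raise ValueError(f"unknown side {side!r}")
    if len(seq) != expected:
        raise ValueError(f"{side} sequence must be {expected} nt, got {len(seq)}")
    seq = seq.upper()
    if any(c not in "ACGTN" for c in seq):
        raise ValueError(f"non-ACGTN character in {seq!r}")
    return seq


def score_site(seq: str, side: str, model: SpliceModel) -> Optional[float]:
    """Score a donor 9-mer or acceptor 23-mer; None for sequences with N."""
    seq = _validate_seq(seq, side)
    if "N" in seq:
        logger.warning("sequence %s contains N; score undefined", seq)
        return None
    if model.kind == "pwm":
        pwm = model.donor_pwm if side == "donor" else model.acceptor_pwm
        if pwm is None:
            raise ValueError(f"model has no {side} PWM")
        return float(
            sum(pwm[i, _BASE_INDEX[b]] for i, b in enumerate(seq))
        )
    if side == "donor":
        if model.me2x5 is None:
            raise ValueError("MaxEnt model lacks the me2x5 donor table")
        cons = (
            _DONOR_CONS1[seq[3]] * _DONOR_CONS2[seq[4]]
            / (_BGD[seq[3]] * _BGD[seq[4]])
        )
        rest = seq[:3] + seq[5:]
        return float(math.log2(cons * model.me2x5[_kmer_index(rest)]))
    if model.acc_tables is None:
        raise ValueError("MaxEnt model lacks acceptor tables")
    cons = (
        _ACC_CONS1[seq[18]] * _ACC_CONS2[seq[19]]
        / (_BGD[seq[18]] * _BGD[seq[19]])
    )
    rest = seq[:18] + seq[20:]
    parts = [
        model.acc_tables[i][_kmer_index(rest[a:b])]
        for i, (a, b) in enumerate(_ACC_WINDOWS)
    ]
    num = parts[0] * parts[1] * parts[2] * parts[3] * parts[4]
    den = parts[5] * parts[6] * parts[7] * parts[8]
    return float(math.log2(cons * num / den))


# ---------------------------------------------------------------------------
# sequence extraction (strand-aware; motifs always read 5'->3')


def _fetch(genome, chrom: str, start: int, end: int) -> Optional[str]:
    """Slice [start, end) from a pyfaidx-like genome; None past contig edges."""
    if start < 0:
        return None
    seq = str(genome[chrom][start:end])
    if len(seq) != end - start:
        return None
    return seq.upper()


def extract_donor_9mer(genome, model: GeneModel, exon_index: int) -> Optional[str]:
    """Last 3 exonic + first 6 intronic nt at an exon's 5' splice site."""
    if model.downstream_intron(exon_index) is None:
        return None
    exon = model.exons[exon_index]
    if model.strand == "+":
        return _fetch(genome, model.chrom, exon.end - 3, exon.end + 6)
    seq = _fetch(genome, model.chrom, exon.start - 6, exon.start + 3)
    return revcomp(seq) if seq is not None else None


def extract_acceptor_23mer(genome, model: GeneModel, exon_index: int) -> Optional[str]:
    """Last 20 intronic + first 3 exonic nt at an exon's 3' splice site."""
    if model.upstream_intron(exon_index) is None:
        return None
    exon = model.exons[exon_index]
    if model.strand == "+":
        return _fetch(genome, model.chrom, exon.start - 20, exon.start + 3)
    seq = _fetch(genome, model.chrom, exon.end - 3, exon.end + 20)
    return revcomp(seq) if seq is not None else None


def extract_site_sequences(
    model: GeneModel, genome, side: str
) -> list[tuple[int, str]]:
    """(exon_index, sequence) for every exon with the relevant flanking intron.

    Terminal exons without the required intron emit nothing; exons at a
    contig edge are skipped and logged.
    """
    extract = extract_donor_9mer if side == "donor" else extract_acceptor_23mer
    if side not in ("donor", "acceptor"):
        raise ValueError(f"unknown side {side!r}")
    out: list[tuple[int, str]] = []
    for i in range(model.n_exons):
        seq = extract(genome, model, i)
        if seq is None:
            if (side == "donor" and model.downstream_intron(i) is not None) or (
                side == "acceptor" and model.upstream_intron(i) is not None
            ):
                logger.warning(
                    "%s exon %d at contig edge; %s site skipped",
                    model.gene_id, i, side,
                )
            continue
        out.append((i, seq))
    return out


def scan_recursive_5ss(
    model: GeneModel,
    exon_index: int,
    genome,
    splice_model: SpliceModel,
    threshold: float = RECURSIVE_THRESHOLD,
    pwm_percentile: float = 90.0,
) -> RecursiveScanResult:
    """Score the donor motif reconstituted at an exon's 5' end after
    upstream-intron splicing.

    The recursive 9-mer is the last 3 nt of the upstream ladder exon
    followed by the first 6 nt of the candidate exon.  With a MaxEnt
    model the fixed threshold (default 5.52) applies; with a PWM model
    the threshold is the given percentile of the annotation's own donor
    scores, reported as such.
    """
    if exon_index == 0:
        raise ValueError("first ladder exon has no upstream neighbor")
    up = model.exons[exon_index - 1]
    exon = model.exons[exon_index]
    if model.strand == "+":
        left = _fetch(genome, model.chrom, up.end - 3, up.end)
        right = _fetch(genome, model.chrom, exon.start, exon.start + 6)
        nine = (left + right) if left is not None and right is not None else None
    else:
        left = _fetch(genome, model.chrom, up.start, up.start + 3)
        right = _fetch(genome, model.chrom, exon.end - 6, exon.end)
        nine = (
            revcomp(left) + revcomp(right)
            if left is not None and right is not None
            else None
        )
    if nine is None:
        raise ValueError(f"{model.gene_id} exon {exon_index}: contig edge")
    score = score_site(nine, "donor", splice_model)
    if splice_model.kind == "maxent_tables":
        thr, kind = threshold, "maxent"
    else:
        if splice_model.donor_reference_scores is None:
            raise ValueError("PWM model lacks reference donor scores")
        thr = float(
            np.percentile(splice_model.donor_reference_scores, pwm_percentile)
        )
        kind = "pwm_percentile"
    return RecursiveScanResult(
        gene_id=model.gene_id,
        exon_index=exon_index,
        recursive_9mer=nine,
        score=score,
        threshold=thr,
        above_threshold=score is not None and not math.isinf(thr) and score > thr,
        threshold_kind=kind,
    )


def extract_ejc_window(
    model: GeneModel,
    exon_index: int,
    genome,
    window_nt: int = EJC_WINDOW_NT,
    offset_nt: int = EJC_OFFSET_NT,
) -> Optional[str]:
    """Sequence around the canonical EJC deposition site of one exon.

    The EJC sits ``offset_nt`` (default 24) nt upstream of the exon's 3'
    end (transcriptional orientation); the window of ``window_nt`` nt is
    centered there.  For a 100-nt exon with defaults this is
    transcript-relative positions 71-80 (1-based).  Returns None (logged)
    when the exon is too short.
    """
    exon = model.exons[exon_index]
    length = len(exon)
    center = length - offset_nt  # 1-based transcript position of the EJC site
    t_start = center - window_nt // 2 - 1  # 0-based inclusive
    t_end = t_start + window_nt
    if t_start < 0 or t_end > length:
        logger.info(
            "%s exon %d too short (%d nt) for EJC window", model.gene_id,
            exon_index, length,
        )
        return None
    if model.strand == "+":
        return _fetch(genome, model.chrom, exon.start + t_start, exon.start + t_end)
    seq = _fetch(genome, model.chrom, exon.end - t_end, exon.end - t_start)
    return revcomp(seq) if seq is not None else None


# ---------------------------------------------------------------------------
# category comparisons


def compare_categories(
    values: Mapping[Union[str, ExonCategory], Sequence[float]],
    reference: Union[str, ExonCategory] = ExonCategory.NON_REGULATED,
) -> dict[str, dict[str, float]]:
    """Two-sided Mann-Whitney U of each category against the reference.

    Works for site scores or exon/intron/gene lengths alike.  Categories
    with fewer than 2 values are excluded (logged).  No multiple-testing
    correction is applied by default.
    """
    vals = {str(getattr(k, "value", k)): list(v) for k, v in values.items()}
    ref_key = str(getattr(reference, "value", reference))
    if ref_key not in vals or len(vals[ref_key]) < 2:
        raise ValueError(f"reference category {ref_key!r} missing or too small")
    ref = vals[ref_key]
    out: dict[str, dict[str, float]] = {
        ref_key: {"n": float(len(ref)), "median": float(np.median(ref))}
    }
    for cat, v in vals.items():
        if cat == ref_key:
            continue
        if len(v) < 2:
            logger.info("category %s has < 2 values; excluded", cat)
            continue
        u, p = sps.mannwhitneyu(v, ref, alternative="two-sided")
        out[cat] = {
            "n": float(len(v)),
            "median": float(np.median(v)),
            "U": float(u),
            "p_value": float(p),
        }
    return out
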
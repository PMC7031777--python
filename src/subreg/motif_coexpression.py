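"""Motif over-representation in peak sequences, gated by coexpression.

A position weight matrix (PWM) is scanned over peak sequences on both
strands with log-odds scoring against background nucleotide frequencies;
the hit threshold is calibrated as a quantile of the per-sequence
max-score distribution on dinucleotide-preserving shuffles.  Enrichment
of hits in foreground peaks (near a subtype's signature genes) versus
background peaks is tested with a one-sided Fisher exact test and
q-value corrected over the motif library.  A motif's candidate TFs are
only reported as regulators when they are themselves coexpressed with
the signature — a motif usually stands for a whole TF family, and
coexpression picks the member actually active in the subtype.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment_stats import qvalues
from .signature_expansion import coexpression_pvalue

__all__ = [
    "PWM",
    "scan_pwm",
    "motif_enrichment",
    "coexpression_filter",
    "infer_motif_regulators",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class PWM:
    """A motif: 4 x L probability matrix plus its TF family.

    ``matrix`` rows are A, C, G, T; columns sum to 1.  ``tf_genes`` lists
    the gene ids of the TF family the motif may represent.
    """

    motif_id: str
    matrix: np.ndarray
    tf_genes: list = field(default_factory=list)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))

    def log_odds(self, pseudo: float = 1e-3) -> np.ndarray:
        p = (self.matrix + pseudo) / (1.0 + 4 * pseudo)
        return np.log2(p / self.background[:, None])

    @classmethod
    def from_consensus(
        cls, motif_id: str, consensus: str, confidence: float = 0.85, tf_genes=()
    ) -> "PWM":
        L = len(consensus)
        mat = np.full((4, L), (1.0 - confidence) / 3.0)
        for j, base in enumerate(consensus.upper()):
            mat[_BASE_INDEX[base], j] = confidence
        return cls(motif_id, mat, list(tf_genes))


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(arr.shape, -1, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        code[arr == ord(base)] = i
    return code


def _window_scores(code: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Log-odds score of every window of length L in an encoded sequence."""
    L = lom.shape[1]
    n = code.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(L):
        col = code[j : j + n]
        ok = col >= 0
        valid &= ok
        scores[ok] += lom[col[ok], j]
    scores[~valid] = -np.inf
    return scores


def _shuffle_seq(seq: str, rng) -> str:
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)


def scan_threshold(
    sequences: dict[str, str], pwm: PWM, quantile: float = 0.95, rng=None
) -> float:
    """Hit threshold: the given quantile of max window scores on shuffles."""
    rng = np.random.default_rng(rng)
    lom = pwm.log_odds()
    maxima = []
    for seq in sequences.values():
        shuffled = _shuffle_seq(seq, rng)
        fwd = _window_scores(_encode(shuffled), lom)
        rev = _window_scores(_encode(shuffled.translate(_COMPLEMENT)[::-1]), lom)
        both = np.concatenate([fwd, rev])
        if both.size:
            maxima.append(both.max())
    if not maxima:
        raise ValueError("no scannable sequence (all shorter than the motif)")
    return float(np.quantile(maxima, quantile))


def scan_pwm(
    sequences: dict[str, str],
    pwm: PWM,
    threshold: float | None = None,
    threshold_quantile: float = 0.95,
    rng=None,
) -> pd.DataFrame:
    """Scan sequences with a PWM on both strands.

    Returns a hit table (seq_id, offset, strand, score) of windows whose
    log-odds score reaches the threshold.  When no absolute threshold is
    given it is calibrated as ``threshold_quantile`` of the max-score
    distribution over shuffled copies of the input sequences.
    """
    if threshold is None:
        threshold = scan_threshold(sequences, pwm, threshold_quantile, rng)
    lom = pwm.log_odds()
    L = pwm.length
    rows = []
    for seq_id, seq in sequences.items():
        code = _encode(seq)
        fwd = _window_scores(code, lom)
        for off in np.flatnonzero(fwd >= threshold):
            rows.append((seq_id, int(off), "+", float(fwd[off])))
        rc = seq.translate(_COMPLEMENT)[::-1]
        rev = _window_scores(_encode(rc), lom)
        for off in np.flatnonzero(rev >= threshold):
            # report the hit's position on the forward strand
            rows.append((seq_id, len(seq) - L - int(off), "-", float(rev[off])))
    return pd.DataFrame(rows, columns=["seq_id", "offset", "strand", "score"])


def motif_enrichment(
    fg_sequences: dict[str, str],
    bg_sequences: dict[str, str],
    pwm: PWM,
    threshold: float | None = None,
    threshold_quantile: float = 0.95,
    rng=None,
) -> dict:
    """One-sided Fisher exact test of hit-bearing peak counts, fg vs bg.

    A peak "has" the motif when at least one window passes the scan
    threshold (calibrated once on the pooled sequences).  Returns a dict
    with counts, odds ratio and p-value.
    """
    if threshold is None:
        pooled = {**fg_sequences, **bg_sequences}
        threshold = scan_threshold(pooled, pwm, threshold_quantile, rng)
    fg_hits = scan_pwm(fg_sequences, pwm, threshold=threshold)
    bg_hits = scan_pwm(bg_sequences, pwm, threshold=threshold)
    fg_pos = fg_hits["seq_id"].nunique()
    bg_pos = bg_hits["seq_id"].nunique()
    n_fg, n_bg = len(fg_sequences), len(bg_sequences)
    if fg_pos == 0 and bg_pos == 0:
        odds, p = np.nan, 1.0
    else:
        table = [[fg_pos, n_fg - fg_pos], [bg_pos, n_bg - bg_pos]]
        odds, p = stats.fisher_exact(table, alternative="greater")
    return {
        "motif_id": pwm.motif_id,
        "fg_hits": int(fg_pos),
        "fg_total": n_fg,
        "bg_hits": int(bg_pos),
        "bg_total": n_bg,
        "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
        "p": float(p),
        "threshold": float(threshold),
    }


def coexpression_filter(
    candidate_tfs,
    esg_genes,
    datasets,
    alpha: float = 0.05,
    n_perm: int = 499,
    rng=None,
) -> pd.DataFrame:
    """Retain candidate TFs coexpressed with the signature genes.

    Each TF's aggregated coexpression score against the ESG (used as the
    seed set) is tested by permutation; TFs with p < alpha are retained.
    TFs absent from every dataset are rejected with a warning.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for tf in sorted(set(candidate_tfs)):
        try:
            p = coexpression_pvalue(tf, esg_genes, datasets, n_perm=n_perm, rng=rng)
        except ValueError:
            warnings.warn(f"TF {tf!r} not measured in any dataset; rejected", stacklevel=2)
            rows.append({"tf": tf, "coexpression_p": np.nan, "retained": False})
            continue
        rows.append({"tf": tf, "coexpression_p": p, "retained": p < alpha})
    return pd.DataFrame(rows, columns=["tf", "coexpression_p", "retained"])


def peak_sequences(peaks: pd.DataFrame, genome: dict[str, str]) -> dict[str, str]:
    """Extract each peak's sequence from a genome dict."""
    out = {}
    for i, row in peaks.iterrows():
        seq = genome.get(str(row["chrom"]))
        if seq is None:
            continue
        out[f"{row['chrom']}:{row['start']}-{row['end']}"] = seq[
            int(row["start"]) : int(row["end"])
        ]
    return out


def infer_motif_regulators(
    fg_sequences: dict[str, str],
    bg_sequences: dict[str, str],
    motif_library: list[PWM],
    esg_genes,
    datasets,
    motif_q: float = 0.05,
    coexpression_alpha: float = 0.05,
    n_perm: int = 499,
    rng=None,
) -> tuple[list[str], pd.DataFrame]:
    """Full motif route: scan -> enrichment (q < 0.05) -> coexpression.

    Returns the retained regulator TFs and an evidence table with one
    row per (motif, candidate TF) recording each step's values.
    """
    rng = np.random.default_rng(rng)
    if not motif_library:
        return [], pd.DataFrame(
            columns=[
                "motif_id", "tf", "fg_hits", "bg_hits", "p", "q",
                "coexpression_p", "retained",
            ]
        )
    enr = [
        motif_enrichment(fg_sequences, bg_sequences, pwm, rng=rng)
        for pwm in motif_library
    ]
    qs = qvalues([e["p"] for e in enr])
    rows = []
    retained: list[str] = []
    for pwm, e, q in zip(motif_library, enr, qs):
        enriched = q < motif_q
        if enriched and pwm.tf_genes:
            coex = coexpression_filter(
                pwm.tf_genes, esg_genes, datasets,
                alpha=coexpression_alpha, n_perm=n_perm, rng=rng,
            )
        else:
            coex = pd.DataFrame(
                {"tf": pwm.tf_genes, "coexpression_p": np.nan, "retained": False}
            )
        for _, crow in coex.iterrows():
            keep = bool(enriched and crow["retained"])
            if keep:
                retained.append(crow["tf"])
            rows.append(
                {
                    "motif_id": pwm.motif_id,
                    "tf": crow["tf"],
                    "fg_hits": e["fg_hits"],
                    "bg_hits": e["bg_hits"],
                    "p": e["p"],
                    "q": float(q),
                    "coexpression_p": crow["coexpression_p"],
                    "retained": keep,
                }
            )
        if not pwm.tf_genes:
            rows.append(
                {
                    "motif_id": pwm.motif_id,
                    "tf": None,
                    "fg_hits": e["fg_hits"],
                    "bg_hits": e["bg_hits"],
                    "p": e["p"],
                    "q": float(q),
                    "coexpression_p": np.nan,
                    "retained": False,
                }
            )
    return sorted(set(retained)), pd.DataFrame(rows)
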
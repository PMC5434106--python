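"""Word-based naive Bayesian genus classifier with bootstrap confidence.

The classifier follows the classic rRNA word scheme: a sequence is reduced to
the set of distinct overlapping 8-mers it contains (presence/absence, not
counts), and the posterior score of genus g is the sum of log conditional
word probabilities over the query's words.  Training uses the joint
sequence-frequency smoothing

    prior(w)     = (n(w) + 0.5) / (N + 1)
    P(w | g)     = (m_g(w) + prior(w)) / (M_g + 1)

where n(w)/m_g(w) count training sequences containing w overall / in genus g,
and N/M_g are sequence counts.  Confidence comes from bootstrap resampling of
one eighth of the query's words per replicate: the fraction of replicates
agreeing with the full-word genus call.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ReferenceSequence

__all__ = [
    "NBCModel",
    "Classification",
    "extract_words",
    "train",
    "classify",
    "classify_scores",
    "classify_bootstrap",
    "evaluate_amplicon_classification",
]

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _c in enumerate(b"ACGT"):
    _CODE[_c] = _i


def _word_indices(seq: str, k: int) -> np.ndarray:
    """Sorted distinct indices (base-4 encoding) of the ACGT k-mers in ``seq``."""
    if len(seq) < k:
        raise ValueError(f"sequence shorter than word size {k}")
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = (windows[valid] * powers).sum(axis=1)
    return np.unique(idx)


def _decode(idx: int, k: int) -> str:
    bases = "ACGT"
    out = []
    for _ in range(k):
        out.append(bases[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def extract_words(seq: str, k: int = 8) -> set[str]:
    """Distinct overlapping k-mers of ``seq``; words with non-ACGT characters skipped."""
    return {_decode(int(i), k) for i in _word_indices(seq, k)}


@dataclass(frozen=True)
class NBCModel:
    """Trained word statistics: genus-conditional log word probabilities."""

    k: int
    genera: tuple[str, ...]  # sorted; row order of cond_log_prob
    word_prior: np.ndarray  # shape (4**k,)
    cond_log_prob: np.ndarray  # shape (len(genera), 4**k)
    n_train: dict[str, int]

    def save(self, path: str | Path) -> None:
        """Serialize to a TSV of per-genus word counts plus header metadata."""
        counts = self._counts
        with Path(path).open("w") as fh:
            fh.write(f"#k\t{self.k}\n")
            fh.write("#genus_counts\t" + "\t".join(
                f"{g}:{self.n_train[g]}" for g in self.genera) + "\n")
            fh.write("#word_index\t" + "\t".join(self.genera) + "\n")
            nz = np.flatnonzero(counts.sum(axis=0))
            for w in nz:
                fh.write(str(int(w)) + "\t" + "\t".join(
                    str(int(c)) for c in counts[:, w]) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "NBCModel":
        k = None
        n_train: dict[str, int] = {}
        genera: tuple[str, ...] = ()
        rows: list[tuple[int, list[int]]] = []
        with Path(path).open() as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#k\t"):
                    k = int(line.split("\t")[1])
                elif line.startswith("#genus_counts\t"):
                    for item in line.split("\t")[1:]:
                        g, n = item.rsplit(":", 1)
                        n_train[g] = int(n)
                    genera = tuple(sorted(n_train))
                elif line.startswith("#") or not line:
                    continue
                else:
                    parts = line.split("\t")
                    rows.append((int(parts[0]), [int(x) for x in parts[1:]]))
        if k is None or not genera:
            raise ValueError(f"malformed model file {path}")
        counts = np.zeros((len(genera), 4 ** k), dtype=np.int64)
        for w, cs in rows:
            counts[:, w] = cs
        return _model_from_counts(k, genera, counts, n_train)

    @property
    def _counts(self) -> np.ndarray:
        # recover integer counts from probabilities: m_g(w) = P(w|g)(M_g+1) - prior(w)
        M = np.array([self.n_train[g] for g in self.genera], dtype=float)
        m = np.exp(self.cond_log_prob) * (M[:, None] + 1.0) - self.word_prior[None, :]
        return np.rint(m).astype(np.int64)


def _model_from_counts(
    k: int,
    genera: tuple[str, ...],
    counts: np.ndarray,
    n_train: Mapping[str, int],
) -> NBCModel:
    N = sum(n_train.values())
    nw = counts.sum(axis=0).astype(float)
    prior = (nw + 0.5) / (N + 1.0)
    M = np.array([n_train[g] for g in genera], dtype=float)
    cond = (counts + prior[None, :]) / (M[:, None] + 1.0)
    return NBCModel(
        k=k,
        genera=genera,
        word_prior=prior,
        cond_log_prob=np.log(cond),
        n_train=dict(n_train),
    )


def train(records: Sequence[ReferenceSequence], k: int = 8) -> NBCModel:
    """Train genus-conditional word statistics from genus-labeled sequences.

    Records without a genus label are skipped with a warning; at least two
    labeled genera, each with at least one sequence, are required.
    """
    by_genus: dict[str, list[ReferenceSequence]] = {}
    for rec in records:
        if not rec.genus:
            warnings.warn(f"skipping {rec.id!r}: no genus label", stacklevel=2)
            continue
        by_genus.setdefault(rec.genus, []).append(rec)
    if len(by_genus) < 2:
        raise ValueError("training requires at least 2 labeled genera")
    genera = tuple(sorted(by_genus))
    counts = np.zeros((len(genera), 4 ** k), dtype=np.int64)
    n_train: dict[str, int] = {}
    for gi, g in enumerate(genera):
        n_train[g] = len(by_genus[g])
        for rec in by_genus[g]:
            idx = _word_indices(rec.sequence, k)
            counts[gi, idx] += 1
    return _model_from_counts(k, genera, counts, n_train)


def classify_scores(model: NBCModel, seq: str) -> np.ndarray:
    """Per-genus log posterior scores (order = model.genera)."""
    idx = _word_indices(seq, model.k)
    if idx.size == 0:
        raise ValueError("query contains no scorable words")
    return model.cond_log_prob[:, idx].sum(axis=1)


def classify(model: NBCModel, seq: str) -> str:
    """Genus maximizing the summed log word probabilities (ties: lexicographic)."""
    scores = classify_scores(model, seq)
    # genera are sorted, and argmax returns the first maximum
    return model.genera[int(np.argmax(scores))]


@dataclass(frozen=True)
class Classification:
    seq_id: str
    predicted_genus: str
    bootstrap_confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.bootstrap_confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


def _query_rng(seed: int | None, seq_id: str | None) -> np.random.Generator:
    if seq_id is None:
        return np.random.default_rng(seed)
    # per-query stream so batch results do not depend on processing order
    return np.random.default_rng([0 if seed is None else seed,
                                  zlib.crc32(seq_id.encode())])


def classify_bootstrap(
    model: NBCModel,
    seq: str,
    n_boot: int = 100,
    seed: int | None = None,
    seq_id: str | None = None,
) -> Classification:
    """Classify with bootstrap confidence.

    Each replicate draws ``max(1, n_words // 8)`` of the query's distinct
    words with replacement and classifies on that subset; confidence is the
    fraction of replicates agreeing with the full-word call.
    """
    idx = _word_indices(seq, model.k)
    if idx.size == 0:
        raise ValueError("query contains no scorable words")
    scores = model.cond_log_prob[:, idx]  # (G, W)
    full_gi = int(np.argmax(scores.sum(axis=1)))
    if n_boot <= 0:
        return Classification(seq_id=seq_id or "", predicted_genus=model.genera[full_gi],
                              bootstrap_confidence=0.0)
    rng = _query_rng(seed, seq_id)
    m = max(1, idx.size // 8)
    draws = rng.integers(0, idx.size, size=(n_boot, m))
    rep_scores = scores[:, draws].sum(axis=2)  # (G, n_boot)
    rep_call = np.argmax(rep_scores, axis=0)
    conf = float((rep_call == full_gi).mean())
    return Classification(seq_id=seq_id or "", predicted_genus=model.genera[full_gi],
                          bootstrap_confidence=conf)


def evaluate_amplicon_classification(
    model: NBCModel,
    amplicons: Iterable[tuple[str, str, str]],
    n_boot: int = 100,
    seed: int | None = 0,
    min_confidence: float = 0.80,
) -> pd.DataFrame:
    """Genus-level accuracy of amplicon classification.

    ``amplicons`` yields ``(seq_id, amplicon_sequence, true_genus)``.
    Identical amplicon sequences are dereplicated (first-seen id/label kept)
    before classification.  Returns one row per true genus with columns
    ``n, n_correct, fraction_correct, fraction_confident`` where
    ``fraction_confident`` is the share of *correct* calls at confidence >=
    ``min_confidence`` (1.0 for a genus with no correct calls would be
    meaningless, so it is reported as NaN then).
    """
    uniq: dict[str, tuple[str, str]] = {}
    for sid, seq, genus in amplicons:
        if seq not in uniq:
            uniq[seq] = (sid, genus)
    if not uniq:
        raise ValueError("no amplicons to evaluate")
    per_genus: dict[str, dict[str, int]] = {}
    for seq, (sid, genus) in uniq.items():
        stats = per_genus.setdefault(genus, {"n": 0, "n_correct": 0, "n_conf": 0})
        stats["n"] += 1
        if genus not in model.genera:
            warnings.warn(f"genus {genus!r} absent from model; counted incorrect",
                          stacklevel=2)
            continue
        res = classify_bootstrap(model, seq, n_boot=n_boot, seed=seed, seq_id=sid)
        if res.predicted_genus == genus:
            stats["n_correct"] += 1
            if res.bootstrap_confidence >= min_confidence:
                stats["n_conf"] += 1
    rows = []
    for genus in sorted(per_genus):
        s = per_genus[genus]
        rows.append({
            "genus": genus,
            "n": s["n"],
            "n_correct": s["n_correct"],
            "fraction_correct": s["n_correct"] / s["n"],
            "fraction_confident": (s["n_conf"] / s["n_correct"]) if s["n_correct"] else float("nan"),
        })
    return pd.DataFrame(rows, columns=["genus", "n", "n_correct",
                                       "fraction_correct", "fraction_confident"])
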
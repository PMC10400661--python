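"""Word-based naive Bayesian taxonomic classifier with bootstrap confidence.

The classical amplicon classifier: every training sequence is decomposed
into overlapping k-mers ("words", k = 8 by default); for each word the
overall prior is ``P_i = (n_i + 0.5) / (N + 1)`` (``n_i`` = training
sequences containing the word, ``N`` = training corpus size) and the
genus-conditional probability is ``P(w_i | G) = (m_i + P_i) / (M + 1)``
(``m_i`` = sequences of genus ``G`` containing the word, ``M`` = number of
sequences in ``G``).  A query is assigned to the genus maximizing the sum
of log conditional probabilities over its distinct words; confidence per
taxonomic rank is estimated by bootstrap: ``n_bootstrap`` draws of
``W // 8`` words with replacement, the per-rank confidence being the
percentage of trials whose winning genus rolls up to the same taxon.  Both
strands are scored and the better one kept, so the classifier does not
depend on query orientation.

Exposed as a scikit-learn style estimator
(:class:`NaiveBayesTaxonomyClassifier`) with ``fit``/``predict``; the
module-level :func:`train` / :func:`classify` / :func:`assignment_rate`
functions are thin wrappers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from amplikit.primer_model import revcomp

__all__ = [
    "RANKS",
    "TaxAssignment",
    "NaiveBayesTaxonomyClassifier",
    "train",
    "classify",
    "assignment_rate",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_SPACER_RUN = re.compile(r"N+")


def parse_lineage(lineage: str) -> dict[str, str | None]:
    """Parse a semicolon lineage (with or without d__/p__ prefixes)."""
    parts = [p.strip() for p in lineage.split(";") if p.strip()]
    out: dict[str, str | None] = {r: None for r in RANKS}
    prefixed = any("__" in p for p in parts)
    for i, p in enumerate(parts):
        if prefixed:
            tag, _, name = p.partition("__")
            rank = {
                "d": "domain", "k": "domain", "p": "phylum", "c": "class",
                "o": "order", "f": "family", "g": "genus", "s": "species",
            }.get(tag.lower())
            if rank and name:
                out[rank] = name
        elif i < len(RANKS):
            out[RANKS[i]] = p
    return out


@dataclass
class TaxAssignment:
    """Ranked lineage with per-rank bootstrap confidence (0-100)."""

    lineage: dict[str, str | None]
    confidence: dict[str, float]
    cutoff: float = 80.0
    unclassified: bool = False
    strand: str = "+"

    def assigned(self, rank: str) -> bool:
        if self.unclassified or self.lineage.get(rank) is None:
            return False
        return self.confidence.get(rank, 0.0) >= self.cutoff

    @property
    def genus(self) -> str | None:
        return self.lineage.get("genus")


def _words(seq: str, k: int) -> set[str]:
    seq = seq.upper()
    return {
        seq[i : i + k]
        for i in range(len(seq) - k + 1)
        if all(c in "ACGT" for c in seq[i : i + k])
    }


def _query_words(seq: str, k: int) -> set[str]:
    """Distinct words of a query; concatenated sequences are split at the
    N spacer and their word sets unioned."""
    out: set[str] = set()
    for segment in _SPACER_RUN.split(seq.upper()):
        if segment:
            out |= _words(segment, k)
    return out


class NaiveBayesTaxonomyClassifier(BaseEstimator, ClassifierMixin):
    """RDP-style naive Bayes genus classifier over k-mer words.

    Parameters
    ----------
    k : word length (default 8).
    n_bootstrap : bootstrap trials for confidence estimation (default 100).
    cutoff : per-rank confidence (%) required for an assignment (default 80).
    random_state : seed for the bootstrap draws.

    Fitted attributes (trailing underscore): ``classes_`` (genus labels),
    ``word_index_``, ``log_cond_`` (genera x words log conditional
    probabilities), ``lineages_`` (genus -> per-rank lineage), ``n_refs_``.
    """

    def __init__(
        self,
        k: int = 8,
        n_bootstrap: int = 100,
        cutoff: float = 80.0,
        random_state: int | None = 0,
    ):
        self.k = k
        self.n_bootstrap = n_bootstrap
        self.cutoff = cutoff
        self.random_state = random_state

    def fit(self, X, y):
        """Train on sequences ``X`` with semicolon lineages ``y``."""
        X = list(X)
        lineages = [parse_lineage(l) for l in y]
        genera = []
        for lin in lineages:
            if lin["genus"] is None:
                raise ValueError("every training lineage needs a genus rank")
            genera.append(lin["genus"])
        if len(set(genera)) < 2:
            raise ValueError("training requires at least 2 genera")
        per_seq_words = []
        for seq, genus in zip(X, genera):
            w = _words(seq, self.k)
            per_seq_words.append(w)
        for genus in set(genera):
            if all(
                not per_seq_words[i]
                for i in range(len(X))
                if genera[i] == genus
            ):
                raise ValueError(
                    f"genus {genus!r} has no sequence of length >= k={self.k}"
                )
        vocabulary = sorted(set().union(*per_seq_words))
        word_index = {w: j for j, w in enumerate(vocabulary)}
        N = len(X)
        n_i = np.zeros(len(vocabulary))
        for words in per_seq_words:
            for w in words:
                n_i[word_index[w]] += 1
        priors = (n_i + 0.5) / (N + 1)
        self.classes_ = np.array(sorted(set(genera)))
        genus_pos = {g: gi for gi, g in enumerate(self.classes_)}
        M = np.zeros(len(self.classes_))
        m_i = np.zeros((len(self.classes_), len(vocabulary)))
        for words, genus in zip(per_seq_words, genera):
            gi = genus_pos[genus]
            M[gi] += 1
            for w in words:
                m_i[gi, word_index[w]] += 1
        self.log_cond_ = np.log(
            (m_i + priors[None, :]) / (M[:, None] + 1.0)
        )
        # floor log-probability per genus for words never seen in training
        # (prior of an unseen word: 0.5 / (N + 1))
        self.log_floor_ = np.log((0.5 / (N + 1)) / (M + 1.0))
        self.word_index_ = word_index
        self.lineages_ = {}
        for lin, genus in zip(lineages, genera):
            self.lineages_.setdefault(genus, lin)
        self.n_refs_ = N
        return self

    def _score(self, words: set[str]) -> np.ndarray | None:
        """Genera x query-words log-probability matrix.

        Words absent from the training vocabulary contribute the per-genus
        floor probability, so scores are comparable across strands and
        queries of different novelty.
        """
        idx = [self.word_index_[w] for w in words if w in self.word_index_]
        n_unseen = len(words) - len(idx)
        if not idx and not n_unseen:
            return None
        parts = []
        if idx:
            parts.append(self.log_cond_[:, np.array(sorted(idx))])
        if n_unseen:
            parts.append(
                np.tile(self.log_floor_[:, None], (1, n_unseen))
            )
        return np.concatenate(parts, axis=1)

    def _classify_one(self, seq: str, rng) -> TaxAssignment:
        best = None
        best_strand = "+"
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            words = _query_words(s, self.k)
            A = self._score(words)
            if A is None:
                continue
            total = A.sum(axis=1)
            if best is None or total.max() > best[1].max():
                best = (A, total)
                best_strand = strand
        if best is None:
            return TaxAssignment(
                lineage={r: None for r in RANKS},
                confidence={r: 0.0 for r in RANKS},
                cutoff=self.cutoff,
                unclassified=True,
            )
        A, total = best
        top = int(np.argmax(total))
        W = A.shape[1]
        m = max(1, W // 8)
        draws = rng.integers(0, W, size=(self.n_bootstrap, m))
        trial_scores = A[:, draws].sum(axis=2)  # (genera, trials)
        winners = np.argmax(trial_scores, axis=0)
        top_lineage = self.lineages_[self.classes_[top]]
        confidence = {}
        for rank in RANKS:
            taxon = top_lineage.get(rank)
            if taxon is None:
                confidence[rank] = 0.0
                continue
            agree = np.fromiter(
                (
                    self.lineages_[self.classes_[wi]].get(rank) == taxon
                    for wi in winners
                ),
                dtype=bool,
                count=len(winners),
            )
            confidence[rank] = 100.0 * float(agree.mean())
        return TaxAssignment(
            lineage=dict(top_lineage),
            confidence=confidence,
            cutoff=self.cutoff,
            strand=best_strand,
        )

    def predict_with_confidence(self, X) -> list[TaxAssignment]:
        rng = np.random.default_rng(self.random_state)
        return [self._classify_one(seq, rng) for seq in X]

    def predict(self, X):
        return np.array(
            [
                a.genus if not a.unclassified else "unclassified"
                for a in self.predict_with_confidence(X)
            ]
        )


def train(
    refs: list[tuple[str, str, str]], k: int = 8, **kwargs
) -> NaiveBayesTaxonomyClassifier:
    """Fit a classifier on (id, lineage, sequence) reference records."""
    model = NaiveBayesTaxonomyClassifier(k=k, **kwargs)
    return model.fit([r[2] for r in refs], [r[1] for r in refs])


def classify(
    seq: str,
    model: NaiveBayesTaxonomyClassifier,
    n_bootstrap: int = 100,
    cutoff: float = 80.0,
    seed: int | None = 0,
) -> TaxAssignment:
    """Classify one sequence with explicit bootstrap/cutoff/seed settings."""
    saved = (model.n_bootstrap, model.cutoff, model.random_state)
    try:
        model.n_bootstrap, model.cutoff, model.random_state = (
            n_bootstrap, cutoff, seed,
        )
        return model.predict_with_confidence([seq])[0]
    finally:
        model.n_bootstrap, model.cutoff, model.random_state = saved


def assignment_rate(
    assignments: list[TaxAssignment], rank: str = "genus"
) -> float:
    """Percentage of assignments confidently resolved at a rank."""
    if not assignments:
        return 0.0
    return 100.0 * sum(a.assigned(rank) for a in assignments) / len(assignments)
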
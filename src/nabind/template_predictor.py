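"""Template-based residue prediction via profile-alignment hits.

A query is searched against a library of labeled training chains; the
top-scoring template (by the 0-100 similarity probability, "HHscore")
donates its binding annotations across matched alignment columns: a query
residue scores 1 iff it aligns to a binding template residue, else 0.

Two search engines satisfy the same contract: ``hhr_engine`` consumes
reports produced externally by an HMM-HMM search tool, and
``ToyProfileSearchEngine`` is a self-contained profile-profile aligner
(global, affine gaps) whose score-to-probability mapping is a calibrated
logistic — a testing stand-in, not an emulation of any external tool's
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .constants import BLOSUM62_BACKGROUND
from .dataset_builder import LabeledChain
from .io_formats import (AlignmentReport, DataError, SequenceProfile,
                         TemplateHit, read_hhr)


@dataclass
class TemplateEntry:
    sequence: str
    labels: np.ndarray
    profile: SequenceProfile | None = None


@dataclass
class TemplateLibrary:
    """Searchable labeled chains, built from training folds only."""

    entries: dict[str, TemplateEntry] = field(default_factory=dict)

    @staticmethod
    def from_chains(chains: list[LabeledChain],
                    profiles: dict[str, SequenceProfile] | None = None) -> "TemplateLibrary":
        lib = TemplateLibrary()
        for c in chains:
            prof = profiles.get(c.id) if profiles else None
            lib.entries[c.id] = TemplateEntry(c.sequence, np.asarray(c.labels, bool), prof)
        return lib

    def without(self, chain_ids: set[str]) -> "TemplateLibrary":
        """Library copy excluding the given chains (e.g. the query itself)."""
        return TemplateLibrary({
            k: v for k, v in self.entries.items() if k not in chain_ids
        })

    def __len__(self) -> int:
        return len(self.entries)


def select_top_template(hits: list[TemplateHit]) -> TemplateHit | None:
    """Hit with maximal HHscore; ties keep the first in engine order."""
    best = None
    for hit in hits:
        if best is None or hit.hhscore > best.hhscore:
            best = hit
    return best


def transfer_annotations(query_length: int, hit: TemplateHit | None,
                         library: TemplateLibrary) -> tuple[np.ndarray, bool]:
    """Per-residue template scores (0/1) and a has-template flag.

    Matched query residues inherit the template residue's binding label;
    unaligned residues score 0. Without a template every residue scores 0
    and the flag is False.
    """
    tscores = np.zeros(query_length)
    if hit is None:
        return tscores, False
    entry = library.entries.get(hit.template_id)
    if entry is None:
        raise DataError(f"template {hit.template_id!r} not in library")
    for q, t in hit.mapping.items():
        if not 0 <= q < query_length:
            raise DataError(f"query index {q} out of range")
        if not 0 <= t < len(entry.labels):
            raise DataError(f"template index {t} out of range")
        tscores[q] = float(entry.labels[t])
    return tscores, True


# ---------------------------------------------------------------------------
# Toy profile-profile search engine
# ---------------------------------------------------------------------------

@dataclass
class ToyEngineConfig:
    gap_open: float = 1.0
    gap_extend: float = 0.1
    score_midpoint: float = 0.025  # length-normalised score mapping to 50
    score_scale: float = 0.004     # logistic temperature of the mapping


def profile_frequencies(profile: SequenceProfile,
                        background: np.ndarray | None = None) -> np.ndarray:
    """Per-column frequency distributions from the WOP matrix.

    All-zero rows (gap-dominated columns) fall back to the background.
    """
    q = background if background is not None else BLOSUM62_BACKGROUND
    freq = profile.wop.astype(float).copy()
    sums = freq.sum(axis=1)
    zero = sums == 0
    freq[zero] = q
    freq[~zero] /= sums[~zero, None]
    return freq


def align_profiles(fq: np.ndarray, ft: np.ndarray, gap_open: float = 1.0,
                   gap_extend: float = 0.1,
                   background: np.ndarray | None = None
                   ) -> tuple[float, dict[int, int]]:
    """Global affine-gap alignment of two frequency profiles (Gotoh).

    Column score = sum_a fq(a) * ft(a), centred so that two background
    columns score zero. Returns (total score, strictly increasing mapping of
    matched columns, 0-based).
    """
    q = background if background is not None else BLOSUM62_BACKGROUND
    S = fq @ ft.T - float(q @ q)
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)  # gap consuming the query (vertical)
    F = np.full((n + 1, m + 1), NEG)  # gap consuming the template (horizontal)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        E[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        F[0, j] = -gap_open - (j - 1) * gap_extend

    js = np.arange(1, m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum.reduce([M[i - 1], E[i - 1], F[i - 1]])
        M[i, 1:] = S[i - 1] + prev_best[:-1]
        E[i, 1:] = np.maximum(M[i - 1, 1:] - gap_open, E[i - 1, 1:] - gap_extend)
        # F depends on M within the row: unrolled via a running maximum of
        # M[i, k] + k * gap_extend over k < j
        A = M[i, :-1] + np.arange(m) * gap_extend
        F[i, 1:] = np.maximum.accumulate(A) - gap_open - (js - 1) * gap_extend

    score = float(max(M[n, m], E[n, m], F[n, m]))

    # traceback
    mapping: dict[int, int] = {}
    i, j = n, m
    state = max((M[n, m], "M"), (E[n, m], "E"), (F[n, m], "F"))[1]
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            mapping[i - 1] = j - 1
            prev = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for cand, val in (("M", M[i, j]), ("E", E[i, j]), ("F", F[i, j])):
                if abs(val - prev) <= tol:
                    state = cand
                    break
        elif state == "E":
            if abs(M[i - 1, j] - gap_open - E[i, j]) <= tol:
                state = "M"
            i -= 1
        else:  # F
            if abs(M[i, j - 1] - gap_open - F[i, j]) <= tol:
                state = "M"
            j -= 1
    return score, dict(sorted(mapping.items()))


@dataclass
class ToyProfileSearchEngine:
    """Deterministic profile-profile search over an in-memory library."""

    profiles: dict[str, SequenceProfile]
    config: ToyEngineConfig = field(default_factory=ToyEngineConfig)
    background: np.ndarray = field(
        default_factory=lambda: BLOSUM62_BACKGROUND.copy()
    )

    def score_to_probability(self, score: float, lq: int, lt: int) -> float:
        norm = score / min(lq, lt)
        return float(100.0 * expit(
            (norm - self.config.score_midpoint) / self.config.score_scale
        ))

    def search(self, query_profile: SequenceProfile,
               library: TemplateLibrary) -> list[TemplateHit]:
        """Hits over the library, sorted by HHscore descending (stable)."""
        fq = profile_frequencies(query_profile, self.background)
        hits: list[TemplateHit] = []
        for tid in library.entries:
            prof = self.profiles.get(tid)
            if prof is None:
                continue
            ft = profile_frequencies(prof, self.background)
            score, mapping = align_profiles(
                fq, ft, self.config.gap_open, self.config.gap_extend,
                self.background,
            )
            hh = self.score_to_probability(score, len(fq), len(ft))
            hits.append(TemplateHit(tid, hh, mapping))
        hits.sort(key=lambda h: -h.hhscore)  # stable: ties keep library order
        return hits


def hhr_engine(query_id: str, hhr_path: str | Path,
               library: TemplateLibrary) -> list[TemplateHit]:
    """Hits from an externally produced HHR report, filtered to the library."""
    report: AlignmentReport = read_hhr(hhr_path)
    if report.query_id != query_id:
        raise DataError(
            f"HHR report is for query {report.query_id!r}, expected {query_id!r}"
        )
    return [h for h in report.hits if h.template_id in library.entries]
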
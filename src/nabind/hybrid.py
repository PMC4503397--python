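"""Piecewise fusion of the feature and template predictors.

For a chain whose best template reaches the similarity cutoff, the final
score is the convex combination

    Cscore = alpha * Fscore + (1 - alpha) * Tscore    if HHscore >= cutoff
    Cscore = Fscore                                   otherwise

with alpha = 0.6 and cutoff = 85% by default. A template exactly at the
cutoff takes the combined branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import DataError


@dataclass
class HybridConfig:
    alpha: float = 0.6
    cutoff: float = 85.0
    call_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 <= self.cutoff <= 100.0:
            raise ValueError("cutoff must lie in [0, 100]")


@dataclass
class PredictionResult:
    """Per-residue scores and calls for one chain."""

    chain_id: str
    residues: str
    fscores: np.ndarray
    tscores: np.ndarray | None
    hhscore_used: float | None
    cscores: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.residues)
        for name in ("fscores", "cscores", "calls"):
            if len(getattr(self, name)) != n:
                raise DataError(f"{self.chain_id}: {name} length mismatch")
        if self.tscores is not None and len(self.tscores) != n:
            raise DataError(f"{self.chain_id}: tscores length mismatch")
        if np.any(self.cscores < 0) or np.any(self.cscores > 1):
            raise DataError(f"{self.chain_id}: Cscore outside [0, 1]")


def combine(chain_id: str, residues: str, fscores: np.ndarray,
            tscores: np.ndarray | None = None,
            hhscore: float | None = None,
            cfg: HybridConfig | None = None) -> PredictionResult:
    """Apply the piecewise combination rule for one chain.

    ``tscores`` and ``hhscore`` must be supplied together. A template below
    the cutoff is recorded (``hhscore_used``) but the scores fall back to
    the feature predictor alone.
    """
    cfg = cfg or HybridConfig()
    fscores = np.asarray(fscores, dtype=float)
    if (tscores is None) != (hhscore is None):
        raise DataError("tscores and hhscore must be provided together")
    if len(fscores) != len(residues):
        raise DataError("fscores length does not match the sequence")
    if tscores is not None:
        tscores = np.asarray(tscores, dtype=float)
        if len(tscores) != len(fscores):
            raise DataError("fscores and tscores differ in length")
    if tscores is not None and hhscore >= cfg.cutoff:
        cscores = cfg.alpha * fscores + (1.0 - cfg.alpha) * tscores
    else:
        cscores = fscores.copy()
    calls = binarize(cscores, cfg.call_threshold)
    return PredictionResult(chain_id=chain_id, residues=residues,
                            fscores=fscores, tscores=tscores,
                            hhscore_used=hhscore, cscores=cscores, calls=calls)


def binarize(scores: np.ndarray, call_threshold: float = 0.5) -> np.ndarray:
    """Binary calls: score >= threshold (ties call binding)."""
    scores = np.asarray(scores, dtype=float)
    if np.any(scores < 0) or np.any(scores > 1):
        raise DataError("scores outside [0, 1]")
    return scores >= call_threshold
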
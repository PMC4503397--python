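"""Per-residue sequence descriptors and sliding-window vector assembly.

Seven feature families characterise each residue: the logistic-normalised
profile row, three conservation scores computed from weighted observed
percentages (Shannon entropy, relative entropy, Jensen-Shannon divergence),
predicted structural descriptors, physicochemical scales, interface
propensity, sequential position indicators, and two chain-global features
(length and composition). A window of the target residue plus five flanking
residues on each side (11 total by default) forms the classifier input.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .constants import (AA_INDEX, AA_ORDER, BLOSUM62_BACKGROUND, MAX_ASA,
                        PHYSCHEM_RAW)
from .dataset_builder import LabeledChain
from .io_formats import DataError, SequenceProfile


def logistic_normalize(x):
    """Squash raw profile elements into (0, 1) via f(x) = 1 / (1 + e^-x)."""
    return expit(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# Conservation scores
# ---------------------------------------------------------------------------

@dataclass
class ConservationConfig:
    lambda_weight: float = 0.5
    background: np.ndarray = field(
        default_factory=lambda: BLOSUM62_BACKGROUND.copy()
    )
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.lambda_weight < 1.0:
            raise ValueError("lambda_weight must lie in (0, 1)")
        self.background = np.asarray(self.background, dtype=float)
        if np.any(self.background <= 0):
            raise ValueError("background frequencies must be strictly positive")
        self.background = self.background / self.background.sum()


@dataclass
class ConservationScores:
    se: np.ndarray
    re: np.ndarray
    jsd: np.ndarray


def _xlogy(p: np.ndarray, y: np.ndarray, base: float) -> np.ndarray:
    """p * log_base(y) with the 0*log(0) := 0 convention."""
    out = np.zeros_like(p)
    mask = p > 0
    out[mask] = p[mask] * (np.log(y[mask]) / np.log(base))
    return out


def conservation_scores(profile: SequenceProfile,
                        cfg: ConservationConfig | None = None) -> ConservationScores:
    """Shannon entropy, relative entropy, and Jensen-Shannon divergence.

    Each WOP row is renormalised to a frequency vector p_i; with
    c_i = lambda*p_i + (1-lambda)*q:

        SE  = -sum p log p
        RE  =  sum p log(p/q)
        JSD =  lambda * sum p log(p/c) + (1-lambda) * sum q log(q/c)

    All-zero WOP rows (gap-dominated profile columns) fall back to p = q,
    giving SE(q), RE = 0 and JSD = 0.
    """
    cfg = cfg or ConservationConfig()
    if np.any(profile.wop < 0):
        raise DataError("negative weighted observed percentage")
    q = cfg.background
    lam = cfg.lambda_weight
    base = cfg.log_base
    n = profile.length
    se = np.zeros(n)
    re = np.zeros(n)
    jsd = np.zeros(n)
    for i in range(n):
        row = profile.wop[i]
        total = row.sum()
        p = q if total == 0 else row / total
        c = lam * p + (1 - lam) * q
        se[i] = -_xlogy(p, p, base).sum()
        re[i] = (_xlogy(p, p, base) - _xlogy(p, q, base)).sum()
        jsd[i] = (lam * (_xlogy(p, p, base) - _xlogy(p, c, base)).sum()
                  + (1 - lam) * (_xlogy(q, q, base) - _xlogy(q, c, base)).sum())
    return ConservationScores(se=se, re=re, jsd=jsd)


# ---------------------------------------------------------------------------
# Structural descriptors
# ---------------------------------------------------------------------------

@dataclass
class StructuralDescriptors:
    ss_onehot: np.ndarray   # (L, 3) over H, E, C
    rsa_norm: np.ndarray    # (L,) in [0, 1]
    phi_norm: np.ndarray    # (L,) in [-1, 1]
    psi_norm: np.ndarray    # (L,) in [-1, 1]
    disorder: np.ndarray    # (L,) in [0, 1]

    def matrix(self) -> np.ndarray:
        return np.column_stack([
            self.ss_onehot, self.rsa_norm, self.phi_norm, self.psi_norm,
            self.disorder,
        ])


_SS_STATES = "HEC"


def structural_descriptors(table: pd.DataFrame, sequence: str,
                           max_asa: dict[str, float] | None = None) -> StructuralDescriptors:
    """Normalise a per-residue predicted-structure table.

    Solvent accessibility is divided by the residue type's maximum surface
    area and clamped to [0, 1] (predictors occasionally overshoot the
    maximum); dihedral angles are divided by 180; disorder is clamped to
    [0, 1]. Unknown residue types use the mean maximum area.
    """
    max_asa = max_asa or MAX_ASA
    if len(table) != len(sequence):
        raise DataError("structure table length does not match the sequence")
    ss = table["ss"].astype(str).to_numpy()
    bad = set(ss) - set(_SS_STATES)
    if bad:
        raise DataError(f"unknown secondary-structure symbols {sorted(bad)}")
    onehot = np.zeros((len(ss), 3))
    for j, state in enumerate(_SS_STATES):
        onehot[:, j] = ss == state
    mean_asa = float(np.mean(list(max_asa.values())))
    denom = np.array([max_asa.get(aa, mean_asa) for aa in sequence])
    rsa = np.clip(table["rsa_raw"].to_numpy(float) / denom, 0.0, 1.0)
    phi = table["phi"].to_numpy(float) / 180.0
    psi = table["psi"].to_numpy(float) / 180.0
    if np.any(np.abs(phi) > 1.0) or np.any(np.abs(psi) > 1.0):
        raise DataError("dihedral angles outside [-180, 180]")
    disorder = np.clip(table["disorder"].to_numpy(float), 0.0, 1.0)
    return StructuralDescriptors(onehot, rsa, phi, psi, disorder)


# ---------------------------------------------------------------------------
# Interface propensity
# ---------------------------------------------------------------------------

@dataclass
class PropensityTable:
    raw: np.ndarray         # (20,) frequency ratio interface / overall
    normalized: np.ndarray  # (20,) min-max scaled to [0, 1]

    def for_sequence(self, sequence: str) -> np.ndarray:
        # unknown residue types get the neutral mid-scale value
        return np.array([
            self.normalized[AA_INDEX[aa]] if aa in AA_INDEX else 0.5
            for aa in sequence
        ])


def interface_propensity(train: list[LabeledChain]) -> PropensityTable:
    """Amino-acid interface propensity pooled over training chains.

    Raw propensity of type i = (frequency of i among binding residues) /
    (frequency of i among all residues); types absent from interfaces score
    0. Values are min-max normalised over the 20 types. Computed on training
    folds only to avoid test-set leakage.
    """
    all_counts = np.zeros(20)
    int_counts = np.zeros(20)
    for chain in train:
        for aa, is_binding in zip(chain.sequence, chain.labels):
            idx = AA_INDEX.get(aa)
            if idx is None:
                continue
            all_counts[idx] += 1
            if is_binding:
                int_counts[idx] += 1
    n_all, n_int = all_counts.sum(), int_counts.sum()
    if n_int == 0 or n_int == n_all:
        raise DataError("degenerate training labels: need both classes")
    raw = np.zeros(20)
    present = all_counts > 0
    raw[present] = (int_counts[present] / n_int) / (all_counts[present] / n_all)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        raise DataError("degenerate propensity table: all types identical")
    return PropensityTable(raw=raw, normalized=(raw - lo) / (hi - lo))


# ---------------------------------------------------------------------------
# Sequential position
# ---------------------------------------------------------------------------

@dataclass
class FeatureConfig:
    window_flank: int = 5
    min_seg_len: int = 3
    include_profile: bool = True
    include_conservation: bool = True
    include_structure: bool = True
    include_physchem: bool = True
    include_propensity: bool = True
    include_seqpos: bool = True
    include_global: bool = True
    physchem_table: np.ndarray = field(
        default_factory=lambda: logistic_normalize(PHYSCHEM_RAW)
    )

    @property
    def window(self) -> int:
        return 2 * self.window_flank + 1


def sequential_position(sequence: str, ss_string: str,
                        cfg: FeatureConfig | None = None) -> np.ndarray:
    """Terminus and secondary-structure segment indicators, (L, 4).

    Columns: terminus (first or last three positions), helix-segment,
    strand-segment, coil. A segment indicator fires when a run of at least
    ``min_seg_len`` consecutive H (or E) states intersects the residue's
    window; coil is the complement of both.
    """
    cfg = cfg or FeatureConfig()
    n = len(sequence)
    if len(ss_string) != n:
        raise DataError("secondary-structure string length mismatch")
    out = np.zeros((n, 4))
    out[:3, 0] = 1.0
    out[max(0, n - 3):, 0] = 1.0

    in_seg = {"H": np.zeros(n, bool), "E": np.zeros(n, bool)}
    i = 0
    while i < n:
        j = i
        while j < n and ss_string[j] == ss_string[i]:
            j += 1
        if ss_string[i] in in_seg and j - i >= cfg.min_seg_len:
            in_seg[ss_string[i]][i:j] = True
        i = j
    flank = cfg.window_flank
    for i in range(n):
        lo, hi = max(0, i - flank), min(n, i + flank + 1)
        helix = bool(in_seg["H"][lo:hi].any())
        strand = bool(in_seg["E"][lo:hi].any())
        out[i, 1] = helix
        out[i, 2] = strand
        out[i, 3] = not (helix or strand)
    return out


def global_features(sequence: str) -> np.ndarray:
    """Chain-level 21-vector: length/1000 then composition over 20 types.

    'X' residues are excluded from both numerator and denominator of the
    composition, which sums to 1 for any chain with at least one canonical
    residue.
    """
    if not sequence:
        raise DataError("empty sequence")
    comp = np.zeros(20)
    for aa in sequence:
        idx = AA_INDEX.get(aa)
        if idx is not None:
            comp[idx] += 1
    total = comp.sum()
    if total > 0:
        comp /= total
    return np.concatenate([[len(sequence) / 1000.0], comp])


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

PER_RESIDUE_BLOCKS = (
    ("profile", 20, "include_profile"),
    ("conservation", 3, "include_conservation"),
    ("structure", 7, "include_structure"),
    ("physchem", 5, "include_physchem"),
    ("propensity", 1, "include_propensity"),
    ("seqpos", 4, "include_seqpos"),
)


def feature_layout(cfg: FeatureConfig) -> list[tuple[str, int]]:
    layout = [(name, width) for name, width, flag in PER_RESIDUE_BLOCKS
              if getattr(cfg, flag)]
    if cfg.include_global:
        layout.append(("global", 21))
    return layout


def layout_fingerprint(cfg: FeatureConfig) -> str:
    desc = {"window_flank": cfg.window_flank, "layout": feature_layout(cfg)}
    return hashlib.sha256(json.dumps(desc, sort_keys=True).encode()).hexdigest()[:16]


def vector_length(cfg: FeatureConfig) -> int:
    per_res = sum(w for name, w in feature_layout(cfg) if name != "global")
    glob = 21 if cfg.include_global else 0
    return cfg.window * per_res + glob


def assemble_vectors(sequence: str, profile: SequenceProfile,
                     struct_table: pd.DataFrame, propensity: PropensityTable,
                     cfg: FeatureConfig | None = None,
                     cons_cfg: ConservationConfig | None = None) -> np.ndarray:
    """Build the (L, D) feature matrix for one chain.

    Per-residue blocks are concatenated over window offsets -flank..+flank
    (positions beyond the termini contribute zeros), then the chain-global
    block is appended once.
    """
    cfg = cfg or FeatureConfig()
    n = len(sequence)
    if profile.length != n or len(struct_table) != n:
        raise DataError("per-residue inputs disagree on chain length")

    blocks: list[np.ndarray] = []
    if cfg.include_profile:
        blocks.append(logistic_normalize(profile.logodds))
    if cfg.include_conservation:
        cs = conservation_scores(profile, cons_cfg)
        blocks.append(np.column_stack([cs.se, cs.re, cs.jsd]))
    if cfg.include_structure:
        sd = structural_descriptors(struct_table, sequence)
        blocks.append(sd.matrix())
    if cfg.include_physchem:
        mid = cfg.physchem_table.mean(axis=0)
        rows = np.array([
            cfg.physchem_table[AA_INDEX[aa]] if aa in AA_INDEX else mid
            for aa in sequence
        ])
        blocks.append(rows)
    if cfg.include_propensity:
        blocks.append(propensity.for_sequence(sequence)[:, None])
    if cfg.include_seqpos:
        ss_string = "".join(struct_table["ss"].astype(str))
        blocks.append(sequential_position(sequence, ss_string, cfg))

    per_res = np.hstack(blocks) if blocks else np.zeros((n, 0))
    if not np.all(np.isfinite(per_res)):
        raise DataError("non-finite per-residue feature values")

    flank = cfg.window_flank
    w = per_res.shape[1]
    padded = np.zeros((n + 2 * flank, w))
    padded[flank:flank + n] = per_res
    windows = np.hstack([padded[off:off + n] for off in range(2 * flank + 1)])

    if cfg.include_global:
        glob = np.tile(global_features(sequence), (n, 1))
        return np.hstack([windows, glob])
    return windows
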
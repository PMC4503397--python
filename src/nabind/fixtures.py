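"""Seeded synthetic data so the whole pipeline is testable end to end.

The generator emulates the raw material of a nucleic-acid-binding residue
study: labeled protein chains, profile matrices whose binding columns carry
a planted evolutionary signal, per-residue predicted-structure tables,
protein-nucleic complex coordinates that reproduce the planted labels under
the 4.5 A contact rule, and a template library of exact or mutated copies.
A single integer seed drives all sub-generators through a splittable seed
sequence.

The geometry places residues on a line 3.8 A apart with one nucleic
phosphate 3.0 A from each binding residue, so planted binding residues are
within the cutoff and all others are at least 4.84 A from every nucleic
atom. Nothing here is biophysically realistic; it is a controlled test bed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import AA_INDEX, AA_ORDER, BLOSUM62_BACKGROUND, PROTEIN_3TO1
from .dataset_builder import LabeledChain
from .io_formats import SequenceProfile
from .template_predictor import TemplateEntry, TemplateLibrary

_AA = np.array(list(AA_ORDER))
_1TO3 = {v: k for k, v in PROTEIN_3TO1.items()}

#: Profile columns receiving the planted binding signal (basic residues).
DEFAULT_SIGNAL_COLUMNS = (AA_INDEX["R"], AA_INDEX["K"])


@dataclass
class FixtureConfig:
    seed: int = 0
    n_chains: int = 50
    length_range: tuple[int, int] = (50, 90)
    binding_fraction: float = 0.12
    feature_effect_size: float = 0.7
    template_mode: str = "exact_copy"  # exact_copy | mutated | none
    template_identity: float = 70.0
    na_type: str = "DNA"
    complementary: bool = False
    signal_columns: tuple[int, ...] = DEFAULT_SIGNAL_COLUMNS
    profile_concentration: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 < self.binding_fraction < 1.0:
            raise ValueError("binding_fraction must lie in (0, 1)")
        if not 0.0 <= self.template_identity <= 100.0:
            raise ValueError("template_identity must lie in [0, 100]")
        if self.template_mode not in ("exact_copy", "mutated", "none"):
            raise ValueError(f"unknown template_mode {self.template_mode!r}")
        if not 0.0 <= self.feature_effect_size <= 1.0:
            raise ValueError("feature_effect_size must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    config: FixtureConfig
    chains: list[LabeledChain]
    profiles: dict[str, SequenceProfile]
    struct_tables: dict[str, pd.DataFrame]
    pdb_texts: dict[str, str]
    library: TemplateLibrary
    library_profiles: dict[str, SequenceProfile]
    #: binding residues whose profile columns carry the planted signal
    signal_mask: dict[str, np.ndarray]
    #: binding residues annotated in the chain's library template
    template_mask: dict[str, np.ndarray]

    def labels(self) -> dict[str, np.ndarray]:
        return {c.id: c.labels for c in self.chains}


def _integer_wop(p: np.ndarray) -> np.ndarray:
    """Round a frequency vector to integer percentages summing to 100."""
    scaled = p * 100.0
    floors = np.floor(scaled)
    remainder = int(round(100 - floors.sum()))
    order = np.argsort(-(scaled - floors), kind="stable")
    floors[order[:remainder]] += 1
    return floors


def _column_base(q: np.ndarray, effect: float,
                 signal_columns: tuple[int, ...]) -> np.ndarray:
    boost = np.zeros_like(q)
    boost[list(signal_columns)] = 1.0 / len(signal_columns)
    return (1.0 - effect) * q + effect * boost


def _sample_profile(rng: np.random.Generator, sequence: str,
                    signal: np.ndarray, cfg: FixtureConfig) -> SequenceProfile:
    q = BLOSUM62_BACKGROUND
    n = len(sequence)
    wop = np.zeros((n, 20))
    logodds = np.zeros((n, 20))
    shifted = _column_base(q, cfg.feature_effect_size, cfg.signal_columns)
    for i in range(n):
        base = shifted if signal[i] else q
        p = rng.dirichlet(cfg.profile_concentration * base)
        wop[i] = _integer_wop(p)
        smooth = (wop[i] + 1.0) / (wop[i].sum() + 20.0)
        logodds[i] = np.clip(np.round(2.0 * np.log2(smooth / q)), -6, 6)
    return SequenceProfile(sequence, logodds, wop)


_SS_TYPES = ("H", "E", "C")


def _sample_ss(rng: np.random.Generator, n: int) -> str:
    out: list[str] = []
    while len(out) < n:
        state = _SS_TYPES[rng.choice(3, p=[0.35, 0.2, 0.45])]
        seg_len = 1 + rng.geometric(0.25 if state != "C" else 0.35)
        out.extend(state * seg_len)
    return "".join(out[:n])


#: Ramachandran-basin centres (phi, psi) per secondary-structure state.
_DIHEDRAL_CENTRES = {"H": (-62.0, -43.0), "E": (-120.0, 130.0), "C": (-80.0, 60.0)}


def _smooth_unit_series(rng: np.random.Generator, n: int,
                        rho: float = 0.7) -> np.ndarray:
    """AR(1) noise squashed to (0, 1): emulates autocorrelated predictions."""
    x = np.zeros(n)
    x[0] = rng.normal()
    for i in range(1, n):
        x[i] = rho * x[i - 1] + math.sqrt(1 - rho * rho) * rng.normal()
    return 1.0 / (1.0 + np.exp(-x))


def _struct_table(rng: np.random.Generator, sequence: str) -> pd.DataFrame:
    from .constants import MAX_ASA

    n = len(sequence)
    ss = _sample_ss(rng, n)
    rsa = _smooth_unit_series(rng, n) * np.array([MAX_ASA[aa] for aa in sequence])
    phi = np.empty(n)
    psi = np.empty(n)
    for i, state in enumerate(ss):
        c_phi, c_psi = _DIHEDRAL_CENTRES[state]
        spread = 15.0 if state in "HE" else 45.0
        phi[i] = np.clip(c_phi + spread * rng.normal(), -180.0, 180.0)
        psi[i] = np.clip(c_psi + spread * rng.normal(), -180.0, 180.0)
    disorder = 0.6 * _smooth_unit_series(rng, n, rho=0.9)
    return pd.DataFrame({
        "position": np.arange(1, n + 1),
        "ss": list(ss),
        "rsa_raw": np.round(rsa, 3),
        "phi": np.round(phi, 3),
        "psi": np.round(psi, 3),
        "disorder": np.round(disorder, 4),
    })


def _pdb_text(chain_id: str, sequence: str, labels: np.ndarray,
              na_type: str, resolution: float = 2.0) -> str:
    lines = [
        f"HEADER    SYNTHETIC COMPLEX                       01-JAN-00   {chain_id[:4].upper():<4s}",
        "EXPDTA    X-RAY DIFFRACTION",
        f"REMARK   2 RESOLUTION.    {resolution:.2f} ANGSTROMS.",
    ]
    serial = 1
    for i, aa in enumerate(sequence):
        x = 3.8 * i
        res3 = _1TO3.get(aa, "UNK")
        lines.append(
            f"ATOM  {serial:5d}  CA  {res3:>3s} A{i + 1:4d}    "
            f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
        )
        serial += 1
    nt_name = "DA" if na_type.upper() == "DNA" else "A"
    nt_num = 1
    for i in np.flatnonzero(labels):
        x = 3.8 * float(i)
        lines.append(
            f"ATOM  {serial:5d}  P   {nt_name:>3s} B{nt_num:4d}    "
            f"{x:8.3f}{3.0:8.3f}{0.0:8.3f}  1.00  0.00           P"
        )
        serial += 1
        nt_num += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _mutate(rng: np.random.Generator, sequence: str,
            identity: float) -> tuple[str, np.ndarray]:
    n = len(sequence)
    n_mut = int(math.ceil(n * (1.0 - identity / 100.0)))
    sites = rng.choice(n, size=n_mut, replace=False)
    seq = list(sequence)
    for i in sites:
        choices = [a for a in AA_ORDER if a != seq[i]]
        seq[i] = choices[rng.integers(len(choices))]
    mask = np.zeros(n, bool)
    mask[sites] = True
    return "".join(seq), mask


def generate_dataset(cfg: FixtureConfig | None = None) -> SyntheticDataset:
    """Generate a fully labeled synthetic study dataset.

    Binding positions are drawn per chain (at least five, matching the
    dataset filter); a fraction of them — all by default, alternate ones in
    complementary mode — carry the profile-column signal. In complementary
    mode the library templates annotate exactly the binding residues that
    do NOT carry the feature signal, so the feature and template arms see
    disjoint halves of the truth.
    """
    cfg = cfg or FixtureConfig()
    root = np.random.SeedSequence(cfg.seed)
    chain_seeds = root.spawn(cfg.n_chains)
    template_seed = root.spawn(1)[0]

    chains: list[LabeledChain] = []
    profiles: dict[str, SequenceProfile] = {}
    struct_tables: dict[str, pd.DataFrame] = {}
    pdb_texts: dict[str, str] = {}
    signal_mask: dict[str, np.ndarray] = {}
    template_mask: dict[str, np.ndarray] = {}

    lo, hi = cfg.length_range
    for idx, seed in enumerate(chain_seeds):
        rng = np.random.default_rng(seed)
        cid = f"syn{idx:03d}_A"
        n = int(rng.integers(lo, hi + 1))
        sequence = "".join(rng.choice(_AA, size=n, p=BLOSUM62_BACKGROUND))
        n_bind = int(np.clip(rng.binomial(n, cfg.binding_fraction), 5, n - 5))
        bind_pos = np.sort(rng.choice(n, size=n_bind, replace=False))
        labels = np.zeros(n, bool)
        labels[bind_pos] = True

        sig = np.zeros(n, bool)
        tmpl = np.zeros(n, bool)
        if cfg.complementary:
            sig[bind_pos[::2]] = True
            tmpl[bind_pos[1::2]] = True
        else:
            sig[bind_pos] = True
            tmpl[bind_pos] = True

        chains.append(LabeledChain(
            id=cid, sequence=sequence, labels=labels, na_type=cfg.na_type,
            source=(f"syn{idx:03d}", "A", 2.0, "X-RAY DIFFRACTION"),
        ))
        profiles[cid] = _sample_profile(rng, sequence, sig, cfg)
        struct_tables[cid] = _struct_table(rng, sequence)
        pdb_texts[cid] = _pdb_text(cid, sequence, labels, cfg.na_type)
        signal_mask[cid] = sig
        template_mask[cid] = tmpl

    library = TemplateLibrary()
    library_profiles: dict[str, SequenceProfile] = {}
    if cfg.template_mode != "none":
        trng = np.random.default_rng(template_seed)
        for chain in chains:
            tid = f"{chain.id}_t"
            tlabels = template_mask[chain.id] if cfg.complementary else chain.labels.copy()
            prof = profiles[chain.id]
            if cfg.template_mode == "exact_copy":
                tseq = chain.sequence
                tprof = SequenceProfile(tseq, prof.logodds.copy(), prof.wop.copy())
            else:
                tseq, mut = _mutate(trng, chain.sequence, cfg.template_identity)
                logodds, wop = prof.logodds.copy(), prof.wop.copy()
                for i in np.flatnonzero(mut):
                    p = trng.dirichlet(
                        cfg.profile_concentration * BLOSUM62_BACKGROUND
                    )
                    wop[i] = _integer_wop(p)
                    smooth = (wop[i] + 1.0) / (wop[i].sum() + 20.0)
                    logodds[i] = np.clip(
                        np.round(2.0 * np.log2(smooth / BLOSUM62_BACKGROUND)),
                        -9, 9,
                    )
                tprof = SequenceProfile(tseq, logodds, wop)
            library.entries[tid] = TemplateEntry(
                tseq, np.asarray(tlabels, bool), tprof
            )
            library_profiles[tid] = tprof

    return SyntheticDataset(
        config=cfg, chains=chains, profiles=profiles,
        struct_tables=struct_tables, pdb_texts=pdb_texts, library=library,
        library_profiles=library_profiles, signal_mask=signal_mask,
        template_mask=template_mask,
    )


def generate_toy_msa(seed: int, length: int, depth: int,
                     conservation_profile: np.ndarray | None = None
                     ) -> tuple[list[str], np.ndarray]:
    """Sample an MSA column-wise and derive its WOP matrix.

    ``conservation_profile`` is an optional (length, 20) matrix of
    per-column emission distributions; columns default to seeded Dirichlet
    draws around the background. The WOP matrix holds unweighted column
    frequencies times 100.
    """
    if depth < 2:
        raise ValueError("depth must be at least 2")
    rng = np.random.default_rng(seed)
    if conservation_profile is None:
        conservation_profile = rng.dirichlet(
            5.0 * BLOSUM62_BACKGROUND, size=length
        )
    conservation_profile = np.asarray(conservation_profile, float)
    if conservation_profile.shape != (length, 20):
        raise ValueError("conservation_profile must be (length, 20)")
    columns = np.empty((length, depth), dtype="<U1")
    for j in range(length):
        columns[j] = rng.choice(_AA, size=depth, p=conservation_profile[j])
    msa = ["".join(columns[:, d]) for d in range(depth)]
    wop = np.zeros((length, 20))
    for j in range(length):
        for aa in columns[j]:
            wop[j, AA_INDEX[aa]] += 1
    wop = wop / depth * 100.0
    return msa, wop
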
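"""Dataset construction: binding-residue labeling from complex structures,
chain-level quality filters, redundancy removal, and cross-validation folds.

A residue counts as nucleic-acid binding when at least one of its heavy atoms
lies within 4.5 A (inclusive) of any atom of a bound DNA/RNA molecule.
Filters retain X-ray chains better than 3 A resolution, at least 40 residues
long, with at least five binding residues; pairwise sequence identity between
retained chains is capped (default 30%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from scipy.spatial import cKDTree

from .io_formats import DataError, StructureModel, sanitize_sequence


@dataclass
class LabeledChain:
    """A protein chain with per-residue binding labels."""

    id: str
    sequence: str
    labels: np.ndarray  # bool, True = binding
    na_type: str = "DNA"
    source: tuple = ()  # (structure id, chain id, resolution, method)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if len(self.labels) != len(self.sequence):
            raise DataError(f"{self.id}: labels/sequence length mismatch")
        if len(self.sequence) == 0:
            raise DataError(f"{self.id}: empty chain")

    @property
    def n_binding(self) -> int:
        return int(self.labels.sum())


@dataclass
class DatasetFilterConfig:
    min_length: int = 40
    min_binding: int = 5
    max_resolution: float = 3.0
    distance_cutoff: float = 4.5
    identity_threshold: float = 30.0

    def __post_init__(self) -> None:
        for name in ("min_length", "min_binding", "max_resolution",
                     "distance_cutoff", "identity_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class CvFolds:
    k: int
    assignment: dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [cid for cid, f in self.assignment.items() if f == fold]

    def split(self, fold: int) -> tuple[list[str], list[str]]:
        """Return (train ids, test ids) for one CV run."""
        test = self.fold_ids(fold)
        train = [cid for cid, f in self.assignment.items() if f != fold]
        return train, test


def label_binding_residues(structure: StructureModel, protein_chain: str,
                           cutoff: float = 4.5) -> np.ndarray:
    """Label each residue of a protein chain by proximity to nucleic atoms.

    Binding iff the minimum heavy-atom distance to any atom of any nucleic
    chain is <= cutoff (the inclusive reading of "within").
    """
    chain = structure.chain(protein_chain)
    if chain.polymer_type != "protein":
        raise DataError(f"chain {protein_chain!r} is not a protein chain")
    nucleic = structure.nucleic_chains
    if not nucleic:
        raise DataError("structure contains no nucleic-acid chain")
    na_atoms = np.vstack([r.heavy_atoms for ch in nucleic for r in ch.residues])
    tree = cKDTree(na_atoms)
    labels = np.zeros(len(chain.residues), dtype=bool)
    for i, res in enumerate(chain.residues):
        dmin = tree.query(res.heavy_atoms, k=1)[0].min()
        labels[i] = dmin <= cutoff
    return labels


def chain_from_structure(structure: StructureModel, chain_id: str,
                         na_type: str = "DNA",
                         cutoff: float = 4.5) -> LabeledChain:
    ch = structure.chain(chain_id)
    return LabeledChain(
        id=f"{structure.structure_id}_{chain_id}",
        sequence=sanitize_sequence(ch.sequence()),
        labels=label_binding_residues(structure, chain_id, cutoff),
        na_type=na_type,
        source=(structure.structure_id, chain_id, structure.resolution,
                structure.method),
    )


def filter_chain(chain: LabeledChain,
                 cfg: DatasetFilterConfig = DatasetFilterConfig()) -> tuple[bool, str]:
    """Apply chain-level dataset filters; returns (accept, reason).

    Rules check in order: experimental method, resolution (strictly better
    than the maximum), length, binding-residue count. The reason names the
    first rule that failed, or "ok".
    """
    _, _, resolution, method = (chain.source + (None, None, None, None))[:4]
    if method is not None and "X-RAY" not in str(method).upper():
        return False, "method"
    if resolution is None:
        return False, "no-resolution"
    if not resolution < cfg.max_resolution:
        return False, "resolution"
    if len(chain.sequence) < cfg.min_length:
        return False, "length"
    if chain.n_binding < cfg.min_binding:
        return False, "min-binding"
    return True, "ok"


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str, denominator: str = "alignment") -> float:
    """Global-alignment sequence identity in percent.

    Alignment scoring: match +1, mismatch 0, affine gaps (open -10,
    extend -0.5). ``denominator`` selects the identity convention:
    "alignment" divides identical pairs by the alignment length (gap columns
    included), "shorter" by the shorter sequence length.
    """
    if not a or not b:
        raise DataError("cannot align empty sequences")
    aln = _aligner().align(a, b)[0]
    identities = aln.counts().identities
    if denominator == "alignment":
        denom = aln.length
    elif denominator == "shorter":
        denom = min(len(a), len(b))
    else:
        raise ValueError(f"unknown identity denominator {denominator!r}")
    return 100.0 * identities / denom


def remove_redundancy(chains: list[LabeledChain], threshold: float = 30.0,
                      reference: list[LabeledChain] | None = None,
                      denominator: str = "alignment") -> list[LabeledChain]:
    """Greedy redundancy reduction preserving input order.

    A chain is dropped iff its identity with any already-kept chain (or any
    chain of an external reference set) exceeds the threshold.
    """
    kept: list[LabeledChain] = []
    ref_seqs = [c.sequence for c in (reference or [])]
    for chain in chains:
        others = ref_seqs + [c.sequence for c in kept]
        if any(pairwise_identity(chain.sequence, s, denominator) > threshold
               for s in others):
            continue
        kept.append(chain)
    return kept


def make_cv_folds(chains: list[LabeledChain], k: int = 5, seed: int = 0) -> CvFolds:
    """Seeded shuffle + round-robin assignment of chains to k folds."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(chains):
        raise ValueError(f"k={k} exceeds the number of chains ({len(chains)})")
    ids = [c.id for c in chains]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate chain ids in dataset")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[j]: i % k for i, j in enumerate(order)}
    return CvFolds(k=k, assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# Dataset TSV serialization
# ---------------------------------------------------------------------------

def write_dataset(chains: list[LabeledChain], path: str | Path) -> None:
    rows = []
    for c in chains:
        sid, cid, res, method = (c.source + (None, None, None, None))[:4]
        rows.append({
            "chain_id": c.id,
            "sequence": c.sequence,
            "labels": "".join("1" if x else "0" for x in c.labels),
            "na_type": c.na_type,
            "structure_id": sid if sid is not None else "NA",
            "structure_chain": cid if cid is not None else "NA",
            "resolution": res if res is not None else "NA",
            "method": method if method is not None else "NA",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_dataset(path: str | Path) -> list[LabeledChain]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    chains = []
    for _, row in df.iterrows():
        labels = np.array([ch == "1" for ch in row["labels"]])
        res = None if row["resolution"] in ("NA", "") else float(row["resolution"])
        method = None if row["method"] in ("NA", "") else row["method"]
        chains.append(LabeledChain(
            id=row["chain_id"], sequence=row["sequence"], labels=labels,
            na_type=row["na_type"],
            source=(row["structure_id"], row["structure_chain"], res, method),
        ))
    if not chains:
        raise DataError(f"{path}: empty dataset")
    return chains
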
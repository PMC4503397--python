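"""Readers and writers for the external file formats the pipeline touches.

Covers FASTA sequences, PSI-BLAST ASCII profile matrices, HHR-style
profile-alignment reports, PDB coordinate files, per-residue predicted
structure tables, and the prediction TSV emitted by the hybrid predictor.

Internal indices are 0-based half-open everywhere; the files themselves use
their native 1-based conventions.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser

from .constants import AA_ORDER, NUCLEIC_RESNAMES, PROTEIN_3TO1, UNKNOWN_AA


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class DataError(ValueError):
    """Well-formed input whose content violates a pipeline contract."""


_CANONICAL = set(AA_ORDER)


def sanitize_sequence(seq: str) -> str:
    """Upper-case and map any non-canonical letter to 'X'."""
    return "".join(c if c in _CANONICAL else UNKNOWN_AA for c in seq.upper())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into sanitized records.

    Sequences are upper-cased; letters outside the 20-residue alphabet are
    mapped to 'X'. Duplicate identifiers and empty files are format errors.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty id")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = sanitize_sequence(str(rec.seq))
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

@dataclass
class SequenceProfile:
    """Log-odds matrix plus weighted observed percentages for one chain.

    ``logodds`` holds the raw PSSM elements (symbol x in the logistic
    normalisation), ``wop`` the weighted observed percentages; each WOP row
    sums to ~100 except for gap-dominated columns, which PSI-BLAST emits as
    all-zero and which are retained as such.
    """

    sequence: str
    logodds: np.ndarray
    wop: np.ndarray
    alphabet: str = AA_ORDER

    def __post_init__(self) -> None:
        self.logodds = np.asarray(self.logodds, dtype=float)
        self.wop = np.asarray(self.wop, dtype=float)
        if self.logodds.shape != self.wop.shape:
            raise DataError("log-odds and WOP matrices differ in shape")
        if self.logodds.shape != (len(self.sequence), 20):
            raise DataError("profile matrices must be length x 20")
        if np.any(self.wop < 0) or np.any(self.wop > 100):
            raise DataError("WOP entries must lie in [0, 100]")

    @property
    def length(self) -> int:
        return len(self.sequence)


_PSSM_HEADER_RE = re.compile(r"^\s*((?:[A-Z]\s+){39}[A-Z])\s*$")


def read_psiblast_pssm(path: str | Path) -> SequenceProfile:
    """Parse the classic PSI-BLAST ``-Q`` ASCII matrix.

    Each residue row carries 20 log-odds integers followed by 20 weighted
    observed percentages (two trailing per-row statistics are ignored when
    present). The 40-letter column header fixes the alphabet order.
    """
    lines = Path(path).read_text().splitlines()
    header_cols: list[str] | None = None
    seq_chars: list[str] = []
    logodds_rows: list[list[float]] = []
    wop_rows: list[list[float]] = []
    expected_idx = 1
    for line in lines:
        if header_cols is None:
            m = _PSSM_HEADER_RE.match(line)
            if m:
                header_cols = m.group(1).split()
                if "".join(header_cols[:20]) != AA_ORDER or "".join(header_cols[20:]) != AA_ORDER:
                    raise FormatError(f"{path}: unexpected PSSM column alphabet")
            continue
        parts = line.split()
        if len(parts) < 2 or not parts[0].isdigit():
            continue
        idx = int(parts[0])
        if idx != expected_idx:
            raise FormatError(f"{path}: residue rows out of order at {idx}")
        expected_idx += 1
        aa = parts[1]
        fields = parts[2:]
        if len(fields) not in (40, 42):
            raise FormatError(
                f"{path}: row {idx} has {len(fields)} numeric fields, expected 40"
            )
        try:
            values = [float(v) for v in fields[:40]]
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric field in row {idx}") from exc
        seq_chars.append(aa if aa in _CANONICAL else UNKNOWN_AA)
        logodds_rows.append(values[:20])
        wop_rows.append(values[20:40])
    if header_cols is None:
        raise FormatError(f"{path}: no PSSM column header found")
    if not seq_chars:
        raise FormatError(f"{path}: no residue rows found")
    return SequenceProfile(
        "".join(seq_chars), np.array(logodds_rows), np.array(wop_rows)
    )


def write_psiblast_pssm(profile: SequenceProfile, path: str | Path) -> None:
    """Write a profile back out in the PSI-BLAST ASCII layout (integer cells)."""
    with open(path, "w") as fh:
        fh.write(
            "\nLast position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, and "
            "relative weight of gapless real matches to pseudocounts\n"
        )
        fh.write("          " + "  ".join(AA_ORDER) + "   " + "  ".join(AA_ORDER) + "\n")
        for i in range(profile.length):
            lo = " ".join(f"{int(round(v)):3d}" for v in profile.logodds[i])
            wo = " ".join(f"{int(round(v)):3d}" for v in profile.wop[i])
            fh.write(f"{i + 1:5d} {profile.sequence[i]} {lo}  {wo}\n")


# ---------------------------------------------------------------------------
# HHR alignment reports
# ---------------------------------------------------------------------------

@dataclass
class TemplateHit:
    """One query-template alignment from a profile-profile search.

    ``mapping`` pairs 0-based query residue indices with 0-based template
    residue indices over matched (gap-free) alignment columns and is strictly
    increasing in both coordinates.
    """

    template_id: str
    hhscore: float
    mapping: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.hhscore <= 100.0:
            raise DataError(f"hhscore {self.hhscore} outside [0, 100]")
        prev_q, prev_t = -1, -1
        for q in sorted(self.mapping):
            t = self.mapping[q]
            if q <= prev_q or t <= prev_t:
                raise DataError("alignment mapping is not strictly increasing")
            prev_q, prev_t = q, t


@dataclass
class AlignmentReport:
    query_id: str
    hits: list[TemplateHit]


def _pair_alignment(qstart: int, qseq: str, tstart: int, tseq: str,
                    qend: int, tend: int, mapping: dict[int, int], path) -> None:
    if len(qseq) != len(tseq):
        raise FormatError(f"{path}: query/template alignment rows differ in length")
    q, t = qstart - 1, tstart - 1
    for qc, tc in zip(qseq, tseq):
        q_gap, t_gap = qc == "-", tc == "-"
        if not q_gap and not t_gap:
            mapping[q] = t
        if not q_gap:
            q += 1
        if not t_gap:
            t += 1
    if q != qend or t != tend:
        raise FormatError(f"{path}: residue numbering does not advance consistently")


def read_hhr(path: str | Path) -> AlignmentReport:
    """Parse an HHR-style report: probability-scored hits plus alignments."""
    lines = Path(path).read_text().splitlines()
    query_id: str | None = None
    hits: list[TemplateHit] = []
    cur_id: str | None = None
    cur_prob: float | None = None
    cur_map: dict[int, int] = {}
    pending_q: tuple[int, str, int] | None = None

    def flush() -> None:
        nonlocal cur_id, cur_prob, cur_map, pending_q
        if cur_id is not None:
            if cur_prob is None:
                raise FormatError(f"{path}: hit {cur_id} lacks a Probab score")
            hits.append(TemplateHit(cur_id, cur_prob, dict(cur_map)))
        cur_id, cur_prob, cur_map, pending_q = None, None, {}, None

    for line in lines:
        if line.startswith("Query"):
            parts = line.split()
            if len(parts) >= 2 and query_id is None:
                query_id = parts[1]
        elif re.match(r"^No\s+\d+", line):
            flush()
        elif line.startswith(">"):
            cur_id = line[1:].split()[0]
        elif line.startswith("Probab="):
            cur_prob = float(line.split()[0].split("=", 1)[1])
        elif line.startswith("Q ") and cur_id is not None:
            parts = line.split()
            if len(parts) >= 5 and parts[1] == query_id:
                pending_q = (int(parts[2]), parts[3], int(parts[4]))
        elif line.startswith("T ") and cur_id is not None:
            parts = line.split()
            if len(parts) >= 5 and parts[1] == cur_id:
                if pending_q is None:
                    raise FormatError(f"{path}: template row without query row")
                qs, qseq, qe = pending_q
                _pair_alignment(qs, qseq, int(parts[2]), parts[3], qe,
                                int(parts[4]), cur_map, path)
                pending_q = None
    flush()
    if query_id is None:
        raise FormatError(f"{path}: no Query line found")
    return AlignmentReport(query_id, hits)


def write_hhr(report: AlignmentReport, query_sequence: str,
              template_sequences: dict[str, str], path: str | Path) -> None:
    """Write an HHR-style report (the dialect :func:`read_hhr` accepts)."""
    with open(path, "w") as fh:
        fh.write(f"Query         {report.query_id}\n")
        fh.write(f"Match_columns {len(query_sequence)}\n\n")
        fh.write(" No Hit                             Prob\n")
        for i, hit in enumerate(report.hits, start=1):
            fh.write(f"{i:3d} {hit.template_id:<30s} {hit.hhscore:5.1f}\n")
        for i, hit in enumerate(report.hits, start=1):
            fh.write(f"\nNo {i}\n>{hit.template_id}\n")
            fh.write(f"Probab={hit.hhscore:.2f}\n")
            if not hit.mapping:
                continue
            tseq_full = template_sequences[hit.template_id]
            qcols, tcols = [], []
            pairs = sorted(hit.mapping.items())
            pq, pt = pairs[0]
            for q, t in pairs:
                while pq < q:
                    qcols.append(query_sequence[pq]); tcols.append("-"); pq += 1
                while pt < t:
                    qcols.append("-"); tcols.append(tseq_full[pt]); pt += 1
                qcols.append(query_sequence[q]); tcols.append(tseq_full[t])
                pq, pt = q + 1, t + 1
            qstart, tstart = pairs[0][0] + 1, pairs[0][1] + 1
            qend, tend = pairs[-1][0] + 1, pairs[-1][1] + 1
            fh.write(f"Q {report.query_id}  {qstart} {''.join(qcols)} {qend}\n")
            fh.write(f"T {hit.template_id}  {tstart} {''.join(tcols)} {tend}\n")


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

@dataclass
class StructureResidue:
    number: int
    insertion_code: str
    name: str
    heavy_atoms: np.ndarray  # (n_atoms, 3) in Angstrom


@dataclass
class StructureChain:
    chain_id: str
    polymer_type: str  # "protein" | "nucleic"
    residues: list[StructureResidue]

    def sequence(self) -> str:
        if self.polymer_type != "protein":
            raise DataError("sequence() is defined for protein chains only")
        return "".join(
            PROTEIN_3TO1.get(r.name, UNKNOWN_AA) for r in self.residues
        )


@dataclass
class StructureModel:
    structure_id: str
    chains: list[StructureChain]
    resolution: float | None
    method: str | None

    def chain(self, chain_id: str) -> StructureChain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise DataError(f"chain {chain_id!r} not present")

    @property
    def protein_chains(self) -> list[StructureChain]:
        return [c for c in self.chains if c.polymer_type == "protein"]

    @property
    def nucleic_chains(self) -> list[StructureChain]:
        return [c for c in self.chains if c.polymer_type == "nucleic"]


def _classify_residues(resnames: set[str]) -> str:
    nucleic = len(resnames & NUCLEIC_RESNAMES)
    return "nucleic" if nucleic > len(resnames) / 2 else "protein"


def read_structure(path: str | Path) -> StructureModel:
    """Parse a PDB coordinate file into protein / nucleic chains.

    Hydrogens are discarded; alternate locations resolve to the
    highest-occupancy conformer. Chains are classified as nucleic when the
    majority of residue names belong to the standard nucleotide vocabulary.
    """
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(Path(path).stem, str(path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise FormatError(f"{path}: unparseable PDB file: {exc}") from exc
    header = structure.header or {}
    resolution = header.get("resolution")
    method = header.get("structure_method") or None
    if method is not None:
        method = method.strip().upper() or None

    model = next(iter(structure), None)
    if model is None:
        raise FormatError(f"{path}: no coordinate model found")
    chains: list[StructureChain] = []
    for chain in model:
        residues: list[StructureResidue] = []
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            if hetflag.strip():  # waters / ligands are not polymer residues
                continue
            coords = []
            for atom in res:
                if atom.element == "H":
                    continue
                coords.append(atom.get_coord())
            if not coords:
                continue
            arr = np.asarray(coords, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise FormatError(f"{path}: non-finite coordinates in {chain.id}")
            residues.append(
                StructureResidue(resseq, icode.strip(), res.get_resname().strip(), arr)
            )
        if not residues:
            continue
        ptype = _classify_residues({r.name for r in residues})
        chains.append(StructureChain(chain.id, ptype, residues))
    if not any(c.polymer_type == "protein" for c in chains):
        raise DataError(f"{path}: no protein chain found")
    return StructureModel(Path(path).stem, chains, resolution, method)


# ---------------------------------------------------------------------------
# Per-residue predicted-structure tables
# ---------------------------------------------------------------------------

STRUCT_TABLE_COLUMNS = ["position", "ss", "rsa_raw", "phi", "psi", "disorder"]


def read_structure_table(path: str | Path) -> pd.DataFrame:
    """Read the per-residue predicted-structure TSV (one row per residue)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in STRUCT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if not (df["position"].to_numpy() == np.arange(1, len(df) + 1)).all():
        raise FormatError(f"{path}: positions must run 1..L without gaps")
    return df


def write_structure_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Prediction TSV
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = [
    "chain_id", "position", "residue", "Fscore", "Tscore",
    "HHscore_used", "Cscore", "call",
]


def write_predictions(results: Sequence["PredictionResult"], path: str | Path) -> None:
    """Serialize per-residue predictions as a round-trippable TSV.

    Chains without a template carry "NA" in the Tscore / HHscore_used
    columns, distinguishing "no template found" from a template that calls a
    residue non-binding (Tscore 0).
    """
    if not results:
        raise DataError("no prediction results to write")
    with open(path, "w") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for res in results:
            for i in range(len(res.fscores)):
                t = "NA" if res.tscores is None else f"{res.tscores[i]:.6f}"
                hh = "NA" if res.hhscore_used is None else f"{res.hhscore_used:.6f}"
                fh.write(
                    f"{res.chain_id}\t{i + 1}\t{res.residues[i]}\t"
                    f"{res.fscores[i]:.6f}\t{t}\t{hh}\t"
                    f"{res.cscores[i]:.6f}\t{int(res.calls[i])}\n"
                )


def read_predictions(path: str | Path) -> list["PredictionResult"]:
    from .hybrid import PredictionResult  # deferred: avoids an import cycle

    df = pd.read_csv(path, sep="\t", dtype={"chain_id": str}, na_values=["NA"])
    if list(df.columns) != PREDICTION_COLUMNS:
        raise FormatError(f"{path}: unexpected prediction columns {list(df.columns)}")
    out = []
    for cid, grp in df.groupby("chain_id", sort=False):
        grp = grp.sort_values("position")
        tvals = grp["Tscore"].to_numpy(float)
        hh = grp["HHscore_used"].to_numpy(float)
        no_template = np.all(np.isnan(tvals))
        out.append(
            PredictionResult(
                chain_id=str(cid),
                residues="".join(grp["residue"]),
                fscores=grp["Fscore"].to_numpy(float),
                tscores=None if no_template else tvals,
                hhscore_used=None if no_template else float(hh[0]),
                cscores=grp["Cscore"].to_numpy(float),
                calls=grp["call"].to_numpy(int).astype(bool),
            )
        )
    if not out:
        raise FormatError(f"{path}: empty prediction table")
    return out
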
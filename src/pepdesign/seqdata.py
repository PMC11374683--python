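"""Sequence and potency data handling.

Aligned peptide records (fixed width 30 over the 20 amino acids plus the
alignment gap symbol), one-hot encoding, mutant enumeration, Hamming
distances, EC50 unit conversions and activity-region classification.

Potencies are handled internally in log10 molar units and displayed in pM.
A measurement recorded only as exceeding an assay ceiling (e.g.
``">10,000"`` pM) is stored at a configurable ceiling value with a
``censored`` flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Alignment width used throughout: 29/30-residue agonists right-padded
# with gaps to a common frame.
WIDTH = 30

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP  # 21 symbols; gap is index 20
SYMBOL_INDEX = {s: i for i, s in enumerate(ALPHABET)}

RECEPTORS = ("GCGR", "GLP1R")

# Reference agonists. Human glucagon is a 29-mer (one trailing alignment
# gap in the 30-wide frame); human GLP-1(7-36) is a 30-mer.
HUMAN_GLUCAGON = "HSQGTFTSDYSKYLDSRRAQDFVQWLMNT"
HUMAN_GLP1 = "HAEGTFTSDVSSYLEGQAAKEFIAWLVKGR"

# Default assay ceiling: 10,000 pM == log10(1e-8 M) == -8.
DEFAULT_CEILING = -8.0
# Potency threshold separating "potent" from "not potent" at a receptor:
# log10 EC50 of -11, i.e. 10 pM, within tenfold of the native ligands.
DEFAULT_THRESHOLD = -11.0


class ParseError(ValueError):
    """Raised for malformed sequence or potency input."""


class ActivityRegion(Enum):
    DUAL = "dual"
    GCGR_SELECTIVE = "gcgr_selective"
    GLP1R_SELECTIVE = "glp1r_selective"
    INACTIVE = "inactive"


@dataclass(frozen=True)
class AlignedPeptide:
    """A peptide in the fixed-width alignment frame."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("peptide id must be non-empty")
        if len(self.residues) != WIDTH:
            raise ParseError(
                f"peptide {self.id!r}: length {len(self.residues)} != {WIDTH}"
            )
        for pos, sym in enumerate(self.residues, start=1):
            if sym not in SYMBOL_INDEX:
                raise ParseError(
                    f"peptide {self.id!r}: invalid symbol {sym!r} at position {pos}"
                )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return WIDTH


@dataclass(frozen=True)
class PotencyRecord:
    """Measured log10-molar EC50 pair with per-receptor censoring flags."""

    peptide_id: str
    log_ec50: tuple[float, float]  # (GCGR, GLP1R)
    censored: tuple[bool, bool] = (False, False)

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.log_ec50)):
            raise ValueError(f"record {self.peptide_id!r}: non-finite potency")


@dataclass(frozen=True)
class OneHotMatrix:
    """Binary 21 x W indicator matrix of a peptide; column b is position b."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(ALPHABET), WIDTH):
            raise ValueError(f"expected shape (21, {WIDTH})")

    @property
    def flat(self) -> np.ndarray:
        """Position-major flattened view of length 21*W = 630."""
        return self.values.flatten(order="F")


@dataclass
class Dataset:
    """Aligned peptides with paired potency records (index-aligned)."""

    peptides: list[AlignedPeptide]
    records: list[PotencyRecord]

    def __post_init__(self) -> None:
        if len(self.peptides) != len(self.records):
            raise ValueError("peptides and records differ in length")
        for p, r in zip(self.peptides, self.records):
            if p.id != r.peptide_id:
                raise ValueError(f"id mismatch: {p.id!r} vs {r.peptide_id!r}")

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    @property
    def sequences(self) -> list[str]:
        return [p.residues for p in self.peptides]

    def labels(self) -> np.ndarray:
        return np.array([r.log_ec50 for r in self.records], dtype=float)

    def censored(self) -> np.ndarray:
        return np.array([r.censored for r in self.records], dtype=bool)

    def subset(self, idx: Sequence[int]) -> "Dataset":
        return Dataset(
            [self.peptides[i] for i in idx], [self.records[i] for i in idx]
        )


# ---------------------------------------------------------------------------
# I/O


def _normalize_width(seq: str, rec_id: str) -> str:
    if len(seq) > WIDTH:
        raise ParseError(f"record {rec_id!r}: length {len(seq)} exceeds {WIDTH}")
    return seq + GAP * (WIDTH - len(seq))


def read_fasta(path: str | Path) -> list[AlignedPeptide]:
    """Read aligned (or plain 29/30-residue) peptides from FASTA.

    Sequences shorter than the alignment width are right-padded with gaps;
    longer sequences are rejected. Ids must be unique.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    peptides: list[AlignedPeptide] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _normalize_width(str(rec.seq).upper(), rec.id)
        peptides.append(AlignedPeptide(rec.id, seq))
    if not peptides:
        raise ParseError(f"no FASTA records in {path}")
    return peptides


def write_fasta(peptides: Iterable[AlignedPeptide], path: str | Path) -> None:
    recs = [SeqRecord(Seq(p.residues), id=p.id, description="") for p in peptides]
    SeqIO.write(recs, str(path), "fasta")


_CENSOR_RE = re.compile(r"^>\s*([\d,._eE+-]+)$")


def _parse_potency(raw: object, units: str, ceiling: float) -> tuple[float, bool]:
    text = str(raw).strip()
    m = _CENSOR_RE.match(text)
    if m is not None:
        return float(ceiling), True
    try:
        value = float(text.replace(",", ""))
    except ValueError:
        raise ParseError(f"unparseable potency value {text!r}") from None
    if units == "pM":
        return pm_to_log_molar(value), False
    return value, False


def read_potency_table(
    path: str | Path,
    units: str = "pM",
    ceiling: float = DEFAULT_CEILING,
) -> list[PotencyRecord]:
    """Read a delimited potency table (columns: id, sequence, ec50_gcgr,
    ec50_glp1r). pM values are converted to log10 molar; ``">X"`` entries
    are censored at ``ceiling``."""
    if units not in ("pM", "log10M"):
        raise ValueError(f"units must be 'pM' or 'log10M', got {units!r}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"id", "ec50_gcgr", "ec50_glp1r"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"potency table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        g, cg = _parse_potency(row["ec50_gcgr"], units, ceiling)
        l, cl = _parse_potency(row["ec50_glp1r"], units, ceiling)
        records.append(PotencyRecord(str(row["id"]), (g, l), (cg, cl)))
    ids = [r.peptide_id for r in records]
    if len(set(ids)) != len(ids):
        raise ParseError("duplicate ids in potency table")
    return records


def load_dataset(
    fasta_path: str | Path,
    table_path: str | Path,
    units: str = "pM",
    ceiling: float = DEFAULT_CEILING,
) -> Dataset:
    """Load and cross-validate a FASTA + potency-table pair by id."""
    peptides = read_fasta(fasta_path)
    records = read_potency_table(table_path, units=units, ceiling=ceiling)
    by_id = {r.peptide_id: r for r in records}
    missing = [p.id for p in peptides if p.id not in by_id]
    if missing:
        raise ParseError(f"ids in FASTA without potency rows: {missing[:5]}")
    return Dataset(peptides, [by_id[p.id] for p in peptides])


def write_potency_table(dataset: Dataset, path: str | Path) -> None:
    """Emit the potency table in pM with ``>`` marking censored entries."""
    rows = []
    for p, r in zip(dataset.peptides, dataset.records):
        cells = []
        for k in range(2):
            pm = log_molar_to_pm(r.log_ec50[k])
            cells.append(f">{pm:.6g}" if r.censored[k] else f"{pm:.6g}")
        rows.append((p.id, p.residues, cells[0], cells[1]))
    pd.DataFrame(
        rows, columns=["id", "sequence", "ec50_gcgr", "ec50_glp1r"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# One-hot codec


def encode_onehot(p: AlignedPeptide) -> OneHotMatrix:
    """Encode as a binary 21 x W matrix S with S[a, b] = 1 iff symbol a
    occupies position b."""
    m = np.zeros((len(ALPHABET), WIDTH), dtype=np.int8)
    for b, sym in enumerate(p.residues):
        m[SYMBOL_INDEX[sym], b] = 1
    return OneHotMatrix(m)


def decode_onehot(m: OneHotMatrix | np.ndarray, id: str = "decoded") -> AlignedPeptide:
    values = m.values if isinstance(m, OneHotMatrix) else np.asarray(m)
    if values.ndim == 1:
        values = values.reshape(WIDTH, len(ALPHABET)).T
    residues = "".join(ALPHABET[int(a)] for a in values.argmax(axis=0))
    return AlignedPeptide(id, residues)


def encode_batch(peptides: Sequence[AlignedPeptide | str]) -> np.ndarray:
    """One-hot encode a batch as (n, W, 21) float32, the layout consumed by
    1-D convolution (positions x channels)."""
    out = np.zeros((len(peptides), WIDTH, len(ALPHABET)), dtype=np.float32)
    for i, p in enumerate(peptides):
        seq = p.residues if isinstance(p, AlignedPeptide) else p
        for b, sym in enumerate(seq):
            out[i, b, SYMBOL_INDEX[sym]] = 1.0
    return out


def onehot_features(peptides: Sequence[AlignedPeptide | str]) -> np.ndarray:
    """Flattened 630-dimensional one-hot features for non-convolutional
    models (position-major, matching OneHotMatrix.flat)."""
    return encode_batch(peptides).reshape(len(peptides), -1)


def features_to_sequence(v: np.ndarray) -> str:
    """Invert :func:`onehot_features` for a single 630-vector."""
    m = np.asarray(v).reshape(WIDTH, len(ALPHABET))
    return "".join(ALPHABET[int(a)] for a in m.argmax(axis=1))


# ---------------------------------------------------------------------------
# Sequence arithmetic


def hamming_distance(
    a: AlignedPeptide | str, b: AlignedPeptide | str, mode: str = "substitutions"
) -> int:
    """Point-mutation distance between equal-width aligned sequences.

    mode="substitutions" (default) counts mismatches only over positions
    where neither sequence is gapped; mode="full" counts every differing
    position, including gap openings/fills.
    """
    sa = a.residues if isinstance(a, AlignedPeptide) else a
    sb = b.residues if isinstance(b, AlignedPeptide) else b
    if len(sa) != len(sb):
        raise ValueError(f"width mismatch: {len(sa)} vs {len(sb)}")
    if mode == "substitutions":
        return sum(
            1 for x, y in zip(sa, sb) if x != y and x != GAP and y != GAP
        )
    if mode == "full":
        return sum(1 for x, y in zip(sa, sb) if x != y)
    raise ValueError(f"unknown mode {mode!r}")


def enumerate_single_mutants(
    p: AlignedPeptide, fill_gaps: bool = False
) -> list[AlignedPeptide]:
    """All single-substitution variants of ``p``.

    Every non-gap position is substituted to each of the other 19 amino
    acids. With ``fill_gaps=True``, gap positions are additionally filled
    with each of the 20 amino acids. The parent is never included.
    """
    mutants: list[AlignedPeptide] = []
    residues = p.residues
    for pos, sym in enumerate(residues):
        if sym == GAP:
            if not fill_gaps:
                continue
            choices = AMINO_ACIDS
        else:
            choices = [a for a in AMINO_ACIDS if a != sym]
        for aa in choices:
            seq = residues[:pos] + aa + residues[pos + 1:]
            mutants.append(AlignedPeptide(f"{p.id}|{sym}{pos + 1}{aa}", seq))
    return mutants


def strip_gaps(seq: str) -> str:
    return seq.replace(GAP, "")


# ---------------------------------------------------------------------------
# Units and activity regions


def pm_to_log_molar(pm: float) -> float:
    """EC50 in pM -> log10 molar. 10 pM -> -11."""
    if not np.isfinite(pm) or pm <= 0:
        raise ValueError(f"EC50 in pM must be positive and finite, got {pm}")
    return float(np.log10(pm) - 12.0)


def log_molar_to_pm(x: float) -> float:
    """log10 molar EC50 -> pM. -11 -> 10 pM."""
    if not np.isfinite(x):
        raise ValueError(f"log10 EC50 must be finite, got {x}")
    return float(10.0 ** (x + 12.0))


def classify_activity_region(
    r: PotencyRecord | tuple[float, float], threshold: float = DEFAULT_THRESHOLD
) -> ActivityRegion:
    """Assign one of the four activity regions.

    A receptor counts as potently activated when log10 EC50 is strictly
    below the threshold (default -11, i.e. 10 pM)."""
    g, l = r.log_ec50 if isinstance(r, PotencyRecord) else r
    potent_g = g < threshold
    potent_l = l < threshold
    if potent_g and potent_l:
        return ActivityRegion.DUAL
    if potent_g:
        return ActivityRegion.GCGR_SELECTIVE
    if potent_l:
        return ActivityRegion.GLP1R_SELECTIVE
    return ActivityRegion.INACTIVE
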
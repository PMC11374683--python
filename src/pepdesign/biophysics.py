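"""Sequence-derived biophysical properties and the one-standard-deviation
group filter.

Six classical properties rank design candidates against the training-set
peptides sharing their target activity profile: isoelectric point, GRAVY
(grand average of Kyte-Doolittle hydropathy), instability index
(Guruprasad dipeptide weights), aromaticity (F/W/Y fraction), molar
extinction coefficient (Gill-von Hippel composition rule) and average
molecular weight. The underlying scales and pKa constants come from
Biopython's ProtParam module (Bjellqvist-style pKa set).

All calculators expect ungapped amino-acid strings; strip alignment gaps
first (``seqdata.strip_gaps``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from . import seqdata
from .seqdata import ActivityRegion, Dataset, classify_activity_region

PROPERTY_NAMES = (
    "isoelectric_point", "gravy", "instability_index",
    "aromaticity", "extinction_coefficient", "molecular_weight",
)


def _check(seq: str, min_len: int = 1) -> str:
    if seqdata.GAP in seq:
        raise ValueError("sequence contains alignment gaps; strip them first")
    if len(seq) < min_len:
        raise ValueError(f"sequence must have at least {min_len} residues")
    bad = set(seq) - set(seqdata.AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    return seq


def gravy(seq: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    return float(ProteinAnalysis(_check(seq)).gravy())


def aromaticity(seq: str) -> float:
    """Fraction of residues in {F, W, Y}."""
    return float(ProteinAnalysis(_check(seq)).aromaticity())


def extinction_coefficient(seq: str, cystine_assumed: bool = False) -> int:
    """Molar extinction coefficient at 280 nm (M^-1 cm^-1):
    5500 per Trp + 1490 per Tyr + 125 per cystine bridge (if half-cystines
    are assumed oxidized)."""
    seq = _check(seq)
    value = 5500 * seq.count("W") + 1490 * seq.count("Y")
    if cystine_assumed:
        value += 125 * (seq.count("C") // 2)
    return int(value)


def instability_index(seq: str) -> float:
    """Guruprasad instability index: (10/L) * sum of dipeptide instability
    weights over consecutive residue pairs."""
    seq = _check(seq, min_len=2)
    return float(ProteinAnalysis(seq).instability_index())


def isoelectric_point(seq: str) -> float:
    """pH at which the Henderson-Hasselbalch net charge over the termini
    and the D/E/C/Y/K/R/H side chains vanishes.

    Bisection runs over the full 0-14 pH range (the ProtParam default
    window clips strongly acidic or basic peptides)."""
    from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
    return float(IsoelectricPoint(_check(seq)).pi(pH=7.0, min_=0.0, max_=14.0))


def charge_at_pH(seq: str, pH: float) -> float:
    """Net charge of the peptide at the given pH (same model as the pI)."""
    return float(ProteinAnalysis(_check(seq)).charge_at_pH(pH))


def molecular_weight(seq: str) -> float:
    """Average molecular mass in Da (residue masses plus one water)."""
    return float(ProteinAnalysis(_check(seq)).molecular_weight())


@dataclass(frozen=True)
class PropertyProfile:
    isoelectric_point: float
    gravy: float
    instability_index: float
    aromaticity: float
    extinction_coefficient: float
    molecular_weight: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PROPERTY_NAMES], float)


def property_profile(seq: str, cystine_assumed: bool = False) -> PropertyProfile:
    """All six properties of an ungapped sequence."""
    seq = _check(seq, min_len=2)
    return PropertyProfile(
        isoelectric_point=isoelectric_point(seq),
        gravy=gravy(seq),
        instability_index=instability_index(seq),
        aromaticity=aromaticity(seq),
        extinction_coefficient=float(
            extinction_coefficient(seq, cystine_assumed)),
        molecular_weight=molecular_weight(seq),
    )


def property_table(sequences, ids=None) -> pd.DataFrame:
    """Property profiles for a set of (possibly gapped) sequences."""
    seqs = [s.residues if hasattr(s, "residues") else s for s in sequences]
    if ids is None:
        ids = [s.id if hasattr(s, "id") else f"seq{i}"
               for i, s in enumerate(sequences)]
    rows = [property_profile(seqdata.strip_gaps(s)).as_array() for s in seqs]
    return pd.DataFrame(rows, columns=list(PROPERTY_NAMES), index=ids)


@dataclass(frozen=True)
class GroupStats:
    """Per-property mean and standard deviation over a named peptide group."""

    group: str
    mean: pd.Series
    sd: pd.Series
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group must be non-empty")
        if (self.sd < 0).any():
            raise ValueError("standard deviations must be non-negative")


def compute_group_stats(
    dataset: Dataset, threshold: float = seqdata.DEFAULT_THRESHOLD
) -> dict[ActivityRegion, GroupStats]:
    """Mean/sd of each property within the three active training-set
    groups (dual, GCGR-selective, GLP-1R-selective)."""
    groups: dict[ActivityRegion, list] = {}
    for p, r in zip(dataset.peptides, dataset.records):
        region = classify_activity_region(r, threshold)
        if region is not ActivityRegion.INACTIVE:
            groups.setdefault(region, []).append(p)
    stats = {}
    for region, peptides in groups.items():
        table = property_table(peptides)
        stats[region] = GroupStats(
            group=region.value, mean=table.mean(),
            sd=table.std(ddof=0), n=len(table))
    return stats


def group_filter_rank(
    candidates: pd.DataFrame, stats: GroupStats
) -> pd.DataFrame:
    """Rank candidates by how many of the six properties fall within one
    standard deviation of the group mean.

    ``candidates`` is a property table (one row per candidate). Returns the
    table with ``pass_count`` (0..6) and ``z_sum`` columns, sorted by
    descending pass count, ties broken by ascending summed |z|-score. A
    zero-sd property auto-passes only on exact equality (with a warning).
    """
    values = candidates[list(PROPERTY_NAMES)].to_numpy(float)
    mean = stats.mean[list(PROPERTY_NAMES)].to_numpy(float)
    sd = stats.sd[list(PROPERTY_NAMES)].to_numpy(float)
    if (sd == 0).any():
        warnings.warn(
            "zero standard deviation for "
            f"{[n for n, s in zip(PROPERTY_NAMES, sd) if s == 0]}; these "
            "properties pass only on exact equality")
    dev = np.abs(values - mean)
    passes = np.where(sd > 0, dev <= sd, dev == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, dev / sd, np.where(dev == 0, 0.0, np.inf))
    out = candidates.copy()
    out["pass_count"] = passes.sum(axis=1).astype(int)
    out["z_sum"] = z.sum(axis=1)
    return out.sort_values(
        ["pass_count", "z_sum"], ascending=[False, True], kind="mergesort")
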
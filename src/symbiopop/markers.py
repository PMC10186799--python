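"""Marker-ratio test for free-living symbiont populations.

Raw reads are assigned unambiguously to symbiont 16S-like vs host CO1-like
marker databases in the presence of mandatory background decoys (related
non-target sequences that absorb spurious matches instead of letting them
inflate target counts). Assignment is a canonical-k-mer vote with a margin
rule — a deterministic stand-in for BBSplit-style read separation that
gives 'unambiguous' a precise definition: a read goes to category c iff at
least ``min_hit_frac`` of its k-mers hit c AND c has at least ``margin``
times the hits of every other category.

Per sample the report carries the percentage of all reads assigned to each
target marker and their ratio (16S:CO1); ratios orders of magnitude above
the host-associated baseline flag a host-independent symbiont population.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._seqcodes import canonical_kmer_ints, encode
from .errors import ConfigurationError

CATEGORIES = ("target_16S", "target_CO1", "background_16S", "background_CO1")
DEFAULT_K_MARKER = 31


@dataclass
class MarkerDatabase:
    k: int
    index: Dict[int, int]  # canonical k-mer -> category bitmask
    n_sequences: Dict[str, int]

    def categories_of(self, kmer: int) -> int:
        return self.index.get(kmer, 0)


def build_marker_index(
    sequences: Mapping[str, Sequence[Tuple[str, str]]],
    k_marker: int = DEFAULT_K_MARKER,
) -> MarkerDatabase:
    """Index canonical k-mers of all four marker categories.

    All four categories are mandatory — decoys exist precisely to absorb
    false-positive mappings — and every sequence must be at least k long.
    """
    missing = [c for c in CATEGORIES if not sequences.get(c)]
    if missing:
        raise ConfigurationError(f"missing marker categories: {missing}")
    index: Dict[int, int] = {}
    n_seqs = {}
    for ci, cat in enumerate(CATEGORIES):
        bit = 1 << ci
        n_seqs[cat] = len(sequences[cat])
        for name, seq in sequences[cat]:
            codes = encode(seq)
            if codes.size < k_marker:
                raise ConfigurationError(
                    f"{cat}/{name}: sequence shorter than k_marker={k_marker}"
                )
            if (codes > 3).any():
                raise ConfigurationError(f"{cat}/{name}: non-ACGT symbols")
            for km in canonical_kmer_ints(codes, k_marker):
                key = int(km)
                index[key] = index.get(key, 0) | bit
    return MarkerDatabase(k=k_marker, index=index, n_sequences=n_seqs)


@dataclass
class MarkerCounts:
    """Per-category unambiguous read counts plus the conservation tallies."""

    assigned: Dict[str, int] = field(default_factory=lambda: {c: 0 for c in CATEGORIES})
    ambiguous: int = 0
    unassigned: int = 0
    too_short: int = 0
    total: int = 0

    def conservation_holds(self) -> bool:
        return sum(self.assigned.values()) + self.ambiguous + self.unassigned == self.total


def classify_reads(
    reads: Iterable[Tuple[str, str]],
    db: MarkerDatabase,
    min_hit_frac: float = 0.5,
    margin: float = 2.0,
) -> MarkerCounts:
    """Assign each read unambiguously to one category, or not at all.

    Reads shorter than k are tallied ``too_short`` and counted unassigned
    (with a warning); reads with some hits but no category passing both the
    hit-fraction and margin rules are ambiguous.
    """
    out = MarkerCounts()
    k = db.k
    idx = db.index
    for _rid, seq in reads:
        out.total += 1
        codes = encode(seq)
        if codes.size < k or (codes > 3).any():
            out.too_short += 1
            out.unassigned += 1
            continue
        hits = [0, 0, 0, 0]
        n_kmers = codes.size - k + 1
        for km in canonical_kmer_ints(codes, k):
            mask = idx.get(int(km), 0)
            if mask:
                for ci in range(4):
                    if mask >> ci & 1:
                        hits[ci] += 1
        if sum(hits) == 0:
            out.unassigned += 1
            continue
        threshold = min_hit_frac * n_kmers
        winner = None
        for ci in range(4):
            if hits[ci] >= threshold and all(
                hits[ci] >= margin * hits[cj] for cj in range(4) if cj != ci
            ):
                winner = ci
                break
        if winner is None:
            out.ambiguous += 1
        else:
            out.assigned[CATEGORIES[winner]] += 1
    if out.too_short:
        warnings.warn(f"{out.too_short} reads shorter than k_marker={k}; counted unassigned")
    return out


# ---------------------------------------------------------------------------
# Ratio report
# ---------------------------------------------------------------------------


def ratio_from_percentages(pct_16s: float, pct_co1: float) -> Tuple[float, bool]:
    """16S:CO1 ratio directly from printed percentages; (inf, True) when the
    CO1 percentage is zero."""
    if pct_co1 == 0:
        return (math.inf, True)
    return (pct_16s / pct_co1, False)


def marker_ratio(counts: MarkerCounts, total_reads: Optional[int] = None) -> Dict[str, object]:
    """One report row: unambiguous target percentages against ALL reads in
    the sample, and their ratio."""
    total = counts.total if total_reads is None else total_reads
    if total <= 0:
        raise ConfigurationError("total_reads must be > 0")
    pct_16s = 100.0 * counts.assigned["target_16S"] / total
    pct_co1 = 100.0 * counts.assigned["target_CO1"] / total
    ratio, infinite = ratio_from_percentages(pct_16s, pct_co1)
    return {
        "total_reads": total,
        "n_16S": counts.assigned["target_16S"],
        "n_CO1": counts.assigned["target_CO1"],
        "n_background_16S": counts.assigned["background_16S"],
        "n_background_CO1": counts.assigned["background_CO1"],
        "n_ambiguous": counts.ambiguous,
        "n_unassigned": counts.unassigned,
        "pct_16S": pct_16s,
        "pct_CO1": pct_co1,
        "ratio": ratio,
        "ratio_infinite": infinite,
    }


def marker_report(
    rows: Mapping[str, Dict[str, object]],
    origins: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(dict(rows), orient="index")
    df.index.name = "sample_id"
    if origins is not None:
        df["origin"] = [origins.get(s, "unknown") for s in df.index]
    return df


def flag_lifestyle(
    report: pd.DataFrame,
    fold_threshold: float = 10.0,
    absolute_threshold: Optional[float] = None,
    host_origin: str = "host_associated",
) -> pd.Series:
    """Flag samples whose 16S:CO1 ratio indicates free-living symbionts.

    Relative mode (default): ratio >= fold_threshold x median host-associated
    ratio. Absolute mode: ratio >= absolute_threshold. The default fold of 10
    is a conservative lower bound for an 'orders of magnitude' contrast.
    """
    ratios = report["ratio"].astype(float)
    if absolute_threshold is not None:
        cutoff = float(absolute_threshold)
    else:
        if "origin" not in report.columns:
            raise ConfigurationError("relative mode requires an 'origin' column")
        host = ratios[report["origin"] == host_origin]
        if host.empty:
            raise ConfigurationError(
                "relative mode requires >= 1 host-associated reference row"
            )
        cutoff = fold_threshold * float(host.median())
    flags = ratios >= cutoff
    flags.name = "free_living_signal"
    return flags
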
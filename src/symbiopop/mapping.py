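"""Reads -> alignments -> nucleotide counts -> filtered variants.

The internal mapper is a deterministic ungapped seed-and-extend aligner
sufficient for short reads against a pangenome of gene clusters: exact
21-mer seeds from three positions of the read are looked up in an index of
both strands of every gene, each candidate diagonal is scored by full-read
Hamming distance, and reads whose best hit is too diverged — or tied across
different genes (paralogs) — are dropped. Externally produced alignments are
accepted as SAM. Internal coordinates are 0-based half-open on the gene's
forward strand; SAM I/O converts to/from 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._seqcodes import decode, encode, kmer_ints, revcomp_codes
from .errors import ConfigurationError, PipelineError
from .simulate import PangenomeReference

DEFAULT_K_MAP = 21  # specific at pangenome scale, tolerant of one error per read end


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------


@dataclass
class AlignmentSet:
    """Ungapped alignments of one sample's reads to the pangenome.

    Aligned sequences are stored in the gene's forward-strand orientation
    (reverse-strand reads are reverse-complemented), so pileup never needs
    strand logic.
    """

    sample_id: str
    gene_names: List[str]  # pangenome gene order
    read_ids: List[str] = field(default_factory=list)
    gene_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    reverse: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    seqs: List[str] = field(default_factory=list)
    n_mismatches: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    stats: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.read_ids)

    @property
    def gene_ids(self) -> List[str]:
        return [self.gene_names[i] for i in self.gene_idx]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_id": self.read_ids,
                "gene_id": self.gene_ids,
                "start": self.starts,
                "strand": np.where(self.reverse, "-", "+"),
                "sequence": self.seqs,
                "n_mismatches": self.n_mismatches,
            }
        )

    def sorted_copy(self) -> "AlignmentSet":
        order = np.lexsort((self.starts, self.gene_idx))
        return AlignmentSet(
            sample_id=self.sample_id,
            gene_names=self.gene_names,
            read_ids=[self.read_ids[i] for i in order],
            gene_idx=self.gene_idx[order],
            starts=self.starts[order],
            reverse=self.reverse[order],
            seqs=[self.seqs[i] for i in order],
            n_mismatches=self.n_mismatches[order],
            stats=dict(self.stats),
        )


# ---------------------------------------------------------------------------
# Internal mapper
# ---------------------------------------------------------------------------


class PangenomeIndex:
    """k-mer index over both strands of every gene; reusable across samples."""

    def __init__(self, pangenome: PangenomeReference, k: int = DEFAULT_K_MAP):
        if not pangenome.genes:
            raise ConfigurationError("empty pangenome")
        if k > pangenome.min_gene_length:
            raise ConfigurationError("k_map exceeds minimum gene length")
        self.pangenome = pangenome
        self.k = k
        self.gene_names = pangenome.gene_ids
        self.codes = [encode(g.sequence) for g in pangenome.genes]
        self.codes_rc = [revcomp_codes(c) for c in self.codes]
        self.lengths = np.array([c.size for c in self.codes])
        index: Dict[int, List[Tuple[int, int, int]]] = {}
        for gi, strands in enumerate(zip(self.codes, self.codes_rc)):
            for si, codes in enumerate(strands):
                for pos, km in enumerate(kmer_ints(codes, k)):
                    index.setdefault(int(km), []).append((gi, si, pos))
        self._index = index

    def seed_hits(self, km: int):
        return self._index.get(km, ())


def map_reads(
    reads: Iterable[Tuple[str, str]],
    pangenome: PangenomeReference,
    max_mismatch_frac: float = 0.05,
    k_map: int = DEFAULT_K_MAP,
    sample_id: str = "sample",
    index: Optional[PangenomeIndex] = None,
) -> AlignmentSet:
    """Map reads to the pangenome; returns one AlignmentSet per call.

    Best candidate = fewest mismatches over the full read among seeded
    diagonals; a read is discarded as ambiguous when two co-best hits fall on
    different genes, and as unmapped when the best hit exceeds
    ``max_mismatch_frac`` of the read length. Reads containing non-ACGT
    symbols are skipped and tallied in ``stats['skipped_non_acgt']``.
    """
    if index is None:
        index = PangenomeIndex(pangenome, k_map)
    elif index.k != k_map:
        raise ConfigurationError("provided index was built with a different k_map")
    k = index.k
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.uint64)
    lengths = index.lengths
    strands = (index.codes, index.codes_rc)
    seed_index = index._index

    out = AlignmentSet(sample_id=sample_id, gene_names=list(index.gene_names))
    rids: List[str] = []
    gidx: List[int] = []
    starts: List[int] = []
    rev: List[bool] = []
    seqs: List[str] = []
    nmm: List[int] = []
    stats = {"total": 0, "mapped": 0, "unmapped": 0, "ambiguous": 0, "skipped_non_acgt": 0}

    for rid, seq in reads:
        stats["total"] += 1
        codes = encode(seq)
        L = codes.size
        if L < k:
            stats["unmapped"] += 1
            continue
        if (codes > 3).any():
            stats["skipped_non_acgt"] += 1
            continue
        max_mm = int(max_mismatch_frac * L)
        # non-overlapping seed tiling plus the read's final k-mer: one error
        # can spoil at most two of these windows
        offsets = list(range(0, L - k + 1, k))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        cands = set()
        for off in offsets:
            km = int(codes[off : off + k] @ powers)
            for gi, si, pos in seed_index.get(km, ()):
                cands.add((gi, si, pos - off))
        best_mm = max_mm + 1
        best: List[Tuple[int, int, int]] = []
        for gi, si, start in cands:
            if start < 0 or start + L > lengths[gi]:
                continue
            ref = strands[si][gi]
            mm = int(np.count_nonzero(ref[start : start + L] != codes))
            if mm < best_mm:
                best_mm = mm
                best = [(gi, si, start)]
            elif mm == best_mm:
                best.append((gi, si, start))
        if not best:
            stats["unmapped"] += 1
            continue
        if len({gi for gi, _s, _p in best}) > 1:
            stats["ambiguous"] += 1
            continue
        gi, si, start = min(best, key=lambda t: (t[1], t[2]))
        if si == 1:  # hit on the reverse strand: convert to forward coordinates
            start_fwd = int(lengths[gi] - start - L)
            aligned = decode(revcomp_codes(codes))
        else:
            start_fwd = int(start)
            aligned = seq
        rids.append(rid)
        gidx.append(gi)
        starts.append(start_fwd)
        rev.append(si == 1)
        seqs.append(aligned)
        nmm.append(best_mm)
        stats["mapped"] += 1

    out.read_ids = rids
    out.gene_idx = np.array(gidx, dtype=np.int32)
    out.starts = np.array(starts, dtype=np.int64)
    out.reverse = np.array(rev, dtype=bool)
    out.seqs = seqs
    out.n_mismatches = np.array(nmm, dtype=np.int32)
    out.stats = stats
    if stats["skipped_non_acgt"]:
        warnings.warn(
            f"{sample_id}: skipped {stats['skipped_non_acgt']} reads with non-ACGT symbols"
        )
    return out


# ---------------------------------------------------------------------------
# SAM I/O (pysam)
# ---------------------------------------------------------------------------


def write_sam(aset: AlignmentSet, pangenome: PangenomeReference, path) -> None:
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": g.gene_id, "LN": len(g)} for g in pangenome.genes],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        name_to_tid = {g.gene_id: i for i, g in enumerate(pangenome.genes)}
        for i in range(len(aset)):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = aset.read_ids[i]
            a.query_sequence = aset.seqs[i]  # already forward-reference oriented
            a.reference_id = name_to_tid[aset.gene_names[aset.gene_idx[i]]]
            a.reference_start = int(aset.starts[i])
            a.cigarstring = f"{len(aset.seqs[i])}M"
            a.mapping_quality = 60
            a.flag = 16 if aset.reverse[i] else 0
            a.query_qualities = pysam.qualitystring_to_array("I" * len(aset.seqs[i]))
            a.set_tag("NM", int(aset.n_mismatches[i]))
            fh.write(a)


def read_sam(path, pangenome: PangenomeReference, sample_id: Optional[str] = None) -> AlignmentSet:
    """Convert mapped, primary, non-supplementary SAM records.

    pysam exposes 0-based starts, matching the internal convention; SAM
    stores reverse-strand SEQ already in forward-reference orientation, so
    sequences are used as-is. Unknown reference names raise with the full
    offender list.
    """
    import pysam

    known = set(pangenome.gene_ids)
    gene_order = {gid: i for i, gid in enumerate(pangenome.gene_ids)}
    aset = AlignmentSet(sample_id=sample_id or str(path), gene_names=pangenome.gene_ids)
    rids: List[str] = []
    gidx: List[int] = []
    starts: List[int] = []
    rev: List[bool] = []
    seqs: List[str] = []
    nmm: List[int] = []
    stats = {"total": 0, "mapped": 0, "unmapped": 0, "ambiguous": 0, "skipped_non_acgt": 0}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        unknown = sorted(set(fh.references) - known)
        if unknown:
            raise ConfigurationError(
                "SAM reference names missing from pangenome: " + ", ".join(unknown)
            )
        gene_codes = {g.gene_id: encode(g.sequence) for g in pangenome.genes}
        for rec in fh:
            stats["total"] += 1
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                stats["unmapped"] += 1
                continue
            gid = rec.reference_name
            seq = rec.query_sequence or ""
            start = rec.reference_start  # 0-based already
            if rec.has_tag("NM"):
                mm = int(rec.get_tag("NM"))
            else:
                ref = gene_codes[gid][start : start + len(seq)]
                mm = int(np.count_nonzero(ref != encode(seq)))
            rids.append(rec.query_name)
            gidx.append(gene_order[gid])
            starts.append(start)
            rev.append(rec.is_reverse)
            seqs.append(seq)
            nmm.append(mm)
            stats["mapped"] += 1
    aset.read_ids = rids
    aset.gene_idx = np.array(gidx, dtype=np.int32)
    aset.starts = np.array(starts, dtype=np.int64)
    aset.reverse = np.array(rev, dtype=bool)
    aset.seqs = seqs
    aset.n_mismatches = np.array(nmm, dtype=np.int32)
    aset.stats = stats
    return aset


# ---------------------------------------------------------------------------
# Pileup and coverage
# ---------------------------------------------------------------------------


@dataclass
class NucleotideCountMatrix:
    """Per variant-candidate site x sample x {A,C,G,T} counts."""

    gene_ids: np.ndarray  # (S,) object
    positions: np.ndarray  # (S,) int, 0-based
    samples: List[str]
    counts: np.ndarray  # (S, N, 4) int

    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=2)

    def site_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays(
            [self.gene_ids, self.positions], names=["gene_id", "pos_0based"]
        )

    def to_tsv(self, path) -> None:
        cols = {}
        for ni, s in enumerate(self.samples):
            for bi, b in enumerate("ACGT"):
                cols[f"{s}:{b}"] = self.counts[:, ni, bi]
        df = pd.DataFrame(
            {"gene_id": self.gene_ids, "pos_0based": self.positions, **cols}
        )
        df.to_csv(path, sep="\t", index=False)


def pileup_counts(
    alignments: Union[Mapping[str, AlignmentSet], Sequence[AlignmentSet]],
    pangenome: PangenomeReference,
    site_list: Optional[Sequence[Tuple[str, int]]] = None,
) -> Tuple[NucleotideCountMatrix, pd.DataFrame]:
    """Nucleotide counts per site per sample plus a coverage summary.

    Without ``site_list`` every pangenome position covered in any sample is a
    candidate site; the coverage summary (mean depth and breadth) is always
    computed over all pangenome positions.
    """
    if isinstance(alignments, Mapping):
        items = list(alignments.items())
    else:
        items = [(a.sample_id, a) for a in alignments]
    samples = [s for s, _ in items]
    gene_ids = pangenome.gene_ids
    gene_lengths = np.array([len(g) for g in pangenome.genes], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(gene_lengths)])
    G = int(offsets[-1])

    per_sample = np.zeros((len(items), 4, G), dtype=np.int64)
    for ni, (_sid, aset) in enumerate(items):
        if len(aset) == 0:
            continue
        if aset.gene_names != gene_ids:
            remap = np.array([gene_ids.index(n) for n in aset.gene_names], dtype=np.int64)
            gidx = remap[aset.gene_idx]
        else:
            gidx = aset.gene_idx.astype(np.int64)
        lens = np.fromiter((len(s) for s in aset.seqs), dtype=np.int64, count=len(aset))
        base = offsets[gidx] + aset.starts
        for L in np.unique(lens):
            sel = np.flatnonzero(lens == L)
            blob = "".join(aset.seqs[i] for i in sel)
            mat = encode(blob).reshape(len(sel), int(L))
            pos = base[sel][:, None] + np.arange(int(L))
            for b in range(4):
                hit = pos[mat == b]
                if hit.size:
                    per_sample[ni, b] += np.bincount(hit, minlength=G)

    depth_all = per_sample.sum(axis=1)  # (N, G)
    coverage = pd.DataFrame(
        {
            "sample_id": samples,
            "mean_depth": depth_all.mean(axis=1),
            "breadth": (depth_all > 0).mean(axis=1),
        }
    ).set_index("sample_id")

    if site_list is not None:
        gene_pos = {gid: offsets[i] for i, gid in enumerate(gene_ids)}
        flat = np.array([gene_pos[g] + p for g, p in site_list], dtype=np.int64)
        site_gene = np.array([g for g, _ in site_list], dtype=object)
        site_off = np.array([p for _, p in site_list], dtype=np.int64)
    else:
        flat = np.flatnonzero(depth_all.sum(axis=0) > 0)
        gi = np.searchsorted(offsets, flat, side="right") - 1
        site_gene = np.array([gene_ids[i] for i in gi], dtype=object)
        site_off = flat - offsets[gi]

    counts = per_sample[:, :, flat].transpose(2, 0, 1)  # (S, N, 4)
    ncm = NucleotideCountMatrix(
        gene_ids=site_gene, positions=site_off, samples=samples, counts=counts
    )
    return ncm, coverage


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------


@dataclass
class QCResult:
    retained: List[str]
    low_coverage: List[str]
    min_mean_depth: float


def sample_qc(coverage: pd.DataFrame, min_mean_depth: float = 10.0) -> QCResult:
    """Partition samples by the mean-depth threshold (boundary inclusive).

    Low-coverage samples are excluded from the primary analysis; the pipeline
    supports a secondary run restricted to sites covered in them.
    """
    if coverage.empty:
        raise PipelineError("coverage summary is empty")
    retained = coverage.index[coverage["mean_depth"] >= min_mean_depth].tolist()
    low = coverage.index[coverage["mean_depth"] < min_mean_depth].tolist()
    if not retained:
        raise PipelineError(
            "no samples meet the coverage threshold; review min_mean_depth "
            f"(={min_mean_depth}) against the coverage summary"
        )
    return QCResult(retained=retained, low_coverage=low, min_mean_depth=min_mean_depth)


# ---------------------------------------------------------------------------
# Variant calling
# ---------------------------------------------------------------------------


@dataclass
class VariantFilters:
    """Conservative strain-variant filters for 10-20x metagenome depth.

    A site is retained iff it has >= min_site_depth in every retained sample
    (complete case, so every pairwise comparison uses one site set), exactly
    two alleles reach min_allele_count pooled, any other allele stays at or
    below noise_allele_max pooled, and the pooled minor-allele frequency is
    at least min_maf.
    """

    min_site_depth: int = 10
    min_allele_count: int = 4
    noise_allele_max: int = 2
    min_maf: float = 0.02


@dataclass
class VariantTable:
    """Filtered biallelic sites with per-sample ref/alt counts."""

    gene_ids: np.ndarray
    positions: np.ndarray
    ref: np.ndarray  # (S,) single characters
    alt: np.ndarray
    samples: List[str]
    ref_counts: np.ndarray  # (S, N)
    alt_counts: np.ndarray
    maf: np.ndarray  # pooled minor-allele frequency

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    def sites(self) -> List[Tuple[str, int]]:
        return [(g, int(p)) for g, p in zip(self.gene_ids, self.positions)]

    def to_tsv(self, path) -> None:
        cols = {}
        for ni, s in enumerate(self.samples):
            cols[f"{s}:ref"] = self.ref_counts[:, ni]
            cols[f"{s}:alt"] = self.alt_counts[:, ni]
        pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "pos_0based": self.positions,
                "ref": self.ref,
                "alt": self.alt,
                "maf": self.maf,
                **cols,
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "VariantTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        samples = [c[:-4] for c in df.columns if c.endswith(":ref")]
        return cls(
            gene_ids=df["gene_id"].to_numpy(dtype=object),
            positions=df["pos_0based"].to_numpy(dtype=np.int64),
            ref=df["ref"].to_numpy(dtype=object),
            alt=df["alt"].to_numpy(dtype=object),
            samples=samples,
            ref_counts=df[[f"{s}:ref" for s in samples]].to_numpy(dtype=np.int64),
            alt_counts=df[[f"{s}:alt" for s in samples]].to_numpy(dtype=np.int64),
            maf=df["maf"].to_numpy(dtype=float),
        )


def call_variants(
    ncm: NucleotideCountMatrix,
    retained_samples: Sequence[str],
    filters: VariantFilters = VariantFilters(),
) -> VariantTable:
    """Filter candidate sites to biallelic polymorphisms (see VariantFilters).

    The reference allele is the majority pooled allele; ties break
    alphabetically. An empty result is returned with a warning, not raised.
    """
    if len(retained_samples) < 2:
        raise PipelineError("variant calling requires >= 2 retained samples")
    idx = [ncm.samples.index(s) for s in retained_samples]
    sub = ncm.counts[:, idx, :]  # (S, N, 4)

    depth_ok = (sub.sum(axis=2) >= filters.min_site_depth).all(axis=1)
    pooled = sub.sum(axis=1)  # (S, 4)
    major = pooled >= filters.min_allele_count
    two_alleles = major.sum(axis=1) == 2
    noise_ok = np.where(major, 0, pooled).max(axis=1) <= filters.noise_allele_max

    # ref = majority pooled allele; alphabetical tie-break falls out of argmax
    # scanning A,C,G,T in order. alt = the other major allele.
    masked = np.where(major, pooled, -1)
    ref_allele = masked.argmax(axis=1)
    alt_masked = masked.copy()
    alt_masked[np.arange(len(pooled)), ref_allele] = -1
    alt_allele = alt_masked.argmax(axis=1)

    two_counts = pooled[np.arange(len(pooled)), ref_allele] + pooled[
        np.arange(len(pooled)), alt_allele
    ]
    with np.errstate(divide="ignore", invalid="ignore"):
        maf = np.where(
            two_counts > 0,
            pooled[np.arange(len(pooled)), alt_allele] / np.maximum(two_counts, 1),
            0.0,
        )
    maf = np.minimum(maf, 1 - maf)
    keep = depth_ok & two_alleles & noise_ok & (maf >= filters.min_maf)

    sel = np.flatnonzero(keep)
    bases = np.array(list("ACGT"))
    if sel.size == 0:
        warnings.warn("no sites survived variant filters; returning empty table")
    ref_c = np.take_along_axis(sub[sel], ref_allele[sel][:, None, None], axis=2)[:, :, 0]
    alt_c = np.take_along_axis(sub[sel], alt_allele[sel][:, None, None], axis=2)[:, :, 0]
    return VariantTable(
        gene_ids=ncm.gene_ids[sel],
        positions=ncm.positions[sel],
        ref=bases[ref_allele[sel]],
        alt=bases[alt_allele[sel]],
        samples=list(retained_samples),
        ref_counts=ref_c.astype(np.int64),
        alt_counts=alt_c.astype(np.int64),
        maf=maf[sel],
    )
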
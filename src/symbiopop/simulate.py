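"""Synthetic data generator for symbiont population-genomic analyses.

Everything downstream (mapping, variant calling, F_ST, ordination, gene
content, marker ratios) is exercised against data produced here, with full
ground truth retained:

* a pangenome of core genes shared by all strains plus deme-specific
  accessory genes (one FASTA record per gene cluster);
* per-deme allele frequencies under the Balding–Nichols island model, whose
  single parameter F equals the expected Hudson F_ST between demes;
* strain haplotypes drawn per deme, and per-sample strain mixtures labelled
  by (vent field x lifestyle);
* 150-bp single-end reads with i.i.d. substitution errors and host-genome
  spike-ins;
* marker-gene read sets (symbiont 16S-like vs host CO1-like targets plus
  diverged background decoys) emulating gill-tissue and vent-fluid samples
  whose 16S:CO1 read ratios differ by orders of magnitude.

All randomness flows from a single integer seed through named substreams, so
identical configuration + seed reproduces identical bytes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seqcodes import BASES, decode, encode
from .errors import ConfigurationError, SimulationError

# Named substreams: each stage derives its RNG from (seed, STREAM) so that
# stages are independent and individually reproducible.
_STREAM_PANGENOME = 1
_STREAM_FREQS = 2
_STREAM_SITES = 3
_STREAM_HAPLOTYPES = 4
_STREAM_HOST = 5
_STREAM_READS = 6  # + sample index
_STREAM_MARKERS = 7
_STREAM_DESIGN = 8

HOST_GENOME_LENGTH = 50_000

# Functional-category labels cycled over accessory genes so that the
# category breakdown of group-unique genes has something to aggregate.
ACCESSORY_CATEGORY_LABELS = (
    "sulfur metabolism",
    "iron acquisition",
    "mobilome",
    "virulence, disease and defense",
    "hypothetical",
)


def _rng(seed: int, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream, *extra)))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gene:
    gene_id: str
    sequence: str
    category: str  # "core" | "accessory"
    deme: Optional[int] = None  # accessory genes carry their deme of origin
    category_label: Optional[str] = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PangenomeReference:
    """One record per gene cluster; the mapping reference for all samples."""

    genes: List[Gene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("pangenome gene_ids must be unique")
        if not any(g.category == "core" for g in self.genes):
            raise ConfigurationError("pangenome needs at least one core gene")
        for g in self.genes:
            if len(g.sequence) == 0 or set(g.sequence) - set(BASES):
                raise ConfigurationError(f"gene {g.gene_id}: sequence must be non-empty ACGT")
        self._by_id = {g.gene_id: g for g in self.genes}

    def gene(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> List[str]:
        return [g.gene_id for g in self.genes]

    @property
    def core_genes(self) -> List[Gene]:
        return [g for g in self.genes if g.category == "core"]

    @property
    def total_length(self) -> int:
        return sum(len(g) for g in self.genes)

    @property
    def min_gene_length(self) -> int:
        return min(len(g) for g in self.genes)

    def to_fasta(self, path) -> None:
        write_fasta(((g.gene_id, g.sequence) for g in self.genes), path)


@dataclass
class SampleSpec:
    sample_id: str
    vent_field: str
    lifestyle: str  # "host_associated" | "free_living"
    deme: int
    strain_proportions: np.ndarray
    mean_depth: float
    host_read_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.strain_proportions = np.asarray(self.strain_proportions, dtype=float)
        if abs(self.strain_proportions.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"sample {self.sample_id}: strain_proportions must sum to 1"
            )
        if (self.strain_proportions < 0).any():
            raise ConfigurationError(f"sample {self.sample_id}: negative strain proportion")
        if self.mean_depth <= 0:
            raise ConfigurationError(f"sample {self.sample_id}: mean_depth must be > 0")
        if not 0 <= self.host_read_fraction < 1:
            raise ConfigurationError(
                f"sample {self.sample_id}: host_read_fraction must be in [0, 1)"
            )
        if self.lifestyle not in ("host_associated", "free_living"):
            raise ConfigurationError(f"sample {self.sample_id}: unknown lifestyle")


@dataclass
class SimulationConfig:
    n_demes: int = 2
    fst_target: float = 0.4
    n_core_genes: int = 20
    n_accessory_per_deme: int = 2
    gene_length_range: Tuple[int, int] = (900, 1100)
    n_variant_sites: int = 2000
    strains_per_deme: int = 40
    samples: List[SampleSpec] = field(default_factory=list)
    read_length: int = 150
    error_rate: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.gene_length_range
        if lo > hi:
            raise ConfigurationError("gene_length_range: min > max")
        if self.read_length > lo:
            raise ConfigurationError("read_length exceeds minimum gene length")
        if not 0 <= self.fst_target < 1:
            raise ConfigurationError("fst_target must be in [0, 1)")
        if not 0 <= self.error_rate < 0.5:
            raise ConfigurationError("error_rate must be in [0, 0.5)")
        for name in ("n_demes", "n_core_genes", "n_variant_sites", "strains_per_deme"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_accessory_per_deme < 0:
            raise ConfigurationError("n_accessory_per_deme must be >= 0")
        for s in self.samples:
            if not 0 <= s.deme < self.n_demes:
                raise ConfigurationError(f"sample {s.sample_id}: deme out of range")
            if s.strain_proportions.size != self.strains_per_deme:
                raise ConfigurationError(
                    f"sample {s.sample_id}: strain_proportions length != strains_per_deme"
                )


@dataclass
class DemeFrequencies:
    """Island-model truth fragment: ancestral and per-deme allele frequencies."""

    ancestral_freqs: np.ndarray  # (L,)
    deme_freqs: np.ndarray  # (n_demes, L)


@dataclass
class TruthSet:
    """Complete simulator ground truth for downstream validation."""

    ancestral_freqs: np.ndarray
    deme_freqs: np.ndarray
    variant_sites: List[Tuple[str, int]]  # (gene_id, 0-based offset), core genes only
    ref_bases: np.ndarray  # (L,) single characters
    alt_bases: np.ndarray
    strain_haplotypes: np.ndarray  # (n_demes, strains_per_deme, L) in {0 ref, 1 alt}
    strain_gene_content: pd.DataFrame  # strains x genes boolean
    read_origins: Dict[str, pd.DataFrame]  # sample -> per-read provenance
    host_genome: str

    def strain_label(self, deme: int, strain: int) -> str:
        return f"d{deme}_s{strain}"

    def sample_gene_content(self, spec: SampleSpec) -> pd.Series:
        """Genes present in a sample = union over strains with non-zero weight."""
        labels = [
            self.strain_label(spec.deme, s)
            for s in np.nonzero(spec.strain_proportions > 0)[0]
        ]
        return self.strain_gene_content.loc[labels].any(axis=0)

    def deme_sample_freqs(self, spec: SampleSpec) -> np.ndarray:
        """Expected alt-allele frequency of the sample's strain mixture per site."""
        hap = self.strain_haplotypes[spec.deme]  # (K, L)
        return spec.strain_proportions @ hap

    def to_json(self, path) -> None:
        payload = {
            "ancestral_freqs": self.ancestral_freqs.tolist(),
            "deme_freqs": self.deme_freqs.tolist(),
            "variant_sites": [[g, int(p)] for g, p in self.variant_sites],
            "ref_bases": self.ref_bases.tolist(),
            "alt_bases": self.alt_bases.tolist(),
            "strain_haplotypes": self.strain_haplotypes.tolist(),
            "strain_gene_content": {
                s: [int(v) for v in row]
                for s, row in self.strain_gene_content.iterrows()
            },
            "gene_order": list(self.strain_gene_content.columns),
            "read_origins": {
                sample: df.to_dict(orient="list") for sample, df in self.read_origins.items()
            },
            "host_genome": self.host_genome,
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# FASTA / FASTQ / metadata output
# ---------------------------------------------------------------------------


def write_fasta(records: Iterable[Tuple[str, str]], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[Tuple[str, str]], path) -> None:
    """Phred-33 FASTQ with the fixed quality 'I' (Q40) the simulator promises."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> List[Tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def read_fasta(path) -> List[Tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_metadata(samples: Sequence[SampleSpec], path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "vent_field": [s.vent_field for s in samples],
            "lifestyle": [s.lifestyle for s in samples],
            "deme": [s.deme for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pangenome
# ---------------------------------------------------------------------------


def generate_pangenome(config: SimulationConfig) -> PangenomeReference:
    """Random pangenome: n_core core genes plus n_demes x n_accessory_per_deme
    deme-tagged accessory genes. Deterministic under the config seed."""
    config.validate()
    rng = _rng(config.seed, _STREAM_PANGENOME)
    lo, hi = config.gene_length_range
    genes: List[Gene] = []

    def random_seq(length: int) -> str:
        return decode(rng.integers(0, 4, size=length).astype(np.uint8))

    for i in range(config.n_core_genes):
        length = int(rng.integers(lo, hi + 1))
        genes.append(Gene(f"core_{i:04d}", random_seq(length), "core"))
    label_cycle = 0
    for d in range(config.n_demes):
        for j in range(config.n_accessory_per_deme):
            length = int(rng.integers(lo, hi + 1))
            label = ACCESSORY_CATEGORY_LABELS[label_cycle % len(ACCESSORY_CATEGORY_LABELS)]
            label_cycle += 1
            genes.append(
                Gene(f"acc_d{d}_{j:03d}", random_seq(length), "accessory", deme=d,
                     category_label=label)
            )
    return PangenomeReference(genes)


# ---------------------------------------------------------------------------
# Island-model allele frequencies
# ---------------------------------------------------------------------------


def simulate_deme_frequencies(
    fst_target: float, n_sites: int, n_demes: int = 2, seed: int = 0
) -> DemeFrequencies:
    """Balding–Nichols island model.

    Ancestral frequencies p ~ Uniform(0.05, 0.95) (avoiding near-fixed sites
    that inflate estimator variance); deme frequencies are Beta with mean p
    and variance F p (1-p), i.e. Beta(p(1-F)/F, (1-p)(1-F)/F), so the expected
    Hudson F_ST between demes equals fst_target. F = 0 collapses to the
    ancestral frequencies exactly.
    """
    if not 0 <= fst_target < 1:
        raise ConfigurationError("fst_target must be in [0, 1)")
    rng = _rng(seed, _STREAM_FREQS)
    p = rng.uniform(0.05, 0.95, size=n_sites)
    if fst_target == 0:
        deme = np.tile(p, (n_demes, 1))
    else:
        scale = (1 - fst_target) / fst_target
        deme = rng.beta(p * scale, (1 - p) * scale, size=(n_demes, n_sites))
    return DemeFrequencies(ancestral_freqs=p, deme_freqs=deme)


def place_variant_sites(
    pangenome: PangenomeReference,
    n_sites: int,
    seed: int,
    sites: Optional[Sequence[Tuple[str, int]]] = None,
    edge_margin: int = 0,
) -> List[Tuple[str, int]]:
    """Distinct (gene, offset) positions for variants, restricted to core genes
    so sequence variation and gene content stay orthogonal truth axes.

    ``edge_margin`` keeps sites out of the first/last bases of each gene:
    uniform read starts taper coverage within one read length of gene
    boundaries, so the read simulator places sites in the uniformly covered
    interior where the nominal depth applies.
    """
    if sites is not None:
        if len(set(sites)) != len(sites):
            raise SimulationError("variant site collision: duplicate (gene, position)")
        core_ids = {g.gene_id for g in pangenome.core_genes}
        for gid, pos in sites:
            if gid not in core_ids:
                raise SimulationError(f"variant site on non-core gene {gid}")
            if not 0 <= pos < len(pangenome.gene(gid)):
                raise SimulationError(f"variant site out of range: {gid}:{pos}")
        return list(sites)
    core = pangenome.core_genes
    spans = []
    for g in core:
        lo, hi = edge_margin, len(g) - edge_margin
        spans.append((g, lo, max(hi - lo, 0)))
    lengths = np.array([n for _g, _lo, n in spans])
    total = int(lengths.sum())
    if n_sites > total:
        raise SimulationError(
            f"cannot place {n_sites} sites in {total} eligible core positions"
        )
    rng = _rng(seed, _STREAM_SITES)
    flat = rng.choice(total, size=n_sites, replace=False)
    flat.sort()
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    gene_idx = np.searchsorted(bounds, flat, side="right") - 1
    return [
        (spans[gi][0].gene_id, int(pos - bounds[gi] + spans[gi][1]))
        for gi, pos in zip(gene_idx, flat)
    ]


# ---------------------------------------------------------------------------
# Strains and reads
# ---------------------------------------------------------------------------


def _apply_errors(reads: np.ndarray, error_rate: float, rng: np.random.Generator) -> None:
    """In-place i.i.d. substitutions: each erroneous base moves to one of the
    three other bases uniformly."""
    if error_rate <= 0 or reads.size == 0:
        return
    mask = rng.random(reads.shape) < error_rate
    n = int(mask.sum())
    if n:
        shifts = rng.integers(1, 4, size=n).astype(np.uint8)
        reads[mask] = (reads[mask] + shifts) % 4


def simulate_strains_and_samples(
    config: SimulationConfig,
    pangenome: PangenomeReference,
    freqs: DemeFrequencies,
    variant_sites: Optional[Sequence[Tuple[str, int]]] = None,
) -> Tuple[Dict[str, List[Tuple[str, str]]], TruthSet]:
    """Draw strain haplotypes and per-sample read sets.

    Haplotypes: allele at each variant site ~ Bernoulli(deme frequency).
    Reads: strain chosen per the sample's strain_proportions, gene chosen
    proportionally to length among genes the strain carries, start uniform,
    substitution errors i.i.d.; host reads from a single random host genome
    at the sample's host_read_fraction. Every read's origin is recorded.
    """
    config.validate()
    if freqs.deme_freqs.shape != (config.n_demes, config.n_variant_sites):
        raise ConfigurationError("deme_freqs shape does not match config")
    sites = place_variant_sites(
        pangenome,
        config.n_variant_sites,
        config.seed,
        variant_sites,
        edge_margin=min(config.read_length, pangenome.min_gene_length // 3),
    )
    L = len(sites)
    RL = config.read_length
    gene_codes = {g.gene_id: encode(g.sequence) for g in pangenome.genes}

    ref_bases = np.array([pangenome.gene(g).sequence[p] for g, p in sites])
    rng_sites = _rng(config.seed, _STREAM_SITES, 1)
    ref_codes = np.array([BASES.index(b) for b in ref_bases], dtype=np.uint8)
    alt_codes = (ref_codes + rng_sites.integers(1, 4, size=L).astype(np.uint8)) % 4
    alt_bases = np.array([BASES[c] for c in alt_codes])

    # Haplotypes per deme: (D, K, L) Bernoulli(deme frequency).
    rng_hap = _rng(config.seed, _STREAM_HAPLOTYPES)
    D, K = config.n_demes, config.strains_per_deme
    haplotypes = (
        rng_hap.random((D, K, L)) < freqs.deme_freqs[:, None, :]
    ).astype(np.uint8)

    # Gene content: every strain carries all core genes plus its deme's
    # accessory genes.
    gene_ids = pangenome.gene_ids
    content = pd.DataFrame(
        False, index=[f"d{d}_s{s}" for d in range(D) for s in range(K)], columns=gene_ids
    )
    for g in pangenome.genes:
        if g.category == "core":
            content[g.gene_id] = True
        else:
            for s in range(K):
                content.loc[f"d{g.deme}_s{s}", g.gene_id] = True

    # Per-gene site bookkeeping for building strain sequences.
    sites_by_gene: Dict[str, List[int]] = {}
    for idx, (gid, _pos) in enumerate(sites):
        sites_by_gene.setdefault(gid, []).append(idx)

    # Strain sequences per (deme, gene): (K, gene_length) uint8, alt alleles
    # substituted where the haplotype says so.
    deme_gene_lists: List[List[str]] = []
    for d in range(D):
        deme_gene_lists.append(
            [gid for gid in gene_ids if bool(content.loc[f"d{d}_s0", gid])]
        )
    strain_seqs: Dict[Tuple[int, str], np.ndarray] = {}
    for d in range(D):
        for gid in deme_gene_lists[d]:
            base = gene_codes[gid]
            mat = np.repeat(base[None, :], K, axis=0)
            idxs = sites_by_gene.get(gid)
            if idxs:
                positions = np.array([sites[i][1] for i in idxs])
                hap = haplotypes[d][:, idxs]  # (K, n_gene_sites)
                mat[:, positions] = np.where(hap == 1, alt_codes[idxs], base[positions])
            strain_seqs[(d, gid)] = mat

    rng_host = _rng(config.seed, _STREAM_HOST)
    host_genome_codes = rng_host.integers(0, 4, size=HOST_GENOME_LENGTH).astype(np.uint8)
    host_genome = decode(host_genome_codes)

    reads_by_sample: Dict[str, List[Tuple[str, str]]] = {}
    origins: Dict[str, pd.DataFrame] = {}

    for si, spec in enumerate(config.samples):
        rng = _rng(config.seed, _STREAM_READS, si)
        d = spec.deme
        glist = deme_gene_lists[d]
        glens = np.array([len(gene_codes[g]) for g in glist], dtype=float)
        gprob = glens / glens.sum()
        mean_len = glens.sum()  # every strain in a deme carries the same genes
        n_sym = int(round(spec.mean_depth * mean_len / RL))
        n_host = (
            int(round(n_sym * spec.host_read_fraction / (1 - spec.host_read_fraction)))
            if spec.host_read_fraction > 0
            else 0
        )

        strain_pick = rng.choice(K, size=n_sym, p=spec.strain_proportions)
        gene_pick = rng.choice(len(glist), size=n_sym, p=gprob)
        u = rng.random(n_sym)
        starts = np.floor(u * (glens[gene_pick] - RL + 1)).astype(np.int64)

        read_mat = np.empty((n_sym, RL), dtype=np.uint8)
        order = np.lexsort((starts, strain_pick, gene_pick))
        sorted_gene = gene_pick[order]
        sorted_strain = strain_pick[order]
        sorted_start = starts[order]
        # group by (gene, strain) runs after the lexsort
        boundaries = np.flatnonzero(
            np.diff(sorted_gene) | np.diff(sorted_strain)
        ) + 1
        group_starts = np.concatenate([[0], boundaries, [n_sym]])
        window = np.arange(RL)
        for b, e in zip(group_starts[:-1], group_starts[1:]):
            if b == e:
                continue
            gid = glist[sorted_gene[b]]
            seq = strain_seqs[(d, gid)][sorted_strain[b]]
            read_mat[order[b:e]] = seq[sorted_start[b:e, None] + window]
        # half the reads sequenced from the reverse strand, as in a real
        # single-end library
        flip = rng.random(n_sym) < 0.5
        if flip.any():
            read_mat[flip] = (3 - read_mat[flip])[:, ::-1]
        _apply_errors(read_mat, config.error_rate, rng)

        host_starts = np.empty(0, dtype=np.int64)
        host_flip = np.empty(0, dtype=bool)
        if n_host:
            host_starts = rng.integers(0, HOST_GENOME_LENGTH - RL + 1, size=n_host)
            host_mat = host_genome_codes[host_starts[:, None] + window].copy()
            host_flip = rng.random(n_host) < 0.5
            if host_flip.any():
                host_mat[host_flip] = (3 - host_mat[host_flip])[:, ::-1]
            _apply_errors(host_mat, config.error_rate, rng)

        reads: List[Tuple[str, str]] = []
        rid_fmt = spec.sample_id + ":%06d"
        for i in range(n_sym):
            reads.append((rid_fmt % i, decode(read_mat[i])))
        for j in range(n_host):
            reads.append((rid_fmt % (n_sym + j), decode(host_mat[j])))
        reads_by_sample[spec.sample_id] = reads

        origins[spec.sample_id] = pd.DataFrame(
            {
                "read_id": [r[0] for r in reads],
                "origin": ["symbiont"] * n_sym + ["host"] * n_host,
                "deme": [d] * n_sym + [-1] * n_host,
                "strain": np.concatenate([strain_pick, np.full(n_host, -1)]).astype(int),
                "gene_id": [glist[g] for g in gene_pick] + ["host"] * n_host,
                "start": np.concatenate([starts, host_starts]).astype(int),
                "strand": np.where(np.concatenate([flip, host_flip]), "-", "+"),
            }
        )

    truth = TruthSet(
        ancestral_freqs=freqs.ancestral_freqs,
        deme_freqs=freqs.deme_freqs,
        variant_sites=sites,
        ref_bases=ref_bases,
        alt_bases=alt_bases,
        strain_haplotypes=haplotypes,
        strain_gene_content=content,
        read_origins=origins,
        host_genome=host_genome,
    )
    return reads_by_sample, truth


# ---------------------------------------------------------------------------
# Study-design helper
# ---------------------------------------------------------------------------

DEFAULT_VENT_FIELDS = ("Illium", "Hafa_Adai", "Burke", "Alice_Springs")


def study_config(
    n_demes: int = 2,
    fst_target: float = 0.4,
    n_core_genes: int = 80,
    n_accessory_per_deme: int = 2,
    gene_length_range: Tuple[int, int] = (900, 1100),
    n_variant_sites: int = 2000,
    strains_per_deme: int = 40,
    samples_per_group: int = 3,
    lifestyles: Sequence[str] = ("host_associated",),
    mean_depth: float = 20.0,
    read_length: int = 150,
    error_rate: float = 0.005,
    host_read_fraction: float = 0.05,
    lifestyle_drift: float = 0.0,
    sample_drift: float = 0.0,
    seed: int = 0,
) -> SimulationConfig:
    """Build a SimulationConfig emulating the study design: demes correspond
    one-to-one to vent fields; within a deme, all lifestyles draw samples from
    the same strain pool.

    ``lifestyle_drift``/``sample_drift`` in [0, 1) control how far lifestyle-
    and sample-level strain mixtures wander from the deme's uniform pool
    (Dirichlet with concentration K(1-d)/d, the Balding–Nichols analogue on
    the simplex); 0 means exact sharing — every sample mixes all strains
    uniformly, which keeps strain-pool sampling noise at its 1/K floor.
    Free-living samples carry an order of magnitude less host DNA than gill
    samples.
    """
    rng = _rng(seed, _STREAM_DESIGN)
    K = strains_per_deme
    samples: List[SampleSpec] = []

    def drifted(center: np.ndarray, d: float) -> np.ndarray:
        if d <= 0:
            return center
        alpha = np.maximum(center * K * (1 - d) / d, 1e-3)
        return rng.dirichlet(alpha)

    for deme in range(n_demes):
        field_name = DEFAULT_VENT_FIELDS[deme % len(DEFAULT_VENT_FIELDS)]
        base = np.full(K, 1.0 / K)
        for lifestyle in lifestyles:
            center = drifted(base, lifestyle_drift)
            for r in range(samples_per_group):
                w = drifted(center, sample_drift)
                w = w / w.sum()
                tag = "HA" if lifestyle == "host_associated" else "FL"
                hf = host_read_fraction if lifestyle == "host_associated" else (
                    host_read_fraction / 10.0
                )
                samples.append(
                    SampleSpec(
                        sample_id=f"{field_name}_{tag}_{r + 1}",
                        vent_field=field_name,
                        lifestyle=lifestyle,
                        deme=deme,
                        strain_proportions=w,
                        mean_depth=mean_depth,
                        host_read_fraction=hf,
                    )
                )
    return SimulationConfig(
        n_demes=n_demes,
        fst_target=fst_target,
        n_core_genes=n_core_genes,
        n_accessory_per_deme=n_accessory_per_deme,
        gene_length_range=gene_length_range,
        n_variant_sites=n_variant_sites,
        strains_per_deme=strains_per_deme,
        samples=samples,
        read_length=read_length,
        error_rate=error_rate,
        seed=seed,
    )


def simulate_study(config: SimulationConfig):
    """Convenience wrapper: pangenome + island-model frequencies + reads."""
    pangenome = generate_pangenome(config)
    freqs = simulate_deme_frequencies(
        config.fst_target, config.n_variant_sites, config.n_demes, config.seed
    )
    reads, truth = simulate_strains_and_samples(config, pangenome, freqs)
    return pangenome, reads, truth


# ---------------------------------------------------------------------------
# Marker-gene read sets (16S vs CO1 with background decoys)
# ---------------------------------------------------------------------------

MARKER_CATEGORIES = ("target_16S", "target_CO1", "background_16S", "background_CO1")

# Read-count compositions per scenario (out of n_reads; remainder is unrelated
# noise). Gill tissue: 16S:CO1 percentage ratio of order 1-10; vent fluid:
# order 10-300, mirroring the orders-of-magnitude contrast between
# host-associated and free-living samples.
_SCENARIO_COMPOSITION = {
    "gill": {"target_16S": 60, "target_CO1": 24, "background_16S": 40, "background_CO1": 40},
    "fluid": {"target_16S": 240, "target_CO1": 3, "background_16S": 40, "background_CO1": 40},
}


@dataclass
class MarkerSimulation:
    scenario: str
    databases: Dict[str, List[Tuple[str, str]]]
    reads: List[Tuple[str, str]]
    truth_counts: Dict[str, int]  # per category + "other"
    truth_ratio: Optional[float]  # 16S:CO1 percentage ratio implied by truth

    def write(self, out_dir) -> Dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for cat, seqs in self.databases.items():
            p = out / f"{cat}.fasta"
            write_fasta(seqs, p)
            paths[cat] = p
        reads_path = out / f"{self.scenario}_reads.fastq"
        write_fastq(self.reads, reads_path)
        paths["reads"] = reads_path
        return paths


def _mutate(codes: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    n = max(1, int(round(fraction * codes.size)))
    pos = rng.choice(codes.size, size=n, replace=False)
    out[pos] = (out[pos] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return out


def generate_marker_read_sets(
    scenario: str,
    seed: int = 0,
    n_reads: int = 6000,
    read_length: int = 150,
    background_divergence: float = 0.08,
    error_rate: float = 0.0,
    composition: Optional[Dict[str, int]] = None,
) -> MarkerSimulation:
    """Marker databases plus a read set of known per-category composition.

    Four FASTA categories are produced: symbiont 16S-like targets, host
    CO1-like targets, and one background decoy set per marker, each decoy
    diverged from its target by ``background_divergence`` (refused at 0:
    indistinguishable decoys make 'unambiguous' meaningless). Reads not drawn
    from any database come from unrelated noise sequences.
    """
    if composition is None:
        if scenario not in _SCENARIO_COMPOSITION:
            raise ConfigurationError(f"unknown scenario {scenario!r} (gill|fluid)")
        composition = _SCENARIO_COMPOSITION[scenario]
    if background_divergence <= 0:
        raise ConfigurationError(
            "background_divergence must be > 0: decoys identical to targets"
        )
    rng = _rng(seed, _STREAM_MARKERS)

    def random_codes(length: int) -> np.ndarray:
        return rng.integers(0, 4, size=length).astype(np.uint8)

    t16 = [("sym16S_%d" % i, random_codes(1500)) for i in range(3)]
    tco1 = [("hostCO1_%d" % i, random_codes(650)) for i in range(2)]
    b16 = [
        (f"bg16S_{name}", _mutate(codes, background_divergence, rng))
        for name, codes in t16
    ] + [("bg16S_extra", random_codes(1500))]
    bco1 = [
        (f"bgCO1_{name}", _mutate(codes, background_divergence, rng))
        for name, codes in tco1
    ] + [("bgCO1_extra", random_codes(650))]
    db_codes = {
        "target_16S": t16,
        "target_CO1": tco1,
        "background_16S": b16,
        "background_CO1": bco1,
    }

    n_db = sum(composition.get(c, 0) for c in MARKER_CATEGORIES)
    if n_db > n_reads:
        raise ConfigurationError("composition exceeds n_reads")
    noise = [("noise_%d" % i, random_codes(2000)) for i in range(5)]

    reads: List[Tuple[str, str]] = []
    truth_counts = {c: int(composition.get(c, 0)) for c in MARKER_CATEGORIES}
    truth_counts["other"] = n_reads - n_db

    def draw(source: List[Tuple[str, np.ndarray]], count: int, tag: str) -> None:
        for i in range(count):
            name, codes = source[int(rng.integers(0, len(source)))]
            start = int(rng.integers(0, codes.size - read_length + 1))
            r = codes[start : start + read_length].copy()
            _apply_errors(r, error_rate, rng)
            reads.append((f"{tag}_{i:05d}", decode(r)))

    for cat in MARKER_CATEGORIES:
        draw(db_codes[cat], truth_counts[cat], cat)
    draw(noise, truth_counts["other"], "other")
    rng.shuffle(reads)

    n16, nco1 = truth_counts["target_16S"], truth_counts["target_CO1"]
    truth_ratio = (n16 / nco1) if nco1 > 0 else None

    databases = {
        cat: [(name, decode(codes)) for name, codes in seqs]
        for cat, seqs in db_codes.items()
    }
    return MarkerSimulation(
        scenario=scenario,
        databases=databases,
        reads=reads,
        truth_counts=truth_counts,
        truth_ratio=truth_ratio,
    )
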
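"""Gene content: coverage-based presence/absence, Jaccard ordination, and
group-unique gene extraction.

Per-sample gene depths are normalized by the sample's median gene depth
(robust to a few high-coverage rRNA-like genes) and converted to calls with
a two-threshold rule: present at or above ``theta_present``, absent at or
below ``theta_absent``, and 'uncertain' in between. Uncertain calls count
as absent for Jaccard distances but disqualify a gene from group-unique
lists, the most biology-facing output of this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .mapping import AlignmentSet
from .popstruct import DistanceMatrix
from .simulate import PangenomeReference

PRESENT, ABSENT, UNCERTAIN = 1, 0, -1


def gene_depths(
    alignments: Union[Mapping[str, AlignmentSet], Sequence[AlignmentSet]],
    pangenome: PangenomeReference,
) -> pd.DataFrame:
    """Mean per-base depth per gene per sample: aligned bases / gene length."""
    if isinstance(alignments, Mapping):
        items = list(alignments.items())
    else:
        items = [(a.sample_id, a) for a in alignments]
    gene_ids = pangenome.gene_ids
    lengths = np.array([len(g) for g in pangenome.genes], dtype=float)
    data = {}
    for sid, aset in items:
        bases = np.zeros(len(gene_ids))
        if len(aset):
            if aset.gene_names != gene_ids:
                remap = np.array([gene_ids.index(n) for n in aset.gene_names])
                gidx = remap[aset.gene_idx]
            else:
                gidx = aset.gene_idx
            read_lens = np.fromiter((len(s) for s in aset.seqs), dtype=float, count=len(aset))
            bases = np.bincount(gidx, weights=read_lens, minlength=len(gene_ids))
        data[sid] = bases / lengths
    return pd.DataFrame(data, index=gene_ids)


@dataclass
class GenePresenceMatrix:
    """Gene x sample calls in {1 present, 0 absent, -1 uncertain}."""

    calls: pd.DataFrame  # int8, genes x samples
    normalized_depth: pd.DataFrame

    @property
    def samples(self) -> List[str]:
        return list(self.calls.columns)

    def present(self) -> pd.DataFrame:
        return self.calls == PRESENT

    def to_tsv(self, path) -> None:
        out = self.calls.replace({UNCERTAIN: pd.NA}).astype("Int8")
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", na_rep="NA")


def call_presence(
    depths: pd.DataFrame,
    theta_present: float = 0.25,
    theta_absent: float = 0.05,
) -> GenePresenceMatrix:
    """Two-threshold presence calls on median-normalized gene depth."""
    if theta_absent >= theta_present:
        raise ConfigurationError("theta_absent must be < theta_present")
    medians = depths[depths > 0].median(axis=0, skipna=True)
    if medians.isna().any() or (medians <= 0).any():
        bad = medians.index[medians.isna() | (medians <= 0)].tolist()
        raise ConfigurationError(f"sample(s) with no covered genes: {bad}")
    norm = depths / medians
    calls = pd.DataFrame(
        np.select(
            [norm.values >= theta_present, norm.values <= theta_absent],
            [PRESENT, ABSENT],
            default=UNCERTAIN,
        ).astype(np.int8),
        index=depths.index,
        columns=depths.columns,
    )
    return GenePresenceMatrix(calls=calls, normalized_depth=norm)


def jaccard_matrix(p: GenePresenceMatrix) -> DistanceMatrix:
    """Jaccard distance 1 - |A∩B| / |A∪B| over present-gene sets.

    Uncertain calls are treated as absent; two empty sets are at distance 0
    by convention.
    """
    B = p.present().to_numpy().T.astype(float)  # samples x genes
    if B.shape[0] < 2:
        raise ConfigurationError("Jaccard needs >= 2 samples")
    inter = B @ B.T
    sizes = B.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        D = np.where(union > 0, 1.0 - inter / np.where(union > 0, union, 1), 0.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(labels=p.samples, matrix=D, metric_name="jaccard")


@dataclass
class UniqueGeneReport:
    unique: Dict[str, List[str]]  # group -> genes present in all of it, absent elsewhere
    category_counts: Optional[pd.DataFrame]  # group x functional category

    def to_tsv(self, path) -> None:
        rows = [
            {"group": g, "gene_id": gid}
            for g, genes in self.unique.items()
            for gid in genes
        ]
        pd.DataFrame(rows, columns=["group", "gene_id"]).to_csv(path, sep="\t", index=False)

    def to_json_dict(self) -> dict:
        out = {"unique": self.unique}
        if self.category_counts is not None:
            out["category_counts"] = {
                g: row.to_dict() for g, row in self.category_counts.iterrows()
            }
        return out


def unique_genes(
    p: GenePresenceMatrix,
    grouping: Mapping[str, Sequence[str]],
    annotation: Optional[Mapping[str, str]] = None,
) -> UniqueGeneReport:
    """Genes uniquely associated with one group under the strict rule:
    present in ALL of the group's samples and absent in ALL other samples;
    any uncertain call disqualifies the gene for that grouping."""
    groups = {g: list(s) for g, s in grouping.items()}
    if len(groups) < 2:
        raise ConfigurationError("unique-gene extraction needs >= 2 groups")
    for g, members in groups.items():
        if not members:
            raise ConfigurationError(f"group {g!r} has no samples")
    calls = p.calls
    unique: Dict[str, List[str]] = {g: [] for g in groups}
    for g, members in groups.items():
        others = [s for gg, mm in groups.items() if gg != g for s in mm]
        in_group = (calls[members] == PRESENT).all(axis=1)
        out_group = (calls[others] == ABSENT).all(axis=1)
        unique[g] = calls.index[in_group & out_group].tolist()
    category_counts = None
    if annotation is not None:
        rows = {}
        for g, genes in unique.items():
            cats = pd.Series([annotation.get(gid, "unannotated") for gid in genes])
            rows[g] = cats.value_counts()
        category_counts = pd.DataFrame(rows).T.fillna(0).astype(int)
        category_counts.index.name = "group"
    return UniqueGeneReport(unique=unique, category_counts=category_counts)
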
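"""End-to-end orchestration: simulate -> map -> variants -> structure ->
genecontent -> markers, as one reproducible run.

A run is driven by a YAML config validated up front (defaults injected,
unknown keys rejected, all problems reported at once). A single top-level
seed deterministically drives every stage, outputs are single-header TSVs
with '#'-prefixed provenance comments, and the RunReport records per-stage
parameters, the site-count ledger of each filter, and a checksum manifest
so re-runs can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import genecontent as gc
from . import mapping as mp
from . import markers as mk
from . import popstruct as ps
from . import simulate as sim
from .errors import ConfigurationError, PipelineError, StageError

STAGES = ("simulate", "map", "variants", "structure", "genecontent", "markers")

_DEFAULTS: Dict[str, Dict[str, object]] = {
    "simulate": {
        "n_demes": 2,
        "fst_target": 0.4,
        "n_core_genes": 80,
        "n_accessory_per_deme": 2,
        "gene_length_range": [900, 1100],
        "n_variant_sites": 2000,
        "strains_per_deme": 40,
        "samples_per_group": 3,
        "lifestyles": ["host_associated", "free_living"],
        "mean_depth": 20.0,
        "read_length": 150,
        "error_rate": 0.005,
        "host_read_fraction": 0.05,
        "lifestyle_drift": 0.0,
        "sample_drift": 0.0,
        "write_reads": False,
        "marker_scenarios": ["gill", "fluid"],
    },
    "inputs": {
        "pangenome": None,
        "metadata": None,
        "reads": {},
        "sam": {},
        "marker_db_dir": None,
        "marker_reads": {},
        "annotation": None,
    },
    "mapping": {"k_map": 21, "max_mismatch_frac": 0.05, "write_sam": False},
    "variants": {
        "min_mean_depth": 10.0,
        "min_site_depth": 10,
        "min_allele_count": 4,
        "noise_allele_max": 2,
        "min_maf": 0.02,
    },
    "structure": {
        "groupings": ["vent_field", "lifestyle", "sample"],
        "bray_curtis_mode": "per_site_freq",
        "n_axes": 2,
        "plots": False,
    },
    "gene_content": {"theta_present": 0.25, "theta_absent": 0.05, "grouping": "vent_field"},
    "markers": {
        "k_marker": 31,
        "min_hit_frac": 0.5,
        "margin": 2.0,
        "fold_threshold": 10.0,
    },
}
_TOP_KEYS = {"seed", "stages", *(k for k in _DEFAULTS)}


@dataclass
class RunConfig:
    seed: int
    stages: List[str]
    sections: Dict[str, Dict[str, object]]
    source: Optional[str] = None

    def __getitem__(self, key: str) -> Dict[str, object]:
        return self.sections[key]

    @property
    def simulate_mode(self) -> bool:
        return self.sections.get("simulate") is not None

    def resolved(self) -> dict:
        return {"seed": self.seed, "stages": self.stages, **self.sections}


def validate_config(source) -> RunConfig:
    """Parse + validate a YAML config (path, YAML string, or dict).

    Defaults are injected, unknown keys rejected, and every problem is
    reported in one ConfigurationError.
    """
    src_name = None
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        src_name = str(source)
        raw = yaml.safe_load(Path(source).read_text()) or {}
    elif isinstance(source, str):
        raw = yaml.safe_load(source) or {}
    elif isinstance(source, Mapping):
        raw = dict(source)
    else:
        raise ConfigurationError(f"cannot read config from {source!r}")

    problems: List[str] = []
    unknown_top = set(raw) - _TOP_KEYS
    if unknown_top:
        problems.append(f"unknown top-level keys: {sorted(unknown_top)}")

    sections: Dict[str, Dict[str, object]] = {}
    for name, defaults in _DEFAULTS.items():
        given = raw.get(name)
        if given is None:
            sections[name] = None if name in ("simulate", "inputs") else dict(defaults)
            continue
        if not isinstance(given, Mapping):
            problems.append(f"section '{name}' must be a mapping")
            continue
        unknown = set(given) - set(defaults)
        if unknown:
            problems.append(f"section '{name}': unknown keys {sorted(unknown)}")
        merged = dict(defaults)
        merged.update({k: v for k, v in given.items() if k in defaults})
        sections[name] = merged

    if sections.get("simulate") is None and sections.get("inputs") is None:
        problems.append("config needs either a 'simulate' or an 'inputs' section")
    if sections.get("simulate") is not None and sections.get("inputs") is not None:
        problems.append("'simulate' and 'inputs' sections are mutually exclusive")

    stages = raw.get("stages", list(STAGES))
    if not isinstance(stages, (list, tuple)) or any(s not in STAGES for s in stages):
        problems.append(f"stages must be a subset of {STAGES}")
        stages = list(STAGES)
    stages = [s for s in STAGES if s in stages]

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        problems.append("seed must be an integer")
        seed = 0

    g = sections.get("gene_content") or _DEFAULTS["gene_content"]
    if g["theta_absent"] >= g["theta_present"]:
        problems.append("gene_content: theta_absent must be < theta_present")
    v = sections.get("variants") or _DEFAULTS["variants"]
    if not 0 <= float(v["min_maf"]) <= 0.5:
        problems.append("variants: min_maf must be in [0, 0.5]")
    if float(v["min_site_depth"]) < 1:
        problems.append("variants: min_site_depth must be >= 1")
    s = sections.get("simulate")
    if s is not None:
        if not 0 <= float(s["fst_target"]) < 1:
            problems.append("simulate: fst_target must be in [0, 1)")
        if not 0 <= float(s["error_rate"]) < 0.5:
            problems.append("simulate: error_rate must be in [0, 0.5)")

    inputs = sections.get("inputs")
    metadata = None
    if inputs is not None:
        for key in ("pangenome", "metadata"):
            if not inputs.get(key):
                problems.append(f"inputs: '{key}' is required")
            elif not Path(str(inputs[key])).exists():
                problems.append(f"inputs: {key} path does not exist: {inputs[key]}")
        if not inputs.get("reads") and not inputs.get("sam"):
            problems.append("inputs: provide per-sample 'reads' (FASTQ) or 'sam'")
        for key in ("reads", "sam", "marker_reads"):
            for sample, p in (inputs.get(key) or {}).items():
                if not Path(str(p)).exists():
                    problems.append(f"inputs: {key}[{sample}] path does not exist: {p}")
        if inputs.get("metadata") and Path(str(inputs["metadata"])).exists():
            metadata = pd.read_csv(inputs["metadata"], sep="\t")
            if metadata["sample_id"].duplicated().any():
                dups = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"]
                problems.append(f"metadata: duplicate sample_id(s): {sorted(set(dups))}")

    if problems:
        raise ConfigurationError("invalid configuration:\n- " + "\n- ".join(problems))
    return RunConfig(seed=seed, stages=list(stages), sections=sections, source=src_name)


# ---------------------------------------------------------------------------
# Run report plumbing
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    seed: int
    stages: Dict[str, dict] = dc_field(default_factory=dict)
    site_ledger: Dict[str, int] = dc_field(default_factory=dict)
    manifest: Dict[str, str] = dc_field(default_factory=dict)
    retained_samples: List[str] = dc_field(default_factory=list)
    low_coverage_samples: List[str] = dc_field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "version": _version,
            "seed": self.seed,
            "stages": self.stages,
            "site_ledger": self.site_ledger,
            "retained_samples": self.retained_samples,
            "low_coverage_samples": self.low_coverage_samples,
            "manifest": self.manifest,
        }


class _Out:
    """Output-directory helper: provenance-commented TSVs, checksums, and
    .partial suffixes for files interrupted mid-write."""

    def __init__(self, out_dir: Path, report: RunReport):
        self.dir = Path(out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.report = report

    def write_tsv(self, name: str, render, provenance: str) -> Path:
        path = self.dir / name
        partial = path.with_suffix(path.suffix + ".partial")
        with open(partial, "w") as fh:
            fh.write(f"# symbiopop {_version} | {provenance}\n")
        # render appends the table under the provenance comment
        with open(partial, "a") as fh:
            render(fh)
        partial.rename(path)
        self.report.manifest[name] = _sha256(path)
        return path

    def write_json(self, name: str, payload: dict, manifest: bool = True) -> Path:
        path = self.dir / name
        partial = path.with_suffix(path.suffix + ".partial")
        partial.write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))
        partial.rename(path)
        if manifest:
            self.report.manifest[name] = _sha256(path)
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(verbose: bool, stage: str, msg: str) -> None:
    if verbose:
        print(f"{time.strftime('%H:%M:%S')} [{stage}] {msg}", flush=True)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    config: RunConfig,
    out_dir,
    seed: Optional[int] = None,
    stages: Optional[Sequence[str]] = None,
    verbose: bool = False,
) -> RunReport:
    """Execute the configured stages in order and write a RunReport JSON.

    Stage failures raise StageError carrying the stage name; files being
    written when a stage fails keep a .partial suffix. Low-coverage samples
    are excluded from the primary variant run and re-analysed on the
    restricted site set covered in them.
    """
    seed = config.seed if seed is None else int(seed)
    run_stages = [s for s in STAGES if s in (stages or config.stages)]
    report = RunReport(seed=seed)
    out = _Out(Path(out_dir), report)

    state: Dict[str, object] = {}
    for stage in run_stages:
        t0 = time.time()
        _log(verbose, stage, "start")
        try:
            _STAGE_FUNCS[stage](config, state, out, seed, report)
        except (ConfigurationError, PipelineError, StageError):
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(stage, str(exc)) from exc
        report.stages.setdefault(stage, {})["elapsed_s"] = round(time.time() - t0, 3)
        _log(verbose, stage, f"done in {report.stages[stage]['elapsed_s']}s")

    # the report carries wall-clock timings, so it is not part of the
    # byte-reproducibility manifest it describes
    out.write_json("run_report.json", report.to_json_dict(), manifest=False)
    out.write_json("resolved_config.json", config.resolved())
    return report


def _stage_simulate(config, state, out, seed, report):
    s = config["simulate"]
    if s is None:
        raise StageError("simulate", "no 'simulate' section in config")
    cfg = sim.study_config(
        n_demes=int(s["n_demes"]),
        fst_target=float(s["fst_target"]),
        n_core_genes=int(s["n_core_genes"]),
        n_accessory_per_deme=int(s["n_accessory_per_deme"]),
        gene_length_range=tuple(s["gene_length_range"]),
        n_variant_sites=int(s["n_variant_sites"]),
        strains_per_deme=int(s["strains_per_deme"]),
        samples_per_group=int(s["samples_per_group"]),
        lifestyles=tuple(s["lifestyles"]),
        mean_depth=float(s["mean_depth"]),
        read_length=int(s["read_length"]),
        error_rate=float(s["error_rate"]),
        host_read_fraction=float(s["host_read_fraction"]),
        lifestyle_drift=float(s["lifestyle_drift"]),
        sample_drift=float(s["sample_drift"]),
        seed=seed,
    )
    pangenome, reads, truth = sim.simulate_study(cfg)
    state.update(
        sim_config=cfg, pangenome=pangenome, reads=reads, truth=truth,
        metadata=pd.DataFrame(
            {
                "sample_id": [x.sample_id for x in cfg.samples],
                "vent_field": [x.vent_field for x in cfg.samples],
                "lifestyle": [x.lifestyle for x in cfg.samples],
                "deme": [x.deme for x in cfg.samples],
            }
        ),
        annotation={
            g.gene_id: g.category_label
            for g in pangenome.genes
            if g.category_label is not None
        },
    )
    pangenome.to_fasta(out.dir / "pangenome.fasta")
    report.manifest["pangenome.fasta"] = _sha256(out.dir / "pangenome.fasta")
    sim.write_metadata(cfg.samples, out.dir / "metadata.tsv")
    report.manifest["metadata.tsv"] = _sha256(out.dir / "metadata.tsv")
    truth.to_json(out.dir / "truth.json")
    if s["write_reads"]:
        for sample_id, rr in reads.items():
            sim.write_fastq(rr, out.dir / f"{sample_id}.fastq")
    report.stages["simulate"] = {
        "n_samples": len(cfg.samples),
        "n_genes": len(pangenome.genes),
        "n_variant_sites_planted": cfg.n_variant_sites,
        "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in s.items()},
    }


def _stage_map(config, state, out, seed, report):
    m = config["mapping"]
    pangenome = state.get("pangenome")
    inputs = config.sections.get("inputs")
    if pangenome is None:
        if inputs is None:
            raise StageError("map", "no pangenome available (simulate stage or inputs)")
        pangenome = sim.PangenomeReference(
            [sim.Gene(n, s, "core") for n, s in sim.read_fasta(inputs["pangenome"])]
        )
        state["pangenome"] = pangenome
        state["metadata"] = pd.read_csv(inputs["metadata"], sep="\t")
    alignments: Dict[str, mp.AlignmentSet] = {}
    if inputs is not None and inputs.get("sam"):
        for sample_id, path in inputs["sam"].items():
            alignments[sample_id] = mp.read_sam(path, pangenome, sample_id=sample_id)
    else:
        index = mp.PangenomeIndex(pangenome, int(m["k_map"]))
        reads_by_sample = state.get("reads")
        if reads_by_sample is None:
            reads_by_sample = {
                sample_id: sim.read_fastq(path)
                for sample_id, path in inputs["reads"].items()
            }
        for sample_id, rr in reads_by_sample.items():
            alignments[sample_id] = mp.map_reads(
                rr,
                pangenome,
                max_mismatch_frac=float(m["max_mismatch_frac"]),
                k_map=int(m["k_map"]),
                sample_id=sample_id,
                index=index,
            )
    state["alignments"] = alignments
    stats = pd.DataFrame({s: a.stats for s, a in alignments.items()}).T
    stats.index.name = "sample_id"
    out.write_tsv("mapping_stats.tsv", lambda fh: stats.to_csv(fh, sep="\t"), "map stage")
    if m["write_sam"]:
        for sample_id, aset in alignments.items():
            mp.write_sam(aset, pangenome, out.dir / f"{sample_id}.sam")
    report.stages["map"] = {"params": dict(m), "n_samples": len(alignments)}


def _stage_variants(config, state, out, seed, report):
    v = config["variants"]
    pangenome = state["pangenome"]
    alignments = state["alignments"]
    ncm, coverage = mp.pileup_counts(alignments, pangenome)
    out.write_tsv(
        "coverage.tsv", lambda fh: coverage.to_csv(fh, sep="\t", float_format="%.4f"),
        "variants stage: coverage summary",
    )
    qc = mp.sample_qc(coverage, float(v["min_mean_depth"]))
    report.retained_samples = qc.retained
    report.low_coverage_samples = qc.low_coverage
    filters = mp.VariantFilters(
        min_site_depth=int(v["min_site_depth"]),
        min_allele_count=int(v["min_allele_count"]),
        noise_allele_max=int(v["noise_allele_max"]),
        min_maf=float(v["min_maf"]),
    )
    vt = mp.call_variants(ncm, qc.retained, filters)
    state.update(ncm=ncm, coverage=coverage, qc=qc, variants=vt)
    out.write_tsv(
        "variants.tsv", lambda fh: _df_tsv(vt, fh), "variants stage: filtered biallelic sites"
    )
    report.site_ledger.update(
        candidate_sites=int(len(ncm.positions)), variant_sites=int(vt.n_sites)
    )
    # Secondary restricted-site analysis including low-coverage samples.
    if qc.low_coverage:
        all_samples = qc.retained + qc.low_coverage
        vt_low = mp.call_variants(ncm, all_samples, filters)
        state["variants_lowcov"] = vt_low
        out.write_tsv(
            "variants_lowcov.tsv",
            lambda fh: _df_tsv(vt_low, fh),
            "variants stage: restricted sites incl. low-coverage samples",
        )
        report.site_ledger["variant_sites_lowcov"] = int(vt_low.n_sites)
    report.stages["variants"] = {
        "params": dict(v),
        "retained": qc.retained,
        "low_coverage": qc.low_coverage,
    }


def _df_tsv(vt, fh):
    import io

    buf = io.StringIO()
    vt.to_tsv(buf)
    fh.write(buf.getvalue())


def _stage_structure(config, state, out, seed, report):
    st = config["structure"]
    vt = state.get("variants")
    inputs = config.sections.get("inputs")
    if vt is None and inputs is not None:
        # allow `--stages structure` on a precomputed VariantTable
        pre = Path(out.dir) / "variants.tsv"
        if pre.exists():
            vt = mp.VariantTable.from_tsv(pre)
            state["variants"] = vt
    if vt is None:
        raise StageError("structure", "no VariantTable available")
    metadata = state.get("metadata")
    if metadata is None and inputs is not None and inputs.get("metadata"):
        metadata = pd.read_csv(inputs["metadata"], sep="\t")
        state["metadata"] = metadata
    if metadata is None:
        raise StageError("structure", "no sample metadata available")
    md = metadata[metadata["sample_id"].isin(vt.samples)]
    results = {}
    for grouping in st["groupings"]:
        groups = ps.make_groups(md, grouping)
        if len(groups) < 2:
            continue
        res = ps.pairwise_fst(vt, groups)
        results[grouping] = res
        out.write_tsv(
            f"fst_{grouping}.tsv",
            lambda fh, r=res: r.fst.to_csv(fh, sep="\t", float_format="%.6g"),
            f"structure stage: pooled-by-{grouping} Hudson F_ST",
        )
    bc = ps.bray_curtis_from_variants(vt, st["bray_curtis_mode"])
    coords = ps.pcoa(bc, n_axes=int(st["n_axes"]))
    out.write_tsv(
        "bray_curtis.tsv", lambda fh: bc.to_dataframe().to_csv(fh, sep="\t", float_format="%.6g"),
        "structure stage: Bray-Curtis on per-site allele proportions",
    )
    out.write_tsv(
        "pcoa_bray_curtis.tsv", lambda fh: coords.coordinates.to_csv(fh, sep="\t", float_format="%.6g"),
        "structure stage: PCoA of Bray-Curtis distances",
    )
    state.update(fst_results=results, bray_curtis=bc, pcoa=coords)
    if st["plots"]:
        from . import plots

        for grouping, res in results.items():
            plots.fst_heatmap(res, out.dir / f"fst_{grouping}.svg")
        hue = dict(zip(md["sample_id"], md["vent_field"]))
        plots.pcoa_scatter(coords, out.dir / "pcoa_bray_curtis.svg", hue=hue)
    report.stages["structure"] = {
        "params": {k: v for k, v in st.items()},
        "fst_groupings": list(results),
    }


def _stage_genecontent(config, state, out, seed, report):
    g = config["gene_content"]
    pangenome = state["pangenome"]
    alignments = state["alignments"]
    metadata = state["metadata"]
    depths = gc.gene_depths(alignments, pangenome)
    presence = gc.call_presence(
        depths, float(g["theta_present"]), float(g["theta_absent"])
    )
    out.write_tsv(
        "gene_depth.tsv", lambda fh: depths.to_csv(fh, sep="\t", float_format="%.4f"),
        "genecontent stage: mean per-base depth per gene",
    )
    out.write_tsv(
        "gene_presence.tsv", lambda fh: _presence_tsv(presence, fh),
        "genecontent stage: presence(1)/absence(0)/uncertain(NA) calls",
    )
    jac = gc.jaccard_matrix(presence)
    coords = ps.pcoa(jac, n_axes=min(2, len(jac.labels) - 1))
    out.write_tsv(
        "pcoa_jaccard.tsv", lambda fh: coords.coordinates.to_csv(fh, sep="\t", float_format="%.6g"),
        "genecontent stage: PCoA of Jaccard distances",
    )
    groups = ps.make_groups(metadata, str(g["grouping"]))
    annotation = state.get("annotation")
    inputs = config.sections.get("inputs")
    if annotation is None and inputs is not None and inputs.get("annotation"):
        ann = pd.read_csv(inputs["annotation"], sep="\t")
        annotation = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))
    ug = gc.unique_genes(presence, groups, annotation)
    out.write_tsv(
        f"unique_genes_{g['grouping']}.tsv", lambda fh: _unique_tsv(ug, fh),
        f"genecontent stage: genes unique per {g['grouping']}",
    )
    out.write_json(f"unique_genes_{g['grouping']}.json", ug.to_json_dict())
    state.update(gene_depths=depths, presence=presence, jaccard=jac, unique=ug)
    report.stages["genecontent"] = {
        "params": dict(g),
        "unique_counts": {k: len(v) for k, v in ug.unique.items()},
    }


def _presence_tsv(presence, fh):
    import io

    buf = io.StringIO()
    presence.to_tsv(buf)
    fh.write(buf.getvalue())


def _unique_tsv(ug, fh):
    import io

    buf = io.StringIO()
    ug.to_tsv(buf)
    fh.write(buf.getvalue())


def _stage_markers(config, state, out, seed, report):
    m = config["markers"]
    inputs = config.sections.get("inputs")
    rows = {}
    origins = {}
    if config.simulate_mode:
        # Scenario-based validation against generated marker sets.
        for scenario in config["simulate"]["marker_scenarios"]:
            msim = sim.generate_marker_read_sets(scenario, seed=seed)
            db = mk.build_marker_index(msim.databases, int(m["k_marker"]))
            counts = mk.classify_reads(
                msim.reads, db, float(m["min_hit_frac"]), float(m["margin"])
            )
            rows[scenario] = mk.marker_ratio(counts)
            origins[scenario] = "host_associated" if scenario == "gill" else "free_living"
    else:
        if not inputs or not inputs.get("marker_db_dir") or not inputs.get("marker_reads"):
            report.stages["markers"] = {"skipped": "no marker inputs configured"}
            return
        db_dir = Path(inputs["marker_db_dir"])
        seqs = {
            cat: sim.read_fasta(db_dir / f"{cat}.fasta") for cat in mk.CATEGORIES
        }
        db = mk.build_marker_index(seqs, int(m["k_marker"]))
        metadata = state.get("metadata")
        lifestyle = (
            dict(zip(metadata["sample_id"], metadata["lifestyle"]))
            if metadata is not None
            else {}
        )
        for sample_id, path in inputs["marker_reads"].items():
            counts = mk.classify_reads(
                sim.read_fastq(path), db, float(m["min_hit_frac"]), float(m["margin"])
            )
            rows[sample_id] = mk.marker_ratio(counts)
            origins[sample_id] = lifestyle.get(sample_id, "unknown")
    df = mk.marker_report(rows, origins)
    try:
        df["free_living_signal"] = mk.flag_lifestyle(df, float(m["fold_threshold"]))
    except ConfigurationError:
        df["free_living_signal"] = pd.NA
    out.write_tsv(
        "marker_report.tsv", lambda fh: df.to_csv(fh, sep="\t", float_format="%.6g"),
        "markers stage: unambiguous 16S/CO1 percentages and ratio",
    )
    state["marker_report"] = df
    report.stages["markers"] = {"params": dict(m), "n_rows": len(df)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "map": _stage_map,
    "variants": _stage_variants,
    "structure": _stage_structure,
    "genecontent": _stage_genecontent,
    "markers": _stage_markers,
}
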
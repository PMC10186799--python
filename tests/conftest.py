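"""Shared fixtures: small synthetic studies run once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import symbiopop as sp


def run_study(cfg: sp.SimulationConfig) -> dict:
    """Simulate + map + pileup + QC for a config; returns all intermediates."""
    pangenome, reads, truth = sp.simulate_study(cfg)
    index = sp.PangenomeIndex(pangenome)
    asets = {
        s: sp.map_reads(r, pangenome, sample_id=s, index=index)
        for s, r in reads.items()
    }
    ncm, coverage = sp.pileup_counts(asets, pangenome)
    qc = sp.sample_qc(coverage)
    metadata = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in cfg.samples],
            "vent_field": [s.vent_field for s in cfg.samples],
            "lifestyle": [s.lifestyle for s in cfg.samples],
            "deme": [s.deme for s in cfg.samples],
        }
    )
    return {
        "config": cfg,
        "pangenome": pangenome,
        "reads": reads,
        "truth": truth,
        "alignments": asets,
        "ncm": ncm,
        "coverage": coverage,
        "qc": qc,
        "metadata": metadata,
    }


@pytest.fixture(scope="session")
def study_clean() -> dict:
    """Error-free study: 2 demes x 2 lifestyles x 2 samples, 2 accessory genes
    per deme — gene content and read origins are exactly recoverable."""
    cfg = sp.study_config(
        n_core_genes=10,
        n_accessory_per_deme=2,
        n_variant_sites=200,
        strains_per_deme=10,
        samples_per_group=2,
        lifestyles=("host_associated", "free_living"),
        mean_depth=20.0,
        error_rate=0.0,
        host_read_fraction=0.0,
        seed=42,
    )
    return run_study(cfg)


@pytest.fixture(scope="session")
def study_recovery() -> dict:
    """Panmictic study (F = 0) with realistic error/host contamination for
    measuring variant-site recovery and coverage calibration."""
    cfg = sp.study_config(
        fst_target=0.0,
        n_variant_sites=2000,
        samples_per_group=2,
        lifestyles=("host_associated",),
        error_rate=0.005,
        host_read_fraction=0.05,
        seed=7,
    )
    return run_study(cfg)


@pytest.fixture(scope="session")
def variants_recovery(study_recovery) -> sp.VariantTable:
    return sp.call_variants(study_recovery["ncm"], study_recovery["qc"].retained)
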
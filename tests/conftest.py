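"""Shared fixtures: small synthetic cohorts sized for fast tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rarecnv.core import PC_COLUMNS
from rarecnv.synthetic import ScenarioConfig, StudySpec, VariantSpec


def make_sheet(n: int, studies=("s1", "s2"), seed: int = 0, case_fraction: float = 0.5):
    """Minimal valid sample sheet with random PCs and labels."""
    rng = np.random.default_rng(seed)
    study = np.asarray(studies)[rng.integers(0, len(studies), n)]
    sheet = pd.DataFrame(
        {
            "sample_id": [f"smp{i:05d}" for i in range(n)],
            "study": study,
            "array": "dense",
            "status": np.where(rng.random(n) < case_fraction, "case", "control"),
            "er_status": rng.choice(["positive", "negative"], n),
            "triple_negative": False,
        }
    )
    for c in PC_COLUMNS:
        sheet[c] = rng.normal(0, 1, n)
    sheet["call_rate"] = 0.999
    sheet["blood_source"] = True
    sheet["wga"] = False
    return sheet


@pytest.fixture(scope="session")
def calling_scenario():
    """Cohort with strong planted deletions/duplications (noise level at
    which the z-windows are comfortably reachable)."""
    variants = [
        VariantSpec("1", 2_000_000 + i * 3_200_000, 2_000_000 + i * 3_200_000 + 1_100_000,
                    "deletion", 0.04, 0.0)
        for i in range(4)
    ] + [
        VariantSpec("2", 2_000_000 + i * 3_200_000, 2_000_000 + i * 3_200_000 + 1_200_000,
                    "duplication", 0.04, 0.0)
        for i in range(4)
    ]
    # batch components dominate the top principal directions (as in real
    # data), so the per-study PCA removes batch rather than CNV signal
    return ScenarioConfig(
        chromosome_lengths={"1": 30_000_000, "2": 30_000_000},
        arrays={"dense": 300},
        studies=[StudySpec("s1", 200, "dense"), StudySpec("s2", 200, "dense")],
        variants=variants,
        noise_sd=0.07,
        shift_del=-0.8,
        shift_dup=0.55,
        batch_components=2,
        batch_scale=0.1,
    )


@pytest.fixture(scope="session")
def called_cohort(calling_scenario):
    """Simulate + call once per session; reused by calling/region tests."""
    from rarecnv.calling import CallingParams, call_cnvs
    from rarecnv.synthetic import generate_truth_cohort, simulate_intensity_panel

    cfg = calling_scenario
    probe_maps, sheet, truth = generate_truth_cohort(cfg, seed=11)
    panel = simulate_intensity_panel(
        probe_maps["dense"], sheet, truth,
        noise_sd=cfg.noise_sd, shift_del=cfg.shift_del, shift_dup=cfg.shift_dup,
        batch_components=cfg.batch_components, batch_scale=cfg.batch_scale,
        seed=12,
    )
    params = CallingParams(n_components=2, noisy_probe_percentile=100.0, seed=13)
    result = call_cnvs(panel, probe_maps["dense"], sheet, params)
    return {
        "config": cfg,
        "probe_map": probe_maps["dense"],
        "sheet": sheet,
        "truth": truth,
        "panel": panel,
        "params": params,
        "result": result,
    }
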
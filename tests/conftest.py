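"""Shared fixtures: small synthetic studies and pooled multi-seed
pipeline runs used by the error-control and negative-control tests."""

from __future__ import annotations

import pytest

from glycopipe.glycans import Pathway
from glycopipe.pipeline import run_pipeline
from glycopipe.synthetic_data import GeneratorConfig, generate_dataset

N_SEEDS = 20


def run_one_study(seed: int, cfg: GeneratorConfig | None = None) -> dict:
    """Generate one synthetic study, run the pipeline, and score the
    accepted glycopeptidoforms against the planted ground truth."""
    cfg = cfg or GeneratorConfig(seed=seed)
    proteins, buckets, truth = generate_dataset(cfg)
    spectra = [s for spectra in buckets.values() for s in spectra]
    result = run_pipeline(proteins, spectra)
    per_strain = {}
    for strain, res in result.per_strain.items():
        accepted = {g.key for g in res.cascade.accepted_glyco}
        eligible = truth.eligible_glyco_keys(strain)
        planted = truth.planted_glyco_keys(strain)
        aglb_accepted = sum(
            1
            for g in res.cascade.accepted_glyco
            if any(
                glycan.pathway is Pathway.AglB
                for _, glycan in g.psms[0].peptidoform.glyco_mods
            )
        )
        per_strain[strain] = {
            "n_accepted": len(accepted),
            "n_eligible": len(eligible),
            "n_true": len(accepted & eligible),
            "n_false": len(accepted - planted),
            "n_aglb_accepted": aglb_accepted,
            "stage_counts": res.cascade.stage_counts,
        }
    return per_strain


@pytest.fixture(scope="session")
def multi_seed_runs() -> list[dict]:
    """Twenty seeded end-to-end runs at default generator settings,
    shared by the recall, error-control and knockout-strain tests."""
    return [run_one_study(seed) for seed in range(1, N_SEEDS + 1)]
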
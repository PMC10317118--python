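import numpy as np
import pytest
from hypothesis import settings

from strmutator import founders as finf
from strmutator.sim import (
    BreedingPlan,
    MutationModelParams,
    generate_founders,
    render_panel,
    simulate_panel,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """Error-free 30-strain panel with a known mutator locus on chr2.

    Shared across inference/calling/phenotype/pattern tests; treat as
    read-only.
    """
    panel, mm = generate_founders(3, 100, 400, seed=101)
    mutator = mm.df["marker"].iloc[150]  # mid chr2
    model = MutationModelParams(
        expansion_prob_B=0.7, expansion_prob_D=0.3, mutator_locus=mutator
    )
    plan = BreedingPlan([("e1", 10, 30), ("e2", 10, 50), ("e3", 10, 70)], seed=202)
    genomes, meta = simulate_panel(panel, mm, plan, model)
    tables, truth = render_panel(genomes, panel, mm, meta, seed=303)
    return {
        "panel": panel,
        "marker_map": mm,
        "model": model,
        "mutator": mutator,
        "genomes": genomes,
        "metadata": meta,
        "tables": tables,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_inferred(small_sim):
    """Founder inference chain on the shared panel."""
    panel = small_sim["panel"]
    tables = small_sim["tables"]
    track0 = finf.assign_founder_labels(tables.snp_calls, panel, small_sim["marker_map"])
    tracks = finf.impute_missing_labels(track0)
    blocks = finf.build_blocks(tracks)
    labels = finf.assign_locus_labels(
        blocks, panel.str_reference, tables.str_genotypes.strains
    )
    resolved, dropped = finf.infer_missing_founder_strs(
        panel.reported_str_reference(), tables.str_genotypes, labels
    )
    return {
        "tracks": tracks,
        "blocks": blocks,
        "locus_labels": labels,
        "resolved": resolved,
        "dropped": dropped,
    }
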